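"""Virus-host linkage on four evidence channels.

A virus unit is linked to a prokaryotic bin when any of these fires:

1. homology — a local alignment between a viral and a host scaffold with
   identity >= 70% over >= 2.5 kb (per alignment);
2. crispr — a CRISPR spacer (> 6 bp) from the host bin matches a viral
   scaffold exactly, on either strand;
3. trna — a viral tRNA gene is identical, full length, to a host tRNA;
4. kmer — the virus and the host bin share at least ``min_shared``
   distinct canonical 25-mers.

Channels are integrated by logical OR into virus-host pairs, and pairs
are projected onto population-level groups as connected components of
the bipartite virus-population / host-population graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from . import seq_core
from .seq_core import SequenceRecord


@dataclass
class CrisprParams:
    min_repeat_len: int = 19
    max_repeat_len: int = 48
    min_spacer_len: int = 19
    max_spacer_len: int = 48
    min_repeats: int = 3


@dataclass
class CrisprArray:
    """One CRISPR array: >= 3 exact repeat copies with admissible spacers."""

    scaffold_id: str
    repeat_seq: str
    spacers: list
    positions: list  # repeat start positions

    def __post_init__(self) -> None:
        if len(self.positions) < 3:
            raise ValueError("a CRISPR array needs >= 3 repeat copies")


@dataclass
class EvidenceLink:
    virus_unit_id: str
    host_bin_id: str
    channel: str  # homology | crispr | trna | kmer
    stat: dict


@dataclass
class VirusHostPair:
    virus_unit_id: str
    host_bin_id: str
    channels: set
    links: list


# ---------------------------------------------------------------------------
# CRISPR array detection (CRT-style, exact repeats)


def detect_crispr_arrays(
    scaffold: SequenceRecord | str, params: CrisprParams | None = None
) -> list[CrisprArray]:
    """Greedy left-to-right scan for arrays of exact repeat copies.

    At each start position candidate repeat lengths are tried longest
    first; the first length that chains >= ``min_repeats`` copies with
    spacer lengths inside the admissible window wins, and the scan resumes
    past the array.
    """
    params = params or CrisprParams()
    sid = scaffold.id if isinstance(scaffold, SequenceRecord) else "scaffold"
    seq = scaffold.seq if isinstance(scaffold, SequenceRecord) else scaffold.upper()
    n = len(seq)
    k = params.min_repeat_len
    max_period = params.max_repeat_len + params.max_spacer_len
    # prescan: a repeat start must have its leading k-mer recur within one
    # array period; positions without that recurrence are skipped outright
    kmer_pos: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        kmer_pos.setdefault(seq[i : i + k], []).append(i)

    def is_candidate(i: int) -> bool:
        positions = kmer_pos.get(seq[i : i + k], [])
        return any(i < j <= i + max_period for j in positions)

    arrays: list[CrisprArray] = []
    i = 0
    while i < n - params.min_repeat_len:
        if not is_candidate(i):
            i += 1
            continue
        # among admissible repeat lengths keep the one chaining the most
        # copies; ties go to the longest repeat
        found = None
        for L in range(params.max_repeat_len, params.min_repeat_len - 1, -1):
            if i + L > n:
                continue
            repeat = seq[i : i + L]
            if "N" in repeat:
                continue
            positions = [i]
            cursor = i
            while True:
                nxt = seq.find(repeat, cursor + L)
                if nxt == -1:
                    break
                spacer_len = nxt - (cursor + L)
                # the literal inter-repeat substring must be admissible: a
                # tandem (0 bp spacer) is not an array
                if not params.min_spacer_len <= spacer_len <= params.max_spacer_len:
                    break
                positions.append(nxt)
                cursor = nxt
            if len(positions) >= params.min_repeats and (
                found is None or len(positions) > len(found[1])
            ):
                found = (repeat, positions)
        if found:
            repeat, positions = found
            L = len(repeat)
            spacers = [
                seq[positions[k] + L : positions[k + 1]]
                for k in range(len(positions) - 1)
            ]
            arrays.append(CrisprArray(sid, repeat, spacers, positions))
            i = positions[-1] + L
        else:
            i += 1
    return arrays


# ---------------------------------------------------------------------------
# Channels


def link_by_spacers(
    arrays: list, virus_scaffolds: list, virus_unit_id: str, host_bin_id: str,
    min_spacer_len: int = 7,
) -> EvidenceLink | None:
    """Exact spacer-to-virus match on either strand; spacers must be > 6 bp."""
    n_hits = 0
    matched = []
    for array in arrays:
        for spacer in array.spacers:
            if len(spacer) < min_spacer_len:
                continue
            for rec in virus_scaffolds:
                if seq_core.find_exact_matches(spacer, rec, both_strands=True):
                    n_hits += 1
                    matched.append(spacer)
                    break
    if n_hits == 0:
        return None
    return EvidenceLink(
        virus_unit_id, host_bin_id, "crispr",
        stat=dict(n_spacer_hits=n_hits),
    )


def link_by_homology(
    virus_scaffolds: list, host_scaffolds: list,
    virus_unit_id: str, host_bin_id: str,
    min_identity: float = 0.70, min_len: int = 2500, seed_k: int = 13,
) -> EvidenceLink | None:
    """Any viral x host scaffold alignment passing both thresholds."""
    best = None
    for v in virus_scaffolds:
        for h in host_scaffolds:
            for aln in seq_core.local_align(
                v, h, seed_k=seed_k, min_identity=min_identity, min_len=min_len
            ):
                if best is None or aln.identity * aln.aln_len > best.identity * best.aln_len:
                    best = aln
    if best is None:
        return None
    return EvidenceLink(
        virus_unit_id, host_bin_id, "homology",
        stat=dict(identity=round(best.identity, 4), aln_len=best.aln_len),
    )


def link_by_trna(
    virus_genes: pd.DataFrame, host_genes: pd.DataFrame,
    virus_unit_id: str, host_bin_id: str,
) -> EvidenceLink | None:
    """Full-length identical tRNA shared between virus and host (either
    strand). Gene tables need ``gene_type`` and ``seq`` columns."""
    v_trnas = [s for s in virus_genes.loc[virus_genes.gene_type == "trna", "seq"] if s]
    h_trnas = {s for s in host_genes.loc[host_genes.gene_type == "trna", "seq"] if s}
    h_trnas |= {seq_core.reverse_complement(s) for s in set(h_trnas)}
    n = sum(1 for s in v_trnas if s in h_trnas)
    if n == 0:
        return None
    return EvidenceLink(
        virus_unit_id, host_bin_id, "trna", stat=dict(n_trna_hits=n)
    )


def link_by_kmers(
    virus_scaffolds: list, host_scaffolds: list,
    virus_unit_id: str, host_bin_id: str,
    k: int = 25, min_shared: int = 10,
    _kmer_cache: dict | None = None,
) -> EvidenceLink | None:
    """Count distinct canonical k-mers present on both sides."""

    def kmers_of(recs):
        out = set()
        for r in recs:
            if _kmer_cache is not None and r.id in _kmer_cache:
                out |= _kmer_cache[r.id]
            else:
                km = seq_core.canonical_kmers(r.seq, k)
                if _kmer_cache is not None:
                    _kmer_cache[r.id] = km
                out |= km
        return out

    shared = len(kmers_of(virus_scaffolds) & kmers_of(host_scaffolds))
    if shared < min_shared:
        return None
    return EvidenceLink(
        virus_unit_id, host_bin_id, "kmer", stat=dict(n_shared_kmers=shared)
    )


# ---------------------------------------------------------------------------
# Integration


def integrate_pairs(links: list) -> list:
    """OR-integrate evidence links into deduplicated virus-host pairs,
    ordered by (virus, host)."""
    by_pair: dict[tuple[str, str], list] = {}
    for link in links:
        by_pair.setdefault((link.virus_unit_id, link.host_bin_id), []).append(link)
    pairs = []
    for (v, h) in sorted(by_pair):
        pl = by_pair[(v, h)]
        pairs.append(
            VirusHostPair(v, h, channels={l.channel for l in pl}, links=pl)
        )
    return pairs


def link_community(
    viral_units: list,
    host_bins: dict,
    scaffold_seqs: dict,
    gene_table: pd.DataFrame,
    min_identity: float = 0.70,
    min_len: int = 2500,
    k: int = 25,
    min_shared: int = 10,
    min_spacer_len: int = 7,
    crispr_params: CrisprParams | None = None,
) -> list:
    """Run all four channels for every viral unit x host bin.

    ``host_bins`` maps bin_id to member scaffold ids; ``scaffold_seqs``
    maps scaffold id to SequenceRecord. Self-matches (a provirus scaffold
    that is itself a member of the host bin) are excluded.
    """
    links: list[EvidenceLink] = []
    kmer_cache: dict = {}
    arrays_by_bin = {}
    genes_by_scaffold = (
        dict(tuple(gene_table.groupby("scaffold"))) if len(gene_table) else {}
    )
    for bin_id in sorted(host_bins):
        arrays = []
        for sid in host_bins[bin_id]:
            if sid in scaffold_seqs:
                arrays.extend(detect_crispr_arrays(scaffold_seqs[sid], crispr_params))
        arrays_by_bin[bin_id] = arrays

    empty = pd.DataFrame(columns=["gene_id", "gene_type", "seq"])
    for unit in sorted(viral_units, key=lambda u: u.unit_id):
        v_recs = [scaffold_seqs[s] for s in unit.scaffolds if s in scaffold_seqs]
        v_genes = pd.concat(
            [genes_by_scaffold.get(s, empty) for s in unit.scaffolds]
        ) if unit.scaffolds else empty
        for bin_id in sorted(host_bins):
            members = [s for s in host_bins[bin_id]]
            if set(unit.scaffolds) & set(members):
                continue  # provirus inside its own host bin
            h_recs = [scaffold_seqs[s] for s in members if s in scaffold_seqs]
            h_genes = pd.concat(
                [genes_by_scaffold.get(s, empty) for s in members]
            ) if members else empty
            for fn in (
                lambda: link_by_homology(
                    v_recs, h_recs, unit.unit_id, bin_id, min_identity, min_len
                ),
                lambda: link_by_spacers(
                    arrays_by_bin[bin_id], v_recs, unit.unit_id, bin_id, min_spacer_len
                ),
                lambda: link_by_trna(v_genes, h_genes, unit.unit_id, bin_id),
                lambda: link_by_kmers(
                    v_recs, h_recs, unit.unit_id, bin_id, k, min_shared, kmer_cache
                ),
            ):
                link = fn()
                if link is not None:
                    links.append(link)
    return integrate_pairs(links)


def pairs_to_table(pairs: list) -> pd.DataFrame:
    rows = []
    for p in pairs:
        stats = {}
        for l in p.links:
            stats.update(l.stat)
        rows.append(
            dict(
                virus_unit=p.virus_unit_id,
                host_bin=p.host_bin_id,
                channels=",".join(sorted(p.channels)),
                stats=";".join(f"{k}={v}" for k, v in sorted(stats.items())),
            )
        )
    return pd.DataFrame(rows, columns=["virus_unit", "host_bin", "channels", "stats"])


# ---------------------------------------------------------------------------
# Pair network


def pair_network_components(
    pairs: list, virus_pop_of: dict, host_pop_of: dict
) -> tuple[list, int]:
    """Connected components of the bipartite population graph.

    ``virus_pop_of`` / ``host_pop_of`` map unit/bin ids to population ids
    (unmapped ids become singleton populations). Returns the components
    (each a sorted list of node labels, virus populations prefixed ``V:``
    and host populations ``H:``) and the number of components containing
    more than one virus or more than one host population.
    """
    g = nx.Graph()
    for p in pairs:
        v = "V:" + virus_pop_of.get(p.virus_unit_id, p.virus_unit_id)
        h = "H:" + host_pop_of.get(p.host_bin_id, p.host_bin_id)
        g.add_edge(v, h)
    components = sorted(
        (sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0]
    )
    n_complex = sum(
        1
        for c in components
        if sum(n.startswith("V:") for n in c) > 1
        or sum(n.startswith("H:") for n in c) > 1
    )
    return components, n_complex
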