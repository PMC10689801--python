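"""Coverage, virus-to-prokaryote ratios, RPKM/TPM and the expression rule.

The canonical depth input is a TSV of per-scaffold mean depths (a
SAM/BAM adapter can compute the same table when alignments are on hand).
VPR for a host is the summed mean depth of its paired viral bins and
closed genomes over the host's own depth — a host paired with several
viruses accumulates their coverage. RPKM and TPM follow the standard
definitions; a gene counts as expressed when at least one assembled
transcript maps to it in any replicate, or it receives reads in every
replicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CoverageProfile:
    unit_or_bin_id: str
    sample_id: str
    mean_depth: float  # reads per base (x)


@dataclass
class ExpressionCall:
    gene_id: str
    tpm: list  # one value per replicate
    n_transcript_hits: int
    expressed: bool


# ---------------------------------------------------------------------------
# Depth


def mean_depth(
    depth_table: pd.DataFrame, member_scaffolds: list, unit_id: str, sample_id: str
) -> CoverageProfile:
    """Length-weighted mean depth of a unit's member scaffolds in one sample.

    ``depth_table`` needs ``scaffold_id``, ``sample_id``, ``mean_depth``
    and ``length`` columns; every member scaffold must be present.
    """
    sub = depth_table[depth_table.sample_id == sample_id].set_index("scaffold_id")
    missing = [s for s in member_scaffolds if s not in sub.index]
    if missing:
        raise KeyError(
            f"no depth for scaffold(s) {missing} of unit {unit_id!r} in {sample_id!r}"
        )
    rows = sub.loc[member_scaffolds]
    total = float((rows.mean_depth * rows.length).sum())
    return CoverageProfile(unit_id, sample_id, total / float(rows.length.sum()))


def mean_depth_from_per_base(per_base: np.ndarray) -> float:
    """Mean of a per-base depth vector (BAM-adapter path)."""
    return float(np.asarray(per_base, dtype=float).mean())


def depth_table_from_sam(sam_path, sample_id: str) -> pd.DataFrame:
    """Compute per-scaffold mean depth from a SAM/BAM file via pysam."""
    import pysam

    with pysam.AlignmentFile(str(sam_path)) as af:
        lengths = dict(zip(af.references, af.lengths))
        depth = {ref: np.zeros(n, dtype=np.int64) for ref, n in lengths.items()}
        for read in af.fetch(until_eof=True):
            if read.is_unmapped:
                continue
            for start, end in read.get_blocks():
                depth[read.reference_name][start:end] += 1
    rows = [
        dict(
            scaffold_id=ref,
            sample_id=sample_id,
            mean_depth=float(depth[ref].mean()),
            length=lengths[ref],
        )
        for ref in lengths
    ]
    return pd.DataFrame(rows, columns=["scaffold_id", "sample_id", "mean_depth", "length"])


# ---------------------------------------------------------------------------
# Virus-to-prokaryote ratios


def virus_host_ratio(
    pairs: list,
    unit_depth: dict,
    host_depth: dict,
    unit_kind: dict,
) -> pd.DataFrame:
    """Per-host VPR: summed depth of paired viral bins/closed genomes over
    the host's depth. Fragments are excluded. Hosts with zero depth are
    flagged undefined (NaN VPR) rather than dropped.

    ``pairs`` is a list of objects with ``virus_unit_id``/``host_bin_id``
    (or (virus, host) tuples); depths are dicts keyed by id.
    """
    virus_of_host: dict[str, set] = {h: set() for h in host_depth}
    for p in pairs:
        v, h = (
            (p.virus_unit_id, p.host_bin_id) if hasattr(p, "virus_unit_id") else p
        )
        if unit_kind.get(v) not in ("bin", "closed_genome"):
            continue
        virus_of_host.setdefault(h, set()).add(v)
    rows = []
    for host in sorted(virus_of_host):
        if host not in host_depth:
            continue
        vsum = sum(unit_depth.get(v, 0.0) for v in virus_of_host[host])
        hd = host_depth[host]
        rows.append(
            dict(
                host_bin=host,
                n_viruses=len(virus_of_host[host]),
                vpr=(vsum / hd) if hd > 0 else np.nan,
                undefined=hd <= 0,
            )
        )
    return pd.DataFrame(rows, columns=["host_bin", "n_viruses", "vpr", "undefined"])


# ---------------------------------------------------------------------------
# RPKM / relative abundance


def rpkm(
    counts: pd.DataFrame, gene_lengths: pd.Series, library_sizes: pd.Series
) -> pd.DataFrame:
    """RPKM = count / (gene length in kb x mapped reads in millions)."""
    if (library_sizes <= 0).any():
        bad = library_sizes[library_sizes <= 0].index.tolist()
        raise ValueError(f"zero/negative library size for sample(s) {bad}")
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    len_kb = gene_lengths.reindex(counts.index) / 1000.0
    reads_m = library_sizes.reindex(counts.columns) / 1e6
    return counts.div(len_kb, axis=0).div(reads_m, axis=1)


def relative_abundance(
    rpkm_table: pd.DataFrame, sample_groups: pd.Series
) -> pd.DataFrame:
    """Divide each gene's RPKM by the summed RPKM of its (location,
    sample-type) group; within each group the values sum to 1 per gene
    set. ``sample_groups`` maps sample -> group label."""
    out = rpkm_table.copy().astype(float)
    for group in sorted(sample_groups.unique()):
        cols = [c for c in rpkm_table.columns if sample_groups.get(c) == group]
        total = rpkm_table[cols].to_numpy().sum()
        if total > 0:
            out[cols] = rpkm_table[cols] / total
    return out


# ---------------------------------------------------------------------------
# TPM and the expression rule


def tpm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """TPM per column: rate = count/length, scaled to one million."""
    rate = counts.div(gene_lengths.reindex(counts.index), axis=0)
    return rate.div(rate.sum(axis=0), axis=1) * 1e6


def tpm_and_expressed(
    counts: pd.DataFrame,
    transcript_hits: dict,
    gene_lengths: pd.Series,
) -> list:
    """Quantify replicates in TPM and apply the binary expression rule:
    expressed iff a transcript maps to the gene in at least one replicate
    OR the gene has reads in every replicate. ``transcript_hits`` maps
    gene_id to total transcript hits (across replicates)."""
    tpm_table = tpm(counts, gene_lengths)
    calls = []
    for gene in counts.index:
        hits = int(transcript_hits.get(gene, 0))
        all_reps = bool((counts.loc[gene] > 0).all())
        calls.append(
            ExpressionCall(
                gene_id=gene,
                tpm=[float(x) for x in tpm_table.loc[gene]],
                n_transcript_hits=hits,
                expressed=hits >= 1 or all_reps,
            )
        )
    return calls


def transcript_hits_from_alignments(
    alignments: pd.DataFrame,
    min_identity: float = 95.0,
    require_full_transcript: bool = True,
) -> dict:
    """Count transcript-to-gene mappings passing identity >= 95% with the
    transcript aligned over 100% of its length. ``alignments`` needs
    ``transcript_id``, ``gene_id``, ``identity`` (percent),
    ``transcript_len``, ``aln_len``."""
    ok = alignments.identity >= min_identity
    if require_full_transcript:
        ok &= alignments.aln_len >= alignments.transcript_len
    return alignments[ok].groupby("gene_id").transcript_id.nunique().to_dict()
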