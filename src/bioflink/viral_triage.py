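"""Viral scaffold triage.

Sorts candidate viral scaffolds into proviruses, closed genomes, genome
bins and loose fragments, assigns a bit-score majority-rule phylum, and
enforces bin purity (one phylum, at most one terminase large subunit).

Provirus and bin-quality calls come in as tables (the upstream callers
are consumed, not reimplemented). A scaffold is a provirus only when it
is both flagged as provirus-containing and a member of a quality
prokaryotic bin (completeness >= 50, contamination <= 10). A scaffold is
a closed genome only when all six rules hold: it has a direct terminal
repeat, is not a provirus, the repeat is not low-complexity, contains no
N, occurs fewer than six times, and covers less than 20% of the scaffold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import seq_core
from .seq_core import SequenceRecord

#: viral phyla known to infect prokaryotes (Virus-Host DB); used as the
#: default allow-list when restricting units to prokaryotic viruses
PROKARYOTIC_VIRUS_PHYLA = frozenset(
    {
        "Dividoviricota",
        "Duplornaviricota",
        "Hofneiviricota",
        "Phixviricota",
        "Preplasmiviricota",
        "Uroviricota",
    }
)

UNCLASSIFIED = "unclassified"


@dataclass
class ViralUnit:
    """A virus entity: a loose fragment, a genome bin or a closed genome."""

    unit_id: str
    kind: str  # fragment | bin | closed_genome
    scaffolds: list
    phylum: str = UNCLASSIFIED
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.scaffolds:
            raise ValueError(f"unit {self.unit_id}: scaffolds must be non-empty")
        if self.kind == "closed_genome" and len(self.scaffolds) != 1:
            raise ValueError(f"unit {self.unit_id}: closed genome must be one scaffold")
        if self.kind not in ("fragment", "bin", "closed_genome"):
            raise ValueError(f"unit {self.unit_id}: unknown kind {self.kind!r}")


@dataclass
class ProvirusFlag:
    scaffold_id: str
    is_provirus: bool
    reason: str = "none"  # checkv_provirus_call | none
    in_prok_bin: bool = False


def flag_proviruses(
    provirus_calls: pd.DataFrame,
    bin_membership: pd.DataFrame,
    min_completeness: float = 50.0,
    max_contamination: float = 10.0,
    known_scaffolds: set | None = None,
) -> list[ProvirusFlag]:
    """Conjoin the provirus caller's verdict with quality bin membership.

    ``provirus_calls`` needs a ``scaffold_id`` column; ``bin_membership``
    needs ``scaffold_id``, ``bin_id``, ``completeness``, ``contamination``.
    Scaffolds flagged by the caller but absent from ``known_scaffolds``
    (when given) are skipped with a warning.
    """
    import warnings

    quality = bin_membership[
        (bin_membership.completeness >= min_completeness)
        & (bin_membership.contamination <= max_contamination)
    ]
    in_quality_bin = set(quality.scaffold_id)
    flags = []
    for sid in provirus_calls.scaffold_id.astype(str):
        if known_scaffolds is not None and sid not in known_scaffolds:
            warnings.warn(f"provirus call for unknown scaffold {sid!r}; skipped")
            continue
        binned = sid in in_quality_bin
        flags.append(
            ProvirusFlag(
                scaffold_id=sid,
                is_provirus=binned,
                reason="checkv_provirus_call" if binned else "none",
                in_prok_bin=binned,
            )
        )
    return flags


def call_closed_genomes(
    scaffolds: list,
    provirus_flags: list,
    min_repeat_len: int = 20,
    max_occurrences: int = 6,
    max_covered_fraction: float = 0.20,
) -> list[ViralUnit]:
    """Apply the six closed-genome rules to every scaffold.

    ``max_occurrences`` is exclusive (a repeat seen six times fails) and
    ``max_covered_fraction`` is exclusive (a repeat region at exactly 20%
    fails), matching strict "< 6" and "< 20%" readings.
    """
    provirus_ids = {f.scaffold_id for f in provirus_flags if f.is_provirus}
    closed = []
    for rec in scaffolds:
        if rec.id in provirus_ids:
            continue
        rep = seq_core.detect_terminal_repeat(rec, min_repeat_len=min_repeat_len)
        if rep is None:
            continue
        if rep.low_complexity or rep.has_N:
            continue
        if rep.occurrences >= max_occurrences:
            continue
        if rep.covered_fraction >= max_covered_fraction:
            continue
        closed.append(
            ViralUnit(
                unit_id=rec.id,
                kind="closed_genome",
                scaffolds=[rec.id],
                sample_id=rec.sample_id,
            )
        )
    return closed


def majority_rule_phylum(gene_tax: pd.DataFrame, fraction: float = 0.5) -> str:
    """Bit-score majority phylum: P wins iff its summed bit-score strictly
    exceeds ``fraction`` of the total; otherwise unclassified.

    ``gene_tax`` needs ``phylum`` and ``bitscore`` columns; rows with an
    empty or unclassified phylum contribute to the total but to no
    candidate.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if gene_tax.empty:
        return UNCLASSIFIED
    tab = gene_tax[["phylum", "bitscore"]].copy()
    total = tab.bitscore.sum()
    if total <= 0:
        return UNCLASSIFIED
    labelled = tab[(tab.phylum.notna()) & (tab.phylum != "") & (tab.phylum != UNCLASSIFIED)]
    if labelled.empty:
        return UNCLASSIFIED
    sums = labelled.groupby("phylum").bitscore.sum().sort_values(ascending=False)
    best = sums.index[0]
    if sums.iloc[0] > fraction * total:
        return best
    return UNCLASSIFIED


def purity_filter(
    bins: dict,
    gene_tax: pd.DataFrame,
    terl_gene_ids: set,
    fraction: float = 0.5,
) -> tuple[dict, list]:
    """Discard candidate viral bins that mix phyla or carry multiple TerL.

    ``bins`` maps bin_id to its member scaffold ids; ``gene_tax`` needs
    ``gene_id``, ``scaffold``, ``phylum``, ``bitscore``. Each scaffold
    gets a majority-rule phylum; a bin fails when its scaffolds resolve to
    more than one phylum (unclassified scaffolds are indifferent) or when
    it contains >= 2 terminase-large-subunit genes. Scaffolds of failed
    bins are released back to the fragment pool.
    """
    kept: dict = {}
    released: list = []
    by_scaffold = dict(tuple(gene_tax.groupby("scaffold"))) if len(gene_tax) else {}
    for bin_id in sorted(bins):
        members = list(bins[bin_id])
        phyla = set()
        n_terl = 0
        for sid in members:
            sub = by_scaffold.get(sid)
            if sub is None:
                continue
            p = majority_rule_phylum(sub, fraction=fraction)
            if p != UNCLASSIFIED:
                phyla.add(p)
            n_terl += sum(g in terl_gene_ids for g in sub.gene_id)
        if len(phyla) > 1 or n_terl >= 2:
            released.extend(members)
        else:
            kept[bin_id] = members
    return kept, released


def build_viral_units(
    scaffolds: list,
    provirus_flags: list,
    bins: dict,
    gene_tax: pd.DataFrame,
    terl_gene_ids: set,
    min_repeat_len: int = 20,
    phylum_allowlist: frozenset | None = PROKARYOTIC_VIRUS_PHYLA,
) -> list[ViralUnit]:
    """Full triage: closed genomes first, then purity-filtered bins over
    the remaining scaffolds, then leftovers as fragments; every unit gets
    a majority-rule phylum and units outside the prokaryote-infecting
    phylum allow-list are dropped (pass ``phylum_allowlist=None`` to keep
    all).
    """
    provirus_ids = {f.scaffold_id for f in provirus_flags if f.is_provirus}
    closed = call_closed_genomes(scaffolds, provirus_flags, min_repeat_len)
    closed_ids = {u.unit_id for u in closed}

    candidate_bins = {
        b: [s for s in members if s not in closed_ids and s not in provirus_ids]
        for b, members in bins.items()
    }
    candidate_bins = {b: m for b, m in candidate_bins.items() if m}
    kept_bins, released = purity_filter(candidate_bins, gene_tax, terl_gene_ids)

    binned = {s for members in kept_bins.values() for s in members}
    units = list(closed)
    sample_of = {r.id: r.sample_id for r in scaffolds}
    for bin_id in sorted(kept_bins):
        units.append(
            ViralUnit(
                unit_id=bin_id,
                kind="bin",
                scaffolds=sorted(kept_bins[bin_id]),
                sample_id=sample_of.get(kept_bins[bin_id][0], ""),
            )
        )
    for rec in scaffolds:
        if rec.id in closed_ids or rec.id in binned or rec.id in provirus_ids:
            continue
        units.append(
            ViralUnit(
                unit_id=rec.id, kind="fragment", scaffolds=[rec.id],
                sample_id=rec.sample_id,
            )
        )
    by_scaffold = dict(tuple(gene_tax.groupby("scaffold"))) if len(gene_tax) else {}
    for unit in units:
        sub = [by_scaffold[s] for s in unit.scaffolds if s in by_scaffold]
        unit.phylum = (
            majority_rule_phylum(pd.concat(sub)) if sub else UNCLASSIFIED
        )
    if phylum_allowlist is not None:
        units = [u for u in units if u.phylum in phylum_allowlist]
    return units


def units_to_table(units: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                unit_id=u.unit_id,
                kind=u.kind,
                phylum=u.phylum,
                sample_id=u.sample_id,
                scaffolds=",".join(u.scaffolds),
            )
            for u in sorted(units, key=lambda u: u.unit_id)
        ],
        columns=["unit_id", "kind", "phylum", "sample_id", "scaffolds"],
    )
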