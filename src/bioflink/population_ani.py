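"""Fragment-based ANI, population clustering and shared pairs.

Genomes are assigned to "populations" at >= 95% average nucleotide
identity, computed fragment-wise: the query is cut into consecutive
500 bp windows, each window is locally aligned to the target, and ANI is
the mean identity over windows whose best alignment covers at least 80%
of the window. A result is reported only when the fraction of aligned
windows reaches ``min_fraction`` (0.8 for viruses, 0.5 for prokaryotic
hosts). Clustering is single-linkage over max(ani(a,b), ani(b,a)) since
fragment ANI is not symmetric.

A virus-host pair is "shared" between two samples when both samples
contain a pair whose members fall in the same virus and host populations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from . import seq_core

#: paper-style fragment parameters
FRAG_LEN = 500
MIN_FRACTION_VIRUS = 0.8
MIN_FRACTION_HOST = 0.5
ANI_THRESHOLD = 95.0


@dataclass
class ANIResult:
    query_id: str
    target_id: str
    ani: float  # percent, [0, 100]
    aligned_fraction: float


@dataclass
class Population:
    population_id: str
    members: list
    entity: str  # virus | host


def fragment_ani(
    query: seq_core.SequenceRecord | str,
    target: seq_core.SequenceRecord | str,
    frag_len: int = FRAG_LEN,
    min_fraction: float = MIN_FRACTION_VIRUS,
    min_frag_cover: float = 0.8,
    seed_k: int = 13,
) -> ANIResult | None:
    """Fragment-based ANI of ``query`` against ``target``."""
    q_id = query.id if isinstance(query, seq_core.SequenceRecord) else "query"
    q_seq = query.seq if isinstance(query, seq_core.SequenceRecord) else query.upper()
    if len(q_seq) < frag_len:
        raise ValueError(f"query {q_id!r} shorter than fragment length {frag_len}")
    if isinstance(target, seq_core.TargetIndex):
        t_id, t_seq = target.id, target.seqs["+"]
    elif isinstance(target, seq_core.SequenceRecord):
        t_id, t_seq = target.id, target.seq
    else:
        t_id, t_seq = "target", target.upper()
    if len(t_seq) < frag_len:
        raise ValueError(f"target {t_id!r} shorter than fragment length {frag_len}")

    n_frags = len(q_seq) // frag_len
    identities = []
    min_len = int(min_frag_cover * frag_len)
    index = (
        target
        if isinstance(target, seq_core.TargetIndex)
        else seq_core.TargetIndex(t_seq, seed_k)
    )
    for i in range(n_frags):
        frag = q_seq[i * frag_len : (i + 1) * frag_len]
        alns = seq_core.local_align(
            frag, index, seed_k=seed_k, min_identity=0.0, min_len=min_len
        )
        if alns:
            best = max(alns, key=lambda a: a.identity * a.aln_len)
            identities.append(best.identity)
    aligned_fraction = len(identities) / n_frags
    if aligned_fraction < min_fraction:
        return None
    ani = 100.0 * sum(identities) / len(identities)
    return ANIResult(q_id, t_id, ani, aligned_fraction)


def pairwise_ani(
    genomes: dict,
    min_fraction: float = MIN_FRACTION_VIRUS,
    frag_len: int = FRAG_LEN,
) -> pd.DataFrame:
    """All ordered pairs; ``genomes`` maps id to sequence string (a
    multi-scaffold bin is concatenated by the caller)."""
    rows = []
    indexes = {g: seq_core.TargetIndex(genomes[g]) for g in genomes}
    for g in indexes:
        indexes[g].id = g
    for a, b in combinations(sorted(genomes), 2):
        for q, t in ((a, b), (b, a)):
            res = fragment_ani(
                seq_core.SequenceRecord(q, genomes[q]),
                indexes[t],
                frag_len=frag_len,
                min_fraction=min_fraction,
            )
            if res is not None:
                rows.append(
                    dict(query=q, target=t, ani=round(res.ani, 4),
                         aligned_fraction=round(res.aligned_fraction, 4))
                )
    return pd.DataFrame(rows, columns=["query", "target", "ani", "aligned_fraction"])


def cluster_populations(
    unit_ids: list,
    ani_table: pd.DataFrame,
    threshold: float = ANI_THRESHOLD,
    entity: str = "virus",
) -> list:
    """Single-linkage components over edges with max-direction ANI >=
    threshold; population ids are ordered by smallest member id, so the
    partition is invariant to input order."""
    parent = {u: u for u in unit_ids}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    best: dict[tuple[str, str], float] = {}
    for row in ani_table.itertuples(index=False):
        key = tuple(sorted((row.query, row.target)))
        best[key] = max(best.get(key, 0.0), row.ani)
    for (a, b), ani in best.items():
        if ani >= threshold and a in parent and b in parent:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    groups: dict[str, list] = {}
    for u in unit_ids:
        groups.setdefault(find(u), []).append(u)
    populations = []
    for k, root in enumerate(sorted(groups, key=lambda r: min(groups[r]))):
        populations.append(
            Population(f"{entity}pop_{k}", sorted(groups[root]), entity)
        )
    return populations


def population_of(populations: list) -> dict:
    """Member id -> population id lookup."""
    return {m: p.population_id for p in populations for m in p.members}


def shared_pairs(
    pairs_by_sample: dict,
    virus_pops: list,
    host_pops: list,
) -> pd.DataFrame:
    """Population-level pair combinations present in >= 2 samples.

    ``pairs_by_sample`` maps sample id to a list of (virus_unit_id,
    host_bin_id) pairs. One output row per shared combination, listing
    every sample that contains it.
    """
    v_of = population_of(virus_pops)
    h_of = population_of(host_pops)
    samples_of: dict[tuple[str, str], set] = {}
    for sample in sorted(pairs_by_sample):
        for v, h in pairs_by_sample[sample]:
            key = (v_of.get(v, v), h_of.get(h, h))
            samples_of.setdefault(key, set()).add(sample)
    rows = [
        dict(virus_population=v, host_population=h,
             n_samples=len(smp), samples=",".join(sorted(smp)))
        for (v, h), smp in sorted(samples_of.items())
        if len(smp) >= 2
    ]
    return pd.DataFrame(
        rows, columns=["virus_population", "host_population", "n_samples", "samples"]
    )


def populations_to_table(populations: list) -> pd.DataFrame:
    rows = [
        dict(population_id=p.population_id, entity=p.entity, member=m)
        for p in populations
        for m in p.members
    ]
    return pd.DataFrame(rows, columns=["population_id", "entity", "member"])
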