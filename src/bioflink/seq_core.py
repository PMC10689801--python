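"""Shared sequence primitives.

Everything downstream of assembly works on plain DNA strings over
``{A, C, G, T, N}``: exact substring search on both strands (CRISPR-spacer
matching), seed-and-extend local alignment (homology linkage and
fragment-based ANI), terminal direct-repeat detection (closed phage
genomes) and a low-complexity score for repeat triage.

Coordinates are 0-based half-open throughout; strands are ``+``/``-``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import edlib
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named assembled scaffold (or genome) from one sample."""

    id: str
    seq: str
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class LocalAlignment:
    """One local alignment (HSP) between a query and a target scaffold.

    ``identity`` is matches / alignment length on the query
    (``aln_len == q_end - q_start``). ``strand`` is the target strand the
    query aligns to.
    """

    query_id: str
    target_id: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    identity: float
    strand: str = "+"

    @property
    def aln_len(self) -> int:
        return self.q_end - self.q_start


@dataclass
class TerminalRepeat:
    """A direct terminal repeat (DTR): identical scaffold prefix and suffix."""

    seq: str
    occurrences: int
    covered_fraction: float
    has_N: bool
    low_complexity: bool

    @property
    def length(self) -> int:
        return len(self.seq)


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path, sample_id: str = "") -> list[SequenceRecord]:
    """Read a multi-record FASTA; tolerates lowercase and N."""
    return [
        SequenceRecord(id=rec.id, seq=str(rec.seq).upper(), sample_id=sample_id)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    """Write records wrapped at 80 columns."""
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Exact substring search


def find_exact_matches(
    pattern: str, subject: SequenceRecord | str, both_strands: bool = True
) -> list[tuple[int, str]]:
    """Every 0-based start where ``pattern`` occurs exactly in ``subject``.

    With ``both_strands`` the reverse complement of the pattern is also
    searched (reported on the subject's forward coordinates with strand
    ``-``). ``N`` never matches, which falls out of exact string equality
    since ``N`` only equals itself. Overlapping occurrences are reported.
    """
    if not pattern:
        raise ValueError("pattern must be non-empty")
    pattern = pattern.upper()
    text = subject.seq if isinstance(subject, SequenceRecord) else subject.upper()
    hits: list[tuple[int, str]] = []
    if "N" not in pattern:
        hits.extend((pos, "+") for pos in _find_all(text, pattern))
        if both_strands:
            rc = reverse_complement(pattern)
            if rc != pattern:  # palindromes are already covered on +
                hits.extend((pos, "-") for pos in _find_all(text, rc))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def _find_all(text: str, pattern: str) -> Iterator[int]:
    start = text.find(pattern)
    while start != -1:
        yield start
        start = text.find(pattern, start + 1)


# ---------------------------------------------------------------------------
# Seed-and-extend local alignment

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _xdrop_extend_right(q: np.ndarray, t: np.ndarray, qi: int, ti: int, xdrop: int) -> int:
    """Ungapped X-drop extension to the right; returns extension length."""
    n = min(len(q) - qi, len(t) - ti)
    if n <= 0:
        return 0
    eq = (q[qi : qi + n] == t[ti : ti + n]) & (q[qi : qi + n] != 255)
    score = np.cumsum(np.where(eq, 1, -2))
    best = np.maximum.accumulate(score)
    dropped = np.nonzero(best - score > xdrop)[0]
    limit = dropped[0] if len(dropped) else n
    if limit == 0:
        return 0
    return int(np.argmax(score[:limit])) + 1


def _xdrop_extend_left(q: np.ndarray, t: np.ndarray, qi: int, ti: int, xdrop: int) -> int:
    n = min(qi, ti)
    if n <= 0:
        return 0
    eq = (q[qi - n : qi][::-1] == t[ti - n : ti][::-1]) & (q[qi - n : qi][::-1] != 255)
    score = np.cumsum(np.where(eq, 1, -2))
    best = np.maximum.accumulate(score)
    dropped = np.nonzero(best - score > xdrop)[0]
    limit = dropped[0] if len(dropped) else n
    if limit == 0:
        return 0
    return int(np.argmax(score[:limit])) + 1


def _region_identity(qs: str, ts: str) -> float:
    """Identity of the best path through a candidate region via edit distance."""
    if not qs or not ts:
        return 0.0
    res = edlib.align(qs, ts, task="distance", mode="NW")
    dist = res["editDistance"]
    # matches >= aln columns - edits; columns >= max(len); identity on query span
    matches = max(len(qs), len(ts)) - dist
    return max(0.0, matches / len(qs))


class TargetIndex:
    """Precomputed k-mer index of a target sequence, both strands.

    Build once, align many queries against it (fragment-based ANI cuts a
    genome into hundreds of windows aligned to the same target).
    """

    def __init__(self, target: SequenceRecord | str, seed_k: int = 13):
        if seed_k < 11:
            raise ValueError("seed_k must be >= 11")
        self.id = target.id if isinstance(target, SequenceRecord) else "target"
        fwd = target.seq if isinstance(target, SequenceRecord) else target.upper()
        self.seed_k = seed_k
        self.seqs = {"+": fwd, "-": reverse_complement(fwd)}
        self.indexes = {s: _kmer_index(t, seed_k) for s, t in self.seqs.items()}
        self.arrays = {s: _encode(t) for s, t in self.seqs.items()}


def local_align(
    query: SequenceRecord | str,
    target: SequenceRecord | str | TargetIndex,
    seed_k: int = 13,
    min_identity: float = 0.70,
    min_len: int = 2500,
    xdrop: int = 30,
    band: int = 25,
) -> list[LocalAlignment]:
    """Seed-and-extend local alignment of ``query`` against both target strands.

    Exact ``seed_k``-mer anchors are clustered by diagonal (within ``band``
    to admit small indels), each cluster is extended ungapped with X-drop,
    and the spanned region is scored by unit-cost edit distance. Only
    maximal non-overlapping alignments individually passing
    ``min_identity`` and ``min_len`` are reported. ``target`` may be a
    prebuilt :class:`TargetIndex` (its ``seed_k`` then wins).
    """
    if seed_k < 11:
        raise ValueError("seed_k must be >= 11")
    q_id = query.id if isinstance(query, SequenceRecord) else "query"
    q_seq = query.seq if isinstance(query, SequenceRecord) else query.upper()
    index = target if isinstance(target, TargetIndex) else TargetIndex(target, seed_k)
    t_id = index.id

    results: list[LocalAlignment] = []
    for strand in ("+", "-"):
        t_seq = index.seqs[strand]
        for qs, qe, ts, te, ident in _align_one_strand(
            q_seq, t_seq, index.seed_k, min_identity, min_len, xdrop, band,
            t_index=index.indexes[strand], t_arr=index.arrays[strand],
        ):
            if strand == "-":
                ts, te = len(t_seq) - te, len(t_seq) - ts
            results.append(
                LocalAlignment(q_id, t_id, qs, qe, ts, te, ident, strand)
            )
    # keep maximal non-overlapping (on the query) by descending score
    results.sort(key=lambda a: (-a.aln_len * a.identity, a.q_start, a.strand))
    kept: list[LocalAlignment] = []
    for aln in results:
        if all(
            aln.q_end <= k.q_start or aln.q_start >= k.q_end for k in kept
        ):
            kept.append(aln)
    kept.sort(key=lambda a: a.q_start)
    return kept


def _align_one_strand(
    q_seq: str,
    t_seq: str,
    seed_k: int,
    min_identity: float,
    min_len: int,
    xdrop: int,
    band: int,
    t_index: dict | None = None,
    t_arr: np.ndarray | None = None,
) -> list[tuple[int, int, int, int, float]]:
    if len(q_seq) < seed_k or len(t_seq) < seed_k:
        return []
    if t_index is None:
        t_index = _kmer_index(t_seq, seed_k)
    # anchors grouped by banded diagonal
    diag_anchors: dict[int, list[tuple[int, int]]] = {}
    for qi in range(len(q_seq) - seed_k + 1):
        kmer = q_seq[qi : qi + seed_k]
        positions = t_index.get(kmer)
        if not positions:
            continue
        for ti in positions:
            diag_anchors.setdefault((ti - qi) // band, []).append((qi, ti))

    q_arr = _encode(q_seq)
    if t_arr is None:
        t_arr = _encode(t_seq)
    raw: list[tuple[int, int, int, int, float]] = []
    seen_spans: set[tuple[int, int]] = set()
    # merge adjacent diagonal bands so a chain crossing a band boundary is whole
    merged: dict[int, list[tuple[int, int]]] = {}
    for d, anchors in diag_anchors.items():
        merged.setdefault(d, []).extend(anchors)
        if d + 1 in diag_anchors:
            merged[d].extend(diag_anchors[d + 1])
    for d in sorted(merged):
        anchors = sorted(set(merged[d]))
        # split chains at large query gaps
        chains: list[list[tuple[int, int]]] = [[anchors[0]]]
        for a in anchors[1:]:
            prev = chains[-1][-1]
            if a[0] - prev[0] > 200 or a[1] < prev[1]:
                chains.append([a])
            else:
                chains[-1].append(a)
        for chain in chains:
            qs, ts = chain[0]
            qe, te = chain[-1]
            qe += seed_k
            te += seed_k
            left = min(
                _xdrop_extend_left(q_arr, t_arr, qs, ts, xdrop), qs, ts
            )
            right = _xdrop_extend_right(q_arr, t_arr, qe, te, xdrop)
            qs, ts = qs - left, ts - left
            qe, te = qe + right, te + right
            span = (qs, qe)
            if span in seen_spans:
                continue
            seen_spans.add(span)
            if qe - qs < min_len:
                continue
            ident = _region_identity(q_seq[qs:qe], t_seq[ts:te])
            if ident >= min_identity:
                raw.append((qs, qe, ts, te, ident))
    return raw


# ---------------------------------------------------------------------------
# Terminal direct repeats


def is_low_complexity(seq: str) -> bool:
    """True when one base exceeds 75% of the repeat or the repeat is a
    perfect 1-3-mer tandem."""
    if not seq:
        return True
    n = len(seq)
    for base in "ACGT":
        if seq.count(base) > 0.75 * n:
            return True
    for period in (1, 2, 3):
        if n >= 2 * period and seq == seq[:period] * (n // period) + seq[: n % period]:
            return True
    return False


def _longest_prefix_suffix(seq: str) -> int:
    """Length of the longest proper prefix of ``seq`` equal to its suffix
    (KMP failure function of the last position)."""
    n = len(seq)
    fail = np.zeros(n, dtype=np.int64)
    k = 0
    for i in range(1, n):
        while k > 0 and seq[i] != seq[k]:
            k = fail[k - 1]
        if seq[i] == seq[k]:
            k += 1
        fail[i] = k
    return int(fail[n - 1])


def detect_terminal_repeat(
    scaffold: SequenceRecord | str, min_repeat_len: int = 20
) -> TerminalRepeat | None:
    """Longest exact prefix of the scaffold that recurs as its suffix.

    Returns ``None`` when no prefix-suffix of at least ``min_repeat_len``
    exists. ``occurrences`` counts every (possibly overlapping) exact
    occurrence in the scaffold and ``covered_fraction`` is the fraction of
    scaffold bases covered by the union of those occurrences.
    """
    if min_repeat_len < 10:
        raise ValueError("min_repeat_len must be >= 10")
    seq = scaffold.seq if isinstance(scaffold, SequenceRecord) else scaffold.upper()
    length = _longest_prefix_suffix(seq)
    if length < min_repeat_len:
        return None
    repeat = seq[:length]
    starts = [pos for pos, _ in find_exact_matches(repeat, seq, both_strands=False)]
    covered = np.zeros(len(seq), dtype=bool)
    for s in starts:
        covered[s : s + length] = True
    return TerminalRepeat(
        seq=repeat,
        occurrences=len(starts),
        covered_fraction=float(covered.sum()) / len(seq),
        has_N="N" in repeat,
        low_complexity=is_low_complexity(repeat),
    )


# ---------------------------------------------------------------------------
# Canonical k-mers (shared-k-mer host linkage)


def canonical_kmers(seq: str, k: int = 25) -> set[str]:
    """Distinct canonical k-mers (lexicographic min of k-mer and its
    reverse complement); k-mers containing N are skipped."""
    out: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        out.add(min(kmer, reverse_complement(kmer)))
    return out
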