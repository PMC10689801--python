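"""Ground-truth synthetic communities.

Builds desk-scale mock biofilm assemblies in which every signal the
pipeline looks for has been planted on purpose: phage/host homology
blocks, CRISPR arrays whose spacers come from phage genomes, shared tRNA
genes, exact 25-mer-rich blocks, direct terminal repeats, integrated
proviruses, ANI population mates, per-sample depth profiles, defence /
counter-defence / AMG hit tables, and negative-binomial count tables with
planted biofilm-vs-seawater fold changes.

All randomness flows from ``CommunitySpec.seed`` through one
``numpy.random.Generator``; the same seed yields byte-identical output
files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seq_core import SequenceRecord, is_low_complexity, reverse_complement

_BASES = np.array(list("ACGT"))

CHANNELS = ("homology", "crispr", "trna", "kmer")


# ---------------------------------------------------------------------------
# Spec and truth containers


@dataclass
class CommunitySpec:
    """Parameters of one synthetic community.

    ``link_plan`` rows are ``(phage_index, host_index, channels)`` with
    channels a subset of ``{homology, crispr, trna, kmer}``. Indices refer
    to the generated ``phage_<i>`` / ``hostbin_<i>`` entities.
    """

    n_hosts: int = 10
    n_phages: int = 20
    host_len: int = 30_000
    phage_len: int = 10_000
    scaffolds_per_host: int = 2
    link_plan: tuple[tuple[int, int, frozenset], ...] = ()
    mutation_rate: float = 0.10  # divergence of planted homology blocks
    seed: int = 0
    n_samples: int = 4
    sample_id: str = "S1"
    closed_phages: tuple[int, ...] = ()  # planted clean DTRs
    provirus_phages: tuple[int, ...] = ()  # integrated + CheckV-flagged
    dtr_len: int = 40
    homology_block: int = 3000
    kmer_block: int = 300
    trna_len: int = 75
    # ANI population mates: groups of phage indices copied from one base
    phage_population_groups: tuple[tuple[int, ...], ...] = ()
    within_population_divergence: float = 0.01
    kmer_min_shared: int = 10  # shared-25-mer link threshold used for truth
    # differential-abundance block
    da_n_genes: int = 200
    da_n_shifted: int = 20
    da_log2fc: float = 1.5
    da_dispersion: float = 0.1
    da_n_per_group: int = 8
    da_locations: tuple[str, ...] = ("HK", "RS")

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_rate <= 0.3:
            raise ValueError("mutation_rate must be in [0, 0.3]")
        if self.phage_len < 5000:
            raise ValueError("phage_len must be >= 5000 (scaffolds >= 5 kb)")
        for phage, host, channels in self.link_plan:
            if not channels:
                raise ValueError("every planted link needs >= 1 channel")
            if not set(channels) <= set(CHANNELS):
                raise ValueError(f"unknown channel in {channels}")
            if not (0 <= phage < self.n_phages and 0 <= host < self.n_hosts):
                raise ValueError("link_plan index out of range")


@dataclass
class GroundTruth:
    """What was planted, keyed by the emitted entity ids."""

    true_links: set = field(default_factory=set)  # (phage_id, host_id, channel)
    true_closed: set = field(default_factory=set)
    true_proviruses: set = field(default_factory=set)
    true_populations: list = field(default_factory=list)  # list of frozensets
    planted_da: dict = field(default_factory=dict)  # gene_id -> log2fc (sw vs bf)


@dataclass
class Community:
    """A generated community: sequences, tables and its ground truth."""

    spec: CommunitySpec
    host_scaffolds: list  # SequenceRecord
    phage_scaffolds: list  # SequenceRecord
    bin_table: pd.DataFrame  # scaffold_id, bin_id, completeness, contamination, domain
    provirus_calls: pd.DataFrame  # scaffold_id
    gene_table: pd.DataFrame  # gene_id, scaffold, start, end, strand, gene_type,
    #                           product, seq, phylum, bitscore
    depth_table: pd.DataFrame  # scaffold_id, sample_id, mean_depth, length
    pads_hits: pd.DataFrame
    pfam_hits: pd.DataFrame
    kegg_hits: pd.DataFrame
    counts: pd.DataFrame  # gene x sample
    sample_sheet: pd.DataFrame  # sample, location, sample_type
    truth: GroundTruth

    def scaffold(self, scaffold_id: str) -> SequenceRecord:
        for rec in self.host_scaffolds + self.phage_scaffolds:
            if rec.id == scaffold_id:
                return rec
        raise KeyError(scaffold_id)

    def host_bin_scaffolds(self, bin_id: str) -> list:
        ids = set(self.bin_table.loc[self.bin_table.bin_id == bin_id, "scaffold_id"])
        return [r for r in self.host_scaffolds + self.phage_scaffolds if r.id in ids]

    def write(self, outdir) -> None:
        from .seq_core import write_fasta

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.host_scaffolds, outdir / "hosts.fasta")
        write_fasta(self.phage_scaffolds, outdir / "phages.fasta")
        for name in (
            "bin_table",
            "provirus_calls",
            "gene_table",
            "depth_table",
            "pads_hits",
            "pfam_hits",
            "kegg_hits",
            "sample_sheet",
        ):
            getattr(self, name).to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        self.counts.to_csv(outdir / "counts.tsv", sep="\t")
        write_truth(self.truth, outdir)


# ---------------------------------------------------------------------------
# Sequence helpers


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base independently with probability ``rate`` (always
    to a different base)."""
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if hit.any():
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        codes = np.array([idx.get(b, 0) for b in arr[hit]])
        shift = rng.integers(1, 4, size=hit.sum())
        arr[hit] = _BASES[(codes + shift) % 4]
    return "".join(arr)


class _Allocator:
    """Hands out non-overlapping intervals inside one scaffold so planted
    features never clobber each other."""

    def __init__(self, length: int, margin: int = 50):
        self.length = length
        self.margin = margin
        self.used: list[tuple[int, int]] = []

    def alloc(self, rng: np.random.Generator, size: int) -> int:
        for _ in range(200):
            start = int(rng.integers(self.margin, self.length - size - self.margin))
            if all(
                start + size + self.margin <= s or start >= e + self.margin
                for s, e in self.used
            ):
                self.used.append((start, start + size))
                return start
        raise ValueError("scaffold too crowded to place a planted feature")


def _overwrite(seq: str, start: int, block: str) -> str:
    return seq[:start] + block + seq[start + len(block) :]


def _random_repeat(rng: np.random.Generator, length: int) -> str:
    """A CRISPR-like repeat that is not low-complexity."""
    while True:
        rep = random_seq(rng, length)
        if not is_low_complexity(rep):
            return rep


# ---------------------------------------------------------------------------
# The generator


def generate_community(spec: CommunitySpec) -> Community:
    """Build a full community per ``spec``; see module docstring."""
    rng = np.random.default_rng(spec.seed)
    truth = GroundTruth()

    # --- phage scaffolds (some with DTRs, some as population mates)
    phage_seqs: dict[int, str] = {}
    mate_of: dict[int, int] = {}
    for group in spec.phage_population_groups:
        for member in group[1:]:
            mate_of[member] = group[0]
    for i in range(spec.n_phages):
        if i in mate_of:
            continue
        seq = random_seq(rng, spec.phage_len)
        if i in spec.closed_phages:
            dtr = _random_repeat(rng, spec.dtr_len)
            seq = dtr + seq[spec.dtr_len : -spec.dtr_len] + dtr
            truth.true_closed.add(f"phage_{i}")
        phage_seqs[i] = seq
    for member, base in mate_of.items():
        phage_seqs[member] = mutate(
            rng, phage_seqs[base], spec.within_population_divergence
        )
    singleton = set(range(spec.n_phages)) - set(mate_of) - {
        g[0] for g in spec.phage_population_groups
    }
    truth.true_populations = [
        frozenset(f"phage_{i}" for i in g) for g in spec.phage_population_groups
    ] + [frozenset({f"phage_{i}"}) for i in sorted(singleton)]

    # --- host scaffolds
    scaff_len = spec.host_len // spec.scaffolds_per_host
    host_seqs: dict[str, str] = {}
    allocators: dict[str, _Allocator] = {}
    bin_rows = []
    for h in range(spec.n_hosts):
        for s in range(spec.scaffolds_per_host):
            sid = f"host_{h}_s{s}"
            host_seqs[sid] = random_seq(rng, scaff_len)
            allocators[sid] = _Allocator(scaff_len)
            bin_rows.append(
                dict(
                    scaffold_id=sid,
                    bin_id=f"hostbin_{h}",
                    completeness=80.0,
                    contamination=2.0,
                    domain="prokaryote",
                )
            )

    gene_rows: list[dict] = []
    gene_counter = [0]

    def add_gene(scaffold, start, end, gene_type, product, seq="", phylum="", bitscore=0.0):
        gene_counter[0] += 1
        gid = f"gene_{gene_counter[0]:05d}"
        gene_rows.append(
            dict(
                gene_id=gid,
                scaffold=scaffold,
                start=start,
                end=end,
                strand="+",
                gene_type=gene_type,
                product=product,
                seq=seq,
                phylum=phylum,
                bitscore=bitscore,
            )
        )
        return gid

    # --- planted evidence channels
    for phage, host, channels in spec.link_plan:
        p_id, h_bin = f"phage_{phage}", f"hostbin_{host}"
        p_seq = phage_seqs[phage]
        host_scaffold_ids = [f"host_{host}_s{s}" for s in range(spec.scaffolds_per_host)]
        for channel in sorted(channels):
            sid = host_scaffold_ids[int(rng.integers(len(host_scaffold_ids)))]
            if channel == "homology":
                size = spec.homology_block
                src = int(rng.integers(spec.dtr_len, len(p_seq) - size - spec.dtr_len))
                block = mutate(rng, p_seq[src : src + size], spec.mutation_rate)
                start = allocators[sid].alloc(rng, size)
                host_seqs[sid] = _overwrite(host_seqs[sid], start, block)
            elif channel == "crispr":
                rep = _random_repeat(rng, int(rng.integers(25, 36)))
                n_spacers = int(rng.integers(3, 9))
                viral_at = int(rng.integers(n_spacers))
                spacers = []
                for k in range(n_spacers):
                    sp_len = int(rng.integers(25, 41))
                    if k == viral_at:
                        pos = int(rng.integers(0, len(p_seq) - sp_len))
                        spacers.append(p_seq[pos : pos + sp_len])
                    else:
                        spacers.append(random_seq(rng, sp_len))
                array = rep + "".join(sp + rep for sp in spacers)
                start = allocators[sid].alloc(rng, len(array))
                host_seqs[sid] = _overwrite(host_seqs[sid], start, array)
            elif channel == "trna":
                trna = random_seq(rng, spec.trna_len)
                start = allocators[sid].alloc(rng, spec.trna_len)
                host_seqs[sid] = _overwrite(host_seqs[sid], start, trna)
                add_gene(sid, start, start + spec.trna_len, "trna", "tRNA-Gly", seq=trna)
                v_start = int(rng.integers(spec.dtr_len, len(p_seq) - spec.trna_len - spec.dtr_len))
                phage_seqs[phage] = _overwrite(p_seq, v_start, trna)
                p_seq = phage_seqs[phage]
                add_gene(p_id, v_start, v_start + spec.trna_len, "trna", "tRNA-Gly", seq=trna)
            elif channel == "kmer":
                size = spec.kmer_block
                src = int(rng.integers(spec.dtr_len, len(p_seq) - size - spec.dtr_len))
                start = allocators[sid].alloc(rng, size)
                host_seqs[sid] = _overwrite(host_seqs[sid], start, p_seq[src : src + size])
            truth.true_links.add((p_id, h_bin, channel))

    # --- proviruses: integrate a copy into a host scaffold; flag the viral
    #     scaffold as CheckV-provirus and as a member of that host's bin
    provirus_rows = []
    for j, phage in enumerate(sorted(spec.provirus_phages)):
        host = j % spec.n_hosts
        sid = f"host_{host}_s0"
        p_id = f"phage_{phage}"
        block = phage_seqs[phage][:2000]
        start = allocators[sid].alloc(rng, len(block))
        host_seqs[sid] = _overwrite(host_seqs[sid], start, block)
        provirus_rows.append(dict(scaffold_id=p_id))
        bin_rows.append(
            dict(
                scaffold_id=p_id,
                bin_id=f"hostbin_{host}",
                completeness=80.0,
                contamination=2.0,
                domain="prokaryote",
            )
        )
        truth.true_proviruses.add(p_id)

    # --- gene annotations: viral CDS with phylum bit-scores, one TerL per phage
    for i in range(spec.n_phages):
        p_id = f"phage_{i}"
        pos = 100
        for g in range(8):
            end = pos + 900
            phylum = "Uroviricota"
            add_gene(p_id, pos, end, "cds", f"hypothetical protein {g}",
                     phylum=phylum, bitscore=float(rng.integers(80, 300)))
            pos = end + 150
        add_gene(p_id, pos, pos + 600, "terl", "terminase large subunit",
                 phylum="Uroviricota", bitscore=float(rng.integers(150, 400)))
    for sid in host_seqs:
        pos = 200
        for g in range(4):
            end = pos + 900
            add_gene(sid, pos, end, "cds", "hypothetical protein",
                     phylum="Proteobacteria", bitscore=float(rng.integers(80, 300)))
            pos = end + 300

    # --- depth profiles: log-normal mean depths per unit per sample
    samples = [f"{spec.sample_id}_r{k}" for k in range(spec.n_samples)]
    depth_rows = []
    for h in range(spec.n_hosts):
        depths = np.exp(rng.normal(np.log(10), 0.4, size=spec.n_samples))
        for s in range(spec.scaffolds_per_host):
            sid = f"host_{h}_s{s}"
            for smp, d in zip(samples, depths):
                depth_rows.append(
                    dict(scaffold_id=sid, sample_id=smp,
                         mean_depth=round(float(d), 4), length=len(host_seqs[sid]))
                )
    for i in range(spec.n_phages):
        depths = np.exp(rng.normal(np.log(50), 0.6, size=spec.n_samples))
        for smp, d in zip(samples, depths):
            depth_rows.append(
                dict(scaffold_id=f"phage_{i}", sample_id=smp,
                     mean_depth=round(float(d), 4), length=len(phage_seqs[i]))
            )

    # planted features leave real shared 25-mers behind (a copied tRNA or a
    # low-divergence homology block IS exact sequence sharing), so the kmer
    # channel is measured from the final sequences rather than assumed
    from .seq_core import canonical_kmers

    phage_kmers = {
        i: canonical_kmers(phage_seqs[i]) for i in range(spec.n_phages)
    }
    bin_kmers: dict[int, set] = {}
    for h in range(spec.n_hosts):
        km: set = set()
        for s in range(spec.scaffolds_per_host):
            km |= canonical_kmers(host_seqs[f"host_{h}_s{s}"])
        bin_kmers[h] = km
    for i in range(spec.n_phages):
        if f"phage_{i}" in truth.true_proviruses:
            continue
        for h in range(spec.n_hosts):
            if len(phage_kmers[i] & bin_kmers[h]) >= spec.kmer_min_shared:
                truth.true_links.add((f"phage_{i}", f"hostbin_{h}", "kmer"))

    gene_table = pd.DataFrame(gene_rows)
    pads, pfam, kegg = _generate_defensome_hits(rng, gene_table)
    counts, sheet, planted = generate_da_counts(
        rng,
        n_genes=spec.da_n_genes,
        n_shifted=spec.da_n_shifted,
        log2fc=spec.da_log2fc,
        dispersion=spec.da_dispersion,
        n_per_group=spec.da_n_per_group,
        locations=spec.da_locations,
    )
    truth.planted_da = planted

    return Community(
        spec=spec,
        host_scaffolds=[
            SequenceRecord(sid, seq, spec.sample_id) for sid, seq in host_seqs.items()
        ],
        phage_scaffolds=[
            SequenceRecord(f"phage_{i}", phage_seqs[i], spec.sample_id)
            for i in range(spec.n_phages)
        ],
        bin_table=pd.DataFrame(bin_rows),
        provirus_calls=pd.DataFrame(provirus_rows, columns=["scaffold_id"]),
        gene_table=gene_table,
        depth_table=pd.DataFrame(depth_rows),
        pads_hits=pads,
        pfam_hits=pfam,
        kegg_hits=kegg,
        counts=counts,
        sample_sheet=sheet,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Defensome / AMG hit tables

_DEFENCE_PLANTS = [
    # (system, component, pfam_accession) drawn from the default config
    ("RM", "methyltransferase", "PF01555"),
    ("RM", "restriction_endonuclease", "PF04313"),
    ("CRISPR-Cas", "cas1", "PF01867"),
    ("CRISPR-Cas", "cas2", "PF09827"),
    ("TA", "toxin", "PF05016"),
    ("TA", "antitoxin", "PF04221"),
    ("BREX", "brxC", "PF10923"),
    ("Gabija", "gajA", "PF13175"),
]
_AMG_PLANTS = [("K00525", "PF00317", "nrdA"), ("K02703", "PF00124", "psbA")]


def _generate_defensome_hits(rng, gene_table):
    """Plant defence hits on host genes, RM counter-defence and AMG hits on
    viral genes, plus sub-threshold decoys that must NOT be called."""
    host_cds = gene_table[
        gene_table.scaffold.str.startswith("host") & (gene_table.gene_type == "cds")
    ].gene_id.tolist()
    phage_cds = gene_table[
        gene_table.scaffold.str.startswith("phage") & (gene_table.gene_type == "cds")
    ].gene_id.tolist()
    pads_rows, pfam_rows, kegg_rows = [], [], []

    def pads(gid, acc, identity, evalue):
        pads_rows.append(dict(gene_id=gid, db="PADS", accession=acc,
                              identity=identity, evalue=evalue, bitscore=200.0))

    def pfam(gid, acc, evalue, bitscore):
        pfam_rows.append(dict(gene_id=gid, db="PFAM", accession=acc,
                              identity=np.nan, evalue=evalue, bitscore=bitscore))

    def kegg(gid, acc, evalue, score, threshold):
        kegg_rows.append(dict(gene_id=gid, db="KEGG", accession=acc,
                              evalue=evalue, bitscore=score, threshold=threshold))

    # true defence genes on hosts (round-robin over systems)
    for k, gid in enumerate(host_cds[: len(host_cds) // 2]):
        system, component, acc = _DEFENCE_PLANTS[k % len(_DEFENCE_PLANTS)]
        pads(gid, f"{system}:{component}", 45.0, 1e-20)
        pfam(gid, acc, 1e-6, 80.0)
    # decoys: PADS identity below 30, or missing PFAM confirmation
    decoys = host_cds[len(host_cds) // 2 : len(host_cds) // 2 + 6]
    for gid in decoys[:3]:
        pads(gid, "RM:methyltransferase", 25.0, 1e-20)
        pfam(gid, "PF01555", 1e-6, 80.0)
    for gid in decoys[3:]:
        pads(gid, "RM:methyltransferase", 45.0, 1e-20)
        pfam(gid, "PF01555", 1e-6, 20.0)  # bit score below 30

    # counter-defence (RM) on some viral genes
    for gid in phage_cds[:6]:
        pads(gid, "RM:methyltransferase", 50.0, 1e-25)
        pfam(gid, "PF01555", 1e-8, 90.0)
    # AMGs on viral genes (KEGG + PFAM + listed accession)
    for k, gid in enumerate(phage_cds[6:12]):
        kegg_acc, pfam_acc, _ = _AMG_PLANTS[k % len(_AMG_PLANTS)]
        kegg(gid, kegg_acc, 1e-12, 150.0, 100.0)
        pfam(gid, pfam_acc, 1e-6, 85.0)
    # AMG decoy: KEGG score below the family threshold
    if len(phage_cds) > 12:
        kegg(phage_cds[12], "K00525", 1e-12, 60.0, 100.0)
        pfam(phage_cds[12], "PF00317", 1e-6, 85.0)

    cols_p = ["gene_id", "db", "accession", "identity", "evalue", "bitscore"]
    cols_k = ["gene_id", "db", "accession", "evalue", "bitscore", "threshold"]
    return (
        pd.DataFrame(pads_rows, columns=cols_p),
        pd.DataFrame(pfam_rows, columns=cols_p),
        pd.DataFrame(kegg_rows, columns=cols_k),
    )


# ---------------------------------------------------------------------------
# Differential-abundance counts


def generate_da_counts(
    rng: np.random.Generator,
    n_genes: int = 200,
    n_shifted: int = 20,
    log2fc: float = 1.5,
    dispersion: float = 0.1,
    n_per_group: int = 8,
    locations: tuple[str, ...] = ("HK", "RS"),
    base_mean: float = 100.0,
):
    """Negative-binomial gene x sample counts with planted seawater-vs-
    biofilm shifts shared across locations.

    Positive planted log2fc means seawater-enriched. Library sizes are
    log-normal; half of the shifted genes go each direction.
    """
    genes = [f"dgene_{i:04d}" for i in range(n_genes)]
    planted = {g: 0.0 for g in genes}
    for k in range(n_shifted):
        planted[genes[k]] = log2fc if k % 2 == 0 else -log2fc
    base = np.exp(rng.normal(np.log(base_mean), 0.8, size=n_genes))
    cols, data = [], []
    sheet_rows = []
    for loc in locations:
        libs = np.exp(rng.normal(0.0, 0.3, size=2 * n_per_group))
        for j in range(2 * n_per_group):
            stype = "biofilm" if j < n_per_group else "seawater"
            name = f"{loc}_{stype}_{j % n_per_group}"
            sheet_rows.append(dict(sample=name, location=loc, sample_type=stype))
            lfc = np.array([planted[g] for g in genes])
            shift = np.where(np.array([stype == "seawater"] * n_genes), lfc / 2, -lfc / 2)
            mu = base * (2.0 ** shift) * libs[j]
            r = 1.0 / dispersion
            counts = rng.negative_binomial(r, r / (r + mu))
            cols.append(name)
            data.append(counts)
    counts_df = pd.DataFrame(
        np.column_stack(data), index=pd.Index(genes, name="gene_id"), columns=cols
    )
    return counts_df, pd.DataFrame(sheet_rows), planted


# ---------------------------------------------------------------------------
# DTR rule panel (closed-genome triage testing)


def generate_dtr_panel(rng_or_seed=0, n_clean: int = 20, scaffold_len: int = 6000):
    """A labelled panel of scaffolds exercising each closed-genome rule.

    Returns ``(scaffolds, provirus_calls, bin_table, labels)`` where
    ``labels`` maps scaffold_id to the rule it violates (or "clean").
    Violations: missing DTR, provirus flag, low-complexity repeat, N in
    repeat, >= 6 occurrences, repeat covering >= 20% of the scaffold.
    """
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    scaffolds, labels = [], {}
    provirus_rows, bin_rows = [], []

    def plant_dtr(seq, dtr):
        return dtr + seq[len(dtr) : -len(dtr)] + dtr

    i = 0

    def emit(seq, label, provirus=False):
        nonlocal i
        sid = f"panel_{i:03d}"
        i += 1
        scaffolds.append(SequenceRecord(sid, seq))
        labels[sid] = label
        if provirus:
            provirus_rows.append(dict(scaffold_id=sid))
            bin_rows.append(dict(scaffold_id=sid, bin_id="panelbin_0",
                                 completeness=80.0, contamination=2.0,
                                 domain="prokaryote"))

    for _ in range(n_clean):
        dtr = _random_repeat(rng, int(rng.integers(25, 80)))
        emit(plant_dtr(random_seq(rng, scaffold_len), dtr), "clean")
    for _ in range(6):
        emit(random_seq(rng, scaffold_len), "no_dtr")
    for _ in range(6):
        dtr = _random_repeat(rng, 40)
        emit(plant_dtr(random_seq(rng, scaffold_len), dtr), "provirus", provirus=True)
    for _ in range(6):
        dtr = "AT" * 20  # perfect 2-mer tandem
        emit(plant_dtr(random_seq(rng, scaffold_len), dtr), "low_complexity")
    for _ in range(4):
        dtr = _random_repeat(rng, 40)
        dtr = dtr[:20] + "N" + dtr[21:]
        emit(plant_dtr(random_seq(rng, scaffold_len), dtr), "has_N")
    for _ in range(4):
        dtr = _random_repeat(rng, 40)
        seq = plant_dtr(random_seq(rng, scaffold_len), dtr)
        mid = scaffold_len // 2
        for k in range(4):  # 2 terminal + 4 internal = 6 occurrences
            pos = mid + k * 200
            seq = _overwrite(seq, pos, dtr)
        emit(seq, "too_many_occurrences")
    for _ in range(4):
        dtr = _random_repeat(rng, 700)  # 2 x 700 / 6000 = 23.3% coverage
        emit(plant_dtr(random_seq(rng, scaffold_len), dtr), "coverage")
    return (
        scaffolds,
        pd.DataFrame(provirus_rows, columns=["scaffold_id"]),
        pd.DataFrame(bin_rows, columns=["scaffold_id", "bin_id", "completeness",
                                        "contamination", "domain"]),
        labels,
    )


# ---------------------------------------------------------------------------
# Ground-truth round-trip


def write_truth(gt: GroundTruth, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        sorted(gt.true_links), columns=["phage_id", "host_id", "channel"]
    ).to_csv(outdir / "truth_links.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(gt.true_closed), columns=["scaffold_id"]).to_csv(
        outdir / "truth_closed.tsv", sep="\t", index=False
    )
    pd.DataFrame(sorted(gt.true_proviruses), columns=["scaffold_id"]).to_csv(
        outdir / "truth_proviruses.tsv", sep="\t", index=False
    )
    pop_rows = [
        dict(population=f"pop_{k}", member=m)
        for k, group in enumerate(sorted(gt.true_populations, key=sorted))
        for m in sorted(group)
    ]
    pd.DataFrame(pop_rows, columns=["population", "member"]).to_csv(
        outdir / "truth_populations.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        sorted(gt.planted_da.items()), columns=["gene_id", "log2fc"]
    ).to_csv(outdir / "truth_da.tsv", sep="\t", index=False)


def read_truth(outdir) -> GroundTruth:
    outdir = Path(outdir)
    links = pd.read_csv(outdir / "truth_links.tsv", sep="\t")
    closed = pd.read_csv(outdir / "truth_closed.tsv", sep="\t")
    prov = pd.read_csv(outdir / "truth_proviruses.tsv", sep="\t")
    pops = pd.read_csv(outdir / "truth_populations.tsv", sep="\t")
    da = pd.read_csv(outdir / "truth_da.tsv", sep="\t")
    groups = [
        frozenset(sub.member) for _, sub in pops.groupby("population", sort=True)
    ] if len(pops) else []
    return GroundTruth(
        true_links=set(map(tuple, links.itertuples(index=False))),
        true_closed=set(closed.scaffold_id),
        true_proviruses=set(prov.scaffold_id),
        true_populations=sorted(groups, key=sorted),
        planted_da=dict(zip(da.gene_id, da.log2fc)),
    )
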