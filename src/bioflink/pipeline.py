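"""End-to-end pipeline over a synthetic community.

Stages: simulate -> triage -> link -> populations -> abundance ->
defensome -> meta. Each stage reads the TSV/FASTA outputs of the ones
before it from the run directory, so stages can be re-run individually.
A manifest records the configuration hash and output checksums; the same
seed and config reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import (
    abundance_expression,
    defensome_calls,
    differential_meta,
    host_linkage,
    population_ani,
    synthetic_community,
    viral_triage,
)
from .seq_core import read_fasta

log = logging.getLogger("bioflink")

#: every tunable threshold, with the study defaults
DEFAULT_CONFIG = {
    "seed": 0,
    "n_hosts": 6,
    "n_phages": 10,
    "phage_len": 10_000,
    "host_len": 30_000,
    "mutation_rate": 0.10,
    "n_links": 12,
    "n_closed": 2,
    "n_proviruses": 1,
    "min_identity": 0.70,
    "min_aln_len": 2500,
    "min_spacer_len": 7,
    "kmer_k": 25,
    "kmer_min_shared": 10,
    "ani_threshold": 95.0,
    "frag_len": 500,
    "min_fraction_virus": 0.8,
    "min_fraction_host": 0.5,
    "pads_min_identity": 30.0,
    "pads_max_evalue": 1e-10,
    "pfam_max_evalue": 1e-3,
    "pfam_min_bitscore": 30.0,
    "kegg_max_evalue": 1e-5,
    "padj_cut": 0.05,
    "da_n_genes": 120,
    "da_n_per_group": 8,
    "da_log2fc": 1.5,
    "da_dispersion": 0.1,
}


class ConfigError(ValueError):
    pass


def load_config(path=None, overrides: dict | None = None) -> dict:
    config = dict(DEFAULT_CONFIG)
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(user, dict):
            raise ConfigError("config file must be a YAML mapping")
        for key, value in user.items():
            if key not in DEFAULT_CONFIG:
                raise ConfigError(f"unknown config field: {key}")
            config[key] = value
    for key, value in (overrides or {}).items():
        if value is not None:
            config[key] = value
    for key in ("min_identity", "min_fraction_virus", "min_fraction_host"):
        if not 0 < float(config[key]) <= 1:
            raise ConfigError(f"config field {key} must be in (0, 1]")
    if int(config["seed"]) < 0:
        raise ConfigError("config field seed must be >= 0")
    return config


def _default_link_plan(config, rng) -> tuple:
    """Spread n_links over phage x host with round-robin channels."""
    channels = list(synthetic_community.CHANNELS)
    plan = []
    n_phages, n_hosts = int(config["n_phages"]), int(config["n_hosts"])
    for i in range(int(config["n_links"])):
        plan.append(
            (i % n_phages, (i * 3 + i // n_phages) % n_hosts,
             frozenset({channels[i % 4]}))
        )
    return tuple(plan)


def community_spec_from_config(config) -> synthetic_community.CommunitySpec:
    rng = np.random.default_rng(int(config["seed"]))
    return synthetic_community.CommunitySpec(
        n_hosts=int(config["n_hosts"]),
        n_phages=int(config["n_phages"]),
        host_len=int(config["host_len"]),
        phage_len=int(config["phage_len"]),
        link_plan=_default_link_plan(config, rng),
        mutation_rate=float(config["mutation_rate"]),
        seed=int(config["seed"]),
        closed_phages=tuple(range(int(config["n_closed"]))),
        provirus_phages=tuple(
            range(int(config["n_closed"]),
                  int(config["n_closed"]) + int(config["n_proviruses"]))
        ),
        da_n_genes=int(config["da_n_genes"]),
        da_n_per_group=int(config["da_n_per_group"]),
        da_log2fc=float(config["da_log2fc"]),
        da_dispersion=float(config["da_dispersion"]),
    )


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(config, outdir: Path):
    spec = community_spec_from_config(config)
    community = synthetic_community.generate_community(spec)
    community.write(outdir / "community")
    log.info("simulate: %d hosts, %d phages, %d planted links",
             spec.n_hosts, spec.n_phages, len(spec.link_plan))
    return community


def _load_community_tables(outdir: Path):
    cdir = outdir / "community"
    if not (cdir / "hosts.fasta").exists():
        raise FileNotFoundError(f"missing FASTA: {cdir / 'hosts.fasta'}")
    return dict(
        hosts=read_fasta(cdir / "hosts.fasta"),
        phages=read_fasta(cdir / "phages.fasta"),
        bin_table=pd.read_csv(cdir / "bin_table.tsv", sep="\t"),
        provirus_calls=pd.read_csv(cdir / "provirus_calls.tsv", sep="\t"),
        gene_table=pd.read_csv(cdir / "gene_table.tsv", sep="\t", keep_default_na=False),
        depth_table=pd.read_csv(cdir / "depth_table.tsv", sep="\t"),
        pads_hits=pd.read_csv(cdir / "pads_hits.tsv", sep="\t"),
        pfam_hits=pd.read_csv(cdir / "pfam_hits.tsv", sep="\t"),
        kegg_hits=pd.read_csv(cdir / "kegg_hits.tsv", sep="\t"),
        counts=pd.read_csv(cdir / "counts.tsv", sep="\t", index_col=0),
        sample_sheet=pd.read_csv(cdir / "sample_sheet.tsv", sep="\t"),
    )


def stage_triage(config, outdir: Path):
    data = _load_community_tables(outdir)
    flags = viral_triage.flag_proviruses(data["provirus_calls"], data["bin_table"])
    units = viral_triage.build_viral_units(
        data["phages"], flags, bins={}, gene_tax=data["gene_table"],
        terl_gene_ids=set(
            data["gene_table"].loc[data["gene_table"].gene_type == "terl", "gene_id"]
        ),
    )
    viral_triage.units_to_table(units).to_csv(
        outdir / "units.tsv", sep="\t", index=False
    )
    log.info("triage: %d viral units (%d closed)",
             len(units), sum(u.kind == "closed_genome" for u in units))
    return units


def _units_from_table(outdir: Path):
    tab = pd.read_csv(outdir / "units.tsv", sep="\t")
    return [
        viral_triage.ViralUnit(
            unit_id=row.unit_id, kind=row.kind,
            scaffolds=row.scaffolds.split(","), phylum=row.phylum,
            sample_id=row.sample_id if isinstance(row.sample_id, str) else "",
        )
        for row in tab.itertuples(index=False)
    ]


def _host_bins(bin_table) -> dict:
    prok = bin_table[bin_table.domain == "prokaryote"]
    # provirus scaffolds listed in host bins are viral sequence, not host
    prok = prok[~prok.scaffold_id.str.startswith("phage_")]
    return {b: sorted(sub.scaffold_id) for b, sub in prok.groupby("bin_id")}


def stage_link(config, outdir: Path):
    data = _load_community_tables(outdir)
    units = _units_from_table(outdir)
    seqs = {r.id: r for r in data["hosts"] + data["phages"]}
    pairs = host_linkage.link_community(
        units, _host_bins(data["bin_table"]), seqs, data["gene_table"],
        min_identity=float(config["min_identity"]),
        min_len=int(config["min_aln_len"]),
        k=int(config["kmer_k"]),
        min_shared=int(config["kmer_min_shared"]),
        min_spacer_len=int(config["min_spacer_len"]),
    )
    host_linkage.pairs_to_table(pairs).to_csv(
        outdir / "pairs.tsv", sep="\t", index=False
    )
    log.info("link: %d virus-host pairs", len(pairs))
    return pairs


def stage_populations(config, outdir: Path):
    data = _load_community_tables(outdir)
    phage_genomes = {r.id: r.seq for r in data["phages"]}
    host_bins = _host_bins(data["bin_table"])
    host_seq = {r.id: r.seq for r in data["hosts"]}
    host_genomes = {
        b: "".join(host_seq[s] for s in members if s in host_seq)
        for b, members in host_bins.items()
    }
    v_ani = population_ani.pairwise_ani(
        phage_genomes, min_fraction=float(config["min_fraction_virus"]),
        frag_len=int(config["frag_len"]),
    )
    h_ani = population_ani.pairwise_ani(
        host_genomes, min_fraction=float(config["min_fraction_host"]),
        frag_len=int(config["frag_len"]),
    )
    v_pops = population_ani.cluster_populations(
        sorted(phage_genomes), v_ani, float(config["ani_threshold"]), "virus"
    )
    h_pops = population_ani.cluster_populations(
        sorted(host_genomes), h_ani, float(config["ani_threshold"]), "host"
    )
    pd.concat([v_ani, h_ani]).to_csv(outdir / "ani.tsv", sep="\t", index=False)
    pd.concat(
        [
            population_ani.populations_to_table(v_pops),
            population_ani.populations_to_table(h_pops),
        ]
    ).to_csv(outdir / "populations.tsv", sep="\t", index=False)

    pairs_tab = pd.read_csv(outdir / "pairs.tsv", sep="\t")
    pairs_by_sample = {"S1": list(zip(pairs_tab.virus_unit, pairs_tab.host_bin))}
    population_ani.shared_pairs(pairs_by_sample, v_pops, h_pops).to_csv(
        outdir / "shared_pairs.tsv", sep="\t", index=False
    )
    log.info("populations: %d virus, %d host", len(v_pops), len(h_pops))
    return v_pops, h_pops


def stage_abundance(config, outdir: Path):
    data = _load_community_tables(outdir)
    units = _units_from_table(outdir)
    pairs_tab = pd.read_csv(outdir / "pairs.tsv", sep="\t")
    depth = data["depth_table"]
    host_bins = _host_bins(data["bin_table"])
    samples = sorted(depth.sample_id.unique())

    cov_rows = []
    vpr_frames = []
    unit_kind = {u.unit_id: u.kind for u in units}
    for sample in samples:
        unit_depth, host_depth = {}, {}
        for u in units:
            prof = abundance_expression.mean_depth(depth, u.scaffolds, u.unit_id, sample)
            unit_depth[u.unit_id] = prof.mean_depth
            cov_rows.append(vars(prof))
        for b, members in host_bins.items():
            prof = abundance_expression.mean_depth(depth, members, b, sample)
            host_depth[b] = prof.mean_depth
            cov_rows.append(vars(prof))
        vpr = abundance_expression.virus_host_ratio(
            list(zip(pairs_tab.virus_unit, pairs_tab.host_bin)),
            unit_depth, host_depth, unit_kind,
        )
        vpr.insert(0, "sample_id", sample)
        vpr_frames.append(vpr)
    pd.DataFrame(cov_rows).to_csv(outdir / "coverage.tsv", sep="\t", index=False)
    pd.concat(vpr_frames).to_csv(outdir / "vpr.tsv", sep="\t", index=False)

    # RPKM + relative abundance of the count table
    counts = data["counts"]
    sheet = data["sample_sheet"].set_index("sample")
    lengths = pd.Series(1000.0, index=counts.index)  # synthetic genes, 1 kb
    lib = counts.sum(axis=0)
    rp = abundance_expression.rpkm(counts, lengths, lib)
    groups = sheet.location + ":" + sheet.sample_type
    rel = abundance_expression.relative_abundance(rp, groups)
    rp.to_csv(outdir / "rpkm.tsv", sep="\t")
    rel.to_csv(outdir / "relative_abundance.tsv", sep="\t")

    # TPM + expression rule on the first three biofilm replicates
    reps = [s for s in counts.columns if "biofilm" in s][:3]
    calls = abundance_expression.tpm_and_expressed(
        counts[reps], transcript_hits={}, gene_lengths=lengths
    )
    pd.DataFrame(
        [
            dict(gene_id=c.gene_id, n_transcript_hits=c.n_transcript_hits,
                 expressed=c.expressed,
                 **{f"tpm_{i}": t for i, t in enumerate(c.tpm)})
            for c in calls
        ]
    ).to_csv(outdir / "expression.tsv", sep="\t", index=False)
    log.info("abundance: %d coverage rows", len(cov_rows))


def stage_defensome(config, outdir: Path):
    data = _load_community_tables(outdir)
    gene_table = data["gene_table"]
    viral_genes = set(
        gene_table.loc[gene_table.scaffold.str.startswith("phage"), "gene_id"]
    )
    kwargs = dict(
        min_identity=float(config["pads_min_identity"]),
        max_pads_evalue=float(config["pads_max_evalue"]),
        max_pfam_evalue=float(config["pfam_max_evalue"]),
        min_pfam_bitscore=float(config["pfam_min_bitscore"]),
    )
    host_pads = data["pads_hits"][~data["pads_hits"].gene_id.isin(viral_genes)]
    defence = defensome_calls.call_defence_genes(
        host_pads, data["pfam_hits"], **kwargs
    )
    counter = defensome_calls.call_counter_defence(
        data["pads_hits"], data["pfam_hits"], viral_genes, **kwargs
    )
    amgs = defensome_calls.call_amgs(
        data["kegg_hits"], data["pfam_hits"], gene_table,
        max_kegg_evalue=float(config["kegg_max_evalue"]),
        max_pfam_evalue=float(config["pfam_max_evalue"]),
        min_pfam_bitscore=float(config["pfam_min_bitscore"]),
    )
    scaffold_of = dict(zip(gene_table.gene_id, gene_table.scaffold))
    systems = defensome_calls.system_completeness(defence, scaffold_of)
    defence.to_csv(outdir / "defence_genes.tsv", sep="\t", index=False)
    counter.to_csv(outdir / "counter_defence.tsv", sep="\t", index=False)
    amgs.to_csv(outdir / "amgs.tsv", sep="\t", index=False)
    defensome_calls.systems_to_table(systems).to_csv(
        outdir / "systems.tsv", sep="\t", index=False
    )
    log.info("defensome: %d defence, %d counter-defence, %d AMGs",
             len(defence), len(counter), len(amgs))


def stage_meta(config, outdir: Path):
    data = _load_community_tables(outdir)
    counts, sheet = data["counts"], data["sample_sheet"]
    results = []
    for loc, sub in sheet.groupby("location"):
        types = sub.set_index("sample").sample_type
        results.extend(
            differential_meta.differential_abundance(
                counts[list(sub["sample"])], types, location=loc
            )
        )
    differential_meta.da_to_table(results).to_csv(
        outdir / "da.tsv", sep="\t", index=False
    )
    metas, summary = differential_meta.select_significant(
        results, padj_cut=float(config["padj_cut"])
    )
    differential_meta.meta_to_table(metas).to_csv(
        outdir / "meta.tsv", sep="\t", index=False
    )
    summary.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    log.info("meta: %d candidate genes pooled", len(metas))


STAGES = {
    "simulate": stage_simulate,
    "triage": stage_triage,
    "link": stage_link,
    "populations": stage_populations,
    "abundance": stage_abundance,
    "defensome": stage_defensome,
    "meta": stage_meta,
}
STAGE_ORDER = list(STAGES)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(config, outdir: Path) -> None:
    outputs = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = dict(
        version=__version__,
        seed=int(config["seed"]),
        config_hash=hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest(),
        config=config,
        outputs=outputs,
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def run_pipeline(config, outdir, stages=None) -> Path:
    """Run the requested stages (default: all, in order)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in stages or STAGE_ORDER:
        log.info("stage %s", name)
        STAGES[name](config, outdir)
    write_manifest(config, outdir)
    return outdir
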