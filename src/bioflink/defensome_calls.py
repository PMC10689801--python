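"""Defence, counter-defence and AMG gene calling.

The search engines themselves (DIAMOND against PADS, HMMER against PFAM,
KofamScan against KEGG) are consumed as tabular hits. Calling is a pure
threshold conjunction:

* defence gene — PADS hit (identity >= 30%, E-value < 1e-10) AND a PFAM
  hit (E-value < 1e-3, bit score >= 30) whose accession is a conserved
  domain of the claimed system;
* counter-defence gene — the same conjunction, restricted to
  restriction-modification accessions on viral genes;
* AMG — KEGG hit (E-value < 1e-5, score above the family threshold
  supplied with the hit) AND PFAM hit (E-value < 1e-3, bit score > 30)
  AND the accession on the curated AMG list; genes sitting first or last
  on their scaffold are flagged (``edge_gene``) rather than dropped,
  mechanising the positional screening step;
* a defence system is complete when every required component has at
  least one called gene in the container (contig or bin).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

PADS_MIN_IDENTITY = 30.0
PADS_MAX_EVALUE = 1e-10
PFAM_MAX_EVALUE = 1e-3
PFAM_MIN_BITSCORE = 30.0
KEGG_MAX_EVALUE = 1e-5


@dataclass
class SystemCall:
    container_id: str
    system: str
    genes: list
    complete: bool


def load_defence_config(path=None) -> dict:
    """System -> component -> [PFAM accessions]; defaults ship with the
    package."""
    if path is None:
        text = resources.files("bioflink.data").joinpath("defence_systems.yaml").read_text()
    else:
        text = Path(path).read_text()
    config = yaml.safe_load(text)
    for system, components in config.items():
        if not isinstance(components, dict) or not components:
            raise ValueError(f"config error: system {system!r} has no component map")
    return config


def load_amg_config(path=None) -> dict:
    if path is None:
        text = resources.files("bioflink.data").joinpath("amg_accessions.yaml").read_text()
    else:
        text = Path(path).read_text()
    config = yaml.safe_load(text)
    return {"kegg": set(config.get("kegg", [])), "pfam": set(config.get("pfam", []))}


def _domain_lookup(config: dict) -> dict:
    """PFAM accession -> (system, component)."""
    lookup = {}
    for system, components in config.items():
        for component, accessions in components.items():
            for acc in accessions:
                lookup[acc] = (system, component)
    return lookup


def call_defence_genes(
    pads_hits: pd.DataFrame,
    pfam_hits: pd.DataFrame,
    config: dict | None = None,
    min_identity: float = PADS_MIN_IDENTITY,
    max_pads_evalue: float = PADS_MAX_EVALUE,
    max_pfam_evalue: float = PFAM_MAX_EVALUE,
    min_pfam_bitscore: float = PFAM_MIN_BITSCORE,
) -> pd.DataFrame:
    """Genes passing the PADS + conserved-PFAM-domain conjunction.

    PADS accessions are expected as ``system:component`` labels. Returns
    one row per called gene with its system and component.
    """
    config = config or load_defence_config()
    lookup = _domain_lookup(config)
    pads_ok = pads_hits[
        (pads_hits.identity >= min_identity) & (pads_hits.evalue < max_pads_evalue)
    ]
    pfam_ok = pfam_hits[
        (pfam_hits.evalue < max_pfam_evalue) & (pfam_hits.bitscore >= min_pfam_bitscore)
    ]
    rows = []
    pfam_by_gene = dict(tuple(pfam_ok.groupby("gene_id"))) if len(pfam_ok) else {}
    for hit in pads_ok.itertuples(index=False):
        system = str(hit.accession).split(":", 1)[0]
        if system not in config:
            raise ValueError(f"config error: PADS hit names unknown system {system!r}")
        confirm = pfam_by_gene.get(hit.gene_id)
        if confirm is None:
            continue
        for dom in confirm.itertuples(index=False):
            hit_sys = lookup.get(dom.accession)
            if hit_sys and hit_sys[0] == system:
                rows.append(
                    dict(
                        gene_id=hit.gene_id,
                        system=system,
                        component=hit_sys[1],
                        pads_identity=hit.identity,
                        pads_evalue=hit.evalue,
                        pfam_accession=dom.accession,
                        pfam_bitscore=dom.bitscore,
                    )
                )
                break
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "system", "component", "pads_identity", "pads_evalue",
            "pfam_accession", "pfam_bitscore",
        ],
    ).drop_duplicates("gene_id")


def call_counter_defence(
    pads_hits: pd.DataFrame,
    pfam_hits: pd.DataFrame,
    viral_gene_ids: set,
    config: dict | None = None,
    **thresholds,
) -> pd.DataFrame:
    """RM-system genes on viral genes only, same conjunction as defence
    calling."""
    config = config or load_defence_config()
    viral_pads = pads_hits[
        pads_hits.gene_id.isin(viral_gene_ids)
        & pads_hits.accession.astype(str).str.startswith("RM:")
    ]
    return call_defence_genes(viral_pads, pfam_hits, {"RM": config["RM"]}, **thresholds)


def call_amgs(
    kegg_hits: pd.DataFrame,
    pfam_hits: pd.DataFrame,
    gene_table: pd.DataFrame,
    amg_config: dict | None = None,
    max_kegg_evalue: float = KEGG_MAX_EVALUE,
    max_pfam_evalue: float = PFAM_MAX_EVALUE,
    min_pfam_bitscore: float = PFAM_MIN_BITSCORE,
) -> pd.DataFrame:
    """AMG calls on viral genes with an edge-gene flag.

    ``kegg_hits`` must carry a per-family ``threshold`` column (the
    adaptive cutoff the KEGG search reports); a hit scores only when its
    bit score exceeds it. ``gene_table`` (gene_id, scaffold, start)
    supplies gene order for the edge flag.
    """
    amg_config = amg_config or load_amg_config()
    kegg_ok = kegg_hits[
        (kegg_hits.evalue < max_kegg_evalue)
        & (kegg_hits.bitscore > kegg_hits.threshold)
        & (kegg_hits.accession.isin(amg_config["kegg"]))
    ]
    pfam_ok = pfam_hits[
        (pfam_hits.evalue < max_pfam_evalue)
        & (pfam_hits.bitscore > min_pfam_bitscore)
        & (pfam_hits.accession.isin(amg_config["pfam"]))
    ]
    pfam_genes = set(pfam_ok.gene_id)

    order = gene_table.sort_values(["scaffold", "start"])
    edge_genes = set()
    for _, sub in order.groupby("scaffold"):
        edge_genes.add(sub.gene_id.iloc[0])
        edge_genes.add(sub.gene_id.iloc[-1])

    rows = []
    for hit in kegg_ok.itertuples(index=False):
        if hit.gene_id not in pfam_genes:
            continue
        rows.append(
            dict(
                gene_id=hit.gene_id,
                kegg_accession=hit.accession,
                kegg_score=hit.bitscore,
                edge_gene=hit.gene_id in edge_genes,
            )
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "kegg_accession", "kegg_score", "edge_gene"]
    ).drop_duplicates("gene_id")


def system_completeness(
    defence_calls: pd.DataFrame,
    gene_container: dict,
    config: dict | None = None,
) -> list:
    """Per-container system calls; complete iff every required component
    of the system has >= 1 called gene in the container."""
    config = config or load_defence_config()
    calls = []
    tab = defence_calls.copy()
    tab["container"] = tab.gene_id.map(gene_container)
    for (container, system), sub in tab.groupby(["container", "system"], sort=True):
        required = set(config[system])
        present = set(sub.component)
        calls.append(
            SystemCall(
                container_id=container,
                system=system,
                genes=sorted(sub.gene_id),
                complete=required <= present,
            )
        )
    return calls


def systems_to_table(calls: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                container_id=c.container_id,
                system=c.system,
                n_genes=len(c.genes),
                complete=c.complete,
                genes=",".join(c.genes),
            )
            for c in calls
        ],
        columns=["container_id", "system", "n_genes", "complete", "genes"],
    )
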