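"""Biofilm-vs-seawater differential abundance and cross-location meta-analysis.

Per location, gene counts are tested between the two sample types with a
negative-binomial Wald test: median-of-ratios size factors, gene-wise
method-of-moments dispersion (with a small floor), a log-link NB GLM fit
on the group indicator, and Benjamini-Hochberg adjustment across genes.
Genes significant within a location feed a DerSimonian-Laird
random-effects meta-analysis pooling the per-location log2 fold changes
weighted by their squared standard errors.

Sign convention: positive log2 fold change = seawater-enriched; pass
``positive_is="biofilm"`` to flip it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

LN2 = np.log(2.0)


@dataclass
class DAResult:
    gene_id: str
    location: str
    log2fc: float
    se: float
    p: float
    padj: float


@dataclass
class MetaEffect:
    gene_id: str
    pooled_log2fc: float
    se_pooled: float
    ci95: tuple
    tau2: float
    q_stat: float
    p: float
    k: int


# ---------------------------------------------------------------------------
# Size factors and dispersion


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style size factors: per-sample median of count ratios to the
    geometric-mean pseudo-reference, over genes with all-positive counts."""
    log_counts = np.log(counts.where(counts > 0))
    log_ref = log_counts.mean(axis=1)
    usable = log_ref.notna() & np.isfinite(log_ref)
    if not usable.any():
        raise ValueError("no gene has positive counts in every sample")
    ratios = log_counts.loc[usable].sub(log_ref[usable], axis=0)
    return np.exp(ratios.median(axis=0))


def moments_dispersion(
    norm_counts: np.ndarray, design: np.ndarray, floor: float = 1e-6
) -> np.ndarray:
    """Per-gene NB dispersion alpha from method of moments, pooling the
    within-group mean/variance: alpha = (var - mu) / mu^2, floored.

    ``norm_counts`` is genes x samples (already size-factor normalised);
    ``design`` is the binary group vector.
    """
    alphas = np.full(norm_counts.shape[0], floor)
    for g in (0, 1):
        cols = design == g
        if cols.sum() < 2:
            continue
        mu = norm_counts[:, cols].mean(axis=1)
        var = norm_counts[:, cols].var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (var - mu) / np.where(mu > 0, mu**2, np.nan)
        a = np.where(np.isfinite(a), a, floor)
        alphas = np.maximum(alphas, a)
    return np.maximum(alphas, floor)


# ---------------------------------------------------------------------------
# Per-location differential abundance


def differential_abundance(
    counts: pd.DataFrame,
    sample_types: pd.Series,
    location: str = "",
    positive_is: str = "seawater",
    alpha_floor: float = 1e-6,
) -> list:
    """NB-Wald differential abundance of one location's counts.

    ``counts``: genes x samples (integers); ``sample_types``: sample ->
    {"biofilm", "seawater"}. All-zero genes are excluded. P-values come
    from a t reference with n - 2 degrees of freedom, a small-sample
    guard on the plug-in dispersion.
    """
    types = sample_types.reindex(counts.columns)
    if types.isna().any():
        raise ValueError("sample sheet missing entries for some count columns")
    groups = sorted(types.unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two sample types, got {groups}")
    if (types == "biofilm").sum() < 2 or (types == "seawater").sum() < 2:
        raise ValueError("need >= 2 samples per group")

    keep = counts.sum(axis=1) > 0
    counts_kept = counts.loc[keep]
    sf = median_of_ratios_size_factors(counts_kept)
    norm = counts_kept.to_numpy(dtype=float) / sf.to_numpy()
    group = (types == positive_is).to_numpy().astype(int)
    alphas = moments_dispersion(norm, group, floor=alpha_floor)

    design = sm.add_constant(group.astype(float))
    offset = np.log(sf.to_numpy())
    df_resid = counts_kept.shape[1] - 2
    results = []
    y_all = counts_kept.to_numpy(dtype=float)
    for i, gene in enumerate(counts_kept.index):
        fam = sm.families.NegativeBinomial(alpha=float(alphas[i]))
        try:
            fit = sm.GLM(y_all[i], design, family=fam, offset=offset).fit()
            beta, se = float(fit.params[1]), float(fit.bse[1])
        except Exception:
            continue
        if not np.isfinite(se) or se <= 0:
            continue
        t_stat = beta / se
        p = 2.0 * stats.t.sf(abs(t_stat), df_resid)
        results.append(
            DAResult(gene, location, beta / LN2, se / LN2, float(p), np.nan)
        )
    pvals = np.array([r.p for r in results])
    if len(pvals):
        padj = multipletests(pvals, method="fdr_bh")[1]
        for r, q in zip(results, padj):
            r.padj = float(q)
    return results


def da_to_table(results: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(gene_id=r.gene_id, location=r.location, log2fc=r.log2fc,
                 se=r.se, p=r.p, padj=r.padj)
            for r in results
        ],
        columns=["gene_id", "location", "log2fc", "se", "p", "padj"],
    )


# ---------------------------------------------------------------------------
# Benjamini-Hochberg (exposed for the oracle property test)


def benjamini_hochberg(pvals) -> np.ndarray:
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# DerSimonian-Laird random-effects meta-analysis


def random_effects_meta(
    effects, ses, gene_id: str = "", alpha: float = 0.05
) -> MetaEffect:
    """Pool per-location effects with the classical DerSimonian-Laird
    moment estimator of between-location variance tau^2.

    With a single location the input effect is returned exactly
    (tau2 = 0, se_pooled = se).
    """
    y = np.asarray(effects, dtype=float)
    se = np.asarray(ses, dtype=float)
    if y.size == 0:
        raise ValueError("meta-analysis needs >= 1 effect")
    if np.any(se <= 0):
        raise ValueError("all standard errors must be > 0")
    k = y.size
    w = 1.0 / se**2
    y_w = float((w * y).sum() / w.sum())
    q = float((w * (y - y_w) ** 2).sum())
    if k > 1:
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    else:
        tau2 = 0.0
    w_star = 1.0 / (se**2 + tau2)
    pooled = float((w_star * y).sum() / w_star.sum())
    se_pooled = float(w_star.sum() ** -0.5)
    z = pooled / se_pooled
    p = 2.0 * stats.norm.sf(abs(z))
    zcrit = stats.norm.ppf(1 - alpha / 2)
    return MetaEffect(
        gene_id=gene_id,
        pooled_log2fc=pooled,
        se_pooled=se_pooled,
        ci95=(pooled - zcrit * se_pooled, pooled + zcrit * se_pooled),
        tau2=tau2,
        q_stat=q,
        p=float(p),
        k=k,
    )


# ---------------------------------------------------------------------------
# Stage wiring


def select_significant(
    da_results: list,
    padj_cut: float = 0.05,
    meta_p_cut: float = 0.05,
    system_of: dict | None = None,
) -> tuple[list, pd.DataFrame]:
    """Meta-analyse genes significant (padj < cut) in the per-location DA
    stage; roll enriched directions up per defence system.

    Returns (meta effects for all candidate genes, enrichment table).
    """
    da = da_to_table(da_results)
    candidates = sorted(set(da.loc[da.padj < padj_cut, "gene_id"]))
    metas = []
    for gene in candidates:
        sub = da[da.gene_id == gene]
        metas.append(
            random_effects_meta(sub.log2fc.to_numpy(), sub.se.to_numpy(), gene)
        )
    rows = []
    for m in metas:
        if m.p >= meta_p_cut:
            continue
        rows.append(
            dict(
                gene_id=m.gene_id,
                system=(system_of or {}).get(m.gene_id, "unassigned"),
                pooled_log2fc=m.pooled_log2fc,
                p=m.p,
                direction="seawater" if m.pooled_log2fc > 0 else "biofilm",
            )
        )
    enr = pd.DataFrame(
        rows, columns=["gene_id", "system", "pooled_log2fc", "p", "direction"]
    )
    summary = (
        enr.groupby(["system", "direction"]).size().rename("n_genes").reset_index()
        if len(enr)
        else pd.DataFrame(columns=["system", "direction", "n_genes"])
    )
    return metas, summary


def meta_to_table(metas: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                gene_id=m.gene_id, pooled_log2fc=m.pooled_log2fc,
                se_pooled=m.se_pooled, ci_lo=m.ci95[0], ci_hi=m.ci95[1],
                tau2=m.tau2, q_stat=m.q_stat, p=m.p, k=m.k,
            )
            for m in metas
        ],
        columns=["gene_id", "pooled_log2fc", "se_pooled", "ci_lo", "ci_hi",
                 "tau2", "q_stat", "p", "k"],
    )
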