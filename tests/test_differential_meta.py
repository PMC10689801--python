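"""NB differential abundance, BH, DerSimonian-Laird meta-analysis."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from bioflink import differential_meta as dm
from bioflink.synthetic_community import generate_da_counts


def textbook_bh(pvals):
    """Step-up BH as written in the original procedure (oracle)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBenjaminiHochberg:
    def test_matches_textbook_step_up(self, rng):
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 40)))
            assert np.allclose(dm.benjamini_hochberg(p), textbook_bh(p))

    def test_padj_never_below_p(self, rng):
        p = rng.random(100)
        assert (dm.benjamini_hochberg(p) >= p - 1e-12).all()


class TestDifferentialAbundance:
    def _sim(self, seed, **kw):
        rng = np.random.default_rng(seed)
        kw.setdefault("locations", ("L",))
        counts, sheet, planted = generate_da_counts(rng, **kw)
        types = sheet.set_index("sample").sample_type
        return counts, types, planted

    def test_planted_effect_recovered(self):
        counts, types, planted = self._sim(
            7, n_genes=150, n_shifted=16, log2fc=1.5, dispersion=0.1, n_per_group=8
        )
        res = dm.differential_abundance(counts, types, "L")
        est = {r.gene_id: r for r in res}
        shifted = [g for g, v in planted.items() if v != 0]
        errors = [est[g].log2fc - planted[g] for g in shifted]
        assert abs(np.mean(np.abs(errors))) < 0.4
        # the planted signal is overwhelmingly detected
        assert np.mean([est[g].padj < 0.05 for g in shifted]) >= 0.8

    def test_size_factor_invariance(self):
        counts, types, _ = self._sim(3, n_genes=60, n_shifted=6)
        res1 = dm.differential_abundance(counts, types, "L")
        res2 = dm.differential_abundance(2 * counts, types, "L")
        lf1 = np.array([r.log2fc for r in res1])
        lf2 = np.array([r.log2fc for r in res2])
        assert np.allclose(lf1, lf2, atol=0.02)

    def test_all_zero_genes_excluded(self):
        counts, types, _ = self._sim(3, n_genes=30, n_shifted=0)
        counts.iloc[0] = 0
        res = dm.differential_abundance(counts, types, "L")
        assert counts.index[0] not in {r.gene_id for r in res}

    def test_needs_two_groups(self):
        counts, types, _ = self._sim(3, n_genes=20, n_shifted=0)
        with pytest.raises(ValueError):
            dm.differential_abundance(counts, pd.Series("biofilm", index=types.index))

    def test_sign_convention_seawater_positive(self):
        rng = np.random.default_rng(9)
        counts, sheet, planted = generate_da_counts(
            rng, n_genes=40, n_shifted=2, log2fc=2.5, locations=("L",)
        )
        types = sheet.set_index("sample").sample_type
        res = {r.gene_id: r for r in dm.differential_abundance(counts, types)}
        for g, v in planted.items():
            if v > 0:  # planted seawater-enriched
                assert res[g].log2fc > 0

    def test_agrees_with_deseq2_oracle(self):
        """Independent cross-check of the NB-Wald effect sizes against
        pydeseq2 on a small simulation (rank correlation, not equality:
        the dispersion/shrinkage machinery differs)."""
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        counts, types, planted = self._sim(21, n_genes=60, n_shifted=10, log2fc=2.0)
        res = dm.differential_abundance(counts, types, "L")
        ours = pd.Series({r.gene_id: r.log2fc for r in res})
        meta = pd.DataFrame({"condition": types})
        dds = DeseqDataSet(
            counts=counts.T, metadata=meta, design="~condition", quiet=True
        )
        dds.deseq2()
        stat = DeseqStats(
            dds, contrast=["condition", "seawater", "biofilm"], quiet=True
        )
        stat.summary()
        theirs = stat.results_df.log2FoldChange
        common = ours.index.intersection(theirs.index)
        r = np.corrcoef(ours[common], theirs[common])[0, 1]
        assert r > 0.95
        shifted = [g for g, v in planted.items() if v != 0]
        assert np.allclose(ours[shifted], theirs[shifted], atol=0.5)


class TestRandomEffectsMeta:
    def test_single_study_degenerate(self):
        m = dm.random_effects_meta([1.2], [0.3])
        assert m.pooled_log2fc == 1.2
        assert m.se_pooled == 0.3
        assert m.tau2 == 0.0

    def test_two_equal_studies_closed_form(self):
        m = dm.random_effects_meta([1.0, 1.0], [0.5, 0.5])
        assert m.pooled_log2fc == pytest.approx(1.0)
        assert m.tau2 == 0.0
        assert m.se_pooled == pytest.approx(0.3536, abs=1e-4)

    def test_heterogeneous_studies_hand_computed(self):
        # w = (4, 1); Q = w1*(y1-yw)^2 + w2*(y2-yw)^2 with yw = 1.2
        y, se = [1.0, 2.0], [0.5, 1.0]
        m = dm.random_effects_meta(y, se)
        w = np.array([4.0, 1.0])
        yw = (w * y).sum() / w.sum()
        q = float((w * (np.array(y) - yw) ** 2).sum())
        tau2 = max(0.0, (q - 1) / (w.sum() - (w**2).sum() / w.sum()))
        wst = 1 / (np.array(se) ** 2 + tau2)
        assert m.q_stat == pytest.approx(q)
        assert m.tau2 == pytest.approx(tau2)
        assert m.pooled_log2fc == pytest.approx((wst * y).sum() / wst.sum())

    def test_ci_contains_pooled(self, rng):
        for _ in range(20):
            k = int(rng.integers(1, 6))
            y = rng.normal(0, 1, k)
            se = rng.uniform(0.1, 1.0, k)
            m = dm.random_effects_meta(y, se)
            assert m.ci95[0] <= m.pooled_log2fc <= m.ci95[1]

    def test_errors(self):
        with pytest.raises(ValueError):
            dm.random_effects_meta([], [])
        with pytest.raises(ValueError):
            dm.random_effects_meta([1.0], [0.0])

    def test_tau2_recovery_in_simulation(self, rng):
        """DL tau2 is approximately unbiased under the random-effects model."""
        tau2_true, k = 0.2, 8
        estimates = []
        for _ in range(500):
            se = rng.uniform(0.2, 0.4, k)
            y = rng.normal(0.5, np.sqrt(tau2_true + se**2))
            estimates.append(dm.random_effects_meta(y, se).tau2)
        assert abs(np.mean(estimates) - tau2_true) < 0.05

    def test_matches_metafor_oracle(self):
        """R metafor rma(method='DL') as the independent implementation."""
        y = [0.8, 1.4, -0.2, 1.1]
        se = [0.3, 0.5, 0.4, 0.25]
        script = (
            "suppressMessages(library(metafor));"
            f"r <- rma(yi=c({','.join(map(str, y))}), sei=c({','.join(map(str, se))}), method='DL');"
            "cat(r$beta, r$se, r$tau2)"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        beta, se_r, tau2 = map(float, out.stdout.split())
        m = dm.random_effects_meta(y, se)
        assert m.pooled_log2fc == pytest.approx(beta, abs=1e-6)
        assert m.se_pooled == pytest.approx(se_r, abs=1e-6)
        assert m.tau2 == pytest.approx(tau2, abs=1e-6)


class TestSelectSignificant:
    def _da(self, gene, loc, lfc, se=0.2, padj=0.01):
        return dm.DAResult(gene, loc, lfc, se, padj / 2, padj)

    def test_padj_gate(self):
        results = [
            self._da("g1", "HK", 1.0, padj=0.06),
            self._da("g2", "HK", 1.0, padj=0.04),
        ]
        metas, _ = dm.select_significant(results)
        assert {m.gene_id for m in metas} == {"g2"}

    def test_direction_counts(self):
        results = []
        for i in range(10):
            results.append(self._da(f"up{i}", "HK", 1.5))
            results.append(self._da(f"up{i}", "RS", 1.4))
            results.append(self._da(f"dn{i}", "HK", -1.5))
            results.append(self._da(f"dn{i}", "RS", -1.6))
        metas, summary = dm.select_significant(results)
        by_dir = summary.set_index("direction").n_genes
        assert by_dir["seawater"] == 10
        assert by_dir["biofilm"] == 10

    def test_single_location_passthrough(self):
        results = [self._da("g1", "HK", 1.23, se=0.4)]
        metas, _ = dm.select_significant(results)
        assert metas[0].pooled_log2fc == 1.23
        assert metas[0].se_pooled == 0.4


class TestEndToEndRecovery:
    def test_two_location_pooled_recovery(self):
        """Planted cross-location shifts are recovered by DA + meta."""
        rng = np.random.default_rng(17)
        counts, sheet, planted = generate_da_counts(
            rng, n_genes=100, n_shifted=10, log2fc=1.5,
            dispersion=0.1, n_per_group=8, locations=("HK", "RS"),
        )
        results = []
        for loc, sub in sheet.groupby("location"):
            types = sub.set_index("sample").sample_type
            results.extend(
                dm.differential_abundance(counts[list(sub["sample"])], types, loc)
            )
        metas, _ = dm.select_significant(results)
        pooled = {m.gene_id: m.pooled_log2fc for m in metas}
        shifted = {g: v for g, v in planted.items() if v != 0}
        recovered = [g for g in shifted if g in pooled]
        assert len(recovered) >= 8  # at least 8/10 survive the padj gate
        errors = [pooled[g] - shifted[g] for g in recovered]
        assert np.mean(np.abs(errors)) < 0.4
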