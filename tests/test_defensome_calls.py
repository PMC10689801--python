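"""Threshold-conjunction gene calling and defence-system completeness."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bioflink import defensome_calls as dc


def pads(gene, acc="RM:methyltransferase", identity=45.0, evalue=1e-20):
    return dict(gene_id=gene, db="PADS", accession=acc, identity=identity,
                evalue=evalue, bitscore=200.0)


def pfam(gene, acc="PF01555", evalue=1e-6, bitscore=80.0):
    return dict(gene_id=gene, db="PFAM", accession=acc, identity=np.nan,
                evalue=evalue, bitscore=bitscore)


def frame(rows):
    return pd.DataFrame(rows)


class TestCallDefenceGenes:
    def test_both_conjuncts_pass(self):
        out = dc.call_defence_genes(frame([pads("g1")]), frame([pfam("g1")]))
        assert list(out.gene_id) == ["g1"]
        assert out.iloc[0].system == "RM"

    @pytest.mark.parametrize(
        "pads_kw,pfam_kw",
        [
            (dict(identity=29.0), {}),  # PADS identity below 30
            (dict(evalue=1e-9), {}),  # PADS e-value too weak
            ({}, dict(bitscore=25.0)),  # PFAM bit score below 30
            ({}, dict(evalue=1e-2)),  # PFAM e-value too weak
            ({}, dict(acc="PF99999")),  # domain not conserved for the system
        ],
    )
    def test_any_failed_conjunct_blocks_call(self, pads_kw, pfam_kw):
        out = dc.call_defence_genes(
            frame([pads("g1", **pads_kw)]), frame([pfam("g1", **pfam_kw)])
        )
        assert out.empty

    def test_unknown_system_is_config_error(self):
        with pytest.raises(ValueError, match="unknown system"):
            dc.call_defence_genes(
                frame([pads("g1", acc="NotASystem:x")]), frame([pfam("g1")])
            )

    def test_relaxing_thresholds_is_monotone(self, rng):
        """Loosening any cutoff never removes a call."""
        rows_p, rows_f = [], []
        for i in range(40):
            rows_p.append(
                pads(f"g{i}", identity=float(rng.uniform(10, 60)),
                     evalue=10.0 ** -rng.uniform(2, 30))
            )
            rows_f.append(
                pfam(f"g{i}", evalue=10.0 ** -rng.uniform(0, 10),
                     bitscore=float(rng.uniform(5, 100)))
            )
        strict = set(
            dc.call_defence_genes(frame(rows_p), frame(rows_f)).gene_id
        )
        loose = set(
            dc.call_defence_genes(
                frame(rows_p), frame(rows_f),
                min_identity=20.0, max_pads_evalue=1e-5,
                max_pfam_evalue=1e-1, min_pfam_bitscore=10.0,
            ).gene_id
        )
        assert strict <= loose


class TestCounterDefence:
    def test_viral_rm_gene_called(self):
        out = dc.call_counter_defence(
            frame([pads("v1")]), frame([pfam("v1")]), viral_gene_ids={"v1"}
        )
        assert list(out.gene_id) == ["v1"]

    def test_host_gene_excluded(self):
        out = dc.call_counter_defence(
            frame([pads("h1")]), frame([pfam("h1")]), viral_gene_ids={"v1"}
        )
        assert out.empty

    def test_non_rm_system_excluded(self):
        out = dc.call_counter_defence(
            frame([pads("v1", acc="CRISPR-Cas:cas1")]),
            frame([pfam("v1", acc="PF01867")]),
            viral_gene_ids={"v1"},
        )
        assert out.empty

    def test_missing_pfam_confirmation_excluded(self):
        out = dc.call_counter_defence(
            frame([pads("v1")]), frame([pfam("other")]), viral_gene_ids={"v1"}
        )
        assert out.empty


def kegg(gene, acc="K00525", evalue=1e-12, score=150.0, threshold=100.0):
    return dict(gene_id=gene, db="KEGG", accession=acc, evalue=evalue,
                bitscore=score, threshold=threshold)


def gene_positions(rows):
    return pd.DataFrame(rows, columns=["gene_id", "scaffold", "start"])


class TestCallAmgs:
    def _positions(self):
        return gene_positions(
            [("gA", "p1", 100), ("gB", "p1", 1100), ("gC", "p1", 2100)]
        )

    def test_internal_amg_called(self):
        out = dc.call_amgs(
            frame([kegg("gB")]), frame([pfam("gB", acc="PF00317")]), self._positions()
        )
        assert list(out.gene_id) == ["gB"]
        assert not out.iloc[0].edge_gene

    def test_terminal_gene_flagged_not_dropped(self):
        out = dc.call_amgs(
            frame([kegg("gA")]), frame([pfam("gA", acc="PF00317")]), self._positions()
        )
        assert list(out.gene_id) == ["gA"]
        assert bool(out.iloc[0].edge_gene)

    def test_unlisted_accession_not_amg(self):
        out = dc.call_amgs(
            frame([kegg("gB", acc="K99999")]),
            frame([pfam("gB", acc="PF00317")]),
            self._positions(),
        )
        assert out.empty

    def test_score_below_family_threshold_not_amg(self):
        out = dc.call_amgs(
            frame([kegg("gB", score=60.0, threshold=100.0)]),
            frame([pfam("gB", acc="PF00317")]),
            self._positions(),
        )
        assert out.empty

    def test_planted_amgs_in_community(self, small_community):
        c = small_community
        out = dc.call_amgs(c.kegg_hits, c.pfam_hits, c.gene_table)
        planted = set(
            c.kegg_hits.loc[c.kegg_hits.bitscore > c.kegg_hits.threshold, "gene_id"]
        )
        assert set(out.gene_id) == planted


class TestSystemCompleteness:
    def _calls(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "system", "component"])

    def test_ta_pair_complete(self):
        calls = self._calls(
            [("g1", "TA", "toxin"), ("g2", "TA", "antitoxin")]
        )
        out = dc.system_completeness(calls, {"g1": "c1", "g2": "c1"})
        assert out[0].complete

    def test_cas1_alone_incomplete(self):
        calls = self._calls([("g1", "CRISPR-Cas", "cas1")])
        out = dc.system_completeness(calls, {"g1": "c1"})
        assert not out[0].complete

    def test_split_across_containers_incomplete(self):
        calls = self._calls(
            [("g1", "TA", "toxin"), ("g2", "TA", "antitoxin")]
        )
        out = dc.system_completeness(calls, {"g1": "c1", "g2": "c2"})
        assert all(not c.complete for c in out)

    def test_random_subsets_match_set_cover_oracle(self, rng):
        config = dc.load_defence_config()
        systems = sorted(config)
        for _ in range(100):
            system = systems[int(rng.integers(len(systems)))]
            components = sorted(config[system])
            present = [c for c in components if rng.random() < 0.6]
            if not present:
                continue
            calls = self._calls(
                [(f"g{i}", system, comp) for i, comp in enumerate(present)]
            )
            out = dc.system_completeness(
                calls, {g: "c1" for g in calls.gene_id}, config
            )
            assert out[0].complete == (set(components) <= set(present))


class TestCommunityDefensome:
    def test_decoys_rejected_and_planted_called(self, small_community):
        c = small_community
        viral = set(
            c.gene_table.loc[c.gene_table.scaffold.str.startswith("phage"), "gene_id"]
        )
        host_pads = c.pads_hits[~c.pads_hits.gene_id.isin(viral)]
        out = dc.call_defence_genes(host_pads, c.pfam_hits)
        called = set(out.gene_id)
        # decoys fail one conjunct each
        ok_pads = host_pads[
            (host_pads.identity >= 30) & (host_pads.evalue < 1e-10)
        ]
        ok_pfam = c.pfam_hits[
            (c.pfam_hits.evalue < 1e-3) & (c.pfam_hits.bitscore >= 30)
        ]
        expected = set(ok_pads.gene_id) & set(ok_pfam.gene_id)
        assert called == expected
        counter = dc.call_counter_defence(c.pads_hits, c.pfam_hits, viral)
        assert set(counter.gene_id) <= viral and len(counter) > 0
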