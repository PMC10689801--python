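"""CRISPR arrays, the four linkage channels, OR-integration, pair network."""

import numpy as np
import pandas as pd
import pytest

from bioflink import host_linkage as hl
from bioflink.seq_core import SequenceRecord, reverse_complement
from bioflink.synthetic_community import _random_repeat, mutate, random_seq


def build_array(rng, repeat_len=28, n_spacers=3, spacer_len=32):
    rep = _random_repeat(rng, repeat_len)
    spacers = [random_seq(rng, spacer_len) for _ in range(n_spacers)]
    return rep, spacers, rep + "".join(sp + rep for sp in spacers)


class TestDetectCrisprArrays:
    def test_planted_array_recovered(self, rng):
        rep, spacers, array = build_array(rng)
        seq = random_seq(rng, 3000) + array + random_seq(rng, 3000)
        arrays = hl.detect_crispr_arrays(seq)
        assert len(arrays) == 1
        assert arrays[0].repeat_seq == rep
        assert arrays[0].spacers == spacers

    def test_tandem_repeat_is_not_an_array(self, rng):
        rep = _random_repeat(rng, 28)
        seq = random_seq(rng, 500) + rep * 5 + random_seq(rng, 500)
        assert hl.detect_crispr_arrays(seq) == []

    def test_many_planted_arrays_all_recovered(self, rng):
        planted = []
        chunks = []
        for _ in range(10):
            rep, spacers, array = build_array(
                rng,
                repeat_len=int(rng.integers(20, 40)),
                n_spacers=int(rng.integers(3, 6)),
                spacer_len=int(rng.integers(20, 45)),
            )
            planted.append(spacers)
            chunks.append(random_seq(rng, 800))
            chunks.append(array)
        chunks.append(random_seq(rng, 800))
        arrays = hl.detect_crispr_arrays("".join(chunks))
        assert [a.spacers for a in arrays] == planted

    def test_random_sequence_has_no_arrays(self, rng):
        assert hl.detect_crispr_arrays(random_seq(rng, 20_000)) == []


class TestLinkBySpacers:
    def test_planted_spacer_links(self, rng):
        phage = SequenceRecord("p", random_seq(rng, 5000))
        spacer = phage.seq[100:132]
        array = hl.CrisprArray("h", "R" * 28, [spacer], [0, 60, 120])
        link = hl.link_by_spacers([array], [phage], "p", "hb")
        assert link is not None and link.stat["n_spacer_hits"] == 1

    def test_reverse_strand_spacer_links(self, rng):
        phage = SequenceRecord("p", random_seq(rng, 5000))
        spacer = reverse_complement(phage.seq[100:132])
        array = hl.CrisprArray("h", "R" * 28, [spacer], [0, 60, 120])
        assert hl.link_by_spacers([array], [phage], "p", "hb") is not None

    def test_six_bp_spacer_ignored(self, rng):
        phage = SequenceRecord("p", random_seq(rng, 5000))
        spacer = phage.seq[10:16]  # 6 bp: below the strict > 6 rule
        array = hl.CrisprArray("h", "R" * 28, [spacer], [0, 40, 80])
        assert hl.link_by_spacers([array], [phage], "p", "hb") is None

    def test_random_spacers_never_link(self, rng):
        phage = SequenceRecord("p", random_seq(rng, 10_000))
        for _ in range(100):
            spacer = random_seq(rng, 30)
            array = hl.CrisprArray("h", "R" * 28, [spacer], [0, 60, 120])
            assert hl.link_by_spacers([array], [phage], "p", "hb") is None


class TestLinkByHomology:
    def test_planted_block_links(self, rng):
        phage = SequenceRecord("p", random_seq(rng, 8000))
        block = mutate(rng, phage.seq[1000:4000], 0.10)
        host = SequenceRecord("h", random_seq(rng, 3000) + block + random_seq(rng, 3000))
        link = hl.link_by_homology([phage], [host], "p", "hb")
        assert link is not None
        assert link.stat["aln_len"] >= 2500
        assert link.stat["identity"] >= 0.85

    def test_short_perfect_match_rejected(self, rng):
        phage = SequenceRecord("p", random_seq(rng, 8000))
        block = phage.seq[1000:3400]  # 2.4 kb, below the 2.5 kb cut
        host = SequenceRecord("h", random_seq(rng, 2000) + block + random_seq(rng, 2000))
        assert hl.link_by_homology([phage], [host], "p", "hb") is None

    def test_identical_scaffold_links_at_identity_one(self, rng):
        s = random_seq(rng, 5000)
        link = hl.link_by_homology(
            [SequenceRecord("p", s)], [SequenceRecord("h", s)], "p", "hb"
        )
        assert link is not None and link.stat["identity"] == 1.0


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "gene_type", "seq"])


class TestLinkByTrna:
    def test_identical_trna_links(self, rng):
        t = random_seq(rng, 75)
        link = hl.link_by_trna(
            _genes([("v1", "trna", t)]), _genes([("h1", "trna", t)]), "p", "hb"
        )
        assert link is not None and link.stat["n_trna_hits"] == 1

    def test_one_mismatch_no_link(self, rng):
        t = random_seq(rng, 75)
        t2 = ("A" if t[0] != "A" else "C") + t[1:]
        assert hl.link_by_trna(
            _genes([("v1", "trna", t)]), _genes([("h1", "trna", t2)]), "p", "hb"
        ) is None

    def test_reverse_strand_trna_links(self, rng):
        t = random_seq(rng, 75)
        assert hl.link_by_trna(
            _genes([("v1", "trna", t)]),
            _genes([("h1", "trna", reverse_complement(t))]),
            "p", "hb",
        ) is not None

    def test_no_viral_trna_no_link(self, rng):
        assert hl.link_by_trna(
            _genes([("v1", "cds", "")]),
            _genes([("h1", "trna", random_seq(rng, 75))]),
            "p", "hb",
        ) is None


class TestLinkByKmers:
    def test_planted_block_shares_expected_kmers(self, rng):
        phage = SequenceRecord("p", random_seq(rng, 5000))
        block = phage.seq[1000:1300]
        host = SequenceRecord("h", random_seq(rng, 2000) + block + random_seq(rng, 2000))
        link = hl.link_by_kmers([phage], [host], "p", "hb")
        assert link is not None
        assert link.stat["n_shared_kmers"] >= 276  # 300 - 25 + 1

    def test_random_sequences_share_nothing(self, rng):
        a = SequenceRecord("p", random_seq(rng, 10_000))
        b = SequenceRecord("h", random_seq(rng, 10_000))
        assert hl.link_by_kmers([a], [b], "p", "hb") is None


class TestIntegratePairs:
    def test_single_channel_gives_pair(self):
        links = [hl.EvidenceLink("v", "h", "crispr", {"n_spacer_hits": 2})]
        pairs = hl.integrate_pairs(links)
        assert len(pairs) == 1 and pairs[0].channels == {"crispr"}

    def test_two_channels_one_pair(self):
        links = [
            hl.EvidenceLink("v", "h", "homology", {}),
            hl.EvidenceLink("v", "h", "kmer", {}),
        ]
        pairs = hl.integrate_pairs(links)
        assert len(pairs) == 1 and pairs[0].channels == {"homology", "kmer"}

    def test_removing_a_channel_never_creates_pairs(self, rng):
        links = [
            hl.EvidenceLink(f"v{int(rng.integers(5))}", f"h{int(rng.integers(5))}",
                            np.random.default_rng(int(rng.integers(1e6))).choice(
                                ["homology", "crispr", "trna", "kmer"]),
                            {})
            for _ in range(40)
        ]
        full = {(p.virus_unit_id, p.host_bin_id) for p in hl.integrate_pairs(links)}
        for drop in ("homology", "crispr", "trna", "kmer"):
            reduced = hl.integrate_pairs([l for l in links if l.channel != drop])
            assert {(p.virus_unit_id, p.host_bin_id) for p in reduced} <= full


class TestPairNetwork:
    def test_one_virus_two_hosts_single_component(self):
        pairs = [
            hl.VirusHostPair("v1", "h1", {"crispr"}, []),
            hl.VirusHostPair("v1", "h2", {"crispr"}, []),
        ]
        comps, n_complex = hl.pair_network_components(pairs, {}, {})
        assert len(comps) == 1 and len(comps[0]) == 3
        assert n_complex == 1

    def test_disjoint_pairs_two_components(self):
        pairs = [
            hl.VirusHostPair("a", "b", {"kmer"}, []),
            hl.VirusHostPair("c", "d", {"kmer"}, []),
        ]
        comps, n_complex = hl.pair_network_components(pairs, {}, {})
        assert len(comps) == 2 and n_complex == 0

    def test_components_match_union_find_oracle(self, rng):
        pairs = [
            hl.VirusHostPair(f"v{int(rng.integers(15))}", f"h{int(rng.integers(15))}",
                             {"kmer"}, [])
            for _ in range(40)
        ]
        comps, _ = hl.pair_network_components(pairs, {}, {})
        # union-find oracle
        parent = {}

        def find(x):
            parent.setdefault(x, x)
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for p in pairs:
            a, b = find("V:" + p.virus_unit_id), find("H:" + p.host_bin_id)
            if a != b:
                parent[a] = b
        groups = {}
        for node in parent:
            groups.setdefault(find(node), set()).add(node)
        assert sorted(map(sorted, groups.values())) == sorted(comps)


class TestLinkCommunity:
    def test_noise_free_per_channel_precision_recall(self, small_community):
        from bioflink import viral_triage as vt

        c = small_community
        flags = vt.flag_proviruses(c.provirus_calls, c.bin_table)
        terl = set(c.gene_table.loc[c.gene_table.gene_type == "terl", "gene_id"])
        units = vt.build_viral_units(c.phage_scaffolds, flags, {}, c.gene_table, terl)
        bins = {
            b: sorted(sub.scaffold_id)
            for b, sub in c.bin_table[
                ~c.bin_table.scaffold_id.str.startswith("phage")
            ].groupby("bin_id")
        }
        seqs = {r.id: r for r in c.host_scaffolds + c.phage_scaffolds}
        pairs = hl.link_community(units, bins, seqs, c.gene_table)
        found = {
            (p.virus_unit_id, p.host_bin_id, ch) for p in pairs for ch in p.channels
        }
        assert found == c.truth.true_links
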