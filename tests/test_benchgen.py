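import collections

import numpy as np
import pytest
import scipy.stats

import msvscan as ms
from msvscan.benchgen import (
    dinucleotide_counts, percent_identity, profmark_build, sample_iid,
    shuffle_seq, single_linkage, synthetic_family_msa,
)


class TestSampleIid:
    def test_composition_converges(self):
        seq = sample_iid(1_000_000, seed=1)
        counts = collections.Counter(seq)
        from msvscan.alphabet import AMINO, BACKGROUND
        for aa, f in zip(AMINO.symbols, BACKGROUND):
            assert counts[aa] / 1e6 == pytest.approx(f, abs=0.005)

    def test_seed_determinism_and_edge(self):
        assert sample_iid(50, seed=3) == sample_iid(50, seed=3)
        assert len(sample_iid(1, seed=0)) == 1
        with pytest.raises(ValueError):
            sample_iid(0)


class TestShuffles:
    def test_mono_preserves_multiset(self):
        s = sample_iid(200, seed=5)
        t = shuffle_seq(s, "mono", seed=1)
        assert sorted(t) == sorted(s)
        assert t != s  # astronomically unlikely to be identity

    def test_di_preserves_pair_counts(self):
        s = sample_iid(300, seed=6)
        t = shuffle_seq(s, "di", seed=2)
        assert dinucleotide_counts(t) == dinucleotide_counts(s)
        assert t[0] == s[0] and t[-1] == s[-1]  # Euler path endpoints

    def test_reverse_is_involution(self):
        s = sample_iid(40, seed=7)
        assert shuffle_seq(shuffle_seq(s, "reverse"), "reverse") == s

    def test_di_rejects_single_residue(self):
        with pytest.raises(ValueError):
            shuffle_seq("A", "di")

    def test_di_randomizes(self):
        s = sample_iid(300, seed=8)
        assert shuffle_seq(s, "di", seed=1) != shuffle_seq(s, "di", seed=2)


class TestPercentIdentity:
    def test_identical_ungapped(self):
        assert percent_identity("ACDEF", "ACDEF") == 1.0

    def test_definition_uses_shorter_length(self):
        # 5 identities, unaligned lengths 10 and 8 -> 5/8
        a = "ACDEFGHIKL"
        b = "ACDEFWWM--"  # identities A,C,D,E,F; unaligned length 8
        assert percent_identity(a, b) == pytest.approx(5 / 8)

    def test_all_mismatch(self):
        assert percent_identity("AAAA", "CCCC") == 0.0

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            percent_identity("--", "AC")


class TestSingleLinkage:
    def test_all_below_threshold_gives_singletons(self):
        clusters = single_linkage(4, lambda i, j: 0.1, 0.25)
        assert sorted(map(len, clusters)) == [1, 1, 1, 1]

    def test_chain_links_transitively(self):
        ident = {(0, 1): 0.5, (1, 2): 0.5}
        f = lambda i, j: ident.get((min(i, j), max(i, j)), 0.0)
        clusters = single_linkage(3, f, 0.25)
        assert sorted(clusters[0]) == [0, 1, 2]

    def test_matches_naive_component_oracle(self):
        rng = np.random.default_rng(9)
        n = 25
        mat = rng.uniform(0, 1, size=(n, n))
        mat = np.triu(mat, 1) + np.triu(mat, 1).T
        clusters = single_linkage(n, lambda i, j: mat[i, j], 0.8)
        import networkx as nx
        g = nx.Graph((i, j) for i in range(n) for j in range(i + 1, n)
                     if mat[i, j] > 0.8)
        g.add_nodes_from(range(n))
        expected = sorted(sorted(c) for c in nx.connected_components(g))
        assert sorted(sorted(c) for c in clusters) == expected
        # cross-cluster pairs are all below threshold
        for a in clusters:
            for b in clusters:
                if a is not b:
                    assert all(mat[i, j] <= 0.8 for i in a for j in b)


@pytest.fixture(scope="module")
def msas():
    return [synthetic_family_msa(70, n_clusters=4, members=4,
                                 divergence=0.2, seed=s, name=f"fam{s}")
            for s in range(3)]


@pytest.fixture(scope="module")
def seqdb():
    rng = np.random.default_rng(0)
    return [sample_iid(int(rng.integers(150, 600)), seed=i)
            for i in range(60)]


class TestProfmark:
    def test_construction_and_posthoc_guarantees(self, msas, seqdb):
        bench = profmark_build(msas, seqdb, n_neg=50, seed=4)
        # verification runs inside profmark_build; re-check shape here
        assert bench.queries and bench.positives and len(bench.decoys) == 50
        for rec in bench.positives:
            info = bench.truth[rec.id]
            assert len(info["domains"]) == 1
            a, b = info["domains"][0]
            assert 1 <= a <= b <= len(rec.seq)

    def test_single_cluster_alignment_excluded(self, seqdb):
        one = synthetic_family_msa(60, n_clusters=1, members=6,
                                   divergence=0.1, seed=1)
        with pytest.raises(ValueError):
            profmark_build([one], seqdb, n_neg=5, seed=0)

    def test_two_domain_mode_segments(self, msas, seqdb):
        bench = profmark_build(msas, seqdb, ndomains=2, n_neg=20, seed=5)
        for rec in bench.positives:
            assert len(bench.truth[rec.id]["domains"]) == 2
            (a1, b1), (a2, b2) = bench.truth[rec.id]["domains"]
            assert b1 < a2  # ordered, non-overlapping

    def test_fragment_removal(self, seqdb):
        msa = synthetic_family_msa(100, n_clusters=3, members=3,
                                   divergence=0.2, seed=2)
        # truncate one row to 40% of its length (a fragment)
        rows = list(msa.rows)
        rows[0] = rows[0][:40] + "-" * 60
        from msvscan.io import MSA
        frag_msa = MSA(name="frag", ids=msa.ids, rows=rows)
        bench = profmark_build([frag_msa], seqdb, n_neg=5, seed=1)
        used = {i for q in bench.queries for i in q.ids}
        assert msa.ids[0] not in used

    def test_decoy_segment_lengths_copied_from_positives(self, msas, seqdb):
        bench = profmark_build(msas, seqdb, n_neg=300, seed=6)
        pos_lens = {len(r.seq) for r in bench.positives}
        dec_lens = [len(r.seq) for r in bench.decoys]
        assert set(dec_lens) <= pos_lens

    def test_decoy_length_distribution_matches(self, msas, seqdb):
        bench = profmark_build(msas, seqdb, n_neg=400, seed=7)
        pos = [len(r.seq) for r in bench.positives]
        dec = [len(r.seq) for r in bench.decoys]
        ks = scipy.stats.ks_2samp(pos, dec)
        assert ks.pvalue > 0.001

    def test_deterministic_under_seed(self, msas, seqdb):
        b1 = profmark_build(msas, seqdb, n_neg=20, seed=9)
        b2 = profmark_build(msas, seqdb, n_neg=20, seed=9)
        assert [r.seq for r in b1.positives] == [r.seq for r in b2.positives]
        assert [r.seq for r in b1.decoys] == [r.seq for r in b2.decoys]


class TestExperiments:
    def test_filter_fraction_trivial_threshold(self, model_mid):
        sp, rp, cal = model_mid
        frac = ms.filter_fraction_experiment(sp, cal, Pthr=1.0, n=200,
                                             L=100, seed=1, rp=rp)
        assert frac == 1.0

    def test_filter_fraction_deterministic(self, model_mid):
        sp, rp, cal = model_mid
        a = ms.filter_fraction_experiment(sp, cal, n=500, L=200, seed=3, rp=rp)
        b = ms.filter_fraction_experiment(sp, cal, n=500, L=200, seed=3, rp=rp)
        assert a == b
        with pytest.raises(ValueError):
            ms.filter_fraction_experiment(sp, cal, n=50, rp=rp)

    def test_roundoff_experiment_reproducible(self, model_mid):
        sp, rp, _ = model_mid
        r1 = ms.roundoff_experiment(sp, rp, n=150, L=200, seed=5)
        r2 = ms.roundoff_experiment(sp, rp, n=150, L=200, seed=5)
        assert r1 == r2
        assert r1["std"] <= 0.6
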