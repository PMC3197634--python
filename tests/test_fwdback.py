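import numpy as np
import pytest

import msvscan as ms
from msvscan.alphabet import AMINO, BACKGROUND
from msvscan.fwdback import (
    LogSumTable, backward_parser_batch, endpoint_posteriors, forward_generic,
    forward_parser_batch, logsum,
)
from msvscan.profile import configure_length
from msvscan.stats import sample_iid_batch

from conftest import tiny_instance


class TestLogSum:
    def test_equal_arguments_gain_one_bit(self):
        for x in (-5.0, 0.0, 17.25):
            assert logsum(x, x) == pytest.approx(x + 1.0, abs=1e-12)

    def test_neg_infinity_identity(self):
        assert logsum(3.5, -np.inf) == 3.5
        t = LogSumTable()
        assert t.logsum(3.5, -np.inf) == 3.5

    def test_table_error_bounded_by_half_resolution(self):
        t = LogSumTable()
        d = np.linspace(0.0, 25.0, 40001)
        exact = np.logaddexp2(0.0, -d)
        approx = np.array([t.logsum(0.0, -x) for x in d])
        assert np.abs(approx - exact).max() <= t.resolution / 2

    def test_table_mode_forward_close_to_exact(self):
        sp, seq = tiny_instance(7, max_m=4, max_l=6)
        assert forward_generic(sp, seq, table=LogSumTable()) == pytest.approx(
            forward_generic(sp, seq), abs=0.01)


class TestForward:
    @pytest.mark.parametrize("trial", range(40))
    def test_generic_matches_enumeration(self, trial):
        sp, seq = tiny_instance(trial + 100, max_m=2, max_l=4)
        assert forward_generic(sp, seq) == pytest.approx(
            ms.brute_force_forward(sp, seq), abs=1e-9)

    @pytest.mark.parametrize("trial", range(25))
    def test_parser_matches_generic(self, trial):
        rng = np.random.default_rng(trial)
        M = int(rng.integers(2, 60))
        L = int(rng.integers(2, 120))
        core = ms.synthetic_profile(M, seed=trial)
        sp = configure_length(core, L)
        seq = ms.sample_iid(L, seed=trial + 9)
        sc, _ = ms.forward_score(sp, seq)
        assert sc == pytest.approx(forward_generic(sp, seq), abs=1e-3)

    def test_parser_matches_generic_large_instance(self):
        core = ms.synthetic_profile(200, seed=5)
        sp = configure_length(core, 400)
        seq = ms.sample_iid(400, seed=6)
        sc, state = ms.forward_score(sp, seq)
        assert sc == pytest.approx(forward_generic(sp, seq), abs=1e-3)

    def test_long_deletion_stress(self):
        # near-1 delete extension on a long model: the rescaled parser must
        # still agree with the log-domain reference, because the multihit
        # re-entry path E->J->B dominates any underflowing deletion chain
        core = ms.synthetic_profile(500, seed=8, entropy_target=1.2)
        core.t_dd[:] = 0.99
        core.t_dm[:] = 0.01
        cons = core.consensus
        seq = cons[:30] + cons[470:]
        sp = configure_length(core, len(seq))
        sc, _ = ms.forward_score(sp, seq)
        assert sc == pytest.approx(forward_generic(sp, seq), abs=1e-3)

    def test_rescaling_triggers_on_strong_hit(self):
        core = ms.synthetic_profile(120, seed=3, entropy_target=1.5)
        seq = core.consensus * 3
        sp = configure_length(core, len(seq))
        _, state = ms.forward_score(sp, seq)
        assert np.sum(state.log2_scale != 0) > 0  # sparse: some rows scaled
        assert np.sum(state.log2_scale != 0) < len(seq)

    def test_scale_bookkeeping_identity(self):
        core = ms.synthetic_profile(80, seed=4, entropy_target=1.2)
        seq = core.consensus + ms.sample_iid(40, seed=2)
        sp = configure_length(core, len(seq))
        sc, state = ms.forward_score(sp, seq)
        # sum of log scales + log of stored C value reproduces the total
        recon = (np.log2(state.specials["C"][0, -1] * sp.move)
                 + state.log2_scale.sum())
        assert recon == pytest.approx(state.total_log2_odds[0], abs=1e-9)

    def test_biased_composition_stress(self):
        rng = np.random.default_rng(0)
        f = BACKGROUND.copy()
        f[:5] *= 6.0
        f /= f.sum()
        core = ms.synthetic_profile(50, seed=1)
        sp = configure_length(core, 150)
        X = rng.choice(20, size=150, p=f).astype(np.int8)
        seq = AMINO.decode(X)
        sc, _ = ms.forward_score(sp, seq)
        assert sc == pytest.approx(forward_generic(sp, seq), abs=1e-3)


class TestBackward:
    @pytest.mark.parametrize("trial", range(20))
    def test_forward_backward_consistency(self, trial):
        rng = np.random.default_rng(trial + 40)
        M = int(rng.integers(1, 80))
        L = int(rng.integers(1, 150))
        core = ms.synthetic_profile(M, seed=trial)
        sp = configure_length(core, L)
        seq = ms.sample_iid(L, seed=trial)
        f, _ = ms.forward_score(sp, seq)
        b, _ = ms.backward_score(sp, seq)
        assert f == pytest.approx(b, abs=1e-3)

    def test_m1_closed_form(self):
        core = ms.synthetic_profile(1, seed=2, entropy_target=None)
        sp = configure_length(core, 1)
        seq = "A"
        # only one path exists: N->B->M1->E->C->T
        expected = (2 * sp.move_bits + np.log2(sp.entry_vit[0])
                    + sp.scores[0, 0] - 1.0 - sp.null.transition_bits())
        b, _ = ms.backward_score(sp, seq)
        assert b == pytest.approx(expected, abs=1e-9)


class TestEndpointPosteriors:
    @staticmethod
    def _sharp_profile(M):
        # alternating near-point-mass emissions: off-register alignments of
        # the consensus are heavily penalized, so start mass cannot smear
        from msvscan.alphabet import AMINO as A, K
        e = np.full((M, K), 0.015 / (K - 1))
        for k in range(M):
            e[k, A.encode("DW"[k % 2])[0]] = 0.985
        ones = np.ones(M)
        return ms.CoreProfile("sharp", e, 0.98 * ones, 0.01 * ones,
                              0.01 * ones, 0.7 * ones, 0.3 * ones,
                              0.7 * ones, 0.3 * ones)

    def test_planted_segment_concentrates_begin_mass(self):
        core = self._sharp_profile(30)
        flank = ms.sample_iid(40, seed=7)
        seq = flank + core.consensus + ms.sample_iid(35, seed=8)
        sp = configure_length(core, len(seq))
        X = AMINO.encode(seq)[None, :]
        _, fs = forward_parser_batch(sp, X)
        _, bs = backward_parser_batch(sp, X)
        begin, end = endpoint_posteriors(fs, bs)
        assert begin[0, 40] > 0.9            # segment starts at position 41
        assert end[0].argmax() == 40 + 30 - 1

    def test_segment_count_matches_enumeration(self):
        # posterior B mass equals the exact E[#segments] over all paths
        from msvscan.oracle import enumerate_path_scores
        sp, seq = tiny_instance(900, max_m=3, max_l=5)
        X = AMINO.encode(seq)[None, :]
        _, fs = forward_parser_batch(sp, X)
        _, bs = backward_parser_batch(sp, X)
        begin, _ = endpoint_posteriors(fs, bs)
        tot, wsum = 0.0, 0.0
        prev = 0.0
        for nseg in range(1, len(seq) + 1):
            cum = np.sum(np.exp2(enumerate_path_scores(
                sp, seq, "gapped", max_segments=nseg)))
            tot, wsum = cum, wsum + nseg * (cum - prev)
            prev = cum
        assert begin.sum() == pytest.approx(wsum / tot, abs=1e-6)

    def test_null_sequence_segment_count_at_baseline(self):
        # every path contains at least one segment, so the posterior count
        # has a floor of one even for pure background sequences
        core = ms.synthetic_profile(40, seed=6)
        seq = ms.sample_iid(200, seed=9)
        sp = configure_length(core, 200)
        X = AMINO.encode(seq)[None, :]
        _, fs = forward_parser_batch(sp, X)
        _, bs = backward_parser_batch(sp, X)
        begin, end = endpoint_posteriors(fs, bs)
        assert begin.sum() >= 1.0 - 1e-9
        assert begin.sum() == pytest.approx(end.sum(), rel=1e-6)

    def test_begin_end_mass_conservation(self):
        core = ms.synthetic_profile(30, seed=1, entropy_target=1.2)
        seq = ms.sample_iid(20, seed=3) + core.consensus + ms.sample_iid(10, seed=4)
        sp = configure_length(core, len(seq))
        X = AMINO.encode(seq)[None, :]
        _, fs = forward_parser_batch(sp, X)
        _, bs = backward_parser_batch(sp, X)
        begin, end = endpoint_posteriors(fs, bs)
        assert begin.sum() == pytest.approx(end.sum(), abs=1e-6)

    def test_mismatched_runs_rejected(self):
        core = ms.synthetic_profile(10, seed=0)
        sp = configure_length(core, 30)
        X1 = AMINO.encode(ms.sample_iid(30, seed=1))[None, :]
        X2 = AMINO.encode(ms.sample_iid(30, seed=2))[None, :]
        _, fs = forward_parser_batch(sp, X1)
        _, bs = backward_parser_batch(sp, X2)
        with pytest.raises(ValueError):
            endpoint_posteriors(fs, bs)
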