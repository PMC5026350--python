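"""Generative sampler: duration laws, emission, reproducibility."""

import numpy as np
import pytest
from scipy import stats

import crmseg as cs
from crmseg.model import BG_GLOBAL, BG_LOCAL, END


def single_state_model(p_g=0.2):
    """Only b_g emits: S -> b_g -> E."""
    pwm = cs.Pwm("m0", np.full((2, 4), 0.25), pseudocount=0.0)
    model = cs.HsmmModel.default([pwm], durations=cs.DurationParams(p_g, 2, 0.5),
                                 bg_order_global=0, bg_order_local=0,
                                 window_halfwidth=50)
    model.transitions[BG_GLOBAL] = {END: 1.0}
    return model


def chi_square_pvalue(observed_durations, pmf):
    """GOF of sampled durations against a pmf array (u = 1..U), merging tail
    bins so every expected count is >= 5."""
    n = len(observed_durations)
    counts = np.bincount(observed_durations, minlength=pmf.shape[0] + 1)[1:]
    expected = pmf * n
    # merge from the right until all expected >= 5
    obs, exp = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(counts[::-1], expected[::-1]):
        acc_o += o
        acc_e += e
        if acc_e >= 5:
            obs.append(acc_o)
            exp.append(acc_e)
            acc_o = acc_e = 0.0
    obs[-1] += acc_o
    exp[-1] += acc_e
    obs, exp = np.array(obs), np.array(exp)
    exp *= obs.sum() / exp.sum()
    return stats.chisquare(obs, exp).pvalue


class TestSamplePath:
    def test_geometric_duration_distribution(self):
        model = single_state_model(0.2)
        pmf = np.exp(model.durations.bg_global_log_pmf())
        durs = []
        rng = np.random.default_rng(11)
        for _ in range(10_000):
            path, trunc = cs.sample_path(model, rng)
            assert not trunc
            segs = path.emitting()
            assert len(segs) == 1 and segs[0].state == BG_GLOBAL
            durs.append(segs[0].duration)
        assert chi_square_pvalue(durs, pmf) > 0.01

    def test_negbin_spacer_distribution(self):
        pwm = cs.Pwm("m0", np.full((2, 4), 0.25), pseudocount=0.0)
        model = cs.HsmmModel.default(
            [pwm], durations=cs.DurationParams(0.5, 3, 0.6), p_spacer=0.79,
            p_motif_again=0.2,
        )
        pmf = np.exp(model.durations.bg_local_log_pmf())
        durs = []
        rng = np.random.default_rng(12)
        while len(durs) < 10_000:
            path, _ = cs.sample_path(model, rng)
            durs.extend(s.duration for s in path.emitting() if s.state == BG_LOCAL)
        assert chi_square_pvalue(durs, pmf) > 0.01

    def test_motif_durations_fixed(self):
        pwm = cs.Pwm("m0", np.full((5, 4), 0.25), pseudocount=0.0)
        model = cs.HsmmModel.default([pwm], durations=cs.DurationParams(0.3, 2, 0.5))
        rng = np.random.default_rng(13)
        seen = 0
        for _ in range(200):
            path, _ = cs.sample_path(model, rng)
            for s in path.emitting():
                if model.states.is_motif(s.state):
                    assert s.duration == 5
                    seen += 1
        assert seen > 0

    def test_truncation_flag_and_length(self):
        model = single_state_model(0.001)
        path, trunc = cs.sample_path(model, 0, max_length=100)
        assert path.total_length() <= 100
        # with mean 1000, truncation at 100 almost surely triggers
        assert trunc


class TestEmitSequence:
    def test_deterministic_consensus(self):
        mat = np.zeros((4, 4))
        for i, b in enumerate([0, 1, 2, 3]):
            mat[i, b] = 1.0
        pwm = cs.Pwm("det", mat, pseudocount=0.0)
        model = cs.HsmmModel.default([pwm], durations=cs.DurationParams(0.3, 2, 0.5))
        rng = np.random.default_rng(14)
        for _ in range(50):
            path, _ = cs.sample_path(model, rng)
            seq = cs.emit_sequence(model, path, rng)
            for s in path.emitting():
                if s.state == "det":
                    assert seq[s.start : s.end] == "ACGT"
                elif s.state == "det_rc":
                    assert seq[s.start : s.end] == "ACGT"  # palindromic consensus

    def test_seed_reproducibility(self):
        model = single_state_model(0.05)
        p1, _ = cs.sample_path(model, 42)
        p2, _ = cs.sample_path(model, 42)
        assert p1 == p2
        s1 = cs.emit_sequence(model, p1, 7)
        s2 = cs.emit_sequence(model, p1, 7)
        s3 = cs.emit_sequence(model, p1, 8)
        assert s1 == s2
        assert s1 != s3

    def test_composition_law_of_large_numbers(self):
        model = single_state_model(1e-5)
        comp = (0.4, 0.1, 0.2, 0.3)
        bg = cs.BackgroundChain(composition=comp)
        path = cs.SegmentPath((cs.Segment(BG_GLOBAL, 0, 100_000),))
        seq = cs.emit_sequence(model, path, 5, background=bg)
        freqs = np.array([seq.count(b) for b in "ACGT"]) / len(seq)
        assert np.allclose(freqs, comp, atol=0.01)


class TestGenerateDataset:
    def test_n_zero_errors(self):
        with pytest.raises(ValueError):
            cs.generate_dataset(single_state_model(), 0, seed=1)

    def test_truth_path_regenerates_crms(self):
        pwm = cs.Pwm("m0", np.full((3, 4), 0.25), pseudocount=0.0)
        model = cs.HsmmModel.default([pwm], durations=cs.DurationParams(0.1, 2, 0.7))
        sims = cs.generate_dataset(model, 5, seed=3, max_length=500)
        for s in sims:
            crms, motifs = cs.decode_to_annotations(s.truth_path)
            assert crms == s.truth_crms
            assert len(s.sequence) == s.truth_path.total_length()
            s.truth_path.validate(model, len(s.sequence))

    def test_likelihood_dominance_of_generating_model(self):
        """Simulated data scores at least as high on average under the
        generating model as under a perturbed one."""
        pwm = cs.Pwm(
            "m0",
            np.array([[0.9, 0.03, 0.03, 0.04]] * 4),
            pseudocount=0.0,
        )
        model = cs.HsmmModel.default(
            [pwm], durations=cs.DurationParams(0.05, 2, 0.8),
            bg_order_global=0, bg_order_local=0, window_halfwidth=200,
        )
        other = model.replace_params(durations=cs.DurationParams(0.4, 5, 0.2))
        sims = cs.generate_dataset(model, 12, seed=9, max_length=400)
        import warnings

        tot = tot_other = 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for s in sims:
                tot += cs.forward(model, s.sequence).loglik
                tot_other += cs.forward(other, s.sequence).loglik
        assert tot >= tot_other
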