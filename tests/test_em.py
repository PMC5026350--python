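"""EM learning: monotonicity, closed-form M-steps, small-scale recovery."""

import warnings

import numpy as np
import pytest

import crmseg as cs
from crmseg.engine import EmConfig, _fit_negbin, em_fit
from crmseg.model import BG_GLOBAL, END


def geometric_only_model(p_g, max_duration=None):
    pwm = cs.Pwm("m0", np.full((2, 4), 0.25), pseudocount=0.0)
    model = cs.HsmmModel.default(
        [pwm],
        durations=cs.DurationParams(p_g, 2, 0.5, max_duration=max_duration),
        bg_order_global=0,
        bg_order_local=0,
        window_halfwidth=100,
    )
    model.transitions[BG_GLOBAL] = {END: 1.0}
    return model


class TestGeometricMStep:
    def test_single_state_closed_form_mle(self):
        """With a single geometric emitting state, each sequence's parse is a
        single segment of its full length, so the M-step p_g must equal the
        closed form 1 / mean(observed lengths) exactly."""
        lengths = [30, 50, 70, 90]
        model = geometric_only_model(0.1, max_duration=200)
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), size=L)) for L in lengths]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = em_fit(model, seqs, config=EmConfig(max_iter=2))
        assert fit.model.durations.p_g == pytest.approx(
            1.0 / np.mean(lengths), abs=1e-12
        )

    def test_trace_monotone(self):
        model = geometric_only_model(0.05, max_duration=500)
        rng = np.random.default_rng(1)
        seqs = ["".join(rng.choice(list("ACGT"), size=int(n))) for n in rng.integers(20, 80, 6)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = em_fit(model, seqs, config=EmConfig(max_iter=10))
        diffs = np.diff(fit.loglik_trace)
        assert (diffs >= -1e-8).all()


class TestNegbinMStep:
    def test_r1_reduces_to_geometric_mle(self):
        hist = np.zeros(50)
        hist[[4, 9, 14]] = [2.0, 1.0, 1.0]  # durations 5,10,15 weighted
        r, pi = _fit_negbin(hist, r_max=1, max_duration=50)
        mean = (2 * 5 + 10 + 15) / 4
        assert r == 1
        assert pi == pytest.approx(1 - 1 / mean, abs=1e-12)

    def test_integer_search_picks_true_r(self):
        """Histogram taken from an exact negative binomial pmf recovers its
        own (r, pi) by the search."""
        from crmseg.durations import truncated_negbin_log_pmf

        for r_true, pi_true in [(2, 0.7), (4, 0.85)]:
            hist = np.exp(truncated_negbin_log_pmf(r_true, pi_true, 400)) * 1000
            r, pi = _fit_negbin(hist, r_max=8, max_duration=400)
            assert r == r_true
            assert pi == pytest.approx(pi_true, abs=0.01)


class TestEmOnToyModels:
    def test_one_iteration_from_truth_does_not_decrease(self):
        """Starting EM at the generating parameters, the first update must
        not lower the log-likelihood."""
        pwm = cs.Pwm(
            "m0", np.array([[0.85, 0.05, 0.05, 0.05]] * 3), pseudocount=0.0
        )
        model = cs.HsmmModel.default(
            [pwm],
            durations=cs.DurationParams(0.05, 2, 0.7, max_duration=300),
            bg_order_global=0,
            bg_order_local=0,
            window_halfwidth=100,
        )
        sims = cs.generate_dataset(model, 8, seed=5, max_length=300)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = em_fit(model, [s.sequence for s in sims], config=EmConfig(max_iter=3))
        diffs = np.diff(fit.loglik_trace)
        assert (diffs >= -1e-8).all()

    def test_small_scale_recovery_improves_parameters(self):
        """Refitting from a perturbed start moves duration parameters toward
        the generating values."""
        pwm = cs.Pwm(
            "m0", np.array([[0.9, 0.04, 0.03, 0.03]] * 6), pseudocount=0.0
        )
        true = cs.HsmmModel.default(
            [pwm],
            durations=cs.DurationParams(1 / 60, 2, 0.8, max_duration=600),
            p_crm=0.7,
            bg_order_global=0,
            bg_order_local=0,
            window_halfwidth=150,
        )
        sims = cs.generate_dataset(true, 15, seed=21, max_length=600)
        start = true.replace_params(
            durations=cs.DurationParams(1 / 200, 3, 0.6, max_duration=600)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = em_fit(
                start,
                [s.sequence for s in sims],
                config=EmConfig(max_iter=15, tol=1e-5),
            )
        diffs = np.diff(fit.loglik_trace)
        assert (diffs >= -1e-8).all()
        got = fit.model.durations
        err_start = abs(1 / 200 - 1 / 60)
        assert abs(got.p_g - 1 / 60) < err_start

    def test_no_parse_errors(self):
        model = geometric_only_model(0.5, max_duration=5)
        # length 20 sequence cannot be tiled by a single b_g of <= 5
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(ValueError):
                em_fit(model, ["ACGTACGTACGTACGTACGT"], config=EmConfig(max_iter=2))
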