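"""PWM scanning, exact p-values, and the candidate lattice."""

import itertools
import warnings

import numpy as np
import pytest

import crmseg as cs
from crmseg.scan import (
    exact_score_pvalue,
    scan_sequence,
    score_site,
    sites_to_bed,
)


def make_model(pwms, **kw):
    kw.setdefault("bg_order_global", 0)
    kw.setdefault("bg_order_local", 0)
    kw.setdefault("window_halfwidth", 5000)
    return cs.HsmmModel.default(pwms, **kw)


def uniform_table(length):
    """An order-0 background table with exactly uniform conditionals."""
    from crmseg.background import LocalMarkovTable

    cond = np.full((length, 4), np.log(0.25))
    logp = np.full(length, np.log(0.25))
    prefix = np.concatenate([[0.0], np.cumsum(logp)])
    return LocalMarkovTable(0, length, 0.0, cond, logp, prefix)


class TestScoreSite:
    def test_identical_models_score_zero(self):
        # PWM equal to an order-0 background: log-odds is 0 everywhere
        seq = "ACGT" * 10
        bg = uniform_table(len(seq))
        pwm = cs.Pwm("uni", np.full((4, 4), 0.25), pseudocount=0.0)
        for i in (0, 7, 36):
            assert score_site(pwm, bg, seq, i, "+") == pytest.approx(0.0, abs=1e-9)

    def test_consensus_under_uniform(self):
        mat = np.eye(4)[[0, 1, 2, 3]]  # deterministic ACGT
        pwm = cs.Pwm("det", mat, pseudocount=0.0)
        seq = "ACGT" * 10
        bg = uniform_table(len(seq))
        assert score_site(pwm, bg, seq, 4, "+") == pytest.approx(4 * np.log2(4))

    def test_strand_mirror_symmetry(self):
        rng = np.random.default_rng(0)
        pwm = cs.Pwm("p", rng.dirichlet(np.ones(4), size=3), pseudocount=0.0)
        seq = "".join(rng.choice(list("ACGT"), size=40))
        from crmseg._alphabet import reverse_complement

        rc = reverse_complement(seq)
        bg = uniform_table(len(seq))  # uniform: position dependence cancels
        for i in (0, 5, 20):
            j = len(seq) - 3 - i
            assert score_site(pwm, bg, seq, i, "+") == pytest.approx(
                score_site(pwm, bg, rc, j, "-"), abs=1e-9
            )

    def test_out_of_bounds(self):
        pwm = cs.Pwm("p", np.full((4, 4), 0.25), pseudocount=0.0)
        bg = uniform_table(40)
        with pytest.raises(IndexError):
            score_site(pwm, bg, "ACGT" * 10, 38, "+")


class TestExactPvalue:
    def test_extremes(self):
        rng = np.random.default_rng(1)
        pwm = cs.Pwm("p", rng.dirichlet(np.ones(4), size=3), pseudocount=0.0)
        comp = np.full(4, 0.25)
        lo = np.log2(pwm.matrix / 0.25)
        assert exact_score_pvalue(pwm, comp, lo.min(axis=1).sum() - 1) == pytest.approx(1.0)
        assert exact_score_pvalue(pwm, comp, lo.max(axis=1).sum() + 1) == 0.0

    def test_dimer_enumeration(self):
        """p-value of the k-th best dimer under uniform background is k/16."""
        rng = np.random.default_rng(2)
        pwm = cs.Pwm("p", rng.dirichlet(np.ones(4), size=2), pseudocount=0.0)
        comp = np.full(4, 0.25)
        lo = np.log2(pwm.matrix / 0.25)
        scores = sorted(
            (lo[0, a] + lo[1, b] for a, b in itertools.product(range(4), repeat=2)),
            reverse=True,
        )
        for s in scores:
            n_ge = sum(1 for x in scores if x >= s - 1e-9)
            assert exact_score_pvalue(pwm, comp, s) == pytest.approx(
                n_ge / 16, abs=1e-9
            )


class TestScanSequence:
    def test_threshold_one_admits_everything(self):
        pwm = cs.Pwm("p", np.full((2, 4), 0.25), pseudocount=0.0)
        model = make_model([pwm])
        seq = "ACGTACGTACGT"
        lat = scan_sequence(model, seq, pvalue_threshold=1.0)
        for state, adm in lat.admissible.items():
            assert adm.all()

    def test_plant_and_recover_site(self):
        mat = np.full((8, 4), 0.01)
        consensus = [0, 1, 2, 3, 0, 1, 2, 3]  # ACGTACGT... not palindromic? it is RC-symmetric!
        consensus = [0, 0, 1, 2, 0, 3, 3, 2]  # AACGATTG (not its own RC)
        for i, b in enumerate(consensus):
            mat[i, b] = 0.97
        mat /= mat.sum(axis=1, keepdims=True)
        pwm = cs.Pwm("site", mat, pseudocount=0.0)
        model = make_model([pwm])
        rng = np.random.default_rng(3)
        seq = list(rng.choice(list("ACGT"), size=200))
        planted = "".join("ACGT"[b] for b in consensus)
        seq[100:108] = planted
        seq = "".join(seq)
        lat = scan_sequence(model, seq, pvalue_threshold=1e-4)
        starts = [(s.start, s.strand) for s in lat.sites]
        # stringent both-strand scan keeps exactly the planted placement
        assert starts == [(100, "+")]

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        pwm = cs.Pwm("p", rng.dirichlet(np.full(4, 0.5), size=5), pseudocount=0.0)
        model = make_model([pwm])
        seq = "".join(rng.choice(list("ACGT"), size=300))
        n_prev = None
        for thr in [1.0, 0.1, 0.01, 1e-3, 1e-5]:
            n = scan_sequence(model, seq, thr).n_sites()
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n

    def test_empty_pwm_set_errors(self):
        pwm = cs.Pwm("p", np.full((2, 4), 0.25), pseudocount=0.0)
        model = make_model([pwm])
        model.pwms = {}
        with pytest.raises(ValueError):
            scan_sequence(model, "ACGT")

    def test_bed_export(self):
        pwm = cs.Pwm("p", np.full((2, 4), 0.25), pseudocount=0.0)
        model = make_model([pwm])
        lat = scan_sequence(model, "ACGTACGT", pvalue_threshold=1.0)
        bed = sites_to_bed(lat.sites, model, "seq1")
        lines = [l.split("\t") for l in bed.strip().split("\n")]
        assert all(len(l) == 6 for l in lines)
        assert all(int(l[2]) - int(l[1]) == 2 for l in lines)


class TestLatticeRestriction:
    def test_restricted_likelihood_bounded_and_trivial_equal(self):
        from .toys import random_toy

        for seed in range(8):
            model, seq = random_toy(seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                full = cs.forward(model, seq).loglik
                lat1 = cs.CandidateLattice.trivial(model, len(seq))
                eq = cs.forward(model, seq, lat1).loglik
                lat = scan_sequence(model, seq, pvalue_threshold=0.05)
                restricted = cs.forward(model, seq, lat).loglik
            assert eq == full  # exact: identical code path, no masking
            assert restricted <= full + 1e-12

    def test_decoded_motifs_come_from_lattice(self):
        from .toys import random_toy

        for seed in range(8):
            model, seq = random_toy(seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lat = scan_sequence(model, seq, pvalue_threshold=0.5)
                try:
                    path = cs.posterior_viterbi(model, seq, lat)
                except ValueError:
                    continue  # no admissible parse under this lattice
            for seg in path.emitting():
                if model.states.is_motif(seg.state):
                    assert lat.admits(seg.state, seg.start)
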