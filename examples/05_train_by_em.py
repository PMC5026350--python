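"""Learn transitions and duration parameters by EM.

Simulates training sequences from a known model, perturbs the parameters,
and refits; the log-likelihood trace is non-decreasing and the duration
parameters move back toward the generating values.
"""

import warnings

import crmseg as cs
from crmseg.engine import EmConfig, em_fit
from crmseg.harness import perturbed_recovery_start, recovery_model
from crmseg.scan import scan_sequence

warnings.simplefilter("ignore")

true = recovery_model()
sims = cs.generate_dataset(true, 10, seed=2, max_length=3000)
seqs = [s.sequence for s in sims]
lattices = [scan_sequence(true, s, 5e-3) for s in seqs]

fit = em_fit(perturbed_recovery_start(), seqs, lattices,
             EmConfig(max_iter=12, tol=1e-5))

print("loglik trace:", [round(x, 1) for x in fit.loglik_trace])
d = fit.model.durations
print(f"fitted p_g {d.p_g:.4f} (true {true.durations.p_g:.4f}), "
      f"r {d.r} (true {true.durations.r}), pi {d.pi:.3f} (true {true.durations.pi})")
print(f"fitted P(b_g -> CRM) {fit.model.trans('b_g', 'c_s'):.3f} "
      f"(true {true.trans('b_g', 'c_s'):.3f})")
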