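"""PWM scanning with exact p-values.

Plants one strong motif instance in random background and scans both
strands; the candidate lattice retains the planted placement and reports
its exact match p-value under the sequence composition.
"""

import numpy as np

import crmseg as cs
from crmseg.harness import strong_pwm

rng = np.random.default_rng(1)
pwm = strong_pwm("site", rng.integers(0, 4, size=8))
model = cs.HsmmModel.default([pwm], bg_order_global=0, bg_order_local=0,
                             window_halfwidth=500)

seq = list(rng.choice(list("ACGT"), size=500))
seq[240:248] = pwm.consensus()
seq = "".join(seq)

lattice = cs.scan_sequence(model, seq, pvalue_threshold=1e-4)
for site in lattice.sites:
    print(f"{site.motif} at {site.start} ({site.strand}): "
          f"{site.score:.1f} bits, p = {site.pvalue:.2e}")
# the planted start (240, +) is recovered; random 500 bp of background
# yields ~0.2 false sites in expectation at this threshold
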