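"""Motif and duration building blocks.

Builds a PWM from counts, scores a segment under the product-multinomial
model, and evaluates the three duration laws of the segmentation model.
"""

import numpy as np

import crmseg as cs

counts = np.array(
    [[8, 0, 1, 1], [0, 9, 0, 1], [0, 0, 10, 0], [2, 2, 2, 4]]
)
pwm = cs.Pwm.from_counts("demo", counts, pseudocount=0.01)
print("PWM width:", pwm.width, "consensus:", pwm.consensus())
print("log P('ACGT' | motif) =", round(cs.motif_emission_logprob(pwm, "ACGT"), 3))
rc = cs.reverse_complement_pwm(pwm)
print("reverse-complement consensus:", rc.consensus())

# motif states occupy exactly their width; backgrounds draw from explicit laws
print("motif duration  d(4|w=4) =", cs.motif_duration_pmf(4, 4))
print("geometric gap   d(100|p_g=0.01) =", round(cs.geometric_duration_pmf(0.01, 100), 6))
print("NB spacer       d(15|r=3,pi=0.8) =", round(cs.negbin_duration_pmf(3, 0.8, 15), 6))
# the NB mean spacer length is r/(1-pi): here 15 bp, matching typical
# binding-site spacing inside a module
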