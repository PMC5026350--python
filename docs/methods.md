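# Methods

## Model

A transcriptional regulatory sequence is modelled as generated by a hidden
semi-Markov process over the state space

    H = {S, E} ∪ {c_s, c_e} ∪ M ∪ M' ∪ {b_g} ∪ {b_c},

where M holds one state per motif and M' their reverse complements (the
reverse-complement state shares the column-reversed, base-complemented
matrix of its forward partner), b_g and b_c are the global (inter-module)
and local (intra-module) backgrounds, and S, E, c_s, c_e are silent: they
emit nothing, have no duration model, and exist to mark sequence ends and
CRM boundaries. Permitted transitions are

    S → b_g;  b_g → {c_s, E};  c_s → any motif;
    motif → {any motif, b_c, c_e};  b_c → any motif;  c_e → b_g.

Consequences of this topology: every sequence begins and ends in global
background; a CRM contains at least one motif (c_s → c_e directly is not
permitted); local background appears only between motifs; there is no
b_c self-loop and no direct exchange between the two background states.
Direct motif → motif transitions carry ordering preferences between
adjacent sites within a module.

Each emitting state s generates a segment of length t with probability
d_s(t) · e_s(o_1:t). The duration laws are a point mass at the PWM width
for motif states, a geometric law with parameter p_g for b_g, and a
negative binomial for b_c,

    d_bc(u) = C(u−1, r−1) π^(u−r) (1−π)^r,

i.e. the number of Bernoulli trials needed to collect r successes of
probability 1−π, supported on u ≥ r with mean r/(1−π). r is constrained to
positive integers (the binomial coefficient is taken literally); estimation
searches over integer r.

Motif emission is the product multinomial: independent positions, each
drawn from its PWM column. Database count matrices get a pseudocount
(default 0.01 per cell) before per-position normalization so that no
mismatch has probability zero. Background emission at position i is an
order-k Markov conditional P(o_i | o_{i−k:i−1}) estimated locally: the
(k+1)-mer and k-mer frequencies are counted in a window [i−D, i+D) clipped
at the sequence ends, and the counts are maintained incrementally as the
window slides one position at a time (each shift removes one (k+1)-mer and
adds one), so the whole table costs one pass. Positions with fewer than k
predecessors use the truncated, lower-order context that exists. Defaults:
global order m = 3, local order m′ = 2, D = 500 bp, pseudocount 0.25 per
cell — the orders and window are conventional values for this class of
model and are all exposed in the configuration. The window length should
satisfy 2D ≥ 4^(k+1) for non-sparse estimates; the fit warns otherwise.

The ambiguity code N emits with probability 1/4 under every state and is
excluded from background counts and composition estimates. Other IUPAC
ambiguity codes are accepted on input and collapsed to N.

## Truncation of duration laws

Dynamic programming bounds the duration dimension at a per-state
max_duration: by default the smallest u whose cumulative mass reaches
1 − 1e−6, optionally capped at a known sequence length, and overridable in
the model document. The truncated pmf is renormalized to sum to one over
1..max_duration. During an EM fit the bounds are frozen at fit start
(quantile bound capped at the longest training sequence) so that a single,
fixed model family is optimized across iterations; this is what makes the
log-likelihood trace non-decreasing. One bound is used per state for the
whole training set rather than per sequence — a per-sequence cap would make
the renormalization, and hence the objective, sequence-dependent.

## Inference

Forward and backward recursions run over segment boundaries:
α_j(t) = Σ_u [Σ_i α_i(t−u) a_ij] d_j(u) e_j(o_{t−u+1:t}), with silent
states composed into effective emitting-to-emitting edges carrying the
product of the underlying probabilities (the CRM boundary markers are
restored in decoded paths). Background segment emissions telescope into
prefix-sum differences, so each position costs one vector operation over
the duration window. All arithmetic is in log space with −∞ as the
impossible-event sentinel and log-sum-exp reductions.

The posterior of a segment (state j, start p, duration u) is
in-flow(j, p) · d_j(u) · e_j · out-flow(j, p+u) / P(o). Decoding maximizes
the product of these segment posteriors over legal paths (posterior
Viterbi) by a dynamic program of the same shape; legality means the
topology's edges, exact motif durations, and well-formed CRM bracketing.
Ties are broken deterministically by scanning durations longest-first
(earliest segment start preferred) and predecessor states in fixed index
order, keeping the first maximum.

## Search-space reduction

Before parsing, every PWM is scored against both strands at every position
(log-odds in bits against the sequence's global base composition with
add-one smoothing). The match p-value is exact: the distribution of the
discretized total score under the iid-composition null is built by dynamic
programming over per-column score distributions (granularity 1e−3 bits),
and P(score′ ≥ score) is read from its survival function. The lookup
threshold is slackened by half a quantum per column so that genuine ties
are never dropped by rounding drift. Placements with p ≤ threshold
(default 1e−4) become the candidate lattice; motif segments may start only
at admissible placements, overlapping candidates are all retained, and the
decoder arbitrates conflicts through path legality. A threshold of 1
reproduces the unrestricted model exactly; any restriction can only lower
the likelihood. The p-value definition and threshold are package defaults,
documented here, not a claim about any external tool.

## Learning

EM (a modified Baum-Welch over segmentations) re-estimates transitions and
duration parameters; PWMs are held fixed at their database values and the
background tables are estimated per sequence before the fit and held fixed
— they are defined by windowed counts, not by responsibilities. The E-step
accumulates, over sequences: expected effective-edge transition counts
(α·a·β sums), expected sequence-end counts, and expected duration
histograms for both background states (computed as a cross-correlation of
scaled in-flow and out-flow vectors, one lag per duration). The M-step is
closed-form: transition rows are renormalized expected counts (rows with no
expected mass keep their previous values); p_g = 1/mean expected b_g
duration (the geometric MLE); for b_c, an exhaustive search over integer
r = 1..r_max (default 20) sets π(r) = 1 − r/mean and keeps the r that
maximizes the expected truncated log-likelihood of the histogram. The
closed forms are the untruncated MLEs; with the default (1 − 1e−6)
truncation bounds the distinction is far below the 1e−8 slack the
monotonicity test allows. Convergence: relative log-likelihood change
below tol (default 1e−6) or max_iter (default 100).

Two practical properties of the integer-r search matter. Downward moves
are always available, but upward moves are blocked as soon as the current
model places posterior mass below a candidate r (the expected
log-likelihood is −∞ there), so r should be initialized at or above the
value one expects. Second, EM can stall in a neighbouring-r basin on hard
data; `harness.fit_with_r_profile` therefore refits from the converged
model with r forced one step down and one step up (π rescaled to preserve
the mean spacer) and keeps the solution with the best final
log-likelihood — a likelihood profile over the one integer parameter.
`EmConfig` also supports seeded random restarts chosen by final
log-likelihood.

## Simulation

Sampling follows the generative reading of the model: a Markov walk over
the full state graph, a duration drawn from the truncated, renormalized pmf
at each emitting state, then column-wise emission from the PWM (reverse
-complement states from their own matrix) or from a stationary background
chain with configurable order and composition (default iid uniform). The
windowed background estimator is a fitting-time device and is deliberately
not used for generation. Walks exceeding max_length are trimmed back to
global background, the final b_g is clipped so the total length is exact,
and the record is flagged truncated. One master seed spawns independent
per-sequence streams, so datasets of any size are reproducible.

What the simulator does not emulate: position-dependent background
composition drift (emission is stationary within a draw), evolutionary
conservation across orthologs, overlapping or nested modules, and
dinucleotide structure inside motifs. Tests passing on simulated data
therefore certify the estimator and decoder under the model's own
assumptions, not performance on real regulatory sequence.

## Reference study conditions

Two fixed settings in `crmseg.harness` define the synthetic experiments.

Parameter recovery: two width-8 motifs with 0.97-dominant columns;
geometric gaps of mean 100 bp (p_g = 1/100); spacers NB(r=3, π=0.8), mean
15 bp; CRM opening probability 0.92; motif rows 0.3/0.5/0.2 across
motif/spacer/close. Fifty sequences (max 6 kb, mean ≈ 2 kb) are simulated,
scanned at p ≤ 5e−3 (training favours candidate recall: the 5e−3 level
retains two-mismatch instances of these matrices, whose absence would
split modules during training), and refit from a perturbed start
(p_g = 1/150, r = 5, π = 0.75, flattened rows) with max_iter 25, tol 1e−5
and the r-profile refit. These sizes keep the experiment within a few
minutes on one CPU. The setting was designed so the two background roles
are identifiable — equal background orders, spacer and gap scales separated
by an order of magnitude — and so each learnable transition row sees
hundreds of expected events; with overlapping duration scales the posterior
genuinely merges short gaps into spacers and no estimator could return the
generating values.

Plant-and-recover: two width-10 strong motifs; 1 kb sequences each
carrying exactly one CRM sampled from the model's CRM sub-process and
placed uniformly; decoding with the generating model at the default 1e−4
scan threshold; performance is the pooled nucleotide CC/F1 against the
planted intervals.

## Numerical choices

- log space throughout; −∞ sentinel; log-sum-exp with max-shifting.
- Expected duration histograms combine the scale offset in log space
  before exponentiation (the offset alone can overflow even though the
  expected count cannot) and clamp negative correlation round-off to zero.
- The exact p-value DP discretizes at 1e−3 bits; score classes closer than
  about w·granularity merge conservatively.
- PWM rows, transition rows and truncated pmfs are validated to sum to 1
  within 1e−9.
- Posterior Viterbi tie-breaks are deterministic (earliest start, then
  state order); forward and backward log-likelihoods agree within 1e−8 and
  posterior covering mass is 1 within 1e−6 at every position.
- Degenerate evaluation denominators (empty margins) produce NaN, never a
  silent 0; F1 is 0 by convention only when precision = recall = 0.

## Limitations

- EM optimizes a restricted likelihood when a candidate lattice is
  supplied; a threshold that drops true sites biases duration and
  transition estimates (the training default 5e−3 is chosen accordingly).
- The integer-r search cannot move r upward once smaller durations carry
  posterior mass; use the r-profile refit or start r high.
- Background tables are per-sequence and fixed; co-regulated sequences do
  not share background statistics.
- Silent-state composition assumes no silent→silent chains, which the
  topology guarantees; alternative topologies would need a transitive
  closure.
- Model selection (number of motifs, background orders, D) is the user's:
  nothing is cross-validated internally.
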