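# Methods

This note documents the models and procedures implemented in
`brainstates`, the parameter choices that matter, what the synthetic data
do and do not emulate, and the numerical decisions a user relying on the
results should know about.

## The hidden Markov model

The core object is a Gaussian-emission HMM over parcellated BOLD data.
One "observation" is the vector of P parcel signals at one TR; a run is a
T×P matrix, z-normalized within run per parcel (sample standard
deviation, ddof=1) before any modeling. Runs from all subjects are
concatenated; the model is a *group* model — one set of parameters
describes everyone, and subject/run identity enters only through run
boundaries.

Assumptions, in decreasing order of importance:

1. **Discrete states.** At every TR the brain occupies exactly one of K
   states; the decoded sequence is a hard Viterbi path. Posterior
   uncertainty is available (`forward_backward`) but the downstream
   statistics use hard labels.
2. **Full state covariances.** Each state has its own P×P covariance, so
   states are distinguished by coupling structure as well as mean
   pattern. A ridge of 1e−6 is added to every covariance at every M-step;
   with P up to ~25 and thousands of TRs this never dominates but
   prevents collapse when a state's expected occupancy gets small.
3. **First-order, homogeneous switching.** Dwell times are implicitly
   geometric. No semi-Markov durations, no autoregressive emissions, no
   time-varying transition probabilities.
4. **Conditional independence over time.** Given the state path,
   observations are independent — there is no within-state
   autocorrelation in the model (nor in the synthetic data; see below).

**Multi-run handling.** The forward recursion restarts with the initial
distribution at every run boundary; pairwise-state expectations (and
empirical transition counts everywhere in the package) exclude
boundary-crossing pairs. The alternative — treating the concatenation as
one long sequence — contaminates the transition matrix with one spurious
pair per run; excluding them is cheap and exact.

**Estimation.** EM with k-means initialization (10 internal k-means
restarts, best inertia; cluster statistics give the initial means,
covariances, and add-one-smoothed transition counts). EM stops when the
log-likelihood gain drops below `tol` (default 1e−4, absolute) or at
`max_iter` (default 1000). The likelihood trace is stored on the fitted
parameters and is non-decreasing up to 1e−6 numerical slack. The
forward–backward pass uses scaled (per-step normalized) recursions with a
per-TR log-shift on the emission densities, so concatenations of any
length neither underflow nor overflow. `fit_with_restarts` (default 10
restarts; 3 in the cross-validated settings below) derives restart seeds
deterministically from the master seed and keeps the highest-likelihood
fit. Viterbi runs in log space; ties break toward the lowest state index.

**Model-order selection.** `select_K` runs leave-one-subject-out
cross-validation: for each fold and candidate K, fit on all-but-one
subject, Viterbi-decode the held-out subject, and compute the
Calinski–Harabasz score of the held-out *observations* grouped by the
*decoded* labels; the K with the best fold-mean wins, ties to the
smaller K. Two open choices were resolved as follows: the score is
computed on the P-dimensional observations with hard decoded labels (not
on posteriors), and a zero within-cluster scatter is reported as a large
sentinel (1e12) rather than infinity so fold means stay finite. Selection
uses a deliberately short EM schedule (50 iterations, tol 1e−2, 3
restarts): the decoded labels — all the score sees — stabilize long
before the likelihood converges, and on the standard synthetic group the
selected K is identical to a 4×-longer schedule while running in a
fraction of the time.

**Surrogate models.** All "chance" state-level quantities come from
refitting the HMM on surrogate data in which each parcel's time course is
independently circularly rotated within run. Rotation preserves each
parcel's marginal distribution and autocorrelation but destroys
cross-parcel covariance, which is exactly the structure the states are
supposed to capture. Random rotation offsets exclude 0 so every surrogate
differs from the original.

## Synthetic data: what it emulates, what it does not

`synthetic_data` generates group datasets from known parameters: a state
path per subject-run from the Markov chain (optionally shared across
subjects to emulate stimulus-driven synchrony), Gaussian draws given the
path, behavioral traces equal to a per-state effect plus noise passed
through the canonical HRF, and interleaved ABAB event structures with
uniform-integer event lengths.

Defaults define the standard study condition used throughout the tests:
K=4 states, P=10 parcels, 8 subjects × T=600 TRs at TR=1 s,
self-transition probability 0.9 (mean dwell 10 TRs, the order of
magnitude seen in slow fMRI state dynamics), and random full covariances
A·Aᵀ/P + 0.1·I (distinct coupling per state, guaranteed positive
definite). State means sit on a sphere of radius `mean_separation`·√P/2,
arranged as a **randomly oriented regular simplex**, so every pairwise
mean distance is identical and the separation knob really does control
decoding difficulty (separation 3 sd for recovery tests — comfortably
decodable; ~1.5 makes decoding genuinely hard). Random mean directions
were rejected for this purpose: their minimum pairwise distance
fluctuates by roughly a factor of two across draws, so nominally
identical conditions would range from easy to nearly degenerate —
particularly damaging for model-order selection, since the
Calinski–Harabasz criterion merges a close pair of states long before
estimation or decoding breaks down.

What the generator deliberately omits: scanner drift, head motion,
physiological noise, spatial structure in the parcel layout, and any
within-state temporal autocorrelation. Consequently, passing tests show
that the *algorithms* recover the structure they model; they do not show
robustness to fMRI nuisance structure.

**The hub-state generator.** `sample_hub_hmm_params` builds a specific
four-state architecture: three "specialized" states with distinct mean
patterns and distinct full covariances, plus a **base** state with zero
mean and a weak diagonal covariance (0.3·I), wired as a transition hub —
specialized states exit mostly into the base state (0.08 vs 0.01 to each
other specialized state) and the base state dwells briefly
(self-probability 0.5) before feeding the next specialized state. This is
the synthetic analogue of the empirically reported state architecture in
naturalistic fMRI: a near-baseline, weakly synchronized state that routes
transitions between functionally specialized states.

An important negative result shaped this design. The qualitative
signature "global cofluctuation dips just before a state transition"
does **not** emerge from the plain generator: with conditionally iid
emissions, transition times are exogenous, and the only candidate source
of a dip — Viterbi placing decoded boundaries on atypical, low-magnitude
samples — measures at ≈ −0.002 ± 0.005 (offset +3 minus offset −1, P=25,
T=30,000, six parameter draws), i.e. nothing; covariance-coded states
even show the opposite (switches trigger on high-coherence samples). In
the hub architecture the dip is a real property of the generating
process — most transitions pass through the desynchronized base state —
and the aligned-cofluctuation analysis recovers it robustly
(dip ≈ 0.05–0.13 at both desk and large scale, minimum at offsets −1/0,
recovered by +3). The corresponding test therefore validates that the
measurement machinery detects a pre-transition desynchronization that is
genuinely present, not that such a dip emerges from decoding alone.

## Cofluctuation

Edge time series are |z_i·z_j| per parcel pair (i<j, row-major),
computed from the run's z-scores (the run normalization is reused; edges
are not re-normalized within analysis windows). Edges are grouped into
cortico-cortical / cortico-subcortical / subcortico-subcortical
categories from per-parcel tags. Transition-aligned traces take the
window −3..+3 TRs around each transition onset (the first TR of the new
state); windows clipped by a run edge are dropped, not padded. The
aligned-trace null redraws as many onsets per run as were observed,
uniformly without replacement, and recomputes the trace (default 1000
iterations, reducible).

## Gradients

The functional connectome is the group mean of per-subject Pearson
correlation matrices (z-normalized runs concatenated within subject),
diagonal zeroed. For the diffusion-map embedding: negatives are clipped
to zero, each row is thresholded at its 90th-percentile quantile, the
affinity is the cosine similarity between thresholded rows, and the
anisotropic diffusion operator (α=0.5) is eigendecomposed via its
symmetric conjugate. Coordinates use diffusion time t=0; the trivial
constant component is dropped; each component's sign is fixed by making
its largest-magnitude loading positive (embeddings are sign-ambiguous);
variance ratios are eigenvalue shares of the non-trivial spectrum. A
disconnected affinity graph is an error, not a warning — an embedding of
a disconnected graph is meaningless. How many gradients to keep is left
to the user; the variance ratios are reported for exactly that decision.

State projection is the mean element-wise product between gradient
loadings and state mean activity — linear in the state means, placing a
zero-mean (base-like) state at the origin. The state-spread test compares
the observed mean pairwise distance in gradient space to surrogate-model
states; per-state axis-extremity p-values compare each observed
coordinate to the pooled null coordinates on that axis (the null states
carry no meaningful identity, so pooling is the only coherent choice),
FDR-corrected over K×G comparisons.

## Behavioral coupling and boundary analyses

RT variability traces: NaN trials filled by 1-D linear interpolation
(edges take the nearest valid value), linear detrend, absolute deviation
from the post-detrend mean, linear resampling onto the TR grid when the
trial grid differs, the subject's mean variability prepended as the
first-TR value, z-normalization, and sign inversion for the attention
proxy. Detrending happens before the prepend (the alternative order is
ill-defined: the prepended value is a summary, not a sample).
Engagement-style traces are z-normalized and HRF-convolved with the
canonical double-gamma kernel (Γ(6,1) − Γ(16,1)/6 on a 32 s support,
unit peak, response mode at 5 s, undershoot near 15 s) — the standard
shape, overridable via the kernel parameters.

Boundary-aligned occurrence uses the window −2..+20 TRs; per-boundary
offsets outside the run are dropped; proportions are averaged over
boundaries within subject, then across subjects, and sum to 1 across
states at every offset with data. The null circularly rotates each
subject's boundary indices within run. Boundary-conditioned transition
classification labels a transition into the target state "boundary" if
its onset falls 5–15 TRs (at TR=1 s; scaled as round(5/tr)..round(15/tr)
otherwise) after any boundary. Attention-by-state nulls rotate the
behavioral trace, not the state sequence.

Paired contrasts across subjects (boundary vs non-boundary source
proportions, block-type occupancy differences) use a sign-permutation
test of subject-level differences — exact enumeration of all 2^n sign
flips for n ≤ 14, Monte-Carlo with add-one correction above — rather
than signed-rank or ANOVA machinery; the inferential target (symmetry of
paired differences about zero) is the same, and the package stays fully
permutation-based.

## Inference conventions

- Permutation p-values are add-one: p = (b+1)/(n+1) per tail, doubled and
  capped at 1 for two-tailed tests — valid at finite n, never exactly 0.
- Null bands are mean ± 1.96·sd of the null realizations.
- Multiple comparisons use Benjamini–Hochberg step-up FDR throughout
  (over states, offsets, or state-axis pairs, as each analysis states).
- Circular shifts are always within run and never cross concatenation
  boundaries; random offsets exclude 0.
- Every stochastic routine takes a seed; derived seeds are drawn below
  2^31 from a `numpy` Generator seeded by the master seed.

## Known limitations

- The group HMM shares parameters across subjects; subject-specific
  deviations in state geometry are not modeled.
- Calinski–Harabasz model selection rewards compact, well-separated
  clusters in observation space; for states distinguished mainly by
  covariance it can be conservative.
- The sentinel cap (1e12) for infinite Calinski–Harabasz scores makes
  degenerate folds comparable but arbitrary in magnitude; it matters only
  when a held-out decoding is perfectly tight, which does not occur off
  toy data.
- Synthetic validation covers the model's own assumptions (see above);
  claims about real fMRI robustness require real data.
- Parametric alternatives (signed-rank, repeated-measures ANOVA,
  mixed-effects models with motion covariates) are intentionally out of
  scope; the permutation substitutes target the same hypotheses.
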