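# Methods

## Model and procedure

The pipeline operationalizes informal leadership as two scores per actor in
a bounded advice-seeking network.

**Advice matrix.** A roster survey asks every participant whom they seek
advice from and how often; responses form a directed nonnegative matrix
x<sub>jk</sub> (row *j* sought advice from column *k*) with a structurally
zero diagonal. Self-nominations are removed at ingest (logged), duplicate
(j, k) rows are summed (logged), and rows without consent or with excluded
roles are dropped and counted. The advice frequency is treated as a generic
nonnegative integer: the pipeline makes no assumption about whether the
instrument records counts or frequency categories.

**Centrality proxies.** Four centralities are computed on the *binarized*
matrix by default: in-degree (number of distinct nominators), unnormalized
directed betweenness on unit-length arcs, and in-/out-closeness. Binarized
arcs are the default because the in-degree narrative of such surveys counts
nominations per distinct nominator, and geodesic metrics on raw frequencies
would need an arbitrary weight-to-distance transform; a frequency-weighted
variant (distance = 1/frequency, weighted in-degree) is available behind a
flag. Closeness defaults to the *harmonic* form normalized by (n−1), because
sparse directed advice networks routinely contain actors with no incoming
(or outgoing) paths, for which classic closeness is undefined; a
Freeman-style variant on the reachable set (Wasserman–Faust corrected) is
available for comparison with desktop SNA packages. Whether betweenness is
pre-normalized by (n−1)(n−2) is immaterial: the subsequent min–max rescaling
is invariant to any positive affine pre-transform (asserted by a property
test).

**Rescaling.** Each raw metric is mapped onto the survey's 1–5 scale by
x ↦ 1 + 4(x − min)/(max − min), computed **within the boundary being
analyzed** (full cohort vs residents-only), so the two boundary conditions
are each internally consistent. A degenerate constant metric maps to the
mid-scale value 3 with a prominent warning, keeping the composite score
defined.

**Style weights.** Preceptors rank the importance of the four styles from 1
(most important) to 4; ranks map to the reciprocal values 1.00, 0.50, 0.33,
0.25. The printed two-decimal constant 0.33 — not 1/3 — is used
deliberately so that aggregated totals match hand-computed tables. Ratings
are independent per style with ties allowed (not a forced permutation):
under a forced permutation every rater would contribute exactly 2.08 and
aggregate totals could only be multiples of it, which real panels do not
show. Weights are the per-style sums divided by the grand total and always
sum to 1 (asserted on construction).

**Scores.** LAD is LS<sub>k</sub> = Σᵢ wᵢ·n<sub>ik</sub>; LAI is the same
weighted sum over per-style means of the two Likert items. Both are convex
combinations of values in [1, 5] and hence bounded by [1, 5]. The
dispersion printed next to each score is interpreted as the sample standard
deviation (n−1 denominator) of the four weighted components; this
interpretation exactly reproduces the worked dispersion values of the
published score tables (e.g. an all-maximum self-rater gives LAI 5.00 with
component SD 0.21) and is an inference, since the original tables do not
define their parenthetical. Scores are kept at full precision internally;
rounding (half-up, 2 decimals for scores, 1 for percentages) happens only
at display. Reconstructions of printed score tables are accurate to ±0.01,
the resolution of two-decimal display.

**Quadrants.** Cut-offs are the sample means: LAI over LAI-eligible actors
(complete 8-item blocks), LAD over all boundary actors. A score exactly at
its cut-off classifies as "high" (the quadrant definitions use ≥). Actors
with incomplete Likert blocks stay in the network and LAD computations but
are excluded from LAI and quadrant assignment, with a warning; no
imputation is attempted.

**Boundary sensitivity.** The residents-only rerun executes the whole
pipeline on the resident–resident submatrix: centralities, their rescaling,
LAD, and both cut-offs are recomputed over residents. Per-actor LAI values
are frozen (self-perception does not depend on who is in the network), but
the LAI cut-off is recomputed over residents, since the quadrant cut-offs
are defined as boundary-specific sample means. Style weights are *not*
re-derived: they come from preceptor ratings, an exogenous input. Any
transition, adjacent or diagonal, is permitted and reported; the stability
share is the fraction of residents keeping their label.

## Synthetic cohort generator

The generator emulates the kind of cohort the analysis targets: 68 actors
(22 preceptors, 22 R1, 23 R2, 1 R3), a rating panel of 19 preceptors, and a
dense directed network centralized on a subset of highly connected actors.
Defaults (all configurable):

| parameter | default | rationale |
|---|---|---|
| base_tie_prob | 0.06 | dense-but-sparse advice network (expected density ≈ 0.1 with the boosts below) |
| hub_fraction | 0.20 | a planted minority of highly sought-out actors |
| hub_tie_multiplier | 6 | strong, visible centralization around hubs |
| preceptor_attraction | 1.5 | residents preferentially consult preceptors |
| frequency_model | {1:.35, 2:.25, 3:.20, 4:.12, 5:.08} | decreasing frequency mass; the analysis is insensitive to it under binarization |
| alignment_rho | 0.5 | partial self-perception/position alignment, the realistic regime |
| likert_noise_sd | 0.5 | about one scale step of item-level noise |
| rating_concentration | 1.0 | panels broadly favor the relational > transformational > adaptive > resilient ordering while disagreeing rater-to-rater |

Ties are independent Bernoulli draws per ordered pair with probability
base × hub-multiplier × preceptor-attraction (target-side factors only),
capped at 0.99; frequencies are drawn independently given the tie. Likert
actor means are drawn near the top of the scale (normal, mean 4.2, SD 0.55,
clipped to [1, 5]), matching the location and spread self-ratings show in
clinical cohorts; item scores add rounding and noise. Alignment is imposed
by rank-coupling: whole 8-item blocks are reassigned to actors so that the
rank correlation between an actor's planted incoming-tie propensity and its
realized block mean is ≈ alignment_rho, without distributional assumptions.
All draws flow from a single seeded generator; identical configuration
yields a byte-identical dataset.

**Planted truth.** Each actor records its hub flag and an expected quadrant:
the LAD axis expectation is the hub flag; the self axis expectation is the
actor's LAI classification itself (weighted style means under the cohort's
elicited weights, at or above the cohort LAI mean). The self axis is
computed, not planted, because LAI involves no network inference — it is a
deterministic function of survey answers — so recovery tests probe what
actually requires inference: whether network centrality identifies the
planted hubs.

**Recovery conditions.** The planted-structure recovery test uses full
alignment (ρ = 1), hub multiplier 8 on a 0.08 base, and no preceptor
attraction, because role attraction deliberately centralizes non-hub
preceptors and would contradict the planted truth by construction. Under
these conditions the pipeline recovers ≥ 90 % of planted labels (mean over
25 seeds). Recovery degrades on sparser networks: out-closeness carries no
hub signal at all under the target-side-only tie model (an actor's
out-reach depends on its own random out-ties), so the adaptive component of
LAD is pure noise with respect to hubness, and the geodesic metrics grow
noisier as the network thins. This is a known limitation of the planted
model, not of the scoring pipeline.

**What the generator does not emulate.** Team/rotation structure and
reciprocity, degree-sequence realism, longitudinal dynamics, response
biases (social desirability, halo effects), and any coupling between
frequency values and tie existence. Passing recovery tests therefore shows
that the pipeline identifies centrality-aligned leadership under the
generative assumptions, not that the instrument is valid on real cohorts.

## Problem sizes

The test suite and the acceptance script work at the emulated cohort size
(n = 68; residents-only n = 46), with Monte-Carlo sweeps of 20–100 seeds
for generator calibration checks and 25 seeds for recovery; brute-force
betweenness oracles run on 200 random digraphs of up to 6 nodes, where
exhaustive path enumeration is exact and fast.

## Known limitations

* The centrality→style proxy map is an approximation by construction; no
  psychometric validation of the Likert instrument is attempted.
* Mean cut-offs make quadrant labels cohort-relative; near-cut-off labels
  are unstable under small perturbations, which the boundary-sensitivity
  analysis makes visible rather than hides.
* The closeness convention (harmonic vs Freeman) affects raw values;
  rankings agree on well-connected networks but can differ in the presence
  of many unreachable pairs. The default is chosen for definedness, not for
  equivalence with any particular desktop package.
* UCINET DL support covers the full-matrix format with embedded labels
  only.
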