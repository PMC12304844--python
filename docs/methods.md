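# Methods

This note documents the models, numerical choices and limitations behind
`mlmetad`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Toy systems and what they emulate

The package's synthetic systems are low-dimensional Langevin particles on
analytic landscapes, standing in for an all-atom ligand–receptor complex.
The `dissociation_funnel` preset encodes the features a dissociation
problem must have for the protocol to be non-trivial:

* **Bound basin** — a Gaussian well of depth `depth_bound` (default 9
  k_BT) at small exit distance. At this depth the default system shows no
  unbiased dissociation within 10⁶ integrator steps (asserted in the test
  suite), so exits are observable only under bias.
* **Gated exit** — a Gaussian ridge (`ridge_height`, default 8 k_BT)
  blocks the direct exit path except near one value of a second, "gating"
  coordinate, where an intermediate well sits. Productive dissociation
  therefore passes through an intermediate sub-state, emulating systems in
  which a local rearrangement (for instance an ion completing its
  hydration shell) must precede ligand release.
* **Distractor CVs** — extra harmonic coordinates (default 2–3) carry no
  information about the transition; the reaction-coordinate learner must
  suppress them.
* **Internal extension mode** (cognate-ligand analog only) — an extra
  coordinate `u` with preferred value `u_bound − contraction·sigmoid((x −
  x_contract)/width)` models a flexible ligand that must shorten to pass
  the exit bottleneck. The pipeline's end-to-end analysis shows the mean
  extension in the 50-frame pre-exit window is measurably below the
  bound-state average; this is a property of the fixture, not a claim
  about any real system.
* **Confinement** — quartic walls beyond the unbound plateau replace a
  solvated periodic box, keeping unbound dwell finite.

The eight-member toy-ligand library varies bound-well depth and
intermediate depth over fixed, arbitrary values (8.0–9.5 k_BT) standing in
for ligand chemistry, and maps each member to an experimentally measured
dissociation constant (ITC, micromolar) of the compound it is named
after. Units are reduced (k_B = 1, T = 1, unit mass and friction) by
default; a kJ/mol + kelvin mode is available for settings stated in
physical units.

What the toys deliberately do not model: solvent and ions, internal
receptor degrees of freedom, rugged multi-pathway exits, CV noise from
coordinate fitting, and the force-field errors of real simulations.
Passing tests therefore demonstrate the correctness and internal
consistency of the machinery, not the accuracy of any all-atom
prediction.

## Integrator

BAOAB splitting (half kick, half drift, full Ornstein–Uhlenbeck step,
half drift, half kick) with per-step Gaussian noise drawn from a
seed-initialized generator; every trajectory is a pure function of
(configuration, seed), which the suite asserts bit-for-bit. Defaults: dt
= 0.005, friction = 1, mass = 1. Validation: equipartition on a harmonic
well to 5%, and free-diffusion mean first-passage time against the
analytic L²/2D value (at friction 50, where the overdamped result holds;
at friction ~1 the inertial boundary layer inflates the MFPT by tens of
percent, which is physics, not error). A committed exit requires the stop
variable to stay beyond its cutoff for `commit_steps` (default 500)
consecutive steps, suppressing recrossing artifacts; the event time is
the first step of the committed excursion.

## Well-tempered metadynamics

Hills are deposited every `pace` on one or two linear bias variables with
tempered heights h₀·exp(−V/(γ−1)k_BT). Inside the simulation kernel the
bias is evaluated from a dense cached grid (spacing σ/5, updated at each
deposit with the Gaussian's exact value and gradient, linearly
interpolated); the `HillsLedger` retains the exact hill sum, and the
recorded per-frame bias agrees with the exact sum to < 0.02 k_BT in the
tests. The per-frame bias is recorded *before* that frame's deposition.
The FES estimator is the final-bias relation F = −γ/(γ−1)·V(·, t_final),
min-shifted; time-dependent reweighting estimators are a documented
extension point, not implemented. On the 5 k_BT quartic double well
(γ=10, h₀=0.5, pace 250 steps, 2×10⁶ steps) the recovered barrier is
within 1 k_BT of truth (acceptance experiment; typical error ~0.2 k_BT).

Hill-width rules follow the two protocol rounds: round 1 biases two
physical CVs with σ = 0.75 × the CV standard deviation of an unbiased
bound-state run; round 2 biases the learned RCs with σ = 0.25 × the
bound-state RC standard deviation. Both fractions are exposed as
parameters rather than hard-coded, since the protocol treats σ as a
tunable. Defaults h₀ = 1.5 (energy units), γ = 40, pace = 1.0 mirror
common biomolecular settings on the reduced-unit toys. Hills deposited
after the event time are dropped from the ledger, so the hill count
equals ⌊t_event/pace⌋ exactly.

## SPIB

The encoder is a linear mean map on z-scored CVs plus a learned diagonal
Gaussian noise scale (variational); the decoder is one hidden ReLU layer
(16 units) with softmax over states, predicting the label `lag` frames
ahead. Loss: cross-entropy + β·KL against a standard-normal prior, β
default 10⁻². Training is hand-written backpropagation with Adam
(deterministic given the seed). Label refinement replaces each frame's
label with the decoder's prediction every `refine_every` epochs, drops
empty states, and stops when fewer than 2% of frames change. z-scoring
constants are taken from the bound state when a mask is supplied (the
pipeline does), making transfer across systems well-defined; constants
are stored in the model together with the CV names, and application
requires an exact name match. `latent_dim` defaults to 2; the second RC
often carries negligible weight (its bound-state σ is then tiny), which
is harmless since the first RC dominates the bias forces.

Numeric hyperparameters (lag 10–20 frames, 30–60 epochs, batch 512,
learning rate 5×10⁻³) are declared package choices sized to the toy data.
On a two-state toy with one informative CV and three distractors the
normalized informative weight exceeds 0.8 (typically 0.96+) for every
seed tested, and a model trained on the training funnel, transferred to a
different funnel sharing CV names, drives dissociation in ≥ 90% (observed
16/16) of seeded WT-MetaD runs.

## Kinetics

The acceleration factor is the running arithmetic mean of e^{βV} over
frames inside the bound set A up to the event, evaluated at the recorded
per-frame bias; t_rel = t_sim·α. The alternative cumulative rescaling
Σ dt·e^{βV} over all frames is provided as a documented option. α ≥ 1
and t_rel ≥ t_sim whenever the bias is non-negative (enforced).
Exponential fitting uses the MLE τ = mean; the KS statistic is the exact
two-sided sup over ECDF jump points and the p-value comes from the exact
finite-n Kolmogorov distribution (`scipy.stats.kstwo`). Because τ is
fitted on the same sample, the test is conservative: the measured type-I
rejection rate at p < 0.05 over 200 samples of 16 true exponential draws
is ~0–3%, well under the 10% bound asserted. A parametric-bootstrap
p-value that accounts for the fitted parameter is available.

The uncertainty on τ is reported two ways: √τ (the square root of the
fitted mean — kept literally despite its odd units for continuous times,
because it is the rule this protocol family uses) and the conventional
τ/√n. k_off_rel = 1/τ; k_on_rel = k_off_rel/K_D with symmetric
relative-error propagation (asymmetric K_D errors are symmetrized).
Outlying rescaled times are retained in the fit; a median-based
diagnostic column accompanies the report. Ligands with KS p ≤ 0.05 stay
in the full table but are excluded from the ranking output.

Oracle equivalence: on a 6 k_BT double well where unbiased exits are
feasible, the mean rescaled time over 16 biased runs is within a factor
of 2 of the brute-force MFPT from 50 unbiased events (measured ratios
~0.7–1.3 across seeds).

## Analyses

Free-energy projections histogram visited CV values weighted by
e^{+βV_final(s)} (final-bias reweighting, matching the FES estimator) and
min-shift −k_BT·ln P. ΔRMSD is the per-coordinate difference in
root-mean-square fluctuation between the exit windows of biased runs
(last 500 bound frames plus post-commitment frames) and an unbiased
bound-basin reference trajectory of the training system — the toy analog
of comparing exit-path flexibility against a ligand-removed reference; a
ligand's internal-mode coordinate is excluded from the shared roster.
Coordination numbers use the rational switching function
(1−(r/r₀)ⁿ)/(1−(r/r₀)ᵐ) with n=6, m=12 and the n/m limit at r = r₀.

## Pipeline, determinism and problem sizes

All stage seeds derive deterministically from the single config seed (and
stay below 2³¹); rerunning a config reproduces the kinetics CSV byte for
byte (asserted). Default problem sizes — 2×10⁵-step unbiased runs,
10⁶-step round-1 biasing, 2×10⁶-step caps on round-2 runs, 16 runs per
ligand — were chosen so a full eight-ligand pass completes in minutes on
one core while every stage retains comfortable statistics; the
acceptance script uses 8 runs per ligand for the pipeline stage. The KS
verdict at n = 8–16 events is noisy by nature; this mirrors the
limited-statistics regime the protocol is designed for, and is why the
pass flag, not the point estimate, gates the ranking.

## Known limitations

* The bias grid cache trades ~10⁻² k_BT interpolation error for speed;
  pathological hill widths far below the grid spacing would degrade it
  (widths are validated positive, and the spacing follows σ).
* SPIB refinement can collapse to a single state on degenerate labels;
  the trainer stops refining, warns, and keeps the previous labels.
* The FES estimator and the projection reweighting both use the
  final-bias approximation; early-time hills bias them slightly for
  short runs.
* Transfer assumes CV rosters agree in names *and semantics*; only the
  name match is checkable and enforced.
* Relative rates share an arbitrary common time scale; only ratios and
  rankings across a ligand set are meaningful.
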