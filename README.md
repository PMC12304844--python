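# mlmetad

Machine-learning-augmented metadynamics for ligand-dissociation kinetics on
model landscapes.

Residence times of ligands on structured RNA (or protein) targets are far
beyond the reach of plain molecular dynamics: a bound state separated from
the unbound ensemble by a many-k<sub>B</sub>T barrier may not dissociate
once in a microsecond of simulation. A practical protocol for ranking
ligands by kinetics is to (i) force dissociation with well-tempered
metadynamics (WT-MetaD), (ii) learn a low-dimensional reaction coordinate
(RC) from one dissociation trajectory with the State Predictive Information
Bottleneck (SPIB) and transfer it to the whole ligand library, (iii)
recover unbiased residence times from the biased runs via the
infrequent-metadynamics acceleration factor, (iv) validate the resulting
first-passage statistics with a Kolmogorov–Smirnov (KS) test, and (v)
combine the relative off-rates with experimentally measured dissociation
constants to obtain *relative on-rates*, k<sub>on</sub><sup>rel</sup> =
k<sub>off</sub><sup>rel</sup>/K<sub>D</sub>.

`mlmetad` implements this full protocol as a tested, reusable library and
exercises it end to end on seeded Langevin toy systems whose landscapes
reproduce the essential structure of an RNA–ligand dissociation problem: a
deep bound basin, an intermediate gating sub-state that must be visited
before exit, distractor collective variables (CVs), and dissociation that
is observable only under bias. It is aimed at method developers and
simulation practitioners who want a desk-scale, fully reproducible testbed
for enhanced-sampling kinetics machinery.

## The method

**Well-tempered metadynamics.** Gaussian hills are deposited every `pace`
on the biased variables *s*:

    V(s, t) = Σ_{t_i ≤ t} h_i exp(−Σ_j (s_j − c_{ij})² / 2σ_j²),
    h_i = h₀ exp(−V(c_i, t_i)/k_B ΔT),   ΔT = (γ − 1) T,

with bias factor γ > 1. The free-energy surface follows from the final
bias, F(s) = −γ/(γ−1) · V(s, t_final) + C.

**SPIB reaction coordinates.** The RC is a *linear* map of z-scored CVs,
z = W x̃ + b + ε·exp(logσ²/2), trained so that a small softmax decoder
predicts the metastable-state label a lag time Δt into the future, with
loss CE + β·KL(q‖N(0,I)) and iterative label refinement. Because the
encoder mean map is linear, the trained model transfers to any system
exposing the same CV names, and the RC compiles into an exact linear bias
variable (chain-rule forces included).

**Kinetics.** For each biased run the acceleration factor
α(t) = ⟨e^{βV(s(R,t))}⟩_{s∈A} is the running mean of e^{βV} over frames in
the bound state A (a cutoff on one CV plus a commitment requirement); the
rescaled transition time is t_rel = t_sim·α. Independent rescaled times
are fitted as an exponential (τ = sample mean, the MLE) and checked
against the fitted distribution with a one-sample KS test; ligands with
p ≤ 0.05 are flagged and excluded from the headline ranking. The reported
uncertainty on τ is √τ (the square root of the fitted mean), with the
conventional MLE error τ/√n alongside; errors propagate into
k<sub>on</sub><sup>rel</sup> = k<sub>off</sub><sup>rel</sup>/K<sub>D</sub>
by symmetric relative-error combination.

## Worked example

Validate the time rescaling against a brute-force first-passage oracle on
a double well with a 6 k<sub>B</sub>T barrier (reduced units):

```python
import numpy as np
import mlmetad as m
from mlmetad import presets

thermo = m.ThermoContext()                      # reduced units: kB = 1, T = 1
system = presets.double_well_system(barrier=6.0, n_distractors=0)

# brute-force oracle: 50 unbiased first-passage events
oracle = m.mfpt_bruteforce(system.surface,
                           m.LangevinParams(n_steps=10_000_000, seed=1000),
                           thermo, system.stop_condition(), n_events=50)
print(f"brute-force MFPT: {oracle.mean:.0f} +/- {oracle.stderr:.0f}")

# 16 biased runs, rescaled by the acceleration factor
bias = [m.BiasVariable("d_exit", np.array([1.0]))]
params = m.MetadParams(sigma=[0.11], h0=0.5, gamma=10.0, pace=5.0,
                       biased_variables=["d_exit"], max_time=50_000.0)
t_rel = []
for i in range(16):
    run = m.run_wtmetad(system.surface, bias, params, thermo,
                        m.LangevinParams(n_steps=10_000_000, seed=500 + i),
                        stop=system.stop_condition(), stride=5)
    rec = m.transition_record(run.trajectory, thermo, system.bound,
                              run.event, run.event_time)
    t_rel.append(rec.t_rel)

fit = m.fit_exponential(t_rel)
print(f"mean rescaled time: {np.mean(t_rel):.0f}  (tau = {fit.tau:.0f})")
print(f"KS: D = {fit.D:.3f}, p = {fit.p:.2f}  -> Poissonian: {fit.p > 0.05}")
```

which prints

```
brute-force MFPT: 509 +/- 102
mean rescaled time: 640  (tau = 640)
KS: D = 0.124, p = 0.94  -> Poissonian: True
```

The biased estimate (640) agrees with the unbiased oracle (509 ± 102)
well within the factor-of-2 fidelity expected of acceleration-factor
rescaling, and the rescaled times pass the Poisson/exponential KS check.
The full protocol — round-1 CV biasing, SPIB training, RC transfer to a
ligand library, kinetics report and mechanistic analyses — runs with

```python
from mlmetad.pipeline import PipelineConfig, run_pipeline
result = run_pipeline(PipelineConfig(seed=1, outdir="out"))
print(result.report)        # per-ligand tau, KS p, k_off_rel, k_on_rel
```

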