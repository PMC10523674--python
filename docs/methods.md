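# Methods

`tenscalib` implements closed-loop calibration of transcutaneous electrical
nerve stimulation (TENS) parameters for somatosensory feedback. Two deep
Q-network (DQN) agents search a discrete (pulse amplitude, pulse width) grid
for the stimulus pairs evoking a target low-intensity and a target
high-intensity somatotopic sensation. The agents are trained entirely
offline against a *simulated subject* — three statistical models fitted to a
reference trial dataset — and then deployed greedily on a new (real or
virtual) subject.

## 1. Parameter space and percepts

| quantity | symbol | range | step | unit |
|---|---|---|---|---|
| pulse amplitude | PA | 1 – 16 | 1 | mA |
| pulse width | PW | 70 – 600 | 10 | µs |
| frequency | f | 50 (fixed) | — | Hz |
| train duration | — | 2 (fixed) | — | s |

The grid has 16 × 54 = 864 points. Injected charge per pulse is
Q = PA · PW / 1000 (µC).

A subject's report has four components: perceived intensity
(not-perceived / low / high / too-high), sensation type
(uncomfortable / comfortable), location (not-somatotopic / somatotopic,
i.e. whether the percept projects to the missing/target foot region), and
an "in-loco" intensity SE ∈ 0–10 felt under the electrode itself.

## 2. Markov decision process

**States.** The 4 × 2 × 2 = 16 raw report combinations collapse to 13
states: when nothing is perceived, type and location are undefined, so all
4 not-perceived combinations map to a single state. The critic receives a
3-vector (intensity/3, type, location), zeros for not-perceived.

**Actions.** 9 parameter deltas: ΔPA ∈ {−1, 0, +1} mA × ΔPW ∈ {−10, 0, +10}
µs, clamped at the grid boundary.

**Rewards.** A fixed table over the 13 states, one per agent level. States
are ranked by desirability with priority intensity > location > type: the
too-high block is worst, the safe-but-wrong-intensity block next, the
not-perceived state sits at a zero pivot just below the target-intensity
block, and the target block tops out at +1 for target + somatotopic +
comfortable. Values are `(-1.0, -0.9, -0.8, -0.6, -0.4, -0.3, -0.2, -0.1,
0.0, 0.2, 0.4, 0.6, 1.0)` by rank. Magnitudes are kept of order one so
that discounted values stay within easy reach of a small critic trained at
learning rate 1e-4; only the ordering carries meaning.

## 3. DQN agents

The critic is a fully connected 3-40-30-9 ReLU network (one Q-value output
per action) implemented in numpy, trained by one-step temporal-difference
learning with experience replay, an Adam optimiser, an L2 weight penalty
and a soft-updated target network.

| hyperparameter | default | note |
|---|---|---|
| learning rate | 1e-4 | Adam |
| L2 factor | 1e-4 | added to weight gradients |
| target smoothing τ | 1e-3 | θ_t ← τθ + (1−τ)θ_t per update |
| discount γ | 0.99 | |
| batch size | 64 | uniform replay sampling |
| ε₀ / decay / ε_min | 1.0 / 0.005 / 0.25 | multiplicative decay per update |
| replay capacity | 5000 | circular FIFO |
| max steps / episode | 60 | training only |
| episodes | 1000–1500 | per agent |

The ε floor of 0.25 is deliberately high: the observation is heavily
aliased (13 states describe 864 grid points), so sustained exploration is
needed to keep rarely visited states' Q-values meaningful. For the same
reason 30 % of training episodes use *exploring starts* (a uniformly random
grid point instead of the dataset initialization), which in particular
creates outgoing transitions from too-strong states so the policy learns
to back out of an overshoot.

Training restarts up to 3 times per agent (deterministic derived seeds) and
keeps the policy with the best (offline accuracy, grid-corner robustness
probe, mean steps); both selection signals are computed against the
simulated environment only.

## 4. Simulated subject (three fitted models)

Features per stimulus: PA, PW, PA·PW, 1000/PW, gender code, weight,
one-hot nerve (peroneal / tibial / sural); z-scored for the distance-based
models. The 1000/PW term is included because perception thresholds follow
a strength–duration law that is linear in PA and 1/PW; without it a planar
intensity model extrapolates a spurious safe region at short pulse widths.

* **Intensity** — ordinary least squares on the 4-level code (0–3), decoded
  by round-and-clamp. Planar class boundaries: it may miss an exact class
  near a boundary but in practice is never off by two.
* **Type** — random-subspace ensemble of 30 k-nearest-neighbour classifiers
  (k = 5, subspace size ⌈√d⌉); majority vote, ties resolve to comfortable.
* **Location** — Gaussian-process regression on the 0/1 somatotopy label
  with exponential kernel k(x,x′) = σ_f² exp(−‖x−x′‖/ℓ) + σ_n² δ
  (σ_f = 1, σ_n² = 1e-4, ℓ = median pairwise distance), solved by Cholesky
  factorisation and thresholded at 0.5.

Single-class label columns fall back to constant predictors with a warning.

## 5. Synthetic cohort generator

No human data ships with the package; a first-class generator emits both
the cohort and the reference trial dataset.

Each virtual subject is a psychometric model:

* perception threshold current at pulse width PW follows Weiss–Lapicque:
  I_th(PW) = rheobase · (1 + chronaxie / PW);
* normalized drive d = (PA − I_th) / ((pain_margin − 1) · rheobase) maps to
  a 0–10 rating as clip(10 d); rating bands: < 0.5 not perceived, < 5 low,
  < 9 high, ≥ 9 too high. The calibration targets are ratings 2 (low) and
  8 (high);
* location is somatotopic iff d ≥ 0.05 (the nerve trunk is recruited) and
  Q ≤ 1.5 · Q_high (beyond that, current spread dominates); comfort is lost
  above 1.3 · Q_high, where Q_high is the subject's ground-truth high-target
  charge;
* SE grows linearly with drive (per-subject slope);
* optional rating noise and label flips are drawn from a stream seeded by
  (subject, stimulus), so identical stimuli always get identical answers.

Cohort distributions (defaults): 27 men / 22 women; per-nerve rheobase
means 2.0 / 2.8 / 2.2 mA (peroneal / tibial / sural), SD 0.25; chronaxie
250 ± 30 µs; pain margin 3.0 ± 0.3; female rheobase factor 0.9; weight
80 ± 9 kg (M), 65 ± 9 kg (F); neuropathic subjects have rheobase doubled.
These were chosen a priori from textbook strength–duration ranges so the
target charges land inside the grid. Each subject contributes an
expert-style ramp trace (PA ramp to somatotopy, then a PW ramp to the first
too-strong report), subsampled evenly to the per-nerve quotas
552 / 108 / 228 (888 trials total).

**What the generator emulates:** threshold physiology and its dependence on
gender/nerve/pathology, the intensity–charge ordering, the dataset's
composition and ramp-like sampling, reproducibility under one seed.
**What it does not emulate:** real psychophysical variability (habituation,
attention, electrode shift), inter-session drift, true somatotopic maps,
the in-loco/projected interplay, or any human wall-clock timing. Human
result figures from stimulation studies are therefore *not* reproduction
targets; only directional analogs are asserted.

## 6. Online calibration and baselines

The RL calibration chains two greedy phases. The low phase starts from the
minimum-charge somatotopic low-level dataset row for the subject's
gender × nerve; the high phase starts from the high-level pair of dataset
subjects who reported the same low pair (exact-match lookup), else from the
found low pair. A phase ends successfully as soon as the subject reports
the desired sensation (target intensity, somatotopic); it fails on a stall
(5 unchanged parameter pairs short of the target), three consecutive
too-strong reports (safety abort), or a 100-stimulus cap. Offline testing
instead uses the 5-consecutive-unchanged convergence rule, matching how the
offline accuracy targets are defined.

Baselines: **BFA** (brute force) is a monotone PW-major ramp — PW up in
10 µs steps at fixed PA, then PA + 1 mA with PW reset — stopping at the
first somatotopic report of the target intensity; it cannot decrease charge
and fails if it overshoots. The **scripted naive** protocol ramps PA at
PW = 300 µs until a somatotopic percept, then ramps PW (with a PA fallback
when PW exhausts) for the low and high targets.

## 7. Evaluation

Per calibration: number of stimuli, charge at both found levels, proxy
mapping time (n_stims × 20 s bookkeeping constant; simulated runs have no
meaningful wall clock), and the sensation quality index

Q = 0.6 · I + 0.15 · T + 0.25 · L · (1 − SE/10)

with I/T/L ∈ {0,1} (target intensity reached, comfortable, somatotopic);
an ideal mapping scores 1.0.

Method comparison is nonparametric throughout: a Kolmogorov–Smirnov
normality screen (reported only), a Friedman omnibus per metric when ≥ 3
methods, pairwise Wilcoxon signed-rank tests Bonferroni-corrected at
0.05 / n_pairs, and Mann–Whitney U for independent (healthy vs neuropathic)
groups.

## 8. Numerical and reproducibility choices

* All randomness flows from one master seed through named
  `numpy.random.SeedSequence` substreams (cohort [seed, 101], trials
  [seed, 202], environment fit [seed, 303], DQN [seed, 404]); every derived
  seed is < 2³¹.
* The GP solve uses `scipy.linalg.cho_factor`/`cho_solve` with jitter
  σ_n² = 1e-4 on the diagonal; tested against a dense `numpy.linalg.solve`
  oracle to 1e-8.
* Per-subject grid answer tables are precomputed once (vectorised over all
  864 points), making a training step a table lookup.
* Episode budgets, cohort sizes and the benchmark cohort (15 nerves: five
  subjects × three nerves) are the package's own desk-scale choices; they
  keep the whole offline pipeline within minutes on one CPU.

## 9. Limitations

* The 13-state observation aliases hundreds of grid points; the learned
  policy is a state → direction map, not a value map over parameters.
  Robustness comes from exploration and restart selection, not from the
  representation.
* The intensity model's planar boundaries limit offline fidelity near class
  transitions (within-one-class accuracy is enforced, exact-class is not).
* The quality index weights and the reward-table values are design
  constants; conclusions that depend on their exact magnitudes (rather than
  orderings) should not be drawn.
* Virtual subjects are noiseless by default; noise robustness can be probed
  via `rating_noise_sd` / `label_flip_prob` but is not part of the
  acceptance gates.
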