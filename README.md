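# tenscalib

Closed-loop reinforcement-learning calibration of transcutaneous electrical
nerve stimulation (TENS) parameters for somatosensory feedback.

## The problem

Non-invasive sensory neuroprostheses restore touch-like feedback by
stimulating a nerve through the skin. Before every use the stimulation must
be *calibrated*: find the pulse amplitude (PA, 1–16 mA) and pulse width
(PW, 70–600 µs) that evoke (a) a just-perceivable and (b) a strong but
comfortable sensation, both projected to the target (somatotopic) region.
Manual calibration is slow and expert-dependent; this package automates it
with reinforcement learning.

Two Deep Q-Network (DQN) agents — one per target intensity level — treat
calibration as a Markov decision process: the state is the subject's
verbal report (perceived intensity, comfort, location; 13 states), the 9
actions are ±1 mA / ±10 µs parameter shifts, and the reward ranks states by
desirability. The agents are trained entirely *offline* against a
simulated subject — three statistical models (linear regression for
intensity, a random-subspace KNN ensemble for comfort, a Gaussian process
for location) fitted to a reference trial dataset — and then deployed
greedily on new subjects. Brute-force (BFA) and scripted-naive ramp
protocols serve as baselines.

No human data is included: a first-class synthetic generator produces
psychometric virtual subjects (Weiss–Lapicque strength–duration thresholds)
and the 49-subject / 888-trial reference dataset the environment is fitted
on. See `docs/methods.md` for the full model description.

## Worked example

Train both agents through the full offline pipeline (synthetic dataset →
environment fit → low agent → high agent) and calibrate a virtual subject:

```python
from tenscalib import run_offline_pipeline, run_calibration
from tenscalib.calibration import VirtualResponder
from tenscalib.subjects import CohortSpec, sample_cohort
from tenscalib.core import charge

run = run_offline_pipeline(seed=1, episodes=1500)   # ~4 min on one CPU
print(f"offline accuracy: low {run.accuracy_low:.2f} high {run.accuracy_high:.2f}")

subject = sample_cohort(CohortSpec(n_men=1, n_women=0, seed=101))[0]
res = run_calibration(run.agent_low, run.agent_high,
                      VirtualResponder(subject), run.trials)
print(f"low  (PA, PW) = ({res.low_params.pa:.0f} mA, {res.low_params.pw:.0f} µs), "
      f"Q = {charge(res.low_params):.2f} µC")
print(f"high (PA, PW) = ({res.high_params.pa:.0f} mA, {res.high_params.pw:.0f} µs), "
      f"Q = {charge(res.high_params):.2f} µC")
print(f"{res.n_stims} stimuli, converged: {res.converged_low and res.converged_high}")
```

Output:

```
offline accuracy: low 1.00 high 1.00
low  (PA, PW) = (11 mA, 90 µs), Q = 0.99 µC
high (PA, PW) = (12 mA, 90 µs), Q = 1.08 µC
5 stimuli, converged: True
```

The same workflow is available on the command line:

```bash
tenscalib gen-cohort --seed 0 --out-dir out      # cohort.json + trials.csv (888 rows)
tenscalib train --seed 1 --episodes 1500 --out-dir out
tenscalib benchmark --seed 1 --n-subjects 5 --out-dir out   # RL vs BFA vs naive
```

On a noiseless 15-nerve benchmark cohort (five subjects × three nerves,
seed 1) the trained RL agents need a mean of 4.3 stimuli per calibration
versus 10.4 for the brute-force ramp and 36.4 for the scripted naive
protocol, and the RL low-level charge recovers each subject's ground-truth
low-target charge to within one grid step on 15/15 nerves.

## Reproduction

All randomness derives from a single seed via named substreams; every
stage is bit-reproducible. To recompute the acceptance target values
(quality index of an ideal mapping; low/high offline accuracies in %):

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

This regenerates the dataset, refits the environment and retrains both
agents from scratch (no cached artifacts) and writes the three values with
their sample sizes to the JSON file. The full pytest suite, including the
acceptance criteria in `tests/test_acceptance.py`, runs with plain
`pytest tests/`.

## Layout

| path | contents |
|---|---|
| `src/tenscalib/core.py` | grid, stimulus/report types, state encoding, quality index |
| `src/tenscalib/mdp.py` | actions, state ordering, reward tables |
| `src/tenscalib/subjects.py` | virtual subjects, cohort + trial generator |
| `src/tenscalib/environment.py` | the three fitted answer models |
| `src/tenscalib/dqn.py` | numpy DQN (network, replay, training, offline test) |
| `src/tenscalib/calibration.py` | online RL calibration, BFA and naive baselines |
| `src/tenscalib/evaluation.py` | metrics, nonparametric statistics, benchmark |
| `src/tenscalib/io.py`, `cli.py` | file formats and the `tenscalib` CLI |
| `src/tenscalib/pipeline.py` | end-to-end offline orchestration |
| `docs/methods.md` | methods note: model, parameters, assumptions, limits |
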