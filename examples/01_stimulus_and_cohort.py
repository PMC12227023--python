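"""Stimulus geometry and a synthetic cohort of step-response recordings.

Builds the difference-of-Gaussians low-acuity patch profile, converts the
two viewing distances to accommodative demand, and simulates a small cohort
under the 7-condition Maddox-cue design.
"""

import numpy as np

from accomstep import (CUE_CONDITIONS, SimConfig, StimulusSpec,
                       demand_from_distance, dog_stimulus_profile, simulate_cohort)

# the low-acuity patch used to diminish the blur cue: 3e^{-x^2/s^2} - 2e^{-x^2/2.25s^2} + K
spec = StimulusSpec(sigma=1.0, K=0.5)
x = np.array([0.0, 1.0, 5.0])
print("DoG luminance at x =", x, "->", np.round(dog_stimulus_profile(x, spec), 4))
print("  (peak 1+K at center, decays to the mean luminance K in the surround)")

near, far = demand_from_distance(0.40), demand_from_distance(1.00)
print(f"demand: 40 cm -> {near} D, 1 m -> {far} D, step = {near - far} D")

cohort = simulate_cohort(SimConfig(n_participants=3, seed=7))
print(f"\nsimulated {len(cohort)} recordings (3 participants x 7 cue conditions)")
for rec in cohort[:7]:
    cond = CUE_CONDITIONS[rec.cue]
    print(f"  {rec.participant_id} {rec.cue:5s} {cond.presentation:9s} "
          f"{len(rec.events):2d} movements, {rec.n_samples} samples at {rec.fs:.0f} Hz, "
          f"{100 * np.mean(rec.both_missing):.1f}% missing")
# each binocular cue records 30 x 5 s movements (7500 samples = 150 s),
# monocular cues 60; focus (far-to-near) and defocus steps are interleaved
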