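# lateralis

Analysis pipeline for **lateralized (turning) motor behavior** and the
neural signals recorded alongside it: pose-derived rotational kinematics,
turn-aligned fiber-photometry ΔF/F, spike-train direction tuning with
modulation-index classification, stimulus-evoked EMG quantification, and
projection-density lateralization. It is aimed at behavioral/systems
neuroscientists who track a rodent's nose, ears and tail base on video,
annotate turn onsets relative to a recorded or stimulated hemisphere, and
need the standard downstream quantities reproducibly.

A synthetic-session generator with known ground truth ships as a
first-class module, so every estimator can be validated end-to-end
without any recorded data.

## Core quantities

* **Angular velocity** — per-frame wrapped change of the tail-base→nose
  heading × frame rate, signed so positive is *ipsiversive* (toward the
  declared hemisphere). Mean angular velocity is taken over active
  rotation periods (|ω| ≥ 20 deg/s sustained ≥ 0.5 s), excluding
  immobile phases.
* **Rotation counts** — the signed angle is integrated; every ±360°
  of accumulated rotation increments the ipsi/contra count, and the
  ipsilateral percentage is 100·N_ipsi/(N_ipsi + N_contra).
* **Head–trunk angle** — deflection between the ear-midpoint→nose and
  tail-base→ear-midpoint segments (0° = straight).
* **ΔF/F** — (F − F₀)/F₀ with a per-trial pre-event baseline or a
  running-percentile baseline; trials aligned on turn onsets into a
  trials × time matrix, averaged as mean ± SEM, directions compared on
  per-trial response means.
* **Modulation index** — MI = (R_ipsi − R_contra)/(R_ipsi + R_contra)
  from mean firing rates in the 0–0.5 s post-turn window; units are
  labeled ipsi/contra/none by a label-permutation test (n = 1000,
  α = 0.05).
* **EMG peak & latency** — max rectified deviation from the pre-stimulus
  baseline median within 5 s after stimulation onset; latency to the
  first sustained 3-SD crossing.
* **Density index** — region density / mean contralateral density, so
  the contralateral mean is 1 and ipsilateral values read as
  fold-change; downstream output proportions are per-animal labeled-cell
  fractions, keeping regions present in ≥ half the animals.

See `docs/methods.md` for estimator details, defaults, and limitations.

## Worked example

Simulate a 2-minute session with seven 360° turns (five ipsiversive, two
contraversive, 90 deg/s) under realistic tracking noise, then recover the
kinematics:

```python
from lateralis import (BehaviorProtocol, TurnBout, gen_pose, angular_velocity,
                       mean_angular_velocity, count_rotations, ipsi_percentage,
                       detect_turn_events)

protocol = BehaviorProtocol(
    session_duration=120.0, frame_rate=30.0,
    turn_schedule=[TurnBout(10.0 + 15.0 * i, d, 360.0, 90.0)
                   for i, d in enumerate(["ipsi", "ipsi", "contra", "ipsi",
                                          "ipsi", "contra", "ipsi"])],
    landmark_noise_sd=0.1,   # cm
)
track, events = gen_pose(protocol, hemisphere="right", seed=42)
series = angular_velocity(track, smooth_s=0.2)
n_ipsi, n_contra = count_rotations(series)
print(f"rotations: {n_ipsi} ipsi, {n_contra} contra "
      f"({ipsi_percentage(n_ipsi, n_contra):.1f}% ipsilateral)")
print(f"mean angular velocity: {mean_angular_velocity(series):.1f} deg/s")
detected = detect_turn_events(series, min_angle=90.0)
print(f"detected turn onsets: {[round(e.onset_s, 2) for e in detected]}")
```

Output:

```
rotations: 5 ipsi, 2 contra (71.4% ipsilateral)
mean angular velocity: 90.2 deg/s
detected turn onsets: [10.02, 24.98, 40.02, 54.98, 70.02, 84.98, 100.02]
```

All five ipsiversive and both contraversive rotations are counted, the
71.4% ipsilateral share follows, the 90 deg/s ground-truth speed is
recovered to 0.2%, and all seven scheduled onsets are detected within a
frame of their true times.

The full chain (kinematics, photometry, spike classification, EMG,
densitometry) runs from the command line:

```sh
lateralis all --seed 7 --out runs/demo        # defaults
lateralis all --config my.yaml --seed 7 --out runs/demo
```

which writes per-stage CSVs plus a `summary.json`; reruns with the same
config and seed are byte-identical.

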