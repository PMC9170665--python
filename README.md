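# osari

A headless, fully testable implementation of the **anticipated-response
inhibition (ARI)** variant of the stop-signal task, together with an
independent horse-race participant simulator and a batch analysis suite for
stop-signal data.

## The task and who this is for

In an ARI task a participant holds a key down while a vertical bar fills over
a fixed trial duration (1 s by default). On **go trials** they release the
key so the bar stops as close as possible to a target drawn at 80% of the bar
height — i.e. a pre-planned response timed at 800 ms. On **stop trials** the
bar halts on its own at the **stop-signal delay (SSD)** and the participant
must keep the key down until the trial ends. A 1-up/1-down staircase adapts
the SSD (start 500 ms, step 25 ms, clamps 50–775 ms) toward the delay at
which the participant responds on half of the stop trials,
P(respond | signal) = .50.

Performance is summarised under the **independent horse-race model**: go and
stop processes race, and the response is inhibited iff the stop process
finishes first. The covert latency of stopping, the **stop-signal reaction
time (SSRT)**, is estimated nonparametrically by the *integration method with
replacement*: append one trial-duration value per go omission to the go-RT
sample, sort, take the RT at 1-based rank ⌈p·N⌉ where p = P(respond | signal),
and subtract the mean SSD:

    SSRT = RT_go[⌈p·N⌉] − mean SSD

This package is for researchers who need the task's logic, data format and
analysis chain without a graphics stack: piloting design choices in
simulation, validating analysis pipelines, running parameter-recovery
studies, or re-analysing existing task exports (including the STOP-IT
choice-reaction dialect).

## Modules

- `osari.task_model` — session composition, trial scheduling, the SSD
  staircase, feedback-band classification, and the bar-position arithmetic.
- `osari.simulator` — race-model participants (truncated-normal go and stop
  finishing times, optional trigger failures) driving full sessions.
- `osari.data_io` — the exact space-delimited `.txt` trial format
  (`id block trialType trial signal response ssd rt`), the STOP-IT dialect,
  the `ID_OSARI_yyyy_month_d_hhmm` naming convention, and condition tables.
- `osari.analysis` — go/stop descriptives, the inhibition function,
  integration-method SSRT, proactive inhibition, and six-panel plot-data
  bundles.
- `osari.cli` — `osari simulate / analyze / visualize / make-config`.

## Worked example

```python
from osari import TaskParameters, ParticipantParams, simulate_session, analysis, data_io

params = TaskParameters()                     # 1 s trial, target at 800 ms
participant = ParticipantParams(go_mean=0.80, go_sd=0.05,
                                ssrt_mean=0.20, ssrt_sd=0.03)
outcomes = simulate_session(participant, params, seed=1)
frame = data_io.outcomes_to_frame(outcomes, "s01")
row = analysis.analyze_participant(frame, params)
print(row[["go_mean_rt", "p_respond_signal", "mean_ssd", "ssrt"]])
```

prints

```
go_mean_rt          0.796803
p_respond_signal    0.466667
mean_ssd               0.595
ssrt                0.195446
```

The simulated participant lifted the key 796.8 ms into the trial on average
(target: 800 ms), responded on 46.7% of test-phase stop trials (the
staircase aims at 50%), saw a mean SSD of 595 ms, and the integration-method
SSRT of 0.195 s recovers the generative stopping latency of 0.200 s to
within 5 ms from a single 300-trial session.

The same workflow from the shell:

```sh
osari simulate -n 3 --seed 1 --out cohort/
osari analyze cohort/ --out metrics/            # one metrics row per participant
osari visualize cohort/ --out viz/ --render     # six-panel bundles + figures
```

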