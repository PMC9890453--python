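# erpmix

Single-trial ERP simulation and mixed-model inference with equivalence
tests, built around one question: is the face-specific **N170** generated in
an **all-or-none** or a **graded** fashion?

## The problem

The N170 is a negative ERP component peaking ≈170 ms after stimulus onset at
lateral-posterior electrodes, and is reliably larger for faces. Averaged
N170 amplitude shrinks when face information is degraded (e.g. shorter
exposure), which looks like a graded neural response. But exactly the same
average arises if a *full* N170 is emitted only on the fraction *p* of trials
on which the face is actually perceived:

```
E[amplitude | all trials] = p · (full response)      (averaging dilution)
```

Distinguishing the two stories requires single-trial modeling: conditioning
on the observer's confidence, and testing the remaining duration effect not
only against zero (NHST) but also for *equivalence* to zero (TOST against a
±0.5 μV region). `erpmix` packages the whole chain — a generative simulator
for both hypotheses, epoch arithmetic, data-driven component windows, a
crossed-random-effects mixed model with a parsimonious selection ladder, and
the joint NHST/equivalence decision framework — so the argument can be run,
stress-tested and rebuilt from nothing but a seed.

## What's inside

| module | contents |
|---|---|
| `erpmix.design` | 2×2×2 (Type×Category×Duration) within-subject design: 4 blocks × 320 trials, first half 33 ms only |
| `erpmix.simulate` | `GenerativeParams`, all-or-none vs. graded trial simulation, Gaussian-template epoch rendering, 5-key confidence responses |
| `erpmix.epochs` | trigger-delay arithmetic, linear detrend, baseline correction, single-trial window mean amplitudes |
| `erpmix.windows` | grand averages, peak search, iterative FWHM integration windows constrained to 36–40 ms |
| `erpmix.behavior` | response-allocation tables, P(face \| key), 95%-accuracy participant screening, Confidence/Duration-Confidence/Duration-Half factors |
| `erpmix.lmm` | `SingleTrialLMM` → `LMMResults`: crossed participant/stimulus random effects, selection ladder, emmeans, pairwise and interaction contrasts |
| `erpmix.equivalence` | NHST, TOST against [−0.5, 0.5] μV, Bonferroni families, the 6(+1)-scenario classifier |
| `erpmix.pipeline` | end-to-end runs, the three-analysis sequence, the all-or-none vs. graded discrimination experiment |
| `erpmix.cli` | `erpmix simulate / windows / amplitudes / behavior / fit / contrast / report / discriminate` |

## Worked example

```python
from erpmix.pipeline import (default_config, simulate_dataset, preprocess,
                             identify_windows, extract_amplitudes, key_contrasts)
import erpmix.behavior as bhv

cfg = default_config("all_or_none", seed=1)      # 8 participants, scaled design
design, trials, epochs = simulate_dataset(cfg)
epochs = preprocess(epochs)                      # detrend + baseline
trials = bhv.derive_factors(trials)
retained, _ = bhv.screen_participants(bhv.key1_accuracy(trials))
# ... subset epochs to retained participants, then:
windows = identify_windows(epochs)
amps = extract_amplitudes(epochs, {"N170": windows["N170"]})
for name, c in key_contrasts(amps, cfg).items():
    print(name, c.b, c.se, c.p_nhst, c.p_tost, c.scenario.id)
```

Output (seed 1):

```
retained 7/8 participants
N170 window: 155.0-191.7 ms (width 36.7 ms, f=0.50)
all_trials_duration        b=+2.24 uV  SE=0.15  p_nhst=1.27e-43  p_tost=1      -> S1
high_confidence_duration   b=+0.47 uV  SE=0.10  p_nhst=4.51e-06  p_tost=0.382  -> S1
within_half2_duration      b=+0.09 uV  SE=0.14  p_nhst=0.519  p_tost=0.00225   -> S3
```

Read bottom-up: averaged over all trials the 33 ms N170 looks 2.2 μV weaker
than the 216 ms one (scenario S1, a clear duration effect); restricted to
high-confidence trials a smaller effect survives (driven by the
half-of-experiment gain, not by grading); but *within the second half*,
where the full response is constant, the duration effect is statistically
equivalent to zero (S3) — the graded appearance was averaging dilution. Run
the same three lines with `default_config("graded", seed=1)` and the last
contrast flips to S1 with b ≈ +2 μV: the chain cleanly separates the two
generative mechanisms.

The same pipeline is scriptable from the shell:

```bash
erpmix report --preset all_or_none --seed 1 --out report/
erpmix discriminate --replicates 5 --seed 1 --out discrimination.tsv
```

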