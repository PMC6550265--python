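# thermowrist

Statistical analysis and classification for wrist-worn position-tracking
sensors that combine four thermopiles with a proximity sensor and two
orientation (IMU) channels. The scientific question the package addresses:
when a wrist device tries to tell **where on the head** the wearer's hand
is — relevant to monitoring body-focused repetitive behaviors such as hair
pulling, skin picking and nail biting — do the thermal channels add
information beyond proximity and orientation alone?

It is written for researchers evaluating sensor complements for wearable
behavior monitoring: it provides the full analysis pipeline plus a
synthetic cohort generator with the study's structure (six head targets
and an off-body recording per participant, ~15 s segments at an irregular
5–7 Hz, dual-rater on-target masking), so every method is runnable and
testable without any recordings.

## What it computes

**Discriminability distance.** Per participant and per pair of head
targets *(A, B)*, with segment samples z-scaled globally per channel and
reduced to per-channel medians *m̃*:

d(A, B) = ‖ m̃_A − m̃_B ‖₂ over a channel subset (proximity+IMU, or all
seven channels).

A permutation baseline re-partitions the pooled samples of the two
segments 1,000 times; across participants, Wilcoxon signed-rank tests
compare (i) observed vs. null-median distance per subset and (ii) the
distance without vs. with thermal channels, Bonferroni-corrected over the
15 pairs, with the robust paired effect size median(Δ)/MAD(Δ) (MAD
unscaled). Distances over nested subsets obey d_with² = d_no² +
d_thermal², so the without-vs-with comparison is supplemented by a
null-calibrated *thermal-gain* test (per-participant permutation quantiles
of the thermal-only distance tested against ½) — see `docs/methods.md`.

**Per-target classification.** One-vs-rest binary classifiers over short
sliding windows of z-scaled sequences, using a compact two-layer LSTM (50
units each, dropout 0.20, sigmoid output) implemented in numpy and exposed
as a scikit-learn style estimator (`LSTMBinaryClassifier`, with
`fit`/`predict_proba`/`get_params`). Evaluation reports AUROC
(Mann–Whitney, ties ½) and confusion matrices per participant
(median ± MAD across the cohort), both per-participant (25% stratified
hold-out) and leave-one-participant-out.

## Worked example

```python
import thermowrist as tw

ds = tw.z_scale(tw.generate_cohort(tw.default_config(n_participants=12, seed=42)))
res = tw.run_discriminability(ds, n_shuffles=1000, seed=1)
cols = ["pair_a", "pair_b", "dist_no_thermal_median", "dist_with_thermal_median",
        "p_no_vs_with_bonf", "p_thermal_gain_bonf", "effect_size"]
print(res.rows[cols].round(4).head(6).to_string(index=False))
```

```
pair_a    pair_b  dist_no_thermal_median  dist_with_thermal_median  p_no_vs_with_bonf  p_thermal_gain_bonf  effect_size
 mouth      nose                  0.3628                    0.8917             0.0073               0.0073      11.6434
 mouth     cheek                  0.5608                    1.4994             0.0073               0.0073      26.2010
 mouth   eyebrow                  0.8508                    1.9060             0.0073               0.0073      23.5544
 mouth  top-head                  2.1662                    3.0459             0.0073               0.0073      48.7614
 mouth back-head                  2.2901                    3.1945             0.0073               0.0073      51.4096
  nose     cheek                  0.3264                    1.0833             0.0073               0.0073      16.7713
```

Each row is one target pair: the cohort median discriminability distance
without and with the thermal channels (nose–cheek is the most confusable
pair without thermal, 0.33, and separates to 1.08 with it), the
Bonferroni-corrected p for the paired without-vs-with comparison, the
calibrated thermal-gain p, and the effect size (positive: thermal
increases the distance). With 12 participants the exact signed-rank
two-sided p-value cannot fall below 2/2¹² ≈ 4.9·10⁻⁴, i.e. 0.0073 after
the ×15 correction — the floor every pair reaches here.

```python
r = tw.evaluate_per_participant(ds, "nose", tw.WITH_THERMAL, epochs=5, seed=0)
s = tw.summarize(r)
print(f"nose, with-thermal: AUROC median {s['auroc_median']:.3f} "
      f"± {s['auroc_mad']:.3f} across {s['n_participants']} participants")
```

```
nose, with-thermal: AUROC median 0.983 ± 0.011 across 12 participants
nose, no-thermal:   AUROC median 0.866 ± 0.033 across 12 participants
```

Detecting "hand at the nose" is near-ceiling with the thermal channels and
markedly harder without them, because the generator (like the physics)
gives nose, cheek and eyebrow nearly identical proximity/orientation
signatures.

The same stages are available from a shell:

```bash
thermowrist simulate --out cohort.csv --seed 0
thermowrist discriminate --in cohort.csv --shuffles 1000 --seed 1 --out table1.csv
thermowrist classify --in cohort.csv --mode per-participant --seed 2 --out report.json
thermowrist run-all --out-dir results/ --seed 0        # all three + manifest
```

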