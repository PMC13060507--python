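# fluctex

Quantitative resting-state EEG features of the dominant rhythm, with the
statistical harness used to relate them to **cognitive fluctuations (CF)
in Lewy body disease** — plus a synthetic-EEG cohort generator so the
entire pipeline can be exercised and validated without clinical data.

Cognitive fluctuations — spontaneous, transient changes in attention and
alertness — are a core feature of Lewy body dementia but are hard to rate
objectively in clinic. A well-replicated electrophysiological correlate is
*slowing of the dominant EEG rhythm*: the eyes-closed posterior alpha
rhythm (8–12 Hz) gives way to pre-alpha (6–7.5 Hz) and theta activity.
`fluctex` implements the feature set that captures this pattern and the
analysis plan that evaluates it as a biomarker, for researchers in
clinical neurophysiology and EEG biomarker development.

## Features extracted

From an eyes-closed recording (EDF, 10–20 montage, nominally 256 Hz),
band-pass filtered 3–14 Hz and cut into 2-second epochs (90 epochs from a
3-minute record), per channel:

- **DF** — dominant frequency: the 0.5 Hz bin of maximum FFT power within
  3–14 Hz, per epoch; subject value is the epoch mean.
- **DFV** — dominant-frequency variability: sample standard deviation of
  DF across epochs.
- **DFP** — dominant-frequency prevalence: percentage of epochs whose DF
  falls in each band of the scheme
  delta ≤ 4.0, theta 4.5–5.5, pre-alpha 6.0–7.5, alpha 8.0–12.0,
  beta > 12.0 Hz (prevalences sum to 100%).
- **IAF** — individual alpha peak frequency: per-epoch spectral peak
  restricted to 8–12 Hz, averaged over epochs.

Channel values are averaged over anterior (Fp1, Fp2, Fz, F3, F4, F7, F8),
temporal (T3, T4, T5, T6) and posterior (Pz, P3, P4, O1, O2) regions and
globally, giving 7 features × 4 derivations = **28 candidate features**
per subject.

## Analysis layer

- Two-group comparison of every feature: Mann–Whitney U (exact for small
  tie-free samples), medians with IQR, signed effect size r = Z/√N, and
  Benjamini–Hochberg FDR over the joint 28-test family.
- Per-feature logistic regression adjusted for age, sex and MoCA
  (odds ratio per raw unit with Wald 95% CI).
- Spearman-correlation pruning, elastic-net logistic regression
  (L1/L2 mix 0.5, penalty chosen by stratified cross-validated AUC),
  forward selection under AIC, and ROC/AUC reporting.

## Worked example

```python
import fluctex as fx

# simulate the default two-group cohort and extract features
spec = fx.CohortSpec(n_cf=29, n_non_cf=24, seed=1)
pairs, meta = fx.synth_cohort(spec)
table = fx.cohort_feature_table(pairs)

report = fx.compare_groups(table)          # reference group: non_cf
row = report.table.set_index("column").loc["global_dfp_alpha"]
print(f"global DFP-alpha: CF {row['median_cf']:.1f}% vs non-CF "
      f"{row['median_non_cf']:.1f}%  (q={row['q']:.2g}, r={row['r']:.2f})")

enet = fx.fit_elastic_net(table, seed=1, case="cf")
print(f"elastic net: CV AUC {enet.cv_auc:.2f}, "
      f"{len(enet.selected)} features selected, "
      f"anterior DFP-alpha kept: {'anterior_dfp_alpha' in enet.selected}")
```

Output:

```
global DFP-alpha: CF 10.0% vs non-CF 56.1%  (q=1.9e-09, r=0.85)
elastic net: CV AUC 1.00, 12 features selected, anterior DFP-alpha kept: True
```

The CF-like group spends far fewer epochs with its dominant rhythm in the
alpha band (10% vs 56% of epochs), the difference survives FDR correction
with a large effect size, and the penalized classifier separates the
groups using (among correlated regional variants) anterior DFP-alpha —
the qualitative signature of EEG slowing with cognitive fluctuations.
Synthetic cohorts are cleaner than clinical EEG, so effect sizes and AUCs
run higher than one should expect on real patients.

The same workflow is available from the shell:

```bash
fluctex simulate --preset paperlike --n-cf 29 --n-noncf 24 --seed 1 --out cohort/
fluctex extract  --edf cohort/ --meta cohort/meta.csv --out features.csv
fluctex compare  --features features.csv --out table1.csv
fluctex model    --features features.csv --method enet --case cf --seed 1 --out model.json
```

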