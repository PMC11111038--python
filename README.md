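# affectgcn

Early-warning prediction of depressive-symptom intensification from
experience-sampling (ESM) mood logs — for researchers in computational
psychiatry and psychometric network analysis who want to test whether a
patient's *affect dynamics*, summarized as a small network, predict
short-term worsening, even with a small cohort.

## The method

Each patient logs six feelings — angry, fearful, sad, pleasantness of the
current event, cheerful, relaxed — on a 1–7 Likert scale at ten random
beeps per day for six days. The pipeline:

1. **Affect networks.** Days 1–5 are reduced to a 6×6 signed directed
   matrix per patient by multilevel lag-1 vector autoregression: for each
   outcome feeling *j*,

   *y*ᵢⱼₜ = (*a*ⱼ + *u*ᵢⱼ) + Σₖ (Φⱼₖ + *b*ᵢⱼₖ) · *y*ᵢₖ,ₜ₋₁ + εᵢⱼₜ,

   fitted by REML with a per-subject random intercept and six random
   slopes (diagonal covariance). The subject network is
   **A**ᵢ = Φ + **b**ᵢ (fixed effects + BLUPs); entry (j, k) is the lagged
   effect of feeling *k* on feeling *j*. Lag pairs never cross a day
   boundary.
2. **Labels.** IDF = mean negative-feeling rating on day 6 over the
   day-1–5 mean; label 1 iff IDF > threshold (cases 1/2/3 use 1.0 / 1.2 /
   1.5).
3. **Augmentation.** Each edge is jittered by Uniform(±1% of its absolute
   value); 126 patients × factor 50 → 6,300 graph samples. Labels and
   node features are copied verbatim.
4. **GCN.** Node features (day-1–5 feeling means) propagate over the
   row-normalized signed adjacency with self-loops,
   H⁽ˡ⁺¹⁾ = σ(Â H⁽ˡ⁾ W⁽ˡ⁾ + b⁽ˡ⁾), mean readout, sigmoid head; trained
   with RMSprop (lr 0.001) on binary cross-entropy. Implemented in pure
   NumPy as a scikit-learn estimator (`GCNGraphClassifier`).
5. **Protocol.** (re-augment → 5-fold CV → one confusion matrix) × 150
   repetitions; accuracy and F1 are the arithmetic means over
   repetitions. `split_mode="pooled"` reproduces the reference protocol
   (replicates of one patient may sit in both train and test folds);
   `split_mode="grouped"` keeps each patient's replicates in one fold and
   is the honest generalization estimate.

A seeded synthetic-cohort generator (`CohortSpec` / `generate_cohort`)
emulates the sampling design, with controllable subject heterogeneity and
a plantable "prone" subpopulation, so the whole pipeline is testable
without any real patient data. See `docs/methods.md` for models,
assumptions and limitations.

## Worked example

```python
import affectgcn as ag

spec = ag.CohortSpec(
    n_patients=40, seed=7,
    prone_fraction=0.4, prone_baseline_shift=1.0,
    prone_autocorr_shift=0.2, day6_negative_shift=1.5,
)
panel = ag.generate_cohort(spec)                      # long-format ESM log
samples, labels = ag.samples_from_panel(panel, ag.CASES[2])  # IDF > 1.2

protocol = ag.EvalProtocol(
    k=5, repeats=5, seed=1,
    augment=ag.AugmentConfig(factor=10, seed=0),
    gcn=dict(epochs=100, learning_rate=0.01),
)
for mode in ("pooled", "grouped"):
    protocol.split_mode = mode
    res = ag.run_protocol(samples, protocol)
    print(f"{mode:>7}: accuracy {res.mean_accuracy:.1f}% (sd {res.sd_accuracy:.1f}), "
          f"F1 {res.mean_f1:.3f}")
```

prints

```
patients: 40, labeled 1: 13 (32.5%)
 pooled: accuracy 76.8% (sd 4.7), F1 0.525
grouped: accuracy 71.5% (sd 5.8), F1 0.376
```

Here 40 synthetic patients (40% "prone": tonically elevated negative
affect, a more self-sustaining negative-affect loop, and a day-6 negative
shift) are fitted, labeled at IDF > 1.2 (32.5% positive), augmented 10×
and evaluated over 5 repetitions. Both splits beat the 67.5%
majority-class baseline; the pooled score is higher than the grouped one
because ±1% replicates of training patients appear in pooled test folds —
quote grouped numbers when you mean generalization.

The same pipeline is scriptable stage by stage:

```bash
affectgcn simulate --out panel.csv
affectgcn networks --panel panel.csv --out networks.json
affectgcn label    --panel panel.csv --case 2 --out labels.csv
affectgcn augment  --networks networks.json --labels labels.csv \
                   --factor 50 --seed 0 --out graphs.jsonl
affectgcn evaluate --config run.yaml --out results/
```

Every stage writes a `provenance.json` (config hash, seed, version) next
to its outputs; identical configs reproduce results byte-for-byte.

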