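# ddisyn

Predicting adverse drug reactions (ADRs) caused by **synergistic
drug–drug interactions (DDIs)** from drug–protein interaction profiles.

Most ADR surveillance concerns single drugs, but co-administered drugs
can trigger reactions that neither drug causes alone. `ddisyn`
implements a scoring approach for such pairs, aimed at
pharmacovigilance and drug-safety researchers who have (a) chemical–
protein interaction data (STITCH-style tables) and (b) pair–ADR
association reports (TWOSIDES-style tables), and want ranked,
calibrated predictions for untested drug combinations.

## The model

Each drug *d* is a binary profile **ĝ**(*d*) over (protein, category)
features — four bits per protein for binding, inhibition, activation,
and catalysis, set when an interaction of at least medium confidence
(≥ 0.40) with a human protein is on record. A drug pair's profile
**ĝ**(*d_i d_j*) is the element-wise logical OR of its constituents.

For an ADR Φ with M positive pairs among N training pairs, the weight
of feature α is the Laplacian-corrected log-odds against the baseline
rate M/N:

    w_α = log[(N_A(α) + 1) / (N_B(α) + N/M)] − log[M/N]

where N_B(α) pairs carry bit α and N_A(α) of those are positive. The
correction adds K = N/M virtual samples at the baseline rate, so a
feature observed once in a single positive pair is not credited with a
100% probability; an unobserved feature (N_B = 0) gets weight exactly 0.

A profile's score is S(Φ, d) = Σ_α g_α(d)·w_α, and the synergy score of
a pair is

    DDI(Φ, d_i d_j) = S(Φ, ĝ(d_i d_j)) − max[S(Φ, d_i), S(Φ, d_j)]

A pair is called positive when DDI > 0: the combined profile must beat
the stronger of the two drugs alone, which is exactly what identical
profiles can never do. Scores are normalized to a 0–100 scale by the
model's maximum training-universe DDI score, and thresholds on that
scale are calibrated by cross-validation to reach target positive
predictive values (PPV = TP/(TP+FP)).

Because real pair–ADR reports are noisy, the package also ships the
evaluation protocol: stratified 10-fold cross-validation, a
minimum-positive-sample gate (≥ 50 pairs), and three robustness designs
that vary the training positive fraction (type I) and plant false
negatives (type II) or false positives (type III) in the training set.
A synthetic-data module generates worlds with planted causal rules —
pairs of proteins whose joint coverage by two drugs (but by neither
alone) induces an ADR — so the whole pipeline is testable without any
external downloads.

## Worked example

```python
import ddisyn as d

rules = d.synthetic.default_rules(n_rules=1, n_proteins=300)
world = d.generate_world(d.WorldConfig(n_drugs=200, n_proteins=300,
                                       causal_rules=rules, seed=42))
adr = world.rules[0].adr_code
positives = world.positives(adr)
print(f"ADR {adr}: {len(positives)} positive pairs "
      f"among {len(world.universe)} candidate pairs")

model = d.scoring.fit_adr_model(
    world.drugs, world.universe.pair_matrix(), positives,
    (world.universe.i_idx, world.universe.j_idx), adr_code=adr)

a, b = sorted(positives)[0].split("|")
score = d.ddi_score(model, world.drugs.row(a), world.drugs.row(b))
print(f"pair {a}+{b}: S_i={score.s_i:.2f} S_j={score.s_j:.2f} "
      f"S_pair={score.s_pair:.2f} DDI={score.ddi:.2f} "
      f"normalized={score.ddi_normalized:.1f}")

cv = d.kfold_cv(world.universe, positives, k=10, seed=42)
p = cv.pooled
print(f"10-fold CV: AUC={p.auc:.3f} accuracy={p.accuracy:.3f} "
      f"sensitivity={p.sensitivity:.3f} specificity={p.specificity:.3f} "
      f"PPV={p.ppv:.3f}")
```

prints

```
ADR C0000000: 1056 positive pairs among 19900 candidate pairs
pair D0000+D0001: S_i=13.82 S_j=3.50 S_pair=17.32 DDI=3.50 normalized=25.3
10-fold CV: AUC=0.980 accuracy=0.949 sensitivity=1.000 specificity=0.946 PPV=0.508
```

The pair D0000+D0001 jointly covers the planted causal features, so its
combined profile out-scores either drug alone (DDI = 3.50 > 0, a
positive call at 25.3 on the normalized scale). Cross-validated AUC of
0.98 on this noise-free world reflects the planted separability; the
PPV of 0.51 against a 5.3% positive base rate is a ~9.6-fold
enrichment.

## Command line

The `ddisyn` console script mirrors the library:

```
ddisyn simulate --outdir out            # synthetic world + robustness grid
ddisyn build-profiles --interactions out/interactions.tsv --outdir out
ddisyn train     --profiles out/profiles.tsv --labels out/pair_labels.csv --outdir out
ddisyn evaluate  --profiles out/profiles.tsv --labels out/pair_labels.csv --outdir out
ddisyn calibrate --profiles out/profiles.tsv --labels out/pair_labels.csv --outdir out
ddisyn predict   --profiles out/profiles.tsv --models out --out predictions.csv
```

All commands take `--config config.yaml` with flag overrides, write
their effective configuration next to their outputs, and are
byte-for-byte reproducible under a fixed seed.

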