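# Methods

## Model

A drug's pharmacology is summarised as a binary interaction profile
over (protein, category) features, with four categories per protein:
binding (B), inhibition (I), activation (A), catalysis (C), in that
fixed slot order. Profiles are built from chemical–protein interaction
records carrying a combined confidence in [0, 1]; when a table reports
per-source confidences c_n instead, they are combined as
1 − Π(1 − c_n), the independent-evidence (noisy-OR) rule. Records are
retained when confidence ≥ 0.40 (boundary inclusive — the filter
removes scores *below* the medium-confidence level), the protein is
human, and the category is one of the four above. Drugs left with no
retained interaction cannot be modelled and are excluded with an
explicit warning. All-zero feature columns are pruned after encoding;
pruning provably changes no score, since a column that is zero in every
row contributes nothing to any dot product.

A drug *pair* profile is the bitwise OR of the two drug profiles: the
pair interacts with the union of its constituents' targets. Pairs are
unordered and canonicalized as (min id, max id).

For one ADR, the training universe is every profiled drug pair; the M
pairs reported for the ADR are positives and the remaining N − M pairs
are "baseline" (not verified negatives — unreported positives are
expected, but rare relative to the baseline mass). Each feature α gets
the Laplacian-corrected weight

    w_α = ln[(N_A(α) + 1) / (N_B(α) + N/M)] − ln[M/N],

i.e. the log-ratio of the corrected conditional positive rate to the
baseline rate, after adding K = N/M virtual observations at baseline.
K is kept as an exact real, never rounded. Properties that matter:

* the corrected estimate (N_A+1)/(N_B+K) always lies in (0, 1];
* N_B = 0 yields w = 0 in the limit, and is set to 0 exactly in code —
  features unseen in training contribute nothing at prediction time;
* the raw estimate N_A/N_B would assign probability 1 to a feature
  observed once in a positive pair; the correction pulls such
  under-sampled features toward baseline.

Scores are sums of weights over set bits. The synergy (DDI) score of a
pair is S(pair) − max(S_i, S_j), computed with the *same* pair-trained
weights for both the pair profile and the single-drug profiles, so the
three scores share one scale (the subtraction is meaningless
otherwise; this is the one place where an alternative — single-drug-
trained weights for the single-drug scores — was conceivable, and it
was rejected for that reason). A pair is positive when DDI strictly
exceeds the threshold; the default threshold 0 is the lowest value
consistent with requiring the combined profile to beat the stronger
constituent. Identical profiles give DDI = 0 (never positive), and a
pair whose second drug's bits are a subset of the first's can never be
positive — synergy requires new bits.

Natural logarithms are used throughout. Any other base multiplies all
weights by one positive constant, which preserves score rankings, AUC,
and the threshold-0 classification; the choice is presentational, and a
test asserts the rescaling property.

Vectorised pair scoring uses the inclusion–exclusion identity
S(pair) = S_i + S_j − S(shared bits), verified against per-bit oracles,
so batch prediction never materialises the full pair-profile matrix.

## Evaluation protocol

* **AUC** is the rank-based Mann–Whitney statistic with midrank tie
  correction (ties count one half), checked against an O(n²)
  pair-counting oracle to 1e-12.
* **Confusion metrics** are exact integer counts; PPV is reported as
  *missing*, never 0 or 100%, when no pair is called positive.
* **k-fold CV** (default k = 10) splits positives and baseline pairs
  into k groups independently (stratified); each group is held out
  once. Pooled metrics over all held-out predictions are primary —
  per-fold PPV is unstable when positives are rare — but per-fold
  reports are also emitted.
* **Minimum-positive gate:** models need ≥ 50 positive pairs; below
  that, weight estimates are too noisy to be predictive, and the model
  is skipped with a logged reason.
* **Robustness designs.** Type I trains on a fraction f ∈ {0.1 … 0.9}
  of the positives plus half (rounded down) of the baseline pairs, and
  tests on the remainder. Type II moves half of the test-set positives
  into the training baseline class (planted false negatives); type III
  moves as many test-set baseline pairs as there are true training
  positives into the training positive class (planted false
  positives). Moved samples leave the test set. Each of the (default
  50) repeats redraws the split from a sub-seed derived
  deterministically from the master seed and repeat index, so any
  single repeat is reproducible in isolation, and a design with zero
  movable samples reduces bit-for-bit to type I.
* **PPV calibration.** Held-out DDI scores are normalized per fold by
  that fold's training-universe maximum (×100). For each target PPV
  (10–50%), the calibrated threshold is the smallest grid point
  (0, 10, …, 90 by default) whose pooled cross-validated PPV reaches
  the target; targets no grid point reaches are reported unreachable.
* Normalized prediction-time scores may exceed 100 (a pair scoring
  above everything seen in training) and are reported uncapped.

## Synthetic worlds

The generator emulates the *structure* of the two real inputs, not
their marginal statistics. Drug profiles are i.i.d. Bernoulli bits at
`background_density` (default 0.02, matching the observed ~2% of
proteins a typical drug interacts with — about 53 of 2,637). Causal
rules plant signal:

* **Case I** (true synergy): a rule's required features are split
  across two disjoint carrier subsets (`carrier_fraction` = 0.15 of
  drugs per side), with the complementary features cleared in each
  carrier, so no carrier satisfies the rule alone. A pair is labelled
  positive iff its combined profile covers all required features and
  neither constituent does alone.
* **Case II** (enhancement of an existing effect): the last required
  feature is a weak trigger that labels a pair with probability
  `enhancer_base_rate` (default 0.05) on its own; the full feature set
  labels with certainty. The mechanism is given qualitatively; these
  probabilities are this package's concrete choice to keep the two
  cases learnable and distinguishable.
* Optional **bystander columns** overwrite random background features
  with flip-noised copies of causal columns, emulating pathway
  neighbours of the causal proteins, to check that fitted models spread
  weight over many correlated features rather than one.

Label noise defaults to zero. `inject_label_noise` drops a fraction of
positives (false negatives) and adds `round(fp_rate × positives)`
uniform unlabelled pairs (false positives), which at fp_rate = 1
mirrors the type III design.

What passing on these worlds shows — and does not. Noise-free planted
worlds are (nearly) linearly separable by construction, so
cross-validated AUC ≈ 0.98 and sensitivity ≈ 1 at threshold 0 here say
the estimator recovers planted structure, not that real
pharmacovigilance data would score this well: real reports have heavy
label noise, correlated profiles, confounded co-prescription patterns,
and no guarantee the causal signal is a conjunction of a few protein
bits. One consequence is visible in the threshold sweep: on the
noise-free world the most balanced sensitivity/specificity operating
point sits slightly above threshold 0, because sensitivity has no room
to fall; in noisy regimes, where sensitivity starts well below 1,
threshold 0 is the balanced point. The generator deliberately does not
reproduce degree distributions or reporting-odds statistics of real
databases.

## Problem sizes and numerics

Desk-scale defaults — 200 drugs (19,900 pairs), 300 proteins (1,200
feature bits), one or two rules, 50 robustness repeats — run the whole
suite and the acceptance script in about a minute each on one CPU.
Counts use exact integer arithmetic; weights and scores are float64;
the only tolerance in the method itself is the strict > 0 positivity
rule. Degenerate cases are signalled, not silently patched: fitting
with zero positives raises, normalizing by a non-positive model
maximum raises, AUC on a single class raises, and an all-zero profile
scores exactly 0.

Model artifacts are JSON with sorted keys (sparse nonzero weights keyed
by `protein:category`, plus N, M, per-feature counts and the
normalization maximum); retraining under the same inputs is
byte-identical, and round-tripping is lossless.

## Known limitations

* Pairwise only; no three-drug combinations.
* No dose, regimen, or patient covariates; a pair's score is a single
  number per ADR.
* Antagonistic interactions are out of scope — reporting data
  under-represents them, and the score construction is one-sided.
* Baseline pairs are presumed negative; the robustness experiments
  quantify, but cannot remove, the effect of that approximation.
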