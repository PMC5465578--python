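"""Synthetic drug-protein interaction worlds with planted causal structure.

The generator emulates the two data sources the pipeline consumes: a
chemical-protein interaction table (drug profiles over protein-category
bits) and a pair-ADR label table.  Labels are produced by planted
protein-requirement rules of two kinds:

* **Case I** — a genuinely synergistic interaction: the ADR occurs only
  when the combined pair profile covers *all* required features while
  neither drug alone does.  The generator splits the required features
  across two disjoint carrier drug subsets, so only cross-subset pairs
  (and chance background pairs) satisfy the rule jointly.
* **Case II** — enhancement of an existing effect: a single weak-trigger
  feature labels a pair with a small baseline probability on its own,
  but co-occurrence with the enhancer feature(s) raises the labelling
  probability to 1.

Optional label noise removes a fraction of true positives (false
negatives) and adds unlabelled pairs as false positives, mimicking the
reporting noise of pharmacovigilance data.  Everything is reproducible
from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ddisyn.profiles import (
    CATEGORY_ORDER,
    FeatureIndex,
    PairUniverse,
    ProfileMatrix,
)


@dataclass(frozen=True)
class CausalRule:
    """A planted protein-requirement rule generating one ADR's labels."""

    required_features: tuple[tuple[str, str], ...]
    adr_code: str
    rule_type: str = "case_I"  # "case_I" or "case_II"

    def __post_init__(self) -> None:
        if not self.required_features:
            raise ValueError("rule needs at least one required feature")
        if self.rule_type not in ("case_I", "case_II"):
            raise ValueError(f"unknown rule type: {self.rule_type!r}")
        if self.rule_type == "case_I" and len(self.required_features) < 2:
            raise ValueError("case_I rules need >= 2 required features")


@dataclass
class WorldConfig:
    """Parameters of a synthetic world.

    ``background_density`` is the per-bit activation probability of the
    i.i.d. background; ``carrier_fraction`` is the fraction of drugs
    assigned to each carrier subset of a rule.  ``bystander_copies``
    duplicates each causal column into that many correlated background
    columns (bits flipped at ``bystander_flip_rate``) to emulate
    pathway-mates of the causal proteins.
    """

    n_drugs: int = 200
    n_proteins: int = 300
    background_density: float = 0.02
    causal_rules: list[CausalRule] = field(default_factory=list)
    label_fp_rate: float = 0.0
    label_fn_rate: float = 0.0
    seed: int = 0
    carrier_fraction: float = 0.15
    enhancer_base_rate: float = 0.05
    bystander_copies: int = 0
    bystander_flip_rate: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.background_density < 1.0:
            raise ValueError("background_density must lie in (0, 1)")
        if not (0.0 <= self.label_fp_rate < 1.0 and 0.0 <= self.label_fn_rate < 1.0):
            raise ValueError("label noise rates must lie in [0, 1)")
        for rule in self.causal_rules:
            for protein, category in rule.required_features:
                if category not in CATEGORY_ORDER:
                    raise ValueError(f"unknown category {category!r} in rule")


def default_rules(
    n_rules: int = 2, n_proteins: int = 300, features_per_rule: int = 2
) -> list[CausalRule]:
    """Case-I rules over the first proteins, one ADR code per rule."""
    rules = []
    for r in range(n_rules):
        feats = tuple(
            (_protein_name(r * features_per_rule + f, n_proteins), "binding")
            for f in range(features_per_rule)
        )
        rules.append(CausalRule(feats, adr_code=f"C{r:07d}", rule_type="case_I"))
    return rules


def _protein_name(i: int, n_proteins: int) -> str:
    width = len(str(n_proteins - 1))
    return f"P{i:0{width}d}"


@dataclass
class SyntheticWorld:
    """Generated drug profiles, pair universe, labels, and ground truth."""

    config: WorldConfig
    drugs: ProfileMatrix
    universe: PairUniverse
    labels: dict[str, set[str]]          # adr_code -> positive pair ids
    true_labels: dict[str, set[str]]     # pre-noise labels
    rules: list[CausalRule]
    carrier_sets: dict[str, tuple[list[str], list[str]]]

    def positives(self, adr_code: str) -> set[str]:
        return self.labels[adr_code]

    # -- export in the dialects the real readers consume --------------------

    def interaction_frame(self, rng: np.random.Generator | None = None) -> pd.DataFrame:
        """STITCH-dialect interaction table for the world's set bits.

        Confidences are sampled uniformly from [0.40, 1.0) — all at or
        above the medium-confidence cutoff, so reading the table back
        reproduces the profile matrix.
        """
        if rng is None:
            rng = np.random.default_rng(self.config.seed + 1)
        rows_idx, cols_idx = np.nonzero(self.drugs.matrix)
        feats = self.drugs.index.features
        records = {
            "chemical": [self.drugs.row_ids[i] for i in rows_idx],
            "protein": [f"9606.{feats[j][0]}" for j in cols_idx],
            "mode": [feats[j][1] for j in cols_idx],
            "combined_score": np.round(
                0.40 + 0.60 * rng.random(len(rows_idx)), 3
            ),
        }
        return pd.DataFrame(records)

    def label_frame(self) -> pd.DataFrame:
        """TWOSIDES-dialect pair-ADR association table."""
        rows = []
        for adr, pairs in sorted(self.labels.items()):
            for pid in sorted(pairs):
                d1, d2 = pid.split("|")
                rows.append((d1, d2, adr))
        return pd.DataFrame(rows, columns=["drug_1", "drug_2", "adr_code"])

    def to_files(self, interactions_path, labels_path) -> None:
        self.interaction_frame().to_csv(interactions_path, sep="\t", index=False)
        self.label_frame().to_csv(labels_path, index=False)


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Draw a world from the config; reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    rules = config.causal_rules or default_rules(n_proteins=config.n_proteins)

    proteins = sorted(_protein_name(i, config.n_proteins) for i in range(config.n_proteins))
    index = FeatureIndex([(p, c) for p in proteins for c in CATEGORY_ORDER])
    n_features = len(index)

    drug_ids = [f"D{i:04d}" for i in range(config.n_drugs)]
    matrix = rng.random((config.n_drugs, n_features)) < config.background_density

    n_carriers = max(1, int(round(config.carrier_fraction * config.n_drugs)))
    carrier_sets: dict[str, tuple[list[str], list[str]]] = {}
    for rule in rules:
        cols = np.array(
            [index.position(p, c) for p, c in rule.required_features], dtype=np.intp
        )
        if 2 * n_carriers > config.n_drugs:
            raise ValueError("carrier_fraction too large for the number of drugs")
        chosen = rng.choice(config.n_drugs, size=2 * n_carriers, replace=False)
        side_a, side_b = chosen[:n_carriers], chosen[n_carriers:]
        # Split the required features across the two carrier subsets so
        # neither side alone can satisfy a case-I rule.
        half = max(1, len(cols) // 2)
        cols_a, cols_b = cols[:half], cols[half:]
        if rule.rule_type == "case_II":
            # enhancer feature(s) on side A, the weak trigger on side B
            cols_a, cols_b = cols[:-1], cols[-1:]
        matrix[np.ix_(side_a, cols_a)] = True
        matrix[np.ix_(side_a, cols_b)] = False
        matrix[np.ix_(side_b, cols_b)] = True
        matrix[np.ix_(side_b, cols_a)] = False
        carrier_sets[rule.adr_code] = (
            [drug_ids[i] for i in side_a],
            [drug_ids[i] for i in side_b],
        )

    if config.bystander_copies > 0:
        _plant_bystanders(matrix, index, rules, config, rng)

    drugs = ProfileMatrix(drug_ids, index, matrix)
    universe = PairUniverse.all_pairs(drugs)

    true_labels: dict[str, set[str]] = {}
    for rule in rules:
        true_labels[rule.adr_code] = _rule_labels(rule, universe, rng, config)

    labels = {
        adr: inject_label_noise(
            pos,
            config.label_fp_rate,
            config.label_fn_rate,
            universe.pair_ids,
            seed=int(rng.integers(2**31)),
        )
        if (config.label_fp_rate or config.label_fn_rate)
        else set(pos)
        for adr, pos in true_labels.items()
    }

    return SyntheticWorld(
        config=config,
        drugs=drugs,
        universe=universe,
        labels=labels,
        true_labels=true_labels,
        rules=rules,
        carrier_sets=carrier_sets,
    )


def _plant_bystanders(
    matrix: np.ndarray,
    index: FeatureIndex,
    rules: Sequence[CausalRule],
    config: WorldConfig,
    rng: np.random.Generator,
) -> None:
    """Overwrite random non-causal columns with noisy copies of causal ones."""
    causal_cols = sorted(
        {
            index.position(p, c)
            for rule in rules
            for p, c in rule.required_features
        }
    )
    free = np.setdiff1d(np.arange(matrix.shape[1]), causal_cols)
    need = len(causal_cols) * config.bystander_copies
    if need > len(free):
        raise ValueError("not enough non-causal columns for bystander copies")
    targets = rng.choice(free, size=need, replace=False)
    t = 0
    for col in causal_cols:
        for _ in range(config.bystander_copies):
            flips = rng.random(matrix.shape[0]) < config.bystander_flip_rate
            matrix[:, targets[t]] = matrix[:, col] ^ flips
            t += 1


def _rule_labels(
    rule: CausalRule,
    universe: PairUniverse,
    rng: np.random.Generator,
    config: WorldConfig,
) -> set[str]:
    index = universe.drugs.index
    cols = np.array(
        [index.position(p, c) for p, c in rule.required_features], dtype=np.intp
    )
    has = universe.drugs.matrix[:, cols]          # drug x required-feature
    has_i = has[universe.i_idx]
    has_j = has[universe.j_idx]
    combined_all = (has_i | has_j).all(axis=1)
    if rule.rule_type == "case_I":
        # neither drug alone triggers: exclude pairs where one constituent
        # already covers every required feature
        alone_i = has_i.all(axis=1)
        alone_j = has_j.all(axis=1)
        positive = combined_all & ~alone_i & ~alone_j
    else:
        # case II: the weak trigger alone labels at a small base rate; the
        # full feature set labels with certainty
        trigger = has_i[:, -1] | has_j[:, -1]
        weak_only = trigger & ~combined_all
        positive = combined_all | (
            weak_only & (rng.random(len(universe)) < config.enhancer_base_rate)
        )
    ids = universe.pair_ids
    return {ids[k] for k in np.nonzero(positive)[0]}


def inject_label_noise(
    labels: Iterable[str],
    fp_rate: float,
    fn_rate: float,
    universe: Sequence[str],
    seed: int = 0,
) -> set[str]:
    """Remove a fraction of positives and add unlabelled pairs as positives.

    ``fn_rate`` of the input positives are dropped; ``round(fp_rate * n)``
    false positives (n = input positive count) are drawn uniformly from
    the unlabelled part of the universe, disjoint from the survivors.
    """
    if not (0.0 <= fp_rate < 1.0 and 0.0 <= fn_rate < 1.0):
        raise ValueError("noise rates must lie in [0, 1)")
    positives = sorted(set(labels))
    rng = np.random.default_rng(seed)
    n_fn = int(round(fn_rate * len(positives)))
    keep = set(positives)
    if n_fn:
        dropped = rng.choice(len(positives), size=n_fn, replace=False)
        keep -= {positives[i] for i in dropped}
    n_fp = int(round(fp_rate * len(positives)))
    if n_fp:
        candidates = sorted(set(universe) - set(positives))
        if n_fp > len(candidates):
            raise ValueError(
                f"universe too small: need {n_fp} false positives, "
                f"only {len(candidates)} unlabelled pairs available"
            )
        chosen = rng.choice(len(candidates), size=n_fp, replace=False)
        keep |= {candidates[i] for i in chosen}
    return keep


def read_label_csv(path) -> dict[str, set[str]]:
    """Read a pair-ADR association CSV into adr_code -> positive pair ids."""
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"drug_1", "drug_2", "adr_code"}
    if not required.issubset(df.columns):
        raise ValueError(f"label table needs columns {sorted(required)}")
    out: dict[str, set[str]] = {}
    for d1, d2, adr in zip(df["drug_1"], df["drug_2"], df["adr_code"]):
        a, b = (d1, d2) if d1 <= d2 else (d2, d1)
        out.setdefault(str(adr), set()).add(f"{a}|{b}")
    return out
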