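"""Per-ADR weight fitting and synergy scoring.

For one adverse drug reaction (ADR) with M positive drug pairs among N
training pairs, the contribution of feature alpha (one protein-category
bit) is the Laplacian-corrected log-odds against the baseline rate::

    w_alpha = log[(N_A(alpha) + 1) / (N_B(alpha) + N/M)] - log[M/N]

where N_B(alpha) pairs carry the bit and N_A(alpha) of those are positive.
The correction adds K = N/M virtual pairs at the baseline positive rate
M/N, so a bit observed once in a single positive pair is not credited
with a 100% probability, and an unobserved bit (N_B = 0) gets weight 0.

A profile's score S is the sum of the weights of its set bits.  The
synergy (DDI) score of a pair is::

    DDI = S(pair profile) - max(S(drug i), S(drug j))

and must exceed 0 for a synergistic interaction call: the combined
profile has to beat the stronger of the two drugs alone.  Weights are
natural-log; any other base rescales all weights by a positive constant
and leaves rankings and the threshold-0 classification unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ddisyn.profiles import (
    FeatureIndex,
    InteractionProfile,
    ProfileMatrix,
    ProfileError,
    combine_pair,
)


class FitError(ValueError):
    """Model cannot be fit (e.g. no positive training pairs)."""


class NormalizationError(ValueError):
    """Score normalization impossible (non-positive model maximum)."""


@dataclass
class ADRModel:
    """Fitted weight vector and training counts for one ADR."""

    adr_code: str
    index: FeatureIndex
    weights: np.ndarray          # w_alpha, aligned to index
    n_total: int                 # N: training pairs
    n_positive: int              # M: positive training pairs
    n_b: np.ndarray              # N_B(alpha): training pairs with bit alpha set
    n_a: np.ndarray              # N_A(alpha): positive pairs with bit alpha set
    log_base: str = "e"
    model_max: float | None = None  # max DDI score over the training pair universe

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.n_b = np.asarray(self.n_b, dtype=np.int64)
        self.n_a = np.asarray(self.n_a, dtype=np.int64)
        if not 0 < self.n_positive <= self.n_total:
            raise FitError(f"need 0 < M <= N, got M={self.n_positive}, N={self.n_total}")
        if np.any(self.n_a > self.n_b) or np.any(self.n_b > self.n_total):
            raise FitError("feature counts violate 0 <= N_A <= N_B <= N")

    @property
    def baseline(self) -> float:
        """Baseline probability M/N of a random pair being positive."""
        return self.n_positive / self.n_total

    @property
    def k_virtual(self) -> float:
        """Number of virtual samples K = N/M added by the Laplacian correction."""
        return self.n_total / self.n_positive

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        nz = np.nonzero(self.weights)[0]
        names = self.index.feature_names()
        obj = {
            "adr_code": self.adr_code,
            "n_total": int(self.n_total),
            "n_positive": int(self.n_positive),
            "log_base": self.log_base,
            "model_max": self.model_max,
            "features": names,
            "weights": {names[i]: float(self.weights[i]) for i in nz},
            "n_b": {names[i]: int(self.n_b[i]) for i in np.nonzero(self.n_b)[0]},
            "n_a": {names[i]: int(self.n_a[i]) for i in np.nonzero(self.n_a)[0]},
        }
        return json.dumps(obj, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ADRModel":
        obj = json.loads(text)
        index = FeatureIndex.from_names(obj["features"])
        pos = {n: i for i, n in enumerate(obj["features"])}
        weights = np.zeros(len(index))
        n_b = np.zeros(len(index), dtype=np.int64)
        n_a = np.zeros(len(index), dtype=np.int64)
        for name, w in obj["weights"].items():
            weights[pos[name]] = w
        for name, c in obj["n_b"].items():
            n_b[pos[name]] = c
        for name, c in obj["n_a"].items():
            n_a[pos[name]] = c
        return cls(
            adr_code=obj["adr_code"],
            index=index,
            weights=weights,
            n_total=obj["n_total"],
            n_positive=obj["n_positive"],
            n_b=n_b,
            n_a=n_a,
            log_base=obj["log_base"],
            model_max=obj["model_max"],
        )


@dataclass
class PairScore:
    """Scores of one drug pair under one ADR model."""

    pair_id: str
    s_i: float
    s_j: float
    s_pair: float
    ddi: float
    ddi_normalized: float | None = None


def laplace_corrected_weights(
    n_b: np.ndarray, n_a: np.ndarray, n_total: int, n_positive: int
) -> np.ndarray:
    """Weight vector from feature counts; features with N_B = 0 get exactly 0."""
    if n_positive < 1:
        raise FitError("no positive samples: cannot fit weights")
    k = n_total / n_positive  # K = N/M, kept as an exact real
    baseline = n_positive / n_total
    corrected = (n_a + 1.0) / (n_b + k)
    w = np.log(corrected) - np.log(baseline)
    w[n_b == 0] = 0.0  # Laplacian limit: unobserved features are uninformative
    return w


def compute_weights(
    matrix: ProfileMatrix, positives: Iterable[str], adr_code: str = "ADR"
) -> ADRModel:
    """Fit an ADR model from a matrix of *pair* profiles and positive pair ids.

    N and M are the total and positive row counts; N_B and N_A are column
    sums over all and over positive rows.
    """
    positives = set(positives)
    pos_mask = np.fromiter(
        (r in positives for r in matrix.row_ids), dtype=bool, count=matrix.n_rows
    )
    n_total = matrix.n_rows
    n_positive = int(pos_mask.sum())
    if n_positive == 0:
        raise FitError("no positive samples among the training rows")
    n_b = matrix.matrix.sum(axis=0, dtype=np.int64)
    n_a = matrix.matrix[pos_mask].sum(axis=0, dtype=np.int64)
    weights = laplace_corrected_weights(n_b, n_a, n_total, n_positive)
    return ADRModel(
        adr_code=adr_code,
        index=matrix.index,
        weights=weights,
        n_total=n_total,
        n_positive=n_positive,
        n_b=n_b,
        n_a=n_a,
    )


def score_profile(p: InteractionProfile, model: ADRModel) -> float:
    """Total score S = sum of weights over set bits (dot product)."""
    if p.index != model.index:
        raise ProfileError("profile and model use different feature indices")
    return float(p.bits @ model.weights)


def ddi_score(
    model: ADRModel, p_i: InteractionProfile, p_j: InteractionProfile
) -> PairScore:
    """Synergy score of a pair: S(combined) - max(S(i), S(j))."""
    s_i = score_profile(p_i, model)
    s_j = score_profile(p_j, model)
    combined = combine_pair(p_i, p_j)
    s_pair = score_profile(combined, model)
    ddi = s_pair - max(s_i, s_j)
    normalized = None
    if model.model_max is not None and model.model_max > 0:
        normalized = 100.0 * ddi / model.model_max
    return PairScore(combined.drug_or_pair_id, s_i, s_j, s_pair, ddi, normalized)


def normalize_scores(scores: Sequence[float], model_max: float) -> np.ndarray:
    """Map scores to the 0-100 scale: 100 * score / model_max.

    The model maximum (largest DDI score over the training pair universe)
    maps to 100.  Prediction-time scores may exceed 100 and are returned
    uncapped.
    """
    if model_max <= 0:
        raise NormalizationError(
            f"model maximum {model_max} is not positive; model is degenerate"
        )
    return 100.0 * np.asarray(scores, dtype=float) / model_max


def classify(ddi: float, threshold: float = 0.0) -> bool:
    """Positive call iff the DDI score strictly exceeds the threshold."""
    return ddi > threshold


# ---------------------------------------------------------------------------
# Vectorized pair scoring over a drug matrix


def pair_ddi_scores(
    drug_matrix: np.ndarray,
    i_idx: np.ndarray,
    j_idx: np.ndarray,
    weights: np.ndarray,
    chunk: int = 16384,
) -> np.ndarray:
    """DDI scores for many pairs at once, by inclusion-exclusion.

    ``S(pair) = S(i) + S(j) - S(shared)`` with the shared part scored on the
    bitwise AND, so the OR profile never needs to be materialised.  Processed
    in chunks to bound memory.
    """
    drug_matrix = np.asarray(drug_matrix, dtype=bool)
    s_drug = drug_matrix @ weights
    n = len(i_idx)
    out = np.empty(n, dtype=float)
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        bi = drug_matrix[i_idx[sl]]
        bj = drug_matrix[j_idx[sl]]
        s_shared = (bi & bj) @ weights
        s_pair = s_drug[i_idx[sl]] + s_drug[j_idx[sl]] - s_shared
        out[sl] = s_pair - np.maximum(s_drug[i_idx[sl]], s_drug[j_idx[sl]])
    return out


def fit_adr_model(
    drugs: ProfileMatrix,
    pair_matrix: ProfileMatrix,
    positives: Iterable[str],
    pair_index: tuple[np.ndarray, np.ndarray],
    adr_code: str = "ADR",
) -> ADRModel:
    """Fit weights on pair profiles and store the training-universe maximum
    DDI score used for 0-100 normalization."""
    model = compute_weights(pair_matrix, positives, adr_code=adr_code)
    i_idx, j_idx = pair_index
    ddi = pair_ddi_scores(drugs.matrix, i_idx, j_idx, model.weights)
    model.model_max = float(ddi.max()) if len(ddi) else None
    return model
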