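"""Binary drug-protein interaction profiles.

Drugs are represented as bit strings over (protein, category) features.
Each protein occupies a block of four bits — binding (B), inhibition (I),
activation (A), catalysis (C) — and a bit is on when the drug has a
retained interaction of that category with that protein.  A drug *pair*
profile is the element-wise logical OR of the two constituent profiles:
the pair interacts with the union of the proteins its drugs interact with.

Interaction records carry a confidence in [0, 1]; records below the
medium-confidence cutoff (0.40), records for non-human proteins, and
records outside the four retained categories are filtered out before
encoding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Slot order of the four interaction categories inside a protein block.
CATEGORY_ORDER: tuple[str, ...] = ("binding", "inhibition", "activation", "catalysis")

#: All recognised interaction categories ("other" is parsed but never retained).
CATEGORIES: frozenset[str] = frozenset((*CATEGORY_ORDER, "other"))

DEFAULT_MIN_CONFIDENCE = 0.40
DEFAULT_ORGANISM = "9606"  # NCBI taxid for Homo sapiens


class ProfileError(ValueError):
    """Inconsistent profile construction (index mismatch, unknown feature)."""


@dataclass(frozen=True)
class InteractionRecord:
    """One chemical-protein interaction with a combined confidence score."""

    chemical_id: str
    protein_id: str
    organism: str
    category: str
    confidence: float

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown interaction category: {self.category!r}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


class FeatureIndex:
    """Ordered (protein_id, category) feature space for bit-string encoding.

    Proteins are sorted lexicographically; inside each protein block the
    four category slots appear in the fixed order B, I, A, C.  Positions
    are 0-based and contiguous.
    """

    def __init__(self, features: Sequence[tuple[str, str]]):
        self.features: tuple[tuple[str, str], ...] = tuple(
            (str(p), str(c)) for p, c in features
        )
        self.positions: dict[tuple[str, str], int] = {
            f: i for i, f in enumerate(self.features)
        }
        if len(self.positions) != len(self.features):
            raise ProfileError("duplicate features in index")

    def __len__(self) -> int:
        return len(self.features)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, FeatureIndex) and self.features == other.features

    def __hash__(self) -> int:
        return hash(self.features)

    def position(self, protein_id: str, category: str) -> int:
        try:
            return self.positions[(protein_id, category)]
        except KeyError:
            raise ProfileError(
                f"feature ({protein_id!r}, {category!r}) not in index"
            ) from None

    def feature_names(self) -> list[str]:
        """Features as ``protein_id:category`` strings (report/serialization form)."""
        return [f"{p}:{c}" for p, c in self.features]

    @classmethod
    def from_names(cls, names: Iterable[str]) -> "FeatureIndex":
        feats = []
        for name in names:
            protein, _, category = name.rpartition(":")
            feats.append((protein, category))
        return cls(feats)


@dataclass
class InteractionProfile:
    """Binary interaction profile of one drug or one drug pair."""

    drug_or_pair_id: str
    bits: np.ndarray
    index: FeatureIndex

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 1 or len(self.bits) != len(self.index):
            raise ProfileError(
                f"profile length {self.bits.size} != index size {len(self.index)}"
            )

    def popcount(self) -> int:
        return int(self.bits.sum())


@dataclass
class ProfileMatrix:
    """Stack of binary profiles sharing one feature index."""

    row_ids: list[str]
    index: FeatureIndex
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.row_ids = [str(r) for r in self.row_ids]
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if self.matrix.ndim != 2:
            raise ProfileError("profile matrix must be 2-D")
        if self.matrix.shape != (len(self.row_ids), len(self.index)):
            raise ProfileError(
                f"matrix shape {self.matrix.shape} != "
                f"({len(self.row_ids)}, {len(self.index)})"
            )
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ProfileError("duplicate row ids in profile matrix")
        self._row_pos = {r: i for i, r in enumerate(self.row_ids)}

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    def row(self, row_id: str) -> InteractionProfile:
        try:
            i = self._row_pos[row_id]
        except KeyError:
            raise KeyError(f"unknown row id: {row_id!r}") from None
        return InteractionProfile(row_id, self.matrix[i], self.index)

    def row_position(self, row_id: str) -> int:
        return self._row_pos[row_id]


def combine_confidences(per_source: Sequence[float]) -> float:
    """Combine per-source confidences as ``1 - prod(1 - c_n)``.

    The combined confidence of independent evidence sources: certainty from
    any single source absorbs, and adding a source never decreases the
    result.
    """
    values = np.asarray(per_source, dtype=float)
    if values.size == 0:
        raise ValueError("at least one confidence value is required")
    if np.any(values < 0.0) or np.any(values > 1.0):
        raise ValueError("confidence values must lie in [0, 1]")
    return float(1.0 - np.prod(1.0 - values))


def filter_interactions(
    records: Iterable[InteractionRecord],
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
    organism: str = DEFAULT_ORGANISM,
    categories: frozenset[str] | set[str] = frozenset(CATEGORY_ORDER),
) -> list[InteractionRecord]:
    """Keep records at or above ``min_confidence`` (boundary inclusive), of the
    requested organism, and in the retained categories.  Order is preserved."""
    return [
        r
        for r in records
        if r.confidence >= min_confidence
        and r.organism == organism
        and r.category in categories
    ]


def build_feature_index(records: Iterable[InteractionRecord]) -> FeatureIndex:
    """One four-slot block (B, I, A, C) per distinct protein, proteins sorted
    lexicographically.  Records are assumed already filtered."""
    proteins = sorted({r.protein_id for r in records})
    return FeatureIndex(
        [(p, c) for p in proteins for c in CATEGORY_ORDER]
    )


def encode_profile(
    drug_id: str,
    records: Iterable[InteractionRecord],
    index: FeatureIndex,
) -> InteractionProfile:
    """Bit i is 1 iff the drug has a retained record for feature i."""
    bits = np.zeros(len(index), dtype=bool)
    for r in records:
        if r.chemical_id != drug_id:
            continue
        bits[index.position(r.protein_id, r.category)] = True
    return InteractionProfile(drug_id, bits, index)


def encode_profile_matrix(
    records: Sequence[InteractionRecord],
    index: FeatureIndex | None = None,
    drug_ids: Sequence[str] | None = None,
    drop_empty_drugs: bool = True,
) -> ProfileMatrix:
    """Encode drugs into one profile matrix.

    ``drug_ids`` defaults to the drugs appearing in ``records``; passing a
    larger universe (e.g. every drug named in a label table) makes the
    exclusion of drugs without retained interactions explicit.  Such drugs
    have all-zero profiles and are dropped from modelling (with a warning)
    unless ``drop_empty_drugs`` is False.
    """
    if index is None:
        index = build_feature_index(records)
    drugs = sorted(drug_ids) if drug_ids is not None else sorted(
        {r.chemical_id for r in records}
    )
    pos = {d: i for i, d in enumerate(drugs)}
    matrix = np.zeros((len(drugs), len(index)), dtype=bool)
    for r in records:
        if r.chemical_id in pos:
            matrix[pos[r.chemical_id], index.position(r.protein_id, r.category)] = True
    if drop_empty_drugs:
        nonzero = matrix.any(axis=1)
        dropped = [d for d, keep in zip(drugs, nonzero) if not keep]
        if dropped:
            warnings.warn(
                f"excluding {len(dropped)} drug(s) with no retained "
                f"interactions: {', '.join(dropped[:10])}"
                + ("..." if len(dropped) > 10 else ""),
                stacklevel=2,
            )
            drugs = [d for d, keep in zip(drugs, nonzero) if keep]
            matrix = matrix[nonzero]
    return ProfileMatrix(drugs, index, matrix)


def combine_pair(p_i: InteractionProfile, p_j: InteractionProfile) -> InteractionProfile:
    """Pair profile: element-wise logical OR of the two drug profiles."""
    if p_i.index != p_j.index:
        raise ProfileError("profiles use different feature indices")
    pair_id = canonical_pair_id(p_i.drug_or_pair_id, p_j.drug_or_pair_id)
    return InteractionProfile(pair_id, p_i.bits | p_j.bits, p_i.index)


def canonical_pair(drug_i: str, drug_j: str) -> tuple[str, str]:
    """Unordered pair identity: (min_id, max_id)."""
    return (drug_i, drug_j) if drug_i <= drug_j else (drug_j, drug_i)


def canonical_pair_id(drug_i: str, drug_j: str) -> str:
    a, b = canonical_pair(drug_i, drug_j)
    return f"{a}|{b}"


def prune_features(m: ProfileMatrix) -> ProfileMatrix:
    """Drop all-zero feature columns and re-map the index.

    Removed columns carry no information: any row score under any weight
    vector restricted to surviving features is unchanged.
    """
    keep = m.matrix.any(axis=0)
    if keep.all():
        return m
    index = FeatureIndex([f for f, k in zip(m.index.features, keep) if k])
    return ProfileMatrix(list(m.row_ids), index, m.matrix[:, keep])


class PairUniverse:
    """A drug profile matrix together with an enumerated set of drug pairs.

    Holds the index arrays needed to score many pairs at once and lazily
    materialises the pair (OR) profile matrix used for model fitting.
    """

    def __init__(self, drugs: ProfileMatrix, pairs: Sequence[tuple[str, str]]):
        self.drugs = drugs
        self.pairs = [canonical_pair(a, b) for a, b in pairs]
        self.pair_ids = [f"{a}|{b}" for a, b in self.pairs]
        if len(set(self.pair_ids)) != len(self.pair_ids):
            raise ProfileError("duplicate pairs in universe")
        self.i_idx = np.fromiter(
            (drugs.row_position(a) for a, _ in self.pairs), dtype=np.intp
        )
        self.j_idx = np.fromiter(
            (drugs.row_position(b) for _, b in self.pairs), dtype=np.intp
        )
        self._pair_bits: np.ndarray | None = None

    @classmethod
    def all_pairs(cls, drugs: ProfileMatrix) -> "PairUniverse":
        """All n(n-1)/2 unordered pairs of the matrix's drugs."""
        ids = drugs.row_ids
        return cls(drugs, [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))])

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def pair_bits(self) -> np.ndarray:
        """Pair profile bits (logical OR of constituent rows), cached."""
        if self._pair_bits is None:
            self._pair_bits = (
                self.drugs.matrix[self.i_idx] | self.drugs.matrix[self.j_idx]
            )
        return self._pair_bits

    def pair_matrix(self) -> ProfileMatrix:
        return ProfileMatrix(list(self.pair_ids), self.drugs.index, self.pair_bits)


# ---------------------------------------------------------------------------
# Readers / writers


def read_interaction_tsv(
    path,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
    organism: str | None = DEFAULT_ORGANISM,
) -> list[InteractionRecord]:
    """Read a chemical-protein interaction table in the STITCH TSV dialect.

    Expected columns (header required): ``chemical``, ``protein``, a category
    column named ``mode`` or ``category``, and either a single
    ``combined_score`` column or one or more per-source ``score_*`` columns
    (combined here via :func:`combine_confidences`).  Scores on a 0-1000
    integer scale are detected (max > 1) and divided by 1000.  When the
    protein id is formatted ``taxid.protein`` and no ``organism`` column is
    present, the organism is inferred from the prefix.

    Filtering (confidence cutoff, organism, four categories) is applied;
    pass ``organism=None`` to keep all organisms.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    if "chemical" not in df.columns or "protein" not in df.columns:
        raise ValueError("interaction table needs 'chemical' and 'protein' columns")
    cat_col = "mode" if "mode" in df.columns else "category"
    if cat_col not in df.columns:
        raise ValueError("interaction table needs a 'mode' or 'category' column")

    source_cols = [c for c in df.columns if c.startswith("score_")]
    if "combined_score" in df.columns:
        conf = df["combined_score"].astype(float).to_numpy()
    elif source_cols:
        per_source = df[source_cols].astype(float).to_numpy()
        if np.nanmax(per_source, initial=0.0) > 1.0:
            per_source = per_source / 1000.0
        conf = 1.0 - np.prod(1.0 - np.nan_to_num(per_source), axis=1)
    else:
        raise ValueError(
            "interaction table needs 'combined_score' or 'score_*' columns"
        )
    if conf.size and conf.max() > 1.0:
        conf = conf / 1000.0

    if "organism" in df.columns:
        orgs = df["organism"].astype(str)
        proteins = df["protein"].astype(str)
    else:
        split = df["protein"].astype(str).str.split(".", n=1, expand=True)
        if split.shape[1] == 2 and split[1].notna().all():
            orgs, proteins = split[0], split[1]
        else:
            orgs = pd.Series([""] * len(df))
            proteins = df["protein"].astype(str)

    records = [
        InteractionRecord(
            chemical_id=str(chem),
            protein_id=str(prot),
            organism=str(org),
            category=str(cat).strip().lower(),
            confidence=float(c),
        )
        for chem, prot, org, cat, c in zip(
            df["chemical"], proteins, orgs, df[cat_col], conf
        )
        if str(cat).strip().lower() in CATEGORIES
    ]
    if organism is None:
        return [
            r for r in records
            if r.confidence >= min_confidence and r.category in CATEGORY_ORDER
        ]
    return filter_interactions(records, min_confidence=min_confidence, organism=organism)


def write_profile_matrix(m: ProfileMatrix, path) -> None:
    """Write a profile matrix as TSV with ``protein_id:category`` columns."""
    df = pd.DataFrame(
        m.matrix.astype(np.uint8), index=m.row_ids, columns=m.index.feature_names()
    )
    df.index.name = "id"
    df.to_csv(path, sep="\t")


def read_profile_matrix(path) -> ProfileMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    index = FeatureIndex.from_names(df.columns)
    return ProfileMatrix(
        [str(i) for i in df.index], index, df.to_numpy(dtype=bool)
    )
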