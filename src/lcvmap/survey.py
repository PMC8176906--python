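"""Expert-survey aggregation into the landscape conservation value matrix.

The elicitation scheme: each expert rates every land-cover class (7) and
landform class (5) on a 1-5 Likert scale and states, from a pairwise
comparison, how much more important one variable is than the other. The
stated importance multiplies the ratings (x1.75 "Very Important", x1.5
"Important", x1.25 "Merely Important" and "Somewhat Important", x1.0
"Same"). An expert's value for a landscape type is the product of the
weighted land-cover and landform scores; types are averaged across the
panel and the 35 mean products are mapped linearly onto the 1-10 scale
(min-max, so the least valued type scores exactly 1 and the most valued
exactly 10).

A published 7x5 reference matrix obtained with this scheme from a 13-expert
panel ships with the package (:func:`load_reference_matrix`).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateRangeError, InputError
from .legends import LANDCOVER_MATRIX_ORDER, LANDFORM_MATRIX_ORDER

#: Multiplicative importance weights from the pairwise comparison answers.
IMPORTANCE_WEIGHTS: dict[str, float] = {
    "Very Important": 1.75,
    "Important": 1.5,
    "Merely Important": 1.25,
    "Somewhat Important": 1.25,
    "Same": 1.0,
}


@dataclass
class LCVMatrix:
    """A 7x5 land-cover x landform conservation-value table.

    ``table`` has land-cover rows (Barren land ... Wetland) and landform
    columns (Flat land ... Summit). ``normalized`` records whether the
    values have been min-max mapped onto [1, 10].
    """

    table: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        missing_rows = set(LANDCOVER_MATRIX_ORDER) - set(self.table.index)
        missing_cols = set(LANDFORM_MATRIX_ORDER) - set(self.table.columns)
        if missing_rows or missing_cols:
            raise InputError(
                f"matrix labels incomplete: rows missing {sorted(missing_rows)}, "
                f"columns missing {sorted(missing_cols)}"
            )
        self.table = self.table.loc[LANDCOVER_MATRIX_ORDER, LANDFORM_MATRIX_ORDER]

    def value(self, landcover: str, landform: str) -> float:
        return float(self.table.at[landcover, landform])

    @property
    def values(self) -> np.ndarray:
        return self.table.to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.rename_axis("landcover").to_csv(path, float_format="%.6g")
        return path

    @classmethod
    def from_csv(cls, path: str | Path, normalized: bool = True) -> "LCVMatrix":
        table = pd.read_csv(path, index_col=0)
        table.index.name = None
        return cls(table=table, normalized=normalized)


def apply_importance_weight(rating: float, category: str,
                            weights: dict[str, float] | None = None) -> float:
    """Weighted score of a single Likert rating: ``rating x factor``."""
    weights = IMPORTANCE_WEIGHTS if weights is None else weights
    if category not in weights:
        raise ConfigurationError(f"unknown importance category {category!r}")
    if rating < 0:
        raise InputError(f"rating must be >= 0, got {rating}")
    return rating * weights[category]


def score_landscape_types(landform_scores: pd.Series,
                          landcover_scores: pd.Series) -> pd.DataFrame:
    """Raw 7x5 product matrix: entry (i, j) = landcover_i x landform_j."""
    if set(landform_scores.index) != set(LANDFORM_MATRIX_ORDER):
        raise InputError("landform_scores must be indexed by the 5 landform classes")
    if set(landcover_scores.index) != set(LANDCOVER_MATRIX_ORDER):
        raise InputError("landcover_scores must be indexed by the 7 land-cover classes")
    if (landform_scores <= 0).any() or (landcover_scores <= 0).any():
        raise InputError("scores must be > 0")
    lc = landcover_scores.loc[LANDCOVER_MATRIX_ORDER].to_numpy(dtype=float)
    lf = landform_scores.loc[LANDFORM_MATRIX_ORDER].to_numpy(dtype=float)
    return pd.DataFrame(
        np.outer(lc, lf), index=LANDCOVER_MATRIX_ORDER, columns=LANDFORM_MATRIX_ORDER
    )


def rescale_1_10(matrix: pd.DataFrame | LCVMatrix) -> LCVMatrix:
    """Min-max map onto [1, 10]: ``v -> 1 + 9 (v - min) / (max - min)``."""
    table = matrix.table if isinstance(matrix, LCVMatrix) else matrix
    values = table.to_numpy(dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise DegenerateRangeError("cannot rescale a constant matrix")
    scaled = 1.0 + 9.0 * (values - lo) / (hi - lo)
    return LCVMatrix(
        table=pd.DataFrame(scaled, index=table.index, columns=table.columns),
        normalized=True,
    )


def expert_scores(ratings: pd.DataFrame,
                  weights: dict[str, float] | None = None) -> pd.DataFrame:
    """Per-expert importance-weighted item scores from a tidy rating table.

    ``ratings`` needs columns ``expert_id, item, rating, importance``.
    Returns one row per (expert_id, item) with the weighted score.
    """
    required = {"expert_id", "item", "rating", "importance"}
    if not required.issubset(ratings.columns):
        raise InputError(f"ratings table needs columns {sorted(required)}")
    out = ratings.copy()
    out["score"] = [
        apply_importance_weight(r, c, weights)
        for r, c in zip(out["rating"], out["importance"])
    ]
    return out[["expert_id", "item", "score"]]


def expert_matrices(ratings: pd.DataFrame,
                    weights: dict[str, float] | None = None) -> list[pd.DataFrame]:
    """One raw 7x5 product matrix per expert, in expert_id order."""
    scores = expert_scores(ratings, weights)
    matrices = []
    for _, group in scores.groupby("expert_id", sort=True):
        by_item = group.set_index("item")["score"]
        lc = by_item.reindex(LANDCOVER_MATRIX_ORDER)
        lf = by_item.reindex(LANDFORM_MATRIX_ORDER)
        if lc.isna().any() or lf.isna().any():
            raise InputError("each expert must rate all 12 items")
        matrices.append(score_landscape_types(lf, lc))
    return matrices


def aggregate_expert_matrices(per_expert: list[pd.DataFrame],
                              rescale_each: bool = False) -> LCVMatrix:
    """Panel aggregation: cell-wise mean across experts, then one rescale.

    With ``rescale_each=True`` every expert's matrix is rescaled to [1, 10]
    before averaging (a sensitivity variant); the mean is rescaled again
    either way so the result always spans exactly [1, 10].
    """
    if not per_expert:
        raise InputError("need at least one expert matrix")
    first = per_expert[0]
    for m in per_expert[1:]:
        if not (m.index.equals(first.index) and m.columns.equals(first.columns)):
            raise InputError("expert matrices carry mismatched labels")
    if rescale_each:
        per_expert = [rescale_1_10(m).table for m in per_expert]
    mean = sum(per_expert[1:], per_expert[0].copy()) / len(per_expert)
    return rescale_1_10(mean)


def aggregate_survey(ratings: pd.DataFrame,
                     weights: dict[str, float] | None = None,
                     rescale_each: bool = False) -> LCVMatrix:
    """Full path from a tidy rating table to the normalized 7x5 matrix."""
    return aggregate_expert_matrices(expert_matrices(ratings, weights),
                                     rescale_each=rescale_each)


def load_reference_matrix() -> LCVMatrix:
    """The packaged published reference conservation-value matrix."""
    ref = resources.files("lcvmap.data") / "reference_lcv_matrix.csv"
    with resources.as_file(ref) as path:
        return LCVMatrix.from_csv(path, normalized=True)
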