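"""Univariate ANOVA feature selection.

Each feature is tested with a one-way F test across the class groups
(control vs essential tremor); features with p < alpha are retained.
The unbalanced one-way F,

    F = (SSB / (g - 1)) / (SSW / (N - g)),

handles unequal group sizes; p-values come from the F distribution.
No multiple-testing correction is applied: the selection deliberately
uses the raw per-feature threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .linear_features import FeatureMatrix


@dataclass
class SelectionResult:
    """Per-feature F statistic, p-value and keep flag at level alpha."""

    table: pd.DataFrame  # index = feature names; columns F, p, kept
    alpha: float

    @property
    def n_kept(self) -> int:
        return int(self.table["kept"].sum())

    @property
    def kept_features(self) -> list[str]:
        return list(self.table.index[self.table["kept"]])

    def to_csv(self, path) -> None:
        self.table.rename_axis("feature").to_csv(path)


def one_way_f(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised one-way ANOVA over the columns of X.

    Returns (F, p) arrays.  Columns with zero within- and between-group
    variability are assigned F = 0, p = 1 (no evidence of a difference).
    """
    X = np.asarray(X, dtype=float)
    groups = [X[labels == g] for g in np.unique(labels)]
    g = len(groups)
    n_total = X.shape[0]
    grand = X.mean(axis=0)
    ssb = sum(len(gr) * (gr.mean(axis=0) - grand) ** 2 for gr in groups)
    ssw = sum(((gr - gr.mean(axis=0)) ** 2).sum(axis=0) for gr in groups)
    df_b, df_w = g - 1, n_total - g
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df_b) / (ssw / df_w)
    # ssw == 0: either a perfectly separated feature (ssb > 0, F -> inf,
    # p -> 0) or a constant feature (ssb == 0, undefined -> p = 1)
    F = np.where((ssw == 0) & (ssb == 0), 0.0, F)
    p = stats.f.sf(F, df_b, df_w)
    p = np.where((ssw == 0) & (ssb == 0), 1.0, p)
    p = np.where(np.isinf(F), 0.0, p)
    return F, p


def anova_select(
    matrix: FeatureMatrix | pd.DataFrame,
    labels=None,
    alpha: float = 0.05,
) -> SelectionResult:
    """Rank every feature by the one-way F test; keep those with p < alpha."""
    if isinstance(matrix, FeatureMatrix):
        X_df = matrix.X
        labels = matrix.labels.to_numpy() if labels is None else np.asarray(labels)
    else:
        X_df = matrix
        if labels is None:
            raise ValidationError("labels are required when passing a bare DataFrame")
        labels = np.asarray(labels)
    if len(labels) != len(X_df):
        raise ValidationError("labels length does not match matrix rows")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("need at least 2 groups for ANOVA")
    small = uniq[counts < 2]
    if len(small):
        raise ValidationError(f"groups with fewer than 2 rows: {list(small)}")
    X = X_df.to_numpy(dtype=float)
    bad = X_df.columns[~np.all(np.isfinite(X), axis=0)]
    if len(bad):
        raise ValidationError(f"non-finite values in features: {list(bad[:5])}")
    F, p = one_way_f(X, labels)
    table = pd.DataFrame(
        {"F": F, "p": p, "kept": p < alpha}, index=list(X_df.columns)
    )
    return SelectionResult(table=table, alpha=alpha)


def apply_selection(matrix: FeatureMatrix, sel: SelectionResult) -> FeatureMatrix:
    """Column-subset the matrix to the kept features, preserving rows."""
    missing = [f for f in sel.table.index if f not in matrix.X.columns]
    if missing:
        raise ValidationError(
            f"selection computed on different features; missing: {missing[:5]}"
        )
    return matrix.subset(sel.kept_features)
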