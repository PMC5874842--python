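"""Comparison of screening methods by principal component analysis.

Observed miscibility classes (or glass-solution thermal properties, or
ranking concordance scores) are arranged into a method x feature matrix,
mean-centered, scaled to unit variance, and decomposed.  The Euclidean
distance of each method's score vector from the reference (spray-dryer)
row quantifies how closely that method mimics the reference, replacing a
visual reading of the score plot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SKPCA

from .classify import ClassLabel
from .errors import DegenerateMatrixError, ValidationError

#: Ordinal encoding of the miscibility gradient.
CLASS_SCORES: dict[str, float] = {"A": 2.0, "AA": 1.0, "AC": 0.0}

Encoding = Literal["ordinal", "onehot"]


@dataclass(frozen=True)
class FeatureMatrix:
    """Rows = methods (or method x drug units), columns = encoded variables."""

    values: pd.DataFrame
    encoding: str = "ordinal"

    def __post_init__(self) -> None:
        if self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise ValidationError("feature matrix needs at least 2 rows and 2 columns")
        if self.values.isna().any().any():
            raise ValidationError("feature matrix contains missing values")


@dataclass(frozen=True)
class PCAResult:
    """Scores, loadings and explained-variance ratios of a decomposition."""

    scores: pd.DataFrame          # rows x components
    loadings: pd.DataFrame        # columns x components
    explained_variance_ratio: np.ndarray
    n_components: int
    dropped_columns: tuple[str, ...] = ()


def encode_class_matrix(
    campaign: Mapping[tuple[str, str, float, str], ClassLabel],
    encoding: Encoding = "ordinal",
) -> FeatureMatrix:
    """Arrange campaign-level classes into a method x condition matrix.

    ``campaign`` maps ``(drug, polymer, drug_loading, method)`` to a class
    label.  One row per method; one column per (drug, polymer, loading)
    cell (ordinal A=2 > AA=1 > AC=0) or three indicator columns per cell
    (one-hot).  The grid must be complete: every method must report every
    cell, otherwise the missing cells are listed in the error.
    """
    methods = sorted({k[3] for k in campaign})
    cells = sorted({(k[0], k[1], k[2]) for k in campaign})
    missing = [
        f"{d}/{p}@{dl:g}:{m}"
        for (d, p, dl) in cells
        for m in methods
        if (d, p, dl, m) not in campaign
    ]
    if missing:
        raise ValidationError(f"incomplete class grid; missing cells: {', '.join(missing)}")

    if encoding == "ordinal":
        data = {
            f"{d}/{p}@{dl:g}": [CLASS_SCORES[campaign[(d, p, dl, m)]] for m in methods]
            for (d, p, dl) in cells
        }
    elif encoding == "onehot":
        data = {
            f"{d}/{p}@{dl:g}={lab}": [
                1.0 if campaign[(d, p, dl, m)] == lab else 0.0 for m in methods
            ]
            for (d, p, dl) in cells
            for lab in ("A", "AA", "AC")
        }
    else:
        raise ValidationError(f"unknown encoding {encoding!r}")
    frame = pd.DataFrame(data, index=methods)
    return FeatureMatrix(values=frame, encoding=encoding)


def pca(matrix: FeatureMatrix, n_components: int | None = None) -> PCAResult:
    """Standardized principal component analysis of a feature matrix.

    Columns are mean-centered and scaled to unit variance; zero-variance
    columns carry no information and are dropped with a warning.  The sign
    of each component is fixed by making its largest-magnitude loading
    positive, so results are reproducible across linear-algebra backends.
    """
    frame = matrix.values
    if not np.all(np.isfinite(frame.to_numpy())):
        raise ValidationError("feature matrix must be finite")
    std = frame.std(axis=0, ddof=0)
    keep = std > 0
    dropped = tuple(frame.columns[~keep])
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} zero-variance column(s): {', '.join(dropped[:5])}"
            + ("..." if len(dropped) > 5 else ""),
            stacklevel=2,
        )
    frame = frame.loc[:, keep]
    n_rows, n_cols = frame.shape
    if n_cols < 2:
        raise DegenerateMatrixError(
            "fewer than 2 non-degenerate columns; nothing to decompose"
        )
    max_rank = min(n_rows - 1, n_cols)
    if n_components is None:
        n_components = max_rank
    if not 1 <= n_components <= max_rank:
        raise ValidationError(
            f"n_components must be in [1, {max_rank}] for a {n_rows}x{n_cols} matrix"
        )

    z = (frame - frame.mean(axis=0)) / frame.std(axis=0, ddof=0)
    model = _SKPCA(n_components=max_rank, svd_solver="full")
    scores_full = model.fit_transform(z.to_numpy())
    components = model.components_  # (max_rank, n_cols), rows orthonormal
    # deterministic sign: largest-|loading| positive per component
    flip = np.array(
        [np.sign(row[np.argmax(np.abs(row))]) or 1.0 for row in components]
    )
    components = components * flip[:, None]
    scores_full = scores_full * flip[None, :]

    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(
            scores_full[:, :n_components], index=frame.index, columns=comp_names
        ),
        loadings=pd.DataFrame(
            components[:n_components].T, index=frame.columns, columns=comp_names
        ),
        explained_variance_ratio=model.explained_variance_ratio_[:n_components].copy(),
        n_components=n_components,
        dropped_columns=dropped,
    )


def proximity_report(result: PCAResult, reference: str) -> pd.DataFrame:
    """Distance of every row from the reference row in score space.

    Returns a DataFrame indexed by row label with columns ``distance`` and
    ``rank`` (1 = the reference itself at distance 0), sorted ascending --
    a quantitative surrogate for reading relative positions off the score
    plot.
    """
    if reference not in result.scores.index:
        raise ValidationError(f"reference row {reference!r} not present in scores")
    ref = result.scores.loc[reference].to_numpy()
    dist = np.linalg.norm(result.scores.to_numpy() - ref[None, :], axis=1)
    report = pd.DataFrame({"distance": dist}, index=result.scores.index)
    report = report.sort_values("distance", kind="stable")
    report["rank"] = np.arange(1, len(report) + 1)
    return report


def concordance_feature_matrix(
    scores: Mapping[str, Mapping[str, tuple[float, float]]]
) -> FeatureMatrix:
    """Method x (drug f1/f2) matrix from concordance scores.

    ``scores[method][drug] = (f_position, f_identity)``.
    """
    methods = sorted(scores)
    drugs = sorted({d for per in scores.values() for d in per})
    data: dict[str, list[float]] = {}
    for drug in drugs:
        data[f"{drug}:f1"] = [scores[m][drug][0] for m in methods]
        data[f"{drug}:f2"] = [scores[m][drug][1] for m in methods]
    return FeatureMatrix(values=pd.DataFrame(data, index=methods), encoding="concordance")
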