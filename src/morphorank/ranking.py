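"""Cohort ranking: feature standardization, PCA-based parameter selection
and Andrews-curve scoring.

The ranking key is the value of each cell's weighted Andrews curve

    S_j(t) = sum_n F_jn * W_n * cos(2 pi n t + phi_n)

at the angle t* where the across-cell variance of the curves is maximal.
F_jn are the standardized (and, for five descriptors, sign-inverted)
feature values of the selected parameters ranked by |PC1 projection|;
the weights W_n and phases phi_n come from the parameters' correlation-
circle projections onto PC1 and PC2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from morphorank.mask_io import FEATURE_NAMES

__all__ = [
    "FeatureMatrix",
    "SelectionResult",
    "AndrewsRanking",
    "INVERTED_PARAMETERS",
    "prepare_matrix",
    "pca_select",
    "andrews_rank",
]

#: Descriptors whose raw direction runs opposite to the ramification axis;
#: they are negated before standardization so every column increases with
#: morphological complexity.
INVERTED_PARAMETERS = (
    "lacunarity",
    "roundness_factor",
    "convex_hull_radii_ratio",
    "processes_cell_areas_ratio",
    "skeleton_processes_ratio",
)


@dataclass
class FeatureMatrix:
    """A cohort feature table: n_cells rows by named descriptor columns."""

    cell_ids: list[str]
    values: np.ndarray
    group_labels: list[str] | None = None
    columns: tuple[str, ...] = FEATURE_NAMES
    prepared: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape[0] != len(self.cell_ids):
            raise ValueError("row count does not match number of cell ids")
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column count does not match column names")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite values")
        if self.group_labels is not None and len(self.group_labels) != len(self.cell_ids):
            raise ValueError("group_labels length does not match cell ids")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.columns.index(name)]


@dataclass(frozen=True)
class SelectionResult:
    """PCA projections and the ranked, weighted parameter selection.

    ``pc1_projections``/``pc2_projections`` are the correlation-circle
    coordinates of every retained column (loading times sqrt(eigenvalue));
    ``selected`` lists the shortest |PC1|-ranked prefix whose normalized
    cumulative projection reaches the threshold, with weights
    ``W_n = |w_n| / |w_0|`` and phases ``phi_n = arctan(y_n / W_n)``.
    """

    columns: tuple[str, ...]
    eigenvalues: np.ndarray
    pc1_projections: np.ndarray
    pc2_projections: np.ndarray
    ranked_params: tuple[str, ...]
    cumulative_curve: np.ndarray
    threshold: float
    selected: tuple[str, ...]
    weights: np.ndarray
    phases: np.ndarray
    dropped: tuple[str, ...] = ()


@dataclass(frozen=True)
class AndrewsRanking:
    """Sampled Andrews curves, the max-variance angle and the cell order.

    ``theta_star`` is reported in degrees on the sampling grid
    (t = theta/360); ``order`` sorts cell ids by descending score, most
    amoeboid first when ``orientation_flipped`` is applied as recorded.
    """

    cell_ids: tuple[str, ...]
    t_grid: np.ndarray
    curves: np.ndarray
    theta_star: int
    scores: np.ndarray
    order: tuple[str, ...]
    orientation_flipped: bool
    group_labels: tuple[str, ...] | None = None


def prepare_matrix(matrix: FeatureMatrix) -> FeatureMatrix:
    """Invert the five opposite-direction descriptors and z-score columns.

    Inversion is a sign flip of the raw column (reverses its ranking
    direction without distorting spacing); standardization uses the
    population standard deviation.  Zero-variance columns carry no ordering
    information and are dropped with a warning.
    """
    if matrix.n_cells < 3:
        raise ValueError(f"need at least 3 cells, got {matrix.n_cells}")
    values = matrix.values.copy()
    for name in INVERTED_PARAMETERS:
        if name in matrix.columns:
            values[:, matrix.columns.index(name)] *= -1.0

    mean = values.mean(axis=0)
    sd = values.std(axis=0)  # population SD
    keep = sd > 0
    if not keep.any():
        raise ValueError("all feature columns have zero variance")
    if not keep.all():
        dropped = [c for c, k in zip(matrix.columns, keep) if not k]
        warnings.warn(f"dropping zero-variance columns: {dropped}", stacklevel=2)
    standardized = (values[:, keep] - mean[keep]) / sd[keep]
    return FeatureMatrix(
        cell_ids=list(matrix.cell_ids),
        values=standardized,
        group_labels=matrix.group_labels,
        columns=tuple(c for c, k in zip(matrix.columns, keep) if k),
        prepared=True,
    )


def _orient_sign(loading_vector: np.ndarray, anchor_idx: int | None) -> float:
    """Sign making the anchor entry (or the largest-|entry|) non-negative."""
    if anchor_idx is not None:
        ref = loading_vector[anchor_idx]
        if ref != 0:
            return 1.0 if ref > 0 else -1.0
    ref = loading_vector[int(np.argmax(np.abs(loading_vector)))]
    return 1.0 if ref >= 0 else -1.0


def pca_select(matrix: FeatureMatrix, threshold: float = 0.8) -> SelectionResult:
    """Rank parameters by |PC1 projection| and keep a cumulative prefix.

    The PCA is an eigen-decomposition of the correlation structure of the
    prepared matrix (all columns unit variance, so covariance equals
    correlation).  Each parameter's correlation-circle projection onto a
    component is its loading scaled by sqrt(eigenvalue).  Parameters are
    ranked by |PC1 projection|; the selection is the shortest ranked
    prefix whose cumulative |projection| share reaches ``threshold``.

    Eigenvector signs are fixed by orienting PC1 so the circularity
    loading is non-negative and PC2 so its largest-|loading| entry is
    non-negative, which makes weights and phases reproducible.
    """
    if not matrix.prepared:
        raise ValueError("pca_select expects a prepared matrix (see prepare_matrix)")
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    X = matrix.values
    n = X.shape[0]
    corr = (X.T @ X) / n  # population covariance of z-scores = correlation
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]

    anchor = (
        matrix.columns.index("circularity") if "circularity" in matrix.columns else None
    )
    v1 = eigvecs[:, 0] * _orient_sign(eigvecs[:, 0], anchor)
    v2 = eigvecs[:, 1] * _orient_sign(eigvecs[:, 1], None)

    w = v1 * np.sqrt(eigvals[0])  # correlation-circle projections onto PC1
    y = v2 * np.sqrt(eigvals[1])

    rank_idx = np.argsort(-np.abs(w), kind="stable")
    ranked = tuple(matrix.columns[i] for i in rank_idx)
    abs_sorted = np.abs(w)[rank_idx]
    cumulative = np.cumsum(abs_sorted) / abs_sorted.sum()
    n_sel = int(np.searchsorted(cumulative, threshold - 1e-12) + 1)
    n_sel = min(n_sel, len(ranked))

    sel_idx = rank_idx[:n_sel]
    weights = np.abs(w)[sel_idx] / np.abs(w)[sel_idx[0]]
    phases = np.arctan(y[sel_idx] / weights)

    return SelectionResult(
        columns=matrix.columns,
        eigenvalues=eigvals,
        pc1_projections=w,
        pc2_projections=y,
        ranked_params=ranked,
        cumulative_curve=cumulative,
        threshold=float(threshold),
        selected=ranked[:n_sel],
        weights=weights,
        phases=phases,
        dropped=tuple(c for c in FEATURE_NAMES if c not in matrix.columns),
    )


def andrews_curves(
    F: np.ndarray, weights: np.ndarray, phases: np.ndarray, t_grid: np.ndarray
) -> np.ndarray:
    """Evaluate S_j(t) = sum_n F_jn W_n cos(2 pi n t + phi_n) on a grid."""
    n_terms = weights.size
    harmonics = np.arange(1, n_terms + 1)
    # shape (n_terms, n_t)
    basis = np.cos(2.0 * np.pi * harmonics[:, None] * t_grid[None, :] + phases[:, None])
    return (F * weights) @ basis


def andrews_rank(
    matrix: FeatureMatrix, sel: SelectionResult, angle_grid: int = 360
) -> AndrewsRanking:
    """Score and order the cells by their Andrews curves at max variance.

    Curves are sampled at ``angle_grid`` points of t in [0, 1) (degrees by
    default); theta* is the grid point maximizing the across-cell variance,
    ties broken toward the smallest angle.  The score axis is oriented so
    scores correlate positively with the prepared circularity column
    (most amoeboid first); whether a flip was applied is recorded.
    """
    if not matrix.prepared:
        raise ValueError("andrews_rank expects a prepared matrix")
    if matrix.n_cells < 2:
        raise ValueError("ranking requires >= 2 cells")
    if not sel.selected:
        raise ValueError("no parameters selected")
    t_grid = np.arange(angle_grid, dtype=float) / angle_grid
    sel_idx = [matrix.columns.index(name) for name in sel.selected]
    F = matrix.values[:, sel_idx]
    curves = andrews_curves(F, sel.weights, sel.phases, t_grid)

    variance = curves.var(axis=0)
    if not variance.any():
        raise ValueError("all cells identical: curve variance is zero everywhere")
    theta_star = int(np.argmax(variance))  # argmax takes the first (smallest) tie
    scores = curves[:, theta_star].copy()

    flipped = False
    if "circularity" in matrix.columns:
        circ = matrix.column("circularity")
        corr = float(np.dot(scores - scores.mean(), circ - circ.mean()))
        if corr < 0:
            scores = -scores
            flipped = True

    order_idx = np.argsort(-scores, kind="stable")
    return AndrewsRanking(
        cell_ids=tuple(matrix.cell_ids),
        t_grid=t_grid,
        curves=curves,
        theta_star=theta_star,
        scores=scores,
        order=tuple(matrix.cell_ids[i] for i in order_idx),
        orientation_flipped=flipped,
        group_labels=tuple(matrix.group_labels) if matrix.group_labels else None,
    )
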