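"""Cross-sample intensity matrix assembly and the PCA work/prediction
protocol.

The multi-sample analysis assembles a samples x formulas intensity matrix
from per-sample assignment tables (formulas matched by exact elemental
identity; absence = 0), preprocesses it by log10(1 + x) transformation
followed by unit-variance (UV) scaling, and fits a principal component
model by iterative NIPALS extraction.  Model quality is reported as the
per-component and cumulative explained variance R2X and its
cross-validated counterpart Q2 (row-wise K-fold, contiguous blocks,
Q2 = 1 - PRESS/TSS accumulated over components).  A work set fits the
model and a prediction (held-out) set is projected into its score space,
mirroring the standard chemometrics train/predict split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .formula_assign import AssignmentTable, MolecularFormula

__all__ = [
    "IntensityMatrix",
    "PreprocessRecord",
    "PCAModel",
    "CVResult",
    "assemble_matrix",
    "preprocess",
    "apply_preprocessing",
    "fit_pca",
    "project",
    "q2_cv",
    "top_loadings",
    "fit_work_predict",
]


class NonConvergenceError(RuntimeError):
    pass


@dataclass
class IntensityMatrix:
    """Samples x formulas intensity table (0 = not detected).

    ``data`` is a DataFrame indexed by sample id with Hill-formula column
    names; ``class_labels`` optionally maps sample id -> class.
    """

    data: pd.DataFrame
    class_labels: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate formulas in the column index")
        if (self.data.values < 0).any():
            raise ValueError("intensities must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def formula_index(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, sample_ids: Sequence[str]) -> "IntensityMatrix":
        labels = (
            {s: self.class_labels[s] for s in sample_ids}
            if self.class_labels
            else None
        )
        return IntensityMatrix(self.data.loc[list(sample_ids)], labels)


def assemble_matrix(tables: Sequence[AssignmentTable]) -> IntensityMatrix:
    """Merge per-sample assignment tables into one intensity matrix.

    Formulas are matched across samples by exact elemental identity; each
    sample contributes the intensity of its primary assignments (summed in
    the rare case one formula is primary for several peaks).  All-zero
    columns are dropped.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 samples to assemble a matrix")
    ids = [t.sample_id for t in tables]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample_id(s): {dup}")
    per_sample: list[dict[str, float]] = []
    for t in tables:
        row: dict[str, float] = {}
        for a in t.primaries:
            row[a.formula.hill] = row.get(a.formula.hill, 0.0) + a.peak.intensity
        per_sample.append(row)
    df = pd.DataFrame(per_sample, index=ids).fillna(0.0)
    df = df.loc[:, (df != 0).any(axis=0)]
    df = df.reindex(sorted(df.columns), axis=1)
    return IntensityMatrix(df)


@dataclass
class PreprocessRecord:
    """Everything needed to reapply the training preprocessing to new rows."""

    log_applied: bool
    column_means: pd.Series
    column_scales: pd.Series
    dropped_columns: list[str]

    @property
    def kept_columns(self) -> list[str]:
        return list(self.column_means.index)


def preprocess(m: IntensityMatrix) -> tuple[pd.DataFrame, PreprocessRecord]:
    """log10(1 + x), then per-column mean centering and unit-variance
    scaling; zero-variance columns are dropped and recorded."""
    x = np.log10(1.0 + m.data)
    std = x.std(axis=0, ddof=1)
    dropped = list(std.index[(std == 0) | std.isna()])
    x = x.drop(columns=dropped)
    means = x.mean(axis=0)
    scales = std.drop(labels=dropped)
    xt = (x - means) / scales
    return xt, PreprocessRecord(True, means, scales, dropped)


def apply_preprocessing(record: PreprocessRecord, raw: pd.DataFrame) -> pd.DataFrame:
    """Apply a stored preprocessing to new raw-intensity rows (missing
    formulas are treated as 0 intensity before the log transform)."""
    raw = raw.reindex(columns=record.kept_columns, fill_value=0.0)
    x = np.log10(1.0 + raw) if record.log_applied else raw
    return (x - record.column_means) / record.column_scales


@dataclass
class PCAModel:
    preprocessing: Optional[PreprocessRecord]
    loadings: np.ndarray  # (n_components, n_formulas), rows orthonormal
    scores: pd.DataFrame  # samples x components
    r2x: np.ndarray
    r2x_cum: np.ndarray
    formula_index: list[str]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


def _nipals(X: np.ndarray, n_components: int, max_iter: int = 500,
            tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """NIPALS extraction of ``n_components`` from a centered matrix.

    Returns (scores T, loadings P, explained SS per component).  Loadings
    are re-orthogonalised against earlier components every iteration
    (Gram-Schmidt stabilisation) and oriented so the loading of largest
    absolute value is positive.  If the score vector has not settled after
    ``max_iter`` sweeps the component is still accepted when its explained
    sum of squares has stabilised — the signature of a (near-)degenerate
    eigenvalue pair, where any vector of the shared subspace is an equally
    valid component; otherwise a :class:`NonConvergenceError` is raised.
    """
    E = X.copy()
    n, p = E.shape
    T = np.zeros((n, n_components))
    P = np.zeros((n_components, p))
    ess = np.zeros(n_components)
    for a in range(n_components):
        col = int(np.argmax(np.sum(E**2, axis=0)))
        t = E[:, col].copy()
        if np.allclose(t, 0):
            # exhausted variance: remaining components are null
            break
        lam_prev = np.inf
        converged = False
        for it in range(max_iter):
            pvec = E.T @ t / (t @ t)
            if a > 0:
                pvec -= P[:a].T @ (P[:a] @ pvec)
            pvec /= np.linalg.norm(pvec)
            t_new = E @ pvec
            lam = float(t_new @ t_new)
            if np.linalg.norm(t_new - t) <= tol * max(np.sqrt(lam), 1e-30):
                t = t_new
                converged = True
                break
            t = t_new
            lam_prev = lam
        if not converged:
            if abs(lam - lam_prev) > 1e-9 * max(lam, 1e-30):
                raise NonConvergenceError(
                    f"NIPALS did not converge for component {a + 1}"
                )
        if pvec[int(np.argmax(np.abs(pvec)))] < 0:
            pvec = -pvec
            t = -t
        T[:, a] = t
        P[a] = pvec
        ess[a] = float(t @ t)
        E = E - np.outer(t, pvec)
    return T, P, ess


def fit_pca(
    xt: pd.DataFrame, n_components: int,
    preprocessing: Optional[PreprocessRecord] = None,
) -> PCAModel:
    """Fit a PCA model on a preprocessed (centered/scaled) matrix by NIPALS."""
    n, p = xt.shape
    if not (1 <= n_components <= min(n - 1, p)):
        raise ValueError(
            f"n_components must be in [1, min(samples - 1, formulas)] = "
            f"[1, {min(n - 1, p)}], got {n_components}"
        )
    X = xt.to_numpy(dtype=float)
    tss = float(np.sum(X**2))
    T, P, ess = _nipals(X, n_components)
    r2x = ess / tss if tss > 0 else np.zeros_like(ess)
    scores = pd.DataFrame(
        T, index=xt.index, columns=[f"PC{a + 1}" for a in range(n_components)]
    )
    return PCAModel(preprocessing, P, scores, r2x, np.cumsum(r2x), list(xt.columns))


def project(model: PCAModel, new_raw: pd.DataFrame) -> pd.DataFrame:
    """Project new samples (raw intensity space) into a fitted model's
    score space: stored log/center/scale, then the orthonormal loadings.
    Training rows project onto their own fitted scores."""
    if model.preprocessing is None:
        xt = new_raw.reindex(columns=model.formula_index, fill_value=0.0)
    else:
        xt = apply_preprocessing(model.preprocessing, new_raw)
    scores = xt.to_numpy(dtype=float) @ model.loadings.T
    return pd.DataFrame(scores, index=new_raw.index, columns=model.scores.columns)


@dataclass
class CVResult:
    q2: np.ndarray
    q2_cum: np.ndarray
    n_folds: int


def _fold_blocks(n: int, n_folds: int) -> list[np.ndarray]:
    return [b for b in np.array_split(np.arange(n), n_folds)]


def q2_cv(xt: pd.DataFrame, n_components: int, n_folds: int = 7) -> CVResult:
    """Row-wise cross-validated predictive power of a PCA model.

    Rows are split into contiguous blocks; per fold, the model is refitted
    on the kept rows and the left-out rows are reconstructed from the
    fold's loadings.  ``Q2_cum(k) = 1 - PRESS(k) / TSS`` with PRESS the
    pooled squared reconstruction error at k components; per-component Q2
    is the increment of the cumulative curve.
    """
    n = xt.shape[0]
    if n_folds < 2 or n_folds > n:
        raise ValueError(f"n_folds must be in [2, {n}], got {n_folds}")
    X = xt.to_numpy(dtype=float)
    tss = float(np.sum(X**2))
    press = np.zeros(n_components)
    for test_idx in _fold_blocks(n, n_folds):
        if len(test_idx) < 1:
            raise ValueError("cross-validation fold with no rows")
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        ncomp_fold = min(n_components, mask.sum() - 1)
        _, P, _ = _nipals(X[mask], ncomp_fold)
        E = X[test_idx].copy()
        for a in range(n_components):
            if a < ncomp_fold:
                t = E @ P[a]
                E = E - np.outer(t, P[a])
            press[a] += float(np.sum(E**2))
    q2_cum = 1.0 - press / tss
    q2 = np.diff(np.concatenate([[0.0], q2_cum]))
    return CVResult(q2, q2_cum, n_folds)


def top_loadings(
    model: PCAModel, component: int, k: int, sign: str = "positive"
) -> list[tuple[str, float]]:
    """The k formulas with the largest positive (or most negative) loading
    on a component, for van Krevelen rendering of discriminating masses."""
    if not (1 <= component <= model.n_components):
        raise ValueError(f"component must be in [1, {model.n_components}]")
    if sign not in ("positive", "negative"):
        raise ValueError("sign must be 'positive' or 'negative'")
    load = model.loadings[component - 1]
    if k > len(load):
        warnings.warn(
            f"k={k} exceeds the {len(load)} available formulas; truncating"
        )
        k = len(load)
    order = np.argsort(load)
    idx = order[::-1][:k] if sign == "positive" else order[:k]
    return [(model.formula_index[i], float(load[i])) for i in idx]


def fit_work_predict(
    m: IntensityMatrix,
    work_ids: Sequence[str],
    predict_ids: Sequence[str],
    n_components: int = 2,
    n_folds: int = 7,
) -> tuple[PCAModel, CVResult, pd.DataFrame, Optional[dict[str, str]]]:
    """The full work/prediction protocol on a labelled study.

    Fits preprocessing + PCA on the work samples, cross-validates Q2, and
    projects the prediction samples into the model.  When class labels are
    available, held-out samples are classified to the training class whose
    mean PC1 score is nearest; returns (model, cv, predicted scores,
    predicted labels or None).
    """
    work = m.subset(work_ids)
    xt, record = preprocess(work)
    model = fit_pca(xt, n_components, preprocessing=record)
    cv = q2_cv(xt, n_components, n_folds=min(n_folds, xt.shape[0]))
    pred_scores = project(model, m.data.loc[list(predict_ids)])
    predicted: Optional[dict[str, str]] = None
    if m.class_labels:
        centers = {}
        for cls in sorted(set(m.class_labels[s] for s in work_ids)):
            rows = [s for s in work_ids if m.class_labels[s] == cls]
            centers[cls] = float(model.scores.loc[rows, "PC1"].mean())
        predicted = {
            s: min(centers, key=lambda c: abs(pred_scores.loc[s, "PC1"] - centers[c]))
            for s in predict_ids
        }
    return model, cv, pred_scores, predicted
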