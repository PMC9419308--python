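"""Network adherence scores: PCA loading weights, per-subject scores, tertiles.

For each dietary network, the standardized intakes of its food groups are
weighted by the loadings of the first principal component of their correlation
matrix and summed; the resulting per-subject score measures adherence to the
network's consumption pattern.  Loadings carry sign information (a food group
consumed in opposition to the pattern gets a negative weight), and the global
sign is fixed so that the loading sum is positive — higher score means higher
adherence.  Scores are split into tertiles with the first tertile serving as
the reference group downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["LoadingVector", "NetworkScore", "pca_loadings", "compute_score", "assign_tertiles"]

TERTILE_LABELS = ("T1", "T2", "T3")


@dataclass
class LoadingVector:
    loadings: pd.Series  # unit-norm, sign-fixed
    variance_explained: float  # fraction of total variance on the first PC

    @property
    def groups(self) -> list[str]:
        return list(self.loadings.index)


@dataclass
class NetworkScore:
    scores: pd.Series
    tertiles: pd.Series  # labels T1/T2/T3, same index
    cutpoints: tuple[float, float]  # type-7 1/3 and 2/3 quantiles
    medians: dict[str, float]  # per-tertile median score
    counts: dict[str, int]


def pca_loadings(z: pd.DataFrame) -> LoadingVector:
    """First-principal-component loadings of one network's standardized intakes.

    The loadings are the unit eigenvector of the correlation matrix's largest
    eigenvalue, with the sign flipped if the loading sum is negative.
    """
    n, p = z.shape
    if p < 3:
        raise ValidationError(f"a network score needs >= 3 food groups, got {p}")
    if n <= p:
        raise ValidationError(f"need more subjects ({n}) than food groups ({p}) for PCA")
    x = z.to_numpy(dtype=float)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = z.columns[np.flatnonzero(sd == 0)]
        raise ValidationError(f"degenerate correlation matrix; constant group(s): {', '.join(bad)}")
    xs = (x - x.mean(0)) / sd
    corr = (xs.T @ xs) / n
    if not np.all(np.isfinite(corr)):
        raise ValidationError("degenerate correlation matrix (non-finite entries)")
    eigval, eigvec = np.linalg.eigh(corr)
    v = eigvec[:, -1]
    if v.sum() < 0:
        v = -v
    return LoadingVector(
        loadings=pd.Series(v, index=z.columns),
        variance_explained=float(eigval[-1] / eigval.sum()),
    )


def compute_score(z: pd.DataFrame, loadings: LoadingVector | pd.Series) -> pd.Series:
    """Per-subject network score: sum of loading-weighted z-scores."""
    w = loadings.loadings if isinstance(loadings, LoadingVector) else loadings
    missing = [g for g in w.index if g not in z.columns]
    if missing:
        raise ValidationError(f"food group(s) missing from intake matrix: {', '.join(missing)}")
    scores = z[list(w.index)].to_numpy(dtype=float) @ w.to_numpy(dtype=float)
    return pd.Series(scores, index=z.index, name="score")


def assign_tertiles(scores: pd.Series) -> NetworkScore:
    """Split scores into tertiles T1 < T2 < T3.

    Cut points are the type-7 (linear-interpolation) 1/3 and 2/3 quantiles;
    subjects are assigned by a stable sort on score so that ties at a cut
    point are resolved by subject order and group sizes differ by at most one.
    """
    n = len(scores)
    if n < 3:
        raise ValidationError(f"tertiles need at least 3 subjects, got {n}")
    values = scores.to_numpy(dtype=float)
    if np.all(values == values[0]):
        raise ValidationError("all scores identical; tertiles are undefined")
    q1, q2 = np.quantile(values, [1 / 3, 2 / 3])  # type-7 by default
    order = np.argsort(values, kind="stable")
    base, rem = divmod(n, 3)
    sizes = [base + (1 if t < rem else 0) for t in range(3)]
    labels = np.empty(n, dtype=object)
    start = 0
    for t, size in enumerate(sizes):
        labels[order[start : start + size]] = TERTILE_LABELS[t]
        start += size
    tert = pd.Series(labels, index=scores.index, name="tertile")
    medians = {lab: float(np.median(values[labels == lab])) for lab in TERTILE_LABELS}
    counts = {lab: int(sizes[i]) for i, lab in enumerate(TERTILE_LABELS)}
    return NetworkScore(
        scores=scores.astype(float),
        tertiles=tert,
        cutpoints=(float(q1), float(q2)),
        medians=medians,
        counts=counts,
    )
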