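"""Correlation matrices with significance masking, and varimax-rotated PCA.

The study-level statistics: Pearson correlation matrices between indices
(entries with p > alpha flagged, not deleted), the max-SD correlation matrix
built from each index at its own most-informative distance d_m, and a PCA of
the standardized max-SD dataset with varimax rotation (Kaiser row
normalization) to expose the two empirical families of indices — the
clustering group {OC, DN, IN, CC, LC, GC} and the spread group
{EG, CL, TD, TL}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sweep_study import MaxSDEntry

__all__ = [
    "CorrelationMatrix",
    "PCAResult",
    "ZeroVarianceError",
    "pearson_with_mask",
    "max_sd_correlations",
    "pca_varimax",
    "varimax",
    "heatmap_export",
]

#: PCA variable order after dropping RW (which correlates with nothing).
PCA_INDICES = ("OC", "DN", "IN", "CC", "LC", "GC", "EG", "CL", "TD", "TL")


class ZeroVarianceError(ValueError):
    """A variable has zero variance — the saturated-index pathology.

    An index that has reached its threshold value is constant across
    patterns and must be excluded, not silently correlated.
    """


@dataclass(frozen=True)
class CorrelationMatrix:
    labels: tuple[str, ...]
    r: np.ndarray
    p: np.ndarray
    mask: np.ndarray  # True where p > alpha (not significant)
    n_obs: int
    alpha: float = 0.05
    context: str = ""

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.labels, columns=self.labels)


@dataclass(frozen=True)
class PCAResult:
    eigenvalues: np.ndarray  # all, descending
    cumulative_variance: np.ndarray  # percent, all components
    loadings_rotated: pd.DataFrame  # variables x retained components
    included_indices: tuple[str, ...]
    n_components: int
    suppression_threshold: float = 0.3

    def display_loadings(self) -> pd.DataFrame:
        """Loadings with |value| <= threshold blanked (display convention)."""
        disp = self.loadings_rotated.copy()
        return disp.mask(disp.abs() <= self.suppression_threshold)


def pearson_with_mask(data: pd.DataFrame, alpha: float = 0.05, context: str = "") -> CorrelationMatrix:
    """Pairwise Pearson r with two-tailed p-values and a p > alpha mask.

    ``data`` is observations x variables.  p-values come from the
    t-distribution with n_obs - 2 degrees of freedom.  A zero-variance
    column raises :class:`ZeroVarianceError` naming the offending index.
    """
    if data.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    if data.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    x = data.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ZeroVarianceError(
            f"zero-variance column(s): {[data.columns[i] for i in dead]}"
        )
    nobs = x.shape[0]
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)  # enforce exact symmetry
    np.fill_diagonal(r, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((nobs - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2 * sps.t.sf(np.abs(t), df=nobs - 2)
    np.fill_diagonal(p, 0.0)
    return CorrelationMatrix(
        labels=tuple(map(str, data.columns)),
        r=r,
        p=p,
        mask=p > alpha,
        n_obs=nobs,
        alpha=alpha,
        context=context,
    )


def max_sd_correlations(
    selections: Mapping[str, MaxSDEntry], alpha: float = 0.05, context: str = "max-SD"
) -> CorrelationMatrix:
    """Correlation matrix of per-pattern values, each index at its own d_m."""
    entries = list(selections.values())
    ids = entries[0].pattern_ids
    for e in entries[1:]:
        if e.pattern_ids != ids:
            raise ValueError("all selections must come from the same pattern set")
    data = pd.DataFrame({e.index: e.values_at_dm for e in entries})
    return pearson_with_mask(data, alpha=alpha, context=context)


def varimax(
    loadings: np.ndarray,
    kaiser_normalize: bool = True,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation (orthogonal), optionally with Kaiser row normalization.

    Returns (rotated loadings, rotation matrix).  Kaiser's pairwise Jacobi
    sweeps: every factor pair is rotated by the closed-form angle that
    maximizes the varimax criterion for the pair, until all angles vanish.
    """
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k == 1:
        return L, np.eye(1)
    if kaiser_normalize:
        h = np.sqrt((L**2).sum(axis=1))
        h[h == 0] = 1.0
        L = L / h[:, None]
    # Kaiser's pairwise (Jacobi) sweeps: each factor pair is rotated by the
    # closed-form angle maximizing the varimax criterion for that pair
    rot = np.eye(k)
    lam = L.copy()
    for _ in range(max_iter):
        max_angle = 0.0
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = lam[:, i], lam[:, j]
                u = x**2 - y**2
                v = 2.0 * x * y
                num = 2.0 * (u * v).sum() - 2.0 * u.sum() * v.sum() / p
                den = (u**2 - v**2).sum() - (u.sum() ** 2 - v.sum() ** 2) / p
                angle = 0.25 * math.atan2(num, den)
                if abs(angle) < tol:
                    continue
                max_angle = max(max_angle, abs(angle))
                c, s = math.cos(angle), math.sin(angle)
                g = np.array([[c, -s], [s, c]])
                lam[:, [i, j]] = lam[:, [i, j]] @ g
                rot[:, [i, j]] = rot[:, [i, j]] @ g
        if max_angle < tol:
            break
    if kaiser_normalize:
        lam = lam * h[:, None]
    return lam, rot


def pca_varimax(
    selections: Mapping[str, MaxSDEntry] | pd.DataFrame,
    n_components: int = 2,
    indices: Sequence[str] = PCA_INDICES,
    use_correlation: bool = True,
    suppression_threshold: float = 0.3,
) -> PCAResult:
    """PCA of the max-SD dataset with varimax-rotated retained components.

    Variables are standardized (PCA of the correlation matrix) by default;
    covariance mode is available via ``use_correlation=False``.  Retained
    loadings (eigenvector x sqrt(eigenvalue)) are varimax-rotated with
    Kaiser normalization, and each component's sign is oriented so its
    largest-magnitude loading is positive.
    """
    if n_components < 2:
        raise ValueError("retain at least 2 components")
    if isinstance(selections, pd.DataFrame):
        data = selections.loc[:, [m for m in indices if m in selections.columns]]
    else:
        data = pd.DataFrame({m: selections[m].values_at_dm for m in indices if m in selections})
    labels = tuple(data.columns)
    if len(labels) < n_components:
        raise ValueError("more components requested than variables")
    x = data.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ZeroVarianceError(f"zero-variance variable(s): {[labels[i] for i in dead]}")
    if use_correlation:
        mat = np.corrcoef(x, rowvar=False)
    else:
        mat = np.cov(x, rowvar=False)
    evals, evecs = np.linalg.eigh(mat)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    cumvar = 100.0 * np.cumsum(evals) / evals.sum()
    load = evecs[:, :n_components] * np.sqrt(evals[:n_components])
    rotated, _ = varimax(load, kaiser_normalize=True)
    # sign convention: largest-|loading| entry of each component positive
    for j in range(n_components):
        if rotated[np.argmax(np.abs(rotated[:, j])), j] < 0:
            rotated[:, j] = -rotated[:, j]
    ldf = pd.DataFrame(
        rotated, index=labels, columns=[f"component_{j+1}" for j in range(n_components)]
    )
    return PCAResult(
        eigenvalues=evals,
        cumulative_variance=cumvar,
        loadings_rotated=ldf,
        included_indices=labels,
        n_components=n_components,
        suppression_threshold=suppression_threshold,
    )


def heatmap_export(
    matrix: CorrelationMatrix,
    csv_path: str | Path,
    image_path: str | Path | None = None,
) -> None:
    """Write a correlation matrix (with mask) to CSV and optionally a heatmap.

    Masked (non-significant) cells are greyed out in the image and flagged
    in a companion ``*_mask.csv``.
    """
    csv_path = Path(csv_path)
    matrix.frame().to_csv(csv_path)
    pd.DataFrame(matrix.mask, index=matrix.labels, columns=matrix.labels).to_csv(
        csv_path.with_name(csv_path.stem + "_mask.csv")
    )
    if image_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        shown = np.ma.masked_array(matrix.r, mask=matrix.mask)
        cmap = plt.get_cmap("RdBu_r").copy()
        cmap.set_bad("0.8")
        im = ax.imshow(shown, vmin=-1, vmax=1, cmap=cmap)
        ax.set_xticks(range(len(matrix.labels)), matrix.labels, rotation=90)
        ax.set_yticks(range(len(matrix.labels)), matrix.labels)
        ax.set_title(matrix.context or "Pearson correlations (p > alpha greyed)")
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        fig.savefig(image_path, dpi=150)
        plt.close(fig)
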