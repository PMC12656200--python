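"""PCA factor loadings and a significance-annotated Pearson correlation matrix.

The fused campaign table mixes volts, degC, hPa and unitless indices, so PCA
is computed on the correlation matrix (z-scored variables).  Loadings are the
orthonormal eigenvectors with a fixed sign convention (the largest-magnitude
loading of each component is positive) so results are reproducible across
runs and solvers.  Pairwise Pearson correlations carry two-sided p-values
from the t transform t = R sqrt((n-2)/(1-R^2)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_ALPHA = 0.05


class StandardizationError(ValueError):
    """A column has zero variance and cannot be z-scored."""


@dataclass
class PcaResult:
    loadings: np.ndarray  # (variables, components), orthonormal columns
    explained_pct: np.ndarray  # (components,), sums to 100
    scores: np.ndarray  # (observations, components)
    columns: Optional[list[str]] = None


@dataclass
class CorrelationMatrix:
    r: np.ndarray
    p: np.ndarray
    n: np.ndarray  # pairwise complete counts
    alpha: float = DEFAULT_ALPHA
    columns: Optional[list[str]] = None

    def significant(self) -> np.ndarray:
        return self.p <= self.alpha


def _as_matrix(data) -> tuple[np.ndarray, Optional[list[str]]]:
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), list(data.columns)
    return np.asarray(data, dtype=float), None


def pca(data, standardize: bool = True) -> PcaResult:
    """Correlation-matrix PCA with deterministic loading signs.

    Requires at least two observations and two variables with no missing
    values; a constant column raises :class:`StandardizationError` naming it.
    """
    X, cols = _as_matrix(data)
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("need at least 2 observations and 2 variables")
    if np.isnan(X).any():
        raise ValueError("PCA input contains missing values")
    if standardize:
        sd = X.std(axis=0, ddof=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            name = cols[bad[0]] if cols else f"column {bad[0]}"
            raise StandardizationError(f"constant column cannot be standardized: {name}")
        Z = (X - X.mean(axis=0)) / sd
    else:
        Z = X - X.mean(axis=0)
    C = Z.T @ Z / (n - 1)
    eigval, eigvec = np.linalg.eigh(C)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    loadings = eigvec[:, order]
    # sign convention: largest |loading| per component points positive
    for j in range(p):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] = -loadings[:, j]
    explained = 100.0 * eigval / eigval.sum()
    return PcaResult(
        loadings=loadings, explained_pct=explained, scores=Z @ loadings, columns=cols
    )


def pearson_matrix(data, alpha: float = DEFAULT_ALPHA) -> CorrelationMatrix:
    """Pairwise-complete Pearson R with two-sided p-values.

    Pairs with fewer than 3 complete observations (or zero variance) are set
    to NaN rather than raising.
    """
    X, cols = _as_matrix(data)
    n_obs, p = X.shape
    r = np.full((p, p), np.nan)
    pv = np.full((p, p), np.nan)
    nn = np.zeros((p, p), dtype=int)
    for i in range(p):
        r[i, i] = 1.0
        pv[i, i] = 0.0
        nn[i, i] = int(np.isfinite(X[:, i]).sum())
        for j in range(i + 1, p):
            ok = np.isfinite(X[:, i]) & np.isfinite(X[:, j])
            m = int(ok.sum())
            nn[i, j] = nn[j, i] = m
            if m < 3:
                continue
            xi, xj = X[ok, i], X[ok, j]
            if xi.std() == 0 or xj.std() == 0:
                continue
            rij = float(np.corrcoef(xi, xj)[0, 1])
            rij = float(np.clip(rij, -1.0, 1.0))
            if abs(rij) == 1.0:
                pij = 0.0
            else:
                t = rij * np.sqrt((m - 2) / (1.0 - rij**2))
                pij = float(2.0 * sps.t.sf(abs(t), df=m - 2))
            r[i, j] = r[j, i] = rij
            pv[i, j] = pv[j, i] = pij
    return CorrelationMatrix(r=r, p=pv, n=nn, alpha=alpha, columns=cols)


def export_pca(result: PcaResult, out_prefix: str | Path) -> None:
    """Write loadings and explained-variance CSVs."""
    out_prefix = str(out_prefix)
    cols = result.columns or [f"v{i}" for i in range(result.loadings.shape[0])]
    comp = [f"PC{j + 1}" for j in range(result.loadings.shape[1])]
    pd.DataFrame(result.loadings, index=cols, columns=comp).to_csv(
        f"{out_prefix}_loadings.csv"
    )
    pd.DataFrame({"component": comp, "explained_pct": result.explained_pct}).to_csv(
        f"{out_prefix}_explained.csv", index=False
    )


def export_correlation(cm: CorrelationMatrix, path: str | Path) -> None:
    """Lower-triangular correlation CSV; significant cells are starred."""
    cols = cm.columns or [f"v{i}" for i in range(cm.r.shape[0])]
    p = len(cols)
    cells = []
    for i in range(p):
        row = []
        for j in range(p):
            if j > i:
                row.append("")
            elif np.isnan(cm.r[i, j]):
                row.append("NA")
            else:
                star = "*" if cm.p[i, j] <= cm.alpha else ""
                row.append(f"{cm.r[i, j]:.3f}{star}")
        cells.append(row)
    pd.DataFrame(cells, index=cols, columns=cols).to_csv(path)
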