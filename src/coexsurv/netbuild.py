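"""Weighted co-expression network construction.

The network is the classic soft-thresholded correlation graph: pairwise
Pearson correlations between gene expression profiles are raised, in absolute
value, to a power β (unsigned network), giving an adjacency a_ij = |r_ij|^β
in [0, 1] with unit diagonal.  β is chosen so the connectivity distribution
approximates a scale-free power law.  The topological overlap measure (TOM)
then credits gene pairs for shared neighbours,

    tom_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),   l_ij = Σ_u a_iu a_uj,

and 1 − TOM is the clustering dissimilarity used downstream.

Adjacency and TOM matrices are square pandas DataFrames with identical gene
index and columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_SYM_TOL = 1e-10


def _check_square(mat: pd.DataFrame, name: str) -> np.ndarray:
    a = mat.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1] or not mat.index.equals(mat.columns):
        raise ValueError(f"{name} must be square with matching gene labels")
    if not np.allclose(a, a.T, atol=_SYM_TOL, rtol=0.0):
        raise ValueError(f"{name} must be symmetric")
    return a


# ---------------------------------------------------------------------------
# adjacency and connectivity
# ---------------------------------------------------------------------------

def pearson_adjacency(expr: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Unsigned soft-thresholded adjacency a_ij = |cor(x_i, x_j)|^β.

    Requires ≥3 samples and no zero-variance gene (the offending gene is
    named in the error).  The diagonal is set to 1 by definition.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate")
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        gene = expr.index[int(np.argmax(sd == 0))]
        raise ValueError(f"zero-variance gene: {gene!r}")
    r = np.corrcoef(x)
    np.clip(np.abs(r), 0.0, 1.0, out=r)
    a = r ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def connectivity(adj: pd.DataFrame,
                 partition: pd.Series | None = None) -> pd.DataFrame:
    """Whole-network (k.total) and within-module (k.in) connectivity.

    k.total_i = Σ_{j≠i} a_ij.  With a module ``partition`` (gene → label,
    "grey" = unassigned), k.in_i sums adjacency over the other genes of
    gene i's module; grey genes get k.in = 0.
    """
    a = _check_square(adj, "adjacency")
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    out = pd.DataFrame({"k_total": a0.sum(axis=1)}, index=adj.index)
    if partition is not None:
        if not adj.index.sort_values().equals(partition.index.sort_values()):
            raise ValueError("partition gene set does not match adjacency")
        labels = partition.reindex(adj.index)
        k_in = np.zeros(len(adj))
        for mod in labels.unique():
            if mod == "grey":
                continue
            mask = (labels == mod).to_numpy()
            k_in[mask] = a0[np.ix_(mask, mask)].sum(axis=1)
        out["k_in"] = k_in
    return out


# ---------------------------------------------------------------------------
# soft-threshold selection
# ---------------------------------------------------------------------------

@dataclass
class SoftThresholdReport:
    """Scale-free topology scan over a β grid.

    ``r_squared`` is the model R² of the regression of log10 p(k) on
    log10 k over a binned connectivity histogram, reported only when the
    fitted slope is negative (else 0); NaN marks grids points where fewer
    than 3 non-empty bins were available.  ``selected_beta`` is the smallest
    β reaching ``r2_cut``, falling back to the β of maximal R².
    """

    beta_grid: list[float]
    r_squared: list[float]
    slope: list[float]
    mean_k: list[float]
    selected_beta: float
    r2_cut: float
    fallback_used: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "beta": self.beta_grid,
            "r_squared": self.r_squared,
            "slope": self.slope,
            "mean_k": self.mean_k,
        })


def _scale_free_fit(k: np.ndarray, n_bins: int) -> tuple[float, float]:
    """R² (signed to penalise positive slopes) and slope of the log-log
    regression of binned frequency p(k) on mean connectivity per bin.
    Returns (nan, nan) when fewer than 3 usable bins exist."""
    lo, hi = float(k.min()), float(k.max())
    if hi <= lo:                      # degenerate: all connectivities equal
        return np.nan, np.nan
    which = np.minimum((n_bins * (k - lo) / (hi - lo)).astype(int),
                       n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=k, minlength=n_bins)
    xs, ys = [], []
    for b in range(n_bins):
        if counts[b] == 0:
            continue
        mk = sums[b] / counts[b]
        if mk <= 0:
            continue
        xs.append(np.log10(mk))
        ys.append(np.log10(counts[b] / k.size))
    if len(xs) < 3:
        return np.nan, np.nan
    fit = stats.linregress(xs, ys)
    r2 = fit.rvalue ** 2 if fit.slope < 0 else 0.0
    return float(r2), float(fit.slope)


def scan_soft_threshold(expr: pd.DataFrame,
                        beta_grid=tuple(range(1, 21)),
                        r2_cut: float = 0.80,
                        n_bins: int = 10) -> SoftThresholdReport:
    """Scan β over a grid, computing the scale-free fit R² and mean
    connectivity at each power, and select the operating β."""
    beta_grid = [float(b) for b in beta_grid]
    if not beta_grid:
        raise ValueError("beta grid must be non-empty")
    base = pearson_adjacency(expr, 1.0).to_numpy()
    np.fill_diagonal(base, 0.0)
    r2s, slopes, mean_ks = [], [], []
    for beta in beta_grid:
        k = (base ** beta).sum(axis=1)
        r2, slope = _scale_free_fit(k, n_bins)
        r2s.append(r2)
        slopes.append(slope)
        mean_ks.append(float(k.mean()))
    r2a = np.asarray(r2s)
    ok = np.where(~np.isnan(r2a) & (r2a >= r2_cut))[0]
    if ok.size:
        selected = beta_grid[int(ok[0])]
        fallback = False
    elif np.isnan(r2a).all():
        # degenerate connectivity histograms (e.g. a single latent factor):
        # no scale-free fit is defined anywhere on the grid
        selected = np.nan
        fallback = True
        logger.warning("scale-free fit undefined on the whole grid; "
                       "no beta selected")
    else:
        selected = beta_grid[int(np.nanargmax(r2a))]
        fallback = True
        logger.warning("no beta reached R^2 >= %.2f; falling back to "
                       "beta=%g (max R^2 %.3f)", r2_cut, selected,
                       float(np.nanmax(r2a)))
    logger.info("soft-threshold scan selected beta=%s", selected)
    return SoftThresholdReport(beta_grid, r2s, slopes, mean_ks,
                               float(selected), r2_cut, fallback)


# ---------------------------------------------------------------------------
# topological overlap
# ---------------------------------------------------------------------------

def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of an unsigned adjacency.

    Vectorised O(n²·m) path (one matrix product); the diagonal is 1 by
    definition.  Output is symmetric with entries in [0, 1].
    """
    a = _check_square(adj, "adjacency")
    if not np.allclose(np.diag(a), 1.0, atol=1e-8):
        raise ValueError("adjacency diagonal must be 1")
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    l = a0 @ a0                       # l_ij = Σ_{u≠i,j} a_iu a_uj for i≠j
    k = a0.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a0
    tom = (l + a0) / denom
    np.fill_diagonal(tom, 1.0)
    tom = 0.5 * (tom + tom.T)         # remove float asymmetry
    return pd.DataFrame(tom, index=adj.index, columns=adj.index)


def tom_dissimilarity(adj: pd.DataFrame) -> pd.DataFrame:
    """1 − TOM, the clustering dissimilarity (zero diagonal)."""
    return 1.0 - tom_similarity(adj)
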