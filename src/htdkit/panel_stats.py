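"""Cross-assay profiling: correlations and standardized PCA with parallel analysis.

The substrate is a :class:`LigandPanel` — one row per ligand, one column per
assay readout.  Correlations are computed pairwise-complete; PCA is
listwise-complete over a chosen variable subset, on z-scored columns (n−1
s.d.), with component retention decided by parallel analysis (eigenvalues of
simulated standard-normal panels of the same shape, 95th percentile per rank
by default).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LigandPanel",
    "PCAResult",
    "pearson_with_p",
    "spearman_with_p",
    "pca_standardized",
    "parallel_analysis",
    "correlation_table",
]

_MIN_PAIRS = 3


@dataclass
class LigandPanel:
    """Per-ligand table of numeric assay readouts plus a class label."""

    data: pd.DataFrame  # index: ligand names; numeric columns
    class_labels: pd.Series | None = None  # pharmacological class per ligand

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise ValueError("panel column names must be unique")
        if self.class_labels is not None:
            self.class_labels = self.class_labels.reindex(self.data.index)

    @property
    def ligands(self) -> list[str]:
        return list(self.data.index)

    def complete_subset(self, variables: list[str]) -> pd.DataFrame:
        """Listwise-complete sub-table over the requested variables."""
        missing = [v for v in variables if v not in self.data.columns]
        if missing:
            raise KeyError(f"unknown panel variables: {missing}")
        return self.data[variables].dropna(axis=0, how="any")


@dataclass
class PCAResult:
    """Scores, loadings and retention decision of a standardized PCA."""

    scores: pd.DataFrame  # ligand x PC
    loadings: pd.DataFrame  # variable x PC
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    retained: list[str] = field(default_factory=list)
    thresholds: np.ndarray | None = None


def _clean_pairs(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < _MIN_PAIRS:
        raise ValueError(f"need at least {_MIN_PAIRS} complete pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return x, y


def _t_pvalue(r: float, n: int) -> float:
    """Two-tailed p from the t transform of a correlation coefficient."""
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return 2.0 * stats.t.sf(abs(t), df=n - 2)


def pearson_with_p(x, y) -> tuple[float, float]:
    """Product-moment correlation with the two-tailed t-test p-value.

    Pairs with a missing member are dropped; at least three complete pairs
    and non-constant vectors are required.
    """
    x, y = _clean_pairs(x, y)
    r = float(np.corrcoef(x, y)[0, 1])
    return r, _t_pvalue(r, x.size)


def _average_ranks(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


def spearman_with_p(x, y) -> tuple[float, float]:
    """Rank correlation; exact permutation p for n < 10, t-approximation otherwise.

    Spearman's ρ is Pearson's r applied to average ranks.  For small panels
    (n < 10) the two-tailed p-value is computed by full enumeration of rank
    permutations; for n ≥ 10 the usual t transform is used.
    """
    x, y = _clean_pairs(x, y)
    rx, ry = _average_ranks(x), _average_ranks(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n >= 10:
        return rho, _t_pvalue(rho, n)
    # exact two-tailed permutation distribution of rho given the observed ranks
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
    perms = np.array(list(itertools.permutations(range(n))))
    rho_perm = (rx_c[perms] @ ry_c) / denom
    p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
    return rho, p


def correlation_table(panel: LigandPanel, pairs=None) -> pd.DataFrame:
    """Pearson and Spearman statistics for every variable pair (or the given pairs)."""
    cols = list(panel.data.columns)
    if pairs is None:
        pairs = list(itertools.combinations(cols, 2))
    rows = []
    for a, b in pairs:
        sub = panel.data[[a, b]].dropna()
        if len(sub) < _MIN_PAIRS:
            continue
        try:
            rp, pp = pearson_with_p(sub[a], sub[b])
            rs, ps = spearman_with_p(sub[a], sub[b])
        except ValueError:
            continue
        rows.append(dict(x=a, y=b, n=len(sub), pearson_r=rp, pearson_p=pp,
                         spearman_rho=rs, spearman_p=ps))
    return pd.DataFrame(rows)


def _standardize(mat: np.ndarray) -> np.ndarray:
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance column: PCA on standardized data undefined")
    return (mat - mean) / sd


def pca_standardized(
    panel: LigandPanel,
    variables: list[str] | None = None,
    *,
    retention: tuple[int, float, int | None] | None = None,
) -> PCAResult:
    """PCA of z-scored panel columns (eigendecomposition of the correlation matrix).

    Ligands with any missing value in the variable subset are dropped
    (listwise).  Per-PC sign is fixed by forcing the largest-magnitude
    loading positive so score/loading tables are reproducible.

    Parameters
    ----------
    retention : (n_sims, percentile, seed), optional
        If given, run :func:`parallel_analysis` with these settings and mark
        the retained components.
    """
    variables = variables or list(panel.data.columns)
    sub = panel.complete_subset(variables)
    n, p = sub.shape
    if n < 3 or p < 2:
        raise ValueError("PCA requires >= 3 complete ligands and >= 2 variables")
    z = _standardize(sub.to_numpy())
    corr = (z.T @ z) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for j in range(p):
        k = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    scores = z @ eigvecs
    pc_names = [f"PC{i + 1}" for i in range(p)]
    result = PCAResult(
        scores=pd.DataFrame(scores, index=sub.index, columns=pc_names),
        loadings=pd.DataFrame(eigvecs, index=variables, columns=pc_names),
        eigenvalues=eigvals,
        variance_fractions=eigvals / eigvals.sum(),
    )
    if retention is not None:
        n_sims, percentile, seed = retention
        thresholds = parallel_analysis((n, p), n_sims=n_sims, percentile=percentile, seed=seed)
        result.thresholds = thresholds
        result.retained = [pc_names[j] for j in range(p) if eigvals[j] > thresholds[j]]
    return result


def parallel_analysis(
    shape: tuple[int, int],
    n_sims: int = 1000,
    percentile: float = 95.0,
    seed: int | None = None,
) -> np.ndarray:
    """Per-rank eigenvalue thresholds from simulated standard-normal panels.

    Simulates ``n_sims`` matrices of the panel's shape, standardizes each,
    and returns the requested percentile of the sorted (descending)
    correlation-matrix eigenvalues at each rank.  A component is retained
    when its observed eigenvalue exceeds its rank's threshold.
    """
    n, p = shape
    if n < 3 or p < 2:
        raise ValueError("parallel analysis requires shape (>=3, >=2)")
    rng = np.random.default_rng(seed)
    eig = np.empty((n_sims, p))
    for s in range(n_sims):
        z = _standardize(rng.standard_normal((n, p)))
        corr = (z.T @ z) / (n - 1)
        eig[s] = np.sort(np.linalg.eigvalsh(corr))[::-1]
    return np.percentile(eig, percentile, axis=0)
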