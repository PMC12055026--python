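"""PLS1 transcription-neuroimaging association.

Partial least squares regression with regional gene expression (regions
x genes, z-scored per gene) as predictors and the unthresholded
group-difference t-map as the single response.  For a univariate
response, the first PLS component is analytic: the weight vector is
proportional to ``X^T y`` (normalized to unit length), the region scores
are ``X w``, and the component's explanatory power is the R^2 of the
t-map regressed on the scores.  Significance of the explained variance
and of the score/t-map correlation comes from region-label permutation;
gene contributions are ranked by bootstrap z (weight / bootstrap SE of
the weight across region resamples), converted to two-sided normal p and
BH-FDR q, and thresholded into positively and negatively weighted gene
sets.

The permutation null shuffles region labels without preserving spatial
autocorrelation; supply precomputed null maps via ``null_maps`` if a
surrogate-map null is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_fdr

__all__ = [
    "PLSResult",
    "pls1_fit",
    "perm_test_pls",
    "bootstrap_gene_z",
    "select_gene_sets",
    "pls_association",
]


@dataclass
class PLSResult:
    """First-component PLS association between expression and a t-map."""

    pls1_scores: np.ndarray
    gene_weights: pd.Series
    var_explained: float
    corr_scores_t: float
    gene_z: pd.Series | None = None
    gene_p: pd.Series | None = None
    gene_q: pd.Series | None = None
    perm_p_var: float | None = None
    perm_p_corr: float | None = None


def _as_matrix(x: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, pd.Index]:
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), x.columns
    arr = np.asarray(x, dtype=float)
    return arr, pd.RangeIndex(arr.shape[1])


def zscore_genes(expression: pd.DataFrame) -> pd.DataFrame:
    """z-score each gene across regions, dropping zero-variance genes."""
    sd = expression.std(axis=0, ddof=1)
    keep = sd > 0
    return (expression.loc[:, keep] - expression.loc[:, keep].mean()) / sd[keep]


def pls1_fit(x: pd.DataFrame | np.ndarray, y: np.ndarray) -> PLSResult:
    """First PLS component of z-scored expression against a regional map.

    Orientation is fixed so that ``corr(pls1_scores, y) >= 0`` (which the
    ``X^T y`` weight satisfies by construction); ``var_explained`` is the
    R^2 of y on the scores.
    """
    arr, genes = _as_matrix(x)
    y = np.asarray(y, dtype=float).ravel()
    n = arr.shape[0]
    if y.size != n:
        raise ValueError("expression and response cover different region sets")
    if n < 10:
        raise ValueError(f"need at least 10 regions, got {n}")
    yc = y - y.mean()
    if np.allclose(yc, 0):
        raise ValueError("constant response map")
    w = arr.T @ yc
    nrm = np.linalg.norm(w)
    if nrm == 0:
        # response orthogonal to every gene: define a degenerate component
        scores = np.zeros(n)
        return PLSResult(
            pls1_scores=scores,
            gene_weights=pd.Series(w, index=genes),
            var_explained=0.0,
            corr_scores_t=0.0,
        )
    w = w / nrm
    scores = arr @ w
    sc = scores - scores.mean()
    denom = np.sqrt((sc @ sc) * (yc @ yc))
    r = float(sc @ yc / denom) if denom > 0 else 0.0
    if r < 0:  # defensive; X^T y orientation makes this non-negative
        w, scores, r = -w, -scores, -r
    return PLSResult(
        pls1_scores=scores,
        gene_weights=pd.Series(w, index=genes),
        var_explained=float(r**2),
        corr_scores_t=r,
    )


def perm_test_pls(
    x: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
    null_maps: np.ndarray | None = None,
) -> tuple[float, float]:
    """Permutation p for PLS1 explained variance and score/t-map |r|.

    Region labels of the response are shuffled (or rows of ``null_maps``
    used as the null ensemble); ``p = (1 + #{perm >= obs}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    arr, _ = _as_matrix(x)
    y = np.asarray(y, dtype=float).ravel()
    obs = pls1_fit(arr, y)
    if null_maps is not None:
        nulls = np.asarray(null_maps, dtype=float)
        n_perm = nulls.shape[0]
    else:
        rng = np.random.default_rng(seed)
        nulls = np.stack([rng.permutation(y) for _ in range(n_perm)])
    yc = nulls - nulls.mean(axis=1, keepdims=True)  # n_perm x regions
    w = arr.T @ yc.T  # genes x n_perm
    nrm = np.linalg.norm(w, axis=0)
    nrm[nrm == 0] = 1.0
    scores = arr @ (w / nrm)  # regions x n_perm
    sc = scores - scores.mean(axis=0)
    num = np.einsum("rp,pr->p", sc, yc)
    den = np.sqrt((sc**2).sum(axis=0) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, 0.0)
    var = r**2
    p_var = (1 + int((var >= obs.var_explained).sum())) / (1 + n_perm)
    p_corr = (1 + int((np.abs(r) >= abs(obs.corr_scores_t)).sum())) / (1 + n_perm)
    return float(p_var), float(p_corr)


def bootstrap_gene_z(
    x: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    n_boot: int = 10000,
    seed: int = 0,
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Bootstrap z, p and BH-FDR q for each gene's PLS1 weight.

    Regions are resampled with replacement; the component is refit per
    resample and sign-aligned to the original weight vector (by the sign
    of their inner product) before the bootstrap SE is taken.  Resamples
    with a constant response are redrawn.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    arr, genes = _as_matrix(x)
    y = np.asarray(y, dtype=float).ravel()
    n = arr.shape[0]
    obs = pls1_fit(arr, y)
    w0 = obs.gene_weights.to_numpy()
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, arr.shape[1]))
    redrawn = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if np.ptp(yb) > 0:
                break
            redrawn += 1
        yc = yb - yb.mean()
        wb = arr[idx].T @ yc
        nrm = np.linalg.norm(wb)
        if nrm > 0:
            wb = wb / nrm
        if wb @ w0 < 0:
            wb = -wb
        boots[b] = wb
    se = boots.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, w0 / se, 0.0)
    p = 2.0 * sps.norm.sf(np.abs(z))
    q = bh_fdr(p)
    return (
        pd.Series(z, index=genes, name="z"),
        pd.Series(p, index=genes, name="p"),
        pd.Series(q, index=genes, name="q"),
    )


def select_gene_sets(
    result: PLSResult, q_threshold: float = 0.001
) -> tuple[list, list]:
    """Ranked positively / negatively weighted significant gene lists.

    genes+ have z > 0, genes- z < 0, both at BH-FDR q below threshold;
    each list is ordered by descending |z|.
    """
    if result.gene_z is None or result.gene_q is None:
        raise ValueError("bootstrap z/q not computed; run bootstrap_gene_z first")
    z, q = result.gene_z, result.gene_q
    plus = z[(z > 0) & (q < q_threshold)].sort_values(ascending=False)
    minus = z[(z < 0) & (q < q_threshold)].sort_values()
    return list(plus.index), list(minus.index)


def pls_association(
    expression: pd.DataFrame,
    t_map: np.ndarray,
    n_perm: int = 10000,
    n_boot: int = 10000,
    q_threshold: float = 0.001,
    seed: int = 0,
) -> tuple[PLSResult, list, list]:
    """Full PLS1 workflow: fit, permutation tests, bootstrap z, gene sets."""
    xz = zscore_genes(expression)
    result = pls1_fit(xz, t_map)
    result.perm_p_var, result.perm_p_corr = perm_test_pls(
        xz, t_map, n_perm=n_perm, seed=seed
    )
    result.gene_z, result.gene_p, result.gene_q = bootstrap_gene_z(
        xz, t_map, n_boot=n_boot, seed=seed + 1
    )
    plus, minus = select_gene_sets(result, q_threshold=q_threshold)
    return result, plus, minus
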