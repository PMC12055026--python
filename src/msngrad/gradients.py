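"""Diffusion-map gradients of morphometric similarity networks.

The gradient workflow turns each subject's MSN into a low-dimensional
embedding whose components ("gradients") order cortical regions along
continuous axes of connectivity-profile variance:

1. per row, keep only the top 10% of MSN entries (by signed value,
   diagonal excluded) — the standard row sparsification;
2. compute cosine similarity between the sparsified rows and map it to a
   normalized angle affinity, ``1 - arccos(cos)/pi`` in [0, 1];
3. diffusion map embedding (alpha = 0.5, diffusion time 0) of the
   affinity kernel;
4. Procrustes-align each subject's components to a template derived from
   the cohort-average MSN, which resolves the eigenvector sign/rotation
   indeterminacy.

Only gradient 1 (maximal variance) is analyzed downstream; the rest are
computed and stored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import eigh, svd
from scipy.sparse.csgraph import connected_components

__all__ = [
    "GradientSet",
    "GradientGlobalMetrics",
    "sparsify_rows",
    "normalized_angle_affinity",
    "diffusion_embed",
    "build_template",
    "procrustes_align",
    "gradient_global_metrics",
    "gradients_from_msn",
    "cohort_gradients",
]


@dataclass
class GradientSet:
    """Regions x k gradient components with explained-variance fractions.

    ``lambdas`` are eigenvalue-derived variance fractions (non-negative,
    non-increasing, summing to at most 1 over the retained components).
    ``degenerate`` flags a rank-deficient kernel (all non-trivial
    eigenvalues ~ 0).
    """

    components: np.ndarray
    lambdas: np.ndarray
    aligned: bool = False
    template_id: str | None = None
    degenerate: bool = False

    @property
    def n_regions(self) -> int:
        return self.components.shape[0]

    @property
    def k(self) -> int:
        return self.components.shape[1]


@dataclass
class GradientGlobalMetrics:
    """Global summaries of gradient 1: variance fraction, range, variance."""

    explained_ratio_1: float
    range_1: float
    variance_1: float


def sparsify_rows(msn: np.ndarray, density: float = 0.10) -> np.ndarray:
    """Keep the top ``floor(density * n)`` entries per row by signed value.

    The diagonal is excluded from the candidate set; everything not kept
    is set to 0.  The result is generally asymmetric.  Ties are broken by
    region index for determinism.
    """
    msn = np.asarray(msn, dtype=float)
    n = msn.shape[0]
    if not 0.0 < density < 1.0:
        raise ValueError(f"density must lie in (0, 1), got {density}")
    k = int(np.floor(density * n))
    if k < 1:
        raise ValueError(f"density {density} keeps 0 entries per row of {n}")
    work = msn.copy()
    np.fill_diagonal(work, -np.inf)
    # stable top-k: sort by (-value, index)
    order = np.argsort(-work, axis=1, kind="stable")
    keep = order[:, :k]
    out = np.zeros_like(msn)
    rows = np.repeat(np.arange(n), k)
    out[rows, keep.ravel()] = msn[rows, keep.ravel()]
    return out


def normalized_angle_affinity(sparse: np.ndarray) -> np.ndarray:
    """Cosine similarity of (full-length) sparsified rows, angle-normalized.

    ``affinity_ij = 1 - arccos(clip(cos_ij, -1, 1)) / pi`` lies in [0, 1]:
    identical rows map to 1, orthogonal rows to 0.5, antiparallel to 0.
    """
    sparse = np.asarray(sparse, dtype=float)
    norms = np.linalg.norm(sparse, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(
            f"all-zero row(s) {zero.tolist()}: cosine similarity undefined"
        )
    unit = sparse / norms[:, None]
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    aff = 1.0 - np.arccos(cos) / np.pi
    return (aff + aff.T) / 2.0


def diffusion_embed(
    affinity: np.ndarray,
    k: int = 10,
    alpha: float = 0.5,
    t: float = 0,
) -> GradientSet:
    """Diffusion map embedding of a non-negative symmetric affinity kernel.

    The kernel is alpha-normalized (``W' = W / (d^a d^a)``), converted to
    a row-stochastic diffusion operator, and eigendecomposed via its
    symmetric conjugate.  The trivial constant component (eigenvalue 1)
    is dropped; the remaining components are ordered by descending
    eigenvalue magnitude and scaled by ``lambda^t`` (or the multiscale
    ``lambda / (1 - lambda)`` when ``t == 0``).

    ``lambdas`` are variance fractions ``lambda_i^2 / sum_j lambda_j^2``
    over the full non-trivial spectrum.
    """
    w = np.asarray(affinity, dtype=float)
    n = w.shape[0]
    if w.ndim != 2 or w.shape[1] != n:
        raise ValueError(f"affinity must be square, got shape {w.shape}")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("affinity must be symmetric")
    if np.any(w < 0):
        raise ValueError("affinity must be non-negative")
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n_regions, got k={k}, n={n}")
    n_comp, _ = connected_components(w > 0, directed=False)
    if n_comp > 1:
        raise ValueError(
            f"affinity graph has {n_comp} connected components; diffusion "
            "embedding requires a single component"
        )

    d = w.sum(axis=1)
    w_alpha = w / np.outer(d**alpha, d**alpha)
    d_alpha = w_alpha.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d_alpha)
    sym = inv_sqrt[:, None] * w_alpha * inv_sqrt[None, :]
    sym = (sym + sym.T) / 2.0
    evals, evecs = eigh(sym)  # ascending
    evals = evals[::-1]
    evecs = evecs[:, ::-1]

    # eigenvectors of the row-stochastic operator
    phi = inv_sqrt[:, None] * evecs
    # trivial component: eigenvalue 1, constant eigenvector
    psi = phi / phi[:, [0]]
    lam = evals[1:]
    order = np.argsort(-np.abs(lam), kind="stable")
    lam = lam[order]
    psi_nt = psi[:, 1:][:, order]

    degenerate = bool(np.all(np.abs(lam) < 1e-12))
    total = float(np.sum(lam**2))
    if degenerate or total == 0.0:
        fractions = np.zeros(len(lam))
    else:
        fractions = lam**2 / total

    lam_k = lam[:k]
    if t == 0:
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(np.abs(1.0 - lam_k) < 1e-12, 0.0, lam_k / (1.0 - lam_k))
    else:
        scale = np.sign(lam_k) * np.abs(lam_k) ** t
    components = psi_nt[:, :k] * scale[None, :]
    if degenerate:
        warnings.warn(
            "degenerate diffusion kernel: all non-trivial eigenvalues are ~0",
            RuntimeWarning,
            stacklevel=2,
        )
    return GradientSet(
        components=components,
        lambdas=fractions[:k].copy(),
        aligned=False,
        degenerate=degenerate,
    )


def gradients_from_msn(
    msn: np.ndarray,
    density: float = 0.10,
    k: int = 10,
    alpha: float = 0.5,
    t: float = 0,
) -> GradientSet:
    """sparsify -> normalized-angle affinity -> diffusion embedding."""
    return diffusion_embed(
        normalized_angle_affinity(sparsify_rows(msn, density)), k=k, alpha=alpha, t=t
    )


def build_template(
    msns: np.ndarray | list[np.ndarray],
    density: float = 0.10,
    k: int = 10,
    alpha: float = 0.5,
    t: float = 0,
) -> GradientSet:
    """Gradient template from the element-wise mean MSN across subjects.

    The template fixes the orientation of every component: the region
    with the largest absolute score on each component is made positive.
    Subjects from both groups should be pooled here.
    """
    arr = np.asarray(msns, dtype=float)
    if arr.ndim != 3:
        raise ValueError("msns must be a collection of square matrices")
    if arr.shape[0] < 1:
        raise ValueError("need at least one MSN")
    mean_msn = arr.mean(axis=0)
    if np.allclose(mean_msn, 0.0):
        raise ValueError("mean MSN is the zero matrix; template is degenerate")
    g = gradients_from_msn(mean_msn, density=density, k=k, alpha=alpha, t=t)
    comp = g.components.copy()
    for j in range(comp.shape[1]):
        i = int(np.argmax(np.abs(comp[:, j])))
        if comp[i, j] < 0:
            comp[:, j] = -comp[:, j]
    return replace(g, components=comp, aligned=True, template_id="average-msn")


def procrustes_align(subject: GradientSet, template: GradientSet) -> GradientSet:
    """Orthogonally rotate/reflect subject components onto the template.

    Solves the orthogonal Procrustes problem (no scaling): ``R = U V^T``
    from the SVD of ``subject^T template``; explained-variance fractions
    are untouched.
    """
    if subject.components.shape != template.components.shape:
        raise ValueError(
            f"dimension mismatch: subject {subject.components.shape} vs "
            f"template {template.components.shape}"
        )
    u, _, vt = svd(subject.components.T @ template.components)
    rot = u @ vt
    return replace(
        subject,
        components=subject.components @ rot,
        aligned=True,
        template_id=template.template_id,
    )


def gradient_global_metrics(g: GradientSet, ddof: int = 1) -> GradientGlobalMetrics:
    """Explained ratio, range (max - min) and variance of gradient 1."""
    g1 = g.components[:, 0]
    return GradientGlobalMetrics(
        explained_ratio_1=float(g.lambdas[0]),
        range_1=float(g1.max() - g1.min()),
        variance_1=float(g1.var(ddof=ddof)),
    )


def cohort_gradients(
    msns: np.ndarray,
    density: float = 0.10,
    k: int = 10,
    alpha: float = 0.5,
    t: float = 0,
) -> tuple[list[GradientSet], GradientSet]:
    """Aligned gradients for every subject plus the average-MSN template."""
    template = build_template(msns, density=density, k=k, alpha=alpha, t=t)
    aligned = [
        procrustes_align(
            gradients_from_msn(m, density=density, k=k, alpha=alpha, t=t), template
        )
        for m in msns
    ]
    return aligned, template
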