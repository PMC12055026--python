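"""Morphometric similarity networks (MSNs).

An MSN is a per-subject regions x regions matrix of Pearson correlations
between the regions' standardized 5-feature morphometric profiles
(cortical thickness, volume, area, gaussian and mean curvature).  It is
an individual-level structural network, in contrast to group-level
structural covariance networks.

Conventions (fixed, documented):

* z-scoring uses the sample SD (ddof=1) across regions;
* the MSN diagonal is set to 0 — self-similarity is uninformative and
  would otherwise always survive row sparsification;
* a region whose standardized feature vector is constant has undefined
  correlations; its entries are set to 0 with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "zscore_features",
    "compute_msn",
    "regional_strength",
    "msn_stack",
]


def zscore_features(table: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Standardize each feature column across regions (mean 0, SD 1).

    Raises if any feature has zero variance across regions, naming it.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 regions to z-score")
    values = table.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("feature table contains missing values")
    sd = values.std(axis=0, ddof=ddof)
    dead = [str(c) for c, s in zip(table.columns, sd) if s == 0]
    if dead:
        raise ValueError(f"zero-variance feature(s): {', '.join(dead)}")
    out = (values - values.mean(axis=0)) / sd
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def compute_msn(table: pd.DataFrame) -> np.ndarray:
    """Pearson-correlate every pair of regions' standardized feature vectors.

    Expects a standardized table (see :func:`zscore_features`); returns a
    symmetric regions x regions matrix with zero diagonal.
    """
    x = table.to_numpy(dtype=float)
    n = x.shape[0]
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    constant = norms == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} region(s) have constant feature vectors; "
            "their correlations are set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        norms = np.where(constant, 1.0, norms)
    unit = centered / norms[:, None]
    msn = unit @ unit.T
    msn[constant, :] = 0.0
    msn[:, constant] = 0.0
    np.clip(msn, -1.0, 1.0, out=msn)
    msn = (msn + msn.T) / 2.0
    np.fill_diagonal(msn, 0.0)
    return msn


def regional_strength(msn: np.ndarray) -> np.ndarray:
    """Per-region sum of correlation coefficients (off-diagonal row sum)."""
    msn = np.asarray(msn, dtype=float)
    if msn.ndim != 2 or msn.shape[0] != msn.shape[1]:
        raise ValueError(f"MSN must be square, got shape {msn.shape}")
    return msn.sum(axis=1) - np.diag(msn)


def msn_stack(features: np.ndarray) -> np.ndarray:
    """MSNs for a whole cohort: (n_subjects, n_regions, 5) -> (n_subjects, n, n).

    Applies per-subject z-scoring then pairwise regional correlation.
    """
    features = np.asarray(features, dtype=float)
    n_sub, n_reg, n_feat = features.shape
    out = np.empty((n_sub, n_reg, n_reg))
    cols = [f"f{i}" for i in range(n_feat)]
    for i in range(n_sub):
        table = pd.DataFrame(features[i], columns=cols)
        out[i] = compute_msn(zscore_features(table))
    return out
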