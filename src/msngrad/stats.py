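"""Group contrasts of gradient maps: GLM t-maps, label-level summaries,
distributional (Kolmogorov-Smirnov) tests, and BH-FDR correction.

The regional contrast is an ordinary-least-squares GLM per region with
group (AD vs NC) plus age, sex and education covariates; the group
coefficient's t statistic, two-sided p, and Benjamini-Hochberg q are
reported.  Class- and network-level values are arithmetic means of the
member regions' gradient scores per subject, contrasted with the same
GLM; FDR is applied within each family (regions, classes, networks)
separately.

Kolmogorov-Smirnov tests compare the *pooled* per-subject regional
gradient values of the two groups (globally or within a class); a
per-subject-mean alternative is available via ``subject_means=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .harmonize import combat_harmonize  # re-exported surface

__all__ = [
    "combat_harmonize",
    "glm_contrast",
    "aggregate_by_label",
    "ks_compare",
    "bh_fdr",
    "label_contrast",
]


def _check_full_rank(x: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        rank = 0
        for j in range(x.shape[1]):
            r = np.linalg.matrix_rank(x[:, : j + 1])
            if r == rank:
                bad.append(names[j])
            rank = r
        raise ValueError(f"collinear design columns: {bad}")


def glm_contrast(
    values: np.ndarray | pd.DataFrame,
    design: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex", "education"),
    group_col: str = "group",
    positive_class: str = "AD",
) -> pd.DataFrame:
    """Per-region GLM contrast of ``positive_class`` minus the other group.

    ``values`` is subjects x regions.  Returns a frame with columns
    ``t``, ``p`` (two-sided, residual-df t distribution) and ``q``
    (BH-FDR across regions); index follows the columns of ``values``.
    """
    if isinstance(values, pd.DataFrame):
        region_index = values.columns
        arr = values.to_numpy(dtype=float)
    else:
        arr = np.asarray(values, dtype=float)
        region_index = pd.RangeIndex(arr.shape[1])
    if arr.shape[0] != len(design):
        raise ValueError("values and design have different numbers of subjects")

    groups = np.asarray(design[group_col])
    g = (groups == positive_class).astype(float)
    if g.sum() == 0 or g.sum() == len(g):
        raise ValueError("both groups must be present in the design")
    cols = [np.ones(len(design)), g]
    names = ["intercept", group_col]
    for c in covariates:
        cols.append(np.asarray(design[c], dtype=float))
        names.append(c)
    x = np.column_stack(cols)
    _check_full_rank(x, names)

    n, p = x.shape
    df = n - p
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ arr  # p x regions
    resid = arr - x @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[1] / se, 0.0)
    pvals = 2.0 * sps.t.sf(np.abs(t), df)
    return pd.DataFrame({"t": t, "p": pvals, "q": bh_fdr(pvals)}, index=region_index)


def aggregate_by_label(
    values: pd.DataFrame,
    atlas: pd.DataFrame,
    level: str = "class",
) -> pd.DataFrame:
    """Mean gradient per atlas label per subject.

    ``values`` is subjects x regions with region_id columns; ``level``
    selects the ``econo_class`` ("class") or ``yeo_network`` ("network")
    labeling.  Every region must be labeled; empty labels are rejected.
    """
    col = {"class": "econo_class", "network": "yeo_network"}.get(level, level)
    if col not in atlas.columns:
        raise ValueError(f"atlas has no labeling column {col!r}")
    labels = atlas.set_index("region_id")[col]
    missing = [c for c in values.columns if c not in labels.index]
    if missing:
        raise ValueError(f"regions without atlas labels: {missing[:5]}")
    out = {}
    for lab in pd.unique(labels.loc[values.columns]):
        members = [c for c in values.columns if labels[c] == lab]
        if not members:
            raise ValueError(f"label {lab!r} has no member regions")
        out[lab] = values[members].mean(axis=1)
    return pd.DataFrame(out, index=values.index)


def ks_compare(a: np.ndarray, b: np.ndarray, method: str = "auto") -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (two-sided).

    D is the supremum distance between the two empirical CDFs; the p-value
    is exact for small samples and asymptotic at scale (``method="auto"``),
    where the two coincide.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q.reshape(np.shape(p))


@dataclass
class LabelContrast:
    """GLM + KS results at one aggregation level."""

    glm: pd.DataFrame  # label-indexed t, p, q
    ks: pd.DataFrame  # label-indexed D, p, q
    means: pd.DataFrame  # subject x label means


def label_contrast(
    values: pd.DataFrame,
    design: pd.DataFrame,
    atlas: pd.DataFrame,
    level: str = "class",
    covariates: tuple[str, ...] = ("age", "sex", "education"),
    subject_means: bool = False,
) -> LabelContrast:
    """Label-level group contrast: GLM on label means + KS on distributions.

    KS pools each group's per-subject regional gradient values within the
    label (default) or compares per-subject label means
    (``subject_means=True``).  FDR is applied across labels within this
    family only.
    """
    means = aggregate_by_label(values, atlas, level=level)
    glm = glm_contrast(means, design, covariates=covariates)

    col = {"class": "econo_class", "network": "yeo_network"}.get(level, level)
    labels = atlas.set_index("region_id")[col]
    is_ad = np.asarray(design["group"]) == "AD"
    rows = []
    for lab in means.columns:
        if subject_means:
            a, b = means.loc[is_ad, lab], means.loc[~is_ad, lab]
        else:
            members = [c for c in values.columns if labels[c] == lab]
            a = values.loc[is_ad, members].to_numpy().ravel()
            b = values.loc[~is_ad, members].to_numpy().ravel()
        d, p = ks_compare(np.asarray(a), np.asarray(b))
        rows.append((lab, d, p))
    ks = pd.DataFrame(rows, columns=["label", "D", "p"]).set_index("label")
    ks["q"] = bh_fdr(ks["p"].to_numpy())
    return LabelContrast(glm=glm, ks=ks, means=means)
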