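"""Synthetic cohorts, atlases, cognition scores and gene expression.

Everything downstream of this module (MSN construction, gradient
decomposition, group statistics, prediction, transcriptomic association)
assumes particular statistical structure in its inputs: z-scorable
morphometric features with smooth regional profiles, group- and
site-structured mean shifts, cognition scores linearly coupled to
class-level gradient summaries, and gene expression spatially correlated
with a planted group-difference map.  This module generates data with
exactly that structure so the full pipeline can be exercised and
calibrated without any restricted-access imaging or transcriptomic data.

Regions are abstract labeled units ordered along a one-dimensional axis;
regional feature means vary smoothly along that axis so that
morphometric similarity matrices have non-trivial block structure and a
meaningful principal gradient.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FEATURES",
    "VON_ECONOMO_CLASSES",
    "YEO_NETWORKS",
    "COGNITION_SCORES",
    "CohortSpec",
    "Cohort",
    "SyntheticExpression",
    "generate_cohort",
    "generate_atlas",
    "generate_cognition",
    "generate_expression",
]

#: The five morphometric features per region: cortical thickness (mm),
#: cortical volume (mm^3), cortical area (mm^2), gaussian curvature
#: (1/mm^2) and mean curvature (1/mm).  Synthetic values are on an
#: arbitrary standardized scale; only their joint regional profile matters
#: because each subject's features are z-scored across regions downstream.
FEATURES = ("CT", "CV", "CA", "GC", "MC")

VON_ECONOMO_CLASSES = (
    "Prim_sens",
    "Sec_sens",
    "Asso1",
    "Asso2",
    "Limbic",
    "Prim_motor",
    "Insula",
)

YEO_NETWORKS = ("VIS", "SOM", "DAN", "SAL", "LIM", "FPN", "DMN")

COGNITION_SCORES = ("MMSE", "ADNI_MEM", "ADNI_EF", "ADNI_VS", "ADNI_LAN")

# Fixed smooth-profile loadings: feature x basis, basis functions of the
# latent 1-D region coordinate s in [0, 1].  Chosen once so the expected
# regional 5-feature profiles vary smoothly and non-degenerately.
_PROFILE_COEF = np.array(
    [
        [1.0, 0.6, 0.3, 0.0, 0.8],
        [0.9, -0.5, 0.0, 0.4, 1.0],
        [0.7, 0.8, -0.4, 0.2, 0.6],
        [-0.6, 0.9, 0.5, -0.3, 0.2],
        [0.4, -0.7, 0.6, 0.5, -0.5],
    ]
)


def _profile_basis(s: np.ndarray) -> np.ndarray:
    """Smooth basis functions of the latent region coordinate, (5, n)."""
    # half-period leading terms keep the axis open-ended (s=0 and s=1 get
    # distinct profiles) so the principal gradient can track it
    return np.vstack(
        [
            np.sin(np.pi * s),
            np.cos(np.pi * s),
            np.sin(2 * np.pi * s),
            np.cos(2 * np.pi * s),
            2.0 * s - 1.0,
        ]
    )


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic two-group (AD vs NC) multi-site cohort.

    Parameters
    ----------
    n_regions
        Number of cortical parcels (400 at desk scale; 1533 mirrors the
        full-resolution parcellation).
    n_per_group
        ``(n_AD, n_NC)`` subject counts.
    n_sites
        Number of acquisition sites; subjects are assigned to sites
        uniformly at random within each group.
    effect_map
        Signed standardized effect per region added to every feature mean
        of AD subjects (units of the within-region noise SD, which is 1).
        ``None`` means no group effect.
    site_offsets
        ``(n_sites, 5)`` additive per-feature shifts (ComBat's location
        component).  ``None`` means no site effect.
    site_scales
        Optional ``(n_sites, 5)`` multiplicative noise-SD factors
        (ComBat's scale component).  ``None`` means all ones.
    profile_amplitude
        Amplitude of the smooth regional mean profiles relative to the
        unit noise SD; controls MSN signal-to-noise.
    """

    n_regions: int = 400
    n_per_group: tuple[int, int] = (100, 100)
    n_sites: int = 2
    effect_map: np.ndarray | None = None
    site_offsets: np.ndarray | None = None
    site_scales: np.ndarray | None = None
    profile_amplitude: float = 2.5
    age_mean: float = 73.0
    age_sd: float = 6.0
    education_mean: float = 16.0
    education_sd: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 3:
            raise ValueError(f"n_regions must be >= 3, got {self.n_regions}")
        if len(self.n_per_group) != 2 or any(n <= 0 for n in self.n_per_group):
            raise ValueError(f"n_per_group must be two positive counts, got {self.n_per_group}")
        if self.n_sites <= 0:
            raise ValueError(f"n_sites must be positive, got {self.n_sites}")
        if self.effect_map is not None:
            em = np.asarray(self.effect_map, dtype=float)
            if em.shape != (self.n_regions,):
                raise ValueError(
                    f"effect_map must have one entry per region "
                    f"(expected {self.n_regions}, got {em.shape})"
                )
            object.__setattr__(self, "effect_map", em)
        if self.site_offsets is not None:
            so = np.asarray(self.site_offsets, dtype=float)
            if so.shape != (self.n_sites, len(FEATURES)):
                raise ValueError(
                    f"site_offsets must be (n_sites, 5) = ({self.n_sites}, 5), got {so.shape}"
                )
            object.__setattr__(self, "site_offsets", so)
        if self.site_scales is not None:
            ss = np.asarray(self.site_scales, dtype=float)
            if ss.shape != (self.n_sites, len(FEATURES)):
                raise ValueError(
                    f"site_scales must be (n_sites, 5) = ({self.n_sites}, 5), got {ss.shape}"
                )
            if np.any(ss <= 0):
                raise ValueError("site_scales must be strictly positive")
            object.__setattr__(self, "site_scales", ss)


@dataclass
class Cohort:
    """Realized synthetic cohort.

    ``features`` is ``(n_subjects, n_regions, 5)`` in the order of
    ``metadata`` rows; ``metadata`` carries subject_id, group, age, sex,
    education and site.
    """

    features: np.ndarray
    metadata: pd.DataFrame
    region_ids: list[str]
    spec: CohortSpec

    def feature_table(self, subject_id: str) -> pd.DataFrame:
        """Per-subject regions x 5 feature table."""
        idx = self.metadata.index[self.metadata["subject_id"] == subject_id]
        if len(idx) == 0:
            raise KeyError(f"unknown subject_id {subject_id!r}")
        return pd.DataFrame(
            self.features[idx[0]], index=pd.Index(self.region_ids, name="region_id"),
            columns=list(FEATURES),
        )


@dataclass
class SyntheticExpression:
    """Regions x genes expression with a planted spatially-correlated subset."""

    expression: pd.DataFrame
    planted_genes: list[str]
    planted_corr: float


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a two-group multi-site cohort of regional morphometric tables.

    Each feature value is Gaussian with a smooth region-specific mean,
    unit noise SD, plus the group effect (AD only) and the site offset.
    Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_ad, n_nc = spec.n_per_group
    n_sub = n_ad + n_nc
    n_reg = spec.n_regions
    n_feat = len(FEATURES)

    s = np.linspace(0.0, 1.0, n_reg)
    mu = spec.profile_amplitude * (_PROFILE_COEF @ _profile_basis(s)).T  # (n_reg, 5)

    group = np.array(["AD"] * n_ad + ["NC"] * n_nc)
    site = rng.integers(0, spec.n_sites, size=n_sub)
    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, n_sub), 55.0, 95.0)
    sex = rng.integers(0, 2, size=n_sub)
    education = np.clip(
        rng.normal(spec.education_mean, spec.education_sd, n_sub), 8.0, 20.0
    )

    noise = rng.standard_normal((n_sub, n_reg, n_feat))
    if spec.site_scales is not None:
        noise *= spec.site_scales[site][:, None, :]
    data = mu[None, :, :] + noise
    if spec.effect_map is not None:
        data[group == "AD"] += spec.effect_map[None, :, None]
    if spec.site_offsets is not None:
        data += spec.site_offsets[site][:, None, :]

    width = len(str(n_sub))
    subject_ids = [f"sub-{i + 1:0{width}d}" for i in range(n_sub)]
    region_ids = [f"region_{i + 1:04d}" for i in range(n_reg)]
    metadata = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "group": group,
            "age": age,
            "sex": sex,
            "education": education,
            "site": [f"site_{k + 1}" for k in site],
        }
    )
    return Cohort(features=data, metadata=metadata, region_ids=region_ids, spec=spec)


def generate_atlas(
    n_regions: int, shuffled: bool = False, seed: int | None = None
) -> pd.DataFrame:
    """Assign each region a Von Economo class and a Yeo network label.

    By default both 7-level labelings are contiguous blocks along the
    region ordering, with the network blocks offset by half a block so
    the two partitions differ.  ``shuffled=True`` permutes each labeling
    independently (seeded).
    """
    if n_regions < len(VON_ECONOMO_CLASSES):
        raise ValueError(f"n_regions must be >= 7, got {n_regions}")
    idx = np.arange(n_regions)
    classes = np.array(VON_ECONOMO_CLASSES)[(idx * 7) // n_regions]
    shift = n_regions // 14  # half a block
    networks = np.array(YEO_NETWORKS)[((np.roll(idx, shift)) * 7) // n_regions]
    if shuffled:
        rng = np.random.default_rng(seed)
        classes = rng.permutation(classes)
        networks = rng.permutation(networks)
    return pd.DataFrame(
        {
            "region_id": [f"region_{i + 1:04d}" for i in range(n_regions)],
            "econo_class": classes,
            "yeo_network": networks,
        }
    )


def generate_cognition(
    gradient_class_means: pd.DataFrame,
    coupling: dict[str, float] | np.ndarray,
    noise_sd: float,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Generate the five cognition scores from class-level gradient means.

    Every score is the same linear combination of the per-subject class
    means plus independent Gaussian noise, so planted couplings can be
    recovered by the correlation and prediction analyses.  Returns the
    scores (subject x 5) and the generating weight vector (class index).
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be non-negative, got {noise_sd}")
    cols = list(gradient_class_means.columns)
    if isinstance(coupling, dict):
        unknown = set(coupling) - set(cols)
        if unknown:
            raise ValueError(f"coupling refers to unknown classes: {sorted(unknown)}")
        w = pd.Series({c: float(coupling.get(c, 0.0)) for c in cols})
    else:
        w = pd.Series(np.asarray(coupling, dtype=float), index=cols)
        if len(w) != len(cols):
            raise ValueError("coupling length must match the number of classes")
    if not np.all(np.isfinite(w.to_numpy())):
        raise ValueError("coupling weights must be finite")

    rng = np.random.default_rng(seed)
    signal = gradient_class_means.to_numpy() @ w.to_numpy()
    n = len(signal)
    scores = signal[:, None] + rng.normal(0.0, noise_sd, size=(n, len(COGNITION_SCORES)))
    frame = pd.DataFrame(scores, columns=list(COGNITION_SCORES), index=gradient_class_means.index)
    return frame, w


def generate_expression(
    region_map: np.ndarray,
    n_genes: int = 2000,
    n_planted: int = 50,
    planted_corr: float = 0.9,
    seed: int = 0,
) -> SyntheticExpression:
    """Regions x genes expression with genes planted to track a region map.

    Planted gene g is ``rho * z(map) + sqrt(1 - rho^2) * noise`` so its
    expected Pearson correlation with the map is ``planted_corr``; the
    remaining genes are independent noise.
    """
    region_map = np.asarray(region_map, dtype=float)
    if n_planted > n_genes:
        raise ValueError(f"n_planted ({n_planted}) must be <= n_genes ({n_genes})")
    if not -1.0 < planted_corr < 1.0:
        raise ValueError(f"planted_corr must lie in (-1, 1), got {planted_corr}")
    sd = region_map.std(ddof=0)
    if sd == 0 and n_planted > 0 and planted_corr != 0:
        raise ValueError(
            "region_map is constant: correlation with planted genes is undefined"
        )
    rng = np.random.default_rng(seed)
    n_reg = len(region_map)
    z = (region_map - region_map.mean()) / sd if sd > 0 else np.zeros(n_reg)
    expr = rng.standard_normal((n_reg, n_genes))
    if n_planted:
        expr[:, :n_planted] = (
            planted_corr * z[:, None]
            + np.sqrt(1.0 - planted_corr**2) * expr[:, :n_planted]
        )
    genes = [f"gene_{i + 1:05d}" for i in range(n_genes)]
    frame = pd.DataFrame(
        expr,
        index=pd.Index([f"region_{i + 1:04d}" for i in range(n_reg)], name="region_id"),
        columns=genes,
    )
    return SyntheticExpression(
        expression=frame, planted_genes=genes[:n_planted], planted_corr=planted_corr
    )
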