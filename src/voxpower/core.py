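"""Power, inflation and replication-overlap simulation for mass-univariate
voxelwise correlation studies.

The module simulates between-subject correlations between a behavioral
variable and per-voxel "activation" on a 2D in-mask grid (a horizontal brain
slice), under two designed effect scenarios:

* **Weak Diffuse (WD)** — ~72% of the slice carries weak correlations
  (|rho| in 0.05-0.14), the remainder carries even smaller nonzero effects.
* **Strong Localized (SL)** — ~3.8% of the slice carries strong correlations
  (|rho| in 0.61-0.80) concentrated in four blobs (two positive, two
  negative); everything else is exactly null.

A large full cohort is generated once per scenario; small studies are
emulated by repeatedly subsampling it, running a mass-univariate Pearson
correlation test per voxel, thresholding (uncorrected p or BH-FDR), and
scoring each repetition with: average power, at-least-one power, mean
significant |r| (winner's-curse inflation), percent significant voxels, and
Dice overlap between paired repetitions.

Alongside the simulator sit the analytic calculators used for calibration:
exact and Fisher-z-approximate power of the correlation test, Fisher-z
confidence intervals, and a type II/type I error-count balancing search for
an uncorrected threshold.

Everything is seeded and deterministic; no external data is required.

Sections below follow the order the method runs: grid/mask construction,
spatial smoothing, effect-field design, cohort generation and subsampling,
univariate statistics and thresholding, analytic power and error balancing,
replication metrics, experiment orchestration, and file I/O.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dataclass_field, replace
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, ndimage, special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("voxpower")

__all__ = [
    "GridMask",
    "ScenarioSpec",
    "EffectField",
    "CohortSample",
    "SubsampleIndex",
    "VoxelStatMap",
    "ThresholdSpec",
    "SignificanceMap",
    "TruthSet",
    "ExperimentConfig",
    "ResultsBundle",
    "UndefinedMetricError",
    "make_mask",
    "fwhm_to_sigma",
    "gaussian_kernel1d",
    "smooth_grid",
    "smooth_field",
    "smoothed_noise_sd",
    "make_effect_field",
    "generate_cohort",
    "draw_subsample",
    "correlate",
    "pearson_map",
    "critical_r",
    "threshold",
    "power_correlation",
    "ci_correlation",
    "balance_error_ratio",
    "truth_set",
    "average_power",
    "at_least_one",
    "mean_significant_effect",
    "percent_significant",
    "dice",
    "selectivity_index",
    "run_experiment",
    "bivariate_demo",
    "field_to_nifti",
    "mask_to_nifti",
    "save_field_nifti",
    "load_grid_nifti",
    "grid_to_csv",
    "grid_from_csv",
    "load_config",
]

# --------------------------------------------------------------------------
# Defaults (the study conditions)
# --------------------------------------------------------------------------

#: Grid dimensions of the simulated axial slice.
DEFAULT_SHAPE: tuple[int, int] = (90, 70)
#: Number of in-mask voxels of the simulated slice.
DEFAULT_N_VOXELS: int = 4713
#: Smoothing kernel width (full width at half maximum), in voxel units.
DEFAULT_FWHM_VOX: float = 6.0
#: Full-cohort size from which subsamples are drawn.
DEFAULT_FULL_N: int = 10_000
#: Uncorrected two-sided voxelwise significance level.
DEFAULT_ALPHA: float = 0.01
#: BH false-discovery-rate level for the FDR thresholding variant.
DEFAULT_FDR_Q: float = 0.05

_KERNEL_TRUNCATE_SD = 4.0  # kernel support is +/- 4 sigma
_COHORT_CHUNK = 1000  # subjects smoothed per block (bounds peak memory)


class UndefinedMetricError(ValueError):
    """Raised when a replication metric has an empty denominator."""


# --------------------------------------------------------------------------
# Grid mask
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GridMask:
    """Boolean in-mask map on a rectangular grid.

    ``inside`` marks which grid cells belong to the analysis domain (the
    "brain" voxels). Per-voxel vectors throughout this module are ordered by
    the row-major traversal of the true cells of ``inside``.
    """

    shape: tuple[int, int]
    inside: np.ndarray  # bool, shape == self.shape

    @property
    def n_voxels(self) -> int:
        return int(self.inside.sum())

    def embed(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a per-voxel vector back onto the full 2D grid."""
        values = np.asarray(values)
        if values.shape[-1] != self.n_voxels:
            raise ValueError(
                f"expected {self.n_voxels} per-voxel values, got {values.shape[-1]}"
            )
        grid = np.full(self.shape, fill, dtype=float)
        grid[self.inside] = values
        return grid

    def extract(self, grid: np.ndarray) -> np.ndarray:
        """Restrict a full-grid field to the in-mask voxels (row-major)."""
        grid = np.asarray(grid)
        if grid.shape[-2:] != self.shape:
            raise ValueError(f"grid shape {grid.shape} does not match mask {self.shape}")
        return grid[..., self.inside]


def make_mask(shape: tuple[int, int] = DEFAULT_SHAPE,
              target_voxels: int = DEFAULT_N_VOXELS) -> GridMask:
    """Build an elliptical mask with an exact in-mask voxel count.

    Cells are ranked by their scaled elliptical distance from the grid
    center (semi-axes proportional to the grid dimensions) and the closest
    ``target_voxels`` cells are taken. Ties are broken deterministically in
    row-major order, so the count is exact and the mask reproducible.
    """
    rows, cols = int(shape[0]), int(shape[1])
    if rows < 1 or cols < 1:
        raise ValueError(f"invalid grid shape {shape!r}")
    if target_voxels < 1:
        raise ValueError(f"target_voxels must be >= 1, got {target_voxels}")
    if target_voxels > rows * cols:
        raise ValueError(
            f"target_voxels={target_voxels} exceeds grid capacity {rows * cols}"
        )
    r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    # Scaled elliptical distance; semi-axes a=rows/2, b=cols/2.
    dist = ((rr - r0) / (rows / 2.0)) ** 2 + ((cc - c0) / (cols / 2.0)) ** 2
    order = np.argsort(dist.ravel(), kind="stable")  # row-major tie-break
    inside = np.zeros(rows * cols, dtype=bool)
    inside[order[:target_voxels]] = True
    return GridMask(shape=(rows, cols), inside=inside.reshape(rows, cols))


# --------------------------------------------------------------------------
# Spatial smoothing
# --------------------------------------------------------------------------


def fwhm_to_sigma(fwhm_vox: float) -> float:
    """Convert a Gaussian kernel's FWHM to its standard deviation.

    FWHM = 2 sqrt(2 ln 2) * sigma, so sigma = FWHM / 2.35482...
    """
    if not fwhm_vox > 0:
        raise ValueError(f"FWHM must be positive, got {fwhm_vox}")
    return float(fwhm_vox) / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def gaussian_kernel1d(fwhm_vox: float) -> np.ndarray:
    """Sampled, sum-normalized 1D Gaussian kernel truncated at +/- 4 sigma."""
    sigma = fwhm_to_sigma(fwhm_vox)
    radius = int(_KERNEL_TRUNCATE_SD * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def smooth_grid(values: np.ndarray, fwhm_vox: float) -> np.ndarray:
    """Convolve full-grid field(s) with an isotropic 2D Gaussian.

    Zero-padded (constant 0) boundaries; the kernel is separable, so the two
    spatial axes are filtered independently. ``values`` may carry leading
    batch axes; the last two axes are treated as (rows, cols).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim < 2:
        raise ValueError("values must be at least 2D (rows, cols)")
    k = gaussian_kernel1d(fwhm_vox)
    out = ndimage.correlate1d(values, k, axis=-2, mode="constant", cval=0.0)
    return ndimage.correlate1d(out, k, axis=-1, mode="constant", cval=0.0)


def smooth_field(values: np.ndarray, fwhm_vox: float, mask: GridMask) -> np.ndarray:
    """Smooth a full-grid field and restrict it to the in-mask voxels."""
    return mask.extract(smooth_grid(values, fwhm_vox))


@lru_cache(maxsize=16)
def _noise_sd_grid(shape: tuple[int, int], fwhm_vox: float) -> np.ndarray:
    """Per-cell standard deviation of zero-padded smoothed unit white noise.

    With a separable kernel k and zero padding, the variance at cell (i, j)
    factorizes into row and column sums of squared kernel weights over the
    in-grid support, computed here exactly (no simulation).
    """
    k2 = gaussian_kernel1d(fwhm_vox) ** 2
    rows, cols = shape
    vrow = ndimage.correlate1d(np.ones(rows), k2, mode="constant", cval=0.0)
    vcol = ndimage.correlate1d(np.ones(cols), k2, mode="constant", cval=0.0)
    out = np.sqrt(np.outer(vrow, vcol))
    out.setflags(write=False)
    return out


def smoothed_noise_sd(shape: tuple[int, int], fwhm_vox: float) -> np.ndarray:
    """Deterministic per-cell sd of the smoothing operator on white noise."""
    return _noise_sd_grid((int(shape[0]), int(shape[1])), float(fwhm_vox))


# --------------------------------------------------------------------------
# Designed effect fields (the two scenarios)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of a designed brain-behavior correlation scenario.

    ``effect_fraction`` is the proportion of in-mask voxels carrying the
    named effect band; ``r_band`` gives the absolute-correlation bounds of
    that band; ``fwhm_vox`` the smoothing kernel FWHM in voxel units.
    """

    kind: Literal["WD", "SL"]
    effect_fraction: float
    r_band: tuple[float, float]
    fwhm_vox: float = DEFAULT_FWHM_VOX
    shape: tuple[int, int] = DEFAULT_SHAPE
    target_voxels: int = DEFAULT_N_VOXELS
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.r_band
        if not (0.0 < lo < hi < 1.0):
            raise ValueError(f"require 0 < r_band.low < r_band.high < 1, got {self.r_band}")
        if not (0.0 < self.effect_fraction <= 1.0):
            raise ValueError(f"effect_fraction must be in (0, 1], got {self.effect_fraction}")
        if self.kind not in ("WD", "SL"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")

    @classmethod
    def weak_diffuse(cls, seed: int = 0, **kw) -> "ScenarioSpec":
        """Weak Diffuse defaults: 72% of voxels with |rho| in [0.05, 0.14]."""
        return cls(kind="WD", effect_fraction=0.72, r_band=(0.05, 0.14), seed=seed, **kw)

    @classmethod
    def strong_localized(cls, seed: int = 0, **kw) -> "ScenarioSpec":
        """Strong Localized defaults: 3.8% of voxels with |rho| in [0.61, 0.80]."""
        return cls(kind="SL", effect_fraction=0.038, r_band=(0.61, 0.80), seed=seed, **kw)


@dataclass(frozen=True)
class EffectField:
    """Designed per-voxel population correlation rho between activity and
    behavior, together with the mask it lives on and the band membership."""

    mask: GridMask
    rho: np.ndarray  # float, (n_voxels,)
    band_mask: np.ndarray  # bool, (n_voxels,)
    spec: ScenarioSpec

    def __post_init__(self) -> None:
        if np.any(np.abs(self.rho) >= 1.0):
            raise ValueError("all designed |rho| must be < 1")
        if self.rho.shape != (self.mask.n_voxels,):
            raise ValueError("rho length must equal the number of in-mask voxels")


def _rank_map_linear(magnitudes: np.ndarray, lo: float, hi: float,
                     endpoint: bool = True) -> np.ndarray:
    """Map magnitudes monotonically by rank onto [lo, hi] (largest -> hi).

    With ``endpoint=False`` the top of the range is approached but excluded,
    i.e. values land in [lo, hi). A single element maps to hi (or to lo when
    the endpoint is excluded).
    """
    m = magnitudes.size
    if m == 1:
        return np.array([hi if endpoint else lo])
    order = np.argsort(magnitudes, kind="stable")  # ascending; stable ties
    levels = np.linspace(lo, hi, num=m, endpoint=endpoint)
    out = np.empty(m)
    out[order] = levels
    return out


def _wd_field(spec: ScenarioSpec, mask: GridMask) -> tuple[np.ndarray, np.ndarray]:
    """Weak Diffuse: smoothed Gaussian random field, rank-rescaled so that an
    exact count of voxels falls in the effect band and the rest carry small
    nonzero effects; signs inherited from the smoothed field."""
    rng = np.random.default_rng(spec.seed)
    raw = smooth_field(rng.standard_normal(mask.shape), spec.fwhm_vox, mask)
    n_vox = mask.n_voxels
    n_band = int(round(spec.effect_fraction * n_vox))
    if n_band == 0:
        raise ValueError("effect band is empty: round(effect_fraction * n_voxels) == 0")
    lo, hi = spec.r_band
    absval = np.abs(raw)
    order = np.argsort(-absval, kind="stable")  # descending |value|
    band_idx, rest_idx = order[:n_band], order[n_band:]
    rho = np.empty(n_vox)
    rho[band_idx] = _rank_map_linear(absval[band_idx], lo, hi)
    if rest_idx.size:
        # continuation of the field: small but strictly nonzero, below the band
        rho[rest_idx] = _rank_map_linear(absval[rest_idx], 0.1 * lo, lo, endpoint=False)
    rho *= np.where(np.signbit(raw), -1.0, 1.0)
    band = np.zeros(n_vox, dtype=bool)
    band[band_idx] = True
    return rho, band


#: SL blob layout: (row offset, col offset) from the grid center as a
#: fraction of the grid dimensions, and the sign of the blob's effect.
_SL_BLOBS: tuple[tuple[float, float, float], ...] = (
    (-0.17, -0.17, +1.0),
    (-0.17, +0.17, -1.0),
    (+0.17, -0.17, -1.0),
    (+0.17, +0.17, +1.0),
)
_SL_BLOB_SIGMA = 3.0  # Gaussian radial profile sd of each blob, in voxels


def _sl_field(spec: ScenarioSpec, mask: GridMask) -> tuple[np.ndarray, np.ndarray]:
    """Strong Localized: four circular Gaussian-profile blobs (two positive,
    two negative) at deterministic well-separated locations; the top-profile
    cells are selected to an exact count and rank-mapped within each blob
    onto the effect band (centers highest); all other voxels exactly zero."""
    rows, cols = mask.shape
    r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    profiles = []
    for dr, dc, sign in _SL_BLOBS:
        d2 = (rr - (r0 + dr * rows)) ** 2 + (cc - (c0 + dc * cols)) ** 2
        profiles.append(np.exp(-0.5 * d2 / _SL_BLOB_SIGMA**2))
    prof = np.stack(profiles)  # (4, rows, cols)
    prof_vox = mask.extract(prof)  # (4, n_voxels)
    combined = prof_vox.max(axis=0)
    owner = prof_vox.argmax(axis=0)

    n_vox = mask.n_voxels
    n_eff = int(round(spec.effect_fraction * n_vox))
    if n_eff == 0:
        raise ValueError("effect band is empty: round(effect_fraction * n_voxels) == 0")
    sel = np.argsort(-combined, kind="stable")[:n_eff]
    lo, hi = spec.r_band
    rho = np.zeros(n_vox)
    for b, (_, _, sign) in enumerate(_SL_BLOBS):
        idx = sel[owner[sel] == b]
        if idx.size:
            rho[idx] = sign * _rank_map_linear(combined[idx], lo, hi)
    band = rho != 0.0
    if not (np.any(rho > 0) and np.any(rho < 0)):
        raise RuntimeError("SL construction must yield both effect signs")
    return rho, band


def make_effect_field(spec: ScenarioSpec) -> EffectField:
    """Construct the designed per-voxel correlation map for a scenario.

    Deterministic given ``spec.seed``; band counts are exact:
    ``round(effect_fraction * n_voxels)`` voxels have |rho| in ``r_band``.
    """
    mask = make_mask(spec.shape, spec.target_voxels)
    if spec.kind == "WD":
        rho, band = _wd_field(spec, mask)
    else:
        rho, band = _sl_field(spec, mask)
    return EffectField(mask=mask, rho=rho, band_mask=band, spec=spec)


# --------------------------------------------------------------------------
# Cohort generation & subsampling
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSample:
    """Simulated cohort: a behavior score per subject and a subjects x voxels
    activation matrix with designed population correlations.

    Construction guarantees corr(activity[:, v], behavior) == rho_v at the
    population level: activation mixes the behavior into spatially smoothed,
    per-voxel variance-renormalized Gaussian noise,
    ``x_v = rho_v * y + sqrt(1 - rho_v^2) * eps_v``.
    """

    n: int
    behavior: np.ndarray  # (n,)
    activity: np.ndarray  # (n, n_voxels)
    field: EffectField
    seed: int


def generate_cohort(field: EffectField, n: int,
                    noise_fwhm_vox: float = DEFAULT_FWHM_VOX,
                    seed: int = 0) -> CohortSample:
    """Draw a cohort of ``n`` subjects from an effect field.

    Behavior is iid standard normal. Each subject's noise field is iid
    standard normal on the full grid, Gaussian-smoothed (``noise_fwhm_vox``),
    restricted to the mask, and divided by the exact per-voxel sd of the
    smoothing operator so every voxel's noise has unit variance while
    retaining spatial autocorrelation. Mean activation is zero; Pearson
    correlation is location-invariant, so means never enter the metrics.
    """
    if n < 4:
        raise ValueError(f"need n >= 4 subjects (correlation df = n - 2), got {n}")
    mask = field.mask
    rng = np.random.default_rng(seed)
    y = rng.standard_normal(n)
    sd = smoothed_noise_sd(mask.shape, noise_fwhm_vox)
    rho = field.rho
    mix = np.sqrt(1.0 - rho**2)
    X = np.empty((n, mask.n_voxels))
    for start in range(0, n, _COHORT_CHUNK):
        stop = min(start + _COHORT_CHUNK, n)
        eps = rng.standard_normal((stop - start, *mask.shape))
        eps = smooth_grid(eps, noise_fwhm_vox) / sd
        X[start:stop] = rho * y[start:stop, None] + mix * mask.extract(eps)
    return CohortSample(n=n, behavior=y, activity=X, field=field, seed=seed)


@dataclass(frozen=True)
class SubsampleIndex:
    """Distinct subject row indices selecting a subsample of a cohort."""

    parent: CohortSample
    indices: np.ndarray

    @property
    def n_sub(self) -> int:
        return int(self.indices.size)


def draw_subsample(parent: CohortSample, n_sub: int,
                   seed: int | Sequence[int] = 0) -> SubsampleIndex:
    """Draw ``n_sub`` distinct subjects uniformly without replacement."""
    if not (4 <= n_sub <= parent.n):
        raise ValueError(f"n_sub must be in [4, {parent.n}], got {n_sub}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(parent.n, size=n_sub, replace=False)
    return SubsampleIndex(parent=parent, indices=idx)


# --------------------------------------------------------------------------
# Mass-univariate correlation testing
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class VoxelStatMap:
    """Per-voxel sample Pearson r, t statistic and two-sided p-value."""

    n: int
    r: np.ndarray
    t: np.ndarray
    p: np.ndarray


def pearson_map(y: np.ndarray, X: np.ndarray) -> VoxelStatMap:
    """Pearson correlation of each column of ``X`` against ``y``.

    Two-sided p-values come from the t distribution with n - 2 degrees of
    freedom via t = r sqrt((n-2)/(1-r^2)). A constant column has no defined
    correlation; it is reported as r = 0, p = 1 with a logged warning.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.size
    if n < 4:
        raise ValueError(f"need n >= 4 observations, got {n}")
    if X.shape[0] != n:
        raise ValueError("X rows must match the length of y")
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    y_ss = float(yc @ yc)
    x_ss = np.einsum("ij,ij->j", Xc, Xc)
    degenerate = x_ss <= 0.0
    if degenerate.any():
        logger.warning("%d constant activation column(s): reporting r=0, p=1",
                       int(degenerate.sum()))
    denom = np.sqrt(np.where(degenerate, 1.0, x_ss) * y_ss)
    r = np.clip((yc @ Xc) / denom, -1.0, 1.0)
    r[degenerate] = 0.0
    df = n - 2
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.isinf(t)] = 0.0
    p[degenerate] = 1.0
    return VoxelStatMap(n=n, r=r, t=t, p=p)


def correlate(sample: CohortSample, subsample: SubsampleIndex | None = None) -> VoxelStatMap:
    """Mass-univariate correlation map of a cohort or one of its subsamples."""
    if subsample is None:
        return pearson_map(sample.behavior, sample.activity)
    if subsample.parent is not sample:
        raise ValueError("subsample was drawn from a different cohort")
    idx = subsample.indices
    return pearson_map(sample.behavior[idx], sample.activity[idx])


def critical_r(alpha: float, n: int) -> float:
    """Absolute sample correlation at which the two-sided p equals alpha.

    r* = t* / sqrt(t*^2 + n - 2) with t* the upper alpha/2 t quantile at
    n - 2 df; |r| >= r* is equivalent to p <= alpha.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    t_star = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(t_star / math.sqrt(t_star**2 + n - 2))


@dataclass(frozen=True)
class ThresholdSpec:
    """Voxelwise significance rule: uncorrected p < alpha, or BH-FDR at q."""

    method: Literal["uncorrected", "fdr_bh"] = "uncorrected"
    level: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise ValueError(f"level must be in (0, 1), got {self.level}")
        if self.method not in ("uncorrected", "fdr_bh"):
            raise ValueError(f"unknown threshold method {self.method!r}")


@dataclass(frozen=True)
class SignificanceMap:
    """Boolean per-voxel significance under a given threshold rule."""

    sig: np.ndarray
    threshold: ThresholdSpec
    source: VoxelStatMap


def threshold(statmap: VoxelStatMap, spec: ThresholdSpec = ThresholdSpec()) -> SignificanceMap:
    """Apply a significance threshold to a voxel statistic map.

    ``uncorrected`` rejects where p < alpha. ``fdr_bh`` runs the
    Benjamini-Hochberg step-up over all in-mask p-values at level q.
    """
    if spec.method == "uncorrected":
        sig = statmap.p < spec.level
    else:
        sig = multipletests(statmap.p, alpha=spec.level, method="fdr_bh")[0]
    return SignificanceMap(sig=np.asarray(sig, dtype=bool), threshold=spec, source=statmap)


# --------------------------------------------------------------------------
# Analytic power, confidence intervals, error balancing
# --------------------------------------------------------------------------


def _exact_r_density(r: np.ndarray, rho: float, n: int) -> np.ndarray:
    """Exact sampling density of the Pearson correlation under bivariate
    normality (Hotelling's hypergeometric form)::

        f(r) = (n-2) G(n-1) (1-rho^2)^((n-1)/2) (1-r^2)^((n-4)/2)
               / (sqrt(2 pi) G(n-1/2) (1-rho r)^(n-3/2))
               * 2F1(1/2, 1/2; n-1/2; (rho r + 1)/2)
    """
    r = np.asarray(r, dtype=float)
    log_c = (
        math.log(n - 2)
        + special.gammaln(n - 1)
        - 0.5 * math.log(2.0 * math.pi)
        - special.gammaln(n - 0.5)
        + 0.5 * (n - 1) * math.log1p(-rho**2)
    )
    with np.errstate(divide="ignore"):
        log_f = (
            log_c
            + 0.5 * (n - 4) * np.log1p(-r**2)
            - (n - 1.5) * np.log1p(-rho * r)
        )
    return np.exp(log_f) * special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1.0) / 2.0)


def _power_exact(rho: float, n: int, alpha: float) -> float:
    """Two-sided rejection probability by adaptive quadrature of the exact
    r density over |r| >= critical_r(alpha, n). Absolute tolerance 1e-7."""
    rc = critical_r(alpha, n)
    upper, _ = integrate.quad(_exact_r_density, rc, 1.0, args=(rho, n),
                              epsabs=1e-7, limit=200)
    lower, _ = integrate.quad(_exact_r_density, -1.0, -rc, args=(rho, n),
                              epsabs=1e-7, limit=200)
    return float(min(1.0, upper + lower))


def _power_fisher(rho: np.ndarray, n: int, alpha: float,
                  bias_correction: bool = True) -> np.ndarray:
    """Fisher-z normal approximation of the two-sided power.

    z(r) is approximately normal with mean atanh(rho) + rho/(2(n-1)) (the
    mean-bias term, optional) and sd 1/sqrt(n-3).
    """
    rho = np.asarray(rho, dtype=float)
    z_rho = np.arctanh(rho)
    if bias_correction:
        z_rho = z_rho + rho / (2.0 * (n - 1))
    z_c = math.atanh(critical_r(alpha, n))
    sd = 1.0 / math.sqrt(n - 3)
    return stats.norm.cdf((z_rho - z_c) / sd) + stats.norm.cdf((-z_c - z_rho) / sd)


def power_correlation(rho, n: int, alpha: float,
                      method: Literal["exact", "fisher_approx"] = "exact",
                      bias_correction: bool = True):
    """Two-sided power of the Pearson correlation significance test.

    Parameters
    ----------
    rho
        Population correlation(s) in (-1, 1). Arrays are accepted with the
        ``fisher_approx`` method (and looped over for ``exact``).
    n
        Sample size (>= 4; the test has n - 2 degrees of freedom).
    alpha
        Two-sided significance level in (0, 1).
    method
        ``exact`` integrates the exact sampling distribution of r;
        ``fisher_approx`` uses the Fisher-z normal approximation.
    bias_correction
        Include the rho/(2(n-1)) mean-bias term in the Fisher approximation.

    Returns
    -------
    Power in [0, 1], scalar for scalar input.
    """
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    rho_arr = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho_arr) >= 1.0):
        raise ValueError("|rho| must be < 1")
    if method == "fisher_approx":
        out = _power_fisher(rho_arr, n, alpha, bias_correction)
    elif method == "exact":
        out = np.vectorize(lambda q: _power_exact(float(q), n, alpha))(rho_arr)
    else:
        raise ValueError(f"unknown power method {method!r}")
    return float(out) if np.isscalar(rho) else out


def ci_correlation(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a sample correlation:
    tanh(atanh(r) +/- z_{(1+level)/2} / sqrt(n - 3))."""
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")
    if abs(r) >= 1.0:
        if abs(r) == 1.0:
            logger.warning("|r| = 1: returning the degenerate interval (r, r)")
            return (float(r), float(r))
        raise ValueError(f"|r| must be <= 1, got {r}")
    z = math.atanh(r)
    half = stats.norm.ppf((1.0 + level) / 2.0) / math.sqrt(n - 3)
    return (math.tanh(z - half), math.tanh(z + half))


def _error_counts_analytic(field: EffectField, n: int, band_min: float):
    """Return FN(alpha), FP(alpha) expected-count functions from voxelwise
    analytic (Fisher-approximate) rejection probabilities."""
    effect = np.abs(field.rho) >= band_min
    comparison = ~effect
    rho_eff, rho_cmp = field.rho[effect], field.rho[comparison]

    def counts(alpha: float) -> tuple[float, float]:
        fn = float(np.sum(1.0 - _power_fisher(rho_eff, n, alpha)))
        fp = float(np.sum(_power_fisher(rho_cmp, n, alpha)))
        return fn, fp

    return counts, int(effect.sum()), int(comparison.sum())


def _error_counts_simulated(field: EffectField, n: int, band_min: float,
                            n_reps: int, seed: int):
    """Monte-Carlo FN/FP expected-count functions: p-values from ``n_reps``
    independent cohorts of size ``n`` are drawn once and counted per alpha."""
    effect = np.abs(field.rho) >= band_min
    comparison = ~effect
    p_eff = np.empty((n_reps, int(effect.sum())))
    p_cmp = np.empty((n_reps, int(comparison.sum())))
    for i in range(n_reps):
        cohort = generate_cohort(field, n, field.spec.fwhm_vox,
                                 seed=np.random.default_rng([seed, i]).integers(2**31))
        stat = correlate(cohort)
        p_eff[i] = stat.p[effect]
        p_cmp[i] = stat.p[comparison]

    def counts(alpha: float) -> tuple[float, float]:
        fn = float(np.mean(np.sum(p_eff >= alpha, axis=1)))
        fp = float(np.mean(np.sum(p_cmp < alpha, axis=1)))
        return fn, fp

    return counts, int(effect.sum()), int(comparison.sum())


def balance_error_ratio(field: EffectField, n: int, target_ratio: float = 4.0,
                        band_min: float = 0.05,
                        mode: Literal["analytic", "sim"] = "analytic",
                        n_reps: int = 2000, seed: int = 0,
                        alpha_bounds: tuple[float, float] = (1e-6, 0.999),
                        tol: float = 1e-4) -> float:
    """Find the uncorrected threshold balancing type II vs type I error counts.

    Effect voxels are those with |rho| >= ``band_min``; the rest are
    comparison voxels. At threshold alpha, FN(alpha) is the expected count of
    non-significant effect voxels and FP(alpha) the expected count of
    significant comparison voxels. The returned alpha solves
    FN(alpha)/FP(alpha) = ``target_ratio`` by bisection; the ratio is
    strictly decreasing in alpha so the root is unique.

    ``mode='analytic'`` uses voxelwise Fisher-approximate rejection
    probabilities (fast, deterministic); ``mode='sim'`` estimates the counts
    from ``n_reps`` freshly generated cohorts of size ``n``.
    """
    if target_ratio <= 0:
        raise ValueError(f"target_ratio must be positive, got {target_ratio}")
    if mode == "analytic":
        counts, n_eff, n_cmp = _error_counts_analytic(field, n, band_min)
    elif mode == "sim":
        counts, n_eff, n_cmp = _error_counts_simulated(field, n, band_min, n_reps, seed)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if n_cmp == 0:
        raise UndefinedMetricError("no comparison voxels: the error ratio is undefined")
    if n_eff == 0:
        raise UndefinedMetricError("no effect voxels: the error ratio is undefined")

    def ratio(alpha: float) -> float:
        fn, fp = counts(alpha)
        if fp == 0.0:
            return math.inf
        return fn / fp

    lo, hi = alpha_bounds
    r_lo, r_hi = ratio(lo), ratio(hi)
    if not (r_hi <= target_ratio <= r_lo):
        raise ValueError(
            f"no solution on alpha in ({lo}, {hi}): "
            f"ratio({lo}) = {r_lo:.4g}, ratio({hi}) = {r_hi:.4g}, target = {target_ratio}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if ratio(mid) > target_ratio:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# --------------------------------------------------------------------------
# Replication metrics
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TruthSet:
    """Which voxels count as true effects when scoring a subsample.

    Modes: ``designed_any`` (rho != 0), ``designed_band``
    (|rho| >= band_min), ``fullsample_sig`` (significant in the full cohort
    under a given threshold).
    """

    mode: Literal["designed_any", "designed_band", "fullsample_sig"]
    true_mask: np.ndarray


def truth_set(field: EffectField,
              mode: Literal["designed_any", "designed_band", "fullsample_sig"] = "designed_any",
              band_min: float | None = None,
              full_sig: SignificanceMap | None = None) -> TruthSet:
    """Build the truth mask used as the power/overlap denominator."""
    if mode == "designed_any":
        mask = field.rho != 0.0
    elif mode == "designed_band":
        if band_min is None:
            band_min = field.spec.r_band[0]
        mask = np.abs(field.rho) >= band_min
    elif mode == "fullsample_sig":
        if full_sig is None:
            raise ValueError("fullsample_sig mode needs the full-cohort significance map")
        mask = full_sig.sig.copy()
    else:
        raise ValueError(f"unknown truth mode {mode!r}")
    return TruthSet(mode=mode, true_mask=np.asarray(mask, dtype=bool))


def average_power(sig: SignificanceMap, truth: TruthSet) -> float:
    """Fraction of true-effect voxels attaining significance."""
    n_true = int(truth.true_mask.sum())
    if n_true == 0:
        raise UndefinedMetricError("empty truth set: average power is undefined")
    return float(np.sum(sig.sig & truth.true_mask) / n_true)


def at_least_one(sig: SignificanceMap, truth: TruthSet) -> bool:
    """Whether at least one true-effect voxel attained significance."""
    if not truth.true_mask.any():
        raise UndefinedMetricError("empty truth set: at-least-one power is undefined")
    return bool(np.any(sig.sig & truth.true_mask))


def mean_significant_effect(statmap: VoxelStatMap, sig: SignificanceMap) -> float:
    """Mean |r| over significant voxels; NaN (undefined) if none are."""
    if not sig.sig.any():
        return float("nan")
    return float(np.mean(np.abs(statmap.r[sig.sig])))


def percent_significant(sig: SignificanceMap) -> float:
    """Percentage of in-mask voxels attaining significance."""
    return 100.0 * float(sig.sig.mean())


def dice(sig_i: SignificanceMap, sig_j: SignificanceMap) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|) of two significance maps; NaN if both
    maps are empty."""
    a, b = sig_i.sig, sig_j.sig
    if a.shape != b.shape:
        raise ValueError("significance maps live on different masks")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return float("nan")
    return 2.0 * float(np.sum(a & b)) / total


def selectivity_index(sig: SignificanceMap, roi: np.ndarray) -> float:
    """Spatial selectivity of an effect relative to a region of interest.

    Defined here as 1 minus the fraction of out-of-ROI voxels that are
    significant: 1 means the effect is confined to the ROI, 0 means the
    whole out-of-ROI slice shows it. This is this package's own
    operationalization of "how specific is the ROI finding".
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != sig.sig.shape:
        raise ValueError("roi must be a per-voxel boolean of the same mask")
    n_out = int((~roi).sum())
    if n_out == 0 or not roi.any():
        raise ValueError("roi must be a nonempty strict subset of the mask")
    return 1.0 - float(np.sum(sig.sig & ~roi)) / n_out


# --------------------------------------------------------------------------
# Experiment orchestration
# --------------------------------------------------------------------------

_METRICS = ("avg_power", "alo", "mean_sig_abs_r", "pct_sig", "dice_prev")


@dataclass(frozen=True)
class ExperimentConfig:
    """Full subsampling-experiment configuration.

    ``n_grid`` defaults to sample sizes 10, 20, ..., 150 with ``n_reps``
    repetitions per size; repetitions are paired (0,1), (2,3), ... for the
    Dice replication overlap, hence ``n_reps`` must be even.
    """

    scenario: ScenarioSpec
    full_n: int = DEFAULT_FULL_N
    n_grid: tuple[int, ...] = tuple(range(10, 151, 10))
    n_reps: int = 2000
    threshold: ThresholdSpec = dataclass_field(default_factory=ThresholdSpec)
    truth_mode: Literal["designed_any", "designed_band", "fullsample_sig"] = "designed_any"
    master_seed: int = 0
    regenerate_cohort_per_rep: bool = False
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if max(self.n_grid) > self.full_n:
            raise ValueError("max(n_grid) must not exceed full_n")
        if self.n_reps < 2 or self.n_reps % 2:
            raise ValueError("n_reps must be even and >= 2 (Dice pairing)")


@dataclass(frozen=True)
class ResultsBundle:
    """Outputs of one experiment: tidy per-repetition records, aggregated
    metric curves, the effect field, and the paths written (if any)."""

    config: ExperimentConfig
    field: EffectField
    records: pd.DataFrame
    curves: pd.DataFrame
    paths: dict[str, str]


def _aggregate_curves(records: pd.DataFrame, scenario: str) -> pd.DataFrame:
    """Mean and 95% percentile interval (2.5/97.5) per size and metric,
    NaN (undefined) repetitions excluded with their count reported."""
    rows = []
    for (n_sub, metric), grp in records.groupby(["n_sub", "metric"], sort=True):
        vals = grp["value"].to_numpy(dtype=float)
        defined = vals[~np.isnan(vals)]
        if defined.size:
            mean = float(defined.mean())
            lo, hi = np.percentile(defined, [2.5, 97.5])
        else:
            mean = lo = hi = float("nan")
        rows.append({"scenario": scenario, "n_sub": int(n_sub), "metric": metric,
                     "mean": mean, "lo95": float(lo), "hi95": float(hi),
                     "n_defined": int(defined.size)})
    return pd.DataFrame(rows)


def run_experiment(config: ExperimentConfig) -> ResultsBundle:
    """Run the full subsampling experiment for one scenario.

    Builds the effect field, generates the full cohort once (unless
    ``regenerate_cohort_per_rep``), then for every size in ``n_grid`` draws
    ``n_reps`` subsamples, computes the voxelwise correlation map, applies
    the threshold, and records all replication metrics. Writes
    ``records.csv``, ``curves.csv`` and NIfTI field/truth maps when
    ``output_dir`` is set; every output is a pure function of the config and
    ``master_seed``.
    """
    import time

    spec = config.scenario
    logger.info("building %s effect field (%d voxels)", spec.kind, spec.target_voxels)
    field = make_effect_field(spec)
    logger.info("generating full cohort (n = %d)", config.full_n)
    cohort = generate_cohort(field, config.full_n, spec.fwhm_vox,
                             seed=config.master_seed)
    if config.truth_mode == "fullsample_sig":
        truth = truth_set(field, "fullsample_sig",
                          full_sig=threshold(correlate(cohort), config.threshold))
    else:
        truth = truth_set(field, config.truth_mode)

    rows = []
    for size_idx, n_sub in enumerate(config.n_grid):
        t0 = time.perf_counter()
        sigs: list[SignificanceMap] = []
        for rep in range(config.n_reps):
            if config.regenerate_cohort_per_rep:
                rep_seed = np.random.default_rng(
                    [config.master_seed, size_idx, rep, 1]).integers(2**31)
                sub_cohort = generate_cohort(field, n_sub, spec.fwhm_vox, seed=rep_seed)
                stat = correlate(sub_cohort)
            else:
                sub = draw_subsample(cohort, n_sub,
                                     seed=[config.master_seed, size_idx, rep])
                stat = correlate(cohort, sub)
            sig = threshold(stat, config.threshold)
            sigs.append(sig)
            rows.append((n_sub, rep, "avg_power", average_power(sig, truth)))
            rows.append((n_sub, rep, "alo", float(at_least_one(sig, truth))))
            rows.append((n_sub, rep, "mean_sig_abs_r", mean_significant_effect(stat, sig)))
            rows.append((n_sub, rep, "pct_sig", percent_significant(sig)))
        # disjoint replication pairs: (0,1), (2,3), ...; value stored at the
        # even repetition index
        for rep in range(0, config.n_reps, 2):
            rows.append((n_sub, rep, "dice_prev", dice(sigs[rep], sigs[rep + 1])))
        logger.info("n_sub = %3d: %d reps in %.2f s", n_sub, config.n_reps,
                    time.perf_counter() - t0)

    records = pd.DataFrame(rows, columns=["n_sub", "rep", "metric", "value"])
    records.insert(0, "scenario", spec.kind)
    curves = _aggregate_curves(records, spec.kind)

    paths: dict[str, str] = {}
    if config.output_dir is not None:
        paths = _write_bundle(config, field, truth, records, curves)
    return ResultsBundle(config=config, field=field, records=records,
                         curves=curves, paths=paths)


def bivariate_demo(rho: float = 0.3, full_n: int = DEFAULT_FULL_N,
                   n_grid: Sequence[int] = tuple(range(10, 151, 10)),
                   reps_per_size: int = 30, alpha: float = 0.05,
                   seed: int = 0) -> dict:
    """Single-variable analogue of the experiment (sampling-error demo).

    One pair of variables with population correlation ``rho`` is sampled at
    ``full_n``; per subsample size, ``reps_per_size`` subsamples record the
    sample r and its significance at ``alpha``. Returns the full-sample r, a
    tidy per-draw table and a per-size summary (proportion significant,
    min/max r) suitable for plotting or animation.
    """
    if not -1.0 < rho < 1.0:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    rng = np.random.default_rng(seed)
    y = rng.standard_normal(full_n)
    x = rho * y + math.sqrt(1.0 - rho**2) * rng.standard_normal(full_n)
    full_r = float(stats.pearsonr(x, y).statistic)
    rows = []
    for n_sub in n_grid:
        for rep in range(reps_per_size):
            idx = rng.choice(full_n, size=n_sub, replace=False)
            res = stats.pearsonr(x[idx], y[idx])
            rows.append({"n_sub": int(n_sub), "rep": rep,
                         "r": float(res.statistic), "p": float(res.pvalue),
                         "significant": bool(res.pvalue < alpha)})
    draws = pd.DataFrame(rows)
    summary = (draws.groupby("n_sub")
               .agg(prop_significant=("significant", "mean"),
                    min_r=("r", "min"), max_r=("r", "max"),
                    mean_r=("r", "mean"))
               .reset_index())
    return {"full_r": full_r, "draws": draws, "summary": summary,
            "rho": rho, "alpha": alpha}


# --------------------------------------------------------------------------
# File I/O: NIfTI / CSV / YAML configuration
# --------------------------------------------------------------------------


def field_to_nifti(field: EffectField):
    """Effect field as a float32 NIfTI volume (rows x cols x 1 slice)."""
    import nibabel as nib

    data = field.mask.embed(field.rho).astype(np.float32)[..., None]
    return nib.Nifti1Image(data, affine=np.eye(4))


def mask_to_nifti(mask: GridMask):
    """Grid mask as a uint8 NIfTI volume (rows x cols x 1 slice)."""
    import nibabel as nib

    return nib.Nifti1Image(mask.inside.astype(np.uint8)[..., None], affine=np.eye(4))


def save_field_nifti(field: EffectField, path: str) -> None:
    import nibabel as nib

    nib.save(field_to_nifti(field), path)


def load_grid_nifti(path: str) -> np.ndarray:
    """Load a rows x cols (x 1) NIfTI volume back into a 2D grid array."""
    import nibabel as nib

    data = np.asarray(nib.load(path).dataobj)
    if data.ndim == 3:
        data = data[..., 0]
    return data


def grid_to_csv(grid: np.ndarray, path: str) -> None:
    """Write a 2D grid as tidy (row, col, value) CSV."""
    rows, cols = np.indices(grid.shape)
    pd.DataFrame({"row": rows.ravel(), "col": cols.ravel(),
                  "value": np.asarray(grid, dtype=float).ravel()}).to_csv(path, index=False)


def grid_from_csv(path: str) -> np.ndarray:
    df = pd.read_csv(path)
    rows, cols = int(df["row"].max()) + 1, int(df["col"].max()) + 1
    grid = np.zeros((rows, cols))
    grid[df["row"].to_numpy(), df["col"].to_numpy()] = df["value"].to_numpy()
    return grid


def _write_bundle(config: ExperimentConfig, field: EffectField, truth: TruthSet,
                  records: pd.DataFrame, curves: pd.DataFrame) -> dict[str, str]:
    import os

    import nibabel as nib
    import yaml

    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    paths = {
        "records": os.path.join(out, "records.csv"),
        "curves": os.path.join(out, "curves.csv"),
        "effect_field": os.path.join(out, "effect_field.nii.gz"),
        "truth_mask": os.path.join(out, "truth_mask.nii.gz"),
        "config_echo": os.path.join(out, "config_echo.yaml"),
    }
    records.to_csv(paths["records"], index=False)
    curves.to_csv(paths["curves"], index=False)
    nib.save(field_to_nifti(field), paths["effect_field"])
    truth_img = field.mask.embed(truth.true_mask.astype(float)).astype(np.uint8)
    nib.save(nib.Nifti1Image(truth_img[..., None], affine=np.eye(4)), paths["truth_mask"])
    with open(paths["config_echo"], "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)
    for key, path in paths.items():
        logger.info("wrote %s -> %s", key, path)
    return paths


def config_to_dict(config: ExperimentConfig) -> dict:
    spec = config.scenario
    return {
        "scenario": {
            "kind": spec.kind,
            "effect_fraction": spec.effect_fraction,
            "r_band": list(spec.r_band),
            "fwhm_vox": spec.fwhm_vox,
            "shape": list(spec.shape),
            "target_voxels": spec.target_voxels,
            "seed": spec.seed,
        },
        "full_n": config.full_n,
        "n_grid": list(config.n_grid),
        "n_reps": config.n_reps,
        "threshold": {"method": config.threshold.method, "level": config.threshold.level},
        "truth_mode": config.truth_mode,
        "master_seed": config.master_seed,
        "regenerate_cohort_per_rep": config.regenerate_cohort_per_rep,
    }


def config_from_dict(doc: dict, **overrides) -> ExperimentConfig:
    """Build an ExperimentConfig from a plain dict (YAML/TOML document).

    Keyword overrides win over document values (CLI-flag semantics).
    """
    doc = dict(doc)
    sc = dict(doc.pop("scenario", {}))
    kind = sc.pop("kind", "WD")
    if "r_band" in sc:
        sc["r_band"] = tuple(sc["r_band"])
    if "shape" in sc:
        sc["shape"] = tuple(sc["shape"])
    base = (ScenarioSpec.weak_diffuse if kind == "WD" else ScenarioSpec.strong_localized)()
    defaults = {"effect_fraction": base.effect_fraction, "r_band": base.r_band}
    scenario = ScenarioSpec(kind=kind, **{**defaults, **sc})
    th = doc.pop("threshold", None)
    kwargs = dict(doc)
    if th is not None:
        kwargs["threshold"] = ThresholdSpec(**th)
    if "n_grid" in kwargs:
        kwargs["n_grid"] = tuple(kwargs["n_grid"])
    cfg = ExperimentConfig(scenario=scenario, **kwargs)
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


def load_config(path: str, **overrides) -> ExperimentConfig:
    """Load an ExperimentConfig from a YAML (or TOML) file."""
    if path.endswith(".toml"):
        import tomllib

        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
    else:
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
    return config_from_dict(doc, **overrides)
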