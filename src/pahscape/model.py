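"""Gaussian surface modeling of activity landscapes.

PAH activity over a [Phe] x [BH4] concentration grid shows substrate-
inhibition kinetics: activity rises, peaks, and falls again along both axes,
giving the landscape a drop shape that becomes symmetric in log-concentration
space.  We therefore model the landscape empirically as an axis-aligned 2D
Gaussian in (x', y') = (ln [Phe], ln [BH4]):

    z_hat(x', y') = a * exp(-0.5 * (((x' - mx') / sx')**2 + ((y' - my') / sy')**2))

with amplitude ``a`` (the maximum residual activity), peak location
(mx', my') and widths (sx', sy') in ln(uM).  Derived per-genotype features are
the amplitude as %WT, the peak concentrations exp(mx'), exp(my'), and the
working range: the [Phe] interval sustaining >= 50% of maximum activity at the
fitted BH4 optimum, which is symmetric about the peak in log space
(low * high = peak**2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import least_squares

from .grids import ConcentrationGrid
from .plates import ActivityLandscape

#: sqrt(2 ln 2): half-width at half maximum of a unit Gaussian.
_HWHM = math.sqrt(2.0 * math.log(2.0))

#: Fitted peaks below this amplitude (%WT of the same-run WT fit) are treated
#: as "no peak": the landscape shows no usable residual activity.  Half the
#: 3% artifact cutoff, below the lowest genuine subpopulation amplitude.
MIN_PEAK_ACTIVITY_PCT_WT = 1.5

#: Artifact rule: a fitted peak above this [Phe] (uM) with amplitude below
#: ARTIFACT_MAX_PCT of the WT is attributed to non-enzymatic Phe->Tyr
#: conversion, not residual PAH activity (strict inequalities).
ARTIFACT_PHE_UM = 1500.0
ARTIFACT_MAX_PCT = 3.0


@dataclass(frozen=True)
class GaussianFit:
    """Fitted log-space Gaussian surface parameters and diagnostics."""

    a: float
    mx_prime: float
    my_prime: float
    sx_prime: float
    sy_prime: float
    converged: bool
    rmse_fit: float

    def predict(self, phe_uM: np.ndarray, bh4_uM: np.ndarray) -> np.ndarray:
        """Evaluate the fitted surface at concentration pairs (uM)."""
        xp = np.log(np.asarray(phe_uM, dtype=float))
        yp = np.log(np.asarray(bh4_uM, dtype=float))
        return gaussian_surface(xp, yp, self.a, self.mx_prime, self.my_prime, self.sx_prime, self.sy_prime)


@dataclass(frozen=True)
class PeakFeatures:
    """Per-genotype phenotype vector derived from the fitted surface.

    ``activity_in_range_pct_wt`` is the modeled maximum within the sampled
    concentration box: identical to ``activity_max_pct_wt`` for peaks inside
    the assayed range, but equal to the modeled edge level when the fitted
    peak extrapolates beyond it — which is what the no-residual-activity
    filter must judge.
    """

    genotype_id: str
    activity_max_pct_wt: float
    phe_peak_uM: float
    bh4_peak_uM: float
    working_range_low_uM: float
    working_range_high_uM: float
    working_range_width_uM: float
    has_peak: bool
    activity_in_range_pct_wt: float = float("nan")


def gaussian_surface(
    x_prime: np.ndarray, y_prime: np.ndarray, a: float, mx: float, my: float, sx: float, sy: float
) -> np.ndarray:
    return a * np.exp(-0.5 * (((x_prime - mx) / sx) ** 2 + ((y_prime - my) / sy) ** 2))


def smooth_landscape(
    landscape: ActivityLandscape, upsample: int = 4, sigma: float = 1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Regular-grid interpolation followed by Gaussian-kernel smoothing.

    Returns ``(dense, phe_dense, bh4_dense)`` where ``dense`` has shape
    ``(upsample * 12, upsample * 8)``.  Used for visualization and peak
    counting only, never for parameter fitting.  ``sigma`` is in units of the
    dense grid's cells.
    """
    if upsample < 1:
        raise ValueError("upsample must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    values = landscape.values
    n_phe, n_bh4 = values.shape
    # interpolate on index coordinates so upsampling is uniform per cell
    interp = RegularGridInterpolator(
        (np.arange(n_phe), np.arange(n_bh4)), values, method="linear"
    )
    ip = np.linspace(0, n_phe - 1, upsample * n_phe)
    ib = np.linspace(0, n_bh4 - 1, upsample * n_bh4)
    pts = np.stack(np.meshgrid(ip, ib, indexing="ij"), axis=-1)
    dense = interp(pts)
    if sigma > 0:
        dense = ndimage.gaussian_filter(dense, sigma=sigma, mode="nearest")
    phe_dense = np.interp(ip, np.arange(n_phe), landscape.grid.phe)
    bh4_dense = np.interp(ib, np.arange(n_bh4), landscape.grid.bh4)
    return dense, phe_dense, bh4_dense


def fit_gaussian(landscape: ActivityLandscape) -> GaussianFit:
    """Nonlinear least-squares fit of the log-space Gaussian surface.

    Wells with zero [Phe] or zero [BH4] are excluded (their log coordinate is
    undefined); no pseudo-count is added.  Initialization: amplitude and peak
    location at the observed argmax, unit widths.  Bounds keep the peak near
    the sampled log range while still admitting the high-[Phe] artifact peaks
    the downstream filter must catch.  A failed optimization returns
    ``converged=False`` rather than raising.
    """
    grid = landscape.grid
    mask = grid.nonzero_mask()
    z = landscape.values[mask]
    if not np.any(z > 0):
        return GaussianFit(0.0, math.nan, math.nan, math.nan, math.nan, False, math.nan)

    lp = np.log(grid.phe[grid.phe > 0])
    lb = np.log(grid.bh4[grid.bh4 > 0])
    xp, yp = np.meshgrid(lp, lb, indexing="ij")
    xp, yp = xp.ravel(), yp.ravel()

    a0 = float(z.max())
    imax = int(np.argmax(z))
    theta0 = np.array([a0, xp[imax], yp[imax], 1.0, 1.0])
    lower = [0.0, lp.min() - 1.0, lb.min() - 1.0, 0.05, 0.05]
    upper = [10.0 * a0, lp.max() + 1.0, lb.max() + 1.0, 5.0, 5.0]
    theta0 = np.clip(theta0, lower, upper)

    def resid(theta):
        return gaussian_surface(xp, yp, *theta) - z

    try:
        sol = least_squares(resid, theta0, bounds=(lower, upper), method="trf")
    except Exception:
        return GaussianFit(0.0, math.nan, math.nan, math.nan, math.nan, False, math.nan)
    if not sol.success or not np.all(np.isfinite(sol.x)):
        return GaussianFit(0.0, math.nan, math.nan, math.nan, math.nan, False, math.nan)
    a, mx, my, sx, sy = (float(v) for v in sol.x)
    rmse = float(np.sqrt(np.mean(sol.fun**2)))
    return GaussianFit(a=a, mx_prime=mx, my_prime=my, sx_prime=sx, sy_prime=sy, converged=True, rmse_fit=rmse)


def working_range(fit: GaussianFit) -> tuple[float, float]:
    """[Phe] interval at >= 50% of peak activity, along x at the BH4 optimum.

    Closed form from the log-space Gaussian: the half-maximum points sit at
    mx' -/+ sx' * sqrt(2 ln 2), so the endpoints are geometrically symmetric
    about the peak (low * high = peak**2).
    """
    if not fit.converged or not fit.sx_prime > 0:
        raise ValueError("working_range requires a converged fit with positive width")
    low = math.exp(fit.mx_prime - fit.sx_prime * _HWHM)
    high = math.exp(fit.mx_prime + fit.sx_prime * _HWHM)
    return low, high


def extract_features(
    fit: GaussianFit,
    wt_fit: GaussianFit,
    genotype_id: str = "",
    min_peak_pct_wt: float = MIN_PEAK_ACTIVITY_PCT_WT,
    grid: ConcentrationGrid | None = None,
) -> PeakFeatures:
    """Derive the genotype feature vector, normalizing amplitude to the run's WT fit.

    ``grid`` bounds the in-range activity evaluation; the package default
    grid is assumed when omitted.
    """
    if not wt_fit.converged or not wt_fit.a > 0:
        raise ValueError("wild-type fit has no amplitude; cannot normalize to WT")
    if not fit.converged:
        return PeakFeatures(genotype_id, 0.0, math.nan, math.nan, math.nan, math.nan, math.nan, False, 0.0)
    grid = grid or ConcentrationGrid()
    pct = 100.0 * fit.a / wt_fit.a
    # modeled maximum inside the sampled box: clamp the peak into the
    # positive-concentration log range and evaluate the surface there
    lp = np.log(grid.phe[grid.phe > 0])
    lb = np.log(grid.bh4[grid.bh4 > 0])
    mx_c = min(max(fit.mx_prime, lp.min()), lp.max())
    my_c = min(max(fit.my_prime, lb.min()), lb.max())
    a_in_range = float(gaussian_surface(np.array(mx_c), np.array(my_c), fit.a, fit.mx_prime, fit.my_prime, fit.sx_prime, fit.sy_prime))
    pct_in_range = 100.0 * a_in_range / wt_fit.a
    low, high = working_range(fit)
    has_peak = pct_in_range >= min_peak_pct_wt
    return PeakFeatures(
        genotype_id=genotype_id,
        activity_max_pct_wt=pct,
        phe_peak_uM=math.exp(fit.mx_prime),
        bh4_peak_uM=math.exp(fit.my_prime),
        working_range_low_uM=low,
        working_range_high_uM=high,
        working_range_width_uM=high - low,
        has_peak=has_peak,
        activity_in_range_pct_wt=pct_in_range,
    )


def artifact_filter(
    features: PeakFeatures,
    phe_threshold_uM: float = ARTIFACT_PHE_UM,
    max_activity_pct: float = ARTIFACT_MAX_PCT,
) -> bool:
    """True when the landscape shows no genuine residual activity (subpopulation 0).

    Flags landscapes with no peak at all, and those whose fitted peak lies
    strictly above ``phe_threshold_uM`` [Phe] with amplitude strictly below
    ``max_activity_pct`` %WT — the signature of the non-enzymatic Phe->Tyr
    conversion seen at high substrate concentrations.  The amplitude
    criterion is judged on the modeled activity within the sampled
    concentration range, so a peak extrapolated far past the assay box is
    assessed at the level the assay actually observed.
    """
    if not features.has_peak:
        return True
    act = features.activity_in_range_pct_wt
    if math.isnan(act):
        act = features.activity_max_pct_wt
    return features.phe_peak_uM > phe_threshold_uM and act < max_activity_pct
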