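"""Quality control of activity landscapes.

Three per-sample statistics gate the pipeline:

* **RMSE** — root-mean-square residual between the observed landscape and the
  fitted Gaussian surface, computed on the landscape rescaled to unit fitted
  amplitude so the statistic is portable across activity magnitudes.
* **NoP** — number of strict local maxima (8-neighborhood) in the lightly
  smoothed raw landscape; genuine landscapes carry one dominant peak, noisy or
  corrupt plates many.
* **VT** — replicate variation: the maximum over wells of
  (max - min) / median across replicates, skipping wells whose replicate
  median falls below a small activity floor where the ratio is pure noise.

Thresholds follow an exponential model of each statistic's cohort
distribution: with rate lambda estimated by 1/mean, the cutoff
mean + 2/lambda collapses to 3x the sample mean.  Published defaults
(0.26, 8.4, 0.23) apply when no calibration cohort is supplied.  A sample
exceeding any threshold fails; samples within a +/-10% band of a threshold
(but not exceeding one) are flagged borderline for manual review.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import GaussianFit, smooth_landscape
from .plates import ActivityLandscape, PlateReplicate

#: Cohort-free defaults for (RMSE, NoP, VT).
DEFAULT_THRESHOLDS = (0.26, 8.4, 0.23)


@dataclass(frozen=True)
class QCReport:
    genotype_id: str
    rmse: float
    nop: int
    vt: float
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS
    status: str = "pass"  # pass | fail | borderline
    failed_features: tuple[str, ...] = ()
    vt_no_eligible_wells: bool = False


def compute_rmse(observed: ActivityLandscape, fit: GaussianFit) -> float:
    """RMSE between observed and modeled landscape on the unit-amplitude scale.

    Computed over the wells included in the fit (nonzero concentrations), with
    both surfaces divided by the fitted amplitude ``a``.
    """
    if not fit.converged or not fit.a > 0:
        return math.inf
    mask = observed.grid.nonzero_mask()
    phe, bh4 = np.meshgrid(observed.grid.phe, observed.grid.bh4, indexing="ij")
    model = fit.predict(phe[mask], bh4[mask])
    resid = (observed.values[mask] - model) / fit.a
    return float(np.sqrt(np.mean(resid**2)))


def count_peaks(
    landscape: ActivityLandscape, min_prominence: float = 0.01, sigma: float = 0.8
) -> int:
    """Count strict 8-neighborhood local maxima in the lightly smoothed landscape.

    Only maxima exceeding ``min_prominence`` times the smoothed grid maximum
    count, so single-well spikes below the noise floor are ignored.
    """
    dense, _, _ = smooth_landscape(landscape, upsample=1, sigma=sigma)
    vmax = dense.max()
    if vmax <= 0:
        return 0
    padded = np.pad(dense, 1, mode="constant", constant_values=-np.inf)
    neighbors = np.full(dense.shape, -np.inf)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            shifted = padded[1 + di : 1 + di + dense.shape[0], 1 + dj : 1 + dj + dense.shape[1]]
            neighbors = np.maximum(neighbors, shifted)
    is_max = (dense > neighbors) & (dense > min_prominence * vmax)
    return int(is_max.sum())


def replicate_variation(
    replicates: Sequence[PlateReplicate], floor_fraction: float = 0.01
) -> tuple[float, bool]:
    """Maximum over wells of replicate (max - min) / median.

    Wells whose replicate median falls below ``floor_fraction`` of the plate's
    maximum median well are skipped — there the ratio diverges on noise alone.
    Returns ``(vt, no_eligible_wells)``; with no eligible well VT is defined
    as 0 and flagged.
    """
    if len(replicates) < 2:
        raise ValueError("replicate_variation needs at least 2 replicates")
    stack = np.stack([r.values for r in replicates])
    med = np.median(stack, axis=0)
    floor = floor_fraction * med.max()
    eligible = med >= max(floor, np.finfo(float).tiny)
    if not np.any(eligible):
        return 0.0, True
    rng = stack.max(axis=0) - stack.min(axis=0)
    ratios = rng[eligible] / med[eligible]
    return float(ratios.max()), False


def calibrate_thresholds(values: Sequence[float], lam: float | None = None) -> float:
    """Exponential-model threshold: sample mean plus 2/lambda.

    With lambda estimated by the method of moments (1/mean, also the MLE for
    the exponential) this is exactly 3x the sample mean; a user-supplied
    ``lam`` is honored in the two-term form.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values to calibrate a threshold")
    if np.any(values < 0):
        raise ValueError("threshold calibration requires nonnegative values")
    mean = float(values.mean())
    if mean <= 0:
        raise ValueError("all-zero statistics cannot calibrate a threshold")
    if lam is None:
        lam = 1.0 / mean
    return mean + 2.0 / lam


def qc_gate(
    genotype_id: str,
    rmse: float,
    nop: int,
    vt: float,
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
    borderline_band: float = 0.10,
    vt_no_eligible_wells: bool = False,
) -> QCReport:
    """Gate a sample: fail if any statistic exceeds its threshold, flag borderline.

    Borderline = within ``borderline_band`` (fraction of the threshold) of any
    threshold while none is exceeded; such samples pass but are flagged for
    manual review.
    """
    stats = {"RMSE": (rmse, thresholds[0]), "NoP": (float(nop), thresholds[1]), "VT": (vt, thresholds[2])}
    failed = tuple(name for name, (v, t) in stats.items() if v > t)
    if failed:
        status = "fail"
    elif any(abs(v - t) <= borderline_band * t for v, t in stats.values()):
        status = "borderline"
    else:
        status = "pass"
    return QCReport(
        genotype_id=genotype_id,
        rmse=rmse,
        nop=nop,
        vt=vt,
        thresholds=tuple(thresholds),
        status=status,
        failed_features=failed,
        vt_no_eligible_wells=vt_no_eligible_wells,
    )
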