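"""Synthetic assay generator: plates, cohorts, and clinical records.

The generator is the forward model of everything the analysis assumes: each
genotype has a ground-truth log-space Gaussian activity surface drawn from a
subpopulation archetype, plates are the surface plus a shared assay baseline,
a high-[Phe] conversion artifact, and replicate noise, and clinical records
are multinomial/binomial draws with subpopulation-specific probabilities.

Archetype parameter ranges mirror the six observed subpopulation classes:
0 no residual activity (flat, or a sub-3% pseudo-peak above 1500 uM [Phe]);
1 reduced activity (4-11 %WT) at a WT-like peak position (220-360 uM);
2 left-shifted narrow peaks around 105 uM with 4-9 %WT;
3 right-shifted higher peaks around 547 uM with 6-16 %WT;
4 right-shifted lower peaks around 476 uM with 3-6 %WT at higher [BH4];
5 high residual activity, 23-32 %WT, variable peak position.
The wild type peaks at [Phe] 330 +/- 15 uM, [BH4] 101 +/- 17 uM with a
working range of roughly 80-1372 uM [Phe] (log-width sx' ~= 1.2).  Where only
a median is reported for a class, a +/-30% uniform band around it is used.

The Tyr-conversion artifact (non-enzymatic Phe->Tyr at high substrate) is a
linear ramp above 1300 uM [Phe] reaching ~2 %WT at 2500 uM, applied to
transfected-cell plates only — it therefore survives background subtraction,
as in the real assay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .clinical import ClinicalRecordSet
from .grids import ConcentrationGrid, default_grid
from .model import GaussianFit, gaussian_surface
from .plates import PlateReplicate

#: Raw-unit amplitude of the wild-type surface (pmol Tyr/mg/min).
RAW_WT_AMPLITUDE = 1000.0


@dataclass(frozen=True)
class ArchetypeSpec:
    """Parameter ranges a subpopulation's ground-truth surfaces are drawn from."""

    label: int
    activity_range: tuple[float, float]  # %WT
    phe_peak_range: tuple[float, float]  # uM
    bh4_peak_range: tuple[float, float]  # uM
    sx_range: tuple[float, float]  # ln(uM)
    sy_range: tuple[float, float]  # ln(uM)
    null_fraction: float = 0.0  # fraction drawn with a = 0 (flat landscape)

    def __post_init__(self) -> None:
        for name in ("activity_range", "phe_peak_range", "bh4_peak_range", "sx_range", "sy_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must satisfy 0 <= low <= high")


def _band(median: float, rel: float = 0.3) -> tuple[float, float]:
    return (median * (1 - rel), median * (1 + rel))


WT_ARCHETYPE = ArchetypeSpec(
    label=-1,
    activity_range=(100.0, 100.0),
    phe_peak_range=(315.0, 345.0),
    bh4_peak_range=(84.0, 118.0),
    sx_range=(1.15, 1.25),
    sy_range=(0.85, 0.95),
)

DEFAULT_ARCHETYPES: dict[int, ArchetypeSpec] = {
    0: ArchetypeSpec(0, (0.3, 0.8), (1700.0, 2200.0), (80.0, 200.0), (0.5, 1.0), (0.5, 1.0), null_fraction=0.5),
    1: ArchetypeSpec(1, (4.0, 11.0), (220.0, 360.0), (84.0, 118.0), (1.05, 1.30), (0.80, 1.05)),
    2: ArchetypeSpec(2, (4.0, 9.0), _band(105.0), (55.0, 72.0), (0.45, 0.75), (0.55, 0.85)),
    3: ArchetypeSpec(3, (6.0, 16.0), _band(547.0), (85.0, 120.0), (1.40, 1.75), (0.70, 0.95)),
    4: ArchetypeSpec(4, (3.0, 6.0), _band(476.0), (110.0, 170.0), (1.30, 1.60), (0.70, 0.95)),
    5: ArchetypeSpec(5, (23.0, 32.0), (150.0, 500.0), (70.0, 130.0), (0.90, 1.40), (0.70, 1.05)),
}

#: Cohort composition (genotypes per subpopulation) totalling 99.
DEFAULT_COHORT_COMPOSITION = {0: 18, 1: 24, 2: 14, 3: 16, 4: 19, 5: 8}


@dataclass(frozen=True)
class NoiseModel:
    """Replicate noise, assay baseline, and the high-[Phe] conversion artifact.

    ``additive_sd`` and ``baseline_pct`` are in %WT (i.e. percent of the raw
    wild-type amplitude); ``artifact_ramp`` is the artifact's height (%WT) at
    the top [Phe] level, ramping linearly from ``artifact_onset_uM``.
    """

    multiplicative_cv: float = 0.08
    additive_sd: float = 0.5
    artifact_ramp: float = 1.5
    artifact_onset_uM: float = 1300.0
    corrupt_replicate_prob: float = 0.0
    baseline_pct: float = 3.0

    def __post_init__(self) -> None:
        for name in ("multiplicative_cv", "additive_sd", "artifact_ramp", "corrupt_replicate_prob", "baseline_pct"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


NOISELESS = NoiseModel(multiplicative_cv=0.0, additive_sd=0.0, artifact_ramp=0.0, corrupt_replicate_prob=0.0)


@dataclass
class SimulatedRun:
    """Plates of one genotype with its matched run controls and ground truth."""

    sample: list[PlateReplicate]
    wt: list[PlateReplicate]
    no_dna: list[PlateReplicate]
    truth: GaussianFit
    wt_truth: GaussianFit
    corrupted: bool = False


@dataclass
class SimulatedCohort:
    """A full synthetic study: replicates per genotype, controls per run, truths."""

    replicates: dict[str, list[PlateReplicate]]
    wt_replicates: dict[str, list[PlateReplicate]]
    no_dna_replicates: dict[str, list[PlateReplicate]]
    run_of: dict[str, str]
    truth: pd.DataFrame  # genotype_id, label, a_pct_wt, phe_peak_uM, bh4_peak_uM, sx, sy, corrupted
    grid: ConcentrationGrid


def _rng(seed, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *[int(t) for t in tags]]))


def _draw_in_range(rng: np.random.Generator, lo: float, hi: float) -> float:
    """Truncated-normal draw: ranges are read as observed min-max, ~ +/-2 sd.

    Centered on the range midpoint with sd = range/4, rejected outside
    [lo, hi]; degenerate ranges return the point."""
    if hi <= lo:
        return lo
    mu, sd = 0.5 * (lo + hi), 0.25 * (hi - lo)
    for _ in range(100):
        v = rng.normal(mu, sd)
        if lo <= v <= hi:
            return v
    return mu


def sample_truth(archetype: ArchetypeSpec, seed) -> GaussianFit:
    """Draw a ground-truth surface from an archetype's parameter ranges."""
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed)
    if archetype.null_fraction > 0 and rng.random() < archetype.null_fraction:
        return GaussianFit(0.0, math.nan, math.nan, math.nan, math.nan, True, 0.0)
    a = _draw_in_range(rng, *archetype.activity_range)
    phe = _draw_in_range(rng, *archetype.phe_peak_range)
    bh4 = _draw_in_range(rng, *archetype.bh4_peak_range)
    sx = _draw_in_range(rng, *archetype.sx_range)
    sy = _draw_in_range(rng, *archetype.sy_range)
    return GaussianFit(a=a, mx_prime=math.log(phe), my_prime=math.log(bh4), sx_prime=sx, sy_prime=sy, converged=True, rmse_fit=0.0)


def truth_surface(truth: GaussianFit, grid: ConcentrationGrid, raw_units: bool = True) -> np.ndarray:
    """Evaluate a ground-truth surface on the grid; zero-concentration wells are 0."""
    values = np.zeros(grid.shape)
    mask = grid.nonzero_mask()
    phe, bh4 = np.meshgrid(grid.phe, grid.bh4, indexing="ij")
    if truth.a > 0:
        values[mask] = gaussian_surface(
            np.log(phe[mask]), np.log(bh4[mask]), truth.a, truth.mx_prime, truth.my_prime, truth.sx_prime, truth.sy_prime
        )
    if raw_units:
        values *= RAW_WT_AMPLITUDE / 100.0
    return values


def _artifact_ramp(grid: ConcentrationGrid, noise: NoiseModel) -> np.ndarray:
    """Raw-unit Tyr-conversion ramp, linear in [Phe] above the onset."""
    top = grid.phe.max()
    if noise.artifact_ramp <= 0 or top <= noise.artifact_onset_uM:
        return np.zeros(grid.shape)
    frac = np.clip((grid.phe - noise.artifact_onset_uM) / (top - noise.artifact_onset_uM), 0, None)
    ramp_pct = noise.artifact_ramp * frac
    return np.broadcast_to(ramp_pct[:, None] * RAW_WT_AMPLITUDE / 100.0, grid.shape).copy()


def _noisy_replicates(
    mean_raw: np.ndarray,
    grid: ConcentrationGrid,
    noise: NoiseModel,
    rng: np.random.Generator,
    genotype_id: str,
    run_id: str,
    n_replicates: int,
    corruptible: bool = False,
) -> tuple[list[PlateReplicate], bool]:
    additive_raw = noise.additive_sd * RAW_WT_AMPLITUDE / 100.0
    reps = []
    values_all = []
    for i in range(n_replicates):
        v = mean_raw * (1.0 + noise.multiplicative_cv * rng.standard_normal(grid.shape))
        v = v + additive_raw * rng.standard_normal(grid.shape)
        values_all.append(np.clip(v, 0.0, None))
    corrupted = False
    if corruptible and noise.corrupt_replicate_prob > 0 and rng.random() < noise.corrupt_replicate_prob:
        corrupted = True
        which = int(rng.integers(n_replicates))
        wells = rng.random(grid.shape) < 0.5
        values_all[which] = np.where(wells, 5.0 * values_all[which], values_all[which])
    for i, v in enumerate(values_all):
        reps.append(PlateReplicate(genotype_id=genotype_id, run_id=run_id, replicate_index=i + 1, values=v, grid=grid))
    return reps, corrupted


def simulate_plates(
    truth: GaussianFit,
    grid: ConcentrationGrid | None = None,
    noise: NoiseModel | None = None,
    n_replicates: int = 3,
    seed: int = 0,
    genotype_id: str = "G000",
    run_id: str = "run01",
    wt_truth: GaussianFit | None = None,
) -> SimulatedRun:
    """Simulate one genotype's replicate plates with matched WT and no-DNA controls.

    The raw plate is baseline + surface (+ artifact ramp on transfected-cell
    plates), with multiplicative then additive noise per replicate; one
    replicate may be corrupted (5x scaling on a random half of wells) with
    probability ``corrupt_replicate_prob``.
    """
    grid = grid or default_grid()
    noise = noise or NoiseModel()
    rng = _rng(seed)
    if wt_truth is None:
        wt_truth = sample_truth(WT_ARCHETYPE, rng)
    baseline = noise.baseline_pct * RAW_WT_AMPLITUDE / 100.0
    ramp = _artifact_ramp(grid, noise)
    sample_mean = baseline + truth_surface(truth, grid) + ramp
    wt_mean = baseline + truth_surface(wt_truth, grid) + ramp
    nodna_mean = np.full(grid.shape, baseline)
    sample, corrupted = _noisy_replicates(sample_mean, grid, noise, rng, genotype_id, run_id, n_replicates, corruptible=True)
    wt, _ = _noisy_replicates(wt_mean, grid, noise, rng, "WT", run_id, n_replicates)
    no_dna, _ = _noisy_replicates(nodna_mean, grid, noise, rng, "noDNA", run_id, n_replicates)
    return SimulatedRun(sample=sample, wt=wt, no_dna=no_dna, truth=truth, wt_truth=wt_truth, corrupted=corrupted)


def simulate_cohort(
    n_per_archetype: dict[int, int] | None = None,
    seed: int = 0,
    noise: NoiseModel | None = None,
    grid: ConcentrationGrid | None = None,
    archetypes: dict[int, ArchetypeSpec] | None = None,
    genotypes_per_run: int = 8,
) -> SimulatedCohort:
    """Simulate a full study cohort, grouped into runs sharing WT/no-DNA controls."""
    n_per_archetype = n_per_archetype or dict(DEFAULT_COHORT_COMPOSITION)
    noise = noise or NoiseModel()
    grid = grid or default_grid()
    archetypes = archetypes or DEFAULT_ARCHETYPES

    labels = [lab for lab, n in sorted(n_per_archetype.items()) for _ in range(n)]
    rng = _rng(seed, 101)
    order = rng.permutation(len(labels))  # mix subpopulations across runs
    replicates: dict[str, list[PlateReplicate]] = {}
    wt_replicates: dict[str, list[PlateReplicate]] = {}
    no_dna_replicates: dict[str, list[PlateReplicate]] = {}
    run_of: dict[str, str] = {}
    rows = []
    for pos, idx in enumerate(order):
        label = labels[idx]
        gid = f"G{pos + 1:03d}"
        run_id = f"run{pos // genotypes_per_run + 1:02d}"
        truth = sample_truth(archetypes[label], _rng(seed, 211, pos))
        run_seed_rng = _rng(seed, 311, pos // genotypes_per_run)
        wt_truth = sample_truth(WT_ARCHETYPE, run_seed_rng)
        sim = simulate_plates(
            truth,
            grid=grid,
            noise=noise,
            seed=int(_rng(seed, 411, pos).integers(0, 2**31 - 1)),
            genotype_id=gid,
            run_id=run_id,
            wt_truth=wt_truth,
        )
        replicates[gid] = sim.sample
        run_of[gid] = run_id
        if run_id not in wt_replicates:  # one control set per run
            wt_replicates[run_id] = sim.wt
            no_dna_replicates[run_id] = sim.no_dna
        rows.append(
            {
                "genotype_id": gid,
                "label": label,
                "a_pct_wt": truth.a,
                "phe_peak_uM": math.exp(truth.mx_prime) if truth.a > 0 else math.nan,
                "bh4_peak_uM": math.exp(truth.my_prime) if truth.a > 0 else math.nan,
                "sx_prime": truth.sx_prime,
                "sy_prime": truth.sy_prime,
                "corrupted": sim.corrupted,
                "run_id": run_id,
            }
        )
    truth_df = pd.DataFrame(rows).sort_values("genotype_id").reset_index(drop=True)
    return SimulatedCohort(
        replicates=replicates,
        wt_replicates=wt_replicates,
        no_dna_replicates=no_dna_replicates,
        run_of=run_of,
        truth=truth_df,
        grid=grid,
    )


# ---------------------------------------------------------------------------
# Clinical record simulation

#: Phenotype class probabilities (classical PKU, mild PKU, MHPA) per
#: subpopulation.  Subpopulation 3's reported vector sums past 1 and is
#: renormalized; subpopulations 1 and 4 mix all classes.
PHENOTYPE_PROBS: dict[int, tuple[float, float, float]] = {
    0: (1.0, 0.0, 0.0),
    1: (0.15, 0.35, 0.50),
    2: (0.13, 0.35, 0.52),
    3: tuple(np.array([0.29, 0.35, 0.53]) / np.sum([0.29, 0.35, 0.53])),
    4: (0.29, 0.38, 0.33),
    5: (0.0, 0.20, 0.80),
}

#: Probability that a response record is responder or slow-responder.
RESPONDER_PROBS: dict[int, float] = {0: 0.0, 1: 0.80, 2: 1.0, 3: 0.80, 4: 0.27, 5: 1.0}

#: Among responders, share recorded as full (vs slow) responders.
FULL_RESPONDER_SHARE = 0.75


def simulate_clinical(
    labels: dict[str, int],
    seed: int = 0,
    phenotype_records_mean: float = 79.0,
    response_records_mean: float = 14.0,
    records_per_genotype: int | None = None,
    n_excluded_variant_genotypes: int = 3,
    phenotype_probs: dict[int, tuple[float, float, float]] | None = None,
    responder_probs: dict[int, float] | None = None,
) -> list[ClinicalRecordSet]:
    """Draw registry-style record counts per genotype from its subpopulation's rates.

    Record volumes follow a negative binomial around the registry-like means
    (so a realistic minority of genotypes falls below the >10-records filter);
    ``records_per_genotype`` fixes both volumes instead when given.  A few
    genotypes (preferably right-shifted ones, mirroring where annotation
    instability was observed) are flagged as excluded-variant carriers.
    """
    phenotype_probs = phenotype_probs or PHENOTYPE_PROBS
    responder_probs = responder_probs or RESPONDER_PROBS
    rng = _rng(seed, 990)
    gids = sorted(labels)
    candidates = [g for g in gids if labels[g] == 3] or gids
    n_ex = min(n_excluded_variant_genotypes, len(candidates))
    excluded = set(rng.choice(candidates, size=n_ex, replace=False)) if n_ex else set()

    def _nbinom(mean: float) -> int:
        shape = 3.0
        return int(rng.negative_binomial(shape, shape / (shape + mean)))

    records = []
    for gid in gids:
        lab = labels[gid]
        n_ph = records_per_genotype if records_per_genotype is not None else _nbinom(phenotype_records_mean)
        n_rs = records_per_genotype if records_per_genotype is not None else _nbinom(response_records_mean)
        classic, mild, mhpa = rng.multinomial(n_ph, phenotype_probs[lab])
        responders = rng.binomial(n_rs, responder_probs[lab])
        full = rng.binomial(responders, FULL_RESPONDER_SHARE)
        records.append(
            ClinicalRecordSet(
                genotype_id=gid,
                n_classic=int(classic),
                n_mild=int(mild),
                n_mhpa=int(mhpa),
                n_responder=int(full),
                n_slow=int(responders - full),
                n_nonresponder=int(n_rs - responders),
                excluded_variant_flag=gid in excluded,
            )
        )
    return records
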