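"""Subpopulation discovery by consensus clustering and k-NN labeling.

Genotypes with residual activity are described by four features — maximum
activity (%WT), ln peak [Phe], ln peak [BH4], and ln working-range width —
each z-standardized.  Consensus clustering repeatedly subsamples the cohort,
runs a seeded base k-means on each subsample, and records how often every
pair of genotypes lands in the same cluster; the resulting consensus matrix
is both the evidence for the optimal number of clusters (via PAC, the
proportion of ambiguous entries) and the similarity used to cut the final
partition.  New genotypes are labeled afterwards by k-nearest neighbors in
the standardized feature space, avoiding re-clustering.

Canonical subpopulation names (1-5) are assigned from cluster medians:
5 = highest activity; 2 = lowest peak [Phe]; 3 and 4 = the right-shifted
pair (peak [Phe] above the wild type's), split by activity; 1 = the
remainder (WT-like peak position, reduced activity).  Subpopulation 0
(no residual activity) never enters clustering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .model import PeakFeatures

FEATURE_COLUMNS = ("activity_max_pct_wt", "ln_phe_peak", "ln_bh4_peak", "ln_wr_width")


class SubpopulationNamingError(ValueError):
    """Raised when the median-based naming rules do not yield a bijection."""


@dataclass(frozen=True)
class FeatureMatrix:
    """Standardized genotype feature matrix with its stored transform."""

    genotype_ids: tuple[str, ...]
    values: np.ndarray  # standardized, shape (n, 4)
    raw: np.ndarray  # unstandardized design matrix (activity, ln phe, ln bh4, ln width)
    means: np.ndarray
    sds: np.ndarray

    @property
    def n(self) -> int:
        return len(self.genotype_ids)

    def transform(self, features: PeakFeatures) -> np.ndarray:
        """Standardize a query genotype with the stored per-column transform."""
        row = _design_row(features)
        return (row - self.means) / self.sds

    def inverse_transform(self, standardized: np.ndarray) -> np.ndarray:
        return np.asarray(standardized) * self.sds + self.means


@dataclass(frozen=True)
class ConsensusResult:
    genotype_ids: tuple[str, ...]
    consensus_matrix: np.ndarray  # for k_selected, row order = genotype_ids
    k_selected: int
    labels: np.ndarray  # cluster ids 1..k, aligned with genotype_ids
    stability_by_k: dict[int, float]  # PAC per candidate k (lower = more stable)
    labels_by_k: dict[int, np.ndarray]
    settings: dict


@dataclass(frozen=True)
class SubpopulationAssignment:
    genotype_id: str
    label: int  # 0-5
    source: str  # artifact_filter | consensus | knn
    neighbor_votes: dict[int, int] | None = None


def _design_row(f: PeakFeatures) -> np.ndarray:
    if not f.has_peak:
        raise ValueError(f"genotype {f.genotype_id!r} has no peak; not clusterable")
    return np.array(
        [
            f.activity_max_pct_wt,
            math.log(f.phe_peak_uM),
            math.log(f.bh4_peak_uM),
            math.log(f.working_range_width_uM),
        ]
    )


def build_feature_matrix(features: list[PeakFeatures]) -> FeatureMatrix:
    """Assemble and z-standardize the four-column feature matrix."""
    if len(features) < 2:
        raise ValueError("need at least 2 genotypes to build a feature matrix")
    raw = np.stack([_design_row(f) for f in features])
    if not np.all(np.isfinite(raw)):
        raise ValueError("feature matrix contains non-finite values")
    means = raw.mean(axis=0)
    sds = raw.std(axis=0, ddof=0)
    if np.any(sds == 0):
        # constant column: center only, keep unit scale
        sds = np.where(sds == 0, 1.0, sds)
    values = (raw - means) / sds
    return FeatureMatrix(
        genotype_ids=tuple(f.genotype_id for f in features),
        values=values,
        raw=raw,
        means=means,
        sds=sds,
    )


def consensus_cluster(
    fm: FeatureMatrix,
    k_range: range | tuple[int, ...] = range(2, 9),
    n_resamples: int = 250,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    n_restarts: int = 1,
    pac_window: tuple[float, float] = (0.1, 0.9),
    pac_tolerance: float = 0.01,
) -> ConsensusResult:
    """Resampled co-association consensus clustering with PAC model selection.

    For each candidate k, ``n_resamples`` row subsamples (without replacement,
    ``subsample_fraction`` of the cohort) are clustered by seeded k-means++
    (``n_restarts`` restarts); the consensus matrix holds, for every genotype
    pair, the fraction of co-sampled runs assigning them together.  Final
    labels per k come from average-linkage hierarchical clustering of
    (1 - consensus); ``k_selected`` minimizes PAC (the fraction of off-diagonal
    consensus entries strictly inside ``pac_window``).  Near-ties are resolved
    by structure: a merge of genuinely separated clusters is just as stable as
    the true partition (PAC ~ 0 at every k up to the true one), so when any k
    reaches essentially perfect stability (PAC <= ``pac_tolerance``) the
    finest such partition (largest k) is selected; otherwise the smallest k
    within ``pac_tolerance`` of the minimum wins (parsimony under noise).

    Reproducibility: a master seed derives per-(k, resample) child seeds, and
    subsampling is keyed to genotype ids sorted lexicographically, so input
    row order cannot change the result.
    """
    k_range = tuple(k_range)
    n = fm.n
    if n < max(k_range) + 2:
        raise ValueError(f"need at least {max(k_range) + 2} genotypes for k up to {max(k_range)}")
    # operate in sorted-genotype order so results are permutation invariant
    order = np.argsort(np.asarray(fm.genotype_ids))
    X = fm.values[order]
    if np.allclose(X, X[0]):
        raise ValueError("no cluster structure: all feature rows identical")
    m = max(2, int(round(subsample_fraction * n)))

    pac: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    consensus_by_k: dict[int, np.ndarray] = {}
    lo, hi = pac_window
    for k in k_range:
        together = np.zeros((n, n))
        sampled = np.zeros((n, n))
        for r in range(n_resamples):
            child = np.random.SeedSequence([int(seed), int(k), int(r)])
            rng = np.random.default_rng(child)
            idx = rng.choice(n, size=m, replace=False)
            km_seed = int(rng.integers(0, 2**31 - 1))
            km = KMeans(n_clusters=k, n_init=n_restarts, random_state=km_seed)
            lab = km.fit_predict(X[idx])
            same = lab[:, None] == lab[None, :]
            together[np.ix_(idx, idx)] += same
            sampled[np.ix_(idx, idx)] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            consensus = np.where(sampled > 0, together / np.maximum(sampled, 1), 0.0)
        np.fill_diagonal(consensus, 1.0)
        consensus = (consensus + consensus.T) / 2.0
        consensus_by_k[k] = consensus
        dist = squareform(1.0 - consensus, checks=False)
        tree = linkage(dist, method="average")
        labels_by_k[k] = fcluster(tree, t=k, criterion="maxclust")
        off = consensus[np.triu_indices(n, k=1)]
        pac[k] = float(np.mean((off > lo) & (off < hi)))

    pac_min = min(pac.values())
    if pac_min <= pac_tolerance:
        k_selected = max(k for k in k_range if pac[k] <= pac_tolerance)
    else:
        k_selected = min(k for k in k_range if pac[k] <= pac_min + pac_tolerance)

    # map results back to the caller's row order
    inv = np.empty(n, dtype=int)
    inv[order] = np.arange(n)
    consensus_orig = consensus_by_k[k_selected][np.ix_(inv, inv)]
    labels_orig = {k: lab[inv] for k, lab in labels_by_k.items()}
    return ConsensusResult(
        genotype_ids=fm.genotype_ids,
        consensus_matrix=consensus_orig,
        k_selected=k_selected,
        labels=labels_orig[k_selected],
        stability_by_k=pac,
        labels_by_k=labels_orig,
        settings={
            "n_resamples": n_resamples,
            "subsample_fraction": subsample_fraction,
            "base_method": f"kmeans(n_init={n_restarts})",
            "k_range": k_range,
            "seed": seed,
            "pac_window": pac_window,
            "pac_tolerance": pac_tolerance,
        },
    )


def name_subpopulations(
    result: ConsensusResult, fm: FeatureMatrix, wt_reference: PeakFeatures
) -> dict[int, int]:
    """Map cluster ids to canonical subpopulation names 1-5 by cluster medians.

    Raises :class:`SubpopulationNamingError` when the geometry does not
    support the rules (e.g. not exactly two right-shifted clusters); callers
    should then report clusters unnamed.
    """
    if result.k_selected != 5:
        raise SubpopulationNamingError(
            f"naming is defined for 5 clusters, got k={result.k_selected}"
        )
    labels = result.labels
    activity = fm.raw[:, 0]
    ln_phe = fm.raw[:, 1]
    clusters = sorted(set(labels.tolist()))
    med_act = {c: float(np.median(activity[labels == c])) for c in clusters}
    med_phe = {c: float(np.median(ln_phe[labels == c])) for c in clusters}

    mapping: dict[int, int] = {}
    # 5: highest median activity
    c5 = max(clusters, key=lambda c: med_act[c])
    mapping[c5] = 5
    rest = [c for c in clusters if c != c5]
    # 2: lowest median peak [Phe]
    c2 = min(rest, key=lambda c: med_phe[c])
    mapping[c2] = 2
    rest = [c for c in rest if c != c2]
    # 3 and 4: the two clusters right-shifted past the WT peak, split by activity
    wt_ln_phe = math.log(wt_reference.phe_peak_uM)
    right = [c for c in rest if med_phe[c] > wt_ln_phe]
    if len(right) != 2:
        raise SubpopulationNamingError(
            f"expected exactly 2 right-shifted clusters (peak [Phe] above WT "
            f"{wt_reference.phe_peak_uM:.0f} uM), found {len(right)}"
        )
    c3 = max(right, key=lambda c: med_act[c])
    c4 = min(right, key=lambda c: med_act[c])
    if c3 == c4:
        raise SubpopulationNamingError("right-shifted clusters tie on median activity")
    mapping[c3], mapping[c4] = 3, 4
    # 1: the remainder
    remainder = [c for c in rest if c not in (c3, c4)]
    if len(remainder) != 1:
        raise SubpopulationNamingError("naming rules did not yield a bijection")
    mapping[remainder[0]] = 1
    return mapping


def assign_knn(
    query: PeakFeatures,
    reference: FeatureMatrix,
    labels: np.ndarray,
    k: int = 5,
) -> SubpopulationAssignment:
    """Label a new genotype by majority vote of its k nearest reference rows.

    Distances are Euclidean in the reference's standardized feature space.
    Ties are broken by smaller mean neighbor distance, then by smaller label.
    """
    labels = np.asarray(labels)
    if k > reference.n:
        raise ValueError(f"k={k} exceeds reference size {reference.n}")
    q = reference.transform(query)
    d = np.linalg.norm(reference.values - q, axis=1)
    nearest = np.argsort(d, kind="stable")[:k]
    votes: dict[int, int] = {}
    for i in nearest:
        votes[int(labels[i])] = votes.get(int(labels[i]), 0) + 1
    best = max(votes.values())
    tied = [lab for lab, v in votes.items() if v == best]
    if len(tied) > 1:
        mean_d = {lab: float(d[nearest[labels[nearest] == lab]].mean()) for lab in tied}
        m = min(mean_d.values())
        tied = sorted(lab for lab, md in mean_d.items() if md == m)
    return SubpopulationAssignment(
        genotype_id=query.genotype_id,
        label=int(tied[0]),
        source="knn",
        neighbor_votes=votes,
    )
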