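"""Cluster residual-activity genotypes into subpopulations.

Consensus-clusters the QC-passing genotypes on (activity %WT, ln peak [Phe],
ln peak [BH4], ln working-range width), selects the cluster number from the
PAC stability curve, names clusters 1-5 by their medians relative to the
wild type, and labels everything else: subpopulation 0 from the
no-activity filter, and a leave-one-out k-NN check for future-sample
classification.  Writes assignments, the consensus matrix, and the
stability curve.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from pahscape.cluster import assign_knn, build_feature_matrix
from pahscape.pipeline import cluster_cohort, process_cohort
from pahscape.simulate import simulate_cohort

SEED = 1
RESULTS = Path("results")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cohort = simulate_cohort(seed=SEED)
    results = process_cohort(cohort)
    fm, consensus, mapping, assignments = cluster_cohort(results, seed=SEED)

    pd.DataFrame(
        {
            "genotype_id": sorted(assignments),
            "label": [assignments[g].label for g in sorted(assignments)],
            "source": [assignments[g].source for g in sorted(assignments)],
        }
    ).to_csv(RESULTS / "assignments.tsv", sep="\t", index=False)
    pd.DataFrame(
        consensus.consensus_matrix, index=consensus.genotype_ids, columns=consensus.genotype_ids
    ).to_csv(RESULTS / "consensus_matrix.tsv", sep="\t", float_format="%.4f")
    pd.DataFrame(
        {"k": list(consensus.stability_by_k), "pac": list(consensus.stability_by_k.values())}
    ).to_csv(RESULTS / "stability_by_k.tsv", sep="\t", index=False, float_format="%.4f")

    pac = {k: round(v, 3) for k, v in consensus.stability_by_k.items()}
    print(f"PAC by k: {pac} -> k = {consensus.k_selected}")
    labels = {g: a.label for g, a in assignments.items()}
    sizes = pd.Series(list(labels.values())).value_counts().sort_index().to_dict()
    print(f"subpopulation sizes: {sizes}")

    truth = cohort.truth.set_index("genotype_id")
    tru = [int(truth.loc[g].label) for g in consensus.genotype_ids]
    ari = adjusted_rand_score(tru, consensus.labels)
    agree = sum(labels[g] == int(truth.loc[g].label) for g in labels)
    print(f"vs planted labels: ARI {ari:.3f}, named agreement {agree}/{len(labels)}")

    # leave-one-out k-NN labeling of "future" samples
    ref_labels = np.array([labels[g] for g in fm.genotype_ids])
    hits = 0
    feats = {g: results.features[g] for g in fm.genotype_ids}
    for i, gid in enumerate(fm.genotype_ids):
        keep = [j for j in range(fm.n) if j != i]
        sub = build_feature_matrix([feats[fm.genotype_ids[j]] for j in keep])
        out = assign_knn(feats[gid], sub, ref_labels[keep], k=5)
        hits += out.label == ref_labels[i]
    print(f"k-NN leave-one-out accuracy (k=5): {hits}/{fm.n}")
    print(f"assignments -> {RESULTS / 'assignments.tsv'}")


if __name__ == "__main__":
    main()
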