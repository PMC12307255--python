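"""Genotype-phenotype correlation over registry-style clinical records.

Per-genotype records carry counts of clinical phenotype classes — classical
PKU (untreated blood [Phe] > 1200 umol/L), mild PKU (600-1200), and MHPA
(< 600) — and of BH4-treatment response classes (responder and slow-responder,
pooled as "responders", versus non-responder).  Genotypes enter a correlation
only with more than ``min_records`` records for that purpose, and genotypes
carrying annotation-unstable variants (p.Ile65Thr, p.Phe39Leu) are excluded.
Subpopulation summaries pool patient records across the genotypes of each
subpopulation, so percentages are patient-level, not genotype-averaged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

EXCLUDED_VARIANTS = ("p.Ile65Thr", "p.Phe39Leu")

#: Standardized per-subpopulation interpretation text for reports.
INTERPRETATION_TEXT = {
    0: "No residual PAH activity; classical PKU expected; no BH4 response.",
    1: "Reduced activity with a WT-like peak; variable BH4 response — consider an "
    "extended loading test or increased BH4 dosage after a negative standard test.",
    2: "Left-shifted narrow peak active at low [Phe]; mild phenotypes and a high "
    "BH4-response rate; the standard loading test is expected to be informative.",
    3: "Right-shifted higher peak; residual activity appears at elevated [Phe] — "
    "testing at higher blood Phe levels reduces false-negative loading tests.",
    4: "Right-shifted lower peak; activity absent at low [Phe] and response rates "
    "are low under the standard protocol — test at higher Phe load and consider "
    "higher BH4 dosage.",
    5: "High residual activity; mild phenotypes (MHPA/mild PKU) and consistent BH4 "
    "response; monitor Phe levels per treatment guidelines.",
}


@dataclass(frozen=True)
class ClinicalRecordSet:
    """Per-genotype phenotype and BH4-response record counts."""

    genotype_id: str
    n_classic: int = 0
    n_mild: int = 0
    n_mhpa: int = 0
    n_responder: int = 0
    n_slow: int = 0
    n_nonresponder: int = 0
    excluded_variant_flag: bool = False

    def __post_init__(self) -> None:
        for name in ("n_classic", "n_mild", "n_mhpa", "n_responder", "n_slow", "n_nonresponder"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def n_phenotype(self) -> int:
        return self.n_classic + self.n_mild + self.n_mhpa

    @property
    def n_response(self) -> int:
        return self.n_responder + self.n_slow + self.n_nonresponder


@dataclass(frozen=True)
class SubpopulationSummary:
    label: int
    n_genotypes: int
    n_phenotype_records: int
    n_response_records: int
    frac_classic: float  # nan when no phenotype records
    frac_mild: float
    frac_mhpa: float
    responder_fraction: float  # (responder + slow) / all response records; nan if none


def flag_excluded_variants(genotype_id: str, variants: Iterable[str] = EXCLUDED_VARIANTS) -> bool:
    """True when either allele of the genotype names an excluded variant."""
    return any(v in genotype_id for v in variants)


def read_clinical_table(path, column_map: dict[str, str] | None = None) -> list[ClinicalRecordSet]:
    """Read a registry-style CSV/XLSX table of per-genotype record counts.

    ``column_map`` maps this package's field names to the file's header names;
    by default headers are expected to match the field names.  The exclusion
    flag is derived from the genotype id unless an ``excluded_variant_flag``
    column is present.
    """
    path = str(path)
    df = pd.read_excel(path) if path.lower().endswith((".xlsx", ".xlsm")) else pd.read_csv(path)
    cm = {k: k for k in (
        "genotype_id", "n_classic", "n_mild", "n_mhpa", "n_responder", "n_slow", "n_nonresponder",
    )}
    if column_map:
        cm.update(column_map)
    records = []
    for _, row in df.iterrows():
        gid = str(row[cm["genotype_id"]])
        flag = bool(row["excluded_variant_flag"]) if "excluded_variant_flag" in df.columns else flag_excluded_variants(gid)
        records.append(
            ClinicalRecordSet(
                genotype_id=gid,
                **{f: int(row[cm[f]]) for f in cm if f != "genotype_id"},
                excluded_variant_flag=flag,
            )
        )
    return records


def filter_records(
    records: Sequence[ClinicalRecordSet], min_records: int = 10, purpose: str = "phenotype"
) -> list[ClinicalRecordSet]:
    """Keep genotypes with strictly more than ``min_records`` records for the purpose.

    Phenotype and response correlations are filtered independently, so their
    retained totals differ.  Excluded-variant genotypes are always dropped.
    """
    if purpose not in ("phenotype", "response"):
        raise ValueError(f"unknown purpose {purpose!r}")
    key = "n_phenotype" if purpose == "phenotype" else "n_response"
    return [
        r for r in records if not r.excluded_variant_flag and getattr(r, key) > min_records
    ]


def summarize_subpopulations(
    assignments: dict[str, int], records: Sequence[ClinicalRecordSet]
) -> list[SubpopulationSummary]:
    """Pool record counts per subpopulation label and report patient-level fractions."""
    missing = [r.genotype_id for r in records if r.genotype_id not in assignments]
    if missing:
        raise ValueError(f"records without a subpopulation assignment: {missing[:5]}")
    out = []
    for label in sorted(set(assignments.values())):
        sub = [r for r in records if assignments[r.genotype_id] == label]
        n_ph = sum(r.n_phenotype for r in sub)
        n_rs = sum(r.n_response for r in sub)
        out.append(
            SubpopulationSummary(
                label=label,
                n_genotypes=len(sub),
                n_phenotype_records=n_ph,
                n_response_records=n_rs,
                frac_classic=sum(r.n_classic for r in sub) / n_ph if n_ph else float("nan"),
                frac_mild=sum(r.n_mild for r in sub) / n_ph if n_ph else float("nan"),
                frac_mhpa=sum(r.n_mhpa for r in sub) / n_ph if n_ph else float("nan"),
                responder_fraction=(
                    sum(r.n_responder + r.n_slow for r in sub) / n_rs if n_rs else float("nan")
                ),
            )
        )
    return out


def residual_activity_vs_response(
    assignments: dict[str, int], records: Sequence[ClinicalRecordSet]
) -> float:
    """Fraction of non-responder records among genotypes with residual activity.

    Residual activity = subpopulation labels 1-5; the denominator pools all
    BH4-response records of those genotypes.
    """
    residual = [r for r in records if assignments.get(r.genotype_id, 0) != 0]
    total = sum(r.n_response for r in residual)
    if total == 0:
        return float("nan")
    return sum(r.n_nonresponder for r in residual) / total


def summaries_to_frame(summaries: Sequence[SubpopulationSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])
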