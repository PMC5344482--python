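"""SNP and phenotype quality control.

SNP filters use strict inequalities (call rate > 0.95, quality score > 0.6,
MAF > 0.01), matching the "greater than" screening convention of chip
genotyping pipelines. The phenotype screen removes whole birds whose ADG or
ADFI deviates more than 3 SD from the mean, with mean and SD computed once
on the input table (a single deterministic pass, not iterated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix


class QCError(ValueError):
    pass


@dataclass
class QCReport:
    """Counts and identities of removed units, per criterion.

    ``removed_by_criterion`` may double-count a unit failing several
    criteria; ``removed_ids`` and ``retained_ids`` partition the input.
    """

    kind: str                       # "snp" or "phenotype"
    n_input: int
    removed_by_criterion: dict = field(default_factory=dict)
    removed_ids: list = field(default_factory=list)
    retained_ids: list = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return len(self.removed_ids)

    @property
    def n_retained(self) -> int:
        return len(self.retained_ids)

    def to_text(self) -> str:
        lines = [f"{self.kind} QC: {self.n_input} in, "
                 f"{self.n_retained} retained, {self.n_removed} removed"]
        for crit, n in self.removed_by_criterion.items():
            lines.append(f"  failed {crit}: {n}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"criterion": c, "n_removed": n}
                for c, n in self.removed_by_criterion.items()]
        rows.append({"criterion": "total_removed", "n_removed": self.n_removed})
        rows.append({"criterion": "retained", "n_removed": self.n_retained})
        return pd.DataFrame(rows)


def filter_snps(genotypes: GenotypeMatrix, panel: pd.DataFrame,
                call_rate_min: float = 0.95, quality_min: float = 0.6,
                maf_min: float = 0.01):
    """Retain SNPs with call rate, quality score and MAF strictly above the
    thresholds.

    Returns (filtered GenotypeMatrix, QCReport). Missing genotypes at
    retained SNPs are kept as missing; imputation happens when the genomic
    relationship matrix is built.
    """
    panel = panel.set_index("snp_id") if "snp_id" in panel.columns else panel
    if list(panel.index.astype(str)) != list(genotypes.snp_ids):
        raise QCError("panel metadata is not aligned with genotype columns")
    for col in ("call_rate", "quality_score", "maf"):
        if col not in panel.columns:
            raise QCError(f"panel lacks column {col!r}")

    ok_cr = panel["call_rate"].to_numpy() > call_rate_min
    ok_q = panel["quality_score"].to_numpy() > quality_min
    ok_maf = panel["maf"].to_numpy() > maf_min
    keep = ok_cr & ok_q & ok_maf

    report = QCReport(
        kind="snp", n_input=genotypes.n_snps,
        removed_by_criterion={
            f"call_rate<={call_rate_min}": int((~ok_cr).sum()),
            f"quality<={quality_min}": int((~ok_q).sum()),
            f"maf<={maf_min}": int((~ok_maf).sum()),
        },
        removed_ids=[s for s, k in zip(genotypes.snp_ids, keep) if not k],
        retained_ids=[s for s, k in zip(genotypes.snp_ids, keep) if k],
    )
    return genotypes.subset_snps(report.retained_ids), report


def filter_phenotypes(traits: pd.DataFrame, check_traits=("ADG", "ADFI"),
                      sd_threshold: float = 3.0):
    """Remove whole birds deviating more than ``sd_threshold`` SD on any
    check trait.

    Means and SDs are computed once on the input table. A zero-SD (constant)
    trait removes nobody. Applying the filter twice can remove further birds
    because the statistics recompute; the pipeline applies it exactly once.

    Returns (filtered TraitTable, QCReport).
    """
    if len(traits) < 3:
        raise QCError("need at least 3 records to estimate an SD")
    removed_by = {}
    bad = pd.Series(False, index=traits.index)
    for t in check_traits:
        if t not in traits.columns:
            raise QCError(f"trait table lacks column {t!r}")
        x = traits[t].astype(float)
        mu, sd = x.mean(), x.std(ddof=1)
        if sd == 0:
            fail = pd.Series(False, index=traits.index)
        else:
            fail = (x - mu).abs() > sd_threshold * sd
        removed_by[f"{t}>|{sd_threshold}SD|"] = int(fail.sum())
        bad |= fail
    report = QCReport(
        kind="phenotype", n_input=len(traits),
        removed_by_criterion=removed_by,
        removed_ids=list(traits.index[bad]),
        retained_ids=list(traits.index[~bad]),
    )
    return traits.loc[~bad].copy(), report
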