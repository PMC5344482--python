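"""Additively coded SNP genotypes (0/1/2 dosages of a counted allele)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GenotypeMatrix:
    """n individuals x m SNPs dosage matrix; ``NaN`` marks a missing call.

    Dosages count copies of one arbitrarily chosen allele per SNP, the usual
    additive coding of PLINK ``--recode A`` output.
    """

    ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.snp_ids = [str(s) for s in self.snp_ids]
        arr = np.asarray(self.dosages, dtype=float)
        if arr.shape != (len(self.ids), len(self.snp_ids)):
            raise ValueError(
                f"dosage shape {arr.shape} does not match "
                f"{len(self.ids)} ids x {len(self.snp_ids)} SNPs"
            )
        finite = arr[np.isfinite(arr)]
        if finite.size and (np.any(finite < 0) or np.any(finite > 2)):
            raise ValueError("dosages must lie in [0, 2]")
        self.dosages = arr

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.dosages)

    def subset_individuals(self, ids) -> "GenotypeMatrix":
        index = {i: k for k, i in enumerate(self.ids)}
        rows = [index[str(i)] for i in ids]
        return GenotypeMatrix([self.ids[r] for r in rows], list(self.snp_ids),
                              self.dosages[rows])

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        index = {s: k for k, s in enumerate(self.snp_ids)}
        cols = [index[str(s)] for s in snp_ids]
        return GenotypeMatrix(list(self.ids), [self.snp_ids[c] for c in cols],
                              self.dosages[:, cols])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.ids, columns=self.snp_ids)
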