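"""File formats: PLINK .raw-style genotypes, CSV tables, matrices, config.

Genotypes are exchanged in the additive PLINK ``--recode A`` dialect
(header ``FID IID PAT MAT SEX PHENOTYPE`` followed by one 0/1/2/NA column
per SNP) and as plain CSV. Relationship matrices round-trip through a
square CSV (header of ids) or a long ``id1,id2,value`` format, both at 12
significant digits. The run configuration is YAML with unknown keys
rejected.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotypes import GenotypeMatrix
from .kinship import RelationshipMatrix
from .pedigree import Pedigree
from .simulate import SimulationConfig


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def write_genotypes_raw(genotypes: GenotypeMatrix, path,
                        pedigree: Pedigree | None = None) -> None:
    """Write a PLINK .raw-style additive table (0/1/2/NA, space-separated)."""
    path = Path(path)
    parents = pedigree.parent_map() if pedigree is not None else {}
    sexes = ({r.id: r.sex for r in pedigree.table.itertuples()}
             if pedigree is not None else {})
    sex_code = {"M": "1", "F": "2"}
    with path.open("w") as fh:
        fh.write(" ".join(_RAW_META + list(genotypes.snp_ids)) + "\n")
        for i, row in zip(genotypes.ids, genotypes.dosages):
            s, d = parents.get(i, (None, None))
            meta = [i, i, s or "0", d or "0",
                    sex_code.get(sexes.get(i), "0"), "-9"]
            codes = ["NA" if not np.isfinite(v) else str(int(v)) for v in row]
            fh.write(" ".join(meta + codes) + "\n")


def read_genotypes_raw(path) -> GenotypeMatrix:
    """Parse a PLINK .raw-style table; bad tokens are reported with their
    line and column."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().split()
        if header[:6] != _RAW_META:
            raise FormatError(f"{path}: not a .raw header (expected "
                              f"{' '.join(_RAW_META)} ...)")
        snp_ids = header[6:]
        ids, rows = [], []
        for ln, line in enumerate(fh, start=2):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + len(snp_ids):
                raise FormatError(f"{path}:{ln}: expected "
                                  f"{6 + len(snp_ids)} fields, got {len(tok)}")
            ids.append(tok[1])
            vals = []
            for col, t in enumerate(tok[6:], start=7):
                if t == "NA":
                    vals.append(np.nan)
                elif t in ("0", "1", "2"):
                    vals.append(float(t))
                else:
                    raise FormatError(f"{path}:{ln}: column {col}: invalid "
                                      f"genotype token {t!r}")
            rows.append(vals)
    return GenotypeMatrix(ids, snp_ids, np.array(rows, dtype=float))


def write_genotypes_csv(genotypes: GenotypeMatrix, path) -> None:
    df = genotypes.to_dataframe()
    df.index.name = "id"
    df.to_csv(path, na_rep="NA")


def read_genotypes_csv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col="id", na_values=["NA"])
    vals = df.to_numpy(dtype=float)
    ok = np.isin(vals, (0.0, 1.0, 2.0)) | ~np.isfinite(vals)
    if not ok.all():
        r, c = np.argwhere(~ok)[0]
        raise FormatError(f"{path}: invalid genotype value {vals[r, c]!r} at "
                          f"row {df.index[r]!r}, SNP {df.columns[c]!r}")
    return GenotypeMatrix([str(i) for i in df.index], list(df.columns), vals)


# ---------------------------------------------------------------------------
# pedigree / phenotypes / panel
# ---------------------------------------------------------------------------

def write_pedigree(pedigree: Pedigree, path) -> None:
    pedigree.table.to_csv(path, index=False)


def read_pedigree(path) -> Pedigree:
    """Read and validate a pedigree CSV; rows are re-sorted parents-first
    if needed, cycles and orphan parents raise."""
    return Pedigree(pd.read_csv(path, dtype={"id": str}))


def write_phenotypes(traits: pd.DataFrame, path) -> None:
    out = traits.copy()
    out.index.name = "id"
    out.to_csv(path)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="id").rename(index=str)


def write_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False)


def read_panel(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"snp_id": str})


# ---------------------------------------------------------------------------
# relationship matrices
# ---------------------------------------------------------------------------

def write_matrix(matrix: RelationshipMatrix, path, fmt: str = "square") -> None:
    path = Path(path)
    if fmt == "square":
        df = matrix.to_dataframe()
        df.index.name = "id"
        df.to_csv(path, float_format="%.12g")
    elif fmt == "long":
        n = len(matrix.ids)
        iu = np.triu_indices(n)
        pd.DataFrame({
            "id1": [matrix.ids[i] for i in iu[0]],
            "id2": [matrix.ids[j] for j in iu[1]],
            "value": matrix.values[iu],
        }).to_csv(path, index=False, float_format="%.12g")
    else:
        raise FormatError(f"unknown matrix format {fmt!r}")


def read_matrix(path, kind: str = "pedigree") -> RelationshipMatrix:
    df = pd.read_csv(path)
    if list(df.columns[:3]) == ["id1", "id2", "value"]:
        ids = list(dict.fromkeys(df["id1"].astype(str)))
        pos = {i: k for k, i in enumerate(ids)}
        vals = np.zeros((len(ids), len(ids)))
        for r in df.itertuples():
            i, j = pos[str(r.id1)], pos[str(r.id2)]
            vals[i, j] = vals[j, i] = r.value
        return RelationshipMatrix(ids, vals, kind=kind)
    df = df.set_index(df.columns[0])
    return RelationshipMatrix([str(i) for i in df.index],
                              df.to_numpy(dtype=float), kind=kind)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class QCConfig:
    call_rate_min: float = 0.95
    quality_min: float = 0.6
    maf_min: float = 0.01
    sd_threshold: float = 3.0
    check_traits: tuple = ("ADG", "ADFI")


@dataclasses.dataclass
class CVConfig:
    n_folds: int = 4
    cvf_repeats: int = 10
    cvr_repeats: int = 50
    traits: tuple = ("FCR", "RFI", "ADG", "ADFI")


@dataclasses.dataclass
class RunConfig:
    """Whole-pipeline configuration; round-trips losslessly through YAML."""

    seed: int = 1
    outdir: str = "results"
    selection_k: int = 50
    simulation: SimulationConfig = dataclasses.field(
        default_factory=SimulationConfig)
    qc: QCConfig = dataclasses.field(default_factory=QCConfig)
    cv: CVConfig = dataclasses.field(default_factory=CVConfig)

    def to_dict(self) -> dict:
        d = {"seed": self.seed, "outdir": self.outdir,
             "selection_k": self.selection_k,
             "simulation": self.simulation.to_dict(),
             "qc": dataclasses.asdict(self.qc),
             "cv": dataclasses.asdict(self.cv)}
        d["qc"]["check_traits"] = list(self.qc.check_traits)
        d["cv"]["traits"] = list(self.cv.traits)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        out = cls()
        sections = {"simulation": (SimulationConfig, "simulation"),
                    "qc": (QCConfig, "qc"), "cv": (CVConfig, "cv")}
        for key in list(data):
            if key in sections:
                klass, attr = sections[key]
                sub = dict(data.pop(key))
                valid = {f.name for f in dataclasses.fields(klass)}
                unknown = set(sub) - valid
                if unknown:
                    raise FormatError(f"unknown {key} config key(s): "
                                      f"{sorted(unknown)}")
                for listy in ("genetic_corr", "residual_corr", "line_a_freqs",
                              "line_b_freqs"):
                    if listy in sub and sub[listy] is not None:
                        sub[listy] = np.asarray(sub[listy], dtype=float)
                for tup in ("check_traits", "traits"):
                    if tup in sub and sub[tup] is not None:
                        sub[tup] = tuple(sub[tup])
                setattr(out, attr, klass(**sub))
            elif key in {"seed", "outdir", "selection_k"}:
                setattr(out, key, data.pop(key))
            else:
                raise FormatError(f"unknown config key {key!r}")
        return out

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
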