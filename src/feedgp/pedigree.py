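"""Pedigree container for a multi-generation intercross.

A pedigree is an ordered table of individuals with optional sire/dam links.
Founders have no recorded parents. The container validates referential
integrity, rejects cyclic parentage, and keeps individuals sorted so that
parents always precede their offspring (required by the tabular
relationship-matrix recursion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical column order for pedigree tables.
PEDIGREE_COLUMNS = ("id", "sire", "dam", "generation", "sex", "hatch", "family")


class PedigreeError(ValueError):
    """Raised for structural problems: duplicate ids, orphan parents, cycles."""


@dataclass
class Pedigree:
    """Ordered pedigree with parents listed before their offspring.

    Parameters
    ----------
    table:
        DataFrame with at least columns ``id``, ``sire``, ``dam``. Missing
        parents are ``None``/``NaN``/empty string/``"0"`` (PLINK convention).
        Extra columns (generation, sex, hatch, family, line, ...) are kept.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in ("id", "sire", "dam"):
            if col not in df.columns:
                raise PedigreeError(f"pedigree table lacks required column {col!r}")
        df["id"] = df["id"].astype(str)
        for col in ("sire", "dam"):
            vals = df[col].astype(object)
            vals = vals.where(~pd.isna(vals), None)
            vals = [None if v in (None, "", "0", 0) else str(v) for v in vals]
            df[col] = vals
        if df["id"].duplicated().any():
            dups = df.loc[df["id"].duplicated(), "id"].tolist()
            raise PedigreeError(f"duplicate individual ids: {dups[:5]}")
        known = set(df["id"])
        for col in ("sire", "dam"):
            orphans = {p for p in df[col] if p is not None and p not in known}
            if orphans:
                raise PedigreeError(f"unknown {col} reference(s): {sorted(orphans)[:5]}")
        df = self._toposort(df)
        self.table = df.reset_index(drop=True)

    @staticmethod
    def _toposort(df: pd.DataFrame) -> pd.DataFrame:
        """Stable Kahn sort (parents before offspring); names any cycle."""
        ids = df["id"].tolist()
        parents = {r.id: [p for p in (r.sire, r.dam) if p is not None]
                   for r in df.itertuples()}
        children: dict[str, list[str]] = {i: [] for i in ids}
        indeg = {i: 0 for i in ids}
        for i in ids:
            for p in parents[i]:
                children[p].append(i)
                indeg[i] += 1
        order: list[str] = []
        ready = [i for i in ids if indeg[i] == 0]
        while ready:
            nxt = ready.pop(0)
            order.append(nxt)
            for c in children[nxt]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
        if len(order) < len(ids):
            cycle = sorted(i for i in ids if indeg[i] > 0)
            raise PedigreeError(
                f"cyclic parentage involving individuals: {cycle}"
            )
        pos = {i: k for k, i in enumerate(order)}
        return df.iloc[np.argsort([pos[i] for i in df["id"]], kind="stable")]

    # -- accessors -----------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return self.table["id"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    @property
    def founders(self) -> list[str]:
        t = self.table
        mask = [s is None and d is None for s, d in zip(t["sire"], t["dam"])]
        return t.loc[mask, "id"].tolist()

    def parent_map(self) -> dict[str, tuple[str | None, str | None]]:
        return {r.id: (r.sire, r.dam) for r in self.table.itertuples()}

    def generation(self, label: str) -> list[str]:
        if "generation" not in self.table.columns:
            raise PedigreeError("pedigree has no 'generation' column")
        return self.table.loc[self.table["generation"] == label, "id"].tolist()

    def subset(self, ids) -> "Pedigree":
        keep = set(ids)
        return Pedigree(self.table[self.table["id"].isin(keep)].copy())

    @classmethod
    def from_records(cls, records) -> "Pedigree":
        return cls(pd.DataFrame.from_records(records))
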