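"""Pedigree container: directed full-sib family structure.

A pedigree is a table with one row per individual carrying ``id``, ``dam``,
``sire``, ``generation`` and ``family``.  Founders have missing parents
(encoded as ``"0"``) and generation 0.  The container validates acyclicity
and parent availability, which the gene-dropping simulator relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

UNKNOWN = "0"  # conventional missing-parent code


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    table: pd.DataFrame  # columns: id, dam, sire, generation, family

    def __post_init__(self) -> None:
        required = {"id", "dam", "sire", "generation", "family"}
        missing = required - set(self.table.columns)
        if missing:
            raise PedigreeError(f"pedigree table lacks columns {sorted(missing)}")
        self.table = self.table.reset_index(drop=True)
        ids = self.table["id"].astype(str)
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise PedigreeError(f"duplicate individual id {dup!r}")
        self._validate()

    def _validate(self) -> None:
        gen = dict(zip(self.ids, self.table["generation"]))
        for _, row in self.table.iterrows():
            for parent in (row["dam"], row["sire"]):
                parent = str(parent)
                if parent == UNKNOWN:
                    continue
                if parent not in gen:
                    raise PedigreeError(
                        f"parent {parent!r} of {row['id']!r} not in pedigree"
                    )
                if gen[parent] >= row["generation"]:
                    raise PedigreeError(
                        f"parent {parent!r} is not from an earlier generation "
                        f"than {row['id']!r} (cycle or mis-ordered pedigree)"
                    )

    # ------------------------------------------------------------------
    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].astype(str).to_numpy()

    @property
    def founders(self) -> np.ndarray:
        is_founder = (self.table["dam"].astype(str) == UNKNOWN) & (
            self.table["sire"].astype(str) == UNKNOWN
        )
        return self.table.loc[is_founder, "id"].astype(str).to_numpy()

    @property
    def nonfounders(self) -> pd.DataFrame:
        is_founder = (self.table["dam"].astype(str) == UNKNOWN) & (
            self.table["sire"].astype(str) == UNKNOWN
        )
        return self.table.loc[~is_founder]

    def parents_of(self, individual: str) -> tuple[str, str]:
        row = self.table.loc[self.table["id"].astype(str) == str(individual)]
        if row.empty:
            raise PedigreeError(f"unknown individual {individual!r}")
        return str(row["dam"].iloc[0]), str(row["sire"].iloc[0])

    def trios(self) -> pd.DataFrame:
        """Offspring with both parents known: columns id, dam, sire."""
        t = self.table
        known = (t["dam"].astype(str) != UNKNOWN) & (t["sire"].astype(str) != UNKNOWN)
        return t.loc[known, ["id", "dam", "sire"]].astype(str)

    def families(self) -> dict[str, np.ndarray]:
        """Family id → member ids (non-founders only)."""
        nf = self.nonfounders
        return {
            str(fam): grp["id"].astype(str).to_numpy()
            for fam, grp in nf.groupby("family")
        }

    # ------------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path) -> "Pedigree":
        table = pd.read_csv(path, sep="\t", dtype={"id": str, "dam": str, "sire": str})
        return cls(table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)
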