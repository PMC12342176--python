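"""Core genotype container shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # sentinel for a missing diploid dosage

#: columns required in the marker table, in order
MARKER_COLUMNS = ("chrom", "pos", "ref", "alt")


@dataclass
class GenotypeMatrix:
    """An ``n`` samples × ``m`` markers dosage matrix with marker metadata.

    Parameters
    ----------
    dosages
        Integer array of ALT-allele counts in ``{0, 1, 2}`` with ``-1``
        marking a missing genotype; stored as ``int8``.  A float array with
        values in ``[0, 2]`` and no missing entries is also accepted — the
        output of mean imputation, where a missing call becomes the real
        number ``2p``.
    sample_ids
        Length-``n`` sequence of unique sample identifiers.
    markers
        DataFrame with columns ``chrom, pos, ref, alt`` (1-based positions,
        VCF convention), sorted by ``(chrom, pos)``.
    haplotypes
        Optional phased ``2n × m`` 0/1 array (row ``2i`` and ``2i+1`` are the
        two haplotypes of sample ``i``); retained by the simulator, dropped
        by readers of unphased data.
    """

    dosages: np.ndarray
    sample_ids: np.ndarray
    markers: pd.DataFrame
    haplotypes: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.dosages)
        if np.issubdtype(arr.dtype, np.floating):
            if np.isnan(arr).any() or arr.min() < 0 or arr.max() > 2:
                raise ValueError("float dosages must lie in [0, 2] with no NaN")
            self.dosages = arr.astype(np.float64)
        else:
            self.dosages = arr.astype(np.int8)
            valid = np.isin(self.dosages, (0, 1, 2, MISSING))
            if not valid.all():
                bad = np.unique(self.dosages[~valid])
                raise ValueError(f"dosages contain invalid values {bad}")
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (samples × markers) array")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.markers) != m:
            raise ValueError(f"{len(self.markers)} marker rows for {m} columns")
        missing_cols = [c for c in MARKER_COLUMNS if c not in self.markers.columns]
        if missing_cols:
            raise ValueError(f"marker table lacks columns {missing_cols}")
        self.markers = self.markers.reset_index(drop=True)
        order = self.markers.sort_values(["chrom", "pos"], kind="stable").index
        if not np.array_equal(order.to_numpy(), np.arange(m)):
            raise ValueError("marker table must be sorted by (chrom, pos)")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosages.shape

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def missing_fraction(self) -> np.ndarray:
        """Per-marker fraction of missing genotypes."""
        return self.missing_mask().mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Per-marker ALT-allele frequency ``p_j`` over non-missing calls."""
        d = self.dosages.astype(float)
        d[self.missing_mask()] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def dosage_float(self, impute_mean: bool = False) -> np.ndarray:
        """Dosages as float with missing as NaN (or mean-imputed ``2p``)."""
        d = self.dosages.astype(float)
        mask = self.missing_mask()
        d[mask] = np.nan
        if impute_mean and mask.any():
            fill = 2.0 * self.allele_freq()
            idx = np.where(mask)
            d[idx] = fill[idx[1]]
        return d

    def centered(self) -> np.ndarray:
        """``W = dosage − 2p`` with mean imputation of missing entries."""
        d = self.dosage_float(impute_mean=True)
        return d - 2.0 * self.allele_freq()

    # ------------------------------------------------------------------
    def take_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset markers by positional index (order is re-sorted by locus)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.where(index)[0]
        index = np.sort(index)
        hap = self.haplotypes[:, index] if self.haplotypes is not None else None
        return GenotypeMatrix(
            self.dosages[:, index],
            self.sample_ids,
            self.markers.iloc[index].reset_index(drop=True),
            haplotypes=hap,
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.where(index)[0]
        hap = None
        if self.haplotypes is not None:
            hap_idx = np.ravel(np.column_stack([2 * index, 2 * index + 1]))
            hap = self.haplotypes[hap_idx]
        return GenotypeMatrix(
            self.dosages[index],
            self.sample_ids[index],
            self.markers,
            haplotypes=hap,
        )

    def marker_ids(self) -> np.ndarray:
        """``chrom_pos`` style identifiers, e.g. ``Chr01_18689600``."""
        return (
            self.markers["chrom"].astype(str) + "_" + self.markers["pos"].astype(str)
        ).to_numpy()

    def sample_index(self, ids) -> np.ndarray:
        """Positional indices of the given sample ids (order preserved)."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from exc
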