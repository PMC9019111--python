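"""The phased-haplotype container underlying every statistic in the package.

A :class:`HaplotypeMatrix` is a (sites x haplotypes) integer matrix of
allele codes (0 = reference), aligned to a list of
:class:`~kdrhap.genemodel.VariantSite` records, with per-haplotype sample
metadata (two haplotypes per diploid sample).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genemodel import VariantSite

__all__ = ["HaplotypeMatrix"]

#: Required haplotype metadata columns.
META_COLUMNS = ("sample_id", "population", "species", "year")


@dataclass
class HaplotypeMatrix:
    """Phased haplotypes over a set of variant sites.

    Parameters
    ----------
    codes : ndarray, shape (n_sites, n_haplotypes), small ints
        Allele codes; 0 is the reference allele, k>0 indexes
        ``sites[i].alts[k-1]``.
    sites : list of VariantSite
        One record per matrix row, sorted by position.
    meta : DataFrame, one row per haplotype
        Columns ``sample_id, population, species, year``; consecutive
        haplotype pairs (2j, 2j+1) belong to the same diploid sample.
    """

    codes: np.ndarray
    sites: list[VariantSite]
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int16)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (sites x haplotypes)")
        if self.codes.shape[0] != len(self.sites):
            raise ValueError(
                f"{self.codes.shape[0]} matrix rows but {len(self.sites)} sites"
            )
        if len(self.meta) != self.codes.shape[1]:
            raise ValueError(
                f"{self.codes.shape[1]} haplotypes but {len(self.meta)} metadata rows"
            )
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"metadata missing columns {missing}")
        if self.n_haplotypes % 2 != 0:
            raise ValueError("haplotype count must be even (two per diploid)")
        for i, site in enumerate(self.sites):
            if self.codes[i].max(initial=0) >= len(site.alleles):
                raise ValueError(
                    f"allele code exceeds allele count at {site.chrom}:{site.pos}"
                )
        positions = [s.pos for s in self.sites]
        if positions != sorted(positions):
            raise ValueError("sites must be sorted by position")
        self.meta = self.meta.reset_index(drop=True)

    # ------------------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.codes.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.codes.shape[1]

    @property
    def n_samples(self) -> int:
        return self.n_haplotypes // 2

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites])

    # ------------------------------------------------------------------
    def site_index_in(self, start: int, end: int) -> np.ndarray:
        """Row indices of sites with start <= pos < end (end-exclusive)."""
        pos = self.positions
        return np.nonzero((pos >= start) & (pos < end))[0]

    def biallelic_mask(self) -> np.ndarray:
        """True for sites with exactly one alternate allele."""
        return np.array([len(s.alts) == 1 for s in self.sites])

    def carriers(self, site_index: int, alt_index: int) -> np.ndarray:
        """Haplotype column indices carrying allele ``alt_index + 1``."""
        return np.nonzero(self.codes[site_index] == alt_index + 1)[0]

    def allele_counts(self, site_index: int) -> np.ndarray:
        """Counts of each allele (ref first) at one site."""
        site = self.sites[site_index]
        return np.bincount(self.codes[site_index], minlength=len(site.alleles))

    def take_haplotypes(self, indices) -> "HaplotypeMatrix":
        """Sub-matrix restricted to the given haplotype columns."""
        indices = np.asarray(indices)
        return HaplotypeMatrix(
            codes=self.codes[:, indices],
            sites=list(self.sites),
            meta=self.meta.iloc[indices].reset_index(drop=True),
        )

    def take_sites(self, indices) -> "HaplotypeMatrix":
        indices = np.asarray(indices)
        return HaplotypeMatrix(
            codes=self.codes[indices, :],
            sites=[self.sites[i] for i in indices],
            meta=self.meta,
        )

    def populations(self) -> list[str]:
        """Distinct population labels in metadata order of first appearance."""
        return list(dict.fromkeys(self.meta["population"]))

    def population_haplotypes(self, population: str) -> np.ndarray:
        return np.nonzero((self.meta["population"] == population).to_numpy())[0]

    def site_lookup(self) -> dict[int, int]:
        """Map genomic position -> matrix row (first row at that position)."""
        lookup: dict[int, int] = {}
        for i, s in enumerate(self.sites):
            lookup.setdefault(s.pos, i)
        return lookup
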