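"""In-cohort linkage-disequilibrium utilities.

LD is computed as composite r²: the squared Pearson correlation between
unphased genotype dosages (0/1/2) over pairwise-complete individuals. This
needs no phasing and no external reference panel; thresholds follow the
conventional gates of r² > 0.8 for proxies and r² < 0.2 for independence.
Coordinates are 1-based inclusive throughout, matching VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "RegionWindow",
    "UndefinedLDError",
    "region_window",
    "genotype_r2",
    "find_proxies",
    "count_independent_snps",
]


class UndefinedLDError(ValueError):
    """r² is undefined (a SNP is monomorphic on the complete-case subset).

    Deliberately distinct from r² = 0: zero correlation is informative,
    an undefined correlation is not.
    """


VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage matrix with per-variant metadata.

    dosages holds alt-allele counts in {0, 1, 2}; missing genotypes are NaN.
    ``variants`` is a DataFrame with columns id, chrom, pos (1-based), ref,
    alt, in matrix column order; positions are strictly increasing within a
    chromosome.
    """

    dosages: np.ndarray
    individual_ids: list[str]
    variants: pd.DataFrame
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D individuals x variants array")
        if self.dosages.shape[0] != len(self.individual_ids):
            raise ValueError("dosage rows do not match individual_ids")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("dosage columns do not match variant table")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing (NaN)")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table lacks columns: {missing}")
        self.variants = self.variants.reset_index(drop=True)
        for _, sub in self.variants.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing or sub["pos"].duplicated().any():
                raise ValueError("positions must be strictly increasing per chromosome")
        self._index = {v: i for i, v in enumerate(self.variants["id"])}
        if len(self._index) != len(self.variants):
            raise ValueError("duplicate variant ids")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def has_variant(self, snp_id: str) -> bool:
        return snp_id in self._index

    def column(self, snp_id: str) -> int:
        try:
            return self._index[snp_id]
        except KeyError:
            raise KeyError(f"variant {snp_id!r} not in genotype data") from None

    def dosage(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.column(snp_id)]

    def alt_freq(self, snp_id: str) -> float:
        d = self.dosage(snp_id)
        d = d[~np.isnan(d)]
        if d.size == 0:
            return float("nan")
        return float(d.mean() / 2.0)

    def maf(self, snp_id: str) -> float:
        f = self.alt_freq(snp_id)
        return min(f, 1.0 - f)

    def variants_in_window(self, window: "RegionWindow") -> list[str]:
        v = self.variants
        mask = (v["chrom"].astype(str) == str(window.chrom)) & (
            v["pos"].between(window.start, window.end)
        )
        return list(v.loc[mask, "id"])

    def subset_individuals(self, individual_ids: list[str]) -> "GenotypeMatrix":
        pos = {ind: i for i, ind in enumerate(self.individual_ids)}
        rows = [pos[i] for i in individual_ids]
        return GenotypeMatrix(
            self.dosages[rows, :], list(individual_ids), self.variants.copy()
        )


@dataclass(frozen=True)
class RegionWindow:
    """1-based inclusive genomic interval [start, end] on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"invalid window [{self.start}, {self.end}]")

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return str(chrom) == str(self.chrom) and self.start <= pos <= self.end


def region_window(chrom: str, pos: int, half_width: int = 500_000) -> RegionWindow:
    """Window of +/- half_width bp around pos, clamped to position 1."""
    if pos < 1:
        raise ValueError("pos must be >= 1")
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    return RegionWindow(str(chrom), max(1, pos - half_width), pos + half_width)


def _pairwise_complete(g1: np.ndarray, g2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("dosage vectors differ in length")
    keep = ~(np.isnan(g1) | np.isnan(g2))
    return g1[keep], g2[keep]


def genotype_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Composite LD: squared Pearson correlation of dosages.

    Uses pairwise-complete individuals; raises :class:`UndefinedLDError` if
    either SNP is monomorphic on that subset (rather than returning 0).
    """
    a, b = _pairwise_complete(g1, g2)
    if a.size < 2:
        raise UndefinedLDError("fewer than 2 pairwise-complete individuals")
    va = a.var()
    vb = b.var()
    if va == 0.0 or vb == 0.0:
        raise UndefinedLDError("SNP monomorphic on pairwise-complete subset")
    cov = np.mean((a - a.mean()) * (b - b.mean()))
    return float(cov * cov / (va * vb))


def find_proxies(
    index_id: str,
    window: RegionWindow,
    genotypes: GenotypeMatrix,
    r2_min: float = 0.8,
    include_index: bool = False,
) -> list[tuple[str, float]]:
    """Variants in ``window`` with r² > r2_min against the index SNP.

    Returns (snp_id, r²) pairs sorted by descending r², ties by ascending
    position. The index itself is excluded unless ``include_index``.
    """
    g_index = genotypes.dosage(index_id)
    out = []
    for snp_id in genotypes.variants_in_window(window):
        if snp_id == index_id and not include_index:
            continue
        try:
            r2 = genotype_r2(g_index, genotypes.dosage(snp_id))
        except UndefinedLDError:
            if snp_id == index_id:
                raise
            continue
        if r2 > r2_min:
            out.append((snp_id, r2))
    pos = {v: p for v, p in zip(genotypes.variants["id"], genotypes.variants["pos"])}
    out.sort(key=lambda t: (-t[1], pos[t[0]]))
    return out


def count_independent_snps(
    window: RegionWindow, genotypes: GenotypeMatrix, r2_prune: float = 0.2
) -> int:
    """Greedy positional LD pruning: number of approximately independent SNPs.

    SNPs are visited in position order; a SNP is kept iff its r² with every
    previously kept SNP is below ``r2_prune``. Monomorphic SNPs are ignored;
    a window with none returns 0. Deterministic for fixed input.
    """
    ids = genotypes.variants_in_window(window)
    polymorphic = []
    for snp_id in ids:
        d = genotypes.dosage(snp_id)
        d = d[~np.isnan(d)]
        if d.size >= 2 and d.var() > 0:
            polymorphic.append(snp_id)
    kept: list[str] = []
    for snp_id in polymorphic:
        g = genotypes.dosage(snp_id)
        independent = True
        for k in kept:
            try:
                if genotype_r2(g, genotypes.dosage(k)) >= r2_prune:
                    independent = False
                    break
            except UndefinedLDError:
                # monomorphic on the pairwise-complete overlap: no evidence
                # of dependence, treat as independent
                continue
        if independent:
            kept.append(snp_id)
    return len(kept)
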