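"""Hi-C contact processing: pair filtering, binning, masking, normalization.

The normalization is the single-pass marginal scheme used throughout the
package: after excluding the diagonal and filtering out rows with an average
of less than ``min_row_mean`` reads per bin, each entry is multiplied by the
total number of read pairs divided by its row and column sums,

    N_ij = C_ij * T / (m_i * m_j),

with marginals recomputed over the surviving (valid) bins.  This is a
deliberate, literal implementation of that one-pass scheme and is *not*
iterative matrix balancing (ICE); the two do not coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple

import numpy as np

from .genome import BinIndex, HybridGenomeSpec

__all__ = [
    "FragmentMap",
    "PairRecord",
    "FilterReport",
    "RawContactMatrix",
    "NormalizedContactMatrix",
    "InsufficientCoverageError",
    "filter_pairs",
    "bin_contacts",
    "apply_masks",
    "normalize_matrix",
]


class InsufficientCoverageError(ValueError):
    """All bins were invalidated during normalization."""


class PairRecord(NamedTuple):
    """One filtered Hi-C ligation pair (positions in base pairs)."""

    chrom_1: str
    pos_1: int
    chrom_2: str
    pos_2: int
    strand_1: str | None = None
    strand_2: str | None = None
    read_id: str | None = None


@dataclass
class FragmentMap:
    """Restriction fragments per chromosome, defined by sorted cut sites.

    ``sites[chrom]`` holds the internal cut positions (strictly increasing,
    inside (0, length)); together with the chromosome ends they delimit
    half-open fragments.
    """

    genome: HybridGenomeSpec
    sites: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, s in self.sites.items():
            arr = np.asarray(s, dtype=np.int64)
            if np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name}: cut sites not strictly increasing")
            length = self.genome[name].length
            if len(arr) and (arr[0] <= 0 or arr[-1] >= length):
                raise ValueError(f"{name}: cut sites outside (0, {length})")
            self.sites[name] = arr

    def fragment_of(self, chrom: str, pos: int) -> int:
        """Index of the fragment containing ``pos`` (0-based per chromosome)."""
        return int(np.searchsorted(self.sites[chrom], pos, side="right"))

    def fragment_bounds(self, chrom: str, frag: int) -> tuple[int, int]:
        s = self.sites[chrom]
        lo = 0 if frag == 0 else int(s[frag - 1])
        hi = self.genome[chrom].length if frag == len(s) else int(s[frag])
        return lo, hi

    def site_for(self, chrom: str, pos: int, strand: str | None) -> int:
        """Restriction-site coordinate assigned to a read end.

        A read on the + strand faces its fragment's downstream boundary (the
        ligation junction), one on the - strand its upstream boundary.  With
        no strand information the nearest boundary is used (ties upstream).
        """
        lo, hi = self.fragment_bounds(chrom, self.fragment_of(chrom, pos))
        if strand == "+":
            return hi
        if strand == "-":
            return lo
        return lo if (pos - lo) <= (hi - pos) else hi

    def n_fragments(self, chrom: str) -> int:
        return len(self.sites[chrom]) + 1


@dataclass
class FilterReport:
    """Counts of ligation-pair removals, by class, in application order."""

    n_input: int = 0
    out_of_bounds: int = 0
    duplicate: int = 0
    same_fragment: int = 0
    short_cis: int = 0
    n_kept: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def filter_pairs(
    pairs: Iterable[PairRecord],
    fragments: FragmentMap,
    min_cis_distance: int = 1000,
) -> tuple[list[PairRecord], FilterReport]:
    """Remove duplicate, same-fragment and short-range cis ligation pairs.

    Removal order: PCR duplicates (identical order-normalized fragment-pair
    signature), then same-fragment pairs, then cis pairs closer than
    ``min_cis_distance`` (unligated / self-ligation products).  Records with
    positions outside their chromosome are rejected and counted separately.
    """
    report = FilterReport()
    seen: set[tuple] = set()
    kept: list[PairRecord] = []
    for rec in pairs:
        report.n_input += 1
        ok = True
        for chrom, pos in ((rec.chrom_1, rec.pos_1), (rec.chrom_2, rec.pos_2)):
            if chrom not in fragments.genome or not (
                0 <= pos < fragments.genome[chrom].length
            ):
                ok = False
        if not ok:
            report.out_of_bounds += 1
            continue
        f1 = (rec.chrom_1, fragments.fragment_of(rec.chrom_1, rec.pos_1))
        f2 = (rec.chrom_2, fragments.fragment_of(rec.chrom_2, rec.pos_2))
        signature = (min(f1, f2), max(f1, f2))
        if signature in seen:
            report.duplicate += 1
            continue
        seen.add(signature)
        if f1 == f2:
            report.same_fragment += 1
            continue
        if rec.chrom_1 == rec.chrom_2 and abs(rec.pos_1 - rec.pos_2) < min_cis_distance:
            report.short_cis += 1
            continue
        kept.append(rec)
        report.n_kept += 1
    return kept, report


@dataclass
class RawContactMatrix:
    """Symmetric integer contact counts over global bins."""

    counts: np.ndarray  # (n, n) int64, symmetric
    index: BinIndex
    masked: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.masked is None:
            self.masked = np.zeros(self.index.n_bins, dtype=bool)
        if self.counts.shape != (self.index.n_bins, self.index.n_bins):
            raise ValueError("counts shape does not match bin index")

    @property
    def total_pairs(self) -> int:
        """Sum of the upper triangle plus the diagonal."""
        return int(np.triu(self.counts).sum())


def bin_contacts(
    pairs: Iterable[PairRecord],
    fragments: FragmentMap,
    index: BinIndex,
) -> RawContactMatrix:
    """Count filtered pairs into a symmetric bin-level matrix.

    Each end is assigned the restriction-site coordinate of its fragment (see
    :meth:`FragmentMap.site_for`) and the bin containing that coordinate is
    incremented symmetrically.
    """
    n = index.n_bins
    counts = np.zeros((n, n), dtype=np.int64)
    for rec in pairs:
        s1 = fragments.site_for(rec.chrom_1, rec.pos_1, rec.strand_1)
        s2 = fragments.site_for(rec.chrom_2, rec.pos_2, rec.strand_2)
        b1 = index.bin_of(rec.chrom_1, s1)
        b2 = index.bin_of(rec.chrom_2, s2)
        counts[b1, b2] += 1
        if b1 != b2:
            counts[b2, b1] += 1
    return RawContactMatrix(counts=counts, index=index)


def apply_masks(
    matrix: RawContactMatrix,
    mask_intervals: Iterable[tuple[str, int, int]],
) -> RawContactMatrix:
    """Zero out rows/columns of bins overlapping any masked interval."""
    masked = matrix.masked.copy()
    for chrom, start, end in mask_intervals:
        spec = matrix.index.genome[chrom]
        if not (0 <= start < end <= spec.length):
            raise ValueError(f"mask interval [{start}, {end}) outside {chrom}")
        lo = matrix.index.bin_of(chrom, start)
        hi = matrix.index.bin_of(chrom, end - 1)
        masked[lo : hi + 1] = True
    counts = matrix.counts.copy()
    counts[masked, :] = 0
    counts[:, masked] = 0
    return RawContactMatrix(counts=counts, index=matrix.index, masked=masked)


@dataclass
class NormalizedContactMatrix:
    """Marginal-normalized contact values; invalid bins and diagonal are NaN."""

    values: np.ndarray  # (n, n) float64, symmetric, NaN where undefined
    valid: np.ndarray  # (n,) bool
    index: BinIndex
    total_pairs: float = 0.0

    def scale_by(self, k: float) -> "NormalizedContactMatrix":
        return replace(self, values=self.values * k)


def normalize_matrix(
    matrix: RawContactMatrix,
    min_row_mean: float = 1.0,
) -> NormalizedContactMatrix:
    """Diagonal exclusion, row filtering, then single-pass marginal scaling.

    Steps, in order: (1) zero the diagonal; (2) invalidate masked bins and
    bins whose off-diagonal row mean (over currently valid bins) is below
    ``min_row_mean``; (3) recompute marginals ``m_i`` and the grand total
    ``T`` over valid off-diagonal cells; (4) ``N_ij = C_ij * T / (m_i m_j)``.
    """
    C = matrix.counts.astype(np.float64)
    if not np.allclose(C, C.T):
        raise ValueError("contact matrix is not symmetric")
    n = matrix.index.n_bins
    np.fill_diagonal(C, 0.0)
    valid = ~matrix.masked
    if valid.any():
        denom = np.maximum(valid.sum() - 1, 1)  # valid off-diagonal bins per row
        row_mean = C[:, valid].sum(axis=1) / denom
        valid &= row_mean >= min_row_mean
    if not valid.any():
        raise InsufficientCoverageError(
            "no bin passes the row-mean filter; increase depth or lower min_row_mean"
        )
    Cv = np.where(np.outer(valid, valid), C, 0.0)
    m = Cv.sum(axis=1)
    T = Cv.sum() / 2.0
    valid &= m > 0
    if not valid.any():
        raise InsufficientCoverageError("all valid bins have zero marginals")
    with np.errstate(divide="ignore", invalid="ignore"):
        N = Cv * T / np.outer(m, m)
    N[~valid, :] = np.nan
    N[:, ~valid] = np.nan
    np.fill_diagonal(N, np.nan)
    return NormalizedContactMatrix(values=N, valid=valid, index=matrix.index, total_pairs=T)
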