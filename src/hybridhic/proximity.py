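"""Homolog proximity statistics with Rabl-orientation controls.

Each homologous bin pair (the *anchor*) is compared to the nonhomologous
intergenome interactions that share one of its two bins, under one of three
control stringencies:

``ALL``
    every qualifying intergenome partner;
``DCEN``
    additionally, the partner bin's centromeric distance (in bins) must equal
    that of the bin it replaces;
``DCEN_ARM``
    additionally, the partner's chromosome-arm length must be within 25%
    (shorter/longer ratio >= ``arm_ratio_min``) of the replaced bin's arm.

The genome-wide statistic is a bootstrap: each replicate draws one comparable
partner per sufficient anchor (uniformly, with replacement) and reports the
ratio of summed homologous to summed drawn interaction frequencies.  The
per-bin profile instead uses the median of each anchor's comparables; the two
summaries intentionally differ.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import NormalizedContactMatrix
from .genome import BinIndex, HomologyMap

__all__ = [
    "ControlLevel",
    "ExclusionPolicy",
    "ComparisonSet",
    "ProximityProfile",
    "ProximityDistribution",
    "LocusPairingResult",
    "PolicyViolationError",
    "admissible_bins",
    "build_comparison_set",
    "proximity_profile",
    "bootstrap_genomic_proximity",
    "locus_pairing_strength",
]


class ControlLevel(enum.Enum):
    """Comparison-set stringency for the Rabl-orientation control."""

    ALL = "all"
    DCEN = "dcen"
    DCEN_ARM = "dcen_arm"


class PolicyViolationError(ValueError):
    """A designated locus fails the policy filters it is measured under."""


@dataclass(frozen=True)
class ExclusionPolicy:
    """Bin-level exclusion filters applied to anchors and their comparables.

    min_dcen : only bins at least this many bins from their centromere.
    telomere_margin : only bins at least this many bins from a chromosome end.
    arm_ratio_min : arm-length similarity threshold for ``DCEN_ARM``
        (shorter/longer >= this; 0.75 encodes "within 25%").
    min_comparables : anchors with fewer comparables are flagged insufficient.
    """

    exclude_rdna_chromosomes: bool = False
    exclude_centromere_bins: bool = False
    min_dcen: int = 0
    telomere_margin: int = 0
    arm_ratio_min: float = 0.75
    min_comparables: int = 2

    @classmethod
    def genome_wide(cls) -> "ExclusionPolicy":
        """Strict genome-wide preset: no rDNA chromosomes, no centromere bins."""
        return cls(exclude_rdna_chromosomes=True, exclude_centromere_bins=True)

    @classmethod
    def locus_background(cls, min_dcen: int = 15) -> "ExclusionPolicy":
        """Locus-strength preset: mid-arm loci only (>= ``min_dcen`` bins from
        a centromere, >= 1 bin from a telomere, no rDNA chromosomes)."""
        return cls(
            exclude_rdna_chromosomes=True,
            exclude_centromere_bins=True,
            min_dcen=min_dcen,
            telomere_margin=1,
        )


def admissible_bins(index: BinIndex, policy: ExclusionPolicy) -> np.ndarray:
    """Boolean mask of bins passing the policy's per-bin filters."""
    ok = ~index.masked
    if policy.exclude_rdna_chromosomes:
        ok &= ~index.rdna_chromosome
    if policy.exclude_centromere_bins:
        ok &= ~index.centromere_bin
    ok &= index.d_cen >= policy.min_dcen
    ok &= index.d_tel >= policy.telomere_margin
    return ok


@dataclass
class ComparisonSet:
    """Admissible nonhomologous partners for one anchor homolog pair."""

    anchor: tuple[int, int]
    pairs: np.ndarray  # (m, 2) int64; each shares exactly one bin with anchor


def build_comparison_set(
    anchor: tuple[int, int],
    level: ControlLevel,
    policy: ExclusionPolicy,
    index: BinIndex,
    hmap: HomologyMap,
) -> ComparisonSet:
    """Enumerate qualifying nonhomologous partners of an anchor pair.

    A candidate pair keeps one anchor bin and replaces the other with a bin
    of the same parental genome that passes the policy filters, is not in the
    homology exclusion zone, and satisfies the control-level matching rules
    (the matching is against the *replaced* bin's annotations).
    """
    b1, b2 = anchor
    ok = admissible_bins(index, policy)
    parent = index.parent
    out: list[tuple[int, int]] = []
    for kept, replaced in ((b1, b2), (b2, b1)):
        cands = np.flatnonzero(ok & (parent == parent[replaced]))
        for c in cands:
            c = int(c)
            if c == replaced:
                continue
            if hmap.exclusion[kept, c]:
                continue
            if level is not ControlLevel.ALL:
                if index.d_cen[c] != index.d_cen[replaced]:
                    continue
                if level is ControlLevel.DCEN_ARM:
                    a, b = index.arm_length[c], index.arm_length[replaced]
                    hi = max(int(a), int(b))
                    if hi > 0 and min(int(a), int(b)) / hi < policy.arm_ratio_min:
                        continue
            pair = (kept, c) if kept == b1 else (c, kept)
            out.append(pair)
    pairs = np.array(sorted(set(out)), dtype=np.int64).reshape(-1, 2)
    return ComparisonSet(anchor=(b1, b2), pairs=pairs)


@dataclass
class ProximityProfile:
    """Per-anchor homolog/nonhomolog interaction ratios (median-based)."""

    frame: pd.DataFrame
    level: ControlLevel
    policy: ExclusionPolicy

    @property
    def sufficient(self) -> pd.DataFrame:
        return self.frame[self.frame["sufficient"]]


def _anchor_values(
    matrix: NormalizedContactMatrix,
    hmap: HomologyMap,
    level: ControlLevel,
    policy: ExclusionPolicy,
) -> list[dict]:
    """Homolog value and comparable values per admissible anchor."""
    index = matrix.index
    ok = admissible_bins(index, policy)
    records = []
    for b1, b2 in hmap.pairs:
        b1, b2 = int(b1), int(b2)
        if not (ok[b1] and ok[b2]):
            continue
        hval = matrix.values[b1, b2]
        cset = build_comparison_set((b1, b2), level, policy, index, hmap)
        if len(cset.pairs):
            vals = matrix.values[cset.pairs[:, 0], cset.pairs[:, 1]]
            vals = vals[np.isfinite(vals)]
        else:
            vals = np.empty(0)
        records.append(
            {
                "bin_1": b1,
                "bin_2": b2,
                "homolog_value": hval,
                "comparables": vals,
            }
        )
    return records


def proximity_profile(
    matrix: NormalizedContactMatrix,
    hmap: HomologyMap,
    level: ControlLevel = ControlLevel.DCEN_ARM,
    policy: ExclusionPolicy | None = None,
) -> ProximityProfile:
    """Per-bin homolog proximity: homolog value over median of comparables."""
    policy = policy or ExclusionPolicy()
    rows = []
    for rec in _anchor_values(matrix, hmap, level, policy):
        vals = rec["comparables"]
        hval = rec["homolog_value"]
        n_comp = len(vals)
        med = float(np.median(vals)) if n_comp else np.nan
        sufficient = (
            n_comp >= policy.min_comparables and np.isfinite(hval) and med > 0
        )
        rows.append(
            {
                "bin_1": rec["bin_1"],
                "bin_2": rec["bin_2"],
                "homolog_value": hval,
                "median_comparable": med,
                "ratio": hval / med if sufficient else np.nan,
                "n_comparables": n_comp,
                "sufficient": sufficient,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "bin_1",
            "bin_2",
            "homolog_value",
            "median_comparable",
            "ratio",
            "n_comparables",
            "sufficient",
        ],
    )
    return ProximityProfile(frame=frame, level=level, policy=policy)


@dataclass
class ProximityDistribution:
    """Bootstrap distribution of the genome-wide homolog proximity ratio."""

    ratios: np.ndarray
    seed: int
    n_anchors: int
    n_redraws: int = 0

    @property
    def median(self) -> float:
        return float(np.median(self.ratios))

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.ratios, q))

    def summary(self) -> dict:
        return {
            "median": self.median,
            "p2.5": self.percentile(2.5),
            "p97.5": self.percentile(97.5),
            "n_reps": int(len(self.ratios)),
            "n_anchors": self.n_anchors,
        }


def bootstrap_genomic_proximity(
    matrix: NormalizedContactMatrix,
    hmap: HomologyMap,
    level: ControlLevel = ControlLevel.DCEN_ARM,
    policy: ExclusionPolicy | None = None,
    n_reps: int = 10_000,
    seed: int = 0,
) -> ProximityDistribution:
    """Bootstrap the genome-wide homologous/nonhomologous frequency ratio.

    Each replicate draws, for every sufficient anchor, one comparable partner
    uniformly with replacement; the replicate's ratio is the sum of homolog
    values over the sum of drawn values.  Replicates with a zero denominator
    are redrawn (and counted), keeping ``n_reps`` fixed.
    """
    policy = policy or ExclusionPolicy()
    anchors = [
        rec
        for rec in _anchor_values(matrix, hmap, level, policy)
        if len(rec["comparables"]) >= policy.min_comparables
        and np.isfinite(rec["homolog_value"])
    ]
    if not anchors:
        raise ValueError("no sufficient anchors for bootstrap")
    rng = np.random.default_rng(seed)
    numerator = float(sum(rec["homolog_value"] for rec in anchors))
    denom = np.zeros(n_reps, dtype=np.float64)
    for rec in anchors:
        vals = np.asarray(rec["comparables"], dtype=np.float64)
        denom += vals[rng.integers(0, len(vals), size=n_reps)]
    n_redraws = 0
    bad = denom == 0.0
    while bad.any():
        n_redraws += int(bad.sum())
        redraw = np.zeros(int(bad.sum()), dtype=np.float64)
        for rec in anchors:
            vals = np.asarray(rec["comparables"], dtype=np.float64)
            redraw += vals[rng.integers(0, len(vals), size=len(redraw))]
        denom[bad] = redraw
        bad = denom == 0.0
    return ProximityDistribution(
        ratios=numerator / denom,
        seed=seed,
        n_anchors=len(anchors),
        n_redraws=n_redraws,
    )


@dataclass
class LocusPairingResult:
    """A locus pair's interaction strength against the filtered background."""

    value: float
    rank: float  # 1 = strongest; midrank under ties
    percentile: float  # strict greater-than counting with midrank for ties
    n_background: int


def locus_pairing_strength(
    matrix: NormalizedContactMatrix,
    locus: tuple[int, int],
    policy: ExclusionPolicy | None = None,
    background: np.ndarray | None = None,
) -> LocusPairingResult:
    """Rank one intergenome bin pair against all policy-filtered pairs.

    The background is every intergenome bin pair whose two bins both pass the
    policy filters and whose value is defined (the locus pair included).
    """
    policy = policy or ExclusionPolicy.locus_background()
    index = matrix.index
    b1, b2 = int(locus[0]), int(locus[1])
    ok = admissible_bins(index, policy)
    for b in (b1, b2):
        if not ok[b]:
            reasons = []
            if index.masked[b]:
                reasons.append("masked")
            if policy.exclude_rdna_chromosomes and index.rdna_chromosome[b]:
                reasons.append("rDNA chromosome")
            if policy.exclude_centromere_bins and index.centromere_bin[b]:
                reasons.append("centromere bin")
            if index.d_cen[b] < policy.min_dcen:
                reasons.append(f"d_cen {index.d_cen[b]} < {policy.min_dcen}")
            if index.d_tel[b] < policy.telomere_margin:
                reasons.append(f"d_tel {index.d_tel[b]} < {policy.telomere_margin}")
            raise PolicyViolationError(f"locus bin {b} fails filters: {', '.join(reasons)}")
    if index.parent[b1] == index.parent[b2]:
        raise PolicyViolationError("locus pair is not intergenome")
    value = float(matrix.values[b1, b2])
    if not np.isfinite(value):
        raise PolicyViolationError(f"locus pair ({b1}, {b2}) has no defined value")
    if background is None:
        parent = index.parent
        p1 = np.flatnonzero(ok & (parent == 1))
        p2 = np.flatnonzero(ok & (parent == 2))
        vals = matrix.values[np.ix_(p1, p2)].ravel()
        background = vals[np.isfinite(vals)]
    others = background[np.arange(len(background)) != _locate(background, value)]
    n_greater = int(np.sum(others > value))
    n_equal = int(np.sum(others == value))
    rank = 1.0 + n_greater + 0.5 * n_equal
    n_less = int(np.sum(others < value))
    percentile = 100.0 * (n_less + 0.5 * n_equal) / max(len(others), 1)
    return LocusPairingResult(
        value=value, rank=rank, percentile=percentile, n_background=len(background)
    )


def _locate(background: np.ndarray, value: float) -> int:
    """Index of one occurrence of ``value`` in the background (the locus)."""
    hits = np.flatnonzero(background == value)
    return int(hits[0]) if len(hits) else -1
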