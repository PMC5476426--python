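"""Synthetic hybrid Hi-C generator with known ground truth.

Builds toy hybrid diploid genomes (parent 2 mirrors parent 1) and expected
contact matrices carrying the statistical signatures the analysis targets:

* intra-chromosomal distance decay (power law on circular bin separation, so
  that every bin of a chromosome carries the same expected cis coverage —
  the wrap-around term stands in for the end-to-end arm association of the
  Rabl orientation);
* centromere clustering: trans contacts enriched as
  ``exp(-(d_cen_i + d_cen_j) / kappa)``;
* telomere clustering: a bonus ``tau`` for trans pairs of telomere-margin bins;
* a genome-wide homolog pairing boost ``beta`` on homologous bin pairs;
* a condition-dependent locus-specific pairing spike ``gamma`` on one
  designated homolog pair;
* a condition-dependent pericentromeric depletion ``rho`` on the trans row of
  one designated anchor bin (its contacts with partners at ``d_cen < kappa``).

Counts are independent Poisson draws over the upper triangle, scaled to a
target sequencing depth.  Every knob is echoed back by :func:`ground_truth`
for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .contacts import RawContactMatrix
from .genome import (
    BinIndex,
    ChromosomeSpec,
    HomologyMap,
    HomologyTable,
    HybridGenomeSpec,
    build_bin_index,
    call_homologous_bins,
)

__all__ = [
    "SyntheticWorldConfig",
    "ConditionEffects",
    "ExpectedMatrix",
    "SyntheticCondition",
    "make_toy_hybrid",
    "expected_matrix",
    "sample_matrix",
    "ground_truth",
    "simulate_condition",
    "rabl_toy_world",
]


@dataclass
class SyntheticWorldConfig:
    """Shape of a toy hybrid world (defaults: 4 + 4 chromosomes, 32 kb bins).

    Parent-2 chromosomes mirror parent-1 lengths and centromeres, giving a
    one-to-one diagonal homology.  The default karyotype includes one long
    chromosome arm (24 bins) so that a mid-arm locus far from the centromere
    (the pairing-spike analog) exists, plus shorter chromosomes for arm-length
    diversity.
    """

    chromosome_lengths: tuple[int, ...] = (960_000, 768_000, 576_000, 384_000)
    centromeres: tuple[int, ...] = (176_000, 368_000, 272_000, 176_000)
    bin_size: int = 32_000
    genes_per_bin: int = 1
    rdna_chromosome: int | None = None  # index into chromosome_lengths
    rdna_interval: tuple[int, int] | None = None
    spike_locus: int | None = None  # parent-1 global bin; None = auto
    anchor_locus: int | None = None  # parent-2 global bin; None = auto
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.chromosome_lengths) != len(self.centromeres):
            raise ValueError("lengths and centromeres differ in count")
        for L in self.chromosome_lengths:
            if L < 2 * self.bin_size:
                raise ValueError("chromosomes must span at least two bins")


@dataclass
class ConditionEffects:
    """Generative parameters of one simulated condition.

    beta : genome-wide homolog pairing boost (multiplier, >= 1; 1 = null).
    gamma : locus-specific pairing spike on the designated homolog pair.
    rho : pericentromeric retention of the designated anchor (< 1 depletes
        its trans contacts with partners at ``d_cen < kappa``).
    alpha : intra-chromosomal decay exponent on circular bin separation.
    kappa : centromere-clustering decay scale in bins.
    tau : telomere-clustering bonus for trans pairs of telomere-margin bins.
    trans_baseline : trans contact baseline ``b``.
    depth : expected total read pairs of a sampled matrix.
    cis_trans_ratio : target ratio of total cis to total trans expected mass.
    """

    beta: float = 1.0
    gamma: float = 1.0
    rho: float = 1.0
    alpha: float = 1.5
    kappa: float = 6.0
    tau: float = 0.5
    trans_baseline: float = 1.0
    depth: float = 1_000_000.0
    cis_trans_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.beta < 1 or self.gamma < 1:
            raise ValueError("beta and gamma must be >= 1 (1 = null)")
        if not 0 < self.rho <= 1:
            raise ValueError("rho must be in (0, 1]")
        if self.alpha <= 0 or self.depth <= 0 or self.kappa <= 0:
            raise ValueError("alpha, kappa and depth must be positive")


@dataclass
class ExpectedMatrix:
    """Expected (mean) contact intensities over global bins; symmetric."""

    values: np.ndarray
    index: BinIndex


@dataclass
class SyntheticCondition:
    """One fully assembled synthetic condition, ready for the analysis."""

    genome: HybridGenomeSpec
    index: BinIndex
    table: HomologyTable
    hmap: HomologyMap
    expected: ExpectedMatrix
    matrix: RawContactMatrix
    registry: dict
    effects: ConditionEffects


def rabl_toy_world() -> SyntheticWorldConfig:
    """Toy hybrid karyotype for the polymer-model experiments.

    Eight chromosomes per parent arranged in mirror-similar pairs (equal
    lengths, staggered centromeres), so that every chromosome arm has an
    exact-length counterpart on a *different* chromosome and the arm-length
    control always has admissible, geometrically equivalent comparables.
    Eight chains per parent keep enough independent chromosome units for the
    genome-wide bootstrap to be stable at 1000-structure populations.
    """
    return SyntheticWorldConfig(
        chromosome_lengths=(
            256_000,
            256_000,
            352_000,
            352_000,
            448_000,
            448_000,
            320_000,
            320_000,
        ),
        centromeres=(
            112_000,
            144_000,
            144_000,
            208_000,
            208_000,
            240_000,
            144_000,
            176_000,
        ),
    )


def make_toy_hybrid(
    config: SyntheticWorldConfig,
) -> tuple[HybridGenomeSpec, HomologyTable, dict]:
    """Build a mirrored hybrid genome, its gene homology table, and a registry
    of designated special loci (pairing-spike pair, relocalization anchor)."""
    chroms: list[ChromosomeSpec] = []
    for parent in (1, 2):
        for i, (L, cen) in enumerate(zip(config.chromosome_lengths, config.centromeres)):
            rdna = None
            if config.rdna_chromosome == i and config.rdna_interval is not None:
                rdna = config.rdna_interval
            chroms.append(
                ChromosomeSpec(
                    name=f"p{parent}_chr{i + 1}",
                    parent=parent,
                    length=L,
                    centromere=cen,
                    rdna=rdna,
                )
            )
    genome = HybridGenomeSpec(chroms)
    index = build_bin_index(genome, config.bin_size)

    rows = []
    pair_id = 0
    bs = config.bin_size
    for i, L in enumerate(config.chromosome_lengths):
        n = -(-L // bs)
        for b in range(n):
            width = min(bs, L - b * bs)
            for g in range(config.genes_per_bin):
                lo = b * bs + (g * width) // (2 * config.genes_per_bin)
                hi = lo + max(width // (2 * config.genes_per_bin), 2)
                hi = min(hi, b * bs + width)
                rows.append(
                    {
                        "pair_id": f"g{pair_id:05d}",
                        "chrom_1": f"p1_chr{i + 1}",
                        "start_1": lo,
                        "end_1": hi,
                        "chrom_2": f"p2_chr{i + 1}",
                        "start_2": lo,
                        "end_2": hi,
                    }
                )
                pair_id += 1
    table = HomologyTable(pd.DataFrame(rows))

    n1 = index.n_bins // 2
    parent = index.parent
    spike1 = config.spike_locus
    if spike1 is None:
        cand = np.flatnonzero(
            (parent == 1) & (index.d_tel >= 2) & ~index.centromere_bin
        )
        spike1 = int(cand[np.argmax(index.d_cen[cand])])
        if index.d_cen[spike1] < 5:
            raise ValueError("no admissible spike locus (need d_cen >= 5, d_tel >= 2)")
    anchor = config.anchor_locus
    if anchor is None:
        cand = np.flatnonzero((parent == 2) & (index.d_cen == 2) & (index.d_tel >= 2))
        if not len(cand):
            raise ValueError("no admissible anchor locus (need d_cen == 2)")
        anchor = int(cand[0])
    registry = {
        "spike_pair": (spike1, spike1 + n1),
        "anchor_bin": anchor,
        "spike_chrom": index.chrom_of(spike1),
        "anchor_chrom": index.chrom_of(anchor),
    }
    return genome, table, registry


def expected_matrix(
    index: BinIndex,
    effects: ConditionEffects,
    hmap: HomologyMap,
    spike_pair: tuple[int, int] | None = None,
    anchor_bin: int | None = None,
) -> ExpectedMatrix:
    """Assemble the expected contact-intensity matrix for one condition."""
    n = index.n_bins
    E = np.zeros((n, n), dtype=np.float64)

    # trans layer: baseline + centromere clustering + telomere clustering
    dc = index.d_cen.astype(np.float64)
    margin = index.telomere_margin
    trans = effects.trans_baseline * (
        1.0
        + np.exp(-np.add.outer(dc, dc) / effects.kappa)
        + effects.tau * np.outer(margin, margin)
    )
    same_chrom = np.equal.outer(index.chrom, index.chrom)
    E[~same_chrom] = trans[~same_chrom]

    # cis layer: power-law decay on circular bin separation, mass-calibrated
    cis = np.zeros((n, n), dtype=np.float64)
    for name in index.chrom_names:
        sl = index.chrom_slice(name)
        nc = sl.stop - sl.start
        ids = np.arange(nc)
        sep = np.abs(np.subtract.outer(ids, ids))
        sep = np.minimum(sep, nc - sep).astype(np.float64)
        block = np.zeros_like(sep)
        nz = sep > 0
        block[nz] = sep[nz] ** (-effects.alpha)
        cis[sl, sl] = block
    cis_mass = np.triu(cis, 1).sum()
    trans_mass = np.triu(E, 1).sum()
    if cis_mass > 0:
        A = effects.cis_trans_ratio * trans_mass / cis_mass
        E += A * cis

    # homolog pairing boost
    for b1, b2 in hmap.pairs:
        E[b1, b2] *= effects.beta
        E[b2, b1] *= effects.beta
    # locus-specific pairing spike
    if spike_pair is not None and effects.gamma != 1.0:
        s1, s2 = spike_pair
        E[s1, s2] *= effects.gamma
        E[s2, s1] *= effects.gamma
    # pericentromeric depletion of the anchor's trans row
    if anchor_bin is not None and effects.rho != 1.0:
        sel = (~same_chrom[anchor_bin]) & (index.d_cen < effects.kappa)
        E[anchor_bin, sel] *= effects.rho
        E[sel, anchor_bin] *= effects.rho
    return ExpectedMatrix(values=E, index=index)


def sample_matrix(expected: ExpectedMatrix, depth: float, seed: int) -> RawContactMatrix:
    """Draw a Poisson count matrix with total expected mass ``depth``."""
    E = expected.values
    if np.any(E < 0):
        raise ValueError("expected intensities must be non-negative")
    rng = np.random.default_rng(seed)
    n = E.shape[0]
    iu = np.triu_indices(n, k=0)
    lam = E[iu]
    total = lam.sum()
    if total <= 0:
        raise ValueError("expected matrix has zero mass")
    counts_u = rng.poisson(lam * (depth / total))
    C = np.zeros((n, n), dtype=np.int64)
    C[iu] = counts_u
    C = C + C.T - np.diag(np.diag(C))
    return RawContactMatrix(counts=C, index=expected.index)


def ground_truth(effects: ConditionEffects, registry: dict | None = None) -> dict:
    """Echo the injected generative parameters and designated loci."""
    out = asdict(effects)
    if registry is not None:
        out.update(registry)
    return out


def simulate_condition(
    world: SyntheticWorldConfig,
    effects: ConditionEffects,
    seed: int,
) -> SyntheticCondition:
    """Generate a complete synthetic condition: genome, homology map, counts."""
    genome, table, registry = make_toy_hybrid(world)
    index = build_bin_index(genome, world.bin_size)
    hmap = call_homologous_bins(table, index, prune_isolated=True, buffer=2)
    exp = expected_matrix(
        index,
        effects,
        hmap,
        spike_pair=registry["spike_pair"],
        anchor_bin=registry["anchor_bin"],
    )
    matrix = sample_matrix(exp, effects.depth, seed)
    return SyntheticCondition(
        genome=genome,
        index=index,
        table=table,
        hmap=hmap,
        expected=exp,
        matrix=matrix,
        registry=registry,
        effects=effects,
    )
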