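"""Volume-exclusion bead-chain model of the diploid Rabl orientation.

Chromosomes are chains of touching beads confined to a spherical nucleus.
Tethering constraints impose the Rabl orientation: centromere beads are
captured in a sphere at the spindle pole body (SPB, on the nuclear envelope
at +z by convention), telomere beads sit in a thin peripheral shell, and
rDNA beads are confined to a nucleolar spherical cap opposite the SPB, from
which all other beads are excluded.  No homolog-specific interaction of any
kind is encoded: the model is homology-agnostic and serves as the null for
the homolog-proximity statistics.

Structures are generated by constraint satisfaction: a guided random-walk
initialization followed by iterative projection (clamp bonds, push
overlapping beads apart, project tethered beads into their regions, pull
escapees back into the nucleus) until every constraint is met.  Populations
of such structures are converted to contact matrices by calling all bead
pairs within ``contact_threshold`` (45 nm) of each other as contacts and
counting them per genomic bin pair.

Scaling: the diploid model multiplies the nuclear and tether geometry
(nuclear radius, capture-sphere radius, shell thickness, nucleolus) by
``ploidy_scale`` (1.25), leaving the chromatin fiber itself unchanged.
``size_multiplier`` (1.0, or 0.8 / 0.64 for the small-nucleus experiments)
instead rescales *all* model lengths — nuclear geometry, bead diameter and
bond lengths alike — so a small-nucleus model is a geometrically similar
shrunken copy.  The 45 nm contact-calling threshold is a property of the
simulated assay, not of the model, and never scales; this is what makes
smaller nuclei produce denser, less specific contact maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .contacts import RawContactMatrix
from .genome import BinIndex, HybridGenomeSpec

__all__ = [
    "PolymerConfig",
    "ChainSpec",
    "Structure3D",
    "StructurePopulation",
    "ConstraintReport",
    "InfeasibleModelError",
    "build_chain_specs",
    "sample_structure",
    "check_constraints",
    "simulate_population",
    "population_to_contact_matrix",
]


class InfeasibleModelError(RuntimeError):
    """The constraint solver could not produce a valid structure."""


@dataclass(frozen=True)
class PolymerConfig:
    """Geometry and solver parameters of the polymer null model.

    All lengths in nm unless noted.  ``base_nuclear_radius``,
    ``centromere_capture_radius``, ``telomere_shell_thickness`` and the
    nucleolus are haploid base values whose effective sizes carry
    ``ploidy_scale * size_multiplier``; ``bead_diameter``, ``bond_length``
    and ``overlap_tolerance`` are fiber properties and scale with
    ``size_multiplier`` only (see the ``effective_*`` properties).
    ``contact_threshold`` never scales.
    """

    bead_size: int = 3_200  # bp per bead
    bead_diameter: float = 30.0
    bond_length: tuple[float, float] = (15.0, 45.0)
    base_nuclear_radius: float = 1_000.0
    ploidy_scale: float = 1.25
    size_multiplier: float = 1.0
    centromere_capture_radius: float = 250.0
    telomere_shell_thickness: float = 100.0
    nucleolus_volume_fraction: float = 0.10
    contact_threshold: float = 45.0
    n_structures: int = 20_000
    max_iterations: int = 3_000
    max_attempts: int = 25
    overlap_tolerance: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contact_threshold <= 0 or self.bead_diameter <= 0:
            raise ValueError("contact_threshold and bead_diameter must be positive")
        if not 0 < self.size_multiplier <= self.ploidy_scale * 10:
            raise ValueError("size_multiplier out of range")
        if self.bond_length[0] > self.bond_length[1]:
            raise ValueError("bond_length (min, max) reversed")

    @property
    def geometry_scale(self) -> float:
        return self.ploidy_scale * self.size_multiplier

    @property
    def nuclear_radius(self) -> float:
        return self.base_nuclear_radius * self.geometry_scale

    @property
    def capture_radius(self) -> float:
        return self.centromere_capture_radius * self.geometry_scale

    @property
    def shell_thickness(self) -> float:
        return self.telomere_shell_thickness * self.geometry_scale

    @property
    def effective_bead_diameter(self) -> float:
        """size_multiplier rescales *all* model lengths, chain geometry
        included; only the contact-calling threshold is an assay parameter
        and stays fixed."""
        return self.bead_diameter * self.size_multiplier

    @property
    def effective_bond_length(self) -> tuple[float, float]:
        return (
            self.bond_length[0] * self.size_multiplier,
            self.bond_length[1] * self.size_multiplier,
        )

    @property
    def effective_overlap_tolerance(self) -> float:
        return self.overlap_tolerance * self.size_multiplier

    @property
    def spb_point(self) -> np.ndarray:
        """SPB position on the envelope (+z by convention)."""
        return np.array([0.0, 0.0, self.nuclear_radius])

    @property
    def nucleolus_cap_height(self) -> float:
        """Height of the nucleolar spherical cap (at -z) holding the
        configured volume fraction."""
        f = self.nucleolus_volume_fraction
        if f <= 0:
            return 0.0
        R = self.nuclear_radius
        # cap volume pi*h^2*(3R - h)/3 = f * 4/3 pi R^3
        return float(brentq(lambda h: h * h * (3 * R - h) - 4 * f * R**3, 0, 2 * R))


@dataclass(frozen=True)
class ChainSpec:
    """Bead-level layout of one chromosome chain."""

    name: str
    n_beads: int
    centromere_bead: int
    telomere_beads: tuple[int, int]
    rdna_beads: tuple[int, int] | None = None  # half-open bead range
    single_bead: bool = False


def build_chain_specs(genome: HybridGenomeSpec, config: PolymerConfig) -> list[ChainSpec]:
    """One chain per chromosome; special bead indices from annotations."""
    chains = []
    for c in genome.chromosomes:
        n = max(-(-c.length // config.bead_size), 1)
        cen = min(c.centromere // config.bead_size, n - 1)
        rdna = None
        if c.rdna is not None:
            rdna = (
                c.rdna[0] // config.bead_size,
                min(-(-c.rdna[1] // config.bead_size), n),
            )
        chains.append(
            ChainSpec(
                name=c.name,
                n_beads=n,
                centromere_bead=int(cen),
                telomere_beads=(0, n - 1),
                rdna_beads=rdna,
                single_bead=n == 1,
            )
        )
    return chains


@dataclass
class _Layout:
    """Flattened bead arrays shared by all structures of a chain set."""

    chain_starts: np.ndarray
    chain_ends: np.ndarray
    bead_chain: np.ndarray
    is_cen: np.ndarray
    is_tel: np.ndarray
    is_rdna: np.ndarray
    bonds_a: np.ndarray
    bonds_b: np.ndarray

    @property
    def n_beads(self) -> int:
        return len(self.bead_chain)


def _build_layout(chains: list[ChainSpec]) -> _Layout:
    starts, ends = [], []
    bead_chain, is_cen, is_tel, is_rdna = [], [], [], []
    bonds_a, bonds_b = [], []
    off = 0
    for ci, ch in enumerate(chains):
        starts.append(off)
        ends.append(off + ch.n_beads)
        for b in range(ch.n_beads):
            bead_chain.append(ci)
            is_cen.append(b == ch.centromere_bead)
            is_tel.append(b in ch.telomere_beads)
            rd = ch.rdna_beads is not None and ch.rdna_beads[0] <= b < ch.rdna_beads[1]
            is_rdna.append(rd)
            if b > 0:
                bonds_a.append(off + b - 1)
                bonds_b.append(off + b)
        off += ch.n_beads
    return _Layout(
        chain_starts=np.array(starts, dtype=np.int64),
        chain_ends=np.array(ends, dtype=np.int64),
        bead_chain=np.array(bead_chain, dtype=np.int64),
        is_cen=np.array(is_cen, dtype=np.bool_),
        is_tel=np.array(is_tel, dtype=np.bool_),
        is_rdna=np.array(is_rdna, dtype=np.bool_),
        bonds_a=np.array(bonds_a, dtype=np.int64),
        bonds_b=np.array(bonds_b, dtype=np.int64),
    )


@dataclass
class Structure3D:
    """One conformation: bead coordinates in nm, flattened over chains."""

    coords: np.ndarray  # (n_beads, 3)
    chains: list[ChainSpec]
    seed: int

    def chain_coords(self, chain_index: int) -> np.ndarray:
        layout = _build_layout(self.chains)
        s, e = layout.chain_starts[chain_index], layout.chain_ends[chain_index]
        return self.coords[s:e]


@dataclass
class StructurePopulation:
    """Ensemble of constraint-satisfying conformations plus provenance."""

    coords: np.ndarray  # (n_structures, n_beads, 3)
    chains: list[ChainSpec]
    config: PolymerConfig
    seeds: np.ndarray

    @property
    def n_structures(self) -> int:
        return self.coords.shape[0]

    def structure(self, i: int) -> Structure3D:
        return Structure3D(coords=self.coords[i], chains=self.chains, seed=int(self.seeds[i]))


@dataclass
class ConstraintReport:
    """Violation counts for one structure."""

    bond: int = 0
    overlap: int = 0
    centromere_tether: int = 0
    telomere_tether: int = 0
    rdna_outside_nucleolus: int = 0
    intruder_in_nucleolus: int = 0
    outside_nucleus: int = 0

    @property
    def total(self) -> int:
        return sum(self.__dict__.values())

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


# --------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _relax(
    pos,
    bonds_a,
    bonds_b,
    is_cen,
    is_tel,
    is_rdna,
    enforce_nucleolus,
    R,
    cap_z,
    cap_r,
    shell,
    zstar,
    d_min,
    bond_min,
    bond_max,
    max_iter,
):
    """Iterative projection onto the constraint sets; returns sweeps used
    (-1 if max_iter was exhausted before a clean sweep)."""
    n = pos.shape[0]
    margin = 0.05
    cell = 150.0
    ndim = int(2.0 * R / cell) + 3
    ncell = ndim * ndim * ndim
    head = np.empty(ncell, dtype=np.int32)
    nxt = np.empty(n, dtype=np.int32)
    for it in range(max_iter):
        moved = 0
        # ---- tether / region projections
        for i in range(n):
            x, y, z = pos[i, 0], pos[i, 1], pos[i, 2]
            if enforce_nucleolus:
                if is_rdna[i]:
                    if z > zstar:
                        z = zstar - margin
                        moved += 1
                else:
                    if z < zstar:
                        z = zstar + margin
                        moved += 1
            if is_cen[i]:
                dx, dy, dz = x, y, z - cap_z
                d = math.sqrt(dx * dx + dy * dy + dz * dz)
                if d > cap_r:
                    f = (cap_r - margin) / d
                    x, y, z = dx * f, dy * f, cap_z + dz * f
                    moved += 1
            r = math.sqrt(x * x + y * y + z * z)
            if is_tel[i]:
                lo = R - shell
                if r < lo or r > R:
                    target = lo + margin if r < lo else R - margin
                    if r < 1e-9:
                        x, y, z = 0.0, 0.0, target
                    else:
                        f = target / r
                        x, y, z = x * f, y * f, z * f
                    moved += 1
            else:
                if r > R:
                    f = (R - margin) / r
                    x, y, z = x * f, y * f, z * f
                    moved += 1
            pos[i, 0], pos[i, 1], pos[i, 2] = x, y, z
        # ---- bond clamps (Gauss-Seidel)
        for k in range(len(bonds_a)):
            a, b = bonds_a[k], bonds_b[k]
            dx = pos[b, 0] - pos[a, 0]
            dy = pos[b, 1] - pos[a, 1]
            dz = pos[b, 2] - pos[a, 2]
            d = math.sqrt(dx * dx + dy * dy + dz * dz)
            if d > bond_max or d < bond_min:
                target = bond_max - margin if d > bond_max else bond_min + margin
                if d < 1e-9:
                    dx, dy, dz, d = 1.0, 0.0, 0.0, 1.0
                shift = 0.5 * (d - target) / d
                pos[a, 0] += dx * shift
                pos[a, 1] += dy * shift
                pos[a, 2] += dz * shift
                pos[b, 0] -= dx * shift
                pos[b, 1] -= dy * shift
                pos[b, 2] -= dz * shift
                moved += 1
        # ---- overlap pushes via cell grid
        for c in range(ncell):
            head[c] = -1
        for i in range(n):
            ix = int((pos[i, 0] + R) / cell) + 1
            iy = int((pos[i, 1] + R) / cell) + 1
            iz = int((pos[i, 2] + R) / cell) + 1
            if ix < 0:
                ix = 0
            if iy < 0:
                iy = 0
            if iz < 0:
                iz = 0
            if ix >= ndim:
                ix = ndim - 1
            if iy >= ndim:
                iy = ndim - 1
            if iz >= ndim:
                iz = ndim - 1
            c = (ix * ndim + iy) * ndim + iz
            nxt[i] = head[c]
            head[c] = np.int32(i)
        for i in range(n):
            ix = int((pos[i, 0] + R) / cell) + 1
            iy = int((pos[i, 1] + R) / cell) + 1
            iz = int((pos[i, 2] + R) / cell) + 1
            for ox in range(-1, 2):
                cx = ix + ox
                if cx < 0 or cx >= ndim:
                    continue
                for oy in range(-1, 2):
                    cy = iy + oy
                    if cy < 0 or cy >= ndim:
                        continue
                    for oz in range(-1, 2):
                        cz = iz + oz
                        if cz < 0 or cz >= ndim:
                            continue
                        j = head[(cx * ndim + cy) * ndim + cz]
                        while j >= 0:
                            if j > i and not (
                                abs(j - i) == 1 and _same_chain_bond(i, j, bonds_a, bonds_b)
                            ):
                                dx = pos[j, 0] - pos[i, 0]
                                dy = pos[j, 1] - pos[i, 1]
                                dz = pos[j, 2] - pos[i, 2]
                                d = math.sqrt(dx * dx + dy * dy + dz * dz)
                                if d < d_min:
                                    if d < 1e-9:
                                        dx = 1e-3 * (j - i)
                                        dy = 1e-3
                                        dz = 0.0
                                        d = math.sqrt(dx * dx + dy * dy + dz * dz)
                                    shift = 0.5 * (d_min + margin - d) / d
                                    pos[i, 0] -= dx * shift
                                    pos[i, 1] -= dy * shift
                                    pos[i, 2] -= dz * shift
                                    pos[j, 0] += dx * shift
                                    pos[j, 1] += dy * shift
                                    pos[j, 2] += dz * shift
                                    moved += 1
                            j = nxt[j]
        if moved == 0:
            return it
    return -1


@njit(cache=True)
def _same_chain_bond(i, j, bonds_a, bonds_b):
    lo = i if i < j else j
    # bonds are (k, k+1) within chains, stored sorted by first index; binary search
    left, right = 0, len(bonds_a)
    while left < right:
        mid = (left + right) // 2
        if bonds_a[mid] < lo:
            left = mid + 1
        else:
            right = mid
    return left < len(bonds_a) and bonds_a[left] == lo and bonds_b[left] == lo + 1


# --------------------------------------------------------------------------


def _init_walk(
    layout: _Layout,
    chains: list[ChainSpec],
    config: PolymerConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Guided random-walk initialization from the centromere bead outward."""
    R = config.nuclear_radius
    cap_r = config.capture_radius
    spb = config.spb_point
    shell = config.shell_thickness
    step = 0.5 * sum(config.effective_bond_length)
    h = config.nucleolus_cap_height
    nucleolus_center = np.array([0.0, 0.0, -(R - h / 2.0)])
    pos = np.zeros((layout.n_beads, 3))
    for ci, ch in enumerate(chains):
        off = int(layout.chain_starts[ci])
        cen = ch.centromere_bead
        # centromere bead: uniform in capture sphere ∩ nucleus
        for _ in range(1000):
            p = spb + cap_r * _random_in_ball(rng)
            if np.linalg.norm(p) <= R - 1.0:
                break
        pos[off + cen] = p
        for direction in (-1, 1):
            arm = range(cen - 1, -1, -1) if direction < 0 else range(cen + 1, ch.n_beads)
            arm = list(arm)
            if not arm:
                continue
            n_steps = len(arm)
            target = _sample_telomere_target(p, n_steps * step, R, shell, rng)
            cur = p.copy()
            for k, b in enumerate(arm):
                togo = target
                if ch.rdna_beads is not None and ch.rdna_beads[0] <= b < ch.rdna_beads[1]:
                    togo = nucleolus_center
                remaining = n_steps - k
                vec = togo - cur
                dist = np.linalg.norm(vec)
                need = dist / max(remaining * step, 1e-9)
                u = _random_unit(rng)
                if dist > 1e-9:
                    w = min(need * need, 4.0)
                    d = w * vec / dist + u
                else:
                    d = u
                d /= np.linalg.norm(d)
                nxt = cur + step * d
                r = np.linalg.norm(nxt)
                if r > R - 1.0:
                    nxt *= (R - 1.0) / r
                pos[off + b] = nxt
                cur = nxt
    return pos


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _random_in_ball(rng: np.random.Generator) -> np.ndarray:
    return _random_unit(rng) * rng.random() ** (1 / 3)


def _sample_telomere_target(
    origin: np.ndarray,
    reach: float,
    R: float,
    shell: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random point at mid-shell radius reachable within the arm's contour.

    Rejection sampling naturally confines short arms' telomeres near the SPB
    side, which is the geometric source of the Rabl arm-length effect."""
    r_target = R - shell / 2.0
    for _ in range(200):
        p = r_target * _random_unit(rng)
        if np.linalg.norm(p - origin) <= 0.9 * reach:
            return p
    nrm = np.linalg.norm(origin)
    if nrm < 1e-9:
        return np.array([0.0, 0.0, r_target])
    return origin * (r_target / nrm)


def check_constraints(
    structure: Structure3D,
    config: PolymerConfig,
    layout: _Layout | None = None,
    eps: float = 1e-6,
) -> ConstraintReport:
    """Count violations of every constraint class for one structure."""
    layout = layout or _build_layout(structure.chains)
    pos = structure.coords
    R = config.nuclear_radius
    report = ConstraintReport()
    # bonds
    bond_lo, bond_hi = config.effective_bond_length
    d = np.linalg.norm(pos[layout.bonds_b] - pos[layout.bonds_a], axis=1)
    report.bond = int(np.sum((d > bond_hi + eps) | (d < bond_lo - eps)))
    # overlaps (non-bonded pairs)
    d_min = config.effective_bead_diameter - config.effective_overlap_tolerance
    tree = cKDTree(pos)
    pairs = tree.query_pairs(r=d_min - eps, output_type="ndarray")
    if len(pairs):
        bonded = (np.abs(pairs[:, 0] - pairs[:, 1]) == 1) & (
            layout.bead_chain[pairs[:, 0]] == layout.bead_chain[pairs[:, 1]]
        )
        report.overlap = int(np.sum(~bonded))
    # radial constraints
    r = np.linalg.norm(pos, axis=1)
    report.outside_nucleus = int(np.sum(r > R + eps))
    cen = layout.is_cen
    dc = np.linalg.norm(pos[cen] - config.spb_point, axis=1)
    report.centromere_tether = int(np.sum(dc > config.capture_radius + eps))
    tel = layout.is_tel
    report.telomere_tether = int(
        np.sum((r[tel] < R - config.shell_thickness - eps) | (r[tel] > R + eps))
    )
    if layout.is_rdna.any() and config.nucleolus_volume_fraction > 0:
        zstar = -(R - config.nucleolus_cap_height)
        z = pos[:, 2]
        report.rdna_outside_nucleolus = int(np.sum(z[layout.is_rdna] > zstar + eps))
        report.intruder_in_nucleolus = int(np.sum(z[~layout.is_rdna] < zstar - eps))
    return report


def sample_structure(
    chains: list[ChainSpec],
    config: PolymerConfig,
    seed: int,
    layout: _Layout | None = None,
) -> Structure3D:
    """Draw one constraint-satisfying structure; deterministic per seed."""
    layout = layout or _build_layout(chains)
    _check_feasibility(layout, config)
    R = config.nuclear_radius
    enforce_nucleolus = bool(layout.is_rdna.any()) and config.nucleolus_volume_fraction > 0
    zstar = -(R - config.nucleolus_cap_height) if enforce_nucleolus else 0.0
    last_report = None
    for attempt in range(config.max_attempts):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), attempt]))
        pos = _init_walk(layout, chains, config, rng)
        ok = _relax(
            pos,
            layout.bonds_a,
            layout.bonds_b,
            layout.is_cen,
            layout.is_tel,
            layout.is_rdna,
            enforce_nucleolus,
            R,
            R,  # capture sphere centered at the SPB point (0, 0, R)
            config.capture_radius,
            config.shell_thickness,
            zstar,
            config.effective_bead_diameter - config.effective_overlap_tolerance,
            config.effective_bond_length[0],
            config.effective_bond_length[1],
            config.max_iterations,
        )
        structure = Structure3D(coords=pos, chains=chains, seed=int(seed))
        if ok >= 0:
            report = check_constraints(structure, config, layout)
            if report.total == 0:
                return structure
            last_report = report
        else:
            last_report = check_constraints(structure, config, layout)
    raise InfeasibleModelError(
        f"no valid structure after {config.max_attempts} attempts "
        f"(seed {seed}); last violation counts: {last_report.as_dict() if last_report else 'n/a'}"
    )


def _check_feasibility(layout: _Layout, config: PolymerConfig) -> None:
    bead_vol = layout.n_beads * (4 / 3) * math.pi * (config.effective_bead_diameter / 2) ** 3
    nuc_vol = (4 / 3) * math.pi * config.nuclear_radius**3
    if bead_vol > 0.35 * nuc_vol:
        raise InfeasibleModelError(
            f"bead volume fraction {bead_vol / nuc_vol:.2f} exceeds packing limit 0.35"
        )


def simulate_population(
    chains: list[ChainSpec],
    config: PolymerConfig,
    progress: bool = False,
) -> StructurePopulation:
    """Generate ``config.n_structures`` independent structures.

    Per-structure seeds are drawn deterministically from ``config.seed`` and
    recorded, so any structure can be replayed with
    :func:`sample_structure`.
    """
    layout = _build_layout(chains)
    seeds = np.random.default_rng(config.seed).integers(
        0, 2**31 - 1, size=config.n_structures
    )
    coords = np.empty((config.n_structures, layout.n_beads, 3))
    for i, s in enumerate(seeds):
        structure = sample_structure(chains, config, int(s), layout=layout)
        coords[i] = structure.coords
        if progress and (i + 1) % 100 == 0:
            print(f"  structures: {i + 1}/{config.n_structures}", flush=True)
    return StructurePopulation(coords=coords, chains=chains, config=config, seeds=seeds)


def _bead_bins(chains: list[ChainSpec], config: PolymerConfig, index: BinIndex) -> np.ndarray:
    """Global bin id per bead, by bead midpoint base-pair coordinate."""
    out = []
    for ch in chains:
        length = index.genome[ch.name].length
        for b in range(ch.n_beads):
            lo = b * config.bead_size
            hi = min((b + 1) * config.bead_size, length)
            out.append(index.bin_of(ch.name, (lo + hi) // 2))
    return np.array(out, dtype=np.int64)


def population_to_contact_matrix(
    pop: StructurePopulation,
    index: BinIndex,
) -> RawContactMatrix:
    """Call bead contacts (pairwise distance <= threshold, inclusive) and
    count them per bin pair over the whole population."""
    bead_bin = _bead_bins(pop.chains, pop.config, index)
    n = index.n_bins
    counts = np.zeros((n, n), dtype=np.int64)
    r = pop.config.contact_threshold
    for s in range(pop.n_structures):
        pairs = cKDTree(pop.coords[s]).query_pairs(r=r, output_type="ndarray")
        if not len(pairs):
            continue
        b1 = bead_bin[pairs[:, 0]]
        b2 = bead_bin[pairs[:, 1]]
        np.add.at(counts, (b1, b2), 1)
        off = b1 != b2
        np.add.at(counts, (b2[off], b1[off]), 1)
    return RawContactMatrix(counts=counts, index=index)
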