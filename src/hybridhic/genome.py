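"""Hybrid diploid genome model: chromosomes, genomic bins, homologous-bin map.

A hybrid genome is the concatenation of two parental chromosome sets
(parent 1 first, then parent 2).  All coordinates are 0-based, half-open.
Genomic bins are fixed-width tiles (default 32 kb); every bin is annotated
with its distance from the centromere in bin units (``d_cen``), the identity
and length of the chromosome arm it sits on, and flags used by downstream
exclusion policies.

Homologous bins are called from a one-to-one gene homology table by vote
counting: each homologous gene pair casts one vote per end (start and end),
linking the parent-1 bin holding that end to the parent-2 bin holding the
corresponding end of the partner gene.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ChromosomeSpec",
    "HybridGenomeSpec",
    "BinIndex",
    "HomologyTable",
    "HomologyMap",
    "GenomeConfigError",
    "build_bin_index",
    "call_homologous_bins",
    "kmer_mappability",
    "mappability_by_bin",
]

DEFAULT_BIN_SIZE = 32_000


class GenomeConfigError(ValueError):
    """Raised for invalid genome specifications."""


@dataclass(frozen=True)
class ChromosomeSpec:
    """One chromosome of a parental genome.

    Parameters
    ----------
    name : unique chromosome identifier.
    parent : parental genome label, 1 or 2.
    length : chromosome length in base pairs.
    centromere : centromere point position in base pairs.
    rdna : optional (start, end) of an rDNA array, half-open.
    """

    name: str
    parent: int
    length: int
    centromere: int
    rdna: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.parent not in (1, 2):
            raise GenomeConfigError(f"{self.name}: parent must be 1 or 2")
        if self.length <= 0:
            raise GenomeConfigError(f"{self.name}: non-positive length")
        if not 0 < self.centromere < self.length:
            raise GenomeConfigError(
                f"{self.name}: centromere {self.centromere} outside (0, {self.length})"
            )
        if self.rdna is not None:
            s, e = self.rdna
            if not (0 <= s < e <= self.length):
                raise GenomeConfigError(f"{self.name}: rDNA interval [{s}, {e}) invalid")
            if s <= self.centromere < e:
                raise GenomeConfigError(f"{self.name}: rDNA interval contains centromere")


@dataclass
class HybridGenomeSpec:
    """Ordered chromosome set of a hybrid diploid: parent-1 then parent-2."""

    chromosomes: list[ChromosomeSpec]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise GenomeConfigError("empty genome")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise GenomeConfigError("duplicate chromosome names")
        parents = [c.parent for c in self.chromosomes]
        for p in (1, 2):
            if p not in parents:
                raise GenomeConfigError(f"parent {p} contributes no chromosome")
        # parent-1 block must precede parent-2 block
        seen2 = False
        for p in parents:
            if p == 2:
                seen2 = True
            elif seen2:
                raise GenomeConfigError("chromosomes must be ordered parent 1 then parent 2")
        self._by_name = {c.name: c for c in self.chromosomes}

    def __getitem__(self, name: str) -> ChromosomeSpec:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def parent_chromosomes(self, parent: int) -> list[ChromosomeSpec]:
        return [c for c in self.chromosomes if c.parent == parent]

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]


@dataclass
class BinIndex:
    """Fixed-width genomic bins over a hybrid genome, with Rabl annotations.

    Arrays are parallel, one entry per global bin (bins of all chromosomes
    concatenated in genome order).

    Attributes
    ----------
    d_cen : distance from the centromere-containing bin, in bins.
    d_tel : distance from the nearest chromosome end, in bins.
    arm_id : global ordinal of the chromosome arm (two per chromosome; the
        centromere bin is attributed to the left arm but belongs to both
        conceptually, with ``d_cen == 0``).
    arm_length : number of bins on the bin's arm (for the centromere bin,
        the longer of the two arms).
    """

    bin_size: int
    genome: HybridGenomeSpec
    chrom: np.ndarray  # chromosome ordinal per bin
    start: np.ndarray
    end: np.ndarray
    d_cen: np.ndarray
    d_tel: np.ndarray
    arm_id: np.ndarray
    arm_length: np.ndarray
    centromere_bin: np.ndarray
    telomere_margin: np.ndarray
    rdna_chromosome: np.ndarray
    masked: np.ndarray
    chrom_offsets: dict[str, int] = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return len(self.start)

    @property
    def chrom_names(self) -> list[str]:
        return self.genome.names

    @property
    def parent(self) -> np.ndarray:
        parents = np.array([c.parent for c in self.genome.chromosomes])
        return parents[self.chrom]

    def chrom_of(self, global_bin: int) -> str:
        return self.genome.chromosomes[int(self.chrom[global_bin])].name

    def bin_of(self, chrom: str, pos: int) -> int:
        """Global bin id containing base-pair position ``pos`` on ``chrom``."""
        spec = self.genome[chrom]
        if not 0 <= pos <= spec.length:
            raise ValueError(f"position {pos} outside {chrom} [0, {spec.length}]")
        local = min(pos // self.bin_size, self.n_chrom_bins(chrom) - 1)
        return self.chrom_offsets[chrom] + int(local)

    def n_chrom_bins(self, chrom: str) -> int:
        length = self.genome[chrom].length
        return -(-length // self.bin_size)

    def chrom_slice(self, chrom: str) -> slice:
        off = self.chrom_offsets[chrom]
        return slice(off, off + self.n_chrom_bins(chrom))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [self.chrom_of(i) for i in range(self.n_bins)],
                "start": self.start,
                "end": self.end,
                "parent": self.parent,
                "d_cen": self.d_cen,
                "d_tel": self.d_tel,
                "arm_id": self.arm_id,
                "arm_length": self.arm_length,
                "centromere_bin": self.centromere_bin,
                "telomere_margin": self.telomere_margin,
                "rdna_chromosome": self.rdna_chromosome,
                "masked": self.masked,
            }
        )


def build_bin_index(
    genome: HybridGenomeSpec,
    bin_size: int = DEFAULT_BIN_SIZE,
    telomere_margin_bins: int = 1,
    split_rdna_arms: bool = False,
) -> BinIndex:
    """Tile every chromosome into fixed-width bins and annotate them.

    The last bin of a chromosome may be shorter than ``bin_size``.  ``d_cen``
    is ``|bin - centromere_bin|`` within the chromosome.  When
    ``split_rdna_arms`` is set, a chromosome carrying an rDNA interval is
    treated as two independent segments on either side of the array for
    ``arm_length`` purposes only (its nucleolar tethering decouples the two
    sides); ``d_cen`` is unaffected.
    """
    if bin_size <= 0:
        raise GenomeConfigError("bin_size must be positive")
    chrom_ord, starts, ends = [], [], []
    d_cen, d_tel, arm_id, arm_len = [], [], [], []
    cen_flag, tel_flag, rdna_flag = [], [], []
    offsets: dict[str, int] = {}
    next_arm = 0
    for ci, c in enumerate(genome.chromosomes):
        n = -(-c.length // bin_size)
        offsets[c.name] = len(starts)
        cen_bin = min(c.centromere // bin_size, n - 1)
        left_len = cen_bin  # bins strictly left of the centromere bin
        right_len = n - cen_bin - 1
        rdna_bins: tuple[int, int] | None = None
        if c.rdna is not None:
            rdna_bins = (c.rdna[0] // bin_size, min((c.rdna[1] - 1) // bin_size, n - 1))
        for b in range(n):
            chrom_ord.append(ci)
            starts.append(b * bin_size)
            ends.append(min((b + 1) * bin_size, c.length))
            dc = abs(b - cen_bin)
            d_cen.append(dc)
            dt = min(b, n - 1 - b)
            d_tel.append(dt)
            on_left = b < cen_bin
            a_id = next_arm if (on_left or b == cen_bin) else next_arm + 1
            if b == cen_bin:
                a_len = max(left_len, right_len)
            else:
                a_len = left_len if on_left else right_len
            if split_rdna_arms and rdna_bins is not None:
                a_len = _rdna_split_arm_length(b, cen_bin, n, rdna_bins)
            arm_id.append(a_id)
            arm_len.append(a_len)
            cen_flag.append(b == cen_bin)
            tel_flag.append(dt < telomere_margin_bins)
            rdna_flag.append(c.rdna is not None)
        next_arm += 2
    return BinIndex(
        bin_size=bin_size,
        genome=genome,
        chrom=np.array(chrom_ord, dtype=np.int64),
        start=np.array(starts, dtype=np.int64),
        end=np.array(ends, dtype=np.int64),
        d_cen=np.array(d_cen, dtype=np.int64),
        d_tel=np.array(d_tel, dtype=np.int64),
        arm_id=np.array(arm_id, dtype=np.int64),
        arm_length=np.array(arm_len, dtype=np.int64),
        centromere_bin=np.array(cen_flag, dtype=bool),
        telomere_margin=np.array(tel_flag, dtype=bool),
        rdna_chromosome=np.array(rdna_flag, dtype=bool),
        masked=np.zeros(len(starts), dtype=bool),
        chrom_offsets=offsets,
    )


def _rdna_split_arm_length(b: int, cen_bin: int, n: int, rdna_bins: tuple[int, int]) -> int:
    """Arm length when the rDNA array splits its chromosome into segments."""
    boundaries = sorted({cen_bin, rdna_bins[0], rdna_bins[1]})
    # segment boundaries partition [0, n); a bin's segment length excludes the
    # boundary bins themselves, mirroring how the centromere bin is excluded.
    cuts = [-1] + boundaries + [n]
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        if lo < b < hi and b not in boundaries:
            return hi - lo - 1
    # boundary bin: longer adjacent segment
    idx = cuts.index(b)
    return max(cuts[idx] - cuts[idx - 1] - 1, cuts[idx + 1] - cuts[idx] - 1)


@dataclass
class HomologyTable:
    """One-to-one homologous gene annotations between the two parents.

    Backed by a DataFrame with columns
    ``pair_id, chrom_1, start_1, end_1, chrom_2, start_2, end_2``.
    """

    frame: pd.DataFrame

    COLUMNS = ("pair_id", "chrom_1", "start_1", "end_1", "chrom_2", "start_2", "end_2")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"homology table missing columns: {sorted(missing)}")
        bad = (self.frame["start_1"] >= self.frame["end_1"]) | (
            self.frame["start_2"] >= self.frame["end_2"]
        )
        if bad.any():
            raise ValueError("homology table has rows with start >= end")

    def validate_against(self, genome: HybridGenomeSpec) -> None:
        for _, row in self.frame.iterrows():
            for side in (1, 2):
                chrom = row[f"chrom_{side}"]
                if chrom not in genome:
                    raise ValueError(f"unknown chromosome {chrom!r} in homology table")
                spec = genome[chrom]
                if spec.parent != side:
                    raise ValueError(f"{chrom} is not a parent-{side} chromosome")
                if row[f"end_{side}"] > spec.length:
                    raise ValueError(f"gene beyond end of {chrom}")

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class HomologyMap:
    """Called homologous bin pairs plus the buffered exclusion zone.

    ``pairs`` holds (parent-1 global bin, parent-2 global bin) rows.
    ``exclusion`` is a symmetric boolean matrix over global bins marking every
    intergenome bin pair within the Chebyshev buffer of any homolog pair (the
    homolog pairs themselves included).
    """

    pairs: np.ndarray  # (k, 2) int64
    exclusion: np.ndarray  # (n, n) bool, symmetric
    buffer: int
    index: BinIndex

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def is_homolog_pair(self, b1: int, b2: int) -> bool:
        a, b = min(b1, b2), max(b1, b2)
        return any((min(p) == a and max(p) == b) for p in self.pairs)

    def partner_of(self, bin1: int) -> int | None:
        hit = self.pairs[self.pairs[:, 0] == bin1]
        return int(hit[0, 1]) if len(hit) else None


def call_homologous_bins(
    table: HomologyTable,
    index: BinIndex,
    prune_isolated: bool = True,
    buffer: int = 2,
) -> HomologyMap:
    """Call one homologous parent-2 bin per voting parent-1 bin.

    Each gene pair casts two votes, one per end: the parent-1 bin containing
    the gene start (resp. end) votes for the parent-2 bin containing the
    partner gene's start (resp. end).  Per parent-1 bin the parent-2 bin with
    most votes wins; ties break to the lowest parent-2 global bin id.

    ``prune_isolated`` drops pairs with no other pair within Chebyshev
    distance 2 on the same chromosome pair (removes spurious homology from
    scattered repeats).  The exclusion zone extends every surviving pair by
    ``buffer`` bins in Chebyshev distance on its chromosome pair.
    """
    table.validate_against(index.genome)
    votes: dict[int, Counter] = defaultdict(Counter)
    for _, row in table.frame.iterrows():
        for end in ("start", "end"):
            b1 = index.bin_of(row["chrom_1"], int(row[f"{end}_1"]))
            b2 = index.bin_of(row["chrom_2"], int(row[f"{end}_2"]))
            votes[b1][b2] += 1
    pairs = []
    for b1 in sorted(votes):
        counter = votes[b1]
        best = max(counter.values())
        winner = min(b for b, v in counter.items() if v == best)
        pairs.append((b1, winner))
    pairs_arr = np.array(pairs, dtype=np.int64).reshape(-1, 2)

    if prune_isolated and len(pairs_arr):
        keep = []
        chrom = index.chrom
        for i, (a1, a2) in enumerate(pairs_arr):
            near = False
            for j, (b1, b2) in enumerate(pairs_arr):
                if i == j:
                    continue
                if chrom[a1] == chrom[b1] and chrom[a2] == chrom[b2]:
                    if max(abs(int(a1) - int(b1)), abs(int(a2) - int(b2))) <= 2:
                        near = True
                        break
            keep.append(near)
        pairs_arr = pairs_arr[np.array(keep, dtype=bool)]

    n = index.n_bins
    exclusion = np.zeros((n, n), dtype=bool)
    chrom = index.chrom
    for a1, a2 in pairs_arr:
        c1, c2 = chrom[a1], chrom[a2]
        same1 = np.flatnonzero((chrom == c1) & (np.abs(np.arange(n) - a1) <= buffer))
        same2 = np.flatnonzero((chrom == c2) & (np.abs(np.arange(n) - a2) <= buffer))
        exclusion[np.ix_(same1, same2)] = True
        exclusion[np.ix_(same2, same1)] = True
    return HomologyMap(pairs=pairs_arr, exclusion=exclusion, buffer=buffer, index=index)


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def kmer_mappability(
    sequences: dict[str, str],
    read_length: int = 80,
    step: int = 10,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Substring-uniqueness mappability track.

    For each window start at multiples of ``step``, the window scores 1 if its
    ``read_length``-mer occurs exactly once in the combined sequence set
    counting both strands, else 0.  Windows containing non-ACGT characters
    score 0.  Returns per chromosome ``(starts, scores)``.

    This is a uniqueness proxy for aligner-based mappability (unique k-mers
    stand in for reads mapping with high mapping quality to the correct
    location); it ignores sequencing error and near-identical paralogs that a
    real aligner would or would not tolerate.
    """
    if read_length <= 0 or step <= 0:
        raise ValueError("read_length and step must be positive")
    shortest = min(len(s) for s in sequences.values())
    if read_length > shortest:
        raise ValueError("read_length exceeds shortest chromosome")
    counts: Counter = Counter()
    upper = {name: seq.upper() for name, seq in sequences.items()}
    for seq in upper.values():
        for i in range(len(seq) - read_length + 1):
            counts[seq[i : i + read_length]] += 1
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    valid = set("ACGT")
    for name, seq in upper.items():
        starts = np.arange(0, len(seq) - read_length + 1, step, dtype=np.int64)
        scores = np.zeros(len(starts), dtype=np.float64)
        for k, i in enumerate(starts):
            sub = seq[i : i + read_length]
            if not set(sub) <= valid:
                continue
            occ = counts[sub] + counts[_revcomp(sub)]
            scores[k] = 1.0 if occ == 1 else 0.0
        out[name] = (starts, scores)
    return out


def mappability_by_bin(
    tracks: dict[str, tuple[np.ndarray, np.ndarray]],
    index: BinIndex,
) -> np.ndarray:
    """Mean window mappability per genomic bin (NaN for bins with no window)."""
    result = np.full(index.n_bins, np.nan)
    for name, (starts, scores) in tracks.items():
        off = index.chrom_offsets[name]
        local = np.minimum(starts // index.bin_size, index.n_chrom_bins(name) - 1)
        for b in range(index.n_chrom_bins(name)):
            sel = local == b
            if sel.any():
                result[off + b] = float(scores[sel].mean())
    return result
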