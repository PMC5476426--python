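"""Plain-text input/output: genome specs, homology tables, pairs, matrices.

All on-disk formats are TSV or JSON.  Matrices travel as COO TSV
(``bin1_id  bin2_id  value``, upper triangle including the diagonal) with
``#``-prefixed header lines carrying provenance (bin size, kind, matrix
dimension, and any extra metadata such as the config hash and seed).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .contacts import NormalizedContactMatrix, PairRecord, RawContactMatrix
from .genome import BinIndex, ChromosomeSpec, HomologyTable, HybridGenomeSpec
from .polymer import StructurePopulation

__all__ = [
    "read_genome_tsv",
    "write_genome_tsv",
    "read_homology_tsv",
    "write_homology_tsv",
    "read_pairs",
    "write_pairs",
    "read_bed_intervals",
    "write_coo_matrix",
    "read_coo_matrix",
    "write_population",
    "write_json",
]

GENOME_COLUMNS = ["chrom", "length", "parent", "centromere", "rdna_start", "rdna_end"]


def read_genome_tsv(path: str | Path) -> HybridGenomeSpec:
    """Genome spec TSV: chrom, length, parent, centromere, rdna_start, rdna_end
    (rdna fields may be ".")."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(GENOME_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"genome spec missing columns: {sorted(missing)}")
    chroms = []
    for _, row in df.iterrows():
        rdna = None
        if row["rdna_start"] != "." and row["rdna_end"] != ".":
            rdna = (int(row["rdna_start"]), int(row["rdna_end"]))
        chroms.append(
            ChromosomeSpec(
                name=row["chrom"],
                parent=int(row["parent"]),
                length=int(row["length"]),
                centromere=int(row["centromere"]),
                rdna=rdna,
            )
        )
    return HybridGenomeSpec(chroms)


def write_genome_tsv(genome: HybridGenomeSpec, path: str | Path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("\t".join(GENOME_COLUMNS) + "\n")
        for c in genome.chromosomes:
            rs, re_ = (str(c.rdna[0]), str(c.rdna[1])) if c.rdna else (".", ".")
            fh.write(f"{c.name}\t{c.length}\t{c.parent}\t{c.centromere}\t{rs}\t{re_}\n")


def read_homology_tsv(path: str | Path) -> HomologyTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    return HomologyTable(df)


def write_homology_tsv(table: HomologyTable, path: str | Path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        table.frame.to_csv(fh, sep="\t", index=False)


def read_pairs(path: str | Path) -> Iterator[PairRecord]:
    """Pairs-style text: read_id chrom1 pos1 chrom2 pos2 [strand1 strand2]."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            strands = (f[5], f[6]) if len(f) >= 7 else (None, None)
            yield PairRecord(
                chrom_1=f[1],
                pos_1=int(f[2]),
                chrom_2=f[3],
                pos_2=int(f[4]),
                strand_1=strands[0],
                strand_2=strands[1],
                read_id=f[0],
            )


def write_pairs(pairs, path: str | Path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("# columns: read_id chrom1 pos1 chrom2 pos2 strand1 strand2\n")
        for i, p in enumerate(pairs):
            rid = p.read_id or f"r{i:08d}"
            s1 = p.strand_1 or "."
            s2 = p.strand_2 or "."
            fh.write(f"{rid}\t{p.chrom_1}\t{p.pos_1}\t{p.chrom_2}\t{p.pos_2}\t{s1}\t{s2}\n")


def read_fragment_sites(path: str | Path, genome: HybridGenomeSpec) -> "FragmentMap":
    """Restriction cut sites as TSV (columns: chrom, position).

    Chromosomes without listed sites get a single full-length fragment.
    """
    from .contacts import FragmentMap

    df = pd.read_csv(path, sep="\t", comment="#")
    sites: dict[str, np.ndarray] = {}
    for c in genome.chromosomes:
        pos = df.loc[df["chrom"] == c.name, "position"].to_numpy(dtype=np.int64)
        sites[c.name] = np.sort(pos)
    return FragmentMap(genome=genome, sites=sites)


def write_fragment_sites(fragments, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tposition\n")
        for name, pos in fragments.sites.items():
            for p in pos:
                fh.write(f"{name}\t{p}\n")


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_coo_matrix(
    matrix: RawContactMatrix | NormalizedContactMatrix,
    path: str | Path,
    meta: dict | None = None,
) -> None:
    """Upper-triangle COO TSV with provenance header lines."""
    if isinstance(matrix, RawContactMatrix):
        values, kind = matrix.counts, "raw"
        fmt = "%d"
    else:
        values, kind = matrix.values, "normalized"
        fmt = "%.10g"
    n = values.shape[0]
    with open(path, "w") as fh:
        fh.write(f"# kind={kind}\tbin_size={matrix.index.bin_size}\tn_bins={n}\n")
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        if kind == "raw" and matrix.masked.any():
            ids = ",".join(str(i) for i in np.flatnonzero(matrix.masked))
            fh.write(f"# masked_bins={ids}\n")
        if kind == "normalized":
            ids = ",".join(str(i) for i in np.flatnonzero(~matrix.valid))
            fh.write(f"# invalid_bins={ids}\n")
        fh.write("bin1_id\tbin2_id\tvalue\n")
        iu = np.triu_indices(n)
        vals = values[iu]
        keep = np.isfinite(vals) & (vals != 0)
        for i, j, v in zip(iu[0][keep], iu[1][keep], vals[keep]):
            fh.write(f"{i}\t{j}\t{fmt % v}\n")


def read_coo_matrix(
    path: str | Path,
    index: BinIndex,
) -> RawContactMatrix | NormalizedContactMatrix:
    """Read a COO TSV written by :func:`write_coo_matrix`."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            for fieldspec in body.split("\t"):
                if "=" in fieldspec:
                    k, v = fieldspec.split("=", 1)
                    meta[k.strip()] = v
    kind = meta.get("kind", "raw")
    n_bins = int(meta.get("n_bins", index.n_bins))
    if n_bins != index.n_bins:
        raise ValueError(f"matrix has {n_bins} bins but index has {index.n_bins}")
    if int(meta.get("bin_size", index.bin_size)) != index.bin_size:
        raise ValueError("bin size mismatch between matrix file and bin index")
    df = pd.read_csv(path, sep="\t", comment="#")
    n = index.n_bins
    if kind == "raw":
        counts = np.zeros((n, n), dtype=np.int64)
        counts[df["bin1_id"], df["bin2_id"]] = df["value"].astype(np.int64)
        counts = np.triu(counts) + np.triu(counts, 1).T
        masked = np.zeros(n, dtype=bool)
        if meta.get("masked_bins"):
            masked[[int(x) for x in meta["masked_bins"].split(",")]] = True
        return RawContactMatrix(counts=counts, index=index, masked=masked)
    values = np.zeros((n, n), dtype=np.float64)
    values[df["bin1_id"], df["bin2_id"]] = df["value"].astype(np.float64)
    values = np.triu(values) + np.triu(values, 1).T
    valid = np.ones(n, dtype=bool)
    if meta.get("invalid_bins"):
        valid[[int(x) for x in meta["invalid_bins"].split(",")]] = False
    values[~valid, :] = np.nan
    values[:, ~valid] = np.nan
    np.fill_diagonal(values, np.nan)
    return NormalizedContactMatrix(values=values, valid=valid, index=index)


def write_population(pop: StructurePopulation, path: str | Path) -> None:
    """Per-bead coordinates as text plus a JSON sidecar of the config."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# structure\tchain\tbead\tx_nm\ty_nm\tz_nm\n")
        offsets = np.cumsum([0] + [c.n_beads for c in pop.chains])
        for s in range(pop.n_structures):
            for ci, ch in enumerate(pop.chains):
                for b in range(ch.n_beads):
                    x, y, z = pop.coords[s, offsets[ci] + b]
                    fh.write(f"{s}\t{ch.name}\t{b}\t{x:.3f}\t{y:.3f}\t{z:.3f}\n")
    sidecar = {
        "config": {k: _jsonable(v) for k, v in pop.config.__dict__.items()},
        "seeds": [int(s) for s in pop.seeds],
        "chains": [
            {"name": c.name, "n_beads": c.n_beads, "centromere_bead": c.centromere_bead}
            for c in pop.chains
        ],
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def _jsonable(v):
    if isinstance(v, (np.integer, np.floating)):
        return v.item()
    if isinstance(v, tuple):
        return list(v)
    return v


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonable)
        fh.write("\n")
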