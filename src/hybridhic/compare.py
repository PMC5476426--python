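"""Between-condition comparison of normalized contact maps.

Differential maps subtract two normalized matrices after rescaling each so
its total over the shared valid off-diagonal cells is 1 (the marginal
normalization is not depth-preserving, so equal-total rescaling is required
before subtraction).

The anchor shift test asks whether one locus's trans interactions moved
between conditions as a function of the partners' centromeric distance:
partner bins are stratified by ``d_cen`` and each stratum is tested with a
two-sample Mann-Whitney rank-sum test, Bonferroni-corrected over the strata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .contacts import NormalizedContactMatrix
from .genome import BinIndex

__all__ = [
    "DifferentialMap",
    "StratifiedTestResult",
    "differential_map",
    "anchor_shift_test",
]


@dataclass
class DifferentialMap:
    """Equal-total-rescaled difference of two normalized matrices (a - b)."""

    values: np.ndarray  # NaN outside the shared valid cells
    valid: np.ndarray
    index: BinIndex
    scale_a: float
    scale_b: float


def differential_map(
    a: NormalizedContactMatrix,
    b: NormalizedContactMatrix,
) -> DifferentialMap:
    """Subtract two normalized maps after rescaling each to unit shared total."""
    if a.index.n_bins != b.index.n_bins:
        raise ValueError("matrices built on different bin indices")
    valid = a.valid & b.valid
    if not valid.any():
        raise ValueError("validity masks are disjoint; no shared bins")
    cell_ok = np.outer(valid, valid)
    np.fill_diagonal(cell_ok, False)
    cell_ok &= np.isfinite(a.values) & np.isfinite(b.values)
    ta = a.values[cell_ok].sum() / 2.0
    tb = b.values[cell_ok].sum() / 2.0
    if ta <= 0 or tb <= 0:
        raise ValueError("a shared-valid total is non-positive")
    diff = np.full_like(a.values, np.nan)
    diff[cell_ok] = a.values[cell_ok] / ta - b.values[cell_ok] / tb
    return DifferentialMap(
        values=diff, valid=valid, index=a.index, scale_a=1.0 / ta, scale_b=1.0 / tb
    )


@dataclass
class StratifiedTestResult:
    """Per-stratum rank-sum tests of an anchor's trans interaction shift."""

    frame: pd.DataFrame
    anchor_bin: int
    alpha: float
    n_strata: int

    @property
    def significant_strata(self) -> list[int]:
        f = self.frame
        sig = f["significant"].fillna(False).astype(bool)
        return [int(s) for s in f.loc[sig, "stratum"]]

    @property
    def any_significant(self) -> bool:
        return len(self.significant_strata) > 0


def anchor_shift_test(
    a: NormalizedContactMatrix,
    b: NormalizedContactMatrix,
    anchor_bin: int,
    index: BinIndex,
    n_strata: int = 9,
    alpha: float = 0.05,
    min_partners: int = 3,
    stratum_vs_rest: bool = False,
) -> StratifiedTestResult:
    """Test an anchor's trans interaction shift, binned by partner ``d_cen``.

    Partner bins are all different-chromosome bins valid in both matrices.
    Strata are unit-width right-open ranges of partner ``d_cen`` with the
    final stratum open-ended (``d_cen >= n_strata - 1``).  By default each
    stratum compares the anchor's values in ``a`` against those in ``b``
    (two-sided Mann-Whitney); with ``stratum_vs_rest`` the equal-total
    rescaled differences inside the stratum are instead compared against
    those outside it.  Adjusted p-values are Bonferroni over the strata
    actually tested; strata with fewer than ``min_partners`` partners are
    reported untested.
    """
    if not (a.valid[anchor_bin] and b.valid[anchor_bin]):
        raise ValueError(f"anchor bin {anchor_bin} invalid in one of the matrices")
    trans = index.chrom != index.chrom[anchor_bin]
    partners = np.flatnonzero(
        trans
        & a.valid
        & b.valid
        & np.isfinite(a.values[anchor_bin])
        & np.isfinite(b.values[anchor_bin])
    )
    strata = np.minimum(index.d_cen[partners], n_strata - 1)
    if stratum_vs_rest:
        dm = differential_map(a, b)
        diffs = dm.values[anchor_bin, partners]
    rows = []
    for s in range(n_strata):
        sel = strata == s
        n = int(sel.sum())
        row: dict = {
            "stratum": s,
            "d_cen_min": s,
            "d_cen_max": np.inf if s == n_strata - 1 else s + 1,
            "n": n,
        }
        if n < min_partners:
            row.update(statistic=np.nan, p_raw=np.nan, tested=False)
        else:
            if stratum_vs_rest:
                x, y = diffs[sel], diffs[~sel]
            else:
                x = a.values[anchor_bin, partners[sel]]
                y = b.values[anchor_bin, partners[sel]]
            res = stats.mannwhitneyu(x, y, alternative="two-sided")
            row.update(statistic=float(res.statistic), p_raw=float(res.pvalue), tested=True)
        rows.append(row)
    frame = pd.DataFrame(rows)
    n_tested = int(frame["tested"].sum())
    frame["p_adj"] = np.minimum(frame["p_raw"] * max(n_tested, 1), 1.0)
    frame["significant"] = pd.array(
        [p < alpha if t else None for p, t in zip(frame["p_adj"], frame["tested"])],
        dtype="boolean",
    )
    return StratifiedTestResult(
        frame=frame, anchor_bin=anchor_bin, alpha=alpha, n_strata=n_strata
    )
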