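"""Human-readable summary of a pipeline output directory.

Renders whatever stage outputs are present — contact-map heat maps, the
bootstrap proximity violin, the per-bin proximity profile, and the
stratified anchor-shift table — and skips missing sections with a warning.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

log = logging.getLogger("hybridhic")

__all__ = ["render_report"]


def _read_coo_dense(path: Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", comment="#")
    n = int(max(df["bin1_id"].max(), df["bin2_id"].max())) + 1
    m = np.zeros((n, n))
    m[df["bin1_id"], df["bin2_id"]] = df["value"]
    return np.triu(m) + np.triu(m, 1).T


def render_report(out: Path) -> dict:
    out = Path(out)
    sections: list[str] = []
    warnings: list[str] = []
    lines: list[str] = ["hybridhic report", "=" * 40]

    for name, title in [
        ("matrix_normalized.tsv", "normalized contact map"),
        ("matrix_polymer_raw.tsv", "polymer-model contact map"),
    ]:
        path = out / name
        if path.exists():
            m = _read_coo_dense(path)
            fig, ax = plt.subplots(figsize=(5, 5))
            with np.errstate(divide="ignore"):
                ax.imshow(np.log1p(np.nan_to_num(m)), cmap="Reds", interpolation="nearest")
            ax.set_title(title)
            fig.savefig(out / f"{path.stem}.png", dpi=120)
            plt.close(fig)
            if "contact maps" not in sections:
                sections.append("contact maps")
                lines.append(f"[contact maps] rendered from {name}")
    if "contact maps" not in sections:
        warnings.append("no contact matrix found; skipping contact-map section")

    boot = out / "proximity_bootstrap.tsv"
    if boot.exists():
        df = pd.read_csv(boot, sep="\t", comment="#")
        fig, ax = plt.subplots(figsize=(3, 5))
        ax.violinplot(df["ratio"], showmedians=True)
        ax.axhline(1.0, color="grey", ls="--", lw=0.8)
        ax.set_ylabel("homologous / nonhomologous interaction ratio")
        fig.savefig(out / "proximity_violin.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        sections.append("proximity bootstrap")
        med = float(df["ratio"].median())
        lines.append(f"[proximity bootstrap] median ratio {med:.3f} over {len(df)} reps")
    else:
        warnings.append("no bootstrap distribution; skipping proximity section")

    prof = out / "proximity_profile.tsv"
    if prof.exists():
        df = pd.read_csv(prof, sep="\t", comment="#")
        ok = df[df["sufficient"]]
        fig, ax = plt.subplots(figsize=(7, 3))
        ax.plot(ok["bin_1"], ok["ratio"], ".-", ms=4)
        ax.axhline(1.0, color="grey", ls="--", lw=0.8)
        ax.set_xlabel("parent-1 bin")
        ax.set_ylabel("proximity ratio")
        fig.savefig(out / "proximity_profile.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        sections.append("per-bin profile")
        lines.append(
            f"[per-bin profile] {len(ok)}/{len(df)} anchors sufficient; "
            f"median per-bin ratio {ok['ratio'].median():.3f}"
        )
    else:
        warnings.append("no per-bin profile; skipping profile section")

    shift = out / "anchor_shift_test.tsv"
    if shift.exists():
        df = pd.read_csv(shift, sep="\t", comment="#")
        sections.append("stratified shift test")
        lines.append("[stratified shift test]")
        lines.append(df.to_string(index=False))
    else:
        warnings.append("no stratified test results; skipping shift-test section")

    for w in warnings:
        log.warning(w)
        lines.append(f"warning: {w}")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return {"sections": sections, "warnings": warnings}
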