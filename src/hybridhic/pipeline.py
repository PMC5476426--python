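"""Staged pipeline: synth → polymer → process → proximity → compare → report.

One flat key-value configuration (YAML) drives every stage; unknown keys are
rejected.  All randomness flows from the single ``seed`` via named
substreams, so rerunning an identical configuration reproduces identical
output files for the deterministic stages.  Every output carries a
provenance header (package version, config hash, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as hio
from .compare import anchor_shift_test, differential_map
from .contacts import apply_masks, bin_contacts, filter_pairs, normalize_matrix
from .genome import build_bin_index, call_homologous_bins
from .polymer import PolymerConfig, build_chain_specs, population_to_contact_matrix, simulate_population
from .proximity import (
    ControlLevel,
    ExclusionPolicy,
    bootstrap_genomic_proximity,
    proximity_profile,
)
from .synth import ConditionEffects, SyntheticWorldConfig, ground_truth, simulate_condition

__all__ = ["PipelineConfig", "PipelineError", "run", "report", "STAGES"]

log = logging.getLogger("hybridhic")

VERSION = "0.1.0"

STAGES = ("synth", "polymer", "process", "proximity", "compare", "report")

DEFAULTS: dict = {
    # paths
    "out_dir": "hybridhic_out",
    "genome": None,
    "homology": None,
    "pairs": None,
    "fragments": None,  # restriction cut sites TSV; required with pairs input
    "matrix": None,
    "matrix_b": None,
    "masks": None,
    # global
    "seed": 0,
    "bin_size": 32_000,
    "log_level": "INFO",
    # synthetic generator (condition A, and B for comparisons)
    "synth_beta": 1.0,
    "synth_gamma": 1.0,
    "synth_rho": 1.0,
    "synth_beta_b": 1.0,
    "synth_gamma_b": 1.0,
    "synth_rho_b": 1.0,
    "synth_alpha": 1.5,
    "synth_kappa": 6.0,
    "synth_tau": 0.5,
    "synth_depth": 1_000_000.0,
    "synth_cis_trans_ratio": 1.0,
    "synth_two_conditions": False,
    # processing
    "min_row_mean": 1.0,
    "min_cis_distance": 1000,
    # polymer model
    "polymer_n_structures": 100,
    "polymer_bead_size": 3200,
    "polymer_size_multiplier": 1.0,
    # proximity
    "proximity_level": "dcen_arm",
    "proximity_n_reps": 10_000,
    "policy_exclude_rdna": True,
    "policy_exclude_centromere_bins": True,
    "policy_min_dcen": 0,
    "policy_telomere_margin": 0,
    "policy_arm_ratio_min": 0.75,
    "policy_min_comparables": 2,
    # comparison
    "compare_anchor_bin": None,
    "compare_n_strata": 9,
    "compare_alpha": 0.05,
}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; unknown keys are rejected on load."""

    values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(DEFAULTS)
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(DEFAULTS)
        merged.update(self.values)
        self.values = merged

    def __getitem__(self, key: str):
        return self.values[key]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise PipelineError("config must be a flat key-value mapping")
        return cls(values=data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.values, fh, sort_keys=True)

    def sha(self) -> str:
        """Hash of the analysis-relevant configuration (output location and
        verbosity excluded, so identical analyses hash identically)."""
        relevant = {k: v for k, v in self.values.items() if k not in ("out_dir", "log_level")}
        blob = json.dumps(relevant, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def provenance(self) -> str:
        return f"hybridhic v{VERSION} config={self.sha()} seed={self.values['seed']}"

    def policy(self) -> ExclusionPolicy:
        return ExclusionPolicy(
            exclude_rdna_chromosomes=self["policy_exclude_rdna"],
            exclude_centromere_bins=self["policy_exclude_centromere_bins"],
            min_dcen=self["policy_min_dcen"],
            telomere_margin=self["policy_telomere_margin"],
            arm_ratio_min=self["policy_arm_ratio_min"],
            min_comparables=self["policy_min_comparables"],
        )


def _substream(seed: int, name: str) -> int:
    """Deterministic named substream seed below 2**31."""
    h = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _need(path: Path, what: str, stage: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"missing {what} at {path}; run the '{stage}' stage first"
        )
    return path


def run(config: PipelineConfig, stages: list[str]) -> dict:
    """Run the requested stages in dependency order; returns a summary dict."""
    for s in stages:
        if s not in STAGES:
            raise PipelineError(f"unknown stage {s!r}; valid: {STAGES}")
    stages = [s for s in STAGES if s in stages]
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config["log_level"])
    summary: dict = {"stages": stages, "provenance": config.provenance()}
    for stage in stages:
        log.info("stage %s", stage)
        summary[stage] = _STAGE_FUNCS[stage](config, out)
    hio.write_json(summary, out / "summary.json")
    return summary


# --------------------------------------------------------------------------
# stages


def _stage_synth(config: PipelineConfig, out: Path) -> dict:
    world = SyntheticWorldConfig(bin_size=config["bin_size"], seed=config["seed"])
    labels = ["a", "b"] if config["synth_two_conditions"] else ["a"]
    info: dict = {}
    for label in labels:
        suffix = "" if label == "a" else "_b"
        effects = ConditionEffects(
            beta=config[f"synth_beta{suffix}"],
            gamma=config[f"synth_gamma{suffix}"],
            rho=config[f"synth_rho{suffix}"],
            alpha=config["synth_alpha"],
            kappa=config["synth_kappa"],
            tau=config["synth_tau"],
            depth=config["synth_depth"],
            cis_trans_ratio=config["synth_cis_trans_ratio"],
        )
        cond = simulate_condition(world, effects, _substream(config["seed"], f"synth_{label}"))
        if label == "a":
            hio.write_genome_tsv(cond.genome, out / "genome.tsv", config.provenance())
            hio.write_homology_tsv(cond.table, out / "homology.tsv", config.provenance())
            hio.write_json(
                ground_truth(cond.effects, cond.registry), out / "ground_truth.json"
            )
        name = "matrix_raw.tsv" if label == "a" else "matrix_raw_b.tsv"
        hio.write_coo_matrix(cond.matrix, out / name, {"provenance": config.provenance()})
        info[label] = {"total_pairs": cond.matrix.total_pairs}
    return info


def _load_index(config: PipelineConfig, out: Path):
    genome_path = Path(config["genome"]) if config["genome"] else out / "genome.tsv"
    genome = hio.read_genome_tsv(_need(genome_path, "genome spec", "synth"))
    return build_bin_index(genome, config["bin_size"])


def _stage_polymer(config: PipelineConfig, out: Path) -> dict:
    index = _load_index(config, out)
    pconf = PolymerConfig(
        bead_size=config["polymer_bead_size"],
        size_multiplier=config["polymer_size_multiplier"],
        n_structures=config["polymer_n_structures"],
        seed=_substream(config["seed"], "polymer"),
    )
    chains = build_chain_specs(index.genome, pconf)
    pop = simulate_population(chains, pconf)
    hio.write_population(pop, out / "population.tsv")
    matrix = population_to_contact_matrix(pop, index)
    hio.write_coo_matrix(
        matrix, out / "matrix_polymer_raw.tsv", {"provenance": config.provenance()}
    )
    return {"n_structures": pop.n_structures, "total_pairs": matrix.total_pairs}


def _process_one(config: PipelineConfig, out: Path, index, raw_name: str, norm_name: str) -> dict:
    info: dict = {}
    if config["pairs"] and raw_name == "matrix_raw.tsv":
        if not config["fragments"]:
            raise PipelineError(
                "pairs input requires a 'fragments' cut-site table (chrom, position)"
            )
        fragments = hio.read_fragment_sites(config["fragments"], index.genome)
        kept, report = filter_pairs(
            hio.read_pairs(config["pairs"]),
            fragments,
            min_cis_distance=config["min_cis_distance"],
        )
        raw = bin_contacts(kept, fragments, index)
        hio.write_coo_matrix(raw, out / raw_name, {"provenance": config.provenance()})
        info["filter_report"] = report.as_dict()
    else:
        matrix_path = Path(config["matrix"]) if config["matrix"] else out / raw_name
        raw = hio.read_coo_matrix(_need(matrix_path, "raw contact matrix", "synth"), index)
    if config["masks"]:
        raw = apply_masks(raw, hio.read_bed_intervals(config["masks"]))
    norm = normalize_matrix(raw, min_row_mean=config["min_row_mean"])
    hio.write_coo_matrix(norm, out / norm_name, {"provenance": config.provenance()})
    info.update(n_valid_bins=int(norm.valid.sum()), total_pairs=norm.total_pairs)
    return info


def _stage_process(config: PipelineConfig, out: Path) -> dict:
    index = _load_index(config, out)
    info = {"a": _process_one(config, out, index, "matrix_raw.tsv", "matrix_normalized.tsv")}
    second = Path(config["matrix_b"]) if config["matrix_b"] else out / "matrix_raw_b.tsv"
    if second.exists():
        saved = config.values["matrix"]
        config.values["matrix"] = str(second)
        info["b"] = _process_one(config, out, index, "matrix_raw_b.tsv", "matrix_normalized_b.tsv")
        config.values["matrix"] = saved
    return info


def _stage_proximity(config: PipelineConfig, out: Path) -> dict:
    index = _load_index(config, out)
    homology_path = Path(config["homology"]) if config["homology"] else out / "homology.tsv"
    table = hio.read_homology_tsv(_need(homology_path, "homology table", "synth"))
    hmap = call_homologous_bins(table, index)
    norm = hio.read_coo_matrix(
        _need(out / "matrix_normalized.tsv", "normalized matrix", "process"), index
    )
    level = ControlLevel(config["proximity_level"])
    policy = config.policy()
    profile = proximity_profile(norm, hmap, level, policy)
    with open(out / "proximity_profile.tsv", "w") as fh:
        fh.write(f"# {config.provenance()}\n")
        profile.frame.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    dist = bootstrap_genomic_proximity(
        norm,
        hmap,
        level,
        policy,
        n_reps=config["proximity_n_reps"],
        seed=_substream(config["seed"], "bootstrap"),
    )
    with open(out / "proximity_bootstrap.tsv", "w") as fh:
        fh.write(f"# {config.provenance()}\n")
        fh.write("rep\tratio\n")
        for i, rep in enumerate(dist.ratios):
            fh.write(f"{i}\t{rep:.10g}\n")
    summary = dist.summary()
    summary["bootstrap_median"] = summary["median"]
    summary["level"] = level.value
    hio.write_json(summary, out / "proximity_summary.json")
    return summary


def _stage_compare(config: PipelineConfig, out: Path) -> dict:
    index = _load_index(config, out)
    a = hio.read_coo_matrix(
        _need(out / "matrix_normalized.tsv", "normalized matrix (condition A)", "process"),
        index,
    )
    b = hio.read_coo_matrix(
        _need(
            out / "matrix_normalized_b.tsv", "normalized matrix (condition B)", "process"
        ),
        index,
    )
    diff = differential_map(a, b)
    n = index.n_bins
    with open(out / "differential_map.tsv", "w") as fh:
        fh.write(f"# {config.provenance()}\n")
        fh.write("bin1_id\tbin2_id\tvalue\n")
        iu = np.triu_indices(n, 1)
        vals = diff.values[iu]
        keep = np.isfinite(vals)
        for i, j, v in zip(iu[0][keep], iu[1][keep], vals[keep]):
            fh.write(f"{i}\t{j}\t{v:.10g}\n")
    anchor = config["compare_anchor_bin"]
    if anchor is None:
        truth_path = out / "ground_truth.json"
        if truth_path.exists():
            anchor = json.loads(truth_path.read_text()).get("anchor_bin")
    info: dict = {"n_shared_bins": int(diff.valid.sum())}
    if anchor is not None:
        result = anchor_shift_test(
            a,
            b,
            int(anchor),
            index,
            n_strata=config["compare_n_strata"],
            alpha=config["compare_alpha"],
        )
        with open(out / "anchor_shift_test.tsv", "w") as fh:
            fh.write(f"# {config.provenance()}\n")
            result.frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        info["anchor_bin"] = int(anchor)
        info["significant_strata"] = result.significant_strata
    hio.write_json(info, out / "compare_summary.json")
    return info


def _stage_report(config: PipelineConfig, out: Path) -> dict:
    from .report import render_report

    return render_report(out)


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "polymer": _stage_polymer,
    "process": _stage_process,
    "proximity": _stage_proximity,
    "compare": _stage_compare,
    "report": _stage_report,
}


def report(out_dir: str | Path) -> dict:
    """Render the human-readable report for an output directory."""
    from .report import render_report

    return render_report(Path(out_dir))
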