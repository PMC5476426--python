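# hybridhic

Homolog proximity analysis for Hi-C data from hybrid diploid yeast genomes,
with a Rabl-orientation polymer null model.

## The problem

In a hybrid diploid — a cross between two diverged yeasts, or between two
distinguishable strains — Hi-C read pairs can be assigned to their parental
genome, so contact frequencies *between* the two homologous chromosome sets
become observable genome-wide.  Homologous loci look strikingly close in
such maps.  But budding yeast nuclei sit in a Rabl-like orientation:
centromeres cluster at the spindle pole body, chromosome arms extend
outward, telomeres tether to the nuclear envelope.  Two homologous loci
automatically share a centromeric distance and an arm length, so nuclear
architecture alone drags them together.  The analytic problem is separating
genuine homolog pairing from this architectural confound.

`hybridhic` implements the full analysis as a tested, reusable library for
computational biologists working with diploid or hybrid Hi-C:

* contact processing — ligation-pair filtering (duplicates, same-fragment,
  < 1 kb cis), 32 kb binning, interval masking, and the single-pass
  marginal normalization `N_ij = C_ij · T / (m_i · m_j)` (diagonal excluded,
  rows with mean < 1 read dropped; deliberately *not* iterative balancing);
* homologous-bin calling from one-to-one gene homology by end-vote
  plurality, with isolation pruning and a 2-bin exclusion buffer;
* the homolog proximity statistic: each homologous bin pair is compared to
  nonhomologous intergenome pairs sharing one of its bins, under three
  nested control stringencies — ALL (no control), DCEN (equal centromeric
  distance), DCEN_ARM (equal centromeric distance *and* arm length within
  25%) — with a 10,000-replicate bootstrap of the genome-wide ratio
  Σ homologous / Σ drawn-nonhomologous;
* a volume-exclusion bead-chain polymer model of the diploid Rabl
  orientation (centromere capture at the SPB, telomere shell, nucleolar
  exclusion, no homology term) as the architectural null: simulated
  structures are contact-called at 45 nm and pushed through the identical
  pipeline;
* condition comparison: equal-total differential maps, and a per-locus
  shift test stratified by partner centromeric distance (Mann-Whitney per
  stratum, Bonferroni n = 9) for relocalization events;
* a synthetic-data generator with known ground truth (distance decay,
  centromere/telomere clustering, pairing boost β, locus spike γ,
  pericentromeric depletion ρ, Poisson depth) driving the package's own
  calibration experiments;
* a `hybridhic` CLI orchestrating the stages with one flat YAML config and
  fully deterministic, seeded outputs.

## Worked example

Generate a synthetic hybrid with a genome-wide pairing boost of β = 1.5,
normalize it, and estimate homolog proximity at full control stringency:

```sh
hybridhic run --out demo --seed 7 synth process proximity
```

or equivalently from Python:

```python
from hybridhic.pipeline import PipelineConfig, run

cfg = PipelineConfig({"out_dir": "demo", "seed": 7, "synth_beta": 1.5,
                      "policy_telomere_margin": 1})
summary = run(cfg, ["synth", "process", "proximity"])
print(summary["proximity"])
```

which prints

```
{'median': 1.513989680091135, 'p2.5': 1.4607004629857292,
 'p97.5': 1.5708958575898004, 'n_reps': 10000, 'n_anchors': 48,
 'level': 'dcen_arm'}
```

Reading this: across 48 homologous bin pairs with at least two comparable
nonhomologous partners, the bootstrap median of the genome-wide
homologous/nonhomologous interaction ratio is 1.51 with a 95% interval of
[1.46, 1.57] — the statistic recovers the injected β = 1.5 boost, and the
interval excludes 1 (no pairing).  On a homology-agnostic polymer
population the same statistic returns ≈ 1.0 at DCEN_ARM stringency while
the uncontrolled (ALL) version reads ≈ 1.3–1.4: the control, not the raw
comparison, is what distinguishes pairing from architecture.

The output directory contains the genome and homology tables, raw and
normalized COO TSV matrices, the per-bin proximity profile, the bootstrap
distribution, and a JSON summary; `hybridhic report --out demo` renders
heat maps, the proximity violin, the per-bin profile and the shift-test
table.  Every artifact carries a provenance header (version, config hash,
seed) and identical configs rerun to byte-identical files.

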