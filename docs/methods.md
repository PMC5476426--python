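# Methods

`hybridhic` quantifies homolog proximity in Hi-C data from hybrid diploid
yeasts — diploids whose two parental chromosome sets are diverged enough
that read pairs can be assigned to a parent, so that contacts *between* the
two parental genomes are observable genome-wide.  The central question the
statistics address: do homologous loci sit closer together than the
Rabl-like orientation of the yeast nucleus (centromeres clustered at the
spindle pole body, arms extending to the periphery, telomeres at the
envelope) already forces them to?

## Contact-matrix processing

Ligation pairs are filtered in three ordered steps: PCR duplicates
(identical order-normalized restriction-fragment signatures), same-fragment
pairs, and intra-chromosomal pairs closer than 1 kb (unligated or
self-ligated products).  Surviving pairs are counted into symmetric
fixed-width bins (32 kb default) at the coordinate of the restriction site
each end faces (downstream boundary for + strand reads, upstream for −,
nearest boundary when strands are unknown).

Normalization is deliberately the single-pass marginal scheme, taken
literally and in order: (1) exclude the diagonal; (2) invalidate masked bins
and bins whose off-diagonal row mean over valid bins is below 1 read; (3)
recompute marginals `m_i` and the grand total `T` over valid off-diagonal
cells; (4) `N_ij = C_ij · T / (m_i · m_j)`.  This is *not* iterative
balancing (ICE) and does not produce equal row sums; all downstream
statistics are built to compare cells sharing structure (same bin, same
centromeric distance) so that residual marginal heterogeneity largely
divides out.  The row-mean denominator counts valid off-diagonal bins, not
all bins.  `N` is homogeneous of degree 0 in the counts, so every
downstream ratio, rank and bootstrap distribution is invariant under global
rescaling of the raw matrix (asserted to 1e-12 relative in the tests).

## Homologous-bin calling

Homology enters as a one-to-one gene table.  Each gene pair casts one vote
per end: the parent-1 bin containing a gene end votes for the parent-2 bin
containing the partner gene's corresponding end.  Per parent-1 bin the
plurality parent-2 bin wins; ties break deterministically to the lowest
parent-2 bin id.  Pairs with no other called pair within Chebyshev distance
2 on their chromosome pair are pruned (isolated "homology" is typically
repeat-driven), and an exclusion buffer of 2 bins in every direction around
each surviving pair is carved out of all nonhomologous comparison sets so
near-homologous signal cannot leak into the background.

## The proximity statistic and its controls

For each homologous bin pair (*anchor*), the comparison set is the set of
intergenome bin pairs sharing exactly one bin with the anchor, minus the
exclusion zone and policy-filtered bins.  Three nested stringencies control
for the Rabl orientation:

* **ALL** — every qualifying partner (no architectural control);
* **DCEN** — the partner bin's centromeric distance (`d_cen`, in bins) must
  equal that of the bin it replaces: controls for centromere clustering;
* **DCEN_ARM** — additionally the partner's arm length must be within 25%
  (shorter/longer ≥ 0.75, in bin units) of the replaced bin's arm: controls
  for the preferential interaction of short arms, whose telomeric tethering
  near the pole makes them mutually close regardless of homology.

Anchors need at least two comparable partners; the per-bin profile reports
homolog value over the *median* of comparables, while the genome-wide
bootstrap draws one comparable per anchor (uniformly, with replacement) and
reports the ratio of *sums*, 10,000 replicates by default.  The two
summaries intentionally differ.  Zero-denominator replicates are redrawn
(counted), keeping the replicate count fixed.

Locus-level pairing strength ranks a single intergenome pair against all
policy-filtered intergenome pairs (the mid-arm preset: both bins ≥ 15 bins
from a centromere, ≥ 1 bin from a telomere, no rDNA chromosomes).  Ranks
and percentiles use strict-greater counting with midrank for ties.

## The Rabl polymer null model

The null model asks what the proximity statistic returns when nuclear
architecture alone, with no homology-specific force, generates the
contacts.  Chromosomes are chains of touching beads (3.2 kb per 30 nm bead
by default; the toy experiments use 8 kb beads) confined to a spherical
nucleus.  Constraints: consecutive beads stay within bond range, no two
non-bonded beads overlap, centromere beads lie in a capture sphere at the
SPB, telomere beads in a peripheral shell, rDNA beads inside (and all other
beads outside) a nucleolar spherical cap opposite the SPB.  Structures are
sampled by a guided random walk from the centromere bead outward followed
by iterative projection until every constraint is satisfied; sampling is
bitwise deterministic per seed and structures failing to converge are
resampled under a derived seed.  Populations of structures are converted to
contact matrices by calling every bead pair within 45 nm (inclusive,
center-to-center) a contact and feeding the counts through the same
normalization as real data.

Geometry defaults are assumptions, not reproductions: haploid nuclear
radius 1000 nm, capture-sphere radius 250 nm centered at the SPB point on
the envelope, telomere shell 100 nm thick, nucleolus 10% of nuclear volume.
The diploid model scales nuclear and tether geometry by 1.25 (nuclear
volume roughly doubles in diploids) while the fiber itself is unchanged.
The small-nucleus experiments (`size_multiplier` 0.8 or 0.64) instead
rescale *all* model lengths, producing a geometrically similar smaller
nucleus; only the 45 nm calling threshold — a property of the simulated
assay — never scales, so smaller nuclei yield denser, less specific contact
maps.  Empirically this reproduces the expected direction: apparent homolog
proximity decreases, not increases, in smaller nuclei.

Toy scale: the packaged polymer experiments use an 8+8-chromosome hybrid
(256–448 kb chromosomes in mirror-similar pairs, 86 bins per parent,
~690 beads per structure) and 1000-structure populations.  Mirror-similar
pairs guarantee every arm an exact-length counterpart on a different
chromosome, so the arm-length control always has geometrically equivalent
comparables; eight chromosomes per parent keep enough independent units
that the genome-wide bootstrap median is stable (population-to-population
SD ≈ 0.02 at this scale).  Populations of ≥ 500 structures reproduce the
qualitative Rabl signatures (contact decay with genomic distance,
pericentromeric trans enrichment).

## Condition comparison

Differential maps rescale each normalized matrix to unit total over the
shared valid off-diagonal cells before subtracting (the normalization is
not depth-preserving), making the map antisymmetric under input swap and
invariant to global scaling of either input.  The anchor shift test takes
one locus, collects its trans partners valid in both conditions, stratifies
them by partner `d_cen` (unit-width strata, ninth stratum open-ended), and
runs a two-sided Mann-Whitney test per stratum on condition-A versus
condition-B values, Bonferroni-corrected over the strata tested (default
9); strata with fewer than 3 partners are reported untested.  Because of
the equal-total constraint, a genuine pericentromeric depletion necessarily
appears alongside compensating relative gains at large `d_cen`; detection
of the depletion itself therefore means a significant stratum *inside* the
depleted range.  An alternative mode tests each stratum's rescaled
differences against all other strata's, for sensitivity analysis.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, with
every effect injected as a known multiplier:

* cis: power-law decay `A·s^(-α)` (α = 1.5) on **circular** bin separation
  within a chromosome.  The wrap-around term stands in for the end-to-end
  arm association of the Rabl orientation and keeps per-bin cis coverage
  exactly uniform within a chromosome, so the single-pass normalization
  introduces no position-dependent artifacts into the locus background —
  a designed-in exchangeability that the null-rank and null-median
  contracts rely on.  `A` is set so total cis mass over trans mass hits a
  configurable target (default 1.0, hybrid maps having large trans
  fractions across 32 chromosomes);
* trans: baseline `b` times `1 + exp(-(d_cen,i + d_cen,j)/κ)` (centromere
  clustering, κ = 6 bins) plus a bonus τ = 0.5 when both bins are
  telomere-margin bins (telomere clustering);
* homologous bin pairs × β (genome-wide pairing boost); one designated
  mid-arm pair × γ (the condition-inducible locus-specific pairing spike);
  the trans row of one designated pericentromeric anchor × ρ for partners
  with `d_cen < κ` (condition-dependent relocalization away from the
  centromere cluster).

Counts are independent Poisson draws over the upper triangle scaled to a
target depth (default 1e6 pairs).  Poisson is the minimal count model; real
Hi-C counts are overdispersed and an overdispersion knob is left as future
work.  The default world is a 4+4-chromosome hybrid (960/768/576/384 kb,
168 bins total) whose first chromosome carries a 24-bin arm so that a
designated locus ≥ 15 bins from the centromere exists.

What passing tests show, and do not show: recovery of β within 10%, rank-1
detection of a γ = 5 spike, uniform null ranks, ≤ 7% family-wise error and
≥ 90% power at ρ = 0.5 all hold under this generative model — independent
Poisson cells, factorizable architecture signal, exact 1:1 homology.  They
do not certify behavior under overdispersion, mappability-driven coverage
holes, structural rearrangements between the parents, or homology maps with
errors; conclusions about real libraries need the usual experimental
caveats on top of what these tests establish.

## Numerical choices

* Bond range (15, 45) nm around the 30 nm bead diameter; overlap tolerance
  1 nm; solver projects with a 0.05 nm interior margin and the checker
  allows 1e-6 slack, so emitted structures are strictly feasible.
* Volume-exclusion pass uses a 150 nm cell grid (overlaps only need
  neighbor cells); contact calling uses a k-d tree with an inclusive
  radius.
* The centromere bin has `d_cen = 0`, belongs to both arms, and carries the
  longer arm's length; policies that cannot control arm length for it
  (genome-wide preset) simply exclude it, as the analysis does.
* Vote ties, overlap pushes for coincident beads, and percentile ties all
  break deterministically; every stochastic step takes an explicit seed and
  per-structure seeds are recorded for replay.
* An optional flag treats an rDNA-carrying chromosome as two quasi-
  independent arm segments for arm-length purposes (off by default; the
  genome-wide preset excludes that chromosome anyway).
* Mappability is substring uniqueness over both strands (windows every
  10 bp by default), a proxy for aligner-based unique mapping; it ignores
  sequencing error and scoring subtleties of a real aligner.

## Problem sizes in the packaged experiments

Polymer experiments run 1000-structure populations of the 8+8 toy hybrid
(the study-scale default of 20,000 structures is configurable); synthetic
experiments run 168-bin worlds at depth 1e6 with 20–200 replicates and
10,000 bootstrap replicates.  These sizes were chosen so the complete
experiment battery reruns from scratch in a few minutes on one CPU while
keeping every statistic's Monte-Carlo error well inside the margins being
asserted.

## Known limitations

* The polymer solver is a projection heuristic, not an equilibrium sampler;
  populations are ensembles of feasible configurations, not Boltzmann
  draws, matching the constraint-satisfaction character of the original
  tethering model but not molecular dynamics.
* The generator's circular cis decay buys exchangeability at the cost of a
  mildly unphysical enrichment between chromosome ends in cis.
* Single-pass marginal normalization leaves residual row effects by design;
  statistics not built on shared-bin comparisons should not be computed
  from these matrices without further correction.
* Bootstrap resampling covers comparable-choice uncertainty only; it does
  not propagate population-to-population (structure-sampling) variance,
  which dominates at small polymer populations.
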