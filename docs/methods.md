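# Methods

This note records the models implemented in `peachsv`, the defaults and why,
what the synthetic cohort does and does not emulate, and the numerical
choices made where the design was genuinely open. No empirical claim here
goes beyond what the test suite and `scripts/acceptance.py` compute.

## Coordinates and containers

Internally every interval is 0-based half-open; VCF and GFF3 (1-based
inclusive) and BED (0-based half-open) convert at the format boundary only.
An `SVRecord` stores the VCF convention (`start` = first affected base,
`end` inclusive, insertions have `end == start`) with `start0`/`end0`
properties exposing the internal view; `svlen` is the absolute event length
(span for DEL/DUP/INV, inserted length for INS). Genotypes are alt-allele
dosages {0, 1, 2} with −1 for missing. SV call sets below 30 bp are dropped
at read time (the SV-map size rule is strictly "> 30 bp"); breakend (BND)
records are rejected.

Call-set merging is single-linkage: two records cluster when their starts
and their ends are each within `max_dist` (default 1000 bp) and share the
SV type; the representative is the lowest-start (ties: longest) member and
support counts the contributing call sets. The defaults mirror the
documented defaults of the usual SV-merging tool; both knobs are arguments.

## Annotation

Categories are assigned with precedence CDS > intron > upstream >
downstream > intergenic: `CDS_full` when the SV contains a gene's whole CDS
extent, `CDS_partial` on any CDS base, then intron, then a strand-aware
1-kb promoter window upstream of the TSS, then 1 kb downstream of the TES.
The published category table does not state a precedence (its rows do not
quite sum to the total, an unexplained ~83-SV remainder); we therefore
assert exhaustiveness and exclusivity for our own partition rather than for
the printed one. An SV touching several genes takes the highest-precedence
feature overall but lists all touched genes, so SV counts and distinct-gene
counts are tallied separately. Genome fraction has two modes: `sum`
(Σ svlen, insertions included) and `union` (merged reference span,
insertions contribute nothing); union ≤ sum always.

## Hotspots

30-kb tiling per chromosome keeps the trailing short interval (configurable
to drop); counts assign each SV to the tile of its midpoint, the same
SVs-as-points convention used for Manhattan positions. λ is the mean count
over all tiles including empty ones (an occupied-tiles-only λ is available
as a switch: the published hotspot count implies a slightly higher
threshold than the stated percentile rule at the stated λ, so the
convention is left to the caller). The threshold is the smallest integer
c ≥ 1 with Poisson CDF(c−1; λ) ≥ 0.99. Enrichment of hotspots for an
interval feature (segmental duplications) is interval-level, for a per-SV
label (NAHR) SV-level, both by two-sided Fisher exact test; degenerate
margins report p = 1 with the odds ratio flagged undefined.

## Mechanism classification

Order matters: VNTR exclusion precedes the homology search, and the
exclusion rule is strictly "more than 80%" span coverage (an SV at exactly
0.8 is retained). Insertions and any SV whose breakpoints are closer than
the offset budget are classified `other` without a homology search: both
reference flank windows would overlap themselves and trivially "align", and
classifying an insertion's true junction homology needs the inserted
sequence, which the reference does not carry.

Block discovery is banded **ungapped** alignment. The published criteria —
identity ≥ 85%, exact run ≥ 20 bp, offset ≤ 20 bp, block covers the
breakpoint in both flanks — are all expressible on ungapped diagonals (an
offset budget is exactly a diagonal band), and the ungapped model makes the
search exhaustively enumerable, so the implementation is verified against a
brute-force all-windows oracle and, on homology-free flanks, calls nothing
across 10⁴ seeded pairs. "Offset" is the difference between a block's start
positions in the two flanks, each measured in flank coordinates with the
junction at the centre; identity is matches/aligned columns over the block.
Per diagonal the maximal-length qualifying window is reported (ties:
leftmost). A gapped local-alignment scorer was considered and rejected: no
published scoring scheme exists to match, and gaps reintroduce exactly the
offset freedom the 20-bp budget is meant to bound.

The inverted-repeat scan at inversion breakpoints is a deliberately simple
exact-match stand-in for a dedicated inversion caller: exact
reverse-complement k-mer matches (k = the 50-bp minimum) between the two
breakpoint windows, merged along diagonals; an empty result is the
"no inverted repeats" NHEJ-compatible signature. Junction-edit reporting
anchors the observed junction's ends into the two reference flanks with
20-bp exact seeds, extends, and reports unmatched reference bases as
deletions and unmatched junction bases as an insertion.

## PAV

Windows are 500 bp at a 100-bp step, full-length only — the window count for
a chromosome of length L is ⌊(L−500)/100⌋+1; a chromosome shorter than one
window is kept as a single truncated window only if at least half a window
long. Coverage is the best **single-locus** aligned fraction (repeat loci
cannot pool coverage across placements): exact 21-mer seeds are grouped by
target diagonal, chained, extended without gaps until three consecutive
mismatches (the mismatched tail trimmed), and merged. Windows under 25%
coverage are genome-specific; overlapping specific windows merge into PAV
regions, which bounds breakpoint error by the window geometry (≤ 400 bp per
edge at the defaults — the recovered planted-insertion edges land ~100 bp
out). "Failed to align" is treated as coverage 0, a special case of the
threshold. The mapper sits behind a `coverage_fn` hook so a general-purpose
aligner can replace it for real assemblies; the exact-seed mapper is the
right tool for the synthetic genomes, not a claim about diverged real
sequence.

## Population genetics

Polarization requires ≥ 2 called outgroup samples and fixation among them;
polymorphic or uncalled outgroups exclude the site (counted in
`n_excluded`). Flipping which allele the outgroup is fixed for maps derived
counts k → 2n−k exactly. Projection to m = 20 alleles uses hypergeometric
weights and conserves site mass; the per-site projection path doubles as
missing-data handling by dropping sites with fewer than m called alleles,
which is also why projection is applied before any DFE-style export (the
two-line text export carries the projected spectrum). θπ per variant site
is 2k(2n−k)/(2n(2n−1)) — the unbiased pairwise-difference probability —
averaged over variant sites only, matching the ~0.2 per-variant-site scale
of published population panels rather than a per-bp genome-wide rate.
Divergent SVs compare carriers (dosage ≥ 1, missing excluded) between
groups by two-sided Fisher exact test with Benjamini–Hochberg control at
FDR < 0.01; direction follows the carrier-frequency comparison. PCA centres
dosages by marker mean and scales by the binomial standard deviation
√(2p(1−p)), mean-imputes missing calls, and drops constant markers.

## Association

The scan is the EMMAX approximation: one REML fit of δ = σ²e/σ²g under the
null (bounded scalar optimization of the eigendecomposed restricted
likelihood, kinship eigenvalues floored at 1e−8 when needed), then
per-marker generalized least squares with the components fixed. The
per-marker error variance is re-estimated from the rotated residuals and
the test is a t-test with n−2 degrees of freedom, which makes the
identity-kinship case *exactly* ordinary per-marker regression — the
analytic correctness anchor in the tests. Binary phenotypes are analysed
with the same linear model, as the reference algorithm does in practice.
Missing dosages are mean-imputed per marker (imputation proper is out of
scope). The Bonferroni threshold follows the reciprocal convention
threshold = 1/(number of tests), which reproduces both published thresholds
from their test counts; the numerator α is configurable. LD is the squared
sample correlation of dosage vectors with pairwise deletion of missing
calls; zero-variance vectors are flagged NaN rather than silently zero. The
segregation check is strict: perfect means every flat sample has dosage
exactly 1 and every round sample exactly 0 — a homozygous-derived flat
sample or any missing call breaks the flag, never silently.

## The synthetic cohort

Defaults are the study conditions: 41 landraces, 108 modern cultivars, 37
outgroup accessions, 37 flat among the 149 ingroup samples; ~1000 SVs
(55% DEL / 39% INS / 5.5% DUP / 0.5% INV, log-normal lengths 31 bp–20 kb)
and 3000 SNPs on a 3 Mb + 0.99 Mb two-chromosome genome. The genome is
i.i.d. uniform ACGT except planted features — sufficient for the
exact-match and alignment-free stages that consume it. Planted structure,
one random stream per component so components never perturb each other:

- **Hotspots:** 5% of 30-kb tiles carry a 10× SV rate (a two-rate mixture
  over tiles, uniform within a tile).
- **SFS shift:** derived frequencies are Beta(0.4, 0.8·(1+shift)) with
  shift = 1 for SVs and 0 for SNPs, putting SV frequencies stochastically
  left of SNP frequencies at an effect size the rank test detects with
  power ≥ 0.9 at these panel sizes.
- **Population structure:** per-population frequencies drift around the
  shared value with variance Fst·f(1−f), Fst = 0.05, in both marker sets —
  this is what makes SNP- and SV-based PCA concordant. Sixty SVs are
  strongly divergent (0.05 vs 0.60) in alternating directions; these are
  kept in ancestral-REF coding so the planted direction is the observable
  carrier-frequency direction.
- **Heterozygosity excess:** in cultivars, derived homozygotes resolve to
  heterozygotes with probability 0.25 — het excess from crossbreeding and
  clonal propagation that deliberately preserves carrier status, so the
  divergence scan is not contaminated.
- **Genotypes** are Hardy–Weinberg draws from the population frequencies
  with 2% missingness; outgroup samples are fixed for the ancestral allele
  everywhere (10% of sites have the derived allele as REF, exercising
  polarity flipping).
- **NAHR:** forty well-separated deletions get an identical 30-bp block
  written across both breakpoints; fifteen deletions are relocated inside
  planted VNTR tandem arrays (real repeats written into the sequence).
- **Inversion:** a 1.674-Mb inversion on Chr1 is heterozygous in every flat
  sample, absent in every round sample and the outgroup, with no missing
  calls; expression is 2.0 per inversion allele plus N(0, 0.5) noise.

What it does **not** emulate, hence what passing tests do not show about
real data: linkage disequilibrium from recombination (LD-decay behaviour is
demonstrated on an explicit hitchhiking panel whose markers copy the
inversion dosage with distance-decaying probability, not on the cohort),
sequence evolution and alignment ambiguity, genotyping error structure
beyond uniform missingness, and realistic gene density (60 sparse genes, so
most synthetic SVs are intergenic). Byte-identical outputs for identical
seeds are tested, as is seed sensitivity.

## Problem sizes and numerics

The suite and the acceptance script run the statistical stages at sizes
chosen to make each Monte-Carlo check sharp but quick on one CPU: hotspot
null calibration at λ = 3.5 × 8000 intervals × 200 replicates against the
binomial 99% CI of the exact exceedance probability (with the known
generating λ — the exceedance probability is only defined for a fixed λ;
the estimated-λ path is tested separately); NAHR oracle equivalence on
hundreds of 200-bp flank pairs straddling every threshold (length 18–25,
offset ±22, 0–3 mutations) and specificity on 10⁴ homology-free pairs;
shift-test power over 100 frequency draws; PAV on a 50-kb genome with a
10-kb insertion. Degenerate inputs are defined rather than special-cased
where possible: a constant phenotype returns p = 1 everywhere, an empty SV
set gives an all-zero annotation table and zero hotspots, a zero-variance
LD vector is NaN-flagged, and Fisher tables with empty margins report p = 1
with the odds ratio flagged.
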