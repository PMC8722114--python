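# Methods

## Scope and data model

`hrrforge` operates on collections of germline small-variant call sets from
one or more samples, where each call set is indexed by its position in an
experimental factor grid: sample × lab × platform × library × replicate ×
aligner × caller. Platform and library are carried as labels but are tied
to the lab in the bundled study designs (each lab runs one platform and one
kit), so the variance analysis treats {lab, platform, library} as a single
"platform" factor.

Variants are normalized on ingestion: multiallelic records are split into
per-ALT calls with the genotype projected per allele (an allele is either
present or absent; other ALTs count as reference), the common suffix and
then prefix of (REF, ALT) are trimmed keeping at least one base each, and —
when a reference sequence is supplied — indels are left-aligned by the
standard shift-left rule. Identity is the tuple (chrom, pos, ref, alt);
matching between call sets is exact on this key. Genotype agreement is
recorded and can be made mandatory (`genotype_strict`), but the default is
allele-level matching: it is deterministic and exactly checkable against
set arithmetic, at the cost of not recognizing complex-region equivalences
that a haplotype-aware comparator would. Records that are homozygous
reference, genotype-missing, FILTER-failed, or on non-autosomes are dropped
at read time; the inheritance machinery assumes autosomal diploidy.

Coordinates: VCF positions are 1-based; all interval sets are 0-based
half-open (BED). The conversion happens exactly once — a variant at VCF
position p occupies base p−1, and its REF footprint is [p−1, p−1+len(ref)).

## Region derivation

Per-run *region files* (intervals with adequate aligned coverage, produced
upstream by a callable-loci tool; this package consumes them as given) are
combined per sample:

- **mappable** = union of the region files;
- **consensus mappable** = bases covered by ≥ k\* region files, where
  k\* = max{k ≥ 1 : bases(count ≥ k) ≥ f · bases(count ≥ 1)} with
  f = 0.99. The "top 99%" rule is interpreted *base-weighted* (99% of
  mappable bases retained); a region-count weighting would depend on
  arbitrary interval fragmentation. Under the max-k definition ties cannot
  occur, and the retained fraction can never fall below f.
- **callable** = consensus minus the union of difficult-region masks.

Coverage counting is an exact sweep-line over interval endpoints,
run-length encoded; all three operations are property-tested against
per-base bit-vector computation.

## The HRV cascade

Filtering runs replicate → lab → aligner → caller → twin → Mendelian, each
stage partitioning its input union into concordant and discordant calls:

- Replicate/lab/aligner stages keep variants present in ≥ 2 of the inputs
  (`min_support`); with triplicates this discards exactly the
  single-replicate variants. A single-lab design passes the lab stage
  unchanged. The presence rule generalizes the fixed arities of typical
  designs so the cascade works for any number of inputs.
- The caller stage keeps variants shared by ≥ `min_callers` callers
  (default 7: variants shared by six or fewer callers are discordant).
- Monozygotic twins share a germline: the twin stage intersects the twins'
  caller-concordant sets.
- The Mendelian stage works site-wise over the union of the family's
  variant keys, with 0/0 imputed for members lacking a call. A variant is
  kept iff every offspring genotype is producible from one allele per
  parent (exhaustively verified against gamete-pair enumeration: 15 of the
  27 biallelic diploid (F, M, C) combinations are consistent). Apparent de
  novo variants therefore count as violations — the target is
  reproducibility, not discovery. Violating variants are discordant for
  every carrier, parents included. An `allele_presence_only` mode relaxes
  the check to presence/absence for callers with unreliable genotypes.

Samples outside any pedigree stop at caller concordance; their HRVs are the
caller-concordant variants.

Concordant representatives carry the modal genotype across supporting call
sets (ties broken toward the smaller genotype), which makes the cascade
invariant to the order in which call sets are supplied. Discordant calls
from *every* stage are pooled per sample; this pool drives HRR carving.

## HRR carving

For each discordant variant position p (0-based), the window
[p−flank, p+flank] (flank = 50, so 101 bases) is compared with HRV
positions:

- no HRV in the window → the whole window is excised;
- otherwise each side is treated independently: a side with no HRV is
  excised entirely; a side whose nearest HRV lies at distance d loses the
  half adjacent to the discordant variant — the ⌈d/2⌉ bases from p toward
  the HRV, inclusive of both ends per the convention fixed here, but
  clipped so the HRV position itself is never removed (this clip matters
  only at d = 1);
- the discordant position p itself is always excised, so no discordant
  variant lies inside the HRR;
- an HRV sharing the discordant position counts as the nearest HRV on both
  sides (only p is then removed).

Excisions from all discordant variants are unioned and subtracted from the
callable regions. Windows are clipped at window boundaries, not snapped to
containing callable intervals, and discordant variants outside the callable
regions still carve where their windows intersect it. The implementation is
interval arithmetic; it is property-tested against a per-base simulation of
the rules above on random instances. Restricting a call set to regions
keeps a variant only when its full REF footprint lies inside a single
interval.

## Metrics

For call sets a (query) and b (baseline), with exact-key matching the
cross-found counts satisfy nᵃ = nᵇ = |a ∩ b|:

- reproducibility R = ½(nᵃ/Nᵃ + nᵇ/Nᵇ);
- pairwise Jaccard J = |a∩b| / |a∪b| (J ≤ R always);
- average Jaccard over a triplicate = mean of the three pairwise terms;
- against a truth set: precision Qᶜ/(Qᶜ+Qᵘ), recall Qᶜ/(Qᶜ+Hᵘ),
  F = 2PR/(P+R), with F = 0 at P = R = 0.

Undefined ratios (empty denominators) propagate as missing values, never as
zeros, so grouped means run over defined cells only. Depth filtering keeps
8 ≤ DP ≤ max inclusive, where max defaults to round(mean + 3·sd) of the
call set's own depths (a per-set statistic; a fixed cutoff can be pinned
instead). Records lacking DP are retained — callers differ in depth
reporting, and dropping them would bias cross-caller comparisons. Metrics
are stratified by variant class (SNV, INS, DEL as headline classes; MNV and
COMPLEX tracked separately), and each pairing (technical, lab, aligner,
caller) is computed with and without HRR restriction to give upper and
lower reproducibility bounds.

## Variance components

The response is one average-Jaccard concordance per (caller, aligner,
platform, sample) cell, replicates already collapsed. The model is a fully
crossed random-effects model with all four main effects, all six 2-way
interactions, and residual:

Y = Zγ + ε, γ ~ N(0, G), ε ~ N(0, σ²Iₙ).

Estimation is balanced-design ANOVA method of moments (Henderson I):
factorial sums of squares by inclusion–exclusion of cell means, expected
mean squares equated to observed ones, the linear system solved exactly,
and negative solutions truncated to zero before proportions are formed.
For balanced designs this coincides in expectation with REML (and is
cross-checked against lme4's REML fit in the test suite); it requires a
complete crossing and at least two levels per factor — inestimable terms
are reported as missing rather than guessed. With one observation per cell
the residual absorbs the 3- and 4-way interactions, which the model assumes
negligible.

A caveat on rankings from small designs: with only a handful of levels per
factor, the *realized* between-level variance of a factor is a heavily
dispersed χ² draw around its component, so single-design rankings of
estimated components are noisy even for an ideal estimator — e.g. six
caller levels at four times the aligner variance still rank below the
aligner in roughly 9% of simulated designs. Mean proportions across many
designs are stable and unbiased within Monte-Carlo tolerance; per-design
ranks are not a reliable readout, and the test suite measures exactly this.

## Synthetic study generator

The generator emulates a replicated WGS study: default conditions are a
monozygotic-twin quartet, 3 labs (platform/library tied 1:1 to lab),
triplicate runs, 3 aligners, 7 callers — one call set per grid cell — on a
2 × 1 Mb two-chromosome genome with 5000 truth sites (80% SNV, 10%
insertions, 10% deletions, indel lengths 1–10 bp, non-overlapping
footprints). Per-site population allele frequencies follow Beta(0.8, 0.8)
(a U-shaped site-frequency spectrum); parents are Hardy–Weinberg draws,
offspring receive one random gamete per parent, twins are copies, so every
truth site is Mendelian-consistent by construction.

Error processes are compositional and independent across factor axes — the
simplest structure that makes the variance decomposition identifiable:
per-caller FN rates 1–7%, per-aligner 1–3%, per-replicate 1% (combined
multiplicatively), genotype errors (het↔hom-alt) at 0.5%, and false
positives drawn per caller from a caller-specific pool (2% of the site
count, each pool FP recurring in a cell with probability 0.9 — a
systematic caller artifact shared across labs/replicates/aligners) plus
rare private FPs (0.2%). Depth is Normal(30, 8) truncated at 1, matching
~30× sequencing. Region files are the genome minus Poisson-placed
exponential gaps (5 gaps/Mb, mean 500 bp), independent across runs;
difficult masks are 20 random intervals of mean 2 kb. Everything is a pure
function of (config, seed): identical configs reproduce identical file
bytes.

What the generator does *not* emulate — and what passing tests therefore do
not establish about real data: sequence-context-dependent error spectra
(homopolymer indel errors, mappability-correlated FPs), correlated errors
between pipelines sharing components, haplotype-representation divergence
in complex regions, coverage-dependent genotype quality, and
sex-chromosome/mosaic inheritance. The generator's role is to verify the
machinery exactly, not to predict real-world reproducibility levels.

## Numerical conventions and degenerate inputs

- Interval sets merge overlapping/adjacent intervals on construction;
  equality is array equality of the merged form.
- Natural chromosome ordering (chr2 < chr10) everywhere; output files are
  deterministically sorted, so reruns are byte-identical.
- Cascade stages raise on configurations that cannot support their rule
  (fewer than 2 replicates; fewer caller sets than `min_callers`); a
  single lab or single aligner passes through rather than failing, matching
  designs where a factor is not varied.
- Empty call sets are legal everywhere; metrics on them are missing, not 0.
- Depth filter bounds are inclusive; `min_dp > max_dp` is a configuration
  error.
- Variance estimation refuses incomplete crossings instead of silently
  using unbalanced formulas.

## Problem sizes used in the test suite

Unit and property tests run on genomes ≤ 10 kb with explicit per-base
oracles (500 random interval instances; exhaustive 27-combination Mendelian
enumeration; 120+ random metric instances). End-to-end cascade checks use
the generator's default 2 × 1 Mb / 5000-site study; determinism and
pipeline tests use a reduced quartet study (120–250 kb, 200–300 sites,
18–54 call sets) — sizes chosen so the whole suite exercises every code
path in about a minute while the default-scale study is still covered.
Variance-component recovery uses 200 simulated 6 × 4 × 2 × 4 designs with
planted components 4 : 1 : 0.25 and residual 0.25 (the residual is this
package's choice; the ranking caveat above applies regardless of it).

## Known limitations

- Exact-key matching undercounts concordance for equivalent complex
  representations; haplotype-aware comparison is out of scope by design.
- The Mendelian engine covers nuclear families (trio, or quartet with one
  monozygotic twin pair) at biallelic autosomal sites only.
- Henderson I assumes balance; real studies with missing cells need a
  REML fit, which this package deliberately does not reimplement.
- The HRR convention choices (which half-interval is removed, mixed-side
  handling, window clipping) follow the definitions above; alternative
  readings of the carving rule would shift HRR boundaries by up to
  ⌈d/2⌉ bases per discordant locus.
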