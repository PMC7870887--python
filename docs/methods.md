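# Methods

## Genotype representation

All stages operate on a samples × sites matrix of alternate-allele dosage
codes (0 hom-ref, 1 het, 2 hom-alt, −1 missing) restricted to biallelic
records; multi-allelic and symbolic VCF records are excluded on read and
tallied.  Positions are 1-based internally (VCF convention); divergence
profiles emit 0-based half-open bins (BED convention).  Indels enter only
the hard filter; every downstream analysis consumes SNP sites.

## Hard filtering

SNPs fail on `QD < 26.0 || FS > 60.0 || MQ < 40.0`, indels on
`QD < 26.0 || FS > 200.0 || MQ < 40.0`, with strict comparisons so
boundary values pass.  A clause whose annotation is absent is treated as
false — a site is never rejected for an unobserved annotation — and such
sites are tallied separately.  The QD lower bound of 26 is far more
aggressive than the conventional 2.0; it is retained as this toolkit's
target convention but is flagged in the API documentation because most
callers' QD distributions would be decimated by it.

## Merging and harmonization

Sites are matched across panels on (chromosome, position) only, because
allele order and strand are the quantities array and sequencing platforms
disagree about.  The second panel's allele pair is then classified as
identical / swapped / strand-flipped / flipped-and-swapped / ambiguous /
incompatible; swap-type sites have codes 0 and 2 exchanged (an involution),
palindromic A/T and C/G pairs are dropped by default (a strand flip is
indistinguishable from a swap there; `keep_ambiguous` retains them), and
incompatible pairs are always dropped.  Retained + dropped equals the raw
positional intersection, a tested identity.  Sample IDs present in both
panels keep the first panel's column and re-enter with a `_b` suffix, so
self-merges act as positive controls.

## Identity verification

Similarity is mean per-site allele sharing `1 − |gᵢ − gⱼ|/2` over
co-called sites; pairs sharing fewer than `min_shared` sites (default 100)
are flagged invalid rather than reported.  The default 100 keeps the
binomial standard error of a similarity near 0.99 under ~1 percentage
point.  Verdict thresholds: `confirm = 0.99`, `floor = 0.90`,
`gap = 0.03`, with the 90–99 % band closed at the bottom and open at the
top and the gap comparison strict (> 0.03).  One verdict cell is not fixed
by the rules above (counterpart exists, gap ≤ 0.03, a different top match,
counterpart similarity < 0.90); it is assigned `DRIFTED`, since such an
accession is still consistent with its counterpart but weakly similar to
everything — the package's own choice, made once.  All internal values are
fractions; reports print fractions (percent only in prose).

## LD decay

r² is the squared Pearson correlation of dosage codes with
pairwise-complete missing handling; on inbred, het-masked data this equals
haplotype r².  Monomorphic-within-the-complete-pairs sites yield no pair
and are tallied.  The decay curve is the Hill–Weir drift expectation
(see README for the formula); its value at C = 0 is ≈ 0.45 + O(1/n) and
its large-C limit is the finite-sample floor 1/n, not zero — the fitted
curve therefore cannot cross baselines at or below 1/n.

Fitting: nonlinear least squares of the expectation against observed r²,
parameterized on log ρ to enforce positivity, initialized at
1/median(distance), tolerances 1e-12, on ~100 log-spaced distance-bin
means by default (robust and fast; `use_bins=False` fits raw pairs and is
what exact self-consistency checks use, since binned means of a curved
function carry a small Jensen bias ~3×10⁻⁴ in ρ).  The decay distance is
found by bracketed bisection over the observed distance range extended
tenfold; a curve that stays on one side of the baseline is reported "not
reached" (NaN), never extrapolated.  Per-chromosome summaries report an
unweighted mean decay distance and the squared Pearson correlation between
chromosome size and decay distance; failed fits become NaN rows excluded
from both, and the correlation is NaN with fewer than two usable
chromosomes.

## Phylogenetics

Alignments code 0 → ref base, 2 → alt base, heterozygotes → IUPAC
ambiguity (or N under `het_policy="missing"`), missing → N.  p-distances
ignore columns where either sequence is N *or* an ambiguity code — the
simplest defensible treatment of residual heterozygosity in inbred
material.  Neighbor joining follows Saitou–Nei exactly: Q-criterion,
ties broken by the smallest index pair in the working order, negative
branch lengths clamped to zero and counted.  NJ is exact on additive
matrices (tested over all 15 labeled 5-taxon topologies) and is used
instead of maximum likelihood deliberately: distance methods are fast and
sufficient for germplasm-relationship overviews, and the alignment is
exported as FASTA so users can run an external ML program when branch
support matters.  Rooting scans every branch for the one minimizing the
number of leaves stranded on the wrong side of a two-group bipartition
(ties → longest branch), splits it at its midpoint, and reports the
residual mixing count rather than failing when the groups are not cleanly
separable.  Site thinning keeps every k-th SNP from a configurable offset
(default 0); an optional invariant-column filter is available because
thinned overlap sets often contain sites monomorphic within the merged
sample.

## Synthetic panels

The generator emulates a resequenced inbred collection with an array
companion: ancestral frequencies Uniform(0.05, 0.95); population
frequencies from the Beta "F-model"
p_k ~ Beta(p(1−d)/d, (1−p)(1−d)/d) with divergence d; per-population
founder haplotype pools drawn site-wise; sample haplotypes built by
copying founders with donor switches at rate ρ per bp (geometric switch
distances); diploids selfed g generations, each halving expected
heterozygosity site-wise independently (linkage during selfing is ignored
— downstream analyses mask heterozygotes, so only the marginal rate
matters); missingness applied uniformly.  The array companion is a random
site subset with 0↔2 genotyping errors, extra missingness, and
representation jitter (ref/alt reversed at 20 % of sites, opposite strand
at 10 %) so harmonization is exercised, not just unit-tested.  Label swaps
exchange the array columns of two accessions from different populations;
duplications clone an array column under a new ID.  All randomness flows
from a single generator seeded by the mandatory `seed`; identical configs
are bit-identical.

Default conditions (40 accessions in 2 populations, divergence 0.3, 6
selfing generations, 8 founders/population, 600 SNPs on 2 chromosomes,
0.5 % genotyping error, 1 % missingness, 4 mislabeled accessions, 2
duplicates) give a missing fraction near 1 %, heterozygosity near 0.4 %,
and merged missing+het near 2 % — the regime of real inbred-crop panel
comparisons.

Two deliberate model facts shape the tests:

* **Founder-pool drift.**  Populations draw separate founder pools, which
  adds ~2pq/F of within-population similarity even at divergence 0;
  exchangeability of populations therefore holds only in the
  large-founder-pool limit, and is tested with F = 64.
* **LD level and shape.**  Drift LD in a founder-copying model plateaus
  near 1/F at short range and decays roughly like exp(−2ρd) — not like
  the Hill–Weir 1/C tail.  Consequently (a) LD-focused configurations use
  F = 2 (one population), since the r² = 0.2 baseline is only crossed
  when 1/F exceeds it, matching the elevated short-range r² of inbred
  crops; and (b) the fitted Hill–Weir ρ is a monotone transform of the
  planted switch rate, not numerically equal to it.  Numeric ρ recovery
  (10⁻⁴ noise-free, 10 % under noise) is asserted on data generated from
  the curve itself; copying-model panels are asserted to give strictly
  decreasing decay distances across ρ ∈ {10⁻⁶, 10⁻⁵, 10⁻⁴}.

What passing tests show about real data, and what they do not: the suite
demonstrates correctness of the statistics (against brute-force oracles
and hand-computed fixtures) and recovery of planted structure under the
generator's assumptions — unstructured missingness, site-independent
error, clean biallelic sites, no batch effects, no allele-frequency
ascertainment bias in the array subset.  Real array content is ascertained
(biased toward common, high-LD-informative SNPs), which shifts similarity
baselines; the verification thresholds are exposed as parameters for that
reason.

## Pipeline

`germpanel run` executes simulate-or-load → filter → merge → verify → LD →
phylogeny → divergence with a strict (unknown-key-rejecting) YAML schema,
stderr logging, and a JSON manifest recording config hash, input
checksums, per-stage counts, version and seed.  Outputs are byte-identical
across reruns of the same config; only the manifest timestamp differs.

## Problem sizes

Tests and the acceptance script run on panels of 16–80 samples and
120–800 sites per chromosome, with five replicate studies for
verification metrics and three-seed grids for fits — sizes at which every
statistic is exact or its sampling error is far inside the asserted
tolerances, chosen as the package's desk-scale reference conditions.

## Known limitations

* No imputation, no liftover: both panels must share one assembly.
* No coalescent ancestry, selection or domestication sweeps in the
  generator; LD comes from a single-parameter copying process.
* NJ only, in-package; no bootstrap support values.
* Similarity is IBS, not kinship: it does not correct for allele
  frequencies and is not an ancestry estimator.
* The divergence module counts differences; it performs no statistical
  test for introgression.
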