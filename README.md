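# germpanel

Toolkit for quality control and population-genomic summaries of crop
germplasm genotype panels, built for the common situation where the same
accessions have been genotyped twice — densely by whole-genome
resequencing and sparsely by a fixed-content SNP array — and the two call
sets must be reconciled, cross-validated and summarized.

It is aimed at curators of germplasm collections and population
geneticists who need to answer, reproducibly:

* **Is each seed lot what its label says?**  Merge the two panels on
  common positions (harmonizing ref/alt orientation and strand), mask
  residual heterozygous calls, compute identity-by-state (IBS)
  similarity, and classify every accession against its expected
  counterpart.
* **How fast does linkage disequilibrium decay?**  Pairwise r² within
  chromosomes, fitted with the Hill–Weir drift expectation, reported as
  the distance at which expected r² falls to a baseline (0.2).
* **How do the accessions relate?**  Thinned concatenated-SNP alignments,
  p-distances, neighbor-joining trees rooted between species groups,
  leaf labels tagged with country of origin (FASTA export for external
  maximum-likelihood programs).
* **Where do genomes differ?**  Binned SNP-difference profiles against a
  chosen reference accession, the computation behind genome-wide
  difference heatmaps.

A fully seeded synthetic-panel generator (structured inbred populations,
distance-decaying LD, an array-style subset with genotyping error, planted
label swaps and duplicated seed lots) provides ground truth for every
stage, so the whole pipeline is testable end to end without external data.

## The statistics at the core

**IBS similarity.** For samples *i, j* with dosage codes
*g ∈ {0, 1, 2}* at co-called sites, similarity is the mean of
*1 − |gᵢ − gⱼ| / 2*.  With heterozygotes masked (standard for inbred
material) this is the simple matching fraction of homozygous calls.
Verification verdicts follow fixed thresholds: top match = expected
counterpart at ≥ 99 % similarity → `CONFIRMED`; 90–99 % → `DRIFTED`
(seed lots grown apart); a different top match within a 3-point gap →
`REDUNDANT_CONSISTENT`; a gap > 3 points → `MIS_ASSIGNED` (probable
tracking error); accessions without a counterpart are `UNIQUE` below 90 %
similarity to everything.

**LD decay.** r² is the squared Pearson correlation of dosage codes on
pairwise-complete observations.  The fitted curve is the Hill–Weir
expectation at population-scaled recombination *C = ρ·d* for sample size
*n*:

    E[r²] = (10 + C) / ((2 + C)(11 + C)) ·
            [1 + ((3 + C)(12 + 12C + C²)) / (n (2 + C)(11 + C))]

*ρ* is estimated by nonlinear least squares on distance-binned means; the
decay distance solves E[r²] = 0.2.  Note E[r²] → 1/n for large *C* (the
finite-sample noise floor), not 0.

**Trees.** Uncorrected p-distances over comparable alignment columns;
classic Saitou–Nei neighbor joining with deterministic tie-breaking;
rooting on the branch that best bipartitions two leaf groups (residual
"mixing count" reported).

## Worked example

`python examples/01_verify_accessions.py` simulates 40 inbred accessions
on two platforms with four label-swapped accessions and two duplicated
lots, then verifies every accession:

```
dense panel : 40 accessions x 600 SNPs
array panel : 42 accessions x 300 SNPs
merged      : 300 common positions, 196 retained after harmonization (55 allele-swapped, 104 ambiguous dropped)

verdict counts:
  CONFIRMED              27
  DRIFTED                9
  REDUNDANT_CONSISTENT   0
  MIS_ASSIGNED           4
  UNIQUE                 0
  NO_EXPECTED            0

flagged as mis-assigned (expected vs observed best match):
  PI600005: expected PI600005_b at 0.603, top match PI600026_b at 1.000 (gap 0.397)
  PI600018: expected PI600018_b at 0.613, top match PI600028_b at 1.000 (gap 0.387)
  PI600026: expected PI600026_b at 0.611, top match PI600005_b at 0.995 (gap 0.383)
  PI600028: expected PI600028_b at 0.610, top match PI600018_b at 0.995 (gap 0.385)

planted label swaps were: [('PI600026', 'PI600005'), ('PI600018', 'PI600028')]
```

The four flagged accessions are exactly the four planted swaps: each one's
best genotype match is the accession it was swapped with (similarity ≈ 1),
while its own label matches at only ~0.61 — a gap far beyond the 3-point
threshold.  The `_b` suffix marks the array copy of a sample ID present in
both panels.  Other examples cover LD decay (`02`), tree building (`03`)
and divergence profiling (`04`); the `germpanel` command exposes the same
stages as shell subcommands (`simulate`, `filter`, `stats`, `merge`,
`verify`, `ld`, `phylo`, `divergence`, `run`).

## Layout

```
src/germpanel/   panel containers, VCF I/O + hard filter, harmonization,
                 identity, LD decay, SNP phylogenetics, divergence,
                 synthetic generator, pipeline, CLI
examples/        narrative scripts, one per capability
tests/           pytest suite (unit, property and acceptance tests)
docs/methods.md  models, assumptions, parameter choices, limitations
```
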