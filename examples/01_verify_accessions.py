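"""Verify accession identity across two genotyping platforms.

Simulates a small germplasm study — a dense resequencing-style panel and a
sparse array-style companion with two planted label swaps (4 accessions)
and two duplicated seed lots — then merges the panels on common positions,
masks heterozygotes, computes identity-by-state similarity, and classifies
every accession against its expected counterpart.
"""

from germpanel import harmonize, identity
from germpanel.synthetic import SimConfig, simulate_study

study = simulate_study(SimConfig(seed=1))
print(f"dense panel : {study.seq.n_samples} accessions x {study.seq.n_sites} SNPs")
print(f"array panel : {study.array.n_samples} accessions x {study.array.n_sites} SNPs")

merged = harmonize.merge_panels(study.seq, study.array)
print(
    f"merged      : {merged.n_common_sites} common positions, "
    f"{merged.panel.n_sites} retained after harmonization "
    f"({merged.n_allele_swapped} allele-swapped, "
    f"{merged.n_dropped_strand_ambiguous} ambiguous dropped)"
)

masked = harmonize.mask_hets(merged.panel)
simmat = identity.ibs_similarity(masked)
references = [merged.rename_map.get(s, s) for s in study.array.samples]
expected = {q: merged.rename_map.get(q, q) for q in study.seq.samples}
report = identity.classify_accessions(
    simmat, expected, queries=study.seq.samples, references=references
)

print("\nverdict counts:")
for verdict, count in identity.verdict_counts(report).items():
    print(f"  {verdict:22s} {count}")

print("\nflagged as mis-assigned (expected vs observed best match):")
for row in report[report["verdict"] == "MIS_ASSIGNED"].itertuples():
    print(
        f"  {row.query}: expected {row.expected} at {row.expected_sim:.3f}, "
        f"top match {row.top_match} at {row.top_sim:.3f} (gap {row.gap:.3f})"
    )
print("\nplanted label swaps were:", study.truth.mislabels)
print(
    "A mis-assigned accession is one whose best genotype match beats its\n"
    "expected counterpart by more than 3 percentage points of similarity —\n"
    "the signature of a seed-source or tracking error."
)
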