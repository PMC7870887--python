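"""Build a neighbor-joining tree from a concatenated SNP alignment.

Simulates two diverged populations (cultivated vs wild species stand-ins),
thins the SNP set, writes each accession as a one-character-per-SNP
sequence, computes p-distances, builds the NJ tree, roots it on the branch
separating the two species, and tags leaf labels with country of origin.
"""

from germpanel import snp_phylo
from germpanel.synthetic import SimConfig, simulate_panel

cfg = SimConfig(
    seed=1, n_pops=2, n_per_pop=6, n_chrom=1, chrom_len_bp=500_000,
    n_sites_per_chrom=300, divergence=0.5, n_mislabels=0, n_duplicates=0,
    missing_rate=0.0,
)
panel, truth = simulate_panel(cfg)

thinned = snp_phylo.thin_sites(panel, step=5)
aln = snp_phylo.panel_to_alignment(thinned)
print(f"alignment: {len(aln.labels)} sequences x {aln.length} SNP columns")

D, _ = snp_phylo.p_distance_matrix(aln)
tree = snp_phylo.nj_tree(D, aln.labels)
rooted = snp_phylo.root_between_groups(tree, truth.species_map())
print(f"root placed between species groups; mixing count = {rooted.mixing_count}")

tagged, _ = snp_phylo.label_with_origin(rooted.tree, truth.metadata_frame())
print("\nrooted, origin-tagged tree (newick):")
print(tagged.as_string(schema="newick").strip())
print(
    "\nA mixing count of 0 means one branch cleanly bipartitions the two\n"
    "species — the expected picture for a wild progenitor vs its crop."
)
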