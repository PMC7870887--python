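"""SNP-alignment phylogenetics: thinning, alignment, distances, NJ, rooting.

A genotype panel is turned into a concatenated one-character-per-SNP
alignment (ref base for code 0, alt base for 2, IUPAC ambiguity or N for
heterozygotes, N for missing), distances are uncorrected p-distances over
comparable columns, and the tree is built by neighbor joining.

Tree inference here is deliberately distance-based: NJ is fast, exact on
additive distances, and adequate for germplasm-relationship overviews.
For publication-grade trees export the alignment with
:meth:`SNPAlignment.to_fasta` and run a maximum-likelihood program (e.g.
FastTree) externally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .panel import GenotypePanel

IUPAC_AMBIGUITY = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
}

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def thin_sites(panel: GenotypePanel, step: int = 5, offset: int = 0) -> GenotypePanel:
    """Keep every ``step``-th site in genomic order, starting at ``offset``."""
    if step < 1:
        raise ValueError("step must be >= 1")
    if not 0 <= offset:
        raise ValueError("offset must be >= 0")
    return panel.take_sites(range(offset, panel.n_sites, step))


def drop_invariant_sites(panel: GenotypePanel) -> GenotypePanel:
    """Remove sites with no genotype variation among non-missing calls."""
    keep = []
    for j in range(panel.n_sites):
        col = panel.geno[:, j]
        called = col[col >= 0]
        if called.size and np.unique(called).size > 1:
            keep.append(j)
    return panel.take_sites(keep)


@dataclass
class SNPAlignment:
    """Equal-length concatenated SNP sequences, one per sample."""

    labels: list[str]
    seqs: list[str]

    def __post_init__(self):
        if len(self.labels) != len(self.seqs):
            raise ValueError("one sequence per label required")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for label, seq in zip(self.labels, self.seqs):
                fh.write(f">{label}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

    @classmethod
    def from_fasta(cls, path) -> "SNPAlignment":
        labels, seqs, cur = [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip()
                if line.startswith(">"):
                    if labels:
                        seqs.append("".join(cur))
                    labels.append(line[1:].split()[0] if len(line) > 1 else "")
                    cur = []
                elif line:
                    cur.append(line)
        if labels:
            seqs.append("".join(cur))
        return cls(labels=labels, seqs=seqs)


def panel_to_alignment(panel: GenotypePanel, het_policy: str = "iupac") -> SNPAlignment:
    """Emit one alignment column per site (code 0 -> ref, 2 -> alt, -1 -> N).

    ``het_policy="iupac"`` writes the two-base ambiguity code for
    heterozygotes; ``"missing"`` writes N.
    """
    if het_policy not in ("iupac", "missing"):
        raise ValueError("het_policy must be 'iupac' or 'missing'")
    for s in panel.sites:
        if len(s.ref) != 1 or len(s.alt) != 1:
            raise ValueError(f"site {s.chrom}:{s.pos} is not a single-base SNP")

    n, m = panel.n_samples, panel.n_sites
    chars = np.full((n, m), "N", dtype="<U1")
    refs = np.array([s.ref for s in panel.sites])
    alts = np.array([s.alt for s in panel.sites])
    hets = np.array(
        [
            IUPAC_AMBIGUITY.get(frozenset((s.ref, s.alt)), "N")
            if het_policy == "iupac"
            else "N"
            for s in panel.sites
        ]
    )
    G = panel.geno
    for j in range(m):
        col = chars[:, j]
        col[G[:, j] == 0] = refs[j]
        col[G[:, j] == 2] = alts[j]
        col[G[:, j] == 1] = hets[j]
    seqs = ["".join(row) for row in chars]
    return SNPAlignment(labels=list(panel.samples), seqs=seqs)


def p_distance_matrix(aln: SNPAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise p-distances: mismatches / comparable columns.

    Columns where either sequence is N or an ambiguity code are excluded.
    Returns ``(D, n_comparable)``; a pair with zero comparable columns gets
    distance NaN (flagged, not fabricated).
    """
    if len(aln.seqs) < 3:
        raise ValueError("need at least 3 sequences for a distance matrix")
    n = len(aln.seqs)
    enc = np.full((n, aln.length), -1, dtype=np.int8)
    for i, seq in enumerate(aln.seqs):
        for j, ch in enumerate(seq.upper()):
            enc[i, j] = _BASE_CODE.get(ch, -1)
    valid = enc >= 0
    D = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        nc = both.sum(axis=1)
        diff = ((enc[i] != enc[i + 1 :]) & both).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(nc > 0, diff / np.maximum(nc, 1), np.nan)
        D[i, i + 1 :] = d
        D[i + 1 :, i] = d
        comp[i, i + 1 :] = nc
        comp[i + 1 :, i] = nc
        comp[i, i] = int(valid[i].sum())
    return D, comp


# ----------------------------------------------------------------------
# neighbor joining
# ----------------------------------------------------------------------

def nj_tree(dist: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Classic neighbor joining (Saitou-Nei Q criterion).

    Deterministic: ties in Q are broken by the smallest (i, j) index pair
    in the current working order; negative branch lengths are clamped to
    zero and counted on the returned tree as
    ``tree.negative_branches_clamped``.  The result is unrooted (final
    trifurcation at the seed node).
    """
    D0 = np.asarray(dist, dtype=np.float64)
    n = len(labels)
    if D0.shape != (n, n):
        raise ValueError("distance matrix does not match labels")
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if not np.allclose(D0, D0.T, equal_nan=True):
        raise ValueError("distance matrix must be symmetric")
    if np.isnan(D0).any():
        raise ValueError("distance matrix contains undefined (NaN) entries")
    if (D0 < 0).any():
        raise ValueError("distances must be non-negative")

    tns = dendropy.TaxonNamespace(labels)
    nodes: list[dendropy.Node] = [
        dendropy.Node(taxon=tns.get_taxon(lab)) for lab in labels
    ]
    size = 2 * n
    D = np.zeros((size, size))
    D[:n, :n] = D0
    active = list(range(n))
    clamped = 0

    def clamp(v: float) -> float:
        nonlocal clamped
        if v < 0:
            clamped += 1
            return 0.0
        return v

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # row-major argmin realizes the smallest-(i, j) tie-break
        i, j = divmod(int(np.argmin(Q)), m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        vi = clamp(0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2)))
        vj = clamp(dij - (0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))))
        parent = dendropy.Node()
        ni, nj_ = nodes[active[i]], nodes[active[j]]
        parent.add_child(ni)
        parent.add_child(nj_)
        ni.edge.length = vi
        nj_.edge.length = vj
        new = len(nodes)
        nodes.append(parent)
        for k in active:
            if k == active[i] or k == active[j]:
                continue
            duk = 0.5 * (D[active[i], k] + D[active[j], k] - dij)
            D[new, k] = D[k, new] = duk
        active = [k for k in active if k not in (active[i], active[j])] + [new]

    root = dendropy.Node()
    if len(active) == 3:
        a, b, c = active
        va = 0.5 * (D[a, b] + D[a, c] - D[b, c])
        vb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
        vc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
        for k, v in zip((a, b, c), (va, vb, vc)):
            root.add_child(nodes[k])
            nodes[k].edge.length = clamp(v)
    elif len(active) == 2:
        a, b = active
        half = D[a, b] / 2.0
        for k in (a, b):
            root.add_child(nodes[k])
            nodes[k].edge.length = clamp(half)
    else:  # single taxon
        root.add_child(nodes[active[0]])
        nodes[active[0]].edge.length = 0.0

    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    tree.negative_branches_clamped = clamped
    return tree


@dataclass
class RootingResult:
    tree: dendropy.Tree
    mixing_count: int
    edge_length: float


def root_between_groups(
    tree: dendropy.Tree, group_map: dict[str, str]
) -> RootingResult:
    """Root the tree on the branch that best bipartitions two leaf groups.

    ``group_map`` assigns each leaf label to one of exactly two groups
    (unmapped leaves do not constrain the choice).  The chosen branch
    minimizes the number of leaves on the "wrong" side; ties go to the
    longest branch.  The residual mixing count (0 when the groups are
    cleanly separable) is reported alongside the rooted clone.
    """
    groups = sorted({g for g in group_map.values() if g is not None})
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    ga, gb = groups
    work = tree.clone(depth=1)
    leaves = [lf for lf in work.leaf_node_iter()]
    labels = {lf: lf.taxon.label for lf in leaves}
    set_a = {lf for lf in leaves if group_map.get(labels[lf]) == ga}
    set_b = {lf for lf in leaves if group_map.get(labels[lf]) == gb}
    if not set_a or not set_b:
        raise ValueError("both groups must be present among the leaves")

    best = None  # (mixing, -length, edge)
    for node in work.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = set(node.leaf_iter())
        a_below = len(set_a & below)
        b_below = len(set_b & below)
        mixing = min(
            (len(set_a) - a_below) + b_below,   # A above / B below
            a_below + (len(set_b) - b_below),   # A below / B above
        )
        length = node.edge.length or 0.0
        key = (mixing, -length)
        if best is None or key < best[0]:
            best = (key, node.edge)
    (mixing, neg_len), edge = best
    length = -neg_len
    work.reroot_at_edge(
        edge,
        length1=length / 2.0,
        length2=length / 2.0,
        update_bipartitions=False,
    )
    work.is_rooted = True
    return RootingResult(tree=work, mixing_count=int(mixing), edge_length=length)


# ----------------------------------------------------------------------
# origin tags
# ----------------------------------------------------------------------

def load_metadata(path) -> pd.DataFrame:
    """Read a sample metadata TSV with columns sample_id, species, country."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise ValueError("metadata must have a 'sample_id' column")
    return meta


def _country_lookup(metadata) -> dict[str, str]:
    if isinstance(metadata, pd.DataFrame):
        col = "country" if "country" in metadata.columns else None
        if col is None:
            raise ValueError("metadata frame lacks a 'country' column")
        return dict(zip(metadata["sample_id"], metadata[col]))
    return dict(metadata)


def label_with_origin(obj, metadata):
    """Append ``|<country>`` tags to sample labels (missing entries tag NA).

    Works on an :class:`SNPAlignment` or a dendropy Tree (cloned, not
    mutated).  Returns ``(tagged_object, mapping)`` where ``mapping`` sends
    each new label back to the original ID, for :func:`unlabel`.
    """
    lookup = _country_lookup(metadata)

    def tag(label: str) -> str:
        country = lookup.get(label) or "NA"
        return f"{label}|{country}"

    if isinstance(obj, SNPAlignment):
        new_labels = [tag(l) for l in obj.labels]
        mapping = dict(zip(new_labels, obj.labels))
        return SNPAlignment(labels=new_labels, seqs=list(obj.seqs)), mapping
    if isinstance(obj, dendropy.Tree):
        work, mapping = _relabel_tree(obj, tag)
        return work, mapping
    raise TypeError(f"cannot tag object of type {type(obj).__name__}")


def _relabel_tree(tree: dendropy.Tree, rename):
    # depth-1 clones share the taxon namespace with the source tree, so give
    # the clone fresh Taxon objects before touching any label
    work = tree.clone(depth=1)
    new_tns = dendropy.TaxonNamespace()
    mapping: dict[str, str] = {}
    for leaf in work.leaf_node_iter():
        old = leaf.taxon.label
        new = rename(old)
        mapping[new] = old
        leaf.taxon = dendropy.Taxon(label=new)
        new_tns.add_taxon(leaf.taxon)
    work.taxon_namespace = new_tns
    return work, mapping


def unlabel(obj, mapping: dict[str, str]):
    """Invert :func:`label_with_origin` using its stored mapping."""
    if isinstance(obj, SNPAlignment):
        return SNPAlignment(
            labels=[mapping.get(l, l) for l in obj.labels], seqs=list(obj.seqs)
        )
    if isinstance(obj, dendropy.Tree):
        work, _ = _relabel_tree(obj, lambda l: mapping.get(l, l))
        return work
    raise TypeError(f"cannot untag object of type {type(obj).__name__}")
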