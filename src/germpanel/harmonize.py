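"""Merge two genotype panels on shared variant positions.

Array-derived and sequencing-derived call sets frequently disagree on
allele orientation: the same site may be reported with ref/alt reversed,
on the opposite strand, or both.  Sites are therefore matched on
(chromosome, position) only, and the allele pair of the second panel is
classified against the first:

``identical``
    same ref/alt — genotypes taken as-is.
``swapped``
    ref/alt reversed — dosage codes 0 and 2 are exchanged.
``flipped``
    opposite strand (complemented alleles) — codes as-is.
``flipped_swapped``
    complemented and reversed — codes exchanged.
``ambiguous``
    A/T or C/G pairs, where a strand flip is indistinguishable from a
    swap; dropped by default.
``incompatible``
    allele sets that cannot be reconciled; always dropped.

Heterozygote masking (1 -> -1) is provided here because identity-by-state
comparison of highly inbred material treats residual heterozygous calls as
noise and removes them before any similarity is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import GenotypePanel, SiteRecord

IDENTICAL = "identical"
SWAPPED = "swapped"
FLIPPED = "flipped"
FLIPPED_SWAPPED = "flipped_swapped"
AMBIGUOUS = "ambiguous"
INCOMPATIBLE = "incompatible"

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})


class MergeError(RuntimeError):
    """Raised when two panels share no usable sites."""


def classify_alleles(ref_a: str, alt_a: str, ref_b: str, alt_b: str) -> str:
    """Classify allele compatibility of one positional match (see module doc)."""
    a = (ref_a.upper(), alt_a.upper())
    b = (ref_b.upper(), alt_b.upper())
    try:
        comp = (_COMPLEMENT[a[0]], _COMPLEMENT[a[1]])
    except KeyError:
        comp = None
    if b == a:
        cls = IDENTICAL
    elif b == a[::-1]:
        cls = SWAPPED
    elif comp is not None and b == comp:
        cls = FLIPPED
    elif comp is not None and b == comp[::-1]:
        cls = FLIPPED_SWAPPED
    else:
        return INCOMPATIBLE
    if set(a) in _AMBIGUOUS_PAIRS:
        return AMBIGUOUS
    return cls


@dataclass(frozen=True)
class MatchedSite:
    idx_a: int
    idx_b: int
    compatibility: str


def intersect_sites(a: GenotypePanel, b: GenotypePanel) -> list[MatchedSite]:
    """Pair sites of two panels on (chrom, pos) and classify allele compatibility."""
    index_b = {s.key: j for j, s in enumerate(b.sites)}
    matches: list[MatchedSite] = []
    for i, site in enumerate(a.sites):
        j = index_b.get(site.key)
        if j is None:
            continue
        other = b.sites[j]
        matches.append(
            MatchedSite(i, j, classify_alleles(site.ref, site.alt, other.ref, other.alt))
        )
    return matches


_KEEP_ASIS = (IDENTICAL, FLIPPED)
_KEEP_SWAP = (SWAPPED, FLIPPED_SWAPPED)


def harmonize_genotypes(
    matches: list[MatchedSite],
    b: GenotypePanel,
    keep_ambiguous: bool = False,
) -> tuple[list[MatchedSite], np.ndarray, dict[str, int]]:
    """Orient panel-b genotype columns onto panel-a's allele frame.

    Returns the retained matches, the adjusted (samples_b x kept sites)
    genotype block, and a tally of dropped sites by reason.  Swap-type
    sites have codes 0 and 2 exchanged (an involution); heterozygous and
    missing codes are orientation-free and pass through.
    """
    kept: list[MatchedSite] = []
    cols: list[np.ndarray] = []
    dropped = {AMBIGUOUS: 0, INCOMPATIBLE: 0}
    for m in matches:
        col = b.geno[:, m.idx_b].copy()
        if m.compatibility in _KEEP_ASIS:
            pass
        elif m.compatibility in _KEEP_SWAP:
            col = swap_codes(col)
        elif m.compatibility == AMBIGUOUS:
            if not keep_ambiguous:
                dropped[AMBIGUOUS] += 1
                continue
        else:  # incompatible
            dropped[INCOMPATIBLE] += 1
            continue
        kept.append(m)
        cols.append(col)
    block = (
        np.stack(cols, axis=1) if cols else np.empty((b.n_samples, 0), dtype=np.int8)
    )
    return kept, block, dropped


def swap_codes(column: np.ndarray) -> np.ndarray:
    """Exchange codes 0 <-> 2 (ref/alt reversal); 1 and -1 unchanged."""
    out = column.copy()
    out[column == 0] = 2
    out[column == 2] = 0
    return out


def mask_hets(panel: GenotypePanel) -> GenotypePanel:
    """Recode every heterozygous call (1) as missing (-1); idempotent."""
    geno = panel.geno.copy()
    geno[geno == 1] = -1
    return GenotypePanel(samples=list(panel.samples), sites=list(panel.sites), geno=geno)


@dataclass
class MergeResult:
    """Union-of-samples panel over the intersected, harmonized sites."""

    panel: GenotypePanel
    n_common_sites: int
    n_allele_swapped: int
    n_dropped_strand_ambiguous: int
    n_dropped_incompatible: int
    missing_het_fraction: float
    rename_map: dict[str, str] = field(default_factory=dict)

    def report_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "n_common_sites": self.n_common_sites,
                    "n_allele_swapped": self.n_allele_swapped,
                    "n_dropped_strand_ambiguous": self.n_dropped_strand_ambiguous,
                    "n_dropped_incompatible": self.n_dropped_incompatible,
                    "missing_het_fraction": self.missing_het_fraction,
                }
            ]
        )


def merge_panels(
    a: GenotypePanel,
    b: GenotypePanel,
    mask_heterozygotes: bool = False,
    keep_ambiguous: bool = False,
    suffix: str = "_b",
) -> MergeResult:
    """Merge two panels on common positions with allele harmonization.

    Samples from both panels are column-bound over the intersected sites
    (site metadata from panel ``a``).  Sample IDs occurring in both panels
    keep panel ``a``'s column unchanged; panel ``b``'s column is retained
    under ``<id><suffix>`` and recorded in ``rename_map`` — self-merges
    thus serve as positive controls downstream.  ``missing_het_fraction``
    is measured on the merged matrix *before* any het masking.
    """
    matches = intersect_sites(a, b)
    if not matches:
        raise MergeError(
            "panels share no (chrom, pos) positions; check that both use the "
            "same reference assembly and chromosome naming"
        )
    kept, block_b, dropped = harmonize_genotypes(matches, b, keep_ambiguous=keep_ambiguous)
    if not kept:
        raise MergeError(
            f"all {len(matches)} common positions dropped "
            f"(ambiguous: {dropped[AMBIGUOUS]}, incompatible: {dropped[INCOMPATIBLE]})"
        )

    idx_a = [m.idx_a for m in kept]
    sites = [a.sites[i] for i in idx_a]
    block_a = a.geno[:, idx_a]

    rename: dict[str, str] = {}
    taken = set(a.samples)
    names_b: list[str] = []
    for sid in b.samples:
        new = sid
        while new in taken:
            new = new + suffix
        if new != sid:
            rename[sid] = new
        taken.add(new)
        names_b.append(new)

    geno = np.concatenate([block_a, block_b], axis=0)
    panel = GenotypePanel(samples=list(a.samples) + names_b, sites=sites, geno=geno)

    n_swapped = sum(1 for m in kept if m.compatibility in _KEEP_SWAP)
    mh = float(((geno == -1) | (geno == 1)).mean()) if geno.size else 0.0
    if mask_heterozygotes:
        panel = mask_hets(panel)
    return MergeResult(
        panel=panel,
        n_common_sites=len(matches),
        n_allele_swapped=n_swapped,
        n_dropped_strand_ambiguous=dropped[AMBIGUOUS],
        n_dropped_incompatible=dropped[INCOMPATIBLE],
        missing_het_fraction=mh,
        rename_map=rename,
    )
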