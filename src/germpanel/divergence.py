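"""Binned genotype-difference profiles against a reference accession.

For each query accession, chromosomes are tiled into fixed-size bins
(0-based, half-open multiples of ``bin_size`` from coordinate 0) and each
bin records how many co-called homozygous sites the query shares with the
reference (``n_compared``) and how many of those disagree (``n_diff``).
These raw counts are the quantity behind genome-wide difference heatmaps;
normalization (``n_diff / n_compared``) is left to consumers so the
output stays lossless.

Heterozygous calls are excluded by default (``het_policy="exclude"``);
``het_policy="count"`` keeps them and counts any code mismatch as a
difference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel import GenotypePanel

DEFAULT_BIN_SIZE = 500_000

_COLUMNS = ["chrom", "start", "end", "query", "n_compared", "n_diff"]


def binned_differences(
    panel: GenotypePanel,
    ref_id: str,
    query_ids: list[str] | None = None,
    bin_size: int = DEFAULT_BIN_SIZE,
    chrom_sizes: dict[str, int] | None = None,
    het_policy: str = "exclude",
) -> pd.DataFrame:
    """Per-bin difference counts of each query against ``ref_id``.

    Bins tile every chromosome from 0 to the chromosome size (given in
    ``chrom_sizes``, else the last site position), and empty bins are
    emitted with zero counts, so ``sum(n_diff)`` over bins equals the
    genome-wide pairwise difference count.  The profile is symmetric under
    exchanging reference and query.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if het_policy not in ("exclude", "count"):
        raise ValueError("het_policy must be 'exclude' or 'count'")
    ref_idx = panel.sample_index(ref_id)  # KeyError -> fatal, per contract
    if query_ids is None:
        query_ids = [s for s in panel.samples if s != ref_id]
    q_idx = [panel.sample_index(q) for q in query_ids]

    rows: list[dict] = []
    for chrom in panel.chroms:
        site_idx = np.array(
            [j for j, s in enumerate(panel.sites) if s.chrom == chrom], dtype=int
        )
        pos = np.array([panel.sites[j].pos for j in site_idx], dtype=np.int64)
        length = (
            int(chrom_sizes[chrom]) if chrom_sizes and chrom in chrom_sizes
            else int(pos.max())
        )
        n_bins = max(1, -(-length // bin_size))  # ceil
        which = (pos - 1) // bin_size  # 1-based position -> 0-based bin
        g_ref = panel.geno[ref_idx, site_idx]
        for q, qi in zip(query_ids, q_idx):
            g_q = panel.geno[qi, site_idx]
            if het_policy == "exclude":
                usable = ((g_ref == 0) | (g_ref == 2)) & ((g_q == 0) | (g_q == 2))
            else:
                usable = (g_ref >= 0) & (g_q >= 0)
            differs = usable & (g_ref != g_q)
            n_comp = np.bincount(which[usable], minlength=n_bins)
            n_diff = np.bincount(which[differs], minlength=n_bins)
            for b in range(n_bins):
                rows.append(
                    {
                        "chrom": chrom,
                        "start": b * bin_size,
                        "end": (b + 1) * bin_size,
                        "query": q,
                        "n_compared": int(n_comp[b]),
                        "n_diff": int(n_diff[b]),
                    }
                )
    out = pd.DataFrame(rows, columns=_COLUMNS)
    out.attrs["reference"] = ref_id
    out.attrs["bin_size"] = bin_size
    return out


def write_bed(profiles: pd.DataFrame, path) -> None:
    """Write profiles as BED-like TSV (chrom, start, end, query, n_compared, n_diff)."""
    profiles.to_csv(path, sep="\t", index=False, header=True)
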