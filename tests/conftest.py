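"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive each statistic with plain Python
loops (or textbook formulas) so the vectorized implementations are checked
against code that shares nothing with them.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from germpanel.panel import GenotypePanel, SiteRecord

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# ----------------------------------------------------------------------
# panel builders
# ----------------------------------------------------------------------

def make_panel(geno, chrom="Gm01", positions=None, samples=None, ref="A", alt="G"):
    """Build a single-chromosome panel from a genotype matrix."""
    geno = np.asarray(geno, dtype=np.int8)
    n, m = geno.shape
    if positions is None:
        positions = [100 * (j + 1) for j in range(m)]
    if samples is None:
        samples = [f"S{i + 1}" for i in range(n)]
    sites = [
        SiteRecord(chrom=chrom, pos=int(p), ref=ref, alt=alt) for p in positions
    ]
    return GenotypePanel(samples=list(samples), sites=sites, geno=geno)


def random_panel(rng, n_samples, n_sites, p_missing=0.1, p_het=0.15, chrom="Gm01"):
    """Random panel with all four genotype codes present in realistic mix."""
    codes = rng.choice(
        [-1, 0, 1, 2],
        size=(n_samples, n_sites),
        p=[p_missing, (1 - p_missing - p_het) / 2, p_het, (1 - p_missing - p_het) / 2],
    )
    positions = np.sort(rng.choice(10_000_000, size=n_sites, replace=False)) + 1
    return make_panel(codes, chrom=chrom, positions=positions)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


# ----------------------------------------------------------------------
# oracles
# ----------------------------------------------------------------------

def brute_ibs(geno):
    """Site-by-site double-loop identity-by-state oracle."""
    geno = np.asarray(geno)
    n = geno.shape[0]
    sim = np.full((n, n), np.nan)
    shared = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            total, count = 0.0, 0
            for k in range(geno.shape[1]):
                gi, gj = geno[i, k], geno[j, k]
                if gi >= 0 and gj >= 0:
                    count += 1
                    total += 1.0 - abs(int(gi) - int(gj)) / 2.0
            shared[i, j] = count
            if count:
                sim[i, j] = total / count
    return sim, shared


def brute_r2(x, y):
    """Pairwise-complete squared Pearson correlation, or None if undefined."""
    pairs = [(a, b) for a, b in zip(x, y) if a >= 0 and b >= 0]
    if len(pairs) < 2:
        return None
    xs = np.array([a for a, _ in pairs], dtype=float)
    ys = np.array([b for _, b in pairs], dtype=float)
    if np.var(xs) == 0 or np.var(ys) == 0:
        return None
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def brute_p_distance(seq_a, seq_b):
    """Column-loop p-distance oracle; ACGT-only columns are comparable."""
    diff, comp = 0, 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a in "ACGT" and b in "ACGT":
            comp += 1
            diff += a != b
    return (diff / comp if comp else None), comp


# ----------------------------------------------------------------------
# VCF text fixture
# ----------------------------------------------------------------------

def write_vcf_text(path, records, samples=("S1",)):
    """Write a minimal VCF from (chrom, pos, ref, alt, info, gts) tuples."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=QD,Number=1,Type=Float,Description="qd">',
        '##INFO=<ID=FS,Number=1,Type=Float,Description="fs">',
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="mq">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for chrom, pos, ref, alt, info, gts in records:
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t{info}\tGT\t" + "\t".join(gts)
        )
    path = str(path)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path
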