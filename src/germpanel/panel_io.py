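"""VCF input/output, SNP ID assignment, hard filtering and call-rate stats.

Reading goes through cyvcf2 (htslib); only biallelic, non-symbolic records
enter the panel — everything else is skipped and tallied.  Writing emits a
minimal GT-only VCF so a panel round-trips losslessly.

The hard filter evaluates the standard short-read expressions

* SNPs:   fail iff  QD < 26.0  or  FS > 60.0   or  MQ < 40.0
* indels: fail iff  QD < 26.0  or  FS > 200.0  or  MQ < 40.0

with strict comparisons, so boundary values (QD = 26.0, FS = 60.0,
MQ = 40.0) pass.  A clause whose annotation is absent is treated as false
(a site is never failed by an unobserved annotation); such sites can be
tallied with :func:`missing_annotation_mask`.

.. note::
   The QD < 26.0 lower bound is unusually aggressive for quality-by-depth
   (many pipelines use 2.0); it is the convention this toolkit targets, but
   users filtering their own call sets should check it suits their caller.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

import numpy as np

from .panel import INDEL, SNP, GenotypePanel, SiteRecord

PASS = "PASS"
FAIL = "FAIL"

# filter thresholds (strict inequalities)
QD_MIN = 26.0
FS_MAX_SNP = 60.0
FS_MAX_INDEL = 200.0
MQ_MIN = 40.0

_ALLELE_OK = frozenset("ACGTN")


class VcfError(RuntimeError):
    """Raised for unreadable or GT-less VCF input."""


@dataclass
class VcfReadResult:
    """A parsed panel plus the tally of records excluded on read."""

    panel: GenotypePanel
    n_skipped: int
    skipped_by_reason: dict[str, int]


def _parse_region(region: str) -> tuple[str, int, int]:
    if ":" not in region:
        return region, 1, 2**62
    chrom, _, span = region.partition(":")
    start_s, _, end_s = span.partition("-")
    start = int(start_s.replace(",", ""))
    end = int(end_s.replace(",", "")) if end_s else 2**62
    if start < 1 or end < start:
        raise ValueError(f"bad region {region!r}")
    return chrom, start, end


def read_vcf(path: str, region: str | None = None) -> VcfReadResult:
    """Read a VCF 4.x file into a :class:`GenotypePanel`.

    Parameters
    ----------
    path:
        Plain or bgzip-compressed VCF with GT in FORMAT.
    region:
        Optional ``chrom`` or ``chrom:start-end`` restriction, 1-based
        inclusive on both ends.

    Only biallelic records with simple (non-symbolic) alleles are kept;
    multi-allelic and symbolic records are skipped and counted.  Phased
    and unphased genotypes are treated identically; any genotype touching
    a missing allele codes ``-1``.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # htslib raises bare exceptions on bad input
        raise VcfError(f"cannot read VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise VcfError(f"VCF {path!r} carries no samples / no GT field")

    want = _parse_region(region) if region else None

    sites: list[SiteRecord] = []
    columns: list[np.ndarray] = []
    skipped = {"multiallelic": 0, "symbolic": 0, "invalid": 0}
    for rec in vcf:
        if want is not None:
            chrom, lo, hi = want
            if rec.CHROM != chrom or not (lo <= rec.POS <= hi):
                continue
        alts = rec.ALT
        if len(alts) != 1:
            skipped["multiallelic"] += 1
            continue
        ref, alt = rec.REF.upper(), alts[0].upper()
        if (
            not set(ref) <= _ALLELE_OK
            or not set(alt) <= _ALLELE_OK
            or alt.startswith("<")
        ):
            skipped["symbolic"] += 1
            continue
        gts = rec.genotypes  # [[a, b, phased], ...]
        if gts is None:
            raise VcfError(f"record {rec.CHROM}:{rec.POS} has no GT data")
        col = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(gts):
            alleles = gt[:-1]
            if any(a < 0 for a in alleles):
                col[i] = -1
            else:
                col[i] = sum(1 for a in alleles if a == 1)
        try:
            site = SiteRecord(
                chrom=rec.CHROM,
                pos=rec.POS,
                id=rec.ID or ".",
                ref=ref,
                alt=alt,
                qd=_info_float(rec, "QD"),
                fs=_info_float(rec, "FS"),
                mq=_info_float(rec, "MQ"),
            )
        except ValueError:
            skipped["invalid"] += 1
            continue
        sites.append(site)
        columns.append(col)

    geno = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    panel = GenotypePanel(samples=samples, sites=sites, geno=geno)
    return VcfReadResult(
        panel=panel,
        n_skipped=sum(skipped.values()),
        skipped_by_reason=skipped,
    )


def _info_float(rec, key: str) -> float | None:
    value = rec.INFO.get(key)
    if value is None:
        return None
    try:
        value = float(value)
    except (TypeError, ValueError):
        return None
    if not np.isfinite(value) or value < 0:
        return None
    return value


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(panel: GenotypePanel, path: str) -> None:
    """Write a panel as a minimal GT-only VCF (bgzip if path ends with .gz)."""
    lines: list[str] = ["##fileformat=VCFv4.2", "##source=germpanel"]
    for chrom in panel.chroms:
        lines.append(f"##contig=<ID={chrom}>")
    lines.append('##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">')
    lines.append('##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand (phred)">')
    lines.append('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(panel.samples)
    )
    for j, site in enumerate(panel.sites):
        info_parts = [
            f"{tag}={getattr(site, attr):g}"
            for tag, attr in (("QD", "qd"), ("FS", "fs"), ("MQ", "mq"))
            if getattr(site, attr) is not None
        ]
        info = ";".join(info_parts) if info_parts else "."
        gts = "\t".join(_GT_STRINGS[int(c)] for c in panel.geno[:, j])
        lines.append(
            f"{site.chrom}\t{site.pos}\t{site.id}\t{site.ref}\t{site.alt}"
            f"\t.\t.\t{info}\tGT\t{gts}"
        )
    payload = ("\n".join(lines) + "\n").encode()
    if str(path).endswith(".gz"):
        import pysam

        with pysam.BGZFile(str(path), "wb") as fh:
            fh.write(payload)
    else:
        with open(path, "wb") as fh:
            fh.write(payload)


# ----------------------------------------------------------------------
# hard filtering
# ----------------------------------------------------------------------

def hard_filter(sites: list[SiteRecord]) -> list[str]:
    """Flag each site PASS/FAIL under the vtype-specific hard-filter expression.

    Total function: the flag list aligns positionally with the input, and a
    missing annotation never fails a site.
    """
    flags: list[str] = []
    for site in sites:
        fs_max = FS_MAX_SNP if site.vtype == SNP else FS_MAX_INDEL
        fails = (
            (site.qd is not None and site.qd < QD_MIN)
            or (site.fs is not None and site.fs > fs_max)
            or (site.mq is not None and site.mq < MQ_MIN)
        )
        flags.append(FAIL if fails else PASS)
    return flags


def missing_annotation_mask(sites: list[SiteRecord]) -> np.ndarray:
    """Boolean mask of sites missing at least one of QD/FS/MQ (tallied, never failed)."""
    return np.array(
        [s.qd is None or s.fs is None or s.mq is None for s in sites], dtype=bool
    )


def filter_panel(panel: GenotypePanel, keep_fail: bool = False) -> tuple[GenotypePanel, dict]:
    """Apply :func:`hard_filter`; return the PASS-only panel and a tally dict."""
    flags = hard_filter(panel.sites)
    passed = [i for i, f in enumerate(flags) if f == PASS]
    tally = {
        "n_sites": panel.n_sites,
        "n_pass": len(passed),
        "n_fail": panel.n_sites - len(passed),
        "n_missing_annotation": int(missing_annotation_mask(panel.sites).sum()),
    }
    if keep_fail:
        return panel.copy(), tally
    return panel.take_sites(passed), tally


# ----------------------------------------------------------------------
# IDs and call-rate stats
# ----------------------------------------------------------------------

def assign_snp_ids(panel: GenotypePanel) -> GenotypePanel:
    """Assign deterministic site IDs ``<chrom>_<pos>_<ref>_<alt>``.

    Idempotent; IDs are unique because (chrom, pos) pairs are (a panel
    invariant guarantees it).
    """
    sites = [s.with_id(f"{s.chrom}_{s.pos}_{s.ref}_{s.alt}") for s in panel.sites]
    if len({s.id for s in sites}) != len(sites):
        raise ValueError("duplicate (chrom, pos, ref, alt) keys; cannot assign unique IDs")
    return GenotypePanel(samples=list(panel.samples), sites=sites, geno=panel.geno.copy())


@dataclass(frozen=True)
class PanelStats:
    missing_fraction: float
    het_fraction: float
    hom_fraction: float


def missing_het_stats(panel: GenotypePanel) -> PanelStats:
    """Fractions of missing / heterozygous / homozygous cells over the whole matrix."""
    cells = panel.geno.size
    if cells == 0:
        raise ValueError("empty panel: no (sample, site) cells")
    missing = int((panel.geno == -1).sum())
    het = int((panel.geno == 1).sum())
    return PanelStats(
        missing_fraction=missing / cells,
        het_fraction=het / cells,
        hom_fraction=(cells - missing - het) / cells,
    )
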