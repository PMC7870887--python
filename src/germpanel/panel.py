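"""Core containers for genotype panels.

A :class:`GenotypePanel` is the in-memory matrix every analysis stage
consumes: samples in rows, biallelic variant sites in columns, genotypes
coded as alternate-allele dosages::

    0  homozygous reference
    1  heterozygous
    2  homozygous alternate
   -1  missing call

Sites are kept in genomic order (chromosomes in blocks, positions strictly
increasing within a chromosome) and carry the per-site annotations the
hard filter consumes (QD, FS, MQ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING: int = -1

SNP = "SNP"
INDEL = "INDEL"

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SiteRecord:
    """One biallelic variant site.

    ``pos`` is the 1-based base-pair coordinate (VCF convention).  ``qd``,
    ``fs`` and ``mq`` are the quality-by-depth, Fisher-strand and
    mapping-quality annotations; ``None`` means the annotation was absent
    from the source record.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str = "."
    qd: float | None = None
    fs: float | None = None
    mq: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")
        for name in ("qd", "fs", "mq"):
            value = getattr(self, name)
            if value is None:
                continue
            value = float(value)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value}")
            object.__setattr__(self, name, value)

    @property
    def vtype(self) -> str:
        """``SNP`` iff both alleles are single bases, else ``INDEL``."""
        return SNP if len(self.ref) == 1 and len(self.alt) == 1 else INDEL

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    def with_id(self, new_id: str) -> "SiteRecord":
        return replace(self, id=new_id)


@dataclass
class GenotypePanel:
    """Samples x sites matrix of coded genotypes.

    Invariants (enforced on construction):

    * ``geno.shape == (len(samples), len(sites))`` with codes in {-1,0,1,2};
    * sample IDs unique;
    * sites grouped by chromosome (each chromosome forms one contiguous
      block, in order of first appearance) with strictly increasing
      positions inside a block — hence no duplicate (chrom, pos).
    """

    samples: list[str]
    sites: list[SiteRecord]
    geno: np.ndarray
    validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.sites = list(self.sites)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.geno.ndim != 2 or self.geno.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"genotype matrix shape {self.geno.shape} does not match "
                f"({len(self.samples)} samples, {len(self.sites)} sites)"
            )
        if self.validate:
            self._check_invariants()

    def _check_invariants(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs")
        bad = ~np.isin(self.geno, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        seen_chroms: set[str] = set()
        prev_chrom: str | None = None
        prev_pos = 0
        for s in self.sites:
            if s.chrom != prev_chrom:
                if s.chrom in seen_chroms:
                    raise ValueError(f"chromosome {s.chrom} is not a contiguous block")
                seen_chroms.add(s.chrom)
                prev_chrom = s.chrom
                prev_pos = 0
            if s.pos <= prev_pos:
                raise ValueError(
                    f"sites not strictly increasing on {s.chrom}: "
                    f"{prev_pos} then {s.pos}"
                )
            prev_pos = s.pos

    # -- shape ---------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def chroms(self) -> list[str]:
        out: list[str] = []
        for s in self.sites:
            if not out or out[-1] != s.chrom:
                out.append(s.chrom)
        return out

    # -- accessors -----------------------------------------------------
    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in panel") from None

    def positions(self, chrom: str | None = None) -> np.ndarray:
        if chrom is None:
            return np.array([s.pos for s in self.sites], dtype=np.int64)
        return np.array([s.pos for s in self.sites if s.chrom == chrom], dtype=np.int64)

    def site_frame(self) -> pd.DataFrame:
        """Per-site metadata as a DataFrame (chrom, pos, id, ref, alt, vtype, qd, fs, mq)."""
        return pd.DataFrame(
            {
                "chrom": [s.chrom for s in self.sites],
                "pos": [s.pos for s in self.sites],
                "id": [s.id for s in self.sites],
                "ref": [s.ref for s in self.sites],
                "alt": [s.alt for s in self.sites],
                "vtype": [s.vtype for s in self.sites],
                "qd": [s.qd for s in self.sites],
                "fs": [s.fs for s in self.sites],
                "mq": [s.mq for s in self.sites],
            }
        )

    # -- subsetting ----------------------------------------------------
    def take_sites(self, indices) -> "GenotypePanel":
        idx = np.asarray(list(indices), dtype=int)
        return GenotypePanel(
            samples=list(self.samples),
            sites=[self.sites[i] for i in idx],
            geno=self.geno[:, idx].copy(),
        )

    def take_samples(self, which) -> "GenotypePanel":
        """Subset samples by a list of IDs or integer indices (order preserved)."""
        idx = [self.sample_index(w) if isinstance(w, str) else int(w) for w in which]
        return GenotypePanel(
            samples=[self.samples[i] for i in idx],
            sites=list(self.sites),
            geno=self.geno[idx, :].copy(),
        )

    def for_chrom(self, chrom: str) -> "GenotypePanel":
        idx = [i for i, s in enumerate(self.sites) if s.chrom == chrom]
        if not idx:
            raise KeyError(f"chromosome {chrom!r} not in panel")
        return self.take_sites(idx)

    def copy(self) -> "GenotypePanel":
        return GenotypePanel(
            samples=list(self.samples), sites=list(self.sites), geno=self.geno.copy()
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GenotypePanel({self.n_samples} samples x {self.n_sites} sites)"
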