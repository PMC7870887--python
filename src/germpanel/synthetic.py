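"""Synthetic genotype panels with known truth for every downstream analysis.

The generator emulates the data regime of a resequenced inbred germplasm
collection compared against a fixed-content genotyping array:

1. ancestral allele frequencies p ~ Uniform(0.05, 0.95) per site;
2. population frequencies from an F-model Beta draw,
   p_k ~ Beta(p (1-d)/d, (1-p)(1-d)/d), with divergence d in [0, 1];
3. a small founder haplotype pool per population, drawn site-wise from
   p_k, from which each sample haplotype is built by a copying process
   that switches donor at ``rho_per_bp`` per bp (geometric switch
   distances) — this single knob produces distance-decaying LD;
4. diploids formed by pairing two copied haplotypes, then selfed
   ``selfing_generations`` times (each generation halves the expected
   heterozygosity, site-wise independently);
5. dosage codes emitted with random missingness.

An array-style companion panel is a random site subset with genotyping
error (hom flips 0<->2) and extra missingness; mislabeling events swap
the array genotype columns of two samples from different populations, and
duplication events clone a sample's array column under a new ID.  The
:class:`SimTruth` ledger records everything needed to score verification
verdicts, so parameter-recovery tests can be exact.

All randomness flows from one generator seeded by ``SimConfig.seed``;
identical config implies bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import panel_io
from .panel import GenotypePanel, SiteRecord

_BASES = np.array(list("ACGT"))
_COUNTRIES = ("China", "Japan", "United States", "South Korea", "Russia",
              "North Korea", "India", "Brazil")


@dataclass
class SimConfig:
    """Generator settings; defaults describe a small two-population study
    of 40 inbred accessions with moderate divergence."""

    seed: int
    n_pops: int = 2
    n_per_pop: int = 20
    n_chrom: int = 2
    chrom_len_bp: int = 1_000_000
    n_sites_per_chrom: int = 300
    divergence: float = 0.3
    rho_per_bp: float = 1e-5
    selfing_generations: int = 6
    founder_haplotypes_per_pop: int = 8
    array_fraction: float = 0.5
    geno_error_rate: float = 0.005
    missing_rate: float = 0.01
    n_mislabels: int = 4
    n_duplicates: int = 2
    info_fail_fraction: float = 0.05
    array_swap_fraction: float = 0.2
    array_flip_fraction: float = 0.1
    chrom_prefix: str = "Gm"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory; implicit entropy is not allowed")
        for name in ("divergence", "array_fraction", "geno_error_rate",
                     "missing_rate", "info_fail_fraction",
                     "array_swap_fraction", "array_flip_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.rho_per_bp < 0:
            raise ValueError("rho_per_bp must be >= 0")
        if self.selfing_generations < 0:
            raise ValueError("selfing_generations must be >= 0")
        if self.n_mislabels % 2:
            raise ValueError("n_mislabels counts affected samples; must be even")
        if self.n_mislabels and self.n_pops < 2:
            raise ValueError("mislabels are planted across populations; need n_pops >= 2")
        if self.n_mislabels + self.n_duplicates > self.n_pops * self.n_per_pop:
            raise ValueError("more planted events than samples")
        if self.n_sites_per_chrom > self.chrom_len_bp:
            raise ValueError("more sites than base pairs on a chromosome")
        if self.founder_haplotypes_per_pop < 2:
            raise ValueError("need at least 2 founder haplotypes per population")

    @property
    def n_samples(self) -> int:
        return self.n_pops * self.n_per_pop


@dataclass
class SimTruth:
    """Ground-truth ledger for one simulated study."""

    sample_pop: dict[str, int]
    expected_map: dict[str, str]
    true_match: dict[str, str]
    mislabels: list[tuple[str, str]] = field(default_factory=list)
    duplicate_groups: list[tuple[str, str]] = field(default_factory=list)
    rho_per_bp: float = 0.0
    allele_freqs: pd.DataFrame | None = field(default=None, repr=False)
    config: SimConfig | None = None

    @property
    def mislabeled_samples(self) -> set[str]:
        return {s for pair in self.mislabels for s in pair}

    def species_map(self) -> dict[str, str]:
        """Populations mapped to species: the last population plays the wild
        relative, all others the cultivated species."""
        wild = max(self.sample_pop.values())
        return {
            s: ("G. soja" if p == wild and len(set(self.sample_pop.values())) > 1
                else "G. max")
            for s, p in self.sample_pop.items()
        }

    def metadata_frame(self) -> pd.DataFrame:
        species = self.species_map()
        return pd.DataFrame(
            {
                "sample_id": list(self.sample_pop),
                "species": [species[s] for s in self.sample_pop],
                "country": [
                    _COUNTRIES[p % len(_COUNTRIES)] for p in self.sample_pop.values()
                ],
            }
        )

    def to_json(self, path) -> None:
        payload = {
            "sample_pop": self.sample_pop,
            "expected_map": self.expected_map,
            "true_match": self.true_match,
            "mislabels": [list(p) for p in self.mislabels],
            "duplicate_groups": [list(p) for p in self.duplicate_groups],
            "rho_per_bp": self.rho_per_bp,
            "config": asdict(self.config) if self.config else None,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def self_fertilize(geno: np.ndarray, generations: int, rng: np.random.Generator) -> np.ndarray:
    """Resolve heterozygous cells after ``generations`` rounds of selfing.

    Each initially heterozygous cell stays heterozygous with probability
    0.5**generations, else fixes to either homozygote with equal chance
    (single-site Mendelian expectation; sites treated independently).
    """
    out = geno.copy()
    het = out == 1
    n_het = int(het.sum())
    if n_het == 0 or generations == 0:
        return out
    stay = rng.random(n_het) < 0.5**generations
    fix_alt = rng.random(n_het) < 0.5
    resolved = np.where(stay, 1, np.where(fix_alt, 2, 0)).astype(np.int8)
    out[het] = resolved
    return out


def _copy_haplotype(founders: np.ndarray, pos: np.ndarray, rho: float,
                    rng: np.random.Generator) -> np.ndarray:
    n_f, n_sites = founders.shape
    gaps = np.diff(pos).astype(np.float64)
    p_switch = 1.0 - np.exp(-rho * gaps)
    switches = rng.random(n_sites - 1) < p_switch
    segment = np.concatenate([[0], np.cumsum(switches)])
    donors = rng.integers(0, n_f, size=segment[-1] + 1)
    return founders[donors[segment], np.arange(n_sites)]


def simulate_panel(config: SimConfig,
                   rng: np.random.Generator | None = None) -> tuple[GenotypePanel, SimTruth]:
    """Generate the dense (sequencing-style) panel plus its truth ledger."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    samples = [f"PI{600001 + i}" for i in range(config.n_samples)]
    pops = {s: i // config.n_per_pop for i, s in enumerate(samples)}

    sites: list[SiteRecord] = []
    blocks: list[np.ndarray] = []
    freq_rows: list[dict] = []
    for c in range(config.n_chrom):
        chrom = f"{config.chrom_prefix}{c + 1:02d}"
        pos = np.sort(
            rng.choice(config.chrom_len_bp, size=config.n_sites_per_chrom,
                       replace=False)
        ) + 1
        p_anc = rng.uniform(0.05, 0.95, size=config.n_sites_per_chrom)
        d = config.divergence
        pop_freqs = np.empty((config.n_pops, config.n_sites_per_chrom))
        for k in range(config.n_pops):
            if d > 0:
                pop_freqs[k] = rng.beta(p_anc * (1 - d) / d, (1 - p_anc) * (1 - d) / d)
            else:
                pop_freqs[k] = p_anc

        geno = np.empty((config.n_samples, config.n_sites_per_chrom), dtype=np.int8)
        for k in range(config.n_pops):
            founders = (
                rng.random((config.founder_haplotypes_per_pop,
                            config.n_sites_per_chrom))
                < pop_freqs[k]
            ).astype(np.int8)
            members = [i for i, s in enumerate(samples) if pops[s] == k]
            for i in members:
                h1 = _copy_haplotype(founders, pos, config.rho_per_bp, rng)
                h2 = _copy_haplotype(founders, pos, config.rho_per_bp, rng)
                geno[i] = h1 + h2
        geno = self_fertilize(geno, config.selfing_generations, rng)
        if config.missing_rate > 0:
            geno[rng.random(geno.shape) < config.missing_rate] = -1

        ref_i = rng.integers(0, 4, size=config.n_sites_per_chrom)
        alt_i = (ref_i + rng.integers(1, 4, size=config.n_sites_per_chrom)) % 4
        qd = rng.uniform(26.0, 45.0, size=config.n_sites_per_chrom)
        fs = rng.uniform(0.0, 50.0, size=config.n_sites_per_chrom)
        mq = rng.uniform(40.0, 60.0, size=config.n_sites_per_chrom)
        fail = rng.random(config.n_sites_per_chrom) < config.info_fail_fraction
        which_clause = rng.integers(0, 3, size=config.n_sites_per_chrom)
        qd = np.where(fail & (which_clause == 0),
                      rng.uniform(5.0, 25.99, size=qd.shape), qd)
        fs = np.where(fail & (which_clause == 1),
                      rng.uniform(60.01, 180.0, size=fs.shape), fs)
        mq = np.where(fail & (which_clause == 2),
                      rng.uniform(10.0, 39.99, size=mq.shape), mq)

        for j in range(config.n_sites_per_chrom):
            sites.append(
                SiteRecord(chrom=chrom, pos=int(pos[j]), ref=_BASES[ref_i[j]],
                           alt=_BASES[alt_i[j]], qd=float(qd[j]), fs=float(fs[j]),
                           mq=float(mq[j]))
            )
            freq_rows.append(
                {"chrom": chrom, "pos": int(pos[j]), "p_ancestral": float(p_anc[j]),
                 **{f"p_pop{k}": float(pop_freqs[k, j]) for k in range(config.n_pops)}}
            )
        blocks.append(geno)

    panel = GenotypePanel(samples=samples, sites=sites,
                          geno=np.concatenate(blocks, axis=1))
    panel = panel_io.assign_snp_ids(panel)
    truth = SimTruth(
        sample_pop=pops,
        expected_map={s: s for s in samples},
        true_match={s: s for s in samples},
        rho_per_bp=config.rho_per_bp,
        allele_freqs=pd.DataFrame(freq_rows),
        config=config,
    )
    return panel, truth


def array_subset(panel: GenotypePanel, config: SimConfig,
                 rng: np.random.Generator | None = None) -> GenotypePanel:
    """Array-style companion: random site subset + genotyping error + missingness.

    Errors flip homozygote codes 0 <-> 2 at ``geno_error_rate``; additional
    cells go missing at ``missing_rate``.  Sample IDs are preserved.  To
    emulate platform reporting conventions, a fraction of sites is emitted
    with ref/alt reversed (codes exchanged accordingly, so the underlying
    genotypes are unchanged) and another fraction on the opposite strand —
    the representation noise allele harmonization exists to undo.
    """
    from dataclasses import replace as _replace

    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if not 0 < config.array_fraction <= 1:
        raise ValueError("array_fraction must be in (0, 1]")
    n_keep = max(1, round(config.array_fraction * panel.n_sites))
    idx = np.sort(rng.choice(panel.n_sites, size=n_keep, replace=False))
    sub = panel.take_sites(idx)
    geno = sub.geno.copy()
    sites = list(sub.sites)
    u = rng.random(len(sites))
    for j, site in enumerate(sites):
        if u[j] < config.array_swap_fraction:
            sites[j] = _replace(site, ref=site.alt, alt=site.ref)
            col = geno[:, j]
            zero, two = col == 0, col == 2
            col[zero], col[two] = 2, 0
        elif u[j] < config.array_swap_fraction + config.array_flip_fraction:
            sites[j] = _replace(site, ref=comp[site.ref], alt=comp[site.alt])
    if config.geno_error_rate > 0:
        hom = (geno == 0) | (geno == 2)
        flip = hom & (rng.random(geno.shape) < config.geno_error_rate)
        geno[flip] = 2 - geno[flip]
    if config.missing_rate > 0:
        geno[rng.random(geno.shape) < config.missing_rate] = -1
    return GenotypePanel(samples=list(sub.samples), sites=sites, geno=geno)


def plant_mislabels(
    array_panel: GenotypePanel,
    truth: SimTruth,
    n_mislabels: int | None = None,
    n_duplicates: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypePanel, SimTruth]:
    """Plant label swaps and duplications into the array panel.

    Mislabels come in pairs: the array genotype columns of two samples
    from *different* populations are exchanged while their labels stay
    put, so each sample's expected counterpart is now genetically wrong.
    Duplicates clone a (so far untouched) sample's array column under
    ``<id>_dup``.  Both event types are recorded in the returned truth.
    """
    cfg = truth.config
    if n_mislabels is None:
        n_mislabels = cfg.n_mislabels if cfg else 0
    if n_duplicates is None:
        n_duplicates = cfg.n_duplicates if cfg else 0
    if n_mislabels % 2:
        raise ValueError("n_mislabels must be even (events are pairwise swaps)")
    rng = rng if rng is not None else np.random.default_rng(
        cfg.seed if cfg else 0
    )

    geno = array_panel.geno.copy()
    samples = list(array_panel.samples)
    pops = truth.sample_pop
    true_match = dict(truth.true_match)
    mislabels: list[tuple[str, str]] = []
    used: set[str] = set()

    pop_ids = sorted(set(pops.values()))
    for _ in range(n_mislabels // 2):
        pa, pb = rng.choice(pop_ids, size=2, replace=False)
        cand_a = [s for s in samples if pops.get(s) == pa and s not in used]
        cand_b = [s for s in samples if pops.get(s) == pb and s not in used]
        if not cand_a or not cand_b:
            raise ValueError("not enough unused samples to plant mislabels")
        sa = str(rng.choice(cand_a))
        sb = str(rng.choice(cand_b))
        ia, ib = samples.index(sa), samples.index(sb)
        geno[[ia, ib], :] = geno[[ib, ia], :]
        used.update((sa, sb))
        mislabels.append((sa, sb))
        true_match[sa], true_match[sb] = sb, sa

    dup_groups: list[tuple[str, str]] = []
    cand = [s for s in samples if s not in used]
    if n_duplicates > len(cand):
        raise ValueError("not enough unused samples to plant duplicates")
    chosen = list(rng.choice(cand, size=n_duplicates, replace=False)) if n_duplicates else []
    for src in chosen:
        src = str(src)
        dup_id = f"{src}_dup"
        samples.append(dup_id)
        geno = np.vstack([geno, geno[array_panel.sample_index(src)][None, :]])
        dup_groups.append((src, dup_id))
        used.add(src)

    new_panel = GenotypePanel(samples=samples, sites=list(array_panel.sites), geno=geno)
    new_truth = SimTruth(
        sample_pop=dict(truth.sample_pop),
        expected_map=dict(truth.expected_map),
        true_match=true_match,
        mislabels=mislabels,
        duplicate_groups=dup_groups,
        rho_per_bp=truth.rho_per_bp,
        allele_freqs=truth.allele_freqs,
        config=truth.config,
    )
    return new_panel, new_truth


@dataclass
class SimStudy:
    """A complete simulated study: dense panel, array panel, truth."""

    seq: GenotypePanel
    array: GenotypePanel
    truth: SimTruth


def simulate_study(config: SimConfig) -> SimStudy:
    """Run the full generator: dense panel, array companion, planted events.

    One generator seeded from ``config.seed`` drives every step, so the
    whole study is reproducible bit-for-bit.
    """
    rng = np.random.default_rng(config.seed)
    seq, truth = simulate_panel(config, rng=rng)
    array = array_subset(seq, config, rng=rng)
    array, truth = plant_mislabels(array, truth, rng=rng)
    return SimStudy(seq=seq, array=array, truth=truth)
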