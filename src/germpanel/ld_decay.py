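"""Linkage-disequilibrium decay: pairwise r², curve fitting, decay distance.

r² between two sites is the squared Pearson correlation of genotype dosage
codes across samples, computed on pairwise-complete observations (cells
missing in either site are dropped for that pair).  On inbred, het-masked
material this equals haplotype r².

The decay curve is the drift expectation of r² for a sample of n
chromosomes at population-scaled recombination C = rho * distance::

    E[r²] = (10 + C) / ((2 + C)(11 + C))
            * (1 + ((3 + C)(12 + 12C + C²)) / (n (2 + C)(11 + C)))

which is fitted to observed (distance, r²) pairs by nonlinear least
squares on distance-binned means, yielding the per-bp scale ``rho`` and
the distance at which the fitted curve crosses a baseline r² (0.2 by
convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .panel import GenotypePanel

DEFAULT_BASELINE = 0.2
DEFAULT_MAX_DIST = 1_000_000


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_rho: float | None = None,
                 residual: float | None = None):
        super().__init__(message)
        self.last_rho = last_rho
        self.residual = residual


def pairwise_r2(
    panel: GenotypePanel,
    chrom: str | None = None,
    max_dist_bp: int = DEFAULT_MAX_DIST,
) -> pd.DataFrame:
    """All within-chromosome site pairs up to ``max_dist_bp`` apart.

    Returns a DataFrame with columns chrom, pos1, pos2, dist, r2; pairs
    whose correlation is undefined (a monomorphic site among the
    pairwise-complete samples, or fewer than two of them) are skipped and
    tallied in ``df.attrs["n_undefined"]``.
    """
    chroms = [chrom] if chrom is not None else panel.chroms
    frames = []
    n_undef = 0
    for c in chroms:
        sub = panel.for_chrom(c)
        if sub.n_sites < 2:
            continue
        frame, bad = _chrom_r2(sub, c, max_dist_bp)
        n_undef += bad
        if len(frame):
            frames.append(frame)
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=["chrom", "pos1", "pos2", "dist", "r2"])
    out.attrs["n_undefined"] = n_undef
    return out


def _chrom_r2(sub: GenotypePanel, chrom: str, max_dist_bp: int):
    # pairwise-complete sums via masked matrix products; genotype codes are
    # small integers, so all the sums below are exact in float64
    pos = sub.positions()
    X = sub.geno.T.astype(np.float64)          # sites x samples
    W = (sub.geno.T >= 0).astype(np.float64)   # validity mask
    Xz = X * W

    n = W @ W.T
    sxy = Xz @ Xz.T
    sx = Xz @ W.T        # sx[i, j] = sum of x_i over samples valid at both
    sxx = (Xz * Xz) @ W.T

    cov_n = n * sxy - sx * sx.T
    var_x = n * sxx - sx * sx
    denom = var_x * var_x.T

    iu, ju = np.triu_indices(len(pos), k=1)
    dist = pos[ju] - pos[iu]
    in_window = dist <= max_dist_bp
    iu, ju, dist = iu[in_window], ju[in_window], dist[in_window]

    d = denom[iu, ju]
    nn = n[iu, ju]
    defined = (d > 0) & (nn >= 2)
    n_undefined = int((~defined).sum())
    iu, ju, dist, d = iu[defined], ju[defined], dist[defined], d[defined]
    r2 = (cov_n[iu, ju] ** 2) / d
    np.clip(r2, 0.0, 1.0, out=r2)

    frame = pd.DataFrame(
        {"chrom": chrom, "pos1": pos[iu], "pos2": pos[ju],
         "dist": dist.astype(np.int64), "r2": r2}
    )
    return frame, n_undefined


def hill_weir_expectation(C, n: int):
    """Expected r² at population-scaled recombination C for sample size n.

    Vectorized over C.  Strictly decreasing in C and in n; starts near
    0.45 + O(1/n) at C = 0 and decays to the finite-sample noise floor
    1/n as C grows.
    """
    C = np.asarray(C, dtype=np.float64)
    if np.any(C < 0):
        raise ValueError("C must be >= 0")
    if n < 2:
        raise ValueError("sample size n must be >= 2")
    denom = (2.0 + C) * (11.0 + C)
    first = (10.0 + C) / denom
    second = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C * C)) / (n * denom)
    out = first * second
    return float(out) if out.ndim == 0 else out


@dataclass
class LDFit:
    """Fitted decay curve for one set of (distance, r²) observations."""

    n: int
    rho_per_bp: float
    baseline: float
    decay_distance: float          # NaN when the curve never crosses baseline
    reached: bool
    n_pairs: int
    bins: pd.DataFrame | None = field(default=None, repr=False)

    def expected_r2(self, dist):
        return hill_weir_expectation(self.rho_per_bp * np.asarray(dist, float), self.n)


def bin_pairs(pairs: pd.DataFrame, n_bins: int = 100) -> pd.DataFrame:
    """Log-spaced distance bins with mean distance, mean r² and pair count."""
    d = pairs["dist"].to_numpy(dtype=np.float64)
    r2 = pairs["r2"].to_numpy(dtype=np.float64)
    lo, hi = d.min(), d.max()
    if lo == hi:
        return pd.DataFrame({"dist": [lo], "r2": [r2.mean()], "count": [len(d)]})
    edges = np.geomspace(lo, hi, n_bins + 1)
    edges[-1] = np.nextafter(edges[-1], np.inf)
    which = np.digitize(d, edges) - 1
    rows = []
    for b in np.unique(which):
        m = which == b
        rows.append({"dist": d[m].mean(), "r2": r2[m].mean(), "count": int(m.sum())})
    return pd.DataFrame(rows)


def fit_decay(
    pairs: pd.DataFrame,
    n: int,
    baseline: float = DEFAULT_BASELINE,
    use_bins: bool = True,
    n_bins: int = 100,
) -> LDFit:
    """Fit the decay curve to observed pairs and locate the baseline crossing.

    ``rho`` is estimated by least squares of the drift expectation against
    r² (on binned means by default, raw pairs via ``use_bins=False``),
    parameterized on log(rho) to keep the scale positive; initialization is
    1 / median(distance).  The decay distance solves
    ``E[r²](rho * d) = baseline`` by bracketed root finding; if the fitted
    curve stays on one side of the baseline over the observed distance
    range extended tenfold, the crossing is flagged as not reached.
    """
    if len(pairs) == 0:
        raise ValueError("no (distance, r2) pairs to fit")
    d_all = pairs["dist"].to_numpy(dtype=np.float64)
    if len(pairs) < 50 or (d_all.max() / max(d_all.min(), 1.0)) < 100.0:
        warnings.warn(
            "few pairs or narrow distance range; decay fit may be unstable",
            stacklevel=2,
        )
    if use_bins:
        bins = bin_pairs(pairs, n_bins=n_bins)
        x, y = bins["dist"].to_numpy(), bins["r2"].to_numpy()
    else:
        bins = None
        x, y = d_all, pairs["r2"].to_numpy(dtype=np.float64)

    theta0 = np.log(1.0 / np.median(d_all))

    def residuals(theta):
        return hill_weir_expectation(np.exp(theta[0]) * x, n) - y

    res = optimize.least_squares(
        residuals, [theta0], xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=200 * 10
    )
    rho = float(np.exp(res.x[0]))
    if not res.success or not np.isfinite(rho) or rho <= 0:
        raise FitError(
            f"decay fit did not converge: {res.message}",
            last_rho=rho,
            residual=float(np.sum(res.fun**2)),
        )

    decay, reached = _baseline_crossing(rho, n, baseline, d_max=d_all.max())
    return LDFit(
        n=int(n), rho_per_bp=rho, baseline=float(baseline),
        decay_distance=decay, reached=reached, n_pairs=len(pairs), bins=bins,
    )


def _baseline_crossing(rho: float, n: int, baseline: float, d_max: float):
    hi = 10.0 * d_max
    f = lambda d: hill_weir_expectation(rho * d, n) - baseline
    if f(0.0) <= 0 or f(hi) > 0:
        return float("nan"), False
    d = float(optimize.brentq(f, 1e-9, hi, xtol=1e-6, rtol=1e-12))
    return d, True


@dataclass
class ChromosomeSummary:
    """Per-chromosome decay table plus the across-chromosome summaries."""

    table: pd.DataFrame
    mean_decay_distance_mb: float
    size_decay_r2: float

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            self.table.to_csv(fh, sep="\t", index=False, float_format="%.6g")
            fh.write(f"# mean_decay_distance_mb\t{self.mean_decay_distance_mb:.6g}\n")
            fh.write(f"# size_decay_correlation_r2\t{self.size_decay_r2:.6g}\n")


def chromosome_summary(
    panel: GenotypePanel,
    chrom_sizes: dict[str, int] | None = None,
    baseline: float = DEFAULT_BASELINE,
    max_dist_bp: int = DEFAULT_MAX_DIST,
    n: int | None = None,
) -> ChromosomeSummary:
    """One decay fit per chromosome, their unweighted mean, and the squared
    correlation between chromosome size and decay distance.

    Chromosomes whose fit fails or never reaches the baseline are reported
    as NaN and excluded from the mean and the correlation; the correlation
    is NaN with fewer than two usable chromosomes.
    """
    n = n if n is not None else panel.n_samples
    rows = []
    for chrom in panel.chroms:
        size = (
            int(chrom_sizes[chrom]) if chrom_sizes and chrom in chrom_sizes
            else int(panel.positions(chrom).max())
        )
        row = {"chromosome": chrom, "chromosome_size_mb": size / 1e6,
               "rho_per_bp": np.nan, "decay_distance_mb": np.nan}
        try:
            pairs = pairwise_r2(panel, chrom=chrom, max_dist_bp=max_dist_bp)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_decay(pairs, n=n, baseline=baseline)
            row["rho_per_bp"] = fit.rho_per_bp
            if fit.reached:
                row["decay_distance_mb"] = fit.decay_distance / 1e6
        except (ValueError, FitError):
            pass
        rows.append(row)
    table = pd.DataFrame(rows)

    ok = table["decay_distance_mb"].notna()
    mean_decay = float(table.loc[ok, "decay_distance_mb"].mean()) if ok.any() else float("nan")
    if ok.sum() >= 2 and table.loc[ok, "chromosome_size_mb"].nunique() > 1 \
            and table.loc[ok, "decay_distance_mb"].nunique() > 1:
        r, _ = stats.pearsonr(
            table.loc[ok, "chromosome_size_mb"], table.loc[ok, "decay_distance_mb"]
        )
        size_decay_r2 = float(r * r)
    else:
        size_decay_r2 = float("nan")
    return ChromosomeSummary(table=table, mean_decay_distance_mb=mean_decay,
                             size_decay_r2=size_decay_r2)
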