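"""Linkage-disequilibrium r² and distance-decay curves.

For fully-imputed inbred (haploid-coded) data, the r² between two sites is
the squared Pearson correlation of their 0/2 call vectors, which equals the
classical haplotype-count r² = D²/(p_A p_a p_B p_b).  Pairs are formed within
chromosomes only; decay curves are Gaussian-kernel regressions of r² on
log10(distance), evaluated per chromosome and pooled, with the summary
statistic d* = the first grid distance at which the smoothed curve drops to
r² = 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import MAJOR, MINOR, GenotypeMatrix


class LDError(ValueError):
    pass


@dataclass
class LDPairs:
    """Per-chromosome (distance bp, r²) pairs with subsampling metadata."""

    pairs: pd.DataFrame  # columns: chrom, dist, r2
    max_dist: int | None
    max_pairs: int | None
    subsampled: bool
    n_pairs_total: int  # before any subsampling
    n_skipped_monomorphic: int

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        return self.pairs[self.pairs["chrom"] == str(chrom)]


def pairwise_r2(
    gm: GenotypeMatrix,
    max_dist: int | None = None,
    max_pairs: int | None = None,
    seed: int = 0,
) -> LDPairs:
    """All within-chromosome pairwise r² values (optionally capped).

    Monomorphic sites carry no LD information and are skipped (counted in
    ``n_skipped_monomorphic``).  When the number of eligible pairs exceeds
    ``max_pairs``, a seeded uniform subsample is taken and flagged.
    """
    bad = ~np.isin(gm.calls, (MAJOR, MINOR))
    if bad.any():
        raise LDError("pairwise_r2 requires a fully imputed {0, 2} matrix")
    rng = np.random.default_rng(seed)
    frames = []
    n_total = 0
    n_mono = 0
    any_poly = False
    for chrom, sl in gm.chrom_slices().items():
        block = gm.calls[:, sl].astype(np.float64)
        pos = gm.sites["pos"].iloc[sl].to_numpy()
        poly = block.std(axis=0) > 0
        n_mono += int((~poly).sum())
        block, pos = block[:, poly], pos[poly]
        m = block.shape[1]
        if m < 2:
            continue
        any_poly = True
        iu, ju = np.triu_indices(m, k=1)
        dist = pos[ju] - pos[iu]
        if max_dist is not None:
            keep = dist <= max_dist
            iu, ju, dist = iu[keep], ju[keep], dist[keep]
        n_total += len(iu)
        if max_pairs is not None and len(iu) > max_pairs:
            pick = rng.choice(len(iu), size=max_pairs, replace=False)
            iu, ju, dist = iu[pick], ju[pick], dist[pick]
        z = (block - block.mean(axis=0)) / block.std(axis=0)
        n = block.shape[0]
        r = np.einsum("ki,ki->i", z[:, iu], z[:, ju]) / n
        frames.append(
            pd.DataFrame({"chrom": str(chrom), "dist": dist, "r2": r**2})
        )
    if not any_poly:
        raise LDError("fewer than 2 polymorphic sites on every chromosome")
    pairs = pd.concat(frames, ignore_index=True)
    return LDPairs(
        pairs=pairs,
        max_dist=max_dist,
        max_pairs=max_pairs,
        subsampled=max_pairs is not None and n_total > len(pairs),
        n_pairs_total=n_total,
        n_skipped_monomorphic=n_mono,
    )


def haplotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Classical two-locus haplotype r² = D² / (p_A p_a p_B p_b).

    ``x`` and ``y`` are haploid allele vectors in {0, 1} (one haplotype per
    line).  Returns NaN for monomorphic input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    p_a, p_b = x.mean(), y.mean()
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom == 0:
        return float("nan")
    d = (x * y).mean() - p_a * p_b
    return float(d * d / denom)


@dataclass
class DecayCurve:
    """Smoothed r²(distance) per chromosome and pooled, on a log grid."""

    grid: np.ndarray  # distances (bp), strictly increasing
    curves: dict  # chrom -> smoothed r2 on grid; "pooled" key included
    bandwidth: float  # in log10(bp) units
    d_star: dict  # chrom -> crossing distance of r2=0.2 (None if no crossing)
    threshold: float = 0.2


def _kernel_smooth(logd: np.ndarray, r2: np.ndarray, loggrid: np.ndarray,
                   bandwidth: float) -> np.ndarray:
    # Nadaraya-Watson with a Gaussian kernel, chunked over the grid
    out = np.empty(len(loggrid))
    for i, g in enumerate(loggrid):
        w = np.exp(-0.5 * ((logd - g) / bandwidth) ** 2)
        s = w.sum()
        out[i] = (w @ r2) / s if s > 0 else np.nan
    return out


def _crossing(grid: np.ndarray, curve: np.ndarray, threshold: float):
    """First grid distance where the smoothed curve drops to <= threshold,
    provided the curve actually starts above it."""
    finite = np.isfinite(curve)
    if not finite.any():
        return None
    first = np.flatnonzero(finite)[0]
    if curve[first] <= threshold:
        return None
    below = np.flatnonzero(finite & (curve <= threshold))
    if len(below) == 0:
        return None
    return float(grid[below[0]])


def decay_curve(
    ld: LDPairs,
    bandwidth: float | None = None,
    n_grid: int = 200,
    threshold: float = 0.2,
) -> DecayCurve:
    """Kernel regression of r² on log10(distance), per chromosome and pooled.

    ``bandwidth`` (log10-bp units) defaults to Silverman's rule of thumb on
    the pooled log-distances, floored at 0.05.
    """
    pairs = ld.pairs
    if len(pairs) == 0:
        raise LDError("no LD pairs to smooth")
    logd_all = np.log10(pairs["dist"].to_numpy())
    lo, hi = logd_all.min(), logd_all.max()
    if hi == lo:
        hi = lo + 1e-9
    loggrid = np.linspace(lo, hi, n_grid)
    grid = 10.0 ** loggrid
    if bandwidth is None:
        sd = logd_all.std()
        bandwidth = max(0.05, 1.06 * sd * len(logd_all) ** (-1 / 5)) if sd > 0 else 0.05

    curves: dict = {}
    d_star: dict = {}
    for chrom in pairs["chrom"].unique():
        sub = pairs[pairs["chrom"] == chrom]
        c = _kernel_smooth(
            np.log10(sub["dist"].to_numpy()), sub["r2"].to_numpy(), loggrid, bandwidth
        )
        curves[str(chrom)] = c
        d_star[str(chrom)] = _crossing(grid, c, threshold)
    pooled = _kernel_smooth(logd_all, pairs["r2"].to_numpy(), loggrid, bandwidth)
    curves["pooled"] = pooled
    d_star["pooled"] = _crossing(grid, pooled, threshold)
    return DecayCurve(grid=grid, curves=curves, bandwidth=bandwidth,
                      d_star=d_star, threshold=threshold)


def plot_decay(curve: DecayCurve, path: str) -> None:
    """Write a decay plot (per-chromosome curves plus pooled trend)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for chrom, c in curve.curves.items():
        if chrom == "pooled":
            continue
        ax.plot(curve.grid, c, lw=0.8, alpha=0.7, label=f"chr {chrom}")
    ax.plot(curve.grid, curve.curves["pooled"], color="black", lw=2, label="pooled")
    ax.axhline(curve.threshold, color="grey", ls="--", lw=0.8)
    ax.set_xscale("log")
    ax.set_xlabel("distance (bp)")
    ax.set_ylabel(r"$r^2$")
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
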