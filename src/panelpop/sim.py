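"""Synthetic structured inbred-panel generator.

Emulates, at the genotype-matrix level, a panel of expected-homozygous maize
lines drawn from a few diverged breeding pools and genotyped on two
partially-overlapping marker platforms:

* **Divergence** — per-group allele frequencies follow the Balding–Nichols
  model: ``p_g ~ Beta(p(1-F)/F, (1-p)(1-F)/F)`` around an ancestral frequency
  ``p ~ U(0.1, 0.9)``, so the expected fixation index among groups equals the
  configured ``divergence_F``.
* **Relatedness and LD** — each group starts from a small founder pool;
  descendant lines are made by crossing two same-group parents, recombining
  (Poisson crossover count, uniform breakpoints) and collapsing the gamete to
  a doubled-haploid homozygous line.  Repeated "recycling" rounds give
  pedigree relatedness and chromosome-scale linkage disequilibrium.
* **Structured missingness** — per-individual missing rates are drawn around
  ``miss_rate_mean`` and inflated linearly with allele-sharing distance to a
  designated reference line, mimicking reference-alignment bias.
* **Call noise** — residual heterozygous and third-allele calls are injected
  uniformly at random to exercise QC.

The generator returns two platform-restricted matrices (site sets overlap by
``platform_overlap`` of their union; individuals are split across platforms)
plus a :class:`SimTruth` with the complete pre-masking matrix and ground-truth
labels for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import HET, MISSING, TERTIARY, GenotypeMatrix, sort_sites

_BASES = np.array(list("ACGT"))


class SimConfigError(ValueError):
    """Raised for degenerate or out-of-range generator configurations."""


@dataclass
class SimConfig:
    """Generator parameters. Defaults describe the panel used throughout the
    test-suite: 3 diverged groups of 44 inbred lines on 10 compressed
    200-kb chromosomes of 1,000 sites each."""

    n_groups: int = 3
    lines_per_group: int = 44
    n_founders_per_group: int = 2
    n_chrom: int = 10
    sites_per_chrom: int = 1000
    chrom_length_bp: int = 200_000
    divergence_F: float | tuple = 0.15
    recycle_generations: int = 2
    recomb_rate: float = 10.0
    miss_rate_mean: float = 0.0622
    miss_rate_sd: float = 0.03
    ref_bias_weight: float = 0.05
    het_rate: float = 0.0025
    tertiary_rate: float = 0.001
    platform_overlap: float = 0.172
    platform1_fraction: float = 291.0 / 349.0
    seed: int = 0

    def group_F(self) -> np.ndarray:
        f = self.divergence_F
        if np.isscalar(f):
            arr = np.full(self.n_groups, float(f))
        else:
            arr = np.asarray(f, dtype=float)
        if arr.shape != (self.n_groups,):
            raise SimConfigError(
                f"divergence_F must be scalar or length {self.n_groups}"
            )
        return arr

    def validate(self) -> None:
        counts = {
            "n_groups": self.n_groups,
            "lines_per_group": self.lines_per_group,
            "n_founders_per_group": self.n_founders_per_group,
            "n_chrom": self.n_chrom,
            "sites_per_chrom": self.sites_per_chrom,
            "chrom_length_bp": self.chrom_length_bp,
        }
        for name, v in counts.items():
            if int(v) != v or v <= 0:
                raise SimConfigError(f"{name} must be a positive integer, got {v}")
        if self.sites_per_chrom > self.chrom_length_bp:
            raise SimConfigError("more sites than base pairs on a chromosome")
        fracs = {
            "miss_rate_mean": self.miss_rate_mean,
            "het_rate": self.het_rate,
            "tertiary_rate": self.tertiary_rate,
            "platform1_fraction": self.platform1_fraction,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.platform_overlap <= 1.0:
            raise SimConfigError("platform_overlap must lie in (0, 1]")
        F = self.group_F()
        if ((F < 0) | (F >= 1)).any():
            raise SimConfigError("divergence_F values must lie in [0, 1)")
        if self.miss_rate_sd < 0 or self.recomb_rate < 0 or self.ref_bias_weight < 0:
            raise SimConfigError("rates must be non-negative")
        if self.recycle_generations < 0:
            raise SimConfigError("recycle_generations must be >= 0")
        if self.recycle_generations > 0:
            if self.n_founders_per_group < 2:
                raise SimConfigError(
                    "recycling requires at least 2 founders per group"
                )
            if self.lines_per_group < 2:
                raise SimConfigError(
                    "recycling requires lines_per_group >= 2 (two parents per cross)"
                )


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated panel."""

    group_labels: list[str]
    ancestral_freq: np.ndarray
    group_freq: np.ndarray  # (n_groups, n_sites)
    complete: GenotypeMatrix  # zero missing calls, {0, 2} only
    pedigree: list[tuple[str, str, str]]  # (child, parent1, parent2)

    def labels_for(self, names) -> list[str]:
        lookup = dict(zip(self.complete.individuals, self.group_labels))
        return [lookup[n] for n in names]


def _site_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    frames = []
    for c in range(1, cfg.n_chrom + 1):
        pos = np.sort(
            rng.choice(cfg.chrom_length_bp, size=cfg.sites_per_chrom, replace=False)
        ) + 1
        frames.append(pd.DataFrame({"chrom": str(c), "pos": pos}))
    sites = pd.concat(frames, ignore_index=True)
    ref_i = rng.integers(0, 4, size=len(sites))
    alt_i = (ref_i + rng.integers(1, 4, size=len(sites))) % 4
    sites["ref"] = _BASES[ref_i]
    sites["alt"] = _BASES[alt_i]
    return sites


def _gamete(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    sites: pd.DataFrame,
    chrom_bounds: list[tuple[int, int]],
    recomb_rate: float,
    chrom_length: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Recombinant haploid gamete from two homozygous parents."""
    out = np.empty_like(hap_a)
    pos = sites["pos"].to_numpy()
    for lo, hi in chrom_bounds:
        k = rng.poisson(recomb_rate)
        start = rng.integers(0, 2)
        if k == 0:
            seg = np.full(hi - lo, start)
        else:
            breaks = np.sort(rng.uniform(0, chrom_length, size=k))
            seg = (start + np.searchsorted(breaks, pos[lo:hi])) % 2
        block = np.where(seg == 0, hap_a[lo:hi], hap_b[lo:hi])
        out[lo:hi] = block
    return out


def simulate_panel(config: SimConfig):
    """Simulate a structured inbred panel.

    Returns
    -------
    (platform1, platform2, truth)
        Two platform-restricted :class:`~panelpop.matrix.GenotypeMatrix`
        objects with structured missingness and call noise, and the
        :class:`SimTruth` ground truth (complete matrix over all individuals
        and sites, group labels, allele frequencies, pedigree).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    F = config.group_F()

    sites = _site_table(config, rng)
    n_sites = len(sites)
    chrom_bounds = [
        (c * config.sites_per_chrom, (c + 1) * config.sites_per_chrom)
        for c in range(config.n_chrom)
    ]

    ancestral = rng.uniform(0.1, 0.9, size=n_sites)
    group_freq = np.empty((config.n_groups, n_sites))
    for g in range(config.n_groups):
        if F[g] == 0.0:
            group_freq[g] = ancestral
        else:
            scale = (1.0 - F[g]) / F[g]
            group_freq[g] = rng.beta(scale * ancestral, scale * (1.0 - ancestral))

    haplotypes = np.empty((config.n_groups * config.lines_per_group, n_sites), dtype=np.int8)
    names: list[str] = []
    labels: list[str] = []
    pedigree: list[tuple[str, str, str]] = []

    # Founder draws are coupled across groups through shared uniforms: founder
    # k of every group uses the same u_{k,s}, so each founder haplotype is ~
    # Bernoulli(group frequency) marginally (exact Balding-Nichols within
    # group) while groups share an ancestral haplotype background and differ
    # only where their frequencies diverge - as diverged breeding pools of one
    # species do.  Lines drawn without recycling stay fully independent.
    founder_u = rng.random((config.n_founders_per_group, n_sites))

    for g in range(config.n_groups):
        gname = f"G{g + 1}"
        if config.recycle_generations == 0:
            pool = rng.binomial(1, group_freq[g], size=(config.lines_per_group, n_sites)).astype(np.int8)
            pool_names = [f"{gname}_L{i:03d}" for i in range(config.lines_per_group)]
        else:
            pool = (founder_u < group_freq[g]).astype(np.int8)
            pool_names = [f"{gname}_F{i:02d}" for i in range(config.n_founders_per_group)]
            for gen in range(1, config.recycle_generations + 1):
                tag = "L" if gen == config.recycle_generations else f"R{gen}"
                children = np.empty((config.lines_per_group, n_sites), dtype=np.int8)
                child_names = []
                for j in range(config.lines_per_group):
                    ia, ib = rng.choice(len(pool), size=2, replace=False)
                    children[j] = _gamete(
                        pool[ia], pool[ib], sites, chrom_bounds,
                        config.recomb_rate, config.chrom_length_bp, rng,
                    )
                    cname = f"{gname}_{tag}{j:03d}"
                    child_names.append(cname)
                    pedigree.append((cname, pool_names[ia], pool_names[ib]))
                pool, pool_names = children, child_names
        lo = g * config.lines_per_group
        haplotypes[lo:lo + config.lines_per_group] = pool
        names.extend(pool_names)
        labels.extend([gname] * config.lines_per_group)

    complete_calls = (2 * haplotypes).astype(np.int8)
    complete = GenotypeMatrix(complete_calls, sites, names)
    truth = SimTruth(
        group_labels=labels,
        ancestral_freq=ancestral,
        group_freq=group_freq,
        complete=complete,
        pedigree=pedigree,
    )

    # ---- platform site sets: shared fraction of the union, rest split ----
    shared_n = int(np.rint(config.platform_overlap * n_sites))
    shared_n = max(1, min(n_sites, shared_n))
    perm = rng.permutation(n_sites)
    shared = perm[:shared_n]
    private = perm[shared_n:]
    half = len(private) // 2
    p1_sites = np.sort(np.concatenate([shared, private[:half]]))
    p2_sites = np.sort(np.concatenate([shared, private[half:]]))

    # ---- individual split across platforms -------------------------------
    n_ind = len(names)
    n1 = int(np.rint(config.platform1_fraction * n_ind))
    n1 = min(max(n1, 1), n_ind - 1) if n_ind > 1 else 1
    ind_perm = rng.permutation(n_ind)
    p1_ind = np.sort(ind_perm[:n1])
    p2_ind = np.sort(ind_perm[n1:])

    # ---- structured missingness ------------------------------------------
    ref_hap = haplotypes[0]  # designated reference line (like B73)
    dist_to_ref = (haplotypes != ref_hap).mean(axis=1)
    base = rng.normal(config.miss_rate_mean, config.miss_rate_sd, size=n_ind)
    miss_rate = np.clip(base, 0.0, 1.0) + config.ref_bias_weight * dist_to_ref
    miss_rate = np.clip(miss_rate, 0.0, 0.95)

    def build_platform(ind_idx, site_idx, tag):
        calls = complete_calls[np.ix_(ind_idx, site_idx)].copy()
        u = rng.random(calls.shape)
        calls[u < miss_rate[ind_idx][:, None]] = MISSING
        obs = calls != MISSING
        noise = rng.random(calls.shape)
        calls[obs & (noise < config.het_rate)] = HET
        calls[obs & (noise >= config.het_rate)
              & (noise < config.het_rate + config.tertiary_rate)] = TERTIARY
        return GenotypeMatrix(
            calls,
            sites.iloc[site_idx],
            [names[i] for i in ind_idx],
            provenance=[tag] * len(ind_idx),
        )

    gm1 = build_platform(p1_ind, p1_sites, "platform1")
    gm2 = build_platform(p2_ind, p2_sites, "platform2")
    return gm1, gm2, truth


class MaskError(ValueError):
    """Raised when a masking request cannot be satisfied."""


def mask_genotypes(gm: GenotypeMatrix, fraction: float, seed: int):
    """Set ``round(fraction * n_non_missing)`` observed cells to MISSING.

    Returns the masked copy and the ``(rows, cols)`` index arrays of the
    masked cells, so the original calls can be restored or scored against.
    """
    if not 0.0 < fraction < 1.0:
        raise MaskError(f"mask fraction must lie in (0, 1), got {fraction}")
    rows, cols = np.nonzero(gm.calls != MISSING)
    n_maskable = len(rows)
    k = int(np.rint(fraction * n_maskable))
    if k == 0:
        raise MaskError(
            f"fraction {fraction} of {n_maskable} maskable cells rounds to zero"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(n_maskable, size=k, replace=False)
    masked = gm.copy()
    masked.calls[rows[pick], cols[pick]] = MISSING
    return masked, (rows[pick], cols[pick])
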