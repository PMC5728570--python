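"""Site-level quality control for merged inbred-panel genotypes.

The filtering pipeline mirrors standard GBS practice for inbred panels:
heterozygous and third-allele calls are first converted to missing (the
downstream analyses assume two alleles and homozygous lines), then sites are
dropped on recomputed missingness and minor-allele-frequency thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import HET, MAJOR, MINOR, MISSING, TERTIARY, GenotypeMatrix


class FilterError(ValueError):
    pass


@dataclass
class FilterConfig:
    """Thresholds for :func:`apply_filters`.

    ``site_missing_max`` defaults to 0.172: sites missing in more than 17.2 %
    of individuals are dropped.  ``individual_missing_max`` is a report-only
    check (no individuals are removed); the default cap of 0.30 flags any
    individual whose post-filter missingness exceeds it.
    """

    maf_min: float = 0.05
    site_missing_max: float = 0.172
    het_to_missing: bool = True
    tertiary_to_missing: bool = True
    individual_missing_max: float | None = 0.30
    #: recompute MAF before (default) or after the HET/TERTIARY conversion
    maf_before_conversion: bool = False

    def validate(self) -> None:
        for name in ("maf_min", "site_missing_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise FilterError(f"{name} must lie in [0, 1], got {v}")
        if self.individual_missing_max is not None and not (
            0.0 <= self.individual_missing_max <= 1.0
        ):
            raise FilterError("individual_missing_max must lie in [0, 1]")


def site_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-site missing fraction, MAF, het fraction and allele count.

    MAF is computed from non-missing, non-het, non-tertiary calls as the
    smaller of the two homozygote-class frequencies.  Sites with no usable
    calls get ``maf = NaN`` and ``maf_defined = False``.
    """
    if gm.n_sites == 0 or gm.n_individuals == 0:
        raise FilterError("site_stats requires a non-empty matrix")
    calls = gm.calls
    n = gm.n_individuals
    n_missing = (calls == MISSING).sum(axis=0)
    n_het = (calls == HET).sum(axis=0)
    n_tert = (calls == TERTIARY).sum(axis=0)
    n_major = (calls == MAJOR).sum(axis=0)
    n_minor = (calls == MINOR).sum(axis=0)
    usable = n_major + n_minor
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(usable > 0, n_minor / np.maximum(usable, 1), np.nan)
        maf = np.minimum(p, 1.0 - p)
    n_alleles = (n_major > 0).astype(int) + (n_minor > 0).astype(int) + (
        n_tert > 0
    ).astype(int)
    return pd.DataFrame(
        {
            "chrom": gm.sites["chrom"].to_numpy(),
            "pos": gm.sites["pos"].to_numpy(),
            "missing_frac": n_missing / n,
            "maf": maf,
            "het_frac": n_het / n,
            "n_alleles": n_alleles,
            "maf_defined": usable > 0,
        }
    )


@dataclass
class FilterReport:
    """Accounting for one :func:`apply_filters` run."""

    n_sites_before: int
    n_sites_after: int
    n_removed_missing: int
    n_removed_maf: int
    n_het_converted: int
    n_tertiary_converted: int
    individual_missing_frac: pd.Series  # indexed by individual name
    pct_missing: float
    pct_het: float
    individuals_over_cap: list[str]

    @property
    def removed_total(self) -> int:
        return self.n_removed_missing + self.n_removed_maf

    def summary(self) -> pd.DataFrame:
        im = self.individual_missing_frac
        return pd.DataFrame(
            {
                "Statistic": [
                    "Sites before", "Sites after",
                    "Removed: site missingness", "Removed: MAF",
                    "HET calls converted", "TERTIARY calls converted",
                    "Percent missing", "Percent het",
                    "Per-individual missing mean", "Per-individual missing median",
                    "Per-individual missing max", "Per-individual missing min",
                ],
                "Value": [
                    self.n_sites_before, self.n_sites_after,
                    self.n_removed_missing, self.n_removed_maf,
                    self.n_het_converted, self.n_tertiary_converted,
                    self.pct_missing, self.pct_het,
                    float(im.mean()), float(im.median()),
                    float(im.max()), float(im.min()),
                ],
            }
        )


def apply_filters(gm: GenotypeMatrix, cfg: FilterConfig | None = None):
    """Convert HET/TERTIARY calls to missing, then drop sites.

    Order of operations: (1) HET -> MISSING, (2) TERTIARY -> MISSING,
    (3) drop sites whose recomputed missing fraction exceeds
    ``site_missing_max``, (4) drop sites with recomputed MAF below
    ``maf_min``.  The output matrix contains only {0, 2, MISSING}.
    """
    cfg = cfg or FilterConfig()
    cfg.validate()
    out = gm.copy()
    maf_pre = site_stats(out)["maf"] if cfg.maf_before_conversion else None

    n_het_conv = n_tert_conv = 0
    if cfg.het_to_missing:
        mask = out.calls == HET
        n_het_conv = int(mask.sum())
        out.calls[mask] = MISSING
    if cfg.tertiary_to_missing:
        mask = out.calls == TERTIARY
        n_tert_conv = int(mask.sum())
        out.calls[mask] = MISSING

    stats = site_stats(out)
    maf = maf_pre.to_numpy() if maf_pre is not None else stats["maf"].to_numpy()
    miss = stats["missing_frac"].to_numpy()

    fail_miss = miss > cfg.site_missing_max
    with np.errstate(invalid="ignore"):
        fail_maf = ~(maf >= cfg.maf_min)  # NaN MAF (all-missing site) fails too
    keep = ~(fail_miss | fail_maf)
    n_removed_missing = int(fail_miss.sum())
    # a site failing both rules is attributed to the missingness rule (step 3)
    n_removed_maf = int((fail_maf & ~fail_miss).sum())
    if not keep.any():
        raise FilterError(
            "no sites survive the configured filters "
            f"(maf_min={cfg.maf_min}, site_missing_max={cfg.site_missing_max})"
        )
    out = out.take_sites(np.flatnonzero(keep))

    total = out.total_data_points()
    n_missing = out.n_missing()
    ind_missing = pd.Series(
        (out.calls == MISSING).mean(axis=1), index=out.individuals, name="missing_frac"
    )
    over_cap = []
    if cfg.individual_missing_max is not None:
        over_cap = list(ind_missing.index[ind_missing > cfg.individual_missing_max])
    report = FilterReport(
        n_sites_before=gm.n_sites,
        n_sites_after=out.n_sites,
        n_removed_missing=n_removed_missing,
        n_removed_maf=n_removed_maf,
        n_het_converted=n_het_conv,
        n_tertiary_converted=n_tert_conv,
        individual_missing_frac=ind_missing,
        pct_missing=100.0 * n_missing / total if total else 0.0,
        pct_het=100.0 * out.n_het() / total if total else 0.0,
        individuals_over_cap=over_cap,
    )
    return out, report
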