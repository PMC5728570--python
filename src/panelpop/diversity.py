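"""Weir-Cockerham F_ST scanning and candidate-region reporting.

The per-locus fixation index theta is estimated with the weighted
analysis-of-variance estimator in its haploid form, appropriate for inbred
lines whose heterozygous calls were removed during QC: with ``r`` groups and
``n_i`` non-missing lines at frequency ``p_i``,

    p_bar = sum(n_i p_i) / sum(n_i)
    n_c   = (sum(n_i) - sum(n_i^2)/sum(n_i)) / (r - 1)
    MSP   = sum(n_i (p_i - p_bar)^2) / (r - 1)
    MSG   = sum(n_i p_i (1 - p_i)) / sum(n_i - 1)
    theta = (MSP - MSG) / (MSP + (n_c - 1) MSG)

The overall statistic defaults to the simple average of defined per-locus
theta values; a ratio-of-sums variant is available by flag.  Around the
per-locus scan the module provides balanced maximally-unrelated subsampling,
a sliding-window genome scan, top-region extraction and gene-proximity
queries against a GFF3 or TSV annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import MINOR, MISSING, GenotypeMatrix
from .structure import DistanceMatrix


class DiversityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# balanced, maximally-unrelated subsampling
# ---------------------------------------------------------------------------

def select_balanced_unrelated(
    dm: DistanceMatrix, labels, target_per_group: int
) -> list[str]:
    """Pick ``target_per_group`` members per group, greedily dropping kin.

    Within each group, the member of the current closest pair with the
    smaller average distance to the rest of the group is removed (ties break
    lexicographically) until the target size remains.  Exact-duplicate pairs
    (distance 0) therefore go first.  Deterministic.
    """
    labels = pd.Series(labels, index=dm.names) if not isinstance(labels, pd.Series) else labels
    kept: list[str] = []
    for group in sorted(set(labels)):
        members = [n for n in dm.names if labels[n] == group]
        if len(members) < target_per_group:
            raise DiversityError(
                f"group {group!r} has {len(members)} members, fewer than the "
                f"target {target_per_group}"
            )
        current = list(members)
        while len(current) > target_per_group:
            sub = dm.submatrix(current).values
            np.fill_diagonal(sub, np.inf)
            i, j = divmod(int(np.argmin(sub)), len(current))
            cand = sorted((current[i], current[j]))
            sub_no_diag = dm.submatrix(current).values
            mean_d = {}
            for name in cand:
                k = current.index(name)
                others = [x for x in range(len(current)) if x != k]
                mean_d[name] = sub_no_diag[k, others].mean()
            # remove the candidate closer on average to the rest of the group
            drop = min(cand, key=lambda nm: (mean_d[nm], nm))
            current.remove(drop)
        kept.extend(current)
    return kept


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    """Per-locus variance components and theta, plus the overall mean."""

    sites: pd.DataFrame  # chrom, pos
    p_group: np.ndarray  # (n_groups, n_loci) minor-allele frequency
    n_group: np.ndarray  # (n_groups, n_loci) non-missing line counts
    p_bar: np.ndarray
    n_c: np.ndarray
    msp: np.ndarray
    msg: np.ndarray
    theta: np.ndarray  # NaN where undefined
    overall: float
    overall_method: str
    group_names: list[str]

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.theta)

    def per_locus_frame(self) -> pd.DataFrame:
        df = self.sites[["chrom", "pos"]].copy()
        df["theta"] = self.theta
        return df


def fst_weir_cockerham(
    gm: GenotypeMatrix,
    labels,
    overall_method: str = "mean",
) -> FstResult:
    """Per-locus and overall Weir-Cockerham theta for grouped inbred lines.

    ``labels`` maps each individual of ``gm`` to its group.  Loci where fewer
    than two groups have at least two non-missing calls, or that are
    monomorphic across all groups, get ``theta = NaN`` and are excluded from
    the overall statistic.  ``overall_method`` is ``"mean"`` (simple average
    of per-locus theta) or ``"ratio"`` (ratio of summed variance components).
    """
    if overall_method not in ("mean", "ratio"):
        raise DiversityError(f"unknown overall_method {overall_method!r}")
    labels = (
        labels if isinstance(labels, pd.Series)
        else pd.Series(list(labels), index=gm.individuals)
    )
    groups = sorted(set(labels.loc[gm.individuals]))
    r = len(groups)
    if r < 2:
        raise DiversityError("theta requires at least 2 groups")
    m = gm.n_sites
    p = np.empty((r, m))
    nmat = np.empty((r, m))
    for gi, g in enumerate(groups):
        rows = [i for i, name in enumerate(gm.individuals) if labels[name] == g]
        block = gm.calls[rows]
        obs = block != MISSING
        nmat[gi] = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p[gi] = np.where(
                nmat[gi] > 0,
                ((block == MINOR) & obs).sum(axis=0) / np.maximum(nmat[gi], 1),
                np.nan,
            )

    usable = nmat >= 2
    estimable = usable.sum(axis=0) >= 2
    # restrict each locus to its usable groups
    n_eff = np.where(usable, nmat, 0.0)
    p_eff = np.where(usable, p, 0.0)
    n_sum = n_eff.sum(axis=0)
    r_eff = usable.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_bar = (n_eff * p_eff).sum(axis=0) / n_sum
        n_c = (n_sum - (n_eff**2).sum(axis=0) / n_sum) / (r_eff - 1)
        msp = (n_eff * (p_eff - p_bar) ** 2).sum(axis=0) / (r_eff - 1)
        msg = (n_eff * p_eff * (1 - p_eff)).sum(axis=0) / (n_eff - usable).sum(axis=0)
        denom = msp + (n_c - 1) * msg
        theta = np.where(estimable & (denom > 0), (msp - msg) / denom, np.nan)

    defined = np.isfinite(theta)
    if overall_method == "mean":
        overall = float(np.nanmean(theta)) if defined.any() else float("nan")
    else:
        num = np.nansum(np.where(defined, msp - msg, 0.0))
        den = np.nansum(np.where(defined, denom, 0.0))
        overall = float(num / den) if den > 0 else float("nan")
    return FstResult(
        sites=gm.sites[["chrom", "pos"]].copy(),
        p_group=p,
        n_group=nmat,
        p_bar=p_bar,
        n_c=n_c,
        msp=msp,
        msg=msg,
        theta=theta,
        overall=overall,
        overall_method=overall_method,
        group_names=[str(g) for g in groups],
    )


# ---------------------------------------------------------------------------
# window scan and regions
# ---------------------------------------------------------------------------

def fst_window_scan(fst: FstResult, window_snps: int = 70) -> pd.DataFrame:
    """Sliding mean of theta over ``window_snps`` consecutive defined loci.

    Windows never span chromosome boundaries; chromosomes with fewer defined
    loci than the window are skipped with a warning.  Each window is anchored
    to the positions of its first and last markers.
    """
    if window_snps < 1:
        raise DiversityError("window_snps must be >= 1")
    rows = []
    df = fst.per_locus_frame()
    df = df[np.isfinite(df["theta"])]
    if df.empty:
        raise DiversityError("no defined theta values to scan")
    for chrom, sub in df.groupby("chrom", sort=False):
        theta = sub["theta"].to_numpy()
        pos = sub["pos"].to_numpy()
        if len(theta) < window_snps:
            warnings.warn(
                f"chromosome {chrom}: {len(theta)} defined loci < window "
                f"{window_snps}; skipped"
            )
            continue
        csum = np.concatenate([[0.0], np.cumsum(theta)])
        means = (csum[window_snps:] - csum[:-window_snps]) / window_snps
        rows.append(
            pd.DataFrame(
                {
                    "chrom": str(chrom),
                    "start_pos": pos[: len(means)],
                    "end_pos": pos[window_snps - 1:],
                    "mean_theta": means,
                }
            )
        )
    if not rows:
        raise DiversityError("no chromosome had enough loci for the window")
    return pd.concat(rows, ignore_index=True)


@dataclass
class Region:
    """A genomic span anchored to its first and last markers (1-based bp)."""

    chrom: str
    first_pos: int
    last_pos: int
    mean_theta: float

    def __post_init__(self) -> None:
        if not self.first_pos < self.last_pos:
            raise DiversityError("region must satisfy first_pos < last_pos")

    @property
    def size(self) -> int:
        return self.last_pos - self.first_pos

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and start <= self.last_pos and end >= self.first_pos


def top_regions(scan: pd.DataFrame, n_regions: int) -> list[Region]:
    """Highest-mean-theta genomic regions from a window scan.

    Windows are visited in descending mean theta (ties by chromosome then
    position).  A window overlapping an already-opened region on its
    chromosome is absorbed into it (span union; the region keeps the highest
    window mean); otherwise it opens a new region, until ``n_regions`` exist.
    Returned sorted by mean theta descending, ties by (chromosome, position).
    """
    if scan.empty:
        raise DiversityError("empty window scan")
    order = scan.sort_values(
        by=["mean_theta", "chrom", "start_pos"], ascending=[False, True, True]
    )
    regions: list[Region] = []
    for row in order.itertuples(index=False):
        merged = False
        for reg in regions:
            if reg.overlaps(row.chrom, int(row.start_pos), int(row.end_pos)):
                reg.first_pos = min(reg.first_pos, int(row.start_pos))
                reg.last_pos = max(reg.last_pos, int(row.end_pos))
                merged = True
                break
        if not merged:
            if len(regions) >= n_regions:
                continue
            regions.append(
                Region(
                    chrom=str(row.chrom),
                    first_pos=int(row.start_pos),
                    last_pos=int(row.end_pos),
                    mean_theta=float(row.mean_theta),
                )
            )
        if len(regions) == n_regions and not merged:
            # quota just filled; later windows may still be absorbed into
            # existing regions via the overlap branch above
            continue
    if len(regions) < n_regions:
        warnings.warn(
            f"only {len(regions)} distinct regions available, "
            f"{n_regions} requested"
        )
    regions.sort(key=lambda r: (-r.mean_theta, r.chrom, r.first_pos))
    return regions


def regions_to_bed(regions: list[Region], path: str) -> None:
    """Write regions as BED (0-based half-open), converted from the internal
    1-based closed convention."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.first_pos - 1}\t{r.last_pos}\t{r.mean_theta:.4f}\n")


# ---------------------------------------------------------------------------
# candidate genes
# ---------------------------------------------------------------------------

@dataclass
class GeneHit:
    chrom: str
    pos: int
    theta: float
    gene_id: str
    description: str
    distance: int  # 0 when the SNP lies inside the gene


def read_annotation(path: str) -> pd.DataFrame:
    """Gene intervals as a frame with columns chrom, start, end, gene_id,
    description (1-based inclusive coordinates).

    ``.gff3``/``.gff`` files are parsed with :mod:`gffutils` (``gene``
    features; description taken from the ``description`` or ``product``
    attribute when present); anything else is read as 4/5-column TSV.
    """
    if str(path).endswith((".gff3", ".gff")):
        import gffutils

        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        rows = []
        for gene in db.features_of_type("gene"):
            desc = (gene.attributes.get("description")
                    or gene.attributes.get("product") or [""])[0]
            gid = (gene.attributes.get("ID") or gene.attributes.get("Name")
                   or [gene.id])[0]
            rows.append((gene.seqid, gene.start, gene.end, gid, desc))
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "gene_id", "description"]
        )
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise DiversityError("TSV annotation needs >= 4 columns")
    df = df.iloc[:, :5] if df.shape[1] >= 5 else df.assign(description="")
    df.columns = ["chrom", "start", "end", "gene_id", "description"][: df.shape[1]]
    if "description" not in df.columns:
        df["description"] = ""
    df["chrom"] = df["chrom"].astype(str)
    return df


def candidate_genes(
    fst: FstResult,
    annotation: pd.DataFrame,
    half_window: int = 10_000,
    theta_min: float = 0.6,
) -> list[GeneHit]:
    """Genes within ``half_window`` bp of each high-theta SNP.

    A gene is a hit when its (1-based, closed) interval intersects
    ``[pos - half_window, pos + half_window]``; distance is 0 for a SNP
    inside the gene, else the gap to the nearer gene end.  Annotation rows on
    chromosomes absent from the panel are skipped with a warning.
    """
    known = set(fst.sites["chrom"].astype(str))
    unknown = set(annotation["chrom"].astype(str)) - known
    if unknown:
        warnings.warn(
            f"annotation chromosomes not in panel, skipped: {sorted(unknown)}"
        )
    ann = annotation[annotation["chrom"].astype(str).isin(known)]
    hits: list[GeneHit] = []
    high = np.flatnonzero(np.isfinite(fst.theta) & (fst.theta >= theta_min))
    for i in high:
        chrom = str(fst.sites["chrom"].iloc[i])
        pos = int(fst.sites["pos"].iloc[i])
        lo, hi = pos - half_window, pos + half_window
        sub = ann[(ann["chrom"] == chrom) & (ann["start"] <= hi) & (ann["end"] >= lo)]
        for g in sub.itertuples(index=False):
            if g.start <= pos <= g.end:
                dist = 0
            else:
                dist = min(abs(pos - g.start), abs(pos - g.end))
            hits.append(
                GeneHit(
                    chrom=chrom, pos=pos, theta=float(fst.theta[i]),
                    gene_id=str(g.gene_id), description=str(g.description),
                    distance=int(dist),
                )
            )
    return hits
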