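"""Reading, writing and merging of genotype matrices.

Two on-disk dialects are supported: the tab-separated HapMap genotype format
used by GBS pipelines (one row per site; single-letter IUPAC calls, ``N`` for
missing) and VCF 4.2 with diploid genotype strings (``0/0``, ``1/1``, ``0/1``,
``2/2`` for third-allele calls).  VCF parsing goes through :mod:`cyvcf2`.

:func:`merge` combines two platforms with disjoint individual sets into one
matrix keyed on (chromosome, position), with full merge accounting in a
:class:`MergeReport`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import (
    HET,
    MAJOR,
    MINOR,
    MISSING,
    TERTIARY,
    GenotypeMatrix,
    sort_sites,
)

_AMBIG = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}
_BASES = "ACGT"

_HAPMAP_HEADER = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]


class ParseError(ValueError):
    """Malformed genotype file; message names the offending line."""


class MergeError(ValueError):
    pass


def _third_base(ref: str, alt: str) -> str:
    for b in _BASES:
        if b not in (ref, alt):
            return b
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# HapMap dialect
# ---------------------------------------------------------------------------

def write_hapmap(gm: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write the HapMap tab-separated dialect (``N`` = missing call)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_HAPMAP_HEADER + gm.individuals) + "\n")
        ref = gm.sites["ref"].to_numpy()
        alt = gm.sites["alt"].to_numpy()
        for j in range(gm.n_sites):
            chrom = gm.sites["chrom"].iloc[j]
            pos = int(gm.sites["pos"].iloc[j])
            r, a = ref[j], alt[j]
            lut = {
                MAJOR: r,
                MINOR: a,
                HET: _AMBIG[frozenset((r, a))],
                TERTIARY: _third_base(r, a),
                MISSING: "N",
            }
            calls = "\t".join(lut[int(c)] for c in gm.calls[:, j])
            fh.write(
                f"S{chrom}_{pos}\t{r}/{a}\t{chrom}\t{pos}\t+\tNA\tNA\tNA\tNA\tNA\tNA\t{calls}\n"
            )


def read_hapmap(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a HapMap genotype file into a :class:`GenotypeMatrix`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 12 or header[1] != "alleles" or header[3] != "pos":
            raise ParseError(f"{path}: line 1: malformed HapMap header")
        names = header[11:]
        if len(set(names)) != len(names):
            raise ParseError(f"{path}: line 1: duplicate individual names")
        rows, meta, seen = [], [], set()
        for lineno, line in enumerate(fh, start=2):
            f = line.rstrip("\n").split("\t")
            if len(f) != 11 + len(names):
                raise ParseError(
                    f"{path}: line {lineno}: expected {11 + len(names)} fields, got {len(f)}"
                )
            alleles = f[1].split("/")
            if len(alleles) != 2 or any(a not in _BASES for a in alleles):
                raise ParseError(
                    f"{path}: line {lineno}: non-ACGT allele pair {f[1]!r}"
                )
            chrom, pos = f[2], f[3]
            try:
                pos = int(pos)
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: bad position {pos!r}") from None
            if (chrom, pos) in seen:
                raise ParseError(
                    f"{path}: line {lineno}: duplicate site {chrom}:{pos}"
                )
            seen.add((chrom, pos))
            r, a = alleles
            het_code = _AMBIG[frozenset((r, a))] if r != a else None
            row = np.empty(len(names), dtype=np.int8)
            for i, call in enumerate(f[11:]):
                if call == "N":
                    row[i] = MISSING
                elif call == r:
                    row[i] = MAJOR
                elif call == a:
                    row[i] = MINOR
                elif call == het_code:
                    row[i] = HET
                else:
                    row[i] = TERTIARY
            rows.append(row)
            meta.append((chrom, pos, r, a))
    if not rows:
        raise ParseError(f"{path}: no site records")
    calls = np.stack(rows, axis=1)
    sites = pd.DataFrame(meta, columns=["chrom", "pos", "ref", "alt"])
    calls, sites = sort_sites(calls, sites)
    return GenotypeMatrix(calls, sites, names)


# ---------------------------------------------------------------------------
# VCF 4.2
# ---------------------------------------------------------------------------

_VCF_GT = {MAJOR: "0/0", MINOR: "1/1", HET: "0/1", TERTIARY: "2/2", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write VCF 4.2; third-allele calls appear as a second ALT with GT 2/2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in gm.chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.individuals) + "\n"
        )
        has_tert = (gm.calls == TERTIARY).any(axis=0)
        for j in range(gm.n_sites):
            chrom = gm.sites["chrom"].iloc[j]
            pos = int(gm.sites["pos"].iloc[j])
            r, a = gm.sites["ref"].iloc[j], gm.sites["alt"].iloc[j]
            alt = f"{a},{_third_base(r, a)}" if has_tert[j] else a
            gts = "\t".join(_VCF_GT[int(c)] for c in gm.calls[:, j])
            fh.write(
                f"{chrom}\t{pos}\tS{chrom}_{pos}\t{r}\t{alt}\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Genotypes with both alleles 0 map to MAJOR, both 1 to MINOR, 0/1 to HET;
    any allele index >= 2 (third-or-higher allele) maps to TERTIARY.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as err:  # cyvcf2 raises bare exceptions on bad headers
        raise ParseError(f"{path}: cannot parse VCF: {err}") from err
    names = list(vcf.samples)
    rows, meta, seen = [], [], set()
    for v in vcf:
        key = (v.CHROM, v.POS)
        if key in seen:
            raise ParseError(f"{path}: duplicate site {v.CHROM}:{v.POS}")
        seen.add(key)
        ref = v.REF
        alt = v.ALT[0] if v.ALT else _third_base(ref, ref if ref != "A" else "C")
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            raise ParseError(
                f"{path}: site {v.CHROM}:{v.POS}: non-SNP or non-ACGT alleles"
            )
        row = np.empty(len(names), dtype=np.int8)
        for i, (a, b, *_phased) in enumerate(v.genotypes):
            if a < 0 or b < 0:
                row[i] = MISSING
            elif a >= 2 or b >= 2:
                row[i] = TERTIARY
            elif a == 0 and b == 0:
                row[i] = MAJOR
            elif a == 1 and b == 1:
                row[i] = MINOR
            else:
                row[i] = HET
        rows.append(row)
        meta.append((v.CHROM, v.POS, ref, alt))
    if not rows:
        raise ParseError(f"{path}: no variant records")
    calls = np.stack(rows, axis=1)
    sites = pd.DataFrame(meta, columns=["chrom", "pos", "ref", "alt"])
    calls, sites = sort_sites(calls, sites)
    return GenotypeMatrix(calls, sites, names)


def read_genotypes(path: str | os.PathLike) -> GenotypeMatrix:
    """Dispatch on extension: ``.vcf`` -> VCF, anything else -> HapMap."""
    if str(path).endswith((".vcf", ".vcf.gz")):
        return read_vcf(path)
    return read_hapmap(path)


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

@dataclass
class SetStats:
    """Per-matrix accounting block (one column of the merge summary table)."""

    n_individuals: int
    n_sites: int
    total_data_points: int
    n_missing: int
    pct_missing: float
    n_het: int
    pct_het: float

    @classmethod
    def from_matrix(cls, gm: GenotypeMatrix) -> "SetStats":
        total = gm.total_data_points()
        n_miss, n_het = gm.n_missing(), gm.n_het()
        return cls(
            n_individuals=gm.n_individuals,
            n_sites=gm.n_sites,
            total_data_points=total,
            n_missing=n_miss,
            pct_missing=100.0 * n_miss / total if total else 0.0,
            n_het=n_het,
            pct_het=100.0 * n_het / total if total else 0.0,
        )


@dataclass
class MergeReport:
    """Merge accounting: inputs, merged set, and the site overlap."""

    input1: SetStats
    input2: SetStats
    merged: SetStats
    n_common_sites: int
    pct_common: float  # 100 * common / merged sites
    n_conflict_sites: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "Inbreds": "n_individuals",
            "Sites": "n_sites",
            "Total data points": "total_data_points",
            "Missing SNPs": "n_missing",
            "Percent missing": "pct_missing",
            "No. Heterozygous": "n_het",
            "Percentage het.": "pct_het",
        }
        data = {
            "Statistic": list(rows),
            "Set 1": [getattr(self.input1, a) for a in rows.values()],
            "Set 2": [getattr(self.input2, a) for a in rows.values()],
            "Merged": [getattr(self.merged, a) for a in rows.values()],
        }
        df = pd.DataFrame(data)
        extra = pd.DataFrame(
            {
                "Statistic": [
                    "Sites common to both sets",
                    "Percent sites common to both sets",
                    "Conflicting-allele sites dropped",
                ],
                "Set 1": ["", "", ""],
                "Set 2": ["", "", ""],
                "Merged": [self.n_common_sites, self.pct_common, self.n_conflict_sites],
            }
        )
        return pd.concat([df, extra], ignore_index=True)


def _site_keys(gm: GenotypeMatrix) -> pd.Index:
    return pd.MultiIndex.from_frame(gm.sites[["chrom", "pos"]])


def merge(gm1: GenotypeMatrix, gm2: GenotypeMatrix):
    """Merge two platforms into one matrix keyed on (chromosome, position).

    The merged site set is the union of the inputs; an individual absent from
    a platform is MISSING at that platform's private sites.  Sites present in
    both platforms with irreconcilable allele pairs are dropped and counted;
    a site whose allele pair is merely swapped between platforms is kept with
    the second platform's calls recoded onto the first platform's orientation.
    """
    overlap = set(gm1.individuals) & set(gm2.individuals)
    if overlap:
        raise MergeError(
            f"individual names present in both inputs: {sorted(overlap)[:5]}"
        )
    k1, k2 = _site_keys(gm1), _site_keys(gm2)
    common = k1.intersection(k2)

    alle1 = {
        k: (r, a)
        for k, r, a in zip(k1, gm1.sites["ref"], gm1.sites["alt"])
    }
    alle2 = {
        k: (r, a)
        for k, r, a in zip(k2, gm2.sites["ref"], gm2.sites["alt"])
    }
    conflict, flip2 = set(), set()
    for k in common:
        p1, p2 = alle1[k], alle2[k]
        if p1 == p2:
            continue
        if p1 == (p2[1], p2[0]):
            flip2.add(k)
        else:
            conflict.add(k)

    keep1 = np.array([k not in conflict for k in k1])
    keep2 = np.array([k not in conflict for k in k2])
    g1 = gm1.take_sites(np.flatnonzero(keep1)) if not keep1.all() else gm1
    g2 = gm2.take_sites(np.flatnonzero(keep2)) if not keep2.all() else gm2

    if flip2:
        g2 = g2.copy()
        cols = [i for i, k in enumerate(_site_keys(g2)) if k in flip2]
        sub = g2.calls[:, cols]
        swapped = sub.copy()
        swapped[sub == MAJOR] = MINOR
        swapped[sub == MINOR] = MAJOR
        g2.calls[:, cols] = swapped
        g2.sites.loc[g2.sites.index[cols], ["ref", "alt"]] = (
            g2.sites.loc[g2.sites.index[cols], ["alt", "ref"]].to_numpy()
        )

    union = pd.concat(
        [g1.sites[list(("chrom", "pos", "ref", "alt"))],
         g2.sites[list(("chrom", "pos", "ref", "alt"))]],
        ignore_index=True,
    ).drop_duplicates(subset=["chrom", "pos"], keep="first")
    dummy = np.empty((0, len(union)), dtype=np.int8)
    _, union = sort_sites(dummy, union)
    union_idx = pd.MultiIndex.from_frame(union[["chrom", "pos"]])

    n1, n2, s = g1.n_individuals, g2.n_individuals, len(union)
    calls = np.full((n1 + n2, s), MISSING, dtype=np.int8)
    pos1 = union_idx.get_indexer(_site_keys(g1))
    pos2 = union_idx.get_indexer(_site_keys(g2))
    calls[:n1, pos1] = g1.calls
    calls[n1:, pos2] = g2.calls

    prov1 = gm1.provenance or ["input1"] * n1
    prov2 = gm2.provenance or ["input2"] * n2
    merged = GenotypeMatrix(
        calls, union, g1.individuals + g2.individuals, list(prov1) + list(prov2)
    )
    n_common = len(common) - len(conflict)
    report = MergeReport(
        input1=SetStats.from_matrix(gm1),
        input2=SetStats.from_matrix(gm2),
        merged=SetStats.from_matrix(merged),
        n_common_sites=n_common,
        pct_common=100.0 * n_common / s if s else 0.0,
        n_conflict_sites=len(conflict),
    )
    return merged, report
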