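"""Core genotype container shared by every analysis stage.

Calls are stored as a dense ``int8`` matrix of individuals x sites with the
haploid-style coding used throughout maize inbred-panel work:

=========  =====  =====================================================
constant   value  meaning
=========  =====  =====================================================
MAJOR        0    homozygous for the major (reference-panel) allele
HET          1    heterozygous call (pre-QC only)
MINOR        2    homozygous for the minor allele
TERTIARY     3    third-or-higher allele state (pre-QC only)
MISSING     -1    no call
=========  =====  =====================================================

Post-QC matrices contain only {0, 2, MISSING}; post-imputation only {0, 2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MAJOR = 0
HET = 1
MINOR = 2
TERTIARY = 3
MISSING = -1

CALL_VALUES = frozenset({MAJOR, HET, MINOR, TERTIARY, MISSING})

#: columns required in the site metadata frame
SITE_COLUMNS = ("chrom", "pos", "ref", "alt")


def chrom_sort_key(chrom: str):
    """Natural ordering for chromosome names: numeric first, then lexical."""
    c = str(chrom)
    body = c[3:] if c.lower().startswith("chr") else c
    if body.isdigit():
        return (0, int(body), "")
    return (1, 0, c)


class GenotypeMatrixError(ValueError):
    """Raised when a genotype matrix violates its structural invariants."""


@dataclass
class GenotypeMatrix:
    """Individuals x sites call matrix with site and individual metadata.

    Parameters
    ----------
    calls
        ``int8`` array of shape ``(n_individuals, n_sites)``.
    sites
        DataFrame with columns ``chrom`` (str), ``pos`` (1-based int bp),
        ``ref`` and ``alt`` (single-base allele strings, major/minor).
    individuals
        Unique individual (inbred line) names, one per matrix row.
    provenance
        Optional source tag per individual (e.g. the originating platform).
    """

    calls: np.ndarray
    sites: pd.DataFrame
    individuals: list[str]
    provenance: list[str] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.individuals = [str(x) for x in self.individuals]
        sites = self.sites.reset_index(drop=True).copy()
        missing_cols = [c for c in SITE_COLUMNS if c not in sites.columns]
        if missing_cols:
            raise GenotypeMatrixError(f"site table lacks columns {missing_cols}")
        sites["chrom"] = sites["chrom"].astype(str)
        sites["pos"] = sites["pos"].astype(np.int64)
        self.sites = sites
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n_ind, n_sites = self.calls.shape if self.calls.ndim == 2 else (0, 0)
        if self.calls.ndim != 2:
            raise GenotypeMatrixError("calls must be a 2-D array")
        if len(self.individuals) != n_ind:
            raise GenotypeMatrixError(
                f"{len(self.individuals)} individual names for {n_ind} matrix rows"
            )
        if len(self.sites) != n_sites:
            raise GenotypeMatrixError(
                f"{len(self.sites)} site records for {n_sites} matrix columns"
            )
        if len(set(self.individuals)) != n_ind:
            raise GenotypeMatrixError("individual names are not unique")
        if self.provenance is not None and len(self.provenance) != n_ind:
            raise GenotypeMatrixError("provenance length mismatch")
        bad = ~np.isin(self.calls, list(CALL_VALUES))
        if bad.any():
            raise GenotypeMatrixError(
                f"invalid call codes present: {sorted(set(self.calls[bad].tolist()))}"
            )
        keys = list(zip(self.sites["chrom"], self.sites["pos"]))
        if len(set(keys)) != len(keys):
            raise GenotypeMatrixError("duplicate (chromosome, position) site keys")
        order_keys = [chrom_sort_key(c) + (p,) for c, p in keys]
        if any(a > b for a, b in zip(order_keys, order_keys[1:])):
            raise GenotypeMatrixError("sites are not sorted by (chromosome, position)")

    # -- basic accessors -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]

    @property
    def chroms(self) -> list[str]:
        """Chromosome names in matrix order."""
        seen: dict[str, None] = {}
        for c in self.sites["chrom"]:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous column slice per chromosome (sites are sorted)."""
        out: dict[str, slice] = {}
        chrom = self.sites["chrom"].to_numpy()
        for c in self.chroms:
            idx = np.flatnonzero(chrom == c)
            out[c] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out

    # -- counting --------------------------------------------------------
    def n_missing(self) -> int:
        return int((self.calls == MISSING).sum())

    def n_het(self) -> int:
        return int((self.calls == HET).sum())

    def total_data_points(self) -> int:
        return self.n_individuals * self.n_sites

    # -- subsetting ------------------------------------------------------
    def take_sites(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            calls=self.calls[:, index],
            sites=self.sites.iloc[index],
        )

    def take_individuals(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        prov = None
        if self.provenance is not None:
            prov = [self.provenance[i] for i in index]
        return replace(
            self,
            calls=self.calls[index, :],
            individuals=[self.individuals[i] for i in index],
            provenance=prov,
        )

    def select_individuals(self, names) -> "GenotypeMatrix":
        lookup = {n: i for i, n in enumerate(self.individuals)}
        try:
            idx = [lookup[n] for n in names]
        except KeyError as err:
            raise GenotypeMatrixError(f"unknown individual {err.args[0]!r}") from None
        return self.take_individuals(idx)

    # -- comparison ------------------------------------------------------
    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.individuals == other.individuals
            and np.array_equal(self.calls, other.calls)
            and self.sites[list(SITE_COLUMNS)].equals(
                other.sites[list(SITE_COLUMNS)]
            )
        )

    def copy(self) -> "GenotypeMatrix":
        prov = list(self.provenance) if self.provenance is not None else None
        return GenotypeMatrix(
            self.calls.copy(), self.sites.copy(), list(self.individuals), prov
        )


def sort_sites(calls: np.ndarray, sites: pd.DataFrame):
    """Return (calls, sites) with columns sorted by (chromosome, position)."""
    order = sorted(
        range(len(sites)),
        key=lambda i: chrom_sort_key(sites["chrom"].iloc[i]) + (int(sites["pos"].iloc[i]),),
    )
    order = np.asarray(order, dtype=np.intp)
    return calls[:, order], sites.iloc[order].reset_index(drop=True)
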