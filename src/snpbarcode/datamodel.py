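"""Shared domain types for the barcode pipeline.

Coordinates are 0-based everywhere in memory; 1-based positions appear
only in human-readable reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .iupac import ALPHABET, genotype_from_code

MISSING = None  # genotype sentinel

VALID_SOURCES = ("pipelineA", "pipelineB", "simulated")


class SpeciesMapError(ValueError):
    pass


@dataclass(frozen=True)
class SpeciesMap:
    """Assignment of individuals to species and analysis groups.

    ``group_code`` is the unit of analysis: distinct species may be
    merged into one group (e.g. sister taxa that are indistinguishable
    with nuclear markers, or a continental species complex treated as a
    single pool), so diagnostic alleles are sought per group.
    """

    table: pd.DataFrame  # columns: individual_id, species_code, group_code

    def __post_init__(self) -> None:
        required = {"individual_id", "species_code", "group_code"}
        missing = required - set(self.table.columns)
        if missing:
            raise SpeciesMapError(f"species map lacks columns {sorted(missing)}")
        dup = self.table["individual_id"].duplicated()
        if dup.any():
            offenders = self.table.loc[dup, "individual_id"].tolist()
            raise SpeciesMapError(f"individuals mapped more than once: {offenders}")

    @classmethod
    def from_records(cls, records) -> "SpeciesMap":
        """Build from an iterable of (individual_id, species_code, group_code)."""
        return cls(pd.DataFrame(records, columns=["individual_id", "species_code", "group_code"]))

    @classmethod
    def read_tsv(cls, path) -> "SpeciesMap":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @property
    def individuals(self) -> list[str]:
        return self.table["individual_id"].tolist()

    @property
    def groups(self) -> list[str]:
        """Sorted list of analysis group codes."""
        return sorted(self.table["group_code"].unique())

    def group_of(self, individual_id: str) -> str:
        sel = self.table.loc[self.table["individual_id"] == individual_id, "group_code"]
        if sel.empty:
            raise KeyError(individual_id)
        return sel.iloc[0]

    def members(self, group_code: str) -> list[str]:
        return self.table.loc[self.table["group_code"] == group_code, "individual_id"].tolist()

    def __contains__(self, individual_id: str) -> bool:
        return (self.table["individual_id"] == individual_id).any()


class AlignmentError(ValueError):
    pass


@dataclass
class LocusAlignment:
    """One short RAD locus: aligned per-individual IUPAC consensus sequences.

    All sequences have the same length; a single character encodes one
    individual's diploid genotype at that column.
    """

    locus_id: str
    sequences: dict[str, str]
    source: str = "pipelineA"

    def __post_init__(self) -> None:
        if self.source not in VALID_SOURCES:
            raise AlignmentError(f"unknown source {self.source!r}")
        if not self.sequences:
            raise AlignmentError(f"locus {self.locus_id}: no sequences")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            detail = {ind: len(s) for ind, s in self.sequences.items()}
            raise AlignmentError(
                f"locus {self.locus_id}: unequal sequence lengths {detail}"
            )
        (L,) = lengths
        if L < 1:
            raise AlignmentError(f"locus {self.locus_id}: empty sequences")
        norm = {}
        for ind, seq in self.sequences.items():
            seq = seq.upper()
            bad = set(seq) - ALPHABET
            if bad:
                raise AlignmentError(
                    f"locus {self.locus_id}, individual {ind}: "
                    f"invalid characters {sorted(bad)}"
                )
            norm[ind] = seq
        self.sequences = norm

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def individuals(self) -> list[str]:
        return list(self.sequences)

    def column(self, site: int) -> dict[str, str]:
        """Per-individual IUPAC character at a 0-based site."""
        if not 0 <= site < self.length:
            raise IndexError(f"site {site} outside locus of length {self.length}")
        return {ind: seq[site] for ind, seq in self.sequences.items()}

    def genotypes_at(self, site: int) -> dict[str, tuple[str, str] | None]:
        """Diploid genotypes at a site; missing / 3+-allele codes map to None."""
        return {ind: genotype_from_code(c) for ind, c in self.column(site).items()}


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs diploid calls.

    ``calls`` is an object array of unordered allele pairs (lexically
    ordered tuples such as ``("A", "C")``) or ``None`` for missing.
    SNPs with more than two observed alleles are flagged in
    ``multiallelic_snps`` rather than silently dropped.
    """

    individuals: list[str]
    snp_ids: list[str]
    calls: np.ndarray
    multiallelic_snps: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (isinstance(self.calls, np.ndarray)
                and self.calls.dtype == object and self.calls.ndim == 2):
            rows = list(self.calls)
            arr = np.empty((len(rows), len(rows[0]) if rows else 0), dtype=object)
            for i, row in enumerate(rows):
                for j, call in enumerate(row):
                    arr[i, j] = tuple(call) if call is not None else None
            self.calls = arr
        if self.calls.shape != (len(self.individuals), len(self.snp_ids)):
            raise GenotypeError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.snp_ids)} SNPs"
            )
        flagged = []
        for j, snp in enumerate(self.snp_ids):
            alleles = set()
            for i in range(len(self.individuals)):
                call = self.calls[i, j]
                if call is not None:
                    alleles.update(call)
            if len(alleles) > 2:
                flagged.append(snp)
        if flagged:
            self.multiallelic_snps = flagged
            warnings.warn(
                f"{len(flagged)} SNP(s) with >2 observed alleles: {flagged[:5]}",
                stacklevel=2,
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.individuals), len(self.snp_ids))

    def alleles_of(self, snp_id: str) -> list[str]:
        """Distinct alleles observed at a SNP, lexically sorted."""
        j = self.snp_ids.index(snp_id)
        out = set()
        for i in range(len(self.individuals)):
            call = self.calls[i, j]
            if call is not None:
                out.update(call)
        return sorted(out)

    def dosage(self, ref_alleles: dict[str, str]) -> np.ndarray:
        """Count of the reference (diagnostic) allele per call.

        Returns a float matrix with entries in {0, 1, 2} and NaN for
        missing calls.  ``ref_alleles`` maps SNP id -> counted allele.
        """
        n, m = self.shape
        D = np.full((n, m), np.nan)
        for j, snp in enumerate(self.snp_ids):
            ref = ref_alleles[snp]
            for i in range(n):
                call = self.calls[i, j]
                if call is not None:
                    D[i, j] = sum(1 for a in call if a == ref)
        return D

    def to_dataframe(self) -> pd.DataFrame:
        """String representation: "A/C" cells, "NA" for missing."""
        data = np.empty(self.shape, dtype=object)
        for i in range(self.shape[0]):
            for j in range(self.shape[1]):
                call = self.calls[i, j]
                data[i, j] = "NA" if call is None else "/".join(call)
        return pd.DataFrame(data, index=self.individuals, columns=self.snp_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        calls = np.empty(df.shape, dtype=object)
        for i in range(df.shape[0]):
            for j in range(df.shape[1]):
                cell = str(df.iat[i, j]).strip().upper()
                if cell in ("NA", "", "NAN", "-"):
                    calls[i, j] = None
                    continue
                parts = cell.split("/")
                if len(parts) != 2 or any(p not in "ACGT" or len(p) != 1 for p in parts):
                    raise GenotypeError(
                        f"cell {df.index[i]}/{df.columns[j]}: bad call {cell!r}"
                    )
                calls[i, j] = tuple(sorted(parts))
        return cls(list(map(str, df.index)), list(map(str, df.columns)), calls)


@dataclass(frozen=True)
class SNPCandidate:
    """One species-diagnostic SNP candidate at a locus site."""

    locus_id: str
    site: int  # 0-based
    target_group: str
    diagnostic_allele: str
    other_allele: str
    max_pairwise_fst: float
    n_pairs_at_threshold: int
    route: str = "unscreened"  # stringent | relaxed | unscreened
    fixedness: str = "candidate"  # fixed | nearly_fixed | candidate
    flank5: int = 0
    flank3: int = 0
    multiallelic: bool = False

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.locus_id, self.site, self.target_group)

    @property
    def site_1based(self) -> int:
        return self.site + 1


@dataclass(frozen=True)
class MaskedAssayRecord:
    """Assay-design export: focal SNP bracketed, other variation IUPAC-masked."""

    locus_id: str
    focal_site: int
    export_sequence: str

    def __post_init__(self) -> None:
        if self.export_sequence.count("[") != 1 or self.export_sequence.count("]") != 1:
            raise ValueError("export sequence must contain exactly one [X/Y] site")


@dataclass(frozen=True)
class HybridCall:
    """Species assignment of one genotyped individual from its ancestry vector."""

    individual_id: str
    assigned_group: str
    max_q: float
    status: str  # pure | admixed
    contributors: tuple[str, ...]
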