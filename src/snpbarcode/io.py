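"""Readers and writers for the pipeline's external formats.

Supported formats: locus FASTA (``>locusID|individualID`` headers, the
separator is configurable), species-map TSV, genotype CSV ("A/C" cells,
"NA" missing), STRUCTURE-style integer input, assay-design FASTA with
IUPAC masking, and candidate/panel report tables.
"""

from __future__ import annotations

import warnings
from collections import OrderedDict

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datamodel import (
    AlignmentError,
    GenotypeMatrix,
    LocusAlignment,
    MaskedAssayRecord,
    SNPCandidate,
    SpeciesMap,
)
from .iupac import genotype_from_code, minimal_cover

#: STRUCTURE-style integer coding of nucleotide alleles.
ALLELE_CODE = {"A": 1, "C": 2, "T": 3, "G": 4}
CODE_ALLELE = {v: k for k, v in ALLELE_CODE.items()}
MISSING_CODE = -1


class FastaParseError(ValueError):
    pass


def read_locus_fasta(path, species_map: SpeciesMap, *, separator: str = "|",
                     source: str = "pipelineA") -> list[LocusAlignment]:
    """Read per-locus alignments from a multi-locus FASTA file.

    Records are grouped by locus id taken from the header
    ``locusID<separator>individualID``.  Unequal sequence lengths within
    a locus and individuals absent from the species map are errors.
    Returns loci in first-appearance order.
    """
    grouped: "OrderedDict[str, dict[str, str]]" = OrderedDict()
    unknown: list[str] = []
    n_records = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        if separator not in rec.id:
            raise FastaParseError(
                f"malformed header {rec.id!r}: expected 'locusID{separator}individualID'"
            )
        locus_id, _, individual_id = rec.id.partition(separator)
        if not locus_id or not individual_id:
            raise FastaParseError(f"malformed header {rec.id!r}: empty field")
        if individual_id not in species_map:
            unknown.append(individual_id)
        grouped.setdefault(locus_id, {})[individual_id] = str(rec.seq)
    if n_records == 0:
        warnings.warn(f"no FASTA records in {path}", stacklevel=2)
        return []
    if unknown:
        raise FastaParseError(
            f"individuals absent from species map: {sorted(set(unknown))}"
        )
    loci = []
    for locus_id, seqs in grouped.items():
        try:
            loci.append(LocusAlignment(locus_id, seqs, source=source))
        except AlignmentError as exc:
            raise AlignmentError(str(exc)) from None
    return loci


def write_locus_fasta(loci, path, *, separator: str = "|") -> None:
    records = [
        SeqRecord(Seq(seq), id=f"{locus.locus_id}{separator}{ind}", description="")
        for locus in loci
        for ind, seq in locus.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# genotype matrices


def read_genotype_csv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0, dtype=str)
    return GenotypeMatrix.from_dataframe(df)


def write_genotype_csv(G: GenotypeMatrix, path) -> None:
    G.to_dataframe().to_csv(path)


def encode_structure_input(G: GenotypeMatrix, out, *,
                           populations: dict[str, int] | None = None) -> None:
    """Write a genotype matrix as STRUCTURE-style plain text.

    Two rows per individual, one allele per row per SNP, with alleles
    coded A=1, C=2, T=3, G=4 and missing data as -1.  Column order is
    the matrix's SNP order.  ``populations`` optionally adds an integer
    population column after the individual label.
    """

    def code(allele: str) -> int:
        try:
            return ALLELE_CODE[allele]
        except KeyError:
            raise ValueError(f"allele outside A/C/G/T: {allele!r}") from None

    lines = []
    for i, ind in enumerate(G.individuals):
        rows: list[list[int]] = [[], []]
        for j in range(len(G.snp_ids)):
            call = G.calls[i, j]
            if call is None:
                rows[0].append(MISSING_CODE)
                rows[1].append(MISSING_CODE)
            else:
                rows[0].append(code(call[0]))
                rows[1].append(code(call[1]))
        prefix = [ind]
        if populations is not None:
            prefix.append(str(populations[ind]))
        for row in rows:
            lines.append("\t".join(prefix + [str(v) for v in row]))
    text = "\n".join(lines) + "\n"
    if hasattr(out, "write"):
        out.write(text)
    else:
        with open(out, "w") as fh:
            fh.write(text)


def decode_structure_input(path_or_text, snp_ids, *, has_population: bool = False) -> GenotypeMatrix:
    """Inverse of :func:`encode_structure_input` (round-trip check helper)."""
    if hasattr(path_or_text, "read"):
        text = path_or_text.read()
    else:
        with open(path_or_text) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) % 2:
        raise ValueError("STRUCTURE input must have two lines per individual")
    skip = 2 if has_population else 1
    individuals, calls = [], []
    for k in range(0, len(lines), 2):
        f1, f2 = lines[k].split("\t"), lines[k + 1].split("\t")
        if f1[0] != f2[0]:
            raise ValueError(f"paired rows disagree on individual: {f1[0]} vs {f2[0]}")
        individuals.append(f1[0])
        row = []
        for v1, v2 in zip(f1[skip:], f2[skip:], strict=True):
            c1, c2 = int(v1), int(v2)
            if c1 == MISSING_CODE or c2 == MISSING_CODE:
                row.append(None)
            else:
                row.append(tuple(sorted((CODE_ALLELE[c1], CODE_ALLELE[c2]))))
        calls.append(row)
    return GenotypeMatrix(individuals, list(snp_ids), calls)


# ---------------------------------------------------------------------------
# assay-design export (IUPAC masking)


def consensus_columns(locus: LocusAlignment) -> list[str]:
    """Per-column IUPAC summary of a locus across individuals.

    Polymorphic columns (over the expanded diploid genotypes) collapse
    to the minimal ambiguity code covering the observed alleles;
    monomorphic columns emit the consensus base; all-missing columns
    emit ``N``; columns where any individual carries a gap emit ``-``.
    """
    out = []
    for site in range(locus.length):
        col = locus.column(site)
        if "-" in col.values():
            out.append("-")
            continue
        alleles: set[str] = set()
        for ch in col.values():
            gt = genotype_from_code(ch)
            if gt is not None:
                alleles.update(gt)
        out.append(minimal_cover(alleles) if alleles else "N")
    return out


def observed_alleles(locus: LocusAlignment, site: int) -> set[str]:
    """Concrete alleles observed at a site across diploid genotypes."""
    alleles: set[str] = set()
    for gt in locus.genotypes_at(site).values():
        if gt is not None:
            alleles.update(gt)
    return alleles


def write_assay_fasta(candidate: SNPCandidate, locus: LocusAlignment) -> MaskedAssayRecord:
    """Build the assay-design record: ``[X/Y]`` at the focal site, other
    polymorphic sites masked with IUPAC codes.
    """
    if candidate.locus_id != locus.locus_id:
        raise ValueError(
            f"candidate locus {candidate.locus_id} != alignment {locus.locus_id}"
        )
    focal = observed_alleles(locus, candidate.site)
    if len(focal) < 2:
        raise ValueError(
            f"focal site {candidate.site} of locus {locus.locus_id} is monomorphic"
        )
    cols = consensus_columns(locus)
    x, y = sorted((candidate.diagnostic_allele, candidate.other_allele))
    cols[candidate.site] = f"[{x}/{y}]"
    return MaskedAssayRecord(locus.locus_id, candidate.site, "".join(cols))


def write_assay_fasta_file(records, path) -> None:
    seqrecords = [
        SeqRecord(
            Seq(rec.export_sequence),
            id=f"{rec.locus_id}_pos{rec.focal_site + 1}",
            description="",
        )
        for rec in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


# ---------------------------------------------------------------------------
# tabular reports


def candidates_to_table(cands) -> pd.DataFrame:
    """Candidate list as a report table (1-based site positions)."""
    return pd.DataFrame(
        [
            {
                "locus_id": c.locus_id,
                "site_1based": c.site_1based,
                "target_group": c.target_group,
                "diagnostic_allele": c.diagnostic_allele,
                "other_allele": c.other_allele,
                "max_fst": c.max_pairwise_fst,
                "n_pairs_at_threshold": c.n_pairs_at_threshold,
                "route": c.route,
                "fixedness": c.fixedness,
                "flank5": c.flank5,
                "flank3": c.flank3,
                "multiallelic": c.multiallelic,
            }
            for c in cands
        ]
    )
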