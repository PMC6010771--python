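"""Cross-pipeline duplicate-locus detection.

Two de novo clustering pipelines run over the same reads recover
overlapping but non-identical locus sets; loci present in both must be
removed from one side before panel design so a SNP is never assayed
twice.  Duplicates are found by local alignment with BLASTN-like
scoring (match +2, mismatch -3, gap open -5, gap extend -2 per base),
both strands, with IUPAC ambiguity codes matching any compatible base.
A pair is a duplicate when the alignment covers at least
``coverage_min`` of the shorter locus at ``identity_min`` identity and
is the reciprocal best hit in both directions.

For speed, pairs are pre-screened with exact shared k-mer seeds (both
strands) before alignment — the same word-seeding idea BLAST uses; at
~85 bp and >=90% identity a true duplicate pair shares a 12-mer with
near certainty, while unrelated random loci essentially never do.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .iupac import CODE_TO_SET, reverse_complement

MATCH = 2.0
MISMATCH = -3.0
GAP_OPEN = -5.0
GAP_EXTEND = -2.0

COVERAGE_MIN = 0.95
IDENTITY_MIN = 0.90
SEED_WORD = 12

_ALPHABET = "ACGTRYSWKMBDHVN"


def _iupac_matrix():
    mat = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            mat[a, b] = MATCH if CODE_TO_SET[a] & CODE_TO_SET[b] else MISMATCH
    return mat


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _iupac_matrix()
    # BLAST charges open + k*extend for a k-base gap
    aligner.open_gap_score = GAP_OPEN + GAP_EXTEND
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


@dataclass(frozen=True)
class AlignmentHit:
    """Best local alignment between two locus sequences."""

    query_id: str
    subject_id: str
    aligned_len: int
    identity: float
    score: float
    strand: str  # "+" or "-"


def _alignment_stats(alignment) -> tuple[int, int]:
    """(aligned columns, compatible-base matches) over the local alignment."""
    q, s = str(alignment[0]), str(alignment[1])
    aligned = len(q)
    matches = 0
    for ca, cb in zip(q, s):
        if ca != "-" and cb != "-" and CODE_TO_SET[ca] & CODE_TO_SET[cb]:
            matches += 1
    return aligned, matches


def local_align(s1: str, s2: str, *, id1: str = "query", id2: str = "subject") -> AlignmentHit:
    """Best local alignment of two IUPAC sequences over both strands."""
    s1, s2 = s1.upper(), s2.upper()
    if not s1 or not s2:
        raise ValueError("cannot align an empty sequence")
    aligner = _aligner()
    best = None
    for strand, subject in (("+", s2), ("-", reverse_complement(s2))):
        alignments = aligner.align(s1, subject)
        if len(alignments) == 0:
            continue
        aln = alignments[0]
        if best is None or aln.score > best[0].score:
            best = (aln, strand)
    if best is None:
        return AlignmentHit(id1, id2, 0, 0.0, 0.0, "+")
    aln, strand = best
    aligned, matches = _alignment_stats(aln)
    identity = matches / aligned if aligned else 0.0
    return AlignmentHit(id1, id2, aligned, identity, float(aln.score), strand)


def _representative(locus) -> str:
    """Gap-free representative sequence for a locus (first individual's
    consensus with missing bases arbitrarily resolved to A)."""
    seq = next(iter(locus.sequences.values()))
    return seq.replace("-", "").replace("N", "A")


def _seed_index(seqs: dict[str, str], word: int):
    index = defaultdict(set)
    for lid, seq in seqs.items():
        for i in range(len(seq) - word + 1):
            kmer = seq[i:i + word]
            if set(kmer) <= set("ACGT"):
                index[kmer].add(lid)
    return index


def _candidate_pairs(seqs_a, seqs_b, word: int):
    index_b = _seed_index(seqs_b, word)
    pairs = set()
    for ida, seq in seqs_a.items():
        for oriented in (seq, reverse_complement(seq)):
            for i in range(len(oriented) - word + 1):
                kmer = oriented[i:i + word]
                for idb in index_b.get(kmer, ()):
                    pairs.add((ida, idb))
    return pairs


def find_duplicates(loci_a, loci_b, *, coverage_min: float = COVERAGE_MIN,
                    identity_min: float = IDENTITY_MIN,
                    seed_word: int = SEED_WORD,
                    with_hits: bool = False):
    """Reciprocal-best duplicate pairs between two locus sets.

    Returns a sorted list of ``(idA, idB)`` pairs; the set-B copy is the
    one conventionally marked for exclusion (see
    :func:`exclusion_list`).  With ``with_hits=True`` also returns the
    accepted :class:`AlignmentHit` per pair.
    """
    seqs_a = {l.locus_id: _representative(l) for l in loci_a}
    seqs_b = {l.locus_id: _representative(l) for l in loci_b}
    hits: dict[tuple[str, str], AlignmentHit] = {}
    for ida, idb in _candidate_pairs(seqs_a, seqs_b, seed_word):
        hit = local_align(seqs_a[ida], seqs_b[idb], id1=ida, id2=idb)
        min_len = min(len(seqs_a[ida]), len(seqs_b[idb]))
        if hit.aligned_len >= coverage_min * min_len and hit.identity >= identity_min:
            hits[(ida, idb)] = hit

    best_a: dict[str, tuple[str, float]] = {}
    best_b: dict[str, tuple[str, float]] = {}
    for (ida, idb), hit in sorted(hits.items()):
        if ida not in best_a or hit.score > best_a[ida][1]:
            best_a[ida] = (idb, hit.score)
        if idb not in best_b or hit.score > best_b[idb][1]:
            best_b[idb] = (ida, hit.score)
    pairs = sorted(
        (ida, idb)
        for (ida, idb) in hits
        if best_a.get(ida, (None,))[0] == idb and best_b.get(idb, (None,))[0] == ida
    )
    if with_hits:
        return pairs, [hits[p] for p in pairs]
    return pairs


def exclusion_list(pairs, side: str = "B") -> set[str]:
    """Locus ids to drop given duplicate pairs; by convention the
    second-pipeline copy is excluded (``side='B'``)."""
    if side not in ("A", "B"):
        raise ValueError("side must be 'A' or 'B'")
    return {p[1] if side == "B" else p[0] for p in pairs}
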