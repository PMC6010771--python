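"""Per-site pairwise F_ST scan over multi-species locus alignments.

Each locus column is expanded into diploid allele counts per analysis
group, and F_ST is computed between every pair of groups.  A site
yields a diagnostic-SNP candidate for a target group when that group is
differentiated at or above the threshold from *every* other group with
sufficient data — the definition of an allele that singles the group
out from the rest of the panel.

Two estimators are available:

``nei87``
    The transparent two-group form F_ST = (H_T - H_S) / H_T with
    H_S the unweighted mean of within-group expected heterozygosities
    2p(1-p) and H_T = 2 p̄ (1-p̄) at the unweighted mean frequency p̄.
    Hand-checkable and the default.

``wc84``
    Weir–Cockerham theta from the a/b/c variance components for two
    populations, using observed heterozygote proportions.  Can be
    negative; negative values are clipped to 0 for thresholding while
    the raw estimate is kept in the record.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from .datamodel import LocusAlignment, SNPCandidate, SpeciesMap
from .iupac import genotype_from_code

logger = logging.getLogger(__name__)

NUCLEOTIDES = ("A", "C", "G", "T")


@dataclass
class SiteCounts:
    """Diploid genotype tallies for one analysis group at one site."""

    group: str
    genotype_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    n_flagged: int = 0  # individuals with 3+-allele ambiguity codes (no copies)

    @property
    def allele_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for (a, b), n in self.genotype_counts.items():
            counts[a] = counts.get(a, 0) + n
            counts[b] = counts.get(b, 0) + n
        return counts

    @property
    def n_copies(self) -> int:
        return 2 * sum(self.genotype_counts.values())

    @property
    def n_individuals_nonmissing(self) -> int:
        return sum(self.genotype_counts.values())

    def restricted(self, alleles: tuple[str, str]) -> tuple[int, int, int]:
        """(copies of alleles[0], total copies, het individuals) among
        genotypes composed only of the two given alleles."""
        x, y = alleles
        n0 = total = het = 0
        for (a, b), n in self.genotype_counts.items():
            if a in (x, y) and b in (x, y):
                n0 += n * ((a == x) + (b == x))
                total += 2 * n
                if a != b:
                    het += n
        return n0, total, het


def site_allele_counts(locus: LocusAlignment, site: int,
                       groups: SpeciesMap) -> dict[str, SiteCounts]:
    """Expand one alignment column into per-group diploid counts.

    Each IUPAC genotype contributes two allele copies (A -> A,A;
    R -> A,G).  ``N`` and ``-`` contribute nothing; 3+-allele ambiguity
    codes contribute nothing and increment the group's flag counter.
    """
    out = {g: SiteCounts(g) for g in groups.groups}
    for ind, code in locus.column(site).items():
        sc = out[groups.group_of(ind)]
        gt = genotype_from_code(code)
        if gt is None:
            if code not in ("N", "-"):
                sc.n_flagged += 1
            continue
        sc.genotype_counts[gt] = sc.genotype_counts.get(gt, 0) + 1
    return out


def _top_two_alleles(a: SiteCounts, b: SiteCounts) -> tuple[str, ...]:
    pooled: dict[str, int] = {}
    for sc in (a, b):
        for al, n in sc.allele_counts.items():
            pooled[al] = pooled.get(al, 0) + n
    # descending count, lexical tie-break
    ranked = sorted(pooled, key=lambda al: (-pooled[al], al))
    return tuple(ranked[:2])


def pairwise_fst(a: SiteCounts, b: SiteCounts, estimator: str = "nei87") -> float | None:
    """F_ST between two groups at one site, or ``None`` when undefined.

    Undefined when either group has fewer than two allele copies.
    Multiallelic sites are reduced to the two most frequent alleles
    pooled across the pair.
    """
    if a.n_copies < 2 or b.n_copies < 2:
        return None
    top = _top_two_alleles(a, b)
    if len(top) < 2:
        return 0.0  # monomorphic across the pair
    xa, na, ha = a.restricted(top)
    xb, nb, hb = b.restricted(top)
    if na == 0 or nb == 0:
        return None
    pa, pb = xa / na, xb / nb
    if estimator == "nei87":
        hs = (2 * pa * (1 - pa) + 2 * pb * (1 - pb)) / 2.0
        pbar = (pa + pb) / 2.0
        ht = 2 * pbar * (1 - pbar)
        if ht == 0:
            return 0.0
        return (ht - hs) / ht
    if estimator == "wc84":
        return _wc84_theta(
            n=(na / 2, nb / 2), p=(pa, pb),
            h=(2 * ha / na, 2 * hb / nb),
        )
    raise ValueError(f"unknown estimator {estimator!r}")


def _wc84_theta(n, p, h) -> float:
    """Weir–Cockerham theta for r=2 populations.

    ``n``: individuals sampled per population; ``p``: focal-allele
    frequencies; ``h``: observed heterozygote proportions.
    """
    r = 2
    n1, n2 = n
    nbar = (n1 + n2) / r
    if nbar <= 1:
        return 0.0
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p[0] + n2 * p[1]) / (r * nbar)
    s2 = (n1 * (p[0] - pbar) ** 2 + n2 * (p[1] - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h[0] + n2 * h[1]) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    denom = a + b + c
    if denom == 0:
        return 0.0
    return a / denom


@dataclass(frozen=True)
class FstRecord:
    """One pairwise F_ST evaluation at a site (raw, unclipped value)."""

    locus_id: str
    site: int
    pair: tuple[str, str]
    fst: float
    estimator: str = "nei87"

    @property
    def fst_clipped(self) -> float:
        return min(1.0, max(0.0, self.fst))


def site_pairwise_fst(counts: dict[str, SiteCounts], locus_id: str, site: int,
                      estimator: str = "nei87") -> list[FstRecord]:
    """All defined pairwise F_ST records at one site."""
    records = []
    for ga, gb in itertools.combinations(sorted(counts), 2):
        value = pairwise_fst(counts[ga], counts[gb], estimator)
        if value is not None:
            records.append(FstRecord(locus_id, site, (ga, gb), value, estimator))
    return records


def scan(loci, groups: SpeciesMap, threshold: float = 0.95,
         estimator: str = "nei87", min_copies: int = 2) -> list[SNPCandidate]:
    """Scan every site of every locus for species-diagnostic SNPs.

    A group qualifies as the target at a site when its clipped F_ST
    against every other group with at least ``min_copies`` allele copies
    is at or above ``threshold`` (and at least one such pair exists).
    ``n_pairs_at_threshold`` records how many of the site's pairwise
    comparisons, over all group pairs, reach the threshold.

    Candidates are sorted by (locus_id, site, target_group), making the
    output deterministic and invariant to individual ordering.
    """
    if len(groups.groups) < 2:
        raise ValueError("need at least two analysis groups to scan")
    out: list[SNPCandidate] = []
    for locus in loci:
        for site in range(locus.length):
            counts = site_allele_counts(locus, site, groups)
            present = [g for g in groups.groups if counts[g].n_copies >= min_copies]
            if len(present) < 2:
                continue
            fst_at: dict[tuple[str, str], float] = {}
            for ga, gb in itertools.combinations(present, 2):
                v = pairwise_fst(counts[ga], counts[gb], estimator)
                if v is not None:
                    fst_at[(ga, gb)] = min(1.0, max(0.0, v))
            if not fst_at:
                continue
            n_at = sum(1 for v in fst_at.values() if v >= threshold)
            if n_at == 0:
                continue
            pooled_alleles: dict[str, int] = {}
            for g in present:
                for al, n in counts[g].allele_counts.items():
                    pooled_alleles[al] = pooled_alleles.get(al, 0) + n
            multi = len(pooled_alleles) > 2 or any(
                counts[g].n_flagged for g in groups.groups
            )
            for target in present:
                others = [g for g in present if g != target]
                pair_vals = [
                    fst_at.get((min(target, g), max(target, g))) for g in others
                ]
                if any(v is None for v in pair_vals):
                    continue
                if all(v >= threshold for v in pair_vals):
                    diag, other = _diagnostic_alleles(counts, target, others)
                    if diag is None:
                        continue
                    out.append(
                        SNPCandidate(
                            locus_id=locus.locus_id,
                            site=site,
                            target_group=target,
                            diagnostic_allele=diag,
                            other_allele=other,
                            max_pairwise_fst=max(pair_vals),
                            n_pairs_at_threshold=n_at,
                            flank5=site,
                            flank3=locus.length - 1 - site,
                            multiallelic=multi,
                        )
                    )
    out.sort(key=lambda c: c.key)
    return out


def _diagnostic_alleles(counts, target, others):
    """Target group's major allele and the major allele of the rest."""
    tc = counts[target].allele_counts
    if not tc:
        return None, None
    diag = min(tc, key=lambda al: (-tc[al], al))
    oc: dict[str, int] = {}
    for g in others:
        for al, n in counts[g].allele_counts.items():
            if al != diag:
                oc[al] = oc.get(al, 0) + n
    if not oc:
        return None, None
    other = min(oc, key=lambda al: (-oc[al], al))
    return diag, other
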