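"""Barcode panel assembly under per-species quotas and multiplex limits.

Verified candidates are ranked per target group — fixed before nearly
fixed, then by descending maximum pairwise F_ST, then by descending
number of pairwise comparisons at the threshold, ties broken lexically
by (locus_id, site) — and taken greedily up to the per-group quota
ceiling (default 5-6 SNPs per group) and a global cap (default 80).
Entries are then packed into multiplexes of at most 40 assays each,
keeping apart entry pairs whose SNP-proximal flanks contain
reverse-complementary 8-mers (a conservative primer-dimer surrogate;
real assay design additionally models primer thermodynamics, which is
out of scope here).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .datamodel import LocusAlignment, SNPCandidate
from .io import consensus_columns, observed_alleles
from .iupac import reverse_complement

logger = logging.getLogger(__name__)

QUOTA = (5, 6)
MAX_TOTAL = 80
MAX_PER_PLEX = 40
FLANK_AMBIGUITY_MAX = 2
DIMER_WORD = 8
DIMER_WINDOW = 10


@dataclass
class Panel:
    """Ordered barcode panel with multiplex assignments and bookkeeping."""

    entries: list[SNPCandidate]
    multiplex_of: dict[tuple, int] = field(default_factory=dict)
    quota: tuple[int, int] = QUOTA
    max_total: int = MAX_TOTAL
    max_per_plex: int = MAX_PER_PLEX
    deficits: dict[str, int] = field(default_factory=dict)
    unplaceable: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(e.locus_id, e.site) for e in self.entries]
        if len(keys) != len(set(keys)):
            raise ValueError("panel entries must be unique by (locus_id, site)")
        if len(self.entries) > self.max_total:
            raise ValueError(f"panel exceeds max_total={self.max_total}")

    @property
    def n_plexes(self) -> int:
        return len(set(self.multiplex_of.values())) if self.multiplex_of else 0

    def per_group_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.entries:
            counts[e.target_group] = counts.get(e.target_group, 0) + 1
        return counts

    def plex_members(self) -> dict[int, list[SNPCandidate]]:
        out: dict[int, list[SNPCandidate]] = {}
        for e in self.entries:
            plex = self.multiplex_of.get(e.key)
            if plex is not None:
                out.setdefault(plex, []).append(e)
        return out

    def to_report(self) -> dict:
        return {
            "n_entries": len(self.entries),
            "quota": list(self.quota),
            "max_total": self.max_total,
            "max_per_plex": self.max_per_plex,
            "per_group": self.per_group_counts(),
            "deficits": self.deficits,
            "n_plexes": self.n_plexes,
            "entries": [
                {
                    "locus_id": e.locus_id,
                    "site_1based": e.site_1based,
                    "target_group": e.target_group,
                    "alleles": f"{e.diagnostic_allele}/{e.other_allele}",
                    "fixedness": e.fixedness,
                    "route": e.route,
                    "max_fst": e.max_pairwise_fst,
                    "multiplex": self.multiplex_of.get(e.key),
                }
                for e in self.entries
            ],
        }


def assay_compatible(cand: SNPCandidate, locus: LocusAlignment, *,
                     flank_ambiguity_max: int = FLANK_AMBIGUITY_MAX,
                     flank_len: int = 20) -> tuple[bool, str]:
    """Surrogate assay-design compatibility check on a candidate's flanks.

    Rejects candidates whose 20-bp flanking consensus contains gap
    characters (reason ``indel``), more than ``flank_ambiguity_max``
    ambiguous/N positions per flank (reason ``ambiguity``), or whose
    focal site is not biallelic (reason ``not_biallelic``).
    """
    cols = consensus_columns(locus)
    site = cand.site
    if site < flank_len or locus.length - 1 - site < flank_len:
        return False, "flank"
    five = cols[site - flank_len:site]
    three = cols[site + 1:site + 1 + flank_len]
    for flank in (five, three):
        if "-" in flank:
            return False, "indel"
        n_ambig = sum(1 for c in flank if c not in "ACGT")
        if n_ambig > flank_ambiguity_max:
            return False, "ambiguity"
    if len(observed_alleles(locus, site)) != 2:
        return False, "not_biallelic"
    return True, ""


def rank_key(cand: SNPCandidate):
    """Deterministic ranking: fixed first, higher F_ST first, more
    qualifying pairs first, then lexical locus/site."""
    return (
        0 if cand.fixedness == "fixed" else 1,
        -cand.max_pairwise_fst,
        -cand.n_pairs_at_threshold,
        cand.locus_id,
        cand.site,
    )


def select_panel(cands, *, quota: tuple[int, int] = QUOTA,
                 max_total: int = MAX_TOTAL,
                 max_per_plex: int = MAX_PER_PLEX) -> Panel:
    """Greedy per-group panel selection under quota and global cap.

    Groups with fewer candidates than the quota minimum contribute all
    they have; the shortfall is recorded in ``Panel.deficits``.  If the
    quota ceilings still exceed ``max_total``, the lowest-ranked
    surplus entries beyond each group's quota minimum are trimmed.
    """
    qmin, qmax = quota
    if qmin > qmax:
        raise ValueError("quota minimum exceeds maximum")
    cands = list(cands)
    if not cands:
        logger.warning("empty candidate set: returning empty panel")
        return Panel([], quota=quota, max_total=max_total, max_per_plex=max_per_plex)

    by_group: dict[str, list[SNPCandidate]] = {}
    seen_sites: set[tuple[str, int]] = set()
    for cand in sorted(cands, key=rank_key):
        site_key = (cand.locus_id, cand.site)
        if site_key in seen_sites:
            continue  # one assay per physical site
        seen_sites.add(site_key)
        by_group.setdefault(cand.target_group, []).append(cand)

    chosen: list[SNPCandidate] = []
    deficits: dict[str, int] = {}
    for group in sorted(by_group):
        take = by_group[group][:qmax]
        chosen.extend(take)
        if len(take) < qmin:
            deficits[group] = qmin - len(take)
            logger.info("group %s: deficit of %d below quota minimum", group,
                        deficits[group])

    if len(chosen) > max_total:
        # trim surplus beyond quota minima, lowest-ranked first
        counts = {g: 0 for g in by_group}
        for e in chosen:
            counts[e.target_group] += 1
        for cand in sorted(chosen, key=rank_key, reverse=True):
            if len(chosen) <= max_total:
                break
            if counts[cand.target_group] > qmin:
                chosen.remove(cand)
                counts[cand.target_group] -= 1
        if len(chosen) > max_total:
            # quota minima alone exceed the cap: drop globally lowest-ranked
            chosen = sorted(chosen, key=rank_key)[:max_total]

    chosen.sort(key=rank_key)
    return Panel(chosen, quota=quota, max_total=max_total,
                 max_per_plex=max_per_plex, deficits=deficits)


def _dimer_kmers(cand: SNPCandidate, locus: LocusAlignment, *,
                 word: int = DIMER_WORD, window: int = DIMER_WINDOW) -> set[str]:
    """8-mers from the SNP-proximal 10 bp of each flank (ACGT-only)."""
    cols = consensus_columns(locus)
    site = cand.site
    windows = (
        "".join(cols[max(0, site - window):site]),
        "".join(cols[site + 1:site + 1 + window]),
    )
    kmers = set()
    for w in windows:
        for i in range(len(w) - word + 1):
            kmer = w[i:i + word]
            if set(kmer) <= set("ACGT"):
                kmers.add(kmer)
    return kmers


def dimer_conflict(kmers_a: set[str], kmers_b: set[str]) -> bool:
    """True when any 8-mer of one entry is the reverse complement of an
    8-mer of the other (extension-primer dimer surrogate)."""
    return any(reverse_complement(k) in kmers_b for k in kmers_a)


def assign_multiplexes(panel: Panel, loci, *, max_per_plex: int | None = None,
                       max_plexes: int | None = None) -> Panel:
    """First-fit-decreasing multiplex packing with dimer-conflict avoidance.

    Entries are placed in rank order into the first plex that is below
    the size cap and contains no conflicting entry; a new plex is
    opened when needed (up to ``max_plexes`` if given).  Entries that
    fit nowhere are recorded in ``Panel.unplaceable``.
    """
    cap = max_per_plex if max_per_plex is not None else panel.max_per_plex
    index = {l.locus_id: l for l in loci}
    kmers = {e.key: _dimer_kmers(e, index[e.locus_id]) for e in panel.entries}
    plexes: list[list[SNPCandidate]] = []
    assignment: dict[tuple, int] = {}
    unplaceable: list[tuple] = []
    for entry in sorted(panel.entries, key=rank_key):
        placed = False
        for pi, members in enumerate(plexes):
            if len(members) >= cap:
                continue
            if any(dimer_conflict(kmers[entry.key], kmers[m.key]) for m in members):
                continue
            members.append(entry)
            assignment[entry.key] = pi
            placed = True
            break
        if not placed:
            if max_plexes is None or len(plexes) < max_plexes:
                plexes.append([entry])
                assignment[entry.key] = len(plexes) - 1
            else:
                unplaceable.append(entry.key)
                logger.warning("entry %s conflicts with every multiplex", entry.key)
    panel.multiplex_of = assignment
    panel.unplaceable = unplaceable
    return panel
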