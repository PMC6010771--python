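"""Assay-suitability filters for diagnostic SNP candidates.

Two discovery routes mirror the two screening philosophies used when
mining short RAD loci for species-diagnostic sites:

* the *stringent* route discards any site where an individual carries a
  heterozygote ambiguity code and requires the diagnostic allele in at
  least half of the target group's individuals (missing individuals
  count in the denominator);
* the *relaxed* route tolerates heterozygous and ambiguous genotypes
  but requires at least one homozygous individual in every group with
  data at the site, with the target group's homozygote carrying the
  diagnostic allele.

Both routes additionally require 20 bp of flanking sequence on each
side of the SNP so amplification and extension primers can be placed.
The stringent route is a strict subset of the relaxed route.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from .datamodel import LocusAlignment, SNPCandidate

logger = logging.getLogger(__name__)

PRESENCE_THRESHOLD = 0.5
FLANK_MIN = 20
LEAKAGE_TOL = 0.05


@dataclass(frozen=True)
class FilterVerdict:
    candidate: SNPCandidate
    passed: bool
    reason: str = ""


def _loci_by_id(loci) -> dict[str, LocusAlignment]:
    return {locus.locus_id: locus for locus in loci}


def _group_genotypes(locus, site, species_map):
    """group -> {individual -> genotype-or-None} at a site."""
    out: dict[str, dict] = {g: {} for g in species_map.groups}
    for ind, gt in locus.genotypes_at(site).items():
        out[species_map.group_of(ind)][ind] = gt
    return out


def flank_ok(cand: SNPCandidate, locus_len: int, flank_min: int = FLANK_MIN) -> bool:
    """True when at least ``flank_min`` bp flank the SNP on both sides."""
    return cand.site >= flank_min and (locus_len - 1 - cand.site) >= flank_min


def stringent_filter(cands, loci, species_map, *,
                     presence_threshold: float = PRESENCE_THRESHOLD,
                     flank_min: int = FLANK_MIN,
                     with_verdicts: bool = False):
    """Apply the stringent route; survivors get ``route='stringent'``."""
    index = _loci_by_id(loci)
    kept, verdicts = [], []
    for cand in cands:
        locus = index[cand.locus_id]
        verdict = _stringent_one(cand, locus, species_map, presence_threshold, flank_min)
        verdicts.append(verdict)
        if verdict.passed:
            kept.append(replace(cand, route="stringent"))
    if with_verdicts:
        return kept, verdicts
    return kept


def _stringent_one(cand, locus, species_map, presence_threshold, flank_min):
    if not flank_ok(cand, locus.length, flank_min):
        return FilterVerdict(cand, False, "flank")
    column = locus.column(cand.site)
    for ind, code in column.items():
        if code in "RYSWKMBDHV":
            return FilterVerdict(cand, False, f"ambiguity:{ind}")
    members = species_map.members(cand.target_group)
    genotypes = locus.genotypes_at(cand.site)
    carriers = 0
    for ind in members:
        gt = genotypes.get(ind)  # individuals absent from the locus are missing
        if gt is not None and cand.diagnostic_allele in gt:
            carriers += 1
    if not members or carriers / len(members) < presence_threshold:
        return FilterVerdict(cand, False, "presence")
    return FilterVerdict(cand, True)


def relaxed_filter(cands, loci, species_map, *,
                   flank_min: int = FLANK_MIN,
                   with_verdicts: bool = False):
    """Apply the relaxed route; survivors get ``route='relaxed'``."""
    index = _loci_by_id(loci)
    kept, verdicts = [], []
    for cand in cands:
        locus = index[cand.locus_id]
        verdict = _relaxed_one(cand, locus, species_map, flank_min)
        verdicts.append(verdict)
        if verdict.passed:
            kept.append(replace(cand, route="relaxed"))
    if with_verdicts:
        return kept, verdicts
    return kept


def _relaxed_one(cand, locus, species_map, flank_min):
    if not flank_ok(cand, locus.length, flank_min):
        return FilterVerdict(cand, False, "flank")
    by_group = _group_genotypes(locus, cand.site, species_map)
    target_hom_diag = False
    for group, genos in by_group.items():
        nonmissing = [gt for gt in genos.values() if gt is not None]
        if not nonmissing:
            continue  # all-missing groups are not held to the homozygote rule
        homs = [gt for gt in nonmissing if gt[0] == gt[1]]
        if not homs:
            return FilterVerdict(cand, False, f"no_homozygote:{group}")
        if group == cand.target_group:
            target_hom_diag = any(gt[0] == cand.diagnostic_allele for gt in homs)
    if not target_hom_diag:
        return FilterVerdict(cand, False, "target_homozygote_allele")
    return FilterVerdict(cand, True)


def classify_fixedness(cand: SNPCandidate, loci, species_map, *,
                       leakage_tol: float = LEAKAGE_TOL):
    """Classify a filtered candidate as ``fixed`` or ``nearly_fixed``.

    *fixed*: every non-missing target-group individual is homozygous for
    the diagnostic allele and no other group's non-missing call carries
    it.  *nearly fixed*: more than half of the non-missing target
    individuals carry it and the carrier fraction outside the target
    group does not exceed ``leakage_tol``.  Candidates meeting neither
    definition return ``(None, reason)`` and are dropped from panel
    consideration.
    """
    index = _loci_by_id(loci)
    locus = index[cand.locus_id]
    by_group = _group_genotypes(locus, cand.site, species_map)
    diag = cand.diagnostic_allele

    target = [gt for gt in by_group[cand.target_group].values() if gt is not None]
    if not target:
        return None, "no_target_data"
    hom_diag = sum(1 for gt in target if gt == (diag, diag))
    carriers = sum(1 for gt in target if diag in gt)

    cross_n = cross_carriers = 0
    for group, genos in by_group.items():
        if group == cand.target_group:
            continue
        for gt in genos.values():
            if gt is None:
                continue
            cross_n += 1
            if diag in gt:
                cross_carriers += 1

    if hom_diag == len(target) and cross_carriers == 0:
        return "fixed", ""
    leakage = cross_carriers / cross_n if cross_n else 0.0
    if carriers / len(target) > 0.5 and leakage <= leakage_tol:
        return "nearly_fixed", ""
    if leakage > leakage_tol:
        return None, f"leakage:{leakage:.3f}"
    return None, "minority_in_target"


def classify_candidates(cands, loci, species_map, *,
                        leakage_tol: float = LEAKAGE_TOL) -> list[SNPCandidate]:
    """Attach fixedness classes; drop candidates that fit neither class."""
    out = []
    for cand in cands:
        klass, reason = classify_fixedness(cand, loci, species_map, leakage_tol=leakage_tol)
        if klass is None:
            logger.info("dropping %s: %s", cand.key, reason)
            continue
        out.append(replace(cand, fixedness=klass))
    return out
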