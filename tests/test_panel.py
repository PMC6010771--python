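"""Panel selection under quotas/caps and multiplex packing with dimer conflicts."""

import itertools

import pytest

import snpbarcode as sb
from snpbarcode.iupac import reverse_complement
from snpbarcode.panel import rank_key
from tests.conftest import make_locus


def cand(locus_id, site=40, target="g1", fst=1.0, n_pairs=2,
         fixedness="fixed", diag="C", other="A"):
    return sb.SNPCandidate(
        locus_id=locus_id, site=site, target_group=target,
        diagnostic_allele=diag, other_allele=other,
        max_pairwise_fst=fst, n_pairs_at_threshold=n_pairs,
        route="stringent", fixedness=fixedness,
        flank5=site, flank3=85 - 1 - site,
    )


def make_candidates(groups, per_group, fixedness="fixed"):
    out = []
    for g in groups:
        for i in range(per_group):
            out.append(cand(f"L_{g}_{i:02d}", target=g, fixedness=fixedness))
    return out


# ---------------------------------------------------------------------------
# assay_compatible


@pytest.fixture
def smap1():
    return sb.SpeciesMap.from_records([("i1", "g1", "g1"), ("i2", "g2", "g2")])


def test_clean_biallelic_flanks_are_compatible(smap1):
    locus = make_locus({40: {"i1": "C"}}, ["i1", "i2"])
    ok, reason = sb.assay_compatible(cand("L1"), locus)
    assert ok and reason == ""


def test_gap_in_flank_is_rejected_as_indel(smap1):
    cols = {40: {"i1": "C"}}
    for pos in (25, 26, 27):
        cols[pos] = {"i1": "-", "i2": "-"}
    locus = make_locus(cols, ["i1", "i2"])
    ok, reason = sb.assay_compatible(cand("L1"), locus)
    assert not ok and reason == "indel"


def test_three_ambiguous_flank_positions_rejected_two_allowed(smap1):
    def locus_with_n(k):
        cols = {40: {"i1": "C"}}
        for pos in range(22, 22 + k):
            cols[pos] = {"i1": "N", "i2": "N"}
        return make_locus(cols, ["i1", "i2"])

    ok2, _ = sb.assay_compatible(cand("L1"), locus_with_n(2))
    ok3, reason = sb.assay_compatible(cand("L1"), locus_with_n(3))
    assert ok2
    assert not ok3 and reason == "ambiguity"


def test_non_biallelic_focal_site_rejected(smap1):
    # triallelic focal column: C, G, and the A fill of the third individual
    locus = make_locus({40: {"i1": "C", "i2": "G"}}, ["i1", "i2", "i3"])
    ok, reason = sb.assay_compatible(cand("L1"), locus)
    assert not ok and reason == "not_biallelic"


# ---------------------------------------------------------------------------
# select_panel


def test_abundant_supply_takes_quota_max_per_group():
    cands = make_candidates(["g1", "g2", "g3"], 10)
    panel = sb.select_panel(cands, quota=(5, 6), max_total=80)
    assert len(panel.entries) == 18
    assert panel.per_group_counts() == {"g1": 6, "g2": 6, "g3": 6}
    assert panel.deficits == {}


def test_scarce_group_contributes_all_and_logs_deficit():
    cands = make_candidates(["g1"], 10) + make_candidates(["g2"], 2)
    panel = sb.select_panel(cands, quota=(5, 6), max_total=80)
    assert panel.per_group_counts() == {"g1": 6, "g2": 2}
    assert panel.deficits == {"g2": 3}


def test_global_cap_trims_surplus_beyond_quota_minima():
    cands = make_candidates(["g1", "g2", "g3"], 10)
    panel = sb.select_panel(cands, quota=(5, 6), max_total=16)
    assert len(panel.entries) == 16
    counts = panel.per_group_counts()
    assert all(c >= 5 for c in counts.values())


def test_selection_is_deterministic_and_order_independent():
    cands = make_candidates(["g1", "g2"], 8)
    a = sb.select_panel(cands)
    b = sb.select_panel(list(reversed(cands)))
    assert [e.key for e in a.entries] == [e.key for e in b.entries]


def test_panel_size_matches_exhaustive_enumeration_on_small_instance():
    """Greedy panel size equals the optimum found by exhaustive search
    over all feasible selections on a 30-candidate instance."""
    groups = ["g1", "g2", "g3"]
    per_group = {"g1": 12, "g2": 3, "g3": 15}
    cands = []
    for g in groups:
        cands.extend(make_candidates([g], per_group[g]))
    qmin, qmax, cap = 5, 6, 14
    panel = sb.select_panel(cands, quota=(qmin, qmax), max_total=cap)

    # oracle: enumerate per-group take counts, maximize total under rules
    best = 0
    ranges = [range(0, min(per_group[g], qmax) + 1) for g in groups]
    for takes in itertools.product(*ranges):
        if sum(takes) > cap:
            continue
        ok = all(
            t == min(per_group[g], qmax) or t >= qmin
            for g, t in zip(groups, takes)
        )
        if ok:
            best = max(best, sum(takes))
    assert len(panel.entries) == best == min(cap, sum(
        min(per_group[g], qmax) for g in groups))


def test_fixed_candidates_outrank_nearly_fixed():
    c_fixed = cand("L_z", fixedness="fixed", fst=0.96)
    c_near = cand("L_a", fixedness="nearly_fixed", fst=1.0)
    assert rank_key(c_fixed) < rank_key(c_near)


def test_empty_candidate_list_gives_empty_panel():
    panel = sb.select_panel([])
    assert panel.entries == [] and panel.n_plexes == 0


# ---------------------------------------------------------------------------
# multiplex assignment


def _loci_for(cands, individuals=("i1", "i2"), flank_seed=0):
    """One monomorphic-except-focal locus per candidate."""
    loci = []
    for c in cands:
        cols = {c.site: {individuals[0]: c.diagnostic_allele}}
        loci.append(make_locus(cols, list(individuals), locus_id=c.locus_id))
    return loci


def test_eighty_entries_without_conflicts_pack_forty_forty():
    cands = make_candidates([f"g{i}" for i in range(1, 17)], 5)  # 80 entries
    panel = sb.select_panel(cands, quota=(5, 5), max_total=80)
    assert len(panel.entries) == 80
    panel = sb.assign_multiplexes(panel, _loci_for(panel.entries))
    sizes = sorted(len(m) for m in panel.plex_members().values())
    assert sizes == [40, 40]
    assert panel.unplaceable == []


def test_forty_one_entries_pack_forty_plus_one():
    cands = make_candidates([f"g{i}" for i in range(1, 42)], 1)
    panel = sb.select_panel(cands, quota=(1, 1), max_total=80)
    panel = sb.assign_multiplexes(panel, _loci_for(panel.entries))
    assert sorted(len(m) for m in panel.plex_members().values()) == [1, 40]


def test_planted_complementary_8mer_pair_lands_in_different_plexes():
    word = "ACGTTCCA"
    c1, c2 = cand("L_a", target="g1"), cand("L_b", target="g2")
    individuals = ["i1", "i2"]
    # place the word in the 10 bp 5'-proximal window of both entries,
    # reverse-complemented in the second
    cols1 = {c1.site: {"i1": "C"}}
    cols2 = {c2.site: {"i1": "C"}}
    loci = []
    for c, cols, w in ((c1, cols1, word), (c2, cols2, reverse_complement(word))):
        base = make_locus(cols, individuals, locus_id=c.locus_id)
        seqs = {}
        for ind, seq in base.sequences.items():
            s = list(seq)
            s[c.site - 10:c.site - 2] = list(w)
            seqs[ind] = "".join(s)
        loci.append(sb.LocusAlignment(c.locus_id, seqs, source="simulated"))
    panel = sb.select_panel([c1, c2], quota=(1, 1), max_total=80)
    panel = sb.assign_multiplexes(panel, loci)
    k1, k2 = c1.key, c2.key
    assert panel.multiplex_of[k1] != panel.multiplex_of[k2]


def test_conflicting_entry_unplaceable_under_plex_cap():
    word = "ACGTTCCA"
    c1, c2 = cand("L_a", target="g1"), cand("L_b", target="g2")
    loci = []
    for c, w in ((c1, word), (c2, reverse_complement(word))):
        base = make_locus({c.site: {"i1": "C"}}, ["i1", "i2"], locus_id=c.locus_id)
        seqs = {ind: seq[:c.site - 10] + w + seq[c.site - 2:]
                for ind, seq in base.sequences.items()}
        loci.append(sb.LocusAlignment(c.locus_id, seqs, source="simulated"))
    panel = sb.select_panel([c1, c2], quota=(1, 1), max_total=80)
    panel = sb.assign_multiplexes(panel, loci, max_plexes=1)
    assert len(panel.unplaceable) == 1
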