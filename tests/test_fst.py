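"""Allele counting and F_ST estimators against hand and brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import snpbarcode as sb
from snpbarcode.fst import SiteCounts, _top_two_alleles, pairwise_fst, site_allele_counts
from snpbarcode.iupac import genotype_from_code
from tests.conftest import make_locus


# ---------------------------------------------------------------------------
# independent brute-force oracle


def brute_force_fst(col_a, col_b):
    """Nei two-group F_ST from raw IUPAC columns, by direct expansion."""
    def copies(column):
        out = []
        for ch in column:
            gt = genotype_from_code(ch)
            if gt is not None:
                out.extend(gt)
        return out

    ca, cb = copies(col_a), copies(col_b)
    if len(ca) < 2 or len(cb) < 2:
        return None
    pooled = sorted(set(ca + cb))
    counts = {al: (ca + cb).count(al) for al in pooled}
    top = sorted(pooled, key=lambda al: (-counts[al], al))[:2]
    if len(top) < 2:
        return 0.0
    ra = [al for al in ca if al in top]
    rb = [al for al in cb if al in top]
    if not ra or not rb:
        return None
    pa = ra.count(top[0]) / len(ra)
    pb = rb.count(top[0]) / len(rb)
    hs = (2 * pa * (1 - pa) + 2 * pb * (1 - pb)) / 2
    ht = 2 * ((pa + pb) / 2) * (1 - (pa + pb) / 2)
    return 0.0 if ht == 0 else (ht - hs) / ht


def brute_force_scan(loci, smap, threshold=0.95):
    """Enumerate every site and group pair; reimplements the candidate rule."""
    hits = set()
    groups = smap.groups
    for locus in loci:
        for site in range(locus.length):
            cols = {g: [] for g in groups}
            for ind, ch in locus.column(site).items():
                cols[smap.group_of(ind)].append(ch)
            fst = {}
            for ga, gb in itertools.combinations(groups, 2):
                v = brute_force_fst(cols[ga], cols[gb])
                if v is not None:
                    fst[(ga, gb)] = min(1.0, max(0.0, v))
            present = [g for g in groups if sum(
                1 for ch in cols[g] if genotype_from_code(ch) is not None) >= 1]
            for target in present:
                vals = [fst.get((min(target, g), max(target, g)))
                        for g in present if g != target]
                if not (vals and all(v is not None and v >= threshold for v in vals)):
                    continue
                # a candidate also needs a target allele and a distinct
                # majority allele among the remaining groups
                tcopies = []
                for ch in cols[target]:
                    gt = genotype_from_code(ch)
                    if gt is not None:
                        tcopies.extend(gt)
                diag = sorted(set(tcopies),
                              key=lambda al: (-tcopies.count(al), al))[0]
                ocopies = []
                for g in present:
                    if g == target:
                        continue
                    for ch in cols[g]:
                        gt = genotype_from_code(ch)
                        if gt is not None:
                            ocopies.extend(a for a in gt if a != diag)
                if ocopies:
                    hits.add((locus.locus_id, site, target))
    return hits


# ---------------------------------------------------------------------------
# site_allele_counts


def test_counts_expand_diploid_iupac(smap2x4):
    # gA column [A, A, R, N]; gB column [C, Y, T, T]
    locus = make_locus(
        {5: {"gA_3": "R", "gA_4": "N",
             "gB_1": "C", "gB_2": "Y", "gB_3": "T", "gB_4": "T"}},
        smap2x4.individuals,
    )
    counts = site_allele_counts(locus, 5, smap2x4)
    assert counts["gA"].allele_counts == {"A": 5, "G": 1}
    assert counts["gA"].n_copies == 6
    assert counts["gA"].n_individuals_nonmissing == 3
    assert counts["gB"].allele_counts == {"C": 3, "T": 5}


def test_all_missing_column_has_zero_copies(smap3):
    locus = make_locus(
        {5: {ind: "N" for ind in smap3.individuals}}, smap3.individuals
    )
    counts = site_allele_counts(locus, 5, smap3)
    assert all(c.n_copies == 0 for c in counts.values())
    assert pairwise_fst(counts["gA"], counts["gB"]) is None


def test_three_allele_codes_flagged_and_contribute_nothing(smap3):
    locus = make_locus({5: {"gA_1": "B"}}, smap3.individuals)
    counts = site_allele_counts(locus, 5, smap3)
    assert counts["gA"].n_flagged == 1
    assert counts["gA"].allele_counts == {"A": 2}


# ---------------------------------------------------------------------------
# pairwise_fst


def _sc(**genos):
    return SiteCounts("g", {k: v for k, v in genos.items()})


def test_fixed_difference_gives_one():
    a = SiteCounts("a", {("A", "A"): 3})
    b = SiteCounts("b", {("T", "T"): 3})
    assert pairwise_fst(a, b) == 1.0
    assert pairwise_fst(a, b, "wc84") == 1.0


def test_equal_frequencies_give_zero():
    a = SiteCounts("a", {("A", "T"): 2})  # p = 0.5
    b = SiteCounts("b", {("A", "A"): 1, ("T", "T"): 1})
    assert pairwise_fst(a, b) == pytest.approx(0.0)


def test_hand_worked_nei_value():
    # pA = 0.9 (9 A / 1 T), pB = 0.1: H_S = 0.18, H_T = 0.5 -> 0.64
    a = SiteCounts("a", {("A", "A"): 4, ("A", "T"): 1})
    b = SiteCounts("b", {("T", "T"): 4, ("A", "T"): 1})
    assert pairwise_fst(a, b) == pytest.approx(0.64)


def test_symmetry_and_allele_relabeling_invariance():
    rng = np.random.default_rng(0)
    for _ in range(50):
        ga = {}
        gb = {}
        for pair in [("A", "A"), ("A", "T"), ("T", "T")]:
            ga[pair] = int(rng.integers(0, 4))
            gb[pair] = int(rng.integers(0, 4))
        a, b = SiteCounts("a", ga), SiteCounts("b", gb)
        for est in ("nei87", "wc84"):
            v1 = pairwise_fst(a, b, est)
            v2 = pairwise_fst(b, a, est)
            # relabel T <-> C
            ra = SiteCounts("a", {tuple(sorted(p.replace("T", "C") for p in k)): v
                                  for k, v in ga.items()})
            rb = SiteCounts("b", {tuple(sorted(p.replace("T", "C") for p in k)): v
                                  for k, v in gb.items()})
            v3 = pairwise_fst(ra, rb, est)
            if v1 is None:
                assert v2 is None and v3 is None
            else:
                assert v1 == pytest.approx(v2)
                assert v1 == pytest.approx(v3)


@settings(deadline=None, max_examples=80)
@given(
    st.integers(0, 6), st.integers(0, 6), st.integers(0, 6),
    st.integers(0, 6), st.integers(0, 6), st.integers(0, 6),
)
def test_nei_estimate_lies_in_unit_interval(a0, a1, a2, b0, b1, b2):
    a = SiteCounts("a", {("A", "A"): a0, ("A", "T"): a1, ("T", "T"): a2})
    b = SiteCounts("b", {("A", "A"): b0, ("A", "T"): b1, ("T", "T"): b2})
    v = pairwise_fst(a, b)
    if v is not None:
        assert -1e-12 <= v <= 1.0 + 1e-12
        pa_fixed = a1 == 0 and (a0 == 0 or a2 == 0)
        pb_fixed = b1 == 0 and (b0 == 0 or b2 == 0)
        opposite = pa_fixed and pb_fixed and (
            (a0 > 0) != (b0 > 0)
        )
        assert (v == pytest.approx(1.0)) == opposite


def test_top_two_allele_selection_pools_the_pair():
    a = SiteCounts("a", {("A", "A"): 5, ("C", "C"): 1})
    b = SiteCounts("b", {("T", "T"): 5})
    assert _top_two_alleles(a, b) == ("A", "T")


# ---------------------------------------------------------------------------
# scan vs brute force


def test_scan_matches_bruteforce_on_small_instances():
    cfg = sb.SimulationConfig(
        n_species=3, n_individuals_per_species=2, n_loci=5, locus_len=45,
        prop_diagnostic=0.4, background_theta=0.05, het_rate=0.6,
        missing_rate=0.05, seed=13,
    )
    loci, smap, _ = sb.simulate_locus_set(cfg)
    cands = sb.scan(loci, smap, threshold=0.95, min_copies=2)
    brute = brute_force_scan(loci, smap, threshold=0.95)
    assert {(c.locus_id, c.site, c.target_group) for c in cands} == brute


def test_scan_recovers_exactly_the_planted_sites_with_background():
    cfg = sb.SimulationConfig(
        n_species=4, n_individuals_per_species=4, n_loci=50,
        prop_diagnostic=0.3, background_theta=0.02, missing_rate=0.02, seed=21,
    )
    loci, smap, truth = sb.simulate_locus_set(cfg)
    cands = sb.scan(loci, smap, threshold=0.95)
    assert {(c.locus_id, c.site, c.target_group) for c in cands} == {
        (r.locus_id, r.site, r.target_group) for r in truth.itertuples()
    }
    assert len(truth) == 15


def test_unreachable_threshold_yields_empty_list(simulated_set):
    _, loci, smap, _ = simulated_set
    assert sb.scan(loci[:10], smap, threshold=1.01) == []


def test_scan_invariant_to_individual_order(simulated_set):
    _, loci, smap, _ = simulated_set
    subset = loci[:10]
    shuffled = [
        sb.LocusAlignment(
            l.locus_id,
            {ind: l.sequences[ind] for ind in reversed(l.individuals)},
            source=l.source,
        )
        for l in subset
    ]
    assert sb.scan(subset, smap) == sb.scan(shuffled, smap)
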