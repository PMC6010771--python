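"""Shared fixtures: small hand-built loci and simulated datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import snpbarcode as sb


def make_locus(columns: dict[int, dict[str, str]], individuals, length=85,
               locus_id="L1", fill="A", source="simulated"):
    """Build a LocusAlignment from per-site overrides.

    ``columns`` maps 0-based site -> {individual: IUPAC char}; all other
    positions are ``fill`` for everyone.
    """
    seqs = {}
    for ind in individuals:
        chars = [fill] * length
        for site, assignment in columns.items():
            chars[site] = assignment.get(ind, fill)
        seqs[ind] = "".join(chars)
    return sb.LocusAlignment(locus_id, seqs, source=source)


@pytest.fixture
def smap3():
    """Three groups of two individuals each."""
    return sb.SpeciesMap.from_records(
        [(f"{g}_{i}", g, g) for g in ("gA", "gB", "gC") for i in (1, 2)]
    )


@pytest.fixture
def smap2x4():
    """Two groups of four individuals each."""
    return sb.SpeciesMap.from_records(
        [(f"{g}_{i}", g, g) for g in ("gA", "gB") for i in range(1, 5)]
    )


@pytest.fixture(scope="session")
def simulated_set():
    """Moderate simulated locus set with planted truth (shared, read-only)."""
    cfg = sb.SimulationConfig(
        n_species=4, n_individuals_per_species=4, n_loci=100,
        prop_diagnostic=0.4, background_theta=0.02, missing_rate=0.02, seed=42,
    )
    loci, smap, truth = sb.simulate_locus_set(cfg)
    return cfg, loci, smap, truth


def diagnostic_panel(n_groups: int, snps_per_group: int, *,
                     target_freq=1.0, leakage=0.0):
    """Planted-truth panel frequencies for offspring simulation."""
    groups = [f"sp{i + 1:02d}" for i in range(n_groups)]
    rows = [
        {"locus_id": f"L{gi}_{j}", "site": 30, "target_group": g,
         "diagnostic_allele": "A", "other_allele": "T"}
        for gi, g in enumerate(groups) for j in range(snps_per_group)
    ]
    pf = sb.diagnostic_panel_frequencies(
        pd.DataFrame(rows), groups, target_freq=target_freq, leakage=leakage
    )
    return pf, groups


def stack_genotypes(G1, G2):
    return sb.GenotypeMatrix(
        G1.individuals + G2.individuals, G1.snp_ids,
        np.vstack([G1.calls, G2.calls]),
    )
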