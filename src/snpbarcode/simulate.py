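"""Synthetic multi-species RAD locus sets and admixed offspring genotypes.

The generator emulates the output shape of a de novo RAD clustering
pipeline applied to a multi-species sample: per-locus alignments of
short (default 85 bp) per-individual consensus sequences in which a
single IUPAC character encodes a diploid genotype.  A controllable
fraction of loci carries one *planted* fixed difference between a
designated target group and all other groups — the ground truth that
downstream discovery must recover.

Within-species background polymorphism is modelled as low-frequency
segregating variation: at a polymorphic (site, species) combination,
individuals are heterozygous for the alternative allele with
probability ``het_rate`` and otherwise homozygous for the reference
base.  The alternative allele therefore never fixes within a species,
which bounds the background two-group F_ST well below the diagnostic
threshold and keeps planted sites identifiable as ground truth.
Missing data (``N``) is applied per base at ``missing_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import GenotypeMatrix, LocusAlignment, SpeciesMap
from .iupac import code_from_genotype

NUCLEOTIDES = np.array(["A", "C", "G", "T"])

#: flanking room required so the primer-flank rule is satisfiable
_FLANK = 20

GENERATIONS = ("pure", "F1", "BC1")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for locus-set simulation.

    Defaults emulate a small multi-species RAD screen: 85-bp loci, a few
    individuals per species, moderate background polymorphism.
    """

    n_species: int = 6
    n_individuals_per_species: int = 4
    n_loci: int = 100
    locus_len: int = 85
    prop_diagnostic: float = 0.3
    background_theta: float = 0.02
    het_rate: float = 0.5
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prop_diagnostic", "background_theta", "het_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.locus_len < 2 * _FLANK + 1:
            raise ValueError(
                f"locus_len must be >= {2 * _FLANK + 1} to leave room for "
                f"{_FLANK}-bp flanks around a diagnostic site"
            )
        if self.n_species < 2 or self.n_individuals_per_species < 1:
            raise ValueError("need >= 2 species and >= 1 individual per species")


@dataclass(frozen=True)
class AncestryTruth:
    """Known ancestry fractions per simulated individual (rows sum to 1)."""

    individuals: list[str]
    groups: list[str]
    q: np.ndarray  # n_individuals x n_groups

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.shape != (len(self.individuals), len(self.groups)):
            raise ValueError("q shape mismatch")
        if (q < 0).any() or not np.allclose(q.sum(axis=1), 1.0):
            raise ValueError("ancestry rows must be non-negative and sum to 1")
        object.__setattr__(self, "q", q)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.q, index=self.individuals, columns=self.groups)


def default_species_map(cfg: SimulationConfig) -> SpeciesMap:
    records = []
    for s in range(cfg.n_species):
        species = f"sp{s + 1:02d}"
        for i in range(cfg.n_individuals_per_species):
            records.append((f"{species}_ind{i + 1}", species, species))
    return SpeciesMap.from_records(records)


def simulate_locus_set(cfg: SimulationConfig):
    """Simulate a locus set with planted diagnostic sites.

    Returns ``(loci, species_map, truth)`` where ``truth`` is a
    DataFrame with one row per planted site: locus_id, site (0-based),
    target_group, diagnostic_allele, other_allele.  Exactly
    ``round(prop_diagnostic * n_loci)`` loci carry a planted fixed
    difference, at a position where both 20-bp flanks fit.  Output is
    bit-reproducible for a given config.
    """
    rng = np.random.default_rng(cfg.seed)
    species_map = default_species_map(cfg)
    groups = species_map.groups
    n_diag = int(round(cfg.prop_diagnostic * cfg.n_loci))

    loci: list[LocusAlignment] = []
    truth_rows = []
    for li in range(cfg.n_loci):
        locus_id = f"L{li + 1:05d}"
        ref = rng.choice(NUCLEOTIDES, size=cfg.locus_len)
        diagnostic = li < n_diag
        diag_site = -1
        target = None
        diag_allele = other_allele = None
        if diagnostic:
            diag_site = int(rng.integers(_FLANK, cfg.locus_len - _FLANK))
            target = groups[int(rng.integers(len(groups)))]
            other_allele = str(ref[diag_site])
            choices = [b for b in "ACGT" if b != other_allele]
            diag_allele = choices[int(rng.integers(3))]
            truth_rows.append(
                {
                    "locus_id": locus_id,
                    "site": diag_site,
                    "target_group": target,
                    "diagnostic_allele": diag_allele,
                    "other_allele": other_allele,
                }
            )

        # per-(site, species) background polymorphism, never at the planted site
        background: dict[tuple[int, str], str] = {}
        if cfg.background_theta > 0:
            for site in range(cfg.locus_len):
                if site == diag_site:
                    continue
                for g in groups:
                    if rng.random() < cfg.background_theta:
                        alts = [b for b in "ACGT" if b != ref[site]]
                        background[(site, g)] = alts[int(rng.integers(3))]

        sequences: dict[str, str] = {}
        for ind in species_map.individuals:
            g = species_map.group_of(ind)
            chars = []
            for site in range(cfg.locus_len):
                if rng.random() < cfg.missing_rate:
                    chars.append("N")
                    continue
                base = str(ref[site])
                if site == diag_site and g == target:
                    chars.append(diag_allele)
                    continue
                alt = background.get((site, g))
                if alt is not None and rng.random() < cfg.het_rate:
                    chars.append(code_from_genotype(base, alt))
                else:
                    chars.append(base)
            sequences[ind] = "".join(chars)
        loci.append(LocusAlignment(locus_id, sequences, source="simulated"))

    truth = pd.DataFrame(
        truth_rows,
        columns=["locus_id", "site", "target_group", "diagnostic_allele", "other_allele"],
    )
    return loci, species_map, truth


def simulate_dual_pipeline_sets(cfg_a: SimulationConfig, cfg_b: SimulationConfig,
                                n_shared: int, seed: int, *,
                                shared_mutations: int = 1):
    """Two independent locus sets sharing ``n_shared`` underlying loci.

    Emulates running two clustering pipelines over the same reads: most
    loci are recovered by only one pipeline, a few by both.  The shared
    copies in set B are the set-A consensus with ``shared_mutations``
    random substitutions (pipelines rarely emit byte-identical
    consensus).  Returns ``(loci_a, loci_b, truth_pairs)`` where
    ``truth_pairs`` lists the planted (idA, idB) duplicates.
    """
    if n_shared > min(cfg_a.n_loci, cfg_b.n_loci):
        raise ValueError("n_shared exceeds a set size")
    rng = np.random.default_rng(seed)
    loci_a, _, _ = simulate_locus_set(cfg_a)
    loci_b, _, _ = simulate_locus_set(cfg_b)
    loci_a = [LocusAlignment(f"A_{l.locus_id}", l.sequences, source="pipelineA") for l in loci_a]
    loci_b = [LocusAlignment(f"B_{l.locus_id}", l.sequences, source="pipelineB") for l in loci_b]
    pairs = []
    idx_a = rng.choice(len(loci_a), size=n_shared, replace=False)
    idx_b = rng.choice(len(loci_b), size=n_shared, replace=False)
    for ia, ib in zip(idx_a, idx_b):
        src = loci_a[int(ia)]
        template = list(next(iter(src.sequences.values())).replace("N", "A"))
        for _ in range(shared_mutations):
            pos = int(rng.integers(len(template)))
            template[pos] = str(rng.choice([b for b in "ACGT" if b != template[pos]]))
        old = loci_b[int(ib)]
        seqs = {ind: "".join(template) for ind in old.sequences}
        loci_b[int(ib)] = LocusAlignment(old.locus_id, seqs, source="pipelineB")
        pairs.append((src.locus_id, old.locus_id))
    return loci_a, loci_b, sorted(pairs)


# ---------------------------------------------------------------------------
# offspring genotypes


@dataclass(frozen=True)
class PanelFrequencies:
    """Per-group frequencies of each panel SNP's diagnostic allele."""

    snp_ids: list[str]
    alleles: dict[str, tuple[str, str]]  # snp -> (diagnostic, other)
    groups: list[str]
    freq: np.ndarray = field(default=None)  # n_groups x n_snps, freq of diagnostic allele

    def __post_init__(self) -> None:
        f = np.asarray(self.freq, dtype=float)
        if f.shape != (len(self.groups), len(self.snp_ids)):
            raise ValueError("freq shape mismatch")
        if (f < 0).any() or (f > 1).any():
            raise ValueError("allele frequencies must lie in [0, 1]")
        object.__setattr__(self, "freq", f)


def diagnostic_panel_frequencies(truth: pd.DataFrame, groups, snp_ids=None, *,
                                 target_freq: float = 1.0,
                                 leakage: float = 0.0) -> PanelFrequencies:
    """Panel frequencies from a planted-truth table.

    With the defaults the diagnostic allele is *fixed*: frequency 1 in
    its target group and 0 elsewhere.  ``target_freq`` and ``leakage``
    relax this to the *nearly fixed* regime typical of verified barcode
    SNPs (e.g. 0.95 in the target group, 0.02 elsewhere).
    """
    if snp_ids is None:
        snp_ids = [f"{r.locus_id}_pos{r.site + 1}" for r in truth.itertuples()]
    groups = list(groups)
    freq = np.full((len(groups), len(truth)), leakage)
    alleles = {}
    for j, row in enumerate(truth.itertuples()):
        alleles[snp_ids[j]] = (row.diagnostic_allele, row.other_allele)
        freq[groups.index(row.target_group), j] = target_freq
    return PanelFrequencies(list(snp_ids), alleles, groups, freq)


def _draw_gamete(freqs_row, alleles, snp_ids, rng):
    out = []
    for j, snp in enumerate(snp_ids):
        diag, other = alleles[snp]
        out.append(diag if rng.random() < freqs_row[j] else other)
    return out


def simulate_offspring(panel: PanelFrequencies, crosses, n_per_cross: int,
                       missing_rate: float, seed: int):
    """Simulate diploid genotypes for pure, F1, and first-backcross individuals.

    ``crosses`` is a list of ``((parentA, parentB), generation)`` with
    generation in {"pure", "F1", "BC1"}.  For "pure" only ``parentA``
    is used.  BC1 draws one gamete from the recurrent parent
    (``parentA``) and one from an F1 parent.  True ancestry is recorded
    as (1, 0), (0.5, 0.5) and (0.75, 0.25).

    Returns ``(GenotypeMatrix, AncestryTruth)``.
    """
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    groups = panel.groups
    gidx = {g: k for k, g in enumerate(groups)}
    individuals, calls, q_rows = [], [], []
    counter = 0
    for (pa, pb), generation in crosses:
        if generation not in GENERATIONS:
            raise ValueError(f"unknown generation code {generation!r}")
        fa = panel.freq[gidx[pa]]
        fb = panel.freq[gidx[pb]] if pb is not None else None
        for _ in range(n_per_cross):
            counter += 1
            if generation == "pure":
                g1 = _draw_gamete(fa, panel.alleles, panel.snp_ids, rng)
                g2 = _draw_gamete(fa, panel.alleles, panel.snp_ids, rng)
                q = {pa: 1.0}
            elif generation == "F1":
                g1 = _draw_gamete(fa, panel.alleles, panel.snp_ids, rng)
                g2 = _draw_gamete(fb, panel.alleles, panel.snp_ids, rng)
                q = {pa: 0.5, pb: 0.5}
            else:  # BC1: recurrent-parent gamete + F1 gamete
                g1 = _draw_gamete(fa, panel.alleles, panel.snp_ids, rng)
                g2 = []
                for j, snp in enumerate(panel.snp_ids):
                    diag, other = panel.alleles[snp]
                    f = fa[j] if rng.random() < 0.5 else fb[j]
                    g2.append(diag if rng.random() < f else other)
                q = {pa: 0.75, pb: 0.25}
            name = f"{generation}_{pa}" + (f"x{pb}" if generation != "pure" else "")
            individuals.append(f"{name}_{counter:03d}")
            row = []
            for j in range(len(panel.snp_ids)):
                if rng.random() < missing_rate:
                    row.append(None)
                else:
                    row.append(tuple(sorted((g1[j], g2[j]))))
            calls.append(row)
            qvec = np.zeros(len(groups))
            for g, v in q.items():
                qvec[gidx[g]] = v
            q_rows.append(qvec)
    G = GenotypeMatrix(individuals, list(panel.snp_ids), calls)
    truth = AncestryTruth(individuals, groups, np.array(q_rows))
    return G, truth
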