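"""Bundled summary counts from a published multi-species oak SNP-barcode
development campaign, used as a worked bookkeeping example.

The fixture records, per species or species group, how many candidate
SNPs entered assay design, survived it, amplified in screening, and
reached the final two-multiplex 80-SNP barcode, plus the per-mother-tree
germination/amplification tallies from the proof-of-concept acorn
genotyping.  The :func:`summarize_*` functions recompute the derived
quantities (stage totals, per-species means and standard deviations,
amplification and hybridization percentages) from the raw counts so the
funnel arithmetic is reproducible without any external data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# Stage funnel per screening route: candidates entering primer design,
# passing it, and actually multiplexed for screening.
SCREEN_FUNNEL = pd.DataFrame(
    {
        "total": [395, 449],
        "passed": [131, 213],
        "multiplexed": [131, 160],
    },
    index=["stringent_screen", "relaxed_screen"],
)

# Per-species SNP counts: sample size, candidates initially selected,
# passing assay design, verified by mass-spectrometry screening,
# included in the 80-SNP barcode, and used in the admixture analysis.
SPECIES_COUNTS = pd.DataFrame(
    [
        ("Q_alba", 4, 95, 30, 20, 5, 3),
        ("Q_austrina", 2, 25, 8, 8, 5, 4),
        ("Q_bicolor", 2, 22, 10, 7, 5, 4),
        ("Q_boyntonii", 2, 2, 1, 0, 0, 0),
        ("Q_chapmanii", 2, 10, 4, 4, 1, 1),
        ("Q_lyrata", 4, 35, 8, 7, 4, 3),
        ("Q_macrocarpa", 9, 64, 15, 7, 4, 3),
        ("Q_michauxii", 5, 57, 23, 19, 8, 5),
        ("Q_montana", 4, 84, 33, 25, 8, 7),
        ("Q_muehlenbergii_prinoides", 6, 143, 45, 25, 8, 7),
        ("Q_oglethorpensis", 3, 22, 7, 6, 4, 4),
        ("Q_sinuata", 2, 31, 16, 13, 8, 7),
        ("Q_stellata", 3, 52, 26, 21, 13, 12),
        ("clade1", 14, 7, 6, 7, 2, 1),
        ("clade2", 4, 3, 0, 0, 0, 0),
        ("east_asian_white_oaks", 4, 98, 29, 10, 4, 4),
        ("european_white_oaks", 11, 94, 30, 8, 1, 1),
    ],
    columns=["group", "n_individuals", "snps_start", "snps_design",
             "snps_verified", "snps_barcode", "snps_admixture"],
).set_index("group")

# Acorn genotyping per mother tree: acorns planted, germinated,
# seedlings with high (71-100%) assay amplification, seedlings with low
# (0-70%) amplification, and hybrids called among the high-amplification
# seedlings (>5% admixture rule).
MOTHER_TREES = pd.DataFrame(
    [
        ("645-48*2", "Q_michauxii", 100, 70, 63, 7, 22),
        ("602-2000*1sd", "Q_montana", 50, 45, 32, 13, 1),
        ("210-91*1", "Q_stellata", 71, 43, 35, 8, 2),
        ("602-2000*2", "Q_montana", 50, 35, 20, 15, 0),
        ("704-46*2sdT", "Q_muehlenbergii", 50, 12, 3, 9, 0),
        ("326-99*2", "Q_prinoides", 29, 9, 6, 3, 0),
        ("742-51*1", "Q_prinoides", 67, 8, 6, 2, 2),
        ("602-2000*3", "Q_montana", 7, 5, 2, 3, 1),
        ("704-46*3sdT", "Q_muehlenbergii", 6, 1, 1, 0, 0),
    ],
    columns=["individual_id", "species", "n_planted", "n_germinated",
             "n_amplified_high", "n_amplified_low", "n_hybrids"],
).set_index("individual_id")


def summarize_funnel() -> pd.DataFrame:
    """Stage funnel with the combined-route totals appended."""
    out = SCREEN_FUNNEL.copy()
    out.loc["both_screens"] = SCREEN_FUNNEL.sum()
    return out


def summarize_species_counts() -> pd.DataFrame:
    """Column totals and per-group mean +/- sample SD of each SNP stage."""
    cols = ["snps_start", "snps_design", "snps_verified",
            "snps_barcode", "snps_admixture"]
    rows = {}
    for c in cols:
        v = SPECIES_COUNTS[c].to_numpy(dtype=float)
        rows[c] = {
            "total": int(v.sum()),
            "mean": float(np.round(v.mean(), 1)),
            "sd": float(np.round(v.std(ddof=1), 1)),
        }
    return pd.DataFrame(rows).T


def summarize_mother_trees() -> pd.DataFrame:
    """Derived per-mother-tree rates.

    Percentages are truncated to whole percent (matching field-report
    convention) except the hybridization frequency, which is reported
    to the shown precision.
    """
    def _trunc_pct(num, den):
        return np.floor(100.0 * num / den + 1e-9).astype(int)

    df = MOTHER_TREES.copy()
    df["germination_pct"] = _trunc_pct(df["n_germinated"], df["n_planted"])
    df["amplification_pct"] = _trunc_pct(df["n_amplified_high"], df["n_germinated"])
    freq = 100 * df["n_hybrids"] / df["n_amplified_high"]
    df["hybridization_freq"] = freq.round(1)
    return df
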