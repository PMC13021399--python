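"""Published reference signature for the male bladder-cancer urobiome.

These are the discriminant taxa reported for a discovery cohort of 51 men
over 50 (27 bladder-cancer patients, 24 healthy controls): for each taxon
the Random-Forest mean-decrease-accuracy importance (scaled form) and the
group-mean relative abundances, in percent, of the cancer (mBCa) and
control (mHC) groups.  Only taxa with MDA > 5 are listed; 7 genera out of
33 post-filter, 10 species out of 85.

They serve two purposes: seeding the synthetic-cohort generator with
realistic compositions, and rebuilding the published signature (weights +
group assignment) without access to the raw sequencing data.
"""

from __future__ import annotations

import pandas as pd

from .discovery import SignatureModel, normalize_mda

# columns: mda, mean_ra_case_pct (mBCa), mean_ra_control_pct (mHC)
GENUS_SIGNATURE_TABLE = pd.DataFrame(
    [
        ("Enhydrobacter", 13.68, 0.05, 1.77),
        ("Porphyromonas", 12.65, 6.05, 0.28),
        ("Arthrobacter", 9.77, 0.01, 2.78),
        ("Aerococcus", 9.32, 3.00, 0.26),
        ("Enterobacter", 8.84, 0.02, 0.10),
        ("Sphingomonas", 8.55, 0.00, 0.22),
        ("Anaerococcus", 7.22, 3.97, 0.87),
    ],
    columns=["taxon", "mda", "mean_ra_case_pct", "mean_ra_control_pct"],
).set_index("taxon")

SPECIES_SIGNATURE_TABLE = pd.DataFrame(
    [
        ("Porphyromonas somerae", 11.45, 2.34, 0.04),
        ("Moraxella osloensis", 9.85, 0.02, 0.78),
        ("Anaerococcus sp gpac028", 9.75, 0.20, 0.02),
        ("Aerococcus urinae", 9.48, 3.00, 0.26),
        ("Porphyromonas sp 2007b", 8.08, 0.95, 0.01),
        ("Arthrobacter sp. mb182", 7.39, 0.01, 2.78),
        ("Endosymbiont of Sphenophorus levis", 6.68, 0.02, 0.10),
        ("Gamma-proteobacterium St.07B", 6.53, 0.02, 0.70),
        ("Actinobaculum massiliense", 6.29, 0.03, 1.88),
        ("Porphyromonas asaccharolytica", 5.52, 1.26, 0.09),
    ],
    columns=["taxon", "mda", "mean_ra_case_pct", "mean_ra_control_pct"],
).set_index("taxon")

# default laboratory-contaminant blacklist (taxa present in negative controls)
DEFAULT_CONTAMINANT_BLACKLIST = (
    "Propionibacterium acnes",
    "Sphingomonas sp. Oral clone AV069",
    "Ralstonia",
)

# post-filter feature counts of the discovery cohort, per level
N_FEATURES = {"genus": 33, "species": 85}


def reference_table(level: str) -> pd.DataFrame:
    if level == "genus":
        return GENUS_SIGNATURE_TABLE.copy()
    if level == "species":
        return SPECIES_SIGNATURE_TABLE.copy()
    raise ValueError(f"level must be 'genus' or 'species', got {level!r}")


def reference_group_means(level: str) -> pd.DataFrame:
    """Group-mean relative abundances of the signature taxa, as fractions."""
    tab = reference_table(level)
    return pd.DataFrame(
        {
            "case": tab["mean_ra_case_pct"] / 100.0,
            "control": tab["mean_ra_control_pct"] / 100.0,
        }
    )


def reference_signature(level: str) -> SignatureModel:
    """Rebuild the published signature from the printed importance table.

    Weights are the MDA values normalised to sum to 1 across the level's
    selected taxa; each taxon is assigned to the group with the larger
    printed mean relative abundance.
    """
    tab = reference_table(level)
    nmda = normalize_mda(tab["mda"])
    case_taxa, control_taxa = {}, {}
    for taxon, row in tab.iterrows():
        if row["mean_ra_case_pct"] > row["mean_ra_control_pct"]:
            case_taxa[taxon] = nmda[taxon]
        else:
            control_taxa[taxon] = nmda[taxon]
    return SignatureModel(
        level=level,
        case_taxa=case_taxa,
        control_taxa=control_taxa,
        provenance={"source": "published reference table", "mda_threshold": 5},
    )
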