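"""Default study conditions: primers, enzymes, test-strain panel, community.

These are configuration data, not code constants - every pipeline stage
accepts alternatives - but the defaults describe the screening protocol this
package models: degenerate primers targeting the NRPS adenylation domain
(480 bp product) and the PKS-II ketosynthase-alpha domain (350 bp product),
AluI/HaeIII fingerprinting with the 5% band-area rule and a 0.93 Jaccard
similarity cut, and a 5-strain antibacterial test panel.
"""
from __future__ import annotations

from .fingerprint import Enzyme
from .screen import PrimerPair

#: Degenerate primer pairs for the two biosynthetic loci (spaces removed
#: from the published 5'->3' sequences).
PRIMER_PAIRS: dict[str, PrimerPair] = {
    "NRPS": PrimerPair(
        locus="NRPS",
        forward="CGCGCGCATGTACTGGACNGGNGAYYT",
        reverse="GGAGTGGCCGCCCARNYBRAARAA",
        expected_size=480,
    ),
    "PKS-II": PrimerPair(
        locus="PKS-II",
        forward="GGCAACGCCTACCACATGCANGGNYT",
        reverse="GGTCCGCGGGACGTARTCNARRTC",
        expected_size=350,
    ),
}

#: 4-base cutters used for amplified-fragment restriction fingerprinting.
#: Sites/offsets from the standard restriction-enzyme catalogue.
ENZYMES: dict[str, Enzyme] = {
    "AluI": Enzyme(name="AluI", site="AGCT", cut_offset=2),
    "HaeIII": Enzyme(name="HaeIII", site="GGCC", cut_offset=2),
}

#: Antibacterial test panel: two multi-drug-resistant clinical isolates and
#: three type cultures, with their Gram classification.
TEST_STRAINS: list[str] = [
    "Enterococcus sp.",
    "Klebsiella pneumoniae",
    "Bacillus subtilis",
    "Staphylococcus aureus",
    "Escherichia coli",
]

GRAM_MAP: dict[str, str] = {
    "Enterococcus sp.": "positive",
    "Klebsiella pneumoniae": "negative",
    "Bacillus subtilis": "positive",
    "Staphylococcus aureus": "positive",
    "Escherichia coli": "negative",
}

#: Genus composition of the default 66-isolate community (isolate counts of
#: the sequenced collection this generator emulates).
GENUS_COUNTS_66: dict[str, int] = {
    "Streptomyces": 41,
    "Micromonospora": 8,
    "Nocardiopsis": 8,
    "Saccharomonospora": 5,
    "Actinomadura": 2,
    "Glycomyces": 1,
    "Nocardia": 1,
}

#: Per-genus (NRPS, PKS-II) carriage probabilities. Overall rates follow the
#: collection-wide prevalences (67.7% NRPS, 45.1% PKS-II); PKS-II is absent
#: from Glycomyces, Micromonospora and Nocardia.
GENE_PREVALENCE: dict[str, tuple[float, float]] = {
    "Streptomyces": (0.677, 0.55),
    "Micromonospora": (0.677, 0.0),
    "Nocardiopsis": (0.677, 0.451),
    "Saccharomonospora": (0.677, 0.451),
    "Actinomadura": (0.677, 0.451),
    "Glycomyces": (0.677, 0.0),
    "Nocardia": (0.677, 0.0),
}

#: P(active | gene content): category-wise activity rates implied by the
#: screened collection (10 of ~19 dual carriers, 8 of ~32 single carriers,
#: 5 of ~11 non-carriers active).
ACTIVITY_MODEL: dict[str, float] = {"both": 0.53, "one": 0.25, "none": 0.45}

#: Fraction of isolates with well-defined aerial mycelium (126 of 148).
AERIAL_MYCELIUM_P: float = 0.851

#: OTU identity thresholds routinely applied to the 16S data.
OTU_THRESHOLDS: tuple[float, ...] = (1.0, 0.99, 0.98)

#: Band-area scoring rule and similarity cut for fingerprint grouping.
MIN_BAND_AREA: float = 0.05
SIMILARITY_CUT: float = 0.93

#: Bootstrap replicates for NJ tree support.
BOOTSTRAP_REPLICATES: int = 1000
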