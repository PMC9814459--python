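"""Packaged study fixtures.

Two small fixtures let the composition and design summaries run without any
external data:

* the species detection table for the two New Jersey woodland sites
  (Rutgers Ecological Preserve, "RU"; Morristown National Historical Park,
  "MO"): every mammal species detected by eDNA metabarcoding or judged
  likely present from external records, with its clade, arboreal status,
  per-site documentation flags and per-site roller/soil detection
  percentages, plus the three species excluded from metabarcoding scoring
  (two for contamination reasons, one because the mammal 12S primer set
  does not amplify bears);

* the sampling design: which trees were visited, how many times, and which
  visits produced an analyzed roller and/or soil sample.

The detection table stores two related but distinct flags per species:
``documented_<site>`` (prior evidence at that site) and ``in_compiled_list``
(membership in the externally compiled species roster).  Four detected
species — brown rat, vole sp., domestic dog and eastern small-footed bat —
were metabarcoding detections that were absent from the compiled roster.
The roster totals quoted in different summaries cannot all be reconstructed
from the table alone; both flags are stored and neither is adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

# Per-species records:
# (clade, species, common_name, arboreal,
#  documented_ru, detected_roller_ru%, detected_soil_ru%,
#  documented_mo, detected_roller_mo%, detected_soil_mo%,
#  in_compiled_list)
# Detection percentages are % of analyzed samples of that method at that
# site containing the species; None means not detected by that method.
_SPECIES_ROWS = [
    ("Chiroptera", "Eptesicus fuscus", "Big brown bat", True,
     True, 7.0, None, True, 3.0, None, True),
    ("Chiroptera", "Lasiurus borealis", "Eastern red bat", True,
     True, None, None, True, None, None, True),
    ("Chiroptera", "Myotis septentrionalis", "Northern long-eared bat", True,
     True, None, None, True, None, None, True),
    ("Chiroptera", "Myotis leibii", "Eastern small-footed bat", False,
     False, None, None, True, 3.0, 5.0, False),
    ("Chiroptera", "Lasionycteris noctivagans", "Silver-haired bat", True,
     True, None, None, True, None, None, True),
    ("Chiroptera", "Lasiurus cinereus", "Hoary bat", True,
     False, None, None, True, None, None, True),
    ("Rodentia", "Sciurus carolinensis", "Eastern gray squirrel", True,
     True, 78.0, 44.0, True, 52.0, 43.0, True),
    ("Rodentia", "Glaucomys volans", "Southern flying squirrel", True,
     True, 52.0, 19.0, True, 47.0, 26.0, True),
    ("Rodentia", "Tamiasciurus hudsonicus", "American red squirrel", True,
     False, None, None, True, 6.0, None, True),
    ("Rodentia", "Tamias striatus", "Eastern chipmunk", True,
     True, 56.0, 38.0, True, 25.0, 16.0, True),
    ("Rodentia", "Marmota monax", "Groundhog", False,
     True, None, None, True, None, None, True),
    ("Rodentia", "Microtus sp.", "Vole sp.", False,
     False, None, 6.0, False, None, None, False),
    ("Rodentia", "Peromyscus leucopus", "White-footed mouse", True,
     True, 19.0, None, True, 13.0, None, True),
    ("Rodentia", "Rattus norvegicus", "Brown rat", False,
     False, 4.0, None, False, None, None, False),
    ("Lagomorpha", "Sylvilagus floridanus", "Eastern cottontail", False,
     True, 4.0, None, True, None, None, True),
    ("Eulipotyphla", "Blarina brevicauda", "Northern short-tailed shrew", False,
     True, None, None, True, None, None, True),
    ("Eulipotyphla", "Scalopus aquaticus", "Eastern mole", False,
     True, None, None, True, None, None, True),
    ("Carnivora", "Procyon lotor", "Raccoon", True,
     True, 41.0, None, True, 9.0, 16.0, True),
    ("Carnivora", "Mephitis mephitis", "Striped skunk", False,
     True, None, None, True, None, None, True),
    ("Carnivora", "Vulpes vulpes", "Red fox", False,
     True, 15.0, None, True, 3.0, None, True),
    ("Carnivora", "Canis latrans", "Coyote", False,
     True, None, None, True, None, None, True),
    ("Carnivora", "Canis lupus familiaris", "Domestic dog", False,
     False, 19.0, None, False, 28.0, None, False),
    ("Carnivora", "Felis catus", "Domestic cat", False,
     True, 4.0, None, False, 3.0, None, True),
    ("Didelphimorphia", "Didelphis virginiana", "Virginia opossum", True,
     True, 4.0, None, True, 6.0, 5.0, True),
    ("Artiodactyla", "Odocoileus virginianus", "White-tailed deer", False,
     True, 52.0, 19.0, True, 28.0, 11.0, True),
]

# Species identified as present at the sites but excluded from
# metabarcoding scoring.
_EXCLUSION_ROWS = [
    ("Rodentia", "Mus musculus", "House mouse", "contamination"),
    ("Chiroptera", "Myotis lucifugus", "Little brown bat", "contamination"),
    ("Carnivora", "Ursus americanus", "American black bear", "primer_ineffective"),
]


@dataclass
class Table1Fixture:
    """Species detection table: 25 scored species + 3 exclusions."""

    species: pd.DataFrame    # indexed by species name
    exclusions: pd.DataFrame  # indexed by species name, column exclusion_reason

    def __post_init__(self) -> None:
        if len(self.species) != 25:
            raise ValueError(f"expected 25 species rows, got {len(self.species)}")
        if len(self.exclusions) != 3:
            raise ValueError(f"expected 3 exclusion rows, got {len(self.exclusions)}")
        for col in ("roller_pct_ru", "soil_pct_ru", "roller_pct_mo", "soil_pct_mo"):
            vals = self.species[col].dropna()
            if ((vals < 0) | (vals > 100)).any():
                raise ValueError(f"{col} outside [0, 100]")


def load_table1_fixture() -> Table1Fixture:
    """Return the packaged species detection table."""
    df = pd.DataFrame(
        _SPECIES_ROWS,
        columns=[
            "clade", "species", "common_name", "arboreal",
            "documented_ru", "roller_pct_ru", "soil_pct_ru",
            "documented_mo", "roller_pct_mo", "soil_pct_mo",
            "in_compiled_list",
        ],
    ).set_index("species")
    df["detected_roller"] = df["roller_pct_ru"].notna() | df["roller_pct_mo"].notna()
    df["detected_soil"] = df["soil_pct_ru"].notna() | df["soil_pct_mo"].notna()
    df["detected"] = df["detected_roller"] | df["detected_soil"]
    exc = pd.DataFrame(
        _EXCLUSION_ROWS,
        columns=["clade", "species", "common_name", "exclusion_reason"],
    ).set_index("species")
    return Table1Fixture(species=df, exclusions=exc)


def sampling_design_fixture() -> pd.DataFrame:
    """Return the analyzed sampling events, one row per event.

    21 focal trees (9 at RU, 12 at MO); 19 trees received three sampling
    visits and two (at MO) a single visit, every visit yielding an analyzed
    roller sample (59 events).  Soil extractions covered a subset of 14
    trees and 35 samples: at RU 16 samples from 6 trees, at MO 19 samples
    from 8 trees.  Columns: tree_id, site, visit, collection_method.
    """
    rows = []

    def add(tree, site, visits, method):
        for v in visits:
            rows.append({"tree_id": tree, "site": site, "visit": v,
                         "collection_method": method})

    # RU: 9 trees x 3 roller visits
    for i in range(1, 10):
        add(f"RU{i:02d}", "RU", (1, 2, 3), "roller")
    # MO: 10 trees x 3 visits, 2 trees x 1 visit
    for i in range(1, 11):
        add(f"MO{i:02d}", "MO", (1, 2, 3), "roller")
    for i in (11, 12):
        add(f"MO{i:02d}", "MO", (1,), "roller")

    # soil subsample: RU 4 trees x 3 + 2 trees x 2 = 16 at 6 trees
    for i in range(1, 5):
        add(f"RU{i:02d}", "RU", (1, 2, 3), "soil")
    for i in (5, 6):
        add(f"RU{i:02d}", "RU", (1, 2), "soil")
    # MO 5 trees x 3 + 1 tree x 2 + 2 trees x 1 = 19 at 8 trees
    for i in range(1, 6):
        add(f"MO{i:02d}", "MO", (1, 2, 3), "soil")
    add("MO06", "MO", (1, 2), "soil")
    for i in (11, 12):
        add(f"MO{i:02d}", "MO", (1,), "soil")

    return pd.DataFrame(rows, columns=["tree_id", "site", "visit", "collection_method"])
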