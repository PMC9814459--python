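"""Species accumulation curves and community composition summaries."""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fixtures import Table1Fixture
from .io import DetectionHistory

logger = logging.getLogger(__name__)


@dataclass
class AccumulationCurve:
    """Mean +/- SD of distinct species detected vs. number of trees.

    ``curve`` has columns method, n_trees, mean, sd; the mean is taken over
    random orderings of the trees, so its value at the full tree count is
    exactly the total number of distinct species detected.
    """

    curve: pd.DataFrame
    visits_per_tree: int
    n_perm: int

    def for_method(self, method: str) -> pd.DataFrame:
        return self.curve[self.curve["method"] == method].reset_index(drop=True)


def _species_sets(history: DetectionHistory, method: str, visits_per_tree: int) -> dict:
    """Detected-species set per tree, using only the first ``visits_per_tree``
    visits of each collection method."""
    obs = history.observed()
    if method != "both":
        obs = obs[obs["collection_method"] == method]
    sets: dict = {}
    warned = False
    for (tree, cm), sub in obs.groupby(["tree", "collection_method"]):
        visits = sorted(sub["visit"].unique())
        if len(visits) < visits_per_tree and not warned:
            logger.warning(
                "tree %s has only %d %s visits; using all available",
                tree, len(visits), cm,
            )
            warned = True
        use = set(visits[:visits_per_tree])
        hits = sub[(sub["visit"].isin(use)) & (sub["y"] == 1)]["species"]
        sets.setdefault(tree, set()).update(hits)
    if method == "both":
        # restrict to trees sampled by both collection methods
        by_tree = obs.groupby("tree")["collection_method"].nunique()
        sets = {t: s for t, s in sets.items() if by_tree.get(t, 0) == 2}
    return sets


def species_accumulation(
    history: DetectionHistory,
    visits_per_tree: int = 3,
    n_perm: int = 1000,
    seed: int = 0,
    methods: tuple = ("roller", "soil", "both"),
    exact: bool = False,
) -> AccumulationCurve:
    """Permutation-based species accumulation curves.

    For each collection method (and "both" = trees sampled by both
    methods, detections pooled) the trees are shuffled ``n_perm`` times and
    the running count of distinct detected species recorded, keeping only
    the first ``visits_per_tree`` visits per tree and method.  With
    ``exact=True`` all tree orderings are enumerated instead (feasible up
    to ~8 trees).
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    rng = np.random.default_rng(seed)
    frames = []
    for method in methods:
        sets = _species_sets(history, method, visits_per_tree)
        tree_list = sorted(sets)
        if not tree_list:
            continue
        if exact:
            if len(tree_list) > 8:
                raise ValueError("exact enumeration limited to 8 trees")
            orders = list(itertools.permutations(tree_list))
        else:
            orders = [rng.permutation(tree_list) for _ in range(n_perm)]
        counts = np.empty((len(orders), len(tree_list)), dtype=float)
        for r, order in enumerate(orders):
            seen: set = set()
            for j, t in enumerate(order):
                seen |= sets[t]
                counts[r, j] = len(seen)
        frames.append(
            pd.DataFrame(
                {
                    "method": method,
                    "n_trees": np.arange(1, len(tree_list) + 1),
                    "mean": counts.mean(axis=0),
                    "sd": counts.std(axis=0, ddof=0),
                }
            )
        )
    return AccumulationCurve(
        curve=pd.concat(frames, ignore_index=True),
        visits_per_tree=visits_per_tree,
        n_perm=n_perm,
    )


@dataclass
class CompositionSummary:
    """Counts of detected species by collection method and arboreal guild."""

    n_detected: int
    arboreal_detected: int
    nonarboreal_detected: int
    roller_arboreal: int
    roller_nonarboreal: int
    soil_arboreal: int
    soil_nonarboreal: int
    bats_detected: int | None = None
    bats_expected: int | None = None
    n_available: int | None = None
    n_undetected: int | None = None
    coverage: float | None = None

    def __post_init__(self) -> None:
        if self.coverage is not None and not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must be in [0, 1]")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def composition_summary(source, guild_labels: dict | None = None) -> CompositionSummary:
    """Summarize detected-species composition by method and guild.

    ``source`` is either the packaged species detection table
    (:class:`Table1Fixture`) — in which case expected-species coverage and
    bat counts are included — or a :class:`DetectionHistory`, whose guild
    (arboreal) labels come from ``guild_labels`` or the history's species
    metadata.  A detected species without a guild label is an error naming
    the species.
    """
    if isinstance(source, Table1Fixture):
        df = source.species
        arb = df["arboreal"]
        det = df["detected"]
        bats = df["clade"] == "Chiroptera"
        n_av = len(df)
        n_det = int(det.sum())
        return CompositionSummary(
            n_detected=n_det,
            arboreal_detected=int((det & arb).sum()),
            nonarboreal_detected=int((det & ~arb).sum()),
            roller_arboreal=int((df["detected_roller"] & arb).sum()),
            roller_nonarboreal=int((df["detected_roller"] & ~arb).sum()),
            soil_arboreal=int((df["detected_soil"] & arb).sum()),
            soil_nonarboreal=int((df["detected_soil"] & ~arb).sum()),
            bats_detected=int((det & bats).sum()),
            bats_expected=int(bats.sum()),
            n_available=n_av,
            n_undetected=n_av - n_det,
            coverage=n_det / n_av,
        )
    if not isinstance(source, DetectionHistory):
        raise TypeError("source must be a Table1Fixture or DetectionHistory")

    obs = source.observed()
    hits = obs[obs["y"] == 1]
    detected = sorted(hits["species"].unique())
    if guild_labels is None:
        if source.species_meta is None or "arboreal" not in source.species_meta.columns:
            guild_labels = {}
        else:
            guild_labels = source.species_meta["arboreal"].to_dict()
    missing = [s for s in detected if s not in guild_labels]
    if missing:
        raise KeyError(f"species lacking an arboreal guild label: {missing}")

    def count(frame, arboreal):
        sp = frame["species"].unique()
        return sum(1 for s in sp if bool(guild_labels[s]) is arboreal)

    roller = hits[hits["collection_method"] == "roller"]
    soil = hits[hits["collection_method"] == "soil"]
    return CompositionSummary(
        n_detected=len(detected),
        arboreal_detected=count(hits, True),
        nonarboreal_detected=count(hits, False),
        roller_arboreal=count(roller, True),
        roller_nonarboreal=count(roller, False),
        soil_arboreal=count(soil, True),
        soil_nonarboreal=count(soil, False),
    )
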