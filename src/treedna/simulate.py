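"""Synthetic data generators with recorded ground truth.

Three generators mirror the statistical structure of a tree-bark/soil eDNA
survey so every downstream stage can be exercised against known truth:

``simulate_community``
    A multi-species detection history.  Species-level occupancy and
    detection parameters are drawn from community-level Normal
    hyper-distributions on the logit scale; detection depends on the
    collection method (roller vs. soil) through a species-specific slope.

``simulate_multimethod``
    A single-species history with an intermediate eDNA-availability layer:
    tree occupancy (psi) -> per-sample eDNA availability (theta, differing
    by collection method) -> conditional detection by each molecular method
    (qPCR and metabarcoding) on every sample.

``simulate_otu_table``
    An OTU read-count table with negative controls and injected
    contamination, for testing the decontamination cascade.  Signal counts
    are negative-binomial (metabarcoding counts are overdispersed);
    contaminant counts leak into negative controls and true samples.

Every generator is deterministic given its config (all draws come from one
``numpy`` Generator, consumed in a fixed field order, so outputs do not
depend on iteration order), and returns a :class:`SimulationTruth` holding
every latent draw, from which each observed datum is reconstructible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import DetectionHistory, OtuTable


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EventSpec:
    """One sampling event applied at every tree.

    ``missing_for`` lists tree indices (0-based) where this event is part
    of the design but yields no observation — e.g. soil extractions that
    were never processed.
    """

    collection_method: str
    missing_for: tuple = ()

    def __post_init__(self) -> None:
        if self.collection_method not in ("roller", "soil"):
            raise ValueError(f"unknown collection method {self.collection_method!r}")


def _default_events() -> tuple:
    return tuple(
        [EventSpec("roller") for _ in range(3)] + [EventSpec("soil") for _ in range(3)]
    )


@dataclass(frozen=True)
class CommunitySimConfig:
    """Community occupancy/detection generator settings.

    Defaults emulate the study design: 16 detected species at 21 focal
    trees, three roller and three soil events per tree.  Hyper-means put
    median occupancy at 0.5, baseline (soil) per-event detection near 0.2,
    and a positive roller effect of one logit unit.
    """

    n_species: int = 16
    n_trees: int = 21
    events_per_tree: Sequence[EventSpec] = field(default_factory=_default_events)
    hyper_mu_psi: float = 0.0
    hyper_sd_psi: float = 1.0
    hyper_mu_alpha: float = -1.4
    hyper_sd_alpha: float = 1.0
    hyper_mu_beta: float = 1.0
    hyper_sd_beta: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_trees < 1:
            raise ValueError("n_species and n_trees must be >= 1")
        if min(self.hyper_sd_psi, self.hyper_sd_alpha, self.hyper_sd_beta) <= 0:
            raise ValueError("hyper sd fields must be > 0")
        if not self.events_per_tree:
            raise ValueError("at least one event per tree is required")


@dataclass(frozen=True)
class MultimethodSimConfig:
    """Single-species availability/detection generator settings.

    Defaults match the big-brown-bat comparison scale: 21 trees with three
    samples each, qPCR per-sample detection 0.49 vs. metabarcoding 0.15
    given eDNA availability, and higher availability on bark (roller)
    samples than in soil.
    """

    n_trees: int = 21
    samples_per_tree: int = 3
    psi: float = 0.7
    theta_roller: float = 0.7
    theta_soil: float = 0.4
    p_qpcr: float = 0.49
    p_metabarcoding: float = 0.15
    soil_fraction: float = 35 / 94
    seed: int = 0
    species: str = "focal_species"

    def __post_init__(self) -> None:
        for name in ("psi", "theta_roller", "theta_soil", "p_qpcr",
                     "p_metabarcoding", "soil_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_trees < 1 or self.samples_per_tree < 1:
            raise ValueError("n_trees and samples_per_tree must be >= 1")


@dataclass(frozen=True)
class OtuSimConfig:
    """Contaminated OTU-table generator settings.

    Defaults give a survey-sized table: 16 species across 94 true samples
    with 46 negative controls, strongly overdispersed signal counts
    (mean 2000 reads where present, dispersion 0.5) and sparse low-level
    contamination (a 2% leak rate of ~5-read blooms).
    """

    n_species: int = 16
    n_samples: int = 94
    n_field_negatives: int = 10
    n_extraction_negatives: int = 12
    n_pcr_negatives: int = 24
    mean_signal_reads: float = 2000.0
    dispersion: float = 0.5
    contam_rate: float = 0.02
    contam_mean_reads: float = 5.0
    presence_prob: float = 0.5
    length_range: tuple = (80, 130)
    insert_range: tuple = (90, 199)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.mean_signal_reads <= 0 or self.dispersion <= 0:
            raise ValueError("mean_signal_reads and dispersion must be > 0")
        if self.contam_mean_reads <= 0:
            raise ValueError("contam_mean_reads must be > 0")
        if not 0.0 <= self.contam_rate <= 1.0:
            raise ValueError("contam_rate must be in [0, 1]")
        if not 0.0 <= self.presence_prob <= 1.0:
            raise ValueError("presence_prob must be in [0, 1]")
        for rng_name in ("length_range", "insert_range"):
            lo, hi = getattr(self, rng_name)
            if hi < lo:
                raise ValueError(f"{rng_name} is empty")

    @property
    def n_negatives_by_role(self) -> dict:
        return {
            "field_negative": self.n_field_negatives,
            "extraction_negative": self.n_extraction_negatives,
            "pcr_negative": self.n_pcr_negatives,
        }


@dataclass
class SimulationTruth:
    """Ground truth attached to a synthetic dataset.

    Only the fields relevant to the generator that produced it are set.
    """

    species_params: pd.DataFrame | None = None   # psi_k, alpha_k, beta_k
    z: np.ndarray | None = None                  # occupancy, species x tree (or tree,)
    detection_prob: np.ndarray | None = None     # community: species x tree x event
    availability: np.ndarray | None = None       # multimethod: tree x sample
    params: dict | None = None                   # scalar generating values
    signal_counts: pd.DataFrame | None = None    # OTU sim: per-cell signal reads
    contaminant_counts: pd.DataFrame | None = None  # OTU sim: per-cell contaminant reads

    def to_sidecar(self) -> pd.DataFrame:
        """Flatten per-species truth for CSV export alongside the dataset."""
        if self.species_params is not None:
            return self.species_params.reset_index()
        if self.params is not None:
            return pd.DataFrame([self.params])
        raise ValueError("no tabular truth recorded")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_community(config: CommunitySimConfig) -> tuple[DetectionHistory, SimulationTruth]:
    """Draw a multi-species detection history from the community model.

    Species parameters come from the logit-Normal hyper-distributions, tree
    occupancy ``z[k, i] ~ Bernoulli(psi_k)`` and event detections
    ``y ~ Bernoulli(z * p)`` with ``logit(p) = alpha_k + beta_k * roller``.
    Events flagged missing for a tree produce a design row with missing
    ``y``.
    """
    rng = np.random.default_rng(config.seed)
    K, I = config.n_species, config.n_trees
    events = list(config.events_per_tree)
    E = len(events)

    u = rng.normal(config.hyper_mu_psi, config.hyper_sd_psi, K)
    alpha = rng.normal(config.hyper_mu_alpha, config.hyper_sd_alpha, K)
    beta = rng.normal(config.hyper_mu_beta, config.hyper_sd_beta, K)
    psi = expit(u)

    z = (rng.random((K, I)) < psi[:, None]).astype(np.int8)
    x = np.array([1.0 if ev.collection_method == "roller" else 0.0 for ev in events])
    p = expit(alpha[:, None, None] + beta[:, None, None] * x[None, None, :])  # K,I,E
    y = ((rng.random((K, I, E)) < p) & (z[:, :, None] == 1)).astype(np.int8)

    missing = np.zeros((I, E), dtype=bool)
    for e, ev in enumerate(events):
        for i in ev.missing_for:
            missing[i, e] = True

    species = [f"species_{k + 1:03d}" for k in range(K)]
    trees = [f"tree_{i + 1:02d}" for i in range(I)]
    # visit numbering restarts within each collection method
    visit_of_event = []
    seen: dict = {}
    for ev in events:
        seen[ev.collection_method] = seen.get(ev.collection_method, 0) + 1
        visit_of_event.append(seen[ev.collection_method])

    rows = []
    for k in range(K):
        for i in range(I):
            for e, ev in enumerate(events):
                rows.append(
                    {
                        "species": species[k],
                        "tree": trees[i],
                        "visit": visit_of_event[e],
                        "collection_method": ev.collection_method,
                        "molecular_method": "metabarcoding",
                        "y": np.nan if missing[i, e] else int(y[k, i, e]),
                    }
                )
    obs = pd.DataFrame(rows)
    history = DetectionHistory(obs=obs)

    truth = SimulationTruth(
        species_params=pd.DataFrame(
            {"psi": psi, "alpha": alpha, "beta": beta, "u": u}, index=pd.Index(species, name="species")
        ),
        z=z,
        detection_prob=p,
        params={
            "hyper_mu_psi": config.hyper_mu_psi, "hyper_sd_psi": config.hyper_sd_psi,
            "hyper_mu_alpha": config.hyper_mu_alpha, "hyper_sd_alpha": config.hyper_sd_alpha,
            "hyper_mu_beta": config.hyper_mu_beta, "hyper_sd_beta": config.hyper_sd_beta,
        },
    )
    return history, truth


def simulate_multimethod(config: MultimethodSimConfig) -> tuple[DetectionHistory, SimulationTruth]:
    """Draw a single-species, two-molecular-method detection history.

    Each sample is soil with probability ``soil_fraction`` (else roller);
    availability ``a[i, s] ~ Bernoulli(z_i * theta_method)``; both molecular
    methods are scored on every sample, ``y ~ Bernoulli(a * p_method)``.
    """
    rng = np.random.default_rng(config.seed)
    I, S = config.n_trees, config.samples_per_tree

    z = (rng.random(I) < config.psi).astype(np.int8)
    is_soil = rng.random((I, S)) < config.soil_fraction
    theta = np.where(is_soil, config.theta_soil, config.theta_roller)
    a = ((rng.random((I, S)) < theta) & (z[:, None] == 1)).astype(np.int8)
    p = np.stack(
        [np.full((I, S), config.p_metabarcoding), np.full((I, S), config.p_qpcr)], axis=-1
    )
    y = ((rng.random((I, S, 2)) < p) & (a[:, :, None] == 1)).astype(np.int8)

    trees = [f"tree_{i + 1:03d}" for i in range(I)]
    methods = ("metabarcoding", "qpcr")
    rows = []
    for i in range(I):
        for s in range(S):
            for m, mm in enumerate(methods):
                rows.append(
                    {
                        "species": config.species,
                        "tree": trees[i],
                        "visit": s + 1,
                        "collection_method": "soil" if is_soil[i, s] else "roller",
                        "molecular_method": mm,
                        "y": int(y[i, s, m]),
                    }
                )
    history = DetectionHistory(obs=pd.DataFrame(rows))
    truth = SimulationTruth(
        z=z,
        availability=a,
        params={
            "psi": config.psi,
            "theta_roller": config.theta_roller,
            "theta_soil": config.theta_soil,
            "p_qpcr": config.p_qpcr,
            "p_metabarcoding": config.p_metabarcoding,
        },
    )
    return history, truth


def simulate_otu_table(config: OtuSimConfig) -> tuple[OtuTable, SimulationTruth]:
    """Generate a contaminated OTU table with per-cell truth labels.

    One OTU per species.  Where a species is present in a true sample its
    signal reads are NB(mean, dispersion); contaminant reads leak
    independently into negative controls and true samples at
    ``contam_rate`` with Poisson(contam_mean_reads) counts.  The truth
    records the signal and contaminant read matrices separately, so every
    table cell equals their sum.
    """
    rng = np.random.default_rng(config.seed)
    K = config.n_species
    otu_ids = [f"otu_{k + 1:03d}" for k in range(K)]
    taxa = [f"species_{k + 1:03d}" for k in range(K)]

    sample_ids = [f"S{j + 1:03d}" for j in range(config.n_samples)]
    neg_ids, neg_roles = [], []
    prefixes = {"field_negative": "FN", "extraction_negative": "EN", "pcr_negative": "PN"}
    for role, n in config.n_negatives_by_role.items():
        for j in range(n):
            neg_ids.append(f"{prefixes[role]}{j + 1:02d}")
            neg_roles.append(role)
    all_ids = sample_ids + neg_ids
    n_cols = len(all_ids)

    # batch structure: true samples cycle through the available negatives'
    # sites / extraction batches / PCR batches so every sample is linked
    nf = max(config.n_field_negatives, 1)
    ne = max(config.n_extraction_negatives, 1)
    np_ = max(config.n_pcr_negatives, 1)
    meta_rows = []
    for j, sid in enumerate(sample_ids):
        meta_rows.append(
            {
                "sample_id": sid, "role": "sample",
                "collection_method": "roller" if j % 2 == 0 else "soil",
                "tree_id": f"tree_{j // 3 + 1:02d}", "visit_index": j % 3 + 1,
                "extraction_batch": f"E{j % ne + 1:02d}",
                "pcr_batch": f"P{j % np_ + 1:02d}",
                "site": f"site_{j % nf + 1:02d}",
            }
        )
    for sid, role in zip(neg_ids, neg_roles):
        j = int(sid[2:]) - 1
        meta_rows.append(
            {
                "sample_id": sid, "role": role,
                "collection_method": "roller",
                "tree_id": "", "visit_index": 0,
                "extraction_batch": f"E{j % ne + 1:02d}" if role == "extraction_negative" else "",
                "pcr_batch": f"P{j % np_ + 1:02d}" if role == "pcr_negative" else "",
                "site": f"site_{j % nf + 1:02d}" if role == "field_negative" else "",
            }
        )
    samples = pd.DataFrame(meta_rows).set_index("sample_id")

    # signal reads in true samples only
    present = rng.random((K, config.n_samples)) < config.presence_prob
    r = config.dispersion
    p_nb = r / (r + config.mean_signal_reads)
    signal_true = rng.negative_binomial(r, p_nb, (K, config.n_samples)) * present
    signal = np.zeros((K, n_cols), dtype=np.int64)
    signal[:, : config.n_samples] = signal_true

    # contamination leaks everywhere (samples and negatives alike)
    leak = rng.random((K, n_cols)) < config.contam_rate
    contam = rng.poisson(config.contam_mean_reads, (K, n_cols)) * leak

    counts = pd.DataFrame(signal + contam, index=pd.Index(otu_ids, name="otu_id"),
                          columns=all_ids)
    features = pd.DataFrame(
        {
            "taxon": taxa,
            "sequence_length": rng.integers(
                config.length_range[0], config.length_range[1] + 1, K
            ),
            "insert_length": rng.integers(
                config.insert_range[0], config.insert_range[1] + 1, K
            ),
        },
        index=pd.Index(otu_ids, name="otu_id"),
    )
    table = OtuTable(features=features, counts=counts, samples=samples)
    truth = SimulationTruth(
        signal_counts=pd.DataFrame(signal, index=counts.index, columns=all_ids),
        contaminant_counts=pd.DataFrame(contam, index=counts.index, columns=all_ids),
        params={
            "mean_signal_reads": config.mean_signal_reads,
            "dispersion": config.dispersion,
            "contam_rate": config.contam_rate,
            "contam_mean_reads": config.contam_mean_reads,
        },
    )
    return table, truth
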