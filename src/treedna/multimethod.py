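"""Single-species multimethod (availability x detection) occupancy model.

The model separates three layers for one focal species:

.. code-block:: text

    z_i  ~ Bernoulli(psi)                    tree occupancy
    a_is ~ Bernoulli(z_i * theta_is)         eDNA availability in sample s
    y_ism ~ Bernoulli(a_is * p_m)            detection by molecular method m
    logit(theta_is) = gamma0 + gamma1 * roller_is
    logit(p_m)      = delta0 + delta1 * qpcr_m

``theta`` is the probability that the species' eDNA is present in a
sample, which depends on how the sample was collected (bark roller vs.
soil); ``p_m`` is the probability that molecular method m (metabarcoding
or qPCR) detects the DNA given it is available.  Both molecular methods
are scored on every sample, and that joint information is what identifies
the availability layer.  The per-visit detection rate used for survey
planning is ``theta * p_m``.

Priors: ``psi ~ Uniform(0, 1)`` (conjugate Beta updates) and Normal(0,
sd^2) on the four logit-scale coefficients (default sd 10).  Inference is
Metropolis-within-Gibbs with exact Bernoulli full conditionals for ``z``
and ``a`` and adaptive random-walk Metropolis for the coefficients.

Survey-design helpers: :func:`cumulative_detection` implements the
probability ``1 - (1 - p)^n`` of at least one success in ``n`` independent
visits, and :func:`visits_for_confidence` inverts it for the smallest
sufficient ``n``.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .community import McmcSettings, _norm_lp, _softplus
from .diagnostics import gelman_rubin, summarize_draws
from .io import DetectionHistory

logger = logging.getLogger(__name__)

_PARAM_NAMES = ("psi", "gamma0", "gamma1", "delta0", "delta1")


# ---------------------------------------------------------------------------
# survey-design math
# ---------------------------------------------------------------------------

def cumulative_detection(p: float, n: int) -> float:
    """Probability of detecting at least once in ``n`` independent visits.

    Computes ``1 - (1 - p)^n`` for per-visit detection rate ``p``.
    """
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    n = int(n)
    if n < 1:
        raise ValueError("n must be a positive integer")
    return float(-np.expm1(n * np.log1p(-p))) if p < 1.0 else 1.0


def visits_for_confidence(p: float, target: float) -> int:
    """Smallest number of visits reaching the target cumulative confidence.

    Returns the minimal integer ``n`` with ``1 - (1 - p)^n >= target``;
    exact ties return that ``n``.
    """
    p, target = float(p), float(target)
    if not 0.0 < target < 1.0:
        raise ValueError(f"target must be in (0, 1), got {target}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if p == 0.0:
        raise ValueError("p = 0: target confidence is unreachable")
    if p == 1.0:
        return 1
    n = max(1, math.ceil(math.log1p(-target) / math.log1p(-p)))
    while n > 1 and cumulative_detection(p, n - 1) >= target:
        n -= 1
    while cumulative_detection(p, n) < target:
        n += 1
    return n


def detection_curve(p_draws, n_max: int = 30) -> pd.DataFrame:
    """Posterior cumulative-detection curve with a 95% band.

    ``p_draws`` are per-draw per-visit detection rates; the curve is
    computed per draw and then summarized, so the band reflects parameter
    uncertainty.
    """
    p = np.asarray(p_draws, dtype=float).ravel()
    ns = np.arange(1, n_max + 1)
    curves = 1.0 - (1.0 - p[:, None]) ** ns[None, :]
    return pd.DataFrame(
        {
            "n": ns,
            "mean": curves.mean(axis=0),
            "lo": np.percentile(curves, 2.5, axis=0),
            "hi": np.percentile(curves, 97.5, axis=0),
        }
    )


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------

@dataclass
class MultimethodPosterior:
    """Kept draws of the multimethod model, shape (chains, kept)."""

    draws: dict
    z: np.ndarray          # (chains, kept, n_trees)
    a: np.ndarray          # (chains, kept, n_trees, n_samples)
    trees: list
    accept: dict
    rhat: dict
    converged: bool
    no_detections: bool
    settings: McmcSettings

    @property
    def psi_draws(self):
        return self.draws["psi"]

    @property
    def theta_roller_draws(self):
        return expit(self.draws["gamma0"] + self.draws["gamma1"])

    @property
    def theta_soil_draws(self):
        return expit(self.draws["gamma0"])

    @property
    def p_qpcr_draws(self):
        return expit(self.draws["delta0"] + self.draws["delta1"])

    @property
    def p_metabarcoding_draws(self):
        return expit(self.draws["delta0"])

    def per_visit_rate_draws(self, collection_method: str, molecular_method: str):
        """Per-draw per-visit detection rate theta * p for a method pair."""
        theta = (
            self.theta_roller_draws
            if collection_method == "roller"
            else self.theta_soil_draws
        )
        p = (
            self.p_qpcr_draws
            if molecular_method == "qpcr"
            else self.p_metabarcoding_draws
        )
        return theta * p

    def summary(self) -> pd.DataFrame:
        rows = {
            "psi": self.psi_draws,
            "theta_roller": self.theta_roller_draws,
            "theta_soil": self.theta_soil_draws,
            "p_qpcr": self.p_qpcr_draws,
            "p_metabarcoding": self.p_metabarcoding_draws,
        }
        return pd.DataFrame(
            {name: summarize_draws(v) for name, v in rows.items()}
        ).T[["mean", "lo", "hi"]]


def detection_rate_ratio(post: MultimethodPosterior) -> dict:
    """Posterior of the qPCR : metabarcoding detection-rate ratio.

    The ratio is formed per draw and then summarized (posterior mean and
    95% equal-tailed interval) — not as a ratio of posterior means.
    """
    ratio = post.p_qpcr_draws / post.p_metabarcoding_draws
    return summarize_draws(ratio.ravel())


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def _history_to_sample_arrays(history: DetectionHistory):
    obs = history.observed()
    species = obs["species"].unique()
    if len(species) != 1:
        raise ValueError(f"multimethod model expects a single species, got {len(species)}")
    keys = obs[["tree", "visit", "collection_method"]].drop_duplicates()
    trees = sorted(keys["tree"].unique())
    samples_by_tree = {
        t: sorted(
            (v, m) for _, v, m in keys[keys["tree"] == t].itertuples(index=False)
        )
        for t in trees
    }
    S = max(len(v) for v in samples_by_tree.values())
    I = len(trees)
    y = np.full((I, S, 2), np.nan)
    roller = np.zeros((I, S))
    present = np.zeros((I, S), dtype=bool)
    m_idx = {"metabarcoding": 0, "qpcr": 1}
    tr_idx = {t: i for i, t in enumerate(trees)}
    sm_idx = {}
    for t, sms in samples_by_tree.items():
        for s, (v, m) in enumerate(sms):
            sm_idx[(t, v, m)] = s
            roller[tr_idx[t], s] = 1.0 if m == "roller" else 0.0
            present[tr_idx[t], s] = True
    for row in obs.itertuples(index=False):
        if row.molecular_method not in m_idx:
            raise ValueError(
                f"molecular_method must be metabarcoding or qpcr, got {row.molecular_method!r}"
            )
        i = tr_idx[row.tree]
        s = sm_idx[(row.tree, row.visit, row.collection_method)]
        y[i, s, m_idx[row.molecular_method]] = row.y
    if np.isnan(y[present]).any():
        raise ValueError("every sample must be scored by both molecular methods")
    return trees, y, roller, present


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

def fit_multimethod_model(
    history: DetectionHistory,
    settings: McmcSettings | None = None,
    prior_sd_gamma: float = 1.75,
    prior_sd_delta: float = 1.75,
) -> MultimethodPosterior:
    """Fit the availability x detection model by Metropolis-within-Gibbs.

    The default prior sd of 1.75 on the logit coefficients makes the
    induced prior on each probability close to uniform; a much larger sd
    (e.g. 10) is *not* vague on the probability scale — it piles prior
    mass at 0 and 1 and, because availability is only weakly identified
    through joint detections, drags theta toward 1.
    """
    settings = settings or McmcSettings()
    trees, y, roller, present = _history_to_sample_arrays(history)
    I, S, _ = y.shape
    yf = np.nan_to_num(y)
    det_sample = (yf.sum(axis=2) > 0) & present        # any method detected
    no_detections = not det_sample.any()
    if no_detections:
        logger.warning("history contains no detections; posterior will track the prior")

    n_keep = (settings.n_iter - settings.n_burn + settings.thin - 1) // settings.thin
    C = settings.n_chains
    draws = {n: np.empty((C, n_keep)) for n in _PARAM_NAMES}
    z_draws = np.empty((C, n_keep, I), dtype=np.uint8)
    a_draws = np.empty((C, n_keep, I, S), dtype=np.uint8)
    accept_tot = {n: 0.0 for n in ("gamma0", "gamma1", "delta0", "delta1")}
    prior_sds = {
        "gamma0": prior_sd_gamma, "gamma1": prior_sd_gamma,
        "delta0": prior_sd_delta, "delta1": prior_sd_delta,
    }

    def ll_theta(g0, g1, z, a):
        eta = g0 + g1 * roller
        mask = present & (z[:, None] == 1)
        return float(((a * eta - _softplus(eta)) * mask).sum())

    def ll_p(d0, d1, a):
        mask = (present & (a == 1))[:, :, None]
        eta = np.array([d0, d1 + d0])[None, None, :]  # meta, qpcr
        return float(((yf * eta - _softplus(eta)) * mask).sum())

    for c in range(C):
        rng = np.random.default_rng([settings.seed, c])
        psi = rng.uniform(0.2, 0.8)
        th = {"gamma0": 0.0, "gamma1": 0.0, "delta0": 0.0, "delta1": 0.0}
        a = det_sample.astype(np.int8)
        z = (a.sum(axis=1) > 0).astype(np.int8)
        scales = {n: settings.proposal_sd for n in accept_tot}
        acc_win = {n: 0 for n in accept_tot}
        acc_post = {n: 0.0 for n in accept_tot}
        n_post = 0
        kept = 0

        for it in range(settings.n_iter):
            in_burn = it < settings.n_burn
            theta = expit(th["gamma0"] + th["gamma1"] * roller)
            p_m = expit(np.array([th["delta0"], th["delta0"] + th["delta1"]]))

            # a | rest: forced 1 where a method detected; 0 where z = 0
            q1 = theta * (1 - p_m[0]) * (1 - p_m[1])
            pa = q1 / (q1 + 1 - theta)
            a = np.where(
                det_sample, 1,
                np.where(z[:, None] == 0, 0, rng.random((I, S)) < pa),
            ).astype(np.int8)
            a = np.where(present, a, 0).astype(np.int8)

            # z | rest: forced 1 where any sample is available
            any_a = a.sum(axis=1) > 0
            log_nodet = (np.log1p(-theta) * present).sum(axis=1)
            pz = expit(np.log(psi) - np.log1p(-psi) + log_nodet)
            z = np.where(any_a, 1, rng.random(I) < pz).astype(np.int8)

            # psi | z: conjugate Beta under the Uniform(0,1) prior
            psi = rng.beta(1 + z.sum(), 1 + I - z.sum())

            # coefficient random walks
            for name, llfun in (
                ("gamma0", lambda v: ll_theta(v, th["gamma1"], z, a)),
                ("gamma1", lambda v: ll_theta(th["gamma0"], v, z, a)),
                ("delta0", lambda v: ll_p(v, th["delta1"], a)),
                ("delta1", lambda v: ll_p(th["delta0"], v, a)),
            ):
                cur = th[name]
                prop = cur + scales[name] * rng.normal()
                lp = (llfun(prop) + _norm_lp(prop, 0.0, prior_sds[name])
                      - llfun(cur) - _norm_lp(cur, 0.0, prior_sds[name]))
                if np.log(rng.random()) < lp:
                    th[name] = prop
                    acc_win[name] += 1

            if in_burn and (it + 1) % 50 == 0:
                for name in scales:
                    rate = acc_win[name] / 50.0
                    scales[name] = float(
                        np.clip(scales[name] * np.exp(rate - 0.3), 1e-3, 50.0)
                    )
                    acc_win[name] = 0
            if not in_burn:
                n_post += 1
                for name in scales:
                    acc_post[name] += acc_win[name]
                    acc_win[name] = 0

            if not in_burn and (it - settings.n_burn) % settings.thin == 0:
                draws["psi"][c, kept] = psi
                for name in th:
                    draws[name][c, kept] = th[name]
                z_draws[c, kept] = z
                a_draws[c, kept] = a
                kept += 1

        for name in acc_post:
            accept_tot[name] += acc_post[name] / max(n_post, 1) / C

    rhat = {n: gelman_rubin(draws[n]) for n in _PARAM_NAMES}
    finite = np.array([v for v in rhat.values() if np.isfinite(v)])
    converged = bool(finite.size and (finite < settings.rhat_threshold).all())
    if not converged:
        logger.warning("r-hat >= %.2f for some parameters; inspect chains",
                       settings.rhat_threshold)
    return MultimethodPosterior(
        draws=draws, z=z_draws, a=a_draws, trees=trees, accept=accept_tot,
        rhat=rhat, converged=converged, no_detections=no_detections,
        settings=settings,
    )


# ---------------------------------------------------------------------------
# exact enumeration oracle
# ---------------------------------------------------------------------------

@dataclass
class MultimethodGrid:
    """Weighted discrete grid over (psi, gamma0, gamma1, delta0, delta1)."""

    psi: np.ndarray
    gamma0: np.ndarray
    gamma1: np.ndarray
    delta0: np.ndarray
    delta1: np.ndarray
    weight: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.psi)
        for arr in (self.gamma0, self.gamma1, self.delta0, self.delta1, self.weight):
            if len(arr) != n:
                raise ValueError("grid arrays must be aligned")
        self.weight = self.weight / self.weight.sum()

    @classmethod
    def gaussian(
        cls, prior_sd_gamma: float, prior_sd_delta: float,
        n_psi: int = 21, n_coef: int = 13,
    ) -> "MultimethodGrid":
        """Quadrature grid for the sampler's priors: Gauss-Legendre for the
        Uniform(0,1) psi prior, Gauss-Hermite for the Normal coefficients."""
        xl, wl = np.polynomial.legendre.leggauss(n_psi)
        psi_nodes, psi_w = (xl + 1) / 2, wl / 2
        t, w = np.polynomial.hermite.hermgauss(n_coef)
        gh_w = w / np.sqrt(np.pi)

        def nodes(sd):
            return np.sqrt(2.0) * sd * t

        grids = np.meshgrid(
            psi_nodes, nodes(prior_sd_gamma), nodes(prior_sd_gamma),
            nodes(prior_sd_delta), nodes(prior_sd_delta), indexing="ij",
        )
        wgrids = np.meshgrid(psi_w, gh_w, gh_w, gh_w, gh_w, indexing="ij")
        weight = np.ones_like(grids[0])
        for wg in wgrids:
            weight = weight * wg
        return cls(*(g.ravel() for g in grids), weight.ravel())


def exact_multimethod_posterior(history: DetectionHistory, grid: MultimethodGrid) -> dict:
    """Exact posterior summaries by enumerating every (z, a) configuration.

    Restricted to tiny instances (at most 3 trees x 3 samples); intended
    as an independent check of the MCMC sampler.  Returns posterior means
    of psi, theta_roller, theta_soil, p_qpcr and p_metabarcoding.
    """
    trees, y, roller, present = _history_to_sample_arrays(history)
    I, S, _ = y.shape
    if I > 3 or S > 3:
        raise ValueError(f"instance too large to enumerate (I={I}, S={S}); limit 3 x 3")
    yf = np.nan_to_num(y)
    yzero = (yf.sum(axis=2) == 0) | ~present

    G = len(grid.psi)
    theta = {}
    for i in range(I):
        for s in range(S):
            theta[(i, s)] = expit(grid.gamma0 + grid.gamma1 * roller[i, s])
    p_meta = expit(grid.delta0)
    p_q = expit(grid.delta0 + grid.delta1)
    det1 = {}
    for i in range(I):
        for s in range(S):
            f = np.ones(G)
            if present[i, s]:
                f = f * (p_meta if yf[i, s, 0] == 1 else 1 - p_meta)
                f = f * (p_q if yf[i, s, 1] == 1 else 1 - p_q)
            det1[(i, s)] = f

    total = np.zeros(G)
    for zcfg in itertools.product((0, 1), repeat=I):
        zterm = np.ones(G)
        for zi in zcfg:
            zterm = zterm * (grid.psi if zi else (1 - grid.psi))
        sample_slots = [(i, s) for i in range(I) for s in range(S) if present[i, s]]
        for acfg in itertools.product((0, 1), repeat=len(sample_slots)):
            term = zterm
            ok = True
            for (i, s), ai in zip(sample_slots, acfg):
                if zcfg[i] == 0:
                    if ai == 1 or not yzero[i, s]:
                        ok = False
                        break
                    continue  # P(a=0 | z=0) = 1, y must be all-zero
                if ai == 1:
                    term = term * theta[(i, s)] * det1[(i, s)]
                else:
                    if not yzero[i, s]:
                        ok = False
                        break
                    term = term * (1 - theta[(i, s)])
            if ok:
                total = total + term

    w = grid.weight * total
    w = w / w.sum()
    theta_r = expit(grid.gamma0 + grid.gamma1)
    theta_s = expit(grid.gamma0)
    return {
        "psi_mean": float(w @ grid.psi),
        "theta_roller_mean": float(w @ theta_r),
        "theta_soil_mean": float(w @ theta_s),
        "p_qpcr_mean": float(w @ p_q),
        "p_metabarcoding_mean": float(w @ p_meta),
    }
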