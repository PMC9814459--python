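"""Hierarchical multi-species (community) occupancy model.

Model
-----
For species ``k`` at tree ``i`` with sampling event ``j``:

.. code-block:: text

    z_ik ~ Bernoulli(psi_k)                  true occupancy
    y_ijk ~ Bernoulli(z_ik * p_ijk)          detection
    logit(psi_k) = u_k,        u_k    ~ Normal(mu_psi,   sd_psi^2)
    logit(p_ijk) = alpha_k + beta_k * x_ij
                               alpha_k ~ Normal(mu_alpha, sd_alpha^2)
                               beta_k  ~ Normal(mu_beta,  sd_beta^2)

``x_ij`` codes the collection method (1 = roller/bark, 0 = soil), so a
positive ``beta_k`` means the species is easier to detect on bark.
Information is shared across species through the six community
hyperparameters; by default these get diffuse hyperpriors
(``mu ~ Normal(0, 10^2)``, ``sd ~ Uniform(0, 10)``), or they can be fixed
(:class:`FixedHypers`) which makes species independent — the configuration
the enumeration oracle checks.

Inference is Metropolis-within-Gibbs: latent ``z`` from its exact
Bernoulli full conditional (forced to 1 where the species was observed),
``u``/``alpha``/``beta`` by adaptive random-walk Metropolis on the logit
scale (tuned to 20-40% acceptance during burn-in, frozen after), the
``mu`` hyperparameters by conjugate Normal draws and the ``sd``
hyperparameters by random-walk Metropolis on the log scale.  Species never
detected anywhere carry no information in this model (no data
augmentation) and are dropped with a warning.

:func:`exact_posterior_oracle` provides an independent check for tiny
instances: the posterior over a weighted discrete grid of
``(psi, p_soil, p_roller)`` values, computed by summing the likelihood
over every latent occupancy configuration.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .diagnostics import gelman_rubin, summarize_draws
from .io import DetectionHistory

logger = logging.getLogger(__name__)

_HYPER_NAMES = ("mu_psi", "sd_psi", "mu_alpha", "sd_alpha", "mu_beta", "sd_beta")


@dataclass(frozen=True)
class McmcSettings:
    """Sampler protocol: chains, iterations, burn-in, thinning.

    The defaults (3 chains of 30,000 iterations, 10,000 burn-in, keeping
    every 10th draw) suit survey-sized data; scale them down for small
    synthetic instances.
    """

    n_chains: int = 3
    n_iter: int = 30000
    n_burn: int = 10000
    thin: int = 10
    seed: int = 1
    proposal_sd: float = 0.5
    rhat_threshold: float = 1.1

    def __post_init__(self) -> None:
        if not 0 <= self.n_burn < self.n_iter:
            raise ValueError("need 0 <= n_burn < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")


@dataclass(frozen=True)
class FixedHypers:
    """Fixed community hyperparameters (no hyperpriors)."""

    mu_psi: float = 0.0
    sd_psi: float = 1.0
    mu_alpha: float = 0.0
    sd_alpha: float = 1.0
    mu_beta: float = 0.0
    sd_beta: float = 1.0

    def __post_init__(self) -> None:
        if min(self.sd_psi, self.sd_alpha, self.sd_beta) <= 0:
            raise ValueError("sd fields must be > 0")


@dataclass
class CommunityPosterior:
    """Kept MCMC draws for the community occupancy model.

    ``draws`` maps parameter names to arrays of shape (chains, kept) for
    hyperparameters or (chains, kept, n_species) for species-level
    parameters; ``z`` has shape (chains, kept, n_species, n_trees).
    """

    species: list
    trees: list
    draws: dict
    z: np.ndarray
    accept: dict
    rhat: dict
    converged: bool
    settings: McmcSettings
    dropped_species: list = field(default_factory=list)

    # derived per-draw probability-scale quantities
    @property
    def psi_draws(self) -> np.ndarray:
        return expit(self.draws["u"])

    @property
    def p_soil_draws(self) -> np.ndarray:
        return expit(self.draws["alpha"])

    @property
    def p_roller_draws(self) -> np.ndarray:
        return expit(self.draws["alpha"] + self.draws["beta"])

    def species_summary(self) -> pd.DataFrame:
        """Posterior mean and 95% equal-tailed interval of psi, p_soil,
        p_roller per species."""
        rows = {}
        for name, arr in (
            ("psi", self.psi_draws), ("p_soil", self.p_soil_draws),
            ("p_roller", self.p_roller_draws),
        ):
            flat = arr.reshape(-1, arr.shape[-1])
            rows[f"{name}_mean"] = flat.mean(axis=0)
            rows[f"{name}_lo"] = np.percentile(flat, 2.5, axis=0)
            rows[f"{name}_hi"] = np.percentile(flat, 97.5, axis=0)
        return pd.DataFrame(rows, index=pd.Index(self.species, name="species"))

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format (chain, draw, parameter, value) export of all draws."""
        rows = []
        for name, arr in self.draws.items():
            C, T = arr.shape[:2]
            if arr.ndim == 2:
                for c in range(C):
                    rows.append(pd.DataFrame({
                        "chain": c, "draw": np.arange(T), "parameter": name,
                        "value": arr[c],
                    }))
            else:
                for k, sp in enumerate(self.species):
                    for c in range(C):
                        rows.append(pd.DataFrame({
                            "chain": c, "draw": np.arange(T),
                            "parameter": f"{name}[{sp}]", "value": arr[c, :, k],
                        }))
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def _history_to_arrays(history: DetectionHistory):
    """Rectangularize a detection history.

    Returns (species, trees, y, x, obs) with ``y`` (K, I, E) in {0, 1, nan},
    ``x`` (I, E) the roller indicator and ``obs`` (I, E) marking events that
    produced an observation.  Events are aligned per tree; trees with fewer
    events than the widest tree are padded with unobserved slots.
    """
    obs_df = history.obs
    species = sorted(obs_df["species"].unique())
    trees = sorted(obs_df["tree"].unique())
    events_by_tree = {}
    for t in trees:
        sub = obs_df[obs_df["tree"] == t]
        events_by_tree[t] = sorted(
            {(v, m) for v, m in zip(sub["visit"], sub["collection_method"])}
        )
    E = max(len(v) for v in events_by_tree.values())
    K, I = len(species), len(trees)
    y = np.full((K, I, E), np.nan)
    x = np.zeros((I, E))
    obs = np.zeros((I, E), dtype=bool)
    sp_idx = {s: k for k, s in enumerate(species)}
    tr_idx = {t: i for i, t in enumerate(trees)}
    ev_idx = {
        (t, ev): e for t, evs in events_by_tree.items() for e, ev in enumerate(evs)
    }
    for t, evs in events_by_tree.items():
        for e, (v, m) in enumerate(evs):
            x[tr_idx[t], e] = 1.0 if m == "roller" else 0.0
    for row in obs_df.itertuples(index=False):
        k = sp_idx[row.species]
        i = tr_idx[row.tree]
        e = ev_idx[(row.tree, (row.visit, row.collection_method))]
        if not np.isnan(row.y):
            y[k, i, e] = row.y
            obs[i, e] = True
    return species, trees, y, x, obs


def _softplus(x):
    return np.logaddexp(0.0, x)


def _norm_lp(x, mu, sd):
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd)


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

def fit_community_model(
    history: DetectionHistory,
    settings: McmcSettings | None = None,
    fixed_hypers: FixedHypers | None = None,
    mu_prior_sd: float = 10.0,
    sigma_upper: float = 10.0,
) -> CommunityPosterior:
    """Fit the community occupancy model by Metropolis-within-Gibbs.

    Parameters
    ----------
    history
        Detection history with roller/soil-labelled events; missing events
        contribute no likelihood term.
    settings
        Chains / iterations / burn-in / thinning / seed.
    fixed_hypers
        When given, the community hyperparameters are held at these values
        instead of receiving hyperpriors.
    mu_prior_sd, sigma_upper
        Hyperprior constants: ``mu ~ Normal(0, mu_prior_sd^2)`` and
        ``sd ~ Uniform(0, sigma_upper)``.
    """
    settings = settings or McmcSettings()
    species, trees, y, x, obs = _history_to_arrays(history)

    detected = np.nansum(np.nan_to_num(y), axis=(1, 2)) > 0
    dropped = [s for s, d in zip(species, detected) if not d]
    if dropped:
        logger.warning(
            "excluding %d species never detected anywhere: %s", len(dropped), dropped
        )
        y = y[detected]
        species = [s for s, d in zip(species, detected) if d]
    if not species:
        raise ValueError("no detected species remain; nothing to fit")

    K, I, E = y.shape
    yf = np.nan_to_num(y)                       # nan -> 0, masked below
    omask = obs[None, :, :] & ~np.isnan(y)      # (K, I, E) observed cells
    det_any = (yf * omask).sum(axis=2) > 0      # (K, I)

    n_keep = (settings.n_iter - settings.n_burn + settings.thin - 1) // settings.thin
    C = settings.n_chains
    estimate_hypers = fixed_hypers is None

    draws = {n: np.empty((C, n_keep, K)) for n in ("u", "alpha", "beta")}
    for n in _HYPER_NAMES:
        draws[n] = np.empty((C, n_keep))
    z_draws = np.empty((C, n_keep, K, I), dtype=np.uint8)
    accept_tot = {n: 0.0 for n in ("u", "alpha", "beta", "sd")}

    def ll_cells(alpha, beta):
        # detection log-likelihood per (species, tree), valid where z = 1;
        # independent of z, so it survives z updates unchanged
        eta = alpha[:, None, None] + beta[:, None, None] * x[None, :, :]
        return ((yf * eta - _softplus(eta)) * omask).sum(axis=2)

    def ll_occ(u, z):
        zs = z.sum(axis=1)
        return zs * (-_softplus(-u)) + (I - zs) * (-_softplus(u))

    for c in range(C):
        rng = np.random.default_rng([settings.seed, c])
        if estimate_hypers:
            hy = {"mu_psi": 0.0, "sd_psi": 1.0, "mu_alpha": 0.0, "sd_alpha": 1.0,
                  "mu_beta": 0.0, "sd_beta": 1.0}
        else:
            hy = {n: getattr(fixed_hypers, n) for n in _HYPER_NAMES}
        u = rng.normal(hy["mu_psi"], hy["sd_psi"], K)
        alpha = rng.normal(hy["mu_alpha"], hy["sd_alpha"], K)
        beta = rng.normal(hy["mu_beta"], hy["sd_beta"], K)
        z = np.where(det_any, 1, rng.integers(0, 2, (K, I))).astype(np.int8)

        scales = {
            "u": np.full(K, settings.proposal_sd),
            "alpha": np.full(K, settings.proposal_sd),
            "beta": np.full(K, settings.proposal_sd),
            "sd": np.full(3, 0.3),
        }
        acc_win = {n: np.zeros_like(v) for n, v in scales.items()}
        acc_post = {n: 0.0 for n in scales}
        n_post = 0
        kept = 0

        cells = ll_cells(alpha, beta)
        for it in range(settings.n_iter):
            in_burn = it < settings.n_burn

            # species-level random-walk Metropolis updates
            prop = alpha + scales["alpha"] * rng.normal(size=K)
            cells_p = ll_cells(prop, beta)
            lp = (((cells_p - cells) * z).sum(axis=1)
                  + _norm_lp(prop, hy["mu_alpha"], hy["sd_alpha"])
                  - _norm_lp(alpha, hy["mu_alpha"], hy["sd_alpha"]))
            acc = np.log(rng.random(K)) < lp
            alpha = np.where(acc, prop, alpha)
            cells = np.where(acc[:, None], cells_p, cells)
            acc_win["alpha"] += acc

            prop = beta + scales["beta"] * rng.normal(size=K)
            cells_p = ll_cells(alpha, prop)
            lp = (((cells_p - cells) * z).sum(axis=1)
                  + _norm_lp(prop, hy["mu_beta"], hy["sd_beta"])
                  - _norm_lp(beta, hy["mu_beta"], hy["sd_beta"]))
            acc = np.log(rng.random(K)) < lp
            beta = np.where(acc, prop, beta)
            cells = np.where(acc[:, None], cells_p, cells)
            acc_win["beta"] += acc

            prop = u + scales["u"] * rng.normal(size=K)
            lp = (ll_occ(prop, z) + _norm_lp(prop, hy["mu_psi"], hy["sd_psi"])
                  - ll_occ(u, z) - _norm_lp(u, hy["mu_psi"], hy["sd_psi"]))
            acc = np.log(rng.random(K)) < lp
            u = np.where(acc, prop, u)
            acc_win["u"] += acc

            # exact full conditional for z
            eta = alpha[:, None, None] + beta[:, None, None] * x[None, :, :]
            log1mp = (-_softplus(eta) * omask).sum(axis=2)      # (K, I)
            logit_z = u[:, None] + log1mp                        # log q1 - log(1-psi)
            pz = expit(logit_z)
            z = np.where(det_any, 1, rng.random((K, I)) < pz).astype(np.int8)

            if estimate_hypers:
                for j, (mu_n, sd_n, vec) in enumerate(
                    (("mu_psi", "sd_psi", u), ("mu_alpha", "sd_alpha", alpha),
                     ("mu_beta", "sd_beta", beta))
                ):
                    # conjugate Normal draw for the mean
                    s2 = hy[sd_n] ** 2
                    prec = K / s2 + 1.0 / mu_prior_sd**2
                    mean = vec.sum() / s2 / prec
                    hy[mu_n] = rng.normal(mean, 1.0 / np.sqrt(prec))
                    # log-scale random walk for the sd (Uniform(0, upper) prior)
                    sd_cur = hy[sd_n]
                    sd_prop = sd_cur * np.exp(scales["sd"][j] * rng.normal())
                    if sd_prop < sigma_upper:
                        lp = (_norm_lp(vec, hy[mu_n], sd_prop).sum() + np.log(sd_prop)
                              - _norm_lp(vec, hy[mu_n], sd_cur).sum() - np.log(sd_cur))
                        if np.log(rng.random()) < lp:
                            hy[sd_n] = sd_prop
                            acc_win["sd"][j] += 1

            # proposal adaptation during burn-in only
            if in_burn and (it + 1) % 50 == 0:
                for name in scales:
                    rate = acc_win[name] / 50.0
                    scales[name] = np.clip(
                        scales[name] * np.exp(rate - 0.3), 1e-3, 50.0
                    )
                    acc_win[name][:] = 0.0
            if not in_burn:
                n_post += 1
                for name in scales:
                    acc_post[name] += float(np.mean(acc_win[name]))
                    acc_win[name][:] = 0.0

            if not in_burn and (it - settings.n_burn) % settings.thin == 0:
                draws["u"][c, kept] = u
                draws["alpha"][c, kept] = alpha
                draws["beta"][c, kept] = beta
                for n in _HYPER_NAMES:
                    draws[n][c, kept] = hy[n]
                z_draws[c, kept] = z
                kept += 1

        for name in acc_post:
            accept_tot[name] += acc_post[name] / max(n_post, 1) / C

    rhat = {}
    if estimate_hypers:
        for n in _HYPER_NAMES:
            rhat[n] = gelman_rubin(draws[n])
    for n in ("u", "alpha", "beta"):
        rhat[n] = np.array([gelman_rubin(draws[n][:, :, k]) for k in range(K)])
    finite = np.concatenate([np.atleast_1d(v) for v in rhat.values()])
    finite = finite[np.isfinite(finite)]
    converged = bool(finite.size and (finite < settings.rhat_threshold).all())
    if not converged:
        logger.warning("r-hat >= %.2f for some parameters; inspect chains",
                       settings.rhat_threshold)

    return CommunityPosterior(
        species=species, trees=trees, draws=draws, z=z_draws,
        accept=accept_tot, rhat=rhat, converged=converged, settings=settings,
        dropped_species=dropped,
    )


def method_effect_summary(post: CommunityPosterior) -> pd.DataFrame:
    """Per-species and community-level collection-method slopes.

    Returns one row per species with the posterior mean and 95%
    equal-tailed interval of the roller-vs-soil slope ``beta_k``, plus a
    ``community`` row for the hyper-mean ``mu_beta`` (constant when the
    model was fitted with fixed hyperparameters).
    """
    rows = []
    beta = post.draws["beta"].reshape(-1, len(post.species))
    for k, sp in enumerate(post.species):
        rows.append({"name": sp, **summarize_draws(beta[:, k])})
    rows.append({"name": "community", **summarize_draws(post.draws["mu_beta"].ravel())})
    return pd.DataFrame(rows).set_index("name")


# ---------------------------------------------------------------------------
# exact enumeration oracle
# ---------------------------------------------------------------------------

@dataclass
class CommunityGrid:
    """Weighted discrete grid over (psi, p_soil, p_roller)."""

    psi: np.ndarray
    p_soil: np.ndarray
    p_roller: np.ndarray
    weight: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.psi)
        if not (len(self.p_soil) == len(self.p_roller) == len(self.weight) == n):
            raise ValueError("grid arrays must be aligned")
        self.weight = self.weight / self.weight.sum()

    @classmethod
    def product(cls, psi_vals, p_soil_vals, p_roller_vals, weights=None) -> "CommunityGrid":
        """Cartesian-product grid; uniform prior unless weights given
        (one weight array per dimension)."""
        if weights is None:
            weights = [np.ones(len(v)) for v in (psi_vals, p_soil_vals, p_roller_vals)]
        P, S, R = np.meshgrid(psi_vals, p_soil_vals, p_roller_vals, indexing="ij")
        WP, WS, WR = np.meshgrid(*weights, indexing="ij")
        return cls(P.ravel(), S.ravel(), R.ravel(), (WP * WS * WR).ravel())

    @classmethod
    def from_logit_normal(
        cls, mu_psi, sd_psi, mu_alpha, sd_alpha, mu_beta, sd_beta, n_nodes=41
    ) -> "CommunityGrid":
        """Gauss-Hermite grid matching the model's logit-Normal priors.

        Nodes are placed in (u, alpha, beta) space so the weighted grid is
        a quadrature rule for the exact continuous prior; ``p_roller``
        inherits the alpha + beta dependence.
        """
        t, w = np.polynomial.hermite.hermgauss(n_nodes)
        def nodes(mu, sd):
            return mu + np.sqrt(2.0) * sd * t, w / np.sqrt(np.pi)
        un, uw = nodes(mu_psi, sd_psi)
        an, aw = nodes(mu_alpha, sd_alpha)
        bn, bw = nodes(mu_beta, sd_beta)
        U, A, B = np.meshgrid(un, an, bn, indexing="ij")
        WU, WA, WB = np.meshgrid(uw, aw, bw, indexing="ij")
        return cls(
            expit(U).ravel(), expit(A).ravel(), expit(A + B).ravel(),
            (WU * WA * WB).ravel(),
        )


@dataclass
class OracleResult:
    summary: pd.DataFrame
    posterior_weights: dict
    grid: CommunityGrid


def exact_posterior_oracle(history: DetectionHistory, grid: CommunityGrid) -> OracleResult:
    """Exact per-species posterior on a discrete parameter grid.

    Sums the likelihood over every latent occupancy configuration
    (2^n_trees per species), so it is restricted to tiny instances:
    at most 2 species, 4 trees and 4 events per tree.  With fixed,
    species-independent priors the species posteriors factorize, and each
    is computed separately.
    """
    species, trees, y, x, obs = _history_to_arrays(history)
    K, I, E = y.shape
    if K > 2 or I > 4 or E > 4:
        raise ValueError(
            f"instance too large to enumerate (K={K}, I={I}, E={E}); "
            "limits are 2 species, 4 trees, 4 events per tree"
        )
    rows, weights_out = {}, {}
    for k, sp in enumerate(species):
        # per-tree likelihood factors across the grid
        L1 = np.ones((I, len(grid.psi)))
        allzero = np.ones(I, dtype=bool)
        for i in range(I):
            for e in range(E):
                if not obs[i, e] or np.isnan(y[k, i, e]):
                    continue
                p = grid.p_roller if x[i, e] == 1 else grid.p_soil
                L1[i] *= p if y[k, i, e] == 1 else (1.0 - p)
                if y[k, i, e] == 1:
                    allzero[i] = False
        lik = np.zeros(len(grid.psi))
        for zcfg in itertools.product((0, 1), repeat=I):
            term = np.ones(len(grid.psi))
            for i, zi in enumerate(zcfg):
                if zi:
                    term = term * grid.psi * L1[i]
                else:
                    if not allzero[i]:
                        term = None
                        break
                    term = term * (1.0 - grid.psi)
            if term is not None:
                lik += term
        w = grid.weight * lik
        w = w / w.sum()
        weights_out[sp] = w
        rows[sp] = {
            "psi_mean": float(w @ grid.psi),
            "p_soil_mean": float(w @ grid.p_soil),
            "p_roller_mean": float(w @ grid.p_roller),
            "psi_sd": float(np.sqrt(w @ grid.psi**2 - (w @ grid.psi) ** 2)),
            "p_soil_sd": float(np.sqrt(w @ grid.p_soil**2 - (w @ grid.p_soil) ** 2)),
            "p_roller_sd": float(
                np.sqrt(w @ grid.p_roller**2 - (w @ grid.p_roller) ** 2)
            ),
        }
    summary = pd.DataFrame.from_dict(rows, orient="index")
    summary.index.name = "species"
    return OracleResult(summary=summary, posterior_weights=weights_out, grid=grid)
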