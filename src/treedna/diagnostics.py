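"""MCMC convergence diagnostics and draw summaries."""

from __future__ import annotations

import numpy as np


def gelman_rubin(draws) -> float | dict:
    """Split-chain potential scale reduction factor (r-hat).

    Each chain is halved before the classic between/within-variance
    computation, so stationarity failures inside a single chain also
    inflate the statistic.  Values near 1 indicate the chains are mixing
    over the same distribution; values above ~1.1 are conventionally taken
    as non-convergence.

    Parameters
    ----------
    draws
        Array of shape (n_chains, n_draws), or a dict of such arrays
        (a dict of r-hats is then returned).  Needs >= 2 chains and >= 4
        draws per chain.

    Returns
    -------
    float
        The PSRF, or NaN when the within-chain variance is zero (constant
        chains leave the statistic undefined).
    """
    if isinstance(draws, dict):
        return {k: gelman_rubin(v) for k, v in draws.items()}
    x = np.asarray(draws, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 4:
        raise ValueError("need a (chains >= 2, draws >= 4) array")
    n = x.shape[1] // 2
    halves = np.concatenate([x[:, :n], x[:, n: 2 * n]], axis=0)
    w = halves.var(axis=1, ddof=1).mean()
    b_over_n = halves.mean(axis=1).var(ddof=1)
    if w == 0.0:
        return float("nan")
    var_hat = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_hat / w))


def summarize_draws(draws, interval: float = 0.95) -> dict:
    """Mean and equal-tailed credible interval of a draw vector."""
    x = np.asarray(draws, dtype=float).ravel()
    tail = 100 * (1 - interval) / 2
    return {
        "mean": float(x.mean()),
        "lo": float(np.percentile(x, tail)),
        "hi": float(np.percentile(x, 100 - tail)),
    }
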