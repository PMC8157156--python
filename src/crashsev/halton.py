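"""Quasi-random standard-normal draws from Halton sequences.

Simulated maximum likelihood replaces the mixing integral with an average
over draws; low-discrepancy Halton points cover the unit interval far more
evenly than pseudo-random numbers, so far fewer draws are needed for a given
simulation error.  Each random dimension gets its own prime base
(2, 3, 5, ...), the leading points of the sequence are discarded (they are
poorly spread), and the uniform points are pushed through the standard
normal quantile function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri
from scipy.stats import qmc

#: Enough primes for any model this package will realistically see.
_PRIMES = (2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47)


@dataclass(frozen=True)
class HaltonConfig:
    """Draw settings for simulated maximum likelihood.

    Parameters
    ----------
    n_draws
        Draws per observation per random dimension (default 500).
    burn
        Initial sequence points discarded before use (default 10).
    antithetic
        If true, the second half of each observation's draws mirrors the
        first (``1 - u``).
    primes
        Prime bases, one consumed per random dimension, in order.
    """

    n_draws: int = 500
    burn: int = 10
    antithetic: bool = False
    primes: tuple[int, ...] = _PRIMES

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.burn < 0:
            raise ValueError("burn must be >= 0")
        if len(set(self.primes)) != len(self.primes):
            raise ValueError("primes must be distinct")


def halton_uniforms(config: HaltonConfig, n_points: int, dims: int) -> np.ndarray:
    """First ``n_points`` Halton points in ``dims`` dimensions, in (0, 1).

    The sequence starts at index 1 (radical inverse 1/b), so the degenerate
    all-zeros point never appears; ``config.burn`` further points are then
    dropped.
    """
    if dims > len(config.primes):
        raise ValueError(
            f"{dims} random dimensions but only {len(config.primes)} primes "
            "configured"
        )
    engine = qmc.Halton(d=dims, scramble=False, seed=None)
    # skip index 0 (the all-zeros point) plus the configured burn-in
    engine.fast_forward(1 + config.burn)
    u = engine.random(n_points)
    # base sequence is pruned of exact zeros by the fast-forward; keep a
    # defensive clip so ndtri never sees 0 or 1
    return np.clip(u, 1e-15, 1 - 1e-15)


def halton_draws(config: HaltonConfig, n_obs: int, dims: int) -> np.ndarray:
    """Standard-normal Halton draws, shaped ``(n_obs, n_draws, dims)``.

    Consecutive blocks of the sequence are assigned to consecutive
    observations.  Fully deterministic given the config: there is no RNG
    anywhere in this path.
    """
    R = config.n_draws
    if config.antithetic:
        half = (R + 1) // 2
        u = halton_uniforms(config, n_obs * half, dims)
        u = u.reshape(n_obs, half, dims)
        u = np.concatenate([u, 1.0 - u], axis=1)[:, :R, :]
    else:
        u = halton_uniforms(config, n_obs * R, dims).reshape(n_obs, R, dims)
    return ndtri(u)
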