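"""Small shared numerical helpers."""

from __future__ import annotations

import math

import numpy as np

LN10 = math.log(10.0)


def spawn_rngs(seed: int | np.random.Generator, n: int) -> list[np.random.Generator]:
    """Spawn ``n`` independent generators from one seed or parent generator."""
    if isinstance(seed, np.random.Generator):
        return [np.random.Generator(np.random.PCG64(s)) for s in
                seed.bit_generator.seed_seq.spawn(n)]
    ss = np.random.SeedSequence(seed)
    return [np.random.Generator(np.random.PCG64(s)) for s in ss.spawn(n)]


def as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def c4_factor(n: int) -> float:
    """Normality-based unbiasing constant for the sample SD.

    E[s] = c4(n) * sigma for iid normal samples, so s / c4(n) is an unbiased
    estimate of sigma.  c4(n) = sqrt(2/(n-1)) * Gamma(n/2) / Gamma((n-1)/2).
    """
    if n < 2:
        raise ValueError("c4 correction requires n >= 2")
    # use log-gammas to stay finite for large n
    return math.sqrt(2.0 / (n - 1)) * math.exp(
        math.lgamma(n / 2.0) - math.lgamma((n - 1) / 2.0)
    )


def delta_method_se_log10(mean: float, se_linear: float) -> float:
    """First-order SE of log10(X) given the mean and SE of X (mean > 0)."""
    if mean <= 0:
        raise ValueError("delta method on the log scale needs mean > 0")
    return se_linear / (mean * LN10)
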