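"""Deterministic per-artifact random streams.

Every generated artifact gets its own ``numpy`` Generator derived from the
study seed plus a stable string key (e.g. the animal id and modality), so
artifacts are reproducible independently of generation order.
"""

from __future__ import annotations

import hashlib

import numpy as np


def rng_for(seed: int, *keys: str | int) -> np.random.Generator:
    """A Generator seeded from the study seed and a stable key path."""
    words = [int(seed) & 0x7FFFFFFF]
    for key in keys:
        digest = hashlib.blake2s(str(key).encode(), digest_size=4).digest()
        words.append(int.from_bytes(digest, "little"))
    return np.random.default_rng(np.random.SeedSequence(words))


def ln_noise(rng: np.random.Generator, sigma: float, size=None):
    """Mean-one multiplicative lognormal noise.

    The log-mean is set to ``-sigma^2/2`` so the noise factor has
    expectation exactly 1 and configured targets are unbiased in
    expectation, not just in the median.
    """
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size)
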