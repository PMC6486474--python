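"""Small distribution-spec objects used to parameterise the fixture generators.

These are deliberately minimal: each law knows how to draw a vector of values
from a ``numpy.random.Generator``. They exist so fixture parameters (MAF
spectra, per-gene mean/dispersion laws, normalization-factor laws, CNV
state-frequency laws) can be declared in configs and round-tripped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class Law:
    """Base class for scalar sampling laws."""

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        raise NotImplementedError


@dataclass(frozen=True)
class PointMass(Law):
    value: float

    def sample(self, rng, size):
        return np.full(size, float(self.value))


@dataclass(frozen=True)
class Uniform(Law):
    low: float
    high: float

    def sample(self, rng, size):
        return rng.uniform(self.low, self.high, size)


@dataclass(frozen=True)
class LogNormal(Law):
    """Parameterised by the mean/sd of log(X)."""

    mu: float
    sigma: float

    def sample(self, rng, size):
        return rng.lognormal(self.mu, self.sigma, size)


@dataclass(frozen=True)
class Gamma(Law):
    shape: float
    scale: float

    def sample(self, rng, size):
        return rng.gamma(self.shape, self.scale, size)


@dataclass(frozen=True)
class Normal(Law):
    mean: float
    sd: float

    def sample(self, rng, size):
        return rng.normal(self.mean, self.sd, size)


@dataclass(frozen=True)
class FixedVector(Law):
    """Deterministic per-element values (length must match the request)."""

    values: tuple

    def sample(self, rng, size):
        v = np.asarray(self.values, dtype=float)
        if v.size != size:
            raise ValueError(f"FixedVector of length {v.size} asked for {size} draws")
        return v.copy()


@dataclass(frozen=True)
class Dirichlet(Law):
    """Law over probability vectors (rows on the simplex)."""

    alpha: tuple = (1.0, 1.0, 1.0, 1.0)

    def sample(self, rng, size):
        return rng.dirichlet(np.asarray(self.alpha, dtype=float), size)


@dataclass(frozen=True)
class PointSimplex(Law):
    """Every draw is the same probability vector."""

    probs: tuple

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probs must be a probability vector")

    def sample(self, rng, size):
        return np.tile(np.asarray(self.probs, dtype=float), (size, 1))


def sample_positive(law: Law, rng: np.random.Generator, size: int,
                    max_attempts: int = 100) -> np.ndarray:
    """Draw from ``law``, rejecting non-positive values elementwise."""
    out = np.asarray(law.sample(rng, size), dtype=float)
    for _ in range(max_attempts):
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = law.sample(rng, int(bad.sum()))
    raise ValueError(f"law {law!r} kept producing non-positive draws "
                     f"after {max_attempts} rejection rounds")
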