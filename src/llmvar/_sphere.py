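"""Sampling on the unit sphere: von Mises–Fisher draws.

The vMF(μ, κ) distribution on S^{d−1} has density ∝ exp(κ μ·x); κ = 0 is
the uniform distribution on the sphere and κ → ∞ concentrates at μ. Used
to simulate embedding clouds of known angular dispersion. Sampling follows
the standard rejection scheme for the cosine W = μ·x (Wood, 1994), with a
Householder reflection carrying the canonical axis onto μ.
"""

from __future__ import annotations

import numpy as np

__all__ = ["sample_vmf", "sample_uniform_sphere"]


def sample_uniform_sphere(dim: int, rng: np.random.Generator) -> np.ndarray:
    """One draw uniform on S^{dim−1}."""
    x = rng.standard_normal(dim)
    n = np.linalg.norm(x)
    while n == 0.0:  # pragma: no cover - probability zero
        x = rng.standard_normal(dim)
        n = np.linalg.norm(x)
    return x / n


def _sample_w(dim: int, kappa: float, rng: np.random.Generator) -> float:
    """Rejection-sample the cosine of the angle to the mean direction."""
    d1 = dim - 1
    b = d1 / (2.0 * kappa + np.sqrt(4.0 * kappa**2 + d1**2))
    x0 = (1.0 - b) / (1.0 + b)
    c = kappa * x0 + d1 * np.log(1.0 - x0**2)
    while True:
        z = rng.beta(d1 / 2.0, d1 / 2.0)
        w = (1.0 - (1.0 + b) * z) / (1.0 - (1.0 - b) * z)
        u = rng.uniform()
        if kappa * w + d1 * np.log(1.0 - x0 * w) - c >= np.log(u):
            return float(w)


def sample_vmf(
    mean_direction: np.ndarray, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """One unit vector from vMF(mean_direction, kappa); kappa = 0 gives the
    uniform distribution on the sphere."""
    mu = np.asarray(mean_direction, dtype=float)
    if mu.ndim != 1 or mu.size < 2:
        raise ValueError("mean_direction must be a vector of dimension >= 2")
    if abs(np.linalg.norm(mu) - 1.0) > 1e-8:
        raise ValueError("mean_direction must be a unit vector")
    if kappa < 0:
        raise ValueError(f"kappa must be >= 0, got {kappa}")
    dim = mu.size
    if kappa == 0.0:
        return sample_uniform_sphere(dim, rng)
    w = _sample_w(dim, kappa, rng)
    # direction orthogonal to the canonical axis e1
    v = rng.standard_normal(dim - 1)
    v /= np.linalg.norm(v)
    x = np.empty(dim)
    x[0] = w
    x[1:] = np.sqrt(max(0.0, 1.0 - w * w)) * v
    # Householder reflection mapping e1 -> mu
    e1 = np.zeros(dim)
    e1[0] = 1.0
    u = e1 - mu
    norm_u = np.linalg.norm(u)
    if norm_u > 1e-12:
        u /= norm_u
        x = x - 2.0 * np.dot(u, x) * u
    out = x / np.linalg.norm(x)
    return out
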