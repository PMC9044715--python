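"""Random generation of the circular distributions used in the power study.

Families: circular uniform, von Mises (the canonical unimodal circular
distribution), wrapped skew normal (an asymmetric unimodal alternative), and
finite mixtures of these (used for the bimodal and trimodal scenarios).

All samplers are driven by a ``numpy.random.Generator`` so that a fixed seed
reproduces draws bitwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core import TWO_PI, AngleSample

FAMILIES = ("uniform", "vonmises", "wrappedskewnormal")


def as_rng(rng) -> np.random.Generator:
    """Coerce a seed or Generator into a Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def sample_uniform(n: int, rng) -> AngleSample:
    """n i.i.d. draws from the circular uniform distribution on [0, 2*pi)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return AngleSample(as_rng(rng).uniform(0.0, TWO_PI, size=n))


def sample_vonmises(n: int, mu: float, kappa: float, rng) -> AngleSample:
    """n i.i.d. von Mises draws with mean direction mu and concentration kappa.

    kappa = 0 degenerates to the circular uniform. Sampling uses the
    Best–Fisher wrapped-Cauchy envelope rejection algorithm (exact, no
    tuning) as implemented by ``numpy.random.Generator.vonmises``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    draws = as_rng(rng).vonmises(mu, kappa, size=n)
    return AngleSample(np.mod(draws, TWO_PI))


def sample_wrapped_skew_normal(
    n: int, xi: float, omega: float, alpha: float, rng
) -> AngleSample:
    """n i.i.d. wrapped skew-normal draws with location xi, scale omega, shape alpha.

    A skew-normal variate z is drawn on the line via the delta
    representation — delta = alpha/sqrt(1+alpha^2),
    z = delta*|u0| + sqrt(1-delta^2)*u1 with u0, u1 independent standard
    normals — then wrapped: theta = (xi + omega*z) mod 2*pi.  alpha = 0
    reduces to the wrapped normal with dispersion omega.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if omega <= 0:
        raise ValueError("omega must be > 0")
    gen = as_rng(rng)
    delta = alpha / np.sqrt(1.0 + alpha * alpha)
    u0 = gen.standard_normal(n)
    u1 = gen.standard_normal(n)
    z = delta * np.abs(u0) + np.sqrt(1.0 - delta * delta) * u1
    return AngleSample(np.mod(xi + omega * z, TWO_PI))


@dataclass(frozen=True)
class MixtureComponent:
    family: str
    params: dict
    weight: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.weight < 0:
            raise ValueError("component weight must be nonnegative")
        p = self.params
        if self.family == "vonmises":
            if not (0.0 <= p["mu"] < TWO_PI):
                raise ValueError("vonmises mu must lie in [0, 2*pi)")
            if p["kappa"] < 0:
                raise ValueError("vonmises kappa must be >= 0")
        elif self.family == "wrappedskewnormal":
            if p["omega"] <= 0:
                raise ValueError("wrappedskewnormal omega must be > 0")


@dataclass(frozen=True)
class MixtureSpec:
    """A finite mixture of circular distributions for simulation scenarios."""

    components: tuple[MixtureComponent, ...]

    def __post_init__(self) -> None:
        comps = tuple(
            c if isinstance(c, MixtureComponent) else MixtureComponent(**c)
            for c in self.components
        )
        if not comps:
            raise ValueError("mixture needs at least one component")
        total = sum(c.weight for c in comps)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component weights must sum to 1, got {total}")
        object.__setattr__(self, "components", comps)

    # -- JSON round trip for scenario config files -----------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "components": [
                    {"family": c.family, "params": c.params, "weight": c.weight}
                    for c in self.components
                ]
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MixtureSpec":
        obj = json.loads(text)
        return cls(
            tuple(MixtureComponent(**c) for c in obj["components"])
        )

    @classmethod
    def vonmises_modes(cls, mus_deg, kappa: float) -> "MixtureSpec":
        """Equal-weight von Mises mixture with modes at the given degrees."""
        mus = np.mod(np.deg2rad(np.asarray(mus_deg, dtype=float)), TWO_PI)
        w = 1.0 / len(mus)
        return cls(
            tuple(
                MixtureComponent("vonmises", {"mu": float(m), "kappa": kappa}, w)
                for m in mus
            )
        )


def _sample_component(comp: MixtureComponent, n: int, rng) -> np.ndarray:
    p = comp.params
    if comp.family == "uniform":
        return sample_uniform(n, rng).angles
    if comp.family == "vonmises":
        return sample_vonmises(n, p["mu"], p["kappa"], rng).angles
    return sample_wrapped_skew_normal(
        n, p.get("xi", 0.0), p["omega"], p.get("alpha", 0.0), rng
    ).angles


def sample_mixture(spec: MixtureSpec, n: int, rng) -> AngleSample:
    """n i.i.d. draws from a mixture: component chosen per draw by weight."""
    if n < 1:
        raise ValueError("n must be >= 1")
    gen = as_rng(rng)
    weights = np.array([c.weight for c in spec.components])
    labels = gen.choice(len(weights), size=n, p=weights / weights.sum())
    out = np.empty(n)
    for k, comp in enumerate(spec.components):
        mask = labels == k
        m = int(mask.sum())
        if m:
            out[mask] = _sample_component(comp, m, gen)
    return AngleSample(out)
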