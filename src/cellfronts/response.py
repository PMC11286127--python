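"""Motility response functions g(s).

An agent sitting on substrate density ``s`` attempts a move with probability
``P * g(s)``.  The default response is the identity ``g(s) = s`` (motility
strictly proportional to local substrate); ``g(s) = s**n`` generalizes the
mechanism in the same way the generalized porous medium equation generalizes
degenerate diffusion, and a constant response recovers the substrate-blind
simple exclusion process.

Responses carry their derivative ``dg/ds`` because the continuum limit of the
generalized mechanism has flux ``-D [ g(s) du/dx + g'(s) u(1-u) ds/dx ]``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

_SAMPLES = np.linspace(0.0, 1.0, 257)
_TOL = 1e-9


@dataclass(frozen=True)
class MotilityResponse:
    """A bounded, non-decreasing map g: [0,1] -> [0,1] and its derivative."""

    g: Callable[[np.ndarray], np.ndarray]
    dg: Callable[[np.ndarray], np.ndarray]
    name: str = "custom"

    def __post_init__(self) -> None:
        vals = np.asarray(self.g(_SAMPLES), dtype=float)
        if vals.shape != _SAMPLES.shape:
            raise ValueError("g must map arrays to arrays elementwise")
        if vals.min() < -_TOL or vals.max() > 1.0 + _TOL:
            raise ValueError(f"g must map [0,1] into [0,1]; got range "
                             f"[{vals.min():g}, {vals.max():g}]")
        if np.any(np.diff(vals) < -_TOL):
            raise ValueError("g must be non-decreasing on [0,1]")

    def table(self, size: int = 4097) -> np.ndarray:
        """g sampled on a uniform grid over [0,1] (for the simulation kernel)."""
        return np.clip(np.asarray(self.g(np.linspace(0.0, 1.0, size)),
                                  dtype=float), 0.0, 1.0)

    def max_value(self) -> float:
        return float(np.max(self.g(_SAMPLES)))


def identity_response() -> MotilityResponse:
    """g(s) = s: motility proportional to local substrate (the default)."""
    return MotilityResponse(g=lambda s: np.asarray(s, dtype=float),
                            dg=lambda s: np.ones_like(np.asarray(s, dtype=float)),
                            name="identity")


def power_response(n: float) -> MotilityResponse:
    """g(s) = s**n for n > 0; n=1 is the identity."""
    if n <= 0:
        raise ValueError("power response requires n > 0")

    def g(s):
        return np.power(np.clip(np.asarray(s, dtype=float), 0.0, 1.0), n)

    def dg(s):
        s = np.clip(np.asarray(s, dtype=float), 0.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = n * np.power(s, n - 1.0)
        # derivative at s=0 diverges for n<1; the flux multiplies it by ds
        # which vanishes there too, so a large finite cap is safe
        return np.nan_to_num(out, nan=0.0, posinf=1e12)

    return MotilityResponse(g=g, dg=dg, name=f"power:{n:g}")


def constant_response(c: float = 1.0) -> MotilityResponse:
    """g(s) = c: substrate-independent motility (simple exclusion process)."""
    if not 0.0 <= c <= 1.0:
        raise ValueError("constant response must lie in [0,1]")
    return MotilityResponse(g=lambda s: np.full_like(np.asarray(s, dtype=float), c),
                            dg=lambda s: np.zeros_like(np.asarray(s, dtype=float)),
                            name=f"constant:{c:g}")


IDENTITY = identity_response()


def as_response(obj) -> MotilityResponse:
    """Coerce None / callable / MotilityResponse to a MotilityResponse.

    Bare callables get a central-difference derivative; passing a
    MotilityResponse with an analytic derivative is preferred for PDE work.
    """
    if obj is None:
        return IDENTITY
    if isinstance(obj, MotilityResponse):
        return obj
    if callable(obj):
        g = obj

        def dg(s, _g=g, _h=1e-6):
            s = np.asarray(s, dtype=float)
            lo = np.clip(s - _h, 0.0, 1.0)
            hi = np.clip(s + _h, 0.0, 1.0)
            return (np.asarray(_g(hi), float) - np.asarray(_g(lo), float)) / (hi - lo)

        return MotilityResponse(g=lambda s: np.asarray(g(np.asarray(s, float)), float),
                                dg=dg, name=getattr(obj, "__name__", "custom"))
    raise TypeError(f"cannot interpret {obj!r} as a motility response")
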