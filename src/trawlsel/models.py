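"""Size-selection retention curves.

Eight retention-probability models are available: four classical sigmoid
families — Logit, Probit, Gompertz and Richard — and their four
contact-probability ("C") variants.  Classical families assume every fish
entering the codend contacts the meshes in a way that gives it a
length-dependent chance of escape; a C-variant assumes only a
length-independent fraction ``C`` of fish make such contact, the remainder
being retained outright, which puts a floor of ``1 - C`` under the curve:

    r(l) = 1 - C + C * base(l | L50_c, SR_c)

All families are parameterised by L50 (length at 50% retention, cm) and
SR (selection range, L75 - L25, cm), the Richard family adding an
asymmetry parameter 1/delta.  Internally each family is a
location-scale sigmoid F((l - a) / b); (a, b) are obtained from
(L50, SR) through the family's standard quantile function X(p):

    b = SR / (X(0.75) - X(0.25)),    a = L50 - b * X(0.5)

The Richard curve is the exponentiated logistic F(z) = expit(z)**(1/delta)
with X(p) = ln(p**delta / (1 - p**delta)); at 1/delta = 1 it reduces to
the Logit curve exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from scipy.special import expit, ndtr, ndtri

__all__ = [
    "FAMILIES",
    "ALL_SPECS",
    "ModelSpec",
    "ParamVector",
    "ParameterError",
    "QuantileDomainError",
    "retention",
    "quantile_length",
    "overall_l50_sr",
]

FAMILIES = ("logit", "probit", "gompertz", "richard")


class ParameterError(ValueError):
    """A parameter vector is invalid for the requested model."""


class QuantileDomainError(ValueError):
    """The requested retention probability is not attained by the curve."""


@dataclass(frozen=True)
class ModelSpec:
    """Identity of one of the eight selection models."""

    family: str
    contact: bool = False

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ParameterError(f"unknown family {self.family!r}")

    @property
    def name(self) -> str:
        base = self.family.capitalize()
        return ("C" + base) if self.contact else base

    @property
    def n_params(self) -> int:
        k = 2
        if self.family == "richard":
            k += 1
        if self.contact:
            k += 1
        return k

    def to_dict(self) -> dict:
        return {"family": self.family, "contact": self.contact}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(family=d["family"], contact=bool(d["contact"]))


#: all eight model specifications, classical families first
ALL_SPECS = tuple(
    ModelSpec(f, contact) for contact in (False, True) for f in FAMILIES
)


@dataclass
class ParamVector:
    """Natural-scale curve parameters.

    For contact variants ``l50``/``sr`` are the contact-conditional
    L50_c / SR_c of the base curve; the overall curve quantiles follow
    from the mixture (see :func:`overall_l50_sr`).
    """

    l50: float
    sr: float
    inv_delta: Optional[float] = None
    c: Optional[float] = None

    def validate(self, spec: ModelSpec) -> None:
        if not np.isfinite(self.l50):
            raise ParameterError("L50 must be finite")
        if not (self.sr > 0):
            raise ParameterError(f"SR must be > 0, got {self.sr}")
        if spec.family == "richard":
            if self.inv_delta is None or not (self.inv_delta > 0):
                raise ParameterError("Richard needs 1/delta > 0")
        if spec.contact:
            if self.c is None or not (0.0 < self.c <= 1.0):
                raise ParameterError(f"C must be in (0, 1], got {self.c}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ParamVector":
        return cls(**{k: d.get(k) for k in ("l50", "sr", "inv_delta", "c")})


def _std_cdf(family: str, z: np.ndarray, inv_delta: Optional[float]) -> np.ndarray:
    if family == "logit":
        return expit(z)
    if family == "probit":
        return ndtr(z)
    if family == "gompertz":
        # exp(-z) overflowing means the curve is exactly at its 0 limit
        with np.errstate(over="ignore"):
            return np.exp(-np.exp(-z))
    if family == "richard":
        return expit(z) ** inv_delta
    raise ParameterError(f"unknown family {family!r}")


def _std_quantile(family: str, p: float, inv_delta: Optional[float]) -> float:
    if family == "logit":
        return math.log(p / (1.0 - p))
    if family == "probit":
        return float(ndtri(p))
    if family == "gompertz":
        return -math.log(-math.log(p))
    if family == "richard":
        delta = 1.0 / inv_delta
        pd_ = p**delta
        return math.log(pd_ / (1.0 - pd_))
    raise ParameterError(f"unknown family {family!r}")


def _loc_scale(spec: ModelSpec, params: ParamVector) -> tuple[float, float]:
    x25 = _std_quantile(spec.family, 0.25, params.inv_delta)
    x50 = _std_quantile(spec.family, 0.50, params.inv_delta)
    x75 = _std_quantile(spec.family, 0.75, params.inv_delta)
    b = params.sr / (x75 - x25)
    a = params.l50 - b * x50
    return a, b


def retention(spec: ModelSpec, params: ParamVector, l) -> np.ndarray:
    """Retention probability r(l) for length(s) ``l`` (cm).

    Classical families return the base sigmoid; contact variants return
    ``1 - C + C * base(l)``.
    """
    params.validate(spec)
    a, b = _loc_scale(spec, params)
    l_arr = np.asarray(l, dtype=float)
    base = _std_cdf(spec.family, (l_arr - a) / b, params.inv_delta)
    if spec.contact:
        base = 1.0 - params.c + params.c * base
    if np.ndim(l) == 0:
        return float(base)
    return base


def quantile_length(spec: ModelSpec, params: ParamVector, p: float) -> float:
    """Length (cm) at which the curve attains retention probability ``p``.

    Inverse of :func:`retention`.  For a contact variant the curve never
    drops below ``1 - C``; asking for a p at or below that floor raises
    :class:`QuantileDomainError` (the overall L50/SR are then "not
    reached").
    """
    params.validate(spec)
    if not (0.0 < p < 1.0):
        raise QuantileDomainError(f"p={p} must be strictly inside (0, 1)")
    if spec.contact:
        floor = 1.0 - params.c
        if p <= floor:
            raise QuantileDomainError(
                f"retention {p} not reached: curve floor is 1 - C = {floor:.4g}"
            )
        p = (p - floor) / params.c
        if p >= 1.0:
            raise QuantileDomainError("retention probability not attained")
    a, b = _loc_scale(spec, params)
    return a + b * _std_quantile(spec.family, p, params.inv_delta)


def overall_l50_sr(
    spec: ModelSpec, params: ParamVector
) -> tuple[Optional[float], Optional[float]]:
    """Overall (mixture-curve) L50 and SR.

    For classical models these are the parameters themselves.  For contact
    variants the overall L50 exists only when the floor 1 - C < 0.5 and
    the overall SR only when 1 - C < 0.25; unreachable quantiles are
    returned as ``None``.
    """
    if not spec.contact:
        return params.l50, params.sr
    try:
        l50 = quantile_length(spec, params, 0.5)
    except QuantileDomainError:
        return None, None
    try:
        sr = quantile_length(spec, params, 0.75) - quantile_length(spec, params, 0.25)
    except QuantileDomainError:
        return l50, None
    return l50, sr
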