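"""Maximum-likelihood fitting of selection curves to covered-codend data.

A fish of length ``l`` entering the codend is retained with probability
``r(l)`` or escapes into the cover with probability ``1 - r(l)``, so the
catch data are binomial per length class.  Hauls are pooled: the
log-likelihood sums, over hauls j and classes l, the raised counts

    - sum_j sum_l { nR_jl / qR_j * ln r(l) + nE_jl / qE_j * ln(1 - r(l)) }

where qR_j, qE_j are the compartment subsampling ratios.  The objective
omits the binomial coefficients, which are parameter-free within a
dataset, so AIC *rankings* are unaffected while absolute AIC values are
offset by a constant.

Optimisation runs a bounded quasi-Newton (L-BFGS-B) on unconstrained
transforms (L50 free, log SR, log 1/delta, logit C) from a deterministic
multi-start grid; mixture (contact) likelihoods are multimodal, so the
best optimum over all starts is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import chi2

from .catch import CatchDataset
from .models import (
    ALL_SPECS,
    ModelSpec,
    ParamVector,
    overall_l50_sr,
    retention,
)

__all__ = [
    "FitResult",
    "neg_log_likelihood",
    "fit",
    "fit_all",
    "goodness_of_fit",
    "select_model",
]

_EPS = 1e-12  # retention clip used in every log
_SR_BOUNDS = (math.log(0.05), math.log(60.0))
_INVD_BOUNDS = (math.log(0.02), math.log(50.0))
_LOGITC_BOUNDS = (logit(1e-4), logit(1.0 - 1e-8))

# default multi-start policy
_START_SR = (2.0, 4.0, 8.0)
_START_C = (0.3, 0.6, 0.9)
_START_INVD = (0.5, 1.0, 2.0)
_START_L50_PCTL = (10.0, 30.0, 50.0, 70.0, 90.0)


@dataclass
class FitResult:
    """Point estimates and diagnostics for one model on one dataset."""

    spec: ModelSpec
    params: ParamVector
    neg_log_lik: float
    aic: float
    deviance: Optional[float] = None
    dof: Optional[int] = None
    p_value: Optional[float] = None
    converged: bool = False
    at_boundary: bool = False
    n_starts_used: int = 0
    message: str = ""

    @property
    def k(self) -> int:
        return self.spec.n_params

    def overall_l50_sr(self):
        return overall_l50_sr(self.spec, self.params)

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "params": self.params.to_dict(),
            "neg_log_lik": self.neg_log_lik,
            "aic": self.aic,
            "deviance": self.deviance,
            "dof": self.dof,
            "p_value": self.p_value,
            "converged": self.converged,
            "at_boundary": self.at_boundary,
            "n_starts_used": self.n_starts_used,
            "message": self.message,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        d = dict(d)
        d["spec"] = ModelSpec.from_dict(d["spec"])
        d["params"] = ParamVector.from_dict(d["params"])
        return cls(**d)


def _xlogy(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    # 0 * log(0) -> 0; y pre-clipped so log is finite
    out = np.zeros_like(y, dtype=float)
    nz = x != 0
    out[nz] = x[nz] * np.log(y[nz])
    return out


def neg_log_likelihood(
    dataset: CatchDataset, spec: ModelSpec, params: ParamVector
) -> float:
    """Pooled-over-hauls negative log-likelihood at ``params``.

    Counts are raised by 1/q per haul and compartment; retention is
    clipped to ``[1e-12, 1 - 1e-12]`` before taking logs, and empty
    cells contribute exactly zero.
    """
    total = 0.0
    for h in dataset:
        r = retention(spec, params, h.length_classes.astype(float))
        r = np.clip(r, _EPS, 1.0 - _EPS)
        total -= float(
            np.sum(_xlogy(h.raised_codend, r) + _xlogy(h.raised_cover, 1.0 - r))
        )
    return total


# ---------------------------------------------------------------------------
# parameter transforms (optimizer space <-> natural space)
# ---------------------------------------------------------------------------

def _to_theta(spec: ModelSpec, p: ParamVector) -> np.ndarray:
    theta = [p.l50, math.log(p.sr)]
    if spec.family == "richard":
        theta.append(math.log(p.inv_delta))
    if spec.contact:
        theta.append(float(logit(min(max(p.c, 1.5e-4), 1.0 - 1.5e-8))))
    return np.asarray(theta)


def _from_theta(spec: ModelSpec, theta: np.ndarray) -> ParamVector:
    l50, log_sr = theta[0], theta[1]
    i = 2
    inv_delta = None
    c = None
    if spec.family == "richard":
        inv_delta = math.exp(theta[i])
        i += 1
    if spec.contact:
        c = float(expit(theta[i]))
    return ParamVector(l50=float(l50), sr=math.exp(log_sr), inv_delta=inv_delta, c=c)


def _bounds(spec: ModelSpec, lmin: float, lmax: float):
    b = [(lmin - 10.0, lmax + 10.0), _SR_BOUNDS]
    if spec.family == "richard":
        b.append(_INVD_BOUNDS)
    if spec.contact:
        b.append(_LOGITC_BOUNDS)
    return b


def _pooled_nll_fn(lengths: np.ndarray, nR: np.ndarray, nE: np.ndarray, spec: ModelSpec):
    """Objective over transformed parameters on pooled raised counts.

    Pooling over hauls is exact here because r(l) is shared across hauls,
    so sum_j nR_jl/qR_j factors out of the log terms.
    """
    maskR = nR > 0
    maskE = nE > 0
    lR, cR = lengths[maskR], nR[maskR]
    lE, cE = lengths[maskE], nE[maskE]

    def fn(theta: np.ndarray) -> float:
        p = _from_theta(spec, theta)
        rR = np.clip(retention(spec, p, lR), _EPS, 1.0 - _EPS)
        rE = np.clip(retention(spec, p, lE), _EPS, 1.0 - _EPS)
        return -(float(np.dot(cR, np.log(rR))) + float(np.dot(cE, np.log1p(-rE))))

    return fn


def _default_starts(
    spec: ModelSpec, lengths: np.ndarray, nR: np.ndarray, nE: np.ndarray
) -> list[ParamVector]:
    tot = nR + nE
    if tot.sum() <= 0:
        centers = [float(np.median(lengths))]
    else:
        cum = np.cumsum(tot) / tot.sum()
        centers = [
            float(lengths[int(np.searchsorted(cum, q / 100.0))])
            for q in _START_L50_PCTL
        ]
        centers = sorted(set(centers))
    starts = []
    invds = _START_INVD if spec.family == "richard" else (None,)
    cs = _START_C if spec.contact else (None,)
    for l50 in centers:
        for sr in _START_SR:
            for invd in invds:
                for c in cs:
                    starts.append(ParamVector(l50, sr, inv_delta=invd, c=c))
    return starts


def _fit_pooled(
    lengths: np.ndarray,
    nR: np.ndarray,
    nE: np.ndarray,
    spec: ModelSpec,
    starts: Sequence[ParamVector],
    tol: float = 1e-9,
) -> FitResult:
    fn = _pooled_nll_fn(lengths, nR, nE, spec)
    bounds = _bounds(spec, float(lengths.min()), float(lengths.max()))
    best = None
    best_val = math.inf
    for p0 in starts:
        res = minimize(
            fn,
            _to_theta(spec, p0),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": tol, "gtol": 1e-8, "maxiter": 500},
        )
        if res.success and np.isfinite(res.fun) and res.fun < best_val:
            best, best_val = res, float(res.fun)
        elif best is None:
            best = res
    converged = best is not None and np.isfinite(best_val) and bool(best.success)
    params = _from_theta(spec, best.x)
    at_boundary = any(
        (x - lo) < 1e-4 or (hi - x) < 1e-4 for x, (lo, hi) in zip(best.x, bounds)
    )
    k = spec.n_params
    return FitResult(
        spec=spec,
        params=params,
        neg_log_lik=best_val,
        aic=(2.0 * k + 2.0 * best_val) if converged else math.inf,
        converged=converged,
        at_boundary=at_boundary,
        n_starts_used=len(starts),
        message=str(getattr(best, "message", "")),
    )


def fit(
    dataset: CatchDataset,
    spec: ModelSpec,
    starts: Sequence[ParamVector] | None = None,
    tol: float = 1e-9,
    with_gof: bool = True,
) -> FitResult:
    """Maximum-likelihood fit of one selection model.

    ``starts`` overrides the default multi-start grid (L50 at weighted
    percentiles of the raised length distribution; SR in {2, 4, 8} cm;
    C in {0.3, 0.6, 0.9}; 1/delta in {0.5, 1, 2}).  Deterministic given
    the dataset and start policy.
    """
    lengths, nR, nE = dataset.pooled_raised()
    if starts is None:
        starts = _default_starts(spec, lengths, nR, nE)
    result = _fit_pooled(lengths, nR, nE, spec, starts, tol=tol)
    if with_gof and result.converged:
        dev, dof, p = goodness_of_fit(result, dataset)
        result.deviance, result.dof, result.p_value = dev, dof, p
    return result


def fit_all(
    dataset: CatchDataset, specs: Sequence[ModelSpec] = ALL_SPECS, **kwargs
) -> list[FitResult]:
    """Fit every model in ``specs`` to the same dataset."""
    return [fit(dataset, s, **kwargs) for s in specs]


def goodness_of_fit(fit_result: FitResult, dataset: CatchDataset):
    """Model deviance against the saturated model on pooled raised counts.

    Returns ``(deviance, dof, p_value)`` with ``dof = occupied classes - k``
    and p the upper chi-square tail.  If ``dof <= 0`` the test is not
    assessable and p is ``None``.
    """
    if not fit_result.converged:
        raise ValueError("goodness of fit requires a converged fit")
    lengths, nR, nE = dataset.pooled_raised()
    tot = nR + nE
    occ = tot > 0
    r = np.clip(
        retention(fit_result.spec, fit_result.params, lengths[occ]), _EPS, 1.0 - _EPS
    )
    nRo, nEo, toto = nR[occ], nE[occ], tot[occ]
    # saturated likelihood uses the raised per-class proportions
    phat = nRo / toto
    sat = np.sum(_xlogy(nRo, phat) + _xlogy(nEo, 1.0 - phat))
    mod = np.sum(_xlogy(nRo, r) + _xlogy(nEo, 1.0 - r))
    deviance = float(2.0 * (sat - mod))
    dof = int(occ.sum()) - fit_result.spec.n_params
    if dof <= 0:
        return deviance, dof, None
    return deviance, dof, float(chi2.sf(deviance, dof))


def select_model(fits: Sequence[FitResult]):
    """Pick the lowest-AIC converged fit and return the ranked AIC table.

    Returns ``(best_fit, table)`` where ``table`` is a pandas DataFrame
    ranked by AIC with the per-model parameter estimates and diagnostics.
    """
    import pandas as pd

    converged = [f for f in fits if f.converged]
    if not converged:
        raise ValueError("no converged fits to select from")
    rows = []
    for f in fits:
        l50o, sro = f.overall_l50_sr() if f.converged else (None, None)
        rows.append(
            {
                "model": f.spec.name,
                "k": f.k,
                "neg_log_lik": f.neg_log_lik,
                "aic": f.aic,
                "deviance": f.deviance,
                "dof": f.dof,
                "p_value": f.p_value,
                "l50": f.params.l50,
                "sr": f.params.sr,
                "inv_delta": f.params.inv_delta,
                "c": f.params.c,
                "overall_l50": l50o,
                "overall_sr": sro,
                "converged": f.converged,
            }
        )
    table = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    best = min(converged, key=lambda f: f.aic)
    return best, table
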