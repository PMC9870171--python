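"""Double bootstrap, Efron percentile intervals and delta selectivity curves.

Uncertainty in covered-codend selectivity has two sources: between-haul
variation and within-haul binomial sampling.  Each bootstrap replicate
therefore resamples m hauls with replacement (outer stage), then within
each selected haul resamples its *measured* fish with replacement per
compartment — subsampling ratios stay fixed, so the raising noise is part
of the resampled variation — and refits the chosen model (inner stage).
Confidence intervals are Efron percentiles of the replicate population,
per curve grid point and per parameter.

Two gears are compared with the delta curve Delta r(l) = r_e(l) - r_c(l).
Because the two bootstrap populations are generated independently, a
valid bootstrap population for the difference is formed by pairing
replicate i of one gear with replicate i of the other; the paired CI can
never be wider than the two marginal CIs combined, which is what gives
the comparison its power.  Lengths where the paired CI excludes zero
differ significantly between gears.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .catch import CatchDataset, HaulRecord
from .fitting import FitResult, _default_starts, _fit_pooled, fit
from .models import ModelSpec, ParamVector, retention

__all__ = [
    "BootstrapPopulation",
    "DeltaResult",
    "default_grid",
    "double_bootstrap",
    "efron_ci",
    "delta_curve",
]

GRID_STEP = 0.1  # cm
GRID_PAD = 2.0  # cm beyond the observed length range


@dataclass
class BootstrapPopulation:
    """Per-replicate parameter vectors and retention curves on a fixed grid."""

    spec: ModelSpec
    grid: np.ndarray
    params: list[ParamVector]
    curves: np.ndarray  # (n_boot, len(grid))
    n_boot: int
    seed: int
    failure_log: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "grid": self.grid.tolist(),
            "params": [p.to_dict() for p in self.params],
            "curves": self.curves.tolist(),
            "n_boot": self.n_boot,
            "seed": self.seed,
            "failure_log": list(self.failure_log),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BootstrapPopulation":
        return cls(
            spec=ModelSpec.from_dict(d["spec"]),
            grid=np.asarray(d["grid"]),
            params=[ParamVector.from_dict(p) for p in d["params"]],
            curves=np.asarray(d["curves"]),
            n_boot=int(d["n_boot"]),
            seed=int(d["seed"]),
            failure_log=list(d["failure_log"]),
        )


@dataclass
class DeltaResult:
    """Pointwise gear difference with paired-bootstrap Efron intervals."""

    grid: np.ndarray
    delta: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    significant_ranges: list[tuple[float, float]]

    def to_dict(self) -> dict:
        return {
            "grid": self.grid.tolist(),
            "delta": self.delta.tolist(),
            "lo": self.lo.tolist(),
            "hi": self.hi.tolist(),
            "significant_ranges": [list(r) for r in self.significant_ranges],
        }


def default_grid(dataset: CatchDataset, step: float = GRID_STEP) -> np.ndarray:
    """0.1-cm grid spanning the observed length range padded by 2 cm."""
    lo = float(dataset.length_classes.min()) - GRID_PAD
    hi = float(dataset.length_classes.max()) + GRID_PAD
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def _resample_haul(h: HaulRecord, rng: np.random.Generator) -> HaulRecord:
    """Inner stage: resample the haul's measured fish list with replacement.

    Each measured fish is a (length class, compartment) observation, so
    resampling the M fish of the haul is one multinomial draw over the
    joint class x compartment cells.  Resampling jointly (rather than
    within each compartment) regenerates the binomial codend/cover split
    noise that the inner stage exists to capture; q stays fixed.
    """
    new = HaulRecord.__new__(HaulRecord)  # skip validation for speed
    new.haul_id = h.haul_id
    new.treatment = h.treatment
    new.length_classes = h.length_classes
    new.q_codend = h.q_codend
    new.q_cover = h.q_cover
    new.meta = h.meta
    cells = np.concatenate([h.n_codend, h.n_cover])
    total = int(cells.sum())
    draw = rng.multinomial(total, cells / total)
    k = h.n_codend.size
    new.n_codend = draw[:k]
    new.n_cover = draw[k:]
    return new


def double_bootstrap(
    dataset: CatchDataset,
    spec: ModelSpec,
    n_boot: int,
    seed: int,
    grid: Optional[np.ndarray] = None,
    point_fit: Optional[FitResult] = None,
    n_extra_starts: int = 2,
    max_redraws: int = 10,
) -> BootstrapPopulation:
    """Double bootstrap of a selection-model fit.

    Each of the ``n_boot`` replicates resamples hauls with replacement
    (outer), resamples measured fish within each selected haul (inner)
    and refits ``spec``.  Replicates that fail to converge are redrawn up
    to ``max_redraws`` times; persistent failures are logged and the last
    refit is kept so the population size is exactly ``n_boot``.  Fully
    deterministic given ``seed``.

    Refits warm-start from the point estimate (with a few coarse extra
    starts); pass ``point_fit`` to avoid recomputing it.
    """
    if len(dataset) < 1:
        raise ValueError("bootstrap needs at least one haul")
    if grid is None:
        grid = default_grid(dataset)
    grid = np.asarray(grid, dtype=float)
    if point_fit is None and n_boot > 0:
        point_fit = fit(dataset, spec, with_gof=False)

    params_out: list[ParamVector] = []
    curves = np.empty((n_boot, grid.size))
    failures: list[int] = []
    hauls = dataset.hauls
    m = len(hauls)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_boot) if n_boot > 0 else []

    for i in range(n_boot):
        rng = np.random.default_rng(child_seeds[i])
        result = None
        for attempt in range(max_redraws + 1):
            idx = rng.integers(0, m, size=m)
            nR = np.zeros(len(dataset.length_classes))
            nE = np.zeros(len(dataset.length_classes))
            for j in idx:
                bh = _resample_haul(hauls[j], rng)
                nR += bh.n_codend / bh.q_codend
                nE += bh.n_cover / bh.q_cover
            lengths = dataset.length_classes.astype(float)
            starts = [point_fit.params]
            if n_extra_starts > 0:
                extra = _default_starts(spec, lengths, nR, nE)
                starts += extra[:: max(1, len(extra) // n_extra_starts)][:n_extra_starts]
            result = _fit_pooled(lengths, nR, nE, spec, starts)
            if result.converged:
                break
        if not result.converged:
            failures.append(i)
        params_out.append(result.params)
        curves[i] = retention(spec, result.params, grid)

    if n_boot > 0 and len(failures) > 0.05 * n_boot:
        warnings.warn(
            f"{len(failures)}/{n_boot} bootstrap replicates failed to converge",
            RuntimeWarning,
        )
    return BootstrapPopulation(
        spec=spec,
        grid=grid,
        params=params_out,
        curves=curves,
        n_boot=n_boot,
        seed=seed,
        failure_log=failures,
    )


def efron_ci(pop: BootstrapPopulation, level: float = 0.95) -> dict:
    """Efron percentile intervals per grid point and per parameter.

    Returns a dict with ``curve_lo``/``curve_hi`` arrays on ``pop.grid``
    and a ``params`` mapping of ``(lo, hi)`` per parameter name.
    """
    if pop.n_boot == 0 or len(pop.params) == 0:
        raise ValueError("empty bootstrap population")
    alpha = (1.0 - level) / 2.0
    lo_q, hi_q = 100.0 * alpha, 100.0 * (1.0 - alpha)
    curve_lo = np.percentile(pop.curves, lo_q, axis=0)
    curve_hi = np.percentile(pop.curves, hi_q, axis=0)
    param_ci = {}
    for name in ("l50", "sr", "inv_delta", "c"):
        vals = np.array(
            [getattr(p, name) for p in pop.params if getattr(p, name) is not None]
        )
        if vals.size == len(pop.params):
            param_ci[name] = (
                float(np.percentile(vals, lo_q)),
                float(np.percentile(vals, hi_q)),
            )
    return {"level": level, "curve_lo": curve_lo, "curve_hi": curve_hi, "params": param_ci}


def delta_curve(
    pop_e: BootstrapPopulation,
    pop_c: BootstrapPopulation,
    fit_e: FitResult,
    fit_c: FitResult,
    level: float = 0.95,
) -> DeltaResult:
    """Delta curve Delta r(l) = r_e(l) - r_c(l) with paired-replicate CIs.

    The point delta comes from the two point fits; the CI comes from the
    index-paired difference of the two (independently generated)
    bootstrap populations.  Lengths where the CI excludes zero are
    returned as maximal closed ``significant_ranges``.
    """
    if pop_e.n_boot != pop_c.n_boot:
        raise ValueError("bootstrap populations differ in n_boot")
    if pop_e.grid.shape != pop_c.grid.shape or not np.allclose(pop_e.grid, pop_c.grid):
        raise ValueError("bootstrap populations use different length grids")
    grid = pop_e.grid
    delta = retention(fit_e.spec, fit_e.params, grid) - retention(
        fit_c.spec, fit_c.params, grid
    )
    diffs = pop_e.curves - pop_c.curves
    alpha = (1.0 - level) / 2.0
    lo = np.percentile(diffs, 100.0 * alpha, axis=0)
    hi = np.percentile(diffs, 100.0 * (1.0 - alpha), axis=0)
    sig = (lo > 0.0) | (hi < 0.0)
    ranges: list[tuple[float, float]] = []
    start = None
    for i, s in enumerate(sig):
        if s and start is None:
            start = i
        elif not s and start is not None:
            ranges.append((float(grid[start]), float(grid[i - 1])))
            start = None
    if start is not None:
        ranges.append((float(grid[start]), float(grid[-1])))
    return DeltaResult(grid=grid, delta=delta, lo=lo, hi=hi, significant_ranges=ranges)
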