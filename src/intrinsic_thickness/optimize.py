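"""Golden-section optimization of the three FWHM free parameters.

The local regression has three free parameters — surface-smoothing FWHM,
curvature-smoothing FWHM, and patch FWHM.  They are tuned against a target
("silver standard") map: the group-average of globally compensated
thickness, in which spatially inconsistent folding effects have largely
averaged out.  The criterion is the proportion of variance (R^2) in each
individual's compensated map explained by the target, averaged across
subjects.

The three parameters are optimized sequentially — (1) patch size,
(2) surface smoothing, (3) curvature smoothing — each by one-dimensional
golden-section search, holding the others at their current values
(not-yet-optimized ones start at their interval midpoints).  Search stops
when the bracket width falls below the tolerance (default 0.1 mm).  The
whole procedure is deterministic.

Reference intervals: patch [3, 10] mm, surface [0, 3] mm, curvature
[0, 3] mm; reference optimized values (2.14, 2.52, 6) mm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .compensate import CompensationParams, compensate_pipeline
from .io_formats import VertexMetric

logger = logging.getLogger(__name__)

__all__ = [
    "OptimizationTrace",
    "golden_section_max",
    "objective_r2",
    "optimize_params",
    "DEFAULT_INTERVALS",
]

INVPHI = (np.sqrt(5.0) - 1.0) / 2.0  # 1/phi = 0.618...

DEFAULT_INTERVALS = {
    "patch_fwhm": (3.0, 10.0),
    "surface_fwhm": (0.0, 3.0),
    "metric_fwhm": (0.0, 3.0),
}

#: reference optimized parameter values when optimization is skipped
REFERENCE_OPTIMUM = CompensationParams(surface_fwhm=2.14, metric_fwhm=2.52,
                                       patch_fwhm=6.0)


@dataclass
class OptimizationTrace:
    """Record of one golden-section run: evaluations, brackets, result."""

    parameter: str = ""
    evaluations: list = field(default_factory=list)  # (x, f(x))
    brackets: list = field(default_factory=list)  # (lo, hi) per iteration
    result: float = float("nan")
    n_iterations: int = 0

    @property
    def best_evaluated(self) -> tuple:
        return max(self.evaluations, key=lambda e: e[1]) if self.evaluations else (None, None)


def golden_section_max(f, lo: float, hi: float, tol: float,
                       parameter: str = "") -> tuple:
    """Maximize a unimodal function on [lo, hi] by golden-section search.

    Shrinks the bracket by 1/phi per iteration until ``hi - lo < tol`` and
    returns ``(midpoint, trace)``.  Evaluations are cached so no point is
    evaluated twice.
    """
    if not lo < hi:
        raise ValueError("need lo < hi")
    if tol <= 0:
        raise ValueError("tol must be positive")
    trace = OptimizationTrace(parameter=parameter)
    cache: dict = {}

    def ev(x: float) -> float:
        if x not in cache:
            cache[x] = float(f(x))
            trace.evaluations.append((x, cache[x]))
        return cache[x]

    a, b = float(lo), float(hi)
    trace.brackets.append((a, b))
    c = b - INVPHI * (b - a)
    d = a + INVPHI * (b - a)
    while b - a > tol:
        if ev(c) < ev(d):
            a = c
            c, d = d, a + INVPHI * (b - a)
        else:
            b = d
            d, c = c, b - INVPHI * (b - a)
        trace.brackets.append((a, b))
        trace.n_iterations += 1
    trace.result = 0.5 * (a + b)
    return trace.result, trace


def objective_r2(individual_map: VertexMetric, target_map: VertexMetric,
                 mask=None) -> float:
    """R^2 of the individual map regressed on the target map over the mask.

    Equals the squared Pearson correlation (simple linear regression), so it
    is invariant to affine rescaling of either map; in [0, 1].
    """
    m = individual_map.mask & target_map.mask
    if mask is not None:
        m = m & np.asarray(mask, bool)
    x = target_map.values[m]
    y = individual_map.values[m]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance map in objective")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def optimize_params(subjects, target_map: VertexMetric,
                    intervals: dict | None = None, tol: float = 0.1,
                    mask=None, base_params: CompensationParams | None = None):
    """Sequential golden-section optimization of the three FWHM parameters.

    ``subjects`` is a sequence of ``(mesh, thickness)`` pairs on the common
    standard mesh of ``target_map``.  For each candidate parameter value the
    objective is the mean across subjects of :func:`objective_r2` between
    that subject's compensated map and the target.  Order: patch size, then
    surface smoothing, then curvature smoothing.  Returns
    ``(CompensationParams, {parameter: OptimizationTrace})``.
    """
    if len(subjects) < 1:
        raise ValueError("need at least one subject")
    iv = dict(DEFAULT_INTERVALS)
    if intervals:
        iv.update(intervals)
    # not-yet-optimized parameters start at interval midpoints
    current = {p: 0.5 * (iv[p][0] + iv[p][1]) for p in iv}
    if base_params is not None:
        current = {
            "patch_fwhm": base_params.patch_fwhm,
            "surface_fwhm": base_params.surface_fwhm,
            "metric_fwhm": base_params.metric_fwhm,
        }
    traces = {}
    per_subject_spread = {}

    def objective(pdict) -> tuple:
        params = CompensationParams(**pdict)
        r2s = []
        for mesh, thickness in subjects:
            tcorr, _, _ = compensate_pipeline(mesh, thickness, params, mask=mask)
            r2s.append(objective_r2(tcorr, target_map, mask=mask))
        return float(np.mean(r2s)), float(np.std(r2s))

    for pname in ("patch_fwhm", "surface_fwhm", "metric_fwhm"):
        lo, hi = iv[pname]
        spread: dict = {}

        def f(x, _pname=pname, _spread=spread):
            trial = dict(current)
            trial[_pname] = x
            mean_r2, sd_r2 = objective(trial)
            _spread[x] = sd_r2
            return mean_r2

        best, trace = golden_section_max(f, lo, hi, tol, parameter=pname)
        current[pname] = best
        traces[pname] = trace
        per_subject_spread[pname] = spread
        logger.info("optimized %s = %.3f mm (%d evaluations)",
                    pname, best, len(trace.evaluations))

    params = CompensationParams(**current)
    for pname in traces:
        traces[pname].per_subject_sd = per_subject_spread[pname]
    return params, traces
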