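"""Persistence and contour length from traced 2D molecule contours.

Molecules equilibrated in a 2D conformation on a surface obey the worm-like
chain tangent-correlation decay

    <cos theta(L)> = exp(-L / (2 P)),

with L the arc-length separation of two tangents and P the persistence
length (in 3D the decay is exp(-L/P)).  The pipeline is: resample each traced
centerline to a uniform arc-length step, take unit tangents from consecutive
segments, pool the cosine of the tangent-pair angle over all in-molecule
pairs of all molecules, bin by separation, and fit the exponential decay by
weighted least squares.

Tangents are attached to segment midpoints (half-integer arc positions), so
pair separations are exact multiples of the resampling step and the discrete
ensemble average satisfies the decay law at those separations with no
smoothing bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ContourTrace",
    "TangentCorrelation",
    "PersistenceFit",
    "contour_length",
    "resample_trace",
    "tangent_correlation",
    "fit_persistence",
]


@dataclass(frozen=True)
class ContourTrace:
    """Ordered 2D centerline of one traced molecule, coordinates in nm."""

    id: str
    points: np.ndarray  # (n, 2)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if len(pts) < 3:
            raise ValueError("a trace needs at least 3 points")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("consecutive trace points must be distinct")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class TangentCorrelation:
    """Binned tangent-correlation function of an ensemble of traces."""

    separation_nm: np.ndarray  # pair-weighted mean separation per bin
    mean_cos: np.ndarray
    pair_counts: np.ndarray
    var_of_mean: np.ndarray  # sample variance of the bin mean

    def __post_init__(self):
        for name in ("separation_nm", "mean_cos", "pair_counts", "var_of_mean"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))


@dataclass(frozen=True)
class PersistenceFit:
    P_nm: float
    stderr_nm: float
    fit_range_nm: tuple[float, float]
    residual_norm: float
    n_bins: int
    dims: int = 2


def _segments(points: np.ndarray) -> np.ndarray:
    return np.diff(np.asarray(points, dtype=float), axis=0)


def contour_length(trace: ContourTrace | np.ndarray) -> float:
    """Total arc length (nm) of the traced polyline."""
    pts = trace.points if isinstance(trace, ContourTrace) else np.asarray(trace, float)
    if len(pts) < 2:
        raise ValueError("need at least 2 points for a contour length")
    return float(np.linalg.norm(_segments(pts), axis=1).sum())


def resample_trace(trace: ContourTrace, step_nm: float) -> ContourTrace:
    """Resample a trace at uniform arc-length spacing along the polyline.

    Points are placed at arc lengths 0, h, 2h, ..., S with h = S / round(S/step)
    so spacing is exactly uniform and both endpoints are preserved; h deviates
    from the requested step by at most half a step.
    """
    if step_nm <= 0:
        raise ValueError("step must be positive")
    pts = trace.points
    seg_len = np.linalg.norm(_segments(pts), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = s[-1]
    if step_nm >= total:
        raise ValueError("step must be smaller than the contour length")
    n_seg = max(2, int(round(total / step_nm)))
    s_new = np.linspace(0.0, total, n_seg + 1)
    x = np.interp(s_new, s, pts[:, 0])
    y = np.interp(s_new, s, pts[:, 1])
    return ContourTrace(trace.id, np.column_stack([x, y]))


def _check_uniform_step(traces: Sequence[ContourTrace], rtol: float = 1e-3) -> float:
    steps = []
    for t in traces:
        seg = np.linalg.norm(_segments(t.points), axis=1)
        if np.ptp(seg) > rtol * seg.mean():
            raise ValueError(f"trace {t.id!r} is not uniformly resampled")
        steps.append(seg.mean())
    steps = np.asarray(steps)
    if np.ptp(steps) > rtol * steps.mean():
        raise ValueError("traces do not share a common resampling step")
    return float(steps.mean())


def tangent_correlation(
    traces: Sequence[ContourTrace],
    bin_width_nm: float = 5.0,
    L_max_nm: float = 150.0,
) -> TangentCorrelation:
    """Pooled tangent correlation <cos theta(L)> of a uniformly resampled ensemble.

    All tangent pairs within each molecule are pooled across molecules, then
    binned by arc-length separation (bins of ``bin_width_nm`` up to
    ``L_max_nm``).
    """
    if len(traces) == 0:
        raise ValueError("empty ensemble")
    step = _check_uniform_step(traces)

    k_max = int(np.floor(L_max_nm / step))
    seps, coss = [], []
    for t in traces:
        seg = _segments(t.points)
        u = seg / np.linalg.norm(seg, axis=1, keepdims=True)
        n = len(u)
        for k in range(1, min(k_max, n - 1) + 1):
            c = np.einsum("ij,ij->i", u[:-k], u[k:])
            coss.append(c)
            seps.append(np.full(len(c), k * step))
    if not seps:
        raise ValueError("no tangent pairs within L_max; traces too short")
    sep = np.concatenate(seps)
    cos = np.concatenate(coss)

    edges = np.arange(0.0, L_max_nm + bin_width_nm, bin_width_nm)
    idx = np.digitize(sep, edges) - 1
    nbin = len(edges) - 1
    centers, means, counts, vars_ = [], [], [], []
    for b in range(nbin):
        m = idx == b
        n = int(m.sum())
        if n == 0:
            continue
        c = cos[m]
        centers.append(sep[m].mean())
        means.append(c.mean())
        counts.append(n)
        vars_.append(c.var(ddof=1) / n if n > 1 else np.inf)
    return TangentCorrelation(
        np.asarray(centers), np.asarray(means), np.asarray(counts), np.asarray(vars_)
    )


def fit_persistence(
    corr: TangentCorrelation,
    fit_range_nm: tuple[float, float] = (5.0, 150.0),
    dims: int = 2,
    p0_nm: float = 50.0,
) -> PersistenceFit:
    """Weighted least-squares fit of the exponential tangent-correlation decay.

    The model is exp(-L/(2P)) for surface-equilibrated (2D) molecules, the
    default, or exp(-L/P) with ``dims=3``.  The fit is performed in linear
    space with weights 1/variance of each bin mean; bins with non-positive
    mean correlation are excluded (and at least 5 usable bins are required).
    """
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    lo, hi = fit_range_nm
    if not lo < hi:
        raise ValueError("fit range must satisfy L_min < L_max")
    m = (corr.separation_nm >= lo) & (corr.separation_nm <= hi) & (corr.mean_cos > 0)
    if m.sum() < 5:
        raise ValueError("need at least 5 bins with positive mean correlation in range")
    L = corr.separation_nm[m]
    y = corr.mean_cos[m]
    var = corr.var_of_mean[m]
    # Floor the weights so noise-free input remains fittable.
    floor = max(np.nanmin(var[np.isfinite(var) & (var > 0)], initial=np.inf), 1e-18)
    sigma = np.sqrt(np.where(np.isfinite(var) & (var > 0), var, floor))

    scale = 2.0 if dims == 2 else 1.0

    def model(Ls, P):
        return np.exp(-Ls / (scale * P))

    popt, pcov = curve_fit(model, L, y, p0=[p0_nm], sigma=sigma, absolute_sigma=False)
    P = float(popt[0])
    stderr = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else 0.0
    resid = y - model(L, P)
    return PersistenceFit(
        P_nm=P,
        stderr_nm=stderr,
        fit_range_nm=(float(lo), float(hi)),
        residual_norm=float(np.linalg.norm(resid)),
        n_bins=int(m.sum()),
        dims=dims,
    )
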