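"""Metropolis Monte Carlo of a discrete worm-like chain in a nanochannel.

The model is a bead-rod chain with bending energy E/kT = (P/(2b)) sum theta_i^2
(b the bond length, P the persistence length), hard walls on the rectangular
channel cross-section (the channel axis is z, the cross-section is centered on
the origin, and the wall condition acts on bead centers), and optional
hard-core excluded volume between beads at least two bonds apart.  Sampling
uses crankshaft and pivot moves that preserve bond lengths exactly.

The headline experiment compares the equilibrium stretch (z-span) of a bare
chain with that of a protein-coated chain whose persistence length is larger
and whose contour is shorter, and reports the relative stretch decrease.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import integrate

from ._mc_kernels import bend_angles, reorder, run_chain

__all__ = [
    "Channel",
    "MCChain",
    "ExtensionEstimate",
    "MoveParams",
    "StretchChangeResult",
    "init_chain",
    "run",
    "mean_extension",
    "blocking_stderr",
    "stretch_change_experiment",
    "wlc_mean_square_ee",
    "mean_cos_quadratic",
    "discrete_chain_mean_square_ee",
]


@dataclass(frozen=True)
class Channel:
    """Rectangular channel cross-section (nm); unbounded along the axis (z)."""

    width_nm: float
    height_nm: float

    def __post_init__(self):
        if self.width_nm <= 0 or self.height_nm <= 0:
            raise ValueError("channel dimensions must be positive")


@dataclass
class MCChain:
    beads: np.ndarray  # (n, 3) nm
    segment_nm: float
    persistence_nm: float
    effective_width_nm: float = 0.0  # hard-core bead diameter; 0 = ideal chain

    def __post_init__(self):
        self.beads = np.ascontiguousarray(self.beads, dtype=float)
        if self.beads.ndim != 2 or self.beads.shape[1] != 3:
            raise ValueError("beads must be an (n, 3) array")
        if self.persistence_nm <= 0 or self.segment_nm <= 0:
            raise ValueError("persistence and segment length must be positive")
        bonds = np.linalg.norm(np.diff(self.beads, axis=0), axis=1)
        if np.any(np.abs(bonds - self.segment_nm) > 1e-9 * max(1.0, self.segment_nm)):
            raise ValueError("bond lengths must equal the segment length")

    @property
    def contour_nm(self) -> float:
        return self.segment_nm * (len(self.beads) - 1)

    @property
    def kappa(self) -> float:
        return self.persistence_nm / (2.0 * self.segment_nm)


@dataclass(frozen=True)
class MoveParams:
    crank_amp: float = 1.0  # rad
    pivot_amp: float = 0.3  # rad
    pivots_per_sweep: int = 10
    reptations_per_sweep: Optional[int] = None  # default: 4x the bead count
    max_span: int = 12  # crankshaft span in bonds
    tune_sweeps: Optional[int] = None  # default: first quarter


@dataclass(frozen=True)
class ExtensionEstimate:
    mean_extension_nm: float
    stderr_nm: float
    n_sweeps: int
    burn_in: int
    acceptance_crank: float
    acceptance_pivot: float
    stationary: bool


def _angle_sampler(kappa: float, n_grid: int = 4096):
    """Inverse-CDF sampler of the joint angle density sin(t) exp(-kappa t^2)."""
    t = np.linspace(0.0, np.pi, n_grid)
    pdf = np.sin(t) * np.exp(-kappa * t * t)
    cdf = np.cumsum(pdf)
    cdf /= cdf[-1]

    def sample(rng, size=None):
        return np.interp(rng.random(size), cdf, t)

    return sample


def init_chain(
    contour_nm: float,
    segment_nm: float,
    channel: Optional[Channel] = None,
    *,
    persistence_nm: float = 50.0,
    effective_width_nm: float = 0.0,
    init: str = "grow",
    seed: int = 0,
    max_retries: int = 200,
) -> MCChain:
    """Seed configuration of a confined bead-rod chain.

    ``init='straight'`` places the chain on the channel axis: always valid
    (no bending energy, no overlaps, inside the walls) but maximally
    stretched, so it needs a long burn-in.  ``init='grow'`` (default) grows
    the chain bead by bead, drawing each joint angle from the bending
    Boltzmann weight and redrawing (up to ``max_retries`` times per bead)
    when a wall or hard-core overlap is hit; this starts the Markov chain
    near a typical confined conformation.  If growth stalls the bead is
    re-grown from a backtracked position; persistent failure raises.
    """
    if segment_nm <= 0 or contour_nm < segment_nm:
        raise ValueError("need 0 < segment <= contour")
    if channel is not None and segment_nm >= min(channel.width_nm, channel.height_nm):
        raise ValueError("segment must be smaller than the channel cross-section")
    n_bonds = int(round(contour_nm / segment_nm))
    beads = np.zeros((n_bonds + 1, 3))
    if init == "straight":
        beads[:, 2] = np.arange(n_bonds + 1) * segment_nm
    elif init == "grow":
        rng = np.random.default_rng(seed)
        kappa = persistence_nm / (2.0 * segment_nm)
        draw = _angle_sampler(kappa)
        hw = channel.width_nm / 2.0 if channel is not None else np.inf
        hh = channel.height_nm / 2.0 if channel is not None else np.inf
        d2 = effective_width_nm**2
        t = np.array([0.0, 0.0, 1.0])
        beads[1] = beads[0] + segment_nm * t
        k = 2
        stalls = 0
        while k <= n_bonds:
            # orthonormal frame around the current tangent
            a = np.array([1.0, 0.0, 0.0]) if abs(t[2]) > 0.9 else np.array([0.0, 0.0, 1.0])
            e1 = np.cross(t, a)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(t, e1)
            placed = False
            for _ in range(max_retries):
                th = draw(rng)
                ph = rng.uniform(0.0, 2.0 * np.pi)
                t_new = (
                    np.cos(th) * t
                    + np.sin(th) * (np.cos(ph) * e1 + np.sin(ph) * e2)
                )
                p = beads[k - 1] + segment_nm * t_new
                if abs(p[0]) > hw or abs(p[1]) > hh:
                    continue
                if effective_width_nm > 0 and k >= 3:
                    prev = beads[: k - 1]
                    if np.min(np.einsum("ij,ij->i", prev - p, prev - p)) < d2:
                        continue
                placed = True
                break
            if placed:
                beads[k] = p
                t = t_new
                k += 1
            else:
                stalls += 1
                if stalls > 50 * n_bonds:
                    raise RuntimeError("chain growth failed; contour too long for the box")
                k = max(2, k - 5)  # backtrack and re-grow
                t = beads[k - 1] - beads[k - 2]
                t /= np.linalg.norm(t)
    else:
        raise ValueError(f"unknown init {init!r}")
    return MCChain(
        beads,
        segment_nm=segment_nm,
        persistence_nm=persistence_nm,
        effective_width_nm=effective_width_nm,
    )


def run(
    chain: MCChain,
    channel: Optional[Channel],
    n_sweeps: int,
    seed: int,
    move_params: Optional[MoveParams] = None,
    *,
    check_invariants: bool = False,
    warn_acceptance: bool = True,
    observable: str = "span",
) -> tuple[np.ndarray, dict]:
    """Sample the chain; returns the per-sweep extension trajectory.

    ``observable`` selects what "extension" means: ``"span"`` is the raw
    z-span of the bead coordinates; ``"moment"`` is sqrt(12 Var(z)), the
    length of the homogeneous rod with the same axial second moment (the
    identity also used for the imaging long axis), which is far less noisy
    because it does not ride on the dilute chain ends.

    The chain's bead array is updated in place to the final configuration.
    Amplitudes are auto-tuned during the tuning window (first quarter of the
    sweeps by default) and then held fixed.  With ``check_invariants`` the
    kernel is run sweep-by-sweep and bond lengths, wall compliance and (if
    enabled) excluded volume are asserted after every sweep.
    """
    col = {"span": 0, "moment": 1}[observable]
    mp = move_params or MoveParams()
    tune = mp.tune_sweeps if mp.tune_sweeps is not None else n_sweeps // 4
    confined = channel is not None
    half_w = channel.width_nm / 2.0 if confined else 0.0
    half_h = channel.height_nm / 2.0 if confined else 0.0
    pos = chain.beads
    n_beads = len(pos)
    n_rept = (
        mp.reptations_per_sweep if mp.reptations_per_sweep is not None else 4 * n_beads
    )
    # inverse CDF of the joint-angle Boltzmann density, for reptation proposals
    t_grid = np.linspace(0.0, np.pi, 4096)
    pdf = np.sin(t_grid) * np.exp(-chain.kappa * t_grid**2)
    cdf = np.cumsum(pdf)
    cdf /= cdf[-1]
    u_grid = np.linspace(0.0, 1.0, 1025)
    theta_cdf = np.interp(u_grid, cdf, t_grid)
    ss = np.random.SeedSequence(seed)

    head = 0

    def kernel(sweeps, tune_until, amps, sub_seed):
        return run_chain(
            pos,
            head,
            chain.segment_nm,
            chain.kappa,
            half_w,
            half_h,
            confined,
            chain.effective_width_nm,
            sweeps,
            tune_until,
            amps[0],
            amps[1],
            mp.pivots_per_sweep,
            n_rept,
            mp.max_span,
            theta_cdf,
            sub_seed,
        )

    amps = (mp.crank_amp, mp.pivot_amp)
    if not check_invariants:
        sub = int(ss.generate_state(1, np.uint32)[0]) & 0x7FFFFFFF
        ext, rate_c, rate_p, rate_r, a0, a1, head = kernel(n_sweeps, tune, amps, sub)
        ext = ext[:, col]
        amps = (a0, a1)
    else:
        subs = ss.generate_state(n_sweeps, np.uint32)
        ext = np.empty(n_sweeps)
        n_acc_c = n_acc_p = n_acc_r = 0.0
        for s in range(n_sweeps):
            e, rc, rp, rr, ca, pa, head = kernel(
                1, 1 if s < tune else 0, amps, int(subs[s]) & 0x7FFFFFFF
            )
            amps = (ca, pa)
            ext[s] = e[0, col]
            n_acc_c += rc
            n_acc_p += rp
            n_acc_r += rr
            chain.beads[:] = reorder(pos, head)
            head = 0
            _assert_state(chain, channel)
        rate_c = n_acc_c / n_sweeps
        rate_p = n_acc_p / n_sweeps
        rate_r = n_acc_r / n_sweeps
    chain.beads[:] = reorder(pos, head)
    info = {
        "acceptance_crank": float(rate_c),
        "acceptance_pivot": float(rate_p),
        "acceptance_reptation": float(rate_r),
        "crank_amp": float(amps[0]),
        "pivot_amp": float(amps[1]),
        "tune_sweeps": int(tune),
    }
    # high acceptance with the amplitude pinned at pi is fine (soft bending at
    # this discretization); warn only when tuning could not reach the window
    if warn_acceptance and (
        rate_c < 0.2 or (rate_c > 0.6 and amps[0] < 0.99 * np.pi)
    ):
        warnings.warn(
            f"crankshaft acceptance {rate_c:.2f} outside [0.2, 0.6] after tuning",
            stacklevel=2,
        )
    return ext, info


def _assert_state(chain: MCChain, channel: Optional[Channel]):
    bonds = np.linalg.norm(np.diff(chain.beads, axis=0), axis=1)
    assert np.all(np.abs(bonds - chain.segment_nm) < 1e-9 * max(1.0, chain.segment_nm)), (
        "bond length violated"
    )
    if channel is not None:
        assert np.all(np.abs(chain.beads[:, 0]) <= channel.width_nm / 2 + 1e-9), "x wall violated"
        assert np.all(np.abs(chain.beads[:, 1]) <= channel.height_nm / 2 + 1e-9), "y wall violated"
    if chain.effective_width_nm > 0:
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(chain.beads))
        n = len(chain.beads)
        ii, jj = np.triu_indices(n, k=2)
        assert np.all(d[ii, jj] >= chain.effective_width_nm - 1e-9), "excluded volume violated"


def blocking_stderr(x: np.ndarray, min_blocks: int = 16) -> float:
    """Standard error of the mean of a correlated series by blocking.

    The series is averaged over blocks of 2^k samples; the reported error is
    the largest naive SE over block sizes that still leave at least
    ``min_blocks`` blocks, i.e. the plateau of the blocking curve.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2 or np.allclose(x, x[0]):
        return 0.0
    best = 0.0
    size = 1
    while n // size >= min_blocks:
        nb = n // size
        blocks = x[: nb * size].reshape(nb, size).mean(axis=1)
        se = blocks.std(ddof=1) / math.sqrt(nb)
        best = max(best, se)
        size *= 2
    return best


def mean_extension(
    trajectory: np.ndarray, burn_in: Optional[int] = None, acceptance: Optional[dict] = None
) -> ExtensionEstimate:
    """Post-burn-in mean extension with a blocking standard error.

    ``burn_in`` defaults to the first quarter of the trajectory.  A
    stationarity check compares the two halves of the production segment and
    flags the estimate when they differ by more than 3 combined SE.
    """
    traj = np.asarray(trajectory, dtype=float)
    if burn_in is None:
        burn_in = len(traj) // 4
    if burn_in >= len(traj):
        raise ValueError("trajectory shorter than the burn-in")
    prod = traj[burn_in:]
    half = len(prod) // 2
    a, b = prod[:half], prod[half:]
    se_a, se_b = blocking_stderr(a), blocking_stderr(b)
    se_h = math.hypot(se_a, se_b)
    stationary = bool(se_h == 0.0 or abs(a.mean() - b.mean()) <= 3.0 * se_h)
    return ExtensionEstimate(
        mean_extension_nm=float(prod.mean()),
        stderr_nm=float(blocking_stderr(prod)),
        n_sweeps=len(traj),
        burn_in=int(burn_in),
        acceptance_crank=float((acceptance or {}).get("acceptance_crank", np.nan)),
        acceptance_pivot=float((acceptance or {}).get("acceptance_pivot", np.nan)),
        stationary=stationary,
    )


@dataclass(frozen=True)
class StretchChangeResult:
    decrease_pct: float
    stderr_pct: float
    bare_extension_nm: float
    bare_stderr_nm: float
    bound_extension_nm: float
    bound_stderr_nm: float
    per_seed_decrease_pct: np.ndarray
    inconclusive: bool


def stretch_change_experiment(
    channel: Channel,
    contour_nm: float,
    P_bare_nm: float,
    P_bound_nm: float,
    contour_reduction: float,
    seeds: Sequence[int],
    *,
    segment_nm: float = 5.0,
    n_sweeps: int = 6000,
    effective_width_nm: float = 5.0,
    move_params: Optional[MoveParams] = None,
) -> StretchChangeResult:
    """Relative stretch decrease from paired bare/bound confined-chain runs.

    For each seed a bare chain (P_bare, full contour) and a bound chain
    (P_bound, contour reduced by ``contour_reduction``) are simulated in the
    same channel; the result is 100 x (1 - <R_bound>/<R_bare>) with the
    blocking errors of both estimates propagated.  Excluded volume (hard-core
    diameter ``effective_width_nm``) is on by default: transverse confinement
    stretches a chain through self-avoidance, so an ideal chain would show
    almost no response of its axial span to the channel (see docs/methods.md).
    """
    if not 0.0 <= contour_reduction < 1.0:
        raise ValueError("contour_reduction must lie in [0, 1)")
    res_bare, res_bound, per_seed = [], [], []
    for sd in seeds:
        pair = []
        for P, L in (
            (P_bare_nm, contour_nm),
            (P_bound_nm, contour_nm * (1.0 - contour_reduction)),
        ):
            ch = init_chain(
                L,
                segment_nm,
                channel,
                persistence_nm=P,
                effective_width_nm=effective_width_nm,
                seed=sd,
            )
            traj, info = run(ch, channel, n_sweeps, seed=sd, move_params=move_params,
                             warn_acceptance=False)
            pair.append(mean_extension(traj, acceptance=info))
        res_bare.append(pair[0])
        res_bound.append(pair[1])
        per_seed.append(100.0 * (1.0 - pair[1].mean_extension_nm / pair[0].mean_extension_nm))

    mb = np.array([r.mean_extension_nm for r in res_bare])
    sb = np.array([r.stderr_nm for r in res_bare])
    mo = np.array([r.mean_extension_nm for r in res_bound])
    so = np.array([r.stderr_nm for r in res_bound])
    bare_mean = float(mb.mean())
    bound_mean = float(mo.mean())
    # combine within-run blocking errors with across-seed scatter
    bare_se = float(
        max(np.sqrt((sb**2).sum()) / len(sb),
            mb.std(ddof=1) / math.sqrt(len(mb)) if len(mb) > 1 else 0.0)
    )
    bound_se = float(
        max(np.sqrt((so**2).sum()) / len(so),
            mo.std(ddof=1) / math.sqrt(len(mo)) if len(mo) > 1 else 0.0)
    )
    ratio = bound_mean / bare_mean
    se_ratio = ratio * math.hypot(bare_se / bare_mean, bound_se / bound_mean)
    decrease = 100.0 * (1.0 - ratio)
    stderr = 100.0 * se_ratio
    return StretchChangeResult(
        decrease_pct=float(decrease),
        stderr_pct=float(stderr),
        bare_extension_nm=bare_mean,
        bare_stderr_nm=bare_se,
        bound_extension_nm=bound_mean,
        bound_stderr_nm=bound_se,
        per_seed_decrease_pct=np.asarray(per_seed),
        inconclusive=bool(abs(decrease) < 2.0 * stderr),
    )


# --- reference statistics ----------------------------------------------------


def wlc_mean_square_ee(contour_nm: float, P_nm: float) -> float:
    """Continuous WLC mean-square end-to-end distance 2PL - 2P^2(1 - e^(-L/P))."""
    L, P = contour_nm, P_nm
    return 2.0 * P * L - 2.0 * P**2 * (1.0 - math.exp(-L / P))


def mean_cos_quadratic(kappa: float) -> float:
    """<cos theta> of one joint under weight sin(theta) exp(-kappa theta^2)."""
    num, _ = integrate.quad(lambda t: math.cos(t) * math.sin(t) * math.exp(-kappa * t * t), 0, math.pi)
    den, _ = integrate.quad(lambda t: math.sin(t) * math.exp(-kappa * t * t), 0, math.pi)
    return num / den


def discrete_chain_mean_square_ee(n_bonds: int, segment_nm: float, mean_cos: float) -> float:
    """Exact <R_ee^2> of a chain with i.i.d. joint angles (freely rotating form)."""
    c = mean_cos
    n = n_bonds
    b2 = segment_nm**2
    return b2 * (n * (1 + c) / (1 - c) - 2 * c * (1 - c**n) / (1 - c) ** 2)


def effective_persistence(segment_nm: float, kappa: Optional[float] = None, P_nm: Optional[float] = None) -> float:
    """Persistence length of the discrete chain, -b / ln <cos theta>."""
    if kappa is None:
        kappa = P_nm / (2.0 * segment_nm)
    c = mean_cos_quadratic(kappa)
    return -segment_nm / math.log(c)
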