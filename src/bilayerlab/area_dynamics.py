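"""Area per lipid, equilibration windowing, and lateral diffusion from MSD.

Area per lipid is the lateral box area divided by the number of lipids in
one leaflet. Lateral diffusion follows the standard Einstein route: lipid
center-of-mass trajectories are unwrapped across the periodic boundaries,
the mean squared displacement (MSD) in the xy plane is averaged over all
time origins and lipids, and D_L is one quarter of the slope of a line fit
to the linear region of MSD(Δt). Error bars come from splitting the lipids
into equal subgroups (five by default), treating the per-subgroup MSDs as
independent measurements, and taking the steepest and gentlest straight
lines that pass within one standard error of the mean of every fitted
point.

A finite-size (periodic hydrodynamics) correction is not computed here;
``DiffusionEstimate.corrected`` applies an externally supplied
multiplicative factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import linprog

from .exceptions import DomainError
from .io_core import BilayerTopology, FrameSeries

logger = logging.getLogger(__name__)

#: nm^2/ns -> m^2/s
NM2_PER_NS_TO_M2_PER_S = 1e-9


@dataclass(frozen=True)
class AreaSeries:
    """Area per lipid (nm²) for each frame."""

    times: np.ndarray  # ps
    a_l: np.ndarray  # nm^2
    n_leaflet: int

    def __post_init__(self) -> None:
        if np.any(self.a_l <= 0):
            raise DomainError("area per lipid must be positive")
        if self.times.shape != self.a_l.shape:
            raise DomainError("times and a_l must have equal length")


@dataclass(frozen=True)
class AnalysisWindow:
    """A [t_start, t_end] ps interval of a trajectory, both ends inclusive."""

    t_start: float
    t_end: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise DomainError(f"empty window [{self.t_start}, {self.t_end}]")

    @property
    def equilibrated(self) -> bool:
        return self.label != "non-equilibrated"


@dataclass(frozen=True)
class MSDCurve:
    """Lateral MSD vs lag with subgroup standard errors.

    ``subgroup_msd`` has shape (n_lags, n_subgroups); ``sem`` is the per-lag
    standard error of the mean across subgroups.
    """

    lags: np.ndarray  # ns
    msd: np.ndarray  # nm^2
    sem: np.ndarray  # nm^2
    n_subgroups: int
    subgroup_msd: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.msd < 0):
            raise DomainError("MSD must be non-negative")
        if self.lags[0] == 0 and self.msd[0] != 0:
            raise DomainError("MSD at zero lag must be zero")
        if np.any(np.diff(self.lags) <= 0):
            raise DomainError("lags must ascend")


@dataclass(frozen=True)
class DiffusionEstimate:
    """Lateral diffusion coefficient with slope-band error bounds (m²/s)."""

    d: float
    d_low: float
    d_high: float
    fit_window: tuple[float, float]  # ns

    def __post_init__(self) -> None:
        if not (self.d_low <= self.d <= self.d_high):
            raise DomainError("require d_low <= d <= d_high")
        if self.d < 0:
            raise DomainError("d must be >= 0")

    def corrected(self, factor: float) -> "DiffusionEstimate":
        """Apply an externally supplied finite-size correction factor."""
        return replace(
            self,
            d=self.d * factor,
            d_low=self.d_low * factor,
            d_high=self.d_high * factor,
        )


# ---------------------------------------------------------------------------
# area per lipid and windows
# ---------------------------------------------------------------------------

def area_per_lipid(frames: FrameSeries, n_leaflet: int) -> AreaSeries:
    """A_L(t) = Lx(t)·Ly(t) / n_leaflet."""
    if n_leaflet <= 0:
        raise DomainError(f"n_leaflet must be > 0, got {n_leaflet}")
    a = frames.box[:, 0] * frames.box[:, 1] / n_leaflet
    return AreaSeries(times=frames.times.copy(), a_l=a, n_leaflet=n_leaflet)


def equilibration_window(
    series: AreaSeries, tolerance_sd: float = 1.0
) -> AnalysisWindow:
    """Detect the steady-state (equilibrated) part of an A_L time series.

    The last half of the series defines the reference mean and SD. The
    returned window starts at the earliest time from which every sliding
    window of length span/5 has a mean within ``tolerance_sd`` reference SDs
    of the reference mean. When no such start exists before 90% of the span
    the window label is "non-equilibrated" (and covers the last half).
    """
    n = series.times.size
    if n < 100:
        raise DomainError(f"need >= 100 frames for equilibration detection, got {n}")
    t = series.times
    a = series.a_l
    span = t[-1] - t[0]
    last_half = a[n // 2 :]
    ref_mean = float(last_half.mean())
    ref_sd = float(last_half.std(ddof=1))
    tiny = 1e-10 * max(1.0, abs(ref_mean))  # numerical floor for a constant tail
    if ref_sd <= tiny:
        if np.allclose(a, ref_mean, rtol=1e-9, atol=tiny):
            return AnalysisWindow(t[0], t[-1], "equilibrated")
        ref_sd = tiny  # any real deviation of the head counts as a violation
    w = max(2, n // 5)
    csum = np.concatenate([[0.0], np.cumsum(a)])
    roll = (csum[w:] - csum[:-w]) / w  # means of windows starting at 0..n-w
    bad = np.abs(roll - ref_mean) > tolerance_sd * ref_sd
    if not bad.any():
        start_idx = 0
    else:
        start_idx = int(np.nonzero(bad)[0][-1]) + 1
    if start_idx >= roll.size or t[start_idx] - t[0] >= 0.9 * span:
        return AnalysisWindow(t[n // 2], t[-1], "non-equilibrated")
    return AnalysisWindow(float(t[start_idx]), float(t[-1]), "equilibrated")


def windowed_analysis(frames: FrameSeries, window_length: float) -> list[AnalysisWindow]:
    """Split the trajectory span into contiguous windows of ``window_length`` ns.

    Windows are non-overlapping and cover the span from the first frame; a
    trailing remainder shorter than one window is dropped with a log
    message. This mirrors re-analyzing a non-stationary run as 10 × 100 ns
    parts.
    """
    if window_length <= 0:
        raise DomainError("window_length must be > 0")
    length_ps = window_length * 1000.0
    span = frames.span
    if length_ps > span * (1 + 1e-9):
        raise DomainError(
            f"window length {window_length} ns exceeds trajectory span {span / 1000} ns"
        )
    n_windows = int(np.floor(span / length_ps + 1e-9))
    t0 = frames.times[0]
    windows = [
        AnalysisWindow(t0 + i * length_ps, t0 + (i + 1) * length_ps, f"part{i + 1}")
        for i in range(n_windows)
    ]
    rem = span - n_windows * length_ps
    if rem > 1e-9:
        logger.info("dropping trailing %.3f ns remainder", rem / 1000.0)
    return windows


# ---------------------------------------------------------------------------
# COM trajectories and MSD
# ---------------------------------------------------------------------------

def unwrap_coordinates(frames: FrameSeries) -> np.ndarray:
    """Remove periodic jumps by minimal-image continuity between frames.

    Each atom's displacement between consecutive frames is shifted by the
    image vector that makes it smallest; displacements near half a box
    length are ambiguous and logged with their frame index.
    """
    coords = frames.coords
    out = np.empty_like(coords)
    out[0] = coords[0]
    for f in range(1, frames.n_frames):
        box = frames.box[f]
        d = coords[f] - coords[f - 1]
        d -= box * np.round(d / box)
        if np.any(np.abs(d) > 0.45 * box):
            logger.warning(
                "frame %d: displacement close to half the box; unwrapping may be ambiguous",
                f,
            )
        out[f] = out[f - 1] + d
    return out


def com_trajectories(
    frames: FrameSeries,
    topology: BilayerTopology,
    remove_system_com: bool = False,
) -> np.ndarray:
    """Unwrapped lipid center-of-mass xy paths, shape (n_frames, n_lipids, 2).

    Coordinates are unwrapped per atom, then mass-weighted per lipid. With
    ``remove_system_com`` the per-frame displacement of the all-lipid COM
    (relative to the first frame) is subtracted, cancelling any common
    drift; solvent is excluded from the COM.
    """
    lipid_ids = sorted({a.lipid_id for a in topology.atoms if a.lipid_id >= 0})
    if not lipid_ids:
        raise DomainError("topology contains no lipids")
    unwrapped = unwrap_coordinates(frames)
    masses = topology.masses()
    paths = np.empty((frames.n_frames, len(lipid_ids), 2))
    lipid_mass = np.empty(len(lipid_ids))
    for k, lid in enumerate(lipid_ids):
        idx = topology.atom_indices(lipid_id=lid)
        m = masses[idx]
        if m.sum() <= 0:
            raise DomainError(f"lipid {lid} has no mass-bearing atoms")
        lipid_mass[k] = m.sum()
        paths[:, k, :] = np.einsum("fij,i->fj", unwrapped[:, idx, :2], m) / m.sum()
    if remove_system_com:
        total = lipid_mass.sum()
        com = np.einsum("fkj,k->fj", paths, lipid_mass) / total
        paths = paths - (com - com[0])[:, None, :]
    return paths


def default_lag_grid(n_frames: int, dt_ns: float, n_lags: int = 40) -> np.ndarray:
    """Logarithmically spaced integer lags up to half the span, as ns."""
    max_lag = max(1, n_frames // 2)
    lags = np.unique(
        np.round(np.geomspace(1, max_lag, n_lags)).astype(int)
    )
    return np.concatenate([[0.0], lags * dt_ns])


def lateral_msd(
    paths: np.ndarray,
    times_ps: np.ndarray,
    lag_grid: Sequence[float] | None = None,
    n_subgroups: int = 5,
) -> MSDCurve:
    """Time-origin-averaged lateral MSD with subgroup standard errors.

    ``paths`` is (n_frames, n_lipids, 2) in nm; every admissible time origin
    contributes to each lag. Lipids are split (in order) into
    ``n_subgroups`` equal contiguous subgroups whose MSDs give the per-lag
    SEM. The lag grid is in ns and must align with the frame spacing.
    """
    n_frames, n_lipids, _ = paths.shape
    if n_lipids % n_subgroups != 0:
        raise DomainError(
            f"{n_lipids} lipids not divisible into {n_subgroups} equal subgroups"
        )
    dt_ns = float(times_ps[1] - times_ps[0]) / 1000.0 if n_frames > 1 else 1.0
    if lag_grid is None:
        lag_grid = default_lag_grid(n_frames, dt_ns)
    lags_ns = np.asarray(lag_grid, dtype=float)
    lag_steps = np.round(lags_ns / dt_ns).astype(int)
    if np.any(np.abs(lag_steps * dt_ns - lags_ns) > 1e-6 * max(dt_ns, 1e-12)):
        raise DomainError("lag grid must be integer multiples of the frame spacing")
    if np.any(lag_steps >= n_frames):
        raise DomainError("lag exceeds trajectory length")

    per_lipid = np.zeros((lags_ns.size, n_lipids))
    for i, m in enumerate(lag_steps):
        if m == 0:
            continue
        disp = paths[m:] - paths[:-m]  # (origins, lipids, 2)
        per_lipid[i] = np.mean(np.sum(disp * disp, axis=2), axis=0)

    group = per_lipid.reshape(lags_ns.size, n_subgroups, n_lipids // n_subgroups)
    subgroup_msd = group.mean(axis=2)  # (n_lags, n_subgroups)
    msd = per_lipid.mean(axis=1)
    sem = subgroup_msd.std(axis=1, ddof=1) / np.sqrt(n_subgroups)
    return MSDCurve(
        lags=lags_ns,
        msd=msd,
        sem=sem,
        n_subgroups=n_subgroups,
        subgroup_msd=subgroup_msd,
    )


def default_fit_window(curve: MSDCurve) -> tuple[float, float]:
    """Fit window for the linear MSD regime.

    Uses the 20–50 ns displacement-time range when the curve reaches it
    (the regime where lipid MSD is typically diffusive at these system
    sizes); otherwise falls back to [10%, 25%] of the effective span (twice
    the maximum lag).
    """
    max_lag = float(curve.lags[-1])
    if max_lag >= 50.0:
        return (20.0, 50.0)
    span = 2.0 * max_lag
    return (0.10 * span, 0.25 * span)


def _extreme_slope(x: np.ndarray, lo: np.ndarray, hi: np.ndarray, maximize: bool):
    """LP: extremize slope of s·x + b subject to lo_i <= s·x_i + b <= hi_i."""
    n = x.size
    a_ub = np.vstack([np.column_stack([x, np.ones(n)]), -np.column_stack([x, np.ones(n)])])
    b_ub = np.concatenate([hi, -lo])
    c = np.array([-1.0, 0.0]) if maximize else np.array([1.0, 0.0])
    res = linprog(c, A_ub=a_ub, b_ub=b_ub, bounds=[(None, None), (None, None)], method="highs")
    if not res.success:
        return None
    return float(res.x[0])


def fit_diffusion(
    curve: MSDCurve, fit_window: tuple[float, float] | None = None
) -> DiffusionEstimate:
    """D_L = slope/4 of a least-squares line on the windowed MSD.

    The error bounds are the steepest and gentlest slopes of straight lines
    passing within ±SEM of every windowed point (a linear program in slope
    and intercept); when no line fits through the band the bounds fall back
    to the least-squares slope ± its standard error, with a log message.
    Negative slopes clamp to zero.
    """
    if fit_window is None:
        fit_window = default_fit_window(curve)
    lo_ns, hi_ns = fit_window
    mask = (curve.lags >= lo_ns) & (curve.lags <= hi_ns)
    x = curve.lags[mask]
    if x.size < 3:
        raise DomainError(
            f"need >= 3 lags inside fit window [{lo_ns}, {hi_ns}] ns, got {x.size}"
        )
    y = curve.msd[mask]
    s = curve.sem[mask]

    slope, intercept = np.polyfit(x, y, 1)
    # standard error of the LS slope (fallback band)
    resid = y - (slope * x + intercept)
    dof = max(1, x.size - 2)
    sxx = float(np.sum((x - x.mean()) ** 2))
    slope_se = float(np.sqrt(np.sum(resid**2) / dof / sxx)) if sxx > 0 else 0.0

    s_max = _extreme_slope(x, y - s, y + s, maximize=True)
    s_min = _extreme_slope(x, y - s, y + s, maximize=False)
    if s_max is None or s_min is None:
        logger.info("no line fits within the SEM band; using slope ± fit SE")
        s_min, s_max = slope - slope_se, slope + slope_se

    to_si = 0.25 * NM2_PER_NS_TO_M2_PER_S
    d = max(0.0, slope * to_si)
    d_low = min(d, max(0.0, s_min * to_si))
    d_high = max(d, s_max * to_si)
    return DiffusionEstimate(d=d, d_low=d_low, d_high=d_high, fit_window=(lo_ns, hi_ns))
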