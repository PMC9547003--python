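"""Mean-square-displacement diffusion analysis.

For a trajectory X_1..X_N sampled at frame interval dt, the
time-averaged MSD over overlapping pairs is

    MSD(n) = sum_{i=1}^{N-n} (X_{i+n} - X_i)^2 / (N - n),   n = 1..N-1,

which for 1D Brownian motion with localization noise of SD sigma behaves
as MSD(tau) = 2·D·tau + 2·sigma². The diffusion coefficient is taken as
half the fitted slope (the 1D convention — see the methods note for why
the slope itself is not D), and the intercept measures localization
accuracy. The default fitting window is lag indices 3–10, which excludes
both the shortest lags (noise-dominated) and long lags (confinement by
the finite tether).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import signal, stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .structures import DIFFUSIVE, MSDResult, Trajectory

__all__ = [
    "compute_msd",
    "fit_msd",
    "MSDDiffusionEstimator",
    "convert_diffusion",
    "convert_diffusion_inverse",
    "localization_precision",
    "survey_speed",
    "compare_groups",
    "GroupComparison",
]


def _positions_and_dt(
    traj: Union[Trajectory, np.ndarray], frame_time: Optional[float]
) -> tuple[np.ndarray, float, Optional[np.ndarray]]:
    if isinstance(traj, Trajectory):
        x = traj.position_nm
        dt = traj.frame_time
        gap = traj.gap
        if len(traj) > 2:
            steps = np.diff(traj.time)
            if not np.allclose(steps, steps[0], rtol=1e-6) and gap is None:
                raise ValueError("non-uniform sampling without gap flags")
    else:
        x = np.asarray(traj, dtype=float).ravel()
        dt = frame_time
        gap = None
    if dt is None:
        raise ValueError("frame_time is required")
    return np.asarray(x, dtype=float), float(dt), gap


def compute_msd(
    traj: Union[Trajectory, np.ndarray],
    frame_time: Optional[float] = None,
) -> MSDResult:
    """Time-averaged MSD over overlapping pairs for every lag 1..N−1.

    Accepts a :class:`Trajectory` or a bare position array (nm) plus
    ``frame_time``. Frames flagged as bridged gaps are excluded
    pairwise: a pair contributes only when both endpoints were actually
    detected.
    """
    x, dt, gap = _positions_and_dt(traj, frame_time)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points for an MSD")
    valid = ~gap if gap is not None else np.ones(n, dtype=bool)
    lags = np.arange(1, n)
    msd = np.empty(n - 1)
    n_pairs = np.empty(n - 1, dtype=int)
    for j, lag in enumerate(lags):
        ok = valid[:-lag] & valid[lag:]
        n_pairs[j] = int(ok.sum())
        d = x[lag:] - x[:-lag]
        msd[j] = float(np.mean(d[ok] ** 2)) if n_pairs[j] else np.nan
    keep = n_pairs > 0
    return MSDResult(
        lags=lags[keep] * dt, msd=msd[keep], n_pairs=n_pairs[keep], frame_time=dt
    )


def fit_msd(
    msd: MSDResult,
    lag_window: tuple[int, int] = (3, 10),
    se_threshold_um2_s: float = 0.001,
    min_duration_s: float = 10.0,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> MSDResult:
    """Ordinary least-squares line through MSD(τ) over a lag-index window.

    ``lag_window`` is inclusive in lag indices (defaults 3–10, i.e.
    0.3–1.0 s at 10 Hz). Sets D = slope/2 (µm²/s and bp²/s), the offset
    b (nm²) and the slope standard error, plus the quality-control
    flags: trajectory duration above ``min_duration_s`` and slope SE
    below ``se_threshold_um2_s``.
    """
    lo, hi = lag_window
    dt = msd.frame_time
    idx = np.round(msd.lags / dt).astype(int)
    mask = (idx >= lo) & (idx <= hi)
    if mask.sum() < 3:
        raise ValueError(
            f"need >= 3 lags inside the window {lag_window}, got {int(mask.sum())}"
        )
    res = stats.linregress(msd.lags[mask], msd.msd[mask])
    slope_nm2_s = res.slope
    msd.D_um2_s = slope_nm2_s / 2.0 * 1e-6
    msd.D_bp2_s = convert_diffusion(msd.D_um2_s, constants)
    msd.offset_nm2 = float(res.intercept)
    msd.slope_se_um2_s = float(res.stderr) * 1e-6
    msd.D_se_um2_s = float(res.stderr) / 2.0 * 1e-6
    duration = (msd.n_pairs[0] + 1) * dt
    msd.qc_long_enough = bool(duration > min_duration_s)
    msd.qc_se_ok = bool(msd.slope_se_um2_s < se_threshold_um2_s)
    return msd


class MSDDiffusionEstimator(BaseEstimator):
    """Diffusion-coefficient estimator: MSD plus a lag-window line fit.

    scikit-learn style: ``fit(X)`` with X a 1D position series in nm (or
    a (n, 1) column); fitted attributes carry the diffusion coefficient
    in both unit systems, the offset, the slope SE and QC flags.

    Parameters
    ----------
    frame_time : float
        Frame interval in s.
    lag_min, lag_max : int
        Inclusive lag-index fitting window (default 3–10).
    bp_rise : float
        nm per base pair for the bp²/s conversion.
    se_threshold_um2_s : float
        QC bound on the slope standard error (µm²/s).
    min_duration_s : float
        QC bound on trajectory duration.
    """

    def __init__(
        self,
        frame_time: float = 0.1,
        lag_min: int = 3,
        lag_max: int = 10,
        bp_rise: float = DEFAULT_CONSTANTS.bp_rise,
        se_threshold_um2_s: float = 0.001,
        min_duration_s: float = 10.0,
    ):
        self.frame_time = frame_time
        self.lag_min = lag_min
        self.lag_max = lag_max
        self.bp_rise = bp_rise
        self.se_threshold_um2_s = se_threshold_um2_s
        self.min_duration_s = min_duration_s

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError("X must be a single 1D position series (nm)")
        constants = PhysicalConstants(bp_rise=self.bp_rise)
        result = compute_msd(X, frame_time=self.frame_time)
        fit_msd(
            result,
            lag_window=(self.lag_min, self.lag_max),
            se_threshold_um2_s=self.se_threshold_um2_s,
            min_duration_s=self.min_duration_s,
            constants=constants,
        )
        self.msd_result_ = result
        self.D_um2_s_ = result.D_um2_s
        self.D_bp2_s_ = result.D_bp2_s
        self.offset_nm2_ = result.offset_nm2
        self.slope_se_um2_s_ = result.slope_se_um2_s
        self.D_se_um2_s_ = result.D_se_um2_s
        self.qc_long_enough_ = result.qc_long_enough
        self.qc_se_ok_ = result.qc_se_ok
        return self

    def transform(self, X):
        """Fit each row of X (one trajectory per row) and return D (µm²/s)."""
        check_is_fitted(self, "D_um2_s_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.array(
            [type(self)(**self.get_params()).fit(row).D_um2_s_ for row in X]
        )


def convert_diffusion(
    D_um2_s: Union[float, np.ndarray],
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> Union[float, np.ndarray]:
    """µm²/s → bp²/s via the helical rise (0.021 µm²/s ↔ 0.18e6 bp²/s).

    Negative inputs pass through unchanged: an apparent D fitted from a
    static track may legitimately come out slightly negative.
    """
    D = np.asarray(D_um2_s, dtype=float)
    out = D * 1e6 / constants.bp_rise**2
    return float(out) if np.isscalar(D_um2_s) else out


def convert_diffusion_inverse(
    D_bp2_s: Union[float, np.ndarray],
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> Union[float, np.ndarray]:
    """bp²/s → µm²/s; exact inverse of :func:`convert_diffusion`."""
    D = np.asarray(D_bp2_s, dtype=float)
    out = D * constants.bp_rise**2 / 1e6
    return float(out) if np.isscalar(D_bp2_s) else out


def localization_precision(traj: Union[Trajectory, np.ndarray]) -> float:
    """Root-mean-square frame-to-frame displacement (nm) of a static track.

    For a junction-docked (static) molecule this measures the tracking
    precision: i.i.d. localization errors of SD σ give an RMS
    displacement of σ·√2. Warns when called on a diffusive trajectory,
    whose value is contaminated by real motion.
    """
    if isinstance(traj, Trajectory):
        if traj.states is not None and np.any(traj.states == DIFFUSIVE):
            warnings.warn(
                "trajectory contains diffusive segments; "
                "localization precision is contaminated by motion",
                stacklevel=2,
            )
        x = traj.position_nm
    else:
        x = np.asarray(traj, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 frames")
    return float(np.sqrt(np.mean(np.diff(x) ** 2)))


def survey_speed(
    traj: Union[Trajectory, np.ndarray],
    smooth_window_s: float = 1.0,
    poly_order: int = 2,
    frame_time: Optional[float] = None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """DNA survey speed (kbp/s): smoothed cumulative displacement over time.

    The trajectory is smoothed with a Savitzky–Golay filter
    (``smooth_window_s`` window, ``poly_order``) and the summed absolute
    frame-to-frame displacement is divided by the total time. Positions
    are taken in kbp when available, otherwise converted from nm via the
    helical rise.
    """
    if isinstance(traj, Trajectory):
        dt = traj.frame_time
        pos_kbp = (
            traj.position_kbp
            if traj.position_kbp is not None
            else traj.position_nm / (constants.bp_rise * 1000.0)
        )
    else:
        dt = frame_time
        pos_kbp = np.asarray(traj, dtype=float) / (constants.bp_rise * 1000.0)
    if dt is None:
        raise ValueError("frame_time is required")
    window = int(round(smooth_window_s / dt))
    if window % 2 == 0:
        window += 1
    if window < 3:
        raise ValueError("smoothing window shorter than 3 frames")
    if window > len(pos_kbp):
        raise ValueError("trajectory shorter than the smoothing window")
    smooth = signal.savgol_filter(pos_kbp, window, poly_order)
    total_time = (len(pos_kbp) - 1) * dt
    return float(np.sum(np.abs(np.diff(smooth))) / total_time)


@dataclass
class GroupComparison:
    """Welch two-sample comparison of diffusion-coefficient groups."""

    t: float
    p: float
    median_a: float
    median_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int


def compare_groups(group_a: np.ndarray, group_b: np.ndarray) -> GroupComparison:
    """Two-sided Welch t-test between two groups of diffusion coefficients.

    Also reports each group's median ± standard error of the mean, the
    summary used for per-condition diffusion distributions. Degenerate
    input (both groups with zero variance) raises.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 values")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("both groups have zero variance; t-test undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        t=float(res.statistic),
        p=float(res.pvalue),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        sem_a=float(stats.sem(a)),
        sem_b=float(stats.sem(b)),
        n_a=len(a),
        n_b=len(b),
    )
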