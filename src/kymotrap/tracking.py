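"""Kymograph particle tracking.

Locates the trapped beads, converts pixel to genomic coordinates,
localizes fluorescent spots at sub-pixel precision by 1D Gaussian
fitting of a 3-line moving window, links detections into trajectories,
segments trajectories into diffusive vs static states, and counts
photobleaching steps.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import optimize, signal, stats

from .structures import (
    DIFFUSIVE,
    STATIC,
    BeadGeometry,
    ForceTrace,
    Kymograph,
    Trajectory,
)

__all__ = [
    "find_beads",
    "to_genomic",
    "SpotFit",
    "localize_spot",
    "track",
    "segment_states",
    "count_bleach_steps",
    "intensity_profile",
    "downsample_kymograph",
    "downsample_force",
]


def _channel(kymo: Kymograph, channel: Optional[str]) -> np.ndarray:
    if channel is None:
        channel = "green" if "green" in kymo.counts else next(iter(kymo.counts))
    return kymo.counts[channel]


def find_beads(
    kymo: Kymograph,
    channel: Optional[str] = None,
    tether_length_kbp: Optional[float] = None,
    psf_sigma_nm: float = 150.0,
    saturation_fraction: float = 0.8,
) -> BeadGeometry:
    """Locate the two bead bands in the time-averaged scan profile.

    Bead centres are the centroids of the two outermost bands whose
    time-averaged counts exceed ``saturation_fraction`` × the saturation
    level (or × the profile maximum when no saturation level is
    recorded). Raises if fewer than two bands are found.
    """
    counts = _channel(kymo, channel)
    profile = counts.mean(axis=0)
    level = kymo.saturation_level if kymo.saturation_level else float(profile.max())
    mask = profile >= saturation_fraction * level
    if mask.sum() == 0:
        raise ValueError("no bead bands found (no saturated pixels)")
    # split mask into connected bands
    idx = np.flatnonzero(mask)
    splits = np.flatnonzero(np.diff(idx) > 1)
    bands = np.split(idx, splits + 1)
    if len(bands) < 2:
        raise ValueError(f"found {len(bands)} bead band(s); need two")
    left, right = bands[0], bands[-1]

    def centroid(band: np.ndarray) -> float:
        w = profile[band]
        return float(np.sum(band * w) / np.sum(w))

    meta = kymo.metadata or {}
    return BeadGeometry(
        left_center_px=centroid(left),
        right_center_px=centroid(right),
        bead_diameter_um=meta.get("bead_diameter_um", 4.5),
        tether_length_kbp=(
            tether_length_kbp
            if tether_length_kbp is not None
            else meta.get("tether_length_kbp", 15.0)
        ),
        pixel_size_nm=kymo.pixel_size,
        psf_sigma_nm=meta.get("psf_sigma_nm", psf_sigma_nm),
    )


def to_genomic(
    position_px: Union[float, np.ndarray],
    beads: BeadGeometry,
    mode: str = "surfaces",
) -> Union[float, np.ndarray]:
    """Convert a pixel position to a genomic coordinate (kbp).

    Linear interpolation along the tether: 0 kbp at the left reference,
    ``tether_length_kbp`` at the right. ``mode="surfaces"`` (default)
    anchors the interpolation at the inner bead surfaces (centre ±
    radius); ``mode="centers"`` uses the bead centres. Positions outside
    the tether raise.

    Note the map is linear in scan position, i.e. it ignores the
    force-dependent extension per base pair.
    """
    if mode == "surfaces":
        left, right = beads.left_surface_px, beads.right_surface_px
    elif mode == "centers":
        left, right = beads.left_center_px, beads.right_center_px
    else:
        raise ValueError("mode must be 'surfaces' or 'centers'")
    pos = np.asarray(position_px, dtype=float)
    tol = 1e-9 * max(1.0, right - left)
    if np.any(pos < left - tol) or np.any(pos > right + tol):
        raise ValueError(
            f"position {position_px} px outside the tether [{left:.2f}, {right:.2f}] px"
        )
    kbp = (pos - left) / (right - left) * beads.tether_length_kbp
    return float(kbp) if np.isscalar(position_px) else kbp


@dataclass
class SpotFit:
    """A sub-pixel Gaussian localization on one (3-line) window."""

    center_px: float
    amplitude: float
    width_px: float
    offset: float
    center_se_px: float


def _gaussian_const(px, amp, center, sigma, offset):
    return offset + amp * np.exp(-0.5 * ((px - center) / sigma) ** 2)


def localize_spot(
    counts: np.ndarray,
    line: int,
    guess_px: float,
    half_width: int = 5,
    width_bounds: tuple[float, float] = (0.5, 5.0),
    min_amplitude_snr: float = 2.0,
    background_sd: Optional[float] = None,
) -> Optional[SpotFit]:
    """Sub-pixel localization by Gaussian fitting of a 3-line window.

    Sums scan lines ``line-1 .. line+1`` and least-squares fits a
    Gaussian plus constant over ±``half_width`` pixels around
    ``guess_px``. Returns None (rejected) when the fitted width falls
    outside ``width_bounds`` or the amplitude is below
    ``min_amplitude_snr`` × the background noise SD; raises when the
    3-line window would cross the kymograph edge.
    """
    counts = np.asarray(counts, dtype=float)
    n_lines, n_px = counts.shape
    if line < 1 or line > n_lines - 2:
        raise ValueError(f"line {line} too close to the kymograph edge for a 3-line window")
    if not (0 <= guess_px < n_px):
        raise ValueError(f"guess {guess_px} px outside the field")
    window = counts[line - 1 : line + 2].sum(axis=0)
    lo = max(0, int(round(guess_px)) - half_width)
    hi = min(n_px, int(round(guess_px)) + half_width + 1)
    px = np.arange(lo, hi, dtype=float)
    y = window[lo:hi]
    if len(px) < 5:
        return None

    offset0 = float(np.min(y))
    amp0 = max(float(np.max(y) - offset0), 1e-6)
    p0 = (amp0, float(guess_px), 1.5, offset0)
    try:
        popt, pcov = optimize.curve_fit(
            _gaussian_const, px, y, p0=p0, method="lm", maxfev=400
        )
    except (RuntimeError, ValueError):
        return None
    amp, center, sigma, offset = popt
    sigma = abs(float(sigma))
    if amp < 0 or not (lo - 1.0 <= center <= hi):
        return None
    if not (width_bounds[0] <= sigma <= width_bounds[1]):
        return None
    if background_sd is None:
        # noise of the 3-line summed profile, from first differences
        diffs = np.diff(window)
        background_sd = float(
            stats.median_abs_deviation(diffs, scale="normal") / np.sqrt(2.0)
        )
    if amp < min_amplitude_snr * background_sd and background_sd > 0:
        return None
    center_se = float(np.sqrt(max(pcov[1, 1], 0.0)))
    return SpotFit(float(center), float(amp), float(sigma), float(offset), center_se)


@dataclass
class _ActiveTrack:
    lines: list
    positions_px: list
    amplitudes: list
    widths: list
    last_line: int


def _detect_lines(
    counts: np.ndarray,
    region: tuple[float, float],
    min_prominence_sd: float = 4.0,
    half_width: int = 5,
) -> dict[int, list[SpotFit]]:
    """Per-line spot detections inside the tracking region."""
    n_lines = counts.shape[0]
    lo = int(np.ceil(region[0]))
    hi = int(np.floor(region[1]))
    detections: dict[int, list[SpotFit]] = {}
    for i in range(1, n_lines - 1):
        window = counts[i - 1 : i + 2].sum(axis=0)
        sub = window[lo : hi + 1]
        if len(sub) < 3:
            continue
        noise = float(stats.median_abs_deviation(np.diff(sub), scale="normal") / np.sqrt(2.0))
        baseline = float(np.median(sub))
        peaks, _ = signal.find_peaks(
            sub, height=baseline + min_prominence_sd * max(noise, 1e-9), distance=4
        )
        fits = []
        for p in peaks:
            fit = localize_spot(counts, i, float(lo + p), half_width=half_width,
                                background_sd=noise)
            if fit is not None and region[0] <= fit.center_px <= region[1]:
                fits.append(fit)
        if fits:
            detections[i] = fits
    return detections


def track(
    kymo: Kymograph,
    channel: Optional[str] = None,
    beads: Optional[BeadGeometry] = None,
    max_step_nm: float = 1000.0,
    max_gap: int = 3,
    min_duration_s: float = 1.0,
    min_prominence_sd: float = 4.0,
    genomic_mode: str = "surfaces",
) -> list[Trajectory]:
    """Detect and link fluorescent particles into trajectories.

    Per-line detections (3-line moving window, Gaussian localization)
    are linked greedily to the nearest active trajectory within a
    per-frame displacement gate of ``max_step_nm`` (scaled by the gap
    length when frames are bridged); gaps up to ``max_gap`` frames are
    bridged by linear interpolation and flagged. Trajectories shorter
    than ``min_duration_s`` are discarded. An empty result is allowed.
    """
    counts = _channel(kymo, channel)
    if beads is None:
        beads = find_beads(kymo, channel=channel)
    region = beads.tracking_region_px
    detections = _detect_lines(counts, region, min_prominence_sd)

    gate_px = max_step_nm / kymo.pixel_size
    active: list[_ActiveTrack] = []
    closed: list[_ActiveTrack] = []
    for line in range(1, counts.shape[0] - 1):
        fits = detections.get(line, [])
        # close stale tracks
        still_active = []
        for tr in active:
            if line - tr.last_line > max_gap:
                closed.append(tr)
            else:
                still_active.append(tr)
        active = still_active

        # greedy nearest-neighbour assignment, shortest distances first
        pairs = []
        for fi, fit in enumerate(fits):
            for ti, tr in enumerate(active):
                gap = line - tr.last_line
                dist = abs(fit.center_px - tr.positions_px[-1])
                if dist <= gate_px * gap:
                    pairs.append((dist, fi, ti))
        pairs.sort(key=lambda p: p[0])
        used_fits: set[int] = set()
        used_tracks: set[int] = set()
        for dist, fi, ti in pairs:
            if fi in used_fits or ti in used_tracks:
                continue
            used_fits.add(fi)
            used_tracks.add(ti)
            tr = active[ti]
            fit = fits[fi]
            tr.lines.append(line)
            tr.positions_px.append(fit.center_px)
            tr.amplitudes.append(fit.amplitude)
            tr.widths.append(fit.width_px)
            tr.last_line = line
        for fi, fit in enumerate(fits):
            if fi not in used_fits:
                active.append(
                    _ActiveTrack([line], [fit.center_px], [fit.amplitude],
                                 [fit.width_px], line)
                )
    closed.extend(active)

    trajectories = []
    for tr in closed:
        lines = np.asarray(tr.lines)
        duration = (lines[-1] - lines[0]) * kymo.line_time
        if duration < min_duration_s:
            continue
        full_lines = np.arange(lines[0], lines[-1] + 1)
        pos_px = np.interp(full_lines, lines, np.asarray(tr.positions_px))
        amp = np.interp(full_lines, lines, np.asarray(tr.amplitudes))
        width = np.interp(full_lines, lines, np.asarray(tr.widths))
        gap = ~np.isin(full_lines, lines)
        pos_nm = (pos_px - beads.left_surface_px) * kymo.pixel_size
        try:
            pos_kbp = to_genomic(pos_px, beads, mode=genomic_mode)
        except ValueError:
            pos_kbp = None
        trajectories.append(
            Trajectory(
                time=full_lines * kymo.line_time,
                position_nm=pos_nm,
                position_kbp=pos_kbp,
                amplitude=amp,
                width_px=width,
                gap=gap,
                frame_time=kymo.line_time,
            )
        )
    trajectories.sort(key=lambda t: (t.time[0], t.position_nm[0]))
    return trajectories


def _local_diffusion(positions_nm: np.ndarray, dt: float, max_lag: int) -> float:
    """Local D (µm²/s) from an OLS line through MSD(lag 1..max_lag)."""
    n = len(positions_nm)
    lags = np.arange(1, min(max_lag, n - 2) + 1)
    if len(lags) < 2:
        return np.nan
    msd = np.array([np.mean((positions_nm[l:] - positions_nm[:-l]) ** 2) for l in lags])
    slope = np.polyfit(lags * dt, msd, 1)[0]  # nm²/s
    return slope / 2.0 * 1e-6


def segment_states(
    traj: Trajectory,
    window: int = 51,
    threshold_D: float = 0.001,
    min_segment_s: float = 1.0,
    max_lag: int = 8,
) -> Trajectory:
    """Label each frame of a trajectory diffusive or static.

    A rolling window of ``window`` frames around each point yields a
    local MSD-slope diffusion coefficient (intercept absorbed, so
    localization noise does not masquerade as motion); frames with local
    D below ``threshold_D`` (µm²/s; default the static detection limit
    0.001) are static. Segments shorter than ``min_segment_s`` are
    merged into their neighbours. A trajectory shorter than the window
    gets a single label from its global estimate.
    """
    n = len(traj)
    dt = traj.frame_time
    x = traj.position_nm
    if n <= window:
        d_global = _local_diffusion(x, dt, max_lag)
        label = STATIC if (np.isfinite(d_global) and d_global < threshold_D) else DIFFUSIVE
        traj.states = np.array([label] * n, dtype=object)
        return traj

    half = window // 2
    local_d = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, lo + window)
        lo = max(0, hi - window)
        local_d[i] = _local_diffusion(x[lo:hi], dt, max_lag)
    states = np.where(local_d < threshold_D, STATIC, DIFFUSIVE).astype(object)

    # merge segments shorter than min_segment_s into their neighbours
    min_frames = max(1, int(round(min_segment_s / dt)))
    changed = True
    while changed:
        changed = False
        bounds = np.flatnonzero(states[1:] != states[:-1]) + 1
        segments = np.split(np.arange(n), bounds)
        if len(segments) <= 1:
            break
        lengths = [len(s) for s in segments]
        shortest = int(np.argmin(lengths))
        if lengths[shortest] < min_frames:
            neighbour = shortest - 1 if shortest > 0 else shortest + 1
            states[segments[shortest]] = states[segments[neighbour][0]]
            changed = True
    traj.states = states
    return traj


def _binseg_splits(y: np.ndarray, penalty: float) -> list[int]:
    """Recursive binary segmentation of a piecewise-constant signal.

    Splits while the SSE reduction of the best split exceeds ``penalty``.
    Returns sorted change-point indices (start of the right segment).
    """

    def sse(seg: np.ndarray) -> float:
        return float(np.sum((seg - seg.mean()) ** 2)) if len(seg) else 0.0

    def best_split(lo: int, hi: int) -> tuple[Optional[int], float]:
        seg = y[lo:hi]
        n = len(seg)
        if n < 4:
            return None, 0.0
        total = sse(seg)
        csum = np.cumsum(seg)
        csq = np.cumsum(seg**2)
        ks = np.arange(2, n - 1)
        left_sse = csq[ks - 1] - csum[ks - 1] ** 2 / ks
        right_sum = csum[-1] - csum[ks - 1]
        right_sq = csq[-1] - csq[ks - 1]
        right_sse = right_sq - right_sum**2 / (n - ks)
        gains = total - (left_sse + right_sse)
        k = int(ks[np.argmax(gains)])
        return lo + k, float(np.max(gains))

    splits: list[int] = []
    stack = [(0, len(y))]
    while stack:
        lo, hi = stack.pop()
        k, gain = best_split(lo, hi)
        if k is not None and gain > penalty:
            splits.append(k)
            stack.append((lo, k))
            stack.append((k, hi))
    return sorted(splits)


def count_bleach_steps(
    intensity: np.ndarray,
    penalty: Optional[float] = None,
    min_step: Optional[float] = None,
) -> int:
    """Count downward photobleaching steps in an intensity series.

    Penalized binary-segmentation change-point detection on the series;
    downward level changes larger than half a single-fluorophore
    amplitude are counted as bleaching steps. The unit amplitude is
    ``min_step``×2 when given, otherwise the median magnitude of the
    detected downward changes. The penalty defaults to 3·σ²·log(n) with
    σ estimated robustly from first differences.
    """
    y = np.asarray(intensity, dtype=float)
    n = len(y)
    if n < 20:
        raise ValueError("need at least 20 frames to count bleaching steps")
    if penalty is None:
        sigma = float(stats.median_abs_deviation(np.diff(y), scale="normal") / np.sqrt(2.0))
        penalty = 3.0 * max(sigma, 1e-12) ** 2 * np.log(n)
    splits = _binseg_splits(y, penalty)
    if not splits:
        return 0
    edges = [0, *splits, n]
    levels = np.array([y[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
    drops = -np.diff(levels)
    downward = drops[drops > 0]
    if len(downward) == 0:
        return 0
    half_unit = min_step if min_step is not None else 0.5 * float(np.median(downward))
    return int(np.sum(downward >= half_unit))


def intensity_profile(
    kymo: Kymograph,
    time_window: tuple[float, float],
    channel: Optional[str] = None,
    beads: Optional[BeadGeometry] = None,
    min_prominence_sd: float = 5.0,
    genomic_mode: str = "surfaces",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cumulative per-pixel intensity over a time window, with peaks.

    Returns (profile, peak_positions_px, peak_positions_kbp): the
    per-pixel sum of counts over the window and the interior peaks
    (inside the tracking region) with their genomic positions. Used to
    confirm where a static, junction-docked enzyme sits on the DNA.
    """
    counts = _channel(kymo, channel)
    t0, t1 = time_window
    i0 = int(np.floor(t0 / kymo.line_time))
    i1 = int(np.ceil(t1 / kymo.line_time))
    i0 = max(0, i0)
    i1 = min(counts.shape[0], i1)
    if i1 <= i0:
        raise ValueError(f"empty time window {time_window}")
    profile = counts[i0:i1].sum(axis=0)
    if beads is None:
        beads = find_beads(kymo, channel=channel)
    lo, hi = beads.tracking_region_px
    lo_i, hi_i = int(np.ceil(lo)), int(np.floor(hi))
    sub = profile[lo_i : hi_i + 1]
    noise = float(stats.median_abs_deviation(np.diff(sub), scale="normal") / np.sqrt(2.0))
    baseline = float(np.median(sub))
    peaks, props = signal.find_peaks(
        sub, height=baseline + min_prominence_sd * max(noise, 1e-9), distance=4
    )
    # refine peak positions by local intensity-weighted centroid
    centers = []
    for p in peaks:
        a = max(0, p - 3)
        b = min(len(sub), p + 4)
        w = sub[a:b] - baseline
        w = np.clip(w, 0, None)
        centers.append(lo_i + (np.sum(np.arange(a, b) * w) / np.sum(w) if w.sum() else p))
    centers_arr = np.asarray(centers, dtype=float)
    kbp = (
        np.asarray(to_genomic(centers_arr, beads, mode=genomic_mode))
        if len(centers_arr)
        else np.array([])
    )
    return profile, centers_arr, kbp


def downsample_kymograph(kymo: Kymograph, factor: int) -> Kymograph:
    """Sum blocks of ``factor`` scan lines; timing metadata rescaled.

    Photon counts are conserved over the retained lines (a trailing
    partial block is dropped). Factor 1 returns an identical copy.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    n_lines = kymo.n_lines
    if factor > n_lines:
        raise ValueError(f"factor {factor} larger than the {n_lines}-line kymograph")
    n_blocks = n_lines // factor
    new_counts = {
        ch: arr[: n_blocks * factor].reshape(n_blocks, factor, -1).sum(axis=1)
        for ch, arr in kymo.counts.items()
    }
    return Kymograph(
        counts=new_counts,
        line_time=kymo.line_time * factor,
        pixel_size=kymo.pixel_size,
        saturation_level=(
            kymo.saturation_level * factor if kymo.saturation_level else None
        ),
        force=kymo.force,
        metadata=dict(kymo.metadata, downsample_factor=factor),
    )


def downsample_force(
    trace: ForceTrace,
    factor: Optional[int] = None,
    target_rate: Optional[float] = None,
) -> ForceTrace:
    """Block-average a force trace by ``factor`` or to ``target_rate`` Hz."""
    if factor is None:
        if target_rate is None:
            raise ValueError("give either factor or target_rate")
        factor = int(round(trace.sample_rate / target_rate))
    if factor < 1:
        raise ValueError("factor must be >= 1")
    n = len(trace.force)
    if factor > n:
        raise ValueError(f"factor {factor} larger than the {n}-sample trace")
    n_blocks = n // factor
    f = trace.force[: n_blocks * factor].reshape(n_blocks, factor).mean(axis=1)
    t = trace.time[: n_blocks * factor].reshape(n_blocks, factor).mean(axis=1)
    return ForceTrace(time=t, force=f, setpoint=trace.setpoint)
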