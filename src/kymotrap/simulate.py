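"""Instrument-faithful synthetic data with known ground truth.

Everything downstream (eWLC fitting, tracking, MSD, kinetics) is validated
by parameter recovery on the outputs of this module. Every generator is a
pure function of (parameters, seed): identical seeds give bit-identical
output.

The emulated instrument is a dual-trap optical tweezers with confocal
line scanning: a ~15 kbp DNA tether held between two 4.5 µm beads, scanned
along its axis to produce kymographs; force-extension records acquired at
a constant pulling rate; force-clamp traces in which DNA cleavage appears
as a drop to zero force.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .force import ewlc_extension
from .structures import (
    EWLCParams,
    ForceExtensionCurve,
    ForceTrace,
    Kymograph,
    DwellTimeSet,
)

__all__ = [
    "SyntheticSceneConfig",
    "RuptureSpec",
    "make_diffusion_track",
    "render_kymograph",
    "make_force_extension",
    "make_dwell_times",
    "make_force_clamp",
]


@dataclass
class RuptureSpec:
    """Force-triggered unfolding/refolding of the central four-way junction.

    The junction unfolds when the stretch first reaches a rupture force
    drawn from N(mean_unfold_force, sd_unfold_force²) and refolds during
    relaxation below a force drawn from N(mean_refold_force,
    sd_refold_force²); hysteresis requires the former above the latter.
    The contour-length gain on unzipping the two hairpins is drawn from
    N(delta_lc_true, sd_delta_lc²).
    """

    mean_unfold_force: float = 23.0  # pN
    sd_unfold_force: float = 0.0
    mean_refold_force: float = 14.0  # pN
    sd_refold_force: float = 0.0
    delta_lc_true: float = 9.5  # nm
    sd_delta_lc: float = 0.0

    def __post_init__(self) -> None:
        if not (self.mean_unfold_force > self.mean_refold_force):
            raise ValueError("hysteresis requires mean_unfold_force > mean_refold_force")
        if min(self.sd_unfold_force, self.sd_refold_force, self.sd_delta_lc) < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass
class SyntheticSceneConfig:
    """Geometry, optics and photophysics of a synthetic kymograph scene.

    Lengths in nm unless suffixed otherwise. The tether spans the region
    between the two bead surfaces; emitter positions are given in nm from
    the left bead surface. Defaults emulate the study conditions: 10 Hz
    line rate, 100 nm pixels, a 15 kbp tether extended to ~4.7 µm at the
    5 pN imaging force, 4.5 µm beads, and a dimeric emitter that bleaches
    in two equal steps.
    """

    seed: int = 0
    duration: float = 60.0  # s
    line_time: float = 0.1  # s
    pixel_size: float = 100.0  # nm
    n_pixels: int = 140
    D_true: float = 0.02  # µm²/s
    junction_position_kbp: Optional[float] = 7.5
    psf_sigma: float = 150.0  # nm
    peak_counts: float = 100.0  # photons/line at the profile peak
    background: float = 2.0  # photons/pixel/line
    bead_diameter_um: float = 4.5
    bleach_step_count: int = 2
    bleach_rate: float = 0.01  # per-fluorophore, s⁻¹
    tether_length_kbp: float = 15.0
    tether_extension_nm: float = 4700.0
    saturation_level: float = 1000.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required for any stochastic call")
        for name in ("line_time", "pixel_size", "psf_sigma", "peak_counts", "duration"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")
        if self.background < 0:
            raise ValueError("background must be non-negative")
        if self.junction_position_kbp is not None and not (
            0 <= self.junction_position_kbp <= self.tether_length_kbp
        ):
            raise ValueError("junction_position must lie within the tether length")
        if self.right_bead_center_px + self.bead_radius_px > self.n_pixels:
            raise ValueError(
                "field too small: increase n_pixels to fit beads and tether "
                f"(need ≥ {int(np.ceil(self.right_bead_center_px + self.bead_radius_px))})"
            )

    # --- derived geometry -------------------------------------------------
    @property
    def n_lines(self) -> int:
        return int(round(self.duration / self.line_time))

    @property
    def bead_radius_px(self) -> float:
        return self.bead_diameter_um * 1000.0 / 2.0 / self.pixel_size

    @property
    def left_bead_center_px(self) -> float:
        return self.bead_radius_px

    @property
    def left_surface_px(self) -> float:
        return self.left_bead_center_px + self.bead_radius_px

    @property
    def right_surface_px(self) -> float:
        return self.left_surface_px + self.tether_extension_nm / self.pixel_size

    @property
    def right_bead_center_px(self) -> float:
        return self.right_surface_px + self.bead_radius_px

    @property
    def tether_span_nm(self) -> float:
        return self.tether_extension_nm

    def kbp_to_nm(self, kbp: float) -> float:
        """Genomic position (kbp) to nm from the left bead surface."""
        return kbp / self.tether_length_kbp * self.tether_span_nm


def _check_finite_positive(value: float, name: str) -> None:
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be finite and positive, got {value}")


def make_diffusion_track(
    D: float,
    dt: float,
    duration: float,
    x0: float = 0.0,
    bounds: Optional[tuple[float, float]] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Simulate 1D Brownian motion of an emitter along the tether.

    Parameters
    ----------
    D : float
        Diffusion coefficient in µm²/s (0 gives a static emitter).
    dt, duration : float
        Frame interval and total duration in s.
    x0 : float
        Initial position in nm.
    bounds : (low, high) in nm, optional
        Reflecting boundaries (the tether has finite length).

    Returns
    -------
    ndarray of length duration/dt + 1, positions in nm.
    """
    _check_finite_positive(dt, "dt")
    _check_finite_positive(duration, "duration")
    if not np.isfinite(D) or D < 0:
        raise ValueError(f"D must be finite and non-negative, got {D}")
    if bounds is not None:
        lo, hi = bounds
        if not (lo < hi):
            raise ValueError("bounds must satisfy low < high")
        if not (lo <= x0 <= hi):
            raise ValueError("x0 must lie within bounds")
    n_steps = int(round(duration / dt))
    if D == 0:
        return np.full(n_steps + 1, float(x0))
    if rng is None:
        rng = np.random.default_rng(seed)
    # 2·D·dt variance per step; D in µm²/s → nm²: ×1e6
    step_sd = np.sqrt(2.0 * D * 1e6 * dt)
    raw = x0 + np.concatenate([[0.0], np.cumsum(rng.normal(0.0, step_sd, n_steps))])
    if bounds is None:
        return raw
    lo, hi = bounds
    span = hi - lo
    # reflect by folding onto a triangle wave of period 2·span
    m = np.mod(raw - lo, 2.0 * span)
    return lo + np.where(m <= span, m, 2.0 * span - m)


def _bleach_schedule(
    n_lines: int,
    line_time: float,
    n_steps: int,
    bleach_rate: float,
    peak_counts: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-line emitter peak amplitude under step-wise photobleaching.

    ``n_steps`` fluorophores each carry peak_counts/n_steps of amplitude
    and bleach independently after an exponential lifetime; n_steps = 0
    disables bleaching (constant amplitude).
    """
    if n_steps <= 0:
        return np.full(n_lines, peak_counts)
    t = np.arange(n_lines) * line_time
    lifetimes = rng.exponential(1.0 / bleach_rate, n_steps)
    active = (t[:, None] < lifetimes[None, :]).sum(axis=1)
    return peak_counts * active / n_steps


def render_kymograph(
    tracks: Sequence[np.ndarray],
    config: SyntheticSceneConfig,
    poisson: bool = True,
    render_beads: bool = True,
    bleach: bool = True,
    rng: Optional[np.random.Generator] = None,
) -> Kymograph:
    """Render emitter tracks into a photon-count kymograph.

    Each track is a position series in nm from the left bead surface,
    one sample per scan line. Per line, each emitter contributes a
    Gaussian profile of width ``psf_sigma`` with a peak amplitude that
    follows its photobleaching schedule; ``background`` photons/pixel are
    added everywhere and counts are Poisson-sampled unless ``poisson`` is
    False. Saturated bands mark both beads. Tracks longer than the
    kymograph are truncated with a warning.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_lines, n_px = config.n_lines, config.n_pixels
    sigma_px = config.psf_sigma / config.pixel_size
    px = np.arange(n_px, dtype=float)

    expected = np.full((n_lines, n_px), float(config.background))
    amplitudes = []
    for track in tracks:
        track = np.asarray(track, dtype=float)
        if len(track) > n_lines:
            warnings.warn(
                f"track of {len(track)} samples truncated to {n_lines} kymograph lines",
                stacklevel=2,
            )
            track = track[:n_lines]
        amp = _bleach_schedule(
            len(track), config.line_time,
            config.bleach_step_count if bleach else 0,
            config.bleach_rate, config.peak_counts, rng,
        )
        amplitudes.append(amp)
        centers_px = config.left_surface_px + track / config.pixel_size
        profile = np.exp(
            -0.5 * ((px[None, :] - centers_px[:, None]) / sigma_px) ** 2
        )
        expected[: len(track)] += amp[:, None] * profile

    counts = rng.poisson(expected).astype(float) if poisson else expected
    if render_beads:
        for center in (config.left_bead_center_px, config.right_bead_center_px):
            band = np.abs(px - center) <= config.bead_radius_px
            counts[:, band] = config.saturation_level

    return Kymograph(
        counts={"green": counts},
        line_time=config.line_time,
        pixel_size=config.pixel_size,
        saturation_level=config.saturation_level,
        metadata={
            "tracks_nm": [np.asarray(t, dtype=float)[:n_lines] for t in tracks],
            "amplitudes": amplitudes,
            "bead_centers_px": (config.left_bead_center_px, config.right_bead_center_px),
            "bead_diameter_um": config.bead_diameter_um,
            "tether_length_kbp": config.tether_length_kbp,
            "psf_sigma_nm": config.psf_sigma,
            "seed": config.seed,
        },
    )


def _draw_positive(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Draw from N(mean, sd²), redrawing until the value is positive."""
    if sd == 0:
        if mean <= 0:
            raise ValueError("degenerate draw with non-positive mean")
        return mean
    for _ in range(1000):
        value = rng.normal(mean, sd)
        if value > 0:
            return value
    raise RuntimeError("could not draw a positive value in 1000 attempts")


def make_force_extension(
    ewlc: EWLCParams,
    rupture: Optional[RuptureSpec] = None,
    pulling_rate: float = 0.2,
    sample_rate: float = 60.0,
    noise_sd: float = 0.0,
    f_min: float = 0.5,
    f_max: float = 50.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> tuple[ForceExtensionCurve, ForceExtensionCurve]:
    """Generate a stretch/relax force-extension cycle of the tether.

    The stretch follows the eWLC with contour length Lc below the drawn
    rupture force and Lc + ΔLc above it; the relax curve switches back to
    the folded branch below the drawn refold force. Gaussian noise of SD
    ``noise_sd`` (pN) is added to the measured force. The force is swept
    on a uniform grid from ``f_min`` to ``f_max``; timestamps follow from
    the extension change at the given pulling rate.

    Returns the (stretch, relax) pair.
    """
    _check_finite_positive(pulling_rate, "pulling_rate")
    _check_finite_positive(sample_rate, "sample_rate")
    if rng is None:
        rng = np.random.default_rng(seed)

    if rupture is not None:
        for _ in range(1000):
            f_unfold = _draw_positive(rng, rupture.mean_unfold_force, rupture.sd_unfold_force)
            f_refold = _draw_positive(rng, rupture.mean_refold_force, rupture.sd_refold_force)
            if f_refold < f_unfold:
                break
        else:  # pragma: no cover
            raise RuntimeError("could not draw hysteretic rupture/refold forces")
        delta_lc = max(0.0, rng.normal(rupture.delta_lc_true, rupture.sd_delta_lc)
                       if rupture.sd_delta_lc > 0 else rupture.delta_lc_true)
    else:
        f_unfold = np.inf
        f_refold = -np.inf
        delta_lc = 0.0

    lc_folded, lc_unfolded = ewlc.Lc, ewlc.Lc + delta_lc
    span_nm = ewlc_extension(f_max, ewlc.Lp, lc_unfolded, ewlc.S, constants) - ewlc_extension(
        f_min, ewlc.Lp, lc_folded, ewlc.S, constants
    )
    n = max(2, int(round(span_nm / (pulling_rate * 1000.0) * sample_rate)))
    force_grid = np.linspace(f_min, f_max, n)

    def branch_extension(forces: np.ndarray, unfolded_mask: np.ndarray) -> np.ndarray:
        x = ewlc_extension(forces, ewlc.Lp, lc_folded, ewlc.S, constants)
        if np.any(unfolded_mask):
            x = np.where(
                unfolded_mask,
                ewlc_extension(forces, ewlc.Lp, lc_unfolded, ewlc.S, constants),
                x,
            )
        return x

    def times_from_extension(x: np.ndarray) -> np.ndarray:
        dt = np.abs(np.diff(x)) / (pulling_rate * 1000.0)
        # strictly increasing even across zero-length steps
        dt = np.maximum(dt, 1e-9)
        return np.concatenate([[0.0], np.cumsum(dt)])

    def noisy(forces: np.ndarray) -> np.ndarray:
        return forces + rng.normal(0.0, noise_sd, len(forces)) if noise_sd > 0 else forces

    truth = {
        "F_unfold": None if not np.isfinite(f_unfold) else float(f_unfold),
        "F_refold": None if not np.isfinite(f_refold) else float(f_refold),
        "delta_Lc": float(delta_lc),
    }
    x_stretch = branch_extension(force_grid, force_grid >= f_unfold)
    stretch = ForceExtensionCurve(
        extension=x_stretch,
        force=noisy(force_grid),
        time=times_from_extension(x_stretch),
        direction="stretch",
        pulling_rate=pulling_rate,
        sample_rate=sample_rate,
    )

    relax_grid = force_grid[::-1]
    # the junction only refolds if it unfolded during the stretch
    unfolded_relax = relax_grid >= f_refold if f_unfold <= f_max else np.zeros(n, bool)
    x_relax = branch_extension(relax_grid, unfolded_relax)
    relax = ForceExtensionCurve(
        extension=x_relax,
        force=noisy(relax_grid),
        time=times_from_extension(x_relax),
        direction="relax",
        pulling_rate=pulling_rate,
        sample_rate=sample_rate,
    )
    # drawn ground truth, for parameter-recovery studies
    stretch.ground_truth = truth
    relax.ground_truth = truth
    return stretch, relax


def make_dwell_times(
    k0: float,
    dx: float,
    F: float,
    n: int,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> DwellTimeSet:
    """Draw cleavage dwell times at clamp force F from a Bell-Evans rate.

    Dwells are exponential with rate k(F) = k0·exp(−F·dx/kBT); dx is the
    activation length in nm (≥ 0: tension hinders cleavage).
    """
    if not (k0 > 0):
        raise ValueError("k0 must be positive")
    if dx < 0:
        raise ValueError("activation length dx must be non-negative")
    if n < 1:
        raise ValueError("n must be at least 1")
    if F < 0:
        raise ValueError("force must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    rate = k0 * np.exp(-F * dx / constants.kBT)
    return DwellTimeSet(dwells=rng.exponential(1.0 / rate, n), force=F)


def make_force_clamp(
    setpoint: float,
    t_cleave: float,
    duration: float,
    sample_rate: float = 60.0,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> ForceTrace:
    """Generate a force-clamp trace with a cleavage-induced drop to zero.

    The force sits at ``setpoint`` (plus Gaussian noise) until
    ``t_cleave`` and at zero afterwards; ``t_cleave = duration`` gives a
    trace that never drops.
    """
    if setpoint < 0:
        raise ValueError("setpoint must be non-negative")
    if not (0 <= t_cleave <= duration):
        raise ValueError("t_cleave must lie within [0, duration]")
    _check_finite_positive(sample_rate, "sample_rate")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    force = np.where(t < t_cleave, float(setpoint), 0.0)
    if noise_sd > 0:
        force = force + rng.normal(0.0, noise_sd, n)
    return ForceTrace(time=t, force=force, setpoint=setpoint)
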