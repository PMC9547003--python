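"""Core data containers shared by the generator and analysis modules."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class EWLCParams:
    """Extensible worm-like chain parameters with standard errors.

    Lp : persistence length (nm); Lc : contour length (nm);
    S : stretch modulus (pN). Errors are least-squares standard errors,
    zero for parameters that were held fixed during fitting.
    """

    Lp: float
    Lc: float
    S: float
    Lp_se: float = 0.0
    Lc_se: float = 0.0
    S_se: float = 0.0
    fit_range: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not (self.Lp > 0 and self.Lc > 0 and self.S > 0):
            raise ValueError(
                f"Lp, Lc, S must be positive (got {self.Lp}, {self.Lc}, {self.S})"
            )
        if min(self.Lp_se, self.Lc_se, self.S_se) < 0:
            raise ValueError("standard errors must be non-negative")


@dataclass
class ForceExtensionCurve:
    """Paired force/extension samples from a single pull or relaxation.

    extension in nm, force in pN, time in s; ``direction`` is "stretch"
    or "relax"; pulling_rate in µm/s and sample_rate in Hz describe how
    the record was acquired.
    """

    extension: np.ndarray
    force: np.ndarray
    time: np.ndarray
    direction: str = "stretch"
    pulling_rate: float = 0.2
    sample_rate: float = 60.0

    def __post_init__(self) -> None:
        self.extension = np.asarray(self.extension, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        n = len(self.extension)
        if len(self.force) != n or len(self.time) != n:
            raise ValueError("extension, force and time must have equal length")
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.force)):
            raise ValueError("forces must be finite")
        if self.direction not in ("stretch", "relax"):
            raise ValueError(f"direction must be 'stretch' or 'relax', got {self.direction!r}")

    def __len__(self) -> int:
        return len(self.force)


@dataclass
class UnfoldingEvent:
    """A detected junction unfolding (and optionally refolding) event."""

    F_unfold: float
    F_refold: Optional[float] = None
    delta_Lc: Optional[float] = None
    delta_Lc_se: Optional[float] = None
    dG_area: Optional[float] = None
    transition: Optional[tuple[int, int]] = None  # sample indices bracketing the jump

    def __post_init__(self) -> None:
        if not (self.F_unfold > 0):
            raise ValueError("F_unfold must be positive")
        if self.delta_Lc is not None and self.delta_Lc < 0:
            raise ValueError("delta_Lc must be non-negative")
        if self.F_refold is not None and not (self.F_refold < self.F_unfold):
            raise ValueError("F_refold must be below F_unfold (hysteresis)")


@dataclass
class ForceTrace:
    """A force-clamp recording: time (s) and force (pN)."""

    time: np.ndarray
    force: np.ndarray
    setpoint: Optional[float] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if len(self.time) != len(self.force):
            raise ValueError("time and force must have equal length")

    @property
    def sample_rate(self) -> float:
        if len(self.time) < 2:
            raise ValueError("need at least two samples to infer the sample rate")
        return 1.0 / float(np.median(np.diff(self.time)))


@dataclass
class Kymograph:
    """Scan-line × pixel photon-count matrices, one per colour channel.

    ``counts`` maps channel name ("green", "red") to a (n_lines, n_pixels)
    array; ``line_time`` in s, ``pixel_size`` in nm. ``force`` optionally
    carries a synchronized force-clamp trace. ``metadata`` is free-form and
    holds generator ground truth for synthetic scenes.
    """

    counts: dict[str, np.ndarray]
    line_time: float
    pixel_size: float
    saturation_level: Optional[float] = None
    force: Optional[ForceTrace] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("at least one channel is required")
        shapes = {ch: np.asarray(arr).shape for ch, arr in self.counts.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"all channels must share a shape, got {shapes}")
        for ch, arr in self.counts.items():
            arr = np.asarray(arr)
            if arr.ndim != 2:
                raise ValueError(f"channel {ch!r} must be 2D (lines × pixels)")
            if np.any(arr < 0):
                raise ValueError(f"channel {ch!r} has negative counts")
            self.counts[ch] = arr
        if not (self.line_time > 0 and self.pixel_size > 0):
            raise ValueError("line_time and pixel_size must be positive")

    @property
    def n_lines(self) -> int:
        return next(iter(self.counts.values())).shape[0]

    @property
    def n_pixels(self) -> int:
        return next(iter(self.counts.values())).shape[1]

    @property
    def duration(self) -> float:
        return self.n_lines * self.line_time


@dataclass
class BeadGeometry:
    """Bead centres (fractional pixels) and tether geometry on a kymograph."""

    left_center_px: float
    right_center_px: float
    bead_diameter_um: float
    tether_length_kbp: float
    pixel_size_nm: float
    psf_sigma_nm: float = 150.0

    def __post_init__(self) -> None:
        if not (self.left_center_px < self.right_center_px):
            raise ValueError("left bead centre must be left of the right bead centre")

    @property
    def radius_px(self) -> float:
        return self.bead_diameter_um * 1000.0 / 2.0 / self.pixel_size_nm

    @property
    def left_surface_px(self) -> float:
        return self.left_center_px + self.radius_px

    @property
    def right_surface_px(self) -> float:
        return self.right_center_px - self.radius_px

    @property
    def tracking_region_px(self) -> tuple[float, float]:
        """Inter-bead region minus 2×PSF on each side, where spots are fitted."""
        margin = 2.0 * self.psf_sigma_nm / self.pixel_size_nm
        return (self.left_surface_px + margin, self.right_surface_px - margin)


#: segment-state labels
DIFFUSIVE = "diffusive"
STATIC = "static"


@dataclass
class Trajectory:
    """A linked single-particle trajectory on a kymograph.

    Positions are stored both in the lab frame (nm from the left bead
    surface) and, when bead geometry is known, in genomic coordinates
    (kbp). ``gap`` flags frames that were bridged by interpolation rather
    than detected. ``states`` labels each frame "diffusive" or "static"
    once :func:`segment_states` has run.
    """

    time: np.ndarray
    position_nm: np.ndarray
    position_kbp: Optional[np.ndarray] = None
    amplitude: Optional[np.ndarray] = None
    width_px: Optional[np.ndarray] = None
    gap: Optional[np.ndarray] = None
    states: Optional[np.ndarray] = None
    frame_time: Optional[float] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.position_nm = np.asarray(self.position_nm, dtype=float)
        if len(self.time) != len(self.position_nm):
            raise ValueError("time and position must have equal length")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if self.gap is None:
            self.gap = np.zeros(len(self.time), dtype=bool)
        if self.frame_time is None and len(self.time) > 1:
            self.frame_time = float(np.median(np.diff(self.time)))

    def __len__(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) if len(self) > 1 else 0.0


@dataclass
class MSDResult:
    """Time-averaged MSD curve and, after fitting, the diffusion estimate.

    lags in s, msd in nm², n_pairs the number of overlapping pairs per
    lag. D is reported in µm²/s and bp²/s (slope/2 convention, see the
    methods note); offset b in nm² reflects localization accuracy.
    """

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray
    frame_time: float
    D_um2_s: Optional[float] = None
    D_bp2_s: Optional[float] = None
    offset_nm2: Optional[float] = None
    slope_se_um2_s: Optional[float] = None
    D_se_um2_s: Optional[float] = None
    qc_long_enough: Optional[bool] = None
    qc_se_ok: Optional[bool] = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if not np.all(np.diff(self.lags) > 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.msd < 0):
            raise ValueError("msd values must be non-negative")
        if np.any(np.diff(self.n_pairs) > 0):
            raise ValueError("n_pairs must be non-increasing in lag")


@dataclass
class DwellTimeSet:
    """Cleavage dwell times measured at one clamp force.

    ``censored`` marks dwells where the recording (or the fluorophore)
    ended before cleavage; those enter the likelihood as right-censored.
    """

    dwells: np.ndarray
    force: float
    censored: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.dwells = np.asarray(self.dwells, dtype=float)
        if self.censored is None:
            self.censored = np.zeros(len(self.dwells), dtype=bool)
        else:
            self.censored = np.asarray(self.censored, dtype=bool)
        if len(self.censored) != len(self.dwells):
            raise ValueError("censored flags must match dwells in length")
        if len(self.dwells) == 0:
            raise ValueError("empty dwell-time set")
        if np.any(self.dwells <= 0):
            raise ValueError("dwell times must be positive")
        if self.force < 0:
            raise ValueError("clamp force must be non-negative")

    def __len__(self) -> int:
        return len(self.dwells)


@dataclass
class BellEvansFit:
    """Zero-force rate and activation length from a ln k vs F regression."""

    k0: float
    dx_nm: float
    k0_se: float = 0.0
    dx_se_nm: float = 0.0
    cov: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not (self.k0 > 0):
            raise ValueError("k0 must be positive")

    @property
    def dx_angstrom(self) -> float:
        return self.dx_nm * 10.0

    @property
    def dx_se_angstrom(self) -> float:
        return self.dx_se_nm * 10.0
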