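"""Core data containers shared across the analysis modules.

All concentrations are molar, times in seconds, lengths in micrometres
unless a field name says otherwise. Containers validate their invariants
at construction so downstream code can rely on them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

COMPARTMENTS = (
    "chromatin",
    "spindle",
    "centrosome",
    "cytoplasm",
    "whole_cell",
    "polar_chromosome",
    "other",
)

CURVE_KINDS = ("auto_g", "auto_r", "cross")


def _as_1d(x, dtype=float) -> np.ndarray:
    arr = np.asarray(x, dtype=dtype)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D sequence")
    return arr


@dataclass(frozen=True)
class PhotonCountTrace:
    """Binned photon counts for one detection channel."""

    channel: str
    bin_width: float  # s
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.size < 2:
            raise ValueError("counts must be a 1-D sequence of length >= 2")
        if not np.issubdtype(counts.dtype, np.integer):
            as_int = counts.astype(np.int64)
            if not np.array_equal(as_int, counts):
                raise ValueError("counts must be integers")
            counts = as_int
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not (self.bin_width > 0 and math.isfinite(self.bin_width)):
            raise ValueError("bin_width must be positive and finite")
        object.__setattr__(self, "counts", counts)

    @property
    def duration(self) -> float:
        return self.bin_width * len(self.counts)

    @property
    def mean_rate(self) -> float:
        """Mean count rate in counts/s."""
        return float(self.counts.mean()) / self.bin_width


@dataclass(frozen=True)
class CorrelationCurve:
    """G(tau) versus lag for an auto- or cross-correlation."""

    kind: str
    lags: np.ndarray  # s, strictly increasing, positive
    g: np.ndarray
    sd: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in CURVE_KINDS:
            raise ValueError(f"kind must be one of {CURVE_KINDS}")
        lags = _as_1d(self.lags)
        g = _as_1d(self.g)
        if len(lags) != len(g):
            raise ValueError("lags and g must have equal length")
        if len(lags) == 0:
            raise ValueError("curve must have at least one lag")
        if lags[0] <= 0 or (np.diff(lags) <= 0).any():
            raise ValueError("lags must be strictly increasing and positive")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "g", g)
        if self.sd is not None:
            sd = _as_1d(self.sd)
            if len(sd) != len(g):
                raise ValueError("sd must match the number of lags")
            if (sd < 0).any():
                raise ValueError("sd must be non-negative")
            object.__setattr__(self, "sd", sd)


@dataclass(frozen=True)
class ObservationVolume:
    """Confocal detection volume: 3-D Gaussian with lateral 1/e^2 radius
    ``w_xy`` (µm) and structure parameter ``kappa = w_z / w_xy``."""

    w_xy: float
    kappa: float

    def __post_init__(self):
        if not (self.w_xy > 0 and math.isfinite(self.w_xy)):
            raise ValueError("w_xy must be positive")
        if not (self.kappa > 1 and math.isfinite(self.kappa)):
            raise ValueError("kappa must be > 1")

    @property
    def w_z(self) -> float:
        return self.kappa * self.w_xy

    @property
    def v_eff_um3(self) -> float:
        return math.pi ** 1.5 * self.w_xy**2 * self.w_z

    @property
    def v_eff(self) -> float:
        """Effective volume in litres (1 µm³ = 1e-15 L)."""
        return self.v_eff_um3 * 1e-15


@dataclass(frozen=True)
class Environment:
    """Thermodynamic context for the Stokes-Einstein conversion."""

    temperature: float  # K
    viscosity: float  # Pa s

    def __post_init__(self):
        if not (self.temperature > 0 and self.viscosity > 0):
            raise ValueError("temperature and viscosity must be positive")


@dataclass(frozen=True)
class DiffusionFit:
    """Result of fitting a diffusion model to one correlation curve."""

    n_molecules: float
    tau_d: float  # s
    d_coef: float  # µm²/s
    kappa_used: float
    goodness: float  # reduced chi-square
    converged: bool
    model_id: str
    fraction_1: Optional[float] = None
    tau_d2: Optional[float] = None

    @property
    def amplitude(self) -> float:
        """Zero-lag amplitude G(0) = 1/N."""
        return 1.0 / self.n_molecules


@dataclass(frozen=True)
class EquilibriumState:
    """Mass-action equilibrium of a 1:1 binding pair (all molar)."""

    a_total: float
    b_total: float
    kd: float
    a_free: float
    b_free: float
    complex: float


@dataclass(frozen=True)
class InteractionResult:
    """Amplitude-derived concentrations, bound fractions, q and K_D."""

    g_g0: float
    g_r0: float
    g_x0: float
    c_g_free: float
    c_r_free: float
    c_complex: float
    kd: float  # molar; +inf means no detectable interaction
    bound_fraction_g: float
    bound_fraction_r: float
    q: float
    valid: bool = True
    note: str = ""


@dataclass(frozen=True)
class DegradationTrace:
    """Anaphase-aligned single-cell intensity trajectory.

    Frame 0 is anaphase; negative frames precede it. ``background`` may be
    a scalar or a per-frame array.
    """

    frames: np.ndarray
    intensities: np.ndarray
    background: object = 0.0
    compartment: str = "other"
    frame_interval: float = 30.0  # s
    cell_id: str = ""

    def __post_init__(self):
        frames = _as_1d(self.frames, dtype=np.int64)
        inten = _as_1d(self.intensities)
        if len(frames) != len(inten):
            raise ValueError("frames and intensities must have equal length")
        if len(frames) < 2:
            raise ValueError("trace must contain at least two frames")
        if not np.array_equal(np.diff(frames), np.ones(len(frames) - 1)):
            raise ValueError("frames must be strictly consecutive integers")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"compartment must be one of {COMPARTMENTS}")
        bg = self.background
        if np.ndim(bg) == 1:
            bg = _as_1d(bg)
            if len(bg) != len(frames):
                raise ValueError("per-frame background must match trace length")
        else:
            bg = float(bg)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "intensities", inten)
        object.__setattr__(self, "background", bg)

    def index_of(self, frame: int) -> int:
        i = int(frame) - int(self.frames[0])
        if i < 0 or i >= len(self.frames):
            raise ValueError(f"frame {frame} not in trace range "
                             f"[{self.frames[0]}, {self.frames[-1]}]")
        return i

    def background_array(self) -> np.ndarray:
        if np.ndim(self.background) == 1:
            return np.asarray(self.background, dtype=float)
        return np.full(len(self.frames), float(self.background))


@dataclass(frozen=True)
class KineticsResult:
    """Extracted degradation kinetics for one trace."""

    onset_frame: Optional[int]
    initial_speed: Optional[float]  # normalised intensity / frame
    max_speed: float
    max_speed_frame: int
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class LineProfile:
    """Intensity profile along a centrosome-to-centrosome axis."""

    positions: np.ndarray  # px along the axis
    values: dict  # channel -> 1-D array
    thickness_px: int = 10

    def __post_init__(self):
        pos = _as_1d(self.positions)
        if (np.diff(pos) <= 0).any():
            raise ValueError("positions must be strictly increasing")
        vals = {k: _as_1d(v) for k, v in dict(self.values).items()}
        for k, v in vals.items():
            if len(v) != len(pos):
                raise ValueError(f"channel {k!r} length mismatch")
        if self.thickness_px < 1:
            raise ValueError("thickness_px must be >= 1")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "values", vals)
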