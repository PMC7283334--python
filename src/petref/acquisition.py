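"""Forward simulation of a dynamic FDG-PET acquisition.

Tissue time-activity curves follow the irreversible two-tissue-compartment
model (FDG trapped after phosphorylation):

    dC1/dt = K1*Cp - (k2+k3)*C1
    dC2/dt = k3*C1
    C_meas = (1 - vB)*(C1 + C2) + vB*Cp

solved with an exponential-integrator recursion on a fine time grid (exact for
a plasma curve that is linear within each step).  Frames report the *mean*
activity over the frame interval, matching how a scanner histograms list-mode
counts.  Voxel rendering paints regional activities into the label atlas,
convolves with an isotropic Gaussian point-spread function -- the sole source
of partial-volume effects in the simulation -- and optionally adds Gaussian
noise whose variance scales with activity over frame duration (count
statistics without projection-space modeling).

All activities are decay-corrected: no 18F half-life is applied anywhere, so
closed-form oracles remain exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "FrameSchedule",
    "TAC",
    "DynamicImage",
    "BloodSamples",
    "default_schedule",
    "DEFAULT_BLOOD_TIMES_MIN",
    "simulate_tissue_tac",
    "simulate_tissue_components",
    "frame_average",
    "render_dynamic_image",
    "sample_blood",
    "gaussian_sigma_vox",
]

#: default venous/arterialized sampling times (minutes post-injection)
DEFAULT_BLOOD_TIMES_MIN = (3.0, 8.0, 16.0, 24.0, 35.0, 55.0)

#: dynamic framing blocks as (count, duration_s): 12x10 s, 8x30 s, 6x4 min,
#: 6x5 min -- a 60-minute, 32-frame protocol
DEFAULT_FRAME_BLOCKS = ((12, 10.0), (8, 30.0), (6, 240.0), (6, 300.0))


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping dynamic frame timing (seconds)."""

    start_s: np.ndarray
    duration_s: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.start_s, dtype=float)
        d = np.asarray(self.duration_s, dtype=float)
        object.__setattr__(self, "start_s", s)
        object.__setattr__(self, "duration_s", d)
        if s.shape != d.shape or s.ndim != 1 or len(s) == 0:
            raise ValueError("start_s and duration_s must be matching 1-D arrays")
        if (d <= 0).any():
            raise ValueError("frame durations must be strictly positive")
        if not np.allclose(s[1:], s[:-1] + d[:-1]):
            raise ValueError("frames must be contiguous and non-overlapping")

    @classmethod
    def from_blocks(cls, blocks) -> "FrameSchedule":
        durations = np.concatenate([[dur] * int(n) for n, dur in blocks])
        starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
        return cls(start_s=starts, duration_s=durations)

    @property
    def n_frames(self) -> int:
        return len(self.start_s)

    @property
    def end_s(self) -> float:
        return float(self.start_s[-1] + self.duration_s[-1])

    @property
    def mid_times_min(self) -> np.ndarray:
        return (self.start_s + self.duration_s / 2.0) / 60.0

    @property
    def duration_min(self) -> np.ndarray:
        return self.duration_s / 60.0


def default_schedule() -> FrameSchedule:
    return FrameSchedule.from_blocks(DEFAULT_FRAME_BLOCKS)


@dataclass
class TAC:
    """A time-activity curve sampled at frame mid-times (minutes, kBq/mL)."""

    times_min: np.ndarray
    activity: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if (np.diff(self.times_min) <= 0).any():
            raise ValueError("TAC times must be strictly increasing")
        if not np.isfinite(self.activity).all():
            raise ValueError("TAC activity must be finite")


@dataclass
class DynamicImage:
    """4D activity volume (x, y, z, frame) with its frame schedule."""

    data: np.ndarray
    schedule: FrameSchedule
    voxel_size_mm: float

    def __post_init__(self):
        if self.data.ndim != 4:
            raise ValueError("dynamic image must be 4-D")
        if self.data.shape[3] != self.schedule.n_frames:
            raise ValueError(
                f"frame count {self.data.shape[3]} does not match schedule "
                f"({self.schedule.n_frames} frames)"
            )

    def frame(self, i: int) -> np.ndarray:
        return self.data[..., i]


@dataclass
class BloodSamples:
    """Timed plasma samples (minutes, kBq/mL) plus plasma glucose (mmol/L)."""

    times_min: np.ndarray
    activity: np.ndarray
    plasma_glucose: float = 5.0

    def __post_init__(self):
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if (np.diff(self.times_min) <= 0).any():
            raise ValueError("sample times must be strictly increasing")
        if (self.activity < 0).any():
            raise ValueError("sample activity must be nonnegative")


def _fine_grid(schedule: FrameSchedule, dt_s: float) -> np.ndarray:
    n = int(round(schedule.end_s / dt_s))
    return np.linspace(0.0, schedule.end_s / 60.0, n + 1)  # minutes


def frame_average(t_min: np.ndarray, values: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Mean of a fine-grid curve over each frame interval (trapezoidal).

    ``values`` may be (n_t,) or (..., n_t); the grid must contain the frame
    boundaries (it does for any dt dividing the shortest frame).
    """
    values = np.asarray(values)
    out = np.empty(values.shape[:-1] + (schedule.n_frames,))
    for i in range(schedule.n_frames):
        lo = schedule.start_s[i] / 60.0
        hi = lo + schedule.duration_s[i] / 60.0
        sel = (t_min >= lo - 1e-12) & (t_min <= hi + 1e-12)
        tt = t_min[sel]
        out[..., i] = np.trapezoid(values[..., sel], tt, axis=-1) / (tt[-1] - tt[0])
    return out


def _solve_2tc(K1, k2, k3, cp, t_min):
    """Exponential-integrator solution of the 2TC system on grid t_min.

    Parameters may be scalars or (R,) arrays; returns C1+C2 of shape
    (R, n_t) (or (n_t,) for scalars).  Exact when Cp is piecewise linear
    between grid points; C2 accumulates k3*C1 by the trapezoidal rule.
    """
    K1 = np.atleast_1d(np.asarray(K1, dtype=float))
    k2 = np.atleast_1d(np.asarray(k2, dtype=float))
    k3 = np.atleast_1d(np.asarray(k3, dtype=float))
    scalar = K1.size == 1 and np.isscalar(t_min) is False and K1.ndim == 1
    a = k2 + k3
    n = len(t_min)
    R = len(K1)
    c1 = np.zeros((R, n))
    c2 = np.zeros((R, n))
    h = np.diff(t_min)
    e = np.exp(-a[:, None] * h[None, :])          # (R, n-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        g0 = (1.0 - e) / a[:, None]               # int e^{-a(h-s)} ds
    for i in range(n - 1):
        hi = h[i]
        c0 = cp[i]
        c1v = (cp[i + 1] - cp[i]) / hi
        ei = e[:, i]
        g0i = g0[:, i]
        # exact response to Cp(s) = c0 + c1v*s over the step
        drive = c0 * g0i + c1v * (hi - g0i) / a
        c1[:, i + 1] = c1[:, i] * ei + K1 * drive
        c2[:, i + 1] = c2[:, i] + k3 * 0.5 * hi * (c1[:, i] + c1[:, i + 1])
    total = c1 + c2
    return (total, c1, c2)


def simulate_tissue_components(K1, k2, k3, input_model, schedule, dt_s=0.5):
    """Frame-averaged tissue activity (C1+C2) and plasma, vectorized over regions.

    Returns (tissue_frames (R, F), plasma_frames (F,)).  The blood-volume term
    is not included here; callers combine ``(1-vB)*tissue + vB*plasma``.
    """
    t = _fine_grid(schedule, dt_s)
    cp = input_model(t)
    total, _, _ = _solve_2tc(K1, k2, k3, cp, t)
    return frame_average(t, total, schedule), frame_average(t, cp, schedule)


def simulate_tissue_tac(kinetics, input_model, schedule, dt_s=0.5, label="tissue") -> TAC:
    """Simulate one frame-averaged tissue TAC.

    ``kinetics`` is (K1, k2, k3, vB) with rate constants in 1/min (K1 in
    mL/g/min) and vB the fractional blood volume.
    """
    K1, k2, k3, vB = kinetics
    if k2 < 0 or k3 < 0 or K1 < 0:
        raise ValueError("rate constants must be nonnegative")
    tissue, plasma = simulate_tissue_components([K1], [k2], [k3], input_model, schedule, dt_s)
    act = (1.0 - vB) * tissue[0] + vB * plasma
    return TAC(times_min=schedule.mid_times_min, activity=act, label=label)


def gaussian_sigma_vox(fwhm_mm: float, voxel_size_mm: float) -> float:
    return fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm


def render_dynamic_image(atlas, region_frame_activity, psf_fwhm_mm=6.0,
                         noise_scale=0.0, seed=None, clip_negative=True,
                         schedule=None) -> DynamicImage:
    """Render a dynamic image from per-region frame activities.

    Parameters
    ----------
    atlas : LabelAtlas
    region_frame_activity : dict[int, array (F,)]
        Frame-averaged activity per label id.  Every nonzero label in the
        atlas must be present (the carotid label takes the frame-averaged
        plasma curve).
    psf_fwhm_mm : float
        Isotropic Gaussian PSF full-width-at-half-maximum; 0 disables blur.
    noise_scale : float
        Gaussian noise with sd = noise_scale * sqrt(activity / frame minutes).
    """
    if schedule is None:
        raise ValueError("a FrameSchedule is required")
    labels = atlas.labels
    present = [int(v) for v in np.unique(labels) if v != 0]
    for rid in present:
        if rid not in region_frame_activity:
            name = atlas.region_table.set_index("region_id")["name"].get(rid, str(rid))
            raise KeyError(f"no TAC supplied for atlas region '{name}' (id {rid})")
    F = schedule.n_frames
    lut = np.zeros((int(labels.max()) + 1, F))
    for rid, act in region_frame_activity.items():
        act = np.asarray(act, dtype=float)
        if act.shape != (F,):
            raise ValueError(f"region {rid}: activity must have {F} frames")
        if 0 <= rid < len(lut):
            lut[rid] = act
    sigma = gaussian_sigma_vox(psf_fwhm_mm, atlas.voxel_size_mm)
    rng = np.random.default_rng(seed)
    out = np.empty(labels.shape + (F,), dtype=np.float64)
    for f in range(F):
        img = lut[labels, f]
        if sigma > 0:
            img = ndimage.gaussian_filter(img, sigma=sigma, mode="constant")
        if noise_scale > 0:
            sd = noise_scale * np.sqrt(np.maximum(img, 0.0) / schedule.duration_min[f])
            img = img + rng.standard_normal(img.shape) * sd
        out[..., f] = img
    if clip_negative:
        np.maximum(out, 0.0, out=out)
    return DynamicImage(data=out, schedule=schedule, voxel_size_mm=atlas.voxel_size_mm)


def sample_blood(input_model, times_min=DEFAULT_BLOOD_TIMES_MIN, noise_sd=0.0,
                 seed=None, plasma_glucose=5.0) -> BloodSamples:
    """Draw timed plasma samples: Cp(t) * (1 + eps), eps ~ N(0, noise_sd^2)."""
    t = np.asarray(times_min, dtype=float)
    cp = input_model(t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        cp = cp * (1.0 + rng.standard_normal(len(t)) * noise_sd)
    return BloodSamples(times_min=t, activity=np.maximum(cp, 0.0),
                        plasma_glucose=plasma_glucose)
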