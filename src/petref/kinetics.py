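"""Patlak graphical analysis and conversion to CMRg.

For an irreversible tracer the transformed tissue curve

    y(t) = Ct(t)/Cp(t)   versus   x(t) = int_0^t Cp dtau / Cp(t)

becomes linear once the reversible compartments equilibrate; the slope is the
net uptake constant Ki = K1*k3/(k2+k3) (1/min) and the intercept the
effective distribution volume.  CMRg converts Ki through plasma glucose and
the lumped constant LC:

    CMRg [umol/100 g/min] = Ki * C_glc / LC / density * 100

with C_glc in mmol/L (= umol/mL) and tissue density in g/mL (default 1.0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .acquisition import TAC, DynamicImage

__all__ = [
    "PatlakPoints",
    "PatlakFit",
    "CMRgValue",
    "patlak_transform",
    "fit_patlak",
    "cmrg_from_ki",
    "cmrg_voxel_map",
    "DEFAULT_LUMPED_CONSTANT",
    "DEFAULT_T_STAR_MIN",
]

DEFAULT_LUMPED_CONSTANT = 0.80
DEFAULT_T_STAR_MIN = 20.0


@dataclass
class PatlakPoints:
    t_min: np.ndarray       # frame mid-times of the retained points
    x: np.ndarray           # normalized time, minutes
    y: np.ndarray           # Ct/Cp, unitless


@dataclass
class PatlakFit:
    Ki: float               # 1/min
    V: float                # intercept (distribution volume, unitless)
    r2_fit: float
    t_star_min: float
    n_points: int


@dataclass
class CMRgValue:
    value: float            # umol/100 g/min
    Ki: float
    plasma_glucose: float   # mmol/L
    lumped_constant: float
    density: float          # g/mL


def patlak_transform(tissue_tac: TAC, input_model) -> PatlakPoints:
    """Patlak coordinates at the TAC's frame mid-times.

    Points where Cp(t) <= 0 are dropped with a warning.
    """
    t = tissue_tac.times_min
    cp = np.asarray(input_model(t), dtype=float)
    keep = cp > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} Patlak points with Cp <= 0")
    t, cp = t[keep], cp[keep]
    ct = tissue_tac.activity[keep]
    x = np.asarray(input_model.integral(t)) / cp
    return PatlakPoints(t_min=t, x=x, y=ct / cp)


def fit_patlak(points: PatlakPoints, t_star_min=DEFAULT_T_STAR_MIN) -> PatlakFit:
    """Ordinary least-squares line through points with t >= t*."""
    sel = points.t_min >= t_star_min
    if sel.sum() < 3:
        raise ValueError(
            f"only {int(sel.sum())} Patlak points at t >= {t_star_min} min; need >= 3"
        )
    x, y = points.x[sel], points.y[sel]
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    ki = sxy / sxx
    v = ym - ki * xm
    ss_res = float(((y - (ki * x + v)) ** 2).sum())
    ss_tot = float(((y - ym) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PatlakFit(Ki=ki, V=v, r2_fit=max(0.0, min(1.0, r2)),
                     t_star_min=float(t_star_min), n_points=int(sel.sum()))


def cmrg_from_ki(Ki, C_glc, LC=DEFAULT_LUMPED_CONSTANT, density=1.0) -> CMRgValue:
    """CMRg = Ki * C_glc / LC / density * 100, in umol/100 g/min.

    Ki in 1/min; C_glc in mmol/L (numerically equal to umol/mL, so the
    mL-to-100 g conversion is the explicit factor 100/density).
    """
    if LC <= 0 or density <= 0:
        raise ValueError("lumped constant and density must be positive")
    if C_glc < 0:
        raise ValueError("plasma glucose must be nonnegative")
    value = Ki * C_glc / LC / density * 100.0
    return CMRgValue(value=float(value), Ki=float(Ki), plasma_glucose=float(C_glc),
                     lumped_constant=float(LC), density=float(density))


def patlak_slope_weights(input_model, times_min, t_star_min=DEFAULT_T_STAR_MIN):
    """Late-frame weights w such that Ki = sum_f w_f * y_f for fixed x.

    The Patlak abscissa depends only on the input function, so voxelwise (or
    region-wise, subject-wise) slopes are a fixed linear combination of the
    transformed ordinates.  Returns (sel, w, cp) where sel flags the frames
    used and cp is Cp at all frame mid-times.
    """
    t = np.asarray(times_min, dtype=float)
    cp = np.asarray(input_model(t), dtype=float)
    sel = (t >= t_star_min) & (cp > 0)
    if sel.sum() < 3:
        raise ValueError("fewer than 3 usable late frames for Patlak")
    x = np.asarray(input_model.integral(t[sel])) / cp[sel]
    w = (x - x.mean()) / float(((x - x.mean()) ** 2).sum())
    return sel, w, cp


def cmrg_voxel_map(dynamic_image: DynamicImage, input_model, C_glc,
                   LC=DEFAULT_LUMPED_CONSTANT, density=1.0,
                   t_star_min=DEFAULT_T_STAR_MIN, valid_mask=None) -> np.ndarray:
    """Voxelwise CMRg map (umol/100 g/min) via the precomputed-abscissa Patlak.

    Voxels outside ``valid_mask`` (if given) are NaN.  Identical to running
    patlak_transform/fit_patlak voxel by voxel (contract covered by tests).
    """
    t = dynamic_image.schedule.mid_times_min
    sel, w, cp = patlak_slope_weights(input_model, t, t_star_min)
    data = dynamic_image.data[..., sel]
    y = data / cp[sel]
    ki = np.tensordot(y, w, axes=([3], [0]))
    cmrg = ki * C_glc / LC / density * 100.0
    if valid_mask is not None:
        cmrg = np.where(valid_mask, cmrg, np.nan)
    return cmrg
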