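"""Reciprocal-space background subtraction and the sine transform to G(r).

Solution-phase total scattering of a metal cluster rides on a large signal
from the surrounding medium (here: aqueous DNA).  The medium is measured
separately and subtracted in Q space, scaled by the user, before the
reduced structure function is transformed,

    G(r) = (2 / pi) * integral_{qmin}^{qmax} F(Q) sin(Q r) dQ.

Full intensity normalisation (Compton, polarisation, absorption, <f>^2
division) belongs to beamline reduction software and is out of scope; this
module accepts pre-reduced F(Q) or raw-ish intensities on a common footing
and performs only scaled subtraction and the transform.  The background
scale is never applied silently: :func:`auto_scale` is a helper that
proposes one, the caller decides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import OptimizationError, ValidationError
from .structure_io import IQCurve, PDFCurve

__all__ = [
    "ReductionConfig",
    "subtract_background",
    "auto_scale",
    "fq_to_gr",
    "gr_to_fq",
]


@dataclass
class ReductionConfig:
    """Q-range, background scale, and target r grid of a reduction run."""

    qmin: float = 0.7          # Å⁻¹; cuts the small-angle region
    qmax: float = 20.0         # Å⁻¹; typical rapid-acquisition PDF bound
    bg_scale: float = 1.0      # multiplier on the background curve
    rmax: float = 30.0         # Å
    dr: float = 0.01           # Å

    def __post_init__(self) -> None:
        if not (0 <= self.qmin < self.qmax):
            raise ValidationError(f"need 0 <= qmin < qmax, got {self.qmin}, {self.qmax}")
        if self.bg_scale < 0:
            raise ValidationError("bg_scale must be >= 0")
        if self.dr <= 0 or self.rmax <= 0:
            raise ValidationError("rmax and dr must be positive")

    @property
    def rgrid(self) -> np.ndarray:
        n = int(round(self.rmax / self.dr))
        return np.linspace(0.0, n * self.dr, n + 1)


def _overlap_background(sample: IQCurve, background: IQCurve) -> np.ndarray:
    """Background values on the sample grid (identity or linear interpolation)."""
    if sample.q.shape == background.q.shape and np.allclose(
        sample.q, background.q, atol=1e-12
    ):
        return background.y
    if background.q[0] > sample.q[-1] or background.q[-1] < sample.q[0]:
        raise ValidationError("sample and background Q ranges are disjoint")
    if background.q[0] > sample.q[0] + 1e-9 or background.q[-1] < sample.q[-1] - 1e-9:
        raise ValidationError("background does not cover the sample Q range")
    return np.interp(sample.q, background.q, background.y)


def subtract_background(sample: IQCurve, background: IQCurve, scale: float) -> IQCurve:
    """Pointwise ``sample - scale * background`` on the sample's Q grid."""
    if scale < 0:
        raise ValidationError("background scale must be >= 0")
    bg = _overlap_background(sample, background)
    out = IQCurve(sample.q.copy(), sample.y - scale * bg, dict(sample.meta))
    out.meta["background_scale"] = scale
    return out


def auto_scale(
    sample: IQCurve,
    background: IQCurve,
    window: tuple[float, float] | None = None,
    negative_tolerance: float = 0.05,
) -> float:
    """Propose a background scale by least squares over a background-dominated window.

    Minimises the integrated squared residual of ``sample - s*background``
    over the window (default: the full overlap), then caps ``s`` so that the
    subtracted signal over the *whole* grid has no negative excursion deeper
    than ``negative_tolerance`` times the sample's maximum absolute value.
    The result is a proposal; apply it explicitly via
    :func:`subtract_background`.
    """
    bg = _overlap_background(sample, background)
    lo, hi = window if window is not None else (sample.q[0], sample.q[-1])
    mask = (sample.q >= lo) & (sample.q <= hi)
    if not np.any(mask):
        raise ValidationError("scaling window contains no sample points")
    denom = float(np.sum(bg[mask] ** 2))
    if denom == 0.0:
        raise OptimizationError("background is zero over the window; scale unbounded")
    s = float(np.sum(sample.y[mask] * bg[mask]) / denom)
    s = max(s, 0.0)
    # For intensity-like (non-negative) curves, cap the scale so the
    # subtraction leaves no negative excursion deeper than the tolerance.
    # Reduced structure functions oscillate through zero by construction,
    # so the cap only applies when both inputs are essentially non-negative.
    tol = negative_tolerance * float(np.max(np.abs(sample.y))) if len(sample.y) else 0.0
    intensity_like = float(np.min(sample.y)) >= -tol and float(np.min(bg)) >= -tol
    positive = bg > tol
    if intensity_like and np.any(positive):
        s_cap = float(np.min((sample.y[positive] + tol) / bg[positive]))
        s = min(s, max(s_cap, 0.0))
    return s


def fq_to_gr(fq: IQCurve, config: ReductionConfig | None = None) -> PDFCurve:
    """Sine Fourier transform of F(Q) to the reduced PDF by trapezoidal quadrature."""
    config = config if config is not None else ReductionConfig()
    if config.qmax > fq.q[-1] + 1e-9:
        raise ValidationError(
            f"qmax {config.qmax} exceeds the data range (max Q = {fq.q[-1]:.3f})"
        )
    if not np.all(np.isfinite(fq.y)):
        raise ValidationError("F(Q) contains non-finite values")
    mask = (fq.q >= config.qmin) & (fq.q <= config.qmax)
    q = fq.q[mask]
    y = fq.y[mask]
    if len(q) < 2:
        raise ValidationError("fewer than 2 points inside [qmin, qmax]")
    r = config.rgrid
    integrand = y[None, :] * np.sin(q[None, :] * r[:, None])   # (Nr, Nq)
    g = (2.0 / np.pi) * np.trapezoid(integrand, q, axis=1)
    return PDFCurve(
        r,
        g,
        meta={
            "source": "fq_to_gr",
            "qmin": config.qmin,
            "qmax": config.qmax,
            "background": fq.meta.get("background_scale", "none"),
        },
    )


def gr_to_fq(gr: PDFCurve, qgrid: np.ndarray) -> IQCurve:
    """Inverse sine transform, F(Q) = integral G(r) sin(Q r) dr (consistency checks)."""
    qgrid = np.asarray(qgrid, dtype=float)
    integrand = gr.g[None, :] * np.sin(qgrid[:, None] * gr.r[None, :])
    y = np.trapezoid(integrand, gr.r, axis=1)
    return IQCurve(qgrid, y, meta={"source": "gr_to_fq"})
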