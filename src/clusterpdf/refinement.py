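"""Two-stage refinement of a cluster model against an experimental PDF.

Stage 1 refines the Cartesian position of every atom (3N parameters) plus
one overall scale — 55 parameters for an 18-atom core — by bounded
trust-region least squares on the pointwise misfit over the fit range.
Position bounds of ``max_shift`` per coordinate around the start model fix
the gauge: the PDF depends only on internal distances, so without bounds a
global rotation/translation drift would be unidentifiable.

Stage 2 adds an empirical solvation wave,

    w(r) = A * sin(2 pi r / lambda + phi) * exp(-r / xi),

an exponentially damped sine that absorbs the solvent-restructuring signal
a dissolved ionic cluster imprints on its surroundings; the stage-1
residual's characteristic sinusoidal shape initialises it.  The wave's four
parameters (and optionally the positions again) are refined jointly; the
fit quality Rw is non-increasing across stages by construction.

Gradients of the Gaussian pair-sum profile are analytic (exact closed
forms in the pair distances); a finite-difference fallback is available via
``RefinementOptions.jac``.  The optimiser is deterministic — identical
inputs give bit-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .exceptions import DegenerateGeometryError, ValidationError
from .pdf_engine import (
    DEFAULT_FIT_RANGE,
    RESOLUTION_FLOOR,
    calc_pdf,
    pair_table,
    rw,
    truncated_gaussian,
)
from .structure_io import ClusterModel, PDFCurve

__all__ = [
    "SolvationWave",
    "RefinementOptions",
    "RefinementResult",
    "wave_curve",
    "refine_positions",
    "refine_wave",
]

#: Atoms closer than this (Å) are treated as colliding; a smooth penalty
#: keeps the optimiser out of this region.
COLLISION_DISTANCE = 0.5


@dataclass
class SolvationWave:
    """Exponentially damped sine: amplitude (PDF units), wavelength, phase, decay (Å)."""

    amplitude: float
    wavelength: float
    phase: float = 0.0
    decay: float = 5.0

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValidationError("wavelength must be > 0")
        if self.decay <= 0:
            raise ValidationError("decay length must be > 0")

    def evaluate(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        return (
            self.amplitude
            * np.sin(2.0 * np.pi * r / self.wavelength + self.phase)
            * np.exp(-r / self.decay)
        )

    def normalized(self) -> "SolvationWave":
        """Canonical form: non-negative amplitude, phase wrapped to [0, 2*pi)."""
        A, phi = self.amplitude, self.phase
        if A < 0:
            A, phi = -A, phi + np.pi
        return SolvationWave(A, self.wavelength, float(np.mod(phi, 2 * np.pi)), self.decay)


def wave_curve(wave: SolvationWave, rgrid: np.ndarray) -> PDFCurve:
    """The solvation wave sampled on an r grid, as a PDF curve."""
    rgrid = np.asarray(rgrid, dtype=float)
    return PDFCurve(rgrid, wave.evaluate(rgrid), meta={"source": "solvation_wave"})


@dataclass
class RefinementOptions:
    """Controls for both refinement stages.

    max_shift is the per-coordinate position bound around the start model
    (Å); 1.0 Å comfortably covers sub-angstrom solution-state distortions
    while keeping the frame anchored.  sigma0 is the resolution floor fed to
    the PDF engine.  jac selects analytic gradients ("analytic") or scipy's
    2-point finite differences ("2-point").
    """

    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE
    max_shift: float = 1.0
    tol: float = 1e-10
    max_iter: int = 300
    refine_scale: bool = True
    scale_init: float | None = None      # None -> closed-form optimum at start
    sigma0: float = RESOLUTION_FLOOR
    weights: dict[str, float] | None = None
    jac: str = "analytic"
    relax_positions_with_wave: bool = False
    wave_phase_starts: tuple[float, ...] = (0.0, np.pi / 2, np.pi, 3 * np.pi / 2)
    rigid_groups: dict[str, str] | None = None
    rigid_max_angle: float = np.radians(30.0)
    #: Optional extra Gaussian blur (Å) applied to both data and model during
    #: the rigid pre-stage.  Off by default: the pre-stage is intended to run
    #: from an unperturbed start, where full resolution is most informative.
    rigid_smooth: float = 0.0

    def __post_init__(self) -> None:
        if self.fit_range[0] >= self.fit_range[1]:
            raise ValidationError("fit range must satisfy r_lo < r_hi")
        if self.max_shift < 0:
            raise ValidationError("max_shift must be >= 0")
        if self.jac not in ("analytic", "2-point"):
            raise ValidationError("jac must be 'analytic' or '2-point'")


@dataclass
class RefinementResult:
    """Refined model, scale, optional wave, fit quality and diagnostics."""

    model: ClusterModel
    scale: float
    wave: SolvationWave | None
    rw_value: float
    stage1_residual: PDFCurve
    converged: bool
    iterations: int
    start_model: ClusterModel | None = None
    rw_stage1: float | None = None
    wave_flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Profile + gradient machinery
# ---------------------------------------------------------------------------

class _Profile:
    """Gaussian pair-sum G(r) on a fixed grid, with analytic coordinate gradient.

    Pair weights and widths are held fixed (Biso is not refined), so only
    the distances move with the coordinates.
    """

    def __init__(self, model: ClusterModel, r: np.ndarray, opts: RefinementOptions):
        pt = pair_table(model, opts.weights, opts.sigma0)
        self.iu, self.ju = pt.i, pt.j
        self.w, self.sigma = pt.w, pt.sigma
        self.r = r
        self.n_atoms = len(model)
        self.amp = 2.0 * self.w / (self.sigma * np.sqrt(2.0 * np.pi))

    def _pair_peaks(self, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        diff = pos[self.iu] - pos[self.ju]
        d = np.linalg.norm(diff, axis=1)
        if np.any(d < 1e-6):
            raise DegenerateGeometryError("atoms coincide during refinement")
        z = (self.r[None, :] - d[:, None]) / self.sigma[:, None]
        peak = self.amp[:, None] * truncated_gaussian(z * z)
        return diff, d, peak, z

    def value(self, pos: np.ndarray) -> np.ndarray:
        _, _, peak, _ = self._pair_peaks(pos)
        return peak.sum(axis=0) / self.r

    def value_and_grad(self, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """G(r) and dG/dx as a (3N, M) array."""
        diff, d, peak, z = self._pair_peaks(pos)
        g = peak.sum(axis=0) / self.r
        # dPeak/dd = peak * z / sigma ; dd/dx_i = (x_i - x_j)/d
        dpeak_dd = peak * z / self.sigma[:, None] / self.r[None, :]
        grad = np.zeros((3 * self.n_atoms, len(self.r)))
        for k in range(3):
            coef = diff[:, k] / d
            contrib = dpeak_dd * coef[:, None]
            np.add.at(grad, 3 * self.iu + k, contrib)
            np.add.at(grad, 3 * self.ju + k, -contrib)
        return g, grad

    def collision_penalty(self, pos: np.ndarray, kappa: float) -> tuple[np.ndarray, np.ndarray]:
        """Hinge penalty on inter-atomic distances below the collision cutoff."""
        diff = pos[self.iu] - pos[self.ju]
        d = np.linalg.norm(diff, axis=1)
        pen = kappa * np.clip(COLLISION_DISTANCE - d, 0.0, None)
        grad = np.zeros((len(pen), 3 * self.n_atoms))
        active = pen > 0
        if np.any(active):
            for p in np.flatnonzero(active):
                i, j = self.iu[p], self.ju[p]
                u = diff[p] / d[p]
                grad[p, 3 * i : 3 * i + 3] = -kappa * u
                grad[p, 3 * j : 3 * j + 3] = kappa * u
        return pen, grad


def _wave_value_and_grad(
    params: np.ndarray, r: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Damped sine and its gradient wrt (A, lambda, phi, xi): (M,), (M, 4)."""
    A, lam, phi, xi = params
    arg = 2.0 * np.pi * r / lam + phi
    env = np.exp(-r / xi)
    s, c = np.sin(arg), np.cos(arg)
    value = A * s * env
    grad = np.empty((len(r), 4))
    grad[:, 0] = s * env
    grad[:, 1] = A * c * env * (-2.0 * np.pi * r / lam**2)
    grad[:, 2] = A * c * env
    grad[:, 3] = A * s * env * (r / xi**2)
    return value, grad


def _fit_wave_fixed(
    fit: PDFCurve,
    g_model: np.ndarray,
    opts: "RefinementOptions",
    scale0: float,
    lam0: float,
    amp0: float,
    xi0: float = 5.0,
):
    """Fit [A, lambda, phi, xi, scale] with the structural profile held fixed.

    Phase is scanned over deterministic starts; returns the best scipy
    solution.  Shared by stage 2 and by the rigid pre-stage's basin ranking.
    """
    lam_min = 2.0 * float(fit.r[1] - fit.r[0])

    def residual(p: np.ndarray) -> np.ndarray:
        wave_val, _ = _wave_value_and_grad(p[:4], fit.r)
        return fit.g - p[4] * g_model - wave_val

    def jacobian(p: np.ndarray) -> np.ndarray:
        _, dwave = _wave_value_and_grad(p[:4], fit.r)
        J = np.empty((len(fit.g), 5))
        J[:, :4] = -dwave
        J[:, 4] = -g_model
        return J

    lb = np.array([-np.inf, lam_min, -2 * np.pi, 0.1, 0.0])
    ub = np.array([np.inf, np.inf, 2 * np.pi, np.inf, np.inf])
    best = None
    for phi0 in opts.wave_phase_starts:
        p0 = np.array([amp0, max(lam0, lam_min * 1.01), phi0, xi0, scale0])
        sol = least_squares(
            residual, p0,
            jac=jacobian if opts.jac == "analytic" else "2-point",
            bounds=(lb, ub), method="trf",
            ftol=opts.tol, xtol=opts.tol, gtol=opts.tol, max_nfev=opts.max_iter,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    return best


def _closed_form_scale(g_obs: np.ndarray, g_model: np.ndarray) -> float:
    denom = float(np.sum(g_model**2))
    if denom == 0.0:
        raise ValidationError("model PDF is zero over the fit range")
    return float(np.sum(g_obs * g_model) / denom)


def _stage1_residual_curve(
    model: ClusterModel, scale: float, data: PDFCurve, opts: RefinementOptions
) -> PDFCurve:
    calc = calc_pdf(model, data.r, scale=scale, weights=opts.weights, sigma0=opts.sigma0)
    return PDFCurve(data.r.copy(), data.g - calc.g, meta={"source": "stage1_residual"})


# ---------------------------------------------------------------------------
# Stage 1: positions (+ scale)
# ---------------------------------------------------------------------------

def _rotvec_matrix(omega: np.ndarray) -> np.ndarray:
    """Rotation matrix from a rotation vector (Rodrigues)."""
    theta = np.linalg.norm(omega)
    if theta < 1e-12:
        return np.eye(3)
    k = omega / theta
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def _rigid_group_prestage(
    start: ClusterModel,
    fit: PDFCurve,
    opts: RefinementOptions,
) -> np.ndarray:
    """Coarse relaxation with atoms tied into rigid axial-twist groups.

    Correlated distortion fields — whole columns of atoms rotating together
    about the cluster axis — are hard for a free-atom local optimiser: the
    coherent move is long, and incoherent moves reach shallow spurious
    minima first.  Following the crystallographic rigid-body-then-individual
    convention, this pre-stage refines one twist angle per group about the
    cluster's principal axis (groups mapped "axis"/"cap" are held fixed)
    plus the overall scale, which lands the free-atom stage in the right
    basin.  Returns positions clipped into the per-coordinate bound box so
    the main stage's constraints still hold.
    """
    from scipy.ndimage import gaussian_filter1d

    from .geometry import principal_axis as _principal_axis

    groups: dict[str, list[int]] = {}
    for k, lab in enumerate(start.labels):
        gid = opts.rigid_groups.get(lab)
        if gid is None:
            raise ValidationError(f"rigid_groups is missing label {lab!r}")
        if str(gid) in ("cap", "axis"):
            continue
        groups.setdefault(str(gid), []).append(k)
    if not groups:
        return start.positions

    # blur data and model alike: start-perturbation and thermal jitter move
    # individual pair distances by ~0.1-0.3 Å, which would drown the coherent
    # twist signal at full resolution
    if opts.rigid_smooth > 0:
        dr = float(fit.r[1] - fit.r[0])
        g_fit = gaussian_filter1d(fit.g, opts.rigid_smooth / dr, mode="nearest")
        fit = PDFCurve(fit.r, g_fit)
        coarse = replace(opts, sigma0=float(np.hypot(opts.sigma0, opts.rigid_smooth)))
    else:
        coarse = opts
    profile = _Profile(start, fit.r, coarse)

    axis = _principal_axis(start)
    n = axis.direction
    origin = axis.origin
    x0 = start.positions
    gids = sorted(groups)
    s0 = _closed_form_scale(fit.g, profile.value(x0))

    # Net rotation about the axis is a gauge mode (an exact isometry of all
    # pair distances), so only twist differences are identifiable; the fit
    # works in the zero-net-rotation gauge: G-1 free angles, the last group
    # balancing the sum.
    nfree = len(gids) - 1

    def twists(p: np.ndarray) -> np.ndarray:
        t = np.empty(len(gids))
        t[:nfree] = p[:nfree]
        t[nfree] = -np.sum(p[:nfree])
        return t

    def positions(p: np.ndarray) -> np.ndarray:
        pos = x0.copy()
        for gi, t in enumerate(twists(p)):
            idx = groups[gids[gi]]
            R = _rotvec_matrix(t * n)
            pos[idx] = (x0[idx] - origin) @ R.T + origin
        return pos

    def residual(p: np.ndarray) -> np.ndarray:
        return fit.g - p[-1] * profile.value(positions(p))

    if nfree == 0:
        return x0
    lb = np.r_[np.full(nfree, -opts.rigid_max_angle), 0.0]
    ub = np.r_[np.full(nfree, opts.rigid_max_angle), np.inf]

    # The twist landscape has distinct basins per sign pattern, so a single
    # descent from zero can land in the wrong one.  Scan a deterministic
    # coarse grid of twist patterns, polish the few best by bounded least
    # squares, and keep the winner.
    grid_1d = np.radians((-10.0, -5.0, 0.0, 5.0, 10.0))
    candidates = []
    for combo in np.stack(np.meshgrid(*([grid_1d] * nfree)), -1).reshape(-1, nfree):
        p = np.r_[combo, s0]
        candidates.append((float(np.sum(residual(p) ** 2)), p))
    candidates.sort(key=lambda t: t[0])

    # Polish the most promising starts, then rank the distinct polished
    # solutions by their misfit AFTER a solvation-wave fit on each residual:
    # the smooth wave component otherwise tips the choice between
    # near-degenerate twist basins.
    polished = []
    for _, p0 in candidates[:8]:
        sol = least_squares(
            residual, p0, jac="2-point", bounds=(lb, ub), method="trf",
            ftol=opts.tol, xtol=opts.tol, gtol=opts.tol, max_nfev=400,
        )
        if not any(np.allclose(sol.x[:nfree], q.x[:nfree], atol=np.radians(0.5))
                   for q in polished):
            polished.append(sol)

    best_x, best_cost = None, np.inf
    for sol in polished:
        g_model = profile.value(positions(sol.x))
        res = fit.g - sol.x[-1] * g_model
        lam0 = _init_wavelength(PDFCurve(fit.r, res))
        wave_sol = _fit_wave_fixed(
            fit, g_model, opts, sol.x[-1], lam0, float(np.max(np.abs(res)))
        )
        if wave_sol.cost < best_cost:
            best_cost, best_x = wave_sol.cost, sol.x

    margin = 1e-9
    return np.clip(
        positions(best_x),
        x0 - opts.max_shift + margin,
        x0 + opts.max_shift - margin,
    )


def refine_positions(
    start: ClusterModel,
    data: PDFCurve,
    opts: RefinementOptions | None = None,
    initial: ClusterModel | None = None,
) -> RefinementResult:
    """Refine atomic positions (and scale) of ``start`` against a PDF.

    Minimises Rw over the 3N Cartesian coordinates, each bounded within
    ``opts.max_shift`` of its start value, plus one overall scale when
    ``opts.refine_scale``.  With ``max_shift == 0`` only the scale is
    refined (closed form).  Non-convergence within ``max_iter`` is flagged
    on the result, not fatal.

    ``initial`` optionally supplies different initial coordinates (e.g. an
    earlier, coarser fit) while the bounds stay anchored to ``start`` — the
    anchor defines the gauge and must not drift between stages.
    """
    opts = opts if opts is not None else RefinementOptions()
    lo, hi = opts.fit_range
    fit = data.restricted(lo, hi)
    if float(np.sum(fit.g**2)) == 0.0:
        raise ValidationError("data is identically zero over the fit range")
    profile = _Profile(start, fit.r, opts)
    x0 = start.positions
    x_init = initial.positions if initial is not None else x0
    if np.any(np.abs(x_init - x0) > opts.max_shift + 1e-12):
        raise ValidationError("initial positions lie outside the bounds around start")
    g0 = profile.value(x_init)
    s0 = (
        opts.scale_init
        if opts.scale_init is not None
        else (_closed_form_scale(fit.g, g0) if opts.refine_scale else 1.0)
    )

    if opts.max_shift == 0.0:
        scale = _closed_form_scale(fit.g, g0) if opts.refine_scale else s0
        model = start.with_positions(x0)
        calc = PDFCurve(fit.r, scale * g0)
        result_rw = rw(fit, calc)
        return RefinementResult(
            model=model,
            scale=scale,
            wave=None,
            rw_value=result_rw,
            stage1_residual=_stage1_residual_curve(model, scale, data, opts),
            converged=True,
            iterations=0,
            start_model=start,
            rw_stage1=result_rw,
        )

    if opts.rigid_groups is not None and initial is None:
        x_init = _rigid_group_prestage(start, fit, opts)
        if opts.refine_scale:
            s0 = _closed_form_scale(fit.g, profile.value(x_init))

    n3 = 3 * len(start)
    kappa = 10.0 * float(np.max(np.abs(fit.g)))
    with_scale = opts.refine_scale
    npar = n3 + (1 if with_scale else 0)

    def unpack(p: np.ndarray) -> tuple[np.ndarray, float]:
        pos = x0 + p[:n3].reshape(-1, 3)
        s = p[n3] if with_scale else s0
        return pos, s

    def residual(p: np.ndarray) -> np.ndarray:
        pos, s = unpack(p)
        g = profile.value(pos)
        pen, _ = profile.collision_penalty(pos, kappa)
        return np.concatenate([fit.g - s * g, pen])

    def jacobian(p: np.ndarray) -> np.ndarray:
        pos, s = unpack(p)
        g, dg = profile.value_and_grad(pos)
        pen, dpen = profile.collision_penalty(pos, kappa)
        J = np.zeros((len(fit.g) + len(pen), npar))
        J[: len(fit.g), :n3] = -s * dg.T
        J[len(fit.g) :, :n3] = dpen
        if with_scale:
            J[: len(fit.g), n3] = -g
        return J

    p0 = np.zeros(npar)
    p0[:n3] = (x_init - x0).flatten()
    lb = np.full(npar, -opts.max_shift)
    ub = np.full(npar, opts.max_shift)
    if with_scale:
        p0[n3] = s0
        lb[n3], ub[n3] = 0.0, np.inf

    sol = least_squares(
        residual,
        p0,
        jac=jacobian if opts.jac == "analytic" else "2-point",
        bounds=(lb, ub),
        method="trf",
        ftol=opts.tol,
        xtol=opts.tol,
        gtol=opts.tol,
        max_nfev=opts.max_iter,
    )
    pos, scale = unpack(sol.x)
    model = start.with_positions(pos)
    calc = PDFCurve(fit.r, scale * profile.value(pos))
    result_rw = rw(fit, calc)
    return RefinementResult(
        model=model,
        scale=scale,
        wave=None,
        rw_value=result_rw,
        stage1_residual=_stage1_residual_curve(model, scale, data, opts),
        converged=bool(sol.status > 0),
        iterations=int(sol.nfev),
        start_model=start,
        rw_stage1=result_rw,
    )


# ---------------------------------------------------------------------------
# Stage 2: solvation wave (+ optionally positions again)
# ---------------------------------------------------------------------------

def _init_wavelength(residual: PDFCurve) -> float:
    """Dominant Fourier period of the stage-1 residual (ignoring DC)."""
    g = residual.g - residual.g.mean()
    if len(g) < 8 or residual.dr == 0:
        return 4.0
    spectrum = np.abs(np.fft.rfft(g))
    freqs = np.fft.rfftfreq(len(g), d=residual.dr)
    spectrum[0] = 0.0
    k = int(np.argmax(spectrum))
    if freqs[k] <= 0:
        return 4.0
    lam = 1.0 / freqs[k]
    span = residual.r[-1] - residual.r[0]
    return float(np.clip(lam, 4 * residual.dr, span))


def refine_wave(
    result: RefinementResult,
    data: PDFCurve,
    opts: RefinementOptions | None = None,
) -> RefinementResult:
    """Stage 2: fit the damped-sine solvation wave on top of a stage-1 result.

    Wavelength is initialised from the dominant Fourier period of the
    stage-1 residual, amplitude from its extremum; several deterministic
    phase starts are tried and the best kept.  If no wave start improves on
    stage 1, a zero-amplitude wave is returned, so Rw never increases.  With
    ``opts.relax_positions_with_wave`` the atomic positions (still bounded
    around the original start model) are re-relaxed jointly with the wave.
    """
    opts = opts if opts is not None else RefinementOptions()
    lo, hi = opts.fit_range
    fit = data.restricted(lo, hi)
    res_fit = result.stage1_residual.restricted(lo, hi)

    lam0 = _init_wavelength(res_fit)
    amp0 = float(np.max(np.abs(res_fit.g)))
    xi0 = 5.0
    lam_min = 2.0 * fit.dr
    flags: list[str] = []

    relax = opts.relax_positions_with_wave
    start_model = result.start_model if result.start_model is not None else result.model
    x_start = start_model.positions
    x_current = result.model.positions
    g_fixed = calc_pdf(
        result.model, fit.r, weights=opts.weights, sigma0=opts.sigma0
    ).g
    kappa = 10.0 * float(np.max(np.abs(fit.g)))

    # phase scan with positions held fixed: parameters [A, lam, phi, xi, scale]
    best = _fit_wave_fixed(fit, g_fixed, opts, result.scale, lam0, amp0, xi0)
    lb5 = np.array([-np.inf, lam_min, -2 * np.pi, 0.1, 0.0])
    ub5 = np.array([np.inf, np.inf, 2 * np.pi, np.inf, np.inf])

    if relax:
        # one joint polish (positions + wave + scale) from the phase-scan winner
        profile = _Profile(start_model, fit.r, opts)
        n3 = 3 * len(start_model)

        def residual_joint(p: np.ndarray) -> np.ndarray:
            wave_val, _ = _wave_value_and_grad(p[:4], fit.r)
            pos = x_start + p[5:].reshape(-1, 3)
            pen, _ = profile.collision_penalty(pos, kappa)
            return np.concatenate(
                [fit.g - p[4] * profile.value(pos) - wave_val, pen]
            )

        def jacobian_joint(p: np.ndarray) -> np.ndarray:
            _, dwave = _wave_value_and_grad(p[:4], fit.r)
            pos = x_start + p[5:].reshape(-1, 3)
            g, dg = profile.value_and_grad(pos)
            pen, dpen = profile.collision_penalty(pos, kappa)
            M = len(fit.g)
            J = np.zeros((M + len(pen), 5 + n3))
            J[:M, :4] = -dwave
            J[:M, 4] = -g
            J[:M, 5:] = -p[4] * dg.T
            J[M:, 5:] = dpen
            return J

        lb = np.concatenate([lb5, np.full(n3, -opts.max_shift)])
        ub = np.concatenate([ub5, np.full(n3, opts.max_shift)])
        p0 = np.concatenate([best.x, (x_current - x_start).flatten()])
        p0 = np.clip(p0, lb + 1e-12, ub - 1e-12)
        best = least_squares(
            residual_joint,
            p0,
            jac=jacobian_joint if opts.jac == "analytic" else "2-point",
            bounds=(lb, ub),
            method="trf",
            ftol=opts.tol,
            xtol=opts.tol,
            gtol=opts.tol,
            max_nfev=opts.max_iter,
        )

    A, lam, phi, xi = best.x[:4]
    scale = best.x[4]
    if relax:
        model = start_model.with_positions(x_start + best.x[5:].reshape(-1, 3))
        g_model = profile.value(model.positions)
    else:
        model = result.model
        g_model = g_fixed
    wave = SolvationWave(float(A), float(lam), float(phi), float(xi))
    calc = PDFCurve(fit.r, scale * g_model + wave.evaluate(fit.r))
    rw2 = rw(fit, calc)

    if abs(lam - lam_min) < 1e-9:
        flags.append("wavelength pinned at grid-resolution bound")

    if rw2 > result.rw_value + 1e-12:
        # no wave start improved on stage 1: report a null wave
        wave = SolvationWave(0.0, lam0, 0.0, xi0)
        return replace(
            result,
            wave=wave,
            rw_stage1=result.rw_value,
            wave_flags=flags + ["wave fit did not improve stage 1; amplitude set to 0"],
        )
    return RefinementResult(
        model=model,
        scale=float(scale),
        wave=wave,
        rw_value=rw2,
        stage1_residual=result.stage1_residual,
        converged=result.converged and bool(best.status > 0),
        iterations=result.iterations + int(best.nfev),
        start_model=result.start_model,
        rw_stage1=result.rw_value,
        wave_flags=flags,
    )
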