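"""Perturbation-ensemble refinement: map the distribution of structures the data allows.

A single PDF of an 18-atom cluster under-determines its 55 refinement
parameters, so one converged refinement is not a unique answer.  Instead
the start model is perturbed many times (each coordinate shifted by an
independent uniform draw within ``max_disp``), every perturbed copy is
refined through both stages, and per-atom position distributions are
aggregated.  The defaults — 500 models, 0.2 Å maximum displacement —
follow the ten-models-per-parameter heuristic for a 55-parameter fit; test
suites run 20-50 models.

All members share one coordinate frame because refinements are bounded
near the common start, so refined positions are averaged directly without
re-superposition (a documented limitation: the frame is fixed by the
bounds, not by an alignment step).  Every output is a pure function of
(base_seed, spec, options); members are independent, so any parallel
schedule must reproduce the sequential result.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import EnsembleError, ValidationError
from .refinement import (
    RefinementOptions,
    RefinementResult,
    refine_positions,
    refine_wave,
)
from .structure_io import ClusterModel, PDFCurve

__all__ = [
    "EnsembleSpec",
    "EnsembleResult",
    "PositionDistribution",
    "perturb",
    "run_ensemble",
    "average_structure",
    "position_distribution",
    "mean_stage1_residual",
]


@dataclass
class EnsembleSpec:
    """Ensemble size, perturbation amplitude (Å per coordinate) and seed root."""

    n_models: int = 500
    max_disp: float = 0.2
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValidationError("n_models must be >= 1")
        if self.max_disp < 0:
            raise ValidationError("max_disp must be >= 0")

    def seed_for(self, index: int) -> int:
        return self.base_seed + index


@dataclass
class EnsembleResult:
    """All member refinements plus their start models and seeds."""

    results: list[RefinementResult]
    start_models: list[ClusterModel]
    seeds: list[int]
    n_failed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.seeds)) != len(self.seeds):
            raise ValidationError("ensemble seeds must be distinct")

    def __len__(self) -> int:
        return len(self.results)

    @property
    def rw_values(self) -> np.ndarray:
        return np.array([r.rw_value for r in self.results])

    def rw_summary(self) -> dict[str, float]:
        v = self.rw_values
        return {"min": float(v.min()), "max": float(v.max()), "mean": float(v.mean())}


@dataclass
class PositionDistribution:
    """Per-atom refined-position clouds and their box-plot spread statistics.

    The spread of an atom is the set of Euclidean distances of each member's
    refined position from that atom's ensemble-mean position; min, max,
    median and interquartile range of those distances build the box plot.
    """

    labels: list[str]
    positions: dict[str, np.ndarray]          # label -> (n_models, 3)
    stats: dict[str, dict[str, float]] = field(default_factory=dict)


def perturb(model: ClusterModel, max_disp: float, seed: int) -> ClusterModel:
    """Shift every Cartesian component by an independent U(-max_disp, +max_disp) draw."""
    if max_disp < 0:
        raise ValidationError("max_disp must be >= 0")
    rng = np.random.default_rng(seed)
    shifts = rng.uniform(-max_disp, max_disp, size=(len(model), 3))
    return model.with_positions(model.positions + shifts)


def run_ensemble(
    start: ClusterModel,
    data: PDFCurve,
    spec: EnsembleSpec,
    opts: RefinementOptions | None = None,
    with_wave: bool = True,
) -> EnsembleResult:
    """Perturb -> refine positions -> refine wave, for each ensemble member.

    Individual non-convergence is recorded on the member; a member raising
    an error is dropped, and more than 20% dropped members aborts with
    :class:`EnsembleError`.
    """
    opts = opts if opts is not None else RefinementOptions()

    # When rigid twist groups are configured, solve the coarse correlated
    # part once from the common (unperturbed) start and let every member
    # begin its free-atom refinement from its own perturbation plus that
    # shared coarse solution.  Running the group fit per member would see
    # the perturbation as incoherent noise on every pair distance and
    # scatter between basins.
    delta_pre = None
    if opts.rigid_groups is not None:
        from .refinement import _rigid_group_prestage

        fit = data.restricted(*opts.fit_range)
        delta_pre = _rigid_group_prestage(start, fit, opts) - start.positions
        opts = replace(opts, rigid_groups=None)

    results: list[RefinementResult] = []
    starts: list[ClusterModel] = []
    seeds: list[int] = []
    n_failed = 0
    for index in range(spec.n_models):
        seed = spec.seed_for(index)
        perturbed = perturb(start, spec.max_disp, seed)
        initial = None
        if delta_pre is not None:
            margin = 1e-9
            init_pos = np.clip(
                perturbed.positions + delta_pre,
                perturbed.positions - opts.max_shift + margin,
                perturbed.positions + opts.max_shift - margin,
            )
            initial = perturbed.with_positions(init_pos)
        try:
            res = refine_positions(perturbed, data, opts, initial=initial)
            if with_wave:
                res = refine_wave(res, data, opts)
        except Exception:
            n_failed += 1
            continue
        results.append(res)
        starts.append(perturbed)
        seeds.append(seed)
    if n_failed > 0.2 * spec.n_models:
        raise EnsembleError(
            f"{n_failed}/{spec.n_models} ensemble members failed to refine"
        )
    return EnsembleResult(results, starts, seeds, n_failed)


def average_structure(ens: EnsembleResult) -> ClusterModel:
    """Per-atom arithmetic mean of refined positions across the ensemble.

    No re-superposition is performed: the bounded refinements share one
    frame by construction.
    """
    if len(ens) == 0:
        raise ValidationError("cannot average an empty ensemble")
    stack = np.stack([r.model.positions for r in ens.results])
    template = ens.results[0].model
    return template.with_positions(stack.mean(axis=0), name="ensemble_average")


def position_distribution(ens: EnsembleResult) -> PositionDistribution:
    """Per-atom position clouds and box-plot statistics of their radial spread."""
    if len(ens) == 0:
        raise ValidationError("empty ensemble")
    labels = ens.results[0].model.labels
    stack = np.stack([r.model.positions for r in ens.results])  # (n, N, 3)
    mean = stack.mean(axis=0)
    dist = np.linalg.norm(stack - mean[None, :, :], axis=2)     # (n, N)
    positions = {lab: stack[:, k, :] for k, lab in enumerate(labels)}
    stats = {}
    for k, lab in enumerate(labels):
        d = dist[:, k]
        q1, med, q3 = np.percentile(d, [25, 50, 75])
        stats[lab] = {
            "min": float(d.min()),
            "max": float(d.max()),
            "median": float(med),
            "iqr": float(q3 - q1),
        }
    return PositionDistribution(labels, positions, stats)


def mean_stage1_residual(ens: EnsembleResult) -> PDFCurve:
    """Pointwise mean of the stage-1 (pre-wave) residual curves.

    Averaging over the ensemble suppresses member-specific fit noise by
    roughly sqrt(n) and exposes any common signal the cluster model cannot
    explain — in the DNA-cluster analysis this is the conformational
    signature of the DNA wrapped around the core.
    """
    if len(ens) == 0:
        raise ValidationError("empty ensemble")
    residuals = [r.stage1_residual for r in ens.results]
    for r in residuals:
        if r is None:
            raise ValidationError("a member is missing its stage-1 residual")
    r0 = residuals[0].r
    g = np.mean([r.g for r in residuals], axis=0)
    return PDFCurve(r0.copy(), g, meta={"source": "mean_stage1_residual", "n": len(ens)})
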