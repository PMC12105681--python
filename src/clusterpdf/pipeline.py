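"""End-to-end orchestration: simulate / reduce / refine / ensemble / geometry / dna-compare.

Each stage reads and writes plain-text artifacts (XYZ, two-column curves,
CSV, JSON) under one output directory, so a run is inspectable and
resumable stage by stage.  A single global seed in the configuration feeds
every source of randomness; re-running with the same configuration
reproduces every output byte-for-byte (modulo no timestamps being written).

With no explicit input paths the pipeline runs self-contained on the
synthetic generators: a distorted toy cluster observable with a solvation
wave, a DNA-like background, and a synthetic DNA strand for the Biso scan.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dna as dna_mod
from . import ensemble as ens_mod
from . import geometry as geo_mod
from . import pdf_engine, reduction, refinement, structure_io, synthetic
from .exceptions import ClusterPDFError, ValidationError

__all__ = ["PipelineConfig", "run", "STAGES"]

log = logging.getLogger("clusterpdf.pipeline")

STAGES = ("simulate", "reduce", "refine", "ensemble", "geometry", "dna-compare")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; loadable from YAML."""

    seed: int = 0
    outdir: str = "clusterpdf_out"
    stages: tuple[str, ...] = STAGES

    # --- input paths (empty -> produced by the simulate stage) ---
    start_model: str = ""          # XYZ of the reference cluster
    data_gr: str = ""              # experimental / reduced G(r)
    sample_iq: str = ""            # F(Q) of the cluster sample
    background_iq: str = ""        # F(Q) of the background (e.g. aqueous DNA)
    channel_map: str = ""          # CSV label,channel
    strand_map: str = ""           # CSV label,strand_tag
    dna_model: str = ""            # XYZ of the DNA structure for the Biso scan
    dna_target: str = ""           # G(r) the Biso scan fits

    # --- simulate stage ---
    twists: tuple[float, ...] = (9.0, 12.0, -3.0, -3.0)
    jitter: float = 0.05                   # Å
    wave_amplitude_fraction: float = 0.1   # of the clean PDF maximum
    wave_wavelength: float = 7.0           # Å
    wave_phase: float = 0.8                # rad
    wave_decay: float = 6.0                # Å
    noise_fraction: float = 0.01           # of the clean PDF maximum
    cluster_biso: float = 0.0              # Å², applied to the cluster model
    dna_sequence: str = "CACCTAGCGA"
    dna_true_biso: float = 2.0             # Å², generates the synthetic scan target
    background_scale_true: float = 0.8

    # --- reduction ---
    qmin: float = 0.7
    qmax: float = 20.0
    bg_scale: float | str = "auto"         # number, or "auto" for auto_scale
    rmax: float = 16.0
    dr: float = 0.01

    # --- refinement / ensemble ---
    fit_lo: float = 1.7
    fit_hi: float = 15.0
    max_shift: float = 1.0
    max_iter: int = 150
    tol: float = 1e-8
    use_rigid_groups: bool = True
    relax_positions_with_wave: bool = False
    n_models: int = 50
    max_disp: float = 0.2

    # --- biso scan ---
    biso_grid_start: float = 0.25
    biso_grid_stop: float = 6.0
    biso_grid_step: float = 0.25
    biso_r_lo: float = 3.0
    biso_r_hi: float = 10.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "twists"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["stages"] = list(self.stages)
        data["twists"] = list(self.twists)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def rgrid(self) -> np.ndarray:
        n = int(round(self.rmax / self.dr))
        return np.linspace(0.0, n * self.dr, n + 1)

    def refinement_options(self, rigid_groups=None) -> refinement.RefinementOptions:
        return refinement.RefinementOptions(
            fit_range=(self.fit_lo, self.fit_hi),
            max_shift=self.max_shift,
            max_iter=self.max_iter,
            tol=self.tol,
            rigid_groups=rigid_groups if self.use_rigid_groups else None,
            relax_positions_with_wave=self.relax_positions_with_wave,
        )


def _write_csv_map(mapping: dict[str, str], header: tuple[str, str], path: Path) -> None:
    lines = [",".join(header)]
    lines += [f"{k},{v}" for k, v in mapping.items()]
    path.write_text("\n".join(lines) + "\n")


def _read_csv_map(path: str | Path, value_column: str) -> dict[str, str]:
    df = pd.read_csv(path)
    if "label" not in df.columns or value_column not in df.columns:
        raise ValidationError(f"{path}: expected columns label,{value_column}")
    return dict(zip(df["label"].astype(str), df[value_column].astype(str)))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, out: Path) -> dict:
    """Generate the full set of synthetic inputs with recorded ground truth."""
    log.info("[simulate] building toy cluster and observables (seed=%d)", cfg.seed)
    reference, channel_map = synthetic.make_toy_cluster()
    if cfg.cluster_biso > 0:
        reference = reference.with_biso(cfg.cluster_biso)
    distorted, truth = synthetic.apply_distortion(
        reference, channel_map,
        synthetic.DistortionSpec(cfg.twists, cfg.jitter, seed=cfg.seed),
    )
    rgrid = cfg.rgrid()
    clean = pdf_engine.calc_pdf(distorted, rgrid)
    gmax = float(np.max(np.abs(clean.g)))
    wave = refinement.SolvationWave(
        cfg.wave_amplitude_fraction * gmax, cfg.wave_wavelength,
        cfg.wave_phase, cfg.wave_decay,
    )
    data = synthetic.simulate_pdf(
        distorted, wave, cfg.noise_fraction * gmax, rgrid, seed=cfg.seed + 1
    )
    data.meta["seed"] = cfg.seed

    structure_io.write_xyz(reference, out / "reference.xyz")
    structure_io.write_xyz(distorted, out / "truth.xyz")
    structure_io.write_gr(data, out / "data.gr", header=f"synthetic observable, seed {cfg.seed}")
    _write_csv_map(channel_map, ("label", "channel"), out / "channel_map.csv")
    strand_map = {
        lab: ("A" if ch in ("ch1", "ch2") else "B" if ch in ("ch3", "ch4") else "none")
        for lab, ch in channel_map.items()
    }
    _write_csv_map(strand_map, ("label", "strand_tag"), out / "strand_map.csv")

    # reciprocal-space pair for the reduce stage: cluster F(Q) on a DNA
    # background scaled so the medium dominates the sample, as in a real
    # dilute-solution measurement
    qgrid = np.arange(0.0, cfg.qmax + 5.0, 0.02)
    f_cluster = reduction.gr_to_fq(pdf_engine.calc_pdf(distorted, rgrid), qgrid)
    dna_bg = synthetic.simulate_dna_background("aqueous", rgrid, seed=cfg.seed + 2)
    f_dna = reduction.gr_to_fq(dna_bg, qgrid)
    rms = lambda y: float(np.sqrt(np.mean(y**2)))  # noqa: E731
    f_dna = structure_io.IQCurve(qgrid, f_dna.y * (3.0 * rms(f_cluster.y) / rms(f_dna.y)))
    scale_bg = cfg.background_scale_true
    sample = structure_io.IQCurve(qgrid, f_cluster.y + scale_bg * f_dna.y)
    structure_io.write_iq(sample, out / "sample.iq", header=f"cluster + {scale_bg} x background")
    structure_io.write_iq(f_dna, out / "background.iq", header="aqueous DNA background")

    # synthetic DNA strand + Biso-scan target
    strand = synthetic.make_dna_strand_model(cfg.dna_sequence, seed=cfg.seed + 3)
    structure_io.write_xyz(strand, out / "dna_model.xyz")
    target = dna_mod.dna_pdf(strand, cfg.dna_true_biso, rgrid)
    rng = np.random.default_rng(cfg.seed + 4)
    noisy = structure_io.PDFCurve(
        target.r,
        target.g + rng.normal(0.0, 0.01 * np.abs(target.g).max(), len(target.g)),
        dict(target.meta),
    )
    structure_io.write_gr(noisy, out / "dna_target.gr",
                          header=f"synthetic DNA target, Biso {cfg.dna_true_biso}")

    truth_record = {
        "seed": cfg.seed,
        "twists_deg": dict(truth.twists),
        "jitter_A": cfg.jitter,
        "mean_displacement_A": truth.mean_displacement(),
        "wave": {"amplitude": wave.amplitude, "wavelength": wave.wavelength,
                 "phase": wave.phase, "decay": wave.decay},
        "noise_sigma": cfg.noise_fraction * gmax,
        "background_scale": scale_bg,
        "dna_true_biso": cfg.dna_true_biso,
    }
    (out / "truth.json").write_text(json.dumps(truth_record, indent=2))
    return {"simulate": {"n_atoms": len(reference), "gmax": gmax}}


def stage_reduce(cfg: PipelineConfig, out: Path) -> dict:
    sample = structure_io.read_iq(cfg.sample_iq or out / "sample.iq")
    background = structure_io.read_iq(cfg.background_iq or out / "background.iq")
    if cfg.bg_scale == "auto":
        scale = reduction.auto_scale(sample, background)
    else:
        scale = float(cfg.bg_scale)
    log.info("[reduce] background scale %.4f", scale)
    net = reduction.subtract_background(sample, background, scale)
    rcfg = reduction.ReductionConfig(cfg.qmin, cfg.qmax, scale, cfg.rmax, cfg.dr)
    gr = reduction.fq_to_gr(net, rcfg)
    gr.meta["seed"] = cfg.seed
    structure_io.write_gr(gr, out / "reduced.gr", header="background-subtracted PDF")
    return {"reduce": {"background_scale": scale, "qmin": cfg.qmin, "qmax": cfg.qmax}}


def _load_inputs(cfg: PipelineConfig, out: Path):
    start = structure_io.read_xyz(cfg.start_model or out / "reference.xyz")
    if cfg.cluster_biso > 0:
        start = start.with_biso(cfg.cluster_biso)
    data = structure_io.read_gr(cfg.data_gr or out / "data.gr")
    chan_path = cfg.channel_map or out / "channel_map.csv"
    channel_map = _read_csv_map(chan_path, "channel") if Path(chan_path).exists() else None
    return start, data, channel_map


def stage_refine(cfg: PipelineConfig, out: Path) -> dict:
    start, data, channel_map = _load_inputs(cfg, out)
    opts = cfg.refinement_options(rigid_groups=channel_map)
    log.info("[refine] stage 1: %d position parameters + scale", 3 * len(start))
    res = refinement.refine_positions(start, data, opts)
    rw1 = res.rw_value
    res = refinement.refine_wave(res, data, opts)
    log.info("[refine] Rw %.4f (stage 1) -> %.4f (with wave)", rw1, res.rw_value)
    structure_io.write_xyz(res.model, out / "refined.xyz")
    structure_io.write_gr(res.stage1_residual, out / "residual.gr", header="stage-1 residual")
    record = {
        "seed": cfg.seed,
        "rw_stage1": rw1,
        "rw": res.rw_value,
        "scale": res.scale,
        "converged": res.converged,
        "iterations": res.iterations,
        "wave": None if res.wave is None else {
            "amplitude": res.wave.amplitude, "wavelength": res.wave.wavelength,
            "phase": res.wave.phase, "decay": res.wave.decay,
        },
    }
    (out / "refinement.json").write_text(json.dumps(record, indent=2))
    return {"refine": {"rw_stage1": rw1, "rw": res.rw_value}}


def stage_ensemble(cfg: PipelineConfig, out: Path) -> dict:
    start, data, channel_map = _load_inputs(cfg, out)
    opts = cfg.refinement_options(rigid_groups=channel_map)
    spec = ens_mod.EnsembleSpec(cfg.n_models, cfg.max_disp, base_seed=cfg.seed)
    log.info("[ensemble] refining %d perturbed models", spec.n_models)
    ens = ens_mod.run_ensemble(start, data, spec, opts)
    avg = ens_mod.average_structure(ens)
    structure_io.write_xyz(avg, out / "average.xyz")
    structure_io.write_gr(ens_mod.mean_stage1_residual(ens), out / "mean_residual.gr",
                          header="ensemble-mean stage-1 residual")
    pd.DataFrame(
        {"seed": ens.seeds, "rw": ens.rw_values,
         "converged": [r.converged for r in ens.results]}
    ).to_csv(out / "ensemble_rw.csv", index=False)
    dist = ens_mod.position_distribution(ens)
    pd.DataFrame.from_dict(dist.stats, orient="index").rename_axis("label").to_csv(
        out / "spread_stats.csv"
    )
    with open(out / "ensemble_models.xyz", "w") as fh:
        for res, seed in zip(ens.results, ens.seeds):
            fh.write(f"{len(res.model)}\nmodel seed {seed} rw {res.rw_value:.5f}\n")
            for s in res.model.sites:
                x, y, z = s.position
                fh.write(f"{s.element} {x:.6f} {y:.6f} {z:.6f}\n")
    summary = ens.rw_summary()
    log.info("[ensemble] Rw min %.3f mean %.3f max %.3f", summary["min"],
             summary["mean"], summary["max"])
    return {"ensemble": {"rw": summary, "n_failed": ens.n_failed}}


def stage_geometry(cfg: PipelineConfig, out: Path) -> dict:
    reference = structure_io.read_xyz(cfg.start_model or out / "reference.xyz")
    refined_path = out / "average.xyz"
    if not refined_path.exists():
        refined_path = out / "refined.xyz"
    refined = structure_io.read_xyz(refined_path)
    chan_path = cfg.channel_map or out / "channel_map.csv"
    channel_map = _read_csv_map(chan_path, "channel") if Path(chan_path).exists() else None
    strand_path = cfg.strand_map or out / "strand_map.csv"
    if Path(strand_path).exists():
        reference = reference.apply_strand_map(structure_io.read_strand_map(strand_path))
    records = geo_mod.analyze_distortion(reference, refined, channel_map=channel_map)
    rows = [
        {
            "label": r.label, "element": r.element,
            "strand": r.strand_tag, "channel": r.channel,
            "dx": r.vector[0], "dy": r.vector[1], "dz": r.vector[2],
            "magnitude": r.magnitude, "radial_distance": r.radial_distance,
            "angle_deg": r.rotation_angle,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(out / "geometry.csv", index=False)
    mags = geo_mod.summarize_magnitudes(records)
    groups = geo_mod.channel_stats(records) if channel_map else {}
    angles = [r.rotation_angle for r in records if np.isfinite(r.rotation_angle)]
    summary = {
        "displacement_A": mags,
        "rotation_deg": {
            "min": float(np.min(angles)) if angles else None,
            "max": float(np.max(angles)) if angles else None,
            "mean": float(np.mean(angles)) if angles else None,
        },
        "channels": groups,
    }
    (out / "geometry_summary.json").write_text(json.dumps(summary, indent=2))
    log.info("[geometry] mean displacement %.3f Å; mean rotation %s",
             mags["mean"], summary["rotation_deg"]["mean"])
    return {"geometry": summary}


def stage_dna_compare(cfg: PipelineConfig, out: Path) -> dict:
    dna_model = structure_io.read_xyz(cfg.dna_model or out / "dna_model.xyz")
    target = structure_io.read_gr(cfg.dna_target or out / "dna_target.gr")
    grid = np.arange(cfg.biso_grid_start, cfg.biso_grid_stop + 1e-9, cfg.biso_grid_step)
    scan = dna_mod.biso_scan(dna_model, target, grid, (cfg.biso_r_lo, cfg.biso_r_hi))
    pd.DataFrame({"biso": scan.biso_grid, "rw": scan.misfit}).to_csv(
        out / "biso_scan.csv", index=False
    )
    record = {
        "optimum_biso_A2": scan.optimum,
        "rms_displacement_A": scan.rms_displacement,
        "scale": scan.scale,
        "r_offset_A": scan.r_offset,
    }
    (out / "dna_summary.json").write_text(json.dumps(record, indent=2))
    log.info("[dna-compare] optimal Biso %.2f Å² (u = %.3f Å)",
             scan.optimum, scan.rms_displacement)
    return {"dna_compare": record}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "reduce": stage_reduce,
    "refine": stage_refine,
    "ensemble": stage_ensemble,
    "geometry": stage_geometry,
    "dna-compare": stage_dna_compare,
}


def run(cfg: PipelineConfig, only: str | None = None) -> dict:
    """Execute the configured stages (or a single one) and write a summary.

    A stage failure aborts with a stage-tagged error; outputs of completed
    stages are preserved.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "effective_config.yaml")
    stages = (only,) if only else cfg.stages
    summary: dict = {"seed": cfg.seed}
    for name in stages:
        if name not in _STAGE_FUNCS:
            raise ValidationError(f"unknown stage {name!r}; choose from {STAGES}")
        try:
            summary.update(_STAGE_FUNCS[name](cfg, out))
        except ClusterPDFError:
            raise
        except Exception as exc:  # tag foreign errors with the failing stage
            raise ClusterPDFError(f"stage {name!r} failed: {exc}") from exc
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
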