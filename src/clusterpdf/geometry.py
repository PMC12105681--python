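"""Distortion geometry: displacements and correlated rotations vs a reference.

The refined average structure is compared with the crystal reference by
(1) per-atom displacement vectors, (2) the cluster's principal axis — the
leading eigenvector of the covariance of the *reference* coordinates, so
the axis is untouched by refinement noise — and (3) the signed rotation of
each atom about that axis, computed between the projections of the
reference and refined positions onto the perpendicular plane.

Sign conventions are fixed and documented so reported angle signs are
reproducible: the axis direction is flipped so that its largest-magnitude
Cartesian component is positive (ties resolved towards +z), and positive
angles are counterclockwise when looking down the +axis direction
(right-hand rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import PairingError, ValidationError
from .structure_io import ClusterModel

__all__ = [
    "PrincipalAxis",
    "DisplacementRecord",
    "displacement_field",
    "principal_axis",
    "rotation_angles",
    "channel_stats",
    "analyze_distortion",
    "summarize_magnitudes",
]

#: Atoms closer than this (Å) to the axis have an ill-conditioned rotation angle.
ON_AXIS_RADIUS = 0.1


@dataclass
class PrincipalAxis:
    """Centroid origin and unit direction of the cluster's long axis."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(self.direction)
        if not np.isclose(norm, 1.0, atol=1e-9):
            raise ValidationError("axis direction must be a unit vector")


@dataclass
class DisplacementRecord:
    """One atom's displacement and rotation between reference and refined positions."""

    label: str
    element: str
    vector: np.ndarray          # refined - reference, Å
    magnitude: float            # |vector|, Å
    rotation_angle: float       # signed degrees about the principal axis; NaN if on-axis
    radial_distance: float      # distance of the reference position from the axis, Å
    strand_tag: str = "none"
    channel: str | None = None

    @property
    def on_axis(self) -> bool:
        return not np.isfinite(self.rotation_angle)


def _pair_by_label(
    reference: ClusterModel, refined: ClusterModel
) -> tuple[np.ndarray, np.ndarray]:
    if sorted(reference.labels) != sorted(refined.labels):
        raise PairingError("reference and refined models have different label sets")
    order = {lab: k for k, lab in enumerate(refined.labels)}
    idx = [order[lab] for lab in reference.labels]
    return reference.positions, refined.positions[idx]


def displacement_field(
    reference: ClusterModel, refined: ClusterModel
) -> list[DisplacementRecord]:
    """Per-atom displacement vectors (refined − reference), matched by label."""
    ref_pos, fin_pos = _pair_by_label(reference, refined)
    vectors = fin_pos - ref_pos
    records = []
    for site, vec in zip(reference.sites, vectors):
        records.append(
            DisplacementRecord(
                label=site.label,
                element=site.element,
                vector=vec,
                magnitude=float(np.linalg.norm(vec)),
                rotation_angle=float("nan"),
                radial_distance=float("nan"),
                strand_tag=site.strand_tag,
            )
        )
    return records


def summarize_magnitudes(records: list[DisplacementRecord]) -> dict[str, float]:
    mags = np.array([r.magnitude for r in records])
    return {"min": float(mags.min()), "max": float(mags.max()), "mean": float(mags.mean())}


def principal_axis(reference: ClusterModel, degeneracy_ratio: float = 1.05) -> PrincipalAxis:
    """Leading principal component of the (unweighted, centered) reference coordinates.

    Warns when the two largest covariance eigenvalues are within
    ``degeneracy_ratio`` of each other — the axis is then poorly defined.
    """
    pos = reference.positions
    if len(pos) < 3:
        raise ValidationError("need at least 3 atoms for a principal axis")
    centered = pos - pos.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValidationError("atoms are collinear; principal axis undefined in-plane")
    cov = centered.T @ centered / len(pos)
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals[-1] < degeneracy_ratio * eigvals[-2] and eigvals[-2] > 0:
        warnings.warn(
            "leading covariance eigenvalues are nearly degenerate; "
            "principal axis is ambiguous",
            stacklevel=2,
        )
    direction = eigvecs[:, -1]
    # sign convention: largest-|component| positive; ties resolved towards +z
    abs_d = np.round(np.abs(direction), 12)
    candidates = np.flatnonzero(abs_d == abs_d.max())
    k = int(candidates[-1])
    if direction[k] < 0:
        direction = -direction
    return PrincipalAxis(pos.mean(axis=0), direction)


def rotation_angles(
    reference: ClusterModel,
    refined: ClusterModel,
    axis: PrincipalAxis,
) -> dict[str, float]:
    """Signed in-plane rotation (degrees) of each atom about the principal axis.

    Both positions are projected onto the plane perpendicular to the axis;
    the returned angle takes the reference projection onto the refined one
    by the right-hand rule about the axis direction.  Atoms within
    ``ON_AXIS_RADIUS`` of the axis get NaN (undefined) and are excluded
    from any downstream summary.
    """
    ref_pos, fin_pos = _pair_by_label(reference, refined)
    n = axis.direction
    angles: dict[str, float] = {}
    for label, p_ref, p_fin in zip(reference.labels, ref_pos, fin_pos):
        u = p_ref - axis.origin
        v = p_fin - axis.origin
        u_perp = u - np.dot(u, n) * n
        v_perp = v - np.dot(v, n) * n
        if np.linalg.norm(u_perp) <= ON_AXIS_RADIUS or np.linalg.norm(v_perp) <= ON_AXIS_RADIUS:
            angles[label] = float("nan")
            continue
        angle = np.degrees(
            np.arctan2(np.dot(n, np.cross(u_perp, v_perp)), np.dot(u_perp, v_perp))
        )
        angles[label] = float(angle)
    return angles


def analyze_distortion(
    reference: ClusterModel,
    refined: ClusterModel,
    channel_map: dict[str, str] | None = None,
    axis: PrincipalAxis | None = None,
) -> list[DisplacementRecord]:
    """Full per-atom distortion records: displacement + rotation about the axis."""
    axis = axis if axis is not None else principal_axis(reference)
    records = displacement_field(reference, refined)
    angles = rotation_angles(reference, refined, axis)
    n = axis.direction
    for rec, site in zip(records, reference.sites):
        u = site.position - axis.origin
        u_perp = u - np.dot(u, n) * n
        rec.radial_distance = float(np.linalg.norm(u_perp))
        rec.rotation_angle = angles[rec.label]
        if channel_map is not None:
            rec.channel = channel_map.get(rec.label)
    return records


def channel_stats(
    records: list[DisplacementRecord],
    by: str = "channel",
) -> dict[str, dict[str, float]]:
    """Per-group mean rotation angle and displacement magnitude.

    ``by`` is "channel" or "strand".  On-axis atoms (NaN angle) are excluded
    from the angle mean; empty groups are dropped with a warning.  Each
    group's mean angle carries a ``sense`` label: counterclockwise for
    positive, clockwise for negative (looking down the +axis direction).
    """
    if by not in ("channel", "strand"):
        raise ValidationError("grouping must be 'channel' or 'strand'")
    groups: dict[str, list[DisplacementRecord]] = {}
    for rec in records:
        key = rec.channel if by == "channel" else rec.strand_tag
        if key is None:
            continue
        groups.setdefault(str(key), []).append(rec)
    out: dict[str, dict[str, float]] = {}
    for key in sorted(groups):
        recs = groups[key]
        angles = np.array([r.rotation_angle for r in recs])
        angles = angles[np.isfinite(angles)]
        if len(angles) == 0:
            warnings.warn(f"group {key!r} has no off-axis atoms; excluded", stacklevel=2)
            continue
        mean_angle = float(angles.mean())
        out[key] = {
            "mean_angle_deg": mean_angle,
            "mean_magnitude_A": float(np.mean([r.magnitude for r in recs])),
            "n_atoms": len(recs),
            "sense": "counterclockwise" if mean_angle >= 0 else "clockwise",
        }
    return out
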