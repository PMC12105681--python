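"""Synthetic ground truth: toy clusters, distortion fields, noisy PDFs, backgrounds.

Everything the pipeline consumes can be generated here with a known
answer, so parameter-recovery tests run without any external download.
The toy cluster mimics the motif of the real core — sixteen Ag atoms in
four axial channels around a common axis, capped by two Cl on the axis —
without being the crystal structure itself (users fetch that separately).
The distortion field is the study's model of solution-state change: a
rigid per-channel twist about the principal axis plus isotropic Gaussian
jitter.  Observables add a damped-sine solvation wave and i.i.d. Gaussian
noise on G(r); every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .pdf_engine import RESOLUTION_FLOOR, calc_pdf
from .refinement import SolvationWave
from .structure_io import AtomSite, ClusterModel, PDFCurve

__all__ = [
    "ToyClusterSpec",
    "DistortionSpec",
    "GroundTruth",
    "make_toy_cluster",
    "apply_distortion",
    "simulate_pdf",
    "simulate_dna_background",
    "make_dna_strand_model",
    "make_random_model",
]


@dataclass
class ToyClusterSpec:
    """Geometry of the synthetic 4-channel Ag cluster with axial Cl caps.

    Defaults give 16 Ag + 2 Cl with a nearest Ag-Ag distance equal to the
    axial spacing (2.8 Å, the first-shell metal-metal distance), channels on
    a 2.4 Å radius, and a small helical stagger per layer so the columns are
    genuinely three-dimensional.
    """

    n_channels: int = 4
    atoms_per_channel: int = 4
    channel_radius: float = 2.4      # Å
    axial_spacing: float = 2.8       # Å, also the nearest Ag-Ag target
    cap_distance: float = 2.4        # Å from the terminal Ag layer, on axis
    helix_twist: float = 10.0        # degrees of stagger per layer
    channel_z_stagger: float = 0.7   # Å scale of the irregular per-channel axial offsets
    element: str = "Ag"
    cap_element: str = "Cl"
    n_caps: int = 2

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.atoms_per_channel < 1:
            raise ValidationError("need at least one channel and one atom per channel")
        if self.channel_radius <= 0 or self.axial_spacing <= 0:
            raise ValidationError("radius and spacing must be positive")
        if self.n_caps not in (0, 2):
            raise ValidationError("caps are placed pairwise on the axis (0 or 2)")


@dataclass
class DistortionSpec:
    """Per-channel rigid twist (degrees) about the axis plus Gaussian jitter (Å)."""

    twists: tuple[float, ...] = (9.0, 12.0, -3.0, -3.0)
    jitter: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if any(abs(t) > 30 for t in self.twists):
            raise ValidationError("twists are limited to ±30 degrees")
        if self.jitter < 0:
            raise ValidationError("jitter scale must be >= 0")


@dataclass
class GroundTruth:
    """Reference + distorted models and every generating parameter."""

    reference: ClusterModel
    distorted: ClusterModel
    channel_map: dict[str, str]
    twists: dict[str, float]                 # channel id -> degrees
    displacement: np.ndarray                 # (N, 3) distorted - reference
    wave: SolvationWave | None = None
    noise_sigma: float = 0.0

    def mean_displacement(self) -> float:
        return float(np.linalg.norm(self.displacement, axis=1).mean())


def make_toy_cluster(spec: ToyClusterSpec | None = None) -> tuple[ClusterModel, dict[str, str]]:
    """Build the toy cluster and its per-atom channel map.

    Channels are axial columns starting at equally spaced azimuths, each
    staggered helically by ``helix_twist`` degrees per layer and offset
    axially by an irregular per-channel multiple of ``channel_z_stagger``.
    The irregular axial stagger makes the channels crystallographically
    inequivalent, as in real DNA-templated clusters; a symmetric column
    arrangement (including any palindromic stagger) would make permuted or
    reflected channel distortions homometric — indistinguishable in the
    pair-distance spectrum — and the recovery problem ill-posed.  Raises on
    geometries with overlaps < 1 Å.
    """
    spec = spec if spec is not None else ToyClusterSpec()
    sites: list[AtomSite] = []
    channel_map: dict[str, str] = {}
    z0 = -(spec.atoms_per_channel - 1) * spec.axial_spacing / 2.0
    idx = 0
    z_values: list[float] = []
    # fixed irregular multipliers; irregularity (no palindrome, no arithmetic
    # progression) is what breaks the channel-permutation symmetries
    if spec.n_channels <= 4:
        multipliers = (0.0, 1.0, 0.45, 1.75)[: spec.n_channels]
    else:
        extra = np.random.default_rng(2024).uniform(0.3, 1.9, spec.n_channels)
        extra[0] = 0.0
        multipliers = tuple(extra)
    for c in range(spec.n_channels):
        base_phi = 2.0 * np.pi * c / spec.n_channels
        z_off = spec.channel_z_stagger * multipliers[c]
        for k in range(spec.atoms_per_channel):
            phi = base_phi + np.radians(spec.helix_twist) * k
            idx += 1
            label = f"{spec.element}{idx}"
            z = z0 + k * spec.axial_spacing + z_off
            z_values.append(z)
            pos = np.array(
                [
                    spec.channel_radius * np.cos(phi),
                    spec.channel_radius * np.sin(phi),
                    z,
                ]
            )
            sites.append(AtomSite(spec.element, pos, label=label))
            channel_map[label] = f"ch{c + 1}"
    if spec.n_caps == 2:
        for z_cap, label in (
            (min(z_values) - spec.cap_distance, f"{spec.cap_element}1"),
            (max(z_values) + spec.cap_distance, f"{spec.cap_element}2"),
        ):
            sites.append(
                AtomSite(spec.cap_element, np.array([0.0, 0.0, z_cap]), label=label)
            )
            channel_map[label] = "cap"
    model = ClusterModel(sites, name="toy_cluster")
    pos = model.positions
    iu, ju = np.triu_indices(len(pos), k=1)
    dmin = np.linalg.norm(pos[iu] - pos[ju], axis=1).min()
    if dmin < 1.0:
        raise ValidationError(f"spec produces overlapping atoms (min distance {dmin:.2f} Å)")
    return model, channel_map


def apply_distortion(
    model: ClusterModel,
    channel_map: dict[str, str],
    spec: DistortionSpec,
) -> tuple[ClusterModel, GroundTruth]:
    """Twist each channel rigidly about the principal axis, then add Gaussian jitter.

    Rotations are about the model's principal axis through its centroid, so
    the distortion and the downstream rotation measurement share one frame
    exactly.  Cap atoms (channel id "cap") are not twisted but receive
    jitter like every other atom.  The returned ground truth records the
    exact displacement field and per-channel twists.
    """
    from .geometry import principal_axis

    channels = sorted({c for c in channel_map.values() if c != "cap"})
    if len(spec.twists) != len(channels):
        raise ValidationError(
            f"{len(channels)} channels but {len(spec.twists)} twist angles"
        )
    twist_of = dict(zip(channels, spec.twists))
    rng = np.random.default_rng(spec.seed)
    axis = principal_axis(model)
    n = axis.direction
    pos = model.positions.copy()
    for k, site in enumerate(model.sites):
        ch = channel_map.get(site.label)
        if ch is None:
            raise ValidationError(f"site {site.label!r} missing from channel map")
        if ch == "cap":
            continue
        alpha = np.radians(twist_of[ch])
        if alpha == 0.0:
            continue
        c, s = np.cos(alpha), np.sin(alpha)
        u = pos[k] - axis.origin
        u_par = np.dot(u, n) * n
        u_perp = u - u_par
        pos[k] = axis.origin + u_par + c * u_perp + s * np.cross(n, u_perp)
    pos += rng.normal(0.0, spec.jitter, size=pos.shape) if spec.jitter > 0 else 0.0
    distorted = model.with_positions(pos, name=f"{model.name}_distorted")
    truth = GroundTruth(
        reference=model,
        distorted=distorted,
        channel_map=dict(channel_map),
        twists=twist_of,
        displacement=pos - model.positions,
    )
    return distorted, truth


def simulate_pdf(
    model: ClusterModel,
    wave: SolvationWave | None,
    noise_sigma: float,
    rgrid: np.ndarray,
    seed: int,
    sigma0: float = RESOLUTION_FLOOR,
) -> PDFCurve:
    """Cluster PDF + optional solvation wave + i.i.d. Gaussian noise on G(r).

    ``noise_sigma`` is in absolute G(r) units (pass e.g. 1% of the clean
    curve's maximum); the result is deterministic in the seed.
    """
    rgrid = np.asarray(rgrid, dtype=float)
    clean = calc_pdf(model, rgrid, sigma0=sigma0)
    g = clean.g.copy()
    if wave is not None:
        g = g + wave.evaluate(rgrid)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        g = g + rng.normal(0.0, noise_sigma, size=g.shape)
    return PDFCurve(rgrid, g, meta={"source": "simulate_pdf", "seed": seed,
                                    "noise_sigma": noise_sigma})


def simulate_dna_background(
    level: str,
    rgrid: np.ndarray,
    seed: int,
    noise_sigma: float = 0.002,
) -> PDFCurve:
    """Empirical DNA-like background PDF, "aqueous" or "cluster-bound".

    Aqueous free DNA: sharp bonded-structure peaks below 4 Å (1.46, 2.43,
    3.69 Å), weak packing features near 5.55 and 7.55 Å, all under a
    decaying envelope so the curve is flat (< 1% of its maximum) beyond
    15 Å.  Cluster-bound DNA adds two broad conformational features near
    5.2 and 7.7 Å on top of the aqueous curve.  The small additive noise is
    enveloped the same way and deterministic in the seed.
    """
    if level not in ("aqueous", "cluster-bound"):
        raise ValidationError("level must be 'aqueous' or 'cluster-bound'")
    r = np.asarray(rgrid, dtype=float)

    def gauss(center: float, width: float, amp: float) -> np.ndarray:
        return amp * np.exp(-0.5 * ((r - center) / width) ** 2)

    g = (
        gauss(1.46, 0.06, 1.00)
        + gauss(2.43, 0.08, 0.65)
        + gauss(3.69, 0.18, 0.40)
        + gauss(5.55, 0.45, 0.12)
        + gauss(7.55, 0.55, 0.10)
    )
    if level == "cluster-bound":
        g = g + gauss(5.2, 0.55, 0.22) + gauss(7.7, 0.60, 0.18)
    envelope = np.exp(-np.clip(r - 4.0, 0.0, None) / 3.0)
    g = g * envelope
    rng = np.random.default_rng(seed)
    g = g + rng.normal(0.0, noise_sigma, size=g.shape) * envelope
    return PDFCurve(r, g, meta={"source": f"dna_background:{level}", "seed": seed})


def make_dna_strand_model(
    sequence: str = "CACCTAGCGA",
    seed: int = 0,
    rise: float = 3.4,
    twist: float = 36.0,
    radius: float = 5.0,
    include_backbone: bool = True,
) -> ClusterModel:
    """Synthetic single-stranded DNA stand-in built from nucleotide fragments.

    Each base's RDKit fragment is randomly oriented (seeded) and placed on a
    helical path (B-DNA-like rise and twist).  This is a geometric stand-in
    with realistic local structure but no real backbone connectivity or
    base pairing — sufficient for Biso-broadening and background studies
    that only see the pair-distance spectrum.
    """
    from scipy.spatial.transform import Rotation

    from .dna import fragment_model

    sequence = sequence.upper()
    if not sequence or set(sequence) - set("ACGT"):
        raise ValidationError("sequence must be a nonempty string over ACGT")
    rng = np.random.default_rng(seed)
    sites: list[AtomSite] = []
    counters: dict[str, int] = {}
    for k, base in enumerate(sequence):
        frag = fragment_model(base, include_backbone)
        local = frag.positions - frag.positions.mean(axis=0)
        rot = Rotation.random(rng=rng).as_matrix()
        phi = np.radians(twist) * k
        anchor = np.array([radius * np.cos(phi), radius * np.sin(phi), rise * k])
        placed = local @ rot.T + anchor
        for site, p in zip(frag.sites, placed):
            counters[site.element] = counters.get(site.element, 0) + 1
            sites.append(
                AtomSite(site.element, p, label=f"{site.element}{counters[site.element]}")
            )
    return ClusterModel(sites, name=f"synthetic_dna_{sequence}")


def make_random_model(
    n_atoms: int,
    seed: int,
    elements: tuple[str, ...] = ("C", "N", "O", "P"),
    box: float = 12.0,
    min_distance: float = 1.2,
) -> ClusterModel:
    """Random well-separated atoms in a cube; a generic stand-in structure.

    Used for oracle-equivalence and performance checks where only "some
    molecule-sized set of atoms" matters, not chemistry.
    """
    rng = np.random.default_rng(seed)
    placed = np.empty((0, 3))
    attempts = 0
    while len(placed) < n_atoms:
        p = rng.uniform(0.0, box, size=3)
        if len(placed) == 0 or np.min(np.linalg.norm(placed - p, axis=1)) >= min_distance:
            placed = np.vstack([placed, p])
        attempts += 1
        if attempts > 500 * n_atoms:
            raise ValidationError("could not place atoms; enlarge the box")
    positions = list(placed)
    counters: dict[str, int] = {}
    sites: list[AtomSite] = []
    for k in range(n_atoms):
        e = elements[k % len(elements)]
        counters[e] = counters.get(e, 0) + 1
        sites.append(AtomSite(e, positions[k], label=f"{e}{counters[e]}"))
    return ClusterModel(sites, name=f"random_{n_atoms}")
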