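"""Atomic-structure and scattering-curve containers plus their file formats.

The pipeline works entirely in Cartesian angstroms.  Structures come in as
XYZ, PDB or mmCIF (fractional coordinates in a CIF are converted using the
file's cell at read time); one-dimensional observables travel as two-column
whitespace text with ``#`` comments, the dominant community convention for
reduced-PDF (``.gr``) and reduced-intensity (``.iq``/``.fq``) data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gemmi
import numpy as np

from .exceptions import (
    EmptySelectionError,
    ParseError,
    ValidationError,
)

__all__ = [
    "AtomSite",
    "ClusterModel",
    "PDFCurve",
    "IQCurve",
    "read_xyz",
    "write_xyz",
    "extract_subset",
    "read_gr",
    "write_gr",
    "read_iq",
    "write_iq",
    "read_strand_map",
]

#: Residue names recognised as nucleic acid when selecting DNA from a
#: crystal-structure file.
NUCLEIC_RESIDUES = frozenset(
    {"DA", "DC", "DG", "DT", "DU", "DI", "A", "C", "G", "T", "U", "I"}
)

VALID_STRAND_TAGS = ("A", "B", "both", "none")


def _atomic_number(symbol: str) -> int:
    return gemmi.Element(symbol).atomic_number


@dataclass
class AtomSite:
    """One atomic site: element, Cartesian position (Å), Biso (Å²), identity tags."""

    element: str
    position: np.ndarray
    biso: float = 0.0
    label: str = ""
    strand_tag: str = "none"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValidationError(f"position must be a 3-vector, got {self.position.shape}")
        if not np.all(np.isfinite(self.position)):
            raise ValidationError(f"non-finite position for site {self.label!r}")
        if self.biso < 0:
            raise ValidationError(f"biso must be >= 0, got {self.biso}")
        if _atomic_number(self.element) == 0:
            raise ValidationError(f"unknown element symbol {self.element!r}")
        if self.strand_tag not in VALID_STRAND_TAGS:
            raise ValidationError(
                f"strand_tag must be one of {VALID_STRAND_TAGS}, got {self.strand_tag!r}"
            )


@dataclass
class ClusterModel:
    """An ordered collection of atom sites; the refinable object.

    Labels must be unique so that sites can be paired across a reference
    and a refined copy of the same structure.
    """

    sites: list[AtomSite]
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.sites) < 2:
            raise ValidationError(f"a model needs at least 2 sites, got {len(self.sites)}")
        labels = [s.label for s in self.sites]
        if len(set(labels)) != len(labels):
            raise ValidationError("site labels must be unique within a model")

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) Cartesian coordinates in Å."""
        return np.array([s.position for s in self.sites], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [s.element for s in self.sites]

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.sites]

    @property
    def bisos(self) -> np.ndarray:
        return np.array([s.biso for s in self.sites], dtype=float)

    def element_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.sites:
            counts[s.element] = counts.get(s.element, 0) + 1
        return counts

    def with_positions(self, positions: np.ndarray, name: str | None = None) -> "ClusterModel":
        """Copy of the model with replaced coordinates (same order/labels)."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (len(self.sites), 3):
            raise ValidationError(
                f"expected positions of shape {(len(self.sites), 3)}, got {positions.shape}"
            )
        sites = [
            AtomSite(s.element, p.copy(), s.biso, s.label, s.strand_tag)
            for s, p in zip(self.sites, positions)
        ]
        return ClusterModel(sites, name if name is not None else self.name)

    def with_biso(self, biso: float) -> "ClusterModel":
        """Copy with a uniform isotropic displacement parameter on every site."""
        sites = [
            AtomSite(s.element, s.position.copy(), float(biso), s.label, s.strand_tag)
            for s in self.sites
        ]
        return ClusterModel(sites, self.name)

    def apply_strand_map(self, strand_map: Mapping[str, str]) -> "ClusterModel":
        sites = []
        for s in self.sites:
            if s.label not in strand_map:
                raise KeyError(f"strand map is missing label {s.label!r}")
            sites.append(
                AtomSite(s.element, s.position.copy(), s.biso, s.label, strand_map[s.label])
            )
        return ClusterModel(sites, self.name)


def _check_curve_arrays(x: np.ndarray, y: np.ndarray, xname: str) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
        raise ValidationError(f"{xname} and values must be 1-D arrays of equal length")
    if len(x) and x[0] < 0:
        raise ValidationError(f"{xname} must be non-negative")
    if np.any(np.diff(x) <= 0):
        raise ValidationError(f"{xname} grid must be strictly increasing")
    return x, y


@dataclass
class PDFCurve:
    """A reduced pair distribution function G(r) on a uniform r grid (Å)."""

    r: np.ndarray
    g: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r, self.g = _check_curve_arrays(self.r, self.g, "r")
        if len(self.r) >= 3:
            steps = np.diff(self.r)
            if np.max(np.abs(steps - steps[0])) > 1e-9:
                raise ValidationError("r grid spacing must be constant to within 1e-9")

    @property
    def dr(self) -> float:
        return float(self.r[1] - self.r[0]) if len(self.r) > 1 else 0.0

    def restricted(self, r_lo: float, r_hi: float) -> "PDFCurve":
        """The sub-curve with r_lo <= r <= r_hi."""
        mask = (self.r >= r_lo) & (self.r <= r_hi)
        if not np.any(mask):
            raise ValidationError(f"no grid points in [{r_lo}, {r_hi}]")
        return PDFCurve(self.r[mask], self.g[mask], dict(self.meta))

    def copy(self) -> "PDFCurve":
        return PDFCurve(self.r.copy(), self.g.copy(), dict(self.meta))


@dataclass
class IQCurve:
    """Reduced structure function F(Q) (or scaled intensity) on an ascending Q grid (Å⁻¹)."""

    q: np.ndarray
    y: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q, self.y = _check_curve_arrays(self.q, self.y, "q")

    def copy(self) -> "IQCurve":
        return IQCurve(self.q.copy(), self.y.copy(), dict(self.meta))


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def read_xyz(path: str | Path) -> ClusterModel:
    """Read a standard XYZ file (count line, comment line, element x y z rows).

    Biso defaults to 0 on every site; labels are auto-generated as
    ``<element><1-based running index>``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        natoms = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"{path}: malformed atom-count line {lines[0]!r}") from exc
    if len(lines) < natoms + 2:
        raise ParseError(f"{path}: expected {natoms} atom rows, file too short")
    comment = lines[1].strip()
    sites: list[AtomSite] = []
    counters: dict[str, int] = {}
    for row in lines[2 : 2 + natoms]:
        parts = row.split()
        if len(parts) < 4:
            raise ParseError(f"{path}: malformed atom row {row!r}")
        element = parts[0]
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric coordinate in {row!r}") from exc
        counters[element] = counters.get(element, 0) + 1
        sites.append(AtomSite(element, np.array(xyz), 0.0, f"{element}{counters[element]}"))
    return ClusterModel(sites, name=comment or path.stem)


def write_xyz(model: ClusterModel, path: str | Path, comment: str | None = None) -> None:
    path = Path(path)
    lines = [str(len(model.sites)), comment if comment is not None else model.name]
    for s in model.sites:
        x, y, z = s.position
        lines.append(f"{s.element} {x:.6f} {y:.6f} {z:.6f}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PDB / mmCIF subset extraction
# ---------------------------------------------------------------------------

def extract_subset(
    path: str | Path,
    elements: Iterable[str] | None = None,
    chains: Iterable[str] | None = None,
    nucleic_only: bool = False,
) -> ClusterModel:
    """Extract a subset of atoms from a PDB or mmCIF file as a :class:`ClusterModel`.

    Exactly one selection mode is applied: an element list (e.g. ``{"Ag", "Cl"}``
    to pull a metal/halide core out of a crystal structure), a chain list, or
    ``nucleic_only=True`` for all atoms of nucleic-acid residues.  Coordinates
    are returned in Cartesian Å; mmCIF fractional coordinates are converted
    with the file's cell by the reader.  Biso values present in the file are
    carried over (gemmi stores them directly as B-factors).
    """
    selectors = sum([elements is not None, chains is not None, nucleic_only])
    if selectors != 1:
        raise ValidationError("give exactly one of elements=, chains=, nucleic_only=True")
    if elements is not None:
        elements = {str(e).capitalize() for e in elements}
        if not elements:
            raise ValidationError("element selector must be nonempty")
    if chains is not None:
        chains = set(chains)
        if not chains:
            raise ValidationError("chain selector must be nonempty")

    path = Path(path)
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(structure) == 0:
        raise ParseError(f"{path}: no models in structure file")

    sites: list[AtomSite] = []
    counters: dict[str, int] = {}
    model = structure[0]
    for chain in model:
        if chains is not None and chain.name not in chains:
            continue
        for residue in chain:
            if nucleic_only and residue.name.strip() not in NUCLEIC_RESIDUES:
                continue
            for atom in residue:
                symbol = atom.element.name
                if elements is not None and symbol not in elements:
                    continue
                counters[symbol] = counters.get(symbol, 0) + 1
                pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                sites.append(
                    AtomSite(symbol, pos, max(float(atom.b_iso), 0.0),
                             f"{symbol}{counters[symbol]}")
                )
    if not sites:
        raise EmptySelectionError(f"{path}: selection matched no atoms")
    if len(sites) == 1:
        raise EmptySelectionError(f"{path}: selection matched a single atom; need >= 2")
    return ClusterModel(sites, name=path.stem)


# ---------------------------------------------------------------------------
# Two-column curve text
# ---------------------------------------------------------------------------

def _read_two_column(path: Path) -> tuple[np.ndarray, np.ndarray]:
    xs: list[float] = []
    ys: list[float] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) < 2:
            raise ParseError(f"{path}:{lineno}: expected two columns, got {line!r}")
        try:
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric token in {line!r}") from exc
    if len(xs) < 2:
        raise ParseError(f"{path}: need at least 2 data rows, got {len(xs)}")
    return np.array(xs), np.array(ys)


def read_gr(path: str | Path) -> PDFCurve:
    """Read a two-column r/G(r) text file ('#' comments allowed)."""
    path = Path(path)
    r, g = _read_two_column(path)
    return PDFCurve(r, g, meta={"source": str(path)})


def write_gr(curve: PDFCurve, path: str | Path, header: str | None = None) -> None:
    """Write a PDF curve as two-column text; meta entries go into '#' comments."""
    path = Path(path)
    lines = []
    if header:
        lines.append(f"# {header}")
    for key, value in curve.meta.items():
        lines.append(f"# {key}: {value}")
    lines.append("# r(A)  G(r)")
    for r, g in zip(curve.r, curve.g):
        lines.append(f"{r:.12g} {g:.12g}")
    path.write_text("\n".join(lines) + "\n")


def read_iq(path: str | Path) -> IQCurve:
    """Read a two-column Q/F(Q) (or intensity) text file."""
    path = Path(path)
    q, y = _read_two_column(path)
    return IQCurve(q, y, meta={"source": str(path)})


def write_iq(curve: IQCurve, path: str | Path, header: str | None = None) -> None:
    path = Path(path)
    lines = []
    if header:
        lines.append(f"# {header}")
    for key, value in curve.meta.items():
        lines.append(f"# {key}: {value}")
    lines.append("# Q(1/A)  F(Q)")
    for q, y in zip(curve.q, curve.y):
        lines.append(f"{q:.8g} {y:.10g}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Strand map
# ---------------------------------------------------------------------------

def read_strand_map(path: str | Path) -> dict[str, str]:
    """Read a CSV mapping site label -> strand tag (A, B, both, none).

    Accepts an optional ``label,strand_tag`` header row.  The map records
    which DNA strand coordinates each metal site; it is supplied by the user
    from inspection of the crystal contacts, not computed.
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].strip().startswith("#"):
                continue
            if len(row) < 2:
                raise ParseError(f"{path}: expected two CSV columns, got {row!r}")
            label, tag = row[0].strip(), row[1].strip()
            if label.lower() == "label" and tag.lower() == "strand_tag":
                continue  # header
            if tag not in VALID_STRAND_TAGS:
                raise ValidationError(
                    f"{path}: unknown strand tag {tag!r} for {label!r}; "
                    f"must be one of {VALID_STRAND_TAGS}"
                )
            if label in mapping:
                raise ValidationError(f"{path}: duplicate label {label!r}")
            mapping[label] = tag
    if not mapping:
        raise ParseError(f"{path}: no entries")
    return mapping
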