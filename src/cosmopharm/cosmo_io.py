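"""Reading and writing COSMO files.

A COSMO file is the text output of a continuum-solvation quantum calculation:
it lists the molecular cavity's surface segments (position, area, screening
charge) together with the total cavity surface area and volume.  Two text
layouts are supported:

* ``dmol3`` — the layout written by :func:`write_cosmo_file`, modelled on the
  DMol3 ``.cosmo`` file (sections ``$coordinates`` and
  ``$segment_information``, lengths in Å).
* ``vt`` — a VT-database-style layout whose numeric sections are annotated
  ``(au)``; positions/areas/volumes are stored in atomic units (bohr) and
  converted to Å at parse time.

Internal canonical units are Å, Å², Å³ and elementary charge e; conversion
happens at parse time only.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SegmentRecord",
    "CosmoMolecule",
    "CosmoParseError",
    "CosmoValidationError",
    "parse_cosmo_file",
    "write_cosmo_file",
    "read_cosmo",
    "atom_hb_classes",
    "segment_hb_classes",
    "BOHR_TO_ANGSTROM",
]

BOHR_TO_ANGSTROM = 0.529177

#: Covalent radii in Å (Cordero et al. consensus values) used for bond
#: detection; a pair of atoms closer than 1.25x the radius sum is bonded.
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}

BOND_SCALE = 1.25

#: Net-charge tolerance (e): the conductor neutralizes the molecule, so the
#: summed segment charges of a valid file are essentially zero.
NET_CHARGE_TOL = 0.01


class CosmoParseError(ValueError):
    """A required section or header of the COSMO file is missing/malformed."""


class CosmoValidationError(ValueError):
    """The parsed molecule violates a physical consistency invariant."""


@dataclass
class SegmentRecord:
    """One cavity surface segment.

    ``charge_density`` is the raw (un-averaged) screening charge density
    sigma* in e/Å²; ``atom_index`` is 1-based and references the parent atom.
    """

    index: int
    atom_index: int
    position: np.ndarray  # (3,) Å
    charge: float  # e
    area: float  # Å²
    charge_density: float  # e/Å²
    potential: float = 0.0  # parsed, unused

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.area <= 0:
            raise CosmoValidationError(
                f"segment {self.index}: area must be positive, got {self.area}"
            )


@dataclass
class CosmoMolecule:
    """A parsed COSMO file: cavity geometry plus the segment table."""

    name: str
    total_area: float  # Å²
    cavity_volume: float  # Å³
    atoms: list  # list of (element symbol, (3,) position Å)
    segments: list = field(default_factory=list)

    @property
    def net_charge(self) -> float:
        return float(sum(s.charge for s in self.segments))

    @property
    def segment_area_sum(self) -> float:
        return float(sum(s.area for s in self.segments))

    def segment_arrays(self):
        """Positions (n,3), areas (n,) and charge densities (n,) as arrays."""
        pos = np.array([s.position for s in self.segments], dtype=float)
        areas = np.array([s.area for s in self.segments], dtype=float)
        sigmas = np.array([s.charge_density for s in self.segments], dtype=float)
        return pos, areas, sigmas

    def validate(self) -> None:
        if not self.segments:
            raise CosmoValidationError(f"{self.name}: molecule has no segments")
        if self.total_area <= 0 or self.cavity_volume <= 0:
            raise CosmoValidationError(
                f"{self.name}: non-positive cavity area/volume"
            )
        area_sum = self.segment_area_sum
        if abs(area_sum - self.total_area) > 0.02 * self.total_area:
            raise CosmoValidationError(
                f"{self.name}: header area {self.total_area:.4f} A^2 differs from "
                f"segment-table sum {area_sum:.4f} A^2 by more than 2%"
            )
        n_atoms = len(self.atoms)
        for s in self.segments:
            if not (1 <= s.atom_index <= n_atoms):
                raise CosmoValidationError(
                    f"{self.name}: segment {s.index} references atom "
                    f"{s.atom_index} but molecule has {n_atoms} atoms"
                )
        net = self.net_charge
        if abs(net) > NET_CHARGE_TOL:
            raise CosmoValidationError(
                f"{self.name}: residual net charge {net:+.5f} e exceeds "
                f"{NET_CHARGE_TOL} e"
            )


# ---------------------------------------------------------------------------
# hydrogen-bonding classification (needed by the three-part sigma profile)
# ---------------------------------------------------------------------------

def _bond_matrix(atoms) -> np.ndarray:
    """Boolean bond adjacency from the interatomic-distance cutoff."""
    n = len(atoms)
    bonded = np.zeros((n, n), dtype=bool)
    for i in range(n):
        ei, pi = atoms[i][0], np.asarray(atoms[i][1], dtype=float)
        ri = COVALENT_RADII.get(ei, 0.77)
        for j in range(i + 1, n):
            ej, pj = atoms[j][0], np.asarray(atoms[j][1], dtype=float)
            rj = COVALENT_RADII.get(ej, 0.77)
            cutoff = BOND_SCALE * (ri + rj)
            if np.linalg.norm(pi - pj) < cutoff:
                bonded[i, j] = bonded[j, i] = True
    return bonded


def atom_hb_classes(mol: CosmoMolecule) -> list:
    """Hydrogen-bonding class per atom: ``OH``, ``OT`` or ``NHB``.

    Oxygen atoms and hydrogens covalently bonded to oxygen are ``OH``;
    nitrogen, fluorine and hydrogens bonded to N/F are ``OT``; everything
    else is non-hydrogen-bonding.  An O-bonded hydrogen that is also within
    bonding distance of N/F counts as ``OH`` (hydroxyl takes precedence).
    """
    bonded = _bond_matrix(mol.atoms)
    classes = []
    elements = [a[0] for a in mol.atoms]
    for i, el in enumerate(elements):
        if el == "O":
            classes.append("OH")
        elif el in ("N", "F"):
            classes.append("OT")
        elif el == "H":
            partners = {elements[j] for j in np.nonzero(bonded[i])[0]}
            if "O" in partners:
                classes.append("OH")
            elif partners & {"N", "F"}:
                classes.append("OT")
            else:
                classes.append("NHB")
        else:
            classes.append("NHB")
    return classes


def segment_hb_classes(mol: CosmoMolecule) -> list:
    """Hydrogen-bonding class of the atom beneath each segment."""
    per_atom = atom_hb_classes(mol)
    return [per_atom[s.atom_index - 1] for s in mol.segments]


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_cosmo_file(mol: CosmoMolecule) -> str:
    """Serialize a molecule to the dmol3-dialect text layout.

    Deterministic (pure formatting): equal molecules produce byte-equal
    output.  Raises :class:`CosmoValidationError` on invariant violations.
    """
    mol.validate()
    lines = [
        "DMol3/COSMO Results",
        f"molecule = {mol.name}",
        f"n_atoms = {len(mol.atoms)}",
        f"n_segments = {len(mol.segments)}",
        f"Total surface area of cavity (A**2) = {mol.total_area:.10f}",
        f"Total volume of cavity (A**3) = {mol.cavity_volume:.10f}",
        "",
        "$coordinates (A)",
    ]
    for i, (el, pos) in enumerate(mol.atoms, start=1):
        p = np.asarray(pos, dtype=float)
        lines.append(
            f"{i:5d}  {el:<2s} {p[0]: .10e} {p[1]: .10e} {p[2]: .10e}"
        )
    lines.append("$end")
    lines.append("")
    lines.append("$segment_information (A)")
    lines.append(
        "# n  atom        x               y               z        "
        "     charge          area        charge/area      potential"
    )
    for s in mol.segments:
        p = s.position
        lines.append(
            f"{s.index:5d} {s.atom_index:5d} {p[0]: .10e} {p[1]: .10e} "
            f"{p[2]: .10e} {s.charge: .10e} {s.area: .10e} "
            f"{s.charge_density: .10e} {s.potential: .10e}"
        )
    lines.append("$end")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_FLOAT = r"[-+]?\d*\.?\d+(?:[eEdD][-+]?\d+)?"


def _to_float(tok: str) -> float:
    return float(tok.replace("D", "e").replace("d", "e"))


def _detect_dialect(text: str) -> str:
    if "DMol3" in text or "$segment_information" in text:
        return "dmol3"
    if "COSMO RESULTS" in text or "SEGMENT INFORMATION" in text:
        return "vt"
    raise CosmoParseError(
        "cannot auto-detect COSMO dialect: no DMol3 or VT sentinel found"
    )


def _header_value(text: str, patterns, what: str) -> tuple:
    """Return (value, is_atomic_units) for the first matching header line."""
    for pat, au in patterns:
        m = re.search(pat, text)
        if m:
            return _to_float(m.group(1)), au
    raise CosmoParseError(f"missing header line: {what}")


def parse_cosmo_file(text: str, dialect: str = "auto") -> CosmoMolecule:
    """Parse COSMO-file text into a validated :class:`CosmoMolecule`.

    ``dialect`` is ``dmol3``, ``vt`` or ``auto`` (sentinel detection).
    Atomic-unit sections (VT layout, annotated ``(au)``) are converted to
    Å / Å² / Å³ / e·Å⁻².
    """
    if dialect == "auto":
        dialect = _detect_dialect(text)
    if dialect not in ("dmol3", "vt"):
        raise ValueError(f"unknown dialect {dialect!r}")

    area, area_au = _header_value(
        text,
        [
            (rf"[Ss]urface area of (?:a )?cavity \(A\*\*2\)\s*=?\s*({_FLOAT})", False),
            (rf"[Ss]urface area of (?:a )?cavity \(au\)\s*=?\s*({_FLOAT})", True),
        ],
        "total surface area of cavity",
    )
    volume, vol_au = _header_value(
        text,
        [
            (rf"[Vv]olume of cavity \(A\*\*3\)\s*=?\s*({_FLOAT})", False),
            (rf"[Vv]olume of cavity \(au\)\s*=?\s*({_FLOAT})", True),
        ],
        "total volume of cavity",
    )
    m = re.search(r"molecule\s*=\s*(\S+)", text)
    name = m.group(1) if m else "unnamed"

    coord_m = re.search(
        r"\$coordinates\s*(\((?:A|au)\))?\s*\n(.*?)\$end", text, re.S
    )
    if coord_m is None:
        raise CosmoParseError("missing section: $coordinates")
    coord_au = coord_m.group(1) == "(au)"
    atoms = []
    for line in coord_m.group(2).splitlines():
        toks = line.split()
        if len(toks) < 5 or line.lstrip().startswith("#"):
            continue
        el = toks[1]
        pos = np.array([_to_float(t) for t in toks[2:5]])
        if coord_au:
            pos = pos * BOHR_TO_ANGSTROM
        atoms.append((el, pos))
    if not atoms:
        raise CosmoParseError("empty $coordinates section")

    seg_m = re.search(
        r"\$(?:segment_information|SEGMENT INFORMATION)\s*(\((?:A|au)\))?\s*\n(.*?)\$end",
        text,
        re.S,
    ) or re.search(r"SEGMENT INFORMATION\s*(\((?:A|au)\))?\s*\n(.*)", text, re.S)
    if seg_m is None:
        raise CosmoParseError("missing section: segment information")
    seg_au = seg_m.group(1) == "(au)" or (dialect == "vt" and seg_m.group(1) is None)

    len_f = BOHR_TO_ANGSTROM if seg_au else 1.0
    segments = []
    for line in seg_m.group(2).splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith(("#", "$")):
            continue
        toks = stripped.split()
        if len(toks) < 8:
            continue
        idx, atom_idx = int(toks[0]), int(toks[1])
        pos = np.array([_to_float(t) for t in toks[2:5]]) * len_f
        charge = _to_float(toks[5])
        seg_area = _to_float(toks[6]) * len_f**2
        sigma = _to_float(toks[7]) / len_f**2
        potential = _to_float(toks[8]) if len(toks) > 8 else 0.0
        if seg_area > 0 and abs(charge) > 1e-12:
            implied = charge / seg_area
            if abs(implied - sigma) > 1e-6 * max(abs(sigma), 1e-30):
                raise CosmoValidationError(
                    f"segment {idx}: charge/area {implied:.8g} inconsistent "
                    f"with stored charge density {sigma:.8g}"
                )
        segments.append(
            SegmentRecord(idx, atom_idx, pos, charge, seg_area, sigma, potential)
        )
    if not segments:
        raise CosmoParseError("segment information section contains no rows")

    mol = CosmoMolecule(
        name=name,
        total_area=area * (BOHR_TO_ANGSTROM**2 if area_au else 1.0),
        cavity_volume=volume * (BOHR_TO_ANGSTROM**3 if vol_au else 1.0),
        atoms=atoms,
        segments=segments,
    )
    mol.validate()
    return mol


def read_cosmo(path, dialect: str = "auto") -> CosmoMolecule:
    with open(path) as fh:
        return parse_cosmo_file(fh.read(), dialect=dialect)


def write_vt_style(mol: CosmoMolecule) -> str:
    """Serialize to the VT-style atomic-unit layout (used for unit tests)."""
    mol.validate()
    b = BOHR_TO_ANGSTROM
    lines = [
        "COSMO RESULTS",
        f"molecule = {mol.name}",
        f"Total surface area of a cavity (au) = {mol.total_area / b**2:.10f}",
        f"Total volume of cavity (au) = {mol.cavity_volume / b**3:.10f}",
        "",
        "$coordinates (au)",
    ]
    for i, (el, pos) in enumerate(mol.atoms, start=1):
        p = np.asarray(pos, dtype=float) / b
        lines.append(f"{i:5d}  {el:<2s} {p[0]: .10e} {p[1]: .10e} {p[2]: .10e}")
    lines.append("$end")
    lines.append("$segment_information (au)")
    for s in mol.segments:
        p = s.position / b
        lines.append(
            f"{s.index:5d} {s.atom_index:5d} {p[0]: .10e} {p[1]: .10e} "
            f"{p[2]: .10e} {s.charge: .10e} {s.area / b**2: .10e} "
            f"{s.charge_density * b**2: .10e} {s.potential: .10e}"
        )
    lines.append("$end")
    return "\n".join(lines) + "\n"
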