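"""Sigma profiles: the molecular fingerprint COSMO-SAC operates on.

The raw screening-charge densities of a COSMO cavity are first spatially
averaged over neighbouring segments, then histogrammed onto a fixed 51-point
charge-density grid spanning -0.025 ... 0.025 e/Å² in 0.001 steps.  The
resulting probability profile p(σ), together with the total cavity area A,
carries all molecular information the segment-activity theory needs.

For the 2010 revision the profile is split into three parts — hydroxyl (OH),
other hydrogen-bonding surface (N, F and their hydrogens; OT) and the
non-hydrogen-bonding remainder (NHB) — using a Gaussian switching factor
1 - exp(-σ²/σ_o²) that removes hydrogen-bonding character near σ = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cosmo_io import CosmoMolecule, segment_hb_classes

__all__ = [
    "SIGMA_GRID",
    "SIGMA_STEP",
    "AveragedSegment",
    "SigmaProfile",
    "SplitSigmaProfile",
    "average_charges",
    "build_profile",
    "split_profile",
    "mixture_profile",
    "profile_from_molecule",
    "split_profile_from_molecule",
    "R_AVE_DEFAULT",
    "SIGMA_O_DEFAULT",
]

SIGMA_STEP = 0.001
SIGMA_GRID = np.round(np.linspace(-0.025, 0.025, 51), 6)

#: Averaging radius (Å), the VT-database value.
R_AVE_DEFAULT = 0.81764
#: Hydrogen-bonding switching width (e/Å²) for the three-part split.
SIGMA_O_DEFAULT = 0.007

HB_CLASSES = ("NHB", "OH", "OT")


@dataclass
class AveragedSegment:
    """A segment after charge averaging: σ_m, its area and its HB class."""

    charge_density: float  # e/Å²
    area: float  # Å²
    hb_class: str = "NHB"

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError(f"segment area must be positive, got {self.area}")
        if self.hb_class not in HB_CLASSES:
            raise ValueError(f"unknown hb class {self.hb_class!r}")


@dataclass
class SigmaProfile:
    """51-bin probability profile p(σ) with the molecule's total area (Å²)."""

    p: np.ndarray
    total_area: float
    grid: np.ndarray = field(default_factory=lambda: SIGMA_GRID.copy())

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (51,):
            raise ValueError("sigma profile must have 51 bins")

    @property
    def area(self) -> np.ndarray:
        """Per-bin surface area A(σ) = p(σ) * total_area (Å²)."""
        return self.p * self.total_area

    def validate(self, rtol: float = 1e-8) -> None:
        if np.any(self.p < -1e-12):
            raise ValueError("sigma profile has negative probabilities")
        s = float(self.p.sum())
        if abs(s - 1.0) > rtol:
            raise ValueError(f"sigma profile not normalized: sum p = {s!r}")


@dataclass
class SplitSigmaProfile:
    """Three-part profile: NHB + OH + OT parts that sum to the full p(σ)."""

    nhb: np.ndarray
    oh: np.ndarray
    ot: np.ndarray
    total_area: float
    sigma_o: float = SIGMA_O_DEFAULT
    grid: np.ndarray = field(default_factory=lambda: SIGMA_GRID.copy())

    def __post_init__(self) -> None:
        for name in ("nhb", "oh", "ot"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (51,):
                raise ValueError(f"{name} part must have 51 bins")
            setattr(self, name, arr)

    @property
    def combined(self) -> np.ndarray:
        return self.nhb + self.oh + self.ot

    def part(self, cls: str) -> np.ndarray:
        return {"NHB": self.nhb, "OH": self.oh, "OT": self.ot}[cls]

    def as_profile(self) -> SigmaProfile:
        return SigmaProfile(self.combined, self.total_area)


# ---------------------------------------------------------------------------
# averaging
# ---------------------------------------------------------------------------

def average_charges(mol: CosmoMolecule, r_ave: float = R_AVE_DEFAULT):
    """Spatially average raw charge densities.

    σ_m is the distance-weighted mean of all raw σ*_n with weights
    ``r_ave² r_n² / (r_ave² + r_n²) · exp(-d_mn² / (r_ave² + r_n²))`` where
    r_n = (A_n/π)^0.5 and d_mn is the inter-segment distance.  Each segment
    (including itself, d_mm = 0) contributes to every average; areas are
    left untouched.  Returns one :class:`AveragedSegment` per input segment,
    tagged with its hydrogen-bonding class.
    """
    if r_ave <= 0:
        raise ValueError("r_ave must be positive")
    if not mol.segments:
        raise ValueError("molecule has no segments")
    pos, areas, sigmas = mol.segment_arrays()
    rn2 = areas / np.pi  # r_n², (n,)
    denom = r_ave**2 + rn2  # (n,)
    radial = (r_ave**2 * rn2) / denom  # (n,)
    # pairwise squared distances d_mn², (m, n)
    diff = pos[:, None, :] - pos[None, :, :]
    d2 = np.einsum("mnk,mnk->mn", diff, diff)
    w = radial[None, :] * np.exp(-d2 / denom[None, :])
    sigma_avg = (w @ sigmas) / w.sum(axis=1)
    classes = segment_hb_classes(mol)
    return [
        AveragedSegment(float(s), float(a), c)
        for s, a, c in zip(sigma_avg, areas, classes)
    ]


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def _bin_areas(segments) -> np.ndarray:
    """Apportion segment areas onto the grid by linear interpolation.

    A segment at σ between grid points σ_left and σ_right contributes
    (1-w)·A to the left point and w·A to the right, with
    w = (σ - σ_left)/0.001.  |σ| beyond the grid edge is clamped to the edge
    bin with a warning.
    """
    areas = np.zeros(51)
    clamped = 0
    for seg in segments:
        s, a = seg.charge_density, seg.area
        if s <= SIGMA_GRID[0]:
            if s < SIGMA_GRID[0] - 1e-12:
                clamped += 1
            areas[0] += a
            continue
        if s >= SIGMA_GRID[-1]:
            if s > SIGMA_GRID[-1] + 1e-12:
                clamped += 1
            areas[-1] += a
            continue
        t = (s - SIGMA_GRID[0]) / SIGMA_STEP
        j = int(np.floor(t))
        w = t - j
        areas[j] += (1.0 - w) * a
        areas[j + 1] += w * a
    if clamped:
        warnings.warn(
            f"{clamped} segment(s) with |sigma| > 0.025 e/A^2 clamped to the "
            "edge bin",
            stacklevel=3,
        )
    return areas


def build_profile(segments) -> SigmaProfile:
    """Histogram averaged segments into a normalized 51-bin sigma profile."""
    if not segments:
        raise ValueError("no segments to bin")
    areas = _bin_areas(segments)
    total = areas.sum()
    prof = SigmaProfile(areas / total, float(total))
    prof.validate()
    return prof


def split_profile(segments, sigma_o: float = SIGMA_O_DEFAULT) -> SplitSigmaProfile:
    """Split a profile into NHB/OH/OT parts.

    The hydroxyl and other-HB parts receive, bin-wise, the fraction
    ``A^cls/(A^OH + A^OT) · p(σ) · (1 - exp(-σ²/σ_o²))`` of the probability;
    the NHB part is the remainder, so the three parts sum exactly to the
    unsplit profile.
    """
    if sigma_o <= 0:
        raise ValueError("sigma_o must be positive")
    full = build_profile(segments)
    a_oh = _bin_areas([s for s in segments if s.hb_class == "OH"])
    a_ot = _bin_areas([s for s in segments if s.hb_class == "OT"])
    hb_total = a_oh + a_ot
    gauss = 1.0 - np.exp(-(SIGMA_GRID**2) / sigma_o**2)
    frac_oh = np.divide(a_oh, hb_total, out=np.zeros(51), where=hb_total > 0)
    frac_ot = np.divide(a_ot, hb_total, out=np.zeros(51), where=hb_total > 0)
    p_oh = frac_oh * full.p * gauss
    p_ot = frac_ot * full.p * gauss
    p_nhb = full.p - p_oh - p_ot
    return SplitSigmaProfile(p_nhb, p_oh, p_ot, full.total_area, sigma_o)


def mixture_profile(profiles, x, areas=None) -> SigmaProfile:
    """Mole-fraction/area-weighted mixture profile.

    ``P_S(σ) = Σ_i x_i A_i p_i(σ) / Σ_i x_i A_i`` with A_i the total
    molecular areas (taken from the profiles when ``areas`` is omitted).
    """
    x = np.asarray(x, dtype=float)
    if areas is None:
        areas = [p.total_area for p in profiles]
    areas = np.asarray(areas, dtype=float)
    if not (len(profiles) == len(x) == len(areas)):
        raise ValueError("profiles, x and areas must have equal lengths")
    if np.any(x < 0) or abs(x.sum() - 1.0) > 1e-9:
        raise ValueError("mole fractions must be nonnegative and sum to 1")
    w = x * areas
    total = w.sum()
    if total <= 0:
        raise ValueError("mixture has zero total surface area")
    p = sum(wi * prof.p for wi, prof in zip(w, profiles)) / total
    return SigmaProfile(p, float(total))


# ---------------------------------------------------------------------------
# convenience pipeline
# ---------------------------------------------------------------------------

def profile_from_molecule(
    mol: CosmoMolecule, r_ave: float = R_AVE_DEFAULT
) -> SigmaProfile:
    return build_profile(average_charges(mol, r_ave))


def split_profile_from_molecule(
    mol: CosmoMolecule,
    r_ave: float = R_AVE_DEFAULT,
    sigma_o: float = SIGMA_O_DEFAULT,
) -> SplitSigmaProfile:
    return split_profile(average_charges(mol, r_ave), sigma_o)


def profile_to_text(profile: SigmaProfile) -> str:
    """51 rows of 'sigma  A(sigma)' (Å² per bin), VT-database-compatible."""
    rows = [
        f"{s: .4f}  {a:.8e}" for s, a in zip(SIGMA_GRID, profile.area)
    ]
    return "\n".join(rows) + "\n"


def split_profile_to_text(sp: SplitSigmaProfile) -> str:
    """51 rows of 'sigma  A_nhb  A_oh  A_ot' (Å² per bin)."""
    rows = [
        f"{s: .4f}  {n * sp.total_area:.8e}  {o * sp.total_area:.8e}  "
        f"{t * sp.total_area:.8e}"
        for s, n, o, t in zip(SIGMA_GRID, sp.nhb, sp.oh, sp.ot)
    ]
    return "\n".join(rows) + "\n"
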