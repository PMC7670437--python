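"""Synthetic inputs: toy COSMO molecules and noisy solubility studies.

The pipeline's natural inputs are quantum-chemistry COSMO files and
literature solubility compilations, neither of which can be regenerated at
desk scale.  This module produces controlled stand-ins:

* :func:`make_toy_molecule` builds a spherical-cavity molecule whose segment
  charge structure is chosen by pattern — apolar (all |σ| below the
  hydrogen-bond cutoff 0.0084 e/Å², so HB terms are exactly zero),
  donor/acceptor patches beyond the cutoff, or uniform.  The toys exercise
  the model mathematics, not chemistry.
* :func:`make_solubility_dataset` draws a "measured" solubility curve from a
  known generating model with multiplicative log-normal noise, returning
  both the noisy data and the noiseless truth for recovery tests.
* :func:`bundled_hansen_table` exposes the embedded Hansen-parameter /
  molar-volume fixture for 13 solvents and 29 drugs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .activity import HansenRecord
from .cosmo_io import CosmoMolecule, SegmentRecord
from .equilibria import FusionProperties, ideal_ln_solubility
from .stats import PairedSeries

__all__ = [
    "ToyMoleculeSpec",
    "SyntheticSolubilityStudy",
    "make_toy_molecule",
    "make_solubility_dataset",
    "bundled_hansen_table",
    "hansen_lookup",
]

PATTERNS = ("neutral-apolar", "donor-acceptor-pair", "uniform")

#: Patch charge density (e/Å²) for the donor-acceptor pattern; beyond the
#: 2002 hydrogen-bonding cutoff 0.0084 so the HB energy activates.
PATCH_SIGMA = 0.012


@dataclass(frozen=True)
class ToyMoleculeSpec:
    """Recipe for a synthetic spherical-cavity molecule."""

    n_segments: int = 60
    total_area: float = 150.0  # Å²
    cavity_volume: float | None = None  # Å³; sphere volume when omitted
    charge_pattern: str = "neutral-apolar"
    uniform_sigma: float = 0.0  # only for the 'uniform' pattern
    hb_fraction: float = 0.0  # fraction of area tagged OH (donor/acceptor)
    seed: int = 0

    def __post_init__(self):
        if self.n_segments < 1:
            raise ValueError("need at least one segment")
        if self.total_area <= 0:
            raise ValueError("total area must be positive")
        if self.cavity_volume is not None and self.cavity_volume <= 0:
            raise ValueError("cavity volume must be positive")
        if self.charge_pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.charge_pattern!r}")
        if not 0.0 <= self.hb_fraction <= 1.0:
            raise ValueError("hb_fraction must lie in [0, 1]")
        if self.hb_fraction > 0 and self.n_segments < 2:
            raise ValueError(
                "hydrogen-bonding patches need at least two segments"
            )


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """n roughly equidistant points on a sphere, ordered pole to pole."""
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    phi = k * math.pi * (3.0 - math.sqrt(5.0))
    rho = np.sqrt(np.maximum(1.0 - z**2, 0.0))
    return radius * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def make_toy_molecule(spec: ToyMoleculeSpec) -> CosmoMolecule:
    """Build a valid :class:`CosmoMolecule` from a toy spec.

    Segments sit on a sphere whose area equals ``total_area``; every segment
    has equal area.  Charge densities follow the pattern and are shifted so
    the net charge is exactly zero (the shift touches only the background
    segments, leaving donor/acceptor patches beyond the cutoff).  The same
    spec and seed always produce the identical molecule.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_segments
    radius = math.sqrt(spec.total_area / (4.0 * math.pi))
    volume = (
        spec.cavity_volume
        if spec.cavity_volume is not None
        else 4.0 / 3.0 * math.pi * radius**3
    )
    positions = _fibonacci_sphere(n, radius)
    if n > 1:
        # seed-dependent rigid orientation so distinct seeds give distinct
        # geometries; drawn before the charges so both depend on the seed
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        positions = positions @ q.T
    seg_area = spec.total_area / n

    sigmas = np.zeros(n)
    is_patch = np.zeros(n, dtype=bool)
    if spec.charge_pattern == "uniform":
        sigmas[:] = spec.uniform_sigma
    elif spec.charge_pattern == "neutral-apolar":
        sigmas = rng.uniform(-0.004, 0.004, size=n)
    else:  # donor-acceptor-pair
        frac = spec.hb_fraction if spec.hb_fraction > 0 else 0.25
        k = max(1, int(round(frac * n / 2.0)))
        if 2 * k >= n:
            k = (n - 1) // 2 or 1
        sigmas = rng.uniform(-0.004, 0.004, size=n)
        # polar caps: the Fibonacci ordering runs pole to pole
        sigmas[:k] = PATCH_SIGMA  # acceptor patch (on O)
        sigmas[-k:] = -PATCH_SIGMA  # donor patch (on hydroxyl H)
        is_patch[:k] = True
        is_patch[-k:] = True

    # neutralize via the non-patch background only; the uniform pattern is
    # left untouched (validation rejects it when the net charge is infeasible)
    bg = ~is_patch
    if spec.charge_pattern != "uniform" and bg.any():
        total = sigmas @ np.full(n, seg_area)
        sigmas[bg] -= total / (seg_area * bg.sum())

    # atoms: a carbon core; O/H pair (bonded) when patches are present
    atoms = [("C", np.zeros(3))]
    atom_idx = np.ones(n, dtype=int)
    if is_patch.any():
        atoms.append(("O", np.array([0.0, 0.0, 0.30])))
        atoms.append(("H", np.array([0.0, 0.0, -0.66])))
        k = int(is_patch[: n // 2].sum())
        atom_idx[:k] = 2  # acceptor cap sits on the oxygen
        atom_idx[-k:] = 3  # donor cap sits on the hydroxyl hydrogen

    segments = [
        SegmentRecord(
            index=i + 1,
            atom_index=int(atom_idx[i]),
            position=positions[i],
            charge=float(sigmas[i] * seg_area),
            area=seg_area,
            charge_density=float(sigmas[i]),
        )
        for i in range(n)
    ]
    mol = CosmoMolecule(
        name=f"toy-{spec.charge_pattern}-{spec.seed}",
        total_area=spec.total_area,
        cavity_volume=volume,
        atoms=atoms,
        segments=segments,
    )
    mol.validate()
    return mol


@dataclass(frozen=True)
class SyntheticSolubilityStudy:
    """A synthetic 'experimental' solubility campaign.

    The generating truth is the ideal van 't Hoff curve of ``fusion``
    (optionally corrected by ``ln_gamma_fn(T)``); observations are the truth
    times exp(ε) with ε ~ N(0, sd²) — multiplicative log-normal noise.
    """

    fusion: FusionProperties
    temperatures: tuple = tuple(np.linspace(280.0, 340.0, 20))
    sd: float = 0.05
    seed: int = 0
    ln_gamma_fn: object = None  # callable T -> ln gamma at saturation

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("noise sd must be nonnegative")


def make_solubility_dataset(study: SyntheticSolubilityStudy):
    """Generate (DataFrame with T/x_true/x_obs, PairedSeries truth-vs-noisy)."""
    rng = np.random.default_rng(study.seed)
    T = np.asarray(study.temperatures, dtype=float)
    ln_x = np.array([ideal_ln_solubility(study.fusion, t) for t in T])
    if study.ln_gamma_fn is not None:
        ln_x = ln_x - np.array([study.ln_gamma_fn(t) for t in T])
    x_true = np.exp(ln_x)
    noise = rng.normal(0.0, study.sd, size=T.size) if study.sd > 0 else np.zeros(T.size)
    x_obs = x_true * np.exp(noise)
    frame = pd.DataFrame({"T_K": T, "x_true": x_true, "x_obs": x_obs})
    return frame, PairedSeries(calculated=x_true, experimental=x_obs)


# ---------------------------------------------------------------------------
# embedded Hansen fixture
# ---------------------------------------------------------------------------

_TABLE_CACHE: list | None = None


def bundled_hansen_table() -> list:
    """The embedded Hansen-parameter table (13 solvents + 29 drugs).

    Each record carries δ_d/δ_p/δ_h/δ_t (MPa^0.5), the group-contribution
    molar volume used by Flory-Huggins and the COSMO cavity molar volume
    (cm³/mol).  Rows whose source digits admit more than one reading are
    flagged ``ambiguous`` and are skipped by consistency checks.
    """
    global _TABLE_CACHE
    if _TABLE_CACHE is None:
        path = resources.files("cosmopharm.data") / "hansen_table1.csv"
        with path.open() as fh:
            frame = pd.read_csv(fh, comment="#")
        _TABLE_CACHE = [
            HansenRecord(
                name=row["name"],
                delta_t=float(row.delta_t),
                delta_d=float(row.delta_d),
                delta_p=float(row.delta_p),
                delta_h=float(row.delta_h),
                volume=float(row.volume_fh),
                volume_cosmo=float(row.volume_cosmo),
                ambiguous=bool(row.ambiguous),
            )
            for _, row in frame.iterrows()
        ]
    return list(_TABLE_CACHE)


def hansen_lookup(name: str) -> HansenRecord:
    """Case-insensitive lookup in the bundled table; KeyError when absent."""
    needle = name.strip().lower()
    for rec in bundled_hansen_table():
        if rec.name.lower() == needle:
            return rec
    raise KeyError(f"no Hansen record for substance {name!r}")
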