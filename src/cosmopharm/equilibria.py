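"""Solid-liquid equilibria: solubility, partitioning, cocrystal diagrams.

The saturation condition for a crystalline solute i dissolving into a liquid
is

    ln x_i = ΔH_m/R (1/T_m − 1/T) − ΔC_p/R (1 − T_m/T − ln(T/T_m)) − ln γ_i

where ΔH_m and T_m are the fusion enthalpy and melting temperature and ΔC_p
the solid/liquid heat-capacity difference (commonly neglected).  With γ = 1
this is the ideal (van 't Hoff) solubility; a non-ideal activity model makes
the equation implicit in x and it is solved by damped fixed-point iteration.

Cocrystal formation a·A + b·B ⇌ A_aB_b is governed by the solubility product
K_CC = (x_A γ_A)^a (x_B γ_B)^b, constant along the cocrystal line of a
ternary (drug/coformer/solvent) diagram.  Invariant points — where a
pure-solid solubility line meets the cocrystal line — are located by
bisection along the solubility line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.constants import R as R_GAS
from scipy.optimize import brentq

__all__ = [
    "FusionProperties",
    "PartitionSpec",
    "CocrystalSpec",
    "TernaryDiagram",
    "ideal_ln_solubility",
    "solve_solubility",
    "solubility_line",
    "log_kow",
    "kcc_from_point",
    "invariant_points",
    "cocrystal_line",
    "ternary_diagram",
    "fit_fusion_enthalpy",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    """A fixed-point or root solve failed to converge."""


@dataclass(frozen=True)
class FusionProperties:
    """Fusion enthalpy (J/mol), melting point (K), ΔC_p (J/(mol K))."""

    dHm: float
    Tm: float
    dCp: float = 0.0

    def __post_init__(self):
        if self.dHm <= 0:
            raise ValueError("fusion enthalpy must be positive")
        if self.Tm <= 0:
            raise ValueError("melting temperature must be positive")


@dataclass(frozen=True)
class PartitionSpec:
    """Octanol/water two-phase specification.

    The octanol-rich phase holds 27.5 mol% water; the water-rich phase is
    octanol-free; ``conc_ratio`` is the total-concentration ratio
    C_o,W / C_o,O of the two phases.
    """

    water_in_octanol: float = 0.275
    conc_ratio: float = 0.151

    def __post_init__(self):
        if not 0.0 <= self.water_in_octanol < 1.0:
            raise ValueError("water fraction of the octanol phase must be in [0,1)")
        if self.conc_ratio <= 0:
            raise ValueError("concentration ratio must be positive")

    @property
    def octanol_in_octanol(self) -> float:
        return 1.0 - self.water_in_octanol


@dataclass(frozen=True)
class CocrystalSpec:
    """Stoichiometry a:b and solubility product of the cocrystal A_aB_b."""

    a: int = 1
    b: int = 1
    k_cc: float = 1e-2

    def __post_init__(self):
        if self.a < 1 or self.b < 1:
            raise ValueError("stoichiometric coefficients must be positive integers")
        if self.k_cc <= 0:
            raise ValueError("solubility product must be positive")


@dataclass
class TernaryDiagram:
    """Computed phase boundaries of a drug/coformer/solvent system.

    Points are (x_A, x_B, x_solvent) triples summing to 1, in mole or mass
    fractions according to ``units``.
    """

    solubility_line_a: list
    solubility_line_b: list
    cocrystal_line: list
    invariant_points: list
    units: str = "mole"
    temperature: float = float("nan")
    names: tuple = ("A", "B", "solvent")

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for branch, pts in (
            ("solubility_A", self.solubility_line_a),
            ("solubility_B", self.solubility_line_b),
            ("cocrystal", self.cocrystal_line),
            ("invariant", self.invariant_points),
        ):
            for p in pts:
                rows.append((branch, *p))
        cols = ["branch", f"x_{self.names[0]}", f"x_{self.names[1]}", f"x_{self.names[2]}"]
        return pd.DataFrame(rows, columns=cols)

    def plot(self, ax=None):
        """Quick-look plot in composition space (x_A vs x_B)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for label, pts, style in (
            (f"{self.names[0]} solubility", self.solubility_line_a, "-"),
            (f"{self.names[1]} solubility", self.solubility_line_b, "-"),
            ("cocrystal line", self.cocrystal_line, "--"),
        ):
            arr = np.asarray(pts)
            if len(arr):
                ax.plot(arr[:, 0], arr[:, 1], style, label=label)
        inv = np.asarray(self.invariant_points)
        if len(inv):
            ax.plot(inv[:, 0], inv[:, 1], "ko", label="invariant points")
        ax.set_xlabel(f"x {self.names[0]}")
        ax.set_ylabel(f"x {self.names[1]}")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# solubility
# ---------------------------------------------------------------------------

def ideal_ln_solubility(fus: FusionProperties, T: float) -> float:
    """Right-hand side of the saturation equation at γ = 1.

    Includes the ΔC_p correction when ``fus.dCp`` is nonzero (it vanishes
    identically at T = T_m).
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    term1 = fus.dHm / R_GAS * (1.0 / fus.Tm - 1.0 / T)
    term2 = fus.dCp / R_GAS * (1.0 - fus.Tm / T - np.log(T / fus.Tm))
    return term1 - term2


def _full_composition(x_solute, solute, solvent_x, n):
    """Assemble the mixture composition: solvents rescaled to 1 − x_solute."""
    x = np.empty(n)
    x[solute] = x_solute
    others = [i for i in range(n) if i != solute]
    for i, f in zip(others, solvent_x):
        x[i] = (1.0 - x_solute) * f
    return x


def solve_solubility(
    model,
    fus: FusionProperties,
    T: float,
    solute: int = 0,
    solvent_x=None,
    tol: float = 1e-8,
    max_iter: int = 500,
    damping: float = 0.5,
) -> float:
    """Saturation mole fraction of the solute in the given solvent blend.

    ``solvent_x`` are solute-free fractions over the remaining components
    (default: single solvent).  Solves x = exp(ideal − ln γ(x)) by damped
    fixed-point iteration; returns x ∈ (0, 1].  When the ideal term itself
    exceeds 0 (T > T_m) the result is clamped to 1 with a warning.
    """
    n = len(model.names)
    if solvent_x is None:
        if n != 2:
            raise ValueError("solvent_x required for more than one solvent")
        solvent_x = [1.0]
    solvent_x = np.asarray(solvent_x, dtype=float)
    if len(solvent_x) != n - 1 or abs(solvent_x.sum() - 1.0) > 1e-9:
        raise ValueError("solute-free solvent fractions must sum to 1")

    ln_x_ideal = ideal_ln_solubility(fus, T)
    if ln_x_ideal >= 0:
        warnings.warn(
            "ideal solubility exceeds 1 (T above the melting point); "
            "returning x = 1",
            stacklevel=2,
        )
        return 1.0

    x_sat = float(np.exp(ln_x_ideal))
    for _ in range(max_iter):
        comp = _full_composition(x_sat, solute, solvent_x, n)
        ln_g = model.ln_gamma(comp, T)[solute]
        x_new = float(np.exp(np.clip(ln_x_ideal - ln_g, -700.0, 0.0)))
        # converge on the saturation-equation residual in ln x (also bounds
        # the step in x itself since x <= 1)
        if abs(np.log(x_new) - np.log(x_sat)) < 0.5 * tol:
            return x_new
        x_sat = (1.0 - damping) * x_sat + damping * x_new

    # Strongly composition-dependent activity coefficients can make the
    # damped substitution oscillate; fall back to bracketed root finding on
    # the saturation residual, which changes sign on (0, 1) whenever the
    # ideal term is negative.
    def _resid(x):
        comp = _full_composition(x, solute, solvent_x, n)
        return np.log(x) - ln_x_ideal + model.ln_gamma(comp, T)[solute]

    try:
        return float(brentq(_resid, 1e-12, 1.0 - 1e-12, xtol=1e-12, rtol=1e-14))
    except ValueError as exc:
        raise ConvergenceError(
            f"solubility solve did not converge (last iterate {x_sat:.6e})"
        ) from exc


def solubility_line(
    model,
    fus: FusionProperties,
    T: float,
    solute: int = 0,
    n_points: int = 25,
    u_max: float = 1.0,
):
    """Solubility of one solid across solute-free solvent-blend ratios.

    For a ternary model [A, B, solvent] with ``solute = 0`` the line runs
    from pure solvent (u = 0) to coformer loading u = ``u_max`` where u is
    the solute-free fraction of the other non-solvent component.  Returns a
    list of full compositions.
    """
    n = len(model.names)
    if n != 3:
        raise ValueError("solubility_line expects a ternary model")
    pts = []
    for u in np.linspace(0.0, u_max, n_points):
        x_sat = solve_solubility(model, fus, T, solute=solute, solvent_x=[u, 1.0 - u])
        pts.append(tuple(_full_composition(x_sat, solute, [u, 1.0 - u], n)))
    return pts


# ---------------------------------------------------------------------------
# octanol/water partition coefficient
# ---------------------------------------------------------------------------

def log_kow(
    model_water,
    model_octanol,
    T: float = 298.15,
    spec: PartitionSpec | None = None,
    solute: int = 0,
) -> float:
    """log10 octanol/water partition coefficient at infinite dilution.

    ``model_water`` covers [solute, water]; ``model_octanol`` covers
    [solute, water, octanol].  The solute activity coefficients are
    evaluated at exactly x_solute = 0 in each phase and combined with the
    total-concentration ratio:  log K_OW = log10(C_o,W γ^W∞ / (C_o,O γ^O∞)).
    """
    spec = spec or PartitionSpec()
    x_w = np.zeros(len(model_water.names))
    x_w[1 - solute if len(x_w) == 2 else 1] = 1.0
    ln_gw = model_water.ln_gamma(x_w, T)[solute]

    x_o = np.zeros(len(model_octanol.names))
    others = [i for i in range(len(x_o)) if i != solute]
    x_o[others[0]] = spec.water_in_octanol
    x_o[others[1]] = spec.octanol_in_octanol
    ln_go = model_octanol.ln_gamma(x_o, T)[solute]

    return float(np.log10(spec.conc_ratio) + (ln_gw - ln_go) / np.log(10.0))


# ---------------------------------------------------------------------------
# cocrystals
# ---------------------------------------------------------------------------

def kcc_from_point(x_a, x_b, gamma_a, gamma_b, a: int = 1, b: int = 1) -> float:
    """Solubility product from one saturated composition.

    K_CC = (x_A γ_A)^a (x_B γ_B)^b; temperature-dependent but
    solvent-independent, so a single calibration point fixes it.
    """
    for v, what in ((x_a, "x_A"), (x_b, "x_B"), (gamma_a, "gamma_A"), (gamma_b, "gamma_B")):
        if v <= 0:
            raise ValueError(f"{what} must be positive, got {v}")
    return float((x_a * gamma_a) ** a * (x_b * gamma_b) ** b)


def _ln_activity_product(model, comp, T, a, b):
    g = np.exp(model.ln_gamma(comp, T))
    return a * np.log(comp[0] * g[0]) + b * np.log(comp[1] * g[1])


def _invariant_on_line(model, fus, spec, T, solid: int, n_scan: int = 40):
    """Intersection of one solubility line with the cocrystal line.

    Parameterizes the solid's solubility line by the solute-free loading u
    of the other crystal former and bisects the activity-product residual
    g(u) = a ln(x_Aγ_A) + b ln(x_Bγ_B) − ln K_CC.
    """
    other = 1 - solid
    ln_k = np.log(spec.k_cc)

    def point_at(u):
        solvent_x = np.zeros(2)
        solvent_x[other - (1 if other > solid else 0)] = u
        solvent_x[1 - (other - (1 if other > solid else 0))] = 1.0 - u
        x_sat = solve_solubility(model, fus, T, solute=solid, solvent_x=solvent_x)
        return _full_composition(x_sat, solid, solvent_x, 3)

    def resid(u):
        comp = point_at(u)
        return _ln_activity_product(model, comp, T, spec.a, spec.b) - ln_k

    # log-spaced low end: strongly non-ideal systems cross the solubility
    # product at very small coformer loadings
    us = np.concatenate(
        [np.geomspace(1e-10, 0.1, n_scan // 2), np.linspace(0.12, 1.0 - 1e-9, n_scan // 2)]
    )
    vals = [resid(u) for u in us]
    bracket = None
    for u0, u1, v0, v1 in zip(us[:-1], us[1:], vals[:-1], vals[1:]):
        if np.sign(v0) != np.sign(v1):
            bracket = (u0, u1)
            break
    if bracket is None:
        raise ConvergenceError(
            "no invariant point; cocrystal region may not exist at this "
            "temperature (activity-product residual does not change sign)"
        )
    u_star = brentq(resid, *bracket, xtol=1e-12, rtol=1e-14)
    return tuple(point_at(u_star))


def invariant_points(model, fus_a: FusionProperties, fus_b: FusionProperties,
                     spec: CocrystalSpec, T: float):
    """The two invariant points of the ternary diagram, A-rich one first.

    Each point simultaneously saturates one pure solid (the solubility
    equation) and the cocrystal (the activity product equals K_CC).  The
    model must cover components [A, B, solvent].
    """
    p_on_a = _invariant_on_line(model, fus_a, spec, T, solid=0)
    p_on_b = _invariant_on_line(model, fus_b, spec, T, solid=1)
    pts = sorted([p_on_a, p_on_b], key=lambda p: -p[0])
    return pts[0], pts[1]


def cocrystal_line(
    model,
    spec: CocrystalSpec,
    T: float,
    point_a,
    point_b,
    n_points: int = 25,
    tol: float = 1e-8,
    max_iter: int = 500,
):
    """Compositions satisfying the solubility product between two points.

    For each x_A on a grid between the invariant points, x_B is solved from
    (x_Aγ_A)^a (x_Bγ_B)^b = K_CC with the activity coefficients re-evaluated
    at the current composition (damped inner fixed point).  Endpoints
    reproduce the invariant points.
    """
    if n_points < 2:
        raise ValueError("need at least two points")
    x_a_grid = np.linspace(point_a[0], point_b[0], n_points)
    pts = []
    x_b = point_a[1]
    for k, x_a in enumerate(x_a_grid):
        if k == 0:
            pts.append(tuple(point_a))
            continue
        if k == n_points - 1:
            pts.append(tuple(point_b))
            continue
        converged = False
        for _ in range(max_iter):
            comp = np.array([x_a, x_b, 1.0 - x_a - x_b])
            if comp[2] < 0:
                raise ConvergenceError(
                    f"cocrystal line left the composition simplex at grid index {k}"
                )
            g = np.exp(model.ln_gamma(comp, T))
            x_b_new = (spec.k_cc / (x_a * g[0]) ** spec.a) ** (1.0 / spec.b) / g[1]
            if abs(x_b_new - x_b) < tol:
                x_b = x_b_new
                converged = True
                break
            x_b = (1.0 - 0.5) * x_b + 0.5 * x_b_new
        if not converged:
            raise ConvergenceError(
                f"cocrystal-line inner iteration failed at grid index {k}"
            )
        pts.append((float(x_a), float(x_b), float(1.0 - x_a - x_b)))
    return pts


def ternary_diagram(
    model,
    fus_a: FusionProperties,
    fus_b: FusionProperties,
    spec: CocrystalSpec,
    T: float,
    n_points: int = 25,
    units: str = "mole",
    molar_masses=None,
) -> TernaryDiagram:
    """Assemble the full ternary diagram of an A/B/solvent cocrystal system.

    Both pure-solid solubility lines, the cocrystal line between the two
    invariant points, and the invariant points themselves.  ``units="mass"``
    converts every point with the supplied molar masses (g/mol, one per
    component in model order).
    """
    if units not in ("mole", "mass"):
        raise ValueError("units must be 'mole' or 'mass'")
    inv_a, inv_b = invariant_points(model, fus_a, fus_b, spec, T)
    line_a = solubility_line(model, fus_a, T, solute=0, n_points=n_points)
    line_b = solubility_line(model, fus_b, T, solute=1, n_points=n_points)
    cc = cocrystal_line(model, spec, T, inv_a, inv_b, n_points=n_points)
    diagram = TernaryDiagram(
        solubility_line_a=line_a,
        solubility_line_b=line_b,
        cocrystal_line=cc,
        invariant_points=[inv_a, inv_b],
        units="mole",
        temperature=T,
        names=tuple(model.names),
    )
    if units == "mass":
        if molar_masses is None or len(molar_masses) != 3:
            raise ValueError("mass units require three molar masses")
        mm = np.asarray(molar_masses, dtype=float)

        def to_mass(p):
            w = np.asarray(p) * mm
            return tuple(w / w.sum())

        diagram = TernaryDiagram(
            solubility_line_a=[to_mass(p) for p in line_a],
            solubility_line_b=[to_mass(p) for p in line_b],
            cocrystal_line=[to_mass(p) for p in cc],
            invariant_points=[to_mass(inv_a), to_mass(inv_b)],
            units="mass",
            temperature=T,
            names=tuple(model.names),
        )
    return diagram


# ---------------------------------------------------------------------------
# fusion-enthalpy recovery (validation of synthetic solubility data)
# ---------------------------------------------------------------------------

def fit_fusion_enthalpy(temperatures, x_obs, Tm: float):
    """Least-squares ΔH_m from a van 't Hoff solubility curve.

    Regresses ln x on (1/T_m − 1/T)/R through the origin (the ideal
    saturation relation with ΔC_p = 0).  Returns (ΔH_m estimate, standard
    error) in J/mol.
    """
    T = np.asarray(temperatures, dtype=float)
    x = np.asarray(x_obs, dtype=float)
    if T.shape != x.shape or T.size < 2:
        raise ValueError("need matching T and x arrays with at least 2 points")
    z = (1.0 / Tm - 1.0 / T) / R_GAS
    y = np.log(x)
    szz = float(z @ z)
    if szz <= 0:
        raise ValueError("temperatures must differ from the melting point")
    dhm = float(z @ y) / szz
    resid = y - dhm * z
    dof = max(T.size - 1, 1)
    se = float(np.sqrt((resid @ resid) / dof / szz))
    return dhm, se
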