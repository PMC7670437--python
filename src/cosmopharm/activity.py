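"""Activity-coefficient models for solid-liquid equilibrium work.

Three models behind one interface (``model.ln_gamma(x, T)``):

* :class:`CosmoSac2002` — the original segment-activity model: a
  Staverman-Guggenheim combinatorial term plus a residual term from
  self-consistent segment activity coefficients on the 51-bin sigma profile,
  with an electrostatic misfit energy and a donor/acceptor hydrogen-bonding
  term.
* :class:`CosmoSac2010` — the revised model with the sigma profile split
  into NHB/OH/OT parts, a temperature-dependent electrostatic constant
  (A_ES + B_ES/T²) and pair-specific hydrogen-bond constants.
* :class:`FloryHuggins` — a semi-predictive lattice model whose interaction
  parameter χ is built from Hansen solubility parameters
  (dispersion/polar/hydrogen-bonding).

All models support exact infinite dilution (x_i = 0) without extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sigma_profile import (
    SIGMA_GRID,
    SigmaProfile,
    SplitSigmaProfile,
    mixture_profile,
    profile_from_molecule,
    split_profile_from_molecule,
)

__all__ = [
    "ModelParameters2002",
    "ModelParameters2010",
    "HansenRecord",
    "Component",
    "staverman_guggenheim",
    "exchange_energy_2002",
    "exchange_energy_2010",
    "segment_gammas",
    "CosmoSac2002",
    "CosmoSac2010",
    "FloryHuggins",
    "IdealSolution",
    "fh_chi",
    "hansen_from_groups",
    "SegmentConvergenceError",
]

#: Gas constant in J/(mol K), used by the Flory-Huggins χ (δ² in MPa = J/cm³).
R_J = 8.314


class SegmentConvergenceError(RuntimeError):
    """The segment-activity fixed point failed to converge."""


@dataclass(frozen=True)
class ModelParameters2002:
    """Universal constants of the 2002 segment-activity model.

    Defaults are the VT-database parameter set.  Units: areas Å², volumes Å³,
    energy constants kcal·Å⁴/(mol·e²), σ_hb e/Å², R kcal/(mol·K).
    """

    a_eff: float = 7.50  # effective segment area
    alpha_prime: float = 16466.72  # misfit (electrostatic) constant
    c_hb: float = 85580.0  # hydrogen-bonding constant
    sigma_hb: float = 0.0084  # hydrogen-bonding cutoff
    q0: float = 79.53  # area normalization
    r0: float = 66.69  # volume normalization
    z: float = 10.0  # lattice coordination number
    R: float = 0.001987  # gas constant, kcal/(mol K)

    def __post_init__(self):
        for name in ("a_eff", "alpha_prime", "c_hb", "sigma_hb", "q0", "r0", "z", "R"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class ModelParameters2010:
    """Constants of the 2010 revision (three-part sigma profile).

    ``hb_sign = -1`` makes the hydrogen-bond energy attractive (the physical
    choice); ``+1`` evaluates the repulsive literal form.
    """

    a_es: float = 6525.69  # kcal Å⁴ / (mol e²)
    b_es: float = 1.4859e8  # kcal Å⁴ K² / (mol e²)
    c_oh_oh: float = 4013.78
    c_ot_ot: float = 932.31
    c_oh_ot: float = 3016.43
    sigma_o: float = 0.007  # e/Å²
    hb_sign: float = -1.0


@dataclass
class HansenRecord:
    """Hansen solubility parameters (MPa^0.5) and molar volumes (cm³/mol)."""

    name: str
    delta_d: float
    delta_p: float
    delta_h: float
    delta_t: float = 0.0
    volume: float = 0.0  # Flory-Huggins (group-contribution) molar volume
    volume_cosmo: float = float("nan")
    ambiguous: bool = False

    def delta_t_from_parts(self) -> float:
        return float(
            np.sqrt(self.delta_d**2 + self.delta_p**2 + self.delta_h**2)
        )


@dataclass
class Component:
    """A molecule as the activity models see it: area, volume and profile."""

    name: str
    area: float  # Å² (A_i)
    volume: float  # Å³ (V_i)
    profile: SigmaProfile
    split: SplitSigmaProfile | None = None

    @classmethod
    def from_molecule(cls, mol, r_ave=None, sigma_o=None, with_split=True):
        kw_prof = {} if r_ave is None else {"r_ave": r_ave}
        kw_split = dict(kw_prof)
        if sigma_o is not None:
            kw_split["sigma_o"] = sigma_o
        return cls(
            name=mol.name,
            area=mol.segment_area_sum,
            volume=mol.cavity_volume,
            profile=profile_from_molecule(mol, **kw_prof),
            split=split_profile_from_molecule(mol, **kw_split) if with_split else None,
        )

    def r_q_n(self, params: ModelParameters2002):
        """Normalized volume r_i, area q_i and segment count n_i."""
        return (
            self.volume / params.r0,
            self.area / params.q0,
            self.area / params.a_eff,
        )


# ---------------------------------------------------------------------------
# combinatorial term
# ---------------------------------------------------------------------------

def staverman_guggenheim(x, r, q, z: float = 10.0) -> np.ndarray:
    """Staverman-Guggenheim combinatorial ln γ^C.

    Uses the ratio forms φ_i/x_i = r_i/Σx_j r_j and θ_i/φ_i so that
    x_i = 0 (infinite dilution) is handled analytically.
    """
    x = np.asarray(x, dtype=float)
    r = np.asarray(r, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(r <= 0) or np.any(q <= 0):
        raise ValueError("r and q must be strictly positive")
    if abs(x.sum() - 1.0) > 1e-9:
        raise ValueError("mole fractions must sum to 1")
    sr = float(x @ r)
    sq = float(x @ q)
    l = (z / 2.0) * (r - q) - (r - 1.0)
    phi_over_x = r / sr
    theta_over_phi = (q / sq) * (sr / r)
    return (
        np.log(phi_over_x)
        + (z / 2.0) * q * np.log(theta_over_phi)
        + l
        - phi_over_x * float(x @ l)
    )


# ---------------------------------------------------------------------------
# exchange energies
# ---------------------------------------------------------------------------

def exchange_energy_2002(sigma_m, sigma_n, params: ModelParameters2002):
    """Pairwise exchange energy ΔW: misfit + donor/acceptor hydrogen bond.

    ``(α'/2)(σ_m+σ_n)² + c_hb·max(0, σ_acc−σ_hb)·min(0, σ_don+σ_hb)`` with
    σ_acc/σ_don the larger/smaller of the pair.  Symmetric in its arguments;
    broadcastable.
    """
    sm = np.asarray(sigma_m, dtype=float)
    sn = np.asarray(sigma_n, dtype=float)
    misfit = 0.5 * params.alpha_prime * (sm + sn) ** 2
    acc = np.maximum(sm, sn)
    don = np.minimum(sm, sn)
    hb = (
        params.c_hb
        * np.maximum(0.0, acc - params.sigma_hb)
        * np.minimum(0.0, don + params.sigma_hb)
    )
    return misfit + hb


def _dw_matrix_2002(params: ModelParameters2002) -> np.ndarray:
    return exchange_energy_2002(SIGMA_GRID[:, None], SIGMA_GRID[None, :], params)


_CLASS_ORDER = ("NHB", "OH", "OT")


def exchange_energy_2010(
    sigma_m, cls_m: str, sigma_n, cls_n: str, T: float, params: ModelParameters2010
):
    """ΔW of the 2010 revision for a labelled segment pair.

    Electrostatic term (A_ES + B_ES/T²)(σ_m+σ_n)²; a hydrogen-bond term
    c_hb(t,s)·(σ_m−σ_n)² (scaled by ``hb_sign``) is active only for OH/OT
    pairs with opposite-sign charge densities.
    """
    for c in (cls_m, cls_n):
        if c not in _CLASS_ORDER:
            raise ValueError(f"unknown hydrogen-bonding class {c!r}")
    sm = np.asarray(sigma_m, dtype=float)
    sn = np.asarray(sigma_n, dtype=float)
    es = (params.a_es + params.b_es / T**2) * (sm + sn) ** 2
    pair = frozenset((cls_m, cls_n))
    if pair == {"OH"}:
        c_hb = params.c_oh_oh
    elif pair == {"OT"}:
        c_hb = params.c_ot_ot
    elif pair == {"OH", "OT"}:
        c_hb = params.c_oh_ot
    else:
        c_hb = 0.0
    hb = np.where(sm * sn < 0, params.hb_sign * c_hb * (sm - sn) ** 2, 0.0)
    return es + hb


def _dw_matrix_2010(T: float, params: ModelParameters2010) -> np.ndarray:
    """(153, 153) exchange-energy matrix over stacked NHB/OH/OT grids."""
    blocks = [
        [
            exchange_energy_2010(
                SIGMA_GRID[:, None], t, SIGMA_GRID[None, :], s, T, params
            )
            for s in _CLASS_ORDER
        ]
        for t in _CLASS_ORDER
    ]
    return np.block(blocks)


# ---------------------------------------------------------------------------
# segment activity coefficients
# ---------------------------------------------------------------------------

def segment_gammas(
    p: np.ndarray,
    dw: np.ndarray,
    T: float,
    R: float,
    tol: float = 1e-8,
    max_iter: int = 1000,
    damping: float = 0.5,
) -> np.ndarray:
    """Solve the self-consistent segment-activity fixed point.

    ln Γ(σ_m) = −ln Σ_n p(σ_n) Γ(σ_n) exp(−ΔW(σ_m,σ_n)/RT), iterated with a
    damped update until the undamped residual max|Γ' − Γ|/Γ drops below
    ``tol``.  Deterministic; raises :class:`SegmentConvergenceError` with the
    residual on failure.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    p = np.asarray(p, dtype=float)
    K = np.exp(-dw / (R * T))
    gamma = np.ones_like(p)
    resid = np.inf
    for _ in range(max_iter):
        gamma_new = 1.0 / (K @ (p * gamma))
        resid = float(np.max(np.abs(gamma_new - gamma) / gamma))
        if resid < tol:
            return gamma_new
        gamma = (1.0 - damping) * gamma + damping * gamma_new
    raise SegmentConvergenceError(
        f"segment activity coefficients did not converge in {max_iter} "
        f"iterations (residual {resid:.3e})"
    )


# ---------------------------------------------------------------------------
# COSMO-SAC models
# ---------------------------------------------------------------------------

class CosmoSac2002:
    """Original segment-activity model on unsplit sigma profiles."""

    def __init__(self, components, params: ModelParameters2002 | None = None):
        if not components:
            raise ValueError("need at least one component")
        self.components = list(components)
        self.params = params or ModelParameters2002()
        self._dw = _dw_matrix_2002(self.params)

    @property
    def names(self):
        return [c.name for c in self.components]

    def _pure_ln_gammas(self, T):
        return [
            np.log(segment_gammas(c.profile.p, self._dw, T, self.params.R))
            for c in self.components
        ]

    def ln_gamma(self, x, T: float) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if len(x) != len(self.components):
            raise ValueError("x length does not match component count")
        rqn = [c.r_q_n(self.params) for c in self.components]
        r = np.array([t[0] for t in rqn])
        q = np.array([t[1] for t in rqn])
        n = np.array([t[2] for t in rqn])
        ln_gc = staverman_guggenheim(x, r, q, self.params.z)

        mix = mixture_profile([c.profile for c in self.components], x)
        ln_gamma_s = np.log(segment_gammas(mix.p, self._dw, T, self.params.R))
        ln_gr = np.array(
            [
                n[i] * float(c.profile.p @ (ln_gamma_s - ln_gi))
                for i, (c, ln_gi) in enumerate(
                    zip(self.components, self._pure_ln_gammas(T))
                )
            ]
        )
        return ln_gc + ln_gr


class CosmoSac2010:
    """Revised model: three-part profiles and T-dependent electrostatics.

    The combinatorial term and the molecular normalizations (r0, q0, a_eff,
    z, R) are shared with the 2002 parameter set via ``geometry``.
    """

    def __init__(
        self,
        components,
        params: ModelParameters2010 | None = None,
        geometry: ModelParameters2002 | None = None,
    ):
        if not components:
            raise ValueError("need at least one component")
        for c in components:
            if c.split is None:
                raise ValueError(
                    f"component {c.name!r} has no split sigma profile"
                )
        self.components = list(components)
        self.params = params or ModelParameters2010()
        self.geometry = geometry or ModelParameters2002()

    @property
    def names(self):
        return [c.name for c in self.components]

    @staticmethod
    def _stack(split: SplitSigmaProfile) -> np.ndarray:
        return np.concatenate([split.nhb, split.oh, split.ot])

    def _ln_seg_gammas(self, p_stacked, T):
        dw = _dw_matrix_2010(T, self.params)
        return np.log(segment_gammas(p_stacked, dw, T, self.geometry.R))

    def ln_gamma(self, x, T: float) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if len(x) != len(self.components):
            raise ValueError("x length does not match component count")
        geo = self.geometry
        rqn = [c.r_q_n(geo) for c in self.components]
        r = np.array([t[0] for t in rqn])
        q = np.array([t[1] for t in rqn])
        n = np.array([t[2] for t in rqn])
        ln_gc = staverman_guggenheim(x, r, q, geo.z)

        areas = np.array([c.area for c in self.components])
        w = x * areas
        p_mix = sum(
            wi * self._stack(c.split) for wi, c in zip(w, self.components)
        ) / w.sum()
        ln_gs = self._ln_seg_gammas(p_mix, T)
        ln_gr = np.empty(len(self.components))
        for i, c in enumerate(self.components):
            p_i = self._stack(c.split)
            ln_gi = self._ln_seg_gammas(p_i, T)
            ln_gr[i] = n[i] * float(p_i @ (ln_gs - ln_gi))
        return ln_gc + ln_gr


# ---------------------------------------------------------------------------
# Hansen / Flory-Huggins
# ---------------------------------------------------------------------------

def _hansen_quadratic(i: HansenRecord, j: HansenRecord) -> float:
    """Hansen distance (δ_d,i−δ_d,j)² + 0.25(δ_p..)² + 0.25(δ_h..)², MPa."""
    return (
        (i.delta_d - j.delta_d) ** 2
        + 0.25 * (i.delta_p - j.delta_p) ** 2
        + 0.25 * (i.delta_h - j.delta_h) ** 2
    )


def fh_chi(i: HansenRecord, j: HansenRecord, T: float) -> float:
    """Flory-Huggins interaction parameter χ_ij = V_i/RT · Hansen distance.

    Asymmetric: χ_ij uses the molar volume of the *first* substance.
    Dimensionless with δ² in MPa = J/cm³, V in cm³/mol, R in J/(mol K).
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    return i.volume / (R_J * T) * _hansen_quadratic(i, j)


class FloryHuggins:
    """Hansen-parameter Flory-Huggins activity model.

    ``convention`` selects how χ enters the multicomponent expression
    ln γ_i = ln(φ_i/x_i) + 1 − φ_i/x_i + 2V_i Σ_j χ_ij φ_j² − V_i ΣΣ φφχ:

    * ``"per-volume"`` (default): χ of the V_i/RT definition is divided by
      V_i before entering the V_i-weighted sums (χ' = Hansen distance / RT,
      symmetric) — the dimensionally consistent reading.
    * ``"as-printed"``: the expression is evaluated literally with the
      V_i-bearing χ.
    * ``"regular"``: the Hansen regular-solution residual
      V_i(δ_i − δ̄)²_H/RT (δ̄ the volume-fraction mixture average), the only
      variant that satisfies the Gibbs-Duhem relation exactly.
    """

    CONVENTIONS = ("per-volume", "as-printed", "regular")

    def __init__(self, records, convention: str = "per-volume"):
        if not records:
            raise ValueError("need at least one Hansen record")
        if convention not in self.CONVENTIONS:
            raise ValueError(
                f"unknown convention {convention!r}; choose from {self.CONVENTIONS}"
            )
        self.records = list(records)
        self.convention = convention
        self._V = np.array([r.volume for r in self.records], dtype=float)
        if np.any(self._V <= 0):
            raise ValueError("all molar volumes must be positive")
        n = len(self.records)
        self._S = np.array(
            [
                [_hansen_quadratic(self.records[i], self.records[j]) for j in range(n)]
                for i in range(n)
            ]
        )

    @property
    def names(self):
        return [r.name for r in self.records]

    def ln_gamma(self, x, T: float) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if len(x) != len(self.records):
            raise ValueError("x length does not match record count")
        if abs(x.sum() - 1.0) > 1e-9:
            raise ValueError("mole fractions must sum to 1")
        V = self._V
        sv = float(x @ V)
        phi_over_x = V / sv
        phi = x * phi_over_x
        comb = np.log(phi_over_x) + 1.0 - phi_over_x

        chi_sym = self._S / (R_J * T)  # χ' = Hansen distance / RT (symmetric)
        if self.convention == "regular":
            # ln γ_i^res = V_i (δ_i − δ̄)²_H / RT via the quadratic-form identity
            res = V * (chi_sym @ phi - 0.5 * phi @ chi_sym @ phi)
        else:
            if self.convention == "per-volume":
                chi = chi_sym
            else:  # as-printed: χ_ij carries V_i
                chi = V[:, None] * chi_sym
            res = 2.0 * V * (chi @ phi**2) - V * (phi @ chi @ phi)
        return comb + res


class IdealSolution:
    """γ = 1 for every component; handy as a reference model."""

    def __init__(self, n: int, names=None):
        self.n = int(n)
        self.names = list(names) if names else [f"c{i}" for i in range(n)]

    def ln_gamma(self, x, T: float) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if len(x) != self.n:
            raise ValueError("x length does not match component count")
        return np.zeros(self.n)


# ---------------------------------------------------------------------------
# group contributions
# ---------------------------------------------------------------------------

def hansen_from_groups(group_values, name: str = "from-groups") -> HansenRecord:
    """Hansen parameters from group contributions.

    ``group_values`` is a sequence of (F_d, F_p, E_h, V) tuples.  The
    combination rules are δ_d = ΣF_d/ΣV, δ_p = sqrt(ΣF_p²)/ΣV,
    δ_h = sqrt(ΣE_h)/ΣV and δ_t = sqrt(δ_d² + δ_p² + δ_h²).
    """
    groups = list(group_values)
    if not groups:
        raise ValueError("need at least one group")
    fd = sum(g[0] for g in groups)
    fp2 = sum(g[1] ** 2 for g in groups)
    eh = sum(g[2] for g in groups)
    v = sum(g[3] for g in groups)
    if v <= 0:
        raise ValueError("total group volume must be positive")
    delta_d = fd / v
    delta_p = np.sqrt(fp2) / v
    delta_h = np.sqrt(max(eh, 0.0)) / v
    rec = HansenRecord(
        name=name,
        delta_d=float(delta_d),
        delta_p=float(delta_p),
        delta_h=float(delta_h),
        volume=float(v),
    )
    rec.delta_t = rec.delta_t_from_parts()
    return rec
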