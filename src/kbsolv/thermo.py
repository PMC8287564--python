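"""Kirkwood-Buff inversion of binary-solution thermodynamics.

For a binary water(1)-cosolvent(3) mixture, the three independent KB
integrals follow from measurable quantities -- composition, partial molar
volumes, isothermal compressibility and the chemical-potential derivative
-- via the Ben-Naim inversion.  With the thermodynamic factor

    D = x3 (dmu3/dx3)_{p,T} / (RT)            (dimensionless)

the molar volume Vm = 1/rho and the compressibility term RT * betaT,

    G13 = RT*betaT - V1*V3 / (Vm * D)
    G33 = G13 + (V1 / D - Vm) / x3
    G11 = G13 + (V3 / D - Vm) / x1

all in cm^3/mol.  The converse route predicts the activity-coefficient
derivative from KBIs:

    f33 = (d ln f3 / d ln x3)_{p,T} = -x1 rho3 D13 / (1 + x1 rho3 D13),
    D13 = G11 + G33 - 2 G13,

which closes the equation system: inverting a state and feeding the KBIs
back must reproduce the state's own f33 = x3 (dmu3/dx3)/(RT) - 1 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline, make_smoothing_spline

from .rdf import cm3_per_mol_to_nm3, nm3_to_cm3_per_mol

__all__ = [
    "GAS_CONSTANT",
    "BinaryThermoState",
    "KBInversionIntermediates",
    "KBITriple",
    "ActivityDerivative",
    "molal_to_molefraction_activity",
    "chem_potential_derivative",
    "invert_thermo_to_kbi",
    "f33_from_kbi",
    "f33_from_state",
    "compare_curves",
]

GAS_CONSTANT = 8.314462618  # J/(mol K)


@dataclass
class KBITriple:
    """The three independent binary KBIs, molar scale (cm^3/mol)."""

    G11: float
    G13: float
    G33: float
    unit: str = "cm^3/mol"

    def __post_init__(self) -> None:
        for v in (self.G11, self.G13, self.G33):
            if not np.isfinite(v):
                raise ValueError("KBIs must be finite")

    @property
    def G31(self) -> float:
        return self.G13

    def in_nm3(self) -> "KBITriple":
        return KBITriple(
            G11=cm3_per_mol_to_nm3(self.G11),
            G13=cm3_per_mol_to_nm3(self.G13),
            G33=cm3_per_mol_to_nm3(self.G33),
            unit="nm^3",
        )

    def in_cm3_per_mol(self) -> "KBITriple":
        if self.unit == "cm^3/mol":
            return self
        return KBITriple(
            G11=nm3_to_cm3_per_mol(self.G11),
            G13=nm3_to_cm3_per_mol(self.G13),
            G33=nm3_to_cm3_per_mol(self.G33),
        )


@dataclass
class KBInversionIntermediates:
    """Intermediates of the inversion: eta is the thermodynamic factor
    x3 (dmu3/dx3)/(RT), xi the compressibility term RT*betaT (cm^3/mol),
    vm the molar volume 1/rho (cm^3/mol)."""

    eta: float
    xi: float
    vm: float


@dataclass
class ActivityDerivative:
    """f33 = (d ln f3 / d ln x3) at constant p, T; dimensionless."""

    f33: float
    x3: float


@dataclass
class BinaryThermoState:
    """One composition point of a binary water(1)-cosolvent(3) solution.

    Units: T in K, p in Pa, densities in mol/L, partial molar volumes in
    cm^3/mol, betaT in 1/Pa, dmu3_dx3 in J/mol.  Densities supplied in
    mol/m^3 are accepted via ``rho_unit="mol/m^3"`` and converted on input.
    """

    T: float
    x3: float
    rho: float
    V1: float
    V3: float
    betaT: float
    dmu3_dx3: float
    p: float = 101325.0
    f3: float | None = None
    f3m: float | None = None
    rho_unit: str = "mol/L"

    def __post_init__(self) -> None:
        if not 0.0 < self.x3 < 1.0:
            raise ValueError("x3 must lie in (0, 1)")
        if self.rho_unit == "mol/m^3":
            self.rho = self.rho / 1000.0
            self.rho_unit = "mol/L"
        elif self.rho_unit != "mol/L":
            raise ValueError(f"unsupported density unit {self.rho_unit!r}")
        if self.rho <= 0:
            raise ValueError("density must be positive")
        if self.betaT <= 0:
            raise ValueError("isothermal compressibility must be positive")

    @property
    def x1(self) -> float:
        return 1.0 - self.x3

    @property
    def rho1(self) -> float:
        return self.x1 * self.rho

    @property
    def rho3(self) -> float:
        return self.x3 * self.rho


def molal_to_molefraction_activity(f3m, x3):
    """Molal- to mole-fraction-scale activity coefficient, f3 = f3m / x3."""
    f3m = np.asarray(f3m, dtype=float)
    x3 = np.asarray(x3, dtype=float)
    if np.any(x3 <= 0) or np.any(x3 >= 1):
        raise ValueError("x3 must lie in (0, 1)")
    if np.any(f3m <= 0):
        raise ValueError("activity coefficient must be positive")
    out = f3m / x3
    return float(out) if out.ndim == 0 else out


def chem_potential_derivative(
    x3: np.ndarray,
    f3: np.ndarray,
    T: float = 298.0,
    lam: float | None = None,
):
    """Chemical-potential derivative from an activity-coefficient table.

        (dmu3/dx3)_{p,T} = RT [ (d ln f3 / d x3) + 1/x3 ]

    d ln f3/dx3 comes from a cubic smoothing spline of ln f3 vs x3 with
    generalized cross-validation (``lam=None``); pass ``lam`` to fix the
    penalty, or rely on the exact interpolating spline for n < 5 points
    where GCV is ill-posed.  Returns (dmu3_dx3, dlnf3_dx3) arrays, J/mol.
    """
    x3 = np.asarray(x3, dtype=float)
    f3 = np.asarray(f3, dtype=float)
    if x3.size < 3:
        raise ValueError("need at least 3 composition points")
    if np.any(np.diff(x3) <= 0):
        raise ValueError("x3 must be strictly increasing (no duplicates)")
    if np.any(f3 <= 0) or np.any(x3 <= 0):
        raise ValueError("x3 and f3 must be positive")
    lnf = np.log(f3)
    if x3.size >= 5:
        spl = make_smoothing_spline(x3, lnf, lam=lam)
    else:
        spl = CubicSpline(x3, lnf)
    dlnf = spl.derivative()(x3)
    dmu = GAS_CONSTANT * T * (dlnf + 1.0 / x3)
    return dmu, dlnf


def inversion_intermediates(state: BinaryThermoState) -> KBInversionIntermediates:
    eta = state.x3 * state.dmu3_dx3 / (GAS_CONSTANT * state.T)
    xi = GAS_CONSTANT * state.T * state.betaT * 1e6  # m^3/mol -> cm^3/mol
    vm = 1000.0 / state.rho  # mol/L -> cm^3/mol
    if abs(eta) < 1e-300:
        raise ValueError(
            f"thermodynamic factor eta vanishes at x3 = {state.x3}; inversion singular"
        )
    return KBInversionIntermediates(eta=eta, xi=xi, vm=vm)


def invert_thermo_to_kbi(state: BinaryThermoState) -> KBITriple:
    """Ben-Naim inversion of one binary state to (G11, G13, G33), cm^3/mol."""
    inter = inversion_intermediates(state)
    eta, xi, vm = inter.eta, inter.xi, inter.vm
    G13 = xi - state.V1 * state.V3 / (vm * eta)
    G33 = G13 + (state.V1 / eta - vm) / state.x3
    G11 = G13 + (state.V3 / eta - vm) / state.x1
    return KBITriple(G11=G11, G13=G13, G33=G33)


def f33_from_kbi(kbi: KBITriple, state: BinaryThermoState) -> ActivityDerivative:
    """Activity-coefficient derivative predicted from KBIs (see module docs)."""
    kbi = kbi.in_cm3_per_mol()
    delta = kbi.G11 + kbi.G33 - 2.0 * kbi.G13  # cm^3/mol
    rho3 = state.rho3 / 1000.0  # mol/cm^3
    q = state.x1 * rho3 * delta
    denom = 1.0 + q
    if abs(denom) < 1e-12:
        raise ValueError(f"f33 denominator vanishes at x3 = {state.x3}")
    return ActivityDerivative(f33=-q / denom, x3=state.x3)


def f33_from_state(state: BinaryThermoState) -> ActivityDerivative:
    """f33 computed directly from the state's chemical-potential derivative,
    f33 = x3 (dmu3/dx3)/(RT) - 1; the independent path used in closure tests."""
    return ActivityDerivative(
        f33=state.x3 * state.dmu3_dx3 / (GAS_CONSTANT * state.T) - 1.0, x3=state.x3
    )


def compare_curves(sim_x, sim_y, exp_x, exp_y) -> float:
    """RMSE between a simulated and an experimental curve, with the simulated
    values linearly interpolated onto the experimental compositions."""
    sim_x = np.asarray(sim_x, dtype=float)
    sim_y = np.asarray(sim_y, dtype=float)
    exp_x = np.asarray(exp_x, dtype=float)
    exp_y = np.asarray(exp_y, dtype=float)
    order = np.argsort(sim_x)
    sim_x, sim_y = sim_x[order], sim_y[order]
    mask = (exp_x >= sim_x[0]) & (exp_x <= sim_x[-1])
    if not mask.any():
        raise ValueError("no overlap between simulated and experimental compositions")
    interp = np.interp(exp_x[mask], sim_x, sim_y)
    return float(np.sqrt(np.mean((interp - exp_y[mask]) ** 2)))
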