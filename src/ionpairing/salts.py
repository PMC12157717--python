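"""Closed-form salt solubility / ion-pairing models and their fitters.

For a sparingly soluble 1:1 salt MA in a nonaqueous solvent, three coupled
processes set the dissolved sodium budget: dissolution of the solid
(``Ks = [M+][A-]`` at saturation), ion-pair association in solution
(``K_IP = [MA]/([M+][A-])``) and, for dihydrogen phosphate, anion
dimerization (``K_dim = [A2^2-]/[A-]^2``).  The total solubility of the pure
salt is then

    s = sqrt(Ks) + Ks * K_IP

and adding a common anion at analytical concentration ``c`` suppresses the
ionic term while leaving the ion-pair term ``Ks*K_IP`` fixed:

    s(c) = 0.5 * (2*Ks*K_IP - c + sqrt(c**2 + 4*Ks))

Four experimental strategies are implemented as fitters:

* method A - solubility vs. added common anion (saturated series),
* method B - potentiometric (pNa) titration crossing a precipitation onset,
* method E - like A with anion dimerization in the model,
* method F - like B with dimerization; Ks from the sensitive region of the
  pNa curve, K_IP recovered afterwards from the saturated pure solution.

All closed forms are validated against the generic speciation solver in
:mod:`ionpairing.equilibria`; fits run in log-parameter space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .equilibria import EquilibriumModel, SpeciationError, solve_speciation

__all__ = [
    "SaltParams",
    "SolubilitySeries",
    "PnaTitrationData",
    "SaltFitResult",
    "solubility_pure",
    "ks_from_solubility",
    "solubility_with_common_anion",
    "free_na_no_solid",
    "free_na_with_solid",
    "regime_test",
    "phosphate_solubility_implicit",
    "phosphate_free_na_saturated",
    "kip_from_saturated",
    "aes_solubility",
    "salt_model",
    "fit_method_A",
    "fit_method_B",
    "fit_method_E",
    "fit_method_F",
]


@dataclass
class SaltParams:
    """Thermodynamic constants of one salt (molar scale, 298.15 K).

    ``Ks`` mol^2 dm^-6, ``K_IP`` mol^-1 dm^3, ``K_dim`` mol^-1 dm^3 (0 when
    the anion does not dimerize); ``s`` is the derived total solubility of
    the pure saturated solution, mol dm^-3.
    """

    Ks: float
    K_IP: float = 0.0
    K_dim: float = 0.0
    s: float | None = None

    def __post_init__(self):
        if self.Ks <= 0:
            raise ValueError("Ks must be positive")
        if self.K_IP < 0 or self.K_dim < 0:
            raise ValueError("K_IP and K_dim must be non-negative")
        if self.s is None:
            self.s = solubility_pure(self.Ks, self.K_IP)
        elif not math.isclose(self.s, solubility_pure(self.Ks, self.K_IP), rel_tol=1e-6):
            raise ValueError("s inconsistent with sqrt(Ks) + Ks*K_IP")


@dataclass
class SolubilitySeries:
    """Measured total solubility vs. co-ion analytical concentration."""

    c_coion: np.ndarray
    s: np.ndarray

    def __post_init__(self):
        self.c_coion = np.asarray(self.c_coion, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.c_coion.shape != self.s.shape:
            raise ValueError("column length mismatch")
        if np.any(self.c_coion < 0) or np.any(self.s <= 0):
            raise ValueError("require c >= 0 and s > 0")

    @classmethod
    def from_csv(cls, path) -> "SolubilitySeries":
        df = pd.read_csv(path)
        return cls(df["c_coion"].to_numpy(), df["s"].to_numpy())


@dataclass
class PnaTitrationData:
    """pNa titration points: totals and measured pNa, optional regime labels."""

    c_na: np.ndarray
    c_anion: np.ndarray
    pna: np.ndarray
    regime: np.ndarray | None = None  # 'no_solid' | 'solid' per row, or None

    def __post_init__(self):
        self.c_na = np.asarray(self.c_na, dtype=float)
        self.c_anion = np.asarray(self.c_anion, dtype=float)
        self.pna = np.asarray(self.pna, dtype=float)
        if not (self.c_na.shape == self.c_anion.shape == self.pna.shape):
            raise ValueError("column length mismatch")
        if np.any(self.c_na <= 0):
            raise ValueError("totals must be positive")
        if self.regime is not None:
            self.regime = np.asarray(self.regime)

    @classmethod
    def from_csv(cls, path) -> "PnaTitrationData":
        df = pd.read_csv(path)
        regime = df["regime"].to_numpy() if "regime" in df else None
        return cls(
            df["c_na"].to_numpy(), df["c_anion"].to_numpy(), df["pna"].to_numpy(), regime
        )


@dataclass
class SaltFitResult:
    """Estimates and diagnostics from a salt-model fit."""

    params: dict[str, float]
    stderr: dict[str, float]
    residuals: np.ndarray
    converged: bool
    message: str = ""
    extra: dict = field(default_factory=dict)

    @property
    def residual_norm(self) -> float:
        return float(np.sqrt(np.sum(self.residuals**2)))

    def to_dict(self) -> dict:
        return {
            "params": self.params,
            "stderr": self.stderr,
            "residual_norm": self.residual_norm,
            "converged": self.converged,
            "message": self.message,
            **{k: v for k, v in self.extra.items()},
        }


# ----------------------------------------------------------------------
# closed forms
# ----------------------------------------------------------------------


def solubility_pure(Ks: float, K_IP: float) -> float:
    """Total solubility of the pure saturated salt: sqrt(Ks) + Ks*K_IP."""
    if Ks <= 0:
        raise ValueError("Ks must be positive")
    if K_IP < 0:
        raise ValueError("K_IP must be non-negative")
    return math.sqrt(Ks) + Ks * K_IP


def ks_from_solubility(s: float, K_IP: float) -> float:
    """Invert ``s = sqrt(Ks) + Ks*K_IP`` for Ks (quadratic in sqrt(Ks))."""
    if s <= 0:
        raise ValueError("s must be positive")
    if K_IP < 0:
        raise ValueError("K_IP must be non-negative")
    if K_IP == 0:
        return s * s
    root = (-1.0 + math.sqrt(1.0 + 4.0 * K_IP * s)) / (2.0 * K_IP)
    return root * root


def solubility_with_common_anion(Ks: float, K_IP: float, c_coion: float) -> float:
    """Total salt solubility in the presence of the common anion at ``c_coion``."""
    if Ks <= 0:
        raise ValueError("Ks must be positive")
    if K_IP < 0 or c_coion < 0:
        raise ValueError("K_IP and c_coion must be non-negative")
    return 0.5 * (2.0 * Ks * K_IP - c_coion + math.sqrt(c_coion**2 + 4.0 * Ks))


def free_na_no_solid(c_na: float, c_anion: float, K_IP: float) -> float:
    """Free cation concentration in a homogeneous ion-pairing solution.

    Solves the 1:1 pairing mass balances; the quadratic root is evaluated in
    a cancellation-safe form and the ``K_IP -> 0`` limit returns ``c_na``
    exactly.
    """
    if K_IP < 0 or c_na < 0 or c_anion < 0:
        raise ValueError("inputs must be non-negative")
    if K_IP * (c_na + c_anion) < 1e-10:
        return c_na
    # K_IP x^2 + (1 + K_IP (c_anion - c_na)) x - c_na = 0
    b = 1.0 + K_IP * (c_anion - c_na)
    disc = math.sqrt(b * b + 4.0 * K_IP * c_na)
    # numerically stable: x = 2 c_na / (b + disc); b + disc > 0 always
    return 2.0 * c_na / (b + disc)


def free_na_with_solid(c_na: float, c_anion: float, Ks: float) -> float:
    """Free cation concentration with the solid salt present (saturation pinned)."""
    if Ks < 0:
        raise ValueError("Ks must be non-negative")
    delta = c_na - c_anion
    if Ks == 0:
        return max(delta, 0.0)
    return 0.5 * (delta + math.sqrt(delta * delta + 4.0 * Ks))


def regime_test(c_na: float, c_anion: float, params: SaltParams) -> str:
    """Classify a composition as ``'no_solid'`` or ``'solid'``.

    The hypothetical homogeneous state is computed first; the solid is
    declared present iff its ion product strictly exceeds Ks (equivalently,
    iff the hypothetical ion-pair concentration exceeds Ks*K_IP).  A state
    exactly at saturation counts as ``'no_solid'``.
    """
    na = free_na_no_solid(c_na, c_anion, params.K_IP)
    an = free_na_no_solid(c_anion, c_na, params.K_IP)  # symmetric balance
    return "solid" if na * an > params.Ks else "no_solid"


def phosphate_solubility_implicit(
    Ks: float, K_IP: float, K_dim: float, c_tba_salt: float
) -> float:
    """Solubility of a dimerizing-anion salt with added common-anion salt.

    The saturated mass balance reduces to a cubic in the free cation
    concentration ``x = s - Ks*K_IP``::

        x**3 + c*x**2 - Ks*x - 2*K_dim*Ks**2 = 0

    which has exactly one positive root (one sign change); the solubility is
    ``s = x + Ks*K_IP``.  At ``K_dim = 0`` and ``c = 0`` this reduces to
    :func:`solubility_pure`.
    """
    if Ks <= 0 or K_IP <= 0:
        raise ValueError("Ks and K_IP must be positive")
    if K_dim < 0 or c_tba_salt < 0:
        raise ValueError("K_dim and c must be non-negative")
    c = c_tba_salt
    if K_dim == 0.0:
        # cubic factors as x*(x^2 + c*x - Ks): the ionic quadratic root
        x = 0.5 * (-c + math.sqrt(c * c + 4.0 * Ks))
        return x + Ks * K_IP

    def poly(x):
        return x**3 + c * x**2 - Ks * x - 2.0 * K_dim * Ks**2

    hi = math.sqrt(Ks) + (2.0 * K_dim * Ks**2) ** (1.0 / 3.0) + 1e-30
    while poly(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise SpeciationError("no positive root consistent with mass balance")
    # poly(0+) = -2*K_dim*Ks^2 < 0, so the unique positive root is bracketed
    x = brentq(poly, 1e-300, hi, xtol=1e-300, rtol=1e-15)
    return x + Ks * K_IP


def phosphate_free_na_saturated(Ks: float, K_dim: float) -> float:
    """Free cation concentration in the pure saturated dimerizing-salt solution.

    The defining sextic ``64*K_dim^2*x^6 - 256*Ks^2*K_dim^3*x^3
    - 64*Ks^2*K_dim^2*x^2 + 256*Ks^4*K_dim^4 = 0`` factors into two cubics;
    only ``x^3 - Ks*x - 2*K_dim*Ks^2 = 0`` satisfies the saturated mass
    balance (the other factor's positive root would imply a negative
    analytical co-ion concentration), so the physical root is selected by
    that consistency condition, not by magnitude.  As ``K_dim -> 0`` the
    root tends to ``sqrt(Ks)``.
    """
    if Ks <= 0 or K_dim < 0:
        raise ValueError("Ks must be positive, K_dim non-negative")
    coeff = 64.0 * K_dim**2 if K_dim > 0 else 1.0
    roots = np.roots(
        [
            coeff,
            0.0,
            0.0,
            -256.0 * Ks**2 * K_dim**3,
            -64.0 * Ks**2 * K_dim**2,
            0.0,
            256.0 * Ks**4 * K_dim**4,
        ]
        if K_dim > 0
        else [1.0, 0.0, -Ks, 0.0]  # degenerate limit: x^2(x^2-Ks)=0 scaled
    )
    candidates = [float(r.real) for r in roots if abs(r.imag) < 1e-12 * max(1.0, abs(r)) and r.real > 0]
    if not candidates:
        raise SpeciationError("root bracketing failed")

    def imbalance(x):
        # pure saturated solution: c_added = Ks/x + 2*K_dim*Ks^2/x^2 - x = 0
        return abs(Ks / x + 2.0 * K_dim * (Ks / x) ** 2 - x)

    return min(candidates, key=imbalance)


def kip_from_saturated(s: float, free_na_sat: float, Ks: float) -> float:
    """K_IP = (s - [Na+]_sat) / Ks from the pure saturated solution."""
    if Ks <= 0:
        raise ValueError("Ks must be positive")
    if free_na_sat < 0:
        raise ValueError("free concentration must be non-negative")
    if s < free_na_sat:
        raise ValueError("s < [Na+]_sat would imply a negative ion-pair concentration")
    return (s - free_na_sat) / Ks


def aes_solubility(
    ppm_measured: float,
    dilution_factor: float,
    diluent_mass_g: float,
    aliquot_volume_mL: float,
    molar_mass: float,
) -> float:
    """Total solubility from a flame-AES reading of an evaporated aliquot.

    The saturated-solvent aliquot (``aliquot_volume_mL``) is evaporated, the
    residue taken up in ``diluent_mass_g`` of water, diluted by
    ``dilution_factor`` into the calibration range and read as
    ``ppm_measured`` (mg analyte per kg of solution; the diluent mass is
    taken as the solution mass).  Returns mol dm^-3 in the original solvent.
    """
    vals = [dilution_factor, diluent_mass_g, aliquot_volume_mL, molar_mass]
    if ppm_measured < 0 or any(v <= 0 for v in vals):
        raise ValueError("inputs must be positive (ppm non-negative)")
    grams = ppm_measured * dilution_factor * 1e-6 * diluent_mass_g
    return (grams / molar_mass) / (aliquot_volume_mL * 1e-3)


# ----------------------------------------------------------------------
# model builder shared with the speciation solver
# ----------------------------------------------------------------------


def salt_model(
    Ks: float | None,
    K_IP: float,
    K_dim: float = 0.0,
    cation: str = "Na",
    anion: str = "A",
) -> EquilibriumModel:
    """EquilibriumModel for one 1:1 salt: ion pair, optional dimer, optional solid."""
    species = []
    if K_IP > 0:
        species.append((f"{cation}{anion}", [1, 1], math.log10(K_IP)))
    if K_dim > 0:
        species.append((f"{anion}2", [0, 2], math.log10(K_dim)))
    solids = []
    if Ks is not None:
        solids.append((f"{cation}{anion}(s)", [1, 1], math.log10(Ks)))
    return EquilibriumModel([cation, anion], species, solids, charges=[1, -1])


# ----------------------------------------------------------------------
# fitters (log-parameter space least squares)
# ----------------------------------------------------------------------


def _ls_fit(residual_fn, names, log10_start, bounds=None):
    """Least squares over log10 parameters with linearized standard errors."""
    res = least_squares(
        residual_fn,
        np.asarray(log10_start, dtype=float),
        bounds=bounds or (-np.inf, np.inf),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    # asymptotic covariance on the log10 scale
    stderr = {}
    try:
        m, n = res.jac.shape
        dof = max(m - n, 1)
        s2 = 2.0 * res.cost / dof
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        diag = np.sqrt(np.maximum(np.diag(cov), 0.0))
        stderr = {f"log10_{k}": float(v) for k, v in zip(names, diag)}
    except np.linalg.LinAlgError:
        stderr = {f"log10_{k}": float("nan") for k in names}
    params = {k: float(10.0**v) for k, v in zip(names, res.x)}
    return params, stderr, res


def _check_series_design(data: SolubilitySeries):
    if len(data.c_coion) < 3 or len(np.unique(data.c_coion)) < 2:
        raise ValueError(
            "non-identifiable design: need >= 3 points with varying co-ion concentration"
        )
    if np.ptp(data.s) == 0:
        raise ValueError("non-identifiable design: solubility column is constant")


def fit_method_A(data: SolubilitySeries) -> SaltFitResult:
    """Fit (Ks, K_IP) to a solubility-vs-common-anion series (method A)."""
    _check_series_design(data)
    s0 = float(data.s[np.argmin(data.c_coion)])
    start = [math.log10(s0**2), 3.0]

    def residual(p):
        Ks, K_IP = 10.0 ** p[0], 10.0 ** p[1]
        model = np.array(
            [solubility_with_common_anion(Ks, K_IP, c) for c in data.c_coion]
        )
        return model - data.s

    params, stderr, res = _ls_fit(residual, ["Ks", "K_IP"], start)
    return SaltFitResult(params, stderr, res.fun, res.success, res.message)


def fit_method_B(
    data: PnaTitrationData, s_fixed: float | None = None
) -> SaltFitResult:
    """Fit the two-regime pNa titration (method B).

    Free parameters: the pure-salt solubility ``s`` and ``Ks`` (``s`` may be
    fixed, as in high-concentration titrations that precipitate from the
    first addition); ``K_IP`` is derived from them through
    ``s = sqrt(Ks) + Ks*K_IP``.  Rows are used with their regime labels when
    present, otherwise auto-labeled at the current parameter iterate.
    """

    def labels_for(params: SaltParams):
        if data.regime is not None:
            return data.regime
        return np.array(
            [
                regime_test(cn, ca, params)
                for cn, ca in zip(data.c_na, data.c_anion)
            ]
        )

    def model_pna(s, Ks):
        if s <= math.sqrt(Ks):
            kip = 0.0
        else:
            kip = kip_from_saturated(s, math.sqrt(Ks), Ks)
        params = SaltParams(Ks, kip)
        lab = labels_for(params)
        free = np.where(
            lab == "solid",
            [free_na_with_solid(cn, ca, Ks) for cn, ca in zip(data.c_na, data.c_anion)],
            [free_na_no_solid(cn, ca, kip) for cn, ca in zip(data.c_na, data.c_anion)],
        )
        return -np.log10(free), lab

    if s_fixed is None:
        names = ["s", "Ks"]
        start = [math.log10(10.0 ** (-data.pna.min()) * 2.0), 2.0 * math.log10(10.0 ** (-data.pna.max()))]

        def residual(p):
            return model_pna(10.0 ** p[0], 10.0 ** p[1])[0] - data.pna

    else:
        names = ["Ks"]
        start = [2.0 * math.log10(10.0 ** (-data.pna.max()))]

        def residual(p):
            return model_pna(s_fixed, 10.0 ** p[0])[0] - data.pna

    params, stderr, res = _ls_fit(residual, names, start)
    s = s_fixed if s_fixed is not None else params["s"]
    Ks = params["Ks"]
    final_params = SaltParams(Ks, kip_from_saturated(s, math.sqrt(Ks), Ks) if s > math.sqrt(Ks) else 0.0)
    lab = labels_for(final_params)
    if data.regime is None and s_fixed is None:
        for reg, pname in (("no_solid", "K_IP identifiability"), ("solid", "Ks identifiability")):
            if not np.any(lab == reg):
                raise ValueError(
                    f"non-identifiable: no rows in regime {reg!r} ({pname} lost)"
                )
    out = dict(params)
    out["s"] = float(s)
    out["K_IP"] = float(final_params.K_IP)
    return SaltFitResult(
        out, stderr, res.fun, res.success, res.message, {"regime": lab.tolist()}
    )


def fit_method_E(data: SolubilitySeries, K_dim_fixed: float) -> SaltFitResult:
    """Fit (Ks, K_IP) to a dimerizing-salt solubility series (method E)."""
    _check_series_design(data)
    if K_dim_fixed < 0:
        raise ValueError("K_dim must be non-negative")
    s0 = float(data.s[np.argmin(data.c_coion)])
    start = [math.log10(max(s0**2 * 1e-4, 1e-16)), math.log10(max(s0 / (s0**2 * 1e-4), 10.0))]

    def residual(p):
        Ks, K_IP = 10.0 ** p[0], 10.0 ** p[1]
        model = np.array(
            [
                phosphate_solubility_implicit(Ks, K_IP, K_dim_fixed, c)
                for c in data.c_coion
            ]
        )
        return (model - data.s) / data.s

    params, stderr, res = _ls_fit(residual, ["Ks", "K_IP"], start)
    return SaltFitResult(params, stderr, res.fun, res.success, res.message)


def fit_method_F(
    data: PnaTitrationData,
    s_fixed: float,
    K_dim_fixed: float,
    weights: np.ndarray | None = None,
    n_reweight: int = 3,
) -> SaltFitResult:
    """Fit Ks to a dimerizing-salt pNa titration (method F), then derive K_IP.

    The pNa residuals are computed from the full speciation (solid + dimer +
    ion pair via the generic solver).  Unless an explicit weight vector is
    supplied, points are weighted by the local sensitivity
    ``|d pNa / d log10 Ks|`` at the current iterate (normalized), focusing
    the fit on the region of the curve most responsive to Ks; a vector of
    ones reduces to ordinary least squares.  K_IP follows from the pure
    saturated solution: ``K_IP = (s - [Na+]_sat)/Ks`` with the free cation
    from :func:`phosphate_free_na_saturated`.
    """
    if s_fixed <= 0 or K_dim_fixed < 0:
        raise ValueError("require s > 0 and K_dim >= 0")

    def kip_of(Ks):
        na_sat = phosphate_free_na_saturated(Ks, K_dim_fixed) if K_dim_fixed > 0 else math.sqrt(Ks)
        if s_fixed <= na_sat:
            return 0.0
        return kip_from_saturated(s_fixed, na_sat, Ks)

    def pna_model(log_ks):
        Ks = 10.0**log_ks
        model = salt_model(Ks, max(kip_of(Ks), 1e-300), K_dim_fixed)
        out = np.empty(len(data.c_na))
        for i, (cn, ca) in enumerate(zip(data.c_na, data.c_anion)):
            out[i] = -math.log10(solve_speciation(model, [cn, ca]).free[0])
        return out

    log_ks = 2.0 * math.log10(10.0 ** (-data.pna.max()))
    w = np.ones(len(data.pna)) if weights is None else np.asarray(weights, float)
    for sweep in range(n_reweight):
        if weights is None and sweep > 0:
            d = 0.05
            sens = np.abs(pna_model(log_ks + d) - pna_model(log_ks - d)) / (2 * d)
            if sens.max() > 0:
                w = sens / sens.max()

        def residual(p):
            return np.sqrt(w) * (pna_model(p[0]) - data.pna)

        params, stderr, res = _ls_fit(residual, ["Ks"], [log_ks])
        new_log_ks = math.log10(params["Ks"])
        done = abs(new_log_ks - log_ks) < 1e-10
        log_ks = new_log_ks
        if done or weights is not None:
            break
    Ks = params["Ks"]
    params["K_IP"] = float(kip_of(Ks))
    params["s"] = float(s_fixed)
    return SaltFitResult(
        params, stderr, res.fun, res.success, res.message, {"weights": w.tolist()}
    )
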