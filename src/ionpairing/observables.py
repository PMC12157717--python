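"""Forward models mapping titration speciation to measured signals.

A :class:`TitrationSchedule` defines the cell composition along a stepwise
titration (exact dilution bookkeeping).  Each ``simulate_*`` function solves
the speciation at every point with :func:`ionpairing.equilibria.solve_speciation`
and maps it to one instrumental observable:

* potentiometry - Nernstian ISE response, ``E = E0 + slope*log10[Na+]``;
* conductometry - ``kappa = 1e-3 * sum(lambda_i * c_i)`` over ionic species
  (molar conductivities in S cm^2 mol^-1, concentrations mol dm^-3, kappa in
  S cm^-1); ion pairs carry no charge and contribute nothing;
* ITC - per-injection heats from the change in species moles weighted by
  the standard formation enthalpies, with the constant-volume overflow
  (perfusion) correction of VP-ITC-class instruments;
* UV - Beer-Lambert additivity over a wavelength grid;
* NMR (fast exchange) - population-weighted average shift over the fast
  pool; slow-exchange species appear as separate signal tracks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .equilibria import (
    GAS_CONSTANT,
    LN10,
    TEMPERATURE,
    EquilibriumModel,
    SpeciationError,
    SpeciationResult,
    solve_speciation,
)

__all__ = [
    "TitrationSchedule",
    "IseCalibration",
    "ConductivityParams",
    "SpectralParams",
    "ShiftParams",
    "EnthalpySet",
    "titration_speciation",
    "simulate_potentiometric",
    "calibrate_ise",
    "simulate_conductometric",
    "fit_conductometric",
    "itc_delta_moles",
    "simulate_itc",
    "simulate_uv",
    "simulate_nmr_fast",
]


@dataclass
class TitrationSchedule:
    """Stepwise titration: initial cell + titrant compositions + additions.

    Volumes in dm^3, concentrations in mol dm^-3.  ``additions`` holds the
    individual injection volumes; totals after ``k`` additions follow the
    exact dilution relation ``(V0*c0 + Vadd*c_titrant)/(V0 + Vadd)`` with
    ``Vadd`` the cumulative added volume.
    """

    v0: float
    c0: dict[str, float]
    c_titrant: dict[str, float]
    additions: np.ndarray

    def __post_init__(self):
        self.additions = np.asarray(self.additions, dtype=float)
        if self.v0 <= 0 or np.any(self.additions <= 0):
            raise ValueError("volumes must be positive")
        for d in (self.c0, self.c_titrant):
            if any(v < 0 for v in d.values()):
                raise ValueError("concentrations must be non-negative")

    @property
    def n_points(self) -> int:
        return len(self.additions) + 1  # initial state is point 0

    @property
    def cumulative_volume(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.additions)])

    def totals(self, components: list[str]) -> np.ndarray:
        """Analytical concentrations, shape (n_points, n_components)."""
        vadd = self.cumulative_volume
        c0 = np.array([self.c0.get(c, 0.0) for c in components])
        ct = np.array([self.c_titrant.get(c, 0.0) for c in components])
        return (self.v0 * c0[None, :] + vadd[:, None] * ct[None, :]) / (
            self.v0 + vadd[:, None]
        )


def titration_speciation(
    schedule: TitrationSchedule, model: EquilibriumModel, allow_solids: bool = True
) -> list[SpeciationResult]:
    """Solve the speciation at every titration point (point 0 = initial)."""
    out = []
    for k, tot in enumerate(schedule.totals(model.components)):
        try:
            out.append(solve_speciation(model, tot, allow_solids=allow_solids))
        except SpeciationError as exc:  # annotate with the failing point
            raise SpeciationError(f"titration point {k}: {exc}") from exc
    return out


def speciation_table(
    schedule: TitrationSchedule, model: EquilibriumModel, allow_solids: bool = True
) -> pd.DataFrame:
    """One row per titration point, one column per species (CSV-ready)."""
    states = titration_speciation(schedule, model, allow_solids)
    rows = []
    for k, st in enumerate(states):
        row = {"point": k, "v_added": schedule.cumulative_volume[k]}
        row.update({f"free_{c}": v for c, v in zip(model.components, st.free)})
        row.update(dict(zip(model.species_names, st.species)))
        row.update({f"solid_{s.name}": a for s, a in zip(model.solids, st.solid_amounts)})
        rows.append(row)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# potentiometry
# ----------------------------------------------------------------------


@dataclass
class IseCalibration:
    """Linear ISE response: ``E = intercept + slope * log10(c)`` (mV)."""

    intercept: float
    slope: float

    def __post_init__(self):
        if not (math.isfinite(self.intercept) and math.isfinite(self.slope)):
            raise ValueError("calibration parameters must be finite")
        if self.slope == 0:
            raise ValueError("slope must be nonzero")


def calibrate_ise(concentrations, potentials) -> IseCalibration:
    """Least-squares line of measured E (mV) vs. log10 of known concentration."""
    c = np.asarray(concentrations, dtype=float)
    e = np.asarray(potentials, dtype=float)
    if len(c) < 2 or len(np.unique(c)) < 2:
        raise ValueError("need at least two distinct standards")
    slope, intercept = np.polyfit(np.log10(c), e, 1)
    return IseCalibration(float(intercept), float(slope))


def simulate_potentiometric(
    schedule: TitrationSchedule,
    model: EquilibriumModel,
    calibration: IseCalibration,
    ion: str = "Na",
) -> pd.DataFrame:
    """pNa and electrode potential along the titration.

    The pNa series is continuous in value across the precipitation onset
    (only its slope changes regime).
    """
    states = titration_speciation(schedule, model)
    free = np.array([st.free_conc(ion) for st in states])
    pna = -np.log10(free)
    e = calibration.intercept + calibration.slope * np.log10(free)
    solid = np.array(
        [bool(np.any(st.solid_amounts > 0)) for st in states]
    )
    return pd.DataFrame(
        {
            "point": np.arange(schedule.n_points),
            "v_added": schedule.cumulative_volume,
            "pna": pna,
            "E": e,
            "solid_present": solid,
        }
    )


# ----------------------------------------------------------------------
# conductometry
# ----------------------------------------------------------------------


@dataclass
class ConductivityParams:
    """Molar conductivities per ionic species, S cm^2 mol^-1.

    Species not listed contribute nothing (ion pairs and other neutral
    species); a *charged* species without an entry is an error when the
    model carries charge information.
    """

    lambdas: dict[str, float]

    def __post_init__(self):
        if any(v < 0 for v in self.lambdas.values()):
            raise ValueError("molar conductivities must be non-negative")


def simulate_conductometric(
    schedule: TitrationSchedule,
    model: EquilibriumModel,
    params: ConductivityParams,
) -> pd.DataFrame:
    """Solution conductivity kappa (S cm^-1) along the titration."""
    if model.charges is not None:
        for name in model.species_names:
            if model.species_charge(name) != 0 and name not in params.lambdas:
                raise ValueError(f"charged species {name!r} has no molar conductivity")
    states = titration_speciation(schedule, model)
    lam = np.array([params.lambdas.get(n, 0.0) for n in model.species_names])
    kappa = np.array([1e-3 * float(lam @ st.species) for st in states])
    return pd.DataFrame(
        {
            "point": np.arange(schedule.n_points),
            "v_added": schedule.cumulative_volume,
            "kappa": kappa,
        }
    )


def fit_conductometric(
    data: pd.DataFrame,
    schedule: TitrationSchedule,
    model_builder,
    lambdas_known: dict[str, float],
    lambda_unknown: str | None,
    fit_kip: bool = True,
    log_kip_start: float = 3.0,
):
    """Joint fit of K_IP and one unknown molar conductivity to a kappa series.

    ``model_builder(K_IP)`` must return the EquilibriumModel at a candidate
    ion-pairing constant.  Literature conductivities are frozen for every
    ion except ``lambda_unknown``, which enters linearly and is solved by
    linear least squares at each K_IP iterate (variable projection); pass
    ``fit_kip=False`` for a conductivity-only fit on a pairing-free system.
    """
    from scipy.optimize import least_squares

    kappa_obs = np.asarray(data["kappa"], dtype=float)

    def kappa_split(log_kip):
        model = model_builder(10.0**log_kip if fit_kip else 0.0)
        states = titration_speciation(schedule, model)
        names = model.species_names
        lam_fixed = np.array([lambdas_known.get(n, 0.0) for n in names])
        base = np.array([1e-3 * float(lam_fixed @ st.species) for st in states])
        if lambda_unknown is None:
            return base, np.zeros_like(base)
        j = names.index(lambda_unknown)
        coef = np.array([1e-3 * st.species[j] for st in states])
        return base, coef

    def solve_lambda(log_kip):
        base, coef = kappa_split(log_kip)
        if lambda_unknown is None:
            return base, 0.0
        denom = float(coef @ coef)
        if denom == 0.0:
            raise ValueError(
                "non-identifiable: the unknown-conductivity species never forms"
            )
        lam = float(coef @ (kappa_obs - base)) / denom
        return base + lam * coef, lam

    if fit_kip:
        res = least_squares(
            lambda p: solve_lambda(p[0])[0] - kappa_obs,
            [log_kip_start],
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-15,
        )
        log_kip = float(res.x[0])
        converged, message, resid = res.success, res.message, res.fun
    else:
        log_kip = -np.inf
        model_k, lam = solve_lambda(log_kip)
        converged, message, resid = True, "linear solve", model_k - kappa_obs
    pred, lam = solve_lambda(log_kip)
    resid = pred - kappa_obs
    out = {"K_IP": 10.0**log_kip if fit_kip else 0.0}
    if lambda_unknown is not None:
        out[f"lambda_{lambda_unknown}"] = lam
    if fit_kip and lambda_unknown is not None and np.allclose(resid, 0) and out["K_IP"] < 1e-6:
        message += "; warning: no pairing signature, K_IP and lambda may be degenerate"
    from .salts import SaltFitResult

    return SaltFitResult(out, {}, resid, bool(converged), str(message))


# ----------------------------------------------------------------------
# calorimetry
# ----------------------------------------------------------------------


@dataclass
class EnthalpySet:
    """Standard formation enthalpies per species (kJ mol^-1) + cell model.

    ``dh`` maps species name -> Delta_r H standard of its formation reaction
    from the free components; identity species implicitly 0.
    ``dilution_heat`` is a constant per-injection baseline in microjoules
    (mirrors blank-titration correction).
    """

    dh: dict[str, float]
    cell_volume: float
    dilution_heat: float = 0.0

    def __post_init__(self):
        if self.cell_volume <= 0:
            raise ValueError("cell volume must be positive")
        if any(not math.isfinite(v) for v in self.dh.values()):
            raise ValueError("enthalpies must be finite")

    def thermo_table(self, model: EquilibriumModel) -> pd.DataFrame:
        """Delta_r G, Delta_r H and -T*Delta_r S per formation reaction."""
        rows = []
        for sp in model.species:
            if sp.log_beta == 0.0 and list(sp.stoich).count(1) == 1 and all(
                v in (0, 1) for v in sp.stoich
            ):
                continue
            dg = -GAS_CONSTANT * TEMPERATURE * LN10 * sp.log_beta / 1000.0
            dh = self.dh.get(sp.name, 0.0)
            rows.append(
                {
                    "species": sp.name,
                    "log10_beta": sp.log_beta,
                    "drG_kJ_mol": dg,
                    "drH_kJ_mol": dh,
                    "minus_TdrS_kJ_mol": dg - dh,
                }
            )
        return pd.DataFrame(rows)


def itc_delta_moles(
    schedule: TitrationSchedule,
    model: EquilibriumModel,
    cell_volume: float,
    allow_solids: bool = True,
) -> np.ndarray:
    """Per-injection change in species moles, shape (n_injections, n_species).

    Perfusion-cell ledger: the active volume stays constant, each injection
    of ``dV`` mixes in and expels ``dV`` of the mixed contents.  Entry
    ``(k, j)`` is the moles of species ``j`` formed by injection ``k`` over
    the whole closed system (cell + expelled liquid + syringe), so columns
    sum exactly to the final-minus-initial species inventory.
    """
    v0 = cell_volume
    comps = model.components
    c_cell = np.array([schedule.c0.get(c, 0.0) for c in comps])
    c_syr = np.array([schedule.c_titrant.get(c, 0.0) for c in comps])
    st_syr = solve_speciation(model, c_syr, allow_solids=False)
    st = solve_speciation(model, c_cell, allow_solids=allow_solids)
    rows = []
    for k, dv in enumerate(schedule.additions, start=1):
        c_cell = (c_cell * v0 + c_syr * dv) / (v0 + dv)
        try:
            st_new = solve_speciation(model, c_cell, allow_solids=allow_solids)
        except SpeciationError as exc:
            raise SpeciationError(f"injection {k}: {exc}") from exc
        rows.append(
            v0 * (st_new.species - st.species) + dv * (st_new.species - st_syr.species)
        )
        st = st_new
    return np.array(rows)


def simulate_itc(
    schedule: TitrationSchedule,
    model: EquilibriumModel,
    enthalpies: EnthalpySet,
    allow_solids: bool = True,
) -> pd.DataFrame:
    """Per-injection heats (microjoules) for a perfusion (overflow) ITC cell.

    ``Q_k = sum_j drH_j * dn_j(k) + dilution baseline`` with the mole ledger
    from :func:`itc_delta_moles`; the per-injection heats therefore sum to
    the enthalpy content difference between the final and initial states.
    """
    dh = np.array([enthalpies.dh.get(n, 0.0) for n in model.species_names])
    dn = itc_delta_moles(schedule, model, enthalpies.cell_volume, allow_solids)
    heats = dn @ dh * 1e9 + enthalpies.dilution_heat  # kJ -> uJ
    return pd.DataFrame(
        {
            "injection": np.arange(1, len(heats) + 1),
            "v_injected": schedule.additions,
            "heat_uJ": heats,
        }
    )


# ----------------------------------------------------------------------
# UV spectrophotometry
# ----------------------------------------------------------------------


@dataclass
class SpectralParams:
    """Wavelength grid (nm), molar absorptivities per species, path length (cm)."""

    wavelengths: np.ndarray
    epsilon: dict[str, np.ndarray]
    path_length: float = 1.0

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.epsilon = {k: np.asarray(v, dtype=float) for k, v in self.epsilon.items()}
        for name, eps in self.epsilon.items():
            if eps.shape != self.wavelengths.shape:
                raise ValueError(f"epsilon grid mismatch for {name!r}")
            if np.any(eps < 0):
                raise ValueError(f"negative absorptivity for {name!r}")
        if self.path_length <= 0:
            raise ValueError("path length must be positive")


def simulate_uv(
    schedule: TitrationSchedule,
    model: EquilibriumModel,
    spectra: SpectralParams,
    allow_solids: bool = True,
) -> pd.DataFrame:
    """Absorbance matrix (titration points x wavelengths), Beer-Lambert additive."""
    states = titration_speciation(schedule, model, allow_solids)
    eps = np.array(
        [
            spectra.epsilon.get(n, np.zeros_like(spectra.wavelengths))
            for n in model.species_names
        ]
    )  # (n_species, n_wl)
    conc = np.array([st.species for st in states])  # (n_points, n_species)
    a = spectra.path_length * conc @ eps
    return pd.DataFrame(
        a, columns=[f"{w:g}" for w in spectra.wavelengths]
    ).assign(point=np.arange(len(states))).set_index("point")


# ----------------------------------------------------------------------
# NMR
# ----------------------------------------------------------------------


@dataclass
class ShiftParams:
    """Chemical shifts per species (ppm) and the fast-exchange species set.

    Species outside ``fast_species`` are slow on the shift timescale: they
    are excluded from population averaging and reported as separate signal
    tracks with intensities proportional to their populations.
    """

    shifts: dict[str, float]
    fast_species: set[str] = field(default_factory=set)


def simulate_nmr_fast(
    schedule: TitrationSchedule,
    model: EquilibriumModel,
    shifts: ShiftParams,
    pool: str,
    normalize: bool = True,
    allow_solids: bool = True,
) -> pd.DataFrame:
    """Fast-exchange averaged shift of the ``pool`` nucleus along the titration.

    ``delta_obs = sum f_i * delta_i`` over fast-exchanging species containing
    the pool component, with ``f_i`` the fraction of the pool they hold.
    With ``normalize=True`` fractions are renormalized within the fast pool
    (the usual approximation when a slow equilibrium sequesters part of the
    pool); with ``normalize=False`` a fast pool not holding the whole
    nucleus budget is an error.  Slow species holding the pool appear as
    extra ``delta_<name>`` / ``frac_<name>`` columns.
    """
    comps = model.components
    if pool not in comps:
        raise ValueError(f"unknown pool component {pool!r}")
    jp = comps.index(pool)
    states = titration_speciation(schedule, model, allow_solids)
    nu = model.nu
    names = model.species_names
    holders = [i for i in range(len(names)) if nu[i, jp] != 0]
    for i in holders:
        if names[i] in shifts.fast_species and names[i] not in shifts.shifts:
            raise ValueError(f"fast species {names[i]!r} has no shift value")
    fast = [i for i in holders if names[i] in shifts.fast_species]
    slow = [i for i in holders if names[i] not in shifts.fast_species]

    rows = []
    for k, st in enumerate(states):
        pool_total = float(sum(nu[i, jp] * st.species[i] for i in holders))
        fast_total = float(sum(nu[i, jp] * st.species[i] for i in fast))
        if fast_total <= 0:
            raise ValueError(f"point {k}: empty fast pool")
        if not normalize and abs(fast_total / pool_total - 1.0) > 1e-9:
            raise ValueError(
                f"point {k}: fast-pool fractions sum to {fast_total / pool_total:.6f}, not 1"
            )
        delta = sum(
            nu[i, jp] * st.species[i] / fast_total * shifts.shifts[names[i]]
            for i in fast
        )
        row = {"point": k, "delta_obs": float(delta)}
        for i in slow:
            row[f"frac_{names[i]}"] = float(nu[i, jp] * st.species[i] / pool_total)
            if names[i] in shifts.shifts:
                row[f"delta_{names[i]}"] = shifts.shifts[names[i]]
        rows.append(row)
    return pd.DataFrame(rows)
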