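"""General solver for simultaneous solution equilibria with optional solid phases.

Chemical systems are described by an :class:`EquilibriumModel`: a set of
*components* (the independent building blocks, e.g. ``Na`` and ``Cl``),
*species* formed from them with cumulative formation constants
``beta = [species] / prod([component]^nu)`` and, optionally, *solid phases*
governed by solubility products ``Ks = prod([component]^nu)`` at saturation.

Speciation (the free and species concentrations satisfying all mass balances
and, for saturated solids, the complementarity condition) is obtained by a
damped Newton iteration in log-concentration space with an active-set
treatment of the solids.  This solver is the single source of truth against
which every closed-form salt model in :mod:`ionpairing.salts` is verified.

Conventions: concentrations in mol dm^-3, constants on the molar scale,
activity coefficients taken as unity (constant ionic strength assumption),
temperature fixed at 298.15 K.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "GAS_CONSTANT",
    "TEMPERATURE",
    "LN10",
    "EquilibriumModel",
    "SpeciationResult",
    "SpeciationError",
    "solve_speciation",
    "ion_product",
    "oracle_solve_1d",
    "load_model",
    "save_model",
]

#: Gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314
#: Working temperature, K.  All K <-> Gibbs-energy conversions use this value.
TEMPERATURE = 298.15
LN10 = math.log(10.0)

# Solver settings (log-residual tolerance, iteration cap per start).
_TOL = 1e-12
_MAX_ITER = 200
_MAX_STEP = 50.0  # cap on a Newton step in ln-concentration units


class SpeciationError(RuntimeError):
    """Raised when the speciation problem cannot be solved."""


@dataclass(frozen=True)
class Species:
    name: str
    stoich: tuple[int, ...]
    log_beta: float


@dataclass(frozen=True)
class Solid:
    name: str
    stoich: tuple[int, ...]
    log_ks: float


@dataclass
class EquilibriumModel:
    """Components, soluble species and solid phases of one chemical system.

    Parameters
    ----------
    components
        Ordered component names.  Each component is automatically present as
        a species with identity stoichiometry and ``log_beta = 0``.
    species
        ``(name, stoichiometry, log10 beta)`` triples for the *formed*
        species; identity species need not (but may) be listed.
    solids
        ``(name, stoichiometry, log10 Ks)`` triples.
    charges
        Optional per-component charges; species charges follow by summation.
        Only needed by observables that distinguish ions from neutral species.
    """

    components: list[str]
    species: list[Species] = field(default_factory=list)
    solids: list[Solid] = field(default_factory=list)
    charges: list[int] | None = None

    def __init__(self, components, species=(), solids=(), charges=None):
        self.components = list(components)
        n = len(self.components)
        if len(set(self.components)) != n:
            raise ValueError("component names must be unique")
        self.charges = None if charges is None else list(charges)
        if self.charges is not None and len(self.charges) != n:
            raise ValueError("charges must match components")

        def _norm(entries, cls):
            out = []
            for entry in entries:
                if isinstance(entry, cls):
                    name, stoich, logk = entry.name, entry.stoich, (
                        entry.log_beta if cls is Species else entry.log_ks
                    )
                else:
                    name, stoich, logk = entry
                if isinstance(stoich, dict):
                    vec = [int(stoich.get(c, 0)) for c in self.components]
                else:
                    vec = [int(v) for v in stoich]
                if len(vec) != n:
                    raise ValueError(f"stoichiometry of {name!r} has wrong length")
                if not any(vec):
                    raise ValueError(f"species {name!r} has all-zero stoichiometry")
                if not math.isfinite(logk):
                    raise ValueError(f"constant of {name!r} is not finite")
                out.append(cls(name, tuple(vec), float(logk)))
            return out

        listed = _norm(species, Species)
        # prepend identity species for each component unless explicitly given
        ident = []
        for j, comp in enumerate(self.components):
            vec = tuple(1 if k == j else 0 for k in range(n))
            if not any(sp.stoich == vec for sp in listed):
                ident.append(Species(comp, vec, 0.0))
        self.species = ident + listed
        names = [sp.name for sp in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        self.solids = _norm(solids, Solid)
        snames = [s.name for s in self.solids]
        if len(set(snames)) != len(snames):
            raise ValueError("solid names must be unique")

    # -- matrix views ----------------------------------------------------
    @property
    def nu(self) -> np.ndarray:
        """Species stoichiometry matrix, shape (n_species, n_components)."""
        return np.array([sp.stoich for sp in self.species], dtype=float)

    @property
    def nu_solid(self) -> np.ndarray:
        return np.array([s.stoich for s in self.solids], dtype=float).reshape(
            len(self.solids), len(self.components)
        )

    @property
    def log_betas(self) -> np.ndarray:
        return np.array([sp.log_beta for sp in self.species])

    @property
    def species_names(self) -> list[str]:
        return [sp.name for sp in self.species]

    def species_charge(self, name: str) -> int:
        if self.charges is None:
            raise ValueError("model has no charge information")
        sp = self.species[self.species_names.index(name)]
        return int(sum(z * v for z, v in zip(self.charges, sp.stoich)))


@dataclass
class SpeciationResult:
    """Converged equilibrium state of one composition."""

    model: EquilibriumModel
    free: np.ndarray  # free component concentrations
    species: np.ndarray  # concentrations per model species
    solid_amounts: np.ndarray  # mol dm^-3 equivalents per model solid
    converged: bool
    residual_norm: float

    def species_conc(self, name: str) -> float:
        return float(self.species[self.model.species_names.index(name)])

    def free_conc(self, name: str) -> float:
        return float(self.free[self.model.components.index(name)])

    def to_dict(self) -> dict:
        m = self.model
        return {
            "free": {c: float(v) for c, v in zip(m.components, self.free)},
            "species": {s: float(v) for s, v in zip(m.species_names, self.species)},
            "solids": {s.name: float(v) for s, v in zip(m.solids, self.solid_amounts)},
            "converged": bool(self.converged),
            "residual_norm": float(self.residual_norm),
        }


def _validate_totals(model: EquilibriumModel, totals) -> np.ndarray:
    t = np.asarray(totals, dtype=float)
    if t.shape != (len(model.components),):
        raise ValueError("totals length must match components")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("totals must be finite and non-negative")
    return t


def _newton(nu, lb_ln, totals, nu_act, lnks_act, x0):
    """Damped Newton for mass balance + pinned-saturation equations.

    Unknowns: x = ln(free) per component, n = solid amount per active solid.
    Residuals: (calc_total + nu_s.n - T)/T per component and
    nu_s.x - ln Ks per active solid.
    """
    ncomp = nu.shape[1]
    nact = nu_act.shape[0]
    x = np.array(x0, dtype=float)
    namt = np.zeros(nact)

    def residual(x, namt):
        conc = np.exp(lb_ln + nu @ x)
        calc = nu.T @ conc
        f = (calc + (nu_act.T @ namt if nact else 0.0) - totals) / totals
        if nact:
            g = nu_act @ x - lnks_act
            return np.concatenate([f, g]), conc
        return f, conc

    f, conc = residual(x, namt)
    norm = np.max(np.abs(f))
    for _ in range(_MAX_ITER):
        if norm < _TOL:
            return x, namt, True, norm
        J = np.zeros((ncomp + nact, ncomp + nact))
        # d calc_j / d x_k = sum_i nu_ij nu_ik c_i
        J[:ncomp, :ncomp] = (nu.T * conc) @ nu / totals[:, None]
        if nact:
            J[:ncomp, ncomp:] = nu_act.T / totals[:, None]
            J[ncomp:, :ncomp] = nu_act
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            return x, namt, False, norm
        smax = np.max(np.abs(step[:ncomp])) if ncomp else 0.0
        if smax > _MAX_STEP:
            step *= _MAX_STEP / smax
        lam = 1.0
        for _ in range(40):
            xn = x + lam * step[:ncomp]
            nn = namt + lam * step[ncomp:]
            fn, cn = residual(xn, nn)
            nn_norm = np.max(np.abs(fn))
            if np.isfinite(nn_norm) and nn_norm < norm * (1.0 - 1e-4 * lam) + 1e-300:
                x, namt, f, conc, norm = xn, nn, fn, cn, nn_norm
                break
            lam *= 0.5
        else:
            return x, namt, norm < 1e-9, norm
    return x, namt, norm < _TOL, norm


def solve_speciation(
    model: EquilibriumModel, totals, allow_solids: bool = True
) -> SpeciationResult:
    """Solve the equilibrium speciation for one analytical composition.

    With ``allow_solids=False`` the solid phases are treated as absent even
    when the solution would be supersaturated (used e.g. to evaluate the
    hypothetical homogeneous state in precipitation-onset tests).

    Raises
    ------
    SpeciationError
        If no Newton start converges.
    ValueError
        For negative or malformed totals.
    """
    totals = _validate_totals(model, totals)
    ncomp = len(model.components)

    # eliminate zero-total components: their free concentration is zero and
    # every species/solid consuming them is absent
    active = totals > 0
    if not np.all(active):
        nu_full = model.nu
        for sp, row in zip(model.species, nu_full):
            if np.any(row[~active] < 0):
                raise SpeciationError(
                    f"species {sp.name!r} releases a zero-total component"
                )
    nu_all = model.nu
    keep_sp = [
        i for i, row in enumerate(nu_all) if not np.any(row[~active] != 0)
    ]
    nu = nu_all[np.ix_(keep_sp, np.where(active)[0])]
    lb_ln = model.log_betas[keep_sp] * LN10
    t_act = totals[active]

    nu_solid_all = model.nu_solid
    solid_ok = [
        i
        for i in range(len(model.solids))
        if not np.any(nu_solid_all[i][~active] != 0)
    ]
    nu_solid = nu_solid_all[np.ix_(solid_ok, np.where(active)[0])] if solid_ok else np.zeros((0, int(active.sum())))
    lnks = np.array([model.solids[i].log_ks for i in solid_ok]) * LN10

    nact_comp = int(active.sum())
    if nact_comp == 0:
        return SpeciationResult(
            model,
            np.zeros(ncomp),
            np.zeros(len(model.species)),
            np.zeros(len(model.solids)),
            True,
            0.0,
        )

    starts = [
        np.log(t_act),  # all free
        np.log(t_act) - 6.0 * LN10,  # strongly bound
        np.full(nact_comp, math.log(1e-7)),  # uniform trace
    ]

    def solve_with(active_set: list[int]):
        na = nu_solid[active_set] if active_set else np.zeros((0, nact_comp))
        ka = lnks[active_set] if active_set else np.zeros(0)
        best = None
        for x0 in starts:
            x, namt, ok, norm = _newton(nu, lb_ln, t_act, na, ka, x0)
            if ok:
                return x, namt, norm
            if best is None or norm < best[2]:
                best = (x, namt, norm)
        raise SpeciationError(
            f"speciation did not converge (best residual {best[2]:.3e})"
        )

    active_solids: list[int] = []
    x = namt = None
    norm = np.inf
    if not allow_solids or not solid_ok:
        x, namt, norm = solve_with([])
    else:
        # active-set loop: activate the most supersaturated solid one at a
        # time, drop solids whose amounts turn negative
        for _ in range(2 * len(solid_ok) + 2):
            x, namt, norm = solve_with(active_solids)
            neg = [s for s, a in zip(active_solids, namt) if a < -1e-15 * t_act.max()]
            if neg:
                active_solids = [s for s in active_solids if s not in neg]
                continue
            lnip = nu_solid @ x
            viol = [
                i
                for i in range(len(solid_ok))
                if i not in active_solids and lnip[i] > lnks[i] + 1e-12
            ]
            if not viol:
                break
            active_solids.append(max(viol, key=lambda i: lnip[i] - lnks[i]))
        else:
            raise SpeciationError("active-set iteration did not settle")

    free = np.zeros(ncomp)
    free[active] = np.exp(x)
    conc = np.zeros(len(model.species))
    conc[keep_sp] = np.exp(lb_ln + nu @ x)
    amounts = np.zeros(len(model.solids))
    for s, a in zip(active_solids, namt):
        amounts[solid_ok[s]] = max(a, 0.0)
    return SpeciationResult(model, free, conc, amounts, True, float(norm))


def ion_product(result: SpeciationResult, solid: str) -> float:
    """Ion product of ``solid``: product of free concentrations to its stoichiometry."""
    names = [s.name for s in result.model.solids]
    if solid not in names:
        raise KeyError(f"unknown solid {solid!r}")
    stoich = result.model.solids[names.index(solid)].stoich
    return float(np.prod(result.free ** np.array(stoich, dtype=float)))


def oracle_solve_1d(model: EquilibriumModel, totals) -> SpeciationResult:
    """Brute-force verifier for models reducible to one unknown free concentration.

    The first component's free concentration is scanned on a log grid and the
    remainder solved in closed form, which requires a triangular structure:
    for every later component ``j`` each species containing it must be linear
    in it and involve only earlier components.  Solution-phase models only.

    Independent of :func:`solve_speciation` (bracketing + bisection, no
    Newton); used to cross-validate it.
    """
    totals = _validate_totals(model, totals)
    if model.solids:
        raise SpeciationError("oracle handles solution-phase models only")
    active_idx = [j for j, t in enumerate(totals) if t > 0]
    if not active_idx:
        return solve_speciation(model, totals)
    nu = model.nu[:, active_idx]
    betas = 10.0 ** model.log_betas
    keep = [i for i, row in enumerate(model.nu) if not any(
        row[j] != 0 for j in range(len(model.components)) if j not in active_idx
    )]
    nu = model.nu[np.ix_(keep, active_idx)]
    betas = betas[keep]
    t = totals[active_idx]
    ncomp = len(active_idx)
    for j in range(1, ncomp):
        for i in range(len(keep)):
            if nu[i, j] != 0:
                if nu[i, j] != 1 or np.any(nu[i, j + 1 :] != 0):
                    raise SpeciationError("model is not reducible to one unknown")

    def closed_form(f0: float) -> np.ndarray:
        f = np.empty(ncomp)
        f[0] = f0
        for j in range(1, ncomp):
            denom = 0.0
            for i in range(len(keep)):
                if nu[i, j] == 1:
                    denom += betas[i] * np.prod(f[:j] ** nu[i, :j])
            f[j] = t[j] / denom
        return f

    def residual(f0: float) -> float:
        f = closed_form(f0)
        conc = betas * np.prod(f ** nu, axis=1)
        return float(nu[:, 0] @ conc - t[0])

    # top of the grid one decade above the total: the pivot's free
    # concentration cannot exceed its total, so the root is bracketed
    grid = np.logspace(math.log10(t[0]) - 20, math.log10(t[0]) + 1, 4000)
    vals = np.array([residual(g) for g in grid])
    sign = np.sign(vals)
    idx = np.where(np.diff(sign) != 0)[0]
    if len(idx) == 0:
        raise SpeciationError("oracle bracketing failed")
    lo, hi = grid[idx[0]], grid[idx[0] + 1]
    from scipy.optimize import brentq

    f0 = brentq(residual, lo, hi, xtol=1e-300, rtol=1e-15, maxiter=300)
    f = closed_form(f0)
    free = np.zeros(len(model.components))
    for j, a in enumerate(active_idx):
        free[a] = f[j]
    conc = np.zeros(len(model.species))
    conc[keep] = betas * np.prod(f ** nu, axis=1)
    return SpeciationResult(model, free, conc, np.zeros(len(model.solids)), True, abs(residual(f0)) / t[0])


# -- model configuration files ------------------------------------------


def load_model(path) -> EquilibriumModel:
    """Read an :class:`EquilibriumModel` from a YAML model-definition file.

    Expected sections: ``components`` (list), ``species`` and ``solids``
    (lists of mappings with ``name``, ``stoich`` and ``log_beta`` /
    ``log_Ks``), optional ``charges``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    species = [
        (sp["name"], sp["stoich"], sp["log_beta"]) for sp in cfg.get("species", [])
    ]
    solids = [
        (s["name"], s["stoich"], s.get("log_Ks", s.get("log_ks")))
        for s in cfg.get("solids", [])
    ]
    return EquilibriumModel(
        cfg["components"], species, solids, cfg.get("charges")
    )


def save_model(model: EquilibriumModel, path) -> None:
    cfg = {
        "components": model.components,
        "species": [
            {"name": sp.name, "stoich": list(sp.stoich), "log_beta": sp.log_beta}
            for sp in model.species
            if sp.log_beta != 0.0 or list(sp.stoich).count(1) != 1 or any(v not in (0, 1) for v in sp.stoich)
        ],
        "solids": [
            {"name": s.name, "stoich": list(s.stoich), "log_Ks": s.log_ks}
            for s in model.solids
        ],
    }
    if model.charges is not None:
        cfg["charges"] = model.charges
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def result_to_json(result: SpeciationResult) -> str:
    return json.dumps(result.to_dict(), indent=2)
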