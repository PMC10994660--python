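"""Flux estimation: multi-start least squares, efflux scan, efflux scaling.

The fitting problem mirrors the study design: glucose uptake is pinned to
100, lactate efflux to a configured value, the remaining boundary fluxes
(nucleotide-synthesis drain, fatty-acid acetyl-CoA supply) are fixed at
profile values, and the free fluxes (by default the oxidative PPP branch
G6PD and anaplerotic pyruvate carboxylase PC) are estimated by weighted
least squares between simulated and measured mass-distribution vectors,
with `cycles` random restarts.

The lactate-efflux scan reproduces the trial-and-error selection: each
candidate efflux is classified as ``infeasible`` (no steady-state flux
vector within the profile's bounds), ``reversed_glycolysis`` (all feasible
vectors run part of glycolysis backwards), or ``ok`` (fit performed); the
ok candidate with minimal residual is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, linprog

from .cumomer import CumomerSimulator, DeadMetaboliteError
from .network import FluxModel, FluxSpace

#: Default modeling cycle counts of the fitting procedure.
DEFAULT_CYCLES = 100
DEFAULT_MAX_ITERATIONS = 2000

#: Net-flux threshold below which a glycolytic step counts as reversed.
REVERSAL_TOL = -1e-6

#: First labeled isotopologue produced from a uniformly labeled glucose
#: feed ("first pass"): fully labeled hexoses/trioses/pentoses, M+2
#: acetyl-CoA-derived first-turn TCA species, M+3 anaplerotic OAA.
FIRST_PASS_SHIFT = {
    "G6P": 6, "F6P": 6, "FBP": 6, "DHAP": 3, "GAP": 3, "PG3": 3, "PEP": 3,
    "PYR": 3, "LAC": 3, "RU5P": 5, "R5P": 5, "X5P": 5, "S7P": 7, "E4P": 4,
    "CIT": 2, "AKG": 2, "SUC": 2, "FUM": 2, "MAL": 2, "OAA": 3,
}


class FitFailureError(RuntimeError):
    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class ScanFailureError(RuntimeError):
    def __init__(self, message, statuses: pd.DataFrame):
        super().__init__(message)
        self.statuses = statuses


@dataclass
class FitProfile:
    """Constraint profile of a fit: what is pinned, fixed, free and bounded.

    ``pinned`` holds the hard boundary constraints (glucose uptake,
    lactate efflux, fixed drains/supplies); ``free`` names the pivot
    reactions estimated from the data; ``bounds`` are linear inequality
    bounds on any reactions, enforced as box bounds where possible and as
    hinge penalties otherwise; ``glycolysis`` lists the reactions whose
    net flux must be non-negative for a solution to count as "glycolysis
    running forward".
    """

    pinned: dict[str, float]
    free: list[str]
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    glycolysis: list[str] = field(default_factory=list)

    def theta_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([self.bounds.get(n, (0.0, np.inf))[0] for n in self.free])
        ub = np.array([self.bounds.get(n, (0.0, np.inf))[1] for n in self.free])
        return lb, ub


#: Glycolytic chain used for reversed-glycolysis detection.
GLYCOLYSIS_CHAIN = ["HK", "PGI", "PFK", "ALD", "TPI", "GAPDH", "PGM_ENO", "PK"]


def hsc_profile(
    lactate_efflux: float = 65.0,
    nas_drain: float = 14.0,
    fao_supply: float = 30.0,
    oxidative_capacity: float = 110.0,
    anaplerosis_cap: float = 20.0,
    glucose_uptake: float = 100.0,
) -> FitProfile:
    """Fitting profile for the central-carbon network.

    Boundary fluxes other than lactate efflux are fixed at configuration
    values (nucleotide-synthesis drain and fatty-acid acetyl-CoA supply);
    the mitochondrial pyruvate-oxidation flux PDH is capped at
    ``oxidative_capacity`` and the anaplerosis/cataplerosis pair (PC and
    the AKG drain) at ``anaplerosis_cap``.  Free fluxes: G6PD and PC.
    """
    return FitProfile(
        pinned={
            "HK": glucose_uptake,
            "LAC_out": lactate_efflux,
            "R5P_out": nas_drain,
            "FAO": fao_supply,
        },
        free=["G6PD", "PC"],
        bounds={
            "G6PD": (0.0, 300.0),
            "PC": (0.0, anaplerosis_cap),
            "PDH": (0.0, oxidative_capacity),
            "PFK": (0.0, np.inf),
            "PK": (0.0, np.inf),
            "CS": (0.0, np.inf),
            "IDH": (0.0, np.inf),
            "AKGDH": (0.0, np.inf),
            "AKG_out": (0.0, anaplerosis_cap),
            "CO2_out": (0.0, np.inf),
        },
        glycolysis=list(GLYCOLYSIS_CHAIN),
    )


@dataclass
class FluxEstimate:
    """Result of a multi-start flux fit."""

    fluxes: pd.Series  # best net flux vector (glucose uptake = 100 scale)
    free: list[str]
    restarts: pd.DataFrame  # restart x reaction net fluxes
    residuals: np.ndarray  # objective norm per restart
    converged: np.ndarray  # per-restart convergence flag
    profile: FitProfile

    @property
    def best_residual(self) -> float:
        ok = self.converged
        return float(np.min(self.residuals[ok])) if ok.any() else float("nan")

    def dispersion(self) -> pd.Series:
        """Standard deviation of each net flux across converged restarts."""
        ok = self.restarts[self.converged]
        return ok.std(ddof=0)


def _measurement_residual(sim_mdvs, measured, mode: str, weights=None) -> np.ndarray:
    res = []
    for met, meas in measured.items():
        sim = sim_mdvs[met]
        meas = np.asarray(meas, dtype=float)
        if mode == "full":
            idx = np.arange(len(meas))
        elif mode == "first_pass":
            shift = FIRST_PASS_SHIFT.get(met, len(meas) - 1)
            idx = np.array([0, min(shift, len(meas) - 1)])
        else:
            raise ValueError(f"unknown measurement mode {mode!r}")
        w = 1.0 if weights is None else weights.get(met, 1.0)
        res.append((sim[: len(meas)][idx] - meas[idx]) / w)
    return np.concatenate(res)


def _measurement_size(measured, mode: str) -> int:
    if mode == "full":
        return sum(len(np.asarray(m)) for m in measured.values())
    return 2 * len(measured)


_PENALTY_WEIGHT = 100.0


def fit_fluxes(
    model: FluxModel,
    measured: dict[str, np.ndarray],
    profile: FitProfile,
    substrate_labeling=None,
    cycles: int = DEFAULT_CYCLES,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
    seed: int = 0,
    measurement_mode: str = "full",
    weights: dict[str, float] | None = None,
    exchange: dict[str, float] | None = None,
) -> FluxEstimate:
    """Multi-start weighted least squares flux estimation.

    ``cycles`` random restarts are drawn from the free-flux box (restart k
    uses seed ``seed + k``); each restart runs bounded nonlinear least
    squares capped at ``max_iterations`` residual evaluations.  Linear
    bounds that are not box bounds on the free fluxes enter the objective
    as hinge penalties.  The best-residual converged restart is reported,
    along with the full restart dispersion.
    """
    space = FluxSpace(model, profile.pinned, profile.free)
    sim = CumomerSimulator(model, substrate_labeling=substrate_labeling, exchange=exchange)
    lb, ub = profile.theta_bounds()
    n_meas = _measurement_size(measured, measurement_mode)

    bound_names = [n for n in profile.bounds if n not in profile.free]
    bound_idx = [space.names.index(n) for n in bound_names]
    bound_lo = np.array([profile.bounds[n][0] for n in bound_names])
    bound_hi = np.array([profile.bounds[n][1] for n in bound_names])
    glyc_idx = [space.names.index(n) for n in profile.glycolysis]

    def residual(theta):
        v = space.fluxes(theta)
        vn = v.to_numpy()
        pen = np.zeros(len(bound_names) + len(glyc_idx))
        if bound_names:
            b = vn[bound_idx]
            viol = np.maximum(bound_lo - b, 0.0) + np.maximum(b - bound_hi, 0.0)
            pen[: len(bound_names)] = _PENALTY_WEIGHT * viol**2  # squared hinge: C1
        if glyc_idx:
            pen[len(bound_names):] = _PENALTY_WEIGHT * np.maximum(-vn[glyc_idx], 0.0) ** 2
        try:
            mdvs = sim.mdvs(v, check_balance=False)
            data_res = _measurement_residual(mdvs, measured, measurement_mode, weights)
        except (DeadMetaboliteError, ValueError, np.linalg.LinAlgError):
            data_res = np.full(n_meas, 10.0)
        return np.concatenate([data_res, pen])

    if not profile.free:
        # fully determined by mass balance: nothing to optimize
        v = space.fluxes(np.zeros(0))
        cost = float(np.linalg.norm(residual(np.zeros(0))))
        return FluxEstimate(
            fluxes=v,
            free=[],
            restarts=pd.DataFrame([v]).reset_index(drop=True),
            residuals=np.array([cost]),
            converged=np.array([True]),
            profile=profile,
        )

    rows, resnorms, flags = [], [], []
    best = None
    for k in range(cycles):
        rng = np.random.default_rng(seed + k)
        span_hi = np.where(np.isfinite(ub), ub, lb + 100.0)
        theta0 = rng.uniform(lb, span_hi)
        try:
            sol = least_squares(
                residual,
                theta0,
                bounds=(lb, ub),
                max_nfev=max_iterations,
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-8,
            )
            ok = bool(sol.status > 0)
            theta, cost = sol.x, float(np.linalg.norm(sol.fun))
        except Exception:
            ok, theta, cost = False, np.full(len(lb), np.nan), float("inf")
        v = space.fluxes(np.nan_to_num(theta, nan=0.0))
        rows.append(v)
        resnorms.append(cost)
        flags.append(ok)
        if ok and (best is None or cost < best[0]):
            best = (cost, v)
    if best is None:
        raise FitFailureError(
            "no restart converged",
            diagnostics=pd.DataFrame({"residual": resnorms, "converged": flags}),
        )
    return FluxEstimate(
        fluxes=best[1],
        free=list(profile.free),
        restarts=pd.DataFrame(rows).reset_index(drop=True),
        residuals=np.asarray(resnorms),
        converged=np.asarray(flags, dtype=bool),
        profile=profile,
    )


# -- feasibility classification ---------------------------------------


def _lp_max_slack(space: FluxSpace, bounds: dict[str, tuple[float, float]]):
    """Maximize the margin t with which v(theta) satisfies all bounds.

    Returns (feasible, t): feasible means some theta satisfies every bound
    (t >= 0 allows solutions on the boundary).
    """
    names = space.names
    k = space.D.shape[1]
    A_ub, b_ub = [], []
    for name, (lo, hi) in bounds.items():
        i = names.index(name)
        d = space.D[i]
        v0 = space.v0[i]
        if np.isfinite(lo):
            # v0 + d.theta >= lo + t  ->  -d.theta + t <= v0 - lo
            A_ub.append(np.concatenate([-d, [1.0]]))
            b_ub.append(v0 - lo)
        if np.isfinite(hi):
            A_ub.append(np.concatenate([d, [1.0]]))
            b_ub.append(hi - v0)
    c = np.zeros(k + 1)
    c[-1] = -1.0  # maximize t
    res = linprog(
        c,
        A_ub=np.asarray(A_ub),
        b_ub=np.asarray(b_ub),
        bounds=[(None, None)] * k + [(None, None)],
        method="highs",
    )
    if not res.success:
        return False, -np.inf
    t = float(-res.fun)
    return t >= -1e-9, t


def classify_candidate(model: FluxModel, profile: FitProfile) -> str:
    """Feasibility status of a constraint profile: ok / reversed_glycolysis / infeasible."""
    try:
        space = FluxSpace(model, profile.pinned, profile.free)
    except Exception:
        return "infeasible"
    bounds = dict(profile.bounds)
    for n in profile.free:
        bounds.setdefault(n, (0.0, np.inf))
    strict = dict(bounds)
    for n in profile.glycolysis:
        lo, hi = strict.get(n, (-np.inf, np.inf))
        strict[n] = (max(lo, 0.0), hi)
    feasible, _ = _lp_max_slack(space, strict)
    if feasible:
        return "ok"
    feasible, _ = _lp_max_slack(space, bounds)
    return "reversed_glycolysis" if feasible else "infeasible"


@dataclass
class ScanResult:
    selected: float
    statuses: pd.DataFrame  # candidate, status, residual
    fits: dict[float, FluxEstimate]


def scan_lactate_efflux(
    model: FluxModel,
    measured: dict[str, np.ndarray],
    profile_for,
    candidates=None,
    cycles: int = 3,
    seed: int = 0,
    substrate_labeling=None,
    measurement_mode: str = "full",
) -> ScanResult:
    """Trial-and-error lactate-efflux selection.

    ``profile_for(efflux)`` builds the constraint profile for a candidate
    efflux value (default candidates: 0..100 in steps of 5).  Candidates
    whose constraint set is infeasible, or feasible only with part of
    glycolysis running backwards, are flagged and not fit; the remaining
    candidates are fit with a reduced restart count and the one with the
    minimal residual is selected.
    """
    if candidates is None:
        candidates = np.arange(0.0, 105.0, 5.0)
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate efflux values")
    records, fits = [], {}
    for cand in candidates:
        profile = profile_for(float(cand))
        status = classify_candidate(model, profile)
        residual = np.nan
        if status == "ok":
            try:
                est = fit_fluxes(
                    model,
                    measured,
                    profile,
                    substrate_labeling=substrate_labeling,
                    cycles=cycles,
                    seed=seed,
                    measurement_mode=measurement_mode,
                )
                fits[float(cand)] = est
                residual = est.best_residual
            except FitFailureError:
                status = "infeasible"
        records.append({"candidate": float(cand), "status": status, "residual": residual})
    statuses = pd.DataFrame(records)
    ok = statuses[statuses["status"] == "ok"]
    if len(ok) == 0:
        raise ScanFailureError("no candidate efflux value admits a forward-glycolysis fit", statuses)
    selected = float(ok.loc[ok["residual"].idxmin(), "candidate"])
    return ScanResult(selected=selected, statuses=statuses, fits=fits)


def scaled_efflux(
    labeled_glycolytic_share_treated: float,
    labeled_glycolytic_share_control: float,
    feasibility_probe=None,
    base: float = 65.0,
    max_modelable: float = 85.0,
    step: float = 5.0,
) -> float:
    """Stress-condition lactate efflux from labeled-glycolytic shares.

    raw = base * treated_share / control_share.  If raw is within the
    modelable range and feasible it is used directly; otherwise the value
    descends from ``max_modelable`` in ``step`` decrements until the
    feasibility probe passes.
    """
    if labeled_glycolytic_share_control <= 0:
        raise ValueError("control labeled-glycolytic share must be positive")
    probe = feasibility_probe if feasibility_probe is not None else (lambda e: True)
    raw = base * labeled_glycolytic_share_treated / labeled_glycolytic_share_control
    if raw <= max_modelable and probe(raw):
        return float(raw)
    value = float(max_modelable)
    while value >= 0.0:
        if probe(value):
            return value
        value -= step
    raise RuntimeError("no feasible lactate efflux value >= 0")
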