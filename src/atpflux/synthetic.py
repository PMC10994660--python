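"""Synthetic data generation for the full pipeline.

Every input the analysis consumes can be generated here with known ground
truth: Hill-shaped sensor calibration titrations, drifting single-cell
FRET event clouds under nutrient/inhibitor perturbations, and steady-state
isotopologue tables produced by the flux simulator from known flux
vectors, contaminated with per-carbon natural abundance and measurement
noise.

Three scenarios mirror the studied HSC conditions:

* ``quiescent`` — steady-state cells: lactate efflux 65 (glucose uptake
  100), an active oxidative PPP branch and TCA flux supplemented by
  fatty-acid-derived acetyl-CoA.
* ``proliferative_5FU`` — cell-cycle-activated cells: elevated glycolytic
  flux and lactate efflux, reduced PPP/FAO share.
* ``oxphos_inhibited`` — OXPHOS-poisoned cells: lactate efflux at the
  modelable maximum 80 and a collapsed nucleotide-synthesis drain.

All random generation uses explicit integer seeds; fixed seed means
bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import binom

from .calibration import HillCalibration, atp_to_ratio
from .mfa.cumomer import CumomerSimulator
from .mfa.network import FluxModel, as_flux_vector, build_network
from .timecourse import EventStream

SCENARIO_NAMES = ("quiescent", "proliferative_5FU", "oxphos_inhibited")

#: Tracer feed isotopomer distributions.
TRACER_FEEDS = {
    "U13C6": {"GLC": [("111111", 1.0)], "FA": [("00", 1.0)]},
    "U12C6": {"GLC": [("000000", 1.0)], "FA": [("00", 1.0)]},
}

#: Informative substrate design used for the synthetic flux-fitting study:
#: an 80/20 mixture of uniformly labeled and unlabeled glucose.  A pure
#: U-13C6 feed labels every intermediate completely at isotopic steady
#: state and leaves fluxes unidentifiable from MDVs.
MFA_FEED = {"GLC": [("111111", 0.8), ("000000", 0.2)], "FA": [("00", 1.0)]}

#: Pathway assignment of the measured metabolite panel.
PATHWAYS = {
    "G6P": "glycolysis", "F6P": "glycolysis", "FBP": "glycolysis",
    "DHAP": "glycolysis", "PG3": "glycolysis", "PEP": "glycolysis",
    "PYR": "glycolysis", "LAC": "glycolysis",
    "R5P": "PPP", "S7P": "PPP", "E4P": "PPP",
    "CIT": "TCA", "AKG": "TCA", "SUC": "TCA", "FUM": "TCA", "MAL": "TCA",
    "PRPP": "NAS",
}

#: Carbon counts for table metabolites not present in the network
#: (PRPP's measured label pattern follows its ribose moiety, i.e. R5P).
EXTRA_CARBONS = {"PRPP": 5}
_TABLE_SOURCE = {"PRPP": "R5P"}  # metabolite whose MDV the entry inherits

#: Metabolite pool sizes (semi-quantitative amount units) per condition.
#: Proliferation and OXPHOS inhibition expand the glycolytic pools —
#: notably F1,6BP, the product of the rate-limiting PFK step.
POOL_SIZES = {
    "quiescent": {
        "G6P": 10, "F6P": 10, "FBP": 8, "DHAP": 6, "PG3": 8, "PEP": 5,
        "PYR": 12, "LAC": 40, "R5P": 4, "S7P": 3, "E4P": 1.5, "PRPP": 2,
        "CIT": 12, "AKG": 8, "SUC": 6, "FUM": 5, "MAL": 10,
    },
    "proliferative_5FU": {
        "G6P": 18, "F6P": 12, "FBP": 25, "DHAP": 10, "PG3": 14, "PEP": 8,
        "PYR": 20, "LAC": 70, "R5P": 5, "S7P": 3, "E4P": 1.5, "PRPP": 4,
        "CIT": 14, "AKG": 9, "SUC": 7, "FUM": 6, "MAL": 11,
    },
    "oxphos_inhibited": {
        "G6P": 16, "F6P": 11, "FBP": 30, "DHAP": 11, "PG3": 15, "PEP": 9,
        "PYR": 22, "LAC": 90, "R5P": 3, "S7P": 2, "E4P": 1, "PRPP": 1,
        "CIT": 8, "AKG": 5, "SUC": 9, "FUM": 4, "MAL": 6,
    },
}

DEFAULT_NOISE = {"event_cv": 0.05, "mdv_sd": 0.01, "autofluorescence_fraction": 0.2}


def _step_trajectory(before: float, after: float, t_step: float) -> Callable[[float], float]:
    def traj(t):
        return np.where(np.asarray(t, dtype=float) < t_step, before, after)

    return traj


@dataclass
class ScenarioSpec:
    """Ground truth for one simulated condition."""

    name: str
    flux_vector: pd.Series
    atp_trajectory: Callable[[float], float]
    noise_model: dict = field(default_factory=lambda: dict(DEFAULT_NOISE))
    seed: int = 0
    pool_sizes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, val in self.noise_model.items():
            if val < 0:
                raise ValueError(f"noise parameter {key} must be >= 0")
        af = self.noise_model.get("autofluorescence_fraction", 0.0)
        if not 0.0 <= af < 1.0:
            raise ValueError("autofluorescence_fraction must be in [0, 1)")


def gen_flux_scenarios(model: FluxModel | None = None) -> dict[str, pd.Series]:
    """Balanced ground-truth net flux vectors (glucose uptake = 100)."""
    model = model or build_network()
    vectors = {
        "quiescent": {
            "HK": 100, "PGI": 80, "PFK": 84, "ALD": 84, "TPI": 84,
            "GAPDH": 170, "PGM_ENO": 170, "PK": 170, "LDH": 65, "LAC_out": 65,
            "G6PD": 20, "RPI": 16, "RPE": 4, "TKT1": 2, "TAL": 2, "TKT2": 2,
            "R5P_out": 14, "PDH": 100, "PC": 5, "FAO": 30, "CS": 130,
            "IDH": 130, "AKGDH": 125, "SDH": 125, "FUMASE": 125, "MDH": 125,
            "AKG_out": 5, "CO2_out": 370,
        },
        # Stressed scenarios carry somewhat more non-oxidative PPP
        # shuttling (TKT/TAL exchange with glycolysis), supplying ribose
        # while the oxidative branch share shrinks during glycolytic surge.
        "proliferative_5FU": {
            "HK": 100, "PGI": 82, "PFK": 90, "ALD": 90, "TPI": 90,
            "GAPDH": 184, "PGM_ENO": 184, "PK": 184, "LDH": 78, "LAC_out": 78,
            "G6PD": 18, "RPI": 10, "RPE": 8, "TKT1": 4, "TAL": 4, "TKT2": 4,
            "R5P_out": 6, "PDH": 102, "PC": 4, "FAO": 20, "CS": 122,
            "IDH": 122, "AKGDH": 118, "SDH": 118, "FUMASE": 118, "MDH": 118,
            "AKG_out": 4, "CO2_out": 356,
        },
        "oxphos_inhibited": {
            "HK": 100, "PGI": 87, "PFK": 93, "ALD": 93, "TPI": 93,
            "GAPDH": 189, "PGM_ENO": 189, "PK": 189, "LDH": 80, "LAC_out": 80,
            "G6PD": 13, "RPI": 7, "RPE": 6, "TKT1": 3, "TAL": 3, "TKT2": 3,
            "R5P_out": 4, "PDH": 103, "PC": 6, "FAO": 10, "CS": 113,
            "IDH": 113, "AKGDH": 107, "SDH": 107, "FUMASE": 107, "MDH": 107,
            "AKG_out": 6, "CO2_out": 330,
        },
    }
    out = {}
    for name, vec in vectors.items():
        v = as_flux_vector({k: float(x) for k, x in vec.items()}, model.reaction_names)
        if not model.is_balanced(v):
            raise AssertionError(f"scenario {name} flux vector is not balanced")
        out[name] = v
    return out


def gen_scenarios(model: FluxModel | None = None) -> dict[str, ScenarioSpec]:
    """Full scenario specifications with trajectories, noise and pools."""
    fluxes = gen_flux_scenarios(model)
    trajectories = {
        "quiescent": lambda t: np.full_like(np.asarray(t, dtype=float), 0.85),
        "proliferative_5FU": lambda t: np.full_like(np.asarray(t, dtype=float), 0.62),
        "oxphos_inhibited": _step_trajectory(0.80, 0.50, t_step=300.0),
    }
    return {
        name: ScenarioSpec(
            name=name,
            flux_vector=fluxes[name],
            atp_trajectory=trajectories[name],
            noise_model=dict(DEFAULT_NOISE),
            seed=i + 1,
            pool_sizes=dict(POOL_SIZES[name]),
        )
        for i, name in enumerate(SCENARIO_NAMES)
    }


# -- calibration titrations -------------------------------------------


def gen_calibration_titration(
    params: HillCalibration,
    concentrations,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Forward-model titration table of (ATP mM, FRET ratio)."""
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("titration concentrations must be positive")
    ratio = atp_to_ratio(conc, params)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ratio = ratio + rng.normal(0.0, noise_sd, size=ratio.shape)
    return pd.DataFrame({"atp_mM": conc, "fret_ratio": ratio})


def default_titration_concentrations(n: int = 12) -> np.ndarray:
    """Log-spaced Mg-ATP titration points between 0.1 and 10 mM."""
    return np.logspace(np.log10(0.1), np.log10(10.0), n)


# -- event streams ----------------------------------------------------


def gen_event_stream(
    scenario: ScenarioSpec,
    n_events: int,
    duration: float,
    params: HillCalibration,
    seed: int | None = None,
) -> EventStream:
    """Simulate a continuously acquired cytometry event stream.

    Event times are uniform over the acquisition window.  Cellular EGFP
    intensities are log-normal well above the MFI floor; FRET intensity is
    EGFP times the sensor ratio at the event's ATP level times
    multiplicative log-normal noise.  A stated fraction of events are
    low-intensity autofluorescence contaminants below the floor.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    cv = scenario.noise_model.get("event_cv", 0.0)
    af = scenario.noise_model.get("autofluorescence_fraction", 0.0)

    t = np.sort(rng.uniform(0.0, duration, n_events))
    is_cell = rng.uniform(size=n_events) >= af
    egfp = np.where(
        is_cell,
        rng.lognormal(np.log(5000.0), 0.4, n_events),
        rng.lognormal(np.log(300.0), 0.5, n_events),
    )
    true_ratio = atp_to_ratio(scenario.atp_trajectory(t), params)
    noise = rng.lognormal(0.0, cv, n_events) if cv > 0 else 1.0
    contaminant_ratio = rng.lognormal(np.log(0.8), 0.3, n_events)
    fret = egfp * np.where(is_cell, true_ratio * noise, contaminant_ratio)
    events = pd.DataFrame({"time_s": t, "egfp": egfp, "fret": fret})
    return EventStream(events, (0.0, duration), gate_label=scenario.name)


# -- isotopologue tables ----------------------------------------------


def natural_abundance_matrix(n_carbons: int, p: float = 0.011) -> np.ndarray:
    """Per-carbon natural-abundance convolution matrix.

    Each unlabeled carbon is independently heavy with probability ``p``,
    so a species at M+k is observed at M+j with probability
    Binom(n_carbons - k, p) at j - k.  Columns index the true mass shift.
    """
    M = np.zeros((n_carbons + 1, n_carbons + 1))
    for k in range(n_carbons + 1):
        extra = np.arange(0, n_carbons - k + 1)
        M[k + extra, k] = binom.pmf(extra, n_carbons - k, p)
    return M


def gen_isotopologue_table(
    flux_vector,
    network: FluxModel,
    tracer: str = "U13C6",
    mdv_sd: float = 0.0,
    natural_abundance_per_carbon: float = 0.011,
    seed: int = 0,
    condition: str = "quiescent",
    pool_sizes: dict | None = None,
) -> pd.DataFrame:
    """Steady-state isotopologue quantitation table for one condition.

    MDVs come from the cumomer forward simulator under the stated tracer
    feed, are convolved per-carbon with natural abundance, perturbed by
    truncated Gaussian noise, renormalized to the simplex and scaled to
    condition pool sizes.
    """
    if tracer not in TRACER_FEEDS:
        raise ValueError(f"unknown tracer {tracer!r}")
    v = as_flux_vector(flux_vector, network.reaction_names)
    if not network.is_balanced(v):
        raise ValueError("flux vector violates steady-state balance")
    pools = pool_sizes if pool_sizes is not None else POOL_SIZES.get(condition)
    if pools is None:
        raise ValueError(f"no pool sizes for condition {condition!r}")

    sim = CumomerSimulator(network, substrate_labeling=TRACER_FEEDS[tracer])
    mdvs = sim.mdvs(v)
    rng = np.random.default_rng(seed)
    rows = []
    for met, amount in pools.items():
        source = _TABLE_SOURCE.get(met, met)
        mdv = mdvs[source].copy()
        c = len(mdv) - 1
        if natural_abundance_per_carbon > 0:
            mdv = natural_abundance_matrix(c, natural_abundance_per_carbon) @ mdv
        if mdv_sd > 0:
            mdv = np.maximum(mdv + rng.normal(0.0, mdv_sd, size=mdv.shape), 0.0)
        total = mdv.sum()
        if total <= 0:
            raise RuntimeError(f"degenerate MDV for {met}")
        mdv = mdv / total
        for shift in range(c + 1):
            rows.append(
                {
                    "metabolite": met,
                    "pathway": PATHWAYS.get(met, "other"),
                    "condition": condition,
                    "tracer": tracer,
                    "mass_shift": shift,
                    "amount": amount * mdv[shift],
                }
            )
    return pd.DataFrame(rows)


def gen_mfa_measurements(
    flux_vector,
    network: FluxModel,
    mdv_sd: float = 0.0,
    seed: int = 0,
    substrate_labeling=None,
    metabolites=None,
) -> dict[str, np.ndarray]:
    """Measured-MDV dictionary for flux fitting (informative-feed design)."""
    v = as_flux_vector(flux_vector, network.reaction_names)
    sim = CumomerSimulator(
        network,
        substrate_labeling=substrate_labeling if substrate_labeling is not None else MFA_FEED,
    )
    mdvs = sim.mdvs(v)
    panel = metabolites if metabolites is not None else [
        m for m in PATHWAYS if m in network.metabolites
    ]
    rng = np.random.default_rng(seed)
    out = {}
    for met in panel:
        mdv = mdvs[met].copy()
        if mdv_sd > 0:
            mdv = np.maximum(mdv + rng.normal(0.0, mdv_sd, size=mdv.shape), 0.0)
            mdv = mdv / mdv.sum()
        out[met] = mdv
    return out


# -- writers -----------------------------------------------------------


def write_flux_json(fluxes: pd.Series, path) -> None:
    with open(path, "w") as fh:
        json.dump({k: float(v) for k, v in fluxes.items()}, fh, indent=2)


def load_flux_json(path) -> pd.Series:
    with open(path) as fh:
        return pd.Series(json.load(fh), dtype=float)
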