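"""Metabolic network model with carbon-atom transitions.

A :class:`FluxModel` is a set of internal (balanced) metabolites, external
substrates, and reactions whose carbon-atom transitions are written as
letter maps, e.g. ``PYR/abc -> ACCOA/bc + CO2/a``.  Every substrate carbon
must map to exactly one product carbon (reactions with no products are
boundary effluxes whose carbons leave the system).

Flux vectors are indexed by reaction name.  The steady-state constraint is
``S v = 0`` with S the internal-metabolite stoichiometric matrix;
:class:`FluxSpace` turns a set of pinned fluxes plus chosen free (pivot)
fluxes into an affine parameterization ``v(theta)`` of the constraint
manifold.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml


class NetworkValidationError(ValueError):
    pass


class ExcludedReactionError(NetworkValidationError):
    """Network contains a reaction the analysis profile excludes."""


#: Reactions excluded from the mammalian central-carbon profile: microbial
#: mixed-acid and ethanol fermentation steps that have no counterpart in
#: hematopoietic cells.
MAMMALIAN_EXCLUDED = {
    "pfl",
    "pyruvate_formate_lyase",
    "pdc",
    "adh",
    "ethanol_fermentation",
    "adhe",
}

_TERM_RE = re.compile(r"^\s*([A-Za-z0-9_]+)\s*/\s*([a-z]+)\s*$")


@dataclass(frozen=True)
class Reaction:
    name: str
    substrates: tuple[tuple[str, str], ...]  # (metabolite, atom letters)
    products: tuple[tuple[str, str], ...]
    reversible: bool = False

    @property
    def is_efflux(self) -> bool:
        return len(self.products) == 0

    def reversed(self) -> "Reaction":
        return Reaction(self.name + "_rev", self.products, self.substrates, False)


def _parse_side(side: str) -> tuple[tuple[str, str], ...]:
    side = side.strip()
    if not side:
        return ()
    terms = []
    for part in side.split("+"):
        m = _TERM_RE.match(part)
        if not m:
            raise NetworkValidationError(f"cannot parse reaction term {part!r}")
        terms.append((m.group(1), m.group(2)))
    return tuple(terms)


def parse_reaction(name: str, equation: str, reversible: bool = False) -> Reaction:
    if "->" not in equation:
        raise NetworkValidationError(f"{name}: equation needs '->'")
    lhs, rhs = equation.split("->", 1)
    return Reaction(name, _parse_side(lhs), _parse_side(rhs), reversible)


@dataclass
class FluxModel:
    """Reaction network with carbon maps, externals and efflux boundaries."""

    metabolites: dict[str, int]  # internal metabolite -> carbon count
    externals: dict[str, int]  # external substrate -> carbon count
    reactions: list[Reaction]
    symmetric: set[str] = field(default_factory=set)
    substrate_labeling: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    name: str = "network"

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------

    def carbons(self, met: str) -> int:
        if met in self.metabolites:
            return self.metabolites[met]
        if met in self.externals:
            return self.externals[met]
        raise NetworkValidationError(f"unknown metabolite {met}")

    def validate(self) -> None:
        names = [r.name for r in self.reactions]
        if len(set(names)) != len(names):
            raise NetworkValidationError("duplicate reaction names")
        for r in self.reactions:
            sub_mets = [m for m, _ in r.substrates]
            if len(set(sub_mets)) != len(sub_mets):
                raise NetworkValidationError(
                    f"{r.name}: a metabolite may appear at most once per side"
                )
            sub_letters: list[str] = []
            for met, atoms in r.substrates:
                if len(atoms) != self.carbons(met):
                    raise NetworkValidationError(
                        f"{r.name}: {met} has {self.carbons(met)} carbons, map {atoms!r}"
                    )
                sub_letters.extend(atoms)
            if len(set(sub_letters)) != len(sub_letters):
                raise NetworkValidationError(f"{r.name}: duplicate substrate atom letters")
            prod_letters: list[str] = []
            for met, atoms in r.products:
                if met in self.externals:
                    raise NetworkValidationError(f"{r.name}: external {met} cannot be produced")
                if len(atoms) != self.carbons(met):
                    raise NetworkValidationError(
                        f"{r.name}: {met} has {self.carbons(met)} carbons, map {atoms!r}"
                    )
                prod_letters.extend(atoms)
            if r.products:
                if sorted(prod_letters) != sorted(sub_letters):
                    missing = set(sub_letters) ^ set(prod_letters)
                    raise NetworkValidationError(
                        f"{r.name}: carbon atoms {sorted(missing)} are not mapped exactly once"
                    )

    def validate_profile(self, excluded: set[str] = frozenset(MAMMALIAN_EXCLUDED)) -> None:
        """Reject reactions the analysis profile excludes (by name)."""
        for r in self.reactions:
            if r.name.lower() in excluded:
                raise ExcludedReactionError(
                    f"reaction {r.name} is excluded from this network profile"
                )

    # -- stoichiometry ------------------------------------------------

    @property
    def reaction_names(self) -> list[str]:
        return [r.name for r in self.reactions]

    def stoichiometric_matrix(self) -> pd.DataFrame:
        """Internal metabolites x reactions net stoichiometric matrix."""
        S = pd.DataFrame(
            0.0, index=list(self.metabolites), columns=self.reaction_names
        )
        for r in self.reactions:
            for met, _ in r.substrates:
                if met in self.metabolites:
                    S.loc[met, r.name] -= 1.0
            for met, _ in r.products:
                if met in self.metabolites:
                    S.loc[met, r.name] += 1.0
        return S

    def balance_residual(self, fluxes) -> pd.Series:
        """Net production minus consumption at each internal metabolite."""
        v = as_flux_vector(fluxes, self.reaction_names)
        S = self.stoichiometric_matrix()
        return pd.Series(S.to_numpy() @ v.to_numpy(), index=S.index)

    def is_balanced(self, fluxes, tol: float = 1e-6) -> bool:
        return bool(np.max(np.abs(self.balance_residual(fluxes))) <= tol)

    def degrees_of_freedom(self, pinned: dict[str, float] | None = None) -> int:
        S = self.stoichiometric_matrix().to_numpy()
        rows = [S]
        for name in pinned or {}:
            e = np.zeros((1, len(self.reactions)))
            e[0, self.reaction_names.index(name)] = 1.0
            rows.append(e)
        A = np.vstack(rows)
        return len(self.reactions) - int(np.linalg.matrix_rank(A))


def as_flux_vector(fluxes, reaction_names: list[str]) -> pd.Series:
    """Coerce a dict/Series of fluxes to a Series over all reactions."""
    v = pd.Series(fluxes, dtype=float)
    missing = set(reaction_names) - set(v.index)
    if missing:
        raise ValueError(f"flux vector missing reactions: {sorted(missing)}")
    return v.reindex(reaction_names)


class FluxSpace:
    """Affine parameterization of the steady-state flux manifold.

    Given pinned fluxes (boundary constraints such as glucose uptake = 100
    and the configured lactate efflux) and a list of free pivot reactions,
    solves the stacked linear system ``[S; pins; pivots] v = [0; values;
    theta]`` so that ``v(theta) = v0 + D theta``.  Raises if the chosen
    pivots do not close the degrees of freedom.
    """

    def __init__(self, model: FluxModel, pinned: dict[str, float], free: list[str]):
        self.model = model
        self.pinned = dict(pinned)
        self.free = list(free)
        names = model.reaction_names
        n = len(names)
        S = model.stoichiometric_matrix().to_numpy()
        rows = [S]
        rhs0 = [np.zeros(S.shape[0])]
        for name, val in self.pinned.items():
            e = np.zeros(n)
            e[names.index(name)] = 1.0
            rows.append(e[None, :])
            rhs0.append(np.array([val]))
        free_row_start = sum(r.shape[0] for r in rows)
        for name in self.free:
            e = np.zeros(n)
            e[names.index(name)] = 1.0
            rows.append(e[None, :])
            rhs0.append(np.array([0.0]))
        A = np.vstack(rows)
        b0 = np.concatenate(rhs0)
        if np.linalg.matrix_rank(A) < n:
            raise NetworkValidationError(
                f"pinned+free fluxes leave the system underdetermined "
                f"(rank {np.linalg.matrix_rank(A)} < {n}); add free fluxes"
            )
        self._pinv = np.linalg.pinv(A)
        self.v0 = self._pinv @ b0
        D = np.zeros((n, len(self.free)))
        for k in range(len(self.free)):
            bk = np.zeros(len(b0))
            bk[free_row_start + k] = 1.0
            D[:, k] = self._pinv @ bk
        self.D = D
        # verify the affine map actually satisfies the constraints
        if np.max(np.abs(A @ self.v0 - b0)) > 1e-8:
            raise NetworkValidationError("pinned fluxes are inconsistent with steady state")
        self.names = names

    def fluxes(self, theta) -> pd.Series:
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        return pd.Series(self.v0 + self.D @ theta, index=self.names)

    def theta_of(self, fluxes) -> np.ndarray:
        """Free-parameter values of a full flux vector (its pivot entries)."""
        v = as_flux_vector(fluxes, self.names)
        return v[self.free].to_numpy()


def build_network(source=None, profile: str | None = "mammalian") -> FluxModel:
    """Load a :class:`FluxModel` from a YAML file, mapping or packaged default.

    ``source=None`` loads the bundled central-carbon network (glycolysis,
    oxidative/non-oxidative PPP, TCA cycle with anaplerotic pyruvate
    carboxylase, lactate/nucleotide/amino-acid boundary fluxes and a
    fatty-acid-derived acetyl-CoA supply).  With ``profile="mammalian"``,
    microbial fermentation reactions are rejected.
    """
    if source is None:
        ref = importlib.resources.files("atpflux.data").joinpath("central_carbon.yaml")
        spec = yaml.safe_load(ref.read_text())
    elif isinstance(source, dict):
        spec = source
    else:
        with open(source) as fh:
            spec = yaml.safe_load(fh)

    reactions = [
        parse_reaction(r["name"], r["equation"], bool(r.get("reversible", False)))
        for r in spec["reactions"]
    ]
    labeling = {}
    for met, entries in (spec.get("substrate_labeling") or {}).items():
        labeling[met] = [(e["pattern"], float(e["fraction"])) for e in entries]
    model = FluxModel(
        metabolites={k: int(v) for k, v in spec["metabolites"].items()},
        externals={k: int(v) for k, v in (spec.get("externals") or {}).items()},
        reactions=reactions,
        symmetric=set(spec.get("symmetric") or ()),
        substrate_labeling=labeling,
        name=spec.get("name", "network"),
    )
    if profile == "mammalian":
        model.validate_profile()
    return model
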