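"""Brute-force isotopomer enumeration simulator.

Independent reference implementation used to validate the cumomer cascade:
it represents every metabolite by its full isotopomer distribution (2^c
states) and solves the steady-state balance by damped fixed-point
iteration, assembling each product distribution by exhaustive enumeration
of substrate isotopomer combinations.  Exact but exponential in carbons —
only suitable for small networks and for cross-checking.
"""

from __future__ import annotations

import itertools

import numpy as np

from .cumomer import DeadMetaboliteError, expand_instances, mdv_from_isotopomers
from .network import FluxModel, as_flux_vector


def _external_isotopomers(model: FluxModel, labeling) -> dict[str, np.ndarray]:
    out = {}
    for met, entries in labeling.items():
        c = model.externals[met]
        x = np.zeros(1 << c)
        for pattern, frac in entries:
            x[int(pattern[::-1], 2)] += frac
        if abs(x.sum() - 1.0) > 1e-9:
            raise ValueError(f"{met}: labeling fractions sum to {x.sum()}")
        out[met] = x
    return out


def enumerate_isotopomers(
    model: FluxModel,
    fluxes,
    substrate_labeling=None,
    exchange=None,
    tol: float = 1e-13,
    max_iter: int = 200000,
) -> dict[str, np.ndarray]:
    """Steady-state isotopomer distributions by fixed-point iteration."""
    v = as_flux_vector(fluxes, model.reaction_names).to_numpy()
    labeling = substrate_labeling if substrate_labeling is not None else model.substrate_labeling
    ext = _external_isotopomers(model, labeling)

    # reuse the instance expansion but recompute directional fluxes locally
    exchange = exchange or {}
    active = {}
    for i, r in enumerate(model.reactions):
        e = exchange.get(r.name, 0.0)
        fwd = max(v[i], 0.0) + (e if r.reversible else 0.0)
        bwd = (max(-v[i], 0.0) + e) if r.reversible else 0.0
        if not r.reversible and v[i] < -1e-6:
            raise ValueError(f"irreversible reaction {r.name} has negative flux")
        if fwd > 1e-12:
            active[(i, True)] = fwd
        if bwd > 1e-12:
            active[(i, False)] = bwd
    instances = expand_instances(model, set(active))

    turnover = {m: 0.0 for m in model.metabolites}
    for inst in instances:
        f = active[(inst.reaction_index, inst.forward)] * inst.variant_weight
        for met, _ in inst.substrates:
            if met in model.metabolites:
                turnover[met] += f
    for m, phi in turnover.items():
        if phi <= 1e-9:
            raise DeadMetaboliteError(m)

    dist = {m: np.zeros(1 << c) for m, c in model.metabolites.items()}
    for m in dist:
        dist[m][0] = 1.0

    def current(met):
        return ext[met] if met in ext else dist[met]

    for _ in range(max_iter):
        production = {m: np.zeros_like(d) for m, d in dist.items()}
        for inst in instances:
            f = active[(inst.reaction_index, inst.forward)] * inst.variant_weight
            subs = inst.substrates
            sub_dists = [current(met) for met, _ in subs]
            # position of each atom letter: (substrate index, bit)
            source = {}
            for si, (met, atoms) in enumerate(subs):
                for pos, letter in enumerate(atoms):
                    source[letter] = (si, pos)
            for states in itertools.product(*[range(len(d)) for d in sub_dists]):
                prob = 1.0
                for si, s in enumerate(states):
                    prob *= sub_dists[si][s]
                if prob == 0.0:
                    continue
                for met, atoms in inst.products:
                    if met not in model.metabolites:
                        continue
                    mask = 0
                    for j, letter in enumerate(atoms):
                        si, pos = source[letter]
                        if states[si] & (1 << pos):
                            mask |= 1 << j
                    production[met][mask] += f * prob
        delta = 0.0
        for m in dist:
            new = production[m] / turnover[m]
            delta = max(delta, float(np.max(np.abs(new - dist[m]))))
            dist[m] = new
        if delta < tol:
            break
    else:
        raise RuntimeError("isotopomer fixed-point iteration did not converge")
    return dist


def enumerate_mdvs(model, fluxes, substrate_labeling=None, exchange=None, **kw):
    """MDVs from the brute-force enumeration simulator."""
    iso = enumerate_isotopomers(model, fluxes, substrate_labeling, exchange, **kw)
    return {
        m: mdv_from_isotopomers(iso[m], model.metabolites[m]) for m in iso
    }
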