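"""IC-MS isotope-tracer table processing.

Works on long-format isotopologue tables with columns ``metabolite``,
``pathway``, ``condition``, ``tracer``, ``mass_shift``, ``amount`` (one row
per M+i species).  Amount units are carried opaquely — every operation here
is a unit-agnostic ratio or sum.

Conventions:

* the *labeling rate* of a metabolite is 1 - fraction(M+0), the fraction of
  the pool carrying at least one tracer-derived carbon;
* natural-isotope correction subtracts the amount measured in the matched
  U-12C6 control from the U-13C6 amount, flooring at zero;
* pathway totals sum the labeled (M+i, i >= 1) amounts over all metabolites
  assigned to the pathway.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TABLE_COLUMNS = ["metabolite", "pathway", "condition", "tracer", "mass_shift", "amount"]

TRACER_13C = "U13C6"
TRACER_12C = "U12C6"


class InvalidCalibrationError(ValueError):
    pass


class UndefinedFractionError(ValueError):
    pass


class UndefinedRatioError(ValueError):
    pass


def validate_table(table: pd.DataFrame, carbon_counts: dict[str, int] | None = None) -> None:
    """Check table schema, non-negative amounts and mass-shift ranges."""
    missing = [c for c in ["metabolite", "condition", "tracer", "mass_shift", "amount"] if c not in table]
    if missing:
        raise ValueError(f"isotopologue table is missing columns: {missing}")
    if (table["amount"] < 0).any():
        raise ValueError("amounts must be non-negative")
    if (table["mass_shift"] < 0).any():
        raise ValueError("mass shifts must be non-negative")
    if carbon_counts:
        for met, grp in table.groupby("metabolite"):
            if met in carbon_counts and int(grp["mass_shift"].max()) > carbon_counts[met]:
                raise ValueError(f"{met}: mass shift exceeds its {carbon_counts[met]} carbons")


def quantify_from_calibration(peak_area, slope: float, intercept: float = 0.0):
    """Amount from an external calibration line, floored at zero.

    amount = (peak_area - intercept) / slope.
    """
    if slope == 0:
        raise InvalidCalibrationError("calibration line has zero slope")
    amount = (np.asarray(peak_area, dtype=float) - intercept) / slope
    amount = np.maximum(amount, 0.0)
    return float(amount) if amount.ndim == 0 else amount


def _select(table, metabolite=None, condition=None, tracer=None) -> pd.DataFrame:
    out = table
    if metabolite is not None:
        out = out[out["metabolite"] == metabolite]
    if condition is not None:
        out = out[out["condition"] == condition]
    if tracer is not None:
        out = out[out["tracer"] == tracer]
    return out


def labeling_fractions(
    table: pd.DataFrame,
    metabolite: str,
    condition: str,
    tracer: str = TRACER_13C,
    n_carbons: int | None = None,
) -> np.ndarray:
    """Amounts of M+0..M+C normalized to sum 1."""
    sub = _select(table, metabolite, condition, tracer)
    if len(sub) == 0:
        raise KeyError(f"no rows for {metabolite}/{condition}/{tracer}")
    cmax = int(n_carbons if n_carbons is not None else sub["mass_shift"].max())
    amounts = np.zeros(cmax + 1)
    for _, row in sub.iterrows():
        amounts[int(row["mass_shift"])] += row["amount"]
    total = amounts.sum()
    if total <= 0:
        raise UndefinedFractionError(f"{metabolite}/{condition}: all amounts are zero")
    return amounts / total


def labeling_rate(table, metabolite, condition, tracer=TRACER_13C) -> float:
    """Fraction of the pool carrying at least one labeled carbon (1 - M+0)."""
    return float(1.0 - labeling_fractions(table, metabolite, condition, tracer)[0])


def natural_isotope_correct(amount_13C, amount_12C_control):
    """Subtract the U-12C6 natural-isotope background, flooring at zero."""
    a = np.asarray(amount_13C, dtype=float)
    b = np.asarray(amount_12C_control, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("amounts must be non-negative")
    out = np.maximum(a - b, 0.0)
    return float(out) if out.ndim == 0 else out


def correct_table(table: pd.DataFrame) -> pd.DataFrame:
    """Apply natural-isotope correction per (metabolite, condition, mass shift).

    Labeled (M+i, i >= 1) amounts under the U-13C6 tracer are corrected by
    the matched U-12C6 control measured under the same condition label.
    Returns a table with U-13C6 rows only.
    """
    lab = _select(table, tracer=TRACER_13C).copy()
    ctl = _select(table, tracer=TRACER_12C)
    if len(ctl) == 0:
        raise ValueError("no U-12C6 control rows present for correction")
    key = ["metabolite", "condition", "mass_shift"]
    ctl_amounts = ctl.set_index(key)["amount"]
    bg = lab.set_index(key).index.map(lambda k: ctl_amounts.get(k, 0.0)).to_numpy(dtype=float)
    labeled = lab["mass_shift"].to_numpy() >= 1
    corrected = lab["amount"].to_numpy(dtype=float).copy()
    corrected[labeled] = natural_isotope_correct(corrected[labeled], bg[labeled])
    lab["amount"] = corrected
    return lab


def flag_high_natural_isotope(table: pd.DataFrame, threshold: float = 0.05) -> set[tuple[str, int]]:
    """Isotopologues whose U-12C6 background exceeds ``threshold`` x the U-13C6 amount.

    These are the species (e.g. citrate M+2, E4P M+4) where natural
    isotopes would inflate the apparent labeling and correction matters.
    """
    lab = _select(table, tracer=TRACER_13C)
    ctl = _select(table, tracer=TRACER_12C)
    if len(ctl) == 0:
        raise ValueError("both tracer conditions must be present")
    key = ["metabolite", "condition", "mass_shift"]
    merged = lab.merge(ctl, on=key, suffixes=("_13c", "_12c"))
    merged = merged[merged["mass_shift"] >= 1]
    hits = merged[merged["amount_12c"] > threshold * merged["amount_13c"]]
    hits = hits[merged.loc[hits.index, "amount_12c"] > 0]
    return {(row["metabolite"], int(row["mass_shift"])) for _, row in hits.iterrows()}


def pathway_total_labeled(
    table: pd.DataFrame, pathway: str, condition: str, tracer: str = TRACER_13C
) -> float:
    """Sum of labeled (M+i, i >= 1) amounts over all metabolites in a pathway."""
    if "pathway" not in table:
        raise ValueError("table has no pathway assignments")
    if pathway not in set(table["pathway"]):
        raise KeyError(f"unknown pathway: {pathway}")
    sub = _select(table, condition=condition, tracer=tracer)
    sub = sub[(sub["pathway"] == pathway) & (sub["mass_shift"] >= 1)]
    return float(sub["amount"].sum())


def heatmap_labeling_matrix(table: pd.DataFrame, tracer: str = TRACER_13C) -> pd.DataFrame:
    """Metabolite x condition matrix of labeling rate + 1.

    The +1 pseudo-count keeps fully unlabeled metabolites at 1.0 (and fully
    labeled at 2.0) so that log-scaled heatmaps remain finite.
    """
    sub = _select(table, tracer=tracer)
    mets = sorted(sub["metabolite"].unique())
    conds = sorted(sub["condition"].unique())
    out = pd.DataFrame(index=mets, columns=conds, dtype=float)
    for met in mets:
        for cond in conds:
            out.loc[met, cond] = 1.0 + labeling_rate(sub, met, cond, tracer)
    return out


def product_substrate_ratio(
    table: pd.DataFrame,
    product: str,
    substrate: str,
    condition: str,
    tracer: str = TRACER_13C,
) -> float:
    """Ratio of total labeled product to total labeled substrate amounts.

    Used for the F1,6BP/F6P readout of phosphofructokinase engagement.
    """
    def _labeled_total(met):
        sub = _select(table, met, condition, tracer)
        if len(sub) == 0:
            raise KeyError(f"no rows for {met}/{condition}/{tracer}")
        return float(sub.loc[sub["mass_shift"] >= 1, "amount"].sum())

    num = _labeled_total(product)
    den = _labeled_total(substrate)
    if den <= 0:
        raise UndefinedRatioError(f"substrate {substrate} has no labeled amount")
    return num / den
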