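"""Real-time FRET time-course analysis.

Turns a stream of single-cell cytometry events (each event = one cell
observed once, with an acquisition time and EGFP/FRET intensities) into a
smoothed, baseline-corrected ATP-vs-time trace:

1. gate out autofluorescence (MFI floor, then the top fraction of each
   channel),
2. smooth the per-event FRET/EGFP ratio against time with a penalized
   B-spline whose smoothness is selected by generalized cross-validation,
3. convert the fitted ratio curve to ATP with the sensor calibration,
4. optionally rescale a control trace so that both arms share the same
   ATP concentration at t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.gam.api import BSplines

from .calibration import HillCalibration, ratio_to_theta, theta_to_atp

DEFAULT_MFI_FLOOR = 1000.0
DEFAULT_TOP_FRACTION = 0.45  # middle of the "top 40-50%" gating band


class InsufficientEventsError(ValueError):
    """Too few gated events to support the spline smoother."""


class UndefinedCorrectionError(ValueError):
    """Baseline correction is undefined when the control trace is 0 at t=0."""


@dataclass
class EventStream:
    """Time-stamped single-cell fluorescence events.

    ``events`` has columns ``time_s``, ``egfp``, ``fret``.  ``gate_meta``
    records the thresholds of the gate already applied to the stream (if
    any), so that re-applying the same gate is a no-op.
    """

    events: pd.DataFrame
    acquisition_window: tuple[float, float]
    gate_label: str = "ungated"
    gate_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t0, t1 = self.acquisition_window
        if not t1 > t0:
            raise ValueError("acquisition window must have t1 > t0")
        t = self.events["time_s"].to_numpy()
        if len(t) and (t.min() < t0 - 1e-9 or t.max() > t1 + 1e-9):
            raise ValueError("event times fall outside the acquisition window")
        if len(t) and ((self.events["egfp"] < 0).any() or (self.events["fret"] < 0).any()):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.events)

    def ratios(self) -> np.ndarray:
        return (self.events["fret"] / self.events["egfp"]).to_numpy()

    @classmethod
    def from_csv(cls, path, acquisition_window=None) -> "EventStream":
        df = pd.read_csv(path)
        if acquisition_window is None:
            acquisition_window = (float(df["time_s"].min()), float(df["time_s"].max()))
        return cls(df[["time_s", "egfp", "fret"]], acquisition_window)

    def to_csv(self, path) -> None:
        self.events.to_csv(path, index=False)


@dataclass
class AtpTrace:
    """Smoothed population ATP concentration on a time grid (mM)."""

    times: np.ndarray
    atp: np.ndarray
    smoother_meta: dict = field(default_factory=dict)
    correction_factor: float = 1.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.atp = np.asarray(self.atp, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(self.atp < 0):
            raise ValueError("ATP concentrations must be non-negative")

    def at_time(self, t: float) -> float:
        """Trace value at the grid point nearest ``t``."""
        return float(self.atp[np.argmin(np.abs(self.times - t))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "atp_mM": self.atp})


def gate_events(
    stream: EventStream,
    mfi_floor: float = DEFAULT_MFI_FLOOR,
    top_fraction: float = DEFAULT_TOP_FRACTION,
) -> EventStream:
    """Keep high-intensity events: MFI floor plus top fraction per channel.

    Events must exceed ``mfi_floor`` in both channels, and lie at or above
    the (1 - top_fraction) linear-interpolation quantile of the post-floor
    distribution of each channel.  A gate is identified by its thresholds:
    re-gating a stream that already carries the same gate returns it
    unchanged (gating is idempotent).
    """
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError("top_fraction must be in (0, 1]")

    gate_id = {"mfi_floor": float(mfi_floor), "top_fraction": float(top_fraction)}
    if self_gate := stream.gate_meta:
        if (
            self_gate.get("mfi_floor") == gate_id["mfi_floor"]
            and self_gate.get("top_fraction") == gate_id["top_fraction"]
        ):
            return stream

    ev = stream.events
    above = ev[(ev["egfp"] > mfi_floor) & (ev["fret"] > mfi_floor)]
    if len(above) == 0:
        kept = above
        thresholds = {"egfp": np.inf, "fret": np.inf}
    else:
        q = 1.0 - top_fraction
        thr_e = float(above["egfp"].quantile(q, interpolation="linear"))
        thr_f = float(above["fret"].quantile(q, interpolation="linear"))
        kept = above[(above["egfp"] >= thr_e) & (above["fret"] >= thr_f)]
        thresholds = {"egfp": thr_e, "fret": thr_f}

    return EventStream(
        kept.reset_index(drop=True),
        stream.acquisition_window,
        gate_label=f"{stream.gate_label}|top{top_fraction:g}",
        gate_meta={**gate_id, "thresholds": thresholds, "n_in": len(ev), "n_out": len(kept)},
    )


def _gcv_penalized_fit(basis: np.ndarray, penalty: np.ndarray, y: np.ndarray, alphas=None):
    """Penalized LS fit with the smoothing weight chosen by GCV.

    Returns (coefficients, alpha, effective_df).  GCV(alpha) =
    n*RSS / (n - tr(H))^2 with H the smoother hat matrix.
    """
    n = len(y)
    BtB = basis.T @ basis
    Bty = basis.T @ y
    if alphas is None:
        alphas = np.logspace(-4, 8, 25)
    best = None
    for alpha in alphas:
        A = BtB + alpha * penalty
        try:
            coef = np.linalg.solve(A, Bty)
            edf = float(np.trace(np.linalg.solve(A, BtB)))
        except np.linalg.LinAlgError:
            continue
        rss = float(np.sum((y - basis @ coef) ** 2))
        denom = max(n - edf, 1e-8)
        gcv = n * rss / denom**2
        if best is None or gcv < best[0]:
            best = (gcv, coef, float(alpha), edf)
    if best is None:
        raise np.linalg.LinAlgError("penalized spline system is singular for all weights")
    return best[1], best[2], best[3]


def smooth_ratio_trace(
    stream: EventStream,
    grid_step: float = 1.0,
    df: int = 15,
    alpha: float | None = None,
    min_events: int = 20,
):
    """Penalized-spline scatterplot smoother of FRET/EGFP ratio vs time.

    Smoothness is selected by generalized cross-validation unless ``alpha``
    is given.  Returns ``(times, fitted_ratio, meta)`` with the curve
    evaluated on a uniform grid over the acquisition window (clipped to the
    observed event-time range, where the spline basis is defined).
    """
    if len(stream) < min_events:
        raise InsufficientEventsError(
            f"need >= {min_events} gated events for smoothing, have {len(stream)}"
        )
    t = stream.events["time_s"].to_numpy(dtype=float)
    y = stream.ratios()
    order = np.argsort(t, kind="stable")
    t, y = t[order], y[order]

    n_df = int(min(df, max(4, len(t) - 1)))
    bs = BSplines(t[:, None], df=[n_df], degree=[3], include_intercept=True)
    basis = bs.basis
    penalty = bs.penalty_matrices[0]

    if alpha is None:
        coef, alpha_used, edf = _gcv_penalized_fit(basis, penalty, y)
    else:
        coef, alpha_used, edf = _gcv_penalized_fit(basis, penalty, y, alphas=[alpha])

    t0, t1 = stream.acquisition_window
    grid = np.arange(t0, t1 + 0.5 * grid_step, grid_step)
    grid_eval = np.clip(grid, t.min(), t.max())  # basis undefined beyond data
    fitted = bs.transform(grid_eval[:, None]) @ coef
    meta = {"basis": f"bspline(df={n_df},degree=3)", "alpha": alpha_used, "effective_df": edf}
    return grid, fitted, meta


def trace_to_atp(times, fitted_ratio, calib: HillCalibration, smoother_meta=None) -> AtpTrace:
    """Convert a fitted ratio curve to an ATP trace (clip conversion mode)."""
    theta = ratio_to_theta(fitted_ratio, offset=calib.offset)
    atp = theta_to_atp(theta, calib, mode="clip")
    return AtpTrace(np.asarray(times, float), atp, smoother_meta=dict(smoother_meta or {}))


def baseline_correct(control: AtpTrace, treated: AtpTrace) -> AtpTrace:
    """Rescale the control trace so both arms agree at t = 0.

    Multiplies every control value by treated(0)/control(0), where the
    anchor is the fitted value at the grid point nearest t = 0.  The
    treated trace is left untouched.
    """
    c0 = control.at_time(0.0)
    if c0 == 0.0:
        raise UndefinedCorrectionError("control trace is zero at t=0")
    factor = treated.at_time(0.0) / c0
    return replace(
        control,
        atp=control.atp * factor,
        correction_factor=control.correction_factor * factor,
    )


def window_mean(trace: AtpTrace, t_start: float, t_end: float) -> float:
    """Mean ATP over grid points in the closed window [t_start, t_end]."""
    mask = (trace.times >= t_start) & (trace.times <= t_end)
    if not mask.any():
        raise ValueError(f"no grid points in window [{t_start}, {t_end}]")
    return float(trace.atp[mask].mean())


def density_grid(stream: EventStream, n_time: int = 64, n_ratio: int = 64):
    """2-D Gaussian kernel density of (time, ratio) events on a plain grid.

    The pseudocolor-plot replacement: returns ``(time_grid, ratio_grid,
    density)`` with bandwidths from the normal reference (Scott) rule.
    """
    from scipy.stats import gaussian_kde

    t = stream.events["time_s"].to_numpy(dtype=float)
    r = stream.ratios()
    kde = gaussian_kde(np.vstack([t, r]))
    tg = np.linspace(t.min(), t.max(), n_time)
    rg = np.linspace(r.min(), r.max(), n_ratio)
    TT, RR = np.meshgrid(tg, rg, indexing="ij")
    dens = kde(np.vstack([TT.ravel(), RR.ravel()])).reshape(n_time, n_ratio)
    return tg, rg, dens
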