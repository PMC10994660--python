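# Methods

## Sensor calibration model

GO-ATeam2 reports cytosolic ATP through the FRET/EGFP emission ratio.  We
model the ratio as offset + θ, where θ is Hill-curve occupancy
θ = [L]ⁿ/(K_Aⁿ + [L]ⁿ) and the offset (1.46) is an instrument constant of
the sensor/cytometer combination — it is never refit.  Parameters are
estimated by OLS on the log-linearized form log(θ/(1−θ)) = n log[L] −
n log K_A.  Natural logarithms are used; the slope (and hence n) is
base-invariant and K_A = exp(−intercept/slope).  Titration points whose
offset-subtracted ratio falls outside (0, 1) cannot be log-transformed;
they are excluded and counted in the fit diagnostics.  This matters in
practice: the logit transform amplifies ratio noise without bound near
θ = 0 or 1, so noisy near-saturated points both bias the regression and
occasionally leave it undefined.  The Monte-Carlo bias check therefore
titrates inside the informative band (θ roughly 0.1–0.9, i.e. 0.4–2 mM
for the default parameters), where the estimator is unbiased to well
under 2 %.

Conversion of noisy per-event data uses a "clip" mode that clips θ into
[1e-6, 1−1e-6] before inversion; single events routinely exceed the
sensor's dynamic range and an exception per event would be useless.  The
clip floor corresponds to ≈0.01 mM.  Strict mode (errors outside (0,1))
is the default for curve-level work.

## Time-course analysis

Events are gated by an MFI floor (1000 in both channels) followed by a
channel-wise top-fraction cut; the "top 40–50 %" band is exposed as one
parameter with default 0.45, using linear-interpolation quantiles
computed after the floor.  A gate is identified by its thresholds, so
re-applying the same gate to an already-gated stream is a no-op.  Note
that gating on the FRET channel selects slightly high-ratio events; with
the default intensity spread (log-normal σ ≈ 0.4) versus ratio noise
(cv 0.05) the induced ratio bias is ≈0.5 %, far below the smoothing
error budget.

The per-event FRET/EGFP ratio is smoothed against acquisition time with a
penalized cubic B-spline (basis and second-difference penalty from
statsmodels' `BSplines`), with the penalty weight chosen by generalized
cross-validation on a fixed log grid.  We solve the penalized normal
equations directly rather than through the GAM IRLS driver because the
noiseless edge cases (exactly constant or linear event streams) must be
reproduced to machine precision, and iterative Gaussian fitting aborts on
zero-residual data.  The penalty null space contains constants and
linear trends, so those are recovered exactly at any penalty.  The fitted
curve is evaluated on a uniform grid (default 1 s) over the acquisition
window, clipped to the observed event-time range where the basis is
defined.

Baseline correction multiplies the control trace by treated(0)/control(0),
where the t = 0 anchor is the fitted curve's value at the grid point
nearest zero (fitted rather than raw, for noise robustness).  Endpoint
summaries are closed-window grid means.  The pseudocolor export is a plain
2-D Gaussian KDE grid (Scott's rule bandwidth), not a plot.

## Tracer-table processing

Operations are unit-agnostic ratios and sums over long-format
isotopologue tables.  "Labeling rate" is defined as 1 − fraction(M+0).
Natural-isotope correction subtracts the matched U-¹²C₆-control amount
per (metabolite, condition, mass shift) and floors at zero; species whose
control amount exceeds 5 % of the labeled amount are flagged (citrate and
α-ketoglutarate isotopologues are the typical hits).  Pathway totals sum
M+i, i ≥ 1 over the pathway's metabolites; both corrected and raw modes
are available because the upstream choice is not fixed by the protocol.
The heatmap matrix adds a pseudo-count of 1 to every labeling rate, so
entries lie in [1, 2].

## Flux model

The bundled central-carbon network (22 internal metabolites, 28
reactions) covers glycolysis, the oxidative and non-oxidative PPP, and
the TCA cycle, with boundary fluxes for lactate efflux, a
nucleotide-synthesis (R5P) drain, an α-ketoglutarate biosynthetic drain,
CO₂ release, and a fatty-acid-derived acetyl-CoA supply reflecting the
known reliance of quiescent HSCs on fatty-acid oxidation.  Steps whose
intermediates carry no extra labeling information are lumped
(GAPDH+PGK, PGM+enolase, G6PD+6PGD, aconitase+IDH); microbial
fermentation reactions (pyruvate formate lyase, ethanol fermentation)
are rejected by the mammalian profile validator.  Atom maps follow the
standard transitions of the EMU literature and live in versioned YAML
data, not code.  Succinate and fumarate are rotationally symmetric and
are scrambled 50/50 at every producing reaction.  Cytosol and
mitochondria are treated as one pool; no compartmentation.

Reversible reactions are net + exchange pairs (forward max(v,0)+e,
backward max(−v,0)+e); exchange defaults to zero and is configurable per
reaction.

## Labeling simulation

The forward simulator solves the cumomer cascade: weight-w cumulative
isotopomer fractions satisfy a linear system whose inhomogeneous part
involves only lower weights, so the full isotopomer state is obtained by
a sequence of small dense solves followed by Möbius inversion — exact,
with no iteration or tolerance.  The equation structure is compiled once
per flux-direction pattern and cached, so an optimizer evaluation costs
a few milliseconds.  An independent brute-force simulator
(fixed-point iteration on full isotopomer distributions with exhaustive
substrate-combination enumeration) validates the cascade to 1e-9 on a
suite of small networks covering cleavage, condensation, symmetry,
exchange flux, and a one-carbon recycle loop, and on the full network.
Metabolites with zero turnover make the labeling state undefined; the
simulator reports the dead metabolite by name.

## Flux fitting

The synthetic tracer study feeds an 80/20 mixture of U-¹³C₆ and
unlabeled glucose.  With a pure uniformly labeled feed, every
intermediate is fully labeled at isotopic steady state and MDVs carry no
flux information — the real experiment's information came from
incomplete labeling at short times and from feasibility screening.  The
mixture is the standard steady-state design that makes the free fluxes
identifiable while the pure U-¹³C₆/U-¹²C₆ feeds remain the defaults for
the tracer-table emulation (where near-100 % glycolytic labeling is the
point).

Fits pin glucose uptake (100) and lactate efflux, fix the remaining
boundary fluxes at profile values (NAS drain, FAO supply), and estimate
the free pivot fluxes (default: G6PD, the oxidative-PPP split, and PC,
anaplerosis) by bounded nonlinear least squares on simulated-vs-measured
MDVs.  The flux vector is an affine function of the pivots obtained by
solving the stacked stoichiometric/pin system once.  Linear bounds that
are not box bounds on the pivots — the mitochondrial pyruvate-oxidation
capacity on PDH (default 110), the anaplerosis cap (20), non-negativity
of irreversible steps — enter the objective as squared hinge penalties
(weight 100); the squared form keeps the objective C¹, which the
trust-region solver needs near active constraints.  Objective weights
are uniform unless per-metabolite weights are supplied.  Multi-start:
`cycles` (default 100) uniform draws from the pivot box, restart k
seeded with base seed + k, each capped at 2000 residual evaluations.
Both full-MDV and "M+0 plus first-pass isotopologue" measurement modes
are provided; validation uses the full-MDV mode.

The lactate-efflux scan classifies each candidate (0–100, step 5) by
linear programming before fitting: `infeasible` if no steady-state vector
satisfies the profile bounds, `reversed_glycolysis` if all feasible
vectors run part of the HK→PK chain backwards (net flux < −1e-6), else
`ok`, fit, and selected by minimal residual.  Under the default profile,
candidates ≤ 10 admit only reversed-glycolysis solutions — the scan's
synthetic counterpart of "simulations error out or run glycolysis
backwards at low efflux" — and the generating value 65 is the residual
optimum.  Stress-condition efflux comes from 65 × (treated/control
labeled-glycolytic share); values above the modelable maximum descend
from 85 in steps of 5 until a feasibility probe passes (80 for the
OXPHOS-inhibited profile).  Whether 85 itself was within the modelable
range is ambiguous in the source procedure; descending from 85 is the
reading implemented.

## Synthetic scenarios

Three ground-truth flux vectors (glucose uptake = 100) encode the study
conditions: quiescent (lactate efflux 65, G6PD 20, PC 5, FAO 30, NAS
drain 14), 5-FU-proliferative (elevated glycolysis — PFK 90, PK 184,
efflux 78 — with a reduced PPP/FAO share and modestly higher TKT/TAL
shuttling), and OXPHOS-inhibited (efflux 80, collapsed NAS drain 4, FAO
10).  All satisfy steady-state balance exactly.  ATP trajectories:
constant 0.85 mM (quiescent), constant 0.62 mM (5-FU), step 0.80→0.50 mM
at t = 300 s (OXPHOS inhibition).  Event streams: uniform event times
(no arrival model is implied by continuous acquisition), log-normal EGFP
(median 5000, σ 0.4), multiplicative log-normal ratio noise (cv 0.05),
and a 20 % autofluorescence component (median 300, σ 0.5) below the MFI
floor for the gate to remove.  Metabolite pool sizes are condition-
specific constants chosen so that stressed conditions expand glycolytic
pools — in particular F1,6BP, giving the rising F1,6BP/F6P ratio — at
magnitudes typical of semi-quantitative IC-MS.  MDV noise is truncated
Gaussian (sd 0.01) renormalized to the simplex; natural abundance is an
independent per-carbon binomial convolution at 1.1 %.

What the generator does *not* emulate: spectral overlap/compensation,
IC-MS peak shapes, isotopically nonstationary labeling, photobleaching,
or pH/temperature dependence of the sensor.  Passing tests therefore
demonstrate correctness of the estimators under the stated statistical
model, not robustness to those instrument effects.

## Problem sizes and numerical choices

Validation runs use 5000 events per time course, 12-point titrations,
1000 Monte-Carlo titration replicates, 100 fitting restarts per scenario
and a 21-candidate efflux scan at 3 restarts each; the whole suite runs
in about a minute on one CPU.  Key tolerances: steady-state balance
1e-6 (relative to the largest flux), simulator-vs-enumeration 1e-9,
reversal detection −1e-6, LP feasibility margin −1e-9 (boundary
solutions count as feasible).

## Known limitations

* With the pure uniformly labeled feed the flux problem is degenerate by
  construction; all fitting claims are for the mixed-feed design.
* Restart dispersion: on noiseless data every scenario's multi-start fit
  collapses to optimizer tolerance (~1e-6 flux units), so "stressed
  fits are not looser than quiescent" holds as a tie.  Under measurement
  noise, occasional secondary local minima appear in any scenario and
  the dispersion ordering follows the noise realization, not the
  scenario — the tight stress-condition ordering seen in real data is
  not reproduced as a robust synthetic property.  Dispersion comparisons
  are therefore made at matched zero noise.
* The OXPHOS-inhibited flux vector keeps substantial PDH flux because
  the closed model offers pyruvate no other exit once lactate efflux is
  pinned at 80; a richer model would add further overflow routes.
* No profile-likelihood confidence intervals; restart dispersion is the
  only uncertainty summary.
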