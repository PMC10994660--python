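# atpflux

Quantitative metabolic analysis of hematopoietic stem cells (HSCs): a
Python library and analysis pipeline covering the three measurement
modalities used to study HSC energy metabolism under stress —

1. **Single-cell ATP quantification** from the GO-ATeam2 ratiometric FRET
   biosensor.  The FRET/EGFP ratio reports sensor occupancy through a Hill
   curve, θ = [L]ⁿ / (K_Aⁿ + [L]ⁿ), with θ = ratio − 1.46 (instrument
   offset).  Parameters are fitted by ordinary least squares on the
   log-linearized form log(θ/(1−θ)) = n·log[L] − n·log K_A; the sensor
   calibration used throughout is n = 3.1234, K_A = 0.84699 mM.
2. **Real-time ATP time courses** from continuously acquired flow-cytometry
   event streams: autofluorescence gating (MFI floor 1000, top 40–50% of
   both channels), penalized-spline smoothing of the per-event ratio with
   GCV-selected smoothness, conversion to ATP, and baseline correction of
   the control arm onto the treated arm at t = 0.
3. **Isotope-tracer processing and steady-state ¹³C metabolic flux
   analysis** over a central-carbon network (glycolysis, oxidative and
   non-oxidative PPP, TCA cycle with pyruvate-carboxylase anaplerosis,
   lactate efflux, nucleotide-synthesis drain, fatty-acid acetyl-CoA
   supply).  Labeling is simulated exactly by a cumomer-cascade solver
   (equivalent to an EMU decomposition, validated against brute-force
   isotopomer enumeration); fluxes are estimated by multi-start bounded
   least squares with glucose uptake pinned to 100 and lactate efflux set
   by a feasibility scan (quiescent HSCs: 65) or by share-based scaling
   for stressed cells (65 × treated/control labeled-glycolytic share,
   capped at the modelable maximum of 80–85).

No raw cytometry or metabolomics data are publicly deposited for this
system, so the package generates every input synthetically with known
ground truth (`atpflux.synthetic`): calibration titrations, drifting event
clouds for quiescent / 5-FU-proliferative / OXPHOS-inhibited scenarios,
and isotopologue tables with ~1.1 %-per-carbon natural abundance.

## Worked example

```python
from atpflux.calibration import REPORTED_CALIBRATION, fit_hill
from atpflux.synthetic import gen_calibration_titration, default_titration_concentrations

tit = gen_calibration_titration(REPORTED_CALIBRATION,
                                default_titration_concentrations(12), noise_sd=0.0)
cal = fit_hill(tit)
print(f"n = {cal.n:.4f}, K_A = {cal.K_A:.5f} mM")
# n = 3.1234, K_A = 0.84699 mM
```

The full pipeline is driven by the numbered scripts in `analysis/`:

```bash
python analysis/01_simulate_inputs.py      # titration, events, MDV tables
python analysis/02_calibrate_sensor.py     # -> n = 3.1234, K_A = 0.84699 mM
python analysis/03_atp_timecourse.py       # gated/smoothed ATP traces
python analysis/04_tracer_analysis.py      # corrections, pathway totals, PFK ratio
python analysis/05_flux_analysis.py        # efflux scan + 100-restart MFA
```

Outputs land under `results/`.  Representative printed results:

```
quiescent: 1733/5000 events gated, ATP(0)=0.856 mM, endpoint=0.856 mM
oxphos_inhibited: 1653/5000 events gated, ATP(0)=0.791 mM, endpoint=0.514 mM
quiescent: glycolysis labeled total 97.8, F1,6BP/F6P = 0.80
proliferative_5FU: glycolysis labeled total 175.8, F1,6BP/F6P = 2.12
efflux scan: selected 65; not-ok candidates [0.0, 5.0, 10.0]
quiescent: 100 restarts, best residual 1.28e-13, free fluxes {'G6PD': 20.0, 'PC': 5.0}
```

i.e. the step perturbation in the OXPHOS-inhibited arm drops single-cell
ATP from ~0.8 to ~0.5 mM, proliferation raises the F1,6BP/F6P
product/substrate ratio of phosphofructokinase, low lactate-efflux
candidates are rejected because they force glycolysis to run backwards,
and the flux fitter recovers the generating free fluxes exactly on
noiseless data.

## Layout

```
src/atpflux/
  calibration.py    Hill sensor model, conversions, log-linear fit
  timecourse.py     gating, penalized-spline smoothing, ATP traces
  tracer.py         isotopologue tables: correction, totals, ratios
  synthetic.py      ground-truth generators for all inputs
  mfa/              network model, cumomer/EMU simulator, isotopomer
                    enumeration oracle, multi-start fitting, efflux scan
  data/central_carbon.yaml   atom-mapped central-carbon network
analysis/           numbered pipeline drivers (writes results/)
tests/              pytest suite incl. end-to-end acceptance checks
docs/methods.md     model assumptions, parameters, design choices
```
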