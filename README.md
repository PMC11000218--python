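# unbindkit

Thermodynamics and kinetics of ligand unbinding from (well-tempered)
metadynamics, as a tested, reusable analysis pipeline.  The package is
aimed at molecular-simulation practitioners who run volume-restrained
metadynamics of protein–ligand dissociation and want the downstream
analysis — free-energy-surface reweighting, standard-state binding free
energies, and unbinding-rate estimation from biased escape times —
implemented once, validated against systems with known answers.

Because the analysis, not the MD engine, is the point, every stage is
exercised end to end on overdamped Langevin model systems: a 1D double
well and a 2D radial binding landscape with a bound basin, a barrier of
several kT, and a flat "solvated" region, plus direct samplers of
escape-time ensembles with known rates.

## What it computes

**Thermodynamics.**  A well-tempered metadynamics bias (Gaussian hills
with heights w₀·e^{−V/((γ_wt−1)kT)}) is deposited along the radial CV;
trajectories are reweighted with the time-independent estimator
(offset c(t) from the growing bias) onto a free-energy surface F(s)
over (ρ, C_N).  The bound/unbound difference is

    ΔG_MetaD = −kT ln( ∫_bound e^{−βF} ds / ∫_unbound e^{−βF} ds ),

integrated on a grid.  Confining the unbound ligand to a sphere of
radius ρ_s (one-sided wall k(ρ−ρ_s)²) perturbs its translational
entropy, corrected by

    TΔS = RT ln( ((4/3)πρ_s³ − V_prot) / V⁰ ),   V⁰ = 1660 Å³,

so that ΔG_b° = ΔG_MetaD − TΔS and K_d = C⁰·e^{ΔG_b°/RT}.  Error bars
come from block analysis.

**Kinetics.**  Escape times from infrequent-metadynamics runs are
modeled with the time-dependent-rate survival law

    S(t) = exp( −k₀ ∫₀ᵗ e^{γβV_MB(t′)} dt′ ),

where V_MB(t) is the maximum bias averaged over runs still in the
bound basin, modeled as a·log(1+bt) up to a cutoff.  The unbiased rate
k₀ and the bias-quality factor γ ∈ [0, 1] are fit by maximum likelihood
over events and censored runs, validated with a Kolmogorov–Smirnov test
against the implied distribution, with 30th/70th-percentile bootstrap
intervals from KS-passing resamples.  The hyperdynamics time-rescaling
estimator (t* = ∫e^{βV}dt) is included for comparison and reports its
own KS verdict.

## Worked example

Standard-state bookkeeping with protein-scale inputs (restraint radius
28 Å, protein volume 48300 Å³, 300 K):

```python
>>> from unbindkit.fes import ThermoParams, ThermoResult
>>> r = ThermoResult.from_dg(-3.3, ThermoParams())
>>> round(r.tds, 2), round(r.dg_b, 1), round(r.kd_mM, 2)
(1.95, -5.2, 0.15)
```

A modest −5.2 kcal/mol binding free energy corresponds to a K_d of
~0.2 mM: weak binding, endergonic product release.

Rates from a synthetic 41-run escape ensemble with known ground truth
(k₀ = 0.002 per time unit, γ = 0.7):

```
$ unbindkit make-escape-times --k0 2e-3 --gamma 0.7 --a 3 --b 1 \
      --t-c 10 --n-runs 41 --horizon 200 --seed 1 --out esc
$ unbindkit rates --escapes esc/ESCAPES --traces esc/TRACES \
      --n-boot 50 --seed 1 --out rates.json
```

`rates.json` then holds the fitted `k0` and `gamma`, the V_MB model,
the KS statistic and p-value, the bootstrap percentiles and the
hyperdynamics comparison.

The numbered drivers under `analysis/` run the full study-scale
analyses and write their tables under `results/`:

```
$ python analysis/01_binding_thermodynamics.py   # TΔS, ΔG_b°, K_d table
$ python analysis/02_fes_recovery.py             # reweighted FES vs analytic
$ python analysis/03_rate_estimation.py          # recovery/calibration/coverage
$ python analysis/04_imetad_toy.py               # full-stack toy iMetaD rates
```

For instance `04_imetad_toy.py` prints (seed 20260924):

```
KTR unbiased rate:        1.016e-03 /time
rescaled direct rate:     2.889e-03 /time
log10 ratio:              -0.45
bias-quality gamma:       1.33
KS p-value of the fit:    0.95
```

— the rate inferred from 41 biased runs on an 8 kT barrier agrees with
an analytically rescaled direct measurement well within one order of
magnitude, the standard this kind of estimate is held to.

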