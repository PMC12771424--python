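# Methods

## The kinetic scheme

All simulation and most of the analysis rest on the minimal mass-action
scheme for a hexacoordinate globin with two competing exogenous ligands:

```
hexa-deoxy   <-- k_H_off / k_H_on -->   penta-deoxy
penta-deoxy + O2   <-- k'_O2 [O2] / k_O2_off -->   oxy
penta-deoxy + CO   <-- k'_CO [CO] / k_CO_off -->   carbonmonoxy
```

Ligands are treated in pseudo-first-order excess: `[O2]` and `[CO]` are
constants of the experiment, so the vector of species fractions obeys a
linear ODE `df/dt = A f` whose rate matrix has columns summing to zero
(total heme conservation is an algebraic identity of the model, and a
validated invariant of every emitted trajectory). This is the smallest
scheme in which the three relations used by the analysis all hold
exactly in their respective limits:

* the coordination partition `F_H = K_H/(1+K_H)` with
  `K_H = k_H_on/k_H_off` (ligand-free equilibrium);
* the CO-competition correction
  `k_O2 = k_obs (1 + k'_O2[O2]/(k'_CO[CO]))`, valid when CO binding is
  effectively irreversible (`k'_CO[CO] >> k_CO_off`) and the
  pentacoordinate intermediate is at quasi-steady state;
* the affinity relation `K_O2 = K_O2,pent/(1+K_H)`.

Assumptions worth stating: photolysis is instantaneous and complete (the
flash-photolysis initial condition is 100 % pentacoordinate deoxy);
geminate (sub-ns) rebinding, instrument response convolution, temperature
and pH dependence are not modeled. Transients are analyzed as single
exponentials throughout — the same model the bench workflow fits — so the
simulator's default regime is one where that model is accurate (see the
His-exchange defaults below).

## Parameters, units, defaults

Units are fixed package-wide: time in s (autoxidation reported in h and
min), concentrations in uM, bimolecular rates in uM^-1 s^-1, absorbance in
AU. The parameters that matter:

| parameter | meaning | default | why |
|---|---|---|---|
| `k'_O2`, `k_O2_off` | O2 association/dissociation at the penta heme | per-protein truth | the quantities under study |
| `k'_CO`, `k_CO_off` | CO association/dissociation | truth; `k_CO_off = 0.001 s^-1` | plant-globin CO release is slow; keeps CO binding effectively irreversible in stopped-flow |
| `k_H_on`, `k_H_off` | distal-His exchange | `k_H_off = 2 s^-1`, `k_H_on = K_H * k_H_off` | plant nsHb His exchange spans roughly 1-1000 s^-1; the slow end is the regime where photolysis transients are cleanly single-exponential, which is the regime the single-exponential analysis (and the published fits) presuppose |
| `[O2]` air | dissolved O2, air-equilibrated buffer, 25 C | 262 uM | standard solubility value used for the single-concentration photolysis analysis |
| stopped-flow `[O2]`, `[CO]` | post-mixing concentrations | 131, 1000 uM | oxy sample diluted 1:1 with CO-saturating buffer; only the ratio enters the correction, and both are free config parameters |
| replicates | traces / spectra / autoox series | 10 / 10 / 3 | traces averaged 10-fold and autoxidation run in triplicate, mirroring the bench protocol |
| time grids | span per relaxation | 10 half-lives, 400 points | >= 5 half-lives are needed to pin offset and amplitude; 10 is cheap |

## Synthetic observables

Basis spectra are sums of Gaussian bands (center, FWHM, peak amplitude).
Defaults: pentacoordinate deoxy, one broad 555 nm band (FWHM 58.5 nm);
hexacoordinate deoxy, split 530/560 nm bands (FWHM 20 nm); oxy 541/577 nm;
carbonmonoxy 540/569 nm; ferric hexa 530 nm with a 560 nm shoulder; plus
Soret bands in the 403-432 nm region so traces monitored at 412/420 nm
have signal. Amplitudes were set so the pure-state A555/A540 ratios land
at the empirical boundary anchors (1.20 pentacoordinate, 3.11
hexacoordinate); band positions are qualitative, and users can supply
their own `BasisSpectra`.

Noise is additive i.i.d. Gaussian per point with an explicit seed;
identical seed and parameters give bit-identical output. "x % noise" in
the recovery tests means an sd of x % of the observable's characteristic
amplitude (trace peak-to-baseline; spectrum peak).

The ratio -> F_H calibration is a first-class input: a monotone
piecewise-linear anchor table. The shipped default holds only the two
boundary anchors (1.2 -> 0, 3.1 -> 1), because the interior of the
empirical relationship is not reproducible from published numbers (the
published interior points are not collinear with the anchors — e.g. maize
Hb1 at ratio 1.8 maps to 0.48, and a ratio of 2.7 maps to 0.83, neither
of which the two-anchor line gives). For synthetic data the pipeline
instead builds a dense calibration from the same basis spectra through
the same measurement protocol, which makes noiseless recovery exact up to
interpolation error (< 1e-4 with 201 anchors).

### Coordination measurement protocol

The band ratio is read from single wavelengths (555 and 540 nm, linear
interpolation), which is robust to shoulder shape but noise-sensitive:
propagating a Gaussian sd of 2 % of the spectrum peak through the ratio
and the calibration slope gives sd(F_H) ~ 0.036 for a single raw scan —
a two-point read simply cannot resolve F_H to 0.02 at that noise. The
pipeline therefore (a) averages 10 replicate scans and (b) applies
standard Savitzky-Golay smoothing (window 9 points, quadratic — much
narrower than any band, so band shapes are preserved) before the read,
with the calibration built through the identical render-smooth-interpolate
protocol. Measured sampling sd of F_H under 2 % noise: ~ 0.007.

## Fitting

Single-exponential fits (`y = offset + amplitude * exp(-k t)`) use
Levenberg-Marquardt least squares (lmfit) with parameter tolerances 1e-12,
initialized from a log-linear regression on the baseline-subtracted
signal (baseline = mean of the last tenth of the trace). Failure is never
silent: constant traces are flagged degenerate (amplitude 0), and fits
with `k <= 0` or R^2 < 0.9 are flagged rejected; the autoxidation wrapper
additionally rejects non-decaying fits. Standard errors come from the
fit covariance and are propagated into the run log.

Bimolecular rates accept either a multi-concentration regression
(ordinary least squares; a negative intercept is reported with a warning,
never clamped) or a single concentration point with a supplied off-rate
(`k' = (k_obs - k_off)/[L]`) — the latter matching the single-concentration
O2 photolysis design, where the pipeline passes `k_off = 0` because the
off-rate contributes < 0.05 % of `k_obs` in air.

Degenerate-input conventions: `F_H = 1` returns `K_H = inf` (with a
warning from `F_H >= 0.999` up, since the inversion is then dominated by
measurement error); `K_H = inf` gives `K_O2 = 0`; the affinity assembly
accepts a `K_O2,pent` override and then also reports the from-rates ratio,
because published pentacoordinate affinities are sometimes computed from
unrounded intermediates and differ from the printed `k'/k` quotient.

## Numerical choices

Trajectories are integrated with LSODA (stiffness matters: photolysis
relaxations near 4e4 s^-1 and stopped-flow displacement near 0.15 s^-1
coexist in one scheme) at rtol 1e-10 / atol 1e-12 — tightened beyond the
level needed for the data so that trajectories agree with the exact
matrix-exponential solution of the linear system to better than 1e-8,
the bound the oracle tests assert. Tiny negative fractions from solver
round-off are clipped at 0; mass conservation is validated at 1e-9.

## What the simulator does and does not emulate

It emulates: two-component equilibrium mixtures, pseudo-first-order
rebinding and displacement transients with replicate-to-replicate noise,
and exponential oxy -> ferric conversion. It does not emulate: baseline
drift, wavelength calibration error, correlated (1/f) noise, photoselection
or partial photolysis, geminate recombination, biphasic His-competition
kinetics in the fast-His regime, or pH/temperature effects. Passing
recovery tests therefore demonstrate that the analysis chain is unbiased
and correctly propagates the stated noise model — not that it is robust to
every systematic error a real instrument can produce.

## Problem sizes

Test and default problem sizes are deliberately small: 400-point traces,
201-point spectra (450-650 nm, 1 nm), 40-spectrum autoxidation series,
10 trace replicates, 3 autoxidation replicates, 20 randomized schemes in
the oracle checks. A full simulated three-protein run completes in about a
second on one core.

## Known limitations

* The empirical interior of the ratio -> F_H relationship is not
  reproduced; users with access to the original calibration should supply
  it as an anchor table.
* Only single-exponential relaxation models are provided; strongly
  biphasic traces (fast His exchange, heterogeneous samples) are flagged
  by R^2 rejection rather than modeled.
* Ferric-state coordination is treated qualitatively (spectra only); no
  ferric K_H is computed.
* The shipped literature comparison table for autoxidation reproduces its
  sources as printed, including two rows whose published half-lives are
  not internally consistent with `t_1/2 = 60 ln2 / k_ox`.
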