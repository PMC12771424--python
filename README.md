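# hexakin

Spectro-kinetic analysis of hexacoordinate plant hemoglobins: heme
coordination equilibria from visible spectra, ligand-binding rate and
equilibrium constants from flash-photolysis and stopped-flow traces, and
autoxidation kinetics — together with a forward simulator of the underlying
kinetic scheme so the whole analysis can be validated against known ground
truth.

## The scientific problem

Nonsymbiotic plant hemoglobins (and vertebrate neuroglobin) are
*hexacoordinate*: the distal histidine reversibly binds the sixth iron
coordination site, so an exogenous ligand (O2, CO) must displace it before
binding. Characterizing such a globin means answering, from instrument
traces and spectra:

1. **How hexacoordinate is it?** The ferrous-deoxy visible spectrum is a
   mixture of a pentacoordinate component (single broad band near 555 nm)
   and a hexacoordinate component (split bands near 530/560 nm). The band
   ratio A555/A540 maps, through an empirical calibration anchored by fully
   pentacoordinate leghemoglobin a (ratio 1.2) and fully hexacoordinate
   neuroglobin (ratio 3.1), onto the fraction hexacoordinate `F_H` and the
   coordination equilibrium constant

   ```
   K_H = F_H / (1 - F_H),        F_H = K_H / (1 + K_H)
   ```

2. **How fast does it bind and release oxygen?** Flash photolysis measures
   rebinding to the transient pentacoordinate intermediate,
   `k_obs = k'[L] + k_off`, giving the bimolecular association rates
   `k'_O2,pent` and `k'_CO,pent`. Stopped-flow mixing of the oxy protein
   with CO measures O2 release under CO competition; the observed rate is
   corrected to the true dissociation rate by

   ```
   k_O2 = k_obs * (1 + k'_O2 [O2] / (k'_CO [CO]))
   ```

   Affinities follow as `K_O2,pent = k'_O2,pent / k_O2` and, paying the
   histidine displacement cost,

   ```
   K_O2 = K_O2,pent / (1 + K_H)
   ```

3. **How stable is the oxy complex?** The oxy alpha band at 575 nm decays
   exponentially as the ferrous oxy heme autoxidizes to the ferric state;
   the fitted rate `k_ox` (h^-1) gives the half-life
   `t_1/2 = 60 ln2 / k_ox` minutes.

The simulator closes the loop: the four heme species (hexa-deoxy,
penta-deoxy, oxy, carbonmonoxy) evolve under the mass-action scheme

```
hexa <--k_H_off/k_H_on--> penta
penta + O2 <--k'_O2[O2]/k_O2_off--> oxy
penta + CO <--k'_CO[CO]/k_CO_off--> carbonmonoxy
```

with ligands in pseudo-first-order excess, and every observable
(equilibrium spectra, delta-OD transients, stopped-flow traces,
autoxidation series) is rendered from Gaussian-band basis spectra with
seeded Gaussian noise.

## Worked example

Simulate a moss-like globin from known ground truth (F_H = 0.83,
k'_O2 = 148 uM^-1 s^-1, k_O2 = 5.2 s^-1, k'_CO = 0.58 uM^-1 s^-1,
k_ox = 0.88 h^-1), then run the full analysis:

```python
from hexakin import ProteinConfig, RunConfig, SimulationTruth, run_pipeline

truth = SimulationTruth(f_h=0.83, k_prime_o2=148.0, k_o2_off=5.2,
                        k_prime_co=0.58, k_ox_per_h=0.88)
cfg = RunConfig(proteins=(ProteinConfig("MossHb", truth=truth),), seed=1)
report = run_pipeline(cfg)[0]

c, b, a = report.coordination, report.binding, report.autoox
print(f"A555/A540 ratio      : {c.ratio:.3f}")
print(f"fraction hexa (F_H)  : {c.f_h:.3f}")
print(f"K_H                  : {c.k_h:.2f}")
print(f"k'_O2,pent           : {b.k_prime_o2_pent:.1f} uM^-1 s^-1")
print(f"k_O2                 : {b.k_o2:.2f} s^-1")
print(f"K_O2,pent            : {b.K_O2_pent:.1f} uM^-1")
print(f"K_O2                 : {b.K_O2:.2f} uM^-1")
print(f"k_ox                 : {a.k_ox_per_h:.3f} h^-1")
print(f"t_1/2                : {a.t_half_min:.0f} min")
```

prints

```
A555/A540 ratio      : 2.371
fraction hexa (F_H)  : 0.830
K_H                  : 4.88
k'_O2,pent           : 148.1 uM^-1 s^-1
k_O2                 : 5.22 s^-1
K_O2,pent            : 28.3 uM^-1
K_O2                 : 4.82 uM^-1
k_ox                 : 0.880 h^-1
t_1/2                : 47 min
```

Reading the output: the simulated spectrum's band ratio (2.371) converts
through the calibration to the generating hexacoordinate fraction 0.83, so
K_H = 0.83/0.17 = 4.88. The fitted photolysis and stopped-flow rates
recover the input association and dissociation rates within a fraction of a
percent, giving the pentacoordinate affinity 28.3 uM^-1 and, after the
1 + K_H histidine penalty, an effective oxygen affinity of 4.82 uM^-1. The
autoxidation fit returns the input 0.88 h^-1, a 47-minute half-life.

The same workflow is available from the shell (`hexakin simulate`, `coord`,
`kinetics`, `autoox`, `run`, `report`); `hexakin run -c config.yaml -o out/`
writes the three delimited result tables (coordination, oxygen binding,
autoxidation) plus a structured JSON run log with every fitted parameter
and its standard error.

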