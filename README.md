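# clexsaxs

Time-resolved small-angle X-ray scattering (SAXS) analysis of Ca²⁺–alginate
gelation by competitive ligand-exchange crosslinking (CLEX), for structural
biophysicists studying ionotropic polysaccharide hydrogels.

When two alginate solutions — one carrying CaEDTA, the other ZnEDDA — meet,
the exchange reaction ZnEDDA + CaEDTA ⇌ ZnEDTA + Ca²⁺ + EDDA²⁻ releases
free Ca²⁺ at constant pH, which crosslinks guluronate blocks into
multi-chain junction zones. In a Kratky representation (q²I(q) vs q) the
locally rod-like scatterers produce a two-component "broken rod" signature

```
q²I(q) ≈ q·k₁·[J₁(q·R_c1)/(q·R_c1)]² + q·k₂·[J₁(q·R_c2)/(q·R_c2)]² + const
```

where R_ci is the cross-sectional radius of component i (thin: single or
thickened chains; thick: junction zones), J₁ the first-order Bessel
function, and k_i amplitudes that give the component weight fractions
w_i = k_i/(k₁+k₂). A single rod term peaks at the universal position
q_peak·R_c = x* ≈ 1.357 (the root of 2x·J₀(x) = 3·J₁(x)), so a ~2.7 nm
junction zone peaks near q = 0.5 nm⁻¹.

The package provides:

- `clexsaxs.formfactor` — the broken-rod Kratky model and peak location;
- `clexsaxs.saxs_io` — plain-text 1D profile and frame-series I/O, buffer
  subtraction, q masking, the Kratky transform;
- `clexsaxs.fitting` — per-frame bounded weighted least squares, one- vs
  two-component selection by BIC, warm-started series fitting, replicate
  averaging;
- `clexsaxs.rdsim` — a 1D reaction–diffusion model of CLEX Ca²⁺ release
  coupled to irreversible alginate binding, with region-of-interest gel
  kinetics;
- `clexsaxs.synthetic` — scenario presets (pH 7.0 / 7.4 / 8.0, GDL
  control) and a seeded generator of noisy frame series with ground truth;
- `clexsaxs.cli` — a `clexsaxs` command with `generate`, `fit`,
  `simulate-rd` and `report` subcommands.

The numbered scripts under `analysis/` run the full study: generate the
synthetic series, fit the time courses, simulate gelation at the solution
contact zone, and render figures; tables land under `results/`.

## Worked example

```python
from clexsaxs import (FitConfig, fit_series, read_profile, read_series,
                      scenario, subtract_buffer, write_fixture)

manifest = write_fixture("fixture", scenario_name="pH7.0", seed=101)
frames = read_series(manifest)
buffer = read_profile("fixture/buffer.dat")
tc = fit_series([subtract_buffer(f, buffer) for f in frames])
print(f"full gel: rc1 = {tc.rc1_series[-1]:.3f} nm, "
      f"rc2 = {tc.rc2_series[-1]:.3f} nm, w2 = {tc.w2_series[-1]:.3f}")
```

prints

```
full gel: rc1 = 0.857 nm, rc2 = 2.851 nm, w2 = 0.812
```

— the fitted 10 h equilibrated gel state at pH 7.0: chains thickened from
0.2 to ~0.9 nm cross-sectional radius, junction zones of ~2.9 nm carrying
~80% of the scattering weight (generating truth 0.90 / 2.90 / 0.80). The
early frames of the same series select a single ~0.2 nm component,
switching to two components once junction zones appear.

The same pipeline from the shell:

```
clexsaxs generate --scenario pH7.0 --seed 101 --out fixture
clexsaxs fit --manifest fixture/manifest.csv --buffer fixture/buffer.dat --out fit
clexsaxs report --timecourse fit/timecourse.csv --manifest fixture/manifest.csv
clexsaxs simulate-rd --out rd
```

The reaction–diffusion run reports, among other things, that a 50 µm
region of interest at the solution interface reaches half of its 120 s gel
concentration by ~12 s while a region offset by 200 µm needs ~60 s — the
diffusion-limited spread of gelation away from the contact point.

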