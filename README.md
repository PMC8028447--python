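# ojipcanopy

Analysis of fast chlorophyll-*a* fluorescence induction (OJIP) transients and
of the spatiotemporal heterogeneity of chlorophyll within crop canopies.

Dark-adapted leaves exposed to saturating light show a polyphasic
fluorescence rise with inflections O (origin, ~50 µs), J (~2 ms), I (~30 ms)
and P (peak). The JIP test reads a handful of landmarks off this curve and
converts them into the PSII energy-flux budget — absorption, trapping,
electron transport and dissipation per reaction centre and per leaf
cross-section. Combined with per-area chlorophyll from leaf-disk extracts,
these parameters let one phenotype how photosynthetic activity is
distributed vertically through a canopy (layers L1 bottom … L5 top), how
that distribution changes from vegetative (V1–V3) to reproductive (R1–R5)
growth, and which fluorescence parameter best tracks chlorophyll content.

The package provides, as importable modules under `src/ojipcanopy/` driven by
the numbered scripts in `analysis/`:

- **transients** — the fluorescence-transient data model, the two-rate
  instrument sampling grid (10 µs steps to 2 ms, 1 ms steps to 1 s), linear
  interpolation, CSV I/O;
- **jip** — landmark extraction (F0 at 50 µs, F300, FJ at 2 ms, FI at 30 ms,
  FM, complementary area) and the full derived panel:
  V_J = (F_J − F_0)/(F_M − F_0), M_0 = 4(F_300 − F_0)/(F_M − F_0),
  φ_Po = 1 − F_0/F_M (= F_v/F_m), ψ_Eo = 1 − V_J, φ_Eo = φ_Po·ψ_Eo,
  φ_Ro = φ_Po(1 − V_I), ABS/RC = M_0(1/V_J)(1/φ_Po), TR_0/RC = M_0/V_J,
  ET_0/RC, DI_0/RC, RE_0/RC, the per-cross-section fluxes (ABS/CS ≈ F_M …),
  RC/CS, S_m = Area/(F_M − F_0), N = S_m·M_0/V_J and PI_ABS, in two published
  formula variants; plus JI-phase classification (JI-fall vs JI-rise);
- **assay** — Lichtenthaler 95%-ethanol chlorophyll equations mapping
  absorbances at 649/665 nm to µg cm⁻² of leaf disk;
- **canopy** — standard errors, one-way ANOVA with Fisher's LSD and
  compact-letter displays, within-leaf basal→top gradients, L1-relative layer
  ratios, the four-way vertical-pattern taxonomy, and reversal-stage
  detection (the stage at which the vertical chlorophyll profile turns from
  bottom-heavy to top-heavy);
- **importance** — per-layer XGBoost regression of chlorophyll on the JIP
  panel (80/20 split, 5-fold CV grid search, 100 trees) with gain-based
  feature ranking and lower- vs upper-canopy cumulative importance;
- **simulate** — a seeded synthetic generator for single transients
  (sum-of-saturating-exponentials with closed-form ground truth) and whole
  canopy trials with designed vertical structure;
- **pipeline / cli** — end-to-end orchestration (`run_pipeline`, and the
  `ojipcanopy` command with `simulate`, `jip`, `assay`, `analyze`, `run`
  subcommands).

## Worked example

```sh
python analysis/01_simulate_canopy.py   # synthetic trial -> results/synthetic/
python analysis/02_jip_parameters.py    # landmarks + JIP panel per leaf
python analysis/03_vertical_heterogeneity.py
python analysis/04_chl_importance.py
```

On the default simulated trial (seed 0) this prints, among other things:

```
vegetative leaves classified JI_fall: 98.6%
reproductive leaves classified JI_rise: 100.0%

detected reversal stages:
nitrogen reversal_stage
      N0             R1
      N1             R2
      N2             R3

L1: rmse_test =  3.70 ug/cm2, top parameters: RE0_CS, TR0_CS, M0
L2: rmse_test =  3.24 ug/cm2, top parameters: RE0_CS, RC_CS, phi_Po
L3: rmse_test =  2.38 ug/cm2, top parameters: RE0_CS, VI, ET0_CS
L4: rmse_test =  3.21 ug/cm2, top parameters: RE0_CS, Sm, ET0_CS
L5: rmse_test =  4.19 ug/cm2, top parameters: RE0_CS, VJ, PI_ABS
```

Reading: vegetative-phase leaves show the JI-fall morphology (the I step
below the J step — fast re-oxidation beyond Q_A in sink leaves) while
reproductive leaves show the canonical rise; the vertical chlorophyll
profile flips from bottom-heavy to top-heavy at the booting/heading
transition, earlier under nitrogen deficit (N0) and later under surplus
(N2); and the PSI end-acceptor flux per cross-section RE_0/CS is the
top-ranked predictor of leaf chlorophyll in every layer, as designed into
the generator. The per-layer test RMSEs of ~2–4 µg cm⁻² compare to a
chlorophyll range of roughly 30–55 µg cm⁻².

In code, the core computation is three calls:

```python
from ojipcanopy import OjipShapeParams, simulate_ojip, jip_panel

transient, truth = simulate_ojip(OjipShapeParams(seed=1))
landmarks, params = jip_panel(transient)
print(f"Fv/Fm = {params.phi_Po:.3f}, PI_ABS = {params.PI_ABS:.2f}")
```

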