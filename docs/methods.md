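# Methods

## The JIP test

A dark-adapted leaf has all PSII reaction centres (RCs) open; under
saturating light, fluorescence rises from F_0 (all Q_A oxidised) to F_M (all
Q_A reduced) in about one second, through the J (~2 ms) and I (~30 ms)
inflections that mark the successive reduction of Q_A, of the plastoquinone
pool, and of the PSI acceptor side. The package reads the landmarks off the
recorded curve by linear interpolation in time — F_0 at 50 µs (the first
reliable sample of continuous-excitation instruments; the curve is never
extrapolated before the first sample), F_300µs, F_J at 2 ms, F_I at 30 ms —
and takes F_M as the maximum recorded value with ties broken toward the
earliest time, which makes the peak time deterministic on noisy plateaus.
No smoothing is applied before landmark reads.

From the landmarks: V_t = (F_t − F_0)/(F_M − F_0),
M_0 = 4(F_300 − F_0)/(F_M − F_0) in ms⁻¹, φ_Po = 1 − F_0/F_M,
ψ_Eo = 1 − V_J, φ_Eo = φ_Po·ψ_Eo, φ_Ro = φ_Po(1 − V_I), the specific fluxes
TR_0/RC = M_0/V_J, ABS/RC = TR_0/RC / φ_Po, ET_0/RC = TR_0/RC·ψ_Eo,
DI_0/RC = ABS/RC − TR_0/RC, the cross-section fluxes with ABS/CS ≈ F_M, the
RC density RC/CS = φ_Po(V_J/M_0)·ABS/CS, and
PI_ABS = [φ_Po V_J/M_0]·[φ_Po/(1−φ_Po)]·[ψ_Eo/(1−ψ_Eo)].

Three quantities have competing published formulations, so a variant switch
selects between them (`as_printed`, the default, carries extra yield
factors: RE_0/RC = M_0(1/V_J)ψ_Eo φ_Ro, ET_0/CS = φ_Po φ_Eo ABS/CS,
RE_0/CS = φ_Eo φ_Ro ABS/CS; `strasser_standard` uses
RE_0/RC = M_0(1/V_J)(1−V_I), ET_0/CS = φ_Eo ABS/CS, RE_0/CS = φ_Ro ABS/CS).
All other parameters are identical between variants. RC/CS is implemented
as the product φ_Po·(V_J/M_0)·(ABS/CS); a subtractive form sometimes seen in
print can go negative and is dimensionally inconsistent, so it is treated as
a typographical artifact.

The complementary area is the trapezoidal integral of (F_M − F(t)) from the
first sample to the peak time, with time in **milliseconds** so that
S_m = Area/(F_M − F_0) (ms) and M_0 (ms⁻¹) are mutually consistent in the
turnover number N = S_m·M_0/V_J — the standard expression adopted because N
has no universally printed formula. Integrating to the peak rather than to
the end of the record matches N's definition ("from time 0 to t_FM").

The JI phase is classified per transient: JI-fall if F_I < F_J(1 − δ),
JI-rise if F_I > F_J(1 + δ), else flat, with δ = 0.01 by default — large
enough that 2% per-point measurement noise rarely produces a spurious class,
small enough to catch genuine falls of a few percent.

## Chlorophyll assay

Leaf disks (diameter 0.85 cm) extracted in 1.8 mL of 95% ethanol; Chl a =
13.36·A665 − 5.19·A649 and Chl b = 27.43·A649 − 8.12·A665 (µg/mL,
Lichtenthaler coefficients for 95% ethanol, exposed as configurable
constants since laboratory standard curves differ); total concentration ×
volume ÷ disk area gives µg cm⁻². Negative computed concentrations raise an
assay-inconsistency error rather than clamping silently, because they
indicate swapped wavelengths or a blank failure. A470 is read and carried
through for provenance but feeds no reported quantity (it belongs to
carotenoid equations).

## Group statistics

SE = SD/√n with the n−1 sample SD. One-way ANOVA F and p come from
`scipy.stats.f_oneway`; Fisher's LSD uses the pooled error mean square with
two-sided t tests at α = 0.05, and the compact-letter display follows the
insert-and-absorb procedure, lettering columns in order of descending column
maximum so that "a" always marks the highest means. With zero pooled
within-group variance the F statistic degenerates: unequal means are
reported with p at the machine floor and separated letters; fully constant
data share one letter.

## Vertical heterogeneity

"Bottom-heavy vs top-heavy" is operationalised as the sign of the
least-squares slope of per-layer mean chlorophyll against layer rank; the
reversal stage is the first stage (in V1…R5 order) whose slope turns
positive after at least one bottom-heavy stage. A single monotone summary is
robust to one noisy layer, which qualitative peak-position rules are not.
Stages with fewer than three layers are skipped with a warning.

Layer-relative ratios divide each layer's mean by the L1 mean (the control,
≡ 1). A parameter "peaks" when the mean ratio of the upper half of the
present layers (L3–L5 of five, L2–L3 of three) exceeds 1 + δ and "valleys"
below 1 − δ, δ = 0.05 — above the jitter of replicate means at n = 4 but
below any designed effect. The four vertical-pattern categories are scored
by concordant minus discordant peak/valley indicators against their
signatures (category 1: peaks in PI_ABS, ET_0/RC, ET_0/CS, φ_Eo, ψ_Eo;
category 2: peaks in N, ABS/RC, TR_0/RC, DI_0/RC, RE_0/RC with valleys in
RC/CS and PI_ABS; category 3: peaks in RE_0/RC, RE_0/CS, φ_Ro; category 4:
peaks in DI_0/RC, DI_0/CS with valleys in PI_ABS, ET_0/RC, φ_Eo, ET_0/CS);
ties resolve to the lowest category id and are flagged. Signatures are
assessed on layer means, not per replicate.

## Boosted-tree importance

One model per canopy layer, pooling nitrogen levels and stages: XGBoost
regression (squared-error objective, 100 trees) of per-leaf chlorophyll
(mean of the three disk portions) on the 21-parameter JIP panel. The 80/20
train/test split is stratified by nitrogen to prevent treatment imbalance
at n ≈ 70–100 per layer; max depth {2, 3, 4, 6}, min child weight
{1, 3, 5} and learning rate {0.05, 0.1, 0.3} are grid-searched under
5-fold CV on the training split; quality is test-set RMSE. Importance is
gain (total loss reduction per feature across splits) normalised to sum 1,
ties broken alphabetically. Repeated-recovery experiments (tests,
acceptance script) use a single fixed hyperparameter combination
(depth 3, weight 1, rate 0.1) so that hundreds of fits stay cheap; the
analysis driver uses the full grid. Note one caveat established during
testing: when two features are *exactly* equally predictive, the booster
breaks the tie by column position, so importance is permutation-equivariant
only up to such ties.

## Synthetic data

No field data ship with the package, so a seeded generator stands in for
them, and its defaults define the conditions under which all stochastic
tests run.

**Single transients.** F(t) = F_0 + A·S(t)/max S with
S(t) = w_OJ(1−e^(−t/τ_OJ)) + w_JI(1−e^(−t/τ_JI)) + w_IP(1−e^(−t/τ_IP)),
τ = 0.25/5/80 ms — phenomenological stand-ins for the Q_A, PQ-pool and
PSI-acceptor phases. A negative w_JI yields the JI-fall morphology.
Because the curve is closed-form, every landmark has an exact ground truth
and extraction tests are exact oracles. Defaults F_0 = 500, A = 2000
(instrument counts, F_v/F_m ≈ 0.8) with 2% multiplicative Gaussian noise
per point, typical of continuous-excitation fluorimeters. A mechanistic
electron-transport ODE model was deliberately not used: it would add
contested kinetics without providing closed-form truth.

**Canopy trials.** 3 nitrogen levels × 8 stages × layers (3 at V1, 4 at V2,
5 from V3 on) × 4 replicates. Chlorophyll per leaf =
45 + nitrogen effect (−8/0/+4 µg cm⁻² for N0/N1/N2, saturating with
surplus) + slope·(rank − centre), the slope −3 µg cm⁻² per rank before the
nitrogen level's reversal stage (R1/R2/R3 for N0/N1/N2) and +3 after;
portion values add a ±8% basal→top gradient (increasing in the upper half
of the canopy, decreasing in the lower) and N(0, 2 µg cm⁻²) noise.
Vegetative leaves get w_JI = −0.4 (JI-fall), reproductive +0.3 (JI-rise).

The planted chlorophyll↔fluorescence dependence targets RE_0/CS through two
routes: the relative chlorophyll deviation rel = coupling·(chl − 45)/45
scales the amplitude by (1 + 0.8·rel), and sets a target
80·(1 + 2·rel)·(1 ± 3%) for the noise-free RE_0/CS itself, which the
generator realises exactly by solving (Brent's method) for the I-P weight —
RE_0/CS is monotone in w_IP while F_M = F_0 + A is independent of the phase
weights, so the inverse always exists within bounds. The consequence is the
designed identifiability structure: the 15% amplitude jitter and 12% shape
jitter land in full on F_M-proportional fluxes and on the solo yield
ratios, but are absorbed out of RE_0/CS, making it decisively the best
single predictor at coupling 1 and uninformative at coupling 0. All
randomness flows from the design seed through one spawned child stream per
leaf (`numpy.random.SeedSequence`), so whole datasets are bitwise
reproducible.

**What the generator does not emulate.** Real canopies have light-gradient
acclimation, non-linear nitrogen dose responses, gradual (not switch-like)
reversal of the vertical profile, instrument drift, and correlated
measurement error along the curve. Passing tests therefore demonstrate that
the pipeline recovers structure *of the designed kind and magnitude*; they
do not certify recovery from field data, where effect sizes and noise may
differ.

## Problem sizes and numerical choices

The default trial is 444 transients (1,198 samples each) and 1,332
chlorophyll values; the test suite runs repeated-recovery experiments at
20–50 seeds and the acceptance script at 10–20, sizes chosen so a full run
completes in a few minutes on one CPU while keeping binomial uncertainty on
recovery rates below ~7 percentage points. Interpolation is linear in time
(the grid is dense where the curve is fast); the complementary area uses
the trapezoid rule on the recorded grid, which agrees with a 10×-refined
integration to better than 1% on simulated curves. Degenerate inputs fail
loudly: FM ≤ F0 (no variable fluorescence), V_J ∈ {0, 1}, φ_Po = 0,
non-monotone time axes and negative pigment concentrations all raise typed
errors rather than propagating NaNs.

## Known limitations

- The `as_printed` flux variant and the literature-standard variant differ
  for RE_0/RC, ET_0/CS and RE_0/CS; analyses comparing absolute values
  across studies must state the variant (the pipeline logs it).
- Fisher's LSD applies no multiple-testing correction beyond the implicit
  ANOVA gate; letters at many layers are anti-conservative.
- Gain importance on strongly correlated features concentrates credit on
  whichever feature the first splits choose; rankings are stable here by
  design of the synthetic data, not as a general property of boosted trees.
- The K- and L-band analyses, the slow Kautsky decline beyond the 1-s rise,
  and carotenoid quantification are out of scope.
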