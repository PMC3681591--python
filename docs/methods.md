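# Methods

This note records the models, numerical choices and known limitations of
`rtmfa`, in the package's own terms.

## Metabolite balancing

The pseudo-steady-state balance `A r = 0` over the 36 intracellular
metabolites is split into unknown and measured columns,
`A_n r_n + A_b r_b = 0`. The estimator follows the classical
reconciliation-then-solve scheme:

1. redundancy matrix `R = A_b − A_n A_n⁺ A_b`, residuals `e = −R r_b`;
2. consistency index `h = eᵀ J⁺ e`, `J = R Ψ_b Rᵀ`, compared with the
   `(1 − α)` χ² quantile at `df = rank(R)` (α defaults to 0.05, critical
   value 3.84 at df = 1);
3. reconciled measurements
   `r_b' = (I − Ψ_b Rᵀ (R Ψ_b Rᵀ)⁺ R) r_b` — the minimum-variance
   projection onto the constraint manifold — and unknown fluxes
   `r_n = −A_n⁺ A_b r_b'`;
4. covariances propagated linearly through both maps; flux standard
   deviations are the square roots of the diagonal.

This is algebraically the weighted-least-squares estimate: the same `r_n`
solves `min (r_b − r̃)ᵀ Ψ_b⁻¹ (r_b − r̃)` subject to exact balance, which
the test suite verifies against an independent KKT solver on random small
networks.

**Numerics.** Pseudo-inverses and rank decisions use a relative
singular-value cutoff of 1e-10. A cutoff at machine epsilon is wrong here:
`R` is itself the output of a pseudo-inverse projection, so its spurious
singular values scale with `eps · cond(A_n)`, not `eps`; with covariance
weighting they would otherwise leak into `J⁺` and inflate `h` by orders of
magnitude. `rank(R) = 0` (exactly determined system) makes the test
vacuous: `h = 0`, pass, with a warning. Reversibility flags on reactions
are metadata only — the linear estimator does not impose sign constraints,
which is standard for metabolite balancing.

**Measured covariances.** Whether the balancing weights should include the
covariances between rates (induced by the shared biomass measurement) or
only the variances is a genuinely open choice; both are supported and the
default is diagonal, which is the conservative reading of
"variance-covariance matrix calculated directly from the measurements"
when per-rate errors are reported individually.

## The reaction network

The packaged *P. pastoris* central-carbon network
(`src/rtmfa/data/pichia_ccm.txt`) has 44 active reactions over 45
compounds, 36 of them balanced intracellular species, giving a 36 × 44
matrix of full row rank and 8 degrees of freedom. Linear chains are lumped
(GAPDH+PGK, PGM+enolase, G6PDH+6PGDH, αKGDH+succinyl-CoA synthetase); the
glyoxylate shunt is present in the file but flagged `inactive` and dropped
when the model is built, since it does not operate on glycerol. Dropping
(rather than zero-constraining) the shunt keeps the active matrix at
36 × 44 with the dimensions above.

**Why the consistency test has one degree of freedom.** An internal
network whose reactions all balance both carbon and available electrons
conserves two quantities, so nine measured rates would carry two redundant
equations. Published lumped networks of this size typically close only the
carbon balance, because at least one lumped step omits its cofactor
bookkeeping. The packaged network makes that choice explicitly: succinate
dehydrogenase passes its electrons directly to the (untracked) quinone
pool. The left null space of `A_n` is then exactly one-dimensional and the
single redundant equation is the carbon balance over the measured rates,
with coefficients equal to the carbon numbers of the exchanged species
(3 glycerol, 1 CO₂, 2 ethanol, 4 succinate, 2 acetate, 3 pyruvate,
6 citrate, and the biomass carbon content implied by the precursor
coefficients). The test suite asserts this structure.

**Measured set.** Nine reactions: glycerol uptake (r40), O₂ uptake, CO₂
evolution, biomass synthesis (r44), and exports of ethanol, succinate,
acetate, pyruvate and citrate, which are below detection in glycerol-grown
cultures and enter as zeros with a variance floor of `(1% of q_gly)²` so
the weight matrix stays invertible.

**Biomass reaction.** The macromolecular composition behind r44 is a
placeholder (precursor demands in mmol per gDCW chosen to give a typical
yeast carbon content of ≈39 mmol C/gDCW and NADPH/ATP demands of 10 and
35 mmol/gDCW); it can be overridden at load time
(`load_network(..., biomass_coefficients=...)`). Compartment tags are
metadata; no transport thermodynamics are modelled.

## Rate estimation

Per steady state, the window is the earliest run of six consecutive
off-line samples (configurable) located after three residence times at the
scheduled dilution rate, in which biomass, substrate, OUR and CER are
time-invariant. Invariance tolerances are per-channel: relative range
bounds for biomass (15%) and the gas rates (6%), and an absolute range
bound (9 g/L ≈ 4 assay sd) for residual glycerol, whose steady-state level
sits far below the assay noise so a relative bound would be meaningless.

`mu` adds the least-squares slope of biomass over the window to the mean
dilution rate; at true steady state the slope term vanishes. Rates use
window means; assay standard deviations (falling back to window sample
sds) are divided by √n for the mean and propagated by the delta method to
the full `Ψ_b`, including the covariances induced by the shared biomass
measurement (verified against Monte-Carlo simulation). Uptake and
production rates are all reported positive; the exchange reactions of the
network are oriented so positive rates plug in without sign juggling.

Off-line vs on-line rate sets are compared per rate with Welch's
two-sample t-test at α = 0.05.

## Chemometrics

Savitzky-Golay second derivatives (window 33 points, polynomial order 2)
run separately over each contiguous wavelength segment after excluding
the water bands (1400 and 1900 nm, ±20 nm — the widths are a package
choice, configurable) and everything above 2000 nm; the filter never
bridges an excluded gap. Mean-centering statistics are stored with the
fitted model and re-applied to new spectra. PLS1 models use NIPALS (via
scikit-learn) — the algorithm variant is immaterial; the contract is the
fitted-prediction behaviour, which the tests pin to a least-squares oracle
on full-rank problems. Latent-variable counts are fixed defaults (3 for
glycerol, 5 for biomass), not auto-selected; cross-validation is
leave-one-out by default (small data sets), with contiguous-block CV
available to respect serial correlation in process data. Reference values
are linearly interpolated to spectral timestamps with no extrapolation.

SEL is the pooled within-replicate standard deviation,
`sqrt(ΣΣ (y_ij − ȳ_j)² / (N (r − 1)))` — the `N(r−1)` denominator is the
standard pooled-error reading. Qualification bands: external R² > 0.90
and RMSEP < 1.5 × SEL → *excellent*; R² ≥ 0.70 and RMSEP ≤ 3 × SEL →
*good* (this closes the gap between the published bands); otherwise
*qualitative-only*.

## Synthetic data

The chemostat simulator integrates Monod kinetics
(`μ_max = 0.17 h⁻¹`, `K_s = 0.1 g/L`, `Y_XS = 0.65 g/g`, `S_in = 40 g/L`)
through a 27 h batch followed by dilution states A/B/C at 0.05/0.10/0.15
h⁻¹ (100/60/45 h — three to five residence times each plus a six-sample
window). Maintenance is off by default: the yields observed across these
dilution rates vary too little to identify a maintenance coefficient.
Off-line samples every 4 h carry truncated Gaussian assay noise at the
reference-method repeatability (biomass 0.56 g/L, glycerol 2.20 g/L);
truncation at zero biases the near-zero residual glycerol upward, which is
a real feature of assaying a limiting substrate. Gas channels carry 0.5%
relative noise.

**Off-gas generation.** CO₂ evolution follows from the network's carbon
balance at the instantaneous `q_gly` and `μ`, so the emitted rates are
exactly balance-consistent before noise; O₂ uptake is then set by the
per-state respiration-quotient targets (0.33/0.36/0.40). Because the
network constrains only carbon, any RQ is feasible — but RQ values below
the catabolic stoichiometry of glycerol oxidation (≈0.6–0.85 at these
yields) imply an oxygen demand beyond what the lumped catabolism supplies,
and the unique flux solution absorbs it through large compensating cycles
(pentose-phosphate NADPH production, NADH kinase running in reverse,
partially reversed TCA). The consistency test is unaffected (it checks
only the carbon balance), but the internal flux map under these RQ targets
should be read with that caveat; with RQ targets in the catabolically
consistent range the distribution is conventional.

Spectra are Beer–Lambert mixtures of Gaussian analyte bands (biomass -CH
bands at 1280/1330 nm, glycerol -OH/-CH bands at 1580/1695/1735 nm) on a
2 nm grid over 800–2200 nm, plus dominant water bands at 1400/1905 nm, a
wavelength-dependent linear baseline drift (1.5 mAU/h at the
long-wavelength end) and white noise (0.2 mAU). Band positions follow the
analyte windows above; amplitudes and noise were chosen once to give
realistic prediction errors (tenths of g/L for biomass, ~1–3 g/L for
glycerol) and are not re-tuned. What the generator does *not* emulate:
scattering nonlinearity, temperature-dependent band shifts, probe fouling,
and detector saturation — so passing tests demonstrate the pipeline's
statistical machinery, not robustness to every real-instrument artefact.

Flux datasets draw a ground-truth vector from the null space of `A`
(8-dimensional), normalize it to O(1), and add multivariate Gaussian noise
with the stated `Ψ_b` to the measured restriction. With correctly
specified noise the consistency index follows χ²(1) — the rejection rate
at 3.84 over 5000 replicates sits in [0.04, 0.06] — and ±1.96 sd intervals
on the unknown fluxes cover the truth for ≈95% of components.

## Orchestration

The off-line and on-line paths are two invocations of one state-level
routine (`pipeline.run_state`); the on-line path merely swaps in PLS
predictions for biomass and glycerol (the gas channels come from the
off-gas analyzer in both paths, interpolated to the spectral timestamps)
and uses the models' RMSEP as the per-channel assay sd. Outputs are
deterministic for fixed seeds, byte-identical across runs.

## Known limitations

* Six consistency tests at α = 0.05 will all pass in only ≈74% of random
  realizations; a single borderline failure in a run is the test's
  false-alarm rate at work, not a pipeline defect. The seed-pinned test
  suite uses a realization where all six pass.
* Batch-phase rates are out of scope: the washout balance returns zero at
  `F = 0` (with a warning) and the accumulation term is not implemented.
* No gross-error localisation: the test is global; with df = 1 the faulty
  measurement cannot be isolated anyway.
* No flux-bound or thermodynamic constraints; negative "irreversible"
  fluxes are reported as operating in reverse, not clipped.
* SBML import/export is not supported; the three on-disk dialects
  round-trip exactly and are the interchange formats.
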