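# Methods

## Scope

`pbpkddi` implements a whole-body physiologically-based pharmacokinetic
(PBPK) model of procainamide (PA) and its metabolite N-acetylprocainamide
(NAPA) in the rat, with a semi-mechanistic kidney, and a minimal
compartmental model of the perpetrator cimetidine whose unbound
concentrations dynamically inhibit the victims' renal transport (OCT2-
mediated basolateral uptake and MATE1-mediated apical secretion). Around
the models sit the closed-form parameter-derivation chain, noncompartmental
analysis (NCA), in-vitro inhibition kinetics, synthetic-study generation,
parameter estimation, interaction evaluation, and an end-to-end pipeline.

## Whole-body victim model

Each victim gets ten perfusion-limited tissues (adipose, bone, brain, gut,
heart, liver, lung, muscle, skin, spleen) plus arterial and venous blood.
The lung sits in series between the venous and arterial pools and carries
the cardiac output. The liver follows the serial splanchnic convention: gut
and spleen drain through it, its arterial inflow is the total hepatic flow
minus the gut and spleen flows. Tissue outflow uses the emergent-venous
convention: venous blood leaving a tissue has concentration `C_T · R / Kp`.

Cardiac output is closed as the venous return (sum of directly draining
tissue flows + total hepatic flow + renal blood flow = 71.2 mL/min for the
reference 0.25 kg rat); the registry's nominal lung flow is overridden by
this closure so that flow balance holds exactly.

Hepatic elimination acts on the unbound emergent venous concentration
(`CLu,int · fup · x_liver / (Kp_liver · V_liver)`). A fraction `F_NAPA` of
the moles eliminated from PA appears in NAPA's liver compartment; the rest
goes to an explicit sink state, so total moles are conserved and auditable.

## Semi-mechanistic kidney

The kidney comprises glomerular blood (GLM), renal blood (RBL), proximal
tubule cells (PTC) and six luminal segments (S1 in three subsegments,
S2/S3, loop of Henle, distal tubule + collecting duct) whose filtrate flows
are fixed decreasing fractions of GFR {1.00, 0.85, 0.70, 0.55, 0.33, 0.18},
with urine flow 0.02·GFR. Because the luminal segment volumes are
numerically the fractions × GFR, water reabsorption concentrates solute in
place: solute leaves segment *i* at (downstream flow) × (segment-*i*
concentration).

Processes:

* filtration `fup·GFR/R` from arterial blood into the first segment (taken
  out of the glomerular inflow balance);
* basolateral exchange RBL ⇌ PTC at `PS_in` (uptake, inhibitable) and
  `PS_out` (passive efflux) on unbound concentrations;
* apical secretion PTC → proximal lumen at `CLu,int,r` (inhibitable) on the
  unbound cell concentration, distributed over the four proximal segments
  in proportion to volume (configurable to first-segment-only);
* luminal reabsorption from the proximal segments back into the cells at
  `CL_rabs`, volume-weighted (configurable likewise);
* distal outflow into a cumulative urine state.

Cumulative filtered and secreted counters are carried as extra states so a
realized reabsorbed fraction can be reported.

## Perpetrator model and inhibition

Cimetidine uses a fitted central + two-peripheral minimal model with
non-renal clearance from the central compartment, and the same kidney
submodel attached by routing renal blood flow out of and back into the
central compartment.

Competitive inhibition scales only the active part of uptake above the
passive floor,

    PS_in(t) = PS_out + (PS_in,0 − PS_out) / (1 + Cu/Ki_OCT2),

with `Cu` the unbound renal-blood cimetidine concentration (configurable to
unbound plasma), and the secretory clearance

    CLu,int,r(t) = CLu,int,r,0 / (1 + Cu,cell/Ki_MATE1),

with `Cu,cell` the unbound proximal-cell concentration. An optional
metabolic-inhibition term (IC50 on the parent's hepatic intrinsic
clearance) is implemented but off by default.

## Numerics

All balances are linear in amounts (nmol; with volumes in mL,
concentrations are numerically µM). Control arms are linear
time-invariant and propagated exactly with the matrix exponential
(augmented-matrix affine step for infusions). Co-dosing arms solve the
perpetrator first (it is unaffected by the victims) with a dense-output
stiff solver, then integrate the victims as a linear time-varying system
(LSODA, rtol 1e-8 / atol 1e-10; a fixed-step classical Runge–Kutta
integrator is available as a cross-check). Mass balance holds to ~1e-13
relative on the exact path and better than 1e-6 on the adaptive path.

The immediate post-bolus distribution phase is fast (venous→lung→arterial
time constants well under a minute); NCA run on simulated output must
sample that phase densely or AUC is underestimated by ~20% and the
clearances correspondingly inflated. The pipeline's simulation grid
therefore includes sub-minute geometric spacing from 0.02 to 1 min.

## Parameter derivation

Closed-form chain, each step unit-preserving and validated:

* extraction ratio `ER = CL/(Q·R)`; steady-state partition correction
  `Kp = Kp,ss/(1−ER)`;
* well-stirred forward `CL = Q·R·fup·CLu,int/(Q·R + fup·CLu,int)` and its
  retrograde inverse (hepatic and renal forms);
* filtration clearance `fup·GFR/R`; secretion by filtration subtraction
  `CL·fe − fup·GFR/R` (negative results rejected as a net-reabsorption
  regime);
* passive-partition chain `Kp,pass = fup/fu,tissue`, `Kp,uu = Kp/Kp,pass`,
  `PS_in = Kp,uu·PS_out`;
* `PS_out` from PAMPA permeability × effective tubule surface area × mass
  (the surface constant is back-solved from PA's permeability/PS_out pair
  and cross-checked against cimetidine's within 0.05%), or from an
  empty-vector cell-uptake rate;
* metabolite formation clearance from the metabolite/parent AUC ratio ×
  the metabolite's disposition clearance, and its in-vitro scale-up from an
  S9 formation rate at sub-Km substrate concentration.

Tissue partition coefficients without a measured steady-state ratio
(adipose, bone, gut, muscle, skin) are predicted with a Rodgers–Rowland
moderate-base scheme whose acidic-phospholipid association constant is
calibrated from red-blood-cell partitioning implied by the blood-to-plasma
ratio.

## NCA and endpoints

AUC/AUMC by linear-up/log-down trapezoid; terminal slope by best
adjusted-R² log-linear regression over trailing windows of ≥3 points
excluding Cmax; `CL = dose/AUC_inf`, `MRT = AUMC_inf/AUC_inf`,
`Vss = CL·MRT` (iv bolus); renal clearance as 0–24 h urinary recovery over
`AUC_inf`, per animal, with summary statistics over animals. Doses are
interpreted as the salt form by default (PA·HCl 271.79 vs base 235.33
g/mol) and converted to base-equivalents internally; clearances are
reported against the base-equivalent dose, consistent with base-equivalent
concentrations.

Interaction endpoints: AUC, CL_R and urinary-recovery ratios
(with-perpetrator over control); prediction accuracy via the absolute
average fold error `AAFE = 10^(mean |log10(pred/obs)|)`; sensitivity by
sweeping each Ki over half-decade multipliers 1e-2…1e2.

## Estimation

`CLu,int,r` is estimated per compound by least squares on pooled
log-plasma-concentrations plus log interval-urine amounts, parent first,
then the metabolite with the parent's estimate plugged in (the coupling is
one-way). The perpetrator's distribution parameters are fitted on
log-concentrations with non-renal clearance and the kidney fixed, in one-,
two- and three-compartment variants ranked by `AIC = n·ln(SSR/n) + 2p`.
All parameters are estimated on the log scale; CV% are asymptotic from the
Jacobian. IC50 fitting uses `v = vmax/(1 + I/IC50)` with IC50 on the
log10 scale and a Wald 95% interval transformed back.

## Synthetic data

The shipped design mirrors a typical rat study: ten plasma samples (1–480
min) and five contiguous urine intervals covering 0–24 h, n = 4.
Measurement noise is multiplicative log-normal with
`sigma = sqrt(ln(1+CV²))`, so the nominal CV matches the sampled CV and
the noise is median-unbiased; generation is fully seeded and reproducible.
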