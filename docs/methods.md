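# Methods

This note documents the models behind `specbind`, the conventions and
numerical choices, and what the synthetic-data generators do and do not
emulate.

## Scope and conventions

The package analyses four kinds of spectroscopic measurements of
small-molecule binding to a soluble protein (the motivating system is a
platinum anticancer complex binding bovine serum albumin, BSA):

1. UV–Vis titrations (ligand concentration vs. absorbance at a fixed
   wavelength) — association constant, half-saturation concentration,
   two-temperature thermodynamics;
2. the derived binding isotherm in (ν, [L]_free) coordinates — binding
   capacity, Hill and Scatchard cooperativity analysis, per-site Gibbs
   energy;
3. thermal melting traces — two-state midpoint T_m and the
   stabilization shift on drug binding;
4. time courses and fluorescence-quenching titrations — kinetic order
   selection and Stern–Volmer/double-log analysis.

Internally every concentration is molar, every temperature kelvin, Gibbs
energies and enthalpies kJ·mol⁻¹, entropies J·mol⁻¹·K⁻¹; Celsius appears
only in file readers/writers. The gas constant is fixed at
R = 8.314 J·mol⁻¹·K⁻¹. One unit convention end to end avoids the
kJ-vs-J and °C-vs-K slips that plague this literature.

## Binding model and mass balance

All equilibrium analysis rests on one set of `g` identical sites with an
empirical Hill exponent:

    ν(L_f) = g·K_H·L_f^n_H / (1 + K_H·L_f^n_H),

ν being moles of bound ligand per mole of total protein. Totals and free
concentrations are linked by L_t = L_f + ν·P_t. This conservation law is
solved by bisection on [0, L_t]: the residual is strictly monotone, so the
bracket is guaranteed, and the iteration runs until the bracket contains no
interior floating-point number. That costs at most ~10² residual
evaluations and keeps the conservation error at machine level even in the
near-total-depletion regime, where the residual's slope is enormous and
off-the-shelf tolerance-based stopping rules return residuals orders of
magnitude above the 10⁻¹² relative target. Multi-set or non-identical-site
partition functions are out of scope.

## Double-reciprocal isotherm analysis

K_b comes from the classical double-reciprocal (Benesi–Hildebrand)
linearization: 1/(A−A₀) regressed on 1/[L], K_b = intercept/slope,
A_∞ = A₀ + 1/intercept. Choices:

- **A₀** is taken from the zero-ligand point when the series has one,
  otherwise it must be supplied.
- **Unweighted OLS** is used, matching how these plots are conventionally
  read; a direct nonlinear fit of the hyperbola (`hyperbola_fit`) is
  provided as a cross-check and agrees with the linearization on noiseless
  data. Under noise the two can differ; the linearized value is the
  primary output.
- **Reciprocal blow-up guard:** points with |A−A₀| below 3× a
  user-supplied noise floor are excluded before transforming, since
  1/(A−A₀) has unbounded noise amplification near A₀.
- **Sign checks:** an intercept on the wrong side of zero for the observed
  signal direction, or a non-positive K_b, raises an error naming the
  offending estimate — this is what non-saturating data look like after
  the transform.

Two properties of the estimator matter for interpretation and are verified
by the test suite rather than assumed. First, it regresses on *total*
ligand, so it is consistent only when depletion (ν·P_t/L_t) is small; the
round-trip tests check recovery to 0.1% only in the <1% depletion regime.
Second, K_b is identifiable in practice only when the titration brackets
the half-saturation point: the noisy-recovery test therefore titrates over
fractional saturation ≈ 0.3–0.9 (63 μM–1.33 mM for K_b ≈ 6.8×10³ M⁻¹),
where the median estimate over 50 noisy replicates lands within a few
percent of truth. At the default 4–40 μM design (maximum saturation ≈ 21%)
the estimator is unusable under realistic noise — a statement about the
measurement design, not the code.

L_1/2 (total ligand at half-saturation) is read off the saturation profile
by piecewise-linear interpolation; non-monotone profiles beyond a 2%
tolerance are smoothed by isotonic regression first (with a warning), and
profiles that do not span α = 0.5 are extrapolated from the end segment and
flagged.

## Thermodynamics

ΔG° = −RT ln K_b; the two-point van't Hoff enthalpy is computed as
(ΔG°₁/T₁ − ΔG°₂/T₂)/(1/T₁ − 1/T₂), algebraically identical to
R·ln(K₂/K₁)/(1/T₁ − 1/T₂) (the equivalence is a property test);
ΔS° = (ΔH° − ΔG°)/T. The chained table therefore satisfies
ΔG = ΔH − TΔS identically at both temperatures, and `ThermoResult`
enforces that cycle to 0.1 kJ·mol⁻¹ whenever all three values are set.
The driving-force call uses the standard sign rules (ΔH<0 ∧ ΔS<0 →
van der Waals / hydrogen bonding; both positive → hydrophobic; ΔH<0 ∧
ΔS>0 → electrostatic), with zeros and the remaining quadrant reported as
mixed — the rules are qualitative and no thresholds beyond the strict
signs are imposed.

## Cooperativity

- **Binding capacity** θ = n_H·ν(g−ν)/(gRT) and its exact linearization
  RTθ/ν = n_H − (n_H/g)ν; the regression of RTθ/ν on ν returns n_H
  (intercept) and g (−intercept/slope), and a straight plot (R² ≥ 0.95 by
  default) is the operational evidence for a single set of sites.
- **Hill fit:** ln(ν/(g−ν)) on ln L_f; slope n_H, intercept ln K_H.
  Points with ν/g outside [0.05, 0.95] are excluded by default because the
  logit transform gives them unbounded leverage. |n_H−1| ≤ 0.05 is
  called non-cooperative (the tie band is a package choice; the underlying
  criterion is only the comparison with 1).
- **Scatchard:** the ν/L_f-vs-ν curve is classified algorithmically
  (the traditional reading is visual): a quadratic is fitted in ν and the
  curvature term's contribution over the ν span compared with the curve's
  range. Below 2% it is a straight line → non-cooperative (the classical
  single-site identity ν/L_f = K(g−ν)); concave-down with a rising onset →
  positive; otherwise (convex, falling throughout) → negative. The
  classification agrees with sign(n_H−1) on forward-model data for
  n_H ∈ {0.5, 1, 1.5, 2, 3} (tested).
- **Per-site Gibbs energy** ΔG°(ν) = −RT·n_H·ln K_H + RT(1−n_H)·ln L_f is
  analytic, not fitted; its slope against ln L_f is exactly RT(1−n_H), in
  J·mol⁻¹ per ln-unit (note the unit: this one quantity is conventionally
  quoted in J, not kJ), so a negative slope corroborates positive
  cooperativity.

## Thermal melts

A(T) = A_pre + (A_post−A_pre)/(1+exp((T_m−T)/w)), i.e. two-state with flat
baselines and width w (K). Fitting is nonlinear least squares with T_m
bounded inside the scanned window and w ∈ (10⁻³, span]. The sigmoid must
beat a straight line by AIC (4 vs 2 parameters), otherwise a
"no transition in range" error is raised — the behaviour wanted for scans
truncated before the unfolding step. A model-free midpoint (smoothed
signal crossing the baseline midline) is returned alongside; on synthetic
data the two agree within w/2 up to 2% amplitude noise. ΔT_m =
T_m(bound) − T_m(free), positive labelled stabilizing. Heating rate is
carried as provenance only. Unfolding enthalpy from transition sharpness
and multi-transition deconvolution are out of scope.

## Kinetics

First order, ln|A_∞−A| = −a·k·t + const, and second order,
1/|A_∞−A| = a·k·t + 1/|A_∞−A₀|, are fitted on the same admissible points
(those strictly on the A₀ side of A_∞; overshoots are excluded with a
warning) so their R² values are directly comparable; the straighter
transform wins, with ΔR² < 10⁻³ flagged indeterminate. The stoichiometric
factor a defaults to 1 and the composite a·k is reported as-is. A_∞
defaults to the mean of the trailing 5% of the trace when not supplied.
The second-order transform used here is the standard integrated law for a
signal approaching equilibrium; it reproduces the "linear in t"
diagnostic that order selection rests on. At 1% amplitude noise on the
default 61-point, 1-h design, selection accuracy over 100 seeded traces is
100% for both ground truths (the test requires ≥ 95%).

## Fluorescence quenching

F₀/F = 1 + K_sv[Q] with K_sv = k_q·τ₀ (τ₀ default 10⁻⁸ s). Because
combined static+dynamic quenching curves the plot upward, the fit is
restricted to the longest low-concentration prefix keeping R² ≥ 0.99
(minimum 3 points); restricting, or an intercept further than 0.1 from 1,
raises a curvature warning. k_q strictly above the diffusion-controlled
limit 2×10¹⁰ M⁻¹·s⁻¹ is classified static, at or below dynamic. The
double-log fit regresses log₁₀((F₀−F)/F) on log₁₀[Q] (base 10 by
convention); intercept = log₁₀K_b, slope = the apparent site number n.
[Q] is the total quencher concentration, with no free-ligand or
inner-filter correction.

## Synthetic data

Generators share a `ScenarioConfig` (seed, design, truth, grid, noise,
endpoints); a single integer seed feeds one `numpy` PRNG stream per
scenario, so identical configs reproduce byte-identically, and every
generator serializes its ground truth next to the data. Default designs:
10 titrant points over 4–40 μM at 15 μM protein and 300 K with
K_b = 6778 M⁻¹; quencher 0–210 μM; melt 25–65 °C in 1 °C steps with
midpoint 47 °C and width 2 °C; kinetics 61 points over 1 h. Default noise
is 0.5% multiplicative for absorbance and additive σ = 1% of F₀ for
fluorescence (chosen as typical bench-spectrophotometer performance; the
underlying reports rarely state noise levels).

What the generators deliberately do **not** emulate: instrument drift,
stray light, inner-filter effects, temperature-dependent baselines,
aggregation, or multi-set binding. Passing round-trip tests therefore
demonstrates that the estimators invert their own forward models at
realistic noise — a necessary condition — not that real albumin titrations
are free of the systematic effects above.

## Known limitations

- The double-reciprocal estimator inherits all the classical pathologies
  of reciprocal linearizations (noise amplification near A₀, depletion
  bias); the low-depletion, transition-bracketing regime documented above
  is where its quantitative claims hold.
- g, n_H and K_H are strongly correlated on narrow titration windows;
  the capacity diagnostic's g estimate is a slope/intercept ratio and is
  noise-sensitive.
- The static/dynamic verdict from k_q alone is a single-criterion
  heuristic; temperature-dependence corroboration requires series at two
  temperatures and is reported only as a secondary flag when available.
- Problem sizes throughout the test suite (50–100 seeded replicates,
  ≤ 61-point traces) were chosen as the smallest designs at which the
  medians and selection rates they assert are stable.
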