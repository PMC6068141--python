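# Methods

## Model

The package treats intracellular pH (pHi) as a global modulator of
enzymatic capacity inside an otherwise standard constraint-based metabolic
model: steady state `S·v = 0` with flux bounds `v_min ≤ v ≤ v_max`, biomass
flux as the proliferation proxy, and flux-variability analysis for
exchange readouts. The pH enters only through the bounds; kinetics,
metabolite concentrations, allostery and pH-dependent thermodynamics are
outside the model.

### Profiles

An enzyme's pH-activity curve is reduced to six critical points
(A0, A50, A100, B100, B50, B0) — the pH of 0/50/100% relative activity on
the acidic and basic flanks — and evaluated by linear interpolation
through (A0,0), (A50,50), (A100,100), (B100,100), (B50,50), (B0,0), with
zero activity outside [A0, B0]. This shape assumes a single-peaked
activity curve; genuinely bimodal enzymes and isoforms with divergent
optima are not represented.

Curation maps record activities into the three levels with closed-left
bins ([0,25] → 0, (25,75] → 50, (75,100] → 100; boundary records go to the
lower level, logged) and median-aggregates the pH values per critical
point. 100%-level records are split at the midpoint of their span and the
per-side medians become A100/B100; a one-sided or single record gives a
degenerate plateau. The per-side median (rather than min/max of the
records) keeps the plateau estimate unbiased when many noisy optimum
records exist. 0%/50%-level records are assigned to a flank by their
position relative to the plateau midpoint; with no optimum record the
median record pH is used as the split. Profiles violating the point
ordering are flagged, never silently re-sorted; imputed profiles that end
up violating it are dropped and reported.

Imputation order is homolog transfer first (median of the k = 5 closest
hits per missing point; k configurable; homology comes from a precomputed
search table, not from a search run here), then ordinary least squares per
target point on whatever other points are available (one cached OLS model
per target/feature-pattern, scikit-learn). Rank-deficient training designs
degrade gracefully to the least-norm fit (intercept-only for constant
training data) with a logged warning. The regressor interface is
deliberately pluggable since richer feature sets (taxonomy, EC class) are
natural extensions. Cross-validation supports seeded k-fold,
leave-species-out and leave-EC-class-out splits and reports per-point
Pearson r and RMSE.

### Constraints

At pHi p, gene weight `W_G = activity(p)/100`; enzymes without a profile
conservatively keep `W_G = 1` so absence of evidence never constrains.
Reaction weights fold the gene-association tree with AND → min (a complex
is as active as its weakest subunit) and OR → max (the best isozyme
carries the reaction). Bounds scale direction-aware so that `LB ≤ UB`
always holds: both bounds for zero-spanning reactions, only the upper for
forward reactions (clamped at `v_min`), only the lower for reverse ones
(clamped at `v_max`).

Organelles are treated as well buffered: only reactions touching a
cytosolic metabolite are rescaled (compartment code "c"). A gene's
reactions in several compartments are gated per reaction, not per leaf,
and transport reactions spanning cytosol and an organelle *are*
constrained (they touch the cytosol); their provenance flag in the state
output makes them easy to single out for sensitivity analysis. The
`cytosol_only=False` mode constrains every compartment for buffering
robustness checks. Knockout overrides (`W_G := 0–0.1`) bypass the
compartment gate — inhibiting a mitochondrial enzyme is not a pH effect.

### Simulation

Proliferation is the FBA optimum of the biomass reaction (GLPK,
single-threaded, feasibility tolerance 1e-9; infeasible grid points report
biomass 0 with a flag rather than raising, since acidic extremes
legitimately kill a model). Exchange readouts fix biomass at ≥ 80% of its
optimum (robust across 70–90%, which the tests exercise) and report FVA
extrema: most-negative flux for uptakes (oxygen, glucose), maximum for
secretions (lactate, ROS). "Total ATP" and "total NADPH" are the maximal
producing flux-sums — Σ over reactions of positive stoichiometric
coefficient × flux for the metabolite across compartments — the standard
flux-sum proxy, since "total production" is not otherwise well defined in
FBA. The anti-Warburg ratio is |oxygen uptake| / lactate secretion
(OCR over the ECAR proxy); zero lactate with positive OCR is reported as
+inf ("fully oxidative"), zero/zero as NaN. All reported rates below
|1e-7| are exact zeros. The default pHi grid is 6.5–8.5 in steps of 0.1.

### Screen

`nB = B_KO/B_WT` per cell and pH (a dead wild type gives nB = 1 if the KO
is equally dead, NaN otherwise, and NaN pairs propagate as missing).
SEL and PHS are mean differences (mean, not median, over pairs/cells);
recurrence is the fraction of strictly positive (> 1e-7) scores, with the
12.5% minimum — on a full 8×12 cell-line panel that is 12 of 96 pairs and 1
of 8 cells. Low and physiological pH default to 6.7 and 7.3; setting them
equal is allowed as a degenerate diagnostic (PHS ≡ 0). Anti-Warburg
re-evaluation of hits fixes biomass at the KO's own optimum fraction
(switchable in principle to the WT optimum; the KO optimum was chosen
because a KO'd cell cannot be held to the WT growth rate).

The divide-and-conquer modulator search bisects the profiled gene set in
model gene order, descending into any half that preserves ≥ θ = 0.8 of
the full constrained-vs-unconstrained biomass gap at low pH; when neither
half preserves it (redundant drivers, e.g. OR-paralogs), the current set
is greedily pruned one gene at a time instead, which returns redundant
pairs whole. θ and the bisection order are package choices; the search is
deterministic.

Robustness modes: *perturb* adds Gaussian shifts (σ pH units) to every
critical point, re-sorting any profile that loses its ordering (counted
and reported) so Monte-Carlo runs stay alive, and reports top-target
preservation and Spearman rank correlation of PHS against baseline;
*randomize* permutes the profile-to-gene assignment and compares the
biomass gap at a probe pH (default 7.8) between a reference
(pH-insensitive) database and the permuted engineered one, on the same
base model — a same-model comparison, because structurally different
models carry a gap no permutation can remove. All stochastic operations
take explicit seeds (default 0).

## Synthetic fixtures

The toy cell is a caricature of central carbon metabolism with round-number
stoichiometry chosen so every LP optimum is hand-checkable (and checked, in
the tests, against an exhaustive vertex-enumeration oracle): glucose
uptake (≤ 20) → one-gene glycolytic steps → a pyruvate-kinase-like
junction (2 pyruvate + 2 ATP per glucose) split into a major (capacity 12)
and minor isozyme — lactate export, a lumped pentose shunt (2 NADPH per
glucose), and a mitochondrial branch (pyruvate import capacity 1, lumped
respiration: 14 ATP + 1 ROS per pyruvate at 3 O2) feeding a biomass
reaction of 20 ATP + 2 NADPH. Fermentation therefore yields 2 ATP/glucose
against 30 via respiration, but respiration is capacity-limited, which is
what makes the optimum fermentative (Warburg-like) when glycolysis is
fully active.

The cancer-like profile database gives glycolytic genes an
alkaline-shifted plateau (A100–B100 ≈ 7.3–7.6) and the mitochondrial
pyruvate importer a neutral profile declining above 7.3, reproducing at
toy scale the engineered phenotype: biomass peaks at pHi ≥ 7.3, drops
below half its maximum at 6.7, glucose uptake rises and |OCR| falls at
alkaline pHi, and the OCR/ECAR ratio is an order of magnitude higher at
6.7 than at 7.4. The normal-like database is a broad plateau (6.5–7.9)
for every gene, hence pH-insensitive across the physiological range.
Inert gene-bearing "padding" reactions (default 24 in the robustness
fixture) emulate the majority of a genome-scale model that never limits
growth; without them, random profile reassignment merely relocates the pH
response instead of destroying it. The screen panel separates cancer from
normal members structurally — normal cells get an auxiliary oxidisable
substrate that bypasses glycolysis, mirroring their lower glycolytic
dependence — while sharing one profile database, as a real screen would.

What the fixtures do **not** emulate: realistic network size and
redundancy, expression-derived cell-specific bounds, medium composition,
cofactor/proton bookkeeping, or measured enzyme profiles. Passing fixture
tests therefore demonstrates correctness of the machinery and the
qualitative direction of the pH phenotypes, not quantitative agreement
with any real cell line. Quantitative fixture thresholds asserted in the
tests (e.g. the 0.5 biomass ratio, the 20% randomization collapse) are
reference-run values committed with their seeds — regression guards, not
biological claims.

The SNARF-1 calibration uses base-10 logarithms (Henderson–Hasselbalch
convention), with the measured MCF7 constants pKa = 7.30, R_min = 2.54,
R_max = 0.56 packaged as a default; the ratio argument must lie strictly
between the asymptotes.

## Numerical choices

- GLPK via optlang; deterministic single-thread configuration; solver
  tolerance 1e-9; reporting threshold |1e-7|.
- Boundary activity records (exactly 25% or 75%) bin to the lower level.
- Piecewise-linear interpolation takes the higher level on zero-width
  segments (degenerate plateaus).
- Homolog-transfer side assignment and imputation fill order
  (A100, B100, A50, B50, A0, B0) follow data abundance: optimum records
  dominate real databases.
- Test problem sizes (toy networks of 18–43 reactions, 50-enzyme profile
  databases, 100-permutation/50-seed Monte-Carlo runs) keep the full suite
  in seconds while leaving every property well above solver noise.

## Limitations

- Only bounds respond to pH; flux *costs* do not, so a half-active enzyme
  is modeled as half-capacity, not half-efficiency.
- Profiles are single-peaked and isoform-agnostic.
- The cytosol gate is binary; partial organelle buffering is not modeled.
- FVA extrema are used for readouts; a single FBA solution's fluxes (the
  other plausible convention) can differ in degenerate optima.
- The genome-scale screen (deposited MATLAB cell models plus a measured
  profile table) is supported through the MAT adapter but is an
  hours-long run and is not exercised by the test suite.
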