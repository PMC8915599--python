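# Methods

This note records the models implemented in `intrinsol`, the conventions
and defaults that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices a maintainer would want to know.

## Ionization models (`intrinsol.ionization`)

**Henderson–Hasselbalch solubility.** For a saturated solution of an
ionizable compound, the neutral-species concentration is pinned at the
intrinsic solubility S₀ and the charged species add on top:

* monoprotic base: `log S = log S₀ + log₁₀(10^(pKa−pH) + 1)`
* monoprotic acid: `log S = log S₀ + log₁₀(10^(pH−pKa) + 1)`
* ordinary ampholyte (one acidic + one basic group):
  `log S = log S₀ + log₁₀(10^(pKa,base−pH) + 10^(pH−pKa,acid) + 1)`

Consequences used as test invariants: `log S(pH) ≥ log S₀` everywhere;
three pH units into the uncharged region the curve is flat to < 10⁻³; at
pH = pKa the solubility is exactly doubled (log₁₀ 2). Anything beyond one
acidic plus one basic group raises `UnsupportedIonizationModel`: multiprotic
speciation, salt products, aggregation and CO₂ uptake are not modeled.
For a genuine zwitterion (basic pKa above the acidic one) no pH window is
fully uncharged and the curve minimum sits above log S₀; the "minimum
equals S₀" identity applies to ordinary ampholytes only.

**Pure-water saturation.** When the free acid/base equilibrates in
initially pure water, the final pH (pH_sat) solves the charge balance of
the saturated solution, e.g. for a base `[BH⁺] + [H⁺] = [OH⁻]` with
`[BH⁺] = S₀·10^(pKa−pH)`. The imbalance is strictly decreasing in pH, so
we bisect on pH ∈ [0, 14] (80 iterations, guaranteed bracketing) and apply
one Newton polish; the returned point satisfies |imbalance| < 10⁻¹² M or
the solver raises. Kw is fixed at 1.0×10⁻¹⁴ (25 °C) and activities are
ignored (I = 0) — ionic-strength and temperature corrections are data-
curation concerns outside this package. The inverse map (reported S_w →
S₀) is solved by bisection on log S₀, exploiting monotonicity of the
forward map; forward/inverse round-trip to better than 10⁻⁶ log units.

**Profile fitting.** With pKa fixed (never refined — an inaccurate pKa is
a data-quality problem, not a fitting degree of freedom), the HH model is
linear in log S₀, so the weighted least-squares estimate is the weighted
mean of `log S_i − log₁₀ F(pH_i)`; its standard error uses the weighted
residual scale on n−1 degrees of freedom (a single point inverts exactly,
SE undefined). Two diagnostics: if every point lies ≥ 3 pH units into the
fully ionized region the estimate is an extrapolation (warned, flagged);
if the weighted RMSE exceeds 0.3 log the profile shape is not HH
(aggregation/complexation suspected) and the fit is flagged rather than
modeled.

**Acid-base classes** follow the predominant charge at pH 7.4: acid(−) if
an acidic pKa < 7.4 and no basic pKa > 7.4, base(+) conversely,
zwitterion(±) both, neutral(0) otherwise. Permanently charged quaternary
ammonium compounds have no neutral form, hence no S₀ in the HH sense; they
bypass the ionization module and the four-class models entirely.

## Records and units (`intrinsol.records`)

The canonical internal scale is log₁₀ molar, converted once at ingestion.
Conventions: "1 in N parts of water" is read as 1 g solute per N mL
(documented, overridable per row); molality (mol/kg) is taken as molarity
with an `approximate_molality` flag (density 1.00 g/mL assumed) and such
rows are never silently mixed into reproducibility statistics; units with
no defined conversion (e.g. IU/mL) are rejected by name rather than
guessed. "Room temperature" or a missing temperature becomes 23 °C.
Parsing is total: every CSV row lands either in the parsed list or in a
rejects table with a reason.

Duplicate molecules filed under different names are reconciled on the
canonical SMILES of the parent structure (largest organic fragment, salts
stripped — salt forms are measurements of the same parent), with a
fingerprint pass (Morgan, Tanimoto = 1.0) catching representations that
canonicalize apart. Unparseable structures become singleton groups with a
warning.

## Descriptors (`intrinsol.descriptors`)

The 2D panel is whatever the installed RDKit exports (210 descriptors for
the pinned version; the count is recorded, not enforced), always including
logP, MR, the LabuteASA/SlogP_VSA/SMR_VSA/PEOE_VSA surface partitions,
BertzCT, Ipc, Chi indices, HallKierAlpha and atom/ring counts. The five
Abraham descriptors (A, B, S_π, E in (cm³/mol)/10, V in (cm³/mol)/100) are
ingested from CSV — their reference calculator is commercial software.
Melting points may be measured or predicted; a predicted T_m is used when
no measurement exists and carries a `tm_predicted` flag. Feature sets are
fixed per model family (`gse`: logP, T_m; `absolv`: A, B, S_π, E, V, A·B;
`absolv_qa`: A, B, S_π; `rfr_full`: everything); rows with missing
mandatory features are excluded and reported, never imputed.

## Linear models (`intrinsol.linear`)

All fits share one weighted-least-squares core: minimize
Σ wᵢ(yᵢ − xᵢβ)² with wᵢ = 1/max(sdᵢ, 0.05)². The 0.05 floor stops
near-zero reported SDs from dominating; rows without an SD get 0.17 log —
the interlaboratory average scatter, i.e. a typical measurement is trusted
at typical-lab precision. Standard errors come from the weighted normal
equations with the residual scale on n−p degrees of freedom (verified
against `statsmodels.WLS` in the tests). Rank deficiency is detected by
pivoted QR and reported with the names of the collinear columns.

The trained GSE uses the design `[1, logP, (T_m−25)⁺]`, so the classic
fixed model (0.5, −1.0, −0.01) is its exact special case; the melting term
is clamped to zero for liquids (T_m < 25 °C), the standard GSE convention.
The fit reports the intercept–T_m coefficient correlation, which is
strongly negative on druglike data (the two terms trade off). Class models
are independent fits per acid-base class (≥ 25 rows, else skipped) plus a
pooled fit — not a hierarchical model. The quaternary-ammonium ABSOLV form
(intercept + A + B + S_π) ships untrained and is fit on ingest; no
published coefficient set is bundled.

## Random forest (`intrinsol.forest`)

The regression tree and forest are implemented from scratch; scikit-learn's
forest is available only as an independent cross-check backend in tests.

* **Splitting.** At each node the best split minimizes
  RSS = Σ(yᵢ−⟨y⟩_L)² + Σ(yⱼ−⟨y⟩_R)² over midpoints between consecutive
  distinct values of each candidate feature, computed in one pass with
  prefix sums of y and y²; both children must keep ≥ nodesize rows. Ties
  are broken deterministically: lowest feature index, then lowest
  threshold (RSS compared with a 10⁻¹² absolute guard).
* **Stopping.** A node becomes a leaf when it holds < 2·nodesize rows or
  no candidate split reduces the node RSS; the leaf predicts the node
  mean. Defaults ntree = 500, mtry = ⌊p/3⌋, nodesize = 5 — the settings
  long established as near-optimal for QSPR forests (the benchmark
  harness uses smaller ntree for speed; accuracy saturates well before
  500 trees at these problem sizes).
* **Randomness.** A master `SeedSequence` spawns one independent stream
  per tree (bootstrap draw, per-node feature subsets, importance
  permutations), so enlarging ntree never reshuffles earlier trees and a
  fixed seed gives bit-identical forests.
* **OOB and importance.** Each row's OOB prediction averages the trees
  whose bootstrap missed it (rows never OOB are counted and reported).
  Importance is OOB *permutation* importance — mean increase in a tree's
  OOB MSE when one feature column is shuffled — chosen over impurity
  importance, which is biased toward many-valued features.
* **No extrapolation.** Leaf values are means of training responses, so
  every prediction lies inside [min y_train, max y_train] exactly. This is
  a real limitation for extremely insoluble outliers far from the training
  chemical space; the PCA nearest-neighbor diagnostic (below) exists to
  recognize such "missing neighbors" cases.

Trees persist as flat arrays in JSON with seed, parameters, feature list
and training response range. A proximity matrix is not computed by default
(O(n²) memory).

## Evaluation (`intrinsol.evaluation`)

Definitions, kept deliberately even where a different textbook convention
exists: r² = 1 − Σ(obs−calc)²/Σ(obs−⟨obs⟩)² (can be negative, never
clamped); RMSE = √(Σ(obs−calc)²/n); bias = mean(obs−calc);
F = (n−p−1)/p · Σ(obs−⟨obs⟩)²/Σ(obs−calc)² (None when n ≤ p+1); MPP =
percentage of |residual| ≤ 0.5 log, boundary inclusive.

**Interlaboratory reproducibility.** Per-molecule scatter uses the
*population* (1/n) SD — so two reports {−3.0, −3.4} give 0.200, not the
sample-SD 0.283 — and SD_avg is the unweighted mean over molecules with
≥ 2 sources (weighting by replicate count is a defensible alternative; the
unweighted mean is what the headline 0.17-log figure uses). Because the
population SD of a handful of draws is biased low (for 3 draws its
expectation is ≈ 0.72 σ), the report also carries `sd_avg_corrected`,
which divides each per-molecule SD by c₄(n)·√((n−1)/n) before averaging —
an unbiased estimate of the underlying lab-to-lab σ. A trend table bins
SD against mean log S₀ (scatter grows as solubility falls).

**Protocol.** Train/test splitting is 70/30, stratified by acid-base class
by default (per-class fractions within one molecule; singleton classes go
to train with a warning), seed recorded. PCA standardizes columns to mean
0 and *population* variance 1 (matching the SD convention), solves the
covariance eigenproblem directly, drops zero-variance columns with a
warning and fixes signs by making the largest-|loading| element of each
component positive. Nearest neighbors use Euclidean distance in the first
`ncomp` score dimensions and report the neighbors' response variance — a
high spread flags regions where a local average is unreliable.

**Benchmark.** `run_benchmark` splits once, fits each requested model on
the training rows, and reports per-model × per-class rows (n, r², RMSE,
bias, F, MPP), with train and OOB rows and top importances for the forest.
Quaternary rows are excluded from the four-class models and routed to the
reduced ABSOLV form. A model failure marks its rows failed and the run
continues. The table is bit-reproducible under a fixed master seed.

## Synthetic data (`intrinsol.synthetic`)

The generator emulates the *statistics* of a large curated intrinsic-
solubility database, not its chemistry:

* Abraham descriptors from a correlated multivariate normal (E, S_π, A, B,
  V positively inter-correlated as in real solutes), clipped to their
  physical ranges; acids/zwitterions get extra H-bond acidity, bases extra
  basicity.
* logP derived from the Abraham block through a solvation-style linear
  relation plus residual noise, recentered to mean 1.89 (≈ 78% of draws in
  [0, 5]); MW ≈ 55 + 125·V (mean ≈ 280 g/mol, ~99% < 500); T_m normal
  (150, 50²) clipped to [40, 300] °C with 19% flagged predicted; H-bond
  donor/acceptor counts Poisson-linked to A and B.
* Class mix defaults to acid 0.225 / base 0.30 / neutral 0.3765 /
  zwitterion 0.095 / quaternary 0.0035, mirroring the published four-class
  composition; class-typical pKas are uniform draws (acidic 2.5–6.5, basic
  8–11). Per-class solubility offsets are not applied (no published
  per-class moments to target).
* Truth families: `gse` (the classic equation, exactly); `absolv_linear`
  (solvation-equation coefficients rescaled so the deterministic part hits
  mean −3.0 and SD √(1.9² − noise²), effective coefficients stored);
  `nonlinear` (the linear core plus a saturating tanh(logP)·tanh(V)
  interaction carrying 28% of the variance, residualized against the
  ABSOLV design so no linear recombination of descriptors can absorb it —
  the forest's advantage in the benchmark is structural, not tuned).
* Observation noise N(0, 0.17) by default; multi-lab replicates add
  N(0, interlab_sd) per lab with distinct source tags; profiles are exact
  HH curves plus noise.

Sampled log S₀ is deliberately *not* truncated to the curated-data span
[−12, +2]: clipping the Gaussian tail would bias coefficient recovery.
The tail mass beyond the span is < 1%.

What passing tests on this data do **not** show: robustness to real
assay pathologies (aggregation, polymorph ambiguity, mixed salt/free-base
reporting), to descriptor error (computed logP off by 1–2 log for extreme
molecules), or to the uneven chemical-space coverage of real databases.
The generator's SMILES are placeholder tokens; structure-derived
descriptor code is exercised on a small fixture of real molecules in the
tests instead.

## Problem sizes and defaults used in checks

The shipped checks run the benchmark at 1 500 molecules / 150 trees,
parameter recovery at n = 2 000, the interlab statistic at 500 molecules ×
3 labs, and forest property checks at n = 1 000 / 200 trees — sizes at
which every statistic is stable (estimator SEs an order of magnitude
inside the asserted bands) while the whole suite stays fast.

## Known limitations

* No temperature normalization (values are recorded at their reported
  temperature; mixing 10–50 °C data degrades reproducibility statistics).
* Ampholyte support stops at one acidic + one basic group.
* The molality→molarity density-1 approximation is flagged but crude for
  concentrated solutions.
* The quaternary-ammonium model is a 3-descriptor stopgap fit on ingest.
* Forest predictions cannot leave the training response range (by
  design); use the nearest-neighbor diagnostic before trusting
  predictions at the edge of chemical space.
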