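# intrinsol

Curation and prediction of **intrinsic aqueous solubility** (log S₀) of
ionizable druglike molecules.

Equilibrium solubility reported in the literature is heterogeneous: values
come as "water solubility" S_w (the compound itself sets the final pH),
buffered solubility S_pH, or full log S–pH profiles, in a zoo of units
(mol/L, µg/mL, %w/v, "1 in 15 parts of water", …). For an ionizable
compound these numbers are not comparable until they are reduced to the
intrinsic solubility S₀ — the solubility of the *uncharged* form — via the
Henderson–Hasselbalch (HH) relation, e.g. for a monoprotic base

    log S(pH) = log S₀ + log₁₀(10^(pKa − pH) + 1)

`intrinsol` implements that curation step (unit normalization, duplicate
reconciliation, the pure-water saturation solver that links S_w, pH_sat and
S₀ through the charge balance, and weighted profile fitting), and then
trains and benchmarks three predictors of log S₀:

* **GSE** — the General Solubility Equation
  `log S₀ = 0.5 − log P − 0.01 (T_m − 25)`, fixed or retrained by weighted
  MLR;
* **ABSOLV** — weighted multiple linear regression on the Abraham solvation
  descriptors `c₀ + c₁A + c₂B + c₃S_π + c₄E + c₅V + c₆A·B` (plus a reduced
  3-descriptor form for permanently charged quaternary ammonium salts);
* **RFR** — a from-scratch Random Forest regression (RSS node splitting,
  bootstrap, random descriptor subsets, OOB validation, permutation
  importance) over the RDKit 2D panel + T_m + Abraham descriptors.

Evaluation uses the statistics standard in this literature: r², RMSE, bias,
F, and MPP (fraction of |residual| ≤ 0.5 log), per acid-base class
(acids/bases/neutrals/zwitterions at pH 7.4), plus the interlaboratory
reproducibility SD_avg of replicated molecules, PCA chemical-space maps and
nearest-neighbor diagnostics.

Because large curated solubility databases are not redistributable, the
package ships a synthetic-data generator (`intrinsol.synthetic`) that
reproduces their published statistical structure (log S₀ ≈ N(−3.0, 1.9²),
mean log P 1.89, four acid-base classes, interlab scatter 0.17 log,
HH-shaped profiles) with the generating truth stored for recovery tests.

## Worked example

```python
from intrinsol import (GeneratorSpec, generate_dataset, run_benchmark,
                       solve_saturation_pure_water, invert_saturation)
from intrinsol.records import PKa

# a weak base (pKa 9.0) with intrinsic solubility log S0 = -5 equilibrated
# in pure water: the dissolved base raises the pH to its pH_sat and the
# measured "water solubility" is twice S0
ph_sat, log_sw = solve_saturation_pure_water(-5.0, [PKa(9.0, "base")])
print(f"pH_sat = {ph_sat:.2f}, log S_w = {log_sw:.3f}")
# -> pH_sat = 9.00, log S_w = -4.699

log_s0, _ = invert_saturation(log_sw, [PKa(9.0, "base")])
print(f"recovered log S0 = {log_s0:.3f}")   # -> -5.000

# benchmark the three predictors on synthetic data whose truth contains a
# smooth logP*V interaction no linear model can absorb
ds = generate_dataset(GeneratorSpec(n_molecules=1500, seed=7, truth="nonlinear"))
data = ds.intrinsic.merge(ds.descriptors, on="molecule_id")
res = run_benchmark(data, seed=7, ntree=150)
t = res["table"]
print(t[t.scope == "all"][["model", "split", "n", "r2", "rmse", "mpp"]]
      .round(3).to_string(index=False))
```

prints

```
      model split    n    r2  rmse    mpp
  gse_fixed train 1047 0.322 1.507 30.564
  gse_fixed  test  449 0.447 1.526 26.949
gse_trained  test  449 0.550 1.377 29.176
     absolv  test  449 0.720 1.086 29.621
        rfr train 1047 0.977 0.275 93.123
        rfr   oob 1047 0.934 0.471 76.886
        rfr  test  449 0.945 0.481 75.501
```

Reading the table: the untrained GSE is the weakest (internal-test RMSE
1.53 log); retraining its three coefficients helps a little (1.38); the
ABSOLV weighted MLR captures the linear solvation structure (1.09); the
random forest also learns the nonlinear interaction and wins (0.48). The
forest's training-set RMSE (0.28) is much tighter than its out-of-bag
error (0.47) — the OOB/internal-test numbers, not the training fit,
measure predictive power. MPP is the percentage of predictions within
0.5 log of the observation.

A command-line surface wraps the same functions:

```
intrinsol simulate --n 1000 --seed 0 --out-dir fixtures/
intrinsol curate --measurements measurements.csv --out intrinsic.csv --rejects rejects.csv
intrinsol train --model absolv --features descriptors.csv --intrinsic intrinsic.csv --out model.json
intrinsol benchmark --data merged.csv --seed 17 --out table.csv
```

## Scope notes

Temperature normalization to 25 °C, ionic-strength pKa corrections,
multiprotic speciation beyond ordinary ampholytes, salt/aggregate/micelle
equilibria and the computation of Abraham descriptors from structure (a
commercial calculator) are out of scope; Abraham descriptors are ingested
from CSV. See `docs/methods.md` for models, conventions and limitations.
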