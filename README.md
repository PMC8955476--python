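# qsarmlr

2D-QSAR model building with ordinary-least-squares multiple linear
regression: genetic-algorithm descriptor selection, a full internal/external
validation battery, and a leverage-based applicability domain.

## What this is for

Quantitative structure–activity relationship (QSAR) modelling links numeric
molecular descriptors (here PaDEL-style 2D descriptors such as AATS7s,
MATS2c, SpMin3_Bhi, MDEC-33) to a biological activity, expressed as
pIC50 = −log10(IC50 in mol/L). The workflow implemented here is the standard
chemometric pipeline used by tools like QSARINS:

1. **Data setup** — load a delimited descriptor table; drop all-zero,
   missing-valued and near-constant descriptors; remove one member of every
   descriptor pair with |Pearson r| > 0.85; split compounds into training
   and prediction sets (default 5:1).
2. **Model building** — OLS regression `y = β₀ + Σ βⱼ xⱼ + ε` on a descriptor
   subset chosen by a genetic algorithm whose fitness is Friedman's
   lack-of-fit, `LOF = (RSS/n) / (1 − (c + d·p)/n)²`, an RSS penalised for
   model size.
3. **Validation** — internal: Q²LOO (leave-one-out via the deleted-residual
   shortcut `eᵢ/(1−hᵢᵢ)`), Q²LMO (leave-many-out, 30% out, 2000 iterations),
   and Y-scrambling (2000 response permutations; the chance-correlation
   baseline, analytically E[R²] = p/(n−1)); external: Q²F1, Q²F2, Q²F3,
   R²ext and Lin's concordance correlation coefficient (CCC).
4. **Applicability domain** — Williams-plot data: leverage
   `hᵢ = xᵢ(XᵀX)⁻¹xᵢᵀ` against standardized residuals, with warning
   leverage `h* = 3(p+1)/n` flagging structural outliers and |residual| > 3σ
   flagging response outliers; iterative outlier pruning.

The package also ships, as fixtures, a published reference study of a
26-compound uracil–coumarin series with MCF7 cell-line inhibitory activity:
the dataset table, the 12 designed pyrimidine–coumarin–triazole compounds,
and the four published model equations (model 2 being the reference "best"
model). A synthetic-data generator with known ground truth makes every
pipeline stage testable without external data.

## Worked example

```python
from qsarmlr import data, predict, fit_ols, q2_loo, y_scramble, warning_leverage

ds = data.load_table3()          # 26 compounds, 4 descriptors, observed pIC50
model2 = data.model_equation(2)  # pIC50 = 17.6885 − 0.0831·AATS7s − 3.6745·MATS2c
                                 #         − 8.2998·SpMin3_Bhi + 0.2438·MDEC-33

print(round(predict(model2, ds)[0], 4))        # 5.5645  (compound 1)
print(round(predict(model2, data.load_table5())[0], 4))  # 8.0071 (designed compound a)

_, stats = fit_ols(ds, data.DESCRIPTORS)
print(round(stats.R2, 4))                      # 0.9834  (refit on all 26 rows)
print(round(q2_loo(ds).Q2, 4))                 # 0.9749

train = ds.subset_by_ids(ds.ids[:20])
scr = y_scramble(train, data.DESCRIPTORS, iterations=2000, seed=1)
print(round(scr.R2_Yscr, 3))                   # 0.209  (null baseline, = p/(n−1))
print(warning_leverage(4, 20))                 # 0.75
```

A prediction of 8.0071 for designed compound *a* means the model expects an
IC50 near 10⁻⁸ M — far more potent than anything in the training series, so
the leverage/applicability-domain check matters before trusting it.

The same steps are available from the shell:

```sh
qsarmlr fit table.csv --activity-column pIC50 --subset AATS7s,MATS2c,SpMin3_Bhi,MDEC-33
qsarmlr validate model.json table.csv --activity-column pIC50 --seed 1
qsarmlr predict model.json new_compounds.csv --train-table table.csv
qsarmlr ad model.json table.csv --activity-column pIC50
qsarmlr simulate --n 26 --seed 1
qsarmlr reproduce-paper --seed 1
```

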