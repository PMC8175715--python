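# emtscreen

Screening for epithelium-expressed mediators of the epithelial–mesenchymal
transition (EMT) from bulk tumor expression data.

## The problem

EMT-induced carcinoma cells acquire a stromal-like expression program, so in
bulk tumor profiles their signature is indistinguishable from contamination by
actual stromal cells: most of the "mesenchymal" signal in a bulk colorectal
tumor sample originates from its stroma, not from transdifferentiated
epithelium. Genes that drive EMT from within the cancer epithelium therefore
cannot be found by differential expression on bulk data alone.

`emtscreen` implements a profiling strategy that triangulates three data
layers to find such genes:

1. **Stromal signature** — paired, micro-dissected tumor epithelium and
   stroma give a per-gene log fold change
   `L(x) = log2( expression in stroma / expression in epithelium )`.
2. **Mesenchymal score** — for a target gene *g*, compute its genome-wide
   co-expression profile in bulk tumors, `r_g(x)` = Pearson correlation of
   *g* with every other gene *x* across samples, and score it against the
   stromal signature:

   `MS(g) = corr_x( r_g(x), L(x) )`

   A high score means the bulk neighbourhood of *g* is stroma-flavoured —
   the co-expression fingerprint of EMT involvement.
3. **Prognosis** — a univariable Cox proportional-hazards fit per gene gives
   a Wald z-score (`z = beta / se`; positive = adverse).

Candidate EMT mediators are genes that look mesenchymal by co-expression but
are expressed in the epithelium and carry prognostic weight:

```
MS > 0.3   and   L < 0   and   z > 1.96      (all strict)
```

The package also provides the downstream validation statistics used around
such a screen: unsupervised hierarchical clustering of cell-line panels with
EMT-prone cluster labeling, Kaplan–Meier curves and log-rank tests,
mean/median dichotomization, likelihood-ratio (G-test) and Pearson chi-square
tests for clinical contingency tables, Mann–Whitney U, a table-one builder,
and a synthetic-data module that generates all inputs with known ground truth
(convex epithelium/stroma mixtures with Beta-distributed stromal fraction,
planted mediators, survival tied to EMT activity, an EMT-prone cell-line
subset, and a clinical table with a configurable marker–covariate odds
ratio).

## Worked example

```python
import emtscreen as es

cfg = es.SimConfig(seed=1)                      # 2000 genes, 200 bulk samples
bulk, truth = es.generate_cohort(cfg)
micro = es.generate_microdissection(cfg, truth) # 13 epithelium/stroma pairs
survival = es.generate_survival(cfg, truth)

model = es.EMTScreen(bulk, micro, survival)
results = model.fit()
print(results.summary())
rec = results.recovery(truth)
print(f"recovered planted mediators: sensitivity {rec.sensitivity:.2f}, "
      f"precision {rec.precision:.2f}")
```

prints

```
EMT mediator screen
===================
genes: 2000 (2000 scored), bulk samples: 200, microdissection pairs: 13
log-ratio aggregation: ratio_of_means, pseudocount: 1.0, Cox transform: raw
score-prognosis correlation: r = 0.821 (p = 0, n = 2000)
62 candidate genes of 2000 scored (MS > 0.3, log2 stroma:epithelium < 0.0, Cox z > 1.96; 0 genes lacked a metric)
top candidates:
         mesenchymal_score  log2_stroma_epi  cox_z
gene_id
G0997                0.744           -0.348  5.480
G0405                0.743           -0.673  6.673
...
recovered planted mediators: sensitivity 1.00, precision 0.97
```

Of 2000 genes the joint rule selects 62; the simulator planted 60 true
mediators, of which all 60 are recovered (two background genes slip in, hence
precision 0.97). The mesenchymal score correlates positively with the
prognostic z because the simulated hazard is coupled to EMT activity — the
screen's central premise.

The same pipeline is scriptable from the shell:

```bash
emtscreen simulate --out sim/ --seed 1
emtscreen logfc --epithelium sim/microdissection_epithelium.tsv \
                --stroma sim/microdissection_stroma.tsv --out L.tsv
emtscreen score --bulk sim/bulk_expression.tsv --logfc L.tsv --out scores.tsv
emtscreen coxz  --bulk sim/bulk_expression.tsv --survival sim/survival.tsv --out z.tsv
emtscreen select --scores scores.tsv --coxz z.tsv --out candidates.tsv
emtscreen clintest --table 52,15,19,14     # likelihood-ratio chi-square on a 2x2
```

## Layout

| Module | Contents |
|---|---|
| `emtscreen.model` | `EMTScreen` / `EMTScreenResults` — the fitted-screen front door |
| `emtscreen.score` | log-ratio `L`, correlation profiles, mesenchymal scores, gene-set comparison |
| `emtscreen.screen` | per-gene Cox z-table, joint candidate selection, recovery metrics |
| `emtscreen.survival` | Cox PH (Newton–Raphson, Efron ties), Kaplan–Meier, log-rank, dichotomization |
| `emtscreen.cluster` | hierarchical clustering of cell lines, EMT-prone cluster labeling, Newick export |
| `emtscreen.clinical` | G-test/Pearson chi-square, Mann–Whitney, table-one builder, inclusion audit |
| `emtscreen.simulate` | synthetic cohort generator with ground truth |
| `emtscreen.pipeline`, `emtscreen.cli` | end-to-end driver and `emtscreen` command |

See `docs/methods.md` for the generative model, parameter choices and known
limitations.
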