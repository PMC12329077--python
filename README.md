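# pclda

Interpretable cell-type annotation for single-cell RNA sequencing.

Given a **reference** cells × genes count matrix with per-cell type labels and
an unlabeled **query** matrix (possibly from a different sequencing platform),
`pclda` assigns a type to every query cell with a pipeline built from three
linear stages, so the final decision rule is a linear function of the original
genes and every gene's contribution to each call can be read off directly.
It is aimed at transcriptomics analysts who want a classifier whose behaviour
they can audit gene by gene, plus the ablation machinery to see what each
stage buys.

## The method

1. **Normalization and gene screening.** Counts are library-size normalized
   and log transformed, `x'_ij = log2(1 + 10^4 · x_ij / Σ_k x_ik)`. For every
   type *c* each gene gets a one-vs-rest Welch t-score
   `T_jc = (x̄_jc − x̄_j,rest) / sqrt(s²_jc/n_c + s²_j,rest/n_rest)`,
   and the union over types of the top-*k* genes by |T| (default k = 400 per
   type) forms the screened set G.

2. **Supervised PCA.** PCA is fitted on the **pooled** reference + query
   cells restricted to G (transductive: the components capture structure
   shared across platforms). Components are then ranked not by explained
   variance but by the between/within class-variance ratio of their
   reference scores, `R_k = Var_B(z_k) / Var_W(z_k)`, and the top *d*
   (default 200) are retained — the criterion mirrors the downstream
   classifier's objective, so class-separating directions win over merely
   high-variance ones.

3. **LDA classification.** A Fisher projection `W` (d × (C−1)) maximizing
   between- relative to within-class scatter is fitted on the reference
   scores; in the projected space each class gets a linear discriminant
   `δ_c(z) = w_c'z + b_c` with `w_c = Σ_W⁻¹μ_c` and
   `b_c = −½ μ_c'Σ_W⁻¹μ_c + log P(y=c)`. Cells take the argmax class;
   posteriors are the softmax of δ, and per-class confidence scores average
   the winning posteriors.

Because screening is a mask and PCA/LDA are linear, the pipeline collapses to
per-gene per-class coefficients `β_c = V_sel · W · w_c` — ranked gene lists
(default top 100 per type) come with signs (enriched vs depleted) and
magnitudes for free.

Ablation variants (`mode=`): `lda_only`, `screen_lda`, `pca_lda`, `topPC`
(variance-ranked PCs), `refPCA` (reference-only PCA), mirroring the design's
A/B comparisons. A synthetic generator with planted markers, library-size
variation, dropout and a reference/query platform shift makes everything
testable offline.

## Worked example

```python
import pclda

spec = pclda.SimulationSpec(n_types=4, cells_per_type=80, n_genes=1000,
                            markers_per_type=10, marker_effect=3.0,
                            batch_shift=1.3, seed=0)
data = pclda.simulate(spec)

model = pclda.PCLDA(data.ref, data.ref_labels, data.query,
                    k=200, d=50, m_max=150)
results = model.fit()
print(results.summary())
report = results.accuracy(data.query_labels, truth_cells=data.query.cell_ids)
print(f"query accuracy vs simulated truth: {report.accuracy:.3f}")
print(results.top_genes("type_0", n=5).to_string(index=False))
```

prints

```
PCLDA results
============================================================
mode            : full
reference cells : 320
query cells     : 320
shared genes    : 1000
screened genes  : 485 (k=200 per type)
PCA             : joint fit, 150 components, d=50 selected
classes         : 4
------------------------------------------------------------
class                    n predicted    confidence
type_0                            81        0.9975
type_1                            79        1.0000
type_2                            80        1.0000
type_3                            80        0.9987
query accuracy vs simulated truth: 0.997
   gene_id  class  coefficient  rank
gene_00448 type_0     1.022951     1
gene_00786 type_0     0.963539     2
gene_00109 type_0     0.920960     3
gene_00860 type_0     0.877684     4
gene_00695 type_0     0.852964     5
```

319 of the 320 query cells receive their true simulated type (accuracy
0.997); the confidence column is the mean winning posterior over the cells
assigned to each type. The top-coefficient genes for `type_0` are
planted markers of that type (e.g. `gene_00448`, `gene_00109`), with positive
signs marking enrichment in the type.

The same pipeline is available from the shell:

```sh
pclda simulate --seed 0 -o sim/
pclda annotate --ref sim/ref.tsv --ref-labels sim/ref_labels.tsv \
      --query sim/query.tsv -o predictions.tsv --confidence confidence.tsv
pclda weights --ref sim/ref.tsv --ref-labels sim/ref_labels.tsv \
      --query sim/query.tsv --top 100 -o weights.tsv
```

plus `cv`, `ablate`, `sweep`, `screen` and `pca` subcommands.

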