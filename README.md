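# phasecall

Calling cell-cycle phase-specific genes from bulk RNA-seq count matrices.

Cells synchronized into the five cell-cycle stages G1, G1/S, S, G2 and M
(two biological replicates each) yield a gene × sample count matrix. Many
genes — protein-coding and long noncoding alike — peak in one stage.
`phasecall` identifies them with a discrete, replicate-aware procedure:

1. **Quantifiable-expression gate** — keep genes with CPM ≥ 0.075 in at
   least two samples (CPM on raw library sizes).
2. **TMM normalization** — trimmed-mean-of-M-values scaling factors define
   effective library sizes.
3. **Exact differential tests between adjacent phases** — for each of the
   five circularly adjacent pairs (G1→G1/S, G1/S→S, S→G2, G2→M, M→G1),
   counts are equalized to a common library size, a common negative-binomial
   dispersion φ (variance = μ + φμ²) is estimated by conditional maximum
   likelihood, and each gene gets an exact conditional NB test p-value with
   Benjamini–Hochberg FDR per pair. DEGs: |fold change| ≥ 1.5 and FDR < 0.05.
4. **Phase-specific classification** — a gene is assigned to a phase iff
   (1) its phase-mean CPM is strictly highest there, and (2) it is
   significantly (FDR < 0.05) up ≥ 1.5-fold versus **both** circular
   neighbors of that phase. Calls are stratified by gene biotype
   (protein_coding / lncRNA / pseudogene / other).

Downstream helpers cover hypergeometric gene-set over-representation against
the quantifiable-gene universe, an anchor-gene Spearman screen (p < 0.01 at
5% FDR), median-split Kaplan–Meier survival with a log-rank test, and the
3C interaction frequency 2^(ΔCt_sample − ΔCt_control). A synthetic-data
module generates NB count matrices with planted phase-specific genes so
every stage is verifiable without external data.

## Worked example

```python
import phasecall as pc

cm, truth = pc.fixture_counts()      # packaged 30-gene, 10-sample fixture
result = pc.run_pipeline(cm)
print(result.assigned[["gene_id", "assigned_phase"]])
```

```
           gene_id assigned_phase
gene_id
PEAK_G1    PEAK_G1             G1
PEAK_G1S  PEAK_G1S           G1/S
PEAK_S      PEAK_S              S
PEAK_G2    PEAK_G2             G2
PEAK_M      PEAK_M              M
```

Exactly the five genes constructed with a single-phase expression peak are
assigned, one per phase; the two genes whose maximum is tied between two
phases, the all-zero gene, and the gene exceeding the CPM threshold in only
one sample are all rejected, while the gene sitting exactly on CPM 0.075 in
two samples passes the filter.

The same pipeline is available from the shell:

```bash
phasecall simulate --out-dir sim --seed 1
phasecall run --counts sim/counts.tsv --samples sim/samples.tsv \
              --biotypes sim/biotypes.tsv --out-dir results
```

which writes per-pair DE tables (`de_G1_vs_G1S.tsv`, …), `phase_calls.tsv`,
a phase × biotype `summary.tsv` and a `manifest.json`; reruns with the same
inputs and seed are byte-identical.

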