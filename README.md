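# xenopsc

Identification of circulating pancreatic stellate cells (cPSCs) and
circulating tumour cells (CTCs) in human-into-mouse xenograft single-cell
RNA-seq, together with the preclinical cohort statistics used to evaluate
adjuvant treatment in an orthotopic pancreatic cancer model.

In these experiments a mixture of luciferase-tagged human AsPC-1 pancreatic
cancer cells and human pancreatic stellate cells (PSCs) is implanted into
the mouse pancreas. Because the only human cells in the animal are the two
implanted types, any human cell recovered from blood must be either a CTC
or a circulating PSC. The package implements that logic as a reproducible
pipeline, and is aimed at computational biologists analysing mixed-species
(barnyard) single-cell experiments with rare circulating populations:

- **Species demultiplexing** — each barcode is called human or mouse from
  the relative UMI content of the combined GRCh38/GRCm38 reference
  (`fraction_human >= t_high` → human, `<= t_low` → mouse, else ambiguous),
  cross-validated with an independent classifier over orthologous gene
  pairs. Transgene UMIs belong to neither genome and are excluded.
- **Three-way rare-cell classification** against cultured reference cells
  (Cult): (1) k-NN vote in an anchor-integrated joint embedding,
  (2) community clustering with cluster labels inherited from Cult members,
  (3) integration-free 2-group clustering on a discriminative reference
  signature (top-N genes per cultured type by rank-sum screen). The
  consensus call requires unanimity among available labels with ≥ 2
  approaches reporting.
- **Transgene non-detection test** — Fisher's exact test of luciferase
  detection (≥ 1 UMI) in putative cPSCs versus cancer cells; the transgene
  is carried only by the implanted cancer line, so non-detection argues
  against a cancer identity of the putative cPSCs.
- **Principal-tree pseudotime** — a simplified reversed-graph-embedding fit
  (soft assignment + MST re-linkage) over PSCs from primary tumour, blood
  and metastasis; pseudotime is geodesic distance from the root leaf;
  pseudotime- and branch-(fate-)dependent expression is tested by
  quasi-Poisson natural-cubic-spline likelihood-ratio tests with
  Benjamini–Hochberg control.
- **Cohort statistics** for the 2×2 factorial treatment design
  (gemcitabine **G** × HGF/c-Met inhibition **HiCi**): rare-cell counts per
  LPF per 200 µL (`raw / n_lpf / (volume/200)`), Poisson regression with
  sandwich (HC0) standard errors, logistic regression of progressive
  disease, a random-intercept mixed model of log10 radiant flux over weeks,
  doubling times `7·log10(2)/slope`, and midrank ROC/AUC with a DeLong CI.
- **Synthetic data generator** with full ground truth (two human expression
  programs, transgene, mouse host cells, ambient contamination, doublets,
  treatment effects), so every stage is testable without downloads.

## Worked example

```bash
xenopsc simulate --seed 1 --outdir demo/data
xenopsc classify --indir demo/data \
    --reference-labels demo/data/cult_reference_labels.csv \
    --seed 0 --outdir demo/classify
xenopsc trajectory --indir demo/data --labels demo/classify/labels.csv \
    --seed 0 --outdir demo/traj
xenopsc stats --cohort demo/data/cohort.csv --flux demo/data/flux.csv \
    --outdir demo/stats
```

On the seed-1 synthetic experiment (blood compartment planted with 62 CTCs
and 16 cPSCs among mouse leucocytes) the classify step reports each
approach finding 16 cPSCs with a triple-intersection Venn count of 16, and
`transgene_test.json` contains

```json
{"table": [[0, 16], [94, 88]], "p_value": 2.175e-05}
```

i.e. none of the 16 consensus cPSCs expresses the luciferase transgene
while 94 of 182 cancer cells do — strong evidence the cPSCs are not tumour
cells. The trajectory step recovers a single branch point
(`"branch_vertices": [3]`), and `stats_report.json` reports tumour-burden
doubling times per arm

```json
{"Ctrl": 10.8, "G": 14.7, "HiCi": 18.2, "G+HiCi": 32.7}
```

(days; the generator's truth is 10.6/14.1/18.5 for the single-treatment
arms) and a CTC-count ROC for recurrence of AUC 0.79 (95% CI 0.66–0.92).

Everything is also available as a library:

```python
from xenopsc import SimConfig, generate_xenograft_samples
from xenopsc.classify import run_rarecell_pipeline

samples, truth = generate_xenograft_samples(SimConfig(seed=1))
ref = truth.set_index("barcode").loc[samples["Cult"].barcodes, "true_type"]
result = run_rarecell_pipeline(samples, ref, seed=0)
result["venn"]           # {'a1_a2_a3': 16, ...}
result["transgene_test"] # {'table': ..., 'p_value': ...}
```

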