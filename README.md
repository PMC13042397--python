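# dnbpipe

Tipping-stage detection and early-biomarker discovery for **staged,
two-compartment proteomics**.

Many diseases progress through ordered histological stages — for esophageal
squamous cell carcinoma (ESCC) the sequence esophagitis (ESO) → mild dysplasia
(MID) → moderate dysplasia (MOD) → severe dysplasia (SED) → carcinoma (ESCC) —
and a central question is *where along that axis the system tips* from a
relatively benign, reversible state into a malignant, irreversible one.
`dnbpipe` implements the computational chain used to answer that question from
a protein-intensity matrix measured in lesion (`L`) and adjacent non-lesion
(`N`) tissue at each stage:

1. **Preprocessing** — median normalization and log2 transform of DIA-style
   intensity matrices with missing values (never imputed).
2. **Dynamic network biomarker (DNB) analysis** — per stage, find the protein
   module maximizing the composite index

   `CI = SD_in · PCC_in / PCC_out`

   where `SD_in` is the mean within-stage standard deviation of the module,
   `PCC_in` the mean absolute Pearson correlation inside it, and `PCC_out`
   the mean absolute correlation to everything else. DNB theory predicts that
   just before a critical transition a small dominant group shows a joint
   variance + internal-correlation spike while decoupling from the rest of
   the network; the stage with maximal CI is called the **tipping stage**,
   which splits progression into a *pre* phase (up to and including the
   tipping stage) and a *post* phase.
3. **Trend clustering** — fuzzy c-means (fuzzifier `m > 1`, soft memberships)
   on per-stage mean trajectories, recovering rising / falling / peaked
   expression programs.
4. **Phase differential expression** — Welch's t or Wilcoxon rank-sum per
   protein (chosen by a Shapiro–Wilk normality gate), significance at
   `p < 0.05` with strict fold-change bounds `FC > 1.20` or `FC < 0.83`.
5. **EMT scoring** — per sample, mean mesenchymal minus mean epithelial
   signature expression, compared between phases.
6. **Biomarker panel** — linear-SVM recursive feature elimination (SVM-RFE)
   ranking with an honest cross-validated AUC-by-size curve (feature selection
   re-run inside every training fold), plus a multi-learner benchmark.
7. **Ligand–receptor crosstalk** — rank-product scoring of annotated pairs
   between the L and N compartments at a chosen stage.

Because cohorts of this kind are rarely public, the package ships a
first-class **synthetic-data generator** that emulates the study design
(5 stages × 2 compartments, group sizes 10/19/11/14/10 L and 8/17/8/10/5 N,
~2000 proteins, intensity-dependent missingness) with planted ground truth —
a DNB spike at a chosen stage, four trend templates, a discriminative panel,
and an EMT drift — so every stage of the pipeline is testable end to end.

## Worked example

```python
from dnbpipe import (DNBAnalysis, SyntheticConfig, build_stage_design,
                     filter_by_completeness, generate_staged_dataset,
                     median_normalize)

matrix, annotations, truth = generate_staged_dataset(SyntheticConfig(seed=1))
design = build_stage_design(annotations)
norm = filter_by_completeness(median_normalize(matrix), design, min_frac=0.5)
result = DNBAnalysis(norm, design, compartment="L").fit()
print(result.summary())
```

prints

```
DNB analysis, compartment L
  tipping stage: MID
  module size at tipping stage: 11

   stage         CI    SD_in   PCC_in  PCC_out  size
     ESO     1.6621   0.7401   0.7440   0.3313     5
     MID     2.4160   0.9185   0.6554   0.2492    11
     MOD     1.6373   0.6570   0.7876   0.3160     7
     SED     1.7833   0.7035   0.7735   0.3051     5
    ESCC     1.5335   0.7444   0.7251   0.3520     6
```

The CI curve peaks at MID — the stage where this cohort's module of 15
equicorrelated, variance-inflated proteins was planted — so MID is called the
tipping stage (9 of the 15 planted members are in the reported module). The
phase split is then pre = {ESO, MID}, post = {MOD, SED, ESCC}, and the
downstream steps (phase DE, EMT comparison, SVM-RFE panel) run on that
contrast.

The same analysis is available from the shell:

```bash
dnbpipe simulate --out cohort --seed 1
dnbpipe dnb --expression cohort/expression.tsv --annotation cohort/annotation.tsv
dnbpipe de  --expression cohort/expression.tsv --annotation cohort/annotation.tsv \
            --contrast "L:MOD+SED+ESCC vs L:ESO+MID"
dnbpipe run-all --config run.yaml      # the full chain from one YAML config
```

`run-all` writes per-stage TSV outputs and a deterministic `report.json`
(byte-identical across repeated runs of one config).

## Layout

```
src/dnbpipe/
  io.py          # matrices, stage designs, TSV I/O, normalization
  simulate.py    # synthetic staged cohorts with planted truth
  diffexp.py     # normality-gated DE, phase split, stage-specific proteins
  trend.py       # stage profiles + fuzzy c-means (FuzzyCMeans.fit())
  dnb.py         # composite index + tipping call (DNBAnalysis.fit())
  signatures.py  # GMT reading, EMT scoring, phase comparison
  panel.py       # AUC, learner benchmark, SVM-RFE (SVMRFEPanel.fit())
  crosstalk.py   # ligand-receptor rank-product scoring
  pipeline.py    # RunConfig + run_pipeline orchestration
  cli.py         # click CLI (`dnbpipe`)
```

The bundled `data/emt_illustrative.gmt` is a small, non-canonical
epithelial/mesenchymal marker set for demonstrations; supply your own curated
GMT for real analyses. See `docs/methods.md` for the model details, parameter
defaults and known limitations.
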