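# cafstate

Tools for quantifying **cancer-associated fibroblast (CAF) states** in
engineered-hydrogel and tumour data: 3D cell-shape analysis, gene-signature
enrichment scoring, an RT-qPCR composite state score, ligand-receptor
consensus aggregation, per-cell immunofluorescence statistics, and
survival stratification. Every stage can be exercised end to end on seeded
synthetic data with known ground truth.

## Who this is for

CAFs polarise into distinct states — **myCAFs** (myofibroblastic: ACTA2,
COL1A1, TAGLN) and **iCAFs** (inflammatory: IL6, IL24, CXCL8) among them —
and hydrogel culture conditions can push cells toward one state or the
other. Analysing such experiments requires a chain of bespoke
computations that are usually scattered across Fiji macros, R sessions and
notebooks. This package implements that chain as a tested Python library
with a CLI.

## What it computes

**3D morphometrics** (`cafstate.morph3d`). Cells in confocal z-stacks are
segmented (despeckle → smooth → binarize → fill holes → open → close →
despeckle, then seeded region growing to recover thin dendritic
protrusions), filtered by inclusion criteria (contains a nucleus, not cut
off by the volume edge), and measured. Two shape descriptors:

    sphericity = (π (6V)²)^(1/3) / SA        roundness = 6V / (π D³)

both equal 1 for a sphere; sphericity drops with spindle-like elongation,
roundness is strongly penalised by protrusions (for an ellipsoid with
semi-axes a ≥ b ≥ c it equals bc/a²).

**Enrichment scoring** (`cafstate.enrichment`). Preranked GSEA (weighted
Kolmogorov–Smirnov running sum, gene-label permutation null, NES and
add-one permutation p) and ssGSEA (sum of weighted hit-vs-miss ECDF
differences). The **CAF subset score** of an expression profile is
NES(up-signature) − NES(down-signature); the per-patient variant uses
ssGSEA. Signatures are built from labelled counts by subset-vs-rest
Wilcoxon tests (|log2FC| > 0.25, BH-adjusted p < 0.05).

**qPCR state score** (`cafstate.state_score`). Relative expression is
−(Ct_gene − Ct_RPL37A); the myCAF:IL-iCAF score contrasts weighted means
of myCAF genes against IL-iCAF genes and is normalised to a baseline
condition by subtraction. Higher = more myofibroblastic.

**Ligand-receptor consensus** (`cafstate.lri`). Aggregates calls from
three upstream methods: CellPhoneDB-like (p < 0.05), NATMI-like (top 20%
per receiving cell type by the geometric mean of weight and specificity),
Scriabin-like (significant in ≥ 3 patients). Each interaction gets a
method count of 0–3.

**Explant quantification** (`cafstate.explant`). QC filtering of per-cell
measurement tables, Otsu-threshold marker positivity (e.g. PDPN⁺α-SMA⁺
myCAFs), and the treated-vs-control median percentage-change statistic
with Wilcoxon rank-sum tests.

**Survival** (`cafstate.survival`). Relative abundance of two CAF subsets
(score difference), tertile stratification (low/medium/high), Kaplan-Meier
curves and k-sample log-rank tests.

**Synthetic data** (`cafstate.synth`). Seeded generators for every input
above, returning ground truth alongside the data.

## Worked example

```python
import numpy as np
from cafstate import synth, morph3d

specs = [
    synth.ShapeSpec(kind="ball", center=(32, 24, 24), radius=12),
    synth.ShapeSpec(kind="dendritic", center=(32, 60, 60), radius=10,
                    n_protrusions=3, protrusion_length=12, protrusion_width=5),
]
data = synth.gen_cell_volume(specs, volume_shape=(64, 96, 96), noise_sd=0, seed=2)
labeled, audit = morph3d.segment_volume(data["cytoskeleton"], data["nuclei"])
table = morph3d.shape_table(labeled, audit=audit)
print(table[["label", "volume_um3", "sphericity", "roundness", "kept"]])
```

prints

```
   label  volume_um3  sphericity  roundness  kept
0      1      7139.0    1.013215   0.991742  True
1      2      4950.0    0.823806   0.272857  True
```

The spherical cell scores ≈ 1 on both metrics; the dendritic cell keeps a
moderate sphericity but its long protrusions collapse the roundness to
≈ 0.27 — exactly the separation the two descriptors are designed to make.
The analytic ground truth for these phantoms is 1.000/1.000 and
0.810/0.251, so the full segment-grow-measure chain recovers both metrics
to within a few percent.

A full demonstration of every stage (volumes, counts, qPCR, LRI, explant,
survival) with invariant checks:

```bash
cafstate demo --seed 0 --out-dir demo_run
```

## CLI

`cafstate --help` lists the subcommands: `synth`, `segment`, `shape`,
`morph-stats`, `gsea`, `ssgsea`, `subset-score`, `state-score`,
`lri-consensus`, `explant-quant`, `km-strata`, `run` (YAML-configured) and
`demo`. All stochastic commands take `--seed`.
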