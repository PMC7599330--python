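# dx2quant

Quantification of exon-skipping splice-variant ratios — specifically the
ratio of the exon-2-skipping AIMP2 variant (AIMP2-DX2) to full-length AIMP2
— from two complementary assays, with the downstream cohort and pathway
statistics used to relate that ratio to clinical outcome. It is written for
researchers studying alternative splicing in cancer (the AIMP2-DX2/AIMP2
ratio is a candidate prognostic marker in acute myeloid leukemia and other
cancers) who need a desk-testable, fully seeded implementation of the whole
measurement chain.

## What it measures

**Two-channel smFISH imaging.** Transcripts are visualised with two probe
sets: *red* (C2) hybridizes exons shared by both isoforms, *green* (C1)
hybridizes only the skipped exon 2 — hence only the full-length transcript.
With per-channel capture efficiencies α (red) and β (green),

```
Red/Green = α([AIMP2] + [AIMP2-DX2]) / (β [AIMP2])
[AIMP2-DX2]/[AIMP2] = C · Red/Green − 1,   C = β/α
```

so the red/green foci pixel-area ratio is affine in the isoform ratio.
Without a measured C the readout is semiquantitative (relative comparisons
only). The pipeline thresholds each channel, removes sub-size speckle,
measures object areas, and computes the ratio per image and — after
assigning every focus to the nearest DAPI nucleus — per cell.

**Splice-junction read counting.** In spliced alignments against hg19, a
CIGAR `N` gap joining the last base of exon 1 (chr7:6009499) to the first
base of exon 2 (6015145) supports the full-length transcript; a longer gap
to exon 3 (6017814) supports the skipping variant. The per-sample ratio is
`n_skip / n_full`.

**Cohort and pathway statistics.** Quartile-cutoff stratification,
Kaplan–Meier curves with median survival, the log-rank test, Cox
proportional-hazards regression (Breslow/Efron ties, Wald CIs, score test),
an exact R×C Fisher test by full margin-constrained enumeration, the
Mann–Whitney U test, and GAGE-style gene-set scoring (per-gene Welch t,
set-level one-sample t against the global mean, Benjamini–Hochberg FDR).

Every stochastic component has a built-in, seeded synthetic generator with
exact ground truth: Gaussian-spot smFISH fields over disk nuclei, SAM reads
with planted junction classes, and expression matrices with planted
perturbed gene sets.

## Worked example

Simulate three smFISH fields (mean 8 red and 4 green foci per cell) and
quantify them:

```
$ dx2quant simulate-images --outdir fields --n-fields 3 --seed 7
$ dx2quant quant-images --indir fields --out quant
$ cat quant_images.csv
image,n_red,n_green,red_area,green_area,rg_ratio,status
field_000.tif,80,40,1531,741,2.06612685560054,ok
field_001.tif,91,23,1799,422,4.26303317535545,ok
field_002.tif,80,47,1643,895,1.835754189944134,ok
```

Each row is one field: foci counts, total thresholded pixel areas per
channel, and their ratio. The per-field ratios scatter around the planted
2:1 red:green expectation (per-field Poisson draws differ; averaging over
~30 fields recovers the planted ratio to within a few percent). Given a
calibration constant, `isoform_ratio(4.43, CalibrationModel.from_C(0.5))`
returns `1.215` — the estimated skipped/full-length transcript ratio.

The junction pipeline is exact by construction:

```
$ dx2quant simulate-reads --out reads.sam --n-full 80 --n-skip 20 --seed 7
$ dx2quant quant-junctions --sam reads.sam --out counts.csv
$ cat counts.csv
sample,n_full,n_skip,n_other,n_unspliced,n_filtered,ratio
reads,80,20,0,0,0,0.25
```

`cohort` and `geneset` subcommands run the survival and pathway statistics
from CSV/GMT inputs; see `dx2quant COMMAND --help`.

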