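# lesiontrack

Longitudinal lesion tracking from 3D segmentation masks: connected-component
lesion extraction, axial orthogonal maximum-diameter (DMAX) measurement,
optimal lesion matching across up to 8 studies, per-lesion treatment-response
classification (CR/PR/SD/PD with configurable ±percent thresholds), and CSV
"lesion tool card" reports. Companion modules evaluate a predicted lesion set
against a reference (size-stratified precision/sensitivity/F1, patient-wise
Dice) and quantify paired-reader agreement (ICC, Spearman, Bland-Altman,
discrepancy summaries). A synthetic phantom generator with known ellipsoid
trajectories, simulated readers, and a degradable simulated segmenter makes
the whole pipeline testable without any imaging data.

## Library overview

| module | what it does |
| --- | --- |
| `volumes` | NIfTI label-volume I/O, voxel geometry, nearest-neighbor label resampling between grids |
| `lesions` | 3D connected components (6/18/26 adjacency), per-lesion geometry, ≥5 mm size class |
| `diametry` | longest axial diameter + orthogonal caliper width per lesion (voxel-center distances) |
| `tracking` | optimal one-to-one lesion matching (voxel overlap + centroid gate), track chaining, percent changes |
| `response` | per-lesion response labels (PD vs nadir, PR vs baseline, CR on absence) and endpoint selection |
| `evaluation` | detection TP/FP/FN with size strata, precision/sensitivity/F1, pooled patient-wise Dice |
| `agreement` | reader consensus construction, per-reader detection metrics, ICC(2,1)/Spearman/Bland-Altman |
| `phantom` | seeded synthetic longitudinal series with ground-truth diameters and response labels |
| `report` | lesion tool card and response-curve CSV export |

```python
from lesiontrack import (extract_lesions, measure_lesions, build_tracks,
                         classify_track, read_label_volume)

vols = [read_label_volume(p, study_index=i) for i, p in enumerate(paths)]
series = [(v.study_index, measure_lesions(extract_lesions(v), v.grid)) for v in vols]
tracks = build_tracks(series)
for t in tracks:
    classify_track(t)
```

## Command line

```bash
# full pipeline on co-registered masks (chronological order, max 8 studies)
lesiontrack track --mask t0.nii.gz --mask t1.nii.gz --mask t2.nii.gz \
    --date 2021-01-01 --date 2021-04-01 --date 2021-07-01 \
    --patient-id p1 --out run/

# detection + Dice evaluation of predicted vs reference mask directories
lesiontrack evaluate --pred-dir pred/ --ref-dir ref/ --out eval.json
# ... or from pre-tabulated counts
lesiontrack evaluate --counts-only --tp 502 --fp 41 --fn 105 --out metrics.json

# inter-rater agreement from reader measurement CSVs
lesiontrack agreement --r1-csv r1.csv --r2-csv r2.csv \
    --adjudication-csv adj.csv --out agreement.json

# synthetic phantom series
lesiontrack phantom --out phantom/ --seed 3 --trajectory grow:30 --trajectory flat
```

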