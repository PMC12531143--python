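# fcnm — coordinate-based functional connectivity network mapping

Voxel-based morphometry (VBM) studies of a trait or symptom often report
scattered, poorly replicating gray-matter (GM) coordinates. Functional
connectivity network mapping (FCNM) asks a different question: do those
heterogeneous locations nevertheless sit inside one common large-scale
functional network? Given a table of published foci and a normative
resting-state fMRI cohort, the pipeline

1. builds a **contrast seed** per study contrast — the union of 4-mm-radius
   spheres around that contrast's coordinates (foci outside the GM mask are
   dropped, Talairach foci converted to MNI through a configurable affine);
2. computes each subject's seed-to-voxel Pearson correlation map and applies
   the Fisher transform, z = atanh(r);
3. runs a voxel-wise one-sample t-test across subjects
   (t = z̄ / (s_z / √n), df = n − 1), thresholds at p < 0.05 voxel-level
   FDR (Benjamini–Hochberg over in-mask voxels), keeps positive
   connectivity only, and binarizes;
4. merges the K contrast-level binary maps into an **overlap probability
   map** P(v) = (# maps containing v)/K and thresholds at P ≥ 0.5 — voxels
   connected to at least half of the contrast seeds define the network;
5. quantifies overlap with canonical networks (visual, somatomotor, dorsal
   and ventral attention, limbic, frontoparietal, default mode, plus a
   subcortical system) as 100·|network ∩ canonical|/|canonical|, calling a
   system involved at ≥ 20%;
6. correlates the network map with receptor/transporter density maps at the
   parcel level (Spearman by default), with significance from a 5,000-
   iteration permutation null, p = (b+1)/(n_perm+1), FDR-corrected across
   the tracer family.

A first-class synthetic-data module generates every input with known ground
truth — cohorts with planted band-limited networks, study foci tables,
motion traces, label atlases, and receptor maps with a calibrated target
Spearman correlation — so the whole pipeline is testable without any data
download. Time-series preparation utilities (volume discard, motion QC,
Power framewise displacement, Friston-24 expansion, spike regressors at
FD > 0.5 mm, nuisance regression, 0.01–0.1 Hz ideal bandpass) are included
for cohorts that still need them.

## Worked example

```python
from fcnm.study_ingest import load_study_table, summarize_sample, bundled_study_table_path
records, foci = load_study_table(bundled_study_table_path())
print(summarize_sample(records))
```

```
{'n_studies': 13, 'total_n': 1478, 'total_female': 768, 'total_male': 710,
 'weighted_mean_age': 27.72, 'min_n': 30, 'max_n': 364}
```

The packaged table carries the sample characteristics of 13 VBM studies of
extraversion (1,478 participants pooled; n-weighted mean age 27.72 years).
Its coordinates are synthetic placeholders — the peak tables of the source
studies are not redistributed — so it demonstrates ingestion and
summarization, not a reanalysis.

End-to-end on synthetic data with a planted ground-truth network:

```python
from fcnm.experiments import run_planted_recovery
from fcnm.atlas import classify_involvement, overlap_proportions
from fcnm.synthetic import simulate_atlas, default_grid

out = run_planted_recovery(seed=1)
print(f"contrast seeds: {out['k_contrasts']}, "
      f"network voxels: {out['network_mask'].mask.n_voxels}, "
      f"Dice vs truth: {out['dice']:.3f}")
atlas = simulate_atlas(default_grid(), out["gm"], rng_seed=1)
report = classify_involvement(overlap_proportions(out["network_mask"], atlas))
print(report.table[["name", "proportion_pct", "involved"]].round(2).to_string(index=False))
```

```
contrast seeds: 8, network voxels: 413, Dice vs truth: 0.994
             name  proportion_pct  involved
           visual            6.80     False
      somatomotor            6.16     False
 dorsal_attention           25.57      True
ventral_attention           12.92     False
           limbic            0.00     False
   frontoparietal            0.62     False
     default_mode           22.99      True
      subcortical            0.00     False
```

The recovered network matches the planted one almost voxel-for-voxel
(Dice 0.994), and the involvement rule flags exactly the synthetic atlas
labels the planted components fall into.

A file-based run goes through the CLI: `fcnm simulate --out bundle/` writes
a complete input bundle (NIfTI cohort, GM mask, foci CSV, atlases, receptor
table), `fcnm run --config cfg.yaml` executes the pipeline and writes the
network mask, overlap report, neurochemical profile, and a JSON manifest
sufficient to reproduce the run, and `fcnm sensitivity --radii 1,4,7`
repeats the analysis across seed radii and reports pairwise Dice overlap of
the resulting masks.

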