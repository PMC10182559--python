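# glycoscape

A toolkit for spatial carbohydrate analysis of MALDI mass spectrometry
imaging (MSI) data: from centroided pixel spectra of enzymatically released
glycogen chains and N-glycans, through lock-mass recalibration, panel peak
integration and per-pixel TIC normalization, to unsupervised pixel
clustering with automatic matrix-cluster removal, cluster-wise carbohydrate
enrichment, chain-length (DP) profiling, on-slide absolute quantitation, and
PLS-DA / ROC biomarker scoring.

Every stage is exercisable without real data through a built-in synthetic
MSI phantom with known ground truth (region signatures, mass drift,
calibration spots).

## Modules

| module         | purpose                                                           |
| -------------- | ----------------------------------------------------------------- |
| `phantom`      | synthetic MSI datasets + ground truth (regions, drift, spots)     |
| `carbo_masses` | glycan/glucan composition masses, DP ladder, peak panel, annotation |
| `msi_io`       | imzML (processed mode), pixel-table CSV, label-map CSV/PNG        |
| `preprocess`   | lock-mass recalibration, panel integration, TIC normalization     |
| `hdr_sc`       | kNN + Leiden pixel clustering, UMAP embedding, matrix removal     |
| `enrichment`   | Wilcoxon one-vs-rest markers, chain profiles, group statistics    |
| `quantitation` | standard-curve fitting and ng/pixel back-calculation              |
| `biomarker`    | log+autoscale, NIPALS PLS-DA with VIP, univariate & CV ROC        |
| `cli`          | `glycoscape` command-line entry point and pipeline orchestration  |

## CLI

Full pipeline from a TOML config (stages: phantom, preprocess, cluster,
enrich, quantify, biomarker):

```sh
glycoscape run --config run.toml --seed 17 --out rundir/
```

Individual stages:

```sh
glycoscape phantom --seed 17 --noise-cv 0.1 --out ph/
glycoscape panel build --path panel.tsv
glycoscape panel annotate --mz 1809.64 --tol 0.2
glycoscape preprocess --imzml ph/phantom.imzML --lock 1257.4296 \
    --tol 1.0 --min-counts 100000 --out pp/
```

A minimal `run.toml`:

```toml
seed = 17
out = "rundir"
stages = ["phantom", "preprocess", "cluster", "enrich", "quantify"]

[phantom]
noise_cv = 0.1
drift_amplitude = 0.1
grid = [40, 40]

[cluster]
k_neighbors = 15
resolution = 1.0
```

## Conventions

- Adduct: [M+Na]⁺ (positive-mode CHCA carbohydrate imaging).
- Feature names: nominal label = floor of the sodiated monoisotopic m/z.
- Coordinates: 0-based, x = column (left→right), y = row (top→bottom).
- Integration windows: ±0.4 Da around each panel target (full width < 1 Da).
- TIC is computed over the full spectrum, not just panel features.
- "Total glycogen" = sum over all glycogen-DP panel features per pixel.
- Quantitation operates on raw (non-TIC-normalized) signal.
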