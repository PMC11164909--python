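# stormquant

Quantitative nanodomain analysis for single-molecule localization microscopy
(STORM/dSTORM) of lymphocyte chromatin.

Activated lymphocytes reorganize their genome at the nanoscale: condensed
chromatin nanodomains fragment into smaller ones, the nuclear envelope is
disrupted, and small double-stranded-DNA nanoclusters (~30–50 nm) appear in
the cytosol. These effects live below the diffraction limit, so they are
measured on *localization tables* — lists of single-emitter blink events with
nanometre coordinates accumulated over ~20,000 camera frames — rather than on
conventional images. `stormquant` is the analysis side of such an
experiment: it turns localization tables into per-cell nanodomain metrics
and condition-level statistics, and ships a fully seeded synthetic STORM
generator with ground truth so every stage is testable end to end.

## What it computes

- **Drift correction** (`DriftCorrector`): fiducial beads are detected as
  persistent bright emitters, linked into tracks, and the stage drift is
  estimated from windowed track means (200 frames = 4 s per window), linearly
  interpolated per frame and subtracted.
- **Nanodomain detection** (`NanodomainDetector`): localizations are rendered
  to a 10 nm histogram, band-pass filtered with a difference of Gaussians,
  local maxima inside the nucleus/cytoplasm mask seed a Gaussian mixture
  model fitted by EM to the localization coordinates. Each surviving
  component is one nanodomain with center, covariance, localization count
  and scalar size

  FWHM = 2·sqrt(2 ln 2) · (λ₁·λ₂)^¼,

  the geometric mean of the covariance eigen-axes (λᵢ in nm²), optionally
  deconvolved for localization precision.
- **Metrology**: nearest-neighbor distance between domain *boundaries*
  (FWHM/2 discs), per-cell means of size and localizations per domain,
  cytosolic nanocluster count and size.
- **Colocalization** (`coloc_degree`): percentage of channel-A domains whose
  FWHM/2 disc touches a channel-B disc.
- **Statistics**: Mann–Whitney U (exact for small tie-free problems,
  tie/continuity-corrected normal approximation otherwise) on per-cell
  metrics between conditions; Pearson correlations between nuclear domain
  size and cytosolic cluster size/count.
- **Simulation** (`simulate_cell`, `simulate_population`): elliptical nuclei
  with Gaussian nanodomains (negative-binomial localization counts, optional
  periphery bias), cytosolic nanoclusters, uniform background, per-frame
  blinking, stage drift, fiducial beads — all bit-reproducible from one seed
  and accompanied by ground truth.

## Worked example

Simulate a small two-arm experiment (5 cells per arm; quiescent-like 90 nm
domains vs activated-like 45 nm domains with cytosolic clusters), detect
nanodomains and compare the arms:

```python
from stormquant.pipeline import run_pipeline

cfg = {
    "n_cells_per_arm": 5,
    "seed": 42,
    "arms": {
        "quiescent": {"domain_fwhm_mean_nm": 90.0, "n_nuclear_domains": 40,
                      "min_domain_separation_nm": 180.0},
        "activated": {"domain_fwhm_mean_nm": 45.0, "domain_fwhm_sd_nm": 6.0,
                      "n_nuclear_domains": 40, "min_domain_separation_nm": 90.0,
                      "n_cytosolic_clusters": 10},
    },
    "detection": {"expected_fwhm_nm": 65.0},
}
manifest = run_pipeline(cfg, out_dir="demo")
```

`demo/cell_records.csv` then holds one row per cell:

```
      cell_id condition  n_nuclear_domains  mean_fwhm_nm  mean_locs_per_domain  mean_nnd_nm  n_cytosolic_clusters
activated_000 activated                 40          48.4                 178.2        406.3                    11
activated_002 activated                 40          33.1                 185.2        455.5                    12
quiescent_000 quiescent                 40          85.9                 216.0        376.3                     0
quiescent_003 quiescent                 43         102.2                 199.2        312.0                     0
...
```

and `demo/comparisons.csv` the between-arm tests:

```
              metric  u_statistic  p_value  n_x  n_y  median_x  median_y method
        mean_fwhm_nm          0.0   0.0079    5    5    45.166   85.9400  exact
mean_locs_per_domain         11.0   0.8413    5    5   185.225  199.2093  exact
```

Reading: activated cells recover ~45 nm mean domain size versus ~86 nm for
quiescent cells (U = 0, exact two-tailed p = 0.0079 at n = 5 + 5 — every
activated cell below every quiescent cell), localizations per domain were
configured equal in both arms and correctly test as indistinguishable, and
cytosolic nanoclusters appear only in the activated arm. `demo/domains.csv`
lists every detected domain; `demo/manifest.json` records the configuration,
seed, versions, timings and output hashes (re-running with the same seed
reproduces the CSVs bit for bit).

The same stages are scriptable from a shell:

```bash
stormquant simulate --seed 5 --out sim --n-domains 40 --drift linear \
    --drift-magnitude 150 --n-fiducials 3
stormquant driftcorrect --in sim/table.csv --out corrected.csv --window 200
stormquant analyze --table corrected.csv --nucleus-mask sim/nucleus_mask.tif \
    --out record.csv --domains-out domains.csv
stormquant compare --records records.csv --metric mean_fwhm_nm
```

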