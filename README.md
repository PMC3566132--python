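# dropquant

Per-cell high-content quantification of lipid-droplet-associated
phospho-proteins in adipocyte plate images.

At the initiation of lipolysis, PKA phosphorylates the droplet coat
protein perilipin 1A and hormone-sensitive lipase (HSL); phospho-specific
antibodies make these events visible as label at the rims of lipid
droplets. `dropquant` implements the image-analysis side of that assay for
96-well plates imaged in four channels (DAPI nuclei, lipid droplets, and
two protein labels):

1. **Segmentation** — nuclei are detected in the DAPI channel by robust
   thresholding (median + k·σ_MAD), hole filling, size filtering and an
   optional distance-transform watershed; every pixel is then assigned to
   its nearest nucleus (ties to the lower label), clipped at a maximum
   radius, giving disjoint per-cell territories.
2. **Masking** — protein- and lipid-positive pixels are classified against
   the per-field robust background (median + k·σ_MAD, default k = 4) with
   small-object suppression.
3. **Per-cell readouts** — for each cell *i*:
   * `Area Pm_i = |M_i| · p²` (µm²/cell), where `M_i` is the protein mask
     within the cell territory and `p` the pixel pitch (0.6848 µm at 20×,
     0.344 µm at 40×);
   * `Tii Pi Pm_i = Σ_{x∈M_i} I(x)` — total integrated intensity of the
     raw protein image over the mask;
   * `Pr_i` — per-cell Pearson correlation of two label channels over the
     cell's pixels, −1 (perfect exclusion) … +1 (perfect coincidence).
   Fields with two protein labels are analyzed twice on the same
   segmentation, once per channel.
4. **Well statistics** — cells pool to well means (the well is the
   experimental unit), with normalization to a control condition, fold
   changes of well means, and one-way ANOVA followed by Tukey's HSD or
   Dunnett's test (or Student's t for two groups), starred at
   0.05/0.01/0.001.
5. **Synthetic plates** — a generator draws nuclei, clustered droplets and
   phospho-positive droplet rims with Poisson–Gaussian camera noise, and
   emits exact per-cell ground truth, so the whole pipeline is testable
   without microscope data. Presets encode published effect sizes
   (e.g. 7–27-fold agonist responses, a 90% siRNA knockdown).
6. **Motifs** — a classifier for the PKA consensus R(R/K)X(S/T): two
   arginines at P-2/P-3 (RRXS class) predict high PKA affinity, a single
   arginine low affinity.

## Worked example

```bash
python analysis/01_simulate_example_plate.py
python analysis/02_quantify_example_plate.py
```

The first script writes a 6-well plate (3 control wells at a ground-truth
27 µm²/cell rim-positive area, 3 "FSK" wells at 189 µm²/cell) as 16-bit
TIFFs under `scratch/example_plate/`. The second reads the images back and
runs the full pipeline, printing:

```
measured vs ground-truth Area Pm (µm²/cell, well means):
              n_cells  mean_area_pm_um2  truth_mean_um2
condition_id
FSK             67.00            184.84          187.54
control         75.33             26.31           26.27
```

i.e. from the pixels alone the pipeline recovers the simulated per-cell
phospho-positive area to within ~1.5% in both conditions — a measured fold
change of 7.0 against a generated 7.1. `analysis/03_agonist_experiments.py`
repeats this for the full agonist, siRNA-titration and time-course
designs, and `analysis/04_motif_classification.py` exercises the PKA
consensus classifier; both write tables under `results/`.

A `dropquant` CLI wraps the same library for shell use:
`dropquant simulate|quantify|stats|run-all|scan-motifs --help`.

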