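# laminarsim

Synthetic-cortex simulations of the **effective laminar resolution** of
high-resolution BOLD fMRI, for researchers who analyse cortical-depth
profiles from sub-millimetre isotropic acquisitions.

Laminar fMRI at 0.7–0.8 mm isotropic cannot resolve cortical layers
directly: the standard analysis upsamples the functional image, assigns
interpolated samples to depth bins, and averages over an extended ROI,
banking on the quasi-random (jittered) position of voxels relative to
the laminae. `laminarsim` asks how well that pipeline can work *at
best*, by simulation:

1. **Synthetic cortex** — a 2-D ribbon with variable cortical thickness
   (1.7–3.7 mm), normalized depth d ∈ [0, 1] from the GM–CSF boundary
   (d = 0) to the GM–WM boundary (d = 1).
2. **Induced laminar PSF** — a Gaussian in depth, FWHM = 1/5 of the
   cortical depth, centred mid-cortex.
3. **Voxel sampling** — isotropic grids (0.75 mm by default) at
   uniformly jittered offsets; voxel signal = boxcar mean over the
   footprint; additive Gaussian noise at SNR ∈ {∞, 1}.
4. **Reconstruction** — 10× linear upsampling and equidistant depth
   binning (N = 3 or 21 depths) over ROIs of increasing voxel count.
5. **Score** — percent overlap between the induced and reconstructed
   profiles: 100 × ∫ min(p̂, p) dd with both curves unit-area
   normalized.

Companion experiments quantify pial-boundary partial-volume leakage at
two voxel sizes (0.75 vs 0.125 mm) and, via PCA across trials, whether
tangential (along-cortex) response variability is reproducible rather
than thermal noise. See `docs/methods.md` for the full model.

## Worked example

```python
import laminarsim as ls

# PSF overlap vs ROI size (variable cortex, 0.75 mm voxels, SNR = inf)
cfg = ls.OverlapConfig(roi_sizes=(24, 100, 1000), n_realizations=200,
                       seed=1, length_mm=260.0)
curve = ls.run_overlap_experiment(cfg)
for r, m, s in zip(curve.roi_sizes, curve.mean_overlap_pct, curve.sd_overlap):
    print(f"ROI {r:5d} voxels: overlap {m:5.1f}% (SD {s:4.1f})")

# Pial-boundary leakage at two voxel sizes
res = ls.run_pial_leakage_experiment(ls.PialConfig(n_realizations=100, seed=1))
for size, ext in res.extent_10pct.items():
    print(f"voxel {size:g} mm: pial signal reaches depth {ext:.2f}")

# Trial-wise PCA of tangential variability
model = ls.TimecourseModel()
patch = ls.make_flat_patch(3.0, 20.0, resolution_mm=0.05)
sim = ls.simulate_trials(model, patch, n_trials=10, noise_sd=1.0, seed=1)
pca = ls.pca_explained_variance(ls.build_trial_matrix(sim))
r = ls.pc1_similarity(pca, sim.modulation)
print(f"PC1 explains {pca.explained_variance_pct[0]:.1f}% ; "
      f"r(PC1, true modulation) = {r:.3f}")
```

Output:

```text
ROI    24 voxels: overlap  66.6% (SD  8.7)
ROI   100 voxels: overlap  68.2% (SD  6.6)
ROI  1000 voxels: overlap  68.8% (SD  3.4)
voxel 0.75 mm: pial signal reaches depth 0.32
voxel 0.125 mm: pial signal reaches depth 0.05
PC1 explains 99.0% ; r(PC1, true modulation) = 0.990
```

Reading: a ~24-voxel ROI already recovers about two thirds of the
induced profile's area, and growing the ROI past 100 voxels barely
helps — the voxel kernel, not the ROI, limits the effective laminar
resolution. Larger voxels drag pial-surface signal several times deeper
into the apparent profile. When a fixed tangential pattern underlies
the trials, PC1 of the across-trial PCA captures it almost perfectly.

A CLI mirrors these drivers
(`laminarsim simulate-resolution|simulate-pial|simulate-trials|analyze-pca|depth-profile
--config cfg.yaml --seed N --out DIR`), with YAML configs; every run
writes TSV outputs plus a `metadata.json` with the resolved parameters,
seed and package version. Encode infinite SNR as the string `"inf"`.

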