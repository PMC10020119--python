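# mesohist

Voxelwise comparison of diffusion-MRI microstructure maps with coregistered
quantitative histology on a shared mesoscopic (200 μm) grid.

## The problem

Diffusion MRI parameters such as mean diffusivity (MD) and fractional
anisotropy (FA) are routinely read as proxies for cell density and tissue
anisotropy in tumors. Whether that reading holds *within* a tumor — voxel by
voxel at the ~200 μm scale — is a quantitative question: how much of the
intra-tumor variability in MD is explained by cell density (CD) from
histology, and how much of the in-plane anisotropy (FA_IP) by the structure
anisotropy (SA) of the stained section? `mesohist` implements the full
analysis pipeline for this question, for researchers working with paired
ex-vivo dMRI and whole-slide histology: tensor fitting and scalar maps,
structure-tensor and cell-density maps from histology, landmark
coregistration, and a repeated-split out-of-sample evaluation framework —
plus a synthetic phantom generator so every stage is testable without any
specimen data.

## The model

**dMRI arm.** Per voxel the signal follows the monoexponential tensor model
S = S₀·exp(−b gᵀDg); taking logs makes it linear in (ln S₀, D) and the
tensor is estimated by ordinary least squares over all measurements (three
shells, b = 100/1000/3000 s/mm², six directions). From **D**: MD = tr(D)/3;
FA from the eigenvalues; and the in-plane FA from the 2×2 restriction
**D**_xy to the section plane,

    FA_IP = (λ₁ − λ₂) / (λ₁ + λ₂),   λ₁ ≥ λ₂ eigenvalues of D_xy,

which is insensitive to through-plane diffusion and therefore the right
quantity to compare against a thin (μm-scale) histology section.

**Histology arm.** The structure tensor H = Gσ_i ∗ (∇I ∇Iᵀ) is computed from
Gaussian-derivative gradients at σ = 0.25 μm, integrated at σ = 15 μm,
block-averaged to the 200 μm MR grid, and summarized by the same eigenvalue
ratio, SA = (λ₁ − λ₂)/(λ₁ + λ₂). CD is the nucleus-centroid count per
MR-voxel-sized area normalized by the sample maximum. Both maps receive the
same final σ = 40 μm smoothing as the dMRI maps.

**Evaluation.** Within a tumor ROI (eroded intersection of the MR and
histology tissue masks), a small model family (polynomials of degree 1–3, a
monotone-decreasing-constrained quadratic for MD, an origin-constrained line
for FA_IP) maps CD → MD or SA → FA_IP. Performance is the out-of-sample R²
over 1000 random 80/20 train/test splits,

    R²_OS = 1 − MSE_model / MSE_μ,

with both errors computed on held-out voxels (MSE_μ scores the mean of the
measured test values), reported as median ± interquartile range. A relative
form RR²_OS = 1 − MSE_feature/MSE_benchmark compares the feature model with
any external benchmark predictor. Signed residual maps (red = model
under-predicts, green = over-predicts) localize the failures.

## Worked example

Generate a 40×40-voxel phantom in which cell count is linked to the
intracellular volume fraction (so CD should predict MD), simulate the
acquisition at SNR 50, fit the tensor, rasterize the centroids, and evaluate
the association:

```python
import mesohist as mh
from mesohist import ModelSpec, PhantomConfig

cfg = PhantomConfig(n_cells=(40, 40), snr=50.0, seed=101)
truth = mh.generate_phantom(cfg)
signals = mh.simulate_dmri_signal(truth)
field = mh.fit_dti(signals, signals.protocol)
md = mh.map_md(field).values[:, :, 0]
centroids, _ = mh.sample_centroids(truth)
cd = mh.map_cell_density(centroids, cfg.grid).values

ev = mh.evaluate_splits(cd.ravel(), md.ravel(), ModelSpec("poly2"),
                        repeats=1000, seed=1)
print("R2_OS (CD -> MD, poly2):", ev.summary())

stats = mh.sample_summary_stats(mh.ParameterMap(md, 200.0, units="mm^2/s"),
                                truth.tissue())
print(f"MD mean {stats['mean']:.2e} mm^2/s, CoV {stats['cov']:.2f}")
```

prints

```
R2_OS (CD -> MD, poly2): 0.93 ± 0.01
MD mean 5.75e-04 mm^2/s, CoV 0.17
```

i.e. in this coupled phantom the quadratic in CD explains ~93% of the
held-out MD variance (median over 1000 splits, ± IQR), and the sample has
enough MD variability (CoV 0.17) for that number to be meaningful. Setting
`large_cell_mode=True` decouples cell count from volume fraction and drives
the median R²_OS to ≈ 0 while MD stays uniform — the regime in which high
CD variability coexists with flat MD.

The same stages are available from the shell:

```bash
mesohist simulate --seed 5 --out-dir bundle/
mesohist associate --bundle bundle/ --model poly2 --predictor CD \
    --response MD --repeats 1000 --seed 1 --out-dir results/
```

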