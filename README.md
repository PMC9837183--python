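# bcseg

Automatic bladder-tumor segmentation on diffusion-weighted MRI (DWI) and
reproducibility analysis of ADC-map radiomics — as a tested, reusable Python
pipeline exercised entirely on synthetic phantoms.

## The problem

Radiomics studies of bladder cancer need tumor regions of interest, and
manual delineation is slow and subjective.  A practical workflow is:

1. segment the tumor automatically with a convolutional network trained on
   DWI (b = 0 and b = 1000 s/mm²) and apparent-diffusion-coefficient (ADC)
   maps, where tumors are bright at b1000 and dark on ADC (restricted
   diffusion, S(b) = S0·e^(−b·ADC));
2. fuse the five models from patient-level five-fold cross-validation by
   per-voxel majority vote — a voxel is tumor when **≥ 3 of 5** models agree;
3. score overlap with the reference standard by the Dice similarity
   coefficient, DSC = 2|T∩P| / (|T| + |P|);
4. extract 107 radiomics features (18 first-order, 14 shape, 24 GLCM,
   16 GLRLM, 16 GLSZM, 5 NGTDM, 14 GLDM) from the ADC map under both the
   manual and the automatic mask, discretized at fixed bin width 0.005 with
   voxel-array shift 1;
5. quantify manual-vs-automatic agreement per feature with the intraclass
   correlation coefficient ICC(2,1) — two-way random-effects ANOVA, absolute
   agreement, single measurement:
   ICC = (MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE)) —
   binned poor (< 0.50), moderate (0.50–0.75), good (0.75–0.90) and
   excellent (> 0.90).

Clinical MRI of this kind is not publicly distributable, so the package
ships a synthetic-data module: mono-exponential DWI phantoms of a
urine-filled bladder with wall-attached tumors, per-patient tissue
heterogeneity, Rician noise and partial-volume blur, plus controlled mask
perturbations for the reproducibility experiments.  The model itself — a
five-level U-Net (Conv–BatchNorm–ReLU blocks, max-pool encoder,
transposed-convolution decoder with skip connections, sigmoid head) trained
with Adam under the soft-Dice loss — is implemented directly in NumPy, with
its backward pass verified against finite differences.

See `docs/methods.md` for the full model description, parameter tables and
design decisions.

## Worked example

```python
from bcseg import synthesize_case, extract_all
from bcseg.phantom import generate_cohort, perturb_mask, calibrate_perturbation
from bcseg.repro_stats import icc_2_1, categorize_icc
import numpy as np

case = synthesize_case(shape=(16, 128, 128), seed=7)
print("tumor voxels:", int(case.reference_mask.voxels.sum()))

fv = extract_all(case.adc, case.reference_mask, case.spacing)
print("features:", len(fv))
print("mean ADC:", round(fv["firstorder_Mean"], 4))

cases = generate_cohort(20, seed=11, shape=(16, 128, 128))
mag = calibrate_perturbation([c.reference_mask for c in cases], target_dsc=0.85, seed=0)
pairs = []
for i, c in enumerate(cases):
    manual = extract_all(c.adc, c.reference_mask, c.spacing)
    auto = extract_all(c.adc, perturb_mask(c.reference_mask, mag, seed=i), c.spacing)
    pairs.append((manual["firstorder_Mean"], auto["firstorder_Mean"]))
res = icc_2_1(np.asarray(pairs))
print(f"ICC(2,1): {res.icc:.3f} ({categorize_icc(res.icc)})")
```

prints

```
tumor voxels: 1064
features: 107
mean ADC: 0.9002
ICC(2,1): 0.747 (moderate)
```

The phantom's tumor occupies 1064 voxels of the 16×128×128 grid; its mean
ADC of ≈0.90 ×10⁻³ mm²/s reflects the restricted-diffusion tissue model.
After perturbing each reference mask to a mean Dice overlap of 0.85 —
emulating the disagreement between a manual and an automatic delineation —
the mean-ADC feature still agrees with ICC 0.747, at the upper edge of the
"moderate" reliability bin.

## Command line

A thin CLI wraps the library stages:

```sh
bcseg simulate --n 50 --seed 1 --out-dir data/            # synthetic cohort as NIfTI
bcseg train --cohort-manifest data/manifest.csv --out models/ --input-mode multi
bcseg predict --models models/ --case data/case-0000 --out pred.nii.gz
bcseg evaluate --pred pred.nii.gz --ref data/case-0000/mask.nii.gz
bcseg features --case data/case-0000 --out features.csv
bcseg icc --features features.csv --out report/
bcseg run-all --seed 1 --out-dir reports/                 # full pipeline
```

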