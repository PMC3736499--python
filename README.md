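# dsareg — nonrigid mask/live registration for digital subtraction angiography

Digital subtraction angiography (DSA) visualizes vessels by subtracting a
pre-contrast **mask** frame from a contrast-filled **live** frame.  In
coronary studies, cardiac and respiratory motion between the two
acquisitions is nonrigid, so rigid or global-shift corrections leave
strong motion artifacts in the subtraction.  `dsareg` implements a fast
elastic registration for such image pairs, together with a synthetic
phantom benchmark so its accuracy claims can be checked without clinical
data.  It is aimed at researchers working on X-ray image registration and
at anyone needing a reference implementation of multilevel B-spline
scattered-data warping.

## Method

Given a mask image M and live image L (8-bit, nominally 512×512):

1. **Control-point selection** on L: fuse the thresholded Gaussian-derivative
   gradient magnitude G (scale σ = 1, threshold = mean) with the clipped,
   normalized Harris corner response R (k = 0.12), R̂ = 0.3·G + 0.7·R;
   take local maxima of R̂ above t₁ = 0.1 (circular radius 5) and thin them
   greedily to a minimum distance D_min = 25 px.
2. **Block matching**: for each control point pᵢ, the 51×51 template around
   pᵢ in L is compared with displaced patches of M.  The similarity is
   ENT — the entropy of the normalized histogram of the pixelwise
   difference, −Σ pⱼ log₂ pⱼ — which is zero for a perfect (offset-free or
   constant-offset) match and robust to local dissimilarities such as
   contrast-filled vessels present only in L.  The integer displacement
   dᵢ (|dx|,|dy| ≤ 20) is found by hill climbing restarted from
   (±5, ±5).
3. **Field construction**: two multilevel B-spline surfaces f_X, f_Y
   (hierarchy of h = 7 control lattices, cell spacing 512 → 8 px) are fit
   to {(pᵢ, dᵢ)}, interpolating the matched displacements and
   extending them smoothly over the frame.
4. **Enhancement and warping**: both images are enhanced by subtracting
   their morphological bottom-hat (nonflat ball, diameter 15 px), the
   enhanced mask is warped by backward mapping through (f_X, f_Y), and the
   DSA image is L̂ − warp(M̂).

Accuracy is quantified on simulated pairs with known ground truth: a
phantom live frame is warped by a random elastic field built from 30
control-point shifts drawn from U[−10, 10] px, and the RMS error δ of the
recovered correspondences at n sampled control points is compared with
the initial error δ₀ through the reduction ratio **R = (δ₀ − δ)/δ₀ × 100**.

## Worked example

```python
from dsareg import gen_phantom, simulate_pair, DSARegistration

scene = gen_phantom(seed=3)                      # synthetic angiogram
pair = simulate_pair(scene.live, seed=103)       # known elastic warp
res = DSARegistration(mask=scene.live, live=pair.sim_live).fit()
print(res.summary())
res.save("outdir")                               # DSA images, matches.csv, field.tif
```

The same run from the shell:

```sh
dsareg simulate --out demo --seed 3
dsareg register --mask demo/mask.png --live demo/sim_live.png --out demo/reg
```

prints

```
DSA nonrigid registration results
==============================================
image size                      512 x 512
similarity measure              ENT
control points                  162
mean |d| (px)                   4.502
max |d| (px)                    12.806
lattice hierarchy levels        7
residual energy before          2612.41
residual energy after           618.31
residual reduction              76.3%
```

162 control points were selected and matched; the mean matched
displacement of 4.5 px reflects the simulated motion, and warping the
mask before subtraction removed 76% of the subtraction-image variance
(the motion-artifact energy).  `demo/reg/dsa_before.png` and
`dsa_after.png` show the subtraction before and after correction;
`matches.csv` lists (x, y, x′, y′, dx, dy, score) per control point.

The quantitative benchmark:

```sh
dsareg evaluate --pairs 10 --seed 1
```

prints a per-pair table of δ₀, max/min/RMS error and reduction ratio,
plus the averages.  `dsareg compare-measures` runs the
similarity-measure sweep (ENT, EHD, CC, MI, SSIM across template sizes).

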