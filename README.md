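# stainquant

Unsupervised quantification of histological calcification staining images
(Alizarin Red, von Kossa) that remain reliable when the slide is
contaminated by off-target, defocused "dirty" stains.

## The problem

Brightfield images of calcification assays are routinely quantified by
thresholding: pick a cutoff, count stained pixels inside the tissue region
of interest (ROI). That works while the background is clean. In practice,
stray dye deposits land outside the section, share the stain's color, and
defeat any intensity-only method — the usual fix is tedious manual ROI
drawing. The one physical property that separates tissue from dirt is
*focus*: the section lies in the focal plane and carries sharp texture,
while stray deposits are defocused and locally smooth.

## The method

For a grayscale image `I`, the pipeline computes at every pixel the local
fourth-order central moment over a small window `η(x, y)` of `N_η` pixels,

    m⁴(x, y) = (1/N_η) Σ_{(s,t)∈η(x,y)} (I(s,t) − m̄(x,y))⁴
    HOS(x, y) = min(255, m⁴(x, y) / 300)

a higher-order-statistics (HOS) focus measure that is large on focused
texture and near zero on smooth, blurred regions. The HOS map is
binarized, the candidate foreground points `p_i` are screened by a
k-nearest-neighbor local density

    d̄_i = (1/k) Σ_j d_ij,    LD(p_i) = (1/k) Σ_j exp(−d_ij / d̄_i)

and the mask is then dilated, hole-filled, and cleaned by size-ranked
object removal (largest connected objects retained until ≥ 95 % of the
foreground area is covered). Positive staining is identified inside the
ROI on the *inverted* 8-bit intensity with an inclusive threshold (100 for
Alizarin Red, 140 for von Kossa), giving four readouts per image — total
area, total intensity, stained area, stained intensity — plus

    stained area %    = stained area / ROI area × 100
    stain intensity % = Σ stained intensity / (ROI area × 255) × 100

Batch agreement against a benchmark is scored with Pearson's r, relative
differences `(x − y)/y` with t-based 95 % CIs, a two-one-sided-tests (TOST)
equivalence test against a ±5 % margin, and the success rate (fraction of
images with |relative difference| < 0.05). Otsu's method and iterative
Triclass thresholding are included as baselines, and a seeded synthetic
slide generator provides ground-truth-annotated test images.

## Worked example

```python
from stainquant import PipelineConfig, SlideParams, generate_slide, to_grayscale
from stainquant.batch import process_image

slide = generate_slide(SlideParams(stain_fraction=0.25), seed=42)
gray = to_grayscale(slide.image)
cfg = PipelineConfig.with_preset("AR")
roi, stain, q = process_image(gray, cfg, method="sq")
print(q.total_area, q.stained_area, round(q.stained_area_pct, 4), round(q.stain_intensity_pct, 4))
```

prints

```
274132 66076 24.1037 18.445
```

The synthetic section truly occupies 264 220 px with 25 % of its area
stained; the segmented ROI (274 132 px) is ~3.8 % larger because the
dilation step pads the tissue boundary by a few pixels, and the measured
stained area percentage (24.10 %) recovers the generated stain load to
within one percentage point. The defocused noise blobs on the slide
contribute nothing: they are erased by the HOS step.

The same pipeline runs from the shell:

```bash
stainquant synth --scenario sweep --seed 0 --out slides/
stainquant run --input slides/ --out results/ --method sq --stain AR
stainquant compare results/report.csv benchmark.csv --out stats.csv
```

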