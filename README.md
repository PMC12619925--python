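# chromentropy

Quantifies **color variegation** in photographs of pigmented skin lesions as
the **Shannon entropy of the gray-level histogram** inside a polygonal region
of interest (ROI), with a **relative entropy** score against a
perilesional-skin internal control.

Color variegation (polychromia) is among the most sensitive dermoscopic signs
of melanoma — the "C" of the ABCD rule — but is usually judged by eye.
chromentropy turns it into a continuous, reproducible number computable from
an ordinary smartphone photograph: the lesion and a patch of adjacent healthy
skin are outlined as polygons (e.g. with Fiji/ImageJ's polygonal selection
tool), the image is reduced to 8-bit grayscale, and each ROI's 256-bin
histogram is summarized as

```
H  = -Σᵢ pᵢ · log₂(pᵢ)          (bits, 0 ≤ H ≤ 8)
ΔH = H_lesion − H_control       (bits)
```

where `pᵢ` is the fraction of ROI pixels with gray value `i`. H is 0 for a
perfectly homogeneous region and 8 for one uniform over all 256 levels; ΔH
corrects for the baseline heterogeneity of the patient's own skin (age,
phototype, photodamage). ΔH here is a plain difference of entropies, not a
Kullback–Leibler divergence. The package computes the metric only — it
proposes no diagnostic threshold and does no lesion classification.

Intended users: dermatology and imaging researchers evaluating chromatic
heterogeneity metrics, and developers of teledermatology pipelines who need a
transparent, dependency-light reference implementation with a validated
synthetic-phantom test bed.

## Worked example

Generate a synthetic lesion scene (uniform-over-16-levels "lesion" on a
constant "skin" background, with lesion and control ROIs written alongside),
then score it:

```bash
chromentropy phantom --kind lesion --width 256 --height 256 --seed 7 --out-prefix scene
chromentropy delta --image scene.png --roi scene_lesion.json \
    --control-roi scene_control.json --out -
```

which prints

```
label,roi_pixels,h_bits,delta_h_bits
lesion,23040,4.00,+4.00
control,29184,0.00,
```

The lesion ROI's gray values are spread uniformly over 16 levels, so its
entropy is log₂(16) = 4.00 bits; the constant background scores 0.00 bits;
ΔH is their difference, `+4.00`. The control row's ΔH cell is empty — only
lesions are scored against the control. On real photographs the same command
takes a PNG/TIFF/JPEG plus ImageJ `.roi` files or polygon-JSON files.

The same computation in Python:

```python
import chromentropy as ce

img = ce.load_image("scene.png")
lesion = ce.load_roi("scene_lesion.json")
control = ce.load_roi("scene_control.json")
h_lesion = ce.compute_roi_entropy(img, lesion, label="lesion")
h_control = ce.compute_roi_entropy(img, control, label="control")
print(ce.relative_entropy(h_lesion, h_control).delta_h_bits)  # ≈ 4.0
```

`--grayscale mean` (default, ImageJ-style unweighted RGB mean) or
`--grayscale luma601` (BT.601 luminance) selects the grayscale conversion;
results record which was used, and ΔH refuses to compare across conventions.

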