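# cfucount

Seeded, prototype-driven enumeration of bacterial colony forming units
(CFUs) from petri-dish photographs, with color-based classification
(e.g., blue/white screens).

The user clicks (or passes) one representative colony per color class.
From that *a priori* prototype the pipeline:

1. detects the dish region of interest and median-denoises the image
   (`plate_io`);
2. flood-fills each seed into a prototype whose gray level, hue, size and
   shape parameterize everything downstream (`prototype`);
3. searches adaptive-threshold parameters (window size `s`, offset `C`) so
   that the grayscale histogram of the binarized foreground is unimodal,
   contains the prototype's gray value, and has maximal area under its
   peak; per-color masks are OR-combined (`binarize`);
4. extracts contours, computes five shape/color features each, clusters
   them with DBSCAN (eps from the k-distance knee, min-samples from the
   1/5-of-contours rule), and accepts the single-colony cluster members
   passing prototype-relative cut-offs (`cluster_filter`);
5. splits the remaining merged/irregular regions by watershed seeded at
   local gray-level minima (colony centers are darker than their rims) that
   pass a prominence noise tolerance, and prunes the resulting segments
   against the single-colony statistics (`separate`);
6. assigns a color label per detection and writes counts, a per-detection
   CSV, and an annotated overlay (`report`).

A fully annotated synthetic plate generator (`synth`) renders every imaging
condition the algorithm exploits — bright dish on dark surround, radial
colony darkening, overlaps, border-crossing colonies, illumination
gradients, downscaling and JPEG noise — so the pipeline is testable without
any external data.

## Command line

```sh
# count a plate; one --seed x,y,label per color class
cfu-count --image plate.png --seed 512,430,blue --seed 300,200,white \
          --out results/ [--roi cx,cy,r] [--config cfg.toml] [--debug]

# generate a synthetic plate with ground truth
cfu-synth --spec spec.json --out fixtures/
```

`cfu-count` writes `counts.json`, `detections.csv` and `overlay.png` into
the output directory. All `RunConfig` keys (flood tolerance, Savitzky-Golay
window, search grids, DBSCAN cap, pruning bands, ...) can be set in a TOML
config file; command-line flags take precedence over the file, which takes
precedence over the defaults.

Conventions: coordinates are `(x, y)` = (column, row), 0-based; grayscale
is BT.601 luma; hue is in degrees (0-360) and always compared circularly.

## Python API

```python
from cfucount import count_plate, load_image, RunConfig

image = load_image("plate.png")
result = count_plate(image, seeds=[(512, 430, "blue"), (300, 200, "white")],
                     config=RunConfig())
print(result.report.per_label, result.report.total)
```

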