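# spinedss

Decision support for lumbar disc herniation (LDH) from T2-weighted MRI.
`spinedss` implements the full reading pathway a spine surgeon follows —
as a library plus a CLI — and ships a seeded phantom generator so every
stage can be tested end to end with exact ground truth:

1. **Vertebra localization** (sagittal): a pluggable detector proposes
   vertebral-body centers; the ordered chain P1..Pn is then repaired with
   anatomical constraints. With Vi = |Pi+1 − Pi|, every interior point
   must satisfy the distance constraint λ1 < Vi/Vi−1 < λ2 and the angle
   constraint θ1 < ∠(Pi→Pi−1, Pi→Pi+1) ≤ θ2, with defaults λ1 = 0.6,
   λ2 = 1.25, θ1 = 140°, θ2 = 180°. Violating points are re-estimated
   from their trusted neighbors.
2. **Herniation diagnosis** (sagittal): the posterior disc ROI — an
   oriented rectangle on the line between adjacent vertebra centers,
   extending a fixed 44 px dorsally — is classified herniated/normal.
3. **MSU classification** (axial): six marker points (disc center, dorsal
   canal point, and the ventral apices of the superior and inferior
   articular processes, plus the posterior disc margin) define a grid;
   the herniated area is segmented (pluggable; reference = thresholding
   in the retro-discal band) and the apex of the herniation assigns size
   1/2/3 and zone A/B/C.
4. **Pfirrmann grading** (I–V): a 572-dimensional descriptor —
   64-bin intensity histogram (HPI) + 256-bin local binary patterns (LBP)
   + 252-bin pyramid HOG (PHOG) — feeds a 572-300-150-5 multi-layer
   perceptron trained by stochastic gradient descent.
5. **Treatment advice**: a deterministic rule table (MSU-1 →
   conservative; MSU-2/3 → surgical consideration, zone A → posterior
   approach / MED, zones B/C → lateral PTED/OLIF; Pfirrmann > 3 → flag
   interbody fusion), with every recommendation traced to rule ids.

Evaluation utilities cover specificity, sensitivity, precision, accuracy,
DSC = 2TP/(FP+2TP+FN), IoU = TP/(FP+TP+FN), Fleiss' kappa, and
reader-study arithmetic (relative accuracy improvement and time
reduction).

## Worked example

```bash
spinedss simulate --kind sagittal --n 12 --seed 9 --out sag
spinedss simulate --kind axial --n 2 --seed 6 --out ax
spinedss localize sag/sagittal_000.png --out loc.json
spinedss train-diagnosis sag --out dx.model
spinedss train-pfirrmann sag --epochs 60 --out pf.model
spinedss msu ax/axial_000.png --markers ax/axial_000.json --out msu.json
```

The `localize` call prints `localized 6 vertebrae -> loc.json`: six
vertebral bodies found and chained cranial→caudal, with any
anatomically implausible center replaced (the JSON records
`repaired_indices`). The `msu` call prints `MSU 2-B -> msu.json`: the
segmented herniation's apex fell between the half-way line and the
intra-facet line (size 2), lateral of half the facet offset (zone B) —
an MSU label that the advice engine maps to surgical consideration via a
lateral approach. Programmatic use mirrors the CLI:

```python
from spinedss import phantom, localization, msu

cfg = phantom.PhantomConfig(seed=0)
ax = phantom.generate_axial(cfg, target_msu=(2, "B"), seed=7)
label = msu.classify_msu(ax.markers, ax.mask_truth)
print(label)            # 2-B
```

## Layout

- `src/spinedss/phantom.py` — seeded sagittal/axial phantom generators
- `src/spinedss/localization.py` — detection interface + constraint repair
- `src/spinedss/diagnosis.py` — posterior-strip ROI + binary classifier
- `src/spinedss/msu.py` — marker grid, segmentation, apex, size/zone
- `src/spinedss/pfirrmann.py` — HPI/LBP/PHOG features + 572-300-150-5 MLP
- `src/spinedss/metrics.py` — overlap metrics, Fleiss' kappa, reader study
- `src/spinedss/decision.py` — rule table and structured reports
- `src/spinedss/io.py`, `src/spinedss/cli.py` — formats, manifest, CLI
- `docs/methods.md` — models, parameters, and design notes
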