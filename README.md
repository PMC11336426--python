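# rbcsmear

Biophysical profiling of red blood cells (RBCs) from thin-film blood-smear
images.

Deformability — an RBC's ability to squeeze through capillary-sized
constrictions — is a biomarker of blood quality: it degrades with cold
storage (the storage lesion) and in disorders such as sickle cell disease
and malaria.  Measuring it directly requires specialized microfluidics and
expert operators.  `rbcsmear` implements the alternative: learn to read
deformability from ordinary Giemsa-stained blood smears, which every
clinical laboratory already produces.

The package is aimed at researchers in transfusion medicine and biomedical
image analysis who want a fully testable, end-to-end reference
implementation of this pipeline:

* **rigidity scoring** — a microfluidic ratchet sorts cells into 12 outlets
  by deformability; the rigidity score (RS) is the outlet number at the
  50 % crossover of the linearly interpolated cumulative distribution,

  $$RS = \min\{x : F(x) = 0.5\},\qquad F(k)=\tfrac1N\sum_{i\le k}c_i ,$$

  discretized into four deformability classes (RS < 2.50, 2.50–2.74,
  2.75–2.99, > 2.99) that label the images;
* **tiling** — 2424×2424 px smear scans are cut into 81 non-overlapping
  256×256 tiles, cleaned of empty and occluded tiles, split 10,000/2,000
  per class with five validation folds, and augmented by right-angle
  rotation and horizontal flips;
* **CNN** — five conv blocks (256·7², 128·5², 64·3², 32·3², 16·3², each
  with ReLU, batch norm, 2×2 max pool) into three fully connected blocks
  with 20 % dropout, with softmax heads for storage-week (3) or
  deformability-bin (4) classification or a linear head for RS regression;
  implemented as a compact numpy engine with full backprop;
* **training & evaluation** — SGD with Nesterov momentum 0.90, plateau
  early stopping, five-fold cross-validation, leave-one-donor-out
  generalization, macro precision/recall/F1, row-normalized confusion
  matrices, MAE/MSE/RMSE/Pearson-r/R²;
* **saliency** — absolute input-gradient maps with warm-colormap overlays
  and a cell-concentration score against ground-truth masks;
* **synthetic smears** — a generator for Giemsa-like scans of discocytes
  (discs with central pallor) and echinocytes (spiculated boundaries,
  $r(\theta)=r_0(1+a\cos k\theta)$) plus a latent-rigidity sorting
  simulator, so the whole pipeline is verifiable without the study's
  (undeposited) donor images.

## Worked example

Score a sorting run and inspect the network:

```bash
$ cat outlets.csv
donor_id,storage_week,outlet_1,...,outlet_12     # counts per outlet
d1,0,0,0,30,0,0,0,0,0,0,0,0,0

$ rbcsmear rs outlets.csv
donor_id  storage_week  n_cells  rs  bin_index
      d1             0       30 2.5          1
```

All 30 cells sit in outlet 3, so the cumulative curve rises from (2, 0) to
(3, 1) and crosses 50 % at RS = 2.5 — deformability class 1 (RS 2.50–2.74).

Run the full desk-scale pipeline on synthetic data (simulate → score →
tile → filter → split → train → evaluate → saliency):

```bash
$ rbcsmear run --seed 5 --out runs/demo
{
  "config_hash": "58b71c7605b0ab5b",
  "tile_counts": { "raw": 1500, "after_empty": 1500, "after_occlusion": 1474 },
  "saliency_concentration_mean": 0.358,
  "runtime_s": 180.6
}
{
  "accuracy": 0.772,
  "precision": 0.779,
  "recall": 0.772,
  "f1": 0.773
}
```

Three synthetic storage classes (echinocyte fractions 0.05/0.35/0.70) are
rendered, tiled and filtered; a 1/8-width network trains on 300 tiles per
class for ~3 minutes and reaches 77 % held-out accuracy — far above the
33 % chance level.  `runs/demo/` holds the scored RS table, tile manifest,
model checkpoint, saliency maps and overlays for a few test tiles (with
their mean cell-concentration score printed above), and a `report.json`,
each stamped with the config hash.

In Python:

```python
from rbcsmear.rigidity import OutletDistribution, compute_rigidity_score, assign_bin

d = OutletDistribution("d1", 0, (0, 10, 20, 10, 0, 0, 0, 0, 0, 0, 0, 0))
score = compute_rigidity_score(d)   # RigidityScore(rs=2.5, n_cells=40)
assign_bin(score)                   # 1
```

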