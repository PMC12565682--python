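# mvskel

Multiview hierarchical classification of skeletal abnormalities in mouse
whole-body X-rays.

High-throughput mouse phenotyping pipelines image every specimen in two
full-body projections — dorsoventral (DV) and lateral (LAT) — and expert
screens annotate up to 53 distinct skeletal abnormalities, several of which
frequently co-occur in one animal.  Single-view classifiers struggle here:
an abnormality confined to the sagittal plane (kyphosis, lumbar
displacement) is nearly invisible dorsoventrally, and vice versa.  `mvskel`
is a tool for researchers working with such data.  It:

* builds a compact **specimen-wise multiview composite** — the pixel-wise
  mean of the DV acquisitions, the mean of the LAT acquisitions, and a
  weighted blend of their Canny edge maps, stacked as three channels;
* derives **three-level hierarchical labels**: L1 normal/abnormal, L2
  anatomical subclass set {Spine, Ribcage, Whole-body}, L3 localized
  subclass set (ten classes) — a 13-slot binary vector per specimen;
* trains two **hierarchical classifier families** on the composites: a
  backbone-driven chain (CNN trunk + GAP/dense L1 head, conv/dense L2 and
  L3 heads) and a convolutional-autoencoder-driven chain (MSE-trained
  encoder latent + dense probe heads), each level consuming the previous
  level's penultimate representation with lower levels frozen;
* evaluates **single-view versus multiview** inputs with a multi-seed,
  stratified 70/20/10 protocol using threshold-free per-class ROC-AUC; and
* explains decisions with **class activation maps** overlaid on the input.

A bundled phantom-skeleton generator emulates the structure of multi-center
phenotyping data (two views, repeated acquisitions, imbalance, co-occurring
abnormalities with view-dependent visibility), so the entire pipeline runs
and is tested without any external data.  See `docs/methods.md` for the
model details and design decisions.

## The hierarchy in brief

With `A` the abnormality vocabulary and `f(i) ⊆ A` an image's annotations:

* L1(i) = abnormal iff |f(i)| ≥ 1
* L2(i) = { g2(a) : a ∈ f(i) },  g2 : A → {Limbs, Ribcage, Skull, Spine, Whole-body}
* L3(i) = { g3(a) : a ∈ f(i) },  g3 : A → {Caudal, Thoracic, Cervical,
  Lumbar, Morphology, Shape, Digits, Fusion, Joints, Other}

Specimen labels are unions over the specimen's images; Skull and Limbs are
excluded from the modelled L2/L3 bits (codes there still count toward L1).
Classification is multi-label at L2/L3: the model outputs 1 + 3 + 10
sigmoid probabilities, no thresholding applied.

## Worked example

Generate a phantom dataset, curate composites, and run the single-view vs.
multiview comparison (CAE family, one seed here for brevity):

```python
from mvskel import (load_taxonomy, PhantomConfig, generate_records,
                    CurationConfig, curate_dataset,
                    SplitSpec, ExperimentConfig, run_experiment)

tax = load_taxonomy()                       # bundled 53-code taxonomy
cfg = PhantomConfig(n_specimens=600, image_size=(64, 64),
                    abnormal_fraction=0.5, seed=11)
records, labels = generate_records(cfg, tax)
ds = curate_dataset(records, tax, CurationConfig(target_size=64))
report = run_experiment(ds, tax, SplitSpec(seeds=(0,)), ExperimentConfig())
print(report.per_level.to_string(index=False))
```

```
view_mode  level  mean_auc  n_classes_skipped
       DV      1  0.913793                  0
       DV      2  0.961111                  0
       DV      3  0.912638                  1
      LAT      1  0.903226                  0
      LAT      2  0.837430                  0
      LAT      3  0.871914                  1
       MV      1  0.993326                  0
       MV      2  0.988889                  0
       MV      3  0.982579                  1
```

Each row is the unweighted mean AUC over that level's classes on the
held-out test split (level 1 = the binary normal/abnormal decision; levels
2 and 3 are evaluated on abnormal test specimens).  The skipped class is
digit fusion, whose Limbs parent is excluded from the modelled label bits,
so it never has positive labels.  The pattern mirrors the motivating
phenomenon: all three input modes separate normal from abnormal well
(L1 ≈ 0.92–0.99), but at the granular levels the single views fail on the
classes hidden in their orthogonal plane (e.g. DV on cervical/lumbar
displacement, LAT on rib fusion), while the multiview composite sees both
planes and dominates.

The same workflow is available from the shell:

```sh
mvskel generate --out raw --n-specimens 600 --image-size 64 --seed 11
mvskel curate   --metadata raw/metadata.csv --image-root raw --out curated --target-size 64
mvskel evaluate --curated curated --out results --family cae --seeds 0,1,2
mvskel train    --curated curated --out model --family cae
mvskel explain  --model model/model.npz --composite curated/composites/S00000.png --out xai
mvskel summarize --metadata raw/metadata.csv --out summary.csv
```

For real radiograph collections, point `curate` at a metadata CSV with
columns `specimen_id,view,path,codes` (codes semicolon-separated; views
DV/LAT, case-insensitive) and 8/16-bit grayscale PNG/TIFF images.  Public
mouse phenotyping radiographs of this form are distributed by the
International Mouse Phenotyping Consortium (https://www.mousephenotype.org/).

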