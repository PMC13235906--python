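# taxovision

Taxonomy-aware image classification for hierarchically structured organisms
— built with cryptic coral-reef fishes in mind, where thousands of small,
bottom-dwelling species differ only in subtle markings and a flat classifier
happily assigns a species to the wrong family.

`taxovision` predicts **family, genus and species simultaneously** with a
multi-output convolutional network and makes the biological hierarchy part
of both training and evaluation:

- **Model.** A convolutional backbone (a compact `small_cnn` for desk-scale
  work, or a pre-activation ResNet-50) feeds a Squeeze-and-Excitation block,
  global max-pooling and a shared dense embedding with three parallel
  softmax heads. Four *fusion* strategies control how a parent head informs
  its child head: `std` (independent heads), `concat` (embedding ⧺ parent
  logits), `gated` (per-dimension sigmoid gate *g* blending the embedding
  *e* with a transform *t* of the parent logits, *g⊙e + (1−g)⊙t*), and
  `att` (a sigmoid attention mask multiplying the embedding).
- **Loss.** The taxonomy-focal cross-loss. Per rank, focal cross-entropy
  `L(p_t) = −α(1−p_t)^γ log p_t` emphasises hard, rare taxa; the genus and
  species terms add a soft consistency penalty `λ·(−log p_parent)` on the
  probability the *parent head* assigns to the true label's parent, and the
  total is `L_fam + L_gen + L_spe`.
- **Evaluation.** Per-rank accuracy/macro-precision/recall/F1, the
  **Taxonomic Alignment Score** (TAS) — the fraction of samples whose
  predicted (family, genus, species) argmax triple forms a valid parent
  chain, `TAS = (1/N) Σ 1[parent(gᵢ)=fᵢ ∧ parent(sᵢ)=gᵢ]` — plus
  alignment-given-miss partial credit, expected calibration error with
  reliability curves, paired McNemar tests and per-species error binning.
- **Data tooling.** Folder-hierarchy ingestion (`root/Family/Genus/Species/`),
  a QC pipeline (64-bit average-hash duplicate removal, Laplacian-variance
  blur and resolution flagging, a minimum-images-per-species filter) and a
  species-stratified 70/15/15 split.
- **Interpretability.** Guided-backpropagation saliency maps for the species
  head, with normalization, pooled statistics and pseudocolor overlays.
- **Synthetic data.** A generator rendering specimen images whose body shape
  encodes family, hue encodes genus and marking pattern encodes species, in
  clean "lab" and degraded "web" regimes — so the full pipeline is testable
  without any real imagery.

The neural-network core (reverse-mode autodiff, conv/pool/batch-norm/dense
layers, Adam) is implemented in pure numpy under `taxovision.nn`, which
keeps the package dependency-light and makes the guided-backprop rule and
every gradient directly testable against finite differences.

## Worked example

```python
import numpy as np
from taxovision import SyntheticSpec, generate_dataset, TaxonomicClassifier
from taxovision.dataqc import stratified_split

dataset = generate_dataset(SyntheticSpec(
    n_families=3, n_genera=6, n_species=12, images_per_species=60,
    image_size=32, seed=7))
split = stratified_split(dataset.manifest, seed=7)
train = dataset.manifest["path"].isin(set(split.subset_ids("train"))).to_numpy()
test = dataset.manifest["path"].isin(set(split.subset_ids("test"))).to_numpy()

clf = TaxonomicClassifier(taxonomy=dataset.tree, fusion="gated",
                          embedding_dim=64, base_channels=8,
                          stage1_epochs=12, stage2_epochs=0, random_state=0)
clf.fit(dataset.images[train], dataset.labels[train])
report = clf.evaluate(dataset.images[test], dataset.labels[test])
print(f"species accuracy: {report['per_rank']['species']['accuracy']:.3f}")
print(f"genus accuracy:   {report['per_rank']['genus']['accuracy']:.3f}")
print(f"family accuracy:  {report['per_rank']['family']['accuracy']:.3f}")
print(f"TAS:              {report['tas']:.3f}")
print(f"species ECE:      {report['ece']['species']:.3f}")
```

prints

```
species accuracy: 0.630
genus accuracy:   0.917
family accuracy:  1.000
TAS:              0.833
species ECE:      0.198
```

Read: after a short training run on 504 synthetic images the model resolves
the coarse ranks almost perfectly (family 1.00, genus 0.92) and two thirds
of species; 83% of its predicted triples form a biologically valid
family→genus→species chain (a uniformly random triple would be consistent
only 5.6% of the time); the species head is still over-confident (ECE 0.20),
which longer training reduces.

`TaxonomicClassifier` is a scikit-learn estimator (`fit` / `predict` /
`predict_proba` / `get_params`), so it composes with sklearn model
selection. The same workflow is available from a shell:

```sh
taxovision generate data/ --families 3 --genera 6 --species 12 --per-species 60
taxovision qc data/ --near-dup-hamming 0 --report qc.json
taxovision split data/ --seed 7 --out split.csv
taxovision train data/ --fusion gated --checkpoint model
taxovision evaluate model data/ --report eval.json
taxovision saliency model data/Fam01/Gen001/"Gen001 sp001"/Gen001_sp001_000.png "Gen001 sp001" --out overlay.png
```

Experiment harnesses `taxovision.train.compare_fusions` (all four fusion
kinds under identical conditions, with pairwise McNemar tests) and
`compare_data_regimes` (degraded-only vs 50:50 mixed training data of
matched size) reproduce the two study designs at desk scale.

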