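# gpcrcontacts

Spatiotemporal analysis of the GPCR:Gα protein interface, for structural
bioinformaticians studying G protein coupling selectivity from molecular
dynamics (MD) ensembles.

G protein-coupled receptors couple to Gα subfamilies (Gs, Gi, Gq, G12/13)
with anywhere from strict selectivity to broad promiscuity. This package
implements the contact-level view of that behavior: which receptor:Gα
residue contacts form during a simulation, how *persistently* they form,
which of them are shared across subfamilies ("common contacts") versus
unique to one ("subfamily-specific contacts"), and which contacts a linear
discriminant model identifies as the signature — the *spatiotemporal code*
— of each coupling class.

## What it computes

* **Contact detection.** Per frame, all sidechain–sidechain contacts
  between the receptor and Gα selections, by five strict geometric
  criteria: salt bridge (< 4.0 Å anion–cation), hydrogen bond (< 3.5 Å
  donor–acceptor, < 70° D→H/D→A angle when hydrogens are present), van der
  Waals (distance < r_i + r_j + 0.5 Å), π-stacking (< 7.0 Å between ring
  centroids, < 30° between ring normals) and cation–π (< 6.0 Å
  cation–centroid, < 60° off the ring normal). Contacts are keyed by
  generic residue numbers (GPCRdb `3x53` / CGN `G.H5.19`), supplied as a
  TSV map.
* **Fingerprints and persistence.** Per-frame binary fingerprints
  (frames × contact pairs), per-system contact frequencies
  f(p) ∈ [0, 1], and the persistence taxonomy: a pair is persistent in a
  class when f(p) > 0.2 in at least one of that class's systems;
  persistent in exactly one class ⇒ *specific*, in all three ⇒ *common*.
* **Selectivity code.** A three-class LDA (SVD solver) on the fingerprints
  gives per-class weights w_X(p); the composite score
  wGx(p) = w_X(p) · cGx(p), with cGx the mean class frequency, ranks
  contacts, and the top 10 per class form the spatiotemporal code. New
  fingerprints (e.g. an engineered promiscuous receptor) can be projected
  into the discriminant plane and classified.
* **Promiscuity index.** Coupling tables from three dataset styles are
  harmonized to categorical scores (primary = 1, secondary = 0.5,
  none = 0; Emax > 0.8 ⇒ primary, 0.2 < Emax < 0.8 ⇒ secondary), averaged
  over the four subfamilies per dataset, weighted 4/2/1 by assay
  directness, and averaged into a composite in [0, 4].
* **Synthetic data.** Toy two-chain complexes that trigger each geometric
  criterion on purpose, and planted Bernoulli fingerprints with known
  common/specific/background structure, so the whole pipeline is testable
  without downloading trajectories.

## Worked example

Generate a planted fingerprint dataset (3 classes × 2 systems × 500
frames, 34 contact pairs), classify persistence, fit the LDA and extract
the code:

```python
from gpcrcontacts import (PlantedSpec, generate_fingerprints, frequencies,
    classify_persistence, fit_lda, class_mean_frequencies,
    composite_scores, extract_code, holdout_accuracy)

planted = generate_fingerprints(PlantedSpec(seed=7))
freq = frequencies(planted.matrix)
labels = classify_persistence(freq, planted.system_to_class, threshold=0.20)
print("label counts:", labels.labels["label"].value_counts().to_dict())

model = fit_lda(planted.matrix)
evr = model.explained_variance_ratio
print(f"explained variance: {100*evr[0]:.2f}% / {100*evr[1]:.2f}%")
print(f"holdout accuracy: {100*holdout_accuracy(planted.matrix, seed=7):.2f}%")

scores = composite_scores(model, class_mean_frequencies(freq, planted.system_to_class))
code = extract_code(scores, k=10, persistence=labels)
print(code[code["class"] == "Gs"].head(4).to_string(index=False))
```

prints

```
label counts: {'other': 20, 'common': 5, 'specific-Gs': 3, 'specific-Gi': 3, 'specific-Gq': 3}
explained variance: 50.78% / 49.22%
holdout accuracy: 93.83%
class  rank    pair_key      wGx   cGx persistence_label in_pdb
   Gs     1 1x46:G.H5.7 2.634286 0.599       specific-Gs   None
   Gs     2 1x47:G.H5.8 2.465768 0.582       specific-Gs   None
   Gs     3 1x45:G.H5.6 2.316775 0.580       specific-Gs   None
   Gs     4 1x44:G.H5.5 0.028660 0.607            common   None
```

The persistence labels recover the planted structure exactly (5 common,
3 specific pairs per class, 20 background pairs). The holdout accuracy of
93.8% reflects the default noise level (specific contacts occupied 60% of
frames in their own class); the three planted Gs-specific pairs top the
Gs code by composite score, followed by a common contact whose weight is
near zero but whose frequency is high.

The same stages are available from a shell. A full run — detection over
multi-model PDB trajectories, fingerprints, persistence, LDA, code,
report and manifest — is one command:

```bash
contacts run --config run.toml
```

with per-stage commands (`contacts detect`, `contacts fingerprint`,
`contacts persist`, `contacts lda fit/code/project`,
`contacts promiscuity`, `contacts synth fingerprints/complex`) for
piecemeal use; see `contacts --help`.

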