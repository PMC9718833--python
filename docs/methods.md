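# Methods

This note documents the models, conventions and design choices behind the
package, in the order the pipeline runs them.

## Coordinate and naming conventions

Coordinates are Ångström throughout. Frame indices are 0-based and frame
windows are half-open `[start, end)`; a window is applied to each
replicate file before concatenation, so an ensemble built from the tail
windows of several replicates preserves replicate order, then frame
order. A residue is identified by `(chain, resnum)`; insertion codes are
rejected because MD-derived PDB files do not carry them. An atom is a
sidechain atom exactly when its name is not one of `N, CA, C, O, OXT`
(glycine therefore has no sidechain heavy atoms). Generic residue numbers
— GPCRdb style (`3x53`, `34x51`) on the receptor side, CGN style
(`G.H5.16`) on the Gα side — are consumed from user-provided TSV tables
and never computed from structure: assignment is a database service, and
recomputing it is out of scope. Contact pairs are keyed
`"<gpcr>:<gprot>"`, e.g. `3x53:G.H5.19`.

## Contact criteria

Five criteria define a sidechain–sidechain contact; all inequalities are
strict, and all thresholds are configurable on `ContactCriteria`:

| type | criterion | default |
|------|-----------|---------|
| SB   | anion–cation atom distance | < 4.0 Å |
| HB   | donor–acceptor heavy distance, D→H vs D→A angle | < 3.5 Å, < 70° |
| VDW  | heavy-atom distance vs r_i + r_j + slack | slack 0.5 Å |
| PS   | ring-centroid distance, ring-normal angle | < 7.0 Å, < 30° |
| PC   | cation–centroid distance, off-normal angle | < 6.0 Å, < 60° |

The van der Waals form follows the getcontacts convention (sum of Bondi
radii plus a 0.5 Å slack); the widely circulated shorthand "< 2 Å
difference between two atoms" is ambiguous as written, so the radius-sum
form is used and the slack exposed. Ring normals and the ring-to-cation
direction are treated as unsigned axes: angles are folded into [0°, 90°]
before comparison, so the criteria are invariant to ring atom ordering
and to which face the partner approaches.

Atom-level chemistry tables are explicit in `contact_detection`:
carboxylate oxygens of Asp/Glu as anions; Lys NZ and Arg NE/NH1/NH2 as
cations (His ND1/NE2 join the cation set only when `his_cation=True`,
since the protonation state is ambiguous at neutral pH); standard
sidechain donor/acceptor sets for hydrogen bonds; Phe/Tyr/His rings plus
both Trp rings as aromatic systems. Hydrogens are paired to their donor
heavy atom by a 1.25 Å covalent-distance rule in the first frame.

Hydrogen handling is auto-selected: if the structure carries sidechain
hydrogens, the hydrogen-bond angle term is evaluated; otherwise detection
runs in heavy-atom mode (distance only) and the mode is recorded in the
timeline metadata, so outputs are never silently mixed.

Detection prefilters residue pairs by sidechain-centroid distance
(12 Å default) with a k-d tree before evaluating criteria. With default
cutoffs (≤ 7 Å) plus maximal sidechain extents this prefilter is
lossless; the test suite verifies equality against the O(n²) all-pairs
path on jittered toy ensembles, and `prefilter=False` forces that path.

## Fingerprints, frequencies, persistence

Timelines are one-hot encoded into frames × pairs binary matrices; all
contact types collapse to a single bit per residue pair per frame, since
the analysis is pair-level. The pair universe is the union of observed
pairs minus those whose receptor-side generic position is not resolved in
every system (a region filter that keeps the feature set comparable
across complexes); Gα-side filtering exists but is off by default.
Per-system frequencies are exact column means.

A pair is *persistent* in a class when its frequency strictly exceeds the
threshold (default 20%) in at least one of that class's systems.
Persistent in exactly one class ⇒ `specific-<class>`; in all three ⇒
`common`; everything else is `other`, sub-labelled `dual` (persistent in
exactly two classes) or `never`. These five labels partition the
universe, and raising the threshold can only shrink the persistent sets.

Composition summaries report the percentage of a pair set per secondary
structural element (TM helices, intracellular loops, H8 on the receptor;
H5, strands and loops on Gα), rounded half-up to one decimal so a chart's
percentages sum to 100 within 0.1.

## Discriminant model and the code

The three-class (Gs/Gi/Gq) LDA uses scikit-learn's SVD solver with
empirical class priors. Conventions fixed for reproducibility:

* classes are ordered (Gs, Gi, Gq) regardless of input order;
* the two discriminant components are re-signed so the first nonzero
  loading of each is positive — projections are then reproducible across
  refits, and duplicating the whole dataset changes only the
  n-dependent normalization, not directions or signs;
* per-class weight vectors `w_X` use the one-vs-rest coefficient
  convention of multiclass LDA, so ranks derived from them are stable;
* the explained-variance ratios of the two components sum to 1 (a
  3-class model has exactly two between-class dimensions), and the
  components are orthogonal in the within-class-whitened metric.

The composite score is the plain product `wGx(p) = w_X(p) · cGx(p)`,
where `cGx` is the mean frequency over the class's systems. The product
is the minimal reading of "combining" a spatial weight with a temporal
frequency; no extra normalization is applied. Ties are broken by larger
|w_X(p)|, then lexicographic pair key. The top-k per class (k = 10) is
the spatiotemporal code, annotated with each pair's persistence label and
optionally whether the contact exists in the starting structure.

Holdout evaluation performs a seeded 80:20 split stratified jointly by
system and class, and fails loudly if a class is missing from the
training side. Projection of external fingerprints aligns universes by
imputing missing model pairs as 0 and dropping novel pairs (they carry no
model weight); both counts are reported so alignment loss is visible.
Note that features with zero within-class variance are absorbed into the
whitening step of the SVD solver, so perfectly noiseless synthetic
features do not contribute separation — the synthetic "separable"
condition therefore uses 0.98/0.02 occupancies rather than 1/0.

`compare_position_subsets` is the generic two-group mean comparison used
for per-position statistics (e.g. population missense-variant frequency
at code positions versus all other positions); the complement mean is
reported as absent when the subset covers every position.

## Promiscuity index

Categories map to numbers primary = 1, secondary = 0.5, none = 0. Emax
categorization is strict: > 0.8 primary, 0.2 < Emax < 0.8 secondary;
the boundary values 0.8 and 0.2 fall to the lower category, and negative
values warn and score as none. A receptor's per-dataset index is the mean
over the four subfamilies; a subfamily a dataset never measured counts as
0 in that mean (keeping the four-subfamily denominator). Dataset weights
are fixed at 4 (direct BRET activation), 2 (curated literature), 1
(chimeric-G-protein assay), reflecting how directly each measures
coupling. The composite is the mean of the weighted indices over the
datasets in which the receptor appears (bounded by [0, 4]); a flag
switches to a fixed three-dataset denominator with absent datasets as 0.
The composite is 0 exactly when every observed category is none, and
upgrading any category can never decrease it.

## Synthetic data

`generate_fingerprints` draws every matrix entry as an independent
Bernoulli variable: common pairs occupied at p = 0.6 in every class,
specific pairs at 0.6 in their own class and 0.02 elsewhere, background
pairs at 0.05 everywhere; 2 systems per class × 500 frames by default.
The pair counts (5 common, 3 specific per class, 20 background) mock a
small interface at roughly the observed proportions of common to specific
contacts. Frames are temporally i.i.d. — real MD frames are strongly
autocorrelated — so passing tests demonstrate correctness of the
marginal-occupancy statistics (frequencies, persistence, class means,
discriminant separation), not robustness to correlated sampling, force
fields or conformational kinetics. Real trajectories also yield
frequencies that drift between replicates; the planted generator's
replicates are exchangeable.

Toy complexes place idealized residues (planar regular rings, literature
scale bond lengths, no rotamer sampling) at prescribed anchor distances
and orientations, with seeded Gaussian jitter per frame. They exist to
trigger each geometric criterion deterministically and to exercise the
PDB round trip; they are not physical conformations.

Both generators are bit-reproducible for a given spec and seed.

## Problem sizes and runtime

The default test and acceptance workloads use 3,000-frame planted
datasets over 34 pairs, 20 replicate generations for code recovery, and
50-frame, ~130-atom toy ensembles for detection checks — sizes chosen so
the whole pipeline re-runs from scratch in seconds on one CPU while
keeping binomial noise (±0.05 at n = 500) far from the 0.2 persistence
threshold.

## Known limitations

* Only receptor:Gα sidechain contacts are considered — no backbone,
  water-mediated, intra-chain or Gβγ contacts.
* mmCIF input, structure-based generic-number assignment and PDB
  remediation are out of scope; multi-model PDB is the reference
  trajectory format, with XTC/DCD supported through MDAnalysis when a
  topology file is supplied.
* The exact atom-level donor/acceptor/cation tables of other contact
  tools vary; ours are explicit and documented above, and results at
  marginal geometries can differ between tools accordingly.
* Contact lifetimes/autocorrelation and per-type (SB vs HB) fingerprints
  are not modelled; persistence is a marginal-frequency notion.
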