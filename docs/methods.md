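# Methods

## 3D pharmacophoric similarity

**Conformer generation.** Each drug is parsed from SMILES; molecules with
more than 150 heavy atoms (proteins, large peptides) are rejected because
a single representative conformer is not meaningful for them. When
stereocentres are unassigned, up to three stereoisomers are enumerated and
embedded independently. Each variant gets 50 distance-geometry conformers
(ETKDGv3, seeded), minimised with MMFF94 (UFF fallback when MMFF
parameters are missing), and the single lowest-energy conformer across all
variants is retained. This "one global-minimum structure per drug" policy
is a deliberate simplification: bioactive conformations are often not the
global minimum, but the downstream similarity only needs one reproducible,
extended representative per drug, and a commercial conformational-search /
implicit-solvent pipeline is not required for that. Hydrogens are dropped
after minimisation; site perception runs on the heavy-atom graph with
implicit-H counts.

**Pharmacophore sites.** A compact SMARTS vocabulary (in
`pharmacophore3d.FEATURE_SMARTS`) assigns six site types: H-bond donor,
H-bond acceptor, aromatic ring, hydrophobic carbon cluster, positive
ionizable, negative ionizable. Each site is a sphere of radius 2 Å at the
centroid of its matched atoms; aromatic sites sit at ring centroids,
hydrophobic sites at the centroid of each connected run of
carbon-only-neighbour aliphatic carbons. Ionisation at physiological pH is
handled at typing time rather than by editing the molecular graph:
neutral carboxylic acids count as negative ionizable and aliphatic
amines/amidines/guanidines as positive ionizable (toggle
`protonate=False` to disable). Typing is what matters downstream — the
geometry of a site barely moves on (de)protonation — so this avoids a pKa
engine entirely. An empty site set is legal; such molecules score 0
against everything and a warning is logged.

**Overlap volume.** Sites are spherical Gaussians ρ(r) = p·exp(−α‖r−c‖²)
with p = 2.7 and α ≈ 0.586 Å⁻² fixed so that the Gaussian's effective
volume p(π/α)^{3/2} equals the 2 Å hard sphere (33.51 ų). The pairwise
overlap between two sites at distance d has the closed form
p²(π/2α)^{3/2}·exp(−αd²/2); the cross overlap O(A,B) sums this over all
site pairs *of identical type*, and is verified against 3D grid quadrature
to within 1% in the test suite. A hard-sphere lens-volume functional is
available behind `overlap_model="hard_sphere"` for sensitivity checks.

**Alignment.** O(A,B) is maximised over rigid transforms of B by
multi-start local optimisation: the identity pose, a centroid-matching
pose, up to 12 Kabsch poses seeded from same-type site-triplet
correspondences (deterministically subsampled when the correspondence set
is large; translation-only site-on-site seeds when fewer than three
correspondences exist), and `n_starts` random orientations drawn
sequentially from a seeded generator (so the best overlap is
non-decreasing in `n_starts`). Each start is refined by L-BFGS-B over the
six rigid-body parameters with an analytic gradient (rotation-vector
Jacobian in closed form). The returned overlap is the best value seen,
including the unrefined starts, which guarantees aligned ≥ identity-pose
overlap.

**Score.** sim3d(A,B) = O(A,B)/max(O(A,A), O(B,B)) ∈ [0, 1]. The score is
symmetric in exact arithmetic but the optimiser is not, so both alignment
directions are computed and the larger overlap kept. Matrix construction
uses a distinct deterministic per-pair seed, zeroes the diagonal
(leave-one-out) and stores exact symmetric entries. Defaults: `n_starts`
10, 50 conformers; at these settings a pair costs ≈ 0.2 s, so libraries of
a few hundred drugs are practical on one CPU and the bundled test suite
uses a 30-drug world for its 3D end-to-end checks.

## 2D comparator

166-bit MACCS structural keys (RDKit's 167-bit vector with the unused
placeholder bit 0 dropped) compared with the Tanimoto coefficient
|A∧B|/|A∨B|. A pair of all-zero fingerprints is defined to score 0
(avoids 0/0 while staying conservative).

## Reference standard and score matrices

`build_reference` collapses duplicate (drug, ADE) pairs, drops ADE columns
with fewer than 5 positive drugs (default, configurable) and reports the
prevalence positives/(drugs×ADEs). Score rules, all leave-one-out via the
zero diagonal and explicit self-exclusion:

* **max** — similarity to the nearest causing drug; per-cell provenance
  records that drug (arg-max ties broken by smallest input index; a drug
  that is the sole positive of an ADE scores 0 with no provenance).
* **double** — max over positives − max over negatives, in [−1, 1]. When
  leave-one-out empties an ADE's negative group the cell falls back to the
  max score with a warning: the negatives are unlabelled rather than
  confirmed safe, so discarding the positive-side signal would be worse.
* **average** — mean similarity over the positive group; the query drug is
  excluded from that group when it is itself a positive, for consistency
  with leave-one-out (the convention is not forced by the definition, but
  any other choice leaks the drug's own label). An empty positive set
  scores 0 with a warning.

Drug sets of Ma and Mb are intersected (Ma order preserved) with a logged
report when they differ.

## Evaluation

AUROC uses the Mann–Whitney formulation with midrank ties
(scikit-learn's `roc_auc_score`; cross-checked against exhaustive pair
counting in the tests). The global curve pools *all* drug×ADE cells —
cells of single-class ADEs included — because every cell receives a score
and a label; per-ADE curves are reported as undefined (excluded from
quartiles and histograms, never imputed) when an ADE has a single class.
Precision@k ranks with a deterministic secondary key (drug_id, ade_id) so
repeated runs are identical; the enrichment factor is the ratio of subset
to reference prevalence. Hold-out splitting partitions *cells* (not
drugs), reproducibly by seed, with the train fraction defaulting to 0.8.
Quartiles use linear-interpolation (type-7) quantiles; the AUROC histogram
uses twenty 0.05-wide bins on [0, 1] and the >0.6 / >0.75 model counts are
strict inequalities.

## Pharmacovigilance re-ranking

Signal tables carry (drug_id, ade_id, EBGM, t, p) with unique keys —
duplicate keys fail loudly since no collapsing rule would be defensible.
Identifiers are matched exactly after case-folding and whitespace
trimming; no fuzzy name matching is attempted. The inner join with the
(dense) score matrix reports retained/dropped counts. EBGM, t and the
similarity score rank descending, p ascending; each method gets pooled and
per-ADE AUROC plus precision@k against reference-standard truth labels.

## Stepwise-LDA QSAR comparator

Descriptors are an open RDKit set (24 constitutional, topological and
physico-chemical descriptors; constant and all-missing columns dropped,
remaining gaps imputed with the training median). Variable selection is
forward stepwise on Wilks' lambda: at each step the candidate with the
largest partial F enters if its p-value is below `alpha_enter` (default
0.05, no removal step), capped at five variables. The final two-class
function reports U = det(W)/det(T), the exact overall F = ((n−p−1)/p)(1−U)/U
and its p-value; classification uses scikit-learn's LDA with priors
proportional to training frequencies, and ranking quality is the AUROC of
the positive-class posterior (identical to the raw discriminant's AUROC by
monotone invariance). A model in which nothing enters predicts the prior
for every sample and scores chance-level AUROC. Under label-independent
descriptors the per-variable entry frequency is ≈ `alpha_enter` (the
max-F candidate must clear the level-α test, and P(a given variable is
that candidate and clears it) ≈ α/m·m = α), which the tests confirm over
200 simulations.

## Synthetic worlds

The generator emulates the three external inputs without any download.

* **Library** — drugs are built by decorating one scaffold per cluster
  (eight distinctive 10–16-heavy-atom cores: biphenyl, quinoline,
  spiro[5.5]undecane, benzenesulfonamide, phenylamide-piperidine,
  diphenyl ether, indole, benzothiazole) with two substituents, the second
  drawn from a four-member cluster-characteristic subset — a congeneric
  series, as real ADE-sharing drug classes tend to be. Cluster identity
  therefore drives both MACCS bits and pharmacophore arrangement by
  construction. All SMILES are validated and unique; invalid
  substituent combinations are resampled.
* **Reference standard** — each ADE belongs to one cluster (cycling);
  members are positive with probability 1−`label_noise`, non-members with
  probability `label_noise` (independent Bernoulli — the simplest
  defensible null); columns failing the ≥5-positives filter are redrawn,
  and infeasible configurations raise.
* **Signals** — for every cell, t ~ N(0,1) with a +2.5 shift mixed in for
  true pairs at weight `informativeness`; EBGM is log-normal with an
  analogous shift; p = erfc(|t|/√2) is the two-sided normal tail, strictly
  decreasing in |t|. `informativeness=0` gives label-independent noise.

What passing tests on these worlds show — and what they do not: the worlds
have clean cluster structure, uniform cluster sizes, a single scaffold per
cluster and independent label noise. Real drug libraries are chemically
heterogeneous, real ADE assignments are biased and incomplete (negatives
are unlabelled, prevalence spans orders of magnitude per ADE), and real
disproportionality statistics are correlated with reporting volume.
Recovery of planted structure demonstrates the machinery end-to-end, not
field performance on SIDER/FAERS-scale data.

A quantitative note on label noise: at `label_noise` = 0.05 with 60 drugs
in 6 clusters, each ADE acquires ≈ 2.5 spurious positives, and under the
*max* rule each spurious positive pulls its whole cluster's scores up.
Substituting a perfect cluster-membership oracle for the similarity matrix
caps the pooled AUROC near 0.86 on these worlds, and the real 2D/3D
pipelines reach ≈ 0.84 — i.e. they operate within a few percent of the
ceiling the noise model permits.

## Numerical and interface choices

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical seeds and inputs give
bit-identical matrices and files. Scores are written at 6 decimal places;
every output file starts with `#` comment lines carrying the tool version,
seed and a hash of the run configuration, and `run` echoes the full config
YAML into its output directory. Long-format CSV is the canonical
interchange for drug–ADE scores (dense matrices are reassembled on read).
SMILES tables are tab-separated `drug_id<TAB>smiles`; `#` only comments
whole lines because it is a legal SMILES bond symbol. SDF input with 3D
coordinates bypasses embedding.

## Known limitations

* Single-conformer similarity: multi-conformer shape screening is out of
  scope, so conformationally flexible drugs may be under-scored.
* The SMARTS feature vocabulary is compact by design; exotic ionizable
  groups (tetrazoles, sulfonic acids) are not typed.
* The alignment optimiser is stochastic-restart local search; scores are
  reproducible for a fixed seed but are lower bounds on the true optimum.
* The QSAR descriptor set is generic; published models built on
  proprietary descriptor engines are not numerically reproducible here.
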