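# Methods

## The classification problem

A protein crystal contains two kinds of protein–protein interfaces: the
biologically relevant ones that exist in solution, and crystallographic
contacts that are artifacts of lattice packing. Given the coordinates of a
two-partner complex (one interface per file), `bioxtal` decides whether the
interface is *bio* or *xtal* from the number and physico-chemical character
of its intermolecular residue contacts, optionally combined with surface
descriptors and externally computed interaction energies.

## Contact model

Two residues, one per partner, are **in contact** (an RC) when any
heavy-atom pair between them is *strictly closer* than the cutoff
(default 5.0 Å; the validated range is 3.5–12.5 Å and values outside it
warn). Distances exactly equal to the cutoff do not count. Hydrogens are
excluded throughout: crystal structures generally lack them, and dropping
them keeps the cutoff semantics uniform across inputs.

Residues are classed as **polar** (ASN, GLN, SER, THR), **charged** (GLU,
ASP, HIS, LYS, ARG) or **apolar** (the remaining eleven). Contacts are
binned into six class pairs — CC, CP, CA, PP, PA, AA — under the canonical
ordering charged < polar < apolar, so a polar–charged contact is a CP and
an apolar–polar one a PA (written `AP` in feature tables; the two labels
are the same bin). Per-amino-acid counts follow the one-increment
convention: a LEU–LEU contact is a single RC involving LEU and adds 1 to
the LEU count (a switch, `count_homotypic_twice`, selects the alternative
both-participants convention).

The **link density** LD = RCs / (Res1 · Res2), where Res1 and Res2 are the
number of residues on each side that participate in at least one contact,
measures how densely the interface network is wired; it is 0 for an empty
interface and at most 1.

The contact engine uses a k-d tree over each partner's atoms; a dedicated
acceptance test requires its output to be *identical* to an exhaustive
all-atom-pair distance scan on hundreds of random fixtures, so the spatial
index is an optimization with no semantic content.

## Surface model

SASA is computed with the Shrake–Rupley algorithm. Each atom's sphere of
radius (vdW + probe) carries a deterministic golden-spiral lattice of test
points (default 960; the isolated-sphere error is well under 1% at that
density), and the accessible fraction is the fraction of points outside
every neighbouring expanded sphere. There is no RNG: identical inputs give
bit-identical output. The probe radius defaults to 1.4 Å (water).

Atomic radii are the Chothia (1976)-type heavy-atom values used by
NACCESS — carbonyl carbon 1.76 Å, other carbon 1.87 Å, nitrogen 1.65 Å,
oxygen 1.40 Å, sulfur 1.85 Å — shipped in `bioxtal.surface.VDW_RADII` and
versioned as `chothia-1976/naccess`. Relative accessibility divides a
residue's SASA by the theoretical maximum ASA of that residue type in an
extended Gly-X-Gly tripeptide (Tien et al. 2013, versioned
`tien-2013-theoretical`).

**BSA** = SASA(partner 1 alone) + SASA(partner 2 alone) − SASA(complex),
clipped at zero with a warning if discretization makes it marginally
negative. Because both runs are accumulated per residue, the whole-complex
difference and the sum of per-residue burials agree to numerical identity.

**NIS** (non-interacting surface): a residue belongs to the NIS when it is
solvent-exposed in the unbound form (relative accessibility ≥ 5%) and its
relative accessibility changes by at most 5 *percentage points* on
binding. The "maximum change of 5%" rule is interpreted as an absolute
difference of the relative values, not a relative change; both thresholds
are exposed as parameters (`surface_threshold`, `nis_threshold`) for the
alternative reading. PNIS/ANIS/CNIS are the percentages of polar, apolar
and charged residues among the NIS and sum to 100 whenever the NIS is
non-empty; an empty NIS reports NaN percentages with an explicit
`nis_defined = False` flag rather than misleading zeros.

## Feature sets

Ten named sets are assembled from the profiles (`bioxtal.features`): S1
(BSA), S2 (RCs), S3 (six class pairs), S4 (S3 + NIS percentages), S5
(S3 + LD + 20 per-amino-acid counts), S6 (S4 + LD + amino acids), E1 (HS),
E2 (Eelec, Evdw, Edes), C (S6 + E2), and FINAL22 — S5 minus the five
features pruned by feature selection (K, CC, W, N, PP), the production
manifest. Energetic terms are external inputs read from a TSV keyed by
entry id; the package never computes force-field energies, and HS is
treated as a single opaque score. Trained models embed their manifest and
validate prediction inputs by feature *name*, never by column position.

## Machine-learning protocol

Five algorithm families (bagging, random forest, adaptive boosting,
gradient boosting, multilayer perceptron) sit behind one scikit-learn
estimator, `InterfaceClassifier`. `bio` is the positive class: sensitivity
is bio recall, specificity xtal recall, and accuracy (TP + TN)/(P + N) is
computed in exact rational arithmetic on the confusion counts.

* **Cross-validation**: stratified 10-fold splits, re-drawn 10 times with
  seeds derived from the run seed; the report aggregates all 100 folds
  (mean ± std) and the summed confusion matrix. Stratification is adopted
  for stability on balanced sets even though plain random splitting would
  also be defensible.
* **Grid search** is exhaustive; exact-accuracy ties are broken toward the
  simplest model (fewest base estimators, then smallest depth / hidden
  layer). `DEFAULT_GRIDS` documents candidate values per algorithm along
  the tuned axes — ensemble size (10–500) for the four ensembles, split
  features for bagging and the forest, learning rate for the boosters,
  tree depth for gradient boosting, hidden-layer size and activation for
  the network; callers supply their own grids where these do not fit.
* **Feature elimination**: a 500-tree random forest supplies
  mean-decrease-in-Gini importances; the least important feature is
  removed one at a time, the cross-validated accuracy of each subset is
  recorded, and the retained subset is the smallest one within one
  standard deviation of the best round ("no increase in accuracy",
  operationalized).
* **Final model**: a 250-tree random forest with max-features = log2 of
  the feature count, trained on the FINAL22 manifest. The neural-network
  path standardizes features inside the fold pipeline, so scaling
  statistics are learned on training data only.
* Models persist as versioned archives embedding the manifest, seed, and
  a hash of the training table; foreign or incompatible archives are
  refused at load time.

Every training and evaluation path is bit-reproducible under a fixed seed.

## Synthetic data

The generator serves two distinct purposes.

**Geometric fixtures** place two chains of single-Cα residues on a regular
grid (chain A at x = 0, chain B at x = gap, residues spaced along y, by
default at the 3.8 Å virtual Cα–Cα bond length), so the inter-residue
distance is `sqrt(gap² + Δi²·spacing²)` in closed form and the expected
contact profile at any cutoff is known by construction, independently of
the contact engine. Sequences default to a pool spanning all three residue
classes so the classification logic is exercised.

**Feature tables** sample class-conditional distributions matching
published statistics on real interfaces: biological interfaces average
91 ± 31 RCs and 2706 ± 803 Å² BSA, crystallographic ones 47 ± 11 RCs and
1698 ± 359 Å², sampled as correlated truncated normals (RCs–BSA
correlation 0.8 by default — both scale with interface size; the exact
value is a generator parameter, not an empirical claim). Class-pair counts
are multinomial with the apolar–apolar share enriched in the bio class
(0.38 vs 0.25), aliphatic amino acids (L, I, V, A) are enriched 2× in the
bio amino-acid mix, and NIS percentages are drawn from the same Dirichlet
for both classes, mirroring their observed similarity. Every row satisfies
the bookkeeping identities of real profiles (class pairs sum to RCs,
amino-acid counts lie in [RCs, 2·RCs], NIS sums to 100, LD ∈ (0, 1]).

These tables are Gaussian/multinomial *proxies*: they reproduce marginal
locations, spreads and one enrichment direction, not the full covariance,
skew or outlier structure of real interfaces, nor any evolutionary or
geometric realism. A classifier accuracy measured on them validates the
training harness (signal of the documented size is recovered; permuted
labels fall to chance), not the accuracy attainable on real structures.
Likewise the grid fixtures have no side chains, rotamers or packing, so
they validate contact counting and surface bookkeeping, not biophysics.

## Numerical choices and limitations

* Sphere-point density: 960 points/atom by default (n ≥ 100 enforced);
  SASA tests compare against a 20 000-point run of the same integrator
  and against an independent implementation at matched radii.
* Altloc policy: highest occupancy, ties to `'A'`. MSE is renamed to MET
  (SE→SD); a small table of unambiguous parent renames (SEP→SER, TPO→THR,
  PTR→TYR, HYP→PRO, CSO→CYS, MLY→LYS) is applied, other non-standard
  residues are dropped with a log entry. Residues with missing side-chain
  atoms are used as-is (no rebuilding), with a log entry.
* Ties and degenerate inputs: an empty partner yields an empty contact
  list, not an error; P + N = 0 makes accuracy undefined (error); an empty
  NIS yields NaN percentages with a flag.
* Default problem sizes in the test and acceptance harnesses (100 random
  fixtures, 2000 samples per class for the ML recovery check, 5 seeds ×
  240 samples for the elimination check) were chosen as the package's
  standard verification conditions.
* Out of scope by design: crystal-symmetry reconstruction from an
  asymmetric unit, assembly enumeration, mmCIF input, force-field
  energetics, and solvated refinement. Multi-model files default to the
  first model.
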