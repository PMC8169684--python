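# Methods

## Scope and model overview

`herbiscreen` characterises small molecules for phytotoxic potential with a
stepwise screen built from three components: a rule-based herbicide-likeness
filter, a weed-selectivity classifier (BL / G / NS) on whole-molecule
physicochemical descriptors, and a mode-of-action classifier (HRAC-style
letter classes) on structural fingerprints. Each classifier is gated by an
applicability domain so that only predictions made near the training
chemistry, with confident class probabilities, are treated as assignments.

The underlying structure–activity assumption is that compounds sharing a
scaffold tend to share a site of action, while uptake and translocation —
and hence weed-type selectivity — are governed by whole-molecule properties.
The two feature spaces are deliberately different: MACCS substructure keys
carry scaffold identity; the nine descriptors carry polarity, lipophilicity,
size and shape.

## Structure cleaning

Input SMILES are desalted (keep the fragment with the most heavy atoms,
preferring carbon-containing fragments, ties broken by lexicographic
canonical SMILES), neutralised where a neutral form exists (protonatable
cations and deprotonated anions; permanently charged centres such as
quaternary ammonium are kept charged with a warning, since bipyridinium
herbicides are genuine permanent cations), and canonicalised with RDKit.
Cleaning is idempotent; unparseable rows go to a rejection report rather
than being dropped.

## Fingerprints and key selection

MACCS fingerprints are the 166 dictionary keys (RDKit's placeholder bit 0 is
discarded; vectors index keys 1–166). Before modelling, keys are reduced to
those present in strictly more than `min_count` training compounds (default
5, i.e. "more than five"), computed on the training split only so no
information from test compounds leaks into the representation.

## Physicochemical descriptors

| name | meaning | default computation |
|---|---|---|
| HBD | O/N atoms bearing H | RDKit donor count |
| HBA | all O + N atoms | atom count |
| clogP | octanol–water partition | Crippen atom-contribution estimate |
| TPSA | topological polar surface area (Å²) | RDKit TPSA |
| RelPSA | TPSA / total approximate surface area | additive per-element vdW surface (H 7, C 10, N/O/F 9, S/Cl 16 … Å²), calibrated so typical herbicides land in 0.1–0.5 |
| net charge | #basic N − #acidic O at pH ~7 | SMARTS rule list (aliphatic amines, amidines/guanidines vs. carboxylic/sulfonic/phosphonic acid O) |
| MW | molecular weight (Da) | RDKit |
| Cat, sp3At | carbon / sp³ atom counts | atom counts |
| ShapeIndex | topological graph diameter / heavy atoms; spherical < 0.5 < linear | graph distance matrix |
| logSw | log₁₀ native water solubility (mol/L) | ESOL-style linear model in clogP, MW, rotatable bonds, aromatic proportion |
| logDiff | log₁₀ aqueous diffusion coefficient in 10⁻⁵ cm²/s | Hayduk–Laudie: D = 13.26·10⁻⁵ / (η^1.14 · V^0.589), η = 0.8904 cP (water, 25 °C), V from a LeBas additive molar-volume estimate with ring corrections |
| logD74 | distribution coefficient at pH 7.4 | pass-through only |

Any descriptor can be supplied externally per compound (`overrides`); a
supplied value wins over the computed one and is flagged. logSw, ShapeIndex
and RelPSA use open additive approximations by design; they reproduce the
ordering and rough magnitude of commercial calculators, not their exact
values, so descriptor-level comparisons against results computed with
proprietary engines should expect calculator-level disagreement.

Descriptor matrices (never fingerprints) are standardised as
(x − mean)/sd with sample (n−1) standard deviation; statistics are fitted on
the training split only and stored in the model bundle for scaling external
compounds. Constant columns are an error, not a silent pass-through.

## Clustering and validation indices

Pairwise structural dissimilarity is the Jaccard distance 1 − TC on
fingerprint bits. Agglomeration uses Ward's minimum-variance criterion
applied to the supplied dissimilarities (the squared-update "ward.D2"
convention for a precomputed distance matrix). Partitions are scored with:

* **Dunn** — minimum between-cluster single-link separation / maximum
  cluster diameter;
* **Dunn2** — minimum average between-cluster dissimilarity / maximum
  average within-cluster dissimilarity;
* **average silhouette** — mean of (b − a)/max(a, b); singleton-cluster
  members score 0;
* **adjusted Rand index** — pair-counting agreement with expected-index
  correction, for comparing a partition against reference class labels.

The indices are implemented from their definitions and cross-checked against
scikit-learn in the test suite. The cluster count `k` is always an explicit
argument.

## Splitting, tuning, metrics

Stratified splits are 80:20 per class (train count = ⌊0.8·n + 0.5⌋, at least
one test member), 50:50 for classes of 3–5 members, and classes with fewer
than 3 labelled members are excluded and treated as unclassified ("Z").
Hyperparameters are chosen by mean accuracy over repeated stratified k-fold
CV (protocol default 10 folds × 10 repeats; the fold count shrinks to the
smallest class size when a class is smaller than the fold count — the
limit of stratification for very small classes). Ties go to the earliest,
least complex grid point. The final model is refit on the whole training
set. The default random-forest grid tunes `mtry` (features per split) over
{√p/2, √p, 2√p, p/3} with 500 trees; XGBoost, RBF-SVM and Gaussian naive
Bayes are pluggable behind the same interface, but only the forest feeds the
applicability domains, because its class probabilities (fraction of trees
voting for a class) are usable without calibration.

Performance metrics follow the standard one-vs-rest formulas: sensitivity,
specificity, precision, F1, balanced accuracy per class with unweighted
macro averages, overall accuracy, and Cohen's kappa
(Po − Pe)/(1 − Pe) both per class and on the full multi-class confusion
matrix. Zero denominators yield 0 with a degeneracy flag rather than NaN.

## Applicability domains

Both gates require the maximum class probability to exceed 0.6 — the level
at which, for a well-fit forest, training compounds are uniformly predicted
correctly — and nearness to training chemistry: minimum Jaccard distance
< 0.4 (TC > 0.6 to at least one training compound) for the structural
domain, minimum Euclidean distance < 2.0 in the training-scaled
nine-descriptor space for the physicochemical domain. All four inequalities
are strict, and all four thresholds are configurable for sensitivity
analysis. The Euclidean domain uses all nine descriptors. Out-of-domain
compounds keep their predicted label in the report but are flagged
unclassified.

## Likeness rules and cascade

The six likeness families (HBD, HBA, clogP, TPSA, RelPSA, net charge) each
contribute one vote; the dual HBA/clogP bounds are a strict/lenient variant
switch. **Default variant: lenient** (HBA ≤ 7, clogP ≤ 4.5) for the
"≥ 4 criteria" gate — both variants are always runnable and both pass
fractions are reported by the acceptance script, since either choice of
variant is defensible for the gate. Lower bounds are strict, upper bounds
inclusive.

The cascade order is fixed: likeness → selectivity (physicochemical AD) →
MoA (structural AD). In strict mode a compound stops at its first failed
gate; audit mode computes every stage for every compound (gates still
determine `stage_reached`), which is what analyses of AD membership across a
whole library need. logSw and ShapeIndex never block likeness evaluation
(they are not likeness criteria) and are computed by the open approximations
when not supplied, so selectivity prediction is never blocked either.

## Synthetic data generator

The generators build molecules by attaching Poisson-distributed numbers of
substituents (halogens, methyl/alkyl, methoxy, hydroxy, amino, amide,
sulfonamide, carboxyl, trifluoromethyl) at uniformly chosen valence-safe
ring or chain positions of library scaffolds; every emitted SMILES is
canonical and survives cleaning unchanged.

* **MoA-style sets**: one distinctive scaffold per class (diphenyl ether,
  phenylurea, sulfonanilide, quinoxaline, …), shared neutral substituent
  pool, default 8 classes × 30 compounds, decoration rate 1.5. Classes are
  separable in MACCS space by construction.
* **Selectivity sets**: all classes share one scaffold library, so no
  structural signal exists; the class signal is injected through the
  substituent pools — NS: polar pool (hydroxy, amino, carboxyl, amide,
  sulfonamide) at rate 3.0 with a guaranteed donor pair, yielding low clogP
  and many acceptors; G: lipophilic pool (Cl, CF₃, alkyl) at rate 2.5 with
  no donors; BL: small scaffolds with exactly one guaranteed donor and small
  apolar extras at rate 1.2. Shifts are realised through the actual
  chemistry, never by editing descriptor values, so the descriptor pipeline
  is exercised honestly. With `descriptor_shifts={}` all classes share the
  neutral pool (null condition).
* **Novel-scaffold sets**: aliphatic/macrocyclic families (cyclododecane,
  adamantane, crown ether, spiro ketal) foreign to both libraries, for
  probing structural-AD rejection.

What the synthetic sets do **not** emulate: real herbicide chemistry and
synthesizability, class imbalance of real collections, within-class scaffold
diversity, and the descriptor correlations of real compound series. Passing
the synthetic tests therefore demonstrates that the pipeline recovers known
structure when it exists and refuses prediction when it does not — not that
any particular accuracy will transfer to real compound sets.

## Problem sizes and numerical choices

The test suite trains on 4 scaffold classes × 20 compounds and 3 selectivity
classes × 40–60 with 5-fold × 2-repeat CV and 150-tree forests; the
acceptance script uses 8 × 30 (MoA) and 3 × 60 (selectivity) with
10-fold × 3-repeat CV and 300 trees — sizes chosen so each separability and
domain property is measured with comfortable margin at interactive runtimes.
The null-condition check averages 5 seeds. Tolerances: scaled-matrix
mean/sd checks at 10⁻⁹; probability row sums at 10⁻⁹; hand-computed toy
indices at 10⁻⁶.

Degenerate inputs are errors, not silent defaults: two empty fingerprints
have no defined Tanimoto value; single-cluster partitions have no validation
indices; constant descriptor columns cannot be scaled; empty compound
tables, duplicate ids and unknown override names are rejected with the
offending name.

## Known limitations

* Open-source descriptor approximations (Crippen clogP, ESOL-style logSw,
  topological ShapeIndex, additive RelPSA denominator, LeBas molar volume)
  differ numerically from commercial calculators; likeness pass fractions
  on real libraries shift accordingly. All of them accept per-compound
  overrides when better values exist.
* The net-charge heuristic is a SMARTS rule list, not a pKa engine;
  zwitterions and unusual acidic/basic groups outside the list are scored 0.
* SVM probabilities come from Platt scaling and are not wired into the
  applicability domains.
* Ward on a non-Euclidean Jaccard matrix is a convention (the distances are
  treated as if Euclidean); results are comparable across runs of this
  package but not bit-identical to other linkage conventions.
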