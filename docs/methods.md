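# Methods

This note records the models, conventions and numerical choices behind
`bbdesign`, in the order the pipeline applies them.

## Building blocks, classes and properties

A building block (BB) is a single connected molecule carrying the defining
functional group of its class: one primary aliphatic amine
(`[NX3;H2;+0;!$([N]c);!$([N]C=O);!$([N]S)]`), one carboxylic acid
(`[CX3](=[OX1])[OX2H1]`), or — for Fmoc-amino acids — one
fluorenylmethyloxycarbonyl carbamate plus one COOH. Salts/multi-fragment
records and structures lacking the defining group are rejected at ingest
and listed in the catalog's rejection log; SMILES are canonicalised on
entry. Costs are USD per 250 mg pack; a missing cost is kept as missing,
never coerced to zero.

Physicochemical properties:

- **MW**: average-atomic-weight molecular weight (Da).
- **clogP**: Crippen atom-contribution estimate. One open estimator is
  used uniformly for BB filtering and product properties; workflows that
  mix two proprietary logP calculators for those two roles will get
  systematically different absolute values.
- **TPSA**: topological polar surface area (Å²).
- **HBD**: atom-based donor count — the number of N/O heavy atoms bearing
  at least one hydrogen. Under this convention water has one donor and a
  primary amide –C(=O)NH₂ contributes exactly one, which is what makes the
  DEL1/DEL2 scaffold delta (+1 HBD) well defined. Note this differs from
  H-count conventions (–NH₂ is one donor, not two).
- **HBA**: Lipinski acceptor count, N + O atoms.

Filter inequalities are applied verbatim: RO3 (MW < 300, clogP ≤ 3,
HBD ≤ 3, HBA ≤ 3) and RO5 (MW < 500, clogP < 5, HBD ≤ 5, HBA ≤ 10) use a
strict MW bound; standalone MW cutoffs (≤ 200/250/300 Da) are inclusive.
Fmoc-AAs are always judged on their Fmoc-removed (free amino acid) form,
since the protecting group never reaches the library product.

## Truncation

Truncation deletes every instance of the defining group(s), implicitly
restoring hydrogens: amines lose the N, acids the CO₂H carbon and both
oxygens, Fmoc-AAs the whole carbamate including its nitrogen together with
the COOH (simultaneously — the order is immaterial because the patterns do
not overlap). The transform strictly reduces heavy-atom count and is
idempotent: a truncate contains no remaining defining group, so
re-truncation is a no-op. BBs carrying more than one instance have all
instances removed and are flagged *polyfunctional*: they stay in
truncate-space analyses but are excluded from enumeration, where their
coupling product would be ambiguous. Truncations that would disconnect or
annihilate the structure (e.g. formic acid) raise an error carrying the
parent id.

## Similarity and projection

Fingerprints are binary Morgan circular fingerprints, radius 3 bonds,
2048 bits, without chirality flags (stereochemistry is outside this
model's scope). Similarity is Tanimoto; distance is 1 − T; two all-zero
fingerprints compare as 0 with a warning. Chemical-space comparisons
fingerprint *truncates*; intralibrary nn-Tanimoto summaries of a selected
library fingerprint the *intact* BBs, because there the question is
redundancy among the actual reagents. Both modes are plain function
arguments.

UMAP runs on the precomputed distance matrix with defaults
n_neighbors = 15, min_dist = 0.1, seed = 42; fixing the seed forces
single-threaded layout optimisation, making coordinates reproducible
bit-for-bit. The embedding is always fit jointly over all sets under
comparison; per-set figures are row-subsets of that one fit, so any
partition of ids concatenates back to the joint embedding exactly.
Embedded distances are treated as qualitative: tests assert cluster-level
topology (separated chemotype families stay separated), never metric
agreement with Tanimoto. Density surfaces are Gaussian KDEs (Scott's rule
by default) on a padded bounding-box grid, normalised to integrate to ~1.

## Selection

- **random** — uniform without replacement from the filtered pool.
- **diversity** — greedy max-min: seed with a random pool member, then
  repeatedly add the candidate maximising its minimum Tanimoto distance to
  the chosen set; ties break to the lowest pool index. On small pools this
  is verified against an independent loop-based oracle for every seed.
- **uniform** — walk a seeded random permutation of the pool, accepting a
  candidate iff its embedded Euclidean distance to all accepted points is
  ≥ the threshold; when a pass cannot reach k, the threshold is multiplied
  by 0.9 (floor 10⁻⁶, then a convergence error) and the walk continues.
  The realized final threshold is reported and all chosen pairwise
  distances respect it. A relaxation-free run is only guaranteed when k is
  at most the worst-case maximal packing of the point set — at tight k the
  greedy order usually cannot realize a perfect packing, and the reported
  threshold says by how much it fell short.

Default k = 192 (two 96-well plates).

## Enumeration

The single BB-linking reaction is amide condensation, as a reaction-SMARTS
transform; preconditions (exactly one eligible amine, exactly one COOH)
make each product unique, and every product obeys
MW(product) = MW(amine) + MW(acid) − 18.0153 Da to ±0.01. Enumeration is
the full cycle-1 × cycle-2 cross product; per-pair failures and upfront
exclusions (polyfunctional BBs) are logged, never silently dropped.

Scheme `DEL1` models the released compound of an Fmoc-AA-first design:
deprotect the Fmoc, convert the amino acid's COOH to the pendant primary
amide left by photocleavage, then couple its amine to the cycle-2 acid.
Scheme `DEL2` couples the cycle-1 primary amine directly; the linker
attachment point of the on-bead secondary amine is ignored because the
released, linker-free compound is the species whose properties matter.
The constant-adduct difference between the schemes is the –C(=O)NH₂
fragment: formula weight 44.03 Da (CH₂NO), +1 HBD, +2 HBA. The fragment
weight convention (not 44.03 − 1.01 for the replaced H) is used because
the adduct is reported as a group contribution.

## Synthetic catalogs

The generator exists to give every stage realistic *structure*, not to
clone any vendor's inventory. Each BB is a scaffold from a weighted
grammar of chemotype families (linear/branched aliphatics, cycloalkanes,
substituted benzenes, dihydrobenzofurans, naphthalenes, heteroaromatics,
benzylsulfonamides, biphenyls) with the class group attached through an
sp3 carbon — guaranteeing validity and exactly one defining group, hence
unambiguous truncation and coupling.

Molecular weight is steered per BB: a target is drawn from
N(class median, 40 Da), a template overshooting it is redrawn (padding can
only add mass), and an aliphatic tail of ⌊(target − base)/14⌉ units (≤ 12)
is inserted. Class medians default to 171 Da (Fmoc-AA, measured on the
deprotected form), 174 Da (amines) and 220 Da (acids); realized medians at
n = 2000 land within ~5 Da. Lipophilicity is steered only softly, by the
probability of ether oxygens in the tail as a function of the class clogP
target (−1.8 / 0.69 / 1.1): the realized class ordering is correct but
absolute medians run ~1.3 log units high, a known limitation of grammar
padding with mostly-carbon units.

Prices are a two-component log-normal mixture — medians $75 and $400 per
250 mg with log-sd 0.35 and weights 0.6/0.4 — giving the "cheap mode /
expensive mode" bimodality typical of vendor packs; a two-component
Gaussian mixture on log-costs recovers both medians within a few percent
at n = 2000.

`generate_paired_catalogs` links the three classes: the Fmoc-AA set is the
smallest (defaults 300 / 1200 amines / 800 acids), and a configurable
fraction (default 0.6) of Fmoc-AA scaffolds is duplicated among the amine
scaffolds. Because all classes truncate to scaffold–CH₃, shared scaffolds
share truncates exactly; the non-shared amines are rejection-sampled
against the Fmoc truncate set (keyed on canonical truncate SMILES, since
distinct scaffold strings can collapse to one truncate), so the overlap
fraction's 0 and 1 limits are exact.

What passing tests on these catalogs do **not** show: vendor-scale
absolute numbers. Commercial amine pools are ~10× larger and far more
heterogeneous, so quantities like the cost-tier nn-Tanimoto medians
computed here (~0.7 at k = 192 from pools of ~2000) are much higher than
the ~0.3 regime seen when sampling 192 from ~15,000, and truncate counts
and retained percentages are properties of the grammar, not of any
catalog. The *relationships* the tests assert — filter nesting, the
diversity ≤ random nn-Tanimoto ordering, cost-total bounds, mass balance,
overlap arithmetic — are scale-free and are the point.

## Problem sizes and determinism

Default analysis sizes (2000-member catalogs for parameter recovery,
192 × 192 = 36,864-product enumeration, 250-member pools for the
selection-ordering checks over 20 seeds) keep a full test-plus-acceptance
cycle around two minutes on one CPU while leaving every statistical check
comfortably powered. All randomness flows from explicit integer seeds
through `numpy.random.default_rng`; UMAP, selection and generation are
reproducible bit-for-bit given a seed, and pipeline runs are pure
functions of (config, catalogs).

## Known limitations

- No stereochemistry, 3D descriptors or coupling-yield modeling; binary
  fingerprints only.
- clogP absolute calibration (see above); one estimator for all roles.
- The uniform strategy depends on the embedding, so it inherits UMAP's
  seed sensitivity: different seeds give different (equally valid)
  uniform selections.
- Three-cycle schemes and protecting groups beyond Fmoc are out of scope;
  the "exotic compound" exclusion list sometimes applied before diversity
  picking is supported as a user-supplied filter hook, not shipped.
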