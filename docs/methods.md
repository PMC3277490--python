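# Methods

## Data model and harmonization

A `MoleculeRecord` carries one structure with per-source Ames labels.
Structures are reduced to an achiral canonical key before any merging:
largest organic fragment, stereochemistry stripped (the 2D descriptors
carry no chirality, and absolute configuration assignments in compiled
data are unreliable anyway), then the RDKit canonical tautomer. The
tautomer dialect is therefore pinned to the RDKit
`TautomerEnumerator` of the installed version; a different
canonicalizer would shift a handful of dedup decisions, which we accept
in exchange for determinism. Salt/solvent handling is the documented
largest-organic-fragment rule — nothing more.

Duplicate records merge by unioning source flags and labels; the
consensus label is positive iff any source reports a positive. This is
deliberately asymmetric: a single positive call outweighs any number of
negatives, reflecting how discordant repeat results are treated in
practice. Molecules above 700 g/mol are excluded from analysis (the
heavy tail sits more than 1.5×IQR above the bulk of any of these
collections and is outside every model's applicability domain).

Weight summaries use the order-statistic median (even sets: mean of the
two middle values), sample quartiles for the IQR, and half-open
`[lo, hi)` range counts. Molecular weight is the average-atomic-weight
MW in g/mol.

Label dialects (`{0,1}`, `{+,-}`, `{POS,NEG}`) are declared in
configuration and never guessed; an unrecognized token is an error, not
a silent skip. Unparseable structures are counted and logged, not
fatal; an input yielding zero parseable records is an error.

## Toxicophore classes

Seven substructure queries are applied as a *sequential* filter in a
fixed priority order — nitroaromatic, ArNH₂, ArNHC(O)R, ArNHMe, ArNMe₂,
aryl-amine alkylring (ArN(CH₂C)₂), ArNHSO₂Me — with `unspecified` as
the fallback, so every molecule receives exactly one class and class
counts partition the set. The queries ship as SMARTS text files (one
per class, rank-prefixed filenames fix the order):

| class | SMARTS | note |
|---|---|---|
| Nitro | `c[$([NX3+](=O)[O-]),$([NX3](=O)=O)]` | both nitro drawings |
| ArNH2 | `[NX3;H2][c]` | primary aromatic amine |
| ArNHC(O)R | `[c][NX3;H1]C(=O)[#6]` | anilide |
| ArNHMe | `[c][NX3;H1][CH3]` | |
| ArNMe2 | `[c][NX3]([CH3])[CH3]` | |
| aryl-amine alkylring | `[c][NX3;R]([CH2;R])[CH2;R]` | aryl N in aliphatic ring |
| ArNHSO2Me | `[c][NX3;H1]S(=O)(=O)[CH3]` | |

Aromaticity perception is RDKit's default model, the same model used in
standardization, so matching and dedup never disagree about what is
aromatic. Aryl-amine subsets keep records containing a primary aromatic
amine and matching none of the exclusion queries (nitroaromatic,
N-nitroso, nitrile oxide) — substructures with their own mutagenicity
mechanism that would confound an aryl-amine-specific analysis.

## Descriptors

Models use hashed circular Morgan **count** fingerprints: radius 3
(ECFP6-style) in 1024 slots for statistical models, radius 2 with
functional-class atom invariants (FCFP-style) for chemical-space maps.
Slot = environment hash mod slots; collisions are accepted. Counts are
invariant to input atom ordering and stable across processes.

A small registry of classical 2D descriptors is implemented under the
customary names, pinned to literature formulas rather than to any
vendor's numeric output (models are always retrained here, so scale
parity is irrelevant): atom counts (`a_count`, `a_nH`, `a_nC`, `a_nO`),
hydrophobic atoms (`a_hyd`: carbons without N/O/S/P neighbours plus
halogens), rotatable bonds (`b_rotN` non-strict / `b_1rotN` strict),
Balaban J, the Kier–Hall carbon valence connectivity `chi0v_C`
(Σ_C δᵥ^−½, δᵥ = 4 − n_H), Kier flexibility (κα₁κα₂/A with
Hall–Kier alpha), `Q_VSA_POS` (Labute approximate-VSA contributions
summed over atoms with positive Gasteiger charge), `density`
(MW / Σ Bondi-sphere van der Waals volumes; the sphere sum ignores
overlap, a documented simplification), and two eigenvalue descriptors:
`BCUT_SMR_3` (Burden matrix: Crippen molar-refractivity diagonal, 0.1 ×
bond order off-diagonals, 0.001 elsewhere; largest eigenvalue) and
`GCUT_SLOGP_3` (Crippen logP diagonal, 1/d² modified graph distance;
largest eigenvalue). Hydrogen contributions fold into the attached
heavy atom.

Preprocessing removes zero-variance columns (optionally near-zero
variance via frequency-ratio/unique-percentage screens) and
centers/scales with training-row statistics only; the identical
transform applies to held-out rows. Inside resampling this is refit on
every training split, so test rows never influence the fit.

## Nitrenium reaction energies

Five bookkeeping reactions generate the aryl-amine reactive
intermediates (hydride loss, N-acetoxy and acid-promoted N-hydroxy
routes to the nitrenium ion, aminyl radical, amide anion). Species are
generated by graph editing at a designated primary-aromatic-amine
nitrogen; elemental composition and total charge are checked to balance
for every equation. The nitrenium ion is evaluated in singlet and
triplet states and the lower kept; the radical is a doublet by electron
parity; H⁻, H·, H₂O, H₃O⁺ and AcO⁻ are fixed reference structures.
When a molecule has several ArNH₂ sites, sites are enumerated and the
minimum formation energy (most reactive site) is used.

Electronic-structure computation is deliberately an injected interface
(`energy(molecule_id, role, conformer_id)` in hartree plus a conformer
list): quantum-chemistry protocols are not desk-reproducible and belong
behind a contract. Shipped backends: a CSV table reader for precomputed
energies and the deterministic synthetic oracle. Conformer lists are
supplied by the backend; the module only enforces lowest-energy-wins.
ΔE_abs = Σ E(lowest product conformers) − Σ E(lowest reactant
conformers), converted at 627.509 kcal/mol per hartree, and reported
relative to aniline (so aniline is 0 by construction and any additive
backend offset cancels). Gas-phase species energies are assumed; no
solvation bookkeeping is attempted for the H₃O⁺/2H₂O equation.

Classification by formation energy uses a declared orientation — lower
energy predicts Ames+ — which is never auto-flipped to force AUC ≥ 0.5.

## Models and evaluation

**PLS** regresses the 0/1 response on the preprocessed matrix
(scikit-learn NIPALS implementation); the continuous prediction is the
classification score and a cutoff (typically chosen for 80% training
sensitivity) turns it into a classifier. Contracts held by
construction and enforced in tests: successive score vectors are
orthogonal, a 1-component model on one predictor equals the OLS slope,
and a full-rank-component model reproduces OLS fitted values.

**Random forest**: 500 unpruned trees (tests and the acceptance script
use 100–200 for speed), √p candidate predictors per split,
with-replacement bootstrap per tree (~63.2% unique rows — the "0.632
bootstrap" is read as the standard bootstrap, not a 63.2% subsample).
Each row is scored by the trees whose bootstrap excluded it
(out-of-bag); the OOB positive-class probability is the training score.
scikit-learn averages per-tree class probabilities rather than hard
votes; since unpruned trees grow to purity the two coincide except at
rows with identical features and conflicting labels, where probability
averaging is standard behaviour. Variable importance is Gini (mean
decrease in impurity).

**Resampling**: random 70/30 splits repeated 100 times (reduced in
tests), non-stratified, with a guard error if a training split is
single-class. One master seed drives per-replicate seeds; all stochastic
outputs carry their seed in metadata. **Cross-set transfer** fits on
100% of one set and scores the other, reporting both AUCs and
five-number summaries of the unscaled scores (a cheap applicability
check: transferred scores concentrating in the training score tails
signal domain mismatch).

**ROC/AUC**: thresholds sweep the unique scores with ties moving
together (diagonal segments); the curve runs exactly from (0,0) to
(1,1); AUC is the trapezoid, which equals Mann–Whitney concordance
(#concordant + ½ ties)/(n₊n₋) — the test suite checks the identity to
1e-12 against a brute-force pair count. Vertical averaging interpolates
each curve's TPR on a fixed FPR grid (default 101 evenly spaced
points), collapsing vertical segments to the upper TPR, and reports
mean ± sample (n−1) SD per grid point.

## Self-organizing maps

A planar 30×30 hexagonal grid (odd-r offset coordinates, cube-distance
neighborhoods) of codebook vectors in fingerprint space, trained online:
each presented vector updates all cells by a Gaussian neighborhood
around the best-matching unit (Euclidean distance, ties to the lowest
cell index). Learning rate decays linearly 0.05 → 0.01 and the
neighborhood radius from max(rows, cols)/2 → 1 across epochs (default
100). The codebook initializes to seeded uniform draws within the
per-feature data range; initializing from data samples was rejected
because such a codebook already quantizes near-optimally and training
then strictly *increases* quantization error, breaking the monotone-
improvement property the tests assert. Given a seed, training and
assignment are fully deterministic.

Cell summaries report membership counts, property fractions (set
origin, Ames outcome, substructure flags) and the model-error map:
mean |predicted probability − experimental class| per cell, so green/red
renderings show where in chemical space a model is reliable.

## Synthetic study sets

The generator emulates the two set archetypes the analysis contrasts:

| | pharma-like | literature-like |
|---|---|---|
| Ames+ base rate | 0.15 | 0.54 |
| aryl-amine class Ames+ rate | 0.22 | 0.71 |
| MW median (spread) | 415 (110) | 229 (60) |
| nitroaromatic prevalence | 1% | 15% |
| polyaromatic scaffold share | 12% | 45% |

Molecules come from an explicit versioned grammar: five aromatic
scaffolds (benzene, pyridine, naphthalene, quinoline, biphenyl) with
four substitution slots; one slot carries the class-defining group for
the drawn toxicophore class, the rest are filled greedily from a
neutral decorator list to hit a per-molecule MW target drawn from the
profile's normal distribution. Class-conditional positive rates follow
the characteristic prevalence tables of the two archetypes, with the
`unspecified` rate solved so the overall base rate is exact in
expectation, and a within-class polyaromatic split (fused-ring members
more often positive, class average preserved) mirroring the known
enrichment of mutagenic polyaromatic amines in literature sets. Every
generated molecule parses, is its own canonical standardization fixed
point, and lands in its intended sequential class.

Replicate-test label noise flips each label with probability p solved
from 2p(1−p) = d, so two independently noised replicate read-outs
disagree at exactly the requested discordance d (~20% in these data);
d ≥ 0.5 saturates at the maximum achievable 50% disagreement.

The energy oracle plants ΔE(hydride loss) = base + scaffold + Σ group
contributions + Gaussian noise (kcal/mol), with electron-donating
substituents stabilizing the nitrenium (negative contributions) and
withdrawing groups destabilizing it, behind the same backend API as a
real energy table; a triplet "conformer" 15 kcal/mol above the singlet
exercises the lowest-energy rule. Two-Gaussian class energies give the
closed-form binormal AUC Φ(Δμ/(σ√2)) for recovery tests.

What the synthetic data does *not* emulate: real pharmaceutical
structural diversity (five scaffolds vs thousands of cores),
activity cliffs, assay artifacts correlated with structure, or any
specific proprietary compound. Passing tests demonstrate that the
pipeline's statistics behave correctly under known ground truth — not
that any model here would reach a particular AUC on real decks.

## Problem sizes and numerical choices

Tests and the acceptance script run scaled-down experiments chosen to
exercise every code path with stable statistics: synthetic sets of
300–4000 molecules, forests of 100–500 trees, 8–10 resampling
replicates, SOM grids of 5×5–10×10 with 8–25 epochs. Statistical
assertions use 3-sigma binomial bands (95% bands where a criterion
states one); exact linear-algebra identities use 1e-6–1e-12 tolerances.
Zero-variance screens compare against exact 0; the near-zero screen
defaults to frequency ratio 19 and unique fraction 10%.

## Known limitations

- The published merged public-set SDF and query archive are not
  redistributable here; the acceptance check that recomputes the
  published per-source counts reports their absence as a failure rather
  than silently skipping. The reading/derivation code path is fully
  exercised on synthetic files in the same field dialect.
- Registry descriptors are literature-pinned reimplementations; their
  absolute values differ from any vendor implementation of the same
  names.
- No conformer/tautomer search is performed for energy calculations;
  conformer enumeration is entirely the backend's responsibility.
- The SOM is planar (non-toroidal) and unsupervised only; no U-matrix
  analytics.
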