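# ameskit

Tools for comparing Ames-mutagenicity data collections and for building
and stress-testing Ames classification models, written for computational
toxicologists and cheminformaticians in drug discovery.

A positive Ames test (bacterial reverse mutation in *Salmonella*
strains) is a serious hurdle for a drug candidate. QSAR models trained
on literature compilations look excellent on paper yet transfer poorly
to pharmaceutical compound decks, which differ sharply in base rate
(~15% vs ~54% Ames+), molecular weight (median ~415 vs ~229 g/mol) and
toxicophore content. `ameskit` implements the full comparison workflow:

- **Set harmonization** — SDF/SMILES readers with per-source labels,
  achiral canonical-tautomer dedup keys, and the consensus rule that a
  structure is Ames+ if *any* source reports a positive
  (`ameskit.io`).
- **Toxicophore profiling** — sequential structural-alert classes
  (nitroaromatic first, then the aryl-amine family, `unspecified` last),
  set profiles and aryl-amine subset extraction with mechanism-based
  exclusions (`ameskit.toxicophores`).
- **Nitrenium-energy scoring** — for an aryl-amine ArNH₂, the energy of
  forming the DNA-reactive nitrenium ion ArNH:⁺ (e.g. ArNH₂ → ArNH:⁺ +
  H⁻, plus N-acetoxy, N-hydroxy, radical and anion variants) is a strong
  single-parameter classifier. Species generation and atom/charge
  balance are handled here; electronic-structure energies come from a
  pluggable backend (precomputed tables or a synthetic oracle), with
  ΔE reported in kcal/mol relative to aniline (`ameskit.nitrenium`).
- **Models and evaluation** — PLS regression on the 0/1 response and
  500-tree random forests scored by out-of-bag probabilities, evaluated
  under repeated 70/30 resampling with vertically averaged ROC curves
  (mean ± SD of TPR at fixed FPR) and AUC = Mann–Whitney concordance
  (`ameskit.models`, `ameskit.evaluation`).
- **Chemical-space maps** — 30×30 hexagonal Kohonen self-organizing maps
  on circular fingerprints, with per-cell membership fractions and
  model-error (|p̂ − y|) maps (`ameskit.som`).
- **Synthetic study sets** — a versioned fragment grammar generates
  labeled "pharma-like" and "literature-like" sets matching the profile
  statistics above, plus a planted energy oracle with closed-form
  expected AUC, so every stage is testable offline
  (`ameskit.synth`).

Estimators (`PlsClassifier`, `ForestOOBClassifier`,
`DescriptorPreprocessor`, `SelfOrganizingMap`) follow scikit-learn
conventions (`fit`/`predict`/`get_params`, fitted attributes with a
trailing underscore) and compose with sklearn tooling.

## Worked example

```python
import numpy as np
from ameskit import builtin_profiles, builtin_queries, generate_set, profile, repeated_resampling
from ameskit.descriptors import fingerprint_matrix
from ameskit.models import ForestOOBClassifier, ForestSpec

profiles = builtin_profiles()
lit = generate_set(profiles["literature_like"], n=1000, seed=0)
print(f"{len(lit)} molecules, {lit.positives()} Ames+ "
      f"({100 * lit.positives() / len(lit):.0f}%)")

table = profile(lit, builtin_queries()).table()
print(table.loc[["Nitro", "ArNH2", "unspecified"]])

X = fingerprint_matrix(lit)                     # ECFP6 counts, 1024 slots
y = np.array([r.consensus for r in lit.records])
res = repeated_resampling(
    X, y, lambda s: ForestOOBClassifier(ForestSpec(n_trees=200), seed=s),
    n_reps=10, seed=1)
s = res.summary()
print(f"forest test AUC {s['test_auc_mean']:.3f} +/- {s['test_auc_sd']:.3f}")
```

prints

```
1000 molecules, 539 Ames+ (54%)
             n_molecules  pct_of_set  n_positive  pct_positive
Nitro                153          15         124            81
ArNH2                 82           8          56            68
unspecified          728          73         343            47
forest test AUC 0.749 +/- 0.013
```

i.e. a literature-like set: ~54% Ames+ overall, nitroaromatics common
and strongly positive (81%), and a fingerprint forest reaching AUC ~0.75
under repeated 70/30 holdout. The same model transferred to a
pharma-like set loses substantial AUC — the covariate-shift effect the
package exists to quantify (see `cross_set_evaluate`).

A CLI mirrors the workflow:

```bash
ameskit profile --seed 3 --out out/      # set sizes, toxicophore tables, MW histograms
ameskit model --model forest --out out/  # resampling AUCs + averaged ROC plots
ameskit crossset --out out/              # train-on-one / test-on-other AUC table
ameskit som --out out/                   # chemical-space map + cell summaries
ameskit synth --out out/                 # write the synthetic sets as SDF
```

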