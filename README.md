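# heckregio

Automated prediction of the regioselectivity of intermolecular,
Pd-catalyzed Heck reactions: branched (α), linear (β), or a mix.

## The problem

The Heck coupling of a monosubstituted alkene CH₂=CH–R with an aryl or
vinyl electrophile Ar–X (X = I, OTf, Br, Cl) can arylate either alkene
carbon.  The classical rules of thumb (EWGs on the alkene give β,
EDGs plus "cationic" conditions give α) have many exceptions, and the
outcome matters to anyone planning a synthesis.  Locating the
transition states of the insertion step with DFT is accurate but hard
to automate; the relative energies of the **post-insertion
intermediates** — the Pd(II) alkyls formed by carbopalladation —
correlate well with the relative barriers and are easy to compute
automatically.  This package implements that proxy as a complete
workflow:

1. **Enumeration.**  From two SMILES strings, explicit reaction SMARTS
   generate every post-insertion complex of both mechanisms: the
   *neutral* pathway (X stays on Pd; α/β × X *cis*/*trans* to the
   alkyl = 4 complexes) and the *cationic* pathway (X dissociated,
   +1 charge, a second phosphine; α/β = 2 complexes).  The leaving
   group reactivity order I ≫ OTf > Br ≫ Cl selects the reactive
   site(s); tied top-ranked sites are all enumerated.
2. **Conformers.**  Each complex gets min(1 + 3·n_rot, 80)
   distance-geometry conformers (n_rot = rotatable bonds of the
   product) embedded around a fixed square-planar Pd catalyst core,
   then deduplicated by Butina clustering on the heavy-atom best-fit
   RMSD (0.5 Å threshold).
3. **Energy ladder.**  Constrained force-field prescreen → 10 kJ/mol
   energy-window filter + re-clustering → constrained, then free,
   semiempirical optimization → connectivity sanity check (a broken or
   created bond, Pd bonds exempt, sets the conformer energy to
   60,000 kJ/mol) → DFT single point.  Backends are pluggable: a
   deterministic mock (default, runs in seconds), RDKit UFF, and
   drivers for external `xtb` (GFN-FF / GFN2-xTB, ALPB solvation) and
   ORCA (r²SCAN-3c, C-PCM).
4. **Call.**  Per pathway, Δ = E_min(α) − E_min(β) over all conformers
   and variants; |Δ| ≤ 12.6 kJ/mol (≈ 3 kcal/mol, the method accuracy)
   is a **mix**, otherwise the lower intermediate names the product.

A curation module classifies registry-style reaction tables
(reaction SMILES + condition fields) into inter/intramolecular ×
α/β/mix outcomes by matching reported products against the generated
ones, and scores predictions with confusion matrices and the relaxed
"not-α"/"not-β" accuracies.

## Worked example

```bash
heckregio predict --alkene "C=Cc1ccccc1" --partner "Clc1ccccc1" \
    --backend mock --bias "neutral-alpha=52" --bias "cationic-alpha=5"
```

```
pathway: neutral
  call: beta
  E(alpha)-E(beta) = +52.5 kJ/mol  (cutoff 12.6)
    beta  cis       -6799999.8 kJ/mol  C(=Cc1ccccc1)c1ccccc1
    beta  trans     -6799998.7 kJ/mol  C(=Cc1ccccc1)c1ccccc1
    alpha cis       -6799947.3 kJ/mol  C=C(c1ccccc1)c1ccccc1
    alpha trans     -6799945.0 kJ/mol  C=C(c1ccccc1)c1ccccc1
pathway: cationic
  call: mix
  E(alpha)-E(beta) = +8.4 kJ/mol  (cutoff 12.6)
    beta  -         -6799999.6 kJ/mol  C(=Cc1ccccc1)c1ccccc1
    alpha -         -6799991.2 kJ/mol  C=C(c1ccccc1)c1ccccc1
```

Styrene + chlorobenzene with the reference intermediate gaps injected
into the mock backend: six complexes are enumerated and ranked; the
neutral pathway's β intermediate lies far below α (+52 kJ/mol gap →
**β**, i.e. stilbene), while the cationic gap is within the 12.6 kJ/mol
cutoff (→ **mix**).  That is the known outcome pattern for this
reaction.  With `--backend uff` the prescreen energies are real UFF
energies; with `xtb`/`orca` installed the full quantum ladder runs.

Other entry points: `heckregio curate --records records.csv --out
labels.csv`, `heckregio score --labels labels.csv --predictions
preds.csv`, and `heckregio fixtures --kind records` for synthetic
test tables.

## Layout

| module | role |
| --- | --- |
| `heckregio.enumeration` | substrate validation, site ranking, complex + product generation |
| `heckregio.templates` | square-planar Pd catalyst-core 3D templates (versioned assets) |
| `heckregio.embedding` | constrained embedding, conformer counting, RMSD + Butina dedup |
| `heckregio.backends` | mock / UFF / xtb / ORCA calculators behind one contract |
| `heckregio.pipeline` | the staged energy ladder with audit trail |
| `heckregio.selectivity` | α/β/mix calls, multi-site pooling, reports |
| `heckregio.curation` | reaction-record classification, filtering, scoring |
| `heckregio.fixtures`, `heckregio.cli` | synthetic inputs and the command line |

See `docs/methods.md` for the model, its assumptions and the numerical
choices.
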