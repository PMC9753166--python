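# Methods

## Model

The regiochemical outcome of an intermolecular Heck coupling is
approximated by the relative electronic energies of the Pd(II)
post-insertion intermediates (the alkyls formed by migratory insertion
of the alkene into the Pd–aryl bond).  This is a proxy: the true
selectivity is set by the insertion barriers, but the intermediate
energies track the relative barriers well while being fully
automatable, since no transition-state search is needed.  Two
mechanisms are evaluated side by side and never merged into one call:

* **neutral** — the halide/triflate X remains bound to Pd; the
  square-planar complex exists with X *cis* or *trans* to the alkyl
  carbon, so α/β × cis/trans = 4 intermediates;
* **cationic** — X has dissociated, the complex carries +1 charge and a
  second phosphine; α/β = 2 intermediates.

Which mechanism operates depends on conditions (triflates and halide
scavengers favour the cationic path) that the energies alone cannot
see; reporting both mirrors how the predictions are used.

The catalyst model is monodentate triphenylphosphine throughout — one
PPh₃ on the neutral intermediates, two on the cationic one — even
though much of the α-selective experimental literature uses bidentate
DPPP/DPPE.  Ligand denticity is annotated during curation instead of
being modelled.

Decision rule: with Δ = E_min(α) − E_min(β) (kJ/mol, minima over
conformers, geometry variants and — for multi-site electrophiles —
reactive sites), Δ < −12.6 → α, Δ > +12.6 → β, |Δ| ≤ 12.6 → mix.  The
12.6 kJ/mol (3 kcal/mol) cutoff expresses the accuracy of the energy
model, not a physical mixing threshold; the boundary is counted as mix
("within" read inclusively).  A pathway missing a successful α or β
intermediate is *undetermined*, never silently dropped.

Known limitation of the proxy: for the neutral pathway the
intermediate gaps are systematically larger than the barrier gaps, so
genuine experimental mixtures can appear as clear β calls; the cutoff
cannot repair that bias.

## Enumeration

Substrates are validated structurally: the alkene must contain exactly
one monosubstituted C=C (`[CH2]=[CH][!#1]`; several distinct units are
an error unless explicitly allowed), the partner at least one aryl or
vinyl C–X bond with X ∈ {I, OTf, Br, Cl}; OTf is matched as the full
triflate ester on oxygen.  Molecules carrying both functionalities are
rejected by default because they signal intramolecular chemistry this
tool does not model.  Site selection uses the empirical oxidative-
addition order I ≫ OTf > Br ≫ Cl; all sites tied at the top rank are
enumerated.  The rewrite rules are explicit reaction SMARTS applied
with RDKit's `RunReactants`; the α rule binds Pd to the terminal CH₂
and the aryl to the substituted carbon (branched product
CH₂=C(Ar)R after β-hydride elimination), the β rule the reverse
(linear R–CH=CH–Ar, double-bond stereochemistry left unset because it
is fixed later in the catalytic cycle).  In the neutral rules the
whole leaving group (halide, or the intact triflate ester) transfers
to Pd; the cationic rules drop it and add the second phosphine.
Phosphine–Pd bonds are dative, so all valences sanitize.

## Templates and conformers

The catalyst cores are idealized square-planar Pd(II) fragments built
from canonical bond lengths (Pd–C 2.0 Å, Pd–P 2.3 Å, Pd–Cl 2.4 Å,
Pd–Br 2.5 Å, Pd–I 2.7 Å, Pd–O(Tf) 2.1 Å) and shipped as versioned XYZ
assets — an idealization chosen because the core geometry only anchors
the conformational search; it is relaxed at the semiempirical stage.
The neutral core holds Pd, the alkyl carbon, the X attachment atom
(90° cis / 180° trans to the carbon) and one P; the cationic core has
two P and no X.

Each complex receives min(1 + 3·n_rot, 80) distance-geometry
conformers, where n_rot counts the rotatable bonds of the organic
product (standard strict definition: non-ring single bonds between
heavy atoms each bearing another heavy neighbour, amides excluded).
Embedding pins the matched core atoms to the template coordinates
(RDKit coordinate-map embedding, fixed seed, single-threaded —
bitwise reproducible on one platform).  Ensembles are thinned by
Butina sphere-exclusion clustering on the pairwise heavy-atom
best-fit (Kabsch) RMSD with a 0.5 Å threshold; the RMSD uses the
identity atom mapping with no graph-symmetry correction, the common
cheap choice.  The Butina implementation is in-package so its
tie-breaking is pinned: candidates in descending neighbour count,
ties by lowest index — deterministic output regardless of library
version.  Only centroids survive; clustering its own output is a
no-op.

## Energy ladder

Stages, in order (asserted in the audit trail of every run):
embed → cluster → constrained force-field optimization → 10 kJ/mol
energy-window filter (the minimum always survives; the boundary is
kept) → re-cluster → constrained semiempirical optimization → free
semiempirical relaxation → connectivity check → DFT single point →
minimum selection.  Whether the window + re-clustering repeats after
the constrained semiempirical stage is a genuinely open reading of the
procedure; it is a flag (`refilter_after_semiempirical`, default off).

The constrained atoms are identified by substructure-matching the
template into each complex (first canonical match); they are true
fixed points during constrained stages.  The connectivity check
perceives bonds from the optimized geometry (two atoms bonded iff
their distance ≤ sum of covalent radii + 0.45 Å, the common XYZ→SDF
converter tolerance; configurable) and compares against the complex
graph with every Pd bond masked on both sides — the Pd coordination
sphere may rearrange, the organic skeleton may not.  A mismatch (or a
perception failure) sets the conformer energy to 60,000 kJ/mol, a
sentinel that can never win the final ranking while keeping the
conformer in the audit.  Final selectivity energies are electronic
single-point energies; no thermal or free-energy corrections are
applied.  All internal energies are kJ/mol; unit conversions happen
only at engine boundaries (Hartree and kcal/mol).

Charges are 0 (neutral) and +1 (cationic); everything is closed-shell
singlet Pd(II) d⁸.  Solvent settings follow the two-stage convention:
implicit phenol (ε = 12.4) for the force-field/semiempirical rungs,
dichloromethane (ε = 9.08) for the DFT single points.  Optimizer
convergence criteria are the engines' defaults.

## Backends

A single calculator contract (`compute(EnergyRequest) → EnergyResult`)
hides the engine.  A backend crash or missing executable returns
`converged=False` for that conformer; the ensemble continues, and a
complex whose ensemble empties is flagged failed and classified as
undetermined downstream.

* **mock** — a pure deterministic function of (rounded-coordinate
  hash, stage name): energy = stage base + spread·U + injected bias,
  with U ∈ [0, 1) from an MD5 digest.  Biases are keyed by substrings
  of the complex id, so any α/β/mix outcome (e.g. a forced
  +52 kJ/mol gap) can be staged.  The default spread is 8 kJ/mol so
  the 10 kJ/mol window filter stays exercised.  The full six-complex
  pipeline runs in seconds and is byte-identical across runs.
* **uff** — RDKit UFF, gas phase; a real force field with parameters
  for Pd, suitable only for the geometric prescreen rung.
* **xtb-gfnff / xtb-gfn2** — input files (geometry, 1-based `$fix`
  atom lists, ALPB solvent flags) for the external `xtb` binary,
  stdout parsed for the total energy.  Deck generation and parsing are
  plain functions, tested without the executable.
* **orca** — r²SCAN-3c / C-PCM single-point input decks for ORCA;
  geometry is untouched by contract.

## Synthetic data

The record generator emulates a registry export: ~200 reactions drawn
from five alkenes (enol ether, enamide, styrene, acrylonitrile,
acrylate) × ~29 aryl electrophiles, with category fractions 40% β-only,
15% α-only (half under silver-scavenger conditions), 10% mix, 10%
no-match, 5% intramolecular, 10% duplicates, 5% over-weight products
and 5% lithium additives — every curation rule has live targets.  What
it does not emulate: free-text noise in real condition fields,
genuinely ambiguous product assignments, salt/solvate notation, or the
real literature's reporting bias toward a single isomer.  Passing
tests therefore demonstrate the correctness of the classification and
scoring logic, not literature-level accuracy figures, which
additionally require the proprietary source data.  The shipped
precatalyst allowlist and additive lists are small documented
placeholders meant to be edited.

Curation details: duplicate removal keys on fragment-canonicalized,
order-independent reaction SMILES; the molecular-weight cut (default
600 g/mol) applies to the largest reported product; element-symbol
matching in additive text is case-sensitive and token-bounded (LiCl is
lithium, aniline is not); β-product matching ignores double-bond
stereochemistry.  "Cationic conditions" means a triflate electrophile
or a configured Ag⁺/Tl⁺ scavenger.  The relaxed score credits a
predicted mix to the observed isomer, giving the "not-α"/"not-β"
accuracies; relaxed ≥ strict always.

## Problem sizes and defaults

The default test suite and the acceptance script run the mock-backend
ladder on styrene + chlorobenzene (6 complexes, 7 requested conformers
each — n_rot = 2) and classify 200 synthetic records; both finish in
well under a minute.  The live-engine scripts use the same code paths
with the conformer counts the formula dictates; their cost is set by
the external engines.  The default RNG seed is fixed in the
configuration and every derived per-complex seed is below 2³¹; the
configuration hash is stamped into every report for provenance.
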