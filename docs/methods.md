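# Methods

This note documents the curation model, its tunable parameters, the
synthetic benchmark, and the numerical and design choices the package
makes where the underlying conventions are genuinely open.

## Potency scale and endpoints

All potencies are handled on the negative decadic logarithmic scale,
pPot = 9 − log₁₀(value in nM), so 10 µM ↔ pPot 5 and 1 nM ↔ pPot 9. Only
the three dose–response endpoints IC50, Ki and Kd are admitted; single-point
readouts ("% inhibition" and similar) are rejected at parse time because
they are unreliable evidence for target annotation. IC50 (assay-dependent)
and Ki/Kd (equilibrium constants) are never mixed in one average: replicate
pools are formed per (compound, target, endpoint), and Ki and Kd — although
both equilibrium measurements — are averaged separately and only combined
at the final max step.

## High-confidence filtering

ChEMBL-dialect records must satisfy: target type `SINGLE PROTEIN`, organism
`Homo sapiens`, assay relationship `D` (direct binding), confidence score 9,
relation `=`, units `nM`. BindingDB-dialect exports carry no
relationship/confidence columns; such records pass on human single-protein
chain, relation `=`, units `nM` alone. Absent fields stay `None` rather
than being defaulted, so the two dialects are filtered under their own
rules. Every rejection carries the first failed rule's name and is written
to a sidecar ledger — auditability of removals is the point of a stringent
curation scheme, since false positives are the dominant error source in
promiscuity assessment.

## Compound aggregation key

Measurements pool under a canonical, non-stereo SMILES key produced by:
component splitting; dropping components on a configurable salt/solvent
list plus any carbon-free component; keeping the largest remaining
component (ties broken by lexicographically smallest canonical SMILES);
valence-preserving neutralization (quaternary nitrogens stay charged);
stereo and isotope removal; RDKit canonicalization. If salt stripping would
empty a structure that does have an organic component (e.g. sodium acetate
as the substance itself), the organic components are retained instead —
stripping never empties a molecule. Keys are toolkit-dependent, so the run
log records the toolkit name and version. Tautomers are deliberately not
merged; this is noted in the run log semantics rather than silently assumed.

## Replicate consistency and the final annotation

Two consistency rules operationalize "replicates must agree":

* **span rule** (kinase-side pairs): average only if max − min < 1.0 pPot
  units. A spread of exactly one full log unit is *not* "the same order of
  magnitude" and is discarded.
* **SD rule** (non-kinase-side pairs): discard averages whose *population*
  standard deviation exceeds 1.0; SD exactly 1.0 survives because the
  cutoff is strictly greater-than.

Both cutoffs and the rule assignment are configurable (a global override
can force one rule everywhere). ChEMBL and BindingDB records for the same
(compound key, UniProt target, endpoint) are pooled into one group before
averaging, since targets are aggregated on UniProt accessions and no source
precedence is defensible.

For each surviving pair, equilibrium averages (pKi, pKd) take precedence
over pIC50, and the *highest* surviving averaged value becomes the final
annotation — the max is taken over averaged group values, not over raw
replicates. Pairs carrying any comment from the contradiction vocabulary
(default: "inactive", "inconclusive", "not active"; case-insensitive,
configurable) lose all their records before grouping. The activity floor
pPot ≥ 5.0 (10 µM) is inclusive at the boundary.

## Quality screens

Three compound-level predicates: a PAINS-style interference catalog, a
reactive-chemistry alert catalog, and an anti-target screen. The shipped
catalogs are compact, documented SMARTS subsets (16 interference patterns,
14 reactive alerts) run through a generic engine that loads any
`name<TAB>SMARTS` file; the full proprietary demerit-scoring rule program
is out of scope by design. Anti-target activity (targets flagged in the
metadata table, e.g. hERG, CYP3A4, albumin) removes a compound entirely at
any reported potency by default; a config switch restricts the trigger to
a pPot floor. Because each screen is a pure per-compound predicate, the
surviving compound set is independent of screen order — a property the
tests assert.

## Promiscuity analysis

The analysis set is the compounds with ≥ 1 kinase and ≥ 1 non-kinase
retained interaction; anti-targets never count toward degrees. Degree
distributions use the bins [1], [2,4], [5,9], [10,∞) — the third bin
completes the partition between the named "two to four" and "ten or more"
bins and is overridable. Percentages are rounded half-up to one decimal to
match conventional reporting. The potency scan fixes the compound set at
the base threshold and re-thresholds only the interactions, which makes
both unique-target columns provably non-increasing. "Inverted-primary"
compounds — nanomolar against their best non-kinase target but only
micromolar against kinases — use the bands pPot ≥ 7 (nanomolar) and
5 ≤ pPot < 6 (micromolar); both are exposed as parameters since the words
alone fix no numbers.

## Target network and kinome annotation

Two targets are connected when ≥ 2 analysis-set compounds (configurable)
are active against both. Isolated targets are excluded from the node set by
default (a flag includes them), and edges are not restricted to
kinase/non-kinase pairs (a bipartite-only switch exists). Exports: GraphML
with node attributes `is_pk`/`degree` and edge attribute `n_shared`, SIF
with interaction label `shares_PKIs`, and a whitespace edge list; element
order is sorted, so outputs are byte-reproducible. The kinome annotation
CSV gives, per analysis-set kinase, the union count of non-kinase targets
over its shared inhibitors (driving both node size and color in external
tree viewers); the UniProt-to-tree-name map is an editable fixture and
unmapped kinases go to a sidecar file, not silently missing.

## Synthetic benchmark

The generator emits both raw dialects plus a target catalog and a manifest
that fully determines the expected output of every stage. Defaults: 200
compounds; 40 kinases (cycling through the eight kinome groups), 20
non-kinase targets (enzyme-heavy class mix with a 7tm1-dominated membrane
receptor slice), 3 anti-targets; promiscuity-degree bin weights
0.573/0.221/0.036/0.170 (PK side) and 0.783/0.192/0.018/0.007 (non-PK
side), i.e. the single-target-dominant, long-tailed shape of the real
analysis set; true pPot values uniform on [5.2, 9.5]; replicate noise
Gaussian on the pPot scale with SD 0.2, clipped at ±0.45 so
planted-consistent groups cannot violate the span/SD rules; 5% each of
contradicted pairs, interference decoys, anti-target actives, relation
violations and wrong-organism rows; 20% of compounds gain a salt or stereo
variant; 30% of replicates appear in both dialects to exercise
cross-database pooling.

Structures are scaffold-plus-enumerated-substituent constructs, unique per
parent after standardization, with a uniform stereo-capable tail; decoys
embed a para-quinone that both the shipped catalog and RDKit's built-in
PAINS catalog match. Expected outcomes are computed at generation time by
direct arithmetic on the exact values serialized into the tables (including
the nM round trip), using exact summation so expectations are independent
of pooling order.

What a green end-to-end test establishes: that the pipeline implements the
stated rules exactly on data whose noise respects the consistency bounds.
What it does not establish: behavior on real chemical diversity, real
kinome coverage, assay-condition artifacts (e.g. varying ATP
concentrations), mutant kinases, or database-snapshot idiosyncrasies — the
generator makes no attempt to mimic those, and headline counts from any
real snapshot are not reproducible from synthetic data.

Stress scenarios regenerate the same world under perturbation:
`all_consistent` (zero noise — the discard ledger must be empty),
`heavy_noise` (unclipped SD 1.5 — discards must match an independent
recount), and `threshold_edge` (exact single measurements at pPot
4.99/5.00/5.01 probing the inclusive floor).

## Numerical choices

* Percentage rounding: decimal half-up to one decimal place.
* Population (not sample) SD for the consistency rule; boundary behaviors
  as above, both overridable.
* Averages use exact summation (`statistics.fmean`), making results
  invariant under record permutation; the tests assert this.
* Ranking tie-breaks: targets by ID ascending after shared-compound count;
  compounds by kinase degree descending, then compound key.
* All tabular outputs are sorted TSVs; two runs on identical inputs are
  byte-identical.

## Known limitations

* The interference/chemistry catalogs are representative subsets, not the
  full published pattern sets; screening results on real data will be
  correspondingly conservative.
* Aggregation keys depend on the RDKit version recorded in the run log.
* BindingDB confidence semantics are not modeled (the export carries no
  such columns); all accepted BindingDB rows are treated as single-protein
  direct measurements.
* No tautomer merging, no mutant-target handling, no assay-condition
  correction.
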