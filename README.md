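# pkitargets

Curation and promiscuity analysis of kinase-inhibitor bioactivity data,
with a focus on systematically profiling the *non-kinase* targets of
protein kinase inhibitors (PKIs).

## The problem

Most PKIs bind the largely conserved ATP pocket of protein kinases (PKs),
so multi-kinase activity is common — but public bioactivity databases also
contain high-confidence evidence that some PKIs engage targets outside the
kinome (GPCRs, epigenetic regulators, metabolic enzymes, …). Finding that
evidence reliably is a data-curation problem: raw activity records are
noisy, replicated, contradictory, and contaminated by assay-interference
chemistry. This package implements the full analysis as a tested pipeline
for anyone studying PKI polypharmacology:

1. **Ingest** ChEMBL-style and BindingDB-style activity tables and a
   target-metadata table into one record model.
2. **Standardize** compound structures (salt stripping, neutralization,
   stereo removal) so salt forms and stereoisomers pool under one
   non-stereo canonical SMILES key.
3. **Curate**: keep only direct single-protein human binding records
   (relationship `D`, confidence 9, relation `=`, nM units; IC50/Ki/Kd
   only), convert to pPot = 9 − log₁₀(value/nM), void pairs with
   contradictory "inactive"/"inconclusive" comments, average replicates
   only when mutually consistent (span < 1 log unit for PK pairs,
   population SD ≤ 1 for non-PK pairs), prioritize equilibrium constants
   (pKi/pKd) over pIC50, take the highest surviving average as the final
   annotation, and apply the 10 µM activity floor (pPot ≥ 5).
4. **Quality-screen** out pan-assay interference (PAINS) substructures,
   reactive-chemistry alerts, and compounds with reported activity against
   anti-targets (hERG, CYP isoforms, albumin).
5. **Analyze**: per-compound promiscuity degrees PK_PD and Non-PK_PD
   (distinct PK / non-PK targets hit), binned degree distributions,
   shared-inhibitor target rankings, a potency-level scan, the
   shared-inhibitor target network (edge ⇔ ≥ 2 shared compounds), target
   class distributions, and a kinome-tree annotation file for external
   viewers.

A first-class synthetic-data generator emits both raw table dialects with
planted ground truth (variant structures, replicate noise, contradictions,
rule violations, interference decoys, anti-target actives), so every stage
is testable without any database download.

## Worked example

```bash
pkitargets simulate --n-compounds 200 --seed 1 --out-dir synthetic
pkitargets run-all --chembl synthetic/chembl_activities.tsv \
    --bindingdb synthetic/bindingdb_activities.tsv \
    --targets synthetic/targets.tsv --out-dir run
```

The run log (`run/run_log.txt`) reports per-stage counts:

```
ingest: 3591 records, 0 rejected rows
curate: 1115 retained interactions; 23 filtered records, 0 unresolved,
        10 contradicted pairs, 0 inconsistent groups, 5 below threshold
quality_filters: 10 flagged by substructure screens, 10 anti-target actives,
        180 compounds retained
promiscuity: 171 compounds in the analysis set
network: 40 PK nodes, 20 non-PK nodes, 1092 edges
```

Reading: of 3,591 raw measurement rows, curation keeps 1,115 consistent,
high-confidence compound–target annotations; the screens then remove the 10
planted interference decoys and 10 anti-target actives, leaving 171
compounds with at least one PK *and* one non-PK target — the analysis set.
`run/distribution_pk.tsv` bins their PK promiscuity degrees:

```
bin_lo  bin     count   percentage
1       1       92      53.8
2       2-4     37      21.6
5       5-9     6       3.5
10      10-inf  36      21.1
```

i.e. 53.8% of these compounds are annotated with a single kinase while
21.1% hit ten or more — the single-target-dominant, long-tailed shape the
generator plants. Other artifacts in `run/` include the curated interaction
table, a discard ledger with machine-readable reasons for every removal,
per-compound profiles, top-target/top-compound rankings, the potency scan,
target-class distributions, GraphML/SIF/edge-list network exports, and
`kinome_annotation.csv` for kinome-tree rendering.

The same analyses are available as library functions
(`pkitargets.curate_interactions`, `build_profiles`, `bin_distribution`,
`build_network`, `potency_scan`, …) operating on plain dataclasses and
pandas DataFrames.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the 200-compound synthetic benchmark from the given seed, runs
the complete pipeline on it from scratch, prints the run log, and writes
the acceptance JSON to `--out`.
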