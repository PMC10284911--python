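# moanet

Network-propagation ensemble modeling of drug-combination mechanisms of
action (MoA) toward an adverse outcome.

## The problem

Some adverse drug reactions only appear when drugs are combined. A motivating
case from hemophilia A care: thrombotic microangiopathy (TMA) — microvascular
thrombosis with thrombocytopenia and hemolytic anemia — has occurred when the
bispecific antibody emicizumab was co-administered with high doses of the
bypassing agent aPCC, but not with the alternative bypassing agent rFVIIa.
Since the three agents act through overlapping sets of coagulation factors
(emicizumab activates FX; rFVIIa supplies FVII; aPCC supplies FII, FVII, FIX,
FX plus trace KNG1 and KLK1), the question is *mechanistic*: which molecular
routes from each combination's targets to the disease effectors could explain
why one combination evokes the outcome and the other does not?

`moanet` implements an in-silico workflow for this class of question:

1. **Curation** (`knowledge_base`) — drug characterizations (targets with
   action signs), condition characterizations (effector proteins with
   pathological direction signs), adverse-event count tables filtered by the
   CIOMS "very common" rule (frequency ≥ 10%), and pharmacovigilance report
   tables filtered at ≥ 5 reports, assembled into a labeled *truth table* of
   drug–condition restrictions.
2. **Response network** (`network_builder`) — the subgraph of a signed
   protein–protein interactome spanned by the disease effectors (and drug
   targets) plus their direct interactors; SIF/GraphML/TSV in and out.
3. **Model ensembles** (`propagation_model`) — signed signal propagation
   `a_i ← (1−λ)·a_i + λ·tanh(Σ_j w_ji·sign_ji·a_j)` with drug targets clamped
   to their action signs, trained by simulated annealing so that known
   relationships hold (a drug that *induces* a condition must drive a strict
   majority of its effectors toward their pathological direction above an
   activation floor; explicit non-associations must fail that criterion).
   An MoA model is an ensemble of 100 independently trained solutions —
   alternative mechanistic hypotheses consistent with the constraints.
4. **Relationship scoring** (`ann_relationship`) — a small neural classifier
   scores stimulus-set ↔ effector-set relationships on a 0–100% scale
   (100 × predicted probability), with empirical permutation p-values and the
   fixed category bins high `[77, 100]`, medium `[38, 77)`, low `< 38`.
5. **MoA comparison** (`moa_comparator`) — interaction-frequency maps across
   the ensemble with a readability-constrained threshold chooser, consensus
   MoA graphs (Graphviz DOT) with per-combination presence flags, perturbed
   protein-set overlap, and differential predicted activity (significant when
   |Δ| > 0.5).
6. **Synthetic scenarios** (`synthetic_data`) — seeded generators for signed
   preferential-attachment interactomes with *planted* target→effector
   mechanisms of known sign parity, so every stage is testable offline with
   ground truth.
7. **Pipeline & CLI** (`pipeline`, `moanet` command) — configuration-driven
   end-to-end runs.

## Worked example

Compare the two hemophilia combinations on the bundled toy scenario (the
three printed drug characterizations wired into a small generated
interactome):

```bash
moanet compare --scenario toy --seed 3 --out scratch/toy_run --ensemble-size 50
```

```
perturbed: A=7 B=7 A⊆B=True; significant differential proteins=4
```

Reading: every protein indirectly perturbed by emicizumab + rFVIIa (set A) is
also perturbed by emicizumab + aPCC (set B) — the full-overlap structure
expected when one combination's target set strictly contains the other's and
all influences are activating — and four proteins differ between the two
trained MoA models by more than the |Δ| > 0.5 activity threshold. The score
table written by the same run:

```
combination        process                          score_pct  p_value  category
emicizumab+rFVIIa  Increased coagulation            83.19      0.01     high
emicizumab+aPCC    Increased coagulation            87.10      0.01     high
emicizumab+rFVIIa  Increased platelet activation    17.42      0.30     low
emicizumab+aPCC    Increased platelet activation    15.33      0.28     low
...
```

Both combinations relate strongly to the coagulation motive (the mechanism
planted in the toy scenario) and to nothing else — the qualitative shape a
practitioner would expect for bypassing agents. The run directory also
contains the response network (GraphML), both solution-ensemble manifests,
the consensus MoA graph in DOT (edges present only under the aPCC
combination are color-coded), and the overlap/differential reports as TSV.

The same analyses are available as library calls; see
`moanet.pipeline.run_pipeline` and the module docstrings.

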