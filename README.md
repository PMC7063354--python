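# pepmine

In-silico proteolysis and bioactive-peptide mining for food-protein
research: given protein sequences, a catalogue of known bioactive
peptides, and protease specificity rules, `pepmine` computes occurrence
and release frequency statistics, simulates gastrointestinal digestion,
and screens released fragments for novel candidate peptides. It is aimed
at researchers profiling storage proteins (cereal, pseudocereal, legume)
as precursors of peptides such as DPP-IV and ACE inhibitors.

## The statistics at its core

For a protein of `N` residues and a peptide catalogue indexed by
activity:

* **Occurrence frequency** `A = a / N`, where `a` counts every position
  at which a catalogued peptide of the given activity occurs as a
  substring (overlaps and repeats included). `ΣA` totals `A` over all
  activities present.
* **Release frequency** `A_E = d / N`, where `d` counts digest fragments
  whose *entire* sequence is a catalogued peptide of that activity — a
  peptide buried inside a longer fragment was not released.
* **Relative release frequency** `W = A_E / A` — the fraction of a
  protein's intrinsic bioactive potential actually liberated (reported
  as NA when `A = 0`).
* **Degree of hydrolysis** `DH = 100 · cut_bonds / (N − 1)` for the
  idealized complete digestion in which every bond matching an enzyme's
  specificity pattern is cleaved.

All four are kept as exact rationals internally and printed at four
decimal places. Protease specificity is modelled over the
Schechter–Berger subsites P2–P2′ with per-position allowed residue sets,
wildcards and blocked clauses (e.g. trypsin cuts after K/R but not
before P); editable YAML rule sets for a pepsin/trypsin/chymotrypsin
gastrointestinal panel and for papain/ficin/stem bromelain are bundled.
The downstream screen labels released length-k fragments by novelty
against the catalogue, imports external bioactivity/toxicity scores,
applies a transparent solubility heuristic, and classifies each
candidate's gastrointestinal fate (intact / partly hydrolyzed / fully
degraded).

## Worked example

```python
>>> import pepmine as pm
>>> gi = pm.bundled_gi_rules()
>>> for pep in ("MAF", "NMF", "HPF", "MCG"):
...     r = pm.gi_stability(pep, gi)
...     print(pep, r.pattern, r.fate, r.secondary_products)
MAF M-A-F fully_degraded ()
NMF N-M-F fully_degraded ()
HPF H-PF partly_hydrolyzed ('PF',)
MCG M-CG partly_hydrolyzed ('CG',)
```

Two tripeptides are fully degraded to free amino acids by the simulated
gastric/pancreatic digestion; the other two are partly hydrolyzed and
regenerate the dipeptides PF (a catalogued DPP-IV inhibitor) and CG —
so even unstable candidates can act as precursors of bioactive
dipeptides. The same engine drives whole-protein work:

```python
>>> d = pm.bundled_dictionary()
>>> protein = pm.ProteinRecord.from_raw("demo", "", "KVR" * 8 + "G" * 124)
>>> trypsin = [r for r in gi if r.enzyme_id == "trypsin"]
>>> prof = pm.profile(protein, d)
>>> rp = pm.release_profile(protein, pm.digest(protein, trypsin), d, prof)
>>> rp.records["DPP-IV inhibitor"].release_frequency_display   # A_E with d=8, N=148
'0.0541'
>>> rp.dh_display                                              # 16 of 147 bonds cut
'10.8844'
```

A full staged analysis (synthetic roster → profiles → proteolysis →
screening → parameter recovery) lives in `analysis/01_…` through
`analysis/05_…`; each script prints what it found and writes its tables
under `results/`. The same stages are exposed as a CLI
(`pepmine profile|digest|release|gi|screen|synth|pipeline`).

## Scope notes

Trained external predictors (bioactivity rankers, toxicity classifiers,
solubility servers) are not reimplemented; their outputs are imported
through score tables, and the bundled solubility rule is a clearly
labelled heuristic stand-in. The bundled dictionary is a small
demonstration fixture — supply your own full catalogue for real
analyses. There is no network access in any code path.
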