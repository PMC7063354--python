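# Methods

## Model

`pepmine` treats enzymatic proteolysis as a deterministic, rule-based
process. A protease is a set of site patterns over the Schechter–Berger
subsites P2, P1, P1′, P2′ around a peptide bond (bond *b* joins residues
*b* and *b + 1*, 1-based). A pattern matches when every non-wildcard
subsite holds a residue from its allowed set and no blocked clause
(subsite, residue set) is satisfied; a subsite that falls outside the
sequence fails any non-wildcard requirement, so termini can never
satisfy a constrained position. Digestion is *idealized and complete*:
every bond matched by any active enzyme is cut in a single pass, with no
kinetics, pH/temperature effects or missed-cleavage probabilities. This
is the standard model of database-driven digestion tools, and its main
consequence is worth keeping in mind: real hydrolysates are produced by
partial, condition-dependent cleavage and will not match the idealized
fragment set exactly.

Fragments are the maximal runs between cut bonds, each carrying a
1-based inclusive interval; concatenating them reproduces the input
(an invariant asserted by property tests). The statistics are

- occurrence frequency `A = a/N` — `a` counts catalogued-peptide
  occurrences of one activity as substrings, with overlaps and repeats,
  one count per activity label a peptide carries;
- release frequency `A_E = d/N` — `d` counts digest fragments whose full
  sequence is a catalogued peptide of that activity (a peptide inside a
  longer fragment is *not* released — that distinction is the whole
  point of having both statistics);
- relative release `W = A_E/A`, undefined (reported `NA`) when `A = 0`;
- degree of hydrolysis `DH = 100·|cuts|/(N − 1)`, defined as 0 for a
  single residue.

`a` and `d` count multiplicity rather than distinct peptide types
because published release inventories annotate repetitions; a distinct
count is emitted alongside both, since printed totals in the literature
are ambiguous between the two conventions.

## Numerical choices

All frequencies and DH are exact `Fraction`s; no floating-point
arithmetic enters any statistic. Reports render them at four decimal
places with round-half-even, converting through `Decimal` at 60-digit
precision so the rounding decision is made on the exact rational. One
consequence the package documents rather than hides: published *W*
values are often the quotient of the already-rounded `A_E` and `A`
(0.0541 / 0.5 = 0.1082), which can differ in the last digit from the
exact rational quotient (16/148 → 0.1081). `pepmine` computes `W`
exactly; the display tests cover both reconstructions explicitly.

Screening reports sort by ranker score descending, unknown scores last,
ties broken lexicographically by peptide. Multi-enzyme digestion is
concurrent (site-set union) by default, matching a one-pot
gastric + pancreatic evaluation; a sequential mode exists and a property
test asserts it coincides with concurrent mode for the bundled GI rules,
whose context windows never cross their own cut sites.

## Bundled rule sets and their provenance

The gastrointestinal set (pepsin pH > 2: cut at P1 ∈ {F,L,W,Y} or
P1′ ∈ {F,L,W,Y,M} unless P1 = P; trypsin: P1 ∈ {K,R} unless P1′ = P;
chymotrypsin A: P1 ∈ {F,Y,W,L,M,H}) is *calibrated* so the engine
reproduces the published worked examples of tripeptide GI digestion
(M-A-F, N-M-F, H-PF, M-CG). It ships as editable YAML and is not an
authoritative reconstruction of any external tool's internal encodings.
The papain/ficin/stem-bromelain set is a best-effort Keil-style default
(papain: P2 ∈ {A,V,L,I,F,W,Y} or P1 ∈ {R,K}, blocked P1′ = V; ficin:
P2 ∈ {F,Y,W,L,V,I}; bromelain: P1 ∈ {K,R,A,Y,G}); the true site models
of the online tools are unpublished, so these are labelled provisional
and no quantitative claim is tied to them.

## External predictors

Bioactivity rankers, toxicity classifiers and solubility servers are
trained or proprietary models. The package imports their outputs from a
score table (`peptide`, `ranker_score` ∈ [0,1], `toxicity`) and marks
absent peptides "unknown" — it never fabricates scores. The only
in-package property rule is the solubility heuristic: *poor* iff
hydrophobic residues {A,V,L,I,M,F,W,Y,C,P} exceed half the length and no
charged residue {D,E,K,R,H} is present. It is deliberately simple and
known to diverge from server predictions on histidine-containing
peptides (it calls HPF "good" where servers have reported poor
solubility); the divergence is documented, not tuned away.

## Residue policy and coordinates

Sequences are uppercased on ingestion. Strict mode (default) admits only
the 20 standard codes; lenient mode keeps X/B/Z/U/O, but such positions
never satisfy a cleavage constraint and never match dictionary peptides,
because all matching is exact over the standard alphabet. Coordinates
are 1-based inclusive everywhere (`f (97–99)` style); the occurrence,
fragment and screening tables all use the same convention.

## Synthetic data: what it emulates and what it does not

The generator emulates a seed-storage-protein roster — by default eight
proteins of 142–542 residues, a range typical of 2S albumins through
13S globulins — with catalogued peptides planted at known positions.
Background residues are uniform over the 20 codes by default (chosen to
maximize rejection-sampling success); a composition table can be
supplied for realism. Under the guard policy a rejection-sampling pass
guarantees each planted peptide occurs exactly as often as planted, and,
when a rule set is supplied, a probe search finds two-residue flanks the
engine is guaranteed to cut so each motif is released intact; the
assembled protein is then re-verified with the engine and resampled on
failure (up to 200 retries, then an explicit error — never silent
truncation). Infeasible motifs exist and are reported as errors: a
peptide with an unavoidable internal cut site (e.g. any X-F bond under
the GI set's pepsin rule) cannot be guard-released.

Passing the parameter-recovery tests on this material shows the pipeline
is internally consistent — planted counts and released sets are read
back exactly — but not that the bundled rule sets describe real enzymes,
and not that uniform-background sequences share the repeat structure,
homology or composition bias of real storage proteins. Claims about real
proteins require real sequences and a curated external dictionary.

## Problem sizes used in the checks

The randomized verification layers use 1,000 sequence/rule-set cases
(N ≤ 500) for brute-force oracle agreement, 1,000 randomized pipeline
runs for the exact equation identities, 500 cases for enzyme-set
monotonicity, and 50 guard-planted proteomes for parameter recovery;
the standalone reproduction script uses 300/500/50 cases for its
corresponding measurements. These sizes give full coverage of the
combinatorics the engine can encounter (terminal bonds, wildcard and
blocked interactions, overlapping occurrences) while keeping a complete
run in seconds.

## Known limitations

- Absolute occurrence/release counts depend entirely on the supplied
  dictionary; the bundled 150-entry fixture is a demonstration subset,
  so its `ΣA` values are not comparable to analyses against a full
  peptide database.
- The complete-digestion assumption upper-bounds release: any bond the
  rules match is always cut.
- No support for modified residues, disulfide constraints or structural
  accessibility; matching is purely sequence-based.
- The plant-protease rule set is provisional (above); conclusions about
  papain/ficin/bromelain selectivity should be drawn only after
  replacing it with site models validated for those enzymes.
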