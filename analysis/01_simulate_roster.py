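"""Generate the synthetic storage-protein roster and its ground truth.

Writes the FASTA panel plus the planted-motif tables that later scripts
(and anyone re-running the analysis) can check against.
"""

from _roster import RESULTS, ROSTER_SPEC, roster
from pepmine.seqio import write_fasta, write_table
from pepmine.synth import expected_count_rows, occurrence_rows

out = RESULTS / "roster"
out.mkdir(parents=True, exist_ok=True)

records, truth = roster()
write_fasta(records, out / "synthetic.fasta")
write_table(
    occurrence_rows(truth),
    out / "truth_occurrences.tsv",
    columns=["protein_id", "peptide", "activity", "start", "end"],
)
write_table(
    expected_count_rows(truth),
    out / "truth_counts.tsv",
    columns=["protein_id", "activity", "a"],
)

lengths = sorted(r.n for r in records)
print(f"Generated {len(records)} proteins (seed={ROSTER_SPEC.seed}), "
      f"lengths {lengths[0]}-{lengths[-1]} residues.")
print(f"Planted motifs per protein: "
      f"{', '.join(f'{p} x{c} ({a})' for p, a, c in ROSTER_SPEC.plants)}.")
print(f"Wrote FASTA and ground-truth tables to {out}/")
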