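"""Shared study conditions for the analysis scripts.

One synthetic roster stands in for a seed-storage protein panel: eight
proteins spanning the 142-542 residue range typical of 2S albumins and
11S/13S globulins, with a handful of catalogued inhibitor peptides
planted at known positions. A fixed seed makes every script reproducible.
"""

from pathlib import Path

from pepmine.synth import PlantingSpec, generate

RESULTS = Path(__file__).resolve().parent.parent / "results"
STUDY_SEED = 20

ROSTER_SPEC = PlantingSpec(
    n_proteins=8,
    length_range=(142, 542),
    plants=(
        ("PF", "DPP-IV inhibitor", 2),
        ("IR", "ACE inhibitor", 2),
        ("CG", "DPP-IV inhibitor", 1),
    ),
    guard=False,  # realistic background: accidental occurrences allowed
    seed=STUDY_SEED,
)


def roster():
    records, truth = generate(ROSTER_SPEC)
    return records, truth
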