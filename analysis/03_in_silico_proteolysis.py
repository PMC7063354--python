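"""In-silico proteolysis of the roster by papain, ficin and stem bromelain.

Each protease is applied independently to every protein; the script
reports the degree of hydrolysis and the release statistics A_E = d/N and
W = A_E/A per activity, plus the released-peptide inventory with
repetition counts — and checks whether DH tracks bioactive release.
"""

from fractions import Fraction

from _roster import RESULTS, roster
from pepmine.cleavage import bundled_plant_rules, digest
from pepmine.dictionary import bundled_dictionary
from pepmine.display import format4
from pepmine.profiles import profile
from pepmine.release import inventory_rows, release_profile, release_rows
from pepmine.seqio import write_table

RESULTS.mkdir(parents=True, exist_ok=True)
records, _ = roster()
dictionary = bundled_dictionary()
enzymes = bundled_plant_rules()

stats, inventory = [], []
per_enzyme_dh = {rs.enzyme_id: [] for rs in enzymes}
per_enzyme_d = {rs.enzyme_id: 0 for rs in enzymes}
for rec in records:
    prof = profile(rec, dictionary)
    for ruleset in enzymes:
        rp = release_profile(rec, digest(rec, [ruleset]), dictionary, prof)
        stats.extend(release_rows(rp))
        inventory.extend(inventory_rows(rp))
        per_enzyme_dh[ruleset.enzyme_id].append(rp.dh)
        per_enzyme_d[ruleset.enzyme_id] += sum(a.d for a in rp.records.values())

write_table(stats, RESULTS / "release_statistics.tsv",
            columns=["protein_id", "enzymes", "DH", "activity", "d", "d_distinct", "A_E", "W"])
write_table(inventory, RESULTS / "release_inventory.tsv",
            columns=["protein_id", "enzymes", "activity", "peptide", "multiplicity", "locations"])

all_dh = [dh for values in per_enzyme_dh.values() for dh in values]
print(f"Digested {len(records)} proteins with {len(enzymes)} proteases "
      f"({len(stats)} protein x enzyme x activity rows).")
print(f"DH range across hydrolysates: {format4(min(all_dh))}% - {format4(max(all_dh))}%")
for enzyme_id in per_enzyme_dh:
    mean_dh = sum(per_enzyme_dh[enzyme_id], Fraction(0)) / len(per_enzyme_dh[enzyme_id])
    print(f"  {enzyme_id}: mean DH {format4(mean_dh)}%, "
          f"total released bioactive fragments d={per_enzyme_d[enzyme_id]}")
print("Note how the enzyme with the highest DH need not release the most "
      "catalogued peptides: release depends on cut-site context, not bulk cutting.")
print(f"Tables written to {RESULTS}/release_statistics.tsv and release_inventory.tsv")
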