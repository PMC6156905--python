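"""Read a pedigree in PED format and compute its kinship matrix.

Writes a small three-generation family to disk, reads it back, and prints
selected kinship coefficients: parent-offspring pairs have phi = 0.25,
grandparent-grandchild pairs phi = 0.125, and unrelated founders phi = 0.
"""

import tempfile
from pathlib import Path

from famethyl import compute_kinship, read_ped, write_ped
from famethyl.pedigree import FEMALE, MALE, Individual, Pedigree

ped = Pedigree(
    [
        Individual("gpa", "FAM1", sex=MALE),
        Individual("gma", "FAM1", sex=FEMALE),
        Individual("dad", "FAM1", father="gpa", mother="gma", sex=MALE),
        Individual("mom", "FAM1", sex=FEMALE),
        Individual("kid1", "FAM1", father="dad", mother="mom", sex=FEMALE),
        Individual("kid2", "FAM1", father="dad", mother="mom", sex=MALE),
    ]
)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "family.ped"
    write_ped(ped, path)
    print("PED file contents:")
    print(path.read_text())
    ped = read_ped(path)

kin = compute_kinship(ped)
for a, b in [("dad", "kid1"), ("gpa", "kid1"), ("kid1", "kid2"), ("gpa", "mom")]:
    phi = kin.phi[kin.index_of(a), kin.index_of(b)]
    print(f"phi({a}, {b}) = {phi:.4f}")
print("relationship matrix 2*Phi diagonal:", kin.relationship().diagonal())
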