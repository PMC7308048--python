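"""Autosomal dominant co-segregation in one family.

Builds a three-generation pedigree by hand and asks whether a candidate
variant tracks with the trait: every genotyped affected member must carry
it, and (strict mode) no genotyped unaffected member may. The
allow_nonpenetrance mode tolerates unaffected carriers, as expected for
traits with incomplete penetrance.
"""

import numpy as np

from famburden import CohortGenotypes, Pedigree, Sample, VariantKey, check_segregation

members = [
    Sample("gran", "FAM1", sex="female", status="affected"),
    Sample("gramp", "FAM1", sex="male", status="unaffected"),
    Sample("mother", "FAM1", father_id="gramp", mother_id="gran",
           sex="female", status="affected"),
    Sample("father", "FAM1", sex="male", status="unaffected"),
    Sample("son", "FAM1", father_id="father", mother_id="mother",
           sex="male", status="affected", is_proband=True),
    Sample("daughter", "FAM1", father_id="father", mother_id="mother",
           sex="female", status="unaffected"),
]
pedigree = Pedigree("FAM1", members)
pedigree.validate()

key = VariantKey("11", 50_000_000, "A", "G")
genotypes = CohortGenotypes(sample_ids=[m.id for m in members])

# het in every affected member, absent elsewhere: clean dominant tracking
genotypes.calls[key] = np.array([1, 0, 1, 0, 1, 0], dtype=np.int8)
res = check_segregation(pedigree, genotypes, key, mode="strict")
print(f"clean transmission: {res.verdict} "
      f"({res.affected_carriers} affected carriers, "
      f"{res.unaffected_carriers} unaffected carriers)")

# now the unaffected daughter also carries it
genotypes.calls[key] = np.array([1, 0, 1, 0, 1, 1], dtype=np.int8)
for mode in ("strict", "allow_nonpenetrance"):
    res = check_segregation(pedigree, genotypes, key, mode=mode)
    print(f"unaffected carrier, {mode}: {res.verdict}")
print()
print("strict mode treats an unaffected carrier as a contradiction of the "
      "dominant model; allow_nonpenetrance counts but tolerates it.")
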