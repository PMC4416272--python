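"""Pedigree algebra: inbreeding and the sparse inverse relationship matrix.

Builds a five-animal pedigree in which the last calf is the offspring of two
full sibs, computes exact inbreeding coefficients, the tabular relationship
matrix A, and its sparse inverse, and verifies Henderson's rules against the
dense inverse.
"""

import numpy as np

from meritsim.pedigree import (
    FEMALE,
    MALE,
    Pedigree,
    build_a_inverse,
    compute_inbreeding,
    relationship_matrix,
)

#                 bull  cow   son   daughter  inbred calf
ped = Pedigree(sire=[-1, -1, 0, 0, 2],
               dam=[-1, -1, 1, 1, 3],
               sex=[MALE, FEMALE, MALE, FEMALE, MALE],
               birth_year=[0, 0, 1, 1, 2])

f = compute_inbreeding(ped)
a = relationship_matrix(ped)
ai = build_a_inverse(ped).toarray()

print("inbreeding F:", np.round(f, 3))
print("the full-sib mating gives the calf F = 0.25\n")
print("relationship matrix A (diagonal is 1 + F):")
print(np.round(a, 3))
print("\nmax |A^-1 A - I| =", f"{np.abs(ai @ a - np.eye(5)).max():.2e}",
      " (Henderson's rules agree with the dense inverse)")
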