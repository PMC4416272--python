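"""Test-only builders and independent oracles.

The oracles here deliberately avoid the package's own computation paths:
the tabular relationship matrix is built by ``meritsim`` but the GLS/BLUP
oracle below works on dense matrices straight from the model definition.
"""

from __future__ import annotations

import numpy as np

from meritsim.mme import RecordSet
from meritsim.params import GeneticParams
from meritsim.pedigree import FEMALE, MALE, Pedigree, relationship_matrix


def random_pedigree(rng: np.random.Generator, n: int, founder_frac: float = 0.1,
                    orphan_rate: float = 0.15) -> Pedigree:
    """Random topologically ordered pedigree with both sexes represented."""
    n_f = max(int(n * founder_frac), 4)
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    sex = np.empty(n, dtype=np.int8)
    sex[:n_f] = np.where(np.arange(n_f) % 2 == 0, MALE, FEMALE)
    for i in range(n_f, n):
        sex[i] = rng.integers(1, 3)
        if rng.random() >= orphan_rate:
            males = np.where(sex[:i] == MALE)[0]
            females = np.where(sex[:i] == FEMALE)[0]
            sire[i] = rng.choice(males)
            dam[i] = rng.choice(females)
    birth_year = np.arange(n) // max(n // 8, 1)
    return Pedigree(sire, dam, sex, birth_year)


def random_records(rng: np.random.Generator, ped: Pedigree, n_herds: int = 3,
                   ndg_rate: float = 0.6) -> RecordSet:
    """Sex-limited random records over a pedigree (values pure noise)."""
    animal, trait, herd, year = [], [], [], []
    for i in range(ped.n):
        traits = [0, 1, 3, 4] if ped.sex[i] == FEMALE else (
            [2] if rng.random() < ndg_rate else [])
        h = int(rng.integers(0, n_herds))
        for t in traits:
            animal.append(i)
            trait.append(t)
            herd.append(h)
            year.append(int(ped.birth_year[i]))
    value = rng.standard_normal(len(animal))
    return RecordSet(np.array(animal), np.array(trait), value,
                     np.array(herd), np.array(year))


def gls_blup_oracle(records: RecordSet, ped: Pedigree, params: GeneticParams,
                    traits=(0, 1, 2, 3, 4), fixed: str = "herd_year"):
    """Dense GLS/BLUP: b = (X'V⁻¹X)⁻¹X'V⁻¹y, u = G Z'V⁻¹(y - Xb).

    Built directly from the model definition with dense matrices; independent
    of the sparse mixed-model assembly it checks.
    """
    traits = list(traits)
    loc = {t: i for i, t in enumerate(traits)}
    k = len(traits)
    n = ped.n
    nr = records.n
    a = relationship_matrix(ped)
    g0 = params.g0[np.ix_(traits, traits)]
    r0 = params.r0[np.ix_(traits, traits)]
    g = np.kron(a, g0)
    z = np.zeros((nr, n * k))
    for r in range(nr):
        z[r, records.animal[r] * k + loc[int(records.trait[r])]] = 1.0
    rmat = np.zeros((nr, nr))
    for i in np.unique(records.animal):
        ridx = np.where(records.animal == i)[0]
        tt = [loc[int(t)] for t in records.trait[ridx]]
        sw = 1.0 / np.sqrt(records.weight[ridx])
        rmat[np.ix_(ridx, ridx)] = r0[np.ix_(tt, tt)] * np.outer(sw, sw)
    if fixed == "herd_year":
        keys = sorted({(int(t), int(h), int(y)) for t, h, y in
                       zip(records.trait, records.herd, records.year)})
        col = {key: j for j, key in enumerate(keys)}
        x = np.zeros((nr, len(keys)))
        for r in range(nr):
            x[r, col[(int(records.trait[r]), int(records.herd[r]),
                      int(records.year[r]))]] = 1.0
    elif fixed == "birth_year":
        keys = sorted({(int(t), int(ped.birth_year[a_]))
                       for t, a_ in zip(records.trait, records.animal)})
        col = {key: j for j, key in enumerate(keys)}
        x = np.zeros((nr, len(keys)))
        for r in range(nr):
            x[r, col[(int(records.trait[r]),
                      int(ped.birth_year[records.animal[r]]))]] = 1.0
    else:
        x = np.zeros((nr, k))
        for r in range(nr):
            x[r, loc[int(records.trait[r])]] = 1.0
    v = z @ g @ z.T + rmat
    vi = np.linalg.inv(v)
    b = np.linalg.solve(x.T @ vi @ x, x.T @ vi @ records.value)
    u = g @ z.T @ vi @ (records.value - x @ b)
    return u.reshape(n, k), b
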