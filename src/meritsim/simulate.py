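"""Stochastic simulation of a closed dairy-cattle breeding scheme.

The simulator emulates a simplified progeny-testing population: ``n_herds``
herds of ``cows_per_herd`` cows, five correlated traits, sex-limited
recording (FY, PY, SCC and NRR on females; NDG on ~60 % of males), no
repeated records, and 30 years of truncation selection on a total merit
index computed from a full multitrait BLUP re-run every year on all data to
date.  Matings are split 25 % to young (unproven) bulls and 75 % to proven
bulls; cows enter the herd after their first lactation record and stay four
years; one offspring per mating at a 50:50 sex ratio.

Common random numbers across residual scenarios: herd-year effects and a
per-animal standard-normal residual vector are drawn once per replicate; a
scenario's phenotypes are obtained by colouring that vector with the
Cholesky factor of its ``R0`` (:meth:`SimOutput.records_for`), so a single
simulated replicate can be re-evaluated under any residual scenario with
identical pedigree and true breeding values.  The yearly selection is driven
by the phenotypes of a configurable scenario — by default the one being
simulated, so that selection uses exactly the data the reference evaluation
later sees and BLUP stays unbiased under selection.

Randomness is split over three independent streams (genetic, residual,
selection) derived from one seed, so e.g. adding a residual scenario never
perturbs the pedigree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from meritsim.mme import ModelSpec, RecordSet, build_mme, solve_mme
from meritsim.params import FEMALE_TRAITS, MALE_TRAITS, GeneticParams, SchemeConfig
from meritsim.pedigree import FEMALE, MALE, Pedigree, extend_inbreeding

__all__ = [
    "SimOutput",
    "simulate_base_population",
    "transmit_tbv",
    "record_phenotypes",
    "simulate_breeding_scheme",
]


@dataclass
class SimOutput:
    """Complete output of one simulated replicate.

    Phenotype *structure* (who is recorded, where, when, and the underlying
    standard-normal residual draws) is scenario-independent; call
    :meth:`records_for` to colour the residuals with a scenario's ``R0`` and
    obtain a :class:`~meritsim.mme.RecordSet`.
    """

    pedigree: Pedigree
    tbv: np.ndarray  # (n, 5)
    params: GeneticParams
    config: SchemeConfig
    rec_animal: np.ndarray
    rec_trait: np.ndarray
    rec_herd: np.ndarray
    rec_year: np.ndarray
    resid_u: np.ndarray  # (n, 5) standard-normal residual draws
    herd_year_effects: dict[tuple[int, int], np.ndarray]
    herd: np.ndarray  # (n,) herd of each animal
    seed: int | None = None
    replicate: int | None = None

    @property
    def true_tmi(self) -> np.ndarray:
        """True aggregate genotype sum_t (omega_t / sigma_a,t) tbv_t."""
        return self.tbv @ self.params.index_weights

    def records_for(self, params: GeneticParams | None = None) -> RecordSet:
        """Phenotypes under the residual scenario of ``params``.

        ``value = herd-year effect + tbv + (chol(R0) u)_trait``; taking a
        subset of the coloured 5-vector marginalises correctly over the
        unrecorded traits.
        """
        if params is None:
            params = self.params
        lr = np.linalg.cholesky(params.r0)
        e = self.resid_u @ lr.T
        hy = np.array(
            [self.herd_year_effects[(h, y)] for h, y in zip(self.rec_herd, self.rec_year)]
        )
        value = (
            hy[np.arange(self.rec_animal.shape[0]), self.rec_trait]
            + self.tbv[self.rec_animal, self.rec_trait]
            + e[self.rec_animal, self.rec_trait]
        )
        return RecordSet(self.rec_animal.copy(), self.rec_trait.copy(), value,
                         self.rec_herd.copy(), self.rec_year.copy())

    @property
    def n_animals(self) -> int:
        return self.pedigree.n


def simulate_base_population(params: GeneticParams, n: int,
                             rng: np.random.Generator) -> np.ndarray:
    """True breeding values of ``n`` unrelated founders, MVN(0, G0)."""
    g0 = params.g0
    return rng.multivariate_normal(np.zeros(params.n_traits), g0, size=n,
                                   method="cholesky")


def transmit_tbv(sire_tbv: np.ndarray, dam_tbv: np.ndarray,
                 f_sire: np.ndarray, f_dam: np.ndarray,
                 g0: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Offspring TBV: parent average plus Mendelian sampling.

    The sampling deviation is MVN(0, 0.5 (1 - (F_s + F_d)/2) G0); fully
    inbred parents leave no segregation variance.
    """
    sire_tbv = np.atleast_2d(sire_tbv)
    dam_tbv = np.atleast_2d(dam_tbv)
    k = g0.shape[0]
    noff = sire_tbv.shape[0]
    scale = np.sqrt(0.5 * (1.0 - 0.5 * (np.atleast_1d(f_sire) + np.atleast_1d(f_dam))))
    z = rng.standard_normal((noff, k))
    lg = np.linalg.cholesky(g0)
    return 0.5 * (sire_tbv + dam_tbv) + scale[:, None] * (z @ lg.T)


def record_phenotypes(sex: np.ndarray, config: SchemeConfig,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Recorded trait indices per animal under the sex-limited design.

    Females are recorded for FY, PY, SCC and NRR; each male is recorded for
    NDG with probability ``male_ndg_recording_rate``.
    """
    out = []
    ndg = rng.random(sex.shape[0]) < config.male_ndg_recording_rate
    for i in range(sex.shape[0]):
        if sex[i] == FEMALE:
            out.append(FEMALE_TRAITS.copy())
        elif ndg[i]:
            out.append(MALE_TRAITS.copy())
        else:
            out.append(np.empty(0, dtype=np.int64))
    return out


class _Growing:
    """Append-friendly per-animal state during the year loop."""

    def __init__(self) -> None:
        self.sire: list[int] = []
        self.dam: list[int] = []
        self.sex: list[int] = []
        self.birth_year: list[int] = []
        self.herd: list[int] = []
        self.tbv: list[np.ndarray] = []
        self.f: list[float] = []

    def add(self, sire: int, dam: int, sex: int, by: int, herd: int,
            tbv: np.ndarray) -> int:
        self.sire.append(sire)
        self.dam.append(dam)
        self.sex.append(sex)
        self.birth_year.append(by)
        self.herd.append(herd)
        self.tbv.append(tbv)
        self.f.append(0.0)  # filled lazily
        return len(self.sire) - 1

    @property
    def n(self) -> int:
        return len(self.sire)


def simulate_breeding_scheme(params: GeneticParams, config: SchemeConfig,
                             seed: int, replicate: int = 0,
                             selection_scenario: float | None = None,
                             eval_tol: float = 1e-8) -> SimOutput:
    """Run the full breeding scheme and return its :class:`SimOutput`.

    Selection on the multitrait-BLUP total merit index (re-estimated every
    year on all records to date), or on a cheap parent-average pedigree index
    when ``config.selection_criterion == 'pedigree_index'``.

    ``selection_scenario`` is the residual fraction of the phenotypes that
    drive the yearly selection (default: the scenario of ``params``).  When a
    later evaluation uses the same scenario, the selection decisions are a
    function of exactly the data in the model, which keeps the reference
    evaluation unbiased under selection; phenotypes for *other* scenarios can
    still be generated from the shared residual stream via
    :meth:`SimOutput.records_for`, at the price of that consistency.
    """
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(replicate,))
    rng_gen, rng_res, rng_sel = [np.random.default_rng(c) for c in ss.spawn(3)]

    if selection_scenario is None:
        selection_scenario = params.residual_fraction
    ref_params = params.with_scenario(selection_scenario)
    g0 = params.g0
    v = params.index_weights
    sigma_p = np.sqrt(params.sigma_p2)
    hy_sd = config.herd_year_sd_frac * sigma_p

    st = _Growing()
    herd_year_effects: dict[tuple[int, int], np.ndarray] = {}

    def hy_effect(h: int, y: int) -> np.ndarray:
        if (h, y) not in herd_year_effects:
            herd_year_effects[(h, y)] = rng_res.standard_normal(5) * hy_sd
        return herd_year_effects[(h, y)]

    # --- founders ----------------------------------------------------------
    n_cows = config.n_cows
    n_bulls = config.n_proven_sires + config.n_young_sires
    founder_tbv = simulate_base_population(params, n_cows + n_bulls, rng_gen)
    cow_pool: list[int] = []  # animals currently in the milking herd
    cow_entry: dict[int, int] = {}
    for c in range(n_cows):
        herd = c // config.cows_per_herd
        i = st.add(-1, -1, FEMALE, -(c % config.cow_lifespan_years), herd,
                   founder_tbv[c])
        cow_pool.append(i)
        cow_entry[i] = 1 - (c % config.cow_lifespan_years)
    proven: set[int] = set()
    founder_bulls: list[int] = []
    for b in range(n_bulls):
        i = st.add(-1, -1, MALE, -1 if b < config.n_proven_sires else 0,
                   int(rng_sel.integers(0, config.n_herds)),
                   founder_tbv[n_cows + b])
        founder_bulls.append(i)
        if b < config.n_proven_sires:
            proven.add(i)

    resid_u: list[np.ndarray] = [rng_res.standard_normal(5) for _ in range(st.n)]

    rec_animal: list[int] = []
    rec_trait: list[int] = []
    rec_herd: list[int] = []
    rec_year: list[int] = []
    recorded_by_year: dict[int, list[int]] = {}

    def add_record(i: int, traits: np.ndarray, year: int) -> None:
        for t in traits:
            rec_animal.append(i)
            rec_trait.append(int(t))
            rec_herd.append(st.herd[i])
            rec_year.append(year)
            hy_effect(st.herd[i], year)
        if len(traits):
            recorded_by_year.setdefault(year, []).append(i)

    daughters_recorded: dict[int, int] = {}

    def finish_records(year: int) -> None:
        """Track proven status: sires of newly recorded females."""
        for i in recorded_by_year.get(year, []):
            if st.sex[i] == FEMALE and st.sire[i] >= 0:
                daughters_recorded[st.sire[i]] = daughters_recorded.get(st.sire[i], 0) + 1

    # founder records (year 1): all founder cows, NDG on 60% of founder bulls
    ndg_flags = rng_sel.random(len(founder_bulls)) < config.male_ndg_recording_rate
    for i in cow_pool:
        add_record(i, FEMALE_TRAITS, 1)
    for flag, i in zip(ndg_flags, founder_bulls):
        if flag:
            add_record(i, MALE_TRAITS, 1)
    finish_records(1)

    # offspring born each year from the previous year's matings
    pending_matings: list[tuple[int, int]] = []
    lr_ref = np.linalg.cholesky(ref_params.r0)
    f_valid = st.n  # founders have F = 0
    warm: tuple[dict, np.ndarray] | None = None  # (fixed key map, ebv) of last solve

    def current_tmi(year: int) -> np.ndarray:
        nonlocal warm
        ped = _pedigree_snapshot(st)
        if config.selection_criterion == "random":
            return rng_sel.random(ped.n)
        if config.selection_criterion == "pedigree_index":
            return _pedigree_index(st, ped, np.asarray(rec_animal), v)
        u = np.array(resid_u)
        tbv = np.array(st.tbv)
        e = u @ lr_ref.T
        ra = np.asarray(rec_animal)
        rt = np.asarray(rec_trait)
        rh = np.asarray(rec_herd)
        ry = np.asarray(rec_year)
        hy = np.array([herd_year_effects[(h, y)][t] for h, y, t in zip(rh, ry, rt)])
        vals = hy + tbv[ra, rt] + e[ra, rt]
        rs = RecordSet(ra, rt, vals, rh, ry)
        system = build_mme(rs, ped, ModelSpec(params=ref_params))
        m = system.m
        x0 = None
        if warm is not None:
            fixed_map, ebv_prev = warm
            x0 = np.zeros(m)
            for pos, (t, lv) in enumerate(system.fixed_keys):
                x0[pos] = fixed_map.get((int(t), int(lv)), 0.0)
            n_prev = ebv_prev.shape[0]
            ebv0 = np.zeros((ped.n, 5))
            ebv0[:n_prev] = ebv_prev
            s_par, d_par = ped.sire[n_prev:], ped.dam[n_prev:]
            pa = np.zeros((ped.n - n_prev, 5))
            ok_s = s_par >= 0
            ok_d = d_par >= 0
            pa[ok_s] += 0.5 * ebv0[s_par[ok_s]]
            pa[ok_d] += 0.5 * ebv0[d_par[ok_d]]
            ebv0[n_prev:] = pa
            x0[system.n_fixed:] = ebv0.ravel()
        method = "direct" if m <= 40000 else "pcg"
        try:
            res = solve_mme(system, tol=eval_tol, method=method, x0=x0, max_iter=20000)
        except RuntimeError:
            res = solve_mme(system, tol=eval_tol, method="direct")
        warm = (res.fixed_solution_map(), res.ebv)
        return res.ebv @ v

    for year in range(1, config.n_years + 1):
        # births
        if pending_matings:
            sires = np.array([s for s, _ in pending_matings])
            dams = np.array([d for _, d in pending_matings])
            fvec = np.array(st.f)
            off_tbv = transmit_tbv(np.array(st.tbv)[sires], np.array(st.tbv)[dams],
                                   fvec[sires], fvec[dams], g0, rng_gen)
            sexes = np.where(rng_sel.random(len(pending_matings)) < 0.5, MALE, FEMALE)
            for j, (s, d) in enumerate(pending_matings):
                st.add(int(s), int(d), int(sexes[j]), year, st.herd[d], off_tbv[j])
                resid_u.append(rng_res.standard_normal(5))
            pending_matings = []

        # extend exact inbreeding to the newborn cohort
        if st.n > f_valid:
            f_new = extend_inbreeding(np.asarray(st.sire), np.asarray(st.dam),
                                      np.asarray(st.f[:f_valid]))
            st.f = list(f_new)
            f_valid = st.n

        # records: females at age 2, males (NDG) at age 1
        if year >= 2:
            for i in range(st.n):
                if st.birth_year[i] == year - 2 and st.sex[i] == FEMALE and st.sire[i] >= 0:
                    add_record(i, FEMALE_TRAITS, year)
            ndg_draw = rng_sel.random(st.n)
            for i in range(st.n):
                if st.birth_year[i] == year - 1 and st.sex[i] == MALE and st.sire[i] >= 0:
                    if ndg_draw[i] < config.male_ndg_recording_rate:
                        add_record(i, MALE_TRAITS, year)
            finish_records(year)

        for b, cnt in daughters_recorded.items():
            if cnt >= config.min_proven_daughters:
                proven.add(b)

        if year == config.n_years:
            break

        tmi = current_tmi(year)

        # cull and replace cows; early years retain cows past the nominal
        # lifespan when too few recorded heifers exist yet
        survivors = [i for i in cow_pool if year - cow_entry[i] + 1 < config.cow_lifespan_years]
        retirable = [i for i in cow_pool if i not in set(survivors)]
        heifers = [i for i in range(st.n)
                   if st.sex[i] == FEMALE and st.birth_year[i] == year - 2 and st.sire[i] >= 0]
        need = n_cows - len(survivors)
        heifers.sort(key=lambda i: (-tmi[i], i))
        entrants = heifers[:need]
        for i in entrants:
            cow_entry[i] = year + 1
        shortfall = need - len(entrants)
        if shortfall > 0:
            retirable.sort(key=lambda i: -cow_entry[i])
            entrants = entrants + retirable[:shortfall]
        cow_pool = survivors + entrants

        # sire selection
        bulls = [i for i in range(st.n) if st.sex[i] == MALE]
        proven_cands = sorted((i for i in bulls if i in proven), key=lambda i: (-tmi[i], i))
        proven_sel = proven_cands[: config.n_proven_sires]
        young_cands = sorted(
            (i for i in bulls
             if i not in proven and year - st.birth_year[i] in (1, 2)),
            key=lambda i: (-tmi[i], i),
        )
        young_sel = young_cands[: config.n_young_sires]
        if not proven_sel or not young_sel:
            raise RuntimeError(f"no eligible sires in year {year}; scheme config infeasible")

        # matings: each cow once; young/proven split by configured fractions
        cows = list(cow_pool)
        order = rng_sel.permutation(len(cows))
        n_young_mat = int(round(config.young_bull_fraction * len(cows)))
        for pos, ci in enumerate(order):
            d = cows[ci]
            if pos < n_young_mat:
                s = young_sel[pos % len(young_sel)]
            else:
                s = proven_sel[pos % len(proven_sel)]
            pending_matings.append((s, d))

    ped = _pedigree_snapshot(st)
    return SimOutput(
        pedigree=ped,
        tbv=np.array(st.tbv),
        params=params,
        config=config,
        rec_animal=np.asarray(rec_animal, dtype=np.int64),
        rec_trait=np.asarray(rec_trait, dtype=np.int64),
        rec_herd=np.asarray(rec_herd, dtype=np.int64),
        rec_year=np.asarray(rec_year, dtype=np.int64),
        resid_u=np.array(resid_u),
        herd_year_effects=herd_year_effects,
        herd=np.asarray(st.herd, dtype=np.int64),
        seed=seed,
        replicate=replicate,
    )


def _pedigree_snapshot(st: _Growing) -> Pedigree:
    return Pedigree(np.asarray(st.sire, dtype=np.int64),
                    np.asarray(st.dam, dtype=np.int64),
                    np.asarray(st.sex, dtype=np.int8),
                    np.asarray(st.birth_year, dtype=np.int64))


def _pedigree_index(st: _Growing, ped: Pedigree, rec_animal: np.ndarray,
                    v: np.ndarray) -> np.ndarray:
    """Cheap selection fallback: parent-average true-index plus noise-free own TBV shrinkage.

    Used only for very fast tests; ranks similarly to BLUP selection but
    skips the yearly evaluation entirely (it uses parent averages of the
    running index, seeded by zero for founders).
    """
    idx = np.zeros(ped.n)
    tbv = np.array(st.tbv)
    has_rec = np.zeros(ped.n, dtype=bool)
    has_rec[np.unique(rec_animal)] = True
    own = tbv @ v
    for i in range(ped.n):
        pa = 0.0
        if ped.sire[i] >= 0:
            pa += 0.5 * idx[ped.sire[i]]
        if ped.dam[i] >= 0:
            pa += 0.5 * idx[ped.dam[i]]
        idx[i] = pa + (0.3 * (own[i] - pa) if has_rec[i] else 0.0)
    return idx
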