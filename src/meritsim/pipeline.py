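"""End-to-end orchestration: replicates x scenarios x methods -> report tables.

``run_experiment`` simulates each replicate once, regenerates phenotypes per
residual scenario from the shared residual stream, runs the four TMI methods
(MULTI, YD, DRP, SI), standardizes all indexes onto the common base-cohort
scale, and aggregates every comparison statistic into a
:class:`ComparisonReport`.  Per-replicate seeds are derived from the master
seed with a counter, so adding replicates never perturbs existing ones.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from meritsim import io as msio
from meritsim.metrics import (
    MIN_CELL_N,
    assign_groups,
    bias_by_group,
    genetic_trend,
    realized_reliability,
    selection_response_loss,
    spearman_by_group,
)
from meritsim.mme import multitrait_evaluation, univariate_evaluation
from meritsim.params import GeneticParams, SchemeConfig
from meritsim.pedigree import build_a_inverse
from meritsim.simulate import SimOutput, simulate_breeding_scheme
from meritsim.tmi import multitrait_tmi_reliability, si_index, standardize, tmi_from_ebv
from meritsim.two_step import (
    deregress,
    edc,
    eop,
    fixed_solution_levels,
    own_information_reliability,
    own_performance_reliability,
    second_step_multitrait,
    yield_deviations,
)

__all__ = ["MethodTables", "ComparisonReport", "run_methods", "run_experiment"]

METHODS = ("MULTI", "YD", "DRP", "SI")


@dataclass
class MethodTables:
    """Per-animal TMI table of one replicate x scenario (all four methods)."""

    tmi: pd.DataFrame  # animal, method, tmi_raw, tmi_std, rel_est
    groups: pd.DataFrame  # animal, birth_year, rel_class, year_group, status
    true_tmi_std: np.ndarray  # per animal (whole pedigree)
    scenario: float
    replicate: int


@dataclass
class ComparisonReport:
    """Aggregated comparison statistics across replicates.

    ``tables`` maps a table name to a tidy DataFrame; replicate-level values
    carry a ``replicate`` column, aggregated ones mean and SD columns.
    """

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stamp = f"# config {self.manifest.get('config_hash', 'unknown')}\n"
        for name, df in self.tables.items():
            path = outdir / f"{name}.tsv"
            with open(path, "w") as fh:
                fh.write(stamp)
                df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def run_methods(sim: SimOutput, scenario_params: GeneticParams,
                reliabilities_for: tuple[str, ...] = ("MULTI",),
                drp_weights: str = "own_performance",
                tol: float = 1e-10) -> MethodTables:
    """All four TMI methods on one replicate under one residual scenario.

    ``drp_weights`` selects the de-regression weighting: own-performance
    record equivalents (default; consistent with the second-step EOP weights)
    or daughter-equivalent ``edc`` weights for sensitivity analysis.
    """
    ped = sim.pedigree
    records = sim.records_for(scenario_params)
    a_inv = build_a_inverse(ped)
    p = scenario_params
    k = p.n_traits

    # --- reference: full multitrait BLUP on phenotypes --------------------
    multi = multitrait_evaluation(records, ped, p, a_inv=a_inv,
                                  reliabilities=True, pev=True, tol=tol)
    tmi_multi = tmi_from_ebv(multi.ebv, p)
    rel_multi = multitrait_tmi_reliability(multi.pev, p)

    # --- univariate first step --------------------------------------------
    uni = [univariate_evaluation(records, ped, t, p, a_inv=a_inv,
                                 reliabilities=True, tol=tol) for t in range(k)]
    ebv_u = np.column_stack([u.ebv[:, 0] for u in uni])
    rel_u = np.column_stack([u.rel[:, 0] for u in uni])

    # own-performance reliability -> EOP weights (one record per trait at most)
    n_rec = np.zeros((ped.n, k))
    np.add.at(n_rec, (records.animal, records.trait), 1.0)
    eop_w = np.zeros((ped.n, k))
    for t in range(k):
        r2_own = own_performance_reliability(n_rec[:, t], p.h2[t])
        eop_w[:, t] = eop(p.alpha[t], r2_own)

    # --- YD: yield deviations + weighted multitrait second step -----------
    fixed_maps = {t: fixed_solution_levels(uni[t]) for t in range(k)}
    yd = yield_deviations(records, fixed_maps)
    yd.weight = eop_w[yd.animal, yd.trait]
    keep = yd.weight > 0
    yd_res = second_step_multitrait(yd.subset(keep), ped, p, a_inv=a_inv,
                                    reliabilities="YD" in reliabilities_for, tol=tol)
    tmi_yd = tmi_from_ebv(yd_res.ebv, p)

    # --- DRP: de-regression + the same weighted second step ---------------
    rel_sire = np.where(ped.sire >= 0, rel_u[np.clip(ped.sire, 0, None)].T, 0.0).T
    rel_dam = np.where(ped.dam >= 0, rel_u[np.clip(ped.dam, 0, None)].T, 0.0).T
    # recorded offspring per trait: a parent's non-parent-average information
    # for trait t flows through offspring phenotyped for t
    off_rec = np.zeros((ped.n, k))
    for par in (ped.sire, ped.dam):
        ok = par >= 0
        np.add.at(off_rec, (par[ok],), (n_rec[ok] > 0).astype(float))
    drp_an, drp_tr, drp_val, drp_w = [], [], [], []
    for t in range(k):
        if drp_weights == "edc":
            # daughter-equivalent weights carrying progeny information; used
            # when pseudo-records must stand in for relatives' data (e.g.
            # bull-only input); slightly double-counts progeny here
            r2_own_info = own_information_reliability(rel_u[:, t], rel_sire[:, t],
                                                      rel_dam[:, t], p.h2[t])
            w = edc(r2_own_info, p.h2[t])
            # the parent-average subtraction is approximate: never let it push
            # a recorded animal below its single-own-record equivalent, and
            # drop animals with neither records nor recorded offspring
            recorded = n_rec[:, t] > 0
            w[recorded] = np.maximum(w[recorded], edc(p.h2[t], p.h2[t]))
            w[~recorded & (off_rec[:, t] == 0)] = 0.0
            w[w < 1e-8] = 0.0
        else:
            # own-performance record equivalents: the same weights the second
            # step uses, so the de-regression and its re-evaluation agree on
            # each pseudo-record's information content
            w = eop_w[:, t].copy()
        y_t, idx_t, _ = deregress(ebv_u[:, t], w, ped, p.sigma_a2[t],
                                  p.sigma_e2[t], a_inv=a_inv)
        drp_an.append(idx_t)
        drp_tr.append(np.full(idx_t.shape[0], t))
        drp_val.append(y_t)
        drp_w.append(w[idx_t] if drp_weights == "edc" else eop_w[idx_t, t])
    drp_rs = msio.pseudo_recordset(np.concatenate(drp_an), np.concatenate(drp_tr),
                                   np.concatenate(drp_val), np.concatenate(drp_w),
                                   ped)
    keep = drp_rs.weight > 0
    drp_res = second_step_multitrait(drp_rs.subset(keep), ped, p, a_inv=a_inv,
                                     reliabilities="DRP" in reliabilities_for, tol=tol)
    tmi_drp = tmi_from_ebv(drp_res.ebv, p)

    # --- SI: selection-index combination of univariate EBV ----------------
    tmi_si, rel_si, _ = si_index(ebv_u, rel_u, p)

    # --- standardization on the common true-genetic scale -----------------
    by = ped.birth_year
    true_tmi = sim.true_tmi
    base_years = sim.config.base_years
    sd_base = float(np.std(true_tmi[(by >= base_years[0]) & (by <= base_years[1])]))
    std = {
        "MULTI": standardize(tmi_multi, by, base_years, sd_genetic=sd_base),
        "YD": standardize(tmi_yd, by, base_years, sd_genetic=sd_base),
        "DRP": standardize(tmi_drp, by, base_years, sd_genetic=sd_base),
        "SI": standardize(tmi_si, by, base_years, sd_genetic=sd_base),
    }
    true_std = standardize(true_tmi, by, base_years, sd_genetic=sd_base)
    raw = {"MULTI": tmi_multi, "YD": tmi_yd, "DRP": tmi_drp, "SI": tmi_si}
    rel_est = {
        "MULTI": rel_multi,
        "YD": multitrait_tmi_reliability(yd_res.pev, p) if yd_res.pev is not None else np.full(ped.n, np.nan),
        "DRP": multitrait_tmi_reliability(drp_res.pev, p) if drp_res.pev is not None else np.full(ped.n, np.nan),
        "SI": rel_si,
    }

    frames = []
    for m in METHODS:
        frames.append(pd.DataFrame({
            "animal": np.arange(ped.n),
            "method": m,
            "tmi_raw": raw[m],
            "tmi_std": std[m],
            "rel_est": rel_est[m],
        }))
    tmi_table = pd.concat(frames, ignore_index=True)
    groups = assign_groups(ped, records, rel_multi, sim.config.analysis_years)
    return MethodTables(tmi_table, groups, true_std,
                        scenario=p.residual_fraction, replicate=sim.replicate or 0)


def _method_columns(mt: MethodTables) -> pd.DataFrame:
    """Wide per-animal frame restricted to analysis animals."""
    wide = mt.tmi.pivot(index="animal", columns="method", values="tmi_std")
    rel = mt.tmi[mt.tmi.method == "MULTI"].set_index("animal").rel_est
    g = mt.groups.set_index("animal")
    out = g.join(wide).join(rel.rename("rel_multi"))
    out["true_std"] = mt.true_tmi_std[out.index.to_numpy()]
    return out.reset_index()


def run_experiment(params: GeneticParams | None = None,
                   config: SchemeConfig | None = None,
                   seed: int = 1,
                   scenarios: tuple[float, ...] = (0.0, 1.0),
                   replicates: int = 3,
                   outdir: str | Path | None = None,
                   reliabilities_for: tuple[str, ...] = ("MULTI",),
                   tol: float = 1e-10) -> ComparisonReport:
    """Full comparison experiment; returns (and optionally writes) the report.

    ``scenarios`` are residual fractions (0 = uncorrelated residuals,
    1 = residual correlations equal to the genetic ones).  A failed replicate
    is recorded in the manifest and skipped in aggregation.
    """
    params = params or GeneticParams()
    config = config or SchemeConfig.scaled()
    t_start = time.time()
    per_cell: list[MethodTables] = []
    failures: list[dict] = []
    for rep in range(replicates):
        for sc in scenarios:
            # each scenario is simulated with selection on its own data, as a
            # breeding program would be; the underlying genetic, residual and
            # selection random streams are shared across scenarios
            try:
                sim = simulate_breeding_scheme(params.with_scenario(sc), config,
                                               seed=seed, replicate=rep)
            except Exception as e:  # pragma: no cover - defensive
                failures.append({"replicate": rep, "scenario": sc,
                                 "stage": "simulate", "error": repr(e)})
                continue
            try:
                per_cell.append(run_methods(sim, params.with_scenario(sc),
                                            reliabilities_for=reliabilities_for,
                                            tol=tol))
            except Exception as e:  # pragma: no cover - defensive
                failures.append({"replicate": rep, "scenario": sc,
                                 "stage": "methods", "error": repr(e)})
    report = aggregate(per_cell)
    report.manifest = {
        "seed": seed,
        "replicates": replicates,
        "scenarios": list(scenarios),
        "config": config.__dict__ | {"base_years": list(config.base_years),
                                     "analysis_years": list(config.analysis_years)},
        "failures": failures,
        "elapsed_s": round(time.time() - t_start, 1),
        "config_hash": msio.config_hash(params, config, seed, scenarios, replicates),
    }
    if outdir is not None:
        report.write(outdir)
    return report


def aggregate(cells: list[MethodTables]) -> ComparisonReport:
    """Comparison tables from per-replicate method tables."""
    rank_rel, rank_year, rank_status = [], [], []
    bias_rel, bias_year, bias_true = [], [], []
    relia, trends = [], []
    for mt in cells:
        w = _method_columns(mt)
        sc, rep = mt.scenario, mt.replicate
        for m in ("YD", "DRP", "SI"):
            for gcol, sink in (("rel_class", rank_rel), ("year_group", rank_year)):
                t = spearman_by_group(w[m].to_numpy(), w.MULTI.to_numpy(),
                                      w[gcol].to_numpy())
                t["method"], t["scenario"], t["replicate"] = m, sc, rep
                sink.append(t)
            for gcol, sink in (("rel_class", bias_rel), ("year_group", bias_year)):
                t = bias_by_group(w[m].to_numpy(), w.MULTI.to_numpy(),
                                  w[gcol].to_numpy())
                t["method"], t["scenario"], t["replicate"] = m, sc, rep
                sink.append(t)
        for m in METHODS:
            t = bias_by_group(w[m].to_numpy(), w.true_std.to_numpy(),
                              w.year_group.to_numpy())
            t["method"], t["scenario"], t["replicate"] = m, sc, rep
            bias_true.append(t)
        # status-group correlations, within reliability classes for bulls
        for m in ("YD", "DRP", "SI"):
            for status in ("BP", "BNP", "FP", "FNP"):
                sub = w[w.status == status]
                if len(sub) < MIN_CELL_N:
                    continue
                t = spearman_by_group(sub[m].to_numpy(), sub.MULTI.to_numpy(),
                                      sub.rel_class.to_numpy())
                t["method"], t["status"], t["scenario"], t["replicate"] = m, status, sc, rep
                rank_status.append(t)
        # reliabilities, SDs, trend (per method incl. MULTI)
        for m in METHODS:
            rr = realized_reliability(w[m].to_numpy(), w.true_std.to_numpy(),
                                      w.year_group.to_numpy())
            est = w.join(mt.tmi[mt.tmi.method == m].set_index("animal").rel_est,
                         on="animal")
            est_by = est.groupby("year_group").rel_est.mean() * 100.0
            sd_obs = w.groupby("year_group")[m].std()
            sd_true = w.groupby("year_group").true_std.std()
            rr = rr.set_index("group")
            rr["rel_est"] = est_by
            rr["sd_obs"] = sd_obs
            rr["sd_true"] = sd_true
            rr["sd_exp"] = np.sqrt(rr.r2.clip(lower=0) / 100.0) * sd_true
            rr = rr.reset_index()
            rr["method"], rr["scenario"], rr["replicate"] = m, sc, rep
            relia.append(rr)
            tr = genetic_trend(w[m].to_numpy(), w.birth_year.to_numpy())
            tr["method"], tr["scenario"], tr["replicate"] = m, sc, rep
            tr["kind"] = "all"
            trends.append(tr)
            tr10 = genetic_trend(w[m].to_numpy(), w.birth_year.to_numpy(),
                                 top_fraction=0.10)
            tr10["method"], tr10["scenario"], tr10["replicate"] = m, sc, rep
            tr10["kind"] = "top10"
            trends.append(tr10)
        tr_true = genetic_trend(w.true_std.to_numpy(), w.birth_year.to_numpy())
        tr_true["method"], tr_true["scenario"], tr_true["replicate"] = "TRUE", sc, rep
        tr_true["kind"] = "all"
        trends.append(tr_true)

    report = ComparisonReport()
    if not cells:
        return report

    def cat(frames):
        return pd.concat(frames, ignore_index=True)

    rel_tab = cat(relia)
    report.tables["rankcorr_replicate_level"] = cat(rank_year)
    report.tables["bias_by_rel_replicate_level"] = cat(bias_rel)
    report.tables["table2_rankcorr_by_rel"] = _avg(cat(rank_rel), "rho")
    report.tables["table3_rankcorr_by_year"] = _avg(cat(rank_year), "rho")
    report.tables["table4_bias_by_rel"] = _avg(cat(bias_rel), "bias")
    report.tables["table5_bias_by_year"] = _avg(cat(bias_year), "bias")
    report.tables["bias_vs_true_by_year"] = _avg(cat(bias_true), "bias")
    report.tables["rankcorr_by_status"] = _avg(cat(rank_status), "rho",
                                               extra_keys=["status"])
    # table 6: reliabilities, SDs and selection-response loss per year group
    loss_rows = []
    for (sc, rep, grp), sub in rel_tab.groupby(["scenario", "replicate", "group"]):
        r2 = sub.set_index("method").r2
        if "SI" in r2.index and "MULTI" in r2.index and np.isfinite(r2[["SI", "MULTI"]]).all():
            loss_rows.append((sc, rep, grp,
                              selection_response_loss(r2["SI"], r2["MULTI"])))
    loss = pd.DataFrame(loss_rows, columns=["scenario", "replicate", "group", "sr_loss"])
    report.tables["sr_loss_replicate_level"] = loss
    report.tables["table6_reliabilities"] = _avg(rel_tab, ["r2", "rel_est", "sd_obs",
                                                           "sd_true", "sd_exp"])
    report.tables["table6_sr_loss"] = _avg(loss, "sr_loss", keys=["scenario", "group"])
    report.tables["trend_bias_by_year"] = _avg(cat(trends), "mean",
                                               keys=["scenario", "method", "kind",
                                                     "birth_year"])
    report.tables["tmi_replicate_level"] = rel_tab
    return report


def _avg(df: pd.DataFrame, value_cols, keys=None, extra_keys=None) -> pd.DataFrame:
    if isinstance(value_cols, str):
        value_cols = [value_cols]
    if keys is None:
        keys = ["scenario", "method", "group"] + (extra_keys or [])
        keys = [k for k in keys if k in df.columns]
    agg = {c: ["mean", "std"] for c in value_cols}
    if "n" in df.columns:
        agg["n"] = ["mean"]
    out = df.groupby(keys, dropna=False).agg(agg)
    out.columns = ["_".join(c).rstrip("_") if c[1] != "mean" else c[0]
                   for c in out.columns]
    return out.reset_index()
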