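"""Comparison statistics between TMI methods.

Everything the method comparison reports is computed here: Spearman rank
correlations and mean bias between each method and the multitrait reference
(grouped by TMI reliability class, by 5-year birth cohorts, and by the four
progeny-status groups), realized reliabilities (squared correlation of
estimated with true TMI), estimated reliabilities, observed versus expected
index SD (``sqrt(r² sigma²_T)``, inflation diagnostics), accuracy-scale
selection-response loss, and per-year genetic trends.

Groupings
---------
* reliability classes ``<39, 40-49, ..., >90`` on the reference TMI
  reliability (x100);
* year groups ``11-15, 16-20, 21-25, 26-30`` plus ``All`` (the analysis is
  restricted to the last 20 simulated birth years);
* status: bulls/females with/without progeny information (BP, BNP, FP, FNP),
  progeny information meaning at least one phenotyped offspring.

Cells with fewer than ``min_n`` animals are flagged (NaN) rather than
computed.  All statistics are computed per replicate and then averaged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from meritsim.mme import RecordSet
from meritsim.pedigree import MALE, Pedigree

__all__ = [
    "reliability_class",
    "year_group",
    "status_group",
    "assign_groups",
    "spearman_by_group",
    "bias_by_group",
    "realized_reliability",
    "expected_sd",
    "selection_response_loss",
    "genetic_trend",
]

REL_CLASSES = ("<39", "40-49", "50-59", "60-69", "70-79", "80-89", ">90")
YEAR_GROUPS = ("11-15", "16-20", "21-25", "26-30")
STATUS_GROUPS = ("BP", "BNP", "FP", "FNP")

MIN_CELL_N = 10


def reliability_class(rel: np.ndarray) -> np.ndarray:
    """Class label per animal from reliability on the 0-1 scale."""
    pct = np.asarray(rel) * 100.0
    edges = [40, 50, 60, 70, 80, 90]
    idx = np.searchsorted(edges, pct, side="right")
    return np.array(REL_CLASSES, dtype=object)[idx]


def year_group(birth_year: np.ndarray,
               analysis_years: tuple[int, int] = (11, 30)) -> np.ndarray:
    """5-year cohort label; animals outside the analysis window get ''. """
    by = np.asarray(birth_year)
    out = np.full(by.shape, "", dtype=object)
    for lo in range(analysis_years[0], analysis_years[1], 5):
        hi = lo + 4
        out[(by >= lo) & (by <= hi)] = f"{lo}-{hi}"
    return out


def status_group(pedigree: Pedigree, records: RecordSet) -> np.ndarray:
    """BP/BNP/FP/FNP: sex crossed with having >= 1 phenotyped offspring."""
    has_progeny_info = np.zeros(pedigree.n, dtype=bool)
    rec_animals = np.unique(records.animal)
    recorded = np.zeros(pedigree.n, dtype=bool)
    recorded[rec_animals] = True
    for par in (pedigree.sire, pedigree.dam):
        ok = par >= 0
        np.logical_or.at(has_progeny_info, par[ok], recorded[np.where(ok)[0]])
    male = pedigree.sex == MALE
    out = np.where(male, np.where(has_progeny_info, "BP", "BNP"),
                   np.where(has_progeny_info, "FP", "FNP"))
    return out.astype(object)


def assign_groups(pedigree: Pedigree, records: RecordSet, rel_tmi: np.ndarray,
                  analysis_years: tuple[int, int] = (11, 30)) -> pd.DataFrame:
    """Per-animal grouping table restricted to the analysis birth years."""
    df = pd.DataFrame(
        {
            "animal": np.arange(pedigree.n),
            "birth_year": pedigree.birth_year,
            "sex": pedigree.sex,
            "rel_class": reliability_class(rel_tmi),
            "year_group": year_group(pedigree.birth_year, analysis_years),
            "status": status_group(pedigree, records),
        }
    )
    return df[df.year_group != ""].reset_index(drop=True)


def _cells(groups: pd.Series) -> list[tuple[str, np.ndarray]]:
    out = []
    for g in groups.unique():
        out.append((g, (groups == g).to_numpy()))
    return out


def spearman_by_group(tmi_a: np.ndarray, tmi_b: np.ndarray, groups: np.ndarray,
                      min_n: int = MIN_CELL_N) -> pd.DataFrame:
    """Spearman's rho (average-rank ties) per group cell plus 'All'."""
    groups = pd.Series(np.asarray(groups, dtype=object))
    rows = [("All", _spearman(tmi_a, tmi_b), len(tmi_a))]
    for g, mask in _cells(groups):
        n = int(mask.sum())
        rho = _spearman(tmi_a[mask], tmi_b[mask]) if n >= min_n else np.nan
        rows.append((g, rho, n))
    return pd.DataFrame(rows, columns=["group", "rho", "n"])


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2:
        return np.nan
    return float(spearmanr(a, b).statistic)


def bias_by_group(tmi_method: np.ndarray, tmi_reference: np.ndarray,
                  groups: np.ndarray, min_n: int = MIN_CELL_N) -> pd.DataFrame:
    """Mean (method - reference) per cell, in standardized index points."""
    d = np.asarray(tmi_method) - np.asarray(tmi_reference)
    groups = pd.Series(np.asarray(groups, dtype=object))
    rows = [("All", float(d.mean()), len(d))]
    for g, mask in _cells(groups):
        n = int(mask.sum())
        rows.append((g, float(d[mask].mean()) if n >= min_n else np.nan, n))
    return pd.DataFrame(rows, columns=["group", "bias", "n"])


def realized_reliability(tmi_est: np.ndarray, true_tmi: np.ndarray,
                         groups: np.ndarray, min_n: int = MIN_CELL_N) -> pd.DataFrame:
    """Squared Pearson correlation of estimated with true TMI, x100."""
    groups = pd.Series(np.asarray(groups, dtype=object))
    rows = [("All", _r2pct(tmi_est, true_tmi), len(tmi_est))]
    for g, mask in _cells(groups):
        n = int(mask.sum())
        rows.append((g, _r2pct(tmi_est[mask], true_tmi[mask]) if n >= min_n else np.nan, n))
    return pd.DataFrame(rows, columns=["group", "r2", "n"])


def _r2pct(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1] ** 2 * 100.0)


def expected_sd(realized_r2_pct: float, true_sd_within: float) -> float:
    """Expected index SD ``sqrt(r² sigma²_T)`` from realized reliability."""
    return float(np.sqrt(max(realized_r2_pct, 0.0) / 100.0) * true_sd_within)


def selection_response_loss(realized_r2_si_pct: float,
                            realized_r2_multi_pct: float) -> float:
    """Accuracy-scale loss ``100 (sqrt(r²_SI) - sqrt(r²_MULTI))`` in points.

    Under the breeder's equation with equal intensity, interval and genetic
    SD, response is proportional to accuracy; 100 % corresponds to accuracy
    1.  Negative values mean the selection index responds less.
    """
    return float(
        100.0 * (np.sqrt(realized_r2_si_pct / 100.0) - np.sqrt(realized_r2_multi_pct / 100.0))
    )


def genetic_trend(values: np.ndarray, birth_year: np.ndarray,
                  top_fraction: float | None = None,
                  subset: np.ndarray | None = None) -> pd.DataFrame:
    """Per-birth-year means of a per-animal quantity.

    ``top_fraction`` restricts each year to its best animals on ``values``
    (e.g. 0.10 for the top decile); ``subset`` masks animals first.
    """
    values = np.asarray(values, dtype=float)
    by = np.asarray(birth_year)
    if subset is not None:
        values, by = values[subset], by[subset]
    rows = []
    for y in np.unique(by):
        vy = values[by == y]
        if top_fraction is not None:
            k = max(int(np.ceil(top_fraction * len(vy))), 1)
            vy = np.sort(vy)[::-1][:k]
        rows.append((int(y), float(vy.mean()), len(vy)))
    return pd.DataFrame(rows, columns=["birth_year", "mean", "n"])
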