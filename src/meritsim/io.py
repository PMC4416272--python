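"""Delimited-text readers and writers for every table the package exchanges.

All formats are plain CSV/TSV with one header line:

* pedigree: ``animal,sire,dam,sex,birth_year`` — external integer ids,
  ``0`` or empty for unknown parents, sex ``M``/``F``;
* phenotypes: ``animal,trait,value,herd,year``;
* EBV: ``animal,trait,ebv,rel``;
* pseudo-records: ``animal,trait,value,weight,kind`` with kind YD or DRP;
* TMI tables: ``animal,method,scenario,replicate,tmi_raw,tmi_std,rel``.

Readers validate as they go and report the offending line number.  External
ids are mapped to internal consecutive indices on read (topological order
required) and back on write.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from meritsim.mme import RecordSet
from meritsim.params import TRAITS, GeneticParams, SchemeConfig
from meritsim.pedigree import FEMALE, MALE, Pedigree

__all__ = [
    "read_pedigree",
    "write_pedigree",
    "read_phenotypes",
    "write_phenotypes",
    "write_ebv",
    "write_pseudo_records",
    "pseudo_recordset",
    "load_config",
    "save_config",
    "config_hash",
]

_SEX_CODE = {"M": MALE, "F": FEMALE, "1": MALE, "2": FEMALE}
_SEX_NAME = {MALE: "M", FEMALE: "F"}


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a pedigree CSV; parents must precede offspring."""
    df = pd.read_csv(path, dtype={"animal": np.int64}, keep_default_na=False)
    required = ["animal", "sire", "dam", "sex", "birth_year"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing pedigree columns {missing}")
    ids = df.animal.to_numpy()
    if len(np.unique(ids)) != len(ids):
        dup = ids[pd.Series(ids).duplicated().to_numpy()][0]
        raise ValueError(f"{path}: duplicate animal id {dup}")
    pos = {int(a): i for i, a in enumerate(ids)}

    def parent(col: str) -> np.ndarray:
        out = np.empty(len(df), dtype=np.int64)
        for line, raw in enumerate(df[col], start=2):
            s = str(raw).strip()
            if s in ("", "0"):
                out[line - 2] = -1
                continue
            try:
                out[line - 2] = pos[int(s)]
            except (ValueError, KeyError):
                raise ValueError(
                    f"{path}:{line}: {col} id {raw!r} unknown or malformed"
                ) from None
        return out

    sex = np.empty(len(df), dtype=np.int8)
    for line, raw in enumerate(df.sex, start=2):
        code = _SEX_CODE.get(str(raw).strip().upper())
        if code is None:
            raise ValueError(f"{path}:{line}: invalid sex code {raw!r}")
        sex[line - 2] = code
    return Pedigree(parent("sire"), parent("dam"), sex,
                    df.birth_year.to_numpy(np.int64), external_id=ids)


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    ext = pedigree.external_id
    par = {}
    for nm, arr in (("sire", pedigree.sire), ("dam", pedigree.dam)):
        par[nm] = np.where(arr >= 0, ext[np.clip(arr, 0, None)], 0)
    pd.DataFrame({
        "animal": ext,
        "sire": par["sire"],
        "dam": par["dam"],
        "sex": [_SEX_NAME[int(s)] for s in pedigree.sex],
        "birth_year": pedigree.birth_year,
    }).to_csv(path, index=False)


def read_phenotypes(path: str | Path, pedigree: Pedigree) -> RecordSet:
    """Read a phenotype CSV against a pedigree (external animal ids)."""
    df = pd.read_csv(path)
    required = ["animal", "trait", "value", "herd", "year"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing phenotype columns {missing}")
    pos = {int(a): i for i, a in enumerate(pedigree.external_id)}
    animal = np.empty(len(df), dtype=np.int64)
    for line, raw in enumerate(df.animal, start=2):
        try:
            animal[line - 2] = pos[int(raw)]
        except (ValueError, KeyError):
            raise ValueError(f"{path}:{line}: animal id {raw!r} not in pedigree") from None
    trait = np.empty(len(df), dtype=np.int64)
    tmap = {t: i for i, t in enumerate(TRAITS)}
    for line, raw in enumerate(df.trait, start=2):
        s = str(raw).strip()
        if s in tmap:
            trait[line - 2] = tmap[s]
        elif s.isdigit() and int(s) < len(TRAITS):
            trait[line - 2] = int(s)
        else:
            raise ValueError(f"{path}:{line}: unknown trait {raw!r}")
    w = df.weight.to_numpy(float) if "weight" in df.columns else None
    return RecordSet(animal, trait, df.value.to_numpy(float),
                     df.herd.to_numpy(np.int64), df.year.to_numpy(np.int64), w)


def write_phenotypes(records: RecordSet, pedigree: Pedigree, path: str | Path) -> None:
    pd.DataFrame({
        "animal": pedigree.external_id[records.animal],
        "trait": [TRAITS[t] for t in records.trait],
        "value": records.value,
        "herd": records.herd,
        "year": records.year,
        "weight": records.weight,
    }).to_csv(path, index=False)


def write_ebv(ebv: np.ndarray, rel: np.ndarray | None, pedigree: Pedigree,
              traits: tuple[int, ...], path: str | Path) -> None:
    n, k = ebv.shape
    rows = {
        "animal": np.repeat(pedigree.external_id, k),
        "trait": [TRAITS[traits[t]] for _ in range(n) for t in range(k)],
        "ebv": ebv.ravel(),
        "rel": (rel.ravel() if rel is not None else np.full(n * k, np.nan)),
    }
    pd.DataFrame(rows).to_csv(path, index=False)


def pseudo_recordset(animal: np.ndarray, trait: np.ndarray, value: np.ndarray,
                     weight: np.ndarray, pedigree: Pedigree) -> RecordSet:
    """RecordSet of pseudo-records, validated against the pedigree.

    Zero-weight rows are dropped (they carry no information); an animal index
    outside the pedigree is an error.
    """
    animal = np.asarray(animal, dtype=np.int64)
    if animal.size and (animal.min() < 0 or animal.max() >= pedigree.n):
        bad = animal[(animal < 0) | (animal >= pedigree.n)][0]
        raise ValueError(f"pseudo-record references unknown animal index {bad}")
    weight = np.asarray(weight, dtype=float)
    keep = weight > 0
    return RecordSet(animal[keep], np.asarray(trait)[keep],
                     np.asarray(value, dtype=float)[keep], weight=weight[keep])


def write_pseudo_records(rs: RecordSet, pedigree: Pedigree, kind: str,
                         path: str | Path) -> None:
    pd.DataFrame({
        "animal": pedigree.external_id[rs.animal],
        "trait": [TRAITS[t] for t in rs.trait],
        "value": rs.value,
        "weight": rs.weight,
        "kind": kind,
    }).to_csv(path, index=False)


def load_config(path: str | Path) -> tuple[GeneticParams, SchemeConfig]:
    """YAML configuration -> (GeneticParams, SchemeConfig), with defaulting."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    g = raw.get("genetics", {})
    kwargs = {}
    for key in ("h2", "genetic_sd", "econ_weights"):
        if key in g:
            kwargs[key] = np.asarray(g[key], dtype=float)
    if "genetic_corr" in g:
        kwargs["genetic_corr"] = np.asarray(g["genetic_corr"], dtype=float)
    if "trait_names" in g:
        kwargs["trait_names"] = tuple(g["trait_names"])
    if "residual_fraction" in g:
        kwargs["residual_fraction"] = float(g["residual_fraction"])
    params = GeneticParams(**kwargs)
    s = dict(raw.get("scheme", {}))
    for key in ("base_years", "analysis_years"):
        if key in s:
            s[key] = tuple(s[key])
    config = SchemeConfig(**s)
    return params, config


def save_config(params: GeneticParams, config: SchemeConfig, path: str | Path) -> None:
    doc = {
        "genetics": {
            "trait_names": list(params.trait_names),
            "h2": params.h2.tolist(),
            "genetic_corr": params.genetic_corr.tolist(),
            "genetic_sd": params.genetic_sd.tolist(),
            "econ_weights": params.econ_weights.tolist(),
            "residual_fraction": params.residual_fraction,
        },
        "scheme": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in config.__dict__.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def config_hash(params: GeneticParams, config: SchemeConfig, seed: int,
                scenarios: tuple[float, ...], replicates: int) -> str:
    blob = json.dumps({
        "h2": params.h2.tolist(),
        "corr": params.genetic_corr.tolist(),
        "sd": params.genetic_sd.tolist(),
        "w": params.econ_weights.tolist(),
        "scheme": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in config.__dict__.items()},
        "seed": seed,
        "scenarios": list(scenarios),
        "replicates": replicates,
    }, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
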