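"""Reading and writing the flat-file interchange formats.

Formats are deliberately plain: CSV for records / pedigree / genotypes,
JSON for the simulation ground truth, YAML for configurations.  A PLINK
``.raw``-style genotype reader is provided for externally recoded data.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from spectragp.simulate import SimConfig, SyntheticDataset, SyntheticTruth


def write_fixtures(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write records.csv, pedigree.csv, genotypes.csv, truth.json and
    config.yaml; returns the paths.  Round-trip via :func:`read_fixtures`
    reproduces every field exactly (floats are written at full repr
    precision)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": directory / "records.csv",
        "pedigree": directory / "pedigree.csv",
        "genotypes": directory / "genotypes.csv",
        "truth": directory / "truth.json",
        "config": directory / "config.yaml",
    }
    dataset.records.to_csv(paths["records"], index=False)
    dataset.pedigree.to_csv(paths["pedigree"], index=False)
    dataset.genotypes.to_csv(paths["genotypes"])
    truth = dataset.truth
    payload = {
        "breeding_values": _frame_to_json(truth.breeding_values),
        "pe_effects": _frame_to_json(truth.pe_effects),
        "hys_effects": _frame_to_json(truth.hys_effects),
        "nsl_effects": _frame_to_json(truth.nsl_effects),
        "env_factors": _frame_to_json(truth.env_factors),
        "sire_slopes": {t: _frame_to_json(df) for t, df in truth.sire_slopes.items()},
    }
    paths["truth"].write_text(json.dumps(payload))
    paths["config"].write_text(yaml.safe_dump(config_to_dict(dataset.config)))
    return paths


def read_fixtures(directory: str | Path) -> SyntheticDataset:
    directory = Path(directory)
    config = config_from_yaml(directory / "config.yaml")
    records = read_records(directory / "records.csv")
    pedigree = read_pedigree(directory / "pedigree.csv")
    genotypes = read_genotypes(directory / "genotypes.csv")
    payload = json.loads((directory / "truth.json").read_text())
    truth = SyntheticTruth(
        breeding_values=_frame_from_json(payload["breeding_values"], "id"),
        pe_effects=_frame_from_json(payload["pe_effects"], "cow_id"),
        hys_effects=_frame_from_json(payload["hys_effects"], None),
        nsl_effects=_frame_from_json(payload["nsl_effects"], "nsl_id", index_type=int),
        env_factors=_frame_from_json(payload["env_factors"], None),
        sire_slopes={t: _frame_from_json(d, "sire_id")
                     for t, d in payload["sire_slopes"].items()},
    )
    return SyntheticDataset(config, records, pedigree, genotypes, truth)


def _frame_to_json(df: pd.DataFrame) -> dict:
    return {"index": [str(i) for i in df.index],
            "columns": list(df.columns),
            "values": df.to_numpy().tolist()}


def _frame_from_json(d: dict, index_name, index_type=str) -> pd.DataFrame:
    idx = pd.Index([index_type(i) for i in d["index"]], name=index_name)
    return pd.DataFrame(np.asarray(d["values"], dtype=float).reshape(len(idx), len(d["columns"])),
                        index=idx, columns=d["columns"])


def read_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cow_id": str, "sire_id": str, "herd_id": str})
    return df


def read_pedigree(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str).fillna("0")


def read_genotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sire_id": str})
    return df.set_index("sire_id")


def read_plink_raw(path: str | Path) -> pd.DataFrame:
    """Read a PLINK ``--recode A`` (.raw) file into the package's genotype
    frame (IID as sire_id, one 0/1/2 column per marker, NA = missing)."""
    df = pd.read_csv(path, sep=r"\s+", dtype={"IID": str})
    meta = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in df.columns]
    out = df.drop(columns=[c for c in meta if c != "IID"]).set_index("IID")
    out.index.name = "sire_id"
    return out.astype(float)


def config_to_dict(config: SimConfig) -> dict:
    d = {}
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        if isinstance(v, np.ndarray):
            v = v.tolist()
        elif isinstance(v, tuple):
            v = list(v)
        d[f.name] = v
    return d


def config_from_yaml(path: str | Path) -> SimConfig:
    d = yaml.safe_load(Path(path).read_text())
    for key in ("maf_range", "records_per_cow_range"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    for key in ("wvn_h2_profile", "link_trait", "link_wvn"):
        if d.get(key) is not None:
            d[key] = np.asarray(d[key], dtype=float)
    if "vc_trait" in d:
        d["vc_trait"] = {t: tuple(v) for t, v in d["vc_trait"].items()}
    return SimConfig(**d)
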