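"""Stage 2: sire-by-HYS daughter-yield-deviations (hysDYD).

Daughter phenotypes are pre-corrected for the NSL fixed effect and averaged
within sire x HYS cells; each cell carries an effective daughter
contribution (EDC) weight summarizing how much information it holds.  The
connectivity filters then produce the condensed dataset ("Data 2") on which
the kernel models of stages 3-4 operate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from spectragp.errors import EmptyDataError
from spectragp.stage1 import VarianceComponents

log = logging.getLogger(__name__)


def precorrect_and_average(records: pd.DataFrame, nsl_blues: pd.Series,
                           trait: str) -> pd.DataFrame:
    """NSL-adjusted daughter means per (sire, HYS).

    Returns one row per sire x HYS cell with columns dyd (mean adjusted
    phenotype), n_daughters, n_records and herd_id.  Records with an
    unknown sire are excluded (count logged).
    """
    missing_nsl = set(records["nsl_id"].unique()) - set(nsl_blues.index)
    if missing_nsl:
        raise KeyError(f"NSL BLUEs missing for classes: {sorted(missing_nsl)[:10]}")
    df = records.copy()
    unknown = df["sire_id"].isna() | (df["sire_id"].astype(str).isin(("", "0")))
    if unknown.any():
        log.info("excluding %d records with unknown sire", int(unknown.sum()))
        df = df[~unknown]
    df["adj"] = df[trait].to_numpy(dtype=float) - nsl_blues.reindex(df["nsl_id"]).to_numpy()
    grouped = df.groupby(["sire_id", "hys_id"], sort=True)
    out = grouped.agg(
        dyd=("adj", "mean"),
        n_daughters=("cow_id", "nunique"),
        n_records=("adj", "size"),
        herd_id=("herd_id", "first"),
    ).reset_index()
    return out


def compute_edc(records: pd.DataFrame, vc: VarianceComponents,
                strategy=None) -> pd.DataFrame:
    """Effective daughter contribution per (sire, HYS).

    The default strategy is the repeatability-weighted daughter count

        EDC_ij = sum over daughters d of sire i recorded in HYS j of
                 n_d / (n_d + lambda_p),   lambda_p = se2 / (sa2 + sp2)

    where n_d is the daughter's record count in that HYS.  Each daughter's
    contribution saturates at 1 as her record count grows, and the measure
    is strictly increasing in records and daughters.  A different callable
    ``strategy(n_records_per_daughter, vc) -> float`` can be supplied.
    """
    denom = vc.sigma_a2 + vc.sigma_p2
    if denom <= 0 or vc.sigma_e2 <= 0:
        raise ValueError("EDC requires sigma_e2 > 0 and sigma_a2 + sigma_p2 > 0")
    lam_p = vc.sigma_e2 / denom
    if strategy is None:
        def strategy(n_d: np.ndarray, _vc) -> float:
            return float((n_d / (n_d + lam_p)).sum())
    df = records[~(records["sire_id"].isna()
                   | records["sire_id"].astype(str).isin(("", "0")))]
    per_daughter = (df.groupby(["sire_id", "hys_id", "cow_id"], sort=True)
                      .size().rename("n_d").reset_index())
    rows = [
        (sire, hys, strategy(grp["n_d"].to_numpy(dtype=float), vc))
        for (sire, hys), grp in per_daughter.groupby(["sire_id", "hys_id"], sort=True)
    ]
    return pd.DataFrame(rows, columns=["sire_id", "hys_id", "edc"])


def build_dyd_table(records: pd.DataFrame, nsl_blues: pd.Series,
                    vc: VarianceComponents, trait: str) -> pd.DataFrame:
    """DYD means merged with their EDC weights."""
    dyd = precorrect_and_average(records, nsl_blues, trait)
    edc = compute_edc(records, vc)
    return dyd.merge(edc, on=["sire_id", "hys_id"], how="left")


@dataclass
class Data2Filters:
    """Connectivity thresholds; the defaults are the standard editing rules
    for this design (EDC >= 1.6; sires in >= 3 HYS; HYS with >= 3 sires;
    herds with >= 3 HYS)."""

    min_edc: float = 1.6
    min_hys_per_sire: int = 3
    min_sires_per_hys: int = 3
    min_hys_per_herd: int = 3


def filter_data2(dyds: pd.DataFrame, filters: Data2Filters | None = None,
                 genotyped_ids: set | None = None) -> pd.DataFrame:
    """Apply the Data-2 filters jointly, iterated to a fixed point.

    The four conditions interact (removing a sire can drop an HYS below
    three sires, which can drop a herd below three HYS, ...), so they are
    re-applied until stable; the fixed point is independent of application
    order.  An empty result raises, naming the rule at which the last rows
    were lost.
    """
    if filters is None:
        filters = Data2Filters()
    df = dyds
    last_rule = "genotyped-sire membership"
    if genotyped_ids is not None:
        df = df[df["sire_id"].isin(genotyped_ids)]
    if len(df) and filters.min_edc > 0:
        df = df[df["edc"].to_numpy(dtype=float) >= filters.min_edc]
        last_rule = f"EDC >= {filters.min_edc}"
    while len(df):
        n_before = len(df)
        counts = df.groupby("sire_id")["hys_id"].transform("nunique")
        if (counts < filters.min_hys_per_sire).any():
            last_rule = f"sires in >= {filters.min_hys_per_sire} HYS"
        df = df[counts >= filters.min_hys_per_sire]
        if not len(df):
            break
        counts = df.groupby("hys_id")["sire_id"].transform("nunique")
        if (counts < filters.min_sires_per_hys).any():
            last_rule = f"HYS with >= {filters.min_sires_per_hys} sires"
        df = df[counts >= filters.min_sires_per_hys]
        if not len(df):
            break
        counts = df.groupby("herd_id")["hys_id"].transform("nunique")
        if (counts < filters.min_hys_per_herd).any():
            last_rule = f"herds with >= {filters.min_hys_per_herd} HYS"
        df = df[counts >= filters.min_hys_per_herd]
        if len(df) == n_before:
            break
    if not len(df):
        raise EmptyDataError(f"Data-2 filtering removed every row (last rule: {last_rule})")
    return df.reset_index(drop=True)


def data2_summary(data2: pd.DataFrame) -> pd.Series:
    """Descriptive statistics of the condensed dataset (counts, EDC range,
    per-sire / per-HYS / per-herd frequencies)."""
    hys_per_herd = data2.groupby("herd_id")["hys_id"].nunique()
    per_sire = data2.groupby("sire_id").size()
    per_hys = data2.groupby("hys_id").size()
    return pd.Series({
        "n_rows": len(data2),
        "n_sires": data2["sire_id"].nunique(),
        "n_hys": data2["hys_id"].nunique(),
        "n_herds": data2["herd_id"].nunique(),
        "min_edc": data2["edc"].min(),
        "mean_edc": data2["edc"].mean(),
        "max_edc": data2["edc"].max(),
        "min_per_sire": per_sire.min(), "mean_per_sire": per_sire.mean(),
        "max_per_sire": per_sire.max(),
        "min_per_hys": per_hys.min(), "mean_per_hys": per_hys.mean(),
        "max_per_hys": per_hys.max(),
        "min_hys_per_herd": hys_per_herd.min(), "mean_hys_per_herd": hys_per_herd.mean(),
        "max_hys_per_herd": hys_per_herd.max(),
    })
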