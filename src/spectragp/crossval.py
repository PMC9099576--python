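"""New-sire / new-herd cross-validation of the kernel models.

Each replicate samples a set of sires and a set of herds uniformly without
replacement.  Every Data-2 row then falls in exactly one section:

    A — unsampled sire, unsampled herd (training)
    B — unsampled sire, sampled herd (known genotypes, new environments)
    C — sampled sire, unsampled herd (new genotypes, known environments)
    D — sampled sire, sampled herd (new genotypes, new environments)

Sampling a herd makes all of its HYS classes "new".  Models are fitted on
section A only (validation phenotypes masked; their sires and HYS classes
stay in the kernels) and scored by the Pearson correlation between
predicted and observed hysDYD within each section, averaged over
replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from spectragp.errors import DegenerateStatisticError
from spectragp.kernels import KernelMatrix
from spectragp.rkhs import ModelSpec, fit_model, predict_rows

log = logging.getLogger(__name__)

SECTIONS = ("A", "B", "C", "D")


@dataclass
class CvPartition:
    replicate: int
    sampled_sires: set
    sampled_herds: set
    sections: pd.Series  # per Data-2 row, values in {A, B, C, D}


def make_partition(data2: pd.DataFrame, n_sires: int, n_herds: int,
                   seed_or_rng, replicate: int = 0) -> CvPartition:
    """Sample ``n_sires`` sires and ``n_herds`` herds uniformly without
    replacement and label every row with its section."""
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    sires = pd.unique(data2["sire_id"])
    herds = pd.unique(data2["herd_id"])
    if n_sires >= len(sires) or n_herds >= len(herds):
        raise ValueError(
            f"sample sizes ({n_sires} sires, {n_herds} herds) must be smaller than "
            f"the totals ({len(sires)}, {len(herds)})")
    s_new = set(rng.choice(sires, size=n_sires, replace=False)) if n_sires else set()
    h_new = set(rng.choice(herds, size=n_herds, replace=False)) if n_herds else set()
    sire_new = data2["sire_id"].isin(s_new).to_numpy()
    herd_new = data2["herd_id"].isin(h_new).to_numpy()
    labels = np.where(sire_new,
                      np.where(herd_new, "D", "C"),
                      np.where(herd_new, "B", "A"))
    return CvPartition(replicate, s_new, h_new,
                       pd.Series(labels, index=data2.index, name="section"))


def section_fractions(partition: CvPartition) -> dict[str, float]:
    counts = partition.sections.value_counts()
    n = counts.sum()
    return {s: float(counts.get(s, 0)) / n for s in SECTIONS}


def pearson_accuracy(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Product-moment correlation; raises on fewer than 3 pairs or a
    zero-variance side rather than silently returning 0."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.ndim != 1:
        raise ValueError("predicted and observed must be equal-length 1-D arrays")
    if len(predicted) < 3:
        raise DegenerateStatisticError("need at least 3 pairs for a correlation")
    sp, so = predicted.std(), observed.std()
    if sp == 0 or so == 0:
        raise DegenerateStatisticError("zero variance; correlation undefined")
    return float(np.mean((predicted - predicted.mean()) * (observed - observed.mean()))
                 / (sp * so))


@dataclass
class CvResult:
    model: str
    include_gxe: bool
    accuracy: pd.DataFrame       # mean_r, sd_r, n_replicates per section
    per_replicate: pd.DataFrame  # replicate x section accuracies
    fractions: pd.DataFrame      # per-replicate section record fractions


def run_cross_validation(data2: pd.DataFrame, g_kernel: KernelMatrix,
                         env_kernels: dict[str, KernelMatrix | None],
                         specs: list[ModelSpec], n_replicates: int,
                         n_sires: int, n_herds: int, seed: int,
                         ) -> dict[str, CvResult]:
    """Run the replicated sampling scheme for every model spec.

    All models see the same replicate partitions (replicate seeds derive
    deterministically from the master seed), so accuracies are paired
    across models.  A section that is degenerate in some replicate (empty
    or constant) is recorded as missing and excluded from the aggregation.
    """
    master = np.random.SeedSequence(seed)
    rep_seeds = master.spawn(n_replicates)
    partitions = [
        make_partition(data2, n_sires, n_herds, np.random.default_rng(s), r)
        for r, s in enumerate(rep_seeds)
    ]
    results: dict[str, CvResult] = {}
    for spec in specs:
        env_kernel = env_kernels[spec.name] if spec.name != "Base" else None
        rows = []
        fracs = []
        for part in partitions:
            train = (part.sections == "A").to_numpy()
            chain = type(spec.chain)(spec.chain.n_iter, spec.chain.burn_in,
                                     spec.chain.thin,
                                     (spec.chain.seed + 7919 * part.replicate) % (2 ** 31))
            fit = fit_model(data2, g_kernel, env_kernel,
                            ModelSpec(spec.name, spec.include_gxe, chain, spec.prior),
                            train_mask=train)
            pred = predict_rows(fit, data2)
            obs = data2["dyd"].to_numpy(dtype=float)
            acc = {}
            for sec in SECTIONS:
                mask = (part.sections == sec).to_numpy()
                try:
                    acc[sec] = pearson_accuracy(pred[mask], obs[mask])
                except DegenerateStatisticError as exc:
                    log.warning("model %s replicate %d section %s: %s",
                                spec.label, part.replicate, sec, exc)
                    acc[sec] = np.nan
            rows.append(acc)
            fracs.append(section_fractions(part))
        per_rep = pd.DataFrame(rows, index=pd.RangeIndex(n_replicates, name="replicate"))
        agg = pd.DataFrame({
            "mean_r": per_rep.mean(),
            "sd_r": per_rep.std(ddof=1),
            "n_replicates": per_rep.notna().sum(),
        })
        results[spec.label] = CvResult(spec.name, spec.include_gxe, agg, per_rep,
                                       pd.DataFrame(fracs))
    return results


def results_table(results: dict[str, CvResult]) -> pd.DataFrame:
    """Long-format summary: model, gxe, section, mean_r, sd_r, n_replicates."""
    rows = []
    for label, res in results.items():
        for sec in SECTIONS:
            rows.append({
                "model": res.model, "gxe": res.include_gxe, "section": sec,
                "mean_r": res.accuracy.loc[sec, "mean_r"],
                "sd_r": res.accuracy.loc[sec, "sd_r"],
                "n_replicates": int(res.accuracy.loc[sec, "n_replicates"]),
            })
    return pd.DataFrame(rows)


def simulate_data2_frame(n_sires: int, n_herds: int, n_rows: int,
                         rng: np.random.Generator,
                         mean_hys_per_herd: float = 8.0) -> pd.DataFrame:
    """A structural stand-in for a condensed Data-2 table (synthetic): rows
    carry a sire, a herd and an HYS label with realistic multiplicities but
    no phenotypes.  Used for design-level questions (section fractions)
    that depend only on the sire/herd incidence pattern."""
    sires = np.array([f"S{i + 1:04d}" for i in range(n_sires)])
    herds = np.array([f"H{h + 1:03d}" for h in range(n_herds)])
    n_hys_per_herd = np.maximum(1, rng.poisson(mean_hys_per_herd, size=n_herds))
    hys_herd = np.repeat(np.arange(n_herds), n_hys_per_herd)
    hys_ids = np.array([f"{herds[h]}_Y{k}" for k, h in enumerate(hys_herd)])
    # skewed sire usage, as in progeny-test data
    sire_w = rng.gamma(1.5, 1.0, size=n_sires)
    sire_w /= sire_w.sum()
    row_sire = rng.choice(n_sires, size=n_rows, p=sire_w)
    row_hys = rng.integers(0, len(hys_ids), size=n_rows)
    return pd.DataFrame({
        "sire_id": sires[row_sire],
        "hys_id": hys_ids[row_hys],
        "herd_id": herds[hys_herd[row_hys]],
    })


def partition_fraction_study(n_sires_total: int = 483, n_herds_total: int = 406,
                             n_rows: int = 16891, n_sires: int = 100,
                             n_herds: int = 100, n_replicates: int = 20,
                             seed: int = 0) -> pd.DataFrame:
    """Replicated section record-fractions of the sampling design on a
    synthetic Data-2 incidence table; returns one row per replicate with
    the A/B/C/D fractions."""
    rng = np.random.default_rng(seed)
    data2 = simulate_data2_frame(n_sires_total, n_herds_total, n_rows, rng)
    fracs = []
    for r in range(n_replicates):
        part = make_partition(data2, n_sires, n_herds, rng, r)
        fracs.append(section_fractions(part))
    return pd.DataFrame(fracs, index=pd.RangeIndex(n_replicates, name="replicate"))
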