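"""End-to-end study driver: synthetic data -> stage 1 -> stage 2 -> kernels
-> cross-validation.

The driver wires the stages together at desk scale with one master seed.
Chain lengths and editing thresholds default to values sized for a
simulated study of a few hundred sires; the stage functions themselves
default to full-scale settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from spectragp import crossval, kernels, rkhs, stage1, stage2
from spectragp.pedigree import build_a_matrix
from spectragp.simulate import SimConfig, SyntheticDataset, simulate_dataset

#: sire and herd sampling fractions of the validation design (100 of 483
#: sires and 100 of 406 herds), preserved proportionally at smaller scale
DEFAULT_SIRE_FRACTION = 100 / 483
DEFAULT_HERD_FRACTION = 100 / 406


@dataclass
class StudyConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    edit: stage1.EditThresholds = field(default_factory=lambda: stage1.EditThresholds(
        max_dim=540, min_cow_records=8, min_hys_size=8))
    stage1_chain: stage1.ChainConfig = field(default_factory=lambda: stage1.ChainConfig(
        n_iter=800, burn_in=300, thin=2))
    vc_subset_min_hys: int | None = None
    trait: str = "my"
    env_variants: tuple = ("AWN", "PROD")
    scale_kernels_by_p: bool = False
    data2_filters: stage2.Data2Filters = field(default_factory=stage2.Data2Filters)
    rkhs_chain: stage1.ChainConfig = field(default_factory=lambda: stage1.ChainConfig(
        n_iter=1500, burn_in=500, thin=2))
    prior: rkhs.PriorConfig = field(default_factory=rkhs.PriorConfig)
    include_gxe: bool = False
    n_replicates: int = 5
    sire_fraction: float = DEFAULT_SIRE_FRACTION
    herd_fraction: float = DEFAULT_HERD_FRACTION
    fit_full_models: bool = True
    seed: int = 0


@dataclass
class StudyResult:
    config: StudyConfig
    dataset: SyntheticDataset
    records: pd.DataFrame                 # edited, with class labels
    vcs: dict                             # phenotype -> VarianceComponents
    blues: stage1.HysBlueTable
    nsl_blues: pd.Series
    data2: pd.DataFrame
    g_kernel: kernels.KernelMatrix
    env_kernels: dict
    full_fits: dict                       # model label -> RkhsModelFit (all data)
    cv_results: dict                      # model label -> CvResult
    cv_table: pd.DataFrame


def run_study(config: StudyConfig) -> StudyResult:
    rng_seed = config.seed
    sim = config.sim
    if sim.seed != rng_seed:
        d = {f: getattr(sim, f) for f in sim.__dataclass_fields__}
        d["seed"] = rng_seed
        sim = SimConfig(**d)
    dataset = simulate_dataset(sim)

    records = stage1.assign_classes(dataset.records)
    records = stage1.apply_editing(records, config.edit)
    a_matrix = build_a_matrix(dataset.pedigree)

    phenotypes = [t for t in sim.traits] + sim.wvn_columns
    vc_records = (stage1.vc_estimation_subset(records, config.vc_subset_min_hys)
                  if config.vc_subset_min_hys else None)
    chain = stage1.ChainConfig(config.stage1_chain.n_iter, config.stage1_chain.burn_in,
                               config.stage1_chain.thin, rng_seed)
    fits, vcs = stage1.fit_all_phenotypes(records, a_matrix, phenotypes, chain,
                                          vc_records=vc_records,
                                          se_phenotypes=set(sim.traits))
    blues = stage1.extract_hys_blues(fits)

    trait = config.trait
    nsl_blues = fits[trait].nsl["blue"]
    dyds = stage2.build_dyd_table(records, nsl_blues, vcs[trait], trait)
    data2 = stage2.filter_data2(dyds, config.data2_filters,
                                genotyped_ids=set(dataset.genotypes.index))

    qc = kernels.snp_qc(dataset.genotypes)
    g_kernel = kernels.vanraden_g(qc)
    env_k = {v: kernels.build_env_kernel(blues, v, scale_by_p=config.scale_kernels_by_p)
             for v in config.env_variants}

    specs = [rkhs.ModelSpec("Base", False, _chain(config, 1), config.prior)]
    for i, v in enumerate(config.env_variants):
        specs.append(rkhs.ModelSpec(v, False, _chain(config, 2 + i), config.prior))
        if config.include_gxe:
            specs.append(rkhs.ModelSpec(v, True, _chain(config, 100 + i), config.prior))

    full_fits = {}
    if config.fit_full_models:
        for spec in specs:
            env = env_k.get(spec.name)
            full_fits[spec.label] = rkhs.fit_model(data2, g_kernel, env, spec)

    n_sires = max(1, round(config.sire_fraction * data2["sire_id"].nunique()))
    n_herds = max(1, round(config.herd_fraction * data2["herd_id"].nunique()))
    cv_results = crossval.run_cross_validation(
        data2, g_kernel, env_k, specs, config.n_replicates,
        n_sires, n_herds, seed=rng_seed + 10_000)
    return StudyResult(config, dataset, records, vcs, blues, nsl_blues, data2,
                       g_kernel, env_k, full_fits, cv_results,
                       crossval.results_table(cv_results))


def _chain(config: StudyConfig, offset: int) -> stage1.ChainConfig:
    c = config.rkhs_chain
    return stage1.ChainConfig(c.n_iter, c.burn_in, c.thin,
                              (config.seed + 31 * offset) % (2 ** 31))
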