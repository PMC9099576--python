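"""Synthetic test-day data with known ground truth.

The generator emulates the data structure of a national milk-recording
scheme at desk scale: genotyped sires, non-genotyped daughters recorded
monthly in herd-year-season (HYS) contemporary groups, phenotypes for two
production traits (milk yield ``my`` and somatic cell score ``scs``) and a
configurable number of spectral wavenumbers.

Each phenotypic record follows the repeatability animal model

    y = NSL_i + HYS_j + a_k + p_k + (s_sire . f_j) + eps

where ``NSL`` is the lactation-number-by-stage fixed class, ``HYS`` the
herd-year-season class effect, ``a`` the additive genetic value, ``p`` the
cow permanent-environment effect and the optional reaction-norm term
``s_sire . f_j`` induces sire-by-environment interaction on a latent herd
environment factor ``f``.

The latent factor is the load-bearing piece: the same ``f_j`` drives both
the trait HYS effects (through ``link_trait``) and the spectral HYS effects
(through ``link_wvn``), so the environmental component of the spectrum
genuinely carries information about the trait environment — the property
the downstream kernels are designed to exploit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from spectragp.errors import ConfigError, ScalingError

TRAITS = ("my", "scs")

#: Generating variance components per trait: (sigma_a2, sigma_p2, sigma_hys2,
#: sigma_e2).  The non-HYS shares reproduce heritability 0.20 / repeatability
#: 0.40 for milk yield and 0.11 / 0.34 for somatic cell score; the SCS HYS
#: variance share (0.08) is deliberately small relative to its phenotypic
#: variance, as is typical of udder-health traits.
DEFAULT_VC_TRAIT = {
    "my": (2.0, 2.0, 3.0, 6.0),
    "scs": (0.11, 0.23, 0.08, 0.66),
}


def default_wvn_h2_profile(n_wavenumbers: int) -> np.ndarray:
    """Piecewise heritability profile across the spectrum.

    Mimics the canonical shape of milk-FTIR heritability curves: a moderate
    plateau at the high-wavenumber end, a null band (the water-absorption
    region), a higher plateau, a second narrow null band, and an irregular
    tail.  Scaled to any number of wavenumbers.
    """
    x = (np.arange(n_wavenumbers) + 0.5) / n_wavenumbers
    h2 = np.empty(n_wavenumbers)
    h2[x < 0.38] = 0.18
    h2[(x >= 0.38) & (x < 0.55)] = 0.0
    h2[(x >= 0.55) & (x < 0.75)] = 0.35
    h2[(x >= 0.75) & (x < 0.80)] = 0.0
    h2[x >= 0.80] = 0.38
    return h2


@dataclass
class SimConfig:
    """Configuration of the synthetic population and recording scheme.

    Parameters
    ----------
    n_sires, daughters_per_sire, n_herds, years
        Population and recording-grid sizes.  Sires are unrelated,
        genotyped founders; every daughter has a known sire and an unknown
        dam.
    herds_per_sire
        Number of herds over which a sire's daughters are clustered.  Real
        progeny-test daughters come in paternal half-sib groups within
        herds; clustering is what gives sire-by-HYS cells more than one
        daughter and hence non-trivial effective daughter contributions.
    seasons_per_year
        Fixed at 4 (calendar quarters); kept as a field for validation.
    n_wavenumbers, n_snps, maf_range
        Spectrum width, marker count, and the uniform interval from which
        per-marker allele frequencies are drawn.
    vc_trait
        Map trait name -> (sigma_a2, sigma_p2, sigma_hys2, sigma_e2).
    wvn_h2_profile
        Heritability per wavenumber on the unit non-HYS variance scale;
        defaults to :func:`default_wvn_h2_profile`.
    wvn_pe_ratio
        sigma_p2 of a wavenumber as a multiple of its sigma_a2, so
        repeatability tracks heritability (null bands stay null).
    wvn_hys_var
        HYS variance of each wavenumber (non-HYS total is 1).
    env_dim, link_trait, link_wvn, trait_env_share, wvn_env_share
        Latent herd-environment factor dimension and the linear maps from
        factor space to trait / wavenumber HYS effects.  When the link
        matrices are left ``None`` they are built so the factor explains
        ``trait_env_share`` (resp. ``wvn_env_share``) of each HYS-effect
        variance, the remainder being independent noise.
    herd_persistence
        Share of latent-factor variance attached to the herd (permanent)
        rather than the individual HYS class; makes whole herds coherent
        environments, which is what leave-herd-out validation probes.
    gxe_sd
        SD of the sire reaction-norm effect on ``f`` (0 disables GxE).
    records_per_cow_range
        Inclusive range of monthly test-day records per cow.
    """

    n_sires: int = 200
    daughters_per_sire: int = 6
    n_herds: int = 60
    years: int = 2
    seasons_per_year: int = 4
    herds_per_sire: int = 2
    n_wavenumbers: int = 100
    n_snps: int = 400
    maf_range: tuple[float, float] = (0.05, 0.5)
    vc_trait: dict = field(default_factory=lambda: dict(DEFAULT_VC_TRAIT))
    wvn_h2_profile: np.ndarray | None = None
    wvn_pe_ratio: float = 0.4
    wvn_hys_var: float = 0.5
    env_dim: int = 3
    link_trait: np.ndarray | None = None
    link_wvn: np.ndarray | None = None
    trait_env_share: float = 0.9
    wvn_env_share: float = 0.5
    herd_persistence: float = 0.7
    gxe_sd: float = 0.0
    records_per_cow_range: tuple[int, int] = (12, 15)
    nsl_sd: float = 1.0
    start_year: int = 2015
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for name in ("n_sires", "daughters_per_sire", "n_herds", "years",
                     "n_wavenumbers", "n_snps", "env_dim", "herds_per_sire"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive count, got {getattr(self, name)}")
        if self.n_sires < 2:
            raise ConfigError("n_sires must be at least 2")
        if self.seasons_per_year != 4:
            raise ConfigError("seasons_per_year must be 4 (calendar quarters)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        for trait, vc in self.vc_trait.items():
            if len(vc) != 4 or any(v < 0 for v in vc):
                raise ConfigError(f"vc_trait[{trait!r}] must be 4 nonnegative variances, got {vc}")
        prof = self.h2_profile()
        if prof.shape != (self.n_wavenumbers,) or np.any(prof < 0) or np.any(prof > 1):
            raise ConfigError("wvn_h2_profile must have one entry per wavenumber in [0, 1]")
        if np.any((1 + self.wvn_pe_ratio) * prof > 1):
            raise ConfigError("wvn h2 profile plus permanent-environment share exceeds unit variance")
        if not 0 <= self.trait_env_share <= 1 or not 0 <= self.wvn_env_share <= 1:
            raise ConfigError("env shares must lie in [0, 1]")
        if not 0 <= self.herd_persistence <= 1:
            raise ConfigError("herd_persistence must lie in [0, 1]")
        if self.gxe_sd < 0:
            raise ConfigError("gxe_sd must be nonnegative")
        lo, hi = self.records_per_cow_range
        if lo < 1 or hi < lo:
            raise ConfigError(f"records_per_cow_range invalid: {self.records_per_cow_range}")
        if self.records_per_cow_range[1] > self.years * 12:
            raise ConfigError("records_per_cow_range exceeds the recording grid length")

    def h2_profile(self) -> np.ndarray:
        if self.wvn_h2_profile is None:
            return default_wvn_h2_profile(self.n_wavenumbers)
        return np.asarray(self.wvn_h2_profile, dtype=float)

    @property
    def traits(self) -> tuple[str, ...]:
        return tuple(self.vc_trait)

    @property
    def wvn_columns(self) -> list[str]:
        return [f"wvn_{i + 1:04d}" for i in range(self.n_wavenumbers)]


# ---------------------------------------------------------------------------
# population


@dataclass
class Population:
    pedigree: pd.DataFrame          # id, sire, dam ('0' = unknown)
    genotypes: pd.DataFrame         # sire_id index, one 0/1/2 column per SNP
    sire_daughters: dict            # sire_id -> list of cow ids
    cow_herd: dict                  # cow_id -> herd_id
    allele_freq: np.ndarray


def simulate_population(config: SimConfig, rng: np.random.Generator | None = None) -> Population:
    """Unrelated genotyped sires, each with daughters from unknown dams.

    Genotypes are independent SNPs in Hardy-Weinberg proportions with
    allele frequencies drawn uniformly within ``maf_range``.  Daughters are
    clustered into ``herds_per_sire`` herds per sire (paternal half-sib
    groups), mirroring progeny-test structure.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sire_ids = [f"S{i + 1:04d}" for i in range(config.n_sires)]
    p = rng.uniform(*config.maf_range, size=config.n_snps)
    geno = rng.binomial(2, p, size=(config.n_sires, config.n_snps))
    genotypes = pd.DataFrame(
        geno, index=pd.Index(sire_ids, name="sire_id"),
        columns=[f"snp_{j + 1:05d}" for j in range(config.n_snps)],
    )

    herd_ids = [f"H{h + 1:03d}" for h in range(config.n_herds)]
    sire_daughters: dict[str, list[str]] = {}
    cow_herd: dict[str, str] = {}
    ped_rows = [(s, "0", "0") for s in sire_ids]
    cow_counter = 0
    for s in sire_ids:
        herds = rng.choice(config.n_herds, size=min(config.herds_per_sire, config.n_herds),
                           replace=False)
        daughters = []
        for d in range(config.daughters_per_sire):
            cow_counter += 1
            cid = f"C{cow_counter:05d}"
            daughters.append(cid)
            cow_herd[cid] = herd_ids[herds[d % len(herds)]]
            ped_rows.append((cid, s, "0"))
        sire_daughters[s] = daughters
    pedigree = pd.DataFrame(ped_rows, columns=["id", "sire", "dam"])
    return Population(pedigree, genotypes, sire_daughters, cow_herd, p)


# ---------------------------------------------------------------------------
# latent herd environment


@dataclass
class Environment:
    hys_index: pd.DataFrame         # hys_id, herd_id, year, season
    env_factors: pd.DataFrame       # hys_id index, f_1..f_env_dim, column-centered
    trait_effects: pd.DataFrame     # hys_id index, one column per trait
    wvn_effects: pd.DataFrame       # hys_id index, one column per wavenumber


def _default_link(env_dim: int, n_cols: int, total_vars: np.ndarray, share: float) -> np.ndarray:
    """Deterministic link matrix (env_dim x n_cols) with column norms set so
    the latent factor explains ``share`` of each column's variance.

    Directions rotate smoothly across columns so different traits and
    wavenumbers load on different mixtures of the latent dimensions.
    """
    d = np.arange(env_dim)[:, None]
    c = np.arange(n_cols)[None, :]
    raw = np.cos(2 * np.pi * (d + 1) * (c + 1) / (n_cols + env_dim) + d)
    norms = np.linalg.norm(raw, axis=0)
    unit = raw / np.where(norms == 0, 1.0, norms)
    return unit * np.sqrt(share * total_vars)[None, :]


def simulate_hys_environment(config: SimConfig,
                             rng: np.random.Generator | None = None,
                             grid: pd.DataFrame | None = None) -> Environment:
    """Latent factors per HYS class and the HYS effects they induce.

    Each HYS class on the herd x year x season grid receives a latent
    factor ``f_j`` composed of a persistent herd component and an
    HYS-specific deviation; factor columns are centered and scaled to unit
    variance across classes.  Trait and wavenumber HYS effects are linear
    in ``f`` plus independent noise, scaled so the total effect variance
    matches the configured HYS variance.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if grid is None:
        rows = [
            (f"{herd}_{config.start_year + y}_{s + 1}", herd, config.start_year + y, s + 1)
            for herd in (f"H{h + 1:03d}" for h in range(config.n_herds))
            for y in range(config.years)
            for s in range(config.seasons_per_year)
        ]
        grid = pd.DataFrame(rows, columns=["hys_id", "herd_id", "year", "season"])
    n_hys = len(grid)
    herd_codes, herd_uniques = pd.factorize(grid["herd_id"])

    rho = config.herd_persistence
    u = rng.standard_normal((len(herd_uniques), config.env_dim))
    v = rng.standard_normal((n_hys, config.env_dim))
    f = np.sqrt(rho) * u[herd_codes] + np.sqrt(1 - rho) * v
    f -= f.mean(axis=0)
    sd = f.std(axis=0)
    if np.any(sd == 0):
        raise ScalingError("degenerate latent factor (zero variance across HYS classes)")
    f /= sd

    trait_vars = np.array([config.vc_trait[t][2] for t in config.traits])
    bt = config.link_trait
    if bt is None:
        bt = _default_link(config.env_dim, len(config.traits), trait_vars, config.trait_env_share)
    bt = np.asarray(bt, dtype=float)
    wvn_vars = np.full(config.n_wavenumbers, config.wvn_hys_var)
    bw = config.link_wvn
    if bw is None:
        bw = _default_link(config.env_dim, config.n_wavenumbers, wvn_vars, config.wvn_env_share)
    bw = np.asarray(bw, dtype=float)

    def effects(link: np.ndarray, totals: np.ndarray, cols: list[str]) -> pd.DataFrame:
        signal_var = (link ** 2).sum(axis=0)
        noise_var = totals - signal_var
        if np.any(noise_var < -1e-12):
            bad = [cols[i] for i in np.where(noise_var < -1e-12)[0]]
            raise ScalingError(
                f"link variance exceeds total HYS variance for: {bad[:5]}"
                f"{'...' if len(bad) > 5 else ''}")
        noise_var = np.clip(noise_var, 0.0, None)
        noise = rng.standard_normal((n_hys, len(cols))) * np.sqrt(noise_var)[None, :]
        noise -= noise.mean(axis=0)
        vals = f @ link + noise
        return pd.DataFrame(vals, index=grid["hys_id"].to_numpy(), columns=cols)

    trait_eff = effects(bt, trait_vars, list(config.traits))
    wvn_eff = effects(bw, wvn_vars, config.wvn_columns)
    env_factors = pd.DataFrame(f, index=grid["hys_id"].to_numpy(),
                               columns=[f"f_{d + 1}" for d in range(config.env_dim)])
    return Environment(grid.reset_index(drop=True), env_factors, trait_eff, wvn_eff)


# ---------------------------------------------------------------------------
# test-day records


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated dataset, keyed the way the model
    stages estimate it."""

    breeding_values: pd.DataFrame   # animal id index, one column per trait
    pe_effects: pd.DataFrame        # cow id index, one column per trait
    hys_effects: pd.DataFrame       # hys_id index, traits then wavenumbers
    nsl_effects: pd.DataFrame       # nsl_id index, traits then wavenumbers
    env_factors: pd.DataFrame       # hys_id index
    sire_slopes: dict               # trait -> DataFrame sire id x env_dim


@dataclass
class SyntheticDataset:
    config: SimConfig
    records: pd.DataFrame
    pedigree: pd.DataFrame
    genotypes: pd.DataFrame
    truth: SyntheticTruth


_MONTH_TO_SEASON = np.repeat([1, 2, 3, 4], 3)  # Jan-Mar, Apr-Jun, Jul-Sep, Oct-Dec


def _genomic_breeding_values(genotypes: pd.DataFrame, sigma_a2: float,
                             rng: np.random.Generator) -> np.ndarray:
    """Sire additive values as sums of SNP effects, rescaled so the realized
    variance across sires equals ``sigma_a2`` exactly."""
    m = genotypes.to_numpy(dtype=float)
    beta = rng.standard_normal(m.shape[1])
    a = (m - m.mean(axis=0)) @ beta
    sd = a.std()
    if sd == 0:
        a = rng.standard_normal(len(a)) * np.sqrt(sigma_a2)
    else:
        a = a / sd * np.sqrt(sigma_a2)
    return a


def simulate_test_days(config: SimConfig, population: Population,
                       environment: Environment,
                       rng: np.random.Generator | None = None
                       ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Monthly test-day records for every daughter, plus the ground truth.

    Cows calve once, are recorded roughly every 30 days, and start a new
    lactation when days-in-milk exceeds a per-lactation length drawn in
    [300, 560] days — so a small share of records falls beyond the 540-day
    editing cutoff, as in real data.  Trait additive values for sires are
    genomic (sums of SNP effects); daughters receive half the sire value
    plus a Mendelian-sampling deviate of variance 0.75 * sigma_a2 (unknown,
    unrelated dams).  Wavenumber additive values are pedigree normals with
    the configured heritability profile.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    traits = config.traits
    n_w = config.n_wavenumbers
    h2w = config.h2_profile()
    sa_w = h2w
    sp_w = config.wvn_pe_ratio * h2w
    se_w = 1.0 - sa_w - sp_w

    sire_ids = list(population.genotypes.index)
    cow_ids = [c for s in sire_ids for c in population.sire_daughters[s]]
    cow_sire = {c: s for s in sire_ids for c in population.sire_daughters[s]}
    n_s, n_c = len(sire_ids), len(cow_ids)
    sire_pos = {s: i for i, s in enumerate(sire_ids)}

    # trait genetics
    a_sire = np.column_stack([
        _genomic_breeding_values(population.genotypes, config.vc_trait[t][0], rng)
        for t in traits])
    sire_of_cow = np.array([sire_pos[cow_sire[c]] for c in cow_ids])
    mend = rng.standard_normal((n_c, len(traits))) * np.sqrt(
        [0.75 * config.vc_trait[t][0] for t in traits])
    a_cow = 0.5 * a_sire[sire_of_cow] + mend
    p_cow = rng.standard_normal((n_c, len(traits))) * np.sqrt(
        [config.vc_trait[t][1] for t in traits])

    # wavenumber genetics (pedigree-only normals)
    aw_sire = rng.standard_normal((n_s, n_w)) * np.sqrt(sa_w)
    aw_cow = 0.5 * aw_sire[sire_of_cow] + rng.standard_normal((n_c, n_w)) * np.sqrt(0.75 * sa_w)
    pw_cow = rng.standard_normal((n_c, n_w)) * np.sqrt(sp_w)

    # NSL true effects (52 classes)
    nsl_ids = np.arange(1, 53)
    nsl_trait = rng.standard_normal((52, len(traits))) * config.nsl_sd
    nsl_wvn = rng.standard_normal((52, n_w)) * (0.2 * config.nsl_sd)

    # GxE sire slopes
    slope_sd = config.gxe_sd / np.sqrt(config.env_dim)
    sire_slopes = {
        t: pd.DataFrame(rng.standard_normal((n_s, config.env_dim)) * slope_sd,
                        index=pd.Index(sire_ids, name="sire_id"),
                        columns=[f"f_{d + 1}" for d in range(config.env_dim)])
        for t in traits}

    hys_lookup = {h: i for i, h in enumerate(environment.env_factors.index)}
    f_vals = environment.env_factors.to_numpy()
    trait_eff = environment.trait_effects.to_numpy()
    wvn_eff = environment.wvn_effects.to_numpy()

    n_months = config.years * 12
    lo, hi = config.records_per_cow_range
    # paternal half-sib groups calve in seasonal batches: daughters of the
    # same sire in the same herd start milking within a couple of months of
    # each other, which is what gives sire-by-HYS cells real daughter depth
    group_start: dict[tuple[str, str], int] = {}
    rows = []
    row_meta = []  # (cow_idx, hys_idx, nsl_idx)
    for ci, cid in enumerate(cow_ids):
        herd = population.cow_herd[cid]
        n_rec = int(rng.integers(lo, hi + 1))
        key = (cow_sire[cid], herd)
        if key not in group_start:
            group_start[key] = int(rng.integers(0, max(1, n_months - hi - 3)))
        start = int(np.clip(group_start[key] + rng.integers(-2, 3),
                            0, n_months - n_rec))
        dim = float(rng.uniform(5, 35))
        lact = 1
        lact_len = float(rng.uniform(300, 560))
        for r in range(n_rec):
            month_abs = start + r
            year = config.start_year + month_abs // 12
            month = month_abs % 12 + 1
            day = int(rng.integers(5, 28))
            season = int(_MONTH_TO_SEASON[month - 1])
            hys = f"{herd}_{year}_{season}"
            stage = min(int(np.ceil(dim / 30.4)), 13)
            nsl = 13 * (min(lact, 4) - 1) + stage
            rows.append((cid, cow_sire[cid], herd, f"{year:04d}-{month:02d}-{day:02d}",
                         lact, round(dim)))
            row_meta.append((ci, hys_lookup[hys], nsl - 1))
            dim += float(rng.uniform(26, 35))
            if dim > lact_len:
                lact += 1
                dim = float(rng.uniform(5, 35))
                lact_len = float(rng.uniform(300, 560))

    if not rows:
        warnings.warn("no test-day records generated")
    meta = np.array(row_meta)
    ci, hj, ni = meta[:, 0], meta[:, 1], meta[:, 2]
    n_rec_total = len(rows)

    records = pd.DataFrame(rows, columns=["cow_id", "sire_id", "herd_id",
                                          "test_date", "lactation_number", "dim"])
    for ti, t in enumerate(traits):
        se = np.sqrt(config.vc_trait[t][3])
        y = (nsl_trait[ni, ti] + trait_eff[hj, ti] + a_cow[ci, ti] + p_cow[ci, ti]
             + rng.standard_normal(n_rec_total) * se)
        if config.gxe_sd > 0:
            y = y + np.einsum("ij,ij->i",
                              sire_slopes[t].to_numpy()[sire_of_cow[ci]], f_vals[hj])
        records[t] = y

    wvn_y = (nsl_wvn[ni] + wvn_eff[hj] + aw_cow[ci] + pw_cow[ci]
             + rng.standard_normal((n_rec_total, n_w)) * np.sqrt(se_w))
    records = pd.concat([records, pd.DataFrame(wvn_y, columns=config.wvn_columns)], axis=1)

    bv = pd.DataFrame(np.vstack([a_sire, a_cow]),
                      index=pd.Index(sire_ids + cow_ids, name="id"), columns=list(traits))
    # truth is restricted to the HYS classes that actually received records
    observed_hys = environment.env_factors.index[np.unique(hj)]
    truth = SyntheticTruth(
        breeding_values=bv,
        pe_effects=pd.DataFrame(p_cow, index=pd.Index(cow_ids, name="cow_id"),
                                columns=list(traits)),
        hys_effects=pd.concat([environment.trait_effects,
                               environment.wvn_effects], axis=1).loc[observed_hys],
        nsl_effects=pd.DataFrame(np.hstack([nsl_trait, nsl_wvn]),
                                 index=pd.Index(nsl_ids, name="nsl_id"),
                                 columns=list(traits) + config.wvn_columns),
        env_factors=environment.env_factors.loc[observed_hys],
        sire_slopes=sire_slopes,
    )
    return records, truth


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Run the full generator (population, environment, test days) with the
    configured seed and bundle the result."""
    rng = np.random.default_rng(config.seed)
    population = simulate_population(config, rng)
    environment = simulate_hys_environment(config, rng)
    records, truth = simulate_test_days(config, population, environment, rng)
    return SyntheticDataset(config, records, population.pedigree,
                            population.genotypes, truth)
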