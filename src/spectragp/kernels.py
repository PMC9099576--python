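"""Covariance structures for the multi-kernel models.

Genomic relationships among sires follow VanRaden's first method,
G = MM' / (2 sum p(1-p)) with M the allele-frequency-centered genotype
matrix.  Environmental covariance among HYS classes is the linear kernel
E = XX' on standardized environmental covariates: all wavenumber BLUEs
(AWN), their leading principal components (PC2..PC40), or the production
trait BLUEs themselves (PROD).  At observation level the structures are
ZGZ' and WEW', and genotype-by-environment interaction uses their Hadamard
product, which is PSD by the Schur product theorem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from spectragp.errors import KernelError
from spectragp.stage1 import HysBlueTable, pca_hys_blues

SYMMETRY_TOL = 1e-10
PSD_TOL = 1e-8

ENV_VARIANTS = ("AWN", "PC2", "PC10", "PC20", "PC30", "PC40", "PROD")


@dataclass
class KernelMatrix:
    """Labeled symmetric PSD covariance among sires or HYS classes."""

    labels: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise KernelError("label / matrix size mismatch")
        validate_kernel(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def validate_kernel(k: np.ndarray) -> None:
    scale = np.abs(k).max() if k.size else 0.0
    if scale == 0:
        return
    if np.abs(k - k.T).max() > SYMMETRY_TOL * max(1.0, scale):
        raise KernelError("kernel is not symmetric")
    eigvals = np.linalg.eigvalsh((k + k.T) / 2)
    if eigvals.min() < -PSD_TOL * max(eigvals.max(), 1e-300):
        raise KernelError(f"kernel not PSD (min eigenvalue {eigvals.min():.3e})")


# ---------------------------------------------------------------------------
# genotypes


def snp_qc(genotypes: pd.DataFrame, min_call_rate: float = 0.90,
           min_maf: float = 0.05) -> pd.DataFrame:
    """Marker quality control: drop markers with call rate below
    ``min_call_rate`` or minor allele frequency below ``min_maf`` (both
    thresholds inclusive on the keep side), then mean-impute the remaining
    missing genotypes per marker."""
    g = genotypes.to_numpy(dtype=float)
    bad_codes = ~(np.isnan(g) | np.isin(g, (0.0, 1.0, 2.0)))
    if bad_codes.any():
        raise ValueError("genotype codes must be 0/1/2 or missing")
    call_rate = 1.0 - np.isnan(g).mean(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(g, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = (call_rate >= min_call_rate) & (maf >= min_maf)
    if not keep.any():
        raise KernelError("all markers removed by QC")
    g = g[:, keep]
    col_mean = np.nanmean(g, axis=0)
    nan_r, nan_c = np.where(np.isnan(g))
    g[nan_r, nan_c] = col_mean[nan_c]
    return pd.DataFrame(g, index=genotypes.index, columns=genotypes.columns[keep])


def vanraden_g(genotypes: pd.DataFrame) -> KernelMatrix:
    """VanRaden method-1 genomic relationship matrix.

    Uses observed allele frequencies in the genotyped set for centering and
    for the 2 sum p(1-p) denominator.
    """
    m = genotypes.to_numpy(dtype=float)
    if m.size == 0 or m.shape[1] < 1:
        raise KernelError("need at least one marker")
    p = m.mean(axis=0) / 2.0
    denom = 2.0 * (p * (1.0 - p)).sum()
    if denom <= 0:
        raise KernelError("all markers monomorphic; VanRaden denominator is zero")
    mc = m - 2.0 * p
    return KernelMatrix(list(genotypes.index), mc @ mc.T / denom)


# ---------------------------------------------------------------------------
# environmental kernels


def _check_standardized(x: pd.DataFrame, tol: float = 1e-6) -> None:
    mu = x.mean()
    var = x.var(ddof=0)
    bad = list(x.columns[(mu.abs() > tol) | ((var - 1).abs() > tol)])
    if bad:
        raise KernelError(f"covariate columns not standardized: {bad[:10]}")


def build_env_kernel(blues: HysBlueTable, variant: str | list[str],
                     scale_by_p: bool = False,
                     restandardize_pc: bool = True) -> KernelMatrix:
    """Environmental kernel E = XX' among HYS classes.

    ``variant`` selects the covariate set: ``"AWN"`` (all wavenumber
    BLUEs), ``"PCk"`` (first k principal components of the wavenumber
    BLUEs, re-standardized to unit variance by default), ``"PROD"`` (the
    trait BLUEs), or an explicit column list.  ``scale_by_p`` divides by
    the number of covariates, putting kernels with very different column
    counts on a comparable variance scale.
    """
    std = blues.std
    if isinstance(variant, (list, tuple)):
        x = std[list(variant)]
        _check_standardized(x)
        x = x.to_numpy()
    elif variant == "AWN":
        cols = [c for c in std.columns if c.startswith("wvn_")]
        if not cols:
            raise KernelError("no wavenumber columns for variant AWN")
        x = std[cols]
        _check_standardized(x)
        x = x.to_numpy()
    elif variant == "PROD":
        cols = [c for c in std.columns if not c.startswith("wvn_")]
        if not cols:
            raise KernelError("no trait columns for variant PROD")
        x = std[cols]
        _check_standardized(x)
        x = x.to_numpy()
    elif variant.startswith("PC"):
        k = int(variant[2:])
        scores, _ = pca_hys_blues(blues, k)
        x = scores.to_numpy()
        if restandardize_pc:
            x = (x - x.mean(axis=0)) / x.std(axis=0)
    else:
        raise KernelError(f"unknown environmental kernel variant {variant!r}")
    e = x @ x.T
    if scale_by_p:
        e = e / x.shape[1]
    return KernelMatrix(list(blues.hys_ids), e)


def identity_kernel(labels: list) -> KernelMatrix:
    return KernelMatrix(list(labels), np.eye(len(labels)))


# ---------------------------------------------------------------------------
# observation-level expansion


@dataclass
class CvDesign:
    """Observation-to-entity incidence: one sire and one HYS per row."""

    sires: np.ndarray
    hys: np.ndarray

    def __post_init__(self):
        self.sires = np.asarray(self.sires)
        self.hys = np.asarray(self.hys)
        if self.sires.shape != self.hys.shape or self.sires.ndim != 1:
            raise ValueError("sires and hys must be equal-length 1-D arrays")

    @classmethod
    def from_data2(cls, data2: pd.DataFrame) -> "CvDesign":
        return cls(data2["sire_id"].to_numpy(), data2["hys_id"].to_numpy())


def expand_and_interact(g: KernelMatrix, e: KernelMatrix, design: CvDesign,
                        with_gxe: bool = False
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Observation-level kernels K_g = ZGZ', K_e = WEW' and, on request,
    the Hadamard interaction K_ge = K_g o K_e."""
    gi = _label_positions(g.labels, design.sires, "sire")
    ei = _label_positions(e.labels, design.hys, "HYS")
    k_g = g.values[np.ix_(gi, gi)]
    k_e = e.values[np.ix_(ei, ei)]
    k_ge = k_g * k_e if with_gxe else None
    return k_g, k_e, k_ge


def _label_positions(labels: list, wanted: np.ndarray, what: str) -> np.ndarray:
    pos = {lab: i for i, lab in enumerate(labels)}
    missing = [w for w in dict.fromkeys(wanted.tolist()) if w not in pos]
    if missing:
        raise KernelError(f"unknown {what} labels in design: {missing[:10]}")
    return np.array([pos[w] for w in wanted], dtype=np.intp)
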