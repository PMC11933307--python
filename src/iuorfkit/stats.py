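"""Screen statistics and the ddCt translation-initiation index.

Two numeric procedures: (1) kinase-overexpression plate-screen hit
calling — Shapiro-Wilk normality gate, per-entry Z scores against the
whole kinase set, two-sided normal P values, optional Benjamini-
Hochberg FDR adjustment; (2) the qPCR ddCt initiation index with double
background correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class RatioTable:
    """Labeled screen ratios; rows matching ``control_label`` are controls."""

    entries: tuple[tuple[str, float], ...]
    control_label: str | None = None

    def __post_init__(self) -> None:
        labels = [label for label, _ in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("ratio labels must be unique")
        for label, ratio in self.entries:
            if not ratio > 0:
                raise ValueError(f"ratio for {label!r} must be positive, got {ratio}")


@dataclass(frozen=True)
class ZResult:
    label: str
    ratio: float
    z: float
    p_two_sided: float
    is_hit: bool
    is_control: bool = False


@dataclass(frozen=True)
class CtRecord:
    """One qPCR replicate: target/reference Ct at initiating and background sites."""

    replicate: str
    ct_target_tis: float
    ct_target_bg: float
    ct_ref_tis: float
    ct_ref_bg: float

    def __post_init__(self) -> None:
        for name in ("ct_target_tis", "ct_target_bg", "ct_ref_tis", "ct_ref_bg"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise ValueError(f"replicate {self.replicate!r}: {name} missing or non-finite")


@dataclass(frozen=True)
class InitiationIndex:
    """Per-replicate ddCt indexes with arithmetic and geometric summaries.

    The geometric mean is the log-scale-unbiased estimator for
    fold-change data (index = 2^-ddCt with Gaussian Ct noise); the
    arithmetic mean +/- SD matches how such assays are usually reported.
    """

    per_replicate: tuple[float, ...]
    mean: float
    sd: float
    geometric_mean: float


def p_from_z(z: float) -> float:
    """Two-sided normal P value, 2*(1 - Phi(|z|))."""
    if not math.isfinite(z):
        raise ValueError("z must be finite")
    return float(2.0 * sps.norm.sf(abs(z)))


def zscore_table(table: RatioTable, alpha: float = 0.05) -> list[ZResult]:
    """Z scores of screen ratios against the whole (non-control) set.

    Centering and scaling use the sample mean and SD (ddof=1) of the
    non-control entries; hits are entries with two-sided P < alpha.
    """
    included = [
        r for label, r in table.entries if label != table.control_label
    ]
    if len(included) < 3:
        raise ValueError("need at least 3 non-control entries")
    arr = np.asarray(included, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if sd == 0.0:
        raise ValueError("degenerate screen: zero variance in ratios")
    all_ratios = np.asarray([r for _, r in table.entries], dtype=float)
    zs = (all_ratios - mean) / sd
    ps = 2.0 * sps.norm.sf(np.abs(zs))  # vectorized: screens can be large
    results = []
    for (label, ratio), z, p in zip(table.entries, zs.tolist(), ps.tolist()):
        is_control = label == table.control_label
        results.append(
            ZResult(
                label=label,
                ratio=ratio,
                z=z,
                p_two_sided=p,
                is_hit=(p < alpha) and not is_control,
                is_control=is_control,
            )
        )
    return results


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and P value (delegates to scipy)."""
    arr = np.asarray(values, dtype=float)
    if not 3 <= arr.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(arr) == 0:
        raise ValueError("constant vector: Shapiro-Wilk undefined")
    res = sps.shapiro(arr)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted P values, input order preserved."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1)) or np.any(~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = sps.false_discovery_control(arr, method="bh")
    return [float(x) for x in adjusted]


def initiation_index(records: Sequence[CtRecord]) -> InitiationIndex:
    """ddCt initiation index with double background correction.

    Per replicate: dCt_target = ct_target_tis - ct_target_bg,
    dCt_ref = ct_ref_tis - ct_ref_bg, index = 2^-(dCt_target - dCt_ref).
    """
    if not records:
        raise ValueError("need at least one replicate")
    per_rep = []
    for rec in records:
        d_target = rec.ct_target_tis - rec.ct_target_bg
        d_ref = rec.ct_ref_tis - rec.ct_ref_bg
        per_rep.append(2.0 ** -(d_target - d_ref))
    arr = np.asarray(per_rep, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
    return InitiationIndex(
        per_replicate=tuple(per_rep),
        mean=float(arr.mean()),
        sd=sd,
        geometric_mean=float(np.exp(np.mean(np.log(arr)))),
    )
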