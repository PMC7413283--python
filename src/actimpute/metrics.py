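"""Evaluation statistics for (original, imputed) record-set pairs.

Reconstruction error is scored only on the cells that were actually imputed
(partial RMSE / partial MAE).  Preservation of within-day structure is scored
through the RMSE, across records, of three per-record aggregates: the sample
standard deviation, the intradaily variability index (IV), and the minutes of
moderate-to-vigorous physical activity (MVPA) inside the missing interval.

IV is the nonparametric circadian fragmentation statistic

    IV = [N * sum_{j=2..N} (X_j - X_{j-1})^2] / [(N-1) * sum_j (X_j - Xbar)^2]

which is ~2 for white noise and near 0 for a slowly varying series.  MVPA
uses the 10-minute bout rule: a bout is credited when at least 80% of a
10-minute window exceeds the intensity cutoff (1267 counts/min for uniaxial
devices, 2691 counts/min for triaxial magnitude data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .records import ActivityRecord, MissingMask, RecordSet

MVPA_CUTOFF_UNIAXIAL = 1267.0
MVPA_CUTOFF_MAGNITUDE = 2691.0


@dataclass
class MvpaConfig:
    """Cutoff and bout rule for MVPA detection."""

    cutoff: float = MVPA_CUTOFF_UNIAXIAL
    bout_len: int = 10
    bout_fraction: float = 0.8
    strict_fraction: bool = False  # True: require fraction strictly > bout_fraction

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not (0 < self.bout_fraction <= 1):
            raise ValueError("bout_fraction must lie in (0, 1]")
        if self.bout_len < 1:
            raise ValueError("bout_len must be >= 1")

    @classmethod
    def for_axis(cls, axis_kind: str, **kwargs) -> "MvpaConfig":
        cutoff = MVPA_CUTOFF_UNIAXIAL if axis_kind == "uniaxial" else MVPA_CUTOFF_MAGNITUDE
        return cls(cutoff=cutoff, **kwargs)


def _aligned_matrices(origin: RecordSet, imputed: RecordSet, masks) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = origin.values_matrix()
    xi = imputed.values_matrix()
    if x.shape != xi.shape:
        raise ValueError("origin and imputed record sets are not aligned")
    if masks is None:
        raise ValueError("masks are required")
    if isinstance(masks, RecordSet):
        mask_list = masks.masks
    elif isinstance(masks, list):
        mask_list = masks
    else:
        mask_list = None
    if mask_list is not None:
        flags = np.stack([m.flags if isinstance(m, MissingMask) else np.asarray(m, bool) for m in mask_list])
    else:
        flags = np.asarray(masks, dtype=bool)
    if flags.shape != x.shape:
        raise ValueError("mask shape does not match record sets")
    return x, xi, flags


def partial_rmse(origin: RecordSet, imputed: RecordSet, masks) -> float:
    """Root-mean-square error over the imputed (masked) cells only."""
    x, xi, flags = _aligned_matrices(origin, imputed, masks)
    n = int(flags.sum())
    if n == 0:
        raise ValueError("partial RMSE requires at least one masked cell")
    diff = (x - xi)[flags]
    return float(np.sqrt(np.sum(diff**2) / n))


def partial_mae(origin: RecordSet, imputed: RecordSet, masks) -> float:
    """Mean absolute error over the imputed (masked) cells only."""
    x, xi, flags = _aligned_matrices(origin, imputed, masks)
    n = int(flags.sum())
    if n == 0:
        raise ValueError("partial MAE requires at least one masked cell")
    return float(np.abs((x - xi)[flags]).mean())


def record_sd(record: ActivityRecord | np.ndarray, ddof: int = 1) -> float:
    """Sample standard deviation of a record (divisor N - ddof)."""
    values = record.values if isinstance(record, ActivityRecord) else np.asarray(record, float)
    if values.size <= ddof:
        raise ValueError("record too short for the requested divisor")
    return float(np.std(values, ddof=ddof))


def iv_index(record: ActivityRecord | np.ndarray) -> float:
    """Intradaily variability; NaN (flagged undefined) for a constant record."""
    values = record.values if isinstance(record, ActivityRecord) else np.asarray(record, float)
    n = values.size
    if n < 2:
        raise ValueError("IV requires at least two values")
    denom = np.sum((values - values.mean()) ** 2)
    if denom == 0.0:
        return float("nan")
    num = np.sum(np.diff(values) ** 2)
    return float(n * num / ((n - 1) * denom))


def mvpa_minutes(values, cfg: MvpaConfig | None = None) -> int:
    """Minutes of MVPA credited by greedy, non-overlapping bout scanning.

    Scanning left to right, a window of ``bout_len`` consecutive minutes with
    at least ``bout_fraction`` of its values above the cutoff credits
    ``bout_len`` minutes and the scan jumps past it; otherwise it advances by
    one minute.
    """
    cfg = cfg or MvpaConfig()
    if isinstance(values, ActivityRecord):
        values = values.values
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < cfg.bout_len:
        return 0
    above = values > cfg.cutoff
    needed = cfg.bout_fraction * cfg.bout_len
    total = 0
    t = 0
    while t <= n - cfg.bout_len:
        hits = int(above[t : t + cfg.bout_len].sum())
        ok = hits > needed if cfg.strict_fraction else hits >= needed
        if ok:
            total += cfg.bout_len
            t += cfg.bout_len
        else:
            t += 1
    return total


def _masked_run(values: np.ndarray, flags: np.ndarray) -> np.ndarray:
    return values[flags]


def rmse_of_aggregate(
    origin: RecordSet,
    imputed: RecordSet,
    aggregator: str,
    masks=None,
    cfg: MvpaConfig | None = None,
    ddof: int = 1,
) -> float:
    """RMSE across records of a per-record aggregate (sd, iv, or MVPA in the
    missing interval).  Records whose IV is undefined in either version are
    excluded, with the divisor reduced accordingly."""
    x = origin.values_matrix()
    xi = imputed.values_matrix()
    if x.shape != xi.shape:
        raise ValueError("origin and imputed record sets are not aligned")
    m = x.shape[0]
    if aggregator == "sd":
        a = np.array([record_sd(row, ddof) for row in x])
        b = np.array([record_sd(row, ddof) for row in xi])
    elif aggregator == "iv":
        a = np.array([iv_index(row) for row in x])
        b = np.array([iv_index(row) for row in xi])
    elif aggregator == "mvpa_missing_only":
        if masks is None:
            raise ValueError("mvpa_missing_only requires masks")
        _, _, flags = _aligned_matrices(origin, imputed, masks)
        cfg = cfg or MvpaConfig.for_axis(origin.records[0].axis_kind)
        a = np.array([float(mvpa_minutes(_masked_run(x[i], flags[i]), cfg)) for i in range(m)])
        b = np.array([float(mvpa_minutes(_masked_run(xi[i], flags[i]), cfg)) for i in range(m)])
    else:
        raise ValueError("aggregator must be 'sd', 'iv' or 'mvpa_missing_only'")
    keep = np.isfinite(a) & np.isfinite(b)
    dropped = int(m - keep.sum())
    if dropped:
        warnings.warn(f"excluded {dropped} record(s) with undefined {aggregator}")
    if keep.sum() == 0:
        raise ValueError("no records with a defined aggregate")
    return float(np.sqrt(np.mean((a[keep] - b[keep]) ** 2)))


@dataclass
class MetricsReport:
    """Headline evaluation metrics for one (original, imputed) pair."""

    partial_rmse: float
    partial_mae: float
    rmse_sd: float
    rmse_iv: float
    rmse_mvpa: float
    sd_origin: np.ndarray = field(repr=False, default=None)
    sd_imputed: np.ndarray = field(repr=False, default=None)
    iv_origin: np.ndarray = field(repr=False, default=None)
    iv_imputed: np.ndarray = field(repr=False, default=None)
    mvpa_origin: np.ndarray = field(repr=False, default=None)
    mvpa_imputed: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict[str, float]:
        return {
            "partial_rmse": self.partial_rmse,
            "partial_mae": self.partial_mae,
            "rmse_sd": self.rmse_sd,
            "rmse_iv": self.rmse_iv,
            "rmse_mvpa": self.rmse_mvpa,
        }


def compute_report(
    origin: RecordSet,
    imputed: RecordSet,
    masks=None,
    cfg: MvpaConfig | None = None,
    ddof: int = 1,
) -> MetricsReport:
    """All headline metrics plus per-record aggregates for one pair of sets."""
    if masks is None:
        masks = origin.masks if origin.masks is not None else imputed.masks
    x, xi, flags = _aligned_matrices(origin, imputed, masks)
    cfg = cfg or MvpaConfig.for_axis(origin.records[0].axis_kind)
    m = x.shape[0]
    return MetricsReport(
        partial_rmse=partial_rmse(origin, imputed, masks),
        partial_mae=partial_mae(origin, imputed, masks),
        rmse_sd=rmse_of_aggregate(origin, imputed, "sd", ddof=ddof),
        rmse_iv=rmse_of_aggregate(origin, imputed, "iv"),
        rmse_mvpa=rmse_of_aggregate(origin, imputed, "mvpa_missing_only", masks=masks, cfg=cfg),
        sd_origin=np.array([record_sd(r, ddof) for r in x]),
        sd_imputed=np.array([record_sd(r, ddof) for r in xi]),
        iv_origin=np.array([iv_index(r) for r in x]),
        iv_imputed=np.array([iv_index(r) for r in xi]),
        mvpa_origin=np.array([float(mvpa_minutes(x[i][flags[i]], cfg)) for i in range(m)]),
        mvpa_imputed=np.array([float(mvpa_minutes(xi[i][flags[i]], cfg)) for i in range(m)]),
    )
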