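"""Outlier detection (Grubbs test), per-group descriptive statistics and the
strain-viability filter.

Readout groups are small (typically 6 measurements per strain x reporter),
so outlier handling uses the classical Grubbs test for a single outlier,
applied iteratively until no point exceeds the critical value or removal
would leave fewer than ``min_n`` usable measurements.  The test assumes the
remaining data are drawn from a normal distribution and is applied to raw
counts, before any normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Hashable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io import ReadoutTable
from .manifest import StrainManifest

__all__ = [
    "QCConfig",
    "GrubbsResult",
    "GroupSummary",
    "grubbs_statistic",
    "grubbs_critical",
    "grubbs_test",
    "flag_outliers",
    "summarize_groups",
    "filter_viable",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCConfig:
    """Outlier policy: two-sided Grubbs at ``alpha``, iterated by default,
    never trimming a group below ``min_n`` usable values."""

    alpha: float = 0.05
    policy: str = "iterative"  # or "single_pass"
    min_n: int = 4

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.policy not in ("iterative", "single_pass"):
            raise ValueError(f"unknown policy {self.policy!r}")
        if self.min_n < 2:
            raise ValueError("min_n must be at least 2")


@dataclass(frozen=True)
class GrubbsResult:
    """Outcome of one Grubbs test: statistic, sample size, candidate key,
    and (when tested against a level) the critical value."""

    G: float
    n: int
    candidate: Hashable
    G_crit: float | None = None
    alpha: float | None = None

    @property
    def is_outlier(self) -> bool:
        return self.G_crit is not None and self.G > self.G_crit


def _as_keyed(values, keys) -> tuple[np.ndarray, list]:
    if isinstance(values, Mapping):
        if keys is not None:
            raise ValueError("pass keys either in the mapping or separately, not both")
        keys = list(values.keys())
        arr = np.asarray([values[k] for k in keys], dtype=float)
    else:
        arr = np.asarray(values, dtype=float)
        keys = list(range(len(arr))) if keys is None else list(keys)
        if len(keys) != len(arr):
            raise ValueError("keys and values have different lengths")
    return arr, keys


def grubbs_statistic(values: Sequence[float] | Mapping, keys=None) -> GrubbsResult:
    """G = max |x_i - mean| / s with the n-1 sample SD; the candidate outlier
    is the argmax.  Requires n >= 3 and non-zero variance."""
    arr, keys = _as_keyed(values, keys)
    n = len(arr)
    if n < 3:
        raise ValueError(f"Grubbs test needs at least 3 values, got {n}")
    s = arr.std(ddof=1)
    if s == 0:
        raise ValueError("degenerate sample: zero variance")
    dev = np.abs(arr - arr.mean())
    idx = int(np.argmax(dev))
    return GrubbsResult(G=float(dev[idx] / s), n=n, candidate=keys[idx])


@lru_cache(maxsize=None)
def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value.

    ``G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2))`` with ``t`` the
    upper ``alpha/(2n)`` quantile of Student's t with ``n-2`` degrees of
    freedom.  As ``alpha -> 0`` this approaches the attainable upper bound
    ``(n-1)/sqrt(n)``.
    """
    if n < 3:
        raise ValueError("Grubbs critical value requires n >= 3")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2)))


def grubbs_test(values, alpha: float = 0.05, keys=None) -> GrubbsResult:
    """Grubbs statistic plus the critical value at ``alpha``."""
    res = grubbs_statistic(values, keys=keys)
    return GrubbsResult(
        G=res.G,
        n=res.n,
        candidate=res.candidate,
        G_crit=grubbs_critical(res.n, alpha),
        alpha=alpha,
    )


def flag_outliers(
    values,
    alpha: float = 0.05,
    policy: str = "iterative",
    min_n: int = 4,
    keys=None,
) -> list:
    """Keys of measurements flagged as outliers, in removal order.

    Under the iterative policy the test-and-remove cycle repeats until no
    point exceeds the critical value or a removal would leave fewer than
    ``min_n`` values; ``single_pass`` removes at most one.  A group whose
    remaining values are identical stops cleanly (nothing left to flag).
    """
    arr, key_list = _as_keyed(values, keys)
    if len(arr) < 3:
        raise ValueError(f"Grubbs test needs at least 3 values, got {len(arr)}")
    if policy not in ("iterative", "single_pass"):
        raise ValueError(f"unknown policy {policy!r}")

    flagged: list = []
    current = arr.copy()
    current_keys = list(key_list)
    while len(current) >= 3 and len(current) - 1 >= min_n:
        if current.std(ddof=1) == 0:
            break
        res = grubbs_test(current, alpha=alpha, keys=current_keys)
        if not res.is_outlier:
            break
        pos = current_keys.index(res.candidate)
        flagged.append(res.candidate)
        current = np.delete(current, pos)
        current_keys.pop(pos)
        if policy == "single_pass":
            break
    return flagged


@dataclass(frozen=True)
class GroupSummary:
    """Descriptive statistics for one group x reporter after outlier removal.

    ``log_bio_means`` aggregates the used log counts per biological
    replicate — the exchangeable unit for strain-vs-wild-type testing when
    technical replicates are nested within cultures.
    """

    group_id: str
    reporter: str
    n_raw: int
    n_used: int
    mean: float
    sd: float
    outlier_flags: tuple = ()
    values: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    log_bio_means: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    @property
    def cv(self) -> float:
        """Within-group coefficient of variation (SD over mean)."""
        return self.sd / self.mean if self.mean > 0 else float("nan")


def summarize_groups(
    table: ReadoutTable, qc: QCConfig = QCConfig()
) -> dict[tuple[str, str], GroupSummary]:
    """Mean and SD of each group x reporter, with Grubbs-flagged readouts
    excluded.  Groups too small to test (n < 3) pass through untouched."""
    out: dict[tuple[str, str], GroupSummary] = {}
    for (group, reporter), sub in table.df.groupby(["group_id", "reporter"], sort=False):
        vals = sub["counts"].to_numpy()
        rep_keys = list(zip(sub["bio_rep"], sub["tech_rep"]))
        if len(vals) >= 3:
            flags = flag_outliers(
                vals, alpha=qc.alpha, policy=qc.policy, min_n=qc.min_n, keys=rep_keys
            )
        else:
            flags = []
        keep = np.array([k not in flags for k in rep_keys], dtype=bool)
        used = vals[keep]
        used_bios = sub["bio_rep"].to_numpy()[keep]
        log_bio_means = np.array(
            [np.log(used[used_bios == b]).mean() for b in np.unique(used_bios)]
        )
        if flags:
            logger.info(
                "outliers in %s/%s: %s", group, reporter, [tuple(map(int, f)) for f in flags]
            )
        out[(group, reporter)] = GroupSummary(
            group_id=group,
            reporter=reporter,
            n_raw=len(vals),
            n_used=len(used),
            mean=float(used.mean()),
            sd=float(used.std(ddof=1)) if len(used) > 1 else 0.0,
            outlier_flags=tuple(flags),
            values=used,
            log_bio_means=log_bio_means,
        )
    return out


def filter_viable(manifest: StrainManifest, table: ReadoutTable) -> ReadoutTable:
    """Drop readouts of non-viable strains.

    Every group must be a manifest strain, the wild-type vehicle, or a
    control/compound condition (which pass through untouched).
    """
    viable = {s.gene_id for s in manifest.viable_strains}
    nonviable = {s.gene_id for s in manifest.strains} - viable
    allowed_extra = {manifest.wildtype_id, "control"}

    keep_groups = []
    dropped = []
    for g in table.groups:
        if g in viable or g in allowed_extra:
            keep_groups.append(g)
        elif g in nonviable:
            dropped.append(g)
        else:
            raise ValueError(f"unknown group {g!r}: not in manifest and not a control")
    if dropped:
        logger.info("dropping %d non-viable strain group(s): %s", len(dropped), dropped)
    sub = table.df[table.df["group_id"].isin(keep_groups)].reset_index(drop=True)
    result = ReadoutTable(df=sub, assay_variant=table.assay_variant)
    logger.info("usable vehicle count: %d", len(result.groups))
    return result
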