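"""Screen-stage inference: wild-type normalization, concordance, the inert
circle, strain classification and the selective-hit call.

Each strain is reduced to a point in *fold space*: (FF fold, REN fold),
the QC-filtered mean of each reporter divided by the wild-type mean, so the
wild type sits at (1, 1).  Strains within a circle of radius twice the SD
of wild-type-normalized FF measurements (the "inert circle") are called
unchanged; strains outside fall into the four quadrants of up/down
combinations, except for the screen's actual objective: a *selective hit*,
which raises FF well beyond the circle while leaving REN inside the
wild-type band and statistically indistinguishable from wild type.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ReadoutTable
from .manifest import StrainManifest
from .qc import GroupSummary, QCConfig, filter_viable, summarize_groups

__all__ = [
    "ScreenConfig",
    "ScreenResult",
    "summarize_and_normalize",
    "pearson_across_strains",
    "inert_radius",
    "classify_strains",
    "run_screen",
]

logger = logging.getLogger(__name__)

CLASSES = (
    "inert",
    "q1_ren_up",
    "q2_both_up",
    "q3_ff_up",
    "q4_both_down",
    "selective_hit",
)

POINT_COLUMNS = ["ff_fold", "ren_fold", "distance", "p_ff", "p_ren", "q_ff", "q_ren"]


@dataclass(frozen=True)
class ScreenConfig:
    """Analysis knobs for the screen stage.

    ``radius_source`` picks the estimator of the measurement-level
    normalized SD behind the inert circle: ``"pooled"`` (default) pools the
    within-group CV over every usable vehicle — the assay noise is
    multiplicative and homoscedastic, so each group's scatter estimates the
    same CV and the wild-type group alone (six readouts) would give a very
    unstable radius; ``"wildtype"`` uses only the wild-type readouts, the
    literal construction.
    """

    alpha: float = 0.05
    qc: QCConfig = QCConfig()
    min_n: int = 4
    radius_source: str = "pooled"  # or "wildtype"
    radius_override: float | None = None
    ren_band_override: float | None = None
    #: used when replicate data cannot support a radius estimate
    radius_fallback: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.radius_source not in ("pooled", "wildtype"):
            raise ValueError(f"unknown radius_source {self.radius_source!r}")


@dataclass
class ScreenResult:
    """Outcome of one screen analysis."""

    points: pd.DataFrame  # index: strain_id; columns: POINT_COLUMNS
    rho: float
    radius: float
    ren_band: float
    classes: pd.Series  # strain_id -> class label
    hits: list[str]
    wildtype_id: str
    excluded: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        counts = self.classes.value_counts().to_dict()
        return {
            "n_strains": int(len(self.points)),
            "rho": None if math.isnan(self.rho) else float(self.rho),
            "radius": float(self.radius),
            "ren_band": float(self.ren_band),
            "class_counts": {c: int(counts.get(c, 0)) for c in CLASSES},
            "hits": list(self.hits),
            "excluded": list(self.excluded),
        }


def _welch_log_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided unequal-variance t-test on log counts.

    Degenerate samples (zero variance in both groups) carry no evidence and
    map to p = 1 so downstream FDR adjustment stays defined.
    """
    la, lb = np.log(a), np.log(b)
    if la.std() == 0 and lb.std() == 0:
        return 0.0 if la.mean() != lb.mean() else 1.0
    res = stats.ttest_ind(la, lb, equal_var=False)
    p = float(res.pvalue)
    return p if not math.isnan(p) else 1.0


def _pooled_bio_sd(summaries, reporter: str) -> tuple[float, int]:
    """SD of per-culture (biological-replicate) mean log counts, pooled
    within groups across the whole screen.

    Technical replicates are nested within cultures, so the culture mean is
    the exchangeable unit for strain-vs-wild-type comparisons; with only
    two cultures per strain the variance must be pooled across strains to
    be usable (each group contributes n_bio - 1 degrees of freedom).
    """
    num = 0.0
    df = 0
    for (_, rep), s in summaries.items():
        if rep != reporter or len(s.log_bio_means) < 2:
            continue
        bm = s.log_bio_means
        num += float(((bm - bm.mean()) ** 2).sum())
        df += len(bm) - 1
    return (math.sqrt(num / df) if df > 0 else float("nan")), df


def _pooled_cv(summaries, reporter: str) -> tuple[float, int]:
    """Marginal measurement CV pooled across groups.

    Estimates the culture-level and within-culture log-variance components
    by one-way random-effects pooling (each group's scatter estimates the
    same assay noise) and converts the marginal log-variance to a CV via
    the lognormal relation ``cv^2 = exp(sigma^2) - 1``.  A naive pooled
    within-group SD would underestimate the marginal SD when readouts are
    clustered by culture.
    """
    ss_tech = 0.0
    df_tech = 0
    ss_bio = 0.0
    df_bio = 0
    tech_sizes: list[int] = []
    for (g, rep), s in summaries.items():
        if rep != reporter or s.n_used < 2:
            continue
        logs = np.log(s.values)
        bm = s.log_bio_means
        if len(bm) >= 2:
            ss_bio += float(((bm - bm.mean()) ** 2).sum())
            df_bio += len(bm) - 1
        # within-culture scatter: total SS minus between-culture SS
        n_per = s.n_used / max(len(bm), 1)
        within_ss = float(((logs - logs.mean()) ** 2).sum()) - n_per * float(
            ((bm - bm.mean()) ** 2).sum()
        )
        if s.n_used - len(bm) > 0:
            ss_tech += max(within_ss, 0.0)
            df_tech += s.n_used - len(bm)
            tech_sizes.append(n_per)
    if df_bio == 0 and df_tech == 0:
        return float("nan"), 0
    var_tech = ss_tech / df_tech if df_tech > 0 else 0.0
    if df_bio > 0:
        var_bm = ss_bio / df_bio
        n_t = float(np.mean(tech_sizes)) if tech_sizes else 1.0
        var_bio = max(var_bm - var_tech / n_t, 0.0)
    else:
        var_bio = 0.0
    sigma2 = var_bio + var_tech
    return math.sqrt(math.expm1(sigma2)), df_bio + df_tech


#: minimum pooled degrees of freedom before the culture-level z-test is
#: preferred over a Welch test on individual readouts.
_MIN_POOLED_DF = 8


def _strain_vs_wt_p(
    s: "GroupSummary", wt: "GroupSummary", pooled_sd: float, pooled_df: int
) -> float:
    """Two-sided strain-vs-wild-type test on log counts.

    Uses the culture-level z-test (difference of mean log culture means,
    standardized by the pooled culture SD) whenever the design supports it;
    falls back to a Welch t-test on the individual log readouts when there
    is no replicate nesting to respect (single culture or too few pooled
    degrees of freedom).
    """
    nb_s, nb_w = len(s.log_bio_means), len(wt.log_bio_means)
    if pooled_df >= _MIN_POOLED_DF and nb_s >= 2 and nb_w >= 2 and pooled_sd > 0:
        z = (s.log_bio_means.mean() - wt.log_bio_means.mean()) / (
            pooled_sd * math.sqrt(1.0 / nb_s + 1.0 / nb_w)
        )
        return float(2.0 * stats.norm.sf(abs(z)))
    return _welch_log_p(s.values, wt.values)


def summarize_and_normalize(
    table: ReadoutTable,
    wildtype_id: str,
    qc: QCConfig = QCConfig(),
    min_n: int = 4,
    summaries: dict[tuple[str, str], GroupSummary] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-strain normalized points with strain-vs-wild-type tests.

    Folds are ratios of QC-filtered means; p-values come from two-sided
    tests on log counts against the wild-type readouts (culture-level
    z-test with screen-pooled variance when the nested replicate design
    supports it, Welch otherwise), adjusted per reporter across strains by
    Benjamini-Hochberg.  Returns the points table (wild type excluded) and
    the list of strains dropped for having fewer than ``min_n`` usable
    readouts on either reporter.
    """
    summaries = summaries if summaries is not None else summarize_groups(table, qc)
    groups = [g for g in table.groups if g != wildtype_id]
    wt_ff = summaries.get((wildtype_id, "FF"))
    wt_ren = summaries.get((wildtype_id, "REN"))
    if wt_ff is None or wt_ren is None:
        raise ValueError(f"wild-type group {wildtype_id!r} missing from table")
    if wt_ff.n_used < min_n or wt_ren.n_used < min_n:
        raise ValueError(
            f"wild-type group has fewer than {min_n} usable readouts per reporter"
        )

    sd_ff, df_ff = _pooled_bio_sd(summaries, "FF")
    sd_ren, df_ren = _pooled_bio_sd(summaries, "REN")

    rows: dict[str, dict] = {}
    excluded: list[str] = []
    for g in groups:
        s_ff, s_ren = summaries[(g, "FF")], summaries[(g, "REN")]
        if s_ff.n_used < min_n or s_ren.n_used < min_n:
            excluded.append(g)
            logger.warning("excluding %s: fewer than %d usable readouts", g, min_n)
            continue
        ff_fold = s_ff.mean / wt_ff.mean
        ren_fold = s_ren.mean / wt_ren.mean
        rows[g] = {
            "ff_fold": ff_fold,
            "ren_fold": ren_fold,
            "distance": math.hypot(ff_fold - 1.0, ren_fold - 1.0),
            "p_ff": _strain_vs_wt_p(s_ff, wt_ff, sd_ff, df_ff),
            "p_ren": _strain_vs_wt_p(s_ren, wt_ren, sd_ren, df_ren),
        }

    points = pd.DataFrame.from_dict(rows, orient="index")
    if len(points):
        points = points.loc[:, ["ff_fold", "ren_fold", "distance", "p_ff", "p_ren"]]
        points["q_ff"] = multipletests(points["p_ff"].to_numpy(), method="fdr_bh")[1]
        points["q_ren"] = multipletests(points["p_ren"].to_numpy(), method="fdr_bh")[1]
    else:
        points = pd.DataFrame(columns=POINT_COLUMNS)
    points.index.name = "strain_id"
    return points, excluded


def pearson_across_strains(points: pd.DataFrame) -> float:
    """Pearson product-moment correlation between FF and REN folds across
    strains (wild type excluded).  NaN (with a warning) if either
    coordinate is degenerate."""
    if len(points) < 3:
        raise ValueError("need at least 3 strains for a correlation")
    x = points["ff_fold"].to_numpy()
    y = points["ren_fold"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("correlation undefined: zero variance in folds")
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def inert_radius(wt_normalized_ff: np.ndarray | list[float]) -> float:
    """Twice the sample SD of individual wild-type FF readouts, each divided
    by their mean — the radius of the inert circle in fold space."""
    arr = np.asarray(wt_normalized_ff, dtype=float)
    if len(arr) < 3:
        raise ValueError("need at least 3 wild-type measurements for a radius")
    mean = arr.mean()
    if not mean > 0:
        raise ValueError("degenerate wild-type measurements (non-positive mean)")
    return float(2.0 * (arr / mean).std(ddof=1))


def classify_strains(
    points: pd.DataFrame,
    radius: float,
    wt_ren_band: float,
    alpha: float = 0.05,
) -> pd.Series:
    """Assign each strain exactly one class.

    Inside the inert circle -> ``inert``.  Outside, a strain is a
    ``selective_hit`` when its FF fold exceeds the circle on the FF axis
    alone (ff_fold - 1 > radius) with an FDR-significant FF shift, while
    REN stays inside the wild-type band (|ren_fold - 1| <= wt_ren_band)
    and is not significantly shifted.  Every other outside strain falls in
    a quadrant by the signs of (ff_fold - 1, ren_fold - 1).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    labels = {}
    for strain, row in points.iterrows():
        d_ff = row["ff_fold"] - 1.0
        d_ren = row["ren_fold"] - 1.0
        if row["distance"] <= radius:
            labels[strain] = "inert"
        elif (
            d_ff > radius
            and row["q_ff"] <= alpha
            and abs(d_ren) <= wt_ren_band
            and row["q_ren"] > alpha
        ):
            labels[strain] = "selective_hit"
        elif d_ff > 0 and d_ren > 0:
            labels[strain] = "q2_both_up"
        elif d_ff <= 0 and d_ren <= 0:
            labels[strain] = "q4_both_down"
        elif d_ren > 0:
            labels[strain] = "q1_ren_up"
        else:
            labels[strain] = "q3_ff_up"
    return pd.Series(labels, dtype=object, name="class").reindex(points.index)


def run_screen(
    table: ReadoutTable,
    manifest: StrainManifest,
    config: ScreenConfig = ScreenConfig(),
) -> ScreenResult:
    """Full screen pipeline: viability filter -> outlier QC -> wild-type
    normalization -> concordance -> inert radius -> classification."""
    usable = filter_viable(manifest, table)
    summaries = summarize_groups(usable, config.qc)
    wt = manifest.wildtype_id

    points, excluded = summarize_and_normalize(
        usable, wt, qc=config.qc, min_n=config.min_n, summaries=summaries
    )

    wt_ff = summaries[(wt, "FF")]
    wt_ren = summaries[(wt, "REN")]
    radius = config.radius_override
    ren_band = config.ren_band_override
    if config.radius_source == "pooled":
        cv_ff, dff = _pooled_cv(summaries, "FF")
        cv_ren, dfr = _pooled_cv(summaries, "REN")
        if radius is None:
            radius = 2.0 * cv_ff if dff >= 3 and cv_ff > 0 else config.radius_fallback
        if ren_band is None:
            ren_band = 2.0 * cv_ren if dfr >= 3 and cv_ren > 0 else radius
    else:
        if radius is None:
            if wt_ff.n_used >= 3 and wt_ff.sd > 0:
                radius = inert_radius(wt_ff.values)
            else:
                radius = config.radius_fallback
                logger.warning("wild-type FF data insufficient; radius fallback %.2f", radius)
        if ren_band is None:
            if wt_ren.n_used >= 3 and wt_ren.sd > 0:
                ren_band = inert_radius(wt_ren.values)  # same 2xSD construction
            else:
                ren_band = radius

    rho = pearson_across_strains(points) if len(points) >= 3 else float("nan")
    classes = classify_strains(points, radius, ren_band, alpha=config.alpha)
    hit_mask = classes == "selective_hit"
    hits = (
        points.loc[hit_mask.index[hit_mask], "ff_fold"]
        .sort_values(ascending=False)
        .index.tolist()
    )
    return ScreenResult(
        points=points,
        rho=rho,
        radius=radius,
        ren_band=ren_band,
        classes=classes,
        hits=hits,
        wildtype_id=wt,
        excluded=excluded,
    )
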