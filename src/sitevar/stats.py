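"""Profile comparison statistics.

Pipeline convention: every profile is smoothed with a centered sliding
window of size three (truncated at the termini) and sign-oriented so that
buried / tightly packed / conserved sites score low, before any correlation
is computed. Two predictors are compared over a dataset of proteins with a
three-test battery (paired t, binomial on the win proportion, Wilcoxon
signed rank), all one-sided in the direction "predictor 1 is better"; the
comparison is called significant only when the *worst* of the three P values
is below alpha (0.01 by default). Explained variance of a reference profile
y under a bivariate fit y ~ x1 + x2 is partitioned into a common term plus
the two squared semipartial correlations (unique contributions):

    R² = rho²(y, x1 or x2) + rho²(y, x1 | x2) + rho²(y, x2 | x1)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .io import MEASURES, SiteProfile

logger = logging.getLogger(__name__)


def smooth_profile(profile: SiteProfile, window: int = 3) -> SiteProfile:
    """Sliding-window mean with the window truncated at the termini.

    Missing (NaN) values are excluded from each local mean; a window of 1 is
    the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    import pandas as pd

    smoothed = (
        pd.Series(profile.values)
        .rolling(window=window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    out = SiteProfile(
        smoothed, profile.measure, oriented=profile.oriented, smoothed=True,
        meta=dict(profile.meta),
    )
    return out


def orient_profile(profile: SiteProfile) -> SiteProfile:
    """Apply the sign convention: conservation-like measures are negated.

    KBSP, VTSP (higher = more conserved) and WCN, CN (higher = more packed,
    hence more conserved) flip sign; variability and accessibility measures
    pass through. Orienting twice is an error.
    """
    if profile.oriented:
        raise ValueError(f"{profile.measure} profile is already oriented")
    flip = MEASURES[profile.measure] == "conservation"
    values = -profile.values if flip else profile.values.copy()
    return SiteProfile(
        values, profile.measure, oriented=True, smoothed=profile.smoothed,
        meta=dict(profile.meta),
    )


def prepare_profile(profile: SiteProfile, window: int = 3) -> SiteProfile:
    """Smooth then orient, skipping steps already applied."""
    p = profile if profile.smoothed else smooth_profile(profile, window)
    return p if p.oriented else orient_profile(p)


def correlate(
    a: SiteProfile | np.ndarray,
    b: SiteProfile | np.ndarray,
    method: str = "pearson",
) -> float:
    """Pearson or Spearman correlation, dropping sites missing in either."""
    x = np.asarray(a.values if isinstance(a, SiteProfile) else a, float)
    y = np.asarray(b.values if isinstance(b, SiteProfile) else b, float)
    if len(x) != len(y):
        raise ValueError("profiles have different lengths")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 shared sites")
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("zero-variance profile; correlation undefined")
        return np.nan
    if method == "pearson":
        return float(sps.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(sps.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


@dataclass
class ComparisonResult:
    """Outcome of the three-test battery 'is x1 a better predictor than x2'."""

    reference: str
    predictor1: str
    predictor2: str
    rho1: np.ndarray
    rho2: np.ndarray
    mean1: float
    mean2: float
    delta: float
    proportion_x1_wins: float
    p_t: float
    p_binomial: float
    p_wilcoxon: float
    significant: bool

    @property
    def worst_p(self) -> float:
        return max(self.p_t, self.p_binomial, self.p_wilcoxon)


def compare_predictors(
    rho1,
    rho2,
    reference: str = "y",
    predictor1: str = "x1",
    predictor2: str = "x2",
    alpha: float = 0.01,
) -> ComparisonResult:
    """Compare per-protein correlations of two predictors with one reference.

    One-sided tests of the directional hypothesis rho(y, x1) > rho(y, x2):
    paired t on the differences, binomial on the number of proteins where x1
    wins (ties dropped), and Wilcoxon signed rank. Significance requires the
    worst of the three P values to fall below ``alpha``.
    """
    r1 = np.asarray(rho1, float)
    r2 = np.asarray(rho2, float)
    if len(r1) != len(r2) or len(r1) < 2:
        raise ValueError("need matched correlation arrays of length >= 2")
    diffs = r1 - r2
    wins = int((diffs > 0).sum())
    non_ties = int((diffs != 0).sum())
    proportion = wins / non_ties if non_ties else 0.0
    if non_ties == 0:
        p_t = p_b = p_w = np.nan
        significant = False
    else:
        p_t = float(sps.ttest_rel(r1, r2, alternative="greater").pvalue)
        p_b = float(
            sps.binomtest(wins, non_ties, 0.5, alternative="greater").pvalue
        )
        p_w = float(
            sps.wilcoxon(
                diffs, alternative="greater", zero_method="wilcox"
            ).pvalue
        )
        significant = max(p_t, p_b, p_w) < alpha
    return ComparisonResult(
        reference=reference,
        predictor1=predictor1,
        predictor2=predictor2,
        rho1=r1,
        rho2=r2,
        mean1=float(r1.mean()),
        mean2=float(r2.mean()),
        delta=float(r1.mean() - r2.mean()),
        proportion_x1_wins=proportion,
        p_t=p_t,
        p_binomial=p_b,
        p_wilcoxon=p_w,
        significant=significant,
    )


@dataclass
class VariancePartition:
    """R² of y ~ x1 + x2 split into common and unique contributions."""

    total_r2: float
    common: float
    unique_x1: float
    unique_x2: float
    names: tuple[str, str, str] = ("y", "x1", "x2")

    @property
    def percentages(self) -> dict[str, float]:
        t = self.total_r2
        return {
            "total": 100.0,
            "common": 100.0 * self.common / t,
            "unique_x1": 100.0 * self.unique_x1 / t,
            "unique_x2": 100.0 * self.unique_x2 / t,
        }


def variance_partition(
    y,
    x1,
    x2,
    names: tuple[str, str, str] = ("y", "x1", "x2"),
) -> VariancePartition:
    """Partition the bivariate R² into common and unique (semipartial) parts.

    unique_x1 is the increase in R² from adding x1 to the fit y ~ x2 (the
    squared semipartial correlation of y with x1 controlling x2), likewise
    unique_x2; the common term is the remainder. The three parts sum to the
    total by construction. Negative unique parts (suppressor configurations)
    are reported as computed, with a warning.
    """
    yv = np.asarray(y.values if isinstance(y, SiteProfile) else y, float)
    x1v = np.asarray(x1.values if isinstance(x1, SiteProfile) else x1, float)
    x2v = np.asarray(x2.values if isinstance(x2, SiteProfile) else x2, float)
    ok = ~(np.isnan(yv) | np.isnan(x1v) | np.isnan(x2v))
    yv, x1v, x2v = yv[ok], x1v[ok], x2v[ok]
    if len(yv) < 4:
        raise ValueError("need at least 4 shared sites")
    r_y1 = float(np.corrcoef(yv, x1v)[0, 1])
    r_y2 = float(np.corrcoef(yv, x2v)[0, 1])
    r_12 = float(np.corrcoef(x1v, x2v)[0, 1])
    if abs(r_12) >= 1.0 - 1e-12:
        raise ValueError("x1 and x2 are collinear; partition undefined")
    total = (r_y1**2 + r_y2**2 - 2.0 * r_y1 * r_y2 * r_12) / (1.0 - r_12**2)
    unique_x1 = total - r_y2**2
    unique_x2 = total - r_y1**2
    common = total - unique_x1 - unique_x2
    if unique_x1 < 0 or unique_x2 < 0:
        logger.warning(
            "negative unique contribution (suppressor configuration): "
            "unique_%s=%.4f unique_%s=%.4f", names[1], unique_x1,
            names[2], unique_x2,
        )
    return VariancePartition(
        total_r2=total,
        common=common,
        unique_x1=unique_x1,
        unique_x2=unique_x2,
        names=names,
    )


@dataclass
class PartitionSummary:
    """Dataset means of per-protein variance partitions, Table-style."""

    names: tuple[str, str, str]
    n: int
    mean: dict[str, float]
    sd: dict[str, float]
    sem: dict[str, float]
    mean_pct: dict[str, float]
    sd_pct: dict[str, float]
    rows: list[dict] = field(default_factory=list)


def summarize_partitions(parts: list[VariancePartition]) -> PartitionSummary:
    """Average per-protein partitions; percentages are averaged per protein."""
    if not parts:
        raise ValueError("no partitions to summarize")
    names = parts[0].names
    keys = ["total", "common", "unique_x1", "unique_x2"]
    vals = {
        "total": np.array([p.total_r2 for p in parts]),
        "common": np.array([p.common for p in parts]),
        "unique_x1": np.array([p.unique_x1 for p in parts]),
        "unique_x2": np.array([p.unique_x2 for p in parts]),
    }
    pcts = {k: np.array([p.percentages[k] for p in parts]) for k in keys}
    n = len(parts)
    return PartitionSummary(
        names=names,
        n=n,
        mean={k: float(v.mean()) for k, v in vals.items()},
        sd={k: float(v.std(ddof=1)) if n > 1 else 0.0 for k, v in vals.items()},
        sem={
            k: float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            for k, v in vals.items()
        },
        mean_pct={k: float(v.mean()) for k, v in pcts.items()},
        sd_pct={k: float(v.std(ddof=1)) if n > 1 else 0.0 for k, v in pcts.items()},
    )
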