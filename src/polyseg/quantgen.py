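"""Variance-based quantitative genetics for segregating crosses.

An F2 population that carries heritable variation shows inflated phenotypic
variance relative to its (genetically uniform) F1; this module provides the
standard tests and summaries of that logic:

* two-sample variance-ratio (F) test and Levene / Brown-Forsythe tests of
  variance homogeneity,
* coefficient of variation with a small-sample correction and a
  normal-approximation confidence interval,
* broad-sense heritability H² = (Var(F2) − V_E)/Var(F2) with V_E built from
  parental and F1 variances,
* two-level nested random-effects variance components (family, maternal line
  within family, residual) by expected-mean-squares method of moments, with
  negative estimates reported rather than truncated, and percent-of-total
  shares.

The nested analysis follows the model/results convention:
``NestedVarianceModel.from_dataframe(df, trait).fit()`` returns a
:class:`NestedVarianceResults` with components, standard errors, F-tests and
a ``summary()`` table.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VarianceTestResult",
    "CVResult",
    "HeritabilityEstimate",
    "VEMethod",
    "variance_ratio_test",
    "levene_test",
    "cv_with_ci",
    "broad_sense_heritability",
    "NestedVarianceModel",
    "NestedVarianceResults",
]


class VEMethod(enum.Enum):
    """How the environmental variance is built from non-segregating classes."""

    WEIGHTED = "weighted"  # (V_P1 + V_P2 + 2 V_F1) / 4
    MEAN3 = "mean3"  # (V_P1 + V_P2 + V_F1) / 3


@dataclass(frozen=True)
class VarianceTestResult:
    statistic: float
    df: tuple
    p_value: float
    method: str


@dataclass(frozen=True)
class CVResult:
    cv: float
    cv_corrected: float
    ci: tuple[float, float]
    n: int
    conf: float


@dataclass(frozen=True)
class HeritabilityEstimate:
    var_f2: float
    var_e: float
    var_g: float
    h2_broad: float
    ve_method: VEMethod


def variance_ratio_test(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> VarianceTestResult:
    """Two-sample F-test of equal variances, F = s_b²/s_a² (F2 over F1).

    Two-sided p-value as 2·min(upper tail, lower tail).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 values")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0:
        raise ValueError("zero variance in denominator sample")
    F = vb / va
    dfn, dfd = b.size - 1, a.size - 1
    tail = stats.f.sf(F, dfn, dfd)
    p = min(2.0 * min(tail, 1.0 - tail), 1.0)
    return VarianceTestResult(statistic=float(F), df=(dfn, dfd), p_value=float(p), method="F_RATIO")


def levene_test(
    groups: Sequence[Sequence[float]], center: str = "median"
) -> VarianceTestResult:
    """Levene's test of variance homogeneity (Brown-Forsythe, median-centered,
    by default; ``center='mean'`` for the classical form)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if center not in ("median", "mean"):
        raise ValueError("center must be 'median' or 'mean'")
    stat, p = stats.levene(*arrays, center=center)
    k = len(arrays)
    n = sum(a.size for a in arrays)
    method = "LEVENE_MEDIAN" if center == "median" else "LEVENE_MEAN"
    return VarianceTestResult(
        statistic=float(stat), df=(k - 1, n - k), p_value=float(p), method=method
    )


def cv_with_ci(sample: Sequence[float], conf: float = 0.95) -> CVResult:
    """Coefficient of variation (%) with small-sample correction and CI.

    CV = 100·s/x̄; the corrected CV* = (1 + 1/(4n))·CV; the interval is
    CV* ± z·CV*·sqrt(1/(2(n−1))) (normal approximation).
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 values")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    n = x.size
    cv = 100.0 * x.std(ddof=1) / mean
    cv_star = (1.0 + 1.0 / (4.0 * n)) * cv
    z = stats.norm.ppf(0.5 + conf / 2.0)
    half = z * cv_star * math.sqrt(1.0 / (2.0 * (n - 1)))
    return CVResult(
        cv=float(cv),
        cv_corrected=float(cv_star),
        ci=(float(cv_star - half), float(cv_star + half)),
        n=n,
        conf=conf,
    )


def broad_sense_heritability(
    var_f2: float,
    var_f1: float,
    var_p1: float,
    var_p2: float,
    ve_method: VEMethod = VEMethod.WEIGHTED,
) -> HeritabilityEstimate:
    """Broad-sense heritability H² = (Var(F2) − V_E)/Var(F2).

    V_E pools the phenotypic variance of the genetically uniform classes:
    WEIGHTED uses (V_P1 + V_P2 + 2·V_F1)/4, MEAN3 the unweighted mean of the
    three.  Negative H² is returned unmodified — it indicates the absence of
    detectable segregational variance, not an error.
    """
    if var_f2 <= 0:
        raise ValueError("var_f2 must be positive")
    if ve_method is VEMethod.WEIGHTED:
        var_e = (var_p1 + var_p2 + 2.0 * var_f1) / 4.0
    else:
        var_e = (var_p1 + var_p2 + var_f1) / 3.0
    var_g = var_f2 - var_e
    return HeritabilityEstimate(
        var_f2=float(var_f2),
        var_e=float(var_e),
        var_g=float(var_g),
        h2_broad=float(var_g / var_f2),
        ve_method=ve_method,
    )


# ---------------------------------------------------------------------------
# nested variance components


class NestedVarianceModel:
    """Two-level nested random-effects model for one trait.

    y_ijk = mu + family_i + maternal_j(i) + e_ijk with independent
    zero-mean random effects.  Estimation is by expected mean squares
    (method of moments) with Searle's coefficients for unbalanced data, so
    estimates can be negative; truncation is left to the reader of the
    percent-of-total column, where negative components count as zero.
    """

    def __init__(
        self,
        values: Sequence[float],
        family: Sequence,
        maternal: Sequence,
        trait_name: str = "trait",
    ) -> None:
        self.data = pd.DataFrame(
            {
                "value": np.asarray(values, dtype=float),
                "family": np.asarray(family).astype(str),
                "maternal": np.asarray(maternal).astype(str),
            }
        )
        self.trait_name = trait_name
        fams = self.data["family"].unique()
        if len(fams) < 2:
            raise ValueError("need >= 2 families")
        cell_sizes = self.data.groupby(["family", "maternal"], sort=False).size()
        if (cell_sizes < 1).any() or cell_sizes.empty:
            raise ValueError("empty family/maternal cells")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        trait: str,
        family: str = "family",
        maternal: str = "maternal_line",
    ) -> "NestedVarianceModel":
        sub = df[[trait, family, maternal]].dropna()
        return cls(sub[trait], sub[family], sub[maternal], trait_name=trait)

    def fit(self) -> "NestedVarianceResults":
        d = self.data
        N = len(d)
        grand = d["value"].mean()
        fam_stats = d.groupby("family", sort=False)["value"].agg(["mean", "count"])
        cell = d.groupby(["family", "maternal"], sort=False)["value"].agg(["mean", "count"])
        a = len(fam_stats)
        B = len(cell)  # total subgroups

        # sums of squares
        ss_family = float((fam_stats["count"] * (fam_stats["mean"] - grand) ** 2).sum())
        fam_mean_of = fam_stats["mean"].reindex(cell.index.get_level_values(0)).to_numpy()
        ss_maternal = float((cell["count"].to_numpy() * (cell["mean"].to_numpy() - fam_mean_of) ** 2).sum())
        cell_mean_of = cell["mean"].reindex(
            pd.MultiIndex.from_frame(d[["family", "maternal"]])
        ).to_numpy()
        ss_within = float(((d["value"].to_numpy() - cell_mean_of) ** 2).sum())

        df_family = a - 1
        df_maternal = B - a
        df_within = N - B
        if df_maternal < 1 or df_within < 1:
            raise ValueError("design too small: need >1 maternal line/family and replication")
        ms_family = ss_family / df_family
        ms_maternal = ss_maternal / df_maternal
        ms_within = ss_within / df_within

        # Searle EMS coefficients for the unbalanced two-level nested model
        n_ij = cell["count"].to_numpy(dtype=float)
        n_i = fam_stats["count"].to_numpy(dtype=float)
        nij2_by_family = (cell["count"] ** 2).groupby(level=0, sort=False).sum()
        sum_nij2_over_ni = float((nij2_by_family / fam_stats["count"]).sum())
        k1 = (N - sum_nij2_over_ni) / df_maternal  # E[MS_mat] = sigma2 + k1 sigma2_B
        k2 = (sum_nij2_over_ni - float((n_ij**2).sum()) / N) / df_family
        k3 = (N - float((n_i**2).sum()) / N) / df_family
        # E[MS_fam] = sigma2 + k2 sigma2_B + k3 sigma2_A

        var_res = ms_within
        var_mat = (ms_maternal - ms_within) / k1
        var_fam = (ms_family - ms_within - k2 * var_mat) / k3

        # large-sample SEs from Var(MS) ~ 2 MS^2 / df
        v_ms = {
            "family": 2.0 * ms_family**2 / df_family,
            "maternal": 2.0 * ms_maternal**2 / df_maternal,
            "within": 2.0 * ms_within**2 / df_within,
        }
        se_res = math.sqrt(v_ms["within"])
        se_mat = math.sqrt((v_ms["maternal"] + v_ms["within"]) / k1**2)
        se_fam = math.sqrt(
            (
                v_ms["family"]
                + (k2 / k1) ** 2 * v_ms["maternal"]
                + (1.0 - k2 / k1) ** 2 * v_ms["within"]
            )
            / k3**2
        )

        # F-tests against the next stratum down
        f_fam = ms_family / ms_maternal
        p_fam = float(stats.f.sf(f_fam, df_family, df_maternal))
        f_mat = ms_maternal / ms_within
        p_mat = float(stats.f.sf(f_mat, df_maternal, df_within))

        return NestedVarianceResults(
            model=self,
            var_family=float(var_fam),
            var_maternal=float(var_mat),
            var_residual=float(var_res),
            se_family=float(se_fam),
            se_maternal=float(se_mat),
            se_residual=float(se_res),
            ms=(ms_family, ms_maternal, ms_within),
            df=(df_family, df_maternal, df_within),
            f_tests={
                "family": (float(f_fam), p_fam),
                "maternal": (float(f_mat), p_mat),
            },
        )


def percent_of_total(components: Sequence[float]) -> list[float]:
    """Percent of total variance per component, flooring negative components
    at zero; shares sum to 100 by construction."""
    floored = [max(c, 0.0) for c in components]
    total = sum(floored)
    if total <= 0:
        raise ValueError("total variance is not positive")
    return [100.0 * c / total for c in floored]


@dataclass
class NestedVarianceResults:
    """EMS variance-component estimates with SEs, F-tests and shares."""

    model: NestedVarianceModel
    var_family: float
    var_maternal: float
    var_residual: float
    se_family: float
    se_maternal: float
    se_residual: float
    ms: tuple[float, float, float]
    df: tuple[int, int, int]
    f_tests: dict

    @property
    def components(self) -> tuple[float, float, float]:
        return (self.var_family, self.var_maternal, self.var_residual)

    @property
    def total(self) -> float:
        """Total variance as the sum of components, negatives floored at zero."""
        return sum(max(c, 0.0) for c in self.components)

    @property
    def pct_total(self) -> tuple[float, float, float]:
        return tuple(percent_of_total(self.components))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": ["family", "maternal(family)", "residual"],
                "variance": self.components,
                "se": (self.se_family, self.se_maternal, self.se_residual),
                "pct_total": self.pct_total,
            }
        )

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            f"Nested variance components — trait: {self.model.trait_name}",
            df.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
            f"total (floored): {self.total:.4f}",
            "F-tests: family F = {:.3f} (p = {:.4g}); maternal F = {:.3f} (p = {:.4g})".format(
                *self.f_tests["family"], *self.f_tests["maternal"]
            ),
        ]
        return "\n".join(lines)
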