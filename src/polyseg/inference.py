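"""Marker-panel inference for segregation in a synthetic allotetraploid.

The observable per marker is a dichotomy over backcross (or selfed) progeny:
heterozygous (a band from each parental subgenome) versus allele loss
(quadruple homozygote for the recurrent/tester subgenome).  From per-marker
counts this module computes

* detection power — the probability of failing to observe any quadruple
  homozygote under a given pairing model,
* apparent heterozygosity with an exact (Clopper–Pearson) binomial CI,
* a Williams-corrected G goodness-of-fit test of the panel against a pairing
  model, plus a heterogeneity G-test across markers,
* a direct estimate of the preferential pairing factor p from the inferred
  gamete counts of the heterozygous F1 parent, with a likelihood-ratio
  comparison against a fixed null.

The panel-level entry point is :class:`MarkerPanelModel`, whose ``fit``
returns a :class:`MarkerPanelResults` carrying the per-marker table and the
pooled statistics, in the spirit of statsmodels model/results pairs.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .pairing import (
    P_MAX,
    PairingModel,
    ProgenyDesign,
    quadruple_homozygote_frequency,
    wu_gn_frequency,
)

__all__ = [
    "MarkerObservation",
    "PairingAssumption",
    "BinomialCI",
    "GTestResult",
    "PreferentialPairingEstimate",
    "MarkerPanelModel",
    "MarkerPanelResults",
    "apparent_heterozygosity",
    "prob_fail_to_detect",
    "clopper_pearson_ci",
    "gtest_goodness_of_fit",
    "heterogeneity_gtest",
    "estimate_preferential_pairing",
    "lrt_preferential_pairing",
    "load_panel",
]


@dataclass(frozen=True)
class MarkerObservation:
    """Counts for one marker: scored individuals, heterozygotes, allele losses.

    ``n_loss_excl`` optionally carries the loss count after excluding a
    designated outlier individual (None if no alternative count applies).
    """

    marker_id: str
    n_scored: int
    n_het: int
    n_loss: int
    arm_label: str = ""
    progeny_class: str = ""
    n_loss_excl: int | None = None

    def __post_init__(self) -> None:
        if min(self.n_scored, self.n_het, self.n_loss) < 0:
            raise ValueError(f"{self.marker_id}: counts must be nonnegative")
        if self.n_het + self.n_loss > self.n_scored:
            raise ValueError(
                f"{self.marker_id}: n_het + n_loss exceeds n_scored "
                f"({self.n_het}+{self.n_loss} > {self.n_scored})"
            )
        if self.n_loss_excl is not None and not 0 <= self.n_loss_excl <= self.n_loss:
            raise ValueError(f"{self.marker_id}: n_loss_excl outside [0, n_loss]")


class PairingAssumption(enum.Enum):
    """How GG/NN gametes arise: homeologous bivalents only, or quadrivalents
    with double reduction contributing 3/8 of the off-class gametes."""

    BIVALENT_ONLY = "bivalent"
    QUADRIVALENT_DR = "quadrivalent"


class LRTStatus(enum.Enum):
    OK = "ok"
    DEGENERATE = "degenerate"  # null assigns probability 0 to the data


@dataclass(frozen=True)
class BinomialCI:
    k: int
    n: int
    conf: float
    lower: float
    upper: float


@dataclass(frozen=True)
class GTestResult:
    G: float
    q_williams: float
    G_adj: float
    df: int
    p_value: float
    degenerate: bool = False


@dataclass(frozen=True)
class PreferentialPairingEstimate:
    p_hat: float
    assumption: PairingAssumption
    f_gn_obs: float
    n_gn: int
    n_gg: int
    n_nn: int
    in_range: bool = True
    lrt_stat: float | None = None
    lrt_p: float | None = None
    lrt_status: LRTStatus | None = None


# ---------------------------------------------------------------------------
# elementary operations


def _pool(observations: Iterable[MarkerObservation], exclude_outlier: bool = False):
    obs = list(observations)
    n = sum(o.n_scored for o in obs)
    if exclude_outlier:
        # recovered losses (outlier individual's calls) become heterozygous calls
        per_loss = [
            o.n_loss_excl if o.n_loss_excl is not None else o.n_loss for o in obs
        ]
        loss = sum(per_loss)
        het = sum(o.n_het for o in obs) + sum(
            o.n_loss - l for o, l in zip(obs, per_loss)
        )
    else:
        loss = sum(o.n_loss for o in obs)
        het = sum(o.n_het for o in obs)
    return n, het, loss


def apparent_heterozygosity(
    obs: "MarkerObservation | Iterable[MarkerObservation]",
    exclude_outlier: bool = False,
) -> float:
    """Observed proportion of individuals carrying a band from each parent.

    Accepts a single marker or a panel (counts are pooled across markers).
    With ``exclude_outlier`` the per-marker ``n_loss_excl`` counts replace
    ``n_loss`` and the recovered individuals count as heterozygous.
    """
    if isinstance(obs, MarkerObservation):
        obs = [obs]
    n, het, _ = _pool(obs, exclude_outlier)
    if n == 0:
        raise ValueError("no scored individuals")
    return het / n


def prob_fail_to_detect(
    model: "PairingModel | str",
    design: ProgenyDesign,
    n_obs: int,
) -> float:
    """Probability of observing no quadruple homozygote in ``n_obs`` progeny.

    ``(1 − q)**n_obs`` where q is the detectable quadruple-homozygote
    frequency of the model/design progeny distribution (selfing of a duplex
    under random chromosome assortment: q = 2/36; backcross: q = 1/6).
    """
    if n_obs < 0:
        raise ValueError("n_obs must be >= 0")
    q = float(quadruple_homozygote_frequency(model, design))
    return (1.0 - q) ** n_obs


def clopper_pearson_ci(k: int, n: int, conf: float = 0.95) -> BinomialCI:
    """Exact binomial (Clopper–Pearson) confidence interval for k/n."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    if not 0.0 < conf < 1.0:
        raise ValueError("conf must be in (0, 1)")
    lower, upper = proportion_confint(k, n, alpha=1.0 - conf, method="beta")
    return BinomialCI(k=k, n=n, conf=conf, lower=float(lower), upper=float(upper))


def gtest_goodness_of_fit(
    observed: Sequence[float],
    expected_probs: Sequence[float],
    williams: bool = True,
) -> GTestResult:
    """Log-likelihood-ratio (G) goodness-of-fit test.

    G = 2·Σ o·ln(o/e); with the Williams correction the statistic is divided
    by q = 1 + (a² − 1)/(6·n·(a − 1)) for a classes and n observations before
    the chi-square tail (df = a − 1) is taken.  An expected probability of 0
    facing a nonzero observed count is degenerate and flagged rather than
    given a finite statistic.
    """
    o = np.asarray(observed, dtype=float)
    e_probs = np.asarray(expected_probs, dtype=float)
    if o.size < 2 or o.size != e_probs.size:
        raise ValueError("need >= 2 classes and matching expected probabilities")
    if abs(e_probs.sum() - 1.0) > 1e-9:
        raise ValueError("expected probabilities must sum to 1")
    n = o.sum()
    if n <= 0:
        raise ValueError("total observed count must be positive")
    a = o.size
    df = a - 1
    if np.any((e_probs == 0) & (o > 0)):
        return GTestResult(
            G=math.inf, q_williams=1.0, G_adj=math.inf, df=df, p_value=0.0,
            degenerate=True,
        )
    e = e_probs * n
    G, _ = stats.power_divergence(o, e, lambda_="log-likelihood")
    G = float(G)
    q = 1.0 + (a * a - 1.0) / (6.0 * n * (a - 1.0)) if williams else 1.0
    G_adj = G / q
    p = float(stats.chi2.sf(G_adj, df))
    return GTestResult(G=G, q_williams=q, G_adj=G_adj, df=df, p_value=p)


def heterogeneity_gtest(panel: Sequence[MarkerObservation]) -> GTestResult:
    """Heterogeneity G-test across markers of a replicated goodness-of-fit design.

    Each marker contributes (het, non-het) counts; expected counts per marker
    come from the pooled heterozygosity proportion.  Equivalently
    G_H = Σ G_marker − G_pooled for any common expected ratio.  df =
    (markers − 1)·(classes − 1); no Williams correction is applied.
    """
    obs = list(panel)
    if len(obs) < 2:
        raise ValueError("heterogeneity test needs >= 2 markers")
    if any(o.n_scored == 0 for o in obs):
        raise ValueError("marker with zero scored individuals")
    table = np.array([[o.n_het, o.n_scored - o.n_het] for o in obs], dtype=float)
    pooled = table.sum(axis=0)
    p_pool = pooled / pooled.sum()
    expected = table.sum(axis=1, keepdims=True) * p_pool
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / expected), 0.0)
    G = 2.0 * float(terms.sum())
    df = (len(obs) - 1) * (table.shape[1] - 1)
    p = float(stats.chi2.sf(G, df))
    return GTestResult(G=G, q_williams=1.0, G_adj=G, df=df, p_value=p)


# ---------------------------------------------------------------------------
# preferential pairing factor


def _solve_p(f_gn: float) -> tuple[float, bool]:
    """Positive root of 2/3 + p/3 + p²/4 = f_gn, clamped to [0, 2/3].

    Returns (p, in_range); in_range is False when f_gn lies outside the
    attainable band [2/3, 1] and the root was clamped.
    """
    c = f_gn - 2.0 / 3.0
    disc = 1.0 / 9.0 + c
    if disc < 0:
        return 0.0, False
    root = 2.0 * (math.sqrt(disc) - 1.0 / 3.0)
    clamped = min(max(root, 0.0), float(P_MAX))
    return clamped, abs(clamped - root) < 1e-12


def estimate_preferential_pairing(
    obs: MarkerObservation,
    assumption: PairingAssumption = PairingAssumption.BIVALENT_ONLY,
    exclude_outlier: bool = False,
) -> PreferentialPairingEstimate:
    """Direct estimate of the preferential pairing factor p from one marker.

    Gamete counts of the segregating F1 parent are inferred from the progeny
    dichotomy: every allele-loss individual received an NN gamete; by the
    symmetry of the duplex parent an equal number of GG gametes is assumed
    (undetectable in the backcross), leaving GN = n − 2·loss.

    Under BIVALENT_ONLY all off-class gametes come from homeologous
    bivalents (double-reduction term set to zero) and the quadratic
    2/3 + p/3 + p²/4 = f_GN is solved for its positive root.  Under
    QUADRIVALENT_DR three-eighths of the off-class gametes are attributed to
    double reduction first, which raises the effective GN frequency to
    1 − (3/4)·(GG+NN fraction) before the same quadratic is solved.
    """
    if obs.n_scored == 0:
        raise ValueError("n_scored must be positive")
    loss = (
        obs.n_loss_excl
        if exclude_outlier and obs.n_loss_excl is not None
        else obs.n_loss
    )
    if 2 * loss > obs.n_scored:
        raise ValueError(
            f"{obs.marker_id}: n_loss > n_scored/2 implies f_GN < 0 — no root in range"
        )
    n = obs.n_scored
    n_nn = loss
    n_gg = loss  # equal-gamete symmetry assumption
    n_gn = n - 2 * loss
    g_frac = 2.0 * loss / n  # inferred GG+NN gamete fraction
    if assumption is PairingAssumption.BIVALENT_ONLY:
        f_target = 1.0 - g_frac
    else:
        # 3/8 of off-class gametes assigned to double reduction; the remaining
        # homeolog-bivalent share enters the quadratic through the 2/3 factor
        f_target = 1.0 - 0.75 * g_frac
    p_hat, in_range = _solve_p(f_target)
    return PreferentialPairingEstimate(
        p_hat=p_hat,
        assumption=assumption,
        f_gn_obs=1.0 - g_frac,
        n_gn=n_gn,
        n_gg=n_gg,
        n_nn=n_nn,
        in_range=in_range,
    )


def _gamete_loglik(n_gn: int, n_gg: int, n_nn: int, p: float) -> float:
    """Multinomial log-likelihood of inferred gamete counts at pairing factor p
    (alpha = 0), up to the multinomial coefficient."""
    f = wu_gn_frequency(p, 0.0)
    off = (1.0 - f) / 2.0
    ll = 0.0
    for count, prob in ((n_gn, f), (n_gg, off), (n_nn, off)):
        if count > 0:
            # f(2/3) is exactly 1 analytically; guard the float round-off
            if prob <= 1e-12:
                return -math.inf
            ll += count * math.log(prob)
    return ll


def lrt_preferential_pairing(
    obs: MarkerObservation,
    est: PreferentialPairingEstimate,
    null_p: float = float(P_MAX),
) -> tuple[float | None, float | None, LRTStatus]:
    """Likelihood-ratio test of p = p_hat against a fixed null value.

    The statistic is 2·(ℓ(p̂) − ℓ(p₀)) on the inferred gamete counts with a
    chi-square(1) reference.  When the null is p = 2/3 and any loss was
    observed, the null likelihood is exactly zero (strict homologous pairing
    permits no GG/NN gametes): the test is DEGENERATE and no finite p-value
    is reported.
    """
    ll_hat = _gamete_loglik(est.n_gn, est.n_gg, est.n_nn, est.p_hat)
    ll_null = _gamete_loglik(est.n_gn, est.n_gg, est.n_nn, null_p)
    if math.isinf(ll_null):
        return None, None, LRTStatus.DEGENERATE
    stat = max(2.0 * (ll_hat - ll_null), 0.0)
    p = float(stats.chi2.sf(stat, 1))
    return stat, p, LRTStatus.OK


# ---------------------------------------------------------------------------
# panel I/O

_PANEL_COLUMNS = ["marker_id", "arm_label", "class", "n_scored", "n_het", "n_loss"]


def load_panel(path: "str | Path") -> list[MarkerObservation]:
    """Read a marker panel TSV (columns marker_id, arm_label, class, n_scored,
    n_het, n_loss and optional n_loss_excl)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel file {path} missing columns: {missing}")
    out = []
    for i, row in df.iterrows():
        try:
            excl = row.get("n_loss_excl")
            out.append(
                MarkerObservation(
                    marker_id=str(row["marker_id"]),
                    arm_label=str(row["arm_label"]),
                    progeny_class=str(row["class"]),
                    n_scored=int(row["n_scored"]),
                    n_het=int(row["n_het"]),
                    n_loss=int(row["n_loss"]),
                    n_loss_excl=None if pd.isna(excl) else int(excl),
                )
            )
        except (ValueError, TypeError) as err:
            raise ValueError(f"panel file {path}, row {i + 2}: {err}") from err
    return out


def bundled_panel_path() -> Path:
    """Path of the marker panel shipped with the package (printed study counts)."""
    return Path(__file__).parent / "data" / "study_panel.tsv"


# ---------------------------------------------------------------------------
# panel model / results


class MarkerPanelModel:
    """Segregation inference over a marker panel.

    Parameters
    ----------
    panel : sequence of MarkerObservation or DataFrame
        Per-marker counts. A DataFrame must carry the panel TSV columns.
    design : ProgenyDesign
        Progeny design the counts come from (default backcross to the
        recessive tester, where allele loss is directly observable).
    null_model : PairingModel or str
        Pairing model providing the null expected class frequencies of the
        goodness-of-fit G-test and of the detection-power computation.
    conf : float
        Confidence level for the exact binomial intervals.
    """

    def __init__(
        self,
        panel: "Sequence[MarkerObservation] | pd.DataFrame",
        design: ProgenyDesign = ProgenyDesign.BACKCROSS_TO_RECESSIVE,
        null_model: "PairingModel | str" = PairingModel.RANDOM_CHROMOSOME,
        conf: float = 0.95,
    ) -> None:
        if isinstance(panel, pd.DataFrame):
            panel = [
                MarkerObservation(
                    marker_id=str(r["marker_id"]),
                    arm_label=str(r.get("arm_label", "")),
                    progeny_class=str(r.get("class", "")),
                    n_scored=int(r["n_scored"]),
                    n_het=int(r["n_het"]),
                    n_loss=int(r["n_loss"]),
                    n_loss_excl=(
                        None
                        if "n_loss_excl" not in r or pd.isna(r["n_loss_excl"])
                        else int(r["n_loss_excl"])
                    ),
                )
                for _, r in panel.iterrows()
            ]
        self.panel = list(panel)
        if not self.panel:
            raise ValueError("empty marker panel")
        self.design = design
        self.null_model = PairingModel.parse(null_model)
        self.conf = conf

    @classmethod
    def from_tsv(cls, path: "str | Path", **kwargs) -> "MarkerPanelModel":
        return cls(load_panel(path), **kwargs)

    @classmethod
    def bundled(cls, progeny_class: str = "BC1N", **kwargs) -> "MarkerPanelModel":
        """Model over the bundled study panel, restricted to one progeny class."""
        panel = [
            o for o in load_panel(bundled_panel_path()) if o.progeny_class == progeny_class
        ]
        return cls(panel, **kwargs)

    def fit(
        self,
        assumption: PairingAssumption = PairingAssumption.BIVALENT_ONLY,
        exclude_outlier: bool = False,
    ) -> "MarkerPanelResults":
        """Run the full per-marker and pooled inference."""
        q_loss = float(quadruple_homozygote_frequency(self.null_model, self.design))
        rows = []
        for obs in self.panel:
            loss = (
                obs.n_loss_excl
                if exclude_outlier and obs.n_loss_excl is not None
                else obs.n_loss
            )
            het = obs.n_het + (obs.n_loss - loss)
            ci = clopper_pearson_ci(het, obs.n_scored, self.conf)
            est = estimate_preferential_pairing(
                obs, assumption=assumption, exclude_outlier=exclude_outlier
            )
            lrt_stat, lrt_p, lrt_status = lrt_preferential_pairing(obs, est)
            rows.append(
                {
                    "marker_id": obs.marker_id,
                    "arm_label": obs.arm_label,
                    "n_scored": obs.n_scored,
                    "n_het": het,
                    "n_loss": loss,
                    "p_fail": prob_fail_to_detect(
                        self.null_model, self.design, obs.n_scored
                    ),
                    "apparent_het": het / obs.n_scored,
                    "ci_lower": ci.lower,
                    "ci_upper": ci.upper,
                    "p_hat": est.p_hat,
                    "lrt_status": lrt_status.value,
                }
            )
        per_marker = pd.DataFrame(rows)

        n, het, loss = _pool(self.panel, exclude_outlier)
        pooled_ci = clopper_pearson_ci(het, n, self.conf)
        pooled_g = gtest_goodness_of_fit(
            [het, n - het], [1.0 - q_loss, q_loss], williams=True
        )
        loss_markers = [o for o in self.panel if o.n_loss > 0]
        het_g = heterogeneity_gtest(loss_markers) if len(loss_markers) >= 2 else None
        return MarkerPanelResults(
            model=self,
            assumption=assumption,
            exclude_outlier=exclude_outlier,
            per_marker=per_marker,
            pooled_n=n,
            pooled_het=het,
            pooled_loss=loss,
            pooled_ci=pooled_ci,
            pooled_gtest=pooled_g,
            heterogeneity=het_g,
        )


@dataclass
class MarkerPanelResults:
    """Fitted panel inference: per-marker table plus pooled statistics."""

    model: MarkerPanelModel
    assumption: PairingAssumption
    exclude_outlier: bool
    per_marker: pd.DataFrame
    pooled_n: int
    pooled_het: int
    pooled_loss: int
    pooled_ci: BinomialCI
    pooled_gtest: GTestResult
    heterogeneity: GTestResult | None

    @property
    def pooled_apparent_het(self) -> float:
        return self.pooled_het / self.pooled_n

    @property
    def pooled_p_fail(self) -> float:
        return prob_fail_to_detect(
            self.model.null_model, self.model.design, self.pooled_n
        )

    def to_frame(self) -> pd.DataFrame:
        """Per-marker table with a pooled summary row appended."""
        pooled = {
            "marker_id": "pooled",
            "arm_label": "",
            "n_scored": self.pooled_n,
            "n_het": self.pooled_het,
            "n_loss": self.pooled_loss,
            "p_fail": self.pooled_p_fail,
            "apparent_het": self.pooled_apparent_het,
            "ci_lower": self.pooled_ci.lower,
            "ci_upper": self.pooled_ci.upper,
            "p_hat": np.nan,
            "lrt_status": "",
        }
        return pd.concat(
            [self.per_marker, pd.DataFrame([pooled])], ignore_index=True
        )

    def summary(self) -> str:
        def sig(x: float) -> str:
            return f"{x:.6g}" if x >= 1e-3 else f"{x:.2E}"

        lines = [
            "Marker panel segregation inference",
            f"  design: {self.model.design.value}   null model: {self.model.null_model.value}",
            f"  assumption: {self.assumption.value}   exclude outlier: {self.exclude_outlier}",
            "",
        ]
        df = self.to_frame().copy()
        for col in ("p_fail", "apparent_het", "ci_lower", "ci_upper", "p_hat"):
            df[col] = df[col].map(lambda v: "" if pd.isna(v) else sig(v))
        lines.append(df.to_string(index=False))
        lines.append("")
        g = self.pooled_gtest
        lines.append(
            f"Pooled G-test vs {self.model.null_model.value}: "
            f"G = {g.G:.4f}, Williams q = {g.q_williams:.6f}, "
            f"G_adj = {g.G_adj:.4f}, df = {g.df}, p = {sig(g.p_value)}"
        )
        if self.heterogeneity is not None:
            h = self.heterogeneity
            lines.append(
                f"Heterogeneity G (loss-bearing markers): G_H = {h.G:.4f}, "
                f"df = {h.df}, p = {sig(h.p_value)}"
            )
        lines.append(
            f"Pooled apparent heterozygosity: {self.pooled_het}/{self.pooled_n} = "
            f"{self.pooled_apparent_het:.4f}  "
            f"[{self.pooled_ci.lower:.3f}, {self.pooled_ci.upper:.3f}] "
            f"({int(self.pooled_ci.conf * 100)}% exact binomial)"
        )
        return "\n".join(lines)
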