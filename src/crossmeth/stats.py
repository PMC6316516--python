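"""Genotype calling, segregation and population statistics of the cross.

Covers the downstream analysis of the allele-resolved methylation
levels: genotype detection from allele read counts, the Mendelian
1:2:1 segregation chi-square for selfed F2 populations, the
distributional comparison between reciprocal crosses that licenses
merging them, per-population summaries (median / mean / s.d.), and
the trans-allelic Spearman correlation with an OLS regression in F2
heterozygotes.

Test choices: the reciprocal comparison uses a two-sided Mann-Whitney
rank-sum test with midranks for ties (a nonparametric comparison of
distributions); the segregation test is Pearson's chi-square without
continuity correction (three classes, df = 2); the allele correlation
is Spearman's rho, with an ordinary-least-squares line and pointwise
95% confidence bounds for display. No multiple-testing correction is
applied across motifs or alleles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .reference import COL, LER
from .reads import MappingSummary

logger = logging.getLogger(__name__)


class EmptyPopulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Genotype calling and segregation
# ---------------------------------------------------------------------------


def call_genotype(summary: MappingSummary, threshold: float = 0.05) -> str | None:
    """Genotype from allele read fractions after mapping-error filtering.

    Both alleles at or above ``threshold`` of mapped reads give CL;
    otherwise the individual is homozygous for the majority allele.
    Failed-QC individuals return None and are excluded downstream.
    """
    if summary.failed_qc or summary.total_mapped == 0:
        return None
    frac_col = summary.n_col / summary.total_mapped
    frac_ler = summary.n_ler / summary.total_mapped
    if frac_col >= threshold and frac_ler >= threshold:
        return "CL"
    return "CC" if frac_col > frac_ler else "LL"


def segregation_test(cc: int, cl: int, ll: int) -> tuple[float, float]:
    """Pearson chi-square of (CC, CL, LL) counts against 1:2:1.

    Returns the statistic and its upper-tail p-value on 2 degrees of
    freedom.
    """
    n = cc + cl + ll
    if n == 0:
        raise EmptyPopulationError("no genotyped individuals")
    expected = np.array([0.25, 0.5, 0.25]) * n
    stat, p = sps.chisquare([cc, cl, ll], f_exp=expected)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# Reciprocal-cross comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReciprocalTest:
    statistic: float
    p_value: float
    merged: bool  # True iff the two crosses may be pooled
    n_a: int
    n_b: int


def reciprocal_comparison(
    levels_a: Sequence[float],
    levels_b: Sequence[float],
    alpha: float = 0.001,
) -> ReciprocalTest:
    """Two-sided rank-sum comparison of two reciprocal-cross samples.

    The crosses are merged (pooled for downstream analysis) unless the
    distributions differ strongly (p < ``alpha``). Samples smaller
    than 2 on either side leave the test undefined and merge by
    default with a warning.
    """
    a = [x for x in levels_a if not np.isnan(x)]
    b = [x for x in levels_b if not np.isnan(x)]
    if len(a) < 2 or len(b) < 2:
        logger.warning(
            "reciprocal comparison undefined (n=%d, %d); merging by default",
            len(a),
            len(b),
        )
        return ReciprocalTest(float("nan"), float("nan"), True, len(a), len(b))
    stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    return ReciprocalTest(float(stat), float(p), bool(p >= alpha), len(a), len(b))


# ---------------------------------------------------------------------------
# Population summaries (median / mean / s.d. surface)
# ---------------------------------------------------------------------------


def summarize_population(levels: pd.DataFrame) -> pd.DataFrame:
    """Median, mean and sample s.d. per population x allele x motif.

    ``levels`` must carry columns population, allele, motif, level.
    NaN (undefined) levels are excluded before aggregation; groups with
    no defined level are omitted; the s.d. uses the n-1 denominator and
    is NaN for single observations (rendered "-" in reports). The
    result is invariant under permutation of individuals.
    """
    defined = levels.dropna(subset=["level"])
    rows = []
    for (pop, allele, motif), grp in defined.groupby(
        ["population", "allele", "motif"], sort=True
    ):
        x = grp["level"].to_numpy()
        rows.append(
            {
                "population": pop,
                "allele": allele,
                "motif": motif,
                "median": float(np.median(x)),
                "mean": float(np.mean(x)),
                "sd": float(np.std(x, ddof=1)) if len(x) > 1 else float("nan"),
                "n": len(x),
            }
        )
    return pd.DataFrame(
        rows, columns=["population", "allele", "motif", "median", "mean", "sd", "n"]
    )


# ---------------------------------------------------------------------------
# Trans-allelic correlation in F2 heterozygotes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman correlation plus OLS regression of Ler level on Col level."""

    motif: str
    rho: float
    p_value: float
    slope: float
    intercept: float
    n: int
    #: pointwise 95% bounds of the regression mean at sorted Col levels
    x_sorted: tuple[float, ...] = ()
    lower: tuple[float, ...] = ()
    upper: tuple[float, ...] = ()

    @property
    def defined(self) -> bool:
        return not np.isnan(self.rho)


def allele_correlation(
    col_levels: Sequence[float],
    ler_levels: Sequence[float],
    motif: str = "",
) -> CorrelationResult:
    """Correlate Col- and Ler-allele methylation across heterozygotes.

    Requires >= 3 heterozygotes with defined levels on both alleles.
    Returns Spearman's rho with its p-value and an OLS fit of the Ler
    level on the Col level with pointwise 95% confidence bounds. A
    constant input vector leaves the correlation undefined (NaN rho).
    """
    import statsmodels.api as sm

    x = np.asarray(col_levels, dtype=float)
    y = np.asarray(ler_levels, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 heterozygotes with defined levels, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("constant methylation vector; correlation undefined")
        return CorrelationResult(motif, float("nan"), float("nan"),
                                 float("nan"), float("nan"), n)
    rho, p = sps.spearmanr(x, y)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    order = np.argsort(x)
    pred = model.get_prediction(sm.add_constant(x[order]))
    ci = pred.conf_int(alpha=0.05)
    return CorrelationResult(
        motif=motif,
        rho=float(rho),
        p_value=float(p),
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        n=n,
        x_sorted=tuple(float(v) for v in x[order]),
        lower=tuple(float(v) for v in ci[:, 0]),
        upper=tuple(float(v) for v in ci[:, 1]),
    )


# ---------------------------------------------------------------------------
# Plots (population boxplots; correlation scatter with regression bounds)
# ---------------------------------------------------------------------------


def plot_population_boxplots(levels: pd.DataFrame, path: str) -> None:
    """Boxplots of per-individual levels per population, one panel per
    motif; Col-allele points red, Ler-allele points blue."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    motifs = sorted(levels["motif"].unique())
    pops = list(dict.fromkeys(levels["population"]))
    fig, axes = plt.subplots(1, len(motifs), figsize=(4 * len(motifs), 4), squeeze=False)
    for ax, motif in zip(axes[0], motifs):
        sub = levels[(levels["motif"] == motif)].dropna(subset=["level"])
        data = [sub.loc[sub["population"] == p, "level"] for p in pops]
        ax.boxplot(data, tick_labels=pops)
        for i, p in enumerate(pops, start=1):
            for allele, color in ((COL, "red"), (LER, "blue")):
                pts = sub.loc[
                    (sub["population"] == p) & (sub["allele"] == allele), "level"
                ]
                ax.plot([i] * len(pts), pts, ".", color=color, alpha=0.6, ms=4)
        ax.set_title(motif)
        ax.set_ylabel("methylation level")
        ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_allele_correlation(
    result: CorrelationResult,
    col_levels: Sequence[float],
    ler_levels: Sequence[float],
    path: str,
) -> None:
    """Scatter of Ler vs Col levels with the OLS line and 95% bounds."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(col_levels, ler_levels, "o", color="black", ms=4)
    if result.defined:
        xs = np.array(result.x_sorted)
        ax.plot(xs, result.intercept + result.slope * xs, "-", color="red")
        ax.plot(xs, result.lower, "--", color="red", lw=0.8)
        ax.plot(xs, result.upper, "--", color="red", lw=0.8)
        ax.set_title(
            f"{result.motif}: rho={result.rho:.2f}, slope={result.slope:.3f}"
        )
    ax.set_xlabel("Col-allele methylation")
    ax.set_ylabel("Ler-allele methylation")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
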