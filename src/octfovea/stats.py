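"""Three-group comparison statistics for foveal layer thicknesses.

The group stage replicates the standard clinical workflow: per-outcome
analysis of covariance (thickness ~ group + age + sex, fitted by ordinary
least squares), the group-term F-test, pairwise contrasts of the
covariate-adjusted group means with Bonferroni correction over the three
pairs, Welch t-tests for the baseline variables (spherical equivalent,
axial length, acuity) and Pearson correlations between thickness and
biometry. Eyes are treated as independent observations, matching the
clinical analysis being reproduced, even though amblyopic and fellow eyes
of one subject are paired; the cohort generator's pairing correlation
exists precisely so users can quantify the consequence of that choice.

The model-object surface follows the statsmodels idiom: build a
:class:`ThicknessAncova` from data, ``fit()`` it, and read estimates,
uncertainties and a ``summary()`` table off the returned
:class:`AncovaResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .core import GROUPS, LAYERS, REGIONS

__all__ = [
    "spherical_equivalent",
    "snellen_to_logmar",
    "bonferroni_adjust",
    "p_display",
    "ThicknessAncova",
    "AncovaResults",
    "GroupComparisonResult",
    "CorrelationResult",
    "ancova_group_compare",
    "baseline_compare",
    "correlate",
    "compare_all",
    "group_mean_difference",
]

PAIRS: tuple[tuple[str, str], ...] = (
    ("amblyopic", "fellow"),
    ("amblyopic", "control"),
    ("fellow", "control"),
)

SIGNIFICANCE_LEVEL = 0.05


def spherical_equivalent(sphere: float, cylinder: float) -> float:
    """Spherical equivalent in diopters: sphere + cylinder / 2."""
    if not (math.isfinite(sphere) and math.isfinite(cylinder)):
        raise ValueError("sphere and cylinder must be finite")
    return sphere + cylinder / 2.0


def snellen_to_logmar(numerator: float, denominator: float) -> float:
    """Convert a Snellen fraction to logMAR: log10(denominator / numerator)."""
    if numerator <= 0 or denominator <= 0:
        raise ValueError("Snellen numerator and denominator must be positive")
    return math.log10(denominator / numerator)


def p_display(p: float) -> str:
    """Reporting convention: three decimals, '>0.999' above 0.9995."""
    return ">0.999" if p > 0.9995 else f"{p:.3f}"


def bonferroni_adjust(p_values, m: int | None = None) -> tuple[np.ndarray, list[str]]:
    """Bonferroni correction: multiply by the family size, cap at 1.

    Returns the adjusted values and their display strings. ``m`` defaults
    to the number of p-values supplied.
    """
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size if m is None else m
    if m < 1:
        raise ValueError("family size m must be >= 1")
    adjusted = np.minimum(1.0, m * p)
    return adjusted, [p_display(v) for v in adjusted]


@dataclass
class GroupComparisonResult:
    """One Table-row worth of group comparison for a (region, layer) outcome."""

    outcome: str
    group_means: dict[str, float]  # covariate-adjusted means
    group_sds: dict[str, float]  # raw within-group SDs
    f_stat: float
    p_overall: float
    pairwise_p: dict[tuple[str, str], float]  # Bonferroni-adjusted
    pairwise_display: dict[tuple[str, str], str]
    n_per_group: dict[str, int]


@dataclass
class CorrelationResult:
    """Pearson correlation between a biometric variable and a thickness."""

    x: str
    y: str
    r: float
    p: float
    n: int


class ThicknessAncova:
    """ANCOVA model for one outcome: thickness ~ group + age + sex.

    Parameters
    ----------
    data
        One row per eye with the outcome column plus ``group``, ``age``
        and ``sex`` (``"M"``/``"F"``).
    outcome
        Name of the outcome column.

    Age is centered before fitting (numerical conditioning only; tests are
    unchanged) and sex enters as a male indicator. Group uses treatment
    coding with the amblyopic group as baseline; the reported adjusted
    means hold age and sex at their sample means.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str = "thickness_um",
        group_col: str = "group",
        age_col: str = "age",
        sex_col: str = "sex",
        groups: tuple[str, ...] = GROUPS,
    ):
        for col in (outcome, group_col, age_col, sex_col):
            if col not in data.columns:
                raise ValueError(f"missing required column {col!r}")
        data = data[[outcome, group_col, age_col, sex_col]].dropna()
        counts = data[group_col].value_counts()
        for g in groups:
            if counts.get(g, 0) < 2:
                raise ValueError(f"need at least 2 observations in group {g!r}")
        self.data = data
        self.outcome = outcome
        self.groups = groups
        self._y = data[outcome].to_numpy(dtype=float)
        self._group = data[group_col].to_numpy()
        self._age = data[age_col].to_numpy(dtype=float)
        self._male = (data[sex_col].to_numpy() == "M").astype(float)

    @classmethod
    def from_long(
        cls, long: pd.DataFrame, region: str, layer: str, **kwargs
    ) -> "ThicknessAncova":
        """Build the model for one (region, layer) cell of a long-format table."""
        cell = long[(long["region"] == region) & (long["layer"] == layer)]
        if cell.empty:
            raise ValueError(f"no rows for region={region!r}, layer={layer!r}")
        model = cls(cell, **kwargs)
        model.outcome_label = f"{region} {layer}"
        return model

    def fit(self) -> "AncovaResults":
        y, group, age, male = self._y, self._group, self._age, self._male
        n = y.size
        dummies = np.column_stack([(group == g).astype(float) for g in self.groups[1:]])
        age_c = age - age.mean()
        X = np.column_stack([np.ones(n), dummies, age_c, male])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(
                "rank-deficient ANCOVA design (e.g. sex or age collinear with group)"
            )
        full = sm.OLS(y, X).fit()
        reduced = sm.OLS(y, np.column_stack([np.ones(n), age_c, male])).fit()
        df_num = len(self.groups) - 1
        df_den = n - X.shape[1]
        f_stat = ((reduced.ssr - full.ssr) / df_num) / (full.ssr / df_den)
        p_overall = float(sps.f.sf(f_stat, df_num, df_den))

        # adjusted means: covariates at their sample means (age_c = 0)
        base = full.params[0] + full.params[-1] * male.mean()
        offsets = {self.groups[0]: 0.0}
        offsets.update({g: full.params[1 + i] for i, g in enumerate(self.groups[1:])})
        adjusted_means = {g: float(base + offsets[g]) for g in self.groups}

        cov = full.cov_params()
        pairwise_raw: dict[tuple[str, str], float] = {}
        pairwise_t: dict[tuple[str, str], float] = {}
        for g1, g2 in PAIRS:
            c = np.zeros(X.shape[1])
            for g, sign in ((g1, 1.0), (g2, -1.0)):
                idx = self.groups.index(g)
                if idx > 0:
                    c[idx] += sign
            diff = float(c @ full.params)
            se = float(np.sqrt(c @ cov @ c))
            t = diff / se
            pairwise_t[(g1, g2)] = t
            pairwise_raw[(g1, g2)] = float(2.0 * sps.t.sf(abs(t), df_den))
        adj, disp = bonferroni_adjust(list(pairwise_raw.values()), m=len(PAIRS))
        pairwise_p = dict(zip(PAIRS, adj))
        pairwise_display = dict(zip(PAIRS, disp))

        group_sds = {g: float(np.std(y[group == g], ddof=1)) for g in self.groups}
        n_per_group = {g: int((group == g).sum()) for g in self.groups}
        return AncovaResults(
            model=self,
            ols=full,
            params=full.params,
            f_stat=float(f_stat),
            p_overall=p_overall,
            adjusted_means=adjusted_means,
            group_sds=group_sds,
            pairwise_t=pairwise_t,
            pairwise_raw=pairwise_raw,
            pairwise_p=pairwise_p,
            pairwise_display=pairwise_display,
            n_per_group=n_per_group,
            df_resid=df_den,
        )


@dataclass
class AncovaResults:
    """Fitted ANCOVA: group F-test, adjusted means and pairwise contrasts."""

    model: ThicknessAncova
    ols: object
    params: np.ndarray
    f_stat: float
    p_overall: float
    adjusted_means: dict[str, float]
    group_sds: dict[str, float]
    pairwise_t: dict[tuple[str, str], float]
    pairwise_raw: dict[tuple[str, str], float]
    pairwise_p: dict[tuple[str, str], float]
    pairwise_display: dict[tuple[str, str], str]
    n_per_group: dict[str, int]
    df_resid: int

    def pairwise_frame(self) -> pd.DataFrame:
        rows = []
        for g1, g2 in PAIRS:
            rows.append(
                {
                    "group_1": g1,
                    "group_2": g2,
                    "mean_difference": self.adjusted_means[g1] - self.adjusted_means[g2],
                    "t": self.pairwise_t[(g1, g2)],
                    "p_raw": self.pairwise_raw[(g1, g2)],
                    "p_bonferroni": self.pairwise_p[(g1, g2)],
                    "display": self.pairwise_display[(g1, g2)],
                }
            )
        return pd.DataFrame(rows)

    def to_result(self, outcome: str | None = None) -> GroupComparisonResult:
        label = outcome or getattr(self.model, "outcome_label", self.model.outcome)
        return GroupComparisonResult(
            outcome=label,
            group_means=self.adjusted_means,
            group_sds=self.group_sds,
            f_stat=self.f_stat,
            p_overall=self.p_overall,
            pairwise_p=self.pairwise_p,
            pairwise_display=self.pairwise_display,
            n_per_group=self.n_per_group,
        )

    def summary(self) -> str:
        label = getattr(self.model, "outcome_label", self.model.outcome)
        lines = [
            f"ANCOVA: {label} ~ group + age + sex",
            f"group F({len(self.model.groups) - 1}, {self.df_resid}) = "
            f"{self.f_stat:.3f}, p = {p_display(self.p_overall)}",
            "",
            "adjusted group means (age, sex held at sample means):",
        ]
        for g in self.model.groups:
            lines.append(
                f"  {g:<10s} {self.adjusted_means[g]:8.2f} μm "
                f"(SD {self.group_sds[g]:.2f}, n = {self.n_per_group[g]})"
            )
        lines.append("")
        lines.append("pairwise contrasts (Bonferroni over 3 pairs):")
        for g1, g2 in PAIRS:
            diff = self.adjusted_means[g1] - self.adjusted_means[g2]
            lines.append(
                f"  {g1} - {g2:<10s} {diff:+7.2f} μm, "
                f"p = {self.pairwise_display[(g1, g2)]}"
            )
        return "\n".join(lines)


def ancova_group_compare(long: pd.DataFrame, region: str, layer: str) -> GroupComparisonResult:
    """Fit the per-outcome ANCOVA for one (region, layer) cell."""
    return ThicknessAncova.from_long(long, region, layer).fit().to_result()


def baseline_compare(
    cohort: pd.DataFrame, variable: str, group_1: str, group_2: str
) -> dict[str, float]:
    """Welch two-sample t-test for a baseline variable between two groups.

    ``variable`` may be a column name or one of the shorthands ``SE``
    (spherical equivalent), ``AL`` (axial length) or ``VA`` (logMAR acuity).
    """
    aliases = {"SE": "spherical_equivalent", "AL": "axial_length_mm", "VA": "va_logmar"}
    column = aliases.get(variable, variable)
    if column not in cohort.columns:
        raise ValueError(f"unknown baseline variable {variable!r}")
    x1 = cohort.loc[cohort["group"] == group_1, column].dropna().to_numpy(dtype=float)
    x2 = cohort.loc[cohort["group"] == group_2, column].dropna().to_numpy(dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("need at least 2 observations per group")
    t, p = sps.ttest_ind(x1, x2, equal_var=False)
    return {
        "t": float(t),
        "p": float(p),
        "mean_1": float(x1.mean()),
        "mean_2": float(x2.mean()),
        "n_1": int(x1.size),
        "n_2": int(x2.size),
    }


def correlate(x, y, x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Pearson correlation with a two-sided p-value (t transform, n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(x=x_name, y=y_name, r=float(r), p=float(p), n=int(x.size))


def compare_all(long: pd.DataFrame) -> pd.DataFrame:
    """Comparison report over every (region, layer) outcome present.

    Returns one row per outcome with covariate-adjusted group means, raw
    group SDs, the group F-test and the three Bonferroni-adjusted pairwise
    p-values plus their display strings.
    """
    rows = []
    for region in REGIONS:
        present = long.loc[long["region"] == region, "layer"].unique()
        for layer in [l for l in ("total",) + LAYERS if l in present]:
            res = ThicknessAncova.from_long(long, region, layer).fit()
            row: dict[str, object] = {"region": region, "layer": layer}
            for g in GROUPS:
                row[f"mean_{g}"] = res.adjusted_means[g]
                row[f"sd_{g}"] = res.group_sds[g]
            row["f_stat"] = res.f_stat
            row["p_overall"] = res.p_overall
            for (g1, g2) in PAIRS:
                row[f"p_{g1}_vs_{g2}"] = res.pairwise_p[(g1, g2)]
                row[f"display_{g1}_vs_{g2}"] = res.pairwise_display[(g1, g2)]
            rows.append(row)
    return pd.DataFrame(rows)


def group_mean_difference(
    report: pd.DataFrame, region: str, layer: str, group_1: str, group_2: str
) -> float:
    """Difference of group means (μm) for one outcome of a report table.

    ``report`` must carry ``region``/``layer`` columns and ``mean_<group>``
    columns, as produced by :func:`compare_all` or
    :func:`octfovea.reference.reference_report`.
    """
    cell = report[(report["region"] == region) & (report["layer"] == layer)]
    if cell.empty:
        raise ValueError(f"no report row for region={region!r}, layer={layer!r}")
    for g in (group_1, group_2):
        if f"mean_{g}" not in report.columns:
            raise ValueError(f"report lacks a mean_{g} column")
    row = cell.iloc[0]
    return float(row[f"mean_{group_1}"] - row[f"mean_{group_2}"])
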