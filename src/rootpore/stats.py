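"""Experiment-level statistics: randomized-block ANOVA, LSD, percentages.

Per-column interaction counts from a 2 genotype x 2 compaction factorial
(10 replicates per cell, blocked over 6 staggered scanning days) are
analysed the way the glasshouse experiment was: a Shapiro-Wilk normality
check, analysis of variance as a randomized block design, and the least
significant difference at p = .05 for comparing cell means.  Count
responses at n = 10 per cell may violate normality; the Shapiro-Wilk
result is reported and the ANOVA proceeds regardless, with a note.

The ANOVA is exposed statsmodels-style: :class:`RandomizedBlockAnova` is a
model built from a tidy per-column table; ``fit()`` returns a results
object carrying the ANOVA table, residual variance, LSD and a ``summary()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "aggregate",
    "shapiro_wilk",
    "RandomizedBlockAnova",
    "RBDAnovaResults",
    "rbd_anova",
    "lsd",
    "combined_percentages",
    "StatsReport",
    "build_report",
    "plot_means",
]

COUNT_RESPONSES = [
    "n_interactions", "n_colonize", "n_cross",
    "n_changed", "n_unchanged", "n_indeterminate",
]


def aggregate(
    column_results,
    manifest: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-column response table with design labels attached.

    ``column_results`` is an iterable of :class:`~rootpore.interactions.ColumnResult`
    (or a DataFrame already holding one row per column with the count
    columns).  If a manifest (column_id, genotype, treatment, block) is
    given it is joined on ``column_id``; missing design labels raise.
    """
    if isinstance(column_results, pd.DataFrame):
        df = column_results.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "column_id": r.column_id,
                    **{k: getattr(r, k) for k in COUNT_RESPONSES},
                }
                for r in column_results
            ]
        )
    if manifest is not None:
        df = df.merge(
            manifest[["column_id", "genotype", "treatment", "block"]],
            on="column_id",
            how="left",
        )
        if df[["genotype", "treatment", "block"]].isna().any().any():
            missing = df.loc[df["genotype"].isna(), "column_id"].tolist()
            raise ValueError(f"columns missing design labels: {missing}")
    return df.sort_values("column_id").reset_index(drop=True)


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test; returns (W, p).

    Requires 3 <= n <= 5000 and a non-constant sample.
    """
    x = np.asarray(values, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0.0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


@dataclass
class RBDAnovaResults:
    """Fitted randomized-block ANOVA: table, variance components, LSD."""

    response: str
    anova_table: pd.DataFrame
    mse: float
    df_resid: int
    n_per_mean: int
    cell_means: pd.DataFrame
    shapiro: tuple[float, float] | None = None

    def lsd(self, alpha: float = 0.05, n_per_mean: int | None = None) -> float:
        return lsd(self.mse, self.df_resid, n_per_mean or self.n_per_mean, alpha)

    def p_value(self, term: str) -> float:
        return float(self.anova_table.loc[term, "p"])

    def summary(self) -> str:
        lines = [
            f"Randomized-block ANOVA: {self.response}",
            "=" * 58,
            self.anova_table.round(4).to_string(),
            "-" * 58,
            f"residual MSE {self.mse:.4f} on {self.df_resid} df; "
            f"LSD(0.05) = {self.lsd():.4f} (n = {self.n_per_mean}/mean)",
        ]
        if self.shapiro is not None:
            w, p = self.shapiro
            lines.append(f"Shapiro-Wilk on residual-free response: W = {w:.4f}, p = {p:.4f}")
            if p < 0.05:
                lines.append("note: normality rejected; ANOVA reported regardless")
        lines.append("cell means:")
        lines.append(self.cell_means.round(3).to_string())
        return "\n".join(lines)


class RandomizedBlockAnova:
    """Two-factor factorial ANOVA in a randomized block design.

    Partitions the response sum of squares into block, the two factors,
    their interaction, and residual, from a tidy per-column table.

    Parameters
    ----------
    data : DataFrame
        One row per column with the response and the design labels.
    response : str
        Name of the response column (e.g. ``"n_colonize"``).
    factors : (str, str)
        Treatment-structure factor names (default genotype, treatment).
    block : str
        Blocking factor name.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str,
        factors: tuple[str, str] = ("genotype", "treatment"),
        block: str = "block",
    ):
        for col in (response, *factors, block):
            if col not in data.columns:
                raise ValueError(f"column '{col}' not in data")
        self.data = data
        self.response = response
        self.factors = factors
        self.block = block

    @classmethod
    def from_columns(cls, column_results, manifest, response: str,
                     **kwargs) -> "RandomizedBlockAnova":
        return cls(aggregate(column_results, manifest), response, **kwargs)

    def fit(self) -> RBDAnovaResults:
        a, b = self.factors
        formula = (
            f"Q('{self.response}') ~ C(Q('{self.block}')) + "
            f"C(Q('{a}')) * C(Q('{b}'))"
        )
        ols_res = smf.ols(formula, data=self.data).fit()
        if ols_res.df_resid < 1:
            raise ValueError("zero residual degrees of freedom")
        # sequential (type I) sums of squares: the block stratum is removed
        # first, as in a classical randomized-block analysis, and the
        # components add up to the total SS exactly
        table = anova_lm(ols_res, typ=1)
        rename = {
            f"C(Q('{self.block}'))": "block",
            f"C(Q('{a}'))": a,
            f"C(Q('{b}'))": b,
            f"C(Q('{a}')):C(Q('{b}'))": f"{a}:{b}",
            "Residual": "residual",
        }
        table = table.rename(index=rename)
        table = table.rename(columns={"sum_sq": "ss", "PR(>F)": "p"})
        table["ms"] = table["ss"] / table["df"]
        table = table[["df", "ss", "ms", "F", "p"]]
        mse = float(table.loc["residual", "ms"])
        df_resid = int(table.loc["residual", "df"])
        cell_means = (
            self.data.groupby([a, b], observed=True)[self.response]
            .agg(["mean", "std", "count"])
            .reset_index()
        )
        n_per_mean = int(cell_means["count"].min())
        try:
            shap = shapiro_wilk(self.data[self.response])
        except ValueError:
            shap = None
        return RBDAnovaResults(
            response=self.response,
            anova_table=table,
            mse=mse,
            df_resid=df_resid,
            n_per_mean=n_per_mean,
            cell_means=cell_means,
            shapiro=shap,
        )


def rbd_anova(
    data: pd.DataFrame,
    response: str,
    factors: tuple[str, str] = ("genotype", "treatment"),
    block: str = "block",
) -> pd.DataFrame:
    """Functional wrapper: fitted randomized-block ANOVA table."""
    return RandomizedBlockAnova(data, response, factors, block).fit().anova_table


def lsd(mse: float, df_resid: int, n_per_mean: int, alpha: float = 0.05) -> float:
    """Least significant difference: t(1-alpha/2, df) * sqrt(2*MSE/n)."""
    if mse <= 0:
        raise ValueError("mse must be positive")
    if df_resid < 1:
        raise ValueError("df_resid must be >= 1")
    t = sps.t.ppf(1.0 - alpha / 2.0, df_resid)
    return float(t * np.sqrt(2.0 * mse / n_per_mean))


def combined_percentages(events: pd.DataFrame, treatment: str | None = None) -> dict:
    """Genotype-combined interaction percentages for one treatment arm.

    ``events`` is the tidy event table (needs ``classification`` and
    ``trajectory``; ``treatment`` rows are selected if a column and value
    are given).  Colonize/cross percentages are over all interactions;
    changed/unchanged over determinate events only.
    """
    df = events
    if treatment is not None:
        df = df[df["treatment"] == treatment]
    n = len(df)
    if n == 0:
        raise ValueError("no events for the requested treatment")
    n_col = int((df["classification"] == "colonize").sum())
    det = df[df["trajectory"].isin(["changed", "unchanged"])]
    out = {
        "n_interactions": n,
        "n_determinate": len(det),
        "pct_colonize": 100.0 * n_col / n,
        "pct_cross": 100.0 * (n - n_col) / n,
    }
    if len(det):
        n_ch = int((det["trajectory"] == "changed").sum())
        out["pct_changed"] = 100.0 * n_ch / len(det)
        out["pct_unchanged"] = 100.0 * (len(det) - n_ch) / len(det)
    else:
        out["pct_changed"] = float("nan")
        out["pct_unchanged"] = float("nan")
    return out


@dataclass
class StatsReport:
    """Bundle of per-response ANOVA results and per-treatment percentages."""

    responses: dict = field(default_factory=dict)   # name -> RBDAnovaResults
    percentages: dict = field(default_factory=dict)  # treatment -> dict
    alpha: float = 0.05

    def to_json(self, path) -> None:
        payload = {
            "alpha": self.alpha,
            "percentages": self.percentages,
            "responses": {
                name: {
                    "anova": json.loads(
                        res.anova_table.reset_index()
                        .rename(columns={"index": "term"})
                        .to_json(orient="records")
                    ),
                    "mse": res.mse,
                    "df_resid": res.df_resid,
                    "lsd": res.lsd(self.alpha),
                    "shapiro_w": None if res.shapiro is None else res.shapiro[0],
                    "shapiro_p": None if res.shapiro is None else res.shapiro[1],
                    "cell_means": json.loads(
                        res.cell_means.to_json(orient="records")
                    ),
                }
                for name, res in self.responses.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def summary(self) -> str:
        parts = [r.summary() for r in self.responses.values()]
        for t, pct in self.percentages.items():
            parts.append(
                f"{t}: {pct['pct_colonize']:.1f}% colonize / "
                f"{pct['pct_cross']:.1f}% cross; "
                f"{pct['pct_changed']:.1f}% changed "
                f"({pct['n_interactions']} interactions, "
                f"{pct['n_determinate']} determinate)"
            )
        return "\n\n".join(parts)


def build_report(
    events: pd.DataFrame,
    per_column: pd.DataFrame,
    responses: list[str] | None = None,
    alpha: float = 0.05,
) -> StatsReport:
    """Fit the randomized-block ANOVA per response and tally percentages.

    ``per_column`` must carry the count responses plus genotype, treatment
    and block labels (see :func:`aggregate`); ``events`` must carry a
    ``treatment`` column for the per-arm percentages.
    """
    responses = responses or ["n_interactions", "n_colonize", "n_changed"]
    report = StatsReport(alpha=alpha)
    for resp in responses:
        try:
            report.responses[resp] = RandomizedBlockAnova(per_column, resp).fit()
        except ValueError:
            continue  # e.g. constant response in a tiny simulated dataset
    for t in sorted(events["treatment"].dropna().unique()):
        report.percentages[t] = combined_percentages(events, t)
    return report


def plot_means(results: RBDAnovaResults, alpha: float = 0.05, ax=None):
    """Bar plot of cell means with an LSD(alpha) bracket, matplotlib axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    cm = results.cell_means
    labels = [
        " / ".join(str(v) for v in row[:2])
        for row in cm.itertuples(index=False)
    ]
    ax.bar(np.arange(len(cm)), cm["mean"], color="tan", edgecolor="k")
    bar = results.lsd(alpha)
    x0 = len(cm) - 0.6
    ax.errorbar([x0], [cm["mean"].max()], yerr=[[0], [bar]], color="k",
                capsize=4)
    ax.annotate("LSD", (x0, cm["mean"].max() + bar), ha="center",
                va="bottom", fontsize=8)
    ax.set_xticks(np.arange(len(cm)), labels, rotation=20, ha="right")
    ax.set_ylabel(results.response)
    return ax
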