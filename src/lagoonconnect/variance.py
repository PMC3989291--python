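"""Variance decomposition of connectivity across the scenario factor grid.

The connectivity experiment is a balanced full-factorial design over
release level (2), swimming (2), wind regime (12), pelagic larval
duration (4), spawning site (12) and destination (14: 12 sectors plus
shallow and ocean). Potential connectivity probabilities are normalized
with an arcsine-square-root transform, realistic larval numbers with a
Box-Cox transform (lambda = 0.3), and a fixed-effects factorial ANOVA
attributes the percentage of total variance to each term.

On a balanced grid the factorial contrast subspaces are mutually
orthogonal, so each term's sum of squares is computed directly from
marginal cell means by inclusion-exclusion (sequential and partial SS
coincide); terms not listed in the model fold into the residual.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "arcsine_sqrt",
    "boxcox",
    "anova_percent_variance",
    "assemble_scenario_grid",
    "ConnectivityAnova",
    "ConnectivityAnovaResults",
    "DEFAULT_TERMS",
]

#: Model terms of the connectivity ANOVA: the six main effects and the
#: interaction set reported for this design.
DEFAULT_TERMS = (
    "RL", "Swim", "WR", "PLD", "S", "D",
    "RL:S", "PLD:S", "RL:D", "WR:D", "PLD:D", "S:D",
    "RL:S:D", "WR:S:D", "PLD:S:D",
)


class DomainError(ValueError):
    """Input outside the transform's domain."""


def arcsine_sqrt(p):
    """Arcsine-square-root transform of probabilities: asin(sqrt(p))."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise DomainError("probabilities must lie in [0, 1]")
    return np.arcsin(np.sqrt(p))


def boxcox(x, lam: float = 0.3, offset: float | None = None):
    """Box-Cox transform: (x^lambda - 1)/lambda, or ln(x) at lambda = 0.

    Zeros are handled by adding ``offset`` to every value; with
    ``offset=None`` and zeros present, the smallest positive observed
    value is used. Strictly positive input needs no offset.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise DomainError("Box-Cox input must be >= 0")
    if np.any(x == 0):
        if offset is None:
            pos = x[x > 0]
            if pos.size == 0:
                raise DomainError("all-zero input cannot be Box-Cox transformed")
            offset = float(pos.min())
        x = x + offset
    elif offset:
        x = x + offset
    if np.any(x <= 0):
        raise DomainError("input not positive after offset")
    if lam == 0.0:
        return np.log(x)
    return (x**lam - 1.0) / lam


def _term_factors(term: str) -> tuple[str, ...]:
    return tuple(term.split(":"))


def anova_percent_variance(data: pd.DataFrame, response: str,
                           terms=DEFAULT_TERMS) -> pd.DataFrame:
    """Fixed-effects factorial ANOVA on a balanced design.

    ``data`` holds one row per factor combination (factor columns plus
    the ``response`` column). Each term's sum of squares comes from
    marginal cell means by inclusion-exclusion over its sub-terms —
    exact for a balanced grid, where sequential and partial SS agree —
    and ``%Var = 100 * SS / SS_total``; the residual completes the
    budget. Returns a table with df, sum_sq, F, p and pct_var rows,
    residual last.
    """
    factors = sorted({f for t in terms for f in _term_factors(t)})
    missing = [f for f in factors if f not in data.columns]
    if missing:
        raise ValueError(f"missing factor columns: {missing}")
    counts = data.groupby(factors, observed=True).size()
    n_cells_expected = int(np.prod([data[f].nunique() for f in factors]))
    if counts.nunique() != 1 or len(counts) != n_cells_expected:
        raise ValueError("design is unbalanced: missing or unequal cells")
    n = len(data)
    y = data[response].to_numpy(float)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    levels = {f: data[f].nunique() for f in factors}

    raw_cache: dict[tuple, float] = {}

    def ss_raw(fs: tuple) -> float:
        if fs not in raw_cache:
            cell_means = data.groupby(list(fs), observed=True)[response].mean()
            n_per = n / len(cell_means)
            raw_cache[fs] = float(n_per * ((cell_means - grand) ** 2).sum())
        return raw_cache[fs]

    ss_cache: dict[tuple, float] = {}

    def ss_term(fs: tuple) -> float:
        if fs not in ss_cache:
            total = ss_raw(fs)
            for r in range(1, len(fs)):
                for sub in itertools.combinations(fs, r):
                    total -= ss_term(sub)
            ss_cache[fs] = total
        return ss_cache[fs]

    rows = []
    ss_model, df_model = 0.0, 0
    for t in terms:
        fs = tuple(sorted(_term_factors(t)))
        ss = max(ss_term(fs), 0.0)
        df = int(np.prod([levels[f] - 1 for f in fs]))
        rows.append({"term": t, "df": df, "sum_sq": ss})
        ss_model += ss
        df_model += df
    ss_res = max(ss_total - ss_model, 0.0)
    df_res = n - 1 - df_model
    ms_res = ss_res / df_res if df_res > 0 else np.nan
    for r in rows:
        if r["df"] > 0 and df_res > 0 and ms_res > 0:
            F = (r["sum_sq"] / r["df"]) / ms_res
            r["F"] = F
            r["p"] = float(stats.f.sf(F, r["df"], df_res))
        else:
            r["F"], r["p"] = np.nan, np.nan
        r["pct_var"] = 100.0 * r["sum_sq"] / ss_total if ss_total > 0 else np.nan
    rows.append({"term": "Residual", "df": df_res, "sum_sq": ss_res,
                 "F": np.nan, "p": np.nan,
                 "pct_var": 100.0 * ss_res / ss_total if ss_total > 0 else np.nan})
    return pd.DataFrame(rows).set_index("term")


def assemble_scenario_grid(matrices: dict) -> pd.DataFrame:
    """Long-format scenario grid from per-treatment connectivity matrices.

    ``matrices`` maps ``(release_level, swim, wind_regime, pld)`` to a
    connectivity matrix; the result has one row per (treatment, site,
    destination) with factor columns RL, Swim, WR, PLD, S, D and the
    cell value.
    """
    frames = []
    for (rl, sw, wr, pld), M in matrices.items():
        long = M.values.stack().rename("value").reset_index()
        long.columns = ["S", "D", "value"]
        long["RL"] = str(rl)
        long["Swim"] = str(sw)
        long["WR"] = str(wr)
        long["PLD"] = str(pld)
        frames.append(long)
    df = pd.concat(frames, ignore_index=True)
    df["S"] = df["S"].astype(str)
    df["D"] = df["D"].astype(str)
    return df


class ConnectivityAnova:
    """Model object: variance decomposition of a connectivity response.

    Parameters
    ----------
    data : DataFrame
        Long-format balanced scenario grid (see
        :func:`assemble_scenario_grid`).
    response_kind : {"potential", "realistic"}
        Chooses the normalizing transform: arcsine-sqrt for potential
        probabilities, Box-Cox (``lam``) for realistic larval numbers.
    """

    def __init__(self, data: pd.DataFrame, response_kind: str = "potential",
                 terms=DEFAULT_TERMS, lam: float = 0.3,
                 value_column: str = "value"):
        if response_kind not in ("potential", "realistic"):
            raise ValueError("response_kind must be 'potential' or 'realistic'")
        self.data = data
        self.response_kind = response_kind
        self.terms = terms
        self.lam = lam
        self.value_column = value_column

    def fit(self) -> "ConnectivityAnovaResults":
        df = self.data.copy()
        vals = df[self.value_column].to_numpy(float)
        if self.response_kind == "potential":
            df["_y"] = arcsine_sqrt(np.clip(vals, 0.0, 1.0))
        else:
            df["_y"] = boxcox(vals, self.lam)
        table = anova_percent_variance(df, "_y", self.terms)
        return ConnectivityAnovaResults(model=self, table=table)


@dataclass
class ConnectivityAnovaResults:
    """Fitted variance decomposition with a printable summary table."""

    model: ConnectivityAnova
    table: pd.DataFrame

    def pct_var(self, term: str) -> float:
        return float(self.table.loc[term, "pct_var"])

    def summary(self) -> pd.DataFrame:
        out = self.table.copy()
        out["pct_var"] = out["pct_var"].round(1)
        return out[["df", "p", "pct_var"]]

    def to_csv(self, path) -> None:
        self.summary().to_csv(path)
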