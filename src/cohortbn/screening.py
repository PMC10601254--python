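"""Univariate predictor screening against a binary outcome.

Categorical predictors are screened with the Pearson chi-squared test
(no continuity correction) on the r x 2 contingency table; ordinal
(rank) predictors with the Mann-Whitney U test using midranks for ties
and the tie-corrected normal approximation for larger samples.

Screening is advisory: downstream training accepts any variable list.
No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, DataError

__all__ = [
    "ScreeningResult",
    "chi_squared_screen",
    "mann_whitney_screen",
    "screen_all",
]

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class ScreeningResult:
    variable: str
    test: str  # "chi_squared" | "mann_whitney_u"
    statistic: float
    p_value: float
    selected: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def _check_columns(table: pd.DataFrame, *columns: str) -> None:
    for col in columns:
        if col not in table.columns:
            raise ValueError(f"unknown column {col!r}")


def chi_squared_screen(
    table: pd.DataFrame,
    variable: str,
    outcome: str,
    alpha: float = DEFAULT_ALPHA,
) -> ScreeningResult:
    """Pearson chi-squared test of association on the r x c table."""
    _check_columns(table, variable, outcome)
    contingency = pd.crosstab(table[variable], table[outcome])
    if contingency.shape[0] < 2 or contingency.shape[1] < 2:
        raise DataError(
            f"degenerate contingency table for {variable!r}: "
            f"{contingency.shape[0]} observed level(s) vs "
            f"{contingency.shape[1]} outcome level(s)"
        )
    result = stats.chi2_contingency(contingency.to_numpy(), correction=False)
    p_value = float(result.pvalue)
    return ScreeningResult(
        variable=variable,
        test="chi_squared",
        statistic=float(result.statistic),
        p_value=p_value,
        selected=bool(p_value < alpha),
    )


def mann_whitney_screen(
    table: pd.DataFrame,
    variable: str,
    outcome: str,
    alpha: float = DEFAULT_ALPHA,
    exact_threshold: int = 20,
) -> ScreeningResult:
    """Mann-Whitney U test of an ordinal variable between outcome groups.

    State labels are compared by their numeric value when possible,
    otherwise by lexicographic order.  The exact null distribution is
    used for small samples without ties; otherwise the tie-corrected
    normal approximation (with continuity correction).  Reports the U
    statistic of the first outcome group (sorted label order):
    U1 + U2 = n1 * n2.
    """
    _check_columns(table, variable, outcome)
    groups = sorted(table[outcome].astype(str).unique())
    if len(groups) != 2:
        raise DataError(
            f"outcome {outcome!r} must have exactly 2 observed levels; "
            f"got {len(groups)}"
        )
    values = table[variable].astype(str)
    try:
        numeric = values.astype(float)
    except ValueError:
        numeric = values.map(
            {s: float(i) for i, s in enumerate(sorted(values.unique()))}
        )
    x = numeric[table[outcome].astype(str) == groups[0]].to_numpy()
    y = numeric[table[outcome].astype(str) == groups[1]].to_numpy()
    if len(x) == 0 or len(y) == 0:
        raise DataError(f"an outcome group is empty for {variable!r}")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    small = max(len(x), len(y)) <= exact_threshold
    method = "exact" if (small and not has_ties) else "asymptotic"
    result = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p_value = float(min(result.pvalue, 1.0))
    return ScreeningResult(
        variable=variable,
        test="mann_whitney_u",
        statistic=float(result.statistic),
        p_value=p_value,
        selected=bool(p_value < alpha),
    )


def screen_all(
    table: pd.DataFrame,
    variable_kinds: Mapping[str, str],
    alpha: float = DEFAULT_ALPHA,
    outcome: str = "np",
) -> list[ScreeningResult]:
    """Screen every predictor with the test its declared kind requires.

    ``variable_kinds`` maps predictor name to ``"categorical"`` (chi-
    squared) or ``"rank"`` (Mann-Whitney U).  ``selected`` is p < alpha.
    """
    results = []
    for variable, kind in variable_kinds.items():
        if kind == "categorical":
            results.append(chi_squared_screen(table, variable, outcome, alpha))
        elif kind == "rank":
            results.append(mann_whitney_screen(table, variable, outcome, alpha))
        else:
            raise ConfigurationError(
                f"unknown kind {kind!r} for {variable!r} "
                "(expected 'categorical' or 'rank')"
            )
    return results


def default_variable_kinds() -> dict[str, str]:
    """Predictor→kind map for the default 16-predictor cohort."""
    categorical = [
        "age", "pbg", "p", "hdop", "ptb", "prom",
        "ms", "nrds", "nnj", "pph", "na", "ngr",
    ]
    rank = ["g", "afv", "afc", "crp"]
    kinds = {v: "categorical" for v in categorical}
    kinds.update({v: "rank" for v in rank})
    return kinds
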