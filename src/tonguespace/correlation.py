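"""Correlation structure among measures and against vowel formants.

All values are first z-scored within speaker, then reduced to by-speaker
by-item means (item = the five word types), which damps the token-level
autocorrelation; Pearson coefficients are computed on the reduced table
with pairwise-complete deletion (flat-shape NaN TC rows drop per pair).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MEASURE_COLUMNS

logger = logging.getLogger(__name__)


def speaker_item_means(
    df: pd.DataFrame,
    value_cols,
    speaker_col: str = "speaker",
    item_col: str = "vowel",
) -> pd.DataFrame:
    """One mean per (speaker, item) cell per variable.

    Input values should already be within-speaker scaled.  Cells with no
    finite values for a variable come out NaN (logged).
    """
    out = df.groupby([speaker_col, item_col], sort=True, observed=True)[
        list(value_cols)
    ].mean().reset_index()
    n_missing = int(out[list(value_cols)].isna().sum().sum())
    if n_missing:
        logger.info("speaker_item_means: %d empty (speaker, item) cells", n_missing)
    return out


@dataclass
class CorrelationMatrix:
    """Symmetric pairwise-complete Pearson correlations with cell sizes."""

    labels: list[str]
    r: pd.DataFrame
    n: pd.DataFrame


def correlation_table(means: pd.DataFrame, variables) -> CorrelationMatrix:
    """Pairwise-complete Pearson r for every variable pair.

    A constant variable yields NaN correlations with a warning.  Pairs with
    fewer than 3 complete observations are NaN.
    """
    variables = list(variables)
    sub = means[variables].replace([np.inf, -np.inf], np.nan)
    constant = [v for v in variables if sub[v].dropna().nunique() <= 1]
    if constant:
        warnings.warn(f"constant variables yield NaN correlations: {constant}",
                      stacklevel=2)
    r = sub.corr(method="pearson", min_periods=3)
    notna = sub.notna().astype(int)
    n = notna.T @ notna
    np.fill_diagonal(r.values, 1.0)
    return CorrelationMatrix(labels=variables, r=r, n=n)


def formant_correlations(
    measure_means: pd.DataFrame,
    formant_means: pd.DataFrame,
    measures=MEASURE_COLUMNS,
    speaker_col: str = "speaker",
    item_col: str = "vowel",
) -> dict[str, pd.DataFrame]:
    """Each measure's correlation with scaled F1 and F2, ranked by |r|.

    Both inputs are by-speaker by-item mean tables (measures and formants
    scaled within speaker upstream); they are merged on (speaker, item) and
    only the intersection of cells enters the correlations.  Returns
    ``{"F1": table, "F2": table}``, each with one row per measure sorted by
    absolute correlation, descending.
    """
    merged = measure_means.merge(
        formant_means, on=[speaker_col, item_col], how="inner"
    )
    out = {}
    for formant, col in (("F1", "f1_hz"), ("F2", "f2_hz")):
        rows = []
        sub = merged.replace([np.inf, -np.inf], np.nan)
        for m in measures:
            pair = sub[[m, col]].dropna()
            if len(pair) < 3 or pair[m].nunique() <= 1 or pair[col].nunique() <= 1:
                r = np.nan
            else:
                r = float(np.corrcoef(pair[m], pair[col])[0, 1])
            rows.append({"measure": m, "r": r, "n": len(pair)})
        table = pd.DataFrame(rows)
        table = table.reindex(
            table["r"].abs().sort_values(ascending=False, kind="mergesort").index
        ).reset_index(drop=True)
        out[formant] = table
    return out
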