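"""Group statistics: mean +/- SD and the unpaired two-tailed Student t-test."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import DataError


@dataclass
class TTestResult:
    t: float
    p: float
    df: int


def pooled_t_test(a, b) -> TTestResult:
    """Unpaired two-tailed Student t-test with pooled variance.

    t = (mean_a - mean_b) / sqrt(s_p^2 (1/n_a + 1/n_b)) with the pooled
    variance s_p^2 = ((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2).
    Identical samples give t = 0, p = 1; zero pooled variance with unequal
    means gives p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise DataError("t-test requires at least two observations per group")
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = a.mean() - b.mean()
    if se == 0:
        if diff == 0:
            return TTestResult(t=0.0, p=1.0, df=df)
        return TTestResult(t=float(np.sign(diff)) * float("inf"), p=0.0, df=df)
    t = diff / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(t=float(t), p=p, df=df)


def welch_t_test(a, b) -> TTestResult:
    """Welch's unequal-variance alternative, available behind a flag."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t, p = sps.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return TTestResult(t=float(t), p=float(p), df=int(round(df)))


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


METRIC_COLUMNS = (
    "VL_mm", "VAD_um", "VD_fraction",
    "BNN", "BND_per_mm", "EPN", "EPD_per_mm",
    "FVSC", "FVLR",
)


def compare_groups(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    metrics: tuple[str, ...] = METRIC_COLUMNS,
    welch: bool = False,
) -> pd.DataFrame:
    """Compare metric distributions between group pairs.

    ``table`` holds one row per (eye, layer, region) with metric columns
    and a ``group`` label.  Returns one row per
    (layer, region, metric, group pair) with means, SDs, t, p, stars.
    Cells with fewer than two observations per group are marked
    not-computable (NaN statistics).
    """
    groups = sorted(table["group"].unique())
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    test = welch_t_test if welch else pooled_t_test
    rows = []
    for (layer, region), cell in table.groupby(["layer", "region"], sort=True):
        for metric in metrics:
            if metric not in cell.columns:
                continue
            for ga, gb in pairs:
                xa = cell.loc[cell["group"] == ga, metric].dropna().to_numpy()
                xb = cell.loc[cell["group"] == gb, metric].dropna().to_numpy()
                row = {
                    "layer": layer, "region": region, "metric": metric,
                    "group_a": ga, "group_b": gb,
                    "n_a": len(xa), "n_b": len(xb),
                    "mean_a": xa.mean() if len(xa) else np.nan,
                    "sd_a": xa.std(ddof=1) if len(xa) > 1 else np.nan,
                    "mean_b": xb.mean() if len(xb) else np.nan,
                    "sd_b": xb.std(ddof=1) if len(xb) > 1 else np.nan,
                }
                if len(xa) >= 2 and len(xb) >= 2:
                    res = test(xa, xb)
                    row.update(t=res.t, p=res.p, stars=significance_stars(res.p))
                else:
                    row.update(t=np.nan, p=np.nan, stars="n/c")
                rows.append(row)
    return pd.DataFrame(rows)
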