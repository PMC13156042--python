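"""Histology statistics: colocalization vs. chance and region correlations.

For count tables (DAPI / c-Fos / marker / double-positive per subject and
subfield), the chance level of colocalization under independence is
(c-Fos/DAPI) x (marker/DAPI) and the enrichment ratio is the observed
double-positive fraction divided by that chance (1 under independence).

For subject x region c-Fos density tables, pairwise Pearson correlations
are computed per group with two-sided p-values; comparing two groups
classifies each region pair as having gained, lost, or kept its
significant correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError

__all__ = [
    "cfos_chance",
    "overlap_vs_chance",
    "chance_table",
    "region_correlation_matrix",
    "correlation_gain_loss",
    "CorrelationComparison",
]

_COUNT_COLS = ("dapi", "cfos", "marker", "double_pos")


def _validate_counts(row) -> None:
    dapi = row["dapi"]
    if dapi <= 0:
        raise InvalidInputError("dapi count must be positive")
    for col in ("cfos", "marker", "double_pos"):
        if not 0 <= row[col] <= dapi:
            raise InvalidInputError(f"{col} count outside [0, dapi]")
    if row["double_pos"] > min(row["cfos"], row["marker"]):
        raise InvalidInputError("double_pos exceeds min(cfos, marker)")


def cfos_chance(counts) -> float | pd.Series:
    """Chance colocalization fraction (c-Fos/DAPI) x (marker/DAPI).

    Accepts a mapping with keys dapi/cfos/marker/double_pos or a
    DataFrame (returns a per-row Series).
    """
    if isinstance(counts, pd.DataFrame):
        return counts.apply(cfos_chance, axis=1)
    _validate_counts(counts)
    d = counts["dapi"]
    return (counts["cfos"] / d) * (counts["marker"] / d)


def overlap_vs_chance(counts) -> float | pd.Series:
    """Observed double-positive fraction divided by the chance level.

    1 indicates independence of the two labels; values > 1 indicate
    above-chance colocalization. NaN when chance is 0 (report as
    undefined).
    """
    if isinstance(counts, pd.DataFrame):
        return counts.apply(overlap_vs_chance, axis=1)
    _validate_counts(counts)
    chance = cfos_chance(counts)
    if chance == 0:
        return float("nan")
    return (counts["double_pos"] / counts["dapi"]) / chance


def chance_table(counts: pd.DataFrame, average_slices: bool = True) -> pd.DataFrame:
    """Per-subject (and subfield) chance and observed/chance ratio table.

    When multiple slices per subject/subfield are present, counts are
    averaged across slices before the ratio is computed.
    """
    df = counts.copy()
    missing = [c for c in _COUNT_COLS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"count table lacks columns: {missing}")
    keys = [c for c in ("subject", "group", "subfield") if c in df.columns]
    if average_slices and keys:
        df = df.groupby(keys, as_index=False)[list(_COUNT_COLS)].mean()
    df["chance"] = cfos_chance(df)
    df["observed"] = df["double_pos"] / df["dapi"]
    df["ratio_vs_chance"] = overlap_vs_chance(df)
    return df


def region_correlation_matrix(
    table: pd.DataFrame, group: str | None = None
) -> pd.DataFrame:
    """Pairwise Pearson r across subjects for every region pair.

    ``table`` is subjects x regions of c-Fos density (an optional
    ``group`` column selects one group). Returns a long table with
    columns region_a, region_b, r, p (two-sided); pairs involving a
    zero-variance region get NaN and a 'degenerate' status.
    """
    df = table
    if group is not None:
        if "group" not in df.columns:
            raise InvalidInputError("table has no 'group' column")
        df = df[df["group"] == group]
    regions = [c for c in df.columns if c not in ("subject", "group")]
    if len(df) < 3:
        raise InvalidInputError("need at least 3 subjects per group")
    if len(regions) < 2:
        raise InvalidInputError("need at least 2 regions")
    rows = []
    for a, b in combinations(regions, 2):
        x = df[a].to_numpy(dtype=float)
        y = df[b].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append((a, b, np.nan, np.nan, "degenerate"))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((a, b, float(r), float(p), "ok"))
    return pd.DataFrame(rows, columns=["region_a", "region_b", "r", "p", "status"])


@dataclass
class CorrelationComparison:
    region_a: str
    region_b: str
    r_group_a: float
    r_group_b: float
    sig_a: bool
    sig_b: bool
    status: str  # gained | lost | unchanged


def correlation_gain_loss(
    corr_a: pd.DataFrame, corr_b: pd.DataFrame, alpha: float = 0.05
) -> list[CorrelationComparison]:
    """Classify region pairs by significance change between two groups.

    'gained' = significant only in group B, 'lost' = significant only in
    group A, else 'unchanged'. Pairs with an undefined correlation in
    either group are skipped (status column in the inputs).
    """
    key = ["region_a", "region_b"]
    a = corr_a.set_index(key)
    b = corr_b.set_index(key)
    if set(a.index) != set(b.index):
        raise InvalidInputError("the two groups cover different region pairs")
    out = []
    for idx in a.index:
        ra, rb = a.loc[idx], b.loc[idx]
        if ra["status"] != "ok" or rb["status"] != "ok":
            continue
        sig_a = ra["p"] < alpha
        sig_b = rb["p"] < alpha
        if sig_b and not sig_a:
            status = "gained"
        elif sig_a and not sig_b:
            status = "lost"
        else:
            status = "unchanged"
        out.append(
            CorrelationComparison(
                idx[0], idx[1], float(ra["r"]), float(rb["r"]), bool(sig_a), bool(sig_b), status
            )
        )
    return out
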