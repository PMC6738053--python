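"""Patient-level cohort modelling.

Endpoints follow the usual endometrial-carcinoma conventions: DSS
(disease-specific survival; event = death from disease, death from other
causes censors at the death date), DFS (disease-free survival; event = any
recurrence), and DDFS (distant disease-free survival; event = distant
recurrence, with distant defined to include para-aortic nodal and
distant-organ disease). Local/regional recurrences censor DDFS at last
follow-up by default (configurable to censor at the recurrence date).
Missing LVSI is recoded to negative before analysis, since unreported LVSI
in a pathology report usually means none was seen.

Biomarker groups combine the slide readouts: CAIX-positive (fCAIX > 1%)
with MVD above the cohort median defines the double-positive group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GROUP_LABELS = ("CAIX-", "CAIX+/MVD-low", "CAIX+/MVD-high")


@dataclass(frozen=True)
class BiomarkerGroup:
    """Three-level biomarker label plus the binary double-positive view."""

    label: str
    binary_positive: bool  # CAIX+ AND high MVD vs rest

    def __post_init__(self) -> None:
        if self.label not in GROUP_LABELS:
            raise ValueError(f"label must be one of {GROUP_LABELS}")
        if self.binary_positive != (self.label == "CAIX+/MVD-high"):
            raise ValueError("binary view must equal (CAIX+ AND high MVD)")


def assign_group(caix_positive: bool, mvd_high: bool) -> BiomarkerGroup:
    """Combine the two dichotomised readouts into the biomarker group."""
    if caix_positive and mvd_high:
        return BiomarkerGroup("CAIX+/MVD-high", True)
    if caix_positive:
        return BiomarkerGroup("CAIX+/MVD-low", False)
    return BiomarkerGroup("CAIX-", False)


def add_groups(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add ``biomarker_group`` (3-level) and ``group_binary`` columns."""
    out = cohort.copy()
    groups = [
        assign_group(bool(c), bool(m))
        for c, m in zip(out["caix_positive"], out["mvd_high"])
    ]
    out["biomarker_group"] = [g.label for g in groups]
    out["group_binary"] = [g.binary_positive for g in groups]
    return out


def recode_lvsi(cohort: pd.DataFrame) -> pd.DataFrame:
    """Recode missing LVSI to negative; idempotent, yes/no unchanged."""
    out = cohort.copy()
    out["lvsi"] = out["lvsi"].replace({"missing": "no"})
    return out


def derive_endpoints(
    cohort: pd.DataFrame, ddfs_censor_at_recurrence: bool = False
) -> pd.DataFrame:
    """Attach DSS / DFS / DDFS time and event columns.

    * DSS: event iff death from disease, at ``death_months``; death from any
      other cause censors at the death date; otherwise censored at last
      follow-up.
    * DFS: event iff any recurrence, at ``recurrence_months``; otherwise
      censored at follow-up (death before recurrence censors at death).
    * DDFS: event iff distant recurrence; a non-distant recurrence censors
      at last follow-up, or at the recurrence date when
      ``ddfs_censor_at_recurrence`` is set.
    """
    required = {"followup_months", "recurrence", "death"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort lacks required columns: {sorted(missing)}")
    if cohort["followup_months"].isna().any():
        bad = cohort.index[cohort["followup_months"].isna()].tolist()
        raise ValueError(f"missing follow-up for records {bad[:5]}")
    out = cohort.copy()
    fu = out["followup_months"].to_numpy(dtype=float)
    death = out["death"].to_numpy()
    death_t = out.get("death_months", pd.Series(np.nan, index=out.index)).to_numpy(dtype=float)
    rec = out["recurrence"].to_numpy()
    rec_t = out.get("recurrence_months", pd.Series(np.nan, index=out.index)).to_numpy(dtype=float)

    dss_event = (death == "disease").astype(int)
    dss_time = np.where(np.isin(death, ["disease", "other_cause"]) & ~np.isnan(death_t), death_t, fu)

    any_rec = rec != "none"
    dfs_event = any_rec.astype(int)
    dfs_time = np.where(any_rec & ~np.isnan(rec_t), rec_t, fu)

    distant = rec == "distant"
    ddfs_event = distant.astype(int)
    if ddfs_censor_at_recurrence:
        ddfs_time = np.where(any_rec & ~np.isnan(rec_t), rec_t, fu)
    else:
        ddfs_time = np.where(distant & ~np.isnan(rec_t), rec_t, fu)

    out["dss_time"], out["dss_event"] = np.maximum(dss_time, 1e-6), dss_event
    out["dfs_time"], out["dfs_event"] = np.maximum(dfs_time, 1e-6), dfs_event
    out["ddfs_time"], out["ddfs_event"] = np.maximum(ddfs_time, 1e-6), ddfs_event
    return out


def _round_half_up(x: float, decimals: int = 1) -> float:
    factor = 10**decimals
    return float(np.floor(x * factor + 0.5) / factor)


def crosstab(
    cohort: pd.DataFrame,
    row_var: str,
    col_var: str = "group",
    percentages: str = "within-column",
) -> pd.DataFrame:
    """Contingency table with counts and percentages in "n (%)" style.

    Percentages are within-column by default (each column sums to 100%) and
    rounded half-up to one decimal. Returns a DataFrame whose cells are
    strings ``"n (p)"``; the raw counts are available via ``counts_table``.
    """
    counts = counts_table(cohort, row_var, col_var)
    if percentages == "within-column":
        denom = counts.sum(axis=0)
    elif percentages == "within-row":
        denom = counts.sum(axis=1)
    else:
        raise ValueError("percentages must be 'within-column' or 'within-row'")
    out = counts.astype(object).copy()
    for r in counts.index:
        for c in counts.columns:
            d = denom[c] if percentages == "within-column" else denom[r]
            pct = _round_half_up(100.0 * counts.loc[r, c] / d) if d else float("nan")
            out.loc[r, c] = f"{counts.loc[r, c]} ({pct})"
    return out


def counts_table(cohort: pd.DataFrame, row_var: str, col_var: str = "group") -> pd.DataFrame:
    """Raw contingency counts for two categorical variables."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    for v in (row_var, col_var):
        if v not in cohort.columns:
            raise KeyError(f"unknown variable {v!r}")
    return pd.crosstab(cohort[row_var], cohort[col_var])


def cell_percentage(
    cohort: pd.DataFrame, row_var: str, row_level: str, col_var: str = "group",
    col_level: str | None = None,
) -> float:
    """Within-column percentage of one cell, rounded half-up to one decimal.

    With ``col_level=None`` the percentage is over the whole cohort.
    """
    if col_level is None:
        n = int((cohort[row_var] == row_level).sum())
        return _round_half_up(100.0 * n / len(cohort))
    counts = counts_table(cohort, row_var, col_var)
    return _round_half_up(
        100.0 * counts.loc[row_level, col_level] / counts[col_level].sum()
    )
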