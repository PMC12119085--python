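"""Behavioural SDT summaries from canonical trial tables.

Turns per-trial response tables into per-subject, per-condition hit and
false-alarm rates, criterion and sensitivity estimates, per-level
response distributions for rating data, and paired group effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .sdt import (
    Correction,
    RatePair,
    criterion_c_from_rates,
    dprime_from_rates,
    hedges_g_paired,
)

__all__ = [
    "REQUIRED_COLUMNS",
    "BehavioralSummary",
    "load_trial_table",
    "rates",
    "pas_level_rates",
    "sdt_summary",
    "simple_sensitivity",
]

REQUIRED_COLUMNS = ("subject", "condition", "stimulus", "response")
_CONDITIONS = ("liberal", "conservative")
_STIMULI = ("target", "no_target")


def _response_range(mode: str) -> tuple[int, int]:
    if mode == "yes_no":
        return 0, 1
    if mode == "pas":
        return 0, 3
    raise ValueError(f"unknown mode {mode!r}")


def validate_trial_table(table: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Schema validation with row/column-naming errors."""
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"trial table is missing required column {col!r}")
    for col, allowed in (("condition", _CONDITIONS), ("stimulus", _STIMULI)):
        bad = ~table[col].isin(allowed)
        if bad.any():
            row = int(table.index[bad][0])
            raise ValueError(
                f"column {col!r}, row {row}: value {table[col].loc[row]!r} "
                f"not in {allowed}"
            )
    lo, hi = _response_range(mode)
    resp = pd.to_numeric(table["response"], errors="coerce")
    bad = resp.isna() | (resp < lo) | (resp > hi) | (resp != resp.round())
    if bad.any():
        row = int(table.index[bad][0])
        raise ValueError(
            f"column 'response', row {row}: value {table['response'].loc[row]!r} "
            f"outside the {mode} range {lo}..{hi}"
        )
    out = table.copy()
    out["response"] = resp.astype(int)
    missing = (
        out.groupby("subject")["condition"].nunique().loc[lambda s: s < 2]
    )
    if len(missing):
        import warnings

        warnings.warn(
            f"subjects missing a condition: {list(missing.index)}", stacklevel=2
        )
    return out


def load_trial_table(path, mode: Literal["yes_no", "pas"]) -> pd.DataFrame:
    """Load and schema-validate a canonical CSV trial table."""
    table = pd.read_csv(path)
    return validate_trial_table(table, mode)


def rates(table: pd.DataFrame, mode: Literal["yes_no", "pas"]) -> pd.DataFrame:
    """Per subject x condition hit/false-alarm rates.

    A 'present' response is any response > 0; for PAS data this
    collapses levels 1-3 ('type I' reading of the scale).  Returns one
    row per subject x condition with counts and rates.
    """
    table = validate_trial_table(table, mode)
    rows = []
    for (subj, cond), grp in table.groupby(["subject", "condition"], sort=True):
        tgt = grp[grp["stimulus"] == "target"]
        ntg = grp[grp["stimulus"] == "no_target"]
        n_signal, n_noise = len(tgt), len(ntg)
        hits = int((tgt["response"] > 0).sum())
        fas = int((ntg["response"] > 0).sum())
        rows.append(
            {
                "subject": subj,
                "condition": cond,
                "n_signal": n_signal,
                "n_noise": n_noise,
                "hits": hits,
                "false_alarms": fas,
                "hit_rate": hits / n_signal if n_signal else np.nan,
                "fa_rate": fas / n_noise if n_noise else np.nan,
            }
        )
    return pd.DataFrame(rows)


def pas_level_rates(table: pd.DataFrame) -> pd.DataFrame:
    """P(response = k | stimulus class) per subject x condition x level.

    Levels sum to 1 within each stimulus class; the collapsed present
    rate equals ``1 - P(level 0)`` exactly.
    """
    table = validate_trial_table(table, "pas")
    rows = []
    for (subj, cond, stim), grp in table.groupby(
        ["subject", "condition", "stimulus"], sort=True
    ):
        n = len(grp)
        counts = grp["response"].value_counts()
        for level in range(4):
            rows.append(
                {
                    "subject": subj,
                    "condition": cond,
                    "stimulus": stim,
                    "pas_level": level,
                    "n_trials": n,
                    "proportion": counts.get(level, 0) / n if n else np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class BehavioralSummary:
    """Per-subject SDT estimates with group aggregates and effect sizes."""

    per_subject: pd.DataFrame  # subject, condition, H, FA, c, dprime
    group: pd.DataFrame  # condition-level means and SDs
    effect_sizes: dict  # paired Hedges g for c and d' (conservative - liberal)
    correction: str
    aggregation: str


def sdt_summary(
    rate_table: pd.DataFrame,
    correction: Correction = "loglinear",
    aggregation: Literal["mean", "pooled"] = "mean",
    effect_variant: Literal["classic_diff", "average_sd"] = "classic_diff",
    compute_effect_sizes: bool = True,
) -> BehavioralSummary:
    """SDT criterion/sensitivity summary from a rate table.

    ``aggregation='mean'`` (default) averages per-subject estimates;
    ``'pooled'`` additionally reports estimates from rates pooled over
    subjects.  Effect sizes are paired Hedges g of the conservative
    minus liberal difference and need at least two subjects with both
    conditions.
    """
    recs = []
    for _, row in rate_table.iterrows():
        rp = RatePair(
            hit_rate=row["hit_rate"],
            fa_rate=row["fa_rate"],
            n_signal=int(row["n_signal"]),
            n_noise=int(row["n_noise"]),
        )
        recs.append(
            {
                "subject": row["subject"],
                "condition": row["condition"],
                "hit_rate": row["hit_rate"],
                "fa_rate": row["fa_rate"],
                "c": criterion_c_from_rates(rp, correction),
                "dprime": dprime_from_rates(rp, correction),
                "h_minus_fa": row["hit_rate"] - row["fa_rate"],
            }
        )
    per_subject = pd.DataFrame(recs)

    group_rows = []
    for cond, grp in per_subject.groupby("condition", sort=True):
        entry = {
            "condition": cond,
            "n_subjects": len(grp),
            "c_mean": grp["c"].mean(),
            "c_sd": grp["c"].std(ddof=1),
            "dprime_mean": grp["dprime"].mean(),
            "dprime_sd": grp["dprime"].std(ddof=1),
            "hit_rate_mean": grp["hit_rate"].mean(),
            "fa_rate_mean": grp["fa_rate"].mean(),
        }
        if aggregation == "pooled":
            sub = rate_table[rate_table["condition"] == cond]
            n_s, n_n = int(sub["n_signal"].sum()), int(sub["n_noise"].sum())
            rp = RatePair(
                hit_rate=float(sub["hits"].sum()) / n_s,
                fa_rate=float(sub["false_alarms"].sum()) / n_n,
                n_signal=n_s,
                n_noise=n_n,
            )
            entry["c_pooled"] = criterion_c_from_rates(rp, correction)
            entry["dprime_pooled"] = dprime_from_rates(rp, correction)
        group_rows.append(entry)
    group = pd.DataFrame(group_rows)

    effect_sizes: dict = {}
    if compute_effect_sizes:
        wide = per_subject.pivot(index="subject", columns="condition")
        both = wide.dropna()
        if len(both) < 2:
            raise ValueError(
                "paired effect sizes need at least two subjects with both "
                f"conditions (got {len(both)})"
            )
        for measure in ("c", "dprime"):
            effect_sizes[measure] = hedges_g_paired(
                both[(measure, "conservative")].to_numpy(),
                both[(measure, "liberal")].to_numpy(),
                variant=effect_variant,
            )
    return BehavioralSummary(
        per_subject=per_subject,
        group=group,
        effect_sizes=effect_sizes,
        correction=correction,
        aggregation=aggregation,
    )


def simple_sensitivity(rate_table: pd.DataFrame) -> pd.DataFrame:
    """Hit rate minus false-alarm rate per subject and condition."""
    out = rate_table[["subject", "condition"]].copy()
    out["h_minus_fa"] = rate_table["hit_rate"] - rate_table["fa_rate"]
    return out
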