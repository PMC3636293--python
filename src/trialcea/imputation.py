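"""Single imputation of longitudinal missingness (intention to treat).

Costs, EQ-5D items and addiction scores are imputed from a
participant's own adjacent measurements: an interior gap whose two
neighboring waves are both observed is replaced by their mean;
otherwise the last observation is carried forward (LOCF), and gaps
before the first observation take the next observation carried backward
(NOCB).  EQ-5D item levels are rounded back to {1,2,3}, with .5 means
rounding toward the more severe level (conservative on utility).
Missing smoking-abstinence status is never interpolated: the negative
scenario counts anyone lost to follow-up as still smoking.

A series with no observation at all cannot be imputed; the record is
flagged and excluded from the analyses that need the field, mirroring
per-outcome availability denominators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NOT_ABSTINENT = 1
ABSTINENT = 2


class AllMissingError(ValueError):
    """A series with no observed value cannot be imputed."""


@dataclass
class ImputationLog:
    """Per-cell record of what was imputed and how."""

    entries: list = field(default_factory=list)

    def add(self, participant, fieldname, wave, method):
        self.entries.append(
            {"participant": participant, "field": fieldname,
             "wave": int(wave), "method": method}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, columns=["participant", "field", "wave", "method"]
        )


def _round_eq5d(x: float) -> float:
    """Round to the nearest level in {1,2,3}; .5 rounds up (more severe)."""
    return float(min(3, max(1, math.floor(x + 0.5))))


def impute_series(series, kind: str = "continuous", log=None,
                  participant=None, fieldname=None):
    """Impute one participant's 4-wave series.

    Rules, applied against the originally observed mask:

    * interior gap with both adjacent waves observed -> mean of the two
      neighbors;
    * otherwise LOCF from the nearest earlier observation;
    * leading gaps (nothing observed earlier) -> NOCB.

    ``kind='eq5d_item'`` rounds results to the nearest level in {1,2,3}
    (.5 toward the more severe level).  Raises :class:`AllMissingError`
    when nothing is observed.
    """
    if kind not in ("continuous", "eq5d_item"):
        raise ValueError(f"unknown series kind {kind!r}")
    values = [None if (v is None or (isinstance(v, float) and math.isnan(v)))
              else float(v) for v in series]
    observed = [v is not None for v in values]
    if not any(observed):
        raise AllMissingError("series has no observed value")
    n = len(values)
    out = list(values)
    for i in range(n):
        if observed[i]:
            continue
        prev = next((j for j in range(i - 1, -1, -1) if observed[j]), None)
        nxt = next((j for j in range(i + 1, n) if observed[j]), None)
        if i - 1 >= 0 and observed[i - 1] and i + 1 < n and observed[i + 1]:
            val, method = (values[i - 1] + values[i + 1]) / 2.0, "neighbor_mean"
        elif prev is not None:
            val, method = values[prev], "locf"
        else:
            val, method = values[nxt], "nocb"
        if kind == "eq5d_item":
            val = _round_eq5d(val)
        out[i] = val
        if log is not None:
            log.add(participant, fieldname, i, method)
    return out


def impute_abstinence(status, log=None, participant=None):
    """Negative scenario: every missing status becomes 1 (not abstinent)."""
    out = []
    for i, v in enumerate(status):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            out.append(float(NOT_ABSTINENT))
            if log is not None:
                log.add(participant, "smoking_status", i, "negative_scenario")
        else:
            out.append(float(v))
    return out


def impute_table(table: pd.DataFrame, cost_categories=None):
    """Apply the imputation rules to a long-format participant table.

    Returns ``(imputed_table, availability, log)``.  ``availability`` is
    a per-participant frame of booleans (``costs``, ``qaly``, ``ftnd``);
    a participant whose series for some cost category or EQ-5D item is
    entirely missing stays missing there and is counted unavailable for
    the corresponding analysis, but abstinence is always complete (the
    negative scenario is always applicable).
    """
    from trialcea.synthetic_trial import COST_CATEGORIES, EQ5D_COLUMNS

    if cost_categories is None:
        cost_categories = [c for c in COST_CATEGORIES if c in table.columns]
    eq5d_cols = [c for c in EQ5D_COLUMNS if c in table.columns]

    out = table.sort_values(["id", "wave"]).reset_index(drop=True)
    float_cols = [c for c in (list(cost_categories) + list(eq5d_cols)
                              + ["ftnd", "smoking_status"])
                  if c in out.columns]
    out[float_cols] = out[float_cols].astype(float)
    log = ImputationLog()
    avail_rows = []
    for pid, g in out.groupby("id", sort=True):
        idx = g.index
        avail = {"id": pid, "costs": True, "qaly": True, "ftnd": True}
        for col, kind, key in (
            [(c, "continuous", "costs") for c in cost_categories]
            + [(c, "eq5d_item", "qaly") for c in eq5d_cols]
            + ([("ftnd", "continuous", "ftnd")] if "ftnd" in out.columns else [])
        ):
            try:
                out.loc[idx, col] = impute_series(
                    g[col].tolist(), kind=kind, log=log,
                    participant=pid, fieldname=col,
                )
            except AllMissingError:
                avail[key] = False
        if "smoking_status" in out.columns:
            out.loc[idx, "smoking_status"] = impute_abstinence(
                g["smoking_status"].tolist(), log=log, participant=pid
            )
        avail_rows.append(avail)
    availability = pd.DataFrame(avail_rows).set_index("id")
    return out, availability, log
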