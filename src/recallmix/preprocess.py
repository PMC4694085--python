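"""Trial exclusion and conditionalization rules.

Recognition decision times are filtered in two fixed stages: (1) drop
responses faster than a 100 ms floor (anticipations), then (2) log-transform
the remainder and drop trials deviating by more than ``sd_mult`` standard
deviations from the pooled ("overall") mean.  Boundaries are kept literal:
exactly 100 ms and exactly +/- 3 SD are retained.  With zero spread in the
log RTs no SD exclusions are made.

Study-phase probe RTs are bounded to ``[100, 2000]`` ms (the response window
closes at 2 s).  Color-judgment analyses are conditionalized on claimed
recognition, and "know" responses are analyzed on the subset of trials
without a "remember" response so the two response types can be treated
independently.

Exclusions are marked (boolean columns on the returned table), not deleted,
so reports can audit counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FilterReport", "filter_recognition_trials", "filter_probe_rts",
    "conditionalize_color_trials", "independent_know_subset",
]


@dataclass
class FilterReport:
    """Counts and retained trials from one filtering pass."""

    n_input: int
    n_rt_floor_excluded: int
    n_sd_excluded: int
    retained: pd.DataFrame
    flagged: pd.DataFrame  # all input rows with exclusion-flag columns

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def prop_rt_floor_excluded(self) -> float:
        return self.n_rt_floor_excluded / self.n_input if self.n_input else 0.0

    @property
    def prop_sd_excluded(self) -> float:
        return self.n_sd_excluded / self.n_input if self.n_input else 0.0

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_rt_floor_excluded": self.n_rt_floor_excluded,
            "n_sd_excluded": self.n_sd_excluded,
            "n_retained": self.n_retained,
            "prop_rt_floor_excluded": self.prop_rt_floor_excluded,
            "prop_sd_excluded": self.prop_sd_excluded,
        }


def filter_recognition_trials(records: pd.DataFrame, rt_floor_ms: float = 100.0,
                              sd_mult: float = 3.0,
                              per_participant: bool = False) -> FilterReport:
    """Two-stage recognition-RT filter (floor, then +/- ``sd_mult`` SD on log RT).

    ``per_participant=True`` switches the SD trim to participant-wise
    means/SDs; the default pools across participants and conditions.
    """
    df = records.copy()
    rt = df["recognition_rt_ms"].to_numpy(dtype=float)
    if not np.isfinite(rt).any():
        raise ValueError("no recognition response times in input")
    floor_excl = np.isfinite(rt) & (rt < rt_floor_ms)
    remaining = np.isfinite(rt) & ~floor_excl
    if not remaining.any():
        raise ValueError("all trials excluded by the recognition-RT filter")

    sd_excl = np.zeros(len(df), dtype=bool)
    log_rt = np.full(len(df), np.nan)
    log_rt[remaining] = np.log(rt[remaining])
    if per_participant:
        part = df["participant"].to_numpy()
        for pid in np.unique(part[remaining]):
            m = remaining & (part == pid)
            sd_excl |= _sd_outliers(log_rt, m, sd_mult)
    else:
        sd_excl = _sd_outliers(log_rt, remaining, sd_mult)

    keep = remaining & ~sd_excl
    if not keep.any():
        raise ValueError("all trials excluded by the recognition-RT filter")
    flagged = df.assign(excluded_rt_floor=floor_excl, excluded_rt_sd=sd_excl)
    return FilterReport(
        n_input=int(np.isfinite(rt).sum()),
        n_rt_floor_excluded=int(floor_excl.sum()),
        n_sd_excluded=int(sd_excl.sum()),
        retained=df.loc[keep],
        flagged=flagged,
    )


def _sd_outliers(log_rt, mask, sd_mult):
    vals = log_rt[mask]
    mu, sd = vals.mean(), vals.std(ddof=0)
    out = np.zeros_like(mask)
    if sd == 0:  # all identical: nothing is an outlier
        return out
    dev = np.abs(log_rt - mu)
    out[mask] = dev[mask] > sd_mult * sd
    return out


def filter_probe_rts(records: pd.DataFrame, floor_ms: float = 100.0,
                     ceiling_ms: float = 2000.0) -> FilterReport:
    """Keep probe trials with ``floor_ms <= RT <= ceiling_ms`` (inclusive)."""
    df = records[records["probe_present"].astype(bool)].copy()
    rt = df["probe_rt_ms"].to_numpy(dtype=float)
    if len(df) == 0:
        raise ValueError("no probe trials in input")
    out = np.isfinite(rt) & ((rt < floor_ms) | (rt > ceiling_ms))
    keep = np.isfinite(rt) & ~out
    flagged = df.assign(excluded_rt_floor=out, excluded_rt_sd=False)
    return FilterReport(
        n_input=int(np.isfinite(rt).sum()),
        n_rt_floor_excluded=int(out.sum()),
        n_sd_excluded=0,
        retained=df.loc[keep],
        flagged=flagged,
    )


def conditionalize_color_trials(records: pd.DataFrame, on=("old",)) -> pd.DataFrame:
    """Color-judgment trials whose recognition response is in ``on``.

    Foils are always excluded (they were never studied, so they carry no
    color error); an empty result raises a warning, not an error.
    """
    on = {on} if isinstance(on, str) else set(on)
    df = records[(records["phase"] == "test")
                 & (records["item_type"] != "foil")
                 & records["signed_error"].notna()]
    if on:
        df = df[df["recognition_response"].isin(on)]
    if len(df) == 0:
        import warnings
        warnings.warn("conditionalization retained no color trials",
                      RuntimeWarning, stacklevel=2)
    return df


def independent_know_subset(records: pd.DataFrame) -> pd.DataFrame:
    """Drop "remember" trials so "know" can be modelled as know vs no.

    This treats familiarity independently of recollection: the "know" rate
    is computed over the trials on which a "remember" response was not made.
    """
    df = records[records["recognition_response"] != "remember"]
    if len(df) == 0:
        import warnings
        warnings.warn("all trials received a 'remember' response",
                      RuntimeWarning, stacklevel=2)
    return df
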