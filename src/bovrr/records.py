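"""Analysis-ready cow-weight (CW) and weight-weaned (WtW) trait records.

A WtW record is created for every breeding exposure: the weaning weight of
the calf from that breeding (zero if none weaned) plus the sum of all
previous calves' weaning weights, so WtW is non-decreasing within cow.  CW
records carry the cow's weight at each pregnancy diagnosis.  Record ages
are intended calving ages in exact 0.5-year steps starting at 2.  Fixed
effects use an opportunity-group code (birth season x maximum single-breed
composition bin) and, for WtW, a cumulative calf-sex covariate
(males weaned minus females weaned).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["cow_id", "trait", "value_kg", "age_yr", "opp_group", "cum_calf_sex"]

#: Maximum single-breed composition bins; the extra "<50" bin covers
#: advanced-generation crosses below any one-breed majority.
COMPOSITION_BINS = ["<50", "50-<75", "75-<87.5", ">=87.5"]


def composition_bin(max_fraction: float) -> str:
    if max_fraction >= 0.875:
        return ">=87.5"
    if max_fraction >= 0.75:
        return "75-<87.5"
    if max_fraction >= 0.50:
        return "50-<75"
    return "<50"


def assign_opportunity_group(composition: dict[str, float], birth_season: int) -> str:
    """Concatenate birth season and maximum-composition bin."""
    total = sum(composition.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"composition sums to {total}")
    max_frac = max(composition.values())
    return f"s{birth_season}:{composition_bin(max_frac)}"


def _check_events(events: pd.DataFrame) -> None:
    for cow, sub in events.groupby("cow_id", sort=False):
        ages = sub["age"].to_numpy()
        if np.any(np.diff(ages) <= 0):
            raise ValueError(f"ages not strictly increasing for cow {cow}")
        if np.any(sub["weaning_weight"].to_numpy() < 0):
            raise ValueError(f"negative weaning weight for cow {cow}")


def cumulative_calf_sex(events: pd.DataFrame) -> pd.Series:
    """Running (males weaned - females weaned) per exposure, per cow."""
    weaned = events["weaned"].to_numpy() if "weaned" in events else events["weaning_weight"].to_numpy() > 0
    sex = events["calf_sex"].to_numpy()
    if np.any(weaned & ~np.isin(sex, ["M", "F"])):
        raise ValueError("weaned calf with unknown sex")
    step = np.where(weaned, np.where(sex == "M", 1, -1), 0)
    out = (
        pd.Series(step, index=events.index)
        .groupby(events["cow_id"], sort=False)
        .cumsum()
    )
    return out.astype(int)


def build_wtw_records(
    events: pd.DataFrame,
    compositions: dict[str, dict[str, float]] | None = None,
    birth_seasons: dict[str, int] | None = None,
) -> pd.DataFrame:
    """One WtW record per breeding exposure (cumulative weaning weight)."""
    if events.empty:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    _check_events(events)
    if events.duplicated(["cow_id", "age"]).any():
        raise ValueError("duplicate (cow, age) exposure")
    wtw = events.groupby("cow_id", sort=False)["weaning_weight"].cumsum()
    ccs = cumulative_calf_sex(events)
    out = pd.DataFrame(
        {
            "cow_id": events["cow_id"],
            "trait": "WtW",
            "value_kg": wtw,
            "age_yr": events["age"],
            "opp_group": _groups_for(events["cow_id"], compositions, birth_seasons),
            "cum_calf_sex": ccs,
        }
    )
    return out.reset_index(drop=True)


def build_cw_records(
    events: pd.DataFrame,
    compositions: dict[str, dict[str, float]] | None = None,
    birth_seasons: dict[str, int] | None = None,
) -> pd.DataFrame:
    """One CW record per pregnancy test with a recorded weight.

    Exposures with a missing weight are skipped (with a logged count): CW
    is an observation, not a derived trait.
    """
    if events.empty:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    _check_events(events)
    have = events["cow_weight"].notna()
    n_missing = int((~have).sum())
    if n_missing:
        logger.info("skipping %d pregnancy tests without a cow weight", n_missing)
    sub = events.loc[have]
    out = pd.DataFrame(
        {
            "cow_id": sub["cow_id"],
            "trait": "CW",
            "value_kg": sub["cow_weight"],
            "age_yr": sub["age"],
            "opp_group": _groups_for(sub["cow_id"], compositions, birth_seasons),
            "cum_calf_sex": 0,
        }
    )
    return out.reset_index(drop=True)


def _groups_for(cow_ids: pd.Series, compositions, birth_seasons) -> pd.Series:
    if compositions is None or birth_seasons is None:
        return pd.Series("s0:<50", index=cow_ids.index)
    cache: dict[str, str] = {}

    def code(cow: str) -> str:
        if cow not in cache:
            cache[cow] = assign_opportunity_group(
                compositions[cow], birth_seasons[cow]
            )
        return cache[cow]

    return cow_ids.map(code)


def build_records(
    events: pd.DataFrame,
    compositions: dict[str, dict[str, float]] | None = None,
    birth_seasons: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Both traits, concatenated."""
    return pd.concat(
        [
            build_cw_records(events, compositions, birth_seasons),
            build_wtw_records(events, compositions, birth_seasons),
        ],
        ignore_index=True,
    )
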