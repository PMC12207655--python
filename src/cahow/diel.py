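"""Diel activity budgets and their dependence on sun angle.

Per-second behaviour labels are aggregated into hourly activity budgets —
the proportion of each clock hour spent in each of the six at-sea behaviour
classes — and each behaviour's proportion is regressed on the solar
elevation at the colony via a zero-inflated beta model
(:mod:`cahow.zib`).  Sun angle is evaluated at the colony because solar
elevation varies negligibly across the foraging range at these scales.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .solar import sun_angle
from .taxonomy import AT_SEA_CLASSES, BehaviourClass, Mode
from .zib import ZeroInflatedBeta, fit_zib

__all__ = ["hourly_budget", "fit_zib", "leave_one_bird_out"]


def hourly_budget(
    labels: pd.Series,
    colony_lonlat=(-64.6667, 32.3333),
    bird: str = "bird",
    min_at_sea: float = 0.5,
    renormalise: bool = True,
) -> pd.DataFrame:
    """Hourly proportions of the six at-sea behaviours, with sun angle.

    Parameters
    ----------
    labels : pandas.Series
        Per-second behaviour labels (class value strings or
        :class:`BehaviourClass`), indexed by UTC timestamp.
    min_at_sea : float
        Keep an hour only if at least this fraction of its labelled seconds
        is at sea (burrow time excluded).
    renormalise : bool
        Compute proportions over at-sea seconds (True) rather than over the
        whole hour (False).

    Returns a DataFrame with one row per retained clock hour: ``bird``,
    ``hour_start``, one proportion column per at-sea class (summing to 1
    when renormalised), ``sun_angle_rad`` at the hour midpoint at the
    colony.
    """
    if len(labels) == 0:
        raise ValueError("empty label sequence")
    vals = pd.Series(
        [BehaviourClass(v).value for v in labels.to_numpy()], index=labels.index
    )
    mode = pd.Series(
        [BehaviourClass(v).mode for v in vals.to_numpy()], index=labels.index
    )
    at_sea = mode != Mode.BURROW
    rows = []
    lon, lat = colony_lonlat
    for hour_start, grp in vals.groupby(vals.index.floor("h")):
        sea = at_sea.loc[grp.index]
        frac_sea = sea.mean()
        if frac_sea < min_at_sea:
            continue
        denom = int(sea.sum()) if renormalise else len(grp)
        counts = grp[sea].value_counts()
        row = {"bird": bird, "hour_start": hour_start}
        for cls in AT_SEA_CLASSES:
            row[cls.value] = counts.get(cls.value, 0) / denom
        row["sun_angle_rad"] = sun_angle(
            lat, lon, hour_start + pd.Timedelta(minutes=30)
        )
        rows.append(row)
    return pd.DataFrame(rows)


def leave_one_bird_out(
    budgets: pd.DataFrame, behaviour: str, **fit_kwargs
) -> pd.DataFrame:
    """Refit the sun-angle model excluding each bird in turn.

    Returns one row per excluded bird with the refitted slopes and
    intercepts, plus the maximum absolute deviation of each coefficient from
    the all-birds fit — a robustness check against any single track
    dominating the diel result.
    """
    birds = budgets["bird"].unique()
    if len(birds) < 3:
        raise ValueError("need at least 3 birds for a leave-one-out analysis")
    full = fit_zib(
        budgets["sun_angle_rad"].to_numpy(),
        budgets[behaviour].to_numpy(),
        **fit_kwargs,
    )
    rows = []
    for b in birds:
        sub = budgets[budgets["bird"] != b]
        fit = fit_zib(
            sub["sun_angle_rad"].to_numpy(), sub[behaviour].to_numpy(), **fit_kwargs
        )
        rows.append(
            {
                "excluded_bird": b,
                "zero_intercept": fit.coef_["zero"][0],
                "zero_slope": fit.coef_["zero"][1],
                "cond_intercept": fit.coef_["cond"][0],
                "cond_slope": fit.coef_["cond"][1],
                "phi": fit.coef_["phi"],
                "converged": fit.converged_,
            }
        )
    out = pd.DataFrame(rows)
    for col, (sub, i) in {
        "zero_intercept": ("zero", 0),
        "zero_slope": ("zero", 1),
        "cond_intercept": ("cond", 0),
        "cond_slope": ("cond", 1),
    }.items():
        out[f"dev_{col}"] = np.abs(out[col] - full.coef_[sub][i])
    return out
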