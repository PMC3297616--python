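"""Month-scale retention: logistic model of any-detection per month since tagging.

Each internally tagged shark contributes up to twelve 30-day blocks counted
from its tagging date; the response is whether it was detected anywhere in
the array during the block.  Restricting to the first year makes the two
battery lives (12 vs 18 months) comparable; externally tagged sharks are
excluded because tethered transmitters shed on a different timescale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .filtering import DailyPresence, array_operational_dates
from .glm import ModelFit, fit_glm

TAGLIFE = {"V9": "12mo", "V16": "18mo"}


def build_monthly_records(presence: DailyPresence, tags: pd.DataFrame,
                          receivers: pd.DataFrame,
                          calendar_months: bool = False) -> pd.DataFrame:
    """Rows (shark_id, sharkmonth 1..12, detected 0/1, taglife).

    Month i is days [30(i-1), 30i) after the tag date (set
    ``calendar_months=True`` to align to calendar months instead; month 1 is
    then the tagging month).  Months during which the array was entirely
    down are dropped rather than scored absent.
    """
    tags = tags[tags["attachment"] == "internal"].copy()
    tags["shark_id"] = tags["shark_id"].astype(str)
    array_dates = array_operational_dates(receivers)
    anyw = presence.anywhere
    rows = []
    for _, shark in tags.iterrows():
        sid = shark["shark_id"]
        tag_date = pd.to_datetime(shark["tag_date"])
        det_dates = set(anyw.loc[anyw["shark_id"] == sid, "date"])
        for m in range(1, 13):
            if calendar_months:
                period = (tag_date + pd.DateOffset(months=m - 1)).to_period("M")
                days = pd.date_range(period.start_time, period.end_time, freq="D")
            else:
                start = tag_date + pd.Timedelta(days=30 * (m - 1))
                days = pd.date_range(start, start + pd.Timedelta(days=29), freq="D")
            operational = days.isin(array_dates)
            if not operational.any():
                continue
            detected = int(any(d in det_dates for d in days[operational]))
            rows.append({"shark_id": sid, "sharkmonth": m, "detected": detected,
                         "taglife": TAGLIFE[shark["tag_type"]]})
    return pd.DataFrame(rows, columns=["shark_id", "sharkmonth", "detected", "taglife"])


def fit_month_model(records: pd.DataFrame) -> ModelFit:
    """Logistic fit of detected ~ sharkmonth + taglife with sequential deviance."""
    return fit_glm(records, "detected", ["sharkmonth", "taglife"], family="binomial_logit")


def predict_retention_curve(fit: ModelFit) -> pd.DataFrame:
    """Per-month detection probability with a +/- 2 SE band, by battery life.

    The band is the inverse-logit of the linear predictor +/- 2 delta-method
    standard errors, so it always contains the point estimate and stays in
    (0, 1).
    """
    taglives = ["12mo", "18mo"] if "taglife" in fit.terms else [None]
    frames = []
    for tl in taglives:
        grid = pd.DataFrame({"sharkmonth": np.arange(1, 13)})
        if tl is not None:
            grid["taglife"] = tl
        # rebuild the full dummy column set even for a single level
        X_cols = fit.params.index
        from .glm import design_matrix
        X, _ = design_matrix(grid, [t for t in fit.terms])
        X = X.reindex(columns=X_cols, fill_value=0.0)
        if tl == "18mo" and "taglife=18mo" in X_cols:
            X["taglife=18mo"] = 1.0
        eta = X.to_numpy(float) @ fit.params.to_numpy(float)
        se = np.sqrt(np.einsum("ij,jk,ik->i", X.to_numpy(float),
                               fit.cov_params.to_numpy(float), X.to_numpy(float)))
        expit = lambda z: 1.0 / (1.0 + np.exp(-z))
        frames.append(pd.DataFrame({
            "taglife": tl or "all", "sharkmonth": grid["sharkmonth"],
            "p": expit(eta), "lower": expit(eta - 2 * se), "upper": expit(eta + 2 * se),
        }))
    return pd.concat(frames, ignore_index=True)
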