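"""The delta-lognormal shark x receiver detection analysis.

Zero-heavy detection data are modeled in two parts: a logit-link binomial
model for whether a shark was *ever* detected at a receiver, and a gaussian
model of the log fraction of operational days with a detection given any.
Their product -- probability of any detection times the bias-corrected
lognormal mean -- is the expected fraction of days with a detection for each
shark x receiver pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .filtering import DailyPresence
from .glm import ModelFit
from .io import haversine_km, operational_days

logger = logging.getLogger(__name__)

DEFAULT_DISTANCE_FLOOR_KM = 0.05


def shark_type(sex: str, maturity: str) -> str:
    """Four-level life-stage x sex factor: adult_F, adult_M, juv_F, juv_M."""
    stage = "adult" if maturity == "adult" else "juv"
    return f"{stage}_{sex}"


def build_summary(presence: DailyPresence, tags: pd.DataFrame,
                  receivers: pd.DataFrame,
                  distance_floor_km: float = DEFAULT_DISTANCE_FLOOR_KM) -> pd.DataFrame:
    """One row per shark x receiver pair: the delta-lognormal design matrix.

    Columns: shark_id, receiver_id, detected (0/1 ever during the tag-active
    window), n_days (detected days at that receiver), days (receiver
    operational days while the tag was active), frac_days (n_days / days,
    NaN when never detected), ldist (natural log of km from tagging point to
    receiver, floored at ``distance_floor_km``), habitat, shark_type.

    Pairs whose receiver was never operational while the tag was active are
    dropped: there was no chance of a detection to model.
    """
    if distance_floor_km <= 0:
        raise ValueError("distance_floor_km must be positive (log of zero distance)")
    tags = tags.copy()
    tags["shark_id"] = tags["shark_id"].astype(str)
    stations = receivers.drop_duplicates("receiver_id").set_index("receiver_id")
    counts = (presence.per_receiver.groupby(["shark_id", "receiver_id"])
              .size().rename("n_days"))
    rows = []
    for _, shark in tags.iterrows():
        sid = shark["shark_id"]
        tag_date = pd.to_datetime(shark["tag_date"])
        expiry = tag_date + pd.Timedelta(days=int(shark["battery_days"]))
        stype = shark_type(shark["sex"], shark["maturity"])
        for rid, st in stations.iterrows():
            days = operational_days(receivers, rid, tag_date, expiry)
            if days == 0:
                continue
            dist = haversine_km(shark["tag_lat"], shark["tag_lon"], st["lat"], st["lon"])
            n_days = int(counts.get((sid, str(rid)), 0))
            rows.append({
                "shark_id": sid, "receiver_id": str(rid),
                "detected": int(n_days > 0), "n_days": n_days, "days": days,
                "frac_days": (n_days / days) if n_days > 0 else np.nan,
                "ldist": float(np.log(max(dist, distance_floor_km))),
                "habitat": st["habitat"], "shark_type": stype,
            })
    df = pd.DataFrame(rows)
    if not df.empty:
        df["log_frac"] = np.log(df["frac_days"])
        # ocean reef is the reference habitat in every model
        df["habitat"] = pd.Categorical(
            df["habitat"], categories=[h for h in
                                       ("ocean_reef", "deep_lagoon", "shallow_lagoon")
                                       if h in set(df["habitat"])])
    return df


def combine_delta(binomial_fit: ModelFit, lognormal_fit: ModelFit,
                  rows: pd.DataFrame, bias_correct: bool = True) -> np.ndarray:
    """Expected fraction of days with a detection per shark x receiver.

    E[frac] = pi_hat * exp(mu_hat + sigma^2/2), the delta-lognormal mean with
    the standard lognormal bias correction (disable with
    ``bias_correct=False`` for sensitivity analysis).  Values are clipped
    into [0, 1]; the number of clipped rows is logged.
    """
    pi = binomial_fit.predict(rows)
    mu = lognormal_fit.predict(rows)
    corr = lognormal_fit.scale / 2.0 if bias_correct else 0.0
    expected = pi * np.exp(mu + corr)
    n_clip = int(np.sum(expected > 1.0))
    if n_clip:
        logger.info("clipped %d expected fraction(s) above 1", n_clip)
    return np.clip(expected, 0.0, 1.0)


@dataclass
class ConfusionMatrix:
    """Predicted x observed presence counts for the shark x receiver rows."""

    true_absent: int     # predicted absent, observed absent
    false_absent: int    # predicted absent, observed present
    false_present: int   # predicted present, observed absent
    true_present: int    # predicted present, observed present

    @property
    def total(self) -> int:
        return self.true_absent + self.false_absent + self.false_present + self.true_present

    @property
    def accuracy(self) -> float:
        return (self.true_absent + self.true_present) / self.total

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.true_absent, self.false_absent],
             [self.false_present, self.true_present]],
            index=pd.Index(["absent", "present"], name="predicted"),
            columns=pd.Index(["absent", "present"], name="observed"))


def predict_presence(binomial_fit: ModelFit, rows: pd.DataFrame,
                     threshold: float = 0.5) -> ConfusionMatrix:
    """Round fitted detection probabilities to 0/1 and cross-tabulate.

    Ties at the threshold round to present.
    """
    pi = binomial_fit.predict(rows)
    pred = (pi >= threshold).astype(int)
    obs = rows["detected"].to_numpy(int)
    return ConfusionMatrix(
        true_absent=int(np.sum((pred == 0) & (obs == 0))),
        false_absent=int(np.sum((pred == 0) & (obs == 1))),
        false_present=int(np.sum((pred == 1) & (obs == 0))),
        true_present=int(np.sum((pred == 1) & (obs == 1))),
    )
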