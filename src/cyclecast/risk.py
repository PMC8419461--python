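"""Low/medium/high risk stratification of hourly seizure likelihoods.

Two thresholds split likelihoods into three states. They are chosen by an
exhaustive rank-based search over all achievable partitions, preferring
pairs under which (C1) more time is spent in low than medium than high
risk and (C2) more seizures occur in high than medium than low risk;
among those (or among all pairs when none satisfies both) the pair
maximizing (time fraction in low risk) x (number of seizures in high
risk) wins — the practical trade-off between a quiet forecast and caught
seizures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

RISK_STATES = ("low", "medium", "high")


class RiskError(ValueError):
    pass


@dataclass
class RiskThresholds:
    """Likelihood cut-ins for the medium and high risk states."""

    medium: float
    high: float
    satisfied_c1_c2: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.medium < self.high < 1.0:
            raise RiskError(
                f"thresholds must satisfy 0 < medium < high < 1, got "
                f"({self.medium}, {self.high})"
            )


def classify(likelihood, thresholds: RiskThresholds) -> np.ndarray | str:
    """Risk state per likelihood: high iff l >= high, medium iff
    medium <= l < high, else low (closed lower bounds)."""
    lik = np.asarray(likelihood, dtype=float)
    out = np.where(
        lik >= thresholds.high,
        "high",
        np.where(lik >= thresholds.medium, "medium", "low"),
    )
    if np.isscalar(likelihood) or out.ndim == 0:
        return str(out)
    return out


def optimize_thresholds(
    likelihoods, seizure_counts
) -> RiskThresholds:
    """Exhaustive threshold search over achievable likelihood partitions.

    Parameters
    ----------
    likelihoods : array of per-hour likelihoods (the training window).
    seizure_counts : array of seizure *events* per corresponding hour
        (events, not hours, are what C2 and the product objective count).

    Candidate thresholds are the midpoints between consecutive distinct
    sorted likelihood values; every achievable 3-way partition is thus
    considered. Ties in the product objective break toward larger
    low-risk time, then the lower high threshold.
    """
    lik = np.asarray(likelihoods, dtype=float)
    sz = np.asarray(seizure_counts, dtype=np.int64)
    if lik.size == 0 or lik.size != sz.size:
        raise RiskError("likelihoods and seizure_counts must align, non-empty")
    if sz.sum() < 1:
        raise RiskError("need >= 1 seizure in the training window")

    order = np.argsort(lik, kind="stable")
    lik_s, sz_s = lik[order], sz[order]
    values, starts = np.unique(lik_s, return_index=True)
    K = values.size
    n = lik.size
    S = int(sz.sum())
    # cumulative hours / seizure events at or below each distinct value
    bounds = np.append(starts, n)
    c = bounds[1:]  # hours <= values[k]
    s = np.add.reduceat(sz_s, starts) if K > 0 else np.array([])
    s = np.cumsum(s)

    if K == 1:
        warnings.warn(
            "all likelihoods identical: degenerate thresholds straddle the "
            "single value",
            stacklevel=2,
        )
        v = float(values[0])
        med = np.clip(v - 1e-6, 1e-9, 1 - 3e-9)
        return RiskThresholds(
            medium=float(med), high=float(min(max(v + 1e-6, med + 1e-9), 1 - 1e-9)),
            satisfied_c1_c2=False,
        )
    mids = (values[:-1] + values[1:]) / 2.0  # K-1 candidate thresholds
    if K == 2:
        warnings.warn(
            "only two distinct likelihoods: medium state unachievable",
            stacklevel=2,
        )
        return RiskThresholds(
            medium=float(mids[0]),
            high=float((mids[0] + values[1]) / 2.0),
            satisfied_c1_c2=False,
        )

    # pair (i < j) of candidate indices: medium = mids[i], high = mids[j];
    # low state = values[..i], medium = values[i+1..j], high = values[j+1..]
    best = None  # (obj, t_low, -mid_high, i, j)

    def consider(i: int, j: int, store: list) -> None:
        t_low = c[i]
        obj = (t_low / n) * (S - s[j])
        key = (obj, t_low, -mids[j])
        if store[0] is None or key > store[0][0]:
            store[0] = (key, i, j)

    feasible: list = [None]
    for j in range(1, K - 1):
        # C1a: c[i] > c[j] - c[i]  <=>  2c[i] > c[j]
        lo1 = int(np.searchsorted(2 * c, c[j], side="right"))
        # C1b: c[j] - c[i] > n - c[j]  <=>  c[i] < 2c[j] - n
        hi1 = int(np.searchsorted(c, 2 * c[j] - n, side="left")) - 1
        # C2a: s[j] - s[i] > s[i]  <=>  2s[i] < s[j]
        hi2 = int(np.searchsorted(2 * s, s[j], side="left")) - 1
        # C2b: S - s[j] > s[j] - s[i]  <=>  s[i] > 2s[j] - S
        lo2 = int(np.searchsorted(s, 2 * s[j] - S, side="right"))
        lo = max(lo1, lo2, 0)
        hi = min(hi1, hi2, j - 1)
        if lo <= hi:
            # objective and the first tie-break both grow with c[i]: take hi
            consider(hi, j, feasible)

    if feasible[0] is not None:
        _, i, j = feasible[0]
        return RiskThresholds(
            medium=float(mids[i]), high=float(mids[j]), satisfied_c1_c2=True
        )

    # fallback: maximize the product over all pairs (C3 x C4)
    fallback: list = [None]
    for j in range(1, K - 1):
        consider(j - 1, j, fallback)
    _, i, j = fallback[0]
    return RiskThresholds(
        medium=float(mids[i]), high=float(mids[j]), satisfied_c1_c2=False
    )
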