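"""Red/white thrombus labels, cutoff classification, and ROC analysis.

The six-stage visual grade maps to a binary label (1-3 white, 4-6 red). ROC
analysis ranks a continuous parameter against the binary reference: the AUC
is the Mann-Whitney U statistic normalised by the number of red/white pairs
(ties counted 0.5), the optimal cutoff maximises the Youden index
J = sensitivity + specificity - 1 over midpoints between adjacent distinct
observed values, and the 95% CI comes from DeLong's covariance estimate.

Orientation is chosen automatically so the AUC is >= 0.5: when red cases
tend to have *lower* values (as for attenuation in shadowed thrombi) the
recorded direction is "below" and values strictly below the cutoff are
called red. Boundary values equal to a cutoff are classified white (strict
inequality).
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import AnalysisError, ConfigurationError

__all__ = [
    "ThrombusLabel",
    "RocResult",
    "tas_to_binary",
    "classify_by_cutoff",
    "roc_curve",
    "roc_table",
    "default_cutoffs",
]


class ThrombusLabel(str, enum.Enum):
    WHITE = "white"
    RED = "red"


@dataclass(frozen=True)
class RocResult:
    """Discrimination summary for one continuous parameter."""

    auc: float
    auc_ci_low: float
    auc_ci_high: float
    cutoff: float | None
    sensitivity: float | None
    specificity: float | None
    direction: str  # 'below': value < cutoff => red; 'above': value > cutoff => red
    n_red: int
    n_white: int

    @property
    def youden(self) -> float | None:
        if self.sensitivity is None or self.specificity is None:
            return None
        return self.sensitivity + self.specificity - 1.0

    def to_dict(self) -> dict:
        d = {
            "auc": self.auc,
            "auc_ci_low": self.auc_ci_low,
            "auc_ci_high": self.auc_ci_high,
            "cutoff": self.cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "youden": self.youden,
            "direction": self.direction,
            "n_red": self.n_red,
            "n_white": self.n_white,
        }
        return d


def tas_to_binary(tas: int) -> ThrombusLabel:
    """Map a six-stage grade to the binary label: 1-3 white, 4-6 red."""
    tas = int(tas)
    if tas not in range(1, 7):
        raise AnalysisError(f"tas must be in 1..6, got {tas}")
    return ThrombusLabel.WHITE if tas <= 3 else ThrombusLabel.RED


def default_cutoffs() -> dict:
    """Load the shipped versioned cutoff registry."""
    payload = resources.files("octhrombus.data").joinpath("default_cutoffs.json").read_text()
    return json.loads(payload)


def classify_by_cutoff(
    value: float,
    parameter_name: str | None = None,
    cutoff: float | None = None,
    direction: str | None = None,
) -> ThrombusLabel:
    """Classify one value as red/white against a cutoff.

    Either pass an explicit ``cutoff`` + ``direction``, or a
    ``parameter_name`` present in the shipped registry. Strict inequality:
    a value exactly at the cutoff is white.
    """
    if cutoff is None or direction is None:
        if parameter_name is None:
            raise ConfigurationError("need parameter_name or explicit cutoff+direction")
        registry = default_cutoffs()["cutoffs"]
        if parameter_name not in registry:
            raise ConfigurationError(
                f"unknown parameter {parameter_name!r}; registry has {sorted(registry)}"
            )
        entry = registry[parameter_name]
        cutoff = entry["cutoff"] if cutoff is None else cutoff
        direction = entry["direction"] if direction is None else direction
    if direction not in ("below", "above"):
        raise ConfigurationError(f"direction must be 'below' or 'above', got {direction!r}")
    if not math.isfinite(cutoff):
        raise ConfigurationError("cutoff must be finite")
    value = float(value)
    is_red = value < cutoff if direction == "below" else value > cutoff
    return ThrombusLabel.RED if is_red else ThrombusLabel.WHITE


def _to_binary(labels: Sequence, positive) -> np.ndarray:
    pos = positive.value if isinstance(positive, ThrombusLabel) else str(positive)

    def one(l) -> bool:
        if isinstance(l, ThrombusLabel):
            return l.value == pos
        return str(l) == pos

    return np.array([one(l) for l in labels], dtype=bool)


def _auc_mann_whitney(values: np.ndarray, y: np.ndarray) -> float:
    """AUC as the normalised rank-sum statistic (ties count 0.5)."""
    m = int(y.sum())
    n = y.size - m
    ranks = rankdata(values)  # midranks
    u = ranks[y].sum() - m * (m + 1) / 2.0
    return float(u / (m * n))


def _delong_ci(values: np.ndarray, y: np.ndarray, auc: float, alpha: float = 0.05):
    """DeLong 95% CI from placement-value variances."""
    pos = values[y]
    neg = values[~y]
    m, n = pos.size, neg.size
    if m < 2 or n < 2:
        return math.nan, math.nan
    all_ranks = rankdata(np.concatenate([pos, neg]))
    v10 = (all_ranks[:m] - rankdata(pos)) / n  # P(X > Y) component per positive
    v01 = 1.0 - (all_ranks[m:] - rankdata(neg)) / m
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    z = 1.959963984540054  # Phi^-1(0.975)
    half = z * math.sqrt(var)
    return max(0.0, auc - half), min(1.0, auc + half)


def _candidate_cutoffs(values: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct values, plus one threshold below
    the minimum and one above the maximum."""
    uniq = np.unique(values)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    lo = uniq[0] - 1.0
    hi = uniq[-1] + 1.0
    return np.concatenate([[lo], mids, [hi]])


def roc_curve(
    values: Sequence[float],
    labels: Sequence,
    positive=ThrombusLabel.RED,
    orient: str = "auto",
) -> RocResult:
    """Full ROC analysis of one parameter against binary labels.

    Parameters
    ----------
    values, labels
        Paired finite observations and their red/white labels.
    positive
        Label treated as the positive (red) class.
    orient
        ``"auto"`` (default) negates values if needed so AUC >= 0.5 and
        records the direction; ``"above"`` fixes higher-value-is-red,
        ``"below"`` fixes lower-value-is-red.

    Raises
    ------
    AnalysisError
        If only one class is present or values are not finite.
    """
    v = np.asarray(values, dtype=np.float64)
    if not np.isfinite(v).all():
        raise AnalysisError("values must be finite")
    y = _to_binary(labels, positive)
    if v.size != y.size:
        raise AnalysisError("values and labels lengths differ")
    m = int(y.sum())
    n = y.size - m
    if m == 0 or n == 0:
        raise AnalysisError("both classes must be present")

    auc_above = _auc_mann_whitney(v, y)
    if orient == "auto":
        direction = "below" if auc_above < 0.5 else "above"
    elif orient in ("above", "below"):
        direction = orient
    else:
        raise AnalysisError(f"unknown orient {orient!r}")

    w = -v if direction == "below" else v  # on w scale, red is high
    auc = _auc_mann_whitney(w, y)

    if np.unique(v).size == 1:
        # no discrimination possible: AUC 0.5, cutoff missing
        return RocResult(
            auc=0.5,
            auc_ci_low=math.nan,
            auc_ci_high=math.nan,
            cutoff=None,
            sensitivity=None,
            specificity=None,
            direction=direction,
            n_red=m,
            n_white=n,
        )

    best = None  # (J, specificity, -cutoff) maximised
    for c in _candidate_cutoffs(w):
        pred_red = w > c
        sens = float((pred_red & y).sum() / m)
        spec = float((~pred_red & ~y).sum() / n)
        j = sens + spec - 1.0
        key = (j, spec, -c)
        if best is None or key > best[0]:
            best = (key, c, sens, spec)
    _, c_best, sens, spec = best
    cutoff = -c_best if direction == "below" else c_best

    ci_low, ci_high = _delong_ci(w, y, auc)
    return RocResult(
        auc=auc,
        auc_ci_low=ci_low,
        auc_ci_high=ci_high,
        cutoff=float(cutoff),
        sensitivity=sens,
        specificity=spec,
        direction=direction,
        n_red=m,
        n_white=n,
    )


def roc_table(
    values: Sequence[float],
    labels: Sequence,
    positive=ThrombusLabel.RED,
    orient: str = "auto",
) -> pd.DataFrame:
    """Per-threshold sensitivity/specificity/J table on the original value
    scale (rows = number of distinct values + 1)."""
    result = roc_curve(values, labels, positive=positive, orient=orient)
    v = np.asarray(values, dtype=np.float64)
    y = _to_binary(labels, positive)
    m = int(y.sum())
    n = y.size - m
    w = -v if result.direction == "below" else v
    rows = []
    for c in _candidate_cutoffs(w):
        pred_red = w > c
        sens = float((pred_red & y).sum() / m)
        spec = float((~pred_red & ~y).sum() / n)
        threshold = -c if result.direction == "below" else c
        rows.append(
            {
                "threshold": float(threshold),
                "sensitivity": sens,
                "specificity": spec,
                "youden": sens + spec - 1.0,
            }
        )
    rows.sort(key=lambda r: r["threshold"])
    return pd.DataFrame(rows, columns=["threshold", "sensitivity", "specificity", "youden"])
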