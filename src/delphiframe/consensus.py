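"""Delphi consensus measurement on Likert criterion ratings.

Consensus for a criterion is read off the interquartile distance
Delta = Q3 - Q1 of its non-missing ratings:

* ``full``        Delta = 0
* ``fair``        0 < Delta <= 1
* ``sufficient``  1 < Delta <= 2
* ``none``        Delta > 2

The printed band edges both claim Delta = 1 for fair and sufficient; the
boundary is assigned to the stronger class (half-open bands), and the
cut Delta > 2 — which the banding leaves unnamed — is labelled ``none``.
The quantile convention matters at n ~ 25 and is therefore explicit:
``linear`` (interpolation between order statistics at p*(n-1), the default),
``nearest`` (closest order statistic) or ``spss`` (weighted average at
(n+1)*p, the SPSS/Minitab convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import InsufficientDataError, ValidationError

QUANTILE_METHODS = {
    "linear": "linear",
    "nearest": "nearest",
    "spss": "weibull",
}

LABELS = ("full", "fair", "sufficient", "none")


@dataclass(frozen=True)
class ConsensusRecord:
    criterion: str
    n: int
    median: float
    q1: float
    q3: float
    delta: float
    label: str


def label_for_delta(delta: float) -> str:
    if delta < 0:
        raise ValueError(f"negative interquartile distance {delta}")
    if delta == 0:
        return "full"
    if delta <= 1:
        return "fair"
    if delta <= 2:
        return "sufficient"
    return "none"


def consensus(
    responses: pd.DataFrame,
    criterion: str,
    quantile_method: str = "linear",
) -> ConsensusRecord:
    """Quartiles, interquartile distance and consensus label for one criterion.

    Missing ("Do not know") replies are excluded before computing
    quantiles; at least 2 non-missing ratings are required.
    """
    if quantile_method not in QUANTILE_METHODS:
        raise ValidationError(
            f"unknown quantile method {quantile_method!r}; "
            f"choose from {sorted(QUANTILE_METHODS)}"
        )
    if criterion not in responses.columns:
        raise ValidationError(f"unknown criterion {criterion!r}")
    values = responses[criterion].dropna().to_numpy(dtype=float)
    if values.size < 2:
        raise InsufficientDataError(
            f"criterion {criterion!r} has {values.size} non-missing responses "
            "(need >= 2)",
            criterion=criterion,
        )
    method = QUANTILE_METHODS[quantile_method]
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75], method=method)
    delta = float(q3) - float(q1)
    return ConsensusRecord(
        criterion=criterion,
        n=int(values.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        delta=delta,
        label=label_for_delta(delta),
    )


def inclusion_rule(
    n_proposing: int, n_respondents: int, threshold: float = 0.30
) -> tuple[str, float]:
    """New-criterion rule: include when proposed by >= ``threshold`` of
    respondents.  Returns (decision, support percentage to one decimal)."""
    if n_respondents < 1:
        raise ValueError("n_respondents must be >= 1")
    if not 0 <= n_proposing <= n_respondents:
        raise ValueError(
            f"n_proposing ({n_proposing}) must lie in [0, {n_respondents}]"
        )
    fraction = n_proposing / n_respondents
    support_pct = round(100.0 * fraction, 1)
    decision = "include" if fraction >= threshold else "reject"
    return decision, support_pct


def should_iterate(records) -> bool:
    """Stopping rule: a further Delphi round is needed iff any criterion
    failed to reach at least sufficient consensus."""
    records = list(records)
    if not records:
        raise ValueError("no consensus records supplied")
    return any(r.label == "none" for r in records)


class DelphiConsensus(BaseEstimator):
    """Per-criterion Delphi consensus analysis of a response table.

    Parameters
    ----------
    quantile_method : {"linear", "nearest", "spss"}
        Quantile convention for Q1/median/Q3.

    Attributes
    ----------
    records_ : list of ConsensusRecord
    table_ : pandas.DataFrame
        One row per criterion: n, median, q1, q3, delta, label.
    needs_iteration_ : bool
        Whether any criterion failed to reach consensus.
    """

    def __init__(self, quantile_method: str = "linear"):
        self.quantile_method = quantile_method

    def fit(self, X: pd.DataFrame, y=None):
        self.records_ = [
            consensus(X, c, quantile_method=self.quantile_method)
            for c in X.columns
        ]
        self.table_ = pd.DataFrame(
            [
                {
                    "criterion": r.criterion,
                    "n": r.n,
                    "median": r.median,
                    "q1": r.q1,
                    "q3": r.q3,
                    "delta": r.delta,
                    "label": r.label,
                }
                for r in self.records_
            ]
        ).set_index("criterion")
        self.needs_iteration_ = should_iterate(self.records_)
        return self
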