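"""Relative Index ranking and Goodman-Kruskal gamma screening.

The Relative Index of a criterion is the weighted response frequency

    RI = sum_i w_i * f_i / N,   w_i = i / 5,  i = 1..5,

with f_i the count of ratings at level i and N the number of non-missing
ratings; RI ranges from 0.2 (all "Very low") to 1.0 (all "Very high").
Criteria are sorted by decreasing RI and split into importance subclasses
(Fundamental / Important / Relevant) at explicit cutpoints.

Ordinal association between two criteria is Goodman-Kruskal gamma,

    gamma = (SOP - IOP) / (SOP + IOP),

counting same-order (concordant) and inverse-order (discordant) pairs over
all C(n, 2) observation pairs; ties on either variable count in neither.
Significance uses the normal approximation
z = gamma * sqrt((SOP + IOP) / (n * (1 - gamma^2))), two-sided, with an
exact/Monte-Carlo permutation alternative for small samples.  A pair of
criteria is a "strong" correlation when |gamma| > 0.5 and p < 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .codebook import CriterionHierarchy
from .errors import InsufficientDataError

WEIGHTS = {i: i / 5.0 for i in range(1, 6)}
DEFAULT_CUTPOINTS = (0.8, 0.7)
SUBCLASSES = ("Fundamental", "Important", "Relevant")


@dataclass(frozen=True)
class RankedCriterion:
    criterion: str
    ri: float
    n: int
    frequencies: tuple[int, int, int, int, int]
    rank: int | None = None
    subclass: str | None = None


@dataclass(frozen=True)
class GammaResult:
    pair: tuple[str, str]
    sop: int
    iop: int
    gamma: float | None
    p_value: float | None
    strong: bool
    n: int

    @property
    def undefined(self) -> bool:
        return self.gamma is None


def relative_index(responses: pd.DataFrame, criterion: str) -> RankedCriterion:
    """RI with its audit trail (per-level frequencies and N)."""
    values = responses[criterion].dropna().to_numpy(dtype=float)
    if values.size == 0:
        raise InsufficientDataError(
            f"criterion {criterion!r} has no non-missing responses",
            criterion=criterion,
        )
    freqs = tuple(int(np.sum(values == i)) for i in range(1, 6))
    n = int(values.size)
    ri = sum(WEIGHTS[i] * f for i, f in zip(range(1, 6), freqs)) / n
    return RankedCriterion(criterion=criterion, ri=float(ri), n=n, frequencies=freqs)


def rank_and_classify(
    ri_values: dict[str, float] | pd.Series,
    cutpoints: tuple[float, float] = DEFAULT_CUTPOINTS,
) -> pd.DataFrame:
    """Sort criteria by decreasing RI and attach importance subclasses.

    Ties are broken by criterion id (ascending, stable).  ``cutpoints``
    (c1, c2) with c1 > c2 split Fundamental (RI >= c1), Important
    (c2 <= RI < c1) and Relevant (RI < c2).
    """
    c1, c2 = cutpoints
    if not c1 > c2:
        raise ValueError(f"cutpoints must satisfy c1 > c2, got {cutpoints}")
    series = pd.Series(dict(ri_values), dtype=float)
    if series.empty:
        raise ValueError("no RI values to rank")
    order = sorted(series.index, key=lambda c: (-series[c], c))
    rows = []
    for rank, crit in enumerate(order, start=1):
        ri = float(series[crit])
        if ri >= c1:
            subclass = "Fundamental"
        elif ri >= c2:
            subclass = "Important"
        else:
            subclass = "Relevant"
        rows.append(
            {"criterion": crit, "ri": ri, "rank": rank, "subclass": subclass}
        )
    return pd.DataFrame(rows).set_index("criterion")


def _pair_counts(x: np.ndarray, y: np.ndarray) -> tuple[int, int]:
    """Concordant/discordant pair counts via sign outer products."""
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    prod = dx * dy
    upper = np.triu_indices(x.size, k=1)
    sop = int(np.sum(prod[upper] == 1))
    iop = int(np.sum(prod[upper] == -1))
    return sop, iop


def gamma(
    x,
    y,
    labels: tuple[str, str] = ("x", "y"),
    p_method: str = "normal",
    n_permutations: int = 10000,
    rng: np.random.Generator | None = None,
) -> GammaResult:
    """Goodman-Kruskal gamma for two paired ordinal vectors.

    Pairs with a missing value in either vector are dropped.  When every
    observation pair is tied (SOP + IOP = 0) the result is flagged
    undefined rather than raising.  ``p_method`` is ``"normal"`` (default)
    or ``"permutation"`` (exact over all n! orderings for n <= 8, else
    Monte-Carlo with ``n_permutations`` draws).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 2:
        raise InsufficientDataError("gamma needs >= 2 complete pairs")
    sop, iop = _pair_counts(x, y)
    if sop + iop == 0:
        return GammaResult(
            pair=labels, sop=sop, iop=iop, gamma=None, p_value=None,
            strong=False, n=n,
        )
    g = (sop - iop) / (sop + iop)
    if p_method == "normal":
        g_clamped = float(np.clip(g, -(1 - 1e-9), 1 - 1e-9))
        z = g_clamped * math.sqrt((sop + iop) / (n * (1.0 - g_clamped**2)))
        p = float(2.0 * stats.norm.sf(abs(z)))
    elif p_method == "permutation":
        p = _permutation_p(x, y, g, n_permutations, rng)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    strong = abs(g) > 0.5 and p < 0.05
    return GammaResult(
        pair=labels, sop=sop, iop=iop, gamma=float(g), p_value=p,
        strong=strong, n=n,
    )


def _permutation_p(x, y, observed, n_permutations, rng) -> float:
    """Permutation p-value for gamma: exhaustive for n <= 8, Monte-Carlo
    above (add-one correction)."""
    from itertools import permutations

    n = x.size

    def stat(perm_y):
        s, i = _pair_counts(x, perm_y)
        if s + i == 0:
            return 0.0
        return (s - i) / (s + i)

    target = abs(observed) - 1e-12
    if n <= 8:
        count = total = 0
        for perm in permutations(range(n)):
            total += 1
            if abs(stat(y[list(perm)])) >= target:
                count += 1
        return count / total
    rng = rng if rng is not None else np.random.default_rng(0)
    count = 0
    for _ in range(n_permutations):
        if abs(stat(rng.permutation(y))) >= target:
            count += 1
    return (count + 1) / (n_permutations + 1)


def domain_gamma_screen(
    responses: pd.DataFrame,
    codebook: CriterionHierarchy,
    p_method: str = "normal",
) -> list[GammaResult]:
    """Gamma for every within-domain criterion pair, pairwise-complete.

    Only pairs within the same domain are screened (association across
    domains is not part of the analysis); the ``strong`` flag encodes the
    reporting rule |gamma| > 0.5 and p < 0.05.
    """
    results = []
    for domain_id, _ in codebook.domains:
        items = [
            c.id for c in codebook.criteria_in(domain_id)
            if c.id in responses.columns
        ]
        for i, a in enumerate(items):
            for b in items[i + 1:]:
                results.append(
                    gamma(
                        responses[a], responses[b], labels=(a, b),
                        p_method=p_method,
                    )
                )
    return results


def gamma_table(results: list[GammaResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        sign = ""
        if r.gamma is not None and r.strong:
            sign = "+" if r.gamma > 0 else "-"
        rows.append(
            {
                "criterion_a": r.pair[0],
                "criterion_b": r.pair[1],
                "n": r.n,
                "sop": r.sop,
                "iop": r.iop,
                "gamma": np.nan if r.gamma is None else r.gamma,
                "p_value": np.nan if r.p_value is None else r.p_value,
                "strong": r.strong,
                "sign": sign,
            }
        )
    return pd.DataFrame(rows)


class RelativeIndexRanker(BaseEstimator):
    """RI ranking of a response table's criteria.

    Attributes
    ----------
    ri_ : pandas.Series of RI per criterion.
    ranking_ : pandas.DataFrame with ri, rank and subclass per criterion,
        sorted by decreasing RI.
    records_ : list of RankedCriterion with audit frequencies.
    """

    def __init__(self, cutpoints: tuple[float, float] = DEFAULT_CUTPOINTS):
        self.cutpoints = cutpoints

    def fit(self, X: pd.DataFrame, y=None):
        base = {c: relative_index(X, c) for c in X.columns}
        self.ri_ = pd.Series({c: r.ri for c, r in base.items()}, dtype=float)
        self.ranking_ = rank_and_classify(self.ri_, cutpoints=self.cutpoints)
        self.records_ = [
            RankedCriterion(
                criterion=c,
                ri=base[c].ri,
                n=base[c].n,
                frequencies=base[c].frequencies,
                rank=int(self.ranking_.loc[c, "rank"]),
                subclass=str(self.ranking_.loc[c, "subclass"]),
            )
            for c in X.columns
        ]
        return self


class GammaScreen(BaseEstimator):
    """Within-domain gamma correlation screen.

    Attributes
    ----------
    results_ : list of GammaResult.
    table_ : pandas.DataFrame with pair, SOP, IOP, gamma, p, strong, sign.
    """

    def __init__(self, codebook: CriterionHierarchy, p_method: str = "normal"):
        self.codebook = codebook
        self.p_method = p_method

    def fit(self, X: pd.DataFrame, y=None):
        self.results_ = domain_gamma_screen(
            X, self.codebook, p_method=self.p_method
        )
        self.table_ = gamma_table(self.results_)
        return self
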