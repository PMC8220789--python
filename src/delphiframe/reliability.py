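"""Ordinal reliability: polychoric correlation, ordinal alpha, alpha-drop.

Likert ratings are treated as discretisations of a latent bivariate normal.
The polychoric correlation rho is estimated in two steps: thresholds from the
inverse standard-normal of each variable's cumulative marginal proportions,
then a one-dimensional maximum-likelihood search for rho over (-1, 1) on the
contingency-table cell probabilities.  Internal consistency per domain is
the standardised Cronbach form applied to the polychoric matrix,

    alpha = k * r_bar / (1 + (k - 1) * r_bar),

with r_bar the mean off-diagonal polychoric correlation and k the number of
items.  This ordinal alpha avoids the attenuation that plagues Pearson-based
Cronbach alpha on ordered-categorical data.  Alpha-if-item-dropped recomputes
alpha on each (k-1)-item submatrix and flags items whose removal raises the
domain alpha by more than a margin — the diagnostic that exposes a
negatively-keyed or off-concept item.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .codebook import CriterionHierarchy
from .errors import DegenerateMarginalError, InsufficientDataError

RHO_BOUND = 1.0 - 1e-6
_CELL_FLOOR = 1e-12

ALPHA_BANDS = (
    (0.9, "Excellent"),
    (0.8, "Good"),
    (0.7, "Acceptable"),
    (0.6, "Questionable"),
)


@dataclass(frozen=True)
class PolychoricEstimate:
    rho: float
    tau_x: np.ndarray
    tau_y: np.ndarray
    loglik: float
    converged: bool
    n: int
    low_n_warning: bool = False


@dataclass
class DomainReliability:
    domain: str
    n_replies: int
    k: int
    matrix: pd.DataFrame
    r_bar: float
    alpha: float
    interpretation: str
    alpha_drop: pd.Series | None = None
    flagged_item: str | None = None


def _thresholds(counts: np.ndarray) -> np.ndarray:
    """Inverse-normal thresholds from marginal category counts."""
    cum = np.cumsum(counts) / counts.sum()
    return stats.norm.ppf(cum[:-1])


def _bvn_cdf_grid(tau_x: np.ndarray, tau_y: np.ndarray, rho: float) -> np.ndarray:
    """Bivariate standard-normal CDF on the full threshold grid, with the
    +/- infinity edges handled through the univariate CDF."""
    r = len(tau_x)
    c = len(tau_y)
    # grid[i, j] = P(X <= a_i, Y <= b_j) with a_0 = b_0 = -inf, a_last = +inf
    grid = np.zeros((r + 2, c + 2))
    grid[-1, -1] = 1.0
    phi_x = stats.norm.cdf(tau_x)
    phi_y = stats.norm.cdf(tau_y)
    grid[1:-1, -1] = phi_x
    grid[-1, 1:-1] = phi_y
    if r and c:
        pts = np.column_stack(
            [np.repeat(tau_x, c), np.tile(tau_y, r)]
        )
        mvn = stats.multivariate_normal(
            mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]], allow_singular=True
        )
        grid[1:-1, 1:-1] = np.atleast_1d(mvn.cdf(pts)).reshape(r, c)
    return grid


def _cell_probs(tau_x: np.ndarray, tau_y: np.ndarray, rho: float) -> np.ndarray:
    g = _bvn_cdf_grid(tau_x, tau_y, rho)
    p = g[1:, 1:] - g[:-1, 1:] - g[1:, :-1] + g[:-1, :-1]
    return np.clip(p, _CELL_FLOOR, None)


def polychoric(x, y) -> PolychoricEstimate:
    """Two-step polychoric correlation of two ordinal vectors.

    Pairs with a missing value in either variable are dropped.  Raises
    :class:`DegenerateMarginalError` if either variable is constant; fewer
    than 10 complete pairs sets ``low_n_warning`` on the result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (equal length)")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n == 0:
        raise InsufficientDataError("no complete pairs")
    cats_x, ix = np.unique(x, return_inverse=True)
    cats_y, iy = np.unique(y, return_inverse=True)
    if cats_x.size < 2 or cats_y.size < 2:
        raise DegenerateMarginalError(
            "a variable with a single observed category has no polychoric "
            "correlation"
        )
    table = np.zeros((cats_x.size, cats_y.size))
    np.add.at(table, (ix, iy), 1.0)
    tau_x = _thresholds(table.sum(axis=1))
    tau_y = _thresholds(table.sum(axis=0))

    def negloglik(rho: float) -> float:
        return -float(np.sum(table * np.log(_cell_probs(tau_x, tau_y, rho))))

    res = optimize.minimize_scalar(
        negloglik,
        bounds=(-RHO_BOUND, RHO_BOUND),
        method="bounded",
        options={"xatol": 1e-6},
    )
    rho = float(np.clip(res.x, -RHO_BOUND, RHO_BOUND))
    low_n = n < 10
    if low_n:
        warnings.warn(
            f"polychoric estimate from only {n} complete pairs", stacklevel=2
        )
    return PolychoricEstimate(
        rho=rho,
        tau_x=tau_x,
        tau_y=tau_y,
        loglik=-float(res.fun),
        converged=bool(res.success),
        n=n,
        low_n_warning=low_n,
    )


def polychoric_matrix(responses: pd.DataFrame) -> pd.DataFrame:
    """Symmetric unit-diagonal polychoric matrix over the table's columns.

    Rows with any missing cell are dropped first (listwise deletion), so
    every pairwise estimate uses the same complete-case panellists.
    """
    complete = responses.dropna(axis=0)
    cols = list(responses.columns)
    k = len(cols)
    mat = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            est = polychoric(complete[cols[i]], complete[cols[j]])
            mat[i, j] = mat[j, i] = est.rho
    return pd.DataFrame(mat, index=cols, columns=cols)


def ordinal_alpha(matrix) -> float:
    """Standardised Cronbach alpha from a correlation matrix."""
    m = np.asarray(matrix, dtype=float)
    k = m.shape[0]
    if m.ndim != 2 or m.shape[0] != m.shape[1] or k < 2:
        raise ValueError("need a square correlation matrix with k >= 2")
    off = m[~np.eye(k, dtype=bool)]
    r_bar = float(off.mean())
    denom = 1.0 + (k - 1) * r_bar
    if denom <= 0:
        raise ValueError(
            f"alpha undefined: mean inter-item correlation {r_bar:.3f} "
            f"<= -1/(k-1) for k={k}"
        )
    return k * r_bar / denom


def interpret_alpha(alpha: float) -> str:
    """Internal-consistency band for an alpha value.

    Excellent >= 0.9 > Good >= 0.8 > Acceptable >= 0.7 > Questionable
    >= 0.6 > Poor > 0.5 >= Unacceptable.
    """
    if not np.isfinite(alpha):
        raise ValueError("alpha must be finite")
    for cut, band in ALPHA_BANDS:
        if alpha >= cut:
            return band
    return "Poor" if alpha > 0.5 else "Unacceptable"


def alpha_drop(
    responses: pd.DataFrame,
    items: list[str] | None = None,
    margin: float = 0.05,
    matrix: pd.DataFrame | None = None,
) -> tuple[pd.Series, str | None]:
    """Alpha-if-item-dropped for a set of items (a domain's criteria).

    Returns the per-item drop alphas and the flagged item, if any: the item
    whose omission raises alpha the most, provided the rise exceeds
    ``margin`` over the full-set alpha.  Needs k >= 3 items.
    """
    if items is None:
        items = list(responses.columns)
    if len(items) < 3:
        raise ValueError(
            f"alpha-drop needs >= 3 items (got {len(items)}): dropping would "
            "leave a single item"
        )
    if matrix is None:
        matrix = polychoric_matrix(responses[items])
    full = ordinal_alpha(matrix.to_numpy())
    drops = {}
    for item in items:
        rest = [i for i in items if i != item]
        drops[item] = ordinal_alpha(matrix.loc[rest, rest].to_numpy())
    drops = pd.Series(drops, name="alpha_drop")
    best = drops.idxmax()
    flagged = best if drops[best] > full + margin else None
    return drops, flagged


class OrdinalReliability(BaseEstimator):
    """Per-domain internal-consistency analysis of a response table.

    Parameters
    ----------
    codebook : CriterionHierarchy
        Maps response columns to domains.
    drop_margin : float
        Minimum rise of alpha-if-dropped over the full-domain alpha before
        an item is flagged as degrading the scale.

    Attributes
    ----------
    domains_ : dict of domain id -> DomainReliability
    table_ : pandas.DataFrame mirroring the per-domain summary (replies,
        alpha, interpretation, flagged item).
    """

    def __init__(self, codebook: CriterionHierarchy, drop_margin: float = 0.05):
        self.codebook = codebook
        self.drop_margin = drop_margin

    def fit(self, X: pd.DataFrame, y=None):
        self.domains_ = {}
        rows = []
        for domain_id, domain_label in self.codebook.domains:
            items = [
                c.id for c in self.codebook.criteria_in(domain_id)
                if c.id in X.columns
            ]
            if len(items) < 2:
                continue
            sub = X[items].dropna(axis=0)
            matrix = polychoric_matrix(sub)
            alpha = ordinal_alpha(matrix.to_numpy())
            k = len(items)
            off = matrix.to_numpy()[~np.eye(k, dtype=bool)]
            result = DomainReliability(
                domain=domain_id,
                n_replies=int(sub.shape[0]),
                k=k,
                matrix=matrix,
                r_bar=float(off.mean()),
                alpha=float(alpha),
                interpretation=interpret_alpha(alpha),
            )
            if k >= 3:
                drops, flagged = alpha_drop(
                    sub, items, margin=self.drop_margin, matrix=matrix
                )
                result.alpha_drop = drops
                result.flagged_item = flagged
            self.domains_[domain_id] = result
            rows.append(
                {
                    "domain": domain_id,
                    "label": domain_label,
                    "n_replies": result.n_replies,
                    "k": k,
                    "alpha": result.alpha,
                    "interpretation": result.interpretation,
                    "flagged_item": result.flagged_item or "",
                }
            )
        self.table_ = pd.DataFrame(rows).set_index("domain")
        return self

    def reliability_exclusions_(self) -> list[str]:
        """Items to exclude: flagged drop items in domains whose full alpha
        sits below the Acceptable band (< 0.7)."""
        out = []
        for res in self.domains_.values():
            if res.alpha < 0.7 and res.flagged_item is not None:
                out.append(res.flagged_item)
        return out
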