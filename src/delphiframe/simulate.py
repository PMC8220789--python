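"""Synthetic panel responses and device performance matrices.

The raw expert-survey responses behind the published framework are not
deposited, so every downstream stage is exercised on simulated data with the
same statistical structure: a latent multivariate standard normal with
block-diagonal (by domain) exchangeable correlation, discretised per
criterion by four strictly increasing thresholds into the 5-point Likert
scale, plus MCAR "Do not know" missingness.  Under this model the polychoric
correlation is consistent for the latent rho, which is what makes the
recovery tests downstream meaningful.

The default panel emulates the published study conditions: 25 panellists
rating 25 surveyed criteria in 7 domains, high latent correlation (0.7)
within six domains, one domain contaminated by a single negatively keyed
item (latent correlation -0.3 to its siblings, the "easiness of use"
analogue), sporadic missingness concentrated on one criterion (so one domain
loses about 5 of 25 complete cases).  Thresholds default to an importance-
skewed marginal (roughly 2/6/17/35/40% across levels 1..5, mean rating ~4),
matching the high relative indices the panel produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codebook import CriterionHierarchy, load_default_codebook
from .errors import ConfigurationError

# cumulative probabilities behind the default importance-skewed marginal
_DEFAULT_CUM_PROBS = (0.02, 0.08, 0.25, 0.60)


def default_thresholds() -> tuple[float, float, float, float]:
    from scipy.stats import norm

    return tuple(float(norm.ppf(p)) for p in _DEFAULT_CUM_PROBS)


@dataclass
class LatentPanelSpec:
    """Configuration of the latent-trait Likert panel simulator.

    Parameters
    ----------
    n_panellists : int
        Panel size (default 25, the study's realised panel).
    domains : list of (domain id, list of criterion ids)
        Block structure of the latent correlation matrix.
    within_domain_rho : dict domain id -> float
        Exchangeable latent correlation inside each domain.
    thresholds : dict criterion id -> 4 increasing cutpoints
        Standard-normal cutpoints mapping the latent value to levels 1..5.
    dnk_rate : float or dict criterion id -> float
        MCAR "Do not know" probability per cell (per-criterion overrides
        allowed, emulating criterion-specific unfamiliarity).
    contamination : dict criterion id -> float
        Optional per-criterion latent correlation to every other item of
        its domain, overriding the exchangeable value (used to plant a
        negatively keyed item).
    seed : int
        Single seed driving one pseudo-random stream.
    """

    n_panellists: int
    domains: list[tuple[str, list[str]]]
    within_domain_rho: dict[str, float]
    thresholds: dict[str, tuple[float, float, float, float]] = field(
        default_factory=dict
    )
    dnk_rate: float | dict[str, float] = 0.0
    contamination: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    @property
    def criterion_ids(self) -> list[str]:
        return [c for _, crits in self.domains for c in crits]

    def thresholds_for(self, criterion: str):
        return tuple(self.thresholds.get(criterion, default_thresholds()))

    def dnk_rate_for(self, criterion: str) -> float:
        if isinstance(self.dnk_rate, dict):
            return float(self.dnk_rate.get(criterion, 0.0))
        return float(self.dnk_rate)

    def validate(self) -> None:
        if self.n_panellists < 1:
            raise ConfigurationError("n_panellists must be positive")
        for crit in self.criterion_ids:
            tau = self.thresholds_for(crit)
            if len(tau) != 4:
                raise ConfigurationError(
                    f"criterion {crit!r}: exactly 4 thresholds required "
                    f"(got {len(tau)})"
                )
            if not all(a < b for a, b in zip(tau, tau[1:])):
                raise ConfigurationError(
                    f"criterion {crit!r}: thresholds must be strictly "
                    f"increasing, got {tau}"
                )
            rate = self.dnk_rate_for(crit)
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(
                    f"criterion {crit!r}: dnk_rate {rate} outside [0, 1]"
                )
        for domain, _ in self.domains:
            rho = self.within_domain_rho.get(domain, 0.0)
            if not -1.0 <= rho <= 1.0:
                raise ConfigurationError(
                    f"domain {domain!r}: within_domain_rho {rho} outside "
                    "[-1, 1]"
                )
            self.domain_correlation(domain)  # PSD check

    def domain_correlation(self, domain: str) -> np.ndarray:
        """Latent correlation block for one domain; raises if not PSD."""
        crits = dict(self.domains)[domain]
        k = len(crits)
        rho = float(self.within_domain_rho.get(domain, 0.0))
        block = np.full((k, k), rho)
        np.fill_diagonal(block, 1.0)
        for idx, crit in enumerate(crits):
            if crit in self.contamination:
                c = float(self.contamination[crit])
                block[idx, :] = c
                block[:, idx] = c
                block[idx, idx] = 1.0
        if np.linalg.eigvalsh(block).min() < -1e-9:
            raise ConfigurationError(
                f"domain {domain!r}: latent correlation block is not "
                "positive semi-definite"
            )
        return block


def generate_responses(spec: LatentPanelSpec) -> pd.DataFrame:
    """Draw a panellist x criterion Likert table from the latent model.

    Deterministic given (spec, spec.seed).  Missingness is MCAR,
    independent of the latent values.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    columns = spec.criterion_ids
    n = spec.n_panellists
    latent = np.empty((n, len(columns)))
    col_pos = {c: i for i, c in enumerate(columns)}
    for domain, crits in spec.domains:
        block = spec.domain_correlation(domain)
        # eigen-based factor tolerates the PSD-but-singular edge cases
        w, v = np.linalg.eigh(block)
        factor = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
        z = rng.standard_normal((n, len(crits))) @ factor.T
        for j, crit in enumerate(crits):
            latent[:, col_pos[crit]] = z[:, j]
    data = np.empty_like(latent)
    for crit in columns:
        tau = np.asarray(spec.thresholds_for(crit), dtype=float)
        data[:, col_pos[crit]] = 1.0 + np.searchsorted(
            tau, latent[:, col_pos[crit]]
        )
    mask = np.empty_like(latent, dtype=bool)
    for crit in columns:
        mask[:, col_pos[crit]] = (
            rng.random(n) < spec.dnk_rate_for(crit)
        )
    data[mask] = np.nan
    index = pd.Index([f"P{i + 1:02d}" for i in range(n)], name="panellist")
    return pd.DataFrame(data, index=index, columns=columns)


COLOURS = ("red", "yellow", "green")


def generate_performance_matrix(
    n_devices: int,
    criteria: list[str],
    colour_probs,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Random device x criterion traffic-light matrix.

    ``colour_probs`` is one (red, yellow, green) probability triple, or a
    dict criterion id -> triple.  Cells are set missing (NaN) with
    ``missing_rate``, independently.  Deterministic given seed.
    """
    if n_devices < 1:
        raise ConfigurationError("n_devices must be positive")
    if not 0.0 <= missing_rate <= 1.0:
        raise ConfigurationError(f"missing_rate {missing_rate} outside [0, 1]")
    if not isinstance(colour_probs, dict):
        colour_probs = {c: colour_probs for c in criteria}
    for crit in criteria:
        probs = np.asarray(colour_probs[crit], dtype=float)
        if probs.shape != (3,) or abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"criterion {crit!r}: colour probabilities {probs.tolist()} "
                "must be a triple summing to 1"
            )
    rng = np.random.default_rng(seed)
    index = pd.Index([f"D{i + 1:02d}" for i in range(n_devices)], name="device")
    out = pd.DataFrame(index=index, columns=criteria, dtype=object)
    for crit in criteria:
        probs = np.asarray(colour_probs[crit], dtype=float)
        draws = rng.choice(3, size=n_devices, p=probs)
        cells = np.array(COLOURS, dtype=object)[draws]
        missing = rng.random(n_devices) < missing_rate
        cells[missing] = None
        out[crit] = cells
    return out


def study_panel_spec(
    codebook: CriterionHierarchy | None = None, seed: int = 0
) -> LatentPanelSpec:
    """The default panel configuration emulating the published survey.

    25 panellists over the 25 surveyed criteria; latent rho 0.7 in every
    domain; the easiness-of-use analogue planted at -0.3 in the user-type
    domain; one criterion with a 20% DNK rate (its domain then keeps about
    20 of 25 complete cases) over a 1% background.
    """
    cb = codebook if codebook is not None else load_default_codebook()
    surveyed = cb.surveyed()
    domains = []
    for domain_id, _ in cb.domains:
        crits = [c.id for c in surveyed if c.domain == domain_id]
        if crits:
            domains.append((domain_id, crits))
    return LatentPanelSpec(
        n_panellists=25,
        domains=domains,
        within_domain_rho={d: 0.7 for d, _ in domains},
        dnk_rate={"4.5": 0.20, **{c.id: 0.01 for c in surveyed if c.id != "4.5"}},
        contamination={"1.2": -0.3},
        seed=seed,
    )
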