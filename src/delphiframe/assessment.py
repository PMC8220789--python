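"""Traffic-light device assessment over the discriminatory criteria.

Devices are scored per criterion on a qualitative three-point scale coded
as traffic lights: red (worst), yellow (intermediate), green (best).
Missing scores are resolved to red — the precautionary worst-case rule.
Two read-outs follow:

* criterion trend — a criterion is "selected" (performs well across the
  board) when it scores green on at least a fraction of the devices
  (default 5/8, ceiling-rounded);
* device classification — each device's class is the modal colour of its
  row (green = efficient, yellow = medium, red = not efficient), with ties
  resolved to the worse class, consistent with the precautionary stance.

Colour ordinality is pinned red < yellow < green for all monotonicity
reasoning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from sklearn.base import BaseEstimator

from .assembly import FrameworkResult, NON_DISCRIMINATORY_REASON
from .codebook import CriterionHierarchy
from .errors import ValidationError

COLOUR_ORDER = {"red": 0, "yellow": 1, "green": 2}
CLASS_BY_COLOUR = {"green": "efficient", "yellow": "medium", "red": "not_efficient"}
DEFAULT_GOOD_FRACTION = 5 / 8


@dataclass(frozen=True)
class DeviceClass:
    device: str
    label: str
    tallies: dict


def resolve_matrix(
    raw: pd.DataFrame,
    framework: FrameworkResult | None = None,
    codebook: CriterionHierarchy | None = None,
) -> tuple[pd.DataFrame, int]:
    """Validate colour tokens, reject non-discriminatory columns, and
    resolve missing cells to red.

    Returns the resolved matrix and the number of missing cells recoloured.
    Idempotent: resolving an already-resolved matrix changes nothing.
    """
    violations = []
    if framework is not None:
        allowed = set(framework.discriminatory)
        for col in raw.columns:
            if col not in allowed:
                detail = ""
                if codebook is not None and col in codebook:
                    if not codebook[col].discriminatory:
                        detail = f": {NON_DISCRIMINATORY_REASON}"
                violations.append(
                    f"column {col!r} is not a discriminatory criterion{detail}"
                )
    resolved = raw.copy()
    n_missing = 0
    for col in raw.columns:
        for device, cell in raw[col].items():
            if pd.isna(cell) or (isinstance(cell, str) and cell.strip() == ""):
                resolved.loc[device, col] = "red"
                n_missing += 1
                continue
            token = str(cell).strip().lower()
            if token not in COLOUR_ORDER:
                violations.append(
                    f"device {device!r}, criterion {col!r}: unknown colour "
                    f"token {cell!r}"
                )
            else:
                resolved.loc[device, col] = token
    if violations:
        raise ValidationError(violations)
    return resolved, n_missing


def criterion_trend(
    matrix: pd.DataFrame, good_fraction: float = DEFAULT_GOOD_FRACTION
) -> pd.DataFrame:
    """Per-criterion green counts and the selected flag.

    A criterion is selected when it is green in at least
    ``ceil(good_fraction * n_devices)`` devices.
    """
    if matrix.shape[0] < 1:
        raise ValidationError("performance matrix has no devices")
    n_devices = matrix.shape[0]
    need = math.ceil(good_fraction * n_devices)
    rows = []
    for col in matrix.columns:
        greens = int((matrix[col] == "green").sum())
        rows.append(
            {
                "criterion": col,
                "green_count": greens,
                "n_devices": n_devices,
                "selected": greens >= need,
            }
        )
    return pd.DataFrame(rows).set_index("criterion")


def classify_device(matrix: pd.DataFrame, device: str) -> DeviceClass:
    """Modal-colour efficiency class for one device, worse class on ties."""
    if device not in matrix.index:
        raise KeyError(f"unknown device {device!r}")
    row = matrix.loc[device]
    if row.size < 1:
        raise ValidationError("performance matrix has no criteria")
    tallies = {c: int((row == c).sum()) for c in COLOUR_ORDER}
    # among maximal tallies pick the worst colour (lowest ordinal value)
    best = max(tallies.values())
    modal = min(
        (c for c, t in tallies.items() if t == best), key=COLOUR_ORDER.get
    )
    return DeviceClass(device=device, label=CLASS_BY_COLOUR[modal], tallies=tallies)


COMPARATIVE_TOKENS = ("lower", "similar", "higher")


def comparative_scores(relative: pd.Series, kind: str) -> pd.Series:
    """Optional reference-device scorer for the non-discriminatory domains.

    Cost and lifetime criteria can only be compared against a reference
    device; given per-device tokens {lower, similar, higher} relative to
    that reference, this maps them to colours: for ``kind="cost"`` lower
    cost is green and higher is red; for ``kind="lifetime"`` the mapping
    is reversed (a longer lifetime is the best case).  Off by default —
    nothing in the standard pipeline calls it.
    """
    if kind not in {"cost", "lifetime"}:
        raise ValueError(f"kind must be 'cost' or 'lifetime', got {kind!r}")
    mapping = {"lower": "green", "similar": "yellow", "higher": "red"}
    if kind == "lifetime":
        mapping = {"lower": "red", "similar": "yellow", "higher": "green"}
    out = {}
    for device, token in relative.items():
        token = str(token).strip().lower()
        if token not in mapping:
            raise ValidationError(
                f"device {device!r}: unknown comparative token {token!r} "
                f"(expected one of {COMPARATIVE_TOKENS})"
            )
        out[device] = mapping[token]
    return pd.Series(out, name=relative.name)


class DeviceAssessor(BaseEstimator):
    """Performance-matrix assessment stage.

    Parameters
    ----------
    framework : FrameworkResult or None
        Restricts columns to the discriminatory subset when given.
    good_fraction : float
        Fraction of devices that must score green for a criterion to be
        selected (default 5/8).

    Attributes
    ----------
    matrix_ : resolved (no missing) colour matrix.
    n_missing_resolved_ : cells recoloured red by the precautionary rule.
    trend_ : per-criterion green counts and selected flags.
    device_classes_ : pandas.DataFrame of device class labels and tallies.
    """

    def __init__(
        self,
        framework: FrameworkResult | None = None,
        codebook: CriterionHierarchy | None = None,
        good_fraction: float = DEFAULT_GOOD_FRACTION,
    ):
        self.framework = framework
        self.codebook = codebook
        self.good_fraction = good_fraction

    def fit(self, X: pd.DataFrame, y=None):
        self.matrix_, self.n_missing_resolved_ = resolve_matrix(
            X, framework=self.framework, codebook=self.codebook
        )
        self.trend_ = criterion_trend(self.matrix_, self.good_fraction)
        classes = [classify_device(self.matrix_, d) for d in self.matrix_.index]
        self.device_classes_ = pd.DataFrame(
            [
                {
                    "device": c.device,
                    "class": c.label,
                    "red": c.tallies["red"],
                    "yellow": c.tallies["yellow"],
                    "green": c.tallies["green"],
                }
                for c in classes
            ]
        ).set_index("device")
        return self
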