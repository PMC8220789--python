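"""Criterion codebook: the hierarchy of design criteria grouped in domains.

The codebook is the backbone every stage validates against.  Each criterion
carries an opaque string id in ``domain.index`` form (ids such as ``7.1`` and
``7.10`` must stay distinct, so they are never parsed as numbers), a human
label, a framework status and a discriminatory flag.  Non-discriminatory
criteria (cost and lifetime domains) cannot be scored against other devices
without a reference device and are excluded from performance-matrix analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import ValidationError

VALID_STATUSES = frozenset(
    {"retained", "excluded_reliability", "excluded_importance", "a_posteriori"}
)


@dataclass(frozen=True)
class Criterion:
    id: str
    domain: str
    label: str
    status: str = "retained"
    discriminatory: bool = True


@dataclass
class CriterionHierarchy:
    """Ordered inventory of domains and criteria.

    Attributes
    ----------
    domains : list of (id, label)
        Ordered domain inventory.
    criteria : list of Criterion
        Ordered criterion inventory; every criterion references a domain.
    """

    domains: list[tuple[str, str]] = field(default_factory=list)
    criteria: list[Criterion] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        violations = []
        if not self.criteria:
            violations.append("codebook contains no criteria")
        domain_ids = [d for d, _ in self.domains]
        if len(set(domain_ids)) != len(domain_ids):
            violations.append("duplicate domain ids")
        seen = set()
        for c in self.criteria:
            if c.id in seen:
                violations.append(f"duplicate criterion id {c.id!r}")
            seen.add(c.id)
            if c.domain not in set(domain_ids):
                violations.append(
                    f"criterion {c.id!r} references unknown domain {c.domain!r}"
                )
            if c.status not in VALID_STATUSES:
                violations.append(
                    f"criterion {c.id!r} has unknown status {c.status!r}"
                )
        if violations:
            raise ValidationError(violations)

    # -- views -----------------------------------------------------------
    @property
    def criterion_ids(self) -> list[str]:
        return [c.id for c in self.criteria]

    def domain_of(self, criterion_id: str) -> str:
        return self._by_id()[criterion_id].domain

    def _by_id(self) -> dict[str, Criterion]:
        return {c.id: c for c in self.criteria}

    def __getitem__(self, criterion_id: str) -> Criterion:
        return self._by_id()[criterion_id]

    def __contains__(self, criterion_id: str) -> bool:
        return criterion_id in self._by_id()

    def criteria_in(self, domain_id: str) -> list[Criterion]:
        return [c for c in self.criteria if c.domain == domain_id]

    def surveyed(self) -> list[Criterion]:
        """Criteria that appeared on the questionnaire (everything except
        the a-posteriori additions, which carry no survey statistics)."""
        return [c for c in self.criteria if c.status != "a_posteriori"]

    def __eq__(self, other):
        return (
            isinstance(other, CriterionHierarchy)
            and self.domains == other.domains
            and self.criteria == other.criteria
        )


def _hierarchy_from_mapping(data: dict) -> CriterionHierarchy:
    try:
        domains = [(str(d["id"]), str(d["label"])) for d in data["domains"]]
        criteria = [
            Criterion(
                id=str(c["id"]),
                domain=str(c["domain"]),
                label=str(c["label"]),
                status=str(c.get("status", "retained")),
                discriminatory=bool(c.get("discriminatory", True)),
            )
            for c in data["criteria"]
        ]
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"malformed codebook structure: {exc}") from exc
    return CriterionHierarchy(domains=domains, criteria=criteria)


def read_codebook(path: str | Path) -> CriterionHierarchy:
    """Read and validate a codebook from a YAML (or JSON) file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError("codebook file does not contain a mapping")
    return _hierarchy_from_mapping(data)


def write_codebook(hierarchy: CriterionHierarchy, path: str | Path) -> None:
    data = {
        "domains": [{"id": d, "label": lb} for d, lb in hierarchy.domains],
        "criteria": [
            {
                "id": c.id,
                "domain": c.domain,
                "label": c.label,
                "status": c.status,
                "discriminatory": c.discriminatory,
            }
            for c in hierarchy.criteria
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False, allow_unicode=True)


def load_default_codebook() -> CriterionHierarchy:
    """The bundled 7-domain, 28-criterion medical-device design inventory."""
    ref = resources.files("delphiframe.data").joinpath("codebook.yaml")
    data = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return _hierarchy_from_mapping(data)
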