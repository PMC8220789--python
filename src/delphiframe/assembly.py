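"""Assemble the final criterion framework from the analysis outputs.

Two exclusion rules prune the surveyed inventory:

* reliability — an item flagged by the alpha-drop diagnostic in a domain
  with low internal consistency (the scale improves without it);
* importance — a criterion whose Delphi consensus settled on the scale
  midpoint ("Middle", median = 3), optionally backed by an RI floor.

A-posteriori criteria (added from field observations after the survey)
join the framework as retained-but-unranked: they carry no consensus
record, no RI and no correlations.  The discriminatory subset is the
retained set minus every cost- and lifetime-domain criterion, since those
can only be compared against a reference device.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .codebook import CriterionHierarchy
from .consensus import ConsensusRecord
from .errors import ValidationError

NON_DISCRIMINATORY_REASON = (
    "non-discriminatory criteria (cost and lifetime domains) are excluded "
    "from performance-matrix analysis"
)


@dataclass
class FrameworkResult:
    retained: list[str]
    excluded: dict[str, str]  # criterion id -> reason in {reliability, importance}
    a_posteriori: list[str]
    discriminatory: list[str]
    domain_ri: dict[str, float] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def n_discriminatory(self) -> int:
        return len(self.discriminatory)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "retained": self.retained,
            "excluded": self.excluded,
            "a_posteriori": self.a_posteriori,
            "discriminatory": self.discriminatory,
            "domain_ri": self.domain_ri,
            "counts": {
                "retained": self.n_retained,
                "excluded": len(self.excluded),
                "discriminatory": self.n_discriminatory,
            },
        }
        Path(path).write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "FrameworkResult":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            retained=list(data["retained"]),
            excluded=dict(data["excluded"]),
            a_posteriori=list(data["a_posteriori"]),
            discriminatory=list(data["discriminatory"]),
            domain_ri={k: float(v) for k, v in data.get("domain_ri", {}).items()},
        )


def assemble(
    codebook: CriterionHierarchy,
    reliability=None,
    consensus: list[ConsensusRecord] | None = None,
    ranking: pd.DataFrame | None = None,
    exclude_reliability: list[str] | None = None,
    exclude_importance: list[str] | None = None,
    ri_floor: float | None = None,
) -> FrameworkResult:
    """Build the framework, deriving exclusions from analysis outputs.

    Explicit ``exclude_reliability`` / ``exclude_importance`` lists override
    derivation (used to apply a published set of flags).  Otherwise the
    reliability exclusions come from a fitted
    :class:`~delphiframe.reliability.OrdinalReliability` and the importance
    exclusions from consensus records with median exactly 3 ("Middle"),
    intersected with ``ranking`` RIs below ``ri_floor`` when a floor is set.
    Reliability exclusions are applied before importance exclusions.
    """
    inventory = [c.id for c in codebook.criteria]
    for supplied in (exclude_reliability or []), (exclude_importance or []):
        for crit in supplied:
            if crit not in codebook:
                raise ValidationError(
                    f"excluded criterion {crit!r} is not in the codebook"
                )
    if exclude_reliability is None:
        exclude_reliability = (
            reliability.reliability_exclusions_() if reliability is not None else []
        )
    if exclude_importance is None:
        exclude_importance = []
        for rec in consensus or []:
            if rec.criterion not in codebook:
                raise ValidationError(
                    f"consensus record for unknown criterion {rec.criterion!r}"
                )
            if rec.median == 3:
                if ri_floor is not None and ranking is not None:
                    if float(ranking.loc[rec.criterion, "ri"]) >= ri_floor:
                        continue
                exclude_importance.append(rec.criterion)

    excluded: dict[str, str] = {}
    for crit in exclude_reliability:
        excluded[crit] = "reliability"
    for crit in exclude_importance:
        excluded.setdefault(crit, "importance")

    a_post = [c.id for c in codebook.criteria if c.status == "a_posteriori"]
    retained = [c for c in inventory if c not in excluded]
    # order retained by domain, then decreasing RI where known (unranked last)
    if ranking is not None:
        ri = ranking["ri"]

        def sort_key(crit):
            dom = codebook.domain_of(crit)
            r = float(ri.get(crit, float("-inf")))
            return (dom, -r, crit)

        retained = sorted(retained, key=sort_key)
    discriminatory = [c for c in retained if codebook[c].discriminatory]

    domain_ri: dict[str, float] = {}
    if ranking is not None:
        for domain_id, _ in codebook.domains:
            rs = [
                float(ranking.loc[c, "ri"])
                for c in retained
                if codebook.domain_of(c) == domain_id and c in ranking.index
            ]
            if rs:
                domain_ri[domain_id] = sum(rs) / len(rs)

    return FrameworkResult(
        retained=retained,
        excluded=excluded,
        a_posteriori=a_post,
        discriminatory=discriminatory,
        domain_ri=domain_ri,
    )
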