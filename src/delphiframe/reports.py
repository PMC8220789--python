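"""Report writers and performance-matrix CSV IO.

All tables go out as comma-separated UTF-8 with a header row; the missing
token for colour matrices is "NA" (configurable).  ``write_reports`` lays
down one CSV per fitted stage plus a run-provenance JSON and a Markdown
summary; nothing in the report files depends on wall-clock time, so a rerun
with the same inputs and seed is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .assembly import FrameworkResult

DEFAULT_COLOUR_MISSING = "NA"


def read_performance_matrix(
    path, missing_token: str = DEFAULT_COLOUR_MISSING
) -> pd.DataFrame:
    """Read a device x criterion colour CSV; missing cells become None.

    Colour tokens are validated later by ``resolve_matrix`` (which also
    applies the missing -> red rule); this reader only rejects structural
    problems so raw (unresolved) matrices round-trip exactly.
    """
    raw = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    raw.index.name = "device"
    out = raw.map(
        lambda cell: None
        if cell.strip() == missing_token or cell.strip() == ""
        else cell.strip()
    )
    return out


def write_performance_matrix(
    matrix: pd.DataFrame, path, missing_token: str = DEFAULT_COLOUR_MISSING
) -> None:
    out = matrix.map(lambda v: missing_token if v is None or pd.isna(v) else v)
    out.index.name = matrix.index.name or "device"
    out.to_csv(path, encoding="utf-8")


def _frame_to_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, encoding="utf-8", float_format="%.6g")


def write_reports(results: dict, path) -> list[Path]:
    """Write every available stage output under ``path``.

    ``results`` maps stage names to fitted objects / frames:
    ``consensus`` (DelphiConsensus), ``reliability`` (OrdinalReliability),
    ``ranking`` (RelativeIndexRanker), ``correlation`` (GammaScreen),
    ``framework`` (FrameworkResult), ``assessment`` (DeviceAssessor),
    ``provenance`` (JSON-serialisable dict).  Returns the files written.
    """
    outdir = Path(path)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create report directory {outdir}: {exc}") from exc
    written: list[Path] = []

    def emit(name: str, frame: pd.DataFrame):
        target = outdir / name
        _frame_to_csv(frame, target)
        written.append(target)

    if "consensus" in results:
        emit("consensus.csv", results["consensus"].table_)
    if "reliability" in results:
        rel = results["reliability"]
        emit("reliability.csv", rel.table_)
        for domain, res in rel.domains_.items():
            emit(f"polychoric_domain_{domain}.csv", res.matrix)
            if res.alpha_drop is not None:
                emit(
                    f"alpha_drop_domain_{domain}.csv",
                    res.alpha_drop.to_frame(),
                )
    if "ranking" in results:
        emit("ranking.csv", results["ranking"].ranking_)
    if "correlation" in results:
        emit("correlation.csv", results["correlation"].table_.set_index("criterion_a"))
    if "framework" in results:
        fw: FrameworkResult = results["framework"]
        fw.to_json(outdir / "framework.json")
        written.append(outdir / "framework.json")
    if "assessment" in results:
        assess = results["assessment"]
        emit("assessment_matrix.csv", assess.matrix_)
        emit("assessment_trend.csv", assess.trend_)
        emit("assessment_devices.csv", assess.device_classes_)
    if "provenance" in results:
        target = outdir / "provenance.json"
        target.write_text(
            json.dumps(results["provenance"], indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        written.append(target)
    summary = outdir / "summary.md"
    summary.write_text(_markdown_summary(results), encoding="utf-8")
    written.append(summary)
    return written


def _markdown_summary(results: dict) -> str:
    lines = ["# Analysis summary", ""]
    if "consensus" in results:
        eng = results["consensus"]
        n = len(eng.records_)
        reached = sum(r.label != "none" for r in eng.records_)
        verdict = "a further round is needed" if eng.needs_iteration_ else (
            "no further round is needed"
        )
        lines += [
            "## Consensus",
            f"{reached} of {n} criteria reached consensus; {verdict}.",
            "",
        ]
    if "reliability" in results:
        tab = results["reliability"].table_
        lines += ["## Reliability", ""]
        for domain, row in tab.iterrows():
            flag = f" (flagged: {row['flagged_item']})" if row["flagged_item"] else ""
            lines.append(
                f"- domain {domain} ({row['label']}): alpha = "
                f"{row['alpha']:.2f} [{row['interpretation']}], "
                f"n = {row['n_replies']}{flag}"
            )
        lines.append("")
    if "ranking" in results:
        rank = results["ranking"].ranking_
        lines += ["## Ranking", ""]
        head = rank.head(5)
        for crit, row in head.iterrows():
            lines.append(
                f"- {row['rank']}. {crit}: RI = {row['ri']:.3f} ({row['subclass']})"
            )
        lines.append("")
    if "correlation" in results:
        tab = results["correlation"].table_
        strong = tab[tab["strong"]]
        lines += [
            "## Correlations",
            f"{len(strong)} of {len(tab)} within-domain pairs are strong "
            "(|gamma| > 0.5, p < 0.05).",
            "",
        ]
    if "framework" in results:
        fw = results["framework"]
        lines += [
            "## Framework",
            f"{fw.n_retained} retained criteria "
            f"({fw.n_discriminatory} discriminatory); "
            f"{len(fw.excluded)} excluded; "
            f"{len(fw.a_posteriori)} added a posteriori.",
            "",
        ]
    if "assessment" in results:
        assess = results["assessment"]
        selected = assess.trend_[assess.trend_["selected"]]
        lines += [
            "## Device assessment",
            f"{assess.n_missing_resolved_} missing cells resolved to red.",
            f"{len(selected)} of {len(assess.trend_)} criteria selected "
            "(green in enough devices).",
            "",
        ]
        for device, row in assess.device_classes_.iterrows():
            lines.append(f"- {device}: {row['class']}")
        lines.append("")
    return "\n".join(lines) + "\n"
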