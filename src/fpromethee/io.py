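"""Configuration loading, matrix CSV parsing and report writing.

Criteria configurations are YAML/JSON documents declaring, per criterion:
id, name, direction, a fuzzy weight (linguistic label or explicit
[a, b, c] triple), a preference-function family with thresholds, and an
optional spread override.  Decision matrices arrive as CSV with one row
per alternative and one column per criterion id; cells are numeric or
linguistic labels, which are defuzzified on read.  Reports mirror the
complete-ranking table layout (Rank / Alternative / Phi_net / Phi+ / Phi-)
with 4-decimal display values in CSV and full precision in JSON, plus a
provenance block so a report is traceable to its inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fuzzy import LinguisticScale, default_scale, make_tfn, resolve_term
from .outranking import AnalysisResult, DecisionMatrix, DecisionMatrixError
from .preference import Criterion, PreferenceFunctionSpec

__all__ = [
    "AnalysisReport",
    "load_criteria_config",
    "read_matrix_csv",
    "write_matrix_csv",
    "build_report",
    "write_report",
    "load_reference_flows",
    "config_hash",
]


def _parse_scale(node) -> LinguisticScale:
    if node is None or node == "default":
        return default_scale()
    terms = tuple((label, make_tfn(*triple)) for label, triple in node.items())
    return LinguisticScale(terms)


def _parse_weight(node, scale: LinguisticScale):
    if isinstance(node, str):
        return resolve_term(node, scale)
    if isinstance(node, (list, tuple)) and len(node) == 3:
        return make_tfn(*node)
    raise ValueError(
        f"weight must be a linguistic label or an [a, b, c] triple, got {node!r}"
    )


def _parse_pf(node) -> PreferenceFunctionSpec:
    if node is None:
        return PreferenceFunctionSpec()
    if isinstance(node, str):
        return PreferenceFunctionSpec(family=node)
    return PreferenceFunctionSpec(
        family=node.get("family", "gaussian"),
        q=node.get("q"),
        p=node.get("p"),
        s=node.get("s"),
    )


def load_criteria_config(path: str | Path) -> tuple[tuple[Criterion, ...], LinguisticScale]:
    """Load criteria and linguistic scale from a YAML (or JSON) config."""
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(doc, dict) or "criteria" not in doc:
        raise ValueError(f"config {path} must be a mapping with a 'criteria' list")
    scale = _parse_scale(doc.get("scale"))
    criteria = []
    for node in doc["criteria"]:
        criteria.append(
            Criterion(
                id=str(node["id"]),
                name=str(node.get("name", "")),
                direction=node.get("direction", "maximize"),
                weight=_parse_weight(node.get("weight", "High"), scale),
                pf=_parse_pf(node.get("pf")),
            )
        )
    return tuple(criteria), scale


def default_criteria_config_path() -> Path:
    """Path of the bundled UTI-study criteria configuration."""
    return Path(str(resources.files("fpromethee").joinpath("data/uti_replica.yaml")))


def read_matrix_csv(
    path: str | Path,
    criteria: tuple[Criterion, ...],
    scale: LinguisticScale | None = None,
) -> DecisionMatrix:
    """Parse a decision-matrix CSV against a criteria configuration.

    First column: alternative label; header: criterion ids (order may
    differ from the config; extra or missing columns are errors).
    Linguistic cells are resolved on ``scale`` and defuzzified; blank or
    unparseable cells raise with their row/column coordinates.
    """
    if scale is None:
        scale = default_scale()
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    want = [c.id for c in criteria]
    have = list(df.columns)
    if sorted(have) != sorted(want):
        missing = sorted(set(want) - set(have))
        extra = sorted(set(have) - set(want))
        raise DecisionMatrixError(
            f"matrix columns do not match criteria config: missing {missing}, "
            f"unexpected {extra}"
        )
    df = df[want]
    values = np.empty(df.shape)
    for i, (alt, row) in enumerate(df.iterrows()):
        for j, cid in enumerate(want):
            cell = str(row[cid]).strip()
            if cell == "":
                raise DecisionMatrixError(
                    f"missing cell at alternative {alt!r}, criterion {cid!r}"
                )
            try:
                values[i, j] = float(cell)
            except ValueError:
                try:
                    values[i, j] = resolve_term(cell, scale).defuzzify()
                except KeyError as exc:
                    raise DecisionMatrixError(
                        f"cell at alternative {alt!r}, criterion {cid!r}: {exc}"
                    ) from exc
    return DecisionMatrix(
        alternatives=tuple(str(a) for a in df.index),
        criteria=criteria,
        values=values,
    )


def write_matrix_csv(m: DecisionMatrix, path: str | Path) -> None:
    """Write a crisp decision matrix as UTF-8 CSV (label column + header)."""
    df = m.to_frame()
    df.index.name = "alternative"
    df.to_csv(path, lineterminator="\n")


def config_hash(criteria: tuple[Criterion, ...]) -> str:
    """Stable short hash of a criteria configuration for provenance."""
    payload = [
        {
            "id": c.id,
            "direction": c.direction,
            "weight": c.weight.as_tuple(),
            "pf": [c.pf.family, c.pf.q, c.pf.p, c.pf.s],
        }
        for c in criteria
    ]
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


@dataclass(frozen=True)
class AnalysisReport:
    """Ranking table with display rounding plus full-precision payload."""

    rows: tuple[tuple[int, str, float, float, float], ...]  # rank, label, net, +, -
    provenance: dict

    def display_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r, lab, _fmt4(net), _fmt4(plus), _fmt4(minus))
                for r, lab, net, plus, minus in self.rows
            ],
            columns=["rank", "alternative", "phi_net", "phi_plus", "phi_minus"],
        )


def _fmt4(v: float) -> str:
    # round-half-even to 4 decimals; ASCII hyphen-minus for negatives
    return format(round(float(v), 4), ".4f")


def build_report(
    result: AnalysisResult,
    seed: int | None = None,
    epsilon: float | None = None,
) -> AnalysisReport:
    """Assemble a report from an analysis result, with provenance."""
    from . import __version__

    flows = result.flows
    idx = {lab: i for i, lab in enumerate(flows.alternatives)}
    rows = tuple(
        (
            rank,
            lab,
            float(net),
            float(flows.phi_plus[idx[lab]]),
            float(flows.phi_minus[idx[lab]]),
        )
        for rank, lab, net in result.ranking.rows
    )
    prov = {
        "tool": "fpromethee",
        "version": __version__,
        "config_hash": config_hash(result.matrix.criteria),
        "seed": seed,
        "epsilon": epsilon,
        "n_alternatives": result.matrix.n,
        "n_criteria": result.matrix.k,
    }
    return AnalysisReport(rows=rows, provenance=prov)


def write_report(report: AnalysisReport, path: str | Path, format: str = "csv") -> None:
    """Write a report as CSV (4-decimal display) or JSON (full precision).

    Output is byte-stable for identical inputs: fixed column order, fixed
    key order, newline line endings.
    """
    path = Path(path)
    if format == "csv":
        lines = ["rank,alternative,phi_net,phi_plus,phi_minus"]
        for r, lab, net, plus, minus in report.rows:
            label = f'"{lab}"' if "," in lab else lab
            lines.append(f"{r},{label},{_fmt4(net)},{_fmt4(plus)},{_fmt4(minus)}")
        lines.append("# provenance: " + json.dumps(report.provenance, sort_keys=True))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "json":
        doc = {
            "ranking": [
                {
                    "rank": r,
                    "alternative": lab,
                    "phi_net": net,
                    "phi_plus": plus,
                    "phi_minus": minus,
                }
                for r, lab, net, plus, minus in report.rows
            ],
            "provenance": report.provenance,
        }
        path.write_text(
            json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    else:
        raise ValueError(f"format must be 'csv' or 'json', got {format!r}")


def load_reference_flows(which: str = "full") -> pd.DataFrame:
    """Published flow tables of the UTI study, as printed.

    ``which="full"`` is the complete-ranking table over all 15 criteria;
    ``which="sensitivity"`` the re-ranking after omitting the
    specimen-volume and specimen-type criteria.  Columns: rank,
    alternative, phi_net, phi_plus, phi_minus (printed precision).
    """
    names = {
        "full": "uti_reference_ranking.csv",
        "sensitivity": "uti_sensitivity_ranking.csv",
    }
    if which not in names:
        raise ValueError(f"which must be one of {sorted(names)}, got {which!r}")
    ref = resources.files("fpromethee").joinpath(f"data/{names[which]}")
    with resources.as_file(ref) as p:
        return pd.read_csv(p)
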