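"""Assemble the written analysis outputs into one human-readable report."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = ["MissingInputError", "build_report"]

_REQUIRED = [
    "manifest.json",
    "inclusion_decisions.csv",
]
_ANALYSIS_FILES = [
    "network_metrics.csv",
    "typology_labels.csv",
    "typology_counts.csv",
    "condition_summary.csv",
    "friedman.csv",
    "spearman_density_centralization.csv",
    "external_exchange.csv",
]


class MissingInputError(FileNotFoundError):
    pass


def _require(path: Path) -> Path:
    if not path.exists():
        raise MissingInputError(f"missing analysis output: {path}")
    return path


def build_report(out_dir: str | Path) -> str:
    """Render a markdown report from a completed analysis directory.

    Raises :class:`MissingInputError` naming the first absent file. If the
    run stopped at the reciprocity gate, the report says so and stops after
    the inclusion summary.
    """
    out = Path(out_dir)
    manifest = json.loads(_require(out / "manifest.json").read_text(encoding="utf-8"))
    decisions = pd.read_csv(_require(out / "inclusion_decisions.csv"))

    counts = manifest["counts"]
    recip = manifest["reciprocity"]
    lines = [
        "# Information-exchange network analysis",
        "",
        f"Input: `{manifest.get('input')}`",
        "",
        "## Inclusion",
        "",
        f"- practices read: {counts['practices_read']}",
        f"- included (>= 3 members, <= 1 non-respondent): {counts['included']}",
        f"- excluded, fewer than 3 members: {counts['excluded_too_few_members']}",
        f"- excluded, more than 1 non-respondent: {counts['excluded_too_many_missing']}",
        "",
        "## Reciprocity gate",
        "",
        f"- pooled reciprocity (included practices): {recip['included_practices']:.3f}"
        if recip["included_practices"] is not None
        else "- pooled reciprocity (included practices): undefined",
        f"- pooled reciprocity (all practices, for transparency): "
        + (
            f"{recip['all_practices']:.3f}"
            if recip["all_practices"] is not None
            else "undefined"
        ),
        f"- threshold: above {recip['gate_threshold']}",
        f"- decision: {'proceed with undirected networks' if recip['gate_passed'] else 'STOP — undirected reconstruction not warranted'}",
        "",
    ]
    if counts["included"] == 0:
        lines += ["No networks were included; nothing further to report.", ""]
        return "\n".join(lines)
    if not recip["gate_passed"]:
        lines += [
            "The analysis halted at the reciprocity gate; only inclusion "
            "diagnostics are available.",
            "",
        ]
        return "\n".join(lines)

    for name in _ANALYSIS_FILES:
        _require(out / name)

    summary = pd.read_csv(out / "condition_summary.csv")
    typ = pd.read_csv(out / "typology_counts.csv")
    friedman = pd.read_csv(out / "friedman.csv")
    spearman = pd.read_csv(out / "spearman_density_centralization.csv")
    external = pd.read_csv(out / "external_exchange.csv")

    lines += [
        "## Network characteristics per condition",
        "",
        "Mean (SD) and median (IQR) over included practices; sample SD (n-1),",
        "quartiles by linear interpolation. Reciprocity rows skip networks",
        "where it is undefined (no assessable directed ties).",
        "",
        summary.to_string(index=False),
        "",
        "## Friedman comparison across conditions (tie-corrected, asymptotic chi-square)",
        "",
        friedman.to_string(index=False),
        "",
        "## Density-centralization correlation (Spearman)",
        "",
        spearman.to_string(index=False) if len(spearman) else "undefined (constant metric)",
        "",
        "## Typology",
        "",
        "Bands: low <= 0.33 < medium <= 0.67 < high. Types: A high density;",
        "B medium density, medium centralization; C medium density, low",
        "centralization; D low density. Other band pairs are 'unmapped'.",
        "",
        typ.to_string(index=False),
        "",
        "## Weekly exchange with groups outside the practice",
        "",
        "Percentages over responding individuals per stratum.",
        "",
        external[external["n"] > 0].to_string(index=False),
        "",
    ]
    cardio_path = out / "cardiologists.csv"
    if cardio_path.exists():
        cardio = pd.read_csv(cardio_path)
        if len(cardio):
            lines += [
                "## Monthly cardiologist contacts",
                "",
                cardio.to_string(index=False),
                "",
            ]
    return "\n".join(lines)
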