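"""End-to-end analysis: cohort in, metrics/typology/statistics out.

The three-phase protocol:

1. **Validation** — apply the inclusion filter (>= 3 members, <= 1
   non-respondent), build the directed nomination networks of the included
   practices and compute their pooled reciprocity; proceed only if it clears
   the gate (strictly above 0.6 by default).
2. **Reconstruction** — symmetrize each directed network (union rule by
   default), which simultaneously reconstructs a single non-respondent's
   edges, and compute the four network properties.
3. **Typology and statistics** — band and type each network, summarise each
   condition, compare conditions with the Friedman test, correlate density
   with centralization (Spearman), and tabulate external exchange and
   cardiologist contacts on the full cohort.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .builder import (
    DEFAULT_GATE_THRESHOLD,
    DirectedTieNetwork,
    InclusionDecision,
    InclusionReason,
    UndirectedNetwork,
    apply_inclusion_filter,
    build_directed_network,
    reciprocity_gate,
    symmetrize,
    write_graphml,
)
from .metrics import NetworkMetrics, metrics_bundle, pooled_reciprocity
from .roster import CONDITIONS, CARDIOLOGIST_CONDITIONS, Cohort, Condition
from .stats import (
    CardiologistSummary,
    ConditionSummary,
    FriedmanResult,
    cardiologist_summary,
    condition_summary,
    external_exchange_table,
    friedman_test,
    spearman_correlation,
    summary_table,
)
from .typology import TypologyLabel, classify_network, typology_counts

__all__ = ["AnalysisResult", "GateStopped", "analyze_cohort", "write_analysis"]


class GateStopped(RuntimeError):
    """The reciprocity gate failed: undirected analysis is not warranted."""

    def __init__(self, reciprocity: float, threshold: float):
        self.reciprocity = reciprocity
        self.threshold = threshold
        super().__init__(
            f"pooled reciprocity {reciprocity:.3f} is not above the gate threshold "
            f"{threshold:.2f}; undirected reconstruction is not warranted"
        )


@dataclass
class AnalysisResult:
    decisions: list[InclusionDecision]
    included_ids: list[str]
    gate_threshold: float
    reciprocity_included: Optional[float]
    reciprocity_all: Optional[float]
    gate_passed: bool
    symmetrize_rule: str
    directed: dict[tuple[str, Condition], DirectedTieNetwork] = field(default_factory=dict)
    undirected: dict[tuple[str, Condition], UndirectedNetwork] = field(default_factory=dict)
    metrics: list[NetworkMetrics] = field(default_factory=list)
    labels: list[TypologyLabel] = field(default_factory=list)
    summaries: list[ConditionSummary] = field(default_factory=list)
    friedman: dict[str, FriedmanResult] = field(default_factory=dict)
    spearman: dict[str, tuple[float, float]] = field(default_factory=dict)
    external: Optional[pd.DataFrame] = None
    cardiologists: dict[str, CardiologistSummary] = field(default_factory=dict)

    @property
    def n_excluded_too_few(self) -> int:
        return sum(d.reason is InclusionReason.TOO_FEW_MEMBERS for d in self.decisions)

    @property
    def n_excluded_too_many_missing(self) -> int:
        return sum(d.reason is InclusionReason.TOO_MANY_MISSING for d in self.decisions)


def _metric_matrix(metrics: list[NetworkMetrics], included_ids: list[str], name: str) -> np.ndarray:
    by_key = {(m.practice_id, m.condition): m for m in metrics}
    rows = []
    for pid in included_ids:
        row = []
        for c in CONDITIONS:
            m = by_key[(pid, c)]
            v = getattr(m, name)
            row.append(math.nan if v is None else float(v))
        rows.append(row)
    return np.asarray(rows, dtype=float)


def analyze_cohort(
    cohort: Cohort,
    symmetrize_rule: str = "union",
    gate_threshold: float = DEFAULT_GATE_THRESHOLD,
    strict_gate: bool = True,
) -> AnalysisResult:
    """Run the full three-phase analysis on a validated cohort.

    With ``strict_gate`` (the default) a failing reciprocity gate raises
    :class:`GateStopped` carrying the partial result in ``exc.result`` — the
    caller decides whether partial diagnostics are still worth writing.
    """
    decisions = apply_inclusion_filter(cohort)
    included_ids = [d.practice_id for d in decisions if d.included]
    included = [cohort.practice(pid) for pid in included_ids]

    directed = {
        (p.practice_id, c): build_directed_network(p, c) for p in included for c in CONDITIONS
    }
    # pooled over every practice large enough to define ties, for transparency
    all_directed = [
        build_directed_network(p, c)
        for p in cohort.practices
        if p.n_members >= 2
        for c in CONDITIONS
    ]
    recip_included = pooled_reciprocity(directed.values())
    recip_all = pooled_reciprocity(all_directed)

    gate_passed = reciprocity_gate(recip_included, gate_threshold)
    result = AnalysisResult(
        decisions=decisions,
        included_ids=included_ids,
        gate_threshold=gate_threshold,
        reciprocity_included=recip_included,
        reciprocity_all=recip_all,
        gate_passed=gate_passed,
        symmetrize_rule=symmetrize_rule,
        directed=directed,
    )
    if not gate_passed:
        if strict_gate:
            exc = GateStopped(recip_included, gate_threshold)
            exc.result = result
            raise exc
        return result

    result.undirected = {key: symmetrize(net, symmetrize_rule) for key, net in directed.items()}
    result.metrics = [
        metrics_bundle(directed[key], result.undirected[key]) for key in sorted(directed)
    ]
    result.labels = [classify_network(m) for m in result.metrics]
    result.summaries = [condition_summary(result.metrics, c) for c in CONDITIONS]

    if len(included_ids) >= 2:
        for name in ("n_edges", "density", "centralization", "reciprocity"):
            matrix = _metric_matrix(result.metrics, included_ids, name)
            complete = (~np.isnan(matrix).any(axis=1)).sum()
            if complete >= 2:
                result.friedman[name] = friedman_test(matrix)

    for c in CONDITIONS:
        sub = [m for m in result.metrics if m.condition is c]
        try:
            result.spearman[c.value] = spearman_correlation(
                [m.density for m in sub], [m.centralization for m in sub]
            )
        except ValueError:
            pass  # fewer than 3 networks or a constant vector: undefined

    result.external = external_exchange_table(cohort)
    for c in CARDIOLOGIST_CONDITIONS:
        try:
            result.cardiologists[c.value] = cardiologist_summary(cohort, c)
        except ValueError:
            pass  # no observed counts
    return result


def _decisions_frame(decisions: list[InclusionDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "practice_id": d.practice_id,
                "included": d.included,
                "reason": d.reason.value,
                "n_members": d.n_members,
                "n_nonrespondents": d.n_nonrespondents,
            }
            for d in decisions
        ]
    )


def _metrics_frame(metrics: list[NetworkMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "practice_id": m.practice_id,
                "condition": m.condition.value,
                "n_nodes": m.n_nodes,
                "n_edges": m.n_edges,
                "density": m.density,
                "centralization": m.centralization,
                "reciprocity": m.reciprocity,  # empty cell when undefined
            }
            for m in metrics
        ]
    )


def _labels_frame(labels: list[TypologyLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "practice_id": lab.practice_id,
                "condition": lab.condition.value,
                "density_band": lab.density_band.value,
                "centralization_band": lab.centralization_band.value,
                "network_type": lab.network_type.value,
                "fully_connected": lab.fully_connected,
            }
            for lab in labels
        ]
    )


def write_analysis(
    result: AnalysisResult,
    out_dir: str | Path,
    input_path: Optional[str] = None,
    config_hash: Optional[str] = None,
    seed: Optional[int] = None,
) -> dict:
    """Write all analysis outputs to ``out_dir`` and return the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []

    def save(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, index=False)
        outputs.append(name)

    save(_decisions_frame(result.decisions), "inclusion_decisions.csv")
    if result.gate_passed:
        save(_metrics_frame(result.metrics), "network_metrics.csv")
        save(_labels_frame(result.labels), "typology_labels.csv")
        save(typology_counts(result.labels), "typology_counts.csv")
        save(summary_table(result.summaries, result.friedman), "condition_summary.csv")
        save(
            pd.DataFrame(
                [
                    {
                        "metric": name,
                        "statistic": fr.statistic,
                        "df": fr.df,
                        "p_value": fr.p_value,
                        "n_blocks": fr.n_blocks,
                        "tie_corrected": fr.tie_corrected,
                    }
                    for name, fr in result.friedman.items()
                ]
            ),
            "friedman.csv",
        )
        save(
            pd.DataFrame(
                [
                    {"condition": c, "rho": rho, "p_value": p}
                    for c, (rho, p) in result.spearman.items()
                ]
            ),
            "spearman_density_centralization.csv",
        )
        save(result.external, "external_exchange.csv")
        save(
            pd.DataFrame(
                [
                    {
                        "condition": c,
                        "n_practices": s.n_practices,
                        "practice_mean": s.practice_mean,
                        "practice_sd": s.practice_sd,
                        "count_min": s.count_min,
                        "count_max": s.count_max,
                        **{
                            f"{role}_{f}": getattr(rm, f)
                            for role, rm in s.by_role.items()
                            for f in ("n", "mean", "sd")
                        },
                    }
                    for c, s in result.cardiologists.items()
                ]
            ),
            "cardiologists.csv",
        )
        gdir = out / "graphml"
        gdir.mkdir(exist_ok=True)
        for (pid, cond), net in sorted(result.undirected.items()):
            name = f"graphml/{pid}_{cond.value}.graphml"
            write_graphml(net, out / name)
            outputs.append(name)

    n_read = len(result.decisions)
    manifest = {
        "input": input_path,
        "config_hash": config_hash,
        "seed": seed,
        "counts": {
            "practices_read": n_read,
            "included": len(result.included_ids),
            "excluded_too_few_members": result.n_excluded_too_few,
            "excluded_too_many_missing": result.n_excluded_too_many_missing,
        },
        "reciprocity": {
            "included_practices": result.reciprocity_included,
            "all_practices": result.reciprocity_all,
            "gate_threshold": result.gate_threshold,
            "gate_passed": result.gate_passed,
        },
        "symmetrize_rule": result.symmetrize_rule,
        "outputs": outputs,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    assert (
        manifest["counts"]["practices_read"]
        == manifest["counts"]["included"]
        + manifest["counts"]["excluded_too_few_members"]
        + manifest["counts"]["excluded_too_many_missing"]
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return manifest
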