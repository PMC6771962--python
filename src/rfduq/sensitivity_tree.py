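"""Deterministic sensitivity tree of candidate reference doses.

Each branch of the tree is one combination of assumption choices — which
POD value to use, whether to account for background dioxin-like TEQ,
and whether the POD is read as a NOAEL or a LOAEL (which decides the
uncertainty-factor set).  Enumerating the full cartesian product of choices
yields the range of reference doses that reasonable alternative readings of
the same evidence support.

Kinetic-variant PODs are inputs supplied in configuration, not recomputed;
confidence labels are static annotations carried from configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd

from . import rfd_core
from .rfd_core import (
    Classification,
    DoseUnit,
    IntakeRate,
    Metric,
    PointOfDeparture,
    RfdEstimate,
    SerumConcentration,
    SerumIntakeAnchor,
    UncertaintyFactorSpec,
)
from .teq_accounting import TeqBreakdown

__all__ = ["PodOption", "ScenarioNode", "enumerate_tree", "tree_report"]


@dataclass(frozen=True)
class PodOption:
    """One candidate POD: a value with units, metric and a source label.

    ``unit`` is ``"ppt"`` (serum, needs an anchor to become an intake) or an
    intake unit (``"ng/kg/day"`` / ``"pg/kg/day"``).
    """

    label: str
    value: float
    unit: str
    metric: Metric = Metric.TCDD

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"POD option {self.label!r} must be positive")
        if not isinstance(self.metric, Metric):
            object.__setattr__(self, "metric", Metric(self.metric))


@dataclass(frozen=True)
class ScenarioNode:
    """One leaf of the sensitivity tree: an ordered branch path, the POD it
    implies, the composite UF, and the derived RfD."""

    branch_path: Tuple[Tuple[str, str], ...]
    pod: PointOfDeparture
    composite_uf: float
    rfd: RfdEstimate
    confidence_label: str = "medium"

    @property
    def path_string(self) -> str:
        return " / ".join(f"{k}={v}" for k, v in self.branch_path)


def _teq_factor(teq: Optional[TeqBreakdown]) -> float:
    """Multiplicative TEQ adjustment: total TEQ per unit TCDD.

    Because the serum-to-intake anchor is proportional, scaling the serum
    concentration and scaling the anchored intake by the same ratio are
    identical operations, so the factor applies on either scale.
    """
    if teq is None:
        return 1.0
    if not teq.tcdd > 0:
        raise ValueError("TEQ adjustment requires a positive TCDD component")
    return teq.total_teq / teq.tcdd


def enumerate_tree(
    pod_options: Sequence[PodOption],
    classifications: Sequence[Union[Classification, str]],
    teq_options: Sequence[Tuple[str, Optional[TeqBreakdown]]],
    uf_table: Dict[Classification, Sequence[UncertaintyFactorSpec]],
    anchor: Optional[SerumIntakeAnchor] = None,
    sigfigs: int = 1,
    confidence_labels: Optional[Dict[str, str]] = None,
) -> List[ScenarioNode]:
    """Enumerate the full cartesian product of POD × TEQ × classification.

    Every node's RfD is recomputed through :func:`rfd_core.derive_rfd`
    (no duplicated arithmetic); ordering is lexicographic on the branch
    path and therefore deterministic.  An unknown classification in the UF
    table lookup is rejected.
    """
    if not pod_options or not classifications or not teq_options:
        raise ValueError("all option lists must be non-empty")
    classifications = [Classification(c) for c in classifications]
    for c in classifications:
        if c not in uf_table:
            raise ValueError(f"UF table has no entry for classification {c.value}")
    confidence_labels = confidence_labels or {}

    nodes: List[ScenarioNode] = []
    for pod_opt in pod_options:
        for teq_label, teq in teq_options:
            factor = _teq_factor(teq)
            metric = pod_opt.metric if factor == 1.0 else Metric.TEQ
            for cl in classifications:
                if pod_opt.unit == "ppt":
                    if anchor is None:
                        raise ValueError(
                            f"serum POD {pod_opt.label!r} requires a serum-intake anchor"
                        )
                    serum = SerumConcentration(pod_opt.value * factor, metric)
                    intake = IntakeRate(
                        anchor.intake.value * serum.value / anchor.serum.value,
                        anchor.intake.unit,
                    )
                else:
                    intake = IntakeRate(pod_opt.value * factor, DoseUnit(pod_opt.unit))
                path = (
                    ("pod", pod_opt.label),
                    ("teq", teq_label),
                    ("classification", cl.value),
                )
                pod = PointOfDeparture(
                    dose=intake,
                    classification=cl,
                    provenance=" / ".join(f"{k}={v}" for k, v in path),
                )
                ufs = uf_table[cl]
                composite = rfd_core.compose_uf(ufs)
                rfd = rfd_core.derive_rfd(pod, composite, sigfigs=sigfigs)
                nodes.append(
                    ScenarioNode(
                        branch_path=path,
                        pod=pod,
                        composite_uf=composite,
                        rfd=rfd,
                        confidence_label=confidence_labels.get(pod_opt.label, "medium"),
                    )
                )
    nodes.sort(key=lambda node: node.branch_path)
    return nodes


def tree_report(nodes: Sequence[ScenarioNode]) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Tabulate the tree leaves and summarise the candidate-RfD range."""
    if not nodes:
        raise ValueError("tree_report needs at least one node")
    rows = [
        {
            "branch": node.path_string,
            "pod_pg_kg_day": node.pod.dose.pg_per_kg_day,
            "classification": node.pod.classification.value,
            "composite_uf": node.composite_uf,
            "rfd_exact_pg_kg_day": node.rfd.value,
            "rfd_rounded": node.rfd.rounded_value,
            "confidence": node.confidence_label,
        }
        for node in nodes
    ]
    table = pd.DataFrame(rows).sort_values("rfd_exact_pg_kg_day").reset_index(drop=True)
    summary = {
        "min_rfd_pg_kg_day": float(table["rfd_exact_pg_kg_day"].min()),
        "max_rfd_pg_kg_day": float(table["rfd_exact_pg_kg_day"].max()),
        "n_scenarios": float(len(table)),
    }
    return table, summary


def to_dot(nodes: Sequence[ScenarioNode]) -> str:
    """Graphviz DOT rendering of the branch structure (presentation only)."""
    lines = ["digraph sensitivity_tree {", '  root [label="POD evidence"];']
    for i, node in enumerate(nodes):
        prev = "root"
        for depth, (k, v) in enumerate(node.branch_path):
            nid = f"n{i}_{depth}"
            lines.append(f'  {nid} [label="{k}={v}"];')
            lines.append(f"  {prev} -> {nid};")
            prev = nid
        lines.append(
            f'  leaf{i} [shape=box, label="RfD {node.rfd.rounded_value:g} pg/kg/day"];'
        )
        lines.append(f"  {prev} -> leaf{i};")
    lines.append("}")
    return "\n".join(lines)
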