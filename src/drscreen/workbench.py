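"""Experiment orchestration: policy comparisons, operating-point sweeps,
and the curated-vs-uncurated evaluation.

Two experiment patterns recur when tuning a screening classifier's
decision layer:

1. *Policy comparison* — evaluate the same labelled probability records
   under the plain argmax ("Original") and one or more boosted decision
   policies, side by side, one metrics column per policy.
2. *Curation experiment* — score image quality, reject inadequate images,
   and run the identical comparison on the full ("un-curated") and
   retained ("curated") sets, reporting the rejection rate alongside.

A *sweep* searches a one-dimensional policy-parameter grid (margins for
margin-max, uniform thresholds for cascading) for the operating point
that meets a screening objective — e.g. sensitivity(Referable) >= 0.85 —
while maximizing the same class's specificity; ties prefer the smallest
(least aggressive) parameter.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .grading import GradeScheme
from .metrics import MetricsReport, compute_metrics, confusion
from .policies import (
    ArgmaxPolicy,
    CascadingPolicy,
    DecisionPolicy,
    MarginMaxPolicy,
    ProbRecord,
    apply_policy,
)
from .quality import CurationResult, QualityScore, curate

__all__ = [
    "SweepSpec",
    "SweepResult",
    "ComparisonReport",
    "CurationExperiment",
    "evaluate_policy",
    "run_comparison",
    "sweep",
    "run_curation_experiment",
    "policy_label",
]


def policy_label(policy: DecisionPolicy) -> str:
    """Human-readable column label for a policy configuration."""
    if isinstance(policy, ArgmaxPolicy):
        return "Original"
    if isinstance(policy, CascadingPolicy):
        cells = [
            "~" if c == policy.scheme.fallback_class else f"{policy.thresholds[c]:g}"
            for c in policy.scheme.classes
        ]
        return f"Cascading Thresholds ({', '.join(cells)})"
    if isinstance(policy, MarginMaxPolicy):
        return f"Margin Max ({policy.margin:g}) preferring {policy.preference[0]}"
    return type(policy).__name__


def evaluate_policy(
    records: Sequence[ProbRecord], policy: DecisionPolicy, scheme: GradeScheme
) -> MetricsReport:
    """Decide every record under one policy and score against true labels."""
    truths = [r.true_label for r in records]
    if any(t is None for t in truths):
        raise ValueError("evaluation requires a true label on every record")
    predicted = [p for _, p in apply_policy(records, policy)]
    return compute_metrics(confusion(truths, predicted, scheme))


@dataclass(frozen=True)
class ComparisonReport:
    """Metrics for several policy configurations, one column per policy."""

    columns: Mapping[str, MetricsReport]
    scheme: GradeScheme
    n: int
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "columns", dict(self.columns))
        if len(self.columns) < 2:
            raise ValueError("a comparison needs at least 2 columns")

    def __getitem__(self, name: str) -> MetricsReport:
        return self.columns[name]

    def to_frame(self) -> pd.DataFrame:
        """Rows = metric/class, columns = policy configurations."""
        frames = {}
        for name, rep in self.columns.items():
            f = rep.to_frame()
            col = {}
            col[("accuracy", "")] = rep.accuracy
            for m in f.index[1:]:
                for c in self.scheme.classes:
                    col[(m, c)] = f.loc[m, c]
            frames[name] = col
        return pd.DataFrame(frames)

    def to_text(self, precision: int = 4) -> str:
        df = self.to_frame()
        lines = ["\t".join(["", *df.columns])]
        for (metric, cls), row in df.iterrows():
            label = f"{metric} {cls}".strip()
            cells = [
                "undefined" if (isinstance(v, float) and math.isnan(v))
                else f"{v:.{precision}f}"
                for v in row
            ]
            lines.append("\t".join([label, *cells]))
        if self.provenance:
            lines.append("# " + json.dumps(self.provenance, sort_keys=True))
        return "\n".join(lines)


def _provenance(scheme: GradeScheme, policies: Sequence[DecisionPolicy],
                n: int) -> dict:
    blob = json.dumps(
        [policy_label(p) for p in policies] + list(scheme.classes), sort_keys=True
    )
    return {
        "artifact_version": __version__,
        "n_records": n,
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:12],
    }


def run_comparison(
    records: Sequence[ProbRecord],
    policies: Sequence[DecisionPolicy],
    scheme: GradeScheme,
) -> ComparisonReport:
    """Evaluate the argmax baseline plus every given policy on one record set.

    The argmax column is labelled "Original" and always present; policies
    keep their configuration labels.
    """
    if not policies:
        raise ValueError("need at least one policy to compare")
    columns: dict[str, MetricsReport] = {}
    all_policies = [ArgmaxPolicy(scheme), *policies]
    for pol in all_policies:
        label = policy_label(pol)
        if label in columns:
            raise ValueError(f"duplicate policy configuration {label!r}")
        columns[label] = evaluate_policy(records, pol, scheme)
    return ComparisonReport(
        columns, scheme, len(records), _provenance(scheme, all_policies, len(records))
    )


@dataclass(frozen=True)
class SweepSpec:
    """A one-dimensional operating-point search.

    ``policy_kind`` is "cascade" (grid values are uniform thresholds for
    all non-fallback classes) or "marginmax" (grid values are margins,
    preference built by boosting ``objective_class``).  The objective is
    ``metric(objective_class) direction target``, e.g.
    sensitivity(Referable DR) >= 0.85.
    """

    policy_kind: str
    grid: tuple[float, ...]
    metric: str = "sensitivity"
    objective_class: str = ""
    direction: str = ">="
    target: float = 0.85
    boost_class: Optional[str] = None  # marginmax preference head; default objective_class

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", tuple(float(g) for g in self.grid))
        if self.policy_kind not in ("cascade", "marginmax"):
            raise ValueError("policy_kind must be 'cascade' or 'marginmax'")
        if not self.grid:
            raise ValueError("empty parameter grid")
        if self.direction not in (">=", "<="):
            raise ValueError("direction must be '>=' or '<='")

    def build_policy(self, value: float, scheme: GradeScheme) -> DecisionPolicy:
        if self.policy_kind == "cascade":
            return CascadingPolicy.uniform(value, scheme)
        boosted = self.boost_class or self.objective_class
        return MarginMaxPolicy.boosting(boosted, value, scheme)


@dataclass(frozen=True)
class SweepResult:
    chosen: float
    objective_met: bool
    report: ComparisonReport


def sweep(
    records: Sequence[ProbRecord], spec: SweepSpec, scheme: GradeScheme
) -> SweepResult:
    """Evaluate the whole grid; pick the best operating point.

    Among parameters meeting the objective, the one maximizing the
    objective class's specificity wins (smallest parameter on ties).  If
    none meets it, the parameter coming closest is returned with
    ``objective_met = False``.
    """
    policies = [spec.build_policy(v, scheme) for v in spec.grid]
    report = run_comparison(records, policies, scheme)
    cls = spec.objective_class or scheme.classes[-1]

    def objective_value(pol: DecisionPolicy) -> float:
        return report[policy_label(pol)].metric(spec.metric, cls)

    def meets(v: float) -> bool:
        return v >= spec.target if spec.direction == ">=" else v <= spec.target

    achieved = [(value, objective_value(pol)) for value, pol in zip(spec.grid, policies)]
    feasible = [(value, obj) for value, obj in achieved if not math.isnan(obj) and meets(obj)]
    if feasible:
        # maximize complementary specificity; ties -> smallest parameter
        def spec_of(value: float) -> float:
            pol = spec.build_policy(value, scheme)
            s = report[policy_label(pol)].per_class[cls]["specificity"]
            return -math.inf if math.isnan(s) else s

        chosen = max(feasible, key=lambda t: (spec_of(t[0]), -t[0]))[0]
        return SweepResult(chosen, True, report)
    # closest to the target in the objective direction
    sign = 1.0 if spec.direction == ">=" else -1.0
    best = max(achieved, key=lambda t: sign * (t[1] if not math.isnan(t[1]) else -math.inf))
    return SweepResult(best[0], False, report)


@dataclass(frozen=True)
class CurationExperiment:
    """Paired un-curated / curated comparison plus the curation outcome."""

    uncurated: ComparisonReport
    curated: Optional[ComparisonReport]  # None when the curated set is empty
    curation: CurationResult

    @property
    def curated_empty(self) -> bool:
        return self.curated is None


def run_curation_experiment(
    records: Sequence[ProbRecord],
    scores: Sequence[QualityScore],
    threshold: float,
    policies: Sequence[DecisionPolicy],
    scheme: GradeScheme,
) -> CurationExperiment:
    """Evaluate identical policies on the full set and its curated subset.

    ``scores`` must cover every record id.  When the curated subset is
    empty (or too small to hold any record) the curated report is None.
    """
    ids = [r.id for r in records]
    curation = curate(ids, scores, threshold)
    uncurated = run_comparison(records, policies, scheme)
    keep = set(curation.curated)
    curated_records = [r for r in records if r.id in keep]
    curated = (
        run_comparison(curated_records, policies, scheme) if curated_records else None
    )
    return CurationExperiment(uncurated, curated, curation)
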