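"""Decision policies mapping class-probability vectors to predicted grades.

A screening classifier ends in a softmax layer producing one probability
per grade.  The default decision is the argmax, but a screening program
can trade accuracy for sensitivity toward a chosen grade by
post-processing the probabilities:

* **Cascading thresholds** scan the grades from most to least severe and
  fire on the first grade whose probability reaches its threshold,
  regardless of the probabilities of less severe grades; if none fires
  the fallback grade (written "~") is returned.  E.g. with thresholds
  (~, 0.3, 0.3) over (Healthy, Non-referable, Referable), a Referable
  probability of 0.3 forces a Referable call.

* **Margin max** overrides the argmax when a preferred ("boosted") grade
  lies within a set margin of the maximum probability: the most-preferred
  grade whose probability is within ``margin`` of the max is returned.
  With margin 0.2 boosting Healthy, the vector (0.3, 0.45, 0.25) is
  called Healthy even though Non-referable is the maximum.

Exact argmax ties are broken toward the more severe grade — the
conservative choice for screening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .grading import GradeScheme

__all__ = [
    "ProbRecord",
    "ArgmaxPolicy",
    "CascadingPolicy",
    "MarginMaxPolicy",
    "DecisionPolicy",
    "decide_argmax",
    "decide_cascading",
    "decide_margin_max",
    "apply_policy",
]

#: Probability vectors are renormalized when |sum - 1| <= this ...
SUM_WARN_TOL = 1e-3
#: ... and accepted silently when within this.
SUM_OK_TOL = 1e-6


@dataclass(frozen=True)
class ProbRecord:
    """One sample's class-probability vector, aligned with a grade scheme.

    Probabilities must be non-negative and sum to one within 1e-6; sums
    off by up to 1e-3 are renormalized with a warning, anything further
    off is rejected.
    """

    id: object
    probs: tuple[float, ...]
    scheme: GradeScheme
    true_label: Optional[str] = None

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=np.float64)
        if probs.ndim != 1 or len(probs) != len(self.scheme):
            raise ValueError(
                f"need {len(self.scheme)} probabilities, got shape {probs.shape}"
            )
        if (probs < 0).any():
            raise ValueError(f"negative probability in record {self.id!r}")
        s = probs.sum()
        if abs(s - 1.0) > SUM_WARN_TOL:
            raise ValueError(
                f"record {self.id!r}: probabilities sum to {s:.6f}, "
                f"beyond the {SUM_WARN_TOL} renormalization tolerance"
            )
        if abs(s - 1.0) > SUM_OK_TOL:
            warnings.warn(
                f"record {self.id!r}: probabilities sum to {s:.6f}; renormalized",
                stacklevel=2,
            )
            probs = probs / s
        object.__setattr__(self, "probs", tuple(float(p) for p in probs))
        if self.true_label is not None and self.true_label not in self.scheme.classes:
            raise ValueError(
                f"true label {self.true_label!r} outside scheme {self.scheme.classes}"
            )

    def prob_of(self, cls: str) -> float:
        return self.probs[self.scheme.index(cls)]


@dataclass(frozen=True)
class ArgmaxPolicy:
    """The plain maximum-probability decision (classifier default)."""

    scheme: GradeScheme

    def decide(self, record: ProbRecord) -> str:
        return decide_argmax(record)


@dataclass(frozen=True)
class CascadingPolicy:
    """Cascading-threshold decision rule.

    ``thresholds`` maps every class except the scheme's fallback class to
    its firing threshold in [0, 1].
    """

    thresholds: Mapping[str, float]
    scheme: GradeScheme

    def __post_init__(self) -> None:
        object.__setattr__(self, "thresholds", dict(self.thresholds))
        expected = set(self.scheme.classes) - {self.scheme.fallback_class}
        if set(self.thresholds) != expected:
            raise ValueError(
                f"thresholds must cover exactly {sorted(expected)}, "
                f"got {sorted(self.thresholds)}"
            )
        for c, t in self.thresholds.items():
            if not 0.0 <= t or not np.isfinite(t):
                raise ValueError(f"invalid threshold {t} for class {c!r}")

    @classmethod
    def uniform(cls, threshold: float, scheme: GradeScheme) -> "CascadingPolicy":
        """The same threshold for every non-fallback class, e.g. (~, t, t)."""
        return cls(
            {c: threshold for c in scheme.classes if c != scheme.fallback_class},
            scheme,
        )

    def decide(self, record: ProbRecord) -> str:
        return decide_cascading(record, self)


@dataclass(frozen=True)
class MarginMaxPolicy:
    """Margin-max decision rule.

    ``preference`` lists the scheme's classes most-preferred first; the
    first class whose probability is within ``margin`` of the global
    maximum wins.  ``boosting(cls)`` builds the conventional preference
    orders: boosting the healthy end puts Healthy first, boosting the
    diseased end prefers classes in descending severity.
    """

    margin: float
    preference: tuple[str, ...]
    scheme: GradeScheme

    def __post_init__(self) -> None:
        object.__setattr__(self, "preference", tuple(self.preference))
        if not 0.0 <= self.margin <= 1.0:
            raise ValueError(f"margin must be in [0, 1], got {self.margin}")
        if sorted(self.preference) != sorted(self.scheme.classes):
            raise ValueError(
                f"preference {self.preference} is not a permutation of "
                f"{self.scheme.classes}"
            )

    @classmethod
    def boosting(
        cls, boosted: str, margin: float, scheme: GradeScheme
    ) -> "MarginMaxPolicy":
        """Preference order for boosting ``boosted``.

        The boosted class comes first; the rest follow by increasing
        severity-distance from it (ties toward the more severe class).
        Boosting the least severe class therefore prefers classes in
        ascending severity — so outside the margin the decision reduces
        to the argmax — and boosting the most severe class prefers them
        in descending severity.
        """
        b = scheme.index(boosted)
        rest = sorted(
            (c for c in scheme.classes if c != boosted),
            key=lambda c: (abs(scheme.index(c) - b), -scheme.index(c)),
        )
        return cls(margin, (boosted, *rest), scheme)

    def decide(self, record: ProbRecord) -> str:
        return decide_margin_max(record, self)


DecisionPolicy = Union[ArgmaxPolicy, CascadingPolicy, MarginMaxPolicy]


def decide_argmax(record: ProbRecord) -> str:
    """Return the class of maximum probability; ties go to the more severe."""
    probs = record.probs
    best = max(range(len(probs)), key=lambda i: (probs[i], i))
    return record.scheme.classes[best]


def decide_cascading(record: ProbRecord, policy: CascadingPolicy) -> str:
    """Scan severest-first; first class whose probability meets its threshold."""
    scheme = policy.scheme
    for cls in scheme.severity_descending():
        if cls == scheme.fallback_class:
            continue
        if record.prob_of(cls) >= policy.thresholds[cls]:
            return cls
    return scheme.fallback_class


def decide_margin_max(record: ProbRecord, policy: MarginMaxPolicy) -> str:
    """Most-preferred class within ``margin`` of the maximum probability.

    The argmax class trivially satisfies the margin condition, so a
    result always exists.
    """
    m_star = max(record.probs)
    for cls in policy.preference:
        if m_star - record.prob_of(cls) <= policy.margin:
            return cls
    raise AssertionError("unreachable: the argmax always meets the margin")


def apply_policy(
    records: Sequence[ProbRecord], policy: DecisionPolicy
) -> list[tuple[object, str]]:
    """Element-wise, order-preserving application of one decision policy."""
    return [(r.id, policy.decide(r)) for r in records]
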