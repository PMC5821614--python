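"""Conformal evaluation measures: validity and efficiency.

Validity is the fraction of prediction sets containing the true label —
a dual ("both") prediction is always correct and an empty prediction is
always incorrect. Efficiency is the fraction of prediction sets that are
single labels. Both are reported overall and conditioned on the true
class, the per-class versions being what the Mondrian calibration
guarantees on exchangeable data.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from ._exceptions import InputError
from .icp import ACTIVE_NAME, INACTIVE_NAME, PValueTable
from .synthlib import ACTIVE, LABEL_NAMES

__all__ = ["ConformalMetrics", "validity", "efficiency", "evaluate_label_sets",
           "metrics_at"]


def _truth_names(truth: Sequence) -> np.ndarray:
    """Normalise truth labels (ints 0/1 or name strings) to name strings."""
    out = []
    for t in truth:
        if isinstance(t, str):
            if t not in (ACTIVE_NAME, INACTIVE_NAME):
                raise InputError(f"unknown label {t!r}")
            out.append(t)
        else:
            out.append(LABEL_NAMES[int(t)])
    return np.array(out, dtype=object)


def validity(
    label_sets: Sequence[frozenset],
    truth: Sequence,
    restrict_to_class: str | None = None,
) -> float:
    """Fraction of prediction sets containing the true label.

    ``restrict_to_class`` conditions on the true label ('active' or
    'inactive'), giving the class-wise validity.
    """
    if len(label_sets) != len(truth):
        raise InputError("label_sets and truth must have equal length")
    names = _truth_names(truth)
    keep = np.ones(len(names), dtype=bool) if restrict_to_class is None \
        else names == restrict_to_class
    if keep.sum() == 0:
        return float("nan")
    hits = sum(1 for s, t, k in zip(label_sets, names, keep) if k and t in s)
    return hits / int(keep.sum())


def efficiency(
    label_sets: Sequence[frozenset],
    truth: Sequence | None = None,
    restrict_to_class: str | None = None,
) -> float:
    """Fraction of prediction sets that are single labels.

    The restricted variant conditions on the true class and therefore
    needs ``truth``.
    """
    if len(label_sets) == 0:
        raise InputError("label_sets must be nonempty")
    if restrict_to_class is None:
        return sum(len(s) == 1 for s in label_sets) / len(label_sets)
    if truth is None:
        raise InputError("restricted efficiency needs truth labels")
    if len(label_sets) != len(truth):
        raise InputError("label_sets and truth must have equal length")
    names = _truth_names(truth)
    keep = names == restrict_to_class
    if keep.sum() == 0:
        return float("nan")
    singles = sum(1 for s, k in zip(label_sets, keep) if k and len(s) == 1)
    return singles / int(keep.sum())


@dataclass(frozen=True)
class ConformalMetrics:
    """Validity/efficiency snapshot plus raw outcome counts."""

    validity_overall: float
    validity_active: float
    validity_inactive: float
    efficiency_overall: float
    efficiency_active: float
    efficiency_inactive: float
    n_single_active: int
    n_single_inactive: int
    n_both: int
    n_empty: int

    @property
    def n_evaluated(self) -> int:
        return self.n_single_active + self.n_single_inactive + self.n_both + self.n_empty

    def to_row(self, **extra) -> dict:
        """Flat dict (one CSV row per dataset/significance)."""
        row = dict(extra)
        row.update(asdict(self))
        return row


def evaluate_label_sets(
    label_sets: Sequence[frozenset], truth: Sequence
) -> ConformalMetrics:
    """All validity/efficiency measures and outcome counts at once."""
    if len(label_sets) == 0:
        raise InputError("label_sets must be nonempty")
    sets = list(label_sets)
    return ConformalMetrics(
        validity_overall=validity(sets, truth),
        validity_active=validity(sets, truth, ACTIVE_NAME),
        validity_inactive=validity(sets, truth, INACTIVE_NAME),
        efficiency_overall=efficiency(sets),
        efficiency_active=efficiency(sets, truth, ACTIVE_NAME),
        efficiency_inactive=efficiency(sets, truth, INACTIVE_NAME),
        n_single_active=sum(s == frozenset({ACTIVE_NAME}) for s in sets),
        n_single_inactive=sum(s == frozenset({INACTIVE_NAME}) for s in sets),
        n_both=sum(len(s) == 2 for s in sets),
        n_empty=sum(len(s) == 0 for s in sets),
    )


def metrics_at(
    pvals: PValueTable, truth: Sequence, significance: float
) -> ConformalMetrics:
    """Metrics of a p-value table at one significance level.

    Compounds with missing (NaN) p-values are excluded.
    """
    truth = np.asarray(truth)
    if len(truth) != len(pvals):
        raise InputError("truth must align with the p-value table")
    mask = pvals.observed_mask
    sets = [s for s, m in zip(pvals.label_sets(significance), mask) if m]
    return evaluate_label_sets(sets, truth[mask])
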