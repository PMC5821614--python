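"""Gain-cost accounting and the significance-level scan.

Screening a compound costs ``screen_cost`` (arbitrary units; defaults 6,
10 and 14 represent cheap biochemical through costly phenotypic assays)
and each confirmed hit is worth ``hit_gain`` (default 400, a level at
which a full unguided screen roughly breaks even at typical hit rates).
The total gain of a two-round campaign is linear in the counts:

    gain = hit_gain * hits_train - screen_cost * screened_train
         + hit_gain * hits_test  - screen_cost * screened_test

The level scan estimates, for each candidate significance level, what
screening the test compounds predicted single-label active would earn,
by scaling the rates observed in internal validation up to the size of
the unscreened remainder. Two baselines complete the option set: screen
everything remaining (at the hit rate observed in the initial screen)
and screen nothing. The decision is the gain-maximising option; if every
option loses money the campaign stops.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._exceptions import InputError, ParameterError
from .icp import PValueTable
from .metrics import ConformalMetrics, evaluate_label_sets
from .synthlib import ACTIVE

__all__ = [
    "DEFAULT_GRID", "GainCostParams", "LevelEvaluation", "GridDecision",
    "total_gain", "evaluate_significance_grid", "decide",
]

#: significance levels matching confidence 90/80/70/60%
DEFAULT_GRID: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4)

#: training-cost-to-indicated-gain ratio beyond which an overall gain is
#: unlikely and the decision carries a warning
LOW_GAIN_WARN_FACTOR = 5.0


@dataclass(frozen=True)
class GainCostParams:
    """Economic parameters: gain per confirmed hit, cost per screened well."""

    hit_gain: float = 400.0
    screen_cost: float = 10.0

    def __post_init__(self) -> None:
        if self.hit_gain <= 0:
            raise ParameterError("hit_gain must be positive")
        if self.screen_cost <= 0:
            raise ParameterError("screen_cost must be positive")


def total_gain(
    n_hits_train: int,
    n_screened_train: int,
    n_hits_test: int,
    n_screened_test: int,
    params: GainCostParams,
) -> float:
    """Total campaign gain: hit gains minus screening costs, both rounds."""
    for hits, screened, name in (
        (n_hits_train, n_screened_train, "train"),
        (n_hits_test, n_screened_test, "test"),
    ):
        if hits < 0 or screened < 0:
            raise InputError(f"{name} counts must be nonnegative")
        if hits > screened:
            raise InputError(f"{name}: hits ({hits}) exceed screened ({screened})")
    return (
        params.hit_gain * n_hits_train
        - params.screen_cost * n_screened_train
        + params.hit_gain * n_hits_test
        - params.screen_cost * n_screened_test
    )


@dataclass
class LevelEvaluation:
    """Outcome of one screening option in the level scan.

    ``kind`` is ``"level"`` for a conformal selection at ``significance``,
    or one of the baselines ``"screen_all"`` / ``"screen_none"``.
    Estimated quantities are scaled to the unscreened remainder;
    ``estimated_total_gain`` adds the (already spent) training-screen
    terms of the gain function.
    """

    kind: str
    significance: float | None
    n_selected: int
    n_hits_selected: int
    n_evaluated: int
    est_screened: float
    est_hits: float
    estimated_test_gain: float
    estimated_total_gain: float
    metrics: ConformalMetrics | None = None

    def to_row(self) -> dict:
        row = {
            "kind": self.kind, "significance": self.significance,
            "n_selected": self.n_selected,
            "n_hits_selected": self.n_hits_selected,
            "n_evaluated": self.n_evaluated,
            "est_screened": self.est_screened, "est_hits": self.est_hits,
            "estimated_test_gain": self.estimated_test_gain,
            "estimated_total_gain": self.estimated_total_gain,
        }
        if self.metrics is not None:
            row.update(
                validity_active=self.metrics.validity_active,
                validity_inactive=self.metrics.validity_inactive,
                efficiency_active=self.metrics.efficiency_active,
                efficiency_inactive=self.metrics.efficiency_inactive,
            )
        return row


def evaluate_significance_grid(
    internal_pvals: PValueTable,
    truth: Sequence,
    grid: Sequence[float],
    params: GainCostParams,
    n_remaining: int,
    n_train: int,
    n_train_hits: int,
) -> list[LevelEvaluation]:
    """Estimate the gain of each candidate policy from internal validation.

    For each significance level the selection is the compounds whose
    prediction set is exactly {active}; the selected fraction and the hit
    fraction among internal-validation compounds are scaled proportionally
    to the ``n_remaining`` unscreened compounds. Appends the screen-all
    baseline (everything remaining screened at the initial screen's hit
    rate) and the screen-none baseline (gain 0). Compounds with missing
    internal p-values are excluded from rate estimation.
    """
    if len(grid) == 0:
        raise ParameterError("significance grid must be nonempty")
    for sig in grid:
        if not 0.0 < sig < 1.0:
            raise ParameterError("grid values must lie in (0, 1)")
    truth = np.asarray(truth)
    if len(truth) != len(internal_pvals):
        raise InputError("truth must align with the internal p-value table")

    mask = internal_pvals.observed_mask
    n_eval = int(mask.sum())
    if n_eval == 0:
        raise InputError("no compound has observed internal p-values")
    is_hit = truth == ACTIVE
    train_gain = params.hit_gain * n_train_hits - params.screen_cost * n_train

    evaluations: list[LevelEvaluation] = []
    for sig in grid:
        selected = internal_pvals.single_active_mask(sig) & mask
        n_sel = int(selected.sum())
        n_hits = int((selected & is_hit).sum())
        est_screened = n_remaining * n_sel / n_eval
        est_hits = n_remaining * n_hits / n_eval
        est_gain = params.hit_gain * est_hits - params.screen_cost * est_screened
        sets = [s for s, m in zip(internal_pvals.label_sets(sig), mask) if m]
        evaluations.append(
            LevelEvaluation(
                kind="level", significance=float(sig),
                n_selected=n_sel, n_hits_selected=n_hits, n_evaluated=n_eval,
                est_screened=est_screened, est_hits=est_hits,
                estimated_test_gain=est_gain,
                estimated_total_gain=train_gain + est_gain,
                metrics=evaluate_label_sets(sets, truth[mask]),
            )
        )

    train_hit_rate = n_train_hits / n_train if n_train else 0.0
    est_hits_all = n_remaining * train_hit_rate
    gain_all = params.hit_gain * est_hits_all - params.screen_cost * n_remaining
    evaluations.append(
        LevelEvaluation(
            kind="screen_all", significance=None,
            n_selected=n_eval, n_hits_selected=int(is_hit[mask].sum()),
            n_evaluated=n_eval, est_screened=float(n_remaining),
            est_hits=est_hits_all, estimated_test_gain=gain_all,
            estimated_total_gain=train_gain + gain_all,
        )
    )
    evaluations.append(
        LevelEvaluation(
            kind="screen_none", significance=None,
            n_selected=0, n_hits_selected=0, n_evaluated=n_eval,
            est_screened=0.0, est_hits=0.0, estimated_test_gain=0.0,
            estimated_total_gain=train_gain,
        )
    )
    return evaluations


@dataclass
class GridDecision:
    """Outcome of the level scan: which policy to apply to the remainder."""

    mode: str  # screen_subset | screen_all | stop
    significance: float | None
    estimated_test_gain: float
    estimated_total_gain: float
    warnings: list[str] = field(default_factory=list)


def decide(evaluations: Sequence[LevelEvaluation]) -> GridDecision:
    """Pick the gain-maximising policy among grid levels and baselines.

    Stops iff no option has a positive estimated test-side gain. Exact
    ties are broken toward the higher-confidence (lower significance)
    level, then toward fewer screened compounds; a conformal selection
    beats the screen-all baseline at equal gain. The training-screen
    terms of the gain function are sunk at decision time and do not enter
    the comparison, but reported totals include them.
    """
    kinds = {ev.kind for ev in evaluations}
    if not {"screen_all", "screen_none"} <= kinds:
        raise InputError("evaluations must include both baselines")

    candidates = [ev for ev in evaluations if ev.kind != "screen_none"]
    best_gain = max(ev.estimated_test_gain for ev in candidates)
    warnings: list[str] = []
    none_ev = next(ev for ev in evaluations if ev.kind == "screen_none")

    if best_gain <= 0:
        return GridDecision(
            mode="stop", significance=None, estimated_test_gain=0.0,
            estimated_total_gain=none_ev.estimated_total_gain,
            warnings=warnings,
        )

    def tie_key(ev: LevelEvaluation) -> tuple:
        sig = ev.significance if ev.kind == "level" else math.inf
        return (sig, ev.est_screened)

    winners = [ev for ev in candidates if ev.estimated_test_gain == best_gain]
    chosen = min(winners, key=tie_key)
    mode = "screen_subset" if chosen.kind == "level" else "screen_all"
    return GridDecision(
        mode=mode,
        significance=chosen.significance,
        estimated_test_gain=chosen.estimated_test_gain,
        estimated_total_gain=chosen.estimated_total_gain,
        warnings=warnings,
    )


def attach_low_gain_warning(
    decision: GridDecision,
    evaluations: Sequence[LevelEvaluation],
    params: GainCostParams,
    n_train: int,
) -> GridDecision:
    """Flag campaigns whose training screen dwarfs the indicated gain.

    When the cost already spent on screening the training set exceeds
    ``LOW_GAIN_WARN_FACTOR`` times the best subset gain indicated by
    internal validation, an overall profit is unlikely even if the subset
    screen itself is profitable.
    """
    level_evals = [ev for ev in evaluations if ev.kind == "level"]
    best_subset_gain = max(
        (ev.estimated_test_gain for ev in level_evals), default=0.0
    )
    train_screen_cost = params.screen_cost * n_train
    if best_subset_gain > 0 and train_screen_cost > LOW_GAIN_WARN_FACTOR * best_subset_gain:
        decision.warnings.append(
            "low expected gain: cost of the initial screen "
            f"({train_screen_cost:.0f}) exceeds {LOW_GAIN_WARN_FACTOR:.0f}x "
            f"the indicated subset gain ({best_subset_gain:.0f}); an overall "
            "profit from further screening is unlikely"
        )
    return decision
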