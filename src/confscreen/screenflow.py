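"""End-to-end iterative screening workflow.

The campaign proceeds in two rounds. First a random 20% of the library
is screened (randomness is what keeps the remaining 80% exchangeable
with the training data, which the conformal validity guarantee needs).
An aggregated conformal predictor is then trained on that initial
screen, its internal leave-out validation supplies per-compound
p-values, and the gain-cost level scan projects the earnings of each
candidate policy onto the unscreened remainder. Three outcomes are
possible: screen the compounds predicted single-label active at the
chosen significance, screen the whole remainder, or stop.

In benchmark mode (the test labels are known) the realized gain of the
chosen policy is computed, along with the oracle best — the maximum
realized gain over every candidate policy — and the regret relative to
it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._exceptions import InputError, StratificationError
from .acp import AcpConfig, acp_internal_validation, acp_predict
from .gaincost import (
    DEFAULT_GRID,
    GainCostParams,
    GridDecision,
    LevelEvaluation,
    attach_low_gain_warning,
    decide,
    evaluate_significance_grid,
    total_gain,
)
from .icp import PValueTable, SplitPlan
from .synthlib import ACTIVE, ScreeningLibrary

__all__ = [
    "ScreeningDecision", "ScreenState", "ScreeningReport", "OracleBest",
    "RegretReport", "prepare_screen", "conclude_screen",
    "run_iterative_screen", "oracle_best_gain", "regret_report",
]


@dataclass
class ScreeningDecision:
    """The workflow's verdict for the second screening round."""

    mode: str  # screen_subset | screen_all | stop
    significance: float | None
    selected_ids: list
    estimated_test_gain: float
    estimated_total_gain: float
    realized_test_gain: float | None = None
    realized_train_gain: float | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.mode == "screen_subset") != (self.significance is not None):
            raise InputError("significance present iff mode is screen_subset")
        if (self.mode == "stop") != (len(self.selected_ids) == 0):
            raise InputError("selected_ids empty iff mode is stop")

    @property
    def realized_total_gain(self) -> float | None:
        if self.realized_test_gain is None or self.realized_train_gain is None:
            return None
        return self.realized_train_gain + self.realized_test_gain

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


@dataclass
class OracleBest:
    """Best realized policy in hindsight: the yardstick for the decision."""

    mode: str
    significance: float | None
    gain: float
    per_level_gains: dict = field(default_factory=dict)


@dataclass
class RegretReport:
    """Loss of the chosen policy relative to the oracle best.

    ``percent_loss`` is 100 * (oracle - realized) / |oracle total gain|
    (training terms included in the denominator). When that total is not
    positive a percentage is meaningless, so ``percent_loss`` is None,
    ``fallback_absolute`` is flagged and only ``absolute_loss`` applies.
    """

    percent_loss: float | None
    absolute_loss: float
    fallback_absolute: bool


@dataclass
class ScreenState:
    """Everything computed before economics enter: splits and p-values."""

    library: ScreeningLibrary
    train_index: np.ndarray
    test_index: np.ndarray
    internal_pvals: PValueTable
    test_pvals: PValueTable
    n_train: int
    n_train_hits: int

    @property
    def train_truth(self) -> np.ndarray:
        return self.library.labels[self.train_index]

    @property
    def test_truth(self) -> np.ndarray:
        return self.library.labels[self.test_index]


@dataclass
class ScreeningReport:
    """Full record of one campaign: decision, scan, and benchmark scores."""

    decision: ScreeningDecision
    evaluations: list[LevelEvaluation]
    state: ScreenState
    oracle: OracleBest | None = None
    regret: RegretReport | None = None
    params: GainCostParams | None = None

    def evaluations_frame(self) -> pd.DataFrame:
        return pd.DataFrame([ev.to_row() for ev in self.evaluations])


def _initial_split(
    library: ScreeningLibrary, plan: SplitPlan, stratify: bool
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(plan.seed)
    n = len(library)
    n_train = int(round(plan.initial_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    if stratify:
        # Stratified draws break exchangeability between rounds and with it
        # the validity guarantee; offered only for tiny benchmark libraries.
        train_parts = []
        for cls in (ACTIVE, 1 - ACTIVE):
            members = np.flatnonzero(library.labels == cls)
            k = max(1, int(round(plan.initial_fraction * members.size)))
            train_parts.append(rng.permutation(members)[:k])
        train_index = np.sort(np.concatenate(train_parts))
    else:
        train_index = np.sort(rng.permutation(n)[:n_train])
    mask = np.ones(n, dtype=bool)
    mask[train_index] = False
    test_index = np.flatnonzero(mask)

    train_labels = library.labels[train_index]
    n_active = int((train_labels == ACTIVE).sum())
    if n_active == 0 or n_active == train_labels.size:
        raise StratificationError(
            "the initial random screen contains a single class only; "
            "use a larger library, or stratify_initial=True at the cost "
            "of the exchangeability-based validity guarantee"
        )
    return train_index, test_index


def prepare_screen(
    library: ScreeningLibrary,
    plan: SplitPlan,
    acp_config: AcpConfig,
    n_trees: int = 500,
    stratify_initial: bool = False,
) -> ScreenState:
    """Initial 20% screen, ACP internal validation, remainder prediction.

    This is the computational bulk of the campaign and is independent of
    the economic parameters, so one state can serve several gain-cost
    settings.
    """
    train_index, test_index = _initial_split(library, plan, stratify_initial)
    train = library.subset(train_index)
    internal = acp_internal_validation(train, acp_config, plan, n_trees=n_trees)
    test_pvals = acp_predict(
        train,
        library.features[test_index],
        acp_config,
        plan,
        n_trees=n_trees,
        new_ids=library.compound_ids[test_index],
    )
    return ScreenState(
        library=library,
        train_index=train_index,
        test_index=test_index,
        internal_pvals=internal,
        test_pvals=test_pvals,
        n_train=len(train),
        n_train_hits=train.n_active,
    )


def conclude_screen(
    state: ScreenState,
    params: GainCostParams,
    grid: Sequence[float] = DEFAULT_GRID,
    benchmark: bool = True,
) -> ScreeningReport:
    """Level scan, decision, selection, and (benchmark mode) realized gain."""
    evaluations = evaluate_significance_grid(
        state.internal_pvals,
        state.train_truth,
        grid,
        params,
        n_remaining=len(state.test_index),
        n_train=state.n_train,
        n_train_hits=state.n_train_hits,
    )
    grid_decision: GridDecision = attach_low_gain_warning(
        decide(evaluations), evaluations, params, state.n_train
    )

    test_ids = state.library.compound_ids[state.test_index]
    if grid_decision.mode == "screen_subset":
        selected_mask = state.test_pvals.single_active_mask(grid_decision.significance)
        selected_ids = list(test_ids[selected_mask])
    elif grid_decision.mode == "screen_all":
        selected_mask = np.ones(len(test_ids), dtype=bool)
        selected_ids = list(test_ids)
    else:
        selected_mask = np.zeros(len(test_ids), dtype=bool)
        selected_ids = []

    decision = ScreeningDecision(
        mode=grid_decision.mode,
        significance=grid_decision.significance,
        selected_ids=selected_ids,
        estimated_test_gain=grid_decision.estimated_test_gain,
        estimated_total_gain=grid_decision.estimated_total_gain,
        warnings=list(grid_decision.warnings),
    )

    oracle = regret = None
    if benchmark:
        test_truth = state.test_truth
        n_sel = int(selected_mask.sum())
        n_hits = int((test_truth[selected_mask] == ACTIVE).sum())
        decision.realized_test_gain = (
            params.hit_gain * n_hits - params.screen_cost * n_sel
        )
        decision.realized_train_gain = total_gain(
            state.n_train_hits, state.n_train, 0, 0, params
        )
        oracle = oracle_best_gain(state.test_pvals, test_truth, grid, params)
        regret = regret_report(decision, oracle)

    return ScreeningReport(
        decision=decision,
        evaluations=evaluations,
        state=state,
        oracle=oracle,
        regret=regret,
        params=params,
    )


def run_iterative_screen(
    library: ScreeningLibrary,
    plan: SplitPlan,
    acp_config: AcpConfig,
    params: GainCostParams,
    grid: Sequence[float] = DEFAULT_GRID,
    n_trees: int = 500,
    stratify_initial: bool = False,
    benchmark: bool = True,
) -> ScreeningReport:
    """The full campaign in one call; reproducible from the seeds alone."""
    state = prepare_screen(
        library, plan, acp_config, n_trees=n_trees,
        stratify_initial=stratify_initial,
    )
    return conclude_screen(state, params, grid, benchmark=benchmark)


def oracle_best_gain(
    test_pvals: PValueTable,
    test_truth: Sequence,
    grid: Sequence[float],
    params: GainCostParams,
) -> OracleBest:
    """Exhaustive realized-gain maximum over every candidate policy.

    Evaluates each grid level (screen the single-label actives it
    selects), screen-all and screen-none on the true test outcomes. The
    workflow's realized gain can never exceed this.
    """
    test_truth = np.asarray(test_truth)
    if len(test_truth) != len(test_pvals):
        raise InputError("test truth must align with the test p-value table")
    is_hit = test_truth == ACTIVE

    gains: dict = {}
    options: list[tuple[str, float | None, float]] = []
    for sig in grid:
        selected = test_pvals.single_active_mask(sig)
        gain = (
            params.hit_gain * int((selected & is_hit).sum())
            - params.screen_cost * int(selected.sum())
        )
        gains[f"level_{sig:g}"] = gain
        options.append(("screen_subset", float(sig), gain))
    gain_all = params.hit_gain * int(is_hit.sum()) - params.screen_cost * len(test_truth)
    gains["screen_all"] = gain_all
    gains["screen_none"] = 0.0
    options.append(("screen_all", None, gain_all))
    options.append(("screen_none", None, 0.0))

    best_gain = max(g for _, _, g in options)
    if best_gain <= 0:
        return OracleBest("screen_none", None, 0.0, gains)
    # mirror the decision tie-breaks: lower significance, subset before all
    winners = [(m, s, g) for m, s, g in options if g == best_gain]
    winners.sort(key=lambda t: (t[1] if t[1] is not None else np.inf))
    mode, sig, gain = winners[0]
    return OracleBest(mode, sig, gain, gains)


def regret_report(decision: ScreeningDecision, oracle: OracleBest) -> RegretReport:
    """Percent loss of the realized gain against the oracle best."""
    if decision.realized_test_gain is None or decision.realized_train_gain is None:
        raise InputError("regret needs realized gains (benchmark mode)")
    diff = oracle.gain - decision.realized_test_gain
    oracle_total = decision.realized_train_gain + oracle.gain
    if oracle_total > 0:
        return RegretReport(
            percent_loss=100.0 * diff / abs(oracle_total),
            absolute_loss=diff,
            fallback_absolute=False,
        )
    return RegretReport(percent_loss=None, absolute_loss=diff, fallback_absolute=True)
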