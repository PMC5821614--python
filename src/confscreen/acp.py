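"""Aggregated conformal predictor: median p-values over resampled ICPs.

A single ICP wastes the calibration split and is sensitive to it; the
aggregated variant refits the ICP many times on freshly resampled
proper/calibration splits and takes, per compound and class, the median
p-value across iterations. Two procedures are provided:

* :func:`acp_predict` — external prediction: every iteration re-splits
  the *full* training data 70/30 and scores the new compounds; medians
  are over all iterations.
* :func:`acp_internal_validation` — leave-out validation on the training
  data itself: every iteration first sets aside a random 20% of the
  training compounds, fits on the remaining 80% (itself split 70/30),
  and scores only the left-out compounds. A compound's medians are over
  exactly the iterations that left it out, which keeps every aggregated
  p-value out-of-sample.

Median aggregation trades the exact finite-sample validity guarantee of
a single ICP for stability; empirically per-class validity still tracks
the confidence level closely on exchangeable data.

Per-iteration seeds are ``seed + iteration`` so that iterations are
individually reproducible and the aggregate is independent of iteration
order. An iteration whose random split leaves a class out of the
calibration set is resampled with a shifted seed (bounded retries).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._exceptions import CalibrationError, FitError, ParameterError
from .icp import ConformityModel, PValueTable, SplitPlan, fit_icp, predict_icp
from .synthlib import ScreeningLibrary

__all__ = ["AcpConfig", "acp_predict", "acp_internal_validation"]

_MAX_RETRIES = 5
_RETRY_STRIDE = 1_000_003  # seed shift per retry; keeps seeds well below 2**31


@dataclass(frozen=True)
class AcpConfig:
    """Aggregation settings: iteration count, leave-out share, seed."""

    n_iterations: int = 100
    leave_out_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ParameterError("n_iterations must be >= 1")
        if not 0.0 < self.leave_out_fraction < 1.0:
            raise ParameterError("leave_out_fraction must lie in (0, 1)")


def _fit_with_retries(
    subset: ScreeningLibrary,
    plan: SplitPlan,
    n_trees: int,
    seed: int,
    mondrian: bool,
    vote_mode: str,
    log: list | None,
) -> ConformityModel:
    last_error: Exception | None = None
    for attempt in range(_MAX_RETRIES):
        try:
            return fit_icp(
                subset, plan, n_trees=n_trees,
                seed=seed + attempt * _RETRY_STRIDE,
                mondrian=mondrian, vote_mode=vote_mode,
            )
        except (CalibrationError, FitError) as exc:
            last_error = exc
            if log is not None:
                log.append({"seed": seed, "attempt": attempt, "error": str(exc)})
    raise CalibrationError(
        f"split resampling failed {_MAX_RETRIES} times (seed {seed}): {last_error}"
    )


def acp_predict(
    train: ScreeningLibrary,
    new_features: np.ndarray,
    config: AcpConfig,
    plan: SplitPlan,
    n_trees: int = 500,
    new_ids: np.ndarray | None = None,
    mondrian: bool = True,
    vote_mode: str = "soft",
    smooth_ties: bool = False,
    iteration_log: list | None = None,
) -> PValueTable:
    """Median-aggregated p-values for new compounds.

    With ``n_iterations=1`` this reduces exactly to a single
    :func:`~confscreen.icp.fit_icp` / :func:`~confscreen.icp.predict_icp`
    pass at the same seed.
    """
    new_features = np.asarray(new_features, dtype=np.float64)
    n_new = new_features.shape[0]
    p_a = np.empty((config.n_iterations, n_new))
    p_i = np.empty((config.n_iterations, n_new))
    for it in range(config.n_iterations):
        model = _fit_with_retries(
            train, plan, n_trees, config.seed + it, mondrian, vote_mode,
            iteration_log,
        )
        table = predict_icp(model, new_features, smooth_ties=smooth_ties)
        p_a[it] = table.p_active
        p_i[it] = table.p_inactive
        if iteration_log is not None:
            iteration_log.append(
                {"iteration": it, "seed": config.seed + it,
                 "n_calib_active": int(model.calib_active.size),
                 "n_calib_inactive": int(model.calib_inactive.size)}
            )
    if new_ids is None:
        new_ids = np.arange(n_new)
    return PValueTable(
        ids=np.asarray(new_ids, dtype=object),
        p_active=np.median(p_a, axis=0),
        p_inactive=np.median(p_i, axis=0),
    )


def acp_internal_validation(
    train: ScreeningLibrary,
    config: AcpConfig,
    plan: SplitPlan,
    n_trees: int = 500,
    mondrian: bool = True,
    vote_mode: str = "soft",
    smooth_ties: bool = False,
    iteration_log: list | None = None,
    return_raw: bool = False,
) -> PValueTable:
    """Leave-out aggregated p-values over the training compounds.

    Each iteration leaves out ``config.leave_out_fraction`` of the
    compounds, fits an ICP on the rest, and scores the left-out part; a
    compound's p-values are medians over its own left-out iterations and
    its contribution count is reported. Compounds never left out (an
    event of probability ``(1 - leave_out)**n_iterations`` each) keep NaN
    p-values and are excluded from downstream estimates.
    """
    n = len(train)
    n_out = max(1, int(round(config.leave_out_fraction * n)))
    per_compound_a: list[list[float]] = [[] for _ in range(n)]
    per_compound_i: list[list[float]] = [[] for _ in range(n)]

    for it in range(config.n_iterations):
        it_seed = config.seed + it
        rng = np.random.default_rng(it_seed)
        left_out = rng.permutation(n)[:n_out]
        mask = np.ones(n, dtype=bool)
        mask[left_out] = False
        model = _fit_with_retries(
            train.subset(mask), plan, n_trees, it_seed, mondrian, vote_mode,
            iteration_log,
        )
        table = predict_icp(model, train.features[left_out], smooth_ties=smooth_ties)
        for j, comp in enumerate(left_out):
            per_compound_a[comp].append(float(table.p_active[j]))
            per_compound_i[comp].append(float(table.p_inactive[j]))
        if iteration_log is not None:
            iteration_log.append(
                {"iteration": it, "seed": it_seed, "n_left_out": int(n_out),
                 "n_calib_active": int(model.calib_active.size),
                 "n_calib_inactive": int(model.calib_inactive.size)}
            )

    p_a = np.full(n, np.nan)
    p_i = np.full(n, np.nan)
    counts = np.zeros(n, dtype=np.int64)
    for comp in range(n):
        counts[comp] = len(per_compound_a[comp])
        if counts[comp]:
            p_a[comp] = np.median(per_compound_a[comp])
            p_i[comp] = np.median(per_compound_i[comp])
    table = PValueTable(
        ids=train.compound_ids, p_active=p_a, p_inactive=p_i,
        n_contributions=counts,
    )
    if return_raw:
        return table, per_compound_a, per_compound_i
    return table
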