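"""Inductive conformal classification on random-forest vote fractions.

The nonconformity design follows the standard HTS recipe: a random-forest
ensemble is fitted on a "proper training" part of the data and the
fraction of trees voting for a class is the conformity score for that
class (higher = more typical). Scores of held-out calibration compounds
form, per true class, an ascending reference list (Mondrian, i.e.
label-conditional calibration — this is what gives per-class validity on
heavily imbalanced screens). A new compound's class-k p-value is the
fraction of the augmented calibration list strictly below its class-k
score:

    p_k = #{calibration scores < score_k} / (n_calibration + 1)

and class k enters the prediction set iff ``p_k >= significance``. The
four possible outcomes are {active}, {inactive}, both, or empty.

Worked example (ten-element augmented lists): a new compound whose
class-1 score lands at position 9 of its augmented list gets p = 8/10 =
0.80, and at position 1 of the class-2 list gets p = 0/10 = 0.0; at
significance 0.20 the prediction set is {class 1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from ._exceptions import CalibrationError, FitError, InputError, ParameterError
from .synthlib import ACTIVE, INACTIVE, LABEL_NAMES, ScreeningLibrary

__all__ = [
    "SplitPlan",
    "ConformityModel",
    "PValueTable",
    "fit_icp",
    "conformity_scores",
    "p_value",
    "assign_label_set",
    "predict_icp",
]

#: the two possible single labels, as they appear inside label sets
ACTIVE_NAME, INACTIVE_NAME = LABEL_NAMES[ACTIVE], LABEL_NAMES[INACTIVE]


@dataclass(frozen=True)
class SplitPlan:
    """Fractions governing the nested data splits.

    ``initial_fraction`` — share of the library screened up front (the
    training data for everything else). ``proper_fraction`` /
    ``calibration_fraction`` — split of the model-building data into
    proper training and calibration (must sum to 1). ``internal_leave_out``
    — share left out per iteration during internal validation.
    """

    initial_fraction: float = 0.2
    proper_fraction: float = 0.7
    calibration_fraction: float = 0.3
    internal_leave_out: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("initial_fraction", "proper_fraction",
                     "calibration_fraction", "internal_leave_out"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ParameterError(f"{name} must lie in (0, 1)")
        if abs(self.proper_fraction + self.calibration_fraction - 1.0) > 1e-9:
            raise ParameterError("proper_fraction + calibration_fraction must equal 1")


@dataclass
class ConformityModel:
    """A fitted ICP: the ensemble plus per-class sorted calibration scores."""

    ensemble: RandomForestClassifier
    calib_active: np.ndarray
    calib_inactive: np.ndarray
    n_features: int
    vote_mode: str = "soft"
    mondrian: bool = True
    proper_index: np.ndarray | None = None
    calib_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calib_active = np.sort(np.asarray(self.calib_active, dtype=np.float64))
        self.calib_inactive = np.sort(np.asarray(self.calib_inactive, dtype=np.float64))
        for name, lst in (("active", self.calib_active), ("inactive", self.calib_inactive)):
            if lst.size == 0:
                raise CalibrationError(f"empty {name} calibration list")
            if lst.min() < 0 or lst.max() > 1:
                raise CalibrationError("calibration scores must lie in [0, 1]")


def _vote_fractions(
    forest: RandomForestClassifier, features: np.ndarray, vote_mode: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class ensemble vote fractions.

    ``soft`` averages per-tree class probabilities (fractions sum to 1).
    ``hard`` counts trees whose leaf has a strict majority for a class;
    trees whose leaf is tied abstain, so fractions may sum to < 1.
    """
    class_col = {c: j for j, c in enumerate(forest.classes_)}
    if vote_mode == "soft":
        proba = forest.predict_proba(features)
        return proba[:, class_col[ACTIVE]], proba[:, class_col[INACTIVE]]
    if vote_mode == "hard":
        votes_a = np.zeros(len(features))
        votes_i = np.zeros(len(features))
        for tree in forest.estimators_:
            p = tree.predict_proba(features)
            pa, pi = p[:, class_col[ACTIVE]], p[:, class_col[INACTIVE]]
            votes_a += pa > pi
            votes_i += pi > pa
        n = len(forest.estimators_)
        return votes_a / n, votes_i / n
    raise ParameterError("vote_mode must be 'soft' or 'hard'")


def fit_icp(
    library_subset: ScreeningLibrary,
    plan: SplitPlan,
    n_trees: int = 500,
    seed: int | None = None,
    mondrian: bool = True,
    vote_mode: str = "soft",
) -> ConformityModel:
    """Fit one inductive conformal predictor on a training library.

    The data are randomly partitioned into proper training
    (``floor(proper_fraction * n)`` compounds) and calibration (the rest);
    the ensemble sees only the proper part, and each calibration
    compound's true-class conformity score enters only its own class's
    reference list (Mondrian). ``mondrian=False`` pools the true-class
    scores of all calibration compounds into one shared list instead.
    """
    if n_trees < 1:
        raise ParameterError("n_trees must be a positive integer")
    if seed is None:
        seed = plan.seed
    n = len(library_subset)
    if n < 2:
        raise FitError("need at least 2 compounds to split")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_proper = int(np.floor(plan.proper_fraction * n))
    proper_idx, calib_idx = perm[:n_proper], perm[n_proper:]

    y = library_subset.labels
    if len(np.unique(y[proper_idx])) < 2:
        raise FitError("a class is absent from the proper training set")
    if (y[calib_idx] == ACTIVE).sum() == 0 or (y[calib_idx] == INACTIVE).sum() == 0:
        raise CalibrationError("a class is absent from the calibration set")

    forest = RandomForestClassifier(
        n_estimators=n_trees,
        random_state=int(rng.integers(2**31 - 1)),
        n_jobs=1,
    )
    forest.fit(library_subset.features[proper_idx], y[proper_idx])

    score_a, score_i = _vote_fractions(
        forest, library_subset.features[calib_idx], vote_mode
    )
    y_cal = y[calib_idx]
    if mondrian:
        calib_active = score_a[y_cal == ACTIVE]
        calib_inactive = score_i[y_cal == INACTIVE]
    else:
        pooled = np.concatenate(
            [score_a[y_cal == ACTIVE], score_i[y_cal == INACTIVE]]
        )
        calib_active = calib_inactive = pooled
    return ConformityModel(
        ensemble=forest,
        calib_active=calib_active,
        calib_inactive=calib_inactive,
        n_features=library_subset.features.shape[1],
        vote_mode=vote_mode,
        mondrian=mondrian,
        proper_index=proper_idx,
        calib_index=calib_idx,
    )


def conformity_scores(
    model: ConformityModel, features: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-compound (score_active, score_inactive) ensemble vote fractions."""
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[1] != model.n_features:
        raise InputError(
            f"feature width {features.shape[-1]} != training width {model.n_features}"
        )
    return _vote_fractions(model.ensemble, features, model.vote_mode)


def p_value(
    score: float | np.ndarray,
    calibration_list: np.ndarray,
    smooth_ties: bool = False,
    rng: np.random.Generator | None = None,
) -> float | np.ndarray:
    """Conformal p-value of a conformity score against a calibration list.

    The new score is placed in the ascending calibration list (augmenting
    it by one) and the fraction of the augmented list strictly below the
    score is returned: ``#{c in list : c < score} / (len(list) + 1)``.
    Calibration scores exactly equal to the new score do not count —
    except under ``smooth_ties``, where each tie contributes 1/2
    (randomised-smoothing in expectation, giving exact rather than
    conservative validity).
    """
    calibration_list = np.asarray(calibration_list, dtype=np.float64)
    if calibration_list.size == 0:
        raise CalibrationError("empty calibration list")
    denom = calibration_list.size + 1
    below = np.searchsorted(calibration_list, score, side="left")
    if smooth_ties:
        upto = np.searchsorted(calibration_list, score, side="right")
        ties = upto - below
        if rng is None:
            below = below + 0.5 * ties
        else:
            below = below + rng.binomial(ties, 0.5)
    result = below / denom
    return float(result) if np.isscalar(score) else result


def assign_label_set(
    p_active: float, p_inactive: float, significance: float
) -> frozenset[str]:
    """Prediction set at a significance level: class k included iff
    its p-value is >= significance (boundary included)."""
    if not 0.0 < significance < 1.0:
        raise ParameterError("significance must lie in (0, 1)")
    labels = set()
    if p_active >= significance:
        labels.add(ACTIVE_NAME)
    if p_inactive >= significance:
        labels.add(INACTIVE_NAME)
    return frozenset(labels)


@dataclass
class PValueTable:
    """Per-compound conformal p-values for the two classes.

    ``n_contributions`` (optional) records, for internal-validation
    tables, how many leave-out iterations contributed to each compound's
    median; compounds never left out carry NaN p-values and are excluded
    from metric and gain estimation rather than fabricated.
    """

    ids: np.ndarray
    p_active: np.ndarray
    p_inactive: np.ndarray
    n_contributions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.p_active = np.asarray(self.p_active, dtype=np.float64)
        self.p_inactive = np.asarray(self.p_inactive, dtype=np.float64)
        n = len(self.ids)
        if self.p_active.shape != (n,) or self.p_inactive.shape != (n,):
            raise InputError("p-value arrays must match the id list")
        for arr in (self.p_active, self.p_inactive):
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise InputError("p-values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def observed_mask(self) -> np.ndarray:
        """True where both p-values are present (not NaN)."""
        return np.isfinite(self.p_active) & np.isfinite(self.p_inactive)

    def membership(self, significance: float) -> tuple[np.ndarray, np.ndarray]:
        """Boolean (in_active, in_inactive) arrays at a significance level.

        NaN p-values yield False in both (the compound predicts nothing).
        """
        if not 0.0 < significance < 1.0:
            raise ParameterError("significance must lie in (0, 1)")
        with np.errstate(invalid="ignore"):
            in_a = self.p_active >= significance
            in_i = self.p_inactive >= significance
        return in_a, in_i

    def label_sets(self, significance: float) -> list[frozenset[str]]:
        in_a, in_i = self.membership(significance)
        out = []
        for a, i in zip(in_a, in_i):
            s = set()
            if a:
                s.add(ACTIVE_NAME)
            if i:
                s.add(INACTIVE_NAME)
            out.append(frozenset(s))
        return out

    def single_active_mask(self, significance: float) -> np.ndarray:
        """Compounds predicted as exactly {active} — the screening picks."""
        in_a, in_i = self.membership(significance)
        return in_a & ~in_i

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"compound_id": self.ids, "p_active": self.p_active,
             "p_inactive": self.p_inactive}
        )
        if self.n_contributions is not None:
            frame["n_contributions"] = self.n_contributions
        return frame

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def predict_icp(
    model: ConformityModel,
    features: np.ndarray,
    ids: Sequence | None = None,
    smooth_ties: bool = False,
) -> PValueTable:
    """Score new compounds with a fitted ICP and return their p-values."""
    score_a, score_i = conformity_scores(model, features)
    if ids is None:
        ids = np.arange(len(score_a))
    return PValueTable(
        ids=np.asarray(ids, dtype=object),
        p_active=p_value(score_a, model.calib_active, smooth_ties=smooth_ties),
        p_inactive=p_value(score_i, model.calib_inactive, smooth_ties=smooth_ties),
    )
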