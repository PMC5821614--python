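"""Synthetic screening libraries with HTS-like statistical structure.

Real iterative-screening benchmarks are large public bioassay screens
(PubChem-scale): tens to
hundreds of thousands of compounds, binary activity labels at hit rates
between roughly 0.3% and 12.5%, and features that are either sparse binary
fingerprints (4096 bits) or dense physicochemical descriptor vectors
(97 columns). This module generates libraries with that shape — sizes,
imbalance, feature sparsity and a tunable activity signal — so that the
conformal screening workflow can be exercised end to end without any
downloads. Rows are i.i.d. (hence exchangeable) by construction, which is
the assumption the conformal validity guarantee rests on.

No attempt is made to imitate chemistry itself (scaffolds, activity
cliffs, assay artefacts); see the package documentation for what that
means for interpreting test results.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from ._exceptions import InputError, ParameterError

__all__ = ["LibrarySpec", "ScreeningLibrary", "generate_library"]

#: integer label codes used throughout the package
ACTIVE, INACTIVE = 1, 0
LABEL_NAMES = {ACTIVE: "active", INACTIVE: "inactive"}


@dataclass(frozen=True)
class LibrarySpec:
    """Parameters of a synthetic screening library.

    Parameters
    ----------
    n_compounds
        Library size.
    hit_rate
        Marginal fraction of actives, in (0, 1). Realistic screens sit
        between 0.003 and 0.125.
    n_features
        Feature width; 4096 mimics folded fingerprints, 97 mimics a
        physicochemical descriptor block.
    feature_kind
        ``"binary"`` (sparse Bernoulli bits) or ``"continuous"``
        (standard-normal descriptors).
    n_informative
        Number of leading features that carry activity signal.
    effect_size
        Log-odds scale of the informative features; 0 means labels are
        independent of the features.
    label_noise
        Probability that a drawn label is flipped, in [0, 0.5).
    binary_density
        Expected fraction of set bits for binary features (fingerprint
        bit densities are a few percent in practice).
    seed
        Seed for the single generator all draws flow from.
    """

    n_compounds: int
    hit_rate: float
    n_features: int = 97
    feature_kind: str = "continuous"
    n_informative: int = 10
    effect_size: float = 0.0
    label_noise: float = 0.0
    binary_density: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ParameterError("n_compounds must be a positive integer")
        if not 0.0 < self.hit_rate < 1.0:
            raise ParameterError("hit_rate must lie in (0, 1)")
        if self.n_features < 1:
            raise ParameterError("n_features must be a positive integer")
        if self.feature_kind not in ("binary", "continuous"):
            raise ParameterError("feature_kind must be 'binary' or 'continuous'")
        if not 0 <= self.n_informative <= self.n_features:
            raise ParameterError("n_informative must lie in [0, n_features]")
        if self.effect_size < 0:
            raise ParameterError("effect_size must be nonnegative")
        if not 0.0 <= self.label_noise < 0.5:
            raise ParameterError("label_noise must lie in [0, 0.5)")
        if not 0.0 < self.binary_density <= 1.0:
            raise ParameterError("binary_density must lie in (0, 1]")


@dataclass
class ScreeningLibrary:
    """A labelled compound library: ids, feature matrix, binary labels.

    ``labels`` uses 1 for active and 0 for inactive. ``provenance`` is the
    generating :class:`LibrarySpec` or the source path for file-loaded
    libraries.
    """

    compound_ids: np.ndarray
    features: np.ndarray
    labels: np.ndarray
    provenance: object = None

    def __post_init__(self) -> None:
        self.compound_ids = np.asarray(self.compound_ids, dtype=object)
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        n = len(self.compound_ids)
        if self.features.ndim != 2 or self.features.shape[0] != n:
            raise InputError("features must be a 2-D matrix with one row per id")
        if self.labels.shape != (n,):
            raise InputError("labels must be one entry per compound")
        if len(set(self.compound_ids)) != n:
            raise InputError("compound ids must be unique")
        if not np.isin(self.labels, (ACTIVE, INACTIVE)).all():
            raise InputError("labels must be binary (1=active, 0=inactive)")

    def __len__(self) -> int:
        return len(self.compound_ids)

    @property
    def n_active(self) -> int:
        return int((self.labels == ACTIVE).sum())

    @property
    def hit_rate(self) -> float:
        return self.n_active / len(self)

    def subset(self, index: np.ndarray) -> "ScreeningLibrary":
        """Row subset by integer or boolean index, keeping provenance."""
        index = np.asarray(index)
        return ScreeningLibrary(
            compound_ids=self.compound_ids[index],
            features=self.features[index],
            labels=self.labels[index],
            provenance=self.provenance,
        )

    # -- plain-text round trip -------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write ``compound_id, label, f_0 … f_{k-1}`` plus a JSON sidecar."""
        path = Path(path)
        frame = pd.DataFrame(
            self.features, columns=[f"f_{j}" for j in range(self.features.shape[1])]
        )
        frame.insert(0, "label", [LABEL_NAMES[v] for v in self.labels])
        frame.insert(0, "compound_id", self.compound_ids)
        frame.to_csv(path, index=False)
        if isinstance(self.provenance, LibrarySpec):
            sidecar = path.with_suffix(path.suffix + ".spec.json")
            sidecar.write_text(json.dumps(dataclasses.asdict(self.provenance), indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ScreeningLibrary":
        frame = pd.read_csv(path)
        required = {"compound_id", "label"}
        if not required.issubset(frame.columns):
            raise InputError(f"library CSV needs columns {sorted(required)}")
        name_to_code = {v: k for k, v in LABEL_NAMES.items()}
        try:
            labels = frame["label"].map(name_to_code).astype(np.int8).to_numpy()
        except (ValueError, TypeError) as exc:
            raise InputError("labels must be 'active' or 'inactive'") from exc
        feat_cols = [c for c in frame.columns if c not in required]
        return cls(
            compound_ids=frame["compound_id"].astype(str).to_numpy(dtype=object),
            features=frame[feat_cols].to_numpy(dtype=np.float64),
            labels=labels,
            provenance=str(path),
        )


def _solve_intercept(linear_score: np.ndarray, hit_rate: float) -> float:
    """Intercept b with mean(sigmoid(b + score)) == hit_rate over the sample."""

    def excess(b: float) -> float:
        return float(expit(b + linear_score).mean() - hit_rate)

    # sigmoid mean is monotone in b; ±60 saturates to 0/1 well past any
    # attainable score, so a root is bracketed.
    return brentq(excess, -60.0, 60.0, xtol=1e-12)


def generate_library(spec: LibrarySpec) -> ScreeningLibrary:
    """Draw a synthetic screening library from ``spec``.

    Features come first (sparse Bernoulli bits or standard normals), then a
    linear activity score over the ``n_informative`` leading columns is
    mapped through a logistic link whose intercept is solved numerically so
    the marginal active probability equals ``hit_rate``. Finally each label
    is flipped independently with probability ``label_noise``. The same
    spec (including seed) reproduces the library bit-exactly.
    """
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_compounds, spec.n_features

    if spec.feature_kind == "binary":
        features = (rng.random((n, k)) < spec.binary_density).astype(np.float64)
    else:
        features = rng.standard_normal((n, k))

    if spec.n_informative > 0 and spec.effect_size > 0:
        weight = spec.effect_size / np.sqrt(spec.n_informative)
        score = features[:, : spec.n_informative].sum(axis=1) * weight
    else:
        score = np.zeros(n)

    intercept = _solve_intercept(score, spec.hit_rate)
    labels = (rng.random(n) < expit(intercept + score)).astype(np.int8)
    flips = rng.random(n) < spec.label_noise
    labels[flips] = 1 - labels[flips]

    width = len(str(n - 1))
    ids = np.array([f"CMP{i:0{width}d}" for i in range(n)], dtype=object)
    return ScreeningLibrary(ids, features, labels, provenance=spec)
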