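"""Hidden binary environments and generation-shared Bernoulli evidence.

The world is a binary feature vector ``x``.  Each generation observes a
block of ``J`` binary outcomes per feature, emitted with probability
``theta1`` when the feature is true and ``theta0`` when it is false.  One
block is drawn per generation and is shared verbatim by every agent of
that generation.  A censoring mask (one per agent) can hide the evidence
for features its companion did not select.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FeatureSpec",
    "EvidenceBlock",
    "InvalidConfigError",
    "sample_truth",
    "generate_evidence",
    "censor_evidence",
]


class InvalidConfigError(ValueError):
    """Raised for structurally invalid environment parameters."""


def _check_prob(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise InvalidConfigError(f"{name} must be in [0, 1], got {value}")
    return value


@dataclass(frozen=True)
class FeatureSpec:
    """A hidden truth vector with its evidence-emission probabilities.

    Parameters
    ----------
    truth
        Binary vector ``x`` of length ``F``.
    theta1
        ``P(y = 1 | x_i = 1)``, applied uniformly to all features.
    theta0
        ``P(y = 1 | x_i = 0)``, applied uniformly to all features.
    """

    truth: np.ndarray
    theta1: float
    theta0: float

    def __post_init__(self) -> None:
        truth = np.asarray(self.truth, dtype=np.int8)
        if truth.ndim != 1 or truth.size < 1:
            raise InvalidConfigError("truth must be a non-empty 1-d vector")
        if not np.isin(truth, (0, 1)).all():
            raise InvalidConfigError("truth entries must be 0 or 1")
        object.__setattr__(self, "truth", truth)
        object.__setattr__(self, "theta1", _check_prob("theta1", self.theta1))
        object.__setattr__(self, "theta0", _check_prob("theta0", self.theta0))

    @property
    def n_features(self) -> int:
        return int(self.truth.size)

    @property
    def emission_probs(self) -> np.ndarray:
        """Per-feature ``P(y = 1)`` implied by the truth vector."""
        return np.where(self.truth == 1, self.theta1, self.theta0)


@dataclass(frozen=True)
class EvidenceBlock:
    """The ``F x J`` outcomes observed at one generation.

    ``generation`` is 1-based and counts blocks, matching the time index
    of the emission model.  All agents of the observing generation share
    the block bit-for-bit.
    """

    generation: int
    outcomes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        outcomes = np.asarray(self.outcomes, dtype=np.int8)
        if outcomes.ndim != 2:
            raise InvalidConfigError("outcomes must be an F x J matrix")
        if outcomes.size and not np.isin(outcomes, (0, 1)).all():
            raise InvalidConfigError("outcomes must be binary")
        object.__setattr__(self, "outcomes", outcomes)
        if self.generation < 1:
            raise InvalidConfigError("generation index is 1-based")

    @property
    def n_features(self) -> int:
        return int(self.outcomes.shape[0])

    @property
    def n_observations(self) -> int:
        return int(self.outcomes.shape[1])

    @property
    def positive_counts(self) -> np.ndarray:
        """Per-feature count of positive outcomes ``S_t``."""
        return self.outcomes.sum(axis=1, dtype=np.int64)


def sample_truth(n_features: int, rng: np.random.Generator) -> np.ndarray:
    """Draw a uniform-random binary truth vector.

    Each entry is independently 1 with probability 0.5.
    """
    if n_features < 1:
        raise InvalidConfigError(f"n_features must be >= 1, got {n_features}")
    return rng.integers(0, 2, size=n_features).astype(np.int8)


def generate_evidence(
    spec: FeatureSpec, J: int, T: int, rng: np.random.Generator
) -> list[EvidenceBlock]:
    """Draw ``T`` independent evidence blocks of ``J`` outcomes per feature.

    Outcomes are iid Bernoulli across features, observations and
    generations; row ``i`` uses ``theta1`` when ``truth[i] == 1`` and
    ``theta0`` otherwise.
    """
    if J < 0:
        raise InvalidConfigError(f"J must be >= 0, got {J}")
    if T < 1:
        raise InvalidConfigError(f"T must be >= 1, got {T}")
    probs = spec.emission_probs[:, None]
    blocks = []
    for t in range(1, T + 1):
        outcomes = (rng.random((spec.n_features, J)) < probs).astype(np.int8)
        blocks.append(EvidenceBlock(generation=t, outcomes=outcomes))
    return blocks


def censor_evidence(
    block: EvidenceBlock, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Apply a per-feature visibility mask to one evidence block.

    Returns ``(S_eff, J_eff)`` vectors of length ``F``: features with
    ``mask == 1`` keep their positive count and observation count,
    features with ``mask == 0`` carry no evidence at all.
    """
    mask = np.asarray(mask)
    if mask.shape != (block.n_features,):
        raise InvalidConfigError(
            f"mask has shape {mask.shape}, expected ({block.n_features},)"
        )
    mask = mask.astype(np.int64)
    s_eff = block.positive_counts * mask
    j_eff = np.full(block.n_features, block.n_observations, dtype=np.int64) * mask
    return s_eff, j_eff
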