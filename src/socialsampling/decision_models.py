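"""The six decision rules and their analytic one-step-ahead predictions.

Three asocial rules act on the current evidence block alone:

* ``nonsocial_matching`` — choose 1 with probability ``S/J``;
* ``nonsocial_bayes_matching`` — choose 1 with the uniform-prior posterior
  probability of the current block;
* ``nonsocial_utility_max`` — choose the posterior mode (fair coin on ties).

Three social rules consult a uniformly sampled member of the previous
generation:

* ``naive_copy`` — adopt the companion's decision unconditionally;
* ``social_sampling_bayes`` — accept the companion's decision with
  probability proportional to the likelihood of the current evidence
  under that decision, resampling companions until acceptance;
* ``social_sampling_matching`` — same loop, but the acceptance
  probability is the fraction of recent positive evidence (``S/J`` for
  belief 1, ``(J-S)/J`` for belief 0).

The resample-until-accept loop has a closed-form marginal: with
companion popularity ``p`` and acceptance weights ``a1, a0``, the
accepted belief is 1 with probability ``p*a1 / (p*a1 + (1-p)*a0)``.  For
the Bayesian weights this is exactly a posterior update that uses the
popularity as prior.  The two social-sampling rules optionally mix with
their like-named asocial rule via a social proportion ``rho``.

The exact acceptance forms of the asocial rules and of the matching rule
for belief 0 are reconstructions: the fractions stated for belief 1 are
applied symmetrically to belief 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MODEL_IDS",
    "SOCIAL_MODELS",
    "ASOCIAL_MODELS",
    "ASOCIAL_PARTNER",
    "ModelConfig",
    "DegenerateEvidenceError",
    "likelihood",
    "acceptance_probability",
    "matching_acceptance",
    "acceptance_weights",
    "accept_marginal",
    "social_update_closed_form",
    "social_sampling_decision",
    "asocial_decision",
    "asocial_choice_probability",
    "single_block_posterior",
    "predicted_popularity",
]

MODEL_IDS = (
    "nonsocial_matching",
    "nonsocial_bayes_matching",
    "nonsocial_utility_max",
    "naive_copy",
    "social_sampling_matching",
    "social_sampling_bayes",
)
ASOCIAL_MODELS = MODEL_IDS[:3]
SOCIAL_MODELS = MODEL_IDS[3:]

# Each social-sampling rule mixes with the asocial rule of its own
# strategy family; naive copying is pure.
ASOCIAL_PARTNER = {
    "social_sampling_bayes": "nonsocial_bayes_matching",
    "social_sampling_matching": "nonsocial_matching",
}


class DegenerateEvidenceError(ZeroDivisionError):
    """Both candidate beliefs have zero likelihood (or zero acceptance)."""


@dataclass(frozen=True)
class ModelConfig:
    """A decision-model id with its free parameters.

    ``social_proportion`` (rho) applies only to the two social-sampling
    models; ``max_resamples`` caps their accept/reject loop, after which
    the last sampled companion's decision is adopted.
    """

    model_id: str
    social_proportion: float = 1.0
    max_resamples: int = 1000

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(
                f"unknown model_id {self.model_id!r}; expected one of {MODEL_IDS}"
            )
        if not 0.0 <= self.social_proportion <= 1.0:
            raise ValueError("social_proportion must be in [0, 1]")
        if self.max_resamples < 1:
            raise ValueError("max_resamples must be >= 1")


def _validate_counts(S, J) -> tuple[np.ndarray, np.ndarray]:
    S = np.asarray(S, dtype=float)
    J = np.asarray(J, dtype=float)
    if np.any(J < 0):
        raise ValueError("J must be >= 0")
    if np.any(S < 0) or np.any(S > J):
        raise ValueError("S must satisfy 0 <= S <= J")
    return S, J


def likelihood(d, S, J, theta1: float, theta0: float):
    """Bernoulli-block likelihood ``theta_d**S * (1 - theta_d)**(J - S)``."""
    S, J = _validate_counts(S, J)
    d = np.asarray(d)
    theta = np.where(d == 1, theta1, theta0)
    out = theta**S * (1.0 - theta) ** (J - S)
    return out if out.ndim else float(out)


def acceptance_weights(kind: str, S, J, theta1: float, theta0: float):
    """Acceptance probabilities ``(a1, a0)`` for companion beliefs 1 and 0.

    ``kind='bayes'`` normalizes the two likelihoods by their maximum (the
    normalizer is a free constant; this choice minimizes loop length).
    ``kind='matching'`` uses the recent-positive-evidence fractions.
    ``J = 0`` entries are uninformative and accept either belief, which
    collapses the loop to naive copying.
    """
    S, J = _validate_counts(S, J)
    if kind == "bayes":
        l1 = likelihood(np.int8(1), S, J, theta1, theta0)
        l0 = likelihood(np.int8(0), S, J, theta1, theta0)
        m = np.maximum(l1, l0)
        if np.any(m == 0.0):
            raise DegenerateEvidenceError(
                "both beliefs have zero likelihood; theta in {0,1} contradicts S"
            )
        return l1 / m, l0 / m
    if kind == "matching":
        with np.errstate(invalid="ignore", divide="ignore"):
            a1 = np.where(J > 0, S / np.where(J > 0, J, 1.0), 1.0)
            a0 = np.where(J > 0, (J - S) / np.where(J > 0, J, 1.0), 1.0)
        return a1, a0
    raise ValueError(f"unknown acceptance kind {kind!r}")


def acceptance_probability(d_companion, S, J, theta1: float, theta0: float):
    """Probability of accepting the companion's belief in one loop round.

    Proportional to the likelihood of the current evidence under the
    companion's belief, normalized by the larger of the two likelihoods
    so the better-supported belief is always accepted.
    """
    a1, a0 = acceptance_weights("bayes", S, J, theta1, theta0)
    out = np.where(np.asarray(d_companion) == 1, a1, a0)
    return out if out.ndim else float(out)


def matching_acceptance(d_companion, S, J):
    """Probability-matching acceptance: ``S/J`` for belief 1, ``(J-S)/J`` for 0."""
    a1, a0 = acceptance_weights("matching", S, J, 0.5, 0.5)
    out = np.where(np.asarray(d_companion) == 1, a1, a0)
    return out if out.ndim else float(out)


def accept_marginal(p_prev, a1, a0):
    """Stationary marginal of resample-until-accept with weights ``a1, a0``.

    Returns ``p*a1 / (p*a1 + (1-p)*a0)``; unanimous populations are
    absorbing regardless of the weights.
    """
    p = np.asarray(p_prev, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p_prev must be in [0, 1]")
    a1 = np.asarray(a1, dtype=float)
    a0 = np.asarray(a0, dtype=float)
    num = p * a1
    den = num + (1.0 - p) * a0
    boundary = (p == 0.0) | (p == 1.0)
    if np.any((den == 0.0) & ~boundary):
        raise DegenerateEvidenceError("acceptance marginal is 0/0")
    out = np.where(boundary, p, num / np.where(den == 0.0, 1.0, den))
    return out if out.ndim else float(out)


def social_update_closed_form(p_prev, S, J, theta1: float, theta0: float):
    """Posterior-style update of the previous popularity by one block.

    ``p*L1 / (p*L1 + (1-p)*L0)`` — the marginal accept-state probability
    of the Bayesian social-sampling chain with companion prior ``p``.
    """
    l1 = likelihood(np.int8(1), S, J, theta1, theta0)
    l0 = likelihood(np.int8(0), S, J, theta1, theta0)
    return accept_marginal(p_prev, l1, l0)


def social_sampling_decision(
    prev_decisions: np.ndarray,
    S: int,
    J: int,
    theta1: float,
    theta0: float,
    max_resamples: int = 1000,
    rng: np.random.Generator | None = None,
    kind: str = "bayes",
) -> int:
    """One agent's resample-until-accept decision for a single feature.

    Samples companions uniformly with replacement from ``prev_decisions``
    and accepts via the configured acceptance rule.  If the cap is hit
    the last sampled companion's decision is adopted.
    """
    if rng is None:
        rng = np.random.default_rng()
    prev = np.asarray(prev_decisions)
    if prev.size < 1:
        raise ValueError("previous generation must contain at least one agent")
    a1, a0 = acceptance_weights(kind, S, J, theta1, theta0)
    d = 0
    for _ in range(max_resamples):
        d = int(prev[rng.integers(prev.size)])
        if rng.random() < (a1 if d == 1 else a0):
            return d
    return d  # cap hit: fall back to the last sampled companion


def single_block_posterior(S, J, theta1: float, theta0: float):
    """Uniform-prior posterior that the feature is true, from one block."""
    l1 = likelihood(np.int8(1), S, J, theta1, theta0)
    l0 = likelihood(np.int8(0), S, J, theta1, theta0)
    den = np.asarray(l1 + l0, dtype=float)
    if np.any(den == 0.0):
        raise DegenerateEvidenceError("both hypotheses have zero likelihood")
    out = l1 / den
    return out if np.ndim(out) else float(out)


def asocial_choice_probability(model_id: str, S, J, theta1: float, theta0: float):
    """P(decision = 1) for an asocial rule given the current block."""
    S_a, J_a = _validate_counts(S, J)
    if model_id == "nonsocial_matching":
        with np.errstate(invalid="ignore"):
            out = np.where(J_a > 0, S_a / np.where(J_a > 0, J_a, 1.0), 0.5)
    elif model_id == "nonsocial_bayes_matching":
        out = np.asarray(single_block_posterior(S, J, theta1, theta0))
    elif model_id == "nonsocial_utility_max":
        post = np.asarray(single_block_posterior(S, J, theta1, theta0))
        out = np.where(post > 0.5, 1.0, np.where(post < 0.5, 0.0, 0.5))
    else:
        raise ValueError(f"{model_id!r} is not an asocial model")
    return out if out.ndim else float(out)


def asocial_decision(
    model_id: str, S, J, theta1: float, theta0: float, rng: np.random.Generator
):
    """Draw a binary decision from an asocial rule's choice probability."""
    prob = np.asarray(asocial_choice_probability(model_id, S, J, theta1, theta0))
    out = (rng.random(prob.shape) < prob).astype(np.int8)
    return out if out.ndim else int(out)


def predicted_popularity(
    model_id: str,
    p_prev,
    S,
    J,
    theta1: float,
    theta0: float,
    rho: float = 1.0,
):
    """Analytic expectation of the next generation's popularity.

    Social-sampling models predict a ``rho``-weighted mixture of their
    accept-loop closed form and their asocial partner's choice
    probability; naive copying predicts the previous popularity; asocial
    models predict their own Bernoulli parameter.
    """
    if model_id == "naive_copy":
        p = np.asarray(p_prev, dtype=float)
        return p if p.ndim else float(p)
    if model_id in ASOCIAL_MODELS:
        return asocial_choice_probability(model_id, S, J, theta1, theta0)
    if model_id in ("social_sampling_bayes", "social_sampling_matching"):
        kind = "bayes" if model_id == "social_sampling_bayes" else "matching"
        a1, a0 = acceptance_weights(kind, S, J, theta1, theta0)
        social = np.asarray(accept_marginal(p_prev, a1, a0), dtype=float)
        partner = ASOCIAL_PARTNER[model_id]
        asocial = np.asarray(
            asocial_choice_probability(partner, S, J, theta1, theta0)
        )
        out = rho * social + (1.0 - rho) * asocial
        return out if out.ndim else float(out)
    raise ValueError(f"unknown model_id {model_id!r}")
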