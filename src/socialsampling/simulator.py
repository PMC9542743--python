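"""Multigenerational network simulation.

Populations are organized in discrete generations of ``N`` agents.  Each
generation shares one evidence block and (from the second generation on)
observes the decisions of uniformly sampled members of the previous
generation.  Two timing regimes are supported:

* ``evidence_timing='current'`` — agents at generation ``t`` decide
  using the block emitted at ``t`` (own lab results); the first
  generation applies an asocial rule to its own block.
* ``evidence_timing='previous'`` — agents at generation ``t`` decide
  using the block emitted at ``t - 1`` (feedback on the previous
  generation's designs); the first generation guesses uniformly.  This
  regime is normally combined with censoring: each agent's evidence is
  masked by its companion's decision vector, so features the companion
  did not select carry no evidence.

Companion sampling is uniform with replacement.  Trials are independent
feature sets with fresh truths and evidence.  All randomness flows from
one root seed through named substreams, so runs are exactly
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .decision_models import (
    ASOCIAL_MODELS,
    ASOCIAL_PARTNER,
    ModelConfig,
    acceptance_weights,
    asocial_choice_probability,
)
from .environment import (
    EvidenceBlock,
    FeatureSpec,
    InvalidConfigError,
    generate_evidence,
    sample_truth,
)
from .metrics import ideal_posterior

__all__ = [
    "ExperimentConfig",
    "GenerationRecord",
    "TrialResult",
    "ExperimentResult",
    "PRESET_NAMES",
    "preset_config",
    "run_generation",
    "run_trial",
    "run_experiment",
    "run_condition_suite",
    "convergence_report",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Full description of one simulated experiment."""

    n_networks: int
    n_generations: int
    n_agents: int
    n_features: int
    n_evidence: int
    theta1: float
    theta0: float
    model: ModelConfig
    censored: bool = False
    evidence_timing: str = "current"  # 'current' or 'previous'
    gen0: str = "asocial"  # 'asocial' or 'guess'
    gen0_model: str = "nonsocial_bayes_matching"
    n_trials: int = 1
    seed: int = 0
    condition: str = "custom"

    def __post_init__(self) -> None:
        for name in ("n_networks", "n_generations", "n_agents", "n_features",
                     "n_trials"):
            if getattr(self, name) < 1:
                raise InvalidConfigError(f"{name} must be >= 1")
        if self.n_evidence < 0:
            raise InvalidConfigError("n_evidence must be >= 0")
        if self.evidence_timing not in ("current", "previous"):
            raise InvalidConfigError("evidence_timing must be 'current' or 'previous'")
        if self.gen0 not in ("asocial", "guess"):
            raise InvalidConfigError("gen0 must be 'asocial' or 'guess'")
        if self.gen0_model not in ASOCIAL_MODELS:
            raise InvalidConfigError(f"gen0_model must be one of {ASOCIAL_MODELS}")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["model"] = {
            "model_id": self.model.model_id,
            "social_proportion": self.model.social_proportion,
            "max_resamples": self.model.max_resamples,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        m = d.pop("model")
        if isinstance(m, dict):
            m = ModelConfig(**m)
        elif isinstance(m, str):
            m = ModelConfig(m)
        return cls(model=m, **d)


# Experiment-2 condition table: (reps, N, J, theta).  theta is symmetric
# evidence strength: theta1 = theta, theta0 = 1 - theta.
_EXP2_CONDITIONS = {
    "exp2-c1": (2, 20, 4, 0.6),
    "exp2-c2": (1, 20, 1, 0.6),
    "exp2-c3": (1, 20, 4, 0.8),
    "exp2-c4": (2, 5, 4, 0.6),
    "exp2-c5": (2, 5, 1, 0.6),
}

PRESET_NAMES = ("exp1",) + tuple(_EXP2_CONDITIONS)


def preset_config(
    name: str, model: ModelConfig, seed: int = 0, **overrides
) -> ExperimentConfig:
    """Build a built-in experiment layout around a decision model.

    ``exp1``: 3 networks x 10 generations x 20 agents, 8 features, J=4,
    theta1=0.6 / theta0=0.3, uncensored, asocial first generation, 2
    trials.  ``exp2-c1``..``exp2-c5``: 10 generations, 8 features, 4
    trials, censored previous-generation feedback, guessing first
    generation, with (reps, N, J, theta) from the condition table.
    """
    if name == "exp1":
        cfg = ExperimentConfig(
            n_networks=3, n_generations=10, n_agents=20, n_features=8,
            n_evidence=4, theta1=0.6, theta0=0.3, model=model,
            censored=False, evidence_timing="current", gen0="asocial",
            n_trials=2, seed=seed, condition="exp1",
        )
    elif name in _EXP2_CONDITIONS:
        reps, n_agents, n_evidence, theta = _EXP2_CONDITIONS[name]
        cfg = ExperimentConfig(
            n_networks=reps, n_generations=10, n_agents=n_agents,
            n_features=8, n_evidence=n_evidence,
            theta1=theta, theta0=1.0 - theta, model=model,
            censored=True, evidence_timing="previous", gen0="guess",
            n_trials=4, seed=seed, condition=name,
        )
    else:
        raise InvalidConfigError(
            f"unknown preset {name!r}; expected one of {PRESET_NAMES}"
        )
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class GenerationRecord:
    """One generation's decisions and bookkeeping.

    ``companions`` are indices into the previous generation (-1 when no
    companion was sampled); ``masks`` are per-agent evidence-visibility
    vectors (all ones when uncensored); ``evidence_generation`` is the
    1-based id of the block the deciders used (0 when none).
    """

    generation: int
    decisions: np.ndarray
    companions: np.ndarray
    masks: np.ndarray
    resamples: np.ndarray
    evidence_generation: int

    @property
    def n_agents(self) -> int:
        return int(self.decisions.shape[0])

    @property
    def popularity(self) -> np.ndarray:
        return self.decisions.mean(axis=0)


def _accept_loop(prev_decisions, comp0, a1, a0, max_resamples, rng):
    """Vectorized resample-until-accept over an (n_agents, F) grid.

    Round one reuses the pre-drawn companion ``comp0`` for every feature
    of an agent; later rounds draw fresh companions per cell.  Cells
    still active at the cap adopt the last sampled companion's decision.
    """
    n_prev, n_feat = prev_decisions.shape
    n = comp0.size
    feat_idx = np.arange(n_feat)[None, :]
    comp = np.broadcast_to(comp0[:, None], (n, n_feat)).copy()
    decisions = np.zeros((n, n_feat), dtype=np.int8)
    resamples = np.zeros((n, n_feat), dtype=np.int32)
    active = np.ones((n, n_feat), dtype=bool)
    a1 = np.broadcast_to(a1, (n, n_feat))
    a0 = np.broadcast_to(a0, (n, n_feat))
    for _ in range(max_resamples):
        d = prev_decisions[comp, feat_idx]
        acc = np.where(d == 1, a1, a0)
        accept = active & (rng.random((n, n_feat)) < acc)
        decisions[accept] = d[accept]
        resamples[active] += 1
        active &= ~accept
        if not active.any():
            break
        fresh = rng.integers(0, n_prev, size=(n, n_feat))
        comp = np.where(active, fresh, comp)
    if active.any():  # cap hit: copy the last sampled companion
        d = prev_decisions[comp, feat_idx]
        decisions[active] = d[active]
    return decisions, resamples


def run_generation(
    prev: GenerationRecord | None,
    evidence: EvidenceBlock | None,
    config: ExperimentConfig,
    rng: np.random.Generator,
) -> GenerationRecord:
    """Advance the network by one generation.

    ``evidence`` is the block the deciders consult (None only for a
    guessing first generation).  The first generation (``prev is None``)
    uses the configured asocial rule or uniform guessing; later
    generations apply the configured decision model.
    """
    n, f = config.n_agents, config.n_features
    model = config.model
    if evidence is not None and evidence.n_features != f:
        raise InvalidConfigError("evidence block does not match n_features")

    if prev is None:
        companions = np.full(n, -1, dtype=np.int64)
        masks = np.ones((n, f), dtype=np.int8)
        resamples = np.zeros((n, f), dtype=np.int32)
        if config.gen0 == "guess":
            decisions = rng.integers(0, 2, size=(n, f)).astype(np.int8)
            ev_gen = 0
        else:
            if evidence is None:
                raise InvalidConfigError("asocial first generation needs evidence")
            s = evidence.positive_counts
            j = evidence.n_observations
            prob = np.asarray(
                asocial_choice_probability(
                    config.gen0_model, s, np.full(f, j), config.theta1, config.theta0
                )
            )
            decisions = (rng.random((n, f)) < prob[None, :]).astype(np.int8)
            ev_gen = evidence.generation
        return GenerationRecord(0, decisions, companions, masks, resamples, ev_gen)

    if evidence is None:
        raise InvalidConfigError("social generations need an evidence block")
    if prev.decisions.shape != (prev.n_agents, f):
        raise InvalidConfigError("previous decisions do not match n_features")

    s_block = evidence.positive_counts
    j_block = evidence.n_observations
    needs_companion = config.censored or model.model_id not in ASOCIAL_MODELS
    if needs_companion:
        comp0 = rng.integers(0, prev.n_agents, size=n)
    else:
        comp0 = np.full(n, -1, dtype=np.int64)
    if config.censored:
        masks = prev.decisions[comp0].astype(np.int8)
    else:
        masks = np.ones((n, f), dtype=np.int8)
    # effective per-agent evidence after censoring
    s_eff = masks.astype(np.int64) * s_block[None, :]
    j_eff = masks.astype(np.int64) * j_block
    resamples = np.zeros((n, f), dtype=np.int32)

    if model.model_id == "naive_copy":
        decisions = prev.decisions[comp0].astype(np.int8)
    elif model.model_id in ASOCIAL_MODELS:
        prob = np.asarray(
            asocial_choice_probability(
                model.model_id, s_eff, j_eff, config.theta1, config.theta0
            )
        )
        decisions = (rng.random((n, f)) < prob).astype(np.int8)
    else:
        kind = "bayes" if model.model_id == "social_sampling_bayes" else "matching"
        a1, a0 = acceptance_weights(kind, s_eff, j_eff, config.theta1, config.theta0)
        rho = model.social_proportion
        social = rng.random(n) < rho if rho < 1.0 else np.ones(n, dtype=bool)
        decisions, resamples = _accept_loop(
            prev.decisions, comp0, a1, a0, model.max_resamples, rng
        )
        if not social.all():
            partner = ASOCIAL_PARTNER[model.model_id]
            prob = np.asarray(
                asocial_choice_probability(
                    partner, s_eff, j_eff, config.theta1, config.theta0
                )
            )
            aso = (rng.random((n, f)) < prob).astype(np.int8)
            idx = ~social
            decisions[idx] = aso[idx]
            resamples[idx] = 0
            companions_out = comp0.copy()
            companions_out[idx] = -1
            comp0 = companions_out
    return GenerationRecord(
        prev.generation + 1, decisions, comp0, masks, resamples,
        evidence.generation,
    )


@dataclass
class TrialResult:
    """One transmission chain: a truth, its evidence stream, and records."""

    network: int
    trial: int
    spec: FeatureSpec
    blocks: list[EvidenceBlock]
    records: list[GenerationRecord]


def _substream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def run_trial(config: ExperimentConfig, network: int, trial: int) -> TrialResult:
    """Simulate one chain of ``n_generations`` for one (network, trial)."""
    truth_rng = _substream(config.seed, network, trial, 0)
    evidence_rng = _substream(config.seed, network, trial, 1)
    agent_rng = _substream(config.seed, network, trial, 2)

    truth = sample_truth(config.n_features, truth_rng)
    spec = FeatureSpec(truth=truth, theta1=config.theta1, theta0=config.theta0)
    blocks = generate_evidence(
        spec, config.n_evidence, config.n_generations, evidence_rng
    )

    records: list[GenerationRecord] = []
    prev = None
    for t in range(config.n_generations):
        if config.evidence_timing == "current":
            ev = blocks[t]
        else:
            ev = blocks[t - 1] if t >= 1 else None
        prev = run_generation(prev, ev, config, agent_rng)
        records.append(prev)
    return TrialResult(network, trial, spec, blocks, records)


@dataclass
class ExperimentResult:
    """All chains of one experiment plus frame/trajectory exporters."""

    config: ExperimentConfig
    trials: list[TrialResult] = field(default_factory=list)

    def decisions_frame(self) -> pd.DataFrame:
        rows = []
        for tr in self.trials:
            for rec in tr.records:
                n, f = rec.decisions.shape
                agent, feat = np.meshgrid(np.arange(n), np.arange(f), indexing="ij")
                rows.append(pd.DataFrame({
                    "network": tr.network,
                    "condition": self.config.condition,
                    "trial": tr.trial,
                    "generation": rec.generation,
                    "agent": agent.ravel(),
                    "feature": feat.ravel(),
                    "decision": rec.decisions.ravel(),
                    "companion_agent": np.repeat(rec.companions, f),
                    "resampled_count": rec.resamples.ravel(),
                }))
        return pd.concat(rows, ignore_index=True)

    def evidence_frame(self) -> pd.DataFrame:
        rows = []
        for tr in self.trials:
            for block in tr.blocks:
                f, j = block.outcomes.shape
                feat, test = np.meshgrid(np.arange(f), np.arange(j), indexing="ij")
                rows.append(pd.DataFrame({
                    "network": tr.network,
                    "condition": self.config.condition,
                    "trial": tr.trial,
                    "generation": block.generation,
                    "feature": feat.ravel(),
                    "test_index": test.ravel(),
                    "outcome": block.outcomes.ravel(),
                }))
        return pd.concat(rows, ignore_index=True)

    def trajectory_frame(self) -> pd.DataFrame:
        """Per (network, trial, feature, generation) accumulation summary.

        ``s_cum`` / ``tj_cum`` count the evidence observed by the whole
        population up to and including the block the deciders used;
        ``ideal_posterior`` is the uniform-prior posterior given that
        evidence.
        """
        cfg = self.config
        j = cfg.n_evidence
        rows = []
        for tr in self.trials:
            s_by_block = np.stack([b.positive_counts for b in tr.blocks])
            cum = np.cumsum(s_by_block, axis=0)
            for rec in tr.records:
                g = rec.generation
                n_blocks = rec.evidence_generation  # blocks observed so far
                if n_blocks > 0:
                    s_cum = cum[n_blocks - 1]
                    s_last = s_by_block[n_blocks - 1]
                    j_last = j
                else:
                    s_cum = np.zeros(cfg.n_features, dtype=np.int64)
                    s_last = np.zeros(cfg.n_features, dtype=np.int64)
                    j_last = 0
                tj = n_blocks * j
                post = ideal_posterior(s_cum, n_blocks, j, cfg.theta1, cfg.theta0)
                rows.append(pd.DataFrame({
                    "network": tr.network,
                    "condition": cfg.condition,
                    "trial": tr.trial,
                    "feature": np.arange(cfg.n_features),
                    "generation": g,
                    "popularity": rec.popularity,
                    "s_last": s_last,
                    "j_last": j_last,
                    "s_cum": s_cum,
                    "tj_cum": tj,
                    "ideal_posterior": np.asarray(post, dtype=float),
                }))
        return pd.concat(rows, ignore_index=True)


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run every (network, trial) chain of an experiment."""
    result = ExperimentResult(config=config)
    for network in range(config.n_networks):
        for trial in range(config.n_trials):
            result.trials.append(run_trial(config, network, trial))
    return result


def run_condition_suite(
    presets: list[str], model: ModelConfig, seed: int = 0, **overrides
) -> dict[str, ExperimentResult]:
    """Run a list of built-in presets with independent seeds."""
    out = {}
    for idx, name in enumerate(presets):
        sub = int(
            np.random.SeedSequence(seed, spawn_key=(idx,)).generate_state(1)[0]
        )
        out[name] = run_experiment(preset_config(name, model, seed=sub, **overrides))
    return out


def convergence_report(
    n_agents_list: list[int],
    n_generations: int = 10,
    theta1: float = 0.6,
    theta0: float = 0.3,
    n_evidence: int = 4,
    n_replicates: int = 1,
    seed: int = 0,
    model: ModelConfig | None = None,
) -> pd.DataFrame:
    """Popularity-vs-ideal-posterior gap as generation size grows.

    Runs single-feature chains under Bayesian social sampling (by
    default) and reports, per generation size, the maximum and mean
    absolute gap between popularity and the realized-evidence ideal
    posterior, together with the largest binomial tolerance
    ``3 * sqrt(q (1 - q) / N)`` attained along the trajectories.
    """
    model = model or ModelConfig("social_sampling_bayes", social_proportion=1.0)
    rows = []
    for idx, n in enumerate(n_agents_list):
        gaps, tols = [], []
        for rep in range(n_replicates):
            cfg = ExperimentConfig(
                n_networks=1, n_generations=n_generations, n_agents=n,
                n_features=1, n_evidence=n_evidence, theta1=theta1,
                theta0=theta0, model=model, n_trials=1,
                seed=int(
                    np.random.SeedSequence(
                        seed, spawn_key=(idx, rep)
                    ).generate_state(1)[0]
                ),
                condition=f"N={n}",
            )
            traj = run_experiment(cfg).trajectory_frame()
            gap = (traj["popularity"] - traj["ideal_posterior"]).abs()
            q = traj["ideal_posterior"]
            gaps.append(gap.to_numpy())
            tols.append((3.0 * np.sqrt(q * (1.0 - q) / n)).to_numpy())
        gaps = np.concatenate(gaps)
        tols = np.concatenate(tols)
        rows.append({
            "n_agents": n,
            "max_abs_gap": float(gaps.max()),
            "mean_abs_gap": float(gaps.mean()),
            "max_tolerance": float(tols.max()),
            "within_tolerance": bool((gaps <= np.maximum(tols, 3.0 / n)).all()),
        })
    return pd.DataFrame(rows)
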