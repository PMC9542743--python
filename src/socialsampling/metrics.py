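"""Accumulation metrics and statistical analyses.

Builds the per-(network, trial, feature, generation) analysis table from
decision/evidence tables, computes the ideal Bayesian posterior given
all evidence observed by the population, and runs the comparisons used
to evaluate decision models: Pearson correlations, fixed-effects OLS of
popularity on evidence fractions, and one-step-ahead predicted-vs-
observed popularity mean squared error.

Prediction convention: each model predicts generation-``t`` popularity
from the *observed* generation-``t-1`` popularity plus the evidence the
generation-``t`` deciders saw — not from the model's own rollout.  This
is the only reading under which a per-generation MSE against observed
popularity is well defined.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
import statsmodels.api as sm

from . import decision_models as dm

__all__ = [
    "SchemaError",
    "UndefinedCorrelationError",
    "SingularDesignError",
    "CorrelationResult",
    "popularity",
    "ideal_posterior",
    "analysis_rows",
    "correlate",
    "regress_popularity",
    "regression_summary",
    "model_mse",
    "DECISION_COLUMNS",
    "EVIDENCE_COLUMNS",
    "validate_schema",
]

DECISION_COLUMNS = (
    "network", "condition", "trial", "generation", "agent", "feature", "decision",
)
EVIDENCE_COLUMNS = (
    "network", "condition", "trial", "generation", "feature", "test_index", "outcome",
)


class SchemaError(ValueError):
    """An input table is missing required columns or is empty."""


class UndefinedCorrelationError(ValueError):
    """Pearson correlation is undefined (too few rows or zero variance)."""


class SingularDesignError(ValueError):
    """The regression design matrix is rank deficient."""


def validate_schema(df: pd.DataFrame, required: Sequence[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table is missing column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise SchemaError(f"{name} table is empty")


def popularity(decisions: np.ndarray, feature: int | None = None):
    """Fraction of agents deciding 1, per feature (or one feature).

    ``decisions`` is an ``N x F`` binary matrix for one generation; the
    result lies exactly on the ``1/N`` grid.
    """
    decisions = np.asarray(decisions)
    if decisions.ndim != 2 or decisions.shape[0] < 1:
        raise ValueError("decisions must be a non-empty N x F matrix")
    pop = decisions.mean(axis=0)
    return float(pop[feature]) if feature is not None else pop


def ideal_posterior(S_cum, t, J, theta1: float, theta0: float):
    """Uniform-prior posterior that a feature is true given all evidence.

    ``S_cum`` positive outcomes out of ``t * J`` total.  Computed in log
    space: ``1 / (1 + exp(log L0 - log L1))``.
    """
    S = np.asarray(S_cum, dtype=float)
    total = np.asarray(t, dtype=float) * float(J)
    if np.any(S < 0) or np.any(S > total):
        raise ValueError("S_cum must satisfy 0 <= S_cum <= t * J")
    with np.errstate(divide="ignore", invalid="ignore"):
        log_l1 = special.xlogy(S, theta1) + special.xlogy(total - S, 1.0 - theta1)
        log_l0 = special.xlogy(S, theta0) + special.xlogy(total - S, 1.0 - theta0)
    if np.any(np.isinf(log_l1) & np.isinf(log_l0)):
        raise dm.DegenerateEvidenceError("both hypotheses have zero likelihood")
    out = special.expit(log_l1 - log_l0)
    return out if out.ndim else float(out)


_KEY = ["network", "condition", "trial"]


def analysis_rows(
    decisions: pd.DataFrame,
    evidence: pd.DataFrame,
    theta1: float,
    theta0: float,
    evidence_timing: str = "current",
    n_evidence: int | None = None,
) -> pd.DataFrame:
    """Build the per-feature-generation analysis table from raw tables.

    One row per (network, condition, trial, feature, social generation),
    carrying the observed popularity, the previous generation's
    popularity, evidence fractions and the ideal posterior.  Generation
    0 (the asocial/guessing generation) contributes only ``p_prev``.

    ``evidence_timing='current'`` maps decision generation ``g`` (0-based)
    to blocks 1..g+1; ``'previous'`` maps it to blocks 1..g.
    """
    validate_schema(decisions, DECISION_COLUMNS, "decisions")
    validate_schema(evidence, EVIDENCE_COLUMNS, "evidence")
    if evidence_timing not in ("current", "previous"):
        raise ValueError("evidence_timing must be 'current' or 'previous'")
    if n_evidence is None:
        n_evidence = int(evidence["test_index"].max()) + 1

    pop = (
        decisions.groupby(_KEY + ["generation", "feature"], as_index=False)
        ["decision"].mean()
        .rename(columns={"decision": "popularity"})
    )
    prev = pop.rename(
        columns={"popularity": "p_prev", "generation": "prev_generation"}
    )
    pop["prev_generation"] = pop["generation"] - 1
    rows = pop[pop["generation"] >= 1].merge(
        prev, on=_KEY + ["prev_generation", "feature"], how="left", validate="1:1"
    )
    if rows["p_prev"].isna().any():
        raise SchemaError("decisions table is missing a previous generation")

    s_block = (
        evidence.groupby(_KEY + ["generation", "feature"], as_index=False)
        ["outcome"].sum()
        .rename(columns={"outcome": "s_block", "generation": "block"})
    )
    s_block = s_block.sort_values(_KEY + ["feature", "block"])
    s_block["s_cum"] = s_block.groupby(_KEY + ["feature"])["s_block"].cumsum()

    offset = 1 if evidence_timing == "current" else 0
    rows["block"] = rows["generation"] + offset
    rows = rows.merge(
        s_block, on=_KEY + ["feature", "block"], how="left", validate="1:1"
    )
    if rows["s_cum"].isna().any():
        raise SchemaError("evidence table is missing blocks for some generations")

    rows["s_last"] = rows["s_block"].astype(int)
    rows["j_last"] = n_evidence
    rows["s_cum"] = rows["s_cum"].astype(int)
    rows["tj_cum"] = rows["block"] * n_evidence
    rows["total_evidence_fraction"] = rows["s_cum"] / rows["tj_cum"]
    rows["last_evidence_fraction"] = rows["s_last"] / n_evidence
    rows["ideal_posterior"] = ideal_posterior(
        rows["s_cum"].to_numpy(), rows["block"].to_numpy(), n_evidence,
        theta1, theta0,
    )
    keep = _KEY + [
        "feature", "generation", "popularity", "p_prev", "s_last", "j_last",
        "s_cum", "tj_cum", "total_evidence_fraction", "last_evidence_fraction",
        "ideal_posterior",
    ]
    return rows[keep].reset_index(drop=True)


class CorrelationResult(NamedTuple):
    r: float
    df: int
    p_value: float


def correlate(rows: pd.DataFrame, x_field: str, y_field: str) -> CorrelationResult:
    """Pearson correlation between two analysis columns, with df = n - 2."""
    x = rows[x_field].to_numpy(dtype=float)
    y = rows[y_field].to_numpy(dtype=float)
    if x.size < 3:
        raise UndefinedCorrelationError("need at least 3 rows")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in input column")
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), x.size - 2, float(res.pvalue))


def regress_popularity(
    rows: pd.DataFrame, group_fields: Sequence[str] = ("network",)
):
    """OLS of popularity on evidence fractions with group fixed effects.

    Groups are dummy coded with the first level as reference.  Returns
    the fitted statsmodels results (params, tvalues, df_resid, ...).
    """
    exog = rows[["total_evidence_fraction", "last_evidence_fraction"]].copy()
    for gf in group_fields:
        dummies = pd.get_dummies(
            rows[gf].astype("category"), prefix=gf, drop_first=True, dtype=float
        )
        exog = pd.concat([exog, dummies], axis=1)
    exog = sm.add_constant(exog, has_constant="add")
    x = exog.to_numpy(dtype=float)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise SingularDesignError("design matrix is rank deficient")
    model = sm.OLS(rows["popularity"].to_numpy(dtype=float), exog)
    return model.fit()


def regression_summary(fit) -> dict:
    """JSON-serializable view of a fitted popularity regression."""
    return {
        "params": {k: float(v) for k, v in fit.params.items()},
        "tvalues": {k: float(v) for k, v in fit.tvalues.items()},
        "pvalues": {k: float(v) for k, v in fit.pvalues.items()},
        "df_resid": int(fit.df_resid),
        "nobs": int(fit.nobs),
        "r_squared": float(fit.rsquared),
    }


def _predict_rows(
    model_id: str, rows: pd.DataFrame, rho: float, censored: bool
) -> np.ndarray:
    p_prev = rows["p_prev"].to_numpy(dtype=float)
    s = rows["s_last"].to_numpy(dtype=float)
    j = rows["j_last"].to_numpy(dtype=float)
    theta1 = rows["theta1"].to_numpy(dtype=float)
    theta0 = rows["theta0"].to_numpy(dtype=float)
    if len(set(zip(rows["theta1"], rows["theta0"]))) == 1:
        t1, t0 = float(theta1[0]), float(theta0[0])
        visible = np.asarray(
            dm.predicted_popularity(model_id, p_prev, s, j, t1, t0, rho=rho),
            dtype=float,
        )
    else:  # heterogeneous conditions: evaluate per distinct (theta1, theta0)
        visible = np.empty(len(rows))
        for (t1, t0), idx in rows.groupby(["theta1", "theta0"]).indices.items():
            visible[idx] = dm.predicted_popularity(
                model_id, p_prev[idx], s[idx], j[idx], t1, t0, rho=rho
            )
    if not censored or model_id == "naive_copy":
        return visible
    # Censored regime: average the per-mask prediction over the previous
    # generation's designs.  A companion that chose the feature exposes
    # the evidence (visible prediction); one that did not leaves no
    # evidence, so social deciders copy the companion's 0 and asocial
    # deciders guess at 0.5.
    if model_id in dm.ASOCIAL_MODELS:
        hidden = 0.5
    else:
        hidden = (1.0 - rho) * 0.5
    return p_prev * visible + (1.0 - p_prev) * hidden


def model_mse(
    rows: pd.DataFrame,
    model_ids: Sequence[str] = dm.MODEL_IDS,
    rho: float = 1.0,
    censored: bool = False,
    theta1: float | None = None,
    theta0: float | None = None,
) -> pd.DataFrame:
    """Mean squared error of predicted vs observed popularity per model.

    ``rows`` must carry ``p_prev``, ``s_last``, ``j_last`` (social
    generations only).  ``theta1``/``theta0`` may be given as scalars or
    as per-row columns.  Returns a frame sorted ascending by MSE with a
    1-based ``rank`` column.
    """
    required = ["popularity", "p_prev", "s_last", "j_last"]
    validate_schema(rows, required, "analysis")
    rows = rows.copy()
    for name, val in (("theta1", theta1), ("theta0", theta0)):
        if val is not None:
            rows[name] = float(val)
        elif name not in rows.columns:
            raise SchemaError(f"analysis table needs a {name} column or argument")
    observed = rows["popularity"].to_numpy(dtype=float)
    records = []
    for model_id in model_ids:
        pred = _predict_rows(model_id, rows, rho, censored)
        records.append({
            "model": model_id,
            "mse": float(np.mean((pred - observed) ** 2)),
        })
    out = pd.DataFrame(records).sort_values("mse", kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
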