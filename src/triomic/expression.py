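"""Two-group moderated differential expression with FDR and fold-change gates.

The test statistic is the empirical-Bayes moderated t: per-gene pooled
residual variances ``s2_g`` (``d`` residual degrees of freedom) are shrunk
toward a prior ``s0^2`` with ``d0`` prior degrees of freedom,

    s2_tilde_g = (d0 * s0^2 + d * s2_g) / (d0 + d)
    t_g = log2FC_g / (s_tilde_g * sqrt(1/n1 + 1/n2)),

with two-sided p-values from a t distribution on ``d0 + d`` degrees of
freedom (a normal when ``d0`` is infinite).  The hyperparameters ``(d0,
s0^2)`` are estimated by the method of moments on the log variances: with
``e_g = log(s2_g) - digamma(d/2) + log(d/2)``,

    trigamma(d0/2) = var(e) - trigamma(d/2)
    s0^2 = exp(mean(e) + digamma(d0/2) - log(d0/2)),

solving the trigamma equation by Newton inversion.  When the observed
spread of log variances is no larger than expected from chi-square sampling
alone, ``d0`` is infinite and all genes share the pooled prior variance.

Fold change is the difference of group means on the log2 scale (group 1 =
tumour minus group 2 = normal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    log2_fc: float
    t_moderated: float
    p_value: float
    q_value: float
    status: Literal["up", "down", "none"]


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration on 1/y scale)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def estimate_variance_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Method-of-moments (d0, s0^2) from per-gene variances with d df each.

    Returns ``(d0, s0_sq)``; ``d0`` may be ``inf`` (complete pooling) when
    the variance of log variances is at or below its chi-square expectation,
    in which case a warning is logged.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        logger.warning("too few positive variances; falling back to d0 = inf")
        m = float(np.mean(s2)) if len(s2) else 1.0
        return np.inf, m if m > 0 else 1.0
    z = np.log(s2[ok])
    e = z - float(special.digamma(d / 2.0)) + np.log(d / 2.0)
    mean_e = float(np.mean(e))
    var_e = float(np.var(e, ddof=1))
    if var_e < 1e-15:
        # all per-gene variances identical: the prior IS that common value,
        # so shrinkage leaves every variance unchanged (pooled-t fixed point)
        return np.inf, float(np.exp(np.mean(z)))
    excess = var_e - float(special.polygamma(1, d / 2.0))
    if excess <= 0:
        logger.warning(
            "log-variance spread at/below chi-square expectation; using d0 = inf"
        )
        return np.inf, float(np.exp(mean_e))
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(mean_e + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s0_sq


def moderated_t_test(
    expr: pd.DataFrame,
    groups: Sequence[str],
    group1: str = "tumour",
    group2: str = "normal",
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated t-test of every gene (row) between two sample groups.

    Parameters
    ----------
    expr
        genes x samples matrix of log2 expression values (no missing values).
    groups
        per-column group labels, aligned with ``expr.columns``.
    prior_df
        override for ``d0``: ``0`` disables moderation (ordinary pooled t),
        ``inf`` forces complete pooling; default estimates it from the data.

    Returns a DataFrame indexed by gene with columns ``log2_fc``, ``t``,
    ``p_value``, ``s2``, ``s2_post``, ``df_total``.
    """
    groups = np.asarray(groups)
    if len(groups) != expr.shape[1]:
        raise ValueError("groups length must match number of expression columns")
    if expr.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    i1 = groups == group1
    i2 = groups == group2
    n1, n2 = int(i1.sum()), int(i2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >= 2 samples (got {n1} and {n2})")

    x1 = expr.loc[:, i1].to_numpy(float)
    x2 = expr.loc[:, i2].to_numpy(float)
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    log2_fc = m1 - m2
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    d = n1 + n2 - 2
    s2 = ss / d

    if prior_df is None:
        d0, s0_sq = estimate_variance_prior(s2, d)
    elif prior_df == 0:
        d0, s0_sq = 0.0, 0.0
    else:
        d0 = float(prior_df)
        _, s0_sq = estimate_variance_prior(s2, d)
        if not np.isfinite(d0):
            d0 = np.inf

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2.copy()
        df_total = float(d)
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2_fc / se, np.where(log2_fc == 0, 0.0, np.inf * np.sign(log2_fc)))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    return pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "t": t,
            "p_value": p,
            "s2": s2,
            "s2_post": s2_post,
            "df_total": df_total,
        },
        index=expr.index,
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def call_de_status(
    results: pd.DataFrame,
    p_threshold: float = 0.05,
    fc_threshold: float = 2.0,
    gate: Literal["q", "p"] = "q",
) -> pd.DataFrame:
    """Attach BH q-values and up/down/none status to moderated-t results.

    A gene is ``up`` when its gated value (BH q by default) is below
    ``p_threshold`` and its log2 fold change is at least ``log2(fc_threshold)``;
    ``down`` symmetrically; otherwise ``none``.
    """
    if fc_threshold <= 0:
        raise ValueError("fc_threshold must be > 0")
    out = results.copy()
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    gated = out["q_value"] if gate == "q" else out["p_value"]
    lfc_min = np.log2(fc_threshold)
    sig = gated < p_threshold
    out["status"] = np.where(
        sig & (out["log2_fc"] >= lfc_min),
        "up",
        np.where(sig & (out["log2_fc"] <= -lfc_min), "down", "none"),
    )
    return out


def de_summary(table: pd.DataFrame) -> dict[str, int]:
    n_up = int((table["status"] == "up").sum())
    n_down = int((table["status"] == "down").sum())
    return {"n_up": n_up, "n_down": n_down, "n_total_de": n_up + n_down}


def run_de(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    p_threshold: float = 0.05,
    fc_threshold: float = 2.0,
    gate: Literal["q", "p"] = "q",
) -> pd.DataFrame:
    """Full DE stage: moderated t, BH adjustment, status calls.

    ``samples`` must have columns ``sample_id`` and ``group`` with values
    ``tumour``/``normal``; expression columns are aligned to it.
    """
    order = [s for s in samples["sample_id"] if s in expr.columns]
    groups = samples.set_index("sample_id").loc[order, "group"].to_numpy()
    res = moderated_t_test(expr[order], groups)
    return call_de_status(res, p_threshold=p_threshold, fc_threshold=fc_threshold, gate=gate)
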