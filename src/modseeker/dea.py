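"""Moderated two-group differential expression.

The test is the empirical-Bayes moderated t: per-gene pooled variances are
shrunk toward a prior variance estimated across genes by fitting a scaled
F distribution to the sample variances (method of moments on the log
variances), and the moderated statistic is referred to a t distribution
with augmented degrees of freedom. With ``prior_df=0`` it reduces exactly
to the ordinary pooled-variance two-sample t-test.

Gene statistics travel as a DataFrame indexed by gene with columns
``log2fc``, ``pvalue``, ``qvalue`` (and a derived ``direction``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: fallback prior degrees of freedom when the across-gene variance spread
#: is degenerate (all sample variances essentially equal)
_DEGENERATE_PRIOR_DF = 4.0

_VARIANCE_FLOOR = 1e-8


@dataclass(frozen=True)
class DeaConfig:
    """Significance rule: q < q_threshold and linear fold change >= fc_threshold_linear.

    The fold-change cut is applied on the log scale as
    ``|log2fc| >= log2(fc_threshold_linear)``.
    """

    q_threshold: float = 0.05
    fc_threshold_linear: float = 1.5
    prior_df: float | str = "auto"

    def __post_init__(self) -> None:
        if not 0.0 < self.q_threshold < 1.0:
            raise ValueError("q_threshold must be in (0, 1)")
        if self.fc_threshold_linear < 1.0:
            raise ValueError("fc_threshold_linear must be >= 1")
        if self.prior_df != "auto" and float(self.prior_df) < 0:
            raise ValueError("prior_df must be nonnegative or 'auto'")

    @property
    def log2fc_cut(self) -> float:
        return math.log2(self.fc_threshold_linear)


@dataclass
class ConcordanceSummary:
    """Direction agreement of the shared significant genes of two contrasts."""

    shared_significant: int
    up_in_both: int
    down_in_both: int
    discordant: int
    discordant_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.up_in_both + self.down_in_both + self.discordant != self.shared_significant:
            raise ValueError("concordance counts do not partition the shared set")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (x > 0)."""
    if x <= 0:
        raise ValueError("trigamma inverse requires a positive argument")
    # starting value from the asymptotic expansion trigamma(y) ~ 1/y + 1/(2y^2)
    y = 0.5 + 1.0 / x
    for _ in range(60):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_prior(variances: np.ndarray, residual_df: float) -> tuple[float, float]:
    """Estimate (prior_df, prior_variance) from per-gene sample variances.

    Moment-matches the marginal distribution of log sample variances under
    the hierarchical model s^2 | sigma^2 ~ sigma^2 * chi^2_d / d with
    1/sigma^2 scaled-chi^2 across genes. Degenerate spread (log variances
    with no excess dispersion beyond the chi^2 sampling noise) falls back
    to a fixed prior_df of 4 with a warning.
    """
    v = np.maximum(np.asarray(variances, dtype=float), _VARIANCE_FLOOR)
    d = float(residual_df)
    z = np.log(v)
    e = z - special.digamma(d / 2.0) + math.log(d / 2.0)
    e_mean = float(np.mean(e))
    excess = float(np.var(e, ddof=1) - special.polygamma(1, d / 2.0))
    if not np.isfinite(excess) or excess <= 1e-10:
        logger.warning(
            "degenerate variance spread across genes; falling back to prior_df=%g",
            _DEGENERATE_PRIOR_DF,
        )
        d0 = _DEGENERATE_PRIOR_DF
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = math.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return d0, s0_sq


def moderated_test(
    expression: pd.DataFrame,
    groups: pd.Series | dict,
    config: DeaConfig | None = None,
    *,
    treated: str = "treated",
    control: str = "control",
) -> pd.DataFrame:
    """Moderated t-test of treated vs control for every gene (row).

    Parameters
    ----------
    expression
        Gene x sample matrix of finite log2 values.
    groups
        Sample -> group label; must contain at least two samples each of
        ``treated`` and ``control``.

    Returns a gene-stats table with ``log2fc`` = mean(treated) - mean(control),
    two-sided ``pvalue`` from the moderated t, BH-adjusted ``qvalue`` and a
    ``direction`` column ('up'/'down' by the sign of log2fc).
    """
    config = config or DeaConfig()
    groups = pd.Series(groups)
    if not np.isfinite(expression.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix contains non-finite values")
    t_cols = [s for s in expression.columns if groups.get(s) == treated]
    c_cols = [s for s in expression.columns if groups.get(s) == control]
    n1, n2 = len(t_cols), len(c_cols)
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"each group needs >= 2 samples (treated={n1}, control={n2})"
        )

    xt = expression[t_cols].to_numpy(dtype=float)
    xc = expression[c_cols].to_numpy(dtype=float)
    log2fc = xt.mean(axis=1) - xc.mean(axis=1)
    d = n1 + n2 - 2
    pooled = (xt.var(axis=1, ddof=1) * (n1 - 1) + xc.var(axis=1, ddof=1) * (n2 - 1)) / d

    floored = pooled < _VARIANCE_FLOOR
    if floored.any():
        logger.warning("%d zero-variance genes floored at %g", int(floored.sum()), _VARIANCE_FLOOR)
        pooled = np.maximum(pooled, _VARIANCE_FLOOR)

    if config.prior_df == "auto":
        d0, s0_sq = estimate_prior(pooled, d)
    else:
        d0 = float(config.prior_df)
        s0_sq = float(np.median(pooled)) if d0 > 0 else 0.0

    if math.isinf(d0):
        s_tilde_sq = np.full_like(pooled, s0_sq)
        df_total = np.inf
    else:
        s_tilde_sq = (d0 * s0_sq + d * pooled) / (d0 + d)
        df_total = d + d0

    se = np.sqrt(s_tilde_sq * (1.0 / n1 + 1.0 / n2))
    tstat = log2fc / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "tstat": tstat,
            "pvalue": pvals,
            "qvalue": bh_adjust(pvals),
            "zero_variance": floored,
        },
        index=expression.index,
    )
    table["direction"] = np.where(table["log2fc"] >= 0, "up", "down")
    table.attrs["prior_df"] = d0
    table.attrs["prior_var"] = s0_sq
    return table


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_significant(table: pd.DataFrame, config: DeaConfig | None = None) -> set[tuple[str, str]]:
    """Genes passing q < q_threshold and |log2fc| >= log2(fc_threshold_linear).

    Returns a set of (gene, direction) pairs, direction from the sign of
    the fold change.
    """
    config = config or DeaConfig()
    if table.empty:
        raise ValueError("empty gene-stats table")
    keep = (table["qvalue"] < config.q_threshold) & (
        table["log2fc"].abs() >= config.log2fc_cut
    )
    sub = table.loc[keep]
    return {
        (gene, "up" if fc >= 0 else "down")
        for gene, fc in zip(sub.index, sub["log2fc"])
    }


def cross_concordance(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    config: DeaConfig | None = None,
) -> ConcordanceSummary:
    """Direction concordance of the genes significant in both tables."""
    config = config or DeaConfig()
    sig_a = dict(call_significant(table_a, config))
    sig_b = dict(call_significant(table_b, config))
    shared = sorted(set(sig_a) & set(sig_b))
    up = sum(1 for g in shared if sig_a[g] == "up" and sig_b[g] == "up")
    down = sum(1 for g in shared if sig_a[g] == "down" and sig_b[g] == "down")
    discordant = [g for g in shared if sig_a[g] != sig_b[g]]
    return ConcordanceSummary(
        shared_significant=len(shared),
        up_in_both=up,
        down_in_both=down,
        discordant=len(discordant),
        discordant_genes=discordant,
    )


def write_stats(table: pd.DataFrame, path, config: DeaConfig | None = None) -> None:
    """Write a gene-stats TSV with significance calls."""
    config = config or DeaConfig()
    out = table.copy()
    out["significant"] = (out["qvalue"] < config.q_threshold) & (
        out["log2fc"].abs() >= config.log2fc_cut
    )
    out.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")


def read_stats(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")
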