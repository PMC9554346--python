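"""Paired tumour/normal differential expression.

The substrate is a genes x samples matrix of log2 expression where samples come
in tumour/normal pairs from the same patient. Per gene, the paired statistic is
computed on the within-pair differences (tumour minus normal); the moderated
variant shrinks per-gene variances toward a pooled prior with the standard
empirical-Bayes scheme (a scaled inverse-chi-square prior whose scale and
degrees of freedom are moment-matched to the observed variance distribution).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)

TUMOUR = "tumour"
NORMAL = "normal"


@dataclass
class PairedExpressionStudy:
    """Genes x samples log2 expression with pair and condition labels.

    ``values`` is indexed by gene identifier; ``samples`` is indexed by the
    column names of ``values`` and carries ``pair_id`` and ``condition``
    (``tumour`` | ``normal``). Every pair_id must appear exactly once per
    condition.
    """

    values: pd.DataFrame
    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("gene identifiers must be unique")
        if list(self.samples.index) != list(self.values.columns):
            raise ValueError("sample metadata must match expression columns")
        bad = set(self.samples["condition"]) - {TUMOUR, NORMAL}
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")
        counts = self.samples.groupby(["pair_id", "condition"]).size()
        if (counts != 1).any():
            raise ValueError("every pair_id must appear exactly once per condition")
        if self.values.isna().any().any():
            n_bad = int(self.values.isna().any(axis=1).sum())
            logger.warning("dropping %d genes with missing values", n_bad)
            object.__setattr__(self, "values", self.values.dropna(axis=0))

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_pairs(self) -> int:
        return self.samples["pair_id"].nunique()

    def paired_differences(self) -> pd.DataFrame:
        """Genes x pairs matrix of (tumour - normal) log2 values."""
        meta = self.samples.reset_index(names="sample")
        wide = meta.pivot(index="pair_id", columns="condition", values="sample")
        tum = self.values[wide[TUMOUR]]
        nor = self.values[wide[NORMAL]]
        diff = tum.to_numpy() - nor.to_numpy()
        return pd.DataFrame(diff, index=self.values.index, columns=wide.index)


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    adj_p[i] = min over j with p[j] >= p[i] of p[j] * n / rank(j), clipped to 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d array of p-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex target)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) / y < 1e-8:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to observed variances.

    Works on z = log(s2): E z = log(s0^2) + digamma(df/2) - log(df/2) plus a
    prior term, and the excess variance of z over trigamma(df/2) identifies the
    prior degrees of freedom. Returns (prior_df, prior_s2); prior_df = inf when
    observed variances underdisperse the sampling distribution.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    df0 = 2.0 * _trigamma_inverse(evar)
    s0 = np.exp(emean + special.digamma(df0 / 2.0) - np.log(df0 / 2.0))
    return float(df0), float(s0)


def compute_paired_de(study: PairedExpressionStudy, moderation: bool = True) -> pd.DataFrame:
    """Per-gene paired differential expression table.

    Returns a DataFrame indexed by gene with columns ``logFC``, ``t``, ``p``,
    ``adj_p`` and ``direction`` (all ``ns`` until :func:`select_degs`). With
    ``moderation`` the per-gene variances are shrunk toward the fitted prior
    and the t null gains the prior degrees of freedom.
    """
    diff = study.paired_differences()
    n = diff.shape[1]
    if n < 2:
        raise ValueError("paired DE requires at least 2 complete pairs")
    d = diff.to_numpy()
    logfc = d.mean(axis=1)
    s2 = d.var(axis=1, ddof=1)
    df = n - 1

    constant = s2 == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant gene(s): p set to 1", stacklevel=2)

    if moderation:
        df0, s0 = fit_variance_prior(s2[~constant] if (~constant).any() else s2, df)
        if np.isinf(df0):
            s2_post = np.full_like(s2, s0)
            df_total = np.inf
        else:
            s2_post = (df0 * s0 + df * s2) / (df0 + df)
            df_total = df + df0
    else:
        s2_post = s2.copy()
        df_total = df

    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / np.sqrt(s2_post / n)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    # zero post-variance can only occur unmoderated; a nonzero mean there is a
    # degenerate exact effect, a zero mean carries no evidence
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isinf(t), 0.0, p)
    p[(s2_post == 0) & (logfc == 0)] = 1.0
    p[constant & (logfc == 0)] = 1.0
    p = np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)

    table = pd.DataFrame(
        {
            "logFC": logfc,
            "t": t,
            "p": p,
            "adj_p": adjust_bh(p),
            "direction": "ns",
        },
        index=study.gene_ids,
    )
    return table


def select_degs(table: pd.DataFrame, logfc_cut: float = 1.5, adjp_cut: float = 0.01) -> pd.DataFrame:
    """Keep genes with |logFC| strictly above ``logfc_cut`` and adj_p strictly
    below ``adjp_cut``; assign direction by the sign of logFC."""
    keep = (table["logFC"].abs() > logfc_cut) & (table["adj_p"] < adjp_cut)
    out = table.loc[keep].copy()
    out["direction"] = np.where(out["logFC"] > 0, "up", "down")
    return out.sort_values("adj_p", kind="stable")
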