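"""Per-study before/after differential abundance on non-rarefied counts.

A deliberately simple negative-binomial Wald estimator: counts are
normalized by median-of-ratios size factors, per-OTU log2 fold changes
(after vs before) are computed from normalized group means, a moment
estimate of the gamma-Poisson dispersion feeds a delta-method standard
error, and two-sided normal p-values are Benjamini-Hochberg adjusted.
There is no dispersion shrinkage toward a fitted trend, no GLM iteration
and no fold-change shrinkage: the meta-analysis downstream needs per-study
log2FC signs and magnitudes, and this estimator is fully specifiable and
testable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountTable, SampleMetadata, ValidationError

__all__ = ["size_factors", "nb_differential", "classify_responders", "DAResult"]

logger = logging.getLogger("fibermeta")


@dataclass(frozen=True)
class DAResult:
    """Per-OTU differential-abundance statistics for one study's contrast.

    ``table`` columns: base_mean (mean normalized abundance), log2fc
    (after vs before), se_log2fc, p, padj, pseudo_flag (True where a zero
    group mean forced a pseudo-count).
    """

    table: pd.DataFrame = field(repr=False)

    @property
    def otu_ids(self) -> tuple[str, ...]:
        return tuple(self.table.index)


def size_factors(
    table: CountTable, pseudo_reference: bool = False
) -> np.ndarray:
    """Median-of-ratios size factors, one per sample.

    The reference profile is the per-OTU geometric mean across samples,
    using only OTUs with strictly positive counts everywhere; each sample's
    factor is the median of count/reference over those OTUs.

    ``pseudo_reference=True`` enables a fallback for sparse tables with no
    all-positive OTU: the geometric mean is computed on counts+0.5,
    restricted to OTUs present in at least half the samples so the median
    ratio still tracks sequencing depth rather than the pseudo-count. The
    fallback is used only when the classic reference is unavailable.
    """
    counts = table.counts.astype(float)
    all_pos = (counts > 0).all(axis=1)
    if all_pos.any():
        sub = counts[all_pos]
        ref = np.exp(np.log(sub).mean(axis=1))
        ratios = sub / ref[:, None]
        return np.median(ratios, axis=0)
    if not pseudo_reference:
        raise ValidationError(
            "no OTU has positive counts in every sample; rerun with "
            "pseudo_reference=True to use a pseudo-count reference"
        )
    prevalent = (counts > 0).mean(axis=1) >= 0.5
    if not prevalent.any():
        prevalent = np.ones(counts.shape[0], dtype=bool)
    sub = counts[prevalent] + 0.5
    ref = np.exp(np.log(sub).mean(axis=1))
    ratios = sub / ref[:, None]
    return np.median(ratios, axis=0)


def nb_differential(
    table: CountTable,
    metadata: SampleMetadata,
    alpha_floor: float = 1e-8,
    pseudo: float = 0.5,
    pseudo_reference: bool = False,
) -> DAResult:
    """Negative-binomial Wald test of after vs before for every OTU.

    Per OTU with normalized counts q = count/size_factor and group means
    mu_b, mu_a:

    - log2fc = log2((mu_a + c)/(mu_b + c)) where the pseudo-count
      c = pseudo/median(size factors) is applied only when a group mean is
      zero (flagged per OTU);
    - dispersion alpha by method of moments on pooled within-group
      residuals, floored at ``alpha_floor``;
    - Var(mu_g) ~= sum_{j in g} (mu_g/s_j + alpha*mu_g^2) / n_g^2
      (Poisson sampling at the sample's depth plus gamma overdispersion);
    - se(log2fc) by the delta method, Wald z, two-sided normal p, BH padj.

    All-zero OTUs are dropped with a warning.
    """
    df = metadata.table.set_index("sample_id").loc[list(table.sample_ids)]
    groups = df["timepoint"].to_numpy()
    b_idx = np.flatnonzero(groups == "before")
    a_idx = np.flatnonzero(groups == "after")
    if len(b_idx) < 2 or len(a_idx) < 2:
        raise ValidationError(
            f"each group needs >= 2 samples (before={len(b_idx)}, "
            f"after={len(a_idx)})"
        )
    counts = table.counts.astype(float)
    nonzero = counts.sum(axis=1) > 0
    if not nonzero.all():
        dropped = [o for o, k in zip(table.otu_ids, nonzero) if not k]
        logger.warning("nb_differential: dropping %d all-zero OTU(s)", len(dropped))
        counts = counts[nonzero]
    otu_ids = [o for o, k in zip(table.otu_ids, nonzero) if k]

    s = size_factors(
        CountTable(tuple(otu_ids), table.sample_ids, counts.astype(np.int64)),
        pseudo_reference=pseudo_reference,
    )
    q = counts / s[None, :]
    qb, qa = q[:, b_idx], q[:, a_idx]
    nb, na = len(b_idx), len(a_idx)
    mu_b = qb.mean(axis=1)
    mu_a = qa.mean(axis=1)
    base_mean = q.mean(axis=1)

    # pooled moment estimate of the gamma overdispersion: remove group
    # means, pool residual variance, subtract the Poisson component
    resid = np.concatenate([qb - mu_b[:, None], qa - mu_a[:, None]], axis=1)
    s2 = (resid ** 2).sum(axis=1) / (nb + na - 2)
    mu_pool = (nb * mu_b + na * mu_a) / (nb + na)
    # Poisson variance of a normalized count is mu/s_j; average over samples
    pois = mu_pool[:, None] / s[None, :]
    pois = pois.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(mu_pool > 0, (s2 - pois) / mu_pool ** 2, alpha_floor)
    alpha = np.maximum(alpha, alpha_floor)

    c = pseudo / np.median(s)
    zero_mean = (mu_b == 0) | (mu_a == 0)
    num = np.where(zero_mean, mu_a + c, mu_a)
    den = np.where(zero_mean, mu_b + c, mu_b)
    log2fc = np.log2(num / den)

    var_a = (mu_a[:, None] / s[None, a_idx] + alpha[:, None] * mu_a[:, None] ** 2
             ).sum(axis=1) / na ** 2
    var_b = (mu_b[:, None] / s[None, b_idx] + alpha[:, None] * mu_b[:, None] ** 2
             ).sum(axis=1) / nb ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(var_a / num ** 2 + var_b / den ** 2) / math.log(2)
    se = np.where(se > 0, se, np.nan)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(np.isnan(p), 1.0, np.clip(p, np.nextafter(0, 1), 1.0))
    padj = multipletests(p, method="fdr_bh")[1]

    out = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se_log2fc": se,
            "p": p,
            "padj": padj,
            "pseudo_flag": zero_mean,
        },
        index=pd.Index(otu_ids, name="otu_id"),
    )
    return DAResult(out)


def classify_responders(
    result: DAResult, alpha: float = 0.05, lfc_cut: float = 0.0
) -> tuple[set, set, set]:
    """Split a DA result into significant / positive / negative OTU sets.

    significant = {padj < alpha and |log2fc| > lfc_cut}; the positive and
    negative sets split *all* tested OTUs by the sign of log2fc (exact
    zeros fall in neither), matching the sign sets used as tree input.
    The conventional cutoffs are 0 and 0.58 (a 1.5-fold change).
    """
    t = result.table
    significant = set(
        t.index[(t["padj"] < alpha) & (t["log2fc"].abs() > lfc_cut)]
    )
    positive = set(t.index[t["log2fc"] > 0])
    negative = set(t.index[t["log2fc"] < 0])
    return significant, positive, negative
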