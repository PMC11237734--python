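"""Iterated rarefaction, alpha-diversity metrics, and the paired before/after test.

Samples are rarefied (subsampled without replacement) to a common depth for
many iterations; Shannon entropy (nats), the Simpson complement 1 - sum(p^2)
and observed richness are computed per iteration and averaged, which
stabilises the metrics against subsampling noise. Each intervention is then
tested with a paired t-test on one pair per subject: the earliest 'before'
sample against the latest 'after' sample.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import CountTable, SampleMetadata, ValidationError

__all__ = [
    "rarefy",
    "alpha_metrics",
    "paired_t_test",
    "alpha_response",
    "PairedTestResult",
    "AlphaResult",
    "METRICS",
]

logger = logging.getLogger("fibermeta")

METRICS = ("shannon", "simpson", "richness")


@dataclass(frozen=True)
class PairedTestResult:
    """Paired t-test outcome for one alpha metric of one intervention."""

    metric: str
    t: float
    df: int
    p: float
    direction: str  # increase / decrease / none
    percent_change: float
    mean_before: float
    mean_after: float
    degenerate: bool = False


@dataclass(frozen=True)
class AlphaResult:
    """Per-sample averaged alpha metrics plus the paired response tests."""

    sample_ids: tuple[str, ...]
    values: dict  # metric -> np.ndarray aligned with sample_ids
    tests: dict  # metric -> PairedTestResult
    depth: int
    n_iter: int


def rarefy(table: CountTable, depth: int, seed) -> CountTable:
    """Subsample every sample without replacement to ``depth`` reads.

    Samples whose total is below ``depth`` are dropped with a logged
    warning. Each retained column sums exactly to ``depth`` and no rarefied
    count exceeds the original. Deterministic for a given seed.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    totals = table.sample_totals()
    keep = totals >= depth
    if not keep.any():
        raise ValueError(
            f"all {len(totals)} samples have fewer than {depth} reads"
        )
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.warning(
            "rarefy: dropping %d sample(s) below depth %d: %s",
            len(dropped), depth, ", ".join(dropped),
        )
    rng = np.random.default_rng(seed)
    kept_ids = tuple(s for s, k in zip(table.sample_ids, keep) if k)
    cols = []
    for j, k in enumerate(keep):
        if not k:
            continue
        col = table.counts[:, j]
        if totals[j] == depth:
            cols.append(col.copy())
        else:
            cols.append(rng.multivariate_hypergeometric(col, depth))
    return CountTable(table.otu_ids, kept_ids, np.column_stack(cols))


def alpha_metrics(column: np.ndarray) -> tuple[float, float, int]:
    """Shannon entropy (nats), Simpson complement and richness of one sample.

    shannon = -sum p_i ln p_i over positive proportions; simpson = 1 - sum p_i^2;
    richness = number of taxa with a positive count.
    """
    counts = np.asarray(column, dtype=float)
    if counts.ndim != 1:
        raise ValueError("alpha_metrics expects a 1-D count vector")
    if (counts < 0).any():
        raise ValueError("negative counts")
    total = counts.sum()
    if total <= 0:
        raise ValueError("all-zero sample has no defined diversity")
    p = counts[counts > 0] / total
    shannon = float(-(p * np.log(p)).sum())
    simpson = float(1.0 - (p ** 2).sum())
    richness = int((counts > 0).sum())
    return shannon, simpson, richness


def paired_t_test(before: np.ndarray, after: np.ndarray):
    """Two-sided paired t-test on ``after - before`` differences.

    Returns ``(t, df, p, degenerate)``. Zero-variance non-zero differences
    are degenerate: the direction is certain under the model, so p is
    reported as the smallest positive float with ``degenerate=True``.
    Identical vectors give t=0 with p=1 and the degenerate flag set.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.ndim != 1:
        raise ValueError("before/after must be 1-D vectors of equal length")
    n = len(before)
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    diffs = after - before
    sd = diffs.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        if diffs[0] == 0.0:
            return 0.0, df, 1.0, True
        t = math.inf if diffs[0] > 0 else -math.inf
        return t, df, float(np.nextafter(0.0, 1.0)), True
    t = diffs.mean() / (sd / math.sqrt(n))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(t), df, p, False


def _select_pairs(metadata: SampleMetadata) -> list[tuple[str, str, str]]:
    """Per subject: (subject_id, earliest 'before' sample, latest 'after' sample)."""
    df = metadata.table
    pairs = []
    for subj in metadata.paired_subjects():
        sub = df[df["subject_id"] == subj]
        bef = sub[sub["timepoint"] == "before"].sort_values("order")
        aft = sub[sub["timepoint"] == "after"].sort_values("order")
        pairs.append((subj, bef["sample_id"].iloc[0], aft["sample_id"].iloc[-1]))
    return pairs


def alpha_response(
    table: CountTable,
    metadata: SampleMetadata,
    depth: int | None = None,
    n_iter: int = 1000,
    seed=0,
    percent_change: str = "relative",
) -> AlphaResult:
    """Alpha-diversity before/after response of one intervention.

    Selects one (earliest-before, latest-after) sample pair per subject,
    averages each metric over ``n_iter`` rarefactions at ``depth`` (default:
    the smallest selected-sample total, the highest depth retaining every
    sample), and runs a paired t-test per metric.

    ``percent_change='relative'`` reports 100*(after-before)/before;
    ``'absolute'`` reports the plain difference of means.
    """
    if percent_change not in ("relative", "absolute"):
        raise ValueError("percent_change must be 'relative' or 'absolute'")
    pairs = _select_pairs(metadata)
    if len(pairs) < 2:
        raise ValidationError(
            "need at least 2 subjects with both a before and an after sample"
        )
    sample_ids = [s for _, b, a in pairs for s in (b, a)]
    sub = table.select_samples(sample_ids)
    if depth is None:
        depth = int(sub.sample_totals().min())
    rng = np.random.default_rng(seed)
    acc = {m: np.zeros(len(sample_ids)) for m in METRICS}
    for _ in range(n_iter):
        rt = rarefy(sub, depth, rng)
        if rt.sample_ids != tuple(sample_ids):
            raise ValidationError(
                "a selected sample fell below the rarefaction depth; "
                "lower the depth or drop the subject"
            )
        for j in range(len(sample_ids)):
            sh, si, ri = alpha_metrics(rt.counts[:, j])
            acc["shannon"][j] += sh
            acc["simpson"][j] += si
            acc["richness"][j] += ri
    values = {m: acc[m] / n_iter for m in METRICS}

    tests = {}
    b_idx = np.arange(0, len(sample_ids), 2)
    a_idx = b_idx + 1
    for m in METRICS:
        before = values[m][b_idx]
        after = values[m][a_idx]
        t, dfree, p, degen = paired_t_test(before, after)
        mb, ma = float(before.mean()), float(after.mean())
        if ma > mb:
            direction = "increase"
        elif ma < mb:
            direction = "decrease"
        else:
            direction = "none"
        if percent_change == "relative":
            pc = 100.0 * (ma - mb) / mb if mb != 0 else math.nan
        else:
            pc = ma - mb
        tests[m] = PairedTestResult(
            metric=m, t=t, df=dfree, p=p, direction=direction,
            percent_change=pc, mean_before=mb, mean_after=ma, degenerate=degen,
        )
    return AlphaResult(
        sample_ids=tuple(sample_ids), values=values, tests=tests,
        depth=depth, n_iter=n_iter,
    )
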