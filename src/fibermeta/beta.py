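"""Bray-Curtis beta diversity, sequential PERMANOVA and dispersion homogeneity.

The compositional analysis averages Bray-Curtis dissimilarity matrices over
many rarefaction iterations of square-root transformed counts, then
partitions the distance variance with a sequential (Type-I) PERMANOVA,
subject entered before timepoint: with strong inter-individual structure the
subject term absorbs most of the variance and the timepoint term measures
the consistent before/after shift. Group dispersion differences are checked
with a PERMDISP-style test (distances to group centroids in principal
coordinates, retaining negative eigenvalues).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist
from skbio import DistanceMatrix

from .io import CountTable, SampleMetadata, ValidationError
from .alpha import rarefy

__all__ = [
    "bray_curtis",
    "averaged_bray_curtis",
    "permanova_sequential",
    "permdisp",
    "PermanovaResult",
    "PermdispResult",
]


@dataclass(frozen=True)
class PermanovaTerm:
    name: str
    df: int
    ss: float
    r2: float
    pseudo_f: float | None
    p: float | None


@dataclass(frozen=True)
class PermanovaResult:
    """Sequential PERMANOVA table: one row per term plus residual and total."""

    terms: tuple[PermanovaTerm, ...]
    residual: PermanovaTerm
    total: PermanovaTerm
    n_permutations: int

    def term(self, name: str) -> PermanovaTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


@dataclass(frozen=True)
class PermdispResult:
    group_means: dict  # group label -> mean distance to centroid
    f: float
    p: float
    n_permutations: int


def bray_curtis(matrix: np.ndarray, sample_ids=None) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between columns of an abundance matrix.

    d(u, v) = 1 - 2 * sum(min(u_i, v_i)) / (sum(u) + sum(v)); accepts real
    (e.g. square-root transformed) abundances.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D taxa x samples matrix")
    if (X < 0).any():
        raise ValueError("negative abundances")
    totals = X.sum(axis=0)
    if (totals <= 0).any():
        j = int(np.argmin(totals))
        sid = sample_ids[j] if sample_ids is not None else j
        raise ValueError(f"all-zero sample {sid!r} has no defined dissimilarity")
    if sample_ids is None:
        sample_ids = [str(j) for j in range(X.shape[1])]
    d = squareform(pdist(X.T, metric="braycurtis"))
    return DistanceMatrix(d, ids=list(map(str, sample_ids)))


def averaged_bray_curtis(
    table: CountTable, depth: int, n_iter: int = 1000, seed=0
) -> DistanceMatrix:
    """Mean Bray-Curtis matrix over rarefaction iterations.

    Each iteration rarefies to ``depth``, square-root transforms the counts
    (damping the influence of dominant taxa) and computes Bray-Curtis; the
    element-wise mean over iterations is returned. Samples below ``depth``
    are dropped (see :func:`fibermeta.alpha.rarefy`).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    acc = None
    ids = None
    for _ in range(n_iter):
        rt = rarefy(table, depth, rng)
        dm = bray_curtis(np.sqrt(rt.counts), rt.sample_ids)
        if acc is None:
            acc, ids = dm.data.copy(), dm.ids
        else:
            acc += dm.data
    return DistanceMatrix(acc / n_iter, ids=ids)


# ---------------------------------------------------------------------------
# PERMANOVA


def _dummy(levels: np.ndarray) -> np.ndarray:
    """Full-rank treatment-coded dummy matrix (first level dropped)."""
    uniq = np.unique(levels)
    return (levels[:, None] == uniq[None, 1:]).astype(float)


def _hat(X: np.ndarray) -> np.ndarray:
    # pinv handles the rank-deficient case (nested/confounded terms)
    return X @ np.linalg.pinv(X)


def permanova_sequential(
    dist: DistanceMatrix,
    metadata: SampleMetadata | dict,
    terms: tuple[str, ...] = ("subject_id", "timepoint"),
    n_perm: int | str = 999,
    seed=0,
) -> PermanovaResult:
    """Sequential (Type-I) PERMANOVA on a distance matrix.

    Uses the Gower-centered inner-product matrix G = -1/2 * J D^2 J and
    attributes variance to terms in the order given (subject first):
    SS_term = tr(H_k G) - tr(H_{k-1} G) for nested hat matrices H. The
    pseudo-F for each term is (SS_term/df_term)/(SS_res/df_res) and its
    p-value comes from free row/column permutations of D, p = (1 + #{F_perm
    >= F_obs}) / (1 + n_perm) with ties counted as exceedances.

    ``n_perm='exact'`` enumerates all n! sample permutations (small n only)
    and reports p = #{F_perm >= F_obs}/n! over the full group, which
    includes the identity.
    """
    n = dist.shape[0]
    if n < 4:
        raise ValidationError("PERMANOVA needs at least 4 samples")
    if isinstance(metadata, SampleMetadata):
        df = metadata.table.set_index("sample_id").loc[list(dist.ids)]
        factors = {t: df[t].to_numpy() for t in terms}
    else:
        factors = {t: np.asarray([metadata[t][s] for s in dist.ids]) for t in terms}
    for t in terms:
        if len(np.unique(factors[t])) < 2:
            raise ValidationError(f"term {t!r} has a single level")

    D2 = dist.data ** 2
    G = -0.5 * D2
    G = G - G.mean(axis=0, keepdims=True) - G.mean(axis=1, keepdims=True) + G.mean()

    # nested hat matrices: intercept-only, then cumulative terms
    hats = []
    X = np.ones((n, 1))
    dfs = []
    for t in terms:
        Xt = _dummy(factors[t])
        X_new = np.column_stack([X, Xt])
        rank_prev = np.linalg.matrix_rank(X)
        rank_new = np.linalg.matrix_rank(X_new)
        dfs.append(rank_new - rank_prev)
        X = X_new
        hats.append(_hat(X))
    df_model = sum(dfs)
    df_resid = n - 1 - df_model
    if df_resid <= 0:
        raise ValidationError("model saturates the samples; no residual df")

    def decompose(Gm: np.ndarray) -> tuple[np.ndarray, float]:
        ss_total = float(np.trace(Gm))
        ss_cum = [float(np.sum(H * Gm)) for H in hats]  # tr(H G), H symmetric
        ss_terms = np.diff([0.0] + ss_cum)
        ss_res = ss_total - ss_cum[-1]
        return ss_terms, ss_res

    ss_terms, ss_res = decompose(G)
    ss_total = float(np.trace(G))
    f_obs = np.array(
        [
            (ss_terms[k] / dfs[k]) / (ss_res / df_resid) if dfs[k] > 0 else math.nan
            for k in range(len(terms))
        ]
    )

    if n_perm == "exact":
        if n > 8:
            raise ValueError("exact enumeration is limited to n <= 8 samples")
        exceed = np.zeros(len(terms))
        count = 0
        for perm in itertools.permutations(range(n)):
            idx = np.array(perm)
            Gp = G[np.ix_(idx, idx)]
            ss_p, ss_rp = decompose(Gp)
            f_p = (ss_p / np.array(dfs)) / (ss_rp / df_resid)
            exceed += f_p >= f_obs - 1e-12
            count += 1
        pvals = exceed / count
        n_reported = count
    else:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(terms))
        for _ in range(int(n_perm)):
            idx = rng.permutation(n)
            Gp = G[np.ix_(idx, idx)]
            ss_p, ss_rp = decompose(Gp)
            f_p = (ss_p / np.array(dfs)) / (ss_rp / df_resid)
            exceed += f_p >= f_obs
        pvals = (1.0 + exceed) / (1.0 + int(n_perm))
        n_reported = int(n_perm)

    rows = tuple(
        PermanovaTerm(
            name=t, df=dfs[k], ss=float(ss_terms[k]),
            r2=float(ss_terms[k] / ss_total), pseudo_f=float(f_obs[k]),
            p=float(pvals[k]),
        )
        for k, t in enumerate(terms)
    )
    residual = PermanovaTerm(
        "residual", df_resid, float(ss_res), float(ss_res / ss_total), None, None
    )
    total = PermanovaTerm("total", n - 1, ss_total, 1.0, None, None)
    return PermanovaResult(rows, residual, total, n_reported)


# ---------------------------------------------------------------------------
# PERMDISP


def _pcoa_coords(dist: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate embedding retaining negative eigenvalues.

    Returns (real_coords, imag_coords): axes with positive eigenvalues give
    ordinary coordinates; axes with negative eigenvalues give 'imaginary'
    coordinates whose squared contribution is subtracted.
    """
    D2 = dist.data ** 2
    G = -0.5 * D2
    G = G - G.mean(axis=0, keepdims=True) - G.mean(axis=1, keepdims=True) + G.mean()
    evals, evecs = np.linalg.eigh(G)
    tol = 1e-10 * max(1.0, abs(evals).max())
    pos = evals > tol
    neg = evals < -tol
    real = evecs[:, pos] * np.sqrt(evals[pos])
    imag = evecs[:, neg] * np.sqrt(-evals[neg])
    return real, imag


def permdisp(
    dist: DistanceMatrix, groups, n_perm: int = 999, seed=0
) -> PermdispResult:
    """Homogeneity of multivariate dispersions (PERMDISP-like, centroids).

    Embeds the distance matrix by principal coordinates keeping negative
    eigenvalues; the squared distance from a sample to its group's
    arithmetic centroid is the real-axis squared distance minus the
    imaginary-axis squared distance, floored at 0 before the square root.
    A one-way ANOVA F on these distances is tested by permuting group
    labels.
    """
    labels = np.asarray([groups[s] for s in dist.ids] if isinstance(groups, dict)
                        else groups)
    if len(labels) != dist.shape[0]:
        raise ValidationError("group labels do not match the distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("need at least 2 groups")
    if counts.min() < 2:
        g = uniq[int(np.argmin(counts))]
        raise ValidationError(f"group {g!r} has fewer than 2 samples")

    real, imag = _pcoa_coords(dist)

    def group_distances(lbl: np.ndarray) -> np.ndarray:
        z = np.empty(len(lbl))
        for g in np.unique(lbl):
            m = lbl == g
            cr = real[m].mean(axis=0)
            ci = imag[m].mean(axis=0) if imag.shape[1] else np.zeros(0)
            d2 = ((real[m] - cr) ** 2).sum(axis=1)
            if imag.shape[1]:
                d2 = d2 - ((imag[m] - ci) ** 2).sum(axis=1)
            z[m] = np.sqrt(np.maximum(d2, 0.0))
        return z

    def anova_f(z: np.ndarray, lbl: np.ndarray) -> float:
        grand = z.mean()
        ss_b = ss_w = 0.0
        k = 0
        for g in np.unique(lbl):
            zg = z[lbl == g]
            ss_b += len(zg) * (zg.mean() - grand) ** 2
            ss_w += ((zg - zg.mean()) ** 2).sum()
            k += 1
        df_b, df_w = k - 1, len(z) - k
        if ss_w == 0:
            return math.inf if ss_b > 0 else 0.0
        return (ss_b / df_b) / (ss_w / df_w)

    z_obs = group_distances(labels)
    f_obs = anova_f(z_obs, labels)
    # permute labels against the observed distances-to-centroid (the
    # conventional betadisper permutation scheme)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        lp = rng.permutation(labels)
        if anova_f(z_obs, lp) >= f_obs:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    means = {str(g): float(z_obs[labels == g].mean()) for g in uniq}
    return PermdispResult(group_means=means, f=float(f_obs), p=p, n_permutations=n_perm)
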