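"""Diversity and hypothesis-testing layer.

Shannon alpha diversity (natural log), weighted/unweighted Bray-Curtis
dissimilarities, classical PCoA, one-way permutation ADONIS (PERMANOVA),
exact paired Wilcoxon and paired t tests, Shapiro-Wilk normality checks, and
the DNA-yield arithmetic used to compare extraction kits.

Weighted Bray-Curtis is computed on per-sample relative abundances (the
raw-count variant is available behind a flag); unweighted on
presence/absence indicators.  PCoA is plain classical scaling: negative
eigenvalues are reported, not corrected, and proportions explained are taken
over the sum of positive eigenvalues only.  The PERMANOVA p-value follows
the conservative (exceedances + 1) / (permutations + 1) convention with a
``>=`` exceedance comparison; an exhaustive mode enumerates all relabelings
for small n.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .tables import OtuTable, ZeroTotalSampleError


# -- alpha ------------------------------------------------------------------

def shannon(counts) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats) of one sample's counts."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ZeroTotalSampleError("Shannon diversity undefined for a zero-total sample")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def shannon_per_sample(table: OtuTable) -> pd.Series:
    """Shannon diversity of every sample in the table."""
    return pd.Series(
        {sid: shannon(row.to_numpy()) for sid, row in table.counts.iterrows()},
        name="shannon",
    )


# -- beta -------------------------------------------------------------------

def bray_curtis(table: OtuTable, weighted: bool = True, *,
                use_relative: bool = True) -> DistanceMatrix:
    """Bray-Curtis dissimilarity matrix over the table's samples.

    ``weighted`` uses abundances (relative by default); unweighted reduces
    each sample to presence/absence first, which makes Bray-Curtis coincide
    with the Sorensen dissimilarity.
    """
    tot = table.totals()
    empty = tot.index[tot == 0].tolist()
    if empty:
        raise ZeroTotalSampleError(f"sample(s) with zero total reads: {empty}")
    if weighted:
        x = table.relative_abundances().to_numpy() if use_relative \
            else table.counts.to_numpy(dtype=float)
    else:
        x = (table.counts.to_numpy() > 0).astype(float)
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(d, ids=[str(s) for s in table.sample_ids])


@dataclass
class PcoaResult:
    """Classical-scaling ordination of a distance matrix."""

    coordinates: pd.DataFrame          # samples x positive axes
    eigenvalues: np.ndarray            # all eigenvalues, descending (negatives kept)
    proportion_explained: np.ndarray   # over the sum of positive eigenvalues


def pcoa(dist: DistanceMatrix) -> PcoaResult:
    """Principal coordinates analysis (classical metric scaling).

    Double-centers -D^2/2, eigendecomposes, and keeps axes with positive
    eigenvalues sorted descending.  Negative eigenvalues (non-Euclidean
    distances) are reported unchanged; no Lingoes/Cailliez correction.
    """
    d = np.asarray(dist.data, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("PCoA requires at least 2 samples")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals).max(), 1.0) * 1e-12
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    axes = [f"PCo{i + 1}" for i in range(int(pos.sum()))]
    pos_sum = eigvals[pos].sum()
    prop = eigvals[pos] / pos_sum if pos_sum > 0 else eigvals[pos]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=list(dist.ids), columns=axes),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


@dataclass
class AdonisResult:
    """One-way PERMANOVA (ADONIS) outcome."""

    pseudo_F: float
    r_squared: float
    p_value: float
    permutations_used: int


def _permanova_ss(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Total and within-group sums of squared distances (SST, SSW)."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    sst = d2[iu].sum() / n
    ssw = 0.0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ssw += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return sst, ssw


def _pseudo_f(d2: np.ndarray, groups: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    sst, ssw = _permanova_ss(d2, groups)
    ssb = sst - ssw
    if ssw <= 0:
        return math.inf
    return (ssb / (n_groups - 1)) / (ssw / (n - n_groups))


def permanova(
    dist: DistanceMatrix,
    groups,
    permutations: int = 5000,
    seed: int | None = None,
    *,
    exhaustive: bool = False,
) -> AdonisResult:
    """One-way PERMANOVA on a distance matrix.

    SST = sum of squared pairwise distances / n; SSW analogously within
    groups; F = (SSB/(g-1)) / (SSW/(n-g)); R^2 = SSB/SST.  The p-value
    counts permuted F >= observed F over ``permutations`` random relabelings
    with the (B+1) correction, or over all n! relabelings when
    ``exhaustive`` is set (then p is the exact exceedance fraction, identity
    included).
    """
    groups = np.asarray(list(groups))
    if len(groups) != len(dist.ids):
        raise ValueError("groups must match the distance matrix samples")
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    d2 = np.asarray(dist.data, dtype=float) ** 2
    n, g = len(groups), len(uniq)
    sst, ssw = _permanova_ss(d2, groups)
    ssb = sst - ssw
    r2 = ssb / sst if sst > 0 else 0.0
    f_obs = _pseudo_f(d2, groups, g)

    if exhaustive:
        total = 0
        exceed = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if _pseudo_f(d2, groups[list(perm)], g) >= f_obs:
                exceed += 1
        return AdonisResult(f_obs, r2, exceed / total, total)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(permutations):
        if _pseudo_f(d2, groups[rng.permutation(n)], g) >= f_obs:
            exceed += 1
    p = (exceed + 1) / (permutations + 1)
    return AdonisResult(f_obs, r2, p, permutations)


# -- paired tests -----------------------------------------------------------

def paired_wilcoxon(a, b) -> float:
    """Exact two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped (Wilcoxon's convention); the exact signed-
    rank distribution is used, which is what makes the small-n landmarks
    reachable (n = 5 all-same-sign pairs give p = 2/32 = 0.0625).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("paired_wilcoxon needs two equal-length vectors, n >= 3")
    diff = a - b
    if np.all(diff == 0):
        raise ValueError("all paired differences are zero; test undefined")
    method = "exact" if np.count_nonzero(diff) <= 25 else "auto"
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                         method=method)
    return float(res.pvalue)


def paired_ttest(a, b) -> float:
    """Two-sided paired t-test p-value; zero-variance differences are an error."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("paired_ttest needs two equal-length vectors, n >= 3")
    diff = a - b
    if np.ptp(diff) == 0:
        raise ValueError("paired differences have zero variance; t-test undefined")
    return float(stats.ttest_rel(a, b).pvalue)


def shapiro_wilk(x) -> float:
    """Shapiro-Wilk normality p-value (diagnostic)."""
    return float(stats.shapiro(np.asarray(x, dtype=float)).pvalue)


# -- extraction QC ----------------------------------------------------------

def dna_yield_per_gram(concentration_ng_per_ul: float, eluate_volume_ul: float,
                       tissue_mass_g: float) -> float:
    """ng of DNA recovered per gram of tissue: concentration x volume / mass."""
    if concentration_ng_per_ul <= 0 or eluate_volume_ul <= 0 or tissue_mass_g <= 0:
        raise ValueError("concentration, volume and mass must all be positive")
    return concentration_ng_per_ul * eluate_volume_ul / tissue_mass_g
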