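"""Richness, normalization, ordination and group-difference statistics.

Formula-level implementations of the alpha/beta-diversity toolbox used on
amplicon count tables: Chao1 richness (bias-corrected by default, with the
standard variance formulas), the closed-form rarefaction curve, total-sum
normalization to a fixed depth (default 100,000 reads), Bray-Curtis
dissimilarity, principal coordinates analysis by Gower double-centering,
correlation-based biplot loadings, one-way PERMANOVA (Anderson's pseudo-F
with whole-label permutation), and one-way ANOVA followed by Tukey's HSD with
a compact letter display.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .io_tables import CountMatrix


# ---------------------------------------------------------------------------
# Result types
# ---------------------------------------------------------------------------


@dataclass
class RichnessResult:
    sample_id: str
    observed_s: int
    chao1: float
    chao1_se: float

    def __post_init__(self) -> None:
        if self.chao1 < self.observed_s - 1e-9:
            raise ValueError("Chao1 estimate below observed richness")
        if self.chao1_se < 0:
            raise ValueError("negative Chao1 SE")


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.sample_ids)
        if m.shape != (n, n):
            raise ValueError(f"distance matrix shape {m.shape} != ({n}, {n})")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal not zero")
        self.matrix = m


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x kept axes
    eigenvalues: np.ndarray  # all eigenvalues, sorted descending
    proportion_explained: np.ndarray  # per kept axis
    feature_loadings: Optional[dict] = None


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError("PERMANOVA p-value outside (0, 1]")
        if not (-1e-12 <= self.r2 <= 1 + 1e-12):
            raise ValueError("R2 outside [0, 1]")


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------


def chao1(
    counts: Sequence[float], bias_corrected: bool = True, sample_id: str = ""
) -> RichnessResult:
    """Chao1 richness from one sample's feature counts.

    Bias-corrected form S_obs + f1(f1-1)/(2(f2+1)); the classic form
    S_obs + f1^2/(2 f2) is available (it falls back to the bias-corrected
    term when no doubletons exist, where it is otherwise undefined).  The SE
    comes from the standard variance formulas for the chosen variant.
    """
    c = np.asarray(counts, dtype=float)
    if c.size and (np.any(c < 0) or np.any(c != np.round(c))):
        raise ValueError("Chao1 requires non-negative integer counts (raw, not normalized)")
    s_obs = int(np.sum(c > 0))
    f1 = int(np.sum(c == 1))
    f2 = int(np.sum(c == 2))

    if bias_corrected or f2 == 0:
        est = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    else:
        est = s_obs + f1 * f1 / (2.0 * f2)

    if f1 == 0:
        var = 0.0
    elif bias_corrected or f2 == 0:
        if f2 > 0:
            var = (
                f1 * (f1 - 1) / (2.0 * (f2 + 1))
                + f1 * (2 * f1 - 1) ** 2 / (4.0 * (f2 + 1) ** 2)
                + f1**2 * f2 * (f1 - 1) ** 2 / (4.0 * (f2 + 1) ** 4)
            )
        else:
            var = (
                f1 * (f1 - 1) / 2.0
                + f1 * (2 * f1 - 1) ** 2 / 4.0
                - f1**4 / (4.0 * est)
            )
    else:
        r = f1 / f2
        var = f2 * (r**2 / 2.0 + r**3 + r**4 / 4.0)
    return RichnessResult(sample_id, s_obs, float(est), float(np.sqrt(max(var, 0.0))))


def richness_per_sample(matrix: CountMatrix, bias_corrected: bool = True) -> list[RichnessResult]:
    if matrix.normalized:
        raise ValueError("Chao1 is undefined on normalized tables; use raw counts")
    return [
        chao1(matrix.counts[:, j], bias_corrected, sid)
        for j, sid in enumerate(matrix.sample_ids)
    ]


def rarefaction_curve(counts: Sequence[float], depths: Sequence[int]) -> np.ndarray:
    """Expected richness at each subsampling depth, by the closed form.

    E[S_n] = sum_i 1 - C(N - N_i, n) / C(N, n), evaluated in log-gamma space.
    """
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0) or np.any(c != np.round(c)):
        raise ValueError("rarefaction requires non-negative integer counts")
    c = c[c > 0]
    n_total = int(c.sum())
    out = np.empty(len(depths), dtype=float)
    for k, depth in enumerate(depths):
        n = int(depth)
        if n > n_total:
            raise ValueError(f"depth {n} exceeds sample total {n_total}")
        if n == 0:
            out[k] = 0.0
            continue
        # log C(N - Ni, n) - log C(N, n); zero probability when N - Ni < n
        keep = (n_total - c) >= n
        log_absent = np.full(c.shape, -np.inf)
        if np.any(keep):
            m = n_total - c[keep]
            log_absent[keep] = (
                _lchoose(m, n) - _lchoose(n_total, n)
            )
        out[k] = float(np.sum(1.0 - np.exp(log_absent)))
    return out


def _lchoose(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize(
    matrix: CountMatrix,
    target: int = 100_000,
    method: str = "total_sum",
    seed: Optional[int] = None,
) -> CountMatrix:
    """Bring every sample to a common depth for composition comparisons.

    ``total_sum`` rescales each column to sum exactly to ``target``
    (fractional values, flagged normalized).  ``rarefy`` draws a
    without-replacement subsample of ``target`` reads per column; columns
    below the target are dropped with a warning.
    """
    sums = matrix.counts.sum(axis=0)
    empty = [s for s, t in zip(matrix.sample_ids, sums) if t == 0]
    if empty:
        raise ValueError(f"cannot normalize empty sample(s): {empty}")
    if method == "total_sum":
        scaled = matrix.counts * (target / sums)
        return CountMatrix(
            list(matrix.feature_ids),
            list(matrix.sample_ids),
            scaled,
            matrix.feature_kind,
            normalized=True,
        )
    if method == "rarefy":
        if matrix.normalized:
            raise ValueError("rarefying requires raw integer counts")
        rng = np.random.default_rng(seed)
        keep_cols, cols = [], []
        for j, sid in enumerate(matrix.sample_ids):
            if sums[j] < target:
                warnings.warn(
                    f"sample {sid} has {int(sums[j])} < {target} reads; dropped",
                    stacklevel=2,
                )
                continue
            col = matrix.counts[:, j].astype(np.int64)
            sub = rng.multivariate_hypergeometric(col, target)
            keep_cols.append(sid)
            cols.append(sub)
        counts = (
            np.column_stack(cols).astype(float)
            if cols
            else np.zeros((len(matrix.feature_ids), 0))
        )
        return CountMatrix(
            list(matrix.feature_ids), keep_cols, counts, matrix.feature_kind, normalized=False
        )
    raise ValueError(f"unknown normalization method {method!r}")


# ---------------------------------------------------------------------------
# Beta diversity & ordination
# ---------------------------------------------------------------------------


def bray_curtis(matrix: CountMatrix) -> DistanceMatrix:
    """Pairwise Bray-Curtis: d(x, y) = 1 - 2*sum(min(x, y)) / (sum x + sum y)."""
    x = matrix.counts
    n = len(matrix.sample_ids)
    if n < 2:
        raise ValueError("Bray-Curtis needs at least 2 samples")
    totals = x.sum(axis=0)
    empty = [s for s, t in zip(matrix.sample_ids, totals) if t == 0]
    if empty:
        raise ValueError(f"sample(s) with zero total: {empty}")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = np.minimum(x[:, i], x[:, j]).sum()
            d[i, j] = d[j, i] = 1.0 - 2.0 * shared / (totals[i] + totals[j])
    return DistanceMatrix(list(matrix.sample_ids), d)


def pcoa(dist: DistanceMatrix, eig_tol: float = 1e-9) -> OrdinationResult:
    """Principal coordinates by Gower double-centering and eigendecomposition.

    B = -1/2 H D^2 H with H = I - 11'/n; axes with eigenvalue > tol (relative
    to the largest) are kept, coordinates are eigenvector * sqrt(eigenvalue).
    Negative eigenvalues are reported unchanged, never corrected.
    """
    d = dist.matrix
    n = d.shape[0]
    a = -0.5 * d**2
    h = np.eye(n) - np.ones((n, n)) / n
    b = h @ a @ h
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    scale = max(abs(eigval[0]), 1.0) if n else 1.0
    keep = eigval > eig_tol * scale
    coords = eigvec[:, keep] * np.sqrt(eigval[keep])
    pos_sum = eigval[eigval > 0].sum()
    prop = eigval[keep] / pos_sum if pos_sum > 0 else np.zeros(int(keep.sum()))
    return OrdinationResult(list(dist.sample_ids), coords, eigval, prop)


def biplot_loadings(
    matrix: CountMatrix, ordination: OrdinationResult, magnitude_cutoff: float = 0.1
) -> dict:
    """Correlation-based feature loadings on the ordination axes.

    Loading of feature f on axis k = Pearson r(f, axis-k coordinates) scaled
    by sd(axis k)/sd(axis 1), so later (lower-variance) axes are
    down-weighted.  Constant features load 0.  Returns per-feature loading
    vectors plus the set flagged above the magnitude cutoff.
    """
    if matrix.sample_ids != ordination.sample_ids:
        raise ValueError("ordination was computed from different samples")
    coords = ordination.coordinates
    if coords.size == 0:
        return {"loadings": {f: np.zeros(0) for f in matrix.feature_ids}, "flagged": []}
    axis_sd = coords.std(axis=0, ddof=1)
    ref_sd = axis_sd[0] if axis_sd[0] > 0 else 1.0
    loadings = {}
    flagged = []
    for i, fid in enumerate(matrix.feature_ids):
        row = matrix.counts[i]
        vec = np.zeros(coords.shape[1])
        if np.std(row) > 0:
            for k in range(coords.shape[1]):
                if axis_sd[k] > 0:
                    r = np.corrcoef(row, coords[:, k])[0, 1]
                    vec[k] = r * axis_sd[k] / ref_sd
        loadings[fid] = vec
        if np.max(np.abs(vec), initial=0.0) > magnitude_cutoff:
            flagged.append(fid)
    return {"loadings": loadings, "flagged": flagged}


# ---------------------------------------------------------------------------
# Group tests
# ---------------------------------------------------------------------------


def permanova(
    dist: DistanceMatrix,
    groups: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA: Anderson's pseudo-F with free label permutation.

    F = ((SS_T - SS_W)/(a-1)) / (SS_W/(N-a)) with SS_T = sum_{i<j} d_ij^2 / N
    and SS_W the within-group analogue; p = (1 + #{F_perm >= F_obs}) /
    (1 + n_perm).
    """
    labels = np.asarray(groups)
    n = len(labels)
    if n != len(dist.sample_ids):
        raise ValueError("group labels do not match distance matrix samples")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if np.any(counts < 2):
        small = uniq[counts < 2].tolist()
        raise ValueError(f"group(s) of size 1: {small}")
    d2 = dist.matrix**2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n

    def ss_within(lab: np.ndarray) -> float:
        ss = 0.0
        for g in uniq:
            idx = np.nonzero(lab == g)[0]
            sub = d2[np.ix_(idx, idx)]
            ss += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        return ss

    a = len(uniq)
    ssw = ss_within(labels)
    f_obs = ((ss_total - ssw) / (a - 1)) / (ssw / (n - a))
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_perm):
        perm = labels[rng.permutation(n)]
        ssw_p = ss_within(perm)
        f_p = ((ss_total - ssw_p) / (a - 1)) / (ssw_p / (n - a))
        if f_p >= f_obs:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_perm)
    r2 = (ss_total - ssw) / ss_total if ss_total > 0 else 0.0
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm, seed)


def anova_tukey(
    groups: dict[str, Sequence[float]], alpha: float = 0.05
) -> dict:
    """One-way ANOVA; Tukey HSD pairwise p-values; compact letter display.

    Groups sharing a letter are not significantly different at ``alpha``.
    Tukey results are always computed; by convention they are interpreted
    only when the ANOVA is significant.
    """
    names = sorted(groups)
    data = [np.asarray(groups[g], dtype=float) for g in names]
    if len(names) < 2 or any(len(v) < 2 for v in data):
        raise ValueError("need >=2 groups with >=2 observations each")
    if all(np.var(v) == 0 for v in data):
        raise ValueError("zero within-group variance in every group")
    f_stat, p_anova = stats.f_oneway(*data)
    hsd = stats.tukey_hsd(*data)
    pairwise = {}
    nonsig = {frozenset((g,)) for g in names}
    nonsig_pairs = set()
    for i, j in itertools.combinations(range(len(names)), 2):
        p = float(hsd.pvalue[i, j])
        pairwise[(names[i], names[j])] = p
        if p >= alpha:
            nonsig_pairs.add(frozenset((names[i], names[j])))
    letters = _compact_letters(names, [float(np.mean(v)) for v in data], nonsig_pairs)
    return {
        "f": float(f_stat),
        "p": float(p_anova),
        "pairwise_p": pairwise,
        "letters": letters,
        "significant": bool(p_anova < alpha),
    }


def _compact_letters(
    names: list[str], means: list[float], nonsig_pairs: set[frozenset]
) -> dict[str, str]:
    """Letters from maximal cliques of the non-significance graph."""

    def compatible(group: tuple[str, ...]) -> bool:
        return all(
            frozenset((a, b)) in nonsig_pairs
            for a, b in itertools.combinations(group, 2)
        )

    cliques: list[tuple[str, ...]] = []
    order = [n for _, n in sorted(zip(means, names), key=lambda t: -t[0])]
    for size in range(len(order), 0, -1):
        for combo in itertools.combinations(order, size):
            if not compatible(combo):
                continue
            if any(set(combo) <= set(c) for c in cliques):
                continue
            cliques.append(combo)
    cliques.sort(key=lambda c: min(order.index(n) for n in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {n: "" for n in names}
    for li, clique in enumerate(cliques):
        for n in clique:
            out[n] += alphabet[li % len(alphabet)]
    return out
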