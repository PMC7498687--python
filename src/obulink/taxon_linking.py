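"""Attribute biosynthetic-domain units (OBUs) to taxa by regression screening.

The model assumes a domain amplicon and the producer's 16S gene sit on the
same chromosome, so their per-sample counts co-vary linearly through the
cell count of the producer.  For every (OBU i, species j) pair a no-intercept
linear model

    OBU_i = alpha_{i,j} * species_j

is fitted by least squares; pairs whose slope t-test does not reach the fixed
significance screen (default P < 0.001, no multiplicity correction — the
number of tests is always reported) are discarded.  Linked OBUs are then
aggregated to the genus level (union semantics: an OBU linked to two
congeneric species counts once) and genus biosynthetic potential is compared
against genus relative abundance.

Before screening, matrices are cleaned by the prevalence/total-read rule and
perfectly collinear species (pairwise Pearson r^2 = 1) are de-duplicated,
keeping one representative per collinear group.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .diversity_stats import normalize
from .io_tables import CountMatrix, TaxonomyTable

_P_MIN = 1e-300  # underflow-safe floor for p-values of exact fits


@dataclass
class LinkRecord:
    """One screened (OBU, species) association."""

    obu_id: str
    species_id: str
    alpha_hat: float
    t_stat: float
    p_value: float
    n_samples: int
    r2: float

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1):
            raise ValueError("p-value outside [0, 1]")
        if self.n_samples < 2:
            raise ValueError("link fitted on fewer than 2 samples")


@dataclass
class GenusSummary:
    genus: str
    order: str
    mean_rel_abundance: float
    n_linked_obus: int
    obu_ids: list[str]

    def __post_init__(self) -> None:
        if self.n_linked_obus != len(self.obu_ids):
            raise ValueError("n_linked_obus inconsistent with obu_ids")
        if not (0 <= self.mean_rel_abundance <= 1):
            raise ValueError("relative abundance outside [0, 1]")


# ---------------------------------------------------------------------------
# Cleaning & de-duplication
# ---------------------------------------------------------------------------


def clean_matrices(
    species: CountMatrix,
    obus: CountMatrix,
    min_total: int = 10,
    combine: str = "AND",
) -> tuple[CountMatrix, CountMatrix, dict]:
    """Drop sparse features; align the two tables on their shared samples.

    A feature is removed when (present in <=1 sample) AND (total reads <
    ``min_total``) under the default reading of the rule; ``combine="OR"``
    removes on either condition.  The report lists every removed id and which
    condition(s) fired, so the AND/OR ambiguity stays visible.
    """
    if combine not in ("AND", "OR"):
        raise ValueError("combine must be 'AND' or 'OR'")
    shared = [s for s in species.sample_ids if s in set(obus.sample_ids)]
    if len(shared) < 2:
        raise ValueError(
            f"only {len(shared)} shared sample(s); regression needs at least 2"
        )
    sp = species.select_samples(shared)
    ob = obus.select_samples(shared)

    report: dict = {"shared_samples": shared, "removed": {}}

    def filter_one(m: CountMatrix, label: str) -> CountMatrix:
        keep = []
        for i, fid in enumerate(m.feature_ids):
            row = m.counts[i]
            prevalence = int(np.sum(row > 0))
            total = float(row.sum())
            low_prev = prevalence <= 1
            low_total = total < min_total
            fired = (low_prev and low_total) if combine == "AND" else (low_prev or low_total)
            if fired:
                reasons = []
                if low_prev:
                    reasons.append("prevalence<=1")
                if low_total:
                    reasons.append(f"total<{min_total}")
                report["removed"][fid] = {"table": label, "reasons": reasons}
            else:
                keep.append(fid)
        return m.select_features(keep)

    return filter_one(sp, "species"), filter_one(ob, "obus"), report


def dedup_collinear_species(
    species: CountMatrix, r2_tol: float = 1 - 1e-12
) -> tuple[CountMatrix, dict]:
    """Collapse species whose pairwise Pearson r^2 reaches 1.

    Groups are the transitive closure of the r^2 >= tol relation; within each
    group only the member with the highest total count survives (ties broken
    by id).  Constant (zero-variance) species have undefined correlations and
    are removed with reason "constant".
    """
    x = species.counts
    n_feat = len(species.feature_ids)
    totals = x.sum(axis=1)
    variances = x.var(axis=1)
    constant = variances == 0

    parent = list(range(n_feat))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    live = np.nonzero(~constant)[0]
    if len(live) > 1:
        sub = x[live]
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub)
        r2 = corr**2
        for a, b in itertools.combinations(range(len(live)), 2):
            if r2[a, b] >= r2_tol:
                union(int(live[a]), int(live[b]))

    groups: dict[int, list[int]] = {}
    for i in live:
        groups.setdefault(find(int(i)), []).append(int(i))

    keep: list[str] = []
    report: dict = {"removed": {}, "groups": []}
    for members in groups.values():
        best = min(members, key=lambda i: (-totals[i], species.feature_ids[i]))
        ids = sorted(species.feature_ids[i] for i in members)
        if len(members) > 1:
            report["groups"].append(
                {"members": ids, "representative": species.feature_ids[best]}
            )
        for i in members:
            if i == best:
                keep.append(species.feature_ids[i])
            else:
                report["removed"][species.feature_ids[i]] = species.feature_ids[best]
    for i in np.nonzero(constant)[0]:
        report["removed"][species.feature_ids[int(i)]] = "constant"

    keep_order = [f for f in species.feature_ids if f in set(keep)]
    return species.select_features(keep_order), report


# ---------------------------------------------------------------------------
# Regression screen
# ---------------------------------------------------------------------------


def fit_link(
    obu_counts: Sequence[float],
    species_counts: Sequence[float],
    obu_id: str = "",
    species_id: str = "",
    df_convention: str = "n-1",
) -> LinkRecord:
    """No-intercept least squares of one OBU on one species.

    alpha_hat = sum(xy)/sum(x^2); s^2 = RSS/df; SE = sqrt(s^2/sum(x^2));
    t = alpha_hat/SE; two-sided p from Student t.  ``df_convention`` selects
    df = n-1 (default) or n.  r^2 uses the no-intercept convention
    1 - RSS/sum(y^2).
    """
    y = np.asarray(obu_counts, dtype=float)
    x = np.asarray(species_counts, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("OBU and species vectors must be equal-length 1-D")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 samples")
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise ValueError(f"species vector all zero ({species_id or 'x'}); link undefined")
    sxy = float(np.dot(x, y))
    syy = float(np.dot(y, y))
    alpha = sxy / sxx
    rss = max(syy - alpha * sxy, 0.0)
    df = n - 1 if df_convention == "n-1" else n
    s2 = rss / df
    if s2 == 0.0:
        t = np.inf if alpha != 0 else 0.0
        p = _P_MIN if alpha != 0 else 1.0
    else:
        se = np.sqrt(s2 / sxx)
        t = alpha / se
        p = max(2.0 * stats.t.sf(abs(t), df), _P_MIN)
    r2 = 1.0 - rss / syy if syy > 0 else 0.0
    return LinkRecord(obu_id, species_id, float(alpha), float(t), float(p), n, float(r2))


def screen_links(
    species: CountMatrix,
    obus: CountMatrix,
    p_threshold: float = 0.001,
    input_scale: str = "normalized",
    norm_target: int = 100_000,
    df_convention: str = "n-1",
) -> tuple[list[LinkRecord], int]:
    """Fit every OBU x species pair; keep links with p below the screen.

    Returns ``(records, n_tests)`` — the pre-filter test count is always
    reported so users can apply their own multiplicity correction.  The fits
    run on total-sum-normalized abundances by default (slopes comparable
    across unequal depths); ``input_scale="raw"`` fits the counts as given.
    All pairs are computed vectorized with the same closed forms as
    :func:`fit_link`.
    """
    if input_scale not in ("normalized", "raw"):
        raise ValueError("input_scale must be 'normalized' or 'raw'")
    if species.sample_ids != obus.sample_ids:
        raise ValueError("species and OBU tables must share an identical sample order")
    if len(species.feature_ids) == 0 or len(obus.feature_ids) == 0:
        return [], 0
    if input_scale == "normalized":
        if not species.normalized:
            species = normalize(species, norm_target)
        if not obus.normalized:
            obus = normalize(obus, norm_target)
    return screen_pairs(
        species.counts,
        obus.counts,
        species.feature_ids,
        obus.feature_ids,
        p_threshold=p_threshold,
        df_convention=df_convention,
    )


def screen_pairs(
    x: np.ndarray,
    y: np.ndarray,
    species_ids: Sequence[str],
    obu_ids: Sequence[str],
    p_threshold: float = 0.001,
    df_convention: str = "n-1",
) -> tuple[list[LinkRecord], int]:
    """Vectorized all-pairs no-intercept screen on raw value matrices.

    ``x`` is species x samples, ``y`` is OBUs x samples; the same closed forms
    as :func:`fit_link`, computed for every pair at once.  This is the
    numeric engine behind :func:`screen_links`; it also accepts mean-centered
    or residual values (e.g., for calibration studies), where negative
    entries are meaningful.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[1]
    if y.shape[1] != n:
        raise ValueError("species and OBU matrices must share samples")
    if y.shape[0] == 0 or x.shape[0] == 0:
        return [], 0
    sxx = np.einsum("pn,pn->p", x, x)
    ok = sxx > 0
    syy = np.einsum("qn,qn->q", y, y)
    sxy = y @ x.T  # q x p
    df = n - 1 if df_convention == "n-1" else n
    records: list[LinkRecord] = []
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = sxy / sxx[None, :]
        rss = np.maximum(syy[:, None] - alpha * sxy, 0.0)
        s2 = rss / df
        se = np.sqrt(s2 / sxx[None, :])
        t = np.where(se > 0, alpha / se, np.where(alpha != 0, np.inf, 0.0))
        p = np.where(
            s2 == 0.0,
            np.where(alpha != 0, _P_MIN, 1.0),
            np.maximum(2.0 * stats.t.sf(np.abs(t), df), _P_MIN),
        )
        r2 = np.where(syy[:, None] > 0, 1.0 - rss / np.maximum(syy[:, None], 1e-300), 0.0)
    n_tests = int(y.shape[0] * ok.sum())
    qi, pi = np.nonzero((p < p_threshold) & ok[None, :])
    for i, j in zip(qi, pi):
        records.append(
            LinkRecord(
                obu_ids[i],
                species_ids[j],
                float(alpha[i, j]),
                float(t[i, j]),
                float(p[i, j]),
                n,
                float(r2[i, j]),
            )
        )
    records.sort(key=lambda r: (r.obu_id, r.p_value, r.species_id))
    return records, n_tests


# ---------------------------------------------------------------------------
# Genus aggregation
# ---------------------------------------------------------------------------


def summarize_by_genus(
    links: Sequence[LinkRecord],
    taxonomy: TaxonomyTable,
    species: CountMatrix,
) -> list[GenusSummary]:
    """Per-genus union of linked OBUs plus mean relative abundance.

    Every genus represented in the species table appears, including genera
    with zero linked OBUs — those are the points shown as triangles rather
    than bubbles in abundance-vs-potential displays.
    """
    missing = sorted(
        {l.species_id for l in links} - set(taxonomy.lineages)
    )
    if missing:
        raise ValueError(f"linked species missing from taxonomy: {missing}")
    rel = species.counts / species.counts.sum(axis=0, keepdims=True)
    mean_rel = rel.mean(axis=1)
    sp_index = {s: i for i, s in enumerate(species.feature_ids)}

    genus_info: dict[str, dict] = {}
    for sp in species.feature_ids:
        if sp not in taxonomy.lineages:
            raise ValueError(f"species {sp} missing from taxonomy")
        g = taxonomy.rank_of(sp, "genus")
        info = genus_info.setdefault(
            g, {"order": taxonomy.rank_of(sp, "order"), "abund": 0.0, "obus": set()}
        )
        info["abund"] += float(mean_rel[sp_index[sp]])
    for link in links:
        if link.species_id not in sp_index:
            continue
        g = taxonomy.rank_of(link.species_id, "genus")
        genus_info[g]["obus"].add(link.obu_id)

    out = [
        GenusSummary(
            genus=g,
            order=info["order"],
            mean_rel_abundance=min(info["abund"], 1.0),
            n_linked_obus=len(info["obus"]),
            obu_ids=sorted(info["obus"]),
        )
        for g, info in genus_info.items()
    ]
    out.sort(key=lambda s: (-s.n_linked_obus, -s.mean_rel_abundance, s.genus))
    return out


def abundance_vs_potential(summaries: Sequence[GenusSummary]) -> dict:
    """OLS (with intercept) of linked-OBU count on genus relative abundance.

    Under the chromosome-cooccurrence model there is no reason for abundant
    genera to carry more biosynthetic domains, so r^2 near zero is the
    expected outcome on communities with abundance-independent planted links.
    """
    if len(summaries) < 3:
        raise ValueError("need at least 3 genera for the regression")
    x = np.array([s.mean_rel_abundance for s in summaries])
    y = np.array([float(s.n_linked_obus) for s in summaries])
    if np.var(x) == 0:
        raise ValueError("zero variance in genus abundance")
    res = stats.linregress(x, y)
    return {
        "r2": float(res.rvalue**2),
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "p": float(res.pvalue),
        "n_genera": len(summaries),
    }
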