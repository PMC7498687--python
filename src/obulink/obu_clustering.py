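"""Biosynthetic-domain amplicon processing: trim, join, two-round clustering.

Pipeline: forward/reverse reads are trimmed to fixed lengths (defaults 240 bp
and 175 bp), joined as ``forward + "N" + reverse_complement(reverse)``,
clustered greedily within each sample at 97% identity, pooled across samples,
clustered a second time at 95% on the round-1 centroids (carrying member
counts as abundance weights), and clusters left with a single member read are
discarded.  The surviving 95% clusters are the operational biosynthetic units
(OBUs); the result is an OBU-by-sample count table.

Identity metric: global Needleman-Wunsch alignment (match +1, mismatch -1,
gap -2); identity = matching columns / alignment columns, excluding
terminal-gap columns and any column containing N (the join spacer must not
penalize).  Chimera checking is a pass-through hook.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from Bio import Align

from .io_tables import CountMatrix, SequenceRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class JoinedRead:
    """A trimmed pair joined with a single N spacer; clustering input."""

    read_id: str
    sample_id: str
    sequence: str
    weight: float = 1.0


@dataclass
class ObuCluster:
    """A greedy identity cluster: centroid, per-sample counts, members."""

    obu_id: str
    centroid: str
    per_sample_counts: dict[str, int]
    member_read_ids: list[str]
    round: str = "within_sample"

    @property
    def total_count(self) -> int:
        return sum(self.per_sample_counts.values())

    def __post_init__(self) -> None:
        if self.total_count != len(self.member_read_ids):
            raise ValueError(
                f"{self.obu_id}: per-sample counts sum {self.total_count} != "
                f"{len(self.member_read_ids)} members"
            )


# ---------------------------------------------------------------------------
# Trim & join
# ---------------------------------------------------------------------------


def _bare_id(read_id: str) -> str:
    for suffix in ("/1", "/2"):
        if read_id.endswith(suffix):
            return read_id[: -len(suffix)]
    return read_id


def trim_pair(
    forward: SequenceRecord,
    reverse: SequenceRecord,
    fwd_len: int = 240,
    rev_len: int = 175,
) -> Optional[tuple[SequenceRecord, SequenceRecord]]:
    """Truncate both mates from the 3' end; None when either is too short.

    Pairs shorter than the target lengths are discarded (returned as None and
    tallied by the caller) rather than padded, because downstream joining
    assumes fixed-length reads.
    """
    if _bare_id(forward.read_id) != _bare_id(reverse.read_id):
        raise ValueError(
            f"unpaired reads: {forward.read_id!r} vs {reverse.read_id!r}"
        )
    if len(forward.sequence) < fwd_len or len(reverse.sequence) < rev_len:
        return None
    f = SequenceRecord(
        forward.read_id,
        forward.sequence[:fwd_len],
        forward.qualities[:fwd_len] if forward.qualities else None,
        forward.sample_id,
    )
    r = SequenceRecord(
        reverse.read_id,
        reverse.sequence[:rev_len],
        reverse.qualities[:rev_len] if reverse.qualities else None,
        reverse.sample_id,
    )
    return f, r


def join_pair(forward: SequenceRecord, reverse: SequenceRecord) -> JoinedRead:
    """forward + 'N' + reverse-complement(reverse), weight 1."""
    return JoinedRead(
        read_id=_bare_id(forward.read_id),
        sample_id=forward.sample_id,
        sequence=forward.sequence + "N" + reverse_complement(reverse.sequence),
        weight=1.0,
    )


# ---------------------------------------------------------------------------
# Identity metric
# ---------------------------------------------------------------------------


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    # terminal gaps are penalized in the SCORE (a free-end-gap score lets two
    # unrelated amplicons "align" over a spurious short overlap and look
    # near-identical) but terminal-gap columns are excluded from the identity
    # VALUE, so length differences still do not depress identity
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Alignment identity with terminal-gap and N columns excluded.

    Matches / columns over the aligned core (outside the leading/trailing
    gap runs); any column where either sequence shows N is excluded from
    numerator and denominator, so the join spacer is identity-neutral.
    """
    if not a or not b:
        return 0.0
    alignment = _ALIGNER.align(a, b)[0]
    ga, gb = str(alignment[0]), str(alignment[1])
    # aligned core: outside either sequence's terminal gap runs
    start = max(_first_base(ga), _first_base(gb))
    end = min(_last_base(ga), _last_base(gb)) + 1
    matches = 0
    columns = 0
    for i in range(start, end):
        ca, cb = ga[i], gb[i]
        if ca == "N" or cb == "N":
            continue
        columns += 1
        if ca == cb and ca != "-":
            matches += 1
    return matches / columns if columns else 0.0


def _first_base(s: str) -> int:
    i = 0
    while i < len(s) and s[i] == "-":
        i += 1
    return i


def _last_base(s: str) -> int:
    i = len(s) - 1
    while i >= 0 and s[i] == "-":
        i -= 1
    return i


def _kmers(seq: str, k: int = 8) -> frozenset:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def _prefilter_passes(
    kmers_a: frozenset, kmers_b: frozenset, len_a: int, len_b: int, threshold: float, k: int = 8
) -> bool:
    """Conservative shared-k-mer bound: False only when identity >= threshold
    is impossible.  Each edit/offset column destroys at most k shared k-mers;
    the slack term covers N columns and alignment offsets."""
    allowed = int(np.ceil((1 - threshold) * max(len_a, len_b))) + 4
    need = min(len(kmers_a), len(kmers_b)) - k * allowed
    if need <= 0:
        return True
    return len(kmers_a & kmers_b) >= need


# ---------------------------------------------------------------------------
# Greedy clustering
# ---------------------------------------------------------------------------


def cluster_greedy(
    items: Sequence[JoinedRead | ObuCluster],
    identity_threshold: float,
    round_label: str = "within_sample",
    use_prefilter: bool = False,
) -> list[ObuCluster]:
    """Greedy centroid clustering, USEARCH-style and fully deterministic.

    Inputs are sorted by abundance weight descending (ties: sequence, then
    id); each item joins the first existing centroid with identity >= the
    threshold, else founds a new cluster.  Cluster ids are provisional
    (``c1``, ``c2``, ...); the pipeline assigns final OBU ids.
    """
    if not (0 < identity_threshold <= 1):
        raise ValueError(f"identity threshold {identity_threshold} outside (0, 1]")
    entries = []
    for it in items:
        if isinstance(it, ObuCluster):
            entries.append(
                (
                    float(it.total_count),
                    it.centroid,
                    it.obu_id,
                    dict(it.per_sample_counts),
                    list(it.member_read_ids),
                )
            )
        else:
            entries.append(
                (float(it.weight), it.sequence, it.read_id, {it.sample_id: 1}, [it.read_id])
            )
    entries.sort(key=lambda e: (-e[0], e[1], e[2]))

    clusters: list[ObuCluster] = []
    kmer_cache: list[frozenset] = []
    for weight, seq, item_id, counts, members in entries:
        kms = _kmers(seq) if use_prefilter else frozenset()
        target = None
        for ci, c in enumerate(clusters):
            if use_prefilter and not _prefilter_passes(
                kms, kmer_cache[ci], len(seq), len(c.centroid), identity_threshold
            ):
                continue
            if pairwise_identity(seq, c.centroid) >= identity_threshold:
                target = c
                break
        if target is None:
            clusters.append(
                ObuCluster(
                    obu_id=f"c{len(clusters) + 1}",
                    centroid=seq,
                    per_sample_counts=dict(counts),
                    member_read_ids=list(members),
                    round=round_label,
                )
            )
            if use_prefilter:
                kmer_cache.append(kms)
        else:
            for s, n in counts.items():
                target.per_sample_counts[s] = target.per_sample_counts.get(s, 0) + n
            target.member_read_ids.extend(members)
    return clusters


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def run_obu_pipeline(
    pairs_by_sample: dict[str, list[tuple[SequenceRecord, SequenceRecord]]],
    domain: str = "KS",
    id_within: float = 0.97,
    id_pooled: float = 0.95,
    fwd_len: int = 240,
    rev_len: int = 175,
    discard_singletons: bool = True,
    singleton_unit: str = "read",
    chimera_hook: Optional[Callable[[list[JoinedRead]], list[JoinedRead]]] = None,
    use_prefilter: bool = True,
) -> tuple[CountMatrix, list[ObuCluster], dict]:
    """Trim, join, cluster within-sample then pooled; emit the OBU table.

    Returns ``(matrix, final_clusters, report)`` where the report carries the
    discard tallies needed for count conservation:
    ``n_input_pairs == matrix.sum() + trim_discards + singleton_discards``.
    ``singleton_unit`` selects whether a singleton is one member *read*
    (default) or one round-1 *centroid*.
    """
    if singleton_unit not in ("read", "centroid"):
        raise ValueError(f"singleton_unit must be 'read' or 'centroid'")
    sample_ids = sorted(pairs_by_sample)
    n_input = sum(len(v) for v in pairs_by_sample.values())
    trim_discards = 0
    round1: list[ObuCluster] = []
    for sid in sample_ids:
        joined: list[JoinedRead] = []
        for fwd, rev in pairs_by_sample[sid]:
            trimmed = trim_pair(fwd, rev, fwd_len, rev_len)
            if trimmed is None:
                trim_discards += 1
                continue
            jf, jr = trimmed
            jr = SequenceRecord(jr.read_id, jr.sequence, jr.qualities, sid)
            jf = SequenceRecord(jf.read_id, jf.sequence, jf.qualities, sid)
            joined.append(join_pair(jf, jr))
        if chimera_hook is not None:
            joined = chimera_hook(joined)
        round1.extend(
            cluster_greedy(joined, id_within, "within_sample", use_prefilter)
        )
    if trim_discards:
        logger.info("discarded %d pairs shorter than trim targets", trim_discards)

    final = cluster_greedy(round1, id_pooled, "pooled", use_prefilter)

    singleton_discards = 0
    kept: list[ObuCluster] = []
    for c in final:
        if discard_singletons:
            n_units = (
                c.total_count if singleton_unit == "read" else _n_round1_members(c, round1)
            )
            if n_units <= 1:
                singleton_discards += c.total_count
                continue
        kept.append(c)

    kept.sort(key=lambda c: (-c.total_count, c.centroid))
    for i, c in enumerate(kept):
        c.obu_id = f"{domain}_OBU_{i + 1:05d}"

    if not kept:
        logger.warning("no OBUs survive clustering; emitting an empty table")
    counts = np.zeros((len(kept), len(sample_ids)), dtype=float)
    for i, c in enumerate(kept):
        for j, sid in enumerate(sample_ids):
            counts[i, j] = c.per_sample_counts.get(sid, 0)
    matrix = CountMatrix(
        [c.obu_id for c in kept], sample_ids, counts, feature_kind=f"OBU_{domain}"
    )
    report = {
        "n_input_pairs": n_input,
        "trim_discards": trim_discards,
        "singleton_discards": singleton_discards,
        "n_round1_clusters": len(round1),
        "n_final_clusters": len(kept),
    }
    return matrix, kept, report


def _n_round1_members(cluster: ObuCluster, round1: list[ObuCluster]) -> int:
    member_sets = {id(c): set(c.member_read_ids) for c in round1}
    mine = set(cluster.member_read_ids)
    return sum(1 for s in member_sets.values() if s and s <= mine)
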