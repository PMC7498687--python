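"""Cultured-fraction accounting: OBU recovery and culturability estimates.

Compares the biosynthetic-domain diversity seen directly in the environment
(eDNA) with the diversity recovered from pooled plate biomass (pDNA), and
expresses plate counts as a fraction of direct microscopy counts.  The two
OBU tables must come from one joint clustering run so their ids share a
namespace; recovery is presence-based (a set intersection), hence invariant
to sequencing-depth rescaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_tables import CountMatrix, SampleMetadata


@dataclass
class RecoveryReport:
    domain_kind: str
    source: str
    n_obus_edna: int
    n_obus_pdna: int
    n_shared: int
    pct_recovered: float
    n_pdna_only: int

    def __post_init__(self) -> None:
        if self.n_shared > min(self.n_obus_edna, self.n_obus_pdna):
            raise ValueError("shared OBUs exceed one of the pools")
        if not (0 <= self.pct_recovered <= 100):
            raise ValueError("recovery percentage outside [0, 100]")


@dataclass
class CulturabilityEstimate:
    sample_id: str
    cfu_per_unit: float
    direct_count_per_unit: float
    pct_culturable: float

    def __post_init__(self) -> None:
        if self.cfu_per_unit < 0 or self.direct_count_per_unit <= 0:
            raise ValueError("counts must be positive (direct count nonzero)")
        if self.pct_culturable < 0:
            raise ValueError("negative culturability")


def _present(matrix: CountMatrix, sample_ids: Sequence[str], min_count: int) -> set[str]:
    sub = matrix.select_samples(list(sample_ids))
    mask = (sub.counts >= min_count).any(axis=1)
    return {f for f, m in zip(sub.feature_ids, mask) if m}


def obu_recovery(
    edna: CountMatrix,
    pdna: CountMatrix,
    metadata: Optional[SampleMetadata] = None,
    pool_by: str = "source",
    min_count: int = 1,
) -> list[RecoveryReport]:
    """Per-source presence overlap between environmental and cultured OBUs.

    Samples of each table are pooled by the metadata field (default the
    environmental source); an OBU counts as present in a pool when any pooled
    sample holds at least ``min_count`` reads.  Without metadata all samples
    form one pool.  ``pct_recovered`` = 100 * shared / eDNA-pool size.
    """
    if edna.feature_kind != pdna.feature_kind:
        raise ValueError(
            f"feature kinds differ: {edna.feature_kind} vs {pdna.feature_kind}"
        )
    shared_ids = set(edna.feature_ids) & set(pdna.feature_ids)
    if not shared_ids:
        pref_e = {f.split("_")[0] for f in edna.feature_ids}
        pref_p = {f.split("_")[0] for f in pdna.feature_ids}
        if pref_e and pref_p and pref_e != pref_p:
            warnings.warn(
                "eDNA and pDNA tables share no OBU ids and use different id "
                "prefixes; were they produced by one joint clustering run?",
                stacklevel=2,
            )

    def pools(matrix: CountMatrix) -> dict[str, list[str]]:
        if metadata is None:
            return {"all": list(matrix.sample_ids)}
        out: dict[str, list[str]] = {}
        for s in matrix.sample_ids:
            if pool_by == "source":
                key = metadata.source(s)
            elif pool_by == "medium":
                key = metadata.medium(s)
            else:
                key = metadata.records[s][pool_by]
            out.setdefault(key, []).append(s)
        return out

    epools, ppools = pools(edna), pools(pdna)
    reports = []
    for source in sorted(set(epools) | set(ppools)):
        e_set = _present(edna, epools.get(source, []), min_count) if source in epools else set()
        p_set = _present(pdna, ppools.get(source, []), min_count) if source in ppools else set()
        n_shared = len(e_set & p_set)
        pct = 100.0 * n_shared / len(e_set) if e_set else 0.0
        reports.append(
            RecoveryReport(
                domain_kind=edna.feature_kind,
                source=source,
                n_obus_edna=len(e_set),
                n_obus_pdna=len(p_set),
                n_shared=n_shared,
                pct_recovered=pct,
                n_pdna_only=len(p_set - e_set),
            )
        )
    return reports


def culturability(
    cfu: Sequence[float] | float,
    direct_counts: Sequence[float] | float,
    sample_ids: Optional[Sequence[str]] = None,
) -> list[CulturabilityEstimate]:
    """CFU as a percentage of direct (stain-based) cell counts, per sample."""
    cfu_arr = np.atleast_1d(np.asarray(cfu, dtype=float))
    direct_arr = np.atleast_1d(np.asarray(direct_counts, dtype=float))
    if cfu_arr.shape != direct_arr.shape:
        raise ValueError("cfu and direct counts must have matching shapes")
    if np.any(direct_arr <= 0):
        raise ValueError("direct counts must be positive")
    if np.any(cfu_arr < 0):
        raise ValueError("CFU counts must be non-negative")
    ids = list(sample_ids) if sample_ids is not None else [
        f"sample{i + 1}" for i in range(len(cfu_arr))
    ]
    if len(ids) != len(cfu_arr):
        raise ValueError("sample_ids length mismatch")
    return [
        CulturabilityEstimate(sid, float(c), float(d), 100.0 * float(c) / float(d))
        for sid, c, d in zip(ids, cfu_arr, direct_arr)
    ]
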