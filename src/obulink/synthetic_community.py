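"""Synthetic paired 16S/biosynthetic-domain communities with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: species abundances follow a log-normal law shared across replicate
samples (up to log-normal replicate jitter), and each *producer* species
carries a fixed set of biosynthetic-domain units (OBUs) whose counts are
proportional to the producer's counts — the two genes sit on one chromosome,
so their amplicon counts co-vary linearly.  Non-producer background OBUs are
sampled independently of every species.  A sequence mode additionally emits
paired reads from per-OBU centroid sequences so that the clustering stage can
be exercised against known memberships.

Three independent random streams (community, OBU counts, reads) are derived
from the master seed so each piece can be regenerated in isolation.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io_tables import (
    CountMatrix,
    SampleMetadata,
    SequenceRecord,
    TaxonomyTable,
)

_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    """Infeasible or inconsistent generator configuration."""


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic community.

    Defaults mirror a two-niche, three-replicate sampling design: six samples,
    a log-normal species-abundance distribution, producers forced below a
    0.1% relative-abundance ceiling (the regime in which taxonomic abundance
    carries no information about biosynthetic potential), and
    negative-binomial overdispersion on OBU counts.  The planted-slope range
    ``alpha_range`` is a placeholder: no empirical distribution of real
    OBU-species slopes is available, so slopes are drawn uniformly.
    """

    n_samples: int = 6
    n_species: int = 40
    n_producers: int = 8
    obus_per_producer: int = 3
    n_background_obus: int = 10
    alpha_range: tuple[float, float] = (1.0, 5.0)
    abundance_logmean: float = 0.0
    abundance_logsd: float = 1.5
    replicate_jitter_sd: float = 0.2
    count_depth: int = 100_000
    dispersion: float = 0.1
    background_mean: float = 50.0
    low_abundance_fraction: float = 1.0
    low_abundance_ceiling: float = 0.001
    species_occupancy: float = 1.0
    domain: str = "KS"
    # taxonomy
    n_genera: int = 0  # 0 -> max(2, n_species // 3)
    n_orders: int = 4
    # sequence mode
    fwd_read_len: int = 300
    rev_read_len: int = 300
    mutation_rate: float = 0.005
    reads_per_obu: tuple[int, int] = (3, 12)
    max_centroid_identity: float = 0.90
    seed: int = 0

    def validate(self) -> None:
        if self.n_producers > self.n_species:
            raise ConfigError(
                f"n_producers ({self.n_producers}) exceeds n_species ({self.n_species})"
            )
        for name in (
            "n_samples",
            "n_species",
            "n_producers",
            "obus_per_producer",
            "n_background_obus",
            "count_depth",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not (0 < self.low_abundance_ceiling < 1):
            raise ConfigError("low_abundance_ceiling must lie in (0, 1)")
        if not (0 <= self.low_abundance_fraction <= 1):
            raise ConfigError("low_abundance_fraction must lie in [0, 1]")
        if not (0 < self.species_occupancy <= 1):
            raise ConfigError("species_occupancy must lie in (0, 1]")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be non-negative")
        if self.alpha_range[0] > self.alpha_range[1]:
            raise ConfigError("alpha_range must be (low, high)")
        if self.mutation_rate > 0.01:
            raise ConfigError(
                "mutation_rate > 0.01 breaks the >=98% within-OBU identity guarantee"
            )
        if self.domain not in ("KS", "AD"):
            raise ConfigError(f"domain must be KS or AD, got {self.domain!r}")

    def resolved_n_genera(self) -> int:
        return self.n_genera if self.n_genera > 0 else max(2, self.n_species // 3)


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset: the acceptance oracle."""

    planted_links: list[tuple[str, str, float]]  # (species_id, obu_id, alpha)
    producer_ids: list[str]
    background_obu_ids: list[str]
    cluster_truth: dict[str, str] = field(default_factory=dict)  # read_id -> obu_id
    centroids: dict[str, str] = field(default_factory=dict)  # obu_id -> sequence
    expected_read_counts: Optional[CountMatrix] = None
    config: Optional[GeneratorConfig] = None

    def linked_obus_of(self, species_id: str) -> list[str]:
        return [o for (s, o, _a) in self.planted_links if s == species_id]


def _streams(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(4)
    names = ("community", "obu", "reads", "taxonomy")
    return {n: np.random.default_rng(k) for n, k in zip(names, kids)}


# ---------------------------------------------------------------------------
# Community (species counts)
# ---------------------------------------------------------------------------


def generate_community(config: GeneratorConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw a species-by-sample count table plus its planted ground truth.

    Species weights are log-normal; each sample multiplies them by independent
    log-normal replicate jitter, renormalizes, and draws a multinomial of size
    ``count_depth`` — so every column sums exactly to the sequencing depth.
    Producers designated low-abundance get their weight replaced by a value
    guaranteed to keep their expected relative abundance below the ceiling.
    """
    config.validate()
    rng = _streams(config.seed)["community"]

    n_sp, n_sam = config.n_species, config.n_samples
    species_ids = [f"sp{i + 1:04d}" for i in range(n_sp)]
    weights = np.exp(rng.normal(config.abundance_logmean, config.abundance_logsd, n_sp))

    producer_idx = rng.choice(n_sp, size=config.n_producers, replace=False)
    n_low = int(round(config.low_abundance_fraction * config.n_producers))
    low_idx = producer_idx[:n_low]
    # force w_p = c * W_other with c < ceiling: relative abundance c/(1+k*c) < ceiling
    other = np.setdiff1d(np.arange(n_sp), low_idx)
    w_other = weights[other].sum()
    for i in low_idx:
        weights[i] = config.low_abundance_ceiling * rng.uniform(0.2, 0.8) * w_other

    # presence/absence structure: real communities are sparse, and a taxon
    # absent from a sample contributes a structural zero (its domains too)
    if config.species_occupancy < 1.0:
        occupancy = (rng.random((n_sp, n_sam)) < config.species_occupancy).astype(float)
        occupancy[:, rng.integers(n_sam)][occupancy.sum(axis=1) == 0] = 1.0
    else:
        occupancy = np.ones((n_sp, n_sam))

    counts = np.zeros((n_sp, n_sam), dtype=float)
    for j in range(n_sam):
        jitter = np.exp(rng.normal(0.0, config.replicate_jitter_sd, n_sp))
        p = weights * jitter * occupancy[:, j]
        p /= p.sum()
        counts[:, j] = rng.multinomial(config.count_depth, p)

    producer_ids = [species_ids[i] for i in sorted(producer_idx)]
    links: list[tuple[str, str, float]] = []
    obu_rng = _streams(config.seed)["obu"]
    k = 0
    prefix = f"OBU_{config.domain}"
    for sp in producer_ids:
        for _ in range(config.obus_per_producer):
            k += 1
            alpha = obu_rng.uniform(*config.alpha_range)
            links.append((sp, f"{prefix}_{k:04d}", alpha))
    background = [
        f"{prefix}_bg{j + 1:04d}" for j in range(config.n_background_obus)
    ]

    matrix = CountMatrix(species_ids, [f"S{j + 1:02d}" for j in range(n_sam)], counts)
    truth = SyntheticTruth(
        planted_links=links,
        producer_ids=producer_ids,
        background_obu_ids=background,
        config=dataclasses.replace(config),
    )
    return matrix, truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draw with Var = mu + dispersion*mu^2.

    dispersion == 0 is the noise-free limit: counts equal the rounded mean
    exactly (not a Poisson draw), so planted proportionality is recoverable
    without error.
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0.0:
        return np.round(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(float)


def generate_obu_counts(
    species: CountMatrix, truth: SyntheticTruth, config: GeneratorConfig
) -> CountMatrix:
    """OBU-by-sample counts: planted links are NB around alpha*species count.

    Background OBUs get a per-OBU log-normal mean level, constant across
    samples, with the same NB noise — independent of every species.
    """
    config.validate()
    rng = _streams(config.seed)["obu"]
    # burn the draws generate_community used for alphas so streams line up
    rng.uniform(size=len(truth.planted_links))

    sp_index = {s: i for i, s in enumerate(species.feature_ids)}
    rows = []
    obu_ids = []
    for sp, obu, alpha in truth.planted_links:
        mu = alpha * species.counts[sp_index[sp], :]
        rows.append(_nb_draw(rng, mu, config.dispersion))
        obu_ids.append(obu)
    for obu in truth.background_obu_ids:
        # a background OBU belongs to an unobserved taxon with its own
        # log-normal abundance trajectory across samples, independent of
        # every species in the table (never a flat profile)
        level = rng.lognormal(math.log(config.background_mean), 1.0)
        n_sam = len(species.sample_ids)
        traj = np.exp(rng.normal(0.0, max(config.replicate_jitter_sd, 0.0), n_sam))
        mask = (
            (rng.random(n_sam) < config.species_occupancy).astype(float)
            if config.species_occupancy < 1.0
            else np.ones(n_sam)
        )
        mu = level * traj * mask
        rows.append(_nb_draw(rng, mu, config.dispersion))
        obu_ids.append(obu)
    counts = np.vstack(rows) if rows else np.zeros((0, len(species.sample_ids)))
    return CountMatrix(
        obu_ids, list(species.sample_ids), counts, feature_kind=f"OBU_{config.domain}"
    )


def generate_null_obu_deviations(
    species: CountMatrix, n_obus: int, config: GeneratorConfig
) -> np.ndarray:
    """Zero-mean OBU abundance deviations independent of every species.

    Returns an ``n_obus x n_samples`` matrix of Gaussian residual-scale
    values (per-OBU sd drawn log-normal).  This is the exact null of the
    no-intercept slope t-test — E[OBU | species] = 0 — under which screening
    p-values are uniform.  Raw positive background *counts* do not satisfy
    that null: a flat positive OBU profile genuinely fits a positive slope
    on any flat positive species profile, which is a property of the screen,
    not a calibration defect.
    """
    config.validate()
    rng = _streams(config.seed)["obu"]
    n_sam = len(species.sample_ids)
    sds = rng.lognormal(0.0, 0.5, size=n_obus)
    return rng.normal(0.0, 1.0, size=(n_obus, n_sam)) * sds[:, None]


# ---------------------------------------------------------------------------
# Taxonomy & metadata
# ---------------------------------------------------------------------------


def generate_taxonomy(species: CountMatrix, config: GeneratorConfig) -> TaxonomyTable:
    """Synthetic lineages: species assigned to genera, genera to orders."""
    config.validate()
    n_gen = config.resolved_n_genera()
    n_ord = max(1, min(config.n_orders, n_gen))
    lineages = {}
    for i, sp in enumerate(species.feature_ids):
        g = i % n_gen
        o = g % n_ord
        lineages[sp] = {
            "domain": "Bacteria",
            "phylum": f"Phylum{o % 2 + 1}",
            "class": f"Class{o + 1}",
            "order": f"Order{o + 1:02d}",
            "family": f"Family{g + 1:03d}",
            "genus": f"Genus{g + 1:03d}",
            "species": sp,
        }
    return TaxonomyTable(lineages)


def generate_metadata(species: CountMatrix, sources: tuple[str, ...] = ("seawater", "sediment")) -> SampleMetadata:
    """Round-robin niche assignment with per-niche replicate labels."""
    records = {}
    reps: dict[str, int] = {}
    n_src = len(sources)
    n_per = max(1, len(species.sample_ids) // n_src)
    for j, sid in enumerate(species.sample_ids):
        src = sources[min(j // n_per, n_src - 1)]
        reps[src] = reps.get(src, 0) + 1
        records[sid] = {"source": src, "medium": "none", "replicate": f"r{reps[src]}"}
    return SampleMetadata(records)


# ---------------------------------------------------------------------------
# Sequence mode
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _hamming_identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return sum(x == y for x, y in zip(a[:n], b[:n])) / n


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def generate_domain_reads(
    truth: SyntheticTruth, config: GeneratorConfig
) -> dict[str, list[tuple[SequenceRecord, SequenceRecord]]]:
    """Emit paired forward/reverse reads per sample with known cluster truth.

    Each OBU gets a random centroid locus (pairwise identity verified below
    ``max_centroid_identity``); forward reads copy its 5' end, reverse reads
    the reverse complement of its 3' end, both mutated at ``mutation_rate``
    per base.  Read counts per (OBU, sample) are uniform on ``reads_per_obu``.
    Fills ``truth.cluster_truth``, ``truth.centroids`` and
    ``truth.expected_read_counts``.
    """
    config.validate()
    rng = _streams(config.seed)["reads"]
    obu_ids = [o for (_s, o, _a) in truth.planted_links] + list(truth.background_obu_ids)
    if not obu_ids:
        raise ConfigError("no OBUs to emit reads for")
    locus_len = config.fwd_read_len + config.rev_read_len
    if locus_len < 50:
        raise ConfigError("reads too short for distinct centroid loci")

    centroids: dict[str, str] = {}
    for obu in obu_ids:
        for _attempt in range(20):
            seq = "".join(_BASES[rng.integers(0, 4, locus_len)])
            if all(
                _hamming_identity(seq, other) < config.max_centroid_identity
                for other in centroids.values()
            ):
                centroids[obu] = seq
                break
        else:
            raise ConfigError(
                f"could not place {len(obu_ids)} centroids below "
                f"{config.max_centroid_identity:.0%} pairwise identity"
            )
    truth.centroids = centroids

    sample_ids = [f"S{j + 1:02d}" for j in range(config.n_samples)]
    lo, hi = config.reads_per_obu
    expected = np.zeros((len(obu_ids), len(sample_ids)), dtype=float)
    out: dict[str, list[tuple[SequenceRecord, SequenceRecord]]] = {s: [] for s in sample_ids}
    truth.cluster_truth = {}
    for oi, obu in enumerate(obu_ids):
        locus = centroids[obu]
        fwd_t = locus[: config.fwd_read_len]
        rev_t = _revcomp(locus[-config.rev_read_len :])
        for j, sid in enumerate(sample_ids):
            n_reads = int(rng.integers(lo, hi + 1))
            expected[oi, j] = n_reads
            for k in range(n_reads):
                rid = f"{sid}.{obu}.{k + 1}"
                fwd = SequenceRecord(
                    rid, _mutate(rng, fwd_t, config.mutation_rate), sample_id=sid
                )
                rev = SequenceRecord(
                    rid, _mutate(rng, rev_t, config.mutation_rate), sample_id=sid
                )
                out[sid].append((fwd, rev))
                truth.cluster_truth[rid] = obu
    truth.expected_read_counts = CountMatrix(
        obu_ids, sample_ids, expected, feature_kind=f"OBU_{config.domain}"
    )
    return out
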