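"""The profiling pipeline: read preprocessing, ASV calling, tiered identity
classification, per-sample composition, cohort summaries and the cohort
exclusion cascade.

Pipeline contract
-----------------
1. ``preprocess_reads`` trims the 23-base index tail from the 3' end of each
   read, strips primer sequences when present (at most one mismatch), and
   drops reads shorter than the minimum ASV length (250 bp).
2. ``call_asvs`` dereplicates exact sequences across samples into amplicon
   sequence variants, discarding singletons (total count 1).  This is a
   deliberate surrogate for error-model denoising: the classification layer,
   not the denoiser, is the method under study.  Externally denoised ASV
   tables can be supplied instead via ``asvs_from_table``.
3. ``classify_asv`` assigns each ASV by its best percent identity against the
   amplicon-extracted reference library: >= 98% -> the species group of the
   best reference; 95% <= id < 98% -> "Other Faecalibacterium";
   < 95% -> "Others".  All boundaries are inclusive on the retained side.
4. ``build_profiles`` converts classified counts into per-sample relative
   abundances (denominator = all retained reads, including the Other
   Faecalibacterium and Others bins); samples under 10,000 reads are removed.
5. ``summarize_cohort`` reports per-label median/IQR, prevalence (fraction of
   samples at >= 0.5% relative abundance), per-sample species richness (same
   detection rule), and flags minor labels.
6. ``apply_cohort_cascade`` applies the study's exclusion cascade in fixed
   order: genus relative abundance < 1% (16S), cancer history, caloric intake
   outside 600-4000 kcal/day, < 10,000 reads.  A sample matching several
   criteria is counted at the first applicable stage only.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .primers import PrimerPair
from .reference import ReferenceRecord
from .seqcore import NucSequence, align_identity, degenerate_match, reverse_complement

__all__ = [
    "GROUP_LABELS",
    "OTHER_FAECALIBACTERIUM",
    "OTHERS",
    "ALL_LABELS",
    "FilterThresholds",
    "ReadBatch",
    "ASVRecord",
    "ClassificationResult",
    "SampleProfile",
    "PreprocessStats",
    "preprocess_reads",
    "call_asvs",
    "asvs_from_table",
    "classify_asv",
    "classify_asvs",
    "build_profiles",
    "profiles_to_frame",
    "summarize_cohort",
    "CohortSummary",
    "apply_cohort_cascade",
    "CascadeReport",
]

logger = logging.getLogger(__name__)

GROUP_LABELS: tuple[str, ...] = tuple(f"Group {i}" for i in range(1, 13))
OTHER_FAECALIBACTERIUM = "Other Faecalibacterium"
OTHERS = "Others"
ALL_LABELS: tuple[str, ...] = GROUP_LABELS + (OTHER_FAECALIBACTERIUM, OTHERS)


@dataclass(frozen=True)
class FilterThresholds:
    """Quality and detection thresholds of the profiling pipeline.

    Relative-abundance thresholds are fractions (0.005 = 0.5%).
    """

    trim_3prime: int = 23
    min_asv_len: int = 250
    min_sample_reads: int = 10_000
    genus_min_relab: float = 0.01
    kcal_range: tuple[float, float] = (600.0, 4000.0)
    detection_relab: float = 0.005
    minor_median: float = 0.01
    minor_prevalence: float = 0.10
    #: identity tiers (percent)
    group_identity: float = 98.0
    genus_identity: float = 95.0

    def __post_init__(self) -> None:
        if self.kcal_range[0] > self.kcal_range[1]:
            raise ValueError("kcal_range must be ordered")


@dataclass
class ReadBatch:
    sample_id: str
    reads: list[NucSequence]

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class ASVRecord:
    asv_id: str
    seq: NucSequence
    counts: dict[str, int]  # sample_id -> count

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class ClassificationResult:
    asv_id: str
    best_identity: float
    label: str
    tie_flag: bool
    best_ref: str


@dataclass
class SampleProfile:
    sample_id: str
    rel_abundance: dict[str, float]
    total_reads: int


# ---------------------------------------------------------------------------
# Preprocessing


@dataclass
class PreprocessStats:
    n_input: int = 0
    n_trimmed_primer: int = 0
    n_dropped_short: int = 0
    n_kept: int = 0


def _strip_primers(seq: str, fwd: str, rc_rev: str) -> tuple[str, bool]:
    """Remove a leading forward-primer match and a trailing reverse-site
    match (each tolerating one mismatch) when present."""
    stripped = False
    nf = len(fwd)
    if len(seq) > nf and degenerate_match(fwd, seq[:nf], 1)[0]:
        seq = seq[nf:]
        stripped = True
    nr = len(rc_rev)
    if len(seq) > nr and degenerate_match(rc_rev, seq[-nr:], 1)[0]:
        seq = seq[:-nr]
        stripped = True
    return seq, stripped


def preprocess_reads(
    batch: ReadBatch,
    pair: PrimerPair | None = None,
    th: FilterThresholds = FilterThresholds(),
) -> tuple[ReadBatch, PreprocessStats]:
    """Trim index tails and primers, drop too-short reads.

    Trims ``trim_3prime`` bases from the 3' end of every read (the indexing
    tail), then removes the forward primer prefix and reverse-site suffix
    when present (<= 1 mismatch), then drops reads shorter than
    ``min_asv_len``.  Drops are counted, never fatal.
    """
    stats = PreprocessStats(n_input=len(batch.reads))
    fwd = pair.fwd.seq if pair is not None else None
    rc_rev = reverse_complement(pair.rev.seq) if pair is not None else None
    kept: list[NucSequence] = []
    cache: dict[str, str | None] = {}
    for read in batch.reads:
        s = read.seq[:-th.trim_3prime] if th.trim_3prime else read.seq
        if not s:
            stats.n_dropped_short += 1
            continue
        done = cache.get(s, "")
        if done == "":
            t = s
            if fwd is not None:
                t, stripped = _strip_primers(s, fwd, rc_rev)  # type: ignore[arg-type]
                if stripped:
                    stats.n_trimmed_primer += 1
            done = t if len(t) >= th.min_asv_len else None
            cache[s] = done
        elif fwd is not None and done is not None and done != s:
            stats.n_trimmed_primer += 1
        if done is None:
            stats.n_dropped_short += 1
            continue
        kept.append(NucSequence(read.id, done))
    stats.n_kept = len(kept)
    return ReadBatch(batch.sample_id, kept), stats


# ---------------------------------------------------------------------------
# ASV calling (dereplication surrogate)


def call_asvs(
    batches: Iterable[ReadBatch], th: FilterThresholds = FilterThresholds()
) -> list[ASVRecord]:
    """Exact-sequence dereplication across samples into ASVs.

    Singletons (total count 1 across all samples) and sequences shorter than
    ``min_asv_len`` are discarded.  ASV ids are assigned deterministically in
    (total count desc, sequence lexicographic) order.
    """
    per_seq: dict[str, Counter] = {}
    for batch in batches:
        for read in batch.reads:
            per_seq.setdefault(read.seq, Counter())[batch.sample_id] += 1
    entries = [
        (seq, counts)
        for seq, counts in per_seq.items()
        if sum(counts.values()) > 1 and len(seq) >= th.min_asv_len
    ]
    entries.sort(key=lambda e: (-sum(e[1].values()), e[0]))
    return [
        ASVRecord(
            asv_id=f"ASV_{i + 1:06d}",
            seq=NucSequence(f"ASV_{i + 1:06d}", seq),
            counts=dict(counts),
        )
        for i, (seq, counts) in enumerate(entries)
    ]


def asvs_from_table(
    fasta_seqs: Sequence[NucSequence], counts: pd.DataFrame
) -> list[ASVRecord]:
    """Build ASV records from an external ASV FASTA plus a samples x ASVs
    count table (entry point for externally denoised data)."""
    out = []
    for ns in fasta_seqs:
        if ns.id not in counts.columns:
            raise KeyError(f"ASV {ns.id!r} missing from count table")
        col = counts[ns.id]
        out.append(
            ASVRecord(
                asv_id=ns.id,
                seq=ns,
                counts={s: int(c) for s, c in col.items() if c > 0},
            )
        )
    return out


# ---------------------------------------------------------------------------
# Classification


def _tier_label(best_identity: float, group_id: int, th: FilterThresholds) -> str:
    if best_identity >= th.group_identity:
        return f"Group {group_id}"
    if best_identity >= th.genus_identity:
        return OTHER_FAECALIBACTERIUM
    return OTHERS


def _edlib_distance(query: str, target: str) -> int:
    if len(query) > len(target):
        query, target = target, query
    return edlib.align(query, target, mode="HW", task="distance")["editDistance"]


def classify_asv(
    asv: ASVRecord,
    library: Sequence[ReferenceRecord],
    th: FilterThresholds = FilterThresholds(),
    screen_margin: int = 5,
    exhaustive: bool = False,
) -> ClassificationResult:
    """Tiered best-identity assignment of one ASV against the library.

    By default candidate references are pre-screened with an infix edit
    distance (edlib) and only those within ``screen_margin`` of the minimum
    are scored with the full end-gap-free aligner; ``exhaustive=True`` scores
    every reference.  If several references in different groups attain the
    best identity at >= the group tier, the earliest record in library order
    wins and ``tie_flag`` is set.
    """
    if not library:
        raise ValueError("empty reference library")
    amplicons = []
    for rec in library:
        if rec.amplicon_seq is None:
            raise ValueError(
                f"reference {rec.record_id} has no amplicon; run extract_amplicons"
            )
        amplicons.append(rec.amplicon_seq.seq)

    idx: Sequence[int]
    if exhaustive:
        idx = range(len(library))
    else:
        dists = [_edlib_distance(asv.seq.seq, a) for a in amplicons]
        dmin = min(dists)
        idx = [i for i, d in enumerate(dists) if d <= dmin + screen_margin]

    best_pct = -1.0
    best_i = -1
    tied_groups: set[int] = set()
    for i in idx:
        pct = align_identity(asv.seq, library[i].amplicon_seq).identity_pct
        if pct > best_pct + 1e-12:
            best_pct = pct
            best_i = i
            tied_groups = {library[i].group_id}
        elif abs(pct - best_pct) <= 1e-12:
            tied_groups.add(library[i].group_id)
    best_rec = library[best_i]
    tie = best_pct >= th.group_identity and len(tied_groups) > 1
    return ClassificationResult(
        asv_id=asv.asv_id,
        best_identity=best_pct,
        label=_tier_label(best_pct, best_rec.group_id, th),
        tie_flag=tie,
        best_ref=best_rec.record_id,
    )


def _hamming_classes(
    library: Sequence[ReferenceRecord], pair: PrimerPair | None
) -> dict[int, np.ndarray]:
    """Reference code matrices keyed by target length, for the Hamming fast
    path: the full amplicons and (when primer lengths are known) the
    primer-stripped cores, provided each class has a uniform length."""
    classes: dict[int, np.ndarray] = {}
    amps = [r.amplicon_seq.seq for r in library]  # type: ignore[union-attr]
    lens = {len(a) for a in amps}
    if len(lens) == 1:
        classes[lens.pop()] = np.stack([NucSequence("r", a).codes() for a in amps])
    if pair is not None:
        nf, nr = len(pair.fwd.seq), len(pair.rev.seq)
        cores = [a[nf:-nr] for a in amps]
        core_lens = {len(c) for c in cores}
        if len(core_lens) == 1 and all(cores):
            classes[core_lens.pop()] = np.stack(
                [NucSequence("r", c).codes() for c in cores]
            )
    return classes


def classify_asvs(
    asvs: Sequence[ASVRecord],
    library: Sequence[ReferenceRecord],
    th: FilterThresholds = FilterThresholds(),
    pair: PrimerPair | None = None,
    fast_hamming_max: int = 6,
    **kwargs,
) -> list[ClassificationResult]:
    """Classify a batch of ASVs (results in input order).

    ASVs whose length equals the library's common amplicon (or, given the
    primer pair, primer-stripped core) length are scored by vectorized
    Hamming distance when their best distance is at most
    ``fast_hamming_max``: in that near-identical regime the core-anchored
    ungapped alignment is the optimal end-gap-free alignment, so identity is
    exactly 100*(L-h)/L.  Everything else falls back to ``classify_asv``.
    """
    if kwargs.get("exhaustive"):
        return [classify_asv(a, library, th, **kwargs) for a in asvs]
    for rec in library:
        if rec.amplicon_seq is None:
            raise ValueError(
                f"reference {rec.record_id} has no amplicon; run extract_amplicons"
            )
    classes = _hamming_classes(library, pair)
    out = []
    for asv in asvs:
        L = len(asv.seq)
        mat = classes.get(L)
        if mat is not None:
            h = np.count_nonzero(mat != asv.seq.codes()[None, :], axis=1)
            hb = int(h.min())
            if hb <= fast_hamming_max:
                pct = 100.0 * (L - hb) / L
                tied = np.flatnonzero(h == hb)
                groups = {library[int(i)].group_id for i in tied}
                best = library[int(tied[0])]
                out.append(
                    ClassificationResult(
                        asv_id=asv.asv_id,
                        best_identity=pct,
                        label=_tier_label(pct, best.group_id, th),
                        tie_flag=pct >= th.group_identity and len(groups) > 1,
                        best_ref=best.record_id,
                    )
                )
                continue
        out.append(classify_asv(asv, library, th, **kwargs))
    return out


# ---------------------------------------------------------------------------
# Profiles and summaries


def build_profiles(
    asvs: Sequence[ASVRecord],
    classifications: Sequence[ClassificationResult],
    th: FilterThresholds = FilterThresholds(),
) -> tuple[list[SampleProfile], list[str]]:
    """Per-sample label relative abundances from classified ASV counts.

    Returns (profiles, excluded_sample_ids); samples whose total retained
    count falls below ``min_sample_reads`` are excluded and reported.
    """
    label_by_asv = {c.asv_id: c.label for c in classifications}
    per_sample: dict[str, Counter] = {}
    for asv in asvs:
        label = label_by_asv[asv.asv_id]
        for sample, count in asv.counts.items():
            per_sample.setdefault(sample, Counter())[label] += count
    profiles, excluded = [], []
    for sample in sorted(per_sample):
        counts = per_sample[sample]
        total = sum(counts.values())
        if total < th.min_sample_reads:
            excluded.append(sample)
            continue
        rel = {lab: counts.get(lab, 0) / total for lab in ALL_LABELS}
        profiles.append(SampleProfile(sample, rel, total))
    if excluded:
        logger.info("excluded %d samples below %d reads", len(excluded), th.min_sample_reads)
    return profiles, excluded


def profiles_to_frame(profiles: Sequence[SampleProfile]) -> pd.DataFrame:
    """Samples x labels relative-abundance DataFrame (fractions)."""
    return pd.DataFrame(
        [[p.rel_abundance.get(lab, 0.0) for lab in ALL_LABELS] for p in profiles],
        index=pd.Index([p.sample_id for p in profiles], name="sample_id"),
        columns=list(ALL_LABELS),
    )


@dataclass
class CohortSummary:
    #: per label: median, q1, q3, prevalence, minor flag
    label_stats: pd.DataFrame
    #: per sample: number of Group labels at/above the detection threshold
    richness: pd.Series


def summarize_cohort(
    profiles: Sequence[SampleProfile], th: FilterThresholds = FilterThresholds()
) -> CohortSummary:
    """Composition summary: per-label median and Q1-Q3, prevalence at the
    detection threshold, per-sample species richness, and minor-label flags
    (median below 1% or prevalence below 10%)."""
    if not profiles:
        raise ValueError("no profiles to summarize")
    frame = profiles_to_frame(profiles)
    stats = pd.DataFrame(
        {
            "median": frame.median(),
            "q1": frame.quantile(0.25),
            "q3": frame.quantile(0.75),
            "prevalence": (frame >= th.detection_relab).mean(),
        }
    )
    stats["minor"] = (stats["median"] < th.minor_median) | (
        stats["prevalence"] < th.minor_prevalence
    )
    richness = (frame[list(GROUP_LABELS)] >= th.detection_relab).sum(axis=1)
    richness.name = "species_richness"
    return CohortSummary(label_stats=stats, richness=richness)


# ---------------------------------------------------------------------------
# Cohort exclusion cascade


@dataclass
class CascadeReport:
    n_enrolled: int
    stages: list[tuple[str, int]]  # (stage name, n removed at this stage)
    retained_ids: list[str]

    @property
    def final_n(self) -> int:
        return len(self.retained_ids)


CASCADE_STAGES = (
    "genus_relab_below_1pct",
    "cancer_history",
    "kcal_outside_range",
    "reads_below_10000",
)


def apply_cohort_cascade(
    cohort: pd.DataFrame,
    read_counts: Mapping[str, int] | Sequence[SampleProfile],
    th: FilterThresholds = FilterThresholds(),
) -> CascadeReport:
    """Apply the four exclusion stages in fixed order.

    ``cohort`` must be indexed by sample id with columns ``genus_relab_16S``
    (fraction), ``cancer_history`` (bool) and ``energy_kcal``.  ``read_counts``
    maps sample id to sequenced read count (a list of SampleProfiles is also
    accepted).  Every cohort sample must be joinable; a sample matching
    several criteria is removed at the first applicable stage only.
    """
    if not isinstance(read_counts, Mapping):
        read_counts = {p.sample_id: p.total_reads for p in read_counts}
    missing = [s for s in cohort.index if s not in read_counts]
    if missing:
        raise KeyError(f"samples without read counts: {missing[:5]}...")

    remaining = list(cohort.index)
    stages: list[tuple[str, int]] = []

    def _apply(name: str, pred) -> None:
        nonlocal remaining
        removed = [s for s in remaining if pred(s)]
        remaining = [s for s in remaining if s not in set(removed)]
        stages.append((name, len(removed)))

    lo, hi = th.kcal_range
    _apply(
        CASCADE_STAGES[0],
        lambda s: cohort.at[s, "genus_relab_16S"] < th.genus_min_relab,
    )
    _apply(CASCADE_STAGES[1], lambda s: bool(cohort.at[s, "cancer_history"]))
    _apply(
        CASCADE_STAGES[2],
        lambda s: not (lo <= cohort.at[s, "energy_kcal"] <= hi),
    )
    _apply(CASCADE_STAGES[3], lambda s: read_counts[s] < th.min_sample_reads)
    return CascadeReport(
        n_enrolled=len(cohort), stages=stages, retained_ids=remaining
    )
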