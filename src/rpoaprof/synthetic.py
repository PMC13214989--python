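"""Synthetic mock communities, reference libraries and cohorts.

These generators emulate the statistical structure the profiling method
assumes, so the whole pipeline is testable without any sequence download:

* a 12-group reference library of 106 *rpoA* sequences whose amplicons are
  exactly 325 bp (21-bp forward site + 283-bp core + 21-bp reverse site)
  with guaranteed separation -- below 94% identity between groups, at least
  98% within a group.  The guarantee is constructive: each group mutates a
  disjoint block of core positions, so cross-group divergence cannot
  collapse by chance;
* merged amplicon reads drawn multinomially from a known composition, with
  independent per-base substitution errors and a random 23-nt index tail
  (so the preprocessing step has something to trim);
* cohort metadata with the four exclusion categories (low genus abundance,
  cancer history, extreme caloric intake, low read count) at configured
  counts, Dirichlet species compositions, and optional injected exposure
  effects whose magnitudes are recorded in the truth manifest.

All generators are pure functions of (config, seed): identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .primers import META_RPOA_F, META_RPOA_R
from .profiling import ALL_LABELS, ReadBatch, SampleProfile
from .reference import ReferenceRecord, TAXONOMY_BY_ID
from .seqcore import NucSequence, expand_degenerate, reverse_complement

__all__ = [
    "SimConfig",
    "TruthManifest",
    "simulate_reference_library",
    "simulate_sample_reads",
    "simulate_cohort",
    "DEFAULT_REFS_PER_GROUP",
    "DEFAULT_COMPOSITION_ALPHA",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: 106 reference sequences over 12 groups (at least one per group).
DEFAULT_REFS_PER_GROUP: tuple[int, ...] = (9, 9, 9, 9, 9, 9, 9, 9, 9, 9, 8, 8)

#: Dirichlet mean composition over the 14 labels, shaped like the cohort the
#: method was built for: two dominant species (Groups 3 and 4), three
#: intermediate ones (Groups 1, 6, 11), minor everything else.
DEFAULT_COMPOSITION_ALPHA: dict[str, float] = {
    "Group 1": 0.36,
    "Group 2": 0.02,
    "Group 3": 1.35,
    "Group 4": 0.95,
    "Group 5": 0.02,
    "Group 6": 0.40,
    "Group 7": 0.02,
    "Group 8": 0.02,
    "Group 9": 0.02,
    "Group 10": 0.02,
    "Group 11": 0.38,
    "Group 12": 0.02,
    "Other Faecalibacterium": 0.01,
    "Others": 0.01,
}


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration.  ``seed`` is mandatory."""

    seed: int
    n_groups: int = 12
    refs_per_group: tuple[int, ...] = DEFAULT_REFS_PER_GROUP
    amplicon_core_len: int = 283
    flank_len: int = 120
    inter_group_divergence: float = 0.08
    intra_group_divergence: float = 0.01
    read_error_rate: float = 0.001
    reads_per_sample: int = 50_000
    index_tail_len: int = 23
    cohort_size: int = 660
    exclusion_counts: tuple[int, int, int, int] = (55, 13, 3, 9)
    #: a mock sample contains one strain per species (the way physical mock
    #: communities are assembled); set True to draw each read's template
    #: uniformly from all of the group's references instead
    strain_mixture: bool = False
    composition_alpha: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION_ALPHA)
    )
    #: exposure column -> {label: log-fold change per SD of the exposure}
    injected_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.intra_group_divergence >= self.inter_group_divergence:
            raise ValueError("intra-group divergence must be below inter-group")
        if not 0 <= self.read_error_rate < 1:
            raise ValueError("read_error_rate must be in [0, 1)")
        if len(self.refs_per_group) != self.n_groups:
            raise ValueError("refs_per_group length must equal n_groups")
        if self.n_groups * int(np.ceil(
            self.inter_group_divergence * self.amplicon_core_len
        )) > self.amplicon_core_len:
            raise ValueError(
                "divergence constraints unsatisfiable: disjoint mutation blocks "
                "do not fit in the amplicon core"
            )


@dataclass
class TruthManifest:
    """Ground truth behind a generated artifact."""

    record_groups: dict[str, int] = field(default_factory=dict)
    true_composition: dict[str, dict[str, float]] = field(default_factory=dict)
    true_read_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    exclusion_labels: dict[str, str] = field(default_factory=dict)
    injected_effects: dict[str, dict[str, float]] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.int8)


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _mutate(
    codes: np.ndarray, positions: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    out = codes.copy()
    out[positions] = (out[positions] + rng.integers(1, 4, size=positions.size)) % 4
    return out


def simulate_reference_library(
    cfg: SimConfig,
) -> tuple[list[ReferenceRecord], TruthManifest]:
    """Generate a group-separated reference library.

    One random ancestral core; each group mutates its own disjoint block of
    ``ceil(inter_group_divergence * core_len)`` positions, guaranteeing
    cross-group amplicon identity below 94%; strain variants mutate at most
    ``intra_group_divergence * core_len`` further positions, keeping
    within-group identity at or above 98%.  Primer binding sites are concrete
    expansions of the degenerate primers, fixed per group; full sequences add
    random flanks so amplicons must be recovered by in-silico PCR.
    """
    rng = np.random.default_rng(cfg.seed)
    core_len = cfg.amplicon_core_len
    ancestor = _random_seq(rng, core_len)
    block = int(np.ceil(cfg.inter_group_divergence * core_len))
    n_intra = int(np.floor(cfg.intra_group_divergence * core_len))

    fwd_variants = expand_degenerate(META_RPOA_F)
    rev_variants = expand_degenerate(META_RPOA_R)

    manifest = TruthManifest()
    records: list[ReferenceRecord] = []
    for g in range(cfg.n_groups):
        gid = g + 1
        positions = np.arange(g * block, (g + 1) * block)
        group_core = _mutate(ancestor, positions, rng)
        fwd_site = fwd_variants[int(rng.integers(len(fwd_variants)))]
        rev_site = rev_variants[int(rng.integers(len(rev_variants)))]
        taxon = TAXONOMY_BY_ID[gid]
        for s in range(cfg.refs_per_group[g]):
            n_mut = int(rng.integers(0, n_intra + 1)) if s > 0 else 0
            strain_core = (
                _mutate(group_core, rng.choice(core_len, n_mut, replace=False), rng)
                if n_mut
                else group_core
            )
            strain = f"{taxon.strain}" if s == 0 else f"SYN{gid:02d}-{s:02d}"
            header = f"Group{gid}|{taxon.species_name}|{strain}"
            amplicon = fwd_site + _to_str(strain_core) + reverse_complement(rev_site)
            full = (
                _to_str(_random_seq(rng, cfg.flank_len))
                + amplicon
                + _to_str(_random_seq(rng, cfg.flank_len))
            )
            rec = ReferenceRecord(
                record_id=header,
                group_id=gid,
                strain=strain,
                full_seq=NucSequence(header, full),
                amplicon_seq=NucSequence(f"{header}|amplicon", amplicon),
            )
            records.append(rec)
            manifest.record_groups[header] = gid
    return records, manifest


def simulate_sample_reads(
    library: list[ReferenceRecord],
    composition: Mapping[str, float],
    cfg: SimConfig,
    sample_id: str = "S1",
    rng: np.random.Generator | None = None,
) -> tuple[ReadBatch, TruthManifest]:
    """Draw merged amplicon reads from a known group composition.

    Reads are sampled multinomially over groups; within a group, the sample
    carries one (seeded) strain -- mock communities are assembled from one
    strain per species -- unless ``cfg.strain_mixture`` asks for a uniform
    draw over all of the group's references.  Each read gets independent
    per-base substitution errors at ``read_error_rate`` and a random
    ``index_tail_len``-nt tail.  The manifest records the true per-group
    read counts.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    labels = list(composition)
    fracs = np.array([composition[l] for l in labels], dtype=float)
    if not np.isclose(fracs.sum(), 1.0):
        raise ValueError("composition must sum to 1")
    if not labels:
        raise ValueError("empty composition")
    by_group: dict[str, list[np.ndarray]] = {}
    for rec in library:
        if rec.amplicon_seq is None:
            raise ValueError("library must have amplicons populated")
        label = f"Group {rec.group_id}"
        codes = np.frombuffer(
            rec.amplicon_seq.seq.encode().translate(
                bytes.maketrans(b"ACGT", bytes([0, 1, 2, 3]))
            ),
            dtype=np.int8,
        )
        by_group.setdefault(label, []).append(codes)

    counts = rng.multinomial(cfg.reads_per_sample, fracs)
    manifest = TruthManifest(
        true_composition={sample_id: dict(composition)},
        true_read_counts={sample_id: dict(zip(labels, (int(c) for c in counts)))},
    )
    reads: list[NucSequence] = []
    read_no = 0
    for label, n_reads in zip(labels, counts):
        if n_reads == 0:
            continue
        templates = by_group.get(label)
        if templates is None:
            raise KeyError(f"composition label {label!r} has no reference sequences")
        if cfg.strain_mixture:
            choice = rng.integers(0, len(templates), size=n_reads)
        else:
            choice = np.full(n_reads, rng.integers(0, len(templates)))
        for t_idx in choice:
            codes = templates[t_idx]
            if cfg.read_error_rate > 0:
                mask = rng.random(codes.size) < cfg.read_error_rate
                if mask.any():
                    codes = codes.copy()
                    pos = np.flatnonzero(mask)
                    codes[pos] = (codes[pos] + rng.integers(1, 4, pos.size)) % 4
            tail = _random_seq(rng, cfg.index_tail_len)
            read_no += 1
            reads.append(
                NucSequence(
                    f"{sample_id}_read{read_no}",
                    _to_str(codes.astype(np.int8)) + _to_str(tail),
                )
            )
    return ReadBatch(sample_id, reads), manifest


_DIET_CATEGORIES = (
    "RICE", "CRL", "POT", "SGR", "BEAN", "SOY", "VEG", "FRT", "FISH", "MEAT",
    "EGG", "MILK", "OIL", "SWT", "BEV", "ALC", "SEA", "FNGI",
)
_NUTRIENTS = ("protein_g", "fat_g", "carbohydrate_g", "fiber_g", "VB12_ug", "VD_ug", "FE_mg")


def simulate_cohort(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, list[SampleProfile], TruthManifest]:
    """Generate cohort metadata, per-sample compositions and the truth manifest.

    The four exclusion categories are assigned to disjoint samples at the
    configured counts (defaults 55/13/3/9 in a cohort of 660), so the cascade
    arithmetic is exact.  Compositions are Dirichlet draws over the 14 labels;
    optional injected effects multiply a label's fraction by
    ``exp(beta * z)`` (z = standardised exposure) before renormalisation.
    """
    if sum(cfg.exclusion_counts) > cfg.cohort_size:
        raise ValueError("exclusion counts exceed cohort size")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.cohort_size
    ids = [f"S{i + 1:04d}" for i in range(n)]

    # disjoint exclusion assignment
    flagged = rng.choice(n, size=sum(cfg.exclusion_counts), replace=False)
    c1, c2, c3, c4 = cfg.exclusion_counts
    idx_genus = set(flagged[:c1].tolist())
    idx_cancer = set(flagged[c1:c1 + c2].tolist())
    idx_kcal = set(flagged[c1 + c2:c1 + c2 + c3].tolist())
    idx_reads = set(flagged[c1 + c2 + c3:].tolist())

    age = rng.integers(21, 84, size=n)
    sex = rng.choice(["M", "F"], size=n, p=[107 / 580, 473 / 580])
    bmi = np.round(rng.normal(22.0, 3.0, size=n).clip(15, 38), 1)
    kcal = np.round(rng.normal(1900, 450, size=n).clip(650, 3900))
    genus_relab = rng.uniform(0.02, 0.25, size=n)
    n_reads = rng.integers(20_000, 60_000, size=n)
    defecation = rng.choice(["<1-3/wk", "4-5/wk", "6-7/wk"], size=n, p=[0.2, 0.3, 0.5])
    exercise = rng.random(n) < 0.25
    region = rng.choice(["urban", "rural"], size=n, p=[0.7, 0.3])
    cancer = np.zeros(n, dtype=bool)

    manifest = TruthManifest()
    for i in range(n):
        if i in idx_genus:
            genus_relab[i] = rng.uniform(0.0, 0.0099)
            manifest.exclusion_labels[ids[i]] = "genus_relab_below_1pct"
        elif i in idx_cancer:
            cancer[i] = True
            manifest.exclusion_labels[ids[i]] = "cancer_history"
        elif i in idx_kcal:
            kcal[i] = float(rng.choice([450.0, 520.0, 4400.0]))
            manifest.exclusion_labels[ids[i]] = "kcal_outside_range"
        elif i in idx_reads:
            n_reads[i] = rng.integers(2_000, 10_000)
            manifest.exclusion_labels[ids[i]] = "reads_below_10000"

    diet = {
        cat: np.round(rng.lognormal(mean=np.log(60), sigma=0.6, size=n), 1)
        for cat in _DIET_CATEGORIES
    }
    nutrients = {
        nut: np.round(rng.lognormal(mean=np.log(30), sigma=0.5, size=n), 2)
        for nut in _NUTRIENTS
    }

    cohort = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "BMI": bmi,
            "energy_kcal": kcal,
            "defecation_freq": defecation,
            "exercise_habit": exercise,
            "region": region,
            "genus_relab_16S": genus_relab,
            "cancer_history": cancer,
            "n_reads": n_reads,
            **diet,
            **nutrients,
        },
        index=pd.Index(ids, name="sample_id"),
    )

    labels = list(ALL_LABELS)
    alpha = np.array([cfg.composition_alpha.get(l, 0.0) for l in labels])
    if np.any(alpha <= 0):
        missing = [l for l, a in zip(labels, alpha) if a <= 0]
        raise ValueError(f"composition_alpha must be positive for every label: {missing}")
    comps = rng.dirichlet(alpha, size=n)

    # injected exposure effects: multiplicative exp(beta * z) on the label
    for exposure, effects in cfg.injected_effects.items():
        z = cohort[exposure].to_numpy(dtype=float)
        z = (z - z.mean()) / z.std()
        manifest.injected_effects[exposure] = dict(effects)
        for label, beta in effects.items():
            j = labels.index(label)
            comps[:, j] *= np.exp(beta * z)
        comps /= comps.sum(axis=1, keepdims=True)

    profiles = []
    for i, sid in enumerate(ids):
        rel = dict(zip(labels, comps[i]))
        profiles.append(SampleProfile(sid, rel, int(n_reads[i])))
        manifest.true_composition[sid] = rel
    return cohort, profiles, manifest
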