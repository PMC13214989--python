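"""Curation and validation of the group-annotated rpoA reference library.

Human-origin *Faecalibacterium* is partitioned into 12 species-level
phylogroups ("Group 1" ... "Group 12"); the classification table bundled
here lists the species name (or "Not classified yet") and the type or
representative strain of each group.  A reference library is a FASTA file
whose headers follow the dialect ``>Group{n}|{species}|{strain}``; each
record carries the full *rpoA* gene, from which the primer-bounded amplicon
region is extracted for classification (reads only ever cover the amplified
region, so identity is computed against amplicons, not full genes).

Library quality control checks the separation the method relies on: amplicon
identity below 94% between groups and at least 98% within a group.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

from .primers import PrimerPair, in_silico_pcr
from .seqcore import NucSequence, align_identity, read_fasta, write_fasta

__all__ = [
    "GroupTaxon",
    "GROUP_TAXONOMY",
    "ReferenceRecord",
    "LibraryValidationReport",
    "load_library",
    "write_library",
    "export_taxonomy_tsv",
    "extract_amplicons",
    "validate_separation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupTaxon:
    group_id: int
    species_name: str
    strain: str


#: The 12 species-level phylogroups of human-origin Faecalibacterium and
#: their type strains (representative strains for yet-unclassified groups).
GROUP_TAXONOMY: tuple[GroupTaxon, ...] = (
    GroupTaxon(1, "F. prausnitzii", "ATCC 27768"),
    GroupTaxon(2, "F. langellae", "CNCM I-4541"),
    GroupTaxon(3, "F. taiwanense", "HLW 78"),
    GroupTaxon(4, "F. longum", "CM 04-06"),
    GroupTaxon(5, "Not classified yet", "APC942/8-14-2"),
    GroupTaxon(6, "F. duncaniae", "A2-165"),
    GroupTaxon(7, "F. hattorii", "APC922/41-1"),
    GroupTaxon(8, "Not classified yet", "MGYG-HGUT-00195"),
    GroupTaxon(9, "F. butyricigenerans", "AF52-21"),
    GroupTaxon(10, "F. wellingii", "HTF-F"),
    GroupTaxon(11, "Not classified yet", "UMGS183"),
    GroupTaxon(12, "Not classified yet", "UMGS253"),
)

TAXONOMY_BY_ID: dict[int, GroupTaxon] = {t.group_id: t for t in GROUP_TAXONOMY}


@dataclass
class ReferenceRecord:
    """A group-labelled rpoA reference sequence."""

    record_id: str
    group_id: int
    strain: str
    full_seq: NucSequence
    amplicon_seq: NucSequence | None = None

    def __post_init__(self) -> None:
        if self.group_id not in TAXONOMY_BY_ID:
            raise ValueError(
                f"unknown group_id {self.group_id} for record {self.record_id!r}"
            )

    @property
    def taxon(self) -> GroupTaxon:
        return TAXONOMY_BY_ID[self.group_id]


class MalformedHeaderError(ValueError):
    """A reference FASTA header does not follow Group{n}|{species}|{strain}."""


def _parse_header(header: str) -> tuple[int, str, str]:
    parts = header.split("|")
    if len(parts) != 3 or not parts[0].startswith("Group"):
        raise MalformedHeaderError(
            f"expected 'Group{{n}}|species|strain', got {header!r}"
        )
    try:
        gid = int(parts[0][len("Group"):])
    except ValueError as exc:
        raise MalformedHeaderError(f"non-integer group in {header!r}") from exc
    if gid not in TAXONOMY_BY_ID:
        raise MalformedHeaderError(f"group_id {gid} outside 1-12 in {header!r}")
    return gid, parts[1], parts[2]


def load_library(path: str | Path) -> list[ReferenceRecord]:
    """Load a reference FASTA with ``>Group{n}|{species}|{strain}`` headers."""
    records = []
    seen: set[str] = set()
    for ns in read_fasta(path):
        header = ns.id
        gid, _species, strain = _parse_header(header)
        if header in seen:
            raise ValueError(f"duplicate record id {header!r}")
        seen.add(header)
        records.append(
            ReferenceRecord(
                record_id=header,
                group_id=gid,
                strain=strain,
                full_seq=NucSequence(header, ns.seq),
            )
        )
    return records


def write_library(path: str | Path, records: list[ReferenceRecord]) -> None:
    """Write reference records back to FASTA (unwrapped; bit-exact round trip)."""
    write_fasta(path, [r.full_seq for r in records], wrap=None)


def export_taxonomy_tsv(path: str | Path) -> None:
    """Write the 12-group classification table as TSV."""
    with open(path, "w") as fh:
        fh.write("group_id\tspecies\tstrain\n")
        for t in GROUP_TAXONOMY:
            fh.write(f"{t.group_id}\t{t.species_name}\t{t.strain}\n")


def extract_amplicons(
    records: list[ReferenceRecord],
    pair: PrimerPair,
    max_mismatch: int = 3,
    protect_3prime: int = 3,
) -> tuple[list[ReferenceRecord], list[str]]:
    """Populate ``amplicon_seq`` on each record via in-silico PCR.

    Records yielding no product are flagged (returned in the second element)
    and excluded from the returned record list; they must not take part in
    classification.  Records with several products keep the first (leftmost).
    """
    kept, flagged = [], []
    for rec in records:
        amps = in_silico_pcr(pair, rec.full_seq, max_mismatch, protect_3prime)
        if not amps:
            logger.warning(
                "reference %s yields no amplicon; excluded from classification",
                rec.record_id,
            )
            flagged.append(rec.record_id)
            continue
        rec.amplicon_seq = amps[0].product_seq
        kept.append(rec)
    return kept, flagged


@dataclass(frozen=True)
class GroupSeparation:
    group_id: int
    n_records: int
    min_intra_identity: float | None  # None for singleton groups
    mean_intra_identity: float | None


@dataclass(frozen=True)
class LibraryValidationReport:
    per_group: list[GroupSeparation]
    #: max amplicon identity for every unordered group pair
    inter_group_max: dict[tuple[int, int], float]
    #: (record_a, record_b, identity) violating the inter-group ceiling
    inter_flags: list[tuple[str, str, float]]
    #: (record_a, record_b, identity) violating the intra-group floor
    intra_flags: list[tuple[str, str, float]]

    @property
    def ok(self) -> bool:
        return not self.inter_flags and not self.intra_flags


def validate_separation(
    records: list[ReferenceRecord],
    intra_min: float = 98.0,
    inter_max: float = 94.0,
) -> LibraryValidationReport:
    """All-pairs amplicon identity QC of a reference library.

    Flags cross-group pairs above ``inter_max`` percent identity and
    within-group pairs below ``intra_min``.  Symmetric: pair orientation does
    not affect flags.  Records must have amplicons extracted (falls back to
    the full sequence when no amplicon is present).
    """
    if not records:
        raise ValueError("empty library")
    seqs = [r.amplicon_seq if r.amplicon_seq is not None else r.full_seq for r in records]
    n = len(records)
    ident = {}
    for i, j in itertools.combinations(range(n), 2):
        ident[(i, j)] = align_identity(seqs[i], seqs[j]).identity_pct

    inter_flags, intra_flags = [], []
    inter_group_max: dict[tuple[int, int], float] = {}
    intra_by_group: dict[int, list[float]] = {}
    for (i, j), pct in ident.items():
        gi, gj = records[i].group_id, records[j].group_id
        if gi == gj:
            intra_by_group.setdefault(gi, []).append(pct)
            if pct < intra_min:
                intra_flags.append((records[i].record_id, records[j].record_id, pct))
        else:
            key = (min(gi, gj), max(gi, gj))
            inter_group_max[key] = max(inter_group_max.get(key, 0.0), pct)
            if pct > inter_max:
                inter_flags.append((records[i].record_id, records[j].record_id, pct))

    per_group = []
    for gid in sorted({r.group_id for r in records}):
        vals = intra_by_group.get(gid)
        per_group.append(
            GroupSeparation(
                group_id=gid,
                n_records=sum(r.group_id == gid for r in records),
                min_intra_identity=min(vals) if vals else None,
                mean_intra_identity=sum(vals) / len(vals) if vals else None,
            )
        )
    return LibraryValidationReport(
        per_group=per_group,
        inter_group_max=inter_group_max,
        inter_flags=inter_flags,
        intra_flags=intra_flags,
    )
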