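"""Degenerate primer design, in-silico PCR and validation arithmetic.

The package ships the genus-specific *rpoA* primer pair used for
species-level profiling of *Faecalibacterium*:

* meta-rpoA-F  5'-CACCCCBGTKCTCAAGGTGAA-3'  (forward)
* meta-rpoA-R  5'-CCSARRTTRCGRACYTTCATC-3'  (reverse, 5'->3' on the
  reverse strand)

which amplify a 325-bp primer-inclusive fragment of the single-copy *rpoA*
gene.  This module can also re-derive such primers from a multiple alignment
(consensus windows under a degeneracy cap), scan templates on both strands
for products, screen primer pairs for sensitivity/specificity against
on-/off-target reference sets, and perform the plasmid-construct copy-number
arithmetic used when validating primers against synthetic DNA.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from .seqcore import (
    IUPAC_FROM_SET,
    NucSequence,
    degeneracy,
    degenerate_match,
    reverse_complement,
)

__all__ = [
    "META_RPOA_F",
    "META_RPOA_R",
    "DegeneratePrimer",
    "PrimerPair",
    "Amplicon",
    "DesignConstraints",
    "DnaConstruct",
    "ScreenRow",
    "ScreenReport",
    "default_primer_pair",
    "column_base_sets",
    "design_primer_pairs",
    "in_silico_pcr",
    "specificity_screen",
    "log10_copies",
    "AVOGADRO",
    "DSDNA_G_PER_MOL_PER_BP",
]

META_RPOA_F = "CACCCCBGTKCTCAAGGTGAA"
META_RPOA_R = "CCSARRTTRCGRACYTTCATC"

#: Avogadro constant, mol^-1 (2019 SI exact value).
AVOGADRO = 6.02214076e23
#: Average molar mass of double-stranded DNA per base pair, g mol^-1 bp^-1.
DSDNA_G_PER_MOL_PER_BP = 650.0


@dataclass(frozen=True)
class DegeneratePrimer:
    """IUPAC-coded oligo.  Reverse primers are stored 5'->3' on the reverse
    strand (the orientation in which they would be synthesised)."""

    name: str
    seq: str
    direction: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "reverse"):
            raise ValueError("direction must be 'forward' or 'reverse'")
        degeneracy(self.seq)  # validates alphabet

    @property
    def degeneracy(self) -> int:
        return degeneracy(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PrimerPair:
    fwd: DegeneratePrimer
    rev: DegeneratePrimer
    min_product: int = 100
    max_product: int = 1000

    def __post_init__(self) -> None:
        if self.min_product > self.max_product:
            raise ValueError("min_product must be <= max_product")


def default_primer_pair(min_product: int = 100, max_product: int = 1000) -> PrimerPair:
    """The meta-rpoA pair used throughout the package."""
    return PrimerPair(
        fwd=DegeneratePrimer("meta-rpoA-F", META_RPOA_F, "forward"),
        rev=DegeneratePrimer("meta-rpoA-R", META_RPOA_R, "reverse"),
        min_product=min_product,
        max_product=max_product,
    )


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product.

    ``start``/``end`` are 0-based half-open coordinates on the template's
    forward strand, primer-inclusive.  ``product_seq`` is given in the
    orientation of the product (it begins with a forward-primer match), which
    for a reverse-strand hit is the reverse complement of the template slice.
    """

    template_id: str
    start: int
    end: int
    product_seq: NucSequence
    fwd_mismatches: int
    rev_mismatches: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.product_seq):
            raise ValueError("amplicon coordinates inconsistent with product length")

    def __len__(self) -> int:
        return len(self.product_seq)


@dataclass(frozen=True)
class DesignConstraints:
    primer_length: tuple[int, int] = (18, 24)
    degeneracy_cap: int = 64
    product_range: tuple[int, int] = (100, 1000)
    max_missed_targets: int = 0
    min_base_freq: float = 0.05

    def __post_init__(self) -> None:
        for lo, hi in (self.primer_length, self.product_range):
            if lo > hi:
                raise ValueError("empty range in design constraints")


@dataclass(frozen=True)
class DnaConstruct:
    """A synthetic plasmid construct: vector backbone plus gene insert."""

    vector_len: int
    insert_len: int
    mass_pg: float

    def __post_init__(self) -> None:
        if self.vector_len + self.insert_len <= 0:
            raise ValueError("construct length must be positive")
        if self.mass_pg <= 0:
            raise ValueError("mass must be positive")

    @property
    def total_len(self) -> int:
        return self.vector_len + self.insert_len


# ---------------------------------------------------------------------------
# Consensus / design


def column_base_sets(
    msa: list[NucSequence | str], min_base_freq: float = 0.05
) -> list[str | None]:
    """Per-column minimal IUPAC code covering bases at frequency >= threshold.

    Columns containing gap characters ('-') are flagged unusable (None).
    Accepts an aligned set of equal-length rows; raises on ragged input.
    """
    rows = [s.seq if isinstance(s, NucSequence) else s.upper() for s in msa]
    if len(rows) < 2:
        raise ValueError("an alignment needs at least two rows")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("ragged alignment: rows have unequal lengths")
    n = len(rows)
    out: list[str | None] = []
    for j in range(width):
        col = [r[j] for r in rows]
        if "-" in col or "." in col:
            out.append(None)
            continue
        kept = set()
        for base in "ACGT":
            if col.count(base) / n >= min_base_freq:
                kept.add(base)
        if not kept:  # column entirely N or all bases below threshold
            out.append(None)
            continue
        out.append(IUPAC_FROM_SET[frozenset(kept)])
    return out


@dataclass(frozen=True)
class _Window:
    start: int
    length: int
    consensus: str
    degeneracy: int
    coverage: int


def _candidate_windows(
    rows: list[str], codes: list[str | None], constraints: DesignConstraints
) -> list[_Window]:
    n = len(rows)
    width = len(codes)
    out = []
    lo, hi = constraints.primer_length
    for length in range(lo, hi + 1):
        for start in range(0, width - length + 1):
            window = codes[start:start + length]
            if any(c is None for c in window):
                continue
            consensus = "".join(window)  # type: ignore[arg-type]
            deg = degeneracy(consensus)
            if deg > constraints.degeneracy_cap:
                continue
            coverage = sum(
                degenerate_match(consensus, r[start:start + length], 0)[0]
                for r in rows
            )
            if coverage < n - constraints.max_missed_targets:
                continue
            out.append(_Window(start, length, consensus, deg, coverage))
    return out


def design_primer_pairs(
    msa: list[NucSequence | str], constraints: DesignConstraints = DesignConstraints()
) -> list[PrimerPair]:
    """Enumerate conserved consensus windows and pair them into primer pairs.

    Windows must have consensus degeneracy within the cap and match at least
    ``n_rows - max_missed_targets`` rows with zero mismatches.  Product length
    is measured in alignment columns from the forward window start to the end
    of the reverse window, primer-inclusive.  Pairs are ranked by (coverage
    desc, fwd*rev degeneracy asc, product length desc, leftmost forward
    start), which makes the ordering deterministic.
    """
    rows = [s.seq if isinstance(s, NucSequence) else s.upper() for s in msa]
    codes = column_base_sets(msa, constraints.min_base_freq)
    windows = _candidate_windows(rows, codes, constraints)
    pairs = []
    lo, hi = constraints.product_range
    for wf, wr in itertools.permutations(windows, 2):
        product_len = (wr.start + wr.length) - wf.start
        if not (lo <= product_len <= hi) or wr.start <= wf.start:
            continue
        fwd = DegeneratePrimer(f"fwd_{wf.start}", wf.consensus, "forward")
        rev = DegeneratePrimer(
            f"rev_{wr.start}", reverse_complement(wr.consensus), "reverse"
        )
        pairs.append(
            (
                -(min(wf.coverage, wr.coverage)),
                wf.degeneracy * wr.degeneracy,
                -product_len,
                wf.start,
                PrimerPair(fwd, rev, min_product=lo, max_product=hi),
            )
        )
    pairs.sort(key=lambda t: t[:4])
    return [p[-1] for p in pairs]


# ---------------------------------------------------------------------------
# In-silico PCR


def _find_sites(
    pattern: str,
    template: str,
    max_mismatch: int,
    protect_3prime: int,
    three_prime_side: str,
) -> list[tuple[int, int]]:
    """(start, mismatches) of every window matching an IUPAC pattern."""
    n, m = len(template), len(pattern)
    hits = []
    for i in range(0, n - m + 1):
        ok, mm = degenerate_match(
            pattern, template[i:i + m], max_mismatch, protect_3prime, three_prime_side
        )
        if ok:
            hits.append((i, mm))
    return hits


def _scan_strand(
    pair: PrimerPair,
    seq: str,
    template_id: str,
    strand: str,
    full_len: int,
    max_mismatch: int,
    protect_3prime: int,
) -> list[Amplicon]:
    fwd_sites = _find_sites(
        pair.fwd.seq, seq, max_mismatch, protect_3prime, "right"
    )
    rc_rev = reverse_complement(pair.rev.seq)
    # on the scanned strand the reverse primer's 3' end faces the product,
    # i.e. the left end of the rc pattern
    rev_sites = _find_sites(rc_rev, seq, max_mismatch, protect_3prime, "left")
    out = []
    for (fi, fmm), (ri, rmm) in itertools.product(fwd_sites, rev_sites):
        end = ri + len(rc_rev)
        product_len = end - fi
        if not (pair.min_product <= product_len <= pair.max_product):
            continue
        product = seq[fi:end]
        if strand == "+":
            start_f, end_f = fi, end
        else:  # map rc-space coordinates back to the forward strand
            start_f, end_f = full_len - end, full_len - fi
        out.append(
            Amplicon(
                template_id=template_id,
                start=start_f,
                end=end_f,
                product_seq=NucSequence(f"{template_id}|amplicon", product),
                fwd_mismatches=fmm,
                rev_mismatches=rmm,
                strand=strand,
            )
        )
    return out


def in_silico_pcr(
    pair: PrimerPair,
    template: NucSequence,
    max_mismatch: int = 3,
    protect_3prime: int = 3,
) -> list[Amplicon]:
    """Predict PCR products of a primer pair on a template, both strands.

    Degenerate primers are matched through base-set membership against the
    concrete template (never code-vs-code), with no mismatch allowed in the
    ``protect_3prime`` bases at each primer's 3' end.  All site pairs whose
    product length falls in the pair's product range are reported; an empty
    list is a valid outcome.
    """
    fwd_hits = _scan_strand(
        pair, template.seq, template.id, "+", len(template), max_mismatch, protect_3prime
    )
    rc = reverse_complement(template.seq)
    rev_hits = _scan_strand(
        pair, rc, template.id, "-", len(template), max_mismatch, protect_3prime
    )
    hits = fwd_hits + rev_hits
    hits.sort(key=lambda a: (a.start, a.end, a.strand))
    return hits


@dataclass(frozen=True)
class ScreenRow:
    seq_id: str
    on_target: bool
    amplified: bool
    product_len: int | None


@dataclass(frozen=True)
class ScreenReport:
    rows: list[ScreenRow]
    sensitivity: float
    specificity: float


def specificity_screen(
    pair: PrimerPair,
    on_targets: list[NucSequence],
    off_targets: list[NucSequence],
    max_mismatch: int = 3,
    protect_3prime: int = 3,
) -> ScreenReport:
    """In-silico sensitivity/specificity screen of a primer pair.

    sensitivity = amplified on-targets / on-targets;
    specificity = 1 - amplified off-targets / off-targets.
    """
    if not on_targets or not off_targets:
        raise ValueError("both reference sets must be non-empty")
    rows = []
    n_on = n_off = 0
    for is_on, seqs in ((True, on_targets), (False, off_targets)):
        for s in seqs:
            amps = in_silico_pcr(pair, s, max_mismatch, protect_3prime)
            amplified = bool(amps)
            rows.append(
                ScreenRow(s.id, is_on, amplified, len(amps[0]) if amps else None)
            )
            if amplified:
                if is_on:
                    n_on += 1
                else:
                    n_off += 1
    return ScreenReport(
        rows=rows,
        sensitivity=n_on / len(on_targets),
        specificity=1.0 - n_off / len(off_targets),
    )


# ---------------------------------------------------------------------------
# Copy-number arithmetic

#: pEX-A2J2-style construct geometry that reproduces the qPCR input of
#: 100 pg = 7.43 log10 gene copies: 2,450 bp vector + 990 bp rpoA insert.
PEX_A2J2_VECTOR_LEN = 2450
DEFAULT_INSERT_LEN = 990


def log10_copies(construct: DnaConstruct) -> float:
    """log10 molecule count of a dsDNA construct of given mass.

    copies = mass[g] * N_A / (total_len * 650 g mol^-1 bp^-1).  Monotone
    increasing in mass, decreasing in construct length.
    """
    grams = construct.mass_pg * 1e-12
    copies = grams * AVOGADRO / (construct.total_len * DSDNA_G_PER_MOL_PER_BP)
    return math.log10(copies)
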