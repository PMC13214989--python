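"""Sequence primitives shared across the package.

This module provides the IUPAC degenerate nucleotide alphabet, degenerate
pattern expansion and matching, reverse complementation, and end-gap-free
pairwise alignment with percent identity -- the identity measure that drives
the tiered taxonomic assignment of amplicon sequence variants (ASVs) against
the curated *rpoA* reference library.

Identity definition
-------------------
``align_identity`` performs a global alignment with free terminal gaps on
both sequences (match +1, mismatch -1, gap -2, linear gap cost).  Identity is
``100 * matches / aligned_columns`` where ``aligned_columns`` excludes the
terminal gap runs but *includes* internal gap columns (which count as
mismatching columns).  Among equally scoring alignments the one with the
fewest counted columns, then the most matches, defines the reported identity;
this makes the quantity deterministic and makes a substitution-only variant
score exactly 100*(L-k)/L.  A read that is an exact substring of a
reference therefore scores 100%.  The ambiguity letter ``N`` in a concrete
sequence matches nothing (it represents a low-quality base, not a wildcard).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._align import semi_global_align

__all__ = [
    "IUPAC_SETS",
    "IUPAC_COMPLEMENT",
    "NucSequence",
    "PairwiseIdentity",
    "InvalidAlphabetError",
    "degeneracy",
    "expand_degenerate",
    "reverse_complement",
    "degenerate_match",
    "align_identity",
    "read_fasta",
    "write_fasta",
]

#: Base sets of the 15-letter IUPAC nucleotide code.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Minimal IUPAC letter for every non-empty subset of {A,C,G,T}.
IUPAC_FROM_SET: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_CONCRETE = frozenset("ACGTN")

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


class InvalidAlphabetError(ValueError):
    """A sequence contains letters outside its declared alphabet."""


def _check_iupac(seq: str) -> None:
    bad = set(seq) - IUPAC_SETS.keys()
    if bad:
        raise InvalidAlphabetError(f"not IUPAC nucleotide letters: {sorted(bad)}")


@dataclass(frozen=True)
class NucSequence:
    """A concrete nucleotide sequence over {A,C,G,T,N}, upper-cased on ingest."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper().replace("U", "T"))
        if not self.seq:
            raise ValueError(f"empty sequence for {self.id!r}")
        bad = set(self.seq) - _CONCRETE
        if bad:
            raise InvalidAlphabetError(
                f"{self.id!r}: letters outside A/C/G/T/N: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def codes(self) -> np.ndarray:
        """Numeric encoding (A=0,C=1,G=2,T=3,N=4) used by the aligner."""
        return np.frombuffer(
            self.seq.encode().translate(_TRANS), dtype=np.uint8
        ).copy()


_TRANS = bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))


@dataclass(frozen=True)
class PairwiseIdentity:
    """Identity of an end-gap-free pairwise alignment.

    ``aligned_columns`` excludes terminal-gap runs; internal gap columns are
    counted (as non-matching).  ``identity_pct`` is 100*matches/aligned_columns,
    or 0.0 for a degenerate alignment with an empty aligned core.
    """

    matches: int
    aligned_columns: int
    identity_pct: float = field(init=False)

    def __post_init__(self) -> None:
        pct = 100.0 * self.matches / self.aligned_columns if self.aligned_columns else 0.0
        object.__setattr__(self, "identity_pct", pct)


def degeneracy(pattern: str) -> int:
    """Number of concrete sequences an IUPAC string stands for."""
    _check_iupac(pattern)
    n = 1
    for c in pattern:
        n *= len(IUPAC_SETS[c])
    return n


def expand_degenerate(pattern: str) -> list[str]:
    """All concrete A/C/G/T realizations of an IUPAC string, lexicographic."""
    if not pattern:
        raise ValueError("empty pattern")
    _check_iupac(pattern)
    pools = [sorted(IUPAC_SETS[c]) for c in pattern]
    return ["".join(p) for p in itertools.product(*pools)]


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC string (degenerate codes included)."""
    _check_iupac(seq)
    return "".join(IUPAC_COMPLEMENT[c] for c in reversed(seq))


def degenerate_match(
    pattern: str,
    window: str,
    max_mismatch: int = 0,
    protect_3prime: int = 0,
    three_prime_side: str = "right",
) -> tuple[bool, int]:
    """Match a concrete window against an IUPAC pattern of equal length.

    Position *i* matches when ``window[i]`` is in the base set of
    ``pattern[i]`` (``N`` in the window matches nothing).  Returns
    ``(ok, mismatches)`` where ``ok`` requires at most ``max_mismatch``
    mismatches overall and *zero* mismatches within the ``protect_3prime``
    positions at the primer's 3' end.  ``three_prime_side`` says on which end
    of the pattern the 3' terminus lies ("right" for a forward-oriented
    primer, "left" when the pattern is the reverse complement of a reverse
    primer laid on the forward strand).
    """
    if len(pattern) != len(window):
        raise ValueError(
            f"length mismatch: pattern {len(pattern)} vs window {len(window)}"
        )
    _check_iupac(pattern)
    n = len(pattern)
    mismatch_pos = [
        i for i, (p, w) in enumerate(zip(pattern, window))
        if w == "N" or w not in IUPAC_SETS[p]
    ]
    total = len(mismatch_pos)
    ok = total <= max_mismatch
    if ok and protect_3prime > 0 and mismatch_pos:
        if three_prime_side == "right":
            ok = mismatch_pos[-1] < n - protect_3prime
        elif three_prime_side == "left":
            ok = mismatch_pos[0] >= protect_3prime
        else:
            raise ValueError("three_prime_side must be 'right' or 'left'")
    return ok, total


def align_identity(a: NucSequence | str, b: NucSequence | str) -> PairwiseIdentity:
    """End-gap-free pairwise identity between two concrete sequences.

    See the module docstring for the exact definition.  Symmetric in its
    arguments.
    """
    if isinstance(a, str):
        a = NucSequence("a", a)
    if isinstance(b, str):
        b = NucSequence("b", b)
    _score, matches, cols = semi_global_align(a.codes(), b.codes())
    return PairwiseIdentity(matches=int(matches), aligned_columns=int(cols))


# ---------------------------------------------------------------------------
# FASTA IO


def read_fasta(path: str | Path) -> list[NucSequence]:
    """Read a FASTA file into NucSequences (upper-cased, U mapped to T)."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(NucSequence(id=rec.description, seq=str(rec.seq)))
    return out


def write_fasta(
    path: str | Path, seqs: Iterable[NucSequence], wrap: int | None = None
) -> None:
    """Write sequences as FASTA; ``wrap=None`` writes unwrapped lines."""
    records = [SeqRecord(Seq(s.seq), id=s.id, description="") for s in seqs]
    if wrap is None:
        with open(path, "w") as fh:
            for r in records:
                fh.write(f">{r.id}\n{r.seq}\n")
    else:
        with open(path, "w") as fh:
            for r in records:
                fh.write(f">{r.id}\n")
                for i in range(0, len(r.seq), wrap):
                    fh.write(f"{str(r.seq)[i:i + wrap]}\n")
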