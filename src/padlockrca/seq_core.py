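"""Sequence primitives shared by the probe-design stack.

This module owns the alphabet-checked sequence container, FASTA input and
output, and the canonical (strand-collapsed) k-mer index used to screen
linker and backbone candidates for similarity against a transcriptome.
The index is deliberately an in-memory set: the design problem only ever
asks "does this short oligo share a full-length k-mer window with any
transcript", which a set answers exactly and fast at transcriptome toy
scale.  All reported coordinates are 1-based inclusive; internal indexing
is ordinary 0-based Python slicing.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alphabet",
    "NucSeq",
    "MiRNARecord",
    "KmerIndex",
    "SequenceError",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "gc_content",
    "canonical_kmer",
    "build_kmer_index",
    "count_index_hits",
]


class Alphabet(str, Enum):
    DNA = "DNA"
    RNA = "RNA"


_BASES = {Alphabet.DNA: frozenset("ACGT"), Alphabet.RNA: frozenset("ACGU")}
_COMPLEMENT = {
    Alphabet.DNA: str.maketrans("ACGT", "TGCA"),
    Alphabet.RNA: str.maketrans("ACGU", "UGCA"),
}
_DNA_COMPLEMENT = _COMPLEMENT[Alphabet.DNA]

# Deterministic resolution of IUPAC ambiguity codes used by the permissive
# FASTA reader: each code maps to its lexicographically smallest member.
_IUPAC_RESOLVE = str.maketrans(
    {"R": "A", "Y": "C", "S": "C", "W": "A", "K": "G", "M": "A",
     "B": "C", "D": "A", "H": "A", "V": "A", "N": "A"}
)


class SequenceError(ValueError):
    """Raised for malformed sequences or FASTA records."""


@dataclass(frozen=True)
class NucSeq:
    """An uppercase nucleotide string with an explicit alphabet.

    Invariants: non-empty, residues drawn from {A,C,G,T} (DNA) or
    {A,C,G,U} (RNA).
    """

    residues: str
    alphabet: Alphabet = Alphabet.DNA

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError("empty sequence")
        if self.residues != self.residues.upper():
            object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - _BASES[self.alphabet]
        if bad:
            raise SequenceError(
                f"illegal {self.alphabet.value} residue(s) {sorted(bad)} "
                f"in {self.residues[:40]!r}"
            )

    @classmethod
    def from_string(cls, s: str, alphabet: Alphabet | None = None) -> "NucSeq":
        """Build a NucSeq, inferring the alphabet from U/T when not given."""
        s = s.upper()
        if alphabet is None:
            alphabet = Alphabet.RNA if "U" in s else Alphabet.DNA
        return cls(s, alphabet)

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def as_dna(self) -> "NucSeq":
        """The same strand rendered in the DNA alphabet (U -> T)."""
        if self.alphabet is Alphabet.DNA:
            return self
        return NucSeq(self.residues.replace("U", "T"), Alphabet.DNA)

    def as_rna(self) -> "NucSeq":
        if self.alphabet is Alphabet.RNA:
            return self
        return NucSeq(self.residues.replace("T", "U"), Alphabet.RNA)


@dataclass(frozen=True)
class MiRNARecord:
    """A mature miRNA (RNA alphabet).

    Functional mature miRNAs are 20-21 nt; lengths in 18..25 are accepted
    with a warning outside the canonical 20-21 band, anything else is an
    error.
    """

    id: str
    sequence: NucSeq

    def __post_init__(self) -> None:
        if self.sequence.alphabet is not Alphabet.RNA:
            object.__setattr__(self, "sequence", self.sequence.as_rna())
        n = len(self.sequence)
        if not 18 <= n <= 25:
            raise SequenceError(
                f"miRNA {self.id!r} has length {n}; expected 18..25 nt"
            )
        if not 20 <= n <= 21:
            warnings.warn(
                f"miRNA {self.id!r} is {n} nt; mature miRNAs are typically "
                "20-21 nt",
                stacklevel=2,
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


def reverse_complement(s: NucSeq, to_dna: bool = False) -> NucSeq:
    """Antiparallel complement of `s`, in the same alphabet.

    With ``to_dna=True`` an RNA input is complemented into the DNA
    alphabet, yielding the DNA strand that hybridizes to it (the strand a
    synthesized probe is made of).
    """
    if to_dna:
        s = s.as_dna()
    rc = s.residues.translate(_COMPLEMENT[s.alphabet])[::-1]
    return NucSeq(rc, s.alphabet)


def gc_content(s: NucSeq) -> float:
    """Fraction of G+C residues, in [0, 1]."""
    r = s.residues
    return (r.count("G") + r.count("C")) / len(r)


def read_fasta(
    path: str | Path,
    alphabet: Alphabet | None = None,
    allow_ambiguous: bool = False,
) -> list[tuple[str, NucSeq]]:
    """Read a FASTA file into ``(id, NucSeq)`` pairs.

    Sequences are uppercased; U/T is preserved as read and the alphabet is
    inferred per record unless forced.  IUPAC ambiguity codes are rejected
    by default; ``allow_ambiguous=True`` resolves each code to its
    lexicographically smallest compatible base (a deterministic, documented
    simplification -- ambiguity-aware matching is out of scope).
    """
    path = Path(path)
    out: list[tuple[str, NucSeq]] = []
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # malformed header structure
        raise SequenceError(f"{path}: {exc}") from exc
    for rec in records:
        if not rec.id:
            raise SequenceError(f"{path}: record with empty header")
        s = str(rec.seq).upper()
        if not s:
            raise SequenceError(f"{path}: record {rec.id!r} has no sequence")
        if allow_ambiguous:
            s = s.translate(_IUPAC_RESOLVE)
        legal = _BASES[Alphabet.DNA] | _BASES[Alphabet.RNA]
        bad = [(i + 1, ch) for i, ch in enumerate(s) if ch not in legal]
        if bad:
            pos, ch = bad[0]
            raise SequenceError(
                f"{path}: record {rec.id!r} contains illegal character "
                f"{ch!r} at position {pos}"
            )
        if "U" in s and "T" in s:
            raise SequenceError(
                f"{path}: record {rec.id!r} mixes U and T residues"
            )
        out.append((rec.id, NucSeq.from_string(s, alphabet)))
    return out


def write_fasta(records: Iterable[tuple[str, NucSeq]], path: str | Path) -> None:
    """Write ``(id, NucSeq)`` pairs as FASTA (round-trips byte-exactly
    through :func:`read_fasta` for ids and residues)."""
    seqrecords = [
        SeqRecord(Seq(seq.residues), id=name, description="")
        for name, seq in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


def canonical_kmer(kmer: str) -> str:
    """Strand-collapsed canonical form: lexicographic min of the DNA k-mer
    and its reverse complement."""
    rc = kmer.translate(_DNA_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc


@dataclass(frozen=True)
class KmerIndex:
    """Canonical k-mer set over a transcriptome.

    Canonicalization collapses strands, so a query window hits the index
    if either it or its reverse complement occurs in any indexed
    transcript -- the conservative convention for off-target screening.
    """

    k: int
    kmers: frozenset[str]
    source_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be positive")
        for km in self.kmers:
            if len(km) != self.k:
                raise ValueError(
                    f"stored k-mer {km!r} has length {len(km)} != k={self.k}"
                )
            break  # frozenset of uniform strings; checking one suffices
        # full check is O(n) but cheap at toy scale; keep it exact
        if any(len(km) != self.k for km in self.kmers):
            raise ValueError("k-mer length inconsistent with k")

    @classmethod
    def empty(cls, k: int = 15) -> "KmerIndex":
        return cls(k=k, kmers=frozenset())

    def __len__(self) -> int:
        return len(self.kmers)

    def __contains__(self, kmer: str) -> bool:
        return canonical_kmer(kmer.upper()) in self.kmers


def build_kmer_index(
    transcripts: Sequence[tuple[str, NucSeq]], k: int = 15
) -> KmerIndex:
    """Index every canonical k-mer of `transcripts`.

    The default k of 15 equals the padlock arm length: an off-target site
    needs a full-arm perfect match to seed ligation, so a 15-mer collision
    is the smallest event worth flagging.  Transcripts shorter than k are
    skipped with a warning.
    """
    if k < 8:
        raise ValueError(f"k={k} too small for a meaningful screen; need k >= 8")
    if not transcripts:
        raise ValueError("no transcripts supplied")
    kmers: set[str] = set()
    ids: list[str] = []
    for tid, seq in transcripts:
        s = seq.as_dna().residues
        if len(s) < k:
            warnings.warn(
                f"transcript {tid!r} shorter than k={k}; skipped", stacklevel=2
            )
            continue
        ids.append(tid)
        for i in range(len(s) - k + 1):
            kmers.add(canonical_kmer(s[i : i + k]))
    return KmerIndex(k=k, kmers=frozenset(kmers), source_ids=tuple(ids))


def count_index_hits(s: NucSeq, index: KmerIndex) -> int:
    """Number of length-k windows of `s` whose canonical k-mer is indexed."""
    q = s.as_dna().residues
    if len(q) < index.k:
        raise ValueError(
            f"query length {len(q)} shorter than index k={index.k}"
        )
    return sum(
        canonical_kmer(q[i : i + index.k]) in index.kmers
        for i in range(len(q) - index.k + 1)
    )
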