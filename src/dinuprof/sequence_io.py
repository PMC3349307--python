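"""FASTA input/output and the bundled 11-species beta-globin dataset.

Sequences are plain A/C/G/T strings with a label.  Lowercase input is
uppercased silently; any other character is rejected unless the caller
opts into the permissive mode, in which case ambiguity codes are kept
and excluded later at the pair-counting stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ACGT = frozenset("ACGT")

#: Species order of the bundled beta-globin dataset.  All tabular output
#: follows this order, never alphabetical.
BETA_GLOBIN_SPECIES = (
    "Human",
    "Chimpanzee",
    "Gorilla",
    "Lemur",
    "Rat",
    "Mouse",
    "Rabbit",
    "Goat",
    "Bovine",
    "Opossum",
    "Gallus",
)


class SequenceError(ValueError):
    """Invalid sequence data (bad alphabet, duplicate labels, empty input)."""


@dataclass(frozen=True)
class DnaSequence:
    """A labelled DNA sequence over the A/C/G/T alphabet.

    Parameters
    ----------
    id :
        Record label (first whitespace-delimited token of a FASTA header).
    residues :
        The nucleotide string.  Lowercase is normalised to uppercase.
    description :
        Remainder of the FASTA header, kept for round-tripping but unused.
    allow_ambiguous :
        If True, characters outside A/C/G/T are retained instead of
        raising; pair counting then skips any pair touching them.
    """

    id: str
    residues: str
    description: str = ""
    allow_ambiguous: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.id:
            raise SequenceError("sequence id must be non-empty")
        if not self.allow_ambiguous:
            for pos, ch in enumerate(self.residues, start=1):
                if ch not in ACGT:
                    raise SequenceError(
                        f"record {self.id!r}: invalid character {ch!r} "
                        f"at position {pos} (expected A/C/G/T)"
                    )
        if self.n < 4:
            raise SequenceError(
                f"record {self.id!r}: length {self.n} < 4; no valid "
                "separation distance exists under the d <= floor(n/4) rule"
            )

    @property
    def n(self) -> int:
        """Sequence length in nucleotides."""
        return len(self.residues)

    def __len__(self) -> int:
        return self.n


@dataclass(frozen=True)
class SequenceSet:
    """An ordered collection of :class:`DnaSequence` with unique labels."""

    records: tuple[DnaSequence, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise SequenceError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(rec.id for rec in self.records)

    def __iter__(self) -> Iterator[DnaSequence]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, key: Union[int, str]) -> DnaSequence:
        if isinstance(key, str):
            for rec in self.records:
                if rec.id == key:
                    return rec
            raise KeyError(key)
        return self.records[key]


def read_fasta(
    path: Union[str, Path], *, allow_ambiguous: bool = False
) -> SequenceSet:
    """Read a multi-record FASTA file into a :class:`SequenceSet`.

    The record id is the first whitespace-delimited token of the header;
    the rest of the header is kept as the description.  An empty file,
    a duplicate id, or (in strict mode) a non-ACGT character is an error.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            DnaSequence(
                id=rec.id,
                residues=str(rec.seq),
                description=rec.description[len(rec.id):].strip(),
                allow_ambiguous=allow_ambiguous,
            )
        )
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return SequenceSet(tuple(records))


def write_fasta(
    seqs: SequenceSet, path: Union[str, Path], *, line_width: int = 70
) -> None:
    """Write a :class:`SequenceSet` to FASTA; round-trips with `read_fasta`."""
    if len(seqs) == 0:
        raise SequenceError("refusing to write an empty SequenceSet")
    records = [
        SeqRecord(
            Seq(rec.residues),
            id=rec.id,
            description=rec.description,
        )
        for rec in seqs
    ]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=line_width)
    writer.write_file(records)


def builtin_beta_globin() -> SequenceSet:
    """The exon-1 beta-globin coding sequences of 11 species.

    A standard benchmark for alignment-free DNA descriptors: Human,
    Chimpanzee, Gorilla, Lemur, Rat, Mouse, Rabbit, Goat, Bovine,
    Opossum and Gallus, in that fixed order (lengths 86-105 nt).
    """
    ref = resources.files("dinuprof").joinpath("data/beta_globin.fasta")
    with resources.as_file(ref) as path:
        seqs = read_fasta(path)
    assert seqs.labels == BETA_GLOBIN_SPECIES
    return seqs
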