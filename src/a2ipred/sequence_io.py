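"""FASTA input/output and fixed-length window extraction.

Sequences are normalized to the RNA alphabet {A, C, G, U}; DNA input is
accepted and T is converted to U. Prediction operates on odd-length windows
centered on a candidate adenosine — by default 51 nt, so the editable A sits
at 1-based position 26. All public coordinates are 1-based and inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_INPUT = set("ACGTUacgtu")
RNA_ALPHABET = set("ACGU")


class SequenceError(ValueError):
    """Raised for malformed sequence input (bad characters, bad windows)."""


@dataclass(frozen=True)
class NucleotideSequence:
    """An RNA sequence with an identifier; residues over {A,C,G,U}."""

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 2:
            raise SequenceError(
                f"sequence {self.identifier!r} has length {len(self.residues)}; "
                "need at least one dinucleotide (length >= 2)"
            )
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            raise SequenceError(
                f"sequence {self.identifier!r} contains non-RNA residues {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SiteWindow:
    """A fixed-length, odd-length window with a candidate A at the center.

    ``center_position_1based`` records where the central A sits in the
    *source* sequence the window was cut from; for a free-standing window it
    equals the central index ``(window_length + 1) // 2``.
    """

    source_id: str
    center_position_1based: int
    residues: str

    def __post_init__(self) -> None:
        n = len(self.residues)
        if n < 3 or n % 2 == 0:
            raise SequenceError(
                f"window {self.source_id!r}: length {n} is not odd and >= 3"
            )
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            raise SequenceError(
                f"window {self.source_id!r} contains non-RNA residues {sorted(bad)}"
            )
        center = n // 2  # 0-based
        if self.residues[center] != "A":
            raise SequenceError(
                f"window {self.source_id!r}: center is not adenosine "
                f"(found {self.residues[center]!r} at 1-based position {center + 1})"
            )

    @property
    def window_length(self) -> int:
        return len(self.residues)

    @property
    def central_index_1based(self) -> int:
        """1-based position of the candidate A inside the window (26 for 51 nt)."""
        return len(self.residues) // 2 + 1


def normalize_rna(raw: str) -> str:
    """Uppercase and convert DNA-style T to U; reject anything outside ACGTU.

    The error names the 1-based position of the first offending character.
    """
    if not raw:
        raise SequenceError("empty sequence")
    for i, ch in enumerate(raw):
        if ch not in VALID_INPUT:
            raise SequenceError(
                f"invalid character {ch!r} at position {i + 1}; "
                "expected one of A, C, G, T, U (ambiguity codes are rejected)"
            )
    return raw.upper().replace("T", "U")


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a multi-record FASTA file into normalized RNA sequences.

    Record order is preserved; wrapped lines are joined. An empty file or a
    record that fails normalization is an error naming the record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    out: list[NucleotideSequence] = []
    for rec in records:
        try:
            residues = normalize_rna(str(rec.seq))
            out.append(NucleotideSequence(rec.id, residues))
        except SequenceError as exc:
            raise SequenceError(f"record {rec.id!r}: {exc}") from exc
    return out


def write_fasta(sequences: Iterable[NucleotideSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.identifier, description="")
        for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def extract_window(
    seq: NucleotideSequence, center_1based: int, flank: int = 25
) -> SiteWindow:
    """Cut the inclusive window [center - flank, center + flank] around a candidate A.

    No padding: a window that would run off either end of the sequence is an
    error (callers that want lenient batch behavior skip and warn instead).
    """
    if not 1 <= center_1based <= seq.length:
        raise SequenceError(
            f"center position {center_1based} outside sequence "
            f"{seq.identifier!r} (length {seq.length})"
        )
    if seq.residues[center_1based - 1] != "A":
        raise SequenceError(
            f"center is not adenosine: {seq.identifier!r} position {center_1based} "
            f"is {seq.residues[center_1based - 1]!r}"
        )
    if center_1based - flank < 1 or center_1based + flank > seq.length:
        raise SequenceError(
            f"window [{center_1based - flank}, {center_1based + flank}] exceeds "
            f"bounds of {seq.identifier!r} (length {seq.length}); no padding is applied"
        )
    residues = seq.residues[center_1based - flank - 1 : center_1based + flank]
    return SiteWindow(seq.identifier, center_1based, residues)


def window_from_sequence(seq: NucleotideSequence) -> SiteWindow:
    """Treat a whole odd-length record as one window centered on its middle A."""
    if seq.length % 2 == 0:
        raise SequenceError(
            f"record {seq.identifier!r} has even length {seq.length}; "
            "cannot define a central position"
        )
    center = seq.length // 2 + 1
    return extract_window(seq, center, flank=seq.length // 2)
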