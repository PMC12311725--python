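"""Sequence I/O, six-frame translation and ORF finding.

Candidate cysteine-rich peptide (CRP) precursors are mined from
transcriptome contigs: contigs are translated in all six frames and
Met-initiated open reading frames are extracted as candidate protein
records for the motif scanner.

Coordinates are 0-based half-open internally; every human-readable
output (FASTA descriptions, TSV) reports 1-based inclusive positions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

NUCLEOTIDE_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

Kind = Literal["nucleotide", "protein"]


class SequenceValidationError(ValueError):
    """A sequence contains characters illegal for its declared alphabet."""


@dataclass
class SequenceRecord:
    """A named nucleotide or protein sequence with provenance.

    Attributes
    ----------
    id : str
        Record identifier (first whitespace-delimited token of the
        FASTA header).
    seq : str
        Uppercase residue string. Nucleotide records use ACGTN;
        protein records use the 20 canonical letters plus X.
    kind : {"nucleotide", "protein"}
    description : str
        Free text (remainder of the FASTA header, or provenance notes).
    """

    id: str
    seq: str
    kind: Kind = "protein"
    description: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")
        alphabet = NUCLEOTIDE_ALPHABET if self.kind == "nucleotide" else PROTEIN_ALPHABET
        bad = set(self.seq) - alphabet
        if bad:
            raise SequenceValidationError(
                f"record {self.id!r}: illegal {self.kind} character(s) "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ProteinFrame:
    """One of the six conceptual translation frames of a contig.

    ``frame`` is +1/+2/+3 for the forward strand and -1/-2/-3 for the
    reverse complement; ``offset`` is the 0-based start of the frame on
    the strand that was translated. Stop codons appear as ``*``.
    """

    source_id: str
    frame: int
    seq: str
    offset: int = field(default=0)


def read_fasta(path: str | Path, kind: Kind = "protein") -> list[SequenceRecord]:
    """Read a multi-record FASTA file into validated SequenceRecords.

    Whitespace inside sequences is stripped and residues uppercased.
    Duplicate record ids are parsed but trigger a warning. An empty
    file yields an empty list with a logged warning.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    SequenceValidationError
        If a record contains characters illegal for *kind*.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            warnings.warn(f"duplicate FASTA id {rec.id!r} in {path}", stacklevel=2)
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(
            SequenceRecord(id=rec.id, seq=str(rec.seq).replace(" ", ""), kind=kind, description=desc)
        )
    if not records:
        log.warning("no FASTA records parsed from %s", path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA wrapped at *width* columns."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def six_frame_translate(rec: SequenceRecord, table: int | str = 1) -> list[ProteinFrame]:
    """Translate a nucleotide record in all six conceptual frames.

    Uses the standard genetic code by default. Codons containing N
    translate to X; trailing partial codons are dropped. Sequences
    shorter than one codon yield six empty frames.
    """
    if rec.kind != "nucleotide":
        raise ValueError(f"record {rec.id!r}: six_frame_translate requires a nucleotide record")
    frames: list[ProteinFrame] = []
    fwd = Seq(rec.seq)
    rev = fwd.reverse_complement()
    for strand_sign, strand in ((1, fwd), (-1, rev)):
        for off in range(3):
            sub = strand[off : off + 3 * ((len(strand) - off) // 3)]
            aa = str(sub.translate(table=table)) if len(sub) >= 3 else ""
            frames.append(
                ProteinFrame(source_id=rec.id, frame=strand_sign * (off + 1), seq=aa, offset=off)
            )
    return frames


def find_orfs(
    frames: Iterable[ProteinFrame],
    min_len: int,
    require_met: bool = True,
) -> list[SequenceRecord]:
    """Extract maximal Met-initiated, stop-terminated ORFs from frames.

    An ORF is the longest segment starting at a Met (or any residue
    when ``require_met=False``) and running to the next stop codon
    (exclusive) or frame end, of length >= *min_len* residues. Each
    output record's description carries the source id, frame and
    1-based residue coordinates within the frame.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    orfs: list[SequenceRecord] = []
    for fr in frames:
        for segment, seg_start in _split_on_stops(fr.seq):
            if require_met:
                m = segment.find("M")
                if m < 0:
                    continue
                segment, seg_start = segment[m:], seg_start + m
            if len(segment) < min_len:
                continue
            start1, end1 = seg_start + 1, seg_start + len(segment)
            orfs.append(
                SequenceRecord(
                    id=f"{fr.source_id}|frame{fr.frame:+d}|{start1}-{end1}",
                    seq=segment,
                    kind="protein",
                    description=(
                        f"source={fr.source_id} frame={fr.frame:+d} "
                        f"aa_coords={start1}-{end1} (1-based)"
                    ),
                )
            )
    return orfs


def _split_on_stops(seq: str) -> list[tuple[str, int]]:
    """Split a translated frame on '*' into (segment, 0-based start) pairs."""
    out = []
    start = 0
    for i, ch in enumerate(seq + "*"):
        if ch == "*":
            if i > start:
                out.append((seq[start:i], start))
            start = i + 1
    return out
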