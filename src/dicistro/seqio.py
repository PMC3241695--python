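"""Sequence and annotation I/O.

All downstream modules work on :class:`GenomeRecord` objects whose sequences
are normalized to the DNA alphabet {A,C,G,T,N}; RNA input (containing U) is
accepted and tagged so reports can re-display U.  Every genome coordinate in
this package is 1-based inclusive on the forward (+) strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlphabetError,
    CoordinateError,
    DuplicateIdError,
    EmptyInputError,
    FastaFormatError,
)

_VALID = set("ACGTUN")
_DNA = {"A", "C", "G", "T", "N"}

GFF_SOURCE = "dicistro"


@dataclass(frozen=True)
class GenomeRecord:
    """One nucleotide sequence with provenance.

    ``sequence`` is always over {A,C,G,T,N}; ``original_alphabet`` records
    whether the input contained U (RNA) before normalization.
    """

    id: str
    description: str
    sequence: str
    original_alphabet: str = "DNA"  # "DNA" | "RNA"

    def __post_init__(self):
        if not self.sequence:
            raise EmptyInputError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - _DNA
        if bad:
            ch = sorted(bad)[0]
            raise AlphabetError(ch, self.sequence.index(ch))

    def __len__(self) -> int:
        return len(self.sequence)

    def subseq(self, start: int, end: int) -> str:
        """Sequence between 1-based inclusive coordinates."""
        if not (1 <= start <= end <= len(self.sequence)):
            raise CoordinateError(
                f"span {start}..{end} outside record {self.id!r} "
                f"of length {len(self.sequence)}"
            )
        return self.sequence[start - 1 : end]


def normalize_alphabet(raw: str) -> tuple[str, str]:
    """Uppercase, map U->T and report which alphabet the input used.

    Returns ``(sequence, tag)`` where tag is ``"RNA"`` if any U/u was seen,
    else ``"DNA"``.  Characters outside {A,C,G,T,U,N} raise
    :class:`AlphabetError` naming the character and its 0-based offset.
    """
    if not raw:
        raise EmptyInputError("cannot normalize an empty sequence")
    up = raw.upper()
    for i, ch in enumerate(up):
        if ch not in _VALID:
            raise AlphabetError(raw[i], i)
    tag = "RNA" if "U" in up else "DNA"
    return up.replace("U", "T"), tag


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a (multi-record) FASTA file into normalized GenomeRecords.

    Record order is preserved.  Duplicate identifiers, stray text before the
    first header, an empty file, and illegal residues are all rejected.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise EmptyInputError(f"{path} is empty")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise FastaFormatError(
                    f"{path}: expected FASTA header before sequence data", lineno
                )
            break

    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaFormatError(f"{path}: record with empty identifier")
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        try:
            seq, tag = normalize_alphabet(str(rec.seq))
        except AlphabetError as err:
            raise FastaFormatError(
                f"{path}: record {rec.id!r}: {err}",
                _locate_line(text, rec.id, err.offset),
            ) from err
        records.append(
            GenomeRecord(
                id=rec.id,
                description=rec.description,
                sequence=seq,
                original_alphabet=tag,
            )
        )
    if not records:
        raise EmptyInputError(f"{path} contains no FASTA records")
    return records


def _locate_line(text: str, record_id: str, seq_offset: int) -> int | None:
    """Line number of the ``seq_offset``-th residue of record ``record_id``."""
    in_record = False
    consumed = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(">"):
            header_id = line[1:].split()[0] if line[1:].split() else ""
            in_record = header_id == record_id
            consumed = 0
            continue
        if in_record:
            chunk = len(line.strip())
            if consumed + chunk > seq_offset:
                return lineno
            consumed += chunk
    return None


def write_fasta(
    records: Iterable[GenomeRecord], path: str | Path, alphabet: str = "DNA"
) -> None:
    """Write records to FASTA; ``alphabet="original"`` re-displays U for RNA."""
    out = []
    for rec in records:
        seq = rec.sequence
        if alphabet == "original" and rec.original_alphabet == "RNA":
            seq = seq.replace("T", "U")
        out.append(SeqRecord(Seq(seq), id=rec.id, description=rec.description))
    SeqIO.write(out, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 annotation output


@dataclass(frozen=True)
class GffFeature:
    """One parsed GFF3 feature line (round-trip checking and reports)."""

    seqid: str
    type: str
    start: int
    end: int
    strand: str = "+"
    attributes: dict = field(default_factory=dict)


def write_annotations(record: GenomeRecord, arch, hits: Sequence, path: str | Path) -> None:
    """Write a five-segment di-cistronic annotation (plus motifs) as GFF3.

    ``arch`` is a :class:`~dicistro.orf_annotator.DicistronicArchitecture`;
    ``hits`` are :class:`~dicistro.polyprotein_annotator.MotifHit` objects
    whose amino-acid coordinates are converted to nucleotide spans on the
    genome (capsid-region motifs are assigned to ORF2, all others to ORF1).
    Zero-length segments are omitted (GFF3 cannot express them).
    """
    length = len(record)
    if arch.genome_length != length:
        raise CoordinateError(
            f"architecture genome_length {arch.genome_length} != record length {length}"
        )
    lines = ["##gff-version 3", f"##sequence-region {record.id} 1 {length}"]

    def fmt(ftype: str, start: int, end: int, attrs: dict) -> str:
        if not (1 <= start <= end <= length):
            raise CoordinateError(
                f"feature {ftype} span {start}..{end} overflows genome of {length} nt"
            )
        attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
        return "\t".join(
            [record.id, GFF_SOURCE, ftype, str(start), str(end), ".", "+", ".", attr_s]
        )

    segments = [
        ("five_prime_UTR", arch.utr5.start, arch.utr5.end, {"ID": "utr5"}),
        ("CDS", arch.orf1.start, arch.orf1.end, {"ID": "orf1", "frame": arch.orf1.frame}),
        ("intergenic_region", arch.igr.start, arch.igr.end, {"ID": "igr"}),
        ("CDS", arch.orf2.start, arch.orf2.end, {"ID": "orf2", "frame": arch.orf2.frame}),
        ("three_prime_UTR", arch.utr3.start, arch.utr3.end, {"ID": "utr3"}),
    ]
    for ftype, s, e, attrs in segments:
        if e >= s:  # skip empty segments
            lines.append(fmt(ftype, s, e, attrs))

    for i, hit in enumerate(hits, start=1):
        orf = arch.orf2 if hit.region == "capsid" else arch.orf1
        parent = "orf2" if hit.region == "capsid" else "orf1"
        nt_start = orf.start + 3 * (hit.aa_start - 1)
        nt_end = nt_start + 3 * len(hit.matched) - 1
        if nt_end > orf.end:
            raise CoordinateError(
                f"motif {hit.name!r} at aa {hit.aa_start} overflows {parent}"
            )
        lines.append(
            fmt(
                "sequence_motif",
                nt_start,
                nt_end,
                {
                    "ID": f"motif{i}",
                    "Name": hit.name,
                    "Parent": parent,
                    "region": hit.region,
                    "aa_start": hit.aa_start,
                },
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotations(path: str | Path) -> list[GffFeature]:
    """Parse a GFF3 file written by :func:`write_annotations`."""
    feats: list[GffFeature] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise FastaFormatError(f"{path}: malformed GFF3 line: {line!r}")
        attrs = {}
        for item in cols[8].split(";"):
            if item:
                k, _, v = item.partition("=")
                attrs[k] = v
        feats.append(
            GffFeature(
                seqid=cols[0],
                type=cols[2],
                start=int(cols[3]),
                end=int(cols[4]),
                strand=cols[6],
                attributes=attrs,
            )
        )
    return feats


# ---------------------------------------------------------------------------
# Host-label tables (TSV: sequence id <tab> host label)


def read_labels(path: str | Path) -> dict[str, str]:
    labels: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise FastaFormatError(f"{path}: expected 'id<TAB>label'", lineno)
        if parts[0] in labels:
            raise DuplicateIdError(f"duplicate id {parts[0]!r} in {path}")
        labels[parts[0]] = parts[1]
    if not labels:
        raise EmptyInputError(f"{path} contains no labels")
    return labels


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{sid}\t{lab}\n" for sid, lab in labels.items())
    )


def as_rna(record: GenomeRecord) -> GenomeRecord:
    """Tag a record as RNA-origin (used when building synthetic +ssRNA genomes)."""
    return replace(record, original_alphabet="RNA")
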