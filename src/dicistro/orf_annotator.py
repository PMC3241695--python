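"""ORF enumeration and di-cistronic architecture detection.

A di-cistronic +ssRNA genome carries two long non-overlapping open reading
frames on the forward strand — ORF1 (replicase polyprotein) and ORF2 (capsid
polyprotein) — flanked by a 5'UTR and 3'UTR and separated by an intergenic
region (IGR).  This module enumerates start/stop codons per frame, finds
maximal AUG-to-stop ORFs, selects the di-cistronic pair, accounts for coding
vs non-coding content, and places PCR primers in silico.

Coordinates are 1-based inclusive on the forward strand.  An ORF's ``start``
is the A of its AUG and ``end`` the last base of its stop codon, so
``nt_length`` is divisible by 3 and ``aa_length = nt_length/3 - 1`` (the stop
codon is not translated).  Minus-strand ORFs keep forward-strand spans
(``start < end``) with ``strand == "-"``; their AUG then sits at ``end``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .errors import (
    AmbiguousArchitectureError,
    CoordinateError,
    NotDicistronicError,
    TranslationError,
)
from .seqio import GenomeRecord

STOP_CODONS = ("TAA", "TAG", "TGA")
START_CODON = "ATG"


@dataclass(frozen=True)
class OrfAnnotation:
    """One open reading frame, AUG through its in-frame stop codon."""

    start: int
    end: int
    frame: int  # 1..3, on the strand the ORF is read
    strand: str = "+"

    def __post_init__(self):
        if self.start >= self.end:
            raise CoordinateError(f"ORF start {self.start} must precede end {self.end}")
        if (self.end - self.start + 1) % 3 != 0:
            raise CoordinateError(
                f"ORF span {self.start}..{self.end} is not a whole number of codons"
            )
        if self.aa_length < 1:
            raise CoordinateError("ORF must encode at least one amino acid")

    @property
    def nt_length(self) -> int:
        return self.end - self.start + 1

    @property
    def aa_length(self) -> int:
        return self.nt_length // 3 - 1


@dataclass(frozen=True)
class Span:
    """A (possibly empty) 1-based inclusive interval; empty iff end < start."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return max(0, self.end - self.start + 1)


@dataclass(frozen=True)
class DicistronicArchitecture:
    """The five-segment partition 5'UTR / ORF1 / IGR / ORF2 / 3'UTR."""

    genome_length: int
    utr5: Span
    orf1: OrfAnnotation
    igr: Span
    orf2: OrfAnnotation
    utr3: Span
    reverse_large_orf: bool = False

    def __post_init__(self):
        total = (
            self.utr5.length
            + self.orf1.nt_length
            + self.igr.length
            + self.orf2.nt_length
            + self.utr3.length
        )
        if total != self.genome_length:
            raise CoordinateError(
                f"segment lengths sum to {total}, genome is {self.genome_length} nt"
            )
        if self.orf1.end >= self.orf2.start:
            raise CoordinateError("ORF1 must end 5' of ORF2")

    def segment_lengths(self) -> dict[str, int]:
        return {
            "utr5": self.utr5.length,
            "orf1": self.orf1.nt_length,
            "igr": self.igr.length,
            "orf2": self.orf2.nt_length,
            "utr3": self.utr3.length,
        }


@dataclass(frozen=True)
class SegmentReport:
    """Per-segment lengths and coding/non-coding accounting (percent)."""

    lengths: dict
    coding_fraction: float
    noncoding_fraction: float
    orf1_aa: int
    orf2_aa: int


@dataclass(frozen=True)
class DetectConfig:
    """Thresholds for di-cistronic detection.

    ``large_orf_min_nt`` is the size above which a reverse-strand ORF is
    flagged (a genuine di-cistronic +ssRNA genome should have none).
    """

    large_orf_min_nt: int = 300


def codon_map(record: GenomeRecord) -> dict[int, dict[str, list[int]]]:
    """Positions of every start (ATG) and stop (TAA/TAG/TGA) codon per frame.

    Returns ``{frame: {"starts": [...], "stops": [...]}}`` for forward frames
    1-3, each list sorted ascending, positions 1-based.  A sequence shorter
    than one codon yields empty lists.
    """
    seq = record.sequence
    out = {f: {"starts": [], "stops": []} for f in (1, 2, 3)}
    for m in re.finditer("(?=(ATG))", seq):
        out[m.start() % 3 + 1]["starts"].append(m.start() + 1)
    for m in re.finditer("(?=(TAA|TAG|TGA))", seq):
        out[m.start() % 3 + 1]["stops"].append(m.start() + 1)
    return out


def _scan_forward_orfs(seq: str, min_aa: int, strand: str) -> list[OrfAnnotation]:
    """Maximal first-AUG-to-stop ORFs on ``seq`` read left to right."""
    n = len(seq)
    orfs: list[OrfAnnotation] = []
    for offset in range(3):
        frame = offset + 1
        atg: int | None = None  # 0-based codon start of 5'-most AUG since last stop
        for i in range(offset, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if atg is not None:
                    orf = OrfAnnotation(atg + 1, i + 3, frame, strand)
                    if orf.aa_length >= min_aa:
                        orfs.append(orf)
                    atg = None
            elif codon == START_CODON and atg is None:
                atg = i
    return orfs


def find_orfs(
    record: GenomeRecord,
    min_aa: int = 100,
    strands: str = "+",
    all_starts: bool = False,
) -> list[OrfAnnotation]:
    """Every maximal ORF with at least ``min_aa`` encoded residues.

    The 5'-most AUG of each stop-bounded region defines the ORF (the rule
    matching a genome map read off a codon plot); ``all_starts=True`` instead
    enumerates one ORF per downstream AUG as well.  ``strands`` is ``"+"`` or
    ``"both"``.  Results are sorted by descending nucleotide length, ties by
    ascending start coordinate.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = record.sequence
    orfs = list(_scan_orfs_dispatch(seq, min_aa, "+", all_starts))
    if strands == "both":
        rc = str(Seq(seq).reverse_complement())
        n = len(seq)
        for orf in _scan_orfs_dispatch(rc, min_aa, "-", all_starts):
            # map the reverse-complement span back onto forward coordinates
            orfs.append(
                OrfAnnotation(n - orf.end + 1, n - orf.start + 1, orf.frame, "-")
            )
    elif strands != "+":
        raise ValueError(f"strands must be '+' or 'both', got {strands!r}")
    orfs.sort(key=lambda o: (-o.nt_length, o.start))
    return orfs


def _scan_orfs_dispatch(seq, min_aa, strand, all_starts):
    if not all_starts:
        return _scan_forward_orfs(seq, min_aa, strand)
    # downstream-AUG enumeration: one ORF per AUG sharing a stop
    n = len(seq)
    orfs = []
    for offset in range(3):
        frame = offset + 1
        pending: list[int] = []
        for i in range(offset, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                for a in pending:
                    orf = OrfAnnotation(a + 1, i + 3, frame, strand)
                    if orf.aa_length >= min_aa:
                        orfs.append(orf)
                pending = []
            elif codon == START_CODON:
                pending.append(i)
    return orfs


def translate_orf(record: GenomeRecord, orf: OrfAnnotation) -> str:
    """Standard-code translation of the ORF, excluding the terminal stop.

    Raises :class:`TranslationError` if the span does not end on a stop codon
    or contains an internal in-frame stop.
    """
    nt = record.subseq(orf.start, orf.end)
    if orf.strand == "-":
        nt = str(Seq(nt).reverse_complement())
    if nt[-3:] not in STOP_CODONS:
        raise TranslationError(
            f"ORF {orf.start}..{orf.end} does not end on a stop codon"
        )
    aa = str(Seq(nt).translate(table=1))
    if "*" in aa[:-1]:
        raise TranslationError(
            f"ORF {orf.start}..{orf.end} has an internal stop at codon "
            f"{aa.index('*') + 1}"
        )
    return aa[:-1]


def _overlap(a: OrfAnnotation, b: OrfAnnotation) -> bool:
    return a.start <= b.end and b.start <= a.end


def detect_dicistronic(
    orfs: Sequence[OrfAnnotation],
    genome_length: int,
    cfg: DetectConfig | None = None,
) -> DicistronicArchitecture:
    """Select the two longest non-overlapping forward ORFs and partition.

    The pair maximizing total coding length wins; ties are broken by the
    smaller ORF1 start, then the smaller ORF2 start.  A remaining exact tie
    between distinct pairs is reported as ambiguous.  The presence of any
    reverse-strand ORF longer than ``cfg.large_orf_min_nt`` is recorded as a
    flag (it argues against a +ssRNA di-cistronic reading), not a failure.
    """
    cfg = cfg or DetectConfig()
    fwd = [o for o in orfs if o.strand == "+"]
    rev_flag = any(
        o.nt_length >= cfg.large_orf_min_nt for o in orfs if o.strand == "-"
    )
    if len(fwd) < 2:
        raise NotDicistronicError(
            f"need two forward ORFs, found {len(fwd)}"
        )
    best: tuple | None = None
    for i, a in enumerate(fwd):
        for b in fwd[i + 1 :]:
            if _overlap(a, b):
                continue
            first, second = (a, b) if a.start < b.start else (b, a)
            key = (-(a.nt_length + b.nt_length), first.start, second.start)
            if best is None or key < best[0]:
                best = (key, first, second, False)
            elif key == best[0] and (first, second) != (best[1], best[2]):
                best = (key, best[1], best[2], True)
    if best is None:
        raise NotDicistronicError("no two forward ORFs are non-overlapping")
    key, orf1, orf2, tied = best
    if tied:
        raise AmbiguousArchitectureError(
            "multiple ORF pairs tie for total length and position",
            candidates=fwd,
        )
    if orf2.end > genome_length:
        raise CoordinateError("ORF exceeds stated genome length")
    return DicistronicArchitecture(
        genome_length=genome_length,
        utr5=Span(1, orf1.start - 1),
        orf1=orf1,
        igr=Span(orf1.end + 1, orf2.start - 1),
        orf2=orf2,
        utr3=Span(orf2.end + 1, genome_length),
        reverse_large_orf=rev_flag,
    )


def segment_report(arch: DicistronicArchitecture) -> SegmentReport:
    """Segment lengths plus coding/non-coding percentages (1 decimal)."""
    coding_nt = arch.orf1.nt_length + arch.orf2.nt_length
    coding = round(100.0 * coding_nt / arch.genome_length, 1)
    noncoding = round(100.0 * (arch.genome_length - coding_nt) / arch.genome_length, 1)
    return SegmentReport(
        lengths=arch.segment_lengths(),
        coding_fraction=coding,
        noncoding_fraction=noncoding,
        orf1_aa=arch.orf1.aa_length,
        orf2_aa=arch.orf2.aa_length,
    )


# ---------------------------------------------------------------------------
# In-silico PCR


@dataclass(frozen=True)
class Amplicon:
    start: int  # 5' end of the sense primer footprint
    end: int  # 3' end of the antisense primer footprint
    length: int


@dataclass(frozen=True)
class AmpliconResult:
    """All predicted products for one primer pair.

    ``primary`` spans the 5'-most sense site to the 3'-most compatible
    antisense site; ``ambiguous`` is set when more than one product exists.
    ``primary is None`` means no product (not an error — the template simply
    lacks one or both primer sites).
    """

    products: tuple[Amplicon, ...]
    primary: Amplicon | None
    ambiguous: bool


def _primer_regex(primer: str) -> re.Pattern:
    """Exact-match regex; degenerate IUPAC bases expand to their base sets."""
    primer = primer.upper().replace("U", "T")
    parts = []
    for ch in primer:
        bases = ambiguous_dna_values.get(ch)
        if bases is None:
            raise ValueError(f"invalid primer base {ch!r}")
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("(?=(" + "".join(parts) + "))")


def insilico_amplicon(
    record: GenomeRecord, sense_primer: str, antisense_primer: str
) -> AmpliconResult:
    """Predict PCR products from exact primer matches.

    The sense primer is matched on the forward strand; the antisense primer
    binds the forward strand where its reverse complement occurs.  Product
    length includes both primer footprints.
    """
    if len(sense_primer) < 10 or len(antisense_primer) < 10:
        raise ValueError("primers must be at least 10 nt")
    seq = record.sequence
    fwd_len = len(sense_primer)
    sense_sites = [m.start() + 1 for m in _primer_regex(sense_primer).finditer(seq)]
    rc = str(Seq(antisense_primer.upper().replace("U", "T")).reverse_complement())
    anti_sites = [
        (m.start() + 1, m.start() + len(antisense_primer))
        for m in _primer_regex(rc).finditer(seq)
    ]
    products = []
    for s in sense_sites:
        for a_start, a_end in anti_sites:
            if a_start >= s + fwd_len:  # antisense footprint 3' of sense footprint
                products.append(Amplicon(s, a_end, a_end - s + 1))
    if not products:
        return AmpliconResult((), None, False)
    start = min(p.start for p in products)
    end = max(p.end for p in products if p.start == start)
    primary = Amplicon(start, end, end - start + 1)
    return AmpliconResult(tuple(products), primary, len(products) > 1)
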