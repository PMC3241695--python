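"""Conserved-motif scanning and polyprotein cleavage annotation.

Picornavirus-like replicase polyproteins carry a conserved ordering of
replication domains — 2C-like helicase, one or more VPg peptides, 3C-like
cysteine protease, 3D-like RNA-dependent RNA polymerase (Hel-(VPg)x-Pro-Pol).
This module scans translated ORFs for a catalogue of short conserved motifs,
verifies that module order, detects the tandem VPg repeat, and cuts the
polyprotein into mature peptides according to a cleavage scheme.

Motif patterns are fixed-length with per-position alternative sets, written
like ``[QH]CAIGLFVKD``: every position is either a single residue or a
bracketed set.  There are no gaps or quantifiers — all catalogued motifs are
fixed length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .errors import CleavageSchemeError, PatternError

AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class MotifPattern:
    """A named fixed-length motif with per-position alternatives."""

    name: str
    region: str  # helicase | VPg | protease | polymerase | capsid | 2A
    pattern: str
    expected_aa_position: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "_positions", parse_pattern(self.pattern))
        if len(self._positions) < 2:
            raise PatternError(f"pattern {self.pattern!r} shorter than 2 positions")

    @property
    def positions(self) -> tuple[frozenset, ...]:
        return self._positions

    def __len__(self) -> int:
        return len(self._positions)


@dataclass(frozen=True)
class MotifHit:
    """One occurrence of a pattern on a polyprotein (1-based aa coordinates)."""

    name: str
    region: str
    aa_start: int
    matched: str
    position_confirmed: bool = False


def parse_pattern(pattern: str) -> tuple[frozenset, ...]:
    """``"[QH]CA"`` -> ({Q,H}, {C}, {A}).  Rejects empty sets and bad residues."""
    positions: list[frozenset] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            j = pattern.find("]", i)
            if j < 0:
                raise PatternError(f"unclosed '[' in {pattern!r}")
            alts = pattern[i + 1 : j]
            if not alts:
                raise PatternError(f"empty alternative set in {pattern!r}")
            i = j + 1
        else:
            alts = ch
            i += 1
        for a in alts:
            if a not in AA:
                raise PatternError(f"invalid residue {a!r} in {pattern!r}")
        positions.append(frozenset(alts))
    return tuple(positions)


def _pattern_regex(pat: MotifPattern) -> re.Pattern:
    body = "".join(
        s if len(s) == 1 else "[" + s + "]"
        for s in ("".join(sorted(p)) for p in pat.positions)
    )
    return re.compile("(?=(" + body + "))")


def scan_motifs(
    protein: str, catalogue: Sequence[MotifPattern]
) -> list[MotifHit]:
    """All occurrences of every catalogue pattern, sorted by position.

    Overlapping occurrences are all reported.  A hit at a pattern's
    ``expected_aa_position`` is marked ``position_confirmed``.
    """
    if not protein:
        raise ValueError("protein must be non-empty")
    hits: list[MotifHit] = []
    for pat in catalogue:
        for m in _pattern_regex(pat).finditer(protein):
            start = m.start() + 1
            hits.append(
                MotifHit(
                    name=pat.name,
                    region=pat.region,
                    aa_start=start,
                    matched=m.group(1),
                    position_confirmed=(pat.expected_aa_position == start),
                )
            )
    hits.sort(key=lambda h: (h.aa_start, h.name))
    return hits


def filter_short_motifs(
    hits: Sequence[MotifHit],
    max_short_len: int = 3,
    window: int = 50,
) -> tuple[list[MotifHit], list[MotifHit]]:
    """Split hits into context-supported and standalone short-motif hits.

    Motifs of ``max_short_len`` residues or fewer match frequently by chance;
    they are kept only within ``window`` residues of a longer hit of the same
    region, or when they sit at their catalogued expected position.  Returns
    ``(kept, standalone)``.
    """
    long_by_region: dict[str, list[MotifHit]] = {}
    for h in hits:
        if len(h.matched) > max_short_len:
            long_by_region.setdefault(h.region, []).append(h)
    kept, standalone = [], []
    for h in hits:
        if len(h.matched) > max_short_len or h.position_confirmed:
            kept.append(h)
            continue
        anchors = long_by_region.get(h.region, [])
        if any(abs(a.aa_start - h.aa_start) <= window for a in anchors):
            kept.append(h)
        else:
            standalone.append(h)
    return kept, standalone


@dataclass(frozen=True)
class OrderVerdict:
    """Result of the Hel-(VPg)x-Pro-Pol ordering check."""

    ordered: bool
    present_regions: tuple[str, ...]
    missing_regions: tuple[str, ...]
    npgp_found: bool


_MODULE_ORDER = ("helicase", "VPg", "protease", "polymerase")


def check_module_order(hits: Iterable[MotifHit]) -> OrderVerdict:
    """Verify helicase < VPg < protease < polymerase along the polyprotein.

    The comparison uses the 3'-most helicase hit and the 5'-most hit of each
    downstream region; absent regions are skipped and reported.  The verdict
    is independent of the input order of ``hits``.  The picornavirus 2A motif
    NPGP (absent from genuine di-cistronic replicases of this kind) is
    reported separately.
    """
    hits = list(hits)
    bounds: dict[str, int] = {}
    for region in _MODULE_ORDER:
        pos = [h.aa_start for h in hits if h.region == region]
        if pos:
            bounds[region] = max(pos) if region == "helicase" else min(pos)
    present = tuple(r for r in _MODULE_ORDER if r in bounds)
    missing = tuple(r for r in _MODULE_ORDER if r not in bounds)
    seq = [bounds[r] for r in present]
    ordered = all(a < b for a, b in zip(seq, seq[1:]))
    npgp = any(h.region == "2A" for h in hits)
    return OrderVerdict(ordered, present, missing, npgp)


@dataclass(frozen=True)
class TandemRepeat:
    """A maximal run of >= 2 consecutive unit matches."""

    unit_name: str
    starts: tuple[int, ...]


def find_tandem_repeat(
    protein: str, unit: MotifPattern, max_gap: int = 0
) -> list[TandemRepeat]:
    """Maximal runs of unit matches whose starts differ by len(unit) +- max_gap."""
    if len(unit) < 3:
        raise ValueError("repeat unit must be at least 3 residues")
    starts = [m.start() + 1 for m in _pattern_regex(unit).finditer(protein)]
    runs: list[TandemRepeat] = []
    i = 0
    while i < len(starts):
        run = [starts[i]]
        j = i
        while j + 1 < len(starts):
            delta = starts[j + 1] - run[-1]
            if abs(delta - len(unit)) <= max_gap:
                run.append(starts[j + 1])
                j += 1
            elif delta < len(unit) - max_gap:
                j += 1  # overlapping re-match inside the run; skip it
            else:
                break
        if len(run) >= 2:
            runs.append(TandemRepeat(unit.name, tuple(run)))
            i = j + 1
        else:
            i += 1
    return runs


# ---------------------------------------------------------------------------
# Cleavage schemes


@dataclass(frozen=True)
class CleavageSite:
    """A cut between residue ``position`` (P1) and ``position + 1`` (P1')."""

    position: int
    site_pattern: str | None = None  # e.g. "RAFGF/SSPPD", documentation only
    tentative: bool = False


@dataclass(frozen=True)
class CleavageScheme:
    name: str
    sites: tuple[CleavageSite, ...]
    peptide_names: tuple[str, ...]

    def __post_init__(self):
        if len(self.peptide_names) != len(self.sites) + 1:
            raise CleavageSchemeError(
                f"scheme {self.name!r}: {len(self.sites)} cuts need "
                f"{len(self.sites) + 1} peptide names"
            )
        cuts = [s.position for s in self.sites]
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise CleavageSchemeError(
                f"scheme {self.name!r}: cut positions must be strictly increasing"
            )


@dataclass(frozen=True)
class MaturePeptide:
    name: str
    start: int
    end: int

    @property
    def aa_length(self) -> int:
        return self.end - self.start + 1


def annotate_cleavage(protein: str, scheme: CleavageScheme) -> list[MaturePeptide]:
    """Cut the polyprotein into contiguous mature peptides.

    Peptide lengths always sum to the polyprotein length.
    """
    n = len(protein)
    cuts = [s.position for s in scheme.sites]
    if cuts and (cuts[0] < 1 or cuts[-1] >= n):
        raise CleavageSchemeError(
            f"scheme {scheme.name!r}: cuts {cuts} outside protein of {n} aa"
        )
    bounds = [0] + cuts + [n]
    return [
        MaturePeptide(name, bounds[i] + 1, bounds[i + 1])
        for i, name in enumerate(scheme.peptide_names)
    ]


# ---------------------------------------------------------------------------
# Shipped catalogue and cleavage presets (HalV-like di-cistronic genome)

# The VPg unit is printed ambiguously in slash notation; the shipped pattern is
# the per-position union over both printed readings of the 11-aa unit, so both
# tandem copies match it.  No single-copy intent is assumed.
VPG_UNIT_PATTERN = "[HQS]C[AL][IM][GN][KL][FH][SV][KL]D[LQS]"

DEFAULT_CATALOGUE: tuple[MotifPattern, ...] = (
    MotifPattern("GKS", "helicase", "GKS", 522),
    MotifPattern("YDDF", "helicase", "YDDF", 575),
    MotifPattern("KATLSEK", "helicase", "KATLSEK", 608),
    MotifPattern("VPg-unit", "VPg", VPG_UNIT_PATTERN, 1116),
    MotifPattern("GDCG", "protease", "GDCG", 1253),
    MotifPattern("ILGIHGA", "protease", "ILGIHGA", 1270),
    MotifPattern("KDERR", "polymerase", "KDERR", 1488),
    MotifPattern("VGINPDSAEW", "polymerase", "VGINPDSAEW", 1543),
    MotifPattern("LGDY", "polymerase", "LGDY", 1590),
    MotifPattern("PSG", "polymerase", "PSG", 1634),
    MotifPattern("YGDD", "polymerase", "YGDD", 1676),
    MotifPattern("FLKR", "polymerase", "FLKR", 1727),
    MotifPattern("APL", "polymerase", "APL", 1741),
    MotifPattern("NPGP", "2A", "NPGP", None),
    MotifPattern("GRLI", "capsid", "GRLI", None),
    MotifPattern("LRIPF", "capsid", "LRIPF", None),
    MotifPattern("FGFSSP", "capsid", "FGFSSP", None),
    MotifPattern("DEM", "capsid", "DEM", None),
    MotifPattern("YWAGSI", "capsid", "YWAGSI", None),
    MotifPattern("VATPFHAGRLVLAYVP", "capsid", "VATPFHAGRLVLAYVP", None),
    MotifPattern("VWD", "capsid", "VWD", None),
    MotifPattern("GE", "capsid", "GE", None),
    MotifPattern("DDFSF", "capsid", "DDFSF", None),
)

# Cleavage presets.  Sites were estimated (in the source analysis) by
# alignment, which is out of scope here; they ship as fixed data.  The VP2/VP4
# boundary is tentative (Q/T at 262/263).
CLEAVAGE_PRESETS: dict[str, CleavageScheme] = {
    "halv-orf1": CleavageScheme(
        "halv-orf1",
        (CleavageSite(1317, "Q/T"),),
        ("Hel-VPg-3C precursor", "3D polymerase"),
    ),
    "halv-orf2": CleavageScheme(
        "halv-orf2",
        (
            CleavageSite(262, "Q/T", tentative=True),
            CleavageSite(339, "RAFGF/SSPPD"),
            CleavageSite(665, "ESMQ/DPY"),
        ),
        ("VP2", "VP4", "VP3", "VP1"),
    ),
    "halv-orf2-major": CleavageScheme(
        "halv-orf2-major",
        (CleavageSite(339, "RAFGF/SSPPD"), CleavageSite(665, "ESMQ/DPY")),
        ("VP2+VP4", "VP3", "VP1"),
    ),
}


def read_catalogue(path: str | Path) -> list[MotifPattern]:
    """Catalogue TSV: name <tab> region <tab> pattern [<tab> expected_position]."""
    patterns = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise PatternError(f"{path}:{lineno}: expected name/region/pattern")
        expected = int(parts[3]) if len(parts) > 3 and parts[3] else None
        patterns.append(MotifPattern(parts[0], parts[1], parts[2], expected))
    return patterns


def write_catalogue(catalogue: Iterable[MotifPattern], path: str | Path) -> None:
    lines = ["#name\tregion\tpattern\texpected_position"]
    for p in catalogue:
        pos = "" if p.expected_aa_position is None else str(p.expected_aa_position)
        lines.append(f"{p.name}\t{p.region}\t{p.pattern}\t{pos}")
    Path(path).write_text("\n".join(lines) + "\n")
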