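"""Synthetic sequence generation with known ground truth.

Two generators make every pipeline stage testable without downloads:

* host-labeled control panels — first-order Markov sequences whose stationary
  mononucleotide frequencies and dinucleotide observed/expected ratios hit
  prescribed, host-typical targets (CpG/UpA suppression in mammal- and
  plant-like classes, none in insect/fish-like classes);
* fully specified di-cistronic genomes — 5'UTR / ORF1 / IGR / ORF2 / 3'UTR
  with conserved motifs embedded at known amino-acid positions, so the
  annotators can be checked by exact round trip.

A note on the chain construction: a lone suppressed dinucleotide (say CpG
O/E = 0.45 with every other ratio 1) is *infeasible* for a stationary chain
with fixed mononucleotide margins — the row and column sums of the joint
dinucleotide table must both equal the margins, which forces compensating
excesses elsewhere (real genomes show exactly this, e.g. TpG/CpA excess
alongside CpG suppression).  Requested (mono, O/E) targets are therefore
projected onto the nearest self-consistent joint table by iterative
proportional fitting (IPF) before the transition matrix is built; the spec
factory additionally calibrates the named dials so the projected table still
attains the requested CpG/UpA values exactly.  The resulting chain has
stationary marginals exactly equal to the target mononucleotide vector and
realized O/E exactly equal to the stored targets; only sampling noise
remains.  When the requested table is already consistent the construction
reduces to the plain product form P(y|x) proportional to f(y)*rho(x,y).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .errors import InfeasibleSpecError, RetryLimitError
from .orf_annotator import (
    DicistronicArchitecture,
    OrfAnnotation,
    Span,
    detect_dicistronic,
    find_orfs,
)
from .polyprotein_annotator import MotifHit
from .seqio import GenomeRecord
from .composition_nca import NUCLEOTIDES

STOPS = ("TAA", "TAG", "TGA")

_CODON_FOR: dict[str, str] = {}
for codon, aa in sorted(unambiguous_dna_by_id[1].forward_table.items()):
    _CODON_FOR.setdefault(aa, codon)  # lexicographically first codon per residue


# ---------------------------------------------------------------------------
# Host composition specs and the Markov chain


@dataclass(frozen=True)
class HostCompositionSpec:
    """Composition targets for one host class.

    ``oe`` is the full, self-consistent 4x4 observed/expected table (build
    specs through :func:`host_spec` to get consistency from named dials).
    ``length`` is either a fixed int or an inclusive ``(lo, hi)`` range
    sampled per sequence.
    """

    label: str
    mono: tuple[float, float, float, float]
    oe: tuple  # 4x4 nested tuple
    length: int | tuple[int, int] = 3000
    n: int = 1

    def __post_init__(self):
        m = np.asarray(self.mono, dtype=float)
        if m.shape != (4,) or not np.isclose(m.sum(), 1.0):
            raise InfeasibleSpecError("mono frequencies must be 4 values summing to 1")
        if (m < 0).any():
            raise InfeasibleSpecError("mono frequencies must be non-negative")
        r = np.asarray(self.oe, dtype=float)
        if r.shape != (4, 4) or (r < 0).any():
            raise InfeasibleSpecError("oe must be a non-negative 4x4 table")
        if self.n < 1:
            raise InfeasibleSpecError("class size must be >= 1")

    @property
    def mono_array(self) -> np.ndarray:
        return np.asarray(self.mono, dtype=float)

    @property
    def oe_array(self) -> np.ndarray:
        return np.asarray(self.oe, dtype=float)


def _ipf_joint(mono: np.ndarray, rho: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Project f_x f_y rho_xy onto joint tables with both margins equal to f."""
    M = np.outer(mono, mono) * rho
    if (M.sum(axis=1) == 0).any():
        bad = NUCLEOTIDES[int(np.argmin(M.sum(axis=1)))]
        raise InfeasibleSpecError(f"row {bad} of the dinucleotide table has zero mass")
    for _ in range(500):
        r = M.sum(axis=1)
        M *= np.where(r > 0, mono / np.where(r > 0, r, 1.0), 0.0)[:, None]
        c = M.sum(axis=0)
        M *= np.where(c > 0, mono / np.where(c > 0, c, 1.0), 0.0)[None, :]
        if np.abs(M.sum(axis=1) - mono).max() < tol:
            break
    return M


def consistent_oe(
    mono: Sequence[float], dials: dict[str, float], iterations: int = 60
) -> np.ndarray:
    """Self-consistent 4x4 O/E table attaining the named dinucleotide dials.

    ``dials`` maps pairs like ``"CG"`` or ``"TA"`` to target O/E values; all
    other ratios start at 1 and absorb the compensation.  A small fixed point
    re-adjusts the dialed entries after each IPF projection so the final
    table attains the requested values exactly (to numerical precision).
    """
    f = np.asarray(mono, dtype=float)
    idx = {c: i for i, c in enumerate(NUCLEOTIDES)}
    rho = np.ones((4, 4))
    targets = {}
    for pair, value in dials.items():
        i, j = idx[pair[0]], idx[pair[1]]
        rho[i, j] = value
        targets[(i, j)] = value
    for _ in range(iterations):
        Q = _ipf_joint(f, rho)
        realized = Q / np.outer(f, f)
        err = 0.0
        for (i, j), value in targets.items():
            if value > 0:
                err = max(err, abs(realized[i, j] - value))
                rho[i, j] *= value / realized[i, j]
        if err < 1e-10:
            break
    return Q / np.outer(f, f)


def host_spec(
    label: str,
    mono: Sequence[float],
    dials: dict[str, float] | None = None,
    length: int | tuple[int, int] = 3000,
    n: int = 1,
) -> HostCompositionSpec:
    """Build a HostCompositionSpec from mono frequencies and named O/E dials."""
    oe = consistent_oe(mono, dials or {})
    return HostCompositionSpec(
        label=label,
        mono=tuple(float(v) for v in mono),
        oe=tuple(tuple(float(v) for v in row) for row in oe),
        length=length,
        n=n,
    )


def markov_from_profile(spec: HostCompositionSpec) -> np.ndarray:
    """Row-stochastic 4x4 transition matrix realizing the spec's composition.

    The joint dinucleotide table f_x f_y rho_xy is projected to consistency
    by IPF (a no-op for already-consistent tables, e.g. all rho = 1, which
    yields the i.i.d. chain with every row equal to the mono vector) and
    divided by its row sums.
    """
    Q = _ipf_joint(spec.mono_array, spec.oe_array)
    rows = Q.sum(axis=1)
    if (rows <= 0).any():
        raise InfeasibleSpecError("zero-mass row in projected dinucleotide table")
    return Q / rows[:, None]


def stationary_distribution(matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (leading left eigvec)."""
    P = np.asarray(matrix, dtype=float)
    _check_stochastic(P)
    evals, evecs = np.linalg.eig(P.T)
    pi = np.real(evecs[:, np.argmin(np.abs(evals - 1.0))])
    pi = np.abs(pi)
    return pi / pi.sum()


def _check_stochastic(P: np.ndarray) -> None:
    if P.shape != (4, 4) or (P < -1e-12).any() or not np.allclose(P.sum(axis=1), 1.0):
        raise InfeasibleSpecError("transition matrix must be 4x4 row-stochastic")


def sample_sequence(
    matrix: np.ndarray, length: int, seed: int | np.random.Generator = 0
) -> str:
    """Draw one nucleotide string from the chain, starting at stationarity."""
    if length < 2:
        raise InfeasibleSpecError("length must be >= 2")
    P = np.asarray(matrix, dtype=float)
    _check_stochastic(P)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pi = stationary_distribution(P)
    return "".join(NUCLEOTIDES[i] for i in _sample_states(rng, P, pi, length))


def _sample_states(
    rng: np.random.Generator, P: np.ndarray, pi: np.ndarray, length: int
) -> list[int]:
    cums = [list(np.cumsum(row)) for row in P]
    u = rng.random(length)
    start_cum = list(np.cumsum(pi))
    state = bisect_right(start_cum, u[0] * start_cum[-1])
    state = min(state, 3)
    out = [state]
    for k in range(1, length):
        row = cums[state]
        state = min(bisect_right(row, u[k] * row[-1]), 3)
        out.append(state)
    return out


# ---------------------------------------------------------------------------
# Default host panel (class sizes mirror a 352-sequence picorna-like control
# set: mammal 117, insect 63, plant 167, fish 5; all sequences >= 3000 nt).
# The mono vectors and CpG/UpA dials are invented, documented simulation
# parameters chosen to reproduce the qualitative host signature: CpG (and
# UpA) suppression in mammal/plant classes, no CpG suppression and an AU-rich
# composition in the insect class, and a fish class close to the genome under
# study (AU 52.3%, CpG O/E > 1).

DEFAULT_PANEL_LENGTH: tuple[int, int] = (3000, 9600)


def default_host_specs() -> list[HostCompositionSpec]:
    return [
        host_spec("mammal", (0.24, 0.26, 0.26, 0.24), {"CG": 0.45, "TA": 0.60},
                  DEFAULT_PANEL_LENGTH, 117),
        host_spec("insect", (0.31, 0.19, 0.18, 0.32), {"CG": 1.05, "TA": 0.70},
                  DEFAULT_PANEL_LENGTH, 63),
        host_spec("plant", (0.28, 0.24, 0.21, 0.27), {"CG": 0.55, "TA": 0.65},
                  DEFAULT_PANEL_LENGTH, 167),
        host_spec("fish", (0.266, 0.274, 0.203, 0.257), {"CG": 1.00, "TA": 0.85},
                  DEFAULT_PANEL_LENGTH, 5),
    ]


def make_control_panel(
    specs: Sequence[HostCompositionSpec] | None = None, seed: int = 0
) -> tuple[list[GenomeRecord], dict[str, str]]:
    """Generate the labeled control panel; returns (records, id->label map)."""
    specs = list(specs) if specs is not None else default_host_specs()
    if len(specs) < 2:
        raise InfeasibleSpecError("a control panel needs at least 2 class specs")
    rng = np.random.default_rng(seed)
    records: list[GenomeRecord] = []
    labels: dict[str, str] = {}
    for spec in specs:
        P = markov_from_profile(spec)
        pi = stationary_distribution(P)
        for k in range(spec.n):
            if isinstance(spec.length, tuple):
                lo, hi = spec.length
                L = int(rng.integers(lo, hi + 1))
            else:
                L = int(spec.length)
            seq = "".join(
                NUCLEOTIDES[i] for i in _sample_states(rng, P, pi, L)
            )
            sid = f"{spec.label}_{k:03d}"
            records.append(
                GenomeRecord(sid, f"{sid} synthetic {spec.label}-like control",
                             seq, "RNA")
            )
            labels[sid] = spec.label
    return records, labels


def write_panel(
    records: Sequence[GenomeRecord],
    labels: dict[str, str],
    fasta_path: str | Path,
    labels_path: str | Path,
) -> None:
    from .seqio import write_fasta, write_labels

    write_fasta(records, fasta_path)
    write_labels(labels, labels_path)


# ---------------------------------------------------------------------------
# Di-cistronic genome builder


@dataclass(frozen=True)
class MotifPlacement:
    """A concrete residue string embedded at a known polyprotein position."""

    orf: int  # 1 or 2
    region: str
    name: str
    residues: str
    aa_start: int


@dataclass(frozen=True)
class GenomeSpec:
    """Fully specified di-cistronic genome with known ground truth."""

    utr5: int
    orf1_nt: int
    igr: int
    orf2_nt: int
    utr3: int
    motifs: tuple[MotifPlacement, ...] = ()
    background: HostCompositionSpec | None = None
    seed: int = 0
    max_retries: int = 10000
    record_id: str = "synthetic_genome"

    def __post_init__(self):
        for name, nt in (("orf1", self.orf1_nt), ("orf2", self.orf2_nt)):
            if nt % 3 != 0 or nt < 6:
                raise InfeasibleSpecError(
                    f"{name} length must be a multiple of 3 and >= 6 nt, got {nt}"
                )
        for seg, v in (("utr5", self.utr5), ("igr", self.igr), ("utr3", self.utr3)):
            if v < 0:
                raise InfeasibleSpecError(f"{seg} length must be >= 0")
        aa_lens = {1: self.orf1_nt // 3 - 1, 2: self.orf2_nt // 3 - 1}
        taken: dict[int, list[tuple[int, int]]] = {1: [], 2: []}
        for m in self.motifs:
            if m.orf not in (1, 2):
                raise InfeasibleSpecError(f"motif {m.name!r}: orf must be 1 or 2")
            lo, hi = m.aa_start, m.aa_start + len(m.residues) - 1
            if lo < 2 or hi > aa_lens[m.orf]:
                raise InfeasibleSpecError(
                    f"motif {m.name!r} at aa {lo}..{hi} outside ORF{m.orf} "
                    f"coding span 2..{aa_lens[m.orf]}"
                )
            for a, b in taken[m.orf]:
                if lo <= b and a <= hi:
                    raise InfeasibleSpecError(
                        f"motif {m.name!r} overlaps another placement in ORF{m.orf}"
                    )
            taken[m.orf].append((lo, hi))

    @property
    def genome_length(self) -> int:
        return self.utr5 + self.orf1_nt + self.igr + self.orf2_nt + self.utr3

    def truth_architecture(self) -> DicistronicArchitecture:
        o1s = self.utr5 + 1
        o1e = self.utr5 + self.orf1_nt
        o2s = o1e + self.igr + 1
        o2e = o2s + self.orf2_nt - 1
        return DicistronicArchitecture(
            genome_length=self.genome_length,
            utr5=Span(1, self.utr5),
            orf1=OrfAnnotation(o1s, o1e, (o1s - 1) % 3 + 1),
            igr=Span(o1e + 1, o2s - 1),
            orf2=OrfAnnotation(o2s, o2e, (o2s - 1) % 3 + 1),
            utr3=Span(o2e + 1, self.genome_length),
        )


@dataclass(frozen=True)
class BuiltGenome:
    record: GenomeRecord
    architecture: DicistronicArchitecture
    expected_hits: tuple[MotifHit, ...]
    proteins: dict


def _sample_codons(rng, P, pi, n_codons: int) -> list[str]:
    """Non-stop sense codons drawn from the background chain."""
    states = _sample_states(rng, P, pi, 3 * n_codons)
    codons = []
    for i in range(n_codons):
        codon = "".join(NUCLEOTIDES[s] for s in states[3 * i : 3 * i + 3])
        while codon in STOPS:
            codon = "".join(
                NUCLEOTIDES[min(bisect_right(list(np.cumsum(pi)), u * pi.sum()), 3)]
                for u in rng.random(3)
            )
        codons.append(codon)
    return codons


def reverse_translate(residues: str) -> str:
    """Deterministic coding sequence: lexicographically first codon per residue."""
    try:
        return "".join(_CODON_FOR[a] for a in residues)
    except KeyError as err:
        raise InfeasibleSpecError(f"cannot reverse-translate residue {err}") from err


def build_dicistronic_genome(spec: GenomeSpec) -> BuiltGenome:
    """Assemble a genome matching ``spec``; ground truth is exact by rejection.

    ORFs start with ATG, end with a stop drawn from the chain-free uniform
    stop set, contain no internal in-frame stop; motif residues are embedded
    by deterministic reverse translation; UTR/IGR segments come from the
    background chain.  The assembled genome is accepted only when the ORF
    annotator recovers exactly the specified architecture (this rejects, for
    example, an in-frame AUG in the 5'UTR or IGR that would extend an ORF),
    so detect_dicistronic(find_orfs(genome)) equals the spec by construction.
    """
    background = spec.background or host_spec(
        "uniform", (0.25, 0.25, 0.25, 0.25), {}
    )
    P = markov_from_profile(background)
    pi = stationary_distribution(P)
    rng = np.random.default_rng(spec.seed)
    truth = spec.truth_architecture()
    min_aa = min(truth.orf1.aa_length, truth.orf2.aa_length)

    def sample_segment(n: int) -> str:
        if n == 0:
            return ""
        if n == 1:
            return NUCLEOTIDES[min(bisect_right(list(np.cumsum(pi)), rng.random()), 3)]
        return "".join(NUCLEOTIDES[i] for i in _sample_states(rng, P, pi, n))

    def build_orf(orf_nt: int, placements: list[MotifPlacement]) -> str:
        n_codons = orf_nt // 3
        codons = _sample_codons(rng, P, pi, n_codons)
        codons[0] = "ATG"
        codons[-1] = STOPS[int(rng.integers(len(STOPS)))]
        for m in placements:
            cds = reverse_translate(m.residues)
            for j in range(len(m.residues)):
                codons[m.aa_start - 1 + j] = cds[3 * j : 3 * j + 3]
        return "".join(codons)

    for _ in range(spec.max_retries):
        seq = (
            sample_segment(spec.utr5)
            + build_orf(spec.orf1_nt, [m for m in spec.motifs if m.orf == 1])
            + sample_segment(spec.igr)
            + build_orf(spec.orf2_nt, [m for m in spec.motifs if m.orf == 2])
            + sample_segment(spec.utr3)
        )
        record = GenomeRecord(
            spec.record_id, f"{spec.record_id} synthetic di-cistronic genome",
            seq, "RNA"
        )
        try:
            orfs = find_orfs(record, min_aa=min_aa, strands="+")
            arch = detect_dicistronic(orfs, spec.genome_length)
        except Exception:
            continue
        if (
            (arch.orf1.start, arch.orf1.end) == (truth.orf1.start, truth.orf1.end)
            and (arch.orf2.start, arch.orf2.end) == (truth.orf2.start, truth.orf2.end)
        ):
            from .orf_annotator import translate_orf

            proteins = {
                1: translate_orf(record, arch.orf1),
                2: translate_orf(record, arch.orf2),
            }
            hits = tuple(
                MotifHit(m.name, m.region, m.aa_start, m.residues, False)
                for m in spec.motifs
            )
            return BuiltGenome(record, arch, hits, proteins)
    raise RetryLimitError(
        f"could not realize genome spec within {spec.max_retries} attempts"
    )


# ---------------------------------------------------------------------------
# A ready-made spec mimicking the studied genome's architecture: segment
# lengths 827 / 5451 / 118 / 3030 / 139 (total 9565 nt; ORF1 1816 aa, ORF2
# 1009 aa), catalogue motifs at their expected positions, and a background
# chain matching the studied genome's composition (A 26.6%, C 27.4%,
# G 20.3%, U 25.7%; UpA O/E 0.57, CpG O/E 1.1).

HALV_LIKE_BACKGROUND = dict(
    mono=(0.266, 0.274, 0.203, 0.257), dials={"TA": 0.57, "CG": 1.10}
)

_ORF1_PLACEMENTS = (
    ("helicase", "GKS", "GKS", 522),
    ("helicase", "YDDF", "YDDF", 575),
    ("helicase", "KATLSEK", "KATLSEK", 608),
    ("VPg", "VPg-copy1", "QCAIGLFVKDQ", 1116),
    ("VPg", "VPg-copy2", "SCLMNKHSLDQ", 1127),
    ("protease", "GDCG", "GDCG", 1253),
    ("protease", "ILGIHGA", "ILGIHGA", 1270),
    ("cleavage", "3C/3D-site", "QT", 1317),
    ("polymerase", "KDERR", "KDERR", 1488),
    ("polymerase", "VGINPDSAEW", "VGINPDSAEW", 1543),
    ("polymerase", "LGDY", "LGDY", 1590),
    ("polymerase", "PSG", "PSG", 1634),
    ("polymerase", "YGDD", "YGDD", 1676),
    ("polymerase", "FLKR", "FLKR", 1727),
    ("polymerase", "APL", "APL", 1741),
)

_ORF2_PLACEMENTS = (
    ("capsid", "GRLI", "GRLI", 50),
    ("capsid", "LRIPF", "LRIPF", 100),
    ("capsid", "VATPFHAGRLVLAYVP", "VATPFHAGRLVLAYVP", 150),
    ("cleavage", "VP2/VP4-site", "QT", 262),
    ("capsid", "RAFGF/SSPPD", "RAFGFSSPPD", 335),
    ("capsid", "YWAGSI", "YWAGSI", 420),
    ("capsid", "DEM", "DEM", 500),
    ("cleavage", "VP3/VP1-site", "ESMQDPY", 662),
    ("capsid", "VWD", "VWD", 700),
    ("capsid", "DDFSF", "DDFSF", 800),
)


def halv_mimic_spec(seed: int = 0) -> GenomeSpec:
    """Di-cistronic genome spec mirroring the studied genome's layout."""
    motifs = tuple(
        MotifPlacement(1, region, name, residues, pos)
        for region, name, residues, pos in _ORF1_PLACEMENTS
    ) + tuple(
        MotifPlacement(2, region, name, residues, pos)
        for region, name, residues, pos in _ORF2_PLACEMENTS
    )
    return GenomeSpec(
        utr5=827,
        orf1_nt=5451,
        igr=118,
        orf2_nt=3030,
        utr3=139,
        motifs=motifs,
        background=host_spec("halv-like", **HALV_LIKE_BACKGROUND),
        seed=seed,
        record_id="halv_mimic",
    )
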