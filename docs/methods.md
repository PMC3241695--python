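# Methods

This note documents the models, conventions and numerical choices behind
`dicistro`, and what the synthetic-data experiments do and do not
demonstrate.

## Coordinates and alphabets

All genome coordinates are 1-based inclusive on the forward (+) strand.
Sequences are normalized internally to the DNA alphabet {A,C,G,T,N}; RNA
input (U) is accepted, tagged, and can be re-displayed as U on output.  An
ORF's span runs from the A of its AUG through the last base of its stop
codon, so `nt_length` is divisible by 3 and `aa_length = nt_length/3 − 1`.
Minus-strand ORFs keep forward-strand spans (`start < end`) with a strand
flag.  N bases are retained in sequences but excluded from composition
counts: mononucleotides are counted over non-N positions and dinucleotides
over overlapping adjacent pairs with both bases non-N (linear windows; no
circularity is assumed).

## ORF finding and architecture detection

Within each reading frame, the 5′-most AUG of each stop-bounded region
defines the ORF; an alternative enumeration of downstream AUGs is available
behind the `all_starts` flag.  This matches how a genome map is read off a
codon plot, where the first AUG after a stop opens the frame.  ORF lists
are sorted by descending nucleotide length with ties broken by ascending
start, for determinism.

Di-cistronic detection selects the pair of non-overlapping forward ORFs
maximizing total coding length, with ties broken by the 5′ ORF's start and
then the 3′ ORF's start; an exact residual tie between distinct pairs is
reported as an ambiguity rather than silently resolved.  The two ORFs need
not share a frame.  A reverse-strand ORF longer than `large_orf_min_nt`
(default 300 nt) sets a flag — for a genuine +ssRNA di-cistronic genome
there should be none — but is not a failure.  "Large ORF" thresholds are
explicit because the biological notion is qualitative: `min_aa` defaults to
100 residues for candidate listing.  Translation uses the standard genetic
code (table 1) only.

In-silico PCR uses exact matching (no mismatch tolerance); degenerate
IUPAC bases in primers (R, V, …) match their expansion sets.  Product
length includes both primer footprints.  When several sense/antisense site
combinations exist, all products are returned and the result is flagged
ambiguous; the primary product spans the 5′-most sense site to the 3′-most
compatible antisense site.

## Motif language and catalogue

Motif patterns are fixed length with per-position alternative sets (no
gaps, no quantifiers) — every catalogued motif, including slash-notation
alternatives like Q/H, is fixed length.  The shipped catalogue carries the
replicase anchors with their expected positions on a 1816-aa ORF1
(helicase GKS@522, YDDF@575, KATLSEK@608; protease GDCG@1253,
ILGIHGA@1270; polymerase KDERR@1488, VGINPDSAEW@1543, LGDY@1590, PSG@1634,
YGDD@1676, FLKR@1727, APL@1741), the 11-aa VPg repeat unit, the 2A marker
NPGP, and capsid motifs without expected positions (GRLI, LRIPF, FGFSSP,
DEM, YWAGSI, VATPFHAGRLVLAYVP, VWD, GE, DDFSF).

The VPg tandem repeat is printed ambiguously in its source notation: the
two 11-aa copies, 11 residues apart, read differently at several positions
and the slash alternatives cannot be assigned per copy with certainty.  The
shipped unit pattern is therefore the per-position **union** over both
readings (`[HQS]C[AL][IM][GN][KL][FH][SV][KL]D[LQS]`), which matches either
copy; no single-copy intent is assumed.

Motifs of ≤ 3 residues (PSG, APL, GE, GKS) match by chance in long
polyproteins (for a 3-mer, roughly once per 8000 residues per exact
pattern, more with alternatives).  Reports therefore keep short-motif hits
only within ±50 residues of a longer hit of the same region, or when the
hit sits at its catalogued expected position; other occurrences are listed
separately as standalone.

The module-order verdict checks max(helicase) < min(VPg) < min(protease) <
min(polymerase) over the filtered hits, skipping and reporting absent
regions; it is invariant to hit-list order.

## Cleavage schemes

Cleavage sites are **data, not inference**: the sites shipped as presets
were estimated upstream by alignment of deduced amino-acid sequences, which
is out of scope here.  Presets: `halv-orf1` cuts the replicase at Q/T
1317/1318 (3C/3D junction; the downstream 3D product on a 1816-aa
polyprotein is 1318–1816 = 499 aa by inclusive arithmetic — one published
table prints 498 aa for this span, a discrepancy we note but do not
resolve); `halv-orf2` cuts the 1009-aa capsid polyprotein at 262/263
(VP2/VP4, explicitly tentative — the boundary is only constrained to
roughly residues 260–280), 339/340 (RAFGF/SSPPD) and 665/666 (ESMQ/DPY),
giving VP2 262, VP4 77, VP3 326 and VP1 344 aa; `halv-orf2-major` omits the
tentative cut.  Mature peptide lengths always sum to the polyprotein
length.

## Composition features and canonical discriminant analysis

Each sequence yields 4 mononucleotide frequencies, 16 dinucleotide
frequencies, and 16 observed/expected ratios
ρ(xy) = p(xy)/(p(x)·p(y)); ρ is flagged undefined when the expected
frequency is zero.  Feature vectors are 20-dimensional in a fixed order
(A,C,G,T; then AA…TT): either raw frequencies (default) or mononucleotides
plus O/E ratios.  Both modes are first-class because either is a defensible
reading of how such features have been used; the default is raw
frequencies.

The discriminant model is classical canonical discriminant analysis:
with class means m_c, grand mean m̄, pooled within-class scatter
W = Σ_c Σ_i (x_i − m_c)(x_i − m_c)ᵀ and between-class scatter
B = Σ_c n_c (m_c − m̄)(m_c − m̄)ᵀ, the canonical factors are the
generalized eigenvectors of B v = λ (W + εI) v, ordered by decreasing λ,
at most #classes − 1 of them.  Numerical choices:

* **Ridge ε = ridge·trace(W)/p** with `ridge = 1e−6` by default.  The
  frequency blocks each sum to 1 (rank deficiency) and a small class (the
  default panel has a 5-member fish class) can make W singular; the scaled
  ridge makes the eigensolve well-posed while perturbing well-conditioned
  problems negligibly.
* Eigenvectors are rescaled so the pooled within-class covariance in
  canonical space is the identity — Euclidean distance in canonical space
  is then Mahalanobis distance in feature space — and sign-fixed so the
  largest-magnitude loading is positive (determinism).
* **Equal class priors by default** (proportional optional).  With a
  5-member class among 352, proportional priors would nearly forbid
  assigning a query to the small class, defeating the purpose of including
  it as a control group.
* Classification is nearest class centroid in canonical space with a
  −log(prior) adjustment; with two classes the leading factor coincides
  with the classical Fisher direction W⁻¹(m₁ − m₂), which the tests verify.

Concordance (fraction of labeled sequences whose prediction matches the
label) defaults to resubstitution — the in-sample figure one gets when
fitting and evaluating on the same control panel — with leave-one-out
offered as the honest alternative; the tests check LOO does not exceed
resubstitution on average.

Confidence ellipses for canonical-factor pairs use the 2-D sample
covariance: semi-axes are sqrt(eigenvalue × χ²₂(level)) along the
covariance eigenvectors, centered on the class centroid.  Near-singular
covariances yield a flagged degenerate ellipse, not an error.

## Synthetic data: what it emulates, and what it does not

**Control panels.** Each host class is a first-order Markov chain whose
stationary composition matches the class spec.  A subtlety drives the
construction: a *lone* suppressed dinucleotide (e.g. CpG O/E = 0.45 with
all other ratios 1) is infeasible for a stationary chain with fixed
mononucleotide margins, because the joint dinucleotide table must have both
margins equal to the mononucleotide vector — suppression in one cell forces
compensating excesses elsewhere, exactly as real genomes show (TpG/CpA
excess alongside CpG suppression).  Requested (mono, ρ) targets are
therefore projected onto the nearest self-consistent joint table by
iterative proportional fitting (IPF); a small fixed point re-adjusts the
named dials so the projected table still attains the requested CpG/UpA
values exactly.  The transition matrix is the projected joint divided by
its row sums; its stationary distribution equals the target mononucleotide
vector exactly, and the realized O/E table equals the stored spec exactly,
leaving only sampling noise.  When the requested table is already
consistent the construction reduces to the plain product form
P(y|x) ∝ f(y)·ρ(xy) (all-ρ=1 gives the i.i.d. chain).  Sequences start
from the stationary distribution and are deterministic given a seed.

Default panel (class sizes 117 mammal / 63 insect / 167 plant / 5 fish,
lengths drawn uniformly from 3000–9600 nt, mirroring a 352-sequence
picorna-like control set of complete genomes and segments ≥ 3000 nt):
mammal mono (0.24, 0.26, 0.26, 0.24) with CpG 0.45, UpA 0.60; insect
(0.31, 0.19, 0.18, 0.32) — AU-rich, as insect dicistroviruses are — with
CpG 1.05, UpA 0.70; plant (0.28, 0.24, 0.21, 0.27) with CpG 0.55, UpA
0.65; fish (0.266, 0.274, 0.203, 0.257) — matching the composition of the
genome that motivated the fish class (AU 52.3%) — with CpG 1.00, UpA 0.85.
These profiles are invented, documented simulation parameters chosen to
reproduce the qualitative host signature; they are deliberately
well-separated in mononucleotide space.

Because the classes are well-separated homogeneous Markov chains, high
panel concordance demonstrates **parameter recovery** of the discriminant
machinery, not the real-world accuracy of host prediction: real control
sets are phylogenetically structured, internally heterogeneous (coding vs
non-coding composition), and overlap between host groups.  The published
concordance on the real 352-sequence control set is not reproducible here
and is not claimed.

**Genomes.** The builder assembles UTR/IGR segments from the background
chain and ORFs codon-wise (initial ATG; stop codon drawn uniformly from
TAA/TAG/TGA; internal stop codons rejected and redrawn; motif residues
reverse-translated with the lexicographically first codon per residue).
The assembled genome is accepted only when the package's own annotator
recovers exactly the specified architecture — this rejection step discards
e.g. an in-frame AUG in the 5′UTR that would extend ORF1 — with a retry cap
(default 10,000, then an error).  Ground truth is therefore exact by
construction, and the builder/annotator round trip is an identity the
tests exercise over randomized specs.  The mimic genome used throughout
tests and the acceptance script has segment lengths 827 / 5451 / 118 /
3030 / 139 (total 9565 nt; ORF1 1816 aa, ORF2 1009 aa) and a background
chain with mono (0.266, 0.274, 0.203, 0.257), UpA 0.57 and CpG 1.10.  The
coding constraints (forced ATG/stop, stop rejection, embedded motifs)
perturb the realized composition of ORF regions slightly, so the mimic's
measured G+C and O/E values sit near, not exactly at, the background
targets.

The generator does not simulate viral evolution (no substitution models,
selection, recombination), codon usage, secondary structure, or the actual
sequences of any published control set.

## Problem sizes and tolerances

Test and acceptance runs use: 500 random sequences for the counting-oracle
comparison (exact to 1e−12); 10 randomized 60×6 four-class problems for
the eigen-oracle comparison (1e−8); the full 352-sequence default panel
for concordance (threshold 0.95); 50 random genome specs for the
round-trip identity; and, per host class, counts pooled over 10 sequences
of 10,000 nt for Markov composition accuracy (tolerance ±0.05 per O/E
entry).  Pooling is a variance decision made up front: a single 10,000-nt
sequence gives each O/E entry a sampling sd of roughly 0.03–0.04, so the
max over 64 class/pair combinations would sit at the tolerance boundary by
chance; pooling ten sequences brings the sd an order of magnitude below
it.  The convergence test uses pooled lengths 3,000 / 10,000 / 100,000
with tolerances 0.08 / 0.05 / 0.02.

## Known limitations

* Primer matching is exact; real PCR tolerates mismatches, so amplicon
  prediction is conservative.
* The first-AUG ORF rule ignores translation-initiation context (Kozak-like
  signals, IRES-driven initiation); IGR-IRES structure is explicitly out of
  scope.
* Cleavage sites are user data; no de novo site inference is attempted.
* The discriminant model is linear with shared within-class covariance;
  strongly non-elliptical class structure would call for other methods.
* Host classes are closed-set: a query is always assigned to one of the
  trained classes, with no novelty detection.
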