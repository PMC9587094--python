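# Methods

This note documents the models implemented in `padckit`, the parameter
choices that matter, the numerical conventions, and what the synthetic
benchmark does and does not demonstrate.

## Family definition and classification

PadCs are recognised purely from sequence, by the presence of five
essential motifs in domain order:

| motif | pattern | domain context |
|---|---|---|
| NTS_CYS | `C` within the first 30 residues | chromophore-binding Cys of the N-terminal segment |
| DIP | `DIP` | GAF-domain cofactor pocket |
| PRXSF | `PR.SF` | PHY-domain tongue |
| DXLT | `D.LT` | wide turn opening the effector domain |
| GGDEF | `GG[DE]EF` | diguanylate-cyclase active site |

PadC-EALs must additionally carry, downstream of the GGDEF hit, an EAL
phosphodiesterase signature `E[AILV]L` (the aliphatic set {A,I,L,V} is a
fixed interpretation of "aliphatic hydrophobic"; the degenerate form
`E[AILV]F` is recognised separately) and the catalytic loop `DDFGTG`.
`pde_active` is False when only the degenerate EAF form is present or the
DDFGTG loop is missing.

Classification chains the required motifs: the leftmost hit of each motif
*downstream of the previous link* is used, so chance matches upstream of
their proper domain cannot derail the verdict. Wildcard pattern positions
match the ambiguity letter X; specific positions never do. The 30-residue
N-terminal window for the cysteine is a configurable default (the known
reference cysteine sits at residue 17; how far the Cys can drift in remote
homologs is unknown, so the window is exposed as a parameter). Removing any
required motif demotes a sequence to non-member with the failure listed in
`missing_motifs` — classification is monotone in the motif set.

## The linker-length statistic

The sensor–effector linker length is the number of residues **strictly
between** a conserved hydrophobic anchor residue at the end of the terminal
PHY helix and the D of the DXLT motif (both endpoints excluded):
`absolute_length = dxlt_index − anchor_index − 1`. The exclusive-endpoint
convention is fixed project-wide; it reproduces the 28-residue reference
value for the reference-length scaffold. Relative lengths subtract 28.

The anchor is located by alignment transfer only: an MSA containing a named
reference row plus the reference's 1-based anchor residue number defines an
anchor column, and the query residue in that column is the query's anchor.
A query gapped at that column raises an explicit "anchor not alignable"
error carrying the sequence id — such sequences are reported as failure
rows, never silently dropped, so prevalence denominators stay explicit. No
structure-free fallback heuristic is attempted.

Family binning uses mathematical modulo, so negative multiples of seven
land in `div7` (−7 mod 7 = 0); −4 and +2 have their own bins; everything
else is `other`.

The EAL-linker length of PadC-EALs uses the same exclusive convention
between the end of the GG(D/E)EF motif hit and the start of the EAL/EAF
hit. This is a motif-to-motif measure (the domain boundaries themselves are
not annotated), which is why the synthetic scaffold plants the GGDEF motif
at the C-terminal end of its domain block — the planted 25-residue
EAL-linker is then exactly recoverable.

## Heptad register model

Linker positions are assigned heptad slots *a*–*g* counted back from the
DXLT turn: under phase *p*, linker index *i* (0 adjacent to the anchor,
L−1 adjacent to the D of DXLT) occupies slot `(i − L − p) mod 7`, slot 0 =
*a*, slot 3 = *d*. Anchoring the frame at the effector-proximal end makes
phases comparable across linkers whose lengths differ by multiples of
seven; it also means prepending a heptad leaves every original position's
slot unchanged.

A phase's score is the fraction of its *a*/*d* slots occupied by
coiled-coil stabilisers. The stabiliser set is hydrophobics plus Asn,
{A,V,L,I,M,F,W,Y,N}; including Ala is a judgement call (it is a weak helix
former often found at core positions) and the set is a parameter. The top
phase is labelled **inhibiting** and the runner-up **stimulating** — these
labels follow the convention that the dark-state structure shows the
inhibited register; they are rank labels, not structure predictions. Ties
break toward the lower phase index, so the two calls are always distinct.

**Overwinding (−4 linkers).** A deletion of four residues is modelled as a
local overwinding in which ten residues span three helical turns instead of
the canonical 7 residues / 2 turns. In scoring terms this is a single +4
phase shift (equivalently a 3-residue retardation) applied to all positions
upstream of a breakpoint: for breakpoint *b*, positions *i < b* are slotted
at effective phase *p + 4*, positions *i ≥ b* at *p*. All breakpoints
0 ≤ *b* ≤ L−10 are scored exhaustively and the one maximising the best
per-phase score is returned, ties toward the smallest *b*. Note that the
breakpoint is only identifiable up to the interval between adjacent heptad
slots of the two frames (positions that are a/d slots under neither frame
cannot discriminate neighbouring breakpoints); the reported value is the
canonical smallest representative of that scoring-equivalent interval.

**Regulatory class.** div7 → `switch_capable` (both registers available),
−4 → `overwound_switch`, +2 → `impaired_cc` (periodicity broken), any other
length → `unknown`. This mapping summarises the observed biochemistry of
the length classes; it is deliberately a function of length alone.

## Similarity networks

Pairwise scores are optimal local (Smith–Waterman) affine-gap alignments
under BLOSUM62 with gap open 11 and extend 1 (a gap of length k costs
11 + k, the convention of common database-search tools); a global mode is
available for controlled experiments. Raw scores are converted to bitscores
with fixed gapped Karlin–Altschul parameters λ = 0.267, K = 0.041. No
compositional score adjustment is applied, so absolute bitscores can
deviate slightly from database-search tools on real data; the edge
threshold is therefore a parameter with default 380, compared strictly
(`bits > threshold`). Bitscores rather than E-values are used so query
length does not enter the edge weight. When directed score lists are
supplied, only the higher score of each unordered pair is kept (the
in-package scorer is symmetric by construction, making that reduction
idempotent). Components are labelled deterministically by their smallest
member id; concordance with linker families is reported as cluster purity
and Rand index.

## Distances, trees, consensus

Protein distances are Kimura-corrected p-distances,
d = −ln(1 − p − 0.2p²), with pairwise deletion (columns gapped in either
sequence are skipped for that pair) and a saturation clamp: pairs with
p ≥ 0.85 — or a non-positive logarithm argument — are set to d_max = 5.0
substitutions/site (configurable). A pair with no comparable columns is an
error naming the pair. The Kimura correction and neighbor joining are
deliberate, documented substitutions for the classic least-squares distance
pipeline: closed-form, fast, and adequate for the clustering-level
questions asked here; branch supports carry that caveat.

Delete-half jackknife replicates keep ⌊L/2⌋ distinct columns in original
order; replicate *i* draws from substream *i* of a single seeded generator,
so partial re-runs reproduce the same replicates. Trees are built by
neighbor joining (scikit-bio's implementation, whose tie handling is
deterministic — required for byte-identical reruns; slightly negative NJ
branch lengths are clamped to zero). The consensus is extended
majority-rule: bipartitions in more than half of the replicates are
retained, then remaining bipartitions are added greedily in order of
decreasing frequency (ties by size, then lexicographically) when compatible
with everything accepted. Supports are integer replicate counts attached as
internal node labels. Singleton and full-set "clades" are trivially
supported by every replicate, by convention. Outgroup rooting requires the
outgroup to form a clade of the unrooted tree (error otherwise) and places
the root at the midpoint of the separating edge.

## The synthetic benchmark

The generator emulates what matters to the analyses: multi-domain proteins
with all essential motifs at fixed scaffold offsets (blocks NTS 30,
PAS+GAF 320, PHY 150, linker 28+rel, GGDEF 160, and for PadC-EALs an
EAL-linker of 25 and EAL of 250 residues — order-of-magnitude realistic and
configurable; only the domain order is biologically fixed), linkers built
from heptad repeats with hydrophobics {L,I,V,M} at the planted *a*/*d*
slots and polar residues {S,T,Q,E,K,R,G} elsewhere, within-family
divergence by uniform point substitution at mutable sites (default rate
0.15 — the natural within-family diversity is not quantified anywhere, so
this is a free, exposed choice), and between-family divergence by
independent redraw of all mutable sites on the shared scaffold.

Three deliberate generator choices, and why:

* **The linker is immutable by default.** The natural families show extreme
  length and sequence constraint in the linker; freezing it makes the
  planted register phases and linker coordinates exactly recoverable at any
  divergence, which is what the recovery tests need. A `within_divergence`
  of 0 can be combined with a mutable-linker variant by editing the mask.
* **The linker polar alphabet excludes D, A and N.** A D could create a
  spurious in-linker DXLT match (corrupting the planted linker length); A
  and N are register stabilisers and would blur the planted phase truth.
* **Templates are scrubbed of chance motif matches** in mutable regions, so
  divergence-0 datasets are motif-clean. Point mutations applied afterwards
  can still create chance matches; the classifier's order chain tolerates
  them, but the PDE flag and EAL-linker length are only guaranteed exact at
  divergence 0.

The true alignment is trivial by construction (no indels outside the
linker): a fixed column frame with the linker right-aligned against the
DXLT turn and gap blocks for the EAL region of EAL-less homologs.

**What passing the benchmark shows — and does not.** Synthetic families are
cleanly separated (within-family identity ≈ 75%, between-family ≈ chance),
motifs never move, and the alignment is exact. Passing therefore
demonstrates correctness of the measurement machinery (coordinates,
scores, thresholds, resampling, consensus logic), not robustness to the
hazards of real data: alignment error around the anchor column, motif
drift beyond the fixed patterns, compositional bias, domain rearrangements,
or families whose between-family similarity falls near the 380-bit
threshold. Absolute bitscores on real sequences will also differ slightly
from database-search tools (no compositional adjustment), so real-data
thresholds may need adjusting.

## Problem sizes and determinism

Default study conditions used throughout the tests and the acceptance
script: six families at relative lengths {−7, −4, 0, +2, +7, +14}, ten
members each, within-divergence 0.15; similarity networks on all 60
sequences; consensus trees from 200 delete-half replicates (1000 for the
smaller EAL-loss scenario, whose three families plus chimera span 13
taxa). These sizes keep a full run of tests plus acceptance script in the
low minutes on a single CPU while leaving every support threshold far from
its decision boundary.

Every stochastic step (generation, mutation, jackknife) draws from spawned
substreams of a single user-supplied seed; reruns with the same
configuration produce byte-identical TSV and newick outputs.

## Known limitations

* Motifs are literal/regex patterns, not profiles; remote homologs with
  drifted motifs will be called non-members (no HMM search by design).
* The anchor requires a trusted MSA with a named reference; there is no
  alignment-free fallback.
* Register calling is occupancy counting, not an energetic or structural
  coiled-coil model; inhibiting/stimulating are rank labels.
* Bitscores approximate, but do not bit-match, database-search tools.
* NJ + Kimura distances replace the classic least-squares distance
  pipeline; supports on deep branches carry that substitution caveat.
* The overwinding breakpoint is reported as the canonical representative of
  a scoring-equivalent interval, not a unique residue position.
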