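# Methods

## Data model

A mitogenome is an ordered feature list over a fixed 39-symbol vocabulary:
13 protein genes (ND1–ND6, ND4L, COI–COIII, ATP6, ATP8, CYTB), 22 tRNAs
(one-letter amino-acid codes, with the leucine and serine isoacceptors
written L(UUR)/L(CUN) and S(UCN)/S(AGY)), the two rRNAs (12S, 16S), the
control region (CR) and the light-strand replication origin (OL).
Coordinates are 1-based inclusive on the circular genome (the GenBank
convention); strand H maps to orientation "+", L to "−". Duplicated
elements are suffixed in genome order (CR-1, CR-2), which keeps every
order a sequence over unique symbols. All order comparisons happen after
linearizing the circle at tRNA-Phe, the conventional first gene of the
vertebrate map; linearization at the same anchor is idempotent.

Control-region lengths may be absent (unresolvable tandem-repeat tracts);
such taxa are excluded from family means. Means are rounded to the nearest
integer with ties away from zero. In the packaged 31-taxon fixture four
taxa lack CR lengths, giving denominators of 10 (Chamaeleonidae),
9 (Agamidae) and 8 (Iguanidae).

## Arrangement characters

Five unordered discrete characters summarise the rearrangements:

| id | character | states | ancestral |
|----|-----------|--------|-----------|
| C1 | IQM cluster order | IQM, QIM | IQM |
| C2 | tRNA-Pro position | typical, inverted, translocated_3prime_CR | typical |
| C3 | CR copy | single, duplicate_ND5_ND6 | single |
| C4 | OL stem-loop | present, absent | present |
| C5 | tRNA-Pro anticodon | TGG, CGG | TGG |

Scoring from a linearized order: C1 is QIM iff Q precedes I; C2 is
translocated iff a CR-labelled element lies between tRNA-Thr and tRNA-Pro
(with the anchor at tRNA-Phe, "3′ of the CR" is the tail of the linear
order), otherwise inverted/typical by tRNA-Pro's strand; C3 is duplicate
iff a CR element lies between ND5 and ND6. C4 and C5 come from the OL call
and the anticodon call, which are sequence-level observations rather than
order properties. C2 is deliberately unordered — no
typical → inverted → translocated pathway is assumed — because the
draconine inversion and the agamine/chamaeleonid translocations are
treated as independent happenings. The different AT-rich flanking context
of the chamaeleonid translocation is reported by the CR annotator, not
folded into the character.

The generic order comparison uses a longest-common-subsequence over gene
names (ties broken by keeping 5′-most reference elements fixed, which
makes the diff deterministic), with orientation flips reported separately;
the breakpoint distance counts oriented circular adjacencies of one order
absent from the other, identifying an adjacency (a, b) with its
reverse-complement reading (−b, −a). With equal symbol sets it is
symmetric and zero exactly on identity.

## Parsimony reconstruction

Ancestral states are reconstructed with the Sankoff dynamic programme
(uniform unit costs by default; arbitrary matrices supported). "?" tips
contribute zero cost in every state; polytomies are handled natively by
the sum-over-children recursion. The number of most-parsimonious
reconstructions (MPRs) is counted exactly by a second pass over the
optimal-choice sets, and all MPRs are enumerated when the count is within
a bound (10^5 by default); beyond it, seeded weighted sampling is
available and flagged as approximate.

**Root polarization.** The canonical vertebrate arrangement serves as the
implicit outgroup: when the character's ancestral state is among the
cost-minimal root states, reconstructions are conditioned on it. This
never changes the minimum change count, only which of several tied
rootings is reported — e.g. for C1 (all acrodonts QIM, all iguanids IQM)
both root states are cost-minimal, and polarization selects the biological
reading with a single IQM → QIM gain on the Acrodonta stem rather than the
mirror-image QIM → IQM change on the iguanid stem.

**Event placement.** DELTRAN (changes delayed tipward) is the default
resolution because the placements of interest sit on subfamily stems;
ACCTRAN and an all-MPRs union are available. Every event is flagged
ambiguous unless it appears in every enumerated MPR. On the fixture tree
the C2 reconstruction needs 3 steps in 3 MPRs: the chamaeleonid
translocation is fixed on the family stem, while the agamine gain floats
between the Agaminae stem and the Agaminae+Draconinae stem (in the latter
case the draconine inversion proceeds from the translocated state); in
every MPR the translocated state arises exactly twice. `constrained_cost`
pins named internal nodes, quantifying alternatives: forcing a single
translocation origin in the agamid+chamaeleonid ancestor costs 4 steps
against the unconstrained 3.

A Fitch implementation (set-based, generalized to polytomies by the
majority-vote rule) provides an internal cross-check; the test suite
additionally verifies both against exhaustive enumeration over all
ancestral labelings.

## Control-region annotation

Motifs are IUPAC consensus strings matched by windowed Hamming distance on
the annotated heavy strand (a sequence N matches only a pattern N);
overlapping hits of one motif collapse to the lowest-mismatch, 5′-most
window. The default mismatch budget is ⌊pattern length / 5⌋. The shipped
default patterns are conventional vertebrate CR consensus approximations
(ETAS blocks carry the TACAT/ATGTA core, CSBs the C-rich cores) and are
fully configurable in YAML; every test plants its own motif instances, so
nothing depends on the defaults' biological fidelity. CSB II is searched
but its absence is an ordinary observation, never an error, since acrodont
CRs are not expected to conserve it.

Domains follow the three-domain convention: Domain 1 ends at the 3′-most
ETAS hit, Domain 2 at the 3′-most Box C/D/F hit, Domain 3 is the
remainder (CSBs, AT-rich arrays). Whether boundaries abut motifs or bisect
spacers is not standardized anywhere; ending each domain exactly at its
3′-most anchor is this package's documented choice. Missing anchor classes
fall back to fractional positions (0.30/0.65 of the CR) and flag the
partition low-confidence; anchors out of canonical order raise or flag,
per configuration.

Tandem repeats are found per period p from the self-match profile
s[i] = s[i+p]: maximal-scoring segments with score (1 − t) per match and
−t per mismatch (t = the identity threshold, 0.85 by default) have
identity ≥ t and end at the last informative match, so boundaries do not
drift into random background (~25% positional identity). Segments are then
made maximal by extending each edge in blocks of up to one period whose
identity — evaluated together with one period of accepted context — stays
above threshold; this reattaches noisy array edges while still rejecting
background. A region of match-length m spans m + p bases, i.e. (m + p)/p
copies (fractional); arrays re-found at a multiple of a smaller period are
suppressed (smallest period wins, ≥ 80% overlap). Defaults: min_copies 3,
min_identity 0.85, periods 10–200 in the full profile.

AT-rich arrays come in the two classes seen in chamaeleonid CRs:
AT_dinucleotide = maximal strictly alternating (AT)n/(TA)n runs;
AT_block = maximal concatenations of ≥ 2 blocks A^xT^y with x, y ≥ 2,
reported with their (x, y) profile. Regions under min_len (20 bp default)
are discarded; a region qualifying as both is labelled dinucleotide (the
stricter pattern). Each AT array is labelled 5′/3′/overlapping relative to
an embedded tRNA-Pro, reproducing the layout argument: block arrays 5′ of
tRNA-Pro, dinucleotide arrays mostly 3′ of it, with the Brookesia-style
exception carrying dinucleotide arrays on both sides.

## Gene-identification heuristics

*Translation* uses an explicitly written vertebrate mitochondrial table
(AGA/AGG stop, ATA Met, TGA Trp; start codons ATG/ATA/ATT/ATC/GTG).
A trailing T or TA is accepted as a stop completed by polyadenylation of
the mature mRNA and recorded as such; internal stops are reported as
validation failures rather than raised. The tests check all 64 codons and
random frames against Biopython's NCBI table 2 as an independent oracle.

*Anticodon extraction* scans for candidate anticodon stems — 5-bp arms
with ≥ 4 allowed pairs enclosing a 7-nt loop whose centre lies in the
middle third of the gene — and reports loop positions 3–5 of the best
candidate (most pairs, ties 5′-most), with confidence = pairs/5. This is a
bounded cloverleaf-anchored heuristic, not thermodynamic folding: it is
sufficient for anticodon readout on annotated genes, which is all the
analysis needs. Input length is restricted to the typical mitochondrial
tRNA range (55–95 nt, configurable); an unfoldable sequence yields an
undetermined call, not an exception.

*OL hairpin detection* looks for a perfect contiguous stem of ≥ min_stem
pairs (default 6) enclosing a 3–20 nt loop, reporting the longest stem
(ties 5′-most, then shortest loop). Watson–Crick plus G·T wobble pairs are
allowed in all stems (configurable); bulges are not, because perfect-stem
presence/absence is reproducible and the published presence/absence calls
give no finer criterion. Presence is monotone in min_stem. The fixture
stores the reported OL states directly (27 present, 4 absent) rather than
recomputing them from sequences it does not carry.

## Synthetic generators

All generators are deterministic under a seed and emit a ground-truth
manifest; regenerating with the same seed reproduces the data
bit-identically.

*Gene orders on a tree*: every lineage starts at the canonical order;
planted events (explicit, or sampled per character) change character
states on branches root-to-tip, and tip orders are built from the final
state vectors. In random mode derived states are drawn during the
root-to-tip pass so every event is a real state change. The default
low-density regime (one event per character on a random branch) makes
every planted event uniquely reconstructable, which is what the recovery
tests assert.

*Control regions*: Domain 1 (optional tandem array of a random unit —
64 bp × 8 copies with 2% point noise by default — then ETAS 1/2), Domain 2
(Boxes F, C, D), Domain 3 (CSBs, AT arrays, optional embedded tRNA-Pro a
200–400 bp spacer from the 3′ end), over i.i.d. background at configurable
GC content. Planted AT arrays are flanked by G/C guard bases so their
boundaries are exact; motif instances are concrete realizations of the
IUPAC patterns. Styles: chamaeleonid (block 5′ / dinucleotide 3′ of
tRNA-Pro), brookesia (dinucleotide both sides), plain (no AT arrays).

*tRNAs and WANCY regions*: cloverleaf-consistent sequences with exact
Watson–Crick stems and the planted anticodon at loop positions 3–5;
WANCY spacers with or without a planted perfect stem-loop, C-guarded
against outward stem extension. Both generators reject draws (reseeding
deterministically) until the corresponding analyzer recovers the plant,
closing the generator→analyzer loop by construction.

What the generators do **not** emulate: nucleotide substitution evolution
(no branch lengths, no rate variation — tree inference is out of scope),
Markov-structured background composition, degraded or partially annotated
genomes, and biologically accurate motif sequences. Passing recovery tests
therefore demonstrates algorithmic correctness on planted structure, not
annotation accuracy on real chamaeleonid CRs.

## Study fixture

The 31-taxon fixture is hand-entered: per-taxon family, accession, mtDNA
and CR lengths; the five character states; and the rooted topology with
labelled internal nodes (Iguanidae sister to Acrodonta; within Agamidae
Uromastycinae, then Leiolepidinae, then Amphibolurinae, Hydrosaurinae and
sister subfamilies Agaminae+Draconinae; within Chamaeleonidae Brookesia,
then Rieppeleon, a six-species Chamaeleo clade, and Trioceros grouping
with Calumma+Furcifer and then Kinyongia). Orderings inside the Chamaeleo
clade and among non-oplurine iguanids carry no character signal (identical
states throughout) and are nested arbitrarily; no event-mapping claim
depends on them. Fixture records carry nominal feature spans — orders, not
coordinates, are what the analyses compare. A cross-check enters the data
a second way: evolving the documented event set on the fixture topology
reproduces the hand-entered tip matrix exactly. All taxa except
*Acanthosaura armata* are entered with the usual TGG anticodon, the single
stated exception being its CGG.

## MCMC bookkeeping

`mcmc_tree_count(total, interval, burnin)` counts retained tree samples:
samples are taken every `interval` generations and the initial `burnin`
fraction **of the samples** is discarded. The fraction applies to samples,
not generations, because that is the only reading consistent with the
published arithmetic (2,500,000 generations / 100 = 25,000 samples,
× 3/4 = 18,750 retained).

## Problem sizes and numerical choices

- Oracle-equivalence checks run on 1,000 random rooted trees, mostly 4–9
  tips with 2–4 states and a 12-tip binary-state tree every tenth
  replicate; the exhaustive oracle enumerates all k^(internal) labelings
  with vectorized edge sums. The fixture-tree oracle check runs on a
  13-taxon informative subtree spanning every distinct character pattern
  (3^12 labelings).
- Recovery suites: 500 seeded arrangement replicates (6–12 tips), 500
  seeded CRs (three styles round-robin), 100 seeded tRNAs; the acceptance
  script reruns smaller versions (200/100/100) plus 300 oracle trees, all
  driven by one seed.
- Tie-breaks are uniformly 5′-most/smallest and documented at each
  operation; the MPR sampling seed defaults to 0 and is surfaced in the
  API and the pipeline config.

## Known limitations

- Character C2's agamine translocation placement is intrinsically
  ambiguous across MPRs (Agaminae vs Agaminae+Draconinae stem); the
  package reports the ambiguity rather than resolving it silently.
- The tandem-repeat detector reports one array per (region, period) after
  smallest-period suppression; heavily nested higher-order repeat
  structure (repeats of repeats) is reported at the smallest period only.
- The GenBank reader maps features through a synonym table and skips what
  it cannot map (with a warning); it does not attempt fuzzy gene-name
  matching.
- Domain boundaries on real CRs depend on motif hits; with the shipped
  default consensus patterns they should be treated as approximate and
  recalibrated per lineage via the YAML config.
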