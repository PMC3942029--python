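# Methods

This note documents the models and procedures implemented in `mulescan`,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Cascade homolog search (`mulescan.cascade`)

A single similarity search from one query underestimates a transposase
superfamily whose members share 15–25% identity.  The cascade protocol
iterates: (1) a Smith–Waterman search of the database with BLOSUM62
(gap open −11 / extend −1), E-values from the Karlin–Altschul form
E = K·m·n·e^(−λS) with the published gapped constants λ = 0.267,
K = 0.041; (2) a position-specific profile search; (3) selection of the
next query as the retained hit most distant from the current query on an
average-distance (UPGMA) tree built from BLOSUM62-derived pairwise
distances d(a,b) = 1 − S(a,b)/min(S(a,a), S(b,b)), ties to the
lexicographically smallest label.  Hits must satisfy E ≤ 0.005 and query
coverage ≥ 60% at their admitting round; the cumulative hit set is monotone
across rounds and the default budget is 7 rounds.

The profile is a query-length log-odds matrix: retained hits are locally
aligned to the query, residues stacked onto query columns, sequences
weighted by the Henikoff position-based scheme, and observed frequencies
blended with Robinson–Robinson background frequencies using 5 pseudocounts
per column.  This is a deliberate simplification of a full PSI-Blast
profile (no compositional adjustment, no gapped profile states).  Because
profile scores have no universal statistics, each profile search calibrates
a Gumbel null by scoring 40 composition-preserving shuffles of database
sequences and fitting location/scale by the method of moments;
E = N·P(S ≥ s) over the N database sequences.

## Family delineation (`mulescan.network`)

All-against-all local alignment gives one E-value per pair; edges with
E < 10⁻⁴ enter an undirected graph weighted −log₁₀(max(E, floor)) (the
floor, default 10⁻²⁰⁰, caps underflowed E-values; log base is a monotone
rescaling choice).  Markov clustering runs on the column-stochastic matrix
with self-loops set to each node's maximum incident weight (isolated nodes
get 1): expansion (matrix squaring) alternates with inflation (entrywise
power 1.2, column renormalization), entries below 10⁻⁵ pruned each step,
until the max-norm change falls below 10⁻⁸ or 200 iterations
(non-convergence returns the current partition with a flag).  Clusters are
read from attractor rows (positive diagonal); attractors whose rows overlap
merge; a node pulled by several clusters joins the one whose smallest
attractor label sorts first.  An inflation of 1.2 suits loosely connected
IS-family graphs; higher values fragment them.

## Boundary calling and element validation (`mulescan.boundaries`)

The transposase CDS ± 400 bp is mapped to the genome by an internal
seed-and-extend nucleotide aligner (exact 12-mers sampled every 4 query
positions, ungapped x-drop 20 extension with match +1/mismatch −3, each
side trimmed to its maximal-scoring segment; standard 12-column hit tables
are accepted as a drop-in).  With more than three non-self hits the modal
HSP start/end in query coordinates define the boundaries (modal ties:
smaller start, larger end); hits reaching the window edge trigger window
growth in 400 bp steps up to 8 kb, so multi-ORF elements and ICEs converge.
Three or fewer copies raise a signal for the related-isolate fallback.

Boundary validation is joint: among ranked IR candidates on the called span
± 12 bp (length 18–39 bp, mismatch fraction ≤ 0.17, score = matches −
mismatches, ties by fewer mismatches, then longer, then more terminal), the
best candidate whose implied boundaries are flanked by an exact 8 or 9 bp
direct repeat wins and refines the boundaries; without a DR-supported
candidate the best IR alone refines them.  The joint rule matters: a target
site that is partially self-reverse-complementary (or shared across copies
under motif-targeted insertion) can extend an IR candidate past the true
terminus at equal or better score, and only the DR disambiguates.  The
conserved terminal cytosine is interpreted strand-symmetrically: each IR
ends in C read outward on its own strand, i.e. the element reads G…C on the
top strand, which is the only reading consistent with the two IRs being
reverse complements of each other.

IR complementarity is reported as 100 × matches / aligned columns from a
global alignment of the left IR against the reverse complement of the right
IR (match 1, mismatch −1, gap −2).  The −1 programmed-frameshift check
accepts two overlapping same-strand ORFs whose frames differ by −1 when
some codon-aligned slip position yields a stop-free chimeric reading
through both; it returns the first such position.

## Insertion-site specificity (`mulescan.sitespec`)

300 bp flanks are extracted on both sides of each validated element,
reading away from the element on the element's own strand, and
deduplicated by (side, sequence) before any counting, so identical
multi-copy insertions cannot fabricate peaks.  σ^A promoters are modelled
as a pair of position weight matrices seeded from the canonical TTGACA/
TATAAT hexamers (pseudocount 0.1, log₂-odds against the A/T-rich flank
background 0.3/0.2/0.2/0.3), paired over spacers of 15–19 bp; hits need a
combined score ≥ 8.0 bits (a perfect consensus pair scores ≈ 17.8; each
consensus violation costs ≈ 3.5) and overlapping hits resolve best-first.
This is a transparent stand-in for an HMM promoter model whose training
data is not distributed; the matrices are user-replaceable.

The junction profile counts, for each signed distance d within ±30 bp
(IRl side negative, IRr positive, measured junction → first base of the
−35 box), the fraction r(d) of all detected promoters at that distance;
Σr(d) = 1 whenever any promoter is found, and the peak is the argmax.
Sides are element-intrinsic, so reverse-complementing the genome leaves
the profile invariant (the sides travel with the element).  Orientation
bias is the fraction of elements whose nearest qualifying promoter lies on
the IRr side.  DR consensus letters are the IUPAC code covering every base
with frequency ≥ 0.25 at that position.

## Conservation profiling (`mulescan.conservation`)

Alignment columns with more than 60% gaps are removed (strict inequality).
The conservation curve is the plotcon-style statistic: per-column mean of
all pairwise BLOSUM62 scores (gap-vs-residue −4, gap-vs-gap excluded),
averaged over a centered window — 15 aa for domain-level profiles, 10 aa
for differential comparisons — with windows shrinking at the edges.  The
DDE triad is anchored by mapping reference residue indices through
alignment columns onto every row (gaps or non-D/E residues flagged); the
C/D(2)H signature ([CD]xxH) is scanned 11–19 aa downstream of each called
D2, nearest offset first.  Anchor-domain localization takes the top
non-overlapping runs above a threshold (default mean + 0.5 sd, width ≥ 5).

Differential conservation projects the two windowed profiles onto the
ungapped coordinates of a shared reference row and reports maximal runs
where profile(A+B1) − profile(A+B2) > 1.0 matrix units for ≥ 8 residues,
each with its consensus PFM.  The 1.0-unit threshold was tuned on the
generator's truth: with ~10-member groups, stochastic conservation
differences produce runs up to ≈ 0.9 units even between exchangeable
partner groups, while a genuinely invariant 8-aa block scores ≈ 1.5–2.2.

## Synthetic study conditions (`mulescan.simulate`, `mulescan.fixtures`)

Protein families descend from per-family ancestors by i.i.d. per-site
substitution (uniform over the 19 alternatives; optional indel mode off by
default), with the catalytic letters (D, D, E; C/D(2)H) and the N1/N2
anchor blocks exempt.  Layout defaults: 320 aa ancestors, triad at
(100, 170, 280) so the D2→E insert is 110 aa (inside the 99–138 aa band
characteristic of the superfamily's α-helical insert), C/D(2)H at D2+14,
anchors at 10–18 and 28–44.  Families may share a root (`root_divergence`);
whether anchor blocks survive root-level divergence is per-spec
(`root_exempt`) — family-level anchors keep between-family similarity in
the twilight zone, superfamily-level anchors are used where cross-group
conservation is the object of study.

Genomes are i.i.d. nucleotides at GC 0.40 (AT-rich, in the spirit of the
Firmicute hosts).  Elements are assembled as IRl–padding–CDS(–passengers)
–padding–IRr; insertion duplicates the dr_length target-site bases so every
copy is flanked by identical DRs; sites are placed by rejection sampling
with a 900 bp minimum separation, strands uniform.  Site models: (i)
promoter-offset — a −35/−10 pair (each base corrupted with probability 0.1,
spacer uniform 15–19) is written with the −35 box at a sampled distance
from the IRr junction, distribution {15: 0.25, 16: 0.5, 17: 0.25} (mode 16,
the characteristic geometry of promoter-targeting elements), IRr facing the
promoter unless the orientation rule is unbiased; (ii) AT-rich motif —
insertion only at genomic `AANATNTT` matches, which become the DR; (iii)
uniform.  The frameshift construction encodes one transposase as two
overlapping ORFs sharing a base at the slip site such that a single −1
shift restores the full product.

Canonical scenario sizes (chosen once as realistic desk-scale conditions):
5 families × 8 members for clustering; 500 insertions of 4 elements for
promoter enrichment; 50 insertions of 5 elements in 200 kb for the AT-rich
model; 30 insertions of 6 elements for boundary recovery; 3 families × 6
members (root divergence 0.65) for the homology chain, a regime measured to
make the end families mutually undetectable by a direct search while each
remains detectable from the middle family.

**What the generator does not emulate:** indel-driven alignment difficulty
(off by default), domain shuffling, compositional bias and low-complexity
segments, nested or truncated elements, decayed element copies, passenger
gene function, and real promoter degeneracy beyond independent per-base
corruption.  Passing tests therefore demonstrate correctness of the
operations and recoverability under these idealized conditions, not
performance on real genomes; the published headline counts depend on the
2013-era public databases and are outside desk scale by design.

## Numerical and engineering choices

- Coordinates are 0-based half-open internally; GFF3 output is 1-based
  inclusive.  Truth tables are emitted as GFF3 + TSV.
- A single global seed fans out to per-stage seeds by SHA-256 hashing
  (`cli.stage_seed`), keeping stages independently reproducible; all
  derived seeds stay below 2³¹.
- The profile-vs-sequence Smith–Waterman kernel is numba-compiled (affine
  gaps, origin tracking for coverage); everything pairwise goes through
  Biopython's C aligner.
- Degenerate inputs: empty databases and empty alignments raise; empty
  sequences are skipped with a warning; zero promoters leave the junction
  profile flagged undefined rather than dividing by zero; MCL on an empty
  graph raises; partitions always cover every node exactly once.

## Known limitations

- Profile E-values rest on a 40-decoy Gumbel fit; they are accurate enough
  for filtering at 0.005 but not for ranking deep in the tail.
- The seed-and-extend mapper is ungapped; indel-rich element copies would
  fragment into multiple HSPs and blur majority boundaries.
- MCL at inflation 1.2 can need many iterations on near-regular graphs;
  the 200-iteration cap returns a flagged partial result.
- The promoter model scans only the strand reading away from the element
  by default (the geometry of promoter-targeted insertion); a both-strands
  mode exists but halves specificity.
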