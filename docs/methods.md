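# Methods

## Coordinate and alphabet conventions

Precursor intervals are 0-based half-open; seed spans on matures are
1-based inclusive (so "nt 2–7" is written exactly as the field says it).
All sequences are RNA internally (T converted to U on input); writers
can emit DNA via a flag.  Positive 5'/3' offsets point downstream along
the precursor: a +1 5' offset means the read starts one base after the
annotated mature start.

## Read mapping (templated-prefix alignment)

Reads are mapped in **precursor space**, not genome space.  For a small
RNA-seq read this loses nothing: every quantity produced downstream
(class counts, RPM, arm fractions, concordance fractions, logos) is
defined on the hairpin.  A candidate alignment is a triple
(precursor, start, split): the read prefix of length `split` aligns
ungapped from `start` with at most `max_mismatches` (default 1)
mismatches, and the remaining suffix — at most `max_nta` (default 3)
bases — is untemplated 3' addition.  `split` must be at least
`min_templated` (default 16; reads shorter than that are dropped before
mapping, a standard small-RNA floor).  Candidates are scored

    score = split − 2 × mismatches

and the maximum wins; ties break by fewer NTA bases, fewer mismatches,
lexicographically smallest precursor id, smallest start.  The −2
mismatch penalty makes an NTA split strictly preferable to absorbing a
terminal mismatch (L vs L+1−2), which is what makes the "+U" class
well-defined.  Equal-score survivors on *different* precursors set an
`ambiguous` flag; ambiguous reads are counted once at the deterministic
winner and their fraction is reported per library.  Only 3' NTA is
modelled; an untemplated 5' base consumes mismatch budget instead.

Every alignment satisfies the reconstruction rule (asserted at run
time): precursor bases over the templated interval, with the read's
bases substituted at the recorded mismatch positions, plus the NTA
suffix, equal the read.

The implementation restricts the split search to the admissible window
`[len(read) − max_nta, len(read)]` using cumulative mismatch counts; the
test suite checks it against a naive oracle that enumerates every
(precursor, start, split) and applies the same score and tie-breaks.

## Classification and profiles

An alignment is assigned to the mature annotation with the largest
interval overlap (ties favour the 5p arm; zero overlap yields
`unassigned`).  The isomiR class of a read is the tuple
(mature, offset5, offset3, nta); profiles tally class counts and
per-sequence counts.  RPM normalises by reads mapped to **any precursor
of the reference set** — the denominator is stated because published
RPM bases often are not; all concordance and arm *fractions* are
denominator-free.  Fold-changes are computed on RPM by default and the
raw-count ratio is carried alongside (which one a published fold-change
used is rarely stated); a zero denominator returns +inf with a flag, and
an optional 0.5 pseudocount is available.

## Logo matrices

The per-miRNA logo is a position-probability matrix over the window
[mature.start − flank, mature.end + flank): each distinct assigned read
sequence is re-placed at its precursor coordinates (NTA bases at the
positions immediately past the templated end) and columns are
count-weighted nucleotide frequencies **among the reads covering the
position**, so every supported column sums to 1.  A 5'-shifted read
population therefore shows up at the annotated start position as a
*support* drop (few reads cover it), not as a probability mixture — with
a 95% +1-shift, the support at the annotated start is ~5% of the arm's
reads while its probability column stays pure.  The matrix is exported
as TSV and can be rendered as a stacked-bar plot with matplotlib (no
external logo tool is required).

## Annotation audit

Per arm, the dominant call is the most frequent full read sequence
(ties: lexicographically smallest) plus the modal 5' and 3' offsets
(ties: smaller offset).  The verdict logic, with `min_depth` default 10
and `dominance_threshold` default 0.5:

* depth < min_depth → `low_coverage` (depth 0 additionally empties the
  seed fields);
* modal offset5 ≠ 0 and the fraction of reads sharing that 5' start ≥
  threshold → `seed_shifted`;
* modal offset5 = 0 but modal offset3 ≠ 0 or >50% of reads carry NTA →
  `three_prime_variant_only`;
* otherwise `concordant`.

Support for the shift rule is deliberately the **5'-start-sharing
fraction**, not full-sequence identity: 3' heterogeneity is ubiquitous
and must not dilute a 5'-shift call.  "Matching the annotation" is
reported under both full-sequence and 5'-end modes, because published
percentages rarely say which was meant; the JSON names the mode.  The
default seed for verdicts is nt 2–7; nt 2–8 and the Argonaute-exposed
nt 2–6 are emitted alongside.  The family check compares the observed
seed with the modal annotated seed across the family's members
(undefined for single-member families).

## Seed sites and isoform overlap

Site motifs are exact reverse complements of the seed span in RNA space
(G:U wobble is not counted); 7mer-A1/8mer types append the adenine
opposite mature position 1 at the 3' side of the UTR motif.  Scanning is
exhaustive and reports overlapping occurrences.  Two isoforms' sites on
a UTR "overlap" when they share ≥1 position; `n_shared` uses a greedy
one-to-one two-pointer matching of the position-sorted site lists (so it
never exceeds either isoform's total), while `retention_a_in_b` is the
plain fraction of a's sites with any overlapping b site.

For a 1-nt 5' shift on iid uniform sequence, a site of the annotated
isoform is retained by the shifted isoform exactly when the adjacent
base happens to complement the shift — probability 1/4.  With canonical
6mer (nt 2–7) sites this is the only overlap case for the miR-34b motif
pair up to O(4⁻⁵) corrections, so retention converges to 25%.  A caveat
worth recording: with the 5mer exposed-2-6 motifs (UGCCU vs CUGCC) the
shifted motif can also arise 3 nt downstream inside an extension of the
annotated site (probability 4⁻³), lifting asymptotic retention to
~26.2%; the null-retention analyses therefore use 6mer sites.

## Synthetic libraries: the stated world

The generator draws, per read: a source mature (per-miRNA expected
counts; precursor-keyed counts are split 5p/3p by `arm5p_fraction`),
5' and 3' offsets, an NTA suffix from an explicit table (table form
makes truth exact; the default weights mono-uridylation highest), and
iid substitutions at `substitution_rate` per templated base —
by default never in read positions 1–8, keeping seed-region classes
unambiguous for recovery tests.  Defaults emulate a mimic-transfection
library: precise 5' ends (`offset5 = 0`), `P(+U) = 0.179`,
`P(offset3 = −4) = 0.194` with the remaining 3'-shortening mass spread
uniformly over −1…−3, `arm5p_fraction = 0.76`, substitution rate 0.

Two documented simplifications:

* Offsets and NTA are sampled **independently**; observed joint class
  fractions (e.g. "22.4% exactly canonical") are not reproduced exactly
  by independent marginals (the defaults imply ~29% canonical).  The
  marginals, not the joint, are the stated quantities.
* **Identifiability**: an NTA suffix that equals the templated
  continuation of the precursor (e.g. +U immediately before a templated
  U) is indistinguishable from templated extension, and the mapper —
  like any mapper — prefers the templated reading.  Exact
  profile-vs-truth recovery therefore holds on references where sampled
  NTA differs from the templated continuation at every offset in
  support; the test fixtures are built that way, and the miR-34b fixture
  (whose downstream base is U by construction) is exactly the case where
  a real +U tail is partially hidden.

Not emulated: adapters, per-cycle error profiles, PCR duplicates,
ligation bias.  A green recovery test establishes that classification
and bookkeeping are exact under the stated read model — not that the
mapper is robust to artefacts outside it.

## Fixtures

The miR-34 fixture hairpins are synthetic scaffolds around the public
mature sequences; they are not genomic precursors (the module docstring
says so).  The only biologically meaningful construction choice is the
U immediately 3' of the annotated miR-34b-5p, which makes the +1/+1
shifted variant equal the endogenously dominant, database-curated form;
the nt 2–8 seed comparison is insensitive to this base.

## Determinism and tolerances

All randomness flows through `numpy.random.default_rng(seed)`; identical
(reference, config, seed) produce byte-identical read files and
manifests.  Stochastic checks use binomial standard errors at the
simulated n (3 SE in acceptance-level checks, 4 SE in small unit
fixtures); probability tables must sum to 1 within 1e-9, as must logo
columns.  Boundary cases: offsets that escape the precursor are
resampled up to 100 times then raise; zero-read miRNAs report missing
arm fractions and `low_coverage` verdicts rather than NaNs.
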