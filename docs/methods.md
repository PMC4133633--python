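# Methods

This note documents the models, rules and numerical choices behind
`pednet`, what the synthetic-data generator does and does not emulate, and
the design decisions taken where more than one reasonable convention
exists.

## Pedigree notation and atomisation

A pedigree string is parsed to a binary *cross tree*: leaves are named
founder lines, internal nodes are crosses. Purdy notation is split at the
highest-order separator present (`/` < `//` < `/3/` < `/4/` …); repeated
equal-order separators associate left, so the common non-strict record
`A/B//C//D` reads ((A×B)×C)×D. The numeric form accepts any order ≥ 3,
including multi-digit orders, so arbitrarily deep trees serialise and
re-parse exactly. Lamacraft–Finlay notation is a conventional infix
grammar: `*` (or `×`) crosses, parentheses (or square brackets) group,
unparenthesised chains associate left. Mixed slash/star strings are
rejected rather than guessed at — such records need a curator.

Atomisation walks the tree and emits one `(child, parent_1, parent_2)`
record per distinct cross, parents before children. Interior crosses have
no name of their own, so they receive their Purdy serialisation as a
canonical name; this is deterministic, human-readable, and merges repeated
identical sub-crosses into a single line. By convention the left operand
is carried as parent_1 (female side); the notation itself encodes no sex,
so sex information only enters through the optional `cross_type` column of
the tabular format.

Serialising a line's ancestry from a net unfolds the DAG into a tree
(shared ancestors are repeated, as pedigree strings require). Round-trip
is therefore isomorphism of the rebuilt ancestor sub-net, not string
identity.

## The pedigree net

The net is a DAG in which each line has at most two parent *roles* and the
same line may fill both (selfing). Validation is strict: cycles are fatal,
and a child defined twice with different parents is fatal rather than
merged, because silent name reuse creates false relationship joins that
are far harder to find later. Parents referenced but never defined are
auto-created as founders, since historical records are chronically
incomplete.

Generations are assigned by **longest path**: founders at layer 0, every
child one below its deepest parent. This keeps ancient founders at the top
while guaranteeing every child sits strictly below all of its parents —
the property that makes a pedigree readable top-down and that
force-directed layouts destroy. Calendar years would be better but are
rarely recorded.

Line classification uses parental usage: `terminal` lines were never used
as a parent; `principal` lines were used at least `principal_threshold`
times (default 5 — "commonly used" has no agreed number, so the threshold
is a parameter); founders below the threshold but above zero are
`flanking`; everything else is `intermediate`.

## Layered layout

The layout pipeline is the standard Sugiyama sequence: longest-path
layering, subdivision of edges spanning more than one layer with one dummy
vertex per intermediate layer, barycenter crossing reduction, and
coordinate assignment on a fixed grid (`x = order index × node_gap`).
Sweeps alternate downward and upward; ties in barycenter keep the previous
order (stable sort); the best ordering seen is retained, so the final
crossing count never exceeds that of the initial (topological-discovery)
order. The barycenter heuristic was chosen over the median for simplicity
and determinism; neither is optimal, and no equivalence with any
particular graph-drawing tool's output is intended. Crossings are counted
per adjacent layer pair as inversions of segment endpoints (merge-sort
inversion count), which equals the brute-force pairwise segment test.

Edges are drawn as straight polylines through their dummy vertices —
bundled or orthogonal routing trades traceability for tidiness and is
deliberately not offered. Layer 0 renders at the top. SVG output is fully
deterministic (sorted element order, fixed float formatting) so diffs are
meaningful.

The local view re-computes generations on the induced sub-net (so its
shallowest layer is 0) and translates the drawing so the focused line sits
at x = 0.

## Colour and size encodings

Nominal classes get distinct hues from an embedded 12-colour qualitative
palette (ColorBrewer Paired values, frozen in source so output never
depends on an external palette library); past 12 classes the palette
cycles with a progressive lightness shift so every class remains
distinguishable *in principle*. Ordinal classes get a saturation ramp at a
fixed blue hue (HSV saturation 0.15 → 0.95, value 0.85), strictly
monotone in class order; a computed ramp was preferred over a fixed
sequential palette table because monotonicity must hold for any class
count. Both scales set `overflow_flag` above eight classes — the point
where adjacent colours stop being reliably distinguishable — and the tools
warn but still render, since merged multi-trait classes (tuples of labels
joined with `|`, often ~20 combinations) would otherwise be unusable.
Lines with no phenotype record are painted a recessive grey (`#BDBDBD`).

Node radius is `s_min + (s_max − s_min)·√(u/u_max)` where `u` is the
number of distinct crosses the line parented: the square root makes node
*area* roughly linear in usage, so visual weight tracks contribution.

## Genotypes, similarity and QC

Calls are unordered diploid pairs normalised to sorted order (`GA` → `AG`)
with `-`/blank for missing. Similarity is plain identity-by-state
allele sharing: per locus, the multiset intersection of the two calls
divided by 2 (1 for identical calls, 0.5 for one shared allele, 0 for
none), averaged over co-called loci and reported as a percentage. This is
the simplest standard IBS score; other choices (Jaccard, correlation)
order pairs differently, and the percentage here is defined by this
formula, not by agreement with any external database. `min_loci` (default
1) guards against percentages computed from too few loci.

Mendelian checking uses the **union rule**: every child allele must occur
in the union of the two parents' alleles. Strict one-allele-per-parent
transmission would be wrong here, because the named offspring of a plant
cross is an inbred descendant of that cross — `AA` offspring of an
`AA × GG` cross is perfectly legitimate, having fixed the first parent's
allele. Residual heterozygotes never violate the union rule by
construction either, so they are reported as a separate per-line
heterozygosity percentage rather than as violations. Children with only
one genotyped parent get a deliberately conservative single-parent rule:
flagged only when parent and child are homozygous for different alleles.
Note this heuristic *can* flag legitimate inheritance from the missing
parent (an inbred child may fix the other parent's allele at any locus);
such flags carry `rule=single_parent` so reports can be filtered, and the
CLI summary counts them separately from trio violations.

Second-parent inference scores every genotyped line (except the child and
its descendants) by the fraction of testable loci at which the trio
(child, known parent, candidate) satisfies the union rule, and ranks
descending. The true parent always scores 1.0 on clean data; candidates
genetically identical to it tie, which is unavoidable and reported as-is.
Genotype matching ranks lines by IBS similarity to a query call vector;
exact genotypic twins (e.g. the offspring of a selfing that fixed no new
alleles) tie at 100%, so "found at rank 1" throughout the tests means
competition ranking — tied at the top score.

## The simulator

`simulate_breeding_program` generates founders with independent homozygous
biallelic SNP genotypes (allele pair fixed per marker, 50/50 frequencies),
then a sequence of crosses. The female parent is drawn from the ten most
recently created lines, which keeps the programme moving forward; the male
parent reaches back into the old pool (lines at least three generations
above the front) with probability `p_old_parent` (default 0.15), which
produces the long cross-generation edges that make plant pedigrees nets
rather than trees; with `selfing_rate` (default 0.02) one line takes both
roles. Per locus the child receives one gamete allele from each parent
and fixes one of them as a homozygote, except with probability
`residual_het_rate` (default 0.004) it retains the heterozygote when the
gametes differ. Consequently the *observed* heterozygous fraction is the
rate times the probability the two gametes differ (about half the nominal
rate early in a programme, less as lines converge) — comfortably inside
the below-half-a-percent regime of real elite inbred panels. Phenotypes
are nominal or ordinal class labels copied from a random parent with
probability 0.8 (else drawn uniformly), enough to make overlays show
inheritance structure without modelling genetics of the traits.

The `elite-panel` preset generates the shape of a national elite barley
panel: 100 founders + 703 crosses = 803 lines, 4,769 markers, genotypes
for 750 of the 803 lines, 33 DUS-style traits. It simulates, lays out,
renders and checks in a few seconds on one CPU.

What the simulator does **not** emulate: linkage (markers segregate
independently), selection, population structure beyond parent reuse,
multi-allelic markers, genotyping error other than the explicitly injected
kind, and trait genetics. Tests passing on simulated data therefore
demonstrate the correctness of the algorithms under the stated model, not
robustness to every artefact of real panels.

Error injection corrupts calls of children with two genotyped parents to a
homozygote of an allele *outside* the parental union, so every injected
error is detectable by construction and detection can be asserted exactly.
A corrupted line that is itself a parent may additionally produce genuine
cascade violations in its own children; the guarantee is that all injected
cells are flagged, not that they are the only flags. Row swaps model
sample mislabelling and are involutions.

## Problem sizes and determinism

Default test-suite problem sizes (nets up to ~200 nodes, panels up to
100×1000, 100–200 random instances per property) were chosen so the whole
suite runs in well under a minute while still exercising multi-generation
topology, dummy chains and tie cases. All randomness flows through
explicit seeds: simulations via `numpy.random.default_rng(seed)`, layout
shuffles via `random.Random(seed)`; identical inputs and seeds give
byte-identical SVG/dot/JSON/TSV outputs.

## Known limitations

* Purdy backcross shorthand (`A*2/B`) and free-text breeder annotations
  are not parsed; only the three documented dialects are.
* Line names consisting solely of digits can collide with the `/n/`
  separator form inside Purdy strings.
* The all-by-all similarity matrix is O(L²·M); at panel scale prefer
  per-line queries (`threshold_similar`, `match_genotype`).
* Layout quality is heuristic: barycenter sweeps reduce crossings but do
  not minimise them, and no attempt is made to match any specific
  graph-drawing tool's output.
* Duplicate line names are detected, never repaired; disambiguation is a
  curation task.
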