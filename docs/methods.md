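# Methods

## Digestion model

Digestion is complete and deterministic. Recognition sites are IUPAC
patterns scanned on the plus strand only; every catalog site's expansion set
is closed under reverse complement (asserted for all eleven enzymes), so a
plus-strand scan finds every double-strand cut. Overlapping occurrences are
all reported (GCWGC self-overlaps at shift 3). A site never matches across
an N. Each occurrence contributes one cut coordinate, site start plus the
top-strand cut offset; the bottom-strand cut (overhang geometry) is not
modeled because fragment coordinates depend on a single boundary per site,
and end fill-in does not change which CpGs a read can reach at the depths
considered. Cuts from different enzymes that coincide are deduplicated, so a
shared boundary produces one fragment edge, never a zero-length fragment.

Terminal chromosome pieces are excluded by default (`include_terminal=False`)
because an RRBS fragment needs two enzyme-cut ends for adapter ligation; the
flag exists because the convention is not universal, and at genome scale the
difference is two fragments per sequence. With terminal pieces included and
no size selection, fragments partition the sequence exactly — a conservation
property the tests check on every fixture.

Methylation sensitivity is reaction metadata only: the in silico digest cuts
regardless, which matches how enzyme combinations are compared before a
library is built. ApeKI's differing reaction conditions (75 °C, NEB 3.1) do
not prevent its use as an in silico baseline component.

## Coverage metrics

Sequencing depth `depth_nt` (default 50) is read from both fragment ends,
approximating paired-end/bidirectional reading; the two windows merge when
the fragment is ≤ 2×depth long. A CpG is covered when its C position lies in
a window. The G may fall one base outside; we read the C because that is the
base the bisulfite methylation call interrogates. `strict_cpg=True` requires
both bases in the same window — at depth 50 the difference is at most one
CpG per fragment end.

Derived columns: coverage % = 100 × covered / denominator; CpG/fragment
ratio = covered / fragments; read coverage = throughput / fragments
(throughput default 150,000,000 reads). The denominator defaults to the CpG
dyad count of the input genome (each CG counted once on the plus strand);
round-number presets (27 M human, 23.9 M rat, 21.9 M mouse) are available
for replicating published tables. All values are carried at full precision;
only the formatting layer rounds (percent and fold to one decimal, ratio to
two, half-up). Zero fragments yield NaN ratio/fold values, rendered as
empty markers, never a division error.

A CG-containing consensus (MspI, TaqI) cannot produce CpG-free *internal*
fragments: every internal fragment starts `CGG…`, i.e. with a CpG at its 5'
end. The one exception is the leading terminal fragment `[0, first_cut)`,
which ends immediately before its site's CG; with `include_terminal=True`
the tests therefore allow exactly that one fragment to be CpG-free. Mapping
rates are deliberately not modeled — they depend on aligner, repeat content
and size selection — so reported folds are pre-alignment expectations.

## Near-neighbor analysis

For each CpG at p, every distinct k-mer (default k=4, window 50 nt) lying
fully within [p − w, p + 2 + w) counts once for that CpG. Presence counting
was chosen over occurrence counting because the quantity of interest is "how
many CpGs become reachable if this site is cut"; multiple occurrences beside
one CpG would inflate the count without adding reachable CpGs. Degenerate
catalog sites (ApeKI) are ranked by the maximum over their concrete
expansions, a lower bound on reachable CpGs; 5-mer tables use the same
machinery with k=5 and are reported separately from 4-mer tables.

## Genomic-context classification

Shores are the 2 kb flanking a CGI (CGI subtracted), shelves the 2–4 kb band
(computed as the 4 kb expansion minus the 2 kb expansion, which excludes
CGIs and shores by construction), promoters the 2 kb strictly upstream of
each TSS — gene start on '+', gene end on '−' — and open sea the residual.
Overlaps between categories are resolved by fixed precedence
CGI > shore > shelf > promoter > gene > open sea. The residual definition
forces open sea to be last; the rest of the order is a package decision
(island-proximity categories describe methylation context more specifically
than transcript categories) since no single convention exists. The
precedence makes classification a partition: category counts over any CpG
set sum to the set size, which is asserted as a property. When exon
intervals are supplied the gene category splits into exon and intron (gene
minus exon), exon first.

## Combinatorial screen

All subsets of size 1..3 of the seven compatible enzymes (63 combinations)
are measured with identical parameters. Per-enzyme cut positions are
computed once per sequence and unioned per combination, so cost scales with
genome size rather than combination count. Ranking is by coverage %
descending, ties by read coverage descending, then label — byte-identical
TSVs across runs. Covered-CpG sets are kept as sorted unique int64 arrays
per sequence: exact set algebra, memory linear in CpG count (~80 MB for the
human genome's 27 M CpGs, well within a laptop). Baselines (MspI,
MspI+ApeKI by default) are digested with the same parameters and compared by
exact intersection; `shared + new = combination's covered count` and
`shared + baseline_only = baseline's covered count` hold identically.

The 10× read-coverage cutoff is a comparison baseline, not a recommendation;
it is a parameter (`--cutoff`).

## Synthetic data

The generator emulates what the pipeline consumes — sequence composition,
CpG-dense islands, known restriction sites — not mammalian genome structure
(no repeats, no karyotype, no realistic CGI length distribution, no
methylation state). Passing tests therefore demonstrate correctness of the
computation, not that a 50 kb toy genome predicts a real genome's coverage
numbers; genome-scale counts additionally depend on conventions (terminal
fragments, N-gap handling) that published tables do not pin down.

Background bases are i.i.d. at `gc_fraction` (default 0.41, mammalian-like).
Islands use an insertion model: at each step a CG dyad is written with
probability ρ = d/(1−d), else one background base, giving an expected CpG
density of exactly d per base; accidental background CG dyads inside islands
are redrawn so the density is the model's. Planted sites are written last;
afterwards any accidental occurrence of a *planted* enzyme's site elsewhere
is destroyed by seeded point mutation outside the planted spans (bounded
iteration, error if planted sites themselves induce an unremovable
occurrence). This makes the truth table exact: digestion with the planted
enzymes returns exactly the planted cut coordinates, for every seed. The
seed appears in the record id.

The seven-site insert places one concrete site per enzyme in catalog order,
separated by AC-repeat spacers (default 50 nt). AC repeats contain no
catalog site, and generation verifies the whole construct: each requested
enzyme matches exactly once, every other catalog enzyme not at all, so
single-enzyme digestion yields exactly one cut and complete digestion by the
seven yields eight terminal-inclusive fragments. The published insert's
exact bases are not transcribed anywhere reusable, so the generator
reproduces the design rule, not the sequence.

## Problem sizes

Tests run on genomes of 1–10 kb (100 seeded replicates for the brute-force
equivalence checks) and synthetic screens on 5–50 kb genomes; these sizes
exercise every code path — islands, N gaps, all eleven enzymes, terminal
policies — while keeping the whole suite under ten seconds. The acceptance
script uses a 50 kb genome for the screen and twenty 6 kb genomes for
planted-site recovery.

## Known limitations

- Complete digestion only; partial digestion and star activity are out of
  scope.
- Isoschizomers are not resolved; TaqαI is accepted as an alias of TaqI.
- CpG totals count dyads once; published genome totals that counted both
  strands would need a doubled denominator (the `--denominator` option
  absorbs either convention).
- Published genome-scale fragment/CpG counts are not reproduced here — they
  require the original multi-gigabase assemblies and their exact masking —
  only the arithmetic that derives the ratio columns from those counts.
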