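# rrbsdesign

In silico design of reduced-representation bisulfite sequencing (RRBS)
experiments: digest a genome with combinations of methylation-insensitive
restriction enzymes, size-select the fragments, count the CpGs observable at
a fixed sequencing depth, and rank enzyme combinations by CpG coverage,
predicted read coverage and genomic context.

## Who this is for

RRBS measures DNA methylation at single-CpG resolution on the genome fraction
captured by restriction digestion plus size selection, so the enzyme choice
fixes the experiment's coverage before any sequencing happens. The classic
MspI (C|CGG) digest concentrates on CpG islands; combinations of four-cutters
with AT- or CG-poor sites reach shores, shelves and open-sea CpGs at the cost
of more fragments (and hence fewer reads per fragment). This package lets a
methylation lab ask, before ordering enzymes: *for my genome, which
combination covers the most CpGs while still giving each fragment enough
reads?*

## The model

For an enzyme set *E* with palindromic recognition sites, digestion is
complete: every site occurrence contributes one cut at its top-strand offset
(the `|` in C|CGG). Fragments between consecutive cuts are kept when their
length lies in the size-selection window [40, 400] bp. With read length
*d* = 50 nt from each fragment end, a fragment's observable part is
[start, start+d) ∪ (end−d, end), and a CpG is covered when its C falls
inside such a window. Per combination the screen reports:

- **CpGs covered** — size of the union of covered-CpG sets over fragments;
- **fragments generated** — after size selection;
- **genomic CpG coverage (%)** — 100 × covered / total CpGs (computed from
  the genome, or an assumed total such as 27 M for human);
- **CpG/fragment ratio** — covered CpGs per fragment (CG density of the
  reduced representation);
- **CpG-free fragments** — fragments whose observable windows hold no CpG,
  i.e. pure sequencing cost;
- **read coverage (fold)** — instrument throughput (150 M reads by default)
  divided by the number of fragments; the screening cutoff is 10×.

A near-neighbor analysis (how many CpGs have a given 4-mer within 50 nt of
the dyad) ranks candidate recognition sites before any digestion, and the
annotation module classifies covered CpGs into CGI / shore (≤2 kb from a
CGI) / shelf (2–4 kb) / promoter (2 kb upstream of the TSS) / gene / open
sea with a fixed precedence, so the counts partition the covered set.

## Worked example

Simulate a 50 kb genome with two CpG-dense islands, then screen all 1- and
2-enzyme combinations of the seven compatible enzymes (AluI, BfaI, HaeIII,
HpyCH4V, MluCI, MseI, MspI — all 37 °C/CutSmart, so one library preparation):

```bash
rrbs-design simulate --length 50000 --seed 1 \
    --islands 10000:2000:0.12,30000:1500:0.15 --out-prefix demo
rrbs-design screen --fasta demo.fa --max-combo 2 --cutoff 0 --out screen.tsv
```

The screen TSV begins with commented provenance (tool version, parameters,
input MD5) and then the ranked table; the top and bottom of the ranking:

```
enzymes      cpgs_covered  fragments_generated  coverage_pct  cpg_per_fragment  cpg_free_fragments  read_coverage  ...
MluCI MseI   1465          387                  60.0          3.79              11                  387596.9
BfaI MluCI   1375          358                  56.3          3.84              10                  418994.4
...
MspI         316           58                   12.9          5.45              0                   2586206.9
```

Reading it: on this AT-rich background the AT-cutters MluCI (|AATT) and MseI
(T|TAA) reach 60.0% of the genome's CpGs versus 12.9% for MspI alone, at the
price of ~6.7× more fragments (387 vs 58) and therefore ~6.7× lower read
coverage per fragment. MspI alone generates zero CpG-free fragments — its
site contains CG, so every internal fragment starts with a CpG — while the
AT-cutters pay for their reach with CpG-free fragments (11 of 387 here).
The `shared_with_MspI` / `new_vs_MspI` columns (elided above) give the
overlap of each combination's covered set with the MspI and MspI+ApeKI
baselines. A single-combination report:

```bash
rrbs-design report --fasta demo.fa --enzymes MspI,HaeIII --out rep.tsv
# -> MspI HaeIII   681  137  27.9  4.97  1  1094890.5
```

Other subcommands: `digest` (fragments as BED3), `neighbor` (CpG-flank
k-mer table), `annotate` (CGI/shore/shelf/promoter/gene/open-sea
distribution of covered CpGs), `profile` (fragment-length histogram).
The read-coverage folds are astronomically large here only because 150 M
reads are spread over a 50 kb toy genome; on a 3 Gb genome the same digest
yields millions of fragments and folds of 10–30×.

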