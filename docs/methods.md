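# Methods

This note records the modelling and numerical choices behind `phylostrat`:
what each stage assumes, which parameters matter, what the synthetic
generator does and does not emulate, and where the design was genuinely
open.

## Phylostratum maps

A map is an ordered list of strata ps1..psP, each a *curated set* of taxon
labels, plus a focal taxon. The species tree is used to validate a map
(every leaf covered, focal present) and to derive one from topology, but
at runtime a taxon's stratum is whatever the specification says. This
reflects practice: published phylostratigraphies group outgroups into
consensus clades that do not always coincide with strict tree topology
(the packaged mouse map, for instance, pools Afrotheria, Xenarthra and
Laurasiatheria into the Boreoeutheria stratum ps17).

Taxon labels are matched after trimming and case folding, nothing more:
hit tables and trees usually come from different providers, and silent
fuzzy matching would hide real data errors. An unknown taxon is always an
error, never a default-to-youngest.

Two fixtures ship with the package: a 20-stratum mouse lineage (ps1 =
cellular organisms ... ps17 Boreoeutheria, ps18 Euarchontoglires, ps20 the
mouse lineage since the rat split) and a 14-stratum zebrafish lineage
sharing the names of ps1–12. In curated maps the focal taxon shares the
youngest stratum with its closest outgroup group; `derive_strata_from_tree`
instead gives the focal taxon its own terminal stratum (path nodes + 1),
which is the natural convention when no curation is available.

## Age assignment

The rule is deliberately minimal: oldest stratum with a qualifying hit,
strict `e < cutoff`, orphans to psP. Three choices deserve a note:

- **Self-hits are ignored.** A hit whose subject taxon equals the focal
  taxon carries no age information; counting it would silently assign psP
  regardless of the rest of the table.
- **Products with hits but no qualifying hit are orphans** (psP), the same
  as hit-less products: "no detectable similarity" is one category.
- **Per-stratum cutoff overrides** exist because evidence for some strata
  comes from different search types with different score statistics (the
  packaged default is 10⁻³ everywhere; a stricter 10⁻¹⁵ override is the
  documented choice for translated-nucleotide evidence).

Making any cutoff stricter can only move ages to equal or younger
(larger index); this monotonicity is property-tested against a brute-force
filter-then-min oracle.

## Trend statistics

Spearman's ρ is computed between stratum index and per-stratum **means**
(medians are reported alongside in the summaries); strata with no genes
are excluded and at least three usable strata are required. Constant means
leave ρ undefined (NaN with a warning) rather than an arbitrary 0.

Per-stratum significance is a two-sample KS test of the stratum against
all other strata. The original analysis idea ("permutations plus KS
tests") leaves the permutation scheme open; the implemented choice —
shuffle stratum labels over loci, i.e. compare against random same-size
subsets — is the simplest exchangeable null and is itself calibrated by
test: under label shuffling the empirical p-values are uniform (checked
over 100 seeds at 500 permutations). p-values use the add-one estimator,
so the smallest reportable p is 1/(B+1); the default B is 10,000 and the
flagging threshold p < 0.01 is exposed in configuration. KS statistics are
two-sided; inside permutation loops the D statistic is computed by a small
vectorized routine (tested equal to `scipy.stats.ks_2samp`) because the
full test call's overhead dominates at 10⁵ calls.

The chromosome-scatter test reuses the same machinery: stratum-s TSS
positions against all TSS positions on the chromosome, null by resampling
same-size gene subsets. The youngest stratum's exon-length comparison is a
Welch (unequal-variance) two-sample t-test of psP against the rest.

## Enrichment

- **TSS–mark association**: distance 0 inside an interval, otherwise base
  pairs to the nearest covered base; the 1,250 bp boundary is inclusive.
  Intervals are 0-based half-open (BED native). Chromosomes missing from a
  mark set make their genes unassociated, logged once.
- **Log-odds** are base 2 with the Haldane–Anscombe +0.5 correction when
  any cell of the 2×2 table is zero; an empty stratum is NaN, not 0.
- **Two-sidedness**: the reported p is twice the smaller hypergeometric
  tail, capped at 1, with direction read from the log-odds sign. Whether
  the original tests were one- or two-tailed is not documented; two-sided
  is the conservative choice and both tails are exposed.
- **Bidirectional promoters** have no standard operational definition; the
  implemented criterion — an opposite-strand TSS within a configurable
  window, default 1,000 bp, the scale of a shared nucleosome-free region —
  is a documented stand-in, and the window is a parameter.
- **Correction**: BH across the P strata for mark profiles, Bonferroni for
  expression-set profiles; α = 0.01 by default. The "any mark" property is
  the union of the three marks.

## Alignment

Alignments are optimal affine-gap DP alignments (Biopython's
PairwiseAligner). Defaults mirror the conventions of the classic tools for
this job: nucleotide +5/−4, protein BLOSUM62, gap open −10 / extend −0.5
(the first gap column costs the open score). Global mode penalizes end
gaps. The aligner's first traceback is reported; it is deterministic, so
outputs are bit-reproducible. Scores are verified against an independent
recursive oracle that explores every alignment (exhaustively validated on
tiny inputs, then used for all two-letter pairs up to length 6 and random
nucleotide pairs up to length 8).

Match/non-match decisions use percent identity over aligned columns plus
an aligned-length floor, **not e-values**: reproducing database-size-
dependent e-value statistics is out of scope, and the screen's decision
only needs to separate two regimes that are far apart (same-frame homology
tracks nucleotide identity; frame-shifted translation has near-random
protein identity). Thresholds — nucleotide ≥ 80% over ≥ 60 columns,
protein ≥ 40% over ≥ 20 columns — sit in the wide margin between those
regimes and are all configurable. The protein column floor matters: best
local alignments of unrelated proteins routinely reach 40–60% identity
over a handful of columns, but not over 20.

Translation uses the standard genetic code, drops the trailing partial
codon, truncates at the first stop and renders any N-containing codon as X.

## Overprint screen

The ≥ 2-stratum age gap guards against borderline classifications between
adjacent strata. Within a candidate locus, every younger product is
compared against every product of the oldest stratum. Verdicts:
`arf` = nucleotide-match and protein-non-match; `same_frame` = both match;
`unresolved` = anything else (including pairs with a missing sequence,
which are reported rather than dropped). For an `arf` the frame offset is
`(older_start − newer_start) mod 3` of the best local nucleotide
alignment. Local alignments drive the decision; global identities are
reported for transparency (requiring both to agree is a stricter variant
the data did not need: local and global agree on all synthetic cases).
Downstream manual curation steps (start/stop conservation in other
species, gene-tree inspection) are outside the package; the report is the
hand-off point.

## Synthetic generator

The generator is the stand-in for genome-database inputs. What it emulates:

- **Feature trends**: lengths are log-normal, counts shifted Poisson —
  strictly positive and right-skewed like real feature distributions —
  with per-stratum means interpolating log-linearly between a ps1 and a
  psP endpoint. Defaults (gene length 30 kb → 2.5 kb, ORF 1,500 → 450 nt,
  exons 9 → 1.3, domains 3 → 0.25, flat 250 bp exon length with a 1.5×
  youngest-stratum boost, 300 genes in each of 20 strata) encode the
  qualitative structure of a mammalian phylostratigraphy: younger genes
  shorter, simpler, with fewer domains, and only the youngest stratum with
  longer exons.
- **Hit tables**: a gene of true stratum s hits taxa of strata s..P
  (labels drawn from the packaged mouse map when P = 20, so synthetic data
  exercise the same code path as real data), qualifying e-values log-
  uniform below the cutoff, plus configurable false negatives,
  non-qualifying older hits (e ≥ 10⁻³) and self-hits.
- **Marks**: association is Bernoulli per gene with background rate 0.30;
  in the youngest stratum the odds are multiplied by 2 for unidirectional
  and by a further 4 for bidirectional loci, concentrating the enrichment
  on divergent promoters. A quarter of loci are laid out as divergent
  pairs (opposite strands, TSSs within 1 kb) that share one promoter and
  one association draw.
- **Overprints**: the constructor copies a stretch of an existing ORF at
  frame offset 1 or 2, edits the minimal bases to create a start codon and
  remove in-frame stops (the lowest-cost start position is chosen; budget
  2% of the stretch, at least 3 bases), and appends a terminator — the
  two products share ≥ 98% of their nucleotides but not their reading
  frame. Planted alongside are same-frame splice-variant decoys and
  unrelated-ORF decoys so that screen specificity is actually exercised.

Unrelated transcription units are spaced ≥ 10 kb apart, so a planted mark
can never leak into another gene's 1,250 bp window: the emitted files
reproduce the truth exactly, which is what makes noise-free recovery a
meaningful test (assignment accuracy 1.0, screen sensitivity and
specificity 1.0).

What it does **not** emulate, and hence what passing tests do not show
about real data: sequence evolution (no substitution model beyond the
constructor's edits), splice-graph structure, annotation error,
correlated features, gene families and paralogy, real promoter
architecture, or realistic e-value distributions. Recovery results on
synthetic data certify the *pipeline's correctness*, not the biological
error rate of phylostratigraphy on real genomes.

Presets: `noise-free` (20×5 loci, 5 overprints, no noise), `paper-like`
(20×300, strong trends, 13 overprints, seed 42), `zero-trend` (flat
trends, no mark boost — the null for calibration). Identical config and
seed give byte-identical outputs.

## Problem sizes in the test suite

The suite runs everything at desk scale: calibration loops use 100 seeds
at 500 permutations on 4×30-gene tables; the oracle-equivalence sweep
covers all 15,876 two-letter sequence pairs up to length 6; parameter
recovery runs one noise-free (100 loci) and one paper-like (6,000 loci)
generation. The full suite completes in well under a minute on one CPU.

## Known limitations

- Strata are totally ordered; reticulate or ambiguous taxon placements
  must be resolved by the user's stratum specification (unmapped taxa are
  errors by design).
- The screen classifies annotated product pairs only; it cannot discover
  unannotated reading frames.
- Identity thresholds replace e-value significance for local alignments;
  for borderline diverged overprints (nucleotide identity near 80%) the
  verdict is sensitive to `t_nt`, and the report carries the raw
  identities so such cases can be re-examined.
- The hypergeometric model treats genes as exchangeable units; it ignores
  gene length and clustering biases that affect real mark association.
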