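# Methods

## Problem and model

A miRNA gene is modelled as a hairpin interval on a chromosome with up to
two mature miRNAs (one per arm), a terminal loop, and user-chosen flanks.
In gene orientation the functional regions tile the interval
`[-flank5p, hairpin_length + flank3p)` without gaps or overlaps:

```
flank5p | arm5p(lower) | mature5p | arm5p(upper) | loop | arm3p(upper) | mature3p | arm3p(lower) | flank3p
```

with seed = nt 2–7 of each mature. An absent mature collapses its arm
subdivision into a single arm segment. Unbounded `upstream`/`downstream`
pseudo-regions extend past the flanks up to a reporting window (default
2000 nt outside the hairpin); variants there are located but not folded,
since the transcript context does not contain them.

The impact of a variant is assessed on secondary structure: the hairpin ±
flanks is extracted in gene orientation as RNA, the variant introduced
(alleles complemented for minus-strand genes), and both sequences folded.
A base counts as changed when its paired/unpaired status differs between
wild-type and variant structures after realigning variant positions to
reference coordinates; a `(`↔`)` flip alone is not a change, deleted bases
are not compared, and inserted bases carry no reference coordinate (their
position is expressed by the variant's own location annotation). Changed
positions are grouped into maximal runs and rendered in the annotation
grammar; comparison is done independently for the MFE, MEA and centroid
representations.

## Folding configuration

ViennaRNA computes the MFE structure and energy, the partition function,
and MEA and centroid structures, with dangling-end energies on both sides
of each helix (model `dangles = 2`); MEA gamma is left at the backend
default. MEA and centroid free energies are evaluated on the same energy
model, so the MFE energy is a lower bound for both. The MFE-structure
ensemble frequency is its Boltzmann probability under the partition
function. Energies drift across thermodynamic-parameter versions, so the
backend name and version are recorded in each run's metadata and
byte-identical output is only guaranteed for a fixed backend version. A
mock backend returning caller-specified structures verbatim makes every
module downstream of folding bit-exactly testable.

## Annotation grammar

`region(reference ± offsets)[seed]`, components joined by `&`, all in gene
orientation. Reference letters name the boundary offsets are counted from:
`a` arm junction, `m` mature, `l` loop; offsets are 1-based, positive
downstream of the boundary, negative upstream. Within arms the nearer of
the two named boundaries is used (ties go upstream); mature and loop
regions, whose two boundaries are both arm junctions, count from the
upstream one — this matches every printed convention for such strings
(e.g. positions late in a mature are still `a+19:20` from the upstream
junction). Flank and upstream/downstream positions count from the hairpin
edge (`a`). Runs in the same region with the same reference merge into one
comma-separated offset list (`2,5,8:9`); an `e` marks an offset where a
run reaches or crosses a region edge, placed on the exit side when a run
continues into the next region (`mature3p(a+21:22e)&arm3p(m+1:3)`).
Insertions are annotated at the base immediately 3' of the insertion
point. The grammar parses back losslessly (format→parse→format is the
identity), which the test suite enforces on every emitted string.

Highest impact is the most important region class among structural
changes, ordered seed > mature > arm > loop > flank, or `none`.

## Conservation

The hairpin-covering slice of the flanked wild-type structure is compared
against the fold of the bare hairpin; identical pairing gives
`conserved`, otherwise `changed(N)` with N the number of differing hairpin
bases. A non-conserved hairpin signals that the prediction depends
strongly on the chosen flank size and should be treated with caution.

## Databases and loop inference

miRBase-style GFF3 carries no loop feature, so the loop is inferred as the
maximal unpaired run enclosed by the innermost base pair of the MFE fold
of the bare hairpin; with multiple terminal loops the one between the two
matures (else the largest) is chosen, and a loop overlapping a mature is
shifted to abut the mature boundary. A pair-free fold flags the gene and
uses the whole hairpin as loop. The TSV dialect stores the loop
explicitly, so a curated database can be supplied instead; matures are
assigned to arms by their position relative to the loop, and a second
mature on the same arm is dropped with a warning. The TSV stores no mature
names; reading synthesizes `<gene>-5p`/`-3p`.

## Variant handling

Input alleles are genome-strand; complementation to the gene strand
happens internally. VCF records are split per ALT and normalised by
trimming shared trailing then leading bases to classify snp/ins/del;
symbolic and complex alleles are skipped with a warning. The reference
allele is verified against the genome at analysis time — a mismatch
aborts with the observed base, signalling a stale genome or wrong build.
Deletions overlapping the folded-context boundary are clipped with a
warning; flanks are clipped at chromosome ends.

## Evaluation statistics

ΔΔG = ΔG(variant) − ΔG(wild-type) on the MFE structures. The `abs_gt0`
strategy calls |ΔΔG| > 0 positive; the `interval` strategy calls ΔΔG
outside (−2.103226, 4.324731) positive — the documented defaults are the
kernel-density crossing points from the published evaluation set, and
`density_interval` recomputes such thresholds from any two ΔΔG samples.
The hairpin approach calls a variant positive when its highest structural
impact lies within the hairpin (seed, mature, arm, loop). Variants farther
from the hairpin than the flank have no structure prediction and are
forced negative. Sensitivity = TP/(TP+FN)·100 and specificity =
TN/(TN+FP)·100 are rounded to integers for reporting (raw ratios kept on
the table object); undefined denominators yield NA.

The two-sided Fisher exact p sums hypergeometric probabilities of all
tables at fixed margins that are no more likely than the observed one
(probability-mass rule, the convention of R and scipy), computed as a
vectorized pmf sum; tests pin it against exact integer enumeration for all
2×2 tables with total ≤ 40 and against `scipy.stats.fisher_exact`.

`density_interval` evaluates Gaussian KDEs (scipy, Scott's rule by
default; bandwidth exposed because thresholds depend on it) of both ΔΔG
groups on a shared 4096-point grid, locates sign changes of the density
difference by linear interpolation and returns the crossings bracketing
the unchanged-group mode. Well-separated groups can have all crossings on
one side of the mode; the missing bound is then ±inf (a one-sided
interval). Identical samples have no crossing and raise "degenerate
densities".

## Synthetic fixtures

Designed hairpins are `arm + loop + revcomp(arm)` with GC-only stems
(60/40 G/C), an A/C loop and A/C-biased flanks, chosen so the flanks
cannot pair with the stems and the designed fold is the unambiguous
optimum under any sane thermodynamic model. Defaults: 30 bp stem, 8 nt
loop, 22 nt matures at hairpin-relative [4,26) and [42,64), 2500 nt
chromosome padding, one gene per chromosome, strands alternating. Variants
are pair-breaking SNPs placed per region class (flank, lower arm, seed,
loop, matures, upper arm, upstream/downstream at 150 nt, plus one 2100 nt
away expected to be absent from output), with expected location
annotations derived by offset arithmetic independent of the annotation
module. What the fixtures do not emulate: natural bulges and internal
loops, isomiR heterogeneity, sequence-motif determinants of processing,
and realistic genome composition — passing tests demonstrate coordinate,
grammar and pipeline correctness, not predictive accuracy on real
variants.

## Numerical and design choices

* Flanks default to 100 nt each (the usual size needed around a hairpin
  for in-vivo overexpression constructs); the reporting window is 2000 nt.
* Energies render with one decimal (kcal/mol), ensemble frequencies with
  six significant digits; −0.0 is normalised to 0.0.
* The nearby-gene query uses half-open interval overlap of the hairpin
  expanded by the window, so a variant exactly `window` nt away is
  excluded and `window − 1` nt is included.
* Analysis output ordering is deterministic (input order × gene
  coordinate), and reruns on identical inputs and backend versions are
  byte-identical.
* The acceptance script evaluates the published strategy statistics from
  the printed 42-pair contingency tables (the genome-scale reproduction
  of the original evaluation requires hg19 and a miRBase-derived
  database, which are deliberately not bundled); its from-scratch checks
  run on the synthetic fixture at 2 genes × 11 variants and a 1000-pair
  randomized structure-diff comparison.

## Known limitations

* Pseudoknots are outside the dot-bracket model.
* Multi-nucleotide substitutions and complex indels beyond
  trim-normalisation are not supported.
* Whether upstream-of-gene alleles should be complemented for
  minus-strand genes is a convention choice (genome-strand input is
  assumed); supplying gene-strand alleles will trigger the
  reference-allele check for non-palindromic bases.
* The HTML report renders annotated linear dot-bracket strings, not 2-D
  structure layouts; record objects keep the per-base payload an external
  renderer would need.
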