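# Methods

## The filtering problem

Spliced alignment with transcript-aware, permissive settings maximizes the
number of reads placed across exon–exon junctions — and hence detection
sensitivity and count accuracy — at the cost of spurious gapped
alignments that materialize junctions which are not expressed. Because no
reliable positive training set exists (the full transcriptome is unknown
by assumption), the filter works semi-supervised: it labels a small subset
of *patently* anomalous junctions, assumes the rest is predominantly
correct, and lets a regularized classifier generalize the anomaly
signature to borderline cases.

## Overhang model

For a read of length `L` spanning a junction, the overhang is
`o = min(l, r)` over the two aligned arm lengths. Under random
fragmentation `o` is discrete-uniform on `{o_min, …, o_max}`. Defaults:
`o_min = 1`, `o_max = ⌊L/2⌋` with `L` the modal read length in the input;
both are configurable because aligners with a minimum anchor length shift
the support. When reads of mixed lengths occur, junctions spanned only by
shorter reads use their own `⌊L/2⌋`.

Mismatch positions are recovered from the MD tag (via pysam's reference
reconstruction; no genome FASTA needed). Each overhang is trimmed at the
first mismatch from the splice site within the shorter arm, penalizing
the systematic near-splice mismatches typical of misalignments. When MD is
absent and NM > 0, positions are unknowable and the read is kept
untrimmed but flagged.

## Labelling rule

A junction with `n` unique reads is labelled POTENTIAL_FP when either

* **single-mismatch rule** — its reads mismatch at exactly one distinct
  position `p*` of the overhang arm, no raw overhang exceeds `p*`, and
  `1 − F(p*)^n > α` with `F(p) = (p − o_min + 1)/(o_max − o_min + 1)` and
  `α = 0.99`; i.e. at this read depth at least one longer overhang would
  almost surely have been observed under uniformity; or
* **no matching overhang** — every trimmed overhang is 0.

"A single mismatch" is read as *one distinct mismatching position across
the junction's reads*, not one mismatching read: the exceedance
probability refers to "the first mismatching position", a per-junction
quantity. The remaining junctions are PRESUMED_OK; label noise in that
class is tolerated by construction.

## Features and classifier

`x_p = log2((C_p + c)/(E_p + c))` for `p = o_min … o_max − 1`, with
observed exceedance counts `C_p` from trimmed overhangs, uniform
expectation `E_p = n (o_max − p)/(o_max − o_min + 1)`, and pseudocount
`c = 0.5` applied symmetrically so that `x_p` is finite everywhere and
exactly 0 at `C_p = E_p`. The index `p = o_max` is excluded (`E_p = 0`).

The logistic regression is fitted by scikit-learn's saga solver with a
pure L1 penalty (`l1_ratio = 1`), inverse strength `C = 1.0` (flag
`--l1-C`), tolerance 1e-6, at most 10⁴ epochs; non-convergence logs a
warning and uses the last iterate. saga leaves the intercept unpenalized,
so in the strong-penalty limit the model degenerates to a constant
posterior as it should. One solver caveat: saga's stopping criterion
tracks only the coefficients, so at extreme penalties the intercept can
stop short of the exact class-prior logit — the weights are still all
zero and the posterior is constant. Features are left unstandardized:
they share a common log2 scale by construction.

Junctions are discarded when the posterior of the false-positive class
strictly exceeds 0.5 (`--posterior-threshold`). Labelled junctions are
re-scored like all others and can survive a low posterior; pass
`--hard-labels` to discard them unconditionally. Degenerate cases: with no
POTENTIAL_FP label no model is fitted and everything is accepted with
posterior 0 (logged prominently); with no PRESUMED_OK junction the run
aborts — the scheme is undefined without both classes. Junctions
supported only by multireads cannot be evaluated and are auto-discarded.

## Multiread rescue

A multiread is rescued when, after filtering, exactly one of its gapped
alignments has all spanned junctions accepted, every other gapped
alignment contains a discarded junction, it has no ungapped alignment
(a contiguous genomic hit survives junction filtering, so the location
stays ambiguous), and all NH-reported hits were actually observed in the
file. The read then adds +1 to each junction of the surviving alignment.
Rescued counts do not feed back into the fit; the pipeline is single-pass.

## Alignment parsing conventions

* Introns are 0-based half-open internally; output follows each format.
* Uniqueness is NH = 1; without NH, MAPQ ≥ 50 stands in (TopHat2's
  unique-hit convention). Secondary alignments only ever feed the
  multiread index.
* Strand comes from the XS tag; junctions equal in coordinates but
  different in strand are distinct.
* Arm lengths are read-consuming lengths (M/I/=/X); deletions do not add
  to the overhang. Observations with an indel within 3 bp of the splice
  site are excluded from evidence (configurable), since the effective
  anchor length is ambiguous there.
* Paired-end mates are independent observations by default
  (`--collapse-pairs` keeps one observation per fragment and junction).
* A read spanning k junctions contributes one independent overhang to
  each.

## Synthetic data generator

The simulator emits valid coordinate-sorted SAM (fictitious contigs, MD
tags synthesized directly — the algorithm never reads the genome) plus a
truth table. Its defaults are the conditions the filter is designed for:
2000 expressed junctions with uniform overhangs at 50 bp reads,
background mismatch rate 0.002/bp (a typical Illumina substitution rate),
200 artefactual junctions with overhangs capped at 4 bp and a recurrent
mismatch position drawn per junction from {1..4} (every read reaching
that position mismatches there, one such read guaranteed; background
mismatches on artefactual reads are confined to the long arm so the
single-position signature stays intact), ~20 reads per junction drawn as
1 + Poisson(mean − 1) so every junction is detectable, and 10% of
expressed-junction reads emitted with NH = 2 plus a secondary alignment
across a random artefactual junction as rescue material.

What a green end-to-end test establishes — and what it does not: the
simulated artefacts are stereotyped (hard overhang cap, one anomalous
position), so the filter separates the classes nearly perfectly; real
artefactual alignments are heterogeneous (quality-dependent error
clusters, paralogy, repeats), and real precision gains are smaller. The
generator models neither an expression distribution, nor fragment-level
biases, nor indels, nor base-quality structure.

## Numerical and tie-break choices

* Ties `l = r` assign the overhang arm to the left arm (affects only
  which arm's mismatches are counted).
* The labelling probability uses the closed form `1 − F(p*)^n`; it is
  validated in the tests against exhaustive enumeration and Monte-Carlo
  simulation.
* The posterior threshold uses a strict inequality (0.5 itself is kept).
* Unweighted likelihood: the OK class dominates by design and its label
  noise is tolerated; class weighting would inflate the influence of the
  small labelled set.
* Uniformity checks on discrete overhangs use a chi-square test plus a
  discrete Kolmogorov–Smirnov statistic compared against the continuous
  critical value (conservative for discrete laws); off-the-shelf
  continuous KS p-values are invalid for discrete data.

## Known limitations

* No sequence-derived features (splice-site consensus, intron length,
  coding potential) — deliberately: the filter uses only mapping-derived
  evidence, which keeps it aligner-agnostic downstream of any tool that
  reports NH/MD/XS.
* Junction detection universe is unique gapped alignments; junctions
  covered exclusively by multireads are never callable.
* The rescue step requires NH to be trustworthy; files with incomplete
  secondary records simply rescue nothing (conservative).
* With very shallow data (few reads per junction) the labelled set can be
  empty, in which case no filtering occurs and the output equals the
  input junction set.
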