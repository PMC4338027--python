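# Methods

This note documents the models, rules, defaults and numerical choices
behind the toolkit, and what the synthetic test bed does and does not
establish about behaviour on real data.

## Coordinates and normalization

All internal coordinates are 0-based half-open; conversion happens only at
I/O boundaries (VCF is 1-based and shifted on read). VCF indel alleles are
normalized by trimming the shared suffix and then the shared leading
anchor base, with the coordinate adjusted and a `prefix_trim` note
attached. Left-alignment across repeat tracts is deliberately **not**
performed: the annotation cache and all catalogs are keyed positionally by
*(start, end, variant type, ref, alt)*, and left-alignment would make
cache keys representation-dependent. Multi-allelic VCF lines are split one
record per alternate allele, with each sample genotype re-expressed
against the split allele (other alternates become `.`).

## Validation and auto-correction

The coordinate convention is decided once per file: the convention
(0- or 1-based) whose direct reference-match fraction over non-insertion
records is strictly greater wins; ties default to 0-based. This is
file-global because per-record convention switching would silently mask
genuine errors in mixed files. After the global decision, each record is
matched against the reference in the fixed precedence

    match > shift_match > swap_match > strand_match > mismatch

and the single applicable correction (coordinate shift, ref/alt exchange,
reverse-complement of both alleles) is applied and noted. Compound errors
(e.g. shifted *and* swapped) are never repaired — such records are
rejected with a reason, and a record that still appears shifted after a
global 1-based correction is likewise rejected. Corrections are counted
per run, so resubmitting the accepted output is idempotent: it yields zero
corrections and zero rejections. Insertions carry no reference bases, are
unverifiable, and inherit the file-level convention.

The precedence order matters in corner cases: on some genomes a true
strand flip can also be explained by a coordinate shift, and the earlier
status wins. The test suite pins this behaviour with an exhaustive
brute-force oracle on genomes up to 50 bp.

## Transcript model and coding consequences

A transcript is sorted non-overlapping exons, an optional CDS interval
(spliced length divisible by 3), per-residue conservation weights (length
= spliced CDS / 3; uniform 1.0 when absent), and optional alternative
start residues. Consequences are computed on the strand-corrected spliced
CDS with the standard genetic code: SNV/MNV changes translate ref and alt
CDS and compare proteins (stop gain = nonsense); CDS indels are
frameshift when the disturbed length is not a multiple of 3, otherwise
in-frame.

Splice windows (field-standard bounds, since only "donor/acceptor" vs
"nearby" is distinguished upstream): donor/acceptor are the first/last two
intronic nucleotides (strand-aware), `splice_region` is intronic positions
3–8 from either junction plus the last three exonic bases of a junction.
When a coding substitution inside the exonic splice-region window changes
the protein, the protein-level effect is reported; `splice_region` is
reported for protein-silent changes there. UTR assignment is strand-aware
(5' vs 3' by position relative to the CDS on the transcript strand).

## Annotation engine and cache

Every overlapping transcript is annotated — there is no canonical-
transcript selection — and per-transcript values are kept positionally
parallel across columns (`///` separation; `-` null; `~` composites, with
`-~-` for null composites so partially complete outputs stay aligned).
Region features (TFBS instances, etc.) intersect on half-open intervals;
an insertion is the zero-length point at its start, so an insertion at a
feature's end coordinate does not hit it.

The cache is one store per chromosome keyed by the five variant
characteristics, persisted as sorted TSV (JSON payload per key). Only
annotation columns are cached; zygosity, record ids, correction notes and
genotypes are submission-level and are re-attached per request. The suite
verifies cache transparency (warm, hit and cold paths value-identical)
and that the persisted form round-trips losslessly — annotation values
are stored as strings from the start for exactly this reason.

Missing allele frequency is rendered `-` but treated as 0 by the
classifier's rarity tests: a variant never observed in any reference
population must be classifiable as rare.

## Predictors: defaults and rationale

* **Truncation**: score = conserved mass removed / total conserved mass,
  with re-initiation rescue at the most downstream annotated alternative
  start (`stop < s*` removes only residues `stop..s*-1`). Damaging at
  ≥ 0.25 (configurable). The exact upstream formulation is not public;
  this rule honours the stated contract (fraction of conserved protein
  removed, adjusted for alternative starts) and makes "rare truncating
  variants not predicted to damage protein function" a realizable class.
* **In-frame indels**: conserved mass of disrupted residues / total;
  damaging at ≥ 0.05 or when any disrupted residue has weight ≥ 0.9.
  This is the weakest-fidelity predictor and is flagged as such.
* **TFBS**: best PSSM score over all offsets of both strands of the site
  window (feature ± width−1); both strands because BED instances are
  strand-ambiguous. Damaging when `best_alt < 0.7 · best_ref` with
  `best_ref > 0`. Ambiguous bases score the position average.
* **Splice region**: relative score `r = (score − min)/(max − min) ∈
  [0,1]` of the donor PWM (exonic −3..intronic +6) or acceptor PWM
  (intronic −14..exonic +1) at the affected junction; damaging when r
  drops from ≥ 0.7 to < 0.7. Defined for substitutions only.
* **miRNA targets**: canonical seed matching (8mer, 7mer-m8, 7mer-A1;
  exact Watson-Crick complement of miRNA positions 2–8, A opposite
  position 1); variant impact is the set difference between ref and alt
  scans, which also covers variants inside the miRNA itself via rescan.
  U and T are equivalent.
* **Missense**: pluggable. The bundled default calls damaging iff the
  residue's conservation weight is ≥ 0.5 and the substitution crosses
  physicochemical classes ({nonpolar, polar, aromatic, acidic, basic,
  special}); a lookup predictor loads tabulated third-party calls.

All thresholds above are documented defaults exposed as parameters; none
is fitted to data in this repository.

## Classification

Classes `1 < 1* < 2 < 2* < 3 < 4 < 4* < 5 < 6`, first matching rule wins.
"Rare" is max AF < 0.01; "uncommon" the closed interval [0.01, 0.05] —
boundaries belong to the starred tier. Rules 1/1\*/2/2\* follow the
published tiering. The intermediate tiers are this package's refinement,
preserving the gradient from "most clinical relevance" to "common risk
factor": 3 = rare variant of uncertain impact in an in-scope gene; 4 =
rare predicted-damaging variant outside disease genes; 4\* = rare coding
variant of uncertain impact outside disease genes; 5 = likely benign
fallback. Research mode widens the in-scope gene set from `clinical` to
`clinical ∪ research` and adds rule 6 (reported risk association with
max AF > 0.05). Rule 6 is evaluated *before* the tier-5 fallback —
written after it, a first-match engine could never reach it, since tier 5
also captures max AF > 0.05.

Threshold-or-better evaluation: class c meets threshold t iff c ≤ t in
the total order, so threshold "1–2" (class 2) includes 1 and 1\* but not
2\*. Sensitivity/specificity/balanced accuracy are computed from the
resulting confusion counts. The published benchmark set (SWISS-PROT
disease/neutral, tens of thousands of variants over licensed catalogs) is
out of scope; the bundled labeled set is synthetic and engineered to
populate every class.

## Privacy tool

Stripping is a pure text projection (drop FORMAT/sample columns and
`##FORMAT` headers), guaranteeing deterministic output bytes. Decoys are
drawn uniformly without replacement (seeded) from the catalog entries not
already present in the input — default k = 1% of the input, minimum 10 —
and the merged file is coordinate-sorted so implanted records are not
positionally identifiable. No manifest is stored anywhere: removal is
key-set subtraction of the returned annotation table against the original
file, which never leaves the client. Uniform sampling makes the round
trip exactly testable; distributional indistinguishability beyond
uniformity (e.g. matching genome-wide spacing of real pathogenic
variants) is explicitly not claimed.

## Filter engine

Multi-valued `///` cells use ANY-semantics (a row passes if any parallel
entry passes; ALL available per call). `-` cells satisfy only `is_null` —
absence is not a value and never compares numerically. Compound filters
are AND/OR trees with order-independent evaluation. Undo/redo replays the
active prefix of the filter stack from the base table, so the visible row
set always equals a from-scratch replay. Compound-het detection uses
parental-origin exclusivity (child het; het in exactly one parent,
hom-ref in the other; a gene qualifies with ≥ 2 such variants covering
both parents) — no read-backed phasing. Summary statistics count each row
once per dimension, using the fixed severity order nonsense > frameshift
> splice_donor/acceptor > missense > in-frame > splice_region >
synonymous > UTR > intronic > intergenic. Pages hold 1000 rows.

## Synthetic test bed

Every generator is a pure function of (seed, generator name) — streams
are derived per generator so adding one never shifts another's output —
and regeneration is byte-identical. The default universe is one 9 kb
chromosome with 6 genes (3 exons each, canonical GT/AG introns, valid
ORFs, 9 nt UTRs, random per-residue conservation), including one
minus-strand gene, one two-isoform gene and one gene with an annotated
alternative start; two width-8 TFBS PSSMs with consensus sites planted
intergenically; donor/acceptor PWMs whose consensus equals a real fixture
junction (so the reference relative score is exactly 1.0) with a heavily
weighted splice-region position; and a miRNA with a planted 8mer site.
Variant files plant a controlled error mix (default 90% clean / 5%
swapped / 5% irreconcilable); trio VCFs plant de-novo, recessive-hom and
compound-het configurations over an intergenic Mendelian background
constructed so no background site can satisfy an inheritance filter by
chance.

What this does not show: performance on real genome scale, realistic
population genetics (LD, site-frequency spectra), real splice/TFBS motif
statistics, or concordance with third-party missense predictors. The
suite demonstrates correctness of the machinery — coordinate handling,
strand logic, caching, rule order, round trips — on inputs whose ground
truth is known by construction. Problem sizes (100-variant files, ~30-site
trios, 45-item labeled set) were chosen so the entire suite and the
acceptance script run in seconds.

## Acceptance script

`scripts/acceptance.py` computes the two reference scenarios through the
rule engine at run time (a rare reported pathogenic variant → class 1; an
unreported rare splice-donor ablation in a disease gene → class 2),
reporting the class magnitude (integer part, starred tiers at +0.5), and
additionally regenerates the seeded universe and runs validation and
annotation over it as a self-check that aborts on any inconsistency.
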