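# adviser

A local, self-contained toolkit for clinical interpretation of human
sequence variants: reference-guided validation with auto-correction,
transcript-aware annotation with a pre-annotation cache, de-novo
functional-effect predictors for the variant classes that cannot be
tabulated ahead of time, an ordered ACMG-style classification schema
("ADVISER classes"), a decoy-implantation privacy tool, and an
inheritance/annotation filtration engine. It is aimed at researchers and
clinical analysts who need an auditable, offline variant-interpretation
pipeline whose every rule and threshold is inspectable, and at method
developers who need a fully synthetic, seeded test bed for such
pipelines.

## What it computes

**Validation.** Variants (VCF v4.x, Complete-Genomics-style var TSV, or
plain 0-based TSV) are checked against the reference genome. The
coordinate convention (0- vs 1-based) is inferred per file by majority of
direct vs shifted reference matches; per-record mismatches are repaired in
the fixed precedence *coordinate shift > ref/alt swap > strand flip*, each
repair is annotated in the output, and irreconcilable records are rejected
without stopping the run.

**Annotation.** Each validated variant is annotated against every
overlapping transcript (no canonical-transcript selection). Columns with
per-transcript values are `///`-separated and positionally parallel across
columns; `-` is the null, and composite values render as `Value1~Value2`
(`-~-` when null). Results are cached per chromosome under the key
*(start, end, variant type, ref allele, alt allele)*; a resubmitted
variant is served from the cache, and the cache never stores genotypes or
any submission-level data.

**Prediction.** For a truncating variant stopping translation at residue
*s* of an *L*-residue protein with per-residue conservation weights *w*,
the damage score is

    T = C(s..L) / C(1..L),        C(a..b) = sum of w over residues a..b

or `C(s..s*-1)/C(1..L)` when an annotated alternative start `s* > s`
allows re-initiation; damaging at `T >= 0.25`. TFBS variants are scored as
`best_alt - best_ref` of a PSSM scanned over both strands of the site
window (damaging when `best_alt < 0.7 * best_ref`). Splice-region variants
(non-donor/acceptor) are scored by the drop of the min-max-relative PWM
score at the junction; miRNA target gain/loss is a rescan of canonical
8mer/7mer-m8/7mer-A1 seed sites; missense impact is a pluggable predictor
(bundled default: conservation-gated physicochemical-class rule).

**Classification.** Classes are ordered `1 < 1* < 2 < 2* < 3 < 4 < 4* < 5
< 6` (lower = more clinically significant); e.g. class 1 = rare (<1% max
reference-population AF) reported pathogenic, 1\* = uncommon (1–5%)
reported pathogenic, 2 = rare predicted-damaging variants in known disease
genes, 6 = common reported risk factors (research mode). Evaluation
against a labeled set is threshold-or-better: a disease variant of class c
counts as a true positive at threshold t iff c <= t.

**Privacy.** Before upload, genotypes are stripped and k seeded decoy
variants from a clinically relevant catalog are mixed in (sorted output,
so decoys are not positionally identifiable); after annotation the decoys
are removed client-side purely by key-set subtraction against the original
file — no manifest is ever stored.

## Worked example

Everything below runs offline on generated data:

```
adviser fixtures --seed 1 --out fx/
adviser validate --ref fx/ref.fa --in fx/variants.tsv \
    --out report.tsv --corrected corrected.tsv
# convention=zero_based valid=90 corrected=5 rejected=5
```

The seed-1 fixture file plants 90 clean records, 5 ref/alt swaps and 5
irreconcilable records: the validator accepts the 90, repairs exactly the
5 swaps (reported as `allele_swap` in `report.tsv`) and rejects the rest.

```
adviser privacy strip --in corrected.tsv --out stripped.tsv
adviser privacy implant --in stripped.tsv --catalog fx/decoys.tsv \
    --k 5 --seed 7 --out implanted.tsv
# implanted 5
adviser annotate --ref fx/ref.fa --sources fx/ --catalogs fx/ \
    --cache cache/ --in implanted.tsv --out annotated.tsv
# annotated=100 de_novo=100 cached=0
adviser privacy remove --in annotated.tsv --original corrected.tsv \
    --out cleaned.tsv
# kept=95 dropped=5
adviser filter --in cleaned.tsv --expr 'maxAF<0.01 || maxAF?' \
    --stats stats.json --out filtered.tsv
```

Re-running the `annotate` step prints `de_novo=0 cached=100`: the second
pass is served entirely from the five-characteristic cache and produces a
byte-identical table. `annotated.tsv` rows carry the eight-column variant
block followed by the annotation columns, e.g. a variant overlapping both
isoforms of a gene shows `GENE0///GENE0`, `missense///missense`,
`p.Y26D///p.Y26D` in parallel, its max AF, catalog hits, and its ADVISER
clinical/research classes.

```
adviser evaluate --labeled fx/labeled.tsv --thresholds 1,2,3 \
    --mode research --out metrics.tsv
```

prints per-threshold confusion counts with sensitivity rising and
specificity falling as the threshold loosens from 1 to 3.

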