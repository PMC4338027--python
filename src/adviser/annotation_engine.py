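"""Transcript-aware annotation with a pre-annotation cache.

The engine computes, for every validated variant, the full set of
transcript-parallel annotations: the coding consequence on each
overlapping transcript, region overlaps (TFBS instances, conserved
elements, ...), the maximum allele frequency over the reference
populations, catalog lookups (reported pathogenic / risk assertions,
gene disease status) and de-novo predictor outputs.  Results are stored
in a per-chromosome cache keyed by the five variant characteristics
(start, end, variant type, reference allele, alternate allele); a second
submission of the same variant is served from the cache without
recomputation.  The cache never stores genotypes, zygosity, record ids
or any other submission-level information.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import Seq
from intervaltree import IntervalTree

from .variant_io import AnnotationRow, VariantRecord, revcomp

__all__ = [
    "TranscriptModel",
    "AnnotationSourceSet",
    "PreAnnotationCache",
    "CodingEffect",
    "annotate",
    "coding_effect",
    "max_allele_frequency",
    "region_overlaps",
    "EFFECTS",
]

EFFECTS = (
    "synonymous", "missense", "nonsense", "frameshift", "inframe_ins",
    "inframe_del", "splice_donor", "splice_acceptor", "splice_region",
    "utr5", "utr3", "intronic", "noncoding",
)

#: splice windows (transcript orientation): donor/acceptor are the first/last
#: two intronic nucleotides; splice_region covers intronic positions 3-8 and
#: the last three exonic nucleotides of a splice boundary.
DONOR_ACCEPTOR_NT = 2
SPLICE_REGION_INTRONIC = 8
SPLICE_REGION_EXONIC = 3


class ModelError(ValueError):
    """A transcript model violates its structural invariants."""


@dataclass
class TranscriptModel:
    gene: str
    tx_id: str
    chrom: str
    strand: str
    exons: list            # sorted, non-overlapping 0-based half-open pairs
    cds_start: int | None = None
    cds_end: int | None = None
    alt_starts: list = field(default_factory=list)   # 1-based residue indices
    conservation: list | None = None                 # per-residue weights

    def __post_init__(self):
        if self.strand not in "+-":
            raise ModelError(f"bad strand {self.strand!r}")
        self.exons = [(int(a), int(b)) for a, b in self.exons]
        last = None
        for a, b in self.exons:
            if b <= a or (last is not None and a < last):
                raise ModelError(f"exons of {self.tx_id} not sorted/disjoint")
            last = b
        if self.coding:
            covered = sum(max(0, min(b, self.cds_end) - max(a, self.cds_start))
                          for a, b in self.exons)
            inside = any(a <= self.cds_start < b for a, b in self.exons) and \
                any(a < self.cds_end <= b for a, b in self.exons)
            if not inside:
                raise ModelError(f"CDS of {self.tx_id} outside exons")
            if covered != self.cds_len or covered % 3:
                raise ModelError(
                    f"spliced CDS length {covered} of {self.tx_id} invalid")
            if self.conservation is not None and \
                    len(self.conservation) != covered // 3:
                raise ModelError(
                    f"conservation length != protein length for {self.tx_id}")

    # -- geometry -----------------------------------------------------------

    @property
    def coding(self) -> bool:
        return self.cds_start is not None and self.cds_end is not None

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_segments(self):
        return [(max(a, self.cds_start), min(b, self.cds_end))
                for a, b in self.exons
                if min(b, self.cds_end) > max(a, self.cds_start)]

    @property
    def cds_len(self) -> int:
        return sum(b - a for a, b in self.cds_segments)

    @property
    def protein_length(self) -> int:
        return self.cds_len // 3

    @property
    def introns(self):
        return [(self.exons[i][1], self.exons[i + 1][0])
                for i in range(len(self.exons) - 1)]

    def weights(self):
        if self.conservation is not None:
            return list(self.conservation)
        return [1.0] * self.protein_length

    def cds_index_of(self, gpos: int) -> int | None:
        """Map a genomic position to a 0-based index into the translated
        (strand-corrected) spliced CDS, or None if non-coding."""
        offset = 0
        for a, b in self.cds_segments:
            if a <= gpos < b:
                idx = offset + (gpos - a)
                return idx if self.strand == "+" else self.cds_len - 1 - idx
            offset += b - a
        return None

    def spliced_cds(self, genome: str) -> str:
        seq = "".join(genome[a:b] for a, b in self.cds_segments).upper()
        return revcomp(seq) if self.strand == "-" else seq

    def protein(self, genome: str) -> str:
        return str(Seq(self.spliced_cds(genome)).translate())


# ---------------------------------------------------------------------------

@dataclass
class AnnotationSourceSet:
    """Pluggable local annotation sources; any field may be left empty."""

    transcripts: list = field(default_factory=list)
    af_tables: dict = field(default_factory=dict)      # pop -> {key: af}
    pathogenicity: dict = field(default_factory=dict)  # key -> assertion
    risk: dict = field(default_factory=dict)           # key -> bool
    gene_catalog: dict = field(default_factory=dict)   # gene -> status
    regions: dict = field(default_factory=dict)        # name -> [(s,e,id)]
    pssms: dict = field(default_factory=dict)          # motif_id -> PSSM
    splice_pwms: tuple | None = None                   # (donor, acceptor)
    missense_predictor: object | None = None

    _tx_index: dict = field(default_factory=dict, repr=False)
    _region_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        for pop, table in self.af_tables.items():
            for key, af in table.items():
                if not 0.0 <= af <= 1.0:
                    raise ValueError(f"AF {af} for {key} in {pop} outside [0,1]")
        for tx in self.transcripts:
            pad = SPLICE_REGION_INTRONIC
            self._tx_index.setdefault(tx.chrom, IntervalTree()).addi(
                tx.start - pad, tx.end + pad, tx)
        for name, feats in self.regions.items():
            tree = IntervalTree()
            for s, e, fid in feats:
                tree.addi(s, e, fid)
            self._region_index[name] = tree

    def overlapping_transcripts(self, rec: VariantRecord):
        tree = self._tx_index.get(rec.chrom)
        if tree is None:
            return []
        if rec.vtype == "ins":
            hits = tree.at(rec.start)
        else:
            hits = tree.overlap(rec.start, rec.end)
        return sorted((iv.data for iv in hits), key=lambda t: (t.gene, t.tx_id))


# ---------------------------------------------------------------------------
# coding effect

@dataclass(frozen=True)
class CodingEffect:
    effect: str
    protein_change: str = ""
    stop_residue: int | None = None      # for truncating effects
    residue: int | None = None           # affected residue (1-based)
    ref_aa: str = ""
    alt_aa: str = ""


def _splice_hit(rec: VariantRecord, tx: TranscriptModel) -> str | None:
    """Splice classification of the variant interval, or None."""
    s, e = rec.start, (rec.end if rec.vtype != "ins" else rec.start + 1)

    def overlaps(a, b):
        return a < e and s < b

    donor = acceptor = region = False
    for i_start, i_end in tx.introns:
        if i_end - i_start < 2 * DONOR_ACCEPTOR_NT:
            continue
        left = (i_start, i_start + DONOR_ACCEPTOR_NT)
        right = (i_end - DONOR_ACCEPTOR_NT, i_end)
        if tx.strand == "+":
            d, a = left, right
        else:
            d, a = right, left
        donor |= overlaps(*d)
        acceptor |= overlaps(*a)
        # intronic splice-region nt 3-8 from either junction
        region |= overlaps(i_start + DONOR_ACCEPTOR_NT,
                           min(i_start + SPLICE_REGION_INTRONIC, i_end))
        region |= overlaps(max(i_end - SPLICE_REGION_INTRONIC, i_start),
                           i_end - DONOR_ACCEPTOR_NT)
    if donor:
        return "splice_donor"
    if acceptor:
        return "splice_acceptor"
    return "splice_region" if region else None


def _exonic_splice_region(rec: VariantRecord, tx: TranscriptModel) -> bool:
    s, e = rec.start, (rec.end if rec.vtype != "ins" else rec.start + 1)
    for idx, (a, b) in enumerate(tx.exons):
        if idx < len(tx.exons) - 1 and s < b and max(a, b - SPLICE_REGION_EXONIC) < e:
            return True
        if idx > 0 and s < min(b, a + SPLICE_REGION_EXONIC) and a < e:
            return True
    return False


def _in_exon(pos: int, tx: TranscriptModel) -> bool:
    return any(a <= pos < b for a, b in tx.exons)


def coding_effect(rec: VariantRecord, tx: TranscriptModel,
                  genome: str) -> CodingEffect:
    """Consequence of ``rec`` on one transcript, on the strand-corrected
    spliced CDS; ``genome`` is the chromosome sequence."""
    if not tx.coding:
        return CodingEffect("noncoding")

    splice = _splice_hit(rec, tx)
    if splice in ("splice_donor", "splice_acceptor"):
        return CodingEffect(splice)

    s = rec.start
    e = rec.end if rec.vtype != "ins" else rec.start
    cds_overlap = [i for p in range(s, max(e, s + (rec.vtype != "ins")))
                   if (i := tx.cds_index_of(p)) is not None]
    ins_in_cds = rec.vtype == "ins" and s > tx.cds_start and s < tx.cds_end \
        and _in_exon(s, tx) and _in_exon(s - 1, tx)

    if not cds_overlap and not ins_in_cds:
        if splice == "splice_region":
            return CodingEffect("splice_region")
        point_in_exon = _in_exon(s, tx) if rec.vtype == "ins" else \
            any(_in_exon(p, tx) for p in range(s, e))
        if point_in_exon:
            upstream = (s < tx.cds_start) if tx.strand == "+" \
                else (e > tx.cds_end if rec.vtype != "ins" else s >= tx.cds_end)
            return CodingEffect("utr5" if upstream else "utr3")
        return CodingEffect("intronic")

    # --- coding ------------------------------------------------------------
    if rec.vtype in ("snp", "sub"):
        cds = tx.spliced_cds(genome)
        alt_cds = list(cds)
        changed = False
        for off in range(len(rec.ref)):
            gpos = rec.start + off
            ci = tx.cds_index_of(gpos)
            if ci is None:
                continue
            base = rec.alt[off]
            alt_cds[ci] = base if tx.strand == "+" else revcomp(base)
            changed = True
        if not changed:
            return CodingEffect("intronic")
        ref_prot = str(Seq(cds).translate())
        alt_prot = str(Seq("".join(alt_cds)).translate())
        diffs = [i for i, (r, a) in enumerate(zip(ref_prot, alt_prot)) if r != a]
        if not diffs:
            if splice == "splice_region" or _exonic_splice_region(rec, tx):
                return CodingEffect("splice_region")
            res = cds_overlap[0] // 3 + 1
            aa = ref_prot[res - 1]
            return CodingEffect("synonymous", f"p.({aa}{res}=)",
                                residue=res, ref_aa=aa, alt_aa=aa)
        res = diffs[0] + 1
        r_aa, a_aa = ref_prot[diffs[0]], alt_prot[diffs[0]]
        if a_aa == "*":
            return CodingEffect("nonsense", f"p.{r_aa}{res}*",
                                stop_residue=res, residue=res,
                                ref_aa=r_aa, alt_aa="*")
        return CodingEffect("missense", f"p.{r_aa}{res}{a_aa}",
                            residue=res, ref_aa=r_aa, alt_aa=a_aa)

    if rec.vtype == "del":
        ncds = len(cds_overlap)
        first = min(cds_overlap) // 3 + 1
        if ncds % 3:
            return CodingEffect("frameshift", f"p.{first}fs",
                                stop_residue=first, residue=first)
        last = max(cds_overlap) // 3 + 1
        return CodingEffect("inframe_del", f"p.{first}_{last}del",
                            residue=first)

    # insertion inside the CDS
    ci = tx.cds_index_of(s if tx.strand == "+" else s - 1)
    if ci is None:
        ci = tx.cds_index_of(s - 1 if tx.strand == "+" else s) or 0
    res = ci // 3 + 1
    if len(rec.alt) % 3:
        return CodingEffect("frameshift", f"p.{res}fs",
                            stop_residue=res, residue=res)
    return CodingEffect("inframe_ins", f"p.{res}ins", residue=res)


# ---------------------------------------------------------------------------
# simple lookups

def max_allele_frequency(rec: VariantRecord, af_tables) -> float | None:
    """Maximum AF over all populations containing the variant key; None if
    absent everywhere (the classifier treats None as 0)."""
    found = [table[rec.key] for table in af_tables.values()
             if rec.key in table]
    return max(found) if found else None


def region_overlaps(rec: VariantRecord, regions):
    """All features intersecting the variant interval (half-open; an
    insertion is the zero-length point at ``start``)."""
    out = []
    for name in sorted(regions):
        feats = regions[name]
        tree = feats if isinstance(feats, IntervalTree) else None
        items = ((iv.begin, iv.end, iv.data) for iv in feats) \
            if tree else feats
        for s, e, fid in items:
            if rec.vtype == "ins":
                hit = s <= rec.start < e
            else:
                hit = s < rec.end and rec.start < e
            if hit:
                out.append((name, fid, (s, e)))
    return out


# ---------------------------------------------------------------------------
# cache

class PreAnnotationCache:
    """Per-chromosome store of annotation columns keyed by the five variant
    characteristics.  Optionally persisted as one sorted TSV per chromosome
    (columns JSON-encoded); nothing submission-specific is ever stored."""

    def __init__(self, directory: str | Path | None = None):
        self.directory = Path(directory) if directory else None
        self._store: dict[str, dict] = {}
        if self.directory and self.directory.exists():
            self.load()

    @staticmethod
    def _key5(rec: VariantRecord):
        return (rec.start, rec.end, rec.vtype, rec.ref, rec.alt)

    def get(self, rec: VariantRecord):
        return self._store.get(rec.chrom, {}).get(self._key5(rec))

    def put(self, rec: VariantRecord, columns: dict):
        banned = {"genotypes", "zygosity", "recordId", "sample"}
        if banned & set(columns):
            raise ValueError("cache must not store submission-level fields")
        self._store.setdefault(rec.chrom, {})[self._key5(rec)] = columns

    def __len__(self):
        return sum(len(v) for v in self._store.values())

    def save(self):
        if not self.directory:
            return
        self.directory.mkdir(parents=True, exist_ok=True)
        for chrom, entries in self._store.items():
            path = self.directory / f"{chrom}.cache.tsv"
            with open(path, "w", newline="\n") as fh:
                for key in sorted(entries):
                    start, end, vtype, ref, alt = key
                    fh.write("\t".join([
                        str(start), str(end), vtype, ref or ".", alt or ".",
                        json.dumps(entries[key], sort_keys=True),
                    ]) + "\n")

    def load(self):
        for path in sorted(self.directory.glob("*.cache.tsv")):
            chrom = path.name[: -len(".cache.tsv")]
            entries = self._store.setdefault(chrom, {})
            with open(path) as fh:
                for line in fh:
                    start, end, vtype, ref, alt, payload = \
                        line.rstrip("\n").split("\t", 5)
                    cols = json.loads(payload)
                    for name, val in cols.items():
                        if isinstance(val, list):
                            cols[name] = [tuple(v) if isinstance(v, list)
                                          else v for v in val]
                    entries[(int(start), int(end), vtype,
                             "" if ref == "." else ref,
                             "" if alt == "." else alt)] = cols


# ---------------------------------------------------------------------------
# the annotation pipeline

def _fmt(x) -> str:
    return format(float(x), "g")


def _zygosity(rec: VariantRecord) -> str | None:
    if not rec.genotypes:
        return None
    alleles = [a for gt in rec.genotypes for a in gt.replace("|", "/").split("/")]
    known = [a for a in alleles if a in ("0", "1")]
    if not known:
        return None
    if all(a == "1" for a in known):
        return "hom"
    if len(known) == 1:
        return "hemizygous"
    return "het" if "1" in known else "hom-ref"


def compute_columns(rec: VariantRecord, sources: AnnotationSourceSet,
                    genome: str) -> dict:
    """De-novo annotation of one variant (everything except the variant
    block); all values are plain strings/tuples so that cache persistence
    is lossless."""
    from . import predictors

    cols: dict = {}
    txs = sources.overlapping_transcripts(rec)
    genes, tx_ids, effects, pchanges = [], [], [], []
    trunc_scores, mis_flags, splice_deltas = [], [], []
    for tx in txs:
        ce = coding_effect(rec, tx, genome)
        genes.append(tx.gene)
        tx_ids.append(tx.tx_id)
        effects.append(ce.effect)
        pchanges.append(ce.protein_change or None)
        if ce.effect in ("nonsense", "frameshift") and ce.stop_residue:
            res = predictors.truncation_score(
                predictors.TruncationInput(tx, ce.stop_residue))
            trunc_scores.append(_fmt(res.score))
        else:
            trunc_scores.append(None)
        if ce.effect == "missense" and sources.missense_predictor is not None:
            weights = tx.weights()
            w = weights[ce.residue - 1] if ce.residue and \
                ce.residue <= len(weights) else 0.0
            res = sources.missense_predictor(
                predictors.ProteinContext(tx.gene, ce.residue,
                                          ce.ref_aa, ce.alt_aa, w))
            mis_flags.append("damaging" if res.damaging else "tolerated")
        else:
            mis_flags.append(None)
        if ce.effect == "splice_region" and sources.splice_pwms and \
                predictors.find_junction_window(rec, tx) is not None:
            res = predictors.splice_region_delta(
                rec, tx, *sources.splice_pwms, genome=genome)
            splice_deltas.append(tuple(res.detail.split("~")))
        else:
            splice_deltas.append(None)
    cols["gene"] = genes
    cols["transcript"] = tx_ids
    cols["effect"] = effects
    cols["proteinChange"] = pchanges
    cols["truncationScore"] = trunc_scores
    cols["missenseDamaging"] = mis_flags
    cols["spliceDelta"] = splice_deltas

    af = max_allele_frequency(rec, sources.af_tables)
    cols["maxAF"] = None if af is None else _fmt(af)
    cols["pathogenic"] = sources.pathogenicity.get(rec.key)
    cols["risk"] = "risk" if sources.risk.get(rec.key) else None
    statuses = {sources.gene_catalog.get(g, "none") for g in genes}
    cols["geneStatus"] = ("clinical" if "clinical" in statuses
                          else "research" if "research" in statuses
                          else None)

    tfbs_ids, tfbs_deltas = [], []
    for name, fid, (s, e) in region_overlaps(rec, sources.regions):
        if name != "tfbs":
            continue
        tfbs_ids.append(fid)
        pssm = sources.pssms.get(fid.split("@")[0])
        if pssm is not None and rec.vtype in ("snp", "sub"):
            res = predictors.pssm_delta_at(rec, (s, e), pssm, genome)
            tfbs_deltas.append(tuple(res.detail.split("~")))
        else:
            tfbs_deltas.append(None)
    cols["tfbs"] = tfbs_ids
    cols["tfbsDelta"] = tfbs_deltas

    if effects:
        coding_set = {"synonymous", "missense", "nonsense", "frameshift",
                      "inframe_ins", "inframe_del"}
        if coding_set & set(effects):
            cols["region"] = "coding"
        elif {"utr5", "utr3"} & set(effects):
            cols["region"] = "utr"
        elif {"splice_donor", "splice_acceptor", "splice_region"} & set(effects):
            cols["region"] = "splice"
        else:
            cols["region"] = "intronic"
    else:
        cols["region"] = "intergenic"

    from .adviser_classifier import classify, classifier_input_from_columns
    inp = classifier_input_from_columns(cols)
    cols["adviserClinical"] = classify(inp, "clinical").value
    cols["adviserResearch"] = classify(inp, "research").value
    return cols


def annotate(rec: VariantRecord, sources: AnnotationSourceSet,
             cache: PreAnnotationCache | None, genome: str,
             record_id: str | None = None) -> tuple[AnnotationRow, bool]:
    """Annotate one validated variant; returns ``(row, computed)`` where
    ``computed`` is False on a cache hit."""
    computed = False
    cols = cache.get(rec) if cache is not None else None
    if cols is None:
        cols = compute_columns(rec, sources, genome)
        computed = True
        if cache is not None:
            cache.put(rec, cols)
    cols = dict(cols)
    cols["correction"] = (f"{rec.correction.kind}:{rec.correction.detail}"
                          if rec.correction else None)
    block = (rec.chrom, str(rec.start), str(rec.end), rec.vtype,
             rec.ref or ".", rec.alt or ".", _zygosity(rec), record_id)
    return AnnotationRow(block, cols), computed
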