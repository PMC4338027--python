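"""Seeded synthetic-data generator.

Produces every input the toolkit consumes: a toy reference chromosome
(``chrT``) carrying genes with valid ORFs (multi-exon, canonical GT/AG
introns, at least one minus-strand gene, one gene with two isoforms and
one with an annotated alternative start), per-residue conservation
weights, TFBS PSSMs with planted intergenic consensus sites, splice PWMs
matched to a real fixture junction, a miRNA with a planted 8mer target
site, variant files with a controlled mix of planted submission errors,
Mendelian trio VCFs with planted inheritance configurations, and the
allele-frequency / pathogenicity / risk / decoy / labeled-classification
catalogs.

Every generator draws from its own pseudo-random stream derived from
``(seed, generator name)``, so outputs are byte-identical for a given
spec and adding a generator never shifts existing outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .adviser_classifier import ClassifierInput
from .annotation_engine import TranscriptModel
from .predictors import PSSM
from .variant_io import VariantRecord, revcomp, write_variants_tsv

__all__ = [
    "FixtureSpec",
    "Reference",
    "Catalogs",
    "generate_reference",
    "generate_variant_file",
    "generate_trio",
    "generate_catalogs",
    "write_reference_files",
    "write_catalog_files",
]

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}
CODONS = [a + b + c for a in BASES for b in BASES for c in BASES
          if a + b + c not in STOPS]

DEFAULT_ERROR_MIX = {
    "clean": 0.90, "one_based": 0.0, "swapped": 0.05,
    "strand_flipped": 0.0, "irreconcilable": 0.05,
}
DEFAULT_TRIO_PLANTS = {"de_novo": 3, "recessive_hom": 2, "compound_het": 2}


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    genome_length: int = 9000
    n_genes: int = 6
    n_variants: int = 100
    error_mix: dict = field(default_factory=lambda: dict(DEFAULT_ERROR_MIX))
    trio_plants: dict = field(default_factory=lambda: dict(DEFAULT_TRIO_PLANTS))

    def __post_init__(self):
        if abs(sum(self.error_mix.values()) - 1.0) > 1e-9:
            raise ValueError("error_mix fractions must sum to 1")
        if any(v < 0 for v in self.trio_plants.values()):
            raise ValueError("trio plant counts must be non-negative")

    def rng(self, name: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, zlib.crc32(name.encode())])


class GenerationError(RuntimeError):
    pass


@dataclass
class Reference:
    chrom: str
    genome: str
    transcripts: list
    pssms: dict                       # motif_id -> PSSM (TFBS matrices)
    tfbs: list                        # (start, end, instance id)
    splice_pwms: tuple                # (donor PSSM, acceptor PSSM)
    mirna: str
    utr_seq: str
    mirna_site: tuple                 # planted ((start, end), class)


# ---------------------------------------------------------------------------
# reference genome + gene models

def _random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def _build_gene(rng, gene_id: str, n_codons: int):
    """Transcript-oriented gene layout: returns (region sequence,
    exon intervals, cds genomic interval) in region-local coordinates."""
    utr5, utr3 = 9, 9
    codons = ["ATG"] + [CODONS[i] for i in
                        rng.integers(0, len(CODONS), size=n_codons - 2)] + ["TAA"]
    cds = "".join(codons)
    tx = _random_seq(rng, utr5) + cds + _random_seq(rng, utr3)
    L = len(tx)
    # two cut points define three exons in spliced coordinates
    while True:
        cuts = sorted(int(x) for x in rng.integers(4, L - 4, size=2))
        if cuts[1] - cuts[0] >= 4:
            break
    spliced_exons = [(0, cuts[0]), (cuts[0], cuts[1]), (cuts[1], L)]
    introns = ["GT" + _random_seq(rng, int(rng.integers(26, 56))) + "AG"
               for _ in range(2)]
    region, exons, pos = [], [], 0
    splice_to_region = {}
    for i, (a, b) in enumerate(spliced_exons):
        exons.append((pos, pos + (b - a)))
        for k in range(a, b):
            splice_to_region[k] = pos + (k - a)
        region.append(tx[a:b])
        pos += b - a
        if i < 2:
            region.append(introns[i])
            pos += len(introns[i])
    region_seq = "".join(region)
    cds_lo = splice_to_region[utr5]
    cds_hi = splice_to_region[utr5 + len(cds) - 1] + 1
    return region_seq, exons, (cds_lo, cds_hi)


def generate_reference(spec: FixtureSpec) -> Reference:
    if spec.genome_length < 200 * spec.n_genes:
        raise GenerationError(
            f"genome of {spec.genome_length} bp cannot host {spec.n_genes} "
            "genes (need >= 200 bp per gene)")
    rng = spec.rng("reference")
    genome = list(_random_seq(rng, spec.genome_length))
    slot = spec.genome_length // spec.n_genes
    transcripts = []
    for g in range(spec.n_genes):
        gene_id = f"GENE{g}"
        strand = "-" if g == 1 else "+"
        n_codons = int(rng.integers(20, 41))
        region_seq, exons, (clo, chi) = _build_gene(rng, gene_id, n_codons)
        L = len(region_seq)
        if L + 40 > slot:
            raise GenerationError(f"gene {gene_id} does not fit its slot")
        offset = g * slot + 20
        if strand == "-":
            placed = revcomp(region_seq)
            exons = sorted((L - b, L - a) for a, b in exons)
            clo, chi = L - chi, L - clo
        else:
            placed = region_seq
        genome[offset:offset + L] = list(placed)
        weights = [round(float(w), 2) for w in rng.uniform(0, 1, n_codons)]
        alt_starts = [max(2, n_codons // 2)] if g == 2 else []
        n_iso = 2 if g == 0 else 1
        for iso in range(1, n_iso + 1):
            transcripts.append(TranscriptModel(
                gene=gene_id, tx_id=f"{gene_id}.t{iso}", chrom="chrT",
                strand=strand,
                exons=[(offset + a, offset + b) for a, b in exons],
                cds_start=offset + clo, cds_end=offset + chi,
                alt_starts=list(alt_starts), conservation=list(weights)))

    # TFBS PSSMs with planted consensus sites in intergenic gaps
    pssms, tfbs = {}, []
    for m in range(2):
        width = 8
        consensus = _random_seq(rng, width)
        matrix = np.full((width, 4), -1.0)
        for i, b in enumerate(consensus):
            matrix[i, BASES.index(b)] = 2.0
        motif_id = f"MOTIF{m}"
        pssms[motif_id] = PSSM(motif_id, matrix)
        site = spec.n_genes * slot - slot // 2 + 30 * m
        if site + width > spec.genome_length:
            raise GenerationError("no intergenic space for TFBS sites")
        genome[site:site + width] = list(consensus)
        tfbs.append((site, site + width, f"{motif_id}@{site}"))

    genome = "".join(genome)

    # splice PWMs matched to the first intron of GENE0 (plus strand):
    # donor spans exonic -3..intronic +6, acceptor intronic -14..exonic +1;
    # consensus scores 1 per position, with a heavily weighted position in
    # the intronic splice-region window so a planted variant drops the
    # relative score below the damaging cutoff.
    g0 = transcripts[0]
    i_start, i_end = g0.introns[0]
    donor_seq = genome[i_start - 3: i_start + 6]
    acceptor_seq = genome[i_end - 14: i_end + 1]

    def _pwm(name, seq, critical_index):
        matrix = np.zeros((len(seq), 4))
        for i, b in enumerate(seq):
            matrix[i, BASES.index(b)] = 10.0 if i == critical_index else 1.0
        return PSSM(name, matrix)

    donor_pwm = _pwm("donor", donor_seq, 5)        # intronic +3
    acceptor_pwm = _pwm("acceptor", acceptor_seq, 11)   # intronic -3

    # miRNA with a planted 8mer site in a synthetic UTR sequence
    mirna = _random_seq(rng, 22)
    site8 = revcomp(mirna[1:8]) + "A"
    utr_seq = _random_seq(rng, 30) + site8 + _random_seq(rng, 30)
    mirna_site = ((30, 38), "8mer")

    return Reference("chrT", genome, transcripts, pssms, tfbs,
                     (donor_pwm, acceptor_pwm), mirna, utr_seq, mirna_site)


# ---------------------------------------------------------------------------
# variant files with planted submission errors

def _category_counts(spec: FixtureSpec) -> list[str]:
    counts = {k: int(round(v * spec.n_variants))
              for k, v in spec.error_mix.items()}
    drift = spec.n_variants - sum(counts.values())
    counts["clean"] = counts.get("clean", 0) + drift
    order = ("clean", "one_based", "swapped", "strand_flipped",
             "irreconcilable")
    return [cat for cat in order for _ in range(counts.get(cat, 0))]


def generate_variant_file(spec: FixtureSpec, reference: Reference,
                          path) -> list[str]:
    """Write a 0-based TSV of SNVs drawn per ``error_mix``; returns the
    per-record ground-truth category labels (never written to the file)."""
    rng = spec.rng("variants")
    genome = reference.genome
    cats = _category_counts(spec)
    used: set[int] = set()
    records = []

    def pick_pos(ok):
        for _ in range(10000):
            p = int(rng.integers(2, len(genome) - 2))
            if p not in used and ok(p):
                used.add(p)
                return p
        raise GenerationError("could not place a fixture variant")

    def other_base(exclude):
        choices = [b for b in BASES if b not in exclude]
        return choices[int(rng.integers(0, len(choices)))]

    for cat in cats:
        if cat == "clean":
            p = pick_pos(lambda p: True)
            ref = genome[p]
            alt = other_base({ref})
            rec = VariantRecord("chrT", p, p + 1, "snp", ref, alt)
        elif cat == "one_based":
            p = pick_pos(lambda p: genome[p + 1] != genome[p])
            ref = genome[p]
            alt = other_base({ref})
            rec = VariantRecord("chrT", p + 1, p + 2, "snp", ref, alt)
        elif cat == "swapped":
            p = pick_pos(lambda p: True)
            ref = genome[p]
            alt = other_base({ref, genome[p - 1]})
            rec = VariantRecord("chrT", p, p + 1, "snp", alt, ref)
        elif cat == "strand_flipped":
            p = pick_pos(lambda p: genome[p - 1] != revcomp(genome[p]))
            ref = genome[p]
            alt = other_base({ref, revcomp(ref)})
            rec = VariantRecord("chrT", p, p + 1, "snp",
                                revcomp(ref), revcomp(alt))
        else:   # irreconcilable: no direct/shift/swap/strand resolution
            p = pick_pos(
                lambda p: len({genome[p], revcomp(genome[p]),
                               genome[p - 1]}) < 4)
            g = genome[p]
            bad_ref = other_base({g, revcomp(g), genome[p - 1]})
            bad_alt = other_base({g, bad_ref})
            rec = VariantRecord("chrT", p, p + 1, "snp", bad_ref, bad_alt)
        records.append(rec)
    write_variants_tsv(records, path)
    return cats


# ---------------------------------------------------------------------------
# trio VCF with planted inheritance configurations

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID={chrom},length={length}>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
    "CHILD\tMOTHER\tFATHER\n"
)


def generate_trio(spec: FixtureSpec, reference: Reference, path):
    """Write a trio VCF (samples CHILD, MOTHER, FATHER) of SNVs with
    Mendelian background genotypes plus exactly the planted de-novo,
    recessive-homozygous and compound-het configurations.  Returns the
    manifest {mode: [variant keys]}.

    Background sites are intergenic and never child-homalt-with-het-
    parents, so the inheritance filters recover exactly the plants.
    """
    rng = spec.rng("trio")
    genome = reference.genome
    spans = [(t.start - 8, t.end + 8) for t in reference.transcripts]
    used: set[int] = set()

    def intergenic(p):
        return not any(a <= p < b for a, b in spans)

    def pick(ok):
        for _ in range(10000):
            p = int(rng.integers(2, len(genome) - 2))
            if p not in used and ok(p):
                used.add(p)
                return p
        raise GenerationError("could not place a trio site")

    def alt_for(p):
        choices = [b for b in BASES if b != genome[p]]
        return choices[int(rng.integers(0, 3))]

    sites = []      # (pos, alt, gt_child, gt_mother, gt_father)
    manifest = {"de_novo": [], "recessive_hom": [], "compound_het": [],
                "dominant": []}

    plants = spec.trio_plants
    for _ in range(plants.get("de_novo", 0)):
        p = pick(intergenic)
        sites.append((p, alt_for(p), "0/1", "0/0", "0/0"))
        manifest["de_novo"].append(p)
    for _ in range(plants.get("recessive_hom", 0)):
        p = pick(intergenic)
        sites.append((p, alt_for(p), "1/1", "0/1", "0/1"))
        manifest["recessive_hom"].append(p)

    genes = sorted({t.gene for t in reference.transcripts})
    n_ch = plants.get("compound_het", 0)
    if n_ch > len(genes):
        raise GenerationError("more compound-het plants than genes")
    for gi in range(n_ch):
        tx = next(t for t in reference.transcripts if t.gene == genes[gi])
        exon_positions = [p for a, b in tx.exons for p in range(a, b)]
        for parent in ("mother", "father"):
            p = pick(lambda p, ep=set(exon_positions): p in ep)
            gt_m = "0/1" if parent == "mother" else "0/0"
            gt_f = "0/1" if parent == "father" else "0/0"
            sites.append((p, alt_for(p), "0/1", gt_m, gt_f))
            manifest["compound_het"].append(p)

    n_background = max(20, spec.n_variants // 5)
    parent_gts = ["0/0", "0/1", "1/1"]
    for _ in range(n_background):
        p = pick(intergenic)
        gm = parent_gts[int(rng.integers(0, 3))]
        gf = parent_gts[int(rng.integers(0, 3))]
        if gm == "0/1" and gf == "0/1":
            gc = "0/1"      # never recessive-hom by chance
        else:
            a = gm.split("/")[int(rng.integers(0, 2))]
            b = gf.split("/")[int(rng.integers(0, 2))]
            gc = "/".join(sorted((a, b)))
        sites.append((p, alt_for(p), gc, gm, gf))

    sites.sort()
    with open(path, "w", newline="\n") as fh:
        fh.write(_VCF_HEADER.format(chrom=reference.chrom,
                                    length=len(genome)))
        for p, alt, gc, gm, gf in sites:
            fh.write("\t".join([
                reference.chrom, str(p + 1), ".", genome[p], alt, ".", ".",
                ".", "GT", gc, gm, gf]) + "\n")
    key = {p: (reference.chrom, p, p + 1, "snp", genome[p], alt)
           for p, alt, *_ in sites}
    return {mode: [key[p] for p in ps] for mode, ps in manifest.items()}


# ---------------------------------------------------------------------------
# catalogs and the labeled classification set

@dataclass
class Catalogs:
    af_tables: dict
    pathogenicity: dict
    risk: dict
    gene_catalog: dict
    decoys: list                     # VariantRecord
    labeled: list                    # (ClassifierInput, label)
    designed_counts: dict            # threshold -> (tp, fp, tn, fn), research


#: AF palette spanning both sides of the 1% and 5% boundaries
_AF_PALETTE = (0.001, 0.004, 0.009, 0.01, 0.02, 0.03, 0.05, 0.06, 0.2, 0.5)


def _random_snp_keys(rng, genome, n, exclude):
    keys, used = [], set(exclude)
    while len(keys) < n:
        p = int(rng.integers(1, len(genome) - 1))
        if p in used:
            continue
        used.add(p)
        ref = genome[p]
        alt = [b for b in BASES if b != ref][int(rng.integers(0, 3))]
        keys.append(("chrT", p, p + 1, "snp", ref, alt))
    return keys


def generate_catalogs(spec: FixtureSpec, reference: Reference,
                      exclude_positions=()) -> Catalogs:
    rng = spec.rng("catalogs")
    genome = reference.genome
    pool = _random_snp_keys(rng, genome, 60, exclude_positions)
    af_tables = {"popA": {}, "popB": {}}
    for i, key in enumerate(pool[:40]):
        af_tables["popA"][key] = _AF_PALETTE[i % len(_AF_PALETTE)]
        if i % 2 == 0:
            af_tables["popB"][key] = _AF_PALETTE[(i + 3) % len(_AF_PALETTE)]
    pathogenicity = {k: ("pathogenic" if i % 3 else "benign")
                     for i, k in enumerate(pool[:15])}
    risk = {k: True for k in pool[15:20]}
    genes = sorted({t.gene for t in reference.transcripts})
    gene_catalog = {}
    for i, g in enumerate(genes):
        gene_catalog[g] = ("clinical" if i % 3 == 0
                           else "research" if i % 3 == 1 else "none")
    decoy_exclude = set(exclude_positions) | {k[1] for k in pool}
    decoys = [VariantRecord(*k) for k in
              _random_snp_keys(rng, genome, 50, decoy_exclude)]

    labeled, per_class = [], 5
    templates = {
        "1": lambda af: ClassifierInput(reported_pathogenic=True,
                                        gene_status="clinical", max_af=af,
                                        effect="missense"),
        "1*": lambda af: ClassifierInput(reported_pathogenic=True,
                                         gene_status="clinical",
                                         max_af=0.01 + af * 4,
                                         effect="missense"),
        "2": lambda af: ClassifierInput(gene_status="clinical", max_af=af,
                                        effect="splice_donor",
                                        splice_site_removed=True),
        "2*": lambda af: ClassifierInput(gene_status="clinical", max_af=af,
                                         effect="nonsense"),
        "3": lambda af: ClassifierInput(gene_status="clinical", max_af=af,
                                        effect="missense"),
        "4": lambda af: ClassifierInput(gene_status="none", max_af=af,
                                        effect="missense",
                                        missense_damaging=True),
        "4*": lambda af: ClassifierInput(gene_status="none", max_af=af,
                                         effect="inframe_del"),
        "5": lambda af: ClassifierInput(gene_status="none",
                                        max_af=0.06 + af * 10,
                                        effect="synonymous"),
        "6": lambda af: ClassifierInput(reported_risk=True,
                                        gene_status="research",
                                        max_af=0.06 + af * 10,
                                        effect="intronic"),
    }
    for cls, make in templates.items():
        majority = "disease" if cls in ("1", "1*", "2", "2*") else "neutral"
        minority = "neutral" if majority == "disease" else "disease"
        for i in range(per_class):
            af = round(float(rng.uniform(0.0005, 0.009)), 4)
            labeled.append((make(af), majority if i < per_class - 1
                            else minority))

    from .adviser_classifier import evaluate_thresholds
    designed = {
        ev.threshold.value: (ev.tp, ev.fp, ev.tn, ev.fn)
        for ev in evaluate_thresholds(labeled, ["1", "2", "3"],
                                      mode="research")
    }
    return Catalogs(af_tables, pathogenicity, risk, gene_catalog, decoys,
                    labeled, designed)


# ---------------------------------------------------------------------------
# file emission (formats consumed by the loaders / CLI)

def write_reference_files(reference: Reference, outdir) -> dict:
    """Write FASTA, GFF3, conservation TSV, PSSM files, TFBS BED and the
    miRNA/UTR FASTAs; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / fname for name, fname in [
        ("fasta", "ref.fa"), ("gff3", "genes.gff3"),
        ("conservation", "conservation.tsv"), ("pssms", "pssms.tsv"),
        ("splice_pwms", "splice_pwms.tsv"), ("tfbs", "tfbs.bed"),
        ("mirna", "mirna.fa"), ("utr", "utr.fa")]}

    with open(paths["fasta"], "w", newline="\n") as fh:
        fh.write(f">{reference.chrom}\n")
        for i in range(0, len(reference.genome), 60):
            fh.write(reference.genome[i:i + 60] + "\n")

    with open(paths["gff3"], "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        seen_genes = set()
        for tx in reference.transcripts:
            if tx.gene not in seen_genes:
                seen_genes.add(tx.gene)
                fh.write("\t".join([
                    tx.chrom, "fixtures", "gene", str(tx.start + 1),
                    str(tx.end), ".", tx.strand, ".",
                    f"ID={tx.gene}"]) + "\n")
            attrs = f"ID={tx.tx_id};Parent={tx.gene}"
            if tx.alt_starts:
                attrs += ";alt_starts=" + ",".join(map(str, tx.alt_starts))
            fh.write("\t".join([
                tx.chrom, "fixtures", "mRNA", str(tx.start + 1),
                str(tx.end), ".", tx.strand, ".", attrs]) + "\n")
            for i, (a, b) in enumerate(tx.exons, 1):
                fh.write("\t".join([
                    tx.chrom, "fixtures", "exon", str(a + 1), str(b), ".",
                    tx.strand, ".",
                    f"ID={tx.tx_id}.e{i};Parent={tx.tx_id}"]) + "\n")
            for i, (a, b) in enumerate(tx.cds_segments, 1):
                fh.write("\t".join([
                    tx.chrom, "fixtures", "CDS", str(a + 1), str(b), ".",
                    tx.strand, "0",
                    f"ID={tx.tx_id}.c{i};Parent={tx.tx_id}"]) + "\n")

    with open(paths["conservation"], "w", newline="\n") as fh:
        fh.write("#tx_id\tresidue\tweight\n")
        for tx in reference.transcripts:
            for i, w in enumerate(tx.conservation or [], 1):
                fh.write(f"{tx.tx_id}\t{i}\t{w:g}\n")

    from .predictors import write_pssm_file
    write_pssm_file(reference.pssms, paths["pssms"])
    donor, acceptor = reference.splice_pwms
    write_pssm_file({"donor": donor, "acceptor": acceptor},
                    paths["splice_pwms"])

    with open(paths["tfbs"], "w", newline="\n") as fh:
        for s, e, fid in reference.tfbs:
            fh.write(f"{reference.chrom}\t{s}\t{e}\t{fid}\n")

    with open(paths["mirna"], "w", newline="\n") as fh:
        fh.write(f">mir-fixture\n{reference.mirna}\n")
    with open(paths["utr"], "w", newline="\n") as fh:
        fh.write(f">utr-fixture\n{reference.utr_seq}\n")
    return paths


def write_catalog_files(cat: Catalogs, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / fname for name, fname in [
        ("af", "af.tsv"), ("pathogenic", "pathogenic.tsv"),
        ("risk", "risk.tsv"), ("gene_status", "gene_status.tsv"),
        ("decoys", "decoys.tsv"), ("labeled", "labeled.tsv")]}

    def key_fields(key):
        c, s, e, vt, ref, alt = key
        return [c, str(s), str(e), vt, ref or ".", alt or "."]

    with open(paths["af"], "w", newline="\n") as fh:
        fh.write("#chrom\tbegin\tend\tvarType\treference\talleleSeq"
                 "\tpopulation\taf\n")
        for pop in sorted(cat.af_tables):
            for key in sorted(cat.af_tables[pop]):
                fh.write("\t".join(key_fields(key) + [pop,
                         f"{cat.af_tables[pop][key]:g}"]) + "\n")
    with open(paths["pathogenic"], "w", newline="\n") as fh:
        fh.write("#chrom\tbegin\tend\tvarType\treference\talleleSeq"
                 "\tassertion\n")
        for key in sorted(cat.pathogenicity):
            fh.write("\t".join(key_fields(key)
                               + [cat.pathogenicity[key]]) + "\n")
    with open(paths["risk"], "w", newline="\n") as fh:
        fh.write("#chrom\tbegin\tend\tvarType\treference\talleleSeq"
                 "\tassociation\n")
        for key in sorted(cat.risk):
            fh.write("\t".join(key_fields(key) + ["risk"]) + "\n")
    with open(paths["gene_status"], "w", newline="\n") as fh:
        fh.write("#gene\tstatus\n")
        for gene in sorted(cat.gene_catalog):
            fh.write(f"{gene}\t{cat.gene_catalog[gene]}\n")
    write_variants_tsv(cat.decoys, paths["decoys"])
    with open(paths["labeled"], "w", newline="\n") as fh:
        fh.write("#reported_pathogenic\treported_risk\tgene_status\tmax_af"
                 "\teffect\tmissense_damaging\ttruncation_damaging"
                 "\tsplice_site_removed\tlabel\n")
        for inp, label in cat.labeled:
            fh.write("\t".join([
                str(int(inp.reported_pathogenic)),
                str(int(inp.reported_risk)), inp.gene_status,
                "-" if inp.max_af is None else f"{inp.max_af:g}",
                inp.effect, str(int(inp.missense_damaging)),
                str(int(inp.truncation_damaging)),
                str(int(inp.splice_site_removed)), label]) + "\n")
    return paths
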