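"""Loaders assembling an :class:`AnnotationSourceSet` from flat files.

Gene models come from GFF3 (gene/mRNA/exon/CDS; read through gffutils)
with per-residue conservation weights in a side TSV and alternative start
residues carried as an ``alt_starts`` attribute on the mRNA line.  AF
tables, pathogenicity/risk catalogs and the gene status catalog are plain
TSVs keyed by the five variant characteristics; TFBS instances are BED
with the name field holding ``motif_id@position``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .annotation_engine import AnnotationSourceSet, TranscriptModel
from .predictors import ConservationRulePredictor, read_pssm_file
from .variant_io import variant_key

__all__ = [
    "load_transcripts_gff3",
    "load_conservation",
    "load_af_table",
    "load_keyed_catalog",
    "load_gene_catalog",
    "load_bed_regions",
    "load_sources",
]


def load_transcripts_gff3(path, conservation: dict | None = None):
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    transcripts = []
    for mrna in db.features_of_type("mRNA"):
        exons = sorted((f.start - 1, f.end)
                       for f in db.children(mrna, featuretype="exon"))
        cds = sorted((f.start - 1, f.end)
                     for f in db.children(mrna, featuretype="CDS"))
        alt = mrna.attributes.get("alt_starts", [])
        alt_starts = [int(x) for part in alt for x in part.split(",")]
        gene = mrna.attributes.get("Parent", [mrna.id])[0]
        transcripts.append(TranscriptModel(
            gene=gene, tx_id=mrna.id, chrom=mrna.seqid,
            strand=mrna.strand, exons=exons,
            cds_start=cds[0][0] if cds else None,
            cds_end=cds[-1][1] if cds else None,
            alt_starts=alt_starts,
            conservation=(conservation or {}).get(mrna.id)))
    return transcripts


def load_conservation(path) -> dict:
    df = pd.read_csv(path, sep="\t", comment=None, header=0,
                     names=["tx_id", "residue", "weight"])
    out: dict[str, list] = {}
    for tx_id, grp in df.groupby("tx_id", sort=False):
        grp = grp.sort_values("residue")
        out[str(tx_id)] = [float(w) for w in grp["weight"]]
    return out


def _key_of(row) -> tuple:
    ref = "" if row.reference in (".", "-") else str(row.reference)
    alt = "" if row.alleleSeq in (".", "-") else str(row.alleleSeq)
    return variant_key(row.chrom, row.begin, row.end, row.varType, ref, alt)


_KEY_NAMES = ["chrom", "begin", "end", "varType", "reference", "alleleSeq"]


def load_af_table(path) -> dict:
    df = pd.read_csv(path, sep="\t", names=_KEY_NAMES + ["population", "af"],
                     header=0)
    tables: dict[str, dict] = {}
    for row in df.itertuples():
        tables.setdefault(str(row.population), {})[_key_of(row)] = float(row.af)
    return tables


def load_keyed_catalog(path, value_column: str) -> dict:
    df = pd.read_csv(path, sep="\t", names=_KEY_NAMES + [value_column],
                     header=0)
    return {_key_of(row): str(getattr(row, value_column))
            for row in df.itertuples()}


def load_gene_catalog(path) -> dict:
    df = pd.read_csv(path, sep="\t", names=["gene", "status"], header=0)
    return {str(r.gene): str(r.status) for r in df.itertuples()}


def load_bed_regions(path) -> list:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name"])
    return [(int(r.start), int(r.end), str(r.name)) for r in df.itertuples()]


def load_sources(refdir, catdir=None) -> AnnotationSourceSet:
    """Assemble the full source set from a reference directory (as written
    by the fixture generator) and an optional catalog directory."""
    refdir = Path(refdir)
    conservation = load_conservation(refdir / "conservation.tsv") \
        if (refdir / "conservation.tsv").exists() else {}
    transcripts = load_transcripts_gff3(refdir / "genes.gff3", conservation)
    pssms = read_pssm_file(refdir / "pssms.tsv") \
        if (refdir / "pssms.tsv").exists() else {}
    splice = None
    if (refdir / "splice_pwms.tsv").exists():
        pwms = read_pssm_file(refdir / "splice_pwms.tsv")
        splice = (pwms["donor"], pwms["acceptor"])
    regions = {}
    if (refdir / "tfbs.bed").exists():
        regions["tfbs"] = load_bed_regions(refdir / "tfbs.bed")

    kw = dict(transcripts=transcripts, pssms=pssms, splice_pwms=splice,
              regions=regions, missense_predictor=ConservationRulePredictor())
    if catdir is not None:
        catdir = Path(catdir)
        if (catdir / "af.tsv").exists():
            kw["af_tables"] = load_af_table(catdir / "af.tsv")
        if (catdir / "pathogenic.tsv").exists():
            kw["pathogenicity"] = load_keyed_catalog(
                catdir / "pathogenic.tsv", "assertion")
        if (catdir / "risk.tsv").exists():
            kw["risk"] = {k: v == "risk" for k, v in load_keyed_catalog(
                catdir / "risk.tsv", "association").items()}
        if (catdir / "gene_status.tsv").exists():
            kw["gene_catalog"] = load_gene_catalog(catdir / "gene_status.tsv")
    return AnnotationSourceSet(**kw)
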