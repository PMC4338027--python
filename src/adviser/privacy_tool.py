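"""Client-side de-identification.

Three operations keep control of a genome's identifying content with its
owner: ``strip_genotypes`` removes all sample/genotype columns before
upload; ``implant_decoys`` mixes a seeded random draw of known clinically
relevant variants into the variant-only file, so intercepted uploads
cannot reveal which clinically informative variants are real; and
``remove_decoys`` reverses the implantation on the returned annotation
table purely by key-set subtraction against the original variant file —
no manifest of the implanted set is ever stored anywhere.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

from .variant_io import (VariantRecord, detect_format, parse_annotation_table,
                         read_variants, write_annotation_table,
                         write_variants_tsv)

__all__ = [
    "DecoyCatalog",
    "CapacityError",
    "strip_genotypes",
    "implant_decoys",
    "remove_decoys",
    "load_decoy_catalog",
    "write_decoy_catalog",
]


class CapacityError(ValueError):
    """The decoy catalog cannot supply enough novel entries."""


@dataclass
class DecoyCatalog:
    entries: list[VariantRecord]
    provenance: str = ""

    def __post_init__(self):
        keys = [e.key for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("decoy catalog entries must be distinct")


def load_decoy_catalog(path, provenance: str = "") -> DecoyCatalog:
    records, _, _ = read_variants(path, "tsv")
    return DecoyCatalog([r.replace(genotypes=None) for r in records],
                        provenance or str(path))


def write_decoy_catalog(catalog: DecoyCatalog, path) -> None:
    write_variants_tsv(catalog.entries, path)


def strip_genotypes(in_path, out_path) -> int:
    """Project a variant file onto its variant-only columns.

    VCF: drop the FORMAT and sample columns and ##FORMAT header lines
    (a pure text projection, so output bytes are deterministic).
    TSV: drop any columns after the six variant fields.  Returns the
    number of variant lines written.
    """
    in_path, out_path = Path(in_path), Path(out_path)
    fmt = detect_format(in_path)
    n = 0
    with open(in_path) as src, open(out_path, "w", newline="\n") as dst:
        for line in src:
            line = line.rstrip("\n")
            if not line:
                continue
            if fmt == "vcf":
                if line.startswith("##FORMAT"):
                    continue
                if line.startswith("#"):
                    if line.startswith("#CHROM"):
                        line = "\t".join(line.split("\t")[:8])
                    dst.write(line + "\n")
                    continue
                dst.write("\t".join(line.split("\t")[:8]) + "\n")
                n += 1
            elif fmt == "tsv":
                if line.startswith("#"):
                    dst.write("#" + "\t".join(
                        line.lstrip("#").split("\t")[:6]) + "\n")
                    continue
                dst.write("\t".join(line.split("\t")[:6]) + "\n")
                n += 1
            else:          # CGI var files carry no per-sample genotypes
                dst.write(line + "\n")
                n += not line.startswith((">", "#"))
    return n


def implant_decoys(in_path, catalog: DecoyCatalog, k: int | None,
                   seed: int, out_path) -> list[VariantRecord]:
    """Mix ``k`` decoys (default: 1% of the input, at least 10) into the
    variant-only file; output is coordinate-sorted plain TSV so implanted
    records are not positionally identifiable.  Returns the implanted set
    (client-side only; never persisted by this function)."""
    records, _, _ = read_variants(in_path)
    present = {r.key for r in records}
    if k is None:
        k = max(10, len(records) // 100)
    eligible = sorted((e for e in catalog.entries if e.key not in present),
                      key=lambda r: r.key)
    if len(eligible) < k:
        raise CapacityError(
            f"catalog offers {len(eligible)} novel decoys, {k} requested")
    rng = random.Random(seed)
    decoys = [d.replace(genotypes=None) for d in rng.sample(eligible, k)]
    merged = sorted([r.replace(genotypes=None) for r in records] + decoys,
                    key=lambda r: r.key)
    write_variants_tsv(merged, out_path)
    return decoys


def remove_decoys(annotation_path, original_path, out_path):
    """Drop every annotation row whose variant key is absent from the
    original (pre-implantation) file.  Returns (kept, dropped, missing)
    where ``missing`` lists original keys absent from the annotations."""
    original, _, _ = read_variants(original_path)
    keep = {r.key for r in original}
    rows = parse_annotation_table(annotation_path)
    kept = [row for row in rows if row.key in keep]
    dropped = len(rows) - len(kept)
    missing = sorted(keep - {row.key for row in kept})
    write_annotation_table(kept, out_path)
    return len(kept), dropped, missing
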