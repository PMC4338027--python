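"""Variant file dialects and the annotation table format.

Three input dialects are supported:

* VCF v4.x — 1-based, anchor-base indels; converted to 0-based half-open
  on read, shared prefix/suffix of indel alleles trimmed.
* CGI-style var TSV — ``>locus`` header, already 0-based half-open.
* plain TSV — columns ``chrom  begin  end  varType  reference
  alleleSeq [genotype...]``, 0-based half-open.

Output is the annotation table: tab-separated, first eight columns describe
the variant itself, remaining columns carry annotations.  Values relative
to a transcript (or another repeated feature such as a TFBS instance) are
``///``-joined lists kept positionally parallel across the columns of the
same group; nulls render as ``-`` and composite nulls as ``-~-``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "VariantRecord",
    "CorrectionNote",
    "AnnotationRow",
    "Column",
    "ANNOTATION_COLUMNS",
    "VARIANT_BLOCK_COLUMNS",
    "FormatError",
    "ParseError",
    "detect_format",
    "read_variants",
    "write_variants_tsv",
    "write_annotation_table",
    "parse_annotation_table",
    "variant_key",
]

VTYPES = ("snp", "ins", "del", "sub")

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when a file's dialect cannot be established or is violated."""


class ParseError(ValueError):
    """Raised for a malformed line; carries the 1-based line number."""

    def __init__(self, line_no: int, reason: str):
        self.line_no = line_no
        self.reason = reason
        super().__init__(f"line {line_no}: {reason}")


@dataclass(frozen=True)
class CorrectionNote:
    kind: str  # coordinate_shift | allele_swap | strand_flip | prefix_trim
    detail: str = ""

    KINDS = ("coordinate_shift", "allele_swap", "strand_flip", "prefix_trim")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown correction kind {self.kind!r}")


@dataclass(frozen=True)
class VariantRecord:
    """One normalized variant, 0-based half-open, positive strand."""

    chrom: str
    start: int
    end: int
    vtype: str
    ref: str
    alt: str
    genotypes: tuple[str, ...] | None = None
    line_no: int = 0
    correction: CorrectionNote | None = None

    def __post_init__(self):
        if self.vtype not in VTYPES:
            raise ValueError(f"bad vtype {self.vtype!r}")
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.vtype == "ins":
            if self.ref or self.start != self.end:
                raise ValueError("insertion must have empty ref and start == end")
        else:
            if self.end - self.start != len(self.ref):
                raise ValueError("end - start must equal len(ref)")
        if self.vtype == "snp" and not (
            len(self.ref) == len(self.alt) == 1 and self.ref != self.alt
        ):
            raise ValueError("snp must be a single differing base")
        if self.vtype == "sub" and not (len(self.ref) == len(self.alt) > 1):
            raise ValueError("sub alleles must be equal length > 1")
        if self.vtype == "del" and self.alt:
            raise ValueError("deletion must have empty alt")
        for allele in (self.ref, self.alt):
            if allele.strip("ACGTN"):
                raise ValueError(f"non-ACGTN allele {allele!r}")

    @property
    def key(self) -> tuple[str, int, int, str, str, str]:
        """The five variant characteristics (plus chromosome) used as the
        cache and catalog key."""
        return (self.chrom, self.start, self.end, self.vtype, self.ref, self.alt)

    def replace(self, **kw) -> "VariantRecord":
        return dataclasses.replace(self, **kw)


def variant_key(chrom, start, end, vtype, ref, alt):
    return (str(chrom), int(start), int(end), str(vtype), str(ref), str(alt))


# ---------------------------------------------------------------------------
# annotation table schema

@dataclass(frozen=True)
class Column:
    name: str
    group: str | None = None     # parallel group ("transcript", "tfbs", ...)
    composite: int = 0           # number of "~"-joined components (0 = plain)


VARIANT_BLOCK_COLUMNS = (
    "chromosome", "begin", "end", "varType", "reference", "alleleSeq",
    "zygosity", "recordId",
)

#: canonical annotation columns; extensible, order defines file layout
ANNOTATION_COLUMNS: tuple[Column, ...] = (
    Column("correction"),
    Column("gene", group="transcript"),
    Column("transcript", group="transcript"),
    Column("effect", group="transcript"),
    Column("proteinChange", group="transcript"),
    Column("truncationScore", group="transcript"),
    Column("missenseDamaging", group="transcript"),
    Column("spliceDelta", group="transcript", composite=2),
    Column("maxAF"),
    Column("pathogenic"),
    Column("risk"),
    Column("geneStatus"),
    Column("tfbs", group="tfbs"),
    Column("tfbsDelta", group="tfbs", composite=2),
    Column("region"),
    Column("adviserClinical"),
    Column("adviserResearch"),
)


_COMPOSITE = {c.name for c in ANNOTATION_COLUMNS if c.composite}


@dataclass
class AnnotationRow:
    """One output line: the eight-column variant block plus annotations.

    ``columns`` maps column name to either a scalar (str/number/None) or,
    for grouped columns, a list kept positionally parallel within its
    group.  Composite values are tuples of components.
    """

    variant_block: tuple
    columns: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.variant_block) != len(VARIANT_BLOCK_COLUMNS):
            raise ValueError("variant block must have exactly 8 values")
        # For plain parallel columns an all-null list and the "-" cell are
        # the same value; composite columns keep per-entry "-~-" nulls so
        # partially complete outputs stay positionally aligned.
        for name, val in self.columns.items():
            if (isinstance(val, list) and val and name not in _COMPOSITE
                    and all(v is None for v in val)):
                self.columns[name] = []

    @property
    def key(self):
        c, b, e, vt, ref, alt = self.variant_block[:6]
        return variant_key(c, b, e, vt, ref, alt)

    def check_parallel(self, schema: Sequence[Column] = ANNOTATION_COLUMNS):
        """Verify equal list lengths within every parallel group."""
        lengths: dict[str, tuple[str, int]] = {}
        for col in schema:
            if col.group is None:
                continue
            val = self.columns.get(col.name)
            if val is None:
                continue
            if not isinstance(val, list):
                raise FormatError(f"column {col.name} must hold a list")
            if not val:     # "-": annotation not applicable, any length
                continue
            seen = lengths.get(col.group)
            if seen is not None and seen[1] != len(val):
                raise FormatError(
                    f"column {col.name} has {len(val)} parallel entries, "
                    f"{seen[0]} has {seen[1]}"
                )
            lengths[col.group] = (col.name, len(val))


# ---------------------------------------------------------------------------
# dialect detection and reading

def detect_format(path) -> str:
    """Identify the variant dialect by header inspection."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"empty variant file: {path}")
    for line in text.splitlines():
        if not line.strip():
            continue
        if line.startswith("##fileformat=VCF"):
            return "vcf"
        if line.startswith(">locus") or line.startswith("#ASSEMBLY_ID"):
            return "cgi"
        return "tsv"
    raise FormatError(f"empty variant file: {path}")


def _normalize_alleles(pos1: int, ref: str, alt: str):
    """Trim the shared suffix then the shared leading anchor of a VCF
    allele pair; return (start0, end0, vtype, ref, alt, trimmed?)."""
    ref, alt = ref.upper(), alt.upper()
    r, a = ref, alt
    while r and a and r[-1] == a[-1] and not (len(r) == 1 and len(a) == 1):
        r, a = r[:-1], a[:-1]
    lead = 0
    while r and a and r[0] == a[0] and not (len(r) == 1 and len(a) == 1):
        r, a, lead = r[1:], a[1:], lead + 1
    start = pos1 - 1 + lead
    if r and a:
        vtype = "snp" if len(r) == len(a) == 1 else "sub"
        if len(r) != len(a):
            raise ValueError(f"unbalanced alleles after trimming: {r}>{a}")
    elif r:
        vtype = "del"
    elif a:
        vtype = "ins"
    else:
        raise ValueError("ref and alt identical")
    end = start + len(r)
    trimmed = (r, a) != (ref, alt)
    return start, end, vtype, r, a, trimmed


def _split_genotype(gt_alleles, alt_index: int) -> str:
    """Re-express one sample's genotype relative to a single split alt."""
    out = []
    for a in gt_alleles:
        if a is None or a < 0:
            out.append(".")
        elif a == 0:
            out.append("0")
        elif a == alt_index + 1:
            out.append("1")
        else:
            out.append(".")
    return "/".join(out)


def _read_vcf(path):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records, errors = [], []
    for line_no, v in enumerate(vcf, start=1):
        for i, alt in enumerate(v.ALT):
            try:
                start, end, vtype, ref, a, trimmed = _normalize_alleles(
                    v.POS, v.REF, alt
                )
            except ValueError as exc:
                errors.append((line_no, str(exc)))
                continue
            note = None
            if trimmed:
                note = CorrectionNote(
                    "prefix_trim", f"{v.REF}>{alt} trimmed to {ref or '.'}>{a or '.'}"
                )
            gts = None
            if samples:
                gts = tuple(
                    _split_genotype(g[:-1], i) for g in v.genotypes
                )
            records.append(
                VariantRecord(v.CHROM, start, end, vtype, ref, a,
                              genotypes=gts, line_no=line_no, correction=note)
            )
    return records, samples, errors


def _parse_plain_row(fields, line_no, gt_cols=True):
    chrom, begin, end, vtype, ref, alt = fields[:6]
    ref = "" if ref in (".", "-", "=") else ref.upper()
    alt = "" if alt in (".", "-") else alt.upper()
    gts = tuple(fields[6:]) if gt_cols and len(fields) > 6 else None
    return VariantRecord(chrom, int(begin), int(end), vtype, ref, alt,
                         genotypes=gts, line_no=line_no)


def _read_tsv(path):
    records, errors = [], []
    samples: list[str] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                fields = line.lstrip("#").split("\t")
                if len(fields) > 6 and fields[3] in ("varType", "vtype"):
                    samples = fields[6:]
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                errors.append((line_no, f"expected >= 6 columns, got {len(fields)}"))
                continue
            try:
                records.append(_parse_plain_row(fields, line_no))
            except (ValueError, IndexError) as exc:
                errors.append((line_no, str(exc)))
    return records, samples, errors


#: CGI var columns we consume (by position after the header)
_CGI_COLS = ("locus", "ploidy", "allele", "chromosome", "begin", "end",
             "varType", "reference", "alleleSeq")


def _read_cgi(path):
    records, errors = [], []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith(">"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                errors.append((line_no, f"expected >= 9 columns, got {len(fields)}"))
                continue
            vtype = fields[6]
            if vtype not in VTYPES:   # ref / no-call / par-called rows
                continue
            try:
                records.append(
                    _parse_plain_row(
                        [fields[3], fields[4], fields[5], vtype, fields[7], fields[8]],
                        line_no, gt_cols=False,
                    )
                )
            except (ValueError, IndexError) as exc:
                errors.append((line_no, str(exc)))
    return records, [], errors


def read_variants(path, fmt: str | None = None):
    """Read a variant file into normalized records.

    Returns ``(records, sample_names, errors)`` where errors is a list of
    ``(line_no, reason)`` for lines that could not be parsed.  Raises
    :class:`FormatError` if every line fails.
    """
    fmt = fmt or detect_format(path)
    if fmt == "vcf":
        out = _read_vcf(path)
    elif fmt == "cgi":
        out = _read_cgi(path)
    elif fmt == "tsv":
        out = _read_tsv(path)
    else:
        raise FormatError(f"unknown format tag {fmt!r}")
    records, samples, errors = out
    if not records and errors:
        raise FormatError(f"no parseable variant line in {path}")
    return records, samples, errors


def write_variants_tsv(records: Iterable[VariantRecord], path,
                       samples: Sequence[str] = ()) -> None:
    """Write records in the 0-based plain TSV dialect."""
    with open(path, "w", newline="\n") as fh:
        header = list(("chromosome", "begin", "end", "varType",
                       "reference", "alleleSeq")) + list(samples)
        fh.write("#" + "\t".join(header) + "\n")
        for r in records:
            fields = [r.chrom, str(r.start), str(r.end), r.vtype,
                      r.ref or ".", r.alt or "."]
            if samples:
                fields += list(r.genotypes or ["."] * len(samples))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# annotation table serialization

def _render_atom(value, composite: int) -> str:
    if composite:
        if value is None:
            parts = [None] * composite
        else:
            parts = list(value)
            if len(parts) != composite:
                raise FormatError(
                    f"composite value {value!r} needs {composite} components")
        return "~".join("-" if p is None else _num(p) for p in parts)
    return "-" if value is None or value == "" else _num(value)


def _num(v) -> str:
    if isinstance(v, float):
        return format(v, "g")
    return str(v)


def _render_cell(value, col: Column) -> str:
    if col.group is not None:
        if not value:
            return "-"
        return "///".join(_render_atom(v, col.composite) for v in value)
    return _render_atom(value, col.composite)


def _parse_atom(text: str, composite: int):
    if composite:
        parts = text.split("~")
        if len(parts) != composite:
            raise FormatError(f"composite cell {text!r} needs {composite} parts")
        parsed = tuple(None if p == "-" else p for p in parts)
        return None if all(p is None for p in parsed) else parsed
    return None if text == "-" else text


def _parse_cell(text: str, col: Column):
    if col.group is not None:
        if text == "-":
            return []
        return [_parse_atom(t, col.composite) for t in text.split("///")]
    return _parse_atom(text, col.composite)


def write_annotation_table(rows: Iterable[AnnotationRow], path,
                           schema: Sequence[Column] = ANNOTATION_COLUMNS) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(VARIANT_BLOCK_COLUMNS
                           + tuple(c.name for c in schema)) + "\n")
        for row in rows:
            row.check_parallel(schema)
            cells = ["-" if v is None else _num(v) for v in row.variant_block]
            cells += [_render_cell(row.columns.get(c.name), c) for c in schema]
            fh.write("\t".join(cells) + "\n")


def parse_annotation_table(path, schema: Sequence[Column] = ANNOTATION_COLUMNS):
    """Inverse of :func:`write_annotation_table` on the same schema."""
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        nblock = len(VARIANT_BLOCK_COLUMNS)
        if header[:nblock] != list(VARIANT_BLOCK_COLUMNS):
            raise FormatError("annotation table missing the 8-column variant block")
        by_name = {c.name: c for c in schema}
        cols = [by_name.get(name, Column(name)) for name in header[nblock:]]
        width = len(header)
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != width:
                raise ParseError(line_no, f"expected {width} cells, got {len(cells)}")
            block = tuple(None if c == "-" else c for c in cells[:nblock])
            columns = {
                col.name: _parse_cell(text, col)
                for col, text in zip(cols, cells[nblock:])
            }
            rows.append(AnnotationRow(block, columns))
    return rows
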