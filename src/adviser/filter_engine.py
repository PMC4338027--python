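"""Annotation-table filtration: the interactive UI's computational core.

Tables are lists of annotation rows.  Single-column predicates, AND/OR
compound filters, predefined inheritance filters for trios, an undo/redo
stack, per-class summary statistics, pagination (1000 rows per page) and
export are provided as library calls.

Multi-valued ``///`` cells use ANY-semantics: a row passes a predicate if
any parallel entry satisfies it.  Null cells (``-``) satisfy only the
``is_null`` operator — absence of an annotation is not a value and never
compares numerically.
"""

from __future__ import annotations

from dataclasses import dataclass

from .variant_io import AnnotationRow, VARIANT_BLOCK_COLUMNS

__all__ = [
    "FilterError",
    "FilterExpr",
    "CompoundFilter",
    "FilterStack",
    "apply_filter",
    "apply_compound",
    "parse_expression",
    "inheritance_filter",
    "load_trio_genotypes",
    "summary_stats",
    "paginate",
    "PRESETS",
    "SEVERITY_ORDER",
]

OPS = ("eq", "ne", "lt", "le", "gt", "ge", "contains", "in_set", "is_null")

SEVERITY_ORDER = (
    "nonsense", "frameshift", "splice_donor", "splice_acceptor", "missense",
    "inframe_ins", "inframe_del", "splice_region", "synonymous", "utr5",
    "utr3", "intronic", "noncoding", "intergenic",
)


class FilterError(ValueError):
    pass


def _available_columns(rows):
    cols = set(VARIANT_BLOCK_COLUMNS)
    for row in rows:
        cols.update(row.columns)
    return sorted(cols)


def _atoms(row: AnnotationRow, column: str):
    """Atomic cell values of one column as a flat list of strings; empty
    list for null cells."""
    if column in VARIANT_BLOCK_COLUMNS:
        v = row.variant_block[VARIANT_BLOCK_COLUMNS.index(column)]
        return [] if v is None else [str(v)]
    if column not in row.columns:
        raise FilterError(
            f"unknown column {column!r}; available: "
            f"{', '.join(_available_columns([row]))}")
    val = row.columns[column]
    if val is None:
        return []
    if not isinstance(val, list):
        val = [val]
    out = []
    for v in val:
        if v is None:
            continue
        if isinstance(v, tuple):
            out.append("~".join("-" if p is None else str(p) for p in v))
        else:
            out.append(str(v))
    return out


@dataclass(frozen=True)
class FilterExpr:
    column: str
    op: str
    value: object = None

    def __post_init__(self):
        if self.op not in OPS:
            raise FilterError(f"unknown operator {self.op!r}")

    def matches(self, row: AnnotationRow, any_semantics: bool = True) -> bool:
        atoms = _atoms(row, self.column)
        if self.op == "is_null":
            return not atoms
        if not atoms:
            return False
        hits = [self._matches_atom(a) for a in atoms]
        return any(hits) if any_semantics else all(hits)

    def _matches_atom(self, atom: str) -> bool:
        if self.op in ("lt", "le", "gt", "ge"):
            try:
                x, y = float(atom), float(self.value)
            except (TypeError, ValueError):
                return False
            return {"lt": x < y, "le": x <= y,
                    "gt": x > y, "ge": x >= y}[self.op]
        if self.op == "contains":
            return str(self.value) in atom
        if self.op == "in_set":
            return atom in {str(v) for v in self.value}
        # eq / ne: numeric comparison when both sides parse, else string
        try:
            equal = float(atom) == float(self.value)
        except (TypeError, ValueError):
            equal = atom == str(self.value)
        return equal if self.op == "eq" else not equal


@dataclass(frozen=True)
class CompoundFilter:
    """AND/OR tree over FilterExpr leaves; evaluation is order-independent
    (no short-circuit side effects)."""

    op: str                      # "and" | "or"
    children: tuple

    def __post_init__(self):
        if self.op not in ("and", "or"):
            raise FilterError(f"compound operator must be and/or, got {self.op!r}")
        if not self.children:
            raise FilterError("compound filter needs at least one child")

    def matches(self, row: AnnotationRow) -> bool:
        results = [c.matches(row) for c in self.children]
        return all(results) if self.op == "and" else any(results)


def apply_filter(rows, f: FilterExpr):
    return [row for row in rows if f.matches(row)]


def apply_compound(rows, cf) -> list:
    return [row for row in rows if cf.matches(row)]


# -- tiny expression language for the CLI: `a<0.01 && b==missense || c~=x` --

_OP_TOKENS = [("==", "eq"), ("!=", "ne"), ("<=", "le"), (">=", "ge"),
              ("~=", "contains"), ("<", "lt"), (">", "gt")]


def _parse_leaf(text: str) -> FilterExpr:
    text = text.strip()
    if text.endswith("?") :
        return FilterExpr(text[:-1].strip(), "is_null")
    for tok, op in _OP_TOKENS:
        if tok in text:
            col, val = text.split(tok, 1)
            return FilterExpr(col.strip(), op, val.strip())
    raise FilterError(f"cannot parse filter expression {text!r}")


def parse_expression(text: str):
    """Parse ``a<1 && b==x || c~=y`` (AND binds tighter than OR; no
    parentheses) into a filter tree."""
    or_parts = [p for p in text.split("||")]
    or_children = []
    for part in or_parts:
        and_leaves = tuple(_parse_leaf(p) for p in part.split("&&"))
        or_children.append(and_leaves[0] if len(and_leaves) == 1
                           else CompoundFilter("and", and_leaves))
    if len(or_children) == 1:
        return or_children[0]
    return CompoundFilter("or", tuple(or_children))


#: editable presets standing in for the UI's predefined custom filters
PRESETS = {
    "rare_coding": "maxAF<0.01 && region==coding",
    "rare_damaging": "maxAF<0.01 && missenseDamaging~=damaging",
    "clinical_candidates": "adviserClinical==1 || adviserClinical==1* || "
                           "adviserClinical==2 || adviserClinical==2*",
    "truncating": "effect~=nonsense || effect~=frameshift",
    "splice_affecting": "effect~=splice",
    "novel": "maxAF?",
}


# ---------------------------------------------------------------------------
# undo / redo

class FilterStack:
    """Applied-filter history with an undo/redo cursor.  The visible rows
    are always recomputed by replaying the active prefix over the base
    table, so undo→redo restores the exact row set."""

    def __init__(self, base_rows):
        self.base = list(base_rows)
        self._stack: list = []
        self._cursor = 0

    def apply(self, f) -> list:
        self._stack = self._stack[: self._cursor]
        self._stack.append(f)
        self._cursor += 1
        return self.current()

    def undo(self) -> list:
        if self._cursor:
            self._cursor -= 1
        return self.current()

    def redo(self) -> list:
        if self._cursor < len(self._stack):
            self._cursor += 1
        return self.current()

    def current(self) -> list:
        rows = self.base
        for f in self._stack[: self._cursor]:
            rows = [row for row in rows if f.matches(row)]
        return rows


# ---------------------------------------------------------------------------
# inheritance filters

def _gt_alleles(gt: str):
    parts = gt.replace("|", "/").split("/")
    if any(p not in ("0", "1") for p in parts):
        return None
    return tuple(int(p) for p in parts)


def _is(gt, kind: str) -> bool:
    a = _gt_alleles(gt) if isinstance(gt, str) else gt
    if a is None:
        return False
    if kind == "het":
        return len(set(a)) > 1
    if kind == "homref":
        return set(a) == {0}
    if kind == "homalt":
        return set(a) == {1}
    if kind == "hasalt":
        return 1 in a
    raise ValueError(kind)


def load_trio_genotypes(path, child: str, mother: str, father: str):
    """Genotype maps {role: {variant key: GT string}} from the original
    variant file (which retained its sample columns)."""
    from .variant_io import read_variants

    records, samples, _ = read_variants(path)
    roles = {"child": child, "mother": mother, "father": father}
    for role, name in roles.items():
        if name not in samples:
            raise FilterError(f"sample {name!r} ({role}) not in {samples}")
    idx = {role: samples.index(name) for role, name in roles.items()}
    out = {role: {} for role in roles}
    for rec in records:
        if not rec.genotypes:
            continue
        for role, i in idx.items():
            out[role][rec.key] = rec.genotypes[i]
    return out


def inheritance_filter(rows, trio, mode: str, affected_parent: str = "mother"):
    """Predefined family-based filters over a trio's genotypes.

    Returns ``(passing rows, n_excluded_missing)`` where the second value
    counts sites skipped for missing genotypes.
    """
    for role in ("child", "mother", "father"):
        if role not in trio:
            raise FilterError(f"trio genotypes missing sample {role!r}")
    missing = 0
    gts = []
    for row in rows:
        key = row.key
        g = tuple(trio[r].get(key) for r in ("child", "mother", "father"))
        if any(x is None or _gt_alleles(x) is None for x in g):
            missing += 1
            gts.append(None)
        else:
            gts.append(g)

    if mode == "de_novo":
        keep = [r for r, g in zip(rows, gts) if g and _is(g[0], "hasalt")
                and _is(g[1], "homref") and _is(g[2], "homref")]
    elif mode == "recessive_hom":
        keep = [r for r, g in zip(rows, gts) if g and _is(g[0], "homalt")
                and _is(g[1], "het") and _is(g[2], "het")]
    elif mode == "dominant":
        aff = 1 if affected_parent == "mother" else 2
        una = 3 - aff
        keep = [r for r, g in zip(rows, gts) if g and _is(g[0], "het")
                and _is(g[aff], "het") and _is(g[una], "homref")]
    elif mode == "compound_het":
        keep = _compound_het(rows, gts)
    else:
        raise FilterError(f"unknown inheritance mode {mode!r}")
    return keep, missing


def _compound_het(rows, gts):
    """Child-het variants grouped by gene; a gene qualifies when it has
    at least two, with at least one inherited exclusively from each parent
    (het in exactly one parent, hom-ref in the other)."""
    per_gene: dict[str, list] = {}
    origin_of = {}
    for row, g in zip(rows, gts):
        if not g or not _is(g[0], "het"):
            continue
        from_mother = _is(g[1], "het") and _is(g[2], "homref")
        from_father = _is(g[2], "het") and _is(g[1], "homref")
        if from_mother == from_father:     # ambiguous or absent origin
            continue
        origin_of[id(row)] = "mother" if from_mother else "father"
        for gene in (row.columns.get("gene") or []):
            if gene:
                per_gene.setdefault(gene, []).append(row)
    keep, seen = [], set()
    for gene, members in per_gene.items():
        origins = {origin_of[id(r)] for r in members}
        if len(members) >= 2 and origins == {"mother", "father"}:
            for r in members:
                if id(r) not in seen:
                    seen.add(id(r))
                    keep.append(r)
    return [r for r in rows if id(r) in seen]     # preserve table order


# ---------------------------------------------------------------------------
# statistics, pagination, export

def most_severe_effect(row: AnnotationRow) -> str:
    effects = [e for e in (row.columns.get("effect") or []) if e]
    ranked = [e for e in effects if e in SEVERITY_ORDER]
    return min(ranked, key=SEVERITY_ORDER.index) if ranked else "intergenic"


def summary_stats(rows) -> dict:
    """Counts and rates by most-severe effect, ADVISER clinical class and
    variant type; each row counts once per dimension."""
    n = len(rows)

    def tally(keyfn):
        counts: dict[str, int] = {}
        for row in rows:
            k = keyfn(row)
            counts[k] = counts.get(k, 0) + 1
        return {k: {"count": c, "rate": c / n if n else 0.0}
                for k, c in sorted(counts.items())}

    return {
        "n": n,
        "effect": tally(most_severe_effect),
        "adviser_class": tally(
            lambda r: r.columns.get("adviserClinical") or "-"),
        "vtype": tally(lambda r: r.variant_block[3] or "-"),
    }


def paginate(rows, page: int, page_size: int = 1000):
    """1-based page of at most ``page_size`` rows (default 1000 per page);
    pages past the end are empty, not an error."""
    if page < 1:
        raise FilterError("page index is 1-based")
    return rows[(page - 1) * page_size: page * page_size]
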