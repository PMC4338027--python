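"""De-novo functional-impact predictors.

These cover the variant classes whose impact cannot be tabulated ahead of
time: protein truncations (scored as the conserved fraction of the protein
removed, with re-initiation rescue at annotated alternative start sites),
TFBS changes (PSSM score delta over both strands), non-donor/acceptor
splice-region variants (relative PWM score drop), miRNA target gain/loss
(seed rescan), in-frame indels (conserved mass disrupted) and a pluggable
missense predictor interface.

Thresholds are documented defaults, configurable per call:

* truncation: damaging when >= 25% of the conserved mass is removed;
* TFBS: damaging when the best alt-window score falls below 0.7x the best
  reference-window score (reference score positive);
* splice region: damaging when the relative PWM score drops from >= 0.7 to
  < 0.7.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .variant_io import VariantRecord, revcomp

__all__ = [
    "PSSM",
    "TruncationInput",
    "ProteinContext",
    "PredictionResult",
    "truncation_score",
    "inframe_score",
    "pssm_delta",
    "pssm_delta_at",
    "splice_region_delta",
    "mirna_target_scan",
    "mirna_site_diff",
    "ConservationRulePredictor",
    "LookupPredictor",
    "read_pssm_file",
    "write_pssm_file",
]

BASES = "ACGT"

TRUNCATION_DAMAGING = 0.25
INFRAME_DAMAGING = 0.05
INFRAME_CRITICAL_WEIGHT = 0.9
TFBS_LOSS_FACTOR = 0.7
SPLICE_RELATIVE_CUTOFF = 0.7


@dataclass(frozen=True)
class PredictionResult:
    score: float
    damaging: bool
    detail: str = ""


@dataclass
class PSSM:
    """Position-specific scoring matrix; ``matrix[i]`` holds the log-odds
    scores for A, C, G, T at motif position i."""

    motif_id: str
    matrix: np.ndarray
    width: int = 0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PSSM matrix must be width x 4 (A C G T)")
        if not self.width:
            self.width = self.matrix.shape[0]
        if self.matrix.shape[0] != self.width or self.width < 1:
            raise ValueError("PSSM width does not match matrix")

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.matrix.min(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def score(self, window: str) -> float:
        window = window.upper()
        if len(window) != self.width:
            raise ValueError(f"window length {len(window)} != width {self.width}")
        total = 0.0
        for i, base in enumerate(window):
            j = BASES.find(base)
            # N (or any ambiguity) contributes the position average
            total += self.matrix[i, j] if j >= 0 else float(self.matrix[i].mean())
        return total

    def best_score(self, seq: str, both_strands: bool = True) -> float:
        if len(seq) < self.width:
            raise ValueError("sequence shorter than PSSM width")
        strands = [seq.upper()]
        if both_strands:
            strands.append(revcomp(seq.upper()))
        return max(self.score(s[i:i + self.width])
                   for s in strands
                   for i in range(len(s) - self.width + 1))

    def relative(self, raw: float) -> float:
        span = self.max_score - self.min_score
        return (raw - self.min_score) / span if span else 0.0


# ---------------------------------------------------------------------------
# truncation / in-frame scoring

@dataclass
class TruncationInput:
    tx: object                 # TranscriptModel
    stop_residue: int          # 1-based residue where translation stops

    def __post_init__(self):
        if not 1 <= self.stop_residue <= self.tx.protein_length:
            raise ValueError(
                f"stop_residue {self.stop_residue} outside protein "
                f"1..{self.tx.protein_length}")


def truncation_score(inp: TruncationInput,
                     threshold: float = TRUNCATION_DAMAGING) -> PredictionResult:
    """Fraction of the conserved protein mass removed by a premature stop,
    after adjustment for alternative start sites.

    With conserved-weight sum C over residues, protein length L and most
    downstream alternative start s*: the score is C(stop..L)/C(1..L), or
    C(stop..s*-1)/C(1..L) when translation can re-initiate at s* downstream
    of the stop.  Damaging at score >= ``threshold``.
    """
    w = np.asarray(inp.tx.weights(), dtype=float)
    total = float(w.sum())
    if total <= 0:
        return PredictionResult(0.0, False, "no conserved mass")
    stop = inp.stop_residue
    alt = max(inp.tx.alt_starts) if inp.tx.alt_starts else None
    if alt is not None and stop < alt:
        removed = float(w[stop - 1: alt - 1].sum())
        note = f"re-initiation at residue {alt}"
    else:
        removed = float(w[stop - 1:].sum())
        note = "no downstream re-initiation"
    score = removed / total
    return PredictionResult(score, score >= threshold,
                            f"{score:g} conserved mass removed; {note}")


def inframe_score(tx, residues,
                  threshold: float = INFRAME_DAMAGING,
                  critical_weight: float = INFRAME_CRITICAL_WEIGHT
                  ) -> PredictionResult:
    """Conserved mass of the residues deleted/disrupted by an in-frame
    indel, as a fraction of the whole protein; damaging at >= ``threshold``
    or when any disrupted residue is highly conserved."""
    w = np.asarray(tx.weights(), dtype=float)
    total = float(w.sum())
    idx = [r - 1 for r in residues if 1 <= r <= len(w)]
    hit = w[idx] if idx else np.array([])
    score = float(hit.sum()) / total if total else 0.0
    damaging = score >= threshold or bool((hit >= critical_weight).any())
    return PredictionResult(score, damaging,
                            f"{len(idx)} residues, mass fraction {score:g}")


# ---------------------------------------------------------------------------
# PSSM / TFBS

def pssm_delta(ref_window: str, alt_window: str, pssm: PSSM,
               loss_factor: float = TFBS_LOSS_FACTOR) -> PredictionResult:
    """Change in best PSSM score between the reference window and the same
    window with the variant applied; both strands and all offsets scanned."""
    best_ref = pssm.best_score(ref_window)
    best_alt = pssm.best_score(alt_window)
    damaging = best_ref > 0 and best_alt < loss_factor * best_ref
    return PredictionResult(best_alt - best_ref, damaging,
                            f"{best_ref:g}~{best_alt:g}")


def pssm_delta_at(rec: VariantRecord, feature: tuple, pssm: PSSM,
                  genome: str) -> PredictionResult:
    """Score a variant inside a TFBS instance: windows are the feature
    interval padded by width-1 flanking bases on each side."""
    pad = pssm.width - 1
    s = max(0, feature[0] - pad)
    e = min(len(genome), feature[1] + pad)
    ref_window = genome[s:e].upper()
    off = rec.start - s
    alt_window = (ref_window[:off] + rec.alt +
                  ref_window[off + len(rec.ref):])
    return pssm_delta(ref_window, alt_window, pssm)


# ---------------------------------------------------------------------------
# splice-region scoring

#: PWM spans in transcript orientation (exonic/intronic nucleotide counts)
DONOR_EXONIC, DONOR_INTRONIC = 3, 6          # exonic -3 .. intronic +6
ACCEPTOR_INTRONIC, ACCEPTOR_EXONIC = 14, 1   # intronic -14 .. exonic +1


def _junction_windows(tx):
    """Genomic (start, end, kind, pwm_width) for each junction's PWM span."""
    out = []
    for i_start, i_end in tx.introns:
        if tx.strand == "+":
            out.append((i_start - DONOR_EXONIC, i_start + DONOR_INTRONIC,
                        "donor"))
            out.append((i_end - ACCEPTOR_INTRONIC, i_end + ACCEPTOR_EXONIC,
                        "acceptor"))
        else:
            out.append((i_end - DONOR_INTRONIC, i_end + DONOR_EXONIC, "donor"))
            out.append((i_start - ACCEPTOR_EXONIC,
                        i_start + ACCEPTOR_INTRONIC, "acceptor"))
    return out


def find_junction_window(rec: VariantRecord, tx):
    """The (start, end, kind) junction PWM span containing the variant, or
    None.  Splice-region positions outside both spans (e.g. donor-side
    intronic +7/+8) carry no PWM prediction."""
    if rec.vtype not in ("snp", "sub"):
        return None
    for w_start, w_end, kind in _junction_windows(tx):
        if w_start <= rec.start and rec.end <= w_end:
            return (w_start, w_end, kind)
    return None


def splice_region_delta(rec: VariantRecord, tx, donor_pwm: PSSM,
                        acceptor_pwm: PSSM, genome: str,
                        cutoff: float = SPLICE_RELATIVE_CUTOFF
                        ) -> PredictionResult:
    """Relative PWM score change at the junction nearest the variant.

    The relative score r(x) = (score - min) / (max - min) lies in [0, 1];
    the call is damaging when r drops from >= ``cutoff`` to < ``cutoff``.
    Only single-base substitutions inside a junction PWM span are scored.
    """
    if rec.vtype not in ("snp", "sub"):
        raise ValueError("splice-region scoring is defined for snp/sub only")
    hit = find_junction_window(rec, tx)
    if hit is not None:
        w_start, w_end, kind = hit
        pwm = donor_pwm if kind == "donor" else acceptor_pwm
        window = genome[w_start:w_end].upper()
        off = rec.start - w_start
        alt_window = window[:off] + rec.alt + window[off + len(rec.ref):]
        if tx.strand == "-":
            window, alt_window = revcomp(window), revcomp(alt_window)
        if len(window) != pwm.width:
            raise ValueError(
                f"{kind} PWM width {pwm.width} != window {len(window)}")
        r_ref = pwm.relative(pwm.score(window))
        r_alt = pwm.relative(pwm.score(alt_window))
        damaging = r_alt < cutoff <= r_ref
        return PredictionResult(r_alt - r_ref, damaging,
                                f"{r_ref:g}~{r_alt:g}")
    raise ValueError("variant lies outside every junction PWM window")


# ---------------------------------------------------------------------------
# miRNA target scanning

def _norm_rna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def mirna_target_scan(utr: str, mirna: str):
    """Canonical seed sites of ``mirna`` in ``utr``.

    Site classes (target 5'->3'): 8mer = complement of miRNA positions 2-8
    followed by A opposite position 1; 7mer_m8 = complement of 2-8 without
    the A; 7mer_A1 = complement of 2-7 plus the A.  Returns a sorted list
    of ((start, end), class) in UTR coordinates.
    """
    utr = _norm_rna(utr)
    mirna = _norm_rna(mirna)
    if len(mirna) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    core6 = revcomp(mirna[1:7])      # complement of positions 2-7
    m8c = revcomp(mirna[7])          # complement of position 8
    sites = []
    for i in range(len(utr) - 6 + 1):
        if utr[i:i + 6] != core6:
            continue
        has_m8 = i >= 1 and utr[i - 1] == m8c
        has_a1 = i + 6 < len(utr) and utr[i + 6] == "A"
        if has_m8 and has_a1:
            sites.append(((i - 1, i + 7), "8mer"))
        elif has_m8:
            sites.append(((i - 1, i + 6), "7mer_m8"))
        elif has_a1:
            sites.append(((i, i + 7), "7mer_A1"))
    return sorted(sites)


def mirna_site_diff(ref_sites, alt_sites):
    """Sites lost and gained between two scans (ref vs alt of either the
    UTR or the miRNA itself)."""
    ref, alt = set(ref_sites), set(alt_sites)
    return sorted(ref - alt), sorted(alt - ref)


# ---------------------------------------------------------------------------
# missense predictor interface

@dataclass(frozen=True)
class ProteinContext:
    gene: str
    residue: int
    ref_aa: str
    alt_aa: str
    conservation: float


#: physicochemical substitution classes for the default rule predictor
AA_CLASS = {
    **dict.fromkeys("AVLIM", "nonpolar"),
    **dict.fromkeys("STNQ", "polar"),
    **dict.fromkeys("FWY", "aromatic"),
    **dict.fromkeys("DE", "acidic"),
    **dict.fromkeys("KRH", "basic"),
    **dict.fromkeys("GCP", "special"),
}


@dataclass
class ConservationRulePredictor:
    """Default bundled missense predictor: damaging iff the residue is
    conserved (weight >= ``min_weight``) and the substitution crosses
    physicochemical classes."""

    min_weight: float = 0.5

    def __call__(self, ctx: ProteinContext) -> PredictionResult:
        conserved = ctx.conservation >= self.min_weight
        nonconservative = AA_CLASS.get(ctx.ref_aa) != AA_CLASS.get(ctx.alt_aa)
        damaging = conserved and nonconservative
        return PredictionResult(
            ctx.conservation if damaging else 0.0, damaging,
            f"{ctx.ref_aa}->{ctx.alt_aa} "
            f"({'non' if nonconservative else ''}conservative), "
            f"weight {ctx.conservation:g}")


@dataclass
class LookupPredictor:
    """Missense predictor backed by a table of precomputed third-party
    calls keyed by (gene, ref_aa, residue, alt_aa)."""

    table: dict = field(default_factory=dict)
    fallback: object | None = None

    def __call__(self, ctx: ProteinContext) -> PredictionResult:
        key = (ctx.gene, ctx.ref_aa, ctx.residue, ctx.alt_aa)
        if key in self.table:
            call = self.table[key]
            return PredictionResult(1.0 if call == "damaging" else 0.0,
                                    call == "damaging", "tabulated")
        if self.fallback is not None:
            return self.fallback(ctx)
        raise KeyError(f"no tabulated prediction for {key}")


# ---------------------------------------------------------------------------
# PSSM file format: one block per motif — motif id line, then `width` rows
# of 4 whitespace-separated scores in base order A C G T; blocks separated
# by blank lines.

def read_pssm_file(path) -> dict[str, PSSM]:
    out: dict[str, PSSM] = {}
    block: list[str] = []

    def flush(lines):
        if not lines:
            return
        motif_id = lines[0].lstrip(">").strip()
        rows = [[float(x) for x in ln.split()] for ln in lines[1:]]
        out[motif_id] = PSSM(motif_id, np.array(rows))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                flush(block)
                block = []
            else:
                block.append(line)
    flush(block)
    return out


def write_pssm_file(pssms, path) -> None:
    with open(path, "w", newline="\n") as fh:
        for pssm in pssms.values() if isinstance(pssms, dict) else pssms:
            fh.write(f">{pssm.motif_id}\n")
            for row in pssm.matrix:
                fh.write(" ".join(format(x, "g") for x in row) + "\n")
            fh.write("\n")
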