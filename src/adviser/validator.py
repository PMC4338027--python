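"""Reference-genome validation with auto-correction.

Submitted variants are checked against the reference FASTA.  Three common
submission mistakes are recognized and repaired, in a fixed precedence:

1. ``shift_match`` — coordinates were 1-based (the reference matches one
   base upstream); repaired by decrementing start/end.
2. ``swap_match`` — reference and alternate alleles were exchanged.
3. ``strand_match`` — alleles were reported on the negative strand.

The coordinate convention is inferred once per file by majority vote of
direct vs. shifted matches; records that still mismatch after the single
applicable correction are rejected with a reason, and processing always
continues on the remaining records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .variant_io import CorrectionNote, VariantRecord, revcomp

__all__ = [
    "MatchStatus",
    "ValidationReport",
    "match_status",
    "infer_convention",
    "correct_record",
    "validate_file",
]

STATUS_ORDER = ("match", "shift_match", "swap_match", "strand_match", "mismatch")


@dataclass(frozen=True)
class MatchStatus:
    status: str
    evidence: str = ""

    def __post_init__(self):
        if self.status not in STATUS_ORDER:
            raise ValueError(f"unknown status {self.status!r}")


@dataclass
class ValidationReport:
    valid: list[VariantRecord] = field(default_factory=list)
    corrected: list[VariantRecord] = field(default_factory=list)
    rejected: list[tuple[int, str]] = field(default_factory=list)
    convention: str = "zero_based"

    @property
    def accepted(self) -> list[VariantRecord]:
        return self.valid + self.corrected


def _slice(ref_genome, chrom: str, start: int, end: int) -> str:
    if start < 0:
        return ""
    return str(ref_genome[chrom][start:end]).upper()


def match_status(rec: VariantRecord, ref_genome) -> MatchStatus:
    """Classify how a record's ref allele relates to the reference genome.

    Statuses are evaluated in the fixed precedence
    match > shift_match > swap_match > strand_match > mismatch.
    Insertions carry no reference bases and always match.
    """
    if rec.chrom not in ref_genome:
        raise KeyError(f"chromosome {rec.chrom!r} absent from reference")
    if rec.vtype == "ins":
        return MatchStatus("match", "insertion: no reference bases to verify")
    here = _slice(ref_genome, rec.chrom, rec.start, rec.end)
    if here == rec.ref:
        return MatchStatus("match", f"genome[{rec.start}:{rec.end}]={here}")
    upstream = _slice(ref_genome, rec.chrom, rec.start - 1, rec.end - 1)
    if upstream == rec.ref:
        return MatchStatus(
            "shift_match", f"genome[{rec.start - 1}:{rec.end - 1}]={upstream}")
    if rec.alt and here == rec.alt:
        return MatchStatus("swap_match", f"genome matches alt allele {rec.alt}")
    if here == revcomp(rec.ref):
        return MatchStatus(
            "strand_match", f"genome matches reverse complement of {rec.ref}")
    return MatchStatus("mismatch", f"genome[{rec.start}:{rec.end}]={here}"
                                   f" != ref {rec.ref}")


def infer_convention(records, ref_genome) -> str:
    """Decide 0- vs 1-based once for the whole file.

    The convention with the strictly greater direct-match fraction over
    non-insertion records wins; ties (and files of only insertions)
    default to zero_based.
    """
    zero = one = total = 0
    for rec in records:
        if rec.vtype == "ins" or rec.chrom not in ref_genome:
            continue
        total += 1
        if _slice(ref_genome, rec.chrom, rec.start, rec.end) == rec.ref:
            zero += 1
        if _slice(ref_genome, rec.chrom, rec.start - 1, rec.end - 1) == rec.ref:
            one += 1
    return "one_based" if total and one > zero else "zero_based"


def correct_record(rec: VariantRecord, status: MatchStatus) -> VariantRecord:
    """Apply the single correction implied by a non-match status."""
    if status.status == "shift_match":
        return rec.replace(
            start=rec.start - 1, end=rec.end - 1,
            correction=CorrectionNote("coordinate_shift",
                                      "1-based coordinates shifted by -1"))
    if status.status == "swap_match":
        # vtype is preserved: swap is only defined for length-preserving types
        return rec.replace(
            ref=rec.alt, alt=rec.ref,
            correction=CorrectionNote("allele_swap",
                                      f"ref/alt exchanged ({rec.ref}<->{rec.alt})"))
    if status.status == "strand_match":
        return rec.replace(
            ref=revcomp(rec.ref), alt=revcomp(rec.alt),
            correction=CorrectionNote("strand_flip",
                                      "alleles reverse-complemented"))
    raise ValueError(f"correct_record called with status {status.status!r}")


def validate_file(records, ref_genome) -> ValidationReport:
    """Validate a whole file: infer the convention globally, then match or
    correct each record; irreconcilable records are rejected, never fatal."""
    report = ValidationReport(convention=infer_convention(records, ref_genome))
    shift_all = report.convention == "one_based"
    for rec in records:
        applied = False     # corrections from THIS run, not from prior reads
        if shift_all and rec.start >= 1:
            rec = rec.replace(
                start=rec.start - 1, end=rec.end - 1,
                correction=CorrectionNote(
                    "coordinate_shift", "file inferred 1-based"))
            applied = True
        try:
            status = match_status(rec, ref_genome)
        except KeyError as exc:
            report.rejected.append((rec.line_no, str(exc)))
            continue
        if status.status == "match":
            (report.corrected if applied else report.valid).append(rec)
        elif status.status == "mismatch":
            report.rejected.append((rec.line_no, status.evidence))
        elif status.status == "shift_match" and shift_all:
            # already shifted globally; a second shift would be a compound fix
            report.rejected.append(
                (rec.line_no, "still shifted after global coordinate correction"))
        else:
            fixed = correct_record(rec, status)
            if match_status(fixed, ref_genome).status == "match":
                report.corrected.append(fixed)
            else:
                report.rejected.append(
                    (rec.line_no, f"correction {status.status} did not resolve "
                                  f"the mismatch ({status.evidence})"))
    return report
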