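"""Raw-read parsing: adapter matching, concatemer splitting, grammar
recognition and artifact filtering.

A pre-circularization molecule reads as

    barcode, Illumina adapter, UMI, GGG, template, polyA,
    rc(Illumina adapter), rc(barcode)               (case 1)

or as the reverse complement of that layout (case 2, the other strand was
read). Records containing several such units end-to-end are circularization
concatemers and are split at (rc(barcode), barcode) boundaries before
parsing. A unit is valid only if one specific barcode and its reverse
complement are identified with no other barcode in between, the barcode is
adjacent (+-10 bp) to the Illumina adapter, and a 10-base A (case 1) or T
(case 2) homopolymer confirms the poly(A) tail.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .sequences import (
    BARCODES,
    ILLUMINA_ADAPTER,
    find_adapters,
    has_homopolymer,
    homopolymer_runs,
    revcomp,
)
from .types import AdapterMatch, ValidRead

DEFAULT_MAX_MM = 2
DEFAULT_PROXIMITY = 10
POLYA_RUN = 10
MAX_G_RUN = 5


@dataclass
class Rejection:
    read_id: str
    subread_index: int
    reason: str


@dataclass
class ExtractionResult:
    valid_reads: list[ValidRead] = field(default_factory=list)
    rejections: list[Rejection] = field(default_factory=list)

    @property
    def rejection_counts(self) -> Counter:
        return Counter(r.reason for r in self.rejections)


def _adapter_set(barcodes: dict[str, str]) -> dict[str, str]:
    return {"illumina": ILLUMINA_ADAPTER, **barcodes}


def split_concatemers(seq: str, matches: list[AdapterMatch]) -> list[tuple[int, int]]:
    """Partition a read at boundaries between consecutive (barcode_rc,
    barcode) adapter pairs.

    Units are ligated end to end, so the end of one unit (rc(barcode)) is
    immediately followed by the start of the next (barcode). A read with at
    most one such boundary pattern absent yields a single interval.
    """
    bc = [m for m in matches if m.base != "illumina"]
    bc.sort(key=lambda m: m.position)
    cuts = []
    for left, right in zip(bc, bc[1:]):
        if left.is_rc and not right.is_rc and right.position >= left.end - 2:
            cuts.append((left.end + right.position) // 2)
    bounds = [0] + cuts + [len(seq)]
    return [(a, b) for a, b in zip(bounds, bounds[1:]) if b > a]


def _parse_case1(seq: str, matches: list[AdapterMatch], proximity: int,
                 ) -> tuple[str | None, str | None, str | None, int, str | None]:
    """Parse a sense-orientation unit.

    Returns (barcode_name, umi, template, g_run, reject_reason); exactly one
    of (umi, reject_reason) is None.
    """
    bc = [m for m in matches if m.base != "illumina"]
    fwd = [m for m in bc if not m.is_rc]
    rcs = [m for m in bc if m.is_rc]
    if not fwd or not rcs:
        return None, None, None, 0, "no_barcode"
    b_fwd = min(fwd, key=lambda m: m.position)
    b_rc = max(rcs, key=lambda m: m.position)
    if b_fwd.base != b_rc.base:
        return None, None, None, 0, "barcode_conflict"
    inner = [m for m in bc
             if b_fwd.position < m.position < b_rc.position
             and m not in (b_fwd, b_rc)]
    if any(m.base != b_fwd.base for m in inner):
        return None, None, None, 0, "barcode_conflict"
    ill_fwd = [m for m in matches if m.which == "illumina"
               and abs(m.position - b_fwd.end) <= proximity]
    ill_rc = [m for m in matches if m.which == "illumina_rc"
              and abs(b_rc.position - m.end) <= proximity]
    if not ill_fwd or not ill_rc:
        return None, None, None, 0, "no_adapter"
    ia = min(ill_fwd, key=lambda m: m.position)
    ib = max(ill_rc, key=lambda m: m.position)
    umi = seq[ia.end: ia.end + 6]
    if len(umi) < 6:
        return None, None, None, 0, "truncated"
    # template-switch G-run: maximal run (<= 5) following the UMI
    g_run = 0
    while (g_run < MAX_G_RUN
           and ia.end + 6 + g_run < len(seq)
           and seq[ia.end + 6 + g_run] == "G"):
        g_run += 1
    # the poly(A) tail: a >= 10-base A-run ending adjacent to rc(adapter)
    tail = None
    for a, b in homopolymer_runs(seq, "A", POLYA_RUN):
        if abs(ib.position - b) <= proximity and a > ia.end:
            tail = (a, b)
    if tail is None:
        return None, None, None, 0, "no_polya"
    template = seq[ia.end + 6 + g_run: tail[0]]
    return b_fwd.base, umi, template, g_run, None


def _looks_case2(seq: str, matches: list[AdapterMatch], proximity: int) -> bool:
    """Case 2 signature: a >= 10-base T-run starting right after the forward
    Illumina adapter (where case 1 has UMI+GGG instead)."""
    for m in matches:
        if m.which != "illumina":
            continue
        for a, _ in homopolymer_runs(seq, "T", POLYA_RUN):
            if abs(a - m.end) <= proximity:
                return True
    return False


def parse_valid_read(seq: str, read_id: str, subread_index: int,
                     barcodes: dict[str, str] | None = None,
                     max_mm: int = DEFAULT_MAX_MM,
                     proximity: int = DEFAULT_PROXIMITY,
                     matches: list[AdapterMatch] | None = None,
                     ) -> ValidRead | Rejection:
    """Parse one subread interval into a ValidRead, or reject with a reason.

    Case-2 units are reverse-complemented and parsed with the case-1 rules
    (the two layouts are exact reverse complements), so template_seq is
    always in transcript orientation.
    """
    barcodes = BARCODES if barcodes is None else barcodes
    adapters = _adapter_set(barcodes)
    if matches is None:
        matches = find_adapters(seq, adapters, max_mm)
    case = 1
    if _looks_case2(seq, matches, proximity):
        case = 2
        seq = revcomp(seq)
        matches = find_adapters(seq, adapters, max_mm)
    bc_name, umi, template, g_run, reason = _parse_case1(seq, matches, proximity)
    if reason is not None:
        return Rejection(read_id, subread_index, reason)
    return ValidRead(
        read_id=read_id, subread_index=subread_index,
        barcode=barcodes[bc_name], umi=umi, case=case,
        template_seq=template, has_polya=True, g_run=g_run,
    )


def filter_polya_polyt(read: ValidRead, run: int = POLYA_RUN) -> bool:
    """Keep (True) unless the template contains both an A- and a T-run of
    >= `run` bases — those are likely PCR artifacts."""
    t = read.template_seq
    return not (has_homopolymer(t, "A", run) and has_homopolymer(t, "T", run))


def extract_reads(fastq: list[tuple[str, str]],
                  barcodes: dict[str, str] | None = None,
                  max_mm: int = DEFAULT_MAX_MM,
                  proximity: int = DEFAULT_PROXIMITY) -> ExtractionResult:
    """Full extraction: adapter scan, concatemer split, per-unit parsing and
    the polyA/polyT artifact filter. Subread indices follow left-to-right
    position in the raw read."""
    barcodes = BARCODES if barcodes is None else barcodes
    adapters = _adapter_set(barcodes)
    result = ExtractionResult()
    for rid, seq in fastq:
        matches = find_adapters(seq, adapters, max_mm)
        intervals = split_concatemers(seq, matches)
        for sub, (a, b) in enumerate(intervals):
            sub_matches = [
                AdapterMatch(m.position - a, m.which, m.length, m.mismatches)
                for m in matches if a <= m.position and m.end <= b
            ]
            parsed = parse_valid_read(
                seq[a:b], rid, sub, barcodes, max_mm, proximity,
                matches=sub_matches,
            )
            if isinstance(parsed, Rejection):
                result.rejections.append(parsed)
            elif not filter_polya_polyt(parsed):
                result.rejections.append(Rejection(rid, sub, "polya_polyt_artifact"))
            else:
                result.valid_reads.append(parsed)
    return result
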