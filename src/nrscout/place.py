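"""Anchoring NRS on the reference via flanking-sequence alignment.

Each candidate's flanks (up to 1 kb immediately outside the source interval)
are aligned to the reference.  A flank *qualifies* when its best block has
identity >= 98 covering >= 95% of the flank; a placement is

* ``precise``     — both flanks qualify with gapless blocks on the same
                    chromosome/strand in consistent order within ``max_span``;
                    the breakends are the inner block ends,
* ``unlocalized`` — one-sided anchoring, a gapped qualifying alignment, or a
                    qualifying flank abutting an N-gap,
* ``unplaced``    — no or conflicting anchoring (conflict reason recorded).

A small negative reference span (target-site duplication / microhomology) is
clamped to a zero-length interval.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .align import AlignParams, AlignmentBlock, KmerIndex, local_align, revcomp
from .errors import IntegrityError
from .extract import NRSRecord


@dataclass
class Placement:
    nrs_id: str
    status: str  # precise | unlocalized | unplaced
    chrom: str | None = None
    left_breakend: int | None = None
    right_breakend: int | None = None
    in_gap: bool = False
    left_flank_aln: AlignmentBlock | None = None
    right_flank_aln: AlignmentBlock | None = None
    conflict_reason: str | None = None


@dataclass(frozen=True)
class AnchorParams:
    flank_len: int = 1000
    min_flank: int = 200
    min_flank_identity: float = 98.0
    min_flank_cov: float = 0.95
    max_span: int = 1_000_000
    microhomology_slop: int = 20
    gap_slop: int = 100
    min_gap_run: int = 10


def find_n_runs(genome: dict[str, str], min_run: int = 10) -> dict[str, list[tuple[int, int]]]:
    """Maximal N-runs of length >= ``min_run`` per chromosome."""
    pat = re.compile("N{%d,}" % min_run)
    return {
        chrom: [(m.start(), m.end()) for m in pat.finditer(seq.upper())]
        for chrom, seq in genome.items()
    }


def extract_flanks(
    record: NRSRecord,
    assembly: dict[str, str],
    flank_len: int = 1000,
    min_flank: int = 200,
) -> tuple[str | None, str | None]:
    """Up to ``flank_len`` bases immediately outside each end of the source
    interval; None when fewer than ``min_flank`` bases are available."""
    contig = assembly.get(record.source_contig)
    if contig is None or not (0 <= record.source_start < record.source_end <= len(contig)):
        raise IntegrityError(
            f"{record.nrs_id}: provenance {record.source_contig}:"
            f"{record.source_start}-{record.source_end} outside assembly"
        )
    if contig[record.source_start : record.source_end] != record.sequence:
        raise IntegrityError(f"{record.nrs_id}: sequence does not match provenance")
    left = contig[max(0, record.source_start - flank_len) : record.source_start]
    right = contig[record.source_end : record.source_end + flank_len]
    return (
        left if len(left) >= min_flank else None,
        right if len(right) >= min_flank else None,
    )


def _best_qualifying(
    flank: str | None,
    reference_index: KmerIndex,
    ap: AnchorParams,
    params: AlignParams,
    qid: str,
) -> AlignmentBlock | None:
    if flank is None:
        return None
    blocks = local_align(flank, reference_index, params, query_id=qid)
    qual = [
        b
        for b in blocks
        if b.identity >= ap.min_flank_identity
        and (b.query_end - b.query_start) >= ap.min_flank_cov * len(flank)
    ]
    return max(qual, key=lambda b: b.score) if qual else None


def _refine_junction(
    ref_seq: str, pos: int, outer: str, inner: str, genomic_left: bool,
    w_outer: int = 50, w_inner: int = 60, max_shift: int = 25,
) -> int:
    """Pin a breakend to the exact flank/variant junction.

    The flank block is gapless, so the bases around its inner end are in
    register with the reference: score each column of [flank tail | NRS
    head] against the reference by a high-versus-divergent log-likelihood
    ratio and put the junction at the changepoint.  The divergent regime's
    match probability is estimated from the variant-side columns themselves
    (an alternate allele sits near its target identity, an insertion near
    the random 25%), which keeps a stray background mismatch inside the
    flank from pulling the boundary outward and chance variant-side matches
    from pushing it inward.
    """
    outer = outer[-w_outer:] if genomic_left else outer[:w_outer]
    inner = inner[:w_inner] if genomic_left else inner[-w_inner:]
    if genomic_left:
        query = outer + inner
        lo = pos - len(outer)
        window = ref_seq[max(0, lo) : pos + len(inner)]
        query = query[max(0, lo) - lo :]
        lo = max(0, lo)
    else:
        query = inner + outer
        lo = pos - len(inner)
        window = ref_seq[max(0, lo) : pos + len(outer)]
        query = query[max(0, lo) - lo :]
        lo = max(0, lo)
    n = min(len(query), len(window))
    if n == 0:
        return pos
    eq = np.frombuffer(query[:n].encode(), dtype=np.uint8) == np.frombuffer(
        window[:n].encode(), dtype=np.uint8
    )
    inner_cols = eq[pos - lo :] if genomic_left else eq[: max(0, pos - lo)]
    p_low = float(inner_cols.mean()) if inner_cols.size >= 10 else 0.25
    p_low = min(max(p_low, 0.05), 0.85)
    p_high = 0.995
    wm = float(np.log(p_high / p_low))
    wx = float(np.log((1 - p_high) / (1 - p_low)))
    c = np.concatenate([[0.0], np.cumsum(np.where(eq, wm, wx))])
    if genomic_left:
        new = lo + int(np.argmax(c))  # keep the high regime on the left
    else:
        suffix = c[-1] - c
        new = lo + int(np.argmax(suffix))
    if abs(new - pos) > max_shift:
        return pos
    return new


def _near_gap(chrom: str, pos: int, gaps: dict[str, list[tuple[int, int]]], slop: int) -> bool:
    for s, e in gaps.get(chrom, []):
        if s - slop <= pos <= e + slop:
            return True
    return False


def anchor(
    record: NRSRecord,
    flanks: tuple[str | None, str | None],
    reference_index: KmerIndex,
    ref_gaps: dict[str, list[tuple[int, int]]] | None = None,
    anchor_params: AnchorParams | None = None,
    params: AlignParams | None = None,
) -> Placement:
    """Evaluate both flanks' best reference alignments into a Placement."""
    ap = anchor_params or AnchorParams()
    params = params or AlignParams()
    ref_gaps = ref_gaps or {}
    left, right = flanks
    lb = _best_qualifying(left, reference_index, ap, params, f"{record.nrs_id}.L")
    rb = _best_qualifying(right, reference_index, ap, params, f"{record.nrs_id}.R")

    if lb is None and rb is None:
        return Placement(record.nrs_id, "unplaced", conflict_reason="no_anchor")
    if lb is None or rb is None:
        b = lb or rb
        inner = _inner_end(b, is_left=(b is lb))
        in_gap = _near_gap(b.target_id, inner, ref_gaps, ap.gap_slop)
        return Placement(
            record.nrs_id, "unlocalized", chrom=b.target_id,
            left_breakend=inner if b is lb else None,
            right_breakend=inner if b is rb else None,
            in_gap=in_gap, left_flank_aln=lb, right_flank_aln=rb,
        )

    if lb.target_id != rb.target_id:
        return Placement(
            record.nrs_id, "unplaced", conflict_reason="different_chrom",
            left_flank_aln=lb, right_flank_aln=rb,
        )
    if lb.strand != rb.strand:
        return Placement(
            record.nrs_id, "unplaced", conflict_reason="different_strand",
            left_flank_aln=lb, right_flank_aln=rb,
        )
    chrom = lb.target_id
    # orient to genomic coordinates: on '-' the right flank is genomic-left
    if lb.strand == "+":
        gl, gr = lb, rb
        gl_flank, gr_flank, g_nrs = left, right, record.sequence
    else:
        gl, gr = rb, lb
        gl_flank, gr_flank = revcomp(right), revcomp(left)
        g_nrs = revcomp(record.sequence)
    ref_seq = reference_index.seqs[chrom]
    left_be = _refine_junction(ref_seq, gl.target_end, gl_flank, g_nrs, True)
    right_be = _refine_junction(ref_seq, gr.target_start, gr_flank, g_nrs, False)
    span = right_be - left_be
    if span < -ap.microhomology_slop:
        return Placement(
            record.nrs_id, "unplaced", conflict_reason="overlap",
            left_flank_aln=lb, right_flank_aln=rb,
        )
    if span > ap.max_span:
        return Placement(
            record.nrs_id, "unplaced", conflict_reason="span_exceeded",
            left_flank_aln=lb, right_flank_aln=rb,
        )
    if span < 0:  # microhomology: clamp to a zero-length interval (leftmost)
        left_be = right_be = min(gl.target_end, gr.target_start)
    gapped = lb.gap_opens > 0 or rb.gap_opens > 0
    near_gap = _near_gap(chrom, left_be, ref_gaps, ap.gap_slop) or _near_gap(
        chrom, right_be, ref_gaps, ap.gap_slop
    )
    status = "precise" if not gapped and not near_gap else "unlocalized"
    pl = Placement(
        record.nrs_id, status, chrom=chrom,
        left_breakend=left_be, right_breakend=right_be,
        left_flank_aln=lb, right_flank_aln=rb,
    )
    pl.in_gap = _overlaps_gap(pl, ref_gaps, ap)
    return pl


def _inner_end(block: AlignmentBlock, is_left: bool) -> int:
    """Reference coordinate where a single anchored flank meets the NRS."""
    if block.strand == "+":
        return block.target_end if is_left else block.target_start
    return block.target_start if is_left else block.target_end


def _overlaps_gap(
    pl: Placement, gaps: dict[str, list[tuple[int, int]]], ap: AnchorParams
) -> bool:
    if pl.chrom is None:
        return False
    if pl.left_breakend is not None and pl.right_breakend is not None:
        lo, hi = pl.left_breakend, pl.right_breakend
    else:
        pos = pl.left_breakend if pl.left_breakend is not None else pl.right_breakend
        lo, hi = pos - ap.gap_slop, pos + ap.gap_slop
    for s, e in gaps.get(pl.chrom, []):
        if s <= hi and e >= lo:
            return True
    return False


def gap_overlap(
    placements: Sequence[Placement],
    reference: dict[str, str],
    anchor_params: AnchorParams | None = None,
) -> list[bool]:
    """Recompute the in-gap flag for each placement against maximal N-runs."""
    ap = anchor_params or AnchorParams()
    gaps = find_n_runs(reference, ap.min_gap_run)
    flags = []
    for pl in placements:
        flag = pl.status != "unplaced" and _overlaps_gap(pl, gaps, ap)
        pl.in_gap = flag
        flags.append(flag)
    return flags
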