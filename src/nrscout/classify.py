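"""Classification of precisely placed NRS and gene-annotation intersection.

A precisely placed sequence is an *insertion* when its breakends (the two
reference coordinates delimiting the reference allele) essentially coincide
— the sequence is simply introduced without replacing reference bases.  It
is an *alternate allele* when the reference allele is at least 400 bp,
shares less than 90% identity with it (or none at all), and the two alleles
have comparable length (ratio within [1/3, 3], inclusive).  Everything else
is *ambiguous*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import AlignParams, align_pair_dp, align_to_genome
from .errors import InputError
from .place import Placement

RATIO_LO = 1.0 / 3.0
RATIO_HI = 3.0


@dataclass
class NRSCall:
    nrs_id: str
    call: str  # insertion | alternate | ambiguous
    chrom: str
    left_breakend: int
    right_breakend: int
    ref_allele_span: int
    ref_allele_identity: float | None  # best local DP identity; None if no alignment
    length_ratio: float | None  # len(NRS) / ref_allele_span


def classify_call(
    placement: Placement,
    nrs_seq: str,
    reference: dict[str, str],
    insertion_slop: int = 20,
    min_alt_ref_span: int = 400,
    max_alt_identity: float = 90.0,
    params: AlignParams | None = None,
) -> NRSCall:
    """Classify one precise placement as insertion / alternate / ambiguous.

    The divergence criterion is strict (< 90); "no alignment" (best local
    score below ``params.min_score``) counts as satisfying it.  Reference
    allele spans between ``insertion_slop`` and ``min_alt_ref_span`` are
    ambiguous by definition.
    """
    if placement.status != "precise":
        raise InputError(f"{placement.nrs_id}: classify_call requires a precise placement")
    params = params or AlignParams()
    span = max(0, placement.right_breakend - placement.left_breakend)
    identity: float | None = None
    ratio: float | None = None
    if span > 0:
        ratio = len(nrs_seq) / span
    if span <= insertion_slop:
        call = "insertion"
    elif span < min_alt_ref_span:
        call = "ambiguous"
        identity = _allele_identity(nrs_seq, placement, reference, params)
    else:
        identity = _allele_identity(nrs_seq, placement, reference, params)
        divergent = identity is None or identity < max_alt_identity
        comparable = ratio is not None and RATIO_LO <= ratio <= RATIO_HI
        call = "alternate" if divergent and comparable else "ambiguous"
    return NRSCall(
        nrs_id=placement.nrs_id,
        call=call,
        chrom=placement.chrom,
        left_breakend=placement.left_breakend,
        right_breakend=placement.right_breakend,
        ref_allele_span=span,
        ref_allele_identity=identity,
        length_ratio=ratio,
    )


def _allele_identity(nrs_seq, placement, reference, params) -> float | None:
    ref_allele = reference[placement.chrom][placement.left_breakend : placement.right_breakend]
    if not ref_allele:
        return None
    if len(nrs_seq) * len(ref_allele) <= params.dp_cap:
        blk = align_pair_dp(nrs_seq, ref_allele, params)
    else:  # large alleles: seeded engine instead of full DP
        blocks = align_to_genome(nrs_seq, {"allele": ref_allele}, params)
        blk = blocks[0] if blocks else None
    if blk is None or blk.score < params.min_score:
        return None
    return blk.identity


# ---------------------------------------------------------------------------
# gene intersection
# ---------------------------------------------------------------------------

@dataclass
class Gene:
    gene_id: str
    chrom: str
    start: int
    end: int
    cds: list[tuple[int, int]] = field(default_factory=list)


def intersect_genes(
    calls: list[NRSCall],
    genes: list[Gene],
) -> list[dict]:
    """One row per (call, overlapped gene) with level genic or CDS.

    Insertions (zero-length reference interval) are expanded by 1 bp on each
    side before testing overlap.
    """
    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    rows = []
    for call in calls:
        lo, hi = call.left_breakend, call.right_breakend
        if hi - lo == 0:
            lo, hi = lo - 1, hi + 1
        for g in by_chrom.get(call.chrom, []):
            if g.start < hi and g.end > lo:
                level = "CDS" if any(s < hi and e > lo for s, e in g.cds) else "genic"
                rows.append({"nrs_id": call.nrs_id, "gene_id": g.gene_id, "level": level})
    return rows
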