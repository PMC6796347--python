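"""Repeat-content profiling and transcription-potential evidence.

Tandem-repeat content inside novel sequence is measured with an internal
periodicity detector (no annotation track exists for sequence absent from
the reference); interspersed (TE) content inside an NRS comes from aligning
it against a TE consensus library, and TE content of the 5 kb reference
flanks from the reference repeat track.  Transcription potential combines
paired RNA-seq read support (>= 10 uniquely, properly paired mapped reads in
>= 2 samples) with EST database hits (identity >= 95 and e-value < 1e-5,
coverage deliberately ignored because ESTs are short end reads).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .align import (
    AlignParams,
    KarlinParams,
    KmerIndex,
    evalue,
    local_align,
    revcomp,
)
from .classify import NRSCall
from .errors import DegenerateInputError, InputError
from .extract import NRSRecord, RepeatTrack, SIMPLE_REPEAT_CLASSES, normalize_repeat_class
from .place import Placement

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# tandem-repeat detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TandemParams:
    max_period: int = 100
    min_copies: float = 3.0
    min_array: int = 24
    max_mismatch_frac: float = 0.10


def _min_window(period: int, tp: TandemParams) -> int:
    return max(tp.min_array, int(np.ceil(tp.min_copies * period)))


def tandem_covered_mask(seq: str, tp: TandemParams | None = None) -> np.ndarray:
    """Boolean per-base mask of positions inside a detected tandem array.

    A position is covered at period p when some window of length
    ``max(min_array, min_copies*p)`` containing it has at most 10% of its
    self-comparisons ``seq[i] != seq[i-p]`` mismatching.
    """
    tp = tp or TandemParams()
    mask = np.zeros(len(seq), dtype=bool)
    for m in per_period_masks(seq, tp).values():
        mask |= m
    return mask


def per_period_masks(seq: str, tp: TandemParams | None = None) -> dict[int, np.ndarray]:
    tp = tp or TandemParams()
    s = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    n = s.shape[0]
    out: dict[int, np.ndarray] = {}
    for p in range(1, min(tp.max_period, n - 1) + 1):
        w = _min_window(p, tp)
        if w > n or w <= p:
            continue
        neq = (s[p:] != s[:-p]).astype(np.int32)
        ncmp = w - p
        window_sums = np.convolve(neq, np.ones(ncmp, dtype=np.int32), mode="valid")
        ok = window_sums <= tp.max_mismatch_frac * ncmp
        if not ok.any():
            continue
        m = np.zeros(n, dtype=bool)
        idx = np.nonzero(ok)[0]
        # mark [start, start+w) for each ok window, vectorised via diff trick
        d = np.zeros(n + 1, dtype=np.int32)
        np.add.at(d, idx, 1)
        np.add.at(d, np.minimum(idx + w, n), -1)
        m = np.cumsum(d[:-1]) > 0
        out[p] = m
    return out


def detect_tandem(
    seq: str, max_period: int = 100, min_copies: float = 3.0, min_array: int = 24
) -> list[tuple[int, int, int, float]]:
    """Maximal tandem arrays as (start, end, period, copies).

    Overlapping calls at different periods are merged to the smallest-period
    call: each covered base is attributed to the smallest period covering it
    and maximal same-period runs are reported.  Deterministic.
    """
    tp = TandemParams(max_period=max_period, min_copies=min_copies, min_array=min_array)
    masks = per_period_masks(seq, tp)
    if not masks:
        return []
    n = len(seq)
    assign = np.zeros(n, dtype=np.int32)  # 0 = not covered
    for p in sorted(masks, reverse=True):  # smaller periods overwrite larger
        assign[masks[p]] = p
    calls = []
    i = 0
    while i < n:
        if assign[i] == 0:
            i += 1
            continue
        p = assign[i]
        j = i
        while j < n and assign[j] == p:
            j += 1
        calls.append((i, j, int(p), (j - i) / p))
        i = j
    return calls


def tandem_fraction(seq: str, tp: TandemParams | None = None) -> float:
    if not seq:
        return 0.0
    return float(tandem_covered_mask(seq, tp).mean())


# ---------------------------------------------------------------------------
# repeat profiles
# ---------------------------------------------------------------------------

@dataclass
class RepeatProfile:
    nrs_id: str
    te_fraction_internal: float
    tr_fraction_internal: float
    te_fraction_flank: float
    tr_fraction_flank: float
    ref_tr_fraction: float | None  # alternate calls only


def _te_coverage_fraction(
    seq: str, te_index: KmerIndex | None, params: AlignParams, min_identity: float = 80.0
) -> float:
    if te_index is None or te_index.total_length == 0 or not seq:
        return 0.0
    blocks = [
        b
        for b in local_align(seq, te_index, params, query_id="q")
        if b.identity >= min_identity
    ]
    if not blocks:
        return 0.0
    covered = np.zeros(len(seq), dtype=bool)
    for b in blocks:
        covered[b.query_start : b.query_end] = True
    return float(covered.mean())


def _track_coverage_fraction(
    chrom: str, intervals: list[tuple[int, int]], windows: list[tuple[int, int]]
) -> float:
    total = sum(e - s for s, e in windows)
    if total == 0:
        return 0.0
    covered = 0
    for ws, we in windows:
        for s, e in intervals:
            lo, hi = max(s, ws), min(e, we)
            if hi > lo:
                covered += hi - lo
    return covered / total


def repeat_profile(
    call: NRSCall,
    placement: Placement,
    nrs_seq: str,
    reference: dict[str, str],
    te_track_on_reference: RepeatTrack,
    te_index: KmerIndex | None = None,
    flank: int = 5000,
    params: AlignParams | None = None,
    tandem_params: TandemParams | None = None,
) -> RepeatProfile:
    """TE and tandem-repeat fractions inside the allele and its 5 kb flanks.

    Requires a precise placement.  ``te_index`` is a k-mer index over a TE
    consensus library; internal TE content is the base-union coverage of
    blocks at >= 80% identity.  Flank windows falling off the chromosome are
    clipped (and logged).
    """
    if placement.status != "precise":
        raise InputError(f"{call.nrs_id}: repeat_profile requires a precise placement")
    params = params or AlignParams()
    tp = tandem_params or TandemParams()
    chrom_seq = reference[placement.chrom]
    te_classes = {
        c for c in te_track_on_reference.classes() if c not in SIMPLE_REPEAT_CLASSES
    }
    te_intervals = te_track_on_reference.by_contig(te_classes).get(placement.chrom, [])
    tr_intervals = te_track_on_reference.by_contig(set(SIMPLE_REPEAT_CLASSES)).get(
        placement.chrom, []
    )

    lwin = (max(0, placement.left_breakend - flank), placement.left_breakend)
    rwin = (placement.right_breakend, min(len(chrom_seq), placement.right_breakend + flank))
    if lwin[1] - lwin[0] < flank or rwin[1] - rwin[0] < flank:
        logger.info("%s: flank window clipped at chromosome edge", call.nrs_id)
    windows = [w for w in (lwin, rwin) if w[1] > w[0]]

    flank_seq = "".join(chrom_seq[s:e] for s, e in windows)
    tr_flank_track = _track_coverage_fraction(placement.chrom, tr_intervals, windows)
    # flank TR content: detector on the actual flank sequence, unioned with
    # the annotated simple-repeat intervals
    tr_flank = max(tandem_fraction(flank_seq, tp), tr_flank_track)

    ref_tr = None
    if call.call == "alternate":
        allele = chrom_seq[placement.left_breakend : placement.right_breakend]
        ref_tr = tandem_fraction(allele, tp)

    return RepeatProfile(
        nrs_id=call.nrs_id,
        te_fraction_internal=_te_coverage_fraction(nrs_seq, te_index, params),
        tr_fraction_internal=tandem_fraction(nrs_seq, tp),
        te_fraction_flank=_track_coverage_fraction(placement.chrom, te_intervals, windows),
        tr_fraction_flank=tr_flank,
        ref_tr_fraction=ref_tr,
    )


def tr_association(profiles: list[RepeatProfile]) -> tuple[float, float, float]:
    """OLS of reference-allele tandem fraction on alternate-allele tandem
    fraction; returns (slope, intercept, r_squared)."""
    pts = [
        (p.tr_fraction_internal, p.ref_tr_fraction)
        for p in profiles
        if p.ref_tr_fraction is not None
    ]
    if len(pts) < 3:
        raise DegenerateInputError("need >= 3 alternate calls with reference TR fractions")
    x = np.array([a for a, _ in pts])
    y = np.array([b for _, b in pts])
    if np.allclose(x.var(), 0):
        raise DegenerateInputError("zero variance in alternate TR fractions")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


# ---------------------------------------------------------------------------
# transcription support
# ---------------------------------------------------------------------------

@dataclass
class TranscriptionEvidence:
    nrs_id: str
    rna_supported: bool
    supporting_samples: int
    read_counts: dict[str, int] = field(default_factory=dict)
    cpm: dict[str, float] = field(default_factory=dict)
    est_supported: bool = False

    @property
    def transcribed(self) -> bool:
        return self.rna_supported or self.est_supported


@dataclass(frozen=True)
class ReadMapParams:
    min_mq_margin: int = 10     # best minus second-best score for MQ proxy >= 30
    insert_min: int = 50
    insert_max: int = 1000
    min_read_len: int = 80      # quality pass-through filter
    max_lowq_frac: float = 0.50
    min_base_q: int = 20
    count_mates: bool = True    # a proper pair contributes 2 mapped reads


def quality_filter(
    pairs: list[tuple[str, str]] | list[tuple[str, str, str, str]],
    rp: ReadMapParams | None = None,
) -> list[tuple[str, str]]:
    """Drop read pairs that are too short or mostly low quality.

    Pairs are (seq1, seq2) or (seq1, qual1, seq2, qual2) with phred+33
    quality strings; sequence-only pairs are length-filtered only.
    """
    rp = rp or ReadMapParams()
    kept = []
    for pair in pairs:
        if len(pair) == 4:
            s1, q1, s2, q2 = pair
            quals = (q1, q2)
        else:
            s1, s2 = pair
            quals = None
        if len(s1) < rp.min_read_len or len(s2) < rp.min_read_len:
            continue
        if quals is not None:
            bad = False
            for q in quals:
                lowq = sum(1 for ch in q if ord(ch) - 33 < rp.min_base_q)
                if lowq > rp.max_lowq_frac * len(q):
                    bad = True
            if bad:
                continue
        kept.append((s1, s2))
    return kept


def _gapless_candidates(seq: str, index: KmerIndex, params: AlignParams):
    """Seed-vote gapless placements of a short read: (score, target, start,
    end, strand) per candidate diagonal, best first."""
    from nrscout.align import _kmer_codes, encode_bases

    out = []
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        codes, valid = _kmer_codes(encode_bases(s), index.k)
        qpos, sid, tpos = index.lookup(codes, valid)
        if qpos.size == 0:
            continue
        diag = tpos - qpos
        key = sid.astype(np.int64) * (1 << 40) + (diag + (1 << 35))
        uniq, counts = np.unique(key, return_counts=True)
        order = np.argsort(counts)[::-1][:8]
        sb = np.frombuffer(s.encode(), dtype=np.uint8)
        for ki in order:
            k = int(uniq[ki])
            s_id = k >> 40
            d = (k & ((1 << 40) - 1)) - (1 << 35)
            tseq = index.seqs[index.names[int(s_id)]]
            t0 = int(d)
            lo = max(0, -t0)
            hi = min(len(s), len(tseq) - t0)
            if hi - lo < index.k:
                continue
            tb = np.frombuffer(tseq[t0 + lo : t0 + hi].encode(), dtype=np.uint8)
            eq = sb[lo:hi] == tb
            score = float(eq.sum() * params.match + (~eq).sum() * params.mismatch)
            out.append(
                (score, index.names[int(s_id)], t0 + lo, t0 + hi, strand)
            )
    out.sort(key=lambda x: (-x[0], x[1], x[2], x[4]))
    return out


def _map_read(seq: str, index: KmerIndex, params: AlignParams, rp: ReadMapParams):
    """Best unique placement of one read: (target, start, end, strand) or None."""
    cands = _gapless_candidates(seq, index, params)
    if not cands or cands[0][0] < params.min_score:
        # fall back to the full engine (clipped or gapped placements)
        blocks = local_align(seq, index, params, query_id="read")
        if not blocks:
            return None
        best = blocks[0]
        if len(blocks) > 1 and best.score - blocks[1].score < rp.min_mq_margin:
            return None
        return best.target_id, best.target_start, best.target_end, best.strand
    best = cands[0]
    second = next((c for c in cands[1:] if (c[1], c[2]) != (best[1], best[2])), None)
    if second is not None and best[0] - second[0] < rp.min_mq_margin:
        return None  # multi-mapping: fails the mapping-quality proxy
    return best[1], best[2], best[3], best[4]


def count_read_support(
    pairs: list[tuple[str, str]],
    index: KmerIndex,
    nrs_names: set[str],
    params: AlignParams,
    rp: ReadMapParams,
) -> tuple[dict[str, int], int]:
    """Per-NRS mapped-read counts and the sample's total mapped reads.

    A pair counts for an NRS iff both mates map uniquely to it in FR
    orientation within the insert bounds.  Totals include proper pairs on
    any target (reference included) for CPM normalisation.
    """
    counts: dict[str, int] = {}
    total = 0
    unit = 2 if rp.count_mates else 1
    for r1, r2 in pairs:
        m1 = _map_read(r1, index, params, rp)
        m2 = _map_read(r2, index, params, rp)
        if m1 is None or m2 is None or m1[0] != m2[0]:
            continue
        if {m1[3], m2[3]} != {"+", "-"}:
            continue
        fwd, rev = (m1, m2) if m1[3] == "+" else (m2, m1)
        insert = rev[2] - fwd[1]
        if not (fwd[1] <= rev[1] and rp.insert_min <= insert <= rp.insert_max):
            continue
        total += unit
        if m1[0] in nrs_names:
            counts[m1[0]] = counts.get(m1[0], 0) + unit
    return counts, total


def transcription_support(
    nrs: list[NRSRecord],
    read_sets: dict[str, list[tuple[str, str]]],
    est_db: dict[str, str],
    reference: dict[str, str] | None = None,
    min_reads: int = 10,
    min_samples: int = 2,
    est_min_identity: float = 95.0,
    est_max_evalue: float = 1e-5,
    params: AlignParams | None = None,
    read_params: ReadMapParams | None = None,
    karlin: KarlinParams | None = None,
) -> dict[str, TranscriptionEvidence]:
    """RNA-seq and EST evidence of transcription for each NRS.

    Reads are mapped to the extended target (reference plus the call set);
    an NRS is RNA-supported when >= ``min_reads`` mapped reads are found in
    >= ``min_samples`` samples.  EST support requires a hit with identity >=
    95% and e-value < 1e-5 regardless of query coverage.
    """
    params = params or AlignParams()
    rp = read_params or ReadMapParams()
    kp = karlin or KarlinParams()
    extended: dict[str, str] = dict(reference or {})
    nrs_names = set()
    for rec in nrs:
        extended[rec.nrs_id] = rec.sequence
        nrs_names.add(rec.nrs_id)

    per_sample_counts: dict[str, dict[str, int]] = {}
    per_sample_total: dict[str, int] = {}
    if read_sets:
        index = KmerIndex(extended, k=params.k, max_occ=params.max_occ)
        for sample, pairs in sorted(read_sets.items()):
            clean = quality_filter(pairs, rp)
            counts, total = count_read_support(clean, index, nrs_names, params, rp)
            per_sample_counts[sample] = counts
            per_sample_total[sample] = total

    est_index = (
        KmerIndex(est_db, k=params.k, max_occ=params.max_occ) if est_db else None
    )
    est_total_len = sum(len(s) for s in est_db.values()) if est_db else 0

    out: dict[str, TranscriptionEvidence] = {}
    for rec in nrs:
        counts = {
            sample: per_sample_counts.get(sample, {}).get(rec.nrs_id, 0)
            for sample in read_sets
        }
        cpm = {
            sample: (
                counts[sample] * 1e6 / per_sample_total[sample]
                if per_sample_total.get(sample)
                else 0.0
            )
            for sample in read_sets
        }
        supporting = sum(1 for c in counts.values() if c >= min_reads)
        est_hit = False
        if est_index is not None:
            for b in local_align(rec.sequence, est_index, params, query_id=rec.nrs_id):
                if b.identity >= est_min_identity and evalue(
                    b.score, len(rec.sequence), est_total_len, kp
                ) < est_max_evalue:
                    est_hit = True
                    break
        out[rec.nrs_id] = TranscriptionEvidence(
            nrs_id=rec.nrs_id,
            rna_supported=supporting >= min_samples,
            supporting_samples=supporting,
            read_counts=counts,
            cpm=cpm,
            est_supported=est_hit,
        )
    return out
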