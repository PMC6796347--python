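"""Local alignment engine and exact-DP oracle.

Every other stage of the pipeline consumes alignments through the
:class:`AlignmentBlock` contract produced here.  Two routes produce blocks:

* :func:`local_align` — a k-mer seed → chain → stitch engine over a
  :class:`KmerIndex`, the package's stand-in for a fast genome-scale local
  aligner.  Chained blocks whose overall identity is high are additionally
  segmented at sustained low-identity runs so that a divergent allele
  embedded between near-identical flanks surfaces as its own low-identity
  block (the behaviour genome aligners show when an HSP is broken at a
  divergent stretch).
* :func:`align_pair_dp` — exact affine-gap Smith–Waterman between two
  sequences (Bio.Align's C implementation), used as the oracle in tests and
  for allele-versus-allele identity.

Coordinates are 0-based half-open throughout.  Reverse-strand blocks report
query coordinates on the forward query with ``strand='-'``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from Bio import Align

from .errors import AlignmentSizeError, InputError

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: DNA alphabet accepted by the engine (ambiguity codes other than N are not).
VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N sequence."""
    return seq.translate(_COMP)[::-1]


def _check_dna(seq: str, what: str = "sequence") -> str:
    s = seq.upper()
    if set(s) - VALID_BASES:
        bad = sorted(set(s) - VALID_BASES)
        raise InputError(f"{what} contains non-DNA characters: {bad}")
    return s


@dataclass(frozen=True)
class AlignParams:
    """Scoring and heuristics for the seed–chain–stitch engine.

    Defaults are megablast-like: short word, +1/-2 substitution scores,
    affine gaps, modest x-drop.
    """

    k: int = 15
    min_seed_chain: int = 1
    match: int = 1
    mismatch: int = -2
    gap_open: int = -4
    gap_extend: int = -1
    x_drop: int = 30
    min_score: int = 40
    # engine heuristics
    max_occ: int = 256         # seeds occurring more often are not indexed
    max_join: int = 500        # max unanchored bp bridged inside one chain
    band: int = 50             # diagonal drift allowed when chaining
    ext_window: int = 200      # bp examined when extending chain ends
    # homogeneity segmentation of high-identity chains
    split_identity: float | None = 90.0
    split_window: int = 100
    split_min_run: int = 250
    split_max_identity: float = 87.0
    tail_max_identity: float = 80.0  # end-trim clearly divergent block tails
    dp_cap: int = 25_000_000
    dp_fallback: bool = True   # exact DP rescue for small query x target

    def __post_init__(self) -> None:
        if self.k < 8:
            raise InputError("seed length k must be >= 8")
        if self.match <= 0 or self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise InputError("require match > 0 and mismatch/gap penalties < 0")


@dataclass(frozen=True)
class KarlinParams:
    """Karlin–Altschul parameters of the e-value model.

    Defaults are the standard ungapped values for +1/-2 scoring.
    """

    lambda_: float = 1.28
    K: float = 0.46

    def __post_init__(self) -> None:
        if self.lambda_ <= 0 or self.K <= 0:
            raise InputError("Karlin parameters must be positive")


@dataclass
class AlignmentBlock:
    """One local alignment between a query and a target interval."""

    query_id: str
    query_start: int
    query_end: int
    target_id: str
    target_start: int
    target_end: int
    strand: str
    matches: int
    aln_columns: int
    gap_opens: int
    score: float
    # per-column bookkeeping used by block segmentation; not part of the
    # public contract and dropped when blocks are serialised.
    _colmatch: np.ndarray | None = field(default=None, repr=False, compare=False)
    _colstate: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def identity(self) -> float:
        """Percent identity, 100 * matches / alignment columns."""
        if self.aln_columns == 0:
            return 0.0
        return 100.0 * self.matches / self.aln_columns

    def query_interval(self) -> tuple[int, int]:
        return (self.query_start, self.query_end)

    def validate(self) -> None:
        if not (self.query_start < self.query_end and self.target_start < self.target_end):
            raise InputError("degenerate block interval")
        if not 0.0 <= self.identity <= 100.0:
            raise InputError("identity outside [0, 100]")


# ---------------------------------------------------------------------------
# k-mer index
# ---------------------------------------------------------------------------

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase


def encode_bases(seq: str) -> np.ndarray:
    """Sequence to uint8 codes (A,C,G,T -> 0..3; anything else 255)."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(bases: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All k-mer integer codes and a validity mask (no ambiguous base)."""
    n = bases.shape[0] - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    codes = np.zeros(n, dtype=np.int64)
    b = np.where(bases < 4, bases, 0).astype(np.int64)
    for j in range(k):
        codes += b[j : j + n] << (2 * (k - 1 - j))
    bad = (bases >= 4).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(bad)])
    valid = (cs[k:] - cs[:-k]) == 0
    return codes, valid


class KmerIndex:
    """Sorted k-mer position index over one or more uppercase DNA sequences.

    Seeds containing N never enter the index; k-mers occurring more than
    ``max_occ`` times are dropped (repeat masking at the seed level).
    """

    def __init__(self, sequences: dict[str, str], k: int = 15, max_occ: int = 256):
        self.k = k
        self.names: list[str] = []
        self.seqs: dict[str, str] = {}
        codes_all, pos_all, sid_all = [], [], []
        for sid, (name, seq) in enumerate(sorted(sequences.items())):
            s = _check_dna(seq, f"index sequence {name!r}")
            self.names.append(name)
            self.seqs[name] = s
            bases = encode_bases(s)
            codes, valid = _kmer_codes(bases, k)
            idx = np.nonzero(valid)[0]
            codes_all.append(codes[idx])
            pos_all.append(idx.astype(np.int64))
            sid_all.append(np.full(idx.shape[0], sid, dtype=np.int32))
        if codes_all:
            codes = np.concatenate(codes_all)
            pos = np.concatenate(pos_all)
            sid = np.concatenate(sid_all)
        else:
            codes = np.empty(0, dtype=np.int64)
            pos = np.empty(0, dtype=np.int64)
            sid = np.empty(0, dtype=np.int32)
        order = np.argsort(codes, kind="stable")
        codes, pos, sid = codes[order], pos[order], sid[order]
        if codes.size and max_occ is not None:
            uniq, starts, counts = np.unique(codes, return_index=True, return_counts=True)
            keep_mask = np.ones(codes.shape[0], dtype=bool)
            for s0, c in zip(starts[counts > max_occ], counts[counts > max_occ]):
                keep_mask[s0 : s0 + c] = False
            codes, pos, sid = codes[keep_mask], pos[keep_mask], sid[keep_mask]
        self._codes, self._pos, self._sid = codes, pos, sid

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.seqs.values())

    def lookup(self, query_codes: np.ndarray, query_valid: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All seed hits: (query_pos, target_seq_id, target_pos) arrays."""
        if self._codes.size == 0 or query_codes.size == 0:
            e = np.empty(0, dtype=np.int64)
            return e, e.astype(np.int32), e
        qidx = np.nonzero(query_valid)[0]
        qc = query_codes[qidx]
        left = np.searchsorted(self._codes, qc, side="left")
        right = np.searchsorted(self._codes, qc, side="right")
        counts = right - left
        total = int(counts.sum())
        if total == 0:
            e = np.empty(0, dtype=np.int64)
            return e, e.astype(np.int32), e
        qpos = np.repeat(qidx, counts)
        base = np.repeat(left, counts)
        prior = np.repeat(np.cumsum(counts) - counts, counts)
        slot = base + (np.arange(total) - prior)
        return qpos.astype(np.int64), self._sid[slot], self._pos[slot]


# ---------------------------------------------------------------------------
# exact DP via Bio.Align
# ---------------------------------------------------------------------------

_ALIGNER_CACHE: dict[tuple, Align.PairwiseAligner] = {}


def _make_aligner(params: AlignParams, mode: str, free_right: bool = False) -> Align.PairwiseAligner:
    key = (params.match, params.mismatch, params.gap_open, params.gap_extend, mode, free_right)
    al = _ALIGNER_CACHE.get(key)
    if al is None:
        al = Align.PairwiseAligner()
        al.mode = mode
        al.match_score = params.match
        al.mismatch_score = params.mismatch
        al.open_gap_score = params.gap_open
        al.extend_gap_score = params.gap_extend
        if free_right:
            al.open_right_insertion_score = 0.0
            al.extend_right_insertion_score = 0.0
            al.open_right_deletion_score = 0.0
            al.extend_right_deletion_score = 0.0
        _ALIGNER_CACHE[key] = al
    return al


def _columns_from_alignment(aln, a: str, b: str) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-column (match?, gap?) arrays and gap-open count for an alignment.

    ``aln`` target = first sequence passed to the aligner.  Leading/trailing
    unaligned tails (free end gaps of global modes) are excluded.
    """
    tsegs, qsegs = aln.aligned
    colmatch: list[np.ndarray] = []
    colstate: list[np.ndarray] = []
    gap_opens = 0
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(tsegs, qsegs):
        if prev_t is not None:
            gt, gq = ts - prev_t, qs - prev_q
            if gt > 0:
                colmatch.append(np.zeros(gt, dtype=bool))
                colstate.append(np.ones(gt, dtype=np.uint8))
                gap_opens += 1
            if gq > 0:
                colmatch.append(np.zeros(gq, dtype=bool))
                colstate.append(np.full(gq, 2, dtype=np.uint8))
                gap_opens += 1
        seg_t = np.frombuffer(a[ts:te].encode(), dtype=np.uint8)
        seg_q = np.frombuffer(b[qs:qe].encode(), dtype=np.uint8)
        colmatch.append(seg_t == seg_q)
        colstate.append(np.zeros(te - ts, dtype=np.uint8))
        prev_t, prev_q = te, qe
    if not colmatch:
        return np.empty(0, dtype=bool), np.empty(0, dtype=np.uint8), 0
    return np.concatenate(colmatch), np.concatenate(colstate), gap_opens


def _score_columns(colmatch: np.ndarray, colstate: np.ndarray, params: AlignParams) -> float:
    aligned = colstate == 0
    m = int(colmatch[aligned].sum())
    mm = int(aligned.sum()) - m
    score = m * params.match + mm * params.mismatch
    gaps = colstate != 0
    if gaps.any():
        d = np.diff(np.concatenate([[0], gaps.view(np.int8), [0]]))
        starts = np.nonzero(d == 1)[0]
        ends = np.nonzero(d == -1)[0]
        for s, e in zip(starts, ends):
            score += params.gap_open + (e - s - 1) * params.gap_extend
    return float(score)


def align_pair_dp(
    a: str,
    b: str,
    params: AlignParams | None = None,
    query_id: str = "query",
    target_id: str = "target",
) -> AlignmentBlock | None:
    """Optimal local (Smith–Waterman, affine gaps) alignment of ``a`` vs ``b``.

    ``a`` is the query, ``b`` the target.  Among co-optimal alignments the
    one with fewest gap opens, then smallest target start, is returned.
    Returns None when no alignment has positive score.

    Raises
    ------
    AlignmentSizeError
        if len(a) * len(b) exceeds ``params.dp_cap``.
    """
    params = params or AlignParams()
    a = _check_dna(a, "query")
    b = _check_dna(b, "target")
    if len(a) == 0 or len(b) == 0:
        return None
    if len(a) * len(b) > params.dp_cap:
        raise AlignmentSizeError(
            f"DP matrix {len(a)}x{len(b)} exceeds cap {params.dp_cap}; "
            "use the seeded engine or a banded fallback"
        )
    aligner = _make_aligner(params, "local")
    alns = aligner.align(b, a)  # target first
    if alns.score <= 0:
        return None
    best = None
    best_key = None
    for i, aln in enumerate(alns):
        if i >= 32:
            break
        colmatch, colstate, gap_opens = _columns_from_alignment(aln, b, a)
        tsegs, qsegs = aln.aligned
        key = (gap_opens, int(tsegs[0][0]))
        if best_key is None or key < best_key:
            best_key = key
            best = (aln, colmatch, colstate, gap_opens)
    aln, colmatch, colstate, gap_opens = best
    tsegs, qsegs = aln.aligned
    return AlignmentBlock(
        query_id=query_id,
        query_start=int(qsegs[0][0]),
        query_end=int(qsegs[-1][1]),
        target_id=target_id,
        target_start=int(tsegs[0][0]),
        target_end=int(tsegs[-1][1]),
        strand="+",
        matches=int(colmatch.sum()),
        aln_columns=int(colmatch.shape[0]),
        gap_opens=gap_opens,
        score=float(alns.score),
        _colmatch=colmatch,
        _colstate=colstate,
    )


# ---------------------------------------------------------------------------
# seed -> chain -> stitch
# ---------------------------------------------------------------------------

def _anchors_from_hits(qpos: np.ndarray, tpos: np.ndarray, k: int):
    """Merge seed hits on one target into maximal exact diagonal runs.

    Returns arrays (q_start, t_start, length, n_seeds), sorted by q_start.
    """
    if qpos.size == 0:
        z = np.empty(0, dtype=np.int64)
        return z, z, z, z
    diag = tpos - qpos
    order = np.lexsort((qpos, diag))
    q, t, d = qpos[order], tpos[order], diag[order]
    brk = np.nonzero((np.diff(d) != 0) | (np.diff(q) != 1))[0] + 1
    starts = np.concatenate([[0], brk])
    ends = np.concatenate([brk, [q.shape[0]]])
    qs = q[starts]
    ts = t[starts]
    ln = q[ends - 1] - qs + k
    ns = ends - starts
    o2 = np.lexsort((ts, qs))
    return qs[o2], ts[o2], ln[o2], ns[o2]


class _Chain:
    __slots__ = ("anchors", "qend", "tend", "nseeds")

    def __init__(self, anchor):
        self.anchors = [anchor]
        self.qend = anchor[0] + anchor[2]
        self.tend = anchor[1] + anchor[2]
        self.nseeds = anchor[3]

    def try_extend(self, anchor, params: AlignParams) -> bool:
        qs, ts, ln, ns = anchor
        qgap = qs - self.qend
        tgap = ts - self.tend
        if qgap > params.max_join or tgap > params.max_join:
            return False
        if qgap < -params.k or tgap < -params.k:
            return False
        indel_cap = max(1, (params.x_drop + params.gap_open) // -params.gap_extend + 1) \
            if params.gap_extend else params.band
        if abs(qgap - tgap) > min(params.band, indel_cap):
            return False
        self.anchors.append(anchor)
        self.qend = qs + ln
        self.tend = ts + ln
        self.nseeds += ns
        return True


def _chain_anchors(qs, ts, ln, ns, params: AlignParams) -> list[list[tuple]]:
    chains: list[_Chain] = []
    active: list[_Chain] = []
    for i in range(qs.shape[0]):
        anchor = (int(qs[i]), int(ts[i]), int(ln[i]), int(ns[i]))
        active = [c for c in active if anchor[0] - c.qend <= params.max_join]
        placed = False
        # prefer the chain whose end is nearest on the same diagonal
        best, best_d = None, None
        for c in active:
            dd = abs((anchor[1] - anchor[0]) - (c.tend - c.qend))
            if best_d is None or dd < best_d:
                best, best_d = c, dd
        if best is not None and best.try_extend(anchor, params):
            placed = True
        else:
            for c in active:
                if c is not best and c.try_extend(anchor, params):
                    placed = True
                    break
        if not placed:
            c = _Chain(anchor)
            chains.append(c)
            active.append(c)
    return [c.anchors for c in chains if c.nseeds >= 1]


def _stitch_chain(anchors, query: str, target: str, params: AlignParams):
    """Turn an anchor chain into per-column match/state arrays + coordinates."""
    colmatch: list[np.ndarray] = []
    colstate: list[np.ndarray] = []
    aligner = _make_aligner(params, "global")
    q0, t0 = anchors[0][0], anchors[0][1]
    qend = tend = None
    for ai, (aqs, ats, aln_len, _ns) in enumerate(anchors):
        if ai > 0:
            # trim overlap with what is already consumed
            delta = max(qend - aqs, tend - ats, 0)
            aqs += delta
            ats += delta
            aln_len -= delta
            if aln_len <= 0:
                continue
            qg, tg = aqs - qend, ats - tend
            if qg < 0 or tg < 0:
                continue
            if qg == 0 and tg > 0:
                colmatch.append(np.zeros(tg, dtype=bool))
                colstate.append(np.ones(tg, dtype=np.uint8))
            elif tg == 0 and qg > 0:
                colmatch.append(np.zeros(qg, dtype=bool))
                colstate.append(np.full(qg, 2, dtype=np.uint8))
            elif qg > 0 and tg > 0:
                sq = query[qend:aqs]
                st = target[tend:ats]
                if qg == tg and qg <= 30:
                    eq = np.frombuffer(sq.encode(), dtype=np.uint8) == np.frombuffer(
                        st.encode(), dtype=np.uint8
                    )
                    colmatch.append(eq)
                    colstate.append(np.zeros(qg, dtype=np.uint8))
                else:
                    sub = aligner.align(st, sq)[0]
                    cm, cs, _go = _columns_from_alignment(sub, st, sq)
                    # global alignment: include any end gaps of the sub-region
                    lead_t = sub.aligned[0][0][0]
                    lead_q = sub.aligned[1][0][0]
                    tail_t = tg - sub.aligned[0][-1][1]
                    tail_q = qg - sub.aligned[1][-1][1]
                    for gl, code in ((lead_t, 1), (lead_q, 2)):
                        if gl > 0:
                            colmatch.append(np.zeros(gl, dtype=bool))
                            colstate.append(np.full(gl, code, dtype=np.uint8))
                    colmatch.append(cm)
                    colstate.append(cs)
                    for gl, code in ((tail_t, 1), (tail_q, 2)):
                        if gl > 0:
                            colmatch.append(np.zeros(gl, dtype=bool))
                            colstate.append(np.full(gl, code, dtype=np.uint8))
        colmatch.append(np.ones(aln_len, dtype=bool))
        colstate.append(np.zeros(aln_len, dtype=np.uint8))
        qend = aqs + aln_len
        tend = ats + aln_len
    # end extensions
    lq, lt, lm, ls = _extend_end(query, target, q0, t0, -1, params)
    rq, rt, rm, rs = _extend_end(query, target, qend, tend, +1, params)
    if lm.size:
        colmatch.insert(0, lm)
        colstate.insert(0, ls)
        q0 -= lq
        t0 -= lt
    if rm.size:
        colmatch.append(rm)
        colstate.append(rs)
        qend += rq
        tend += rt
    cm = np.concatenate(colmatch) if colmatch else np.empty(0, dtype=bool)
    cs = np.concatenate(colstate) if colstate else np.empty(0, dtype=np.uint8)
    return cm, cs, q0, qend, t0, tend


def _extend_end(query, target, qpos, tpos, direction, params: AlignParams):
    """Best-scoring anchored extension beyond a chain end, iterating window
    by window while the whole window keeps scoring.

    Returns (q_advance, t_advance, colmatch, colstate) in block orientation.
    """
    q_adv = t_adv = 0
    cms: list[np.ndarray] = []
    css: list[np.ndarray] = []
    for _ in range(64):
        dq, dt, cm, cs = _extend_end_once(
            query, target, qpos + direction * q_adv, tpos + direction * t_adv,
            direction, params,
        )
        if cm.size == 0:
            break
        if direction > 0:
            cms.append(cm)
            css.append(cs)
        else:
            cms.insert(0, cm)
            css.insert(0, cs)
        q_adv += dq
        t_adv += dt
        # stop unless the extension consumed (almost) the whole window
        if max(dq, dt) < params.ext_window - 5:
            break
    if not cms:
        return 0, 0, np.empty(0, dtype=bool), np.empty(0, dtype=np.uint8)
    return q_adv, t_adv, np.concatenate(cms), np.concatenate(css)


def _extend_end_once(query, target, qpos, tpos, direction, params: AlignParams):
    w = params.ext_window
    if direction > 0:
        sq, st = query[qpos : qpos + w], target[tpos : tpos + w]
    else:
        sq, st = query[max(0, qpos - w) : qpos][::-1], target[max(0, tpos - w) : tpos][::-1]
    if not sq or not st:
        return 0, 0, np.empty(0, dtype=bool), np.empty(0, dtype=np.uint8)
    # gapless fast path: in-register comparison; gapped DP only when a
    # register-shift probe past the gapless stop hints at an indel
    m = min(len(sq), len(st))
    eq = np.frombuffer(sq[:m].encode(), dtype=np.uint8) == np.frombuffer(
        st[:m].encode(), dtype=np.uint8
    )
    run = np.cumsum(np.where(eq, params.match, params.mismatch))
    gbest = int(np.argmax(run))
    adv = gbest + 1 if run[gbest] > 0 else 0
    # a divergent tail can eke out a marginal score gain (e.g. the shared
    # motif backbone at a tandem-array junction); give it back when the
    # tail is clearly low-identity and the sacrifice is small
    if adv >= 6:
        llr = np.cumsum(np.where(eq[:adv], 0.5, -3.7))
        cut = int(np.argmax(llr)) + 1 if llr.max() > 0 else 0
        if cut < adv:
            tail = eq[cut:adv]
            loss = run[adv - 1] - (run[cut - 1] if cut else 0.0)
            if tail.mean() < 0.75 and loss <= 10:
                adv = cut
    need_dp = False
    if adv < m - 2:
        qb = np.frombuffer(sq.encode(), dtype=np.uint8)
        tb = np.frombuffer(st.encode(), dtype=np.uint8)
        for shift in (1, 2, 3):
            a = qb[adv + shift : adv + shift + 30]
            b = tb[adv : adv + 30]
            n = min(a.shape[0], b.shape[0])
            if n >= 15 and (a[:n] == b[:n]).mean() >= 0.7:
                need_dp = True
                break
            a = qb[adv : adv + 30]
            b = tb[adv + shift : adv + shift + 30]
            n = min(a.shape[0], b.shape[0])
            if n >= 15 and (a[:n] == b[:n]).mean() >= 0.7:
                need_dp = True
                break
    if not need_dp:
        if adv == 0:
            return 0, 0, np.empty(0, dtype=bool), np.empty(0, dtype=np.uint8)
        cm = eq[:adv]
        cs = np.zeros(adv, dtype=np.uint8)
        if direction < 0:
            cm, cs = cm[::-1], cs[::-1]
        return adv, adv, cm, cs
    al = _make_aligner(params, "global", free_right=True)
    aln = al.align(st, sq)[0]
    cm, cs, _go = _columns_from_alignment(aln, st, sq)
    if cm.size == 0:
        return 0, 0, cm, cs
    aligned = cs == 0
    per_col = np.where(
        aligned & cm, params.match, np.where(aligned, params.mismatch, params.gap_extend)
    ).astype(float)
    # charge gap opens at the start of each gap run
    gaps = cs != 0
    d = np.diff(np.concatenate([[0], gaps.view(np.int8)]))
    per_col[d == 1] += params.gap_open - params.gap_extend
    run = np.cumsum(per_col)
    best = int(np.argmax(run))
    if run[best] <= 0:
        return 0, 0, np.empty(0, dtype=bool), np.empty(0, dtype=np.uint8)
    cm, cs = cm[: best + 1], cs[: best + 1]
    q_adv = int((cs != 1).sum())  # columns consuming query
    t_adv = int((cs != 2).sum())
    if direction < 0:
        cm, cs = cm[::-1], cs[::-1]
    return q_adv, t_adv, cm, cs


def _sub_block(
    block: AlignmentBlock, c0: int, c1: int, params: AlignParams
) -> AlignmentBlock | None:
    """Slice a block to column range [c0, c1), shrunk to match columns."""
    cm, cs = block._colmatch, block._colstate
    seg = np.nonzero(cm[c0:c1])[0]
    if seg.size == 0:
        return None
    c0n, c1n = c0 + int(seg[0]), c0 + int(seg[-1]) + 1
    q_adv = np.cumsum(cs != 1)  # query bases consumed up to column (inclusive)
    t_adv = np.cumsum(cs != 2)
    q0 = block.query_start + (int(q_adv[c0n - 1]) if c0n else 0)
    q1 = block.query_start + int(q_adv[c1n - 1])
    t0 = block.target_start + (int(t_adv[c0n - 1]) if c0n else 0)
    t1 = block.target_start + int(t_adv[c1n - 1])
    sub_cm, sub_cs = cm[c0n:c1n], cs[c0n:c1n]
    gaps = sub_cs != 0
    go = int((np.diff(np.concatenate([[0], gaps.view(np.int8)])) == 1).sum())
    return AlignmentBlock(
        query_id=block.query_id,
        query_start=q0,
        query_end=q1,
        target_id=block.target_id,
        target_start=t0,
        target_end=t1,
        strand=block.strand,
        matches=int(sub_cm.sum()),
        aln_columns=int(sub_cm.shape[0]),
        gap_opens=go,
        score=_score_columns(sub_cm, sub_cs, params),
        _colmatch=sub_cm,
        _colstate=sub_cs,
    )


def _low_runs(cm: np.ndarray, w: int, threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Maximal runs where the w-smoothed match fraction is below threshold."""
    kern = np.ones(w) / w
    sm = np.convolve(cm.astype(float), kern, mode="same")
    low = sm < threshold
    d = np.diff(np.concatenate([[0], low.view(np.int8), [0]]))
    return np.nonzero(d == 1)[0], np.nonzero(d == -1)[0]


def _refine_boundary(
    cm: np.ndarray, pos: int, w: int, run_mean: float, keep_left: bool
) -> int:
    """Locate the exact high/low identity junction near ``pos``.

    Columns are scored by the log-likelihood ratio of the high regime versus
    the observed low regime (``run_mean``); the cumulative sum peaks (high on
    the left) or bottoms out (high on the right) at the junction.
    """
    p_high = 0.995
    p_low = min(max(run_mean, 0.05), 0.85)
    wm = float(np.log(p_high / p_low))
    wx = float(np.log((1 - p_high) / (1 - p_low)))
    # a locally milder stretch of the low regime can delay (or hasten) the
    # smoothed run boundary; search further on the side it smears toward
    if keep_left:
        lo, hi = max(0, pos - 3 * w), min(cm.shape[0], pos + w)
    else:
        lo, hi = max(0, pos - w), min(cm.shape[0], pos + 3 * w)
    g = np.where(cm[lo:hi], wm, wx)
    c = np.concatenate([[0.0], np.cumsum(g)])
    return lo + int(np.argmax(c) if keep_left else np.argmin(c))


def _trim_block_ends(block: AlignmentBlock, params: AlignParams) -> AlignmentBlock | None:
    """Trim clearly divergent leading/trailing stretches off a high-identity
    block (a chain end dragged into foreign sequence by a chance seed)."""
    if params.split_identity is None or block.identity < params.split_identity:
        return block
    cm = block._colmatch
    w = params.split_window
    if cm is None or cm.shape[0] < 2 * w:
        return block
    starts, ends = _low_runs(cm, w, params.split_identity / 100.0)
    n = cm.shape[0]
    c0, c1 = 0, n
    for s, e in zip(starts, ends):
        mean = float(cm[s:e].mean())
        if s == 0 and e < n and mean * 100.0 < params.tail_max_identity:
            c0 = _refine_boundary(cm, int(e), w, mean, keep_left=False)
        if e == n and s > 0 and mean * 100.0 < params.tail_max_identity:
            c1 = _refine_boundary(cm, int(s), w, mean, keep_left=True)
    if c0 == 0 and c1 == n:
        return block
    if c1 - c0 < 30:
        return None
    return _sub_block(block, c0, c1, params)


def _split_block(block: AlignmentBlock, params: AlignParams) -> list[AlignmentBlock]:
    """Segment a high-identity block at sustained low-identity runs."""
    if params.split_identity is None or block.identity < params.split_identity:
        return [block]
    cm = block._colmatch
    if cm is None or cm.shape[0] < 2 * params.split_min_run:
        return [block]
    w = params.split_window
    starts, ends = _low_runs(cm, w, params.split_identity / 100.0)
    cuts = []
    for s, e in zip(starts, ends):
        mean = float(cm[s:e].mean())
        if e - s >= params.split_min_run and mean * 100.0 < params.split_max_identity:
            s_ref = _refine_boundary(cm, int(s), w, mean, keep_left=True)
            e_ref = _refine_boundary(cm, int(e), w, mean, keep_left=False)
            if e_ref > s_ref:
                cuts.append((s_ref, e_ref))
    if not cuts:
        return [block]
    cuts.sort()
    merged_cuts = [cuts[0]]
    for s, e in cuts[1:]:
        if s < merged_cuts[-1][1]:
            merged_cuts[-1] = (merged_cuts[-1][0], max(merged_cuts[-1][1], e))
        else:
            merged_cuts.append((s, e))
    bounds = [0]
    for s, e in merged_cuts:
        bounds.extend([s, e])
    bounds.append(cm.shape[0])
    pieces = []
    for i in range(len(bounds) - 1):
        c0, c1 = bounds[i], bounds[i + 1]
        if c1 - c0 < 50:
            continue
        piece = _sub_block(block, c0, c1, params)
        if piece is not None:
            pieces.append(piece)
    return pieces or [block]


def _quick_extend_score(anchors, query: str, target: str, params: AlignParams) -> float:
    """Upper-bound-ish score from gapless in-register extension of a sparse
    chain; cheap filter that spares chance seed hits the full DP stitch."""
    q0, t0 = anchors[0][0], anchors[0][1]
    q1 = anchors[-1][0] + anchors[-1][2]
    t1 = anchors[-1][1] + anchors[-1][2]
    score = float(sum(a[2] for a in anchors))
    w = params.ext_window
    for sq, st in (
        (query[max(0, q0 - w) : q0][::-1], target[max(0, t0 - w) : t0][::-1]),
        (query[q1 : q1 + w], target[t1 : t1 + w]),
    ):
        m = min(len(sq), len(st))
        if m == 0:
            continue
        eq = np.frombuffer(sq[:m].encode(), dtype=np.uint8) == np.frombuffer(
            st[:m].encode(), dtype=np.uint8
        )
        run = np.cumsum(np.where(eq, params.match, params.mismatch))
        best = float(run.max())
        if best > 0:
            score += best
    return score


def local_align(
    query: str,
    target_index: KmerIndex,
    params: AlignParams | None = None,
    query_id: str = "query",
) -> list[AlignmentBlock]:
    """All maximal local alignments of ``query`` against an indexed target set.

    Both strands are searched; reverse-strand blocks carry forward-query
    coordinates with ``strand='-'``.  Blocks are sorted by score descending
    (ties broken by target position for determinism) and filtered at
    ``params.min_score``.
    """
    params = params or AlignParams()
    q = _check_dna(query, "query")
    if len(q) < params.k or target_index.total_length == 0:
        return []
    blocks: list[AlignmentBlock] = []
    for strand in "+-":
        qseq = q if strand == "+" else revcomp(q)
        bases = encode_bases(qseq)
        codes, valid = _kmer_codes(bases, params.k)
        qpos, sid, tpos = target_index.lookup(codes, valid)
        for s in np.unique(sid):
            name = target_index.names[int(s)]
            tseq = target_index.seqs[name]
            m = sid == s
            aqs, ats, aln, ans = _anchors_from_hits(qpos[m], tpos[m], params.k)
            for anchors in _chain_anchors(aqs, ats, aln, ans, params):
                if sum(a[3] for a in anchors) < params.min_seed_chain:
                    continue
                if (
                    sum(a[2] for a in anchors) < 25
                    and _quick_extend_score(anchors, qseq, tseq, params) < params.min_score
                ):
                    continue
                cm, cs, q0, q1, t0, t1 = _stitch_chain(anchors, qseq, tseq, params)
                if cm.size == 0:
                    continue
                gaps = cs != 0
                go = int((np.diff(np.concatenate([[0], gaps.view(np.int8)])) == 1).sum())
                blk = AlignmentBlock(
                    query_id=query_id,
                    query_start=q0,
                    query_end=q1,
                    target_id=name,
                    target_start=t0,
                    target_end=t1,
                    strand=strand,
                    matches=int(cm.sum()),
                    aln_columns=int(cm.shape[0]),
                    gap_opens=go,
                    score=_score_columns(cm, cs, params),
                    _colmatch=cm,
                    _colstate=cs,
                )
                trimmed = _trim_block_ends(blk, params)
                if trimmed is None:
                    continue
                for piece in _split_block(trimmed, params):
                    if piece.score >= params.min_score:
                        if strand == "-":
                            piece = replace(
                                piece,
                                query_start=len(q) - piece.query_end,
                                query_end=len(q) - piece.query_start,
                            )
                        blocks.append(piece)
    # divergent short pairs can carry no exact seed at all; for small
    # problems exact DP guarantees the optimum the heuristic may miss
    if params.dp_fallback and len(q) * target_index.total_length <= params.dp_cap:
        top = max((b.score for b in blocks), default=0.0)
        for name in target_index.names:
            tseq = target_index.seqs[name]
            for strand in "+-":
                qseq = q if strand == "+" else revcomp(q)
                blk = align_pair_dp(qseq, tseq, params, query_id=query_id, target_id=name)
                if blk is not None and blk.score >= params.min_score and blk.score > top:
                    if strand == "-":
                        blk = replace(
                            blk,
                            query_start=len(q) - blk.query_end,
                            query_end=len(q) - blk.query_start,
                            strand="-",
                        )
                    blocks.append(blk)
    seen = set()
    out = []
    for b in sorted(
        blocks, key=lambda b: (-b.score, b.target_id, b.target_start, b.query_start, b.strand)
    ):
        key = (b.query_start, b.query_end, b.target_id, b.target_start, b.target_end, b.strand)
        if key not in seen:
            seen.add(key)
            out.append(b)
    return out


def align_to_genome(
    query: str,
    genome: dict[str, str],
    params: AlignParams | None = None,
    query_id: str = "query",
) -> list[AlignmentBlock]:
    """Convenience: build a throwaway index over ``genome`` and align."""
    params = params or AlignParams()
    idx = KmerIndex(genome, k=params.k, max_occ=params.max_occ)
    return local_align(query, idx, params, query_id=query_id)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def identity_and_coverage(
    blocks: Sequence[AlignmentBlock], query_len: int
) -> tuple[float, float]:
    """Best single-block identity and union query coverage, both percent.

    Coverage counts each query base once across the union of block query
    intervals.  Empty block list -> (0, 0).
    """
    if query_len <= 0:
        raise InputError("query_len must be positive")
    if not blocks:
        return 0.0, 0.0
    qids = {b.query_id for b in blocks}
    if len(qids) > 1:
        raise InputError(f"blocks from mixed queries: {sorted(qids)}")
    best = max(blocks, key=lambda b: b.score)
    ivs = sorted(b.query_interval() for b in blocks)
    covered = 0
    cur_s, cur_e = ivs[0]
    for s, e in ivs[1:]:
        if s > cur_e:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    covered += cur_e - cur_s
    return best.identity, 100.0 * covered / query_len


def evalue(score: float, query_len: int, db_len: int, kp: KarlinParams | None = None) -> float:
    """Karlin–Altschul expectation E = K * m * n * exp(-lambda * S)."""
    kp = kp or KarlinParams()
    if score < 0 or query_len <= 0 or db_len <= 0:
        raise InputError("evalue arguments must be positive")
    return kp.K * query_len * db_len * float(np.exp(-kp.lambda_ * score))
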