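"""Per-assembly extraction of candidate non-reference sequences (NRS).

The cascade harvests assembly regions that fail to align to the reference at
high identity, realigns and subtracts residual high-identity pieces, removes
annotated simple repeats, merges nearby survivors and applies the minimum
length rule — then repeats the subtract/merge/filter pass once more:

    uncovered_segments -> subtract_high_identity -> mask_repeat_classes
    -> merge_and_filter -> subtract_high_identity -> merge_and_filter

All thresholds default to the published rules: a base counts as covered only
when some alignment block of identity >= 90% spans it; harvested pieces must
be >= 100 bp before merging; neighbours <= 200 bp apart are merged (gap bases
re-included, so every NRS is a contiguous assembly substring); merged
sequences < 400 bp are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .align import AlignParams, AlignmentBlock, KmerIndex, local_align
from .errors import ConfigError, InputError

logger = logging.getLogger(__name__)

#: repeat classes removed from candidate segments (TE classes are retained)
SIMPLE_REPEAT_CLASSES = frozenset({"simple_repeat", "low_complexity", "microsatellite"})

_CLASS_ALIASES = {
    "simple_repeat": "simple_repeat",
    "simple repeat": "simple_repeat",
    "low_complexity": "low_complexity",
    "low complexity": "low_complexity",
    "microsatellite": "microsatellite",
    "satellite/micro": "microsatellite",
}


def normalize_repeat_class(name: str) -> str:
    """Map a RepeatMasker-style class/family string to a canonical class."""
    key = name.strip().lower()
    return _CLASS_ALIASES.get(key, name.strip())


@dataclass(frozen=True)
class Segment:
    """A half-open interval on an assembly contig."""

    contig_id: str
    start: int
    end: int
    source_assembly: str = ""

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise InputError(f"empty segment {self.contig_id}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class NRSRecord:
    """A candidate non-reference sequence with provenance coordinates."""

    nrs_id: str
    sequence: str
    source_assembly: str
    source_contig: str
    source_start: int
    source_end: int

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class RepeatTrack:
    """Repeat annotation intervals: (contig_id, start, end, repeat_class)."""

    intervals: list[tuple[str, int, int, str]]

    def classes(self) -> set[str]:
        return {normalize_repeat_class(c) for _, _, _, c in self.intervals}

    def by_contig(self, classes: set[str] | None = None):
        out: dict[str, list[tuple[int, int]]] = {}
        for contig, s, e, c in self.intervals:
            cn = normalize_repeat_class(c)
            if classes is None or cn in classes:
                out.setdefault(contig, []).append((s, e))
        for v in out.values():
            v.sort()
        return out


# ---------------------------------------------------------------------------
# interval helpers
# ---------------------------------------------------------------------------

def _union(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract(interval: tuple[int, int], removals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    s, e = interval
    out = []
    cur = s
    for rs, re_ in removals:
        if re_ <= cur or rs >= e:
            continue
        if rs > cur:
            out.append((cur, min(rs, e)))
        cur = max(cur, re_)
        if cur >= e:
            break
    if cur < e:
        out.append((cur, e))
    return out


# ---------------------------------------------------------------------------
# cascade stages
# ---------------------------------------------------------------------------

def uncovered_segments(
    assembly: dict[str, str],
    blocks: Sequence[AlignmentBlock],
    min_identity: float = 90.0,
    min_len: int = 100,
    source_assembly: str = "",
) -> list[Segment]:
    """Maximal per-contig intervals not covered by any block of qualifying identity.

    A base covered only by blocks with identity below ``min_identity`` counts
    as uncovered (harvestable).  A contig with no qualifying block at all is
    returned whole when it is at least ``min_len``.
    """
    covered: dict[str, list[tuple[int, int]]] = {c: [] for c in assembly}
    for b in blocks:
        if b.identity >= min_identity and b.query_id in covered:
            covered[b.query_id].append(b.query_interval())
    out: list[Segment] = []
    for contig in sorted(assembly):
        clen = len(assembly[contig])
        for s, e in _subtract((0, clen), _union(covered[contig])):
            if e - s >= min_len:
                out.append(Segment(contig, s, e, source_assembly))
    return out


def subtract_high_identity(
    segments: Sequence[Segment],
    assembly: dict[str, str],
    reference_index: KmerIndex,
    min_identity: float = 90.0,
    params: AlignParams | None = None,
) -> list[Segment]:
    """Realign each segment to the reference and cut out sub-intervals that
    align at identity >= ``min_identity`` (strict: 89.9% survives)."""
    params = params or AlignParams()
    out: list[Segment] = []
    for seg in segments:
        seq = assembly[seg.contig_id][seg.start : seg.end]
        blocks = local_align(seq, reference_index, params, query_id=seg.contig_id)
        removals = _union(
            b.query_interval() for b in blocks if b.identity >= min_identity
        )
        for s, e in _subtract((0, len(seq)), removals):
            out.append(Segment(seg.contig_id, seg.start + s, seg.start + e, seg.source_assembly))
    return out


def mask_repeat_classes(
    segments: Sequence[Segment],
    track: RepeatTrack,
    classes: set[str] = SIMPLE_REPEAT_CLASSES,
) -> list[Segment]:
    """Base-level subtraction of the named repeat classes (TE intervals stay).

    ``track`` coordinates must be on assembly contigs.
    """
    known = SIMPLE_REPEAT_CLASSES | track.classes()
    unknown = {normalize_repeat_class(c) for c in classes} - known
    if unknown:
        raise ConfigError(f"unknown repeat classes requested: {sorted(unknown)}")
    per_contig = track.by_contig({normalize_repeat_class(c) for c in classes})
    out: list[Segment] = []
    for seg in segments:
        removals = _union(per_contig.get(seg.contig_id, []))
        for s, e in _subtract((seg.start, seg.end), removals):
            out.append(Segment(seg.contig_id, s, e, seg.source_assembly))
    return out


def merge_and_filter(
    segments: Sequence[Segment],
    max_gap: int = 200,
    min_len: int = 400,
) -> list[Segment]:
    """Merge per-contig neighbours separated by <= ``max_gap`` bp (the gap
    bases are re-included so merged intervals stay contiguous substrings) and
    keep merged intervals of length >= ``min_len``.  Order-independent."""
    by_contig: dict[tuple[str, str], list[Segment]] = {}
    for seg in segments:
        by_contig.setdefault((seg.source_assembly, seg.contig_id), []).append(seg)
    out: list[Segment] = []
    for (asm, contig) in sorted(by_contig):
        ivs = sorted((s.start, s.end) for s in by_contig[(asm, contig)])
        merged: list[tuple[int, int]] = []
        for s, e in ivs:
            if merged and s - merged[-1][1] <= max_gap:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        for s, e in merged:
            if e - s >= min_len:
                out.append(Segment(contig, s, e, asm))
    return out


def extract_assembly_nrs(
    assembly: dict[str, str],
    reference_index: KmerIndex,
    track: RepeatTrack,
    assembly_name: str = "assembly",
    params: AlignParams | None = None,
    min_identity: float = 90.0,
    min_seed_len: int = 100,
    merge_gap: int = 200,
    min_nrs_len: int = 400,
    mask_classes: set[str] = SIMPLE_REPEAT_CLASSES,
) -> list[NRSRecord]:
    """Run the full extraction cascade for one assembly.

    Stage order is fixed and logged with per-stage counts; the second
    subtract/merge pass guarantees no output realigns to the reference at
    >= ``min_identity`` over a sub-interval the seeded engine can see.
    """
    params = params or AlignParams()

    def _log(stage: str, segs: Sequence[Segment]) -> None:
        logger.info(
            "%s/%s: %d segments, %d bp", assembly_name, stage, len(segs),
            sum(len(s) for s in segs),
        )

    all_blocks: list[AlignmentBlock] = []
    for contig in sorted(assembly):
        all_blocks.extend(
            local_align(assembly[contig], reference_index, params, query_id=contig)
        )
    segs = uncovered_segments(assembly, all_blocks, min_identity, min_seed_len, assembly_name)
    _log("uncovered", segs)
    segs = subtract_high_identity(segs, assembly, reference_index, min_identity, params)
    _log("subtract1", segs)
    segs = mask_repeat_classes(segs, track, mask_classes)
    _log("mask", segs)
    segs = merge_and_filter(segs, merge_gap, min_nrs_len)
    _log("merge1", segs)
    segs = subtract_high_identity(segs, assembly, reference_index, min_identity, params)
    _log("subtract2", segs)
    segs = merge_and_filter(segs, merge_gap, min_nrs_len)
    _log("merge2", segs)

    records = []
    for i, seg in enumerate(segs):
        records.append(
            NRSRecord(
                nrs_id=f"{assembly_name}.nrs{i:04d}",
                sequence=assembly[seg.contig_id][seg.start : seg.end],
                source_assembly=assembly_name,
                source_contig=seg.contig_id,
                source_start=seg.start,
                source_end=seg.end,
            )
        )
    return records
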