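"""Synthetic cohort generator with machine-readable planted truth.

Emulates the study design the pipeline targets: one reference genome plus a
cohort of derived assemblies carrying planted insertions, divergent
alternate alleles (optionally built from a shared tandem-repeat array),
simple-repeat decoys, assembly-gap fillers and contaminant contigs, with
population-structured sharing, ape-like outgroups, an EST-like transcript
database, a decoy/contaminant database and paired RNA-seq reads transcribed
from a subset of planted sequences.

Every output byte is a deterministic function of (spec, seed).  Planted
junctions are disambiguated (the first/last planted base always differs
from the adjacent reference base) so that each planted breakpoint has a
unique coordinate representation and recovery can be scored exactly.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .align import AlignParams, align_pair_dp
from .classify import Gene
from .errors import InputError
from .extract import RepeatTrack

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def random_dna(rng: np.random.Generator, n: int, gc: float = 0.41) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=n, p=p)
    return _BASES[idx].tobytes().decode("ascii")


def mutate_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitution-only mutation at the given per-base rate (N preserved)."""
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    code = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        code[b] = i
    idx = code[arr]
    hits = np.nonzero((rng.random(arr.shape[0]) < rate) & (idx < 4))[0]
    if hits.size:
        shift = rng.integers(1, 4, size=hits.size)
        arr[hits] = _BASES[(idx[hits] + shift) % 4]
    return arr.tobytes().decode("ascii")


def noisy_tandem_array(
    motif: str, length: int, noise: float, rng: np.random.Generator
) -> str:
    reps = -(-length // len(motif))
    return mutate_substitutions((motif * reps)[:length], noise, rng)


def _differ_base(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(0, 3))]


# ---------------------------------------------------------------------------
# spec / truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults define the package's standard benchmark cohort: a 2 Mb
    reference with four derived assemblies, 30 insertions (300-3000 bp),
    20 alternate alleles (target identity 60-85%, length ratio 0.5-2, half
    with tandem-repeat architecture), 10 simple-repeat decoys, 5 contaminant
    contigs and 2 assembly gaps.
    """

    reference_length: int = 2_000_000
    n_assemblies: int = 4
    group_sizes: tuple[tuple[str, int], ...] | None = None  # population structure

    n_insertions: int = 30
    insertion_size: tuple[int, int] = (300, 3000)

    n_alternates: int = 20
    alternate_identity: tuple[float, float] = (60.0, 85.0)
    alternate_ratio: tuple[float, float] = (0.5, 2.0)
    alternate_ref_span: tuple[int, int] = (1200, 2000)
    tr_fraction_of_alternates: float = 0.5
    tr_alt_fraction_range: tuple[float, float] = (0.4, 1.0)
    tr_ref_slope: float = 0.8       # ref_tr = slope * alt_tr + noise
    tr_ref_noise_sd: float = 0.05

    n_decoys: int = 10
    decoy_size: tuple[int, int] = (500, 1500)
    n_contaminants: int = 5
    contaminant_size: tuple[int, int] = (5000, 20000)
    n_gaps: int = 2
    gap_size: tuple[int, int] = (2000, 5000)

    # reference annotation content
    n_alu: int = 40
    n_l1: int = 3
    n_simple_repeats: int = 30
    simple_repeat_size: tuple[int, int] = (100, 400)
    n_genes: int = 20
    gene_size: tuple[int, int] = (2000, 6000)
    gc: float = 0.41

    carrier_prob: float = 0.6
    group_carrier_prob: float = 0.8
    transcribed_fraction: float = 0.25

    assembly_divergence: float = 0.001
    outgroup_divergence: float = 0.015
    n_outgroups: int = 2
    outgroup_carry_prob: float = 0.3
    contigs_per_assembly: int = 4

    n_rna_samples: int = 3
    rna_depth: float = 20.0
    read_len: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    read_error: float = 0.001


@dataclass
class TruthEvent:
    event_id: str
    kind: str  # insertion | alternate | simple_repeat_decoy | contaminant | gap
    ref_chrom: str
    ref_start: int
    ref_end: int
    planted_seq: str
    carrier_assemblies: list[str] = field(default_factory=list)
    target_identity: float | None = None
    realized_identity: float | None = None
    length_ratio: float | None = None
    transcribed: bool = False
    tr_architecture: bool = False
    motif: str | None = None
    alt_tr_fraction: float | None = None
    ref_tr_fraction: float | None = None


@dataclass
class TruthSet:
    events: list[TruthEvent]

    def by_kind(self, *kinds: str) -> list[TruthEvent]:
        return [e for e in self.events if e.kind in kinds]

    def sharing_matrix(self, genome_names: list[str]) -> pd.DataFrame:
        """Binary event x genome carriage table for recoverable events."""
        rows = {}
        for ev in self.by_kind("insertion", "alternate"):
            rows[ev.event_id] = [g in ev.carrier_assemblies for g in genome_names]
        return pd.DataFrame.from_dict(rows, orient="index", columns=genome_names)

    def to_records(self) -> list[dict]:
        out = []
        for ev in self.events:
            d = asdict(ev)
            d["planted_len"] = len(ev.planted_seq)
            del d["planted_seq"]
            out.append(d)
        return out


@dataclass
class Reference:
    genome: dict[str, str]
    repeat_track: RepeatTrack
    genes: list[Gene]
    gaps: dict[str, list[tuple[int, int]]]
    te_library: dict[str, str]


@dataclass
class Cohort:
    spec: CohortSpec
    seed: int
    reference: Reference
    assemblies: dict[str, dict[str, str]]
    assembly_tracks: dict[str, RepeatTrack]
    outgroups: dict[str, dict[str, str]]
    truth: TruthSet
    est_db: dict[str, str]
    decoy_db: dict[str, str]
    read_samples: dict[str, list[tuple[str, str]]]

    @property
    def assembly_names(self) -> list[str]:
        return sorted(self.assemblies)

    @property
    def outgroup_names(self) -> list[str]:
        return sorted(self.outgroups)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


# ---------------------------------------------------------------------------
# layout allocation
# ---------------------------------------------------------------------------

class _Layout:
    """Non-overlapping interval allocator on [0, length)."""

    def __init__(self, length: int, rng: np.random.Generator, edge: int = 2000):
        self.length = length
        self.rng = rng
        self.edge = edge
        self.starts: list[int] = []
        self.ends: list[int] = []

    def _free(self, s: int, e: int) -> bool:
        i = bisect.bisect_right(self.starts, e) - 1
        if i >= 0 and self.ends[i] > s:
            return False
        j = bisect.bisect_left(self.starts, s)
        if j < len(self.starts) and self.starts[j] < e:
            return False
        return True

    def reserve(self, size: int, margin: int = 0) -> int:
        """Allocate a free interval of ``size`` (+margin on each side)."""
        for _ in range(2000):
            pos = int(self.rng.integers(self.edge, self.length - self.edge - size))
            s, e = pos - margin, pos + size + margin
            if self._free(s, e):
                i = bisect.bisect_left(self.starts, s)
                self.starts.insert(i, s)
                self.ends.insert(i, e)
                return pos
        raise InputError(
            "infeasible packing: requested features/events exceed the reference length"
        )


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------

def make_te_library(rng: np.random.Generator) -> dict[str, str]:
    """Toy Alu-like (300 bp) and L1-like (6 kb) consensus sequences."""
    return {"AluToy": random_dna(rng, 300, gc=0.55), "L1Toy": random_dna(rng, 6000, gc=0.40)}


def make_reference(spec: CohortSpec, seed: int) -> Reference:
    """Random reference (GC ~ 0.41) with embedded TE copies, simple-repeat
    arrays, genes with CDS and N-gaps; annotation tracks consistent with the
    embedded content base-for-base."""
    rng = _rng(seed, 0)
    n = spec.reference_length
    seq = np.frombuffer(random_dna(rng, n, spec.gc).encode("ascii"), dtype=np.uint8).copy()
    layout = _Layout(n, rng)
    te_library = make_te_library(rng)
    track: list[tuple[str, int, int, str]] = []
    gaps: list[tuple[int, int]] = []

    def _emplace(s: str, pos: int) -> None:
        seq[pos : pos + len(s)] = np.frombuffer(s.encode("ascii"), dtype=np.uint8)

    for i in range(spec.n_alu):
        copy = mutate_substitutions(te_library["AluToy"], rng.uniform(0.02, 0.10), rng)
        pos = layout.reserve(len(copy), margin=100)
        _emplace(copy, pos)
        track.append(("chr1", pos, pos + len(copy), "SINE/Alu"))
    for i in range(spec.n_l1):
        copy = mutate_substitutions(te_library["L1Toy"], rng.uniform(0.02, 0.10), rng)
        pos = layout.reserve(len(copy), margin=100)
        _emplace(copy, pos)
        track.append(("chr1", pos, pos + len(copy), "LINE/L1"))
    simple_classes = ["simple_repeat", "low_complexity", "microsatellite"]
    for i in range(spec.n_simple_repeats):
        motif_len = int(rng.integers(1, 7))
        motif = random_dna(rng, motif_len, gc=0.5)
        size = int(rng.integers(*spec.simple_repeat_size))
        arr = noisy_tandem_array(motif, size, 0.01, rng)
        pos = layout.reserve(size, margin=100)
        _emplace(arr, pos)
        cls = "low_complexity" if motif_len == 1 else simple_classes[i % 3]
        track.append(("chr1", pos, pos + size, cls))
    for i in range(spec.n_gaps):
        size = int(rng.integers(*spec.gap_size))
        pos = layout.reserve(size, margin=1500)
        seq[pos : pos + size] = ord("N")
        gaps.append((pos, pos + size))
    genes: list[Gene] = []
    for i in range(spec.n_genes):
        size = int(rng.integers(*spec.gene_size))
        for _ in range(2000):
            pos = int(rng.integers(2000, n - 2000 - size))
            if layout._free(pos, pos + size):
                break
        else:
            raise InputError("infeasible packing: cannot place genes")
        n_cds = int(rng.integers(2, 5))
        bounds = np.sort(rng.choice(np.arange(50, size - 50), size=2 * n_cds, replace=False))
        cds = [(pos + int(bounds[2 * j]), pos + int(bounds[2 * j + 1])) for j in range(n_cds)]
        genes.append(Gene(f"gene{i:03d}", "chr1", pos, pos + size, cds))
    genes.sort(key=lambda g: g.start)
    track.sort(key=lambda t: t[1])
    return Reference(
        genome={"chr1": seq.tobytes().decode("ascii")},
        repeat_track=RepeatTrack(track),
        genes=genes,
        gaps={"chr1": sorted(gaps)},
        te_library=te_library,
    )


# ---------------------------------------------------------------------------
# event construction
# ---------------------------------------------------------------------------

def evolve_to_identity(
    ref_allele: str,
    alt_len: int,
    target: float,
    rng: np.random.Generator,
    params: AlignParams | None = None,
    tolerance: float = 1.0,
    max_iter: int = 8,
) -> tuple[str, float]:
    """Mutate (a copy of) the reference allele until its best local-DP
    identity against it enters ``target`` +/- ``tolerance``.

    Binary search on the substitution rate with a seed-stable fallback: when
    the band is never hit (heavy divergence can leave only short residual
    alignments) the closest candidate with identity safely below 90 wins.
    """
    params = params or AlignParams()
    if alt_len <= len(ref_allele):
        base = ref_allele[:alt_len]
    else:
        base = ref_allele + random_dna(rng, alt_len - len(ref_allele))
    lo, hi = 0.005, 0.75
    r = min(max(1 - target / 100.0, lo), hi)
    best: tuple[float, str, float] | None = None
    for _ in range(max_iter):
        cand = mutate_substitutions(base, r, rng)
        blk = align_pair_dp(cand, ref_allele, params)
        ident = blk.identity if blk is not None and blk.score >= params.min_score else 0.0
        gap = abs(ident - target)
        if ident < 89.0 and (best is None or gap < best[0]):
            best = (gap, cand, ident)
        if gap <= tolerance and ident < 89.0:
            break
        if ident > target:
            lo = max(lo, r)
        else:
            hi = min(hi, r)
        r = (lo + hi) / 2.0
    if best is None:  # everything measured >= 89: force clear divergence
        cand = mutate_substitutions(base, 0.25, rng)
        blk = align_pair_dp(cand, ref_allele, params)
        ident = blk.identity if blk is not None and blk.score >= params.min_score else 0.0
        best = (abs(ident - target), cand, ident)
    return best[1], best[2]


def build_tr_alternate(
    span: int, alt_len: int, target: float, spec: CohortSpec, rng: np.random.Generator
) -> tuple[str, str, str, float, float]:
    """(ref_allele, alt_seq, motif, alt_tr_fraction, ref_tr_fraction).

    Both alleles are arrays of a shared motif; the alternate copy's motif is
    mutated so the alleles diverge to roughly the target identity while both
    stay tandem-repeat rich.
    """
    m = int(rng.integers(16, 31))
    motif = random_dna(rng, m, gc=0.5)
    n_mut = max(3, int(round((1 - target / 100.0) * m)))
    # position 0 always mutates: the two arrays then disagree right at the
    # junction, keeping the planted breakpoint representation unique
    pos = np.concatenate([[0], 1 + rng.choice(m - 1, size=n_mut - 1, replace=False)])
    alt_motif = list(motif)
    for p in pos:
        alt_motif[p] = _differ_base(alt_motif[p], rng)
    alt_motif = "".join(alt_motif)
    f_alt = float(rng.uniform(*spec.tr_alt_fraction_range))
    f_ref = float(
        np.clip(spec.tr_ref_slope * f_alt + rng.normal(0.0, spec.tr_ref_noise_sd), 0.05, 1.0)
    )
    ref_tr_len = int(round(f_ref * span))
    alt_tr_len = int(round(f_alt * alt_len))
    ref_allele = noisy_tandem_array(motif, ref_tr_len, 0.02, rng) + random_dna(
        rng, span - ref_tr_len
    )
    alt_seq = noisy_tandem_array(alt_motif, alt_tr_len, 0.02, rng) + random_dna(
        rng, alt_len - alt_tr_len
    )
    return ref_allele, alt_seq, motif, f_alt, f_ref


def _disambiguate_junctions(planted: str, ref: str, start: int, end: int, rng) -> str:
    """Force the planted sequence's terminal bases to differ from the
    adjacent reference bases so the breakpoint representation is unique."""
    s = list(planted)
    if start < len(ref) and s and s[0] == ref[start]:
        s[0] = _differ_base(s[0], rng)
    if end >= 1 and s and s[-1] == ref[end - 1]:
        s[-1] = _differ_base(s[-1], rng)
    return "".join(s)


def _assembly_names(spec: CohortSpec) -> tuple[list[str], dict[str, list[str]]]:
    if spec.group_sizes:
        names, groups = [], {}
        for gname, size in spec.group_sizes:
            members = [f"{gname}{i + 1:02d}" for i in range(size)]
            groups[gname] = members
            names.extend(members)
        return names, groups
    names = [f"asm{i + 1:02d}" for i in range(spec.n_assemblies)]
    return names, {}


def plan_events(spec: CohortSpec, reference: Reference, seed: int) -> TruthSet:
    """Choose event sites, build planted sequences and assign carriers.

    TR-architecture alternates overwrite the reference span with their
    tandem reference allele (the reference is returned modified in place via
    the Reference object's genome dict).
    """
    rng = _rng(seed, 1)
    ref = reference.genome["chr1"]
    n = len(ref)
    layout = _Layout(n, rng)
    # pre-occupy hard features and gaps so events land in clean sequence
    for contig, s, e, _c in reference.repeat_track.intervals:
        layout.starts.append(s - 100)
        layout.ends.append(e + 100)
    for s, e in reference.gaps["chr1"]:
        layout.starts.append(s - 1500)
        layout.ends.append(e + 1500)
    order = np.argsort(layout.starts)
    layout.starts = [layout.starts[i] for i in order]
    layout.ends = [layout.ends[i] for i in order]

    names, groups = _assembly_names(spec)
    group_cycle = sorted(groups) if groups else []

    def carriers(idx: int) -> list[str]:
        if groups:
            pool = groups[group_cycle[idx % len(group_cycle)]]
            chosen = [a for a in pool if rng.random() < spec.group_carrier_prob]
        else:
            chosen = [a for a in names if rng.random() < spec.carrier_prob]
            pool = names
        if not chosen:
            chosen = [pool[int(rng.integers(len(pool)))]]
        return chosen

    events: list[TruthEvent] = []
    params = AlignParams()
    n_tr = int(round(spec.n_alternates * spec.tr_fraction_of_alternates))

    for i in range(spec.n_insertions):
        size = int(rng.integers(*spec.insertion_size))
        pos = layout.reserve(0, margin=1500)
        planted = _disambiguate_junctions(random_dna(rng, size, spec.gc), ref, pos, pos, rng)
        events.append(
            TruthEvent(f"ins{i:03d}", "insertion", "chr1", pos, pos, planted, carriers(i))
        )

    ref_arr = np.frombuffer(ref.encode("ascii"), dtype=np.uint8).copy()
    for i in range(spec.n_alternates):
        target = float(rng.uniform(*spec.alternate_identity))
        ratio = float(rng.uniform(*spec.alternate_ratio))
        span = int(rng.integers(*spec.alternate_ref_span))
        alt_len = max(int(round(ratio * span)), span // 3 + 300)
        pos = layout.reserve(span, margin=1500)
        tr = i < n_tr
        if tr:
            allele, alt_seq, motif, f_alt, f_ref = build_tr_alternate(
                span, alt_len, target, spec, rng
            )
            ref_arr[pos : pos + span] = np.frombuffer(allele.encode("ascii"), dtype=np.uint8)
            realized = None
        else:
            allele = ref[pos : pos + span]
            alt_seq, realized = evolve_to_identity(allele, alt_len, target, rng, params)
            motif, f_alt, f_ref = None, None, None
        # junction uniqueness is judged against the allele actually planted
        # in the reference (for TR events the reference span was rewritten)
        s = list(alt_seq)
        if s[0] == allele[0]:
            s[0] = _differ_base(s[0], rng)
        if s[-1] == allele[-1]:
            s[-1] = _differ_base(s[-1], rng)
        alt_seq = "".join(s)
        events.append(
            TruthEvent(
                f"alt{i:03d}", "alternate", "chr1", pos, pos + span, alt_seq,
                carriers(spec.n_insertions + i),
                target_identity=target, realized_identity=realized,
                length_ratio=len(alt_seq) / span, tr_architecture=tr,
                motif=motif, alt_tr_fraction=f_alt, ref_tr_fraction=f_ref,
            )
        )
    if n_tr:  # TR reference alleles were written into the reference
        reference.genome["chr1"] = ref_arr.tobytes().decode("ascii")
        ref = reference.genome["chr1"]

    for i in range(spec.n_decoys):
        motif_len = int(rng.integers(1, 7))
        motif = random_dna(rng, motif_len, gc=0.5)
        size = int(rng.integers(*spec.decoy_size))
        pos = layout.reserve(0, margin=1500)
        planted = noisy_tandem_array(motif, size, 0.01, rng)
        events.append(
            TruthEvent(
                f"decoy{i:03d}", "simple_repeat_decoy", "chr1", pos, pos, planted,
                carriers(i), motif=motif,
            )
        )

    for i in range(spec.n_contaminants):
        size = int(rng.integers(*spec.contaminant_size))
        carrier = names[i % len(names)]
        events.append(
            TruthEvent(
                f"contam{i:03d}", "contaminant", "chr1", 0, 0,
                random_dna(rng, size, gc=0.55), [carrier],
            )
        )

    for i, (gs, ge) in enumerate(reference.gaps["chr1"]):
        filler = _disambiguate_junctions(random_dna(rng, ge - gs, spec.gc), ref, gs, ge, rng)
        events.append(TruthEvent(f"gap{i:03d}", "gap", "chr1", gs, ge, filler, list(names)))

    for ev in events:
        if ev.kind in ("insertion", "alternate"):
            ev.transcribed = bool(rng.random() < spec.transcribed_fraction)
    return TruthSet(events)


# ---------------------------------------------------------------------------
# assembly derivation
# ---------------------------------------------------------------------------

_DECOY_CLASS = {1: "low_complexity", 2: "simple_repeat", 3: "simple_repeat",
                4: "simple_repeat", 5: "microsatellite", 6: "microsatellite"}


def derive_assembly(
    reference: Reference,
    truth: TruthSet,
    name: str,
    spec: CohortSpec,
    seed: int,
    stream: int,
) -> tuple[dict[str, str], RepeatTrack]:
    """One derived assembly (contig dict) plus its lifted repeat track.

    Carrier events are applied left to right with coordinate lifting,
    substitution-only background divergence is added, the chromosome is
    fragmented into contigs away from event footprints, and any contaminant
    contigs are appended.
    """
    rng = _rng(seed, stream)
    ref = reference.genome["chr1"]
    my_events = sorted(
        (
            ev
            for ev in truth.events
            if name in ev.carrier_assemblies and ev.kind != "contaminant"
        ),
        key=lambda e: (e.ref_start, e.event_id),
    )
    for a, b in zip(my_events, my_events[1:]):
        if b.ref_start < a.ref_end:
            raise InputError(f"overlapping events for carrier {name}: {a.event_id}/{b.event_id}")
    parts: list[str] = []
    blocks: list[tuple[int, int, int]] = []  # (ref_start, ref_end, asm_offset)
    protected: list[tuple[int, int]] = []
    decoy_spans: list[tuple[int, int, str]] = []  # asm coords + class
    cursor = out = 0
    for ev in my_events:
        if ev.ref_start > cursor:
            parts.append(ref[cursor : ev.ref_start])
            blocks.append((cursor, ev.ref_start, out))
            out += ev.ref_start - cursor
        ins = ev.planted_seq
        protected.append((out - 1500, out + len(ins) + 1500))
        if ev.kind == "simple_repeat_decoy":
            decoy_spans.append((out, out + len(ins), _DECOY_CLASS[len(ev.motif)]))
        parts.append(ins)
        out += len(ins)
        cursor = ev.ref_end
    if cursor < len(ref):
        parts.append(ref[cursor:])
        blocks.append((cursor, len(ref), out))
        out += len(ref) - cursor
    seq = mutate_substitutions("".join(parts), spec.assembly_divergence, rng)

    # fragment into contigs away from event footprints
    cuts: list[int] = []
    if spec.contigs_per_assembly > 1:
        tries = 0
        while len(cuts) < spec.contigs_per_assembly - 1 and tries < 2000:
            tries += 1
            pos = int(rng.integers(50_000, len(seq) - 50_000))
            if any(s <= pos < e for s, e, *_ in protected):
                continue
            if any(abs(pos - c) < 20_000 for c in cuts):
                continue
            cuts.append(pos)
        cuts.sort()
    bounds = [0] + cuts + [len(seq)]
    contigs = {
        f"{name}_ctg{i + 1}": seq[bounds[i] : bounds[i + 1]] for i in range(len(bounds) - 1)
    }

    # lift the reference repeat annotation through the coordinate map
    lifted: list[tuple[str, int, int, str]] = []

    def _to_contig(s: int, e: int, cls: str) -> None:
        for i in range(len(bounds) - 1):
            lo, hi = max(s, bounds[i]), min(e, bounds[i + 1])
            if hi > lo:
                lifted.append((f"{name}_ctg{i + 1}", lo - bounds[i], hi - bounds[i], cls))

    for contig, rs, re_, cls in reference.repeat_track.intervals:
        for bs, be, off in blocks:
            lo, hi = max(rs, bs), min(re_, be)
            if hi > lo:
                _to_contig(off + lo - bs, off + hi - bs, cls)
    for s, e, cls in decoy_spans:
        _to_contig(s, e, cls)

    for ev in truth.events:
        if ev.kind == "contaminant" and name in ev.carrier_assemblies:
            contigs[f"{name}_{ev.event_id}"] = mutate_substitutions(
                ev.planted_seq, spec.assembly_divergence, rng
            )
    lifted.sort()
    return contigs, RepeatTrack(lifted)


def make_outgroups_and_dbs(
    reference: Reference,
    truth: TruthSet,
    spec: CohortSpec,
    seed: int,
) -> tuple[dict[str, dict[str, str]], dict[str, str], dict[str, str]]:
    """Ape-like outgroups (subset of events + ~1.5% divergence), an EST-like
    database of transcribed-event subsequences, and the decoy/contaminant
    source database.  Outgroup carriage is recorded in the truth set."""
    rng = _rng(seed, 50)
    ref = reference.genome["chr1"]
    outgroups: dict[str, dict[str, str]] = {}
    for j in range(spec.n_outgroups):
        name = f"outgroup{j + 1}"
        events = []
        for ev in truth.events:
            if ev.kind in ("insertion", "alternate") and rng.random() < spec.outgroup_carry_prob:
                events.append(ev)
                ev.carrier_assemblies.append(name)
            elif ev.kind == "gap":
                events.append(ev)
        events.sort(key=lambda e: e.ref_start)
        parts, cursor = [], 0
        for ev in events:
            parts.append(ref[cursor : ev.ref_start])
            parts.append(ev.planted_seq)
            cursor = ev.ref_end
        parts.append(ref[cursor:])
        outgroups[name] = {
            f"{name}_chr1": mutate_substitutions("".join(parts), spec.outgroup_divergence, rng)
        }
    est_db: dict[str, str] = {}
    k = 0
    for ev in truth.by_kind("insertion", "alternate"):
        if not ev.transcribed:
            continue
        n_est = int(rng.integers(1, 4))
        for _ in range(n_est):
            size = int(rng.integers(150, 401))
            if len(ev.planted_seq) <= size + 100:
                start = 0
                size = min(size, len(ev.planted_seq))
            else:
                start = int(rng.integers(50, len(ev.planted_seq) - size - 50))
            est_db[f"est{k:04d}"] = mutate_substitutions(
                ev.planted_seq[start : start + size], 0.005, rng
            )
            k += 1
    decoy_db = {
        ev.event_id: ev.planted_seq for ev in truth.by_kind("contaminant")
    }
    return outgroups, est_db, decoy_db


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def simulate_reads(
    transcripts: dict[str, str],
    depth: float,
    seed: int,
    read_len: int = 100,
    insert_mean: float = 300.0,
    insert_sd: float = 30.0,
    error: float = 0.001,
    stream: int = 200,
) -> list[tuple[str, str]]:
    """Paired FR reads at uniform coverage over the given transcripts.

    Pair counts are Poisson around depth * length / (2 * read_len);
    deterministic per (seed, stream).
    """
    from .align import revcomp

    rng = _rng(seed, stream)
    pairs: list[tuple[str, str]] = []
    for tname in sorted(transcripts):
        seq = transcripts[tname]
        if len(seq) < 2 * read_len:
            continue
        n_pairs = int(rng.poisson(depth * len(seq) / (2.0 * read_len)))
        for _ in range(n_pairs):
            insert = int(np.clip(rng.normal(insert_mean, insert_sd), 2 * read_len, len(seq)))
            start = int(rng.integers(0, len(seq) - insert + 1))
            r1 = mutate_substitutions(seq[start : start + read_len], error, rng)
            r2 = mutate_substitutions(
                revcomp(seq[start + insert - read_len : start + insert]), error, rng
            )
            pairs.append((r1, r2))
    return pairs


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec | None = None, seed: int = 0) -> Cohort:
    """Generate a full synthetic cohort: reference, assemblies with tracks,
    outgroups, truth, databases and RNA-seq read samples."""
    spec = spec or CohortSpec()
    reference = make_reference(spec, seed)
    truth = plan_events(spec, reference, seed)
    names, _groups = _assembly_names(spec)
    assemblies: dict[str, dict[str, str]] = {}
    tracks: dict[str, RepeatTrack] = {}
    for i, name in enumerate(names):
        contigs, track = derive_assembly(reference, truth, name, spec, seed, stream=10 + i)
        assemblies[name] = contigs
        tracks[name] = track
    outgroups, est_db, decoy_db = make_outgroups_and_dbs(reference, truth, spec, seed)
    transcripts = {
        ev.event_id: ev.planted_seq
        for ev in truth.by_kind("insertion", "alternate")
        if ev.transcribed
    }
    read_samples = {
        f"sample{s + 1}": simulate_reads(
            transcripts, spec.rna_depth, seed,
            read_len=spec.read_len, insert_mean=spec.insert_mean,
            insert_sd=spec.insert_sd, error=spec.read_error, stream=200 + s,
        )
        for s in range(spec.n_rna_samples)
    }
    return Cohort(
        spec=spec, seed=seed, reference=reference, assemblies=assemblies,
        assembly_tracks=tracks, outgroups=outgroups, truth=truth,
        est_db=est_db, decoy_db=decoy_db, read_samples=read_samples,
    )
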