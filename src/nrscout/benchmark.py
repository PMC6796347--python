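"""Scoring a pipeline run against a synthetic cohort's planted truth.

Used by the benchmark suite: per-class sensitivity (a planted event counts
as recovered when a precise placement lands on its breakpoints), per-class
classification accuracy, breakend exactness, and decoy/contaminant leakage
into the final call set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pipeline import PipelineResult
from .simulate import Cohort, TruthEvent


@dataclass
class RecoveryScore:
    insertion_recovered: int
    insertion_total: int
    alternate_recovered: int
    alternate_total: int
    breakend_exact: int
    breakend_near: int
    class_correct: int
    class_scored: int
    leaked_decoys: int
    leaked_contaminants: int

    @property
    def insertion_sensitivity(self) -> float:
        return 100.0 * self.insertion_recovered / max(1, self.insertion_total)

    @property
    def alternate_sensitivity(self) -> float:
        return 100.0 * self.alternate_recovered / max(1, self.alternate_total)

    @property
    def breakend_exact_pct(self) -> float:
        matched = self.breakend_exact + self.breakend_near
        return 100.0 * self.breakend_exact / max(1, matched)

    @property
    def classification_accuracy(self) -> float:
        return 100.0 * self.class_correct / max(1, self.class_scored)


def _matches_planted(record_seq: str, planted: str, probe: int = 60) -> bool:
    """Does the record share sequence with a planted decoy/contaminant?

    Background divergence is ~0.1%, so several exact probes of the planted
    sequence are expected to survive verbatim in any derived copy.
    """
    step = max(100, len(planted) // 10)
    hits = 0
    for off in range(0, max(1, len(planted) - probe), step):
        if planted[off : off + probe] in record_seq:
            hits += 1
            if hits >= 1:
                return True
    return False


def score_recovery(cohort: Cohort, result: PipelineResult, near_bp: int = 100) -> RecoveryScore:
    truth_events = cohort.truth.by_kind("insertion", "alternate")
    bykey = {(ev.ref_start, ev.ref_end): ev for ev in truth_events}
    recovered: dict[str, str] = {}
    exact = near = class_ok = class_scored = 0
    for rec in result.call_set:
        pl = result.placements[rec.nrs_id]
        if pl.status != "precise":
            continue
        ev = bykey.get((pl.left_breakend, pl.right_breakend))
        if ev is not None:
            exact += 1
        else:
            cands = [
                e
                for e in truth_events
                if pl.left_breakend is not None
                and abs(pl.left_breakend - e.ref_start) < near_bp
                and abs(pl.right_breakend - e.ref_end) < near_bp
            ]
            if cands:
                ev = cands[0]
                near += 1
        if ev is None:
            continue
        recovered[ev.event_id] = rec.nrs_id
        call = result.calls.get(rec.nrs_id)
        if call is not None:
            class_scored += 1
            if call.call == ev.kind:
                class_ok += 1
    ins = [e for e in truth_events if e.kind == "insertion"]
    alt = [e for e in truth_events if e.kind == "alternate"]
    leaked_d = leaked_c = 0
    for rec in result.call_set:
        for ev in cohort.truth.by_kind("simple_repeat_decoy"):
            if _matches_planted(rec.sequence, ev.planted_seq):
                leaked_d += 1
                break
        for ev in cohort.truth.by_kind("contaminant"):
            if _matches_planted(rec.sequence, ev.planted_seq):
                leaked_c += 1
                break
    return RecoveryScore(
        insertion_recovered=sum(1 for e in ins if e.event_id in recovered),
        insertion_total=len(ins),
        alternate_recovered=sum(1 for e in alt if e.event_id in recovered),
        alternate_total=len(alt),
        breakend_exact=exact,
        breakend_near=near,
        class_correct=class_ok,
        class_scored=class_scored,
        leaked_decoys=leaked_d,
        leaked_contaminants=leaked_c,
    )


def presence_truth_match(cohort: Cohort, result: PipelineResult, near_bp: int = 100):
    """Fraction of presence-matrix cells agreeing with the truth sharing
    matrix, over call-set records matched to planted events."""
    names = cohort.assembly_names + cohort.outgroup_names
    sharing = cohort.truth.sharing_matrix(names)
    truth_events = cohort.truth.by_kind("insertion", "alternate")
    agree = total = 0
    matched = 0
    for rec in result.call_set:
        pl = result.placements[rec.nrs_id]
        if pl.status != "precise" or rec.nrs_id not in result.presence.table.index:
            continue
        cands = [
            e
            for e in truth_events
            if abs(pl.left_breakend - e.ref_start) < near_bp
            and abs(pl.right_breakend - e.ref_end) < near_bp
        ]
        if not cands:
            continue
        matched += 1
        got = result.presence.table.loc[rec.nrs_id, names].to_numpy()
        want = sharing.loc[cands[0].event_id].to_numpy()
        agree += int((got == want).sum())
        total += len(names)
    return (100.0 * agree / total if total else 0.0), matched


def pca_group_silhouette(result: PipelineResult, groups: dict[str, list[str]]) -> float:
    """Silhouette of the PC1 coordinate under the population labels."""
    from sklearn.metrics import silhouette_score

    coords = result.pca_coords
    labels = []
    values = []
    for gname, members in sorted(groups.items()):
        for m in members:
            if m in coords.index:
                labels.append(gname)
                values.append(coords.loc[m, "PC1"])
    x = np.array(values).reshape(-1, 1)
    return float(silhouette_score(x, labels))
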