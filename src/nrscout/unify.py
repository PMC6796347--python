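"""Cross-assembly unification of candidate NRS.

Covers redundancy clustering (CD-HIT-like greedy longest-first, identity of
the alignment over >= 80% of the shorter sequence), the contamination screen
(90% identity + 90% query coverage against a decoy set), the per-genome
presence/absence matrix (identity >= 95%, coverage >= 80%) with non-private
and major-allele flags, novelty stratification against the reference,
reciprocal comparison with published sets, and PCA of occurrence matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .align import (
    AlignParams,
    AlignmentBlock,
    KmerIndex,
    align_pair_dp,
    identity_and_coverage,
    local_align,
    revcomp,
)
from .errors import DegenerateInputError, InputError
from .extract import NRSRecord

logger = logging.getLogger(__name__)


@dataclass
class Cluster:
    """A redundancy cluster; the representative is one of the members."""

    representative: str
    members: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# redundancy clustering
# ---------------------------------------------------------------------------

def _shared_kmers(a: str, b_kmers: set[str], k: int = 15) -> int:
    n = 0
    for i in range(0, len(a) - k + 1, k):  # non-overlapping probes suffice
        if a[i : i + k] in b_kmers:
            n += 1
    return n


def _cluster_hit(
    seq: str, rep: str, min_identity: float, min_short_coverage: float,
    params: AlignParams, kmer_cache: dict | None = None,
) -> bool:
    """Does ``seq`` align to ``rep`` at the clustering thresholds (either strand)?"""
    shorter, longer = (seq, rep) if len(seq) <= len(rep) else (rep, seq)
    need = min_short_coverage * len(shorter)
    if kmer_cache is not None and longer in kmer_cache:
        lk = kmer_cache[longer]
    else:
        lk = {longer[i : i + 15] for i in range(len(longer) - 14)}
        if kmer_cache is not None:
            kmer_cache[longer] = lk
    for s in (shorter, revcomp(shorter)):
        # fast accept: near-global identity of the shorter inside the longer
        res = edlib.align(s, longer, mode="HW", task="distance")
        if res["editDistance"] >= 0 and 1 - res["editDistance"] / len(s) >= min_identity:
            return True
        # k-mer prefilter: a qualifying alignment implies shared exact seeds
        if _shared_kmers(s, lk) < 2:
            continue
        try:
            blk = align_pair_dp(s, longer, params)
        except Exception:
            blk = None
        if blk is None:
            continue
        if (
            blk.identity >= 100 * min_identity
            and (blk.query_end - blk.query_start) >= need
        ):
            return True
    return False


def cluster_redundant(
    nrs: list[NRSRecord],
    min_identity: float = 0.95,
    min_short_coverage: float = 0.8,
    params: AlignParams | None = None,
) -> list[Cluster]:
    """Greedy longest-first clustering with CD-HIT ``-c/-aS`` semantics.

    Sequences are visited by decreasing length (ties: lexicographic id); each
    joins the first cluster whose representative aligns to it at identity >=
    ``min_identity`` over >= ``min_short_coverage`` of the shorter sequence on
    either strand, else founds its own cluster.  Deterministic.
    """
    if not nrs:
        raise InputError("cluster_redundant requires at least one record")
    params = params or AlignParams()
    by_id = {r.nrs_id: r for r in nrs}
    order = sorted(nrs, key=lambda r: (-len(r.sequence), r.nrs_id))
    clusters: list[Cluster] = []
    kmer_cache: dict = {}
    for rec in order:
        placed = False
        for cl in clusters:
            rep = by_id[cl.representative]
            if _cluster_hit(
                rec.sequence, rep.sequence, min_identity, min_short_coverage,
                params, kmer_cache,
            ):
                cl.members.append(rec.nrs_id)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(representative=rec.nrs_id, members=[rec.nrs_id]))
    return clusters


def representatives(clusters: list[Cluster], nrs: list[NRSRecord]) -> list[NRSRecord]:
    by_id = {r.nrs_id: r for r in nrs}
    return [by_id[c.representative] for c in clusters]


# ---------------------------------------------------------------------------
# contamination screen
# ---------------------------------------------------------------------------

def screen_contamination(
    nrs: list[NRSRecord],
    decoy: dict[str, str],
    min_identity: float = 90.0,
    min_query_cov: float = 90.0,
    params: AlignParams | None = None,
) -> tuple[list[NRSRecord], list[NRSRecord]]:
    """Partition records into (kept, removed).

    A record is removed iff its best identity against the decoy set is >=
    ``min_identity`` AND its query coverage is >= ``min_query_cov`` — both
    thresholds must hold.
    """
    params = params or AlignParams()
    if not decoy:
        return list(nrs), []
    idx = KmerIndex(decoy, k=params.k, max_occ=params.max_occ)
    kept, removed = [], []
    for rec in nrs:
        blocks = local_align(rec.sequence, idx, params, query_id=rec.nrs_id)
        ident, cov = identity_and_coverage(blocks, len(rec.sequence)) if blocks else (0.0, 0.0)
        (removed if ident >= min_identity and cov >= min_query_cov else kept).append(rec)
    return kept, removed


# ---------------------------------------------------------------------------
# presence matrix
# ---------------------------------------------------------------------------

@dataclass
class PresenceMatrix:
    """Binary NRS x genome occurrence table with derived per-row flags.

    ``human_columns`` names the subset of columns counted for the
    major-allele rule; non-private counting pools humans and outgroups
    (the source assembly's own occurrence included).
    """

    table: pd.DataFrame  # bool, rows nrs_id, columns genome names
    human_columns: list[str]

    @property
    def occurrence_count(self) -> pd.Series:
        return self.table.sum(axis=1)

    @property
    def non_private(self) -> pd.Series:
        return self.occurrence_count >= 2

    @property
    def major_allele(self) -> pd.Series:
        human = self.table[self.human_columns]
        return human.sum(axis=1) > len(self.human_columns) / 2

    def to_frame(self) -> pd.DataFrame:
        df = self.table.astype(int).copy()
        df["occurrence_count"] = self.occurrence_count
        df["non_private"] = self.non_private.astype(int)
        df["major_allele"] = self.major_allele.astype(int)
        return df


def build_presence_matrix(
    nrs: list[NRSRecord],
    genomes: dict[str, dict[str, str]],
    human_names: list[str] | None = None,
    min_identity: float = 95.0,
    min_cov: float = 80.0,
    params: AlignParams | None = None,
) -> PresenceMatrix:
    """Presence of each NRS in each named genome (identity >= 95, coverage >= 80).

    The source assembly's cell is expected true (self-recovery); a warning is
    logged when it is not.
    """
    params = params or AlignParams()
    human_names = human_names if human_names is not None else list(genomes)
    indexes = {
        name: KmerIndex(g, k=params.k, max_occ=params.max_occ) for name, g in genomes.items()
    }
    data = {}
    for name, idx in indexes.items():
        col = []
        for rec in nrs:
            blocks = local_align(rec.sequence, idx, params, query_id=rec.nrs_id)
            ident, cov = identity_and_coverage(blocks, len(rec.sequence)) if blocks else (0.0, 0.0)
            col.append(ident >= min_identity and cov >= min_cov)
        data[name] = col
    table = pd.DataFrame(data, index=[r.nrs_id for r in nrs])
    for rec in nrs:
        if rec.source_assembly in table.columns and not table.loc[rec.nrs_id, rec.source_assembly]:
            logger.warning(
                "self-recovery failed: %s not recovered in its source assembly %s",
                rec.nrs_id, rec.source_assembly,
            )
    return PresenceMatrix(table=table, human_columns=[h for h in human_names if h in table.columns])


# ---------------------------------------------------------------------------
# novelty stratification
# ---------------------------------------------------------------------------

def novelty_stratify(
    nrs: list[NRSRecord],
    reference_index: KmerIndex,
    min_identity: float = 80.0,
    min_cov: float = 50.0,
    params: AlignParams | None = None,
) -> tuple[list[NRSRecord], list[NRSRecord]]:
    """Partition into (no_alignment_set, residual_set) against the reference.

    A record falls in the residual set when blocks of identity >=
    ``min_identity`` jointly cover >= ``min_cov`` percent of it; otherwise it
    has, per the published criteria, "no alignment" to the reference.
    """
    params = params or AlignParams()
    none_set, residual = [], []
    for rec in nrs:
        blocks = [
            b
            for b in local_align(rec.sequence, reference_index, params, query_id=rec.nrs_id)
            if b.identity >= min_identity
        ]
        cov = identity_and_coverage(blocks, len(rec.sequence))[1] if blocks else 0.0
        (residual if cov >= min_cov else none_set).append(rec)
    return none_set, residual


# ---------------------------------------------------------------------------
# reciprocal comparison
# ---------------------------------------------------------------------------

def reciprocal_intersect(
    set_a: dict[str, str],
    set_b: dict[str, str],
    min_identity: float = 95.0,
    min_query_cov: float = 80.0,
    params: AlignParams | None = None,
) -> list[str]:
    """Members of A shared with B under the reciprocal-hit strategy.

    A member of A is shared if it has a qualifying A->B hit, or if it is the
    best target of a qualifying B->A hit; the two directions are unioned.
    """
    params = params or AlignParams()
    shared: set[str] = set()
    if set_b:
        idx_b = KmerIndex(set_b, k=params.k, max_occ=params.max_occ)
        for name, seq in set_a.items():
            blocks = local_align(seq, idx_b, params, query_id=name)
            ident, cov = identity_and_coverage(blocks, len(seq)) if blocks else (0.0, 0.0)
            if ident >= min_identity and cov >= min_query_cov:
                shared.add(name)
    if set_a:
        idx_a = KmerIndex(set_a, k=params.k, max_occ=params.max_occ)
        for name, seq in set_b.items():
            blocks = local_align(seq, idx_a, params, query_id=name)
            if not blocks:
                continue
            ident, cov = identity_and_coverage(blocks, len(seq))
            if ident >= min_identity and cov >= min_query_cov:
                best = max(blocks, key=lambda b: b.score)
                shared.add(best.target_id)
    return sorted(shared)


# ---------------------------------------------------------------------------
# occurrence-matrix PCA
# ---------------------------------------------------------------------------

def pca_occurrence(
    matrix: PresenceMatrix | pd.DataFrame,
    columns: list[str] | None = None,
    n_components: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of an occurrence matrix: assemblies are observations, NRS features.

    Features (rows) are centered; coordinates are made deterministic by
    fixing each component's sign so its largest-magnitude loading is
    positive.  Returns (per-column PC coordinates, explained-variance
    fractions).
    """
    table = matrix.table if isinstance(matrix, PresenceMatrix) else matrix
    if columns is not None:
        table = table[columns]
    X = table.T.to_numpy(dtype=float)  # observations x features
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise DegenerateInputError("need >= 3 columns and >= 2 rows")
    if np.allclose(X.var(axis=0), 0):
        raise DegenerateInputError("occurrence matrix has zero variance")
    n_components = n_components or min(X.shape[0] - 1, X.shape[1], 10)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    for j in range(coords.shape[1]):
        loading = pca.components_[j]
        if loading[np.argmax(np.abs(loading))] < 0:
            coords[:, j] *= -1
            pca.components_[j] *= -1
    out = pd.DataFrame(
        coords,
        index=table.columns,
        columns=[f"PC{j + 1}" for j in range(coords.shape[1])],
    )
    return out, pca.explained_variance_ratio_
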