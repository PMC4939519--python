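"""Combinatorial-extension style pairwise structural alignment.

Two chains are aligned by finding aligned fragment pairs (AFPs) — fixed-length
windows whose internal CA-CA distance matrices agree — and chaining compatible
AFPs into the best sequential path by dynamic programming. The winning path
yields the residue correspondence; a single Kabsch superposition on the paired
CA atoms yields the rigid transform and RMSD.

Distance matrices are rotation- and translation-invariant, so AFP detection
and chaining are unaffected by the pose of either chain; only the final
superposition depends on coordinates.

The similarity score used to rank templates is

    score = (aligned_length / min(len_query, len_template)) * 1 / (1 + rmsd / r0)

with r0 = 3 A: length-normalized, bounded in [0, 1], equal to 1 exactly for a
full-length zero-RMSD alignment.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import Transform, kabsch_superpose
from .structure_io import ChainRecord

__all__ = [
    "AFP",
    "AlignmentResult",
    "AlignConfig",
    "find_afps",
    "extend_alignment",
    "align",
    "rank_templates",
]

SCORE_R0 = 3.0  # A; RMSD scale in the similarity score


@dataclass(frozen=True)
class AlignConfig:
    """CE-style aligner parameters (window length and distance cutoffs)."""

    afp_len: int = 8
    d_intra: float = 3.0   # A; mean |d_q - d_t| within a fragment pair
    d_join: float = 4.0    # A; mean |d_q - d_t| across two chained AFPs
    gap_max: int = 30      # residues; largest gap between consecutive AFPs
    max_afps: int = 5000   # cap on candidate AFPs (best kept by difference)


@dataclass(frozen=True)
class AFP:
    """An aligned fragment pair: windows starting at ``q_start``/``t_start``."""

    q_start: int
    t_start: int
    length: int
    diff: float = 0.0  # mean abs internal-distance difference

    @property
    def diagonal(self) -> int:
        return self.q_start - self.t_start


@dataclass(frozen=True)
class AlignmentResult:
    pairs: tuple[tuple[int, int], ...]
    transform: Transform          # maps template coordinates into query frame
    rmsd: float
    score: float

    @property
    def aligned_length(self) -> int:
        return len(self.pairs)

    @classmethod
    def empty(cls) -> "AlignmentResult":
        return cls(pairs=(), transform=Transform.identity(), rmsd=0.0, score=0.0)


def _window_distance_profiles(dmat: np.ndarray, length: int) -> np.ndarray:
    """Upper-triangle internal distances of every length-``length`` window."""
    n = dmat.shape[0] - length + 1
    iu, ju = np.triu_indices(length, k=1)
    out = np.empty((n, len(iu)))
    for s in range(n):
        out[s] = dmat[s + iu, s + ju]
    return out


def find_afps(query: ChainRecord, template: ChainRecord,
              cfg: AlignConfig = AlignConfig()) -> list[AFP]:
    """All window pairs whose internal CA distance matrices agree within
    ``cfg.d_intra`` (mean absolute difference over corresponding distances)."""
    qca, tca = query.ca_coords(), template.ca_coords()
    length = cfg.afp_len
    if len(qca) < length or len(tca) < length:
        return []
    dq = cdist(qca, qca)
    dt = cdist(tca, tca)
    qprof = _window_distance_profiles(dq, length)
    tprof = _window_distance_profiles(dt, length)
    # (nq, nt) matrix of mean |d_q - d_t|
    diffs = np.abs(qprof[:, None, :] - tprof[None, :, :]).mean(axis=2)
    qi, ti = np.nonzero(diffs <= cfg.d_intra)
    afps = [AFP(int(q), int(t), length, float(diffs[q, t])) for q, t in zip(qi, ti)]
    if len(afps) > cfg.max_afps:
        afps = sorted(afps, key=lambda a: (a.diff, a.q_start, a.t_start))[:cfg.max_afps]
    afps.sort(key=lambda a: (a.q_start, a.t_start))
    return afps


def _beam_prune(afps: list[AFP], beam: int) -> list[AFP]:
    """Keep at most ``beam`` best AFPs (smallest difference) per query start.

    A search heuristic only: it bounds the DP graph on dissimilar chain pairs,
    where thousands of incidental window matches would otherwise dominate the
    cost. Near-identical chains keep their (zero-difference) diagonal intact.
    """
    by_q: dict[int, list[AFP]] = {}
    for a in afps:
        by_q.setdefault(a.q_start, []).append(a)
    kept: list[AFP] = []
    for q in sorted(by_q):
        group = sorted(by_q[q], key=lambda a: (a.diff, a.t_start))[:beam]
        kept.extend(sorted(group, key=lambda a: a.t_start))
    return kept


def extend_alignment(afps: list[AFP], query: ChainRecord, template: ChainRecord,
                     cfg: AlignConfig = AlignConfig(), beam: int = 24) -> list[AFP]:
    """Best sequential chain of compatible AFPs, by dynamic programming.

    Maximizes the number of aligned residue pairs; ties broken by the smaller
    total internal-distance difference of the path's AFPs. Returns the AFPs of
    the winning path in order; empty input gives an empty path.
    """
    if not afps:
        return []
    afps = _beam_prune(afps, beam)
    length = cfg.afp_len
    qca, tca = query.ca_coords(), template.ca_coords()
    dq = cdist(qca, qca)
    dt = cdist(tca, tca)
    n = len(afps)
    qs = np.array([a.q_start for a in afps])
    ts = np.array([a.t_start for a in afps])
    diag = qs - ts
    diffs = np.array([a.diff for a in afps])
    pairs = np.full(n, length)          # best pair count of a path ending at i
    cost = diffs.copy()                 # tie-break: summed AFP differences
    prev = np.full(n, -1)
    win = np.arange(length)
    row = win[:, None]
    col = win[None, :]
    for j in range(n):
        # same-diagonal overlap/extension: shared pairs coincide, no join check
        ov = np.nonzero((diag == diag[j]) & (qs < qs[j]) & (qs > qs[j] - length))[0]
        gains = []
        cands = []
        if ov.size:
            cands.append(ov)
            gains.append(qs[j] - qs[ov])
        # disjoint predecessors within the gap bound: cross-fragment join check
        dis = np.nonzero((qs <= qs[j] - length) & (ts <= ts[j] - length) &
                         (qs >= qs[j] - length - cfg.gap_max) &
                         (ts >= ts[j] - length - cfg.gap_max))[0]
        if dis.size:
            cross_q = dq[qs[dis][:, None, None] + row, qs[j] + col]
            cross_t = dt[ts[dis][:, None, None] + row, ts[j] + col]
            join = np.abs(cross_q - cross_t).mean(axis=(1, 2))
            dis = dis[join <= cfg.d_join]
            if dis.size:
                cands.append(dis)
                gains.append(np.full(dis.size, length))
        if not cands:
            continue
        cand = np.concatenate(cands)
        gain = np.concatenate(gains)
        cand_pairs = pairs[cand] + gain
        cand_cost = cost[cand] + diffs[j]
        # lexicographic (max pairs, min cost): pairs are integers, costs bounded
        best = np.argmax(cand_pairs * 1e6 - cand_cost)
        if (cand_pairs[best], -cand_cost[best]) > (pairs[j], -cost[j]):
            pairs[j] = cand_pairs[best]
            cost[j] = cand_cost[best]
            prev[j] = cand[best]
    end = max(range(n), key=lambda i: (pairs[i], -cost[i]))
    path = []
    i = end
    while i != -1:
        path.append(afps[i])
        i = prev[i]
    path.reverse()
    return path


def path_pairs(path: list[AFP]) -> tuple[tuple[int, int], ...]:
    """Residue-index pairs covered by an AFP path (strictly monotone union)."""
    out: list[tuple[int, int]] = []
    for afp in path:
        for k in range(afp.length):
            pair = (afp.q_start + k, afp.t_start + k)
            if not out or (pair[0] > out[-1][0] and pair[1] > out[-1][1]):
                out.append(pair)
    return tuple(out)


def align(query: ChainRecord, template: ChainRecord,
          cfg: AlignConfig = AlignConfig()) -> AlignmentResult:
    """Align two chains; returns correspondence, template->query transform,
    CA RMSD over the aligned pairs, and the similarity score.

    A pair of chains with no acceptable AFP yields an empty result with
    score 0, signalling an unusable template.
    """
    afps = find_afps(query, template, cfg)
    if not afps:
        return AlignmentResult.empty()
    path = extend_alignment(afps, query, template, cfg)
    pairs = path_pairs(path)
    if len(pairs) < 3:
        return AlignmentResult.empty()
    qca, tca = query.ca_coords(), template.ca_coords()
    qsel = qca[[p[0] for p in pairs]]
    tsel = tca[[p[1] for p in pairs]]
    transform, rmsd = kabsch_superpose(tsel, qsel)
    coverage = len(pairs) / min(query.length, template.length)
    score = coverage / (1.0 + rmsd / SCORE_R0)
    return AlignmentResult(pairs=pairs, transform=transform, rmsd=rmsd,
                           score=float(score))


def rank_templates(results, k: int = 20):
    """Sort (template, alignment) pairs by score descending and keep the top k.

    Ties broken by lower RMSD, then lexicographic template identity, so the
    ranking is deterministic across runs.
    """
    ordered = sorted(
        results,
        key=lambda ta: (-ta[1].score, ta[1].rmsd, ta[0].key),
    )
    return ordered[:k]
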