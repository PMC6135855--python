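"""Candidate-reduction cascade: sequence, clustering, profile, clash.

The raw window search can return far more candidates than can be built
and scored, so four filters are applied in order:

1. BLOSUM62 similarity of the candidate loop sequence to the query loop
   sequence; negative total scores are discarded (zero is kept).
2. Hierarchical (complete-linkage) clustering on pairwise loop C-alpha
   RMSD at a 1 angstrom cutoff, with chunked iteration for very large
   candidate sets; one representative per cluster — the highest BLOSUM
   score — survives.
3. Structural-alphabet profile divergence: candidates whose average
   Jensen-Shannon divergence from the query profile exceeds 0.40 nats
   are discarded (0.40 itself is kept).
4. Steric clash: any loop C-alpha strictly closer than 3 angstroms to a
   scaffold C-alpha disqualifies the grafted model.

Each stage returns a subset of its input, so candidate counts are
non-increasing along the cascade.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .fragment_db import CandidateHit
from .sa_profiles import SAProfile, profile_jsd

__all__ = ["ClusterAssignment", "filter_sequence", "blosum_score",
           "cluster_candidates", "filter_profile", "detect_clashes",
           "ClashReport"]

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def blosum_score(a: str, b: str) -> int:
    """Positionwise BLOSUM62 score of two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return int(sum(_BLOSUM62[x, y] for x, y in zip(a, b)))


def filter_sequence(candidates: Sequence[CandidateHit],
                    loop_sequence: str) -> list[CandidateHit]:
    """Keep candidates whose loop scores non-negatively against the query."""
    kept = []
    for hit in candidates:
        hit.blosum_score = blosum_score(loop_sequence, hit.loop_sequence)
        if hit.blosum_score >= 0:
            kept.append(hit)
    return kept


@dataclasses.dataclass
class ClusterAssignment:
    labels: dict          # candidate key -> cluster id
    representatives: list  # one CandidateHit per cluster
    clusters: list         # list of lists of CandidateHit


def _rep_rank(hit: CandidateHit, order: dict) -> tuple:
    # highest BLOSUM first, then highest BC, then original source order
    return (-(hit.blosum_score or 0), -hit.bc, order[hit.key])


def _single_pass(cands: list[CandidateHit], cutoff: float,
                 method: str) -> list[list[CandidateHit]]:
    if len(cands) == 1:
        return [[cands[0]]]
    flat = np.stack([h.loop_ca().ravel() for h in cands])
    n_atoms = cands[0].loop_ca().shape[0]
    # pairwise RMSD in the shared query frame, no refit
    dists = pdist(flat) / np.sqrt(n_atoms)
    labels = fcluster(linkage(dists, method=method), t=cutoff,
                      criterion="distance")
    groups: dict[int, list[CandidateHit]] = {}
    for lab, hit in zip(labels, cands):
        groups.setdefault(lab, []).append(hit)
    return list(groups.values())


def cluster_candidates(candidates: Sequence[CandidateHit],
                       rmsd_cutoff: float = 1.0, chunk: int = 25_000,
                       method: str = "complete") -> ClusterAssignment:
    """Group near-identical loop conformations; keep one representative each.

    Pairwise distances are loop C-alpha RMSDs computed in the common
    query frame (the candidates are already superposed via their
    flanks).  When more than ``chunk`` candidates are present, clustering
    proceeds iteratively over consecutive chunks of that size, merging
    within-chunk clusters, until at most ``chunk`` clusters remain; a
    final full pass then merges across chunk boundaries.
    """
    candidates = list(candidates)
    order = {h.key: i for i, h in enumerate(candidates)}
    if not candidates:
        return ClusterAssignment(labels={}, representatives=[], clusters=[])

    clusters: list[list[CandidateHit]] = [[h] for h in candidates]
    while len(clusters) > chunk:
        reps = [min(c, key=lambda h: _rep_rank(h, order)) for c in clusters]
        merged: list[list[CandidateHit]] = []
        for lo in range(0, len(reps), chunk):
            sub = reps[lo:lo + chunk]
            for group in _single_pass(sub, rmsd_cutoff, method):
                members: list[CandidateHit] = []
                for rep in group:
                    members.extend(clusters[reps.index(rep)])
                merged.append(members)
        if len(merged) == len(clusters):
            clusters = merged
            break
        clusters = merged

    reps = [min(c, key=lambda h: _rep_rank(h, order)) for c in clusters]
    rep_to_members = {id(rep): clusters[i] for i, rep in enumerate(reps)}
    final: list[list[CandidateHit]] = []
    for group in _single_pass(reps, rmsd_cutoff, method):
        members: list[CandidateHit] = []
        for rep in group:
            members.extend(rep_to_members[id(rep)])
        final.append(members)

    final.sort(key=lambda ms: min(order[h.key] for h in ms))
    labels = {}
    representatives = []
    for cid, members in enumerate(final):
        rep = min(members, key=lambda h: _rep_rank(h, order))
        representatives.append(rep)
        for h in members:
            labels[h.key] = cid
    return ClusterAssignment(labels=labels, representatives=representatives,
                             clusters=final)


def filter_profile(candidates: Sequence[CandidateHit],
                   query_profile: SAProfile,
                   candidate_profiles: Sequence[SAProfile],
                   jsd_max: float = 0.40) -> list[CandidateHit]:
    """Keep candidates whose profile divergence does not exceed ``jsd_max``.

    The divergence is stored on each surviving hit; the comparison is
    strict (a candidate at exactly ``jsd_max`` is retained).
    """
    if len(candidates) != len(candidate_profiles):
        raise ValueError("one profile per candidate required")
    kept = []
    for hit, prof in zip(candidates, candidate_profiles):
        hit.jsd = profile_jsd(query_profile, prof)
        if hit.jsd <= jsd_max:
            kept.append(hit)
    return kept


@dataclasses.dataclass
class ClashReport:
    clash: bool
    pairs: list  # (loop residue index, scaffold residue index, distance)


def detect_clashes(ca_coords: np.ndarray, loop_range: tuple[int, int],
                   cutoff: float = 3.0) -> ClashReport:
    """Flag loop C-alphas strictly closer than ``cutoff`` to the scaffold.

    ``ca_coords`` is the (L, 3) C-alpha trace of the full grafted model;
    ``loop_range`` the 0-based half-open residue range of the loop.  A
    separation of exactly ``cutoff`` is not a clash.
    """
    ca_coords = np.asarray(ca_coords, dtype=float)
    start, stop = loop_range
    if not (0 <= start < stop <= ca_coords.shape[0]):
        raise ValueError(f"loop range {loop_range} outside structure")
    loop = ca_coords[start:stop]
    env_idx = np.r_[0:start, stop:ca_coords.shape[0]]
    if env_idx.size == 0:
        return ClashReport(clash=False, pairs=[])
    tree = cKDTree(ca_coords[env_idx])
    pairs = []
    for i, point in enumerate(loop):
        for j in tree.query_ball_point(point, cutoff):
            dist = float(np.linalg.norm(point - ca_coords[env_idx[j]]))
            if dist < cutoff:
                pairs.append((start + i, int(env_idx[j]), dist))
    return ClashReport(clash=bool(pairs), pairs=pairs)
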