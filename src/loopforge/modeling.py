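"""Model building, scoring, selection and the end-to-end pipeline.

Surviving candidates are grafted rigidly into the gapped template: the
superposition that mapped the candidate flanks onto the query flanks
carries the candidate loop main chain into the template frame, the loop
residues are renamed to the query loop sequence and renumbered
continuously into the gap.  Peptide-bond continuity at the two junctions
is reported as a quality flag, not enforced.

Each grafted model carries two scores: the profile divergence (JSD) from
the filtering stage and a distance-dependent statistical potential.  The
built-in potential is a simplified main-chain contact statistic trained
on the fragment database — deliberately not DOPE, whose parameter tables
are not public — and any external scorer can be plugged in through the
same callable interface.  The final set is the union of the five best
models by each score (at most 10 after deduplication), and the target's
prediction confidence is high when the lowest JSD among the final
candidates is at most 0.20 nats.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import filters, structure_io
from .config import SearchConfig
from .fragment_db import (CandidateHit, FragmentDB, LoopQuery,
                          bc_loop_search, exclude_homologs, make_query)
from .sa_profiles import SAAlphabet, SAProfile, default_alphabet, \
    encode_structure
from .structure_io import Chain, Residue

__all__ = ["GraftedModel", "RankedModel", "ConfidenceReport",
           "ContactPotential", "graft_candidate", "score_potential",
           "select_models", "confidence", "run_pipeline", "PipelineResult"]

#: junction C-N separation above which peptide continuity is flagged
JUNCTION_CN_MAX = 2.5


@dataclasses.dataclass(eq=False)
class GraftedModel:
    """A full-length model with the candidate loop spliced in."""

    chains: list
    chain_id: str
    loop_range: tuple  # 0-based half-open residue index range in the chain
    junction_cn: tuple  # (N-side C-N distance, C-side C-N distance)

    @property
    def continuous_junctions(self) -> bool:
        return all(d is not None and d < JUNCTION_CN_MAX
                   for d in self.junction_cn)

    def chain(self) -> Chain:
        return next(c for c in self.chains if c.id == self.chain_id)

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.chain().residues])

    def mainchain_coords(self) -> np.ndarray:
        return np.array([r.mainchain_array() for r in self.chain().residues])


@dataclasses.dataclass(eq=False)
class RankedModel:
    candidate: CandidateHit
    jsd: float
    potential: float
    selected_by: str  # "JSD", "potential" or "both"
    structure: GraftedModel | None = None


@dataclasses.dataclass
class ConfidenceReport:
    """min(JSD) over the final candidates; the per-target confidence index."""

    min_jsd: float | None
    high_confidence: bool
    n_candidates: int


def graft_candidate(template: Sequence[Chain], query: LoopQuery,
                    candidate: CandidateHit) -> GraftedModel:
    """Splice a candidate loop into the gapped template.

    The candidate's main-chain loop atoms (already in the query frame via
    the flank superposition) are inserted between the flanks, renamed to
    the query loop sequence and numbered ``gap_start..gap_end``.  Raises
    if the candidate loop is missing main-chain atoms.
    """
    if np.any(~np.isfinite(candidate.loop_mainchain)):
        raise ValueError("candidate loop is missing main-chain atoms")
    if candidate.loop_mainchain.shape[0] != query.loop_length:
        raise ValueError("candidate length does not match the gap")

    loop_residues = []
    for i, letter in enumerate(query.loop_sequence):
        mc = {a: candidate.loop_mainchain[i, j].copy()
              for j, a in enumerate(structure_io.MAINCHAIN_ATOMS)}
        loop_residues.append(Residue(name=structure_io.one_to_three(letter),
                                     num=query.gap_start + i,
                                     mainchain=mc, standard=True))

    new_chains = []
    loop_range = None
    for chain in template:
        if chain.id != query.chain_id:
            new_chains.append(Chain(id=chain.id,
                                    residues=list(chain.residues)))
            continue
        before = [r for r in chain.residues if r.num < query.gap_start]
        after = [r for r in chain.residues if r.num > query.gap_end]
        residues = before + loop_residues + after
        loop_range = (len(before), len(before) + len(loop_residues))
        new_chains.append(Chain(id=chain.id, residues=residues))
    if loop_range is None:
        raise ValueError(f"chain {query.chain_id!r} not in template")

    def cn_dist(res_c: Residue, res_n: Residue) -> float | None:
        c = res_c.mainchain.get("C")
        n = res_n.mainchain.get("N")
        if c is None or n is None:
            return None
        return float(np.linalg.norm(c - n))

    junction = (cn_dist(query.flank_n[-1], loop_residues[0]),
                cn_dist(loop_residues[-1], query.flank_c[0]))
    return GraftedModel(chains=new_chains, chain_id=query.chain_id,
                        loop_range=loop_range, junction_cn=junction)


class ContactPotential:
    """Distance-binned main-chain contact pseudo-energy.

    Pair distances between main-chain atoms of residues at sequence
    separation of at least two are histogrammed in 0.5 angstrom bins up
    to 10 angstroms over the fragment database; bin energies are
    ``-ln((observed + 1) / (expected + 1))`` against a distance-squared
    (volume-element) reference state scaled to the same total count.
    Scoring a model sums the bin energies over loop-vs-environment atom
    pairs.  Lower is better; the score is deterministic given the
    database.  This is a simplified contact statistic, not DOPE.
    """

    def __init__(self, bin_width: float = 0.5, r_max: float = 10.0,
                 min_separation: int = 2):
        self.bin_width = bin_width
        self.r_max = r_max
        self.min_separation = min_separation
        self.n_bins = int(round(r_max / bin_width))
        self.energies: np.ndarray | None = None

    def _pair_bins(self, mainchain: np.ndarray) -> np.ndarray:
        """Bin indices of qualifying atom pairs of one structure block."""
        n_res = mainchain.shape[0]
        coords = mainchain.reshape(-1, 3)
        res_idx = np.repeat(np.arange(n_res), mainchain.shape[1])
        valid = np.all(np.isfinite(coords), axis=1)
        coords, res_idx = coords[valid], res_idx[valid]
        tree = cKDTree(coords)
        out = []
        for i, j in tree.query_pairs(self.r_max):
            if abs(res_idx[i] - res_idx[j]) < self.min_separation:
                continue
            d = np.linalg.norm(coords[i] - coords[j])
            out.append(min(int(d / self.bin_width), self.n_bins - 1))
        return np.asarray(out, dtype=int)

    def train(self, db: FragmentDB) -> "ContactPotential":
        observed = np.zeros(self.n_bins)
        for seg in db.segments:
            bins = self._pair_bins(seg.mainchain_coords())
            if bins.size:
                observed += np.bincount(bins, minlength=self.n_bins)
        total = observed.sum()
        if total == 0:
            raise ValueError("no atom pairs found; cannot train potential")
        mids = (np.arange(self.n_bins) + 0.5) * self.bin_width
        reference = mids ** 2
        reference *= total / reference.sum()
        self.energies = -np.log((observed + 1.0) / (reference + 1.0))
        return self

    def __call__(self, model: GraftedModel,
                 loop_range: tuple[int, int] | None = None) -> float:
        if self.energies is None:
            raise RuntimeError("potential not trained")
        start, stop = loop_range or model.loop_range
        mainchain = model.mainchain_coords()
        n_res = mainchain.shape[0]
        if not (0 <= start < stop <= n_res):
            raise ValueError("loop range outside model")
        if start == 0 and stop == n_res:
            raise ValueError("empty environment; nothing to score against")
        coords = mainchain.reshape(-1, 3)
        n_atoms = mainchain.shape[1]
        res_idx = np.repeat(np.arange(n_res), n_atoms)
        in_loop = (res_idx >= start) & (res_idx < stop)
        tree = cKDTree(coords[~in_loop])
        env_res = res_idx[~in_loop]
        score = 0.0
        for i in np.flatnonzero(in_loop):
            for j in tree.query_ball_point(coords[i], self.r_max):
                if abs(res_idx[i] - env_res[j]) < self.min_separation:
                    continue
                d = np.linalg.norm(coords[i] - coords[~in_loop][j])
                score += self.energies[min(int(d / self.bin_width),
                                           self.n_bins - 1)]
        return float(score)


def score_potential(model: GraftedModel,
                    potential: Callable[[GraftedModel], float],
                    loop_range: tuple[int, int] | None = None) -> float:
    """Evaluate a (pluggable) statistical potential on a grafted model."""
    if loop_range is not None and isinstance(potential, ContactPotential):
        return potential(model, loop_range)
    return potential(model)


def select_models(candidates: Sequence[CandidateHit], k_each: int = 5,
                  models: dict | None = None) -> list[RankedModel]:
    """Union of the ``k_each`` best candidates by JSD and by potential.

    Both scores rank ascending (lower is better); ties are broken by the
    other score, then by provenance order.  A candidate in both top sets
    appears once with ``selected_by="both"``, so the output holds at most
    ``2 * k_each`` models.
    """
    cands = list(candidates)
    for h in cands:
        if h.jsd is None or h.potential is None:
            raise ValueError("candidates must carry jsd and potential scores")
    order = {h.key: i for i, h in enumerate(cands)}
    by_jsd = sorted(cands, key=lambda h: (h.jsd, h.potential,
                                          order[h.key]))[:k_each]
    by_pot = sorted(cands, key=lambda h: (h.potential, h.jsd,
                                          order[h.key]))[:k_each]
    jsd_keys = {h.key for h in by_jsd}
    pot_keys = {h.key for h in by_pot}
    selected = {h.key: h for h in by_jsd + by_pot}
    out = []
    for key, hit in selected.items():
        tag = "both" if key in jsd_keys and key in pot_keys else \
            "JSD" if key in jsd_keys else "potential"
        out.append(RankedModel(candidate=hit, jsd=hit.jsd,
                               potential=hit.potential, selected_by=tag,
                               structure=(models or {}).get(key)))
    out.sort(key=lambda m: (m.jsd, m.potential, order[m.candidate.key]))
    return out


def confidence(final_candidates: Sequence[CandidateHit],
               threshold: float = 0.20) -> ConfidenceReport:
    """min(JSD) confidence index; high iff the minimum is at most 0.20."""
    jsds = [h.jsd for h in final_candidates if h.jsd is not None]
    if not jsds:
        return ConfidenceReport(min_jsd=None, high_confidence=False,
                                n_candidates=0)
    m = min(jsds)
    return ConfidenceReport(min_jsd=m, high_confidence=m <= threshold,
                            n_candidates=len(jsds))


@dataclasses.dataclass
class PipelineResult:
    models: list
    confidence: ConfidenceReport
    stages: dict  # stage name -> candidate count, in cascade order
    query: LoopQuery


def _candidate_profile(hit: CandidateHit, alphabet: SAAlphabet,
                       flank_size: int, pseudocount: float) -> SAProfile:
    # encode the flank+loop+flank window so junction geometry informs the
    # loop rows, then keep the loop positions only
    prof = encode_structure(hit.window_ca_source, alphabet, pseudocount)
    return prof[flank_size:flank_size + len(hit.loop_sequence)]


def _grafted_context_profile(query: LoopQuery, hit: CandidateHit,
                             alphabet: SAAlphabet, pseudocount: float
                             ) -> SAProfile:
    flank_n = np.array([r.ca for r in query.flank_n])
    flank_c = np.array([r.ca for r in query.flank_c])
    region = np.concatenate([flank_n, hit.loop_ca(), flank_c])
    prof = encode_structure(region, alphabet, pseudocount)
    return prof[query.flank_size:query.flank_size + query.loop_length]


def run_pipeline(template: Sequence[Chain], loop_spec, db: FragmentDB,
                 config: SearchConfig | None = None,
                 query_profile: SAProfile | None = None,
                 alphabet: SAAlphabet | None = None,
                 scorer: Callable[[GraftedModel], float] | None = None,
                 refine: Callable[[GraftedModel], GraftedModel] | None = None,
                 seed: int = 0) -> PipelineResult:
    """Run search, the filter cascade, grafting, scoring and selection.

    ``loop_spec`` is either a :class:`LoopQuery` or a tuple
    ``(chain_id, gap_start, gap_end, loop_sequence)`` in author
    numbering.  When no ``query_profile`` is supplied, the query-side
    profile is derived from the best-scoring candidate's loop grafted
    between the template flanks (a structure-derived stand-in for a
    sequence-predicted profile).  ``scorer`` defaults to a
    :class:`ContactPotential` trained on the database; ``refine`` is an
    optional hook applied to each grafted model before clash testing.
    An empty candidate set at any stage yields an empty, low-confidence
    result rather than an error.
    """
    config = config or SearchConfig()
    if isinstance(loop_spec, LoopQuery):
        query = loop_spec
    else:
        chain_id, gap_start, gap_end, loop_sequence = loop_spec
        query = make_query(template, chain_id, gap_start, gap_end,
                           loop_sequence, flank_size=config.flank_size)
    stages: dict[str, int] = {}

    # target sequence = template chain sequence with the loop restored
    chain = next(c for c in template if c.id == query.chain_id)
    target_seq = ("".join(r.letter for r in chain.residues
                          if r.standard and r.num < query.gap_start)
                  + query.loop_sequence
                  + "".join(r.letter for r in chain.residues
                            if r.standard and r.num > query.gap_end))
    searchable = exclude_homologs(db, target_seq,
                                  identity_max=config.homolog_identity_max)

    hits = bc_loop_search(query, searchable, config)
    stages["search"] = len(hits)

    hits = filters.filter_sequence(hits, query.loop_sequence)
    stages["sequence"] = len(hits)

    if hits:
        assignment = filters.cluster_candidates(
            hits, rmsd_cutoff=config.cluster_rmsd,
            chunk=config.cluster_chunk, method=config.cluster_linkage)
        hits = assignment.representatives
    stages["cluster"] = len(hits)

    if hits:
        if alphabet is None:
            alphabet = default_alphabet()
        if query_profile is None:
            best = min(hits, key=lambda h: -h.bc)
            query_profile = _grafted_context_profile(
                query, best, alphabet, config.pseudocount)
        cand_profiles = [_candidate_profile(h, alphabet, config.flank_size,
                                            config.pseudocount)
                         for h in hits]
        hits = filters.filter_profile(hits, query_profile, cand_profiles,
                                      jsd_max=config.jsd_max)
    stages["profile"] = len(hits)

    grafted: dict[tuple, GraftedModel] = {}
    survivors = []
    for hit in hits:
        model = graft_candidate(template, query, hit)
        if refine is not None:
            model = refine(model)
        report = filters.detect_clashes(model.ca_coords(), model.loop_range,
                                        cutoff=config.clash_cutoff)
        if report.clash:
            continue
        grafted[hit.key] = model
        survivors.append(hit)
    hits = survivors
    stages["clash"] = len(hits)

    if hits:
        if scorer is None:
            scorer = ContactPotential().train(db)
        for hit in hits:
            hit.potential = score_potential(grafted[hit.key], scorer)
    models = select_models(hits, models=grafted) if hits else []
    stages["selected"] = len(models)

    return PipelineResult(models=models,
                          confidence=confidence(
                              hits, threshold=config.confidence_jsd),
                          stages=stages, query=query)
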