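"""Fragment database construction and flank-anchored loop search.

The database is the set of gap-free chain segments extracted from a
directory of PDB files.  A gap in a template is described by a
:class:`LoopQuery` — the missing-loop length and sequence plus the
``flank_size`` residues on each side of the gap.  The search slides a
window of ``flank + loop + flank`` residues over every segment and keeps
candidates whose flank C-alpha geometry matches the query flanks under
three cutoffs: Binet-Cauchy kernel score (length-dependent minimum),
Rigidity score and post-superposition flank RMSD.

Before searching, chains with high global sequence identity to the target
(default above 70%) are excluded so recovery cannot come from trivial
homologs.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from . import geometry, structure_io
from .config import SearchConfig
from .structure_io import Chain, ChainSegment, Residue

log = logging.getLogger(__name__)

__all__ = ["FragmentDB", "LoopQuery", "CandidateHit", "build_database",
           "exclude_homologs", "bc_loop_search", "make_query",
           "sequence_identity"]


@dataclasses.dataclass
class LoopQuery:
    """A gap in a template: flanks, loop length and loop sequence."""

    chain_id: str
    gap_start: int
    gap_end: int
    loop_sequence: str
    flank_n: list
    flank_c: list
    template: list | None = None

    def __post_init__(self) -> None:
        if self.loop_length < 1:
            raise ValueError("loop length must be at least 1")
        if len(self.flank_n) != len(self.flank_c):
            raise ValueError("flanks must have equal size")

    @property
    def loop_length(self) -> int:
        return len(self.loop_sequence)

    @property
    def flank_size(self) -> int:
        return len(self.flank_n)

    def flank_ca(self) -> np.ndarray:
        """(2 * flank_size, 3) concatenated C-alpha matrix, N then C flank."""
        return np.array([r.ca for r in self.flank_n + self.flank_c])


@dataclasses.dataclass(eq=False)
class CandidateHit:
    """A database window whose flanks match a query gap."""

    source_id: str
    segment_index: int
    offset: int
    bc: float
    rigidity: float
    flank_rmsd: float
    transform: geometry.SuperpositionResult
    loop_sequence: str
    loop_mainchain: np.ndarray   # (L, 4, 3) in the query frame
    window_ca_source: np.ndarray  # (2F + L, 3), source frame
    blosum_score: int | None = None
    jsd: float | None = None
    potential: float | None = None

    @property
    def key(self) -> tuple:
        return (self.source_id, self.segment_index, self.offset)

    def loop_ca(self) -> np.ndarray:
        return self.loop_mainchain[:, 1, :]


class FragmentDB:
    """Segments plus per-chain sequences for homolog exclusion."""

    def __init__(self, segments: Sequence[ChainSegment],
                 chain_sequences: dict[str, str]):
        self.segments = sorted(
            segments, key=lambda s: (s.source_id, s.residues[0].num,
                                     s.residues[0].icode))
        self.chain_sequences = dict(chain_sequences)

    def __len__(self) -> int:
        return len(self.segments)

    def subset(self, keep_chains: Iterable[str]) -> "FragmentDB":
        keep = set(keep_chains)
        return FragmentDB(
            [s for s in self.segments if s.source_id in keep],
            {c: s for c, s in self.chain_sequences.items() if c in keep})

    # -- plain-text index + packed coordinates on disk -------------------
    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        lines = []
        blocks = []
        for seg in self.segments:
            lines.append(f"{seg.source_id}\t{seg.residues[0].num}\t"
                         f"{len(seg)}\t{seg.sequence}")
            blocks.append(seg.mainchain_coords())
        (out / "index.tsv").write_text("\n".join(lines) + "\n" if lines else "")
        np.save(out / "coords.npy",
                np.concatenate(blocks) if blocks else np.empty((0, 4, 3)))
        (out / "chains.tsv").write_text("".join(
            f"{c}\t{s}\n" for c, s in sorted(self.chain_sequences.items())))

    @classmethod
    def load(cls, db_dir: str | Path) -> "FragmentDB":
        db = Path(db_dir)
        coords = np.load(db / "coords.npy")
        segments = []
        pos = 0
        index_text = (db / "index.tsv").read_text()
        for line in index_text.splitlines():
            source_id, start, length, seq = line.split("\t")
            start, length = int(start), int(length)
            residues = []
            for i, letter in enumerate(seq):
                block = coords[pos + i]
                mc = {a: block[j] for j, a in
                      enumerate(structure_io.MAINCHAIN_ATOMS)
                      if np.all(np.isfinite(block[j]))}
                residues.append(Residue(
                    name=structure_io.one_to_three(letter) if letter != "X"
                    else "UNK", num=start + i, mainchain=mc, standard=True))
            pos += length
            segments.append(ChainSegment(source_id=source_id,
                                         residues=residues))
        chains = {}
        for line in (db / "chains.tsv").read_text().splitlines():
            cid, seq = line.split("\t")
            chains[cid] = seq
        return cls(segments, chains)


def build_database(pdb_dir: str | Path,
                   config: SearchConfig | None = None) -> FragmentDB:
    """Segment every chain of every PDB file in a directory.

    Segment ordering is deterministic (lexicographic by source id, then
    position), so two builds of the same directory are identical
    regardless of filesystem order.  Unreadable files are skipped with a
    warning; an empty directory is an error.
    """
    config = config or SearchConfig()
    paths = sorted(p for p in Path(pdb_dir).iterdir()
                   if p.suffix.lower() in (".pdb", ".ent"))
    if not paths:
        raise ValueError(f"no PDB files found in {pdb_dir}")
    segments: list[ChainSegment] = []
    chain_sequences: dict[str, str] = {}
    for path in paths:
        try:
            chains = structure_io.read_structure_file(path)
        except (structure_io.FormatError, OSError) as exc:
            log.warning("skipping unreadable file %s: %s", path.name, exc)
            continue
        for chain in chains:
            source_id = f"{path.stem}_{chain.id}"
            chain_sequences[source_id] = "".join(
                r.letter for r in chain.residues if r.standard)
            segments.extend(structure_io.segment_chain(
                chain.residues, min_length=config.min_segment_length,
                source_id=source_id))
    return FragmentDB(segments, chain_sequences)


def _blosum_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def sequence_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches over alignment length.

    Needleman-Wunsch with BLOSUM62, gap open 11 / extend 1.
    """
    if not a or not b:
        return 0.0
    aln = _blosum_aligner().align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def exclude_homologs(db: FragmentDB, target_sequence: str,
                     identity_max: float = 0.70) -> FragmentDB:
    """Drop chains whose identity to the target exceeds ``identity_max``."""
    if not target_sequence:
        raise ValueError("target sequence must be non-empty")
    keep = [cid for cid, seq in db.chain_sequences.items()
            if sequence_identity(seq, target_sequence) <= identity_max]
    dropped = len(db.chain_sequences) - len(keep)
    if dropped:
        log.info("homolog exclusion removed %d of %d chains", dropped,
                 len(db.chain_sequences))
    return db.subset(keep)


def make_query(template: list[Chain], chain_id: str, gap_start: int,
               gap_end: int, loop_sequence: str,
               flank_size: int = 4) -> LoopQuery:
    """Build a query from a gapped template and the missing-residue range.

    ``gap_start``..``gap_end`` is the inclusive author-numbering range of
    the residues absent from the template.  The flanks are the
    ``flank_size`` residues immediately adjacent to the gap; if the
    template does not provide them with C-alpha coordinates, the query is
    rejected rather than silently shrinking the flanks.
    """
    if len(loop_sequence) != gap_end - gap_start + 1:
        raise ValueError("loop sequence length does not match the gap range")
    chain = next((c for c in template if c.id == chain_id), None)
    if chain is None:
        raise ValueError(f"chain {chain_id!r} not in template")
    nums = [r.num for r in chain.residues]
    if any(gap_start <= n <= gap_end for n in nums):
        raise ValueError("gap range overlaps residues present in template")
    before = [r for r in chain.residues if r.num < gap_start]
    after = [r for r in chain.residues if r.num > gap_end]
    flank_n = before[-flank_size:]
    flank_c = after[:flank_size]
    if len(flank_n) < flank_size or len(flank_c) < flank_size:
        raise ValueError("template lacks a full flank on one side of the gap")
    if flank_n[-1].num != gap_start - 1 or flank_c[0].num != gap_end + 1:
        raise ValueError("flanks are not contiguous with the gap")
    if any(r.ca is None for r in flank_n + flank_c):
        raise ValueError("flank residue without a C-alpha coordinate")
    return LoopQuery(chain_id=chain_id, gap_start=gap_start, gap_end=gap_end,
                     loop_sequence=loop_sequence, flank_n=flank_n,
                     flank_c=flank_c, template=template)


def bc_loop_search(query: LoopQuery, db: FragmentDB,
                   config: SearchConfig | None = None) -> list[CandidateHit]:
    """All database windows whose flanks match the query gap.

    For every window of ``flank + loop_length + flank`` residues in every
    segment, the concatenated flank C-alphas are compared with the query
    flanks; the window survives iff the kernel score reaches the
    length-dependent minimum, the Rigidity score is at most
    ``rigidity_max`` and the flank C-alpha RMSD after optimal
    superposition is at most ``flank_rmsd_max``.  Hits are sorted by
    descending kernel score, ties by source id then offset.
    """
    config = config or SearchConfig()
    fs = config.flank_size
    length = query.loop_length
    if length < 1:
        raise ValueError("loop length must be at least 1")
    if query.flank_size != fs:
        raise ValueError(f"query flank size {query.flank_size} differs from "
                         f"configured flank size {fs}")
    bc_min = config.bc_min(length)
    window = 2 * fs + length
    x = query.flank_ca()
    x_end = float(np.linalg.norm(x[-1] - x[0]))
    hits: list[CandidateHit] = []
    for seg_idx, seg in enumerate(db.segments):
        if len(seg) < window:
            continue
        ca = seg.ca_coords()
        mainchain = seg.mainchain_coords()
        for off in range(len(seg) - window + 1):
            y = np.concatenate([ca[off:off + fs],
                                ca[off + fs + length:off + window]])
            if config.prefilter:
                # |end-to-end difference| is a lower bound on the Rigidity
                # score, so this prune is exact
                y_end = float(np.linalg.norm(y[-1] - y[0]))
                if abs(x_end - y_end) > config.rigidity_max:
                    continue
            try:
                bc = geometry.bc_kernel(x, y)
            except geometry.DegenerateFragmentError:
                continue
            if bc < bc_min:
                continue
            rig = geometry.rigidity(x, y, mode=config.rigidity_mode)
            if rig > config.rigidity_max:
                continue
            fit = geometry.superimpose(x, y)
            if fit.rmsd > config.flank_rmsd_max:
                continue
            loop_mc = mainchain[off + fs:off + fs + length]
            loop_query_frame = fit.apply(loop_mc.reshape(-1, 3)) \
                .reshape(loop_mc.shape)
            hits.append(CandidateHit(
                source_id=seg.source_id,
                segment_index=seg_idx,
                offset=off,
                bc=bc,
                rigidity=rig,
                flank_rmsd=fit.rmsd,
                transform=fit,
                loop_sequence=seg.sequence[off + fs:off + fs + length],
                loop_mainchain=loop_query_frame,
                window_ca_source=ca[off:off + window].copy(),
            ))
    hits.sort(key=lambda h: (-h.bc, h.source_id, h.segment_index, h.offset))
    return hits
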