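"""Search and filtering configuration.

All thresholds of the loop-candidate pipeline live in one dataclass so the
whole cascade can be tuned from a single ``key=value`` config file.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path


@dataclasses.dataclass
class SearchConfig:
    """Cutoffs governing fragment search, filtering and model selection.

    Parameters
    ----------
    flank_size : int
        Residues per flank anchoring the gap (each side).
    bc_min_short, bc_min_long : float
        Minimum Binet-Cauchy kernel score for loops of at most 8 residues
        and for longer loops, respectively.
    rigidity_max : float
        Maximum Rigidity score in angstroms.
    flank_rmsd_max : float
        Maximum post-superposition flank C-alpha RMSD in angstroms.
    homolog_identity_max : float
        Chains with global sequence identity to the target above this
        fraction are excluded from the searchable database.
    cluster_rmsd : float
        Hierarchical-clustering cutoff on pairwise loop C-alpha RMSD.
    cluster_chunk : int
        Chunk size for iterative clustering of very large candidate sets.
    jsd_max : float
        Candidates whose profile divergence exceeds this (nats) are dropped.
    clash_cutoff : float
        Loop-vs-scaffold C-alpha distance below which a model clashes.
    confidence_jsd : float
        min(JSD) at or below this marks a target as high confidence.
    rigidity_mode : str
        ``"text"`` (default) compares distances to the respective geometric
        centers, which is invariant to rigid motion; ``"printed"`` compares
        paired coordinates directly in the lab frame.
    prefilter : bool
        Prune windows with an end-to-end anchor-distance test before the
        kernel evaluation (a necessary condition of the rigidity score,
        so it never changes the result in ``"text"`` mode).
    """

    flank_size: int = 4
    bc_min_short: float = 0.9
    bc_min_long: float = 0.8
    loop_length_short_max: int = 8
    rigidity_max: float = 3.0
    flank_rmsd_max: float = 4.0
    homolog_identity_max: float = 0.70
    cluster_rmsd: float = 1.0
    cluster_chunk: int = 25_000
    cluster_linkage: str = "complete"
    jsd_max: float = 0.40
    clash_cutoff: float = 3.0
    confidence_jsd: float = 0.20
    rigidity_mode: str = "text"
    prefilter: bool = True
    pseudocount: float = 1e-4

    def __post_init__(self) -> None:
        if not (0 < self.bc_min_short <= 1 and 0 < self.bc_min_long <= 1):
            raise ValueError("BC cutoffs must lie in (0, 1]")
        for name in ("rigidity_max", "flank_rmsd_max", "cluster_rmsd",
                     "jsd_max", "clash_cutoff", "confidence_jsd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.flank_size < 1:
            raise ValueError("flank_size must be at least 1")
        if self.rigidity_mode not in ("text", "printed"):
            raise ValueError("rigidity_mode must be 'text' or 'printed'")

    def bc_min(self, loop_length: int) -> float:
        """Length-dependent kernel cutoff: stricter for short loops."""
        if loop_length <= self.loop_length_short_max:
            return self.bc_min_short
        return self.bc_min_long

    @property
    def min_segment_length(self) -> int:
        """Shortest segment worth keeping in the database (flank + 1)."""
        return self.flank_size + 1

    @classmethod
    def from_file(cls, path: str | Path) -> "SearchConfig":
        """Load ``key = value`` overrides from a plain-text config file."""
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if key not in fields:
                raise KeyError(f"unknown config key: {key}")
            default = getattr(cls(), key)
            if isinstance(default, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                kwargs[key] = int(value)
            elif isinstance(default, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)
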