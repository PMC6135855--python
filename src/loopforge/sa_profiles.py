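"""Structural-alphabet encoding and profile divergence.

A fragment's local backbone conformation is summarized by sliding a
4-residue window along its C-alpha trace and describing each window by
four rigid-motion-invariant numbers: the three non-consecutive inter
C-alpha distances d(1,3), d(1,4), d(2,4) in angstroms and the signed
tetrahedral volume in cubic angstroms (the sign encodes chirality).
Windows are assigned to the nearest of 27 prototype descriptors — the
structural alphabet — and a fragment becomes an L x 27 profile of
per-position letter probabilities.

Two profiles are compared by the average positionwise Jensen-Shannon
divergence (natural log, so values are in nats and bounded by ln 2);
0 means identical local-conformation profiles.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy.cluster.vq import kmeans2
from scipy.spatial.distance import cdist

N_LETTERS = 27
WINDOW = 4

__all__ = [
    "SAAlphabet", "SAProfile", "window_descriptors", "train_alphabet",
    "encode_structure", "js_divergence", "profile_jsd",
]


def window_descriptors(ca: np.ndarray) -> np.ndarray:
    """Descriptors of every overlapping 4-residue window of a C-alpha trace.

    Returns an (L-3, 4) array: d(1,3), d(1,4), d(2,4) and the signed
    volume of the tetrahedron spanned by the four positions.
    """
    ca = np.asarray(ca, dtype=float)
    if ca.ndim != 2 or ca.shape[1] != 3:
        raise ValueError("expected an L x 3 C-alpha array")
    if ca.shape[0] < WINDOW:
        raise ValueError(f"need at least {WINDOW} residues")
    p1, p2, p3, p4 = (ca[i:ca.shape[0] - WINDOW + 1 + i] for i in range(4))
    d13 = np.linalg.norm(p3 - p1, axis=1)
    d14 = np.linalg.norm(p4 - p1, axis=1)
    d24 = np.linalg.norm(p4 - p2, axis=1)
    vol = np.einsum("ij,ij->i", np.cross(p2 - p1, p3 - p1), p4 - p1) / 6.0
    return np.column_stack([d13, d14, d24, vol])


@dataclasses.dataclass
class SAAlphabet:
    """27 prototype window descriptors defining the structural alphabet."""

    prototypes: np.ndarray
    seed: int | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.prototypes = np.asarray(self.prototypes, dtype=float)
        if self.prototypes.shape != (N_LETTERS, 4):
            raise ValueError(f"expected {N_LETTERS} x 4 prototypes, got "
                             f"{self.prototypes.shape}")
        if not np.all(np.isfinite(self.prototypes)):
            raise ValueError("prototypes must be finite")

    def assign(self, descriptors: np.ndarray) -> np.ndarray:
        """Nearest-prototype letter index for each descriptor row."""
        d = cdist(np.atleast_2d(descriptors), self.prototypes)
        return np.argmin(d, axis=1)

    def save(self, path: str | Path) -> None:
        header = f"structural alphabet: {N_LETTERS} letters x 4 descriptors" \
                 f" (d13 d14 d24 volume); source={self.source!r}"
        np.savetxt(path, self.prototypes, header=header)

    @classmethod
    def load(cls, path: str | Path) -> "SAAlphabet":
        return cls(prototypes=np.loadtxt(path), source=str(path))


def default_alphabet() -> SAAlphabet:
    """The alphabet shipped with the package.

    Trained once by k-means on the 4-residue windows of a large batch of
    synthetic helix-loop-helix structures (see the fixtures module); a
    synthetic stand-in for published structural alphabets, which users
    can substitute via :meth:`SAAlphabet.load`.
    """
    path = Path(__file__).parent / "data" / "default_alphabet_synthetic.txt"
    return SAAlphabet.load(path)


def train_alphabet(fragments: list[np.ndarray], k: int = N_LETTERS,
                   seed: int = 0) -> SAAlphabet:
    """K-means an alphabet from the 4-residue windows of C-alpha traces.

    Prototypes are sorted canonically (by d(1,4), then signed volume) so
    the letter indexing is reproducible across runs and platforms.
    Raises if the pooled windows are too few or too degenerate to support
    ``k`` distinct clusters.
    """
    desc = np.vstack([window_descriptors(f) for f in fragments])
    if desc.shape[0] < k * 10:
        raise ValueError(f"need at least {k * 10} windows to train "
                         f"{k} letters, got {desc.shape[0]}")
    distinct = np.unique(np.round(desc, 6), axis=0)
    if distinct.shape[0] < k:
        raise ValueError(f"only {distinct.shape[0]} distinct window "
                         f"descriptors; cannot form {k} clusters")
    rng = np.random.default_rng(seed)
    centroids, _ = kmeans2(desc, k, minit="++", seed=rng, iter=50)
    order = np.lexsort((centroids[:, 3], centroids[:, 1]))
    return SAAlphabet(prototypes=centroids[order], seed=seed,
                      source=f"kmeans on {desc.shape[0]} windows")


@dataclasses.dataclass
class SAProfile:
    """L x 27 per-residue letter-probability matrix."""

    rows: np.ndarray

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 2 or self.rows.shape[1] != N_LETTERS:
            raise ValueError(f"expected L x {N_LETTERS} matrix")
        if np.any(self.rows <= 0):
            raise ValueError("profile entries must be strictly positive "
                             "(apply a pseudocount)")
        if not np.allclose(self.rows.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("profile rows must sum to 1")

    def __len__(self) -> int:
        return self.rows.shape[0]

    def __getitem__(self, idx) -> "SAProfile":
        return SAProfile(rows=np.atleast_2d(self.rows[idx]))

    def save(self, path: str | Path, name: str = "") -> None:
        np.savetxt(path, self.rows,
                   header=f"chain {name}: {len(self)} positions x "
                          f"{N_LETTERS} letters")

    @classmethod
    def load(cls, path: str | Path) -> "SAProfile":
        return cls(rows=np.loadtxt(path))


def encode_structure(ca: np.ndarray, alphabet: SAAlphabet,
                     pseudocount: float = 1e-4) -> SAProfile:
    """Pseudocount-smoothed one-hot profile of a C-alpha trace.

    Window w covers residues w..w+3 and its letter is attributed to the
    residue it starts at; the trailing three residues inherit the last
    window's letter.  Each row is the letter's one-hot vector smoothed
    with ``pseudocount`` per letter and renormalized, so every entry is
    strictly positive and the Kullback-Leibler terms stay finite.
    """
    ca = np.asarray(ca, dtype=float)
    letters = alphabet.assign(window_descriptors(ca))
    n = ca.shape[0]
    per_residue = np.concatenate([letters, np.repeat(letters[-1], WINDOW - 1)])
    rows = np.full((n, N_LETTERS), pseudocount)
    rows[np.arange(n), per_residue[:n]] += 1.0
    rows /= rows.sum(axis=1, keepdims=True)
    return SAProfile(rows=rows)


def _check_distribution(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("distribution entries must be non-negative")
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("distribution must sum to 1")
    return p


def _kl_to_mixture(p: np.ndarray, m: np.ndarray) -> float:
    # 0 log 0 = 0 convention; m > 0 wherever p > 0 since m >= p/2
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / m[mask])))


def js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence in nats: 0 for identity, at most ln 2."""
    p = _check_distribution(p)
    q = _check_distribution(q)
    if p.shape != q.shape:
        raise ValueError("distributions must have equal length")
    m = 0.5 * (p + q)
    return 0.5 * _kl_to_mixture(p, m) + 0.5 * _kl_to_mixture(q, m)


def profile_jsd(p: SAProfile, q: SAProfile) -> float:
    """Average positionwise Jensen-Shannon divergence of two profiles."""
    if len(p) != len(q):
        raise ValueError(f"profile lengths differ: {len(p)} vs {len(q)}")
    pm = p.rows
    qm = q.rows
    m = 0.5 * (pm + qm)
    js = 0.5 * np.sum(pm * np.log(pm / m), axis=1) \
        + 0.5 * np.sum(qm * np.log(qm / m), axis=1)
    return float(np.mean(js))
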