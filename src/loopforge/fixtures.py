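"""Synthetic structure generation for testing the whole pipeline.

Real benchmark sets (homology models with crystal-structure references)
cannot ship with the package, so every stage is exercised on synthetic
helix-loop-helix structures: two ideal alpha-helical flanking segments
joined by a seeded self-avoiding random-walk loop, with full (synthetic)
main-chain atoms placed from the C-alpha trace.

A planted-loop database contains the *donor* — the target's own
coordinates under a mutated sequence, so homolog exclusion keeps it —
plus decoy chains whose C-alpha traces are planar zig-zags: any flank
window drawn from them is rank-deficient, so by construction decoys can
never match a three-dimensional query.  Deleting the loop from the
target and searching such a database must recover the donor fragment
exactly; adding Gaussian noise to the template emulates the flank error
of a homology model.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from . import structure_io
from .structure_io import Chain, Residue

__all__ = ["HLHTarget", "FixtureSpec", "make_helix_loop_helix",
           "make_planted_db", "perturb_template", "generate_fixture_set"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# ideal alpha-helix C-alpha parameters: 2.3 A radius, 1.5 A rise,
# 100 degrees per residue -> consecutive C-alpha distance ~3.83 A
_HELIX_RADIUS = 2.3
_HELIX_RISE = 1.5
_HELIX_TURN = np.deg2rad(100.0)

#: closest approach allowed between non-adjacent C-alphas of a fixture
_SELF_AVOID = 3.5


def _helix_ca(n: int) -> np.ndarray:
    t = np.arange(n)
    return np.column_stack([_HELIX_RADIUS * np.cos(_HELIX_TURN * t),
                            _HELIX_RADIUS * np.sin(_HELIX_TURN * t),
                            _HELIX_RISE * t])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _clear(point: np.ndarray, existing: np.ndarray, skip_last: int) -> bool:
    others = existing[:-skip_last] if skip_last else existing
    if others.size == 0:
        return True
    return bool(np.min(np.linalg.norm(others - point, axis=1)) >= _SELF_AVOID)


def _walk_loop(start: np.ndarray, prev: np.ndarray, length: int,
               existing: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding random walk of C-alpha steps in [3.7, 3.9] angstroms."""
    points = []
    trace = existing
    pos = start
    for _ in range(length):
        for attempt in range(200):
            direction = rng.normal(size=3)
            if attempt >= 100:
                # escape crowded regions by walking away from the centroid
                direction += 2.0 * (pos - trace.mean(axis=0)) / \
                    max(np.linalg.norm(pos - trace.mean(axis=0)), 1e-9)
            direction /= np.linalg.norm(direction)
            step = rng.uniform(3.7, 3.9)
            cand = pos + step * direction
            if _clear(cand, trace, skip_last=1):
                break
        points.append(cand)
        trace = np.vstack([trace, cand])
        pos = cand
    return np.array(points)


def _place_second_helix(n: int, loop_end: np.ndarray, existing: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    local = _helix_ca(n)
    for _ in range(500):
        rot = _random_rotation(rng)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        start = loop_end + rng.uniform(3.7, 3.9) * direction
        coords = (local - local[0]) @ rot.T + start
        combined = np.vstack([existing, coords])
        d = np.linalg.norm(combined[:, None] - combined[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        off = np.abs(np.arange(len(combined))[:, None]
                     - np.arange(len(combined))[None]) > 1
        if np.min(np.where(off, d, np.inf)) >= _SELF_AVOID:
            return coords
    raise RuntimeError("could not place second helix without self-collision")


def mainchain_from_ca(ca: np.ndarray) -> np.ndarray:
    """Synthetic N, CA, C, O placement from a C-alpha trace.

    Atoms are placed along the inter-C-alpha directions at standard bond
    lengths; the geometry is idealized, not Ramachandran-accurate, but
    junction C-N distances of a correctly grafted loop stay well under
    the 2.5 angstrom continuity flag.
    """
    ca = np.asarray(ca, dtype=float)
    n = ca.shape[0]
    if n < 2:
        raise ValueError("need at least 2 residues")
    fwd = np.zeros_like(ca)
    fwd[:-1] = ca[1:] - ca[:-1]
    fwd[-1] = fwd[-2]
    fwd /= np.linalg.norm(fwd, axis=1, keepdims=True)
    back = np.zeros_like(ca)
    back[1:] = ca[1:] - ca[:-1]
    back[0] = back[1]
    back /= np.linalg.norm(back, axis=1, keepdims=True)

    out = np.empty((n, 4, 3))
    out[:, 1] = ca
    out[:, 0] = ca - 1.46 * back          # N, toward the previous residue
    out[:, 2] = ca + 1.52 * fwd           # C, toward the next residue
    perp = np.cross(fwd, back)
    norms = np.linalg.norm(perp, axis=1, keepdims=True)
    fallback = np.cross(fwd, np.array([0.0, 0.0, 1.0]))
    fb_norm = np.linalg.norm(fallback, axis=1, keepdims=True)
    fallback = np.where(fb_norm > 1e-8, fallback / np.maximum(fb_norm, 1e-12),
                        np.array([1.0, 0.0, 0.0]))
    perp = np.where(norms > 1e-8, perp / np.maximum(norms, 1e-12), fallback)
    out[:, 3] = out[:, 2] + 1.23 * perp   # carbonyl O, off the chain axis
    return out


def _chain_from_mainchain(mainchain: np.ndarray, sequence: str,
                          chain_id: str = "A",
                          first_num: int = 1) -> Chain:
    residues = []
    for i, letter in enumerate(sequence):
        mc = {a: mainchain[i, j].copy()
              for j, a in enumerate(structure_io.MAINCHAIN_ATOMS)}
        residues.append(Residue(name=structure_io.one_to_three(letter),
                                num=first_num + i, mainchain=mc,
                                standard=True))
    return Chain(id=chain_id, residues=residues)


@dataclasses.dataclass
class HLHTarget:
    """A synthetic helix-loop-helix structure with its native loop record."""

    chains: list
    loop_start: int      # 0-based residue index of the first loop residue
    loop_length: int
    sequence: str
    seed: int

    @property
    def gap_start(self) -> int:
        """Author number of the first loop residue (numbering starts at 1)."""
        return self.loop_start + 1

    @property
    def gap_end(self) -> int:
        return self.loop_start + self.loop_length

    @property
    def loop_sequence(self) -> str:
        return self.sequence[self.loop_start:
                             self.loop_start + self.loop_length]

    def mainchain_coords(self) -> np.ndarray:
        return np.array([r.mainchain_array()
                         for r in self.chains[0].residues])

    def native_loop_mainchain(self) -> np.ndarray:
        return self.mainchain_coords()[self.loop_start:
                                       self.loop_start + self.loop_length]

    @property
    def loop_range(self) -> tuple[int, int]:
        return (self.loop_start, self.loop_start + self.loop_length)


def make_helix_loop_helix(loop_length: int, seed: int,
                          helix_len: int = 12) -> HLHTarget:
    """Generate one helix-loop-helix target; byte-identical for a seed."""
    if loop_length < 1:
        raise ValueError("loop_length must be at least 1")
    rng = np.random.default_rng(seed)
    h1 = _helix_ca(helix_len)
    loop = _walk_loop(h1[-1], h1[-2], loop_length, h1, rng)
    trace = np.vstack([h1, loop])
    h2 = _place_second_helix(helix_len, loop[-1], trace, rng)
    ca = np.vstack([trace, h2])
    sequence = "".join(rng.choice(list(AMINO_ACIDS), size=ca.shape[0]))
    chain = _chain_from_mainchain(mainchain_from_ca(ca), sequence)
    return HLHTarget(chains=[chain], loop_start=helix_len,
                     loop_length=loop_length, sequence=sequence, seed=seed)


def _mutate_sequence(sequence: str, keep: tuple[int, int],
                     rng: np.random.Generator) -> str:
    """Mutate every residue outside ``keep`` to a different amino acid."""
    out = []
    for i, letter in enumerate(sequence):
        if keep[0] <= i < keep[1]:
            out.append(letter)
        else:
            choices = [a for a in AMINO_ACIDS if a != letter]
            out.append(choices[int(rng.integers(len(choices)))])
    return "".join(out)


def _zigzag_decoy(n_res: int, rng: np.random.Generator) -> np.ndarray:
    """Planar zig-zag C-alpha trace: rank-deficient by construction.

    Every flank window taken from a strictly planar chain has a singular
    Gram matrix, so the kernel is undefined there and the search skips
    it — decoys contribute windows without ever matching a query.
    """
    x = np.arange(n_res) * 3.0
    y = np.where(np.arange(n_res) % 2 == 0, 0.0, 2.34)
    ca = np.column_stack([x, y, np.zeros(n_res)])
    rot = _random_rotation(rng)
    return ca @ rot.T + rng.uniform(-50, 50, size=3)


def make_planted_db(target: HLHTarget, n_decoys: int, seed: int,
                    out_dir: str | Path,
                    extra_targets: list | None = None) -> Path:
    """Write a synthetic PDB directory containing the target's donor.

    The donor shares the target's coordinates but carries a mutated
    sequence outside the loop, keeping chain identity safely below the
    70% homolog-exclusion threshold while the loop itself still scores
    positively against the query.  ``extra_targets`` lets several
    planted donors share one database.
    """
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for idx, tgt in enumerate([target] + list(extra_targets or [])):
        donor_seq = _mutate_sequence(tgt.sequence, tgt.loop_range, rng)
        donor = _chain_from_mainchain(tgt.mainchain_coords(), donor_seq)
        structure_io.write_model([donor], out / f"donor_{idx:03d}.pdb")
    for d in range(n_decoys):
        n_res = int(rng.integers(30, 45))
        ca = _zigzag_decoy(n_res, rng)
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=n_res))
        decoy = _chain_from_mainchain(mainchain_from_ca(ca), seq)
        structure_io.write_model([decoy], out / f"decoy_{d:03d}.pdb")
    return out


def perturb_template(target: HLHTarget, sigma: float,
                     seed: int) -> list[Chain]:
    """Delete the loop and add isotropic Gaussian noise to what remains.

    Emulates the flank error of a homology-model template; ``sigma`` is
    the per-coordinate noise scale in angstroms (0 reproduces the native
    flanks exactly).
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    chains = []
    for chain in target.chains:
        residues = []
        for r in chain.residues:
            if target.gap_start <= r.num <= target.gap_end:
                continue
            mc = {a: xyz + rng.normal(0.0, sigma, size=3)
                  for a, xyz in r.mainchain.items()}
            residues.append(Residue(name=r.name, num=r.num, icode=r.icode,
                                    mainchain=mc, standard=r.standard))
        chains.append(Chain(id=chain.id, residues=residues))
    return chains


@dataclasses.dataclass
class FixtureSpec:
    """Conditions for a batch of planted-loop fixtures."""

    n_structures: int = 20
    loop_lengths: tuple = tuple(range(5, 30))
    flank_noise_sigma: float = 0.3
    decoy_count: int = 30
    seed: int = 0


def generate_fixture_set(spec: FixtureSpec, out_dir: str | Path) -> list:
    """Materialize targets, perturbed templates and a shared database.

    Writes ``target_XXX.pdb`` and ``template_XXX.pdb`` per structure and
    a ``db/`` directory containing every donor plus the decoys; returns
    the in-memory targets.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lengths = [spec.loop_lengths[i % len(spec.loop_lengths)]
               for i in range(spec.n_structures)]
    targets = [make_helix_loop_helix(length, seed=spec.seed + i)
               for i, length in enumerate(lengths)]
    for i, tgt in enumerate(targets):
        structure_io.write_model(tgt.chains, out / f"target_{i:03d}.pdb")
        template = perturb_template(tgt, spec.flank_noise_sigma,
                                    seed=spec.seed + 1000 + i)
        structure_io.write_model(template, out / f"template_{i:03d}.pdb")
    make_planted_db(targets[0], spec.decoy_count, seed=spec.seed + 2000,
                    out_dir=out / "db", extra_targets=targets[1:])
    return targets
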