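import numpy as np
import pytest

from loopforge import fixtures, geometry, structure_io
from loopforge.config import SearchConfig
from loopforge.fragment_db import (FragmentDB, bc_loop_search,
                                   build_database, exclude_homologs,
                                   make_query, sequence_identity)

from conftest import planted_setup


def brute_force_search(query, db, config):
    """Exhaustive double-loop reference: apply the three cutoffs directly."""
    fs = config.flank_size
    length = query.loop_length
    window = 2 * fs + length
    x = query.flank_ca()
    found = []
    for seg_idx, seg in enumerate(db.segments):
        ca = seg.ca_coords()
        for off in range(max(0, len(seg) - window + 1)):
            y = np.concatenate([ca[off:off + fs],
                                ca[off + fs + length:off + window]])
            try:
                bc = geometry.bc_kernel(x, y)
            except geometry.DegenerateFragmentError:
                continue
            rig = geometry.rigidity(x, y, mode=config.rigidity_mode)
            fit = geometry.superimpose(x, y)
            if bc >= config.bc_min(length) and rig <= config.rigidity_max \
                    and fit.rmsd <= config.flank_rmsd_max:
                found.append((bc, seg.source_id, seg_idx, off))
    found.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))
    return [(sid, idx, off) for _, sid, idx, off in found]


class TestBuildDatabase:
    def test_counts_by_construction(self, tmp_path):
        # one continuous chain + one chain with a numbering gap -> 3 segments
        t1 = fixtures.make_helix_loop_helix(5, seed=11)
        structure_io.write_model(t1.chains, tmp_path / "a.pdb")
        t2 = fixtures.make_helix_loop_helix(5, seed=12)
        gapped = fixtures.perturb_template(t2, 0.0, seed=0)
        structure_io.write_model(gapped, tmp_path / "b.pdb")
        db = build_database(tmp_path)
        assert len(db) == 3
        assert len(db.chain_sequences) == 2

    def test_deterministic_index(self, tmp_path):
        planted_setup(tmp_path, loop_length=6, seed=21)
        src = next(tmp_path.iterdir())
        db1 = build_database(src)
        db2 = build_database(src)
        out1, out2 = tmp_path / "o1", tmp_path / "o2"
        db1.save(out1)
        db2.save(out2)
        assert (out1 / "index.tsv").read_bytes() == \
            (out2 / "index.tsv").read_bytes()
        assert np.array_equal(np.load(out1 / "coords.npy"),
                              np.load(out2 / "coords.npy"))

    def test_empty_directory_raises(self, tmp_path):
        empty = tmp_path / "empty"
        empty.mkdir()
        with pytest.raises(ValueError):
            build_database(empty)

    def test_unreadable_file_skipped(self, tmp_path):
        t = fixtures.make_helix_loop_helix(5, seed=13)
        structure_io.write_model(t.chains, tmp_path / "good.pdb")
        (tmp_path / "bad.pdb").write_text("garbage, not a structure\n")
        db = build_database(tmp_path)
        assert len(db.chain_sequences) == 1

    def test_save_load_roundtrip_preserves_search(self, tmp_path):
        target, db, template = planted_setup(tmp_path, loop_length=6,
                                             seed=22)
        db.save(tmp_path / "saved")
        reloaded = FragmentDB.load(tmp_path / "saved")
        q = make_query(template, "A", target.gap_start, target.gap_end,
                       target.loop_sequence)
        h1 = bc_loop_search(q, db)
        h2 = bc_loop_search(q, reloaded)
        assert [(h.source_id, h.offset) for h in h1] == \
            [(h.source_id, h.offset) for h in h2]
        assert len(h1) >= 1


class TestSequenceIdentity:
    def test_needleman_wunsch_oracle_pair(self):
        # ungapped optimal alignment; identity checked by hand: 9/10
        assert sequence_identity("ACDEFGHIKL", "ACDEFGHIKV") == \
            pytest.approx(0.9)

    def test_own_chain_excluded(self, tmp_path):
        target, db, _ = planted_setup(tmp_path, loop_length=6, seed=23)
        # plant the target's own (unmutated) chain in the database
        db.chain_sequences["self_A"] = target.sequence
        filtered = exclude_homologs(db, target.sequence)
        assert "self_A" not in filtered.chain_sequences

    def test_half_identity_retained(self, tmp_path):
        target, db, _ = planted_setup(tmp_path, loop_length=6, seed=24)
        n = len(db.chain_sequences)
        filtered = exclude_homologs(db, target.sequence)
        # donor was mutated below the threshold; decoys are unrelated
        assert len(filtered.chain_sequences) == n
        assert sequence_identity("ACDEFGHIKL", "ACDEFWYWYW") < 0.70

    def test_empty_target_rejected(self, tmp_path):
        target, db, _ = planted_setup(tmp_path, loop_length=5, seed=25)
        with pytest.raises(ValueError):
            exclude_homologs(db, "")


class TestMakeQuery:
    def test_flanks_contiguous_and_sized(self, tmp_path):
        target, _, template = planted_setup(tmp_path, loop_length=7, seed=26)
        q = make_query(template, "A", target.gap_start, target.gap_end,
                       target.loop_sequence)
        assert q.flank_size == 4
        assert [r.num for r in q.flank_n] == list(range(target.gap_start - 4,
                                                        target.gap_start))
        assert [r.num for r in q.flank_c] == list(range(target.gap_end + 1,
                                                        target.gap_end + 5))

    def test_missing_flank_rejected(self, tmp_path):
        target, _, template = planted_setup(tmp_path, loop_length=7, seed=27)
        chain = template[0]
        chain.residues = chain.residues[10:]  # eat into the N-side flank
        with pytest.raises(ValueError, match="flank"):
            make_query(template, "A", target.gap_start, target.gap_end,
                       target.loop_sequence)

    def test_overlapping_gap_rejected(self, tmp_path):
        target, _, _ = planted_setup(tmp_path, loop_length=7, seed=28)
        with pytest.raises(ValueError):
            make_query(target.chains, "A", target.gap_start, target.gap_end,
                       target.loop_sequence)


class TestBCLoopSearch:
    def test_planted_loop_recovered_first(self, tmp_path):
        target, db, template = planted_setup(tmp_path, loop_length=7,
                                             seed=29)
        q = make_query(template, "A", target.gap_start, target.gap_end,
                       target.loop_sequence)
        hits = bc_loop_search(q, db)
        assert hits, "planted donor not found"
        top = hits[0]
        assert top.source_id == "donor_000_A"
        assert top.offset == target.loop_start - 4
        # PDB 3-decimal rounding keeps these near-exact, not exact
        assert top.bc == pytest.approx(1.0, abs=1e-6)
        assert top.rigidity == pytest.approx(0.0, abs=1e-3)
        assert top.flank_rmsd == pytest.approx(0.0, abs=1e-3)
        assert top.loop_sequence == target.loop_sequence

    def test_every_hit_satisfies_cutoffs(self, tmp_path):
        target, db, template = planted_setup(tmp_path, loop_length=9,
                                             seed=30, sigma=0.3)
        cfg = SearchConfig()
        q = make_query(template, "A", target.gap_start, target.gap_end,
                       target.loop_sequence)
        for h in bc_loop_search(q, db, cfg):
            assert h.bc >= cfg.bc_min(q.loop_length)
            assert h.rigidity <= cfg.rigidity_max
            assert h.flank_rmsd <= cfg.flank_rmsd_max
            assert len(h.loop_sequence) == q.loop_length

    @pytest.mark.parametrize("loop_length,seed", [(5, 31), (8, 32), (9, 33),
                                                  (16, 34)])
    def test_matches_brute_force_oracle(self, tmp_path, loop_length, seed):
        target, db, template = planted_setup(tmp_path, loop_length=loop_length,
                                             seed=seed, sigma=0.3)
        cfg = SearchConfig()
        q = make_query(template, "A", target.gap_start, target.gap_end,
                       target.loop_sequence)
        hits = bc_loop_search(q, db, cfg)
        assert [(h.source_id, h.segment_index, h.offset) for h in hits] == \
            brute_force_search(q, db, cfg)

    def test_length_dependent_cutoff(self, tmp_path):
        # at loop length 8 the stricter 0.9 minimum applies, at 9 only 0.8
        assert SearchConfig().bc_min(8) == 0.9
        assert SearchConfig().bc_min(9) == 0.8
        target, db, template = planted_setup(tmp_path, loop_length=9,
                                             seed=35, sigma=0.6)
        q = make_query(template, "A", target.gap_start, target.gap_end,
                       target.loop_sequence)
        relaxed = bc_loop_search(q, db, SearchConfig())
        strict = bc_loop_search(q, db, SearchConfig(bc_min_long=0.9))
        keys = {h.key for h in strict}
        assert keys <= {h.key for h in relaxed}
        for h in relaxed:
            assert (h.bc >= 0.9) == (h.key in keys)

    def test_no_window_long_enough(self, tmp_path):
        target, db, template = planted_setup(tmp_path, loop_length=7,
                                             seed=36)
        q = make_query(template, "A", target.gap_start, target.gap_end,
                       target.loop_sequence)
        short = FragmentDB([s for s in db.segments if len(s) < 15],
                           db.chain_sequences)
        assert bc_loop_search(q, short, SearchConfig()) == []

    def test_prefilter_does_not_change_results(self, tmp_path):
        target, db, template = planted_setup(tmp_path, loop_length=10,
                                             seed=37, sigma=0.4)
        q = make_query(template, "A", target.gap_start, target.gap_end,
                       target.loop_sequence)
        with_pf = bc_loop_search(q, db, SearchConfig(prefilter=True))
        without = bc_loop_search(q, db, SearchConfig(prefilter=False))
        assert [h.key for h in with_pf] == [h.key for h in without]

    def test_file_order_independence(self, tmp_path):
        # renaming files permutes read order; sorted index keeps results equal
        target, db, template = planted_setup(tmp_path, loop_length=6,
                                             seed=38)
        q = make_query(template, "A", target.gap_start, target.gap_end,
                       target.loop_sequence)
        base = [(h.source_id, h.offset) for h in bc_loop_search(q, db)]
        db2 = FragmentDB(list(reversed(db.segments)), db.chain_sequences)
        again = [(h.source_id, h.offset) for h in bc_loop_search(q, db2)]
        assert base == again
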