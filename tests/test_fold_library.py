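"""Fold matrix, recursive fold search, filters and library generation."""

import numpy as np
import pytest

from conftest import (embedded_fold_target_spec, mixed_fold_spec,
                      random_target_spec)
from cvfold import fixtures as fx
from cvfold.annotation import ScoringParams, annotate_structure
from cvfold.fold_library import (MODEL_NAME_RE, MatchConfig,
                                 UnusableTemplateError, apply_filters,
                                 brute_force_fold_occurrences,
                                 build_fold_matrix, cluster_library,
                                 find_fold_occurrences, generate_library,
                                 score_similarity, _block_cells)
from cvfold.structures import transform_stretch, write_structure


class TestFoldMatrix:
    def test_diagonal_layout(self, mixed_fold_matrix):
        fm = mixed_fold_matrix
        n = fm.order
        assert len(fm.diag) == n
        assert len(fm.second_diag) == n - 1
        moduli = fm.annotated.graph.moduli()
        for (m, lab), mod in zip(fm.diag, moduli):
            assert m == pytest.approx(mod)
            assert lab in ("ah", "bs", "coil")

    def test_fragment_index_covers_member_cvs(self, mixed_fold_matrix):
        fm = mixed_fold_matrix
        idx = fm.fragment_index
        for fi, frag in enumerate(fm.fragments):
            for ci in frag.cv_indices:
                assert idx[ci] == fi

    def test_matrix_rigid_motion_invariance(self, mixed_fold):
        stretches, _ = mixed_fold
        rng = np.random.default_rng(9)
        moved = [transform_stretch(s, fx.random_rotation(rng),
                                   rng.normal(scale=30, size=3))
                 for s in stretches]
        # same transform applied to all stretches
        R = fx.random_rotation(rng)
        t = rng.normal(scale=30, size=3)
        moved = [transform_stretch(s, R, t) for s in stretches]
        a = build_fold_matrix(annotate_structure(stretches))
        b = build_fold_matrix(annotate_structure(moved))
        for (a1, d1), (a2, d2) in zip(a.second_diag, b.second_diag):
            assert a1 == pytest.approx(a2, abs=1e-3)
            assert d1 == pytest.approx(d2, abs=1e-6)


class TestScoreSimilarity:
    def test_identical_blocks_score_100(self, mixed_fold_matrix):
        fm = mixed_fold_matrix
        cells = _block_cells(fm.fragments[0].cv_indices,
                             fm.fragments[2].cv_indices)
        assert score_similarity(fm, cells, fm, cells) == 100.0

    def test_disjoint_geometry_scores_0(self, mixed_fold):
        stretches, _ = mixed_fold
        fm = build_fold_matrix(annotate_structure(stretches))
        far = [transform_stretch(s, np.eye(3), np.array([200.0 * i, 0, 0]))
               for i, s in enumerate(stretches)]
        fm2 = build_fold_matrix(annotate_structure(far))
        cells = _block_cells(fm.fragments[0].cv_indices,
                             fm.fragments[2].cv_indices)
        # distances across fragments moved by ~200 A: every cell out of band
        assert score_similarity(fm, cells, fm2, cells) == 0.0

    def test_score_decreases_with_hinge_angle(self):
        """Bending the helix away from the sheet degrades the inter score
        monotonically."""
        base_spec = mixed_fold_spec()
        base_st, _ = fx.assemble_fold(base_spec)
        base = build_fold_matrix(annotate_structure(base_st))
        tpl_cells = _block_cells(base.fragments[0].cv_indices,
                                 base.fragments[2].cv_indices)
        scores = []
        for hinge in (0.0, 25.0, 50.0):
            R = fx.rotation_matrix([0, 1, 0], hinge)
            spec = mixed_fold_spec()
            spec.elements[2].rotation = R
            st, _ = fx.assemble_fold(spec)
            fm = build_fold_matrix(annotate_structure(st))
            assert len(fm.fragments) == 3
            cells = _block_cells(fm.fragments[0].cv_indices,
                                 fm.fragments[2].cv_indices)
            scores.append(score_similarity(base, tpl_cells, fm, cells))
        assert scores[0] == 100.0
        assert scores[0] >= scores[1] >= scores[2]
        assert scores[2] < scores[0]


class TestFoldSearch:
    def test_self_search_identity(self, mixed_fold_matrix):
        for ss, tt in ((0, 0), (45, 55), (100, 100)):
            cfg = MatchConfig(ss_threshold=ss, tt_threshold=tt)
            matches = find_fold_occurrences(mixed_fold_matrix,
                                            mixed_fold_matrix, cfg)
            assert matches
            best = matches[0]
            assert best.ss_score == 100.0
            assert best.tt_score == 100.0

    def test_template_without_fragments_is_unusable(self, coil12):
        fm = build_fold_matrix(annotate_structure([coil12]))
        with pytest.raises(UnusableTemplateError):
            find_fold_occurrences(fm, fm, MatchConfig())

    def test_helix_only_target_cannot_host_strand_template(self,
                                                           mixed_fold_matrix):
        spec = fx.FixtureSpec(elements=[
            fx.ElementSpec("ah", 12),
            fx.ElementSpec("ah", 12, translation=np.array([12.0, 0, 0])),
        ])
        stretches, _ = fx.assemble_fold(spec)
        target = build_fold_matrix(annotate_structure(stretches))
        cfg = MatchConfig(ss_threshold=0, tt_threshold=0)
        assert find_fold_occurrences(mixed_fold_matrix, target, cfg) == []

    def test_two_disjoint_copies_found(self, mixed_fold_matrix):
        """A target holding two far-apart copies of the fold yields exactly
        the brute-force set of matches."""
        spec = mixed_fold_spec()
        far = np.array([80.0, 0, 0])
        elements = list(spec.elements)
        for el in mixed_fold_spec().elements:
            elements.append(fx.ElementSpec(el.kind, el.length, el.rotation,
                                           el.translation + far))
        stretches, _ = fx.assemble_fold(fx.FixtureSpec(elements=elements))
        target = build_fold_matrix(annotate_structure(stretches))
        cfg = MatchConfig(ss_threshold=45, tt_threshold=55, multi_chain=True)
        rec = find_fold_occurrences(mixed_fold_matrix, target, cfg)
        brute = brute_force_fold_occurrences(mixed_fold_matrix, target, cfg)
        key = lambda ms: sorted(tuple(m.assignment) for m in ms)
        assert key(rec) == key(brute)
        assert len(rec) == 2
        # the two sites share no target residue
        sites = [set(m.target_residue_keys()) for m in rec]
        assert not sites[0] & sites[1]

    def test_search_equals_brute_force_on_random_targets(self,
                                                         mixed_fold_matrix):
        """Pruning is admissible: the recursion returns exactly the
        enumeration's assignment set on random small targets."""
        rng = np.random.default_rng(23)
        agree = 0
        for trial in range(15):
            spec = (embedded_fold_target_spec(rng) if trial % 2 == 0
                    else random_target_spec(rng))
            stretches, _ = fx.assemble_fold(spec)
            target = build_fold_matrix(annotate_structure(stretches))
            cfg = MatchConfig(ss_threshold=30, tt_threshold=30,
                              multi_chain=True)
            rec = find_fold_occurrences(mixed_fold_matrix, target, cfg)
            brute = brute_force_fold_occurrences(mixed_fold_matrix, target,
                                                 cfg)
            assert (sorted(tuple(m.assignment) for m in rec)
                    == sorted(tuple(m.assignment) for m in brute))
            agree += len(rec)
        # the embedded-fold targets must actually contain matches
        assert agree > 0

    def test_match_set_shrinks_with_thresholds(self, mixed_fold_matrix):
        rng = np.random.default_rng(31)
        stretches, _ = fx.assemble_fold(random_target_spec(rng))
        target = build_fold_matrix(annotate_structure(stretches))
        prev = None
        for tt in (0, 30, 60, 90):
            cfg = MatchConfig(ss_threshold=30, tt_threshold=tt,
                              multi_chain=True)
            got = {tuple(m.assignment)
                   for m in find_fold_occurrences(mixed_fold_matrix, target,
                                                  cfg)}
            if prev is not None:
                assert got <= prev
            prev = got

    def test_connectivity_requirement(self, mixed_fold_matrix):
        """With connectivity required, matches keep the template's N-to-C
        fragment order."""
        cfg = MatchConfig(ss_threshold=45, tt_threshold=55,
                          require_connectivity=True)
        matches = find_fold_occurrences(mixed_fold_matrix, mixed_fold_matrix,
                                        cfg)
        assert matches and all(m.connectivity_ok for m in matches)


class TestFilters:
    def _self_match(self, fm):
        return find_fold_occurrences(fm, fm, MatchConfig())[0]

    def test_all_x_pattern_filters_nothing(self, mixed_fold_matrix):
        m = self._self_match(mixed_fold_matrix)
        n_res = len(m.target_residue_keys())
        kept = apply_filters([m], mixed_fold_matrix,
                             sequence_pattern="X" * n_res)
        assert kept == [m]

    def test_cysteine_pattern(self):
        """A C in the pattern keeps only matches with Cys at that spot."""
        spec = fx.FixtureSpec(elements=[
            fx.ElementSpec("bs", 6, res_names=["ALA", "ALA", "ALA", "CYS",
                                               "ALA", "ALA"]),
            fx.ElementSpec("bs", 6,
                           rotation=fx.rotation_matrix([1, 0, 0], 180.0),
                           translation=np.array([0, 0, 4.8])),
        ])
        stretches, _ = fx.assemble_fold(spec)
        fm = build_fold_matrix(annotate_structure(stretches))
        m = self._self_match(fm)
        seq_len = len(m.target_residue_keys())
        pat_hit = list("X" * seq_len)
        # locate the Cys position within the matched residues
        residues = [fm.annotated.stretches[si].residues[ri]
                    for si, ri in m.target_residue_keys()]
        cys_at = [i for i, r in enumerate(residues) if r.res_name == "CYS"]
        assert cys_at
        pat_hit[cys_at[0]] = "C"
        assert apply_filters([m], fm, sequence_pattern="".join(pat_hit))
        pat_miss = list("X" * seq_len)
        pat_miss[(cys_at[0] + 1) % seq_len] = "C"
        assert apply_filters([m], fm,
                             sequence_pattern="".join(pat_miss)) == []

    def test_disulfide_filter(self):
        spec = fx.FixtureSpec(elements=[
            fx.ElementSpec("bs", 6, res_names=["ALA", "ALA", "CYS", "ALA",
                                               "ALA", "ALA"]),
            fx.ElementSpec("bs", 6,
                           rotation=fx.rotation_matrix([1, 0, 0], 180.0),
                           translation=np.array([0, 0, 4.8]),
                           res_names=["ALA", "ALA", "ALA", "CYS", "ALA",
                                      "ALA"]),
        ])
        stretches, _ = fx.assemble_fold(spec)
        # place the two S-gamma atoms at bonding distance by hand
        sgs = [r for s in stretches for r in s if "SG" in r.atoms]
        assert len(sgs) == 2
        sgs[0].atoms["SG"].position = np.array([0.0, 0.0, 2.4])
        sgs[1].atoms["SG"].position = np.array([0.0, 0.0, 4.45])
        fm = build_fold_matrix(annotate_structure(stretches))
        m = self._self_match(fm)
        assert apply_filters([m], fm, disulfide=True)
        # move one S-gamma out of range
        sgs[1].atoms["SG"].position = np.array([0.0, 0.0, 9.0])
        assert apply_filters([m], fm, disulfide=True) == []

    def test_zero_rmsd_cut_keeps_only_self_match(self, mixed_fold,
                                                 mixed_fold_matrix):
        stretches, _ = mixed_fold
        m = self._self_match(mixed_fold_matrix)
        kept = apply_filters([m], mixed_fold_matrix, max_rmsd=1e-6,
                             template=mixed_fold_matrix)
        assert len(kept) == 1
        assert kept[0].rmsd_to_template == pytest.approx(0.0, abs=1e-9)


class TestLibrary:
    @pytest.fixture()
    def library_inputs(self, tmp_path, mixed_fold):
        stretches, _ = mixed_fold
        tpl = tmp_path / "template.pdb"
        write_structure(stretches, tpl)
        db = tmp_path / "db"
        db.mkdir()
        for k in range(10):
            noisy = fx.perturb(stretches, noise_sigma=0.3, seed=100 + k)
            write_structure(noisy, db / f"fix{k:02d}.pdb")
        return tpl, db

    def test_template_against_itself(self, tmp_path, mixed_fold):
        stretches, _ = mixed_fold
        tpl = tmp_path / "tpl.pdb"
        write_structure(stretches, tpl)
        db = tmp_path / "selfdb"
        db.mkdir()
        write_structure(stretches, db / "tpl.pdb")
        models = generate_library(tpl, db, tmp_path / "lib")
        assert len(models) >= 1
        assert models[0].rmsd_to_template == pytest.approx(0.0, abs=1e-6)

    def test_noisy_database_full_recovery(self, tmp_path, library_inputs):
        tpl, db = library_inputs
        models = generate_library(tpl, db, tmp_path / "lib")
        assert len(models) == 10
        assert all(m.rmsd_to_template < 1.0 for m in models)
        for m in models:
            assert MODEL_NAME_RE.match(m.filename)
            assert m.path.exists()
            bvals = {line[60:66].strip()
                     for line in m.path.read_text().splitlines()
                     if line.startswith("ATOM")}
            assert bvals == {"25.00"}

    def test_pairwise_clustering_single_family(self, tmp_path,
                                               library_inputs):
        tpl, db = library_inputs
        models = generate_library(tpl, db, tmp_path / "lib")
        clusters = cluster_library(models, "pairwise_rmsd", rmsd_cut=1.0)
        assert len(clusters) == 1

    def test_two_conformer_families_split(self, tmp_path, mixed_fold):
        """Models at ~0 and ~3 A from the template separate at a 1 A cut."""
        stretches, _ = mixed_fold
        tpl = tmp_path / "tpl.pdb"
        write_structure(stretches, tpl)
        db = tmp_path / "famdb"
        db.mkdir()
        for k in range(3):
            write_structure(fx.perturb(stretches, 0.05, seed=k),
                            db / f"near{k}.pdb")
        # a far family: slide the helix 4 A along the strand direction --
        # angles unchanged and distance cells still in band, but a distinct
        # conformer well beyond the 1 A clustering cut
        spec = mixed_fold_spec()
        spec.elements[2].translation = spec.elements[2].translation + \
            np.array([4.0, 0, 0])
        far_st, _ = fx.assemble_fold(spec)
        for k in range(3):
            write_structure(fx.perturb(far_st, 0.05, seed=10 + k),
                            db / f"far{k}.pdb")
        models = generate_library(tpl, db, tmp_path / "lib")
        rmsds = sorted(m.rmsd_to_template for m in models)
        assert rmsds[0] < 1.0
        clusters = cluster_library(models, "pairwise_rmsd", rmsd_cut=1.0)
        assert len(clusters) >= 2

    def test_random_subset_seeded(self, tmp_path, library_inputs):
        tpl, db = library_inputs
        models = generate_library(tpl, db, tmp_path / "lib")
        a = cluster_library(models, "random_subset", n_random=4, seed=5)
        b = cluster_library(models, "random_subset", n_random=4, seed=5)
        assert [m.filename for m in a[0]] == [m.filename for m in b[0]]
        assert len(a[0]) == 4

    def test_lower_tt_threshold_never_shrinks_library(self, tmp_path,
                                                      library_inputs):
        from cvfold.fold_library import LibraryConfig
        tpl, db = library_inputs
        sizes = []
        for tt in (80.0, 55.0, 30.0):
            cfg = LibraryConfig(match=MatchConfig(tt_threshold=tt))
            out = tmp_path / f"lib{int(tt)}"
            sizes.append(len(generate_library(tpl, db, out, cfg)))
        assert sizes[0] <= sizes[1] <= sizes[2]
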