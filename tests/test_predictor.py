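"""Routing, bound-site read-off, template selection, clustering, prediction."""
import numpy as np
import pytest
from scipy.spatial.distance import cdist

from bsite.geometry import min_distance
from bsite.predictor import (MappedLigand, PredictorConfig, Route,
                             cluster_ligand_centers, detect_site_residues,
                             map_ligands, predict, predict_bound, route,
                             select_templates)
from bsite.structure_io import Atom, LigandRecord, StructureRecord, parse_structure
from bsite.synthetic_fixtures import (FixtureSpec, GroundTruth, build_structure,
                                      derive_unbound, generate_bound)
from bsite.template_db import site_residues

CFG = PredictorConfig()


def mapped(center, template_rank=0, index=0, n=6):
    center = np.asarray(center, dtype=float)
    atoms = tuple(Atom(f"C{k}", "C", center + 0.5 * np.eye(3)[k % 3] * (-1) ** k,
                       is_hetero=True) for k in range(n))
    # recenter so the ligand's geometric center is exactly the requested point
    shift = center - np.mean([a.coords for a in atoms], axis=0)
    atoms = tuple(a.with_coords(a.coords + shift) for a in atoms)
    return MappedLigand(atoms=atoms, source=f"T{template_rank}",
                        template_rank=template_rank, index=index)


class TestRoute:
    def test_stable_bound_chain_goes_part1(self, corpus_db, first_structure):
        s = first_structure
        r = route(s.chains[0], s.ligands, corpus_db, CFG, homology_class="a.1.1.1")
        assert r is Route.PART1

    def test_unstable_ligand_with_mapped_class_goes_part2(self, corpus_db, tmp_path):
        path, _ = generate_bound(FixtureSpec(seed=41, defects=("unstable_ligand",)),
                                 tmp_path / "u.pdb")
        s = parse_structure(path)
        r = route(s.chains[0], s.ligands, corpus_db, CFG, homology_class="a.1.1.1")
        assert r is Route.PART2

    def test_unmapped_chain_goes_part3(self, corpus_db, first_structure):
        chain = first_structure.chains[0]
        assert route(chain, [], corpus_db, CFG, homology_class=None) is Route.PART3
        assert route(chain, [], corpus_db, CFG, homology_class="z.9.9.9") is Route.PART3


class TestPredictBound:
    def test_site_residues_all_within_radius(self, first_structure):
        s = first_structure
        preds = predict_bound(s.chains[0], s.ligands, CFG)
        assert len(preds) == 1
        assert preds[0].mode == "bound"
        lig_coords = s.ligands[0].coords()
        for res in preds[0].residues:
            d = cdist([a.coords for a in res.heavy_atoms], lig_coords).min()
            assert d <= CFG.db.bound_site_radius

    def test_residue_just_beyond_radius_excluded(self, chain_factory):
        # residues flank the ligand line symmetrically (so the complex is
        # stable); two probes sit exactly at 8.0 and just past at 8.05 A
        coords = np.array([[0.0, 5.0, 0], [4.0, -5.0, 0], [8.0, 5.0, 0],
                           [12.0, -5.0, 0], [6.0, 8.0, 0], [6.0, -8.05, 0]])
        chain = chain_factory(coords)
        lig = _line_ligand()
        preds = predict_bound(chain, [lig], CFG)
        ids = {r.seq_id for r in preds[0].residues}
        assert "5" in ids and "6" not in ids

    def test_two_ligands_ranked_by_atom_count(self, tmp_path):
        rec, _ = build_structure(FixtureSpec(seed=42, ligand_atoms=10))
        chain = rec.chains[0]
        big = rec.ligands[0]
        small_center = big.coords().mean(axis=0) + np.array([0.5, 0, 0])
        small = LigandRecord("SML", chain.chain_id, "502", tuple(
            Atom(f"C{k}", "C", small_center + 0.9 * np.eye(3)[k % 3] * (-1) ** k,
                 is_hetero=True) for k in range(7)))
        preds = predict_bound(chain, [small, big], CFG)
        assert len(preds) == 2
        assert preds[0].rank == 1 and preds[1].rank == 2
        # rank 1 belongs to the 10-atom ligand's site


def _line_ligand():
    atoms = tuple(Atom(f"C{k}", "C", np.array([k * 2.0, 0.0, 0.0]),
                       is_hetero=True) for k in range(7))
    return LigandRecord("LIG", "A", "501", atoms)


class TestSelectAndMap:
    def test_rigid_copy_template_retained_with_high_score(self, corpus_db, corpus):
        s = parse_structure(corpus["paths"][0])
        unbound, _ = derive_unbound(corpus["paths"][0], _truth_of(s), seed=5)
        selected = select_templates(unbound.chains[0], corpus_db.entries[:4], CFG)
        assert selected
        assert selected[0][1].score > 0.8

    def test_mismatched_template_discarded_by_stability(self, corpus_db, corpus):
        # query from one family vs templates of another: the mapped ligand
        # lands off the query surface and the stability gate rejects it
        s = parse_structure(corpus["paths"][0])
        unbound, _ = derive_unbound(corpus["paths"][0], _truth_of(s), seed=6)
        strangers = [e for e in corpus_db.entries if e.entry_id.startswith("S2")]
        selected = select_templates(unbound.chains[0], strangers, CFG)
        assert all(r.score < 0.5 for _, r in selected)

    def test_identity_alignment_maps_ligand_in_place(self, corpus_db):
        entry = corpus_db.entries[0]
        selected = select_templates(entry.chain, [entry], CFG)
        assert len(selected) == 1
        ligs = map_ligands(selected, CFG)
        assert np.allclose(ligs[0].coords(), entry.ligands[0].coords(),
                           atol=1e-6)

    def test_mapped_ligand_count(self, corpus_db):
        entry = corpus_db.entries[0]
        selected = select_templates(entry.chain, [entry], CFG)
        ligs = map_ligands(selected * 3, CFG)  # 3 templates x 1 ligand
        assert len(ligs) == 3
        assert [l.template_rank for l in ligs] == [0, 1, 2]


def brute_force_clusters(ligands, radius, max_sites):
    """Oracle: literal count-and-remove with scalar arithmetic."""
    remaining = list(ligands)
    out = []
    while remaining and len(out) < max_sites:
        counts = []
        for i, a in enumerate(remaining):
            c = sum(1 for j, b in enumerate(remaining) if j != i and
                    np.linalg.norm(a.center.coords - b.center.coords) < radius)
            counts.append(c)
        best = min(range(len(remaining)),
                   key=lambda i: (-counts[i], remaining[i].template_rank,
                                  remaining[i].index))
        cluster = [i for i in range(len(remaining))
                   if i == best or np.linalg.norm(
                       remaining[i].center.coords -
                       remaining[best].center.coords) < radius]
        out.append((tuple(remaining[best].center.coords), len(cluster)))
        remaining = [l for i, l in enumerate(remaining) if i not in cluster]
    return out


class TestClustering:
    def test_single_ligand_is_top1(self):
        one = mapped([1.0, 2.0, 3.0])
        clusters = cluster_ligand_centers([one], CFG)
        assert len(clusters) == 1
        assert np.allclose(clusters[0].center.coords, [1, 2, 3], atol=1e-9)

    def test_worked_tie_break_example(self):
        ligs = [mapped(c, template_rank=i, index=i) for i, c in enumerate(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [10, 10, 10]])]
        clusters = cluster_ligand_centers(ligs, CFG)
        assert np.allclose(clusters[0].center.coords, [0, 0, 0], atol=1e-9)
        assert clusters[0].support == 3
        assert np.allclose(clusters[1].center.coords, [10, 10, 10], atol=1e-9)
        assert clusters[1].support == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 51))
        ligs = [mapped(r.uniform(-8, 8, 3), template_rank=int(r.integers(0, 20)),
                       index=i) for i in range(n)]
        got = [(tuple(c.center.coords), c.support)
               for c in cluster_ligand_centers(ligs, CFG)]
        want = brute_force_clusters(ligs, CFG.cluster_radius, CFG.max_sites)
        assert len(got) == len(want)
        for (gc, gs), (wc, ws) in zip(got, want):
            assert gs == ws
            assert np.allclose(gc, wc, atol=1e-12)

    def test_elected_centers_pairwise_separated(self):
        r = np.random.default_rng(11)
        ligs = [mapped(r.uniform(-6, 6, 3), index=i) for i in range(40)]
        clusters = cluster_ligand_centers(ligs, CFG)
        centers = np.array([c.center.coords for c in clusters])
        if len(centers) > 1:
            d = cdist(centers, centers)
            np.fill_diagonal(d, np.inf)
            assert d.min() >= CFG.cluster_radius

    def test_support_sums_bounded_by_input(self):
        r = np.random.default_rng(12)
        ligs = [mapped(r.uniform(-5, 5, 3), index=i) for i in range(30)]
        clusters = cluster_ligand_centers(ligs, CFG)
        assert sum(c.support for c in clusters) <= len(ligs)

    def test_empty_input_empty_output(self):
        assert cluster_ligand_centers([], CFG) == []


class TestDetectSiteResidues:
    def test_boundary_residue_excluded(self, chain_factory):
        coords = np.array([[0.0, 9.9, 0], [40.0, 10.5 + 1.0, 0],
                           [4.0, 9.9, 0], [8.0, 9.9, 0]])
        chain = chain_factory(coords)
        lig = mapped([1.0, 0.0, 0.0], n=6)
        from bsite.predictor import Cluster
        cluster = Cluster(elected=lig, support=1, members=(lig,))
        ids = {r.seq_id for r in detect_site_residues(chain, cluster, CFG)}
        assert "1" in ids and "2" not in ids

    def test_remote_ligand_gives_empty_site(self, first_structure):
        lig = mapped(first_structure.chains[0].ca_coords().mean(axis=0) + 500)
        from bsite.predictor import Cluster
        cluster = Cluster(elected=lig, support=1, members=(lig,))
        assert detect_site_residues(first_structure.chains[0], cluster, CFG) == []


def _truth_of(s):
    lig = s.ligands[0]
    from bsite.geometry import geometric_center
    return GroundTruth(lig, geometric_center(lig.atoms), [], {})


class TestPredict:
    def test_bound_query_site_matches_ground_truth(self, corpus_db, corpus):
        s = parse_structure(corpus["paths"][0])
        truth_ids = set(corpus["truth"]["S000"]["site_residues"])
        results = predict(s, corpus_db, CFG, mapping=corpus["mapping"])
        assert results[0].route is Route.PART1
        got = {r.seq_id for r in results[0].predictions[0].residues}
        assert got == truth_ids

    def test_unbound_recovery_within_hit_distance(self, corpus_db, corpus):
        s = parse_structure(corpus["paths"][2])
        unbound, truth = derive_unbound(corpus["paths"][2], _truth_of(s), seed=8,
                                        noise_sigma=0.25)
        results = predict(unbound, corpus_db, CFG, mapping=corpus["mapping"])
        assert results[0].status == "ok"
        top1 = results[0].predictions[0]
        assert min_distance(top1.center.coords, truth.true_ligand.coords()) <= 4.0

    def test_rigid_motion_equivariance(self, corpus_db, corpus):
        s = parse_structure(corpus["paths"][1])
        unb_a, truth_a = derive_unbound(corpus["paths"][1], _truth_of(s), seed=9)
        unb_b, truth_b = derive_unbound(corpus["paths"][1], _truth_of(s), seed=10)
        res_a = predict(unb_a, corpus_db, CFG, mapping=corpus["mapping"])
        res_b = predict(unb_b, corpus_db, CFG, mapping=corpus["mapping"])
        # the two queries differ by a rigid motion; compare in the truth frame
        d_a = min_distance(res_a[0].predictions[0].center.coords,
                           truth_a.true_ligand.coords())
        d_b = min_distance(res_b[0].predictions[0].center.coords,
                           truth_b.true_ligand.coords())
        assert d_a == pytest.approx(d_b, abs=1e-3)

    def test_tiny_chain_reports_no_template(self, corpus_db, chain_factory):
        coords = np.arange(30).reshape(10, 3) * 3.8
        s = StructureRecord("TINY", "X-RAY DIFFRACTION", 2.0, {"protein"},
                            [chain_factory(coords)], [])
        results = predict(s, corpus_db, CFG)
        assert results[0].status == "no_template"
        assert results[0].predictions == []
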