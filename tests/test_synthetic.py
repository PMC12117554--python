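import numpy as np
import pytest

from znbench.predictions import select_top
from znbench.scoring import SiteCounts, classify, precision, r_top, tally, unique_tp
from znbench.structures import StructureError, build_reference_site, find_ligands
from znbench.synthetic import (
    ApoNoiseModel,
    PredictorProfile,
    SiteTemplate,
    build_holo,
    make_abstract_dataset,
    make_benchmark,
    make_cles,
    recover_parameters,
    simulate_predictor,
    write_pdb,
)
from znbench.variability import build_tensor


class TestTemplates:
    def test_impossible_geometry_rejected(self):
        with pytest.raises(StructureError):
            SiteTemplate(n_ligands=3, composition=("CYS", "CYS", "CYS"), geometry="tetrahedral")
        with pytest.raises(StructureError):
            SiteTemplate(n_ligands=4, composition=("CYS", "ALA", "CYS", "CYS"))

    def test_holo_round_trip(self):
        """Generated holo sites re-extract to exactly the planted ligands."""
        for template in (
            SiteTemplate(),
            SiteTemplate(3, ("CYS", "ASP", "HIS"), geometry="trigonal"),
        ):
            holo = build_holo(template)
            element, pos = holo.metals[0]
            planted = {("A", i + 1, "") for i in range(template.n_ligands)}
            assert find_ligands(holo, pos) == planted
            site = build_reference_site(holo, holo.metals[0])
            assert set(site.ligands) == planted


class TestMakeCles:
    def test_zero_noise_matches_holo(self):
        template = SiteTemplate()
        noise = ApoNoiseModel(sigma_iso=0.0)
        _, sites, structures = make_cles(template, 4, noise, seed=1)
        holo = build_holo(template)
        holo_site = build_reference_site(holo, holo.metals[0])
        t_holo = build_tensor([(holo_site, holo)])
        t_apo = build_tensor(list(zip(sites, structures)))
        for s in range(4):
            np.testing.assert_allclose(t_apo.stack[s], t_holo.stack[0], atol=1e-12)

    def test_deterministic_per_seed(self):
        template = SiteTemplate(3, ("CYS", "ASP", "HIS"), geometry="trigonal")
        noise = ApoNoiseModel(sigma_iso=0.4, rigid_jitter=1.0)
        _, _, a = make_cles(template, 5, noise, seed=7)
        _, _, b = make_cles(template, 5, noise, seed=7)
        for sa, sb in zip(a, b):
            for key in sa.residues:
                for name in sa.residues[key].atoms:
                    np.testing.assert_array_equal(
                        sa.residues[key].atoms[name], sb.residues[key].atoms[name]
                    )

    def test_prefix_stability_under_resize(self):
        """Per-site substreams: site k is identical in 5- and 10-site runs."""
        template = SiteTemplate()
        noise = ApoNoiseModel(sigma_iso=0.3)
        _, _, small = make_cles(template, 5, noise, seed=3)
        _, _, big = make_cles(template, 10, noise, seed=3)
        for sa, sb in zip(small, big):
            for i in range(4):
                key = ("A", i + 1, "")
                np.testing.assert_array_equal(
                    sa.residues[key].atoms["SG"], sb.residues[key].atoms["SG"]
                )

    def test_sd_grows_with_sigma(self):
        template = SiteTemplate()
        sds = []
        for sigma in (0.1, 0.4, 0.8):
            _, sites, structures = make_cles(
                template, 200, ApoNoiseModel(sigma_iso=sigma), seed=13
            )
            t = build_tensor(list(zip(sites, structures)))
            iu = np.triu_indices(4, k=1)
            sds.append(float(t.sd_mat[iu].mean()))
        assert sds[0] < sds[1] < sds[2]

    def test_pdb_round_trip(self, tmp_path):
        from znbench.structures import parse_structure

        template = SiteTemplate(3, ("CYS", "ASP", "HIS"), geometry="trigonal")
        _, sites, structures = make_cles(template, 2, ApoNoiseModel(), seed=2)
        path = tmp_path / "apo.pdb"
        write_pdb(structures[0], path)
        reparsed = parse_structure(path.read_text(), structures[0].struct_id)
        assert set(reparsed.residues) == set(structures[0].residues)
        for key, res in structures[0].residues.items():
            for name, xyz in res.atoms.items():
                np.testing.assert_allclose(
                    reparsed.residues[key].atoms[name], xyz, atol=1e-3
                )


class TestSimulatePredictor:
    def test_oracle_profile(self):
        dataset = make_abstract_dataset(50, seed=0, sites_per_structure=2)
        profile = PredictorProfile("oracle", 1.0, 0.0, 0.0, 0.0, 1.0)
        preds = simulate_predictor(dataset, profile, seed=5)
        records = []
        for ss in dataset:
            mine = [p for p in preds if p.struct_id == ss.struct_id]
            records += classify(select_top(mine, profile.get_convention(), 10), ss.sites)
        t = tally(records)
        assert precision(t) == 100.0
        assert unique_tp(records) == 100

    def test_blind_profile(self):
        dataset = make_abstract_dataset(30, seed=0)
        profile = PredictorProfile("blind", p_detect=0.0, fp_rate=1.0)
        preds = simulate_predictor(dataset, profile, seed=5)
        records = []
        for ss in dataset:
            mine = [p for p in preds if p.struct_id == ss.struct_id]
            records += classify(mine, ss.sites)
        assert tally(records).n_tp == 0

    def test_deterministic(self):
        dataset = make_abstract_dataset(20, seed=1, sites_per_structure=2)
        profile = PredictorProfile()
        a = simulate_predictor(dataset, profile, seed=9)
        b = simulate_predictor(dataset, profile, seed=9)
        assert len(a) == len(b)
        for pa, pb in zip(a, b):
            assert (pa.struct_id, pa.rank, pa.score, pa.residues) == (
                pb.struct_id, pb.rank, pb.score, pb.residues,
            )

    def test_binomial_recall_recovery(self):
        """Measured recall lands within 3 SE of p_detect at n=500."""
        n = 500
        p = 0.8
        dataset = make_abstract_dataset(n, seed=2)
        profile = PredictorProfile("sim", p_detect=p, fp_rate=2.0)
        preds = simulate_predictor(dataset, profile, seed=3)
        report = recover_parameters(dataset, profile, preds=preds)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(report["measured"]["recall"] - p) <= 3 * se

    def test_partial_drop_does_not_reduce_recall(self):
        """One-ligand drops still satisfy the n-1 rule: recall tracks p_detect."""
        dataset = make_abstract_dataset(400, seed=4)
        base = PredictorProfile("a", p_detect=0.7, p_partial=0.0, fp_rate=0.0)
        partial = PredictorProfile("b", p_detect=0.7, p_partial=1.0, fp_rate=0.0)
        r0 = recover_parameters(dataset, base, seed=6)["measured"]["recall"]
        r1 = recover_parameters(dataset, partial, seed=6)["measured"]["recall"]
        se = np.sqrt(0.7 * 0.3 / 400)
        assert abs(r0 - r1) <= 4 * se

    def test_full_informativeness_ranks_tps_first(self):
        dataset = make_abstract_dataset(100, seed=5)
        profile = PredictorProfile("sharp", 1.0, 0.0, 2.0, 0.0, 1.0)
        preds = simulate_predictor(dataset, profile, seed=7)
        counts = SiteCounts.from_sites([s for ss in dataset for s in ss.sites])
        records = []
        for ss in dataset:
            mine = sorted(
                (p for p in preds if p.struct_id == ss.struct_id),
                key=lambda p: p.rank,
            )
            records += classify(mine[:1], ss.sites)
        assert r_top(unique_tp(records), counts, 1) == 100.0

    def test_empty_run_empty_report(self):
        assert recover_parameters([], PredictorProfile()) == {}


class TestMakeBenchmark:
    def test_shapes_and_cles_consistency(self):
        dataset, cles_list = make_benchmark(25, seed=8)
        assert len(dataset) == 25
        site_ids = {s.site_id for ss in dataset for s in ss.sites}
        member_ids = {sid for c in cles_list for sid in c.site_ids}
        assert member_ids == site_ids
        for ss in dataset:
            for site in ss.sites:
                assert not set(site.ligands) & set(ss.decoy_keys)

    def test_sites_extractable_from_coordinates(self):
        """Planted metal positions re-derive the planted ligand sets."""
        dataset, _ = make_benchmark(10, seed=8, noise=ApoNoiseModel(sigma_iso=0.0))
        for ss in dataset:
            for site in ss.sites:
                found = find_ligands(ss.structure, site.metal_pos)
                assert found == set(site.ligands)
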