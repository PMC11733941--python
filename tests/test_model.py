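import numpy as np
import pytest

from dmdgp.geometry import dist
from dmdgp.model import (Conformation, DistanceRestraint, GeometryParams,
                         ModelError, ParseError, build_instance,
                         pruning_pairs, read_restraints, write_restraints)
from dmdgp.order import build_order
from dmdgp.synthetic import sample_conformation


class TestRestraintInvariants:
    def test_role_must_match_span(self):
        with pytest.raises(ValueError):
            DistanceRestraint(2, 11, 4.0, "discretization")
        with pytest.raises(ValueError):
            DistanceRestraint(4, 5, 1.0, "pruning")

    def test_zero_distance_only_for_repeat_span(self):
        DistanceRestraint(7, 10, 0.0, "discretization")  # CA repeat pair
        with pytest.raises(ValueError):
            DistanceRestraint(8, 10, 0.0, "discretization")


class TestSampler:
    def test_discretization_distances_consistent(self, params_jitter):
        conf = sample_conformation(4, params_jitter, seed=9)
        inst = build_instance(conf)
        worst = max(abs(conf.distance(r.i, r.j) - r.value)
                    for r in inst.restraints)
        assert worst <= 1e-9

    def test_repeated_vertices_copy_coordinates(self, params_jitter):
        conf = sample_conformation(5, params_jitter, seed=4)
        for pos in conf.order.repeat_positions:
            first = conf.order.position_of("CA", conf.order[pos].residue)
            assert conf.point(pos) == conf.point(first)

    def test_exact_omega_gives_coplanar_peptide_units(self, params_planar):
        conf = sample_conformation(3, params_planar, seed=1)
        o = conf.order
        for i in (1, 2):
            plane_atoms = [o.position_of("CA", i), o.position_of("C", i),
                           o.position_of("N", i + 1),
                           o.position_of("H", i + 1),
                           o.position_of("CA", i + 1)]
            pts = np.array([conf.point(p) for p in plane_atoms])
            sv = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
            assert sv[-1] <= 1e-6

    def test_same_seed_same_coordinates(self, params_jitter):
        a = sample_conformation(4, params_jitter, seed=77)
        b = sample_conformation(4, params_jitter, seed=77)
        assert a.coords == b.coords

    def test_different_seeds_differ(self, params_jitter):
        a = sample_conformation(4, params_jitter, seed=1)
        b = sample_conformation(4, params_jitter, seed=2)
        assert a.coords != b.coords

    def test_bad_geometry_reported(self):
        # angles at CA violating the spherical triangle inequality:
        # C cannot sit 111 deg from N while 20 deg from HA, with HA
        # itself only 20 deg from N
        bad = GeometryParams(ang_n_ca_ha=20.0, ang_ha_ca_c=20.0)
        from dmdgp.geometry import (DegenerateReferenceError,
                                    InfeasibleGeometryError)
        with pytest.raises((InfeasibleGeometryError,
                            DegenerateReferenceError)):
            sample_conformation(3, bad, seed=0)


class TestBuildInstance:
    def test_default_policy_edges_n3(self, planted):
        _, inst = planted(3, seed=0)
        pairs = sorted((r.i, r.j) for r in inst.pruning_restraints)
        assert pairs == [(2, 8), (2, 11), (3, 7), (8, 14), (9, 13)]

    def test_edge_counts_scale_with_residues(self, params_jitter):
        for n in (3, 5, 8):
            conf = sample_conformation(n, params_jitter, seed=n)
            inst = build_instance(conf)
            labels = [f"{r.kind_i}-{r.j - r.i + 1}-{r.kind_j}"
                      for r in inst.pruning_restraints]
            assert labels.count("HA-7-HA") == n - 1
            assert labels.count("HA-10-H") == n - 2
            assert labels.count("C-5-CA") == n - 1

    def test_pruning_values_measured_from_conformation(self, planted):
        conf, inst = planted(4, seed=3)
        for r in inst.pruning_restraints:
            assert abs(dist(conf.point(r.i), conf.point(r.j)) - r.value) \
                <= 1e-9

    def test_empty_policy_keeps_h2(self, params_jitter):
        conf = sample_conformation(3, params_jitter, seed=0)
        inst = build_instance(conf, policy=())
        assert inst.pruning_restraints == ()
        inst.validate()  # H1/H2 intact


class TestRestraintIO:
    def test_round_trip(self, planted, tmp_path):
        _, inst = planted(4, seed=5)
        path = tmp_path / "inst.tsv"
        write_restraints(inst, path)
        back = read_restraints(path)
        assert sorted((r.i, r.j, round(r.value, 9), r.role)
                      for r in back.restraints) == \
            sorted((r.i, r.j, round(r.value, 9), r.role)
                   for r in inst.restraints)

    def test_missing_h2_restraint_names_vertex(self, planted, tmp_path):
        _, inst = planted(3, seed=5)
        path = tmp_path / "broken.tsv"
        write_restraints(inst, path)
        lines = [ln for ln in path.read_text().splitlines()
                 if not ln.startswith("1\t4\t")]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ModelError, match="vertex 4"):
            read_restraints(path)

    def test_malformed_value_reports_line(self, planted, tmp_path):
        _, inst = planted(3, seed=5)
        path = tmp_path / "bad.tsv"
        write_restraints(inst, path)
        lines = path.read_text().splitlines()
        idx = next(k for k, ln in enumerate(lines)
                   if not ln.startswith("#"))
        parts = lines[idx].split("\t")
        parts[2] = "abc"
        lines[idx] = "\t".join(parts)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ParseError, match=f"line {idx + 1}"):
            read_restraints(path)


class TestConformationIO:
    def test_coordinate_tsv_round_trip(self, planted, tmp_path):
        conf, _ = planted(3, seed=8)
        path = tmp_path / "coords.tsv"
        conf.to_tsv(path)
        back = Conformation.from_tsv(path)
        assert back.order.n_residues == 3
        worst = max(dist(p, q) for p, q in zip(conf.coords, back.coords))
        assert worst <= 1e-5  # 6-decimal TSV precision
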