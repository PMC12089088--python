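"""Coronene-unit substitution generator for the three fractal families."""

import math

import numpy as np
import networkx as nx
import pytest
import sympy

from coronene_fractals import (
    FractalSpec,
    Template,
    build_template,
    closed_form_counts,
    coronene_unit,
    count_perfect_matchings,
    expand_template,
    generate,
    spectrum,
)
from conftest import all_small_specs


class TestFractalSpec:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"family": "XHCF", "n": 1},
            {"family": "ZHCF", "n": 0},
            {"family": "RCF", "n": 1},          # missing m
            {"family": "RCF", "n": 1, "m": 0},
            {"family": "ZHCF", "n": 1, "m": 2},  # stray m
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FractalSpec(**kwargs)


class TestCoroneneUnit:
    def test_counts_and_degree_sequence(self, coronene):
        assert coronene.n_atoms == 24 and coronene.n_bonds == 30
        degs = sorted(coronene.degrees().values())
        assert degs == [2] * 12 + [3] * 12

    def test_edge_partition(self, coronene):
        assert coronene.edge_partition() == {(2, 2): 6, (2, 3): 12, (3, 3): 12}

    def test_fusable_bonds_are_exactly_the_22_bonds(self):
        unit = coronene_unit()
        g = unit.graph()
        deg = g.degrees()
        two_two = {
            b for b in g.bonds if deg[b[0]] == 2 and deg[b[1]] == 2
        }
        fus = {tuple(sorted(pair)) for pair in unit.fusable.values()}
        assert fus == two_two and len(fus) == 6

    def test_kekule_count_is_twenty(self, coronene):
        assert count_perfect_matchings(coronene) == 20


class TestTemplates:
    @pytest.mark.parametrize(
        "spec, nv, ne",
        [
            (FractalSpec("ZHCF", 1), 6, 6),      # benzene
            (FractalSpec("ZHCF", 2), 24, 30),    # coronene skeleton
            (FractalSpec("AHCF", 1), 6, 6),
            (FractalSpec("AHCF", 2), 42, 54),    # hexabenzocoronene skeleton
            (FractalSpec("RCF", 1, 1), 6, 6),
            (FractalSpec("RCF", 2, 2), 20, 24),  # perylene skeleton
        ],
    )
    def test_known_template_skeletons(self, spec, nv, ne):
        t = build_template(spec)
        assert (t.n_vertices, t.n_edges) == (nv, ne)

    @pytest.mark.parametrize("spec", all_small_specs(4))
    def test_template_count_polynomials(self, spec):
        from coronene_fractals.generator import template_counts

        t = build_template(spec)
        assert (t.n_vertices, t.n_edges) == template_counts(spec)

    def test_template_max_degree_three(self):
        t = build_template(FractalSpec("AHCF", 2))
        degree = {}
        for u, v, _ in t.edges:
            degree[u] = degree.get(u, 0) + 1
            degree[v] = degree.get(v, 0) + 1
        assert max(degree.values()) == 3

    def test_template_rejects_non_lattice_edges(self):
        with pytest.raises(ValueError):
            Template(((0, 0), (5, 5)), (((0, 0), (5, 5), 0),))


class TestExpansion:
    def test_two_fused_units(self):
        t = Template(((1, 1), (2, 2)), (((1, 1), (2, 2), 0),))
        g = expand_template(t)
        assert g.n_atoms == 46 and g.n_bonds == 59  # 24*2-2 and 30*2-1

    def test_zhcf1_totals(self):
        g = generate(FractalSpec("ZHCF", 1))
        assert g.n_atoms == 132 and g.n_bonds == 174

    def test_zhcf2_partition(self):
        g = generate(FractalSpec("ZHCF", 2))
        assert g.edge_partition() == {(2, 2): 84, (2, 3): 168, (3, 3): 438}

    @pytest.mark.parametrize("spec", all_small_specs(3))
    def test_generate_matches_closed_forms(self, spec):
        g = generate(spec)
        nv, ne, part = closed_form_counts(spec)
        assert g.n_atoms == nv and g.n_bonds == ne
        assert g.edge_partition() == part

    @pytest.mark.parametrize("spec", all_small_specs(2))
    def test_generated_graphs_are_connected_bipartite_planar_cubic(self, spec):
        g = generate(spec)
        nxg = g.to_networkx()
        assert nx.is_connected(nxg)
        assert nx.is_bipartite(nxg)
        assert nx.check_planarity(nxg)[0]
        assert g.max_degree() == 3

    def test_geometry_bonded_unit_distance_nonbonded_separated(self):
        g = generate(FractalSpec("RCF", 2, 2))
        coords = g.coords
        bonded = set(g.bonds)
        pts = {a: np.array(coords[a]) for a in g.atoms}
        for a, b in bonded:
            assert abs(np.linalg.norm(pts[a] - pts[b]) - 1.0) < 1e-9
        atoms = sorted(g.atoms)
        arr = np.array([pts[a] for a in atoms])
        d2 = np.sum((arr[:, None, :] - arr[None, :, :]) ** 2, axis=-1)
        for i, a in enumerate(atoms):
            for j in range(i + 1, len(atoms)):
                if (a, atoms[j]) not in bonded and (atoms[j], a) not in bonded:
                    assert d2[i, j] > 1.5**2

    def test_size_one_members_of_all_families_are_isomorphic(self):
        spectra = [
            np.round(spectrum(generate(s)), 9)
            for s in (
                FractalSpec("ZHCF", 1),
                FractalSpec("AHCF", 1),
                FractalSpec("RCF", 1, 1),
            )
        ]
        assert np.allclose(spectra[0], spectra[1])
        assert np.allclose(spectra[0], spectra[2])

    def test_swapped_orientation_isomorphic_on_tree_templates(self):
        # single edge and a 3-unit path: the mirror image of one subtree
        # realises the swapped identification
        path3 = Template(
            ((1, 1), (2, 2), (3, 1)),
            (((1, 1), (2, 2), 0), ((2, 2), (3, 1), 5)),
        )
        for t in (Template(((1, 1), (2, 2)), (((1, 1), (2, 2), 0),)), path3):
            a = expand_template(t, orientation="standard")
            b = expand_template(t, orientation="swapped")
            sa = np.linalg.eigvalsh(a.adjacency_matrix().astype(float))
            sb = np.linalg.eigvalsh(b.adjacency_matrix().astype(float))
            assert np.allclose(sa, sb, atol=1e-9)

    def test_swapped_orientation_on_cyclic_template_is_a_twisted_isomer(self):
        # on the 6-cycle template the all-swapped gluing produces a valid
        # (connected, bipartite, count-identical) but non-isomorphic graph;
        # the geometric orientation is therefore pinned in generate()
        t = build_template(FractalSpec("ZHCF", 1))
        a = expand_template(t, orientation="standard")
        b = expand_template(t, orientation="swapped")
        assert (b.n_atoms, b.n_bonds) == (a.n_atoms, a.n_bonds)
        assert b.is_bipartite() and b.is_connected()
        assert not nx.is_isomorphic(a.to_networkx(), b.to_networkx())


class TestClosedForms:
    @pytest.mark.parametrize(
        "spec, nv, ne, part",
        [
            (FractalSpec("ZHCF", 2), 516, 690, {(2, 2): 84, (2, 3): 168, (3, 3): 438}),
            (FractalSpec("AHCF", 1), 132, 174, {(2, 2): 24, (2, 3): 48, (3, 3): 102}),
            (
                FractalSpec("RCF", 3, 5),  # m=5, n=3
                1408,
                1892,
                {(2, 2): 220, (2, 3): 440, (3, 3): 1232},
            ),
        ],
    )
    def test_polynomial_evaluations(self, spec, nv, ne, part):
        assert closed_form_counts(spec) == (nv, ne, part)

    def test_substitution_identities_hold_symbolically(self):
        """24 V_T - 2 E_T and 30 V_T - E_T reproduce the family polynomials."""
        n, m = sympy.symbols("n m")
        cases = {
            "ZHCF": (6 * n**2, 9 * n**2 - 3 * n,
                     126 * n**2 + 6 * n, 171 * n**2 + 3 * n),
            "AHCF": (18 * n**2 - 18 * n + 6, 27 * n**2 - 33 * n + 12,
                     378 * n**2 - 366 * n + 120, 513 * n**2 - 507 * n + 168),
            "RCF": (4 * m * n + 2 * n, 6 * m * n - m + n,
                    84 * m * n + 2 * m + 46 * n, 114 * m * n + m + 59 * n),
        }
        for vt, et, v_poly, e_poly in cases.values():
            assert sympy.expand(24 * vt - 2 * et - v_poly) == 0
            assert sympy.expand(30 * vt - et - e_poly) == 0

    def test_partition_identity_polynomials(self):
        """The (2,2)/(2,3)/(3,3) class polynomials follow from V_T, E_T."""
        n, m = sympy.symbols("n m")
        data = {
            "ZHCF": (6 * n**2, 9 * n**2 - 3 * n,
                     {(2, 2): 18 * n**2 + 6 * n,
                      (2, 3): 36 * n**2 + 12 * n,
                      (3, 3): 117 * n**2 - 15 * n}),
            "AHCF": (18 * n**2 - 18 * n + 6, 27 * n**2 - 33 * n + 12,
                     {(2, 2): 54 * n**2 - 42 * n + 12,
                      (2, 3): 108 * n**2 - 84 * n + 24,
                      (3, 3): 351 * n**2 - 381 * n + 132}),
            "RCF": (4 * m * n + 2 * n, 6 * m * n - m + n,
                    {(2, 2): 12 * m * n + 2 * m + 10 * n,
                     (2, 3): 24 * m * n + 4 * m + 20 * n,
                     (3, 3): 78 * m * n - 5 * m + 29 * n}),
        }
        weights = {(2, 2): (6, -2), (2, 3): (12, -4), (3, 3): (12, 5)}
        for vt, et, partition in data.values():
            for cls, poly in partition.items():
                wv, we = weights[cls]
                assert sympy.expand(wv * vt + we * et - poly) == 0
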