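"""Linker windows, torsion application and full-length construction."""

import numpy as np
import pytest

from domassembly.errors import LayoutError, ValidationError
from domassembly.geometry import rotation_about_axis
from domassembly.kinematics import (apply_torsions, build_base_full_length,
                                    initial_full_length, linker_residues,
                                    measure_torsions, recovery_genes)
from domassembly.structure import (Domain, DomainLayout, extract_domains)
from domassembly.synthetic import build_chain_from_torsions


def two_span_layout():
    return DomainLayout(["A"], [Domain("D1", "A", [(1, 50)]),
                                Domain("D2", "A", [(51, 100)])])


class TestLinkerResidues:
    def test_stated_split_rule(self):
        spec = linker_residues(two_span_layout(), width=8)
        residues = sorted({r for _, r, _ in spec.torsions})
        assert residues == [47, 48, 49, 50, 51, 52, 53, 54]
        assert spec.n_torsion_genes == 16  # phi and psi per residue

    def test_three_domains_two_disjoint_windows(self):
        lay = DomainLayout(["A"], [Domain("D1", "A", [(1, 40)]),
                                   Domain("D2", "A", [(41, 80)]),
                                   Domain("D3", "A", [(81, 120)])])
        spec = linker_residues(lay, width=8)
        residues = sorted({r for _, r, _ in spec.torsions})
        assert residues == [37, 38, 39, 40, 41, 42, 43, 44,
                            77, 78, 79, 80, 81, 82, 83, 84]

    def test_short_domains_overlap_is_layout_error(self):
        lay = DomainLayout(["A"], [Domain("D1", "A", [(1, 4)]),
                                   Domain("D2", "A", [(5, 8)]),
                                   Domain("D3", "A", [(9, 12)])])
        with pytest.raises(LayoutError):
            linker_residues(lay, width=8)

    def test_odd_width_rejected(self):
        with pytest.raises(ValidationError):
            linker_residues(two_span_layout(), width=7)

    def test_non_anchor_chains_get_slots(self, two_chain):
        _, layout = two_chain
        spec = linker_residues(layout, width=8)
        assert spec.chain_slots == ["B"]
        assert spec.n_genes == spec.n_torsion_genes + 6


class TestApplyTorsions:
    def test_zero_vector_is_identity(self, two_domain):
        target, layout = two_domain
        spec = linker_residues(layout, width=8)
        out = apply_torsions(target, spec, np.zeros(spec.n_genes))
        assert np.allclose(out.coords, target.coords, atol=1e-9,
                           equal_nan=True)

    def test_rigid_cores_preserved_under_any_vector(self, three_domain, rng):
        """Residues outside the movable windows keep all pairwise CA
        distances exactly (domains move as rigid bodies)."""
        target, layout = three_domain
        spec = linker_residues(layout, width=8)
        windows = spec.window_residues()
        out = apply_torsions(target, spec,
                             rng.uniform(-np.pi, np.pi, spec.n_genes))
        for dom in layout.domains:
            idx = [i for i in range(len(target))
                   if target.domain_labels[i] == dom.id
                   and (target.chain_ids[i],
                        int(target.res_nums[i])) not in windows]
            a = target.ca[idx]
            b = out.ca[idx]
            da_ = np.linalg.norm(a[:, None] - a[None, :], axis=2)
            db_ = np.linalg.norm(b[:, None] - b[None, :], axis=2)
            assert np.allclose(da_, db_, atol=1e-9)

    def test_single_phi_matches_axis_angle_oracle(self):
        st = build_chain_from_torsions([0, -57, -57], [-47, -47, 180])
        from domassembly.kinematics import LinkerSpec
        spec = LinkerSpec([("A", 2, "phi")])
        offset = np.deg2rad(60.0)
        out = apply_torsions(st, spec, np.array([offset]))
        n, ca = st.coords[1, 0], st.coords[1, 1]
        R = rotation_about_axis(ca - n, offset)
        expected = (st.coords[2].reshape(-1, 3) - ca) @ R.T + ca
        assert np.allclose(out.coords[2].reshape(-1, 3), expected, atol=1e-9)
        # residue 2's own C/O/CB rotate with phi; N and CA stay put
        assert np.allclose(out.coords[1, :2], st.coords[1, :2], atol=1e-12)
        assert np.allclose(out.coords[1, 2], R @ (st.coords[1, 2] - ca) + ca,
                           atol=1e-9)

    def test_offsets_add_to_measured_dihedrals(self, two_domain, rng):
        target, layout = two_domain
        spec = linker_residues(layout, width=8)
        v = rng.uniform(-1.0, 1.0, spec.n_genes)
        out = apply_torsions(target, spec, v)
        before = measure_torsions(target, spec)
        after = measure_torsions(out, spec)
        from domassembly.frames import wrap_angle
        assert np.allclose(wrap_angle(after - before),
                           wrap_angle(v[:spec.n_torsion_genes]), atol=1e-9)

    def test_group_action(self, two_domain, rng):
        target, layout = two_domain
        spec = linker_residues(layout, width=8)
        v = rng.uniform(-0.8, 0.8, spec.n_genes)
        w = rng.uniform(-0.8, 0.8, spec.n_genes)
        one = apply_torsions(apply_torsions(target, spec, v), spec, w)
        both = apply_torsions(target, spec, v + w)
        assert np.allclose(one.coords, both.coords, atol=1e-6,
                           equal_nan=True)

    def test_wrong_length_rejected(self, two_domain):
        target, layout = two_domain
        spec = linker_residues(layout, width=8)
        with pytest.raises(ValidationError):
            apply_torsions(target, spec, np.zeros(spec.n_genes + 1))


class TestFullLength:
    def test_single_domain_returned_unchanged(self):
        dom = build_chain_from_torsions([-57] * 12, [-47] * 12)
        lay = DomainLayout(["A"], [Domain("D1", "A", [(1, 12)])])
        dom = lay.attach(dom)
        out = initial_full_length([dom], lay, rng_seed=0)
        assert np.allclose(out.coords, dom.coords, equal_nan=True)

    def test_junction_bond_is_ideal(self, two_domain):
        target, layout = two_domain
        parts = extract_domains(target, layout)
        base = build_base_full_length(parts, layout)
        junctions = 0
        for chain, _, _, jres in layout.boundaries():
            idx = base.residue_index()
            c = base.coords[idx[(chain, jres)], 2]
            n = base.coords[idx[(chain, jres + 1)], 0]
            assert abs(np.linalg.norm(n - c) - 1.329) < 1e-6
            junctions += 1
        assert junctions == 1

    def test_seed_determinism_and_variation(self, two_domain):
        target, layout = two_domain
        parts = extract_domains(target, layout)
        a = initial_full_length(parts, layout, rng_seed=7)
        b = initial_full_length(parts, layout, rng_seed=7)
        c = initial_full_length(parts, layout, rng_seed=8)
        assert np.array_equal(a.coords, b.coords)
        assert not np.allclose(a.coords, c.coords, equal_nan=True)

    def test_mismatched_layout_rejected(self, two_domain):
        target, layout = two_domain
        parts = extract_domains(target, layout)
        with pytest.raises(LayoutError):
            build_base_full_length(parts[:1], layout)

    def test_recovery_genes_restore_target(self, three_domain):
        target, layout = three_domain
        parts = extract_domains(target, layout)
        base = build_base_full_length(parts, layout)
        spec = linker_residues(layout, width=8)
        rec = apply_torsions(base, spec, recovery_genes(base, target, spec))
        assert np.allclose(rec.coords, target.coords, atol=1e-6,
                           equal_nan=True)
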