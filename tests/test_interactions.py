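"""Interaction maps: oracle, binning, decoding, file round trips."""

import numpy as np
import pytest

from domassembly.errors import (DegenerateInputError, InteractionFormatError,
                                ValidationError)
from domassembly.interactions import (DEFAULT_BLUR, ELEMENTS, BinScheme,
                                      InteractionMap, decode_distributions,
                                      discretize_targets,
                                      oracle_targets_from_structure,
                                      read_interactions, write_interactions)
from domassembly.structure import Domain, DomainLayout
from domassembly.synthetic import build_chain_from_torsions


@pytest.fixture(scope="module")
def scheme():
    return BinScheme.default()


@pytest.fixture(scope="module")
def toy_two_by_five():
    """Two 5-residue 'domains' on one short chain, all CAs within 40 A."""
    st = build_chain_from_torsions([-120] * 10, [120] * 10)
    layout = DomainLayout(["A"], [Domain("D1", "A", [(1, 5)]),
                                  Domain("D2", "A", [(6, 10)])])
    return layout.attach(st), layout


class TestOracle:
    def test_pair_count_is_brute_force_enumeration(self, toy_two_by_five):
        st, layout = toy_two_by_five
        m = oracle_targets_from_structure(st, layout, r_max=40.0)
        assert len(m) == 2 * 5 * 5  # ordered pairs across two 5-residue sets

    def test_both_orderings_emitted(self, toy_two_by_five):
        st, layout = toy_two_by_five
        m = oracle_targets_from_structure(st, layout, r_max=40.0)
        pairs = {tuple(p) for p in m.pairs}
        assert all((j, i) in pairs for i, j in pairs)

    def test_r_equals_ca_distance(self, two_domain, two_domain_oracle):
        target, _ = two_domain
        m = two_domain_oracle
        ca = target.ca
        d = np.linalg.norm(ca[m.pairs[:, 0]] - ca[m.pairs[:, 1]], axis=1)
        assert np.allclose(m.values[:, 3], d, atol=1e-9)

    def test_r_max_zero_degenerate(self, toy_two_by_five):
        st, layout = toy_two_by_five
        with pytest.raises(DegenerateInputError):
            oracle_targets_from_structure(st, layout, r_max=0.0)


class TestDiscretize:
    def test_zero_blur_is_delta_on_containing_bin(self, scheme):
        m = InteractionMap(np.array([[0, 1]]), "mode", [("A", 1), ("A", 2)],
                           values=np.array([[0.1, 0.2, 0.3, 7.3, 1.0, 0.5]]))
        d = discretize_targets(m, scheme, 0.0)
        r_row = d.dist["r"][0]
        bin_idx = int(np.argmax(r_row))
        assert r_row[bin_idx] == 1.0
        lo, hi = scheme.edges["r"][bin_idx], scheme.edges["r"][bin_idx + 1]
        assert lo <= 7.3 < hi and (lo, hi) == (7.0, 8.0)

    def test_blurred_rows_normalized(self, two_domain_oracle, scheme):
        d = discretize_targets(two_domain_oracle, scheme, DEFAULT_BLUR)
        for el in ELEMENTS:
            assert np.allclose(d.dist[el].sum(axis=1), 1.0, atol=1e-6)

    def test_quantization_error_at_most_half_bin(self, two_domain_oracle,
                                                 scheme):
        d = discretize_targets(two_domain_oracle, scheme, 0.0)
        back = decode_distributions(d, scheme)
        assert len(back) == len(two_domain_oracle)
        for col, el in enumerate(ELEMENTS):
            half = np.max(scheme.half_widths(el))
            err = np.abs(back.values[:, col]
                         - two_domain_oracle.values[:, col])
            if el in ("alpha", "gamma", "phi"):
                err = np.minimum(err, 2 * np.pi - err)
            assert np.all(err <= half + 1e-9), el

    def test_value_outside_domain_rejected(self, scheme):
        m = InteractionMap(np.array([[0, 1]]), "mode", [("A", 1), ("A", 2)],
                           values=np.array([[0, 0, 0, 1.0, 0.2, 0.1]]))
        with pytest.raises(ValidationError):
            discretize_targets(m, scheme, 0.0)  # r = 1.0 below first edge


class TestDecode:
    def test_uniform_r_distribution_ties_to_lowest_bin(self, scheme):
        nb = {el: scheme.n_bins(el) for el in ELEMENTS}
        dist = {el: np.full((1, nb[el]), 1.0 / nb[el]) for el in ELEMENTS}
        m = InteractionMap(np.array([[0, 1]]), "dist", [("A", 1), ("A", 2)],
                           dist=dist, scheme=scheme)
        out = decode_distributions(m, scheme)
        assert np.isclose(out.values[0, 3], 2.5)  # midpoint of [2, 3)

    def test_overflow_argmax_drops_pair(self, scheme):
        nb = {el: scheme.n_bins(el) for el in ELEMENTS}
        dist = {el: np.zeros((2, nb[el])) for el in ELEMENTS}
        for el in ELEMENTS:
            dist[el][:, 1] = 1.0
        dist["r"][1] = 0.0
        dist["r"][1, scheme.overflow_bin()] = 1.0
        m = InteractionMap(np.array([[0, 1], [1, 0]]), "dist",
                           [("A", 1), ("A", 2)], dist=dist, scheme=scheme)
        out = decode_distributions(m, scheme)
        assert len(out) == 1 and tuple(out.pairs[0]) == (0, 1)

    def test_negative_mass_rejected(self, scheme):
        nb = {el: scheme.n_bins(el) for el in ELEMENTS}
        dist = {el: np.zeros((1, nb[el])) for el in ELEMENTS}
        for el in ELEMENTS:
            dist[el][0, 0] = 1.0
        m = InteractionMap(np.array([[0, 1]]), "dist", [("A", 1), ("A", 2)],
                           dist=dist, scheme=scheme)
        m.dist["r"][0, 2] = -0.5
        with pytest.raises(ValidationError):
            decode_distributions(m, scheme)


class TestFileRoundTrip:
    def test_mode_round_trip_exact_keys_close_values(self, tmp_path,
                                                     two_domain_oracle):
        p = tmp_path / "m.tsv"
        write_interactions(two_domain_oracle, p)
        back = read_interactions(p)
        assert back.dialect == "mode"
        assert np.array_equal(back.pairs, two_domain_oracle.pairs)
        assert np.allclose(back.values, two_domain_oracle.values, atol=1e-6)
        assert back.index_map == two_domain_oracle.index_map

    def test_empty_map_round_trip(self, tmp_path):
        m = InteractionMap(np.empty((0, 2), dtype=int), "mode",
                           [("A", 1)], values=np.empty((0, 6)))
        p = tmp_path / "empty.tsv"
        write_interactions(m, p)
        back = read_interactions(p)
        assert len(back) == 0 and back.dialect == "mode"

    def test_sparse_dist_rows_reconstruct_distributions(self, tmp_path,
                                                        two_domain_oracle,
                                                        scheme):
        d = discretize_targets(two_domain_oracle, scheme, DEFAULT_BLUR)
        p = tmp_path / "d.tsv"
        write_interactions(d, p)
        back = read_interactions(p)
        assert back.dialect == "dist"
        key = lambda m: {tuple(pr): k for k, pr in enumerate(m.pairs)}
        kd, kb = key(d), key(back)
        for pair, row_d in kd.items():
            row_b = kb[pair]
            for el in ELEMENTS:
                assert np.allclose(back.dist[el][row_b], d.dist[el][row_d],
                                   atol=1e-6)

    def test_malformed_row_reports_line_number(self, tmp_path,
                                               two_domain_oracle):
        p = tmp_path / "bad.tsv"
        write_interactions(two_domain_oracle, p)
        lines = p.read_text().splitlines()
        first_data = next(i for i, ln in enumerate(lines)
                          if not ln.startswith("#"))
        lines[first_data] = "0\t1\tnot_a_number"
        p.write_text("\n".join(lines) + "\n")
        with pytest.raises(InteractionFormatError) as exc:
            read_interactions(p)
        assert exc.value.line == first_data + 1
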