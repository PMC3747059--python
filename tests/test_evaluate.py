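import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octabarrel import reference as ref
from octabarrel._sasa import atom_sasa, golden_spiral_points
from octabarrel.evaluate import (
    CompositionProfile,
    category_profile,
    compare_to_control,
    composition,
    evaluate_model,
    helix_segment_count,
    hydrophobic_patches,
    ramachandran,
    report_to_json,
    sasa,
    sasa_probability,
    ss_score,
)
from octabarrel.fixtures import ideal_helix_model
from octabarrel.geometry import build_backbone
from octabarrel.secstruct import SSAssignment, SSPrediction
from octabarrel.structmodel import StructureModel


def _pred(rows):
    return SSPrediction(probs=np.array(rows))


def _assign(states):
    return SSAssignment(states=states, hbonds=[])


class TestSSScore:
    def test_perfect_agreement_scores_minus_one(self):
        pred = _pred([[1.0, 0.0, 0.0]] * 4)
        assert ss_score(pred, _assign("HHHH")).score == pytest.approx(-1.0)

    def test_random_baseline_scores_zero(self):
        pred = _pred([[0.33, 0.33, 0.34]] * 3)
        assert ss_score(pred, _assign("HHH")).score == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_mixture(self):
        # P of assigned state: 1.0, 0.33, 0.665 -> s = 1, 0, 0.5 -> score -0.5
        pred = _pred([[1.0, 0.0, 0.0],
                      [0.33, 0.37, 0.30],
                      [0.20, 0.135, 0.665]])
        assert ss_score(pred, _assign("HHL")).score == pytest.approx(-0.5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ss_score(_pred([[1, 0, 0]]), _assign("HH"))

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0.001, 1), st.floats(0.001, 1),
                              st.floats(0.001, 1)),
                    min_size=1, max_size=30),
           st.integers(0, 2 ** 30))
    def test_score_bounds(self, raw, state_seed):
        probs = np.array(raw)
        probs /= probs.sum(axis=1, keepdims=True)
        rng = np.random.default_rng(state_seed)
        states = "".join(rng.choice(list("HEL"), size=len(raw)))
        score = ss_score(SSPrediction(probs=probs), _assign(states)).score
        assert -1.0 - 1e-9 <= score <= 0.33 / 0.67 + 1e-9


class TestComposition:
    def test_pure_glycine(self):
        comp = composition("GGGG")
        assert comp.fractions["G"] == 100.0
        assert all(v == 0.0 for a, v in comp.fractions.items() if a != "G")

    def test_two_residues(self):
        comp = composition("AG")
        assert comp.fractions["A"] == 50.0
        assert comp.fractions["G"] == 50.0

    def test_percentages_sum_to_hundred(self, designed):
        comp = composition(designed.sequence)
        assert sum(comp.fractions.values()) == pytest.approx(100.0, abs=1e-9)
        # each of the 20 entries contributes at most 0.05 rounding error
        rounded = sum(round(v, 1) for v in comp.fractions.values())
        assert abs(rounded - 100.0) <= 1.0

    def test_invalid_input(self):
        with pytest.raises(ValueError):
            composition("")
        with pytest.raises(ValueError):
            composition("AXB")


class TestCategories:
    def test_published_category_arithmetic(self):
        comp = CompositionProfile(fractions=dict(ref.OCTARELLIN_VI_COMPOSITION),
                                  n_res=ref.OCTARELLIN_VI_N_RES)
        cats = category_profile(comp).values
        assert cats["aromatic"] == 20.4
        assert cats["charged"] == 16.7

    def test_all_zero_profile(self):
        comp = CompositionProfile(fractions={a: 0.0 for a in "ACDEFGHIKLMNPQRSTVWY"},
                                  n_res=0)
        assert all(v == 0.0 for v in category_profile(comp).values.values())

    def test_category_sum_rules(self, designed):
        cats = category_profile(composition(designed.sequence)).values
        assert cats["charged"] == pytest.approx(
            cats["negative"] + cats["positive"], abs=0.1)
        assert cats["polar_charged"] == pytest.approx(
            cats["polar"] + cats["charged"], abs=0.1)


class TestControlComparison:
    def test_glycine_excess_flagged(self):
        comp = CompositionProfile(fractions=dict(ref.OCTARELLIN_VI_COMPOSITION),
                                  n_res=216)
        entries = {e["name"]: e for e in compare_to_control(comp)}
        assert entries["G"]["z"] == pytest.approx((18.1 - 7.4) / 1.7, abs=0.01)
        assert entries["G"]["flagged"]
        assert entries["W"]["z"] == pytest.approx((5.6 - 1.7) / 1.1, abs=0.01)
        assert entries["W"]["flagged"]

    def test_value_at_mean_is_unflagged(self):
        fractions = {a: m for a, (m, _) in ref.CONTROL_COMPOSITION.items()}
        comp = CompositionProfile(fractions=fractions, n_res=100)
        for e in compare_to_control(comp):
            assert e["z"] == pytest.approx(0.0, abs=1e-9)
            assert not e["flagged"]

    def test_category_flags(self):
        comp = CompositionProfile(fractions=dict(ref.OCTARELLIN_VI_COMPOSITION),
                                  n_res=216)
        entries = {e["name"]: e for e in
                   compare_to_control(category_profile(comp))}
        assert entries["aromatic"]["flagged"]
        assert entries["small"]["flagged"]


class TestSasa:
    def test_isolated_residue_fully_exposed(self):
        coords = build_backbone(np.array([-120.0]), np.array([130.0]))
        m = StructureModel(coords=coords, seq="F")
        prof = sasa(m)
        assert prof.relative[0] >= 0.95

    def test_enclosed_atom_is_buried(self):
        shell = golden_spiral_points(80) * 2.5
        centers = np.vstack([[0.0, 0.0, 0.0], shell])
        radii = np.full(len(centers), 1.7)
        areas = atom_sasa(centers, radii, probe=1.4, points=960)
        assert areas[0] < 1.0

    def test_point_count_convergence(self, barrel, designed):
        p1 = sasa(barrel, designed.sequence, points=960)
        p2 = sasa(barrel, designed.sequence, points=1920)
        rel = (np.abs(p1.absolute - p2.absolute).mean()
               / p2.absolute.mean())
        assert rel < 0.02

    def test_occluding_neighbor_monotonicity(self):
        base = np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
        radii = np.array([1.7, 1.7])
        before = atom_sasa(base, radii, points=960)
        withn = atom_sasa(np.vstack([base, [[2.0, 2.0, 0.0]]]),
                          np.array([1.7, 1.7, 1.7]), points=960)
        assert withn[0] <= before[0] + 1e-9
        assert withn[1] <= before[1] + 1e-9

    def test_relative_range(self, barrel, designed):
        prof = sasa(barrel, designed.sequence, points=480)
        assert np.all(prof.absolute >= 0.0)
        assert np.all(prof.relative >= 0.0) and np.all(prof.relative <= 1.2)


class TestSasaProbability:
    def test_uniform_table_limits(self, barrel, designed):
        prof = sasa(barrel, designed.sequence, points=240)
        uniform = np.full((20, 5), 1.0 / 100.0)
        probs = sasa_probability(prof, designed.sequence, table=uniform)
        assert probs["mean_p_aa_given_bin"] == pytest.approx(1 / 20)
        assert probs["mean_p_bin_given_aa"] == pytest.approx(1 / 5)

    def test_buried_phe_more_probable_than_exposed(self, barrel):
        prof = sasa(barrel, "F" * len(barrel), points=240)
        probs = sasa_probability(prof, "F" * len(barrel))
        buried = prof.relative < 0.1
        exposed = prof.relative > 0.5
        assert buried.any() and exposed.any()
        assert (probs["p_bin_given_aa"][buried].mean()
                > probs["p_bin_given_aa"][exposed].mean())

    def test_aggregates_in_unit_interval(self, barrel, designed):
        prof = sasa(barrel, designed.sequence, points=240)
        probs = sasa_probability(prof, designed.sequence)
        assert 0.0 <= probs["mean_p_aa_given_bin"] <= 1.0
        assert 0.0 <= probs["mean_p_bin_given_aa"] <= 1.0


class TestPatches:
    def test_all_polar_surface_is_empty(self, barrel):
        prof = sasa(barrel, "S" * len(barrel), points=240)
        report = hydrophobic_patches(barrel, "S" * len(barrel), prof)
        assert report.patches == []
        assert report.total_area == 0.0

    def test_constructed_leucine_cluster(self, barrel, regions):
        surface = regions.positions("surface")
        # three sequence-adjacent surface residues on one helix
        trio = None
        for i in surface:
            if i + 1 in surface and i + 2 in surface and barrel.ss3[i] == "H":
                trio = [i, i + 1, i + 2]
                break
        assert trio is not None
        seq = list("S" * len(barrel))
        for i in trio:
            seq[i] = "L"
        seq = "".join(seq)
        prof = sasa(barrel, seq, points=240)
        report = hydrophobic_patches(barrel, seq, prof, min_area=10.0)
        assert len(report.patches) == 1
        assert report.patches[0][0] == trio

    def test_matches_brute_force_union_find(self, barrel, designed):
        from octabarrel.structmodel import pseudo_cb_array
        from octabarrel.tables import HYDROPHOBIC_AA
        prof = sasa(barrel, designed.sequence, points=240)
        report = hydrophobic_patches(barrel, designed.sequence, prof,
                                     min_area=0.0)
        nodes = [i for i in range(len(barrel))
                 if designed.sequence[i] in HYDROPHOBIC_AA
                 and prof.relative[i] > 0.25]
        parent = {i: i for i in nodes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        cb = pseudo_cb_array(barrel)
        for a in nodes:
            for b in nodes:
                if a < b and np.linalg.norm(cb[a] - cb[b]) < 8.0:
                    parent[find(a)] = find(b)
        comps = {}
        for i in nodes:
            comps.setdefault(find(i), set()).add(i)
        expect = sorted(sorted(c) for c in comps.values())
        got = sorted(members for members, _ in report.patches)
        assert got == expect


class TestRamachandran:
    def test_ideal_helix_all_favored(self):
        m = ideal_helix_model(12)
        rep = ramachandran(m)
        assert rep.percentages["favored"] == 100.0

    def test_left_handed_extended_nongly_is_outlier(self):
        from octabarrel.evaluate import _rama_class
        assert _rama_class(60.0, 180.0, is_gly=False) == "outlier"
        assert _rama_class(-57.0, -47.0, is_gly=False) == "favored"
        assert _rama_class(-120.0, 135.0, is_gly=False) == "favored"

    def test_glycine_gets_mirrored_boxes(self):
        from octabarrel.evaluate import _rama_class
        assert _rama_class(57.0, 47.0, is_gly=True) == "favored"

    def test_two_residue_chain_empty_report(self):
        coords = build_backbone(np.full(2, -60.0), np.full(2, -45.0))
        m = StructureModel(coords=coords, seq="AA")
        rep = ramachandran(m)
        assert rep.classes == []
        assert rep.note != ""

    def test_barrel_mostly_favored(self, barrel):
        rep = ramachandran(barrel)
        assert rep.percentages["favored"] >= 70.0


class TestHelixSegments:
    @pytest.mark.parametrize("density,n,expect", [
        (3.8, 216, 8.2),
        (0.0, 216, 0.0),
        (3.8, 100, 3.8),
    ])
    def test_cases(self, density, n, expect):
        assert helix_segment_count(density, n) == expect

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            helix_segment_count(-1.0, 100)


class TestReport:
    def test_report_has_all_sections(self, barrel, designed):
        rep = evaluate_model(barrel, designed.sequence, points=240)
        for section in ("energy", "secondary_structure", "composition",
                        "control_comparison", "sasa", "patches",
                        "ramachandran"):
            assert section in rep

    def test_builtin_predictor_flagged(self, barrel, designed):
        rep = evaluate_model(barrel, designed.sequence, points=240)
        assert rep["secondary_structure"]["builtin_predictor"] is True

    def test_rerun_is_byte_identical(self, barrel, designed):
        a = report_to_json(evaluate_model(barrel, designed.sequence, points=240))
        b = report_to_json(evaluate_model(barrel, designed.sequence, points=240))
        assert a == b
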