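"""The seven substitution features: values, symmetries, exclusions."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ddgfeat import (
    AMINO_ACIDS,
    ConservationProfile,
    ResourceBundle,
    StructureModel,
    ToyStructureSpec,
    VariantExclusion,
    VariantRecord,
    bastolla_vendruscolo_diff,
    blosum_score,
    compute_feature_table,
    compute_feature_vector,
    conservation_log_ratio,
    generate_profile,
    generate_test_matrices,
    generate_toy_structure,
    hydrophobicity_difference,
    read_variant_table,
    relative_accessibility,
    skolnick_potential_diff,
    volume_difference,
)
from ddgfeat.features import (
    KYTE_DOOLITTLE,
    MAX_ASA,
    RESIDUE_VOLUME,
    _ResidueData,
    load_blosum62,
    read_substitution_matrix,
)
from ddgfeat.synthetic_data import write_substitution_matrix

ALL_PAIRS = list(itertools.permutations(AMINO_ACIDS, 2))  # 380 ordered pairs


class TestScalarFeatures:
    def test_hydrophobicity_matches_scale_lookup(self):
        """Ile->Arg equals the direct subtraction of published hydropathies."""
        assert hydrophobicity_difference("I", "R") == pytest.approx(
            KYTE_DOOLITTLE["I"] - KYTE_DOOLITTLE["R"]
        )

    def test_hydrophobicity_identity_and_antisymmetry(self):
        assert hydrophobicity_difference("A", "A") == 0.0
        for wt, mut in ALL_PAIRS:
            assert hydrophobicity_difference(wt, mut) == -hydrophobicity_difference(mut, wt)

    def test_hydrophobicity_orientation_flag(self):
        assert hydrophobicity_difference("I", "R", wt_minus_mut=False) == pytest.approx(
            -(KYTE_DOOLITTLE["I"] - KYTE_DOOLITTLE["R"])
        )

    def test_missing_residue_in_scale_errors(self):
        with pytest.raises(KeyError):
            hydrophobicity_difference("A", "V", scale={"A": 1.8})

    def test_volume_matches_table_for_all_pairs(self):
        """Brute force over all 380 ordered pairs against the volume table."""
        for wt, mut in ALL_PAIRS:
            assert volume_difference(wt, mut) == pytest.approx(
                RESIDUE_VOLUME[mut] - RESIDUE_VOLUME[wt]
            )

    def test_volume_orientation_small_to_large_positive(self):
        grows = volume_difference("G", "W")
        shrinks = volume_difference("W", "G")
        assert grows > 0
        assert shrinks == -grows

    def test_blosum_symmetric_for_all_pairs(self):
        m = load_blosum62()
        for wt, mut in ALL_PAIRS:
            assert blosum_score(wt, mut, m) == blosum_score(mut, wt, m)

    def test_blosum_file_round_trip_all_cells(self, tmp_path):
        """Every cell of a written matrix file equals the in-memory value."""
        sub, _, _ = generate_test_matrices(seed=5)
        path = tmp_path / "m.mat"
        write_substitution_matrix(sub, path)
        back = read_substitution_matrix(path)
        for wt, mut in itertools.product(AMINO_ACIDS, repeat=2):
            assert blosum_score(wt, mut, back) == blosum_score(wt, mut, sub)

    def test_constant_matrix_gives_constant_score(self):
        from Bio.Align import substitution_matrices

        const = substitution_matrices.Array(alphabet=AMINO_ACIDS, dims=2)
        const += 3.0
        for wt, mut in ALL_PAIRS[:40]:
            assert blosum_score(wt, mut, const) == 3.0


class TestConservation:
    def test_equal_frequencies_give_zero(self):
        prof = generate_profile("ACD", conservation_level=1 / 20)
        assert conservation_log_ratio(prof, 1, "A", "C") == pytest.approx(0.0)

    def test_hand_computed_extreme_case(self):
        """CONS_W=0.99, CONS_M=0 -> ln(1.00/0.01) = ln 100 with eps=0.01."""
        freqs = pd.DataFrame(
            [{aa: 0.0 for aa in AMINO_ACIDS} | {"A": 0.99, "position": "1"}]
        ).set_index("position")
        prof = ConservationProfile(freqs=freqs)
        assert conservation_log_ratio(prof, 1, "A", "C") == pytest.approx(
            math.log(100.0), abs=1e-10
        )

    def test_swap_negates(self):
        prof = generate_profile("ACDEF", conservation_level=0.7)
        v = conservation_log_ratio(prof, 3, "D", "W")
        assert conservation_log_ratio(prof, 3, "W", "D") == pytest.approx(-v)

    def test_monotone_in_frequencies(self):
        """Increasing CONS_W raises the ratio; increasing CONS_M lowers it."""
        vals = []
        for cw in (0.2, 0.5, 0.8):
            freqs = pd.DataFrame(
                [{aa: 0.0 for aa in AMINO_ACIDS} | {"A": cw, "C": 0.1, "position": "1"}]
            ).set_index("position")
            vals.append(conservation_log_ratio(ConservationProfile(freqs), 1, "A", "C"))
        assert vals == sorted(vals)

    def test_missing_position_is_nan(self, caplog):
        prof = generate_profile("ACD", conservation_level=0.5)
        with caplog.at_level("WARNING"):
            assert math.isnan(conservation_log_ratio(prof, 99, "A", "C"))


class TestAccessibility:
    def test_buried_and_clipped_limits(self):
        dssp = {("A", "1"): (0.0, "A"), ("A", "2"): (2 * MAX_ASA["G"], "G")}
        assert relative_accessibility(dssp, "A", 1) == 0.0
        assert relative_accessibility(dssp, "A", 2) == 1.0

    def test_terminal_residues_more_exposed_than_central(self, toy_extended):
        model, _ = toy_extended
        first = relative_accessibility(model, "A", 1)
        central = relative_accessibility(model, "A", 4)
        last = relative_accessibility(model, "A", 7)
        assert first > central
        assert last > central
        assert 0.0 <= central <= 1.0

    def test_swap_invariance(self, toy_extended):
        """Accessibility depends on the wild-type site only, never the mutant."""
        model, _ = toy_extended
        v = relative_accessibility(model, "A", 2)
        assert relative_accessibility(model, "A", 2) == v

    def test_unresolvable_residue_excluded(self, toy_extended):
        model, _ = toy_extended
        with pytest.raises(VariantExclusion, match="3D neighbors"):
            relative_accessibility(model, "A", 99)


class TestSkolnick:
    def test_identity_substitution_cancels(self, hand_potential):
        assert skolnick_potential_diff("ACDEF", 2, "D", "D", hand_potential) == 0.0

    def test_hand_summed_window(self, hand_potential):
        """5-residue toy sequence: value equals the four hand-summed terms."""
        seq = "ACDEF"
        wt, mut = "D", "W"
        expected = sum(
            hand_potential(wt, seq[2 + off]) - hand_potential(mut, seq[2 + off])
            for off in (-2, -1, 1, 2)
        )
        got = skolnick_potential_diff(seq, 2, wt, mut, hand_potential)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_window_truncated_at_terminus(self, hand_potential):
        seq = "ACDEF"
        expected = sum(
            hand_potential("A", seq[0 + off]) - hand_potential("W", seq[0 + off])
            for off in (1, 2)
        )
        assert skolnick_potential_diff(seq, 0, "A", "W", hand_potential) == pytest.approx(expected)

    def test_antisymmetry_over_pairs(self, hand_potential):
        for wt, mut in ALL_PAIRS[::19]:
            v = skolnick_potential_diff("MKTAYIAK", 3, wt, mut, hand_potential)
            assert skolnick_potential_diff("MKTAYIAK", 3, mut, wt, hand_potential) == pytest.approx(-v)

    def test_out_of_range_index_errors(self, hand_potential):
        with pytest.raises(IndexError):
            skolnick_potential_diff("ACD", 5, "A", "V", hand_potential)


def two_residue_model(separation: float) -> StructureModel:
    """Two single-atom residues (Ala, Trp) at a controlled distance."""
    model = StructureModel(name="pair")
    model.residues[("A", "1")] = _ResidueData("A", np.array([[0.0, 0.0, 0.0]]))
    model.residues[("A", "2")] = _ResidueData("W", np.array([[separation, 0.0, 0.0]]))
    model.chain_order["A"] = ["1", "2"]
    return model


class TestBastollaVendruscolo:
    def test_identity_substitution_cancels(self, hand_potential):
        model = two_residue_model(4.0)
        assert bastolla_vendruscolo_diff(model, "A", 1, "A", "A", hand_potential) == 0.0

    def test_single_neighbor_hand_computation(self, hand_potential):
        """Two residues 4 A apart: exactly bv(wt, W) - bv(mut, W)."""
        model = two_residue_model(4.0)
        got = bastolla_vendruscolo_diff(model, "A", 1, "A", "V", hand_potential)
        assert got == pytest.approx(hand_potential("A", "W") - hand_potential("V", "W"), abs=1e-12)

    def test_empty_neighborhood_gives_zero(self, hand_potential):
        model = two_residue_model(6.0)
        assert bastolla_vendruscolo_diff(model, "A", 1, "A", "V", hand_potential) == 0.0

    def test_neighborhood_membership_is_symmetric(self, hand_potential):
        """j in I(k) iff k in I(j) under the minimal-distance rule."""
        spec = ToyStructureSpec(sequence="ACDEFGHIKL", mode="ideal-helix")
        model, _ = generate_toy_structure(spec)
        for (_, pos_k) in list(model.residues):
            for (_, pos_j) in model.neighbors_within("A", pos_k, radius=5.0):
                back = model.neighbors_within("A", pos_j, radius=5.0)
                assert ("A", pos_k) in back

    def test_absent_residue_excluded(self, hand_potential, toy_extended):
        model, _ = toy_extended
        with pytest.raises(VariantExclusion, match="3D neighbors"):
            bastolla_vendruscolo_diff(model, "A", 99, "A", "V", hand_potential)


@pytest.fixture(scope="module")
def bundle(fixture_study):
    return ResourceBundle(
        blosum=read_substitution_matrix(fixture_study["blosum"]),
        skolnick=__import__("ddgfeat").PairPotential.read_tsv(fixture_study["skolnick"]),
        bv=__import__("ddgfeat").PairPotential.read_tsv(fixture_study["bv"], role="structural"),
        structures={
            p.stem: StructureModel.from_pdb(p)
            for p in fixture_study["structures"].glob("*.pdb")
        },
        profiles={
            p.stem: ConservationProfile.read_tsv(p)
            for p in fixture_study["profiles"].glob("*.tsv")
        },
    )


class TestFeatureVector:
    def test_happy_path_all_seven_finite(self, fixture_study, bundle):
        ds = read_variant_table(fixture_study["variants"])
        vec = compute_feature_vector(ds.records[0], bundle)
        values = list(vec.as_dict().values())
        assert len(values) == 7
        assert all(math.isfinite(v) for v in values)

    def test_structure_mismatch_is_excluded(self, fixture_study, bundle):
        ds = read_variant_table(fixture_study["variants"])
        good = ds.records[0]
        wrong_wt = next(aa for aa in AMINO_ACIDS if aa not in (good.wt_res, good.mut_res))
        bad = VariantRecord(
            "test", good.protein_id, good.chain, good.position, wrong_wt, good.mut_res, -1.0
        )
        with pytest.raises(VariantExclusion, match="3D neighbors"):
            compute_feature_vector(bad, bundle)

    def test_missing_structure_is_excluded(self, fixture_study, bundle):
        missing = VariantRecord("test", "ZZZZ", "A", "1", "A", "V", -1.0)
        with pytest.raises(VariantExclusion, match="3D neighbors"):
            compute_feature_vector(missing, bundle)

    def test_batch_exclusion_count_matches_broken_fixtures(self, tmp_path):
        """With one deliberately missing structure, exactly its variants drop."""
        from ddgfeat import make_fixture_study

        paths = make_fixture_study(
            tmp_path / "broken", n_variants_per_protein=4, n_proteins=3,
            seed=11, break_structure=True,
        )
        ds = read_variant_table(paths["variants"])
        bundle = ResourceBundle(
            skolnick=__import__("ddgfeat").PairPotential.read_tsv(paths["skolnick"]),
            bv=__import__("ddgfeat").PairPotential.read_tsv(paths["bv"], role="structural"),
            structures={
                p.stem: StructureModel.from_pdb(p) for p in paths["structures"].glob("*.pdb")
            },
            profiles={
                p.stem: ConservationProfile.read_tsv(p) for p in paths["profiles"].glob("*.tsv")
            },
        )
        table, excluded = compute_feature_table(ds.records, bundle)
        broken_protein = {r.protein_id for r in ds.records} - set(bundle.structures)
        expected = sum(r.protein_id in broken_protein for r in ds.records)
        assert len(excluded) == expected > 0
        assert all(reason.startswith("3D neighbors") for _, reason in excluded)
        assert len(table) + len(excluded) == len(ds)

    def test_swap_behaviour_of_the_full_vector(self, fixture_study, bundle):
        """Role swap W <-> M negates the five difference features and fixes
        the substitution-matrix score and the accessibility."""
        from ddgfeat.features import ANTISYMMETRIC_FEATURES, SYMMETRIC_FEATURES

        ds = read_variant_table(fixture_study["variants"])
        rec = ds.records[0]
        direct = compute_feature_vector(rec, bundle).as_dict()
        assert set(direct) == set(ANTISYMMETRIC_FEATURES) | set(SYMMETRIC_FEATURES)

        structure = bundle.structures[rec.protein_id]
        seq = structure.chain_sequence(rec.chain)
        idx = structure.position_index(rec.chain, rec.position)
        swapped = {
            "hydrophobicity_diff": hydrophobicity_difference(
                rec.mut_res, rec.wt_res, bundle.hydro_scale
            ),
            "volume_diff": volume_difference(rec.mut_res, rec.wt_res, bundle.volume_scale),
            "cons_log_ratio": conservation_log_ratio(
                bundle.profiles[rec.protein_id], rec.position, rec.mut_res, rec.wt_res
            ),
            "blosum_score": blosum_score(rec.mut_res, rec.wt_res, bundle.blosum),
            "accessibility": relative_accessibility(
                structure, rec.chain, rec.position, bundle.max_asa, residue_type=rec.wt_res
            ),
            "skolnick_diff": skolnick_potential_diff(
                seq, idx, rec.mut_res, rec.wt_res, bundle.skolnick
            ),
            "bv_diff": bastolla_vendruscolo_diff(
                structure, rec.chain, rec.position, rec.mut_res, rec.wt_res, bundle.bv
            ),
        }
        for name in ANTISYMMETRIC_FEATURES:
            assert swapped[name] == pytest.approx(-direct[name], abs=1e-10)
        for name in SYMMETRIC_FEATURES:
            assert swapped[name] == pytest.approx(direct[name], abs=1e-10)
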