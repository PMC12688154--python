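"""Feature engine: registry bookkeeping, the four groups, table assembly."""

import numpy as np
import pandas as pd
import pytest

import ddgkit as dk
from ddgkit.dataset import DDGDataset, MutationKey, MutationRecord, augment_reverse
from ddgkit.features import (
    DEFAULT_MANIFEST_COUNTS,
    StructureContext,
    assemble_table,
    compute_group1,
    compute_group2_diff,
    compute_group3_mutation_type,
    compute_group4_evolutionary,
    default_registry,
)
from ddgkit.profiles import PSSMProfile, PSSM_ALPHABET


@pytest.fixture(scope="module")
def registry():
    return default_registry()


@pytest.fixture(scope="module")
def assembled(helix_structure, helix_pssm):
    recs = [
        MutationRecord(MutationKey("S000", "A", 6, "I", "A"), 7.0, 25.0, 1.2),
        MutationRecord(MutationKey("S000", "A", 10, "R", "E"), 7.0, 25.0, -0.4),
    ]
    data = augment_reverse(DDGDataset(records=recs))
    table, failures = assemble_table(data, {"S000": helix_structure}, {"S000": helix_pssm})
    assert failures == []
    return data, table


class TestRegistry:
    def test_counts_match_shipped_manifest(self, registry):
        assert registry.manifest()["group_counts"] == DEFAULT_MANIFEST_COUNTS

    def test_names_unique_and_grouped(self, registry):
        names = registry.names
        assert len(set(names)) == len(names)
        assert all(s.group in DEFAULT_MANIFEST_COUNTS for s in registry.specs)

    def test_group4_size_follows_window(self):
        for window in (3, 5, 8):
            reg = default_registry(window=window)
            g4 = sum(s.group == "G4_evolutionary" for s in reg.specs)
            assert g4 == 2 * (2 * window + 1) + 4

    def test_group1_has_no_pssm_columns(self, registry):
        g1 = [s.name for s in registry.specs if s.group == "G1_wt_struct_env"]
        assert not any("PSSM" in n for n in g1)

    def test_diff_set_excludes_disorder_and_burial(self, registry):
        g2 = [s.name for s in registry.specs if s.group == "G2_diff"]
        assert not any("disorder" in n or "buried" in n or "exposed" in n for n in g2)


class TestGroup1:
    def test_shell_proportions_compose(self, helix_structure, registry):
        ctx = StructureContext(helix_structure)
        site = ("A", 10, "")
        vals = compute_group1(ctx, site, 7.0, 25.0, registry)
        members = ctx.shell(site, "13").members
        residues = [r for r in helix_structure.residues if r.rid in members]
        from ddgkit.struct_features import aa_category_proportions

        direct = aa_category_proportions(residues)
        assert vals["wt_shell13_prop_cat_nonpolar"] == direct["prop_cat_nonpolar"]

    def test_conditions_passed_through(self, helix_structure, registry):
        ctx = StructureContext(helix_structure)
        vals = compute_group1(ctx, ("A", 5, ""), 6.3, 37.0, registry)
        assert vals["cond_ph"] == 6.3
        assert vals["cond_temperature"] == 37.0

    def test_foldx_masked_without_adapter(self, helix_structure, registry):
        ctx = StructureContext(helix_structure)
        vals = compute_group1(ctx, ("A", 5, ""), 7.0, 25.0, registry)
        assert np.isnan(vals["wt_foldx_total_energy"])

    def test_foldx_present_with_adapter(self, helix_structure, registry):
        from ddgkit.profiles import EnergyTermBundle, FOLDX_TERMS

        bundle = EnergyTermBundle(terms={t: float(i) for i, t in enumerate(FOLDX_TERMS)})
        ctx = StructureContext(helix_structure, foldx=bundle)
        vals = compute_group1(ctx, ("A", 5, ""), 7.0, 25.0, registry)
        assert vals["wt_foldx_cis_bond"] == float(FOLDX_TERMS.index("cis_bond"))


class TestGroup2:
    def test_identical_structures_all_zero(self, helix_structure, registry):
        ctx = StructureContext(helix_structure)
        g1 = compute_group1(ctx, ("A", 5, ""), 7.0, 25.0, registry)
        diffs = compute_group2_diff(g1, g1)
        vals = np.array([v for v in diffs.values() if not np.isnan(v)])
        assert np.all(vals == 0.0)

    def test_simple_difference(self):
        wt = {"wt_site_rsa": 3.0}
        mut = {"wt_site_rsa": 5.0}
        assert compute_group2_diff(wt, mut) == {"diff_site_rsa": 2.0}

    def test_name_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_group2_diff({"wt_site_rsa": 1.0}, {"wt_site_gnm_fluct": 1.0})


class TestGroup3:
    def test_one_hot_and_category_flags(self, helix_structure, registry):
        ctx = StructureContext(helix_structure)
        key = MutationKey("S000", "A", 2, "K", "Q")
        vals = compute_group3_mutation_type(
            key, ctx, ctx, ("A", 2, ""), {}, None, default_registry(matrices=())
        )
        assert vals["mut3_wt_is_K"] == 1.0
        assert sum(vals[f"mut3_wt_is_{aa}"] for aa in dk.AA_ALPHABET) == 1.0
        assert vals["mut3_wt_cat_positively_charged_polar"] == 1.0
        assert vals["mut3_mut_cat_uncharged_polar"] == 1.0
        assert vals["mut3_mut_cat_positively_charged_polar"] == 0.0

    def test_blosum_lookup_symmetric(self, helix_structure, registry):
        from ddgkit.features import _default_matrices

        mats = _default_matrices(registry)
        ctx = StructureContext(helix_structure)
        k_q = compute_group3_mutation_type(
            MutationKey("S000", "A", 2, "K", "Q"), ctx, ctx, ("A", 2, ""),
            mats, None, registry,
        )["mut3_matrix_BLOSUM62"]
        q_k = compute_group3_mutation_type(
            MutationKey("S000", "A", 9, "Q", "K"), ctx, ctx, ("A", 9, ""),
            mats, None, registry,
        )["mut3_matrix_BLOSUM62"]
        assert k_q == q_k == 1.0  # BLOSUM62 K<->Q score

    def test_reverse_one_hot_swaps_blocks(self, assembled):
        data, table = assembled
        direct = table.values.iloc[0]
        reverse = table.values.iloc[1]
        for aa in dk.AA_ALPHABET:
            assert direct[f"mut3_wt_is_{aa}"] == reverse[f"mut3_mut_is_{aa}"]
            assert direct[f"mut3_mut_is_{aa}"] == reverse[f"mut3_wt_is_{aa}"]


class TestGroup4:
    @pytest.fixture()
    def toy_pssm(self):
        scores = np.zeros((9, 20))
        scores[4, PSSM_ALPHABET.index("Q")] = -2
        scores[4, PSSM_ALPHABET.index("K")] = 5
        return PSSMProfile(sequence="AAAAKAAAA", scores=scores)

    def test_diff_score_from_fixture(self, toy_pssm):
        vals = compute_group4_evolutionary(toy_pssm, 5, "K", "Q", window=2)
        assert vals["diff_PSSM_score"] == -7.0
        assert vals["wt_PSSM_score"] == 5.0

    def test_window_feature_count_is_26(self, toy_pssm):
        vals = compute_group4_evolutionary(toy_pssm, 5, "K", "Q", window=5)
        assert len(vals) == 26

    def test_edge_positions_masked_and_excluded_from_average(self, toy_pssm):
        vals = compute_group4_evolutionary(toy_pssm, 1, "A", "C", window=3)
        assert np.isnan(vals["wt_PSSM_m1"])
        assert not np.isnan(vals["wt_PSSM_score_aver"])

    def test_missing_profile_masks_everything(self):
        vals = compute_group4_evolutionary(None, 5, "K", "Q")
        assert all(np.isnan(v) for v in vals.values())

    def test_out_of_range_site_raises(self, toy_pssm):
        with pytest.raises(IndexError):
            compute_group4_evolutionary(toy_pssm, 99, "K", "Q")


class TestAssembly:
    def test_column_order_matches_registry(self, assembled, registry):
        _, table = assembled
        assert list(table.values.columns) == registry.names

    def test_group2_antisymmetry_exact(self, assembled):
        _, table = assembled
        diff_cols = [
            c for c in table.values.columns
            if c.startswith("diff_") and "PSSM" not in c
        ]
        for i in (0, 2):  # direct rows; reverse is the next row
            d = table.values.iloc[i][diff_cols].to_numpy(float)
            r = table.values.iloc[i + 1][diff_cols].to_numpy(float)
            mask = ~(np.isnan(d) & np.isnan(r))
            assert np.array_equal(d[mask], -r[mask])

    def test_deterministic_across_runs(self, helix_structure, helix_pssm):
        recs = [MutationRecord(MutationKey("S000", "A", 6, "I", "A"), 7.0, 25.0, 1.2)]
        data = augment_reverse(DDGDataset(records=recs))
        t1, _ = assemble_table(data, {"S000": helix_structure}, {"S000": helix_pssm})
        t2, _ = assemble_table(data, {"S000": helix_structure}, {"S000": helix_pssm})
        pd.testing.assert_frame_equal(t1.values, t2.values)

    def test_unresolvable_record_reported_not_fatal(self, helix_structure):
        recs = [
            MutationRecord(MutationKey("S000", "A", 6, "I", "A"), 7.0, 25.0, 1.2),
            MutationRecord(MutationKey("S000", "B", 6, "I", "A"), 7.0, 25.0, 0.5),
        ]
        data = augment_reverse(DDGDataset(records=recs))
        table, failures = assemble_table(data, {"S000": helix_structure})
        assert len(table) == 2  # the resolvable pair
        assert len(failures) == 2  # direct and reverse of the bad chain
        assert all(f.key.chain_id == "B" for f in failures)

    def test_csv_roundtrip(self, assembled, tmp_path):
        _, table = assembled
        path = tmp_path / "features.csv"
        table.write_csv(path, manifest_path=tmp_path / "manifest.json")
        back = dk.FeatureTable.read_csv(path)
        assert list(back.values.columns) == list(table.values.columns)
        assert np.allclose(
            back.values.to_numpy(float), table.values.to_numpy(float), equal_nan=True
        )
        assert (tmp_path / "manifest.json").exists()
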