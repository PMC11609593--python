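"""Domain-swapping workflows: composed units, guest contribution, batches."""

import numpy as np
import pytest

from fodm.model import FodModel, fod_status
from fodm.structure import UnitSelection, write_fixture
from fodm.swap import (
    assess_unit,
    average_profiles,
    batch_table,
    guest_contribution,
    load_manifest,
    select_effective,
)
from fodm.synthetic import make_micelle, make_swapped_pair


@pytest.fixture(scope="module")
def swapped():
    return make_swapped_pair(120, seed=0, complete=True)


class TestAssessUnit:
    def test_single_chain_selection_equals_substructure_status(self, swapped):
        host, _, structure = swapped
        via_assess = assess_unit(structure, host)
        direct = fod_status(select_effective(structure, host))
        assert via_assess.rd == direct.rd
        assert via_assess.k == direct.k

    def test_fragment_order_does_not_change_rd_or_k(self, swapped):
        host, guest, structure = swapped
        ab = UnitSelection(fragments=host.fragments + guest.fragments)
        ba = UnitSelection(fragments=guest.fragments + host.fragments)
        s1, s2 = assess_unit(structure, ab), assess_unit(structure, ba)
        assert s1.rd == pytest.approx(s2.rd, abs=1e-12)
        assert s1.k == s2.k

    def test_separate_units_get_separate_envelopes(self, swapped):
        host, guest, structure = swapped
        combined = assess_unit(structure, UnitSelection(fragments=host.fragments + guest.fragments))
        host_alone = assess_unit(structure, host)
        guest_alone = assess_unit(structure, guest)
        assert host_alone.rd != combined.rd
        assert guest_alone.rd != combined.rd

    def test_assess_from_fixture_file(self, swapped, tmp_path):
        host, _, structure = swapped
        path = tmp_path / "sw.txt"
        write_fixture(structure, path)
        from fodm.structure import read_fixture

        status = assess_unit(read_fixture(path), host)
        assert status.n_residues == 60


class TestGuestContribution:
    def test_complete_guest_improves_rd(self, swapped):
        host, guest, structure = swapped
        sa = guest_contribution(structure, host, guest)
        assert sa.delta_rd < 0
        assert sa.guest_completes_core
        assert sa.delta_rd == pytest.approx(sa.combined_status.rd - sa.host_status.rd)

    def test_combined_beats_each_half_alone(self, swapped):
        host, guest, structure = swapped
        combined = assess_unit(structure, UnitSelection(fragments=host.fragments + guest.fragments))
        assert combined.rd < assess_unit(structure, host).rd
        assert combined.rd < assess_unit(structure, guest).rd

    def test_disrupting_guest_does_not_improve(self):
        host, guest, structure = make_swapped_pair(120, seed=0, complete=False)
        sa = guest_contribution(structure, host, guest)
        assert sa.delta_rd >= 0

    def test_overlapping_selections_rejected(self, swapped):
        host, _, structure = swapped
        with pytest.raises(ValueError, match="overlap"):
            guest_contribution(structure, host, host)

    def test_empty_guest_selection_unconstructable(self):
        with pytest.raises(ValueError):
            UnitSelection(fragments=())


class TestBatchTable:
    def test_empty_manifest_rejected(self):
        with pytest.raises(ValueError):
            batch_table([])

    def test_single_fixture_single_row(self, micelle100):
        table = batch_table([(micelle100, None, "micelle")])
        assert len(table) == 1
        row = table.iloc[0]
        assert row["label"] == "micelle"
        assert row["RD"] == round(fod_status(micelle100).rd, 3)
        assert row["error"] == ""

    def test_failures_reported_not_raised(self, micelle100):
        table = batch_table([
            (micelle100, None, "good"),
            (micelle100, "Z:1-5", "bad-selection"),
        ])
        assert len(table) == 2
        assert table.iloc[0]["error"] == ""
        assert table.iloc[1]["error"] != ""
        assert np.isnan(table.iloc[1]["RD"])

    def test_rows_reproducible(self, micelle100):
        m = [(micelle100, None, "a"), (micelle100, "A:1-50", "b")]
        t1, t2 = batch_table(m), batch_table(m)
        assert t1.equals(t2)

    def test_manifest_csv_round_trip(self, micelle100, tmp_path):
        fixture = tmp_path / "m.txt"
        write_fixture(micelle100, fixture)
        manifest = tmp_path / "manifest.csv"
        manifest.write_text(f"path,selection,label\n{fixture},A:1-100,unit1\n")
        entries = load_manifest(manifest)
        assert entries == [(str(fixture), "A:1-100", "unit1")]


class TestAverageProfiles:
    def test_identical_units_have_zero_std(self):
        r1 = FodModel(make_micelle(60, seed=5)).fit()
        r2 = FodModel(make_micelle(60, seed=5)).fit()
        table, mean_k = average_profiles([r1, r2])
        for role in ("T", "O", "M"):
            np.testing.assert_allclose(table[f"{role}_std"], 0.0, atol=1e-15)
            np.testing.assert_allclose(table[f"{role}_mean"], r1.residue_table()[role], atol=1e-15)
        assert mean_k == r1.k

    def test_differing_units_localize_std(self):
        r1 = FodModel(make_micelle(60, seed=5)).fit()
        r2 = FodModel(make_micelle(60, seed=6)).fit()
        table, _ = average_profiles([r1, r2])
        assert (table["O_std"] > 0).any()
        # population std of two values is half their absolute difference
        expected = 0.5 * np.abs(r1.o.values - r2.o.values)
        np.testing.assert_allclose(table["O_std"], expected, atol=1e-12)

    def test_mean_matches_direct_formula(self):
        results = [FodModel(make_micelle(60, seed=s)).fit() for s in (1, 2, 3)]
        table, mean_k = average_profiles(results)
        stacked = np.stack([r.t.values for r in results])
        np.testing.assert_allclose(table["T_mean"], stacked.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(table["T_std"], stacked.std(axis=0), atol=1e-12)
        assert mean_k == pytest.approx(np.mean([r.k for r in results]))

    def test_partial_overlap_uses_intersection(self):
        r1 = FodModel(make_micelle(60, seed=5)).fit()
        full = FodModel(make_micelle(60, seed=5))
        r2 = full.exclude(UnitSelection(fragments=(("A", 1, 5),))).fit()
        table, _ = average_profiles([r1, r2])
        assert len(table) == 55

    def test_single_unit_rejected(self):
        r1 = FodModel(make_micelle(60, seed=5)).fit()
        with pytest.raises(ValueError):
            average_profiles([r1])
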