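"""TRIZ registries, contradiction matrix, determinant mapping, suggestion."""

import pytest

from fmea_triz.fmea import Cause, FailureMode
from fmea_triz.triz import (
    CASE_STUDY_CELLS,
    ContradictionMatrix,
    DeterminantMap,
    lookup_matrix,
    map_causes_to_parameters,
    suggest_principles,
    validate_matrix_assets,
)


def fm(fid, *causes):
    return FailureMode(fid, "", "", tuple(causes))


class TestRegistriesAndMatrix:
    def test_bundled_assets_validate_clean(self, matrix, registries):
        params, principles = registries
        report = validate_matrix_assets(matrix, params, principles)
        assert report.ok, report.deviations

    def test_registry_sizes(self, registries):
        params, principles = registries
        assert len(params) == 39 and sorted(params) == list(range(1, 40))
        assert len(principles) == 40 and sorted(principles) == list(range(1, 41))

    def test_altered_cell_is_one_deviation(self, matrix, registries):
        params, principles = registries
        cells = dict(matrix.cells)
        cells[(9, 22)] = (1, 2, 3)
        report = validate_matrix_assets(ContradictionMatrix(cells), params, principles)
        assert len(report.deviations) == 1
        assert "(9, 22)" in report.deviations[0]

    def test_short_principle_registry_fails(self, matrix, registries):
        params, principles = registries
        short = {k: v for k, v in principles.items() if k != 40}
        report = validate_matrix_assets(matrix, params, short)
        assert any("39 entries, expected 40" in d for d in report.deviations)

    def test_matrix_round_trips_through_file(self, matrix, tmp_path):
        path = tmp_path / "matrix.json"
        matrix.to_file(path)
        loaded = ContradictionMatrix.from_file(path)
        assert loaded.cells == matrix.cells
        for cell, expected in CASE_STUDY_CELLS.items():
            assert loaded.cells[cell] == expected

    def test_diagonal_cell_rejected_at_construction(self):
        with pytest.raises(ValueError, match="self-contradiction"):
            ContradictionMatrix({(9, 9): (1,)})


class TestLookup:
    @pytest.mark.parametrize("cell,expected", [
        ((9, 22), (20, 14, 19, 35)),
        ((35, 36), (15, 29, 28, 37)),
        ((26, 36), (3, 13, 10, 27)),
    ])
    def test_case_cells(self, matrix, cell, expected):
        assert lookup_matrix(*cell, matrix) == expected

    def test_diagonal_query_rejected(self, matrix):
        with pytest.raises(ValueError, match="self-contradiction undefined"):
            lookup_matrix(9, 9, matrix)

    def test_absent_cell_returns_empty_with_notice(self, matrix, caplog):
        with caplog.at_level("INFO", logger="fmea_triz.triz"):
            assert lookup_matrix(1, 2, matrix) == ()
        assert any("no cell" in r.message for r in caplog.records)

    def test_out_of_range_parameter_rejected(self, matrix):
        with pytest.raises(ValueError, match="outside 1..39"):
            lookup_matrix(40, 22, matrix)


class TestDeterminantMapping:
    def test_case_failure_f1(self, dmap, register):
        f1 = next(f for f in register if f.id == "F1")
        assert map_causes_to_parameters(f1, dmap) == [26, 35]

    def test_case_failure_f2(self, dmap, register):
        f2 = next(f for f in register if f.id == "F2")
        assert map_causes_to_parameters(f2, dmap) == [26, 9]

    def test_unmapped_determinant_names_the_cause(self, dmap):
        failure = fm("FX", Cause("mystery cause", (99,)))
        with pytest.raises(ValueError, match="mystery cause"):
            map_causes_to_parameters(failure, dmap)

    def test_untagged_cause_rejected(self, dmap):
        failure = fm("FX", Cause("untagged cause"))
        with pytest.raises(ValueError, match="no determinant tag"):
            map_causes_to_parameters(failure, dmap)

    def test_map_rejects_out_of_range_parameter(self):
        with pytest.raises(ValueError, match="1..39"):
            DeterminantMap({1: 40})


class TestSuggestion:
    def test_case_study_screened_principles(self, dmap, matrix, register):
        top3 = [f for f in register if f.id in ("F1", "F6", "F2")]
        report = suggest_principles(top3, dmap, (22, 36), matrix,
                                    roster=(1, 4, 21, 25, 27, 10, 28))
        assert sorted(report.screened) == [1, 4, 10, 21, 25, 27, 28]
        assert sorted(report.improving) == [9, 17, 26, 35]
        assert set(report.screened) <= set(report.raw_union)

    def test_no_failures_yields_empty_report(self, dmap, matrix):
        report = suggest_principles([], dmap, (22, 36), matrix)
        assert report.raw_union == () and report.screened == ()

    def test_disjoint_roster_empties_screened_only(self, dmap, matrix, register):
        f1 = [f for f in register if f.id == "F1"]
        report = suggest_principles(f1, dmap, (22, 36), matrix, roster=(40,))
        assert report.screened == ()
        assert report.raw_union != ()

    def test_empty_worsening_rejected(self, dmap, matrix, register):
        with pytest.raises(ValueError, match="non-empty"):
            suggest_principles(register[:1], dmap, (), matrix)

    def test_adding_a_failure_never_shrinks_raw_union(self, dmap, matrix, register):
        tagged = [f for f in register if all(c.determinants for c in f.causes)]
        prev: set[int] = set()
        for k in range(1, len(tagged) + 1):
            report = suggest_principles(tagged[:k], dmap, (22, 36), matrix)
            assert prev <= set(report.raw_union)
            prev = set(report.raw_union)

    def test_pooled_and_per_failure_modes_share_raw_union(self, dmap, matrix, register):
        tagged = [f for f in register if all(c.determinants for c in f.causes)]
        pooled = suggest_principles(tagged, dmap, (22, 36), matrix, pooled=True)
        per = suggest_principles(tagged, dmap, (22, 36), matrix, pooled=False)
        assert set(pooled.raw_union) == set(per.raw_union)

    def test_provenance_chains_are_complete(self, dmap, matrix, register):
        tagged = [f for f in register if all(c.determinants for c in f.causes)]
        report = suggest_principles(tagged, dmap, (22, 36), matrix)
        mapped_params = {param for p in report.provenance for _, _, param in p.chains}
        assert set(report.improving) == mapped_params
        # every suggested principle traces back to >=1 consulted cell whose
        # improving parameter came from some cause chain
        for principle in report.raw_union:
            sources = [cell for cell, ps in report.cells_consulted if principle in ps]
            assert sources
            assert all(imp in mapped_params for imp, _ in sources)
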