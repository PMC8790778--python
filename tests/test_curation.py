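import numpy as np
import pandas as pd
import pytest

from dyesol import (
    SpectralRecord,
    canonicalize_smiles,
    curate,
    deduplicate,
    filter_structures,
    parse_records,
)
from dyesol.curation import InvalidSmilesError


def rec(dye, solv, lam, src="A", row=-1):
    return SpectralRecord(dye, solv, lam, src, row=row)


class TestParseRecords:
    def test_name_map_resolution(self, name_map):
        table = pd.DataFrame(
            {
                "smiles": ["c1ccc2cc3ccccc3cc2c1"],
                "solvent": ["thf"],
                "peak_wavelength_nm": [375],
                "source": ["A"],
            }
        )
        records, drops = parse_records(table, name_map)
        assert drops == []
        assert records[0].solvent_smiles == "C1CCOC1"

    def test_name_map_is_case_insensitive(self, name_map):
        table = pd.DataFrame(
            {
                "smiles": ["CCO"],
                "solvent": [" THF "],
                "peak_wavelength_nm": [375],
                "source": ["A"],
            }
        )
        records, _ = parse_records(table, name_map)
        assert records[0].solvent_smiles == "C1CCOC1"

    @pytest.mark.parametrize(
        "solvent,lam",
        [("unknownium", 375.0), ("O", -5.0), ("O", float("nan"))],
    )
    def test_bad_rows_dropped_as_missing_field(self, name_map, solvent, lam):
        table = pd.DataFrame(
            {
                "smiles": ["CCO"],
                "solvent": [solvent],
                "peak_wavelength_nm": [lam],
                "source": ["A"],
            }
        )
        records, drops = parse_records(table, name_map)
        assert records == []
        assert drops == [(0, "missing_field")]

    def test_missing_column_raises(self):
        with pytest.raises(KeyError):
            parse_records(pd.DataFrame({"smiles": ["C"]}))


class TestFilterStructures:
    def test_valid_kept_and_canonicalized(self):
        kept, drops = filter_structures([rec("c1ccccc1", "O", 400.0)])
        assert drops == []
        assert kept[0].dye_smiles == canonicalize_smiles("C1=CC=CC=C1")

    def test_unclosed_ring_dropped_invalid(self):
        kept, drops = filter_structures([rec("C1CC", "O", 400.0, row=3)])
        assert kept == []
        assert drops == [(3, "invalid_smiles")]

    def test_dot_component_dropped_multi_component(self):
        kept, drops = filter_structures([rec("CCO.[Na+]", "O", 400.0, row=4)])
        assert kept == []
        assert drops == [(4, "multi_component")]


class TestDeduplicate:
    def test_mean_within_tolerance(self):
        records = [rec("CCO", "O", 500.0, row=0), rec("CCO", "O", 503.0, row=1)]
        out, drops, prov = deduplicate(records)
        assert len(out) == 1 and drops == []
        assert out[0].lambda_max_nm == pytest.approx(501.5)
        assert sorted(prov[0]) == [0, 1]

    def test_conflict_beyond_tolerance_drops_group(self):
        records = [rec("CCO", "O", 500.0, row=0), rec("CCO", "O", 507.0, row=1)]
        out, drops, _ = deduplicate(records)
        assert out == []
        assert sorted(drops) == [(0, "duplicate_conflict"), (1, "duplicate_conflict")]

    def test_boundary_spread_is_inclusive(self):
        records = [rec("CCO", "O", 500.0), rec("CCO", "O", 505.0)]
        out, drops, _ = deduplicate(records)
        assert len(out) == 1 and out[0].lambda_max_nm == pytest.approx(502.5)

    def test_singleton_unchanged(self):
        records = [rec("CCO", "O", 500.0)]
        out, _, _ = deduplicate(records)
        assert out[0].lambda_max_nm == 500.0

    def test_cross_source_merge_uses_same_rule(self):
        records = [rec("CCO", "O", 500.0, "A"), rec("CCO", "O", 502.0, "B")]
        out, drops, _ = deduplicate(records)
        assert len(out) == 1
        assert out[0].lambda_max_nm == pytest.approx(501.0)
        assert out[0].source == "A+B"

    def test_idempotent(self, noisy_synth):
        _, ds, _ = noisy_synth
        once, d1, _ = deduplicate(ds.records)
        twice, d2, _ = deduplicate(once)
        assert [r.lambda_max_nm for r in twice] == [r.lambda_max_nm for r in once]
        assert d2 == []

    def test_order_invariance(self):
        records = [
            rec("CCO", "O", 500.0, row=0),
            rec("CO", "O", 410.0, row=1),
            rec("CCO", "O", 503.0, row=2),
            rec("CO", "CCO", 420.0, row=3),
        ]
        out_fwd, _, _ = deduplicate(records)
        out_rev, _, _ = deduplicate(records[::-1])
        key = lambda r: (r.dye_smiles, r.solvent_smiles)
        fwd = {key(r): r.lambda_max_nm for r in out_fwd}
        rev = {key(r): r.lambda_max_nm for r in out_rev}
        assert fwd == rev


class TestCanonicalize:
    @pytest.mark.parametrize("a,b", [("OCC", "CCO"), ("c1ccccc1", "C1=CC=CC=C1")])
    def test_same_molecule_same_string(self, a, b):
        assert canonicalize_smiles(a) == canonicalize_smiles(b)

    def test_idempotent(self):
        s = canonicalize_smiles("c1ccc2cc3ccccc3cc2c1")
        assert canonicalize_smiles(s) == s

    def test_invalid_raises(self):
        with pytest.raises(InvalidSmilesError):
            canonicalize_smiles("C1CC")


class TestCuratePipeline:
    def test_full_accounting(self, raw_table, name_map):
        ds = curate(raw_table, name_map)
        n_rows = len(raw_table)
        merged_away = sum(len(p) - 1 for p in ds.provenance)
        assert len(ds.records) + merged_away + len(ds.drop_log) == n_rows
        reasons = {r for _, r in ds.drop_log}
        assert reasons == {
            "invalid_smiles",
            "multi_component",
            "missing_field",
            "duplicate_conflict",
        }

    def test_no_key_appears_twice(self, raw_table, name_map):
        ds = curate(raw_table, name_map)
        keys = [(r.dye_smiles, r.solvent_smiles) for r in ds.records]
        assert len(keys) == len(set(keys))

    def test_row_permutation_invariance(self, raw_table, name_map):
        ds1 = curate(raw_table, name_map)
        shuffled = raw_table.sample(frac=1.0, random_state=5).reset_index(drop=True)
        ds2 = curate(shuffled, name_map)
        key = lambda r: (r.dye_smiles, r.solvent_smiles)
        m1 = {key(r): r.lambda_max_nm for r in ds1.records}
        m2 = {key(r): r.lambda_max_nm for r in ds2.records}
        assert m1 == m2
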