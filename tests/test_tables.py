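"""Review assembly, group tabulation, criterion filtering, and header scans."""

import numpy as np
import pytest

from fmriqc.io import ReviewDict, read_review_dict, write_review_dict
from fmriqc.tables import (Criterion, GroupTable, MISSING, build_group_table,
                           build_ss_review, filter_report, gtkyd_scan)


def _rd(**kw):
    return ReviewDict(kw)


class TestBuildSSReview:
    def test_merges_fragments_and_keeps_order(self):
        rd = build_ss_review([_rd(**{"TRs censored": 3}),
                              _rd(**{"TSNR average": 191.52})],
                             software={"QC tool": "fmriqc"})
        assert list(rd.keys()) == ["QC tool", "TRs censored", "TSNR average"]

    def test_label_collision_is_error(self):
        with pytest.raises(ValueError, match="collision"):
            build_ss_review([_rd(a=1), _rd(a=2)])

    def test_df_identity_holds_in_assembled_dict(self):
        from fmriqc.motion import CensorVector, censor_summary
        from fmriqc.regress import df_accounting
        keep = np.ones(242, dtype=int)
        keep[:3] = 0
        rd = build_ss_review([censor_summary(CensorVector(keep)),
                              df_accounting(242, 3, n_motion=6, n_drift=5,
                                            n_stim=2).as_review_fragment()])
        assert (rd["degrees of freedom used"] + rd["degrees of freedom left"]
                + rd["TRs censored"]) == rd["TRs total (uncensored)"]

    def test_round_trip_both_dialects_equal(self, tmp_path):
        rd = build_ss_review([_rd(**{"censor fraction": 0.012397,
                                     "flip guess": "NO_FLIP"})])
        write_review_dict(rd, tmp_path / "a.txt", "colon")
        write_review_dict(rd, tmp_path / "a.json", "json")
        assert (read_review_dict(tmp_path / "a.txt", "colon")
                == read_review_dict(tmp_path / "a.json", "json"))


class TestGroupTable:
    def test_identical_dicts_identical_rows(self):
        d = _rd(**{"TSNR average": 150.0, "flip guess": "NO_FLIP"})
        t = build_group_table([d, d, d], subject_ids=list("abc"))
        assert len(t.df) == 3
        assert t.df["TSNR average"].nunique() == 1

    def test_missing_key_gets_sentinel(self):
        t = build_group_table([_rd(a=1, b=2), _rd(a=3)], subject_ids=["s1", "s2"])
        assert t.df.loc[1, "b"] == MISSING

    def test_column_order_is_first_seen(self):
        dicts = [_rd(x=1, y=2), _rd(z=3, x=4), _rd(w=5)]
        t = build_group_table(dicts, subject_ids=["a", "b", "c"])
        assert list(t.df.columns) == ["subject", "x", "y", "z", "w"]

    def test_list_values_expand_to_suffixed_columns(self):
        t = build_group_table([_rd(**{"fraction TRs censored": [0.015, 0.0]})],
                              subject_ids=["a"])
        assert "fraction TRs censored[0]" in t.df.columns
        assert "fraction TRs censored[1]" in t.df.columns


def filter_loop_oracle(table, criteria, show_keepers):
    """Literal row-by-row re-evaluation of the filtering semantics."""
    df = table.df
    hits = []
    for _, row in df.iterrows():
        any_true = False
        for c in criteria:
            if c.op == "SHOW":
                continue
            cols = [col for col in df.columns
                    if col == c.label or col.startswith(f"{c.label}[")]
            for col in cols:
                cell = row[col]
                if isinstance(cell, str) and cell == MISSING:
                    continue
                ref = df[col].iloc[0] if c.op == "VARY" else c.value
                num = isinstance(cell, (int, float, np.number))
                if c.op == "VARY":
                    if num and isinstance(ref, (int, float, np.number)):
                        ok = not np.isclose(float(cell), float(ref), rtol=1e-9,
                                            atol=0.0)
                    else:
                        ok = str(cell) != str(ref)
                elif c.op == "EQ":
                    ok = (np.isclose(float(cell), float(ref), rtol=1e-9, atol=0.0)
                          if num and isinstance(ref, (int, float))
                          else str(cell) == str(ref))
                else:
                    ok = {"GT": cell > ref, "LT": cell < ref,
                          "GE": cell >= ref, "LE": cell <= ref}[c.op]
                if ok:
                    any_true = True
        if any_true != show_keepers:
            hits.append(row["subject"])
    return hits


class TestFilterReport:
    def _table(self):
        return build_group_table(
            [_rd(**{"TSNR average": 150.0, "flip guess": "NO_FLIP"}),
             _rd(**{"TSNR average": 90.0, "flip guess": "DO_FLIP"})],
            subject_ids=["A", "B"])

    def test_lt_selects_low_tsnr_subject(self):
        rep = filter_report(self._table(),
                            [Criterion.parse("'TSNR average' LT 100")])
        assert rep.subjects == ["B"]
        assert rep.df.loc[0, "TSNR average"] == 90.0

    def test_eq_on_string_selects_flipped_subject(self):
        rep = filter_report(self._table(),
                            [Criterion.parse("'flip guess' EQ DO_FLIP")])
        assert rep.subjects == ["B"]

    def test_show_keepers_inverts_and_union_is_everyone(self):
        crit = [Criterion.parse("'TSNR average' LT 100")]
        out = filter_report(self._table(), crit)
        keep = filter_report(self._table(), crit, show_keepers=True)
        assert sorted(out.subjects + keep.subjects) == ["A", "B"]
        assert set(out.subjects) & set(keep.subjects) == set()

    def test_vary_compares_to_first_subject(self):
        t = build_group_table([_rd(TR=2.0), _rd(TR=2.0), _rd(TR=2.5)],
                              subject_ids=["a", "b", "c"])
        rep = filter_report(t, [Criterion(label="TR", op="VARY")])
        assert rep.subjects == ["c"]

    def test_type_mismatch_is_error_not_false(self):
        with pytest.raises(TypeError):
            filter_report(self._table(),
                          [Criterion(label="flip guess", op="GT", value=1)])

    def test_unknown_label_errors(self):
        with pytest.raises(KeyError, match="nope"):
            filter_report(self._table(), [Criterion(label="nope", op="VARY")])

    def test_random_tables_match_row_by_row_oracle(self, rng):
        for trial in range(25):
            n = int(rng.integers(2, 7))
            dicts = [
                _rd(**{"m1": float(rng.normal(100, 30)),
                       "m2": float(rng.normal(0.05, 0.03)),
                       "tag": str(rng.choice(["x", "y"]))})
                for _ in range(n)]
            t = build_group_table(dicts, subject_ids=[f"s{i}" for i in range(n)])
            criteria = [
                Criterion(label="m1", op=str(rng.choice(["LT", "GT", "GE", "LE"])),
                          value=float(rng.normal(100, 20))),
                Criterion(label="m2", op="GE", value=0.05),
                Criterion(label="tag", op="VARY"),
            ]
            keepers = bool(rng.integers(2))
            got = filter_report(t, criteria, show_keepers=keepers).subjects
            assert got == filter_loop_oracle(t, criteria, keepers)


class TestGtkyd:
    def _write_phantom(self, path, tr=2.0, maxval=None, seed=0):
        import nibabel as nib
        rng = np.random.default_rng(seed)
        data = rng.uniform(0, 100, (6, 6, 4, 8))
        if maxval is not None:
            data[0, 0, 0, 0] = maxval
        img = nib.Nifti1Image(data, np.diag([2.5, 2.5, 2.5, 1.0]))
        img.header.set_zooms((2.5, 2.5, 2.5, tr))
        nib.save(img, path)

    def test_identical_files_empty_variability_report(self, tmp_path):
        p = tmp_path / "a.nii"
        self._write_phantom(p)
        _, report = gtkyd_scan([p, p, p])
        assert len(report.df) == 0

    def test_differing_tr_is_reported(self, tmp_path):
        p1, p2, p3 = (tmp_path / f"{n}.nii" for n in "abc")
        self._write_phantom(p1, tr=2.0)
        self._write_phantom(p2, tr=2.0)
        self._write_phantom(p3, tr=2.5)
        _, report = gtkyd_scan([p1, p2, p3])
        assert report.subjects == [str(p3)]
        assert report.df.loc[0, "TR"] == 2.5

    def test_saturated_max_value_surfaces(self, tmp_path):
        p1 = tmp_path / "a.nii"
        p2 = tmp_path / "b.nii"
        self._write_phantom(p1)
        self._write_phantom(p2, maxval=4095.0)
        table, report = gtkyd_scan([p1, p2])
        assert 4095.0 in list(table.df["max value"])
        assert str(p2) in report.subjects

    def test_unreadable_file_becomes_error_row(self, tmp_path):
        good = tmp_path / "a.nii"
        self._write_phantom(good)
        bad = tmp_path / "bad.nii"
        bad.write_bytes(b"not a nifti")
        table, _ = gtkyd_scan([good, bad])
        assert len(table.df) == 2
        assert "error" in table.df.columns
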