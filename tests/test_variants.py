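import io
import textwrap

import numpy as np
import pandas as pd
import pytest

from mitodyn.variants import (
    FilterConfig,
    PatientTriplet,
    annotate_known,
    apply_filters,
    build_triplets,
    classify_patient,
    count_summary,
    count_table,
    load_sample_tables,
    read_catalog,
    read_manifest,
    read_variant_table,
)


def _table(rows, sample="S1"):
    """Build a variant table from (pos, ref, alt, af, dp) tuples."""
    return pd.DataFrame(
        [{"sample": sample, "pos": p, "ref": r, "alt": a, "af": f, "dp": d}
         for p, r, a, f, d in rows],
        columns=["sample", "pos", "ref", "alt", "af", "dp"],
    )


def _triplet(normal, primary, *relapses, patient="pt1"):
    return PatientTriplet(
        patient_id=patient, normal=normal, primary=primary,
        relapses=list(relapses) or [_table([])],
    )


class TestReadVariantTable:
    def test_csv_row(self):
        df = read_variant_table(
            io.StringIO("sample,pos,ref,alt,af,dp\nS1,100,A,G,0.05,200\n"))
        row = df.iloc[0]
        assert (row.pos, row.ref, row.alt) == (100, "A", "G")
        assert row.af == pytest.approx(0.05)
        assert row.dp == 200

    def test_tab_dialect_autodetected(self):
        df = read_variant_table(
            io.StringIO("sample\tpos\tref\talt\taf\tdp\nS1\t5\tC\tT\t0.5\t80\n"))
        assert df.iloc[0].pos == 5

    def test_duplicate_key_rejected(self):
        text = ("sample,pos,ref,alt,af,dp\n"
                "S1,100,A,G,0.05,200\nS1,100,A,G,0.10,150\n")
        with pytest.raises(ValueError, match="duplicate variant key"):
            read_variant_table(io.StringIO(text))

    def test_af_out_of_range_names_line(self):
        text = "sample,pos,ref,alt,af,dp\nS1,100,A,G,1.5,200\n"
        with pytest.raises(ValueError, match="line 2"):
            read_variant_table(io.StringIO(text))

    def test_negative_depth_rejected(self):
        text = "sample,pos,ref,alt,af,dp\nS1,100,A,G,0.5,-3\n"
        with pytest.raises(ValueError, match="negative depth"):
            read_variant_table(io.StringIO(text))

    def test_ref_equals_alt_rejected(self):
        text = "sample,pos,ref,alt,af,dp\nS1,100,A,A,0.5,10\n"
        with pytest.raises(ValueError, match="ref allele equals alt"):
            read_variant_table(io.StringIO(text))

    def test_position_outside_reference(self):
        text = "sample,pos,ref,alt,af,dp\nS1,100,A,G,0.5,10\n"
        with pytest.raises(ValueError, match="outside reference"):
            read_variant_table(io.StringIO(text), reference_length=50)

    def test_vcf_round_trip(self, tmp_path):
        vcf = textwrap.dedent("""\
            ##fileformat=VCFv4.2
            ##INFO=<ID=AF,Number=A,Type=Float,Description="Allele fraction">
            ##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">
            ##contig=<ID=MT,length=16569>
            #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
            MT\t73\t.\tA\tG\t.\t.\tAF=0.5;DP=80
            """)
        path = tmp_path / "s1.vcf"
        path.write_text(vcf)
        df = read_variant_table(path, sample_id="S1")
        row = df.iloc[0]
        assert (row["sample"], row.pos, row.ref, row.alt) == ("S1", 73, "A", "G")
        assert row.af == pytest.approx(0.5)
        assert row.dp == 80


class TestApplyFilters:
    def test_depth_threshold_is_exclusive(self, fcfg):
        tab = _table([(1, "A", "G", 0.10, 50), (2, "A", "G", 0.10, 51)])
        out = apply_filters(tab, fcfg, "classify")
        assert list(out["pos"]) == [2]
        assert out.attrs["removed"]["depth"] == 1

    def test_purpose_selects_abundance_threshold(self, fcfg):
        tab = _table([(1, "A", "G", 0.015, 100)])
        assert len(apply_filters(tab, fcfg, "classify")) == 0
        assert len(apply_filters(tab, fcfg, "dynamics")) == 1

    def test_empty_table(self, fcfg):
        assert len(apply_filters(_table([]), fcfg, "classify")) == 0

    def test_filters_are_monotone(self):
        """Raising any threshold never increases the retained count."""
        rng = np.random.default_rng(5)
        tab = _table([
            (p, "A", "G", rng.uniform(0, 0.3), int(rng.integers(0, 300)))
            for p in range(1, 201)
        ])
        retained = [
            len(apply_filters(
                tab,
                FilterConfig(min_depth=d, abundance_classify=a,
                             abundance_dynamics=min(a, 0.01)),
                "classify"))
            for d in (0, 50, 100) for a in (0.01, 0.02, 0.05)
        ]
        by_depth = np.array(retained).reshape(3, 3)
        assert (np.diff(by_depth, axis=0) <= 0).all()  # depth raised
        assert (np.diff(by_depth, axis=1) <= 0).all()  # abundance raised


class TestClassifyPatient:
    def test_tumor_specific_definition(self, fcfg):
        trip = _triplet(
            _table([], sample="N"),
            _table([(100, "A", "G", 0.05, 200)], sample="P"),
            _table([(100, "A", "G", 0.08, 200)], sample="R"),
        )
        out = classify_patient(trip, fcfg)
        assert list(out["category"]) == ["tumor_specific"]
        assert out.iloc[0]["occurrence"] == "P,R1"

    def test_germline_definition(self, fcfg):
        trip = _triplet(
            _table([(100, "A", "G", 0.5, 200)], sample="N"),
            _table([(100, "A", "G", 0.5, 200)], sample="P"),
            _table([(100, "A", "G", 0.5, 200)], sample="R"),
        )
        out = classify_patient(trip, fcfg)
        assert list(out["category"]) == ["germline"]
        assert out.iloc[0]["occurrence"] == "P,R1"

    def test_normal_only_variant_is_germline(self, fcfg):
        trip = _triplet(
            _table([(100, "A", "G", 0.5, 200)], sample="N"),
            _table([], sample="P"),
            _table([], sample="R"),
        )
        out = classify_patient(trip, fcfg)
        assert list(out["category"]) == ["germline"]
        assert out.iloc[0]["occurrence"] == ""

    def test_low_depth_in_normal_is_uninformative(self, fcfg):
        trip = _triplet(
            _table([(100, "A", "G", 0.5, 30)], sample="N"),
            _table([(100, "A", "G", 0.5, 200)], sample="P"),
            _table([], sample="R"),
        )
        out = classify_patient(trip, fcfg)
        assert list(out["category"]) == ["uninformative"]

    def test_below_threshold_in_normal_is_tumor_specific(self, fcfg):
        trip = _triplet(
            _table([(100, "A", "G", 0.01, 200)], sample="N"),
            _table([(100, "A", "G", 0.10, 200)], sample="P"),
            _table([], sample="R"),
        )
        out = classify_patient(trip, fcfg)
        assert list(out["category"]) == ["tumor_specific"]

    def test_categories_partition_observed_keys(self, small_cohort, fcfg):
        """Every key gets exactly one category; none is both germline and
        tumor-specific."""
        for trip in small_cohort.triplets:
            out = classify_patient(trip, fcfg)
            keys = out[["pos", "ref", "alt"]].apply(tuple, axis=1)
            assert keys.is_unique
            assert set(out["category"]) <= {
                "germline", "tumor_specific", "uninformative"}


class TestAnnotateKnown:
    def test_known_novel_unannotated(self, fcfg):
        trip = _triplet(
            _table([(100, "A", "G", 0.5, 200), (200, "C", "T", 0.5, 200)],
                   sample="N"),
            _table([], sample="P"),
            _table([], sample="R"),
        )
        classified = classify_patient(trip, fcfg)
        catalog = read_catalog(io.StringIO("pos,ref,alt,id\n100,A,G,mt100\n"))
        out = annotate_known(classified, catalog)
        status = dict(zip(out["pos"], out["known_status"]))
        assert status == {100: "known", 200: "novel"}
        out2 = annotate_known(classified, None)
        assert set(out2["known_status"]) == {"unannotated"}

    def test_malformed_catalog_rejected(self):
        with pytest.raises(ValueError, match="catalog"):
            read_catalog(io.StringIO("pos,ref\n1,A\n"))


class TestCounts:
    def test_zero_variant_patient_gives_zero_row(self, fcfg):
        trip = _triplet(_table([], sample="N"), _table([], sample="P"),
                        _table([], sample="R"))
        counts = count_table(classify_patient(trip, fcfg))
        assert counts.empty or (counts.drop(columns="patient_id") == 0).all().all()

    def test_summary_on_handmade_cohort(self):
        counts = pd.DataFrame({
            "patient_id": ["a", "b"],
            "ts_p": [1, 0], "ts_r": [3, 0],
            "germ_p": [10, 20], "germ_r": [8, 22],
        })
        s = count_summary(counts)
        assert s["tumor_specific"]["mean_per_tumor"] == pytest.approx(1.0)
        assert s["germline"]["max_per_tumor"] == 22
        assert s["n_patients_with_tumor_specific"] == 1
        assert s["mean_paired_difference"] == pytest.approx(1.0)


class TestManifestRoundTrip:
    def test_write_load_build(self, tmp_path, small_cohort):
        from mitodyn.simulate import write_cohort

        write_cohort(small_cohort, tmp_path)
        manifest = read_manifest(tmp_path / "manifest.tsv")
        tables = load_sample_tables(manifest, tmp_path)
        triplets = build_triplets(manifest, tables)
        assert len(triplets) == len(small_cohort.triplets)
        orig = {t.patient_id: t for t in small_cohort.triplets}
        for t in triplets:
            pd.testing.assert_frame_equal(
                t.normal.reset_index(drop=True),
                orig[t.patient_id].normal.reset_index(drop=True),
                check_dtype=False,
            )

    def test_missing_role_rejected(self):
        manifest = read_manifest(io.StringIO(
            "patient_id,sample_id,role\npt1,s1,normal\npt1,s2,relapse\n"))
        with pytest.raises(ValueError, match="lacks a normal or primary"):
            build_triplets(manifest, {"s1": _table([]), "s2": _table([])})
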