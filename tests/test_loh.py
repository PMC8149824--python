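import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_loh, make_track, random_track
from wgdkit.loh import (
    MarkerTrack,
    assign_parent_alleles,
    compute_af,
    detect_loh,
    filter_snps,
    loh_summary,
    triploid_allele_loss,
)


def snp_row(**over):
    row = {
        "chrom": "chr01",
        "pos": 1000,
        "ref": "A",
        "alt": "T",
        "qual": 50.0,
        "ao": 4.0,
        "ro": 20.0,
        "saf": 2.0,
        "sar": 2.0,
        "rpr": 2.0,
        "rpl": 2.0,
        "mqm": 60.0,
        "mqmr": 60.0,
    }
    row.update(over)
    return row


class TestFilterSNPs:
    @pytest.mark.parametrize(
        "override, reason",
        [
            ({"saf": 0.0}, "saf"),
            ({"sar": 0.0}, "sar"),
            ({"qual": 0.5}, "qual"),
            ({"qual": 30.0, "ao": 4.0}, "qual_per_ao"),  # ratio 7.5
            ({"rpr": 1.0}, "rpr"),
            ({"rpl": 0.0}, "rpl"),
            ({"mqm": 50.0, "mqmr": 60.0}, "mqm_ratio"),  # ratio 0.833
            ({"alt": "T,G"}, "multiallelic"),
            ({"ref": "AT"}, "indel"),
            ({"mqm": np.nan}, "missing_fields"),
        ],
    )
    def test_each_criterion_excludes(self, override, reason):
        df = pd.DataFrame([snp_row(), snp_row(pos=2000, **override)])
        kept, dropped = filter_snps(df)
        assert len(kept) == 1
        assert dropped == {reason: 1}

    def test_borderline_quality_ratio_retained(self):
        # QUAL 50 / AO 4 = 12.5 > 10: retained
        kept, dropped = filter_snps(pd.DataFrame([snp_row(qual=50.0, ao=4.0)]))
        assert len(kept) == 1 and not dropped

    def test_repeat_overlap_excluded(self):
        df = pd.DataFrame([snp_row(pos=100), snp_row(pos=5000)])
        bed = pd.DataFrame({"chrom": ["chr01"], "start": [0], "end": [200]})
        kept, dropped = filter_snps(df, repeat_bed=bed)
        assert list(kept["pos"]) == [5000]
        assert dropped == {"repeat": 1}

    def test_matches_predicate_oracle_on_random_records(self, rng):
        n = 400
        df = pd.DataFrame(
            {
                "chrom": "chr01",
                "pos": np.arange(1, n + 1) * 10,
                "ref": "A",
                "alt": "T",
                "qual": rng.uniform(0, 100, n),
                "ao": rng.integers(1, 20, n).astype(float),
                "ro": rng.integers(1, 60, n).astype(float),
                "saf": rng.integers(0, 5, n).astype(float),
                "sar": rng.integers(0, 5, n).astype(float),
                "rpr": rng.integers(0, 5, n).astype(float),
                "rpl": rng.integers(0, 5, n).astype(float),
                "mqm": rng.uniform(50, 65, n),
                "mqmr": rng.uniform(50, 65, n),
            }
        )
        kept, _ = filter_snps(df)
        expected = set()
        for _, r in df.iterrows():  # independent predicate-by-predicate check
            if (
                r["qual"] > 1
                and r["qual"] / r["ao"] > 10
                and r["saf"] > 0
                and r["sar"] > 0
                and r["rpr"] > 1
                and r["rpl"] > 1
                and 0.9 < r["mqm"] / r["mqmr"] < 1.05
            ):
                expected.add(r["pos"])
        assert set(kept["pos"]) == expected


class TestComputeAF:
    def make_markers(self, rows):
        return pd.DataFrame(
            [
                {"chrom": "chr01", "pos": p, "depth_a": a, "total_depth": t}
                for p, a, t in rows
            ]
        )

    def test_depth_exactly_20_excluded(self):
        # the cutoff is strictly greater-than
        tracks = compute_af(self.make_markers([(100, 10, 20), (200, 11, 22)]))
        assert len(tracks) == 1
        assert list(tracks[0].markers["pos"]) == [200]

    def test_balanced_het_af_half(self):
        tracks = compute_af(self.make_markers([(100, 11, 22), (200, 11, 22), (300, 11, 22)]))
        assert np.allclose(tracks[0].markers["af"], 0.5)
        assert tracks[0].baseline_af == pytest.approx(0.5)

    def test_triploid_two_to_one_af(self):
        tracks = compute_af(
            self.make_markers([(100, 20, 30)]), ploidy_context=3
        )
        assert tracks[0].markers["af"].iloc[0] == pytest.approx(2 / 3)

    def test_all_filtered_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="depth filter"):
            assert compute_af(self.make_markers([(100, 5, 10)])) == []


class TestDetectLOH:
    def test_hand_traced_three_marker_segment(self):
        track = make_track([1000, 1100, 1200], [1.0, 1.0, 1.0], baseline=0.5)
        segs = detect_loh(track, max_gap=300)
        assert len(segs) == 1
        (s,) = segs
        assert (s.start, s.end, s.size, s.n_markers) == (1000, 1200, 200, 3)
        assert s.retained_parent == "a"

    def test_two_deviating_markers_insufficient(self):
        track = make_track([1000, 1100], [1.0, 1.0], baseline=0.5)
        assert detect_loh(track, max_gap=300) == []

    def test_gap_beyond_window_breaks_run(self):
        track = make_track([1000, 1100, 1600], [1.0, 1.0, 1.0], baseline=0.5)
        assert detect_loh(track, max_gap=300) == []

    def test_gap_allowed_under_vlb_window(self):
        track = make_track([1000, 1100, 1600], [1.0, 1.0, 1.0], baseline=0.5)
        assert len(detect_loh(track, max_gap=1000)) == 1

    def test_interrupting_non_candidate_breaks_run(self):
        track = make_track(
            [1000, 1100, 1200, 1300, 1400],
            [1.0, 1.0, 0.5, 1.0, 1.0],
            baseline=0.5,
        )
        assert detect_loh(track, max_gap=300) == []

    def test_running_mean_tolerance_splits_drifting_run(self):
        # two level shifts > 0.1 apart cannot share a segment
        track = make_track(
            [1000, 1100, 1200, 1300, 1400, 1500],
            [1.0, 1.0, 1.0, 0.72, 0.72, 0.72],
            baseline=0.5,
        )
        segs = detect_loh(track, max_gap=300)
        assert len(segs) == 2
        assert [s.n_markers for s in segs] == [3, 3]

    def test_terminal_vs_interstitial(self):
        pos = [100, 200, 300, 1000, 1100, 5000, 5100, 5200, 5300]
        af = [1.0, 1.0, 1.0, 0.5, 0.5, 0.0, 0.0, 0.0, 0.0]
        segs = detect_loh(make_track(pos, af, baseline=0.5), max_gap=300)
        kinds = {(s.start, s.kind) for s in segs}
        assert kinds == {(100, "terminal"), (5000, "terminal")}
        # shift the same runs away from the track ends -> interstitial
        pos2 = [50] + pos + [9000]
        af2 = [0.5] + af + [0.5]
        segs2 = detect_loh(make_track(pos2, af2, baseline=0.5), max_gap=300)
        assert {s.kind for s in segs2} == {"interstitial"}

    def test_parent_swap_symmetry(self, rng):
        for _ in range(50):
            track = random_track(rng)
            flipped = MarkerTrack(
                chromosome=track.chromosome,
                markers=track.markers.assign(af=1.0 - track.markers["af"]),
                baseline_af=1.0 - track.baseline_af,
                ploidy_context=track.ploidy_context,
            )
            a = detect_loh(track)
            b = detect_loh(flipped)
            assert [(s.start, s.end, s.n_markers, s.kind) for s in a] == [
                (s.start, s.end, s.n_markers, s.kind) for s in b
            ]
            assert [s.retained_parent for s in b] == [
                {"a": "b", "b": "a"}[s.retained_parent] for s in a
            ]

    def test_matches_brute_force_oracle_on_random_tracks(self, rng):
        for _ in range(300):
            track = random_track(rng)
            got = detect_loh(track)
            expected = brute_force_loh(track)
            assert [
                (s.start, s.end, s.n_markers, s.retained_parent, s.kind) for s in got
            ] == [
                (e["start"], e["end"], e["n_markers"], e["retained_parent"], e["kind"])
                for e in expected
            ]

    def test_low_marker_density_refused(self):
        track = make_track([1, 50_000, 100_000], [1.0, 1.0, 1.0], baseline=0.5)
        with pytest.raises(ValueError, match="density"):
            detect_loh(track, min_marker_density=1 / 10_000)


class TestSummary:
    def segment_set(self):
        pos_small = [1000, 1400, 1800]  # 800 bp tract
        pos_big = [10_000, 10_300, 10_600, 11_500, 12_400]  # 2.4 kb tract
        track = make_track(
            [500] + pos_small + [5000] + pos_big + [50_000],
            [0.5] + [1.0] * 3 + [0.5] + [0.0] * 5 + [0.5],
            baseline=0.5,
        )
        return detect_loh(track, max_gap=1000)

    def test_small_segment_only_in_full_table(self):
        segs = self.segment_set()
        per_line, table = loh_summary({"l1": segs}, min_size_for_comparison=1000)
        assert per_line["n_segments"].iloc[0] == 2
        assert per_line["n_comparison"].iloc[0] == 1
        assert set(table["size"]) == {800, 2400}
        assert not table.loc[table["size"] == 800, "in_comparison"].iloc[0]

    def test_no_segments_zero_rates(self):
        per_line, table = loh_summary({"l1": []})
        assert per_line["n_segments"].iloc[0] == 0
        assert table.empty


class TestTriploid:
    def test_one_of_two_spc_copies_lost(self):
        # baseline 2/3 (two copies of parent a); tract at 1/3 lost one a copy
        track = make_track(
            [1000, 1100, 1200, 2000],
            [1 / 3, 1 / 3, 1 / 3, 2 / 3],
            baseline=0.66,
            ploidy_context=3,
        )
        ann = triploid_allele_loss(track, max_gap=300)
        assert len(ann) == 1
        row = ann.iloc[0]
        assert row["lost_parent"] == "a"
        assert row["copies_lost"] == 1
        assert row["two_copy_parent"] == "a"

    def test_single_copy_parent_fully_lost(self):
        track = make_track(
            [1000, 1100, 1200, 2000],
            [0.0, 0.0, 0.0, 1 / 3],
            baseline=0.34,
            ploidy_context=3,
        )
        ann = triploid_allele_loss(track, max_gap=300)
        assert len(ann) == 1
        assert ann.iloc[0]["lost_parent"] == "a"
        assert ann.iloc[0]["two_copy_parent"] == "b"

    def test_inconsistent_baseline_warns(self):
        track = make_track(
            [1000, 1100, 1200], [0.5, 0.5, 0.5], baseline=0.5, ploidy_context=3
        )
        with pytest.warns(UserWarning, match="triploid"):
            triploid_allele_loss(track)


VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr01,length=230000>
##INFO=<ID=AO,Number=A,Type=Integer,Description="Alternate allele observations">
##INFO=<ID=RO,Number=1,Type=Integer,Description="Reference allele observations">
##INFO=<ID=SAF,Number=A,Type=Integer,Description="Alt observations forward strand">
##INFO=<ID=SAR,Number=A,Type=Integer,Description="Alt observations reverse strand">
##INFO=<ID=RPR,Number=A,Type=Float,Description="Reads right of alt">
##INFO=<ID=RPL,Number=A,Type=Float,Description="Reads left of alt">
##INFO=<ID=MQM,Number=A,Type=Float,Description="Mean mapping quality alt">
##INFO=<ID=MQMR,Number=1,Type=Float,Description="Mean mapping quality ref">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


class TestVCFReader:
    def test_freebayes_vcf_parsed_and_filtered(self, tmp_path):
        body = [
            # passes every filter
            "chr01\t1000\t.\tA\tT\t500\t.\t"
            "AO=20;RO=22;SAF=10;SAR=10;RPR=9;RPL=11;MQM=60;MQMR=60",
            # multiallelic: read but dropped by filter_snps
            "chr01\t2000\t.\tG\tC,T\t300\t.\t"
            "AO=10,8;RO=20;SAF=5,4;SAR=5,4;RPR=5,4;RPL=5,4;MQM=60,59;MQMR=60",
            # one-sided strand support: dropped
            "chr01\t3000\t.\tC\tG\t400\t.\t"
            "AO=18;RO=20;SAF=18;SAR=0;RPR=9;RPL=9;MQM=60;MQMR=60",
        ]
        path = tmp_path / "calls.vcf"
        path.write_text(VCF_HEADER + "\n".join(body) + "\n")
        from wgdkit.loh import read_freebayes_vcf

        df = read_freebayes_vcf(path)
        assert list(df["pos"]) == [1000, 2000, 3000]
        assert df.loc[0, "ro"] == 22
        kept, dropped = filter_snps(df)
        assert list(kept["pos"]) == [1000]
        assert dropped == {"multiallelic": 1, "sar": 1}


class TestParentAssignment:
    def test_heterozygous_parent_pair_labelled(self):
        snps = pd.DataFrame(
            [
                snp_row(pos=100, ref="A", alt="T", ro=30.0, ao=10.0),
                snp_row(pos=200, ref="G", alt="C", ro=12.0, ao=18.0),
                snp_row(pos=300, ref="A", alt="T", ro=20.0, ao=20.0),
            ]
        )
        parents = pd.DataFrame(
            {
                "chrom": ["chr01", "chr01", "chr01"],
                "pos": [100, 200, 300],
                "parent_a_allele": ["A", "C", "G"],
                "parent_b_allele": ["T", "G", "G"],
            }
        )
        out = assign_parent_alleles(snps, parents)
        # pos 300: parents not heterozygous there; also allele pair mismatch
        assert list(out["pos"]) == [100, 200]
        assert list(out["depth_a"]) == [30.0, 18.0]
        assert list(out["total_depth"]) == [40.0, 30.0]
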