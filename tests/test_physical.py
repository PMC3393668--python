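import numpy as np
import pandas as pd
import pytest

from f2linkage import mapbuild as mb, physical as ph, simulate as sim


class TestFlankLength:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ACGT[A/G]TT", 4), ("[C/T]AAA", 0), ("A" * 60 + "[G/T]" + "C" * 10, 60)],
    )
    def test_left_flank_counted(self, seq, expected):
        assert ph.flank_length_from_bracket(seq) == expected

    @pytest.mark.parametrize("seq", ["ACGTTT", "A[A/G]C[C/T]G", "AC[AG/T]T"])
    def test_malformed_rejected(self, seq):
        with pytest.raises(ph.PhysicalError):
            ph.flank_length_from_bracket(seq)

    def test_flanked_snp_consistency_checked(self):
        with pytest.raises(ph.PhysicalError, match="disagrees"):
            ph.FlankedSnp("s", 3, bracket_seq="ACGT[A/G]TT")


class TestBestHit:
    def make_hit(self, score, evalue=1e-50, chrom="ch01"):
        return ph.AlignmentHit("q", chrom, 1, 100, 1000, 1099, score, evalue)

    def test_single_hit_returned(self):
        hit = self.make_hit(180.0)
        best, ambiguous = ph.select_best_hit([hit])
        assert best is hit and not ambiguous

    def test_highest_bitscore_wins(self):
        best, _ = ph.select_best_hit([self.make_hit(120.0), self.make_hit(180.0)])
        assert best.bitscore == 180.0

    def test_evalue_breaks_bitscore_tie(self):
        best, ambiguous = ph.select_best_hit(
            [self.make_hit(180.0, evalue=1e-40), self.make_hit(180.0, evalue=1e-60)]
        )
        assert not ambiguous and best.evalue == 1e-60

    def test_full_tie_is_ambiguous(self):
        best, ambiguous = ph.select_best_hit(
            [self.make_hit(180.0, chrom="ch01"), self.make_hit(180.0, chrom="ch02")]
        )
        assert ambiguous and best is None

    def test_empty_list_errors(self):
        with pytest.raises(ph.PhysicalError, match="no alignment hits"):
            ph.select_best_hit([])


class TestSnpPosition:
    def test_forward_strand(self):
        hit = ph.AlignmentHit("q", "ch01", 1, 120, 1000, 1119, 200.0, 1e-50)
        assert ph.snp_position_from_hit(hit, ph.FlankedSnp("q", 60)).position_bp == 1060

    def test_reverse_strand(self):
        hit = ph.AlignmentHit("q", "ch01", 1, 120, 5000, 4881, 200.0, 1e-50)
        assert ph.snp_position_from_hit(hit, ph.FlankedSnp("q", 60)).position_bp == 4940

    def test_zero_flank_is_subject_start(self):
        hit = ph.AlignmentHit("q", "ch01", 1, 120, 777, 896, 200.0, 1e-50)
        assert ph.snp_position_from_hit(hit, ph.FlankedSnp("q", 0)).position_bp == 777

    def test_partial_alignment_offset(self):
        # alignment starts at query base 11; SNP at base 61 is 50 bases in
        hit = ph.AlignmentHit("q", "ch01", 11, 120, 1000, 1109, 200.0, 1e-50)
        assert ph.snp_position_from_hit(hit, ph.FlankedSnp("q", 60)).position_bp == 1050

    def test_uncovered_site_errors(self):
        hit = ph.AlignmentHit("q", "ch01", 70, 120, 1000, 1050, 200.0, 1e-50)
        with pytest.raises(ph.PhysicalError, match="outside aligned"):
            ph.snp_position_from_hit(hit, ph.FlankedSnp("q", 10))

    @pytest.mark.parametrize("strand", ["forward", "reverse"])
    @pytest.mark.parametrize("flank", [0, 17, 59])
    def test_round_trip_recovers_planted_position(self, strand, flank):
        """Plant a SNP in a synthetic chromosome, derive the hit analytically,
        and recover the original bp exactly on both strands."""
        true_pos = 123_456
        qlen = 121
        if strand == "forward":
            sstart = true_pos - flank
            send = sstart + qlen - 1
        else:
            sstart = true_pos + flank
            send = sstart - qlen + 1
        hit = ph.AlignmentHit("q", "ch05", 1, qlen, sstart, send, 240.0, 1e-60)
        placed = ph.snp_position_from_hit(hit, ph.FlankedSnp("q", flank))
        assert placed.position_bp == true_pos


class TestPlaceSnps:
    def test_report_covers_failures(self):
        frame = pd.DataFrame(
            [
                ["s1", "ch01", 100.0, 120, 0, 0, 1, 120, 1000, 1119, 1e-50, 200.0],
                ["s2", "ch01", 100.0, 120, 0, 0, 1, 120, 2000, 2119, 1e-50, 200.0],
                ["s2", "ch02", 100.0, 120, 0, 0, 1, 120, 3000, 3119, 1e-50, 200.0],
            ],
            columns=ph.BLAST_COLUMNS,
        )
        snps = [ph.FlankedSnp("s1", 60), ph.FlankedSnp("s2", 60), ph.FlankedSnp("s3", 60)]
        placements, report = ph.place_snps(frame, snps)
        assert list(placements["marker_id"]) == ["s1"]
        reasons = dict(zip(report["marker_id"], report["reason"]))
        assert reasons == {"s2": "ambiguous_best_hit", "s3": "no_hit"}


class TestSynteny:
    def make_map(self):
        g1 = mb.LinkageGroup("LG1", ["a", "b", "c"], np.array([0.0, 5.0, 10.0]), np.arange(3))
        g2 = mb.LinkageGroup("LG2", ["d", "e"], np.array([0.0, 5.0]), np.arange(2))
        return mb.LinkageMap([g1, g2])

    def test_concordant_set_no_nonsyntenic(self):
        placements = pd.DataFrame(
            {
                "marker_id": list("abcde"),
                "chromosome": ["ch01"] * 3 + ["ch02"] * 2,
                "position_bp": [1, 2, 3, 1, 2],
            }
        )
        syn, non, assigned = ph.synteny_classify(self.make_map(), placements)
        assert non == []
        assert assigned == {"LG1": "ch01", "LG2": "ch02"}

    def test_cross_assigned_marker_flagged(self):
        placements = pd.DataFrame(
            {
                "marker_id": list("abcde"),
                "chromosome": ["ch01", "ch01", "ch02", "ch02", "ch02"],
                "position_bp": [1, 2, 3, 1, 2],
            }
        )
        syn, non, _ = ph.synteny_classify(self.make_map(), placements)
        assert non == ["c"]


class TestPhysicalSummary:
    def test_arithmetic(self):
        placements = pd.DataFrame(
            {
                "marker_id": ["a", "b", "c"],
                "chromosome": ["ch01"] * 3,
                "position_bp": [1, 2_000_001, 3_000_001],
            }
        )
        df = ph.physical_summary(placements)
        row = df[df["chromosome"] == "ch01"].iloc[0]
        assert row["coverage_Mbp"] == pytest.approx(3.0)
        assert row["max_gap_Mbp"] == pytest.approx(2.0)

    def test_single_marker_degenerate(self):
        placements = pd.DataFrame(
            {"marker_id": ["a"], "chromosome": ["ch01"], "position_bp": [500]}
        )
        df = ph.physical_summary(placements)
        row = df[df["chromosome"] == "ch01"].iloc[0]
        assert row["coverage_Mbp"] == 0.0
        assert row["max_gap_Mbp"] == 0.0
        assert bool(row["single_marker"])

    def test_total_row_sums_chromosomes(self):
        rng = np.random.default_rng(0)
        placements = pd.DataFrame(
            {
                "marker_id": [f"s{k}" for k in range(60)],
                "chromosome": [f"ch{1 + k % 3:02d}" for k in range(60)],
                "position_bp": rng.integers(1, 50_000_000, size=60),
            }
        )
        df = ph.physical_summary(placements)
        total = df[df["chromosome"] == "Total"].iloc[0]
        per = df[df["chromosome"] != "Total"]
        assert total["coverage_Mbp"] == pytest.approx(per["coverage_Mbp"].sum())
        assert total["n_markers"] == per["n_markers"].sum()


class TestMareyProfile:
    def test_linear_map_constant_rate(self):
        bp = np.linspace(1, 20_000_000, 60)
        cm = 2.0 * bp / 1e6
        prof = ph.marey_rate_profile(cm, bp)
        rates = prof.windows["rate_cM_per_Mbp"].dropna()
        assert rates.min() == pytest.approx(2.0, abs=1e-6)
        assert rates.max() == pytest.approx(2.0, abs=1e-6)
        assert prof.suppression_regions == []
        assert prof.clamped_windows == 0

    def test_flat_region_reported(self):
        bp = np.linspace(1, 30_000_000, 90)
        cm = np.where(bp < 10e6, bp / 1e6, 10.0)
        cm = np.where(bp > 20e6, 10.0 + (bp - 20e6) / 1e6, cm)
        prof = ph.marey_rate_profile(cm, bp, suppression_rate=0.2, suppression_span_mb=2.0)
        assert len(prof.suppression_regions) == 1
        s, e = prof.suppression_regions[0]
        assert s < 12e6 and e > 18e6

    def test_monotone_map_never_clamped(self):
        rng = np.random.default_rng(3)
        bp = np.sort(rng.integers(1, 40_000_000, size=120))
        cm = np.cumsum(rng.uniform(0, 1, size=120))
        prof = ph.marey_rate_profile(cm, bp)
        assert prof.clamped_windows == 0
        assert (prof.windows["rate_cM_per_Mbp"].dropna() >= 0).all()

    def test_synthetic_plateau_recovered(self):
        """Pericentromeric compression shows up as a suppression region
        covering the constructed plateau."""
        ch = sim.bp_uniform_chromosome("c", 200, 100.0, pericentromere=(0.25, 0.75), compression=20.0)
        prof = ph.marey_rate_profile(ch.cm_positions, ch.bp_positions)
        span = ch.bp_positions[-1]
        plateau = (0.25 * span, 0.75 * span)
        overlap = sum(
            max(0.0, min(e, plateau[1]) - max(s, plateau[0]))
            for s, e in prof.suppression_regions
        )
        assert overlap >= 0.8 * (plateau[1] - plateau[0])
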