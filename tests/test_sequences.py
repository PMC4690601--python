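"""Osmylation accounting: counts, profiles, duplex arithmetic, R calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osmotrace.datasets import AMPLICON_202BP, OLIGO_PANEL, r_calibration_points
from osmotrace.sequences import (
    DUPLEX_PARTIAL,
    PROTOCOL_A,
    PROTOCOL_B,
    DuplexOsmylationSummary,
    NucleotideSequence,
    OsmylationProtocol,
    SequenceValidationError,
    count_osmylatable,
    duplex_osmylation_summary,
    fit_r_calibration,
    label_positions,
    osmylation_fraction,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=120)


class TestNucleotideSequence:
    def test_normalizes_case_and_whitespace(self):
        seq = NucleotideSequence("x", "acg t\nTT")
        assert seq.bases == "ACGTTT"
        assert len(seq) == 6

    def test_rejects_non_acgt_with_position(self):
        with pytest.raises(SequenceValidationError) as exc:
            NucleotideSequence("x", "ACGNU")
        assert exc.value.position == 4
        assert exc.value.residue == "N"

    def test_rejects_uracil(self):
        with pytest.raises(SequenceValidationError):
            NucleotideSequence("rna", "ACGU")

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            NucleotideSequence("x", "  ")


class TestCountOsmylatable:
    @pytest.mark.parametrize(
        "rec", [r for r in OLIGO_PANEL if r.protocol is not None], ids=lambda r: r.sample_id
    )
    def test_reproduces_panel_counts(self, rec):
        """Every oligo's reported osbipy count follows from its sequence."""
        assert count_osmylatable(rec.sequence, rec.protocol) == rec.osbipy_count

    def test_single_thymine(self):
        assert count_osmylatable(NucleotideSequence("t", "ACGT"), PROTOCOL_A) == 1

    @given(dna)
    @settings(max_examples=200, deadline=None)
    def test_protocol_b_dominates_a(self, bases):
        """T+C labeling can never modify fewer bases than T-only labeling."""
        seq = NucleotideSequence("h", bases)
        a = count_osmylatable(seq, PROTOCOL_A)
        b = count_osmylatable(seq, PROTOCOL_B)
        assert b >= a
        assert (b == a) == (seq.count("C") == 0)


class TestOsmylationProfile:
    def test_deterministic_profile_marks_every_target(self):
        rec = next(r for r in OLIGO_PANEL if r.sample_id == "ODN3-R2")
        profile = label_positions(rec.sequence, PROTOCOL_B)
        assert profile.osbipy_count == 10
        assert osmylation_fraction(profile) == pytest.approx(0.5)
        for pos in profile.modified_positions:
            assert rec.sequence.bases[pos - 1] in "TC"

    def test_fraction_examples(self):
        odn4 = next(r for r in OLIGO_PANEL if r.sample_id == "ODN4-R2")
        profile = label_positions(odn4.sequence, PROTOCOL_B)
        assert profile.osmylation_fraction == pytest.approx(41 / 80)
        unreacted = label_positions(odn4.sequence, OsmylationProtocol("none", 0.0, 0.0))
        assert unreacted.osbipy_count == 0

    def test_stochastic_labeling_is_bernoulli_thinning(self, rng):
        seq = NucleotideSequence("t30", "GCA" + "T" * 300)
        profile = label_positions(seq, DUPLEX_PARTIAL, rng=rng)
        t_positions = {i for i, b in enumerate(seq.bases, 1) if b == "T"}
        assert profile.modified_positions <= t_positions
        # Binomial(300, 0.5): 4-sigma band
        assert abs(profile.osbipy_count - 150) < 4 * np.sqrt(300 * 0.25)

    def test_profile_rejects_position_on_wrong_base(self):
        seq = NucleotideSequence("x", "ACGT")
        from osmotrace.sequences import OsmylationProfile

        with pytest.raises(ValueError):
            OsmylationProfile(seq, PROTOCOL_A, frozenset({1}))  # position 1 is A


class TestDuplexSummary:
    def test_reference_arithmetic(self):
        """55% AT pairs at half T-efficiency -> 27.5% strand osmylation, ~55 bp."""
        s = DuplexOsmylationSummary(length_bp=202, at_pair_fraction=0.55, t_efficiency=0.5)
        assert s.strand_osmylation_percent == pytest.approx(27.5)
        assert s.expected_osmylated_bp == pytest.approx(55.55)
        assert abs(s.expected_osmylated_bp - 55) <= 1

    def test_zero_efficiency(self):
        s = duplex_osmylation_summary(AMPLICON_202BP, 0.0)
        assert s.strand_osmylation_percent == 0.0
        assert s.expected_osmylated_bp == 0.0

    def test_amplicon_composition(self):
        """The built-in 202-nt strand is ~55% A+T, as quoted for the duplex."""
        assert len(AMPLICON_202BP) == 202
        assert AMPLICON_202BP.at_fraction == pytest.approx(0.55, abs=0.005)

    def test_linear_in_efficiency(self):
        s1 = duplex_osmylation_summary(AMPLICON_202BP, 0.25)
        s2 = duplex_osmylation_summary(AMPLICON_202BP, 0.5)
        assert s2.expected_osmylated_bp == pytest.approx(2 * s1.expected_osmylated_bp)
        full = duplex_osmylation_summary(AMPLICON_202BP, 1.0)
        assert full.expected_osmylated_bp == pytest.approx(
            len(AMPLICON_202BP) * AMPLICON_202BP.at_fraction
        )

    def test_efficiency_out_of_range(self):
        with pytest.raises(ValueError):
            duplex_osmylation_summary(AMPLICON_202BP, 1.5)


def _ols_closed_form(points):
    x = np.array([p[0] for p in points])
    y = np.array([p[1] for p in points])
    slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
    return slope, y.mean() - slope * x.mean()


class TestRCalibration:
    def test_panel_fit_matches_closed_form(self):
        """OLS on the panel's (fraction, R) pairs: slope ~2.13, intercept ~0.015."""
        points = r_calibration_points()
        fit = fit_r_calibration(points)
        slope, intercept = _ols_closed_form(points)
        assert fit.slope == pytest.approx(slope, abs=1e-9)
        assert fit.intercept == pytest.approx(intercept, abs=1e-9)
        assert fit.slope == pytest.approx(2.1319, abs=1e-3)
        assert fit.intercept == pytest.approx(0.0149, abs=1e-3)

    def test_prediction_near_unmodified_baseline(self):
        fit = fit_r_calibration(r_calibration_points())
        # unreacted oligos measured R = 0.03; agreement is loose (one residual sd)
        assert abs(fit.predict_R(0.0) - 0.03) <= fit.residual_sd

    def test_residual_sd_small_relative_to_range(self):
        fit = fit_r_calibration(r_calibration_points())
        r_values = [r for _, r in fit.points]
        assert fit.residual_sd < 0.1 * (max(r_values) - min(r_values))

    def test_two_point_line(self):
        fit = fit_r_calibration([(0.0, 0.0), (1.0, 1.0)])
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_r_calibration([(0.3, 0.5), (0.3, 0.6)])

    def test_summary_mentions_slope(self):
        assert "slope" in fit_r_calibration(r_calibration_points()).summary()
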