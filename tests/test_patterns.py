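"""Sign/quadrant classification, k-mer counting, bootstrap SDs, distributions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmjoints.geometry import AngleSeries, DihedralRecord
from tmjoints.patterns import (
    DEFAULT_TM_GROUPS,
    SignSequence,
    angle_distributions,
    bootstrap_sd,
    classify_quadrant,
    consecutive_patterns,
    count_patterns,
    quadrant_sequence,
    sign_of,
    sign_sequence,
    write_histogram_tsv,
    write_pattern_tsv,
)
from tmjoints.synthetic import build_chain, generate_cohort
from tmjoints.geometry import compute_series


def series_from_angles(pid, angles):
    """Build an AngleSeries directly from an alternating angle list."""
    records = []
    for k, a in enumerate(angles, start=1):
        kind, index = ("omega", (k + 1) // 2) if k % 2 == 1 else ("lambda", k // 2)
        records.append(DihedralRecord(pid, kind, index, a, (k, k + 1, k + 2, k + 3)))
    return AngleSeries(pid, (len(angles) + 3) // 2, records)


class TestClassification:
    @pytest.mark.parametrize("angle, expected", [(23.4, "+"), (-0.1, "-"), (180.0, "+")])
    def test_sign_of(self, angle, expected):
        assert sign_of(angle) == expected

    def test_exact_zero_is_positive_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert sign_of(0.0) == "+"
        assert "boundary" in caplog.text

    @pytest.mark.parametrize(
        "angle, expected",
        [(45, "A"), (135, "B"), (-45, "-A"), (-135, "-B"),
         (90, "A"), (180, "B"), (-90, "-A"), (0.0, "A")],
    )
    def test_quadrants_and_boundary_edges(self, angle, expected):
        assert classify_quadrant(angle) == expected

    def test_quadrant_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            classify_quadrant(-180.0)

    @given(st.floats(min_value=-179.99, max_value=180.0, allow_nan=False))
    @settings(max_examples=200, derandomize=True)
    def test_quadrant_sign_consistency(self, angle):
        """A/B quadrants carry '+' angles, -A/-B carry '-' (0 goes to A/+)."""
        q = classify_quadrant(angle)
        s = sign_of(angle)
        assert (q in ("A", "B")) == (s == "+")


class TestWindows:
    @pytest.mark.parametrize(
        "signs, k, expected",
        [(("+", "+", "-"), 2, [("+", "+"), ("+", "-")]),
         (("+", "-"), 3, []),
         (("-", "-", "-", "-"), 3, [("-", "-", "-"), ("-", "-", "-")])],
    )
    def test_enumeration(self, signs, k, expected):
        seq = SignSequence("P", "omega", signs)
        assert consecutive_patterns(seq, k) == expected

    def test_only_dyads_and_triads_supported(self):
        with pytest.raises(ValueError):
            consecutive_patterns(SignSequence("P", "omega", ("+",)), 4)


class TestCountPatterns:
    def test_two_protein_omega_dyads_zero_filled(self):
        cohort = [series_from_angles("P1", [10, 50, 20]),    # omega signs (+, +)
                  series_from_angles("P2", [15, -60, -25])]  # omega signs (+, -)
        (pc,) = count_patterns(cohort, "omega", 2)
        assert pc.counts == {("+", "+"): 1, ("+", "-"): 1, ("-", "+"): 0, ("-", "-"): 0}

    def test_lambda_quadrant_dyads_have_16_patterns(self):
        # one protein, 5 helices: lambda angles all in -A
        cohort = [series_from_angles("P1", [10, -45, 20, -30, 15, -60, 25])]
        (pc,) = count_patterns(cohort, "lambda", 2, alphabet="quadrant")
        assert len(pc.counts) == 16
        assert pc.counts[("-A", "-A")] == 2
        assert sum(pc.counts.values()) == 2

    def test_quadrants_rejected_for_omega(self):
        cohort = [series_from_angles("P1", [10, -45, 20])]
        with pytest.raises(ValueError, match="lambda"):
            count_patterns(cohort, "omega", 2, alphabet="quadrant")

    def test_tm_size_groups_partition_the_cohort(self):
        four = generate_cohort(1, (4, 4), seed=0)[0]
        twelve = generate_cohort(1, (12, 12), seed=1)[0]
        cohort = [compute_series(build_chain(s)) for s in (four, twelve)]
        groups = count_patterns(cohort, "omega", 2, groups=DEFAULT_TM_GROUPS)
        assert [g.group_label for g in groups] == ["3-6 TM", "7-10 TM", "11-14 TM"]
        assert groups[0].total == 2   # 4 TM: 3 omega -> 2 dyads
        assert groups[1].total == 0
        assert groups[2].total == 10  # 12 TM: 11 omega -> 10 dyads

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_window_count_conservation(self, seed):
        """Total dyad/triad counts equal sum over proteins of max(L-k+1, 0)."""
        cohort_specs = generate_cohort(8, (3, 9), seed=seed)
        cohort = [compute_series(build_chain(s)) for s in cohort_specs]
        for kind in ("omega", "lambda"):
            for k in (2, 3):
                (pc,) = count_patterns(cohort, kind, k)
                expected = sum(max(len(s.angles(kind)) - k + 1, 0) for s in cohort)
                assert pc.total == expected


class TestBootstrap:
    def test_degenerate_resample_has_zero_sd(self):
        sd = bootstrap_sd([("+", "+")] * 10, B=200, seed=0)
        assert sd[("+", "+")] == 0.0
        assert sd[("-", "-")] == 0.0  # impossible pattern: SD 0

    def test_fixed_seed_is_deterministic(self):
        obs = [("+", "-"), ("-", "-"), ("+", "+")] * 4
        assert bootstrap_sd(obs, B=100, seed=7) == bootstrap_sd(obs, B=100, seed=7)

    def test_two_observation_sd_matches_binomial_closed_form(self):
        """N=2 windows, one (+,+) and one (-,-): resampled count of (+,+) is
        Binomial(2, 1/2), so its SD is sqrt(0.5) ~ 0.707."""
        sd = bootstrap_sd([("+", "+"), ("-", "-")], B=500, seed=11)
        assert sd[("+", "+")] == pytest.approx(np.sqrt(0.5), rel=0.10)
        assert sd[("-", "-")] == pytest.approx(np.sqrt(0.5), rel=0.10)

    def test_empty_observations_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_sd([], B=10, seed=0)

    def test_protein_level_resampling_option(self):
        groups = [[("+", "+")] * 3, [("-", "-")] * 3]
        obs = [w for g in groups for w in g]
        sd = bootstrap_sd(obs, B=400, seed=3, protein_groups=groups)
        # counts jump in steps of 3 -> SD is 3x the binomial window SD
        assert sd[("+", "+")] == pytest.approx(3 * np.sqrt(0.5), rel=0.15)


class TestDistributions:
    def test_three_helix_protein_has_one_scatter_pair(self):
        cohort = [series_from_angles("P1", [10, -45, 20])]
        dist = angle_distributions(cohort)
        assert len(dist.scatter) == 1
        pid, i, om, lam = dist.scatter[0]
        assert (pid, i, om, lam) == ("P1", 1, 10, -45)

    def test_range_query_fraction(self):
        cohort = [series_from_angles("P1", [-20, 100, 20])]
        dist = angle_distributions(cohort)
        assert dist.omega_fraction_in(-40, 40) == 1.0
        assert dist.omega_fraction_in(0, 40) == 0.5

    def test_generator_controlled_bimodal_histogram(self, small_cohort):
        """Cohort omegas drawn from +-(10..40) must leave bins beyond +-40 empty."""
        cohort = [compute_series(build_chain(s)) for s in small_cohort]
        dist = angle_distributions(cohort, bin_width=20.0)
        counts, edges = dist.omega_hist
        outside = (edges[:-1] >= 40) | (edges[1:] <= -40)
        assert counts[outside].sum() == 0
        assert counts[~outside].sum() == len(dist.omega_all)
        # bimodal: the two flanking 20-degree bands outnumber the central band
        central = counts[(edges[:-1] >= -20) & (edges[1:] <= 20)].sum()
        flanks = counts[((edges[:-1] >= -40) & (edges[1:] <= -20))
                        | ((edges[:-1] >= 20) & (edges[1:] <= 40))].sum()
        assert flanks > central

    def test_per_position_pools_align_with_indices(self, small_cohort):
        cohort = [compute_series(build_chain(s)) for s in small_cohort]
        dist = angle_distributions(cohort)
        n_om_1 = sum(1 for s in cohort if len(s.omega) >= 1)
        assert len(dist.omega_by_position[1]) == n_om_1
        max_lam = max(len(s.lam) for s in cohort)
        assert max(dist.lambda_by_position) == max_lam

    def test_bin_width_must_divide_360(self):
        cohort = [series_from_angles("P1", [10, -45, 20])]
        with pytest.raises(ValueError):
            angle_distributions(cohort, bin_width=25.0)

    def test_report_writers_are_well_formed(self, small_cohort):
        cohort = [compute_series(build_chain(s)) for s in small_cohort[:6]]
        pcs = count_patterns(cohort, "lambda", 2, alphabet="quadrant",
                             bootstrap_reps=50, seed=1)
        tsv = write_pattern_tsv(pcs)
        assert len(tsv.splitlines()) == 17  # header + 16 quadrant dyads
        hist = write_histogram_tsv(angle_distributions(cohort))
        assert len(hist.splitlines()) == 1 + 2 * 18  # 18 bins per kind at 20 deg
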