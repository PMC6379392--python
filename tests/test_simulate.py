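"""The synthetic-data generator: determinism, conservation, mixing law."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import alkdeep as ad
from alkdeep import reference as R
from alkdeep import simulate as S
from alkdeep.errors import InvalidConfigurationError, TooFewControlsError


class TestErrorProfile:
    def test_rates_respect_invariants(self, profile):
        assert (profile.rates >= 0).all()
        assert (profile.rates <= S.MAX_RATE).all()
        assert (profile.rates.sum(axis=1) < 0.15).all()
        # reference base carries no error rate
        for i, b in enumerate(R.BASES):
            assert (profile.rates[profile.ref_bases == b, i] == 0).all()

    def test_deterministic_given_seed(self):
        a = ad.draw_error_profile(seed=5)
        b = ad.draw_error_profile(seed=5)
        assert np.array_equal(a.rates, b.rates)
        assert not np.array_equal(a.rates, ad.draw_error_profile(seed=6).rates)

    def test_median_rate_near_configured_location(self):
        prof = ad.draw_error_profile(seed=9)
        alt_rates = prof.rates[prof.rates > 0]
        assert len(alt_rates) >= 1000
        med = np.median(alt_rates)
        assert 5e-4 <= med <= 2e-3  # within a factor 2 of 1e-3


class TestSimulatePileup:
    def test_counts_sum_to_depth_everywhere(self, profile):
        sample = ad.SimulatedSample("s", depth=7000, seed=1)
        pu = ad.simulate_pileup(sample, profile)
        assert (pu[["A", "C", "G", "T", "other"]].sum(axis=1) == pu["depth"]).all()
        assert (pu["depth"] == 7000).all()

    def test_spike_fraction_within_binomial_noise(self, profile, reference):
        # emulates a clonal F1245I tumour at 53% VAF
        pos, _, alt = R.mutation_site("F1245I", reference)
        sample = ad.SimulatedSample(
            "t", spike_ins=(ad.SpikeIn(pos, alt, 0.53),), depth=10000, seed=3
        )
        pu = ad.simulate_pileup(sample, profile, jitter_sigma_log10=0.0)
        row = pu[pu["pos"] == pos].iloc[0]
        frac = row[alt] / row["depth"]
        assert abs(frac - 0.53) <= 3 * np.sqrt(0.53 * 0.47 / 10000)

    def test_purity_scales_somatic_but_not_germline_spikes(self, reference):
        prof = ad.draw_error_profile(seed=2, rate_median=1e-12)
        pos, _, alt = R.mutation_site("F1174L", reference)
        fracs = {}
        for germline in (False, True):
            totals = 0
            for seed in range(40):
                sample = ad.SimulatedSample(
                    "t", purity=0.5,
                    spike_ins=(ad.SpikeIn(pos, alt, 0.6, germline=germline),),
                    depth=5000, seed=seed,
                )
                pu = ad.simulate_pileup(sample, prof, jitter_sigma_log10=0.0)
                row = pu[pu["pos"] == pos].iloc[0]
                totals += row[alt] / row["depth"]
            fracs[germline] = totals / 40
        assert fracs[False] == pytest.approx(0.30, abs=0.01)  # purity x VAF
        assert fracs[True] == pytest.approx(0.60, abs=0.01)  # constitutional

    def test_zero_error_profile_gives_zero_alt_counts(self):
        prof = ad.draw_error_profile(seed=4, rate_median=0.0)
        sample = ad.SimulatedSample("s", depth=5000, seed=5)
        pu = ad.simulate_pileup(sample, prof, jitter_sigma_log10=0.0)
        melted = pu.melt(id_vars=["ref"], value_vars=list(R.BASES),
                         var_name="base", value_name="count")
        assert (melted.loc[melted["base"] != melted["ref"], "count"] == 0).all()

    def test_overloaded_probabilities_raise(self, profile, reference):
        pos, _, alt = R.mutation_site("F1174L", reference)
        spikes = (ad.SpikeIn(pos, alt, 0.99),)
        other_alt = next(
            b for b in R.BASES if b not in (alt, reference.base(pos))
        )
        spikes += (ad.SpikeIn(pos, other_alt, 0.99),)
        sample = ad.SimulatedSample("s", spike_ins=spikes, depth=100, seed=0)
        with pytest.raises(InvalidConfigurationError):
            ad.simulate_pileup(sample, profile)


class TestControlCohort:
    def test_cohort_shape_and_depth(self, controls):
        assert len(controls) == 8
        for ctrl in controls:
            assert (ctrl["depth"] >= 5000).all()
            assert len(ctrl) == R.total_target_span()

    def test_single_control_rejected(self, profile):
        with pytest.raises(TooFewControlsError):
            ad.simulate_control_cohort(profile, n_controls=1)

    def test_no_jitter_leaves_pure_binomial_spread(self, profile):
        # across many controls the per-position alt-fraction SD should match
        # the binomial prediction when sample jitter is off
        ctrls = ad.simulate_control_cohort(
            profile, n_controls=40, depth=20000, seed=11, jitter_sigma_log10=0.0
        )
        pos = int(profile.positions[10])
        ref_base = str(profile.ref_bases[10])
        alt = next(b for b in R.BASES if b != ref_base)
        fracs = np.array([
            c.loc[c["pos"] == pos, alt].iloc[0] / 20000 for c in ctrls
        ])
        rate = profile.rate(pos, alt)
        binom_sd = np.sqrt(rate * (1 - rate) / 20000)
        assert fracs.std(ddof=1) == pytest.approx(binom_sd, rel=0.6)


class TestDilutionSeries:
    def test_expected_vaf_algebra(self):
        assert S.expected_dilution_vafs(0.5, [0]) == [0.5]
        assert S.expected_dilution_vafs(0.5, [10])[0] == pytest.approx(0.5 / 11)
        assert S.expected_dilution_vafs(0.5, [40])[0] == pytest.approx(0.5 / 41)

    def test_series_vafs_strictly_decrease(self, reference):
        pos, _, alt = R.mutation_site("F1174L", reference)
        base = ad.SimulatedSample(
            "d", spike_ins=(ad.SpikeIn(pos, alt, 0.5),), depth=10000, seed=1
        )
        series = ad.simulate_dilution_series(base, [0, 10, 40])
        vafs = [s.spike_ins[0].vaf for s in series]
        assert len(series) == 3
        assert vafs[0] == 0.5
        assert vafs[0] > vafs[1] > vafs[2]

    def test_negative_ratio_and_unspiked_base_rejected(self, reference):
        pos, _, alt = R.mutation_site("F1174L", reference)
        base = ad.SimulatedSample(
            "d", spike_ins=(ad.SpikeIn(pos, alt, 0.5),), depth=100, seed=1
        )
        with pytest.raises(InvalidConfigurationError):
            ad.simulate_dilution_series(base, [-1])
        with pytest.raises(InvalidConfigurationError):
            ad.simulate_dilution_series(ad.SimulatedSample("x"), [0])


class TestSimulateCohort:
    def test_mirrors_cohort_spec(self, cohort_table, profile):
        spec = cohort_table.head(45)  # includes mutated, Amp. and dual cases
        table, pileups = ad.simulate_cohort(spec, profile, seed=7)
        assert len(pileups) == len(spec)
        assert table.equals(spec)
        # case 40 carries both clones in its pileup
        pu40 = pileups["40"]
        from alkdeep.cohort import parse_deep_seq
        muts = parse_deep_seq(spec.loc[spec["case_id"] == "40", "deep_seq"].iloc[0])
        assert len(muts.mutations) == 2
        ref = ad.default_reference()
        for name, vaf_pct in muts.mutations:
            pos, _, alt = R.mutation_site(name, ref)
            row = pu40[pu40["pos"] == pos].iloc[0]
            frac = row[alt] / row["depth"]
            assert frac == pytest.approx(vaf_pct / 100, abs=0.03)

    def test_empty_spec_gives_no_pileups(self, cohort_table, profile):
        table, pileups = ad.simulate_cohort(cohort_table.head(0), profile, seed=1)
        assert len(table) == 0 and pileups == {}


class TestEmitReads:
    def test_single_position_depth_equals_read_count(self, reference):
        pu = pd.DataFrame(
            [{"chrom": "chr2", "pos": 29443695, "ref": reference.base(29443695),
              "A": 0, "C": 0, "G": 60, "T": 40, "other": 0, "depth": 100}]
        )
        reads = ad.emit_reads(pu, read_length=1, seed=0)
        assert len(reads) == 100

    def test_round_trip_recovers_counts_exactly(self, profile):
        sample = ad.SimulatedSample("s", depth=150, seed=8)
        pu = ad.simulate_pileup(sample, profile)
        pu = pu[pu["pos"].between(29443572, 29443701)].reset_index(drop=True)
        reads = ad.emit_reads(pu, read_length=36, seed=1)
        rebuilt = ad.build_pileup(reads, min_base_quality=0)
        merged = pu.merge(rebuilt, on="pos", suffixes=("_in", "_out"))
        assert len(merged) == len(pu)
        for col in ["A", "C", "G", "T", "other", "depth"]:
            assert (merged[f"{col}_in"] == merged[f"{col}_out"]).all()

    def test_low_quality_bases_filtered_at_q30(self, profile):
        sample = ad.SimulatedSample("s", depth=500, seed=9)
        pu = ad.simulate_pileup(sample, profile)
        pu = pu[pu["pos"].between(29436850, 29436947)].reset_index(drop=True)
        reads = ad.emit_reads(pu, read_length=50, seed=2,
                              low_quality_fraction=0.10)
        filtered = ad.build_pileup(reads, min_base_quality=30)
        merged = pu.merge(filtered, on="pos", suffixes=("_in", "_out"))
        high_q = (
            merged[["A_out", "C_out", "G_out", "T_out"]].sum(axis=1).sum()
        )
        total = merged["depth_in"].sum()
        assert high_q / total == pytest.approx(0.90, abs=0.02)
        # low-quality bases moved to "other", not dropped from depth
        assert (merged["depth_out"] == merged["depth_in"]).all()


class TestDeterminismProperties:
    @given(st.integers(min_value=0, max_value=2**20))
    def test_identical_seed_identical_pileup(self, seed):
        prof = ad.draw_error_profile(
            regions=[ad.TargetRegion("exon24", "chr2", 29436850, 29436947)],
            seed=3,
        )
        s = ad.SimulatedSample("s", depth=500, seed=seed)
        a = ad.simulate_pileup(s, prof)
        b = ad.simulate_pileup(s, prof)
        assert a.equals(b)
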