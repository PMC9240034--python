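import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import meripkit as mk
from meripkit.peakcall import (
    Peak,
    PeakSet,
    WindowTable,
    bh_adjust,
    call_peaks,
    differential_methylation,
    exclusion_filter,
    make_windows,
    merge_windows,
    window_enrichment_test,
    window_enrichment_tests,
)


def hypergeom_tail(ip, inp, ip_total, input_total):
    """Independent brute-force oracle: exact upper-tail sum over the margin."""
    t = ip + inp
    denom = math.comb(ip_total + input_total, t)
    lo = max(0, t - input_total)
    hi = min(t, ip_total)
    return sum(
        math.comb(ip_total, k) * math.comb(input_total, t - k)
        for k in range(ip, hi + 1)
        if lo <= k
    ) / denom


class TestMakeWindows:
    def test_standard_tiling(self):
        w = make_windows(250, 100, 10)
        assert len(w) == 16  # floor((250-100)/10) + 1
        assert list(w[0]) == [0, 100]
        assert list(w[-1]) == [150, 250]

    def test_exact_fit_single_window(self):
        assert make_windows(100, 100, 10).tolist() == [[0, 100]]

    def test_short_transcript_whole_window(self):
        assert make_windows(60, 100, 10).tolist() == [[0, 60]]

    def test_coverage_up_to_last_window(self):
        # windows advance while start + W fits; the uncovered tail is
        # always shorter than one step
        w = make_windows(537, 100, 10)
        covered = np.zeros(537, dtype=bool)
        for s, e in w:
            covered[s:e] = True
        assert covered[: w[-1, 1]].all()
        assert 537 - w[-1, 1] < 10

    @pytest.mark.parametrize("window,step", [(0, 10), (100, 0), (-1, 5)])
    def test_non_positive_parameters_rejected(self, window, step):
        with pytest.raises(ValueError):
            make_windows(500, window, step)


def _table(rows, columns=("IP_WT_rep1", "input_WT_rep1")):
    df = pd.DataFrame(rows, columns=["transcript_id", "window_start",
                                     "window_end", *columns])
    return WindowTable(df)


class TestExclusionFilter:
    def test_hand_computed_thresholds_and_and_rule(self):
        # top IP 200 -> threshold 10; top input 100 -> threshold 5
        wt = _table([
            ("t1", 0, 100, 200, 100),
            ("t1", 10, 110, 4, 3),    # below both -> excluded
            ("t1", 20, 120, 4, 50),   # fails IP only -> retained
            ("t1", 30, 130, 50, 3),   # fails input only -> retained
            ("t1", 40, 140, 10, 4),   # exactly at IP threshold -> retained
        ])
        kept, log = exclusion_filter(wt, fraction=1 / 20)
        assert kept.df["window_start"].tolist() == [0, 20, 30, 40]
        row = log.set_index("transcript_id").loc["t1"]
        assert row.threshold_ip == 10 and row.threshold_input == 5

    def test_zero_fraction_retains_everything(self):
        wt = _table([("t1", 0, 100, 5, 5), ("t1", 10, 110, 0, 0)])
        kept, _ = exclusion_filter(wt, fraction=0)
        assert len(kept) == 2

    def test_all_zero_transcript_fully_excluded(self, caplog):
        wt = _table([("t1", 0, 100, 0, 0), ("t1", 10, 110, 0, 0)])
        with caplog.at_level("WARNING"):
            kept, _ = exclusion_filter(wt)
        assert len(kept) == 0
        assert "all-zero" in caplog.text

    def test_either_mode_is_stricter(self):
        wt = _table([
            ("t1", 0, 100, 200, 100),
            ("t1", 10, 110, 4, 50),
        ])
        kept_both, _ = exclusion_filter(wt, mode="both")
        kept_either, _ = exclusion_filter(wt, mode="either")
        assert len(kept_both) == 2 and len(kept_either) == 1

    def test_replicates_summed_within_assay(self):
        wt = _table(
            [
                ("t1", 0, 100, 100, 100, 50, 50),
                ("t1", 10, 110, 4, 3, 0, 0),  # pooled IP 7, input 3
            ],
            columns=("IP_WT_rep1", "IP_WT_rep2", "input_WT_rep1",
                     "input_WT_rep2"),
        )
        kept, log = exclusion_filter(wt, fraction=1 / 20)
        # pooled tops: IP 200, input 100 -> thresholds 10 and 5 -> excluded
        assert kept.df["window_start"].tolist() == [0]


class TestEnrichmentTest:
    def test_equal_rates_zero_enrichment(self):
        _, lfc = window_enrichment_test(10, 10, 1000, 1000)
        assert lfc == 0.0

    def test_empty_table_p_one(self):
        p, _ = window_enrichment_test(0, 0, 1000, 1000)
        assert p == 1.0

    def test_matches_bruteforce_enumeration(self):
        p, _ = window_enrichment_test(12, 3, 40, 40)
        assert p == pytest.approx(hypergeom_tail(12, 3, 40, 40), rel=1e-12)

    def test_matches_scipy_fisher_greater(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            ip_t, in_t = rng.integers(20, 200, size=2)
            a = int(rng.integers(0, ip_t + 1))
            b = int(rng.integers(0, in_t + 1))
            p, _ = window_enrichment_test(a, b, int(ip_t), int(in_t))
            expected = stats.fisher_exact(
                [[a, ip_t - a], [b, in_t - b]], alternative="greater"
            )[1]
            assert p == pytest.approx(expected, rel=1e-9)

    def test_count_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            window_enrichment_test(11, 0, 10, 10)

    def test_vectorized_matches_scalar(self):
        ips, inps = np.array([0, 3, 12, 40]), np.array([0, 9, 3, 1])
        p, lfc = window_enrichment_tests(ips, inps, 40, 40)
        for i in range(len(ips)):
            ps, ls = window_enrichment_test(
                int(ips[i]), int(inps[i]), 40, 40
            )
            assert p[i] == pytest.approx(ps) and lfc[i] == pytest.approx(ls)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_all_equal_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_hand_computed_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.04, 0.9])
        assert q == pytest.approx([0.04, 0.04, 0.04 * 4 / 3, 0.9])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30)
    )
    def test_q_dominates_p_and_stays_in_unit_interval(self, pvals):
        q = bh_adjust(pvals)
        assert (q >= np.asarray(pvals) - 1e-12).all()
        assert (q <= 1.0).all()


def _sig_windows(rows):
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "window_start", "window_end", "p_value",
                 "q_value", "log2_enrichment"],
    )


class TestMergeWindows:
    def test_overlapping_windows_merge(self):
        peaks = merge_windows(_sig_windows([
            ("t1", 0, 100, 1e-4, 1e-3, 2.0),
            ("t1", 10, 110, 1e-5, 1e-4, 2.5),
        ]))
        assert len(peaks) == 1
        assert (peaks[0].start, peaks[0].end) == (0, 110)
        assert peaks[0].member_starts == (0, 10)

    def test_gap_gives_two_peaks(self):
        peaks = merge_windows(_sig_windows([
            ("t1", 0, 100, 1e-4, 1e-3, 2.0),
            ("t1", 200, 300, 1e-4, 1e-3, 2.0),
        ]))
        assert len(peaks) == 2

    def test_summit_is_min_p_window_midpoint(self):
        peaks = merge_windows(_sig_windows([
            ("t1", 0, 100, 1e-4, 1e-3, 2.0),
            ("t1", 10, 110, 1e-8, 1e-6, 3.0),
            ("t1", 20, 120, 1e-4, 1e-3, 2.0),
        ]))
        assert len(peaks) == 1
        assert peaks[0].summit == 60  # midpoint of the middle window
        assert peaks[0].p_value == pytest.approx(1e-8)
        assert peaks[0].n_windows == 3

    def test_non_significant_windows_ignored(self):
        peaks = merge_windows(_sig_windows([
            ("t1", 0, 100, 0.5, 0.8, 0.1),
        ]))
        assert peaks == []


class TestCallPeaks:
    def test_empty_table_empty_peakset(self):
        df = pd.DataFrame(
            columns=["transcript_id", "window_start", "window_end",
                     "IP_WT_rep1", "input_WT_rep1"]
        )
        assert len(call_peaks(WindowTable(df))) == 0

    def test_recovers_planted_site(self, transcriptome, merip_table,
                                   called_peaks):
        by_tx = transcriptome.truth.by_transcript()
        for g in transcriptome.truth.genes:
            site = g.sites[0]
            hits = [
                p for p in called_peaks
                if p.transcript_id == g.transcript_id
                and p.start <= site < p.end
            ]
            assert hits, f"site of {g.gene_id} not recovered"

    def test_invariant_to_transcript_and_column_order(self, merip_table):
        base = call_peaks(merip_table).to_dataframe()
        shuffled = merip_table.df.sample(frac=1.0, random_state=0)
        cols = list(shuffled.columns)
        reordered = cols[:3] + cols[3:][::-1]
        wt2 = WindowTable(shuffled[reordered])
        again = call_peaks(wt2).to_dataframe()
        pd.testing.assert_frame_equal(
            base.sort_values(["transcript_id", "start"]).reset_index(drop=True),
            again.sort_values(["transcript_id", "start"]).reset_index(drop=True),
        )

    def test_null_simulation_calls_almost_no_peaks(self):
        # with no planted enrichment, FDR control keeps the fraction of
        # transcripts with any peak near zero
        frac = []
        for seed in range(60):
            cfg = mk.SimConfig(seed=seed, n_genes=20, site_enrichment=1.0,
                               ko_effect=1.0)
            tr = mk.simulate_transcriptome(cfg)
            peaks = call_peaks(mk.simulate_merip_counts(tr, cfg))
            with_peak = {p.transcript_id for p in peaks}
            frac.append(len(with_peak) / cfg.n_genes)
        assert np.mean(frac) <= 0.02

    def test_provenance_reports_counts(self, called_peaks):
        prov = called_peaks.provenance
        assert prov["n_tested"] <= prov["n_windows"]
        assert prov["n_significant"] >= len(called_peaks)

    def test_peakset_tsv_round_trip(self, called_peaks, tmp_path):
        path = tmp_path / "peaks.tsv"
        called_peaks.write_tsv(path)
        again = PeakSet.read_tsv(path)
        assert [p for p in again] == [p for p in called_peaks]


class TestDifferentialMethylation:
    def test_identical_genotypes_zero_ratio(self):
        df = pd.DataFrame({
            "transcript_id": ["t1"] * 3,
            "window_start": [0, 10, 20],
            "window_end": [100, 110, 120],
            "IP_WT_rep1": [50, 60, 50],
            "input_WT_rep1": [20, 20, 20],
            "IP_KO_rep1": [50, 60, 50],
            "input_KO_rep1": [20, 20, 20],
        })
        peaks = PeakSet([Peak("t1", 0, 120, 55, 1e-6, 1e-5, 2.0, 3,
                              (0, 10, 20))])
        res = differential_methylation(peaks, WindowTable(df))
        assert res["log2_ratio"].iloc[0] == pytest.approx(0.0)
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_label_swap_negates_exactly(self, called_peaks, merip_table):
        fwd = differential_methylation(called_peaks, merip_table, "WT", "KO")
        rev = differential_methylation(called_peaks, merip_table, "KO", "WT")
        np.testing.assert_allclose(
            fwd["log2_ratio"].to_numpy(), -rev["log2_ratio"].to_numpy(),
            atol=1e-12,
        )
        np.testing.assert_allclose(
            fwd["p_value"].to_numpy(), rev["p_value"].to_numpy(), rtol=1e-9
        )

    def test_missing_genotype_rejected(self, called_peaks):
        df = pd.DataFrame({
            "transcript_id": ["t1"],
            "window_start": [0],
            "window_end": [100],
            "IP_WT_rep1": [5],
            "input_WT_rep1": [5],
        })
        with pytest.raises(ValueError, match="KO"):
            differential_methylation(called_peaks, WindowTable(df))

    def test_ko_effect_detected_on_targets(self, transcriptome, merip_table,
                                           called_peaks):
        res = differential_methylation(called_peaks, merip_table)
        sites = {
            g.transcript_id: g.sites[0] for g in transcriptome.truth.targets
        }
        on_site = res.apply(
            lambda r: r.transcript_id in sites
            and r.start <= sites[r.transcript_id] < r.end,
            axis=1,
        )
        assert res.loc[on_site, "log2_ratio"].mean() == pytest.approx(
            1.0, abs=0.35
        )
        assert (res.loc[on_site, "q_value"] < 0.05).all()
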