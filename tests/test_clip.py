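import math

import numpy as np
import pandas as pd
import pytest

from subloc.clip import (ClipPeakTable, binding_partitions, median_targets,
                         shortlist_rbps, stringent_targets)


def table(col, rbp="RBP1", genes=None):
    genes = genes or [f"g{i}" for i in range(len(col))]
    return ClipPeakTable(pd.DataFrame({rbp: col},
                                      index=pd.Index(genes, name="gene_id")))


def brute_median_targets(counts: pd.Series) -> set:
    med = sorted(counts)[len(counts) // 2] if len(counts) % 2 else \
        0.5 * (sorted(counts)[len(counts) // 2 - 1]
               + sorted(counts)[len(counts) // 2])
    return {g for g, c in counts.items() if c > med}


def brute_stringent_targets(counts: pd.Series) -> set:
    withpeak = [(c, g) for g, c in counts.items() if c >= 1]
    if len(withpeak) < 3:
        return {g for _, g in withpeak}
    ranked = sorted(withpeak, key=lambda t: (-t[0], t[1]))
    return {g for _, g in ranked[: math.ceil(len(ranked) / 3)]}


class TestMedianTargets:
    def test_zero_median_counts_any_peak(self):
        out = median_targets(table([0, 0, 0, 1, 2]))
        assert out["RBP1"] == {"g3", "g4"}

    def test_strictly_greater_than_median(self):
        out = median_targets(table([3, 3, 3, 3]))
        assert out["RBP1"] == set()

    def test_hand_counted_example(self):
        out = median_targets(table([0, 1, 2, 3, 4]))
        assert out["RBP1"] == {"g3", "g4"}

    def test_all_zero_column_warns(self):
        with pytest.warns(UserWarning):
            out = median_targets(table([0, 0, 0]))
        assert out["RBP1"] == set()

    def test_matches_bruteforce_on_random_tables(self):
        rng = np.random.default_rng(9)
        for _ in range(300):
            n = rng.integers(4, 40)
            counts = pd.Series(rng.poisson(1.5, n),
                               index=[f"g{i}" for i in range(n)])
            got = median_targets(ClipPeakTable(counts.to_frame("R")))["R"]
            if (counts == 0).all():
                continue
            assert got == brute_median_targets(counts)


class TestStringentTargets:
    def test_top_third_of_nine(self):
        out = stringent_targets(table(list(range(1, 10))))
        assert out["RBP1"] == {"g6", "g7", "g8"}  # counts 7, 8, 9

    def test_tie_break_is_deterministic_by_gene_id(self):
        out = stringent_targets(table([5, 5, 5, 5, 5, 5]))
        assert out["RBP1"] == {"g0", "g1"}  # ceil(6/3) = 2, id order

    def test_single_peak_gene_returned_with_warning(self):
        with pytest.warns(UserWarning):
            out = stringent_targets(table([0, 0, 7]))
        assert out["RBP1"] == {"g2"}

    def test_matches_bruteforce_on_random_tables(self):
        rng = np.random.default_rng(10)
        for _ in range(300):
            n = int(rng.integers(3, 40))
            counts = pd.Series(rng.poisson(2.0, n),
                               index=[f"g{i}" for i in range(n)])
            if (counts >= 1).sum() == 0:
                continue
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                got = stringent_targets(ClipPeakTable(counts.to_frame("R")))["R"]
            assert got == brute_stringent_targets(counts)


class TestTiaMerge:
    def test_tia1_and_tial1_sum_into_one_column(self):
        counts = pd.DataFrame({"TIA1": [1, 2], "TIAL1": [3, 0],
                               "HuR": [0, 1]}, index=["g0", "g1"])
        peaks = ClipPeakTable.from_counts(counts)
        assert list(peaks.counts["TIA1/L1"]) == [4, 2]
        assert "TIA1" not in peaks.counts.columns

    def test_premerged_column_accepted(self):
        counts = pd.DataFrame({"TIA1/L1": [2]}, index=["g0"])
        peaks = ClipPeakTable.from_counts(counts)
        assert list(peaks.counts["TIA1/L1"]) == [2]


class TestShortlist:
    def _calls(self):
        # exact study composition over 1000 genes
        labels = (["TG_plus"] * 178 + ["ER_plus"] * 131 + ["CY_plus"] * 211
                  + ["unbiased"] * 480)
        return pd.DataFrame({"label": labels},
                            index=[f"g{i}" for i in range(1000)])

    def test_enriched_rbp_is_shortlisted(self):
        calls = self._calls()
        # 100 targets of which 40 are TG+: expected 17.8, ratio 2.247
        targets = {"R": set(f"g{i}" for i in range(40))
                   | set(f"g{i}" for i in range(520, 580))}
        out = shortlist_rbps(targets, calls)
        assert out.at["R", "ratio_TG_plus"] == pytest.approx(40 / 17.8,
                                                             rel=1e-12)
        assert bool(out.at["R", "shortlisted"])

    def test_proportional_targets_not_shortlisted(self):
        calls = self._calls()
        # composition exactly proportional to the class fractions
        targets = {"R": set(f"g{i}" for i in range(89))          # 89 TG
                   | set(f"g{i}" for i in range(178, 243))       # 65.5 -> 65 ER
                   | set(f"g{i}" for i in range(309, 415))       # 105.5 CY
                   | set(f"g{i}" for i in range(520, 760))}      # 240 unbiased
        out = shortlist_rbps(targets, calls)
        ratios = out.filter(like="ratio_").iloc[0]
        assert (ratios < 1.1).all()
        assert not bool(out.at["R", "shortlisted"])

    def test_zero_target_rbp_flagged(self):
        with pytest.warns(UserWarning):
            out = shortlist_rbps({"R": set()}, self._calls())
        assert not bool(out.at["R", "shortlisted"])


class TestBindingPartitions:
    RBPS = ("TIS11B", "HuR", "PUM2", "HNRNPC", "TIA1/L1", "LARP4B", "METAP2")

    def _peaks(self, rows):
        df = pd.DataFrame(rows, columns=list(self.RBPS))
        df.index = pd.Index([f"g{i}" for i in range(len(rows))],
                            name="gene_id")
        return ClipPeakTable(df)

    def _stringent_from_counts(self, peaks):
        return {r: set(peaks.counts.index[peaks.counts[r] > 0])
                for r in self.RBPS}

    def test_ratio_rule_assigns_predominance(self):
        #        TIS  HuR PUM2 HNR  TIA LARP META
        peaks = self._peaks([
            [8, 0, 0, 0, 3, 0, 0],   # 8/3 >= 2 -> TIS11B predominant
            [3, 0, 0, 0, 2, 0, 0],   # 1.5 < 2 -> TIA1/L1 predominant
            [0, 0, 0, 0, 0, 4, 0],   # only LARP4B
            [5, 0, 0, 0, 0, 0, 0],   # exclusively TIS11B
            [0, 0, 0, 0, 6, 0, 0],   # exclusively TIA1/L1
            [0, 2, 0, 0, 0, 4, 0],   # LARP4B but co-bound by HuR -> excluded
        ])
        parts = binding_partitions(self._stringent_from_counts(peaks), peaks)
        assert parts["tis11b_predominant"] == {"g0", "g3"}
        assert parts["tia1l1_predominant"] == {"g1", "g4"}
        assert parts["larp4b_metap2_only"] == {"g2"}

    def test_zero_tia_count_with_cobinding_is_tis_predominant(self):
        peaks = self._peaks([[4, 0, 0, 0, 0, 0, 0]])
        stringent = self._stringent_from_counts(peaks)
        stringent["TIA1/L1"] = {"g0"}  # claimed co-binding, zero peaks
        parts = binding_partitions(stringent, peaks)
        assert parts["tis11b_predominant"] == {"g0"}

    def test_partitions_disjoint_on_random_tables(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            rows = rng.poisson(0.8, size=(60, 7))
            peaks = self._peaks(rows.tolist())
            parts = binding_partitions(self._stringent_from_counts(peaks),
                                       peaks)
            sets = list(parts.values())
            for i in range(3):
                for j in range(i + 1, 3):
                    assert not (sets[i] & sets[j])

    def test_missing_rbp_raises(self):
        peaks = self._peaks([[1, 0, 0, 0, 0, 0, 0]])
        with pytest.raises(ValueError, match="METAP2"):
            binding_partitions({"TIS11B": {"g0"}}, peaks)
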