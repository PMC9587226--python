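"""Normalization, fold changes, testing, FDR control, specificity calls."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from glycopipe.differential import test_sites as site_contrast
from glycopipe.differential import (
    assign_isoform_specificity,
    benjamini_hochberg,
    build_site_table,
    changed_proteins,
    normalize_total,
    protein_abundance_filter,
    summarize_panel,
)
from glycopipe.models import RegulationCall, ValidationError
from glycopipe.simulate import SimConfig, simulate_proteome, simulate_sites_and_psms


def table(rows: dict, columns: list[str]) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    df.index = pd.MultiIndex.from_tuples(df.index,
                                         names=["accession", "position"])
    return df


WT_KO = ["WT:1", "WT:2", "WT:3", "KO1:1", "KO1:2", "KO1:3"]


class TestNormalizeTotal:
    def test_totals_equal_grand_mean(self):
        df = pd.DataFrame({"WT:1": [60.0, 40.0], "KO1:1": [150.0, 50.0]})
        out = normalize_total(df)
        # totals [100, 200] -> factors [1.5, 0.75] -> post totals both 150
        assert out["WT:1"].tolist() == [90.0, 60.0]
        assert out["KO1:1"].tolist() == [112.5, 37.5]
        assert out.sum().tolist() == pytest.approx([150.0, 150.0])

    def test_equal_totals_is_identity(self):
        df = pd.DataFrame({"WT:1": [60.0, 40.0], "KO1:1": [30.0, 70.0]})
        assert normalize_total(df).equals(df)

    def test_property_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            df = pd.DataFrame(
                rng.lognormal(10, 1, size=(int(rng.integers(2, 30)), 6)),
                columns=WT_KO,
            )
            totals = normalize_total(df).sum()
            assert np.allclose(totals, totals.iloc[0], rtol=1e-9)

    def test_zero_total_channel_is_an_error(self):
        df = pd.DataFrame({"WT:1": [1.0], "KO1:1": [0.0]})
        with pytest.raises(ValidationError, match="zero total"):
            normalize_total(df)


class TestBenjaminiHochberg:
    def test_hand_computed_example(self):
        # max over the tail of p*m/rank: all four adjust to 0.04
        adjusted = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert adjusted == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_matches_direct_step_up_on_random_vectors(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            m = len(p)
            order = np.argsort(p)
            stepped = np.minimum.accumulate(
                (p[order] * m / np.arange(1, m + 1))[::-1]
            )[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(stepped, 1.0)
            assert benjamini_hochberg(p) == pytest.approx(expected)

    def test_monotone_under_reordering(self):
        p = [0.3, 0.01, 0.2, 0.05, 0.9]
        base = dict(zip(p, benjamini_hochberg(p)))
        shuffled = [0.9, 0.05, 0.3, 0.01, 0.2]
        again = dict(zip(shuffled, benjamini_hochberg(shuffled)))
        assert base == again

    def test_adjusted_bounded_by_raw_and_one(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=100)
        adjusted = benjamini_hochberg(p)
        assert np.all(adjusted >= p) and np.all(adjusted <= 1.0)


class TestTestSites:
    def test_fold_change_is_ratio_of_medians(self):
        df = table({("P1", 10): [8.0, 8.0, 8.0, 2.0, 4.0, 6.0]}, WT_KO)
        call = site_contrast(df, "WT", "KO1")[0]
        assert call.fold_change == pytest.approx(0.5)
        assert call.log2_fc == pytest.approx(-1.0)

    def test_identical_groups_unchanged(self):
        df = table({("P1", 10): [5.0] * 6}, WT_KO)
        call = site_contrast(df, "WT", "KO1")[0]
        assert call.fold_change == pytest.approx(1.0)
        assert call.call == "unchanged"
        assert call.p_raw == pytest.approx(1.0)

    def test_missing_values_excluded_pairwise(self):
        df = table(
            {("P1", 10): [8.0, 8.0, np.nan, 2.0, 2.0, 2.0],
             ("P1", 20): [8.0, np.nan, np.nan, 2.0, 2.0, 2.0]},
            WT_KO,
        )
        calls = {c.position: c for c in site_contrast(df, "WT", "KO1")}
        assert calls[10].call != "untested"
        assert calls[20].call == "untested"
        assert np.isnan(calls[20].fold_change)

    def test_fold_change_equivariance_under_condition_scaling(self):
        rng = np.random.default_rng(6)
        rows = {("P", i): rng.lognormal(10, 0.3, 6).tolist() for i in range(15)}
        df = table(rows, WT_KO)
        base = {c.position: c.fold_change for c in site_contrast(df, "WT", "KO1")}
        c = 3.7
        scaled = df.copy()
        scaled[["KO1:1", "KO1:2", "KO1:3"]] *= c
        after = {call.position: call.fold_change
                 for call in site_contrast(scaled, "WT", "KO1")}
        for pos in base:
            assert after[pos] == pytest.approx(base[pos] * c)

    def test_raw_p_mode_uses_unadjusted_threshold(self):
        rng = np.random.default_rng(8)
        rows = {("P", i): rng.lognormal(10, 0.3, 6).tolist() for i in range(50)}
        rows[("Q", 1)] = [64.0 * f for f in (1.0, 1.05, 0.97)] + \
            [20.0 * f for f in (1.0, 1.04, 0.96)]
        df = table(rows, WT_KO)
        adj = {c.site_key: c for c in site_contrast(df, "WT", "KO1")}
        raw = {c.site_key: c for c in site_contrast(df, "WT", "KO1",
                                                 use_raw_p=True)}
        key = ("Q", 1)
        assert raw[key].p_raw < 0.05
        # the single strong site survives raw-p calling even when BH across
        # 50 null sites pushes its adjusted p above alpha
        if adj[key].p_adj >= 0.05:
            assert adj[key].call == "unchanged" and raw[key].call == "down"

    def test_requires_two_replicates_per_condition(self):
        df = pd.DataFrame({"WT:1": [1.0], "KO1:1": [1.0], "KO1:2": [1.0]})
        df.index = pd.MultiIndex.from_tuples([("P1", 1)],
                                             names=["accession", "position"])
        with pytest.raises(ValidationError, match="replicates"):
            site_contrast(df, "WT", "KO1")


class TestProteinAbundanceFilter:
    def _protein_table(self):
        rng = np.random.default_rng(12)
        rows = {f"N{i}": rng.lognormal(12, 0.1, 6).tolist() for i in range(20)}
        # strong, clean 0.3x drop -> removed
        rows["CHANGED"] = [100.0, 101.0, 99.0, 30.0, 30.5, 29.5]
        # same 0.3x ratio of medians but hugely noisy -> not significant
        rows["NOISY"] = [100.0, 5000.0, 20.0, 30.0, 1500.0, 4.0]
        return pd.DataFrame.from_dict(rows, orient="index", columns=WT_KO)

    def test_changed_protein_sites_removed(self):
        proteins = self._protein_table()
        sites = table(
            {("CHANGED", 5): [1.0] * 6, ("NOISY", 9): [1.0] * 6,
             ("N0", 3): [1.0] * 6, ("ORPHAN", 2): [1.0] * 6},
            WT_KO,
        )
        filtered, flags = protein_abundance_filter(sites, proteins, "WT",
                                                   ["KO1"])
        kept = set(filtered.index.get_level_values("accession"))
        assert "CHANGED" not in kept
        assert {"NOISY", "N0", "ORPHAN"} <= kept
        assert flags == {"ORPHAN": "protein-unquantified"}

    def test_both_fc_and_significance_required(self):
        proteins = self._protein_table()
        changed = changed_proteins(proteins, "WT", "KO1")
        assert "CHANGED" in changed
        assert "NOISY" not in changed  # fc outside bounds but p not significant
        assert "N0" not in changed

    def test_simulated_abundance_changes_removed_exactly(self):
        config = SimConfig(seed=21, n_proteins=40, n_sites=80, cv_noise=0.0,
                           abundance_changed_fraction=0.2,
                           frac_below_cutoff=0.0)
        proteome, features = simulate_proteome(config)
        truth, psms = simulate_sites_and_psms(config, proteome, features)
        site_table, _ = build_site_table(psms, proteome)
        kos = sorted({c.split(":")[0] for c in site_table.columns} - {"WT"})
        filtered, _ = protein_abundance_filter(site_table, truth.protein_table,
                                               "WT", kos)
        assert truth.abundance_changed  # the scenario is non-trivial
        before = set(site_table.index.get_level_values("accession"))
        after = set(filtered.index.get_level_values("accession"))
        assert before - after == set(truth.abundance_changed) & before


class TestIsoformSpecificity:
    def _call(self, acc, pos, ko, verdict):
        return RegulationCall(acc, pos, ko, 0.3, -1.7, 0.001, 0.004, verdict)

    def test_down_in_exactly_one_knockout_is_specific(self):
        calls = [self._call("P1", 10, "T11KO", "down"),
                 self._call("P1", 10, "T2KO", "unchanged"),
                 self._call("P1", 10, "T3KO", "unchanged")]
        annotated = assign_isoform_specificity(calls)
        assert annotated[0].isoform_specific and not annotated[0].shared

    def test_down_in_two_knockouts_is_shared(self):
        calls = [self._call("P1", 10, "T2KO", "down"),
                 self._call("P1", 10, "T18KO", "down"),
                 self._call("P1", 10, "T3KO", "unchanged")]
        annotated = assign_isoform_specificity(calls)
        down = [c for c in annotated if c.call == "down"]
        assert all(c.shared and not c.isoform_specific for c in down)

    def test_summary_counts(self):
        calls = assign_isoform_specificity([
            self._call("P1", 10, "T2KO", "down"),
            self._call("P1", 10, "T3KO", "unchanged"),
            self._call("P2", 5, "T2KO", "up"),
            self._call("P2", 5, "T3KO", "unchanged"),
        ])
        summary = summarize_panel(calls)
        assert summary["n_sites_down"] == 1
        assert summary["n_sites_up"] == 1
        assert summary["n_sites_isoform_specific"] == 1
        assert summary["per_knockout"]["T2KO"]["down"] == 1
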