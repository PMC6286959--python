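"""Integration layer: counts, Spearman coupling, persistence,
concordance, pathway ranking and miRNA overlap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from persistomics.expression import diff_all_contrasts
from persistomics.integration import (build_records, concordance,
                                      concordance_summary, correlate_epi_ge,
                                      impact_counts, mirna_overlap,
                                      persistence, persistent_gene_set,
                                      rank_pathway, significance_stars,
                                      _exact_spearman_p)
from persistomics.synthetic import (simulate_expression, simulate_tiling,
                                    uniform_magnitudes)
from persistomics.tiling import call_regions


def _calls(rows, cols=("gene", "treatment", "timepoint", "lfc", "p", "fdr", "direction")):
    return pd.DataFrame(rows, columns=list(cols))


class TestImpactCounts:
    def test_empty_tables_give_empty_counts(self):
        out = impact_counts(_calls([]), None, None)
        assert len(out) == 0

    def test_direction_partition(self):
        de = _calls([
            ("g1", "OTA", "T1", 1.0, 1e-4, 0.01, 1),
            ("g2", "OTA", "T1", -2.0, 1e-5, 0.01, -1),
            ("g3", "OTA", "T1", 0.5, 1e-4, 0.02, 1),
            ("g4", "OTA", "T1", 0.5, 0.5, 0.9, 1),  # not significant
        ])
        out = impact_counts(de_calls=de)
        cell = out[(out["endpoint"] == "mRNA") & (out["timepoint"] == "T1")]
        assert cell["n"].sum() == 3
        assert set(zip(cell["direction"], cell["n"])) == {(1, 2), (-1, 1)}

    def test_planted_hyper_regions_counted(self, design2):
        track, truth = simulate_tiling(design2, n_genes=120, region_fraction=0.4,
                                       effect_size=1.2, noise_sd=0.15, seed=30)
        calls = call_regions(track, design2, "OTA", "T5")
        out = impact_counts(region_calls=calls)
        planted_hyper = sum(1 for g, l in truth.epi_regions.items()
                            if l["HA"]["T5"]["direction"] == 1)
        got = out[(out["endpoint"] == "HA") & (out["direction"] == 1)]["n"].sum()
        assert got == pytest.approx(planted_hyper, abs=0.1 * planted_hyper)


class TestCorrelateEpiGe:
    def _records(self, x, y, trt="OTA", tp="T1"):
        n = len(x)
        return pd.DataFrame({
            "gene": [f"g{i}" for i in range(n)], "treatment": trt, "timepoint": tp,
            "ge_lfc": x, "ge_p": 1e-6, "ge_fdr": 1e-5, "ge_direction": np.sign(x),
            "ha_direction": np.sign(y), "ha_score": y,
            "dm_direction": np.nan, "dm_score": np.nan,
        })

    def test_perfectly_monotone_rho_one(self):
        rec = self._records([0.1, 0.5, 1.0, 2.0], [1.0, 2.0, 3.0, 4.0])
        res = correlate_epi_ge(rec, "HA", "OTA", "T1")
        assert res["rho"] == pytest.approx(1.0)

    def test_three_point_example_minus_half(self):
        rec = self._records([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
        res = correlate_epi_ge(rec, "HA", "OTA", "T1", min_n=3)
        assert res["rho"] == pytest.approx(-0.5)

    def test_too_few_genes_returns_none(self):
        rec = self._records([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
        assert correlate_epi_ge(rec, "HA", "OTA", "T1") is None

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        a = correlate_epi_ge(self._records(x, y), "HA", "OTA", "T1")
        b = correlate_epi_ge(self._records(np.exp(x), y**3 + 5 * y), "HA", "OTA", "T1")
        assert a["rho"] == pytest.approx(b["rho"], abs=1e-12)

    def test_exact_permutation_p_matches_enumeration_null(self):
        # under exchangeability the exact p of rho=1 at n=4 is 2/4! (two
        # permutations reach |rho| = 1)
        p = _exact_spearman_p(np.arange(4.0), np.arange(4.0), 1.0)
        assert p == pytest.approx(2 / 24)

    def test_downstream_recovery_of_coupling(self, design2):
        """End-to-end: planted coupling 0.75 recovered within +-0.1 from
        measured LFCs and region scores at 2000 genes."""
        _, ge_truth = simulate_expression(design2, 2000, 1.0, uniform_magnitudes(),
                                          seed=61)
        matrix, _ = simulate_expression(design2, 2000, 1.0, uniform_magnitudes(),
                                        seed=61)
        track, _ = simulate_tiling(design2, n_genes=2000, region_fraction=1.0,
                                   coupling_rho=0.75, ge_truth=ge_truth,
                                   effect_size=1.0, noise_sd=0.2, seed=62)
        ge_calls = diff_all_contrasts(matrix, design2)
        ha_calls = call_regions(track, design2, "OTA", "T1")
        records = build_records(ge_calls, ha_calls)
        res = correlate_epi_ge(records, "HA", "OTA", "T1")
        assert res["n"] > 500
        assert res["rho"] == pytest.approx(0.75, abs=0.1)

    def test_stars_convention(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.2) == ""


class TestPersistence:
    def _set(self, pairs, tp):
        return _calls([(g, "OTA", tp, 1.0 * d, 1e-4, 1e-3, d) for g, d in pairs])

    def test_worked_example(self):
        r3 = self._set([("A", 1), ("B", 1), ("C", -1)], "R3")
        t5 = self._set([("A", 1), ("B", -1)], "T5")
        out = persistence(t5, r3).set_index("direction")
        assert out.loc["hyper", "n_R3"] == 2
        assert out.loc["hyper", "n_persistent"] == 1
        assert out.loc["hyper", "pct_persistent"] == pytest.approx(50.0)
        assert out.loc["hypo", "pct_persistent"] == pytest.approx(0.0)

    def test_identical_sets_fully_persistent(self):
        t5 = self._set([("A", 1), ("B", -1)], "T5")
        r3 = self._set([("A", 1), ("B", -1)], "R3")
        out = persistence(t5, r3)
        assert (out["pct_persistent"] == 100.0).all()

    def test_disjoint_sets_zero(self):
        t5 = self._set([("A", 1)], "T5")
        r3 = self._set([("B", 1)], "R3")
        out = persistence(t5, r3).set_index("direction")
        assert out.loc["hyper", "pct_persistent"] == 0.0

    def test_anti_monotone_under_t5_shrinkage(self):
        t5 = self._set([("A", 1), ("B", 1), ("C", 1)], "T5")
        r3 = self._set([("A", 1), ("B", 1), ("D", 1)], "R3")
        full = persistence(t5, r3).set_index("direction").loc["hyper", "n_persistent"]
        shrunk = persistence(t5.iloc[:1], r3).set_index("direction").loc["hyper", "n_persistent"]
        assert shrunk <= full

    def test_persistent_set_subset_of_intersection(self):
        t5 = self._set([("A", 1), ("B", -1), ("C", 1)], "T5")
        r3 = self._set([("A", 1), ("B", 1), ("C", 1)], "R3")
        pset = persistent_gene_set(t5, r3)
        assert set(pset["gene"]) == {"A", "C"}  # B flips direction


class TestConcordance:
    def _persistent(self, pairs):
        return pd.DataFrame({"gene": [g for g, _ in pairs],
                             "direction": [d for _, d in pairs]})

    def _ge(self, rows):
        return _calls([(g, "OTA", "R3", lfc, p, p * 2, int(np.sign(lfc)))
                       for g, lfc, p in rows])

    def test_up_with_hyper_is_consistent(self):
        out = concordance(self._persistent([("A", 1)]), self._ge([("A", 1.0, 1e-4)]))
        assert bool(out["consistent"].iloc[0])

    def test_down_with_hyper_is_inconsistent(self):
        out = concordance(self._persistent([("A", 1)]), self._ge([("A", -1.0, 1e-4)]))
        assert not bool(out["consistent"].iloc[0])

    def test_small_lfc_excluded(self):
        out = concordance(self._persistent([("A", 1)]), self._ge([("A", 0.5, 1e-4)]))
        assert len(out) == 0

    def test_boundary_lfc_included(self):
        out = concordance(self._persistent([("A", 1)]), self._ge([("A", 0.58, 1e-4)]))
        assert len(out) == 1

    def test_partition(self):
        pers = self._persistent([("A", 1), ("B", 1), ("C", -1), ("D", -1)])
        ge = self._ge([("A", 1.0, 1e-4), ("B", -1.0, 1e-4),
                       ("C", -2.0, 1e-4), ("D", 0.7, 1e-4)])
        out = concordance(pers, ge)
        s = concordance_summary(out)
        assert s["consistent"] + s["inconsistent"] == s["total"] == 4
        assert s["consistent"] == 2


class TestRankPathway:
    def _calls(self):
        rows = []
        for gene, pc_p, pc_lfc, test_lfcs in (
            ("NQO1", 1e-5, 2.0, (2.0, 1.0, 0.0)),
            ("HMOX1", 1e-4, 1.5, (3.0, 2.0, 1.0)),
            ("GCLM", 0.5, 0.1, (1.0, 1.0, 1.0)),  # never significant in control
        ):
            for tp, lfc in zip(("T1", "T3", "T5"), test_lfcs):
                rows.append((gene, "KBrO3", tp, pc_lfc, pc_p, pc_p * 2, 1))
                rows.append((gene, "OTA", tp, lfc, 1e-3, 2e-3, 1))
        return _calls(rows)

    def test_unmodulated_gene_removed(self):
        out = rank_pathway(self._calls(), ["NQO1", "HMOX1", "GCLM"], "KBrO3", "OTA")
        retained = out[out["in_data"] & ~out["gated_out"]] if "gated_out" in out else out
        assert "GCLM" not in set(retained["gene"])

    def test_average_and_descending_order(self):
        out = rank_pathway(self._calls(), ["NQO1", "HMOX1"], "KBrO3", "OTA")
        assert out["avg_lfc_test"].iloc[0] == pytest.approx(2.0)  # HMOX1 (3+2+1)/3
        assert list(out["gene"]) == ["HMOX1", "NQO1"]
        assert out["avg_lfc_test"].iloc[1] == pytest.approx(1.0)  # NQO1 (2+1+0)/3

    def test_missing_gene_flagged(self):
        out = rank_pathway(self._calls(), ["NQO1", "TP53"], "KBrO3", "OTA")
        row = out[out["gene"] == "TP53"].iloc[0]
        assert not row["in_data"]

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            rank_pathway(self._calls(), [], "KBrO3", "OTA")


class TestMirnaOverlap:
    def _calls(self, rows):
        return _calls(rows)

    def test_disjoint_sets_empty(self):
        calls = self._calls([
            ("mir1", "KBrO3", "T5", 1.0, 1e-3, 0.01, 1),
            ("mir2", "OTA", "T5", 1.0, 1e-3, 0.01, 1),
        ])
        out = mirna_overlap(calls, ("KBrO3", "T5"), "OTA")
        assert not out["shared"].any() if len(out) else True

    def test_shared_mirnas_reported(self):
        calls = self._calls([
            ("mir1", "KBrO3", "T5", 1.0, 1e-3, 0.01, 1),
            ("mir1", "OTA", "T5", 0.8, 1e-3, 0.02, 1),
            ("mir1", "OTA", "R3", 0.1, 0.5, 0.8, 1),
        ])
        out = mirna_overlap(calls, ("KBrO3", "T5"), "OTA")
        byp = out.set_index("timepoint")
        assert bool(byp.loc["T5", "shared"])
        assert not bool(byp.loc["R3", "shared"])

    def test_planted_shared_count(self, design3):
        matrix, truth = simulate_expression(design3, 80, 0.2, 2.0, seed=41,
                                            feature_prefix="mir")
        calls = diff_all_contrasts(matrix, design3)
        out = mirna_overlap(calls, ("KBrO3", "T5"), "OTA", fdr_cutoff=0.05)
        shared = set(out[(out["timepoint"] == "T5") & out["shared"]]["mirna"])
        # planted effects apply to both treatments, so strong DE miRNAs are shared
        assert shared <= set(truth.de_genes)
        assert len(shared) >= 0.7 * len(truth.de_genes)


def test_null_coupling_stays_in_null_band(design2):
    """With coupling_rho = 0 planted, |rho| remains inside the null band
    at every timepoint (99.9% two-sided bound 3.3/sqrt(n), sized for the
    four-timepoint multiplicity of this check)."""
    _, ge_truth = simulate_expression(design2, 1000, 1.0, uniform_magnitudes(), seed=71)
    matrix, _ = simulate_expression(design2, 1000, 1.0, uniform_magnitudes(), seed=71)
    track, _ = simulate_tiling(design2, n_genes=1000, region_fraction=1.0,
                               coupling_rho=0.0, ge_truth=ge_truth, seed=72)
    ge_calls = diff_all_contrasts(matrix, design2)
    for tp in design2.timepoints:
        ha_calls = call_regions(track, design2, "OTA", tp)
        records = build_records(ge_calls, ha_calls)
        res = correlate_epi_ge(records, "HA", "OTA", tp)
        if res is None:
            continue
        assert abs(res["rho"]) < 3.3 / np.sqrt(res["n"])
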