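import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import lofscreen.io as io
from lofscreen import (
    call_essential,
    control_size_factors,
    count_guides,
    gen_screen_counts,
    gene_level_call,
    nb_depletion_test,
    run_screen_analysis,
    sample_qc,
)
from lofscreen.screen import adjusted_results
from lofscreen.simulate import SimulationConfig, screen_fastq_records


def _matrix(rows: dict, columns) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns).rename_axis(
        "guide_id"
    )


def _ones(columns):
    return pd.Series(1.0, index=columns)


class TestCountGuides:
    def test_single_read(self, tmp_path, small_screen):
        manifest = small_screen[0]
        g = manifest.iloc[0]
        io.write_fastq([("r1", "ACCG" + g["sequence"] + "GTTT")], tmp_path / "a.fastq")
        counts, rate = count_guides(tmp_path / "a.fastq", manifest)
        assert counts[g["guide_id"]] == 1
        assert counts.sum() == 1
        assert rate == 1.0

    def test_unmatched_read_lowers_mapping_rate(self, tmp_path, small_screen):
        manifest = small_screen[0]
        g = manifest.iloc[0]
        io.write_fastq(
            [("r1", "ACCG" + g["sequence"] + "GTTT"), ("r2", "T" * 28)],
            tmp_path / "a.fastq",
        )
        counts, rate = count_guides(tmp_path / "a.fastq", manifest)
        assert counts.sum() == 1
        assert rate == 0.5

    def test_generator_round_trip(self, tmp_path, small_screen):
        """Counting the simulator's FASTQ recovers the sampled counts exactly."""
        manifest, _, counts, _, _ = small_screen
        io.write_fastq(
            screen_fastq_records(counts["T7_r1"], manifest), tmp_path / "s.fastq"
        )
        got, rate = count_guides(tmp_path / "s.fastq", manifest)
        assert (got == counts["T7_r1"]).all()
        assert rate == 1.0

    def test_offset_mode(self, tmp_path, small_screen):
        manifest = small_screen[0]
        g = manifest.iloc[3]
        io.write_fastq([("r1", "ACCG" + g["sequence"] + "GTTT")], tmp_path / "a.fastq")
        counts, rate = count_guides(tmp_path / "a.fastq", manifest, offset=4)
        assert counts[g["guide_id"]] == 1
        counts_bad, _ = count_guides(tmp_path / "a.fastq", manifest, offset=0)
        assert counts_bad.sum() == 0

    def test_empty_fastq_rejected(self, tmp_path, small_screen):
        (tmp_path / "e.fastq").write_text("")
        with pytest.raises(ValueError, match="empty"):
            count_guides(tmp_path / "e.fastq", small_screen[0])

    def test_duplicate_sequences_rejected(self, tmp_path, small_screen):
        manifest = small_screen[0].copy()
        manifest.loc[1, "sequence"] = manifest.loc[0, "sequence"]
        io.write_fastq([("r1", "A" * 28)], tmp_path / "a.fastq")
        with pytest.raises(ValueError, match="duplicate"):
            count_guides(tmp_path / "a.fastq", manifest)


class TestControlSizeFactors:
    def test_identical_samples_equal_factors(self):
        m = _matrix({"c1": [10, 10], "c2": [20, 20], "g": [5, 5]}, ["a", "b"])
        f = control_size_factors(m, ["c1", "c2"])
        assert f["a"] == pytest.approx(f["b"])

    def test_doubled_sample_hand_computed(self):
        """B = 2x A on five control guides: median of ratios gives factor ratio 2."""
        a = np.array([10, 20, 30, 40, 50])
        m = _matrix(
            {f"c{i}": [a[i], 2 * a[i]] for i in range(5)}, ["A", "B"]
        )
        ref = np.sqrt(a * 2 * a)  # geometric mean per control guide
        expected = (np.median(a / ref), np.median(2 * a / ref))
        f = control_size_factors(m, [f"c{i}" for i in range(5)])
        assert f["A"] == pytest.approx(expected[0])
        assert f["B"] == pytest.approx(expected[1])
        assert f["B"] / f["A"] == pytest.approx(2.0)

    def test_scaling_one_sample_scales_its_factor(self):
        m = _matrix({f"c{i}": [k, k] for i, k in enumerate([10, 20, 30])}, ["A", "B"])
        f0 = control_size_factors(m, m.index)
        m2 = m.copy()
        m2["B"] = m2["B"] * 3
        f1 = control_size_factors(m2, m2.index)
        assert f1["B"] / f0["B"] == pytest.approx(3.0 / np.sqrt(3.0))
        # dispersion-free controls: factor ratio between samples is exact
        assert f1["B"] / f1["A"] == pytest.approx(3.0)

    def test_guides_with_zeros_excluded(self):
        m = _matrix({"c1": [0, 10], "c2": [20, 20]}, ["A", "B"])
        f = control_size_factors(m, ["c1", "c2"])
        assert f["A"] == pytest.approx(1.0)  # only c2 usable

    def test_no_usable_control_rejected(self):
        m = _matrix({"c1": [0, 10], "c2": [5, 0]}, ["A", "B"])
        with pytest.raises(ValueError, match="control"):
            control_size_factors(m, ["c1", "c2"])

    def test_recovers_known_multipliers(self):
        """Median-of-ratios recovers simulated depth multipliers within 10%."""
        from lofscreen import GeneSet, design_library

        mult = (1.0, 0.5, 2.0, 1.0, 1.5, 0.8, 1.2, 1.0, 0.7, 1.3, 1.0)
        cfg = SimulationConfig(seed=11, library_size_multipliers=mult, dispersion=0.05)
        man = design_library(
            GeneSet("t", [f"G{i:05d}" for i in range(1, 201)]), n_safeharbor=25, seed=3
        )
        counts, _, _ = gen_screen_counts(man, cfg)
        sh = man.loc[man["target_class"] == "safe_harbor", "guide_id"]
        f = control_size_factors(counts, sh).values
        m = np.asarray(mult)
        rel = (f / np.exp(np.log(f).mean())) / (m / np.exp(np.log(m).mean()))
        assert np.abs(rel - 1).max() < 0.10


class TestNbDepletionTest:
    def test_null_identity(self):
        m = _matrix({"g": [30, 30, 30, 30]}, ["b1", "b2", "t1", "t2"])
        res = nb_depletion_test(m, ["b1", "b2"], ["t1", "t2"], _ones(m.columns))
        assert res["log2fc"].iloc[0] == pytest.approx(0.0)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_poisson_oracle_pinned_counts(self):
        """Totals 100 vs 25, equal arms: log2FC = -2; Wald agrees with the exact
        conditional-binomial Poisson test on the equivalent-normal-quantile scale."""
        m = _matrix({"g": [50, 50, 13, 12]}, ["b1", "b2", "t1", "t2"])
        res = nb_depletion_test(m, ["b1", "b2"], ["t1", "t2"], _ones(m.columns))
        assert res["log2fc"].iloc[0] == pytest.approx(-2.0)
        p_exact = sps.binomtest(25, 125, 0.5).pvalue
        z_wald = abs(res["wald"].iloc[0])
        z_exact = sps.norm.isf(p_exact / 2)
        assert abs(z_wald - z_exact) / z_exact < 0.10

    def test_poisson_oracle_moderate_effect(self):
        """Large counts, moderate depletion: raw p within 10% of the exact test."""
        m = _matrix({"g": [500, 500, 440, 440]}, ["b1", "b2", "t1", "t2"])
        res = nb_depletion_test(m, ["b1", "b2"], ["t1", "t2"], _ones(m.columns))
        p_exact = sps.binomtest(880, 1880, 0.5).pvalue
        assert abs(res["p"].iloc[0] - p_exact) / p_exact < 0.10

    def test_type_one_error_calibration(self):
        """Null NB simulation (alpha=0.1, 3v4, 2000 guides): type-I error near 0.05."""
        rates = []
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            n_g, mu, a = 2000, 500.0, 0.1
            r = 1 / a
            ab = mu * np.exp(0.5 * rng.standard_normal(n_g))
            counts = rng.negative_binomial(r, r / (r + ab[:, None]), size=(n_g, 7))
            m = pd.DataFrame(
                counts,
                index=[f"g{i}" for i in range(n_g)],
                columns=[f"s{i}" for i in range(7)],
            )
            res = nb_depletion_test(
                m, list(m.columns[:3]), list(m.columns[3:]), _ones(m.columns)
            )
            rates.append((res["p"] < 0.05).mean())
        assert 0.03 <= np.mean(rates) <= 0.07

    def test_zero_timepoint_arm_uses_pseudocount(self):
        m = _matrix({"g": [40, 40, 0, 0]}, ["b1", "b2", "t1", "t2"])
        res = nb_depletion_test(m, ["b1", "b2"], ["t1", "t2"], _ones(m.columns))
        assert np.isfinite(res["log2fc"].iloc[0])
        assert res["log2fc"].iloc[0] < -6  # ~log2(0.5/80.5)

    def test_absent_guide_flagged_not_testable(self):
        m = _matrix(
            {"g": [0, 0, 0, 0], "h": [10, 10, 10, 10]}, ["b1", "b2", "t1", "t2"]
        )
        res = nb_depletion_test(m, ["b1", "b2"], ["t1", "t2"], _ones(m.columns))
        assert not res.loc["g", "testable"]
        assert np.isnan(res.loc["g", "p"])
        adj = adjusted_results(res)
        assert np.isnan(adj.loc["g", "padj"])  # excluded from the BH family

    def test_size_factor_offsets_respected(self):
        # counts doubled in the timepoint arm purely by depth: no fold change
        m = _matrix({"g": [30, 30, 60, 60]}, ["b1", "b2", "t1", "t2"])
        sf = pd.Series({"b1": 1.0, "b2": 1.0, "t1": 2.0, "t2": 2.0})
        res = nb_depletion_test(m, ["b1", "b2"], ["t1", "t2"], sf)
        assert res["log2fc"].iloc[0] == pytest.approx(0.0)

    def test_arm_size_validation(self):
        m = _matrix({"g": [1, 2, 3]}, ["a", "b", "c"])
        with pytest.raises(ValueError, match="2 samples"):
            nb_depletion_test(m, ["a"], ["b", "c"], _ones(m.columns))


class TestGeneLevelCalls:
    @staticmethod
    def _results(padjs: dict) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "padj": pd.Series(padjs),
                "log2fc": -1.0,
                "p": pd.Series(padjs) / 2,
                "testable": True,
            }
        )
        df.index.name = "guide_id"
        return df

    @staticmethod
    def _manifest(gene_guides: dict) -> pd.DataFrame:
        rows = []
        for gene, guides in gene_guides.items():
            for gid in guides:
                rows.append((gid, "SET1", "targeting", gene, "A" * 20))
        return pd.DataFrame(
            rows, columns=["guide_id", "set_id", "target_class", "target_gene", "sequence"]
        )

    @pytest.mark.parametrize(
        "padjs,expected",
        [({"a": 0.01, "b": 0.2}, True), ({"a": 0.2, "b": 0.2}, False),
         ({"a": 0.04, "b": 0.04}, True)],
    )
    def test_one_significant_guide_suffices(self, padjs, expected):
        man = self._manifest({"G": list(padjs)})
        calls = gene_level_call(self._results(padjs), man, alpha=0.05)
        assert bool(calls.loc["G", "significant"]) is expected

    def test_untestable_gene_flagged(self):
        man = self._manifest({"G": ["a", "b"]})
        res = self._results({"a": 0.5, "b": 0.5})
        res["testable"] = False
        res[["padj", "p"]] = np.nan
        calls = gene_level_call(res, man, alpha=0.05)
        assert not calls.loc["G", "testable"]

    @staticmethod
    def _contrast(lfc: float, padj: float) -> pd.DataFrame:
        df = pd.DataFrame(
            {"log2fc": [lfc, lfc + 0.1], "padj": [padj, min(1.0, padj * 3)],
             "p": padj, "testable": True},
            index=pd.Index(["a", "b"], name="guide_id"),
        )
        return df

    @pytest.mark.parametrize(
        "lfc7,padj7,lfc14,padj14,expected",
        [
            (-1.0, 0.01, -2.0, 0.01, True),   # deepening depletion, both significant
            (-2.0, 0.01, -1.0, 0.01, False),  # depletion not increasing
            (1.0, 0.01, 2.0, 0.01, False),    # enriched, not depleted
            (-1.0, 0.2, -2.0, 0.01, False),   # T7 not significant
        ],
    )
    def test_essentiality_criteria(self, lfc7, padj7, lfc14, padj14, expected):
        man = self._manifest({"G": ["a", "b"]})
        ess = call_essential(
            self._contrast(lfc7, padj7), self._contrast(lfc14, padj14), man
        )
        assert bool(ess.loc["G", "essential"]) is expected

    def test_mean_aggregate_option(self):
        man = self._manifest({"G": ["a", "b"]})
        ess = call_essential(
            self._contrast(-1.0, 0.01), self._contrast(-2.0, 0.01), man,
            aggregate="mean",
        )
        assert ess.loc["G", "log2fc_T7"] == pytest.approx(-0.95)


class TestSampleQc:
    def test_identical_samples_same_point(self):
        m = _matrix({"g1": [10, 10, 30], "g2": [20, 20, 5]}, ["a", "b", "c"])
        qc = sample_qc(m)
        coords = qc["pca_coords"]
        assert np.allclose(coords.loc["a"], coords.loc["b"], atol=1e-8)

    def test_constant_matrix_zero_variance(self):
        m = _matrix({"g1": [5, 5], "g2": [5, 5]}, ["a", "b"])
        qc = sample_qc(m, size_factors=_ones(m.columns))
        assert np.allclose(qc["pca_coords"], 0.0)
        assert np.allclose(qc["explained_variance_ratio"], 0.0)

    def test_explained_variance_bounded(self, small_screen):
        _, _, counts, _, _ = small_screen
        qc = sample_qc(counts)
        assert qc["explained_variance_ratio"].sum() <= 1.0 + 1e-9

    def test_timepoints_separate_on_pc1(self):
        """With strong spiked depletion, PC1 separates T0 from T14 (sign-invariant)."""
        from lofscreen import GeneSet, design_library

        gs = GeneSet("t", [f"g{i}" for i in range(100)])
        man = design_library(gs, n_ntc=10, n_safeharbor=5, seed=1)
        cfg = SimulationConfig(seed=2, n_essential=40, depletion_per_doubling=0.7)
        counts, sheet, _ = gen_screen_counts(man, cfg)
        qc = sample_qc(counts)
        pc1 = qc["pca_coords"]["PC1"]
        t0 = pc1[sheet.loc[sheet["timepoint"] == "T0", "sample"]]
        t14 = pc1[sheet.loc[sheet["timepoint"] == "T14", "sample"]]
        assert (t0.max() < t14.min()) or (t14.max() < t0.min())


class TestFullScreenAnalysis:
    def test_spiked_essentials_recovered(self, small_screen):
        manifest, _, counts, sheet, truth = small_screen
        out = run_screen_analysis(counts, sheet, manifest)
        called = set(out["essential"].query("essential").index)
        assert called == set(truth["essential_genes"])

    def test_control_guides_neutral(self, fullscale_manifest):
        """Mean control log2FC within +/-0.1 of zero in every simulated contrast."""
        cfg = SimulationConfig(seed=1, n_essential=20)
        counts, sheet, _ = gen_screen_counts(fullscale_manifest, cfg)
        out = run_screen_analysis(counts, sheet, fullscale_manifest)
        ctrl = fullscale_manifest.loc[
            fullscale_manifest["target_class"] != "targeting", "guide_id"
        ]
        for contrast in ("T7vsT0", "T14vsT0"):
            assert abs(out["results"][contrast].loc[ctrl, "log2fc"].mean()) < 0.1

    def test_bh_family_is_per_contrast(self, small_screen):
        manifest, _, counts, sheet, _ = small_screen
        out = run_screen_analysis(counts, sheet, manifest)
        for contrast, res in out["results"].items():
            ok = res["p"].notna()
            assert (res.loc[ok, "padj"] >= res.loc[ok, "p"] - 1e-12).all()
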