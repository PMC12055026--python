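"""Site harmonization, GLM contrasts, label aggregation, KS tests, BH-FDR."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_hyp
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from msngrad.stats import (
    aggregate_by_label,
    bh_fdr,
    combat_harmonize,
    glm_contrast,
    ks_compare,
    label_contrast,
)


def _design(n, n_sites=2, seed=0, groups=None):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "group": groups if groups is not None else rng.permutation(["AD", "NC"] * (n // 2)),
            "age": rng.normal(73, 6, n),
            "sex": rng.integers(0, 2, n),
            "education": rng.normal(16, 2, n),
            "site": [f"s{i % n_sites}" for i in range(n)],
        }
    )


class TestCombat:
    def test_single_site_round_trip(self, rng):
        values = rng.standard_normal((20, 15))
        design = _design(20, n_sites=1)
        np.testing.assert_allclose(
            combat_harmonize(values, design), values, atol=1e-8
        )

    def test_planted_offset_removed(self, rng):
        n, p, delta = 100, 40, 2.0
        design = _design(n, n_sites=2, seed=3)
        values = rng.standard_normal((n, p))
        values[np.asarray(design["site"]) == "s1"] += delta
        out = combat_harmonize(values, design)
        is_b = np.asarray(design["site"]) == "s1"
        diff = out[is_b].mean(axis=0) - out[~is_b].mean(axis=0)
        assert abs(diff.mean()) < 0.05 * delta

    def test_group_effect_preserved(self, rng):
        n, p = 100, 40
        design = _design(n, n_sites=2, seed=4)
        is_ad = np.asarray(design["group"]) == "AD"
        values = rng.standard_normal((n, p))
        values[is_ad] += 1.0
        values[np.asarray(design["site"]) == "s1"] += 0.8
        out = combat_harmonize(values, design)
        before = values[is_ad].mean() - values[~is_ad].mean()
        after = out[is_ad].mean() - out[~is_ad].mean()
        assert abs(after - before) / abs(before) < 0.05

    def test_singleton_site_rejected(self, rng):
        design = _design(10, n_sites=1)
        design.loc[0, "site"] = "lonely"
        with pytest.raises(ValueError, match="lonely"):
            combat_harmonize(rng.standard_normal((10, 5)), design)

    def test_rank_deficient_rejected(self, rng):
        design = _design(20, n_sites=2)
        design["education"] = (np.asarray(design["site"]) == "s1").astype(float)
        with pytest.raises(ValueError, match="collinear|rank"):
            combat_harmonize(rng.standard_normal((20, 5)), design)

    def test_matches_sva_combat(self, rng, tmp_path):
        """Cross-check against the reference Bioconductor implementation."""
        n, p = 40, 20
        design = _design(n, n_sites=2, seed=9)
        is_b = np.asarray(design["site"]) == "s1"
        values = rng.standard_normal((n, p)) + 0.8 * is_b[:, None]
        ours = combat_harmonize(values, design)

        np.savetxt(tmp_path / "y.csv", values.T, delimiter=",")
        pd.DataFrame(
            {
                "site": design["site"],
                "group": (design["group"] == "AD").astype(int),
                "age": design["age"],
                "sex": design["sex"],
                "education": design["education"],
            }
        ).to_csv(tmp_path / "meta.csv", index=False)
        script = f"""
suppressMessages(library(sva))
y <- as.matrix(read.csv("{tmp_path}/y.csv", header=FALSE))
meta <- read.csv("{tmp_path}/meta.csv")
mod <- model.matrix(~group+age+sex+education, data=meta)
out <- ComBat(dat=y, batch=meta$site, mod=mod, par.prior=TRUE)
write.table(out, "{tmp_path}/out.csv", sep=",", row.names=FALSE, col.names=FALSE)
"""
        (tmp_path / "combat.R").write_text(script)
        proc = subprocess.run(
            ["Rscript", str(tmp_path / "combat.R")], capture_output=True, text=True
        )
        assert proc.returncode == 0, proc.stderr
        theirs = np.loadtxt(tmp_path / "out.csv", delimiter=",").T
        np.testing.assert_allclose(ours, theirs, atol=1e-8)


class TestGlmContrast:
    def test_identical_groups_give_zero_t(self, rng):
        half = rng.standard_normal((10, 8))
        values = np.vstack([half, half])
        design = _design(20, groups=np.array(["AD"] * 10 + ["NC"] * 10))
        design.iloc[10:, design.columns.get_loc("age")] = design["age"][:10].to_numpy()
        design.iloc[10:, design.columns.get_loc("sex")] = design["sex"][:10].to_numpy()
        design.iloc[10:, design.columns.get_loc("education")] = design["education"][
            :10
        ].to_numpy()
        res = glm_contrast(values, design)
        np.testing.assert_allclose(res["t"], 0.0, atol=1e-10)

    def test_covariate_free_matches_two_sample_t(self, rng):
        values = rng.standard_normal((30, 12))
        groups = np.array(["AD"] * 14 + ["NC"] * 16)
        design = _design(30, groups=groups)
        res = glm_contrast(values, design, covariates=())
        expected = sps.ttest_ind(values[groups == "AD"], values[groups == "NC"])
        np.testing.assert_allclose(res["t"], expected.statistic, atol=1e-10)
        np.testing.assert_allclose(res["p"], expected.pvalue, atol=1e-10)

    def test_covariate_rescaling_invariance(self, rng):
        values = rng.standard_normal((40, 6))
        design = _design(40, seed=5)
        t1 = glm_contrast(values, design)["t"]
        design2 = design.copy()
        design2["age"] = design2["age"] * 12.0 + 100.0
        t2 = glm_contrast(values, design2)["t"]
        np.testing.assert_allclose(t1, t2, atol=1e-9)

    def test_collinear_covariates_named(self, rng):
        design = _design(20)
        design["education"] = design["age"] * 2.0
        with pytest.raises(ValueError, match="education"):
            glm_contrast(rng.standard_normal((20, 4)), design)

    def test_planted_sign_recovery(self, rng):
        effects = rng.normal(0, 0.5, 60)
        n = 200
        groups = np.array(["AD"] * 100 + ["NC"] * 100)
        design = _design(n, groups=groups)
        values = rng.standard_normal((n, 60))
        values[:100] += effects
        res = glm_contrast(values, design)
        big = np.abs(effects) >= 0.8
        agree = np.sign(res["t"].to_numpy()[big]) == np.sign(effects[big])
        assert agree.mean() >= 0.95


class TestAggregate:
    def test_one_region_per_label_identity(self):
        values = pd.DataFrame([[1.0, 2.0]], columns=["region_0001", "region_0002"])
        atlas = pd.DataFrame(
            {
                "region_id": ["region_0001", "region_0002"],
                "econo_class": ["A", "B"],
                "yeo_network": ["X", "Y"],
            }
        )
        out = aggregate_by_label(values, atlas, level="class")
        assert out.loc[0, "A"] == 1.0 and out.loc[0, "B"] == 2.0

    def test_single_label_is_global_mean(self, rng):
        values = pd.DataFrame(
            rng.standard_normal((4, 6)), columns=[f"region_{i+1:04d}" for i in range(6)]
        )
        atlas = pd.DataFrame(
            {
                "region_id": values.columns,
                "econo_class": ["only"] * 6,
                "yeo_network": ["only"] * 6,
            }
        )
        out = aggregate_by_label(values, atlas, level="class")
        np.testing.assert_allclose(out["only"], values.mean(axis=1))

    def test_random_partition_oracle(self, rng):
        cols = [f"region_{i+1:04d}" for i in range(9)]
        values = pd.DataFrame(rng.standard_normal((5, 9)), columns=cols)
        labels = rng.choice(["a", "b", "c"], size=9)
        atlas = pd.DataFrame(
            {"region_id": cols, "econo_class": labels, "yeo_network": labels}
        )
        out = aggregate_by_label(values, atlas, level="class")
        for lab in "abc":
            members = [c for c, l in zip(cols, labels) if l == lab]
            np.testing.assert_allclose(out[lab], values[members].mean(axis=1))

    def test_unlabeled_region_rejected(self, rng):
        values = pd.DataFrame(rng.standard_normal((2, 2)), columns=["r1", "r2"])
        atlas = pd.DataFrame(
            {"region_id": ["r1"], "econo_class": ["A"], "yeo_network": ["X"]}
        )
        with pytest.raises(ValueError, match="r2"):
            aggregate_by_label(values, atlas, level="class")


def _ks_oracle(a, b):
    pooled = np.sort(np.concatenate([a, b]))
    ecdf_a = np.searchsorted(np.sort(a), pooled, side="right") / len(a)
    ecdf_b = np.searchsorted(np.sort(b), pooled, side="right") / len(b)
    return np.max(np.abs(ecdf_a - ecdf_b))


class TestKs:
    def test_identical_samples(self, rng):
        a = rng.standard_normal(30)
        d, _ = ks_compare(a, a.copy())
        assert d == 0.0

    def test_disjoint_supports(self, rng):
        d, p = ks_compare(rng.uniform(0, 1, 25), rng.uniform(2, 3, 30))
        assert d == 1.0 and p < 1e-10

    def test_ecdf_sweep_oracle(self, rng):
        for _ in range(10):
            a = rng.standard_normal(int(rng.integers(5, 40)))
            b = rng.standard_normal(int(rng.integers(5, 40)))
            d, _ = ks_compare(a, b)
            assert d == pytest.approx(_ks_oracle(a, b), abs=1e-12)

    def test_symmetry_and_range(self, rng):
        a, b = rng.standard_normal(20), rng.normal(1, 2, 35)
        d_ab, p_ab = ks_compare(a, b)
        d_ba, p_ba = ks_compare(b, a)
        assert d_ab == d_ba and p_ab == p_ba
        assert 0 <= d_ab <= 1

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_compare(np.array([]), np.array([1.0]))


class TestBhFdr:
    def test_reference_values(self):
        assert bh_fdr(np.array([0.03]))[0] == pytest.approx(0.03)
        np.testing.assert_allclose(
            bh_fdr(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(bh_fdr(np.full(6, 0.5)), 0.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.2, 1.3]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st_hyp.lists(
            st_hyp.floats(0, 1, allow_nan=False), min_size=1, max_size=40
        )
    )
    def test_matches_statsmodels_step_up(self, pvals):
        p = np.array(pvals)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)


class TestLabelContrast:
    def test_pooled_and_subject_mean_modes(self, small_cohort, rng):
        cols = [f"region_{i+1:04d}" for i in range(20)]
        values = pd.DataFrame(rng.standard_normal((20, 20)), columns=cols)
        design = _design(20, seed=8)
        atlas = pd.DataFrame(
            {
                "region_id": cols,
                "econo_class": ["c1"] * 10 + ["c2"] * 10,
                "yeo_network": ["n1"] * 10 + ["n2"] * 10,
            }
        )
        pooled = label_contrast(values, design, atlas, level="class")
        by_mean = label_contrast(
            values, design, atlas, level="class", subject_means=True
        )
        assert set(pooled.ks.index) == {"c1", "c2"}
        # pooled ECDFs use 10x more points -> the two modes genuinely differ
        assert not np.allclose(
            pooled.ks["D"].to_numpy(), by_mean.ks["D"].to_numpy()
        )
        np.testing.assert_allclose(
            pooled.glm["t"].to_numpy(), by_mean.glm["t"].to_numpy()
        )
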