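"""Statistical layer: rank tests, ordination, clustering, permutation tests,
and multivariable associations, each checked against an independent route
(enumeration, closed form, scikit-bio, or R vegan)."""

import subprocess
import textwrap
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from _oracles import bh_oracle, mwu_exact_p_enumeration, pseudo_f_oracle
from rpoaprof.stats import (
    bh_fdr,
    bray_curtis,
    confidence_tier,
    envfit_vectors,
    fit_associations,
    kruskal_wallis,
    mann_whitney_u,
    pairwise_bonferroni,
    pam_with_silhouette,
    pcoa,
    permanova,
)


class TestMannWhitney:
    def test_complete_separation_exact(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2 * 1/20
        assert res.method == "mann-whitney-exact"

    def test_identical_multisets(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney_u(x, x)
        assert res.statistic == len(x) ** 2 / 2
        assert res.p_value == pytest.approx(1.0)

    def test_exact_branch_matches_enumeration_small(self, rng):
        values = [3.1, 1.4, 4.1, 5.9, 2.6, 8.5, 0.3, 7.2]
        for n1 in (2, 3, 4):
            for idx in combinations(range(len(values)), n1):
                x = [values[i] for i in idx]
                y = [values[i] for i in range(len(values)) if i not in idx]
                res = mann_whitney_u(x, y)
                assert res.p_value == pytest.approx(
                    mwu_exact_p_enumeration(x, y), abs=1e-12
                )

    def test_asymptotic_branch_close_to_exact(self, rng):
        # the tie/continuity-corrected normal approximation tracks the exact
        # enumeration closely at n = 8 per group
        diffs = []
        for _ in range(20):
            x = list(rng.normal(0, 1, 8))
            y = list(rng.normal(0.5, 1, 8))
            res = mann_whitney_u(x, y, exact_limit=0)  # force asymptotic
            assert res.method == "mann-whitney-asymptotic"
            diffs.append(abs(res.p_value - mwu_exact_p_enumeration(x, y)))
        assert max(diffs) < 0.02
        assert np.mean(diffs) < 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestKruskalWallis:
    def test_identical_groups(self):
        res = kruskal_wallis([[5, 5], [5, 5], [5, 5]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_hand_computed_h(self):
        # ranks 1..6, group mean ranks 1.5/3.5/5.5:
        # H = 12/(6*7) * 2*((1.5-3.5)^2 + 0 + (5.5-3.5)^2) = 32/7
        res = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert res.statistic == pytest.approx(32 / 7)

    def test_two_groups_routed_to_mwu(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert res.method.startswith("mann-whitney")

    def test_pairwise_bonferroni_multiplier(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        results = pairwise_bonferroni(groups)
        assert len(results) == 3
        for r in results:
            assert r.adjusted_p == pytest.approx(min(1.0, r.p_value * 3))
            assert r.adjusted_p >= r.p_value


class TestBrayCurtis:
    def test_known_values(self):
        d = bray_curtis(np.array([[2.0, 2.0], [2.0, 0.0]]))
        assert d[0, 1] == pytest.approx(2 / 6)
        assert bray_curtis(np.array([[1.0, 1.0], [1.0, 1.0]]))[0, 1] == 0.0
        assert bray_curtis(np.array([[1.0, 0.0], [0.0, 1.0]]))[0, 1] == 1.0

    def test_metric_properties_random(self, rng):
        x = rng.random((40, 14))
        d = bray_curtis(x)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert np.all((d >= 0) & (d <= 1 + 1e-12))

    def test_all_zero_pair_warns_and_is_zero(self):
        with pytest.warns(UserWarning):
            d = bray_curtis(np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 2.0]]))
        assert d[0, 1] == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(np.array([[-1.0, 2.0], [1.0, 1.0]]))


class TestPcoa:
    def test_collinear_points(self):
        pts = np.array([[0.0], [1.0], [2.0], [3.5]])
        d = np.abs(pts - pts.T)
        ordi = pcoa(d)
        # one positive axis carrying everything
        assert ordi.pct_variance[0] == pytest.approx(100.0)
        order = np.argsort(ordi.coordinates[:, 0])
        assert list(order) == [0, 1, 2, 3] or list(order) == [3, 2, 1, 0]

    def test_reconstructs_euclidean_configuration(self, rng):
        pts = rng.normal(size=(20, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ordi = pcoa(d)
        recon = np.linalg.norm(
            ordi.coordinates[:, None] - ordi.coordinates[None, :], axis=-1
        )
        assert np.max(np.abs(recon - d)) < 1e-8
        assert ordi.pct_variance.sum() == pytest.approx(100.0)

    def test_sign_convention_deterministic(self, rng):
        pts = rng.normal(size=(15, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        a, b = pcoa(d), pcoa(d.copy())
        assert np.array_equal(a.coordinates, b.coordinates)
        for k in range(a.coordinates.shape[1]):
            i = np.argmax(np.abs(a.coordinates[:, k]))
            assert a.coordinates[i, k] > 0

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_against_skbio(self, rng):
        skbio_pcoa = pytest.importorskip("skbio.stats.ordination").pcoa
        from skbio import DistanceMatrix

        x = rng.random((25, 6))
        d = bray_curtis(x)
        ours = pcoa(d)
        theirs = skbio_pcoa(DistanceMatrix(d), number_of_dimensions=0)
        ev_theirs = np.sort(theirs.eigvals.to_numpy())[::-1]
        npos = ours.pct_variance.size
        assert np.allclose(
            ours.eigenvalues[:npos], ev_theirs[:npos], atol=1e-8
        )
        # embeddings agree up to sign per axis
        for k in range(3):
            ref = theirs.samples.to_numpy()[:, k]
            got = ours.coordinates[:, k]
            assert min(
                np.max(np.abs(got - ref)), np.max(np.abs(got + ref))
            ) < 1e-8


class TestPam:
    def _two_clouds(self, rng, n=20, sep=10.0):
        pts = np.vstack(
            [rng.normal(0, 1, (n, 2)), rng.normal(sep, 1, (n, 2))]
        )
        return np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)

    def test_selects_k2_for_two_clouds(self, rng):
        d = self._two_clouds(rng)
        sol = pam_with_silhouette(d, k_range=range(2, 6))
        assert sol.k == 2
        assert sol.avg_silhouette > 0.7
        # the two clouds are exactly recovered
        assert len(set(sol.assignments[:20])) == 1
        assert len(set(sol.assignments[20:])) == 1

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError):
            pam_with_silhouette(np.zeros((5, 5)))

    def test_k_outside_range_rejected(self, rng):
        d = self._two_clouds(rng, n=3)
        with pytest.raises(ValueError):
            pam_with_silhouette(d, k_range=[6])

    def test_deterministic(self, rng):
        d = self._two_clouds(rng)
        a = pam_with_silhouette(d, k_range=range(2, 5))
        b = pam_with_silhouette(d, k_range=range(2, 5))
        assert a.k == b.k
        assert np.array_equal(a.assignments, b.assignments)


class TestEnvfit:
    def _ordination(self, rng, n=40):
        x = rng.random((n, 8))
        return pcoa(bray_curtis(x))

    def test_axis_variable_r2_one(self, rng):
        ordi = self._ordination(rng)
        v = pd.DataFrame({"v": ordi.coordinates[:, 0]})
        fit = envfit_vectors(ordi, v, n_perm=99, seed=0)[0]
        assert fit.r2 == pytest.approx(1.0)
        assert abs(fit.direction[0]) == pytest.approx(1.0, abs=1e-8)
        assert fit.p_value == pytest.approx(1 / 100)  # minimal attainable p

    def test_constant_variable(self, rng):
        ordi = self._ordination(rng)
        fit = envfit_vectors(ordi, pd.DataFrame({"c": np.ones(40)}), 99, 0)[0]
        assert fit.r2 == 0.0 and fit.p_value == 1.0

    def test_reproducible_under_seed(self, rng):
        ordi = self._ordination(rng)
        v = pd.DataFrame({"v": rng.normal(size=40)})
        a = envfit_vectors(ordi, v, n_perm=199, seed=42)[0]
        b = envfit_vectors(ordi, v, n_perm=199, seed=42)[0]
        assert a.p_value == b.p_value and a.r2 == b.r2

    def test_noise_type1_quick(self, rng):
        # light-weight null calibration; the full 500-replicate check lives
        # in the acceptance suite
        ordi = self._ordination(rng, n=30)
        vars_ = pd.DataFrame(
            {f"v{i}": rng.normal(size=30) for i in range(200)}
        )
        fits = envfit_vectors(ordi, vars_, n_perm=99, seed=7)
        rate = np.mean([f.p_value <= 0.05 for f in fits])
        assert 0.01 <= rate <= 0.10


class TestPermanova:
    def test_equals_brute_force_oracle(self, rng):
        for _ in range(5):
            x = rng.random((12, 5))
            d = bray_curtis(x)
            groups = list("aaabbbbccccd"[:12])
            # need >=2 per group
            groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
            res = permanova(d, groups, n_perm=99, seed=0)
            assert res.statistic == pytest.approx(
                pseudo_f_oracle(d.tolist(), groups)
            )

    def test_separated_clouds_saturate_significance(self, rng):
        pts = np.vstack([rng.normal(0, 1, (10, 3)), rng.normal(50, 1, (10, 3))])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = permanova(d, ["a"] * 10 + ["b"] * 10, n_perm=999, seed=1)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_reproducible_under_seed(self, rng):
        x = rng.random((20, 5))
        d = bray_curtis(x)
        g = ["a"] * 10 + ["b"] * 10
        assert (
            permanova(d, g, 199, 9).p_value == permanova(d, g, 199, 9).p_value
        )

    def test_single_group_rejected(self, rng):
        d = bray_curtis(rng.random((6, 3)))
        with pytest.raises(ValueError):
            permanova(d, ["a"] * 6)

    def test_against_skbio(self, rng):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        from skbio import DistanceMatrix

        x = rng.random((18, 6))
        d = bray_curtis(x)
        g = ["a"] * 6 + ["b"] * 6 + ["c"] * 6
        ours = permanova(d, g, n_perm=99, seed=0)
        theirs = skbio_distance.permanova(DistanceMatrix(d), g, permutations=99)
        assert ours.statistic == pytest.approx(theirs["test statistic"])


class TestBhFdr:
    def test_printed_toy_set(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_matches_hand_step_up_random(self, rng):
        for _ in range(10):
            p = rng.random(rng.integers(2, 15)).tolist()
            assert np.allclose(bh_fdr(p), bh_oracle(p))

    def test_monotone_and_dominates_raw(self, rng):
        p = np.sort(rng.random(30))
        q = bh_fdr(p)
        assert np.all(np.diff(q) >= -1e-12)
        assert np.all(q >= p - 1e-12)

    def test_confidence_tiers(self):
        assert confidence_tier(0.05) == "high"
        assert confidence_tier(0.1) == "moderate"
        assert confidence_tier(0.25) == "exploratory"
        assert confidence_tier(0.3) == "ns"


class TestFitAssociations:
    def _cohort(self, rng, n, beta=0.0):
        bmi = rng.normal(22, 3, n)
        age = rng.integers(21, 80, n)
        sex = rng.choice(["M", "F"], n)
        expo = rng.normal(0, 1, n)
        y = 0.05 * np.exp(beta * expo + rng.normal(0, 0.5, n))
        prof = pd.DataFrame(
            {"Group 3": 0.6 - y, "Group 11": y, "Group 4": np.full(n, 0.4)},
            index=[f"s{i}" for i in range(n)],
        )
        meta = pd.DataFrame(
            {"BMI": bmi, "age": age, "sex": sex, "expo": expo},
            index=prof.index,
        )
        return prof, meta

    def test_null_type1_error(self, rng):
        hits, m = 0, 400
        for _ in range(m):
            prof, meta = self._cohort(rng, 60)
            res = fit_associations(
                prof, meta, ["expo"], features=["Group 11"]
            )
            hits += res[0].p_value < 0.05
        assert 0.03 <= hits / m <= 0.07

    def test_recovers_injected_effect_sign(self, rng):
        correct = 0
        for _ in range(50):
            prof, meta = self._cohort(rng, 200, beta=0.4)
            res = fit_associations(prof, meta, ["expo"], features=["Group 11"])
            correct += res[0].coef > 0 and res[0].p_value < 0.05
        assert correct >= 48

    def test_minor_features_excluded_by_default(self, rng):
        prof, meta = self._cohort(rng, 80)
        prof["Group 9"] = 1e-4  # minor: median below 1%
        res = fit_associations(prof, meta, ["expo"])
        assert "Group 9" not in {r.feature for r in res}

    def test_collinear_exposure_dropped(self, rng):
        prof, meta = self._cohort(rng, 50)
        meta["twice_bmi"] = 2 * meta["BMI"]
        with pytest.warns(UserWarning, match="collinear"):
            res = fit_associations(prof, meta, ["twice_bmi"], features=["Group 11"])
        assert res == []

    def test_q_and_tier_consistency(self, rng):
        prof, meta = self._cohort(rng, 120, beta=0.5)
        res = fit_associations(prof, meta, ["expo"])
        pvals = [r.p_value for r in res]
        qvals = bh_fdr(pvals)
        for r, q in zip(res, qvals):
            assert r.q_value == pytest.approx(float(q))
            assert r.tier == confidence_tier(r.q_value)


class TestAgainstRVegan:
    """Point-value cross-check of pseudo-F and envfit R^2 against R vegan."""

    def test_adonis_and_envfit(self, rng, tmp_path):
        n = 24
        x = rng.random((n, 6))
        d = bray_curtis(x)
        groups = ["a"] * 8 + ["b"] * 8 + ["c"] * 8
        ordi = pcoa(d)
        v = rng.normal(size=n)
        ours_f = permanova(d, groups, n_perm=99, seed=0).statistic
        ours_r2 = envfit_vectors(ordi, pd.DataFrame({"v": v}), 99, 0)[0].r2

        np.savetxt(tmp_path / "x.csv", x, delimiter=",")
        np.savetxt(tmp_path / "v.csv", v, delimiter=",")
        script = textwrap.dedent(
            """
            suppressMessages(library(vegan))
            x <- as.matrix(read.csv('x.csv', header=FALSE))
            v <- scan('v.csv', quiet=TRUE)
            g <- factor(rep(c('a','b','c'), each=8))
            d <- vegdist(x, method='bray')
            a <- adonis2(d ~ g, permutations=9)
            cat(a$F[1], '\\n')
            ord <- cmdscale(d, k=2)
            ef <- envfit(ord, data.frame(v=v), permutations=9)
            cat(ef$vectors$r[1], '\\n')
            """
        )
        (tmp_path / "oracle.R").write_text(script)
        out = subprocess.run(
            ["Rscript", "oracle.R"], cwd=tmp_path, capture_output=True, text=True,
            timeout=120,
        )
        assert out.returncode == 0, out.stderr
        f_r, r2_r = (float(t) for t in out.stdout.split())
        assert ours_f == pytest.approx(f_r, rel=1e-6)
        assert ours_r2 == pytest.approx(r2_r, rel=1e-6)
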