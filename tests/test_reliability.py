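"""Polychoric estimation, ordinal alpha, interpretation bands, alpha-drop."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import delphiframe as df
from delphiframe.errors import DegenerateMarginalError
from delphiframe.reliability import _cell_probs

from conftest import discretise_bivariate


def tetrachoric_grid_oracle(x, y):
    """Brute-force 2x2 tetrachoric estimate by direct grid search on rho."""
    x = np.asarray(x)
    y = np.asarray(y)
    table = np.array(
        [
            [(np.sum((x == a) & (y == b))) for b in np.unique(y)]
            for a in np.unique(x)
        ],
        dtype=float,
    )
    tau_x = stats.norm.ppf(table.sum(axis=1).cumsum()[:-1] / table.sum())
    tau_y = stats.norm.ppf(table.sum(axis=0).cumsum()[:-1] / table.sum())
    grid = np.linspace(-0.999, 0.999, 4001)
    lls = [
        np.sum(table * np.log(_cell_probs(tau_x, tau_y, r))) for r in grid
    ]
    return grid[int(np.argmax(lls))]


class TestPolychoric:
    def test_identical_vectors_clamp_toward_one(self):
        x = np.array([1, 2, 2, 3, 3, 3, 4, 4, 5, 5] * 3, dtype=float)
        est = df.polychoric(x, x)
        assert est.rho >= 0.99
        assert est.converged

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(11)
        x = rng.integers(1, 6, size=2000).astype(float)
        y = rng.integers(1, 6, size=2000).astype(float)
        assert abs(df.polychoric(x, y).rho) <= 0.05

    @pytest.mark.parametrize("rho", [-0.6, 0.6])
    def test_recovers_latent_rho(self, rho):
        rng = np.random.default_rng(42)
        x, y = discretise_bivariate(rho, 2000, rng)
        assert df.polychoric(x, y).rho == pytest.approx(rho, abs=0.05)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(5)
        x, y = discretise_bivariate(0.4, 300, rng)
        assert df.polychoric(x, y).rho == pytest.approx(
            df.polychoric(y, x).rho, abs=1e-6
        )

    def test_invariant_to_increasing_relabelling(self):
        rng = np.random.default_rng(6)
        x, y = discretise_bivariate(0.5, 400, rng)
        relabel = {1: 10, 2: 20, 3: 25, 4: 40, 5: 100}
        x2 = np.vectorize(relabel.get)(x.astype(int)).astype(float)
        assert df.polychoric(x, y).rho == pytest.approx(
            df.polychoric(x2, y).rho, abs=1e-9
        )

    def test_agrees_with_tetrachoric_grid_oracle(self):
        rng = np.random.default_rng(8)
        x, y = discretise_bivariate(0.55, 500, rng, cum_probs=(0.45,))
        est = df.polychoric(x, y)
        assert est.rho == pytest.approx(tetrachoric_grid_oracle(x, y), abs=1e-3)

    def test_pearson_attenuation(self):
        rng = np.random.default_rng(9)
        x, y = discretise_bivariate(0.7, 2000, rng)
        pearson = np.corrcoef(x, y)[0, 1]
        assert abs(pearson) < abs(df.polychoric(x, y).rho)

    def test_constant_variable_rejected(self):
        with pytest.raises(DegenerateMarginalError):
            df.polychoric([3, 3, 3, 3], [1, 2, 3, 4])

    def test_low_n_warns(self):
        with pytest.warns(UserWarning, match="complete pairs"):
            est = df.polychoric([1, 2, 3, 4], [1, 2, 3, 5])
        assert est.low_n_warning

    def test_missing_pairs_dropped(self):
        x = [1, 2, 3, 4, 5, np.nan] * 4
        y = [1, 2, 3, 4, np.nan, 5] * 4
        assert df.polychoric(x, y).n == 16


class TestOrdinalAlpha:
    def test_closed_form_k3_half(self):
        m = np.full((3, 3), 0.5)
        np.fill_diagonal(m, 1.0)
        assert df.ordinal_alpha(m) == pytest.approx(0.75)

    @pytest.mark.parametrize("k", [2, 4, 7])
    def test_perfect_and_zero_homogeneity(self, k):
        ones = np.ones((k, k))
        assert df.ordinal_alpha(ones) == pytest.approx(1.0)
        assert df.ordinal_alpha(np.eye(k)) == pytest.approx(0.0)

    def test_monotone_in_rbar_and_k(self):
        def alpha(k, r):
            m = np.full((k, k), r)
            np.fill_diagonal(m, 1.0)
            return df.ordinal_alpha(m)

        rs = np.linspace(0.0, 0.95, 20)
        assert all(
            alpha(4, a) <= alpha(4, b) for a, b in zip(rs, rs[1:])
        )
        assert all(alpha(k, 0.5) <= alpha(k + 1, 0.5) for k in range(2, 10))

    def test_undefined_alpha_raises(self):
        m = np.full((3, 3), -0.6)  # r_bar below -1/(k-1)
        np.fill_diagonal(m, 1.0)
        with pytest.raises(ValueError, match="undefined"):
            df.ordinal_alpha(m)
        with pytest.raises(ValueError):
            df.ordinal_alpha(np.ones((1, 1)))


class TestInterpretation:
    @pytest.mark.parametrize(
        "alpha,band",
        [
            (0.92, "Excellent"),
            (0.9, "Excellent"),
            (0.84, "Good"),
            (0.76, "Acceptable"),
            (0.7, "Acceptable"),
            (0.65, "Questionable"),
            (0.58, "Poor"),
            (0.5, "Unacceptable"),
            (-0.2, "Unacceptable"),
        ],
    )
    def test_bands(self, alpha, band):
        assert df.interpret_alpha(alpha) == band

    def test_total_on_grid(self):
        for alpha in np.linspace(-1, 1.2, 221):
            assert df.interpret_alpha(float(alpha)) in {
                "Excellent", "Good", "Acceptable", "Questionable", "Poor",
                "Unacceptable",
            }


def contaminated_domain(n, seed, rho=0.7, bad_rho=-0.3):
    spec = df.LatentPanelSpec(
        n_panellists=n,
        domains=[("d", ["i1", "i2", "i3", "bad"])],
        within_domain_rho={"d": rho},
        contamination={"bad": bad_rho},
        thresholds={
            c: tuple(stats.norm.ppf([0.2, 0.4, 0.6, 0.8]))
            for c in ["i1", "i2", "i3", "bad"]
        },
        seed=seed,
    )
    return df.generate_responses(spec)


class TestAlphaDrop:
    def test_contaminated_item_flagged(self):
        hits = 0
        for seed in range(5):
            table = contaminated_domain(200, seed)
            drops, flagged = df.alpha_drop(table)
            full = df.ordinal_alpha(df.polychoric_matrix(table).to_numpy())
            if flagged == "bad" and drops["bad"] > full:
                hits += 1
        assert hits >= 4

    def test_exchangeable_items_have_equal_drops(self):
        m = pd.DataFrame(
            np.full((4, 4), 0.6) + np.eye(4) * 0.4,
            index=list("abcd"), columns=list("abcd"),
        )
        table = pd.DataFrame(np.ones((12, 4)), columns=list("abcd"))
        drops, flagged = df.alpha_drop(table, list("abcd"), matrix=m)
        assert drops.max() - drops.min() < 1e-9
        assert flagged is None

    def test_two_items_rejected(self):
        table = contaminated_domain(50, 0)[["i1", "i2"]]
        with pytest.raises(ValueError, match=">= 3 items"):
            df.alpha_drop(table)


class TestOrdinalReliabilityEstimator:
    def test_study_panel_summary(self, codebook, study_spec):
        table = df.generate_responses(study_spec)
        rel = df.OrdinalReliability(codebook).fit(table)
        assert set(rel.table_.index) == {"1", "2", "3", "4", "5", "6", "7"}
        # listwise deletion: complete cases never exceed the panel
        assert (rel.table_["n_replies"] <= 25).all()
        for res in rel.domains_.values():
            m = res.matrix.to_numpy()
            assert np.allclose(m, m.T)
            assert np.allclose(np.diag(m), 1.0)

    def test_contaminated_domain_drives_exclusion(self, codebook):
        # high rho elsewhere, strongly negative item in the user-type domain
        spec = df.study_panel_spec(codebook, seed=3)
        spec.n_panellists = 300
        spec.contamination = {"1.2": -0.5}
        table = df.generate_responses(spec)
        rel = df.OrdinalReliability(codebook).fit(table)
        assert rel.domains_["1"].alpha < 0.7
        assert rel.reliability_exclusions_() == ["1.2"]
        dropped = rel.domains_["1"].alpha_drop["1.2"]
        assert dropped > rel.domains_["1"].alpha
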