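import math

import numpy as np
import pandas as pd
import pytest

from civrank import (
    LOG_OR_TO_SMD,
    CorrelationSpec,
    EffectsError,
    LeagueTable,
    OutcomeEffects,
    covariance_from_league,
    or_to_smd,
    orient,
    orient_civ,
    read_outcome,
    to_smd,
)


def write_basic_csvs(tmp_path, treatments, mu, sigma):
    eff = tmp_path / "effects.csv"
    pd.DataFrame({"treatment": treatments, "effect": mu}).to_csv(eff, index=False)
    cov = tmp_path / "cov.csv"
    pd.DataFrame(sigma, index=treatments, columns=treatments).to_csv(cov)
    return eff, cov


class TestReadOutcome:
    def test_basic_form_round_trips(self, tmp_path):
        treatments = ["P", "X", "Y"]
        mu = [0.0, 0.4, -0.1]
        sigma = np.diag([0.0, 0.04, 0.09])
        eff, cov = write_basic_csvs(tmp_path, treatments, mu, sigma)
        oc = read_outcome(eff, {"name": "eff", "measure": "SMD",
                                "direction": "higher_better",
                                "reference": "P", "covariance": cov})
        assert oc.treatments == ("P", "X", "Y")
        assert oc.n_treatments == 3
        np.testing.assert_allclose(oc.mu, mu)
        np.testing.assert_allclose(oc.sigma, sigma)
        assert not oc.oriented

    def test_league_form_autodetected_and_converted(self, tmp_path):
        league = tmp_path / "league.csv"
        pd.DataFrame(
            {
                "treatment_i": ["B", "C", "C"],
                "treatment_j": ["A", "A", "B"],
                "diff": [0.5, 0.2, -0.3],
                "se": [0.2, 0.3, math.sqrt(0.11)],
            }
        ).to_csv(league, index=False)
        oc = read_outcome(league, {"name": "eff", "measure": "SMD",
                                   "direction": "higher_better",
                                   "reference": "A"})
        assert oc.treatments[0] == "A"
        np.testing.assert_allclose(oc.mu[oc.index("B")], 0.5)
        # reconstructed covariance reproduces every pairwise SE
        se = oc.pairwise_se()
        assert se[oc.index("B"), oc.index("C")] == pytest.approx(
            math.sqrt(0.11), abs=1e-10
        )

    def test_missing_reference_is_reported(self, tmp_path):
        eff, cov = write_basic_csvs(
            tmp_path, ["P", "X"], [0.0, 0.1], np.diag([0.0, 0.04])
        )
        with pytest.raises(EffectsError, match="Z"):
            read_outcome(eff, {"measure": "SMD", "direction": "higher_better",
                               "reference": "Z", "covariance": cov})

    def test_duplicate_treatments_rejected(self):
        with pytest.raises(EffectsError, match="duplicate"):
            OutcomeEffects(
                outcome_name="eff", treatments=("A", "A", "B"), reference="A",
                mu=np.zeros(3), sigma=np.zeros((3, 3)),
            )

    def test_non_psd_covariance_rejected(self):
        sigma = np.array([[0.0, 0.0, 0.0], [0.0, 0.01, 0.05], [0.0, 0.05, 0.01]])
        with pytest.raises(EffectsError, match="eigenvalue"):
            OutcomeEffects(
                outcome_name="eff", treatments=("A", "B", "C"), reference="A",
                mu=np.zeros(3), sigma=sigma,
            )


class TestLeagueTable:
    def test_both_orders_collapse_to_one_antisymmetric_row(self):
        lt = LeagueTable("eff", (("A", "B", 0.5, 0.2), ("B", "A", -0.5, 0.2)))
        assert len(lt.rows) == 1
        assert lt.diff("A", "B") == pytest.approx(0.5)
        assert lt.diff("B", "A") == pytest.approx(-0.5)
        assert lt.se("B", "A") == pytest.approx(0.2)

    def test_inconsistent_duplicate_rows_rejected(self):
        with pytest.raises(EffectsError, match="antisymmetric"):
            LeagueTable("eff", (("A", "B", 0.5, 0.2), ("B", "A", 0.5, 0.2)))
        with pytest.raises(EffectsError, match="SE"):
            LeagueTable("eff", (("A", "B", 0.5, 0.2), ("B", "A", -0.5, 0.3)))

    def test_nonpositive_se_rejected(self):
        with pytest.raises(EffectsError, match="SE"):
            LeagueTable("eff", (("A", "B", 0.5, 0.0),))


class TestCovarianceFromLeague:
    def test_two_treatments(self):
        lt = LeagueTable("eff", (("B", "A", 0.5, 0.2),))
        oc = covariance_from_league(lt, "A")
        np.testing.assert_allclose(oc.sigma, [[0.0, 0.0], [0.0, 0.04]])
        np.testing.assert_allclose(oc.mu, [0.0, 0.5])

    def test_equal_pairwise_variances_give_half_covariance(self):
        # all pairwise variances v  =>  off-diagonal covariance v/2, and the
        # pairwise-variance identity recovers every input SE
        v = 0.09
        se = math.sqrt(v)
        lt = LeagueTable(
            "eff",
            (("B", "A", 0.1, se), ("C", "A", 0.2, se), ("C", "B", 0.1, se)),
        )
        oc = covariance_from_league(lt, "A")
        b, c = oc.index("B"), oc.index("C")
        assert oc.sigma[b, c] == pytest.approx(v / 2)
        s = oc.pairwise_se()
        for i, j in ((0, b), (0, c), (b, c)):
            assert s[i, j] == pytest.approx(se, abs=1e-10)

    def test_star_geometry_gives_independent_basics(self):
        # se(i,j)^2 = se(i,R)^2 + se(j,R)^2 means the basic parameters are
        # uncorrelated
        se_br, se_cr = 0.2, 0.3
        se_bc = math.sqrt(se_br**2 + se_cr**2)
        lt = LeagueTable(
            "eff",
            (("B", "R", 0.3, se_br), ("C", "R", -0.1, se_cr),
             ("C", "B", -0.4, se_bc)),
        )
        oc = covariance_from_league(lt, "R")
        assert oc.sigma[oc.index("B"), oc.index("C")] == pytest.approx(0.0, abs=1e-12)

    def test_round_trip_reproduces_all_ses(self):
        # build a consistent league table from a known covariance, then
        # reconstruct and compare s_ij = sqrt(s_ii + s_jj - 2 s_ij)
        rng = np.random.default_rng(5)
        a = rng.normal(size=(3, 3))
        base = a @ a.T + np.eye(3)
        sigma = np.zeros((4, 4))
        sigma[1:, 1:] = 0.01 * base
        mu = np.array([0.0, 0.2, -0.1, 0.5])
        labels = ("R", "B", "C", "D")
        rows = []
        for i in range(4):
            for j in range(i + 1, 4):
                s_ij = math.sqrt(sigma[i, i] + sigma[j, j] - 2 * sigma[i, j])
                rows.append((labels[i], labels[j], mu[i] - mu[j], s_ij))
        oc = covariance_from_league(LeagueTable("eff", tuple(rows)), "R")
        got = oc.pairwise_se()
        for i in range(4):
            for j in range(i + 1, 4):
                want = math.sqrt(sigma[i, i] + sigma[j, j] - 2 * sigma[i, j])
                assert got[i, j] == pytest.approx(want, abs=1e-10)
        np.testing.assert_allclose(oc.sigma, sigma, atol=1e-10)

    def test_missing_pair_named_in_error(self):
        lt = LeagueTable("eff", (("B", "A", 0.1, 0.2), ("C", "A", 0.2, 0.2)))
        with pytest.raises(EffectsError, match="B.*C|C.*B"):
            covariance_from_league(lt, "A")

    def test_inconsistent_table_reports_smallest_eigenvalue(self):
        # variances violating the triangle-type constraint make the
        # reconstruction indefinite
        lt = LeagueTable(
            "eff",
            (("B", "A", 0.1, 0.1), ("C", "A", 0.2, 0.1), ("C", "B", 0.1, 1.0)),
        )
        with pytest.raises(EffectsError, match="eigenvalue"):
            covariance_from_league(lt, "A")


class TestOrToSmd:
    def test_point_and_se_conversion(self):
        assert or_to_smd(0.0, 0.0) == (0.0, 0.0)
        smd, _ = or_to_smd(1.0, 0.0)
        assert smd == pytest.approx(math.sqrt(3.0) / math.pi, abs=1e-12)
        _, se = or_to_smd(0.0, 2.0)
        assert se == pytest.approx(2.0 * math.sqrt(3.0) / math.pi, abs=1e-12)

    def test_linearity(self):
        a, b = 0.7, -1.3
        sa, _ = or_to_smd(a, 0.1)
        sb, _ = or_to_smd(b, 0.1)
        sab, _ = or_to_smd(a + b, 0.1)
        assert sab == pytest.approx(sa + sb, abs=1e-12)

    def test_negative_se_rejected(self):
        with pytest.raises(EffectsError):
            or_to_smd(0.1, -0.5)

    def test_outcome_level_conversion_rescales_cov_by_square(self):
        oc = OutcomeEffects(
            outcome_name="acc", treatments=("A", "B"), reference="A",
            mu=np.array([0.0, 1.0]), sigma=np.array([[0.0, 0.0], [0.0, 1.0]]),
            measure="logOR",
        )
        conv = to_smd(oc)
        assert conv.measure == "SMD"
        assert conv.mu[1] == pytest.approx(LOG_OR_TO_SMD)
        assert conv.sigma[1, 1] == pytest.approx(LOG_OR_TO_SMD**2)
        # SMD input passes through untouched
        assert to_smd(conv) is conv


class TestOrient:
    def test_higher_better_is_identity_on_mu(self, three_treatment_effects):
        oc = OutcomeEffects(
            outcome_name="eff", treatments=("A", "B"), reference="A",
            mu=np.array([0.0, 0.4]), sigma=np.diag([0.0, 0.01]),
            direction="higher_better",
        )
        oriented = orient(oc)
        np.testing.assert_array_equal(oriented.mu, oc.mu)
        assert oriented.oriented

    def test_lower_better_flips_sign_keeps_sigma(self):
        sigma = np.array([[0.0, 0.0], [0.0, 0.01]])
        oc = OutcomeEffects(
            outcome_name="harm", treatments=("A", "B"), reference="A",
            mu=np.array([0.0, -0.3]), sigma=sigma, direction="lower_better",
        )
        oriented = orient(oc)
        np.testing.assert_allclose(oriented.mu, [0.0, 0.3])
        np.testing.assert_array_equal(oriented.sigma, sigma)

    def test_double_orientation_guarded(self):
        oc = OutcomeEffects(
            outcome_name="harm", treatments=("A", "B"), reference="A",
            mu=np.array([0.0, -0.3]), sigma=np.diag([0.0, 0.01]),
            direction="lower_better",
        )
        with pytest.raises(EffectsError, match="already oriented"):
            orient(orient(oc))

    def test_civ_resigning_follows_direction(self):
        assert orient_civ(0.2, "higher_better") == 0.2
        assert orient_civ(0.2, "lower_better") == -0.2
        np.testing.assert_allclose(
            orient_civ(np.array([-0.1, 0.3]), "lower_better"), [0.1, -0.3]
        )


class TestCorrelationSpec:
    def test_valid_spec_and_submatrix(self):
        rho = np.array([[1.0, 0.5, -0.5], [0.5, 1.0, -0.5], [-0.5, -0.5, 1.0]])
        spec = CorrelationSpec(("a", "b", "c"), rho)
        sub = spec.submatrix(("c", "a"))
        np.testing.assert_allclose(sub.rho, [[1.0, -0.5], [-0.5, 1.0]])

    def test_invalid_matrices_rejected(self):
        with pytest.raises(EffectsError):
            CorrelationSpec(("a", "b"), np.array([[1.0, 0.5], [0.4, 1.0]]))
        with pytest.raises(EffectsError):
            CorrelationSpec(("a", "b"), np.array([[1.0, 1.5], [1.5, 1.0]]))
        with pytest.raises(EffectsError):  # PSD violation
            CorrelationSpec(
                ("a", "b", "c"),
                np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]]),
            )
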