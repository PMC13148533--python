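"""Analytic MLD model: single events, Laplace relation, power-law terms."""

import numpy as np
import pytest

from hgtnet.match_core import InputError
from hgtnet.hgt_model import (
    TaxonNetwork,
    TreeLengthDensity,
    count_mlds,
    count_params,
    direct_mld,
    direct_prefactor,
    example_network,
    gamma_from_rates,
    hub_mld,
    mld_from_density,
    mld_single_event,
    total_mld,
)


def loglog_slopes(r, m):
    return np.diff(np.log(m)) / np.diff(np.log(r))


class TestSingleEvent:
    def test_direct_evaluation(self):
        assert mld_single_event(1e4, 0.01, 500) == pytest.approx(np.exp(-5), rel=1e-12)

    def test_zero_tree_length(self):
        assert mld_single_event(1e4, 0.0, 123.0) == 0.0

    def test_exponential_decay_rate(self):
        tau = 3e-3
        m1 = mld_single_event(1.0, tau, 100.0)
        m2 = mld_single_event(1.0, tau, 400.0)
        assert m2 / m1 == pytest.approx(np.exp(-tau * 300), rel=1e-12)

    def test_negative_input_error(self):
        with pytest.raises(InputError):
            mld_single_event(1.0, -0.1, 10.0)


class TestLaplaceRelation:
    def test_near_delta_density_reproduces_single_event(self):
        tau0, sigma = 0.02, 1e-7
        pdf = lambda t: np.exp(-((t - tau0) ** 2) / (2 * sigma**2)) / (sigma * np.sqrt(2 * np.pi))
        P = TreeLengthDensity(pdf, support=(tau0 - 8 * sigma, tau0 + 8 * sigma))
        for r in (50.0, 500.0):
            got = mld_from_density(P, 1e4, r)
            assert got == pytest.approx(mld_single_event(1e4, tau0, r), rel=1e-6)

    def test_exponential_closed_form(self):
        lam, L = 100.0, 1e4
        P = TreeLengthDensity(lambda t: lam * np.exp(-lam * t))
        assert mld_from_density(P, L, 100.0) == pytest.approx(0.25, rel=1e-6)
        for r in (10.0, 1000.0, 5000.0):
            assert mld_from_density(P, L, r) == pytest.approx(
                2 * L * lam / (r + lam) ** 3, rel=1e-6
            )

    def test_exponential_tail_slope_is_minus_3(self):
        lam = 10.0
        P = TreeLengthDensity(lambda t: lam * np.exp(-lam * t))
        r = np.array([2e4, 4e4])
        m = np.array([mld_from_density(P, 1.0, x) for x in r])
        # residual lambda/r curvature leaves a ~1e-3 deviation at these r
        assert loglog_slopes(r, m)[0] == pytest.approx(-3.0, abs=5e-3)

    def test_unnormalized_density_rejected(self):
        with pytest.raises(InputError):
            TreeLengthDensity(lambda t: 2 * np.exp(-t))


class TestDirect:
    def test_pairwise_value(self):
        net = TaxonNetwork(taxa=("A", "B"), gamma=np.array([1.0, 1.0]), L_direct=1.0)
        assert direct_mld(net, ("A", "B"), 10.0)[0] == pytest.approx(2e-3, rel=1e-12)

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_slope_is_exactly_minus_n_plus_1(self, n):
        rng = np.random.default_rng(n)
        taxa = tuple(f"T{i}" for i in range(n))
        net = TaxonNetwork(taxa=taxa, gamma=rng.uniform(0.01, 0.1, n), L_direct=1e5)
        r = np.geomspace(1e3, 1e5, 9)
        slopes = loglog_slopes(r, direct_mld(net, taxa, r))
        assert np.allclose(slopes, -(n + 1), rtol=1e-10)

    def test_trio_unit_rates_prefactor_both_readings(self):
        rho = np.ones((3, 3))
        np.fill_diagonal(rho, 0)
        assert direct_prefactor(rho, (0, 1, 2)) == pytest.approx(12.0)
        assert direct_prefactor(rho, (0, 1, 2), reading="recipients_only") == pytest.approx(24.0)

    def test_subset_error(self):
        net = TaxonNetwork(taxa=("A", "B"), gamma=np.array([1.0, 1.0]))
        with pytest.raises(InputError):
            direct_mld(net, ("A",), 10.0)

    def test_scaling_exponent_in_gamma(self):
        # scaling all gamma by c scales the n-set direct term by c^(2(n-1))
        for n, c in [(2, 3.0), (4, 2.0)]:
            taxa = tuple(f"T{i}" for i in range(n))
            g = np.linspace(0.01, 0.05, n)
            m1 = direct_mld(TaxonNetwork(taxa=taxa, gamma=g), taxa, 100.0)[0]
            m2 = direct_mld(TaxonNetwork(taxa=taxa, gamma=c * g), taxa, 100.0)[0]
            assert m2 / m1 == pytest.approx(c ** (2 * (n - 1)), rel=1e-10)


class TestHub:
    def net(self, mode="bidirectional", g0=1.0):
        return TaxonNetwork(
            taxa=("A", "B"),
            gamma=np.array([1.0, 1.0]),
            hub_gamma=g0,
            L_hub=1.0,
            hub_mode=mode,
        )

    def test_pairwise_value(self):
        assert hub_mld(self.net(), ("A", "B"), 10.0)[0] == pytest.approx(2 / 6e4, rel=1e-12)

    def test_common_source_is_half(self):
        r = np.geomspace(10, 1e4, 5)
        bi = hub_mld(self.net("bidirectional"), ("A", "B"), r)
        cs = hub_mld(self.net("common_source"), ("A", "B"), r)
        assert np.allclose(cs, bi / 2)

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_slope_is_exactly_minus_n_plus_2(self, n):
        taxa = tuple(f"T{i}" for i in range(n))
        net = TaxonNetwork(
            taxa=taxa, gamma=np.full(n, 0.5), hub_gamma=2.0, L_hub=1e4
        )
        r = np.geomspace(1e3, 1e5, 9)
        slopes = loglog_slopes(r, hub_mld(net, taxa, r))
        assert np.allclose(slopes, -(n + 2), rtol=1e-10)

    def test_hub_gamma_power(self):
        # prefactor carries gamma_0^n
        taxa = ("A", "B", "C")
        g = np.array([0.1, 0.2, 0.3])
        m1 = hub_mld(TaxonNetwork(taxa=taxa, gamma=g, hub_gamma=1.0, L_hub=1.0), taxa, 10.0)[0]
        m2 = hub_mld(TaxonNetwork(taxa=taxa, gamma=g, hub_gamma=2.0, L_hub=1.0), taxa, 10.0)[0]
        assert m2 / m1 == pytest.approx(2**3, rel=1e-10)

    def test_no_hub_returns_zero_with_warning(self):
        net = TaxonNetwork(taxa=("A", "B"), gamma=np.array([1.0, 1.0]))
        with pytest.warns(RuntimeWarning):
            out = hub_mld(net, ("A", "B"), np.array([10.0, 100.0]))
        assert np.all(out == 0)


class TestTotal:
    def test_sum_and_hub_off(self):
        net = example_network()
        r = np.geomspace(1e3, 1e5, 20)
        curve = total_mld(net, net.taxa[:3], r)
        assert np.allclose(curve.m_total, curve.m_direct + curve.m_hub)
        no_hub = TaxonNetwork(taxa=net.taxa, gamma=net.gamma, L_direct=net.L_direct)
        curve2 = total_mld(no_hub, net.taxa[:2], r)
        assert np.allclose(curve2.m_total, curve2.m_direct)

    def test_trio_crossover_and_slope_transition(self):
        # hub term falls faster, so it dominates below the crossover r*:
        # the local slope rises monotonically from -(n+2) to -(n+1)
        net = example_network()
        s = net.taxa[:3]
        r = np.geomspace(10, 1e8, 400)
        curve = total_mld(net, s, r)
        ratio = curve.m_hub / curve.m_direct
        # unique crossover where direct = hub
        sign_changes = np.flatnonzero(np.diff(np.sign(ratio - 1)))
        assert sign_changes.size == 1
        r_star = r[sign_changes[0]]
        assert 1e3 < r_star < 1e4
        slopes = loglog_slopes(r, curve.m_total)
        assert np.all(np.diff(slopes) > 0)
        assert slopes[0] == pytest.approx(-5, abs=1e-2)
        assert slopes[-1] == pytest.approx(-4, abs=1e-2)


class TestCombinatorics:
    @pytest.mark.parametrize("n,mlds,params", [(2, 1, 5), (3, 4, 6), (8, 247, 11)])
    def test_counts(self, n, mlds, params):
        assert count_mlds(n) == mlds
        assert count_params(n) == params

    def test_invalid_n(self):
        with pytest.raises(InputError):
            count_mlds(1)
        with pytest.raises(InputError):
            count_params(1)


class TestRank1:
    @pytest.mark.parametrize("n", [3, 4, 6])
    def test_gamma_roundtrip(self, n):
        rng = np.random.default_rng(n)
        g = rng.uniform(0.01, 2.0, n)
        net = TaxonNetwork(taxa=tuple(map(str, range(n))), gamma=g)
        assert np.allclose(gamma_from_rates(net.rates()), g)

    def test_network_json_roundtrip(self, tmp_path):
        net = example_network()
        p = tmp_path / "net.json"
        net.save(p)
        back = TaxonNetwork.load(p)
        assert back.taxa == net.taxa
        assert np.allclose(back.gamma, net.gamma)
        assert back.hub_gamma == net.hub_gamma
        assert back.L_direct == net.L_direct and back.L_hub == net.L_hub

    def test_validation(self):
        with pytest.raises(InputError):
            TaxonNetwork(taxa=("A", "B"))  # neither gamma nor matrix
        with pytest.raises(InputError):
            TaxonNetwork(taxa=("A", "B"), gamma=np.array([-1.0, 1.0]))
        with pytest.raises(InputError):
            TaxonNetwork(taxa=("A", "B"), rate_matrix=np.eye(2))
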