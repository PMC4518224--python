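"""Model-specific behaviour of the bundled systems, checked against
independent scalar-reduction / closed-form oracles."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from dynamap.classify import classify
from dynamap.library import (
    MIXED_FEEDBACK_SETS,
    REGISTRY,
    get_model,
    mapk_nfb,
)
from dynamap.sampling import monte_carlo
from dynamap.steady import find_steady_states


def _goodwin_root_oracle(p):
    """Unique steady state of the Goodwin loop by bisection on the
    strictly decreasing scalar reduction g(S3) = C*H(S3) - S3."""
    C = p["k1"] * p["k2"] * p["k3"] / (p["kd1"] * p["kd2"] * p["kd3"])

    def g(s3):
        Kn = p["K"] ** p["n"]
        return C * Kn / (Kn + s3 ** p["n"]) - s3

    s3 = brentq(g, 0.0, C * 1.0000001, xtol=1e-14, rtol=1e-15)
    s2 = p["kd3"] * s3 / p["k3"]
    s1 = p["kd2"] * s2 / p["k2"]
    return np.array([s1, s2, s3])


def test_goodwin_unique_steady_state_matches_bisection(goodwin_model):
    specs = [goodwin_model.spec_for(n) for n in ("kd1", "kd2", "kd3", "K", "n")]
    ens = monte_carlo(specs, 50, seed=7)
    for pt in ens.points:
        states = find_steady_states(goodwin_model, pt)
        assert len(states) == 1
        expected = _goodwin_root_oracle(goodwin_model.params_with(pt.values))
        np.testing.assert_allclose(states[0].state, expected, rtol=1e-6, atol=1e-9)


def test_goodwin_oscillates_at_high_hill_coefficient(goodwin_model):
    # equal slow degradation rates with n=9 put the loop past its
    # instability threshold; the single steady state is unstable and a
    # simulated trajectory keeps a non-decaying oscillation amplitude
    p = goodwin_model.params_with(
        {"kd1": 0.01, "kd2": 0.01, "kd3": 0.01, "n": 9.0, "K": 1.0}
    )
    assert classify(goodwin_model, p).dynamics_class == "oscillatory"
    f = lambda t, y: goodwin_model.rhs(np.asarray(y), p)
    sol = solve_ivp(f, (0, 20000), [0.1, 0.2, 0.3], rtol=1e-8, atol=1e-10,
                    t_eval=np.linspace(10000, 20000, 800), method="LSODA")
    half = sol.y[:, :400], sol.y[:, 400:]
    amp = [w.max(axis=1) - w.min(axis=1) for w in half]
    assert np.all(amp[1] > 0.5 * amp[0])  # not decaying
    assert amp[1].max() > 0.1


def test_mapk_mm_variant_linearises_at_large_km():
    linear = mapk_nfb(())
    mm = mapk_nfb((2,))
    p_lin = linear.default_params
    km2 = 1e9
    p_mm = mm.params_with({"Km2": km2, "V2": p_lin["k2"] * km2})
    rng = np.random.default_rng(3)
    x = rng.uniform(0, 100, size=(20, 3))
    a = linear.rhs(x, p_lin)
    b = mm.rhs(x, p_mm)
    assert np.all(np.abs(a - b) <= 1e-6 * (1 + np.abs(a)))


def test_mapk_rejects_bad_mm_reaction():
    with pytest.raises(ValueError, match="subset"):
        mapk_nfb((3,))


def test_mapk_states_stay_in_conserved_box():
    model = get_model("mapk_nfb")
    p = model.default_params
    ub = model.state_upper_bounds(p)
    f = lambda t, y: model.rhs(np.asarray(y), p)
    rng = np.random.default_rng(11)
    for x0 in rng.uniform(0, ub, size=(5, 3)):
        sol = solve_ivp(f, (0, 2000), x0, rtol=1e-8, atol=1e-10, method="LSODA")
        assert np.all(sol.y >= -1e-6)
        assert np.all(sol.y.T <= ub + 1e-6)


def test_pfb_fig_defaults_bistable_with_ordered_stability(pfb_model):
    states = find_steady_states(pfb_model, {})
    assert len(states) == 3
    by_ps2 = sorted(states, key=lambda s: s.state[1])
    assert [s.stability for s in by_ps2] == ["stable", "unstable", "stable"]
    # low branch: feedback negligible, so k1*(S1t-x) = k2*x in closed form
    low = by_ps2[0]
    assert low.state[0] == pytest.approx(0.002 * 30 / 0.402, rel=1e-2)


def test_pfb_without_feedback_is_monostable(pfb_model):
    rng = np.random.default_rng(5)
    for _ in range(20):
        p = {
            "alpha": 0.0,
            "k1": 10 ** rng.uniform(-3, 0), "k2": 10 ** rng.uniform(-3, 0),
            "k3": 10 ** rng.uniform(-4, -1), "k4": 10 ** rng.uniform(-3, 0),
        }
        states = find_steady_states(pfb_model, pfb_model.params_with(p))
        assert len(states) == 1
        assert states[0].stability == "stable"


def test_mixed_feedback_published_sets_span_three_regimes(mixed_model):
    got = {
        name: classify(mixed_model, p).dynamics_class
        for name, p in MIXED_FEEDBACK_SETS.items()
    }
    assert got == {
        "oscillation": "oscillatory",
        "bistable_fixed_point": "bistable",
        "mixed_bistability": "excitable_or_mixed",
    }


def test_multisite_rates_conserve_total(multisite_model):
    # d(M + pM + ppM)/dt == 0 by construction; with M eliminated this
    # shows up as trajectories never leaking past the conserved total
    p = multisite_model.params_with({"k1": 0.5, "k4": 0.01})
    f = lambda t, y: multisite_model.rhs(np.asarray(y), p)
    sol = solve_ivp(f, (0, 5000), [10.0, 5.0], rtol=1e-9, atol=1e-11,
                    method="LSODA")
    total = sol.y.sum(axis=0)
    assert np.all(total <= p["Mt"] + 1e-6)
    assert np.all(sol.y >= -1e-9)


def test_multisite_equal_km_bistable_example():
    # beta = Km/Mt = 0.1 and k2k4/(k1k3) = 2500 >> (1+b)^2/(1-2b)^2 ~ 1.89
    model = get_model("multisite_eqkm")
    p = {"Mt": 100.0, "Km": 10.0, "Kin": 10.0, "Phos": 10.0,
         "k1": 0.02, "k2": 1.0, "k3": 0.02, "k4": 1.0}
    assert classify(model, p).dynamics_class == "bistable"


def test_multisite_reference_set_not_bistable(multisite_model):
    # the printed reference set has beta = Km/Mt = 1 > 1/2: the necessary
    # condition fails and enumeration finds a single stable state
    c = classify(multisite_model, {})
    assert c.dynamics_class == "monostable"


def test_hopf_fixture_closed_form():
    model = get_model("hopf")
    for mu, expected in [(-0.5, "monostable"), (0.5, "oscillatory")]:
        c = classify(model, {"mu": mu, "omega": 1.0})
        assert c.dynamics_class == expected
        assert len(c.steady_states) == 1
        np.testing.assert_allclose(c.steady_states[0].state, [0, 0], atol=1e-8)
        eig = np.sort_complex(c.steady_states[0].eigenvalues)
        np.testing.assert_allclose(eig, [mu - 1j, mu + 1j], atol=1e-7)


def test_hopf_fixture_marginal_at_zero_growth():
    c = classify(get_model("hopf"), {"mu": 0.0, "omega": 1.0})
    assert c.dynamics_class == "undetermined"


def test_registry_contains_all_bundled_models():
    assert set(REGISTRY) == {
        "goodwin", "mapk_nfb", "mapk_nfb_mm2", "mapk_nfb_mm246",
        "pfb2", "mixed", "multisite", "multisite_eqkm", "hopf",
    }
    with pytest.raises(KeyError, match="unknown model"):
        get_model("nope")
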