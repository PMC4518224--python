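"""Bundled ODE models: negative-feedback Goodwin oscillator, MAPK cascade
with negative feedback (first-order or Michaelis–Menten dephosphorylation),
two-layer positive-feedback cascade, three-layer mixed-feedback cascade,
dual-site phosphorylation cycle, and a Hopf normal-form fixture.

All models are written with conservation laws pre-substituted: the ODE state
holds only the phosphorylated/free forms and conserved totals are
parameters. Right-hand sides and Jacobians are vectorised over leading axes
of the state array. Default parameter values come from the published
figure parameterisations where available; default sampling ranges are
documented per model and overridable at run time.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

from .core import OdeModel, ParameterSpec

__all__ = [
    "MIXED_FEEDBACK_SETS",
    "REGISTRY",
    "get_model",
    "goodwin",
    "hopf_fixture",
    "list_models",
    "mapk_nfb",
    "mixed_feedback",
    "multisite",
    "pfb_two_layer",
]


# --- Hill kinetics helpers (vectorised; n may be an integer-valued float) ---

def _hill_rep(x, K, n):
    """Repressive Hill term K^n / (K^n + x^n)."""
    Kn = K**n
    return Kn / (Kn + x**n)


def _d_hill_rep(x, K, n):
    Kn = K**n
    return -Kn * n * x ** (n - 1) / (Kn + x**n) ** 2


def _hill_act(x, K, n):
    """Activating Hill term x^n / (K^n + x^n)."""
    xn = x**n
    return xn / (K**n + xn)


def _d_hill_act(x, K, n):
    Kn = K**n
    return Kn * n * x ** (n - 1) / (Kn + x**n) ** 2


def _spec(name, low, high, scale="log", integer=False):
    return ParameterSpec(name, low, high, scale=scale, integer=integer)


# ---------------------------------------------------------------------------
# Goodwin negative-feedback loop
# ---------------------------------------------------------------------------

def goodwin() -> OdeModel:
    """Three-species Goodwin loop: S1 -> S2 -> S3 --| S1.

    dS1/dt = k1*K^n/(K^n + S3^n) - kd1*S1
    dS2/dt = k2*S1 - kd2*S2
    dS3/dt = k3*S2 - kd3*S3

    Synthesis and degradation are first order; the end product S3
    represses S1 synthesis through a Hill function with threshold K and
    coefficient n (sampled as an integer). The constant input species is
    absorbed into k1. For any positive parameters the system has a unique
    steady state; sustained oscillation requires high n (the classical
    secant condition gives n > 8 for a three-stage loop).
    """

    def rhs(x, p):
        s1, s2, s3 = x[..., 0], x[..., 1], x[..., 2]
        return np.stack(
            [
                p["k1"] * _hill_rep(s3, p["K"], p["n"]) - p["kd1"] * s1,
                p["k2"] * s1 - p["kd2"] * s2,
                p["k3"] * s2 - p["kd3"] * s3,
            ],
            axis=-1,
        )

    def jac(x, p):
        s3 = x[..., 2]
        J = np.zeros(x.shape[:-1] + (3, 3))
        J[..., 0, 0] = -p["kd1"]
        J[..., 0, 2] = p["k1"] * _d_hill_rep(s3, p["K"], p["n"])
        J[..., 1, 0] = p["k2"]
        J[..., 1, 1] = -p["kd2"]
        J[..., 2, 1] = p["k3"]
        J[..., 2, 2] = -p["kd3"]
        return J

    def bounds(p):
        # Cascade of bounded-synthesis stages: dS1 <= k1 - kd1*S1, etc.
        b1 = p["k1"] / p["kd1"]
        b2 = p["k2"] * b1 / p["kd2"]
        b3 = p["k3"] * b2 / p["kd3"]
        return np.array([b1, b2, b3])

    defaults = {
        "k1": 0.1, "k2": 0.1, "k3": 0.1,
        "kd1": 0.01, "kd2": 0.01, "kd3": 0.01,
        "K": 1.0, "n": 9.0,
    }
    specs = (
        _spec("k1", 1e-3, 1.0), _spec("k2", 1e-3, 1.0), _spec("k3", 1e-3, 1.0),
        _spec("kd1", 1e-3, 1e-1), _spec("kd2", 1e-3, 1e-1), _spec("kd3", 1e-3, 1e-1),
        _spec("K", 1e-2, 1e1),
        _spec("n", 1, 12, scale="linear", integer=True),
    )
    return OdeModel(
        name="goodwin",
        state_names=("S1", "S2", "S3"),
        param_names=tuple(defaults),
        rhs=rhs,
        jacobian=jac,
        state_upper_bounds=bounds,
        default_params=defaults,
        default_specs=specs,
    )


# ---------------------------------------------------------------------------
# Three-tier MAPK cascade with negative feedback
# ---------------------------------------------------------------------------

def mapk_nfb(mm_reactions: Iterable[int] = ()) -> OdeModel:
    """Three-tier phosphorylation cascade; output pS3 feeds back on level 1.

    States are the phosphorylated forms (pS1, pS2, pS3); totals S1t..S3t are
    parameters (conservation pre-substituted):

    d(pS1)/dt = k1*(S1t-pS1)*K1^n1/(K1^n1 + pS3^n1) - D2(pS1)
    d(pS2)/dt = k3*pS1*(S2t-pS2) - D4(pS2)
    d(pS3)/dt = k5*pS2*(S3t-pS3) - D6(pS3)

    Dephosphorylation D_i is first order, ``k_i * x``, unless reaction i is
    listed in ``mm_reactions`` (subset of {2, 4, 6}), in which case it is
    Michaelis–Menten, ``V_i * x / (Km_i + x)``, introducing saturation as an
    extra nonlinearity source. Maximal rates V_i are independent parameters.
    """
    mm = frozenset(int(i) for i in mm_reactions)
    if not mm <= {2, 4, 6}:
        raise ValueError(f"mm_reactions must be a subset of {{2, 4, 6}}, got {sorted(mm)}")

    def dephos(i, x, p):
        if i in mm:
            return p[f"V{i}"] * x / (p[f"Km{i}"] + x)
        return p[f"k{i}"] * x

    def d_dephos(i, x, p):
        if i in mm:
            return p[f"V{i}"] * p[f"Km{i}"] / (p[f"Km{i}"] + x) ** 2
        return np.broadcast_to(np.float64(p[f"k{i}"]), np.shape(x))

    def rhs(x, p):
        ps1, ps2, ps3 = x[..., 0], x[..., 1], x[..., 2]
        fb = _hill_rep(ps3, p["K1"], p["n1"])
        return np.stack(
            [
                p["k1"] * (p["S1t"] - ps1) * fb - dephos(2, ps1, p),
                p["k3"] * ps1 * (p["S2t"] - ps2) - dephos(4, ps2, p),
                p["k5"] * ps2 * (p["S3t"] - ps3) - dephos(6, ps3, p),
            ],
            axis=-1,
        )

    def jac(x, p):
        ps1, ps2, ps3 = x[..., 0], x[..., 1], x[..., 2]
        fb = _hill_rep(ps3, p["K1"], p["n1"])
        J = np.zeros(x.shape[:-1] + (3, 3))
        J[..., 0, 0] = -p["k1"] * fb - d_dephos(2, ps1, p)
        J[..., 0, 2] = p["k1"] * (p["S1t"] - ps1) * _d_hill_rep(ps3, p["K1"], p["n1"])
        J[..., 1, 0] = p["k3"] * (p["S2t"] - ps2)
        J[..., 1, 1] = -p["k3"] * ps1 - d_dephos(4, ps2, p)
        J[..., 2, 1] = p["k5"] * (p["S3t"] - ps3)
        J[..., 2, 2] = -p["k5"] * ps2 - d_dephos(6, ps3, p)
        return J

    def bounds(p):
        return np.array([p["S1t"], p["S2t"], p["S3t"]])

    defaults: dict[str, float] = {
        "k1": 0.01, "k3": 0.01, "k5": 0.01,
        "S1t": 100.0, "S2t": 100.0, "S3t": 100.0,
        "K1": 10.0, "n1": 10.0,
    }
    specs = [
        _spec("k1", 1e-4, 1e-1), _spec("k3", 1e-4, 1e-1), _spec("k5", 1e-4, 1e-1),
        _spec("S1t", 1, 100, scale="linear"),
        _spec("S2t", 1, 100, scale="linear"),
        _spec("S3t", 1, 100, scale="linear"),
        _spec("K1", 1e-2, 1e2),
        _spec("n1", 1, 12, scale="linear", integer=True),
    ]
    for i in (2, 4, 6):
        if i in mm:
            defaults[f"V{i}"] = 10.0
            defaults[f"Km{i}"] = 50.0
            specs.append(_spec(f"V{i}", 1e-1, 1e2))
            specs.append(_spec(f"Km{i}", 1e-2, 1e3))
        else:
            defaults[f"k{i}"] = 0.1
            specs.append(_spec(f"k{i}", 1e-3, 1.0))

    suffix = "" if not mm else "_mm" + "".join(str(i) for i in sorted(mm))
    return OdeModel(
        name=f"mapk_nfb{suffix}",
        state_names=("pS1", "pS2", "pS3"),
        param_names=tuple(defaults),
        rhs=rhs,
        jacobian=jac,
        state_upper_bounds=bounds,
        default_params=defaults,
        default_specs=tuple(specs),
    )


# ---------------------------------------------------------------------------
# Two-layer cascade with positive feedback
# ---------------------------------------------------------------------------

def pfb_two_layer() -> OdeModel:
    """Two-tier cascade in which the output pS2 activates level-1
    phosphorylation through an additive Hill term:

    d(pS1)/dt = (k1 + alpha*pS2^n/(K^n + pS2^n))*(S1t - pS1) - k2*pS1
    d(pS2)/dt = k3*pS1*(S2t - pS2) - k4*pS2

    alpha, n and K are the feedback strength, nonlinearity level and
    activation threshold. Lacking negative feedback the cascade cannot
    oscillate; its characteristic regimes are monostable and bistable.
    Defaults are the published bistable parameterisation.
    """

    def rhs(x, p):
        ps1, ps2 = x[..., 0], x[..., 1]
        act = p["k1"] + p["alpha"] * _hill_act(ps2, p["K"], p["n"])
        return np.stack(
            [
                act * (p["S1t"] - ps1) - p["k2"] * ps1,
                p["k3"] * ps1 * (p["S2t"] - ps2) - p["k4"] * ps2,
            ],
            axis=-1,
        )

    def jac(x, p):
        ps1, ps2 = x[..., 0], x[..., 1]
        act = p["k1"] + p["alpha"] * _hill_act(ps2, p["K"], p["n"])
        J = np.zeros(x.shape[:-1] + (2, 2))
        J[..., 0, 0] = -act - p["k2"]
        J[..., 0, 1] = p["alpha"] * _d_hill_act(ps2, p["K"], p["n"]) * (p["S1t"] - ps1)
        J[..., 1, 0] = p["k3"] * (p["S2t"] - ps2)
        J[..., 1, 1] = -p["k3"] * ps1 - p["k4"]
        return J

    def bounds(p):
        return np.array([p["S1t"], p["S2t"]])

    defaults = {
        "S1t": 30.0, "S2t": 45.0,
        "k1": 0.002, "k2": 0.4, "k3": 0.005, "k4": 0.04,
        "n": 10.0, "K": 7.0, "alpha": 5.0,
    }
    specs = (
        _spec("k1", 1e-3, 1.0), _spec("k2", 1e-3, 1.0),
        _spec("k3", 1e-4, 1e-1), _spec("k4", 1e-3, 1.0),
        _spec("S1t", 1, 100, scale="linear"), _spec("S2t", 1, 100, scale="linear"),
        _spec("alpha", 0, 100, scale="linear"),
        _spec("K", 1e-1, 1e2),
        _spec("n", 1, 12, scale="linear", integer=True),
    )
    return OdeModel(
        name="pfb2",
        state_names=("pS1", "pS2"),
        param_names=tuple(defaults),
        rhs=rhs,
        jacobian=jac,
        state_upper_bounds=bounds,
        default_params=defaults,
        default_specs=specs,
    )


# ---------------------------------------------------------------------------
# Three-tier cascade with mixed negative + positive feedback
# ---------------------------------------------------------------------------

#: Published parameterisations of the mixed-feedback cascade, one per
#: dynamic regime it displays.
MIXED_FEEDBACK_SETS: dict[str, dict[str, float]] = {
    "oscillation": {
        "S1t": 100.0, "S2t": 100.0, "S3t": 100.0,
        "k1": 0.1, "k2": 0.01, "k3": 0.01, "k4": 0.01, "k5": 0.01, "k6": 0.01,
        "n1": 10.0, "K1": 1.0, "n2": 15.0, "K2": 8.0, "alpha": 10.0,
    },
    "bistable_fixed_point": {
        "S1t": 0.22, "S2t": 10.0, "S3t": 53.0,
        "k1": 0.0012, "k2": 0.006, "k3": 0.049, "k4": 0.084,
        "k5": 0.043, "k6": 0.066,
        "n1": 5.0, "K1": 9.5, "n2": 10.0, "K2": 15.0, "alpha": 95.0,
    },
    "mixed_bistability": {
        "S1t": 20.0, "S2t": 50.0, "S3t": 30.0,
        "k1": 0.001, "k2": 0.08, "k3": 0.001, "k4": 0.08,
        "k5": 0.001, "k6": 0.05,
        "n1": 10.0, "K1": 0.66, "n2": 5.0, "K2": 0.8, "alpha": 96.0,
    },
}


def mixed_feedback() -> OdeModel:
    """Three-tier cascade under opposing feedbacks: the output pS3
    represses level-1 phosphorylation (negative loop, threshold K1,
    coefficient n1) and amplifies level-2 phosphorylation multiplicatively
    (positive loop, strength alpha, threshold K2, coefficient n2):

    d(pS1)/dt = k1*(S1t-pS1)*K1^n1/(K1^n1 + pS3^n1) - k2*pS1
    d(pS2)/dt = k3*(1 + alpha*pS3^n2/(K2^n2 + pS3^n2))*pS1*(S2t-pS2) - k4*pS2
    d(pS3)/dt = k5*pS2*(S3t-pS3) - k6*pS3

    The multiplicative gain form is the one that reproduces all three
    published regime parameterisations (unique unstable state for the
    oscillatory set; 2 stable + 1 unstable for the bistable set; 1 stable
    + 2 unstable for the mixed set); an additive form does not.

    Depending on parameters the cascade is monostable, oscillatory,
    bistable, or shows mixed fixed-point/limit-cycle coexistence. The three
    published regime parameterisations are in :data:`MIXED_FEEDBACK_SETS`;
    defaults are the oscillatory set.
    """

    def rhs(x, p):
        ps1, ps2, ps3 = x[..., 0], x[..., 1], x[..., 2]
        neg = _hill_rep(ps3, p["K1"], p["n1"])
        pos = p["k3"] * (1.0 + p["alpha"] * _hill_act(ps3, p["K2"], p["n2"]))
        return np.stack(
            [
                p["k1"] * (p["S1t"] - ps1) * neg - p["k2"] * ps1,
                pos * ps1 * (p["S2t"] - ps2) - p["k4"] * ps2,
                p["k5"] * ps2 * (p["S3t"] - ps3) - p["k6"] * ps3,
            ],
            axis=-1,
        )

    def jac(x, p):
        ps1, ps2, ps3 = x[..., 0], x[..., 1], x[..., 2]
        neg = _hill_rep(ps3, p["K1"], p["n1"])
        pos = p["k3"] * (1.0 + p["alpha"] * _hill_act(ps3, p["K2"], p["n2"]))
        J = np.zeros(x.shape[:-1] + (3, 3))
        J[..., 0, 0] = -p["k1"] * neg - p["k2"]
        J[..., 0, 2] = p["k1"] * (p["S1t"] - ps1) * _d_hill_rep(ps3, p["K1"], p["n1"])
        J[..., 1, 0] = pos * (p["S2t"] - ps2)
        J[..., 1, 1] = -pos * ps1 - p["k4"]
        J[..., 1, 2] = (
            p["k3"] * p["alpha"] * _d_hill_act(ps3, p["K2"], p["n2"])
            * ps1 * (p["S2t"] - ps2)
        )
        J[..., 2, 1] = p["k5"] * (p["S3t"] - ps3)
        J[..., 2, 2] = -p["k5"] * ps2 - p["k6"]
        return J

    def bounds(p):
        return np.array([p["S1t"], p["S2t"], p["S3t"]])

    defaults = dict(MIXED_FEEDBACK_SETS["oscillation"])
    specs = (
        _spec("k1", 1e-4, 1e-1), _spec("k3", 1e-4, 1e-1), _spec("k5", 1e-4, 1e-1),
        _spec("k2", 1e-3, 1.0), _spec("k4", 1e-3, 1.0), _spec("k6", 1e-3, 1.0),
        _spec("S1t", 1, 100, scale="linear"),
        _spec("S2t", 1, 100, scale="linear"),
        _spec("S3t", 1, 100, scale="linear"),
        _spec("K1", 1e-2, 1e2), _spec("K2", 1e-2, 1e2),
        _spec("alpha", 0, 100, scale="linear"),
        _spec("n1", 1, 12, scale="linear", integer=True),
        _spec("n2", 1, 12, scale="linear", integer=True),
    )
    return OdeModel(
        name="mixed",
        state_names=("pS1", "pS2", "pS3"),
        param_names=tuple(defaults),
        rhs=rhs,
        jacobian=jac,
        state_upper_bounds=bounds,
        default_params=defaults,
        default_specs=specs,
    )


# ---------------------------------------------------------------------------
# Dual-site phosphorylation cycle (shared kinase / shared phosphatase)
# ---------------------------------------------------------------------------

def multisite(equal_km: bool = False) -> OdeModel:
    """Two sequential phosphorylation sites on substrate M: steps 1 and 2
    (M -> pM -> ppM) are catalysed by a common kinase Kin, steps 3 and 4
    (ppM -> pM -> M) by a common phosphatase Phos. Under the quasi
    steady-state assumption with competition for the shared enzymes the
    rate laws are

    v1 = k1*Kin*(M/Km1)  / (1 + M/Km1 + pM/Km2)
    v2 = k2*Kin*(pM/Km2) / (1 + M/Km1 + pM/Km2)
    v3 = k3*Phos*(ppM/Km3) / (1 + ppM/Km3 + pM/Km4)
    v4 = k4*Phos*(pM/Km4)  / (1 + ppM/Km3 + pM/Km4)

    with M = Mt - pM - ppM, and the ODEs d(pM)/dt = v1 - v2 + v3 - v4,
    d(ppM)/dt = v2 - v3. Substrate competition alone can create bistability
    without explicit positive feedback; under the equal-Km simplification
    (``equal_km=True``, single parameter Km) bistability requires
    beta = Km/Mt < 1/2 and k2*k4/(k1*k3) > (1+beta)^2 / (1-2*beta)^2.
    """

    def km(p, i):
        return p["Km"] if equal_km else p[f"Km{i}"]

    def rhs(x, p):
        pm, ppm = x[..., 0], x[..., 1]
        m = p["Mt"] - pm - ppm
        dk = 1.0 + m / km(p, 1) + pm / km(p, 2)
        dp_ = 1.0 + ppm / km(p, 3) + pm / km(p, 4)
        v1 = p["k1"] * p["Kin"] * (m / km(p, 1)) / dk
        v2 = p["k2"] * p["Kin"] * (pm / km(p, 2)) / dk
        v3 = p["k3"] * p["Phos"] * (ppm / km(p, 3)) / dp_
        v4 = p["k4"] * p["Phos"] * (pm / km(p, 4)) / dp_
        return np.stack([v1 - v2 + v3 - v4, v2 - v3], axis=-1)

    def jac(x, p):
        pm, ppm = x[..., 0], x[..., 1]
        km1, km2, km3, km4 = (km(p, i) for i in (1, 2, 3, 4))
        m = p["Mt"] - pm - ppm
        u1, u2 = m / km1, pm / km2          # kinase site occupancies
        w3, w4 = ppm / km3, pm / km4        # phosphatase site occupancies
        dk = 1.0 + u1 + u2
        dp_ = 1.0 + w3 + w4
        a1 = p["k1"] * p["Kin"]
        a2 = p["k2"] * p["Kin"]
        a3 = p["k3"] * p["Phos"]
        a4 = p["k4"] * p["Phos"]
        # partials of the occupancies: dM/dpm = dM/dppm = -1
        u1_x, u1_y = -1.0 / km1, -1.0 / km1
        u2_x, u2_y = 1.0 / km2, 0.0
        dk_x, dk_y = u1_x + u2_x, u1_y
        dp_x, dp_y = 1.0 / km4, 1.0 / km3
        v1_x = a1 * (u1_x * dk - u1 * dk_x) / dk**2
        v1_y = a1 * (u1_y * dk - u1 * dk_y) / dk**2
        v2_x = a2 * (u2_x * dk - u2 * dk_x) / dk**2
        v2_y = a2 * (0.0 - u2 * dk_y) / dk**2
        v3_x = a3 * (0.0 - w3 * dp_x) / dp_**2
        v3_y = a3 * ((1.0 / km3) * dp_ - w3 * dp_y) / dp_**2
        v4_x = a4 * ((1.0 / km4) * dp_ - w4 * dp_x) / dp_**2
        v4_y = a4 * (0.0 - w4 * dp_y) / dp_**2
        J = np.zeros(x.shape[:-1] + (2, 2))
        J[..., 0, 0] = v1_x - v2_x + v3_x - v4_x
        J[..., 0, 1] = v1_y - v2_y + v3_y - v4_y
        J[..., 1, 0] = v2_x - v3_x
        J[..., 1, 1] = v2_y - v3_y
        return J

    def bounds(p):
        return np.array([p["Mt"], p["Mt"]])

    defaults: dict[str, float] = {
        "Mt": 100.0, "Kin": 10.0, "Phos": 10.0,
        "k1": 0.01, "k2": 1.0, "k3": 0.084, "k4": 0.06,
    }
    specs = [
        _spec("k1", 1e-3, 1e1), _spec("k2", 1e-3, 1e1),
        _spec("k3", 1e-3, 1e1), _spec("k4", 1e-3, 1e1),
        _spec("Mt", 10, 500, scale="linear"),
        _spec("Kin", 1, 100, scale="linear"),
        _spec("Phos", 1, 100, scale="linear"),
    ]
    if equal_km:
        defaults["Km"] = 100.0
        specs.append(_spec("Km", 1, 1e3))
    else:
        for i in (1, 2, 3, 4):
            defaults[f"Km{i}"] = 100.0
            specs.append(_spec(f"Km{i}", 1, 1e3))

    return OdeModel(
        name="multisite_eqkm" if equal_km else "multisite",
        state_names=("pM", "ppM"),
        param_names=tuple(defaults),
        rhs=rhs,
        jacobian=jac,
        state_upper_bounds=bounds,
        default_params=defaults,
        default_specs=tuple(specs),
    )


# ---------------------------------------------------------------------------
# Hopf normal-form fixture (analytic oracle for the classifier)
# ---------------------------------------------------------------------------

def hopf_fixture(mu: float = 0.5, omega: float = 1.0) -> OdeModel:
    """Supercritical Hopf normal form,

    dx/dt = mu*x - omega*y - x*(x^2 + y^2)
    dy/dt = omega*x + mu*y - y*(x^2 + y^2).

    The origin is the unique steady state with eigenvalues mu ± i*omega;
    for mu > 0 a stable limit cycle of radius sqrt(mu) exists. Used as a
    closed-form oracle for the classifier and the simulation-based
    attractor detector.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")

    def rhs(x, p):
        u, v = x[..., 0], x[..., 1]
        r2 = u**2 + v**2
        return np.stack(
            [p["mu"] * u - p["omega"] * v - u * r2,
             p["omega"] * u + p["mu"] * v - v * r2],
            axis=-1,
        )

    def jac(x, p):
        u, v = x[..., 0], x[..., 1]
        J = np.zeros(x.shape[:-1] + (2, 2))
        J[..., 0, 0] = p["mu"] - (3 * u**2 + v**2)
        J[..., 0, 1] = -p["omega"] - 2 * u * v
        J[..., 1, 0] = p["omega"] - 2 * u * v
        J[..., 1, 1] = p["mu"] - (u**2 + 3 * v**2)
        return J

    def bounds(p):
        r = np.sqrt(max(p["mu"], 0.0))
        return np.full(2, max(1.0, 2.0 * r))

    defaults = {"mu": float(mu), "omega": float(omega)}
    specs = (
        ParameterSpec("mu", -1.0, 1.0, scale="linear"),
        ParameterSpec("omega", 0.1, 10.0, scale="log"),
    )
    return OdeModel(
        name="hopf",
        state_names=("x", "y"),
        param_names=("mu", "omega"),
        rhs=rhs,
        jacobian=jac,
        state_upper_bounds=bounds,
        default_params=defaults,
        default_specs=specs,
    )


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

REGISTRY: dict[str, Callable[[], OdeModel]] = {
    "goodwin": goodwin,
    "mapk_nfb": mapk_nfb,
    "mapk_nfb_mm2": lambda: mapk_nfb((2,)),
    "mapk_nfb_mm246": lambda: mapk_nfb((2, 4, 6)),
    "pfb2": pfb_two_layer,
    "mixed": mixed_feedback,
    "multisite": multisite,
    "multisite_eqkm": lambda: multisite(equal_km=True),
    "hopf": hopf_fixture,
}


def get_model(name: str) -> OdeModel:
    """Instantiate a bundled model by registry name."""
    try:
        return REGISTRY[name]()
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {', '.join(sorted(REGISTRY))}"
        ) from None


def list_models() -> list[dict[str, object]]:
    """Registry listing: name, state/parameter counts, default specs."""
    rows = []
    for name in REGISTRY:
        m = REGISTRY[name]()
        rows.append(
            {
                "name": name,
                "n_states": m.n_states,
                "n_params": len(m.param_names),
                "states": list(m.state_names),
                "params": list(m.param_names),
                "default_specs": [
                    {"name": s.name, "low": s.low, "high": s.high,
                     "scale": s.scale, "integer": s.integer}
                    for s in m.default_specs
                ],
            }
        )
    return rows
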