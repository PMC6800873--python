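"""ODE builders against closed-form survival oracles and hand-coded systems."""

import math

import numpy as np
import pytest

from glct import (CompetingDist, ErlangParams, EventTimeDist,
                  IntermediateSpec, MixtureDist, RateFunction, RecipientSpec,
                  ValidationError, build_competing, build_extended_chain,
                  build_glct, build_intermediate_preserve,
                  build_intermediate_reset, build_lct_chain, build_max,
                  build_mixture, build_proportional_outputs, build_series,
                  competing_survival, erlang_survival,
                  evaluate_recipient_integral, glct_from_phasetype, integrate,
                  mixture_survival, nhpp_event_survival, rate_sum,
                  survival_from_model, to_generator)
from glct.builders import GLCTModel
from conftest import random_rate_routing

GRID = np.linspace(0.0, 15.0, 301)


def sup_survival_error(sys, oracle, grid=GRID):
    s, _ = survival_from_model(sys, grid)
    return float(np.max(np.abs(s - oracle(grid))))


class TestGLCTCore:
    def test_single_state_is_loss_equation(self):
        """n=1, constant rate: dx/dt = I(t) - r x, solved in closed form."""
        r = 0.8
        model = GLCTModel.from_arrays(
            ["X"], inflows=lambda t: np.array([1.0]),
            rates=[r], within=np.zeros((1, 1)), exit=np.ones((1, 1)),
            recipients=[RecipientSpec.sink("Y")])
        sys = build_glct(model)
        t = np.linspace(0, 10, 101)
        traj = integrate(sys, 10, t, rtol=1e-11, atol=1e-13)
        closed = (1.0 / r) * (1 - np.exp(-r * t))
        assert np.max(np.abs(traj.states[:, 0] - closed)) < 1e-8

    def test_zero_rates_pure_accumulation(self):
        model = GLCTModel.from_arrays(
            ["X1", "X2"], inflows=lambda t: np.array([0.5, 0.25]),
            rates=[0.0, 0.0], within=np.eye(2),
            exit=np.zeros((2, 0)), recipients=[])
        sys = build_glct(model)
        t = np.linspace(0, 4, 41)
        traj = integrate(sys, 4, t)
        assert np.allclose(traj.states[:, 0], 0.5 * t, atol=1e-8)
        assert np.allclose(traj.states[:, 1], 0.25 * t, atol=1e-8)

    def test_rhs_matches_generator_form(self, rng):
        """Constant parameters: RHS on the X block equals I + G_X^T x."""
        for _ in range(10):
            n = int(rng.integers(1, 6))
            m = int(rng.integers(1, 3))
            rrr = random_rate_routing(n, m, rng)
            g = to_generator(rrr)
            model = glct_from_phasetype(g, inflow=lambda t: 1.0 + 0.3 * t)
            sys = build_glct(model)
            for t in (0.0, 1.3):
                x = rng.uniform(size=sys.dim)
                lhs = sys.rhs(t, x)[:n]
                rhs = g.initial * (1.0 + 0.3 * t) + g.subgenerator.T @ x[:n]
                assert np.allclose(lhs, rhs, atol=1e-12)

    def test_bad_row_sums_rejected(self):
        model = GLCTModel.from_arrays(
            ["X"], inflows=np.zeros(1), rates=[1.0],
            within=np.array([[0.2]]), exit=np.array([[0.5]]),
            recipients=[RecipientSpec.sink("Y")])
        with pytest.raises(ValidationError, match="row"):
            build_glct(model)

    def test_mass_conservation_closed_model(self, rng):
        """With absorbing recipients, d/dt(total) = external inflow."""
        rrr = random_rate_routing(4, 2, rng)
        g = to_generator(rrr)
        model = glct_from_phasetype(g, inflow=0.7)
        sys = build_glct(model)
        t = np.linspace(0, 8, 81)
        traj = integrate(sys, 8, t, rtol=1e-11, atol=1e-13)
        total = traj.observables["total"]
        assert np.max(np.abs(total - 0.7 * t)) < 1e-8


class TestChains:
    @pytest.mark.parametrize("r,k", [(1.0, 1), (1.0, 5), (2.0, 3)])
    def test_chain_survival_identity(self, r, k):
        sys = build_lct_chain(ErlangParams(r, k))
        grid = np.linspace(0, (k + 8 * math.sqrt(k)) / r, 200)
        err = sup_survival_error(
            sys, lambda t: erlang_survival(ErlangParams(r, k), t), grid)
        assert err < 1e-6

    def test_chain_density_identity(self):
        p = ErlangParams(1.0, 5)
        sys = build_lct_chain(p)
        _, dens = survival_from_model(sys, GRID)
        from glct import erlang_pdf
        assert np.max(np.abs(dens - erlang_pdf(p, GRID))) < 1e-6

    def test_time_varying_chain_matches_quadrature_oracle(self):
        d = EventTimeDist(RateFunction.sinusoidal(1.0, 0.5), 3)
        sys = build_extended_chain(d)
        dq = EventTimeDist(RateFunction.from_callable(
            lambda t: 1.0 + 0.5 * math.sin(t)), 3)
        err = sup_survival_error(
            sys, lambda ts: np.array([nhpp_event_survival(dq, t)
                                      for t in ts]))
        assert err < 1e-6

    def test_constant_rate_extended_equals_simple(self):
        p = ErlangParams(1.4, 4)
        s1 = build_lct_chain(p)
        s2 = build_extended_chain(p.to_event_time())
        t = np.linspace(0, 10, 51)
        a, _ = survival_from_model(s1, t)
        b, _ = survival_from_model(s2, t)
        assert np.allclose(a, b, atol=1e-12)

    def test_zero_rate_interval_freezes_states(self):
        rate = RateFunction.piecewise_linear([0, 1, 2, 3], [1, 0, 0, 1])
        sys = build_extended_chain(EventTimeDist(rate, 2))
        x = np.array([0.3, 0.5, 0.0])
        assert np.allclose(sys.flow(1.5, x), 0.0, atol=1e-12)


class TestProportionalOutputs:
    def test_structure_matches_hand_equations(self):
        """Two recipients with exponential dwell: probe the full RHS."""
        r, k, p, muY, muZ = 1.3, 3, 0.4, 0.6, 0.9
        recs = [RecipientSpec.exponential("Y", muY),
                RecipientSpec.exponential("Z", muZ)]
        sys = build_proportional_outputs(
            ErlangParams(r, k).to_event_time(), 2.0, [p, 1 - p], recs)
        x = np.array([0.5, 0.3, 0.2, 0.7, 0.4])
        dx = sys.rhs(0.0, x)
        hand = np.array([
            2.0 - r * x[0],
            r * x[0] - r * x[1],
            r * x[1] - r * x[2],
            p * r * x[2] - muY * x[3],
            (1 - p) * r * x[2] - muZ * x[4],
        ])
        assert np.allclose(dx, hand, atol=1e-14)

    def test_recipient_influx_sums_to_exit_flow(self):
        sys = build_proportional_outputs(
            ErlangParams(1.0, 2).to_event_time(), 0.0, [0.3, 0.7],
            [RecipientSpec.sink("Y"), RecipientSpec.sink("Z")])
        x = np.array([0.2, 0.6, 0.0, 0.0])
        total = sum(sys.recipient_influx[l](1.0, x) for l in ("Y", "Z"))
        assert total == pytest.approx(1.0 * x[1], rel=1e-12)

    def test_probs_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            build_proportional_outputs(
                ErlangParams(1.0, 2).to_event_time(), 0.0, [0.3, 0.6],
                [RecipientSpec.sink("Y"), RecipientSpec.sink("Z")])


class TestMixture:
    MIX = MixtureDist((0.3, 0.2, 0.5),
                      (ErlangParams(1.0, 2).to_event_time(),
                       ErlangParams(2.0, 1).to_event_time(),
                       ErlangParams(0.5, 3).to_event_time()))

    def test_impulse_survival_matches_mixture(self):
        routing = np.ones((3, 1))
        sys = build_mixture(self.MIX, 0.0, routing, [RecipientSpec.sink("Y")])
        grid = np.linspace(0, 30, 301)
        err = sup_survival_error(
            sys, lambda ts: np.array([mixture_survival(self.MIX, t)
                                      for t in ts]), grid)
        assert err < 1e-6

    def test_branchwise_recipient_routing_structure(self):
        """Third branch splits between Y and Z: probe the RHS terms."""
        pY = 0.25
        routing = np.array([[1.0, 0.0], [1.0, 0.0], [pY, 1 - pY]])
        recs = [RecipientSpec.exponential("Y", 0.7),
                RecipientSpec.exponential("Z", 0.4)]
        sys = build_mixture(self.MIX, 1.0, routing, recs)
        labels = sys.state_labels
        x = np.arange(1.0, len(labels) + 1.0) / 10
        dx = sys.rhs(0.0, x)
        iY = labels.index("Y")
        iZ = labels.index("Z")
        # chain tails: X1_2 (idx 1), X2_1 (idx 2), X3_3 (idx 5)
        influx_Y = 1.0 * x[1] + 2.0 * x[2] + pY * 0.5 * x[5]
        influx_Z = (1 - pY) * 0.5 * x[5]
        assert dx[iY] == pytest.approx(influx_Y - 0.7 * x[iY], rel=1e-12)
        assert dx[iZ] == pytest.approx(influx_Z - 0.4 * x[iZ], rel=1e-12)

    def test_single_component_reduces_to_proportional(self):
        mix1 = MixtureDist((1.0,), (ErlangParams(1.2, 3).to_event_time(),))
        s1 = build_mixture(mix1, 0.5, np.ones((1, 1)),
                           [RecipientSpec.sink("Y")])
        s2 = build_proportional_outputs(
            ErlangParams(1.2, 3).to_event_time(), 0.5, [1.0],
            [RecipientSpec.sink("Y")])
        t = np.linspace(0, 10, 101)
        a = integrate(s1, 10, t, rtol=1e-10, atol=1e-12)
        b = integrate(s2, 10, t, rtol=1e-10, atol=1e-12)
        assert np.allclose(a.observables["X_total"],
                           b.observables["X_total"], atol=1e-10)


class TestCompeting:
    def test_state_count_law(self):
        c = CompetingDist((ErlangParams(1, 2).to_event_time(),
                           ErlangParams(1, 3).to_event_time(),
                           ErlangParams(1, 2).to_event_time()))
        sys = build_competing(c, 0.0, np.ones((3, 1)),
                              [RecipientSpec.sink("Y")])
        n_x = sum(1 for l in sys.state_labels if l.startswith("X"))
        assert n_x == 2 * 3 * 2

    def test_two_by_two_matches_hand_equations(self):
        """k1 = k2 = 2 with exponential recipients: the worked example."""
        r1, r2, mu = 0.9, 1.4, 0.5
        c = CompetingDist((ErlangParams(r1, 2).to_event_time(),
                           ErlangParams(r2, 2).to_event_time()))
        recs = [RecipientSpec.exponential("Y1", mu),
                RecipientSpec.exponential("Y2", mu)]
        sys = build_competing(c, 2.0, np.eye(2), recs)
        labels = sys.state_labels
        assert labels[:4] == ["X_(1,1)", "X_(1,2)", "X_(2,1)", "X_(2,2)"]
        x = np.array([0.5, 0.4, 0.3, 0.2, 0.1, 0.6])
        x11, x12, x21, x22, y1, y2 = x
        r = r1 + r2
        hand = np.array([
            2.0 - r * x11,
            r2 * x11 - r * x12,
            r1 * x11 - r * x21,
            r1 * x12 + r2 * x21 - r * x22,
            r1 * (x21 + x22) - mu * y1,
            r2 * (x12 + x22) - mu * y2,
        ])
        assert np.allclose(sys.rhs(0.0, x), hand, atol=1e-13)

    def test_impulse_survival_matches_product(self):
        c = CompetingDist((ErlangParams(1.0, 2).to_event_time(),
                           ErlangParams(2.0, 2).to_event_time()))
        sys = build_competing(c, 0.0, np.ones((2, 1)),
                              [RecipientSpec.sink("Y")])
        err = sup_survival_error(
            sys, lambda ts: np.array([competing_survival(c, t) for t in ts]))
        assert err < 1e-6

    def test_first_event_equivalence_with_proportional(self):
        """All k_i = 1 competing == single summed-rate proportional model."""
        rfs = [RateFunction.sinusoidal(1.0, 0.3),
               RateFunction.sinusoidal(0.5, 0.2, 2.0),
               RateFunction.constant(0.8)]
        P = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]])
        inflow = lambda t: 1.0 + 0.2 * np.sin(t)
        c = CompetingDist(tuple(EventTimeDist(r, 1) for r in rfs))
        recs = lambda: [RecipientSpec.sink("Y1"), RecipientSpec.sink("Y2")]
        sys_c = build_competing(c, inflow, P, recs())

        total = rate_sum(rfs)

        def probs(t):
            r = np.array([rf.evaluate(t) for rf in rfs])
            return (P.T @ r) / r.sum()

        sys_p = build_proportional_outputs(EventTimeDist(total, 1), inflow,
                                           probs, recs())
        t = np.linspace(0, 10, 201)
        a = integrate(sys_c, 10, t, rtol=1e-11, atol=1e-13)
        b = integrate(sys_p, 10, t, rtol=1e-11, atol=1e-13)
        assert np.max(np.abs(a.states - b.states)) < 1e-8


class TestIntermediates:
    def reset_spec(self, r0=0.7, r1=1.3, varrho=0.9):
        return IntermediateSpec(
            base=CompetingDist((ErlangParams(r0, 2).to_event_time(),
                                ErlangParams(r1, 2).to_event_time())),
            inter_routing=np.array([[1.0]]),
            out_routing=np.array([[1.0]]),
            exit_probs=np.array([1.0]),
            intermediates=((varrho, 3),),
            recipients=(RecipientSpec.exponential("Y", 0.5),))

    def test_reset_matches_hand_equations(self):
        r0, r1, vr, mu = 0.7, 1.3, 0.9, 0.5
        sys = build_intermediate_reset(self.reset_spec(r0, r1, vr))
        assert sys.state_labels == [
            "X0_(1,1)", "X0_(1,2)", "X0_(2,1)", "X0_(2,2)",
            "XI1_1", "XI1_2", "XI1_3", "Y"]
        x = np.arange(1.0, 9.0) / 10
        x11, x12, x21, x22, i1, i2, i3, y = x
        r = r0 + r1
        hand = np.array([
            -r * x11,
            r1 * x11 - r * x12,
            r0 * x11 - r * x21,
            r0 * x12 + r1 * x21 - r * x22,
            r1 * x12 + r1 * x22 - vr * i1,
            vr * i1 - vr * i2,
            vr * i2 - vr * i3,
            r0 * x21 + r0 * x22 + vr * i3 - mu * y,
        ])
        assert np.allclose(sys.flow(0.0, x), hand, atol=1e-13)

    def test_reset_without_intermediate_entry_reduces_to_competing(self):
        """p_1j = 0 for intermediates is impossible (rows sum to 1), but a
        zero-rate competing component gives an equivalent reduction."""
        r0 = 0.7
        spec = IntermediateSpec(
            base=CompetingDist((ErlangParams(r0, 2).to_event_time(),
                                EventTimeDist(RateFunction.constant(0.0), 2))),
            inter_routing=np.array([[1.0]]),
            out_routing=np.array([[1.0]]),
            exit_probs=np.array([1.0]),
            intermediates=((0.9, 3),))
        sys = build_intermediate_reset(spec)
        err = sup_survival_error(
            sys, lambda t: erlang_survival(ErlangParams(r0, 2), t))
        assert err < 1e-6

    def preserve_spec(self, r0=1.0, r1=1.7, p=None, q=None):
        return IntermediateSpec(
            base=CompetingDist((ErlangParams(r0, 2).to_event_time(),
                                ErlangParams(r1, 2).to_event_time())),
            inter_routing=np.array([[0.6, 0.4]]) if p is None else p,
            out_routing=np.array([[1.0], [1.0]]) if q is None else q,
            exit_probs=np.array([1.0]))

    def test_preserve_matches_hand_equations(self):
        """Single intermediate, entry slot = events awaited under process 0."""
        r0, r1, mu = 1.0, 1.7, 0.5
        spec = IntermediateSpec(
            base=CompetingDist((ErlangParams(r0, 2).to_event_time(),
                                ErlangParams(r1, 2).to_event_time())),
            inter_routing=np.array([[1.0]]),
            out_routing=np.array([[1.0]]),
            exit_probs=np.array([1.0]),
            recipients=(RecipientSpec.exponential("Y", mu),))
        sys = build_intermediate_preserve(spec)
        assert sys.state_labels == [
            "X0_(1,1)", "X0_(1,2)", "X0_(2,1)", "X0_(2,2)",
            "XI1_1", "XI1_2", "Y"]
        x = np.arange(1.0, 8.0) / 10
        x11, x12, x21, x22, i1, i2, y = x
        r = r0 + r1
        hand = np.array([
            -r * x11,
            r1 * x11 - r * x12,
            r0 * x11 - r * x21,
            r0 * x12 + r1 * x21 - r * x22,
            r1 * x12 - r0 * i1,
            r1 * x22 + r0 * i1 - r0 * i2,
            r0 * x21 + r0 * x22 + r0 * i2 - mu * y,
        ])
        assert np.allclose(sys.flow(0.0, x), hand, atol=1e-13)

    def test_preservation_of_total_dwell(self):
        """Total-X survival is Erlang(r0, 2) whatever r1 and the routing."""
        grid = np.linspace(0, 12, 241)
        oracle = lambda t: erlang_survival(ErlangParams(1.0, 2), t)
        base = build_intermediate_preserve(self.preserve_spec())
        assert sup_survival_error(base, oracle, grid) < 1e-6
        for r1 in (0.85, 2.55, 5.0):
            for p in (np.array([[0.6, 0.4]]), np.array([[0.1, 0.9]])):
                sys = build_intermediate_preserve(
                    self.preserve_spec(r1=r1, p=p))
                assert sup_survival_error(sys, oracle, grid) < 1e-6


class TestSeriesAndMax:
    def test_series_state_count_and_rates(self):
        comps = [ErlangParams(1.0, 2).to_event_time(),
                 ErlangParams(2.0, 3).to_event_time()]
        sys = build_series(comps)
        n_x = sum(1 for l in sys.state_labels if l.startswith("X"))
        assert n_x == 5
        assert [r.value for r in sys.model.rates] == [1, 1, 2, 2, 2]

    def test_hypoexponential_survival(self):
        sys = build_series([ErlangParams(1.0, 1).to_event_time(),
                            ErlangParams(2.0, 1).to_event_time()])
        err = sup_survival_error(
            sys, lambda t: 2 * np.exp(-t) - np.exp(-2 * t))
        assert err < 1e-6

    def test_single_component_series_is_chain(self):
        d = ErlangParams(1.3, 3).to_event_time()
        t = np.linspace(0, 10, 101)
        a, _ = survival_from_model(build_series([d]), t)
        b, _ = survival_from_model(build_extended_chain(d), t)
        assert np.allclose(a, b, atol=1e-12)

    def test_max_example_states_and_rates(self):
        r1, r2 = 1.0, 2.0
        sys = build_max([ErlangParams(r1, 2), ErlangParams(r2, 2)])
        xlabels = [l for l in sys.state_labels if l.startswith("X")]
        assert len(xlabels) == 8
        rate_of = dict(zip(xlabels, [r.value for r in sys.model.rates]))
        r = r1 + r2
        assert rate_of["X_(1,1)"] == pytest.approx(r)
        assert rate_of["X_(2,2)"] == pytest.approx(r)
        assert rate_of["X_(1,*)"] == pytest.approx(r1)
        assert rate_of["X_(2,*)"] == pytest.approx(r1)
        assert rate_of["X_(*,1)"] == pytest.approx(r2)
        assert rate_of["X_(*,2)"] == pytest.approx(r2)

    def test_max_rhs_matches_hand_equations(self):
        r1, r2, mu = 1.0, 2.0, 0.5
        sys = build_max([ErlangParams(r1, 2), ErlangParams(r2, 2)],
                        recipient=RecipientSpec.exponential("Y", mu))
        lab = sys.state_labels
        x = np.arange(1.0, len(lab) + 1.0) / 10
        v = dict(zip(lab, x))
        r = r1 + r2
        hand = {
            "X_(1,1)": -r * v["X_(1,1)"],
            "X_(2,1)": r1 * v["X_(1,1)"] - r * v["X_(2,1)"],
            "X_(1,2)": r2 * v["X_(1,1)"] - r * v["X_(1,2)"],
            "X_(*,1)": r1 * v["X_(2,1)"] - r2 * v["X_(*,1)"],
            "X_(2,2)": r2 * v["X_(2,1)"] + r1 * v["X_(1,2)"] - r * v["X_(2,2)"],
            "X_(1,*)": r2 * v["X_(1,2)"] - r1 * v["X_(1,*)"],
            "X_(*,2)": r2 * v["X_(*,1)"] + r1 * v["X_(2,2)"] - r2 * v["X_(*,2)"],
            "X_(2,*)": r1 * v["X_(1,*)"] + r2 * v["X_(2,2)"] - r1 * v["X_(2,*)"],
            "Y": r1 * v["X_(2,*)"] + r2 * v["X_(*,2)"] - mu * v["Y"],
        }
        dx = sys.flow(0.0, x)
        for name, val in hand.items():
            assert dx[lab.index(name)] == pytest.approx(val, abs=1e-13), name

    def test_max_survival_product_of_cdfs(self):
        p1, p2 = ErlangParams(1.0, 2), ErlangParams(2.0, 2)
        sys = build_max([p1, p2])
        oracle = lambda t: 1 - (1 - erlang_survival(p1, t)) * \
            (1 - erlang_survival(p2, t))
        assert sup_survival_error(sys, oracle) < 1e-6

    def test_max_single_component_is_chain(self):
        t = np.linspace(0, 10, 101)
        a, _ = survival_from_model(build_max([ErlangParams(1.0, 3)]), t)
        assert np.max(np.abs(a - erlang_survival(ErlangParams(1.0, 3), t))) \
            < 1e-7


class TestRecipientIntegral:
    def test_no_exit_accumulates_influx(self):
        rec = RecipientSpec.generic("Y", lambda t, tau: 1.0)
        tg = np.linspace(0, 5, 501)
        y = evaluate_recipient_integral(rec, tg, np.full_like(tg, 2.0),
                                        tg[::100], y0=1.0)
        assert np.allclose(y, 1.0 + 2.0 * tg[::100], atol=1e-9)

    def test_exponential_recipient_closed_form(self):
        rec = RecipientSpec.exponential("Y", 0.8)
        tg = np.linspace(0, 10, 2001)
        y = evaluate_recipient_integral(rec, tg, np.full_like(tg, 1.3),
                                        tg[::50], y0=0.5)
        closed = (1.3 / 0.8) * (1 - np.exp(-0.8 * tg[::50])) + \
            0.5 * np.exp(-0.8 * tg[::50])
        assert np.max(np.abs(y - closed)) < 1e-4

    def test_erlang_recipient_agrees_with_ode_states(self):
        sys = build_lct_chain(ErlangParams(1.5, 2), inflow=1.0,
                              recipient=RecipientSpec.erlang("Y", 1.0, 3))
        t = np.linspace(0, 12, 2401)
        traj = integrate(sys, 12, t, rtol=1e-10, atol=1e-12)
        influx = np.array([sys.recipient_influx["Y"](ti, x)
                           for ti, x in zip(traj.times, traj.states)])
        yq = evaluate_recipient_integral(
            RecipientSpec.erlang("Y", 1.0, 3), t, influx, t[::40])
        assert np.max(np.abs(yq - traj.observables["Y"][::40])) < 1e-4

    def test_outside_history_rejected(self):
        rec = RecipientSpec.exponential("Y", 1.0)
        tg = np.linspace(0, 2, 21)
        with pytest.raises(ValueError):
            evaluate_recipient_integral(rec, tg, np.ones_like(tg), [3.0])
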