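"""Farm decision model: economics, evaluation, actions, market, succession."""

import numpy as np
import pytest

import alpscape as alp
from alpscape import landuse as lu
from alpscape.abm import (
    ACTIONS,
    DecisionTable,
    EvaluationState,
    Farm,
    Parcel,
    ScenarioTimeline,
    SimulationConfig,
    apply_action,
    choose_action,
    clear_rental_market,
    advance_succession,
    compute_economics,
    evaluate_farm,
    peer_mean,
    step_year,
)


def _timeline(margin=800.0, subsidy=200.0, labour=60.0, n_years=5):
    """Flat timeline with the same economics for every activity."""
    shape = (n_years + 1, lu.N_CLASSES + 1)
    return ScenarioTimeline(
        "flat",
        margin=np.full(shape, margin),
        labour=np.full(shape, labour),
        subsidy=np.full(shape, subsidy),
    )


def _parcel(pid, n_cells, code=10, owner=0):
    return Parcel(id=pid, cells=np.arange(n_cells), landuse=code, owner=owner)


class TestEconomics:
    def test_farm_without_parcels_earns_nothing(self):
        farm = Farm(id=0, ftype="livestock", intensity=2, style="traditionalist")
        assert compute_economics(farm, {}, _timeline(), 0) == (0.0, 0.0)

    def test_hand_arithmetic_single_parcel(self):
        # 10 ha at 800 €/ha margin + 200 €/ha subsidy and 60 hr/ha
        parcels = {0: _parcel(0, 160)}  # 160 cells x 0.0625 ha = 10 ha
        farm = Farm(id=0, ftype="livestock", intensity=2, style="idealist", owned=[0])
        income, workload = compute_economics(farm, parcels, _timeline(), 0)
        assert income == pytest.approx(10_000.0)
        assert workload == pytest.approx(600.0)

    def test_linearity_in_area(self):
        small = {0: _parcel(0, 80)}
        big = {0: _parcel(0, 160)}
        farm = Farm(id=0, ftype="livestock", intensity=2, style="idealist", owned=[0])
        inc1, wl1 = compute_economics(farm, small, _timeline(), 0)
        inc2, wl2 = compute_economics(farm, big, _timeline(), 0)
        assert inc2 == pytest.approx(2 * inc1)
        assert wl2 == pytest.approx(2 * wl1)


class TestEvaluation:
    @pytest.mark.parametrize(
        "workload,income,peer,expect",
        [
            (1700, 25_000, 22_000, (True, True)),
            (1900, 25_000, 22_000, (False, True)),
            (1700, 21_000, 30_000, (True, False)),  # above floor, below peers
            (1800, 20_000, 0, (True, False)),  # floor is strict
            (1800, 20_001, 20_001, (True, True)),  # peer tie counts as ok
        ],
    )
    def test_threshold_logic(self, workload, income, peer, expect):
        farm = Farm(id=0, ftype="livestock", intensity=3, style="idealist",
                    income=income, workload=workload)
        state = evaluate_farm(farm, peer)
        assert (state.workload_ok, state.income_ok) == expect

    def test_negative_peer_mean_rejected(self):
        farm = Farm(id=0, ftype="livestock", intensity=3, style="idealist")
        with pytest.raises(ValueError):
            evaluate_farm(farm, -1.0)

    def test_peer_mean_over_type(self):
        farms = [
            Farm(id=i, ftype="livestock", intensity=3, style="idealist", income=x)
            for i, x in enumerate((10_000.0, 20_000.0, 30_000.0))
        ]
        assert peer_mean(farms, "livestock") == pytest.approx(20_000.0)
        assert peer_mean(farms, "cash crop") == 0.0
        assert peer_mean(farms[::-1], "livestock") == pytest.approx(20_000.0)


class TestDecisionTable:
    def test_default_table_rows_are_valid(self):
        table = DecisionTable.default()
        assert len(table.rows) == 60
        for p in table.rows.values():
            assert p.sum() == pytest.approx(1.0, abs=1e-9)
            assert (p >= 0).all()

    def test_unnormalized_row_rejected(self):
        rows = DecisionTable.default().rows.copy()
        key = next(iter(rows))
        rows[key] = np.full(10, 0.2)
        with pytest.raises(ValueError):
            DecisionTable(rows)

    def test_csv_roundtrip(self):
        table = DecisionTable.default()
        back = DecisionTable.from_frame(table.to_frame())
        for k, p in table.rows.items():
            assert np.allclose(back.rows[k], p)

    def test_degenerate_row_always_chosen(self, rng):
        table = DecisionTable.degenerate("extensify_grassland")
        farm = Farm(id=0, ftype="livestock", intensity=3, style="idealist")
        ev = EvaluationState(True, True)
        assert all(
            choose_action(ev, farm, table, rng) == "extensify_grassland" for _ in range(20)
        )

    def test_sampling_frequencies_within_binomial_bounds(self, rng):
        p = np.zeros(10)
        p[0], p[1] = 0.5, 0.5
        rows = {k: p for k in DecisionTable.degenerate().rows}
        table = DecisionTable(rows)
        farm = Farm(id=0, ftype="livestock", intensity=3, style="idealist")
        ev = EvaluationState(True, True)
        n = 100_000
        hits = sum(choose_action(ev, farm, table, rng) == ACTIONS[0] for _ in range(n))
        sigma = np.sqrt(n * 0.25)
        assert abs(hits - n / 2) < 3 * sigma


class TestActions:
    def test_intensify_grassland_moves_meadows_up(self, farm_state):
        st = farm_state.copy()
        farm = next(
            f for f in st.farms.values()
            if any(st.parcels[p].landuse == 10 for p in f.holdings)
        )
        apply_action(farm, "intensify_grassland", st, np.random.default_rng(0))
        for pid in farm.holdings:
            assert st.parcels[pid].landuse not in (10, 11)

    def test_terminate_releases_everything(self, farm_state):
        st = farm_state.copy()
        farm = next(f for f in st.farms.values() if len(f.holdings) == 1)
        apply_action(farm, "shrink_or_terminate", st, np.random.default_rng(0))
        assert not farm.active
        assert farm.holdings == []
        assert st.pending  # released parcels await market entry
        st.market.extend(st.pending)
        st.pending = []
        st.check_tenure_partition()

    def test_no_change_leaves_map_bit_identical(self, farm_state):
        st = farm_state.copy()
        before = st.landuse.copy()
        for farm in st.farms.values():
            apply_action(farm, "no_change", st, np.random.default_rng(0))
        assert np.array_equal(st.landuse, before)

    def test_illegal_action_resolves_to_no_change(self, farm_state):
        st = farm_state.copy()
        farm = next(
            f for f in st.farms.values()
            if all(st.parcels[p].landuse in lu.GRASSLAND_FARM_CLASSES for p in f.holdings)
        )
        before = st.landuse.copy()
        expand = apply_action(farm, "intensify_cropland", st, np.random.default_rng(0))
        assert not expand
        assert np.array_equal(st.landuse, before)


class TestMarket:
    def test_no_expanders_only_ages_the_market(self, farm_state):
        st = farm_state.copy()
        pid = st.farms[0].owned[0]
        st.farms[0].owned.remove(pid)
        st.parcels[pid].owner = None
        st.parcels[pid].tenure = "market"
        st.market = [pid]
        clear_rental_market(st, [], _timeline(), 0, np.random.default_rng(0))
        assert st.market == [pid]
        advance_succession(st)
        assert st.parcels[pid].fallow == 1

    def test_single_expander_with_slack_takes_all(self, farm_state):
        st = farm_state.copy()
        released = []
        for fid in (1, 2):
            for pid in list(st.farms[fid].owned):
                st.farms[fid].owned.remove(pid)
                st.parcels[pid].owner = None
                st.parcels[pid].tenure = "market"
                released.append(pid)
        st.market = released
        st.farms[0].workload = 0.0
        alloc = clear_rental_market(
            st, [0], _timeline(labour=0.01), 0, np.random.default_rng(0)
        )
        assert sorted(alloc[0]) == sorted(released)
        assert st.market == []
        st.check_tenure_partition()

    def test_workload_cap_limits_acceptance(self, farm_state):
        st = farm_state.copy()
        pid = st.farms[1].owned[0]
        st.farms[1].owned.remove(pid)
        st.parcels[pid].owner = None
        st.parcels[pid].tenure = "market"
        st.market = [pid]
        st.farms[0].workload = 1799.9  # no slack for any parcel
        alloc = clear_rental_market(
            st, [0], _timeline(labour=60.0), 0, np.random.default_rng(0)
        )
        assert alloc == {}
        assert st.market == [pid]


class TestSuccession:
    def test_abandonment_timeline_is_exact(self, farm_state):
        """Released in year t: rentable t+1..t+4, scrub from t+5, forever."""
        st = farm_state.copy()
        table = DecisionTable.degenerate("no_change")
        tl = _timeline(n_years=30)
        rng = np.random.default_rng(0)
        fid = 3
        release = list(st.farms[fid].owned)
        for pid in release:
            st.farms[fid].owned.remove(pid)
            st.parcels[pid].owner = None
            st.parcels[pid].tenure = "market"
            st.pending.extend(release)
        st.pending = release
        t0 = st.year
        for _ in range(8):
            year = st.year
            on_market = set(st.market)
            if t0 + 1 <= year <= t0 + 4:
                assert set(release) <= on_market
            if year >= t0 + 5:
                assert on_market.isdisjoint(release)
                for pid in release:
                    assert st.parcels[pid].tenure == "retired"
                    assert (st.landuse[st.parcels[pid].cells] == lu.SCRUB_CLASS).all()
            step_year(st, tl, table, rng)

    def test_cultivated_parcels_keep_zero_fallow(self, farm_state):
        st = farm_state.copy()
        advance_succession(st)
        assert all(
            p.fallow == 0 for p in st.parcels.values() if p.tenure in ("owned", "rented")
        )

    def test_retired_parcel_becomes_forest_after_lag(self, farm_state):
        st = farm_state.copy()
        st.config = SimulationConfig(forest_lag=3)
        pid = st.farms[0].owned.pop(0)
        p = st.parcels[pid]
        p.owner, p.tenure = None, "market"
        st.market = [pid]
        table = DecisionTable.degenerate("no_change")
        tl = _timeline(n_years=30)
        rng = np.random.default_rng(0)
        for _ in range(15):
            step_year(st, tl, table, rng)
        assert p.tenure == "retired"
        assert p.forested
        codes = np.unique(st.landuse[p.cells])
        assert set(codes) <= {lu.BROADLEAF_FOREST, lu.CONIFER_FOREST}
        assert not np.isin(st.landuse[p.cells], lu.FARM_CLASSES).any()


class TestSimulation:
    def test_no_change_table_is_a_fixpoint(self, farm_state):
        tl = _timeline(n_years=10)
        trajs = alp.run_simulation(
            farm_state, tl, n_years=10, n_replicates=2, root_seed=5,
            table=DecisionTable.degenerate("no_change"),
        )
        for traj in trajs:
            assert np.array_equal(traj[0], traj[-1])

    def test_zero_years_returns_initial_map(self, farm_state):
        trajs = alp.run_simulation(farm_state, _timeline(), 0, 1, root_seed=5)
        assert len(trajs[0]) == 1
        assert np.array_equal(trajs[0][0], farm_state.landuse_map())

    def test_same_root_seed_reproduces_trajectories(self, farm_state):
        tl = alp.default_timeline("SSP5", 8)
        a = alp.run_simulation(farm_state, tl, 8, 2, root_seed=9)
        b = alp.run_simulation(farm_state, tl, 8, 2, root_seed=9)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta[-1], tb[-1])

    def test_replicates_differ(self, farm_state):
        tl = alp.default_timeline("BAU", 8)
        a, b = alp.run_simulation(farm_state, tl, 8, 2, root_seed=9)
        assert not np.array_equal(a[-1], b[-1])

    def test_monotone_abandonment_under_shrink_table(self, farm_state):
        """All probability mass on shrink/terminate: farmed area never grows."""
        tl = _timeline(n_years=20)
        trajs = alp.run_simulation(
            farm_state, tl, 20, 1, root_seed=5,
            table=DecisionTable.degenerate("shrink_or_terminate"), keep_annual=True,
        )
        areas = [np.isin(m, lu.FARM_CLASSES).sum() for m in trajs[0]]
        assert all(a2 <= a1 for a1, a2 in zip(areas, areas[1:]))
        assert areas[-1] < areas[0]

    def test_park_cells_never_change(self, farm_state):
        park_cells = np.concatenate(
            [p.cells for p in farm_state.parcels.values() if p.owner == -1]
        )
        tl = alp.default_timeline("SSP1", 10)
        trajs = alp.run_simulation(farm_state, tl, 10, 1, root_seed=5)
        before = farm_state.landuse[park_cells]
        after = trajs[0][-1].ravel()[park_cells]
        assert np.array_equal(before, after)


def test_default_timelines_are_defined_and_nonnegative():
    for scen in ("BAU", "SSP1", "SSP5"):
        tl = alp.default_timeline(scen, 36)
        assert tl.n_years == 37
        assert (tl.labour >= 0).all()
    with pytest.raises(ValueError):
        alp.default_timeline("RCP8.5", 10)
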