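"""Population loop: initialization, binning, look-up tables, convergence,
painting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from signalfate.config import RunConfig, SignalSpec
from signalfate.errors import NonConvergenceError, OutOfRangeError
from signalfate.fixtures import make_fixture
from signalfate.population_model import (
    LINEAGE_CODES,
    bin_signal,
    bin_signal_array,
    emergence_probabilities,
    init_population,
    new_lookup_tables,
    record_virtual_fates,
    run_algorithm1,
    run_cycle,
    signal_pair_combinations,
)
from signalfate.signal_fields import SignalField


class TestInitPopulation:
    def test_binomial_counts(self):
        g = init_population(100, 0.5, seed=0)
        n1 = (g.codes == 1).sum()
        assert abs(n1 - 5000) < 3 * 50  # 3 sigma of Binomial(1e4, .5)
        assert set(np.unique(g.codes)) <= {1, 4}

    def test_all_sc1(self):
        assert (init_population(10, 1.0, seed=1).codes == 1).all()

    def test_seed_determinism(self):
        a = init_population(20, 0.3, seed=9)
        b = init_population(20, 0.3, seed=9)
        assert np.array_equal(a.codes, b.codes)


class TestBinning:
    @pytest.mark.parametrize("s,idx", [(0.0, 0), (5.0, 5), (2.4, 2)])
    def test_examples(self, s, idx):
        assert bin_signal(s) == idx

    @pytest.mark.parametrize("s", [-0.1, 5.2])
    def test_out_of_range(self, s):
        with pytest.raises(OutOfRangeError):
            bin_signal(s)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.floats(0.0, 5.0))
    def test_matches_floor_rule(self, s):
        expect = min(int(np.floor(s * 6 / 5)), 5)
        assert bin_signal(s) == expect
        assert bin_signal_array(np.array([s]))[0] == expect


class TestRunCycle:
    def test_uniform_high_signals_bias_lineage1_to_A(self, sw_default, stem_xy):
        lin = np.full((12, 12), 1)
        s = np.full((12, 12), 5.0)
        fates = run_cycle(lin, s, s, sw_default, seed=2, stem_xy=stem_xy)
        assert (fates == 2).all()

    def test_zero_signal_lineage2_self_renews_with_even_escapes(
            self, sw_default, stem_xy):
        lin = np.full((30, 30), 2)
        z = np.zeros((30, 30))
        counts = {4: 0, 5: 0, 6: 0}
        for s in range(3):
            fates = run_cycle(lin, z, z, sw_default, seed=50 + s,
                              stem_xy=stem_xy)
            for c in (4, 5, 6):
                counts[c] += int((fates == c).sum())
        total = sum(counts.values())
        assert counts[4] / total > 0.85  # self-renewal dominates at baseline
        escapes = counts[5] + counts[6]
        if escapes >= 20:  # the rare escapes split near-evenly between C/D
            assert abs(counts[5] - counts[6]) < 0.5 * escapes

    def test_zero_length_cycle_leaves_state_at_stem(self, sw_default, stem_xy):
        lin = np.full((5, 5), 1)
        s = np.full((5, 5), 5.0)
        fates = run_cycle(lin, s, s, sw_default, steps=0, seed=3,
                          stem_xy=stem_xy)
        assert (fates == 1).all()  # still at the stem point


class TestLookupTables:
    def test_counting_conservation(self, sw_default, stem_xy):
        tables = new_lookup_tables()
        sz = 10
        lin = np.where(init_population(sz, 0.5, 0).codes == 1, 1, 2)
        rng_s = np.random.default_rng(4)
        s1 = rng_s.uniform(0, 5, (sz, sz))
        s2 = rng_s.uniform(0, 5, (sz, sz))
        for k in range(3):
            fates = run_cycle(lin, s1, s2, sw_default, seed=k, stem_xy=stem_xy)
            record_virtual_fates(tables, fates, s1, s2)
            assert sum(t.total for t in tables.values()) == (k + 1) * sz * sz

    def test_uniform_signals_touch_single_bin(self, sw_default, stem_xy):
        tables = new_lookup_tables()
        lin = np.full((6, 6), 1)
        s = np.full((6, 6), 5.0)
        fates = run_cycle(lin, s, s, sw_default, seed=1, stem_xy=stem_xy)
        record_virtual_fates(tables, fates, s, s)
        for t in tables.values():
            nz = np.argwhere(t.counts > 0)
            assert all((tuple(ij) == (5, 5)) for ij in nz)

    def test_lineage_separation(self, sw_default, stem_xy):
        tables = new_lookup_tables()
        lin = np.full((6, 6), 2)  # no lineage-1 sites at all
        s = np.full((6, 6), 2.5)
        fates = run_cycle(lin, s, s, sw_default, seed=1, stem_xy=stem_xy)
        record_virtual_fates(tables, fates, s, s)
        for code in (1, 2, 3):
            assert tables[code].total == 0

    def test_emergence_probabilities(self):
        tables = new_lookup_tables()
        probs = emergence_probabilities(tables, 100)
        assert all((p == 0).all() for p in probs.values())
        tables[2].counts[5, 5] = 40
        probs = emergence_probabilities(tables, 100)
        assert probs[2][5, 5] == pytest.approx(0.4)
        # per-bin normalization sums to one over the lineage triple
        tables[1].counts[5, 5] = 10
        tables[3].counts[5, 5] = 50
        per_bin = emergence_probabilities(tables, 100, per_bin=True)
        s = per_bin[1][5, 5] + per_bin[2][5, 5] + per_bin[3][5, 5]
        assert s == pytest.approx(1.0)


def _uniform_cfg(sz=10, v1=5.0, v2=5.0, **kw):
    kw.setdefault("max_cycles", 2000)
    return RunConfig(
        sz=sz,
        signal1=SignalSpec(kind="uniform", value=v1),
        signal2=SignalSpec(kind="uniform", value=v2),
        **kw)


class TestAlgorithm1:
    def test_huge_epsilon_exits_after_first_evaluation(self):
        cfg = _uniform_cfg(epsilon=10.0)
        res = run_algorithm1(cfg, seed=1)
        assert res.n_cycles == cfg.eval_every_steps // cfg.cycle_steps
        assert res.grid.codes.shape == (10, 10)
        assert len(res.diff_trace) == 1

    def test_uniform_55_paints_lineage1_A(self):
        res = run_algorithm1(_uniform_cfg(), seed=2)
        assert (res.grid.codes[res.lineages == 1] == 2).all()
        # default lineage scope: every painted code stays in its triple
        for lin, codes in LINEAGE_CODES.items():
            painted = res.grid.codes[res.lineages == lin]
            assert np.isin(painted, codes).all()

    def test_uniform_signals_make_lineages_exchangeable(self):
        # spatially uniform signals put every site of a lineage in the same
        # bin, so painting cannot depend on position
        res = run_algorithm1(_uniform_cfg(v1=0.0, v2=5.0), seed=3)
        for lin in (1, 2):
            assert len(np.unique(res.grid.codes[res.lineages == lin])) == 1

    def test_end_to_end_determinism(self):
        cfg = _uniform_cfg(v1=1.0, v2=4.0)
        a = run_algorithm1(cfg, seed=11)
        b = run_algorithm1(cfg, seed=11)
        assert np.array_equal(a.grid.codes, b.grid.codes)
        assert a.n_cycles == b.n_cycles
        assert a.diff_trace == b.diff_trace

    def test_epsilon_monotonicity(self):
        slack = run_algorithm1(_uniform_cfg(epsilon=0.05), seed=5)
        tight = run_algorithm1(_uniform_cfg(epsilon=0.0025), seed=5)
        assert slack.n_cycles <= tight.n_cycles

    def test_nonconvergence_cap(self):
        cfg = _uniform_cfg(max_cycles=5)  # cap below the first evaluation
        with pytest.raises(NonConvergenceError) as err:
            run_algorithm1(cfg, seed=1)
        assert err.value.diff_trace == []

    def test_turing_pair_yields_rich_pattern(self):
        # two binarized reverse-spot-style planes (high plateaus with cold
        # holes, partially overlapping) expose all four extreme signal
        # combinations and give a multi-phenotype patchwork congruent with
        # the signal geometry
        sz = 24
        v1 = np.full((sz, sz), 5.0)
        v2 = np.full((sz, sz), 5.0)
        v1[2:8, 2:8] = 0.0    # (0, 5) region
        v2[14:20, 14:20] = 0.0  # (5, 0) region
        v1[14:20, 2:8] = 0.0    # (0, 0) region (overlapping holes)
        v2[14:20, 2:8] = 0.0
        f1, f2 = SignalField(v1), SignalField(v2)
        cfg = RunConfig(sz=sz, max_cycles=2000)
        res = run_algorithm1(cfg, seed=7, signals=(f1, f2))
        codes = set(np.unique(res.grid.codes))
        assert len(codes) >= 5
        # patch congruence: lineage-1 sites on the high/high plateau are A,
        # lineage-2 sites inside the (0, 5) hole are C
        plateau = (v1 == 5.0) & (v2 == 5.0) & (res.lineages == 1)
        assert (res.grid.codes[plateau] == 2).all()
        hole_c = (v1 == 0.0) & (v2 == 5.0) & (res.lineages == 2)
        assert (res.grid.codes[hole_c] == 5).all()


def test_coevolving_signals_stay_in_range():
    # co-evolution mode: the stochastic signal lattice advances each cycle
    # and the rescaled planes remain on the (0, 5) decision scale
    cfg = RunConfig(
        sz=6, epsilon=10.0, max_cycles=100, signal_mode="coevolve",
        signal1=SignalSpec(kind="uniform", value=4.0),
        signal2=SignalSpec(kind="uniform", value=4.0),
        omega=30.0)
    res = run_algorithm1(cfg, seed=2)
    for f in (res.s1, res.s2):
        assert (f.values >= 0).all() and (f.values <= 5.0).all()
    assert res.grid.codes.shape == (6, 6)


def test_signal_pair_combinations():
    combos = signal_pair_combinations()
    assert len(combos) == 9
    assert len(set(combos)) == 9
    for a, b in combos:
        # every combination is accepted by the config layer
        RunConfig(signal1=SignalSpec(kind="preset", name=a),
                  signal2=SignalSpec(kind="preset", name=b))
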