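"""EHH decay, integrated EHH, XP-EHH sign/antisymmetry, normalization."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sweepscan.ehh import (
    EHHDecay,
    ehh_at_core,
    integrated_ehh,
    normalize_scores,
    xpehh_scan,
    xpehh_site,
)

from conftest import make_dataset


def brute_force_ehh(haps, positions, core, direction, include_core=False):
    """Exhaustive pair-comparison EHH at every successive flanking site.

    Returns (offsets, ehh) with the same truncation-free semantics as
    ehh_at_core(cutoff=0, max_gap=inf): identity of a pair at extension
    site j means equality at every site between the core and j
    (excluding or including the core per ``include_core``).
    """
    n, m = haps.shape
    step = -1 if direction == "upstream" else 1
    sites = []
    offsets = [0.0]
    if include_core:
        sites.append(core)
        n_pairs = sum(
            1 for a, b in itertools.combinations(range(n), 2)
            if haps[a, core] == haps[b, core]
        )
        ehh = [n_pairs / (n * (n - 1) / 2)]
    else:
        ehh = [1.0]
    j = core + step
    while 0 <= j < m:
        sites.append(j)
        ident = sum(
            1
            for a, b in itertools.combinations(range(n), 2)
            if all(haps[a, s] == haps[b, s] for s in sites)
        )
        offsets.append(abs(int(positions[j]) - int(positions[core])))
        ehh.append(ident / (n * (n - 1) / 2))
        j += step
    return np.asarray(offsets), np.asarray(ehh)


class TestEhhAtCore:
    def test_identical_haplotypes_stay_at_one(self):
        haps = np.tile([0, 1, 0, 1, 1], (4, 1)).astype(np.uint8)
        d = ehh_at_core(haps, [10, 20, 30, 40, 50], 0, "downstream")
        np.testing.assert_allclose(d.ehh, 1.0)
        assert d.offsets[-1] == 40

    def test_half_split_gives_two_sixths(self):
        # alleles {0,0,1,1} at the single flanking site: 2 identical pairs of 6
        haps = np.array([[0, 0], [0, 0], [0, 1], [0, 1]], dtype=np.uint8)
        d = ehh_at_core(haps, [100, 200], 0, "downstream")
        np.testing.assert_allclose(d.ehh, [1.0, 2 / 6])

    def test_zero_ehh_stops_extension(self):
        # two haplotypes differing at the first flanking site: EHH drops to 0
        # there and no further sites are visited despite being available
        haps = np.array([[0, 0, 0, 0], [0, 1, 0, 0]], dtype=np.uint8)
        d = ehh_at_core(haps, [100, 200, 300, 400], 0, "downstream")
        np.testing.assert_allclose(d.ehh, [1.0, 0.0])
        assert len(d.offsets) == 2

    def test_pairwise_distinct_sample_decays_to_zero(self):
        # 4 haplotypes made pairwise distinct by two flanking sites: the
        # curve reaches 0 at the second offset and stops
        haps = np.array(
            [[0, 0, 0], [0, 0, 1], [0, 1, 0], [0, 1, 1]], dtype=np.uint8
        )
        d = ehh_at_core(haps, [100, 200, 300], 0, "downstream", cutoff=0.05)
        np.testing.assert_allclose(d.ehh, [1.0, 2 / 6, 0.0])

    def test_requires_two_haplotypes(self):
        with pytest.raises(ValueError):
            ehh_at_core(np.zeros((1, 3), dtype=np.uint8), [1, 2, 3], 0, "downstream")
        with pytest.raises(IndexError):
            ehh_at_core(np.zeros((4, 3), dtype=np.uint8), [1, 2, 3], 9, "downstream")

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_pair_comparison(self, data):
        n = data.draw(st.integers(2, 8))
        m = data.draw(st.integers(2, 12))
        bits = data.draw(
            st.lists(st.integers(0, 1), min_size=n * m, max_size=n * m)
        )
        haps = np.asarray(bits, dtype=np.uint8).reshape(n, m)
        core = data.draw(st.integers(0, m - 1))
        direction = data.draw(st.sampled_from(["upstream", "downstream"]))
        include_core = data.draw(st.booleans())
        got = ehh_at_core(
            haps, np.arange(1, m + 1) * 10, core, direction,
            cutoff=0.0, max_gap=10**9, include_core=include_core,
        )
        offsets, ehh = brute_force_ehh(
            haps, np.arange(1, m + 1) * 10, core, direction, include_core
        )
        np.testing.assert_array_equal(got.offsets, offsets)
        np.testing.assert_allclose(got.ehh, ehh, rtol=0, atol=0)

    def test_decay_is_non_increasing_on_simulated_data(self, sweep_sim):
        ds, _, _ = sweep_sim
        haps = ds.population_matrix("wild", "chr1")
        pos = ds.positions["chr1"]
        rng = np.random.default_rng(5)
        for core in rng.integers(0, len(pos), size=25):
            for direction in ("upstream", "downstream"):
                d = ehh_at_core(haps, pos, int(core), direction, cutoff=0.0)
                assert np.all(np.diff(d.ehh) <= 1e-12)


class TestIntegratedEhh:
    def test_rectangle_area(self):
        up = EHHDecay(0, "upstream", np.array([0.0, 10_000.0]), np.array([1.0, 1.0]))
        down = EHHDecay(0, "downstream", np.array([0.0, 10_000.0]), np.array([1.0, 1.0]))
        area, ok = integrated_ehh(up, down)
        assert ok and area == pytest.approx(20_000.0)

    def test_one_sided_trapezoid(self):
        up = EHHDecay(0, "upstream", np.array([0.0]), np.array([1.0]))
        down = EHHDecay(0, "downstream", np.array([0.0, 1_000.0]), np.array([1.0, 0.5]))
        area, ok = integrated_ehh(up, down)
        assert ok and area == pytest.approx(750.0)

    def test_doubling_offsets_doubles_area(self):
        off = np.array([0.0, 500.0, 1_500.0])
        ehh = np.array([1.0, 0.6, 0.2])
        a1, _ = integrated_ehh(EHHDecay(0, "upstream", off, ehh), EHHDecay(0, "downstream", off, ehh))
        a2, _ = integrated_ehh(
            EHHDecay(0, "upstream", 2 * off, ehh), EHHDecay(0, "downstream", 2 * off, ehh)
        )
        assert a2 == pytest.approx(2 * a1)

    def test_no_flanking_sites_hits_floor(self):
        lone = EHHDecay(0, "upstream", np.array([0.0]), np.array([1.0]))
        area, ok = integrated_ehh(lone, EHHDecay(0, "downstream", np.array([0.0]), np.array([1.0])))
        assert not ok and area == 1.0

    def test_mismatched_cores_raise(self):
        a = EHHDecay(0, "upstream", np.array([0.0]), np.array([1.0]))
        b = EHHDecay(1, "downstream", np.array([0.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            integrated_ehh(a, b)


class TestXpehh:
    def test_identical_population_haplotypes_score_zero(self):
        block = np.array(
            [[0, 1, 0, 1, 1], [1, 0, 0, 1, 0], [0, 1, 1, 0, 1], [1, 1, 0, 0, 0]],
            dtype=np.uint8,
        )
        haps = np.vstack([block, block])  # farm identical to wild
        ds = make_dataset(haps, [100, 5_000, 20_000, 40_000, 90_000], n_wild=2)
        from sweepscan.dataio import PopulationPanel

        panel = PopulationPanel(
            populations={"wild": ["w0", "w1"], "farm": ["f0", "f1"]}, reference="wild"
        )
        rec = xpehh_site(ds, panel, "farm", "chr1", 2)
        assert rec["raw_lnratio"] == pytest.approx(0.0, abs=1e-12)

    def test_population_swap_negates_lnratio(self, sweep_sim, wf_panel):
        ds, _, panel = sweep_sim
        from sweepscan.dataio import PopulationPanel

        swapped = PopulationPanel(populations=panel.populations, reference="farm")
        fwd = xpehh_scan(ds, panel, "farm")
        rev = xpehh_scan(ds, swapped, "wild")
        merged = fwd.merge(rev, on="pos", suffixes=("_f", "_r"))
        assert len(merged) == len(fwd) == len(rev)
        np.testing.assert_allclose(
            merged["raw_lnratio_f"], -merged["raw_lnratio_r"], rtol=0, atol=1e-12
        )

    def test_positive_score_at_simulated_sweep_core(self, sweep_sim):
        ds, truth, panel = sweep_sim
        assert truth.sweep_loci["farm_freq"].iloc[0] > 0.9
        scores = xpehh_scan(ds, panel, "farm")
        sweep_pos = int(truth.sweep_loci["pos"].iloc[0])
        near = scores[(scores["pos"] - sweep_pos).abs() < 10_000]
        assert near["raw_lnratio"].max() > 0


class TestNormalizeScores:
    def test_closed_form_zscores(self):
        got = normalize_scores(np.array([-1.0, 0.0, 1.0]))
        np.testing.assert_allclose(got, [-1.224745, 0.0, 1.224745], atol=1e-6)
        assert abs(got.mean()) < 1e-9 and abs(got.std() - 1) < 1e-9

    def test_affine_invariance(self):
        raw = np.array([0.3, -1.2, 2.2, 0.9])
        np.testing.assert_allclose(
            normalize_scores(raw), normalize_scores(5.0 * raw - 3.0), atol=1e-12
        )

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            normalize_scores(np.array([2.0, 2.0, 2.0]))
        with pytest.raises(ValueError):
            normalize_scores(np.array([1.0]))
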