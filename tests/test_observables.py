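"""Structure and transport observables."""

import numpy as np
import pandas as pd
import pytest

from golgi_sos.observables import (
    EnrichmentVector,
    directionality,
    enrichment_vector,
    exit_kinetics,
    simplex_grid,
    simplex_maps,
    size_distribution,
    steady_state_stats,
    system_purity,
    typical_size,
)


def snapshot(rows, time=0.0):
    """rows: list of (n_cis, n_medial, n_trans[, cargo])."""
    return pd.DataFrame(
        {
            "time": time,
            "compartment_id": range(len(rows)),
            "n_cis": [r[0] for r in rows],
            "n_medial": [r[1] for r in rows],
            "n_trans": [r[2] for r in rows],
            "n_cargo": [r[3] if len(r) > 3 else 0 for r in rows],
        }
    )


def transport(rows):
    """rows: (donor_phi, acceptor_phi, cargo[, back_fusion[, is_exit]])."""
    return pd.DataFrame(
        {
            "time": np.arange(len(rows), dtype=float),
            "identity": 0,
            "donor_phi_cis": [r[0][0] for r in rows],
            "donor_phi_medial": [r[0][1] for r in rows],
            "donor_phi_trans": [r[0][2] for r in rows],
            "acceptor_phi_cis": [r[1][0] for r in rows],
            "acceptor_phi_medial": [r[1][1] for r in rows],
            "acceptor_phi_trans": [r[1][2] for r in rows],
            "cargo": [r[2] for r in rows],
            "back_fusion": [bool(r[3]) if len(r) > 3 else False for r in rows],
            "is_exit": [bool(r[4]) if len(r) > 4 else False for r in rows],
            "donor_id": 0,
            "acceptor_id": 1,
        }
    )


class TestSizeDistribution:
    def test_degenerate_distribution(self):
        snap = snapshot([(4, 0, 0)] * 5)
        hist, typ = size_distribution(snap)
        assert typ == pytest.approx(4.0)
        assert hist["freq"].sum() == pytest.approx(1.0)

    def test_moments_by_hand(self):
        snap = snapshot([(1, 0, 0)] * 4 + [(4, 0, 0)])
        _, typ = size_distribution(snap)
        assert typ == pytest.approx(2.5)  # <n^2>/<n> = 4 / (8/5)

    def test_powerlaw_cutoff_half_rule(self):
        # scission-aggregation size law n^(-3/2) exp(-n/n0): the typical
        # size <n^2>/<n> sits at half the exponential cut-off
        n0 = 400
        sizes = np.arange(1, 10 * n0)
        weights = sizes**-1.5 * np.exp(-sizes / n0)
        rng = np.random.default_rng(0)
        sample = rng.choice(sizes, p=weights / weights.sum(), size=200_000)
        assert typical_size(sample) == pytest.approx(n0 / 2, rel=0.1)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            size_distribution(snapshot([]))


class TestSystemPurity:
    def test_all_pure_nonvesicles(self):
        assert system_purity(snapshot([(3, 0, 0), (0, 5, 0)])) == pytest.approx(1.0)

    def test_weighted_mean_by_hand(self):
        # sizes (2, 6) with purities (1, 0.5) -> 0.625
        snap = snapshot([(2, 0, 0), (3, 3, 0)])
        assert system_purity(snap) == pytest.approx(0.625)

    def test_vesicles_ignored(self):
        base = snapshot([(2, 0, 0), (3, 3, 0)])
        with_ves = snapshot([(2, 0, 0), (3, 3, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)])
        assert system_purity(with_ves) == pytest.approx(system_purity(base))

    def test_only_vesicles_undefined(self):
        with pytest.warns(RuntimeWarning):
            assert np.isnan(system_purity(snapshot([(1, 0, 0), (0, 0, 1)])))


class TestSteadyStateStats:
    def test_constant_series(self):
        series = pd.DataFrame({"time": np.arange(100.0), "n_total": 42.0})
        mean, rel_sd = steady_state_stats(series, t_burn=10.0)
        assert (mean, rel_sd) == (42.0, 0.0)

    def test_insufficient_samples(self):
        series = pd.DataFrame({"time": [0.0, 1.0], "n_total": [1.0, 2.0]})
        with pytest.raises(ValueError):
            steady_state_stats(series, t_burn=0.5)


class TestEnrichment:
    def test_single_event(self):
        ev = transport([((1, 0, 0), (0, 0, 1), 1)])
        e = enrichment_vector(ev)
        assert e.raw == pytest.approx([-1.0, 0.0, 1.0])
        assert e.normalized == pytest.approx([-0.5, 0.0, 0.5])

    def test_mean_then_normalize(self):
        # dphi = (+1,-1,0) and (+1,0,-1), equal weight
        ev = transport([((0, 1, 0), (1, 0, 0), 1), ((0, 0, 1), (1, 0, 0), 1)])
        e = enrichment_vector(ev)
        assert e.normalized == pytest.approx([0.5, -0.25, -0.25])

    def test_cargo_weighting(self):
        ev = transport([((1, 0, 0), (0, 1, 0), 3), ((0, 1, 0), (1, 0, 0), 1)])
        e = enrichment_vector(ev, normalize=False)
        # (3*(-1) + 1*(+1))/4 = -0.5 on cis
        assert e.raw[0] == pytest.approx(-0.5)
        e_unw = enrichment_vector(ev, normalize=False, cargo_weighted=False)
        assert e_unw.raw[0] == pytest.approx(0.0)

    def test_filters(self):
        ev = transport(
            [((1, 0, 0), (0, 0, 1), 1), ((1, 0, 0), (1, 0, 0), 5, True),
             ((0, 0, 1), (0, 0, 1), 9, False, True)]
        )
        e = enrichment_vector(ev, include_back_fusion=False, include_exits=False)
        assert e.raw == pytest.approx([-1.0, 0.0, 1.0])

    def test_normalized_abs_sums_to_one(self):
        ev = transport([((1, 0, 0), (0, 0.4, 0.6), 2), ((0, 1, 0), (0.1, 0.3, 0.6), 1)])
        e = enrichment_vector(ev)
        assert np.abs(e.normalized).sum() == pytest.approx(1.0)

    def test_no_events_errors(self):
        with pytest.raises(ValueError):
            enrichment_vector(transport([]))


class TestDirectionality:
    @pytest.mark.parametrize(
        "vec,expected",
        [
            ((-0.5, 0.0, 0.5), "anterograde"),
            ((0.5, 0.0, -0.5), "retrograde"),
            ((-0.2, 0.6, -0.2), "centripetal"),
            ((0.3, 0.4, 0.3), "mixed"),
        ],
    )
    def test_classification(self, vec, expected):
        assert directionality(np.array(vec)) == expected

    def test_accepts_enrichment_vector(self):
        e = EnrichmentVector(raw=np.array([-0.1, 0.0, 0.1]), normalized=None)
        assert directionality(e) == "anterograde"


class TestSimplexMaps:
    def test_grid_is_closed_simplex(self):
        grid = simplex_grid(10)
        assert len(grid) == 66  # (R+1)(R+2)/2
        phi = grid[["phi_cis", "phi_medial", "phi_trans"]].to_numpy()
        assert np.allclose(phi.sum(axis=1), 1.0)
        assert phi.min() >= 0.0

    def test_pure_cis_occupies_cis_vertex(self):
        snap = snapshot([(5, 0, 0), (3, 0, 0)])
        occ, _ = simplex_maps(snap, transport([]), resolution=20)
        vertex = occ[(occ["bin_i"] == 20) & (occ["bin_j"] == 0)]
        assert vertex["size_content"].iloc[0] == pytest.approx(8.0)
        assert occ["size_content"].sum() == pytest.approx(8.0)

    def test_occupancy_conserves_time_averaged_size(self):
        snaps = pd.concat(
            [snapshot([(5, 3, 2), (1, 0, 0)], time=0.0),
             snapshot([(2, 2, 2)], time=1.0)],
            ignore_index=True,
        )
        occ, _ = simplex_maps(snaps, transport([]), resolution=5)
        assert occ["size_content"].sum() == pytest.approx((10 + 1 + 6) / 2)

    def test_arrows_match_bruteforce_aggregation(self):
        events = transport(
            [((1, 0, 0), (0, 1, 0), 2),      # cis vertex -> medial, weight 2
             ((1, 0, 0), (0, 0, 1), 1),      # cis vertex -> trans, weight 1
             ((0, 0, 1), (0, 1, 0), 4)]      # trans vertex -> medial
        )
        _, arrows = simplex_maps(snapshot([(1, 0, 0)]), events, resolution=4)
        cis_arrow = arrows[(arrows["bin_i"] == 4) & (arrows["bin_j"] == 0)].iloc[0]
        # cargo-weighted mean acceptor: (2*(0,1,0)+1*(0,0,1))/3
        assert cis_arrow["tip_phi_medial"] == pytest.approx(2 / 3)
        assert cis_arrow["tip_phi_trans"] == pytest.approx(1 / 3)
        assert cis_arrow["cargo_flux"] == pytest.approx(3.0)
        assert arrows["weight"].sum() == pytest.approx(1.0)

    def test_back_fusion_excluded_from_arrows(self):
        events = transport([((1, 0, 0), (1, 0, 0), 5, True)])
        _, arrows = simplex_maps(snapshot([(1, 0, 0)]), events, resolution=4)
        assert len(arrows) == 0


class TestExitKinetics:
    def test_recovers_exact_exponential(self):
        t = np.linspace(0.0, 10.0, 101)
        rate, r2 = exit_kinetics(t, 100.0 * np.exp(-0.8 * t))
        assert rate == pytest.approx(0.8, rel=0.01)
        assert r2 == pytest.approx(1.0)

    def test_memoryless_single_compartment_toy(self):
        # one compartment whose cargo exit independently at rate rho:
        # remaining-count curve from iid exponential exit times
        rho = 0.5
        rng = np.random.default_rng(11)
        exits = rng.exponential(1.0 / rho, size=2000)
        t = np.linspace(0.0, 6.0, 61)
        remaining = (exits[None, :] > t[:, None]).sum(axis=1)
        rate, r2 = exit_kinetics(t, remaining)
        assert rate == pytest.approx(rho, rel=0.1)
        assert r2 > 0.95

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            exit_kinetics(np.arange(4.0), np.exp(-np.arange(4.0)))
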