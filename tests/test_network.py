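"""Reaction network: structure, genotypes, heterogeneity, simulation invariants."""

import numpy as np
import pandas as pd
import pytest

from necroptodyn import network as nw

NFKB_MOIETY = (
    "NFkB", "NFkBn", "IkBa_NFkB", "IkBan_NFkBn", "IkBe_NFkB", "IkBen_NFkBn", "IkBd_NFkB",
)


@pytest.fixture(scope="module")
def net():
    return nw.build_network()


@pytest.fixture(scope="module")
def small_population(net):
    """30 heterogeneous cells under sustained TNF (module-scoped; reused)."""
    overrides = nw.sample_cell_parameters(nw.HeterogeneitySpec(seed=0), 30)
    res = nw.simulate_population(
        net, overrides, nw.TnfSchedule.sustained(),
        tracked=nw.TRACKED_SPECIES + NFKB_MOIETY,
    )
    return res


class TestStructure:
    def test_species_and_reaction_counts(self, net):
        assert net.n_species == 41
        assert net.n_reactions == 98

    def test_module_tags_partition(self, net):
        mods = {r.module for r in net.reactions}
        assert mods == {"TNFR-IKK", "IkB-NFkB", "necroptosis"}

    def test_undeclared_species_rejected(self, net):
        bad = net.copy()
        bad.reactions[0].reactants = {"Ghost": 1}
        with pytest.raises(ValueError, match="Ghost"):
            bad.validate()

    def test_table_round_trip_bit_exact(self, net, tmp_path):
        path = tmp_path / "network.csv"
        net.write_table(path)
        back = nw.ReactionNetwork.read_table(path)
        assert back.n_species == net.n_species
        for a, b in zip(net.reactions, back.reactions):
            assert a.rid == b.rid and a.value == b.value and a.kind == b.kind
            assert a.reactants == b.reactants and a.products == b.products
        assert np.array_equal(back.initial_state(), net.initial_state())

    def test_malformed_table_row_names_index(self, net):
        df = net.to_table()
        df.loc[5, "value"] = "not-a-number"
        species = pd.DataFrame(
            [{"name": s.name, "compartment": s.compartment, "initial": s.initial}
             for s in net.species]
        )
        with pytest.raises(ValueError, match="row 5"):
            nw.ReactionNetwork.from_table(df, species)


class TestGenotypes:
    def test_wt_identity(self, net):
        wt = nw.apply_genotype(net, "wt")
        for a, b in zip(net.reactions, wt.reactions):
            assert a.value == b.value

    def test_relA_ko_zeroes_inducible_synthesis_only(self, net):
        ko = nw.apply_genotype(net, "relA_ko")
        assert ko.n_species == 41 and ko.n_reactions == 98
        for r in ko.reactions:
            if r.kind == "transcriptional-synthesis":
                assert r.value == 0.0
        # constitutive synthesis untouched
        assert ko.reaction("a20_tx_con").value == net.reaction("a20_tx_con").value
        # original unchanged
        assert net.reaction("a20_tx_ind").value > 0

    def test_a20_const_2x(self, net):
        g = nw.apply_genotype(net, "a20_const_2x")
        assert g.reaction("a20_tx_ind").value == 0.0
        assert g.reaction("a20_tx_con").value == pytest.approx(
            2 * net.reaction("a20_tx_con").value
        )

    def test_unknown_genotype(self, net):
        with pytest.raises(KeyError):
            nw.apply_genotype(net, "supercell")

    def test_ikb_ko_uses_forced_nfkb(self, net):
        g = nw.apply_genotype(net, "ikb_ko_extrinsic_nfkb")
        assert g.forced_nfkb is not None
        for r in g.reactions:
            if r.nfkb_circuit:
                assert r.value == 0.0
        # A20 induction still driven by (forced) NFkBn
        assert g.reaction("a20_tx_ind").value > 0


class TestHeterogeneity:
    def test_degenerate_spec_gives_identical_cells(self):
        het = nw.HeterogeneitySpec(responder_fraction=1.0, sigma_a20=0.0, sigma_ripk1=0.0)
        ov = nw.sample_cell_parameters(het, 5)
        for o in ov:
            assert o["responder"] is True
            assert o["a20_tx_ind"] == pytest.approx(1.0)
            assert o["ripk1_act"] == pytest.approx(1.0)

    def test_expected_responder_count(self):
        het = nw.HeterogeneitySpec(responder_fraction=0.76, seed=1)
        ov = nw.sample_cell_parameters(het, 3000)
        frac = np.mean([o["responder"] for o in ov])
        assert abs(frac - 0.76) < 4 * np.sqrt(0.76 * 0.24 / 3000)
        # non-responders have no inducible A20
        for o in ov:
            if not o["responder"]:
                assert o["a20_tx_ind"] == 0.0

    def test_seeded_determinism(self):
        het = nw.HeterogeneitySpec(seed=3)
        assert nw.sample_cell_parameters(het, 10) == nw.sample_cell_parameters(het, 10)


class TestSimulation:
    def test_no_tnf_no_death(self, net):
        res = nw.simulate_population(
            net, None, nw.TnfSchedule(amplitude=0.0, duration_hours=6.0, total_hours=6.0),
            n_cells=1, grid_step_hours=0.05,
        )
        assert res.fractional_survival_end == 1.0
        assert res.death_table.data["censored"].all()
        # resting state is quiet: pMLKL never rises
        assert res.trajectories["pMLKL"].max() < 1e-6

    def test_nfkb_moiety_conserved(self, small_population):
        tot = sum(small_population.trajectories[s] for s in NFKB_MOIETY)
        drift = np.max(np.abs(tot - tot[0])) / np.mean(tot[0])
        assert drift < 1e-6

    def test_species_nonnegative(self, small_population):
        for arr in small_population.trajectories.values():
            assert arr.min() > -1e-9

    def test_wt_transients_peak_early(self, small_population):
        """NFkB activity and A20 mRNA rise then fall, peaking before 4 h."""
        t = small_population.times_hours
        for sp in ("NFkBn", "A20_mRNA"):
            m = small_population.trajectories[sp].mean(axis=1)
            assert t[np.argmax(m)] < 4.0
            assert m[-1] < 0.5 * m.max()
        # necrosome activity develops over hours, not minutes
        neca = small_population.trajectories["NecA"].mean(axis=1)
        assert t[np.argmax(neca >= 0.5 * neca.max())] > 1.0

    def test_death_monotone_and_survival_bounds(self, small_population):
        dt = small_population.death_table.data["death_time"].to_numpy()
        died = np.isfinite(dt)
        counts = [np.sum(dt[died] <= t) for t in (6, 12, 18, 24)]
        assert np.all(np.diff(counts) >= 0)
        for t in (6.0, 12.0, 24.0):
            s = nw.fractional_survival(small_population, t)
            assert 0.0 <= s <= 1.0
        assert nw.fractional_survival(small_population, 24.0) <= nw.fractional_survival(
            small_population, 6.0
        )

    def test_common_random_numbers_relA_ko_dies_no_later(self, net):
        """Removing inducible protection can only accelerate death."""
        overrides = nw.sample_cell_parameters(nw.HeterogeneitySpec(seed=4), 20)
        wt = nw.simulate_population(net, overrides, nw.TnfSchedule.sustained())
        ko = nw.simulate_population(
            nw.apply_genotype(net, "relA_ko"), overrides, nw.TnfSchedule.sustained()
        )
        t_wt = wt.death_table.data["death_time"].to_numpy()
        t_ko = ko.death_table.data["death_time"].to_numpy()
        t_wt = np.where(np.isfinite(t_wt), t_wt, np.inf)
        t_ko = np.where(np.isfinite(t_ko), t_ko, np.inf)
        assert np.all(t_ko <= t_wt + 1e-9)

    def test_theta_validation(self, net):
        with pytest.raises(ValueError):
            nw.simulate_population(net, None, theta_death=0.0, n_cells=1)
        with pytest.raises(ValueError):
            nw.simulate_population(net, None, grid_step_hours=0.2, n_cells=1)


class TestSummaries:
    def test_identical_cells_zero_band(self, net):
        het = nw.HeterogeneitySpec(responder_fraction=1.0, sigma_a20=0.0, sigma_ripk1=0.0)
        ov = nw.sample_cell_parameters(het, 3)
        res = nw.simulate_population(net, ov, nw.TnfSchedule.sustained(total_hours=4.0))
        s = nw.population_summary(res, "A20", band_percentile=20.0)
        assert np.allclose(s["band_hi"] - s["band_lo"], 0.0, atol=1e-8)

    def test_band_100_is_envelope_and_median_inside(self, small_population):
        s = nw.population_summary(small_population, "pMLKL", central="median",
                                  band_percentile=100.0)
        traj = small_population.trajectories["pMLKL"]
        assert np.allclose(s["band_lo"], traj.min(axis=1))
        assert np.allclose(s["band_hi"], traj.max(axis=1))
        assert np.all(s["central"] >= s["band_lo"] - 1e-12)
        assert np.all(s["central"] <= s["band_hi"] + 1e-12)

    def test_fractional_survival_arithmetic(self, small_population):
        dt = small_population.death_table.data
        t = 12.0
        expected = 1.0 - np.mean(
            np.isfinite(dt["death_time"].to_numpy()) & (dt["death_time"].to_numpy() <= t)
        )
        assert nw.fractional_survival(small_population, t) == pytest.approx(expected)
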