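"""Label-dilution recursion: closed forms, backends, and Monte-Carlo checks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brdusim import (
    Efficacy,
    Grid,
    LabelDensity,
    closed_form_normal,
    conditional_density_table,
    conditional_label_density,
    heterogeneous_efficacy,
    l1_distance,
    one_division_update,
    simulate_label_content,
)


class TestEfficacy:
    def test_mixture_moments(self):
        eff = heterogeneous_efficacy((1 / 3, 2 / 3), (0.5, 1.0), 0.05)
        assert eff.mean() == pytest.approx(5 / 6)
        assert eff.variance() == pytest.approx(0.05**2 + (1 / 3) * (2 / 3) * 0.25)

    def test_rejects_bad_weights(self):
        with pytest.raises(ValueError, match="sum to 1"):
            heterogeneous_efficacy((0.5, 0.49), (0.5, 1.0), 0.05)
        with pytest.raises(ValueError):
            Efficacy.normal(1.0, -0.2)

    def test_single_component_mixture_is_plain_normal(self):
        eff = heterogeneous_efficacy((1.0,), (1.0,), 0.2)
        plain = Efficacy.normal(1.0, 0.2)
        assert eff.mean() == plain.mean() and eff.variance() == plain.variance()

    def test_gridded_requires_unit_mass(self):
        x = np.linspace(0, 2, 401)
        with pytest.raises(ValueError, match="integrate to 1"):
            Efficacy.gridded(x, np.ones_like(x))


class TestOneDivisionUpdate:
    def test_dirac_uptake_from_zero(self):
        out = one_division_update(LabelDensity.delta(0.0), Efficacy.dirac(1.0))
        assert len(out.atom_w) == 1
        assert out.atom_x[0] == pytest.approx(0.5)

    def test_normal_uptake_from_zero_halves_mean_and_sd(self):
        out = one_division_update(LabelDensity.delta(0.0), Efficacy.normal(1.0, 0.2))
        assert out.gauss_mu[0] == pytest.approx(0.5)
        assert out.gauss_sd[0] == pytest.approx(0.1)

    def test_delabeling_halves_gaussian(self):
        prior = LabelDensity(gauss_w=(1.0,), gauss_mu=(0.5,), gauss_sd=(0.1,))
        out = one_division_update(prior, Efficacy.dirac(0.0))
        assert out.gauss_mu[0] == pytest.approx(0.25)
        assert out.gauss_sd[0] == pytest.approx(0.05)

    def test_gridded_rejects_too_coarse_grid(self):
        coarse = Grid(-0.5, 1.5, 41)  # dx = 0.05
        prior = LabelDensity.delta(0.0).to_gridded(coarse)
        with pytest.raises(ValueError, match="grid too coarse"):
            one_division_update(prior, Efficacy.normal(1.0, 0.05), grid=coarse)


class TestConditionalDensity:
    def test_undivided_cell_is_point_mass_at_zero(self, noisy_efficacies):
        d = conditional_label_density((0, 0), noisy_efficacies)
        assert len(d.gauss_w) == 0
        assert d.atom_x[0] == 0.0 and d.atom_w[0] == 1.0

    def test_dirac_uptake_geometric_sum(self):
        d = conditional_label_density((2, 0), (Efficacy.dirac(1.0), Efficacy.dirac(0.0)))
        assert len(d.atom_w) == 1
        assert d.atom_x[0] == pytest.approx(0.75)  # (1 - 2^-2) * 1

    def test_uplabel_then_delabel_scales_gaussian(self, noisy_efficacies):
        d = conditional_label_density((1, 3), noisy_efficacies)
        assert len(d.gauss_w) == 1
        assert d.gauss_mu[0] == pytest.approx(0.5 / 8)
        assert d.gauss_sd[0] == pytest.approx(0.1 / 8)

    @pytest.mark.parametrize("i", range(1, 8))
    def test_dirac_special_case_single_atom(self, i):
        """Uniform uptake value reproduces the sharp-peak prediction of the
        classical single-value models."""
        d = conditional_label_density((i,), (Efficacy.dirac(1.0),))
        assert len(d.atom_w) == 1 and d.atom_w[0] == pytest.approx(1.0)
        assert d.atom_x[0] == pytest.approx(1.0 - 2.0 ** (-i))

    def test_phase_order_matters_but_is_chronological(self):
        up, down = Efficacy.dirac(1.0), Efficacy.dirac(0.0)
        chron = conditional_label_density((1, 1), (up, down))
        swapped = conditional_label_density((1, 1), (down, up))
        assert chron.atom_x[0] == pytest.approx(0.25)  # label then dilute
        assert swapped.atom_x[0] == pytest.approx(0.5)  # dilute nothing, then label

    def test_rejects_mismatched_lengths(self, noisy_efficacies):
        with pytest.raises(ValueError):
            conditional_label_density((1,), noisy_efficacies)
        with pytest.raises(ValueError):
            conditional_label_density((1,), ())

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        i1=st.integers(0, 6),
        i2=st.integers(0, 4),
        mu=st.floats(0.2, 1.5),
        sigma=st.floats(0.01, 0.4),
    )
    def test_normalization_preserved(self, i1, i2, mu, sigma):
        d = conditional_label_density((i1, i2), (Efficacy.normal(mu, sigma), Efficacy.dirac(0.0)))
        assert d.total_mass() == pytest.approx(1.0, abs=1e-8)

    def test_mixture_normalization_after_many_updates(self):
        eff = heterogeneous_efficacy((1 / 3, 2 / 3), (0.5, 1.0), 0.05)
        d = conditional_label_density((12,), (eff,))
        assert d.total_mass() == pytest.approx(1.0, abs=1e-8)

    def test_support_bound_for_bounded_efficacies(self):
        """Uptakes concentrated on [0, u_max] keep the content there too."""
        eff = heterogeneous_efficacy((1 / 3, 2 / 3), (0.5, 1.0), 0.05)
        u_max = 1.0 + 6 * 0.05
        grid = Grid(-1.0, 2.0, 3001)
        for i in (1, 3, 6):
            d = conditional_label_density((i,), (eff,)).to_gridded(grid)
            x, f = d.grid_x, d.grid_f
            outside = float(np.trapezoid(np.where((x < -0.05) | (x > u_max), f, 0.0), x))
            assert outside < 1e-6


class TestClosedFormNormal:
    def test_single_division(self):
        m, v = closed_form_normal(1, 0, 1.0, 0.2)
        assert m == pytest.approx(0.5)
        assert v == pytest.approx(0.01)  # (0.2/2)^2

    def test_mean_saturates_at_mu(self):
        m, _ = closed_form_normal(60, 0, 1.0, 0.2)
        assert m == pytest.approx(1.0, rel=1e-12)

    def test_delabeling_halves_mean_quarters_variance(self):
        m0, v0 = closed_form_normal(4, 0, 1.0, 0.2)
        m1, v1 = closed_form_normal(4, 1, 1.0, 0.2)
        assert m1 == pytest.approx(m0 / 2)
        assert v1 == pytest.approx(v0 / 4)

    @pytest.mark.parametrize("i1", range(0, 11))
    @pytest.mark.parametrize("i2", range(0, 6))
    def test_recursion_reproduces_closed_form(self, i1, i2, noisy_efficacies):
        d = conditional_label_density((i1, i2), noisy_efficacies)
        m, v = closed_form_normal(i1, i2, 1.0, 0.2)
        assert abs(d.mean() - m) < 1e-10
        assert abs(d.variance() - v) < 1e-10


class TestMonteCarlo:
    @pytest.mark.parametrize(
        "i,eff_kind",
        [
            ((3, 0), "normal"),
            ((1, 2), "normal"),
            ((6, 3), "normal"),
            ((2,), "mixture"),
            ((5,), "mixture"),
        ],
    )
    def test_density_moments_match_direct_recursion_sampling(self, i, eff_kind, rng):
        """4-standard-error agreement between the density machinery and raw
        Monte-Carlo simulation of X <- U/2 + X/2 (1e5 draws)."""
        if eff_kind == "normal":
            effs = (Efficacy.normal(1.0, 0.2), Efficacy.dirac(0.0))
        else:
            effs = (heterogeneous_efficacy((1 / 3, 2 / 3), (0.5, 1.0), 0.05),)
        n = 100_000
        draws = simulate_label_content(i, effs, n, rng)
        d = conditional_label_density(i, effs)
        se_mean = draws.std(ddof=1) / math.sqrt(n)
        assert abs(draws.mean() - d.mean()) < 4 * se_mean
        var = draws.var(ddof=1)
        m4 = np.mean((draws - draws.mean()) ** 4)
        se_var = math.sqrt(max(m4 - var**2, 0.0) / n)
        assert abs(var - d.variance()) < 4 * se_var


class TestBackendEquivalence:
    @pytest.mark.parametrize(
        "i,eff",
        [
            ((3,), Efficacy.normal(1.0, 0.2)),
            ((2,), heterogeneous_efficacy((1 / 3, 2 / 3), (0.5, 1.0), 0.05)),
        ],
    )
    def test_analytic_and_gridded_agree_in_sup_norm(self, i, eff, default_grid):
        ana = conditional_label_density(i, (eff,)).to_gridded(default_grid)
        gri = conditional_label_density(i, (eff,), backend="gridded", grid=default_grid)
        assert float(np.max(np.abs(ana.grid_f - gri.grid_f))) < 1e-3

    def test_gridded_total_mass(self, default_grid):
        eff = Efficacy.normal(1.0, 0.2)
        d = conditional_label_density((4,), (eff,), backend="gridded", grid=default_grid)
        assert d.total_mass() == pytest.approx(1.0, abs=1e-4)


class TestMixtureStructure:
    def test_one_division_from_mixture_has_two_modes(self, default_grid):
        eff = heterogeneous_efficacy((1 / 3, 2 / 3), (0.5, 1.0), 0.05)
        d = conditional_label_density((1,), (eff,)).to_gridded(default_grid)
        from scipy.signal import find_peaks

        idx, _ = find_peaks(d.grid_f, prominence=0.05 * d.grid_f.max())
        assert sorted(np.round(d.grid_x[idx], 3)) == [0.25, 0.5]
        assert d.pdf(np.array([0.25]))[0] > 0  # sd halved to 0.025

    def test_density_table_matches_direct_recursion(self):
        eff = heterogeneous_efficacy((1 / 3, 2 / 3), (0.5, 1.0), 0.05)
        table = conditional_density_table(4, (eff,))
        direct = conditional_label_density((3,), (eff,))
        assert l1_distance(table[(3,)], direct) < 1e-9


def test_l1_distance_of_identical_density_is_zero(noisy_efficacies):
    d = conditional_label_density((2, 1), noisy_efficacies)
    assert l1_distance(d, d) == pytest.approx(0.0, abs=1e-12)


def test_truncate_at_zero_removes_negative_mass(default_grid):
    d = conditional_label_density((1,), (Efficacy.normal(0.1, 0.2),))
    t = d.truncated_at_zero(default_grid)
    x, f = t.grid_x, t.grid_f
    assert float(np.trapezoid(np.where(x < 0, f, 0.0), x)) == 0.0
    assert t.total_mass() == pytest.approx(1.0, abs=1e-6)
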