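"""Synthetic population generator: measurement model, determinism, arrest pairs."""
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import cytomito as cm
from cytomito.errors import SpecError

from conftest import mode_of, pipeline_shift_2n

PURE_G2M = {"G1": 0.0, "S": 0.0, "G2M": 1.0}


class TestGeneratePopulation:
    def test_rho_zero_has_no_copies(self):
        spec = cm.PopulationSpec(n_events=2000, mito_status="rho_zero", seed=1)
        t = cm.generate_population(spec)
        assert (t.events["truth_mtdna_copies"] == 0).all()

    def test_noiseless_closed_form_signal(self):
        """With all noise off, every 2n event fluoresces gain*(N + c*s) and the
        analytic rho contrast is log2(1 + c*s/N) ~ 0.148, matching the
        published 0.15 +/- 0.03 shift."""
        spec = cm.PopulationSpec(
            n_events=500, ploidy_fractions=PURE_G2M, copies_cv=0.0,
            size_coupling_beta=0.0, measurement_cv=0.0, seed=2,
        )
        t = cm.generate_population(spec)
        # copies are integer-valued per cell: 30.8 rounds to 31
        assert (t.events["truth_mtdna_copies"] == 31).all()
        expected = spec.gain * (24.2 + 31 * 0.085)
        np.testing.assert_allclose(t.events["fluor_linear"], expected, rtol=1e-12)
        contrast = cm.expected_rho_contrast(spec)
        assert contrast == pytest.approx(np.log2(1 + 2.618 / 24.2), rel=1e-9)
        assert abs(contrast - 0.15) <= 0.03

    def test_same_seed_identical_tables(self):
        spec = cm.PopulationSpec(n_events=3000, seed=77)
        t1 = cm.generate_population(spec)
        t2 = cm.generate_population(spec)
        pd.testing.assert_frame_equal(t1.events, t2.events)

    def test_different_seeds_differ(self):
        t1 = cm.generate_population(cm.PopulationSpec(n_events=1000, seed=1))
        t2 = cm.generate_population(cm.PopulationSpec(n_events=1000, seed=2))
        assert not t1.events["fluor_linear"].equals(t2.events["fluor_linear"])

    def test_invalid_fractions_rejected(self):
        with pytest.raises(SpecError):
            cm.PopulationSpec(ploidy_fractions={"G1": 0.7, "S": 0.0, "G2M": 0.7})
        with pytest.raises(SpecError):
            cm.PopulationSpec(ploidy_fractions={"G1": -0.1, "S": 0.55, "G2M": 0.55})

    def test_g1_cells_carry_half_the_2n_copy_mean(self):
        spec = cm.PopulationSpec(
            n_events=20_000, copies_cv=0.0, size_coupling_beta=0.0, seed=3
        )
        t = cm.generate_population(spec).events
        g1 = t.loc[t["truth_ploidy_class"] == "G1", "truth_mtdna_copies"]
        g2m = t.loc[t["truth_ploidy_class"] == "G2M", "truth_mtdna_copies"]
        assert g1.mean() == pytest.approx(g2m.mean() / 2, rel=0.05)

    def test_s_phase_ndna_between_1n_and_2n(self):
        spec = cm.PopulationSpec(n_events=5000, measurement_cv=0.0, seed=4)
        t = cm.generate_population(spec).events
        g = spec.genome
        s_rows = t["truth_ploidy_class"] == "S"
        fluor_dna = t.loc[s_rows, "fluor_linear"] / spec.gain \
            - t.loc[s_rows, "truth_mtdna_copies"] * g.mtdna_size
        assert fluor_dna.between(g.ndna_1n - 1e-9, g.ndna_2n + 1e-9).all()


class TestAnalyticContrast:
    def test_pipeline_shift_converges_to_analytic_value(self):
        """At 200k events the detected 2n contrast matches log2(1 + c*s/N)
        within 0.01 log2 units."""
        common = dict(
            n_events=200_000, ploidy_fractions=PURE_G2M, copies_cv=0.0,
            measurement_cv=0.05,
        )
        plus = cm.PopulationSpec(seed=42, **common)
        zero = cm.PopulationSpec(mito_status="rho_zero", seed=43, **common)
        shift = pipeline_shift_2n(
            cm.generate_population(plus), cm.generate_population(zero)
        )
        assert shift == pytest.approx(cm.expected_rho_contrast(plus), abs=0.01)

    def test_shared_background_inflation_leaves_contrast_unbiased(self, g2m_specs):
        """Equal multiplicative background on rho+ and rho0 cancels in the
        contrast, so the copy estimate is gain-equivariant end to end."""
        plus, zero = g2m_specs
        shift0 = pipeline_shift_2n(
            cm.generate_population(plus), cm.generate_population(zero)
        )
        b = 2**0.3
        shift1 = pipeline_shift_2n(
            cm.generate_population(replace(plus, background_inflation=b)),
            cm.generate_population(replace(zero, background_inflation=b)),
        )
        assert shift1 == pytest.approx(shift0, abs=0.01)


class TestGenerateArrestPair:
    def test_null_arrest_reproduces_control_exactly(self):
        base = cm.PopulationSpec(
            n_events=3000, ploidy_fractions=PURE_G2M, size_coupling_beta=1.0, seed=21
        )
        pair = cm.generate_arrest_pair(
            cm.ArrestSpec(base=base, arrest_ploidy="2n",
                          growth_factor=1.0, accumulation_fold=1.0)
        )
        pd.testing.assert_frame_equal(pair["control"].events, pair["arrested"].events)

    def test_arrested_population_is_pure_and_larger(self, arrest_base_spec):
        pair = cm.generate_arrest_pair(
            cm.ArrestSpec(base=arrest_base_spec, arrest_ploidy="2n",
                          accumulation_fold=3.3, growth_factor=2.5)
        )
        arr = pair["arrested"].events
        assert (arr["truth_ploidy_class"] == "G2M").all()
        ratio = arr["truth_cell_size"].mean() / pair["control"].events["truth_cell_size"].mean()
        assert ratio == pytest.approx(2.5, rel=0.05)

    def test_size_coupled_fold_recovered_by_pipeline(self):
        """End-to-end: generate a 1n-arrest design at fold 3.3 and recover the
        fold from detected mode shifts within 15%."""
        g = cm.GenomeParams()
        pure_g1 = {"G1": 1.0, "S": 0.0, "G2M": 0.0}
        arrest = dict(arrest_ploidy="1n", accumulation_fold=3.3, growth_factor=2.5)
        mk = lambda status, seed: cm.PopulationSpec(
            ploidy_fractions=pure_g1, mito_status=status, measurement_cv=0.05,
            copies_cv=0.0, background_inflation=2**0.1, seed=seed,
        )
        plus = cm.generate_arrest_pair(cm.ArrestSpec(base=mk("rho_plus", 31), **arrest))
        zero = cm.generate_arrest_pair(cm.ArrestSpec(base=mk("rho_zero", 32), **arrest))

        def m1n(table):
            return mode_of(table, expected_ploidy="1n").mode_1n

        dp = m1n(plus["arrested"]) - m1n(plus["control"])
        dz = m1n(zero["arrested"]) - m1n(zero["control"])
        baseline = cm.copies_from_rho_contrast(
            m1n(plus["control"]) - m1n(zero["control"]), g, ploidy="1n"
        )
        res = cm.arrest_surplus(dp, dz, baseline, g, ploidy="1n")
        assert res.fold_change == pytest.approx(3.3, rel=0.15)

    def test_walk_dispersion_grows_copy_spread_with_size(self, arrested_walk):
        ev = arrested_walk.events
        q = ev["truth_cell_size"].quantile([0.25, 0.75])
        small = ev.loc[ev["truth_cell_size"] <= q.iloc[0], "truth_mtdna_copies"]
        large = ev.loc[ev["truth_cell_size"] >= q.iloc[1], "truth_mtdna_copies"]
        cv = lambda v: v.std() / v.mean()
        assert cv(large) > cv(small)
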