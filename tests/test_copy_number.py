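"""Copy-number arithmetic: rho contrasts, plasmid bound, arrest surplus, folds."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cytomito as cm
from cytomito.copynumber import baseline_for_ploidy
from cytomito.errors import ContractError

G = cm.GenomeParams()


class TestCopiesFromRhoContrast:
    def test_measured_2n_shift_gives_published_copy_number(self):
        """delta = 0.15 at the 2n peak -> ~31 copies, inside 30.8 +/- 6.2."""
        est = cm.copies_from_rho_contrast(0.15, G, ploidy="2n")
        assert abs(est.copies - 30.8) <= 6.2
        assert est.copies == pytest.approx(31.195, abs=0.01)

    def test_zero_shift_zero_copies(self):
        assert cm.copies_from_rho_contrast(0.0, G, ploidy="2n").copies == 0.0

    def test_signal_doubling_inversion(self):
        """delta = 1 means mtDNA mass equals nuclear mass exactly."""
        est = cm.copies_from_rho_contrast(1.0, G, ploidy="2n")
        assert est.copies * G.mtdna_size == pytest.approx(G.ndna_2n, rel=1e-12)

    def test_negative_shift_floored_with_warning(self):
        with pytest.warns(UserWarning):
            est = cm.copies_from_rho_contrast(-0.05, G, ploidy="2n")
        assert est.copies == 0.0
        assert est.clipped_negative

    def test_ploidy_uses_matching_nuclear_size(self):
        e1 = cm.copies_from_rho_contrast(0.15, G, ploidy="1n")
        e2 = cm.copies_from_rho_contrast(0.15, G, ploidy="2n")
        assert e2.copies == pytest.approx(2 * e1.copies)

    def test_wrong_shift_kind_rejected(self):
        shift = cm.ModeShift(0.2, "2n", "arrest_contrast")
        with pytest.raises(ContractError):
            cm.copies_from_rho_contrast(shift, G)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(min_value=0.0, max_value=2.0), st.floats(min_value=1e-4, max_value=2.0))
    def test_strictly_increasing_and_continuous_at_zero(self, d, eps):
        c0 = cm.copies_from_rho_contrast(d, G, ploidy="2n").copies
        c1 = cm.copies_from_rho_contrast(d + eps, G, ploidy="2n").copies
        assert c1 > c0
        near_zero = cm.copies_from_rho_contrast(1e-9, G, ploidy="2n").copies
        assert near_zero == pytest.approx(0.0, abs=1e-4)


class TestPlasmidBound:
    def test_default_bound_matches_published_value(self):
        """60 plasmids x 6.3 kb / 85 kb = 4.45 mtDNA equivalents."""
        assert cm.plasmid_equivalent_copies(G) == pytest.approx(4.45, abs=0.005)

    def test_zero_plasmids(self):
        g = cm.GenomeParams(plasmid_max_count=0)
        assert cm.plasmid_equivalent_copies(g) == 0.0

    @settings(deadline=None, max_examples=30)
    @given(
        st.integers(min_value=0, max_value=500),
        st.floats(min_value=1e-4, max_value=0.1),
        st.floats(min_value=0.01, max_value=1.0),
    )
    def test_arithmetic_oracle(self, count, unit, mt):
        g = cm.GenomeParams(mtdna_size=mt, plasmid_unit=unit, plasmid_max_count=count)
        assert cm.plasmid_equivalent_copies(g) == pytest.approx(count * unit / mt)


class TestArrestSurplus:
    def test_g1_arrest_surplus_and_fold(self):
        """Shifts (0.4, 0.1) at 1n -> surplus inside ~36 +/- 6, fold ~3.3."""
        res = cm.arrest_surplus(0.4, 0.1, 15.4, G, ploidy="1n")
        assert abs(res.surplus_copies - 36.0) <= 6.0
        assert res.fold_change == pytest.approx(3.3, abs=0.1)

    def test_equal_shifts_mean_no_accumulation(self):
        res = cm.arrest_surplus(0.25, 0.25, 20.0, G, ploidy="1n")
        assert res.surplus_copies == pytest.approx(0.0, abs=1e-12)
        assert res.fold_change == pytest.approx(1.0)

    def test_published_fold_identities(self):
        """fold = 1 + surplus/baseline reproduces ~3.3 and ~5.8."""
        assert 1 + 36 / 15.4 == pytest.approx(3.3, abs=0.1)
        assert 1 + 147 / 30.8 == pytest.approx(5.8, abs=0.1)

    def test_ratio_variant_close_to_default_for_small_shifts(self):
        d = cm.arrest_surplus(0.4, 0.1, 15.4, G, ploidy="1n", formula="background")
        r = cm.arrest_surplus(0.4, 0.1, 15.4, G, ploidy="1n", formula="ratio")
        assert abs(r.surplus_copies - 36.0) <= 6.0
        assert d.surplus_copies == pytest.approx(r.surplus_copies, rel=0.1)

    def test_mismatched_ploidy_rejected(self):
        dp = cm.ModeShift(0.4, "1n", "arrest_contrast")
        dz = cm.ModeShift(0.1, "2n", "arrest_contrast")
        with pytest.raises(ContractError):
            cm.arrest_surplus(dp, dz, 15.4, G)

    @settings(deadline=None, max_examples=50)
    @given(
        st.floats(min_value=-0.5, max_value=1.0),
        st.floats(min_value=-0.5, max_value=1.0),
    )
    def test_antisymmetric_in_shift_pair(self, a, b):
        s1 = cm.arrest_surplus(a, b, 20.0, G, ploidy="2n").surplus_copies
        s2 = cm.arrest_surplus(b, a, 20.0, G, ploidy="2n").surplus_copies
        assert s1 + s2 == pytest.approx(0.0, abs=1e-9 * max(1, abs(s1)))

    @settings(deadline=None, max_examples=50)
    @given(
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=1.0, max_value=200.0),
    )
    def test_fold_identity_invariant(self, dp, dz, baseline):
        res = cm.arrest_surplus(dp, dz, baseline, G, ploidy="2n")
        assert res.fold_change == pytest.approx(
            1.0 + res.surplus_copies / res.baseline_copies, rel=1e-12
        )


class TestAggregation:
    def test_baseline_halving_for_1n_arrest(self):
        assert baseline_for_ploidy(30.8, "1n") == pytest.approx(15.4)
        assert baseline_for_ploidy(30.8, "2n") == pytest.approx(30.8)
        assert baseline_for_ploidy(30.8, "1n", override=10.0) == 10.0

    def test_replicate_mean_sd_matches_manual(self):
        ests = [
            cm.copies_from_rho_contrast(d, G, ploidy="2n") for d in (0.13, 0.15, 0.17)
        ]
        agg = cm.aggregate_replicates(ests)
        vals = np.array([e.copies for e in ests])
        assert agg.copies == pytest.approx(vals.mean())
        assert agg.copies_sd == pytest.approx(vals.std(ddof=1))

    def test_single_replicate_has_no_sd(self):
        agg = cm.aggregate_replicates([cm.copies_from_rho_contrast(0.15, G, ploidy="2n")])
        assert agg.copies_sd is None

    def test_mixed_ploidies_rejected(self):
        with pytest.raises(ContractError):
            cm.aggregate_replicates(
                [
                    cm.copies_from_rho_contrast(0.15, G, ploidy="1n"),
                    cm.copies_from_rho_contrast(0.15, G, ploidy="2n"),
                ]
            )


class TestGenomeParams:
    def test_diploid_must_be_twice_haploid(self):
        with pytest.raises(ContractError):
            cm.GenomeParams(ndna_1n=12.1, ndna_2n=25.0)
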