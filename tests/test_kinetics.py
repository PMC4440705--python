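import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitoqc import (
    Mitochondrion,
    QCParams,
    Subcompartment,
    fission_propensity,
    fusion_pair_propensity,
    fusion_selectivity,
    mitophagy_propensity,
    oxphos_defect,
    replication_propensity_per_nucleoid,
)


def mito(w, m, comp=0):
    return Mitochondrion(chain=[Subcompartment(w, m)], compartment=comp)


NOMINAL = QCParams.nominal()


class TestOxphosDefect:
    @pytest.mark.parametrize(
        "R,K,m,expected",
        [
            (0.0, 0.75, 11.0, 0.0),
            (0.6, 0.75, 11.0, 0.6**11 / (0.75**11 + 0.6**11)),  # ~0.0791
            (1.0, 0.75, 11.0, 1.0 / (1.0 + 0.75**11)),  # ~0.9595
        ],
    )
    def test_values(self, R, K, m, expected):
        assert oxphos_defect(R, K, m) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(0.05, 1.0), st.floats(1.0, 20.0))
    @settings(max_examples=50, deadline=None)
    def test_midpoint_is_half_for_any_threshold(self, K, m):
        assert oxphos_defect(K, K, m) == pytest.approx(0.5)

    def test_strictly_increasing(self):
        grid = np.linspace(0, 1, 101)
        vals = [oxphos_defect(r, 0.75, 11.0) for r in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1.0  # approaches but never reaches 1

    def test_domain_error(self):
        with pytest.raises(ValueError):
            oxphos_defect(1.2, 0.75, 11.0)


class TestMitophagy:
    def test_baseline_and_amplification(self, nominal):
        assert mitophagy_propensity(0.0, nominal) == pytest.approx(0.023)
        # at the threshold midpoint s = 0.5
        assert mitophagy_propensity(0.75, nominal) == pytest.approx(0.023 * 3.5)
        # the upper bound (r_D_max + 1) k_D is approached as s -> 1
        bound = nominal.k_D * (nominal.r_D_max + 1.0)
        assert mitophagy_propensity(1.0, nominal) < bound
        assert mitophagy_propensity(1.0, nominal) == pytest.approx(bound, rel=0.05)

    @given(st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_bounded(self, R):
        a = mitophagy_propensity(R, NOMINAL)
        assert NOMINAL.k_D <= a <= NOMINAL.k_D * (NOMINAL.r_D_max + 1.0)


class TestReplication:
    def test_basal_per_nucleoid_rate(self, nominal):
        r = replication_propensity_per_nucleoid(False, 0.0, nominal)
        assert r == pytest.approx(7.4 / 320)
        # a homoplasmic WT cell at N_ss nucleoids totals a_R0
        assert 320 * r == pytest.approx(nominal.a_R0)

    def test_retrograde_amplification_bound(self, nominal):
        # as s -> 1 the per-nucleoid rate approaches (r_R_max + 1) a_R0/N_ss
        r = replication_propensity_per_nucleoid(False, 1.0, nominal)
        assert r == pytest.approx(10 * 7.4 / 320, rel=0.05)

    def test_mutant_replicative_advantage(self, nominal):
        p = nominal.with_(k_R=2.0)
        wt = replication_propensity_per_nucleoid(False, 0.0, p)
        mut = replication_propensity_per_nucleoid(True, 0.0, p)
        assert mut == pytest.approx(2.0 * wt)
        assert mut == pytest.approx(2.0 * 7.4 / 320)


class TestFusion:
    def test_selectivity_examples(self, nominal):
        assert fusion_selectivity(0.0, nominal) == pytest.approx(1.0)
        assert fusion_selectivity(0.75, nominal) == pytest.approx(0.6)  # 1 - 0.8/2
        full = nominal.with_(r_fusion_max=1.0)
        assert fusion_selectivity(1.0, full) == pytest.approx(0.0, abs=0.05)

    def test_pair_propensity_examples(self, nominal):
        healthy = fusion_pair_propensity(mito(4, 0), mito(3, 0, 1), nominal)
        assert healthy == pytest.approx(0.123)
        scaled = nominal.with_(ff_scale=0.25)
        assert fusion_pair_propensity(mito(4, 0), mito(3, 0, 1), scaled) == (
            pytest.approx(0.03075)
        )

    def test_defective_partner_reduces_propensity(self, nominal):
        a = fusion_pair_propensity(mito(4, 0), mito(0, 4, 1), nominal)
        assert a < 0.123 * 0.25  # one partner near-fully selected against


class TestFission:
    def test_hill_midpoint(self, nominal):
        assert fission_propensity(mito(30, 0), nominal) == pytest.approx(4.3e4)

    def test_small_content_value(self, nominal):
        expected = 8.6e4 * 4**6 / (30**6 + 4**6)
        assert fission_propensity(mito(4, 0), nominal) == pytest.approx(expected)
        assert expected == pytest.approx(0.483, rel=1e-3)

    def test_single_nucleoid_clamped_to_zero(self, nominal):
        assert fission_propensity(mito(1, 0), nominal) == 0.0

    def test_monotone_in_content(self, nominal):
        vals = [fission_propensity(mito(t, 0), nominal) for t in range(2, 40)]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestFrequencyScaling:
    def test_ff_scale_preserves_fusion_fission_ratio(self, nominal):
        a, b = mito(4, 0), mito(5, 1, 1)
        for s in (0.25, 1.0, 4.0):
            p = nominal.with_(ff_scale=s)
            ratio = fusion_pair_propensity(a, b, p) / fission_propensity(b, p)
            base = fusion_pair_propensity(a, b, nominal) / fission_propensity(
                b, nominal
            )
            assert ratio == pytest.approx(base)
        assert nominal.alpha == pytest.approx(8.6e4 / 0.123)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            QCParams(r_fusion_max=1.5)
        with pytest.raises(ValueError):
            QCParams(k_R=0.5)
        with pytest.raises(ValueError):
            QCParams(ff_scale=0.0)
        with pytest.raises(ValueError):
            QCParams(K_D=0.0)

    def test_threshold_helper_sets_all_midpoints(self, nominal):
        p = nominal.with_threshold(0.6)
        assert p.K_D == p.K_fusion == p.K_R == 0.6
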