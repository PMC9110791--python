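"""Kinetic forward models and scalar physiology."""

import numpy as np
import pytest

from aslhemo.exceptions import DomainError
from aslhemo.signal_models import (AcquisitionParams, BloodProperties,
                                   arterial_oxygen_content,
                                   pasl_kinetic_signal, pcasl_kinetic_signal,
                                   pcasl_single_ti_cbf, t1_blood)


class TestAcquisitionParams:
    def test_protocol_defaults(self, multi_acq, single_acq):
        assert single_acq.lambda_partition == 0.9
        assert single_acq.alpha_efficiency == 0.85
        assert single_acq.tau_bolus == 1.8
        assert single_acq.post_labeling_delay == 1.5
        assert multi_acq.lambda_partition == 0.9
        assert multi_acq.alpha_efficiency == 0.98
        assert multi_acq.tau_bolus == 0.7
        tis = np.asarray(multi_acq.inflow_times)
        assert tis.size == 10
        assert tis[0] == pytest.approx(0.350)
        assert tis[-1] == pytest.approx(2.600)
        assert np.allclose(np.diff(tis), 0.250)

    def test_invalid_inflow_times_rejected(self):
        with pytest.raises(DomainError):
            AcquisitionParams.multi_ti_pasl(inflow_times=[0.5, 0.5, 1.0])
        with pytest.raises(DomainError):
            AcquisitionParams(sequence_kind="single_ti_pcasl",
                              post_labeling_delay=None)


class TestPaslKineticSignal:
    @pytest.mark.parametrize("t,expected", [
        (0.35, 0.0),                       # before arrival: no label delivered
        (1.0, 0.002635148683154789),       # on the inflow ramp (hand-evaluated)
        (2.0, 0.005580006896517126),       # past the bolus (hand-evaluated)
    ])
    def test_piecewise_values(self, t, expected, multi_acq, blood_sca):
        value = pasl_kinetic_signal(t, 60.0, 0.8, multi_acq, blood_sca,
                                    m0_tissue=1.0)
        assert value == pytest.approx(expected, rel=1e-12)

    def test_zero_flow_gives_zero_signal(self, multi_acq, blood_sca):
        for t in (0.1, 0.9, 2.5):
            assert pasl_kinetic_signal(t, 0.0, 0.8, multi_acq, blood_sca) == 0.0

    def test_linear_in_cbf(self, multi_acq, blood_sca):
        s1 = pasl_kinetic_signal(1.2, 30.0, 0.8, multi_acq, blood_sca)
        s2 = pasl_kinetic_signal(1.2, 60.0, 0.8, multi_acq, blood_sca)
        assert s2 == pytest.approx(2 * s1, rel=1e-12)

    @pytest.mark.parametrize("model", ["simplified", "single_compartment"])
    def test_continuous_at_breakpoints(self, model, multi_acq, blood_sca):
        bat, tau = 0.8, multi_acq.tau_bolus
        eps = 1e-9
        for edge in (bat, bat + tau):
            lo = pasl_kinetic_signal(edge - eps, 60, bat, multi_acq, blood_sca,
                                     model=model)
            hi = pasl_kinetic_signal(edge + eps, 60, bat, multi_acq, blood_sca,
                                     model=model)
            assert hi == pytest.approx(lo, abs=1e-7)

    def test_vanishes_at_long_times(self, multi_acq, blood_sca):
        assert pasl_kinetic_signal(40.0, 60, 0.8, multi_acq, blood_sca) < 1e-10

    def test_tissue_model_reduces_to_simplified_when_rates_match(
            self, multi_acq, blood_sca):
        # choose tissue T1 so the apparent tissue rate equals the blood rate
        f = 60.0 / 6000.0
        t1_tissue = 1.0 / (1.0 / blood_sca.t1_blood - f / 0.9)
        for t in (0.9, 1.2, 2.2):
            simple = pasl_kinetic_signal(t, 60, 0.8, multi_acq, blood_sca)
            full = pasl_kinetic_signal(t, 60, 0.8, multi_acq, blood_sca,
                                       model="single_compartment",
                                       t1_tissue=t1_tissue)
            assert full == pytest.approx(simple, rel=1e-9)

    def test_domain_errors(self, multi_acq, single_acq, blood_sca):
        with pytest.raises(DomainError):
            pasl_kinetic_signal(-0.1, 60, 0.8, multi_acq, blood_sca)
        with pytest.raises(DomainError):
            pasl_kinetic_signal(1.0, -5, 0.8, multi_acq, blood_sca)
        with pytest.raises(DomainError):
            pasl_kinetic_signal(1.0, 60, -0.8, multi_acq, blood_sca)
        with pytest.raises(DomainError):
            pasl_kinetic_signal(1.0, 60, 0.8, single_acq, blood_sca)
        with pytest.raises(DomainError):
            BloodProperties(t1_blood=-1.0)


class TestPcaslQuantification:
    def test_zero_difference_gives_zero_cbf(self, single_acq, blood_sca):
        assert pcasl_single_ti_cbf(0.0, 100.0, single_acq, blood_sca) == 0.0

    def test_linearity(self, single_acq, blood_sca):
        c1 = pcasl_single_ti_cbf(0.5, 100.0, single_acq, blood_sca)
        c2 = pcasl_single_ti_cbf(1.0, 100.0, single_acq, blood_sca)
        c3 = pcasl_single_ti_cbf(1.0, 200.0, single_acq, blood_sca)
        assert c2 == pytest.approx(2 * c1, rel=1e-12)
        assert c3 == pytest.approx(c1, rel=1e-12)

    def test_closed_form_oracle(self, single_acq):
        blood = BloodProperties(t1_blood=1.65)
        cbf = pcasl_single_ti_cbf(0.01, 1.0, single_acq, blood)
        assert cbf == pytest.approx(71.95281023767554, rel=1e-12)

    def test_nonpositive_m0(self, single_acq, blood_sca):
        with pytest.raises(DomainError):
            pcasl_single_ti_cbf(0.5, 0.0, single_acq, blood_sca)
        out = pcasl_single_ti_cbf(np.array([0.5, 0.5]), np.array([100.0, 0.0]),
                                  single_acq, blood_sca)
        assert np.isfinite(out[0]) and np.isnan(out[1])

    def test_forward_model_round_trip_when_bolus_arrived(self, single_acq,
                                                         blood_sca):
        # at readout, any arrival earlier than the PLD cancels exactly
        t_read = single_acq.readout_time
        for bat in (0.2, 0.8, 1.49):
            dm = pcasl_kinetic_signal(t_read, 47.0, bat, single_acq, blood_sca,
                                      m0_tissue=100.0)
            cbf = pcasl_single_ti_cbf(dm, 100.0, single_acq, blood_sca)
            assert cbf == pytest.approx(47.0, rel=1e-10)

    def test_late_arrival_attenuates_signal(self, single_acq, blood_sca):
        t_read = single_acq.readout_time
        dm_early = pcasl_kinetic_signal(t_read, 47.0, 1.0, single_acq,
                                        blood_sca, m0_tissue=100.0)
        dm_late = pcasl_kinetic_signal(t_read, 47.0, 1.9, single_acq,
                                       blood_sca, m0_tissue=100.0)
        assert dm_late < dm_early


class TestBloodT1:
    def test_monotone_decreasing_in_hematocrit(self):
        sats = 0.97
        values = [t1_blood(h, sats) for h in (0.2, 0.3, 0.4, 0.5)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_plausibility_bands(self):
        # low (anemic) hematocrit -> long T1; normal hematocrit -> shorter
        assert t1_blood(0.25, 0.97) == pytest.approx(1.99, abs=0.15)
        assert t1_blood(0.41, 0.98) == pytest.approx(1.77, abs=0.15)

    def test_domain_errors(self):
        for hct, sat in ((0.0, 0.97), (1.0, 0.97), (0.4, 0.0), (0.4, 1.5)):
            with pytest.raises(DomainError):
                t1_blood(hct, sat)

    def test_blood_properties_computes_t1(self):
        blood = BloodProperties(hematocrit=0.25, oxygen_saturation=0.97)
        assert blood.t1_blood == pytest.approx(t1_blood(0.25, 0.97))


class TestArterialOxygenContent:
    @pytest.mark.parametrize("hb,sat,po2,expected", [
        (0.0, 1.0, 100.0, 0.3),          # only the dissolved term remains
        (13.5, 0.98, 100.0, 18.0282),    # hand-evaluated
        (13.5, 0.0, 100.0, 0.3),         # bound term vanishes
    ])
    def test_values(self, hb, sat, po2, expected):
        assert arterial_oxygen_content(hb, sat, po2) == pytest.approx(expected)

    def test_additive_and_homogeneous(self, rng):
        hb, sat = 12.0, 0.95
        bound = arterial_oxygen_content(hb, sat, 0.0)
        dissolved = arterial_oxygen_content(0.0, sat, 80.0)
        assert arterial_oxygen_content(hb, sat, 80.0) == pytest.approx(
            bound + dissolved)
        assert arterial_oxygen_content(2 * hb, sat, 0.0) == pytest.approx(
            2 * bound)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            arterial_oxygen_content(-1.0, 0.97)
        with pytest.raises(DomainError):
            arterial_oxygen_content(12.0, 1.2)
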