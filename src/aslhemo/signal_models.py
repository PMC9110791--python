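"""Forward signal models and scalar physiology for arterial spin labeling.

This module holds the kinetic models and calculators every later stage builds
on:

* the pulsed-ASL (PASL) difference-signal curve with a Q2TIPS-bounded bolus,
  used for voxel-wise fitting of cerebral blood flow (CBF) and bolus arrival
  time (BAT) from multi-inflow-time data;
* the (pseudo-)continuous-ASL forward curve and the standard single-delay
  pCASL quantification formula;
* the longitudinal relaxation time of blood as a function of hematocrit and
  oxygen saturation;
* arterial oxygen content (CaO2).

Conventions: CBF is expressed externally in ml/100g/min; times in seconds;
difference signals in the units of the proton-density (M0) image they are
normalised against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .exceptions import DomainError

__all__ = [
    "SINGLE_TI_PCASL",
    "MULTI_TI_PASL",
    "CBF_UNIT_SCALE",
    "DEFAULT_T1_BLOOD_CALIBRATION",
    "AcquisitionParams",
    "BloodProperties",
    "KineticCurve",
    "pasl_kinetic_signal",
    "pcasl_kinetic_signal",
    "pcasl_single_ti_cbf",
    "t1_blood",
    "arterial_oxygen_content",
]

SINGLE_TI_PCASL = "single_ti_pcasl"
MULTI_TI_PASL = "multi_ti_pasl"

#: ml/100g/min -> ml/g/s conversion factor (the only place this lives).
CBF_UNIT_SCALE = 6000.0

#: Fast-exchange two-pool calibration of blood R1 = 1/T1 at 3 T:
#:   R1 = (1 - Hct) * r1_plasma + Hct * (r1_ery_oxy + r1_deoxy_per_desat * (1 - SaO2))
#: Coefficients in 1/s; chosen to reproduce published 3 T blood T1 behaviour
#: (T1 falls with hematocrit and, weakly, with desaturation).
DEFAULT_T1_BLOOD_CALIBRATION: Mapping[str, float] = {
    "r1_plasma": 0.3965,
    "r1_ery_oxy": 0.7815,
    "r1_deoxy_per_desat": 1.30,
}


def _default_inflow_times() -> tuple[float, ...]:
    # 350-2600 ms in 250 ms steps: 10 inflow times.
    return tuple(np.round(np.arange(0.350, 2.601, 0.250), 3))


@dataclass(frozen=True)
class AcquisitionParams:
    """Sequence constants for one ASL protocol.

    Parameters
    ----------
    sequence_kind : {"single_ti_pcasl", "multi_ti_pasl"}
    lambda_partition : blood-brain partition coefficient (ml/g), 0.9 for both
        protocols.
    alpha_efficiency : labeling efficiency (fraction).
    tau_bolus : label/bolus duration (s): 1.8 for the pCASL protocol, 0.7 for
        the Q2TIPS-bounded PASL bolus.
    post_labeling_delay : s, single-TI pCASL only.
    inflow_times : ordered inflow times (s), multi-TI PASL only.
    """

    sequence_kind: str
    lambda_partition: float = 0.9
    alpha_efficiency: float = 0.85
    tau_bolus: float = 1.8
    post_labeling_delay: float | None = None
    inflow_times: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.sequence_kind not in (SINGLE_TI_PCASL, MULTI_TI_PASL):
            raise DomainError(f"unknown sequence_kind: {self.sequence_kind!r}")
        if not (0 < self.lambda_partition <= 2):
            raise DomainError("lambda_partition out of range")
        if not (0 < self.alpha_efficiency <= 1):
            raise DomainError("alpha_efficiency must be in (0, 1]")
        if self.tau_bolus <= 0:
            raise DomainError("tau_bolus must be positive")
        if self.sequence_kind == SINGLE_TI_PCASL:
            if self.post_labeling_delay is None or self.post_labeling_delay <= 0:
                raise DomainError("single-TI pCASL requires a positive post_labeling_delay")
        else:
            if self.inflow_times is None or len(self.inflow_times) < 2:
                raise DomainError("multi-TI PASL requires >= 2 inflow_times")
            tis = np.asarray(self.inflow_times, dtype=float)
            if np.any(np.diff(tis) <= 0):
                raise DomainError("inflow_times must be strictly increasing")
            if np.any(tis <= 0):
                raise DomainError("inflow_times must be positive")

    @classmethod
    def single_ti_pcasl(cls, *, lambda_partition: float = 0.9,
                        alpha_efficiency: float = 0.85, tau_bolus: float = 1.8,
                        post_labeling_delay: float = 1.5) -> "AcquisitionParams":
        """The single-delay pCASL protocol (λ=0.9, α=0.85, τ=1.8 s, PLD=1.5 s)."""
        return cls(SINGLE_TI_PCASL, lambda_partition, alpha_efficiency,
                   tau_bolus, post_labeling_delay, None)

    @classmethod
    def multi_ti_pasl(cls, *, lambda_partition: float = 0.9,
                      alpha_efficiency: float = 0.98, tau_bolus: float = 0.7,
                      inflow_times: Sequence[float] | None = None) -> "AcquisitionParams":
        """The multi-inflow-time PASL protocol (λ=0.9, α=0.98, τ=0.7 s, 10 TIs)."""
        tis = tuple(inflow_times) if inflow_times is not None else _default_inflow_times()
        return cls(MULTI_TI_PASL, lambda_partition, alpha_efficiency,
                   tau_bolus, None, tis)

    @property
    def readout_time(self) -> float:
        """Time of the single-TI readout from the start of labeling (τ + PLD)."""
        if self.sequence_kind != SINGLE_TI_PCASL:
            raise DomainError("readout_time is defined for the single-TI protocol only")
        return self.tau_bolus + float(self.post_labeling_delay)

    def with_(self, **kwargs) -> "AcquisitionParams":
        return replace(self, **kwargs)


def t1_blood(hematocrit, oxygen_saturation,
             coefficients: Mapping[str, float] | None = None):
    """Blood T1 (s) at 3 T from hematocrit and oxygen saturation.

    Uses a fast-exchange two-pool relaxation model: whole-blood R1 is the
    hematocrit-weighted average of plasma R1 and erythrocyte R1, with the
    erythrocyte rate increasing linearly with desaturation. Monotonically
    decreasing in hematocrit (erythrocytes relax faster than plasma).
    """
    coeff = dict(DEFAULT_T1_BLOOD_CALIBRATION if coefficients is None else coefficients)
    hct = np.asarray(hematocrit, dtype=float)
    sat = np.asarray(oxygen_saturation, dtype=float)
    if np.any(hct <= 0) or np.any(hct >= 1):
        raise DomainError("hematocrit must be a fraction in (0, 1)")
    if np.any(sat <= 0) or np.any(sat > 1):
        raise DomainError("oxygen_saturation must be a fraction in (0, 1]")
    r1 = (1.0 - hct) * coeff["r1_plasma"] + hct * (
        coeff["r1_ery_oxy"] + coeff["r1_deoxy_per_desat"] * (1.0 - sat))
    out = 1.0 / r1
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class BloodProperties:
    """Hematology of one subject and the derived blood T1.

    ``t1_blood`` may be given directly (e.g. a protocol assumption) or is
    computed from hematocrit and saturation via :func:`t1_blood`.
    """

    hemoglobin: float | None = None          # g/dl
    oxygen_saturation: float | None = None   # fraction
    hematocrit: float | None = None          # fraction
    po2: float = 100.0                       # Torr, room-air arterial assumption
    t1_blood: float | None = None            # s
    t1_calibration: Mapping[str, float] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.t1_blood is None:
            if self.hematocrit is None or self.oxygen_saturation is None:
                raise DomainError(
                    "t1_blood not given and hematocrit/oxygen_saturation missing")
            object.__setattr__(
                self, "t1_blood",
                t1_blood(self.hematocrit, self.oxygen_saturation, self.t1_calibration))
        if self.t1_blood <= 0:
            raise DomainError("t1_blood must be positive")
        if self.po2 < 0:
            raise DomainError("po2 must be non-negative")

    @property
    def cao2(self) -> float:
        """Arterial oxygen content (ml O2/dl); needs hemoglobin and saturation."""
        if self.hemoglobin is None or self.oxygen_saturation is None:
            raise DomainError("cao2 requires hemoglobin and oxygen_saturation")
        return arterial_oxygen_content(self.hemoglobin, self.oxygen_saturation, self.po2)


@dataclass(frozen=True)
class KineticCurve:
    """A sampled PASL difference curve with its generating ground truth."""

    times: tuple[float, ...]
    delta_m: tuple[float, ...]
    cbf_true: float
    bat_true: float


def _validate_kinetics(t, cbf, bat, blood: BloodProperties) -> None:
    if np.any(np.asarray(t, dtype=float) < 0):
        raise DomainError("t must be non-negative")
    if np.any(np.asarray(cbf, dtype=float) < 0):
        raise DomainError("cbf must be non-negative")
    if np.any(np.asarray(bat, dtype=float) < 0):
        raise DomainError("bat must be non-negative")
    if blood.t1_blood is None or blood.t1_blood <= 0:
        raise DomainError("t1_blood must be positive")


def pasl_kinetic_signal(t, cbf, bat, params: AcquisitionParams,
                        blood: BloodProperties, m0_tissue=1.0,
                        model: str = "simplified", t1_tissue: float = 1.3):
    """PASL difference signal ΔM(t) of the general kinetic model.

    The default ``model="simplified"`` keeps the label relaxing with blood T1
    throughout (delivery factor 1), which is the identifiable choice for
    arrival-time-centric fitting:

    * ``t < bat``:            0
    * ``bat <= t < bat+τ``:   2·M0_blood·f·α·(t−bat)·exp(−t/T1_blood)
    * ``t >= bat+τ``:         2·M0_blood·f·α·τ·exp(−t/T1_blood)

    with ``M0_blood = m0_tissue / λ`` and ``f = cbf / 6000`` (ml/g/s).

    ``model="single_compartment"`` applies the tissue-exchange delivery factor
    with apparent tissue relaxation ``1/T1' = 1/t1_tissue + f/λ``; it reduces
    to the simplified form as the blood and apparent tissue rates coincide.

    The curve is continuous in ``t`` and exactly linear in ``cbf``.
    """
    _validate_kinetics(t, cbf, bat, blood)
    if params.sequence_kind != MULTI_TI_PASL:
        raise DomainError("pasl_kinetic_signal requires multi-TI PASL params")
    t = np.asarray(t, dtype=float)
    cbf = np.asarray(cbf, dtype=float)
    bat = np.asarray(bat, dtype=float)
    m0 = np.asarray(m0_tissue, dtype=float)
    t, cbf, bat, m0 = np.broadcast_arrays(t, cbf, bat, m0)

    lam = params.lambda_partition
    tau = params.tau_bolus
    alpha = params.alpha_efficiency
    t1b = float(blood.t1_blood)
    f = cbf / CBF_UNIT_SCALE
    m0_blood = m0 / lam
    amp = 2.0 * m0_blood * f * alpha * np.exp(-t / t1b)

    in_ramp = (t >= bat) & (t < bat + tau)
    in_tail = t >= bat + tau

    if model == "simplified":
        ramp = amp * (t - bat)
        tail = amp * tau
    elif model == "single_compartment":
        with np.errstate(divide="ignore"):
            r1_app = 1.0 / t1_tissue + f / lam
        k = 1.0 / t1b - r1_app
        k_safe = np.where(np.abs(k) < 1e-12, 1.0, k)
        dt_ = t - bat
        # delivery-corrected forms; expm1 keeps the k -> 0 limit exact
        ramp_corr = np.where(np.abs(k) < 1e-12, dt_, np.expm1(k_safe * dt_) / k_safe)
        tail_corr = np.where(
            np.abs(k) < 1e-12, tau,
            np.exp(k_safe * dt_) * -np.expm1(-k_safe * tau) / k_safe)
        ramp = amp * ramp_corr
        tail = amp * tail_corr
    else:
        raise DomainError(f"unknown kinetic model variant: {model!r}")

    out = np.where(in_ramp, ramp, np.where(in_tail, tail, 0.0))
    return float(out) if out.ndim == 0 else out


def pcasl_kinetic_signal(t, cbf, bat, params: AcquisitionParams,
                         blood: BloodProperties, m0_tissue=1.0):
    """(p)CASL difference signal ΔM(t) with arrival time, blood-T1 decay only.

    * ``t < bat``:            0
    * ``bat <= t < bat+τ``:   2·M0b·f·α·T1b·exp(−bat/T1b)·(1 − exp(−(t−bat)/T1b))
    * ``t >= bat+τ``:         plateau value · exp(−(t−bat−τ)/T1b)

    Evaluated at the readout time ``τ + PLD`` with ``bat <= PLD`` this equals
    the standard single-delay quantification model exactly (the arrival time
    cancels); for ``bat > PLD`` part of the bolus has not arrived at readout
    and the signal — hence any CBF computed from it — is reduced.
    """
    _validate_kinetics(t, cbf, bat, blood)
    if params.sequence_kind != SINGLE_TI_PCASL:
        raise DomainError("pcasl_kinetic_signal requires single-TI pCASL params")
    t = np.asarray(t, dtype=float)
    cbf = np.asarray(cbf, dtype=float)
    bat = np.asarray(bat, dtype=float)
    m0 = np.asarray(m0_tissue, dtype=float)
    t, cbf, bat, m0 = np.broadcast_arrays(t, cbf, bat, m0)

    lam, tau, alpha = params.lambda_partition, params.tau_bolus, params.alpha_efficiency
    t1b = float(blood.t1_blood)
    f = cbf / CBF_UNIT_SCALE
    amp = 2.0 * (m0 / lam) * f * alpha * t1b * np.exp(-bat / t1b)
    ramp = amp * -np.expm1(-(t - bat) / t1b)
    tail = amp * -np.expm1(-tau / t1b) * np.exp(-(t - bat - tau) / t1b)
    out = np.where((t >= bat) & (t < bat + tau), ramp,
                   np.where(t >= bat + tau, tail, 0.0))
    return float(out) if out.ndim == 0 else out


def pcasl_single_ti_cbf(delta_m, m0, params: AcquisitionParams,
                        blood: BloodProperties):
    """Single-delay pCASL CBF (ml/100g/min) from the mean difference signal.

    cbf = 6000·λ·ΔM·exp(PLD/T1b) / (2·α·T1b·M0·(1 − exp(−τ/T1b)))

    Zero-preserving and linear in ``delta_m / m0``. For scalar input a
    non-positive ``m0`` raises; for array input those voxels become NaN so a
    map-level caller can flag rather than abort.
    """
    if params.sequence_kind != SINGLE_TI_PCASL:
        raise DomainError("pcasl_single_ti_cbf requires single-TI pCASL params")
    lam, tau, alpha = params.lambda_partition, params.tau_bolus, params.alpha_efficiency
    pld = float(params.post_labeling_delay)
    t1b = float(blood.t1_blood)
    dm = np.asarray(delta_m, dtype=float)
    m0a = np.asarray(m0, dtype=float)
    scalar = dm.ndim == 0 and m0a.ndim == 0
    if scalar and m0a <= 0:
        raise DomainError("m0 must be positive")
    denom = 2.0 * alpha * t1b * m0a * -np.expm1(-tau / t1b)
    with np.errstate(divide="ignore", invalid="ignore"):
        cbf = CBF_UNIT_SCALE * lam * dm * np.exp(pld / t1b) / denom
    cbf = np.where(m0a > 0, cbf, np.nan)
    return float(cbf) if cbf.ndim == 0 else cbf


def arterial_oxygen_content(hemoglobin, oxygen_saturation, po2=100.0):
    """Arterial oxygen content CaO2 = 1.34·Hb·SaO2 + 0.003·pO2 (ml O2/dl).

    Hemoglobin in g/dl, saturation as a fraction in [0, 1], pO2 in Torr
    (default 100, the room-air arterial assumption).
    """
    hb = np.asarray(hemoglobin, dtype=float)
    sat = np.asarray(oxygen_saturation, dtype=float)
    p = np.asarray(po2, dtype=float)
    if np.any(hb < 0) or np.any(p < 0):
        raise DomainError("hemoglobin and po2 must be non-negative")
    if np.any((sat < 0) | (sat > 1)):
        raise DomainError("oxygen_saturation must be in [0, 1]")
    out = 1.34 * hb * sat + 0.003 * p
    return float(out) if out.ndim == 0 else out
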