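"""Voxel-wise hemodynamic parameter estimation.

Multi-TI PASL series are fit per voxel for (CBF, BAT) by least squares
against the kinetic forward model. The model is linear in CBF, so for any
candidate arrival time the optimal CBF has a closed form (a projection onto
the unit-CBF basis curve); the fit therefore reduces to a one-dimensional
profiled search over BAT. An exhaustive coarse BAT grid (the objective is
multimodal in BAT at low SNR) seeds a dense local refinement with parabolic
interpolation, ties broken toward the smallest BAT. This is deterministic
given the inputs.

Single-TI pCASL maps apply the closed-form quantification voxel-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError, GridMismatchError
from .signal_models import (MULTI_TI_PASL, SINGLE_TI_PCASL, AcquisitionParams,
                            BloodProperties, pasl_kinetic_signal,
                            pcasl_single_ti_cbf)

__all__ = ["HemodynamicMaps", "fit_multi_ti", "quantify_single_ti",
           "MultiTIFitter", "CBF_BOUNDS", "BAT_BOUNDS"]

#: Fit bounds: CBF in ml/100g/min, BAT in s (covers observed late-arrival
#: medians with headroom).
CBF_BOUNDS = (0.0, 400.0)
BAT_BOUNDS = (0.1, 3.0)


@dataclass
class HemodynamicMaps:
    """Voxel-wise hemodynamic maps; undefined voxels carry NaN."""

    cbf: np.ndarray                      # ml/100g/min
    bat: np.ndarray | None               # s; None for single-TI maps
    fit_quality: np.ndarray | None       # residual sum of squares (signal units)
    reliability: np.ndarray | None       # uint8 mask the fit was restricted to
    n_fit: int = 0                       # voxels with a defined estimate
    n_low_signal: int = 0                # voxels flagged at the CBF=0 bound
    meta: dict = field(default_factory=dict)


def _unit_basis(times: np.ndarray, bats: np.ndarray,
                params: AcquisitionParams, blood: BloodProperties,
                model: str) -> np.ndarray:
    """Model curves at unit CBF and unit M0: shape (len(bats), len(times))."""
    return np.asarray(pasl_kinetic_signal(
        times[np.newaxis, :], 1.0, bats[:, np.newaxis], params, blood,
        m0_tissue=1.0, model=model))


def _profile_rss(y: np.ndarray, basis: np.ndarray, yy: np.ndarray,
                 cbf_bounds: tuple[float, float]):
    """Optimal clipped CBF and RSS for each voxel x candidate BAT.

    ``y``: (n_vox, n_t) m0-normalised signals, ``basis``: (n_bat, n_t).
    """
    gg = np.einsum("bt,bt->b", basis, basis)
    numer = y @ basis.T                                   # (n_vox, n_bat)
    with np.errstate(divide="ignore", invalid="ignore"):
        cbf = numer / gg[np.newaxis, :]
    cbf = np.clip(np.nan_to_num(cbf), *cbf_bounds)
    rss = yy[:, np.newaxis] - 2.0 * cbf * numer + cbf ** 2 * gg[np.newaxis, :]
    return cbf, rss


def fit_multi_ti(diff_series: np.ndarray, m0: np.ndarray,
                 params: AcquisitionParams, blood: BloodProperties,
                 mask: np.ndarray,
                 cbf_bounds: tuple[float, float] = CBF_BOUNDS,
                 bat_bounds: tuple[float, float] = BAT_BOUNDS,
                 coarse_bat_step: float = 0.05,
                 n_refine: int = 41,
                 model: str = "simplified") -> HemodynamicMaps:
    """Fit (CBF, BAT) per reliable voxel from a multi-TI difference series.

    Parameters
    ----------
    diff_series : 4D array (x, y, z, TI), one volume per inflow time.
    m0 : proton-density volume on the same grid; voxels with ``m0 <= 0`` are
        undefined (NaN) in the output.
    mask : reliability mask restricting the fit.
    coarse_bat_step : spacing of the exhaustive BAT seed grid (s).
    n_refine : points of the dense local BAT grid spanning +/- one coarse step.

    Returns maps with NaN outside the fitted set; voxels whose best fit sits
    at the CBF=0 bound are flagged low-signal and get ``bat = NaN`` (arrival
    time is unidentifiable without signal).
    """
    if params.sequence_kind != MULTI_TI_PASL:
        raise DomainError("fit_multi_ti requires multi-TI PASL params")
    series = np.asarray(diff_series, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    mask = np.asarray(mask).astype(bool)
    times = np.asarray(params.inflow_times, dtype=float)
    if series.ndim != 4 or series.shape[3] != times.size:
        raise GridMismatchError("series length must equal the number of inflow times")
    if m0.shape != series.shape[:3] or mask.shape != series.shape[:3]:
        raise GridMismatchError("m0/mask grid does not match the series grid")
    if not mask.any():
        raise DomainError("reliability mask is empty")

    valid = mask & (m0 > 0)
    shape = series.shape[:3]
    cbf_map = np.full(shape, np.nan)
    bat_map = np.full(shape, np.nan)
    rss_map = np.full(shape, np.nan)
    if not valid.any():
        return HemodynamicMaps(cbf_map, bat_map, rss_map,
                               mask.astype(np.uint8), 0, 0)

    y = series[valid, :] / m0[valid][:, np.newaxis]
    yy = np.einsum("nt,nt->n", y, y)
    n_vox = y.shape[0]

    # exhaustive coarse profile over BAT
    bats = np.arange(bat_bounds[0], bat_bounds[1] + 1e-9, coarse_bat_step)
    basis = _unit_basis(times, bats, params, blood, model)
    _, rss = _profile_rss(y, basis, yy, cbf_bounds)
    best = rss.argmin(axis=1)            # first minimum -> smallest BAT on ties

    # dense local refinement around the coarse seed
    offsets = np.linspace(-coarse_bat_step, coarse_bat_step, n_refine)
    fine_bats = np.clip(bats[best][:, np.newaxis] + offsets[np.newaxis, :],
                        *bat_bounds)                       # (n_vox, n_refine)
    fine_cbf = np.empty_like(fine_bats)
    fine_rss = np.empty_like(fine_bats)
    for j in range(n_refine):
        g = np.asarray(pasl_kinetic_signal(
            times[np.newaxis, :], 1.0, fine_bats[:, j][:, np.newaxis],
            params, blood, m0_tissue=1.0, model=model))
        gg = np.einsum("nt,nt->n", g, g)
        numer = np.einsum("nt,nt->n", y, g)
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.clip(np.nan_to_num(numer / gg), *cbf_bounds)
        fine_cbf[:, j] = c
        fine_rss[:, j] = yy - 2.0 * c * numer + c ** 2 * gg

    jbest = fine_rss.argmin(axis=1)
    rows = np.arange(n_vox)
    bat_hat = fine_bats[rows, jbest]
    cbf_hat = fine_cbf[rows, jbest]
    rss_hat = fine_rss[rows, jbest]

    # one parabolic step through the fine minimum where it is interior
    interior = (jbest > 0) & (jbest < n_refine - 1)
    if interior.any():
        r0 = fine_rss[rows, np.maximum(jbest - 1, 0)]
        r1 = rss_hat
        r2 = fine_rss[rows, np.minimum(jbest + 1, n_refine - 1)]
        denom = r0 - 2.0 * r1 + r2
        ok = interior & (denom > 0)
        if ok.any():
            h = offsets[1] - offsets[0]
            shift = 0.5 * h * (r0 - r2) / np.where(denom == 0, 1.0, denom)
            bat_par = np.clip(bat_hat + np.where(ok, shift, 0.0), *bat_bounds)
            g = np.asarray(pasl_kinetic_signal(
                times[np.newaxis, :], 1.0, bat_par[:, np.newaxis],
                params, blood, m0_tissue=1.0, model=model))
            gg = np.einsum("nt,nt->n", g, g)
            numer = np.einsum("nt,nt->n", y, g)
            with np.errstate(divide="ignore", invalid="ignore"):
                c = np.clip(np.nan_to_num(numer / gg), *cbf_bounds)
            rss_par = yy - 2.0 * c * numer + c ** 2 * gg
            take = ok & (rss_par < rss_hat)
            bat_hat = np.where(take, bat_par, bat_hat)
            cbf_hat = np.where(take, c, cbf_hat)
            rss_hat = np.where(take, rss_par, rss_hat)

    low_signal = cbf_hat <= 0.0
    bat_hat = np.where(low_signal, np.nan, bat_hat)
    # back to signal units for the quality map
    rss_signal = rss_hat * m0[valid] ** 2

    cbf_map[valid] = cbf_hat
    bat_map[valid] = bat_hat
    rss_map[valid] = rss_signal
    return HemodynamicMaps(
        cbf=cbf_map, bat=bat_map, fit_quality=rss_map,
        reliability=mask.astype(np.uint8),
        n_fit=int(valid.sum()), n_low_signal=int(low_signal.sum()),
        meta={"model": model, "coarse_bat_step": coarse_bat_step,
              "bat_bounds": bat_bounds, "cbf_bounds": cbf_bounds})


def quantify_single_ti(diff_mean: np.ndarray, m0: np.ndarray,
                       params: AcquisitionParams, blood: BloodProperties,
                       mask: np.ndarray | None = None) -> HemodynamicMaps:
    """Single-TI pCASL CBF map from the repetition-mean difference volume.

    Applies the closed-form quantification voxel-wise; there is no arrival
    parameter (``bat`` is None). Voxels with ``m0 <= 0`` (or outside an
    optional mask) carry NaN.
    """
    if params.sequence_kind != SINGLE_TI_PCASL:
        raise DomainError("quantify_single_ti requires single-TI pCASL params")
    dm = np.asarray(diff_mean, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    if dm.shape != m0.shape:
        raise GridMismatchError("diff_mean and m0 grids differ")
    cbf = np.asarray(pcasl_single_ti_cbf(dm, m0, params, blood))
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != dm.shape:
            raise GridMismatchError("mask grid does not match diff_mean")
        cbf = np.where(mask, cbf, np.nan)
    return HemodynamicMaps(cbf=cbf, bat=None, fit_quality=None,
                           reliability=None if mask is None
                           else mask.astype(np.uint8),
                           n_fit=int(np.isfinite(cbf).sum()))


class MultiTIFitter:
    """Thin reusable wrapper around :func:`fit_multi_ti` with fixed settings."""

    def __init__(self, params: AcquisitionParams, blood: BloodProperties,
                 **options):
        self.params = params
        self.blood = blood
        self.options = options

    def fit(self, diff_series, m0, mask) -> HemodynamicMaps:
        return fit_multi_ti(diff_series, m0, self.params, self.blood, mask,
                            **self.options)
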