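"""Synthetic study generator: ASL phantoms, FLAIR with lesions, and a
two-group cohort table with known ground truth.

The phantoms are piecewise-constant digital objects on the acquisition grid
(default 64 x 64 x 24): a gray-matter shell with fast arrival, an
early-arrival white-matter core, and a late-arrival white-matter pocket
emulating an individual watershed area (sized to ~30% of the eroded white
matter so the percentile rule has a well-defined target). Image corners
carry no signal, only noise, so background-noise estimation is exercised.
Noise is additive Gaussian on the difference images (background-suppressed
ASL difference noise is approximately Gaussian); the default SD gives a
peak gray-matter difference-signal SNR of roughly 15.

Compartment defaults reflect a sickle-cell-anemia (SCA) vs control study:
elevated CBF and shortened arrival times in patients, late watershed
arrival near 1.5 s (SCA) / 1.9 s (control) — longer than a 1.5 s
post-labeling delay, which is what makes the single-delay sequence
underestimate watershed CBF.

The cohort generator draws hematology, cognition, lesion burden and ROI
summary values from group-specific distributions matching the study-scale
summary table, plants a mediation triple (watershed CBF -> watershed FA ->
processing speed) with configurable path coefficients, and leaves a few
hemoglobin/saturation values missing to exercise group-mean substitution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import DomainError
from .roi import RoiSet, erode_mask
from .signal_models import (AcquisitionParams, BloodProperties,
                            pasl_kinetic_signal, pcasl_kinetic_signal)

__all__ = ["PhantomSpec", "CohortSpec", "MultiTIPhantom", "SingleTIPhantom",
           "FlairPhantom", "make_phantom_multiti", "make_phantom_singleti",
           "make_flair_with_lesions", "make_cohort", "default_blood",
           "GROUP_TABLES"]

# ---------------------------------------------------------------------------
# phantom geometry and specs

#: Per-compartment (CBF ml/100g/min, BAT s) defaults by group, single-TI scale
#: CBF magnitudes with arrival times from the study-scale summary table.
_COMPARTMENTS = {
    "sca": {"gm": (54.0, 0.72), "wm_early": (34.0, 0.74), "iwsa": (24.0, 1.51)},
    "control": {"gm": (43.0, 0.82), "wm_early": (26.0, 0.85), "iwsa": (17.0, 1.86)},
}

#: Typical hematology by group (hematocrit, oxygen saturation, hemoglobin g/dl).
_HEMATOLOGY = {"sca": (0.25, 0.97, 8.8), "control": (0.41, 0.98, 13.2)}


def default_blood(group: str = "sca") -> BloodProperties:
    hct, sat, hb = _HEMATOLOGY[group]
    return BloodProperties(hemoglobin=hb, oxygen_saturation=sat, hematocrit=hct)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, true parameters and noise level of a digital ASL phantom."""

    shape: tuple[int, int, int] = (64, 64, 24)
    group: str = "sca"
    compartments: Mapping[str, tuple[float, float]] | None = None
    m0_value: float = 100.0
    noise_sd: float = 0.05          # M0 units, on each difference volume
    erosion_width: int = 2
    iwsa_fraction: float = 0.30     # of eroded WM, the percentile complement
    n_repeats_single_ti: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in _COMPARTMENTS:
            raise DomainError(f"unknown group {self.group!r}")
        if min(self.shape) < 12:
            raise DomainError("phantom grid too small")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")

    @property
    def params(self) -> Mapping[str, tuple[float, float]]:
        return dict(self.compartments or _COMPARTMENTS[self.group])

    def with_(self, **kwargs) -> "PhantomSpec":
        return replace(self, **kwargs)


def _box(shape, xfrac, yfrac, zfrac) -> np.ndarray:
    nx, ny, nz = shape
    m = np.zeros(shape, dtype=bool)
    m[int(round(xfrac[0] * nx)):int(round(xfrac[1] * nx)),
      int(round(yfrac[0] * ny)):int(round(yfrac[1] * ny)),
      int(round(zfrac[0] * nz)):int(round(zfrac[1] * nz))] = True
    return m


def phantom_geometry(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Disjoint compartment masks: gm shell, early-WM core, late-WM pocket.

    The pocket is a central box sized so it occupies ~``iwsa_fraction`` of
    the *eroded* white matter, i.e. the planted target of the percentile
    segmentation; it always sits strictly inside the eroded core.
    """
    shape = spec.shape
    brain = _box(shape, (0.19, 0.81), (0.19, 0.81), (0.17, 0.83))
    wm = _box(shape, (0.25, 0.75), (0.25, 0.75), (0.25, 0.75))
    gm = brain & ~wm
    wm_eroded = erode_mask(wm, spec.erosion_width)
    # bounding box of the eroded core
    idx = np.argwhere(wm_eroded)
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
    depth = hi[2] - lo[2]
    target = spec.iwsa_fraction * wm_eroded.sum()
    side = max(2, int(round(np.sqrt(target / depth))))
    side = min(side, hi[0] - lo[0] - 2, hi[1] - lo[1] - 2)
    cx, cy = (lo[0] + hi[0]) // 2, (lo[1] + hi[1]) // 2
    pocket = np.zeros(shape, dtype=bool)
    pocket[cx - side // 2: cx - side // 2 + side,
           cy - side // 2: cy - side // 2 + side,
           lo[2]:hi[2]] = True
    pocket &= wm_eroded
    assert not (gm & wm).any()
    return {"brain": brain, "gm": gm, "wm": wm, "wm_eroded": wm_eroded,
            "iwsa": pocket, "wm_early": wm & ~pocket}


def _truth_maps(spec: PhantomSpec, geo: dict[str, np.ndarray]):
    cbf = np.zeros(spec.shape)
    bat = np.zeros(spec.shape)
    params = spec.params
    for name, region in (("gm", geo["gm"]), ("wm_early", geo["wm_early"]),
                         ("iwsa", geo["iwsa"])):
        c, b = params[name]
        cbf[region] = c
        bat[region] = b
    truth_cbf = np.where(geo["brain"], cbf, np.nan)
    truth_bat = np.where(geo["brain"], bat, np.nan)
    return cbf, bat, truth_cbf, truth_bat


@dataclass
class MultiTIPhantom:
    diff_series: np.ndarray
    m0: np.ndarray
    truth_cbf: np.ndarray
    truth_bat: np.ndarray
    masks: dict[str, np.ndarray]
    spec: PhantomSpec
    blood: BloodProperties
    acq: AcquisitionParams


@dataclass
class SingleTIPhantom:
    diff_mean: np.ndarray
    m0: np.ndarray
    truth_cbf: np.ndarray
    truth_bat: np.ndarray
    masks: dict[str, np.ndarray]
    spec: PhantomSpec
    blood: BloodProperties
    acq: AcquisitionParams


def make_phantom_multiti(spec: PhantomSpec | None = None,
                         acq: AcquisitionParams | None = None,
                         blood: BloodProperties | None = None) -> MultiTIPhantom:
    """Multi-TI PASL difference series + M0 + truth maps from a spec."""
    spec = spec or PhantomSpec()
    acq = acq or AcquisitionParams.multi_ti_pasl()
    blood = blood or default_blood(spec.group)
    geo = phantom_geometry(spec)
    cbf, bat, truth_cbf, truth_bat = _truth_maps(spec, geo)
    m0 = np.where(geo["brain"], spec.m0_value, 0.0)
    times = np.asarray(acq.inflow_times)
    series = np.stack([
        np.asarray(pasl_kinetic_signal(t, cbf, bat, acq, blood, m0_tissue=m0))
        for t in times], axis=-1)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        series = series + rng.normal(0.0, spec.noise_sd, series.shape)
    return MultiTIPhantom(series, m0, truth_cbf, truth_bat, geo, spec, blood, acq)


def make_phantom_singleti(spec: PhantomSpec | None = None,
                          acq: AcquisitionParams | None = None,
                          blood: BloodProperties | None = None) -> SingleTIPhantom:
    """Repetition-mean single-TI pCASL difference volume + M0 + truth maps.

    The forward model is arrival-time aware, so compartments whose true BAT
    exceeds the post-labeling delay produce an attenuated difference signal
    — the mechanism behind single-delay CBF underestimation in late-arrival
    territory. For BAT <= PLD it reduces exactly to the closed-form
    quantification model (noiseless round trips are exact). Noise SD is
    scaled by 1/sqrt(n_repeats) for the repetition mean.
    """
    spec = spec or PhantomSpec()
    acq = acq or AcquisitionParams.single_ti_pcasl()
    blood = blood or default_blood(spec.group)
    geo = phantom_geometry(spec)
    cbf, bat, truth_cbf, truth_bat = _truth_maps(spec, geo)
    m0 = np.where(geo["brain"], spec.m0_value, 0.0)
    diff = np.asarray(pcasl_kinetic_signal(
        acq.readout_time, cbf, bat, acq, blood, m0_tissue=m0))
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        diff = diff + rng.normal(0.0, spec.noise_sd / np.sqrt(spec.n_repeats_single_ti),
                                 diff.shape)
    return SingleTIPhantom(diff, m0, truth_cbf, truth_bat, geo, spec, blood, acq)


# ---------------------------------------------------------------------------
# FLAIR + lesions

@dataclass
class FlairPhantom:
    flair: np.ndarray
    cortex_mask: np.ndarray
    seed_masks: list[np.ndarray]
    truth_roi: RoiSet
    truth_counts: dict[str, int]
    spec: PhantomSpec


def make_flair_with_lesions(spec: PhantomSpec | None = None,
                            n_lesions_iwsa: int = 2,
                            n_lesions_early: int = 2,
                            lesion_size: int = 3,
                            cortex_intensity: float = 100.0,
                            wm_intensity: float = 92.0,
                            intensity_sd: float = 2.0,
                            lesion_factor: float = 1.10) -> FlairPhantom:
    """FLAIR volume with hyperintense lesions planted in known ROI classes.

    Lesion cores are set to ``lesion_factor`` x the cortical baseline — above
    the 1.02 x cortical-mean threshold — while their generous seed masks
    extend one voxel into normal-intensity tissue, so thresholding trims the
    seeds back to the planted cores. Truth counts are relative to the truth
    white-matter partition (pocket = watershed class).
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed + 1)
    geo = phantom_geometry(spec)
    flair = np.zeros(spec.shape)
    flair[geo["gm"]] = rng.normal(cortex_intensity, intensity_sd, int(geo["gm"].sum()))
    flair[geo["wm"]] = rng.normal(wm_intensity, intensity_sd, int(geo["wm"].sum()))

    wm_eroded = geo["wm_eroded"]
    pocket = geo["iwsa"]
    early_eroded = wm_eroded & ~pocket
    truth_roi = RoiSet(wm_eroded=wm_eroded, iwsa=pocket, wm_early=early_eroded,
                       bat_threshold=float("nan"))

    def plant(region: np.ndarray, count: int) -> list[np.ndarray]:
        # deterministic candidate centres: spread along the region's extent
        idx = np.argwhere(ndimage.binary_erosion(
            region, structure=np.ones((lesion_size + 2,) * 3)))
        if idx.size == 0:
            idx = np.argwhere(region)
        masks = []
        for i in range(count):
            c = idx[(i + 1) * len(idx) // (count + 1)]
            core = np.zeros(spec.shape, dtype=bool)
            h = lesion_size // 2
            core[c[0] - h:c[0] - h + lesion_size,
                 c[1] - h:c[1] - h + lesion_size,
                 c[2] - h:c[2] - h + lesion_size] = True
            core &= region
            masks.append(core)
        return masks

    cores = plant(pocket, n_lesions_iwsa) + plant(early_eroded, n_lesions_early)
    seed_masks = []
    all_cores = np.zeros(spec.shape, dtype=bool)
    for core in cores:
        flair[core] = cortex_intensity * lesion_factor
        all_cores |= core
        # generous masks stay within white matter, as drawn on FLAIR
        seed_masks.append(ndimage.binary_dilation(core, np.ones((3, 3, 3)))
                          & geo["wm"])
    n_iwsa = int((all_cores & pocket).sum())
    n_early = int((all_cores & early_eroded).sum())
    truth_counts = {"total": n_iwsa + n_early, "n_iwsa": n_iwsa,
                    "n_wm_early": n_early, "n_unclassified": 0}
    return FlairPhantom(flair=flair, cortex_mask=geo["gm"], seed_masks=seed_masks,
                        truth_roi=truth_roi, truth_counts=truth_counts, spec=spec)


# ---------------------------------------------------------------------------
# cohort table

#: Group-wise generative parameters: normal (mean, sd) unless noted.
GROUP_TABLES = {
    "sca": {
        "n": 94, "p_male": 46 / 94, "age": (16.7, 4.3),
        "hemoglobin": (8.8, 1.2), "saturation": (0.97, 0.015),
        "iq": (92.63, 13.44), "wmi": (91.73, 13.69), "psi_mean": 89.49,
        "lesion_prevalence": 45 / 94, "lesion_burden_lognorm": (np.log(75.0), 1.36),
        "sti_gm_cbf": (54.06, 7.78), "sti_wm_early_cbf": (34.12, 4.82),
        "sti_iwsa_cbf": (24.11, 4.41),
        "mti_gm_cbf": (129.02, 22.26), "mti_wm_early_cbf": (73.80, 14.55),
        "mti_iwsa_cbf": (59.54, 14.61),
        "mti_gm_bat": (0.72, 0.067), "mti_wm_early_bat": (0.74, 0.074),
        "mti_iwsa_bat": (1.51, 0.245),
        "fa_base": 0.395, "p_transfusion": 7 / 94, "p_hydroxycarbamide": 34 / 94,
    },
    "control": {
        "n": 42, "p_male": 16 / 42, "age": (17.6, 4.3),
        "hemoglobin": (13.2, 1.0), "saturation": (0.98, 0.010),
        "iq": (98.10, 12.00), "wmi": (99.24, 13.48), "psi_mean": 97.55,
        "lesion_prevalence": 10 / 42, "lesion_burden_lognorm": (np.log(15.0), 1.24),
        "sti_gm_cbf": (42.52, 7.13), "sti_wm_early_cbf": (26.08, 4.85),
        "sti_iwsa_cbf": (16.85, 3.95),
        "mti_gm_cbf": (89.62, 11.83), "mti_wm_early_cbf": (49.52, 8.39),
        "mti_iwsa_cbf": (55.13, 13.14),
        "mti_gm_bat": (0.82, 0.089), "mti_wm_early_bat": (0.85, 0.074),
        "mti_iwsa_bat": (1.86, 0.252),
        "fa_base": 0.410, "p_transfusion": 0.0, "p_hydroxycarbamide": 0.0,
    },
}

#: Wechsler composite scores are bounded.
COGNITIVE_BOUNDS = (40.0, 160.0)


@dataclass(frozen=True)
class CohortSpec:
    """Sample sizes, planted mediation paths and missingness of a cohort."""

    n_sca: int = 94
    n_control: int = 42
    a_path: float = -0.000375    # watershed CBF -> FA (FA units per ml/100g/min)
    b_path: float = 160.0        # FA -> processing speed (points per FA unit)
    direct: float = -0.16        # CBF -> processing speed, direct (points per ml/100g/min)
    fa_noise_sd: float = 0.02
    psi_noise_sd: float = 12.1
    missing_hemoglobin_sca: int = 4
    missing_saturation_control: int = 7
    seed: int = 0

    @property
    def indirect(self) -> float:
        """Planted indirect effect a*b."""
        return self.a_path * self.b_path


def _trunc_normal(rng, mean, sd, n, lo=None, hi=None):
    x = rng.normal(mean, sd, n)
    if lo is not None or hi is not None:
        x = np.clip(x, lo, hi)
    return x


def _one_group(rng: np.random.Generator, spec: CohortSpec, group: str,
               n: int) -> pd.DataFrame:
    g = GROUP_TABLES[group]
    df = pd.DataFrame({
        "group": "SCA" if group == "sca" else "control",
        "age": _trunc_normal(rng, *g["age"], n, 8.0, 30.0),
        "sex": np.where(rng.random(n) < g["p_male"], "male", "female"),
        "education_decile": np.clip(np.round(rng.normal(5.5, 2.0, n)), 1, 10).astype(int),
        "hemoglobin": _trunc_normal(rng, *g["hemoglobin"], n, 4.0, 18.0),
        "oxygen_saturation": _trunc_normal(rng, *g["saturation"], n, 0.80, 1.0),
        "iq": np.clip(rng.normal(*g["iq"], n), *COGNITIVE_BOUNDS),
        "wmi": np.clip(rng.normal(*g["wmi"], n), *COGNITIVE_BOUNDS),
        "etiv": rng.normal(1450.0, 130.0, n),
        "chronic_transfusion": rng.random(n) < g["p_transfusion"],
        "hydroxycarbamide": rng.random(n) < g["p_hydroxycarbamide"],
    })
    df["hematocrit"] = np.clip(0.03 * df["hemoglobin"]
                               + rng.normal(0, 0.01, n), 0.15, 0.55)
    for col in ("sti_gm_cbf", "sti_wm_early_cbf", "sti_iwsa_cbf",
                "mti_gm_cbf", "mti_wm_early_cbf", "mti_iwsa_cbf",
                "mti_gm_bat", "mti_wm_early_bat", "mti_iwsa_bat"):
        df[col] = np.clip(rng.normal(*g[col], n), 1e-3, None)

    # planted mediation triple on the multi-TI watershed CBF
    cbf = df["mti_iwsa_cbf"].to_numpy()
    mu_cbf = g["mti_iwsa_cbf"][0]
    fa = (g["fa_base"] + spec.a_path * (cbf - mu_cbf)
          + rng.normal(0, spec.fa_noise_sd, n))
    df["iwsa_fa"] = np.clip(fa, 0.05, 0.8)
    psi = (g["psi_mean"] + spec.direct * (cbf - mu_cbf)
           + spec.b_path * (df["iwsa_fa"].to_numpy() - g["fa_base"])
           + rng.normal(0, spec.psi_noise_sd, n))
    df["psi"] = np.clip(psi, *COGNITIVE_BOUNDS)

    lesion = rng.random(n) < g["lesion_prevalence"]
    mu, sigma = g["lesion_burden_lognorm"]
    burden = np.where(lesion, np.round(rng.lognormal(mu, sigma, n)), 0.0)
    df["lesion_present"] = lesion
    df["lesion_burden"] = burden.astype(int)
    return df


def make_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Two-group subject table with planted effects; deterministic per seed.

    ``hemoglobin`` is missing for a few patients and ``oxygen_saturation``
    for a few controls (counts per spec) so that group-mean substitution is
    exercised downstream; CaO2 is deliberately *not* precomputed here.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    sca = _one_group(rng, spec, "sca", spec.n_sca)
    ctl = _one_group(rng, spec, "control", spec.n_control)
    if spec.missing_hemoglobin_sca:
        idx = rng.choice(spec.n_sca, size=min(spec.missing_hemoglobin_sca, spec.n_sca),
                         replace=False)
        sca.loc[sca.index[idx], "hemoglobin"] = np.nan
    if spec.missing_saturation_control:
        idx = rng.choice(spec.n_control,
                         size=min(spec.missing_saturation_control, spec.n_control),
                         replace=False)
        ctl.loc[ctl.index[idx], "oxygen_saturation"] = np.nan
    df = pd.concat([sca, ctl], ignore_index=True)
    df.insert(0, "subject_id", [f"sub-{i + 1:03d}" for i in range(len(df))])
    return df
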