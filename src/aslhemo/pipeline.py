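"""End-to-end orchestration of a synthetic study.

``run_pipeline`` executes the full chain from one seeded configuration:

    simulate -> background/reliability -> multi-TI (CBF, BAT) fit and
    single-TI quantification -> mask erosion and watershed segmentation ->
    FLAIR lesion burden -> cohort statistics (group tests with FDR,
    regression, bootstrap mediation)

and writes tidy TSVs, NIfTI maps and a JSON provenance record. The run is
deterministic: the same configuration (and hence seed) produces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .cohort_stats import (bh_fdr, compare_groups, correlate, fit_regression,
                           mediate_bootstrap, phi_2x2, prepare_cohort,
                           adjust_age_sex)
from .exceptions import AslHemoError
from .fitting import fit_multi_ti, quantify_single_ti
from .io import write_json, write_nifti, write_table
from .lesions import flair_threshold, lesion_burden
from .reliability import estimate_background, reliable_voxel_mask
from .roi import erode_mask, segment_iwsa, summarize_roi
from .signal_models import AcquisitionParams
from .synthetic import (default_blood, make_cohort, make_flair_with_lesions,
                        make_phantom_multiti, make_phantom_singleti)

__all__ = ["run_pipeline"]

#: variable -> FDR family for the between-group comparisons
COMPARISON_FAMILIES = {
    "cao2": "hematology", "iq": "cognitive", "wmi": "cognitive",
    "psi": "cognitive", "lesion_burden": "lesions",
    "sti_gm_cbf": "sti_cbf", "sti_wm_early_cbf": "sti_cbf",
    "sti_iwsa_cbf": "sti_cbf",
    "mti_gm_cbf": "mti_cbf", "mti_wm_early_cbf": "mti_cbf",
    "mti_iwsa_cbf": "mti_cbf",
    "mti_gm_bat": "mti_bat", "mti_wm_early_bat": "mti_bat",
    "mti_iwsa_bat": "mti_bat",
}

REGRESSION_PREDICTORS = ["mti_iwsa_cbf", "iwsa_fa", "lesion_burden", "cao2",
                         "age", "male", "chronic_transfusion",
                         "hydroxycarbamide", "etiv", "education_decile"]


def _roi_rows(subject, roi_set, gm_eroded, maps_by_sequence):
    rows = []
    rois = {"gm": gm_eroded, "wm_early": roi_set.wm_early, "iwsa": roi_set.iwsa}
    for sequence, maps in maps_by_sequence.items():
        params = {"cbf": maps.cbf}
        if maps.bat is not None:
            params["bat"] = maps.bat
        for roi_name, roi_mask in rois.items():
            for pname, vol in params.items():
                value, n = summarize_roi(vol, roi_mask)
                rows.append({"subject": subject, "roi": roi_name,
                             "parameter": pname, "sequence": sequence,
                             "mean": value, "n_voxels": n})
    return rows


def run_pipeline(config: RunConfig) -> dict:
    """Run the synthetic study end to end; returns the results bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config.to_dict()}
    errors: list[str] = []

    try:
        # ---- simulate -----------------------------------------------------
        blood = default_blood(config.group)
        acq_multi = AcquisitionParams.multi_ti_pasl()
        acq_single = AcquisitionParams.single_ti_pcasl()
        phantom = make_phantom_multiti(config.phantom, acq_multi, blood)
        phantom_sti = make_phantom_singleti(config.phantom, acq_single, blood)
        flair = make_flair_with_lesions(config.phantom)
        cohort = make_cohort(config.cohort)

        # ---- reliability --------------------------------------------------
        noise = estimate_background(phantom.diff_series,
                                    roi_width=config.background_roi_width)
        rel_mask = reliable_voxel_mask(phantom.diff_series, noise)

        # ---- fitting ------------------------------------------------------
        maps_multi = fit_multi_ti(phantom.diff_series, phantom.m0, acq_multi,
                                  blood, rel_mask, model=config.kinetic_model)
        maps_single = quantify_single_ti(phantom_sti.diff_mean, phantom_sti.m0,
                                         acq_single, blood,
                                         mask=phantom.masks["brain"])

        # ---- ROIs ---------------------------------------------------------
        gm_eroded = erode_mask(phantom.masks["gm"], config.erosion_width)
        wm_eroded = erode_mask(phantom.masks["wm"], config.erosion_width)
        roi_set = segment_iwsa(maps_multi.bat, wm_eroded,
                               percentile=config.iwsa_percentile)
        roi_set.gm_eroded = gm_eroded

        # ---- lesions ------------------------------------------------------
        thr = flair_threshold(flair.flair, flair.cortex_mask,
                              factor=config.flair_factor)
        burden = lesion_burden(flair.flair, flair.seed_masks, thr, roi_set,
                               reliability=rel_mask)

        # ---- subject-level outputs ---------------------------------------
        affine = np.diag([1.7, 1.7, 4.0, 1.0])
        maps_dir = out / "maps"
        write_nifti(maps_dir / "mti_cbf.nii", maps_multi.cbf, affine)
        write_nifti(maps_dir / "mti_bat.nii", maps_multi.bat, affine)
        write_nifti(maps_dir / "mti_quality.nii", maps_multi.fit_quality, affine)
        write_nifti(maps_dir / "sti_cbf.nii", maps_single.cbf, affine)
        write_nifti(maps_dir / "reliability.nii", rel_mask, affine)
        write_nifti(maps_dir / "iwsa.nii", roi_set.iwsa, affine)
        write_nifti(maps_dir / "wm_early.nii", roi_set.wm_early, affine)
        write_nifti(maps_dir / "lesion_burden.nii", burden.burden_mask, affine)

        subject = f"phantom-{config.group}"
        roi_rows = _roi_rows(subject, roi_set, gm_eroded,
                             {"multi_ti": maps_multi, "single_ti": maps_single})
        roi_df = pd.DataFrame(roi_rows)
        write_table(out / "roi_summary.tsv", roi_df)
        write_table(out / "lesion_burden.tsv", pd.DataFrame([{
            "subject": subject, "total_voxels": burden.total_voxels,
            "n_wm_early": burden.n_wm_early, "n_iwsa": burden.n_iwsa,
            "n_unclassified": burden.n_unclassified,
            "proportion_iwsa": burden.proportion_iwsa,
            "flair_threshold": thr}]))

        bundle.update(phantom=phantom, phantom_sti=phantom_sti,
                      flair=flair, noise=noise, reliability=rel_mask,
                      maps_multi=maps_multi, maps_single=maps_single,
                      roi_set=roi_set, burden=burden, roi_summary=roi_df)

        # ---- cohort statistics -------------------------------------------
        cohort = prepare_cohort(cohort)
        cohort["male"] = (cohort["sex"] == "male").astype(float)
        write_table(out / "cohort.tsv", cohort)
        sca = cohort[cohort["group"] == "SCA"]
        ctl = cohort[cohort["group"] == "control"]

        comparisons = []
        for var, family in COMPARISON_FAMILIES.items():
            res = compare_groups(sca[var], ctl[var], variable=var, family=family)
            comparisons.append(res)
        p_adj = bh_fdr([r.p_raw for r in comparisons],
                       [r.family for r in comparisons])
        for r, p in zip(comparisons, p_adj):
            r.p_fdr = float(p)
        comp_df = pd.DataFrame([dataclasses.asdict(r) for r in comparisons])
        write_table(out / "group_comparisons.tsv", comp_df)

        lesion_table = [[int(sca["lesion_present"].sum()),
                         int((~sca["lesion_present"]).sum())],
                        [int(ctl["lesion_present"].sum()),
                         int((~ctl["lesion_present"]).sum())]]
        phi = phi_2x2(lesion_table)

        # correlations with CaO2, within patients, FDR across parameter maps
        corr_rows = []
        for var, family in COMPARISON_FAMILIES.items():
            if family not in ("sti_cbf", "mti_cbf", "mti_bat"):
                continue
            adj = adjust_age_sex(sca[var].to_numpy(), sca["age"].to_numpy(),
                                 sca["male"].to_numpy())
            res = correlate(sca["cao2"].to_numpy(), adj)
            corr_rows.append({"variable": var, "family": family,
                              "method": res.method, "r": res.r,
                              "p_raw": res.p, "n": res.n})
        corr_df = pd.DataFrame(corr_rows)
        corr_df["p_fdr"] = bh_fdr(corr_df["p_raw"], corr_df["family"])
        write_table(out / "correlations.tsv", corr_df)

        regression = fit_regression(sca, "psi", REGRESSION_PREDICTORS)
        reg_df = regression.table.reset_index(names="predictor")
        write_table(out / "regression_psi.tsv", reg_df)

        med = mediate_bootstrap(
            sca["mti_iwsa_cbf"].to_numpy(), sca["iwsa_fa"].to_numpy(),
            sca["psi"].to_numpy(),
            covariates=np.column_stack([sca["age"], sca["male"]]),
            n_boot=config.n_boot, seed=config.seed)
        write_json(out / "mediation.json", {
            "a_path": med.a_path, "b_path": med.b_path, "direct": med.direct,
            "total": med.total, "indirect": med.indirect,
            "ci_low": med.ci_low, "ci_high": med.ci_high,
            "p_indirect": med.p_indirect,
            "proportion_mediated": med.proportion_mediated,
            "n": med.n, "n_boot": med.n_boot, "seed": med.seed})

        bundle.update(cohort=cohort, comparisons=comp_df, lesion_phi=phi,
                      correlations=corr_df, regression=regression,
                      mediation=med)
    except AslHemoError as exc:       # preserve partial results with a manifest
        errors.append(str(exc))

    write_json(out / "provenance.json", {
        "package": "aslhemo", "version": __version__,
        "seed": config.seed, "config": config.to_dict(),
        "config_hash": config.config_hash,
        "n_fit": getattr(bundle.get("maps_multi"), "n_fit", None),
        "n_low_signal": getattr(bundle.get("maps_multi"), "n_low_signal", None),
        "errors": errors})
    bundle["errors"] = errors
    return bundle
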