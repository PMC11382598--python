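"""End-to-end single-subject QC: run every detector and summary on a phantom
(or user-supplied datasets), assemble the review dictionary, and write the
HTML report directory.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import correlations, motion, regress, report, tsnr, warns
from .io import Dataset3D, Dataset4D, Mask3D, ReviewDict, sig6, write_review_dict
from .synthetic import SimSpec, phantom_suite
from .timeseries import detrend_dataset, legendre_basis, polort_for_run

__all__ = ["run_subject_qc", "run_phantom_qc"]

_VERSION_FIELDS = {"QC tool": "fmriqc", "QC tool version": "0.1.0"}


def _regress_residuals(epi: Dataset4D, mp, ideal, mask: Mask3D):
    """OLS residuals of in-mask series against drift + motion (+ stimulus)
    regressors; returns (errts Dataset4D, n_regressors excluding drift DC)."""
    T = epi.n_volumes
    cols = []
    start = 0
    for rl in epi.run_lengths:
        order = polort_for_run(rl, epi.tr)
        basis = legendre_basis(rl, order)
        block = np.zeros((T, basis.shape[1]))
        block[start:start + rl] = basis
        cols.append(block)
        start += rl
    X = np.hstack(cols + [mp.values])
    n_drift = sum(c.shape[1] for c in cols)
    n_stim = 0
    if ideal is not None:
        X = np.hstack([X, ideal.series])
        n_stim = ideal.n_stim
    data = epi.values.reshape(-1, T)
    beta, *_ = np.linalg.lstsq(X, data.T, rcond=None)
    resid = (data.T - X @ beta).T.reshape(epi.shape)
    errts = Dataset4D(resid, epi.voxel_size, epi.tr, epi.affine, epi.run_lengths)
    return errts, {"n_drift": n_drift, "n_motion": mp.values.shape[1],
                   "n_stim": n_stim}


def run_subject_qc(epi: Dataset4D, anat: Dataset3D, mask: Mask3D, mp,
                   out_dir, subject: str = "sub-000", atlas: Dataset3D = None,
                   template: Dataset3D = None, ideal=None,
                   seed_coords_mm=None, limits=None) -> dict:
    """Run the full QC battery on one subject's datasets.

    Returns a dict with the review dictionary, censor vector, warning items,
    and the report path.  ``seed_coords_mm`` maps network label -> mm triple
    for seed-correlation maps in the vstat block.
    """
    out_dir = Path(out_dir)
    media = out_dir / "media"
    media.mkdir(parents=True, exist_ok=True)

    # --- motion, outliers, censoring -----------------------------------
    enorm = motion.compute_enorm(mp)
    outfrac = motion.compute_outlier_fraction(epi, mask)
    cv = motion.build_censor(enorm, outfrac, limits=limits,
                             run_lengths=epi.run_lengths)
    min_out_vol = motion.select_min_outlier_volume(outfrac)
    cen_frag = motion.censor_summary(cv, epi.run_lengths)

    # --- regression residuals, DF accounting ---------------------------
    errts, nreg = _regress_residuals(epi, mp, ideal, mask)
    dfs = regress.df_accounting(epi.n_volumes, cv.n_censored,
                                n_motion=nreg["n_motion"],
                                n_drift=nreg["n_drift"], n_stim=nreg["n_stim"])
    warn_items = []
    if dfs.warn:
        warn_items.append(dfs.warn)

    # --- TSNR at two stages --------------------------------------------
    detrended = Dataset4D(
        detrend_dataset(epi.values, epi.run_lengths, epi.tr),
        epi.voxel_size, epi.tr, epi.affine, epi.run_lengths)
    tsnr_volreg = tsnr.compute_tsnr(epi, detrended, mask, stage="volreg")
    tsnr_regress = tsnr.compute_tsnr(epi, errts, mask, stage="regress")
    roi_rows = None
    if atlas is not None:
        roi_rows = [tsnr.assign_roi_warn_levels(r)
                    for r in tsnr.roi_stats_table(tsnr_regress, atlas)]

    # --- correlation maps ----------------------------------------------
    gcor = correlations.compute_gcor(errts, mask)
    corr_brain = correlations.compute_corr_brain(errts, mask)
    radcor_maps = {
        "tcat": correlations.compute_radcor(epi, mask, stage="tcat"),
        "regress": correlations.compute_radcor(errts, mask, stage="regress"),
    }
    seed_maps = {}
    for label, mm in (seed_coords_mm or {}).items():
        seed_maps[label] = correlations.compute_seed_corr(errts, mask, mm)

    # --- artifact detectors --------------------------------------------
    epi_vol = epi.volume(min_out_vol)
    flip_res, flip_item = warns.check_flip(epi_vol, anat, mask)
    warn_items.append(flip_item)
    lines, line_item = warns.find_variance_lines(epi, mask)
    warn_items.append(line_item)
    presteady_n, pre_item = warns.check_presteady(epi, mask)
    warn_items.append(pre_item)
    if ideal is not None:
        stim_frac = regress.stim_censor_fractions(ideal, cv)
        warn_items.extend(stim_frac["warnings"])
    else:
        stim_frac = None

    # --- review dictionary ---------------------------------------------
    rd = ReviewDict(dict(_VERSION_FIELDS))
    rd["subject ID"] = subject
    rd = rd.merge(cen_frag)
    rd = rd.merge(dfs.as_review_fragment())
    if stim_frac is not None:
        rd["num regs of interest"] = len(stim_frac["labels"])
        rd["num TRs per stim (orig)"] = stim_frac["n_response"]
        rd["num TRs censored per stim"] = stim_frac["n_censored"]
        rd["fraction TRs censored"] = [f if f is not None else "NA"
                                       for f in stim_frac["fractions"]]
    in_tsnr = tsnr_regress.values[mask.values]
    rd["TSNR average"] = sig6(float(in_tsnr.mean()))
    rd["global correlation (GCOR)"] = sig6(gcor)
    epi_mask = Mask3D((epi.values.mean(axis=3) >
                       0.25 * np.percentile(epi.values.mean(axis=3), 98)
                       ).astype(int), epi.voxel_size, epi.affine)
    rd["anat/EPI mask Dice coef"] = sig6(
        correlations.dice_coefficient(mask, epi_mask))
    rd["flip guess"] = flip_res.guess
    rd["num variance lines"] = len(lines)
    rd["presteady-state volumes"] = presteady_n
    rd["minimum outlier volume"] = min_out_vol
    rd["max motion enorm"] = sig6(float(enorm.max()))
    rd["max outlier fraction"] = sig6(float(outfrac.max()))

    # --- render block content ------------------------------------------
    blocks = {}
    vmax = np.percentile(epi_vol.values, 99)
    report._save_montage(media / "vorig_epi.png", epi_vol,
                         title=f"original EPI (min-outlier volume {min_out_vol})",
                         vmax=vmax)
    report._save_montage(media / "vorig_anat.png", anat, title="anatomical")
    blocks["vorig"] = [
        "<p>original EPI and anatomical volumes; "
        f"EPI value range [{sig6(float(epi.values.min()))}, "
        f"{sig6(float(epi.values.max()))}]</p>",
        "<img src='media/vorig_epi.png'>", "<img src='media/vorig_anat.png'>"]

    edges = report.render_edge_overlay(epi_vol, anat)
    report._save_montage(media / "ve2a.png", epi_vol, edge=edges,
                         title="anatomical edges over EPI", vmax=vmax)
    blocks["ve2a"] = ["<img src='media/ve2a.png'>"]

    if template is not None:
        tedges = report.render_edge_overlay(template, anat)
        report._save_montage(media / "va2t.png", template, edge=tedges,
                             title="anatomical edges over template")
        blocks["va2t"] = ["<img src='media/va2t.png'>"]

    vstat_parts = []
    for label, cmap in list(seed_maps.items())[:5]:
        alpha, boxed = report.apply_alpha_threshold(
            cmap.values, cmap.render["threshold"])
        fname = f"vstat_seed_{label}.png"
        report._save_montage(media / fname, anat, overlay=cmap.values,
                             alpha=alpha, boxed=boxed,
                             overlay_range=cmap.render["range"],
                             title=f"seed correlation: {label}")
        vstat_parts.append(f"<img src='media/{fname}'>")
    if vstat_parts:
        blocks["vstat"] = vstat_parts

    report._plot_series(media / "mot_enorm.png",
                        {"enorm": enorm, "outlier frac": outfrac},
                        censored=cv.censored_indices,
                        limits=[cv.limits["enorm_limit"],
                                cv.limits["outlier_limit"]],
                        title="motion enorm and outlier fraction")
    report.render_grayplot(epi, mask, enorm, outfrac,
                           out_png=media / "mot_grayplot.png")
    blocks["mot"] = [
        f"<p>censored {cv.n_censored} of {cv.n_total} volumes "
        f"(fraction {rd['censor fraction']})</p>",
        "<img src='media/mot_enorm.png'>", "<img src='media/mot_grayplot.png'>"]

    regr_parts = [f"<p>DF total {dfs.total} = censored {dfs.censored} + "
                  f"regressors {dfs.used_by_regressors} + left {dfs.left} "
                  f"(final fraction {sig6(dfs.final_fraction)})</p>"]
    if ideal is not None:
        series = {lab: ideal.series[:, j] for j, lab in enumerate(ideal.labels)}
        series["sum"] = ideal.summed
        report._plot_series(media / "regr_ideal.png", series,
                            censored=cv.censored_indices,
                            title="idealized stimulus responses")
        regr_parts.append("<img src='media/regr_ideal.png'>")
    alpha, boxed = report.apply_alpha_threshold(
        corr_brain.values, corr_brain.render["threshold"])
    report._save_montage(media / "regr_corr_brain.png", anat,
                         overlay=corr_brain.values, alpha=alpha, boxed=boxed,
                         overlay_range=corr_brain.render["range"],
                         title="corr_brain")
    report._save_montage(media / "regr_tsnr.png",
                         tsnr_regress.as_dataset(),
                         title="TSNR (regress stage)")
    regr_parts += ["<img src='media/regr_corr_brain.png'>",
                   "<img src='media/regr_tsnr.png'>"]
    if roi_rows:
        cells = "".join(
            "<tr>" + "".join(
                f"<td style='background:{row.warns.get(m, warns.WarnLevel.none).color}'>"
                f"{v}</td>" for m, v in [
                    ("", row.label), ("nvox", row.nvox), ("zero_frac", row.nzer),
                    ("dvox", row.dvox), ("", f"{row.tmin:.1f}"),
                    ("", f"{row.t25:.1f}"), ("", f"{row.tmed:.1f}"),
                    ("t75", f"{row.t75:.1f}"), ("", f"{row.tmax:.1f}")])
            + "</tr>" for row in roi_rows)
        regr_parts.append(
            "<table class='qtable'><tr><th>ROI</th><th>Nvox</th><th>Nzer</th>"
            "<th>Dvox</th><th>Tmin</th><th>T25</th><th>Tmed</th><th>T75</th>"
            "<th>Tmax</th></tr>" + cells + "</table>")
    blocks["regr"] = regr_parts

    radcor_parts = []
    for stage, cmap in radcor_maps.items():
        fname = f"radcor_{stage}.png"
        report._save_montage(media / fname, anat, overlay=cmap.values,
                             alpha=np.abs(cmap.values),
                             overlay_range=1.0, title=f"radcor ({stage})")
        radcor_parts.append(f"<img src='media/{fname}'>")
    blocks["radcor"] = radcor_parts

    index = report.assemble_report(out_dir, subject, blocks, review=rd,
                                   warn_items=warn_items)
    write_review_dict(rd, out_dir / f"out.ss_review.{subject}.txt", "colon")
    return {"review": rd, "censor": cv, "warn_items": warn_items,
            "flip": flip_res, "report": index, "roi_rows": roi_rows,
            "tsnr": {"volreg": tsnr_volreg, "regress": tsnr_regress},
            "gcor": gcor, "variance_lines": lines}


def run_phantom_qc(spec: SimSpec, out_dir, subject: str = "sub-000") -> dict:
    """Simulate a phantom subject per ``spec`` and run the full QC battery."""
    from scipy.ndimage import gaussian_filter

    suite = phantom_suite(spec)
    ideal = None
    if spec.stim_onsets:
        ideal = regress.build_ideal_response(
            spec.stim_onsets, spec.stim_durations, spec.hrf, spec.tr,
            spec.n_volumes)
    seed_coords = {}
    for net in suite["truth"].network_seeds:
        seed_coords[net["label"]] = suite["epi"].ijk_to_mm(net["seed"])
    # toy template: a smoothed copy of the anatomical on the same grid
    template = Dataset3D(gaussian_filter(suite["anat"].values, 1.5),
                         spec.voxel_size, spec.affine)
    result = run_subject_qc(
        suite["epi"], suite["anat"], suite["mask"], suite["motion"],
        out_dir, subject=subject, atlas=suite["atlas"], template=template,
        ideal=ideal, seed_coords_mm=seed_coords)
    suite["truth"].to_json(Path(out_dir) / "truth.json")
    result["truth"] = suite["truth"]
    return result
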