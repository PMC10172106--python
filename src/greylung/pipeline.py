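"""End-to-end orchestration: simulate -> roi -> measure -> pvfit -> agree.

Each stage persists its artifacts (frames, ROI JSONs, CSV tables) under the
run's output directory so any stage can be re-run or audited in isolation;
``run_all`` chains them and emits a machine-readable ``report.json`` plus a
plain-text ``summary.txt``. Every stochastic step draws its seed from the
run's ``master_seed``, making a run byte-reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import friedman, icc_two_way_random, spearman, wilcoxon_pairs
from .config import RunConfig
from .errors import GreyLungError
from .grey import delta_series, mgv
from .pv import (EITCalibration, PVSeries, VenegasModel, calibrate_eit,
                 detect_hysteresis, empirical_pressures, pool_series)
from .roi import detect_roi, import_manual_roi, load_frame
from .synth import WINDOW_REGION, EITRecord, simulate_cohort

__all__ = ["run_all", "stage_simulate", "stage_roi", "stage_measure",
           "stage_pvfit", "stage_agree"]

log = logging.getLogger("greylung")

GROUPS = ("dependent", "non_dependent")
VOLUME_COLUMNS = ("total", "right_whole", "ventral", "central", "dorsal")
_FLOAT_FMT = "%.10g"


def _seed_for(cfg: RunConfig, stage: int) -> int:
    """Stable sub-seed (< 2**31) for one stage of the run."""
    return int(np.random.SeedSequence([cfg.master_seed, stage])
               .generate_state(1, dtype=np.uint32)[0] >> 1)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, out_dir: Path) -> dict[str, Path]:
    return simulate_cohort(cfg.n_lambs, out_dir, schedule=cfg.schedule(),
                           config=cfg.generator, master_seed=cfg.master_seed)


def stage_roi(cfg: RunConfig, out_dir: Path,
              manual_dir: Path | None = None) -> pd.DataFrame:
    """Delineate the pleural ROI for every frame listed in metadata.csv.

    With ``manual_dir`` given, a ``<frame stem>.json`` found there overrides
    automatic detection for that frame (the hand-traced workflow).
    """
    meta = pd.read_csv(out_dir / "metadata.csv")
    rois_dir = out_dir / "rois"
    rois_dir.mkdir(exist_ok=True)
    rows = []
    for rec in meta.to_dict("records"):
        frame_path = out_dir / rec["frame_path"]
        frame = load_frame(frame_path, meta=rec,
                           pixel_spacing_mm=rec["pixel_spacing_mm"])
        manual = (manual_dir / f"{frame_path.stem}.json") if manual_dir else None
        if manual is not None and manual.exists():
            roi = import_manual_roi(manual, image_shape=frame.shape)
        else:
            roi = detect_roi(frame, search_band=cfg.search_band,
                             shadow_threshold_frac=cfg.shadow_threshold_frac,
                             depth_mm=cfg.depth_mm)
        roi_file = rois_dir / f"{frame_path.stem}.json"
        roi.save(roi_file, image=frame_path.name)
        rows.append({**rec, "roi_file": f"rois/{roi_file.name}",
                     "pleural_row": roi.pleural_row, "left_col": roi.left_col,
                     "right_col": roi.right_col, "depth_px": roi.depth_px})
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "rois.csv", index=False, float_format=_FLOAT_FMT)
    return df


def stage_measure(cfg: RunConfig, out_dir: Path) -> pd.DataFrame:
    """Measure Q-LUS_MGV per frame for two observers and fill delta_mgv.

    Observer A reads the ROI mean directly; observer B emulates a second
    reader re-measuring the same image by adding independent Gaussian noise
    of sd ``observer_sigma`` AU to A's value (clipped to the 8-bit scale).
    delta_mgv is taken within observer against the inflation 0 cm H2O frame.
    """
    rois = pd.read_csv(out_dir / "rois.csv")
    rng = np.random.default_rng(_seed_for(cfg, 1))
    rows = []
    for rec in rois.to_dict("records"):
        frame = load_frame(out_dir / rec["frame_path"], meta=rec,
                           pixel_spacing_mm=rec["pixel_spacing_mm"])
        roi = import_manual_roi(out_dir / rec["roi_file"],
                                image_shape=frame.shape)
        measure = mgv(frame, roi)
        b_value = float(np.clip(measure.mgv + rng.normal(0, cfg.observer_sigma),
                                0, 255))
        for observer, value in (("A", measure.mgv), ("B", b_value)):
            rows.append({
                "lamb_id": rec["lamb_id"], "region": rec["region"],
                "limb": rec["limb"], "pressure_cmH2O": rec["pressure_cmH2O"],
                "observer_id": observer, "mgv": value,
                "n_pixels": measure.n_pixels, "roi_file": rec["roi_file"],
            })
    df = pd.DataFrame(rows)

    deltas = []
    for (_, _), grp in df.groupby(["lamb_id", "observer_id"], sort=False):
        measures = [mk for mk in grp.to_dict("records")]
        gm = delta_series([_as_measure(r) for r in measures])
        for rec, m in zip(measures, gm):
            rec["delta_mgv"] = m.delta_mgv
            deltas.append(rec)
    df = pd.DataFrame(deltas)
    df["mgv"] = df["mgv"].round(3)          # reporting precision only
    df["delta_mgv"] = df["delta_mgv"].round(3)
    df.to_csv(out_dir / "measures.csv", index=False, float_format=_FLOAT_FMT)
    return df


def _as_measure(rec: dict):
    from .grey import GreyMeasure
    return GreyMeasure(mgv=rec["mgv"], n_pixels=rec["n_pixels"],
                       meta={"limb": rec["limb"],
                             "pressure_cmH2O": rec["pressure_cmH2O"]})


def _lamb_delta_series(measures: pd.DataFrame, lamb_id: str) -> PVSeries:
    sub = measures[(measures.lamb_id == lamb_id)
                   & (measures.observer_id == "A")]
    inf = sub[sub.limb == "inflation"].sort_values("pressure_cmH2O")
    dfl = sub[sub.limb == "deflation"].sort_values("pressure_cmH2O",
                                                   ascending=False)
    return PVSeries(lamb_id, "delta_mgv",
                    inf.pressure_cmH2O.to_numpy(), inf.delta_mgv.to_numpy(),
                    dfl.pressure_cmH2O.to_numpy(), dfl.delta_mgv.to_numpy())


def _eit_record(eit: pd.DataFrame, lamb_id: str) -> EITRecord:
    sub = eit[eit.lamb_id == lamb_id]
    return EITRecord(
        lamb_id=lamb_id, limbs=sub.limb.to_numpy(),
        pressures=sub.pressure_cmH2O.to_numpy(),
        syringe_volumes=sub.syringe_volume_mlkg.to_numpy(),
        z_right_whole=sub.z_right_whole.to_numpy(),
        z_ventral=sub.z_ventral.to_numpy(),
        z_central=sub.z_central.to_numpy(),
        z_dorsal=sub.z_dorsal.to_numpy(),
    )


def _volume_series(volumes: pd.DataFrame, lamb_id: str,
                   column: str) -> PVSeries:
    sub = volumes[volumes.lamb_id == lamb_id]
    inf = sub[sub.limb == "inflation"].sort_values("pressure_cmH2O")
    dfl = sub[sub.limb == "deflation"].sort_values("pressure_cmH2O",
                                                   ascending=False)
    return PVSeries(lamb_id, f"volume_{column}",
                    inf.pressure_cmH2O.to_numpy(), inf[column].to_numpy(),
                    dfl.pressure_cmH2O.to_numpy(), dfl[column].to_numpy())


def stage_pvfit(cfg: RunConfig, out_dir: Path) -> dict:
    """PV analysis: empirical pressures and hysteresis per lamb, pooled
    Venegas fits per imaging group and limb (greyscale and EIT volume),
    model-predicted opening/closing pressures, EIT calibration."""
    measures = pd.read_csv(out_dir / "measures.csv")
    eit = pd.read_csv(out_dir / "eit.csv")
    meta = measures[measures.observer_id == "A"] \
        .groupby("lamb_id", sort=False).region.first()
    fit_seed = _seed_for(cfg, 2)

    # EIT calibration -> calibrated volumes per lamb
    vol_rows = []
    for lamb_id in meta.index:
        record = _eit_record(eit, lamb_id)
        cal: EITCalibration = calibrate_eit(record)
        for j in range(len(record.pressures)):
            vol_rows.append({
                "lamb_id": lamb_id, "limb": record.limbs[j],
                "pressure_cmH2O": record.pressures[j],
                "total": record.syringe_volumes[j],
                "right_whole": cal.volumes["right_whole"][j],
                "ventral": cal.volumes["ventral"][j],
                "central": cal.volumes["central"][j],
                "dorsal": cal.volumes["dorsal"][j],
            })
    volumes = pd.DataFrame(vol_rows)
    volumes.to_csv(out_dir / "volumes.csv", index=False,
                   float_format=_FLOAT_FMT)

    # per-lamb empirical pressures and hysteresis on delta-MGV
    press_rows, hyst_rows = [], []
    lamb_series: dict[str, PVSeries] = {}
    for lamb_id in meta.index:
        series = _lamb_delta_series(measures, lamb_id)
        lamb_series[lamb_id] = series
        step = empirical_pressures(series)
        press_rows.append({"lamb_id": lamb_id, "method": "empirical",
                           "opening_cmH2O": step.opening_pressure,
                           "closing_cmH2O": step.closing_pressure})
        hyst = detect_hysteresis(series)
        hyst_rows.append({"lamb_id": lamb_id, "region": meta[lamb_id],
                          "present": hyst.present,
                          "mean_paired_difference": hyst.mean_paired_difference,
                          "loop_area": hyst.loop_area,
                          "wilcoxon_p": hyst.wilcoxon_p})

    # pooled fits per group, greyscale and EIT imaged-region volume
    fit_rows = []
    model_pressures: dict[str, dict[str, tuple[float, float]]] = {}
    for group in GROUPS:
        lamb_ids = [l for l in meta.index if meta[l] == group]
        pooled_mgv = pool_series([lamb_series[l] for l in lamb_ids])
        region = WINDOW_REGION[group]
        pooled_eit = pool_series([_volume_series(volumes, l, region)
                                  for l in lamb_ids])
        model_pressures[group] = {}
        for label, pooled in (("delta_mgv", pooled_mgv),
                              (f"eit_{region}", pooled_eit)):
            limb_fits = {}
            for limb in ("inflation", "deflation"):
                p, v = pooled.limb(limb)
                res = VenegasModel(p, v).fit(n_starts=cfg.n_starts,
                                             seed=fit_seed)
                limb_fits[limb] = res
                fit_rows.append({
                    "scope": "pooled", "lamb_id": f"pooled_{group}",
                    "signal_kind": label, "limb": limb, **res.params,
                    "adj_r2": res.rsquared_adj, "runs_p": res.runs_p,
                    "converged": res.converged, "n": res.nobs,
                })
            opening = limb_fits["inflation"].predicted_pressure(cfg.grid_step)
            closing = limb_fits["deflation"].predicted_pressure(cfg.grid_step)
            model_pressures[group][label] = (opening, closing)
            press_rows.append({"lamb_id": f"pooled_{group}",
                               "method": f"model_{label}",
                               "opening_cmH2O": opening,
                               "closing_cmH2O": closing})

    pd.DataFrame(fit_rows).to_csv(out_dir / "fits.csv", index=False,
                                  float_format=_FLOAT_FMT)
    pd.DataFrame(press_rows).to_csv(out_dir / "pressures.csv", index=False,
                                    float_format=_FLOAT_FMT)
    hyst_df = pd.DataFrame(hyst_rows)
    hyst_df.to_csv(out_dir / "hysteresis.csv", index=False,
                   float_format=_FLOAT_FMT)
    return {"volumes": volumes, "fits": pd.DataFrame(fit_rows),
            "pressures": pd.DataFrame(press_rows), "hysteresis": hyst_df,
            "model_pressures": model_pressures}


def stage_agree(cfg: RunConfig, out_dir: Path) -> dict:
    """Agreement battery: delta-MGV vs total and regional volumes (Spearman),
    interobserver ICC(2,1), Friedman across inflation pressures with post-hoc
    Wilcoxon pairs."""
    measures = pd.read_csv(out_dir / "measures.csv")
    volumes = pd.read_csv(out_dir / "volumes.csv")
    seed = _seed_for(cfg, 3)

    obs_a = measures[measures.observer_id == "A"]
    merged = obs_a.merge(volumes, on=["lamb_id", "limb", "pressure_cmH2O"])

    agree_rows = []
    for group in GROUPS:
        sub = merged[merged.region == group]
        for column in VOLUME_COLUMNS:
            res = spearman(sub["delta_mgv"], sub[column],
                           ci_method=cfg.ci_method, n_boot=cfg.n_boot,
                           seed=seed, alpha=cfg.alpha)
            agree_rows.append({
                "comparison": f"{group}_vs_{column}", "kind": "spearman",
                "rho_or_icc": res.rho, "ci_low": res.ci_low,
                "ci_high": res.ci_high, "p": res.p_value, "n": res.n,
                "strength_or_model": res.strength,
            })
        # interobserver agreement on raw MGV, one row per frame
        wide = measures[measures.region == group].pivot_table(
            index=["lamb_id", "limb", "pressure_cmH2O"],
            columns="observer_id", values="mgv")
        icc = icc_two_way_random(wide[["A", "B"]].to_numpy(), alpha=cfg.alpha)
        agree_rows.append({
            "comparison": f"{group}_interobserver", "kind": "icc",
            "rho_or_icc": icc.icc, "ci_low": icc.ci_low,
            "ci_high": icc.ci_high, "p": np.nan, "n": icc.n_subjects,
            "strength_or_model": icc.model_label,
        })
    agree_df = pd.DataFrame(agree_rows)
    agree_df.to_csv(out_dir / "agreement.csv", index=False,
                    float_format=_FLOAT_FMT)

    # Friedman across inflation pressure steps + post-hoc Wilcoxon pairs
    comp_rows = []
    for group in GROUPS:
        sub = obs_a[(obs_a.region == group) & (obs_a.limb == "inflation")]
        block = sub.pivot_table(index="lamb_id", columns="pressure_cmH2O",
                                values="delta_mgv")
        pressures = list(block.columns)
        if len(block) < 2:  # pressure comparisons need >= 2 lambs per group
            log.warning("group %s has %d lamb(s); skipping Friedman/Wilcoxon",
                        group, len(block))
            continue
        stat, p = friedman(block.to_numpy())
        comp_rows.append({"group": group, "test": "friedman",
                          "pair": "all_inflation", "statistic": stat,
                          "raw_p": p, "adjusted_p": p,
                          "significant": p < cfg.alpha})
        pairs = [(i, i + 1) for i in range(len(pressures) - 1)]
        m = cfg.bonferroni_m if cfg.bonferroni_m is not None else len(pairs)
        for cmp_res in wilcoxon_pairs(block.to_numpy(), pairs,
                                      m_comparisons=m, alpha=cfg.alpha):
            i, j = cmp_res.pair
            comp_rows.append({
                "group": group, "test": "wilcoxon",
                "pair": f"{pressures[i]:g}_vs_{pressures[j]:g}",
                "statistic": cmp_res.statistic, "raw_p": cmp_res.raw_p,
                "adjusted_p": cmp_res.adjusted_p,
                "significant": cmp_res.significant,
            })
    comp_df = pd.DataFrame(comp_rows)
    comp_df.to_csv(out_dir / "comparisons.csv", index=False,
                   float_format=_FLOAT_FMT)
    return {"agreement": agree_df, "comparisons": comp_df}


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_all(cfg: RunConfig) -> dict:
    """Execute every stage in order and write report.json + summary.txt.

    Returns the report as a dict. Idempotent: rerunning with the same config
    rewrites byte-identical artifacts.
    """
    cfg = cfg.validated()
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def _timed(name, fn, *args):
        t0 = time.perf_counter()
        try:
            result = fn(cfg, *args)
        except GreyLungError as exc:
            raise GreyLungError(f"stage {name!r} failed: {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 3)
        log.info("stage %s done in %.2fs", name, timings[name])
        return result

    _timed("simulate", stage_simulate, out_dir)
    _timed("roi", stage_roi, out_dir)
    _timed("measure", stage_measure, out_dir)
    pvfit = _timed("pvfit", stage_pvfit, out_dir)
    agree = _timed("agree", stage_agree, out_dir)

    report = _build_report(cfg, out_dir, pvfit, agree, timings)
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_jsonify) + "\n")
    (out_dir / "summary.txt").write_text(_render_summary(report))
    return report


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _build_report(cfg, out_dir, pvfit, agree, timings) -> dict:
    hyst = pvfit["hysteresis"]
    press = pvfit["pressures"]
    volumes = pvfit["volumes"]
    meta = pd.read_csv(out_dir / "metadata.csv")
    region_of = meta.groupby("lamb_id").region.first()

    empirical = press[press.method == "empirical"].copy()
    empirical["region"] = empirical.lamb_id.map(region_of)

    per_group: dict[str, dict] = {}
    for group in GROUPS:
        lamb_ids = region_of[region_of == group].index
        sub_h = hyst[hyst.region == group]
        v35 = volumes[(volumes.lamb_id.isin(lamb_ids))
                      & (volumes.limb == "inflation")
                      & (volumes.pressure_cmH2O == 35)]["total"]
        emp = empirical[empirical.region == group]
        per_group[group] = {
            "n_lambs": int(len(lamb_ids)),
            "hysteresis_prevalence": float(sub_h.present.mean()),
            "median_volume_35cmH2O_mlkg": float(v35.median()),
            "empirical_opening_mode_cmH2O": float(emp.opening_cmH2O.mode().iloc[0]),
            "empirical_closing_mode_cmH2O": float(emp.closing_cmH2O.mode().iloc[0]),
            "model_pressures": {
                label: {"opening_cmH2O": o, "closing_cmH2O": c}
                for label, (o, c) in pvfit["model_pressures"][group].items()
            },
        }

    fits = pvfit["fits"]
    return {
        "software": {"package": "greylung", "version": __version__},
        "config": asdict(cfg),
        "timings_s": timings,
        "n_lambs": int(cfg.n_lambs),
        "hysteresis_prevalence": float(hyst.present.mean()),
        "groups": per_group,
        "pooled_fits": fits.to_dict("records"),
        "agreement": agree["agreement"].to_dict("records"),
        "comparisons": agree["comparisons"].to_dict("records"),
    }


def _render_summary(report: dict) -> str:
    lines = [
        f"greylung {report['software']['version']} — synthetic cohort run",
        f"lambs: {report['n_lambs']}   "
        f"hysteresis prevalence: {report['hysteresis_prevalence']:.0%}",
        "",
    ]
    for group, g in report["groups"].items():
        lines.append(f"[{group}]  n={g['n_lambs']}")
        lines.append(f"  median volume at 35 cm H2O: "
                     f"{g['median_volume_35cmH2O_mlkg']:.1f} ml/kg")
        lines.append(f"  empirical opening/closing (modal): "
                     f"{g['empirical_opening_mode_cmH2O']:g} / "
                     f"{g['empirical_closing_mode_cmH2O']:g} cm H2O")
        for label, mp in g["model_pressures"].items():
            lines.append(f"  model ({label}) opening/closing: "
                         f"{mp['opening_cmH2O']:.1f} / "
                         f"{mp['closing_cmH2O']:.1f} cm H2O")
        lines.append(f"  hysteresis: {g['hysteresis_prevalence']:.0%}")
    lines.append("")
    lines.append("agreement:")
    for row in report["agreement"]:
        ci = f"[{row['ci_low']:.2f}, {row['ci_high']:.2f}]"
        lines.append(f"  {row['comparison']:<30s} {row['kind']:<8s} "
                     f"{row['rho_or_icc']:.3f} {ci} (n={row['n']})")
    lines.append("")
    lines.append("pooled Venegas fits (adj R2 / runs p):")
    for row in report["pooled_fits"]:
        lines.append(f"  {row['lamb_id']:<22s} {row['signal_kind']:<12s} "
                     f"{row['limb']:<10s} {row['adj_r2']:.3f} / "
                     f"{row['runs_p']:.2f}")
    return "\n".join(lines) + "\n"
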