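"""CSV/config IO and the end-to-end analysis pipeline.

One flat CSV schema serves both single-toxicant and mixture mortality
records (the second component's columns stay empty for singles).  The
pipeline strings the stages together: fit single-agent curves, estimate
effect levels, design mixture rays, (optionally) simulate mixture data,
fit mixture curves, run the CA/IA/surrogate comparison, and classify
interactions — emitting one CSV per report plus a plain-text run log.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .crc import CRCRegressor, select_best_family
from .design import MixtureRay, eecr_ray, equray_rays, frrd_series
from .effect import effect_concentration
from .mixture import compare_models, predict_ray_effects, synergistic_ratio
from .records import DoseResponseRecord, frame_to_records, pool_records, records_to_frame
from .simulate import SyntheticStudyConfig, simulate_mixture
from .surface import MixtureSurface, build_feature_table

__all__ = [
    "read_mortality_csv",
    "write_mortality_csv",
    "PipelineConfig",
    "run_pipeline",
]

log = logging.getLogger("toxmix")


def read_mortality_csv(path) -> list[DoseResponseRecord]:
    """Read and validate mortality records from the flat CSV schema."""
    path = Path(path)
    frame = pd.read_csv(path, keep_default_na=True)
    if frame.empty:
        raise ValueError(f"{path}: no mortality rows found")
    if "component_b" in frame.columns:
        frame["component_b"] = frame["component_b"].fillna("")
    return frame_to_records(frame)


def write_mortality_csv(records: list[DoseResponseRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """Everything one analysis run needs, loadable from YAML."""

    single_input: str | None = None      # None -> bundled reference records
    mixture_input: str | None = None     # None -> simulate from fitted curves
    components: tuple[str, str] = ("Cr", "Ni")
    time_points: tuple[int, ...] = (24, 48, 72, 96)
    design_time_h: int = 96
    confidence: float = 0.95
    n_rays: int = 5
    n_levels: int = 12
    dilution_factor: float = 2.0
    top_multiplier: float = 1.0   # headroom above each ray's defining sum
    sr_tolerance: float = 0.05
    qsar_families: tuple[str, ...] = ("ridge", "xgboost", "mlp", "mlr")
    qsar_split: float = 0.8
    truth_model: str = "ca"
    seed: int = 0
    output_dir: str = "toxmix_out"

    def __post_init__(self) -> None:
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must lie in (0, 1)")
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must exceed 1")
        from .surface import DEFAULT_FAMILIES
        unknown = set(self.qsar_families) - set(DEFAULT_FAMILIES)
        if unknown:
            raise ValueError(f"unknown surface model families: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for attr in ("single_input", "mixture_input"):
            p = getattr(cfg, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p} does not exist")
        return cfg

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _single_records(config: PipelineConfig) -> dict[tuple[str, int], list[DoseResponseRecord]]:
    if config.single_input is not None:
        records = read_mortality_csv(config.single_input)
        grouped: dict[tuple[str, int], list[DoseResponseRecord]] = {}
        for r in records:
            if len(r.component_ids) == 1:
                grouped.setdefault((r.component_ids[0], int(r.time_h)), []).append(r)
        return grouped
    return {
        (comp, t): datasets.load_single_records(comp, t)
        for comp in config.components for t in config.time_points
    }


def _fit_table_row(component: str, time_h: int, fit: CRCRegressor,
                   confidence: float) -> dict:
    row = {
        "element": component, "time_h": time_h, "function": fit.family_,
        "alpha": round(fit.alpha_, 4), "beta": round(fit.beta_, 4),
        "gamma": round(fit.gamma_, 4) if fit.gamma_ is not None else "",
        "R2": round(fit.quality_.r2, 4), "MAE": round(fit.quality_.mae, 4),
    }
    for p, name in ((0.1, "LC10"), (0.3, "LC30"), (0.5, "LC50")):
        try:
            ec = effect_concentration(fit, p, level=confidence)
        except ValueError:
            # e.g. a BCW fit with a positive zero-dose baseline above p
            row[name] = row[f"{name}_lo"] = row[f"{name}_hi"] = ""
            continue
        row[name] = round(ec.value, 4)
        row[f"{name}_lo"] = round(ec.ci_low, 4)
        row[f"{name}_hi"] = "" if np.isinf(ec.ci_high) else round(ec.ci_high, 4)
    return row


def _design_rays(config: PipelineConfig, fits: dict) -> list[MixtureRay]:
    comp_a, comp_b = config.components
    fit_a = fits[(comp_a, config.design_time_h)]
    fit_b = fits[(comp_b, config.design_time_h)]
    rays = []
    for p in (0.1, 0.3, 0.5):
        try:
            ray = eecr_ray(float(fit_a.inverse(p)), float(fit_b.inverse(p)),
                           label=f"EECR {round(p * 100)}", components=(comp_a, comp_b))
        except ValueError:
            log.warning("EECR %d skipped: LC%d not attainable for a component",
                        round(p * 100), round(p * 100))
            continue
        rays.append(frrd_series(ray, config.n_levels, config.dilution_factor,
                                top=ray.series[0] * config.top_multiplier))
    lc50_a, lc50_b = float(fit_a.inverse(0.5)), float(fit_b.inverse(0.5))
    for ray in equray_rays(lc50_a, lc50_b, config.n_rays, components=(comp_a, comp_b)):
        rays.append(frrd_series(ray, config.n_levels, config.dilution_factor,
                                top=ray.series[0] * config.top_multiplier))
    return rays


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the report bundle.

    Writes single-fit, mixture-comparison and interaction tables (CSV)
    plus ``run_log.txt`` into ``config.output_dir``.  Stage failures are
    logged; stages depending on a failed stage are skipped and the bundle
    marks them accordingly.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    status: dict[str, str] = {}
    bundle: dict = {"status": status, "output_dir": str(out)}

    # --- stage 1: single-toxicant CRC fits --------------------------------
    fits: dict[tuple[str, int], CRCRegressor] = {}
    rows = []
    try:
        for (comp, t), recs in _single_records(config).items():
            fit = select_best_family(recs)
            fits[(comp, t)] = fit
            rows.append(_fit_table_row(comp, t, fit, config.confidence))
        single_table = pd.DataFrame(rows)
        single_table.to_csv(out / "single_fits.csv", index=False)
        bundle["single_fits"] = single_table
        status["single_fits"] = "ok"
    except Exception as exc:
        log.error("single-fit stage failed: %s", exc)
        status["single_fits"] = f"failed: {exc}"
        _write_log(config, status, out)
        return bundle

    # --- stage 2: mixture design ------------------------------------------
    try:
        rays = _design_rays(config, fits)
        design_rows = [
            {"design": ray.design, "level": k + 1, "total_mg_L": total,
             config.components[0]: conc[0], config.components[1]: conc[1]}
            for ray in rays
            for k, (total, conc) in enumerate(zip(ray.series, ray.component_concentrations()))
        ]
        design_table = pd.DataFrame(design_rows)
        design_table.to_csv(out / "mixture_design.csv", index=False)
        bundle["design"] = design_table
        status["design"] = "ok"
    except Exception as exc:
        log.error("design stage failed: %s", exc)
        status["design"] = f"failed: {exc}"
        _write_log(config, status, out)
        return bundle

    # --- stage 3: mixture records (measured or simulated) ------------------
    t = config.design_time_h
    mixture_records: dict[str, list[DoseResponseRecord]] = {}
    if config.mixture_input is not None:
        for r in read_mortality_csv(config.mixture_input):
            if len(r.component_ids) == 2 and int(r.time_h) == t:
                # assign each record to the ray whose fraction matches best
                frac = r.concentrations[0] / r.total_concentration
                ray = min(rays, key=lambda ry: abs(ry.fractions[0] - frac))
                mixture_records.setdefault(ray.design, []).append(r)
        status["mixture_data"] = "measured"
    else:
        truth = {}
        for (comp, tt), fit in fits.items():
            from .simulate import TrueCRC
            truth[(comp, tt)] = TrueCRC(fit.family_, fit.alpha_, fit.beta_, fit.gamma_)
        sim = SyntheticStudyConfig(truth=truth, truth_model=config.truth_model,
                                   seed=config.seed)
        for ray in rays:
            mixture_records[ray.design] = simulate_mixture(sim, ray, t)
        status["mixture_data"] = f"simulated ({config.truth_model} truth)"

    # --- stage 4: mixture fits, CA/IA/surrogate comparison, SR -------------
    comp_a, comp_b = config.components
    single_fit_a, single_fit_b = fits[(comp_a, t)], fits[(comp_b, t)]
    lc50_a = float(single_fit_a.inverse(0.5))
    lc50_b = float(single_fit_b.inverse(0.5))

    all_mix_records = [r for recs in mixture_records.values() for r in recs]
    surface = None
    try:
        X, y = build_feature_table(all_mix_records)
        surface = MixtureSurface(families=config.qsar_families,
                                 split_ratio=config.qsar_split,
                                 random_state=config.seed).fit(X.values, y)
        pd.DataFrame([
            {"family": r.model_family, "selected": r.selected, "failed": r.failed,
             "train_R2": r.train_quality.r2 if r.train_quality else "",
             "test_R2": r.test_quality.r2 if r.test_quality else "",
             "test_MSE": r.test_quality.mse if r.test_quality else ""}
            for r in surface.reports_
        ]).to_csv(out / "surface_models.csv", index=False)
        status["surface"] = f"ok (best: {surface.best_family_})"
    except Exception as exc:
        log.error("surface stage failed: %s", exc)
        status["surface"] = f"failed: {exc}"

    mix_rows, sr_rows, model_scores = [], [], []
    for ray in rays:
        recs = mixture_records.get(ray.design, [])
        row: dict = {"combination": ray.design}
        try:
            mix_fit = select_best_family(recs)
            for p, name in ((0.3, "LC30"), (0.5, "LC50")):
                ec = effect_concentration(mix_fit, p, level=config.confidence)
                row[name] = round(ec.value, 4)
                row[f"{name}_lo"] = round(ec.ci_low, 4)
                row[f"{name}_hi"] = "" if np.isinf(ec.ci_high) else round(ec.ci_high, 4)
            mixture_lc50 = float(mix_fit.inverse(0.5))
        except Exception as exc:
            log.error("mixture fit failed for %s: %s", ray.design, exc)
            status[f"mixture_fit:{ray.design}"] = f"failed: {exc}"
            mix_rows.append(row)
            continue

        if surface is not None:
            try:
                for p, name in ((0.3, "QSAR_LC30"), (0.5, "QSAR_LC50")):
                    row[name] = round(surface.effect_concentration(ray.fractions, p), 4)
            except ValueError:
                row["QSAR_LC30"] = row["QSAR_LC50"] = ""
        mix_rows.append(row)

        x_obs, y_obs = pool_records(recs)
        preds = {"CA": predict_ray_effects(ray, [single_fit_a, single_fit_b], "ca", x_obs),
                 "IA": predict_ray_effects(ray, [single_fit_a, single_fit_b], "ia", x_obs)}
        if surface is not None:
            fr = np.asarray(ray.fractions)
            feats = np.column_stack([fr[0] * x_obs, fr[1] * x_obs, x_obs,
                                     np.full_like(x_obs, fr[0])])
            preds["QSAR"] = surface.predict(feats)
        for name, q in compare_models(list(zip(x_obs, y_obs)), preds).items():
            model_scores.append({"combination": ray.design, "model": name,
                                 "R2": round(q.r2, 4), "MSE": round(q.mse, 4)})

        for comp, lc50 in ((comp_a, lc50_a), (comp_b, lc50_b)):
            res = synergistic_ratio(lc50, mixture_lc50, comp, config.sr_tolerance)
            sr_rows.append({"combination": ray.design, "component": comp,
                            "mixture_LC50": round(mixture_lc50, 4),
                            "SR": round(res.sr, 4), "label": res.label})

    mixture_table = pd.DataFrame(mix_rows)
    mixture_table.to_csv(out / "mixture_effects.csv", index=False)
    interaction_table = pd.DataFrame(sr_rows)
    interaction_table.to_csv(out / "interactions.csv", index=False)
    scores_table = pd.DataFrame(model_scores)
    scores_table.to_csv(out / "model_comparison.csv", index=False)
    bundle.update(mixture_effects=mixture_table, interactions=interaction_table,
                  model_comparison=scores_table, surface=surface)
    status.setdefault("mixture_effects", "ok")
    status.setdefault("interactions", "ok")

    _write_log(config, status, out)
    return bundle


def _write_log(config: PipelineConfig, status: dict, out: Path) -> None:
    import toxmix
    lines = [
        f"toxmix {toxmix.__version__}",
        f"seed: {config.seed}",
        f"config sha256: {config.digest()}",
        "stages:",
    ]
    lines += [f"  {k}: {v}" for k, v in status.items()]
    (out / "run_log.txt").write_text("\n".join(lines) + "\n")
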