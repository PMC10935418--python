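"""End-to-end orchestration of the four SSC model variants.

The comparison grid crosses two switches — CARS wavelength selection on/off,
Monte Carlo outlier removal on/off — with the preprocessing methods, giving
the PLSR / CARS-PLSR / PLSR+outlier / CARS-PLSR+outlier family.  Stage order
for one variant:

    preprocess (screening fit on the full table)
    -> optional outlier removal on the full table
    -> 7:3 calibration/prediction split
    -> preprocess again, fitted on calibration rows only and frozen
    -> optional CARS on the calibration rows only
    -> LOOCV factor selection (cap 20) -> final PLSR fit
    -> metrics on calibration (R2_c, RMSEC), cross-validation (R2_v, RMSEV)
       and the held-out prediction set (R2_p, RMSEP)

Nothing downstream of the split ever sees prediction rows: the MSC reference,
the CARS subset and the factor count all derive from calibration data alone.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cars import CARSResult, cars_select
from .outliers import OutlierReport, mc_outlier_detect
from .plsr import (
    MAX_FACTORS_DEFAULT,
    EvaluationReport,
    PLSRModel,
    SpectraTable,
    cross_validate,
    evaluate,
    fit,
    split_dataset,
)
from .preprocessing import METHODS, Preprocessor

__all__ = [
    "PipelineConfig",
    "VariantResult",
    "run_variant",
    "run_pipeline",
    "compare_models",
    "VARIANTS",
]

# (label, use_cars, remove_outliers)
VARIANTS = (
    ("PLSR", False, False),
    ("CARS-PLSR", True, False),
    ("PLSR+outlier", False, True),
    ("CARS-PLSR+outlier", True, True),
)


@dataclass
class PipelineConfig:
    """Validated configuration for a pipeline run; serialized with every output."""

    preprocessing_methods: tuple[str, ...] = METHODS
    window_nm: float = 6.0
    split_fraction: float = 0.7
    seed: int = 0
    max_factors: int = MAX_FACTORS_DEFAULT
    group_by_fruit: bool = False
    outlier_n_runs: int = 500
    outlier_train_fraction: float = 0.75
    outlier_k_sigma: float = 2.5
    cars_n_iterations: int = 100
    cars_mc_fraction: float = 0.8
    cars_max_factors: int = 10
    cars_cv_folds: int = 5
    variants: tuple[str, ...] = tuple(v[0] for v in VARIANTS)
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if isinstance(self.preprocessing_methods, str):
            self.preprocessing_methods = (self.preprocessing_methods,)
        self.preprocessing_methods = tuple(self.preprocessing_methods)
        unknown = set(self.preprocessing_methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown preprocessing methods {sorted(unknown)}")
        self.variants = tuple(self.variants)
        known = {v[0] for v in VARIANTS}
        bad = set(self.variants) - known
        if bad:
            raise ValueError(f"unknown variants {sorted(bad)}; expected subset of {sorted(known)}")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.max_factors < 1:
            raise ValueError("max_factors must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        import dataclasses

        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**d)

    def stage_seeds(self) -> dict[str, int]:
        """Deterministic per-stage sub-seeds derived from the master seed."""
        state = np.random.SeedSequence(self.seed).generate_state(3)
        return {
            "outliers": int(state[0] % (2**31 - 1)),
            "split": int(state[1] % (2**31 - 1)),
            "cars": int(state[2] % (2**31 - 1)),
        }


@dataclass
class VariantResult:
    """One variant's evaluation plus the stage artifacts behind it."""

    report: EvaluationReport
    model: PLSRModel
    cars: CARSResult | None
    outliers: OutlierReport | None
    removed_sample_ids: list
    predicted: pd.DataFrame  # true vs predicted SSC on the prediction set


def run_variant(
    table: SpectraTable,
    config: PipelineConfig,
    preprocessing: str,
    use_cars: bool,
    remove_outliers: bool,
    variant_label: str | None = None,
) -> VariantResult:
    """Run one model variant end-to-end on a spectra table."""
    from .hypercube import make_wavelength_grid

    seeds = config.stage_seeds()
    step = float(np.median(np.diff(table.band_centers))) if table.n_bands > 1 else 2.0
    grid = make_wavelength_grid(
        table.band_centers[0], table.band_centers[-1] + step, step
    )
    label = variant_label or (
        ("CARS-" if use_cars else "") + "PLSR" + ("+outlier" if remove_outliers else "")
    )

    outlier_report = None
    removed_ids: list = []
    work = table
    if remove_outliers:
        screen_pp = Preprocessor(preprocessing, config.window_nm)
        screen = work.with_X(screen_pp.fit_transform(work.X, grid))
        outlier_report = mc_outlier_detect(
            screen,
            n_runs=config.outlier_n_runs,
            train_fraction=config.outlier_train_fraction,
            k_sigma=config.outlier_k_sigma,
            seed=seeds["outliers"],
        )
        keep = ~outlier_report.flags
        removed_ids = list(work.sample_ids[outlier_report.flags])
        work = work.take_rows(np.flatnonzero(keep))

    cal, pred = split_dataset(
        work, config.split_fraction, seed=seeds["split"], group_by_fruit=config.group_by_fruit
    )

    pp = Preprocessor(preprocessing, config.window_nm)
    pp.fit(cal.X, grid)
    cal_t = cal.with_X(pp.transform(cal.X, grid))
    pred_t = pred.with_X(pp.transform(pred.X, grid))

    cars_result = None
    if use_cars:
        cars_result = cars_select(
            cal_t,
            n_iterations=config.cars_n_iterations,
            mc_fraction=config.cars_mc_fraction,
            cv_folds=config.cars_cv_folds,
            max_factors=config.cars_max_factors,
            seed=seeds["cars"],
        )
        cal_t = cal_t.take_bands(cars_result.selected_bands)
        pred_t = pred_t.take_bands(cars_result.selected_bands)

    cv = cross_validate(cal_t, max_factors=config.max_factors, scheme="loo")
    F = cv.optimal_factors
    model = fit(cal_t, F)

    m_cal = evaluate(cal_t.y, model.predict(cal_t.X), "calibration")
    m_pred = evaluate(pred_t.y, model.predict(pred_t.X), "prediction")
    rmsev = float(cv.rmsecv[F - 1])
    ss_tot = float(np.sum((cal_t.y - cal_t.y.mean()) ** 2))
    r2_v = 1.0 - (rmsev**2 * cal_t.n_samples) / ss_tot if ss_tot > 0 else None

    report = EvaluationReport(
        model=label,
        preprocessing=preprocessing,
        R2_c=m_cal.r2,
        RMSEC=m_cal.rmse,
        R2_v=r2_v,
        RMSEV=rmsev,
        R2_p=m_pred.r2,
        RMSEP=m_pred.rmse,
        optimal_factors=F,
        n_bands=cal_t.n_bands,
        n_calibration=cal_t.n_samples,
        n_prediction=pred_t.n_samples,
        selected_bands_nm=list(map(float, cal_t.band_centers)) if use_cars else [],
    )
    predicted = pd.DataFrame(
        {
            "sample_id": pred_t.sample_ids,
            "ssc_true": pred_t.y,
            "ssc_predicted": model.predict(pred_t.X),
        }
    )
    return VariantResult(report, model, cars_result, outlier_report, removed_ids, predicted)


def run_pipeline(
    table: SpectraTable, config: PipelineConfig
) -> tuple[pd.DataFrame, dict[tuple[str, str], VariantResult]]:
    """Run the configured variants x preprocessing grid.

    Returns the comparison table (one row per variant/preprocessing cell) and
    the per-cell artifacts.  When ``config.output_dir`` is set, writes
    ``report.csv``, per-cell ``coefficients.csv`` / ``scatter.csv`` data and
    JSON artifacts, plus the config itself for provenance.  Identical configs
    and seeds produce byte-identical outputs.
    """
    wanted = {v[0] for v in VARIANTS if v[0] in config.variants}
    rows = []
    results: dict[tuple[str, str], VariantResult] = {}
    for label, use_cars, remove_outliers in VARIANTS:
        if label not in wanted:
            continue
        for method in config.preprocessing_methods:
            res = run_variant(table, config, method, use_cars, remove_outliers, label)
            rows.append(res.report.to_row())
            results[(label, method)] = res
    report_df = pd.DataFrame(rows)

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report_df.to_csv(out / "report.csv", index=False)
        (out / "config.json").write_text(json.dumps(asdict(config), indent=2, default=str))
        coef_rows = []
        scatter_frames = []
        artifacts: dict = {"models": {}, "cars": {}, "outliers": {}}
        for (label, method), res in results.items():
            key = f"{label}|{method}"
            bc = res.model.band_centers
            for j, c in enumerate(res.model.coef):
                coef_rows.append(
                    {"model": label, "preprocessing": method,
                     "band_nm": float(bc[j]) if bc is not None else j, "coefficient": float(c)}
                )
            sf = res.predicted.copy()
            sf.insert(0, "model", label)
            sf.insert(1, "preprocessing", method)
            scatter_frames.append(sf)
            artifacts["models"][key] = res.model.to_dict()
            if res.cars is not None:
                artifacts["cars"][key] = {
                    "selected_bands_nm": res.cars.selected_centers_nm.tolist(),
                    "selected_indices": res.cars.selected_bands.tolist(),
                    "rmsecv_curve": res.cars.rmsecv_curve.tolist(),
                    "ratio_curve": res.cars.ratio_curve.tolist(),
                    "selected_iteration": res.cars.selected_iteration,
                    "seed": res.cars.seed,
                }
            if res.outliers is not None:
                artifacts["outliers"][key] = {
                    "flagged_sample_ids": [str(s) for s in res.removed_sample_ids],
                    "mean_cutoff": res.outliers.mean_cutoff,
                    "sd_cutoff": res.outliers.sd_cutoff,
                    "n_runs": res.outliers.n_runs,
                    "factor_count": res.outliers.factor_count,
                }
        pd.DataFrame(coef_rows).to_csv(out / "coefficients.csv", index=False)
        pd.concat(scatter_frames, ignore_index=True).to_csv(out / "scatter.csv", index=False)
        (out / "artifacts.json").write_text(json.dumps(artifacts, indent=2))

    return report_df, results


def compare_models(reports: pd.DataFrame) -> pd.DataFrame:
    """Rank model rows by R2_v (descending), ties by RMSEV (ascending).

    The top row is flagged optimal.  Rows with missing R2_v are excluded with
    a warning.
    """
    if len(reports) == 0:
        raise ValueError("no reports to compare")
    df = reports.copy()
    missing = df["R2_v"].isna()
    if missing.any():
        warnings.warn(
            f"excluding {int(missing.sum())} report(s) with missing R2_v", stacklevel=2
        )
        df = df[~missing]
    if len(df) == 0:
        raise ValueError("all reports lack R2_v")
    df = df.sort_values(["R2_v", "RMSEV"], ascending=[False, True], kind="mergesort")
    df = df.reset_index(drop=True)
    df["optimal"] = False
    df.loc[0, "optimal"] = True
    return df
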