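"""End-to-end site analysis: chronologies, SPEI suite and reconstruction.

Thin orchestration over the library modules, shared by the numbered
analysis drivers.  Each function returns plain containers/DataFrames so
drivers only decide what to write where.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import chronology as ch
from . import climate_spei as cs
from . import reconstruction as rec
from .ringwidth_io import HydroSeries, MonthlyClimate, RingWidthSeries

__all__ = ["SiteChronologies", "build_site_chronologies", "stats_table_row",
           "spei_suite", "ReconResult", "reconstruct_site"]

RECON_SCALES = (12, 24, 36, 48, 60, 72)


@dataclass
class SiteChronologies:
    """Both chronology variants for one site, with their index series."""

    site_id: str
    detrended: list[ch.IndexSeries]
    standardized: list[ch.IndexSeries]
    chron_detrended: ch.SiteChronology
    chron_standardized: ch.SiteChronology


def build_site_chronologies(trees: list[RingWidthSeries]) -> SiteChronologies:
    """Average cores per tree, detrend/standardize, and build both masters."""
    tree_series = ch.average_cores_per_tree(trees)
    detrended = [ch.detrend_spline(t) for t in tree_series]
    standardized = [ch.standardize_horizontal(t) for t in tree_series]
    return SiteChronologies(
        site_id=trees[0].site_id,
        detrended=detrended,
        standardized=standardized,
        chron_detrended=ch.build_chronology(detrended),
        chron_standardized=ch.build_chronology(standardized),
    )


def stats_table_row(site: SiteChronologies, period: tuple[int, int]) -> dict:
    """One row of the site-statistics table, detrended/standardized pairs."""
    sd = ch.chronology_stats(site.detrended, site.chron_detrended, period)
    ss = ch.chronology_stats(site.standardized, site.chron_standardized, period)
    return {
        "site": site.site_id,
        "n_trees": sd.n_series,
        "period": f"{period[0]}-{period[1]}",
        "rbar_detr": round(sd.rbar, 2), "rbar_std": round(ss.rbar, 2),
        "ms_detr": round(sd.ms, 2), "ms_std": round(ss.ms, 2),
        "ac_detr": round(sd.ac1, 2), "ac_std": round(ss.ac1, 2),
        "ac_chron_detr": round(sd.ac1_chronology, 2),
        "ac_chron_std": round(ss.ac1_chronology, 2),
        "eps_detr": round(sd.eps, 2), "eps_std": round(ss.eps, 2),
    }


def spei_suite(
    climate: MonthlyClimate,
    latitude_deg: float,
    scales: tuple[int, ...] = cs.SPEI_SCALES,
    calibration_period: tuple[int, int] | None = None,
) -> dict[int, cs.SPEISeries]:
    """SPEI at every requested accumulation scale for one site's climate."""
    pet = cs.thornthwaite_pet(climate, latitude_deg)
    d = cs.water_balance(climate, pet)
    return {
        k: cs.spei(d, k, calibration_period=calibration_period, site_id=climate.site_id)
        for k in scales
    }


@dataclass
class ReconResult:
    """Fitted candidate pools, selected models, gate window and predictions."""

    site_id: str
    table: pd.DataFrame
    rwi_models: list[rec.LinearReconModel]
    spei_models: list[rec.LinearReconModel]
    best_rwi: rec.LinearReconModel
    best_spei: rec.LinearReconModel
    window: rec.ReconstructionWindow | None
    predictions: pd.DataFrame
    verification: dict[str, dict] | None


def reconstruct_site(
    chron: ch.SiteChronology,
    spei_set: dict[int, cs.SPEISeries],
    target: HydroSeries | cs.WaterYearSeries,
    scales: tuple[int, ...] = RECON_SCALES,
    min_trees: int = 10,
    eps_threshold: float = 0.85,
) -> ReconResult:
    """Fit both predictor pools, select the best models, and reconstruct
    over the reliability-gated window."""
    target_wy = cs.water_year_mean(target) if isinstance(target, HydroSeries) else target
    spei_sub = {k: spei_set[k] for k in scales}
    table = rec.build_predictor_table(chron, spei_sub, target_wy)
    rwi_models = [rec.fit_ols(table, list(p)) for p in rec.RWI_POOL]
    spei_models = [rec.fit_ols(table, [f"spei_{k}"]) for k in scales]
    best_rwi = rec.select_best(rwi_models)
    best_spei = rec.select_best(spei_models)
    window = rec.reconstruction_window(chron, min_trees, eps_threshold)
    # predictors reach far beyond the short gauge record: reconstruct over
    # the whole gated window and attach observations where they exist
    chron_s = chron.to_series()
    frame = pd.DataFrame(
        {
            "rwi_t": chron_s,
            "rwi_t1": pd.Series(chron_s.to_numpy(), index=chron_s.index - 1),
            **{
                f"spei_{k}": cs.water_year_mean(spei_sub[k]).values()
                for k in scales
            },
        }
    )
    preds = pd.DataFrame(
        {
            "reconstructed_rwi": rec.predict(best_rwi, frame, window),
            "reconstructed_spei": rec.predict(best_spei, frame, window),
        }
    )
    preds.insert(0, "observed", target_wy.values().reindex(preds.index))
    preds.index.name = "water_year"
    verification = None
    if len(table) >= 20:
        verification = {
            "rwi": rec.verify(best_rwi, table),
            "spei": rec.verify(best_spei, table),
        }
    return ReconResult(
        site_id=target_wy.site_id,
        table=table,
        rwi_models=rwi_models,
        spei_models=spei_models,
        best_rwi=best_rwi,
        best_spei=best_spei,
        window=window,
        predictions=preds,
        verification=verification,
    )
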