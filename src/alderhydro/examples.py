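"""Worked-example reconstruction equations for the three-lake case study.

These are the published single-predictor regression equations for lake
level (LL) and groundwater level (GW) at the three Mecklenburg Lake
District study lakes, encoded as :class:`LinearReconModel` fixtures.  They
carry the original coefficients (abstract gauge units) so the prediction
interface can be exercised against known arithmetic; the calibration R²
values are the published ones, not refits.
"""

from __future__ import annotations

from .reconstruction import LinearReconModel

__all__ = ["WORKED_EXAMPLE_MODELS"]


def _model(target: str, predictor: str, slope: float, intercept: float,
           r2: float) -> LinearReconModel:
    return LinearReconModel(
        target=target,
        predictors=(predictor,),
        intercept=intercept,
        coefficients={predictor: slope},
        calibration_period=(1972, 2011),
        r2=r2,
        p_value=float("nan"),
        nobs=0,
    )


WORKED_EXAMPLE_MODELS: dict[str, LinearReconModel] = {
    # lake level, Tiefer See
    "tiefer_see_rwi": _model("lake_level", "rwi_t", 31.7834, 31.3010, 0.27),
    "tiefer_see_spei": _model("lake_level", "spei_24", 14.4390, 60.0453, 0.70),
    # lake level, Drewitzer See
    "drewitzer_rwi": _model("lake_level", "rwi_t1", -81.3328, 166.1264, 0.19),
    "drewitzer_spei": _model("lake_level", "spei_72", 36.8243, 100.8282, 0.47),
    # groundwater, Grosser Fuerstenseer See
    "fuerstensee_rwi": _model("groundwater", "rwi_t1", 0.7238, 59.7108, 0.16),
    "fuerstensee_spei": _model("groundwater", "spei_72", 0.3564, 60.3187, 0.63),
}
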