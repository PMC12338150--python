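"""Standard-curve quantitation, activity calling and Z-score matrices.

Quantitation follows the five-point external-calibration scheme: an
ordinary-least-squares line of intensity on concentration (μg/ml) per
species, inverted for unknowns and converted to μM with the species' average
molar mass.  Values below the 0.05 μM detection limit are reported as the
computed value with a below-LOD censoring flag; core transformations are
only *called* at or above the 0.1 μM reporting threshold.  An activity call
requires the (substrate, product) pair to be an edge of the transformation
graph under the condition actually fed to the strain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bile_chem import TransformationEdge

__all__ = [
    "StandardCurve",
    "LOD_UM",
    "REPORT_THRESHOLD_UM",
    "FLAG_QUANTIFIED",
    "FLAG_BELOW_REPORT",
    "FLAG_BELOW_LOD",
    "fit_standard_curve",
    "invert_curve",
    "ug_per_ml_to_uM",
    "call_activities",
    "percent_transformed",
    "zscore_matrix",
]

LOD_UM = 0.05
REPORT_THRESHOLD_UM = 0.1

FLAG_QUANTIFIED = "quantified"
FLAG_BELOW_REPORT = "below-report"
FLAG_BELOW_LOD = "below-LOD"

CONDITIONS = ("CA", "CDCA", "DCA", "MIX", "NONE")
TIME_POINTS_H = (24, 48)


@dataclass(frozen=True)
class StandardCurve:
    """Fitted calibration line: intensity = slope * conc(μg/ml) + intercept."""

    species_id: str
    slope: float
    intercept: float
    r_squared: float
    conc_min: float
    conc_max: float
    n_points: int

    @property
    def usable(self) -> bool:
        return self.slope > 0


def fit_standard_curve(concentrations, intensities, species_id: str = "") -> StandardCurve:
    """OLS fit of a calibration series (needs >=3 distinct concentrations)."""
    conc = np.asarray(concentrations, dtype=float)
    inten = np.asarray(intensities, dtype=float)
    if conc.size != inten.size:
        raise ValueError("concentration and intensity arrays differ in length")
    if conc.size < 3:
        raise ValueError("calibration needs at least 3 points")
    if np.any(conc <= 0):
        raise ValueError("calibration concentrations must be positive")
    if np.unique(conc).size < 2:
        raise ValueError("calibration concentrations have zero spread")
    res = stats.linregress(conc, inten)
    return StandardCurve(
        species_id=species_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        conc_min=float(conc.min()),
        conc_max=float(conc.max()),
        n_points=int(conc.size),
    )


def ug_per_ml_to_uM(conc_ug_ml: float, molar_mass: float) -> float:
    """μg/ml to μM via the average molar mass (g/mol)."""
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    return conc_ug_ml * 1000.0 / molar_mass


def invert_curve(intensity: float, curve: StandardCurve, molar_mass: float,
                 dilution_factor: float = 1.0, lod_um: float = LOD_UM,
                 report_um: float = REPORT_THRESHOLD_UM) -> tuple[float, str]:
    """Invert a calibration line to a μM concentration and a censoring flag.

    ``dilution_factor`` scales the measured concentration back to the culture
    (samples are typically diluted before injection).  Negative computed
    concentrations clamp to zero with a below-LOD flag.
    """
    if not curve.usable:
        raise ValueError(f"standard curve for {curve.species_id or '?'} is unusable "
                         f"(slope {curve.slope})")
    conc_ug_ml = (intensity - curve.intercept) / curve.slope
    if conc_ug_ml < 0:
        return 0.0, FLAG_BELOW_LOD
    conc_um = ug_per_ml_to_uM(conc_ug_ml, molar_mass) * dilution_factor
    if conc_um < lod_um:
        flag = FLAG_BELOW_LOD
    elif conc_um < report_um:
        flag = FLAG_BELOW_REPORT
    else:
        flag = FLAG_QUANTIFIED
    return conc_um, flag


def percent_transformed(product_sum_um: float, substrate_added_um: float) -> float:
    """Percentage of the added substrate recovered as products."""
    if substrate_added_um <= 0:
        raise ValueError("substrate_added_um must be positive")
    return 100.0 * product_sum_um / substrate_added_um


def call_activities(records: pd.DataFrame, graph: list[TransformationEdge],
                    threshold_um: float = REPORT_THRESHOLD_UM,
                    substrate_added_um: float = 100.0,
                    mass_balance_slack: float = 0.05
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Derive transformation-activity calls from concentration records.

    ``records`` columns: strain_id, condition, time_h, species_id, conc_um.
    For each graph edge whose substrate matches the condition (all three
    substrates under MIX, except that DCA production is never scored under
    MIX because DCA is itself an input there) and whose product reaches
    ``threshold_um`` at any time point, one call carries the maximum
    concentration.  Returns ``(calls, flags)`` where flags collects product
    detections in no-substrate controls (background) and products exceeding
    the added substrate by more than ``mass_balance_slack`` — both reported,
    never silently dropped.
    """
    call_cols = ["strain_id", "label", "substrate", "product",
                 "max_conc_um", "time_h", "condition"]
    flag_cols = ["strain_id", "condition", "time_h", "species_id", "conc_um", "flag"]
    calls: list[dict] = []
    flags: list[dict] = []
    if records.empty:
        return pd.DataFrame(columns=call_cols), pd.DataFrame(columns=flag_cols)

    products = {e.product for e in graph}
    by_edge_product = {e.product: e for e in graph}

    for _, r in records.iterrows():
        if r["condition"] == "NONE" and r["species_id"] in products and r["conc_um"] > 0:
            flags.append({**{k: r[k] for k in
                             ["strain_id", "condition", "time_h", "species_id", "conc_um"]},
                          "flag": "background"})
        if (r["species_id"] in products
                and r["conc_um"] > substrate_added_um * (1 + mass_balance_slack)
                and r["condition"] != "NONE"):
            flags.append({**{k: r[k] for k in
                             ["strain_id", "condition", "time_h", "species_id", "conc_um"]},
                          "flag": "exceeds-substrate"})

    for (strain,), strain_grp in records.groupby(["strain_id"]):
        for edge in graph:
            eligible = strain_grp[
                (strain_grp["species_id"] == edge.product)
                & (strain_grp["condition"].isin([edge.substrate, "MIX"]))
            ]
            if edge.product == "DCA":
                eligible = eligible[eligible["condition"] != "MIX"]
            if eligible.empty:
                continue
            best = eligible.loc[eligible["conc_um"].idxmax()]
            if best["conc_um"] >= threshold_um:
                calls.append({
                    "strain_id": strain,
                    "label": edge.label,
                    "substrate": edge.substrate,
                    "product": edge.product,
                    "max_conc_um": float(best["conc_um"]),
                    "time_h": int(best["time_h"]),
                    "condition": best["condition"],
                })
    return (pd.DataFrame(calls, columns=call_cols),
            pd.DataFrame(flags, columns=flag_cols))


def zscore_matrix(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Row-wise Z-score normalization (sample standard deviation, ddof=1).

    Rows are species, columns strains, mirroring signal-intensity heat maps.
    Zero-variance rows come back all-zero and are listed in the second
    return value rather than propagating NaNs.
    """
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    if values.shape[1] < 2:
        sd = np.zeros_like(mean)
    else:
        sd = values.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0) | ~np.isfinite(sd)
    safe_sd = np.where(flat, 1.0, sd)
    z = (values - mean) / safe_sd
    z[flat[:, 0], :] = 0.0
    out = pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
    return out, list(matrix.index[flat[:, 0]])
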