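"""MS1/MS2 ingestion, exact-mass library matching and fragment confirmation.

MS1 features are matched to library species by relative mass error (strictly
less than the configured ppm tolerance; default 2 ppm).  Retention time is
deliberately not used to identify conjugates without authentic standards; it
only associates MS2 spectra with features, gates species that do have a
standards retention time, and groups enantiomer double peaks.  MS2 evidence
follows the all-ion-fragmentation geometry of the acquisition: fixed
precursor windows (default centers 370/408/446/484/522 Th, 40 Th wide), and
a match is upgraded when at least two of the three predicted triad fragments
are found in an eligible window at the feature's retention time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Ms2Spectrum",
    "EVIDENCE_MS1",
    "EVIDENCE_MS1_MS2",
    "DEFAULT_MS2_CENTERS",
    "DEFAULT_ISOLATION_WIDTH",
    "ppm_error",
    "read_peak_table",
    "write_peak_table",
    "match_ms1",
    "confirm_ms2",
    "detect_double_peaks",
]

EVIDENCE_MS1 = "MS1_only"
EVIDENCE_MS1_MS2 = "MS1_plus_MS2"

DEFAULT_MS2_CENTERS = (370.0, 408.0, 446.0, 484.0, 522.0)
DEFAULT_ISOLATION_WIDTH = 40.0
DEFAULT_RUN_LENGTH_MIN = 31.5

PEAK_TABLE_COLUMNS = ["sample_id", "ms_level", "rt_min", "mz", "intensity",
                      "precursor_center", "isolation_width"]

FRAGMENT_NAMES = ("aa_anion", "aa_loss", "sterol")


@dataclass
class Ms2Spectrum:
    """One all-ion-fragmentation scan: a precursor window plus its peak list."""

    sample_id: str
    rt_min: float
    precursor_center: float
    isolation_width: float = DEFAULT_ISOLATION_WIDTH
    peaks: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))  # (m/z, intensity)

    def covers(self, mz: float) -> bool:
        return abs(mz - self.precursor_center) <= self.isolation_width / 2.0


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error, parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


def read_peak_table(path, run_length_min: float = DEFAULT_RUN_LENGTH_MIN
                    ) -> tuple[pd.DataFrame, list[Ms2Spectrum]]:
    """Read the comma-separated peak-table dialect.

    Returns the MS1 feature table and the grouped MS2 spectra.  Malformed
    rows (non-positive m/z, negative intensity, retention time outside the
    run) are dropped and reported with their line numbers via the module
    logger.
    """
    df = pd.read_csv(path)
    missing = [c for c in PEAK_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peak table {path} is missing required column(s): "
                         + ", ".join(missing))
    if df.empty:
        logger.warning("peak table %s contains a header but no rows", path)
        return df.assign(), []

    bad = (
        (df["mz"] <= 0)
        | (df["intensity"] < 0)
        | (df["rt_min"] < 0)
        | (df["rt_min"] > run_length_min)
    )
    if bad.any():
        # +2: one for the header line, one for 0-based indexing
        lines = [int(i) + 2 for i in df.index[bad]]
        logger.warning("peak table %s: dropped %d malformed row(s) at line(s) %s",
                       path, int(bad.sum()), lines)
        df = df[~bad]

    features = df[df["ms_level"] == 1].reset_index(drop=True)
    spectra = []
    ms2 = df[df["ms_level"] == 2]
    for (sample, rt, center, width), grp in ms2.groupby(
            ["sample_id", "rt_min", "precursor_center", "isolation_width"], sort=False):
        spectra.append(Ms2Spectrum(
            sample_id=sample, rt_min=float(rt), precursor_center=float(center),
            isolation_width=float(width),
            peaks=grp[["mz", "intensity"]].to_numpy(dtype=float)))
    return features, spectra


def write_peak_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=PEAK_TABLE_COLUMNS)


def match_ms1(features: pd.DataFrame, library: pd.DataFrame, tol_ppm: float = 2.0,
              standards_rt: dict[str, float] | None = None,
              rt_window: float = 0.5) -> pd.DataFrame:
    """Match MS1 features against a species library at strict ppm tolerance.

    ``library`` needs columns ``species_id``, ``mz_M_minus_H`` and
    ``isobaric_group``.  Every (feature, species) pair with |ppm| < tol_ppm
    is emitted, so a feature can hit several isobaric entries; the
    ``isobaric_n`` column counts the co-matching entries so downstream code
    can treat the ambiguity explicitly.  Species present in ``standards_rt``
    (authentic standards) are additionally gated to |rt - standard rt| <=
    rt_window.  Output is sorted by |ppm|.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    out_cols = ["sample_id", "feature_idx", "species_id", "rt_min", "intensity",
                "mz_obs", "mz_theo", "ppm", "evidence", "fragments_found",
                "isobaric_group", "isobaric_n"]
    if library.empty:
        logger.warning("match_ms1 called with an empty library")
        return pd.DataFrame(columns=out_cols)
    if features.empty:
        return pd.DataFrame(columns=out_cols)

    library = library.copy()
    if "isobaric_group" not in library.columns:
        # equal-formula species are indistinguishable by mass
        library["isobaric_group"] = library.get("formula", library["species_id"])
    lib = library.sort_values("mz_M_minus_H").reset_index(drop=True)
    lib_mz = lib["mz_M_minus_H"].to_numpy(dtype=float)
    feat_mz = features["mz"].to_numpy(dtype=float)

    lo = np.searchsorted(lib_mz, feat_mz * (1 - tol_ppm * 1e-6), side="left")
    hi = np.searchsorted(lib_mz, feat_mz * (1 + tol_ppm * 1e-6), side="right")

    rows = []
    for i in range(len(features)):
        if lo[i] >= hi[i]:
            continue
        feat = features.iloc[i]
        for j in range(lo[i], hi[i]):
            theo = lib_mz[j]
            err = ppm_error(feat["mz"], theo)
            if abs(err) >= tol_ppm:   # strict boundary
                continue
            sid = lib.at[j, "species_id"]
            if standards_rt and sid in standards_rt:
                if abs(feat["rt_min"] - standards_rt[sid]) > rt_window:
                    continue
            rows.append({
                "sample_id": feat["sample_id"],
                "feature_idx": int(i),
                "species_id": sid,
                "rt_min": float(feat["rt_min"]),
                "intensity": float(feat["intensity"]),
                "mz_obs": float(feat["mz"]),
                "mz_theo": float(theo),
                "ppm": float(err),
                "evidence": EVIDENCE_MS1,
                "fragments_found": "",
                "isobaric_group": lib.at[j, "isobaric_group"],
                "isobaric_n": 0,
            })
    matches = pd.DataFrame(rows, columns=out_cols)
    if matches.empty:
        return matches
    counts = matches.groupby(["feature_idx", "isobaric_group"])["species_id"].transform("size")
    matches["isobaric_n"] = counts.astype(int)
    return matches.sort_values("ppm", key=np.abs, kind="stable").reset_index(drop=True)


def confirm_ms2(matches: pd.DataFrame, spectra: list[Ms2Spectrum],
                triads: pd.DataFrame, frag_tol_ppm: float = 10.0,
                rt_window: float = 0.5, min_fragments: int = 2) -> pd.DataFrame:
    """Upgrade MS1 matches whose fragment triad is found in eligible MS2 scans.

    A scan is eligible when it belongs to the same sample, its precursor
    window contains the matched m/z, and its retention time lies within
    ``rt_window`` of the feature.  Fragments found across all eligible scans
    are pooled; evidence becomes MS1_plus_MS2 when at least ``min_fragments``
    of the three are found within ``frag_tol_ppm``.
    """
    if frag_tol_ppm <= 0:
        raise ValueError("frag_tol_ppm must be positive")
    if matches.empty:
        return matches.copy()
    triad_map = triads.set_index("species_id")[
        ["frag_aa_anion", "frag_aa_loss", "frag_sterol"]]

    out = matches.copy()
    evidence = []
    found_col = []
    for _, m in out.iterrows():
        sid = m["species_id"]
        if sid not in triad_map.index:
            evidence.append(EVIDENCE_MS1)
            found_col.append("")
            continue
        frag_mz = triad_map.loc[sid].to_numpy(dtype=float)
        found: set[str] = set()
        for spec in spectra:
            if spec.sample_id != m["sample_id"]:
                continue
            if not spec.covers(m["mz_obs"]):
                continue
            if abs(spec.rt_min - m["rt_min"]) > rt_window:
                continue
            if spec.peaks.size == 0:
                continue
            peak_mz = spec.peaks[:, 0]
            for name, fmz in zip(FRAGMENT_NAMES, frag_mz):
                if np.any(np.abs(peak_mz - fmz) / fmz * 1e6 <= frag_tol_ppm):
                    found.add(name)
        ordered = [n for n in FRAGMENT_NAMES if n in found]
        found_col.append(",".join(ordered))
        evidence.append(EVIDENCE_MS1_MS2 if len(found) >= min_fragments else EVIDENCE_MS1)
    out["evidence"] = evidence
    out["fragments_found"] = found_col
    return out


def detect_double_peaks(matches: pd.DataFrame, min_sep: float = 0.3) -> pd.DataFrame:
    """Find enantiomer-style double chromatographic peaks per species.

    For each (sample, species) with two or more matched features, adjacent
    features in retention-time order separated by at least ``min_sep``
    minutes form one pair.  Identical-mass d-/l-amino-acid conjugates show
    up exactly this way.
    """
    cols = ["sample_id", "species_id", "rt_first", "rt_second", "delta_rt"]
    if matches.empty:
        return pd.DataFrame(columns=cols)
    rows = []
    for (sample, sid), grp in matches.groupby(["sample_id", "species_id"]):
        rts = np.sort(grp["rt_min"].unique())
        for a, b in zip(rts[:-1], rts[1:]):
            if b - a >= min_sep:
                rows.append({"sample_id": sample, "species_id": sid,
                             "rt_first": float(a), "rt_second": float(b),
                             "delta_rt": float(b - a)})
    return pd.DataFrame(rows, columns=cols)
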