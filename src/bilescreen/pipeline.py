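"""End-to-end orchestration of the screen analysis stages.

``run_pipeline`` chains the stages over a simulated study: library
enumeration, MS1 matching and MS2 confirmation, calibration-curve
quantitation, activity calling, genotype prediction (operon + HSD cutoffs)
and genotype-phenotype concordance, then scores every stage against the
truth ledger.  All stage parameters live in :class:`RunConfig`, whose
defaults are the screen's published operating points (2 ppm MS1 tolerance,
0.05 μM detection limit, 0.1 μM reporting threshold, E <= 1e-10, 100,000 bp
operon window).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, bile_chem, concordance, genotype, ms_screen, quantify
from . import synthetic_data as synth

__all__ = ["RunConfig", "run_pipeline", "score_against_ledger", "write_outputs"]


@dataclass
class RunConfig:
    ms1_ppm: float = 2.0
    ms2_ppm: float = 10.0
    rt_window_min: float = 0.5
    lod_um: float = 0.05
    report_threshold_um: float = 0.1
    evalue_max: float = 1e-10
    operon_window_bp: int = 100_000
    evidence_min_fragments: int = 2     # 2-of-3 rule; set 3 for 3-of-3
    double_peak_min_sep: float = 0.3
    normalization_axis: str = "species"  # or "strain"
    panel: synth.PanelConfig = field(default_factory=synth.PanelConfig)

    def validate(self) -> list[str]:
        bad = [k for k in ("ms1_ppm", "ms2_ppm", "rt_window_min")
               if getattr(self, k) <= 0]
        if self.evalue_max <= 0:
            bad.append("evalue_max")
        if self.operon_window_bp <= 0:
            bad.append("operon_window_bp")
        if self.evidence_min_fragments not in (1, 2, 3):
            bad.append("evidence_min_fragments")
        if self.normalization_axis not in ("species", "strain"):
            bad.append("normalization_axis")
        return bad + self.panel.validate()

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        panel = synth.PanelConfig(**d.pop("panel", {}))
        return cls(panel=panel, **d)


def _split_sample(sample_id: str) -> tuple[str, str, int]:
    strain, cond, t = sample_id.split("|")
    return strain, cond, int(t)


def _spectra_from_frame(peaks: pd.DataFrame) -> list:
    ms2 = peaks[peaks["ms_level"] == 2]
    spectra = []
    for (sample, rt, center, width), grp in ms2.groupby(
            ["sample_id", "rt_min", "precursor_center", "isolation_width"],
            sort=False):
        spectra.append(ms_screen.Ms2Spectrum(
            sample_id=sample, rt_min=float(rt), precursor_center=float(center),
            isolation_width=float(width),
            peaks=grp[["mz", "intensity"]].to_numpy(dtype=float)))
    return spectra


def run_pipeline(config: RunConfig | None = None, seed: int = 0) -> dict:
    """Simulate one study and run every analysis stage over it.

    Returns a dict of stage artifacts: the truth ledger, the match report,
    concentration records, activity calls, genotype predictions, cutoffs,
    the concordance summary, the Z-score matrix and the ledger scores.
    """
    config = config or RunConfig()
    bad = config.validate()
    if bad:
        raise ValueError("invalid config key(s): " + ", ".join(bad))

    ledger = synth.simulate_panel(config.panel, seed)
    peaks = synth.emit_peak_tables(ledger)
    calibration = synth.emit_calibration(ledger)
    proteomes = synth.emit_proteomes(ledger)

    conj = bile_chem.enumerate_conjugates()
    conj_lib = bile_chem.library_frame(conj)
    core_lib = bile_chem.core_library_frame()
    library = pd.concat([conj_lib, core_lib], ignore_index=True)

    features = peaks[peaks["ms_level"] == 1].reset_index(drop=True)
    spectra = _spectra_from_frame(peaks)

    matches = ms_screen.match_ms1(
        features, library, tol_ppm=config.ms1_ppm,
        standards_rt=ledger["species_rt"], rt_window=config.rt_window_min)
    matches = ms_screen.confirm_ms2(
        matches, spectra, conj_lib, frag_tol_ppm=config.ms2_ppm,
        rt_window=config.rt_window_min,
        min_fragments=config.evidence_min_fragments)
    double_peaks = ms_screen.detect_double_peaks(
        matches[matches["species_id"].isin(conj_lib["species_id"])],
        min_sep=config.double_peak_min_sep)

    # calibration curves for quantified species
    curves = {}
    molar_mass = {}
    for sid, grp in calibration.groupby("species_id"):
        curves[sid] = quantify.fit_standard_curve(
            grp["conc_ug_ml"], grp["intensity"], species_id=sid)
        molar_mass[sid] = float(grp["molar_mass"].iloc[0])

    # concentration records for matched, quantifiable species
    conc_rows = []
    quantifiable = matches[matches["species_id"].isin(curves)]
    for (sample, sid), grp in quantifiable.groupby(["sample_id", "species_id"]):
        strain, cond, t = _split_sample(sample)
        inten = float(grp["intensity"].max())
        conc, flag = quantify.invert_curve(
            inten, curves[sid], molar_mass[sid],
            dilution_factor=config.panel.dilution_factor,
            lod_um=config.lod_um, report_um=config.report_threshold_um)
        conc_rows.append({"strain_id": strain, "condition": cond, "time_h": t,
                          "species_id": sid, "conc_um": conc, "flag": flag})
    concentrations = pd.DataFrame(
        conc_rows, columns=["strain_id", "condition", "time_h", "species_id",
                            "conc_um", "flag"])

    graph = bile_chem.transformation_graph()
    calls, qc_flags = quantify.call_activities(
        concentrations, graph, threshold_um=config.report_threshold_um,
        substrate_added_um=config.panel.substrate_um)

    # conjugate intensity matrix (24 h), Z-scored for the heat-map view
    conj_matches = matches[matches["species_id"].isin(conj_lib["species_id"])].copy()
    if not conj_matches.empty:
        parts = conj_matches["sample_id"].str.split("|", expand=True)
        conj_matches["strain_id"] = parts[0]
        conj_matches["time_h"] = parts[2].astype(int)
        pivot = (conj_matches[conj_matches["time_h"] == 24]
                 .pivot_table(index="species_id", columns="strain_id",
                              values="intensity", aggfunc="max", fill_value=0.0))
    else:
        pivot = pd.DataFrame()
    if pivot.empty:
        zscores, flat_rows = pd.DataFrame(), []
    elif config.normalization_axis == "strain":
        zt, flat_rows = quantify.zscore_matrix(pivot.T)
        zscores = zt.T
    else:
        zscores, flat_rows = quantify.zscore_matrix(pivot)

    # genotype: cutoffs from the reference score sets, then per-strain calls
    cutoffs = {}
    for cls, refs in proteomes["reference_scores"].items():
        cutoffs[cls] = genotype.select_cutoff(refs["pos"], refs["neg"], hsd_class=cls)
    operon_calls = {}
    hsd_predictions = {}
    for strain_id, art in proteomes["strains"].items():
        hits = genotype.filter_hits(art["blast_hits"], e_max=config.evalue_max)
        cds = _cds_frame_from_gff_text(art["gff"], strain_id)
        operon_calls[strain_id] = genotype.detect_bai_operon(
            hits, cds, window_bp=config.operon_window_bp, strain_id=strain_id)
        scores_by_class = {
            cls: list(df[["target_id", "bitscore"]].itertuples(index=False, name=None))
            for cls, df in art["hsd_scores"].items()}
        hsd_predictions[strain_id] = genotype.classify_hsd(
            scores_by_class, cutoffs, strain_id=strain_id)

    predicted = _predicted_records(operon_calls, hsd_predictions)
    observed = _observed_records(calls)
    summary = concordance.compare(predicted, observed)

    scores = score_against_ledger(ledger, features, matches, calls,
                                  operon_calls, hsd_predictions, cutoffs)
    return {
        "config": config, "seed": seed, "ledger": ledger, "peaks": peaks,
        "library": library, "matches": matches, "double_peaks": double_peaks,
        "calibration": calibration, "curves": curves,
        "concentrations": concentrations, "activity_calls": calls,
        "qc_flags": qc_flags, "zscores": zscores, "zscore_flat_rows": flat_rows,
        "cutoffs": cutoffs, "operon_calls": operon_calls,
        "hsd_predictions": hsd_predictions, "predicted": predicted,
        "observed": observed, "concordance": summary, "ledger_scores": scores,
    }


def _cds_frame_from_gff_text(gff_text: str, strain_id: str) -> pd.DataFrame:
    rows = []
    for line in gff_text.splitlines():
        if line.startswith("#") or not line.strip():
            continue
        f = line.split("\t")
        if f[2] != "CDS":
            continue
        attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
        rows.append({"cds_id": attrs.get("ID", ""), "contig": f[0],
                     "start": int(f[3]), "end": int(f[4]), "strand": f[6]})
    return pd.DataFrame(rows, columns=["cds_id", "contig", "start", "end", "strand"])


def _predicted_records(operon_calls: dict, hsd_predictions: dict) -> pd.DataFrame:
    rows = []
    for strain_id, pred in hsd_predictions.items():
        for cls, flag in pred.predicted.items():
            if flag:
                rows.append({"strain_id": strain_id, "activity_class": f"{cls}-HSD"})
    for strain_id, op in operon_calls.items():
        if op.canonical:
            rows.append({"strain_id": strain_id,
                         "activity_class": "7α-dehydroxylation"})
    return pd.DataFrame(rows, columns=["strain_id", "activity_class"])


def _observed_records(calls: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for _, c in calls.iterrows():
        for cls in concordance.map_activity_label(c["label"]):
            rows.append({"strain_id": c["strain_id"], "activity_class": cls})
    return pd.DataFrame(rows, columns=["strain_id", "activity_class"]
                        ).drop_duplicates().reset_index(drop=True)


def score_against_ledger(ledger: dict, features: pd.DataFrame,
                         matches: pd.DataFrame, calls: pd.DataFrame,
                         operon_calls: dict, hsd_predictions: dict,
                         cutoffs: dict) -> dict:
    """Score every pipeline stage against the generator's planted truth."""
    # --- conjugate recovery / decoy false matches / MS2 upgrades
    planted_pairs = set()
    planted_groups_by_strain: dict[str, set] = {}
    for strain_id, rec in ledger["strains"].items():
        for cj in rec["conjugates"]:
            planted_pairs.add((strain_id, cj["species_id"]))
            planted_groups_by_strain.setdefault(strain_id, set()).add(
                cj["isobaric_group"])

    m = matches.copy()
    if not m.empty:
        m["strain_id"] = m["sample_id"].str.split("|").str[0]
        m["origin"] = features.loc[m["feature_idx"], "origin"].to_numpy()
        m["origin_species"] = features.loc[m["feature_idx"],
                                           "origin_species"].to_numpy()
    conj_m = m[m["origin"] == "conjugate"] if not m.empty else m
    recovered = {(r["strain_id"], r["species_id"])
                 for _, r in conj_m.iterrows()} if not conj_m.empty else set()
    n_planted = len(planted_pairs)
    n_recovered = len(planted_pairs & recovered)
    decoy_matches = int((m["origin"] == "decoy").sum()) if not m.empty else 0
    false_groups = 0
    if not conj_m.empty:
        for _, r in conj_m.iterrows():
            if r["isobaric_group"] not in planted_groups_by_strain.get(
                    r["strain_id"], set()):
                false_groups += 1
    # MS2 upgrades are judged on each planted species' own feature; a planted
    # species co-matching an isobaric partner's feature is expected to stay
    # MS1-only there (that is what fragment confirmation disambiguates)
    planted_conj_m = conj_m[
        (conj_m["origin_species"] == conj_m["species_id"])
        & np.array([(r["strain_id"], r["species_id"]) in planted_pairs
                    for _, r in conj_m.iterrows()])] if not conj_m.empty else conj_m
    n_conf = int((planted_conj_m["evidence"] == ms_screen.EVIDENCE_MS1_MS2).sum()) \
        if not planted_conj_m.empty else 0
    n_conj_matches = len(planted_conj_m)

    # --- activity agreement and quantitation error
    planted_edges = {(sid, a["substrate"], a["product"])
                     for sid, rec in ledger["strains"].items()
                     for a in rec["activities"]}
    called_edges = {(c["strain_id"], c["substrate"], c["product"])
                    for _, c in calls.iterrows()}
    union = planted_edges | called_edges
    agreement = len(planted_edges & called_edges) / len(union) if union else 1.0

    planted_c48 = {(sid, a["substrate"], a["product"]): a["conc_um"]["48"]
                   for sid, rec in ledger["strains"].items()
                   for a in rec["activities"]}
    rel_errors = []
    for _, c in calls.iterrows():
        key = (c["strain_id"], c["substrate"], c["product"])
        if key in planted_c48:
            truth = planted_c48[key]
            rel_errors.append(abs(c["max_conc_um"] - truth) / truth)
    median_rel_err = float(np.median(rel_errors)) if rel_errors else float("nan")

    # --- genotype accuracy
    operon_correct = sum(
        1 for sid, rec in ledger["strains"].items()
        if operon_calls[sid].canonical
        == (bool(rec["operon"]) and rec["operon"]["kind"] == "canonical"))
    hsd_cells = 0
    hsd_correct = 0
    for sid, rec in ledger["strains"].items():
        planted = set(rec["hsd_classes"])
        for cls in genotype.HSD_CLASSES:
            hsd_cells += 1
            if hsd_predictions[sid].predicted.get(cls, False) == (cls in planted):
                hsd_correct += 1

    n_strains = len(ledger["strains"])
    return {
        "n_strains": n_strains,
        "n_planted_conjugates": n_planted,
        "conjugate_recovery": n_recovered / n_planted if n_planted else 1.0,
        "decoy_matches": decoy_matches,
        "false_isobaric_groups": false_groups,
        "ms2_upgrade_rate": n_conf / n_conj_matches if n_conj_matches else 1.0,
        "n_planted_activities": len(planted_edges),
        "n_activity_calls": len(called_edges),
        "activity_agreement": agreement,
        "median_quant_rel_error": median_rel_err,
        "operon_accuracy": operon_correct / n_strains,
        "hsd_accuracy": hsd_correct / hsd_cells if hsd_cells else 1.0,
        "cutoff_f": {cls: r.f_at_cutoff for cls, r in cutoffs.items()},
    }


# ---------------------------------------------------------------------------
# file outputs

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_outputs(result: dict, out_dir) -> Path:
    """Write the stage outputs plus a reproducibility manifest; returns out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = result["config"]

    result["library"].to_csv(out / "library.tsv", sep="\t", index=False)
    result["matches"].to_csv(out / "matches.tsv", sep="\t", index=False)
    result["double_peaks"].to_csv(out / "double_peaks.tsv", sep="\t", index=False)
    result["concentrations"].to_csv(out / "concentrations.tsv", sep="\t", index=False)
    result["activity_calls"].to_csv(out / "activity_calls.tsv", sep="\t", index=False)
    result["qc_flags"].to_csv(out / "qc_flags.tsv", sep="\t", index=False)
    result["zscores"].to_csv(out / "zscore_matrix.tsv", sep="\t")
    synth.save_ledger(result["ledger"], out / "ledger.json")

    cutoffs = {cls: {"cutoff": r.cutoff, "f": r.f_at_cutoff,
                     "scan": [{"threshold": t, "f": f, "tp": tp, "fp": fp, "fn": fn}
                              for t, f, tp, fp, fn in r.scan]}
               for cls, r in result["cutoffs"].items()}
    (out / "cutoffs.json").write_text(json.dumps(cutoffs, ensure_ascii=False, indent=1))

    op_rows = [{"strain_id": sid, "genes_present": ",".join(sorted(op.genes_present)),
                "n_genes": len(op.genes_present), "span_bp": op.span,
                "contig": op.contig or "", "canonical": op.canonical}
               for sid, op in result["operon_calls"].items()]
    pd.DataFrame(op_rows).to_csv(out / "operon_calls.tsv", sep="\t", index=False)

    pred_rows = []
    for sid, pred in result["hsd_predictions"].items():
        for cls, flag in pred.predicted.items():
            pred_rows.append({
                "strain_id": sid, "hsd_class": cls, "predicted": flag,
                "support": ";".join(f"{c}:{s:.1f}" for c, s in pred.support[cls])})
    pd.DataFrame(pred_rows).to_csv(out / "hsd_predictions.tsv", sep="\t", index=False)

    (out / "concordance.json").write_text(
        json.dumps(result["concordance"].to_dict(), ensure_ascii=False, indent=1))
    (out / "ledger_scores.json").write_text(
        json.dumps(result["ledger_scores"], ensure_ascii=False, indent=1))

    manifest = {
        "package_version": __version__,
        "seed": result["seed"],
        "config": asdict(config),
        "config_hash": synth.config_hash(asdict(config)),
        "output_checksums": {p.name: _sha256(p) for p in sorted(out.iterdir())
                             if p.is_file() and p.name != "run_manifest.json"},
    }
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, ensure_ascii=False, indent=1, sort_keys=True))
    return out
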