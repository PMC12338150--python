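"""Synthetic bile acid screens with a verifiable truth ledger.

One seeded call produces a full in-silico study: a strain panel with planted
transformation activities and conjugation repertoires, MS1 peak tables with
ppm-jittered features plus decoys, MS2 fragment triads in the correct
precursor windows, five-point calibration series, and per-strain proteomes
(CDS coordinates, bai BLAST hit tables, HSD profile score tables) consistent
with the planted genotype.  The ledger records everything planted so each
downstream stage can be scored exactly.

The default panel mirrors the scale and conditions of a typical in vitro
screen: 72 strains, three single-substrate conditions (CA, CDCA, DCA at
100 μM), a 300 μM MIX condition, a no-substrate control, and sampling at 24
and 48 h.  Concentration-to-intensity follows the same linear calibration
model the quantitation stage inverts, so recovery is exact at zero noise by
construction — the generator tests the pipeline's plumbing, not the
chemistry.  Planted conjugates are restricted to species whose [M-H]- falls
inside an MS2 isolation window, since species outside the acquisition
windows could never be fragment-confirmed.

All randomness flows from numpy Generators derived from (seed, stage), so a
ledger and every emission from it are reproducible bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bile_chem
from .bile_chem import (LABEL_3A, LABEL_7A, LABEL_12A, LABEL_7A12A,
                        LABEL_DEHYDROX, LABEL_EPI, LABEL_OTHER)
from .genotype import BAI_GENES, CANONICAL_BAI_GENES, HSD_CLASSES
from .ms_screen import (DEFAULT_ISOLATION_WIDTH, DEFAULT_MS2_CENTERS,
                        PEAK_TABLE_COLUMNS)

__all__ = [
    "PanelConfig",
    "simulate_panel",
    "emit_peak_tables",
    "emit_calibration",
    "emit_proteomes",
    "make_protein_family",
    "save_ledger",
    "load_ledger",
    "write_study",
    "format_tblout",
    "config_hash",
]

CONDITIONS = ("CA", "CDCA", "DCA", "MIX", "NONE")
SUBSTRATES = ("CA", "CDCA", "DCA")
TIME_POINTS = (24, 48)

#: calibration grid, μg/ml
CALIBRATION_GRID = (0.01, 0.05, 0.1, 0.5, 1.0)

_REF_SET_SIZES = {"3α": 6, "7α": 5, "12α": 6}


@dataclass
class PanelConfig:
    """Study-design knobs for the synthetic screen.

    Defaults reproduce the conditions of the screen the generator emulates:
    panel size 72, ~60% of strains transforming at least one bile acid,
    substrate dosing at 100 μM, and per-class product concentration ranges
    matching the reported 48-h spreads (7α dehydrogenation up to ~94 μM, 12α
    up to ~29 μM, 3α up to ~9 μM).
    """

    n_strains: int = 72
    prevalence: float = 0.6
    conjugation_prevalence: float = 0.4
    activity_prevalence: dict = field(default_factory=lambda: {
        LABEL_7A: 0.88, LABEL_3A: 0.58, LABEL_12A: 0.28,
        LABEL_DEHYDROX: 0.12, LABEL_7A12A: 0.03, LABEL_EPI: 0.05,
        LABEL_OTHER: 0.07,
    })
    # 48-h product concentration ranges, μM, drawn log-uniformly.  Lower
    # bounds sit just above the 0.1 μM reporting threshold so that every
    # planted activity is in principle detectable.
    conc_range_um: dict = field(default_factory=lambda: {
        LABEL_7A: (0.16, 93.9), LABEL_3A: (0.12, 9.35), LABEL_12A: (0.19, 28.6),
        LABEL_DEHYDROX: (0.5, 50.0), LABEL_7A12A: (0.12, 2.0),
        LABEL_EPI: (0.12, 2.0), LABEL_OTHER: (0.12, 2.0),
    })
    substrate_um: float = 100.0
    # the generator emits intensities in measured space; sample-prep dilution
    # is not modelled by default but flows through quantitation if set
    dilution_factor: float = 1.0
    jitter_ppm_sigma: float = 0.3
    jitter_ppm_max: float = 1.5
    decoys_per_strain: int = 500
    decoy_min_ppm: float = 5.0
    intensity_noise: float = 0.05
    calibration_noise: float = 0.01
    rt_noise_min: float = 0.05
    enantiomer_fraction: float = 0.3
    max_conjugates_per_strain: int = 8
    n_background_cds: int = 30
    partial_operon_prob: float = 0.1
    ref_pos_band: tuple = (220.0, 370.0)
    ref_neg_band: tuple = (10.0, 90.0)
    planted_score_band: tuple = (380.0, 450.0)
    background_score_band: tuple = (10.0, 90.0)

    def validate(self) -> list[str]:
        bad = []
        if self.n_strains < 1:
            bad.append("n_strains")
        for key in ("prevalence", "conjugation_prevalence", "enantiomer_fraction",
                    "partial_operon_prob"):
            v = getattr(self, key)
            if not (0.0 <= v <= 1.0):
                bad.append(key)
        for key in ("jitter_ppm_sigma", "jitter_ppm_max", "intensity_noise",
                    "calibration_noise", "rt_noise_min", "decoy_min_ppm"):
            if getattr(self, key) < 0:
                bad.append(key)
        if self.decoys_per_strain < 0:
            bad.append("decoys_per_strain")
        if self.substrate_um <= 0:
            bad.append("substrate_um")
        if self.dilution_factor <= 0:
            bad.append("dilution_factor")
        for label, (lo, hi) in self.conc_range_um.items():
            if not (0 < lo <= hi):
                bad.append(f"conc_range_um[{label}]")
        return bad


def config_hash(config: PanelConfig | dict) -> str:
    d = asdict(config) if isinstance(config, PanelConfig) else config
    blob = json.dumps(d, sort_keys=True, ensure_ascii=False, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stage)])


def _loguniform(rng, lo, hi, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def _classes_of(activities) -> list[str]:
    classes = set()
    for a in activities:
        if a["label"] == LABEL_3A:
            classes.add("3α")
        elif a["label"] == LABEL_7A:
            classes.add("7α")
        elif a["label"] == LABEL_12A:
            classes.add("12α")
        elif a["label"] == LABEL_7A12A:
            classes.update(("7α", "12α"))
    return sorted(classes, key=HSD_CLASSES.index)


def _ms2_coverable(mz: float) -> bool:
    return any(abs(mz - c) <= DEFAULT_ISOLATION_WIDTH / 2 for c in DEFAULT_MS2_CENTERS)


def _condition_for_core(core_abbrev: str, rng) -> str:
    if core_abbrev in SUBSTRATES:
        return core_abbrev
    if core_abbrev == "7-oxoLCA":
        return "CDCA"
    return str(rng.choice(SUBSTRATES))


def simulate_panel(config: PanelConfig | None = None, seed: int = 0) -> dict:
    """Generate the truth ledger for one synthetic screen."""
    config = config or PanelConfig()
    bad = config.validate()
    if bad:
        raise ValueError("invalid config key(s): " + ", ".join(bad))
    rng = _rng(seed, 0)

    cores = bile_chem.build_core_registry()
    conjugates = bile_chem.enumerate_conjugates()
    graph = bile_chem.transformation_graph()
    edges_by_label: dict[str, list] = {}
    for e in graph:
        edges_by_label.setdefault(e.label, []).append(e)

    # canonical standards retention times: cores spaced well apart so that
    # isobaric cores are resolved chromatographically, glycine conjugates last
    species_rt = {c.abbreviation: round(4.0 + 1.6 * i, 3)
                  for i, c in enumerate(cores)}
    for i, sid in enumerate(("CA-Gly", "CDCA-Gly", "DCA-Gly")):
        species_rt[sid] = round(28.6 + 0.8 * i, 3)

    # linear calibration model per quantified species
    curves = {}
    quantified = [(c.abbreviation, c.average_mass) for c in cores]
    conj_by_id = {s.species_id: s for s in conjugates}
    for sid in ("CA-Gly", "CDCA-Gly", "DCA-Gly"):
        quantified.append((sid, bile_chem.average_mass(conj_by_id[sid].composition)))
    for sid, mw in quantified:
        curves[sid] = {"slope": float(_loguniform(rng, 5e3, 5e4)),
                       "intercept": 0.0, "molar_mass": float(mw)}

    coverable = [s for s in conjugates if _ms2_coverable(s.mz_mh)]
    aa_weight = {"Gly": 4.0, "Phe": 3.0}
    weights = np.array([aa_weight.get(s.aa_label, 1.0) for s in coverable])
    weights = weights / weights.sum()

    labels = list(config.activity_prevalence)
    label_p = np.array([config.activity_prevalence[l] for l in labels])

    strains = {}
    for i in range(config.n_strains):
        sid = f"S{i + 1:03d}"
        activities = []
        if rng.random() < config.prevalence:
            chosen = [l for l, p in zip(labels, label_p) if rng.random() < p]
            if not chosen:
                chosen = [str(rng.choice(labels, p=label_p / label_p.sum()))]
            for label in chosen:
                edges = edges_by_label[label]
                take = [e for e in edges if rng.random() < 0.8]
                if not take:
                    take = [edges[int(rng.integers(len(edges)))]]
                lo, hi = config.conc_range_um[label]
                for e in take:
                    c48 = float(_loguniform(rng, lo, hi))
                    c24 = float(c48 * rng.uniform(0.4, 0.95))
                    activities.append({"substrate": e.substrate, "product": e.product,
                                       "label": label,
                                       "conc_um": {"24": c24, "48": c48}})
        conj_records = []
        if rng.random() < config.conjugation_prevalence:
            n = int(rng.integers(1, config.max_conjugates_per_strain + 1))
            idx = rng.choice(len(coverable), size=min(n, len(coverable)),
                             replace=False, p=weights)
            for j in sorted(int(k) for k in idx):
                sp = coverable[j]
                # species with an authentic standard elute at the standard RT
                rt = float(species_rt.get(sp.species_id,
                                          np.round(rng.uniform(5.0, 27.0), 3)))
                rts = [rt]
                if (sp.aa_label in ("Ala", "Val")
                        and rng.random() < config.enantiomer_fraction):
                    rts.append(float(np.round(rt + rng.uniform(0.5, 1.5), 3)))
                conj_records.append({
                    "species_id": sp.species_id,
                    "isobaric_group": sp.isobaric_group,
                    "condition": _condition_for_core(sp.core.abbreviation, rng),
                    "rt_min": rts,
                    "intensity": float(_loguniform(rng, 1e4, 1e6)),
                })
        hsd_classes = _classes_of(activities)
        has_dehydrox = any(a["label"] == LABEL_DEHYDROX for a in activities)
        if has_dehydrox:
            operon = {"genes": sorted(CANONICAL_BAI_GENES), "kind": "canonical"}
        elif rng.random() < config.partial_operon_prob:
            n_genes = int(rng.integers(4, 6))
            genes = sorted(rng.choice(list(CANONICAL_BAI_GENES), size=n_genes,
                                      replace=False))
            operon = {"genes": [str(g) for g in genes], "kind": "partial"}
        else:
            operon = None
        strains[sid] = {
            "activities": activities,
            "conjugates": conj_records,
            "hsd_classes": hsd_classes,
            "operon": operon,
        }

    # canonical JSON form so the ledger round-trips losslessly
    cfg = json.loads(json.dumps(asdict(config)))
    return {
        "seed": int(seed),
        "config": cfg,
        "config_hash": config_hash(cfg),
        "species_rt": species_rt,
        "curves": curves,
        "strains": strains,
    }


# ---------------------------------------------------------------------------
# peak tables

def _noise_factor(rng, sigma: float) -> float:
    if sigma == 0:
        return 1.0
    return 1.0 + sigma * float(np.clip(rng.standard_normal(), -3.0, 3.0))


def emit_peak_tables(ledger: dict) -> pd.DataFrame:
    """MS1 features and MS2 triad spectra for every strain sample.

    Returns one frame in the peak-table dialect plus two bookkeeping columns
    (``origin``, ``origin_species``) that identify each MS1 row as
    substrate / product / conjugate / decoy; ``write_study`` drops them when
    writing dialect files.
    """
    cfg = PanelConfig(**ledger["config"])
    rng = _rng(ledger["seed"], 1)
    cores = {c.abbreviation: c for c in bile_chem.build_core_registry()}
    conjugates = {s.species_id: s for s in bile_chem.enumerate_conjugates()}
    curves = ledger["curves"]
    species_rt = ledger["species_rt"]

    lib_mz = np.sort(np.array(
        [s.mz_mh for s in conjugates.values()]
        + [c.monoisotopic_mass - bile_chem.PROTON_MASS for c in cores.values()]))

    def jitter(mz: float) -> float:
        j = float(np.clip(rng.standard_normal() * cfg.jitter_ppm_sigma,
                          -cfg.jitter_ppm_max, cfg.jitter_ppm_max))
        return mz * (1.0 + j * 1e-6)

    def core_intensity(sid: str, conc_um: float) -> float:
        cur = curves[sid]
        conc_ug_ml = conc_um * cur["molar_mass"] / 1000.0 / cfg.dilution_factor
        return (cur["slope"] * conc_ug_ml + cur["intercept"]) \
            * _noise_factor(rng, cfg.intensity_noise)

    rows = []

    def add_ms1(sample, rt, mz, inten, origin, species):
        rows.append({"sample_id": sample, "ms_level": 1, "rt_min": round(rt, 4),
                     "mz": mz, "intensity": inten, "precursor_center": np.nan,
                     "isolation_width": np.nan, "origin": origin,
                     "origin_species": species})

    def add_ms2(sample, rt, mz_parent, triad):
        center = next((c for c in DEFAULT_MS2_CENTERS
                       if abs(mz_parent - c) <= DEFAULT_ISOLATION_WIDTH / 2), None)
        if center is None:
            return
        peaks = [(fmz * (1.0 + rng.normal(0, 2.0) * 1e-6), rng.uniform(1e3, 1e5))
                 for fmz in triad]
        # unrelated noise peaks
        peaks += [(rng.uniform(center - 20, center + 20), rng.uniform(1e2, 1e3))
                  for _ in range(2)]
        for mz, inten in peaks:
            rows.append({"sample_id": sample, "ms_level": 2, "rt_min": round(rt, 4),
                         "mz": mz, "intensity": inten,
                         "precursor_center": center,
                         "isolation_width": DEFAULT_ISOLATION_WIDTH,
                         "origin": "ms2", "origin_species": ""})

    for strain_id, rec in ledger["strains"].items():
        products_by_cond: dict[str, list] = {}
        for a in rec["activities"]:
            products_by_cond.setdefault(a["substrate"], []).append(a)
        samples = [(cond, t) for cond in CONDITIONS for t in TIME_POINTS]
        for cond, t in samples:
            sample = f"{strain_id}|{cond}|{t}"
            substrates = (SUBSTRATES if cond == "MIX"
                          else (cond,) if cond in SUBSTRATES else ())
            active = ([a for s in substrates for a in products_by_cond.get(s, [])]
                      if substrates else [])
            if cond == "MIX":
                active = [a for a in active if a["product"] != "DCA"]
            # substrate features at what remains after transformation
            for s in substrates:
                used = sum(a["conc_um"][str(t)] for a in products_by_cond.get(s, []))
                remaining = max(cfg.substrate_um - used, 0.02 * cfg.substrate_um)
                mz = cores[s].monoisotopic_mass - bile_chem.PROTON_MASS
                rt = species_rt[s] + rng.normal(0, cfg.rt_noise_min)
                add_ms1(sample, rt, jitter(mz), core_intensity(s, remaining),
                        "substrate", s)
            # product features
            for a in active:
                conc = a["conc_um"][str(t)]
                if conc <= 0:
                    continue
                p = a["product"]
                mz = cores[p].monoisotopic_mass - bile_chem.PROTON_MASS
                rt = species_rt[p] + rng.normal(0, cfg.rt_noise_min)
                add_ms1(sample, rt, jitter(mz), core_intensity(p, conc),
                        "product", p)
            # conjugates, with MS2 triads
            if cond in SUBSTRATES:
                for cj in rec["conjugates"]:
                    if cj["condition"] != cond:
                        continue
                    sp = conjugates[cj["species_id"]]
                    for k, rt in enumerate(cj["rt_min"]):
                        inten = cj["intensity"] * (0.6 if k else 1.0) \
                            * _noise_factor(rng, cfg.intensity_noise)
                        add_ms1(sample, rt, jitter(sp.mz_mh), inten,
                                "conjugate", sp.species_id)
                        add_ms2(sample, rt, sp.mz_mh,
                                (sp.fragments.aa_anion, sp.fragments.aa_loss,
                                 sp.fragments.sterol))
        # decoys, kept >= decoy_min_ppm away from every library mass
        n = cfg.decoys_per_strain
        mzs = np.empty(0)
        while mzs.size < n:
            draw = rng.uniform(290.0, 1000.0, size=2 * (n - mzs.size))
            pos = np.searchsorted(lib_mz, draw)
            lo = lib_mz[np.clip(pos - 1, 0, lib_mz.size - 1)]
            hi = lib_mz[np.clip(pos, 0, lib_mz.size - 1)]
            dist_ppm = np.minimum(np.abs(draw - lo), np.abs(draw - hi)) / draw * 1e6
            mzs = np.concatenate([mzs, draw[dist_ppm >= cfg.decoy_min_ppm]])
        mzs = mzs[:n]
        which = rng.integers(0, len(samples), size=n)
        rts = rng.uniform(0.5, 31.0, size=n)
        intens = _loguniform(rng, 1e3, 1e5, size=n)
        for mz, w, rt, inten in zip(mzs, which, rts, intens):
            cond, t = samples[int(w)]
            add_ms1(f"{strain_id}|{cond}|{t}", float(rt), float(mz), float(inten),
                    "decoy", "")

    return pd.DataFrame(rows, columns=PEAK_TABLE_COLUMNS + ["origin", "origin_species"])


# ---------------------------------------------------------------------------
# calibration

def emit_calibration(ledger: dict) -> pd.DataFrame:
    """Five-point standards series per quantified species.

    Columns: species_id, rt_min, molar_mass, conc_ug_ml, intensity.  The
    intensities follow each species' planted line with multiplicative
    calibration noise.
    """
    cfg = PanelConfig(**ledger["config"])
    rng = _rng(ledger["seed"], 2)
    rows = []
    for sid, cur in ledger["curves"].items():
        for conc in CALIBRATION_GRID:
            inten = (cur["slope"] * conc + cur["intercept"]) \
                * _noise_factor(rng, cfg.calibration_noise)
            rows.append({"species_id": sid,
                         "rt_min": ledger["species_rt"].get(sid, np.nan),
                         "molar_mass": cur["molar_mass"],
                         "conc_ug_ml": conc, "intensity": inten})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# proteomes, hit tables, score tables

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(rng, length: int) -> str:
    return "".join(rng.choice(list(_AA20), size=length))


def make_protein_family(rng, length: int = 120, n_members: int = 8,
                        mutation_rate: float = 0.1) -> list[str]:
    """An ungapped synthetic protein family: mutated copies of one ancestor."""
    ancestor = _random_protein(rng, length)
    family = []
    for _ in range(n_members):
        seq = list(ancestor)
        for i in range(length):
            if rng.random() < mutation_rate:
                seq[i] = str(rng.choice(list(_AA20)))
        family.append("".join(seq))
    return family


def format_tblout(query_id: str, rows: list[tuple[str, float, float]]) -> str:
    """Render (target, evalue, bitscore) rows in hmmsearch --tblout layout."""
    header = (
        "#                                                               "
        "--- full sequence ---- --- best 1 domain ---- "
        "--- domain number estimation ----\n"
        "# target name        accession  query name           accession  "
        "  E-value  score  bias   E-value  score  bias   exp reg clu  ov "
        "env dom rep inc description of target\n"
        "#------------------- ---------- -------------------- ---------- "
        "--------- ------ ----- --------- ------ -----   --- --- --- --- "
        "--- --- --- --- ---------------------\n")
    lines = [header]
    for target, evalue, score in rows:
        lines.append(
            f"{target:<20s} -          {query_id:<20s} -          "
            f"{evalue:9.2g} {score:6.1f}   0.0 {evalue:9.2g} {score:6.1f}"
            f"   0.0   1.0   1   0   0   1   1   1   1 -\n")
    lines.append("#\n# Program:         hmmsearch\n")
    return "".join(lines)


def emit_proteomes(ledger: dict) -> dict:
    """Per-strain proteome artifacts plus panel-level reference score sets.

    Returns ``{"strains": {id: {"fasta", "gff", "blast_hits", "hsd_scores"}},
    "reference_scores": {class: {"pos": [...], "neg": [...]}}}``.  Planted
    HSD genes score inside the high band, background genes in the low band;
    the per-class reference sets are separable so cutoff selection recovers
    F = 1.  bai-operon genes are placed as a contiguous gene block on one
    contig, well inside the co-localization window.
    """
    cfg = PanelConfig(**ledger["config"])
    rng = _rng(ledger["seed"], 3)

    reference_scores = {}
    for cls in HSD_CLASSES:
        pos = sorted(float(x) for x in
                     rng.uniform(*cfg.ref_pos_band, size=_REF_SET_SIZES[cls]))
        n_neg = sum(n for c, n in _REF_SET_SIZES.items() if c != cls)
        neg = sorted(float(x) for x in rng.uniform(*cfg.ref_neg_band, size=n_neg))
        reference_scores[cls] = {"pos": pos, "neg": neg}

    strains_out = {}
    for strain_id, rec in ledger["strains"].items():
        operon_genes = list(rec["operon"]["genes"]) if rec["operon"] else []
        hsd_classes = list(rec["hsd_classes"])

        n_bg = cfg.n_background_cds
        gene_plan = [("bg", None)] * n_bg
        insert_at = int(rng.integers(0, n_bg + 1))
        gene_plan[insert_at:insert_at] = [("bai", g) for g in operon_genes]
        # dedicate one background gene per planted HSD class
        hsd_cds_slots = {}
        bg_indices = [i for i, (kind, _) in enumerate(gene_plan) if kind == "bg"]
        picks = rng.choice(len(bg_indices), size=len(hsd_classes), replace=False)
        for cls, p in zip(hsd_classes, picks):
            hsd_cds_slots[bg_indices[int(p)]] = cls

        fasta_lines = []
        gff_lines = ["##gff-version 3\n"]
        cds_meta = []
        cursor = int(rng.integers(200, 600))
        for idx, (kind, gene) in enumerate(gene_plan):
            aa_len = int(rng.integers(250, 550))
            length = 3 * (aa_len + 1)
            start, end = cursor, cursor + length - 1
            cursor = end + int(rng.integers(100, 400))
            cds_id = f"{strain_id}_cds{idx:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            seq = _random_protein(rng, aa_len)
            fasta_lines.append(f">{cds_id}\n{seq}\n")
            gff_lines.append(
                f"ctg1\tsynth\tCDS\t{start}\t{end}\t.\t{strand}\t0\tID={cds_id}\n")
            cds_meta.append({"cds_id": cds_id, "idx": idx, "kind": kind,
                             "gene": gene, "aa_len": aa_len})

        blast_rows = []
        for meta in cds_meta:
            if meta["kind"] != "bai":
                continue
            evalue = 10.0 ** -rng.uniform(30, 120)
            blast_rows.append({
                "query_id": meta["gene"], "target_id": meta["cds_id"],
                "pident": float(np.round(rng.uniform(70, 99), 1)),
                "length": meta["aa_len"], "mismatch": int(rng.integers(1, 40)),
                "gapopen": 0, "qstart": 1, "qend": meta["aa_len"],
                "sstart": 1, "send": meta["aa_len"],
                "evalue": float(evalue), "bitscore": float(rng.uniform(300, 800)),
            })
        # weak spurious hits that must fall to the E-value gate
        for _ in range(3):
            meta = cds_meta[int(rng.integers(len(cds_meta)))]
            blast_rows.append({
                "query_id": str(rng.choice(BAI_GENES)), "target_id": meta["cds_id"],
                "pident": float(np.round(rng.uniform(20, 35), 1)),
                "length": int(rng.integers(40, 120)), "mismatch": int(rng.integers(20, 80)),
                "gapopen": int(rng.integers(0, 5)), "qstart": 1, "qend": 100,
                "sstart": 1, "send": 100,
                "evalue": 10.0 ** -rng.uniform(3, 9),
                "bitscore": float(rng.uniform(25, 60)),
            })
        blast_hits = pd.DataFrame(
            blast_rows, columns=["query_id", "target_id", "pident", "length",
                                 "mismatch", "gapopen", "qstart", "qend",
                                 "sstart", "send", "evalue", "bitscore"])

        hsd_scores = {}
        slot_by_class = {cls: idx for idx, cls in hsd_cds_slots.items()}
        for cls in HSD_CLASSES:
            rows = []
            if cls in slot_by_class:
                planted = cds_meta[slot_by_class[cls]]
                rows.append({"query_id": f"hsd_{cls}", "target_id": planted["cds_id"],
                             "evalue": 10.0 ** -rng.uniform(60, 120),
                             "bitscore": float(rng.uniform(*cfg.planted_score_band))})
            bg_pick = rng.choice(len(cds_meta), size=4, replace=False)
            for b in bg_pick:
                meta = cds_meta[int(b)]
                if cls in slot_by_class and meta["idx"] == slot_by_class[cls]:
                    continue
                rows.append({"query_id": f"hsd_{cls}", "target_id": meta["cds_id"],
                             "evalue": 10.0 ** -rng.uniform(2, 8),
                             "bitscore": float(rng.uniform(*cfg.background_score_band))})
            hsd_scores[cls] = pd.DataFrame(
                rows, columns=["query_id", "target_id", "evalue", "bitscore"])

        strains_out[strain_id] = {
            "fasta": "".join(fasta_lines),
            "gff": "".join(gff_lines),
            "blast_hits": blast_hits,
            "hsd_scores": hsd_scores,
        }

    return {"strains": strains_out, "reference_scores": reference_scores}


# ---------------------------------------------------------------------------
# serialization

def save_ledger(ledger: dict, path) -> None:
    Path(path).write_text(json.dumps(ledger, ensure_ascii=False, indent=1,
                                     sort_keys=True))


def load_ledger(path) -> dict:
    return json.loads(Path(path).read_text())


def write_study(ledger: dict, out_dir) -> dict:
    """Write every synthetic artifact in the dialects the analysis stages read.

    Layout: ledger.json, peaks/<strain>.csv, standards/calibration.csv,
    proteomes/<strain>.faa + .gff, hits/<strain>.blast.tsv,
    scores/<strain>.<class>.tbl, refscores/<class>.tbl.  Returns the paths.
    """
    out = Path(out_dir)
    paths = {"ledger": out / "ledger.json"}
    out.mkdir(parents=True, exist_ok=True)
    save_ledger(ledger, paths["ledger"])

    peaks = emit_peak_tables(ledger)
    (out / "peaks").mkdir(exist_ok=True)
    paths["peaks"] = []
    for strain_id in ledger["strains"]:
        sub = peaks[peaks["sample_id"].str.startswith(strain_id + "|")]
        p = out / "peaks" / f"{strain_id}.csv"
        sub[PEAK_TABLE_COLUMNS].to_csv(p, index=False)
        paths["peaks"].append(p)

    (out / "standards").mkdir(exist_ok=True)
    paths["calibration"] = out / "standards" / "calibration.csv"
    emit_calibration(ledger).to_csv(paths["calibration"], index=False)

    prot = emit_proteomes(ledger)
    for sub in ("proteomes", "hits", "scores", "refscores"):
        (out / sub).mkdir(exist_ok=True)
    for strain_id, art in prot["strains"].items():
        (out / "proteomes" / f"{strain_id}.faa").write_text(art["fasta"])
        (out / "proteomes" / f"{strain_id}.gff").write_text(art["gff"])
        art["blast_hits"].to_csv(out / "hits" / f"{strain_id}.blast.tsv",
                                 sep="\t", header=False, index=False)
        for cls, df in art["hsd_scores"].items():
            rows = [(r["target_id"], r["evalue"], r["bitscore"])
                    for _, r in df.iterrows()]
            (out / "scores" / f"{strain_id}.{cls}.tbl").write_text(
                format_tblout(f"hsd_{cls}", rows))
    for cls, refs in prot["reference_scores"].items():
        rows = ([(f"ref_{cls}_pos{i}", 1e-60, s) for i, s in enumerate(refs["pos"])]
                + [(f"ref_{cls}_neg{i}", 1e-3, s) for i, s in enumerate(refs["neg"])])
        (out / "refscores" / f"{cls}.tbl").write_text(
            format_tblout(f"hsd_{cls}", rows))
    return paths
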