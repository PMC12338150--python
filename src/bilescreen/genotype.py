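"""Genotype prediction: bai-operon detection and HSD classification cutoffs.

Two homology-driven predictions are made per strain.  7α-dehydroxylation
capability is inferred from BLASTP hits of the eight bai-operon proteins
(BaiA2, BaiB, BaiCD, BaiE, BaiF, BaiG, BaiH, BaiI) against the strain's CDS:
hits passing E <= 1e-10 must co-localize within a <100,000 bp genome window;
the canonical operon needs all seven genes other than the optional BaiI.
Position-specific HSD capability (3α/7α/12α) is called from profile scores:
the classification cutoff per class is the minimal observed bit score that
maximizes the F measure, F = 2/(recall^-1 + precision^-1), over a labelled
reference score set (positives = the class's own reference sequences,
negatives = the other two classes pooled).

Scores may come from external hmmsearch --tblout files or from the built-in
position-specific scoring matrix (PSSM); cutoffs are only comparable within
one scoring backend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SearchIO

__all__ = [
    "BAI_GENES",
    "CANONICAL_BAI_GENES",
    "HSD_CLASSES",
    "ConfusionCounts",
    "CutoffResult",
    "OperonCall",
    "HsdPrediction",
    "read_blast_tab",
    "read_hmmer_tblout",
    "read_cds_gff",
    "filter_hits",
    "detect_bai_operon",
    "f_measure",
    "select_cutoff",
    "classify_hsd",
    "score_with_pssm",
]

BAI_GENES = ("BaiA2", "BaiB", "BaiCD", "BaiE", "BaiF", "BaiG", "BaiH", "BaiI")
#: BaiI is dispensable in the canonical operon.
CANONICAL_BAI_GENES = frozenset(g for g in BAI_GENES if g != "BaiI")

HSD_CLASSES = ("3α", "7α", "12α")

BLAST6_COLUMNS = ["query_id", "target_id", "pident", "length", "mismatch",
                  "gapopen", "qstart", "qend", "sstart", "send",
                  "evalue", "bitscore"]

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


# ---------------------------------------------------------------------------
# readers

def read_blast_tab(path) -> pd.DataFrame:
    """Read 12-column tabular BLAST output (outfmt 6)."""
    return pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, comment="#")


def read_hmmer_tblout(path) -> pd.DataFrame:
    """Read hmmsearch --tblout into (query_id, target_id, evalue, bitscore)."""
    rows = []
    for qresult in SearchIO.parse(str(path), "hmmer3-tab"):
        for hit in qresult:
            rows.append({"query_id": qresult.id, "target_id": hit.id,
                         "evalue": float(hit.evalue), "bitscore": float(hit.bitscore)})
    return pd.DataFrame(rows, columns=["query_id", "target_id", "evalue", "bitscore"])


def read_cds_gff(path) -> pd.DataFrame:
    """CDS coordinates from a GFF3 file (1-based inclusive, as in the file)."""
    import gffutils
    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    rows = []
    for feat in db.features_of_type("CDS"):
        cds_id = feat.attributes.get("ID", [feat.id])[0]
        rows.append({"cds_id": cds_id, "contig": feat.seqid,
                     "start": feat.start, "end": feat.end, "strand": feat.strand})
    return pd.DataFrame(rows, columns=["cds_id", "contig", "start", "end", "strand"])


# ---------------------------------------------------------------------------
# hit filtering and operon detection

def filter_hits(hits: pd.DataFrame, e_max: float = 1e-10) -> pd.DataFrame:
    """Apply the E-value gate (inclusive) and keep the best hit per (query, target).

    Best = lowest E-value, ties broken by higher bit score.
    """
    if e_max <= 0:
        raise ValueError("e_max must be positive")
    if hits.empty:
        return hits.copy()
    kept = hits[hits["evalue"] <= e_max]
    kept = kept.sort_values(["evalue", "bitscore"], ascending=[True, False], kind="stable")
    return kept.drop_duplicates(subset=["query_id", "target_id"], keep="first"
                                ).reset_index(drop=True)


@dataclass
class OperonCall:
    """Co-localized bai genes on one contig."""

    strain_id: str
    genes_present: frozenset
    span: int
    contig: str | None
    canonical: bool
    best_hit_cds: dict = field(default_factory=dict)   # gene -> cds_id
    excluded_hits: list = field(default_factory=list)  # hits lacking coordinates


def detect_bai_operon(hits: pd.DataFrame, cds: pd.DataFrame,
                      window_bp: int = 100_000, strain_id: str = "") -> OperonCall:
    """Find the densest co-localized set of distinct bai-gene hits.

    For every candidate anchor hit the set of hits on the same contig whose
    footprint fits in ``[anchor start, anchor start + window_bp)`` is
    considered; the call reports the gene set of the best such window
    (most distinct genes, ties broken by smaller span).  Coordinates are
    1-based inclusive, so a single gene spans ``end - start``.  Hits whose
    CDS is absent from the coordinate table are excluded and listed.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    empty = OperonCall(strain_id, frozenset(), 0, None, False)
    if hits.empty:
        return empty
    coords = cds.set_index("cds_id")
    merged = []
    excluded = []
    for _, h in hits.iterrows():
        if h["target_id"] not in coords.index:
            excluded.append(h["target_id"])
            continue
        c = coords.loc[h["target_id"]]
        merged.append({"gene": h["query_id"], "cds_id": h["target_id"],
                       "contig": c["contig"], "start": int(c["start"]),
                       "end": int(c["end"]), "bitscore": float(h["bitscore"])})
    empty.excluded_hits = excluded
    if not merged:
        return empty

    best: OperonCall | None = None
    mdf = pd.DataFrame(merged)
    for contig, grp in mdf.groupby("contig"):
        recs = grp.to_dict("records")
        for anchor in recs:
            a0 = anchor["start"]
            eligible = [r for r in recs
                        if r["start"] >= a0 and r["end"] - a0 < window_bp]
            if not eligible:
                continue
            chosen: dict[str, dict] = {}
            for r in eligible:
                cur = chosen.get(r["gene"])
                if cur is None or r["bitscore"] > cur["bitscore"]:
                    chosen[r["gene"]] = r
            span = (max(r["end"] for r in chosen.values())
                    - min(r["start"] for r in chosen.values()))
            cand = OperonCall(
                strain_id=strain_id,
                genes_present=frozenset(chosen),
                span=int(span),
                contig=str(contig),
                canonical=(CANONICAL_BAI_GENES <= set(chosen) and span < window_bp),
                best_hit_cds={g: r["cds_id"] for g, r in chosen.items()},
                excluded_hits=excluded,
            )
            if (best is None
                    or len(cand.genes_present) > len(best.genes_present)
                    or (len(cand.genes_present) == len(best.genes_present)
                        and cand.span < best.span)):
                best = cand
    return best if best is not None else empty


# ---------------------------------------------------------------------------
# F-measure cutoff selection and classification

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")


def f_measure(counts: ConfusionCounts) -> float:
    """Harmonic mean of recall and precision; zero when there are no TPs."""
    if counts.tp == 0:
        return 0.0
    return 2.0 / (1.0 / counts.recall + 1.0 / counts.precision)


@dataclass
class CutoffResult:
    hsd_class: str
    cutoff: float
    f_at_cutoff: float
    scan: list  # (threshold, F, tp, fp, fn) per candidate, ascending threshold


def select_cutoff(pos_scores, neg_scores, hsd_class: str = "") -> CutoffResult:
    """Minimal bit-score threshold maximizing the F measure.

    Candidate thresholds are the observed scores themselves (any value
    between two adjacent scores produces identical confusion counts).  At a
    threshold t: TP = #positives >= t, FP = #negatives >= t,
    FN = #positives < t.
    """
    pos = np.asarray(list(pos_scores), dtype=float)
    neg = np.asarray(list(neg_scores), dtype=float)
    if pos.size == 0:
        raise ValueError("positive score set must be non-empty")
    candidates = np.unique(np.concatenate([pos, neg]))
    scan = []
    best_t, best_f = None, -1.0
    for t in candidates:
        tp = int((pos >= t).sum())
        fp = int((neg >= t).sum())
        fn = int((pos < t).sum())
        f = f_measure(ConfusionCounts(tp, fp, fn))
        scan.append((float(t), f, tp, fp, fn))
        if f > best_f:           # first (minimal) threshold at the max F
            best_t, best_f = float(t), f
    return CutoffResult(hsd_class=hsd_class, cutoff=best_t, f_at_cutoff=best_f,
                        scan=scan)


@dataclass
class HsdPrediction:
    strain_id: str
    predicted: dict           # class -> bool
    support: dict             # class -> [(cds_id, score) descending]


def classify_hsd(scores_by_class: dict, cutoffs: dict, strain_id: str = "") -> HsdPrediction:
    """Call HSD classes for one strain from per-CDS profile scores.

    ``scores_by_class`` maps a class to ``[(cds_id, score), ...]``;
    ``cutoffs`` maps a class to its bit-score cutoff (or a CutoffResult).
    A class is predicted when any CDS scores at or above the cutoff — the
    boundary is inclusive because the cutoff is itself an observed positive
    score.
    """
    predicted = {}
    support = {}
    for cls, scores in scores_by_class.items():
        if cls not in cutoffs:
            raise ValueError(f"no cutoff available for class {cls!r}")
        cut = cutoffs[cls]
        cut = cut.cutoff if isinstance(cut, CutoffResult) else float(cut)
        hits = sorted([(c, float(s)) for c, s in scores if float(s) >= cut],
                      key=lambda x: -x[1])
        predicted[cls] = bool(hits)
        support[cls] = hits
    return HsdPrediction(strain_id=strain_id, predicted=predicted, support=support)


# ---------------------------------------------------------------------------
# native profile scoring (stand-in usable without external search tools)

def score_with_pssm(msa: list[str], sequence: str, pseudocount: float = 1.0,
                    max_gap_fraction: float = 0.5) -> float:
    """Score a sequence against a PSSM built from an aligned reference set.

    Match columns are alignment columns with a gap fraction at most
    ``max_gap_fraction``.  Column probabilities use Laplace-style
    pseudocounts over the 20-letter alphabet against a uniform background;
    the score is the best ungapped placement of the match-column profile
    along the sequence, in bits.  Deterministic, and invariant to the row
    order of the alignment.
    """
    if not msa:
        raise ValueError("alignment must contain at least one row")
    width = len(msa[0])
    if any(len(row) != width for row in msa):
        raise ValueError("alignment rows differ in length")
    for row in msa:
        bad = set(row) - AA_ALPHABET - {"-"}
        if bad:
            raise ValueError(f"alignment contains invalid symbol(s): {sorted(bad)}")
    bad = set(sequence) - AA_ALPHABET
    if bad:
        raise ValueError(f"sequence contains invalid symbol(s): {sorted(bad)}")

    n_rows = len(msa)
    alphabet = sorted(AA_ALPHABET)
    index = {a: i for i, a in enumerate(alphabet)}
    match_cols = [j for j in range(width)
                  if sum(row[j] == "-" for row in msa) / n_rows <= max_gap_fraction]
    if not match_cols:
        raise ValueError("alignment has no match columns")

    log_odds = np.empty((len(match_cols), 20))
    background = 1.0 / 20.0
    for k, j in enumerate(match_cols):
        counts = np.full(20, pseudocount)
        total = 20 * pseudocount
        for row in msa:
            if row[j] != "-":
                counts[index[row[j]]] += 1.0
                total += 1.0
        log_odds[k] = np.log2(counts / total / background)

    m = len(match_cols)
    if len(sequence) < m:
        # pad conceptually by scoring the only partial placement available
        seq_idx = np.array([index[a] for a in sequence])
        return float(log_odds[np.arange(len(sequence)), seq_idx].sum())
    seq_idx = np.array([index[a] for a in sequence])
    best = -math.inf
    for offset in range(len(sequence) - m + 1):
        s = float(log_odds[np.arange(m), seq_idx[offset:offset + m]].sum())
        if s > best:
            best = s
    return best
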