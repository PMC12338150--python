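"""Operon detection, F-measure cutoffs, HSD classification, PSSM scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from bilescreen import genotype
from bilescreen.genotype import (ConfusionCounts, classify_hsd,
                                 detect_bai_operon, f_measure, filter_hits,
                                 read_blast_tab, read_cds_gff,
                                 read_hmmer_tblout, score_with_pssm,
                                 select_cutoff)
from bilescreen.synthetic_data import format_tblout, make_protein_family

from oracles import brute_force_operon, exhaustive_cutoff


def hits_frame(rows):
    return pd.DataFrame(rows, columns=["query_id", "target_id", "evalue",
                                       "bitscore"])


def cds_frame(rows):
    return pd.DataFrame(rows, columns=["cds_id", "contig", "start", "end",
                                       "strand"])


class TestFilterHits:
    def test_evalue_gate_is_inclusive(self):
        hits = hits_frame([("BaiB", "c1", 1e-12, 100.0),
                           ("BaiB", "c2", 1e-10, 90.0),
                           ("BaiB", "c3", 1e-9, 80.0)])
        kept = filter_hits(hits)
        assert set(kept["target_id"]) == {"c1", "c2"}

    def test_best_hit_per_query_target(self):
        hits = hits_frame([("BaiB", "c1", 1e-15, 100.0),
                           ("BaiB", "c1", 1e-20, 120.0)])
        kept = filter_hits(hits)
        assert len(kept) == 1
        assert kept.iloc[0]["evalue"] == 1e-20

    def test_tie_broken_by_bitscore(self):
        hits = hits_frame([("BaiB", "c1", 1e-20, 100.0),
                           ("BaiB", "c1", 1e-20, 150.0)])
        assert filter_hits(hits).iloc[0]["bitscore"] == 150.0


class TestFMeasure:
    def test_perfect_separation(self):
        assert f_measure(ConfusionCounts(6, 0, 0)) == 1.0

    def test_half_recall_full_precision(self):
        assert f_measure(ConfusionCounts(1, 0, 1)) == pytest.approx(2 / 3)

    def test_zero_tp_is_zero_regardless(self):
        assert f_measure(ConfusionCounts(0, 5, 3)) == 0.0
        assert f_measure(ConfusionCounts(0, 0, 0)) == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0)


class TestSelectCutoff:
    def test_clean_separation(self):
        res = select_cutoff([150, 160], [100])
        assert res.cutoff == 150 and res.f_at_cutoff == 1.0

    def test_inverted_scores(self):
        res = select_cutoff([100], [200])
        assert res.cutoff == 100
        assert res.f_at_cutoff == pytest.approx(2 / 3)

    def test_no_negatives(self):
        res = select_cutoff([50], [])
        assert res.cutoff == 50 and res.f_at_cutoff == 1.0

    def test_empty_positives_rejected(self):
        with pytest.raises(ValueError):
            select_cutoff([], [1.0])

    def test_scan_is_complete_and_ascending(self):
        res = select_cutoff([150, 160], [100, 160])
        thresholds = [t for t, *_ in res.scan]
        assert thresholds == sorted(set([150.0, 160.0, 100.0]))

    @given(st.lists(st.integers(0, 40), min_size=1, max_size=20),
           st.lists(st.integers(0, 40), max_size=20))
    def test_agrees_with_exhaustive_scan(self, pos, neg):
        res = select_cutoff(pos, neg)
        t, f = exhaustive_cutoff([float(p) for p in pos],
                                 [float(n) for n in neg])
        assert res.cutoff == t
        assert res.f_at_cutoff == pytest.approx(f, abs=1e-12)


class TestClassifyHsd:
    CUTOFFS = {"3α": 146.1, "7α": 220.6, "12α": 120.2}

    def test_above_cutoff_predicts(self):
        pred = classify_hsd({"3α": [("c1", 200.0)]}, self.CUTOFFS)
        assert pred.predicted["3α"]

    def test_all_below_predicts_nothing(self):
        pred = classify_hsd({c: [("c1", 50.0)] for c in self.CUTOFFS},
                            self.CUTOFFS)
        assert not any(pred.predicted.values())

    def test_boundary_is_inclusive(self):
        pred = classify_hsd({"3α": [("c1", 146.1)]}, self.CUTOFFS)
        assert pred.predicted["3α"]

    def test_support_sorted_descending(self):
        pred = classify_hsd({"3α": [("lo", 150.0), ("hi", 300.0)]}, self.CUTOFFS)
        assert [c for c, _ in pred.support["3α"]] == ["hi", "lo"]

    def test_missing_cutoff_rejected(self):
        with pytest.raises(ValueError, match="7α"):
            classify_hsd({"7α": [("c1", 10.0)]}, {"3α": 146.1})

    def test_raising_cutoff_never_adds_predictions(self):
        rng = np.random.default_rng(2)
        scores = {"3α": [(f"c{i}", float(s))
                         for i, s in enumerate(rng.uniform(0, 300, 30))]}
        predicted_at = []
        for cut in [50.0, 150.0, 250.0, 350.0]:
            pred = classify_hsd(scores, {"3α": cut})
            predicted_at.append({c for c, _ in pred.support["3α"]})
        for smaller, larger in zip(predicted_at[1:], predicted_at[:-1]):
            assert smaller <= larger


class TestOperonDetection:
    def linear_layout(self, genes, start=1000, gene_len=1500, gap=500,
                      contig="ctg1"):
        hits, cds = [], []
        pos = start
        for i, g in enumerate(genes):
            cid = f"cds{i}"
            hits.append((g, cid, 1e-50, 400.0))
            cds.append((cid, contig, pos, pos + gene_len - 1, "+"))
            pos += gene_len + gap
        return hits_frame(hits), cds_frame(cds)

    def test_eight_gene_cluster_is_canonical(self):
        hits, cds = self.linear_layout(genotype.BAI_GENES)
        op = detect_bai_operon(hits, cds)
        assert len(op.genes_present) == 8 and op.canonical
        assert op.span < 20_000

    def test_seven_genes_without_bai_i_still_canonical(self):
        hits, cds = self.linear_layout(sorted(genotype.CANONICAL_BAI_GENES))
        op = detect_bai_operon(hits, cds)
        assert op.canonical and "BaiI" not in op.genes_present

    def test_scattered_cluster_not_canonical(self):
        hits, cds = self.linear_layout(genotype.BAI_GENES, gene_len=1500,
                                       gap=20_000)
        op = detect_bai_operon(hits, cds)   # span ~150 kb
        assert not op.canonical
        assert len(op.genes_present) < 8

    def test_split_contigs_cannot_form_operon(self):
        h1, c1 = self.linear_layout(["BaiA2", "BaiB", "BaiCD", "BaiE"],
                                    contig="ctg1")
        h2, c2 = self.linear_layout(["BaiF", "BaiG", "BaiH"], contig="ctg2")
        h2["target_id"] = h2["target_id"] + "_b"
        c2["cds_id"] = c2["cds_id"] + "_b"
        op = detect_bai_operon(pd.concat([h1, h2]), pd.concat([c1, c2]))
        assert not op.canonical
        assert len(op.genes_present) == 4

    def test_hits_without_coordinates_excluded_and_flagged(self):
        hits, cds = self.linear_layout(["BaiA2", "BaiB"])
        hits.loc[len(hits)] = ("BaiCD", "ghost", 1e-40, 300.0)
        op = detect_bai_operon(hits, cds)
        assert op.excluded_hits == ["ghost"]
        assert op.genes_present == {"BaiA2", "BaiB"}

    def test_single_gene_span_is_end_minus_start(self):
        hits, cds = self.linear_layout(["BaiB"], gene_len=1200)
        op = detect_bai_operon(hits, cds)
        assert op.span == 1199

    def test_agrees_with_brute_force_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(1, 11))
            rows, coords = [], {}
            for i in range(n):
                g = str(rng.choice(genotype.BAI_GENES))
                contig = f"ctg{int(rng.integers(1, 3))}"
                start = int(rng.integers(1, 150_000))
                end = start + int(rng.integers(600, 2400))
                cid = f"c{i}"
                rows.append((g, cid, 1e-30, float(rng.uniform(100, 500))))
                coords[cid] = (contig, start, end)
            hits = hits_frame(rows)
            cds = cds_frame([(cid, *coords[cid], "+") for cid in coords])
            op = detect_bai_operon(hits, cds, window_bp=100_000)
            n_best, _ = brute_force_operon(
                [(r[0], r[1]) for r in rows], coords, 100_000)
            assert len(op.genes_present) == n_best


class TestReaders:
    def test_blast_tab_roundtrip(self, tmp_path):
        df = pd.DataFrame([["BaiB", "c1", 98.2, 300, 5, 0, 1, 300, 1, 300,
                            1e-50, 550.0]])
        p = tmp_path / "hits.tsv"
        df.to_csv(p, sep="\t", header=False, index=False)
        out = read_blast_tab(p)
        assert out.iloc[0]["query_id"] == "BaiB"
        assert out.iloc[0]["evalue"] == pytest.approx(1e-50, rel=1e-9)
        assert out.iloc[0]["bitscore"] == 550.0

    def test_tblout_roundtrip(self, tmp_path):
        text = format_tblout("hsd_3α", [("cds_0001", 1.2e-50, 210.5),
                                        ("cds_0002", 3.1e-08, 22.1)])
        p = tmp_path / "scores.tbl"
        p.write_text(text)
        df = read_hmmer_tblout(p)
        assert list(df["target_id"]) == ["cds_0001", "cds_0002"]
        assert df.iloc[0]["bitscore"] == pytest.approx(210.5)
        assert df.iloc[1]["evalue"] == pytest.approx(3.1e-8)
        assert (df["query_id"] == "hsd_3α").all()

    def test_gff_cds_coordinates(self, tmp_path):
        p = tmp_path / "genes.gff"
        p.write_text("##gff-version 3\n"
                     "ctg1\tsynth\tCDS\t100\t1299\t.\t+\t0\tID=cdsA\n"
                     "ctg1\tsynth\tgene\t100\t1299\t.\t+\t.\tID=geneA\n"
                     "ctg2\tsynth\tCDS\t500\t800\t.\t-\t0\tID=cdsB\n")
        df = read_cds_gff(p)
        assert len(df) == 2
        a = df[df["cds_id"] == "cdsA"].iloc[0]
        assert (a["contig"], a["start"], a["end"], a["strand"]) == \
            ("ctg1", 100, 1299, "+")


class TestPssm:
    def test_family_member_outscores_its_shuffle(self):
        rng = np.random.default_rng(4)
        family = make_protein_family(rng, length=80, n_members=6)
        member = family[0]
        shuffled = "".join(rng.permutation(list(member)))
        msa = family[1:]
        assert score_with_pssm(msa, member) > score_with_pssm(msa, shuffled)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(5)
        family = make_protein_family(rng, length=60, n_members=5)
        seq = family[0]
        assert score_with_pssm(family, seq) == score_with_pssm(family[::-1], seq)

    def test_alphabet_violations_rejected(self):
        with pytest.raises(ValueError):
            score_with_pssm(["ACDX"], "ACDE")
        with pytest.raises(ValueError):
            score_with_pssm(["ACDE"], "AC1E")

    def test_planted_families_separable_with_f_one(self):
        rng = np.random.default_rng(6)
        fam_a = make_protein_family(rng, length=100, n_members=8)
        fam_b = make_protein_family(rng, length=100, n_members=8)
        msa = fam_a[:4]
        pos = [score_with_pssm(msa, s) for s in fam_a[4:]]
        neg = [score_with_pssm(msa, s) for s in fam_b]
        res = select_cutoff(pos, neg)
        assert res.f_at_cutoff == 1.0
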