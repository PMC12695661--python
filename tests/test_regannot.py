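import numpy as np
import pandas as pd
import pytest

from euseqtools import io, regannot, simulate


def gene(gene_id, tss, strand, chrom="chr1", tes=None):
    if tes is None:
        tes = tss + 20_000 if strand == "+" else tss - 20_000
    return {"gene_id": gene_id, "chrom": chrom, "strand": strand, "tss": tss, "tes": tes}


def peak(chrom, summit, signal=10.0, name="p"):
    return {
        "chrom": chrom, "start": summit - 250, "end": summit + 250, "name": name,
        "score": 0, "strand": ".", "signal_value": signal, "p_value": -1,
        "q_value": -1, "summit_offset": 250, "summit": summit,
    }


class TestAnnotatePromoterPeaks:
    def test_upstream_summit_plus_strand(self):
        genes = pd.DataFrame([gene("g1", 100_000, "+")])
        peaks = pd.DataFrame([peak("chr1", 100_000 - 1 - 150)])
        ann = regannot.annotate_promoter_peaks(peaks, genes)
        assert ann.loc[0, "nearest_summit_distance"] == -150
        assert ann.loc[0, "in_200bp"] and ann.loc[0, "in_400bp"] and ann.loc[0, "in_2kb"]

    def test_minus_strand_flips_sign(self):
        # summit left of a minus-strand TSS in genomic coordinates is downstream
        genes = pd.DataFrame([gene("g1", 100_000, "-")])
        peaks = pd.DataFrame([peak("chr1", 100_000 - 1 - 150)])
        ann = regannot.annotate_promoter_peaks(peaks, genes)
        assert ann.loc[0, "nearest_summit_distance"] == 150

    def test_nearest_rule_and_window_membership(self):
        genes = pd.DataFrame([gene("g1", 100_000, "+")])
        tss0 = 100_000 - 1
        peaks = pd.DataFrame([peak("chr1", tss0 - 300, 5.0), peak("chr1", tss0 - 1_500, 50.0)])
        ann = regannot.annotate_promoter_peaks(peaks, genes)
        assert ann.loc[0, "nearest_summit_distance"] == -300
        assert ann.loc[0, "peak_height"] == 5.0  # height of the nearest peak
        assert ann.loc[0, "in_2kb"] and ann.loc[0, "in_400bp"]
        assert not ann.loc[0, "in_200bp"]

    def test_window_nesting_invariant(self, small_dataset):
        genes = small_dataset["genes"]
        ctcf, _ = simulate.build_peak_tables(genes)
        ann = regannot.annotate_promoter_peaks(ctcf, genes)
        assert ((~ann["in_200bp"]) | ann["in_400bp"]).all()
        assert ((~ann["in_400bp"]) | ann["in_2kb"]).all()

    def test_rad21_ctcf_ratio_from_paired_summits(self):
        genes = pd.DataFrame([gene("g1", 100_000, "+")])
        tss0 = 100_000 - 1
        ctcf = pd.DataFrame([peak("chr1", tss0 - 100, signal=10.0)])
        rad21 = pd.DataFrame([peak("chr1", tss0 - 100 + 40, signal=25.0)])
        ann = regannot.annotate_promoter_peaks(ctcf, genes, rad21)
        assert ann.loc[0, "rad21_ctcf_ratio"] == pytest.approx(2.5)
        far = pd.DataFrame([peak("chr1", tss0 - 100 + 500, signal=25.0)])
        ann2 = regannot.annotate_promoter_peaks(ctcf, genes, far)
        assert np.isnan(ann2.loc[0, "rad21_ctcf_ratio"])

    def test_peak_without_summit_errors(self, tmp_path):
        path = tmp_path / "bad.narrowPeak"
        path.write_text("chr1\t10\t30\tp1\t0\t.\t5.0\t-1\t-1\t-1\n")
        with pytest.raises(ValueError, match="summit"):
            io.read_narrowpeak(path)


@pytest.fixture(scope="module")
def pwm():
    return io.read_jaspar_motif()


@pytest.fixture(scope="module")
def consensus(pwm):
    return io.motif_consensus(pwm)


class TestMotifOrientation:

    @staticmethod
    def revcomp(seq):
        return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]

    @staticmethod
    def background(n, seed=0):
        rng = np.random.default_rng(seed)
        return "".join(rng.choice(list("ACGT"), size=n))

    def embed(self, insert, seed=1):
        bg = self.background(400, seed=seed)
        return bg[:200] + insert + bg[200 + len(insert):]

    def test_consensus_on_plus_gene_is_forward(self, pwm, consensus):
        seq = self.embed(consensus)
        scan = regannot.classify_motif_orientation(200 + len(consensus) // 2, seq, pwm, "+")
        assert scan.orientation == "forward"

    def test_same_sequence_minus_gene_is_reverse(self, pwm, consensus):
        seq = self.embed(consensus)
        scan = regannot.classify_motif_orientation(200 + len(consensus) // 2, seq, pwm, "-")
        assert scan.orientation == "reverse"

    def test_both_strands(self, pwm, consensus):
        insert = consensus + "TTTT" + self.revcomp(consensus)
        seq = self.embed(insert)
        scan = regannot.classify_motif_orientation(200 + len(insert) // 2, seq, pwm, "+")
        assert scan.orientation == "both"

    def test_no_hit_is_none(self, pwm):
        seq = self.background(400, seed=3)
        scan = regannot.classify_motif_orientation(200, seq, pwm, "+")
        assert scan.orientation == "none"

    def test_strand_flip_invariance(self, pwm, consensus):
        """Flipping both gene strand and motif strand preserves orientation;
        flipping only one toggles forward <-> reverse."""
        fwd_seq = self.embed(consensus)
        rev_seq = self.embed(self.revcomp(consensus))
        summit = 200 + len(consensus) // 2
        o_pp = regannot.classify_motif_orientation(summit, fwd_seq, pwm, "+").orientation
        o_mm = regannot.classify_motif_orientation(summit, rev_seq, pwm, "-").orientation
        o_pm = regannot.classify_motif_orientation(summit, rev_seq, pwm, "+").orientation
        o_mp = regannot.classify_motif_orientation(summit, fwd_seq, pwm, "-").orientation
        assert o_pp == o_mm == "forward"
        assert o_pm == o_mp == "reverse"

    def test_window_truncation_warns(self, pwm, consensus):
        seq = consensus + self.background(120, seed=4)
        with pytest.warns(UserWarning, match="truncated"):
            scan = regannot.classify_motif_orientation(10, seq, pwm, "+")
        assert scan.orientation == "forward"

    def test_planted_orientations_recovered(self, small_dataset):
        genes = small_dataset["genes"]
        genome = small_dataset["genome"]
        ctcf, _ = simulate.build_peak_tables(genes)
        ann = regannot.annotate_promoter_peaks(ctcf, genes)
        pwm = io.read_jaspar_motif()
        ann = regannot.annotate_motif_orientations(ann, genes, genome, pwm)
        truth = genes.set_index("gene_id")["motif_orientation"]
        merged = ann.dropna(subset=["motif_orientation"]).set_index("gene_id")
        assert len(merged) > 5
        assert (merged["motif_orientation"] == truth.loc[merged.index]).all()


class TestSummarizeBindingPositions:
    def test_planted_constant_offset_median(self):
        ann = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(6)],
            "nearest_summit_distance": [-79.0] * 6,
        })
        labels = pd.Series(["X"] * 6, index=ann["gene_id"])
        dists, summary, notes = regannot.summarize_binding_positions(ann, labels)
        assert summary.set_index("class").loc["X", "median_distance"] == -79.0

    def test_symmetric_offsets_median_zero(self):
        ann = pd.DataFrame({
            "gene_id": ["g1", "g2"],
            "nearest_summit_distance": [-100.0, 100.0],
        })
        labels = pd.Series(["X", "X"], index=ann["gene_id"])
        _, summary, _ = regannot.summarize_binding_positions(ann, labels)
        assert summary.loc[0, "median_distance"] == 0.0

    def test_unbound_class_omitted_with_note(self):
        ann = pd.DataFrame({
            "gene_id": ["g1", "g2"],
            "nearest_summit_distance": [-50.0, np.nan],
        })
        labels = pd.Series(["X", "Y"], index=ann["gene_id"])
        dists, summary, notes = regannot.summarize_binding_positions(ann, labels)
        assert "X" in dists and "Y" not in dists
        assert any("Y" in note for note in notes)

    def test_distance_window_restriction(self):
        ann = pd.DataFrame({
            "gene_id": ["g1", "g2"],
            "nearest_summit_distance": [-50.0, 900.0],
        })
        labels = pd.Series(["X", "X"], index=ann["gene_id"])
        dists, _, _ = regannot.summarize_binding_positions(ann, labels)
        assert dists["X"].tolist() == [-50.0]


class TestPolIINormalization:
    def test_anchoring_identity_with_pure_confounder(self):
        idx = [f"g{i}" for i in range(9)]
        body = pd.DataFrame({"control": [100.0] * 9, "treatment": [200.0] * 9}, index=idx)
        prom = pd.DataFrame({"control": [50.0] * 9, "treatment": [100.0] * 9}, index=idx)
        quant, factor = regannot.polii_normalize_quantify(prom, body, idx)
        assert factor == pytest.approx(2.0)
        assert np.allclose(quant["body_log2fc"], 0.0)
        assert np.allclose(quant["promoter_log2fc"], 0.0)

    def test_nc_median_exactly_zero_even_n(self):
        idx = [f"g{i}" for i in range(10)]
        rng = np.random.default_rng(8)
        body = pd.DataFrame({
            "control": rng.integers(100, 1_000, size=10).astype(float),
            "treatment": rng.integers(100, 1_000, size=10).astype(float),
        }, index=idx)
        prom = body * 0.5
        quant, _ = regannot.polii_normalize_quantify(prom, body, idx)
        assert np.median(quant["body_log2fc"]) == pytest.approx(0.0, abs=1e-12)

    def test_promoter_only_gain_recovered(self, small_dataset):
        cfg = small_dataset["config"]
        genes, truth = small_dataset["genes"], small_dataset["truth"]
        tracks = simulate.generate_signal_tracks(cfg, genes, truth)
        nc = truth.index[(truth["true_fc"] == 1.0) & ~truth["uastrx_up"]]
        quant, factor = regannot.polii_normalize_quantify(
            tracks["polii_promoter"], tracks["polii_body"], nc
        )
        assert factor == pytest.approx(cfg.polii_confounder, rel=0.05)
        gained = truth.index[truth["uastrx_up"]]
        if len(gained):
            assert quant.loc[gained, "promoter_log2fc"].mean() > 0.5
            assert abs(quant.loc[gained, "body_log2fc"].mean()) < 0.3

    def test_empty_anchor_set_errors(self):
        body = pd.DataFrame({"control": [1.0], "treatment": [1.0]}, index=["g"])
        with pytest.raises(ValueError, match="anchor"):
            regannot.polii_normalize_quantify(body, body, [])


class TestQuartiles:
    def test_eight_heights_partition_into_pairs(self):
        h = pd.Series([1, 2, 3, 4, 5, 6, 7, 8], index=[f"p{i}" for i in range(8)])
        q = regannot.quartile_stratify(h)
        groups = {lab: sorted(h[q == lab]) for lab in q.unique()}
        assert groups == {"Q1": [7, 8], "Q2": [5, 6], "Q3": [3, 4], "Q4": [1, 2]}

    def test_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(1)
        h = pd.Series(rng.uniform(size=37), index=[f"p{i}" for i in range(37)])
        sizes = regannot.quartile_stratify(h).value_counts()
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == 37

    def test_deterministic_under_ties(self):
        h = pd.Series([5.0] * 8, index=[f"p{i}" for i in range(8)])
        q1 = regannot.quartile_stratify(h)
        q2 = regannot.quartile_stratify(h.sample(frac=1.0, random_state=3))
        assert q1.sort_index().equals(q2.sort_index())


class TestAtacDifferential:
    def test_all_unchanged_gives_zero_fractions(self):
        idx = [f"p{i}" for i in range(20)]
        counts = pd.DataFrame({"control": [500] * 20, "treatment": [500] * 20}, index=idx)
        counts.index.name = "peak_id"
        positions = pd.DataFrame({
            "peak_id": idx, "chrom": "chr1",
            "start": np.arange(20) * 10_000, "end": np.arange(20) * 10_000 + 500,
            "summit": np.arange(20) * 10_000 + 250,
        })
        genes = pd.DataFrame([gene("g1", 5_000, "+")])
        sheet = pd.DataFrame({"sample": ["control", "treatment"],
                              "condition": ["control", "treatment"]})
        result, summary = regannot.atac_differential(counts, sheet, positions, genes)
        assert summary["fraction_lost"] == 0.0 and summary["fraction_gained"] == 0.0

    def test_zero_both_excluded_with_tally(self):
        idx = ["p0", "p1"]
        counts = pd.DataFrame({"control": [0, 100], "treatment": [0, 100]}, index=idx)
        counts.index.name = "peak_id"
        positions = pd.DataFrame({
            "peak_id": idx, "chrom": "chr1", "start": [0, 10_000],
            "end": [500, 10_500], "summit": [250, 10_250],
        })
        genes = pd.DataFrame([gene("g1", 500_000, "+")])
        sheet = pd.DataFrame({"sample": ["control", "treatment"],
                              "condition": ["control", "treatment"]})
        result, summary = regannot.atac_differential(counts, sheet, positions, genes)
        assert summary["excluded_zero_both"] == 1
        assert len(result) == 1

    def test_planted_losses_and_strata(self, small_dataset):
        cfg = small_dataset["config"]
        genes, truth = small_dataset["genes"], small_dataset["truth"]
        tracks = simulate.generate_signal_tracks(cfg, genes, truth)
        result, summary = regannot.atac_differential(
            tracks["atac_counts"], tracks["atac_sample_sheet"],
            tracks["atac_positions"], genes, tracks["ctcf_peaks"],
        )
        atac_truth = tracks["atac_truth"]
        lost_truth = atac_truth.index[atac_truth["true_change"] < 0.5]
        called_lost = set(result.index[result["log2fc"] <= -1])
        assert set(lost_truth) <= called_lost | set(atac_truth.index[atac_truth["true_change"] >= 0.5])
        # every co-placed CTCF/ATAC peak is stratified
        bound = atac_truth["ctcf_bound"].reindex(result.index)
        assert (result.loc[bound, "ctcf_quartile"] != "no_CTCF").all()
        # no_CTCF peaks genuinely overlap no CTCF interval (background
        # peaks may land on CTCF peaks by chance, so check by brute force)
        positions = tracks["atac_positions"].set_index("peak_id")
        ctcf = tracks["ctcf_peaks"]
        for peak_id in result.index[result["ctcf_quartile"] == "no_CTCF"]:
            p = positions.loc[peak_id]
            hits = ctcf[
                (ctcf["chrom"] == p["chrom"])
                & (ctcf["start"] < p["end"])
                & (ctcf["end"] > p["start"])
            ]
            assert hits.empty
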