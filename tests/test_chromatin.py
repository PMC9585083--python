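"""Interval engine, variance stabilization, PCA and signature-cascade contracts."""

import numpy as np
import pandas as pd
import pytest

from isopair import chromatin
from isopair.errors import ComputationError, InputFormatError


def iv(*rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# dense per-bp oracles
# ---------------------------------------------------------------------------

def dense_union(per_sample, genome_len):
    cov = np.zeros(genome_len, dtype=bool)
    for df in per_sample.values():
        for _, r in df.iterrows():
            cov[r["start"]:r["end"]] = True
    return cov


def dense_support(per_sample, genome_len):
    support = np.zeros(genome_len, dtype=int)
    for df in per_sample.values():
        cov = np.zeros(genome_len, dtype=bool)
        for _, r in df.iterrows():
            cov[r["start"]:r["end"]] = True
        support += cov
    return support


def runs_from_bool(cov):
    """(start, end) runs of True in a boolean array."""
    padded = np.concatenate([[False], cov, [False]]).astype(int)
    diff = np.diff(padded)
    return list(zip(np.where(diff == 1)[0], np.where(diff == -1)[0]))


def random_intervals(rng, genome_len, n):
    starts = rng.integers(0, genome_len - 100, n)
    lengths = rng.integers(1, 120, n)
    return iv(*[("chr1", int(s), int(min(s + l, genome_len))) for s, l in zip(starts, lengths)])


# ---------------------------------------------------------------------------
# consensus and support
# ---------------------------------------------------------------------------

class TestConsensus:
    def test_single_sample_is_merged_self(self):
        peaks = iv(("chr1", 100, 200), ("chr1", 150, 250), ("chr2", 0, 10))
        out = chromatin.build_consensus({"s1": peaks})
        assert [tuple(r) for r in out[["chrom", "start", "end", "support"]].to_numpy()] == [
            ("chr1", 100, 250, 1), ("chr2", 0, 10, 1)
        ]

    def test_two_sample_overlap_merges_with_support_two(self):
        out = chromatin.build_consensus(
            {"s1": iv(("chr1", 100, 200)), "s2": iv(("chr1", 150, 250))}
        )
        assert out.iloc[0][["start", "end", "support"]].tolist() == [100, 250, 2]

    def test_book_ended_intervals_merge(self):
        out = chromatin.build_consensus(
            {"s1": iv(("chr1", 100, 200)), "s2": iv(("chr1", 200, 300))}
        )
        assert out.iloc[0][["start", "end", "support"]].tolist() == [100, 300, 2]

    def test_malformed_interval_reports_context(self):
        with pytest.raises(InputFormatError, match="sample s1"):
            chromatin.build_consensus({"s1": iv(("chr1", 50, 50))})

    def test_matches_dense_oracle(self, rng):
        genome_len = 5000
        for _ in range(10):
            per_sample = {
                f"s{k}": random_intervals(rng, genome_len, 15) for k in range(4)
            }
            out = chromatin.build_consensus(per_sample)
            cov = dense_union(per_sample, genome_len)
            expected_runs = runs_from_bool(cov)
            got_runs = [(s, e) for s, e in out[["start", "end"]].to_numpy()]
            assert got_runs == expected_runs
            # support = number of samples contributing >= 1 bp to the run
            sample_cov = {
                name: dense_union({name: df}, genome_len)
                for name, df in per_sample.items()
            }
            for (s, e), sup in zip(got_runs, out["support"]):
                expected = sum(int(c[s:e].any()) for c in sample_cov.values())
                assert sup == expected

    def test_support_filter_counts(self):
        cons = iv(("chr1", 0, 10), ("chr1", 20, 30), ("chr1", 40, 50))
        cons["support"] = [1, 2, 3]
        assert len(chromatin.filter_by_support(cons, 1)) == 3
        assert len(chromatin.filter_by_support(cons, 2)) == 2
        assert len(chromatin.filter_by_support(cons, 4)) == 0


# ---------------------------------------------------------------------------
# VST
# ---------------------------------------------------------------------------

class TestVST:
    def test_identical_columns_identical_output(self, rng):
        x = rng.poisson(100, 50)
        m = pd.DataFrame({"a": x, "b": x})
        out = chromatin.vst_transform(m)
        np.testing.assert_allclose(out["a"], out["b"])

    def test_depth_scaled_replicate_maps_onto_itself(self, rng):
        x = rng.poisson(500, 200) + 1
        m = pd.DataFrame({"a": x, "b": 2 * x, "c": x})
        out = chromatin.vst_transform(m)
        np.testing.assert_allclose(out["a"], out["b"], atol=1e-9)

    def test_zero_count_peak_maps_to_zero(self):
        m = pd.DataFrame({"a": [0, 10], "b": [0, 12], "c": [0, 9]})
        out = chromatin.vst_transform(m)
        np.testing.assert_allclose(out.iloc[0].to_numpy(), 0.0)

    def test_fallback_without_all_positive_peaks(self, caplog):
        m = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with caplog.at_level("WARNING", logger="isopair.chromatin"):
            out = chromatin.vst_transform(m)
        assert "library-size" in caplog.text
        assert np.isfinite(out.to_numpy()).all()


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class TestPCA:
    def test_rank_one_data(self, rng):
        direction = rng.normal(size=20)
        weights = np.array([1.0, 2.0, 3.0, 4.0])
        m = pd.DataFrame(np.outer(direction, weights),
                         columns=["s1", "s2", "s3", "s4"])
        pca = chromatin.pca_over_samples(m)
        assert pca.explained_fraction.iloc[0] == pytest.approx(1.0)
        assert pca.explained_fraction.iloc[1:].max() < 1e-12

    def test_explained_fractions_sum_to_one_and_scores_orthogonal(self, rng):
        m = pd.DataFrame(rng.normal(size=(50, 6)))
        pca = chromatin.pca_over_samples(m)
        assert pca.explained_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        S = pca.sample_scores.to_numpy()
        gram = S.T @ S
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_matches_covariance_eigen_oracle(self, rng):
        m = pd.DataFrame(rng.normal(size=(30, 5)))
        pca = chromatin.pca_over_samples(m)
        X = m.to_numpy().T
        Xc = X - X.mean(axis=0)
        cov = Xc @ Xc.T  # sample Gram; eigenvalues proportional to variances
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(
            pca.explained_fraction.to_numpy()[: len(evals)],
            (evals / evals.sum())[: pca.n_components],
            atol=1e-9,
        )

    def test_constant_matrix_rejected(self):
        m = pd.DataFrame(np.ones((10, 4)))
        with pytest.raises(ComputationError):
            chromatin.pca_over_samples(m)


# ---------------------------------------------------------------------------
# component-correlated peak selection
# ---------------------------------------------------------------------------

class TestSelectPCPeaks:
    @staticmethod
    def _matrix(rng, n_samples=10):
        scores = rng.normal(size=n_samples)
        rows = {
            "chr1:100-200": scores.copy(),  # identical to scores -> r = 1
            "chr1:300-400": rng.normal(size=n_samples),
            "chr1:500-600": np.zeros(n_samples),  # zero variance
        }
        m = pd.DataFrame(rows).T
        m.columns = [f"s{i}" for i in range(n_samples)]
        return m, scores

    def test_peak_equal_to_scores_retained(self, rng):
        m, scores = self._matrix(rng)
        out = chromatin.select_pc_correlated_peaks(m, scores=scores, alpha=0.05)
        assert "chr1:100-200" in out.index
        assert out.loc["chr1:100-200", "pearson_r"] == pytest.approx(1.0)

    def test_orthogonal_peak_excluded(self):
        scores = np.array([1.0, -1.0] * 5)
        orth = np.array([1.0, 1.0, -1.0, -1.0] * 2 + [1.0, -1.0])
        orth -= orth.mean()
        orth -= scores * (orth @ scores) / (scores @ scores)  # exactly orthogonal
        m = pd.DataFrame([orth], index=["chr1:0-10"],
                         columns=[f"s{i}" for i in range(10)])
        out = chromatin.select_pc_correlated_peaks(m, scores=scores, alpha=0.9999)
        assert "chr1:0-10" not in out.index  # r = 0 -> p = 1

    def test_zero_variance_peak_excluded(self, rng):
        m, scores = self._matrix(rng)
        out = chromatin.select_pc_correlated_peaks(m, scores=scores, alpha=1.0 - 1e-12)
        assert "chr1:500-600" not in out.index

    def test_needs_four_samples(self, rng):
        m = pd.DataFrame(rng.normal(size=(5, 3)),
                         index=[f"chr1:{i}0-{i}5" for i in range(5)])
        with pytest.raises(ComputationError):
            chromatin.select_pc_correlated_peaks(m, scores=np.ones(3))


# ---------------------------------------------------------------------------
# chromatin-state and gene filters
# ---------------------------------------------------------------------------

def sig(*rows):
    df = iv(*rows)
    df.index = [f"{c}:{s}-{e}" for c, s, e in df.itertuples(index=False)]
    return df


class TestStateFilter:
    states = pd.DataFrame(
        [("chr1", 199, 300, "active"), ("chr1", 400, 500, "quiescent")],
        columns=["chrom", "start", "end", "state"],
    )
    active_map = {"active": True, "quiescent": False}

    def test_all_active_is_identity(self):
        s = sig(("chr1", 100, 200), ("chr1", 450, 460))
        states = pd.DataFrame([("chr1", 0, 1000, "active")],
                              columns=["chrom", "start", "end", "state"])
        out = chromatin.filter_by_chromatin_state(s, states, {"active": True})
        assert list(out.index) == list(s.index)

    def test_one_bp_overlap_retained(self):
        out = chromatin.filter_by_chromatin_state(
            sig(("chr1", 100, 200)), self.states, self.active_map
        )
        assert len(out) == 1

    def test_half_open_boundary_removed(self):
        states = pd.DataFrame([("chr1", 200, 300, "active")],
                              columns=["chrom", "start", "end", "state"])
        out = chromatin.filter_by_chromatin_state(
            sig(("chr1", 100, 200)), states, {"active": True}
        )
        assert len(out) == 0

    def test_inactive_only_overlap_removed(self):
        out = chromatin.filter_by_chromatin_state(
            sig(("chr1", 420, 430)), self.states, self.active_map
        )
        assert len(out) == 0

    def test_unknown_state_label_rejected(self):
        with pytest.raises(InputFormatError, match="quiescent"):
            chromatin.filter_by_chromatin_state(
                sig(("chr1", 100, 200)), self.states, {"active": True}
            )

    def test_uncovered_chromosome_treated_inactive(self):
        out = chromatin.filter_by_chromatin_state(
            sig(("chr9", 100, 200)), self.states, self.active_map
        )
        assert len(out) == 0


class TestGeneAnnotation:
    @staticmethod
    def genes(*rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "strand"])

    def test_peak_in_gene_body(self):
        out = chromatin.annotate_to_genes(
            sig(("chr1", 5500, 5600)), self.genes(("chr1", 5000, 9000, "GENE1", "+"))
        )
        assert out["annotated_gene"].tolist() == ["GENE1"]

    def test_promoter_extension_reaches_upstream_peak(self):
        # + strand gene [5000, 9000): extension moves the start to 3500
        genes = self.genes(("chr1", 5000, 9000, "GENE1", "+"))
        assert len(chromatin.annotate_to_genes(sig(("chr1", 3600, 3700)), genes)) == 1
        assert len(chromatin.annotate_to_genes(sig(("chr1", 3400, 3500)), genes)) == 0
        # - strand: extension moves the end, not the start
        minus = self.genes(("chr1", 5000, 9000, "GENE1", "-"))
        assert len(chromatin.annotate_to_genes(sig(("chr1", 3600, 3700)), minus)) == 0
        assert len(chromatin.annotate_to_genes(sig(("chr1", 9100, 9200)), minus)) == 1

    def test_largest_overlap_wins_ties_by_gene_id(self):
        genes = self.genes(
            ("chr1", 0, 150, "B_SHORT", "+"),
            ("chr1", 0, 190, "A_LONG", "+"),
        )
        out = chromatin.annotate_to_genes(sig(("chr1", 100, 200)), genes,
                                          promoter_extension=0)
        assert out["annotated_gene"].tolist() == ["A_LONG"]
        ties = self.genes(
            ("chr1", 0, 150, "B_GENE", "+"),
            ("chr1", 0, 150, "A_GENE", "+"),
        )
        out = chromatin.annotate_to_genes(sig(("chr1", 100, 200)), ties,
                                          promoter_extension=0)
        assert out["annotated_gene"].tolist() == ["A_GENE"]

    def test_matches_all_pairs_oracle(self, rng):
        genome_len = 20000
        peaks = random_intervals(rng, genome_len, 25)
        peaks = sig(*[tuple(r) for r in peaks.to_numpy()])
        peaks = peaks[~peaks.index.duplicated()]
        genes = self.genes(
            *[
                ("chr1", int(s), int(s + rng.integers(200, 2000)),
                 f"G{k:02d}", "+" if rng.random() < 0.5 else "-")
                for k, s in enumerate(rng.integers(0, genome_len - 2000, 15))
            ]
        )
        ext = 1500
        out = chromatin.annotate_to_genes(peaks, genes, promoter_extension=ext)
        for pid, row in peaks.iterrows():
            best = None  # (overlap, gene_id)
            for _, g in genes.iterrows():
                gs, ge = g["start"], g["end"]
                if g["strand"] == "+":
                    gs = max(0, gs - ext)
                else:
                    ge = ge + ext
                ov = min(ge, row["end"]) - max(gs, row["start"])
                if ov <= 0:
                    continue
                if best is None or ov > best[0] or (ov == best[0] and g["gene_id"] < best[1]):
                    best = (ov, g["gene_id"])
            if best is None:
                assert pid not in out.index
            else:
                assert out.loc[pid, "annotated_gene"] == best[1]


# ---------------------------------------------------------------------------
# paired subtracted signal
# ---------------------------------------------------------------------------

def bg(*rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def dense_track(df, genome_len):
    arr = np.zeros(genome_len)
    for _, r in df.iterrows():
        arr[int(r["start"]):int(r["end"])] = r["value"]
    return arr


class TestSubtractedSignal:
    def test_identical_pair_gives_empty_track(self):
        t = bg(("chr1", 0, 100, 5.0))
        out = chromatin.paired_subtracted_signal([(t, t.copy())])
        assert len(out) == 0

    def test_constant_difference(self):
        out = chromatin.paired_subtracted_signal(
            [(bg(("chr1", 0, 100, 5.0)), bg(("chr1", 0, 100, 2.0)))]
        )
        assert out.to_numpy().tolist() == [["chr1", 0, 100, 3.0]]

    def test_absent_runs_read_as_zero(self):
        out = chromatin.paired_subtracted_signal(
            [(bg(("chr1", 50, 60, 4.0)), bg())]
        )
        assert out.to_numpy().tolist() == [["chr1", 50, 60, 4.0]]

    def test_matches_dense_oracle(self, rng):
        genome_len = 2000
        pairs = []
        dense = np.zeros(genome_len)
        for _ in range(3):
            t = random_intervals(rng, genome_len, 8)
            t["value"] = np.round(rng.uniform(-3, 5, len(t)), 3)
            c = random_intervals(rng, genome_len, 8)
            c["value"] = np.round(rng.uniform(0, 5, len(c)), 3)
            t = chromatin.merge_intervals(t[["chrom", "start", "end"]]).assign(
                value=lambda d: np.round(rng.uniform(-3, 5, len(d)), 3))
            c = chromatin.merge_intervals(c[["chrom", "start", "end"]]).assign(
                value=lambda d: np.round(rng.uniform(0, 5, len(d)), 3))
            pairs.append((t, c))
            dense += dense_track(t, genome_len) - dense_track(c, genome_len)
        dense /= len(pairs)
        out = chromatin.paired_subtracted_signal(pairs)
        got = dense_track(out, genome_len)
        np.testing.assert_allclose(got, dense, atol=1e-12)
        # run-length encoding is minimal and zero-suppressed
        assert (out["value"] != 0).all()

    def test_additive_in_treated_track(self):
        c = bg(("chr1", 0, 50, 1.0))
        t1 = bg(("chr1", 0, 50, 3.0))
        t2 = bg(("chr1", 0, 50, 5.0))
        out1 = chromatin.paired_subtracted_signal([(t1, c)])
        out2 = chromatin.paired_subtracted_signal([(t2, c)])
        both = chromatin.paired_subtracted_signal([(t1, c), (t2, c)])
        assert both["value"].iloc[0] == pytest.approx(
            (out1["value"].iloc[0] + out2["value"].iloc[0]) / 2
        )

    def test_unknown_chromosome_listed(self):
        with pytest.raises(InputFormatError, match="chrX"):
            chromatin.paired_subtracted_signal(
                [(bg(("chrX", 0, 10, 1.0)), bg(("chr1", 0, 10, 1.0)))],
                chroms=["chr1"],
            )


def test_stage_monotonicity(chip_sim):
    """Signature stages only ever shrink the peak set."""
    from isopair import synthetic

    exp = chip_sim
    consensus = chromatin.build_consensus(exp.peaks)
    supported = chromatin.filter_by_support(consensus, 2)
    vst = chromatin.vst_transform(exp.counts.loc[supported.index])
    pca = chromatin.pca_over_samples(vst)
    cond = exp.samples.set_index("sample").loc[list(vst.columns), "condition"]
    comp = chromatin.condition_component_scan(pca, cond.to_numpy()).abs().idxmax()
    sel = chromatin.select_pc_correlated_peaks(
        vst, pca, int(comp.removeprefix("PC")), peaks=supported
    )
    states, active_map, genes = synthetic.simulate_annotation(exp.intervals, seed=0)
    state_filtered = chromatin.filter_by_chromatin_state(sel, states, active_map)
    annotated = chromatin.annotate_to_genes(state_filtered, genes)
    assert len(annotated) <= len(state_filtered) <= len(sel) <= len(supported)
    assert set(annotated.index) <= set(state_filtered.index) <= set(sel.index)
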