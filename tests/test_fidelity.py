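import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pdoimmune import fidelity, simulate as sim
from pdoimmune.errors import DomainError, StateError
from pdoimmune.types import ExpressionMatrix, GeneSet, SampleMetadata


def raw(values: dict, genes) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame(values, index=genes), scale="raw")


class TestLogTransform:
    def test_known_values(self):
        m = raw({"s1": [0.0, 7.0]}, ["gA", "gB"])
        t = fidelity.log_transform(m)
        assert t.values.loc["gA", "s1"] == 0.0
        assert t.values.loc["gB", "s1"] == 3.0
        assert t.scale == "log2"

    def test_inverse_identity(self):
        rng = np.random.default_rng(1)
        m = raw({f"s{i}": rng.uniform(0, 50, 20) for i in range(4)},
                [f"g{i}" for i in range(20)])
        t = fidelity.log_transform(m)
        back = 2 ** t.values - 1
        assert np.allclose(back, m.values, atol=1e-9)

    def test_double_transform_rejected(self, toy_matrix):
        with pytest.raises(StateError):
            fidelity.log_transform(toy_matrix)


class TestGenesetScore:
    def test_single_gene_is_zscore(self, toy_matrix):
        score = fidelity.geneset_score(toy_matrix, GeneSet("one", ["gA"]))
        x = toy_matrix.values.loc["gA"]
        expected = (x - x.mean()) / x.std(ddof=0)
        assert np.allclose(score, expected)

    def test_scores_center_to_zero(self, toy_matrix):
        score = fidelity.geneset_score(toy_matrix, GeneSet("both", ["gA", "gB"]))
        assert abs(score.mean()) < 1e-9

    def test_opposing_genes_cancel(self, toy_matrix):
        # gA rises 1,2,3 while gB falls 3,2,1: z-scores cancel exactly
        score = fidelity.geneset_score(toy_matrix, GeneSet("both", ["gA", "gB"]))
        assert np.allclose(score, 0.0, atol=1e-12)

    def test_gene_order_and_absent_gene_invariance(self, toy_matrix):
        a = fidelity.geneset_score(toy_matrix, GeneSet("s", ["gA", "gB"]))
        b = fidelity.geneset_score(toy_matrix, GeneSet("s", ["gB", "gA", "gZ"]))
        assert np.allclose(a, b)

    def test_zero_variance_gene_contributes_zero(self):
        m = ExpressionMatrix(pd.DataFrame(
            {"s1": [1.0, 5.0], "s2": [2.0, 5.0], "s3": [3.0, 5.0]},
            index=["gA", "gflat"]), scale="log2")
        with_flat = fidelity.geneset_score(m, GeneSet("s", ["gA", "gflat".replace("f", "f")]))
        only_a = fidelity.geneset_score(m, GeneSet("s", ["gA"]))
        assert np.allclose(with_flat, only_a / 2)

    def test_no_overlap_rejected(self, toy_matrix):
        with pytest.raises(DomainError, match="absent"):
            fidelity.geneset_score(toy_matrix, GeneSet("absent", ["gX", "gY"]))


class TestMcpScores:
    def test_monotone_in_expression(self):
        rng = np.random.default_rng(2)
        genes = ["CD3D", "CD3E", "other1", "other2"]
        values = pd.DataFrame(rng.uniform(1, 2, (4, 4)), index=genes,
                              columns=list("ABCD"))
        values.loc[["CD3D", "CD3E"], "A"] *= 4
        m = ExpressionMatrix(np.log2(values + 1), scale="log2")
        scores = fidelity.mcp_scores(m, [GeneSet("T_cell", ["CD3D", "CD3E"])])
        assert scores["T_cell"].idxmax() == "A"

    def test_empty_population_list(self, toy_matrix):
        out = fidelity.mcp_scores(toy_matrix, [])
        assert out.shape == (3, 0)

    def test_stromal_elevated_in_synthetic_metastases(self, default_bulk):
        """The generator plants monocytic/fibroblast/endothelial elevation in
        metastasis samples, mirroring the organoid-vs-tumor contrast."""
        from pdoimmune.io import default_mcp_populations
        matrix, metadata, _ = default_bulk
        scores = fidelity.mcp_scores(matrix, default_mcp_populations())
        mets = [m.sample_id for m in metadata if m.tissue == "metastasis"]
        pdos = [m.sample_id for m in metadata if m.tissue == "pdo"]
        for pop in ("monocytic", "fibroblast", "endothelial"):
            assert scores.loc[mets, pop].mean() > scores.loc[pdos, pop].mean()


class TestPca:
    def test_duplicated_samples_identical_coordinates(self):
        rng = np.random.default_rng(3)
        base = rng.normal(3, 1, 50)
        values = pd.DataFrame({
            "a": base, "a2": base,
            "b": base + rng.normal(0, 2, 50), "c": rng.normal(3, 1, 50),
        }, index=[f"g{i}" for i in range(50)])
        res = fidelity.top_variable_pca(ExpressionMatrix(values, "log2"), n_genes=50)
        assert np.allclose(res.coordinates.loc["a"], res.coordinates.loc["a2"], atol=1e-8)

    def test_variance_fractions_bounded_and_sorted(self, default_bulk):
        matrix, _, _ = default_bulk
        res = fidelity.top_variable_pca(matrix, n_genes=500, n_components=5)
        v = res.variance_fractions
        assert v.sum() <= 1 + 1e-9
        assert (np.diff(v) <= 1e-12).all()

    def test_patient_clusters_separate(self):
        """Two patients with a large planted between-patient effect separate
        on the first component beyond the within-patient spread."""
        cfg = sim.SimulationConfig(seed=21, n_patients=2, n_genes=300,
                                   between_patient_sd=3.0, tumor_pdo_noise_sd=0.2,
                                   residual_sd=0.1)
        matrix, metadata, _ = sim.simulate_bulk(cfg)
        res = fidelity.top_variable_pca(matrix, n_genes=300)
        pc1 = res.coordinates["PC1"]
        groups = {m.sample_id: m.patient_id for m in metadata}
        means = pc1.groupby(pc1.index.map(groups)).mean()
        spread = pc1.groupby(pc1.index.map(groups)).std().max()
        assert abs(means.iloc[0] - means.iloc[1]) > spread

    def test_too_few_samples_rejected(self):
        m = ExpressionMatrix(pd.DataFrame({"a": [1.0], "b": [2.0]}, index=["g"]),
                             scale="log2")
        with pytest.raises(DomainError):
            fidelity.top_variable_pca(m)


class TestMatchedCorrelation:
    def test_perfect_copy_limit(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(200)]
        cols, meta = {}, []
        for i in range(5):
            met = rng.uniform(0, 100, 200)
            cols[f"P{i}_MET"] = met
            cols[f"P{i}_PDO"] = met  # organoid is an exact copy
            meta.append(SampleMetadata(sample_id=f"P{i}_MET", patient_id=f"P{i}",
                                       tissue="metastasis"))
            meta.append(SampleMetadata(sample_id=f"P{i}_PDO", patient_id=f"P{i}",
                                       tissue="pdo"))
        m = ExpressionMatrix(pd.DataFrame(cols, index=genes), scale="raw")
        rep = fidelity.matched_correlation_test(m, meta, n_top_genes=200)
        assert np.allclose(rep.matched, 1.0)
        assert rep.p_value < 0.05

    def test_synthetic_cohort_matched_higher(self, default_bulk):
        matrix, metadata, _ = default_bulk
        rep = fidelity.matched_correlation_test(matrix, metadata)
        assert rep.matched.median() > rep.unmatched.median()
        assert rep.p_value < 1e-4

    def test_duplicate_pdo_timepoint_rejected(self):
        meta = [
            SampleMetadata(sample_id="a", patient_id="P1", tissue="pdo"),
            SampleMetadata(sample_id="b", patient_id="P1", tissue="pdo"),
            SampleMetadata(sample_id="c", patient_id="P1", tissue="metastasis"),
            SampleMetadata(sample_id="d", patient_id="P2", tissue="pdo"),
            SampleMetadata(sample_id="e", patient_id="P2", tissue="metastasis"),
        ]
        values = pd.DataFrame(np.random.default_rng(0).uniform(0, 9, (10, 5)),
                              index=[f"g{i}" for i in range(10)],
                              columns=list("abcde"))
        with pytest.raises(DomainError, match="P1"):
            fidelity.matched_correlation_test(ExpressionMatrix(values), meta)


class TestCnv:
    @pytest.fixture
    def positioned_cohort(self):
        # copy-number signal (log2 ratio -1) must dominate residual biology:
        # keep patient effects and tissue programs well below the 0.15 call
        # threshold once averaged over ~50 genes per chromosome
        cfg = sim.SimulationConfig(seed=30, n_genes=1100, n_patients=6,
                                   between_patient_sd=0.2, tumor_pdo_noise_sd=0.2,
                                   stroma_tumor_lfc=0.0, tcell_coupling=0.0)
        matrix, metadata, _ = sim.simulate_bulk(cfg)
        positions = sim.synthetic_gene_positions(matrix.gene_ids)
        return matrix, metadata, positions

    def test_reference_mean_sample_neutral(self, positioned_cohort):
        matrix, metadata, positions = positioned_cohort
        refs = [m.sample_id for m in metadata if m.tissue == "metastasis"][:3]
        log = fidelity.ensure_log(matrix)
        ref_mean = log.values[refs].mean(axis=1)
        values = log.values.copy()
        values["query"] = ref_mean
        m2 = ExpressionMatrix(values, scale="log2")
        prof = fidelity.cnv_profile(m2, positions, refs)["query"]
        assert (prof.calls == "neutral").all()

    def test_planted_chromosome_loss_called(self, positioned_cohort):
        """Halving all chr9/chr10 genes in one sample yields loss calls on
        exactly those chromosomes."""
        matrix, metadata, positions = positioned_cohort
        mets = [m.sample_id for m in metadata if m.tissue == "metastasis"]
        refs, query = mets[:5], mets[-1]
        altered = sim.apply_copy_number_change(
            matrix, positions, [query], ["chr9", "chr10"])
        profs = fidelity.cnv_profile(altered, positions, refs)
        calls = profs[query].calls
        assert calls["chr9"] == "loss" and calls["chr10"] == "loss"
        others = calls.drop(["chr9", "chr10"])
        assert (others != "loss").all()

    def test_winsorization_clamps_outlier(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(120)]
        base = rng.uniform(4, 6, 120)
        cols = {f"r{i}": 2 ** (base + rng.normal(0, 0.01, 120)) - 1 for i in range(3)}
        query = 2 ** base - 1
        query[0] = 2 ** (base[0] - 10) - 1  # single extreme loss
        cols["q"] = np.maximum(query, 0)
        m = ExpressionMatrix(pd.DataFrame(cols, index=genes), scale="raw")
        positions = sim.synthetic_gene_positions(genes, n_chromosomes=1)
        prof = fidelity.cnv_profile(m, positions, ["r0", "r1", "r2"])["q"]
        assert prof.bins["log2_ratio"].min() >= -3.0

    def test_matched_pairs_same_calls(self):
        """Matched tumor/organoid samples with the same planted karyotype get
        identical chromosome calls."""
        cfg = sim.SimulationConfig(seed=31, n_genes=1100, n_patients=6,
                                   tumor_pdo_noise_sd=0.2,
                                   between_patient_sd=0.2, stroma_tumor_lfc=0.0,
                                   tcell_coupling=0.0)
        matrix, metadata, _ = sim.simulate_bulk(cfg)
        positions = sim.synthetic_gene_positions(matrix.gene_ids)
        pat = "P06"
        refs = [m.sample_id for m in metadata
                if m.tissue == "metastasis" and m.patient_id != pat][:4]
        altered = sim.apply_copy_number_change(
            matrix, positions, [f"{pat}_MET", f"{pat}_PDO_B"], ["chr9", "chr10"])
        profs = fidelity.cnv_profile(altered, positions, refs)
        assert profs[f"{pat}_MET"].calls.equals(profs[f"{pat}_PDO_B"].calls)

    def test_no_positions_rejected(self, toy_matrix):
        positions = sim.synthetic_gene_positions(["gX", "gY", "gZ"])
        m = ExpressionMatrix(2 ** toy_matrix.values - 1, scale="raw")
        with pytest.raises(DomainError):
            fidelity.cnv_profile(m, positions, ["s1", "s2", "s3"])
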