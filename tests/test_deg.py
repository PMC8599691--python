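"""Threshold DEG selection: worked examples, brute-force oracle, invariants."""

import numpy as np
import pandas as pd
import pytest

from tgfbsig.datatypes import ExpressionMatrix, OrthologMap
from tgfbsig.deg import (
    DEGThresholds,
    compute_fold_change,
    map_orthologs,
    select_downregulated,
    select_upregulated,
    venn_overlap,
)
from tgfbsig.errors import PipelineError, ScaleError, ValidationError


def _matrix(treated, control):
    genes = [f"g{i}" for i in range(len(treated))]
    data = pd.DataFrame({"ctrl": control, "tgfb": treated},
                        index=pd.Index(genes, name="gene"))
    return ExpressionMatrix(data, scale_tag="linear")


class TestFoldChange:
    @pytest.mark.parametrize(
        "treated,control,pc,expected",
        [(6, 2, 0, 3.0), (5, 5, 0.3, 1.0), (5, 0, 0.1, 51.0), (0.7, 0.7, 0, 1.0)],
    )
    def test_worked_examples(self, treated, control, pc, expected):
        assert compute_fold_change(treated, control, pc) == pytest.approx(expected)

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            compute_fold_change(-1, 2, 0.1)

    def test_pseudocount_pulls_fold_change_toward_one(self):
        fc_small = compute_fold_change(8, 2, 0.1)
        fc_large = compute_fold_change(8, 2, 5.0)
        assert abs(fc_large - 1) < abs(fc_small - 1)


class TestSelection:
    @pytest.mark.parametrize(
        "treated,control,included",
        [
            (6.0, 2.0, True),    # FC 3 > 2 and treated 6 > 2
            (4.0, 2.0, False),   # FC exactly 2: strict threshold fails
            (1.5, 0.4, False),   # FC 3.75 but treated <= 2
        ],
    )
    def test_upregulated_threshold_edges(self, treated, control, included):
        thr = DEGThresholds(pseudocount=0.0)
        result = select_upregulated(_matrix([treated], [control]), "tgfb", "ctrl", thr)
        assert ("g0" in result.up_genes) is included

    @pytest.mark.parametrize(
        "treated,control,included",
        [
            (0.5, 4.0, True),    # FC 0.125 < 0.25, control 4 > 1
            (1.0, 4.0, False),   # FC exactly 0.25: strict threshold fails
            (0.1, 0.8, False),   # control <= 1: abundance gate on untreated value
        ],
    )
    def test_downregulated_threshold_edges(self, treated, control, included):
        thr = DEGThresholds(pseudocount=0.0)
        result = select_downregulated(_matrix([treated], [control]), "tgfb", "ctrl", thr)
        assert ("g0" in result.down_genes) is included

    def test_unknown_sample_id(self, tiny_matrix):
        with pytest.raises(PipelineError):
            select_upregulated(tiny_matrix, "nope", "s1")

    def test_log_scale_matrix_rejected(self, tiny_matrix):
        log_m = tiny_matrix.log2_transform()
        with pytest.raises(ScaleError):
            select_upregulated(log_m, "s1", "s2")

    def test_up_and_down_never_share_genes(self, noiseless_cellline):
        matrix, _ = noiseless_cellline
        up = select_upregulated(matrix, "tgfb", "ctrl")
        down = select_downregulated(matrix, "tgfb", "ctrl")
        assert not (up.up_genes & down.down_genes)

    def test_raising_fc_threshold_only_shrinks_selection(self, noiseless_cellline):
        matrix, _ = noiseless_cellline
        loose = select_upregulated(matrix, "tgfb", "ctrl", DEGThresholds(up_fc_min=2))
        tight = select_upregulated(matrix, "tgfb", "ctrl", DEGThresholds(up_fc_min=4))
        assert tight.up_genes <= loose.up_genes

    def test_brute_force_oracle_on_small_random_matrices(self):
        """Selection must match an independent gene-by-gene filter loop."""
        rng = np.random.default_rng(42)
        thr = DEGThresholds()
        for _ in range(10):
            n = rng.integers(3, 20)
            treated = rng.gamma(1.0, 4.0, n).round(3)
            control = rng.gamma(1.0, 4.0, n).round(3)
            matrix = _matrix(treated, control)
            up = select_upregulated(matrix, "tgfb", "ctrl", thr)
            down = select_downregulated(matrix, "tgfb", "ctrl", thr)
            expected_up, expected_down = set(), set()
            for g, t, c in zip(matrix.gene_ids, treated, control):
                fc = (t + 0.1) / (c + 0.1)
                if fc > 2 and t > 2:
                    expected_up.add(g)
                if fc < 0.25 and c > 1:
                    expected_down.add(g)
            assert up.up_genes == expected_up
            assert down.down_genes == expected_down

    def test_noiseless_recovery_of_planted_sets(self, noiseless_cellline):
        matrix, truth = noiseless_cellline
        up = select_upregulated(matrix, "tgfb", "ctrl")
        down = select_downregulated(matrix, "tgfb", "ctrl")
        assert up.up_genes == truth.planted_up
        assert down.down_genes == truth.planted_down

    def test_costimulation_venn_counts_planted_structure(self, noiseless_cellline):
        """Up under TGF-beta alone vs co-stimulation: induced genes respond in
        both columns, synergy genes only under co-stimulation."""
        matrix, truth = noiseless_cellline
        up = select_upregulated(matrix, "tgfb", "ctrl")
        up_co = select_upregulated(matrix, "tgfb_tnfa", "ctrl")
        venn = venn_overlap(up.up_genes, up_co.up_genes)
        assert venn.shared == len(truth.planted_up)
        assert truth.planted_synergy <= up_co.up_genes


class TestVenn:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"a", "b", "c"}, {"b", "c", "d"}, (1, 2, 1)),
            ({"a", "b"}, {"c"}, (2, 0, 1)),
            ({"a"}, {"a", "b", "c"}, (0, 1, 2)),
        ],
    )
    def test_partition_counts(self, a, b, expected):
        venn = venn_overlap(a, b)
        assert (venn.only_a, venn.shared, venn.only_b) == expected
        assert venn.only_a + venn.shared == len(a)
        assert venn.only_b + venn.shared == len(b)


class TestOrthologMapping:
    def test_simple_mapping(self):
        omap = OrthologMap(frozenset({("Snai1", "SNAI1")}))
        mapped, unmapped = map_orthologs({"Snai1"}, omap)
        assert mapped == {"SNAI1"} and unmapped == frozenset()

    def test_unmapped_gene_reported(self):
        mapped, unmapped = map_orthologs({"Xyz1"}, OrthologMap(frozenset()))
        assert mapped == frozenset() and unmapped == {"Xyz1"}

    def test_one_to_many_keeps_all_targets(self):
        omap = OrthologMap(frozenset({("G", "H1"), ("G", "H2")}))
        mapped, _ = map_orthologs({"G"}, omap)
        assert mapped == {"H1", "H2"}

    def test_many_to_one_collapses_by_union(self):
        omap = OrthologMap(frozenset({("A", "H"), ("B", "H")}))
        mapped, _ = map_orthologs({"A", "B"}, omap)
        assert mapped == {"H"}
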