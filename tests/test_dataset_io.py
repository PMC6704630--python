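"""Container invariants and reader/writer contracts."""

import json

import numpy as np
import pytest

from immunosig.dataset import ExpressionDataset, GeneSet, SplitSpec
from immunosig.errors import DataFormatError, ValidationError
from immunosig.io import (
    read_counts,
    read_gene_annotation,
    read_gene_sets,
    read_model,
    read_sparse_matrix,
    write_counts,
    write_gene_sets,
    write_model,
)
from immunosig.model import ClassifierModel, PenaltySpec
from immunosig.preprocess import within_lane_gc_normalize


class TestExpressionDataset:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError, match="duplicate gene"):
            ExpressionDataset(["g1", "g1"], ["s1"], np.ones((2, 1)))
        with pytest.raises(ValidationError, match="duplicate sample"):
            ExpressionDataset(["g1"], ["s1", "s1"], np.ones((1, 2)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="inconsistent"):
            ExpressionDataset(["g1"], ["s1"], np.ones((2, 2)))

    def test_negative_value_names_coordinates(self):
        with pytest.raises(ValidationError, match="g1.*s2"):
            ExpressionDataset(["g1"], ["s1", "s2"], np.array([[1.0, -3.0]]))

    def test_masked_positions_exempt_from_nonnegativity(self):
        ds = ExpressionDataset(
            ["g1"], ["s1", "s2"], np.array([[1.0, -1.0]]),
            missing_mask=np.array([[False, True]]),
        )
        assert ds.missing_mask.sum() == 1

    def test_subset_preserves_order_and_mask(self, tiny_ds):
        sub = tiny_ds.subset_genes(["g3", "g1"]).subset_samples(["x2", "x4"])
        assert sub.gene_ids == ["g3", "g1"]
        assert sub.values[1, 0] == 0.0 and sub.values[0, 1] == 9.0
        assert not sub.missing_mask.any()

    def test_encoded_matrix_places_dummy(self, tiny_ds):
        X = tiny_ds.encoded_matrix()
        assert X.shape == (4, 3)
        assert X[1, 1] == -1.0  # the masked (g2, x2) entry
        assert X[0, 0] == 5.0


class TestSplitSpec:
    def test_overlap_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            SplitSpec(("a", "b"), ("b", "c"))

    def test_every_label_needed_in_train(self, tiny_ds):
        split = SplitSpec(("x1", "x2"), ("x3", "x4"))  # B only in test
        with pytest.raises(ValidationError, match="missing from training"):
            split.check(tiny_ds)
        SplitSpec(("x1", "x3"), ("x2", "x4")).check(tiny_ds)  # ok


class TestReadCounts:
    def test_parses_matrix_and_na_mask(self, tmp_path):
        f = tmp_path / "m.tsv"
        f.write_text("gene\ts1\ts2\ng1\t5\t0\ng2\t2\tNA\ng3\t7\t1\n")
        ds = read_counts(f)
        assert ds.gene_ids == ["g1", "g2", "g3"] and ds.sample_ids == ["s1", "s2"]
        expected_mask = np.zeros((3, 2), dtype=bool)
        expected_mask[1, 1] = True
        assert np.array_equal(ds.missing_mask, expected_mask)
        assert np.array_equal(ds.values, [[5, 0], [2, 0], [7, 1]])

    @pytest.mark.parametrize("token", ["NA", "NaN", ""])
    def test_all_na_tokens_masked(self, tmp_path, token):
        f = tmp_path / "m.tsv"
        f.write_text(f"gene\ts1\ng1\t{token}\n")
        assert read_counts(f).missing_mask[0, 0]

    def test_empty_file_is_an_error(self, tmp_path):
        f = tmp_path / "empty.tsv"
        f.write_text("")
        with pytest.raises(DataFormatError, match="empty"):
            read_counts(f)

    def test_duplicate_gene_named(self, tmp_path):
        f = tmp_path / "m.tsv"
        f.write_text("gene\ts1\ngX\t1\ngX\t2\n")
        with pytest.raises(ValidationError, match="gX"):
            read_counts(f)

    def test_ragged_row_reports_line(self, tmp_path):
        f = tmp_path / "m.tsv"
        f.write_text("gene\ts1\ts2\ng1\t1\t2\ng2\t3\n")
        with pytest.raises(DataFormatError, match="line 3"):
            read_counts(f)

    def test_negative_count_reports_coordinates(self, tmp_path):
        f = tmp_path / "m.tsv"
        f.write_text("gene\ts1\ng1\t-4\n")
        with pytest.raises(DataFormatError, match="g1.*s1"):
            read_counts(f)

    def test_samples_in_rows_orientation(self, tmp_path):
        f = tmp_path / "m.csv"
        f.write_text("sample,g1,g2\ns1,1,2\ns2,3,4\n")
        ds = read_counts(f, orientation="samples_in_rows")
        assert ds.gene_ids == ["g1", "g2"] and ds.sample_ids == ["s1", "s2"]
        assert ds.values[1, 0] == 2.0

    def test_write_read_round_trip(self, tmp_path, tiny_ds):
        f = tmp_path / "rt.tsv"
        write_counts(tiny_ds, f)
        back = read_counts(f)
        assert back.gene_ids == tiny_ds.gene_ids
        assert np.array_equal(back.values, tiny_ds.values * ~tiny_ds.missing_mask)
        assert np.array_equal(back.missing_mask, tiny_ds.missing_mask)


class TestGeneAnnotation:
    def test_valid_row_stored(self, tmp_path):
        f = tmp_path / "ann.tsv"
        f.write_text("gene_id\tgc_fraction\tlength_bp\nGENE1\t0.41\t2100\n")
        ann = read_gene_annotation(f)
        assert ann.loc["GENE1", "gc_fraction"] == 0.41
        assert ann.loc["GENE1", "length_bp"] == 2100

    def test_gc_out_of_range_rejected(self, tmp_path):
        f = tmp_path / "ann.tsv"
        f.write_text("gene_id\tgc_fraction\tlength_bp\nGENE2\t1.2\t500\n")
        with pytest.raises(ValidationError, match="GENE2"):
            read_gene_annotation(f)

    def test_missing_annotation_deferred_to_normalization(self, tmp_path, tiny_ds):
        f = tmp_path / "ann.tsv"
        f.write_text("gene_id\tgc_fraction\tlength_bp\ng1\t0.5\t1000\n")
        ann = read_gene_annotation(f)  # succeeds despite covering one gene
        with pytest.raises(ValidationError, match="lack GC annotation"):
            within_lane_gc_normalize(tiny_ds, annotation=ann)


class TestSparseMatrix:
    def _write(self, tmp_path, header, triplets, genes=("g1", "g2"), barcodes=("c1", "c2")):
        m = tmp_path / "m.mtx"
        body = "\n".join(" ".join(map(str, t)) for t in triplets)
        m.write_text(
            "%%MatrixMarket matrix coordinate real general\n"
            f"{header[0]} {header[1]} {len(triplets)}\n{body}\n"
        )
        g = tmp_path / "genes.tsv"
        g.write_text("\n".join(genes) + "\n")
        b = tmp_path / "barcodes.tsv"
        b.write_text("\n".join(barcodes) + "\n")
        return m, g, b

    def test_single_triplet_rest_zero_not_missing(self, tmp_path):
        ds = read_sparse_matrix(*self._write(tmp_path, (2, 2), [(1, 1, 4)]))
        assert np.array_equal(ds.values, [[4, 0], [0, 0]])
        assert not ds.missing_mask.any()

    def test_out_of_bounds_index_rejected(self, tmp_path):
        paths = self._write(tmp_path, (2, 2), [(4, 1, 1)])
        with pytest.raises(DataFormatError):
            read_sparse_matrix(*paths)

    def test_duplicate_coordinates_summed(self, tmp_path):
        # dialect decision: repeated entries accumulate (2 + 3 = 5)
        ds = read_sparse_matrix(*self._write(tmp_path, (2, 2), [(1, 2, 2), (1, 2, 3)]))
        assert np.array_equal(ds.values, [[0, 5], [0, 0]])

    def test_shape_mismatch_with_id_lists(self, tmp_path):
        paths = self._write(tmp_path, (3, 2), [(1, 1, 1)])
        with pytest.raises(DataFormatError, match="2 genes"):
            read_sparse_matrix(*paths)


class TestModelRoundTrip:
    def _model(self, p=3, k=2):
        return ClassifierModel(
            kind="multinomial",
            class_labels=[f"c{i}" for i in range(k)],
            gene_ids=[f"g{i}" for i in range(p)],
            intercepts=np.linspace(-1, 1, k),
            coefficients=np.arange(p * k, dtype=float).reshape(p, k) / 7.0,
            penalty=PenaltySpec(alpha=0.93, lam=0.01),
            training_provenance={"note": "fixture"},
        )

    def test_round_trip_identity(self, tmp_path):
        m = self._model()
        write_model(m, tmp_path / "m.json")
        back = read_model(tmp_path / "m.json")
        assert back.allclose(m, tol=1e-12)
        assert back.training_provenance == m.training_provenance

    def test_unknown_schema_version_rejected(self, tmp_path):
        write_model(self._model(), tmp_path / "m.json")
        doc = json.loads((tmp_path / "m.json").read_text())
        doc["schema_version"] = 99
        (tmp_path / "m.json").write_text(json.dumps(doc))
        with pytest.raises(DataFormatError, match="schema version"):
            read_model(tmp_path / "m.json")

    def test_zero_gene_model_legal(self, tmp_path):
        m = ClassifierModel(
            kind="binary", class_labels=["rest", "T"], gene_ids=[],
            intercepts=np.array([0.3]), coefficients=np.zeros((0, 1)),
            penalty=PenaltySpec(lam=0.1),
        )
        write_model(m, tmp_path / "m.json")
        assert read_model(tmp_path / "m.json").allclose(m)


class TestGeneSets:
    def test_gmt_and_tsv_agree(self, tmp_path):
        (tmp_path / "s.gmt").write_text("setA\tdesc\tg1\tg2\nsetB\tdesc\tg3\n")
        gmt = read_gene_sets(tmp_path / "s.gmt")
        write_gene_sets(gmt, tmp_path / "s.tsv")
        tsv = read_gene_sets(tmp_path / "s.tsv")
        assert {s.name: s.genes for s in gmt} == {s.name: s.genes for s in tsv}

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            GeneSet(name="bad", genes=frozenset())
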