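"""Per-gene tables, percentile lists, density binning, syntelog differences."""

import numpy as np
import pytest

from tedensity.density_core import WindowSpec, DensityTensor
from tedensity.density_store import read_density, write_density
from tedensity.errors import LookupKeyError, TEDensityError
from tedensity.reporting import (
    NO_TE,
    SyntelogPair,
    bin_genes_by_density,
    info_of_gene,
    load_syntelog_pairs,
    percentile_gene_list,
    syntelog_density_difference,
)
from tedensity.revision import TOTAL_LABEL


def build_store(tmp_path, name, order_spec, superfam_spec, strands, windows=(1000,)):
    """order_spec/superfam_spec: (labels, values array (I, W, G, 3))."""

    def tensor(level, spec):
        labels, values = spec
        return DensityTensor(
            level=level,
            pseudomolecule="Chr1",
            identity_labels=labels,
            windows=WindowSpec(windows),
            gene_names=[f"g{i}" for i in range(values.shape[2])],
            gene_strands=list(strands),
            values=values,
        )

    return write_density(
        tensor("order", order_spec), tensor("superfamily", superfam_spec),
        tmp_path / f"{name}_Chr1.h5", genome_id=name,
    )


@pytest.fixture
def zero_store(tmp_path):
    labels = ["LTR", "SINE", TOTAL_LABEL]
    shape = (3, 1, 2, 3)
    path = build_store(
        tmp_path, "zeros",
        (labels, np.zeros(shape)), (["Alu", "Copia", TOTAL_LABEL], np.zeros(shape)),
        ["sense", "sense"],
    )
    return read_density(path)


class TestInfoOfGene:
    def test_zero_te_gene_yields_no_te_placeholders(self, zero_store):
        table = info_of_gene(zero_store, "g0", 1000)
        for level in ("order", "superfamily"):
            for direction in ("upstream", "intragenic", "downstream"):
                assert table.sections[level][direction] == [(NO_TE, 0.0)] * 5

    def test_single_superfamily_upstream_with_total(self, tmp_path):
        order_labels = ["LTR", TOTAL_LABEL]
        superfam_labels = ["Copia", "Gypsy", TOTAL_LABEL]
        order_values = np.zeros((2, 1, 1, 3))
        superfam_values = np.zeros((3, 1, 1, 3))
        # one Copia element upstream; Total equals Copia
        superfam_values[0, 0, 0, 0] = 0.3
        superfam_values[2, 0, 0, 0] = 0.3
        order_values[0, 0, 0, 0] = 0.3
        order_values[1, 0, 0, 0] = 0.3
        data = read_density(build_store(
            tmp_path, "one",
            (order_labels, order_values), (superfam_labels, superfam_values),
            ["sense"],
        ))
        table = info_of_gene(data, "g0", 1000, n=2)
        upstream = table.sections["superfamily"]["upstream"]
        # tie between Copia and Total broken alphabetically
        assert upstream == [("Copia", 0.3), (TOTAL_LABEL, 0.3)]
        assert table.sections["superfamily"]["downstream"] == [(NO_TE, 0.0)] * 2

    def test_top1_total_dominates_section(self, tmp_path):
        superfam_labels = ["Alu", "MIR", TOTAL_LABEL]
        superfam_values = np.zeros((3, 1, 1, 3))
        superfam_values[:, 0, 0, 0] = [0.301, 0.1, 0.401]
        order_values = np.zeros((2, 1, 1, 3))
        data = read_density(build_store(
            tmp_path, "dom",
            (["SINE", TOTAL_LABEL], order_values), (superfam_labels, superfam_values),
            ["sense"],
        ))
        table = info_of_gene(data, "g0", 1000)
        upstream = table.sections["superfamily"]["upstream"]
        assert upstream[0] == (TOTAL_LABEL, 0.401)
        assert upstream[1] == ("Alu", 0.301)
        assert upstream[2] == ("MIR", 0.1)
        assert upstream[3:] == [(NO_TE, 0.0)] * 2

    def test_unknown_gene_raises(self, zero_store):
        with pytest.raises(LookupKeyError):
            info_of_gene(zero_store, "nope", 1000)

    def test_frame_layout(self, zero_store):
        frame = info_of_gene(zero_store, "g0", 1000).to_frame()
        assert len(frame) == 2 * 3 * 5  # levels x directions x top-5
        assert set(frame["Direction"]) == {"upstream", "intragenic", "downstream"}


class TestPercentile:
    def make_accessor(self, tmp_path, densities, name="p"):
        n = len(densities)
        order_values = np.zeros((2, 1, n, 3))
        order_values[0, 0, :, 0] = densities
        superfam_values = np.zeros((2, 1, n, 3))
        path = build_store(
            tmp_path, name,
            (["LTR", TOTAL_LABEL], order_values),
            (["Copia", TOTAL_LABEL], superfam_values),
            ["sense"] * n,
        )
        return read_density(path)

    def test_constant_vector_returns_all_genes(self, tmp_path):
        data = self.make_accessor(tmp_path, [0.4] * 6)
        cutoff, genes = percentile_gene_list([data], "order", "LTR", 1000, "upstream", 99)
        assert cutoff == 0.4
        assert len(genes) == 6

    def test_uniform_vector_matches_interpolation_oracle(self, tmp_path):
        densities = [i / 99 for i in range(100)]
        data = self.make_accessor(tmp_path, densities)
        cutoff, genes = percentile_gene_list([data], "order", "LTR", 1000, "upstream", 99)
        # linear interpolation between order statistics, computed by hand:
        # rank = 99/100 * (n - 1) = 98.01 -> v[98] + 0.01 * (v[99] - v[98])
        expected = densities[98] + 0.01 * (densities[99] - densities[98])
        assert cutoff == pytest.approx(expected, abs=1e-12)
        assert len(genes) == 1  # only the maximum exceeds the cutoff

    def test_median_on_symmetric_vector_returns_half(self, tmp_path):
        densities = [i / 9 for i in range(10)]
        data = self.make_accessor(tmp_path, densities)
        cutoff, genes = percentile_gene_list([data], "order", "LTR", 1000, "upstream", 50)
        assert 4 <= len(genes) <= 6
        assert all(genes["Density"] >= cutoff)

    def test_all_zero_vector_warns_and_returns_everyone(self, tmp_path, caplog):
        data = self.make_accessor(tmp_path, [0.0] * 5)
        with caplog.at_level("WARNING"):
            cutoff, genes = percentile_gene_list(
                [data], "order", "LTR", 1000, "upstream", 99
            )
        assert cutoff == 0.0
        assert len(genes) == 5
        assert any("zero" in m for m in caplog.messages)

    def test_percentile_out_of_range_rejected(self, tmp_path):
        data = self.make_accessor(tmp_path, [0.1, 0.2])
        with pytest.raises(TEDensityError):
            percentile_gene_list([data], "order", "LTR", 1000, "upstream", 100)


class TestBinning:
    def test_half_open_bins_and_closed_last(self):
        binning = bin_genes_by_density([0.0, 0.3, 0.1, 0.95, 1.0])
        assert binning.counts.tolist() == [1, 1, 0, 1, 0, 0, 0, 0, 0, 2]
        assert binning.intervals()[0] == "[0.0,0.1)"
        assert binning.intervals()[-1] == "[0.9,1.0]"

    def test_boundary_value_goes_to_upper_bin(self):
        # 0.3 belongs to [0.3, 0.4), not [0.2, 0.3)
        binning = bin_genes_by_density([0.3])
        assert binning.counts[3] == 1

    def test_counts_conserved_after_exclusion(self):
        rng = np.random.default_rng(5)
        values = rng.random(100)
        expression = rng.exponential(1.0, 100)
        binning = bin_genes_by_density(values, expression, expressed_cutoff=0.1)
        assert binning.counts.sum() + binning.n_excluded == 100

    def test_zero_cutoff_excludes_nothing(self):
        values = [0.1, 0.5]
        binning = bin_genes_by_density(values, [0.0, 5.0], expressed_cutoff=0.0)
        assert binning.n_excluded == 0
        assert binning.counts.sum() == 2

    def test_width_must_partition_unit_interval(self):
        with pytest.raises(TEDensityError):
            bin_genes_by_density([0.5], bin_width=0.3)

    def test_density_outside_unit_interval_rejected(self):
        with pytest.raises(TEDensityError):
            bin_genes_by_density([1.2])


class TestSyntelogDifferences:
    def paired_stores(self, tmp_path, densities_a, densities_b):
        store_a = TestPercentile.make_accessor(self, tmp_path / "a", densities_a, "A")
        store_b = TestPercentile.make_accessor(self, tmp_path / "b", densities_b, "B")
        return store_a, store_b

    def test_identical_genomes_give_zero_differences(self, tmp_path):
        (tmp_path / "a").mkdir(), (tmp_path / "b").mkdir()
        a, b = self.paired_stores(tmp_path, [0.2, 0.5], [0.2, 0.5])
        pairs = [SyntelogPair("g0", "g0"), SyntelogPair("g1", "g1")]
        result = syntelog_density_difference(
            pairs, [a], [b], "order", "LTR", 1000, "upstream"
        )
        assert result.n_zero == 2 and result.n_nonzero == 0

    def test_complete_presence_absence_is_plus_one(self, tmp_path):
        (tmp_path / "a").mkdir(), (tmp_path / "b").mkdir()
        a, b = self.paired_stores(tmp_path, [1.0], [0.0])
        result = syntelog_density_difference(
            [SyntelogPair("g0", "g0")], [a], [b], "order", "LTR", 1000, "upstream"
        )
        assert result.differences["Difference"].tolist() == [1.0]

    def test_zero_and_nonzero_tallied_separately(self, tmp_path):
        (tmp_path / "a").mkdir(), (tmp_path / "b").mkdir()
        a, b = self.paired_stores(
            tmp_path, [0.1, 0.2, 0.3, 0.4, 0.5], [0.1, 0.9, 0.3, 0.0, 1.0]
        )
        pairs = [SyntelogPair(f"g{i}", f"g{i}") for i in range(5)]
        result = syntelog_density_difference(
            pairs, [a], [b], "order", "LTR", 1000, "upstream"
        )
        assert result.n_zero == 2 and result.n_nonzero == 3

    def test_antisymmetric_under_genome_swap(self, tmp_path):
        (tmp_path / "a").mkdir(), (tmp_path / "b").mkdir()
        a, b = self.paired_stores(tmp_path, [0.8, 0.1, 0.6], [0.2, 0.1, 0.9])
        pairs = [SyntelogPair(f"g{i}", f"g{i}") for i in range(3)]
        forward = syntelog_density_difference(
            pairs, [a], [b], "order", "LTR", 1000, "upstream"
        )
        swapped_pairs = [SyntelogPair(p.gene_b, p.gene_a) for p in pairs]
        backward = syntelog_density_difference(
            swapped_pairs, [b], [a], "order", "LTR", 1000, "upstream"
        )
        assert np.array_equal(
            forward.differences["Difference"].to_numpy(),
            -backward.differences["Difference"].to_numpy(),
        )

    def test_unresolvable_pair_skipped_with_count(self, tmp_path, caplog):
        (tmp_path / "a").mkdir(), (tmp_path / "b").mkdir()
        a, b = self.paired_stores(tmp_path, [0.5], [0.5])
        pairs = [SyntelogPair("g0", "g0"), SyntelogPair("ghost", "g0")]
        with caplog.at_level("WARNING"):
            result = syntelog_density_difference(
                pairs, [a], [b], "order", "LTR", 1000, "upstream"
            )
        assert result.n_skipped == 1
        assert len(result.differences) == 1

    def test_pair_loader_applies_e_value_cutoff(self, tmp_path):
        path = tmp_path / "pairs.tsv"
        path.write_text(
            "GeneA\tGeneB\tE_value\n"
            "g0\tg0\t0.001\n"
            "g1\tg1\t0.2\n"
        )
        pairs = load_syntelog_pairs(path, e_value_cutoff=0.05)
        assert [p.gene_a for p in pairs] == ["g0"]
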