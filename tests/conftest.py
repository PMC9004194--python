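import numpy as np
import pytest

from tedensity.annotation_io import GeneRecord, TERecord
from tedensity.density_core import WindowSpec, compute_pseudomolecule_density
from tedensity.fixtures import SyntheticGenomeParams, generate_synthetic_genome, oracle_density
from tedensity.revision import revise


def gene(name, g0, g1, strand="sense", pseudo="Chr1"):
    return GeneRecord(pseudomolecule=pseudo, name=name, g0=g0, g1=g1, strand=strand)


def te(t0, t1, order="LTR", superfamily="Copia", pseudo="Chr1"):
    return TERecord(pseudomolecule=pseudo, t0=t0, t1=t1, order=order, superfamily=superfamily)


def pipeline_vs_oracle_max_error(genes_by_pseudo, tes_by_pseudo, windows):
    """Largest |pipeline − oracle| cell difference over both grouping levels."""
    revised = revise(tes_by_pseudo)
    worst = 0.0
    for pseudo, gene_group in genes_by_pseudo.items():
        for level in ("order", "superfamily"):
            tensor = compute_pseudomolecule_density(gene_group, revised, level, windows)
            reference = oracle_density(
                gene_group,
                tes_by_pseudo.get(pseudo, []),
                windows,
                level,
                identity_labels=tensor.identity_labels,
            )
            worst = max(worst, float(np.max(np.abs(tensor.values - reference.values))))
    return worst


def random_genome_params(rng, *, max_length=100_000):
    """Draw generator settings covering the adversarial structure the suite needs:
    nested/overlapping TEs, genes at the origin, antisense genes, 2-4 orders."""
    order_pool = {
        "LTR": ("Copia", "Gypsy"),
        "TIR": ("Mutator", "CACTA"),
        "LINE": ("L1",),
        "Helitron": ("Helitron",),
    }
    n_orders = int(rng.integers(2, 5))
    chosen = rng.choice(sorted(order_pool), size=n_orders, replace=False)
    return SyntheticGenomeParams(
        pseudomolecule_count=1,
        pseudomolecule_length=int(rng.integers(20_000, max_length + 1)),
        gene_count=int(rng.integers(3, 11)),
        gene_length_range=(200, 1_500),
        te_count=int(rng.integers(5, 51)),
        te_length_range=(50, 1_200),
        identities={order: order_pool[order] for order in chosen},
        te_te_overlap_prob=float(rng.uniform(0.1, 0.9)),
        te_gene_overlap_prob=float(rng.uniform(0.0, 0.4)),
        antisense_fraction=0.5,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


@pytest.fixture
def small_windows():
    return WindowSpec((100, 500, 1000))


@pytest.fixture
def small_genome():
    """One 100 kb pseudomolecule, 6 genes, 30 TEs, deterministic."""
    params = SyntheticGenomeParams(seed=11, gene_count=6, te_count=30)
    return generate_synthetic_genome(params)


@pytest.fixture
def multi_pseudo_genome():
    params = SyntheticGenomeParams(
        seed=7, pseudomolecule_count=3, gene_count=4, te_count=15
    )
    return generate_synthetic_genome(params)
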