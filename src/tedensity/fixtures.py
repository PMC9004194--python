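"""Synthetic annotations with controlled overlap structure, and an
independent per-base occupancy-mask oracle.

The generator emits gene and TE annotations that exercise the cases the
pipeline must get right — nested and partially overlapping TEs, TEs
straddling window edges and gene boundaries, genes at position 0,
antisense genes — without any genome download.  The oracle computes every
density by explicit boolean occupancy vectors (per-base union), so it
shares no code with the revision or overlap modules and checks them
end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from tedensity.annotation_io import (
    ANTISENSE,
    SENSE,
    GeneRecord,
    TERecord,
    write_gene_annotation,
    write_te_annotation,
)
from tedensity.density_core import DensityTensor, WindowSpec
from tedensity.errors import TEDensityError
from tedensity.revision import TOTAL_LABEL

#: default TE identity alphabet: orders with nested superfamilies
DEFAULT_IDENTITIES: Mapping[str, tuple[str, ...]] = {
    "LTR": ("Copia", "Gypsy"),
    "TIR": ("Mutator", "CACTA"),
    "LINE": ("L1",),
    "Helitron": ("Helitron",),
}


@dataclass(frozen=True)
class SyntheticGenomeParams:
    """Knobs for one synthetic genome; identical seeds give identical output."""

    pseudomolecule_count: int = 1
    pseudomolecule_length: int = 100_000
    gene_count: int = 5
    gene_length_range: tuple[int, int] = (500, 3_000)
    te_count: int = 20
    te_length_range: tuple[int, int] = (100, 2_000)
    identities: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_IDENTITIES)
    )
    te_te_overlap_prob: float = 0.3
    te_gene_overlap_prob: float = 0.1
    antisense_fraction: float = 0.5
    gene_at_origin_prob: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.pseudomolecule_count, self.gene_count, self.te_count) < 0:
            raise TEDensityError("counts must be >= 0")
        for lo, hi in (self.gene_length_range, self.te_length_range):
            if lo < 1 or hi < lo:
                raise TEDensityError("length ranges must satisfy 1 <= lo <= hi")
        for p in (
            self.te_te_overlap_prob,
            self.te_gene_overlap_prob,
            self.antisense_fraction,
            self.gene_at_origin_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise TEDensityError("probabilities must lie in [0, 1]")
        if self.gene_count * self.gene_length_range[1] > self.pseudomolecule_length:
            raise TEDensityError(
                "infeasible packing: requested gene footprint exceeds the "
                "pseudomolecule length"
            )


def generate_synthetic_genome(
    params: SyntheticGenomeParams,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, list[GeneRecord]], dict[str, list[TERecord]]]:
    """Draw a synthetic (gene, TE) annotation pair.

    When a TE is drawn as overlapping a previous TE it also inherits that
    TE's identity, so with overlap probability 1 and at least two TEs the
    annotation always contains an overlapping same-superfamily pair for the
    revision step to merge.  With ``out_dir`` set, ``genes.tsv`` and
    ``tes.tsv`` are written in the cleaned-tsv dialect.
    """
    rng = np.random.default_rng(params.seed)
    length = params.pseudomolecule_length
    genes: dict[str, list[GeneRecord]] = {}
    tes: dict[str, list[TERecord]] = {}
    flat_identities = [
        (order, superfamily)
        for order, superfamilies in params.identities.items()
        for superfamily in superfamilies
    ]

    for p in range(params.pseudomolecule_count):
        pseudo = f"Chr{p + 1}"
        gene_records: list[GeneRecord] = []
        for k in range(params.gene_count):
            g_len = int(rng.integers(*params.gene_length_range, endpoint=True))
            if k == 0 and rng.random() < params.gene_at_origin_prob:
                g0 = 0
            else:
                g0 = int(rng.integers(0, length - g_len + 1))
            strand = ANTISENSE if rng.random() < params.antisense_fraction else SENSE
            gene_records.append(
                GeneRecord(
                    pseudomolecule=pseudo,
                    name=f"Gene_{pseudo}_{k}",
                    g0=g0,
                    g1=g0 + g_len - 1,
                    strand=strand,
                )
            )
        gene_records.sort(key=lambda g: g.g0)
        genes[pseudo] = gene_records

        te_records: list[TERecord] = []
        for _ in range(params.te_count):
            t_len = int(rng.integers(*params.te_length_range, endpoint=True))
            roll = rng.random()
            if te_records and roll < params.te_te_overlap_prob:
                # overlap (and share identity with) a previously placed TE
                target = te_records[int(rng.integers(len(te_records)))]
                t0 = int(rng.integers(target.t0, target.t1 + 1))
                order, superfamily = target.order, target.superfamily
            elif (
                gene_records
                and roll < params.te_te_overlap_prob + params.te_gene_overlap_prob
            ):
                target_gene = gene_records[int(rng.integers(len(gene_records)))]
                t0 = int(rng.integers(target_gene.g0, target_gene.g1 + 1))
                order, superfamily = flat_identities[
                    int(rng.integers(len(flat_identities)))
                ]
            else:
                t0 = int(rng.integers(0, length))
                order, superfamily = flat_identities[
                    int(rng.integers(len(flat_identities)))
                ]
            t1 = min(t0 + t_len - 1, length - 1)
            te_records.append(
                TERecord(
                    pseudomolecule=pseudo,
                    t0=t0,
                    t1=t1,
                    order=order,
                    superfamily=superfamily,
                )
            )
        te_records.sort(key=lambda t: t.t0)
        if te_records:
            tes[pseudo] = te_records

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_gene_annotation(genes, out_dir / "genes.tsv")
        write_te_annotation(tes, out_dir / "tes.tsv")
    return genes, tes


_MAX_ORACLE_SPAN = 2_000_000  # explicit masks only make sense for small instances


def oracle_density(
    genes: Sequence[GeneRecord],
    tes: Sequence[TERecord],
    windows: WindowSpec,
    level: str,
    identity_labels: Sequence[str] | None = None,
) -> DensityTensor:
    """Reference densities for one pseudomolecule via explicit occupancy masks.

    For each identity a boolean vector marks every base covered by any
    matching TE (union semantics — shared bases count once, so no revision
    step is needed).  Left density is the occupied count over
    ``[max(g0 − 1 − w, 0), g0 − 1]`` divided by ``w + 1``, right over
    ``[g1 + 1, g1 + 1 + w]``, intra over ``[g0, g1]`` divided by the gene
    length.  The ``Total_TE_Density`` row uses the union of all TEs.
    """
    if level not in ("order", "superfamily"):
        raise TEDensityError(f"unknown grouping level {level!r}")
    if not genes:
        raise TEDensityError("no genes supplied")
    pseudo = genes[0].pseudomolecule
    tes = [t for t in tes if t.pseudomolecule == pseudo]

    max_w = max(windows)
    span = max(
        [g.g1 + max_w + 2 for g in genes] + [t.t1 + 2 for t in tes]
    )
    if span > _MAX_ORACLE_SPAN:
        raise TEDensityError(
            f"instance span {span} too large for explicit masks; "
            "use the main pipeline"
        )

    if identity_labels is None:
        identity_labels = sorted({getattr(t, level) for t in tes}) + [TOTAL_LABEL]
    identity_labels = list(identity_labels)

    masks: dict[str, np.ndarray] = {
        label: np.zeros(span, dtype=bool) for label in identity_labels
    }
    total = masks.get(TOTAL_LABEL, np.zeros(span, dtype=bool))
    for te in tes:
        label = getattr(te, level)
        if label in masks:
            masks[label][te.t0 : te.t1 + 1] = True
        total[te.t0 : te.t1 + 1] = True
    masks[TOTAL_LABEL] = total

    values = np.zeros(
        (len(identity_labels), len(windows), len(genes), 3), dtype=np.float64
    )
    for i, label in enumerate(identity_labels):
        mask = masks[label]
        for k, gene in enumerate(genes):
            intra = mask[gene.g0 : gene.g1 + 1].sum() / gene.length
            for j, w in enumerate(windows):
                left_lo = max(gene.g0 - 1 - w, 0)
                left = mask[left_lo : gene.g0].sum() / (w + 1)
                right = mask[gene.g1 + 1 : gene.g1 + 2 + w].sum() / (w + 1)
                values[i, j, k, 0] = left
                values[i, j, k, 1] = intra
                values[i, j, k, 2] = right
    return DensityTensor(
        level=level,
        pseudomolecule=pseudo,
        identity_labels=identity_labels,
        windows=windows,
        gene_names=[g.name for g in genes],
        gene_strands=[g.strand for g in genes],
        values=values,
    )
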