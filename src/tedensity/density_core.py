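"""Windowed overlap and density computation.

For one gene with inclusive bounds ``[g0, g1]`` and a window length ``w``,
the left window is ``[max(g0 - 1 - w, 0), g0 - 1]`` and the right window is
``[g1 + 1, g1 + 1 + w]`` — each spans ``w + 1`` base pairs (the window
bounds are offset by one from the gene edge), so flank densities are
normalized by ``w + 1``.  Intragenic overlap uses the gene bounds
themselves and is normalized by the gene length ``g1 - g0 + 1``; it does
not depend on the window.  All coordinates are 0-based inclusive.

Left windows are clipped at position 0; right windows are not clipped at
the pseudomolecule end (sequence length is not an input to the model), and
the denominator stays ``w + 1`` either way.

Densities are assembled per pseudomolecule into a 4-D tensor indexed by
(identity, window, gene, direction) with direction fixed as
(left, intra, right).  Overlap sums run over the revised (disjoint)
intervals of one grouping level, so no base pair is counted twice and every
density lies in [0, 1].
"""

from __future__ import annotations

import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from tedensity.annotation_io import GeneRecord, TERecord
from tedensity.errors import AnnotationValidationError, ConsistencyError
from tedensity.revision import TOTAL_LABEL, RevisedTEAnnotation, revise

logger = logging.getLogger(__name__)

DIRECTIONS = ("left", "intra", "right")
LEFT, INTRA, RIGHT = 0, 1, 2


@dataclass(frozen=True)
class WindowSpec:
    """Strictly increasing flank window lengths in base pairs."""

    windows: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "windows", tuple(int(w) for w in self.windows))
        if not self.windows:
            raise AnnotationValidationError("window specification is empty")
        if any(w < 1 for w in self.windows):
            raise AnnotationValidationError("window lengths must be >= 1")
        if any(b <= a for a, b in zip(self.windows, self.windows[1:])):
            raise AnnotationValidationError("windows must be strictly increasing")

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    @classmethod
    def default(cls) -> "WindowSpec":
        """500 bp to 10 kb in 500 bp steps (20 windows)."""
        return cls(tuple(range(500, 10_001, 500)))

    @classmethod
    def from_range(cls, first: int, last: int, step: int) -> "WindowSpec":
        return cls(tuple(range(first, last + 1, step)))


def overlap_left(w: int, g0: int, t0: int, t1: int) -> int:
    """Base pairs of ``[t0, t1]`` inside the left window of a gene at ``g0``.

    The window is ``[max(g0 - 1 - w, 0), g0 - 1]``; a gene at position 0
    has an empty left window and the overlap is 0.
    """
    w1 = g0 - 1
    w0 = max(w1 - w, 0)
    b0 = max(w0, t0)
    b1 = min(w1, t1)
    return max(0, b1 - b0 + 1)


def overlap_intra(g0: int, g1: int, t0: int, t1: int) -> int:
    """Base pairs of ``[t0, t1]`` inside the gene body ``[g0, g1]``."""
    b0 = max(g0, t0)
    b1 = min(g1, t1)
    return max(0, b1 - b0 + 1)


def overlap_right(w: int, g1: int, t0: int, t1: int) -> int:
    """Base pairs of ``[t0, t1]`` inside the right window ``[g1 + 1, g1 + 1 + w]``."""
    w0 = g1 + 1
    w1 = w0 + w
    b0 = max(w0, t0)
    b1 = min(w1, t1)
    return max(0, b1 - b0 + 1)


def density_flank(overlap_sum: int, w: int) -> float:
    """Normalize a flank overlap sum by the window span ``w + 1``.

    The sum must come from a disjoint interval set; exceeding ``w + 1``
    means the input was not revised and is an internal-consistency error.
    """
    if overlap_sum < 0:
        raise ConsistencyError("negative overlap sum")
    if overlap_sum > w + 1:
        raise ConsistencyError(
            f"overlap sum {overlap_sum} exceeds window span {w + 1}: "
            "input intervals overlap (annotation not revised?)"
        )
    return overlap_sum / (w + 1)


def density_intra(overlap_sum: int, g0: int, g1: int) -> float:
    """Normalize an intragenic overlap sum by the gene length."""
    length = g1 - g0 + 1
    if overlap_sum < 0:
        raise ConsistencyError("negative overlap sum")
    if overlap_sum > length:
        raise ConsistencyError(
            f"overlap sum {overlap_sum} exceeds gene length {length}: "
            "input intervals overlap (annotation not revised?)"
        )
    return overlap_sum / length


@dataclass
class DensityTensor:
    """Densities for one pseudomolecule at one grouping level.

    ``values`` has shape (identities, windows, genes, 3) with the direction
    axis fixed as (left, intra, right).  The intra slice is identical
    across the window axis.  ``swapped`` records whether the flank slices
    of antisense genes have been exchanged into upstream/downstream
    orientation (done at read time, never on freshly computed tensors).
    """

    level: str
    pseudomolecule: str
    identity_labels: list[str]
    windows: WindowSpec
    gene_names: list[str]
    gene_strands: list[str]
    values: np.ndarray
    swapped: bool = False

    def __post_init__(self) -> None:
        expected = (
            len(self.identity_labels),
            len(self.windows),
            len(self.gene_names),
            3,
        )
        if self.values.shape != expected:
            raise ConsistencyError(
                f"tensor shape {self.values.shape} != expected {expected}"
            )
        if len(self.gene_strands) != len(self.gene_names):
            raise ConsistencyError("gene strand vector length mismatch")


def _flank_overlap_matrix(
    g_edge: np.ndarray, w: int, starts: np.ndarray, stops: np.ndarray, side: int
) -> np.ndarray:
    """Summed flank overlap for every gene against one label's intervals."""
    if side == LEFT:
        w1 = g_edge - 1
        w0 = np.maximum(w1 - w, 0)
    else:
        w0 = g_edge + 1
        w1 = w0 + w
    b0 = np.maximum(w0[:, None], starts[None, :])
    b1 = np.minimum(w1[:, None], stops[None, :])
    return np.maximum(0, b1 - b0 + 1).sum(axis=1)


def compute_pseudomolecule_density(
    genes: Sequence[GeneRecord],
    revised: RevisedTEAnnotation,
    level: str,
    windows: WindowSpec,
    identity_labels: Sequence[str] | None = None,
) -> DensityTensor:
    """Fill the (identity, window, gene, direction) tensor for one pseudomolecule.

    The identity axis is the level's labels plus ``Total_TE_Density``
    (computed from the total-level merged intervals).  An identity with no
    intervals on this pseudomolecule yields an all-zero slice; a gene whose
    pseudomolecule is absent from the TE data yields all-zero densities
    with a logged warning.
    """
    if level not in ("order", "superfamily"):
        raise AnnotationValidationError(f"unknown grouping level {level!r}")
    if not genes:
        raise AnnotationValidationError("no genes supplied")
    pseudo = genes[0].pseudomolecule
    if any(g.pseudomolecule != pseudo for g in genes):
        raise AnnotationValidationError("genes span multiple pseudomolecules")

    if identity_labels is None:
        identity_labels = revised.all_labels(level) + [TOTAL_LABEL]
    identity_labels = list(identity_labels)

    if pseudo not in revised.intervals:
        logger.warning(
            "pseudomolecule %r has no TEs; densities are all zero", pseudo
        )

    g0 = np.array([g.g0 for g in genes], dtype=np.int64)
    g1 = np.array([g.g1 for g in genes], dtype=np.int64)
    lengths = g1 - g0 + 1

    values = np.zeros(
        (len(identity_labels), len(windows), len(genes), 3), dtype=np.float64
    )
    window_arr = np.fromiter(windows, dtype=np.int64)

    for i, label in enumerate(identity_labels):
        source_level = "total" if label == TOTAL_LABEL else level
        spans = revised.subset(pseudo, source_level, label)
        if not spans:
            continue
        starts = np.array([s for s, _ in spans], dtype=np.int64)
        stops = np.array([e for _, e in spans], dtype=np.int64)

        b0 = np.maximum(g0[:, None], starts[None, :])
        b1 = np.minimum(g1[:, None], stops[None, :])
        intra = np.maximum(0, b1 - b0 + 1).sum(axis=1) / lengths

        for j, w in enumerate(window_arr):
            left = _flank_overlap_matrix(g0, w, starts, stops, LEFT) / (w + 1)
            right = _flank_overlap_matrix(g1, w, starts, stops, RIGHT) / (w + 1)
            values[i, j, :, LEFT] = left
            values[i, j, :, INTRA] = intra
            values[i, j, :, RIGHT] = right

    if values.min() < 0.0 or values.max() > 1.0:
        raise ConsistencyError(
            "density out of [0, 1]; revised intervals must be disjoint"
        )
    return DensityTensor(
        level=level,
        pseudomolecule=pseudo,
        identity_labels=identity_labels,
        windows=windows,
        gene_names=[g.name for g in genes],
        gene_strands=[g.strand for g in genes],
        values=values,
    )


def _process_one(args) -> tuple[str, dict[str, DensityTensor]]:
    pseudo, genes, revised, windows, labels_by_level = args
    return pseudo, {
        level: compute_pseudomolecule_density(
            genes, revised, level, windows, identity_labels=labels
        )
        for level, labels in labels_by_level.items()
    }


def process_genome(
    genes: dict[str, list[GeneRecord]],
    tes: dict[str, list[TERecord]],
    windows: WindowSpec | None = None,
    levels: Sequence[str] = ("order", "superfamily"),
    workers: int = 1,
    revised: RevisedTEAnnotation | None = None,
    output_dir: str | Path | None = None,
    genome_id: str = "genome",
    overwrite: bool = False,
) -> dict[str, dict[str, DensityTensor]]:
    """Compute density tensors for every pseudomolecule of a genome.

    Pseudomolecules are independent and may be computed in parallel; the
    result is bit-identical regardless of ``workers``.  Identity axes are
    shared genome-wide so every pseudomolecule's tensors align.  When
    ``output_dir`` is given, one HDF5 store is written per pseudomolecule.

    The gene and TE annotations must cover the same pseudomolecule set;
    a mismatch is fatal and reports the set difference.
    """
    if windows is None:
        windows = WindowSpec.default()
    gene_pseudos = set(genes)
    te_pseudos = set(tes)
    if gene_pseudos != te_pseudos:
        only_genes = sorted(gene_pseudos - te_pseudos)
        only_tes = sorted(te_pseudos - gene_pseudos)
        raise AnnotationValidationError(
            "pseudomolecule names differ between gene and TE annotations: "
            f"gene-only={only_genes}, TE-only={only_tes}"
        )
    if revised is None:
        revised = revise(tes)

    labels_by_level = {
        level: revised.all_labels(level) + [TOTAL_LABEL] for level in levels
    }
    tasks = [
        (pseudo, genes[pseudo], revised, windows, labels_by_level)
        for pseudo in sorted(genes)
    ]
    if workers <= 1 or len(tasks) <= 1:
        results = dict(map(_process_one, tasks))
    else:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            results = dict(pool.map(_process_one, tasks))

    if output_dir is not None:
        from tedensity.density_store import write_density

        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        for pseudo in sorted(results):
            path = output_dir / f"{genome_id}_{pseudo}.h5"
            if path.exists() and not overwrite:
                raise FileExistsError(f"{path} exists; pass overwrite=True to replace")
            write_density(
                results[pseudo]["order"],
                results[pseudo]["superfamily"],
                path,
                genome_id=genome_id,
            )
    return results
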