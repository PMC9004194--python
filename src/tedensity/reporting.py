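"""Downstream summaries over density stores.

Four report types: a per-gene table of the densest TE groupings
(``info_of_gene``), percentile-cutoff gene lists for e.g. GO-enrichment
candidate selection, binning of genes by density against a companion
scalar such as expression, and signed density differences between syntelog
pairs of two genomes.  All densities come from swap-applied accessors, so
directions are upstream / intragenic / downstream throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from tedensity.density_store import ACCESS_DIRECTIONS, DensityData
from tedensity.errors import LookupKeyError, TEDensityError

logger = logging.getLogger(__name__)

NO_TE = "No TE"
LEVELS = ("order", "superfamily")


@dataclass
class GeneInfoTable:
    """Top-N TE groupings by density for one gene at one window.

    ``sections[level][direction]`` is a list of (identity, density) pairs
    in descending density (ties broken alphabetically), padded with
    ("No TE", 0.0) when fewer than N identities have nonzero density.
    """

    gene: str
    window: int
    top_n: int
    sections: dict[str, dict[str, list[tuple[str, float]]]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for level in LEVELS:
            for direction in ACCESS_DIRECTIONS:
                for rank, (identity, value) in enumerate(
                    self.sections[level][direction], start=1
                ):
                    rows.append((self.gene, self.window, level, direction, rank, identity, value))
        return pd.DataFrame(
            rows,
            columns=["Gene", "Window", "Level", "Direction", "Rank", "Identity", "Density"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def info_of_gene(
    accessor: DensityData, gene: str, window: int, n: int = 5
) -> GeneInfoTable:
    """Rank the densest TE groupings around one gene.

    ``Total_TE_Density`` participates as an ordinary identity, so it ranks
    first whenever any TE is present.  Identities at zero density are not
    listed; their slots are filled with the "No TE" placeholder at 0.
    """
    if gene not in accessor.gene_names:
        raise LookupKeyError(f"unknown gene {gene!r} in store {accessor.path}")
    sections: dict[str, dict[str, list[tuple[str, float]]]] = {}
    for level in LEVELS:
        _, names = accessor._level(level)
        sections[level] = {}
        for direction in ACCESS_DIRECTIONS:
            pairs = [
                (identity, accessor.density_of(gene, level, identity, window, direction))
                for identity in names
            ]
            ranked = sorted(
                ((ident, v) for ident, v in pairs if v > 0),
                key=lambda item: (-item[1], item[0]),
            )[:n]
            ranked += [(NO_TE, 0.0)] * (n - len(ranked))
            sections[level][direction] = ranked
    return GeneInfoTable(gene=gene, window=window, top_n=n, sections=sections)


def percentile_gene_list(
    accessors: Sequence[DensityData],
    level: str,
    identity: str,
    window: int,
    direction: str,
    percentile: float,
) -> tuple[float, pd.DataFrame]:
    """Genes at or above a density percentile, pooled across pseudomolecules.

    The cutoff is the requested percentile of the pooled per-gene density
    vector, with linear interpolation between order statistics.  Returns
    the cutoff and a frame of (Gene, Pseudomolecule, Density) sorted by
    density descending; "within the percentile" is inclusive (ρ ≥ cutoff).
    An all-zero vector yields cutoff 0 and every gene, with a warning.
    """
    if not 0 < percentile < 100:
        raise TEDensityError(f"percentile must be in (0, 100), got {percentile}")
    chunks = []
    for accessor in accessors:
        vector = accessor.gene_vector(level, identity, window, direction)
        chunks.append(
            pd.DataFrame(
                {
                    "Gene": accessor.gene_names,
                    "Pseudomolecule": accessor.pseudomolecule,
                    "Density": vector,
                }
            )
        )
    pooled = pd.concat(chunks, ignore_index=True)
    cutoff = float(np.percentile(pooled["Density"].to_numpy(), percentile))
    if pooled["Density"].max() == 0.0:
        logger.warning(
            "all densities are zero for %s/%s window=%d %s; cutoff is 0 and the "
            "list contains every gene",
            level, identity, window, direction,
        )
    selected = (
        pooled[pooled["Density"] >= cutoff]
        .sort_values(["Density", "Gene"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    return cutoff, selected


def write_gene_list(cutoff: float, genes: pd.DataFrame, path: str | Path) -> None:
    """Persist a percentile gene list as TSV with the cutoff in a header comment."""
    path = Path(path)
    with open(path, "w") as handle:
        handle.write(f"# density_cutoff\t{cutoff:.6g}\n")
        genes.to_csv(handle, sep="\t", index=False)


@dataclass
class DensityBinning:
    """Genes partitioned into fixed-width density bins over [0, 1].

    Every bin is half-open ``[a, b)`` except the last, which is closed at
    1.0 so full-density genes are counted.  ``members[i]`` holds the gene
    indices (into the post-exclusion order) of bin ``i``; ``companion[i]``
    the matching companion scalars (e.g. expression).
    """

    bin_width: float
    edges: np.ndarray
    counts: np.ndarray
    members: list[np.ndarray]
    companion: list[np.ndarray]
    n_excluded: int

    def intervals(self) -> list[str]:
        closers = [")"] * (len(self.counts) - 1) + ["]"]
        return [
            f"[{self.edges[i]:.1f},{self.edges[i + 1]:.1f}{closers[i]}"
            for i in range(len(self.counts))
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"Bin": self.intervals(), "N": self.counts})


def bin_genes_by_density(
    values: Iterable[float],
    companion: Iterable[float] | None = None,
    bin_width: float = 0.1,
    expressed_cutoff: float | None = None,
) -> DensityBinning:
    """Assign genes to density bins, optionally excluding lowly expressed ones.

    When ``expressed_cutoff`` is given, genes whose companion value falls
    below it are removed before binning (the convention used when pairing
    density with TPM expression, cutoff 0.1).  The bin width must divide
    [0, 1] evenly.
    """
    values = np.asarray(list(values), dtype=np.float64)
    if values.size and (values.min() < 0 or values.max() > 1):
        raise TEDensityError("density values must lie in [0, 1]")
    n_bins = round(1.0 / bin_width)
    if abs(n_bins * bin_width - 1.0) > 1e-9 or n_bins < 1:
        raise TEDensityError(
            f"bin width {bin_width} does not partition [0, 1] evenly"
        )
    if companion is not None:
        companion = np.asarray(list(companion), dtype=np.float64)
        if companion.shape != values.shape:
            raise TEDensityError("companion vector length mismatch")
    if expressed_cutoff is not None:
        if companion is None:
            raise TEDensityError("expressed_cutoff requires a companion vector")
        keep = companion >= expressed_cutoff
        n_excluded = int((~keep).sum())
        values, companion = values[keep], companion[keep]
    else:
        n_excluded = 0

    # arange/n gives the correctly rounded double for each decimal edge, so a
    # literal like 0.3 compares equal to its bin boundary; linspace does not
    edges = np.arange(n_bins + 1) / n_bins
    # digitize gives [a, b) bins; fold the v == 1.0 boundary into the last bin
    assignment = np.clip(np.digitize(values, edges, right=False) - 1, 0, n_bins - 1)
    members = [np.flatnonzero(assignment == i) for i in range(n_bins)]
    companion_per_bin = [
        companion[idx] if companion is not None else np.empty(0) for idx in members
    ]
    return DensityBinning(
        bin_width=bin_width,
        edges=edges,
        counts=np.array([idx.size for idx in members]),
        members=members,
        companion=companion_per_bin,
        n_excluded=n_excluded,
    )


@dataclass(frozen=True)
class SyntelogPair:
    """A syntenic gene pair between genome A and genome B."""

    gene_a: str
    gene_b: str
    e_value: float = 0.0


def load_syntelog_pairs(
    path: str | Path, e_value_cutoff: float = 0.05
) -> list[SyntelogPair]:
    """Read a TSV of (GeneA, GeneB, E_value), dropping pairs above the cutoff."""
    frame = pd.read_csv(path, sep="\t")
    required = ["GeneA", "GeneB", "E_value"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise TEDensityError(f"{path}: missing column(s) {', '.join(missing)}")
    return [
        SyntelogPair(str(row.GeneA), str(row.GeneB), float(row.E_value))
        for row in frame.itertuples()
        if float(row.E_value) <= e_value_cutoff
    ]


@dataclass
class SyntelogDifferences:
    """Signed per-pair density differences, genome A minus genome B."""

    differences: pd.DataFrame  # columns GeneA, GeneB, DensityA, DensityB, Difference
    n_zero: int
    n_nonzero: int
    n_skipped: int

    def write_tsv(self, path: str | Path) -> None:
        self.differences.to_csv(path, sep="\t", index=False)


def _gene_lookup(accessors: Sequence[DensityData]) -> dict[str, DensityData]:
    lookup: dict[str, DensityData] = {}
    for accessor in accessors:
        for name in accessor.gene_names:
            lookup[name] = accessor
    return lookup


def syntelog_density_difference(
    pairs: Sequence[SyntelogPair],
    accessors_a: Sequence[DensityData],
    accessors_b: Sequence[DensityData],
    level: str,
    identity: str,
    window: int,
    direction: str,
) -> SyntelogDifferences:
    """Per-pair signed differences ρ_A − ρ_B for one (identity, window, direction).

    Differences lie in [−1, 1]; a value of ±1 is complete presence/absence
    variation.  Pairs whose gene names cannot be resolved in their genome's
    stores are skipped with a warning and tallied.  Pairs with exactly zero
    difference are counted separately from the nonzero set.
    """
    lookup_a = _gene_lookup(accessors_a)
    lookup_b = _gene_lookup(accessors_b)
    rows = []
    n_skipped = 0
    for pair in pairs:
        acc_a = lookup_a.get(pair.gene_a)
        acc_b = lookup_b.get(pair.gene_b)
        if acc_a is None or acc_b is None:
            missing = pair.gene_a if acc_a is None else pair.gene_b
            logger.warning("syntelog pair skipped: gene %r not found", missing)
            n_skipped += 1
            continue
        rho_a = acc_a.density_of(pair.gene_a, level, identity, window, direction)
        rho_b = acc_b.density_of(pair.gene_b, level, identity, window, direction)
        rows.append((pair.gene_a, pair.gene_b, rho_a, rho_b, rho_a - rho_b))
    frame = pd.DataFrame(
        rows, columns=["GeneA", "GeneB", "DensityA", "DensityB", "Difference"]
    )
    n_zero = int((frame["Difference"] == 0.0).sum()) if len(frame) else 0
    return SyntelogDifferences(
        differences=frame,
        n_zero=n_zero,
        n_nonzero=len(frame) - n_zero,
        n_skipped=n_skipped,
    )
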