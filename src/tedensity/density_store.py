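"""Persist density tensors per pseudomolecule in HDF5, and reload them
through an accessor that reorients flank values to upstream/downstream.

On disk every store holds the raw left/intra/right orientation.  Gene
annotations list start < stop regardless of strand, so for an antisense
gene "left of the start" is biologically downstream.  The accessor swaps
the left and right slices of antisense genes once, at initialization, so
callers always query in upstream/intragenic/downstream terms; the file
itself is never mutated, and the SWAPPED attribute guards a swapped view
from being re-persisted and double-swapped.

Layout of ``{genome}_{pseudomolecule}.h5``:

* datasets ``ORDER_DENSITY`` and ``SUPERFAMILY_DENSITY``, 4-D float64 with
  axes identity × window × gene × direction (direction length 3, fixed
  order left, intra, right);
* label vectors ``ORDER_NAMES``, ``SUPERFAMILY_NAMES``, ``WINDOWS``,
  ``GENE_NAMES``, ``GENE_STRANDS`` (UTF-8);
* root attributes ``GENOME_ID``, ``PSEUDOMOLECULE``, ``SWAPPED``.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from tedensity.annotation_io import ANTISENSE
from tedensity.density_core import INTRA, LEFT, RIGHT, DensityTensor
from tedensity.errors import LookupKeyError, StoreError

_STR = h5py.string_dtype(encoding="utf-8")

#: accessor-facing direction names, mapped onto the stored axis after the swap
ACCESS_DIRECTIONS = ("upstream", "intragenic", "downstream")
_ACCESS_INDEX = {"upstream": LEFT, "intragenic": INTRA, "downstream": RIGHT}


def _validate_pair(order: DensityTensor, superfamily: DensityTensor) -> None:
    if order.gene_names != superfamily.gene_names:
        raise StoreError("order and superfamily tensors disagree on gene names")
    if order.gene_strands != superfamily.gene_strands:
        raise StoreError("order and superfamily tensors disagree on gene strands")
    if order.windows.windows != superfamily.windows.windows:
        raise StoreError("order and superfamily tensors disagree on windows")
    if order.pseudomolecule != superfamily.pseudomolecule:
        raise StoreError("order and superfamily tensors disagree on pseudomolecule")
    for tensor in (order, superfamily):
        if tensor.swapped:
            raise StoreError("refusing to persist a swapped (upstream/downstream) view")


def write_density(
    order: DensityTensor,
    superfamily: DensityTensor,
    path: str | Path,
    genome_id: str = "genome",
) -> Path:
    """Write one pseudomolecule's order + superfamily tensors to ``path``.

    Validation runs before any write, so a failed call leaves no file.
    """
    _validate_pair(order, superfamily)
    path = Path(path)
    with h5py.File(path, "w") as handle:
        handle.create_dataset("ORDER_DENSITY", data=order.values, dtype=np.float64, track_times=False)
        handle.create_dataset(
            "SUPERFAMILY_DENSITY", data=superfamily.values, dtype=np.float64,
            track_times=False,
        )
        handle.create_dataset("ORDER_NAMES", data=order.identity_labels, dtype=_STR, track_times=False)
        handle.create_dataset(
            "SUPERFAMILY_NAMES", data=superfamily.identity_labels, dtype=_STR,
            track_times=False,
        )
        handle.create_dataset(
            "WINDOWS", data=np.fromiter(order.windows, dtype=np.int64),
            track_times=False,
        )
        handle.create_dataset("GENE_NAMES", data=order.gene_names, dtype=_STR, track_times=False)
        handle.create_dataset("GENE_STRANDS", data=order.gene_strands, dtype=_STR, track_times=False)
        handle.attrs["GENOME_ID"] = genome_id
        handle.attrs["PSEUDOMOLECULE"] = order.pseudomolecule
        handle.attrs["SWAPPED"] = False
    return path


def _read_dataset(handle: h5py.File, name: str):
    if name not in handle:
        raise StoreError(f"{handle.filename}: missing dataset {name!r}")
    return handle[name][...]


class DensityData:
    """In-memory view of one pseudomolecule's density store.

    On construction the left/right slices of antisense genes are swapped so
    that the first and last direction always mean upstream and downstream;
    intra slices are untouched.  ``swapped`` is therefore True on every
    live accessor while the file on disk keeps ``SWAPPED=False``.
    """

    def __init__(self, path: str | Path):
        path = Path(path)
        if not path.exists():
            raise StoreError(f"density store not found: {path}")
        with h5py.File(path, "r") as handle:
            self.order_values = _read_dataset(handle, "ORDER_DENSITY").astype(np.float64)
            self.superfamily_values = _read_dataset(
                handle, "SUPERFAMILY_DENSITY"
            ).astype(np.float64)
            self.order_names = [
                s.decode() for s in _read_dataset(handle, "ORDER_NAMES")
            ]
            self.superfamily_names = [
                s.decode() for s in _read_dataset(handle, "SUPERFAMILY_NAMES")
            ]
            self.windows = [int(w) for w in _read_dataset(handle, "WINDOWS")]
            self.gene_names = [s.decode() for s in _read_dataset(handle, "GENE_NAMES")]
            self.gene_strands = [
                s.decode() for s in _read_dataset(handle, "GENE_STRANDS")
            ]
            self.genome_id = str(handle.attrs.get("GENOME_ID", ""))
            self.pseudomolecule = str(handle.attrs.get("PSEUDOMOLECULE", ""))
            stored_swapped = bool(handle.attrs.get("SWAPPED", False))
        self.path = path
        self._gene_index = {name: i for i, name in enumerate(self.gene_names)}
        self._window_index = {w: i for i, w in enumerate(self.windows)}
        self.swapped = stored_swapped
        if not self.swapped:
            self.swap_antisense()

    def swap_antisense(self) -> None:
        """Exchange left and right flank slices of antisense genes (involution)."""
        mask = np.array(
            [strand == ANTISENSE for strand in self.gene_strands], dtype=bool
        )
        for values in (self.order_values, self.superfamily_values):
            flanks = values[:, :, mask][:, :, :, [RIGHT, LEFT]]
            values[:, :, mask, LEFT] = flanks[:, :, :, 0]
            values[:, :, mask, RIGHT] = flanks[:, :, :, 1]
        self.swapped = not self.swapped

    def _level(self, level: str):
        if level == "order":
            return self.order_values, self.order_names
        if level == "superfamily":
            return self.superfamily_values, self.superfamily_names
        raise LookupKeyError(f"unknown level {level!r}; expected 'order' or 'superfamily'")

    def density_of(
        self, gene: str, level: str, identity: str, window: int, direction: str
    ) -> float:
        """Return one density value in upstream/intragenic/downstream terms."""
        values, names = self._level(level)
        if gene not in self._gene_index:
            raise LookupKeyError(
                f"unknown gene {gene!r}; known genes include "
                f"{self.gene_names[:5]}..."
            )
        if identity not in names:
            raise LookupKeyError(f"unknown identity {identity!r}; valid: {names}")
        if window not in self._window_index:
            raise LookupKeyError(f"unknown window {window}; valid: {self.windows}")
        if direction not in _ACCESS_INDEX:
            raise LookupKeyError(
                f"unknown direction {direction!r}; valid: {ACCESS_DIRECTIONS}"
            )
        return float(
            values[
                names.index(identity),
                self._window_index[window],
                self._gene_index[gene],
                _ACCESS_INDEX[direction],
            ]
        )

    def gene_vector(
        self, level: str, identity: str, window: int, direction: str
    ) -> np.ndarray:
        """Densities of every gene for one (identity, window, direction)."""
        values, names = self._level(level)
        if identity not in names:
            raise LookupKeyError(f"unknown identity {identity!r}; valid: {names}")
        if window not in self._window_index:
            raise LookupKeyError(f"unknown window {window}; valid: {self.windows}")
        if direction not in _ACCESS_INDEX:
            raise LookupKeyError(
                f"unknown direction {direction!r}; valid: {ACCESS_DIRECTIONS}"
            )
        return values[
            names.index(identity), self._window_index[window], :, _ACCESS_INDEX[direction]
        ].copy()


def read_density(path: str | Path) -> DensityData:
    """Open a store and return the swap-applied accessor."""
    return DensityData(path)
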