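"""Merge overlapping same-grouping TEs into disjoint intervals.

TE annotations frequently contain overlapping elements — nested insertions
or annotation-software artifacts.  Because density is a proportion of
occupied base pairs, overlap would double-count bases and push densities
past 1.  Revision therefore merges, per pseudomolecule, (1) TEs sharing an
order, (2) TEs sharing a superfamily, and (3) all TEs together into the
synthetic ``Total_TE_Density`` grouping.  Each level's intervals are then
pairwise disjoint while covering exactly the same base pairs as the input.

Touching-but-not-overlapping intervals (stop + 1 == next start) are kept
separate: the per-base union, and hence every density, is identical either
way, and not merging keeps merging equal to plain interval union.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from tedensity.annotation_io import TERecord
from tedensity.errors import AnnotationFormatError, AnnotationValidationError

TOTAL_LABEL = "Total_TE_Density"
LEVELS = ("order", "superfamily", "total")

#: interval sets keyed pseudomolecule -> level -> label -> [(t0, t1), ...]
IntervalSets = dict[str, dict[str, dict[str, list[tuple[int, int]]]]]


def merge_label_subset(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping intervals of one (pseudomolecule, level, label) subset.

    Sort by start, then sweep once: an interval starting at or before the
    current stop extends the current run.  The output is sorted, pairwise
    disjoint, and covers exactly the union of the input base pairs.
    """
    for t0, t1 in intervals:
        if t0 > t1 or t0 < 0:
            raise AnnotationValidationError(f"invalid interval ({t0}, {t1})")
    if not intervals:
        return []
    merged: list[tuple[int, int]] = []
    run_start, run_stop = None, None
    for t0, t1 in sorted(intervals):
        if run_start is None:
            run_start, run_stop = t0, t1
        elif t0 <= run_stop:  # strict overlap only; adjacency stays split
            run_stop = max(run_stop, t1)
        else:
            merged.append((run_start, run_stop))
            run_start, run_stop = t0, t1
    merged.append((run_start, run_stop))
    return merged


@dataclass
class RevisedTEAnnotation:
    """Disjoint interval sets per pseudomolecule at all three grouping levels."""

    intervals: IntervalSets = field(default_factory=dict)

    def pseudomolecules(self) -> list[str]:
        return sorted(self.intervals)

    def labels(self, pseudomolecule: str, level: str) -> list[str]:
        return sorted(self.intervals.get(pseudomolecule, {}).get(level, {}))

    def subset(
        self, pseudomolecule: str, level: str, label: str
    ) -> list[tuple[int, int]]:
        return self.intervals.get(pseudomolecule, {}).get(level, {}).get(label, [])

    def all_labels(self, level: str) -> list[str]:
        """Sorted union of labels at one level across every pseudomolecule."""
        labels: set[str] = set()
        for per_level in self.intervals.values():
            labels.update(per_level.get(level, {}))
        return sorted(labels)


def revise(tes: dict[str, list[TERecord]]) -> RevisedTEAnnotation:
    """Run the three independent merge passes over a parsed TE annotation.

    Pass 1 merges within each order, pass 2 within each superfamily, and
    pass 3 merges everything into ``Total_TE_Density``.  Any one input TE
    thus contributes to at most one merged interval per level.
    """
    if not tes or not any(tes.values()):
        raise AnnotationValidationError("cannot revise an empty TE annotation")
    revised: IntervalSets = {}
    for pseudo, group in tes.items():
        by_order: dict[str, list[tuple[int, int]]] = {}
        by_superfam: dict[str, list[tuple[int, int]]] = {}
        everything: list[tuple[int, int]] = []
        for te in group:
            span = (te.t0, te.t1)
            by_order.setdefault(te.order, []).append(span)
            by_superfam.setdefault(te.superfamily, []).append(span)
            everything.append(span)
        revised[pseudo] = {
            "order": {lab: merge_label_subset(iv) for lab, iv in by_order.items()},
            "superfamily": {
                lab: merge_label_subset(iv) for lab, iv in by_superfam.items()
            },
            "total": {TOTAL_LABEL: merge_label_subset(everything)},
        }
    return RevisedTEAnnotation(intervals=revised)


# --- persistence -----------------------------------------------------------
#
# The revised annotation only depends on the TE annotation, so it is cached
# to disk as cleaned-tsv with a Revision_Level column and re-used across
# runs with different windows.  A digest of the source file guards against
# stale caches.

_REVISED_COLUMNS = ["Chromosome", "Start", "Stop", "Label", "Revision_Level"]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_revised_annotation(
    revised: RevisedTEAnnotation, path: str | Path, source: str | Path | None = None
) -> None:
    """Persist as cleaned-tsv (1-based inclusive coordinates on disk).

    When ``source`` is given, a sidecar ``<path>.digest`` records the SHA-256
    of the input annotation for staleness checks.
    """
    path = Path(path)
    rows = [
        (pseudo, t0 + 1, t1 + 1, label, level)
        for pseudo, per_level in sorted(revised.intervals.items())
        for level in LEVELS
        for label, spans in sorted(per_level.get(level, {}).items())
        for t0, t1 in spans
    ]
    pd.DataFrame(rows, columns=_REVISED_COLUMNS).to_csv(path, sep="\t", index=False)
    if source is not None:
        path.with_suffix(path.suffix + ".digest").write_text(_digest(Path(source)) + "\n")


def read_revised_annotation(
    path: str | Path, source: str | Path | None = None
) -> RevisedTEAnnotation:
    """Reload a cached revised annotation, verifying freshness if possible."""
    path = Path(path)
    if not path.exists():
        raise AnnotationFormatError(f"revised annotation not found: {path}")
    if source is not None:
        sidecar = path.with_suffix(path.suffix + ".digest")
        if sidecar.exists() and sidecar.read_text().strip() != _digest(Path(source)):
            raise AnnotationFormatError(
                f"{path}: stale cache, source annotation has changed"
            )
    frame = pd.read_csv(path, sep="\t", dtype={"Chromosome": str})
    missing = [c for c in _REVISED_COLUMNS if c not in frame.columns]
    if missing:
        raise AnnotationFormatError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    intervals: IntervalSets = {}
    for row in frame.itertuples():
        per_level = intervals.setdefault(str(row.Chromosome), {})
        per_label = per_level.setdefault(row.Revision_Level, {})
        per_label.setdefault(row.Label, []).append((int(row.Start) - 1, int(row.Stop) - 1))
    return RevisedTEAnnotation(intervals=intervals)
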