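"""Parse, validate, and reclassify gene and TE annotations.

Coordinates are held internally as 0-based, inclusive on both ends, so a
feature's length is ``stop - start + 1``.  Both supported dialects store
1-based inclusive coordinates on disk (GFF3 by definition; the cleaned-tsv
format by convention), so parsing subtracts 1 from start and stop.

The cleaned-tsv dialect is a tab-separated file with a header row:

* genes: ``Chromosome  Gene_Name  Start  Stop  Strand  Length``
* TEs:   ``Chromosome  Start  Stop  Strand  Order  SuperFamily  Length``

TE classification strings of the RepeatMasker style ``ORDER/SUPERFAMILY``
(e.g. ``LTR/Copia``) are split on the first slash; a bare label is taken as
an order with unknown superfamily.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from tedensity.errors import AnnotationFormatError, AnnotationValidationError

logger = logging.getLogger(__name__)

SENSE = "sense"
ANTISENSE = "antisense"

#: Sentinel labels for TEs whose classification could not be determined.
UNKNOWN_ORDER = "Unknown_Order"
UNKNOWN_SUPERFAMILY = "Unknown_Superfam"

GENE_COLUMNS = ["Chromosome", "Gene_Name", "Start", "Stop", "Strand", "Length"]
TE_COLUMNS = ["Chromosome", "Start", "Stop", "Strand", "Order", "SuperFamily", "Length"]

_STRAND_SYMBOLS = {"+": SENSE, "-": ANTISENSE}


@dataclass(frozen=True, slots=True)
class GeneRecord:
    """One gene as a single inclusive interval on a pseudomolecule.

    ``g0``/``g1`` are 0-based inclusive start/stop; the gene body spans the
    first-exon start to the last-exon stop, so "intragenic" means anywhere
    inside that interval, intron or exon.
    """

    pseudomolecule: str
    name: str
    g0: int
    g1: int
    strand: str

    def __post_init__(self) -> None:
        if self.g0 < 0 or self.g0 > self.g1:
            raise AnnotationValidationError(
                f"gene {self.name!r}: invalid coordinates ({self.g0}, {self.g1})"
            )
        if self.strand not in (SENSE, ANTISENSE):
            raise AnnotationValidationError(
                f"gene {self.name!r}: strand must be {SENSE!r} or {ANTISENSE!r}"
            )

    @property
    def length(self) -> int:
        return self.g1 - self.g0 + 1


@dataclass(frozen=True, slots=True)
class TERecord:
    """One transposable element: inclusive interval plus its grouping labels."""

    pseudomolecule: str
    t0: int
    t1: int
    order: str
    superfamily: str

    def __post_init__(self) -> None:
        if self.t0 < 0 or self.t0 > self.t1:
            raise AnnotationValidationError(
                f"TE on {self.pseudomolecule!r}: invalid coordinates "
                f"({self.t0}, {self.t1})"
            )
        if not self.order or not self.superfamily:
            raise AnnotationValidationError(
                "TE order/superfamily labels must be non-empty "
                "(use the sentinel labels for unknowns)"
            )

    @property
    def length(self) -> int:
        return self.t1 - self.t0 + 1


@dataclass(frozen=True)
class IdentityMap:
    """Rename and drop rules applied to one grouping level.

    ``level`` is ``"order"`` or ``"superfamily"``; ``rename`` maps old
    labels to new ones; labels in ``drop`` have their records removed.
    """

    level: str
    rename: Mapping[str, str] = field(default_factory=dict)
    drop: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.level not in ("order", "superfamily"):
            raise AnnotationValidationError(
                f"identity-map level must be 'order' or 'superfamily', got {self.level!r}"
            )
        if any(not to for to in self.rename.values()):
            raise AnnotationValidationError("rename rules may not target the empty label")
        bad = set(self.drop) & set(self.rename.values())
        if bad:
            raise AnnotationValidationError(
                f"drop-list overlaps rename targets: {sorted(bad)}"
            )
        object.__setattr__(self, "drop", frozenset(self.drop))


def _parse_strand(symbol: str, context: str) -> str:
    symbol = str(symbol).strip()
    if symbol in _STRAND_SYMBOLS:
        return _STRAND_SYMBOLS[symbol]
    if symbol in (".", "", "nan"):
        logger.warning("%s: unstranded feature treated as sense", context)
        return SENSE
    raise AnnotationValidationError(f"{context}: unknown strand symbol {symbol!r}")


def split_classification(label: str) -> tuple[str, str]:
    """Split ``ORDER/SUPERFAMILY`` on the first slash.

    A bare label is an order with unknown superfamily; an empty or missing
    label maps to both sentinels.
    """
    label = str(label).strip()
    if not label or label.lower() in ("nan", "none", "."):
        return UNKNOWN_ORDER, UNKNOWN_SUPERFAMILY
    order, sep, superfamily = label.partition("/")
    order = order.strip() or UNKNOWN_ORDER
    superfamily = superfamily.strip() if sep else ""
    return order, superfamily or UNKNOWN_SUPERFAMILY


def _read_tsv(path: Path, required: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise AnnotationFormatError(f"annotation file not found: {path}")
    frame = pd.read_csv(path, sep="\t", dtype={"Chromosome": str})
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise AnnotationFormatError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    return frame


def _gff3_records(path: Path) -> Iterable[tuple[int, str, str, int, int, str, dict]]:
    """Yield (line_no, seqid, type, start, stop, strand, attrs) via gffutils."""
    if not path.exists():
        raise AnnotationFormatError(f"annotation file not found: {path}")
    import gffutils.iterators

    try:
        for line_no, feature in enumerate(
            gffutils.iterators.DataIterator(str(path)), start=1
        ):
            attrs = {key: values[0] for key, values in feature.attributes.items() if values}
            yield (
                line_no,
                feature.seqid,
                feature.featuretype,
                int(feature.start),
                int(feature.end),
                feature.strand,
                attrs,
            )
    except (ValueError, TypeError) as exc:
        raise AnnotationFormatError(f"{path}: malformed GFF3 ({exc})") from exc


def _group_and_sort(records, start_of):
    grouped: dict[str, list] = {}
    for record in records:
        grouped.setdefault(record.pseudomolecule, []).append(record)
    return {
        pseudo: sorted(recs, key=start_of)
        for pseudo, recs in sorted(grouped.items())
    }


def parse_gene_annotation(
    path: str | Path, dialect: str = "cleaned-tsv"
) -> dict[str, list[GeneRecord]]:
    """Parse a gene annotation into records grouped by pseudomolecule.

    Groups are keyed by pseudomolecule name (sorted); within each group the
    records are sorted by start coordinate.  GFF3 input keeps only ``gene``
    feature lines (the mRNA/exon sub-features are redundant with the
    single-interval gene model).  Duplicate gene names are rejected.
    """
    path = Path(path)
    records: list[GeneRecord] = []
    if dialect == "cleaned-tsv":
        frame = _read_tsv(path, ["Chromosome", "Gene_Name", "Start", "Stop", "Strand"])
        for row in frame.itertuples(index=True):
            line = row.Index + 2  # header + 1-based
            start, stop = int(row.Start), int(row.Stop)
            if start > stop:
                raise AnnotationValidationError(
                    f"{path}:{line}: gene {row.Gene_Name!r} has start > stop"
                )
            records.append(
                GeneRecord(
                    pseudomolecule=str(row.Chromosome),
                    name=str(row.Gene_Name),
                    g0=start - 1,
                    g1=stop - 1,
                    strand=_parse_strand(row.Strand, f"{path}:{line}"),
                )
            )
    elif dialect == "gff3":
        for line_no, seqid, ftype, start, stop, strand, attrs in _gff3_records(path):
            if ftype != "gene":
                continue
            name = attrs.get("ID") or attrs.get("Name")
            if not name:
                raise AnnotationFormatError(
                    f"{path}:{line_no}: gene line lacks ID/Name attribute"
                )
            if start > stop:
                raise AnnotationValidationError(
                    f"{path}:{line_no}: gene {name!r} has start > stop"
                )
            records.append(
                GeneRecord(
                    pseudomolecule=seqid,
                    name=name,
                    g0=start - 1,
                    g1=stop - 1,
                    strand=_parse_strand(strand, f"{path}:{line_no}"),
                )
            )
    else:
        raise AnnotationFormatError(f"unknown dialect {dialect!r}")

    seen: dict[str, int] = {}
    duplicates = set()
    for record in records:
        seen[record.name] = seen.get(record.name, 0) + 1
        if seen[record.name] > 1:
            duplicates.add(record.name)
    if duplicates:
        raise AnnotationValidationError(
            f"{path}: duplicate gene name(s): {', '.join(sorted(duplicates))}"
        )
    return _group_and_sort(records, lambda r: r.g0)


def parse_te_annotation(
    path: str | Path, dialect: str = "cleaned-tsv"
) -> dict[str, list[TERecord]]:
    """Parse a TE annotation into records grouped by pseudomolecule.

    For GFF3 input the classification is read from a ``Classification``
    attribute if present, else from the feature-type column.  Labels are
    whitespace-stripped; undetermined classifications get the sentinel
    labels.  An empty annotation is an error (there is nothing to compute).
    """
    path = Path(path)
    records: list[TERecord] = []
    if dialect == "cleaned-tsv":
        frame = _read_tsv(path, ["Chromosome", "Start", "Stop", "Order", "SuperFamily"])
        for row in frame.itertuples(index=True):
            line = row.Index + 2
            start, stop = int(row.Start), int(row.Stop)
            if start > stop:
                raise AnnotationValidationError(
                    f"{path}:{line}: TE has start > stop"
                )
            order = str(row.Order).strip()
            superfamily = str(row.SuperFamily).strip()
            if not order or order.lower() == "nan":
                order = UNKNOWN_ORDER
            if not superfamily or superfamily.lower() == "nan":
                superfamily = UNKNOWN_SUPERFAMILY
            records.append(
                TERecord(
                    pseudomolecule=str(row.Chromosome),
                    t0=start - 1,
                    t1=stop - 1,
                    order=order,
                    superfamily=superfamily,
                )
            )
    elif dialect == "gff3":
        for line_no, seqid, ftype, start, stop, _strand, attrs in _gff3_records(path):
            if start > stop:
                raise AnnotationValidationError(f"{path}:{line_no}: TE has start > stop")
            classification = attrs.get("Classification", ftype)
            order, superfamily = split_classification(classification)
            records.append(
                TERecord(
                    pseudomolecule=seqid,
                    t0=start - 1,
                    t1=stop - 1,
                    order=order,
                    superfamily=superfamily,
                )
            )
    else:
        raise AnnotationFormatError(f"unknown dialect {dialect!r}")

    if not records:
        raise AnnotationFormatError(f"{path}: TE annotation is empty, nothing to compute")
    return _group_and_sort(records, lambda r: r.t0)


def reclassify_identities(
    tes: dict[str, list[TERecord]], identity_map: IdentityMap
) -> dict[str, list[TERecord]]:
    """Apply rename and drop rules at one grouping level.

    Renamed labels are replaced everywhere; records whose label is on the
    drop-list are removed; everything else passes through unchanged.  Rules
    referencing labels absent from the data produce a warning, not an error.
    """
    attr = identity_map.level
    present = {getattr(te, attr) for group in tes.values() for te in group}
    for label in set(identity_map.rename) | set(identity_map.drop):
        if label not in present:
            logger.warning(
                "identity map rule for %s label %r matches no record", attr, label
            )

    out: dict[str, list[TERecord]] = {}
    for pseudo, group in tes.items():
        kept = []
        for te in group:
            label = getattr(te, attr)
            if label in identity_map.drop:
                continue
            new_label = identity_map.rename.get(label, label)
            kept.append(te if new_label == label else replace(te, **{attr: new_label}))
        if kept:
            out[pseudo] = kept
    return out


def load_identity_map(path: str | Path) -> list[IdentityMap]:
    """Load identity maps from YAML or TSV.

    YAML: a mapping or list of mappings with keys ``level``, ``rename``
    (old → new), and ``drop`` (list).  TSV: header ``Level  Action  From  To``
    with Action ∈ {rename, drop} (To empty for drop rows).
    """
    path = Path(path)
    if not path.exists():
        raise AnnotationFormatError(f"identity-map file not found: {path}")
    if path.suffix.lower() in (".yml", ".yaml"):
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        entries = raw if isinstance(raw, list) else [raw]
        return [
            IdentityMap(
                level=entry["level"],
                rename=dict(entry.get("rename") or {}),
                drop=frozenset(entry.get("drop") or ()),
            )
            for entry in entries
        ]
    frame = _read_tsv(path, ["Level", "Action", "From"])
    maps: dict[str, dict] = {}
    for row in frame.itertuples():
        bucket = maps.setdefault(row.Level, {"rename": {}, "drop": set()})
        if row.Action == "rename":
            bucket["rename"][row.From] = str(row.To)
        elif row.Action == "drop":
            bucket["drop"].add(row.From)
        else:
            raise AnnotationFormatError(f"{path}: unknown action {row.Action!r}")
    return [
        IdentityMap(level=level, rename=spec["rename"], drop=frozenset(spec["drop"]))
        for level, spec in maps.items()
    ]


def write_gene_annotation(genes: dict[str, list[GeneRecord]], path: str | Path) -> None:
    """Write genes back to cleaned-tsv (1-based inclusive on disk)."""
    rows = [
        (g.pseudomolecule, g.name, g.g0 + 1, g.g1 + 1,
         "+" if g.strand == SENSE else "-", g.length)
        for group in genes.values()
        for g in group
    ]
    pd.DataFrame(rows, columns=GENE_COLUMNS).to_csv(path, sep="\t", index=False)


def write_te_annotation(tes: dict[str, list[TERecord]], path: str | Path) -> None:
    """Write TEs back to cleaned-tsv (1-based inclusive on disk)."""
    rows = [
        (t.pseudomolecule, t.t0 + 1, t.t1 + 1, "+", t.order, t.superfamily, t.length)
        for group in tes.values()
        for t in group
    ]
    pd.DataFrame(rows, columns=TE_COLUMNS).to_csv(path, sep="\t", index=False)
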