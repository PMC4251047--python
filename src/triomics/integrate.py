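"""Set-based association of modality datasets onto gene identities.

The central product is the integrated per-gene grid: a full outer join
of up to three modalities (WES variants, Cuffdiff RNA-seq at gene or
isoform level, microarray probes) keyed by resolved gene identity.  The
column layout is fixed regardless of which studies are loaded — the
first three columns are always Entrez ID, Gene Symbol, Gene Name and
the last is Member List, with the WES (green), RNA-seq (light red) and
microarray (blue) blocks in between.  Block colors travel as metadata;
this library renders nothing.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .idmap import GeneIdentity, IdGraph, Namespace, resolve_row_identity
from .ingest import (
    ExpressionDiffRecord,
    IsoformRecord,
    ProbeMeasurement,
    VariantRecord,
    average_probe_values,
)

MODALITIES = ("wes", "rnaseq_gene", "rnaseq_isoform", "microarray")

#: Slot occupied by each modality; gene- and isoform-level RNA-seq share one.
_SLOT = {
    "wes": "wes",
    "rnaseq_gene": "rnaseq",
    "rnaseq_isoform": "rnaseq",
    "microarray": "microarray",
}

BLOCK_COLORS = {
    "core": "grey",
    "wes": "green",
    "rnaseq": "light red",
    "microarray": "blue",
    "member": "grey",
}

CORE_COLUMNS = ["Entrez ID", "Gene Symbol", "Gene Name"]
MEMBER_COLUMN = "Member List"

_MINIMAL_BLOCK_COLUMNS = {
    "wes": ["Effect", "Codon Change", "AA Change", "Tumor DP", "Tumor AF"],
    "rnaseq_gene": ["Sample 1 FPKM", "Sample 2 FPKM", "p-value"],
    "rnaseq_isoform": ["Transcript Id", "Sample 1 FPKM", "Sample 2 FPKM", "P-Value"],
    "microarray": ["Affy Probes", "Avg Probe Values"],
}

_MAXIMAL_EXTRA_COLUMNS = {
    "wes": ["Chrom", "Pos", "Ref", "Alt", "Normal DP", "Normal AF"],
    "rnaseq_gene": ["Log2 Fold Change", "q-value", "Significant"],
    "rnaseq_isoform": ["Significant", "Novel"],
    "microarray": ["Probe Values"],
}


@dataclass(frozen=True)
class GeneGroup:
    """A user-defined named gene set; members may use any namespace."""

    name: str
    owner: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("gene group must have at least one member")


@dataclass
class ModalityDataset:
    """Parsed records of one study keyed by resolved gene identity.

    Records whose identity could not be resolved through the graph are
    kept (stub-keyed) in the unresolved bucket — never dropped.
    """

    modality: str
    study_date: _dt.date | None = None
    records: dict[str, list] = field(default_factory=dict)
    identities: dict[str, GeneIdentity] = field(default_factory=dict)
    unresolved: dict[str, list] = field(default_factory=dict)

    @property
    def record_count(self) -> int:
        return sum(len(v) for v in self.records.values()) + sum(
            len(v) for v in self.unresolved.values()
        )


def _record_identity_hints(record):
    """(gene_id, symbol, locus) hints carried by a record for resolution."""
    if isinstance(record, VariantRecord):
        return None, record.gene.symbol, record.locus
    if isinstance(record, (ExpressionDiffRecord, IsoformRecord)):
        return None, record.gene.symbol, record.gene.locus
    if isinstance(record, ProbeMeasurement):
        return None, record.gene_symbol, None
    raise TypeError(f"unsupported record type {type(record).__name__}")


def associate(
    records: Sequence,
    graph: IdGraph,
    modality: str,
    study_date: _dt.date | None = None,
) -> ModalityDataset:
    """Key validated records by resolved gene identity.

    Records resolving to the same gene (through any namespace path)
    group under one canonical key; unresolved records land in the
    unresolved bucket keyed by their stub identity.
    """
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}; expected one of {MODALITIES}")
    dataset = ModalityDataset(modality=modality, study_date=study_date)
    for record in records:
        gene_id, symbol, locus = _record_identity_hints(record)
        identity = resolve_row_identity(gene_id, symbol, locus, graph)
        key = identity.canonical_key
        if identity.resolved:
            dataset.records.setdefault(key, []).append(record)
        else:
            dataset.unresolved.setdefault(key, []).append(record)
        # keep the richer identity if one resolution carried a locus
        if key not in dataset.identities:
            dataset.identities[key] = identity
    return dataset


# ---------------------------------------------------------------------------
# integrated table
# ---------------------------------------------------------------------------


@dataclass
class IntegratedTable:
    """Ordered per-gene grid with fixed, color-tagged column blocks."""

    frame: pd.DataFrame
    column_blocks: list[tuple[str, str, list[str]]]
    view_mode: str
    unresolved_counts: dict[str, int] = field(default_factory=dict)
    record_counts: dict[str, int] = field(default_factory=dict)

    @property
    def rows(self) -> pd.DataFrame:
        return self.frame

    @property
    def columns(self) -> list[str]:
        return [c for c in self.frame.columns if not c.startswith("_")]

    def blocks_header(self) -> str:
        parts = [
            f"{name}={color}" for name, color, _cols in self.column_blocks
        ]
        return "#blocks: " + ";".join(parts)

    def to_tsv(self, path) -> None:
        with open(path, "w") as handle:
            handle.write(self.blocks_header() + "\n")
            self.frame[self.columns].to_csv(handle, sep="\t", index=False)

    def to_json(self, path=None) -> str:
        payload = {
            "view_mode": self.view_mode,
            "blocks": [
                {"name": name, "color": color, "columns": cols}
                for name, color, cols in self.column_blocks
            ],
            "rows": self.frame[self.columns].to_dict(orient="records"),
            "unresolved": self.unresolved_counts,
        }
        text = json.dumps(payload, indent=2, default=str)
        if path is not None:
            with open(path, "w") as handle:
                handle.write(text)
        return text


def _format_af(af: float) -> str:
    """Display allelic frequency the way the grid does: whole percent."""
    return f"{round(af * 100)}%"


def _join(values: Iterable) -> str:
    return "; ".join(str(v) for v in values)


def _wes_cells(variants: list[VariantRecord], maximal: bool) -> dict:
    cells = {
        "Effect": _join(v.effect for v in variants),
        "Codon Change": _join(v.codon_change or "" for v in variants),
        "AA Change": _join(v.aa_change or "" for v in variants),
        "Tumor DP": variants[0].tumor_depth
        if len(variants) == 1
        else _join(v.tumor_depth for v in variants),
        "Tumor AF": _format_af(variants[0].tumor_af)
        if len(variants) == 1
        else _join(_format_af(v.tumor_af) for v in variants),
    }
    if maximal:
        cells.update(
            {
                "Chrom": _join(v.locus.chrom for v in variants),
                "Pos": _join(v.locus.start + 1 for v in variants),
                "Ref": _join(v.ref_allele for v in variants),
                "Alt": _join(v.alt_allele for v in variants),
                "Normal DP": _join(
                    "" if v.normal_depth is None else v.normal_depth for v in variants
                ),
                "Normal AF": _join(
                    "" if v.normal_af is None else _format_af(v.normal_af)
                    for v in variants
                ),
            }
        )
    return cells


def _rna_gene_cells(records: list[ExpressionDiffRecord], maximal: bool) -> dict:
    one = len(records) == 1
    cells = {
        "Sample 1 FPKM": records[0].sample1_fpkm
        if one
        else _join(r.sample1_fpkm for r in records),
        "Sample 2 FPKM": records[0].sample2_fpkm
        if one
        else _join(r.sample2_fpkm for r in records),
        "p-value": records[0].p_value if one else _join(r.p_value for r in records),
    }
    if maximal:
        cells.update(
            {
                "Log2 Fold Change": _join(r.log2_fold_change for r in records),
                "q-value": _join(r.q_value for r in records),
                "Significant": _join(
                    "yes" if r.significant else "no" for r in records
                ),
            }
        )
    return cells


def _rna_isoform_cells(record: IsoformRecord, maximal: bool) -> dict:
    cells = {
        "Transcript Id": record.transcript_id,
        "Sample 1 FPKM": record.sample1_fpkm,
        "Sample 2 FPKM": record.sample2_fpkm,
        "P-Value": record.p_value,
    }
    if maximal:
        cells["Significant"] = "yes" if record.significant else "no"
        cells["Novel"] = "yes" if record.novel else "no"
    return cells


def _microarray_cells(measurements: list[ProbeMeasurement], maximal: bool) -> dict:
    ordered = sorted(measurements, key=lambda m: m.probe_id)
    cells = {
        "Affy Probes": _join(m.probe_id for m in ordered),
        "Avg Probe Values": round(average_probe_values(measurements), 4),
    }
    if maximal:
        cells["Probe Values"] = _join(m.value for m in ordered)
    return cells


def _group_keys(group: GeneGroup, graph: IdGraph) -> set[str]:
    """Canonical keys of a group's members, converting namespaces via the graph."""
    keys: set[str] = set()
    for member in group.members:
        identity = resolve_row_identity(str(member), str(member), None, graph)
        keys.add(identity.canonical_key)
        if not identity.resolved:
            # an unresolved member might still be a bare symbol
            keys.add(f"symbol:{str(member).upper()}")
    return keys


def member_list(
    gene: GeneIdentity, groups: Sequence[GeneGroup], graph: IdGraph
) -> list[str]:
    """Names of every group containing the gene under any identifier, sorted."""
    key = gene.canonical_key
    names = [g.name for g in groups if key in _group_keys(g, graph)]
    return sorted(names)


def build_view(
    datasets: Sequence[ModalityDataset],
    graph: IdGraph,
    mode: str = "minimal",
    group: GeneGroup | None = None,
    all_groups: Sequence[GeneGroup] = (),
) -> IntegratedTable:
    """Full outer join of 1–3 modality datasets into the integrated grid.

    A gene present in any selected dataset yields a row (empty cells for
    the modalities it is missing from).  When an isoform-level RNA-seq
    dataset is selected the join emits one row per isoform, repeating
    the gene-level WES/microarray cells on each.  Rows are ordered
    genomically (chromosome, start), unresolved rows last.
    """
    if mode not in ("minimal", "maximal"):
        raise ValueError(f"view mode must be minimal or maximal, got {mode!r}")
    if not 1 <= len(datasets) <= 3:
        raise ValueError("build_view takes between one and three datasets")
    slots: dict[str, ModalityDataset] = {}
    for ds in datasets:
        slot = _SLOT[ds.modality]
        if slot in slots:
            raise ValueError(f"two datasets occupy the {slot!r} modality slot")
        slots[slot] = ds
    maximal = mode == "maximal"

    # union of gene keys over all selected datasets
    identities: dict[str, GeneIdentity] = {}
    unresolved_keys: set[str] = set()
    for ds in datasets:
        for key, identity in ds.identities.items():
            identities.setdefault(key, identity)
        unresolved_keys.update(ds.unresolved)
    unresolved_keys -= {
        k for ds in datasets for k in ds.records
    }  # resolved anywhere wins

    group_keys = _group_keys(group, graph) if group is not None else None
    all_groups = list(all_groups)
    if group is not None and group not in all_groups:
        all_groups.append(group)

    def records_for(slot: str, key: str) -> list:
        ds = slots.get(slot)
        if ds is None:
            return []
        return ds.records.get(key, []) + ds.unresolved.get(key, [])

    rows: list[dict] = []
    for key in identities:
        if group_keys is not None and key not in group_keys:
            continue
        identity = identities[key]
        base = {
            "_key": key,
            "_unresolved": key in unresolved_keys,
            "Entrez ID": "" if identity.entrez_id is None else identity.entrez_id,
            "Gene Symbol": identity.symbol or "",
            "Gene Name": identity.gene_name or "",
        }
        wes_records = records_for("wes", key)
        rna_ds = slots.get("rnaseq")
        array_records = records_for("microarray", key)
        cells: dict = {}
        if "wes" in slots and wes_records:
            cells.update(_wes_cells(wes_records, maximal))
        if "microarray" in slots and array_records:
            cells.update(_microarray_cells(array_records, maximal))
        base[MEMBER_COLUMN] = _join(member_list(identity, all_groups, graph))
        sort_key = _row_sort_key(identity, key in unresolved_keys)
        if rna_ds is not None and rna_ds.modality == "rnaseq_isoform":
            isoforms = records_for("rnaseq", key)
            if isoforms:
                for iso in sorted(isoforms, key=lambda r: r.transcript_id):
                    row = dict(base)
                    row.update(cells)
                    row.update(_rna_isoform_cells(iso, maximal))
                    row["_sort"] = sort_key + (iso.transcript_id,)
                    rows.append(row)
                continue
        elif rna_ds is not None:
            gene_records = records_for("rnaseq", key)
            if gene_records:
                cells.update(_rna_gene_cells(gene_records, maximal))
        row = dict(base)
        row.update(cells)
        row["_sort"] = sort_key + ("",)
        rows.append(row)

    columns = _schema_columns(slots, maximal)
    frame = pd.DataFrame(
        rows, columns=["_key", "_unresolved", "_sort", *columns], dtype=object
    )
    if len(frame):
        frame = frame.sort_values("_sort", kind="stable").reset_index(drop=True)
    frame = frame.drop(columns=["_sort"])
    frame = frame.where(frame.notna(), "")

    return IntegratedTable(
        frame=frame,
        column_blocks=_column_blocks(slots, maximal),
        view_mode=mode,
        unresolved_counts={
            ds.modality: sum(len(v) for v in ds.unresolved.values())
            for ds in datasets
        },
        record_counts={ds.modality: ds.record_count for ds in datasets},
    )


def _row_sort_key(identity: GeneIdentity, unresolved: bool) -> tuple:
    locus = identity.locus
    if locus is not None and not unresolved:
        return (0, locus.chrom, locus.start, identity.symbol or "")
    return (1, "~", 0, identity.symbol or identity.canonical_key)


def _block_columns(slot: str, rna_modality: str | None, maximal: bool) -> list[str]:
    modality = slot if slot != "rnaseq" else (rna_modality or "rnaseq_gene")
    cols = list(_MINIMAL_BLOCK_COLUMNS[modality])
    if maximal:
        cols += _MAXIMAL_EXTRA_COLUMNS[modality]
    return cols


def _column_blocks(
    slots: dict[str, ModalityDataset], maximal: bool
) -> list[tuple[str, str, list[str]]]:
    rna_modality = slots["rnaseq"].modality if "rnaseq" in slots else None
    blocks = [("core", BLOCK_COLORS["core"], list(CORE_COLUMNS))]
    for slot in ("wes", "rnaseq", "microarray"):  # fixed order, always
        if slot in slots:
            blocks.append(
                (slot, BLOCK_COLORS[slot], _block_columns(slot, rna_modality, maximal))
            )
    blocks.append(("member", BLOCK_COLORS["member"], [MEMBER_COLUMN]))
    return blocks


def _schema_columns(slots: dict[str, ModalityDataset], maximal: bool) -> list[str]:
    cols: list[str] = []
    for _name, _color, block_cols in _column_blocks(slots, maximal):
        for col in block_cols:
            if col not in cols:
                cols.append(col)
    return cols


def filter_by_group(
    table: IntegratedTable, group: GeneGroup, graph: IdGraph
) -> IntegratedTable:
    """Restrict a built table to rows matching any group member; order kept."""
    keys = _group_keys(group, graph)
    frame = table.frame[table.frame["_key"].isin(keys)].reset_index(drop=True)
    return IntegratedTable(
        frame=frame,
        column_blocks=table.column_blocks,
        view_mode=table.view_mode,
        unresolved_counts=dict(table.unresolved_counts),
        record_counts=dict(table.record_counts),
    )
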