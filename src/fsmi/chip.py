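"""Chip panels, slide layouts and the spot-table file dialect.

A *chip* is a printed panel of capture antibodies: each antibody is spotted in
replicate (triplicate by default) inside every *assay field* of a slide,
together with control spots (BSA, printing buffer, and a dilution of
fluorescently labelled pre-immune antiserum).  One slide carries a grid of
identical fields so that many assays run in parallel.

Two panels ship with the package:

* ``masechip()`` — the 26-antibody panel raised against anaerobic/halophilic
  isolates and environmental extracts, transcribed from its published table;
  printed in a 3 x 8 field grid, i.e. 24 assays per slide.
* ``ldchip168()`` — a synthetic stand-in for the 168-antibody life-detector
  panel whose full annotation is not public; it satisfies every constraint
  the accompanying text states (168 antibodies, 46 Proteobacteria, cluster
  letters a–j, >50 control spots per field).

Spot measurements travel in a simplified GenePix-results-style dialect:
tab-delimited with header ``Block, Row, Column, ID, Name, F635 Median,
B635 Median, Flags`` plus optional ``# key=value`` metadata comment lines.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .errors import (
    ChipValidationError,
    FormatError,
    LayoutCapacityError,
    SpotTableParseError,
)


class Origin(str, Enum):
    """Provenance of an antibody's immunogen."""

    MASE_ISOLATE = "mase_isolate"
    MASE_ENVIRONMENTAL = "mase_environmental"
    PRIOR_COLLECTION = "prior_collection"


class ControlKind(str, Enum):
    """Printed control-spot chemistries; their average defines the null baseline."""

    BSA = "BSA"
    BUFFER = "buffer"
    PREIMMUNE = "preimmune"


CONTROL_IDS = frozenset(k.value for k in ControlKind)


class SpotFlag(str, Enum):
    OK = "ok"
    DEFECTIVE = "defective"


@dataclass(frozen=True)
class AntibodyRecord:
    """One capture antibody on the panel.

    ``peak_index`` is the 1-based position in the chip's canonical order and
    is the peak number used on immunograms.
    """

    antibody_id: str
    name: str
    immunogen_source: str
    origin: Origin
    cluster: str = ""
    phylum: str = ""
    peak_index: int = 0
    has_tracer: bool = True
    reference: str = ""


@dataclass
class ChipDefinition:
    """A printed antibody panel plus its slide geometry."""

    name: str
    antibodies: list[AntibodyRecord]
    replicates_per_antibody: int = 3
    control_spot_count: int = 54
    control_kinds: tuple[ControlKind, ...] = (
        ControlKind.BSA,
        ControlKind.BUFFER,
        ControlKind.PREIMMUNE,
    )
    grid: tuple[int, int] = (3, 8)  # (columns, rows) of assay fields

    def __post_init__(self) -> None:
        if not self.antibodies:
            raise ChipValidationError("chip has an empty antibody list")
        seen: set[str] = set()
        for ab in self.antibodies:
            if ab.antibody_id in seen:
                raise ChipValidationError(
                    f"duplicate antibody_id {ab.antibody_id!r} in chip {self.name!r}"
                )
            seen.add(ab.antibody_id)
        # peak_index must be the contiguous 1..N chip order; assign if unset
        expected = list(range(1, len(self.antibodies) + 1))
        peaks = [ab.peak_index for ab in self.antibodies]
        if peaks != expected:
            if any(p != 0 for p in peaks):
                raise ChipValidationError(
                    f"peak_index values of chip {self.name!r} are not contiguous 1..N"
                )
            self.antibodies = [
                replace(ab, peak_index=i) for i, ab in enumerate(self.antibodies, 1)
            ]
        if self.replicates_per_antibody < 1:
            raise ChipValidationError("replicates_per_antibody must be >= 1")
        if self.control_spot_count < 1:
            raise ChipValidationError(
                "control_spot_count must be >= 1: quantification needs a baseline"
            )

    @property
    def fields_per_slide(self) -> int:
        cols, rows = self.grid
        return cols * rows

    @property
    def antibody_ids(self) -> list[str]:
        return [ab.antibody_id for ab in self.antibodies]

    def antibody(self, antibody_id: str) -> AntibodyRecord:
        for ab in self.antibodies:
            if ab.antibody_id == antibody_id:
                return ab
        raise KeyError(antibody_id)

    def groups(self, group_key: str) -> dict[str, list[str]]:
        """Map each group label (cluster or phylum) to its antibody IDs.

        Unannotated antibodies fall into the ``"unannotated"`` group.
        """
        if group_key not in ("cluster", "phylum"):
            raise ValueError(f"group_key must be 'cluster' or 'phylum', got {group_key!r}")
        out: dict[str, list[str]] = {}
        for ab in self.antibodies:
            label = getattr(ab, group_key).strip() or "unannotated"
            out.setdefault(label, []).append(ab.antibody_id)
        return out


# ---------------------------------------------------------------------------
# chip definition TSV
# ---------------------------------------------------------------------------

_CHIP_COLUMNS = (
    "antibody_id",
    "name",
    "immunogen_source",
    "origin",
    "cluster",
    "phylum",
    "has_tracer",
)


def load_chip_definition(path: str | Path, **chip_kwargs) -> ChipDefinition:
    """Read a chip definition TSV (columns ``antibody_id, name, immunogen_source,
    origin, cluster, phylum, has_tracer`` and optionally ``reference``).

    Row order defines the canonical antibody order (``peak_index`` 1..N).
    Extra keyword arguments (replicates, control counts, grid) go to
    :class:`ChipDefinition`.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in _CHIP_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path.name}: missing required column(s) {missing}")
        records = []
        for row in reader:
            try:
                origin = Origin(row["origin"].strip())
            except ValueError as exc:
                raise FormatError(
                    f"{path.name}: unknown origin {row['origin']!r} "
                    f"for antibody {row['antibody_id']!r}"
                ) from exc
            records.append(
                AntibodyRecord(
                    antibody_id=row["antibody_id"].strip(),
                    name=row["name"].strip(),
                    immunogen_source=row["immunogen_source"].strip(),
                    origin=origin,
                    cluster=row["cluster"].strip(),
                    phylum=row["phylum"].strip(),
                    has_tracer=row["has_tracer"].strip() in ("1", "true", "True", "yes"),
                    reference=(row.get("reference") or "").strip(),
                )
            )
    chip_kwargs.setdefault("name", path.stem)
    return ChipDefinition(antibodies=records, **chip_kwargs)


def write_chip_definition(chip: ChipDefinition, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_CHIP_COLUMNS + ("reference",))
        for ab in chip.antibodies:
            writer.writerow(
                [
                    ab.antibody_id,
                    ab.name,
                    ab.immunogen_source,
                    ab.origin.value,
                    ab.cluster,
                    ab.phylum,
                    "1" if ab.has_tracer else "0",
                    ab.reference,
                ]
            )


def _packaged(filename: str) -> Path:
    return Path(str(resources.files("fsmi.data").joinpath(filename)))


def masechip(**chip_kwargs) -> ChipDefinition:
    """The packaged 26-antibody anaerobe/halophile panel (24 assay fields per slide)."""
    chip_kwargs.setdefault("name", "MASE-Chip")
    chip_kwargs.setdefault("grid", (3, 8))
    return load_chip_definition(_packaged("masechip_table1.tsv"), **chip_kwargs)


def ldchip168(**chip_kwargs) -> ChipDefinition:
    """The packaged synthetic 168-antibody life-detector panel fixture.

    The real panel's full annotation is not public; this fixture satisfies the
    documented constraints (168 antibodies, 46 Proteobacteria, clusters a–j,
    >50 control spots per field, 9 assays per slide) with the remaining
    annotation filled deterministically.
    """
    chip_kwargs.setdefault("name", "LDChip168")
    chip_kwargs.setdefault("grid", (3, 3))
    chip_kwargs.setdefault("control_spot_count", 54)
    return load_chip_definition(_packaged("ldchip168_fixture.tsv"), **chip_kwargs)


# ---------------------------------------------------------------------------
# slide layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbeAssignment:
    """What is printed at one spot position: an antibody replicate or a control."""

    probe_id: str
    kind: str  # "antibody" or a ControlKind value
    replicate_index: int

    @property
    def is_control(self) -> bool:
        return self.kind != "antibody"


@dataclass(frozen=True)
class ChipLayout:
    """Deterministic spot layout; identical across all fields of the slide."""

    chip_name: str
    field_shape: tuple[int, int]  # (rows, cols) of spots within one field
    n_fields: int
    template: tuple[tuple[tuple[int, int], ProbeAssignment], ...]

    def positions(self, field_index: int) -> Iterable[tuple[int, int, int, ProbeAssignment]]:
        for (r, c), assign in self.template:
            yield field_index, r, c, assign

    def as_mapping(self) -> dict[tuple[int, int, int], ProbeAssignment]:
        """Mapping (field, row, col) -> probe assignment over the whole slide."""
        return {
            (f, r, c): a
            for f in range(self.n_fields)
            for (f, r, c, a) in self.positions(f)
        }

    @property
    def spots_per_field(self) -> int:
        return len(self.template)


def generate_layout(
    chip: ChipDefinition, field_shape: tuple[int, int] | None = None
) -> ChipLayout:
    """Lay out one assay field and replicate it over the slide.

    Antibody replicates are printed consecutively in chip order; control spots
    are interleaved at evenly spaced positions so the baseline samples the whole
    field.  The same template repeats in every field, so the layout is fully
    deterministic.

    ``field_shape`` is ``(rows, cols)`` of spots within one field; when omitted
    a near-square grid just large enough is used (the source text does not fix
    the within-field geometry).
    """
    n_ab_spots = len(chip.antibodies) * chip.replicates_per_antibody
    n_ctl = chip.control_spot_count
    total = n_ab_spots + n_ctl
    if field_shape is None:
        cols = math.ceil(math.sqrt(total))
        rows = math.ceil(total / cols)
        field_shape = (rows, cols)
    rows, cols = field_shape
    if rows * cols < total:
        raise LayoutCapacityError(
            f"field of {rows}x{cols}={rows * cols} spots cannot hold "
            f"{len(chip.antibodies)} antibodies x {chip.replicates_per_antibody} "
            f"replicates + {n_ctl} controls = {total} spots"
        )
    # control slots spread evenly through the print order
    ctl_slots = {int((i + 0.5) * total / n_ctl) for i in range(n_ctl)}
    assert len(ctl_slots) == n_ctl
    sequence: list[ProbeAssignment] = []
    ab_iter = iter(
        (ab.antibody_id, rep)
        for ab in chip.antibodies
        for rep in range(chip.replicates_per_antibody)
    )
    ctl_count = 0
    for slot in range(total):
        if slot in ctl_slots:
            kind = chip.control_kinds[ctl_count % len(chip.control_kinds)]
            sequence.append(
                ProbeAssignment(
                    probe_id=kind.value,
                    kind=kind.value,
                    replicate_index=ctl_count // len(chip.control_kinds),
                )
            )
            ctl_count += 1
        else:
            ab_id, rep = next(ab_iter)
            sequence.append(ProbeAssignment(probe_id=ab_id, kind="antibody", replicate_index=rep))
    template = tuple(
        ((i // cols, i % cols), assign) for i, assign in enumerate(sequence)
    )
    return ChipLayout(
        chip_name=chip.name,
        field_shape=field_shape,
        n_fields=chip.fields_per_slide,
        template=template,
    )


# ---------------------------------------------------------------------------
# spot tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpotRecord:
    field_index: int
    row: int
    col: int
    probe_id: str
    replicate_index: int
    f_fore: float
    f_back: float
    flag: SpotFlag = SpotFlag.OK

    @property
    def is_control(self) -> bool:
        return self.probe_id in CONTROL_IDS


@dataclass
class SpotTable:
    """Per-spot measurements of one assay (sample, blank, or titration point)."""

    assay_id: str
    role: str = "sample"  # sample | blank | titration_point
    spots: list[SpotRecord] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[int, int, int]] = set()
        for s in self.spots:
            key = (s.field_index, s.row, s.col)
            if key in seen:
                raise ChipValidationError(f"duplicate spot position {key} in {self.assay_id!r}")
            seen.add(key)

    def validate_against(self, chip: ChipDefinition) -> None:
        known = set(chip.antibody_ids) | CONTROL_IDS
        unknown = sorted({s.probe_id for s in self.spots} - known)
        if unknown:
            raise ChipValidationError(
                f"assay {self.assay_id!r}: probe ids not on chip {chip.name!r}: {unknown}"
            )

    def position_map(self) -> dict[tuple[int, int, int], str]:
        return {(s.field_index, s.row, s.col): s.probe_id for s in self.spots}


_SPOT_COLUMNS = (
    "Block",
    "Row",
    "Column",
    "ID",
    "Name",
    "F635 Median",
    "B635 Median",
    "Flags",
)

_DEFECT_FLAG = -100  # GenePix convention for a manually flagged bad spot


def write_spot_table(table: SpotTable, path: str | Path) -> None:
    """Write the tab-delimited dialect; metadata goes into ``# key=value`` lines."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        fh.write(f"# assay_id={table.assay_id}\n")
        fh.write(f"# role={table.role}\n")
        for key in sorted(table.metadata):
            fh.write(f"# {key}={table.metadata[key]}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_SPOT_COLUMNS)
        for s in table.spots:
            writer.writerow(
                [
                    s.field_index + 1,
                    s.row + 1,
                    s.col + 1,
                    s.probe_id,
                    s.probe_id,
                    repr(float(s.f_fore)),
                    repr(float(s.f_back)),
                    _DEFECT_FLAG if s.flag is SpotFlag.DEFECTIVE else 0,
                ]
            )


def read_spot_table(path: str | Path) -> SpotTable:
    """Read the dialect back; ``read(write(x)) == x`` field-for-field.

    ``Block`` maps to the 0-based field index; any non-zero ``Flags`` value
    marks the spot defective.  Replicate indices are reconstructed from the
    order of appearance of each probe within its field.
    """
    path = Path(path)
    assay_id = path.stem
    role = "sample"
    metadata: dict[str, str] = {}
    spots: list[SpotRecord] = []
    rep_counter: dict[tuple[int, str], int] = {}
    header: list[str] | None = None
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    key, value = key.strip(), value.strip()
                    if key == "assay_id":
                        assay_id = value
                    elif key == "role":
                        role = value
                    else:
                        metadata[key] = value
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                missing = [c for c in _SPOT_COLUMNS if c not in header]
                if missing:
                    raise FormatError(f"{path.name}: missing column(s) {missing}")
                idx = {c: header.index(c) for c in _SPOT_COLUMNS}
                continue
            try:
                block = int(parts[idx["Block"]])
                row = int(parts[idx["Row"]])
                col = int(parts[idx["Column"]])
                f_fore = float(parts[idx["F635 Median"]])
                f_back = float(parts[idx["B635 Median"]])
                flags = int(float(parts[idx["Flags"]]))
            except (ValueError, IndexError) as exc:
                raise SpotTableParseError(str(exc), line=lineno) from None
            probe_id = parts[idx["ID"]]
            key = (block - 1, probe_id)
            rep = rep_counter.get(key, 0)
            rep_counter[key] = rep + 1
            spots.append(
                SpotRecord(
                    field_index=block - 1,
                    row=row - 1,
                    col=col - 1,
                    probe_id=probe_id,
                    replicate_index=rep,
                    f_fore=f_fore,
                    f_back=f_back,
                    flag=SpotFlag.DEFECTIVE if flags != 0 else SpotFlag.OK,
                )
            )
    if header is None:
        raise FormatError(f"{path.name}: no header row found")
    return SpotTable(assay_id=assay_id, role=role, spots=spots, metadata=metadata)
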