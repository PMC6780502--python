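"""Cross-reactivity mapping from checkerboard assays.

Each checkerboard assay exposes the whole capture panel to a single antigen;
collecting the per-antibody final fluorescences over all antigens yields the
antigen x antibody cross-reactivity matrix.  From it the package derives a
specificity class per antibody (specific / cross_reactive / non_reactive),
the recognition graph (directed edges antibody -> recognized antigen, with
cognate recognitions as self-loops), and annotations that flag which positive
calls in a field sample could be explained by a non-cognate antigen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DuplicateAssayError
from .quantify import AssayQuant, QCStatus


@dataclass
class CrossReactMatrix:
    """Antigen (rows) x tracer-antibody (columns) final fluorescences and calls.

    ``values`` holds f_final with NaN for unobserved/QC-excluded combinations
    (never imputed); ``calls`` is boolean and False wherever a value is
    missing — consult :meth:`missing` to distinguish the two.
    """

    values: pd.DataFrame
    calls: pd.DataFrame
    cognate: dict[str, str]  # antibody -> its immunogen antigen

    @property
    def antigens(self) -> list[str]:
        return list(self.values.index)

    @property
    def antibodies(self) -> list[str]:
        return list(self.values.columns)

    def missing(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_calls(self) -> int:
        return int(self.calls.to_numpy().sum())


def build_crossreact_matrix(
    quants: Mapping[str, AssayQuant] | Iterable[tuple[str, AssayQuant]],
    cognate: Mapping[str, str],
) -> CrossReactMatrix:
    """Assemble the matrix from single-antigen assay quantifications.

    ``quants`` maps each tested antigen to the quantification of its
    checkerboard assay; duplicate antigens are an error, missing combinations
    stay NaN.
    """
    pairs = list(quants.items()) if isinstance(quants, Mapping) else list(quants)
    seen: set[str] = set()
    for ag, _ in pairs:
        if ag in seen:
            raise DuplicateAssayError(f"duplicate checkerboard assay for antigen {ag!r}")
        seen.add(ag)
    if not pairs:
        raise ValueError("no checkerboard assays given")
    antigens = [ag for ag, _ in pairs]
    antibodies: list[str] = []
    for _, quant in pairs:
        for ab in quant.rows:
            if ab not in antibodies:
                antibodies.append(ab)
    values = pd.DataFrame(np.nan, index=antigens, columns=antibodies, dtype=float)
    calls = pd.DataFrame(False, index=antigens, columns=antibodies, dtype=bool)
    for ag, quant in pairs:
        for ab, row in quant.rows.items():
            if row.qc_status is QCStatus.OK and row.f_final is not None:
                values.loc[ag, ab] = row.f_final
                calls.loc[ag, ab] = row.positive
    return CrossReactMatrix(values=values, calls=calls, cognate=dict(cognate))


def write_matrix_tsv(matrix: CrossReactMatrix, path: str | Path) -> None:
    matrix.values.rename_axis("antigen").to_csv(Path(path), sep="\t")


# ---------------------------------------------------------------------------
# specificity
# ---------------------------------------------------------------------------


@dataclass
class AntibodySpecificity:
    antibody_id: str
    cognate_detected: bool | None  # None when no cognate assay was observed
    off_target: list[str]
    specificity: str  # specific | cross_reactive | non_reactive


@dataclass
class SpecificityReport:
    per_antibody: dict[str, AntibodySpecificity]
    recognized_by: dict[str, list[str]]  # antigen -> antibodies calling it

    def antibodies_in_class(self, specificity: str) -> list[str]:
        return [ab for ab, s in self.per_antibody.items() if s.specificity == specificity]


def specificity_report(matrix: CrossReactMatrix) -> SpecificityReport:
    """Classify each antibody from its column of checkerboard calls.

    *specific*: detects its cognate antigen and nothing else; *cross_reactive*:
    any non-cognate call; *non_reactive*: no call at all.  An antibody whose
    cognate assay is absent or QC-excluded gets ``cognate_detected=None`` and
    is never classified specific.
    """
    per_antibody: dict[str, AntibodySpecificity] = {}
    for ab in matrix.antibodies:
        cognate_ag = matrix.cognate.get(ab)
        col = matrix.calls[ab]
        called = [ag for ag in matrix.antigens if bool(col[ag])]
        off_target = sorted(ag for ag in called if ag != cognate_ag)
        if cognate_ag is None or cognate_ag not in matrix.antigens or bool(
            matrix.missing().loc[cognate_ag, ab]
        ):
            cognate_detected: bool | None = None
        else:
            cognate_detected = bool(matrix.calls.loc[cognate_ag, ab])
        if off_target:
            specificity = "cross_reactive"
        elif cognate_detected:
            specificity = "specific"
        else:
            specificity = "non_reactive"
        per_antibody[ab] = AntibodySpecificity(
            antibody_id=ab,
            cognate_detected=cognate_detected,
            off_target=off_target,
            specificity=specificity,
        )
    recognized_by = {
        ag: sorted(ab for ab in matrix.antibodies if bool(matrix.calls.loc[ag, ab]))
        for ag in matrix.antigens
    }
    return SpecificityReport(per_antibody=per_antibody, recognized_by=recognized_by)


# ---------------------------------------------------------------------------
# recognition graph
# ---------------------------------------------------------------------------


def export_graph(
    matrix: CrossReactMatrix,
    drop_self_loops: bool = False,
    origins: Mapping[str, str] | None = None,
) -> nx.DiGraph:
    """Directed recognition graph: one edge antibody -> antigen per positive call.

    Cognate recognitions are self-edges in the data model; pass
    ``drop_self_loops=True`` to omit them (display convention).  Node ordering
    is deterministic (antibodies in column order, then remaining antigens).
    """
    g = nx.DiGraph()
    origins = dict(origins or {})
    for ab in matrix.antibodies:
        g.add_node(ab, kind="antibody", origin=origins.get(ab, ""))
    for ag in matrix.antigens:
        if ag in g:
            g.nodes[ag]["kind"] = "both"
        else:
            g.add_node(ag, kind="antigen", origin=origins.get(ag, ""))
    for ab in matrix.antibodies:
        for ag in matrix.antigens:
            if not bool(matrix.calls.loc[ag, ab]):
                continue
            if drop_self_loops and matrix.cognate.get(ab) == ag:
                continue
            value = matrix.values.loc[ag, ab]
            g.add_edge(ab, ag, f_final=float(value), cognate=matrix.cognate.get(ab) == ag)
    return g


def matrix_from_graph(graph: nx.DiGraph, matrix_like: CrossReactMatrix) -> CrossReactMatrix:
    """Rebuild a call matrix from a (loop-keeping) recognition graph.

    Used to check graph/matrix duality; values come from edge attributes,
    shape and cognate map from ``matrix_like``.
    """
    values = pd.DataFrame(
        np.nan, index=matrix_like.antigens, columns=matrix_like.antibodies, dtype=float
    )
    calls = pd.DataFrame(
        False, index=matrix_like.antigens, columns=matrix_like.antibodies, dtype=bool
    )
    for ab, ag, data in graph.edges(data=True):
        calls.loc[ag, ab] = True
        values.loc[ag, ab] = data.get("f_final", np.nan)
    return CrossReactMatrix(values=values, calls=calls, cognate=dict(matrix_like.cognate))


def write_graphml(graph: nx.DiGraph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


def write_dot(graph: nx.DiGraph, path: str | Path) -> None:
    """Minimal DOT export (nodes with kind/origin, edges labelled by f_final)."""
    lines = ["digraph crossreactivity {"]
    for node, data in graph.nodes(data=True):
        attrs = f'kind="{data.get("kind", "")}", origin="{data.get("origin", "")}"'
        lines.append(f'    "{node}" [{attrs}];')
    for u, v, data in graph.edges(data=True):
        f = data.get("f_final")
        label = f' [label="{f:.1f}"]' if f is not None and np.isfinite(f) else ""
        lines.append(f'    "{u}" -> "{v}"{label};')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# interpreting sample profiles through the matrix
# ---------------------------------------------------------------------------


@dataclass
class CallAnnotation:
    antibody_id: str
    status: str  # unambiguous | ambiguous | unknown
    alternatives: list[str] = field(default_factory=list)


def flag_ambiguous_calls(
    quant: AssayQuant, matrix: CrossReactMatrix
) -> dict[str, CallAnnotation]:
    """Annotate each positive call of a sample with its possible explanations.

    A positive on antibody ``i`` is *unambiguous* when the checkerboard shows
    ``i`` reacting only with its cognate antigen; *ambiguous* when non-cognate
    antigens could explain the signal (they are listed); *unknown* when ``i``
    was never characterized in the matrix.
    """
    out: dict[str, CallAnnotation] = {}
    for ab in quant.positives:
        if ab not in matrix.antibodies or bool(matrix.missing()[ab].all()):
            out[ab] = CallAnnotation(antibody_id=ab, status="unknown")
            continue
        col = matrix.calls[ab]
        called = [ag for ag in matrix.antigens if bool(col[ag])]
        cognate_ag = matrix.cognate.get(ab)
        alternatives = sorted(ag for ag in called if ag != cognate_ag)
        if not called:
            out[ab] = CallAnnotation(antibody_id=ab, status="unknown")
        elif alternatives:
            out[ab] = CallAnnotation(antibody_id=ab, status="ambiguous", alternatives=alternatives)
        else:
            out[ab] = CallAnnotation(antibody_id=ab, status="unambiguous")
    return out
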