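"""Reporting artefacts: immunograms, group hit counts and abundance profiles.

An *immunogram* is the bar-plot representation of one assay: one numbered
peak per positive antibody (peak number = position in the chip's canonical
order) with its final fluorescence.  Hits can be tallied per cluster or per
phylum and normalized by the relative weight of each group on the chip
(hit rate ``hits_g / n_g`` rescaled to percentages), which corrects for
groups represented by few antibodies.  A phylum profile can be compared
against an external relative-abundance table (e.g. from 16S sequencing) via
simple concordance statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chip import ChipDefinition
from .errors import AnnotationError, PairingError
from .quantify import AssayQuant


@dataclass
class Immunogram:
    """Ordered positive peaks of one assay, plus the chip's cluster bands."""

    assay_id: str
    peaks: list[tuple[int, str, float]]  # (peak_index, antibody_id, f_final)
    cluster_bands: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def peak_indices(self) -> list[int]:
        return [p for p, _, _ in self.peaks]

    @property
    def antibody_ids(self) -> list[str]:
        return [ab for _, ab, _ in self.peaks]


def _cluster_bands(chip: ChipDefinition) -> dict[str, list[tuple[int, int]]]:
    """Contiguous peak-index ranges per cluster, in chip order."""
    bands: dict[str, list[tuple[int, int]]] = {}
    prev_cluster: str | None = None
    for ab in chip.antibodies:
        cluster = ab.cluster or "unannotated"
        if cluster == prev_cluster:
            ranges = bands[cluster]
            ranges[-1] = (ranges[-1][0], ab.peak_index)
        else:
            bands.setdefault(cluster, []).append((ab.peak_index, ab.peak_index))
        prev_cluster = cluster
    return bands


def build_immunogram(quant: AssayQuant, chip: ChipDefinition) -> Immunogram:
    """Keep only positive calls, numbered and ordered by chip position."""
    peaks = []
    for ab in chip.antibodies:
        row = quant.rows.get(ab.antibody_id)
        if row is not None and row.positive:
            peaks.append((ab.peak_index, ab.antibody_id, float(row.f_final)))
    return Immunogram(assay_id=quant.assay_id, peaks=peaks, cluster_bands=_cluster_bands(chip))


def plot_immunogram(immunogram: Immunogram, ax=None):
    """Bar-plot convenience (peak index vs final fluorescence)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    if immunogram.peaks:
        ax.bar(immunogram.peak_indices, [f for _, _, f in immunogram.peaks], width=0.8)
    ax.set_xlabel("peak (antibody) number")
    ax.set_ylabel("final fluorescence F")
    ax.set_title(immunogram.assay_id)
    return ax


# ---------------------------------------------------------------------------
# group profiles
# ---------------------------------------------------------------------------


def count_hits_by_group(
    quant: AssayQuant, chip: ChipDefinition, group_key: str
) -> dict[str, int]:
    """Number of positive antibodies per cluster/phylum; totals match positives."""
    groups = chip.groups(group_key)
    positives = set(quant.positives)
    return {g: sum(1 for ab in members if ab in positives) for g, members in groups.items()}


def normalize_by_group_weight(
    hits: Mapping[str, int], chip: ChipDefinition, group_key: str
) -> dict[str, float]:
    """Relative abundance (%) after weighting by group size on the chip.

    Each group's hit count is divided by the number of its antibodies on the
    chip (the group's relative weight) and the resulting rates are rescaled to
    sum to 100%.  All-zero when there is no hit at all.
    """
    groups = chip.groups(group_key)
    rates: dict[str, float] = {}
    for g, h in hits.items():
        n_g = len(groups.get(g, ()))
        if h > 0 and n_g == 0:
            raise AnnotationError(f"hits in group {g!r} but no antibody of that group on chip")
        rates[g] = h / n_g if n_g else 0.0
    total = sum(rates.values())
    if total == 0:
        return {g: 0.0 for g in rates}
    return {g: 100.0 * r / total for g, r in rates.items()}


@dataclass
class GroupProfile:
    """Per-group panel size, hit count and normalized relative abundance."""

    group_key: str
    n: dict[str, int]
    hits: dict[str, int]
    rel_abundance: dict[str, float]


def build_group_profile(
    quant: AssayQuant, chip: ChipDefinition, group_key: str
) -> GroupProfile:
    groups = chip.groups(group_key)
    hits = count_hits_by_group(quant, chip, group_key)
    return GroupProfile(
        group_key=group_key,
        n={g: len(m) for g, m in groups.items()},
        hits=hits,
        rel_abundance=normalize_by_group_weight(hits, chip, group_key),
    )


def profile_matrix(
    assays: Sequence[AssayQuant],
    chip: ChipDefinition,
    group_key: str,
    mode: str = "hits",
) -> pd.DataFrame:
    """Groups x assays matrix of hit counts or relative abundances (%).

    Row order follows the chip's group order; column order follows the input.
    """
    if mode not in ("hits", "rel_abundance"):
        raise ValueError("mode must be 'hits' or 'rel_abundance'")
    groups = list(chip.groups(group_key))
    columns = {}
    for quant in assays:
        if quant.assay_id in columns:
            raise PairingError(f"duplicate assay id {quant.assay_id!r} in profile")
        hits = count_hits_by_group(quant, chip, group_key)
        values = hits if mode == "hits" else normalize_by_group_weight(hits, chip, group_key)
        columns[quant.assay_id] = [values[g] for g in groups]
    return pd.DataFrame(columns, index=pd.Index(groups, name=group_key))


def write_profile_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(Path(path), sep="\t")


def read_profile_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t", index_col=0)


def plot_profile_heatmap(matrix: pd.DataFrame, ax=None, **imshow_kwargs):
    """White-to-red heat map of a profile matrix."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(0.6 * matrix.shape[1] + 3, 0.4 * matrix.shape[0] + 2))
    imshow_kwargs.setdefault("cmap", "Reds")
    im = ax.imshow(matrix.to_numpy(dtype=float), aspect="auto", **imshow_kwargs)
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90)
    ax.set_yticks(range(matrix.shape[0]), matrix.index)
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    return ax


# ---------------------------------------------------------------------------
# comparison with an external phylum-abundance table
# ---------------------------------------------------------------------------


def read_reference_table(path: str | Path, sample: str | None = None) -> dict[str, float]:
    """Read a ``phylum, sample, rel_abundance`` TSV into a phylum -> % mapping."""
    df = pd.read_csv(Path(path), sep="\t")
    required = {"phylum", "sample", "rel_abundance"}
    if not required.issubset(df.columns):
        raise ValueError(f"reference table needs columns {sorted(required)}")
    if sample is not None:
        df = df[df["sample"] == sample]
    return dict(zip(df["phylum"], df["rel_abundance"].astype(float)))


def compare_with_reference(
    profile: GroupProfile | Mapping[str, float],
    reference: Mapping[str, float],
) -> dict:
    """Descriptive concordance between a phylum profile and a reference table.

    Reports the presence/absence agreement fraction (phyla detected by both
    methods over phyla detected by either) and the Spearman rank correlation
    of relative abundances over the phyla detected by both.  Labels are
    harmonized case-insensitively; a phylum absent from one table counts as 0.
    """
    if not reference:
        raise ValueError("empty reference table")
    ours = profile.rel_abundance if isinstance(profile, GroupProfile) else dict(profile)

    def norm(d: Mapping[str, float]) -> dict[str, float]:
        return {str(k).strip().lower(): float(v) for k, v in d.items()}

    a, b = norm(ours), norm(reference)
    detected_a = {k for k, v in a.items() if v > 0}
    detected_b = {k for k, v in b.items() if v > 0}
    union = detected_a | detected_b
    shared = sorted(detected_a & detected_b)
    agreement = len(shared) / len(union) if union else 1.0
    if len(shared) >= 2:
        va, vb = [a[k] for k in shared], [b[k] for k in shared]
        rho = stats.spearmanr(va, vb).statistic
        if np.isfinite(rho):
            rank_correlation = float(rho)
        else:
            # constant ranks in one table: undefined unless the rankings agree exactly
            same = np.array_equal(stats.rankdata(va), stats.rankdata(vb))
            rank_correlation = 1.0 if same else float("nan")
    elif len(shared) == 1:
        rank_correlation = 1.0
    else:
        rank_correlation = float("nan")
    return {
        "agreement": agreement,
        "rank_correlation": rank_correlation,
        "shared_phyla": shared,
        "only_profile": sorted(detected_a - detected_b),
        "only_reference": sorted(detected_b - detected_a),
    }
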