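"""Spot-level quantification: from raw spot tables to positive calls.

The pipeline, per antibody:

1. local-background subtraction, ``max(0, F635 - B635)`` per spot;
2. replicate QC — flagged/defective spots are dropped, and a replicate set
   whose sample standard deviation exceeds ``cv_threshold`` (default 0.2)
   times its mean is excluded from quantification;
3. the per-assay control baseline ``F_avcontrol``: the mean background-
   subtracted intensity of all valid control spots (BSA, buffer, pre-immune);
4. the final fluorescence

       F = F_sample - F_blank - stringency_multiplier * F_avcontrol

   with ``stringency_multiplier`` defaulting to 2.5, and a positive call
   whenever ``F > 0``.

``F_sample`` and ``F_blank`` are each the aggregated (mean by default)
replicate intensity of the antibody in the sample and in the parallel
buffer-only blank assay; the control baseline is taken from the sample assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chip import ChipDefinition, SpotFlag, SpotRecord, SpotTable
from .errors import BaselineError, PairingError


class QCStatus(str, Enum):
    OK = "ok"
    EXCLUDED_CV = "excluded_cv"
    EXCLUDED_DEFECTIVE = "excluded_defective"
    EXCLUDED_MISSING = "excluded_missing"


@dataclass
class QuantConfig:
    stringency_multiplier: float = 2.5
    cv_threshold: float = 0.2
    replicate_aggregator: str = "mean"  # mean | median
    clamp_negative: bool = True

    def __post_init__(self) -> None:
        if self.stringency_multiplier <= 0 or self.cv_threshold <= 0:
            raise ValueError("stringency_multiplier and cv_threshold must be positive")
        if self.replicate_aggregator not in ("mean", "median"):
            raise ValueError("replicate_aggregator must be 'mean' or 'median'")

    def aggregate(self, values: Sequence[float]) -> float:
        arr = np.asarray(values, dtype=float)
        return float(np.median(arr) if self.replicate_aggregator == "median" else arr.mean())


@dataclass
class AntibodySignal:
    """Replicate-level intensities of one antibody in one assay, after QC."""

    antibody_id: str
    replicate_intensities: list[float]
    n_valid: int
    f_component: float | None
    qc_status: QCStatus


@dataclass
class QuantRow:
    antibody_id: str
    f_sample: float | None
    f_blank: float | None
    f_final: float | None
    positive: bool
    qc_status: QCStatus


@dataclass
class AssayQuant:
    """Per-antibody quantification of one sample/blank assay pair."""

    assay_id: str
    blank_id: str
    f_avcontrol: float
    rows: dict[str, QuantRow] = field(default_factory=dict)

    @property
    def positives(self) -> list[str]:
        return [ab for ab, row in self.rows.items() if row.positive]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "antibody_id": list(self.rows),
                "f_sample": [r.f_sample for r in self.rows.values()],
                "f_blank": [r.f_blank for r in self.rows.values()],
                "f_avcontrol": self.f_avcontrol,
                "f_final": [r.f_final for r in self.rows.values()],
                "positive": [int(r.positive) for r in self.rows.values()],
                "qc_status": [r.qc_status.value for r in self.rows.values()],
            }
        )

    def write_tsv(self, path: str | Path, metadata: dict[str, str] | None = None) -> None:
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            fh.write(f"# assay_id={self.assay_id}\n")
            fh.write(f"# blank_id={self.blank_id}\n")
            for k in sorted(metadata or {}):
                fh.write(f"# {k}={metadata[k]}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def read_quant_tsv(path: str | Path) -> AssayQuant:
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open(encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, value = line.lstrip("#").strip().partition("=")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
        df = pd.read_csv(fh, sep="\t")
    quant = AssayQuant(
        assay_id=meta.get("assay_id", path.stem),
        blank_id=meta.get("blank_id", ""),
        f_avcontrol=float(df["f_avcontrol"].iloc[0]) if len(df) else 0.0,
    )
    for _, row in df.iterrows():
        quant.rows[row["antibody_id"]] = QuantRow(
            antibody_id=row["antibody_id"],
            f_sample=None if pd.isna(row["f_sample"]) else float(row["f_sample"]),
            f_blank=None if pd.isna(row["f_blank"]) else float(row["f_blank"]),
            f_final=None if pd.isna(row["f_final"]) else float(row["f_final"]),
            positive=bool(row["positive"]),
            qc_status=QCStatus(row["qc_status"]),
        )
    return quant


# ---------------------------------------------------------------------------
# pipeline steps
# ---------------------------------------------------------------------------


def background_subtract(spot: SpotRecord, config: QuantConfig | None = None) -> float:
    """Foreground minus local background, floored at zero unless configured off."""
    config = config or QuantConfig()
    value = spot.f_fore - spot.f_back
    return max(0.0, value) if config.clamp_negative else value


def replicate_qc(
    intensities: Sequence[float], config: QuantConfig | None = None
) -> tuple[QCStatus, float | None]:
    """QC a replicate set and aggregate it.

    Excluded when the sample standard deviation (n-1 denominator) exceeds
    ``cv_threshold`` times the mean; single replicates and zero-mean sets pass
    trivially (no spread to test).
    """
    config = config or QuantConfig()
    values = [float(v) for v in intensities]
    if not values:
        return QCStatus.EXCLUDED_MISSING, None
    if len(values) >= 2:
        mean = float(np.mean(values))
        sd = float(np.std(values, ddof=1))
        if mean > 0 and sd > config.cv_threshold * mean:
            return QCStatus.EXCLUDED_CV, None
    return QCStatus.OK, config.aggregate(values)


def control_baseline(table: SpotTable, config: QuantConfig | None = None) -> float:
    """Mean background-subtracted intensity of all valid control spots."""
    config = config or QuantConfig()
    values = [
        background_subtract(s, config)
        for s in table.spots
        if s.is_control and s.flag is SpotFlag.OK
    ]
    if not values:
        raise BaselineError(
            f"assay {table.assay_id!r} has no valid control spot; cannot quantify"
        )
    return float(np.mean(values))


def final_fluorescence(
    f_sample: float,
    f_blank: float,
    f_avcontrol: float,
    config: QuantConfig | None = None,
) -> tuple[float, bool]:
    """The stringency-thresholded final intensity and its positive call."""
    config = config or QuantConfig()
    f_final = f_sample - f_blank - config.stringency_multiplier * f_avcontrol
    return f_final, f_final > 0


def _antibody_signal(
    table: SpotTable, antibody_id: str, config: QuantConfig, cv_gate: float = 0.0
) -> AntibodySignal:
    """Collect, QC and aggregate one antibody's replicates in one assay.

    ``cv_gate``: the replicate-spread exclusion only applies when the replicate
    mean exceeds this level.  The full pipeline passes the control baseline
    here: replicate sets at or below the null are background-dominated, their
    coefficient of variation is meaningless, and keeping them is safe because
    they can only produce negative calls.
    """
    spots = [s for s in table.spots if s.probe_id == antibody_id]
    if not spots:
        return AntibodySignal(antibody_id, [], 0, None, QCStatus.EXCLUDED_MISSING)
    valid = [s for s in spots if s.flag is SpotFlag.OK]
    if not valid:
        return AntibodySignal(antibody_id, [], 0, None, QCStatus.EXCLUDED_DEFECTIVE)
    intensities = [background_subtract(s, config) for s in valid]
    if float(np.mean(intensities)) <= cv_gate:
        return AntibodySignal(
            antibody_id, intensities, len(valid), config.aggregate(intensities), QCStatus.OK
        )
    status, value = replicate_qc(intensities, config)
    return AntibodySignal(antibody_id, intensities, len(valid), value, status)


def quantify_assay(
    sample: SpotTable,
    blank: SpotTable,
    chip: ChipDefinition,
    config: QuantConfig | None = None,
) -> AssayQuant:
    """Run the full per-antibody pipeline on a sample/blank assay pair."""
    config = config or QuantConfig()
    sample.validate_against(chip)
    blank.validate_against(chip)
    if sample.position_map() != blank.position_map():
        raise PairingError(
            f"sample {sample.assay_id!r} and blank {blank.assay_id!r} "
            "do not share a spot layout"
        )
    f_avcontrol = control_baseline(sample, config)
    quant = AssayQuant(assay_id=sample.assay_id, blank_id=blank.assay_id, f_avcontrol=f_avcontrol)
    for ab_id in chip.antibody_ids:
        sig_s = _antibody_signal(sample, ab_id, config, cv_gate=f_avcontrol)
        sig_b = _antibody_signal(blank, ab_id, config, cv_gate=f_avcontrol)
        status = sig_s.qc_status if sig_s.qc_status is not QCStatus.OK else sig_b.qc_status
        if status is not QCStatus.OK:
            quant.rows[ab_id] = QuantRow(
                antibody_id=ab_id,
                f_sample=sig_s.f_component,
                f_blank=sig_b.f_component,
                f_final=None,
                positive=False,
                qc_status=status,
            )
            continue
        f_final, positive = final_fluorescence(
            sig_s.f_component, sig_b.f_component, f_avcontrol, config
        )
        quant.rows[ab_id] = QuantRow(
            antibody_id=ab_id,
            f_sample=sig_s.f_component,
            f_blank=sig_b.f_component,
            f_final=f_final,
            positive=positive,
            qc_status=QCStatus.OK,
        )
    return quant
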