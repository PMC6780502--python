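"""Tracer-dilution optimization and titration-based detection limits.

Two validation experiments characterize each antibody pair:

* a *dilution series* — fixed cognate antigen, serial dilutions of the
  labelled tracer antibody (1/500 ... 1/5000); the best working dilution
  maximizes the signal-to-blank ratio;
* a *titration series* — fixed tracer, antigen concentration stepped until
  the positive-call rule stops firing; the limit of detection (LOD) is the
  lowest tested concentration from which every higher tested concentration
  still calls positive in all replicates.  The LOD is reported as a tested
  concentration (dilution stepping, no interpolation), and the median
  f_final per concentration forms a piecewise-linear calibration curve in
  log10 concentration space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chip import ChipDefinition
from .errors import ExtrapolationError, NoOptimumError
from .quantify import QCStatus, QuantConfig, quantify_assay
from .simulate import AffinityMatrix, BindingParams, NoiseModel, simulate_titration


@dataclass(frozen=True)
class TitrationPoint:
    concentration: float  # cells/mL
    f_finals: tuple[float, ...]  # per replicate assay
    positive_fraction: float


@dataclass
class TitrationSeries:
    antibody_id: str
    points: list[TitrationPoint]
    blank_ref: str = ""

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("a titration series needs at least 2 points")
        self.points = sorted(self.points, key=lambda p: p.concentration)
        concs = [p.concentration for p in self.points]
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise ValueError("concentrations must be strictly increasing")


@dataclass(frozen=True)
class DilutionPoint:
    dilution: float  # fraction, e.g. 1/500
    f_final: float  # on the fixed cognate antigen
    f_blank: float


@dataclass
class DilutionSeries:
    antibody_id: str
    points: list[DilutionPoint]

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise ValueError("a dilution series needs at least 3 points")
        # store from most to least concentrated tracer (1/500 -> 1/5000)
        self.points = sorted(self.points, key=lambda p: -p.dilution)


def optimize_tracer_dilution(series: DilutionSeries, eps: float = 1.0) -> float:
    """The tested dilution maximizing f_final / (blank + eps); ties go dilute.

    ``eps`` (one fluorescence unit) guards the division when the blank is
    clean.  All-non-positive signals mean no working dilution exists.
    """
    candidates = [p for p in series.points if p.f_final > 0]
    if not candidates:
        raise NoOptimumError(
            f"antibody {series.antibody_id!r}: no dilution yields positive signal"
        )
    best = max(candidates, key=lambda p: (p.f_final / (p.f_blank + eps), -p.dilution))
    return best.dilution


def estimate_lod(
    series: TitrationSeries, min_positive_fraction: float = 1.0
) -> float | None:
    """Smallest tested concentration above which calling is consistently positive.

    Monotone enforcement: a concentration only qualifies if every *higher*
    tested concentration also reaches ``min_positive_fraction``; an isolated
    positive below a negative does not set the LOD.  ``None`` when even the
    highest concentration fails.
    """
    lod: float | None = None
    for point in reversed(series.points):  # scan from the top down
        if point.positive_fraction >= min_positive_fraction:
            lod = point.concentration
        else:
            break
    return lod


@dataclass
class CalibrationCurve:
    """Median f_final vs log10 concentration, defined on the tested range only."""

    antibody_id: str
    log10_concentrations: np.ndarray
    median_f: np.ndarray
    lod: float | None = None

    def __call__(self, concentration: float) -> float:
        logc = np.log10(concentration)
        lo, hi = self.log10_concentrations[0], self.log10_concentrations[-1]
        if logc < lo or logc > hi:
            raise ExtrapolationError(
                f"concentration {concentration:g} outside tested range "
                f"[{10 ** lo:g}, {10 ** hi:g}]"
            )
        return float(np.interp(logc, self.log10_concentrations, self.median_f))


def fit_calibration_curve(
    series: TitrationSeries, min_positive_fraction: float = 1.0
) -> CalibrationCurve:
    """Piecewise-linear interpolation of median f_final in log10 concentration.

    Zero-concentration points (no defined log) are dropped from the curve.
    """
    pts = [p for p in series.points if p.concentration > 0]
    if len(pts) < 2:
        raise ValueError("need at least 2 positive-concentration points to fit a curve")
    return CalibrationCurve(
        antibody_id=series.antibody_id,
        log10_concentrations=np.log10([p.concentration for p in pts]),
        median_f=np.array([float(np.median(p.f_finals)) for p in pts]),
        lod=estimate_lod(series, min_positive_fraction),
    )


# ---------------------------------------------------------------------------
# simulated titration experiments
# ---------------------------------------------------------------------------


def titration_series_from_tables(
    tables,
    blank,
    chip: ChipDefinition,
    antibody_id: str,
    config: QuantConfig | None = None,
) -> TitrationSeries:
    """Quantify replicate titration assays and collect one antibody's series."""
    config = config or QuantConfig()
    by_conc: dict[float, list[float]] = {}
    pos_by_conc: dict[float, list[bool]] = {}
    for table in tables:
        conc = float(table.metadata["concentration"])
        quant = quantify_assay(table, blank, chip, config)
        row = quant.rows[antibody_id]
        if row.qc_status is not QCStatus.OK:
            continue
        by_conc.setdefault(conc, []).append(row.f_final)
        pos_by_conc.setdefault(conc, []).append(row.positive)
    points = [
        TitrationPoint(
            concentration=conc,
            f_finals=tuple(by_conc[conc]),
            positive_fraction=float(np.mean(pos_by_conc[conc])),
        )
        for conc in sorted(by_conc)
    ]
    return TitrationSeries(antibody_id=antibody_id, points=points, blank_ref=blank.assay_id)


def half_log_concentrations(lo: float = 1e2, hi: float = 1e6) -> list[float]:
    """Half-decade concentration ladder, e.g. 1e2, 10^2.5, 1e3, ... 1e6 cells/mL."""
    n = int(round(2 * (np.log10(hi) - np.log10(lo)))) + 1
    return [float(10 ** (np.log10(lo) + 0.5 * i)) for i in range(n)]


def lod_survey(
    chip: ChipDefinition,
    concentrations: Sequence[float] | None = None,
    affinity: AffinityMatrix | None = None,
    binding: BindingParams | None = None,
    noise: NoiseModel | None = None,
    *,
    replicates: int = 3,
    config: QuantConfig | None = None,
    seed: int = 0,
    min_positive_fraction: float = 1.0,
) -> dict[str, float | None]:
    """Per-antibody simulated LOD over the whole panel (cognate titrations).

    Each antibody's cognate antigen is titrated through ``concentrations``
    (half-log ladder 1e2–1e6 cells/mL by default) with ``replicates``
    simulated assays per point; the positive-call rule then fixes the LOD.
    """
    concentrations = list(concentrations) if concentrations is not None else half_log_concentrations()
    affinity = affinity or AffinityMatrix.identity(chip.antibody_ids)
    cognate = dict(zip(affinity.antibodies, affinity.antigens))
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(len(chip.antibody_ids))]
    out: dict[str, float | None] = {}
    for ab_id, ab_seed in zip(chip.antibody_ids, seeds):
        tables, blank = simulate_titration(
            chip,
            cognate[ab_id],
            concentrations,
            affinity,
            binding,
            noise,
            replicates=replicates,
            seed=ab_seed,
        )
        series = titration_series_from_tables(tables, blank, chip, ab_id, config)
        out[ab_id] = estimate_lod(series, min_positive_fraction)
    return out
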