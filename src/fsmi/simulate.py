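"""Forward model of the sandwich immunoassay.

The simulator generates spot tables with known ground truth, standing in for
field samples.  The signal model is a saturating (Langmuir-type) binding
curve: the loading of capture antibody ``i`` is

    theta_i = sum_j a[i][j] * c[j]

where ``a`` is the antibody x antigen relative-affinity matrix (cognate pairs
have affinity 1 by convention) and ``c[j]`` the antigen concentration in
cells/mL.  The noise-free spot signal is

    S_i = s_max * tracer_response(d) * theta_i / (k_half + theta_i)

with ``tracer_response`` a unimodal function of the tracer dilution ``d``
(too concentrated raises background binding, too dilute starves the
sandwich), modelled as a Gaussian in log10(d) peaking at the working optimum.

Observed foregrounds add a truncated-Gaussian background and multiply the
signal by lognormal noise ``exp(sigma * z)``; spots fail (are flagged
defective) independently with a small probability.  All defaults live in
``fsmi/data/defaults.yaml``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

from .chip import (
    ChipDefinition,
    ChipLayout,
    ControlKind,
    SpotFlag,
    SpotRecord,
    SpotTable,
    generate_layout,
)


def load_defaults() -> dict:
    """Load the packaged defaults file (single source of truth for emulation)."""
    text = resources.files("fsmi.data").joinpath("defaults.yaml").read_text(encoding="utf-8")
    return yaml.safe_load(text)


@dataclass
class AffinityMatrix:
    """Relative affinities in [0, 1] of each antibody (row) for each antigen (column)."""

    antibodies: list[str]
    antigens: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.antibodies), len(self.antigens)):
            raise ValueError("affinity matrix shape does not match id lists")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("affinities must lie in [0, 1]")

    @classmethod
    def identity(cls, ids: Sequence[str]) -> "AffinityMatrix":
        """Cognate-only panel: antigen IDs equal antibody IDs, diagonal affinity 1."""
        ids = list(ids)
        return cls(antibodies=ids, antigens=ids, values=np.eye(len(ids)))

    @classmethod
    def from_cross_reactions(
        cls, ids: Sequence[str], cross: Mapping[tuple[str, str], float]
    ) -> "AffinityMatrix":
        """Identity panel plus off-diagonal (antibody, antigen) -> affinity entries."""
        m = cls.identity(ids)
        for (ab, ag), a in cross.items():
            m.values[m.antibodies.index(ab), m.antigens.index(ag)] = a
        return m

    def affinity(self, antibody: str, antigen: str) -> float:
        return float(self.values[self.antibodies.index(antibody), self.antigens.index(antigen)])


@dataclass
class SampleComposition:
    """Antigen concentrations of a (simulated) sample, cells/mL."""

    concentrations: dict[str, float]

    def __post_init__(self) -> None:
        for ag, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for antigen {ag!r}: {c}")

    @classmethod
    def blank(cls) -> "SampleComposition":
        return cls(concentrations={})

    @property
    def positive_antigens(self) -> frozenset[str]:
        return frozenset(ag for ag, c in self.concentrations.items() if c > 0)


@dataclass
class BindingParams:
    """Saturating binding curve plus the tracer-dilution response."""

    s_max: float
    k_half: float
    tracer_optimum: float
    tracer_log_width: float
    tracer_response_fn: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        if self.s_max <= 0 or self.k_half <= 0:
            raise ValueError("s_max and k_half must be positive")

    @classmethod
    def default(cls) -> "BindingParams":
        return cls(**{k: v for k, v in load_defaults()["binding"].items()})

    def tracer_response(self, dilution: float) -> float:
        """Multiplicative factor in [0, 1]; 0 at zero tracer, 1 at the optimum."""
        if self.tracer_response_fn is not None:
            return float(self.tracer_response_fn(dilution))
        if dilution <= 0:
            return 0.0
        dx = math.log10(dilution) - math.log10(self.tracer_optimum)
        return math.exp(-(dx * dx) / (2.0 * self.tracer_log_width**2))


@dataclass
class NoiseModel:
    """Additive background + multiplicative lognormal signal noise + spot defects."""

    background_mean: float
    background_sd: float
    sigma: float
    defect_prob: float
    control_level: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_sd < 0 or self.sigma < 0:
            raise ValueError("noise scales must be non-negative")
        if not 0 <= self.defect_prob <= 1:
            raise ValueError("defect_prob must be in [0, 1]")

    @classmethod
    def default(cls, seed: int = 0) -> "NoiseModel":
        return cls(seed=seed, **load_defaults()["noise"])

    @classmethod
    def noise_free(cls, seed: int = 0) -> "NoiseModel":
        """Degenerate model for oracle tests: no background, no noise, no defects."""
        return cls(
            background_mean=0.0,
            background_sd=0.0,
            sigma=0.0,
            defect_prob=0.0,
            control_level=0.0,
            seed=seed,
        )


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside every simulated assay."""

    composition: SampleComposition
    affinity: AffinityMatrix
    expected_signal: dict[str, float]
    positives_truth: frozenset[str] = field(default_factory=frozenset)


def expected_signal(
    affinity: AffinityMatrix,
    composition: SampleComposition,
    binding: BindingParams,
    dilution: float | None = None,
) -> dict[str, float]:
    """Noise-free per-antibody signal under the saturating binding model."""
    if dilution is None:
        dilution = binding.tracer_optimum
    c = np.zeros(len(affinity.antigens))
    for ag, conc in composition.concentrations.items():
        if conc < 0:
            raise ValueError(f"negative concentration for antigen {ag!r}")
        try:
            c[affinity.antigens.index(ag)] = conc
        except ValueError:
            raise KeyError(f"antigen {ag!r} absent from affinity matrix") from None
    theta = affinity.values @ c
    tr = binding.tracer_response(dilution)
    with np.errstate(invalid="ignore"):
        s = binding.s_max * tr * theta / (binding.k_half + theta)
    s = np.where(theta > 0, s, 0.0)
    return dict(zip(affinity.antibodies, s.tolist()))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    return max(0.0, float(rng.normal(mean, sd))) if sd > 0 else max(0.0, mean)


def simulate_assay(
    chip: ChipDefinition,
    affinity: AffinityMatrix,
    composition: SampleComposition,
    binding: BindingParams | None = None,
    noise: NoiseModel | None = None,
    *,
    role: str = "sample",
    dilution: float | None = None,
    assay_id: str = "assay",
    field_index: int = 0,
    layout: ChipLayout | None = None,
    seed: int | None = None,
    metadata: Mapping[str, str] | None = None,
) -> tuple[SpotTable, SyntheticTruth]:
    """Simulate one assay field and return its spot table plus ground truth.

    ``role="blank"`` forces all antigen concentrations to zero (the parallel
    buffer-only assay revealed with the same tracer cocktail).  Identical
    seeds produce byte-identical tables.
    """
    binding = binding or BindingParams.default()
    noise = noise or NoiseModel.default()
    layout = layout or generate_layout(chip)
    if role == "blank":
        composition = SampleComposition.blank()
    if dilution is None:
        dilution = binding.tracer_optimum
    signal = expected_signal(affinity, composition, binding, dilution)
    missing = set(chip.antibody_ids) - set(signal)
    if missing:
        raise KeyError(f"chip antibodies absent from affinity matrix: {sorted(missing)}")
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    spots: list[SpotRecord] = []
    for f, r, c, assign in layout.positions(field_index):
        bg_fore = _truncated_normal(rng, noise.background_mean, noise.background_sd)
        bg_back = _truncated_normal(rng, noise.background_mean, noise.background_sd)
        z = float(rng.standard_normal())
        defective = bool(rng.uniform() < noise.defect_prob)
        if assign.kind == "antibody":
            level = signal[assign.probe_id]
        elif assign.kind == ControlKind.PREIMMUNE.value:
            level = noise.control_level
        else:  # BSA / buffer: chemically inert, background only
            level = 0.0
        f_fore = bg_fore + level * math.exp(noise.sigma * z)
        if defective:
            f_fore = 0.0  # missing/tiny spot: no measurable foreground
        spots.append(
            SpotRecord(
                field_index=f,
                row=r,
                col=c,
                probe_id=assign.probe_id,
                replicate_index=assign.replicate_index,
                f_fore=f_fore,
                f_back=bg_back,
                flag=SpotFlag.DEFECTIVE if defective else SpotFlag.OK,
            )
        )
    meta = {"dilution": repr(dilution), "seed": str(noise.seed if seed is None else seed)}
    if metadata:
        meta.update({k: str(v) for k, v in metadata.items()})
    table = SpotTable(assay_id=assay_id, role=role, spots=spots, metadata=meta)
    truth = SyntheticTruth(
        composition=composition,
        affinity=affinity,
        expected_signal=signal,
        positives_truth=composition.positive_antigens,
    )
    return table, truth


def simulate_assay_pair(
    chip: ChipDefinition,
    affinity: AffinityMatrix,
    composition: SampleComposition,
    binding: BindingParams | None = None,
    noise: NoiseModel | None = None,
    *,
    assay_id: str = "assay",
    seed: int = 0,
    **kwargs,
) -> tuple[SpotTable, SpotTable, SyntheticTruth]:
    """Convenience: a sample assay plus its parallel blank (independent seeds)."""
    ss = np.random.SeedSequence(seed)
    s_seed, b_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    sample, truth = simulate_assay(
        chip, affinity, composition, binding, noise,
        role="sample", assay_id=assay_id, seed=s_seed, **kwargs,
    )
    blank, _ = simulate_assay(
        chip, affinity, SampleComposition.blank(), binding, noise,
        role="blank", assay_id=f"{assay_id}-blank", seed=b_seed, **kwargs,
    )
    return sample, blank, truth


def simulate_titration(
    chip: ChipDefinition,
    antigen: str,
    concentrations: Sequence[float],
    affinity: AffinityMatrix | None = None,
    binding: BindingParams | None = None,
    noise: NoiseModel | None = None,
    *,
    replicates: int = 3,
    dilution: float | None = None,
    seed: int = 0,
) -> tuple[list[SpotTable], SpotTable]:
    """One single-antigen sample assay per concentration (x replicates) + shared blank.

    Concentration metadata is recorded on every table.  Concentrations must be
    strictly increasing; the zero point, if present, is model-identical to the
    blank.
    """
    if len(concentrations) == 0:
        raise ValueError("empty concentration list")
    if any(b <= a for a, b in zip(concentrations, concentrations[1:])):
        raise ValueError("concentrations must be strictly increasing")
    affinity = affinity or AffinityMatrix.identity(chip.antibody_ids)
    if antigen not in affinity.antigens:
        raise KeyError(f"antigen {antigen!r} absent from affinity matrix")
    binding = binding or BindingParams.default()
    noise = noise or NoiseModel.default()
    layout = generate_layout(chip)
    ss = np.random.SeedSequence(seed)
    seeds = iter(int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(len(concentrations) * replicates + 1))
    tables: list[SpotTable] = []
    for conc in concentrations:
        for rep in range(replicates):
            table, _ = simulate_assay(
                chip,
                affinity,
                SampleComposition({antigen: float(conc)}),
                binding,
                noise,
                role="titration_point",
                dilution=dilution,
                assay_id=f"{antigen}-c{conc:g}-r{rep}",
                layout=layout,
                seed=next(seeds),
                metadata={"antigen": antigen, "concentration": f"{conc:g}", "replicate": str(rep)},
            )
            tables.append(table)
    blank, _ = simulate_assay(
        chip, affinity, SampleComposition.blank(), binding, noise,
        role="blank", dilution=dilution, assay_id=f"{antigen}-blank",
        layout=layout, seed=next(seeds),
    )
    return tables, blank


def simulate_checkerboard(
    chip: ChipDefinition,
    antigens: Sequence[str] | None = None,
    affinity: AffinityMatrix | None = None,
    binding: BindingParams | None = None,
    noise: NoiseModel | None = None,
    *,
    concentration: float | None = None,
    seed: int = 0,
) -> tuple[dict[str, SpotTable], SpotTable, AffinityMatrix]:
    """Single-antigen x full-panel assays used to map cross-reactivity.

    Each antigen is assayed alone at a saturating concentration against the
    whole capture panel; a shared blank accompanies the set.
    """
    affinity = affinity or AffinityMatrix.identity(chip.antibody_ids)
    antigens = list(antigens) if antigens is not None else list(affinity.antigens)
    for ag in antigens:
        if ag not in affinity.antigens:
            raise KeyError(f"antigen {ag!r} absent from affinity matrix")
    if concentration is None:
        concentration = float(load_defaults()["simulate"]["checkerboard_concentration"])
    binding = binding or BindingParams.default()
    noise = noise or NoiseModel.default()
    layout = generate_layout(chip)
    ss = np.random.SeedSequence(seed)
    seeds = iter(int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(len(antigens) + 1))
    tables: dict[str, SpotTable] = {}
    for ag in antigens:
        table, _ = simulate_assay(
            chip,
            affinity,
            SampleComposition({ag: concentration}),
            binding,
            noise,
            role="sample",
            assay_id=f"checkerboard-{ag}",
            layout=layout,
            seed=next(seeds),
            metadata={"antigen": ag, "concentration": f"{concentration:g}"},
        )
        tables[ag] = table
    blank, _ = simulate_assay(
        chip, affinity, SampleComposition.blank(), binding, noise,
        role="blank", assay_id="checkerboard-blank", layout=layout, seed=next(seeds),
    )
    return tables, blank, affinity
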