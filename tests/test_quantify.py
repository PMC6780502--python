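"""Quantification pipeline: background subtraction, replicate QC, calls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fsmi.chip import SpotFlag, SpotRecord, SpotTable
from fsmi.errors import BaselineError, PairingError
from fsmi.quantify import (
    QCStatus,
    QuantConfig,
    background_subtract,
    control_baseline,
    final_fluorescence,
    quantify_assay,
    read_quant_tsv,
    replicate_qc,
)
from fsmi.simulate import (
    AffinityMatrix,
    BindingParams,
    NoiseModel,
    SampleComposition,
    simulate_assay,
    simulate_assay_pair,
)

from conftest import build_chip


def _spot(f_fore, f_back, flag=SpotFlag.OK):
    return SpotRecord(0, 0, 0, "AB1", 0, f_fore, f_back, flag)


class TestBackgroundSubtract:
    @pytest.mark.parametrize(
        "fore,back,expected", [(500.0, 100.0, 400.0), (100.0, 100.0, 0.0), (50.0, 100.0, 0.0)]
    )
    def test_clamped_subtraction(self, fore, back, expected):
        assert background_subtract(_spot(fore, back)) == expected

    def test_unclamped_when_configured(self):
        config = QuantConfig(clamp_negative=False)
        assert background_subtract(_spot(50.0, 100.0), config) == -50.0


class TestReplicateQC:
    @pytest.mark.parametrize(
        "values,status,aggregated",
        [
            ((100.0, 100.0, 100.0), QCStatus.OK, 100.0),  # zero spread
            ((50.0, 100.0, 150.0), QCStatus.EXCLUDED_CV, None),  # SD 50, ratio 0.5
            ((98.0, 100.0, 102.0), QCStatus.OK, 100.0),  # SD 2, ratio 0.02
            ((), QCStatus.EXCLUDED_MISSING, None),
            ((7.0,), QCStatus.OK, 7.0),  # single replicate: no spread to test
        ],
    )
    def test_exclusion_rule(self, values, status, aggregated):
        got_status, got_value = replicate_qc(values)
        assert got_status is status
        assert got_value == aggregated

    def test_exclusion_boundary_sits_at_cv_threshold(self):
        """Triplets (m-s, m, m+s) have sample SD exactly s; exclusion flips at s/m = 0.2."""
        mean = 100.0
        below = replicate_qc((mean - 19.9, mean, mean + 19.9))[0]
        above = replicate_qc((mean - 20.1, mean, mean + 20.1))[0]
        assert below is QCStatus.OK
        assert above is QCStatus.EXCLUDED_CV

    def test_median_aggregator(self):
        config = QuantConfig(replicate_aggregator="median")
        assert replicate_qc((90.0, 100.0, 104.0), config)[1] == 100.0


class TestControlBaseline:
    def _table(self, intensities, flag=SpotFlag.OK):
        spots = [
            SpotRecord(0, 0, i, "BSA", i, v, 0.0, flag) for i, v in enumerate(intensities)
        ]
        return SpotTable(assay_id="t", spots=spots)

    def test_mean_of_controls(self):
        assert control_baseline(self._table([10.0, 20.0, 30.0])) == 20.0

    def test_single_control(self):
        assert control_baseline(self._table([7.0])) == 7.0

    def test_all_defective_raises(self):
        with pytest.raises(BaselineError):
            control_baseline(self._table([10.0, 20.0], flag=SpotFlag.DEFECTIVE))


class TestFinalFluorescence:
    def test_hand_value_positive(self):
        f, positive = final_fluorescence(1000.0, 100.0, 200.0)
        assert f == 400.0 and positive

    def test_threshold_boundary_is_not_positive(self):
        f, positive = final_fluorescence(100.0 + 2.5 * 40.0, 100.0, 40.0)
        assert f == pytest.approx(0.0) and not positive

    def test_empty_assay(self):
        assert final_fluorescence(0.0, 0.0, 0.0) == (0.0, False)

    @given(
        f_sample=st.floats(0, 1e5),
        f_blank=st.floats(0, 1e5),
        f_avcontrol=st.floats(0, 1e4),
        delta=st.floats(1e-3, 1e4),
    )
    @settings(derandomize=True, max_examples=200)
    def test_monotonicity(self, f_sample, f_blank, f_avcontrol, delta):
        """F rises with sample signal and falls with blank and control baseline."""
        base, _ = final_fluorescence(f_sample, f_blank, f_avcontrol)
        assert final_fluorescence(f_sample + delta, f_blank, f_avcontrol)[0] > base
        assert final_fluorescence(f_sample, f_blank + delta, f_avcontrol)[0] < base
        assert final_fluorescence(f_sample, f_blank, f_avcontrol + delta)[0] < base

    def test_positive_call_infimum_recovers_multiplier(self):
        """With no blank and unit-scaled controls, the calling boundary sits at 2.5x."""
        c = 100.0
        lo, hi = 0.0, 10_000.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if final_fluorescence(mid, 0.0, c)[1]:
                hi = mid
            else:
                lo = mid
        assert hi / c == pytest.approx(2.5, abs=1e-9)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def brute_force_quantify(sample, blank, chip, config):
    """Independent naive re-computation of the whole pipeline (loops, no reuse)."""
    def subtracted(table, probe):
        out = []
        for s in table.spots:
            if s.probe_id == probe and s.flag is SpotFlag.OK:
                d = s.f_fore - s.f_back
                if config.clamp_negative and d < 0:
                    d = 0.0
                out.append(d)
        return out

    control_vals = []
    for s in sample.spots:
        if s.probe_id in ("BSA", "buffer", "preimmune") and s.flag is SpotFlag.OK:
            d = s.f_fore - s.f_back
            control_vals.append(max(0.0, d) if config.clamp_negative else d)
    baseline = sum(control_vals) / len(control_vals)

    def component(table, probe):
        has_any = any(s.probe_id == probe for s in table.spots)
        if not has_any:
            return "excluded_missing", None
        vals = subtracted(table, probe)
        if not vals:
            return "excluded_defective", None
        mean = sum(vals) / len(vals)
        if mean > baseline and len(vals) >= 2:
            var = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
            if mean > 0 and math.sqrt(var) > config.cv_threshold * mean:
                return "excluded_cv", None
        if config.replicate_aggregator == "median":
            agg = float(np.median(vals))
        else:
            agg = mean
        return "ok", agg

    result = {}
    for ab in chip.antibody_ids:
        status_s, f_s = component(sample, ab)
        status_b, f_b = component(blank, ab)
        status = status_s if status_s != "ok" else status_b
        if status != "ok":
            result[ab] = (status, f_s, f_b, None, False)
            continue
        f = f_s - f_b - config.stringency_multiplier * baseline
        result[ab] = ("ok", f_s, f_b, f, f > 0)
    return baseline, result


class TestQuantifyAssay:
    def _simulated_pair(self, chip, concentrations, seed, noise=None):
        aff = AffinityMatrix.identity(chip.antibody_ids)
        return simulate_assay_pair(
            chip, aff, SampleComposition(concentrations),
            noise=noise or NoiseModel.default(), seed=seed,
        )

    def test_noise_free_cognate_call(self):
        chip = build_chip(n_antibodies=4)
        binding = BindingParams.default()
        aff = AffinityMatrix.identity(chip.antibody_ids)
        comp = SampleComposition({"AB3": 10 * binding.k_half})
        sample, _ = simulate_assay(chip, aff, comp, binding, NoiseModel.noise_free(), seed=0)
        blank, _ = simulate_assay(
            chip, aff, SampleComposition.blank(), binding, NoiseModel.noise_free(),
            role="blank", seed=1,
        )
        quant = quantify_assay(sample, blank, chip)
        assert quant.positives == ["AB3"]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        """Naive loop re-computation agrees exactly on small noisy assays."""
        chip = build_chip(n_antibodies=5, control_spot_count=6)
        rng = np.random.default_rng(seed)
        concs = {ab: float(rng.choice([0.0, 1e3, 1e5, 1e6])) for ab in chip.antibody_ids}
        noise = NoiseModel.default(seed=seed)
        sample, blank, _ = self._simulated_pair(chip, concs, seed, noise)
        config = QuantConfig()
        quant = quantify_assay(sample, blank, chip, config)
        baseline, expected = brute_force_quantify(sample, blank, chip, config)
        assert quant.f_avcontrol == pytest.approx(baseline)
        for ab, (status, f_s, f_b, f_final, positive) in expected.items():
            row = quant.rows[ab]
            assert row.qc_status.value == status
            assert row.positive == positive
            if f_final is None:
                assert row.f_final is None
            else:
                assert row.f_final == pytest.approx(f_final)

    def test_missing_antibody_marked(self, tiny_chip):
        sample, blank, _ = self._simulated_pair(tiny_chip, {}, seed=0)
        sample.spots = [s for s in sample.spots if s.probe_id != "AB2"]
        blank.spots = [s for s in blank.spots if s.probe_id != "AB2"]
        quant = quantify_assay(sample, blank, tiny_chip)
        assert quant.rows["AB2"].qc_status is QCStatus.EXCLUDED_MISSING
        assert not quant.rows["AB2"].positive

    def test_layout_mismatch_is_pairing_error(self, tiny_chip):
        sample, blank, _ = self._simulated_pair(tiny_chip, {}, seed=0)
        moved = blank.spots[0]
        blank.spots[0] = SpotRecord(
            moved.field_index, moved.row + 7, moved.col, moved.probe_id,
            moved.replicate_index, moved.f_fore, moved.f_back, moved.flag,
        )
        with pytest.raises(PairingError):
            quantify_assay(sample, blank, tiny_chip)

    def test_quant_tsv_round_trip(self, tiny_chip, tmp_path):
        sample, blank, _ = self._simulated_pair(tiny_chip, {"AB1": 1e6}, seed=5)
        quant = quantify_assay(sample, blank, tiny_chip)
        path = tmp_path / "quant.tsv"
        quant.write_tsv(path)
        back = read_quant_tsv(path)
        assert back.assay_id == quant.assay_id
        assert back.positives == quant.positives
        for ab, row in quant.rows.items():
            assert back.rows[ab].qc_status is row.qc_status
            if row.f_final is not None:
                assert back.rows[ab].f_final == pytest.approx(row.f_final)
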