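"""Local evidence scoring against brute-force oracles, and re-ranking."""

import numpy as np
import pytest

from nmr2struct.decoding import Candidate
from nmr2struct.rerank import (
    EvidenceScoreParams,
    ShiftPrediction,
    evidence_score_1d,
    evidence_score_hsqc,
    rerank_candidates,
    toy_shift_predictor,
)
from nmr2struct.spectra import (
    Nucleus,
    PeakList1D,
    PpmGrid,
    Spectrum1D,
    SpectrumHSQC,
    render_peaklist_1d,
)
from nmr2struct.synthetic import assign_toy_shifts, simulate_record, MoleculeRecord

RNG = np.random.default_rng(11)


def brute_force_1d(y, grid_values, shifts, sigma):
    """Independent O(N*P) double summation of the evidence score."""
    total = 0.0
    for s in shifts:
        num = den = 0.0
        for j, d in enumerate(grid_values):
            k = np.exp(-((d - s) ** 2) / (2 * sigma**2))
            num += k * y[j]
            den += k
        total += num / den
    return total / len(shifts)


def brute_force_hsqc(img, h_values, c_values, pairs, sigma_h, sigma_c):
    total = 0.0
    for (hs, cs) in pairs:
        num = den = 0.0
        for i, h in enumerate(h_values):
            for j, c in enumerate(c_values):
                k = np.exp(
                    -((h - hs) ** 2) / (2 * sigma_h**2)
                    - ((c - cs) ** 2) / (2 * sigma_c**2)
                )
                num += k * img[i, j]
                den += k
        total += num / den
    return total / len(pairs)


class TestEvidence1D:
    grid = PpmGrid(0.0, 10.0, 200)

    def spec(self, y):
        return Spectrum1D(Nucleus.H1, self.grid, y, normalized=True)

    def test_uniform_spectrum_scores_one(self):
        assert evidence_score_1d(
            self.spec(np.ones(200)), [1.0, 5.0, 9.0], sigma=0.2
        ) == pytest.approx(1.0)

    def test_zero_spectrum_scores_zero(self):
        assert evidence_score_1d(self.spec(np.zeros(200)), [5.0], sigma=0.2) == 0.0

    def test_matches_brute_force_on_random_instances(self):
        for _ in range(30):
            y = RNG.random(200)
            shifts = RNG.uniform(0, 10, size=RNG.integers(1, 5))
            sigma = float(RNG.uniform(0.05, 1.0))
            exact = evidence_score_1d(
                self.spec(y), shifts, sigma, kernel_truncate=None
            )
            oracle = brute_force_1d(y, self.grid.values(), shifts, sigma)
            assert exact == pytest.approx(oracle, abs=1e-9)

    def test_locality(self):
        spec = render_peaklist_1d(
            PeakList1D(Nucleus.H1, [(2.0, 1.0)]), self.grid, 0.1
        )
        on_peak = evidence_score_1d(spec, [2.0], sigma=0.2)
        off_peak = evidence_score_1d(spec, [8.0], sigma=0.2)
        assert on_peak > off_peak

    def test_appending_dead_region_shift_strictly_lowers_positive_score(self):
        spec = render_peaklist_1d(
            PeakList1D(Nucleus.H1, [(2.0, 1.0)]), self.grid, 0.1
        )
        base = evidence_score_1d(spec, [2.0], sigma=0.2)
        worse = evidence_score_1d(spec, [2.0, 9.5], sigma=0.2)
        assert base > 0
        assert worse < base

    def test_invariance_under_positive_rescaling(self):
        from nmr2struct.spectra import normalize_instance

        y = RNG.random(200) * 3.0
        raw = Spectrum1D(Nucleus.H1, self.grid, y)
        scaled = Spectrum1D(Nucleus.H1, self.grid, 5.0 * y + 2.0)
        a = evidence_score_1d(normalize_instance(raw), [3.0, 7.0], 0.3)
        b = evidence_score_1d(normalize_instance(scaled), [3.0, 7.0], 0.3)
        assert a == pytest.approx(b, abs=1e-12)

    def test_truncated_kernel_close_to_exact(self):
        y = RNG.random(200)
        shifts = [2.5, 6.0]
        exact = evidence_score_1d(self.spec(y), shifts, 0.2, kernel_truncate=None)
        trunc = evidence_score_1d(self.spec(y), shifts, 0.2, kernel_truncate=5.0)
        assert trunc == pytest.approx(exact, abs=1e-6)

    def test_empty_shifts_rejected(self):
        with pytest.raises(ValueError):
            evidence_score_1d(self.spec(np.ones(200)), [], 0.2)

    def test_far_outside_shift_warns_and_contributes_nothing(self):
        with pytest.warns(UserWarning, match="outside"):
            score = evidence_score_1d(self.spec(np.ones(200)), [1.0, 500.0], 0.2)
        assert score == pytest.approx(0.5, abs=1e-6)


class TestEvidenceHSQC:
    h_grid = PpmGrid(0.0, 12.0, 8)
    c_grid = PpmGrid(0.0, 200.0, 8)

    def test_uniform_matrix_scores_one(self):
        spec = SpectrumHSQC(self.h_grid, self.c_grid, np.ones((8, 8)), normalized=True)
        assert evidence_score_hsqc(spec, [(3.0, 50.0)], 0.5, 10.0) == pytest.approx(1.0)

    def test_matches_brute_force_on_random_instances(self):
        for _ in range(20):
            img = RNG.random((8, 8))
            spec = SpectrumHSQC(self.h_grid, self.c_grid, img, normalized=True)
            pairs = [
                (float(RNG.uniform(0, 12)), float(RNG.uniform(0, 200)))
                for _ in range(2)
            ]
            sh = float(RNG.uniform(0.2, 2.0))
            sc = float(RNG.uniform(2.0, 30.0))
            exact = evidence_score_hsqc(spec, pairs, sh, sc, kernel_truncate=None)
            oracle = brute_force_hsqc(
                img, self.h_grid.values(), self.c_grid.values(), pairs, sh, sc
            )
            assert exact == pytest.approx(oracle, abs=1e-9)

    def test_cross_peak_locality(self):
        rec = MoleculeRecord.from_smiles("CCO")
        spec = simulate_record(rec, ("HSQC",), noise_sd=0.0)["HSQC"]
        pairs = assign_toy_shifts("CCO").hc_pairs
        on = evidence_score_hsqc(spec, [pairs[0]], 0.2, 2.0)
        off = evidence_score_hsqc(spec, [(pairs[0][0], 190.0)], 0.2, 2.0)
        assert on > off


class TestRerank:
    def _spectra_for(self, smiles):
        rec = MoleculeRecord.from_smiles(smiles)
        return {
            "C13": simulate_record(rec, ("C13",), noise_sd=0.0)["C13"],
        }

    def test_single_candidate_order_unchanged_score_populated(self):
        cands = [Candidate("CCO", -0.5, 1, True, True)]
        out = rerank_candidates(cands, self._spectra_for("CCO"))
        assert len(out) == 1
        assert out[0].smiles == "CCO"
        assert out[0].evidence_score is not None
        assert cands[0].evidence_score is None  # input untouched

    def test_true_molecule_promoted_from_rank_5(self):
        # pool of formula-consistent C5H12O isomers; the true molecule sits
        # at source rank 5 but is the only one whose toy shifts coincide
        # with the synthetic spectrum
        target = "CCCCCO"
        pool_smiles = ["CCCC(C)O", "CCC(C)CO", "CC(C)CCO", "CCC(CC)O", target]
        cands = [
            Candidate(s, -0.1 * (i + 1), i + 1, True, True)
            for i, s in enumerate(pool_smiles)
        ]
        out = rerank_candidates(cands, self._spectra_for(target))
        assert out[0].smiles == target

    def test_identical_molecules_tie_broken_by_log_prob(self):
        cands = [
            Candidate("CCO", -0.2, 1, True, True),
            Candidate("CCO", -0.9, 2, True, True),
        ]
        out = rerank_candidates(cands, self._spectra_for("CCO"))
        assert out[0].log_prob == pytest.approx(-0.2)

    def test_predictor_failure_ranks_last_with_warning(self):
        def flaky(smiles):
            if smiles == "CCN":
                raise RuntimeError("boom")
            return toy_shift_predictor(smiles)

        cands = [
            Candidate("CCN", -0.1, 1, True, True),
            Candidate("CCO", -0.5, 2, True, True),
        ]
        with pytest.warns(UserWarning, match="failed"):
            out = rerank_candidates(cands, self._spectra_for("CCO"), flaky)
        assert out[-1].smiles == "CCN"
        assert len(out) == 2

    def test_mean_mode_uses_all_modalities(self):
        rec = MoleculeRecord.from_smiles("CCO")
        spectra = simulate_record(rec, ("H1", "C13"), noise_sd=0.0)
        cands = [Candidate("CCO", -0.5, 1, True, True)]
        auto = rerank_candidates(cands, spectra, mode="auto")
        mean = rerank_candidates(cands, spectra, mode="mean")
        assert auto[0].evidence_score != pytest.approx(mean[0].evidence_score)


class TestToyPredictor:
    def test_environment_counts_for_ethanol(self):
        pred = toy_shift_predictor("CCO")
        assert len(pred.c_shifts) == 2
        assert len(pred.h_shifts) == 3

    def test_deterministic(self):
        a = toy_shift_predictor("CC(=O)Oc1ccccc1")
        b = toy_shift_predictor("CC(=O)Oc1ccccc1")
        assert a == b

    def test_matches_generator_shifts_exactly(self):
        assign = assign_toy_shifts("CCCO")
        pred = toy_shift_predictor("CCCO")
        assert pred.h_shifts == assign.h_shifts
        assert pred.c_shifts == assign.c_shifts
        assert pred.hc_pairs == assign.hc_pairs

    def test_invalid_smiles_rejected(self):
        with pytest.raises(ValueError):
            toy_shift_predictor("C(C")


def test_json_predictor_adapter():
    from nmr2struct.rerank import shift_prediction_from_json

    pred = shift_prediction_from_json(
        {"h": [1.0, 7.3], "c": [15.0], "hc": [[1.0, 15.0]]}
    )
    assert pred.h_shifts == [1.0, 7.3]
    assert pred.c_shifts == [15.0]
    assert pred.hc_pairs == [(1.0, 15.0)]
    assert pred.h_weights is None


def test_evidence_params_validation():
    with pytest.raises(ValueError):
        EvidenceScoreParams(sigma_h=0.0)
    with pytest.raises(ValueError):
        EvidenceScoreParams(power=-1.0)
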