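"""Sensitivities, Fisher information, correlation and pseudo-global analysis."""

import numpy as np
import pandas as pd
import pytest

from kdpselect.identifiability import (
    FIMatrix,
    NonIdentifiableError,
    correlation_from_fim,
    fisher_information,
    local_analysis,
    msqr_indices,
    pseudo_global_analysis,
    relative_sensitivities,
    sobol_sample,
    SensitivityMatrix,
)
from kdpselect.objective import ModelObjective
from kdpselect.synthetic_data import NOMINAL_STRUCTURE


def _manual_sm(values, raw=None, params=None):
    values = np.asarray(values, dtype=float)
    params = params or tuple(f"p{i}" for i in range(values.shape[1]))
    return SensitivityMatrix(
        values=values, raw=values if raw is None else np.asarray(raw, dtype=float),
        parameters=tuple(params),
        row_index=pd.DataFrame({"experiment_id": "e", "variable": "v",
                                "time_h": np.arange(values.shape[0], dtype=float)}),
    )


class TestRelativeSensitivities:
    def test_linear_model_gives_unit_sensitivity(self, tiny_dataset, nominal, monkeypatch):
        # y = ktr * t  ->  S = (ktr/y) dy/dktr = 1 at every t > 0
        s, p = nominal
        times = tiny_dataset.experiments[0].table["time_h"].to_numpy()
        monkeypatch.setattr(ModelObjective, "predict",
                            lambda self, s_, p_: p_.ktr * np.maximum(times, 1e-3))
        sm = relative_sensitivities(s, p, tiny_dataset, parameters=("ktr",))
        np.testing.assert_allclose(sm.values[:, 0], 1.0, rtol=1e-8)

    def test_mutant_data_insensitive_to_khy(self, mutant_dataset, nominal):
        s, p = nominal
        sm = relative_sensitivities(s, p, mutant_dataset, parameters=("khy", "ktl3"))
        np.testing.assert_array_equal(sm.values[:, 0], 0.0)
        assert np.any(sm.values[:, 1] != 0.0)

    def test_step_halving_self_convergence(self, tiny_dataset, nominal):
        s, p = nominal
        a = relative_sensitivities(s, p, tiny_dataset, rel_step=1e-4,
                                   parameters=("ktr", "kz"))
        b = relative_sensitivities(s, p, tiny_dataset, rel_step=5e-5,
                                   parameters=("ktr", "kz"))
        scale = np.max(np.abs(b.values))
        assert np.max(np.abs(a.values - b.values)) / scale < 1e-4


class TestMsqr:
    def test_zero_column_and_single_entry(self):
        sm = _manual_sm([[0.0, 2.0], [0.0, 0.0]])
        idx = msqr_indices(sm)
        assert idx["p0"] == 0.0
        assert idx["p1"] == 4.0

    def test_dataset_duplication_doubles_indices(self):
        base = np.array([[1.0, -2.0], [0.5, 0.3]])
        one = msqr_indices(_manual_sm(base))
        two = msqr_indices(_manual_sm(np.vstack([base, base])))
        np.testing.assert_allclose(two.to_numpy(), 2.0 * one.to_numpy())
        assert list(one.sort_values(ascending=False).index) == \
            list(two.sort_values(ascending=False).index)

    def test_rms_variant(self):
        sm = _manual_sm([[2.0], [0.0]])
        assert msqr_indices(sm, "rms")["p0"] == pytest.approx(np.sqrt(2.0))


class TestFisherInformation:
    def test_scalar_case(self):
        raw = np.array([[1.0], [2.0], [3.0]])
        sig = np.array([1.0, 0.5, 2.0])
        fim = fisher_information(raw, sigmas=sig)
        assert fim.values[0, 0] == pytest.approx(np.sum((raw[:, 0] / sig) ** 2))

    def test_duplicated_parameter_gives_rank_one(self):
        col = np.array([[1.0], [2.0], [-1.0]])
        fim = fisher_information(np.hstack([col, col]), sigmas=np.ones(3))
        rank, _ = fim.rank()
        assert rank == 1

    def test_matches_denormalised_sensitivities(self, tiny_dataset, nominal):
        # the Fisher matrix assembled from raw derivatives must equal the one
        # rebuilt from the normalised sensitivities S * y / theta
        s, p = nominal
        sm = relative_sensitivities(s, p, tiny_dataset, parameters=("ktr", "DNA0"))
        mo = ModelObjective(tiny_dataset)
        y = mo.predict(s, p)
        theta = np.array([p.ktr, p.DNA0])
        raw_back = sm.values * y[:, None] / theta
        fim_a = fisher_information(sm, tiny_dataset)
        fim_b = fisher_information(raw_back, sigmas=tiny_dataset.sigmas)
        np.testing.assert_allclose(fim_a.values, fim_b.values, rtol=1e-10)

    def test_psd_and_symmetric(self, tiny_dataset, nominal):
        s, p = nominal
        sm = relative_sensitivities(s, p, tiny_dataset, parameters=("ktr", "kz", "kd"))
        fim = fisher_information(sm, tiny_dataset)
        np.testing.assert_allclose(fim.values, fim.values.T)
        assert np.min(np.linalg.eigvalsh(fim.values)) > -1e-6 * np.max(fim.values)


class TestCorrelation:
    def test_diagonal_fim_gives_identity(self):
        fim = FIMatrix(np.diag([2.0, 5.0, 0.1]), ("a", "b", "c"))
        np.testing.assert_allclose(correlation_from_fim(fim), np.eye(3), atol=1e-14)

    def test_hand_inverted_two_by_two(self):
        fim = FIMatrix(np.array([[2.0, 1.0], [1.0, 2.0]]), ("a", "b"))
        C = correlation_from_fim(fim)
        assert C[0, 1] == pytest.approx(-0.5)
        np.testing.assert_allclose(np.diag(C), 1.0)

    def test_rank_deficient_raises(self):
        fim = FIMatrix(np.array([[1.0, 1.0], [1.0, 1.0]]), ("a", "b"))
        with pytest.raises(NonIdentifiableError):
            correlation_from_fim(fim)

    def test_entries_within_unit_interval(self, ident_dataset, nominal):
        # restrict to strongly informative, non-degenerate parameters: ktl
        # acts only through the small reverse-phosphotransfer term, and ktr/K
        # enter transcription almost exclusively as the ratio ktr/K — either
        # would park the rank decision at the numerical cutoff
        s, p = nominal
        report = local_analysis(
            s, p, ident_dataset,
            parameters=("ktr", "kz", "alpha", "ktl2", "DNA0", "kd", "khy"),
        )
        assert report.identifiable
        C = report.correlation
        assert np.all(C <= 1.0) and np.all(C >= -1.0)
        np.testing.assert_allclose(np.diag(C), 1.0)


class TestPseudoGlobal:
    @pytest.fixture()
    def small_bounds(self, nominal):
        _, p = nominal
        active = NOMINAL_STRUCTURE.active_reals()
        centre = np.log10([getattr(p, n) for n in active])
        return np.column_stack([centre - 0.05, centre + 0.05])

    def test_weights_normalise_and_points_in_bounds(self, ident_dataset, nominal, small_bounds):
        s, p = nominal
        report = pseudo_global_analysis(s, p, small_bounds, ident_dataset,
                                        n_points=8, seed=1)
        assert report.weights.sum() == pytest.approx(1.0)
        assert report.identifiable
        X = sobol_sample(small_bounds, 16, seed=3)
        assert np.all(X >= small_bounds[:, 0]) and np.all(X <= small_bounds[:, 1])

    def test_uniform_weighting_is_plain_mean(self, ident_dataset, nominal, small_bounds):
        s, p = nominal
        report = pseudo_global_analysis(s, p, small_bounds, ident_dataset,
                                        n_points=8, seed=1, weighting="uniform")
        np.testing.assert_allclose(report.weights, 1.0 / report.weights.size)

    def test_inflated_noise_flattens_weights(self, ident_dataset, nominal, small_bounds):
        # multiply all sigmas: likelihood differences shrink, weights approach uniform
        import copy

        s, p = nominal
        sharp = pseudo_global_analysis(s, p, small_bounds, ident_dataset,
                                       n_points=8, seed=1)
        flat_ds = copy.deepcopy(ident_dataset)
        flat_ds.sigmas = flat_ds.sigmas * 10.0
        flat_ds.sigma_log_term = float(
            -0.5 * np.sum(np.log(2.0 * np.pi * flat_ds.sigmas**2)))
        for e in flat_ds.experiments:
            e.table = e.table.assign(sigma=e.table["sigma"] * 10.0)
        flat = pseudo_global_analysis(s, p, small_bounds, flat_ds, n_points=8, seed=1)
        def spread(w):
            return np.max(w) - np.min(w)
        assert spread(flat.weights) < spread(sharp.weights)
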