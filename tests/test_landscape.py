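"""PCA landscape, reference projection, extreme selection, PC1-TM correlation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from altconf.errors import DomainError, InputError, UndefinedCorrelationError
from altconf.fixtures import _ideal_trace, make_end_states, make_ensemble
from altconf.landscape import (
    fit_landscape,
    pc_tm_correlation,
    project_reference,
    select_extremes,
)
from altconf.structures import StructureModel
from altconf.superpose import align_ensemble
from altconf.ensemble_stats import filter_misfolded
from oracles import pearson_definitional


def as_model(coords, model_id="m"):
    n = len(coords)
    return StructureModel(model_id, np.arange(1, n + 1), "A" * n, coords)


def interpolation_ensemble(n_models=9, n_res=20):
    """Noiseless linear interpolation between two fixed states."""
    a = _ideal_trace(n_res)
    b = a + np.linspace(0, 1, n_res)[:, None] * np.array([4.0, 0, 0])
    ts = np.linspace(0.1, 0.9, n_models)
    models = [as_model((1 - t) * a + t * b, f"m{k:02d}") for k, t in enumerate(ts)]
    return models, as_model(a, "refA"), as_model(b, "refB")


ALL20 = np.arange(1, 21)


class TestFitLandscape:
    def test_rank_one_ensemble_pc1_fraction_one(self):
        models, _, _ = interpolation_ensemble()
        scape = fit_landscape(models, include_mask=ALL20)
        assert scape.variance_fractions[0] == pytest.approx(1.0, abs=1e-8)

    def test_two_orthogonal_modes_match_eigen_oracle(self):
        """Ensemble built from two orthonormal modes with 9:1 coefficient
        variance: fractions (0.9, 0.1), components matching a direct
        eigendecomposition of the constructed covariance."""
        rng = np.random.default_rng(8)
        base = _ideal_trace(20).ravel()
        m1 = rng.normal(size=60)
        m1 /= np.linalg.norm(m1)
        m2 = rng.normal(size=60)
        m2 -= (m2 @ m1) * m1
        m2 /= np.linalg.norm(m2)
        c1 = np.array([3.0, 3.0, -3.0, -3.0])
        c2 = np.array([1.0, -1.0, 1.0, -1.0])
        models = [
            as_model((base + a * m1 + b * m2).reshape(-1, 3), f"m{k}")
            for k, (a, b) in enumerate(zip(c1, c2))
        ]
        scape = fit_landscape(models, include_mask=ALL20)
        cov = 9.0 * np.outer(m1, m1) + 1.0 * np.outer(m2, m2)
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(
            scape.variance_fractions[:2], evals[:2] / evals.sum(), atol=1e-6)
        np.testing.assert_allclose(scape.variance_fractions[:2], [0.9, 0.1], atol=1e-6)
        assert abs(scape.components[0] @ m1) == pytest.approx(1.0, abs=1e-8)

    def test_components_orthonormal_and_fractions_sum_to_one(self, ensemble):
        models, labels = ensemble
        kept = [m for m in models if labels[m.model_id] != "decoy"]
        scape = fit_landscape(align_ensemble(kept))
        gram = scape.components @ scape.components.T
        np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-8)
        assert scape.variance_fractions.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.all(np.diff(scape.variance_fractions) <= 1e-12)

    def test_reconstruction_exact_from_full_basis(self):
        models, _, _ = interpolation_ensemble()
        rng = np.random.default_rng(1)
        noisy = [as_model(m.coords + rng.normal(0, 0.3, m.coords.shape), m.model_id)
                 for m in models]
        scape = fit_landscape(noisy, include_mask=ALL20)
        for m in noisy[:3]:
            flat = m.coords.ravel()
            proj = scape.projections[m.model_id]
            recon = scape.mean_coords + proj @ scape.components
            np.testing.assert_allclose(recon, flat, atol=1e-6)

    def test_mean_projects_to_origin(self):
        models, _, _ = interpolation_ensemble()
        scape = fit_landscape(models, include_mask=ALL20)
        mean_model = as_model(scape.mean_coords.reshape(-1, 3), "mean")
        proj = project_reference(scape, mean_model, store=False)
        np.testing.assert_allclose(proj, 0.0, atol=1e-8)

    def test_invariant_under_common_rigid_transform(self, ensemble, rng):
        models, labels = ensemble
        kept = [m for m in models if labels[m.model_id] != "decoy"][:15]
        rot, trans = Rotation.random(rng=rng).as_matrix(), rng.normal(0, 5, 3)
        moved = [m.with_coords(m.coords @ rot.T + trans) for m in kept]
        f1 = fit_landscape(align_ensemble(kept)).variance_fractions
        f2 = fit_landscape(align_ensemble(moved)).variance_fractions
        np.testing.assert_allclose(f1, f2, atol=1e-8)

    def test_too_few_models(self):
        models, _, _ = interpolation_ensemble(n_models=2)
        with pytest.raises(DomainError):
            fit_landscape(models, include_mask=ALL20)


class TestProjectReference:
    def test_end_states_flank_and_straddle_with_opposite_signs(self):
        models, ref_a, ref_b = interpolation_ensemble()
        scape = fit_landscape(align_ensemble(models), include_mask=ALL20)
        pa = project_reference(scape, ref_a)
        pb = project_reference(scape, ref_b)
        scape.orient("refA")
        pa, pb = scape.reference_projections["refA"], scape.reference_projections["refB"]
        assert pa[0] < 0 < pb[0]
        pc1 = [p[0] for p in scape.projections.values()]
        assert pa[0] < min(pc1) and pb[0] > max(pc1)

    def test_member_model_projects_to_stored_projection(self):
        """Holds for mean-aligned ensembles, where each model is already
        superposition-optimal with respect to the mean."""
        models, _, _ = interpolation_ensemble()
        aligned = align_ensemble(models)
        scape = fit_landscape(aligned, include_mask=ALL20)
        proj = project_reference(scape, aligned[3], store=False)
        np.testing.assert_allclose(proj, scape.projections["m03"], atol=1e-6)

    def test_missing_masked_residue_lists_it(self):
        models, ref_a, _ = interpolation_ensemble()
        scape = fit_landscape(models, include_mask=ALL20)
        short = StructureModel("short", ref_a.residue_ids[:-1], ref_a.sequence[:-1],
                               ref_a.coords[:-1])
        with pytest.raises(InputError, match="20"):
            project_reference(scape, short)


class TestSelectExtremes:
    def _scape_with_pc1(self, values):
        models, _, _ = interpolation_ensemble(n_models=len(values))
        scape = fit_landscape(models, include_mask=ALL20)
        for mid, v in zip(sorted(scape.projections), values):
            scape.projections[mid] = np.array([float(v)])
        return scape

    def test_high_side_top1(self):
        scape = self._scape_with_pc1([-3, -1, 0, 2, 5])
        assert select_extremes(scape, 1, "high") == ["m04"]

    def test_low_side_ordering_outermost_first(self):
        scape = self._scape_with_pc1([-3, -1, 0, 2, 5])
        assert select_extremes(scape, 2, "low") == ["m00", "m01"]

    def test_k_equals_ensemble_size(self):
        scape = self._scape_with_pc1([-3, -1, 0, 2, 5])
        assert select_extremes(scape, 5, "high") == ["m04", "m03", "m02", "m01", "m00"]

    def test_ties_broken_lexicographically(self):
        scape = self._scape_with_pc1([1, 1, 0, 1, -2])
        assert select_extremes(scape, 2, "high") == ["m00", "m01"]

    def test_k_zero_empty(self):
        scape = self._scape_with_pc1([1, 2, 3])
        assert select_extremes(scape, 0, "high") == []


class TestPcTmCorrelation:
    def test_affine_tm_gives_unit_correlation(self):
        models, _, _ = interpolation_ensemble()
        scape = fit_landscape(models, include_mask=ALL20)
        tm = {mid: 0.5 + 0.01 * p[0] for mid, p in scape.projections.items()}
        assert abs(pc_tm_correlation(scape, tm)) == pytest.approx(1.0)

    def test_matches_definitional_oracle(self):
        models, _, _ = interpolation_ensemble(n_models=5)
        scape = fit_landscape(models, include_mask=ALL20)
        tm = {"m00": 0.91, "m01": 0.85, "m02": 0.78, "m03": 0.80, "m04": 0.70}
        mids = sorted(tm)
        expected = pearson_definitional(
            np.array([scape.projections[m][0] for m in mids]),
            np.array([tm[m] for m in mids]))
        assert pc_tm_correlation(scape, tm) == pytest.approx(expected, abs=1e-12)

    def test_shuffled_tm_uncorrelated_vs_permutation_null(self):
        """TM values decoupled from PC1 give |r| typical of the permutation
        null rather than of the coupled case."""
        models, _, _ = interpolation_ensemble(n_models=30)
        scape = fit_landscape(models, include_mask=ALL20)
        rng = np.random.default_rng(11)
        pc1 = np.array([scape.projections[f"m{k:02d}"][0] for k in range(30)])
        coupled = 0.5 + 0.005 * pc1
        shuffled = rng.permutation(coupled)
        r_obs = abs(pc_tm_correlation(scape, {f"m{k:02d}": shuffled[k] for k in range(30)}))
        null = []
        for _ in range(500):
            perm = rng.permutation(coupled)
            null.append(abs(pearson_definitional(pc1, perm)))
        # the shuffled |r| is unexceptional under the null ...
        assert np.mean(np.array(null) >= r_obs) > 0.01
        # ... while the coupled |r| is essentially never reached
        assert np.mean(np.array(null) >= 0.99) == 0.0

    def test_zero_variance_error(self):
        models, _, _ = interpolation_ensemble(n_models=5)
        scape = fit_landscape(models, include_mask=ALL20)
        with pytest.raises(UndefinedCorrelationError):
            pc_tm_correlation(scape, {f"m{k:02d}": 0.8 for k in range(5)})


class TestHingeRecovery:
    def test_pc1_recovers_hinge_mode_and_references_flank(self, default_spec, ensemble, end_states):
        """PC1 of the aligned fixture ensemble points along the injected
        hinge mode (|cos| >= 0.99) and the end-state references flank every
        model's PC1 projection."""
        models, labels = ensemble
        state_a, state_b = end_states
        report = filter_misfolded(models)
        kept = [m for m in models if m.model_id in set(report.kept)]
        aligned = align_ensemble(kept)
        scape = fit_landscape(aligned)
        project_reference(scape, state_a)
        project_reference(scape, state_b)
        scape.orient("stateA")
        mask_pos = state_a.positions_of(scape.mask_residues)
        mode = (state_b.coords[mask_pos] - state_a.coords[mask_pos]).ravel()
        mode /= np.linalg.norm(mode)
        assert abs(mode @ scape.components[0]) >= 0.99
        pa = scape.reference_projections["stateA"][0]
        pb = scape.reference_projections["stateB"][0]
        pc1 = np.array([p[0] for p in scape.projections.values()])
        assert pa < pc1.min() and pb > pc1.max()
        assert pa < 0  # orientation convention
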