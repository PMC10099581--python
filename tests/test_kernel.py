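import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stepscale import (
    Covariate,
    KernelSpec,
    RasterLayer,
    SelectionFreeKernel,
    StudyArea,
    evaluate_kernel,
    make_coupled_kernels,
    make_resource_central_place_kernel,
    normalising_constant,
)


def brute_force_kernel(area, x, lam, beta, layer):
    """Independent enumeration oracle: loop every cell, weight, normalise."""
    w = np.zeros(area.shape)
    for i in range(area.n_rows):
        for j in range(area.n_cols):
            cx, cy = area.centre_of(i, j)
            d = math.hypot(cx - x[0], cy - x[1])
            w[i, j] = math.exp(-lam * d) * math.exp(beta * layer.values[i, j])
    return w / w.sum(), w.sum() * area.cell_area


@pytest.fixture
def layer_3x3():
    vals = np.array([[0.1, 0.9, 0.3], [0.4, 0.2, 0.8], [0.0, 0.5, 0.6]])
    return RasterLayer(vals)


class TestEvaluateKernel:
    def test_uniform_psi_no_selection_is_uniform(self, area_3x3):
        spec = KernelSpec(SelectionFreeKernel("uniform"), [], [], area_3x3)
        p = evaluate_kernel(spec, (1.5, 1.5))
        assert np.allclose(p, 1.0 / 9.0)

    def test_single_admissible_cell_gets_all_mass(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        area = StudyArea(3, 3, admissible=mask)
        spec = KernelSpec(
            SelectionFreeKernel("exponential-decay", rate=0.5), [], [], area
        )
        p = evaluate_kernel(spec, (1.5, 1.5))
        assert p[1, 1] == pytest.approx(1.0)
        assert p.sum() == pytest.approx(1.0)

    def test_matches_brute_force_enumeration(self, layer_3x3):
        area = StudyArea(3, 3)
        lam, beta = 0.2, 1.3
        spec = KernelSpec(
            SelectionFreeKernel("exponential-decay", rate=lam),
            [Covariate("z", "endpoint", layer=layer_3x3)],
            [beta],
            area,
        )
        for x in [(0.5, 0.5), (1.5, 1.5), (2.5, 0.5)]:
            expected, _ = brute_force_kernel(area, x, lam, beta, layer_3x3)
            assert np.allclose(evaluate_kernel(spec, x), expected, atol=1e-12)

    def test_no_admissible_mass_is_signalled(self):
        mask = np.ones((2, 2), dtype=bool)
        mask[0, 0] = False
        area = StudyArea(2, 2, admissible=mask)
        spec = KernelSpec(SelectionFreeKernel("delta"), [], [], area)
        with pytest.raises(ValueError, match="no admissible mass"):
            evaluate_kernel(spec, (0.5, 0.5))  # delta aimed at a no-go cell

    def test_start_outside_area_rejected(self, area_3x3):
        spec = KernelSpec(SelectionFreeKernel("uniform"), [], [], area_3x3)
        with pytest.raises(ValueError, match="outside"):
            evaluate_kernel(spec, (5.0, 5.0))

    def test_covariate_shift_equivariance(self, layer_3x3):
        # adding a constant to a covariate layer cancels in normalisation
        area = StudyArea(3, 3)
        shifted = RasterLayer(layer_3x3.values + 7.5)
        sf = SelectionFreeKernel("exponential-decay", rate=0.4)
        p1 = evaluate_kernel(
            KernelSpec(sf, [Covariate("z", "endpoint", layer=layer_3x3)], [1.1], area),
            (1.5, 0.5),
        )
        p2 = evaluate_kernel(
            KernelSpec(sf, [Covariate("z", "endpoint", layer=shifted)], [1.1], area),
            (1.5, 0.5),
        )
        assert np.allclose(p1, p2, atol=1e-12)

    def test_bearing_independent_when_kappa_zero(self, layer_3x3):
        area = StudyArea(3, 3)
        spec = KernelSpec(
            SelectionFreeKernel("gaussian", scale=1.0, kappa=0.0),
            [Covariate("z", "endpoint", layer=layer_3x3)],
            [0.8],
            area,
        )
        p0 = evaluate_kernel(spec, (1.5, 1.5), bearing=0.0)
        p1 = evaluate_kernel(spec, (1.5, 1.5), bearing=2.5)
        assert np.array_equal(p0, p1)

    def test_turning_angle_biases_towards_previous_bearing(self):
        area = StudyArea(5, 5)
        spec = KernelSpec(
            SelectionFreeKernel("exponential-decay", rate=0.5, kappa=3.0),
            [],
            [],
            area,
        )
        p = evaluate_kernel(spec, (2.5, 2.5), bearing=0.0)  # arrived heading north
        north = p[3:, :].sum()
        south = p[:2, :].sum()
        assert north > south

    @settings(max_examples=25, deadline=None)
    @given(
        x=st.tuples(
            st.floats(0.01, 4.99, allow_nan=False),
            st.floats(0.01, 4.99, allow_nan=False),
        ),
        lam=st.floats(0.05, 2.0),
        beta=st.floats(-3.0, 3.0),
    )
    def test_normalisation_property(self, x, lam, beta):
        area = StudyArea(5, 5)
        rng = np.random.default_rng(0)
        layer = RasterLayer(rng.random((5, 5)))
        spec = KernelSpec(
            SelectionFreeKernel("exponential-decay", rate=lam),
            [Covariate("z", "endpoint", layer=layer)],
            [beta],
            area,
        )
        p = evaluate_kernel(spec, x)
        assert abs(p.sum() - 1.0) < 1e-10
        assert np.all(p >= 0)


class TestNormalisingConstant:
    def test_counts_admissible_cells_for_flat_kernel(self, area_3x3):
        spec = KernelSpec(SelectionFreeKernel("uniform"), [], [], area_3x3)
        assert normalising_constant(spec, (1.5, 1.5)) == pytest.approx(9.0)

    def test_exponential_shift_identity(self, layer_3x3):
        # adding a constant c to beta.Z multiplies K by e^c
        area = StudyArea(3, 3)
        sf = SelectionFreeKernel("exponential-decay", rate=0.3)
        ones = RasterLayer(np.ones((3, 3)))
        base = KernelSpec(
            sf, [Covariate("z", "endpoint", layer=layer_3x3)], [1.2], area
        )
        shifted = KernelSpec(
            sf,
            [
                Covariate("z", "endpoint", layer=layer_3x3),
                Covariate("one", "endpoint", layer=ones),
            ],
            [1.2, 2.0],
            area,
        )
        K0 = normalising_constant(base, (0.5, 2.5))
        K1 = normalising_constant(shifted, (0.5, 2.5))
        assert K1 / K0 == pytest.approx(math.exp(2.0), rel=1e-12)

    def test_matches_enumeration_oracle(self, layer_3x3):
        area = StudyArea(3, 3)
        lam, beta = 0.2, 1.3
        spec = KernelSpec(
            SelectionFreeKernel("exponential-decay", rate=lam),
            [Covariate("z", "endpoint", layer=layer_3x3)],
            [beta],
            area,
        )
        _, K_expected = brute_force_kernel(area, (1.5, 1.5), lam, beta, layer_3x3)
        assert normalising_constant(spec, (1.5, 1.5)) == pytest.approx(
            K_expected, rel=1e-12
        )

    def test_kernel_equals_weight_over_K(self, layer_3x3):
        # per-cell probability mass = unnormalised density * cell area / K
        area = StudyArea(3, 3)
        lam, beta = 0.4, 0.9
        spec = KernelSpec(
            SelectionFreeKernel("exponential-decay", rate=lam),
            [Covariate("z", "endpoint", layer=layer_3x3)],
            [beta],
            area,
        )
        x = (2.5, 1.5)
        w, _ = brute_force_kernel(area, x, lam, beta, layer_3x3)
        K = normalising_constant(spec, x)
        w_raw = w * K  # undo the oracle's own normalisation (unit cells)
        assert np.allclose(evaluate_kernel(spec, x), w_raw * area.cell_area / K)


class TestResourceCentralPlaceKernel:
    def test_figure_configuration_is_valid(self):
        resource = np.random.default_rng(1).random((100, 100))
        layer = RasterLayer(resource)
        spec = make_resource_central_place_kernel(
            layer, (50.0, 50.0), lam=0.2, beta_r=1.5, beta_c=0.2
        )
        assert len(spec.covariates) == 2
        assert spec.is_endpoint_only()
        p = evaluate_kernel(spec, (50.0, 50.0))
        assert p.sum() == pytest.approx(1.0, abs=1e-10)

    def test_zero_betas_reduce_to_pure_step_length_decay(self, resource_20):
        spec = make_resource_central_place_kernel(
            resource_20, (10.0, 10.0), lam=0.5, beta_r=0.0, beta_c=0.0
        )
        p = evaluate_kernel(spec, (10.5, 10.5))
        area = spec.study_area
        cx, cy = area.cell_centres()
        d = np.hypot(cx - 10.5, cy - 10.5)
        expected = np.exp(-0.5 * d)
        assert np.allclose(p, expected / expected.sum(), atol=1e-12)

    def test_strong_central_place_concentrates_near_den(self, resource_20):
        spec = make_resource_central_place_kernel(
            resource_20, (10.5, 10.5), lam=0.2, beta_r=1.5, beta_c=50.0
        )
        p = evaluate_kernel(spec, (10.5, 10.5))
        i, j = np.unravel_index(np.argmax(p), p.shape)
        assert (i, j) == spec.study_area.cell_of(10.5, 10.5)
        assert p[i, j] > 0.9

    def test_nonpositive_lambda_rejected(self, resource_20):
        with pytest.raises(ValueError, match="lambda"):
            make_resource_central_place_kernel(
                resource_20, (10, 10), lam=0.0, beta_r=1.0, beta_c=0.1
            )


class TestCoupledKernels:
    @staticmethod
    def _od_provider_factory(area, hot_cell=None):
        vals = np.full(area.shape, 1.0 / area.n_cells)
        if hot_cell is not None:
            vals = np.zeros(area.shape)
            vals[hot_cell] = 1.0
        layer = RasterLayer(vals)
        return lambda j, t: layer

    def test_zero_interactions_decouple(self, resource_20):
        area = StudyArea.from_raster(resource_20)
        centres = [(5.0, 5.0), (15.0, 15.0), (5.0, 15.0), (15.0, 5.0)]
        specs = make_coupled_kernels(
            resource_20, centres, 0.2, 1.5, 0.2,
            interaction=np.zeros((4, 4)),
            od_provider=self._od_provider_factory(area),
        )
        for spec, centre in zip(specs, centres):
            solo = make_resource_central_place_kernel(
                resource_20, centre, 0.2, 1.5, 0.2
            )
            assert np.allclose(
                evaluate_kernel(spec, (10.5, 10.5)),
                evaluate_kernel(solo, (10.5, 10.5)),
                atol=1e-14,
            )

    def test_avoidance_lowers_mass_at_other_animals_location(self, resource_20):
        area = StudyArea.from_raster(resource_20)
        hot = (7, 7)
        interaction = np.array([[0.0, 2.0], [2.0, 0.0]])
        coupled = make_coupled_kernels(
            resource_20, [(5.0, 5.0), (7.5, 7.5)], 0.2, 1.5, 0.2,
            interaction=interaction,
            od_provider=self._od_provider_factory(area, hot_cell=hot),
        )
        solo = make_resource_central_place_kernel(
            resource_20, (5.0, 5.0), 0.2, 1.5, 0.2
        )
        p_coupled = evaluate_kernel(coupled[0], (6.5, 6.5), t=0.0)
        p_solo = evaluate_kernel(solo, (6.5, 6.5))
        assert p_coupled[hot] < p_solo[hot]

    def test_nonzero_diagonal_rejected(self, resource_20):
        area = StudyArea.from_raster(resource_20)
        with pytest.raises(ValueError, match="zero diagonal"):
            make_coupled_kernels(
                resource_20, [(5, 5), (15, 15)], 0.2, 1.5, 0.2,
                interaction=np.eye(2),
                od_provider=self._od_provider_factory(area),
            )
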