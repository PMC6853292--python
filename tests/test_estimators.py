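"""Morphometric estimators: S/V formula, sampling, volumes, Feret, phenotype."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import chisquare

from nervestereo.cohort import build_bundle_scene, generate_cohort
from nervestereo.errors import NotFoundError, UndefinedEstimateError
from nervestereo.estimators import (
    Phenotype,
    classify_bundle,
    estimate_bundle_sv,
    estimate_sv,
    make_section_plane,
    pore_diameter,
    select_section,
    volume_from_labels,
)
from nervestereo.grid import CountTally
from nervestereo.scene import (
    ROLE_EPITHELIUM,
    ROLE_FUSING,
    ROLE_LAMINA,
    ROLE_PENETRATING,
    ROLE_PORE,
)
from nervestereo.stack import LabelStack


def tally(i, p):
    return CountTally(I=i, P=p, n_arcs_cast=1)


def toy_stack(z_with_label, nz=25, label=7, shape=(6, 6)):
    sections = [np.zeros(shape, np.uint16) for _ in range(nz)]
    for k in z_with_label:
        sections[k][2:4, 2:4] = label
    return LabelStack(sections=sections, spacing=(0.01, 0.01, 0.1), legend={label: "x"})


class TestEstimateSv:
    def test_formula(self):
        assert estimate_sv([tally(10, 5)], lp=2.0) == pytest.approx(2.0)

    def test_zero_intersections(self):
        assert estimate_sv([tally(0, 7)], lp=1.0) == 0.0

    def test_ratio_of_sums_aggregation(self):
        # (2·(3+9)) / (1·(2+6)), not the mean of per-cast ratios
        assert estimate_sv([tally(3, 2), tally(9, 6)], lp=1.0) == pytest.approx(3.0)

    def test_no_points_raises(self):
        with pytest.raises(UndefinedEstimateError):
            estimate_sv([tally(4, 0)], lp=1.0)

    def test_ratio_of_sums_beats_mean_of_ratios(self, rng):
        """Pooling counts before dividing has lower variance than averaging
        per-cast ratios, over resamples of heterogeneous tallies."""
        true_sv, lp = 3.0, 1.0
        ros, mor = [], []
        for _ in range(100):
            sizes = rng.uniform(3, 40, size=8)
            ps = rng.poisson(sizes) + 1
            is_ = rng.poisson(true_sv * lp * sizes / 2)
            ros.append(2 * is_.sum() / (lp * ps.sum()))
            mor.append(np.mean(2 * is_ / (lp * ps)))
        assert np.var(ros) < np.var(mor)


class TestSelectSection:
    def test_single_candidate(self):
        stack = toy_stack([13])
        assert select_section(stack, 7, seed=0) == 13
        assert select_section(stack, 7, seed=99) == 13

    def test_uniform_over_candidates(self, rng):
        stack = toy_stack(range(10, 20))
        draws = [select_section(stack, 7, rng) for _ in range(10_000)]
        counts = np.bincount(draws, minlength=25)[10:20]
        freqs = counts / 10_000
        assert np.all(np.abs(freqs - 0.1) < 0.01)
        assert chisquare(counts).pvalue > 1e-3

    def test_deterministic_from_seed(self):
        stack = toy_stack(range(10, 20))
        assert select_section(stack, 7, seed=5) == select_section(stack, 7, seed=5)

    def test_absent_label_raises(self):
        with pytest.raises(NotFoundError):
            select_section(toy_stack([3]), 99, seed=0)


class TestVolume:
    def test_arithmetic(self):
        # 1000 voxels at 0.01 × 0.01 × 0.1 μm³ = 0.01 μm³
        sections = [np.zeros((10, 10), np.uint16) for _ in range(10)]
        for s in sections:
            s[:, :] = 2
        stack = LabelStack(sections, spacing=(0.01, 0.01, 0.1), legend={2: "x"})
        assert volume_from_labels(stack, 2) == pytest.approx(0.01)

    def test_additivity_of_disjoint_labels(self):
        sections = [np.zeros((8, 8), np.uint16) for _ in range(3)]
        sections[0][:2] = 1
        sections[1][3:5] = 2
        stack = LabelStack(sections, spacing=(0.02, 0.02, 0.1), legend={1: "a", 2: "b"})
        v_union = (
            sum(np.count_nonzero(np.asarray(s)) for s in sections) * stack.voxel_volume
        )
        assert volume_from_labels(stack, 1) + volume_from_labels(stack, 2) == pytest.approx(
            v_union
        )

    def test_voxelized_sphere_volume(self, unit_sphere_stack):
        v = volume_from_labels(unit_sphere_stack, 1)
        assert v == pytest.approx(4 * math.pi / 3, rel=0.01)

    def test_absent_label_warns_and_returns_zero(self):
        stack = toy_stack([3])
        with pytest.warns(UserWarning, match="absent"):
            assert volume_from_labels(stack, 42) == 0.0


def ellipse_stack(a, b, angle_deg, dx=0.01, label=4, pad=0.4, sections_scale=None):
    """Single-section (or growing multi-section) in-plane elliptical region."""
    phi = math.radians(angle_deg)
    half = max(a, b) + pad
    n = int(2 * half / dx)
    jj, ii = np.meshgrid(np.arange(n), np.arange(n))
    x = (jj + 0.5) * dx - half
    y = (ii + 0.5) * dx - half
    xr = x * math.cos(phi) + y * math.sin(phi)
    yr = -x * math.sin(phi) + y * math.cos(phi)
    scales = sections_scale or [1.0]
    sections = []
    for s in scales:
        mask = (xr / (a * s)) ** 2 + (yr / (b * s)) ** 2 <= 1.0
        img = np.zeros((n, n), np.uint16)
        img[mask] = label
        sections.append(img)
    return LabelStack(sections, spacing=(dx, dx, 0.1), legend={label: ROLE_PORE})


class TestPoreDiameter:
    def test_ellipse_major_axis(self):
        stack = ellipse_stack(2.0, 1.0, 0.0)
        assert pore_diameter(stack, 4) == pytest.approx(4.0, abs=0.01)

    @pytest.mark.parametrize("angle", [37.0, 61.0, 118.0])
    def test_rotation_invariance(self, angle):
        """Max Feret equals the major axis under in-plane rotation (± 1 px)."""
        stack = ellipse_stack(2.0, 1.0, angle)
        assert pore_diameter(stack, 4) == pytest.approx(4.0, abs=0.01)

    def test_growing_ellipse_takes_largest_section(self):
        stack = ellipse_stack(1.0, 0.5, 20.0, sections_scale=[0.5, 0.8, 1.0])
        assert pore_diameter(stack, 4) == pytest.approx(2.0, abs=0.01)

    def test_at_least_equivalent_circle_diameter(self):
        stack = ellipse_stack(1.5, 0.6, 45.0)
        area = np.count_nonzero(np.asarray(stack.sections[0])) * 0.01**2
        d_circle = 2 * math.sqrt(area / math.pi)
        assert pore_diameter(stack, 4) >= d_circle

    def test_absent_pore_raises(self):
        with pytest.raises(NotFoundError):
            pore_diameter(toy_stack([1]), 4)


class TestClassifyBundle:
    def test_generator_phantoms_classified_by_construction(self):
        cohort = generate_cohort(n_pen=1, n_fus=1, cv=0.0, seed=4)
        phenos = {t.bundle_id: classify_bundle(s) for s, t in cohort}
        assert phenos["pen_000"] is Phenotype.PENETRATING
        assert phenos["fus_001"] is Phenotype.FUSING_MIXED

    def test_fusing_label_sealed_by_intact_lamina_is_penetrating(self):
        """Without a pore the fusing axon cannot reach the epithelium."""
        scene = build_bundle_scene(Phenotype.FUSING_MIXED, 2.25, pore_diameter=1.8, seed=0)
        sealed = replace(scene, pores=())
        from nervestereo.voxelize import voxelize

        stack = voxelize(sealed, (0.02, 0.02, 0.1))
        assert classify_bundle(stack) is Phenotype.PENETRATING

    def test_no_nerve_labels_raises(self):
        stack = toy_stack([2])
        with pytest.raises(NotFoundError):
            classify_bundle(stack)


class TestScaleCovariance:
    def test_spacings_scale_volumes_pores_and_sv(self):
        """Scaling all spacings by k scales volume by k³, pore diameter by k,
        and S/V estimates by 1/k (with the grid scaled alongside)."""
        k = 2.5
        cohort1 = generate_cohort(n_pen=1, n_fus=0, cv=0.0, seed=9, spacing=(0.02, 0.02, 0.1))
        stack1, _ = cohort1[0]
        stack_k = LabelStack(
            sections=stack1.sections,
            spacing=tuple(np.array(stack1.spacing) * k),
            legend=stack1.legend,
            label_zranges=stack1.label_zranges,
        )
        assert volume_from_labels(stack_k, 1) == pytest.approx(
            k**3 * volume_from_labels(stack1, 1), rel=1e-12
        )
        assert pore_diameter(stack_k, 4) == pytest.approx(
            k * pore_diameter(stack1, 4), rel=1e-9
        )
        sv1, t1 = estimate_bundle_sv(stack1, 1, lp=0.7, casts=3, seed=11)
        svk, tk = estimate_bundle_sv(stack_k, 1, lp=0.7 * k, casts=3, seed=11)
        assert [(a.I, a.P) for _, a in t1] == [(b.I, b.P) for _, b in tk]
        assert svk == pytest.approx(sv1 / k, rel=1e-9)


class TestSectionPlane:
    def test_trace_and_pore_endpoints_from_stack(self):
        cohort = generate_cohort(n_pen=1, n_fus=0, cv=0.0, seed=2)
        stack, truth = cohort[0]
        # centre section cuts the middle of the pore
        ks = stack.sections_with_label(4)
        sp = make_section_plane(stack, ks[len(ks) // 2])
        assert sp.lamina_trace is not None and len(sp.lamina_trace) > 10
        assert sp.pore_endpoints is not None
        gap = np.linalg.norm(sp.pore_endpoints[1] - sp.pore_endpoints[0])
        assert gap == pytest.approx(truth.pore_diameter, rel=0.1)
        assert sp.epithelium_centroid is not None
        # epithelium lies above the lamina (smaller y)
        assert sp.epithelium_centroid[1] < sp.lamina_trace[:, 1].mean()
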