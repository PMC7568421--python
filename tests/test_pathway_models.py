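"""Model construction, unit conversion, signal grids, initial conditions,
and the extrinsic-noise polymerase sampler."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from signoise import (
    ModelSpec,
    build_model,
    expected_complexes,
    initial_state,
    molar_to_count,
    propensities,
    sample_polymerase_count,
    signal_grid,
)
from signoise.defaults import VOLUME_NUCLEUS_L, VOLUME_RECEPTOR_L


class TestMolarToCount:
    @pytest.mark.parametrize(
        "conc,vol,expected",
        [
            (1e-8, VOLUME_RECEPTOR_L, 10.0),
            (0.0, VOLUME_RECEPTOR_L, 0.0),
            (1e-6, VOLUME_RECEPTOR_L, 1000.0),
            (1e-11, VOLUME_NUCLEUS_L, 10.0),
        ],
    )
    def test_conversion(self, conc, vol, expected):
        assert molar_to_count(conc, vol) == pytest.approx(expected)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            molar_to_count(-1e-9, VOLUME_RECEPTOR_L)


class TestSignalGrid:
    @pytest.mark.parametrize(
        "nmax,n,expected",
        [
            (1000, 10, list(range(100, 1001, 100))),
            (8, 8, list(range(1, 9))),
            (1000, 1, [1000]),
        ],
    )
    def test_examples(self, nmax, n, expected):
        assert signal_grid(nmax, n).tolist() == expected

    def test_more_levels_than_molecules_rejected(self):
        with pytest.raises(ValueError):
            signal_grid(5, 6)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(1, 5000), st.data())
    def test_strictly_increasing_integers(self, nmax, data):
        n = data.draw(st.integers(1, nmax))
        grid = signal_grid(nmax, n)
        assert len(grid) == n
        assert grid[-1] == nmax
        assert (np.diff(grid) > 0).all()
        assert (grid >= 1).all()


class TestExpectedComplexes:
    @pytest.mark.parametrize(
        "nb,ns,keq,expected",
        [
            (10, 100, 100.0, 5.0),  # half occupancy at N_signal = K_eq
            (1, 100, 100.0, 0.5),  # single site: occupancy probability
            (10, 1000, 100.0, 10 * 1000 / 1100),
        ],
    )
    def test_examples(self, nb, ns, keq, expected):
        assert expected_complexes(nb, ns, keq) == pytest.approx(expected)

    def test_clamped_to_available_signal(self):
        # strong affinity with receptors in excess: at most N_signal complexes
        assert expected_complexes(100, 10, 1e-4) == pytest.approx(10.0)

    def test_zero_denominator_convention(self):
        assert expected_complexes(10, 0, 0.0) == 0.0

    @settings(max_examples=100, derandomize=True)
    @given(
        st.integers(0, 50),
        st.integers(0, 2000),
        st.floats(1e-6, 1e6),
    )
    def test_monotone_in_signal_and_affinity(self, nb, ns, keq):
        v = expected_complexes(nb, ns, keq)
        assert 0.0 <= v <= min(nb, ns) + 1e-12
        assert expected_complexes(nb, ns + 1, keq) >= v - 1e-12
        assert expected_complexes(nb, ns, keq * 2) <= v + 1e-12

    def test_limits_match_saturation_regimes(self):
        # K_eq -> 0 with signal in excess: all receptors bound
        assert expected_complexes(10, 100, 1e-12) == pytest.approx(10.0)
        # K_eq -> inf: no complexes
        assert expected_complexes(10, 100, 1e12) == pytest.approx(0.0, abs=1e-9)


class TestInitialState:
    def test_binding_nearest_integer(self, rng):
        spec = ModelSpec.binding(keq_m=1e-7)  # K_eq = 100 counts
        state = initial_state(spec, 100, rng)  # expected complexes 5.0
        assert state.tolist() == [95, 5, 5]  # S, R, RS

    def test_gene_mrna_protein_expectations(self, rng):
        # occupancy probability 0.5, k1/d1 = 20, k2/d2 = 50
        spec = ModelSpec.gene(
            keq_m=1e-10,  # 100 counts at nucleus volume
            k_transcription=0.02, d_mrna=0.001,
            k_translation=0.05, d_protein=0.001,
        )
        states = np.array([initial_state(spec, 100, rng) for _ in range(400)])
        # TF, Dbs, TFD, mR, P
        assert set(states[:, 2]) <= {0, 1}
        assert (states[:, 3] == 10).all()
        assert (states[:, 4] == 500).all()
        assert (states[:, 0] + states[:, 2] == 100).all()

    def test_site_occupancy_is_bernoulli(self):
        spec = ModelSpec.gene(keq_m=1e-10)  # occupancy prob 0.5 at N_TF = 100
        rng = np.random.default_rng(77)
        n = 10_000
        bound = sum(initial_state(spec, 100, rng)[2] for _ in range(n))
        se = math.sqrt(0.25 / n)
        assert abs(bound / n - 0.5) < 3 * se

    def test_no_negative_counts_anywhere(self, rng):
        # receptors greatly in excess of signal at strong affinity
        spec = ModelSpec.binding(n_receptors=100, n_signal_max=10, keq_m=1e-10)
        for ns in spec.levels():
            assert (initial_state(spec, int(ns), rng) >= 0).all()


class TestPolymeraseSampler:
    def test_zero_sd_is_deterministic(self, rng):
        assert all(
            sample_polymerase_count(10_000, 0.0, rng) == 10_000 for _ in range(5)
        )

    def test_moment_matching(self):
        rng = np.random.default_rng(123)
        draws = np.array(
            [sample_polymerase_count(10_000, 0.10, rng) for _ in range(100_000)]
        )
        se_mean = 1000 / math.sqrt(len(draws))
        assert abs(draws.mean() - 10_000) < 3 * se_mean
        assert draws.std() == pytest.approx(1000, rel=0.05)

    def test_underdispersion_rejected_with_guidance(self, rng):
        with pytest.raises(ValueError, match="sd_fraction"):
            sample_polymerase_count(10, 0.10, rng)


class TestBuildModel:
    def test_binding_two_reactions_and_conserved_sums(self):
        sys_ = build_model(ModelSpec.binding(), 500)
        assert len(sys_.reactions) == 2
        labels = {c[0] for c in sys_.conserved}
        assert labels == {"total receptors", "total signal"}
        assert sys_.output_species == "RS"

    def test_gene_single_site_six_reactions(self):
        sys_ = build_model(ModelSpec.gene(), 50)
        assert len(sys_.reactions) == 6
        # occupancy bounded by one site
        assert dict(
            (c[0], c[2]) for c in sys_.conserved
        )["total DNA sites"] == 1

    def test_polymerase_transcription_requires_full_complex(self):
        spec = ModelSpec.gene_polymerase()
        sys_ = build_model(spec, 50)
        i = {s: k for k, s in enumerate(sys_.species)}
        state = np.zeros(len(sys_.species), dtype=int)
        state[i["TF"]], state[i["Pol"]], state[i["TFD"]] = 49, 1000, 1
        a = propensities(state, sys_)
        tx = [j for j, r in enumerate(sys_.reactions) if r.name == "transcription"]
        assert a[tx[0]] == 0.0  # TF bound but no polymerase: no leaky expression
        state[i["TFD"]], state[i["TFPD"]] = 0, 1
        assert propensities(state, sys_)[tx[0]] == pytest.approx(
            spec.k_transcription
        )

    def test_full_pathway_wiring(self):
        sys_ = build_model(ModelSpec.full_pathway(), 200)
        assert sys_.species == ("S", "R", "RS", "D", "RSD", "mR", "P")
        assert sys_.output_species == "P"
        assert len(sys_.reactions) == 8

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec.binding(variant="oscillator")

    @pytest.mark.parametrize(
        "spec,ns",
        [
            (ModelSpec.binding(), 300),
            (ModelSpec.cascade(), 300),
            (ModelSpec.gene(), 40),
            (ModelSpec.gene_polymerase(), 40),
            (ModelSpec.full_pathway(), 300),
        ],
        ids=["binding", "cascade", "gene", "gene_polymerase", "full_pathway"],
    )
    def test_initial_state_satisfies_conservation(self, spec, ns, rng):
        sys_ = build_model(spec, ns)
        for _ in range(20):
            sys_.check_state(initial_state(spec, ns, rng))
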