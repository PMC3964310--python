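import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apms.errors import DataError
from apms.idirt import (
    IdirtExperiment,
    PeptidePair,
    input_normalizer,
    peptide_light_fraction,
    protein_stability,
)
from apms.simulate import SimConfig, simulate_counts, simulate_peptides


def pair(prey="P", seq="SEQ1", light=0.0, heavy=0.0):
    return PeptidePair(prey=prey, peptide_seq=seq, light_intensity=light,
                       heavy_intensity=heavy)


class TestPeptideLightFraction:
    def test_symmetric_pair_is_half(self):
        assert peptide_light_fraction(pair(light=100, heavy=100)) == pytest.approx(0.5)

    def test_light_only_is_one(self):
        assert peptide_light_fraction(pair(light=100, heavy=0)) == 1.0

    def test_heavy_only_is_zero(self):
        assert peptide_light_fraction(pair(light=0, heavy=100)) == 0.0

    def test_light_rich_input_corrects_odds(self):
        # input mixed 2:1 light -> a symmetric pair is really 1/3 light
        assert peptide_light_fraction(
            pair(light=100, heavy=100), normalizer=2.0
        ) == pytest.approx(1 / 3)

    def test_both_zero_is_error(self):
        with pytest.raises(DataError):
            peptide_light_fraction(pair())

    @given(
        light=st.floats(1e-3, 1e9),
        heavy=st.floats(1e-3, 1e9),
        norm=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=200, deadline=None)
    def test_fraction_always_in_unit_interval(self, light, heavy, norm):
        f = peptide_light_fraction(pair(light=light, heavy=heavy), norm)
        assert 0.0 <= f <= 1.0


class TestInputNormalizer:
    def test_balanced_input_is_unity(self):
        pairs = [pair(seq=f"S{i}", light=50, heavy=50) for i in range(4)]
        assert input_normalizer(pairs) == pytest.approx(1.0)

    def test_constant_bias_recovered(self):
        pairs = [pair(seq=f"S{i}", light=120, heavy=100) for i in range(4)]
        assert input_normalizer(pairs) == pytest.approx(1.2)

    def test_median_over_proteins(self):
        pairs = []
        for prot, odds in [("A", 0.8), ("B", 1.0), ("C", 1.5)]:
            pairs += [
                pair(prey=prot, seq=f"{prot}{i}", light=100 * odds, heavy=100)
                for i in range(2)
            ]
        assert input_normalizer(pairs) == pytest.approx(1.0)

    def test_unquantifiable_input_disables_normalization(self):
        # single-peptide proteins are below the quantification minimum
        with pytest.warns(UserWarning, match="disabled"):
            assert input_normalizer([pair(light=10, heavy=10)]) == 1.0


class TestProteinStability:
    def _exp(self, pairs):
        return IdirtExperiment(bait="BAITX", pairs=pairs, input_pairs=[])

    def test_median_of_peptide_fractions(self):
        pairs = [pair(seq=f"S{i}", light=100, heavy=100) for i in range(3)]
        (r,) = protein_stability(self._exp(pairs), normalizer=1.0)
        assert r.ratio == pytest.approx(0.5) and r.n_peptides == 3

    def test_light_only_protein_is_exactly_one(self):
        pairs = [pair(seq=f"S{i}", light=100, heavy=0) for i in range(2)]
        (r,) = protein_stability(self._exp(pairs), normalizer=1.0)
        assert r.ratio == 1.0

    def test_single_peptide_protein_excluded(self):
        with pytest.warns(UserWarning, match="dropped"):
            out = protein_stability(self._exp([pair(light=10, heavy=10)]),
                                    normalizer=1.0)
        assert out == []

    def test_shared_peptide_dropped(self):
        pairs = [
            pair(prey="A", seq="SHARED", light=10, heavy=10),
            pair(prey="B", seq="SHARED", light=10, heavy=10),
            pair(prey="A", seq="S1", light=10, heavy=10),
            pair(prey="A", seq="S2", light=30, heavy=10),
        ]
        (r,) = protein_stability(self._exp(pairs), normalizer=1.0)
        assert r.prey == "A" and r.n_peptides == 2

    def test_global_light_rescaling_cancels_through_input(self):
        rng = np.random.default_rng(0)
        ip, inp = [], []
        for i in range(10):
            ip.append(pair(prey="A", seq=f"A{i}", light=rng.uniform(10, 100),
                           heavy=rng.uniform(10, 100)))
            inp.append(pair(prey=f"I{i % 3}", seq=f"N{i}",
                            light=rng.uniform(10, 100), heavy=rng.uniform(10, 100)))
        base = protein_stability(IdirtExperiment("B", ip, inp))
        scaled_ip = [pair(p.prey, p.peptide_seq, 2 * p.light_intensity,
                          p.heavy_intensity) for p in ip]
        scaled_inp = [pair(p.prey, p.peptide_seq, 2 * p.light_intensity,
                           p.heavy_intensity) for p in inp]
        scaled = protein_stability(IdirtExperiment("B", scaled_ip, scaled_inp))
        for a, b in zip(base, scaled):
            assert b.ratio == pytest.approx(a.ratio, abs=1e-9)


class TestSimulatedSignatures:
    def test_fully_exchanging_prey_converges_to_half(self):
        cfg = SimConfig(seed=11, stable_fraction=0.0, peptides_per_prey=100,
                        shared_complex_size=0)
        _, truth = simulate_counts(cfg)
        exp, ptruth = simulate_peptides(cfg, truth, "BAIT1")
        ratios = {r.prey: r.ratio for r in protein_stability(exp)}
        exchanging = ptruth.index[ptruth["exchange_f"] == 1.0]
        med = np.median([ratios[p] for p in exchanging])
        assert med == pytest.approx(0.50, abs=0.02)

    def test_stable_prey_exact_one_without_leakage(self):
        cfg = SimConfig(seed=11, stable_fraction=1.0)
        _, truth = simulate_counts(cfg)
        exp, ptruth = simulate_peptides(cfg, truth, "BAIT1")
        ratios = {r.prey: r.ratio for r in protein_stability(exp)}
        stable = ptruth.index[ptruth["exchange_f"] == 0.0]
        assert all(ratios[p] == 1.0 for p in stable)

    def test_stable_prey_above_95_at_5pct_leakage(self):
        # noise-free: the leakage signal model gives exactly 1/1.05 ~ 0.952
        cfg = SimConfig(seed=11, stable_fraction=1.0, heavy_leakage=0.05,
                        intensity_sigma=0.0)
        _, truth = simulate_counts(cfg)
        exp, ptruth = simulate_peptides(cfg, truth, "BAIT1")
        ratios = {r.prey: r.ratio for r in protein_stability(exp)}
        stable = ptruth.index[ptruth["exchange_f"] == 0.0]
        assert all(ratios[p] >= 0.95 for p in stable)
        # with default intensity noise the population median stays >= 0.95
        noisy = SimConfig(seed=11, stable_fraction=1.0, heavy_leakage=0.05)
        exp_n, _ = simulate_peptides(noisy, truth, "BAIT1")
        ratios_n = [r.ratio for r in protein_stability(exp_n)]
        assert np.median(ratios_n) >= 0.95
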