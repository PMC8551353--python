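"""Current profiles, gradient quantities, and their algebraic identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cscurrent.genetic_code import CodonLookupError, derive_amino_acid_table
from cscurrent.profile import CurrentProfile, compute_profile, gradient
from cscurrent.sequence_io import frame

from .oracles import gradient_oracle


def make_profile(currents, seq_id="p"):
    arr = np.array([np.nan if c is None else c for c in currents], dtype=float)
    return CurrentProfile(
        sequence_id=seq_id,
        level="codon",
        currents=arr,
        codons=("NNN",) * len(arr),
        table_variant="printed",
    )


class TestComputeProfile:
    def test_codon_level_currents(self, printed_table):
        prof = compute_profile(frame("TTTTTC", 0), "codon", printed_table)
        assert prof.currents.tolist() == [0.7071, 0.5000]

    def test_amino_acid_level_uses_class_mean(self, printed_table, aa_table):
        prof = compute_profile(
            frame("TTTTTC", 0), "amino_acid", printed_table, aa_table
        )
        assert prof.currents.tolist() == pytest.approx([0.60355, 0.60355])

    def test_single_codon(self, printed_table):
        prof = compute_profile(frame("ATG", 0), "codon", printed_table)
        assert prof.currents.tolist() == [0.0841]

    def test_masked_codon_gives_nan(self, printed_table):
        prof = compute_profile(frame("TTNTTC", 0), "codon", printed_table)
        assert np.isnan(prof.currents[0]) and prof.currents[1] == 0.5

    def test_stop_at_aa_level_names_position(self, printed_table, aa_table):
        with pytest.raises(CodonLookupError, match="position 2"):
            compute_profile(frame("TTTTAA", 0), "amino_acid", printed_table, aa_table)

    def test_stop_ok_with_include_stop(self, printed_table):
        aa21 = derive_amino_acid_table(printed_table, include_stop=True)
        prof = compute_profile(frame("TTTTAA", 0), "amino_acid", printed_table, aa21)
        assert prof.currents[1] == pytest.approx(0.0167, abs=5e-5)

    def test_bad_level_rejected(self, printed_table):
        with pytest.raises(ValueError):
            compute_profile(frame("TTTTTC", 0), "protein", printed_table)


class TestGradient:
    def test_hand_computed_phe_pair(self, printed_table):
        gp = gradient(compute_profile(frame("TTTTTC", 0), "codon", printed_table))
        assert gp.d[0] == pytest.approx(-0.2071)
        assert gp.v1[0] == pytest.approx(-0.29289, abs=5e-6)
        assert gp.v2[1] == pytest.approx(-0.29289, abs=5e-6)
        # boundary entries undefined, never zero-filled
        assert np.isnan(gp.d[1]) and np.isnan(gp.v1[1]) and np.isnan(gp.v2[0])

    def test_adjacent_tyr_codons(self, printed_table):
        gp = gradient(compute_profile(frame("UAUUAC", 0), "codon", printed_table))
        assert gp.v1[0] == pytest.approx(-0.04206, abs=5e-6)

    def test_constant_profile_all_zero(self):
        gp = gradient(make_profile([0.3] * 5))
        assert np.allclose(gp.d[:-1], 0) and np.allclose(gp.e, 0)

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            gradient(make_profile([0.5]))

    def test_mask_propagates_to_neighbours(self, printed_table):
        gp = gradient(compute_profile(frame("TTTNNNTTC", 0), "codon", printed_table))
        assert np.isnan(gp.v1[0])  # forward into the mask
        assert np.isnan(gp.v2[2])  # backward into the mask
        assert np.isnan(gp.e[1])  # the mask itself


currents_strategy = st.lists(
    st.floats(min_value=1e-3, max_value=1.0, allow_nan=False), min_size=2, max_size=100
)


class TestGradientProperties:
    @given(currents_strategy)
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_reconstruction_identity(self, js):
        """Cumulative application of (1 + v1_n) to j_1 rebuilds the profile."""
        gp = gradient(make_profile(js))
        j = js[0]
        for i in range(len(js) - 1):
            j = j * (1.0 + gp.v1[i])
            assert j == pytest.approx(js[i + 1], rel=1e-9)

    @given(currents_strategy)
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_forward_equals_shifted_backward(self, js):
        gp = gradient(make_profile(js))
        np.testing.assert_allclose(gp.v1[:-1], gp.v2[1:], rtol=1e-12)

    @given(currents_strategy, st.floats(min_value=1e-2, max_value=100.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_scale_covariance(self, js, c):
        """Scaling j by c > 0 leaves v1, v2, e unchanged and scales d by c."""
        base = gradient(make_profile(js))
        scaled = gradient(make_profile([c * j for j in js]))
        # atol covers variations at machine-epsilon scale (j_{n+1} ~ j_n),
        # where relative comparison of rounding noise is meaningless
        np.testing.assert_allclose(scaled.v1[:-1], base.v1[:-1], rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(scaled.e, base.e, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(scaled.d[:-1] / c, base.d[:-1], rtol=1e-9, atol=1e-12)


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_sequences(self, printed_table, sense_codons):
        """Vectorised gradient equals the plain-loop oracle, masks included."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = rng.integers(2, 51)
            codons = list(rng.choice(sense_codons, size=n))
            # mask a couple of positions at random
            for i in rng.choice(n, size=min(2, n), replace=False):
                if rng.random() < 0.3:
                    codons[i] = "NNN"
            fs = frame("".join(codons), 0)
            prof = compute_profile(fs, "codon", printed_table)
            gp = gradient(prof)
            js = [None if np.isnan(x) else x for x in prof.currents]
            d, v1, v2, e = gradient_oracle(js)
            for i in range(n):
                for ours, ref in ((gp.d[i], d[i]), (gp.v1[i], v1[i]),
                                  (gp.v2[i], v2[i]), (gp.e[i], e[i])):
                    if ref is None:
                        assert np.isnan(ours)
                    else:
                        assert ours == pytest.approx(ref, rel=1e-12)
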