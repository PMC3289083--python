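"""Window encoders, conservation scores and the collocation screen."""

import math

import numpy as np
import pytest

from atpsite.features import (AA20, BACKGROUND_FREQS, CollocationScreen,
                              WindowSpec, aagroup_window_features,
                              collocation_features, conservation_scores,
                              encode_chain, normalize_pssm_value,
                              pssm_window_features, screen_collocations,
                              segment_indicators, terminal_indicator,
                              ss3_window_features, rsa_window_features,
                              dihedral_window_features)
from atpsite.simulate import SimConfig, simulate_dataset

SPEC = WindowSpec(17)


class TestNormalization:
    @pytest.mark.parametrize("x,expected", [
        (0.0, 0.5),
        (1.0, 2.0 / 3.0),
        (-1.0, 1.0 / 3.0),
    ])
    def test_logistic_values(self, x, expected):
        assert normalize_pssm_value(x) == pytest.approx(expected)

    def test_strictly_increasing_and_bounded(self, rng):
        xs = np.sort(rng.normal(scale=5, size=100))
        fs = normalize_pssm_value(xs)
        assert np.all(np.diff(fs) >= 0)
        assert np.all((fs > 0) & (fs < 1))

    def test_complement_symmetry(self, rng):
        xs = rng.normal(size=50)
        np.testing.assert_allclose(normalize_pssm_value(-xs),
                                   1 - normalize_pssm_value(xs))


class TestPssmWindow:
    def test_output_width_180(self, rng):
        f = rng.uniform(size=(30, 20))
        assert pssm_window_features(f, SPEC).shape == (30, 180)

    def test_z0_equals_central_value(self, rng):
        f = rng.uniform(size=(30, 20))
        g = pssm_window_features(f, SPEC)
        np.testing.assert_allclose(g[:, :20], f)

    def test_symmetric_mean(self):
        f = np.full((30, 20), 0.5)
        f[13, 0] = 0.4   # i - 3
        f[19, 0] = 0.2   # i + 3
        g = pssm_window_features(f, SPEC)
        assert g[16, 3 * 20 + 0] == pytest.approx(0.3)

    def test_palindromic_profile_yields_one_sided_values(self, rng):
        # for a profile symmetric around position i, g_z equals f_{i+z}
        half = rng.uniform(size=(9, 20))
        f = np.vstack([half[:0:-1], half])  # palindrome around row 8
        g = pssm_window_features(f, SPEC)
        i = 8
        for z in range(9):
            np.testing.assert_allclose(g[i, z * 20:(z + 1) * 20], f[i + z])

    def test_chain_end_padding_is_neutral(self):
        f = np.full((3, 20), 0.9)
        g = pssm_window_features(f, SPEC)
        # at position 0, z=8 reaches only padding on the left: (0.5+0.5)/2
        np.testing.assert_allclose(g[0, 8 * 20:], 0.5)


class TestTrackWindows:
    def test_widths(self, rng):
        L = 25
        ss3 = rng.dirichlet((1, 1, 1), size=L)
        assert ss3_window_features(ss3, SPEC).shape == (L, 51)
        assert rsa_window_features(rng.uniform(size=L), SPEC).shape == (L, 17)
        phi = rng.uniform(-180, 180, size=L)
        psi = rng.uniform(-180, 180, size=L)
        d = dihedral_window_features(phi, psi, SPEC)
        assert d.shape == (L, 34)
        assert np.all((d >= -1) & (d <= 1))

    def test_dihedral_scaling(self):
        d = dihedral_window_features(np.array([180.0]), np.array([-90.0]),
                                     SPEC)
        # central position (k=0) is column pair index 8
        assert d[0, 16] == pytest.approx(1.0)
        assert d[0, 17] == pytest.approx(-0.5)

    def test_ss3_padding_is_coil(self, rng):
        ss3 = rng.dirichlet((1, 1, 1), size=1)
        w = ss3_window_features(ss3, SPEC)[0]
        # all off-chain window positions padded with (H,E,C)=(0,0,1)
        pads = [w[3 * j:3 * j + 3] for j in range(17) if j != 8]
        np.testing.assert_allclose(pads, [[0, 0, 1]] * 16)


class TestAAGroups:
    def test_width_36(self):
        assert aagroup_window_features("ACDEFGHIKLMNPQRSTVWY", SPEC).shape \
            == (20, 36)

    def test_central_negative_residue(self):
        g = aagroup_window_features("AAADAAA", SPEC)
        # z=0 block columns: (hydrophobic, negative, positive, amide)
        assert g[3, 1] == pytest.approx(1.0)

    def test_half_membership_at_z2(self):
        # K at i+2, A at i-2: positive-group slot at z=2 averages (1+0)/2
        seq = "AAAAKAA"  # i=2: i+2 = K (positive), i-2 = A (not positive)
        g = aagroup_window_features(seq, SPEC)
        assert g[2, 2 * 4 + 2] == pytest.approx(0.5)

    def test_x_belongs_to_no_group(self):
        g = aagroup_window_features("XXX", SPEC)
        np.testing.assert_allclose(g, 0.0)


class TestTerminalAndSegments:
    def test_terminal_indicator_rule(self):
        t = terminal_indicator(100)
        assert t[2] == 1.0 and t[3] == 0.0 and t[96] == 0.0 and t[97] == 1.0

    def test_terminal_short_chain_overlap(self):
        assert terminal_indicator(4).tolist() == [1.0] * 4

    def test_helix_run_on_left_side(self):
        # put a 4-helix run in the 8 residues left of the window of residue i
        states = ["C"] * 40
        i = 20
        for j in range(i - SPEC.radius - 8, i - SPEC.radius - 4):
            states[j] = "H"
        seg = segment_indicators(states, SPEC)
        assert seg[i, :3].tolist() == [1.0, 0.0, 0.0]

    def test_strand_run_of_three_on_right_side(self):
        states = ["C"] * 40
        i = 10
        for j in range(i + SPEC.radius + 1, i + SPEC.radius + 4):
            states[j] = "E"
        seg = segment_indicators(states, SPEC)
        assert seg[i, 3:].tolist() == [0.0, 1.0, 0.0]

    def test_short_helix_run_falls_through_to_coil(self):
        states = ["C"] * 40
        i = 20
        for j in range(i - SPEC.radius - 8, i - SPEC.radius - 5):  # only 3 H
            states[j] = "H"
        seg = segment_indicators(states, SPEC)
        assert seg[i, :3].tolist() == [0.0, 0.0, 1.0]


class TestConservation:
    def test_uniform_entropy(self):
        A, B, C = conservation_scores(np.full(20, 1 / 20))
        assert A[0] == pytest.approx(math.log2(20))

    def test_background_has_zero_divergence(self):
        A, B, C = conservation_scores(BACKGROUND_FREQS)
        assert B[0] == pytest.approx(0.0, abs=1e-12)
        assert C[0] == pytest.approx(0.0, abs=1e-12)

    def test_concentrated_distribution_zero_entropy(self):
        q = np.zeros(20)
        q[0] = 1.0
        A, B, C = conservation_scores(q)
        assert A[0] == pytest.approx(0.0)
        assert B[0] > 0 and C[0] > 0

    def test_off_sum_rows_renormalized(self, caplog):
        q = np.full(20, 1 / 20) * 1.02  # sums to 1.02
        A, _, _ = conservation_scores(q)
        assert A[0] == pytest.approx(math.log2(20))


class TestCollocations:
    def test_candidate_space_is_4000(self):
        from atpsite.features import collocation_offsets
        assert 20 * 20 * len(collocation_offsets(5)) == 4000

    def test_planted_motif_survives_and_null_does_not(self, rng):
        # motif G..K (offset +3) at every binding residue, nowhere else
        seqs, labels = [], []
        for _ in range(20):
            L = 60
            seq = [AA20[c] for c in rng.choice(
                [AA20.index(a) for a in "ACDEFHIMNPQRSTVWY"], size=L)]
            lab = np.zeros(L, dtype=int)
            for i in rng.choice(L - 4, size=4, replace=False):
                lab[i] = 1
                seq[i] = "G"
                seq[i + 3] = "K"
            seqs.append("".join(seq))
            labels.append(lab)
        pairs = screen_collocations(seqs, labels)
        names = {(p.center, p.partner, p.offset) for p in pairs}
        assert ("G", "K", 3) in names
        # an unassociated pair must not appear
        assert ("A", "C", 1) not in names

    def test_screen_is_deterministic(self, small_dataset):
        seqs = [c.bundle.sequence.sequence for c in small_dataset]
        labels = [c.labeled.labels for c in small_dataset]
        p1 = screen_collocations(seqs, labels, p_cut=1e-3)
        p2 = screen_collocations(seqs, labels, p_cut=1e-3)
        assert [(p.center, p.partner, p.offset, p.p_value) for p in p1] == \
               [(p.center, p.partner, p.offset, p.p_value) for p in p2]

    def test_fisher_pvalues_match_enumeration_oracle(self, rng):
        # exact two-sided Fisher by enumerating all tables with the margins
        def fisher_enum(a, b, c, d):
            n, r1, c1 = a + b + c + d, a + b, a + c

            def table_p(k):
                return (math.comb(r1, k) * math.comb(n - r1, c1 - k)
                        / math.comb(n, c1))

            p_obs = table_p(a)
            lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
            return sum(table_p(k) for k in range(lo, hi + 1)
                       if table_p(k) <= p_obs * (1 + 1e-9))

        from scipy.stats import fisher_exact
        for _ in range(25):
            a, b, c, d = rng.integers(0, 12, size=4)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            _, p = fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(fisher_enum(a, b, c, d), rel=1e-9)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            screen_collocations([], [])

    def test_binary_presence_features(self):
        from atpsite.features import CollocationPair
        pairs = [CollocationPair("G", "K", 3)]
        f = collocation_features("AGAAKA", pairs)
        assert f[:, 0].tolist() == [0, 1, 0, 0, 0, 0]


class TestEncodeChain:
    def test_group_widths_and_total(self, small_dataset):
        X = encode_chain(small_dataset[0].bundle)
        counts = {}
        for col in X.columns:
            counts[col.split(".")[0]] = counts.get(col.split(".")[0], 0) + 1
        assert counts == {"pssm": 180, "ss": 51, "rsa": 17, "dih": 34,
                          "aagrp": 36, "term": 1, "seg": 6,
                          "consA": 17, "consB": 17, "consC": 17}

    def test_deterministic(self, small_dataset):
        b = small_dataset[0].bundle
        X1, X2 = encode_chain(b), encode_chain(b)
        assert X1.equals(X2)

    def test_length_one_chain(self):
        chains = simulate_dataset(SimConfig(n_chains=1, length_mean=1,
                                            length_sd=0, min_length=1,
                                            positive_fraction=0.5,
                                            segment_len_range=(1, 1),
                                            motif=None, seed=3))
        X = encode_chain(chains[0].bundle)
        assert X.shape == (1, 376)

    def test_value_ranges(self, small_dataset):
        X = encode_chain(small_dataset[0].bundle)
        pssm_cols = [c for c in X.columns if c.startswith("pssm.")]
        assert ((X[pssm_cols] > 0) & (X[pssm_cols] < 1)).all().all()
        track_cols = [c for c in X.columns
                      if c.startswith(("ss.", "rsa."))]
        assert ((X[track_cols] >= 0) & (X[track_cols] <= 1)).all().all()
        dih_cols = [c for c in X.columns if c.startswith("dih.")]
        assert ((X[dih_cols] >= -1) & (X[dih_cols] <= 1)).all().all()

    def test_fitted_screen_excludes_test_only_pairs(self, rng):
        # a pair present only in chains outside the fit set must not appear
        train_seqs = ["ACDEF" * 10] * 3
        train_labels = [np.zeros(50, dtype=int) for _ in range(3)]
        for lab in train_labels:
            lab[:2] = 1
        screen = CollocationScreen(p_cut=0.5).fit(train_seqs, train_labels)
        names = {(p.center, p.partner, p.offset) for p in screen.pairs_}
        assert ("W", "W", 1) not in names  # W absent from training chains
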