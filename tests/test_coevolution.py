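"""Mutual information, mean-field DCA and residue-level summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thoipakit import errors
from thoipakit.coevolution import (
    ALPHABET,
    Q,
    CoevolutionMatrix,
    DcaParams,
    coevolution_features,
    coevolution_summaries,
    di_matrix,
    encode_alignment,
    mi_matrix,
    normalise_per_tmd,
    sequence_weights,
)
from thoipakit.msa_features import Alignment
from thoipakit.synthetic_fixtures import FixtureSpec, synth_msa


def _aln(rows):
    return Alignment(rows=list(rows))


class TestMutualInformation:
    def test_perfectly_covarying_two_state_columns(self):
        # equal frequency, no pseudocount: MI = 1 bit
        aln = _aln(["AC", "CA", "AC", "CA"])
        mi = mi_matrix(aln, DcaParams(theta=0.8, pseudocount=0.0))
        assert mi.values[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_bounded_by_column_entropies(self, rng):
        rows = ["".join(rng.choice(list("ACDEFG"), 8)) for _ in range(40)]
        aln = _aln(rows)
        mi = mi_matrix(aln, DcaParams(pseudocount=0.0)).values
        states = encode_alignment(aln)
        w = sequence_weights(states, 0.8)
        w = w / w.sum()
        for i in range(8):
            p = np.bincount(states[:, i], weights=w, minlength=Q)
            h_i = -(p[p > 0] * np.log2(p[p > 0])).sum()
            assert (mi[i] <= h_i + 1e-9).all()

    def test_independent_columns_give_near_zero_mean(self):
        rng = np.random.default_rng(11)
        n = 2000
        rows = ["".join(rng.choice(list(ALPHABET[:20]), 6)) for _ in range(n)]
        mi = mi_matrix(_aln(rows), DcaParams(pseudocount=0.0)).values
        off = mi[np.triu_indices(6, 1)]
        # Miller-Madow finite-sample bias of the plug-in MI estimate
        bias = (20 - 1) ** 2 / (2 * n * np.log(2))
        assert abs(off.mean() - bias) < 0.05
        assert off.mean() < 3 * bias

    def test_single_row_rejected(self):
        with pytest.raises(errors.InsufficientDepthError):
            mi_matrix(_aln(["ACDE"]))


def _brute_force_di(aln, params):
    """Independent mean-field DI oracle for a 2-column alignment.

    Re-derives weights, regularised frequencies, the single coupling block
    from a direct 2x2 linear solve per state pair, and the two-site direct
    model by an explicit fixed point, all with plain loops.
    """
    states = encode_alignment(aln)
    m, length = states.shape
    assert length == 2
    # weights
    w = []
    for i in range(m):
        n = 0
        for j in range(m):
            ident = sum(states[i, k] == states[j, k] for k in range(length))
            if ident >= params.theta * length:
                n += 1
        w.append(1.0 / n)
    w = np.array(w)
    meff = w.sum()
    lam = params.pseudocount * meff
    fi = np.full((length, Q), lam / Q)
    for s in range(m):
        for i in range(length):
            fi[i, states[s, i]] += w[s]
    fi /= meff + lam
    fij = np.full((Q, Q), lam / Q**2)
    for s in range(m):
        fij[states[s, 0], states[s, 1]] += w[s]
    fij /= meff + lam
    # covariance matrix over (site, state) with the last state removed
    q1 = Q - 1
    cov = np.zeros((2 * q1, 2 * q1))
    for a in range(q1):
        for b in range(q1):
            cov[a, b] = (a == b) * fi[0, a] - fi[0, a] * fi[0, b]
            cov[q1 + a, q1 + b] = (a == b) * fi[1, a] - fi[1, a] * fi[1, b]
            cov[a, q1 + b] = fij[a, b] - fi[0, a] * fi[1, b]
            cov[q1 + a, b] = fij[b, a] - fi[0, b] * fi[1, a]
    inv = np.linalg.inv(cov)
    e = np.zeros((Q, Q))
    for a in range(q1):
        for b in range(q1):
            e[a, b] = -inv[a, q1 + b]
    wmat = np.exp(e)
    # fit the auxiliary fields by a damped alternating update until the
    # marginals of the direct model match fi to high precision
    mu1 = np.full(Q, 1.0 / Q)
    mu2 = np.full(Q, 1.0 / Q)
    for _ in range(50000):
        n1 = fi[0] / (wmat @ mu2)
        mu1 = 0.7 * mu1 + 0.3 * n1 / n1.sum()
        n2 = fi[1] / (wmat.T @ mu1)
        mu2 = 0.7 * mu2 + 0.3 * n2 / n2.sum()
        p = wmat * np.outer(mu1, mu2)
        p /= p.sum()
        if max(abs(p.sum(1) - fi[0]).max(), abs(p.sum(0) - fi[1]).max()) < 1e-11:
            break
    p = wmat * np.outer(mu1, mu2)
    p /= p.sum()
    di = 0.0
    for a in range(Q):
        for b in range(Q):
            if p[a, b] > 0:
                di += p[a, b] * np.log(p[a, b] / (fi[0, a] * fi[1, b]))
    return max(di, 0.0)


class TestDirectInformation:
    def test_symmetric_and_nonnegative(self, planted_msa):
        di = di_matrix(planted_msa)
        assert np.allclose(di.values, di.values.T)
        assert (di.values >= 0).all()
        assert np.allclose(np.diag(di.values), 0.0)

    def test_two_column_toy_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(2)
        rows = ["".join(rng.choice(list("AC"), 2)) for _ in range(30)]
        params = DcaParams()
        aln = _aln(rows)
        di = di_matrix(aln, params).values[0, 1]
        oracle = _brute_force_di(aln, params)
        assert di == pytest.approx(oracle, rel=1e-5)

    def test_planted_pair_attains_max_nonadjacent_di(self, planted_msa):
        v = di_matrix(planted_msa).values
        length = v.shape[0]
        best = max(
            ((i, j) for i in range(length) for j in range(i + 4, length)),
            key=lambda p: v[p],
        )
        assert best == (5, 12)

    def test_planted_recovery_rate_over_seeds(self):
        hits = 0
        for seed in range(20):
            spec = FixtureSpec(L=20, n_seqs=100, coupled_pairs=((5, 12, 0.9),), seed=seed)
            v = di_matrix(synth_msa(spec)).values
            pairs = sorted(
                ((i, j) for i in range(20) for j in range(i + 4, 20)),
                key=lambda p: -v[p],
            )
            hits += (5, 12) in pairs[:2]
        assert hits >= 18

    def test_neighbour_effect(self):
        # neighbouring residues carry a high coevolution background
        sep1, sep5 = [], []
        for seed in range(5):
            spec = FixtureSpec(L=20, n_seqs=80, seed=seed)
            v = di_matrix(synth_msa(spec)).values
            seps = np.abs(np.subtract.outer(np.arange(20), np.arange(20)))
            sep1.append(v[seps == 1].mean())
            sep5.append(v[seps >= 5].mean())
        assert np.mean(sep1) > np.mean(sep5)


class TestSummaries:
    def test_constant_matrix(self):
        v = np.full((6, 6), 0.7)
        summ = coevolution_summaries(CoevolutionMatrix("DI", v))
        for col in ("max", "mean", "top4mean", "mean_nb2"):
            assert np.allclose(summ[col], 0.7)

    def test_toy_matrix_hand_enumeration(self):
        v = np.zeros((4, 4))
        vals = {(0, 1): 0.1, (0, 2): 0.4, (0, 3): 0.2, (1, 2): 0.8, (1, 3): 0.3, (2, 3): 0.6}
        for (i, j), x in vals.items():
            v[i, j] = v[j, i] = x
        summ = coevolution_summaries(CoevolutionMatrix("MI", v))
        assert summ.loc[0, "max"] == pytest.approx(0.4)
        assert summ.loc[0, "mean"] == pytest.approx((0.1 + 0.4 + 0.2) / 3)
        assert summ.loc[1, "mean_nb1"] == pytest.approx((0.1 + 0.8) / 2)
        assert summ.loc[2, "top2mean"] == pytest.approx((0.8 + 0.6) / 2)
        # span of 4 < 5: top4mean falls back to the 3 available pairs
        assert summ.loc[3, "top4mean"] == pytest.approx((0.2 + 0.3 + 0.6) / 3)

    def test_max_is_row_maximum(self, planted_msa):
        mat = mi_matrix(planted_msa)
        summ = coevolution_summaries(mat)
        v = mat.values.copy()
        np.fill_diagonal(v, -np.inf)
        assert np.allclose(summ["max"], v.max(axis=1))


class TestNormalisation:
    def test_constant_maps_to_zero(self):
        assert np.allclose(normalise_per_tmd([2.0, 2.0, 2.0]), 0.0)

    def test_endpoints(self):
        out = normalise_per_tmd([3.0, 1.0, 2.0])
        assert out[1] == 0.0 and out[0] == 1.0

    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=20, unique=True),
        st.floats(0.1, 5),
        st.floats(-10, 10),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_affine_invariance(self, values, a, b):
        base = normalise_per_tmd(values)
        scaled = normalise_per_tmd([a * v + b for v in values])
        assert np.allclose(base, scaled, atol=1e-8)


def test_feature_family_has_52_columns(planted_msa):
    feats = coevolution_features(planted_msa)
    assert feats.shape[1] == 52
    norm_cols = [c for c in feats.columns if c.endswith("_norm")]
    assert len(norm_cols) == 26
    for c in norm_cols:
        assert feats[c].between(0, 1).all()
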