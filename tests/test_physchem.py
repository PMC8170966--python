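import numpy as np
import pytest

from nucleocgr.physchem_features import (
    AutocovParams,
    PseKNCParams,
    all_oligos,
    autocovariance_features,
    load_index_table,
    pse_knc_parallel,
)


def naive_autocov(seq, table, params):
    """Independent double-loop implementation of AC and CC."""
    k = table.order
    M = len(seq) - k + 1
    prof = np.array(
        [table.values[all_oligos(k).index(seq[i : i + k])] for i in range(M)]
    )
    means = prof.mean(axis=0)
    N = table.n_indices
    out = []
    for u in range(N):
        for d in range(1, params.lag + 1):
            s = 0.0
            for i in range(M - d):
                s += (prof[i, u] - means[u]) * (prof[i + d, u] - means[u])
            out.append(s / (M - d))
    if params.include_cross:
        for u1 in range(N):
            for u2 in range(N):
                if u1 == u2:
                    continue
                for d in range(1, params.lag + 1):
                    s = 0.0
                    for i in range(M - d):
                        s += (prof[i, u1] - means[u1]) * (prof[i + d, u2] - means[u2])
                    out.append(s / (M - d))
    return np.array(out)


def naive_pse(seq, table, params):
    """Independent implementation of the parallel pseudo composition."""
    k = table.order
    M = len(seq) - k + 1
    oligos = all_oligos(k)
    freqs = np.zeros(4**k)
    for i in range(M):
        freqs[oligos.index(seq[i : i + k])] += 1
    freqs /= M
    prof = np.array([table.values[oligos.index(seq[i : i + k])] for i in range(M)])
    thetas = []
    for j in range(1, params.lam + 1):
        tot = 0.0
        for i in range(M - j):
            tot += np.mean((prof[i] - prof[i + j]) ** 2)
        thetas.append(tot / (M - j))
    thetas = np.array(thetas)
    denom = 1 + params.w * thetas.sum()
    return np.concatenate([freqs / denom, params.w * thetas / denom])


def test_builtin_tables_standardized(dinuc_table, trinuc_table):
    for tab, n_oligo in ((dinuc_table, 16), (trinuc_table, 64)):
        assert tab.values.shape[0] == n_oligo
        assert np.allclose(tab.values.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(tab.values.std(axis=0), 1, atol=1e-9)
    assert dinuc_table.n_indices == 6
    assert trinuc_table.n_indices == 2


def test_load_table_errors(tmp_path):
    p = tmp_path / "t.tsv"
    rows = [f"{o}\t1.0" for o in all_oligos(2) if o != "GT"]
    p.write_text("oligo\tIdx\n" + "\n".join(rows) + "\n")
    with pytest.raises(ValueError, match="GT"):
        load_index_table(p, 2)
    p2 = tmp_path / "c.tsv"
    p2.write_text("oligo\tIdx\n" + "\n".join(f"{o}\t3.0" for o in all_oligos(2)) + "\n")
    with pytest.raises(ValueError, match="constant"):
        load_index_table(p2, 2)
    with pytest.raises(FileNotFoundError):
        load_index_table("no-such-table", 2)


def test_autocov_zero_on_homopolymer(dinuc_table):
    v = autocovariance_features("A" * 50, dinuc_table, AutocovParams(lag=2))
    assert np.allclose(v, 0)


def test_autocov_dimensions(dinuc_table, trinuc_table):
    seq = "ACGTACGTACGTACGTACGT"
    assert autocovariance_features(seq, dinuc_table, AutocovParams(lag=2)).shape == (12,)
    assert autocovariance_features(
        seq, dinuc_table, AutocovParams(lag=2, include_cross=True)
    ).shape == (72,)
    assert autocovariance_features(
        seq, trinuc_table, AutocovParams(lag=2, order=3)
    ).shape == (4,)
    assert autocovariance_features(
        seq, trinuc_table, AutocovParams(lag=2, order=3, include_cross=True)
    ).shape == (4 + 2 * 1 * 2,)


def test_autocov_matches_naive_oracle(dinuc_table, trinuc_table):
    rng = np.random.default_rng(2)
    for _ in range(25):
        seq = "".join(rng.choice(list("ACGT"), int(rng.integers(30, 80))))
        for tab in (dinuc_table, trinuc_table):
            params = AutocovParams(lag=3, order=tab.order, include_cross=True)
            got = autocovariance_features(seq, tab, params)
            want = naive_autocov(seq, tab, params)
            np.testing.assert_allclose(got, want, atol=1e-10)


def test_autocov_too_short(dinuc_table):
    with pytest.raises(ValueError):
        autocovariance_features("ACG", dinuc_table, AutocovParams(lag=2))


def test_autocov_invariant_to_raw_index_shift(tmp_path):
    """Adding a constant to a raw index before standardization changes nothing."""
    rng = np.random.default_rng(1)
    vals = rng.normal(size=16)
    for shift in (0.0, 100.0):
        p = tmp_path / f"s{shift}.tsv"
        p.write_text(
            "oligo\tIdx\n"
            + "\n".join(f"{o}\t{v + shift}" for o, v in zip(all_oligos(2), vals))
            + "\n"
        )
        tab = load_index_table(p, 2)
        out = autocovariance_features("ACGTTGCAACGT", tab, AutocovParams(lag=2))
        if shift == 0.0:
            base = out
    np.testing.assert_allclose(out, base, atol=1e-12)


def test_pse_dimensions_and_normalization(dinuc_table, trinuc_table):
    seq = "ACGTACGTACGTACGTACGTACGT"
    v2 = pse_knc_parallel(seq, dinuc_table, PseKNCParams(lam=8, w=0.5, order=2))
    v3 = pse_knc_parallel(seq, trinuc_table, PseKNCParams(lam=8, w=0.5, order=3))
    assert v2.shape == (24,)
    assert v3.shape == (72,)
    assert v2.sum() == pytest.approx(1.0, abs=1e-9)
    assert v3.sum() == pytest.approx(1.0, abs=1e-9)
    assert (v2 >= 0).all() and (v3 >= 0).all()


def test_pse_w_zero_reduces_to_frequencies(dinuc_table):
    seq = "ACGTTGCATTGCAACG"
    v = pse_knc_parallel(seq, dinuc_table, PseKNCParams(lam=4, w=0.0, order=2))
    M = len(seq) - 1
    freqs = np.zeros(16)
    for i in range(M):
        freqs[all_oligos(2).index(seq[i : i + 2])] += 1 / M
    np.testing.assert_allclose(v[:16], freqs, atol=1e-12)
    assert np.allclose(v[16:], 0)


def test_pse_matches_naive_oracle(dinuc_table, trinuc_table):
    rng = np.random.default_rng(3)
    for _ in range(20):
        seq = "".join(rng.choice(list("ACGT"), int(rng.integers(40, 90))))
        for tab in (dinuc_table, trinuc_table):
            params = PseKNCParams(lam=6, w=0.5, order=tab.order)
            np.testing.assert_allclose(
                pse_knc_parallel(seq, tab, params),
                naive_pse(seq, tab, params),
                atol=1e-10,
            )


def test_pse_lambda_too_large(dinuc_table):
    with pytest.raises(ValueError):
        pse_knc_parallel("ACGTA", dinuc_table, PseKNCParams(lam=8, order=2))
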