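"""Distance matrices and the Mantel permutation test."""

import itertools

import numpy as np
import pandas as pd
import pytest

from clonalquant import (
    CloneGenealogySpec,
    mantel_test,
    p_distance,
    phenotypic_distance,
    simulate_snp_matrix,
)
from clonalquant.distance import DistanceMatrix, read_fasta_matrix


def _blups(n=5, p=3, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(n, p)),
        index=[f"g{i}" for i in range(n)],
        columns=[f"t{j}" for j in range(p)],
    )


def _random_dm(rng, n=5):
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix(tuple(f"g{i}" for i in range(n)), m)


class TestPhenotypicDistance:
    def test_identical_rows_have_zero_distance(self):
        blups = _blups(5, 3)
        blups.iloc[1] = blups.iloc[0]
        d = phenotypic_distance(blups)
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_squared_distances_add_across_traits(self):
        blups = _blups(5, 4, seed=3)
        overall = phenotypic_distance(blups).values ** 2
        per_trait = sum(
            phenotypic_distance(blups, [t]).values ** 2 for t in blups.columns
        )
        assert np.allclose(overall, per_trait, atol=1e-10)

    def test_zero_variance_trait_rejected_by_name(self):
        blups = _blups()
        blups["t1"] = 1.0
        with pytest.raises(ValueError, match="t1"):
            phenotypic_distance(blups)

    def test_two_genotypes_rejected_as_degenerate(self):
        with pytest.raises(ValueError):
            phenotypic_distance(_blups(2, 3))

    def test_csv_round_trip(self, tmp_path):
        d = phenotypic_distance(_blups(seed=9))
        path = tmp_path / "d.csv"
        d.to_csv(path)
        back = DistanceMatrix.from_csv(path)
        assert back.labels == d.labels
        assert np.allclose(back.values, d.values)


class TestPDistance:
    def test_identical_rows(self):
        m = pd.DataFrame([[0, 1, 0], [0, 1, 0]], index=["a", "b"])
        assert p_distance(m).values[0, 1] == 0.0

    def test_two_of_ten_sites_differ(self):
        a = np.zeros(10)
        b = a.copy()
        b[[3, 7]] = 1
        m = pd.DataFrame([a, b], index=["a", "b"])
        assert p_distance(m).values[0, 1] == pytest.approx(0.2)

    def test_missing_sites_excluded_pairwise(self):
        m = pd.DataFrame(
            [[0, 1, np.nan, 0], [0, 0, 1, 0], [1, 0, 1, np.nan]],
            index=["a", "b", "c"],
        )
        d = p_distance(m)
        assert d.values[0, 1] == pytest.approx(1 / 3)  # site 2 dropped for (a,b)
        assert d.values[1, 2] == pytest.approx(1 / 3)  # site 3 dropped for (b,c)

    def test_matches_brute_force_site_count_oracle(self):
        spec = CloneGenealogySpec.caterpillar(
            ["a", "b", "c", "d", "e"], [3, 4, 5, 6, 7], [2, 3, 4], 400
        )
        m = simulate_snp_matrix(spec, seed=5)
        d = p_distance(m)
        arr = m.to_numpy()
        for i in range(len(m)):
            for j in range(len(m)):
                count = sum(
                    1 for s in range(arr.shape[1]) if arr[i, s] != arr[j, s]
                )
                assert d.values[i, j] == pytest.approx(count / 400)

    def test_no_comparable_sites_rejected(self):
        m = pd.DataFrame([[np.nan, 1.0], [0.0, np.nan]], index=["a", "b"])
        with pytest.raises(ValueError, match="comparable"):
            p_distance(m)

    def test_fasta_input(self, tmp_path):
        fasta = tmp_path / "aln.fasta"
        fasta.write_text(">a\nACGTAC\n>b\nACGTTT\n>c\nACNTTT\n")
        d = p_distance(read_fasta_matrix(fasta))
        assert d.values[0, 1] == pytest.approx(2 / 6)
        assert d.values[1, 2] == pytest.approx(0.0)  # N site excluded


class TestMantel:
    def test_self_comparison_gives_r_one_and_smallest_p(self):
        d = _random_dm(np.random.default_rng(0))
        res = mantel_test(d, d)
        assert res.r == pytest.approx(1.0)
        assert res.exhaustive
        assert res.n_permutations == 120
        # p is the smallest attainable value: only permutations tying r=1
        assert res.p == pytest.approx(1 / 120)

    def test_exhaustive_null_matches_independent_enumeration(self):
        rng = np.random.default_rng(1)
        d1, d2 = _random_dm(rng), _random_dm(rng)
        res = mantel_test(d1, d2)

        # brute-force oracle with plain itertools + corrcoef
        idx = np.tril_indices(5, k=-1)
        x = d1.values[idx]
        r_null = []
        for perm in itertools.permutations(range(5)):
            y = d2.values[np.ix_(perm, perm)][idx]
            r_null.append(np.corrcoef(x, y)[0, 1])
        r_null = np.array(r_null)
        r_obs = np.corrcoef(x, d2.values[idx])[0, 1]
        assert res.r == pytest.approx(r_obs, abs=1e-12)
        assert res.p == pytest.approx(np.mean(r_null >= r_obs - 1e-12))
        assert res.p * 120 == pytest.approx(round(res.p * 120))

    def test_invariance_under_positive_affine_rescaling(self):
        rng = np.random.default_rng(2)
        d1, d2 = _random_dm(rng), _random_dm(rng)
        res = mantel_test(d1, d2)
        scaled = 3.0 * d2.values + 0.7
        np.fill_diagonal(scaled, 0.0)
        res2 = mantel_test(d1, DistanceMatrix(d2.labels, scaled))
        assert res2.r == pytest.approx(res.r, abs=1e-12)
        assert res2.p == res.p

    def test_r_matches_scikit_bio(self):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(3)
        d1, d2 = _random_dm(rng, n=8), _random_dm(rng, n=8)
        res = mantel_test(d1, d2, n_perm=99, seed=0)
        r_ref, _, _ = skbio_mantel(
            SkbioDM(d1.values, ids=d1.labels),
            SkbioDM(d2.values, ids=d2.labels),
            permutations=0,
        )
        assert res.r == pytest.approx(float(r_ref), abs=1e-10)

    def test_label_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        d1 = _random_dm(rng)
        d2 = DistanceMatrix(tuple("vwxyz"), d1.values)
        with pytest.raises(ValueError, match="label"):
            mantel_test(d1, d2)

    def test_constant_off_diagonal_rejected(self):
        rng = np.random.default_rng(5)
        other = _random_dm(rng)
        const = np.ones((5, 5)) - np.eye(5)
        with pytest.raises(ValueError, match="constant"):
            mantel_test(DistanceMatrix(other.labels, const), other)

    def test_phylip_round_trip_values(self, tmp_path):
        d = _random_dm(np.random.default_rng(6))
        path = tmp_path / "d.phy"
        d.to_phylip(path)
        lines = path.read_text().strip().splitlines()
        assert lines[0].strip() == "5"
        row0 = np.array([float(v) for v in lines[1].split()[1:]])
        assert np.allclose(row0, d.values[0], atol=1e-6)
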