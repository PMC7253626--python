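"""Relationship matrix and Gibbs animal model."""

from functools import lru_cache

import numpy as np
import pandas as pd
import pytest

from phenoseg.errors import PedigreeError
from phenoseg.genetics import (GibbsConfig, build_a_matrix,
                               gibbs_animal_model, read_pedigree,
                               summarize_posterior)
from phenoseg.synthetic import PedigreeSimSpec, simulate_pedigree_phenotypes


def _ped(rows):
    return pd.DataFrame(rows, columns=["id", "sire", "dam"]).astype(str)


def kinship_oracle(sire: dict, dam: dict):
    """Independent memoized kinship recursion; A_ij = 2 * phi(i, j)."""

    @lru_cache(maxsize=None)
    def phi(i, j):
        if i is None or j is None:
            return 0.0
        if i == j:
            return 0.5 * (1.0 + phi(sire[i], dam[i]))
        # recurse on the individual that cannot be the other's ancestor:
        # the later one in topological order
        a, b = (i, j) if order[i] > order[j] else (j, i)
        return 0.5 * (phi(sire[a], b) + phi(dam[a], b))

    order = {k: n for n, k in enumerate(sire)}
    order[None] = -1
    return phi


def random_pedigree(rng, n):
    ids = [str(i) for i in range(1, n + 1)]
    rows = []
    for k, i in enumerate(ids):
        if k < 2 or rng.random() < 0.3:
            rows.append((i, "0", "0"))
        else:
            s = ids[rng.integers(0, k)] if rng.random() < 0.85 else "0"
            d = ids[rng.integers(0, k)] if rng.random() < 0.85 else "0"
            rows.append((i, s, d))
    return _ped(rows)


def a_vs_oracle_max_diff(df) -> float:
    ped = read_pedigree(df)
    a = build_a_matrix(ped)
    sire = {i: (ped.ids[ped.sire_idx[k]] if ped.sire_idx[k] >= 0 else None)
            for k, i in enumerate(ped.ids)}
    dam = {i: (ped.ids[ped.dam_idx[k]] if ped.dam_idx[k] >= 0 else None)
           for k, i in enumerate(ped.ids)}
    phi = kinship_oracle(sire, dam)
    n = len(ped.ids)
    diffs = [abs(a[i, j] - 2.0 * phi(ped.ids[i], ped.ids[j]))
             for i in range(n) for j in range(i, n)]
    return max(diffs)


class TestReadPedigree:
    def test_topological_order(self):
        ped = read_pedigree(_ped([("3", "1", "2"), ("1", "0", "0"),
                                  ("2", "0", "0")]))
        assert len(ped) == 3
        assert ped.ids.index("3") > ped.ids.index("1")
        assert ped.ids.index("3") > ped.ids.index("2")

    def test_undeclared_parents_become_founders(self):
        ped = read_pedigree(_ped([("3", "1", "2")]))
        assert sorted(ped.ids) == ["1", "2", "3"]
        k = ped.ids.index("1")
        assert ped.sire_idx[k] == -1 and ped.dam_idx[k] == -1

    def test_cycle_is_an_error(self):
        with pytest.raises(PedigreeError, match="cycle"):
            read_pedigree(_ped([("1", "2", "0"), ("2", "1", "0")]))

    def test_duplicate_id_is_an_error(self):
        with pytest.raises(PedigreeError, match="duplicate"):
            read_pedigree(_ped([("1", "0", "0"), ("1", "0", "0")]))


class TestAMatrix:
    def test_trio(self):
        ped = read_pedigree(_ped([("1", "0", "0"), ("2", "0", "0"),
                                  ("3", "1", "2")]))
        a = build_a_matrix(ped)
        idx = ped.index
        expected = np.array([[1.0, 0.0, 0.5], [0.0, 1.0, 0.5], [0.5, 0.5, 1.0]])
        perm = [idx["1"], idx["2"], idx["3"]]
        assert np.allclose(a[np.ix_(perm, perm)], expected)

    def test_full_sibs_and_inbred_diagonal(self):
        ped = read_pedigree(_ped([("1", "0", "0"), ("2", "0", "0"),
                                  ("3", "1", "2"), ("4", "1", "2"),
                                  ("5", "3", "1")]))
        a = build_a_matrix(ped)
        idx = ped.index
        assert a[idx["3"], idx["4"]] == 0.5          # full sibs
        assert a[idx["5"], idx["5"]] == 1.25         # sire-daughter mating
        assert a[idx["1"], idx["2"]] == 0.0          # founders unrelated

    def test_matches_kinship_oracle_on_random_pedigrees(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            df = random_pedigree(rng, int(rng.integers(5, 50)))
            assert a_vs_oracle_max_diff(df) <= 1e-12

    def test_positive_semidefinite_and_symmetric(self):
        rng = np.random.default_rng(23)
        df = random_pedigree(rng, 40)
        a = build_a_matrix(read_pedigree(df))
        assert np.allclose(a, a.T)
        assert np.linalg.eigvalsh(a).min() > -1e-10
        assert ((np.diag(a) >= 1.0) & (np.diag(a) <= 2.0)).all()


@pytest.fixture(scope="module")
def sim_h05():
    spec = PedigreeSimSpec(h2=0.5, seed=42)
    ped, phen, _ = simulate_pedigree_phenotypes(spec)
    p = read_pedigree(ped)
    a = build_a_matrix(p)
    pos = np.array([p.index[i] for i in phen["id"]])
    order = np.argsort(pos)
    return phen["trait"].to_numpy()[order], a[np.ix_(pos[order], pos[order])]


class TestGibbsAnimalModel:
    def test_sample_support(self, sim_h05):
        y, a = sim_h05
        post = gibbs_animal_model(y[:200], a[:200, :200],
                                  GibbsConfig(n_iter=120, burn_in=20, seed=1))
        assert ((post.h2 > 0) & (post.h2 < 1)).all()
        assert (post.sigma2_a > 0).all() and (post.sigma2_e > 0).all()
        assert np.allclose(post.h2, post.sigma2_a
                           / (post.sigma2_a + post.sigma2_e))

    def test_chain_determinism(self, sim_h05):
        y, a = sim_h05
        cfg = GibbsConfig(n_iter=80, burn_in=10, seed=9)
        p1 = gibbs_animal_model(y[:150], a[:150, :150], cfg)
        p2 = gibbs_animal_model(y[:150], a[:150, :150], cfg)
        assert (p1.h2 == p2.h2).all()
        assert (p1.sigma2_a == p2.sigma2_a).all()

    def test_recovers_moderate_heritability(self, sim_h05):
        y, a = sim_h05
        post = gibbs_animal_model(y, a, GibbsConfig(n_iter=1200, burn_in=200,
                                                    seed=3))
        assert abs(post.h2.mean() - 0.5) <= 0.10

    def test_near_zero_heritability_concentrates_low(self):
        spec = PedigreeSimSpec(h2=0.0, seed=11)
        ped, phen, _ = simulate_pedigree_phenotypes(spec)
        p = read_pedigree(ped)
        a = build_a_matrix(p)
        pos = np.sort(np.array([p.index[i] for i in phen["id"]]))
        post = gibbs_animal_model(phen["trait"].to_numpy(), a[np.ix_(pos, pos)],
                                  GibbsConfig(n_iter=600, burn_in=150, seed=5))
        assert post.h2.mean() <= 0.15

    def test_refuses_tiny_or_bad_input(self):
        a = np.eye(5)
        with pytest.raises(ValueError, match="10"):
            gibbs_animal_model(np.ones(5), a, GibbsConfig(n_iter=20, burn_in=1))
        y = np.random.default_rng(0).normal(size=12)
        y[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            gibbs_animal_model(y, np.eye(12), GibbsConfig(n_iter=20, burn_in=1))

    def test_half_sib_anova_agreement(self):
        # balanced design: 100 unrelated sires x 10 progeny, dams unknown
        rng = np.random.default_rng(31)
        n_sires, k = 100, 10
        s2a, s2e = 0.4, 0.6
        rows = [(str(s + 1), "0", "0") for s in range(n_sires)]
        a_sire = rng.normal(0, np.sqrt(s2a), n_sires)
        y = np.empty(n_sires * k)
        for s in range(n_sires):
            for j in range(k):
                pid = n_sires + s * k + j + 1
                rows.append((str(pid), str(s + 1), "0"))
                a_prog = 0.5 * a_sire[s] + rng.normal(0, np.sqrt(0.75 * s2a))
                y[s * k + j] = a_prog + rng.normal(0, np.sqrt(s2e))
        groups = y.reshape(n_sires, k)
        msb = k * groups.mean(axis=1).var(ddof=1)
        msw = groups.var(axis=1, ddof=1).mean()
        sig_s = (msb - msw) / k
        h2_anova = 4 * sig_s / (sig_s + msw)

        ped = read_pedigree(_ped(rows))
        a = build_a_matrix(ped)
        prog_ids = [str(i) for i in range(n_sires + 1, n_sires + n_sires * k + 1)]
        pos = np.array([ped.index[i] for i in prog_ids])
        order = np.argsort(pos)
        post = gibbs_animal_model(y[order], a[np.ix_(pos[order], pos[order])],
                                  GibbsConfig(n_iter=1200, burn_in=200, seed=13))
        assert abs(post.h2.mean() - h2_anova) <= 0.05


class TestSummarizePosterior:
    def _posterior(self, h2):
        from phenoseg.genetics import HeritabilityPosterior

        h2 = np.asarray(h2, dtype=float)
        return HeritabilityPosterior(sigma2_a=h2, sigma2_e=1 - h2, h2=h2)

    def test_constant_samples(self):
        summ, dens = summarize_posterior(self._posterior(np.full(100, 0.3)))
        assert summ["h2_mean"] == summ["h2_median"] == pytest.approx(0.3)
        assert summ["h2_ci95_lo"] == summ["h2_ci95_hi"] == pytest.approx(0.3)

    def test_uniform_grid_mean(self):
        summ, dens = summarize_posterior(
            self._posterior(np.linspace(0.1, 0.9, 81)))
        assert summ["h2_mean"] == pytest.approx(0.5)
        assert dens.shape[1] == 2

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            summarize_posterior(self._posterior(np.linspace(0.2, 0.4, 20)))

    def test_summary_recomputable_from_samples(self):
        rng = np.random.default_rng(3)
        post = self._posterior(rng.beta(2, 3, size=500))
        s1 = summarize_posterior(post)[0]
        s2 = summarize_posterior(post)[0]
        assert s1 == s2 == post.summary()
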