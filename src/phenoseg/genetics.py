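"""Pedigree relationships and Bayesian heritability via Gibbs sampling.

Given a pedigree (id, sire, dam; unknown parents coded 0/NA/blank) this
module builds the additive (numerator) relationship matrix A by the tabular
method and fits, one trait at a time, the animal model

    y = 1 mu + a + e,    a ~ N(0, A sigma2_a),   e ~ N(0, I sigma2_e)

with a Gibbs sampler, yielding the posterior of the variance components and
of the narrow-sense heritability h2 = sigma2_a / (sigma2_a + sigma2_e).

Variance priors are scaled inverse chi-square; by default the prior scales
split the observed phenotypic variance 50/50 between the two components
(df 5 each), which mirrors common "default prior" practice in Bayesian
animal-model software.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PedigreeError

UNKNOWN = {"", "0", "na", "nan", "none", "."}


@dataclass
class Pedigree:
    """Topologically ordered pedigree (every parent precedes its offspring)."""

    ids: list[str]
    sire_idx: np.ndarray   # -1 when unknown
    dam_idx: np.ndarray

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def index(self) -> dict[str, int]:
        return {i: k for k, i in enumerate(self.ids)}


def _norm_parent(v) -> str | None:
    s = str(v).strip()
    return None if s.lower() in UNKNOWN else s


def read_pedigree(source) -> Pedigree:
    """Read and validate a pedigree from a CSV path or DataFrame.

    Columns ``id, sire, dam``; 0/NA/empty mean unknown.  Parents that never
    appear as individuals are inserted as founders.  Duplicate ids and
    ancestry cycles are errors (the cycle is named in the message).
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(
        source, dtype=str, keep_default_na=False)
    missing_cols = {"id", "sire", "dam"} - set(df.columns)
    if missing_cols:
        raise PedigreeError(f"pedigree is missing columns {sorted(missing_cols)}")

    ids = [str(v).strip() for v in df["id"]]
    dup = pd.Series(ids)[pd.Series(ids).duplicated()]
    if len(dup):
        raise PedigreeError(f"duplicate individual id(s): {sorted(set(dup))}")
    parents = {i: (_norm_parent(s), _norm_parent(d))
               for i, s, d in zip(ids, df["sire"], df["dam"])}
    # auto-insert undeclared parents as founders
    declared = set(ids)
    for s, d in list(parents.values()):
        for p in (s, d):
            if p is not None and p not in declared:
                parents[p] = (None, None)
                declared.add(p)
                ids.append(p)

    # Kahn topological sort, parents before offspring
    order: list[str] = []
    n_parents = {i: sum(p is not None for p in parents[i]) for i in ids}
    children: dict[str, list[str]] = {i: [] for i in ids}
    for i, (s, d) in parents.items():
        for p in {s, d} - {None}:
            children[p].append(i)
    ready = sorted(i for i in ids if n_parents[i] == 0)
    remaining = dict(n_parents)
    while ready:
        cur = ready.pop()
        order.append(cur)
        for ch in children[cur]:
            remaining[ch] -= sum(p == cur for p in parents[ch] if p is not None)
            if remaining[ch] <= 0 and ch not in order:
                ready.append(ch)
    if len(order) != len(ids):
        cyc = sorted(set(ids) - set(order))
        raise PedigreeError(f"pedigree contains an ancestry cycle among {cyc}")

    idx = {i: k for k, i in enumerate(order)}
    sire_idx = np.array([idx[parents[i][0]] if parents[i][0] else -1
                         for i in order], dtype=np.int64)
    dam_idx = np.array([idx[parents[i][1]] if parents[i][1] else -1
                        for i in order], dtype=np.int64)
    return Pedigree(ids=order, sire_idx=sire_idx, dam_idx=dam_idx)


def build_a_matrix(pedigree: Pedigree) -> np.ndarray:
    """Additive relationship matrix by the tabular method.

    A_ii = 1 + A_{s,d}/2 (0 for an unknown parent pair); A_ij for j < i is
    the mean of j's relationships to i's parents.  Exact recursion in
    topological order, so founders are mutually unrelated and inbreeding
    accumulates on the diagonal.
    """
    n = len(pedigree)
    a = np.zeros((n, n))
    s, d = pedigree.sire_idx, pedigree.dam_idx
    for i in range(n):
        row = np.zeros(i)
        if s[i] >= 0:
            row += 0.5 * a[s[i], :i]
        if d[i] >= 0:
            row += 0.5 * a[d[i], :i]
        a[i, :i] = row
        a[:i, i] = row
        a[i, i] = 1.0 + (0.5 * a[s[i], d[i]] if s[i] >= 0 and d[i] >= 0 else 0.0)
    return a


@dataclass(frozen=True)
class GibbsConfig:
    n_iter: int = 1000
    burn_in: int = 200
    thin: int = 1
    df_a: float = 5.0
    df_e: float = 5.0
    scale_a: float | None = None   # None = AUTO: var(y)/2
    scale_e: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.df_a <= 0 or self.df_e <= 0:
            raise ValueError("prior degrees of freedom must be positive")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class HeritabilityPosterior:
    """Retained Gibbs samples of (sigma2_a, sigma2_e, h2)."""

    sigma2_a: np.ndarray
    sigma2_e: np.ndarray
    h2: np.ndarray

    def summary(self) -> dict[str, float]:
        q_lo, q_hi = np.quantile(self.h2, [0.025, 0.975])
        return {
            "h2_mean": float(self.h2.mean()),
            "h2_median": float(np.median(self.h2)),
            "h2_ci95_lo": float(q_lo),
            "h2_ci95_hi": float(q_hi),
            "sigma2_a_mean": float(self.sigma2_a.mean()),
            "sigma2_e_mean": float(self.sigma2_e.mean()),
        }


def _scaled_inv_chi2(rng: np.random.Generator, df: float, scale: float) -> float:
    return df * scale / rng.chisquare(df)


def gibbs_animal_model(y: np.ndarray, a_matrix: np.ndarray,
                       config: GibbsConfig = GibbsConfig()) -> HeritabilityPosterior:
    """Gibbs sampler for the intercept-only animal model.

    ``y`` must be the phenotypes of exactly the individuals indexing
    ``a_matrix`` (rows with missing phenotypes are dropped by the caller,
    with the relationship matrix subsetted accordingly).  Breeding values
    are updated single-site from their full conditionals using the inverse
    relationship matrix; variances from scaled inverse chi-square
    conditionals.  Fully deterministic for a fixed seed.
    """
    config.validate()
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError(f"refusing to fit on {n} records (need at least 10)")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite phenotype values")
    if a_matrix.shape != (n, n):
        raise ValueError("A matrix does not match the phenotype vector")

    # invert A, adding a whisker of jitter if it is numerically singular
    jitter = 0.0
    while True:
        try:
            chol = np.linalg.cholesky(a_matrix + jitter * np.eye(n))
            break
        except np.linalg.LinAlgError:
            if jitter >= 1e-8:
                raise
            jitter = 1e-8
    ainv = np.linalg.inv(chol.T) @ np.linalg.inv(chol)
    ainv = (ainv + ainv.T) / 2.0
    adiag = np.diag(ainv).copy()

    vary = float(np.var(y))
    if vary <= 0:
        raise ValueError("phenotype has zero variance")
    s_a = config.scale_a if config.scale_a is not None else 0.5 * vary
    s_e = config.scale_e if config.scale_e is not None else 0.5 * vary

    rng = np.random.default_rng(config.seed)
    mu = float(y.mean())
    a = np.zeros(n)
    s2a = s_a
    s2e = s_e
    u = ainv @ a  # maintained as Ainv @ a

    keep_a, keep_e, keep_h = [], [], []
    for it in range(config.n_iter):
        # mu | rest
        mu = rng.normal((y - a).mean(), np.sqrt(s2e / n))
        # a_i | rest, single site
        z = rng.standard_normal(n)
        for i in range(n):
            prec = 1.0 / s2e + adiag[i] / s2a
            off = u[i] - adiag[i] * a[i]
            m = ((y[i] - mu) / s2e - off / s2a) / prec
            new = m + z[i] / np.sqrt(prec)
            delta = new - a[i]
            if delta != 0.0:
                u += ainv[:, i] * delta
                a[i] = new
        if (it + 1) % 100 == 0:
            u = ainv @ a  # refresh accumulated rounding
        # variance components | rest
        qa = float(a @ (ainv @ a))
        s2a = _scaled_inv_chi2(rng, config.df_a + n,
                               (qa + config.df_a * s_a) / (config.df_a + n))
        resid = y - mu - a
        qe = float(resid @ resid)
        s2e = _scaled_inv_chi2(rng, config.df_e + n,
                               (qe + config.df_e * s_e) / (config.df_e + n))
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            keep_a.append(s2a)
            keep_e.append(s2e)
            keep_h.append(s2a / (s2a + s2e))

    return HeritabilityPosterior(sigma2_a=np.array(keep_a),
                                 sigma2_e=np.array(keep_e),
                                 h2=np.array(keep_h))


def summarize_posterior(posterior: HeritabilityPosterior,
                        n_grid: int = 256) -> tuple[dict[str, float], np.ndarray]:
    """Posterior summary plus kernel-density curve points for plotting.

    Returns (summary dict, (n_grid, 2) array of (h2, density)).  Requires at
    least 50 retained samples; a degenerate (constant) posterior yields a
    point-mass spike at the constant.
    """
    h2 = posterior.h2
    if h2.size < 50:
        raise ValueError(f"only {h2.size} retained samples; need at least 50")
    summ = posterior.summary()
    if np.ptp(h2) == 0:
        grid = np.full(n_grid, h2[0])
        dens = np.zeros(n_grid)
        dens[n_grid // 2] = 1.0
    else:
        from scipy.stats import gaussian_kde

        kde = gaussian_kde(h2)
        lo = max(0.0, h2.min() - 3 * h2.std())
        hi = min(1.0, h2.max() + 3 * h2.std())
        grid = np.linspace(lo, hi, n_grid)
        dens = kde(grid)
    return summ, np.column_stack([grid, dens])
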