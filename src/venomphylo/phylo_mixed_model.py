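"""Bayesian phylogenetic ("animal-model") Gaussian mixed models.

The model for a response y (log10 LD50 or log10 venom yield) over repeated
per-species measurements is

    y = X b + Z a + Z s + e
    a ~ N(0, sigma2_a * A),  s ~ N(0, sigma2_s * I),  e ~ N(0, sigma2_e * I)

where A is the phylogenetic correlation matrix (entry i,j = shared
root-to-MRCA path length divided by total tree depth, the Brownian-motion
expectation), the "animal" effect a absorbs variance structured by shared
ancestry, and the species effect s absorbs repeat-measure variance.  All
full conditionals are conjugate (flat improper prior on b, inverse-gamma
priors on each variance component), so the posterior is explored with a
Gibbs sampler; multiple chains with distinct seeded streams support the
Gelman-Rubin convergence diagnostic.  Phylogenetic heritability h2 is the
per-draw share sigma2_a / (sigma2_a + sigma2_s + sigma2_e) (denominator
configurable to animal + residual), interpreted like Pagel's lambda.

Significance of a fixed effect follows the credibility-interval rule: an
effect is significant when its equal-tailed 95% interval excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, qr, solve_triangular

from .data_io import CalibratedPhylogeny
from .errors import (
    DomainError,
    InsufficientDataError,
    RankDeficiencyError,
    TaxonLookupError,
)

# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------


@dataclass
class VariancePrior:
    """Inverse-gamma prior on one variance component.

    The default shape = scale = 0.001 is the conventional weakly
    informative conjugate choice standing in for "flat" variance priors.
    """

    shape: float = 0.001
    scale: float = 0.001

    @classmethod
    def strong(cls, value: float, weight: float = 1e6) -> "VariancePrior":
        """A prior tightly concentrated on a known variance value."""
        return cls(shape=weight, scale=value * (weight - 1.0))


@dataclass
class ChainSettings:
    """MCMC run lengths; defaults follow the published analysis protocol."""

    iterations: int = 2_400_000
    burnin: int = 40_000
    thin: int = 100
    n_chains: int = 3
    seed: int = 0

    def __post_init__(self):
        if not self.burnin < self.iterations:
            raise DomainError("burn-in must be smaller than iterations")
        if self.thin < 1:
            raise DomainError("thinning must be >= 1")
        if self.n_chains < 1:
            raise DomainError("need at least one chain")

    @property
    def n_draws(self) -> int:
        # one draw at burnin, then every `thin` iterations
        return (self.iterations - self.burnin + self.thin - 1) // self.thin


@dataclass
class ModelSpec:
    """Declarative mixed-model definition.

    ``categorical`` maps each factor column to its explicit reference
    level (e.g. route -> "IP", the published baseline); ``interactions``
    are pairs of continuous columns multiplied into a product term.
    """

    response: str
    continuous: list[str] = field(default_factory=list)
    categorical: dict[str, str] = field(default_factory=dict)
    interactions: list[tuple[str, str]] = field(default_factory=list)
    random_terms: tuple[str, ...] = ("animal", "species")
    priors: dict[str, VariancePrior] = field(default_factory=dict)
    chains: ChainSettings = field(default_factory=ChainSettings)

    def __post_init__(self):
        for t in self.random_terms:
            if t not in ("animal", "species"):
                raise DomainError(f"unknown random term {t!r}")
        for key in ("animal", "species", "residual"):
            self.priors.setdefault(key, VariancePrior())

    @classmethod
    def from_dict(cls, cfg: dict) -> "ModelSpec":
        """Build a spec from a parsed YAML mapping."""
        priors = {
            k: VariancePrior(**v) for k, v in cfg.get("priors", {}).items()
        }
        chains = ChainSettings(**cfg.get("chains", {}))
        return cls(
            response=cfg["response"],
            continuous=list(cfg.get("continuous", [])),
            categorical=dict(cfg.get("categorical", {})),
            interactions=[tuple(p) for p in cfg.get("interactions", [])],
            random_terms=tuple(cfg.get("random", ("animal", "species"))),
            priors=priors,
            chains=chains,
        )


# ---------------------------------------------------------------------------
# Phylogenetic correlation matrix
# ---------------------------------------------------------------------------


def phylo_correlation_matrix(
    tree: CalibratedPhylogeny, species_list
) -> np.ndarray:
    """Brownian-motion correlation matrix for a list of tip species.

    Entry (i, j) is the shared root-to-MRCA path length divided by the
    total tree depth; the diagonal is exactly 1.  Symmetric and positive
    semidefinite by construction.
    """
    tree.require_ultrametric()
    nodes = []
    missing = []
    for sp in species_list:
        try:
            node = tree.resolve(sp)
        except TaxonLookupError:
            missing.append(sp)
            continue
        if not node.is_leaf():
            missing.append(sp)
            continue
        nodes.append(node)
    if missing:
        raise TaxonLookupError(missing)

    depth = tree.depth
    q = len(nodes)
    a = np.eye(q)
    for i in range(q):
        for j in range(i + 1, q):
            shared = tree.mrca_depth(nodes[i], nodes[j])
            a[i, j] = a[j, i] = max(shared, 0.0) / depth
    return a


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------


def build_design(data: pd.DataFrame, spec: ModelSpec):
    """Assemble the fixed-effect design matrix and its column names."""
    n = len(data)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    for term in spec.continuous:
        _require_column(data, term)
        cols.append(data[term].to_numpy(dtype=float))
        names.append(term)
    for term, reference in spec.categorical.items():
        _require_column(data, term)
        values = data[term].astype(str)
        levels = sorted(values.unique())
        if reference not in levels:
            raise DomainError(
                f"reference level {reference!r} absent from column {term!r}"
            )
        for level in levels:
            if level == reference:
                continue
            cols.append((values == level).to_numpy(dtype=float))
            names.append(f"{term}[{level}]")
    for left, right in spec.interactions:
        for t in (left, right):
            _require_column(data, t)
        cols.append(
            data[left].to_numpy(dtype=float)
            * data[right].to_numpy(dtype=float)
        )
        names.append(f"{left}:{right}")
    x = np.column_stack(cols)
    if not np.all(np.isfinite(x)):
        raise DomainError("non-finite values in fixed-effect columns")
    _check_rank(x, names)
    return x, names


def _require_column(data: pd.DataFrame, name: str) -> None:
    if name not in data.columns:
        raise DomainError(f"column {name!r} missing from data")


def _check_rank(x: np.ndarray, names) -> None:
    _, r, piv = qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < x.shape[1]:
        bad = [names[piv[k]] for k in range(rank, x.shape[1])]
        raise RankDeficiencyError(bad)


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------


@dataclass
class PosteriorDraws:
    """Thinned post-burn-in draws, one array per parameter.

    ``fixed`` has shape (n_chains, n_draws, p); each variance component is
    (n_chains, n_draws); ``animal``/``species_effect`` are
    (n_chains, n_draws, q) when the corresponding random term is present.
    """

    fixed_names: list[str]
    fixed: np.ndarray
    sigma2: dict[str, np.ndarray]
    animal: np.ndarray | None
    species_effect: np.ndarray | None
    species_order: list[str]
    spec: ModelSpec

    @property
    def n_chains(self) -> int:
        return self.fixed.shape[0]

    @property
    def n_draws(self) -> int:
        return self.fixed.shape[1]

    def parameter(self, name: str) -> np.ndarray:
        """Per-chain draws (n_chains, n_draws) for a named scalar."""
        if name in self.fixed_names:
            return self.fixed[:, :, self.fixed_names.index(name)]
        if name in self.sigma2:
            return self.sigma2[name]
        raise KeyError(name)

    @property
    def scalar_names(self) -> list[str]:
        return list(self.fixed_names) + [
            f"sigma2_{k}" for k in self.sigma2
        ]

    def h2_draws(self, denominator: str = "all") -> np.ndarray:
        """Per-draw phylogenetic heritability (n_chains, n_draws)."""
        if "animal" not in self.sigma2:
            raise DomainError("model has no animal term; h2 undefined")
        sa = self.sigma2["animal"]
        se = self.sigma2["residual"]
        if denominator == "all":
            ss = self.sigma2.get("species", np.zeros_like(sa))
            return sa / (sa + ss + se)
        if denominator == "animal_residual":
            return sa / (sa + se)
        raise ValueError(f"unknown denominator {denominator!r}")


def fit_pmm(
    data: pd.DataFrame,
    spec: ModelSpec,
    tree: CalibratedPhylogeny | None = None,
    species_column: str = "species",
) -> PosteriorDraws:
    """Gibbs-sample the phylogenetic mixed model posterior.

    ``data`` holds one row per measurement with a species column linking
    repeats to random effects; ``tree`` is required whenever the animal
    term is in the model.  Each chain runs on its own deterministically
    seeded stream, so the full draw stream is reproducible bit-for-bit
    from ``spec.chains.seed``.
    """
    _require_column(data, spec.response)
    y = data[spec.response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise DomainError("non-finite response values")
    x, names = build_design(data, spec)
    n, p = x.shape

    use_animal = "animal" in spec.random_terms
    use_species = "species" in spec.random_terms
    if use_animal or use_species:
        _require_column(data, species_column)
        species_order = list(dict.fromkeys(data[species_column]))
        sp_index = {s: i for i, s in enumerate(species_order)}
        idx = data[species_column].map(sp_index).to_numpy(dtype=np.intp)
        q = len(species_order)
        counts = np.bincount(idx, minlength=q).astype(float)
    else:
        species_order, idx, q, counts = [], None, 0, None

    a_inv = None
    if use_animal:
        if tree is None:
            raise DomainError("animal term requires a tree")
        a_mat = phylo_correlation_matrix(tree, species_order)
        a_inv = _spd_inverse(a_mat)

    xtx = x.T @ x
    l_x = cho_factor(xtx, lower=True, check_finite=False)

    ch = spec.chains
    seeds = np.random.SeedSequence(ch.seed).spawn(ch.n_chains)
    n_draws = ch.n_draws
    fixed = np.empty((ch.n_chains, n_draws, p))
    sigma2 = {}
    if use_animal:
        sigma2["animal"] = np.empty((ch.n_chains, n_draws))
    if use_species:
        sigma2["species"] = np.empty((ch.n_chains, n_draws))
    sigma2["residual"] = np.empty((ch.n_chains, n_draws))
    animal = (
        np.empty((ch.n_chains, n_draws, q)) if use_animal else None
    )
    species_effect = (
        np.empty((ch.n_chains, n_draws, q)) if use_species else None
    )

    for c in range(ch.n_chains):
        rng = np.random.default_rng(seeds[c])
        _run_chain(
            c, rng, y, x, l_x, idx, counts, a_inv, use_animal,
            use_species, q, spec, fixed, sigma2, animal, species_effect,
        )

    return PosteriorDraws(
        fixed_names=names,
        fixed=fixed,
        sigma2=sigma2,
        animal=animal,
        species_effect=species_effect,
        species_order=species_order,
        spec=spec,
    )


def _spd_inverse(a: np.ndarray) -> np.ndarray:
    """Inverse of a symmetric PSD matrix, with jitter if near-singular."""
    eye = np.eye(a.shape[0])
    for jitter in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            c = cho_factor(a + jitter * eye, lower=True, check_finite=False)
            return cho_solve(c, eye, check_finite=False)
        except np.linalg.LinAlgError:
            continue
        except Exception:
            continue
    raise DomainError("phylogenetic correlation matrix is not PSD")


def _run_chain(
    c, rng, y, x, l_x, idx, counts, a_inv, use_animal, use_species, q,
    spec, fixed, sigma2, animal_out, species_out,
):
    ch = spec.chains
    n, p = x.shape
    pr_a = spec.priors["animal"]
    pr_s = spec.priors["species"]
    pr_e = spec.priors["residual"]

    # Initial values: OLS for b, residual variance split across components.
    beta = cho_solve(l_x, x.T @ y, check_finite=False)
    resid = y - x @ beta
    s2 = max(float(resid @ resid) / max(n - p, 1), 1e-8)
    sig_a = s2 / 3 if use_animal else 0.0
    sig_s = s2 / 3 if use_species else 0.0
    sig_e = s2 / 3 if (use_animal or use_species) else s2
    a_vec = np.zeros(q) if use_animal else None
    s_vec = np.zeros(q) if use_species else None

    ranef = np.zeros(n)
    keep = 0
    for it in range(ch.iterations):
        # --- fixed effects -------------------------------------------------
        if use_animal or use_species:
            ranef = (a_vec[idx] if use_animal else 0.0) + (
                s_vec[idx] if use_species else 0.0
            )
        beta_hat = cho_solve(l_x, x.T @ (y - ranef), check_finite=False)
        z = rng.standard_normal(p)
        beta = beta_hat + np.sqrt(sig_e) * _chol_upper_solve(l_x, z)
        fit_fixed = x @ beta

        # --- animal effect -------------------------------------------------
        if use_animal:
            r = y - fit_fixed - (s_vec[idx] if use_species else 0.0)
            t = np.bincount(idx, weights=r, minlength=q)
            prec = a_inv * (1.0 / sig_a)
            prec[np.diag_indices_from(prec)] += counts / sig_e
            lp = cholesky(prec, lower=True, check_finite=False)
            mean = _chol_solve_lower(lp, t / sig_e)
            a_vec = mean + _solve_triangular_t(lp, rng.standard_normal(q))
            quad = float(a_vec @ a_inv @ a_vec)
            sig_a = _draw_inv_gamma(
                rng, pr_a.shape + 0.5 * q, pr_a.scale + 0.5 * quad
            )

        # --- species effect ------------------------------------------------
        if use_species:
            r = y - fit_fixed - (a_vec[idx] if use_animal else 0.0)
            t = np.bincount(idx, weights=r, minlength=q)
            d = counts / sig_e + 1.0 / sig_s
            mean = (t / sig_e) / d
            s_vec = mean + rng.standard_normal(q) / np.sqrt(d)
            sig_s = _draw_inv_gamma(
                rng, pr_s.shape + 0.5 * q,
                pr_s.scale + 0.5 * float(s_vec @ s_vec),
            )

        # --- residual variance ---------------------------------------------
        e = y - fit_fixed
        if use_animal:
            e = e - a_vec[idx]
        if use_species:
            e = e - s_vec[idx]
        sig_e = _draw_inv_gamma(
            rng, pr_e.shape + 0.5 * n, pr_e.scale + 0.5 * float(e @ e)
        )

        if it >= ch.burnin and (it - ch.burnin) % ch.thin == 0:
            fixed[c, keep] = beta
            if use_animal:
                sigma2["animal"][c, keep] = sig_a
                animal_out[c, keep] = a_vec
            if use_species:
                sigma2["species"][c, keep] = sig_s
                species_out[c, keep] = s_vec
            sigma2["residual"][c, keep] = sig_e
            keep += 1


def _draw_inv_gamma(rng, shape: float, scale: float) -> float:
    return scale / rng.gamma(shape)


def _chol_upper_solve(l_fac, z):
    """Solve L^T w = z for a cho_factor lower factorization."""
    return solve_triangular(l_fac[0], z, lower=True, trans="T",
                            check_finite=False)


def _chol_solve_lower(lp, b):
    w = solve_triangular(lp, b, lower=True, check_finite=False)
    return solve_triangular(lp, w, lower=True, trans="T",
                            check_finite=False)


def _solve_triangular_t(lp, z):
    return solve_triangular(lp, z, lower=True, trans="T",
                            check_finite=False)


# ---------------------------------------------------------------------------
# Summaries and convergence
# ---------------------------------------------------------------------------


@dataclass
class PosteriorSummary:
    """Fixed-effect estimates, variance components, h2 and diagnostics."""

    fixed_effects: pd.DataFrame
    variance_components: dict[str, float]
    h2_mean: float | None
    h2_lower: float | None
    h2_upper: float | None
    rhat: dict[str, float]
    ess: dict[str, float]

    def significant(self, term: str) -> bool:
        return bool(self.fixed_effects.loc[term, "significant"])


def summarize(
    draws: PosteriorDraws,
    conf: float = 0.95,
    h2_denominator: str = "all",
) -> PosteriorSummary:
    """Posterior means, equal-tailed intervals, CI-rule significance, h2.

    An effect is flagged significant when zero lies outside its
    equal-tailed credibility interval.  R-hat is reported per scalar when
    at least two chains were run; effective sample sizes come from the
    rank-normalized estimator.
    """
    if draws.n_draws < 2:
        raise InsufficientDataError("need at least 2 draws per parameter")
    lo_q, hi_q = (1 - conf) / 2, 1 - (1 - conf) / 2

    rows = []
    for k, name in enumerate(draws.fixed_names):
        flat = draws.fixed[:, :, k].ravel()
        lo, hi = np.quantile(flat, [lo_q, hi_q])
        rows.append({
            "term": name,
            "mean": flat.mean(),
            "lower": lo,
            "upper": hi,
            "significant": not (lo <= 0.0 <= hi),
        })
    fixed_df = pd.DataFrame(rows).set_index("term")

    var_means = {k: float(v.mean()) for k, v in draws.sigma2.items()}

    h2_mean = h2_lo = h2_hi = None
    if "animal" in draws.sigma2:
        h2 = draws.h2_draws(denominator=h2_denominator).ravel()
        h2_mean = float(h2.mean())
        h2_lo, h2_hi = (float(v) for v in np.quantile(h2, [lo_q, hi_q]))

    rhat = {}
    ess = {}
    for name in draws.scalar_names:
        key = name
        chains = (
            draws.parameter(name)
            if name in draws.fixed_names
            else draws.sigma2[name.removeprefix("sigma2_")]
        )
        rhat[key] = (
            gelman_rubin(chains) if draws.n_chains >= 2 else float("nan")
        )
        ess[key] = _effective_sample_size(chains)

    return PosteriorSummary(
        fixed_effects=fixed_df,
        variance_components=var_means,
        h2_mean=h2_mean,
        h2_lower=h2_lo,
        h2_upper=h2_hi,
        rhat=rhat,
        ess=ess,
    )


def _effective_sample_size(chains: np.ndarray) -> float:
    import arviz as az

    with np.errstate(all="ignore"):
        return float(az.ess(np.asarray(chains)))


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor over >= 2 equal-length chains.

    R-hat = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
    variance and B the between-chain variance of means; values near 1
    indicate the chains have mixed.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise DomainError("need >= 2 chains of equal length")
    m, n = arr.shape
    if n < 10:
        raise InsufficientDataError("chains too short for R-hat (need >= 10)")
    w = arr.var(axis=1, ddof=1).mean()
    b = n * arr.mean(axis=1).var(ddof=1)
    if w == 0.0:
        return 1.0 if b == 0.0 else float("inf")
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))
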