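"""Bayesian animal models fitted by Gibbs sampling.

Single-trait model: y = Xb + Za + e with a ~ N(0, A sigma2_a),
e ~ N(0, I sigma2_e); fixed effects are farm, season, sex and month-of-age
class effects.  Two-trait model: the same structure per trait with 2x2
genetic (G0) and residual (R0) covariance matrices, records complete on both
traits.  Fixed effects get flat priors and are sampled unconstrained (all
levels of all factors, no reference level) — only estimable functions and the
variance components are interpreted.  Variance priors are weak scaled inverse
chi-square / inverse-Wishart distributions (df 4) whose scale is set from an
ordinary-least-squares split of the phenotypic variance, recorded in the
chain metadata.

Heritability, genetic/residual/phenotypic correlations are computed per
retained cycle and summarised as posterior means and SDs of those per-sample
values (never ratios of posterior means).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import arviz as az
import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._gibbs import single_trait_kernel, two_trait_kernel
from .pedigree import Pedigree

__all__ = [
    "GibbsConfig",
    "GibbsChains",
    "AnimalModelData",
    "gibbs_single_trait",
    "gibbs_two_trait",
    "summarize_posterior",
]

DEFAULT_FACTORS = ("farm", "season", "sex", "age")

SINGLE_TRAIT_COLUMNS = ("sigma2_a", "sigma2_e", "h2")
TWO_TRAIT_COLUMNS = (
    "g11", "g12", "g22", "r11", "r12", "r22",
    "h2_1", "h2_2", "rg", "re", "rp",
)


class GibbsError(RuntimeError):
    pass


@dataclass
class GibbsConfig:
    """Chain length and prior settings for the Gibbs samplers.

    Defaults are the desk-scale settings (20,000 cycles, 5,000 burn-in,
    thinning 10).  ``prior_df`` applies to both the genetic and residual
    (co)variance priors; prior scales default to an OLS-based split of the
    phenotypic variance with ``init_h2`` assigned to the genetic part.
    """

    n_cycles: int = 20_000
    burn_in: int = 5_000
    thin: int = 10
    prior_df: float = 4.0
    init_h2: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_cycles:
            raise ValueError("burn_in must be smaller than n_cycles")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0.0 < self.init_h2 < 1.0:
            raise ValueError("init_h2 must be in (0, 1)")

    @property
    def n_retained(self) -> int:
        # cycles burn_in+thin, burn_in+2*thin, ..., <= n_cycles (1-based)
        return (self.n_cycles - self.burn_in) // self.thin


@dataclass
class GibbsChains:
    """Retained posterior samples plus metadata.

    ``samples`` has one row per retained cycle; derived quantities
    (heritability, correlations) are per-cycle columns.
    """

    samples: pd.DataFrame
    config: GibbsConfig
    meta: dict = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return len(self.samples)

    def effective_sample_size(self) -> pd.Series:
        return pd.Series(
            {c: float(az.ess(self.samples[c].to_numpy())) for c in self.samples.columns}
        )

    def split_rhat(self) -> pd.Series:
        """Potential scale reduction on the chain split in two halves."""
        half = self.n_retained // 2
        out = {}
        for c in self.samples.columns:
            x = self.samples[c].to_numpy()[: 2 * half].reshape(2, half)
            out[c] = float(az.rhat(x))
        return pd.Series(out)

    def to_csv(self, path) -> None:
        self.samples.to_csv(path, index=False)


@dataclass
class AnimalModelData:
    """Phenotypes with fixed-effect incidence and pedigree links.

    ``y`` is (n,) for one trait or (n, 2) for two; ``fixed_levels`` holds
    0-based level codes, one column per factor; ``animal`` maps each record
    to a pedigree position.
    """

    y: np.ndarray
    fixed_levels: np.ndarray
    factor_names: tuple
    n_levels: tuple
    animal: np.ndarray
    n_pedigree: int

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        n = self.y.shape[0]
        if self.fixed_levels.shape != (n, len(self.factor_names)):
            raise ValueError("fixed_levels shape inconsistent with y / factors")
        if self.animal.shape != (n,):
            raise ValueError("animal index shape inconsistent with y")
        if self.animal.min() < 0 or self.animal.max() >= self.n_pedigree:
            raise ValueError("record maps to an animal outside the pedigree")

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        ped: Pedigree,
        response,
        factors: tuple = DEFAULT_FACTORS,
        animal_col: str = "animal",
    ) -> "AnimalModelData":
        responses = [response] if isinstance(response, str) else list(response)
        y = frame[responses].to_numpy(dtype=float)
        if y.shape[1] == 1:
            y = y[:, 0]
        codes = np.column_stack(
            [pd.Categorical(frame[f]).codes.astype(np.int64) for f in factors]
        )
        n_levels = tuple(int(codes[:, j].max()) + 1 for j in range(codes.shape[1]))
        animal = ped.positions_of(frame[animal_col])
        return cls(y, codes, tuple(factors), n_levels, animal, ped.n_animals)

    @property
    def n_records(self) -> int:
        return self.y.shape[0]

    @property
    def n_traits(self) -> int:
        return 1 if self.y.ndim == 1 else self.y.shape[1]


def _records_by_group(groups: np.ndarray, n_groups: int):
    """CSR-style (indptr, records) listing record indices per group."""
    order = np.argsort(groups, kind="stable")
    counts = np.bincount(groups, minlength=n_groups)
    indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    return indptr, order.astype(np.int64)


def _flatten_fixed(data: AnimalModelData):
    """Concatenate all factors into one level index space."""
    offsets = np.concatenate([[0], np.cumsum(data.n_levels)])[:-1]
    flat = (data.fixed_levels + offsets).ravel(order="F")
    # each record appears once per factor; group by flat level
    rec = np.tile(np.arange(data.n_records, dtype=np.int64), len(data.n_levels))
    total = int(sum(data.n_levels))
    order = np.lexsort((rec, flat))
    counts = np.bincount(flat, minlength=total)
    indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    return indptr, rec[order]


def _design_matrix(data: AnimalModelData) -> np.ndarray:
    total = int(sum(data.n_levels))
    x = np.zeros((data.n_records, total))
    offsets = np.concatenate([[0], np.cumsum(data.n_levels)])[:-1]
    for j in range(len(data.n_levels)):
        x[np.arange(data.n_records), data.fixed_levels[:, j] + offsets[j]] = 1.0
    return x


def _ols_residual_cov(data: AnimalModelData) -> np.ndarray:
    """Residual covariance of the traits after an OLS fixed-effect fit."""
    x = _design_matrix(data)
    y = data.y if data.y.ndim == 2 else data.y[:, None]
    coef, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    dof = max(data.n_records - rank, 1)
    return resid.T @ resid / dof


def _check_inputs(data: AnimalModelData, a_inv: sp.spmatrix, cfg: GibbsConfig):
    if a_inv.shape != (data.n_pedigree, data.n_pedigree):
        raise ValueError("A-inverse not conformable with the pedigree")
    a_csr = sp.csr_matrix(a_inv)
    return a_csr


def gibbs_single_trait(
    data: AnimalModelData, a_inv: sp.spmatrix, cfg: GibbsConfig
) -> GibbsChains:
    """Run the single-trait sampler; deterministic for a fixed config seed."""
    if data.n_traits != 1:
        raise ValueError("data holds two traits; use gibbs_two_trait")
    a_csr = _check_inputs(data, a_inv, cfg)
    vp = float(_ols_residual_cov(data)[0, 0])
    va0 = cfg.init_h2 * vp
    ve0 = (1.0 - cfg.init_h2) * vp
    lev_indptr, lev_records = _flatten_fixed(data)
    an_indptr, an_records = _records_by_group(data.animal, data.n_pedigree)
    out = np.empty((cfg.n_retained, 3))
    status = single_trait_kernel(
        np.ascontiguousarray(data.y, dtype=np.float64),
        lev_indptr,
        lev_records,
        an_indptr,
        an_records,
        a_csr.indptr.astype(np.int64),
        a_csr.indices.astype(np.int64),
        a_csr.data.astype(np.float64),
        cfg.n_cycles,
        cfg.burn_in,
        cfg.thin,
        va0,
        ve0,
        cfg.prior_df,
        cfg.prior_df * va0,
        cfg.prior_df,
        cfg.prior_df * ve0,
        int(cfg.seed) % (2**31),
        out,
    )
    if status != 0:
        raise GibbsError(f"variance draw became non-finite at cycle {status}")
    samples = pd.DataFrame(out, columns=list(SINGLE_TRAIT_COLUMNS))
    meta = {
        "model": "single_trait",
        "prior": {"df": cfg.prior_df, "scale_a": va0, "scale_e": ve0},
        "n_records": data.n_records,
        "n_pedigree": data.n_pedigree,
    }
    return GibbsChains(samples, replace(cfg), meta)


def gibbs_two_trait(
    data: AnimalModelData, a_inv: sp.spmatrix, cfg: GibbsConfig
) -> GibbsChains:
    """Run the two-trait sampler (complete cases on both traits)."""
    if data.n_traits != 2:
        raise ValueError("two-trait sampler needs a (n, 2) response")
    if not np.all(np.isfinite(data.y)):
        raise ValueError("two-trait model requires complete cases on both traits")
    a_csr = _check_inputs(data, a_inv, cfg)
    cov = _ols_residual_cov(data)
    # degenerate trait pairs (e.g., a trait paired with itself) leave the
    # phenotypic covariance singular; jitter the prior scales so the
    # inverse-Wishart conditionals stay proper
    if np.linalg.det(cov) < 1e-8 * float(np.prod(np.diag(cov))):
        ridge = 1e-4 * float(np.mean(np.diag(cov)))
        cov = cov + ridge * np.eye(2)
        warnings.warn(
            "near-singular trait covariance; ridge added to prior scales", stacklevel=2
        )
    g0 = cfg.init_h2 * cov
    r0 = (1.0 - cfg.init_h2) * cov
    lev_indptr, lev_records = _flatten_fixed(data)
    an_indptr, an_records = _records_by_group(data.animal, data.n_pedigree)
    out = np.empty((cfg.n_retained, len(TWO_TRAIT_COLUMNS)))
    status = two_trait_kernel(
        np.ascontiguousarray(data.y, dtype=np.float64),
        lev_indptr,
        lev_records,
        an_indptr,
        an_records,
        a_csr.indptr.astype(np.int64),
        a_csr.indices.astype(np.int64),
        a_csr.data.astype(np.float64),
        cfg.n_cycles,
        cfg.burn_in,
        cfg.thin,
        np.ascontiguousarray(g0),
        np.ascontiguousarray(r0),
        cfg.prior_df,
        np.ascontiguousarray(cfg.prior_df * g0),
        cfg.prior_df,
        np.ascontiguousarray(cfg.prior_df * r0),
        int(cfg.seed) % (2**31),
        out,
    )
    if status != 0:
        raise GibbsError(f"covariance draw became non-finite at cycle {status}")
    samples = pd.DataFrame(out, columns=list(TWO_TRAIT_COLUMNS))
    meta = {
        "model": "two_trait",
        "prior": {"df": cfg.prior_df, "scale_G": g0, "scale_R": r0},
        "n_records": data.n_records,
        "n_pedigree": data.n_pedigree,
    }
    return GibbsChains(samples, replace(cfg), meta)


def summarize_posterior(chains: GibbsChains) -> pd.DataFrame:
    """Posterior mean and SD per parameter over the retained samples.

    Derived quantities (h2, correlations) were computed per cycle before
    retention, so their summaries are means of per-sample values.
    """
    if chains.n_retained < 2:
        raise ValueError("need at least 2 retained samples to summarise")
    return pd.DataFrame(
        {
            "mean": chains.samples.mean(),
            "sd": chains.samples.std(ddof=1),
        }
    )
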