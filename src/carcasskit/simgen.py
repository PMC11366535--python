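"""Synthetic pedigrees and phenotypes for the genetic-parameter stages.

Generates multi-generation random-mating pedigrees and phenotypes that follow
the animal-model structure the estimators assume: additive genetic values
propagated by Mendelian sampling (with parental-inbreeding shrinkage),
categorical fixed effects (farm, season, sex, month of age) whose level
effects are drawn once, and i.i.d. residuals.  True breeding values and true
variance components are carried along so recovery can be tested.

The default scale mirrors the shape of a one-plant, one-year Wagyu study at
roughly one third of its size: ~4,000 pedigree animals in 3 generations,
~1,500 phenotyped, farm collapsed to 40 levels so the fixed-effect design
stays estimable at this n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree, inbreeding_coefficients

__all__ = [
    "GeneticSimConfig",
    "simulate_pedigree",
    "simulate_phenotypes",
    "simulate_price_records",
]

FIXED_FACTORS = ("farm", "season", "sex", "age")


def _chol(m: np.ndarray) -> np.ndarray:
    """Cholesky that tolerates the scalar zero-variance edge case."""
    if m.shape == (1, 1):
        return np.sqrt(m)
    return np.linalg.cholesky(m)


@dataclass
class GeneticSimConfig:
    """True parameters and scale of a genetic simulation.

    Variance components: either scalar ``sigma2_a``/``sigma2_e`` (one trait)
    or 2x2 ``G0``/``R0`` (two traits).  Fixed-effect level counts follow the
    study design (season 4, sex 2, month-of-age 9; farm collapsed to 40).
    """

    n_founders: int = 1000
    generations: int = 3
    matings_per_generation: int = 500
    offspring_per_mating: int = 2
    n_phenotyped: int = 1500
    farm_levels: int = 40
    season_levels: int = 4
    sex_levels: int = 2
    age_levels: int = 9
    effect_sds: dict = field(
        default_factory=lambda: {"farm": 0.5, "season": 0.25, "sex": 0.25, "age": 0.25}
    )
    sigma2_a: float = 0.5
    sigma2_e: float = 0.5
    G0: np.ndarray | None = None
    R0: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_founders <= 0:
            raise ValueError("n_founders must be positive")
        if min(self.matings_per_generation, self.offspring_per_mating) <= 0:
            raise ValueError("mating counts must be positive")
        for m in ("G0", "R0"):
            v = getattr(self, m)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (2, 2) or np.any(np.linalg.eigvalsh(v) <= 0):
                    raise ValueError(f"{m} must be a 2x2 positive definite matrix")
                setattr(self, m, v)
        if (self.G0 is None) != (self.R0 is None):
            raise ValueError("G0 and R0 must be given together")
        if self.G0 is None and (self.sigma2_a < 0 or self.sigma2_e < 0):
            raise ValueError("variance components must be non-negative")

    @property
    def n_traits(self) -> int:
        return 1 if self.G0 is None else 2

    @property
    def n_animals(self) -> int:
        per_gen = self.matings_per_generation * self.offspring_per_mating
        return self.n_founders + self.generations * per_gen

    @classmethod
    def single_trait(cls, h2: float, phenotypic_variance: float = 1.0, **kw):
        """Desk-scale preset with a chosen true heritability."""
        if not 0.0 <= h2 < 1.0:
            raise ValueError("h2 must be in [0, 1)")
        return cls(
            sigma2_a=h2 * phenotypic_variance,
            sigma2_e=(1.0 - h2) * phenotypic_variance,
            **kw,
        )

    @classmethod
    def two_trait(cls, h2_1: float, h2_2: float, rg: float, re: float = 0.0, **kw):
        """Desk-scale preset with chosen heritabilities and correlations.

        Unit phenotypic variance per trait: G0 diag = heritabilities,
        R0 diag = 1 - h2, off-diagonals from rg / re.
        """
        g12 = rg * np.sqrt(h2_1 * h2_2)
        r12 = re * np.sqrt((1 - h2_1) * (1 - h2_2))
        return cls(
            G0=np.array([[h2_1, g12], [g12, h2_2]]),
            R0=np.array([[1 - h2_1, r12], [r12, 1 - h2_2]]),
            **kw,
        )


def simulate_pedigree(cfg: GeneticSimConfig, seed: int) -> Pedigree:
    """Random-mating pedigree: founders plus ``generations`` discrete cohorts.

    Each mating draws two distinct parents from the previous cohort
    (no selfing); every mating produces ``offspring_per_mating`` full sibs.
    """
    rng = np.random.default_rng(seed)
    n = cfg.n_animals
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    cohort = np.arange(cfg.n_founders)
    nxt = cfg.n_founders
    for _ in range(cfg.generations):
        start = nxt
        for _ in range(cfg.matings_per_generation):
            if len(cohort) >= 2:
                s, d = rng.choice(cohort, size=2, replace=False)
            else:
                s, d = cohort[0], -1
            for _ in range(cfg.offspring_per_mating):
                sire[nxt] = s
                dam[nxt] = d
                nxt += 1
        cohort = np.arange(start, nxt)
    inb = inbreeding_coefficients(sire, dam)
    ids = np.arange(1, n + 1, dtype=np.int64)
    return Pedigree(ids, sire, dam, inb, {int(a): i for i, a in enumerate(ids)})


def _breeding_values(ped: Pedigree, g0: np.ndarray, rng) -> np.ndarray:
    """Additive genetic values by gene dropping with Mendelian sampling.

    Founder values ~ N(0, G0); non-founders get the mean of their known
    parents plus a deviation with variance D_i * G0, where D_i comes from the
    same inbreeding recursion as the relationship matrix.
    """
    n = ped.n_animals
    k = g0.shape[0]
    chol = _chol(g0)
    dvals = ped.mendelian_variance_factor
    u = np.zeros((n, k))
    z = rng.standard_normal((n, k))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        pa = np.zeros(k)
        if s >= 0:
            pa += 0.5 * u[s]
        if d >= 0:
            pa += 0.5 * u[d]
        u[i] = pa + np.sqrt(dvals[i]) * (chol @ z[i])
    return u


def simulate_phenotypes(ped: Pedigree, cfg: GeneticSimConfig, seed: int) -> pd.DataFrame:
    """Phenotype table for the last ``n_phenotyped`` animals of the pedigree.

    Columns: animal id, the four fixed-effect levels, trait value(s) and true
    breeding value(s).  The returned frame's ``attrs`` carry the true variance
    components and per-level fixed effects.
    """
    rng = np.random.default_rng(seed)
    k = cfg.n_traits
    g0 = cfg.G0 if k == 2 else np.array([[cfg.sigma2_a]])
    r0 = cfg.R0 if k == 2 else np.array([[cfg.sigma2_e]])
    u = _breeding_values(ped, g0, rng)

    n_ph = min(cfg.n_phenotyped, ped.n_animals)
    rec = np.arange(ped.n_animals - n_ph, ped.n_animals)

    level_counts = {
        "farm": cfg.farm_levels,
        "season": cfg.season_levels,
        "sex": cfg.sex_levels,
        "age": cfg.age_levels,
    }
    out = pd.DataFrame({"animal": np.asarray(ped.ids)[rec]})
    effects = {}
    fixed_part = np.zeros(n_ph)
    for name in FIXED_FACTORS:
        levels = rng.integers(0, level_counts[name], size=n_ph)
        vals = rng.normal(0.0, cfg.effect_sds[name], size=level_counts[name])
        effects[name] = vals
        out[name] = levels
        fixed_part = fixed_part + vals[levels]

    resid = rng.standard_normal((n_ph, k)) @ _chol(r0).T
    y = fixed_part[:, None] + u[rec] + resid
    if k == 1:
        out["y"] = y[:, 0]
        out["tbv"] = u[rec, 0]
    else:
        out["y1"], out["y2"] = y[:, 0], y[:, 1]
        out["tbv1"], out["tbv2"] = u[rec, 0], u[rec, 1]
    out.attrs["true_G0"] = g0
    out.attrs["true_R0"] = r0
    out.attrs["fixed_effects"] = effects
    return out


def simulate_price_records(
    n: int,
    seed: int,
    *,
    iat_name: str = "iat",
    iat_mean: float = 50.0,
    iat_sd: float = 8.0,
    iat_coefficient: float = 10.0,
    n_dates: int = 17,
    n_age: int = 9,
    n_farm: int = 20,
    mq_levels: tuple = (2, 3, 4, 5),
    effect_sds: dict | None = None,
    residual_sd: float = 80.0,
    base_price: float = 2200.0,
) -> pd.DataFrame:
    """Carcass records with unit price generated from a fixed-effects model.

    UP (yen/kg) = base + date + age + sex + farm + MQ effects +
    ``iat_coefficient`` x trait + noise, with each categorical effect drawn
    once per level.  Used to exercise the price ANOVA on data whose
    generating coefficients are known.
    """
    rng = np.random.default_rng(seed)
    sds = {"date": 60.0, "age": 10.0, "sex": 20.0, "farm": 30.0, "MQ": 120.0}
    if effect_sds:
        sds.update(effect_sds)
    df = pd.DataFrame(
        {
            "date": rng.integers(0, n_dates, n),
            "age": rng.integers(0, n_age, n),
            "sex": rng.integers(0, 2, n),
            "farm": rng.integers(0, n_farm, n),
            "MQ": rng.choice(mq_levels, n),
            iat_name: rng.normal(iat_mean, iat_sd, n),
        }
    )
    up = np.full(n, base_price)
    for col, n_lev in (("date", n_dates), ("age", n_age), ("sex", 2), ("farm", n_farm)):
        vals = rng.normal(0.0, sds[col], n_lev)
        up = up + vals[df[col].to_numpy()]
    mq_map = {m: v for m, v in zip(mq_levels, rng.normal(0.0, sds["MQ"], len(mq_levels)))}
    up = up + df["MQ"].map(mq_map).to_numpy()
    up = up + iat_coefficient * (df[iat_name] - iat_mean).to_numpy()
    up = up + rng.normal(0.0, residual_sd, n)
    df["UP"] = up
    df.attrs["iat_coefficient"] = iat_coefficient
    return df
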