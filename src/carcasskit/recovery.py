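"""Parameter-recovery studies: simulate at known truth, re-estimate, compare.

Because real carcass records and pedigrees are private, genetic-parameter
estimates can only be validated by recovery: phenotypes are simulated on a
desk-scale pedigree (~4,000 animals over 3 generations, ~1,500 phenotyped,
farm/season/sex/age fixed effects) with the true heritability or genetic
correlation set to a published estimate, and the Gibbs sampler must find its
way back.  The chain settings here (20,000 cycles, 5,000 burn-in, thinning
10) are a scaled-down version of the production setting of 500,000 cycles
with 100,000 burn-in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .animalmodel import (
    AnimalModelData,
    GibbsConfig,
    gibbs_single_trait,
    gibbs_two_trait,
)
from .pedigree import a_inverse
from .simgen import GeneticSimConfig, simulate_pedigree, simulate_phenotypes

__all__ = ["RecoveryResult", "recover_heritability", "recover_genetic_correlation"]

DESK_GIBBS = dict(n_cycles=20_000, burn_in=5_000, thin=10)


@dataclass
class RecoveryResult:
    """Truth, posterior mean and posterior SD for one recovery run."""

    truth: float
    posterior_mean: float
    posterior_sd: float
    n_records: int
    n_pedigree: int

    @property
    def error(self) -> float:
        return self.posterior_mean - self.truth


def _seeds(seed: int, n: int = 3) -> list[int]:
    return [int(s % 2**31) for s in np.random.SeedSequence(seed).generate_state(n)]


def recover_heritability(
    h2_true: float, seed: int, sim_kw: dict | None = None, gibbs_kw: dict | None = None
) -> RecoveryResult:
    """Single-trait recovery: posterior mean h2 on data simulated at ``h2_true``."""
    s_ped, s_pheno, s_chain = _seeds(seed)
    cfg = GeneticSimConfig.single_trait(h2_true, **(sim_kw or {}))
    ped = simulate_pedigree(cfg, s_ped)
    pheno = simulate_phenotypes(ped, cfg, s_pheno)
    data = AnimalModelData.from_frame(pheno, ped, "y")
    chains = gibbs_single_trait(
        data, a_inverse(ped), GibbsConfig(seed=s_chain, **{**DESK_GIBBS, **(gibbs_kw or {})})
    )
    h2 = chains.samples["h2"]
    return RecoveryResult(h2_true, float(h2.mean()), float(h2.std(ddof=1)),
                          data.n_records, ped.n_animals)


def recover_genetic_correlation(
    h2_1: float,
    h2_2: float,
    rg_true: float,
    seed: int,
    re: float | None = None,
    sim_kw: dict | None = None,
    gibbs_kw: dict | None = None,
) -> RecoveryResult:
    """Two-trait recovery: posterior mean rg on data simulated at ``rg_true``.

    The residual correlation defaults to half the genetic correlation — a
    moderate environmental echo of the genetic relationship.
    """
    s_ped, s_pheno, s_chain = _seeds(seed)
    re = rg_true / 2.0 if re is None else re
    cfg = GeneticSimConfig.two_trait(h2_1, h2_2, rg=rg_true, re=re, **(sim_kw or {}))
    ped = simulate_pedigree(cfg, s_ped)
    pheno = simulate_phenotypes(ped, cfg, s_pheno)
    data = AnimalModelData.from_frame(pheno, ped, ("y1", "y2"))
    chains = gibbs_two_trait(
        data, a_inverse(ped), GibbsConfig(seed=s_chain, **{**DESK_GIBBS, **(gibbs_kw or {})})
    )
    rg = chains.samples["rg"]
    return RecoveryResult(rg_true, float(rg.mean()), float(rg.std(ddof=1)),
                          data.n_records, ped.n_animals)
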