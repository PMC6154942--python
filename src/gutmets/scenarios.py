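"""Named synthetic-study scenarios used by the tests and validation scripts.

Each scenario fixes the cohort size, community size, planted-effect structure
and generator configuration for one question the pipeline answers, and
derives all stage seeds deterministically from a single master seed. Sizes
are chosen so each scenario runs in seconds to a few minutes on one CPU
while leaving the planted structure clearly recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import OtuTable
from .simulate import (
    CohortConfig,
    OtuConfig,
    assign_taxonomy,
    generate_cohort,
    generate_otu_table,
    plant_effects,
)

__all__ = [
    "Scenario",
    "association_scenario",
    "coupling_scenario",
    "grid_scenario",
    "diversity_scenario",
    "saturation_scenario",
]


@dataclass
class Scenario:
    """A generated study: cohort, OTU table, taxonomy and ground truth."""

    cohort: pd.DataFrame
    table: OtuTable
    taxonomy: pd.Series
    effects: list
    cohort_config: CohortConfig
    otu_config: OtuConfig

    @property
    def planted_otus(self) -> set:
        return {e.otu_id for e in self.effects}

    def planted_map(self) -> dict:
        out: dict = {}
        for e in self.effects:
            out.setdefault(e.otu_id, {})[e.factor] = e.effect
        return out


def _seeds(seed: int, k: int) -> list[int]:
    """Derive k independent 31-bit stage seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(k)]


def _build(
    n: int,
    n_otus: int,
    n_signal: int,
    seed: int,
    depth: int = 10000,
    effect_range: tuple = (0.3, 0.6),
    cohort_config: CohortConfig | None = None,
    otu_config: OtuConfig | None = None,
) -> Scenario:
    s_cohort, s_tax, s_eff, s_table = _seeds(seed, 4)
    cc = cohort_config or CohortConfig()
    oc = otu_config or OtuConfig()
    cohort = generate_cohort(n, cc, seed=s_cohort)
    taxonomy = assign_taxonomy(n_otus, seed=s_tax)
    effects = (
        plant_effects(taxonomy, n_signal, effect_range=effect_range, seed=s_eff)
        if n_signal
        else []
    )
    table = generate_otu_table(
        cohort, effects, n_otus=n_otus, depth=depth, seed=s_table,
        config=oc, taxonomy=taxonomy,
    )
    return Scenario(cohort, table, taxonomy, effects, cc, oc)


def association_scenario(
    seed: int, n: int = 3000, n_otus: int = 1000, n_signal: int = 200
) -> Scenario:
    """Planted-recovery scenario for the association engine.

    1000 OTUs, 200 of them carrying effects of magnitude 0.3-0.6 (log
    composition per SD of factor) on MetS and a subset of its diagnostic
    factors; 3000 participants rarefied at depth 10000.
    """
    return _build(n, n_otus, n_signal, seed)


def coupling_scenario(seed: int, n: int = 5000, coupling: float = -0.06) -> Scenario:
    """Index-economics coupling recovery.

    The direct spending-to-risk path is switched off so the only
    index-spending link is the configured leak of spending into the planted
    dysbiosis profile.
    """
    return _build(
        n,
        600,
        120,
        seed,
        cohort_config=CohortConfig(spending_risk_weight=0.0),
        otu_config=OtuConfig(index_spending_coupling=coupling),
    )


def grid_scenario(seed: int, n: int = 4000) -> Scenario:
    """Additive dysbiosis x sedentary risk grid.

    Moderate planted effects (0.15-0.3) plus a phenotype-independent
    dysbiosis latent (profile noise SD 3) keep the index an informative but
    imperfect marker, and a sedentary-to-risk weight of 0.35 provides the
    independent lifestyle effect, so the 16-cell grid shows the graded
    additive pattern rather than a saturated classifier.
    """
    return _build(
        n,
        300,
        60,
        seed,
        effect_range=(0.15, 0.3),
        cohort_config=CohortConfig(sedentary_risk_weight=0.35),
        otu_config=OtuConfig(profile_noise_sd=3.0),
    )


def diversity_scenario(seed: int, n: int = 1000) -> Scenario:
    """Alpha-diversity contrast: dysbiosis concentrates abundance into the
    (already abundant) disorder-positive taxa, lowering Shannon and PD in
    MetS-positive samples. The baseline boost of disorder-positive OTUs is
    raised to 1.5 log units so the concentration mechanism dominates the
    richness signal at this cohort size."""
    return _build(n, 300, 60, seed, otu_config=OtuConfig(positive_extra_boost=1.5))


def saturation_scenario(seed: int, n: int = 600) -> Scenario:
    """Sample-size saturation: weak community-wide effects (0.12-0.22 on 30
    OTUs) so PERMANOVA power climbs visibly over subsample sizes of tens to
    hundreds instead of saturating immediately."""
    return _build(n, 300, 30, seed, effect_range=(0.12, 0.22))
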