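"""Study-shaped experiment harness on synthetic data.

Builds the population structure the evaluation experiments assume: one
breeding program of ~500 lines partitioned into three disjoint
subpopulations -- a field-scored winter-hardiness training pool, a
growth-chamber frost-tolerance training pool, and an independently
field-scored validation pool -- together with the processed genotype panel,
kinship matrix and per-trait BLUEs.  Both the acceptance checks and the
worked examples run through this harness so that every reported number is
recomputed from a fresh simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geno as gmod
from . import pheno as pmod
from .evaluate import Dataset
from .simulate import SimConfig, simulate_field_trial, simulate_frost_experiment, simulate_population

__all__ = ["StudyData", "build_study", "prepare_dataset"]


@dataclass
class StudyData:
    dataset: Dataset
    pop: object
    winter_pool: list
    frost_pool: list
    valid_pool: list
    valid_blues: pd.DataFrame
    h2_valid: float


def prepare_dataset(pop, pheno_by_trait: dict[str, pd.DataFrame], seed: int = 0) -> Dataset:
    """Run the genotype pipeline and phenotypic analysis for one population.

    ``pheno_by_trait`` maps 'winter' to a list of field-trial tables (stage 1
    + stage 2) and 'frost' to one complete-block table.
    """
    filtered, _ = gmod.qc_filter(pop.genotypes)
    imputed = gmod.impute(filtered)
    tag_a, tag_b = pop.truth.tag_markers
    haploblocks = {}
    if tag_a in imputed.markers and tag_b in imputed.markers:
        haploblocks["CNV_FrA2"] = gmod.build_haploblock(
            imputed, tag_a, tag_b, pop.truth.haploblock_favorable, name="CNV_FrA2"
        )
    deduped, _ = gmod.dedup_perfect_ld(imputed, seed=seed)
    K = gmod.compute_grm(deduped)

    blues, h2 = {}, {}
    if "frost" in pheno_by_trait:
        b, h = pmod.fit_frost_model(pheno_by_trait["frost"])
        blues["frost"], h2["frost"] = b, h.h2
    if "winter" in pheno_by_trait:
        tables = pheno_by_trait["winter"]
        per_trial = [pmod.fit_trial_model(t, [("block",), ("block", "row", "column")])[0] for t in tables]
        if len(per_trial) > 1:
            b, h = pmod.across_trial_model(per_trial)
        else:
            b, h, _ = pmod.fit_trial_model(tables[0], [("block",), ("block", "row", "column")])
        blues["winter"], h2["winter"] = b, h.h2
    return Dataset(blues=blues, geno=deduped, K=K, h2=h2, haploblocks=haploblocks)


def build_study(
    seed: int,
    n_lines: int = 504,
    n_families: int = 311,
    markers_per_chromosome: int = 20,
    n_winter: int = 181,
    n_frost: int = 213,
    n_valid: int = 110,
) -> StudyData:
    """Simulate the three-subpopulation structure used for independent validation.

    Defaults follow the evaluated breeding program: 504 lines from 311
    crosses split into disjoint subpopulations of 181 (winter hardiness,
    two field trials), 213 (frost chamber test) and 110 (validation field
    trial) lines.  The marker panel is thinned to 20 per chromosome to keep
    the replicated experiments fast; the genetic architecture is unchanged.
    """
    if n_winter + n_frost + n_valid > n_lines:
        raise ValueError("subpopulation sizes exceed the program size")
    cfg = SimConfig(
        n_lines=n_lines,
        n_families=n_families,
        markers_per_chromosome=markers_per_chromosome,
        seed=seed,
    )
    pop = simulate_population(cfg, with_phenotypes=False)
    ss = np.random.SeedSequence([seed, 20180417])
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)]
    rng = np.random.default_rng(sub[0])
    perm = rng.permutation(cfg.n_lines)
    lines = np.array(pop.lines)
    winter_pool = list(lines[perm[:n_winter]])
    frost_pool = list(lines[perm[n_winter : n_winter + n_frost]])
    valid_pool = list(lines[perm[n_winter + n_frost : n_winter + n_frost + n_valid]])

    def field(pool, s, name):
        n_rep = max(1, int(round(0.3 * len(pool))))
        return simulate_field_trial(
            pop, "winter", n_rep, len(pool) - n_rep, seed=s, trial_name=name, lines=pool
        )

    winter_trials = [field(winter_pool, sub[1], "winter_2012a"), field(winter_pool, sub[2], "winter_2012b")]
    frost_tab = simulate_frost_experiment(pop, 4, seed=sub[3], lines=frost_pool)
    valid_trial = field(valid_pool, sub[4], "winter_2018")

    dataset = prepare_dataset(
        pop, {"winter": winter_trials, "frost": frost_tab}, seed=seed
    )
    vb, vh, _ = pmod.fit_trial_model(valid_trial, [("block",), ("block", "row", "column")])
    return StudyData(
        dataset=dataset,
        pop=pop,
        winter_pool=winter_pool,
        frost_pool=frost_pool,
        valid_pool=valid_pool,
        valid_blues=vb,
        h2_valid=vh.h2,
    )
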