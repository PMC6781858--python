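"""Synthetic winter-wheat breeding populations for the prediction pipeline.

The generator emulates the data structure of a commercial winter wheat
breeding program phenotyped for two cold-stress traits:

* lines come from bi-parental crosses (families), are largely homozygous
  (F4:6/F5:7 or doubled-haploid material) and genotyped with a genome-wide
  biallelic SNP panel on 21 chromosomes;
* one major frost-tolerance locus -- a CBF copy-number variant of the Fr-A2
  type on chromosome 5A -- carries a configurable share of the genetic
  variance and is tagged by two flanking SNPs that match the causal state
  imperfectly (default concordance 0.95 per haplotype);
* a polygenic background of many small-effect QTL produces two genetically
  correlated traits: a 1-9 field winter-hardiness score and a 0-100% chamber
  frost-damage percentage, both lower-is-better;
* field trials use partially replicated row-column layouts, the frost test a
  complete-block design with four replicates.

True breeding values, QTL effects and noise variances are recorded so that
every downstream estimator can be checked for parameter recovery.  The same
seed reproduces the population bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geno import GenotypeMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimulatedPopulation",
    "simulate_population",
    "simulate_field_trial",
    "simulate_frost_experiment",
    "write_phenotypes",
]

TRAITS = ("winter", "frost")


@dataclass
class SimConfig:
    """Parameters of one simulated breeding population.

    Defaults mirror the frost-tolerance subpopulation of a mid-size European
    winter wheat program: 213 lines from 131 crosses, ~1,400 post-QC SNPs on
    21 chromosomes, a major CNV locus worth 20% of the genetic variance,
    heritabilities 0.71 (field winter hardiness) and 0.98 (chamber frost
    test), and a genetic correlation of 0.6 between the two traits.
    """

    n_lines: int = 213
    n_families: int = 131
    n_chromosomes: int = 21
    markers_per_chromosome: int = 67
    major_qtl_rho: float = 0.20
    h2_winter: float = 0.71
    h2_frost: float = 0.98
    genetic_correlation: float = 0.6
    maf_range: tuple[float, float] = (0.10, 0.5)
    missing_rate: float = 0.03
    seed: int = 0
    # architecture knobs beyond the headline parameters
    sigma2_g: float = 1.0
    n_background_qtl: int = 40
    n_founders: int = 16
    tag_concordance: float = 0.95
    cnv_allele_freq: float = 0.45
    residual_het: float = 0.02

    def __post_init__(self) -> None:
        for name in ("major_qtl_rho", "h2_winter", "h2_frost", "missing_rate",
                     "tag_concordance", "cnv_allele_freq", "residual_het"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not -1.0 <= self.genetic_correlation <= 1.0:
            raise ValueError("genetic_correlation outside [-1, 1]")
        if self.n_lines < 2:
            raise ValueError("n_lines must be at least 2")
        if self.n_lines < self.n_families:
            raise ValueError("n_lines must be >= n_families")
        if self.markers_per_chromosome < 1 or self.n_chromosomes < 1:
            raise ValueError("need at least one marker and one chromosome")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be ordered and within (0, 0.5]")
        if self.sigma2_g < 0:
            raise ValueError("sigma2_g must be nonnegative")
        if self.n_founders < 2:
            raise ValueError("need at least 2 founder haplotypes")


@dataclass
class SimTruth:
    """Ground truth retained for parameter-recovery tests."""

    complete_codes: pd.DataFrame
    copy_number: pd.Series
    family: pd.Series
    tag_markers: tuple[str, str]
    haploblock_favorable: dict
    genetic_correlation_realized: float


@dataclass
class SimulatedPopulation:
    genotypes: GenotypeMatrix
    qtl_effects: pd.DataFrame
    true_breeding_values: pd.DataFrame
    variance_components_truth: dict
    phenotypes: dict
    truth: SimTruth
    config: SimConfig

    @property
    def marker_map(self) -> pd.DataFrame:
        return self.genotypes.marker_map

    @property
    def lines(self) -> pd.Index:
        return self.genotypes.lines


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ZeroDivisionError
    return (v - v.mean()) / sd


def _orthogonalize(v: np.ndarray, *others: np.ndarray) -> np.ndarray:
    for o in others:
        denom = float(o @ o)
        if denom > 0:
            v = v - (float(v @ o) / denom) * o
    return v


def _recombine(rng, hap_a: np.ndarray, hap_b: np.ndarray) -> np.ndarray:
    """One mosaic gamete from two haplotypes: segment-wise inheritance."""
    m = hap_a.shape[0]
    n_cross = rng.poisson(1.0)
    cuts = np.sort(rng.integers(1, m, size=n_cross)) if (n_cross and m > 1) else np.array([], int)
    out = np.empty(m, dtype=hap_a.dtype)
    src = int(rng.integers(2))
    start = 0
    for cut in list(cuts) + [m]:
        out[start:cut] = (hap_a if src == 0 else hap_b)[start:cut]
        src = 1 - src
        start = cut
    return out


def _founder_mosaic(rng, founders: np.ndarray, mean_cross: float = 1.0) -> np.ndarray:
    """One base-population haplotype as a segment mosaic of founder haplotypes.

    The shared founder segments are what give the marker panel its linkage
    disequilibrium, without which neither imputation nor marker tagging would
    have anything to work with.
    """
    n_f, m = founders.shape
    n_cross = rng.poisson(mean_cross)
    cuts = np.sort(rng.integers(1, m, size=n_cross)) if (n_cross and m > 1) else np.array([], int)
    out = np.empty(m, dtype=founders.dtype)
    start = 0
    for cut in list(cuts) + [m]:
        out[start:cut] = founders[int(rng.integers(n_f)), start:cut]
        start = cut
    return out


def simulate_population(config: SimConfig, with_phenotypes: bool = True) -> SimulatedPopulation:
    """Draw one breeding population: pedigree, genotypes, QTL, TBVs, trials.

    Lines are recombinant inbreds: per chromosome, each parent contributes a
    mosaic gamete of its two haplotypes, the two gametes recombine once more
    and the result is doubled, leaving only a small residual heterozygosity.
    The CNV causal state and its two tag SNPs travel on the same haplotypes,
    so their linkage survives inheritance exactly.  True breeding values are
    built from a standardized copy-number score (share ``major_qtl_rho``) and
    an orthogonalized polygenic background, scaled to variance ``sigma2_g``
    and to the configured genetic correlation between the two traits --
    empirically exact, so variance-recovery checks are limited only by the
    downstream estimators.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(6)]
    r_map, r_base, r_inherit, r_effects, r_missing, r_pheno = rngs

    n_chrom, m_per = cfg.n_chromosomes, cfg.markers_per_chromosome
    n_markers = n_chrom * m_per
    chroms = np.repeat(np.arange(1, n_chrom + 1), m_per)
    pos = np.concatenate(
        [np.cumsum(r_map.integers(5_000, 2_000_000, size=m_per)) for _ in range(n_chrom)]
    )
    marker_names = [f"M{c}_{i + 1:03d}" for c, i in zip(chroms, np.tile(np.arange(m_per), n_chrom))]

    # major locus: chromosome "5A" analogue, tags flank an unobserved CNV
    cnv_chrom = min(5, n_chrom)
    chrom_idx = {c: np.where(chroms == c)[0] for c in range(1, n_chrom + 1)}
    cnv_slot = chrom_idx[cnv_chrom][len(chrom_idx[cnv_chrom]) // 2]
    if m_per >= 2:
        tag_idx = (cnv_slot - 1 if cnv_slot > chrom_idx[cnv_chrom][0] else cnv_slot, None)
        tag_a = int(tag_idx[0])
        tag_b = int(tag_a + 1)
    else:
        tag_a = tag_b = int(cnv_slot)
    tag_markers = (marker_names[tag_a], marker_names[tag_b])

    # base-population allele frequencies of the +1 allele, MAF within bounds
    maf = r_base.uniform(cfg.maf_range[0], cfg.maf_range[1], size=n_markers)
    flip = r_base.random(n_markers) < 0.5
    p_base = np.where(flip, maf, 1.0 - maf)

    # founder haplotypes of the base population; the CNV causal allele and its
    # two tag SNPs are coupled at the founder level (imperfect concordance)
    cnv_idx = chrom_idx[cnv_chrom]
    insert_at = int(np.searchsorted(cnv_idx, cnv_slot, side="right"))
    # exact-count founder draws keep the pool frequency at the target p_k,
    # so realized line frequencies stay near the configured MAF bounds
    n_f = cfg.n_founders
    lo_count = int(np.ceil(cfg.maf_range[0] * n_f - 1e-9))
    counts = np.clip(np.round(p_base * n_f).astype(int), lo_count, n_f - lo_count)
    founders = np.zeros((n_f, n_markers), dtype=np.int8)
    for j in range(n_markers):
        founders[r_base.permutation(n_f)[: counts[j]], j] = 1
    f_cnv = (r_base.random(cfg.n_founders) < cfg.cnv_allele_freq).astype(np.int8)
    ext_founders = np.insert(founders[:, cnv_idx], insert_at, f_cnv, axis=1)

    # parents are mosaics of founder segments: shared segments create LD and
    # heterogeneous kinship across the crossing program
    n_par = cfg.n_families * 2
    par_hap = np.empty((n_par, 2, n_markers), dtype=np.int8)
    cnv_allele = np.empty((n_par, 2), dtype=np.int8)
    for par in range(n_par):
        for h in (0, 1):
            for c in range(1, n_chrom + 1):
                idx = chrom_idx[c]
                if c == cnv_chrom:
                    mosaic = _founder_mosaic(r_base, ext_founders)
                    cnv_allele[par, h] = mosaic[insert_at]
                    par_hap[par, h, idx] = np.delete(mosaic, insert_at)
                else:
                    par_hap[par, h, idx] = _founder_mosaic(r_base, founders[:, idx])

    # assign lines to families roughly evenly
    fam_of_line = np.sort(np.resize(np.arange(cfg.n_families), cfg.n_lines))
    line_names = [f"L{i + 1:04d}" for i in range(cfg.n_lines)]

    hap_final = np.empty((cfg.n_lines, n_markers), dtype=np.int8)
    cnv_final = np.empty(cfg.n_lines, dtype=np.int8)
    cnv_col = np.empty((n_par, 2, 1), dtype=np.int8)
    cnv_col[:, :, 0] = cnv_allele
    # carry the CNV with its chromosome by appending it to that chromosome's
    # marker vector at the tag position
    for i in range(cfg.n_lines):
        f = fam_of_line[i]
        pa, pb = 2 * f, 2 * f + 1
        line_hap = np.empty(n_markers, dtype=np.int8)
        for c in range(1, n_chrom + 1):
            idx = chrom_idx[c]
            if c == cnv_chrom:
                insert_at = int(np.searchsorted(idx, cnv_slot, side="right"))
                ext_a1 = np.insert(par_hap[pa, 0, idx], insert_at, cnv_allele[pa, 0])
                ext_a2 = np.insert(par_hap[pa, 1, idx], insert_at, cnv_allele[pa, 1])
                ext_b1 = np.insert(par_hap[pb, 0, idx], insert_at, cnv_allele[pb, 0])
                ext_b2 = np.insert(par_hap[pb, 1, idx], insert_at, cnv_allele[pb, 1])
                g1 = _recombine(r_inherit, ext_a1, ext_a2)
                g2 = _recombine(r_inherit, ext_b1, ext_b2)
                final = _recombine(r_inherit, g1, g2)
                cnv_final[i] = final[insert_at]
                line_hap[idx] = np.delete(final, insert_at)
            else:
                g1 = _recombine(r_inherit, par_hap[pa, 0, idx], par_hap[pa, 1, idx])
                g2 = _recombine(r_inherit, par_hap[pb, 0, idx], par_hap[pb, 1, idx])
                line_hap[idx] = _recombine(r_inherit, g1, g2)
        hap_final[i] = line_hap

    codes = (2 * hap_final - 1).astype(float)  # doubled haplotype: homozygous
    het = r_inherit.random(codes.shape) < cfg.residual_het
    codes[het] = 0.0
    copy_number = pd.Series(1 + 2 * cnv_final.astype(int), index=line_names, name="copy_number")
    # residual heterozygosity at the CNV: a 2-copy intermediate class
    cnv_het = r_inherit.random(cfg.n_lines) < cfg.residual_het
    copy_number[cnv_het] = 2
    # tag SNP assays read the causal CNV state with imperfect per-haplotype
    # concordance; they overwrite the placeholder marker columns so their
    # linkage to the CNV does not erode through the simulated meioses
    cnv_hap = np.column_stack([cnv_final, cnv_final]).astype(np.int8)
    cnv_hap[cnv_het, 1] = 1 - cnv_hap[cnv_het, 1]
    for t in (tag_a, tag_b):
        flips = r_inherit.random((cfg.n_lines, 2)) >= cfg.tag_concordance
        tag_hap = np.where(flips, 1 - cnv_hap, cnv_hap)
        codes[:, t] = tag_hap.sum(axis=1) - 1.0

    # --- true breeding values ------------------------------------------------
    rho = cfg.major_qtl_rho
    sigma_g = np.sqrt(cfg.sigma2_g)
    cn = copy_number.to_numpy(dtype=float)
    try:
        S = _standardize(cn)
    except ZeroDivisionError:
        if rho > 0:
            warnings.warn("CNV locus monomorphic in this draw; major-QTL share set to 0")
        rho, S = 0.0, np.zeros(cfg.n_lines)
    # high copy number -> better cold acclimation -> lower damage/score
    S_eff = -S

    qtl_pool = [j for j in range(n_markers) if j not in (tag_a, tag_b)]
    n_qtl = min(cfg.n_background_qtl, len(qtl_pool))
    qtl_idx = np.sort(r_effects.choice(qtl_pool, size=n_qtl, replace=False))
    W = codes - codes.mean(axis=0)
    # exchangeable minor loci: equal magnitude, random sign, so no single
    # background QTL rivals the planted major locus
    beta1 = r_effects.choice([-1.0, 1.0], size=n_qtl)
    beta_q = r_effects.choice([-1.0, 1.0], size=n_qtl)
    raw1 = W[:, qtl_idx] @ beta1
    P1 = _standardize(_orthogonalize(raw1 - raw1.mean(), S_eff))
    rawq = W[:, qtl_idx] @ beta_q
    Q = _standardize(_orthogonalize(rawq - rawq.mean(), S_eff, P1))
    if rho >= 1.0 - 1e-12:
        r_p = 0.0
    else:
        r_p = (cfg.genetic_correlation - rho) / (1.0 - rho)
    if not -1.0 <= r_p <= 1.0:
        warnings.warn(
            f"requested genetic correlation {cfg.genetic_correlation} not reachable "
            f"with major_qtl_rho={rho}; clamping"
        )
        r_p = float(np.clip(r_p, -1.0, 1.0))
    P2 = r_p * P1 + np.sqrt(max(0.0, 1.0 - r_p**2)) * Q

    tbv = {}
    for trait, P in zip(TRAITS, (P1, P2)):
        tbv[trait] = sigma_g * (np.sqrt(rho) * S_eff + np.sqrt(1.0 - rho) * P)
    tbv_df = pd.DataFrame(tbv, index=line_names)
    realized_corr = float(np.corrcoef(tbv_df["winter"], tbv_df["frost"])[0, 1]) if cfg.n_lines > 2 and tbv_df.std().min() > 0 else np.nan

    # bookkeeping of effect sizes: polygenic betas scaled to the share they
    # carry; tag markers annotated with the major-locus regression effect
    eff = pd.DataFrame(0.0, index=marker_names, columns=[f"effect_{t}" for t in TRAITS])
    beta2 = r_p * beta1 + np.sqrt(max(0.0, 1.0 - r_p**2)) * beta_q
    for trait, (raw, beta) in zip(TRAITS, ((raw1, beta1), (rawq, beta2))):
        if raw.std() > 0:
            scale = sigma_g * np.sqrt(1.0 - rho) / raw.std()
            eff.loc[np.array(marker_names)[qtl_idx], f"effect_{trait}"] = beta * scale
    for t in (tag_a, tag_b):
        tc = codes[:, t]
        if tc.std() > 0:
            b = float(np.cov(sigma_g * np.sqrt(rho) * S_eff, tc)[0, 1] / tc.var())
            eff.loc[marker_names[t], [f"effect_{tr}" for tr in TRAITS]] = b / 2.0
    eff["is_major_tag"] = [m in tag_markers for m in marker_names]

    # observed genotypes: inject MCAR missingness after the TBVs are fixed
    observed = codes.copy()
    mask = r_missing.random(observed.shape) < cfg.missing_rate
    observed[mask] = np.nan

    marker_map = pd.DataFrame({"chrom": chroms, "pos": pos}, index=marker_names)
    geno = GenotypeMatrix(pd.DataFrame(observed, index=line_names, columns=marker_names), marker_map)

    truth = SimTruth(
        complete_codes=pd.DataFrame(codes, index=line_names, columns=marker_names),
        copy_number=copy_number,
        family=pd.Series(fam_of_line, index=line_names, name="family"),
        tag_markers=tag_markers,
        haploblock_favorable={tag_markers[0]: 1.0, tag_markers[1]: 1.0},
        genetic_correlation_realized=realized_corr,
    )
    vc_truth = {
        t: {"sigma2_g": cfg.sigma2_g, "h2": getattr(cfg, f"h2_{t}")} for t in TRAITS
    }
    vc_truth["genetic_covariance"] = cfg.sigma2_g * cfg.genetic_correlation

    pop = SimulatedPopulation(
        genotypes=geno,
        qtl_effects=eff,
        true_breeding_values=tbv_df,
        variance_components_truth=vc_truth,
        phenotypes={},
        truth=truth,
        config=cfg,
    )
    if with_phenotypes:
        sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
        n_rep = max(1, int(round(0.3 * cfg.n_lines)))
        n_unrep = cfg.n_lines - n_rep
        pop.phenotypes["winter_a"] = simulate_field_trial(
            pop, "winter", n_rep, n_unrep, seed=sub[0], trial_name="winter_a"
        )
        pop.phenotypes["winter_b"] = simulate_field_trial(
            pop, "winter", n_rep, n_unrep, seed=sub[1], trial_name="winter_b"
        )
        pop.phenotypes["frost_chamber"] = simulate_frost_experiment(pop, 4, seed=sub[2])
    return pop


def _h2_to_resid(sigma2_g: float, h2: float, reps: float) -> float:
    """Residual variance making the entry-mean heritability come out at h2."""
    if h2 >= 1.0:
        return 0.0
    return reps * sigma2_g * (1.0 - h2) / h2


def simulate_field_trial(
    pop: SimulatedPopulation,
    trait: str,
    n_replicated: int,
    n_unreplicated: int,
    seed: int = 0,
    trial_name: str | None = None,
    block_sd: float = 0.25,
    row_sd: float = 0.10,
    col_sd: float = 0.10,
    h2: float | None = None,
    discretize: bool | None = None,
    lines: list | None = None,
) -> pd.DataFrame:
    """One partially replicated row-column field trial.

    ``n_replicated`` lines appear once in each of two blocks, the remaining
    ``n_unreplicated`` once in a random block; plots are arranged on a
    per-block row-column grid.  ``lines`` restricts the trial to a
    subpopulation (a breeding program rarely phenotypes every line in every
    experiment); by default all simulated lines are candidates.  The residual variance is solved from the
    configured entry-mean heritability under the realized replication.  The
    winter-hardiness score is discretized to the 1-9 scale (1 = dense stand,
    9 = complete winter kill) unless ``discretize`` overrides that.
    """
    if trait not in TRAITS:
        raise KeyError(f"unknown trait {trait!r}; expected one of {TRAITS}")
    cfg = pop.config
    candidates = np.array(pop.lines if lines is None else list(lines))
    n_lines = len(candidates)
    if n_replicated + n_unreplicated > n_lines:
        raise ValueError("n_replicated + n_unreplicated exceeds the number of lines")
    rng = np.random.default_rng(seed)
    if h2 is None:
        h2 = getattr(cfg, f"h2_{trait}")
    if discretize is None:
        discretize = trait == "winter"
    trial_name = trial_name or f"{trait}_trial"

    chosen = rng.permutation(n_lines)[: n_replicated + n_unreplicated]
    rep_lines = candidates[chosen[:n_replicated]]
    unrep_lines = candidates[chosen[n_replicated : n_replicated + n_unreplicated]]

    n_plots = 2 * n_replicated + n_unreplicated
    reps_eff = n_plots / max(1, n_replicated + n_unreplicated)
    sigma2_r = _h2_to_resid(cfg.sigma2_g, h2, reps_eff) if h2 > 0 else cfg.sigma2_g

    tbv = pop.true_breeding_values[trait]
    entries = []
    for b in (1, 2):
        entries.extend((ln, b) for ln in rep_lines)
    assign = rng.integers(1, 3, size=len(unrep_lines))
    entries.extend((ln, int(bb)) for ln, bb in zip(unrep_lines, assign))

    block_eff = {b: rng.normal(0.0, block_sd) for b in (1, 2)}
    rows_of, cols_of = {}, {}
    table = []
    for b in (1, 2):
        plots = [e for e in entries if e[1] == b]
        order = rng.permutation(len(plots))
        ncol = max(1, int(np.ceil(np.sqrt(len(plots)))))
        row_eff = {}
        col_eff = {}
        for slot, k in enumerate(order):
            ln, _ = plots[k]
            r_i, c_i = divmod(slot, ncol)
            rlab, clab = f"b{b}r{r_i + 1}", f"b{b}c{c_i + 1}"
            if rlab not in row_eff:
                row_eff[rlab] = rng.normal(0.0, row_sd)
            if clab not in col_eff:
                col_eff[clab] = rng.normal(0.0, col_sd)
            value = (
                (tbv[ln] if h2 > 0 else 0.0)
                + block_eff[b]
                + row_eff[rlab]
                + col_eff[clab]
                + (rng.normal(0.0, np.sqrt(sigma2_r)) if sigma2_r > 0 else 0.0)
            )
            table.append(
                {
                    "line": ln,
                    "trial": trial_name,
                    "block": f"b{b}",
                    "row": rlab,
                    "column": clab,
                    "trait": trait,
                    "value": value,
                }
            )
    out = pd.DataFrame(table)
    if discretize:
        sd = np.sqrt(cfg.sigma2_g + sigma2_r) if (cfg.sigma2_g + sigma2_r) > 0 else 1.0
        out["value"] = np.clip(np.round(5.0 + 1.5 * out["value"] / sd), 1, 9)
    return out


def simulate_frost_experiment(
    pop: SimulatedPopulation,
    n_blocks: int = 4,
    seed: int = 0,
    block_sd: float = 0.15,
    h2: float | None = None,
    trial_name: str = "frost_chamber",
    lines: list | None = None,
) -> pd.DataFrame:
    """Randomized complete-block growth-chamber frost test.

    Every line appears in every block; the response is percent frost damage
    after regrowth, an affine map of the liability truncated to [0, 100].
    Residual noise is calibrated so the entry-mean heritability matches the
    configured ``h2_frost`` (default) under ``n_blocks`` replicates.
    """
    if n_blocks < 2:
        raise ValueError("a complete-block frost test needs at least 2 blocks")
    cfg = pop.config
    rng = np.random.default_rng(seed)
    if h2 is None:
        h2 = cfg.h2_frost
    sigma2_r = _h2_to_resid(cfg.sigma2_g, h2, n_blocks) if h2 > 0 else cfg.sigma2_g
    candidates = list(pop.lines if lines is None else lines)
    tbv = pop.true_breeding_values.loc[candidates, "frost"]
    rows = []
    for b in range(1, n_blocks + 1):
        be = rng.normal(0.0, block_sd) if block_sd > 0 else 0.0
        noise = rng.normal(0.0, np.sqrt(sigma2_r), size=len(candidates)) if sigma2_r > 0 else np.zeros(len(candidates))
        liab = (tbv.to_numpy() if h2 > 0 else 0.0) + be + noise
        pct = np.clip(50.0 + 16.0 * liab, 0.0, 100.0)
        for ln, v in zip(candidates, pct):
            rows.append(
                {
                    "line": ln,
                    "trial": trial_name,
                    "block": f"b{b}",
                    "row": np.nan,
                    "column": np.nan,
                    "trait": "frost",
                    "value": v,
                }
            )
    return pd.DataFrame(rows)


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    """Tidy CSV: line, trial, block, row, column, trait, value."""
    pheno.to_csv(path, index=False)
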