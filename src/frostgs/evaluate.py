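"""Cross-validation, independent validation and pipeline orchestration.

Prediction accuracy follows the plant-breeding convention: the Pearson
correlation between predicted and observed line values divided by the square
root of the heritability of the validation experiment, so that accuracies
estimate the correlation with true breeding values rather than with noisy
phenotypes.  Within-population merit is assessed by a replicated random
train/validation resampling scheme (default 130/30 lines, 100 replicates);
independent validation trains on one dataset and predicts a disjoint pool
phenotyped elsewhere.  Marker selection and association scans are re-run
inside every training split -- never on the full data -- so reported
accuracies are free of selection leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geno import GenotypeMatrix, Haploblock
from .index import compute_index_values, compute_index_weights
from .markersel import sample_random_markers, select_chromosome_wise, select_genome_wide
from .predict import gblup_predict, gwas_scan, rrblup_predict, wblup_predict

__all__ = [
    "CVScheme",
    "Dataset",
    "AccuracyReport",
    "prediction_accuracy",
    "cross_validate",
    "independent_validate",
    "run_pipeline",
    "accuracy_boxplot",
]


@dataclass
class CVScheme:
    """Resampling layout: replicate count, split sizes, seed."""

    n_replicates: int = 100
    n_train: int = 130
    n_validation: int = 30
    seed: int = 0
    mode: str = "within"

    def __post_init__(self) -> None:
        if self.n_validation < 1:
            raise ValueError("n_validation must be at least 1")
        if self.n_train < 2:
            raise ValueError("n_train must be at least 2")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")


@dataclass
class Dataset:
    """Everything one prediction experiment needs, keyed by trait."""

    blues: dict[str, pd.DataFrame]
    geno: GenotypeMatrix
    K: pd.DataFrame
    h2: dict[str, float]
    haploblocks: dict[str, Haploblock] = field(default_factory=dict)


@dataclass
class AccuracyReport:
    results: pd.DataFrame
    summary: pd.DataFrame
    scheme: CVScheme
    predictions: dict | None = None


def prediction_accuracy(predicted: pd.DataFrame, observed: pd.DataFrame, h2) -> float:
    """Pearson r(predicted, observed) / sqrt(h2).

    Both scales are lower-is-better, so a positive value means useful
    prediction.  The estimator can exceed 1 when h2 is small; it is not
    clipped.
    """
    h2_val = getattr(h2, "h2", h2)
    if not h2_val > 0:
        raise ValueError("heritability must be positive to scale accuracy")
    p = predicted.set_index("line")["value"]
    o = observed.set_index("line")["blue"]
    shared = p.index.intersection(o.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared lines between predictions and observations")
    pv, ov = p.loc[shared].to_numpy(float), o.loc[shared].to_numpy(float)
    if pv.std() == 0 or ov.std() == 0:
        raise ValueError("zero-variance predictions or observations; accuracy undefined")
    r = float(stats.pearsonr(pv, ov)[0])
    return r / float(np.sqrt(h2_val))


def _model_label(model: dict) -> str:
    if "label" in model:
        return model["label"]
    name = model["name"]
    if name == "MAS":
        return f"MAS_{model.get('route', 'random')}_{model.get('n_markers', 21)}"
    if name == "wGS" and "haploblock" in model:
        return f"wGS_{model['haploblock'].name}"
    return name


def _fit_model(model: dict, train_blues: pd.DataFrame, val_lines, dataset: Dataset,
               rep_seed: int):
    """Train one model spec on the training split; return (GEBVs, info)."""
    name = model["name"]
    if name == "GS":
        return gblup_predict(train_blues, dataset.K, val_lines), {}
    if name == "wGS":
        hb = model.get("haploblock")
        if hb is None:
            key = model.get("haploblock_name")
            if key not in dataset.haploblocks:
                raise KeyError(f"model references absent haploblock {key!r}")
            hb = dataset.haploblocks[key]
        return wblup_predict(train_blues, dataset.K, hb, val_lines), {}
    if name == "MAS":
        route = model.get("route", "random")
        k = model.get("n_markers", 21)
        if route == "random":
            subset = sample_random_markers(dataset.geno, k, seed=rep_seed)
        else:
            gwas = gwas_scan(train_blues, dataset.geno, dataset.K)
            if route in ("chromwise", "chromosome-wise"):
                subset = select_chromosome_wise(
                    gwas, train_blues, dataset.geno,
                    per_chrom_top=model.get("per_chrom_top", 12),
                    per_chrom_max=model.get("per_chrom_max", 6),
                    final_cap=k,
                )
            elif route in ("genomewide", "genome-wide"):
                subset = select_genome_wide(
                    gwas, train_blues, dataset.geno,
                    top=model.get("top", 126), final_cap=k,
                )
            else:
                raise ValueError(f"unknown MAS route {route!r}")
        codes = dataset.geno.subset_markers(subset.markers)
        pred, _ = rrblup_predict(train_blues, codes, val_lines)
        return pred, {"markers": list(subset.markers)}
    raise ValueError(f"unknown model {name!r}")


def _summarize(results: pd.DataFrame) -> pd.DataFrame:
    g = results.groupby("model")["accuracy"]
    out = pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1)})
    out["cv"] = out["sd"] / out["mean"].abs()
    return out.reset_index()


def cross_validate(
    dataset: Dataset,
    scheme: CVScheme,
    models: list[dict],
    trait: str,
    return_predictions: bool = False,
) -> AccuracyReport:
    """Replicated within-population random train/validation resampling.

    Every replicate draws disjoint training and validation line sets of the
    exact configured sizes; association scans and stepwise marker selection
    run inside the training split of each replicate.
    """
    blues = dataset.blues[trait].dropna(subset=["blue"])
    pool = [ln for ln in blues["line"] if ln in dataset.K.index]
    if scheme.n_train + scheme.n_validation > len(pool):
        raise ValueError(
            f"scheme needs {scheme.n_train + scheme.n_validation} lines, pool has {len(pool)}"
        )
    h2 = dataset.h2[trait]
    children = np.random.SeedSequence(scheme.seed).spawn(scheme.n_replicates)
    rows = []
    predictions: dict = {}
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        rep_seed = int(rng.integers(2**31))
        perm = rng.permutation(len(pool))
        train_lines = [pool[i] for i in perm[: scheme.n_train]]
        val_lines = [pool[i] for i in perm[scheme.n_train : scheme.n_train + scheme.n_validation]]
        train_blues = blues[blues["line"].isin(train_lines)]
        val_blues = blues[blues["line"].isin(val_lines)]
        for model in models:
            label = _model_label(model)
            pred, _info = _fit_model(model, train_blues, val_lines, dataset, rep_seed)
            acc = prediction_accuracy(pred, val_blues, h2)
            rows.append({"model": label, "replicate": rep, "accuracy": acc})
            if return_predictions:
                predictions[(label, rep)] = pred
    results = pd.DataFrame(rows)
    return AccuracyReport(results, _summarize(results), scheme,
                          predictions if return_predictions else None)


def independent_validate(
    train_blues_by_trait: dict[str, pd.DataFrame],
    valid_blues: pd.DataFrame,
    dataset: Dataset,
    scheme: CVScheme,
    models: list[dict],
    h2_valid,
    include_index: bool = True,
    fixed_validation: bool = False,
) -> AccuracyReport:
    """Independent validation with an optional two-trait selection index.

    Models are trained per trait on lines sampled from each training pool;
    validation lines are sampled from the (disjoint) validation pool -- or
    fixed when the pool size equals ``n_validation`` or ``fixed_validation``
    is set.  For every model kind the two single-trait predictions are also
    combined into a desired-gains index whose weights come from the
    validation candidates' predicted values.
    """
    valid_blues = valid_blues.dropna(subset=["blue"])
    valid_pool = [ln for ln in valid_blues["line"] if ln in dataset.K.index]
    if scheme.n_validation > len(valid_pool):
        raise ValueError("validation pool smaller than n_validation")
    train_pools = {}
    for t, tab in train_blues_by_trait.items():
        tab = tab.dropna(subset=["blue"])
        pool = [ln for ln in tab["line"] if ln in dataset.K.index]
        overlap = set(pool) & set(valid_pool)
        if overlap:
            raise ValueError(f"training pool for {t!r} overlaps the validation pool")
        if scheme.n_train > len(pool):
            raise ValueError(f"training pool for {t!r} smaller than n_train")
        train_pools[t] = (tab, pool)
    h2_val = getattr(h2_valid, "h2", h2_valid)
    children = np.random.SeedSequence(scheme.seed).spawn(scheme.n_replicates)
    rows = []
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        rep_seed = int(rng.integers(2**31))
        if fixed_validation or len(valid_pool) == scheme.n_validation:
            val_lines = list(valid_pool)
        else:
            vp = rng.permutation(len(valid_pool))[: scheme.n_validation]
            val_lines = [valid_pool[i] for i in vp]
        val_obs = valid_blues[valid_blues["line"].isin(val_lines)]
        for model in models:
            label = _model_label(model)
            per_trait: dict[str, pd.DataFrame] = {}
            infos = {}
            for t, (tab, pool) in train_pools.items():
                tp = rng.permutation(len(pool))[: scheme.n_train]
                train_lines = [pool[i] for i in tp]
                tb = tab[tab["line"].isin(train_lines)]
                pred, info = _fit_model(model, tb, val_lines, dataset, rep_seed)
                per_trait[t] = pred
                infos[t] = info
                rows.append(
                    {"model": f"{label}[{t}]", "replicate": rep,
                     "accuracy": prediction_accuracy(pred, val_obs, h2_val)}
                )
            if include_index and set(per_trait) >= {"winter", "frost"}:
                try:
                    w = compute_index_weights(per_trait["winter"], per_trait["frost"])
                    idx = compute_index_values(w, per_trait["winter"], per_trait["frost"])
                except ValueError as exc:
                    warnings.warn(f"replicate {rep}: index skipped ({exc})")
                    continue
                row = {"model": f"index({label})", "replicate": rep,
                       "accuracy": prediction_accuracy(idx, val_obs, h2_val)}
                if all("markers" in i for i in infos.values()):
                    union = set().union(*(i["markers"] for i in infos.values()))
                    row["n_markers_union"] = len(union)
                rows.append(row)
    results = pd.DataFrame(rows)
    return AccuracyReport(results, _summarize(results), scheme)


# ---------------------------------------------------------------------------
# end-to-end pipeline


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(config: dict | str, outdir) -> dict:
    """Simulate -> phenotypic analysis -> genotype QC -> CV -> index -> report.

    ``config`` is a dict or a path to a YAML file with blocks ``simulation``
    (SimConfig fields), ``cv`` (CVScheme fields) and ``models`` (labels among
    GS, wGS, MAS_chromwise, MAS_genomewide, MAS_random).  All randomness
    derives from the configured seeds, and no output embeds a timestamp, so a
    fixed config reproduces every output file byte for byte.
    """
    import io
    from pathlib import Path

    import frostgs
    from . import geno as gmod
    from . import pheno as pmod
    from .simulate import SimConfig, simulate_population

    if not isinstance(config, dict):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = io.StringIO()
    log.write(f"frostgs {frostgs.__version__}\n")
    log.write(f"config: {config!r}\n")

    sim_cfg = SimConfig(**config.get("simulation", {}))
    cv_cfg = dict(config.get("cv", {}))
    model_names = config.get("models", ["GS", "wGS", "MAS_chromwise", "MAS_random"])
    scheme = CVScheme(**cv_cfg)

    pop = _stage("simulate")(simulate_population)(sim_cfg)
    log.write(f"simulated {sim_cfg.n_lines} lines, {pop.genotypes.n_markers} markers, seed {sim_cfg.seed}\n")

    @_stage("pheno")
    def _pheno():
        blues_frost, h2_frost = pmod.fit_frost_model(pop.phenotypes["frost_chamber"])
        trial_blues = []
        for name in ("winter_a", "winter_b"):
            b, h2w, chosen = pmod.fit_trial_model(pop.phenotypes[name])
            log.write(f"trial {name}: model {chosen}, h2 {h2w.h2:.3f}\n")
            trial_blues.append(b)
        blues_winter, h2_winter = pmod.across_trial_model(trial_blues)
        return blues_frost, h2_frost, blues_winter, h2_winter

    blues_frost, h2_frost, blues_winter, h2_winter = _pheno()
    log.write(f"h2 frost {h2_frost.h2:.3f}, h2 winter {h2_winter.h2:.3f}\n")

    @_stage("geno")
    def _geno():
        filtered, qc_report = gmod.qc_filter(pop.genotypes)
        imputed = gmod.impute(filtered)
        tag_a, tag_b = pop.truth.tag_markers
        hb = None
        if tag_a in imputed.markers and tag_b in imputed.markers:
            hb = gmod.build_haploblock(
                imputed, tag_a, tag_b, pop.truth.haploblock_favorable, name="CNV_FrA2"
            )
        deduped, dedup_report = gmod.dedup_perfect_ld(imputed, seed=sim_cfg.seed)
        K = gmod.compute_grm(deduped)
        scores, frac = gmod.pca(K, n_components=min(4, K.shape[0]))
        return deduped, hb, K, scores, frac, qc_report, dedup_report

    geno_clean, hb, K, pca_scores, pca_frac, qc_report, dedup_report = _geno()
    log.write(f"post-QC markers {geno_clean.n_markers}; PCA var fractions {np.round(pca_frac, 3).tolist()}\n")

    dataset = Dataset(
        blues={"winter": blues_winter, "frost": blues_frost},
        geno=geno_clean,
        K=K,
        h2={"winter": h2_winter.h2, "frost": h2_frost.h2},
        haploblocks={"CNV_FrA2": hb} if hb is not None else {},
    )
    model_specs = []
    for nm in model_names:
        if nm == "GS":
            model_specs.append({"name": "GS", "label": "GS"})
        elif nm == "wGS":
            if hb is None:
                raise RuntimeError("pipeline stage 'evaluate' failed: haploblock unavailable for wGS")
            model_specs.append({"name": "wGS", "haploblock": hb, "label": "wGS"})
        elif nm == "MAS_chromwise":
            model_specs.append({"name": "MAS", "route": "chromwise", "n_markers": 21,
                                "label": "MAS_chromwise_21"})
        elif nm == "MAS_genomewide":
            model_specs.append({"name": "MAS", "route": "genomewide", "n_markers": 21,
                                "label": "MAS_genomewide_21"})
        elif nm == "MAS_random":
            model_specs.append({"name": "MAS", "route": "random", "n_markers": 21,
                                "label": "MAS_random_21"})
        else:
            raise RuntimeError(f"pipeline stage 'evaluate' failed: unknown model {nm!r}")

    @_stage("evaluate")
    def _evaluate():
        reports = {}
        for trait in ("winter", "frost"):
            reports[trait] = cross_validate(dataset, scheme, model_specs, trait)
        return reports

    reports = _evaluate()

    @_stage("index")
    def _index():
        # disjoint pools for an independent-style index validation
        rng = np.random.default_rng(sim_cfg.seed)
        lines = list(dataset.K.index)
        perm = rng.permutation(len(lines))
        n_tr_pool = int(0.6 * len(lines))
        train_pool = {lines[i] for i in perm[:n_tr_pool]}
        valid_pool = {lines[i] for i in perm[n_tr_pool:]}
        n_train = min(scheme.n_train, max(2, n_tr_pool - 1))
        n_val = min(scheme.n_validation, max(3, len(valid_pool)))
        ind_scheme = CVScheme(
            n_replicates=scheme.n_replicates, n_train=n_train,
            n_validation=n_val, seed=scheme.seed, mode="independent",
        )
        tbt = {
            t: dataset.blues[t][dataset.blues[t]["line"].isin(train_pool)]
            for t in ("winter", "frost")
        }
        vb = dataset.blues["winter"][dataset.blues["winter"]["line"].isin(valid_pool)]
        base_models = [m for m in model_specs if m["name"] in ("GS", "wGS")]
        if not base_models:
            return None
        return independent_validate(
            tbt, vb, dataset, ind_scheme, base_models, dataset.h2["winter"]
        )

    index_report = _index()

    # ---- outputs ----------------------------------------------------------
    results = pd.concat(
        [r.results.assign(trait=t) for t, r in reports.items()]
        + ([index_report.results.assign(trait="independent_winter")] if index_report is not None else []),
        ignore_index=True,
    )
    summary = pd.concat(
        [r.summary.assign(trait=t) for t, r in reports.items()]
        + ([index_report.summary.assign(trait="independent_winter")] if index_report is not None else []),
        ignore_index=True,
    )
    float_fmt = "%.10g"
    results.to_csv(outdir / "accuracies.csv", index=False, float_format=float_fmt)
    summary.to_csv(outdir / "summary.csv", index=False, float_format=float_fmt)
    blues_winter.to_csv(outdir / "blues_winter.csv", index=False, float_format=float_fmt)
    blues_frost.to_csv(outdir / "blues_frost.csv", index=False, float_format=float_fmt)
    pd.DataFrame(
        [
            {"trait": "winter", "h2": h2_winter.h2, "sigma2_g": h2_winter.sigma2_g, "mvd": h2_winter.mvd},
            {"trait": "frost", "h2": h2_frost.h2, "sigma2_g": h2_frost.sigma2_g, "mvd": h2_frost.mvd},
        ]
    ).to_csv(outdir / "h2_summary.csv", index=False, float_format=float_fmt)
    K.to_csv(outdir / "grm.tsv", sep="\t", float_format=float_fmt)
    pca_scores.to_csv(outdir / "pca_scores.csv", float_format=float_fmt)
    gmod.write_genotypes(geno_clean, outdir / "genotypes_postqc.tsv", outdir / "marker_map.tsv")
    (outdir / "run.log").write_text(log.getvalue())
    return {
        "reports": reports,
        "index_report": index_report,
        "dataset": dataset,
        "h2": {"winter": h2_winter, "frost": h2_frost},
        "outdir": outdir,
    }


def accuracy_boxplot(report: AccuracyReport, path) -> None:
    """Convenience distribution plot of per-replicate accuracies by model."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    groups = [g["accuracy"].to_numpy() for _, g in report.results.groupby("model")]
    labels = [m for m, _ in report.results.groupby("model")]
    ax.boxplot(groups, tick_labels=labels)
    ax.set_ylabel("prediction accuracy")
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
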