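"""Genotype QC, imputation, haploblocks, GRM and PCA."""

import numpy as np
import pandas as pd
import pytest

import frostgs as fg
from conftest import make_geno


# ---------------------------------------------------------------------------
# quality control


def test_qc_removes_hand_counted_markers():
    """10-line fixture: low-MAF and high-missingness markers go, the rest stay."""
    codes = pd.DataFrame(
        {
            # one minor homozygote among 10 lines -> MAF 0.10, kept (not < 0.10)
            "keep_maf10": [-1.0] + [1.0] * 9,
            # one heterozygote -> MAF 0.05, removed
            "drop_maf05": [0.0] + [1.0] * 9,
            # 2/10 missing (20%) -> removed
            "drop_miss20": [np.nan, np.nan, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0],
            # 1/10 missing (10%) -> kept, rule is a strict 'more than'
            "keep_miss10": [np.nan, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0],
            "keep_clean": [1.0, -1.0] * 5,
        },
        index=[f"L{i}" for i in range(10)],
    )
    g = make_geno(codes)
    filtered, report = fg.qc_filter(g)
    assert set(filtered.markers) == {"keep_maf10", "keep_miss10", "keep_clean"}
    removed = dict(zip(report["marker"], report["reason"]))
    assert removed == {"drop_maf05": "maf", "drop_miss20": "missingness"}


def test_qc_clean_matrix_unchanged_and_all_removed_errors():
    clean = make_geno(np.array([[1.0, -1.0], [-1.0, 1.0], [1.0, -1.0], [-1.0, 1.0]]))
    out, report = fg.qc_filter(clean)
    assert report.empty
    pd.testing.assert_frame_equal(out.codes, clean.codes)
    allbad = make_geno(np.array([[1.0], [1.0], [1.0], [1.0]]))
    with pytest.raises(ValueError, match="every marker"):
        fg.qc_filter(allbad)


# ---------------------------------------------------------------------------
# perfect-LD de-duplication


def test_dedup_drops_duplicates_signflips_and_monomorphic():
    base = np.array([1.0, -1.0, 1.0, 1.0, -1.0, -1.0])
    codes = pd.DataFrame(
        {"a": base, "a_dup": base, "a_flip": -base, "mono": np.ones(6), "other": [1, 1, -1, -1, 1, -1.0]},
        index=[f"L{i}" for i in range(6)],
    )
    g = make_geno(codes)
    out, report = fg.dedup_perfect_ld(g, seed=0)
    # the {a, a_dup, a_flip} clique keeps exactly one member
    clique = {"a", "a_dup", "a_flip"}
    assert len(clique & set(out.markers)) == 1
    assert "other" in out.markers
    assert "mono" not in out.markers
    assert set(report.loc[report["reason"] == "monomorphic", "marker"]) == {"mono"}
    # determinism
    out2, _ = fg.dedup_perfect_ld(g, seed=0)
    assert list(out.markers) == list(out2.markers)


def test_dedup_requires_complete_data():
    codes = np.array([[1.0, np.nan], [-1.0, 1.0], [1.0, -1.0]])
    with pytest.raises(ValueError, match="complete"):
        fg.dedup_perfect_ld(make_geno(codes), seed=0)


# ---------------------------------------------------------------------------
# imputation


def test_impute_no_missing_identity():
    g = make_geno(np.array([[1.0, -1.0], [-1.0, 1.0], [1.0, 1.0]]))
    out = fg.impute(g)
    pd.testing.assert_frame_equal(out.codes, g.codes)


def test_impute_copies_from_duplicate_line():
    """A zero-distance neighbour dictates the imputed value."""
    rng = np.random.default_rng(0)
    base = rng.choice([-1.0, 1.0], size=(8, 12))
    codes = pd.DataFrame(base, index=[f"L{i}" for i in range(8)], columns=[f"M{j}" for j in range(12)])
    codes.loc["L7"] = codes.loc["L0"]  # duplicate line
    codes.loc["L7", "M5"] = np.nan
    g = make_geno(codes)
    out = fg.impute(g)
    assert out.codes.loc["L7", "M5"] == codes.loc["L0", "M5"]
    # observed entries never change
    mask = codes.notna()
    pd.testing.assert_frame_equal(out.codes[mask].dropna(axis=1, how="all"), codes[mask].dropna(axis=1, how="all"))


def test_impute_mask_and_recover_error_rate():
    """5% MCAR masking recovered with < 15% error, averaged over 20 seeds.

    Run at the default marker density, where the founder-segment linkage the
    imputer exploits is present (two chromosomes keep the run light).
    """
    errs = []
    for seed in range(20):
        cfg = fg.SimConfig(
            n_lines=180, n_families=110, n_chromosomes=2, markers_per_chromosome=67,
            missing_rate=0.0, seed=seed,
        )
        pop = fg.simulate_population(cfg, with_phenotypes=False)
        sub = fg.GenotypeMatrix(pop.truth.complete_codes, pop.marker_map)
        rng = np.random.default_rng(10_000 + seed)
        arr = sub.codes.to_numpy().copy()
        mask = rng.random(arr.shape) < 0.05
        truth = arr[mask].copy()
        arr[mask] = np.nan
        g = fg.GenotypeMatrix(
            pd.DataFrame(arr, index=sub.codes.index, columns=sub.codes.columns), sub.marker_map
        )
        out = fg.impute(g)
        errs.append(np.mean(out.codes.to_numpy()[mask] != truth))
    assert np.mean(errs) < 0.15


def test_impute_all_missing_marker_errors():
    codes = np.array([[np.nan, 1.0], [np.nan, -1.0], [np.nan, 1.0]])
    with pytest.raises(ValueError, match="all calls missing"):
        fg.impute(make_geno(codes))


# ---------------------------------------------------------------------------
# haploblock coding


@pytest.mark.parametrize(
    "a,b,expected",
    [
        (1.0, 1.0, 1.0),
        (-1.0, -1.0, -1.0),
        (1.0, -1.0, 0.0),
        (-1.0, 1.0, 0.0),
        (0.0, 1.0, 0.0),
        (1.0, 0.0, 0.0),
        (0.0, 0.0, 0.0),
        (0.0, -1.0, 0.0),
        (-1.0, 0.0, 0.0),
    ],
)
def test_haploblock_truth_table(a, b, expected):
    """Homozygous only when both components carry the same allele class."""
    codes = pd.DataFrame({"ma": [a, 1.0, -1.0], "mb": [b, 1.0, -1.0]}, index=["x", "p", "q"])
    hb = fg.build_haploblock(make_geno(codes), "ma", "mb")
    assert hb.block_codes["x"] == expected


def test_haploblock_favorable_orientation_and_errors():
    codes = pd.DataFrame({"ma": [-1.0, 1.0, 0.0], "mb": [1.0, -1.0, 1.0]}, index=["x", "y", "z"])
    g = make_geno(codes)
    hb = fg.build_haploblock(g, "ma", "mb", favorable={"ma": -1.0, "mb": 1.0})
    assert hb.block_codes["x"] == 1.0  # both favorable alleles, homozygous
    assert hb.block_codes["y"] == -1.0
    assert hb.block_codes["z"] == 0.0
    with pytest.raises(KeyError):
        fg.build_haploblock(g, "ma", "nope")
    gm = make_geno(pd.DataFrame({"ma": [1.0, np.nan], "mb": [1.0, 1.0]}, index=["x", "y"]))
    with pytest.raises(ValueError, match="imputed"):
        fg.build_haploblock(gm, "ma", "mb")


# ---------------------------------------------------------------------------
# genomic relationship matrix


def test_grm_two_line_worked_example():
    """2 lines, 1 marker, codes (+1,-1): p=0.5, denom=0.5 -> [[2,-2],[-2,2]]."""
    g = make_geno(np.array([[1.0], [-1.0]]))
    K = fg.compute_grm(g)
    np.testing.assert_allclose(K.to_numpy(), [[2.0, -2.0], [-2.0, 2.0]], atol=1e-12)


def test_grm_identical_lines_and_row_sums(complete_geno):
    K = fg.compute_grm(complete_geno)
    np.testing.assert_allclose(K.sum(axis=1).to_numpy(), 0.0, atol=1e-8)
    np.testing.assert_allclose(K.to_numpy(), K.to_numpy().T, atol=1e-12)
    dup = make_geno(np.array([[1.0, -1.0, 1.0], [1.0, -1.0, 1.0], [-1.0, 1.0, 1.0]]))
    Kd = fg.compute_grm(dup)
    assert Kd.iloc[0, 0] == pytest.approx(Kd.iloc[1, 1])
    assert Kd.iloc[0, 1] == pytest.approx(Kd.iloc[0, 0])


def test_grm_marker_permutation_and_monomorphic_invariance():
    rng = np.random.default_rng(2)
    codes = pd.DataFrame(
        rng.choice([-1.0, 1.0], size=(12, 30)),
        index=[f"L{i}" for i in range(12)],
        columns=[f"M{j}" for j in range(30)],
    )
    g = make_geno(codes)
    K = fg.compute_grm(g)
    perm = list(rng.permutation(codes.columns))
    K2 = fg.compute_grm(make_geno(codes[perm]))
    np.testing.assert_allclose(K.to_numpy(), K2.to_numpy(), atol=1e-12)
    with_mono = codes.copy()
    with_mono["mono"] = 1.0
    K3 = fg.compute_grm(make_geno(with_mono))
    np.testing.assert_allclose(K.to_numpy(), K3.to_numpy(), atol=1e-12)


def test_grm_errors():
    with pytest.raises(ValueError, match="denominator"):
        fg.compute_grm(make_geno(np.ones((3, 2))))
    with pytest.raises(ValueError, match="complete"):
        fg.compute_grm(make_geno(np.array([[1.0], [np.nan]])))


# ---------------------------------------------------------------------------
# PCA


def test_pca_variance_fractions_and_degenerate_kinship():
    rng = np.random.default_rng(4)
    codes = pd.DataFrame(
        rng.choice([-1.0, 1.0], size=(15, 40)),
        index=[f"L{i}" for i in range(15)],
        columns=[f"M{j}" for j in range(40)],
    )
    K = fg.compute_grm(make_geno(codes))
    scores, frac = fg.pca(K, n_components=15)
    assert frac.sum() == pytest.approx(1.0, abs=1e-9)
    with pytest.raises(ValueError, match="exceeds"):
        fg.pca(K, n_components=16)
    # kinship of mutually identical lines: rank one, a single trivial
    # component carries everything
    w = np.array([1.0, -1.0, 1.0, -1.0])
    Ks = pd.DataFrame(np.full((5, 5), w @ w / 4.0), index=list("abcde"), columns=list("abcde"))
    _, frac_s = fg.pca(Ks, n_components=5)
    assert frac_s[0] == pytest.approx(1.0)
    np.testing.assert_allclose(frac_s[1:], 0.0, atol=1e-12)


def test_pca_separates_diverged_families():
    """First PC separates two groups drawn at different allele frequencies."""
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        m = 120
        p1, p2 = 0.2, 0.8
        grp1 = (rng.random((25, m)) < p1) * 2.0 - 1.0
        grp2 = (rng.random((25, m)) < p2) * 2.0 - 1.0
        g = make_geno(np.vstack([grp1, grp2]))
        K = fg.compute_grm(g)
        scores, _ = fg.pca(K, 2)
        lab = np.r_[np.zeros(25), np.ones(25)]
        r = np.corrcoef(scores["PC1"], lab)[0, 1]
        hits += abs(r) > 0.8
    assert hits == 20


# ---------------------------------------------------------------------------
# I/O round trips


def test_matrix_map_roundtrip(tmp_path, complete_geno):
    sub = complete_geno.subset_markers(list(complete_geno.markers[:25]))
    from frostgs.geno import read_genotypes, write_genotypes

    write_genotypes(sub, tmp_path / "m.tsv", tmp_path / "map.tsv")
    back = read_genotypes(tmp_path / "m.tsv", tmp_path / "map.tsv")
    pd.testing.assert_frame_equal(back.codes, sub.codes, check_dtype=False, check_names=False)
    pd.testing.assert_frame_equal(back.marker_map, sub.marker_map, check_dtype=False, check_names=False)


def test_vcf_roundtrip(tmp_path, small_pop):
    from frostgs.geno import read_vcf, write_vcf

    sub = small_pop.genotypes.subset_markers(list(small_pop.genotypes.markers[:30]))
    write_vcf(sub, tmp_path / "g.vcf")
    back = read_vcf(tmp_path / "g.vcf")
    # VCF reorders by position but preserves codes incl. missing
    back_aligned = back.codes[sub.codes.columns].loc[sub.codes.index]
    pd.testing.assert_frame_equal(back_aligned, sub.codes, check_dtype=False)


def test_qc_impute_dedup_idempotent(small_pop):
    filtered, _ = fg.qc_filter(small_pop.genotypes)
    imputed = fg.impute(filtered)
    deduped, _ = fg.dedup_perfect_ld(imputed, seed=3)
    # a second pass through the pipeline is a no-op
    f2, rep2 = fg.qc_filter(deduped)
    assert rep2.empty
    i2 = fg.impute(f2)
    d2, drep2 = fg.dedup_perfect_ld(i2, seed=3)
    assert list(d2.markers) == list(deduped.markers)
    pd.testing.assert_frame_equal(d2.codes, deduped.codes)
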