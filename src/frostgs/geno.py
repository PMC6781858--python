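"""Genotype handling: QC, LD de-duplication, imputation, haploblocks, GRM, PCA.

Marker calls are coded +1 (homozygous major), -1 (homozygous minor) and 0
(heterozygous), with NaN for missing, the convention used throughout
genomic-prediction work on inbred wheat panels.  The quality-control rules are
the ones routinely applied to GBS panels in breeding programs: drop markers
with minor allele frequency below 0.10 or more than 10% missing calls, then
drop one marker of every perfectly correlated (r^2 = 1) pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

__all__ = [
    "GenotypeMatrix",
    "Haploblock",
    "qc_filter",
    "dedup_perfect_ld",
    "impute",
    "build_haploblock",
    "compute_grm",
    "pca",
    "read_genotypes",
    "write_genotypes",
    "read_vcf",
    "write_vcf",
]

_VALID_CODES = {-1.0, 0.0, 1.0}


@dataclass
class GenotypeMatrix:
    """Lines x markers call matrix with a chromosome/position map.

    ``codes``: DataFrame indexed by line id, columns marker ids, values in
    {-1, 0, +1, NaN}.  ``marker_map``: DataFrame indexed by marker id with
    columns ``chrom`` and ``pos``, covering every marker exactly once.
    """

    codes: pd.DataFrame
    marker_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.codes = self.codes.astype(float)
        if self.codes.index.has_duplicates:
            raise ValueError("line identifiers are not unique")
        if self.codes.columns.has_duplicates:
            raise ValueError("marker identifiers are not unique")
        vals = self.codes.to_numpy().ravel()
        finite = vals[~np.isnan(vals)]
        if not np.isin(finite, [-1.0, 0.0, 1.0]).all():
            raise ValueError("genotype codes must be in {-1, 0, +1} or missing")
        if set(self.marker_map.index) != set(self.codes.columns):
            raise ValueError("marker map does not cover the marker set exactly once")
        self.marker_map = self.marker_map.loc[self.codes.columns]

    # -- derived quantities -------------------------------------------------

    @property
    def n_lines(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    @property
    def lines(self) -> pd.Index:
        return self.codes.index

    @property
    def markers(self) -> pd.Index:
        return self.codes.columns

    def allele_freq(self) -> pd.Series:
        """Frequency p_k of the +1-coded allele, from non-missing calls."""
        return (self.codes.mean(axis=0, skipna=True) + 1.0) / 2.0

    def maf(self) -> pd.Series:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> pd.Series:
        return self.codes.isna().mean(axis=0)

    def subset_markers(self, markers) -> "GenotypeMatrix":
        return GenotypeMatrix(self.codes[list(markers)].copy(), self.marker_map.loc[list(markers)].copy())

    def subset_lines(self, lines) -> "GenotypeMatrix":
        return GenotypeMatrix(self.codes.loc[list(lines)].copy(), self.marker_map.copy())


@dataclass
class Haploblock:
    """Composite two-SNP marker tagging a multi-allelic locus (e.g. a CNV).

    The block code is +1 when both component markers carry the favorable
    (tolerance) allele homozygously, -1 when both carry the unfavorable allele
    homozygously, and 0 for every mixed or heterozygous combination.
    """

    name: str
    marker_a: str
    marker_b: str
    block_codes: pd.Series
    favorable_allele: dict = field(default_factory=dict)

    def codes_for(self, lines) -> np.ndarray:
        return self.block_codes.loc[list(lines)].to_numpy(dtype=float)


# ---------------------------------------------------------------------------


def qc_filter(geno: GenotypeMatrix, maf_min: float = 0.10, max_missing: float = 0.10):
    """Remove markers with MAF < ``maf_min`` or missingness > ``max_missing``.

    Frequencies are computed on non-missing calls; the missingness rule is a
    strict 'more than' so a marker at exactly the threshold is kept.  Returns
    the filtered matrix and a report with one row per removed marker.
    """
    if geno.n_markers == 0:
        raise ValueError("empty genotype matrix")
    maf = geno.maf()
    miss = geno.missing_rate()
    # strict inequalities with a float guard so a marker at exactly the
    # threshold (e.g. MAF 16/160) is kept regardless of rounding
    eps = 1e-9
    rows = []
    for m in geno.markers:
        if miss[m] > max_missing + eps:
            rows.append({"marker": m, "reason": "missingness", "value": miss[m]})
        elif maf[m] < maf_min - eps:
            rows.append({"marker": m, "reason": "maf", "value": maf[m]})
    report = pd.DataFrame(rows, columns=["marker", "reason", "value"])
    keep = [m for m in geno.markers if m not in set(report["marker"])]
    if not keep:
        raise ValueError("quality control removed every marker")
    return geno.subset_markers(keep), report


def dedup_perfect_ld(geno: GenotypeMatrix, seed: int = 0):
    """Drop all but one (seeded-random) marker of every r^2 = 1 clique.

    Requires complete data (run after imputation).  Monomorphic markers have
    undefined r^2 and are dropped with reason ``monomorphic``.
    """
    codes = geno.codes.to_numpy()
    if np.isnan(codes).any():
        raise ValueError("de-duplication requires complete (imputed) genotypes")
    rng = np.random.default_rng(seed)
    markers = list(geno.markers)
    sd = codes.std(axis=0)
    mono = [m for m, s in zip(markers, sd) if s == 0.0]
    poly_idx = [j for j, s in enumerate(sd) if s > 0.0]
    dropped = [{"marker": m, "reason": "monomorphic", "kept_as": None} for m in mono]

    if poly_idx:
        sub = codes[:, poly_idx]
        r = np.corrcoef(sub, rowvar=False)
        r2 = np.atleast_2d(r) ** 2
        n = len(poly_idx)
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        ii, jj = np.where(np.triu(r2 >= 1.0 - 1e-12, 1))
        for i, j in zip(ii.tolist(), jj.tolist()):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
        groups: dict[int, list[int]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(i)
        keep = []
        for members in groups.values():
            if len(members) == 1:
                keep.append(members[0])
                continue
            chosen = members[int(rng.integers(len(members)))]
            keep.append(chosen)
            for m in members:
                if m != chosen:
                    dropped.append(
                        {
                            "marker": markers[poly_idx[m]],
                            "reason": "r2=1",
                            "kept_as": markers[poly_idx[chosen]],
                        }
                    )
        keep_names = {markers[poly_idx[i]] for i in keep}
    else:
        keep_names = set()

    surviving = [m for m in markers if m in keep_names]
    if not surviving:
        raise ValueError("no polymorphic markers survive de-duplication")
    report = pd.DataFrame(dropped, columns=["marker", "reason", "kept_as"])
    return geno.subset_markers(surviving), report


def _masked_distance(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Mean |code difference| between rows of A and rows of B, NaN-aware.

    Pairs with no co-observed marker get an infinite distance.
    """
    diff = np.abs(A[:, None, :] - B[None, :, :])
    cnt = np.sum(~np.isnan(diff), axis=2)
    with np.errstate(invalid="ignore"):
        D = np.nansum(diff, axis=2) / cnt
    D[cnt == 0] = np.inf
    return D


def impute(geno: GenotypeMatrix, k: int = 5, sweeps: int = 3, window: int = 10) -> GenotypeMatrix:
    """Chromosome-wise k-nearest-neighbour imputation of missing calls.

    For each missing call the mode of the k nearest lines observed at that
    marker is filled in, with line distances computed over a local window of
    up to ``window`` map-adjacent markers on either side -- the local
    haplotype context that carries the linkage information.  Zero-distance
    neighbours (lines duplicating the local haplotype) take precedence.
    Distances use co-observed markers on the first sweep and the
    progressively completed matrix on later sweeps; observed entries are
    never altered.  Deterministic: ties resolve by distance order, then line
    order.
    """
    codes = geno.codes.copy()
    if not codes.isna().to_numpy().any():
        return GenotypeMatrix(codes, geno.marker_map.copy())
    all_missing = codes.columns[codes.isna().all(axis=0)]
    if len(all_missing):
        raise ValueError(
            f"markers with all calls missing (should be QC-removed): {list(all_missing)}"
        )
    for chrom, mk in geno.marker_map.groupby("chrom").groups.items():
        cols = [m for m in codes.columns if m in set(mk)]
        order_by_pos = np.argsort(geno.marker_map.loc[cols, "pos"].to_numpy(), kind="mergesort")
        cols = [cols[i] for i in order_by_pos]
        block = codes[cols].to_numpy()
        obs_mask = ~np.isnan(block)
        if obs_mask.all():
            continue
        m = len(cols)
        work = block.copy()
        miss_cols = np.where(~obs_mask.all(axis=0))[0]
        for sweep in range(max(1, sweeps)):
            source = block if sweep == 0 else work
            newwork = work.copy()
            for j in miss_cols:
                lo, hi = max(0, j - window), min(m, j + window + 1)
                rows = np.where(~obs_mask[:, j])[0]
                donors = np.where(obs_mask[:, j])[0]
                D = _masked_distance(source[rows, lo:hi], source[donors, lo:hi])
                for ri, i in enumerate(rows):
                    nearest = donors[np.lexsort((donors, D[ri]))]
                    zero = nearest[D[ri, np.lexsort((donors, D[ri]))] <= 1e-12]
                    pool = zero if len(zero) else nearest[:k]
                    vals, counts = np.unique(block[pool, j], return_counts=True)
                    tied = vals[counts == counts.max()]
                    if len(tied) == 1:
                        newwork[i, j] = tied[0]
                    else:
                        for d in nearest:
                            if block[d, j] in tied:
                                newwork[i, j] = block[d, j]
                                break
            work = newwork
        block[~obs_mask] = work[~obs_mask]
        codes[cols] = block
    return GenotypeMatrix(codes, geno.marker_map.copy())


def build_haploblock(
    geno: GenotypeMatrix,
    marker_a: str,
    marker_b: str,
    favorable: dict | None = None,
    name: str = "haploblock",
) -> Haploblock:
    """Combine two tag SNPs into a composite haploblock marker.

    ``favorable`` maps each component marker to the code (+1 or -1) of its
    frost-tolerance allele (default +1 for both).  A line is coded +1 when
    homozygous favorable at both components, -1 when homozygous unfavorable at
    both, and 0 otherwise -- including when either component is heterozygous.
    """
    for m in (marker_a, marker_b):
        if m not in geno.markers:
            raise KeyError(f"unknown marker id {m!r}")
    favorable = dict(favorable or {})
    oa = float(favorable.get(marker_a, 1.0))
    ob = float(favorable.get(marker_b, 1.0))
    if abs(oa) != 1.0 or abs(ob) != 1.0:
        raise ValueError("favorable allele spec must be +1 or -1 per marker")
    a = geno.codes[marker_a] * oa
    b = geno.codes[marker_b] * ob
    if a.isna().any() or b.isna().any():
        raise ValueError("component markers must be imputed before block coding")
    block = pd.Series(0.0, index=geno.lines, name=name)
    block[(a == 1.0) & (b == 1.0)] = 1.0
    block[(a == -1.0) & (b == -1.0)] = -1.0
    return Haploblock(
        name=name,
        marker_a=marker_a,
        marker_b=marker_b,
        block_codes=block,
        favorable_allele={marker_a: oa, marker_b: ob},
    )


def compute_grm(geno: GenotypeMatrix) -> pd.DataFrame:
    """VanRaden genomic relationship matrix K = W W' / (2 sum p_k (1-p_k)).

    W is the column-centered marker matrix W_ik = Z_ik + 1 - 2 p_k with p_k
    the +1-allele frequency, so every row of K sums to zero and K is PSD.
    """
    Z = geno.codes.to_numpy()
    if np.isnan(Z).any():
        raise ValueError("GRM requires complete (imputed) genotypes")
    p = (Z.mean(axis=0) + 1.0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all markers monomorphic: GRM denominator is zero")
    W = Z + 1.0 - 2.0 * p
    K = (W @ W.T) / denom
    return pd.DataFrame(K, index=geno.lines, columns=geno.lines)


def pca(K: pd.DataFrame, n_components: int = 2):
    """Principal components of a genomic relationship matrix.

    Returns scores (eigenvectors scaled by sqrt(eigenvalue)) and the fraction
    of relationship variance carried by each requested component.
    """
    n = K.shape[0]
    if n_components > n:
        raise ValueError(f"n_components={n_components} exceeds {n} lines")
    w, U = linalg.eigh(np.asarray(K, dtype=float))
    w = np.clip(w[::-1], 0.0, None)
    U = U[:, ::-1]
    total = w.sum()
    frac = w[:n_components] / total if total > 0 else np.zeros(n_components)
    scores = U[:, :n_components] * np.sqrt(w[:n_components])
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(scores, index=K.index, columns=cols), frac


# ---------------------------------------------------------------------------
# I/O: tab-separated matrix + map, and minimal VCF


def write_genotypes(geno: GenotypeMatrix, matrix_path, map_path) -> None:
    out = geno.codes.copy()
    out.index.name = "line"
    out.to_csv(matrix_path, sep="\t", na_rep="NA", float_format="%g")
    mp = geno.marker_map.copy()
    mp.index.name = "marker"
    mp.to_csv(map_path, sep="\t")


def read_genotypes(matrix_path, map_path) -> GenotypeMatrix:
    codes = pd.read_csv(matrix_path, sep="\t", index_col=0, na_values="NA")
    mp = pd.read_csv(map_path, sep="\t", index_col=0)
    return GenotypeMatrix(codes, mp)


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Export calls as an uncompressed diploid VCF (GT field only).

    +1 maps to 0/0 (homozygous REF = major allele), 0 to 0/1, -1 to 1/1 and
    missing to ./..  Placeholder REF/ALT alleles A/T are written since the
    underlying assay alleles are not tracked.
    """
    mp = geno.marker_map
    chroms = list(dict.fromkeys(mp["chrom"]))
    gt_map = {1.0: "0/0", 0.0: "0/1", -1.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            maxpos = int(mp.loc[mp["chrom"] == c, "pos"].max()) + 1
            fh.write(f"##contig=<ID={c},length={maxpos}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, geno.lines))
            + "\n"
        )
        order = mp.sort_values(["chrom", "pos"]).index
        for m in order:
            chrom, pos = mp.at[m, "chrom"], int(mp.at[m, "pos"])
            calls = geno.codes[m]
            gts = "\t".join(gt_map.get(v, "./.") if not np.isnan(v) else "./." for v in calls)
            fh.write(f"{chrom}\t{pos}\t{m}\tA\tT\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a diploid GT-only VCF back into a GenotypeMatrix (unphased accepted)."""
    code_map = {
        ("0", "0"): 1.0,
        ("0", "1"): 0.0,
        ("1", "0"): 0.0,
        ("1", "1"): -1.0,
    }
    markers, rows, lines = [], [], None
    mp_rows = []
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("##"):
                continue
            parts = raw.rstrip("\n").split("\t")
            if raw.startswith("#CHROM"):
                lines = parts[9:]
                continue
            chrom, pos, mid = parts[0], int(parts[1]), parts[2]
            fmt = parts[8].split(":")
            gi = fmt.index("GT")
            vals = []
            for cell in parts[9:]:
                gt = cell.split(":")[gi].replace("|", "/")
                alleles = tuple(gt.split("/"))
                vals.append(code_map.get(alleles, np.nan))
            markers.append(mid)
            mp_rows.append({"marker": mid, "chrom": chrom, "pos": pos})
            rows.append(vals)
    if lines is None:
        raise ValueError("no #CHROM header line in VCF")
    codes = pd.DataFrame(np.array(rows, dtype=float).T, index=lines, columns=markers)
    mp = pd.DataFrame(mp_rows).set_index("marker")
    # chrom labels may be numeric in the matrix+map representation
    try:
        mp["chrom"] = pd.to_numeric(mp["chrom"])
    except (ValueError, TypeError):
        pass
    return GenotypeMatrix(codes, mp)
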