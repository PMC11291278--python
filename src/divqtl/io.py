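"""Readers, writers and phenotype preparation.

On-disk conventions
-------------------
* Genotypes: VCF 4.x, biallelic SNVs only. Reading goes through :mod:`cyvcf2`;
  multiallelic records are skipped (counted), missing genotypes are imputed to
  the per-variant mean dosage rounded to the nearest integer and flagged.
* Phenotypes: BED-like TSV — ``chrom  start  end  feature_id`` then one column
  per sample. BED start is 0-based half-open on disk; in memory the TSS is
  stored 1-based (``tss = start + 1``).
* Sample metadata: TSV with columns ``sample_id, population,
  continental_group, sex, batch``; every population maps to exactly one
  continental group.

Preparation follows the usual QTL-mapping recipe: median-of-ratios size
factors, ``log2(count/sf + 1)``, per-feature rank inverse-normal transform,
then OLS residualisation against batch/sex (and optionally expression PCs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

MISSING_FRAC_MAX = 0.05  # variants with more missing genotypes are dropped


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SampleTable:
    """Per-sample metadata: population nested in continental group, sex, batch."""

    table: pd.DataFrame  # columns: sample_id, population, continental_group, sex, batch

    REQUIRED = ("sample_id", "population", "continental_group", "sex", "batch")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")
        if t["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in sample table")
        if t[list(self.REQUIRED)].isna().any().any():
            raise ValueError("sample table has missing fields")
        # each population must nest in exactly one continental group
        n_groups = t.groupby("population")["continental_group"].nunique()
        bad = n_groups[n_groups > 1]
        if len(bad):
            raise ValueError(f"populations in multiple groups: {list(bad.index)}")

    @property
    def sample_ids(self) -> np.ndarray:
        return self.table["sample_id"].to_numpy()

    @property
    def groups(self) -> np.ndarray:
        return self.table["continental_group"].to_numpy()

    @property
    def populations(self) -> np.ndarray:
        return self.table["population"].to_numpy()

    def reindex(self, sample_ids) -> "SampleTable":
        t = self.table.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleTable(t)


@dataclass
class GenotypeMatrix:
    """Biallelic dosages (variants x samples), optionally phased haplotypes."""

    variants: pd.DataFrame  # columns: chrom, pos (1-based), ref, alt, variant_id
    dosages: np.ndarray  # (n_variants, n_samples) int8 in {0,1,2}
    sample_ids: np.ndarray
    haplotypes: np.ndarray | None = None  # (n_variants, n_samples, 2) in {0,1}
    imputed_mask: np.ndarray | None = None  # True where a genotype was imputed

    def __post_init__(self) -> None:
        v = self.variants
        if self.dosages.shape != (len(v), len(self.sample_ids)):
            raise ValueError("dosage shape does not match variants/samples")
        order = v.sort_values(["chrom", "pos"], kind="stable").index
        if not np.array_equal(order.to_numpy(), np.arange(len(v))):
            raise ValueError("variants must be sorted by (chrom, pos)")
        if self.haplotypes is not None:
            if not np.array_equal(self.haplotypes.sum(axis=2), self.dosages):
                raise ValueError("dosages must equal haplotype sums")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def allele_freq(self) -> np.ndarray:
        return self.dosages.mean(axis=1) / 2.0

    def maf(self) -> np.ndarray:
        af = self.allele_freq()
        return np.minimum(af, 1.0 - af)

    def subset_variants(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.variants.iloc[idx].reset_index(drop=True),
            self.dosages[idx],
            self.sample_ids,
            None if self.haplotypes is None else self.haplotypes[idx],
            None if self.imputed_mask is None else self.imputed_mask[idx],
        )


@dataclass
class PhenotypeMatrix:
    """Per-feature per-sample values with TSS metadata.

    ``features`` columns: feature_id, gene_id, chrom, tss (1-based), strand and
    optionally cluster_id (for intron excision ratios).
    """

    features: pd.DataFrame
    values: np.ndarray  # (n_features, n_samples)
    sample_ids: np.ndarray
    value_kind: str = "counts"  # counts | normalized | ratios

    def __post_init__(self) -> None:
        if self.features["feature_id"].duplicated().any():
            raise ValueError("duplicate feature_id")
        if self.values.shape != (len(self.features), len(self.sample_ids)):
            raise ValueError("value matrix shape mismatch")
        if self.value_kind == "counts" and (self.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.value_kind == "ratios" and (
            (self.values < 0).any() or (self.values > 1 + 1e-9).any()
        ):
            raise ValueError("ratios must lie in [0, 1]")

    @property
    def n_features(self) -> int:
        return len(self.features)


@dataclass
class CovariateMatrix:
    """Covariates x samples design block (no intercept row)."""

    values: np.ndarray  # (n_covariates, n_samples)
    names: list[str] = field(default_factory=list)
    sample_ids: np.ndarray | None = None

    def design(self) -> np.ndarray:
        """Samples x (1 + covariates) design matrix with intercept."""
        n = self.values.shape[1]
        X = np.column_stack([np.ones(n), self.values.T])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("covariate design is rank-deficient with intercept")
        return X


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, sample_subset=None) -> GenotypeMatrix:
    """Read biallelic genotypes from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic records are skipped (logged count). Missing genotypes are
    imputed to the per-variant mean dosage rounded to nearest integer; variants
    with more than 5% missingness are excluded. Phased haplotypes are retained
    when every genotype of every variant is phased.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    all_samples = np.array(vcf.samples)
    if sample_subset is not None:
        keep = np.isin(all_samples, np.asarray(sample_subset))
        if not keep.any():
            raise ValueError("no overlap between VCF samples and sample_subset")
    else:
        keep = np.ones(len(all_samples), dtype=bool)
    sample_ids = all_samples[keep]

    rows, dosage_rows, hap_rows, imputed_rows = [], [], [], []
    n_multi = n_highmiss = 0
    all_phased = True
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        gt = np.array(rec.genotypes, dtype=object)[keep]  # rows: [a0, a1, phased]
        a = np.array([[g[0], g[1]] for g in gt], dtype=np.int16)
        phased = all(bool(g[2]) for g in gt)
        missing = (a < 0).any(axis=1)
        if missing.mean() > MISSING_FRAC_MAX:
            n_highmiss += 1
            continue
        dos = a.sum(axis=1).astype(np.float64)
        if missing.any():
            mean_d = dos[~missing].mean() if (~missing).any() else 0.0
            fill = int(np.rint(mean_d))
            dos[missing] = fill
            a[missing] = [fill // 2 + fill % 2, fill // 2]  # consistent hap fill
            all_phased = all_phased and False
        all_phased = all_phased and phased
        rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0],
                     rec.ID or f"{rec.CHROM}_{rec.POS}_{rec.REF}_{rec.ALT[0]}"))
        dosage_rows.append(dos.astype(np.int8))
        hap_rows.append(a.astype(np.int8))
        imputed_rows.append(missing)
    if n_multi:
        log.info("read_vcf: skipped %d multiallelic records", n_multi)
    if n_highmiss:
        log.info("read_vcf: dropped %d variants with >%.0f%% missing genotypes",
                 n_highmiss, 100 * MISSING_FRAC_MAX)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "variant_id"])
    dosages = np.array(dosage_rows, dtype=np.int8).reshape(len(rows), len(sample_ids))
    haps = None
    if all_phased and rows:
        haps = np.array(hap_rows, dtype=np.int8)
    gm = GenotypeMatrix(variants, dosages, sample_ids, haplotypes=haps,
                        imputed_mask=np.array(imputed_rows).reshape(dosages.shape))
    gm.n_multiallelic_skipped = n_multi  # type: ignore[attr-defined]
    return gm


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write biallelic genotypes as uncompressed VCF 4.2 (phased GT when available)."""
    path = Path(path)
    v = genotypes.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(v["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, genotypes.sample_ids)) + "\n")
        haps = genotypes.haplotypes
        for i in range(genotypes.n_variants):
            row = v.iloc[i]
            if haps is not None:
                gts = [f"{haps[i, j, 0]}|{haps[i, j, 1]}"
                       for j in range(genotypes.n_samples)]
            else:
                conv = {0: "0/0", 1: "0/1", 2: "1/1"}
                gts = [conv[int(d)] for d in genotypes.dosages[i]]
            fh.write(f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.ref}\t"
                     f"{row.alt}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# phenotype BED
# ---------------------------------------------------------------------------

def read_phenotype_bed(path, value_kind: str = "counts") -> PhenotypeMatrix:
    """Read a BED-like phenotype matrix; ``tss = start + 1`` (0-based BED start).

    The 4th column (``feature_id``) may carry structured ids of the form
    ``gene:cluster:intron`` for splicing phenotypes; they are split into
    gene_id / cluster_id when present.
    """
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if len(cols) < 5:
        raise ValueError("phenotype BED needs 4 annotation columns plus samples")
    chrom_c, start_c, end_c, id_c = cols[:4]
    if df[id_c].duplicated().any():
        dups = df[id_c][df[id_c].duplicated()].tolist()
        raise ValueError(f"duplicate feature_id: {dups}")
    sample_ids = np.array(cols[4:], dtype=object)
    vals = df[cols[4:]]
    bad = vals.isna()
    if bad.any().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric/empty value for feature {df[id_c].iloc[i]!r} "
            f"sample {sample_ids[j]!r}")
    values = vals.to_numpy(dtype=float)
    fid = df[id_c].astype(str)
    parts = fid.str.split(":", expand=True)
    if parts.shape[1] >= 3:
        gene_id, cluster_id = parts[0], parts[0] + ":" + parts[1]
    else:
        gene_id, cluster_id = fid, None
    features = pd.DataFrame({
        "feature_id": fid,
        "gene_id": gene_id,
        "chrom": df[chrom_c].astype(str),
        "tss": df[start_c].astype(int) + 1,
        "strand": "+",
    })
    if cluster_id is not None:
        features["cluster_id"] = cluster_id
    return PhenotypeMatrix(features, values, sample_ids, value_kind=value_kind)


def write_phenotype_bed(pheno: PhenotypeMatrix, path) -> None:
    """Write the 0-based half-open BED-like phenotype table (round-trips read)."""
    f = pheno.features
    out = pd.DataFrame({
        "#chrom": f["chrom"],
        "start": f["tss"] - 1,
        "end": f["tss"],
        "feature_id": f["feature_id"],
    })
    vals = pd.DataFrame(pheno.values, columns=pheno.sample_ids)
    pd.concat([out.reset_index(drop=True), vals], axis=1).to_csv(
        path, sep="\t", index=False, float_format="%.10g")


def read_sample_table(path) -> SampleTable:
    return SampleTable(pd.read_csv(path, sep="\t", dtype={"batch": int}))


def write_sample_table(table: SampleTable, path) -> None:
    table.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# preparation
# ---------------------------------------------------------------------------

def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors against the geometric-mean pseudo-reference.

    Features with a zero in any sample are excluded from factor estimation
    (their geometric mean would vanish); factors are normalised to geometric
    mean 1 so a uniform library is all ones.
    """
    counts = np.asarray(counts, dtype=float)
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("sample with all-zero counts")
    nonzero = (counts > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError("no feature is nonzero in every sample")
    logc = np.log(counts[nonzero])
    ref = logc.mean(axis=1, keepdims=True)  # log geometric mean per feature
    sf = np.exp(np.median(logc - ref, axis=0))
    return sf / np.exp(np.mean(np.log(sf)))


def normalize_expression(counts: PhenotypeMatrix) -> PhenotypeMatrix:
    """Size-factor-normalise counts and move to ``log2(count/sf + 1)``."""
    if counts.value_kind != "counts":
        raise ValueError("normalize_expression expects raw counts")
    sf = size_factors(counts.values)
    values = np.log2(counts.values / sf[None, :] + 1.0)
    out = PhenotypeMatrix(counts.features.copy(), values, counts.sample_ids,
                          value_kind="normalized")
    out.size_factors = sf  # type: ignore[attr-defined]
    return out


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform per feature (rows).

    Uses ``Phi^{-1}((rank - 0.5)/n)`` with average ranks for ties; invariant to
    any strictly monotone transform of the input. Constant rows raise.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    out = np.empty_like(values)
    for i, row in enumerate(values):
        if np.unique(row).size < 2:
            raise ValueError(f"constant feature at row {i}: cannot rank-transform")
        ranks = stats.rankdata(row, method="average")
        out[i] = stats.norm.ppf((ranks - 0.5) / row.size)
    return out


def residualize(values: np.ndarray, covariates: CovariateMatrix) -> np.ndarray:
    """OLS residuals of each feature (row) on the covariates (with intercept)."""
    X = covariates.design()  # raises on rank deficiency
    Y = np.atleast_2d(np.asarray(values, dtype=float)).T  # samples x features
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return (Y - X @ beta).T


def expression_pcs(normalized: PhenotypeMatrix, n_pcs: int = 10) -> np.ndarray:
    """Top principal components of the normalized matrix (PCs x samples).

    Stand-in for hidden-factor correction: features are centred, PCs are the
    right singular vectors scaled to unit variance.
    """
    Y = normalized.values - normalized.values.mean(axis=1, keepdims=True)
    n_pcs = min(n_pcs, min(Y.shape) - 1)
    _, _, vt = np.linalg.svd(Y, full_matrices=False)
    pcs = vt[:n_pcs]
    return pcs / pcs.std(axis=1, keepdims=True)


def batch_sex_covariates(samples: SampleTable) -> CovariateMatrix:
    """Batch indicator (dropping one level) + sex indicator covariate block."""
    t = samples.table
    batches = np.sort(t["batch"].unique())
    rows, names = [], []
    for b in batches[1:]:
        rows.append((t["batch"] == b).to_numpy(float))
        names.append(f"batch_{b}")
    rows.append((t["sex"] == "M").to_numpy(float))
    names.append("sex_M")
    return CovariateMatrix(np.array(rows), names, t["sample_id"].to_numpy())


def prepare_phenotypes(
    counts: PhenotypeMatrix,
    samples: SampleTable,
    n_pcs: int = 0,
) -> tuple[np.ndarray, CovariateMatrix]:
    """Full preparation for QTL scanning.

    Normalise, inverse-normal transform per feature, then residualise against
    batch + sex (+ optional expression PCs). Returns the residual matrix and
    the covariate block used.
    """
    norm = normalize_expression(counts) if counts.value_kind == "counts" else counts
    Y = inverse_normal_transform(norm.values)
    cov = batch_sex_covariates(samples)
    if n_pcs > 0:
        pcs = expression_pcs(norm, n_pcs)
        cov = CovariateMatrix(
            np.vstack([cov.values, pcs]),
            cov.names + [f"PC{i+1}" for i in range(pcs.shape[0])],
            cov.sample_ids,
        )
    return residualize(Y, cov), cov
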