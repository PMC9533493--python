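"""SNP quality control and genomic relationship matrices.

The genomic relationship matrix (GRM) follows VanRaden's method 2: dosages
are column-centred at twice the allele frequency and each SNP is weighted by
the reciprocal of its expected heterozygosity, so every locus contributes
equally to relationships regardless of allele frequency,

    G = Z D Z',   Z = M - 2p,   D_jj = 1 / (m * 2 p_j (1 - p_j)).

Under Hardy-Weinberg equilibrium the diagonal of G averages ~1, off-diagonals
~0 for unrelated animals and ~0.25 for half sibs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class EmptyResultError(ValueError):
    """All rows/columns were removed by a filter."""


@dataclass
class GenotypeMatrix:
    """Animals x SNPs dosage matrix with 0/1/2 coding (NaN = missing)."""

    animal_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray  # float array, entries in {0,1,2} or NaN
    snp_info: pd.DataFrame | None = None  # chrom/pos/alleles, optional

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing (NaN)")
        if self.dosages.shape != (len(self.animal_ids), len(self.snp_ids)):
            raise ValueError("dosage shape does not match id lists")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.animal_ids, columns=self.snp_ids)


@dataclass
class Grm:
    """Symmetric genomic relationship matrix with the ridge used to ensure PD."""

    animal_ids: list[str]
    values: np.ndarray
    ridge_epsilon: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.animal_ids)
        if self.values.shape != (n, n):
            raise ValueError("GRM must be square over animal_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    def diagonal(self) -> np.ndarray:
        return np.diag(self.values).copy()

    def eigendecompose(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (ascending) and eigenvectors of the (ridged) GRM."""
        vals, vecs = np.linalg.eigh(self.values)
        return vals, vecs

    def reorder(self, animal_ids: list[str]) -> "Grm":
        idx = [self.animal_ids.index(a) for a in animal_ids]
        return Grm(list(animal_ids), self.values[np.ix_(idx, idx)], self.ridge_epsilon)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.animal_ids, columns=self.animal_ids)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "Grm":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy())


@dataclass
class QcReport:
    n_snps_in: int
    n_snps_out: int
    removed_call_rate: int
    removed_hwe: int
    removed_maf: int
    n_animals_in: int
    n_animals_out: int
    removed_animals: list[str] = field(default_factory=list)
    mean_imputed: bool = False

    def __str__(self) -> str:  # human readable QC summary
        return (
            f"SNPs: {self.n_snps_in} -> {self.n_snps_out} "
            f"(call rate {self.removed_call_rate}, HWE {self.removed_hwe}, "
            f"MAF {self.removed_maf}); animals: {self.n_animals_in} -> "
            f"{self.n_animals_out}"
        )


def hwe_chisq(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, float]:
    """One-df chi-square test for Hardy-Weinberg proportions.

    Expected genotype counts come from the estimated allele frequency.
    Monomorphic SNPs return statistic 0 (they carry no HWE information and
    are removed by the MAF filter anyway).
    """
    n = n_aa + n_ab + n_bb
    if n <= 0:
        raise ValueError("no genotyped animals")
    p = (2 * n_aa + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        return 0.0, 1.0
    expected = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    pval = float(stats.chi2.sf(chi2, df=1))
    return chi2, pval


def _hwe_chisq_vectorized(dosages: np.ndarray) -> np.ndarray:
    """HWE chi-square per SNP column (missing entries ignored)."""
    obs = np.stack(
        [np.nansum(dosages == d, axis=0) for d in (2.0, 1.0, 0.0)], axis=0
    ).astype(float)
    n = obs.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (2 * obs[0] + obs[1]) / (2 * n)
        exp = np.stack([n * p**2, 2 * n * p * (1 - p), n * (1 - p) ** 2], axis=0)
        chi2 = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0).sum(
            axis=0
        )
    mono = (p <= 0) | (p >= 1) | (n == 0)
    chi2 = np.where(mono, 0.0, chi2)
    return chi2


def qc_filter(
    geno: GenotypeMatrix,
    snp_call_rate: float = 0.95,
    hwe_p_cut: float = 1e-8,
    maf_cut: float = 0.05,
    animal_call_rate: float = 0.90,
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove SNPs failing call-rate / HWE / MAF criteria, then low-call animals.

    SNP filters are applied jointly on the input matrix; the animal call-rate
    filter runs afterwards on the retained SNPs.
    """
    for thr in (snp_call_rate, hwe_p_cut, maf_cut, animal_call_rate):
        if not 0.0 <= thr <= 1.0:
            raise ValueError("QC thresholds must lie in [0, 1]")
    d = geno.dosages
    observed = ~np.isnan(d)
    call = observed.mean(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(d, axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    chi2 = _hwe_chisq_vectorized(d)
    hwe_p = stats.chi2.sf(chi2, df=1)

    fail_call = call < snp_call_rate
    fail_hwe = hwe_p < hwe_p_cut
    fail_maf = maf < maf_cut
    keep_snp = ~(fail_call | fail_hwe | fail_maf)
    if not keep_snp.any():
        raise EmptyResultError("all SNPs removed by QC")

    d2 = d[:, keep_snp]
    animal_call = (~np.isnan(d2)).mean(axis=1)
    keep_animal = animal_call >= animal_call_rate
    if not keep_animal.any():
        raise EmptyResultError("all animals removed by QC")

    removed_animals = [a for a, k in zip(geno.animal_ids, keep_animal) if not k]
    out = GenotypeMatrix(
        [a for a, k in zip(geno.animal_ids, keep_animal) if k],
        [s for s, k in zip(geno.snp_ids, keep_snp) if k],
        d2[keep_animal],
        geno.snp_info.loc[keep_snp].reset_index(drop=True)
        if geno.snp_info is not None
        else None,
    )
    report = QcReport(
        n_snps_in=geno.n_snps,
        n_snps_out=out.n_snps,
        removed_call_rate=int(fail_call.sum()),
        removed_hwe=int(fail_hwe.sum()),
        removed_maf=int(fail_maf.sum()),
        n_animals_in=geno.n_animals,
        n_animals_out=out.n_animals,
        removed_animals=removed_animals,
    )
    return out, report


def mean_impute(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Fill missing dosages with the per-SNP mean (kept fractional)."""
    d = geno.dosages.copy()
    if np.isnan(d).any():
        col_mean = np.nanmean(d, axis=0)
        idx = np.where(np.isnan(d))
        d[idx] = col_mean[idx[1]]
    g = GenotypeMatrix.__new__(GenotypeMatrix)  # bypass 0/1/2 check for imputed values
    g.animal_ids = list(geno.animal_ids)
    g.snp_ids = list(geno.snp_ids)
    g.dosages = d
    g.snp_info = geno.snp_info
    return g


def compute_grm_vanraden2(geno: GenotypeMatrix, ridge_epsilon: float = 1e-6) -> Grm:
    """VanRaden method-2 GRM from a complete dosage matrix.

    Missing dosages must be imputed first (`mean_impute`); monomorphic SNPs
    are rejected because their weight 1/(2 p (1-p)) is undefined.
    """
    d = geno.dosages
    if np.isnan(d).any():
        raise ValueError("missing dosages present; run mean_impute first")
    p = d.mean(axis=0) / 2.0
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("monomorphic SNPs present; filter before computing the GRM")
    z = d - 2 * p
    m = d.shape[1]
    weights = 1.0 / (m * 2 * p * (1 - p))
    g = (z * weights) @ z.T
    g = (g + g.T) / 2.0
    if ridge_epsilon:
        g = g + ridge_epsilon * np.eye(g.shape[0])
    return Grm(list(geno.animal_ids), g, ridge_epsilon)


# ---------------------------------------------------------------------------
# I/O

def read_dosage_tsv(path) -> GenotypeMatrix:
    """Read an animals x SNPs dosage TSV (row index = animal ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GenotypeMatrix(
        list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(float)
    )


def write_dosage_tsv(geno: GenotypeMatrix, path) -> None:
    geno.to_frame().to_csv(path, sep="\t")


def read_vcf(path) -> GenotypeMatrix:
    """Read diploid GT calls from a VCF into a dosage matrix (ALT-allele count)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    animal_ids = list(vcf.samples)
    snp_ids: list[str] = []
    rows: list[np.ndarray] = []
    info: list[tuple] = []
    for var in vcf:
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        info.append((var.CHROM, var.POS, var.REF, var.ALT[0] if var.ALT else "."))
        gts = np.asarray(var.gt_types, dtype=float)  # 0=hom ref,1=het,2=unknown,3=hom alt
        dos = np.select([gts == 0, gts == 1, gts == 3], [0.0, 1.0, 2.0], default=np.nan)
        rows.append(dos)
    dosages = np.vstack(rows).T if rows else np.empty((len(animal_ids), 0))
    snp_info = pd.DataFrame(info, columns=["chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(animal_ids, snp_ids, dosages, snp_info)


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write dosages as an unphased-GT VCF (synthetic chrom/pos if unknown)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.animal_ids)
            + "\n"
        )
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, snp in enumerate(geno.snp_ids):
            if geno.snp_info is not None:
                chrom = geno.snp_info.iloc[j]["chrom"]
                pos = geno.snp_info.iloc[j]["pos"]
                ref = geno.snp_info.iloc[j]["ref"]
                alt = geno.snp_info.iloc[j]["alt"]
            else:
                chrom, pos, ref, alt = "1", j + 1, "A", "B"
            gts = [
                "./." if np.isnan(v) else gt_map[v] for v in geno.dosages[:, j]
            ]
            fh.write(
                f"{chrom}\t{pos}\t{snp}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
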