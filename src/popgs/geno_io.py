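"""Genotype and phenotype input/output plus resequencing-style quality control.

The QC contract mirrors standard short-read resequencing practice for a
hybrid breeding population: bi-allelic SNPs only, then per-marker filters
applied in a fixed order — call rate, minor allele frequency, and a
Hardy–Weinberg equilibrium test — followed by simple mean or mode
imputation of the surviving missing genotypes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from scipy import stats
from scipy.special import gammaln

from popgs.genotypes import MISSING, GenotypeMatrix
from popgs.pedigree import Pedigree  # noqa: F401  (re-exported I/O surface)

log = logging.getLogger(__name__)


class QCError(ValueError):
    pass


# ----------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------

def read_vcf(path, region: tuple[str, int, int] | None = None,
             min_gq: float | None = None) -> tuple[GenotypeMatrix, dict]:
    """Read bi-allelic SNPs from a VCF into a dosage matrix.

    Multi-allelic and non-SNP records are skipped and counted.  Returns the
    matrix and a dict of skip counts (``non_biallelic``, ``non_snp``).

    ``region`` is an optional ``(chrom, start, end)`` filter, 1-based
    inclusive on both ends.
    """
    vcf = VCF(str(path), gts012=True)
    samples = np.asarray(vcf.samples, dtype=object)
    rows, chroms, poss, refs, alts = [], [], [], [], []
    skipped = {"non_biallelic": 0, "non_snp": 0}
    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped["non_biallelic"] += 1
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            skipped["non_snp"] += 1
            continue
        if region is not None:
            chrom, start, end = region
            if rec.CHROM != chrom or not (start <= rec.POS <= end):
                continue
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt (gts012), 3=unknown
        g = np.asarray(rec.gt_types, dtype=np.int8)
        dos = np.where(g == 3, MISSING, g).astype(np.int8)
        rows.append(dos)
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
    vcf.close()
    if not rows:
        raise QCError("no bi-allelic SNP records found")
    markers = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    dosages = np.vstack(rows).T
    order = markers.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
    return GenotypeMatrix(dosages[:, order], samples, markers.iloc[order]), skipped


def write_vcf(g: GenotypeMatrix, path, phased: bool | None = None) -> None:
    """Write a GenotypeMatrix as VCF v4.2 (GT only).

    Simulated data with retained haplotypes is written phased (``|``);
    otherwise genotypes are unphased heterozygote-ambiguous ``0/1`` calls.
    """
    if phased is None:
        phased = g.haplotypes is not None
    sep = "|" if phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in g.markers["chrom"].unique():
            last = g.markers.loc[g.markers["chrom"] == chrom, "pos"].max()
            fh.write(f"##contig=<ID={chrom},length={int(last) + 1}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(map(str, g.sample_ids)) + "\n")
        ids = g.marker_ids()
        for j in range(g.n_markers):
            row = g.markers.iloc[j]
            if phased and g.haplotypes is not None:
                a, b = g.haplotypes[0::2, j], g.haplotypes[1::2, j]
                gts = [f"{x}{sep}{y}" for x, y in zip(a, b)]
            else:
                lut = {0: f"0{sep}0", 1: f"0{sep}1", 2: f"1{sep}1", MISSING: "./."}
                gts = [lut[int(d)] for d in g.dosages[:, j]]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{ids[j]}\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ----------------------------------------------------------------------
# Hardy–Weinberg
# ----------------------------------------------------------------------

def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy–Weinberg test P-value (two-sided, SNP-HWE style).

    Sums the probabilities of all heterozygote counts compatible with the
    observed allele counts that are no more probable than the observed one.
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom1, n_hom2) + n_het
    # log-probability of each possible het count with the same parity as rare
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(homr + 1)
        - gammaln(homc + 1)
        + hets * np.log(2.0)
        + gammaln(rare + 1)
        + gammaln(2 * n - rare + 1)
        - gammaln(2 * n + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = prob[hets == n_het]
    if obs.size == 0:  # parity mismatch cannot happen with valid counts
        return 1.0
    return float(min(1.0, prob[prob <= obs[0] + 1e-12].sum()))


def hwe_chi2_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """One-degree-of-freedom chi-square HWE test (large samples)."""
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    p = (2 * n_hom2 + n_het) / (2 * n)
    q = 1.0 - p
    exp = np.array([n * q * q, 2 * n * p * q, n * p * p])
    obs = np.array([n_hom1, n_het, n_hom2], dtype=float)
    keep = exp > 0
    chi2 = ((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum()
    return float(stats.chi2.sf(chi2, df=1))


def hwe_pvalues(g: GenotypeMatrix, exact_max_n: int = 1000) -> np.ndarray:
    """Per-marker HWE P: exact test below ``exact_max_n`` samples, else χ²."""
    d = g.dosages
    valid = d != MISSING
    pvals = np.ones(g.n_markers)
    for j in range(g.n_markers):
        col = d[valid[:, j], j]
        n_hom1 = int((col == 0).sum())
        n_het = int((col == 1).sum())
        n_hom2 = int((col == 2).sum())
        n = n_hom1 + n_het + n_hom2
        if n == 0:
            continue
        if n < exact_max_n:
            pvals[j] = hwe_exact_p(n_het, n_hom1, n_hom2)
        else:
            pvals[j] = hwe_chi2_p(n_het, n_hom1, n_hom2)
    return pvals


# ----------------------------------------------------------------------
# QC
# ----------------------------------------------------------------------

@dataclass
class QCReport:
    """Accounting of markers removed per filter, in application order."""

    n_input: int
    removed_callrate: int = 0
    removed_maf: int = 0
    removed_hwe: int = 0
    n_retained: int = 0
    thresholds: dict = field(default_factory=dict)
    skipped_records: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = self.removed_callrate + self.removed_maf + self.removed_hwe
        if self.n_retained and total + self.n_retained != self.n_input:
            raise QCError("QC accounting does not sum to the input marker count")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def apply_qc(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    max_missing: float = 0.02,
    hwe_alpha: float = 1e-6,
) -> tuple[GenotypeMatrix, QCReport]:
    """Marker filters in fixed order: call rate → MAF → HWE.

    * markers with missing fraction > ``max_missing`` removed;
    * then markers with MAF < ``maf_min`` removed (monomorphic markers have
      MAF 0 and always fail);
    * then markers with HWE test P < ``hwe_alpha`` removed.
    """
    n_input = g.n_markers
    keep = np.ones(n_input, dtype=bool)

    miss = g.missing_fraction()
    fail_cr = miss > max_missing
    keep &= ~fail_cr

    maf = g.maf()
    fail_maf = keep & (np.nan_to_num(maf, nan=0.0) < maf_min)
    keep &= ~fail_maf

    sub = g.take_markers(np.where(keep)[0])
    hwe_p = hwe_pvalues(sub)
    fail_hwe_local = hwe_p < hwe_alpha
    kept_idx = np.where(keep)[0]
    keep[kept_idx[fail_hwe_local]] = False

    if not keep.any():
        raise QCError("quality control removed every marker")
    report = QCReport(
        n_input=n_input,
        removed_callrate=int(fail_cr.sum()),
        removed_maf=int(fail_maf.sum()),
        removed_hwe=int(fail_hwe_local.sum()),
        n_retained=int(keep.sum()),
        thresholds={"maf_min": maf_min, "max_missing": max_missing, "hwe_alpha": hwe_alpha},
    )
    return g.take_markers(np.where(keep)[0]), report


def impute_missing(g: GenotypeMatrix, method: str = "mean") -> GenotypeMatrix:
    """Fill missing genotypes per marker.

    ``mean`` fills the expected dosage ``2p_j`` — a real number, so the
    result carries float dosages (used only in numeric matrices downstream);
    ``mode`` fills the most frequent observed dosage and keeps the matrix
    integer-valued.
    """
    mask = g.missing_mask()
    if not mask.any():
        return g
    if (~mask).sum(axis=0).min() < 2:
        raise QCError("a marker has fewer than 2 observed genotypes")
    if method == "mode":
        filled = g.dosages.copy()
        for j in np.where(mask.any(axis=0))[0]:
            col = g.dosages[~mask[:, j], j]
            counts = np.bincount(col, minlength=3)
            filled[mask[:, j], j] = int(np.argmax(counts))
        log.info("mode-imputed %d genotypes", int(mask.sum()))
        return GenotypeMatrix(filled, g.sample_ids, g.markers)
    if method == "mean":
        filled = g.dosage_float(impute_mean=True)
        log.info("mean-imputed %d genotypes", int(mask.sum()))
        return GenotypeMatrix(filled, g.sample_ids, g.markers)
    raise ValueError(f"unknown imputation method {method!r}")


def impute_mean_matrix(g: GenotypeMatrix) -> np.ndarray:
    """Float dosage matrix with missing entries set to the marker mean 2p."""
    return g.dosage_float(impute_mean=True)


# ----------------------------------------------------------------------
# phenotypes
# ----------------------------------------------------------------------

def read_phenotypes(path) -> pd.DataFrame:
    ph = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in ph.columns:
        raise ValueError("phenotype table must have an 'id' column")
    return ph


def write_phenotypes(ph: pd.DataFrame, path) -> None:
    ph.to_csv(path, sep="\t", index=False)


def trait_summary(ph: pd.DataFrame) -> pd.DataFrame:
    """Per-trait mean, sample SD, extrema, CV% and a Shapiro normality P.

    CV% = 100·sd/mean (sample n−1 SD), the convention used for positive
    growth and wood-property traits.
    """
    rows = []
    for trait in ph.columns:
        if trait == "id":
            continue
        x = ph[trait].dropna().to_numpy(dtype=float)
        if len(x) < 3:
            raise ValueError(f"trait {trait!r}: need at least 3 non-missing values")
        mean = x.mean()
        sd = x.std(ddof=1)
        cv = 100.0 * sd / mean if mean != 0 else np.nan
        if sd == 0:
            cv, shap_p = 0.0, np.nan
        else:
            shap_p = stats.shapiro(x if len(x) <= 5000 else x[:5000]).pvalue
        rows.append(
            {
                "trait": trait,
                "mean": mean,
                "sd": sd,
                "max": x.max(),
                "min": x.min(),
                "cv_pct": cv,
                "normality_p": shap_p,
                "n": len(x),
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# GFF3 gene models
# ----------------------------------------------------------------------

def read_gff_genes(path) -> pd.DataFrame:
    """Gene features from a GFF3 file: seqid, start, end, strand, gene_id.

    Only ``gene`` features are kept; coordinates stay 1-based inclusive.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID", attrs.get("Name", f"{parts[0]}:{parts[3]}"))
            rows.append(
                {
                    "gene_id": gene_id,
                    "chrom": parts[0],
                    "start": int(parts[3]),
                    "end": int(parts[4]),
                    "strand": parts[6],
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
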