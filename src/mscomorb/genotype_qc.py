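"""Genotype quality control and ancestry principal components.

Implements the standard array-QC cascade used before and after genotype
imputation: per-sample filters (duplicates, heterozygosity outliers, call
rate, sex discrepancy, PC outliers), per-variant filters (call rate >= 90%,
MAF >= 0.01, Hardy-Weinberg p >= 1e-6), the post-imputation filter
(imputation R2 >= 0.6, MAF >= 0.001), conversion of imputed dosages to
best-guess genotypes, and principal components on the
sqrt(2p(1-p))-standardized genotype matrix for ancestry covariates and
outlier removal.

Genotypes travel as a :class:`GenotypeMatrix`: a samples x variants dosage
array (NaN = missing) with variant and sample metadata, read from / written
to VCF (FORMAT ``GT``/``DS``, INFO ``R2``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats as st

__all__ = [
    "GenotypeMatrix",
    "QcReport",
    "dosage_to_best_guess",
    "hwe_test",
    "sample_qc",
    "snp_qc",
    "post_imputation_filter",
    "compute_pcs",
]

VARIANT_COLUMNS = ("variant_id", "chrom", "pos", "ref", "alt", "r2", "is_hla")


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with metadata.

    ``dosages``: float array, shape (n_samples, n_variants), entries in
    [0, 2] on the ALT-allele scale or NaN for missing.
    ``variants``: DataFrame with columns ``variant_id, chrom, pos, ref,
    alt, r2, is_hla``.  ``samples``: DataFrame with ``sample_id`` and
    optionally ``reported_sex``.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.dosages < 0) | (self.dosages > 2))
        if bad:
            raise ValueError("dosages must lie in [0, 2] (or NaN for missing)")
        if self.variants["variant_id"].duplicated().any():
            raise ValueError("variant ids must be unique")
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def best_guess(self) -> np.ndarray:
        """Best-guess genotype array (float; NaN preserved for missing)."""
        return dosage_to_best_guess(self.dosages)

    def alt_freq(self) -> np.ndarray:
        """Per-variant ALT-allele frequency from best-guess genotypes."""
        g = self.best_guess()
        return np.nanmean(g, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def variant_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def het_rate(self) -> np.ndarray:
        """Per-sample heterozygosity among observed best-guess genotypes."""
        g = self.best_guess()
        obs = ~np.isnan(g)
        n_obs = obs.sum(axis=1)
        het = np.nansum(g == 1.0, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, het / n_obs, np.nan)

    def take_samples(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages[mask],
            variants=self.variants.copy(),
            samples=self.samples.loc[mask].copy(),
        )

    def take_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages[:, mask],
            variants=self.variants.loc[mask].copy(),
            samples=self.samples.copy(),
        )

    def dosage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages,
            index=self.samples["sample_id"].to_numpy(),
            columns=self.variants["variant_id"].to_numpy(),
        )

    # -- VCF round trip -----------------------------------------------------

    def to_vcf(self, path) -> None:
        """Write a plain-text VCF 4.2 with GT:DS genotypes and INFO R2."""
        lines = [
            "##fileformat=VCFv4.2",
            '##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality">',
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Best-guess genotype">',
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="ALT dosage">',
        ]
        for chrom in pd.unique(self.variants["chrom"].astype(str)):
            lines.append(f"##contig=<ID={chrom}>")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        header += list(self.samples["sample_id"].astype(str))
        lines.append("\t".join(header))

        g = self.best_guess()
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        order = np.lexsort(
            (self.variants["pos"].to_numpy(), self.variants["chrom"].astype(str).to_numpy())
        )
        for j in order:
            v = self.variants.iloc[j]
            fields = [
                str(v["chrom"]),
                str(int(v["pos"])),
                str(v["variant_id"]),
                str(v["ref"]),
                str(v["alt"]),
                ".",
                "PASS",
                f"R2={float(v['r2']):.4f}",
                "GT:DS",
            ]
            col = self.dosages[:, j]
            gcol = g[:, j]
            for i in range(len(col)):
                if np.isnan(col[i]):
                    fields.append("./.:.")
                else:
                    fields.append(f"{gt_map[gcol[i]]}:{col[i]:.3f}")
            lines.append("\t".join(fields))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_vcf(cls, path, reported_sex=None) -> "GenotypeMatrix":
        """Read GT/DS genotypes via cyvcf2; DS preferred, GT as fallback."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        sample_ids = list(vcf.samples)
        rows, cols = [], []
        for variant in vcf:
            ds = None
            try:
                ds = variant.format("DS")
            except KeyError:
                ds = None
            if ds is not None:
                col = np.asarray(ds, dtype=float).reshape(-1)
                col = np.where((col < -1) | (col > 2.5), np.nan, col)
            else:
                # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
                gt = np.asarray(variant.gt_types, dtype=float)
                col = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
            r2 = variant.INFO.get("R2")
            rows.append(
                {
                    "variant_id": variant.ID or f"{variant.CHROM}:{variant.POS}",
                    "chrom": str(variant.CHROM),
                    "pos": int(variant.POS),
                    "ref": variant.REF,
                    "alt": variant.ALT[0] if variant.ALT else ".",
                    "r2": float(r2) if r2 is not None else 1.0,
                    "is_hla": str(variant.ID or "").startswith("HLA"),
                }
            )
            cols.append(np.clip(col, 0.0, 2.0))
        samples = pd.DataFrame({"sample_id": sample_ids})
        if reported_sex is not None:
            samples["reported_sex"] = [reported_sex.get(s) for s in sample_ids]
        return cls(
            dosages=np.column_stack(cols) if cols else np.empty((len(sample_ids), 0)),
            variants=pd.DataFrame(rows, columns=list(VARIANT_COLUMNS)),
            samples=samples,
        )


@dataclass
class QcReport:
    """Ordered record of applied filters with tested/removed counts."""

    steps: list = field(default_factory=list)

    def add(self, name: str, axis: str, n_tested: int, n_removed: int, threshold, removed_ids=None):
        self.steps.append(
            {
                "filter": name,
                "axis": axis,
                "n_tested": int(n_tested),
                "n_removed": int(n_removed),
                "threshold": threshold,
                "removed_ids": sorted(map(str, removed_ids)) if removed_ids is not None else [],
            }
        )

    def total_removed(self, axis: str) -> int:
        return sum(s["n_removed"] for s in self.steps if s["axis"] == axis)

    def removed_ids(self, axis: str | None = None) -> list:
        return [
            i
            for s in self.steps
            if axis is None or s["axis"] == axis
            for i in s["removed_ids"]
        ]

    def to_json(self, path=None) -> str:
        text = json.dumps({"steps": self.steps}, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def dosage_to_best_guess(dosage) -> np.ndarray:
    """Round dosages to the nearest genotype in {0, 1, 2}.

    Exact .5 ties resolve toward the heterozygote (0.5 -> 1, 1.5 -> 1),
    a deterministic convention; NaN stays NaN.
    """
    x = np.asarray(dosage, dtype=float)
    g = np.floor(x + 0.5)
    tie = np.mod(x, 1.0) == 0.5
    g = np.where(tie, 1.0, g)
    return np.clip(g, 0.0, 2.0)


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Hardy-Weinberg chi-square goodness-of-fit p-value (1 df).

    Expected genotype counts p^2 N, 2pq N, q^2 N from the observed allele
    frequency; symmetric in the homozygote labels.  A monomorphic sample
    fits equilibrium trivially (p-value 1).
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("total genotype count is zero")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(st.chi2.sf(chi2, df=1))


def _hwe_pvalues(matrix: GenotypeMatrix) -> np.ndarray:
    g = matrix.best_guess()
    out = np.ones(matrix.n_variants)
    for j in range(matrix.n_variants):
        col = g[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            out[j] = np.nan
            continue
        out[j] = hwe_test(int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
    return out


def compute_pcs(matrix: GenotypeMatrix, k: int = 3):
    """Principal components of the standardized genotype matrix.

    Each variant is centered at 2p and scaled by sqrt(2p(1-p)), the
    variance of a binomial allele count — the conventional genotype
    standardization for ancestry PCA.  Missing entries are mean-imputed
    (zero after centering); monomorphic variants carry no information and
    are dropped.  The sign of each component is fixed by making its
    largest-magnitude variant loading positive.

    Returns ``(coords, explained_variance_ratio)`` with ``coords`` of
    shape (n_samples, k).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > min(matrix.n_samples, matrix.n_variants):
        raise ValueError(
            f"k={k} exceeds min(n_samples, n_variants)="
            f"{min(matrix.n_samples, matrix.n_variants)}"
        )
    g = matrix.best_guess()
    p = np.nanmean(g, axis=0) / 2.0
    keep = (p > 0.0) & (p < 1.0) & ~np.isnan(p)
    g = g[:, keep]
    p = p[keep]
    if g.shape[1] == 0:
        return np.zeros((matrix.n_samples, k)), np.zeros(k)
    z = (g - 2 * p) / np.sqrt(2 * p * (1 - p))
    z = np.where(np.isnan(z), 0.0, z)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    kk = min(k, s.size)
    coords = np.zeros((matrix.n_samples, k))
    coords[:, :kk] = u[:, :kk] * s[:kk]
    for j in range(kk):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            coords[:, j] = -coords[:, j]
    var = s**2
    evr = np.zeros(k)
    if var.sum() > 0:
        evr[:kk] = var[:kk] / var.sum()
    return coords, evr


def _duplicate_mask(matrix: GenotypeMatrix, threshold: float) -> np.ndarray:
    """True for samples to drop as duplicates (later member of each pair)."""
    g = matrix.best_guess()
    obs = ~np.isnan(g)
    obs_f = obs.astype(float)
    both = obs_f @ obs_f.T
    match = np.zeros_like(both)
    for geno in (0.0, 1.0, 2.0):
        a = ((g == geno) & obs).astype(float)
        match += a @ a.T
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(both > 0, match / both, 0.0)
    n = matrix.n_samples
    drop = np.zeros(n, dtype=bool)
    for i in range(n):
        if drop[i]:
            continue
        dups = np.flatnonzero((prop[i] > threshold) & (np.arange(n) > i))
        drop[dups] = True
    return drop


def sample_qc(
    matrix: GenotypeMatrix,
    pcs: np.ndarray | None = None,
    *,
    duplicate_threshold: float = 0.95,
    het_sd: float = 3.0,
    call_rate_threshold: float = 0.95,
    pc_sd: float = 3.0,
    n_pcs: int = 3,
):
    """Per-sample QC cascade.

    Filters, in order, each recomputed on the survivors of the previous:
    duplicate pairs (identity proportion > ``duplicate_threshold``; the
    first of each pair is kept), heterozygosity outliers (> ``het_sd`` SD
    from the mean), low call rate (< ``call_rate_threshold``), sex
    discrepancies (only when X-chromosome variants and reported sex are
    both present), and PC outliers (> ``pc_sd`` SD on any of the first
    ``n_pcs`` components).  The two SD-based filters trim iteratively,
    re-estimating mean and SD on the survivors until no sample is beyond
    the threshold, so the cascade is a fixed point of itself
    (re-running it removes nothing).  ``pcs`` may supply externally
    computed coordinates aligned with ``matrix.samples``; otherwise PCs
    are computed on the surviving samples.

    Returns ``(filtered_matrix, QcReport)``.
    """
    if matrix.n_samples < 3:
        raise ValueError("sample QC needs at least 3 samples (SD undefined otherwise)")
    report = QcReport()
    current = matrix
    pc_current = np.asarray(pcs, dtype=float) if pcs is not None else None

    def apply(name, drop_mask, threshold):
        nonlocal current, pc_current
        ids = current.samples["sample_id"].to_numpy()[drop_mask]
        report.add(name, "samples", current.n_samples, int(drop_mask.sum()), threshold, ids)
        if drop_mask.any():
            current = current.take_samples(~drop_mask)
            if pc_current is not None:
                pc_current = pc_current[~drop_mask]

    apply("duplicates", _duplicate_mask(current, duplicate_threshold), duplicate_threshold)

    def autosomal_het(m):
        # X heterozygosity is sex-dependent; the outlier filter is autosomal
        auto = ~m.variants["chrom"].astype(str).isin(["X", "23", "chrX"]).to_numpy()
        return m.take_variants(auto).het_rate() if (~auto).any() else m.het_rate()

    n_before, removed_het = current.n_samples, []
    while current.n_samples >= 3:
        het = autosomal_het(current)
        mu, sd = np.nanmean(het), np.nanstd(het)
        drop = np.abs(het - mu) > het_sd * sd if sd > 0 else np.zeros(current.n_samples, bool)
        if not drop.any():
            break
        removed_het.extend(current.samples["sample_id"].to_numpy()[drop])
        current = current.take_samples(~drop)
        if pc_current is not None:
            pc_current = pc_current[~drop]
    report.add(
        "heterozygosity", "samples", n_before, len(removed_het),
        f"> {het_sd} SD from mean (iterated)", removed_het,
    )

    cr = current.sample_call_rate()
    apply("call_rate", cr < call_rate_threshold, call_rate_threshold)

    x_mask = current.variants["chrom"].astype(str).isin(["X", "23", "chrX"]).to_numpy()
    if x_mask.any() and "reported_sex" in current.samples.columns:
        gx = current.best_guess()[:, x_mask]
        obs = ~np.isnan(gx)
        n_obs = obs.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            xhet = np.where(n_obs > 0, np.nansum(gx == 1.0, axis=1) / n_obs, np.nan)
        inferred_female = xhet > 0.02
        reported_female = (current.samples["reported_sex"] == "female").to_numpy()
        drop = (inferred_female != reported_female) & ~np.isnan(xhet)
        apply("sex_check", drop, "X heterozygosity vs reported sex")

    recompute = pc_current is None
    n_before, removed_pc = current.n_samples, []
    while current.n_samples >= 3:
        if recompute:
            k = max(min(n_pcs, current.n_samples - 1, current.n_variants), 1)
            pc_current, _ = compute_pcs(current, k=k)
        dims = min(n_pcs, pc_current.shape[1])
        drop = np.zeros(current.n_samples, dtype=bool)
        for j in range(dims):
            col = pc_current[:, j]
            sd = col.std()
            if sd > 0:
                drop |= np.abs(col - col.mean()) > pc_sd * sd
        if not drop.any():
            break
        removed_pc.extend(current.samples["sample_id"].to_numpy()[drop])
        current = current.take_samples(~drop)
        pc_current = pc_current[~drop]
    report.add(
        "pc_outliers", "samples", n_before, len(removed_pc),
        f"> {pc_sd} SD on any of first {n_pcs} PCs (iterated)", removed_pc,
    )
    return current, report


def snp_qc(
    matrix: GenotypeMatrix,
    *,
    call_rate_threshold: float = 0.90,
    maf_threshold: float = 0.01,
    hwe_threshold: float = 1e-6,
):
    """Per-variant QC: call rate >= 90%, MAF >= 1%, HWE p >= 1e-6.

    Filters applied in that order, each recomputed on survivors; MAF and
    HWE use best-guess genotypes.  Returns ``(filtered_matrix, QcReport)``.
    """
    report = QcReport()
    current = matrix

    def apply(name, keep_mask, threshold):
        nonlocal current
        drop = ~keep_mask
        ids = current.variants["variant_id"].to_numpy()[drop]
        report.add(name, "variants", current.n_variants, int(drop.sum()), threshold, ids)
        if drop.any():
            current = current.take_variants(keep_mask)

    apply("variant_call_rate", current.variant_call_rate() >= call_rate_threshold, call_rate_threshold)
    apply("maf", current.maf() >= maf_threshold, maf_threshold)
    pvals = _hwe_pvalues(current)
    apply("hwe", np.isnan(pvals) | (pvals >= hwe_threshold), hwe_threshold)
    return current, report


def post_imputation_filter(
    matrix: GenotypeMatrix,
    *,
    r2_threshold: float = 0.6,
    maf_threshold: float = 0.001,
):
    """Post-imputation variant filter: drop R2 < 0.6 or MAF < 0.001.

    Thresholds are strict 'less-than' removals: a variant at exactly
    R2 = 0.6 or MAF = 0.001 is retained.
    """
    report = QcReport()
    r2 = matrix.variants["r2"].to_numpy(dtype=float)
    keep = r2 >= r2_threshold
    report.add(
        "imputation_r2",
        "variants",
        matrix.n_variants,
        int((~keep).sum()),
        r2_threshold,
        matrix.variants["variant_id"].to_numpy()[~keep],
    )
    current = matrix.take_variants(keep) if (~keep).any() else matrix
    keep2 = current.maf() >= maf_threshold
    report.add(
        "maf",
        "variants",
        current.n_variants,
        int((~keep2).sum()),
        maf_threshold,
        current.variants["variant_id"].to_numpy()[~keep2],
    )
    if (~keep2).any():
        current = current.take_variants(keep2)
    return current, report
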