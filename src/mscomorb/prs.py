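"""Cumulative autoimmune-comorbidity polygenic risk scores.

Nine disease-specific unweighted PRSs (MS plus eight autoimmune
diseases) are computed as risk-allele counts over each disease's
GWAS-significant non-HLA variant panel, normalized by the maximum
achievable score (2 x number of variants) so every disease contributes
on a [0, 1] scale, and summed into the cumulative score ``PRS_comorb``
in [0, 9].  ``PRS_comorb_HLA`` additionally folds each disease's
classical HLA-allele burden into the disease score before
renormalization (denominator 2 x (n_snps + n_hla)).

Group comparison between MS subjects with and without autoimmune
comorbidity is by ANCOVA: ordinary least squares of the score on the
group indicator with age, sex and the first three ancestry PCs as
covariates; the reduced model without sex is fitted alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genotype_qc import GenotypeMatrix

__all__ = [
    "VariantPanel",
    "HlaPanel",
    "disease_raw_score",
    "disease_raw_scores",
    "normalize_score",
    "cumulative_prs",
    "hla_augmented_scores",
    "compute_profiles",
    "compare_groups",
    "AncovaResult",
    "plot_prs_distribution",
    "load_variant_panels",
    "save_variant_panels",
    "load_hla_panels",
    "save_hla_panels",
]


@dataclass(frozen=True)
class VariantPanel:
    """Non-HLA risk-variant panel for one disease.

    ``entries`` is a tuple of (variant_id, risk_allele) pairs, all at
    genome-wide significance (p < 5e-8) in the source GWAS.
    """

    disease: str
    entries: tuple
    gwas_threshold: float = 5e-8

    def __post_init__(self):
        ids = [vid for vid, _ in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate variant ids in {self.disease} panel")

    @property
    def n_snps(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class HlaPanel:
    """Classical HLA alleles for one disease, treated as diallelic carrier loci."""

    disease: str
    alleles: tuple

    def __post_init__(self):
        if len(self.alleles) != len(set(self.alleles)):
            raise ValueError(f"duplicate HLA alleles in {self.disease} panel")

    @property
    def n_hla(self) -> int:
        return len(self.alleles)


def _risk_dosage_columns(matrix: GenotypeMatrix, panel: VariantPanel) -> np.ndarray:
    """Best-guess risk-allele counts, samples x panel variants (NaN missing)."""
    meta = matrix.variants.set_index("variant_id")
    g = matrix.best_guess()
    col_index = {v: i for i, v in enumerate(matrix.variants["variant_id"])}
    cols = []
    for vid, risk in panel.entries:
        if vid not in col_index:
            cols.append(np.full(matrix.n_samples, np.nan))
            continue
        ref, alt = meta.loc[vid, "ref"], meta.loc[vid, "alt"]
        col = g[:, col_index[vid]]
        if risk == alt:
            cols.append(col)
        elif risk == ref:
            cols.append(2.0 - col)
        else:
            raise ValueError(
                f"risk allele {risk!r} of {vid} matches neither REF {ref!r} nor ALT {alt!r}"
            )
    return np.column_stack(cols)


def disease_raw_scores(
    matrix: GenotypeMatrix,
    panel: VariantPanel,
    missing_rule: str = "rescale",
) -> pd.Series:
    """Unweighted risk-allele sum over one disease panel, per sample.

    Post-QC genotypes are expected complete; if a panel variant is
    missing for a subject, ``missing_rule="rescale"`` scales the observed
    sum by n_total/n_observed (keeping the score on the full-panel
    scale), while ``"strict"`` raises, naming the variant.
    """
    if panel.n_snps == 0:
        raise ValueError(f"panel for {panel.disease!r} is empty")
    if missing_rule not in ("rescale", "strict"):
        raise ValueError("missing_rule must be 'rescale' or 'strict'")
    risk = _risk_dosage_columns(matrix, panel)
    missing = np.isnan(risk)
    if missing.any() and missing_rule == "strict":
        j = int(np.argwhere(missing.any(axis=0)).ravel()[0])
        raise ValueError(
            f"panel variant {panel.entries[j][0]!r} missing from genotype data (strict mode)"
        )
    n_obs = (~missing).sum(axis=1)
    raw = np.nansum(risk, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(n_obs > 0, raw * panel.n_snps / n_obs, np.nan)
    return pd.Series(raw, index=matrix.samples["sample_id"].to_numpy(), name=panel.disease)


def disease_raw_score(matrix: GenotypeMatrix, panel: VariantPanel, subject_id) -> float:
    """Raw score for a single subject (integer-valued when data are complete)."""
    return float(disease_raw_scores(matrix, panel).loc[subject_id])


def normalize_score(raw, n_loci: int):
    """Scale a raw allele count to [0, 1] by the maximum achievable score 2*n."""
    if n_loci <= 0:
        raise ValueError("n_loci must be positive")
    return np.asarray(raw, dtype=float) / (2.0 * n_loci) if np.ndim(raw) else float(raw) / (2.0 * n_loci)


def cumulative_prs(norm_scores: pd.DataFrame) -> pd.Series:
    """Sum of the per-disease normalized scores (order-invariant, range [0, n_diseases])."""
    return norm_scores.sum(axis=1)


def hla_augmented_scores(
    matrix: GenotypeMatrix,
    hla_counts: pd.DataFrame,
    panels: dict,
    hla_panels: dict,
    missing_rule: str = "rescale",
) -> pd.DataFrame:
    """Per-disease normalized scores with the HLA burden folded in.

    For each disease, raw = SNP risk-allele sum + sum of HLA carrier
    counts; normalized by 2 x (n_snps + n_hla).  With empty HLA panels
    this reduces exactly to the non-HLA normalized scores.
    """
    out = {}
    for d, panel in panels.items():
        snp_raw = disease_raw_scores(matrix, panel, missing_rule=missing_rule)
        hp = hla_panels.get(d)
        if hp is None or hp.n_hla == 0:
            out[d] = snp_raw / (2.0 * panel.n_snps)
            continue
        missing_alleles = [a for a in hp.alleles if a not in hla_counts.columns]
        if missing_alleles:
            raise ValueError(f"HLA allele {missing_alleles[0]!r} absent from the count matrix")
        counts = hla_counts.loc[snp_raw.index, list(hp.alleles)]
        bad = ~counts.isin([0, 1, 2]).to_numpy()
        if bad.any():
            raise ValueError(f"HLA allele counts outside {{0, 1, 2}} for disease {d!r}")
        out[d] = (snp_raw + counts.sum(axis=1)) / (2.0 * (panel.n_snps + hp.n_hla))
    return pd.DataFrame(out)


def compute_profiles(
    matrix: GenotypeMatrix,
    panels: dict,
    hla_counts: pd.DataFrame | None = None,
    hla_panels: dict | None = None,
    covariates: pd.DataFrame | None = None,
    pcs: np.ndarray | None = None,
    missing_rule: str = "rescale",
) -> pd.DataFrame:
    """Per-subject PRS profile table.

    Columns: ``raw_<disease>`` and ``norm_<disease>`` per panel,
    ``prs_comorb``, and ``prs_comorb_hla`` when HLA panels are given.
    ``covariates`` (indexed or keyed by ``subject_id`` with ``comorbid``,
    ``age_years``, ``sex``) and ``pcs`` (aligned with ``matrix.samples``)
    are merged in when provided, ready for :func:`compare_groups`.
    """
    profiles = pd.DataFrame(index=pd.Index(matrix.samples["sample_id"].to_numpy(), name="subject_id"))
    norm = {}
    for d, panel in panels.items():
        raw = disease_raw_scores(matrix, panel, missing_rule=missing_rule)
        profiles[f"raw_{d}"] = raw
        norm[d] = raw / (2.0 * panel.n_snps)
        profiles[f"norm_{d}"] = norm[d]
    profiles["prs_comorb"] = cumulative_prs(pd.DataFrame(norm))
    if hla_panels is not None:
        if hla_counts is None:
            hla_counts = pd.DataFrame(index=profiles.index)
        aug = hla_augmented_scores(matrix, hla_counts, panels, hla_panels, missing_rule)
        profiles["prs_comorb_hla"] = cumulative_prs(aug)
    if covariates is not None:
        cov = covariates.set_index("subject_id") if "subject_id" in covariates.columns else covariates
        for col in ("comorbid", "age_years", "sex"):
            if col in cov.columns:
                profiles[col] = cov.loc[profiles.index, col]
    if pcs is not None:
        pcs = np.asarray(pcs, dtype=float)
        for j in range(min(3, pcs.shape[1])):
            profiles[f"pc{j + 1}"] = pcs[:, j]
    return profiles


@dataclass
class AncovaResult:
    """Adjusted comorbid-vs-non-comorbid contrast on a cumulative PRS."""

    coef: float
    se: float
    t: float
    p: float
    covariate_coefs: pd.Series
    adjusted_means: dict
    n_comorbid: int
    n_noncomorbid: int
    collinear: bool
    reduced: "AncovaResult | None" = None

    def as_dict(self) -> dict:
        out = {
            "group_coef": self.coef,
            "se": self.se,
            "t": self.t,
            "p": self.p,
            "adjusted_means": self.adjusted_means,
            "n_comorbid": self.n_comorbid,
            "n_noncomorbid": self.n_noncomorbid,
            "collinear": self.collinear,
            "covariates": {k: float(v) for k, v in self.covariate_coefs.items()},
        }
        if self.reduced is not None:
            out["reduced_model_no_sex"] = self.reduced.as_dict()
        return out


def _fit_ancova(y, X) -> tuple:
    fit = sm.OLS(y, X).fit()
    collinear = np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]
    return fit, collinear


def compare_groups(
    profiles: pd.DataFrame,
    score_col: str = "prs_comorb_hla",
    include_reduced: bool = True,
) -> AncovaResult:
    """ANCOVA of a cumulative PRS on comorbidity status.

    Fits OLS of ``score_col`` on the group indicator plus age, sex
    (female = 1) and PC1-PC3, reporting the two-sided t-test on the group
    coefficient and covariate-adjusted group means (covariates held at
    their sample means).  The reduced model without sex is attached as
    ``.reduced``.  Requires at least two subjects per group; collinear
    covariates are flagged, not fatal.
    """
    if score_col not in profiles.columns:
        raise ValueError(f"score column {score_col!r} not in profiles")
    needed = ["comorbid", "age_years"]
    for col in needed:
        if col not in profiles.columns:
            raise ValueError(f"profiles missing covariate column {col!r}")
    group = profiles["comorbid"].astype(bool)
    if group.sum() < 2 or (~group).sum() < 2:
        raise ValueError("each comorbidity group needs at least 2 subjects")

    y = profiles[score_col].astype(float)
    X = pd.DataFrame(index=profiles.index)
    X["const"] = 1.0
    X["group"] = group.astype(float)
    X["age"] = profiles["age_years"].astype(float)
    if "sex" in profiles.columns:
        X["sex_female"] = (profiles["sex"] == "female").astype(float)
    for pc in ("pc1", "pc2", "pc3"):
        if pc in profiles.columns:
            X[pc] = profiles[pc].astype(float)

    fit, collinear = _fit_ancova(y, X)
    cov_means = X.drop(columns=["group"]).mean()
    base = float((fit.params.drop("group") * cov_means).sum())
    adjusted = {
        "non_comorbid": base,
        "comorbid": base + float(fit.params["group"]),
    }
    result = AncovaResult(
        coef=float(fit.params["group"]),
        se=float(fit.bse["group"]),
        t=float(fit.tvalues["group"]),
        p=float(fit.pvalues["group"]),
        covariate_coefs=fit.params.drop("group"),
        adjusted_means=adjusted,
        n_comorbid=int(group.sum()),
        n_noncomorbid=int((~group).sum()),
        collinear=bool(collinear),
    )
    if include_reduced and "sex_female" in X.columns:
        Xr = X.drop(columns=["sex_female"])
        fit_r, coll_r = _fit_ancova(y, Xr)
        result.reduced = AncovaResult(
            coef=float(fit_r.params["group"]),
            se=float(fit_r.bse["group"]),
            t=float(fit_r.tvalues["group"]),
            p=float(fit_r.pvalues["group"]),
            covariate_coefs=fit_r.params.drop("group"),
            adjusted_means={},
            n_comorbid=int(group.sum()),
            n_noncomorbid=int((~group).sum()),
            collinear=bool(coll_r),
        )
    return result


def plot_prs_distribution(profiles: pd.DataFrame, path, score_col: str = "prs_comorb_hla"):
    """Violin + box summary of the cumulative PRS by comorbidity group."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    group = profiles["comorbid"].astype(bool)
    data = [
        profiles.loc[~group, score_col].astype(float).to_numpy(),
        profiles.loc[group, score_col].astype(float).to_numpy(),
    ]
    if any(len(d) == 0 for d in data):
        raise ValueError("both comorbidity groups must be non-empty to plot")
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.violinplot(data, showextrema=False)
    ax.boxplot(data, widths=0.15)
    ax.set_xticks([1, 2], ["no AID comorbidity", ">=1 AID comorbidity"])
    ax.set_ylabel(score_col)
    ax.set_title("Cumulative comorbidity PRS by group")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


# ---------------------------------------------------------------------------
# panel TSV I/O: (disease, variant_id, risk_allele) and (disease, hla_allele)


def save_variant_panels(panels: dict, path) -> None:
    rows = [
        {"disease": d, "variant_id": vid, "risk_allele": risk}
        for d, p in panels.items()
        for vid, risk in p.entries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_variant_panels(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {
        d: VariantPanel(disease=d, entries=tuple(zip(g["variant_id"], g["risk_allele"])))
        for d, g in df.groupby("disease", sort=False)
    }


def save_hla_panels(hla_panels: dict, path) -> None:
    rows = [
        {"disease": d, "hla_allele": a} for d, p in hla_panels.items() for a in p.alleles
    ]
    pd.DataFrame(rows, columns=["disease", "hla_allele"]).to_csv(path, sep="\t", index=False)


def load_hla_panels(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {
        d: HlaPanel(disease=d, alleles=tuple(g["hla_allele"]))
        for d, g in df.groupby("disease", sort=False)
    }
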