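"""Matrix-scale vQTL scans with permutation-based FDR.

Applies chosen variance tests across a phenotype (feature x sample) matrix
and a genotype (variant x sample) matrix, mirroring how vQTLs are mapped in
expression data: variants are filtered on minor allele frequency and a
minimum per-genotype-class sample count, each surviving (feature, variant)
pair is tested, and significance is calibrated by re-running the scan on
sample-permuted phenotypes.  An interaction linear model checks putative
epistatic partners of a variance QTL.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .methods import TestResult, run_method
from .preprocess import PreprocessPlan, _check_full_rank, build_design

__all__ = [
    "ScanResult",
    "filter_variants",
    "vqtl_scan",
    "permutation_fdr",
    "epistasis_interaction_test",
    "read_genotype_tsv",
    "read_genotype_vcf",
]


@dataclass
class ScanResult:
    """Per (feature, variant, method) p-values with permutation FDR."""

    table: pd.DataFrame  # columns: feature, variant, method, statistic, p_value, effect_size, fdr
    skipped: pd.DataFrame  # columns: variant, reason


def _class_counts(g: np.ndarray) -> np.ndarray:
    return np.array([(g == k).sum() for k in (0, 1, 2)])


def filter_variants(
    genotypes: pd.DataFrame, maf_min: float = 0.0, min_group: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep variants with maf >= maf_min and every genotype class >= min_group.

    Returns (passed genotype matrix, skipped log with reasons).
    """
    reasons = []
    keep = []
    for vid, row in genotypes.iterrows():
        g = row.to_numpy()
        maf = g.mean() / 2.0
        maf = min(maf, 1.0 - maf)
        if maf < maf_min:
            reasons.append({"variant": vid, "reason": "maf"})
        elif _class_counts(g).min() < min_group:
            reasons.append({"variant": vid, "reason": "min_group"})
        else:
            keep.append(vid)
    return genotypes.loc[keep], pd.DataFrame(reasons, columns=["variant", "reason"])


def _scan_pvalues(
    phenotypes: pd.DataFrame,
    genotypes: pd.DataFrame,
    covariates,
    methods: Sequence[str],
    plan: PreprocessPlan,
) -> pd.DataFrame:
    rows = []
    for fid, y in phenotypes.iterrows():
        yv = y.to_numpy(dtype=float)
        for vid, grow in genotypes.iterrows():
            g = grow.to_numpy(dtype=float)
            for m in methods:
                res = run_method(m, yv, g, covariates, plan=plan)
                rows.append(
                    {
                        "feature": fid,
                        "variant": vid,
                        "method": m,
                        "statistic": res.statistic,
                        "p_value": res.p_value,
                        "effect_size": res.effect_size,
                    }
                )
    return pd.DataFrame(rows)


def vqtl_scan(
    phenotypes: pd.DataFrame,
    genotypes: pd.DataFrame,
    covariates=None,
    methods: Sequence[str] = ("bf", "svlm", "drm"),
    maf_min: float = 0.0,
    min_group: int = 10,
    plan: PreprocessPlan | None = None,
    n_perm: int = 20,
    per_feature: bool = True,
    seed: int = 0,
) -> ScanResult:
    """Scan every (feature, variant, method) triple and attach permutation FDR.

    Phenotype columns and genotype columns must carry identical sample ids.
    With ``n_perm = 0`` no FDR column is computed.  Permutations shuffle the
    phenotype sample labels against the whole genotype matrix, preserving
    inter-variant correlation; ``per_feature`` estimates the FDR within each
    feature (set False for a single global estimate).
    """
    if list(phenotypes.columns) != list(genotypes.columns):
        raise ValueError("phenotype and genotype matrices must share identical sample id columns")
    if plan is None:
        plan = PreprocessPlan()
    passed, skipped = filter_variants(genotypes, maf_min=maf_min, min_group=min_group)
    if passed.empty:
        raise ValueError("no variant passed the maf/min_group filters")
    observed = _scan_pvalues(phenotypes, passed, covariates, methods, plan)

    if n_perm > 0:
        rng = np.random.default_rng(seed)
        perm_tables = []
        for _ in range(n_perm):
            order = rng.permutation(phenotypes.shape[1])
            perm_ph = pd.DataFrame(
                phenotypes.to_numpy()[:, order], index=phenotypes.index, columns=phenotypes.columns
            )
            perm_cov = None if covariates is None else np.asarray(covariates)[order]
            perm_tables.append(_scan_pvalues(perm_ph, passed, perm_cov, methods, plan))
        fdr = np.full(len(observed), np.nan)
        group_keys = ["feature", "method"] if per_feature else ["method"]
        for key, obs_idx in observed.groupby(group_keys).groups.items():
            obs_p = observed.loc[obs_idx, "p_value"].to_numpy(dtype=float)
            perm_p = np.concatenate(
                [t.loc[obs_idx, "p_value"].to_numpy(dtype=float) for t in perm_tables]
            )
            fdr[observed.index.get_indexer(obs_idx)] = _empirical_fdr(obs_p, perm_p, n_perm)
        observed["fdr"] = fdr
    return ScanResult(table=observed, skipped=skipped)


def _empirical_fdr(observed_p: np.ndarray, perm_p: np.ndarray, n_perm: int) -> np.ndarray:
    """FDR(t) = mean permuted count at p <= t over observed count, clipped and monotone."""
    order = np.argsort(observed_p)
    fdr = np.ones_like(observed_p, dtype=float)
    sorted_p = observed_p[order]
    perm_sorted = np.sort(perm_p)
    n_obs_le = np.arange(1, sorted_p.size + 1)
    n_perm_le = np.searchsorted(perm_sorted, sorted_p, side="right") / n_perm
    vals = np.clip(n_perm_le / n_obs_le, 0.0, 1.0)
    # step-up: the estimate at a threshold cannot exceed the one at any larger threshold
    vals = np.minimum.accumulate(vals[::-1])[::-1]
    fdr[order] = vals
    return fdr


def permutation_fdr(
    observed_p: np.ndarray,
    y: np.ndarray,
    genotypes: pd.DataFrame,
    method: str,
    n_perm: int = 20,
    seed: int = 0,
    covariates=None,
    plan: PreprocessPlan | None = None,
) -> np.ndarray:
    """Permutation FDR for one feature's observed p-values across a variant set.

    For each observed threshold t, FDR(t) is the mean number of permuted
    p-values <= t per permutation divided by the observed count at t,
    clipped to [0, 1] and made monotone.  Permutations shuffle the phenotype
    sample labels against the genotype matrix.  With no discovery at any
    threshold all FDR values are 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed_p = np.asarray(observed_p, dtype=float)
    y = np.asarray(y, dtype=float)
    if plan is None:
        plan = PreprocessPlan()
    rng = np.random.default_rng(seed)
    perm_p = []
    for _ in range(n_perm):
        order = rng.permutation(y.size)
        yp = y[order]
        cp = None if covariates is None else np.asarray(covariates)[order]
        for _, grow in genotypes.iterrows():
            res = run_method(method, yp, grow.to_numpy(dtype=float), cp, plan=plan)
            perm_p.append(res.p_value if res.p_value is not None else 1.0)
    return _empirical_fdr(observed_p, np.asarray(perm_p, dtype=float), n_perm)


def epistasis_interaction_test(
    y: np.ndarray,
    g1: np.ndarray,
    g2: np.ndarray,
    covariates=None,
) -> TestResult:
    """Interaction linear model y ~ g1 + g2 + g1*g2 (+ covariates).

    Wald test of the product term; its coefficient is the effect size.
    Collinear or degenerate variant pairs raise.
    """
    from .methods import _ols_slope

    y = np.asarray(y, dtype=float)
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    X = build_design(len(y), covariates)
    X = np.column_stack([X, g1, g2, g1 * g2])
    _check_full_rank(X)
    idx = X.shape[1] - 1
    coef, t, p, dof = _ols_slope(X, y, idx=idx)
    return TestResult("epistasis_lm", t, p, effect_size=coef, df=dof)


def read_genotype_tsv(path: str) -> pd.DataFrame:
    """Variant x sample matrix of 0/1/2 codes from a TSV (first column = variant id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_genotype_vcf(path: str) -> pd.DataFrame:
    """Variant x sample 0/1/2 matrix from a VCF (diploid GT; missing -> NaN)."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows, ids = [], []
    for var in vcf:
        # gt_types: 0=hom ref, 1=het, 2=hom alt (gts012 not set -> 3=unknown)
        codes = np.array([sum(a for a in gt[:2] if a >= 0) if gt[0] >= 0 and gt[1] >= 0 else np.nan
                          for gt in var.genotypes], dtype=float)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        rows.append(codes)
    return pd.DataFrame(rows, index=ids, columns=samples)
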