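"""Single-variant association testing in family samples.

Quantitative traits use a linear mixed model with a sibship-shared random
effect and a likelihood-ratio test for the dosage term; binary outcomes use
GEE logistic regression with an exchangeable working correlation over
sibships (model-based or robust standard errors).  The admixture covariate
is a per-individual two-population mixture fraction maximising the genotype
likelihood at a panel of informative markers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .core_data import Cohort, allele_freqs_from_founders

logger = logging.getLogger(__name__)

__all__ = [
    "AssocResult",
    "additive_dosage",
    "lmm_quant_assoc",
    "gee_logistic_assoc",
    "admixture_estimate",
    "stepwise_conditional",
    "region_scan",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass
class AssocResult:
    variant: str
    effect_allele: str | None
    coding: str  # e.g. "additive dosage" or "haplotype dosage"
    beta: float
    se: float
    se_robust: float | None
    p: float
    n: int
    model: str  # "lmm" | "gee_logistic"
    covariates: list[str] = field(default_factory=list)
    or_: float | None = None
    ci: tuple[float, float] | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def testable(self) -> bool:
        return "untestable" not in self.flags


def additive_dosage(
    genotype: tuple[str, str] | None, effect_allele: str, alleles: tuple[str, ...]
) -> float:
    """Count of the effect allele in a biallelic genotype (NaN if missing)."""
    if effect_allele not in alleles:
        raise ValueError(f"allele {effect_allele!r} not among {alleles}")
    if len(alleles) != 2:
        raise ValueError("additive dosage requires a biallelic SNP")
    if genotype is None:
        return float("nan")
    for a in genotype:
        if a not in alleles:
            raise ValueError(f"genotype allele {a!r} not among {alleles}")
    return float(sum(a == effect_allele for a in genotype))


def _design_frame(
    cohort: Cohort,
    outcome: str | pd.Series,
    dosages: dict[str, pd.Series],
    covariates: list[str],
) -> pd.DataFrame:
    tdf = cohort.traits.df
    y = tdf[outcome] if isinstance(outcome, str) else outcome
    data = {"_y": y.astype(float)}
    for name, d in dosages.items():
        data[name] = d.reindex(y.index).astype(float)
    for c in covariates:
        s = tdf[c]
        if c == "sex":
            s = s.map({"male": 1.0, "female": 0.0}) if s.dtype == object else s
        data[c] = pd.to_numeric(s, errors="coerce")
    df = pd.DataFrame(data)
    fam = pd.Series(
        {ind.id: ind.family_id for ind in cohort.individuals}, name="_family"
    )
    df["_family"] = fam.reindex(df.index)
    return df.dropna()


def _fit_mixedlm(y, X, groups):
    """ML MixedLM fit with optimizer fallbacks (boundary-prone likelihoods)."""
    last_exc = None
    for method in ("lbfgs", "cg", "powell"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return sm.MixedLM(y, X, groups=groups).fit(reml=False, method=method)
        except np.linalg.LinAlgError as exc:
            last_exc = exc
    raise last_exc


def lmm_quant_assoc(
    cohort: Cohort,
    trait: str | pd.Series,
    snp: str,
    covariates: list[str] | None = None,
    effect_allele: str | None = None,
    dosage: pd.Series | None = None,
) -> AssocResult:
    """Mixed-model association of a quantitative trait with one variant.

    trait ~ dosage + covariates with a family-level random intercept; the
    p-value comes from the likelihood-ratio test of the dosage term (ML
    fits).  ``dosage`` may be supplied directly (e.g. a haplotype dosage),
    otherwise it is the additive count of ``effect_allele`` at ``snp``.
    """
    covariates = list(covariates or [])
    if dosage is None:
        mk = cohort.marker(snp)
        if effect_allele is None:
            freqs = allele_freqs_from_founders(cohort, snp)
            effect_allele = min(freqs, key=freqs.get)  # minor allele by default
        dosage = cohort.snp_dosage(snp, effect_allele)
        coding = "additive dosage"
    else:
        coding = "supplied dosage"
    df = _design_frame(cohort, trait, {"_g": dosage}, covariates)
    n = len(df)
    if n == 0:
        raise ValueError(f"{snp}: no complete observations")
    if df["_y"].nunique() <= 1:
        return AssocResult(snp, effect_allele, coding, np.nan, np.nan, None, 1.0,
                           n, "lmm", covariates, flags=["untestable", "zero-variance trait"])
    if df["_g"].nunique() <= 1:
        return AssocResult(snp, effect_allele, coding, 0.0, np.nan, None, 1.0,
                           n, "lmm", covariates, flags=["untestable", "monomorphic"])

    X_full = sm.add_constant(df[["_g"] + covariates], has_constant="add")
    X_null = sm.add_constant(df[covariates], has_constant="add")
    y = df["_y"]
    groups = df["_family"]
    full = _fit_mixedlm(y, X_full, groups)
    null = _fit_mixedlm(y, X_null, groups)
    lr = max(0.0, 2.0 * (full.llf - null.llf))
    p = float(stats.chi2.sf(lr, df=1))
    beta = float(full.params["_g"])
    se = float(full.bse["_g"])
    return AssocResult(
        variant=snp, effect_allele=effect_allele, coding=coding,
        beta=beta, se=se, se_robust=None, p=p, n=n, model="lmm",
        covariates=covariates,
    )


def gee_logistic_assoc(
    cohort: Cohort,
    disease: str | pd.Series,
    snp: str,
    covariates: list[str] | None = None,
    se_mode: str = "model_based",
    effect_allele: str | None = None,
    dosage: pd.Series | None = None,
) -> AssocResult:
    """GEE logistic association of a binary outcome with one variant.

    Exchangeable working correlation over sibships (families); the odds
    ratio is per copy of the effect allele.  ``se_mode`` selects the
    model-based (naive) or robust (sandwich) standard error for the CI and
    p-value.
    """
    if se_mode not in ("model_based", "robust"):
        raise ValueError("se_mode must be 'model_based' or 'robust'")
    covariates = list(covariates or [])
    if dosage is None:
        if effect_allele is None:
            freqs = allele_freqs_from_founders(cohort, snp)
            effect_allele = min(freqs, key=freqs.get)
        dosage = cohort.snp_dosage(snp, effect_allele)
        coding = "additive dosage"
    else:
        coding = "supplied dosage"
    df = _design_frame(cohort, disease, {"_g": dosage}, covariates)
    n = len(df)
    yvals = df["_y"]
    if yvals.nunique() <= 1:
        raise ValueError(f"{snp}: outcome has a single level (all {yvals.iloc[0]:g})")
    if df["_g"].nunique() <= 1:
        return AssocResult(snp, effect_allele, coding, 0.0, np.nan, None, 1.0,
                           n, "gee_logistic", covariates,
                           flags=["untestable", "monomorphic"])

    X = sm.add_constant(df[["_g"] + covariates], has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GEE(
            df["_y"], X, groups=df["_family"],
            family=sm.families.Binomial(),
            cov_struct=sm.cov_struct.Exchangeable(),
        )
        res = model.fit()
    beta = float(res.params["_g"])
    k = list(X.columns).index("_g")
    with np.errstate(invalid="ignore"):
        se_naive = float(np.sqrt(max(np.diag(res.cov_naive)[k], 0.0)))
        se_robust = float(np.sqrt(max(np.diag(res.cov_robust)[k], 0.0)))
    se = se_naive if se_mode == "model_based" else se_robust
    flags = []
    if abs(beta) > 15 or not np.isfinite(se) or se > 1e3:
        flags.append("separation: infinite estimate suspected")
    z = beta / se if se > 0 else np.nan
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 1.0
    p = max(p, np.finfo(float).tiny)
    return AssocResult(
        variant=snp, effect_allele=effect_allele, coding=coding,
        beta=beta, se=se_naive, se_robust=se_robust, p=p, n=n,
        model="gee_logistic", covariates=covariates,
        or_=float(np.exp(beta)),
        ci=(float(np.exp(beta - _Z95 * se)), float(np.exp(beta + _Z95 * se))),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Admixture (two-population mixture) estimate
# ---------------------------------------------------------------------------


def admixture_estimate(
    genotypes: list[tuple[str, str] | None],
    pop_freqs_a: list[dict[str, float]],
    pop_freqs_b: list[dict[str, float]],
) -> float:
    """Per-individual ancestry fraction m maximising the genotype likelihood.

    Under HWE at each marker with mixed frequency p(m) = m p_A + (1-m) p_B;
    solved on [0, 1].  Returns NaN when every genotype is missing.
    """
    obs = [
        (g, fa, fb)
        for g, fa, fb in zip(genotypes, pop_freqs_a, pop_freqs_b)
        if g is not None
    ]
    if not obs:
        return float("nan")

    def negll(m: float) -> float:
        ll = 0.0
        for g, fa, fb in obs:
            p = {
                a: m * fa.get(a, 0.0) + (1 - m) * fb.get(a, 0.0)
                for a in set(fa) | set(fb)
            }
            x, y = g
            px, py = p.get(x, 0.0), p.get(y, 0.0)
            like = px * py * (1.0 if x == y else 2.0)
            ll += np.log(max(like, 1e-300))
        return -ll

    res = optimize.minimize_scalar(negll, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": 1e-8})
    return float(res.x)


# ---------------------------------------------------------------------------
# Step-wise conditional selection and region scan
# ---------------------------------------------------------------------------


def _conditional_p(cohort, trait, snp, selected, covariates, binary, dosage_fn):
    """LRT (lmm) or Wald (GEE) p for ``snp`` given ``selected`` in the model."""
    covariates = list(covariates or [])
    tdf = cohort.traits.df
    dosages = {f"_sel_{s}": dosage_fn(s) for s in selected}
    dosages["_g"] = dosage_fn(snp)
    df = _design_frame(cohort, trait, dosages, covariates)
    if df["_g"].nunique() <= 1:
        return 1.0, 0.0
    sel_cols = [f"_sel_{s}" for s in selected]
    X_full = sm.add_constant(df[["_g"] + sel_cols + covariates], has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if binary:
            model = sm.GEE(df["_y"], X_full, groups=df["_family"],
                           family=sm.families.Binomial(),
                           cov_struct=sm.cov_struct.Exchangeable())
            res = model.fit()
            z = res.params["_g"] / np.sqrt(np.diag(res.cov_robust))[
                list(X_full.columns).index("_g")
            ]
            return float(2 * stats.norm.sf(abs(z))), float(res.params["_g"])
        X_null = sm.add_constant(df[sel_cols + covariates], has_constant="add")
        full = _fit_mixedlm(df["_y"], X_full, df["_family"])
        null = _fit_mixedlm(df["_y"], X_null, df["_family"])
    lr = max(0.0, 2.0 * (full.llf - null.llf))
    return float(stats.chi2.sf(lr, df=1)), float(full.params["_g"])


def stepwise_conditional(
    cohort: Cohort,
    trait: str | pd.Series,
    snp_set: list[str],
    covariates: list[str] | None = None,
    alpha_enter: float = 0.05,
    binary: bool = False,
    effect_alleles: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Forward selection by smallest conditional p-value.

    At each step the variant with the smallest conditional p (LRT given the
    variants already selected) enters; selection stops when min p >=
    ``alpha_enter``.  Returns a DataFrame of selected variants in order.
    """
    effect_alleles = effect_alleles or {}

    def dosage_fn(s):
        ea = effect_alleles.get(s)
        if ea is None:
            freqs = allele_freqs_from_founders(cohort, s)
            ea = min(freqs, key=freqs.get)
        return cohort.snp_dosage(s, ea)

    remaining = list(snp_set)
    selected: list[str] = []
    rows = []
    while remaining:
        pvals = {}
        betas = {}
        for s in remaining:
            p, b = _conditional_p(cohort, trait, s, selected, covariates,
                                  binary, dosage_fn)
            pvals[s] = p
            betas[s] = b
        best = min(remaining, key=lambda s: (pvals[s], snp_set.index(s)))
        if pvals[best] >= alpha_enter:
            break
        selected.append(best)
        remaining.remove(best)
        rows.append({"snp": best, "step": len(selected),
                     "conditional_p": pvals[best], "beta": betas[best]})
    return pd.DataFrame(rows, columns=["snp", "step", "conditional_p", "beta"])


def region_scan(
    cohort: Cohort,
    outcome: str | pd.Series,
    snps: list[str],
    covariates: list[str] | None = None,
    binary: bool = False,
    maf_plot_threshold: float = 0.05,
    se_mode: str = "model_based",
    effect_alleles: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-SNP association table across a region.

    Every SNP appears in the table; the ``in_plot_set`` column marks SNPs
    with minor allele frequency >= ``maf_plot_threshold`` (rarer SNPs are
    omitted from plots, not from the table).
    """
    effect_alleles = effect_alleles or {}
    rows = []
    for snp in snps:
        mk = cohort.marker(snp)
        freqs = allele_freqs_from_founders(cohort, snp)
        maf = min(freqs.values()) if len(freqs) >= 2 else 0.0
        ea = effect_alleles.get(snp) or min(freqs, key=freqs.get)
        try:
            if binary:
                r = gee_logistic_assoc(cohort, outcome, snp, covariates,
                                       se_mode=se_mode, effect_allele=ea)
            else:
                r = lmm_quant_assoc(cohort, outcome, snp, covariates,
                                    effect_allele=ea)
        except ValueError as exc:
            logger.warning("region_scan: %s skipped (%s)", snp, exc)
            continue
        rows.append(
            {
                "snp": snp,
                "cM": mk.position_cM,
                "effect_allele": ea,
                "freq": freqs.get(ea, np.nan),
                "maf": maf,
                "beta": r.beta,
                "se": r.se,
                "or": r.or_,
                "ci_low": r.ci[0] if r.ci else np.nan,
                "ci_high": r.ci[1] if r.ci else np.nan,
                "p": r.p,
                "n": r.n,
                "in_plot_set": maf >= maf_plot_threshold,
            }
        )
    cols = ["snp", "cM", "effect_allele", "freq", "maf", "beta", "se", "or",
            "ci_low", "ci_high", "p", "n", "in_plot_set"]
    return pd.DataFrame(rows, columns=cols)
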