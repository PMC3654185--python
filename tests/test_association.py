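import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from conftest import build_cohort
from famlink.association import (
    additive_dosage,
    admixture_estimate,
    gee_logistic_assoc,
    lmm_quant_assoc,
    region_scan,
    stepwise_conditional,
)
from famlink.core_data import TraitTable


def test_additive_dosage_trivials():
    assert additive_dosage(("G", "G"), "G", ("A", "G")) == 2
    assert additive_dosage(("G", "A"), "G", ("A", "G")) == 1
    assert additive_dosage(("A", "A"), "G", ("A", "G")) == 0
    assert np.isnan(additive_dosage(None, "G", ("A", "G")))


def test_additive_dosage_bad_allele():
    with pytest.raises(ValueError, match="not among"):
        additive_dosage(("G", "G"), "T", ("A", "G"))


# ---------------------------------------------------------------------------
# Fixture builders: singleton-family cohorts (independent individuals)
# ---------------------------------------------------------------------------


def _singleton_cohort(dosages, trait=None, disease=None, covars=None, seed=0,
                      extra_snps=None):
    """Cohort of unrelated individuals with one SNP coded by dosage."""
    n = len(dosages)
    snps = {"rs1": dosages}
    if extra_snps:
        snps.update(extra_snps)
    mdefs = [(name, 1.0 + i, ("A", "G"), "snp") for i, name in enumerate(snps)]
    records = []
    for i in range(n):
        genos = []
        for name in snps:
            d = snps[name][i]
            if np.isnan(d):
                genos.append(None)
            else:
                genos.append({0: "G/G", 1: "A/G", 2: "A/A"}[int(d)])
        records.append((f"F{i}", f"I{i}", None, None, "male", genos))
    cohort = build_cohort(mdefs, records)
    rows = {"iid": [f"I{i}" for i in range(n)]}
    if trait is not None:
        rows["trait"] = trait
    if disease is not None:
        rows["affected"] = disease
    for k, v in (covars or {}).items():
        rows[k] = v
    cohort.attach_traits(TraitTable(pd.DataFrame(rows).set_index("iid")))
    return cohort


def test_lmm_matches_ols_on_singletons():
    rng = np.random.default_rng(1)
    n = 500
    g = rng.integers(0, 3, size=n).astype(float)
    age = rng.uniform(20, 60, size=n)
    y = 1.0 * g + 0.05 * age + rng.standard_normal(n)
    cohort = _singleton_cohort(g, trait=y, covars={"age": age})
    res = lmm_quant_assoc(cohort, "trait", "rs1", ["age"], effect_allele="A")
    X = sm.add_constant(np.column_stack([g, age]))
    ols = sm.OLS(y, X).fit()
    assert res.beta == pytest.approx(ols.params[1], abs=1e-6)
    assert res.beta == pytest.approx(1.0, abs=0.15)


def test_lmm_permutation_null_uniform():
    rng = np.random.default_rng(2)
    n = 120
    g = rng.integers(0, 3, size=n).astype(float)
    y = rng.standard_normal(n)
    pvals = []
    for _ in range(250):
        yp = rng.permutation(y)
        cohort = _singleton_cohort(g, trait=yp)
        pvals.append(lmm_quant_assoc(cohort, "trait", "rs1",
                                     effect_allele="A").p)
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_lmm_zero_variance_trait_flagged():
    g = np.array([0.0, 1.0, 2.0, 1.0])
    cohort = _singleton_cohort(g, trait=np.ones(4))
    res = lmm_quant_assoc(cohort, "trait", "rs1", effect_allele="A")
    assert not res.testable
    assert res.p == 1.0


def test_lmm_monomorphic_flagged():
    g = np.zeros(10)
    cohort = _singleton_cohort(g, trait=np.arange(10.0))
    res = lmm_quant_assoc(cohort, "trait", "rs1", effect_allele="A")
    assert not res.testable
    assert res.p == 1.0


def test_lmm_allele_swap_negates_beta():
    rng = np.random.default_rng(3)
    n = 200
    g = rng.integers(0, 3, size=n).astype(float)
    y = 0.8 * g + rng.standard_normal(n)
    cohort = _singleton_cohort(g, trait=y)
    r_a = lmm_quant_assoc(cohort, "trait", "rs1", effect_allele="A")
    r_g = lmm_quant_assoc(cohort, "trait", "rs1", effect_allele="G")
    assert r_a.beta == pytest.approx(-r_g.beta, abs=1e-8)
    assert r_a.p == pytest.approx(r_g.p, rel=1e-6)


def test_lmm_p_invariant_to_affine_rescale():
    rng = np.random.default_rng(4)
    n = 300
    g = rng.integers(0, 3, size=n).astype(float)
    y = 0.3 * g + rng.standard_normal(n)
    c1 = _singleton_cohort(g, trait=y)
    c2 = _singleton_cohort(g, trait=5.0 * y - 3.0)
    p1 = lmm_quant_assoc(c1, "trait", "rs1", effect_allele="A").p
    p2 = lmm_quant_assoc(c2, "trait", "rs1", effect_allele="A").p
    assert p1 == pytest.approx(p2, rel=1e-4)


# ---------------------------------------------------------------------------
# GEE logistic
# ---------------------------------------------------------------------------


def _two_by_two_cohort():
    # g=1: 30 cases / 10 controls ; g=0: 10 cases / 30 controls
    g = np.array([1.0] * 40 + [0.0] * 40)
    d = np.array([1.0] * 30 + [0.0] * 10 + [1.0] * 10 + [0.0] * 30)
    return _singleton_cohort(g, disease=d)


def test_gee_2x2_closed_form():
    cohort = _two_by_two_cohort()
    res = gee_logistic_assoc(cohort, "affected", "rs1", effect_allele="A")
    assert res.or_ == pytest.approx(9.0, abs=1e-5)
    assert res.beta == pytest.approx(np.log(9.0), abs=1e-6)
    woolf = np.sqrt(1 / 30 + 1 / 10 + 1 / 10 + 1 / 30)
    assert res.se == pytest.approx(woolf, abs=1e-6)
    assert res.ci[0] < 9.0 < res.ci[1]


def test_gee_reduces_to_logistic_on_singletons():
    rng = np.random.default_rng(7)
    n = 400
    g = rng.integers(0, 3, size=n).astype(float)
    logit = -0.5 + 0.6 * g
    d = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
    cohort = _singleton_cohort(g, disease=d)
    res = gee_logistic_assoc(cohort, "affected", "rs1", effect_allele="A")
    ml = sm.Logit(d, sm.add_constant(g)).fit(disp=0)
    assert res.beta == pytest.approx(ml.params[1], abs=1e-6)


def test_gee_all_zero_outcome_errors():
    g = np.array([0.0, 1.0, 2.0, 1.0])
    cohort = _singleton_cohort(g, disease=np.zeros(4))
    with pytest.raises(ValueError, match="single level"):
        gee_logistic_assoc(cohort, "affected", "rs1", effect_allele="A")


def test_gee_robust_close_to_model_based_when_correct():
    rng = np.random.default_rng(8)
    n = 2000
    g = rng.integers(0, 3, size=n).astype(float)
    logit = -0.2 + 0.4 * g
    d = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
    cohort = _singleton_cohort(g, disease=d)
    res = gee_logistic_assoc(cohort, "affected", "rs1", effect_allele="A")
    assert res.se_robust == pytest.approx(res.se, rel=0.10)


def test_gee_swap_allele_inverts_or():
    cohort = _two_by_two_cohort()
    r_a = gee_logistic_assoc(cohort, "affected", "rs1", effect_allele="A")
    r_g = gee_logistic_assoc(cohort, "affected", "rs1", effect_allele="G")
    assert r_a.or_ == pytest.approx(1 / r_g.or_, rel=1e-6)


# ---------------------------------------------------------------------------
# Admixture
# ---------------------------------------------------------------------------


def test_admixture_boundaries():
    genos = [("A", "A")] * 10
    fa = [{"A": 1.0, "G": 0.0}] * 10
    fb = [{"A": 0.0, "G": 1.0}] * 10
    assert admixture_estimate(genos, fa, fb) == pytest.approx(1.0, abs=1e-4)
    genos_b = [("G", "G")] * 10
    assert admixture_estimate(genos_b, fa, fb) == pytest.approx(0.0, abs=1e-4)


def test_admixture_all_missing():
    assert np.isnan(admixture_estimate([None, None], [{}, {}], [{}, {}]))


def test_admixture_mid_matches_grid_oracle():
    rng = np.random.default_rng(90)
    m_true = 0.5
    fa, fb, genos = [], [], []
    for _ in range(45):
        pa = rng.uniform(0.7, 0.95)
        pb = pa - 0.6
        fa.append({"A": pa, "G": 1 - pa})
        fb.append({"A": pb, "G": 1 - pb})
        p = m_true * pa + (1 - m_true) * pb
        g = tuple("A" if rng.random() < p else "G" for _ in range(2))
        genos.append(g)
    m_hat = admixture_estimate(genos, fa, fb)
    assert m_hat == pytest.approx(0.5, abs=0.1)

    # independent 1e-4-step grid search oracle
    def ll(m):
        out = 0.0
        for g, a, b in zip(genos, fa, fb):
            p = {k: m * a[k] + (1 - m) * b[k] for k in a}
            w = p[g[0]] * p[g[1]] * (1 if g[0] == g[1] else 2)
            out += np.log(max(w, 1e-300))
        return out

    grid = np.arange(0.0, 1.0 + 1e-9, 1e-4)
    m_grid = grid[np.argmax([ll(m) for m in grid])]
    assert m_hat == pytest.approx(m_grid, abs=2e-4)


# ---------------------------------------------------------------------------
# Stepwise selection and region scan
# ---------------------------------------------------------------------------


def test_stepwise_single_strong_snp():
    rng = np.random.default_rng(10)
    n = 300
    g = rng.integers(0, 3, size=n).astype(float)
    noise = rng.integers(0, 3, size=n).astype(float)
    y = 2.0 * g + rng.standard_normal(n)
    cohort = _singleton_cohort(g, trait=y, extra_snps={"rs2": noise})
    sel = stepwise_conditional(cohort, "trait", ["rs1", "rs2"], alpha_enter=0.05,
                               effect_alleles={"rs1": "A", "rs2": "A"})
    assert list(sel["snp"]) == ["rs1"]


def test_stepwise_pure_noise_mostly_empty():
    rng = np.random.default_rng(11)
    n = 300
    y = rng.standard_normal(n)
    snps = {f"rs{k}": rng.integers(0, 3, size=n).astype(float) for k in range(1, 6)}
    first = snps.pop("rs1")
    cohort = _singleton_cohort(first, trait=y, extra_snps=snps)
    sel = stepwise_conditional(
        cohort, "trait", [f"rs{k}" for k in range(1, 6)],
        alpha_enter=0.05 / 5,
        effect_alleles={f"rs{k}": "A" for k in range(1, 6)},
    )
    assert len(sel) <= 1


def test_stepwise_two_causal_one_proxy():
    # the two causal SNPs (and not the proxy) are selected in >= 80% of seeds
    hits = 0
    for seed in range(5):
        rng = np.random.default_rng(1200 + seed)
        n = 600
        g1 = rng.integers(0, 3, size=n).astype(float)
        g2 = rng.integers(0, 3, size=n).astype(float)
        proxy = g1.copy()
        flip = rng.random(n) < 0.03  # r2 ~ 0.95 with g1
        proxy[flip] = rng.integers(0, 3, size=int(flip.sum())).astype(float)
        y = 1.0 * g1 + 1.0 * g2 + rng.standard_normal(n)
        cohort = _singleton_cohort(g1, trait=y,
                                   extra_snps={"rs2": g2, "rs3": proxy})
        sel = stepwise_conditional(
            cohort, "trait", ["rs1", "rs2", "rs3"], alpha_enter=0.05,
            effect_alleles={"rs1": "A", "rs2": "A", "rs3": "A"},
        )
        if set(sel["snp"]) == {"rs1", "rs2"}:
            hits += 1
    assert hits >= 4


def test_region_scan_maf_filter_and_empty():
    rng = np.random.default_rng(13)
    n = 200
    g = rng.integers(0, 3, size=n).astype(float)
    rare = np.zeros(n)
    rare[:4] = 1.0  # MAF 0.01
    y = 0.5 * g + rng.standard_normal(n)
    cohort = _singleton_cohort(g, trait=y, extra_snps={"rs_rare": rare})
    tab = region_scan(cohort, "trait", ["rs1", "rs_rare"],
                      effect_alleles={"rs1": "A", "rs_rare": "A"})
    assert set(tab["snp"]) == {"rs1", "rs_rare"}
    row = tab[tab["snp"] == "rs_rare"].iloc[0]
    assert not row["in_plot_set"]
    assert tab[tab["snp"] == "rs1"].iloc[0]["in_plot_set"]
    empty = region_scan(cohort, "trait", [])
    assert len(empty) == 0
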