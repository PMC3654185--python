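import itertools

import numpy as np
import pandas as pd
import pytest

from famlink.ld_haplotype import (
    LDPair,
    cohort_haplotype_dosages,
    em_haplotype_freqs,
    extract_genotypes,
    family_haplotype_dosage,
    gabriel_blocks,
    pairwise_ld,
    select_tags,
)
from famlink.synthetic_cohort import (
    ClusterSpec,
    simulate_founder_haplotypes,
)


def _genos_from_hap_pairs(pairs):
    """(n, L, 2) genotype array from explicit haplotype pairs."""
    n = len(pairs)
    L = len(pairs[0][0])
    out = np.empty((n, L, 2), dtype=object)
    for i, (h1, h2) in enumerate(pairs):
        for k in range(L):
            a, b = sorted((h1[k], h2[k]))
            out[i, k] = (a, b)
    return out


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------


def test_em_phase_unambiguous_counting():
    pairs = [(("A", "B"), ("A", "B"))] * 9 + [(("a", "b"), ("a", "b"))]
    res = em_haplotype_freqs(_genos_from_hap_pairs(pairs))
    assert res.freqs[("A", "B")] == pytest.approx(0.9, abs=1e-9)
    assert res.freqs[("a", "b")] == pytest.approx(0.1, abs=1e-9)


def test_em_double_het_ambiguity():
    pairs = [(("A", "B"), ("a", "b"))] * 10
    res = em_haplotype_freqs(_genos_from_hap_pairs(pairs), n_starts=8, seed=0)
    # two equivalent modes (AB/ab vs Ab/aB); one is returned, ambiguity flagged
    assert res.ambiguous
    top = sorted(res.freqs.values(), reverse=True)
    assert top[0] == pytest.approx(0.5, abs=1e-6)
    assert top[1] == pytest.approx(0.5, abs=1e-6)


def test_em_loglik_monotone():
    rng = np.random.default_rng(0)
    cluster = ClusterSpec(
        ("s1", "s2", "s3", "s4"),
        {
            ("A", "B", "C", "D"): 0.35,
            ("a", "B", "c", "D"): 0.30,
            ("A", "b", "C", "d"): 0.25,
            ("a", "b", "c", "d"): 0.10,
        },
    )
    pool = simulate_founder_haplotypes(cluster, 400, seed=1)
    pairs = [(pool[2 * i], pool[2 * i + 1]) for i in range(200)]
    res = em_haplotype_freqs(_genos_from_hap_pairs(pairs), n_starts=2)
    diffs = np.diff(res.loglik_history)
    assert (diffs >= -1e-9).all()


def test_em_recovery_four_haplotypes():
    cluster = ClusterSpec(
        ("s1", "s2", "s3", "s4"),
        {
            ("A", "B", "C", "D"): 0.35,
            ("a", "B", "c", "D"): 0.30,
            ("A", "b", "C", "d"): 0.25,
            ("a", "b", "c", "d"): 0.10,
        },
    )
    pool = simulate_founder_haplotypes(cluster, 2000, seed=2)
    pairs = [(pool[2 * i], pool[2 * i + 1]) for i in range(1000)]
    res = em_haplotype_freqs(_genos_from_hap_pairs(pairs))
    for hap, f in cluster.haplotype_freqs.items():
        assert res.freqs.get(hap, 0.0) == pytest.approx(f, abs=0.03)


def test_em_no_complete_genotypes_errors():
    g = np.empty((2, 2, 2), dtype=object)
    g[:] = None
    with pytest.raises(ValueError, match="no complete genotypes"):
        em_haplotype_freqs(g)


# ---------------------------------------------------------------------------
# Pairwise LD
# ---------------------------------------------------------------------------


def _ld_fixture_genos():
    # haplotype counts AB=40, ab=40, Ab=10, aB=10, paired homozygously so
    # phase is unambiguous and EM recovers the counts exactly
    pairs = (
        [(("A", "B"), ("A", "B"))] * 20
        + [(("a", "b"), ("a", "b"))] * 20
        + [(("A", "b"), ("A", "b"))] * 5
        + [(("a", "B"), ("a", "B"))] * 5
    )
    g = _genos_from_hap_pairs(pairs)
    return g[:, 0, :], g[:, 1, :]


def test_pairwise_ld_hand_computation():
    ga, gb = _ld_fixture_genos()
    p = pairwise_ld(ga, gb, "x", "y")
    assert p.D == pytest.approx(0.15, abs=1e-9)
    assert p.Dprime == pytest.approx(0.6, abs=1e-9)
    assert p.r2 == pytest.approx(0.36, abs=1e-9)
    assert p.ci_low <= p.Dprime <= p.ci_high


def test_pairwise_ld_duplicated_snp():
    rng = np.random.default_rng(3)
    n = 200
    a = rng.choice(["A", "a"], size=(n, 2), p=[0.4, 0.6]).astype(object)
    p = pairwise_ld(a, a.copy())
    assert p.Dprime == pytest.approx(1.0, abs=1e-9)
    assert p.r2 == pytest.approx(1.0, abs=1e-9)


def test_pairwise_ld_exact_independence():
    # haplotypes constructed so p_AB = p_A * p_B exactly
    pairs = []
    for ha, hb, cnt in [("A", "B", 25), ("A", "b", 25), ("a", "B", 25), ("a", "b", 25)]:
        pairs += [((ha, hb), (ha, hb))] * cnt
    g = _genos_from_hap_pairs(pairs)
    p = pairwise_ld(g[:, 0, :], g[:, 1, :])
    assert p.D == pytest.approx(0.0, abs=1e-9)
    assert p.r2 == pytest.approx(0.0, abs=1e-9)


def test_pairwise_ld_monomorphic_errors():
    n = 50
    a = np.full((n, 2), "A", dtype=object)
    b = np.array([["B", "b"]] * n, dtype=object)
    with pytest.raises(ValueError, match="monomorphic"):
        pairwise_ld(a, b)


def test_r2_bounded_by_dprime_squared():
    rng = np.random.default_rng(4)
    for rep in range(5):
        pa, pb = rng.uniform(0.2, 0.8, size=2)
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
        D = rng.uniform(0, dmax)
        freqs = {
            ("A", "B"): pa * pb + D,
            ("A", "b"): pa * (1 - pb) - D,
            ("a", "B"): (1 - pa) * pb - D,
            ("a", "b"): (1 - pa) * (1 - pb) + D,
        }
        pool = simulate_founder_haplotypes(freqs, 600, seed=rep)
        pairs = [(pool[2 * i], pool[2 * i + 1]) for i in range(300)]
        g = _genos_from_hap_pairs(pairs)
        p = pairwise_ld(g[:, 0, :], g[:, 1, :])
        assert p.r2 <= p.Dprime**2 + 1e-9
        assert 0 <= p.Dprime <= 1
        assert 0 <= p.r2 <= 1


# ---------------------------------------------------------------------------
# Blocks
# ---------------------------------------------------------------------------


def _mkpair(a, b, lo, hi):
    return (a, b), LDPair(a, b, 0.1, (lo + hi) / 2, 0.5, lo, hi)


def test_blocks_single_tight_block():
    cluster = ClusterSpec(
        ("s1", "s2", "s3"),
        {("A", "B", "C"): 0.55, ("a", "b", "c"): 0.40, ("A", "b", "c"): 0.05},
    )
    pool = simulate_founder_haplotypes(cluster, 1000, seed=5)
    pairs_h = [(pool[2 * i], pool[2 * i + 1]) for i in range(500)]
    g = _genos_from_hap_pairs(pairs_h)
    snps = ["s1", "s2", "s3"]
    lds = {}
    for i, j in itertools.combinations(range(3), 2):
        lds[(snps[i], snps[j])] = pairwise_ld(g[:, i, :], g[:, j, :],
                                              snps[i], snps[j])
    blocks = gabriel_blocks(lds, snps, 0.05)
    assert blocks == [["s1", "s2", "s3"]]


def test_blocks_split_by_recombination():
    snps = ["a1", "a2", "b1", "b2"]
    lds = dict([
        _mkpair("a1", "a2", 0.95, 1.0),
        _mkpair("b1", "b2", 0.95, 1.0),
        _mkpair("a1", "b1", 0.0, 0.5),
        _mkpair("a1", "b2", 0.0, 0.5),
        _mkpair("a2", "b1", 0.0, 0.5),
        _mkpair("a2", "b2", 0.0, 0.5),
    ])
    blocks = gabriel_blocks(lds, snps, 0.05)
    assert blocks == [["a1", "a2"], ["b1", "b2"]]


def test_blocks_uninformative_tiny_n():
    snps = ["s1", "s2"]
    lds = dict([_mkpair("s1", "s2", 0.1, 0.95)])  # wide CI: uninformative
    assert gabriel_blocks(lds, snps, 0.05) == []


def test_blocks_maf_filter():
    snps = ["s1", "rare", "s2"]
    lds = dict([
        _mkpair("s1", "s2", 0.95, 1.0),
        _mkpair("s1", "rare", 0.0, 0.3),
        _mkpair("rare", "s2", 0.0, 0.3),
    ])
    blocks = gabriel_blocks(lds, snps, 0.05, mafs={"rare": 0.01})
    assert blocks == [["s1", "s2"]]


# ---------------------------------------------------------------------------
# Tag selection
# ---------------------------------------------------------------------------


def test_select_tags_hand_case():
    m = pd.DataFrame(
        [[1.0, 0.95, 0.1], [0.95, 1.0, 0.1], [0.1, 0.1, 1.0]],
        index=["s1", "s2", "s3"], columns=["s1", "s2", "s3"],
    )
    tags, capture = select_tags(m, 0.8, {"s1": 1.0, "s2": 2.0, "s3": 3.0})
    assert tags == ["s1", "s3"]
    assert capture["s1"] == ["s1", "s2"]
    assert capture["s3"] == ["s3"]


def test_select_tags_all_independent():
    n = 5
    names = [f"s{i}" for i in range(n)]
    m = pd.DataFrame(np.eye(n) + 0.1 - 0.1 * np.eye(n), index=names, columns=names)
    np.fill_diagonal(m.values, 1.0)
    tags, capture = select_tags(m, 0.8)
    assert len(tags) == 5
    assert sorted(itertools.chain.from_iterable(capture.values())) == sorted(names)


def test_select_tags_21_snp_block():
    # 21 SNPs generated from 5 haplotype prototypes: SNPs sharing a
    # partition pattern have r2 = 1, so few tags should cover everything
    rng = np.random.default_rng(6)
    hap_freqs = np.array([0.3, 0.25, 0.2, 0.15, 0.1])
    # four allelic partition classes (a one-block region: every SNP is a
    # duplicate or complement of one of four prototypes)
    prototypes = [(1, 0, 0, 0, 0), (1, 1, 0, 0, 0), (1, 1, 1, 0, 0),
                  (0, 0, 0, 1, 0)]
    patterns = []
    for _ in range(21):
        p = prototypes[rng.integers(len(prototypes))]
        if rng.random() < 0.5:
            p = tuple(1 - x for x in p)
        patterns.append(p)
    names = [f"snp{i}" for i in range(21)]
    # population r2 from the haplotype distribution
    m = pd.DataFrame(np.eye(21), index=names, columns=names)
    for i in range(21):
        for j in range(i + 1, 21):
            pi = np.array(patterns[i], dtype=float)
            pj = np.array(patterns[j], dtype=float)
            pa = float(hap_freqs @ pi)
            pb = float(hap_freqs @ pj)
            pab = float(hap_freqs @ (pi * pj))
            denom = pa * (1 - pa) * pb * (1 - pb)
            r2 = (pab - pa * pb) ** 2 / denom if denom > 0 else 0.0
            m.iloc[i, j] = m.iloc[j, i] = r2
    tags, capture = select_tags(m, 0.8)
    assert len(tags) <= 6
    covered = set(itertools.chain.from_iterable(capture.values()))
    assert covered == set(names)


# ---------------------------------------------------------------------------
# Family haplotype dosages
# ---------------------------------------------------------------------------

FREQS4 = {
    ("A", "B"): 0.5,
    ("a", "b"): 0.3,
    ("A", "b"): 0.1,
    ("a", "B"): 0.1,
}


def test_dosage_homozygous_individual():
    geno = (("A", "A"), ("B", "B"))
    dos, mp, flag = family_haplotype_dosage({"S1": geno}, None, None, FREQS4)
    assert not flag
    assert dos["S1"][("A", "B")] == pytest.approx(2.0, abs=1e-12)
    assert sum(dos["S1"].values()) == pytest.approx(2.0, abs=1e-9)


def test_dosage_singleton_forced_phase():
    freqs = {("A", "B"): 0.5, ("a", "b"): 0.5}
    geno = (("A", "a"), ("B", "b"))
    dos, mp, flag = family_haplotype_dosage({"S1": geno}, None, None, freqs)
    assert dos["S1"][("A", "B")] == pytest.approx(1.0, abs=1e-12)
    assert dos["S1"][("a", "b")] == pytest.approx(1.0, abs=1e-12)


def test_dosage_parents_resolve_phase():
    # double-het child; parents homozygous AABB and aabb force phase AB|ab
    child = (("A", "a"), ("B", "b"))
    father = (("A", "A"), ("B", "B"))
    mother = (("a", "a"), ("b", "b"))
    dos, mp, flag = family_haplotype_dosage(
        {"S1": child}, father, mother, FREQS4, father_id="F", mother_id="M"
    )
    assert dos["S1"][("A", "B")] == pytest.approx(1.0, abs=1e-12)
    assert dos["S1"][("a", "b")] == pytest.approx(1.0, abs=1e-12)
    assert dos["S1"].get(("A", "b"), 0.0) == pytest.approx(0.0, abs=1e-12)
    assert mp["S1"] == (("A", "B"), ("a", "b"))


def test_dosage_inconsistent_family_flagged():
    freqs = {("A", "B"): 0.6, ("a", "b"): 0.4}  # (A,b) has zero frequency
    child = (("A", "A"), ("b", "b"))
    dos, mp, flag = family_haplotype_dosage({"S1": child}, None, None, freqs)
    assert flag
    assert sum(dos["S1"].values()) == pytest.approx(2.0, abs=1e-9)


def test_cohort_dosages_rows_sum_to_two():
    from famlink.synthetic_cohort import default_paper_config, simulate_cohort
    from dataclasses import replace

    cfg = replace(default_paper_config(seed=9), n_families=30,
                  n_rep_full=0, n_rep_mixed=0)
    cohort = simulate_cohort(cfg)
    hs = cohort_haplotype_dosages(cohort, ["tag1", "tag2", "tag3", "tag4"])
    sums = hs.dosages.dropna().sum(axis=1)
    assert np.allclose(sums, 2.0, atol=1e-6)
    assert sum(hs.freqs.values()) == pytest.approx(1.0, abs=1e-6)


def test_family_dosages_no_less_certain_than_singleton():
    """Family information never increases dosage uncertainty (on average)."""
    from famlink.synthetic_cohort import default_paper_config, simulate_cohort
    from dataclasses import replace

    cfg = replace(default_paper_config(seed=10), n_families=40,
                  n_rep_full=0, n_rep_mixed=0, parent_genotyping_rate=1.0)
    cohort = simulate_cohort(cfg)
    snps = ["tag1", "tag2", "tag3", "tag4"]
    em = em_haplotype_freqs(extract_genotypes(cohort, snps))
    fam_hs = cohort_haplotype_dosages(cohort, snps, em.freqs)

    # singleton route: every individual phased alone
    single = {}
    for ind in cohort.individuals:
        geno = tuple(cohort.genotype(ind.id, s) for s in snps)
        if any(g is None for g in geno):
            continue
        dos, _, _ = family_haplotype_dosage({ind.id: geno}, None, None, em.freqs)
        single[ind.id] = dos[ind.id]

    def entropy_like(d):
        # distance of the dosage vector from integers: 0 when fully resolved
        return sum(min(v % 1, 1 - v % 1) for v in d.values())

    fam_unc = []
    sing_unc = []
    for iid, sdos in single.items():
        fd = fam_hs.dosages.loc[iid]
        if fd.isna().any():
            continue
        fam_unc.append(entropy_like(dict(fd)))
        sing_unc.append(entropy_like(sdos))
    assert np.mean(fam_unc) <= np.mean(sing_unc) + 1e-9
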