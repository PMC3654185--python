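"""Pairwise LD, haplotype blocks, tag SNPs, EM haplotype frequencies,
family-aware haplotype dosages, and haplotype association.

Two-locus LD statistics come from EM haplotype frequencies; the D' 90%
confidence interval is a profile multinomial likelihood normalised over a
1001-point grid on [0, 1].  Blocks follow the confidence-interval rule:
"strong LD" pairs have CI upper >= 0.98 and lower >= 0.70, "strong
recombination" pairs have CI upper < 0.90, and a block is a contiguous run
whose outermost pair is strong LD and in which >= 95% of informative pairs
are strong LD (markers below the MAF threshold are ignored).

Family haplotype dosages assume zero recombination within the SNP cluster:
all phase configurations of a nuclear family consistent with Mendelian
transmission are enumerated, weighted by founder haplotype frequencies, and
the posterior expected copy count of each haplotype is returned.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "LDPair",
    "HaplotypeSet",
    "EMResult",
    "em_haplotype_freqs",
    "pairwise_ld",
    "ld_matrix",
    "gabriel_blocks",
    "select_tags",
    "family_haplotype_dosage",
    "cohort_haplotype_dosages",
    "haplotype_assoc",
    "HaplotypeAssocReport",
    "extract_genotypes",
]


@dataclass
class LDPair:
    snp_a: str
    snp_b: str
    D: float
    Dprime: float
    r2: float
    ci_low: float
    ci_high: float

    @property
    def strong_ld(self) -> bool:
        return self.ci_high >= 0.98 and self.ci_low >= 0.70

    @property
    def strong_recombination(self) -> bool:
        return self.ci_high < 0.90

    @property
    def informative(self) -> bool:
        return self.strong_ld or self.strong_recombination


@dataclass
class EMResult:
    freqs: dict[tuple, float]
    loglik: float
    loglik_history: list[float]
    converged: bool
    ambiguous: bool
    n_used: int


@dataclass
class HaplotypeSet:
    snps: list[str]
    freqs: dict[tuple, float]
    dosages: pd.DataFrame  # index iid, columns haplotype labels
    map_pairs: dict[str, tuple] = field(default_factory=dict)
    flagged_families: list[str] = field(default_factory=list)


def extract_genotypes(cohort: Cohort, snps: list[str]) -> np.ndarray:
    """(n, L, 2) object array of alleles (None = missing) for ``snps``."""
    cols = [cohort.marker_index(s) for s in snps]
    return cohort.genotypes[:, cols, :]


# ---------------------------------------------------------------------------
# EM haplotype frequency estimation
# ---------------------------------------------------------------------------


def _compatible_pairs(geno_row) -> list[tuple[tuple, tuple]]:
    """All unordered haplotype pairs consistent with one unphased genotype."""
    L = len(geno_row)
    het_sites = [k for k in range(L) if geno_row[k][0] != geno_row[k][1]]
    base1 = [geno_row[k][0] for k in range(L)]
    base2 = [geno_row[k][1] for k in range(L)]
    if not het_sites:
        return [(tuple(base1), tuple(base2))]
    pairs = []
    # fix the first het site's assignment to avoid double counting
    for combo in itertools.product((0, 1), repeat=len(het_sites) - 1):
        h1 = list(base1)
        h2 = list(base2)
        for k, flip in zip(het_sites[1:], combo):
            if flip:
                h1[k], h2[k] = h2[k], h1[k]
        pairs.append((tuple(h1), tuple(h2)))
    return pairs


def em_haplotype_freqs(
    genotypes: np.ndarray,
    n_starts: int = 5,
    seed: int = 0,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> EMResult:
    """EM haplotype frequencies from unphased multilocus genotypes.

    ``genotypes`` is (n, L, 2) with allele labels; individuals with any
    missing site are dropped.  The log-likelihood is non-decreasing per
    iteration; runs from ``n_starts`` seeded initialisations and returns the
    best mode (ambiguity flagged when distinct modes are tied to within
    1e-6 in log-likelihood).
    """
    complete = []
    for i in range(genotypes.shape[0]):
        row = genotypes[i]
        if any(row[k][0] is None or row[k][1] is None for k in range(row.shape[0])):
            continue
        complete.append(tuple((row[k][0], row[k][1]) for k in range(row.shape[0])))
    if not complete:
        raise ValueError("no complete genotypes for EM")

    uniq: dict[tuple, int] = {}
    for g in complete:
        key = tuple(tuple(sorted(site)) for site in g)
        uniq[key] = uniq.get(key, 0) + 1
    pair_lists = {g: _compatible_pairs(g) for g in uniq}
    haps = sorted({h for pl in pair_lists.values() for p in pl for h in p})
    hidx = {h: k for k, h in enumerate(haps)}
    H = len(haps)
    n = len(complete)

    rng = np.random.default_rng(seed)
    best = None
    modes = []
    for start in range(n_starts):
        if start == 0:
            f = np.full(H, 1.0 / H)
        else:
            f = rng.dirichlet(np.ones(H))
        history = []
        prev = -np.inf
        converged = False
        for _ in range(max_iter):
            ll = 0.0
            counts = np.zeros(H)
            for g, c in uniq.items():
                ps = []
                for h1, h2 in pair_lists[g]:
                    w = f[hidx[h1]] * f[hidx[h2]]
                    if h1 != h2:
                        w *= 2.0
                    ps.append(w)
                tot = sum(ps)
                if tot <= 0:
                    tot = 1e-300
                ll += c * np.log(tot)
                for (h1, h2), w in zip(pair_lists[g], ps):
                    frac = c * w / tot
                    counts[hidx[h1]] += frac
                    counts[hidx[h2]] += frac
            history.append(ll)
            f = counts / (2.0 * n)
            if ll - prev < tol and np.isfinite(prev):
                converged = True
                break
            prev = ll
        result = (history[-1], f.copy(), history, converged)
        modes.append(result)
        if best is None or result[0] > best[0] + 1e-12:
            best = result

    ambiguous = any(
        abs(m[0] - best[0]) < 1e-6 and np.max(np.abs(m[1] - best[1])) > 1e-3
        for m in modes
    )
    freqs = {h: float(best[1][hidx[h]]) for h in haps}
    return EMResult(
        freqs=freqs,
        loglik=float(best[0]),
        loglik_history=best[2],
        converged=best[3],
        ambiguous=ambiguous,
        n_used=n,
    )


# ---------------------------------------------------------------------------
# Pairwise LD
# ---------------------------------------------------------------------------


def _ld_from_hap_freqs(p_ab, p_a, p_b):
    """(D, D', r2) with the A/B labels being the tracked alleles."""
    D = p_ab - p_a * p_b
    qa, qb = 1 - p_a, 1 - p_b
    if D >= 0:
        dmax = min(p_a * qb, qa * p_b)
    else:
        dmax = min(p_a * p_b, qa * qb)
    dprime = abs(D) / dmax if dmax > 0 else 0.0
    denom = p_a * qa * p_b * qb
    r2 = D * D / denom if denom > 0 else 0.0
    return D, min(dprime, 1.0), min(r2, 1.0)


def pairwise_ld(
    genos_a: np.ndarray,
    genos_b: np.ndarray,
    name_a: str = "A",
    name_b: str = "B",
    ci_grid: int = 1001,
) -> LDPair:
    """Two-locus LD from unphased genotypes via EM.

    ``genos_a``/``genos_b`` are (n, 2) allele arrays for the two SNPs.  The
    tracked allele at each locus is the lexicographically first label.  The
    D' 90% CI integrates the profile multinomial likelihood (allele
    frequencies held at their estimates) over a grid on [0, 1].
    """
    n = genos_a.shape[0]
    stacked = np.empty((n, 2, 2), dtype=object)
    stacked[:, 0, :] = genos_a
    stacked[:, 1, :] = genos_b
    alleles_a = sorted({a for a in genos_a.ravel() if a is not None})
    alleles_b = sorted({b for b in genos_b.ravel() if b is not None})
    if len(alleles_a) < 2 or len(alleles_b) < 2:
        raise ValueError("monomorphic SNP in pairwise_ld")
    A, B = alleles_a[0], alleles_b[0]

    em = em_haplotype_freqs(stacked, n_starts=3)
    p_a = sum(f for h, f in em.freqs.items() if h[0] == A)
    p_b = sum(f for h, f in em.freqs.items() if h[1] == B)
    p_ab = em.freqs.get((A, B), 0.0)
    D, dprime, r2 = _ld_from_hap_freqs(p_ab, p_a, p_b)

    # profile likelihood of D' on a grid, allele freqs fixed
    qa, qb = 1 - p_a, 1 - p_b
    sign = 1.0 if D >= 0 else -1.0
    dmax = min(p_a * qb, qa * p_b) if D >= 0 else min(p_a * p_b, qa * qb)
    grid = np.linspace(0.0, 1.0, ci_grid)

    # genotype class counts for the likelihood
    uniq: dict[tuple, int] = {}
    for i in range(n):
        if any(x is None for x in (*genos_a[i], *genos_b[i])):
            continue
        key = (tuple(sorted(genos_a[i])), tuple(sorted(genos_b[i])))
        uniq[key] = uniq.get(key, 0) + 1
    pair_lists = {
        g: _compatible_pairs(g) for g in uniq
    }

    lls = np.empty(ci_grid)
    for gi, dp in enumerate(grid):
        Dg = sign * dp * dmax
        fAB = max(p_a * p_b + Dg, 0.0)
        fAb = max(p_a * qb - Dg, 0.0)
        faB = max(qa * p_b - Dg, 0.0)
        fab = max(qa * qb + Dg, 0.0)
        hf = {}
        for ha in alleles_a:
            for hb in alleles_b:
                if ha == A and hb == B:
                    hf[(ha, hb)] = fAB
                elif ha == A:
                    hf[(ha, hb)] = fAb
                elif hb == B:
                    hf[(ha, hb)] = faB
                else:
                    hf[(ha, hb)] = fab
        ll = 0.0
        for g, c in uniq.items():
            tot = 0.0
            for h1, h2 in pair_lists[g]:
                w = hf.get(h1, 0.0) * hf.get(h2, 0.0)
                if h1 != h2:
                    w *= 2.0
                tot += w
            ll += c * np.log(max(tot, 1e-300))
        lls[gi] = ll
    w = np.exp(lls - lls.max())
    w /= w.sum()
    cum = np.cumsum(w)
    ci_low = float(grid[int(np.searchsorted(cum, 0.05))])
    ci_high = float(grid[min(int(np.searchsorted(cum, 0.95)), ci_grid - 1)])
    ci_low = min(ci_low, dprime)
    ci_high = max(ci_high, dprime)
    return LDPair(name_a, name_b, float(D), float(dprime), float(r2),
                  ci_low, ci_high)


def ld_matrix(cohort: Cohort, snps: list[str]) -> dict[tuple[str, str], LDPair]:
    """All pairwise LD among ``snps`` (ordered as given)."""
    genos = {s: extract_genotypes(cohort, [s])[:, 0, :] for s in snps}
    out = {}
    for i, a in enumerate(snps):
        for b in snps[i + 1:]:
            out[(a, b)] = pairwise_ld(genos[a], genos[b], a, b)
    return out


# ---------------------------------------------------------------------------
# Blocks and tags
# ---------------------------------------------------------------------------


def gabriel_blocks(
    ld_pairs: dict[tuple[str, str], LDPair],
    snps: list[str],
    maf_threshold: float = 0.05,
    mafs: dict[str, float] | None = None,
) -> list[list[str]]:
    """Confidence-interval haplotype blocks over an ordered SNP list.

    Markers with MAF below ``maf_threshold`` are ignored.  Non-overlapping
    blocks are chosen longest-first.
    """
    mafs = mafs or {}
    keep = [s for s in snps if mafs.get(s, 1.0) >= maf_threshold]
    idx = {s: i for i, s in enumerate(keep)}

    def pair(a, b):
        return ld_pairs.get((a, b)) or ld_pairs.get((b, a))

    candidates = []
    for i in range(len(keep)):
        for j in range(i + 1, len(keep)):
            outer = pair(keep[i], keep[j])
            if outer is None or not outer.strong_ld:
                continue
            informative = strong = 0
            for a in range(i, j + 1):
                for b in range(a + 1, j + 1):
                    p = pair(keep[a], keep[b])
                    if p is None or not p.informative:
                        continue
                    informative += 1
                    if p.strong_ld:
                        strong += 1
            if informative == 0:
                continue
            if strong / informative >= 0.95:
                candidates.append((i, j))
    candidates.sort(key=lambda ij: (-(ij[1] - ij[0]), ij[0]))
    taken = np.zeros(len(keep), dtype=bool)
    blocks = []
    for i, j in candidates:
        if taken[i:j + 1].any():
            continue
        taken[i:j + 1] = True
        blocks.append(keep[i:j + 1])
    blocks.sort(key=lambda b: idx[b[0]])
    return blocks


def select_tags(
    r2_matrix: pd.DataFrame,
    threshold: float = 0.8,
    positions: dict[str, float] | None = None,
) -> tuple[list[str], dict[str, list[str]]]:
    """Greedy tag-SNP selection at an r2 redundancy threshold.

    Repeatedly picks the SNP capturing the most not-yet-captured SNPs
    (itself included) at r2 > ``threshold``; ties break toward the lower map
    position (then input order).  Every SNP ends up captured by >= 1 tag.
    """
    snps = list(r2_matrix.index)
    positions = positions or {s: float(i) for i, s in enumerate(snps)}
    uncaptured = set(snps)
    tags: list[str] = []
    capture: dict[str, list[str]] = {}
    while uncaptured:
        def captures(s):
            return {
                t for t in uncaptured
                if t == s or float(r2_matrix.loc[s, t]) > threshold
            }
        best = min(
            snps,
            key=lambda s: (-len(captures(s)), positions[s], snps.index(s)),
        )
        got = captures(best)
        tags.append(best)
        capture[best] = sorted(got, key=snps.index)
        uncaptured -= got
    return tags, capture


# ---------------------------------------------------------------------------
# Family-aware haplotype dosages (zero-recombination within the cluster)
# ---------------------------------------------------------------------------


def _hap_pair_consistent(h1, h2, geno) -> bool:
    for k in range(len(geno)):
        if tuple(sorted((h1[k], h2[k]))) != tuple(sorted(geno[k])):
            return False
    return True


def _parent_pair_candidates(geno, haps, freqs):
    """Ordered haplotype pairs with prior weights for one parent."""
    out = []
    for h1 in haps:
        for h2 in haps:
            w = freqs[h1] * freqs[h2]
            if w <= 0:
                continue
            if geno is not None and not _hap_pair_consistent(h1, h2, geno):
                continue
            out.append(((h1, h2), w))
    return out


def family_haplotype_dosage(
    sib_genos: dict[str, tuple | None],
    father_geno,
    mother_geno,
    hap_freqs: dict[tuple, float],
    father_id: str | None = None,
    mother_id: str | None = None,
):
    """Posterior expected haplotype copy counts for one nuclear family.

    ``sib_genos`` maps sib id -> tuple of per-site allele pairs (or None for
    an ungenotyped sib); parent genotypes likewise.  Assumes no recombination
    within the cluster.  Returns (dosages, map_pairs, flagged) where dosages
    maps individual id -> {haplotype: expected copies}; parents are included
    under ``father_id``/``mother_id`` when given.  With no consistent
    configuration the family is flagged and the population-frequency prior
    (dosage = 2 * freq) is returned.
    """
    haps = [h for h, f in hap_freqs.items() if f > 0]
    fa_cands = _parent_pair_candidates(father_geno, haps, hap_freqs)
    mo_cands = _parent_pair_candidates(mother_geno, haps, hap_freqs)
    sibs = list(sib_genos)

    def child_lik_and_post(geno, fp, mp):
        """(likelihood, posterior over the 4 transmitted pairs)."""
        post = np.zeros(4)
        for t, (a, b) in enumerate(itertools.product((0, 1), (0, 1))):
            pair = (fp[a], mp[b])
            if geno is None or _hap_pair_consistent(pair[0], pair[1], geno):
                post[t] = 0.25
        lik = post.sum()
        return lik, post

    Z = 0.0
    dos = {iid: {h: 0.0 for h in haps} for iid in sibs}
    pair_mass: dict[str, dict] = {iid: {} for iid in sibs}
    parent_dos = {pid: {h: 0.0 for h in haps} for pid in (father_id, mother_id) if pid}
    parent_pair_mass = {pid: {} for pid in (father_id, mother_id) if pid}

    for fp, wf in fa_cands:
        for mp, wm in mo_cands:
            liks = []
            posts = []
            ok = True
            for iid in sibs:
                lik, post = child_lik_and_post(sib_genos[iid], fp, mp)
                if lik <= 0:
                    ok = False
                    break
                liks.append(lik)
                posts.append(post)
            if not ok:
                continue
            w = wf * wm * float(np.prod(liks))
            Z += w
            if father_id:
                for h in fp:
                    parent_dos[father_id][h] += w
                key = tuple(sorted(fp))
                parent_pair_mass[father_id][key] = (
                    parent_pair_mass[father_id].get(key, 0.0) + w
                )
            if mother_id:
                for h in mp:
                    parent_dos[mother_id][h] += w
                key = tuple(sorted(mp))
                parent_pair_mass[mother_id][key] = (
                    parent_pair_mass[mother_id].get(key, 0.0) + w
                )
            for s_i, iid in enumerate(sibs):
                post = posts[s_i] / liks[s_i]
                for t, (a, b) in enumerate(itertools.product((0, 1), (0, 1))):
                    if post[t] <= 0:
                        continue
                    pw = w * post[t]
                    pair = (fp[a], mp[b])
                    dos[iid][pair[0]] += pw
                    dos[iid][pair[1]] += pw
                    key = tuple(sorted(pair))
                    pair_mass[iid][key] = pair_mass[iid].get(key, 0.0) + pw

    if Z <= 0:
        fallback = {h: 2.0 * f for h, f in hap_freqs.items() if f > 0}
        out = {iid: dict(fallback) for iid in sibs}
        for pid in parent_dos:
            out[pid] = dict(fallback)
        return out, {}, True

    out = {}
    map_pairs = {}
    for iid in sibs:
        out[iid] = {h: v / Z for h, v in dos[iid].items()}
        if pair_mass[iid]:
            map_pairs[iid] = max(pair_mass[iid], key=pair_mass[iid].get)
    for pid in parent_dos:
        out[pid] = {h: v / Z for h, v in parent_dos[pid].items()}
        if parent_pair_mass[pid]:
            map_pairs[pid] = max(parent_pair_mass[pid], key=parent_pair_mass[pid].get)
    return out, map_pairs, False


def cohort_haplotype_dosages(
    cohort: Cohort,
    snps: list[str],
    hap_freqs: dict[tuple, float] | None = None,
) -> HaplotypeSet:
    """Family-aware haplotype dosages for every individual in the cohort.

    When ``hap_freqs`` is None they are estimated by EM from the cohort's
    unphased genotypes first.
    """
    if len(snps) > 6:
        raise ValueError("exact family phasing supports at most 6 SNPs")
    if hap_freqs is None:
        hap_freqs = em_haplotype_freqs(extract_genotypes(cohort, snps)).freqs
    haps = sorted(h for h, f in hap_freqs.items() if f > 0)

    def geno_of(iid):
        if iid is None:
            return None
        gs = tuple(cohort.genotype(iid, s) for s in snps)
        if any(g is None for g in gs):
            return None
        return gs

    rows = {}
    map_pairs = {}
    flagged = []
    for fam in cohort.families:
        sib_genos = {s: geno_of(s) for s in fam.sib_ids}
        dosages, mp, flag = family_haplotype_dosage(
            sib_genos,
            geno_of(fam.father_id),
            geno_of(fam.mother_id),
            hap_freqs,
            father_id=fam.father_id,
            mother_id=fam.mother_id,
        )
        if flag:
            flagged.append(fam.family_id)
        rows.update(dosages)
        map_pairs.update(mp)

    labels = ["".join(h) for h in haps]
    df = pd.DataFrame(
        [[rows.get(iid, {}).get(h, np.nan) for h in haps] for iid in cohort.iids],
        index=pd.Index(cohort.iids, name="iid"),
        columns=labels,
    )
    return HaplotypeSet(
        snps=list(snps),
        freqs={h: hap_freqs[h] for h in haps},
        dosages=df,
        map_pairs=map_pairs,
        flagged_families=flagged,
    )


# ---------------------------------------------------------------------------
# Haplotype association
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeAssocReport:
    per_haplotype: pd.DataFrame
    combinations: pd.DataFrame | None
    p_trend: float | None
    collinearity_note: str = (
        "dosages of all haplotypes sum to 2 per individual; the last "
        "haplotype's effect is determined by the others"
    )


def haplotype_assoc(
    cohort: Cohort,
    outcome: str | pd.Series,
    hapset: HaplotypeSet,
    covariates: list[str] | None = None,
    binary: bool = False,
    min_freq: float = 0.05,
    disease: str | None = None,
    trait_for_ordering: str | None = None,
) -> HaplotypeAssocReport:
    """Association of each common haplotype's dosage with an outcome.

    One model per haplotype (dosage in place of the SNP count), restricted
    to haplotypes with frequency > ``min_freq``.  When ``disease`` and
    ``trait_for_ordering`` are given, a combination report is added: MAP
    haplotype pairs ordered by mean trait level, with a GEE trend test of
    disease across the ordered combinations.
    """
    from .association import gee_logistic_assoc, lmm_quant_assoc

    common = [
        "".join(h) for h, f in sorted(hapset.freqs.items()) if f > min_freq
    ]
    rows = []
    for lab in common:
        dosage = hapset.dosages[lab]
        if binary:
            r = gee_logistic_assoc(cohort, outcome, f"hap_{lab}", covariates,
                                   dosage=dosage)
        else:
            r = lmm_quant_assoc(cohort, outcome, f"hap_{lab}", covariates,
                                dosage=dosage)
        rows.append(
            {
                "haplotype": lab,
                "freq": hapset.freqs[tuple(lab)],
                "beta": r.beta,
                "se": r.se,
                "or": r.or_,
                "p": r.p,
                "n": r.n,
            }
        )
    per_hap = pd.DataFrame(rows, columns=["haplotype", "freq", "beta", "se",
                                          "or", "p", "n"])

    combos = None
    p_trend = None
    if disease is not None and trait_for_ordering is not None and hapset.map_pairs:
        tdf = cohort.traits.df
        combo_label = {
            iid: "/".join(sorted(("".join(a), "".join(b))))
            for iid, (a, b) in hapset.map_pairs.items()
        }
        recs = []
        for iid, lab in combo_label.items():
            if iid not in tdf.index:
                continue
            recs.append(
                {
                    "iid": iid,
                    "combo": lab,
                    "trait": tdf.loc[iid, trait_for_ordering],
                    "disease": tdf.loc[iid, disease],
                }
            )
        cdf = pd.DataFrame(recs)
        grp = cdf.groupby("combo").agg(
            n=("iid", "size"),
            mean_trait=("trait", "mean"),
            prevalence=("disease", "mean"),
        ).sort_values("mean_trait")
        grp["order"] = np.arange(len(grp))
        combos = grp.reset_index()
        score = cdf["combo"].map(grp["order"]).astype(float)
        if cdf["disease"].nunique() > 1 and score.nunique() > 1:
            score_ser = pd.Series(score.to_numpy(), index=cdf["iid"].to_numpy())
            r = gee_logistic_assoc(
                cohort, disease, "combo_trend", covariates, dosage=score_ser
            )
            p_trend = r.p
    return HaplotypeAssocReport(per_hap, combos, p_trend)
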