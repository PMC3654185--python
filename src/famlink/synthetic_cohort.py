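"""Synthetic nuclear-family cohorts with known genetic architecture.

Gene-dropping simulator producing cohorts with the statistical structure the
downstream analyses assume: founder haplotypes with a specified LD cluster,
Mendelian transmission with Haldane (no-interference) recombination, an
additive/genotype-mean QTL plus a sibship-shared polygenic term, and an
age-dependent binary disease generated from a liability with a Gompertz-like
onset hazard.  A single seeded generator drives every draw, so a config's
seed fully determines the output.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_data import Cohort, Individual, Marker, TraitTable, _build_families
from .ibd import haldane_theta

__all__ = [
    "MarkerSpec",
    "ClusterSpec",
    "QtlSpec",
    "DiseaseSpec",
    "SimConfig",
    "simulate_founder_haplotypes",
    "two_snp_haplotype_freqs",
    "simulate_cohort",
    "default_paper_config",
    "simple_qtl_config",
    "cluster_genetic_variance",
    "validate_mendelian",
    "tune_disease_prevalence",
    "true_ibd_matrices",
]


@dataclass(frozen=True)
class MarkerSpec:
    name: str
    position_cM: float
    alleles: tuple[str, ...]
    freqs: tuple[float, ...]
    kind: str = "snp"

    def __post_init__(self):
        if abs(sum(self.freqs) - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: freqs sum to {sum(self.freqs)}")
        if len(self.alleles) != len(self.freqs) or len(self.alleles) < 2:
            raise ValueError(f"{self.name}: bad allele/freq spec")


@dataclass(frozen=True)
class ClusterSpec:
    """Joint haplotype distribution over a set of tightly linked SNPs."""

    snp_names: tuple[str, ...]
    haplotype_freqs: dict[tuple[str, ...], float] = field(default_factory=dict)

    def __post_init__(self):
        tot = sum(self.haplotype_freqs.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"cluster haplotype freqs sum to {tot}")
        for h in self.haplotype_freqs:
            if len(h) != len(self.snp_names):
                raise ValueError(f"haplotype {h} length != {len(self.snp_names)}")

    def snp_alleles(self, k: int) -> tuple[str, ...]:
        return tuple(sorted({h[k] for h in self.haplotype_freqs}))


@dataclass(frozen=True)
class QtlSpec:
    """Trait effect of the QTL SNP (and optional secondary SNP effects)."""

    snp: str
    effect_allele: str
    beta: float = 0.0
    genotype_means: tuple[float, float, float] | None = None  # overrides beta
    extra_betas: dict[str, tuple[str, float]] = field(default_factory=dict)

    def mean_contribution(self, dosages: dict[str, float]) -> float:
        g = dosages[self.snp]
        if self.genotype_means is not None:
            out = self.genotype_means[int(round(g))]
        else:
            out = self.beta * g
        for snp, (_, b) in self.extra_betas.items():
            out += b * dosages[snp]
        return out


@dataclass(frozen=True)
class DiseaseSpec:
    """Liability + Gompertz-like onset hazard.

    hazard(age) = base_hazard * exp(age_slope * age + liability) with
    liability = w_trait * z_qtl + w_polygenic * z_poly + w_admixture * m
                + sigma_liability * N(0, 1).
    """

    w_trait: float = 0.8
    w_polygenic: float = 0.5
    w_admixture: float = 0.0
    sigma_liability: float = 1.0
    base_hazard: float = 2e-4
    age_slope: float = 0.07


@dataclass(frozen=True)
class SimConfig:
    n_families: int
    sib_dist: dict[int, float]
    markers: tuple[MarkerSpec, ...]
    cluster: ClusterSpec | None = None
    qtl: QtlSpec | None = None
    mu: float = 0.0
    sigma2_g: float = 0.0
    sigma2_e: float = 1.0
    parent_genotyping_rate: float = 1.0
    disease: DiseaseSpec | None = None
    admixture_beta: tuple[float, float] = (1.0, 9.0)
    trait_nondiabetic_only: bool = False
    n_rep_full: int = 0
    n_rep_mixed: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.sigma2_g < 0 or self.sigma2_e < 0:
            raise ValueError("variance components must be nonnegative")
        if not (0 <= self.parent_genotyping_rate <= 1):
            raise ValueError("parent_genotyping_rate outside [0, 1]")
        tot = sum(self.sib_dist.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"sib_dist probabilities sum to {tot}")
        pos = [m.position_cM for m in self.markers]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("marker positions must be strictly increasing")
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate marker names")
        if self.cluster is not None:
            for s in self.cluster.snp_names:
                if s not in names:
                    raise ValueError(f"cluster SNP {s} not in marker list")

    def validate(self) -> None:  # construction already validates
        self.__post_init__()


# ---------------------------------------------------------------------------
# Founder haplotypes and LD specs
# ---------------------------------------------------------------------------


def two_snp_haplotype_freqs(p_a: float, p_b: float, r2: float) -> dict[tuple[str, str], float]:
    """Two-SNP haplotype frequencies achieving a target r2 (positive D).

    Alleles are labelled A/a and B/b with frequencies p_a, p_b for the
    capital alleles.  Raises when the requested r2 is infeasible for the
    given allele frequencies.
    """
    if not (0 <= r2 <= 1):
        raise ValueError("r2 outside [0, 1]")
    D = math.sqrt(r2 * p_a * (1 - p_a) * p_b * (1 - p_b))
    freqs = {
        ("A", "B"): p_a * p_b + D,
        ("A", "b"): p_a * (1 - p_b) - D,
        ("a", "B"): (1 - p_a) * p_b - D,
        ("a", "b"): (1 - p_a) * (1 - p_b) + D,
    }
    if any(f < -1e-12 for f in freqs.values()):
        raise ValueError(
            f"infeasible LD spec: r2={r2} incompatible with p_a={p_a}, p_b={p_b}"
        )
    return {h: max(f, 0.0) for h, f in freqs.items()}


def simulate_founder_haplotypes(ld_spec, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` founder haplotypes over a SNP cluster.

    ``ld_spec`` is either a :class:`ClusterSpec`, a mapping
    haplotype-tuple -> frequency, or a dict ``{"p_a", "p_b", "r2"}`` for a
    two-SNP spec.  Returns an (n, L) array of allele labels.
    """
    if isinstance(ld_spec, ClusterSpec):
        freqs = ld_spec.haplotype_freqs
    elif isinstance(ld_spec, dict) and "r2" in ld_spec:
        freqs = two_snp_haplotype_freqs(ld_spec["p_a"], ld_spec["p_b"], ld_spec["r2"])
    else:
        freqs = dict(ld_spec)
        tot = sum(freqs.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {tot}")
    haps = sorted(freqs)
    p = np.array([freqs[h] for h in haps], dtype=float)
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(haps), size=n, p=p)
    return np.array([haps[i] for i in idx], dtype=object)


def empirical_r2(pool: np.ndarray, i: int, j: int) -> float:
    """Empirical haplotype r2 between cluster columns i and j of a pool."""
    a = pool[:, i]
    b = pool[:, j]
    ai = sorted(set(a))[0]
    bi = sorted(set(b))[0]
    x = (a == ai).astype(float)
    y = (b == bi).astype(float)
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def _draw_founder_haplotype(config: SimConfig, rng, cluster_haps, cluster_p) -> np.ndarray:
    """One gamete across all markers: cluster SNPs jointly, others independent."""
    hap = np.empty(len(config.markers), dtype=object)
    cluster_cols = (
        {s: k for k, s in enumerate(config.cluster.snp_names)} if config.cluster else {}
    )
    chap = None
    if config.cluster is not None:
        chap = cluster_haps[rng.choice(len(cluster_haps), p=cluster_p)]
    for j, mk in enumerate(config.markers):
        if mk.name in cluster_cols:
            hap[j] = chap[cluster_cols[mk.name]]
        else:
            hap[j] = mk.alleles[rng.choice(len(mk.alleles), p=np.asarray(mk.freqs))]
    return hap


def _meiosis(hap_pair: tuple[np.ndarray, np.ndarray], thetas: np.ndarray, rng):
    """Recombine a parent's two haplotypes into one gamete (Haldane).

    Returns (gamete, source) where source[j] in {0, 1} records which parental
    haplotype was transmitted at marker j (kept for IBD oracles).
    """
    L = len(hap_pair[0])
    which = np.empty(L, dtype=int)
    which[0] = rng.integers(2)
    flips = rng.random(L - 1) < thetas
    for j in range(1, L):
        which[j] = which[j - 1] ^ int(flips[j - 1])
    out = np.empty(L, dtype=object)
    for j in range(L):
        out[j] = hap_pair[which[j]][j]
    return out, which


def simulate_cohort(config: SimConfig) -> Cohort:
    """Simulate a full cohort (pedigree, genotypes, traits, disease).

    The returned :class:`Cohort` carries a trait table with columns trait,
    affected, age_last_exam, age_onset, sex, birth_year, admixture, stratum.
    """
    rng = np.random.default_rng(config.seed)
    markers = [
        Marker(
            m.name, m.position_cM, m.alleles, np.asarray(m.freqs), "11",
            m.kind, bp=int(round(m.position_cM * 1e4)),
        )
        for m in config.markers
    ]
    pos = np.array([m.position_cM for m in config.markers])
    thetas = np.array([haldane_theta(d) for d in np.diff(pos)])

    cluster_haps = cluster_p = None
    if config.cluster is not None:
        items = sorted(config.cluster.haplotype_freqs.items())
        cluster_haps = [h for h, _ in items]
        cluster_p = np.array([f for _, f in items])
        cluster_p = cluster_p / cluster_p.sum()

    sib_sizes = sorted(config.sib_dist)
    sib_p = np.array([config.sib_dist[s] for s in sib_sizes], dtype=float)

    sg = math.sqrt(config.sigma2_g) if config.sigma2_g > 0 else 0.0
    se = math.sqrt(config.sigma2_e) if config.sigma2_e > 0 else 0.0

    # analytic standardization for the liability's QTL term
    qtl_mean = qtl_sd = None
    if config.qtl is not None and config.cluster is not None and (
        config.qtl.snp in config.cluster.snp_names
    ):
        qtl_mean, qv = cluster_genetic_variance(config.cluster, config.qtl)
        qtl_sd = math.sqrt(qv) if qv > 0 else 1.0

    individuals: list[Individual] = []
    geno_rows: list[np.ndarray] = []
    hap_store: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    trows: list[dict] = []

    def qtl_value(haps) -> float:
        if config.qtl is None:
            return 0.0
        dos = {}
        need = [config.qtl.snp] + list(config.qtl.extra_betas)
        idx = {m.name: j for j, m in enumerate(config.markers)}
        for snp in need:
            j = idx[snp]
            eff = (
                config.qtl.effect_allele if snp == config.qtl.snp
                else config.qtl.extra_betas[snp][0]
            )
            dos[snp] = (haps[0][j] == eff) + (haps[1][j] == eff)
        return config.qtl.mean_contribution(dos)

    def genotype_row(haps, genotyped=True, only_cluster=False) -> np.ndarray:
        row = np.empty((len(config.markers), 2), dtype=object)
        cluster_names = set(config.cluster.snp_names) if config.cluster else set()
        for j, mk in enumerate(config.markers):
            if not genotyped or (only_cluster and mk.name not in cluster_names):
                row[j] = (None, None)
            else:
                a, b = haps[0][j], haps[1][j]
                row[j] = (a, b) if a <= b else (b, a)
        return row

    def disease_draw(liab_core: float, age_last: float):
        """Returns (affected, age_onset)."""
        d = config.disease
        ell = liab_core + d.sigma_liability * rng.standard_normal()
        E = rng.exponential()
        # solve Lambda(t) = E with Lambda(t) = lam0/b * exp(ell) * (exp(b t)-1)
        arg = 1.0 + d.age_slope * E * math.exp(-ell) / d.base_hazard
        onset = math.log(arg) / d.age_slope
        if onset <= age_last:
            return 1, onset
        return 0, np.nan

    def add_person(iid, fid, father, mother, haps, sex, age_last, a_poly, m_admix,
                   stratum, genotyped=True, only_cluster=False):
        individuals.append(
            Individual(iid, fid, father, mother, sex,
                       founder_flag=(father is None and mother is None))
        )
        geno_rows.append(genotype_row(haps, genotyped, only_cluster))
        qv = qtl_value(haps)
        y = config.mu + qv + a_poly + se * rng.standard_normal()
        affected, onset = 0, np.nan
        if config.disease is not None:
            if qtl_sd is not None:
                zq = (qv - qtl_mean) / qtl_sd
            else:
                zq = 0.0
            zg = a_poly / sg if sg > 0 else 0.0
            liab = (
                config.disease.w_trait * zq
                + config.disease.w_polygenic * zg
                + config.disease.w_admixture * m_admix
            )
            affected, onset = disease_draw(liab, age_last)
        trait_val = y
        if config.trait_nondiabetic_only and affected:
            draw_age = age_last - rng.uniform(0.0, 20.0)
            if onset <= draw_age:
                trait_val = np.nan
        trows.append(
            {
                "iid": iid,
                "trait": trait_val,
                "affected": affected,
                "age_last_exam": age_last,
                "age_onset": onset,
                "sex": sex,
                "birth_year": 2000 - age_last,
                "admixture": m_admix,
                "stratum": stratum,
            }
        )

    for f in range(config.n_families):
        fid = f"F{f + 1:04d}"
        n_sibs = sib_sizes[rng.choice(len(sib_sizes), p=sib_p)]
        m_admix = float(rng.beta(*config.admixture_beta))
        parents = {}
        for tag, sex in (("P1", "male"), ("P2", "female")):
            haps = (
                _draw_founder_haplotype(config, rng, cluster_haps, cluster_p),
                _draw_founder_haplotype(config, rng, cluster_haps, cluster_p),
            )
            a_poly = sg * rng.standard_normal()
            genotyped = bool(rng.random() < config.parent_genotyping_rate)
            age = float(rng.uniform(50, 85))
            add_person(f"{fid}_{tag}", fid, None, None, haps, sex, age,
                       a_poly, m_admix, "linkage", genotyped=genotyped)
            parents[tag] = {"haps": haps, "a": a_poly}
        for s in range(n_sibs):
            pat, pat_src = _meiosis(parents["P1"]["haps"], thetas, rng)
            mat, mat_src = _meiosis(parents["P2"]["haps"], thetas, rng)
            a_poly = 0.5 * (parents["P1"]["a"] + parents["P2"]["a"]) + (
                sg / math.sqrt(2.0)
            ) * rng.standard_normal()
            sex = "male" if rng.random() < 0.5 else "female"
            age = float(rng.uniform(25, 70))
            iid = f"{fid}_S{s + 1}"
            add_person(iid, fid, f"{fid}_P1", f"{fid}_P2", (pat, mat), sex, age,
                       a_poly, m_admix, "linkage")
            hap_store[iid] = {"pat_src": pat_src, "mat_src": mat_src}

    for stratum, count, beta_m in (
        ("full_heritage", config.n_rep_full, (1.0, 19.0)),
        ("mixed_heritage", config.n_rep_mixed, (2.0, 4.0)),
    ):
        for r in range(count):
            fid = f"R{stratum[0].upper()}{r + 1:05d}"
            haps = (
                _draw_founder_haplotype(config, rng, cluster_haps, cluster_p),
                _draw_founder_haplotype(config, rng, cluster_haps, cluster_p),
            )
            m_admix = float(rng.beta(*beta_m))
            sex = "male" if rng.random() < 0.5 else "female"
            age = float(rng.uniform(20, 80))
            a_poly = sg * rng.standard_normal()
            iid = f"{fid}_1"
            add_person(iid, fid, None, None, haps, sex, age, a_poly, m_admix,
                       stratum, only_cluster=True)
            # replication samples have no trait measurement
            trows[-1]["trait"] = np.nan

    genotypes = np.stack(geno_rows) if geno_rows else np.empty((0, len(markers), 2), dtype=object)
    families = _build_families(individuals)
    cohort = Cohort(individuals, families, markers, genotypes)
    tdf = pd.DataFrame(trows).set_index("iid")
    cohort.attach_traits(TraitTable(tdf))
    cohort.true_sib_haplotypes = hap_store  # for oracle checks
    return cohort


def true_ibd_matrices(cohort: Cohort, position_cM: float) -> dict[str, np.ndarray]:
    """Exact IBD sharing among sibs at a position from stored meiosis sources.

    Requires the cohort to come from :func:`simulate_cohort` (which records
    which parental haplotype each meiosis transmitted at every marker).
    Evaluated at the marker nearest the position.
    """
    srcs = cohort.true_sib_haplotypes
    pos = np.array([m.position_cM for m in cohort.markers])
    j = int(np.argmin(np.abs(pos - position_cM)))
    out = {}
    for fam in cohort.families:
        sibs = [s for s in fam.sib_ids if s in srcs]
        if len(sibs) < 2:
            continue
        n = len(sibs)
        M = np.eye(n)
        for a in range(n):
            for b in range(a + 1, n):
                sa, sb = srcs[sibs[a]], srcs[sibs[b]]
                share = int(sa["pat_src"][j] == sb["pat_src"][j]) + int(
                    sa["mat_src"][j] == sb["mat_src"][j]
                )
                M[a, b] = M[b, a] = share / 2.0
        out[fam.family_id] = M
    return out


# ---------------------------------------------------------------------------
# Canned configurations
# ---------------------------------------------------------------------------


def cluster_genetic_variance(cluster: ClusterSpec, qtl: QtlSpec) -> tuple[float, float]:
    """Exact mean and variance of the cluster's trait contribution.

    Enumerates ordered haplotype pairs under random mating (HWE at the
    haplotype level).
    """
    items = sorted(cluster.haplotype_freqs.items())
    idx = {s: k for k, s in enumerate(cluster.snp_names)}
    mean = 0.0
    m2 = 0.0
    for (h1, f1), (h2, f2) in itertools.product(items, items):
        w = f1 * f2
        if w == 0:
            continue
        dos = {}
        need = [qtl.snp] + list(qtl.extra_betas)
        for snp in need:
            k = idx[snp]
            eff = qtl.effect_allele if snp == qtl.snp else qtl.extra_betas[snp][0]
            dos[snp] = (h1[k] == eff) + (h2[k] == eff)
        v = qtl.mean_contribution(dos)
        mean += w * v
        m2 += w * v * v
    return mean, m2 - mean * mean


def simple_qtl_config(
    n_families: int = 500,
    n_sibs: int = 3,
    sigma2_q: float = 0.5,
    sigma2_g: float = 0.2,
    sigma2_e: float = 0.3,
    qtl_maf: float = 0.5,
    qtl_position: float = 50.0,
    n_flank_microsats: int = 4,
    microsat_alleles: int = 20,
    span_cM: float = 100.0,
    seed: int = 0,
    parent_genotyping_rate: float = 1.0,
    disease: DiseaseSpec | None = None,
    second_independent_qtl: bool = False,
    null_snp: bool = False,
) -> SimConfig:
    """A sibship design with one additive biallelic QTL.

    The QTL's variance contribution is sigma2_q = 2 p q beta^2, so beta is
    chosen as sqrt(sigma2_q / (2 p q)).  A fully informative multiallelic
    marker sits at the QTL position (equifrequent ``microsat_alleles``
    alleles), with further microsatellites spread over ``span_cM``.
    ``second_independent_qtl`` adds a SNP "QTL2" right at the QTL position
    with founder alleles independent of "QTL" (for coincident-linkage
    designs); ``null_snp`` adds an unassociated SNP "NULLSNP" at the far end
    of the map.
    """
    beta = (
        math.sqrt(sigma2_q / (2.0 * qtl_maf * (1 - qtl_maf))) if sigma2_q > 0 else 0.0
    )
    ms_alleles = tuple(str(a + 1) for a in range(microsat_alleles))
    ms_freqs = tuple(1.0 / microsat_alleles for _ in range(microsat_alleles))
    specs = []
    if n_flank_microsats > 0:
        grid = np.linspace(0.0, span_cM, n_flank_microsats)
    else:
        grid = np.array([])
    k = 0
    for p in grid:
        if abs(p - qtl_position) < 1e-9:
            continue
        k += 1
        specs.append(MarkerSpec(f"MS{k}", float(p), ms_alleles, ms_freqs, "microsat"))
    specs.append(
        MarkerSpec("MS_QTL", qtl_position, ms_alleles, ms_freqs, "microsat")
    )
    specs.append(
        MarkerSpec(
            "QTL", qtl_position + 1e-3, ("A", "a"),
            (qtl_maf, 1 - qtl_maf), "snp",
        )
    )
    if second_independent_qtl:
        specs.append(
            MarkerSpec("QTL2", qtl_position + 2e-3, ("B", "b"), (0.5, 0.5), "snp")
        )
    if null_snp:
        far = max(span_cM, qtl_position) + 150.0  # effectively unlinked
        specs.append(MarkerSpec("NULLSNP", far, ("C", "c"), (0.5, 0.5), "snp"))
    specs = sorted(specs, key=lambda m: m.position_cM)
    return SimConfig(
        n_families=n_families,
        sib_dist={n_sibs: 1.0},
        markers=tuple(specs),
        cluster=None,
        qtl=QtlSpec(snp="QTL", effect_allele="A", beta=beta),
        mu=0.0,
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        parent_genotyping_rate=parent_genotyping_rate,
        disease=disease,
        seed=seed,
    )


# Default four-SNP cluster patterned after a promoter/coding tag-SNP set:
# minor-allele frequencies ~ (0.37, 0.08, 0.28, 0.13).
_DEFAULT_CLUSTER = ClusterSpec(
    snp_names=("tag1", "tag2", "tag3", "tag4"),
    haplotype_freqs={
        ("C", "G", "A", "A"): 0.13,
        ("T", "G", "G", "G"): 0.37,
        ("C", "G", "A", "G"): 0.15,
        ("C", "T", "G", "G"): 0.08,
        ("C", "G", "G", "G"): 0.27,
    },
)


def default_paper_config(seed: int = 0, variance_fraction: float = 0.51) -> SimConfig:
    """264 nuclear families (~966 members) with a 4-SNP trait-driving cluster.

    The strong SNP (tag2, MAF ~0.08) has genotype means ~ (15, 35, 80)
    enzyme units; the other cluster SNPs carry smaller additive effects.
    The environmental variance is calibrated analytically so the cluster
    accounts for ``variance_fraction`` (default 51%) of the trait variance.
    """
    qtl = QtlSpec(
        snp="tag2",
        effect_allele="T",
        genotype_means=(15.0, 35.0, 80.0),
        extra_betas={
            "tag1": ("T", 4.0),
            "tag3": ("G", 2.0),
            "tag4": ("G", 6.0),
        },
    )
    _, vq = cluster_genetic_variance(_DEFAULT_CLUSTER, qtl)
    total = vq / variance_fraction
    sigma2_g = 0.20 * total
    sigma2_e = max(total - vq - sigma2_g, 1e-6)

    ms_alleles = tuple(str(a + 1) for a in range(8))
    ms_freqs = tuple([0.25, 0.20, 0.15, 0.12, 0.10, 0.08, 0.06, 0.04])
    specs: list[MarkerSpec] = []
    for k, p in enumerate(np.arange(75.0, 176.0, 10.0), start=1):
        specs.append(MarkerSpec(f"D11S_{k}", float(p), ms_alleles, ms_freqs, "microsat"))
    cluster_pos = {"tag1": 130.90, "tag2": 130.95, "tag3": 131.00, "tag4": 131.05}
    for name, p in cluster_pos.items():
        k = list(_DEFAULT_CLUSTER.snp_names).index(name)
        alleles = _DEFAULT_CLUSTER.snp_alleles(k)
        af = sum(
            f for h, f in _DEFAULT_CLUSTER.haplotype_freqs.items() if h[k] == alleles[0]
        )
        specs.append(MarkerSpec(name, p, alleles, (af, 1 - af), "snp"))
    # background SNPs across the region for the association scan
    rng = np.random.default_rng(12345)  # marker-panel layout, not data
    for k, p in enumerate(np.arange(77.5, 174.0, 5.0), start=1):
        maf = float(rng.uniform(0.1, 0.5))
        specs.append(MarkerSpec(f"bg{k}", float(p), ("A", "G"), (maf, 1 - maf), "snp"))
    specs = sorted(specs, key=lambda m: m.position_cM)

    return SimConfig(
        n_families=264,
        sib_dist={1: 0.55, 2: 0.25, 3: 0.12, 4: 0.05, 5: 0.02, 6: 0.01},
        markers=tuple(specs),
        cluster=_DEFAULT_CLUSTER,
        qtl=qtl,
        mu=0.0,
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        parent_genotyping_rate=0.9,
        disease=DiseaseSpec(
            w_trait=0.6, w_polygenic=0.6, w_admixture=-0.5,
            sigma_liability=1.0, base_hazard=3.5e-3, age_slope=0.06,
        ),
        trait_nondiabetic_only=True,
        n_rep_full=300,
        n_rep_mixed=300,
        seed=seed,
    )


def tune_disease_prevalence(
    config: SimConfig,
    target: float = 0.4,
    min_age: float = 45.0,
    tol: float = 0.02,
    max_iter: int = 20,
    probe_families: int = 300,
    seed: int = 999,
) -> SimConfig:
    """Bisection on the baseline hazard to hit a target adult prevalence."""
    if config.disease is None:
        raise ValueError("config has no disease model")

    def prevalence(lam0: float) -> float:
        probe = replace(
            config,
            n_families=probe_families,
            n_rep_full=0,
            n_rep_mixed=0,
            disease=replace(config.disease, base_hazard=lam0),
            seed=seed,
        )
        coh = simulate_cohort(probe)
        df = coh.traits.df
        adults = df[df["age_last_exam"] >= min_age]
        return float(adults["affected"].mean())

    lo, hi = config.disease.base_hazard * 1e-3, config.disease.base_hazard * 1e3
    lam = config.disease.base_hazard
    for _ in range(max_iter):
        p = prevalence(lam)
        if abs(p - target) < tol:
            break
        if p < target:
            lo = lam
        else:
            hi = lam
        lam = math.sqrt(lo * hi)
    return replace(config, disease=replace(config.disease, base_hazard=lam))


# ---------------------------------------------------------------------------
# Independent Mendelian validator (used by property tests)
# ---------------------------------------------------------------------------


def validate_mendelian(cohort: Cohort) -> list[tuple[str, str, str]]:
    """Return (family, individual, marker) triples violating Mendelian rules.

    A child allele pair must be splittable into one allele present in each
    genotyped parent's genotype.  Works directly on the genotype matrix and
    shares no code with the IBD emission model.
    """
    errors = []
    for fam in cohort.families:
        for sib in fam.sib_ids:
            for mk in cohort.markers:
                child = cohort.genotype(sib, mk.name)
                if child is None:
                    continue
                fg = cohort.genotype(fam.father_id, mk.name) if fam.father_id else None
                mg = cohort.genotype(fam.mother_id, mk.name) if fam.mother_id else None
                ok = False
                for a, b in (child, (child[1], child[0])):
                    pa_ok = fg is None or a in fg
                    mb_ok = mg is None or b in mg
                    if pa_ok and mb_ok:
                        ok = True
                        break
                if not ok:
                    errors.append((fam.family_id, sib, mk.name))
    return errors
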