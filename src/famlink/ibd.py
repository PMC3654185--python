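"""Multipoint IBD estimation for nuclear families.

A hidden-Markov model over inheritance vectors: each non-founder (sib)
contributes two meiosis bits (paternal, maternal) selecting which parental
allele was transmitted.  Between adjacent positions each bit flips
independently with the Haldane recombination fraction, which is exactly the
no-interference assumption the Markov chain requires.  Posterior inheritance
distributions are marginalised to per-sib-pair IBD sharing probabilities
(P0, P1, P2) and pihat = P1/2 + P2.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import Cohort, NuclearFamily, allele_freqs_from_founders

logger = logging.getLogger(__name__)

__all__ = [
    "haldane_theta",
    "multipoint_ibd",
    "cohort_ibd",
    "expected_kinship",
    "IBDSurface",
    "default_grid",
]


def haldane_theta(d_cM: float) -> float:
    """Haldane map function: theta = (1 - exp(-2d/100)) / 2, in [0, 0.5)."""
    if d_cM < 0:
        raise ValueError(f"negative map distance: {d_cM}")
    theta = 0.5 * (1.0 - np.exp(-0.02 * d_cM))
    return float(min(theta, np.nextafter(0.5, 0.0)))  # keep the interval open


def expected_kinship(family: NuclearFamily, ids: list[str] | None = None) -> np.ndarray:
    """Expected relationship matrix 2*Phi for members of a nuclear family.

    1 on the diagonal, 0.5 for sib-sib and parent-offspring pairs, 0 between
    the two founders.  ``ids`` selects/orders the rows (default: parents then
    sibs).
    """
    if ids is None:
        ids = list(family.parent_ids) + list(family.sib_ids)
    parents = set(family.parent_ids)
    sibs = set(family.sib_ids)
    n = len(ids)
    K = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            ia, ib = ids[a], ids[b]
            if ia in parents and ib in parents:
                r = 0.0
            elif (ia in parents and ib in sibs) or (ia in sibs and ib in parents):
                r = 0.5
            elif ia in sibs and ib in sibs:
                r = 0.5
            else:
                r = 0.0
            K[a, b] = K[b, a] = r
    return K


@dataclass
class IBDSurface:
    """Per-family, per-sib-pair IBD sharing probabilities on a cM grid."""

    grid: np.ndarray  # (G,) evaluation positions in cM
    families: dict[str, dict] = field(default_factory=dict)
    # families[fid] = {"sibs": [...], "pairs": [(i, j) id tuples],
    #                  "probs": array (n_pairs, G, 3)}
    excluded_markers: dict[str, list[str]] = field(default_factory=dict)

    def add_family(self, fid: str, sibs: list[str], probs: np.ndarray) -> None:
        pairs = list(itertools.combinations(sibs, 2))
        if probs.shape != (len(pairs), len(self.grid), 3):
            raise ValueError("probs shape mismatch")
        self.families[fid] = {"sibs": list(sibs), "pairs": pairs, "probs": probs}

    def grid_index(self, position: float) -> int:
        k = int(np.argmin(np.abs(self.grid - position)))
        if abs(self.grid[k] - position) > 1e-6:
            raise ValueError(f"position {position} not on the IBD grid")
        return k

    def pair_probs(self, fid: str, id_a: str, id_b: str, position: float) -> np.ndarray:
        ent = self.families[fid]
        k = self.grid_index(position)
        for p, pair in enumerate(ent["pairs"]):
            if set(pair) == {id_a, id_b}:
                return ent["probs"][p, k]
        raise KeyError((fid, id_a, id_b))

    def pihat_matrix(self, fid: str, ids: list[str], position: float) -> np.ndarray:
        """Matrix of expected IBD sharing (pihat) among ``ids`` (sibs)."""
        ent = self.families[fid]
        k = self.grid_index(position)
        idx = {iid: i for i, iid in enumerate(ids)}
        M = np.eye(len(ids))
        for p, (a, b) in enumerate(ent["pairs"]):
            if a in idx and b in idx:
                p0, p1, p2 = ent["probs"][p, k]
                pihat = 0.5 * p1 + p2
                M[idx[a], idx[b]] = M[idx[b], idx[a]] = pihat
        return M

    def to_long_dataframe(self) -> pd.DataFrame:
        rows = []
        for fid, ent in sorted(self.families.items()):
            for p, (a, b) in enumerate(ent["pairs"]):
                for k, c in enumerate(self.grid):
                    p0, p1, p2 = ent["probs"][p, k]
                    rows.append(
                        (fid, a, b, float(c), p0, p1, p2, 0.5 * p1 + p2)
                    )
        return pd.DataFrame(
            rows,
            columns=["family", "id_a", "id_b", "cM", "p0", "p1", "p2", "pihat"],
        )


def default_grid(markers, step_cM: float = 1.0) -> np.ndarray:
    """Marker positions plus ``step_cM`` steps between adjacent markers."""
    pos = np.array([m.position_cM for m in markers], dtype=float)
    pts = set(np.round(pos, 9))
    for a, b in zip(pos, pos[1:]):
        x = a + step_cM
        while x < b - 1e-9:
            pts.add(round(x, 9))
            x += step_cM
    return np.array(sorted(pts))


# ---------------------------------------------------------------------------
# HMM internals
# ---------------------------------------------------------------------------


def _ordered_parent_genotypes(
    geno: tuple[str, str] | None, freqs: dict[str, float]
) -> list[tuple[tuple[str, str], float]]:
    """Ordered genotype hypotheses for one parent with prior weights.

    A genotyped parent contributes its (up to two) phase orderings with equal
    weight; an ungenotyped parent contributes every ordered genotype under
    HWE with founder allele-frequency weights.
    """
    if geno is not None:
        a, b = geno
        if a == b:
            return [((a, b), 1.0)]
        return [((a, b), 0.5), ((b, a), 0.5)]
    alleles = list(freqs)
    out = []
    for x in alleles:
        for y in alleles:
            w = freqs[x] * freqs[y]
            if w > 0:
                out.append(((x, y), w))
    return out


def _sib_bitvec(
    sib_geno: tuple[str, str] | None,
    father: tuple[str, str],
    mother: tuple[str, str],
) -> np.ndarray:
    """Indicator over the sib's 4 meiosis-bit combos (2*pat_bit + mat_bit)."""
    v = np.ones(4)
    if sib_geno is None:
        return v
    target = frozenset_pair(sib_geno)
    for pb in (0, 1):
        for mb in (0, 1):
            got = frozenset_pair((father[pb], mother[mb]))
            v[2 * pb + mb] = 1.0 if got == target else 0.0
    return v


def frozenset_pair(g: tuple[str, str]):
    return (g[0], g[1]) if g[0] <= g[1] else (g[1], g[0])


def _emission_vector(
    fam_genos: dict,
    sibs: list[str],
    freqs: dict[str, float],
) -> np.ndarray:
    """P(observed marker genotypes | inheritance vector), up to a constant.

    State index = sum_s digit_s * 4**s with digit_s = 2*pat_bit + mat_bit for
    sib s.  Sums over ordered parental genotype hypotheses.
    """
    S = len(sibs)
    E = np.zeros(4**S)
    for fo, wf in _ordered_parent_genotypes(fam_genos.get("father"), freqs):
        for mo, wm in _ordered_parent_genotypes(fam_genos.get("mother"), freqs):
            w = wf * wm
            vecs = [_sib_bitvec(fam_genos["sibs"][s], fo, mo) for s in range(S)]
            acc = vecs[S - 1]
            for s in range(S - 2, -1, -1):
                acc = np.kron(acc, vecs[s])
            E += w * acc
    return E


def _propagate(v: np.ndarray, theta: float, n_bits: int) -> np.ndarray:
    """Apply the per-meiosis symmetric bit-flip kernel to a state vector."""
    if theta == 0:
        return v
    T = np.array([[1 - theta, theta], [theta, 1 - theta]])
    t = v.reshape((2,) * n_bits)
    for axis in range(n_bits):
        t = np.tensordot(T, t, axes=([1], [axis]))
        t = np.moveaxis(t, 0, axis)
    return t.reshape(-1)


def multipoint_ibd(
    family: NuclearFamily,
    cohort: Cohort,
    grid_cM: np.ndarray | None = None,
    marker_names: list[str] | None = None,
    allele_freqs: dict[str, dict[str, float]] | None = None,
    max_sibs: int = 8,
) -> IBDSurface:
    """Forward-backward multipoint IBD for one nuclear family.

    Markers with a Mendelian inconsistency in this family (zero emission mass
    over all inheritance vectors) are excluded for the family, with a warning.
    """
    sibs = list(family.sib_ids)
    if len(sibs) > max_sibs:
        raise ValueError(f"family {family.family_id}: {len(sibs)} sibs > max_sibs={max_sibs}")
    markers = (
        [cohort.marker(n) for n in marker_names]
        if marker_names is not None
        else list(cohort.markers)
    )
    markers = sorted(markers, key=lambda m: m.position_cM)
    if grid_cM is None:
        grid_cM = default_grid(markers)
    grid_cM = np.asarray(grid_cM, dtype=float)

    S = len(sibs)
    n_states = 4**S
    n_bits = 2 * S

    # Per-marker emission vectors; drop Mendelian-inconsistent markers.
    excluded: list[str] = []
    used_markers: list = []
    emissions: list[np.ndarray] = []
    for mk in markers:
        freqs = allele_freqs[mk.name] if allele_freqs else allele_freqs_from_founders(cohort, mk.name)
        fam_genos = {
            "father": cohort.genotype(family.father_id, mk.name) if family.father_id else None,
            "mother": cohort.genotype(family.mother_id, mk.name) if family.mother_id else None,
            "sibs": [cohort.genotype(s, mk.name) for s in sibs],
        }
        E = _emission_vector(fam_genos, sibs, freqs)
        if E.sum() <= 0:
            excluded.append(mk.name)
            continue
        used_markers.append(mk)
        emissions.append(E)
    if excluded:
        warnings.warn(
            f"family {family.family_id}: Mendelian inconsistency at "
            f"{excluded}; marker(s) excluded for this family",
            stacklevel=2,
        )

    M = len(used_markers)
    uniform = np.full(n_states, 1.0 / n_states)

    if M == 0:
        post = np.tile(uniform, (len(grid_cM), 1))
    else:
        mpos = np.array([m.position_cM for m in used_markers])
        thetas = [haldane_theta(b - a) for a, b in zip(mpos, mpos[1:])]
        # forward (alpha includes emission at the marker), with scaling
        alpha = np.empty((M, n_states))
        a = uniform * emissions[0]
        alpha[0] = a / a.sum()
        for t in range(1, M):
            a = _propagate(alpha[t - 1], thetas[t - 1], n_bits) * emissions[t]
            alpha[t] = a / a.sum()
        beta = np.empty((M, n_states))
        beta[M - 1] = 1.0
        for t in range(M - 2, -1, -1):
            b = _propagate(beta[t + 1] * emissions[t + 1], thetas[t], n_bits)
            beta[t] = b / b.sum()

        post = np.empty((len(grid_cM), n_states))
        for k, c in enumerate(grid_cM):
            if c <= mpos[0]:
                p = _propagate(alpha[0] * beta[0], haldane_theta(mpos[0] - c), n_bits)
            elif c >= mpos[-1]:
                p = _propagate(alpha[M - 1] * beta[M - 1], haldane_theta(c - mpos[-1]), n_bits)
            else:
                t = int(np.searchsorted(mpos, c, side="right")) - 1
                if abs(c - mpos[t]) < 1e-12:
                    p = alpha[t] * beta[t]
                else:
                    left = _propagate(alpha[t], haldane_theta(c - mpos[t]), n_bits)
                    right = _propagate(
                        beta[t + 1] * emissions[t + 1],
                        haldane_theta(mpos[t + 1] - c),
                        n_bits,
                    )
                    p = left * right
            post[k] = p / p.sum()

    # Marginalise to pairwise IBD counts.
    pairs = list(itertools.combinations(range(S), 2))
    probs = np.zeros((len(pairs), len(grid_cM), 3))
    if pairs:
        states = np.arange(n_states)
        digits = (states[:, None] // (4 ** np.arange(S))[None, :]) % 4
        pat = digits // 2
        mat = digits % 2
        for p, (i, j) in enumerate(pairs):
            ibd = (pat[:, i] == pat[:, j]).astype(int) + (mat[:, i] == mat[:, j]).astype(int)
            for cnt in (0, 1, 2):
                probs[p, :, cnt] = post[:, ibd == cnt].sum(axis=1)

    surface = IBDSurface(grid=grid_cM)
    surface.add_family(family.family_id, sibs, probs)
    if excluded:
        surface.excluded_markers[family.family_id] = excluded
    return surface


def cohort_ibd(
    cohort: Cohort,
    grid_cM: np.ndarray | None = None,
    marker_names: list[str] | None = None,
    max_sibs: int = 8,
    step_cM: float = 1.0,
) -> IBDSurface:
    """Multipoint IBD for every family in the cohort with >= 2 sibs."""
    markers = (
        [cohort.marker(n) for n in marker_names]
        if marker_names is not None
        else list(cohort.markers)
    )
    if grid_cM is None:
        grid_cM = default_grid(sorted(markers, key=lambda m: m.position_cM), step_cM)
    freqs = {m.name: allele_freqs_from_founders(cohort, m.name) for m in markers}
    surface = IBDSurface(grid=np.asarray(grid_cM, dtype=float))
    for fam in cohort.families:
        if fam.n_sibs < 2:
            continue
        one = multipoint_ibd(
            fam, cohort, grid_cM=surface.grid,
            marker_names=[m.name for m in markers],
            allele_freqs=freqs, max_sibs=max_sibs,
        )
        surface.families[fam.family_id] = one.families[fam.family_id]
        surface.excluded_markers.update(one.excluded_markers)
    return surface
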