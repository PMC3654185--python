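import itertools

import numpy as np
import pytest

from famlink.core_data import Cohort, Individual, Marker, _build_families


def build_cohort(marker_defs, records, traits=None):
    """Construct a Cohort inline.

    marker_defs: list of (name, cM, alleles tuple[, kind])
    records: list of (fid, iid, pat, mat, sex, [genotype strings "a/b" or None])
    """
    markers = []
    for md in marker_defs:
        name, cm, alleles = md[0], md[1], tuple(md[2])
        kind = md[3] if len(md) > 3 else ("microsat" if len(alleles) > 2 else "snp")
        markers.append(Marker(name, cm, alleles, None, "1", kind))
    individuals = []
    rows = []
    for fid, iid, pat, mat, sex, genos in records:
        individuals.append(
            Individual(iid, fid, pat, mat, sex, founder_flag=(pat is None and mat is None))
        )
        row = np.empty((len(markers), 2), dtype=object)
        for j, g in enumerate(genos):
            if g is None:
                row[j] = (None, None)
            else:
                a, b = g.split("/")
                row[j] = (a, b)
        rows.append(row)
    genotypes = np.stack(rows) if rows else np.empty((0, len(markers), 2), dtype=object)
    cohort = Cohort(individuals, _build_families(individuals), markers, genotypes)
    if traits is not None:
        cohort.attach_traits(traits)
    return cohort


# ---------------------------------------------------------------------------
# Independent exhaustive-enumeration IBD oracle (test-only implementation).
# Enumerates every inheritance-vector path over the markers; shares no code
# with famlink.ibd.
# ---------------------------------------------------------------------------


def _oracle_emission(state, sibs_genos, father_geno, mother_geno, freqs, n_sibs):
    """P(marker genotypes | inheritance state), summing parental phases."""
    alleles = list(freqs)

    def parent_hyps(geno):
        if geno is not None:
            a, b = geno
            if a == b:
                return [((a, b), 1.0)]
            return [((a, b), 0.5), ((b, a), 0.5)]
        return [((x, y), freqs[x] * freqs[y]) for x in alleles for y in alleles]

    total = 0.0
    for fo, wf in parent_hyps(father_geno):
        for mo, wm in parent_hyps(mother_geno):
            ok = 1.0
            for s in range(n_sibs):
                digit = (state // 4**s) % 4
                pb, mb = digit // 2, digit % 2
                got = tuple(sorted((fo[pb], mo[mb])))
                g = sibs_genos[s]
                if g is not None and got != tuple(sorted(g)):
                    ok = 0.0
                    break
            total += wf * wm * ok
    return total


def oracle_ibd_posteriors(sib_genos_by_marker, father_by_marker, mother_by_marker,
                          freqs_by_marker, positions, n_sibs):
    """Posterior state distribution at each marker by full path enumeration.

    Returns (M, n_states) posterior array.  Only feasible for <=3 sibs and
    <=3 markers.
    """
    n_states = 4**n_sibs
    M = len(positions)
    thetas = [
        0.5 * (1 - np.exp(-0.02 * (positions[t + 1] - positions[t])))
        for t in range(M - 1)
    ]

    def trans(s1, s2, theta):
        p = 1.0
        for bit in range(2 * n_sibs):
            sib, which = divmod(bit, 2)
            d1 = (s1 // 4**sib) % 4
            d2 = (s2 // 4**sib) % 4
            b1 = (d1 >> (1 - which)) & 1
            b2 = (d2 >> (1 - which)) & 1
            p *= theta if b1 != b2 else (1 - theta)
        return p

    emis = np.array(
        [
            [
                _oracle_emission(
                    s,
                    sib_genos_by_marker[t],
                    father_by_marker[t],
                    mother_by_marker[t],
                    freqs_by_marker[t],
                    n_sibs,
                )
                for s in range(n_states)
            ]
            for t in range(M)
        ]
    )

    post = np.zeros((M, n_states))
    total = 0.0
    for path in itertools.product(range(n_states), repeat=M):
        w = 1.0 / n_states
        for t in range(M):
            w *= emis[t, path[t]]
            if t > 0:
                w *= trans(path[t - 1], path[t], thetas[t - 1])
        if w == 0:
            continue
        total += w
        for t in range(M):
            post[t, path[t]] += w
    if total > 0:
        post /= total
    return post


def oracle_pair_ibd(post_row, n_sibs, i, j):
    """(P0, P1, P2) for sib pair (i, j) from a posterior state distribution."""
    out = np.zeros(3)
    for s, w in enumerate(post_row):
        di = (s // 4**i) % 4
        dj = (s // 4**j) % 4
        ibd = int(di // 2 == dj // 2) + int(di % 2 == dj % 2)
        out[ibd] += w
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
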