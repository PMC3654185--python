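"""Domain types and readers/writers for pedigrees, genotypes, maps and traits.

Conventions used throughout the package:

* Alleles are arbitrary string labels (microsatellites and SNPs alike);
  the missing-genotype sentinel in .ped files is ``"0"``.
* Map positions are sex-averaged centimorgans from the p-terminus and must
  be strictly increasing within a map.
* Nuclear families only: a family is a (possibly ungenotyped) parent pair
  plus one or more full sibs, or a parent-less sibship.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_ALLELE = "0"

__all__ = [
    "Individual",
    "NuclearFamily",
    "Marker",
    "TraitTable",
    "Cohort",
    "PedParseError",
    "read_ped_map",
    "write_ped_map",
    "read_traits",
    "write_traits",
    "allele_freqs_from_founders",
]


class PedParseError(ValueError):
    """Raised when a pedigree/map/trait file violates the format contract."""


@dataclass(frozen=True)
class Individual:
    id: str
    family_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # "male" | "female" | "unknown"
    founder_flag: bool

    @property
    def is_founder(self) -> bool:
        return self.founder_flag


@dataclass(frozen=True)
class NuclearFamily:
    family_id: str
    father_id: str | None
    mother_id: str | None
    sib_ids: tuple[str, ...]

    @property
    def parent_ids(self) -> tuple[str, ...]:
        return tuple(p for p in (self.father_id, self.mother_id) if p is not None)

    @property
    def n_sibs(self) -> int:
        return len(self.sib_ids)


@dataclass
class Marker:
    """A mapped genetic marker (SNP or multiallelic microsatellite)."""

    name: str
    position_cM: float
    alleles: tuple[str, ...] = ()
    allele_freqs: np.ndarray | None = None
    chrom: str = "1"
    kind: str = "snp"  # "snp" | "microsat"
    bp: int = 0

    def __post_init__(self) -> None:
        if self.position_cM < 0:
            raise ValueError(f"marker {self.name}: negative cM position")
        if self.allele_freqs is not None:
            f = np.asarray(self.allele_freqs, dtype=float)
            if len(f) != len(self.alleles):
                raise ValueError(f"marker {self.name}: freq/allele length mismatch")
            if abs(f.sum() - 1.0) > 1e-9:
                raise ValueError(f"marker {self.name}: allele_freqs sum to {f.sum()}")
            self.allele_freqs = f

    @property
    def is_biallelic(self) -> bool:
        return len(self.alleles) == 2


# Canonical trait-table column names.  read_traits maps arbitrary CSV headers
# onto these via a column map.
TRAIT_COLUMNS = (
    "trait",
    "affected",
    "age_last_exam",
    "age_onset",
    "sex",
    "birth_year",
    "admixture",
)


class TraitTable:
    """Per-individual phenotype/covariate table, indexed by individual id.

    Wraps a :class:`pandas.DataFrame`; any column beyond the canonical set is
    carried along as an extra covariate.
    """

    def __init__(self, df: pd.DataFrame):
        if df.index.name != "iid":
            raise ValueError("TraitTable expects a DataFrame indexed by 'iid'")
        self.df = df
        self._validate()

    def _validate(self) -> None:
        df = self.df
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].tolist()
            raise PedParseError(f"duplicate individual ids in trait table: {dups}")
        if "age_onset" in df and "age_last_exam" in df:
            both = df["age_onset"].notna() & df["age_last_exam"].notna()
            bad = df.index[both & (df["age_onset"] > df["age_last_exam"] + 1e-9)]
            if len(bad):
                raise PedParseError(
                    f"age_at_onset exceeds age_at_last_exam for: {list(bad)}"
                )
        if "admixture" in df:
            m = df["admixture"].dropna()
            if ((m < -1e-9) | (m > 1 + 1e-9)).any():
                raise PedParseError("admixture fraction outside [0, 1]")

    def __len__(self) -> int:
        return len(self.df)

    def __getitem__(self, col: str) -> pd.Series:
        return self.df[col]

    def __contains__(self, col: str) -> bool:
        return col in self.df.columns

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    def equals(self, other: "TraitTable") -> bool:
        a = self.df.sort_index()
        b = other.df.sort_index()
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for c in a.columns:
            sa, sb = a[c], b[c]
            if sa.dtype.kind in "fc" or sb.dtype.kind in "fc":
                if not np.allclose(
                    sa.astype(float), sb.astype(float), equal_nan=True, atol=1e-12
                ):
                    return False
            elif not sa.fillna("").astype(str).equals(sb.fillna("").astype(str)):
                return False
        return True


@dataclass
class Cohort:
    """Pedigree + genotype matrix + genetic map + trait table.

    ``genotypes`` has shape (n_individuals, n_markers, 2) with dtype=object;
    entries are allele labels (str) or None for missing.  Row order matches
    ``individuals``; column order matches ``markers`` (sorted by cM).
    """

    individuals: list[Individual]
    families: list[NuclearFamily]
    markers: list[Marker]
    genotypes: np.ndarray
    traits: TraitTable | None = None
    _iid_index: dict[str, int] = field(default_factory=dict, repr=False)
    _marker_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._iid_index = {ind.id: i for i, ind in enumerate(self.individuals)}
        self._marker_index = {m.name: j for j, m in enumerate(self.markers)}
        self.validate()

    # -- accessors ---------------------------------------------------------

    def iid_index(self, iid: str) -> int:
        return self._iid_index[iid]

    def marker_index(self, name: str) -> int:
        return self._marker_index[name]

    def marker(self, name: str) -> Marker:
        return self.markers[self._marker_index[name]]

    def family(self, family_id: str) -> NuclearFamily:
        for f in self.families:
            if f.family_id == family_id:
                return f
        raise KeyError(family_id)

    def genotype(self, iid: str, marker: str) -> tuple[str, str] | None:
        g = self.genotypes[self._iid_index[iid], self._marker_index[marker]]
        if g[0] is None or g[1] is None:
            return None
        return (g[0], g[1])

    def snp_dosage(self, marker: str, effect_allele: str) -> pd.Series:
        """Per-individual count of ``effect_allele`` (NaN when missing)."""
        m = self.marker(marker)
        if not m.is_biallelic:
            raise ValueError(f"{marker} is not biallelic")
        if effect_allele not in m.alleles:
            raise ValueError(f"allele {effect_allele!r} not among {m.alleles} for {marker}")
        j = self._marker_index[marker]
        out = np.full(len(self.individuals), np.nan)
        for i in range(len(self.individuals)):
            a, b = self.genotypes[i, j]
            if a is None or b is None:
                continue
            out[i] = (a == effect_allele) + (b == effect_allele)
        return pd.Series(out, index=[ind.id for ind in self.individuals], name=marker)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def iids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        ids = set(self._iid_index)
        if len(ids) != len(self.individuals):
            raise PedParseError("duplicate individual ids in cohort")
        for ind in self.individuals:
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid in self._iid_index:
                    parent = self.individuals[self._iid_index[pid]]
                    if parent.family_id != ind.family_id:
                        raise PedParseError(
                            f"{ind.id}: parent {pid} belongs to family "
                            f"{parent.family_id}, not {ind.family_id}"
                        )
        pos = [m.position_cM for m in self.markers]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise PedParseError("marker positions not strictly increasing in cM")
        if self.genotypes.shape[:2] != (len(self.individuals), len(self.markers)):
            raise PedParseError("genotype matrix shape does not match pedigree/map")
        if self.traits is not None:
            missing = set(self.traits.df.index) - ids
            if missing:
                raise PedParseError(
                    f"trait ids absent from pedigree: {sorted(missing)}"
                )

    def attach_traits(self, traits: TraitTable) -> None:
        self.traits = traits
        self.validate()


# ---------------------------------------------------------------------------
# Pedigree construction
# ---------------------------------------------------------------------------


def _build_families(individuals: Sequence[Individual]) -> list[NuclearFamily]:
    by_fid: dict[str, list[Individual]] = {}
    for ind in individuals:
        by_fid.setdefault(ind.family_id, []).append(ind)
    families = []
    for fid, members in by_fid.items():
        sibs = [m for m in members if m.father_id is not None or m.mother_id is not None]
        parent_ids = {m.father_id for m in sibs} | {m.mother_id for m in sibs}
        parent_ids.discard(None)
        named = {m.id for m in members}
        if sibs:
            pairs = {(m.father_id, m.mother_id) for m in sibs}
            if len(pairs) > 1:
                raise PedParseError(
                    f"family {fid}: sibs do not share a single parent pair ({pairs})"
                )
            father_id, mother_id = sibs[0].father_id, sibs[0].mother_id
            extra = [
                m for m in members
                if m not in sibs and m.id not in parent_ids
            ]
            if extra:
                raise PedParseError(
                    f"family {fid}: individuals {[m.id for m in extra]} are neither "
                    "sibs nor parents (non-nuclear pedigree)"
                )
            for pid in (father_id, mother_id):
                if pid is not None and pid not in named:
                    # parent referenced but not a pedigree row: treat as absent
                    pass
            families.append(
                NuclearFamily(
                    family_id=fid,
                    father_id=father_id if father_id in named else None,
                    mother_id=mother_id if mother_id in named else None,
                    sib_ids=tuple(m.id for m in sibs),
                )
            )
        else:
            # parent-less sibship (unknown parents share a dummy pair)
            families.append(
                NuclearFamily(
                    family_id=fid,
                    father_id=None,
                    mother_id=None,
                    sib_ids=tuple(m.id for m in members),
                )
            )
    return families


def _sex_from_code(code: str) -> str:
    return {"1": "male", "2": "female"}.get(code, "unknown")


def _sex_to_code(sex: str) -> str:
    return {"male": "1", "female": "2"}.get(sex, "0")


# ---------------------------------------------------------------------------
# .ped / .map I/O
# ---------------------------------------------------------------------------


def read_ped_map(
    ped_path,
    map_path,
    markers: Sequence[Marker] | None = None,
) -> Cohort:
    """Parse PLINK-style .ped/.map files into a :class:`Cohort`.

    The .map cM column (third) is honoured; marker order follows the map.
    When ``markers`` is supplied, its declared allele sets are enforced and a
    genotype with an undeclared allele is a parse error naming the marker and
    line.  Otherwise allele sets are collected from the data.
    """
    map_rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise PedParseError(f"{map_path}:{lineno}: expected CHR NAME cM BP")
            chrom, name, cm, bp = parts[0], parts[1], float(parts[2]), int(parts[3])
            map_rows.append((chrom, name, cm, bp))
    for (c1, n1, p1, _), (c2, n2, p2, _) in zip(map_rows, map_rows[1:]):
        if p2 <= p1:
            raise PedParseError(
                f"{map_path}: non-increasing cM at marker {n2} ({p2} after {p1})"
            )

    declared = {m.name: m for m in markers} if markers else {}
    marker_objs: list[Marker] = []
    for chrom, name, cm, bp in map_rows:
        if name in declared:
            src = declared[name]
            marker_objs.append(
                Marker(name, cm, src.alleles, src.allele_freqs, chrom, src.kind, bp)
            )
        else:
            marker_objs.append(Marker(name, cm, (), None, chrom, "snp", bp))

    n_mark = len(marker_objs)
    individuals: list[Individual] = []
    geno_rows = []
    seen: set[tuple[str, str]] = set()
    allele_sets: list[set[str]] = [set() for _ in range(n_mark)]

    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_mark:
                raise PedParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_mark} fields, "
                    f"got {len(parts)}"
                )
            fid, iid, pat, mat, sexcode = parts[:5]
            if (fid, iid) in seen:
                raise PedParseError(f"{ped_path}:{lineno}: duplicate IID {iid} in FID {fid}")
            seen.add((fid, iid))
            father = None if pat == "0" else pat
            mother = None if mat == "0" else mat
            individuals.append(
                Individual(
                    id=iid,
                    family_id=fid,
                    father_id=father,
                    mother_id=mother,
                    sex=_sex_from_code(sexcode),
                    founder_flag=(father is None and mother is None),
                )
            )
            row = np.empty((n_mark, 2), dtype=object)
            for j in range(n_mark):
                a, b = parts[6 + 2 * j], parts[7 + 2 * j]
                for al in (a, b):
                    if al != MISSING_ALLELE:
                        mk = marker_objs[j]
                        if mk.alleles and al not in mk.alleles:
                            raise PedParseError(
                                f"{ped_path}:{lineno}: allele {al!r} not in declared "
                                f"set for marker {mk.name}"
                            )
                        allele_sets[j].add(al)
                row[j, 0] = None if a == MISSING_ALLELE else a
                row[j, 1] = None if b == MISSING_ALLELE else b
            geno_rows.append(row)

    for j, mk in enumerate(marker_objs):
        if not mk.alleles:
            mk.alleles = tuple(sorted(allele_sets[j]))
            if mk.kind == "snp" and len(mk.alleles) > 2:
                mk.kind = "microsat"

    genotypes = (
        np.stack(geno_rows) if geno_rows else np.empty((0, n_mark, 2), dtype=object)
    )
    families = _build_families(individuals)
    return Cohort(individuals, families, marker_objs, genotypes)


def write_ped_map(cohort: Cohort, ped_path, map_path) -> None:
    with open(map_path, "w") as fh:
        for m in cohort.markers:
            fh.write(f"{m.chrom}\t{m.name}\t{m.position_cM!r}\t{m.bp}\n")
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(cohort.individuals):
            fields = [
                ind.family_id,
                ind.id,
                ind.father_id or "0",
                ind.mother_id or "0",
                _sex_to_code(ind.sex),
                "0",
            ]
            for j in range(len(cohort.markers)):
                a, b = cohort.genotypes[i, j]
                fields.append(a if a is not None else MISSING_ALLELE)
                fields.append(b if b is not None else MISSING_ALLELE)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Trait CSV I/O
# ---------------------------------------------------------------------------

_NUMERIC_TRAIT_COLS = ("trait", "affected", "age_last_exam", "age_onset",
                       "birth_year", "admixture")


def read_traits(
    csv_path,
    column_map: Mapping[str, str] | None = None,
    pedigree_ids: Iterable[str] | None = None,
) -> TraitTable:
    """Read a trait/covariate CSV.

    ``column_map`` maps canonical names (``iid``, ``trait``, ``affected``,
    ``age_last_exam``, ``age_onset``, ``sex``, ``birth_year``, ``admixture``)
    to the CSV's header names.  Unparseable numeric cells become missing with
    a logged warning.  When ``pedigree_ids`` is given, trait ids must be a
    subset of it.
    """
    raw = pd.read_csv(csv_path, dtype=str)
    column_map = dict(column_map or {})
    rename = {v: k for k, v in column_map.items()}
    raw = raw.rename(columns=rename)
    if "iid" not in raw.columns:
        raise PedParseError(f"{csv_path}: no 'iid' column (column_map={column_map})")
    raw = raw.set_index("iid")
    raw.index.name = "iid"

    out = {}
    for col in raw.columns:
        s = raw[col]
        if col in _NUMERIC_TRAIT_COLS or col not in ("sex", "stratum"):
            conv = pd.to_numeric(s, errors="coerce")
            bad = s.notna() & conv.isna()
            if bad.any():
                if col in ("sex", "stratum") or conv.isna().all():
                    out[col] = s
                    continue
                logger.warning(
                    "read_traits: %d unparseable cells in column %r set to missing",
                    int(bad.sum()), col,
                )
            out[col] = conv
        else:
            out[col] = s
    df = pd.DataFrame(out, index=raw.index)
    if pedigree_ids is not None:
        missing = sorted(set(df.index) - set(pedigree_ids))
        if missing:
            raise PedParseError(f"trait ids absent from pedigree: {missing}")
    return TraitTable(df)


def write_traits(traits: TraitTable, csv_path) -> None:
    traits.df.to_csv(csv_path, float_format="%.17g")


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------


def allele_freqs_from_founders(cohort: Cohort, marker: str) -> dict[str, float]:
    """Counting estimate of allele frequencies from genotyped founders.

    Falls back (with a warning) to all individuals when no founder carries a
    genotype at the marker.  Raises if there are no non-missing alleles at all.
    """
    j = cohort.marker_index(marker)
    counts: dict[str, int] = {}

    def _count(indices) -> dict[str, int]:
        c: dict[str, int] = {}
        for i in indices:
            for allele in cohort.genotypes[i, j]:
                if allele is not None:
                    c[allele] = c.get(allele, 0) + 1
        return c

    founder_idx = [i for i, ind in enumerate(cohort.individuals) if ind.founder_flag]
    counts = _count(founder_idx)
    if not counts:
        counts = _count(range(cohort.n_individuals))
        if counts:
            warnings.warn(
                f"allele_freqs_from_founders({marker}): no genotyped founders; "
                "falling back to all individuals",
                stacklevel=2,
            )
    if not counts:
        raise ValueError(f"marker {marker}: zero non-missing alleles")
    total = sum(counts.values())
    mk = cohort.markers[j]
    order = mk.alleles if mk.alleles else tuple(sorted(counts))
    freqs = {a: counts.get(a, 0) / total for a in order}
    for a in counts:
        if a not in freqs:
            freqs[a] = counts[a] / total
    return freqs
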