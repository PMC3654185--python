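"""Univariate and bivariate variance-components linkage analysis.

The trait covariance within a sibship is modelled as

    Omega = sigma2_q * Pihat(c) + sigma2_g * 2Phi + sigma2_e * I

with mean X beta.  Fixed effects are profiled out by generalised least
squares at every likelihood evaluation; variance parameters are maximised by
bounded quasi-Newton with deterministic plus random multi-starts (the
likelihood is boundary-prone).  The LOD score is the base-10 log-likelihood
ratio of the linked model against the nested polygenic null, floored at 0.

The bivariate model stacks two traits per sibship with cross-trait blocks
rho_q*sq1*sq2*Pihat + rho_g*sg1*sg2*2Phi + rho_e*se1*se2*I, giving the
genetic correlation between the two traits' locus-specific effects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core_data import Cohort, TraitTable
from .ibd import IBDSurface, expected_kinship

logger = logging.getLogger(__name__)

__all__ = [
    "VCFit",
    "BivariateVCFit",
    "LodCurve",
    "fit_vc_univariate",
    "fit_vc_bivariate",
    "lod_score",
    "lod_pvalue",
    "lod_curve",
    "age_adjusted_score",
    "cumulative_incidence",
    "build_vc_data",
]

_LN10 = np.log(10.0)


@dataclass
class VCFit:
    sigma2_q: float
    sigma2_g: float
    sigma2_e: float
    beta: np.ndarray
    beta_names: list[str]
    loglik: float
    converged: bool
    n: int
    n_families: int
    degenerate: bool = False
    messages: list[str] = field(default_factory=list)


@dataclass
class BivariateVCFit:
    # per-trait components: index 0 = trait1, 1 = trait2
    sigma2_q: tuple[float, float]
    sigma2_g: tuple[float, float]
    sigma2_e: tuple[float, float]
    rho_q: float
    rho_g: float
    rho_e: float
    beta: np.ndarray
    loglik: float
    converged: bool
    n: int
    p_rho_q_zero: float | None = None
    p_rho_q_minus1: float | None = None
    messages: list[str] = field(default_factory=list)


@dataclass
class LodCurve:
    positions: np.ndarray
    lods: np.ndarray

    @property
    def peak_position(self) -> float:
        return float(self.positions[int(np.argmax(self.lods))])

    @property
    def peak_lod(self) -> float:
        return float(np.max(self.lods))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"cM": self.positions, "LOD": self.lods})


# ---------------------------------------------------------------------------
# Data assembly
# ---------------------------------------------------------------------------


def build_vc_data(
    cohort: Cohort,
    trait: str | pd.Series,
    covariates: list[str] | None = None,
):
    """Assemble per-family sib trait vectors, design matrices and kinship.

    Returns a list of dicts with keys fid, ids, y (s,), X (s,p), K (s,s),
    plus the design column names.  Only sibs with a non-missing trait and
    complete covariates enter; families with zero phenotyped sibs drop out.
    """
    if cohort.traits is None:
        raise ValueError("cohort has no trait table attached")
    tdf = cohort.traits.df
    yser = tdf[trait] if isinstance(trait, str) else trait
    covariates = list(covariates or [])
    names = ["intercept"] + covariates

    fams = []
    for fam in cohort.families:
        ids = []
        for iid in fam.sib_ids:
            if iid not in yser.index or pd.isna(yser.loc[iid]):
                continue
            row_ok = True
            for c in covariates:
                v = _covariate_value(tdf, iid, c)
                if v is None or (isinstance(v, float) and np.isnan(v)):
                    row_ok = False
                    break
            if row_ok:
                ids.append(iid)
        if not ids:
            continue
        y = np.array([float(yser.loc[i]) for i in ids])
        X = np.ones((len(ids), len(names)))
        for k, c in enumerate(covariates, start=1):
            X[:, k] = [_covariate_value(tdf, i, c) for i in ids]
        K = expected_kinship(fam, ids)
        fams.append({"fid": fam.family_id, "ids": ids, "y": y, "X": X, "K": K})
    return fams, names


def _covariate_value(tdf: pd.DataFrame, iid: str, col: str):
    if col not in tdf.columns:
        raise KeyError(f"covariate {col!r} not in trait table")
    v = tdf.loc[iid, col]
    if col == "sex" and isinstance(v, str):
        return {"male": 1.0, "female": 0.0}.get(v, np.nan)
    try:
        return float(v)
    except (TypeError, ValueError):
        return np.nan


def _group_by_size(fams, pihat):
    """Stack families of equal sibship size for batched linear algebra."""
    groups = {}
    for f in fams:
        s = len(f["ids"])
        g = groups.setdefault(s, {"y": [], "X": [], "K": [], "P": []})
        g["y"].append(f["y"])
        g["X"].append(f["X"])
        g["K"].append(f["K"])
        if pihat is not None:
            P = pihat.get(f["fid"])
            if P is None:
                P = f["K"]  # no IBD information: prior expectation = kinship
            g["P"].append(P)
    out = []
    for s, g in groups.items():
        out.append(
            {
                "s": s,
                "y": np.stack(g["y"]),
                "X": np.stack(g["X"]),
                "K": np.stack(g["K"]),
                "P": np.stack(g["P"]) if pihat is not None else None,
            }
        )
    return out


def _nll_univariate(params, groups, use_q):
    """Negative profile (over beta) log-likelihood."""
    if use_q:
        sq, sg, se = params
    else:
        sq = 0.0
        sg, se = params
    p = groups[0]["X"].shape[2]
    A = np.zeros((p, p))
    b = np.zeros(p)
    logdet = 0.0
    yOy = 0.0
    N = 0
    for g in groups:
        s = g["s"]
        Omega = sg * g["K"] + se * np.eye(s)[None, :, :]
        if use_q:
            Omega = Omega + sq * g["P"]
        try:
            L = np.linalg.cholesky(Omega)
        except np.linalg.LinAlgError:
            return 1e12
        logdet += 2.0 * np.log(np.einsum("fii->fi", L)).sum()
        # solve Omega^{-1} [X y]
        Xy = np.concatenate([g["X"], g["y"][:, :, None]], axis=2)
        sol = np.linalg.solve(Omega, Xy)
        iX = sol[:, :, :-1]
        iy = sol[:, :, -1]
        A += np.einsum("fsp,fsq->pq", g["X"], iX)
        b += np.einsum("fsp,fs->p", g["X"], iy)
        yOy += np.einsum("fs,fs->", g["y"], iy)
        N += g["y"].size
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(A, b, rcond=None)[0]
    quad = yOy - beta @ b
    return 0.5 * (logdet + quad + N * np.log(2 * np.pi))


def _beta_hat(params, groups, use_q):
    if use_q:
        sq, sg, se = params
    else:
        sq = 0.0
        sg, se = params
    p = groups[0]["X"].shape[2]
    A = np.zeros((p, p))
    b = np.zeros(p)
    for g in groups:
        s = g["s"]
        Omega = sg * g["K"] + se * np.eye(s)[None, :, :]
        if use_q:
            Omega = Omega + sq * g["P"]
        Xy = np.concatenate([g["X"], g["y"][:, :, None]], axis=2)
        sol = np.linalg.solve(Omega, Xy)
        A += np.einsum("fsp,fsq->pq", g["X"], sol[:, :, :-1])
        b += np.einsum("fsp,fs->p", g["X"], sol[:, :, -1])
    return np.linalg.lstsq(A, b, rcond=None)[0]


def fit_vc_univariate(
    cohort: Cohort,
    trait: str | pd.Series,
    pihat_at_c: dict[str, np.ndarray] | None = None,
    covariates: list[str] | None = None,
    n_starts: int = 5,
    seed: int = 0,
    _prefit=None,
) -> VCFit:
    """ML variance-components fit; ``pihat_at_c=None`` fits the polygenic null.

    ``pihat_at_c`` maps family id -> pihat matrix over that family's
    phenotyped sibs (ordered as in :func:`build_vc_data`).
    """
    fams, names = build_vc_data(cohort, trait, covariates)
    if not fams:
        raise ValueError("no families with phenotyped sibs")
    use_q = pihat_at_c is not None
    groups = _group_by_size(fams, pihat_at_c if use_q else None)
    n = sum(g["y"].size for g in groups)

    degenerate = False
    messages: list[str] = []
    if use_q:
        dev = max(
            float(np.max(np.abs(g["P"] - g["K"]))) if g["P"].size else 0.0
            for g in groups
        )
        if dev < 1e-9:
            degenerate = True
            messages.append(
                "Pihat coincides with 2*Phi for every pair: sigma2_q and "
                "sigma2_g are jointly unidentifiable"
            )

    yall = np.concatenate([g["y"].ravel() for g in groups])
    v = float(np.var(yall))
    if v <= 0:
        raise ValueError("trait has zero variance")

    rng = np.random.default_rng(seed)
    if use_q:
        starts = [
            (0.3 * v, 0.2 * v, 0.5 * v),
            (0.05 * v, 0.05 * v, 0.9 * v),
            (0.6 * v, 0.1 * v, 0.3 * v),
        ]
        bounds = [(0.0, 10 * v), (0.0, 10 * v), (1e-8 * v, 10 * v)]
    else:
        starts = [(0.3 * v, 0.7 * v), (0.05 * v, 0.95 * v), (0.6 * v, 0.4 * v)]
        bounds = [(0.0, 10 * v), (1e-8 * v, 10 * v)]
    if _prefit is not None:
        starts.insert(0, _prefit)
    while len(starts) < n_starts:
        w = rng.dirichlet(np.ones(len(bounds)))
        starts.append(tuple(max(lo, wi * v) for wi, (lo, hi) in zip(w, bounds)))

    best = None
    for x0 in starts:
        res = optimize.minimize(
            _nll_univariate,
            x0=np.asarray(x0, dtype=float),
            args=(groups, use_q),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    params = best.x
    beta = _beta_hat(params, groups, use_q)
    loglik = -float(best.fun)
    if not np.isfinite(loglik):
        raise RuntimeError("variance-components likelihood not finite at optimum")
    if use_q:
        sq, sg, se = params
    else:
        sq = 0.0
        sg, se = params
    converged = bool(best.success)
    if not converged:
        messages.append(f"optimizer: {best.message}")
    return VCFit(
        sigma2_q=float(sq),
        sigma2_g=float(sg),
        sigma2_e=float(se),
        beta=beta,
        beta_names=names,
        loglik=loglik,
        converged=converged,
        n=n,
        n_families=len(fams),
        degenerate=degenerate,
        messages=messages,
    )


def lod_score(fit_linked: VCFit, fit_null: VCFit) -> float:
    """LOD = (loglik_linked - loglik_null) / ln(10), floored at 0."""
    if fit_linked.n != fit_null.n:
        raise ValueError(
            f"non-nested fits: n={fit_linked.n} (linked) vs {fit_null.n} (null)"
        )
    return max(0.0, (fit_linked.loglik - fit_null.loglik) / _LN10)


def lod_pvalue(lod: float) -> float:
    """Pointwise p-value for a LOD score under the 1/2 chi2_0 + 1/2 chi2_1 mixture."""
    if lod <= 0:
        return 1.0
    return 0.5 * float(stats.chi2.sf(2.0 * _LN10 * lod, df=1))


def lod_curve(
    cohort: Cohort,
    trait: str | pd.Series,
    ibd_surface: IBDSurface,
    covariates: list[str] | None = None,
    positions: np.ndarray | None = None,
    seed: int = 0,
) -> LodCurve:
    """LOD at each grid position; the polygenic null is fitted once."""
    if positions is None:
        positions = ibd_surface.grid
    fams, _ = build_vc_data(cohort, trait, covariates)
    null = fit_vc_univariate(cohort, trait, None, covariates, seed=seed)
    lods = np.empty(len(positions))
    prev = None
    for k, c in enumerate(positions):
        pihat = {}
        for f in fams:
            fid = f["fid"]
            if fid in ibd_surface.families:
                pihat[fid] = ibd_surface.pihat_matrix(fid, f["ids"], c)
            else:
                # no IBD information: prior expectation = kinship
                pihat[fid] = f["K"]
        linked = fit_vc_univariate(
            cohort, trait, pihat, covariates, seed=seed, _prefit=prev
        )
        prev = (linked.sigma2_q, linked.sigma2_g, linked.sigma2_e)
        lods[k] = lod_score(linked, null)
    return LodCurve(positions=np.asarray(positions, dtype=float), lods=lods)


# ---------------------------------------------------------------------------
# Age-adjusted disease score
# ---------------------------------------------------------------------------


def cumulative_incidence(durations, events):
    """Kaplan-Meier cumulative incidence F(a) = 1 - S(a) as a step function.

    Returns a callable evaluating F at arbitrary ages (right-continuous).
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    order = np.argsort(durations, kind="stable")
    t = durations[order]
    e = events[order]
    uniq = np.unique(t[e == 1])
    n_at_risk = len(t)
    surv = 1.0
    steps_t, steps_s = [], []
    for u in uniq:
        d = int(((t == u) & (e == 1)).sum())
        at_risk = int((t >= u).sum())
        if at_risk > 0:
            surv *= 1.0 - d / at_risk
        steps_t.append(u)
        steps_s.append(surv)
    steps_t = np.array(steps_t)
    steps_s = np.array(steps_s)

    def F(age):
        age = np.asarray(age, dtype=float)
        if len(steps_t) == 0:  # no events observed
            return np.zeros_like(age)
        idx = np.searchsorted(steps_t, age, side="right") - 1
        s = np.where(idx >= 0, steps_s[np.clip(idx, 0, None)], 1.0)
        return 1.0 - s

    return F


def age_adjusted_score(
    trait_table: TraitTable,
    affected_col: str = "affected",
    onset_col: str = "age_onset",
    exam_col: str = "age_last_exam",
    incidence=None,
) -> pd.Series:
    """Disease status minus age-specific cumulative incidence.

    score_i = D_i - F(a_i) with a_i = onset age when affected, else last-exam
    age; F is the Kaplan-Meier cumulative incidence of onset with censoring
    at last exam (or a supplied function).
    """
    df = trait_table.df
    D = df[affected_col].astype(float)
    ages = np.where(D == 1, df[onset_col].astype(float), df[exam_col].astype(float))
    mask = ~(np.isnan(ages) | D.isna().to_numpy())
    if incidence is None:
        dsub = D.to_numpy()[mask]
        if dsub.min() == dsub.max():
            warnings.warn(
                "age_adjusted_score: all individuals share one affection status; "
                "scores are degenerate",
                stacklevel=2,
            )
        incidence = cumulative_incidence(ages[mask], dsub.astype(int))
    score = np.full(len(df), np.nan)
    score[mask] = D.to_numpy()[mask] - incidence(ages[mask])
    return pd.Series(score, index=df.index, name="age_adjusted_score")


# ---------------------------------------------------------------------------
# Bivariate covariance-components model
# ---------------------------------------------------------------------------


def build_bivariate_data(cohort, trait1, trait2, covariates):
    """Families where both traits are observed on the same sibs."""
    tdf = cohort.traits.df
    y1 = tdf[trait1] if isinstance(trait1, str) else trait1
    y2 = tdf[trait2] if isinstance(trait2, str) else trait2
    covariates = list(covariates or [])
    fams = []
    for fam in cohort.families:
        ids = []
        for iid in fam.sib_ids:
            if iid not in y1.index or iid not in y2.index:
                continue
            if pd.isna(y1.loc[iid]) or pd.isna(y2.loc[iid]):
                continue
            vals = [_covariate_value(tdf, iid, c) for c in covariates]
            if any(v is None or np.isnan(v) for v in vals):
                continue
            ids.append(iid)
        if not ids:
            continue
        X = np.ones((len(ids), 1 + len(covariates)))
        for k, c in enumerate(covariates, start=1):
            X[:, k] = [_covariate_value(tdf, i, c) for i in ids]
        fams.append(
            {
                "fid": fam.family_id,
                "ids": ids,
                "y1": np.array([float(y1.loc[i]) for i in ids]),
                "y2": np.array([float(y2.loc[i]) for i in ids]),
                "X": X,
                "K": expected_kinship(cohort.family(fam.family_id), ids),
            }
        )
    return fams


def _biv_groups(fams, pihat, position=None):
    groups = {}
    for f in fams:
        s = len(f["ids"])
        g = groups.setdefault(s, {"y": [], "X": [], "K": [], "P": []})
        g["y"].append(np.concatenate([f["y1"], f["y2"]]))
        g["X"].append(f["X"])
        g["K"].append(f["K"])
        P = None
        if hasattr(pihat, "pihat_matrix"):  # an IBDSurface
            if f["fid"] in pihat.families:
                P = pihat.pihat_matrix(f["fid"], f["ids"], position)
        elif pihat is not None:
            P = pihat.get(f["fid"])
            if P is not None and P.shape != f["K"].shape:
                raise ValueError(
                    f"pihat matrix for family {f['fid']} has shape {P.shape}; "
                    f"expected {f['K'].shape} (phenotyped sibs only)"
                )
        g["P"].append(P if P is not None else f["K"])
    out = []
    for s, g in groups.items():
        X1 = np.stack(g["X"])
        F, _, p1 = X1.shape
        # block design: trait1 rows use columns [0:p1], trait2 rows [p1:2p1]
        X = np.zeros((F, 2 * s, 2 * p1))
        X[:, :s, :p1] = X1
        X[:, s:, p1:] = X1
        out.append(
            {
                "s": s,
                "y": np.stack(g["y"]),
                "X1": X1,
                "X": X,
                "K": np.stack(g["K"]),
                "P": np.stack(g["P"]),
            }
        )
    return out


def _cross_cov(c11, c22, rho):
    return np.array([[c11, rho * np.sqrt(c11 * c22)], [rho * np.sqrt(c11 * c22), c22]])


def _nll_bivariate(x, groups, fixed, tie_sigma_q, ridge):
    # unpack with optional fixed entries
    names = ["sq1", "sg1", "se1", "sq2", "sg2", "se2", "rq", "rg", "re"]
    vals = {}
    i = 0
    for nm in names:
        if nm in fixed:
            vals[nm] = fixed[nm]
        elif nm == "sq2" and tie_sigma_q:
            vals[nm] = None  # set below
        else:
            vals[nm] = x[i]
            i += 1
    if tie_sigma_q:
        vals["sq2"] = vals["sq1"]
    Cq = _cross_cov(vals["sq1"], vals["sq2"], vals["rq"])
    Cg = _cross_cov(vals["sg1"], vals["sg2"], vals["rg"])
    Ce = _cross_cov(vals["se1"], vals["se2"], vals["re"])

    p1 = groups[0]["X1"].shape[2]
    p = 2 * p1
    A = np.zeros((p, p))
    b = np.zeros(p)
    logdet = 0.0
    yOy = 0.0
    N = 0
    for g in groups:
        s = g["s"]
        I = np.eye(s)[None, :, :]
        F = g["K"].shape[0]
        Omega = (
            np.einsum("ab,fij->faibj", Cq, g["P"])
            + np.einsum("ab,fij->faibj", Cg, g["K"])
            + np.einsum("ab,fij->faibj", Ce, np.broadcast_to(I, g["K"].shape))
        ).reshape(F, 2 * s, 2 * s)
        Omega = Omega + ridge * np.eye(2 * s)[None, :, :]
        try:
            L = np.linalg.cholesky(Omega)
        except np.linalg.LinAlgError:
            return 1e12
        logdet += 2.0 * np.log(np.einsum("fii->fi", L)).sum()
        X = g["X"]
        Xy = np.concatenate([X, g["y"][:, :, None]], axis=2)
        sol = np.linalg.solve(Omega, Xy)
        A += np.einsum("fsp,fsq->pq", X, sol[:, :, :-1])
        b += np.einsum("fsp,fs->p", X, sol[:, :, -1])
        yOy += np.einsum("fs,fs->", g["y"], sol[:, :, -1])
        N += g["y"].size
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(A, b, rcond=None)[0]
    quad = yOy - beta @ b
    if quad < 0:
        return 1e12
    return 0.5 * (logdet + quad + N * np.log(2 * np.pi))


def fit_vc_bivariate(
    cohort: Cohort,
    trait1: str | pd.Series,
    trait2: str | pd.Series,
    pihat: dict[str, np.ndarray] | None,
    covariates: list[str] | None = None,
    fixed: dict[str, float] | None = None,
    tie_sigma_q: bool = False,
    n_starts: int = 3,
    seed: int = 0,
    compute_rho_tests: bool = True,
    position: float | None = None,
) -> BivariateVCFit:
    """Bivariate covariance-components fit with optional fixed parameters.

    ``pihat`` is either a dict family_id -> matrix over that family's
    phenotyped sibs, or an :class:`IBDSurface` together with ``position``.
    ``fixed`` pins parameters by name among {sq1, sg1, se1, sq2, sg2, se2,
    rq, rg, re}; ``tie_sigma_q`` constrains sq2 == sq1 (used by the
    linked-variance-reduction test).  When ``compute_rho_tests`` is on, LRT
    p-values for rho_q = 0 (chi2_1) and rho_q = -1 (boundary: half-mixture)
    are attached.
    """
    fixed = dict(fixed or {})
    fams = build_bivariate_data(cohort, trait1, trait2, covariates)
    if not fams:
        raise ValueError("no families with both traits observed")
    groups = _biv_groups(fams, pihat, position)
    n = sum(g["y"].size for g in groups)

    v1 = float(np.var(np.concatenate([f["y1"] for f in fams])))
    v2 = float(np.var(np.concatenate([f["y2"] for f in fams])))
    v1 = max(v1, 1e-12)
    v2 = max(v2, 1e-12)
    ridge = 1e-9 * max(v1, v2)

    names = ["sq1", "sg1", "se1", "sq2", "sg2", "se2", "rq", "rg", "re"]
    base = {
        "sq1": 0.3 * v1, "sg1": 0.2 * v1, "se1": 0.5 * v1,
        "sq2": 0.3 * v2, "sg2": 0.2 * v2, "se2": 0.5 * v2,
        "rq": 0.0, "rg": 0.0, "re": 0.0,
    }
    bnds = {
        "sq1": (0.0, 10 * v1), "sg1": (0.0, 10 * v1), "se1": (1e-8 * v1, 10 * v1),
        "sq2": (0.0, 10 * v2), "sg2": (0.0, 10 * v2), "se2": (1e-8 * v2, 10 * v2),
        "rq": (-1.0, 1.0), "rg": (-1.0, 1.0), "re": (-1.0, 1.0),
    }
    free = [
        nm for nm in names
        if nm not in fixed and not (nm == "sq2" and tie_sigma_q)
    ]
    bounds = [bnds[nm] for nm in free]
    rng = np.random.default_rng(seed)
    starts = [np.array([base[nm] for nm in free])]
    for sgn in (0.8, -0.8):
        s0 = dict(base)
        s0.update({"rq": sgn, "rg": 0.5 * sgn, "re": 0.0})
        starts.append(np.array([s0[nm] for nm in free]))
    while len(starts) < n_starts:
        pert = {
            nm: (
                rng.uniform(*bnds[nm]) if nm.startswith("r")
                else rng.uniform(0.05, 0.9) * (v1 if nm.endswith("1") else v2)
            )
            for nm in free
        }
        starts.append(np.array([pert[nm] for nm in free]))

    def _opt(extra_fixed, warm=None, max_starts=None):
        allfixed = {**fixed, **extra_fixed}
        fr = [nm for nm in free if nm not in extra_fixed]
        bd = [bnds[nm] for nm in fr]
        use = [np.array([x0[free.index(nm)] for nm in fr]) for x0 in starts]
        if warm is not None:
            use.insert(0, np.array([np.clip(warm[nm], *bnds[nm]) for nm in fr]))
        if max_starts is not None:
            use = use[:max_starts]
        best = None
        for x0r in use:
            res = optimize.minimize(
                _nll_bivariate, x0r, args=(groups, allfixed, tie_sigma_q, ridge),
                method="L-BFGS-B", bounds=bd,
                options={"ftol": 1e-11, "gtol": 1e-7, "maxiter": 500},
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        return best, fr, allfixed

    best, fr, allfixed = _opt({})
    vals = {}
    i = 0
    for nm in names:
        if nm in allfixed:
            vals[nm] = allfixed[nm]
        elif nm == "sq2" and tie_sigma_q:
            vals[nm] = None
        else:
            vals[nm] = float(best.x[i])
            i += 1
    if tie_sigma_q:
        vals["sq2"] = vals["sq1"]
    loglik = -float(best.fun)

    p0 = pm1 = None
    if compute_rho_tests and "rq" not in fixed:
        b0, _, _ = _opt({"rq": 0.0}, warm=vals, max_starts=2)
        bm1, _, _ = _opt({"rq": -1.0}, warm=vals, max_starts=2)
        lr0 = max(0.0, 2.0 * (-float(best.fun) + float(b0.fun)))
        lrm1 = max(0.0, 2.0 * (-float(best.fun) + float(bm1.fun)))
        p0 = float(stats.chi2.sf(lr0, df=1))
        # rho_q = -1 is a boundary of the parameter space: half-mixture
        pm1 = 0.5 * float(stats.chi2.sf(lrm1, df=1)) if lrm1 > 0 else 1.0

    # recover beta at the optimum
    fit = BivariateVCFit(
        sigma2_q=(vals["sq1"], vals["sq2"]),
        sigma2_g=(vals["sg1"], vals["sg2"]),
        sigma2_e=(vals["se1"], vals["se2"]),
        rho_q=vals["rq"],
        rho_g=vals["rg"],
        rho_e=vals["re"],
        beta=np.array([]),
        loglik=loglik,
        converged=bool(best.success),
        n=n,
        p_rho_q_zero=p0,
        p_rho_q_minus1=pm1,
    )
    return fit
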