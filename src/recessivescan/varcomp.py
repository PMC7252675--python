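"""Pedigree-based REML for the repeated-records animal model.

Model per ejaculate record:

    y = Xb + Z_u u + Z_p p + e,
    u ~ N(0, A sigma_g^2),  p ~ N(0, I sigma_pe^2),  e ~ N(0, I sigma_e^2)

where ``A`` is the additive (numerator) relationship matrix from the
pedigree, ``u`` are animal polygenic effects and ``p`` permanent-environment
effects for animals with records.  Heritability h2 = sigma_g^2 / total and
repeatability = (sigma_g^2 + sigma_pe^2) / total, so repeatability >= h2 by
construction.

The restricted likelihood is maximized with EM-REML on Henderson's
mixed-model equations (monotone in the likelihood); an Aitken-style
extrapolation with a likelihood safeguard accelerates the terminal
geometric phase.  The permanent-environment block is absorbed (it is
diagonal), so each iteration factors only a (p + q) system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve


def _normalise_pedigree(pedigree: pd.DataFrame) -> pd.DataFrame:
    ped = pedigree.rename(columns=str.lower).copy()
    for col in ("animal", "sire", "dam"):
        if col not in ped.columns:
            raise ValueError(f"pedigree lacks column '{col}'")
        ped[col] = ped[col].fillna("").astype(str).replace({"0": "", "nan": ""})
    if ped["animal"].duplicated().any():
        raise ValueError("duplicate animals in pedigree")
    return ped[["animal", "sire", "dam"]]


def _toposort(ped: pd.DataFrame) -> list:
    """Order animals so parents precede offspring; detects cycles."""
    parents = {r.animal: (r.sire, r.dam) for r in ped.itertuples(index=False)}
    order, placed = [], set()
    remaining = list(parents)
    while remaining:
        progressed = False
        nxt = []
        for a in remaining:
            s, d = parents[a]
            if (s in placed or s not in parents) and (d in placed or d not in parents):
                order.append(a)
                placed.add(a)
                progressed = True
            else:
                nxt.append(a)
        if not progressed:
            raise ValueError("pedigree contains a cycle or unresolvable ordering")
        remaining = nxt
    return order


def build_A(pedigree: pd.DataFrame):
    """Additive relationship matrix by the tabular method.

    Returns ``(A, ids)`` with animals ordered parents-before-offspring.
    Diagonal is 1 + inbreeding coefficient.
    """
    ped = _normalise_pedigree(pedigree)
    order = _toposort(ped)
    idx = {a: i for i, a in enumerate(order)}
    parents = {r.animal: (r.sire, r.dam) for r in ped.itertuples(index=False)}
    n = len(order)
    A = np.zeros((n, n))
    for i, a in enumerate(order):
        s, d = parents[a]
        si, di = idx.get(s, -1), idx.get(d, -1)
        if si >= 0 and di >= 0:
            A[i, i] = 1.0 + 0.5 * A[si, di]
        else:
            A[i, i] = 1.0
        row = np.zeros(i)
        if si >= 0:
            row += 0.5 * A[si, :i]
        if di >= 0:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
    return A, order


def build_A_inverse(pedigree: pd.DataFrame):
    """A^-1 by Henderson's rules, inbreeding-corrected via the tabular diagonal."""
    ped = _normalise_pedigree(pedigree)
    A, order = build_A(pedigree)
    F = {a: A[i, i] - 1.0 for i, a in enumerate(order)}
    idx = {a: i for i, a in enumerate(order)}
    parents = {r.animal: (r.sire, r.dam) for r in ped.itertuples(index=False)}
    n = len(order)
    Ainv = np.zeros((n, n))
    for a in order:
        i = idx[a]
        s, d = parents[a]
        si, di = idx.get(s, -1), idx.get(d, -1)
        if si >= 0 and di >= 0:
            dvar = 0.5 - 0.25 * (F[s] + F[d])
        elif si >= 0 or di >= 0:
            known = s if si >= 0 else d
            dvar = 0.75 - 0.25 * F[known]
        else:
            dvar = 1.0
        alpha = 1.0 / dvar
        Ainv[i, i] += alpha
        for pi in (si, di):
            if pi >= 0:
                Ainv[i, pi] -= alpha / 2.0
                Ainv[pi, i] -= alpha / 2.0
        for pi in (si, di):
            for pj in (si, di):
                if pi >= 0 and pj >= 0:
                    Ainv[pi, pj] += alpha / 4.0
    return Ainv, order


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_pe2: float
    sigma_e2: float
    h2: float
    repeatability: float
    loglik: float
    n_iter: int
    converged: bool
    loglik_path: list = field(default_factory=list)
    se_h2: float | None = None
    se_repeatability: float | None = None

    def __post_init__(self) -> None:
        if min(self.sigma_g2, self.sigma_pe2, self.sigma_e2) < 0:
            raise ValueError("variance components must be non-negative")


def reml_fit(
    y,
    X,
    record_animal,
    pedigree: pd.DataFrame,
    tol: float = 1e-8,
    max_iter: int = 1000,
    accelerate: bool = True,
    init=None,
    n_boot: int = 0,
    seed: int = 0,
) -> VarianceComponents:
    """EM-REML for (sigma_g2, sigma_pe2, sigma_e2) on the repeated-records model.

    Parameters
    ----------
    y : (N,) phenotype vector, one entry per record.
    X : (N, p) fixed-effects design (include the intercept column).
    record_animal : length-N sequence mapping each record to a pedigree animal id.
    pedigree : animal/sire/dam table ('' or 0 = unknown parent).
    tol : max relative parameter change declaring convergence.
    accelerate : Aitken extrapolation with a likelihood safeguard (pure EM when False).
    n_boot : parametric-bootstrap replicates for SEs of h2/repeatability (0 = off).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    N = len(y)
    if X.shape[0] != N or len(record_animal) != N:
        raise ValueError("y, X and record_animal must have matching lengths")

    Ainv, ids = build_A_inverse(pedigree)
    sign, logdetAinv = np.linalg.slogdet(Ainv)
    if sign <= 0:
        raise ValueError("additive relationship matrix is not positive definite")
    logdetA = -logdetAinv
    idx = {a: i for i, a in enumerate(ids)}
    missing = sorted({a for a in record_animal if a not in idx})
    if missing:
        raise ValueError(f"records refer to animals absent from the pedigree: {missing[:5]}")
    q = len(ids)
    anim = np.array([idx[a] for a in record_animal])
    rec_animals = np.unique(anim)  # permanent-environment levels
    m = len(rec_animals)
    if not (np.bincount(anim).max() >= 2):
        raise ValueError("sigma_pe2 unidentifiable: no animal has repeated records")
    pe_of = {a: k for k, a in enumerate(rec_animals)}
    pe = np.array([pe_of[a] for a in anim])
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effects design is rank deficient")

    # constant cross-products
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    n_a = np.bincount(anim, minlength=q).astype(float)  # records per animal row
    n_b = n_a[rec_animals]  # per pe level
    ZutX = np.zeros((q, p))
    np.add.at(ZutX, anim, X)
    Zuty = np.bincount(anim, weights=y, minlength=q)
    Zpty = Zuty[rec_animals]
    Bx = ZutX[rec_animals].T  # X'Zp, (p, m)

    vary = max(float(np.var(y)), np.finfo(float).tiny)
    floor = 1e-12 * vary

    def evaluate(theta, need_traces):
        sg, sp, se_ = theta
        lg, lp = se_ / max(sg, floor), se_ / max(sp, floor)
        D = n_b + lp
        S = np.empty((p + q, p + q))
        S[:p, :p] = XtX
        S[:p, p:] = ZutX.T
        S[p:, :p] = ZutX
        S[p:, p:] = lg * Ainv
        S[p + rec_animals, p + rec_animals] += n_b
        # absorb the diagonal permanent-environment block
        BD = Bx / D  # (p, m)
        S[:p, :p] -= BD @ Bx.T
        S[np.ix_(np.arange(p), p + rec_animals)] -= BD * n_b
        S[np.ix_(p + rec_animals, np.arange(p))] -= (BD * n_b).T
        S[p + rec_animals, p + rec_animals] -= n_b**2 / D
        rhs = np.concatenate([Xty, Zuty])
        rhs[:p] -= BD @ Zpty
        rhs[p + rec_animals] -= n_b / D * Zpty
        c, low = cho_factor(S, lower=True)
        sol = cho_solve((c, low), rhs)
        bhat, uhat = sol[:p], sol[p:]
        phat = (Zpty - Bx.T @ bhat - n_b * uhat[rec_animals]) / D
        resid_q = yty - bhat @ Xty - uhat @ Zuty - phat @ Zpty
        yPy = resid_q / se_
        logdetC = 2.0 * np.sum(np.log(np.diag(c))) + np.sum(np.log(D))
        m2ll = (
            (N - p - q - m) * np.log(se_)
            + q * np.log(max(sg, floor))
            + m * np.log(max(sp, floor))
            + logdetA
            + logdetC
            + yPy
        )
        out = {
            "loglik": -0.5 * m2ll,
            "uhat": uhat,
            "phat": phat,
            "resid_q": resid_q,
        }
        if need_traces:
            Sinv = cho_solve((c, low), np.eye(p + q))
            Cuu = Sinv[p:, p:]
            out["tr_ACuu"] = float(np.sum(Ainv * Cuu))
            Sxx, Sxu = Sinv[:p, :p], Sinv[:p, p:]
            t1 = np.einsum("ib,ij,jb->b", Bx, Sxx, Bx)
            t2 = 2.0 * n_b * np.einsum("ib,ib->b", Bx, Sxu[:, rec_animals])
            t3 = n_b**2 * np.diag(Cuu)[rec_animals]
            out["tr_Cpp"] = float(np.sum(1.0 / D) + np.sum((t1 + t2 + t3) / D**2))
        return out

    def em_step(theta, ev):
        sg, sp, se_ = theta
        uhat, phat = ev["uhat"], ev["phat"]
        sg_new = (uhat @ Ainv @ uhat + se_ * ev["tr_ACuu"]) / q
        sp_new = (phat @ phat + se_ * ev["tr_Cpp"]) / m
        se_new = ev["resid_q"] / (N - p)
        return np.maximum([sg_new, sp_new, se_new], floor)

    if init is None:
        theta = np.array([0.3, 0.2, 0.5]) * vary
    else:
        theta = np.maximum(np.asarray(init, float), floor)

    path = []
    prev_delta = None
    converged = False
    ev = evaluate(theta, need_traces=True)
    for it in range(1, max_iter + 1):
        path.append(ev["loglik"])
        theta_new = em_step(theta, ev)
        delta = theta_new - theta
        rel = np.max(np.abs(delta) / np.maximum(theta_new, floor))
        if rel < tol:
            theta = theta_new
            converged = True
            ev = evaluate(theta, need_traces=True)
            path.append(ev["loglik"])
            break
        proposal = None
        if accelerate and prev_delta is not None and it % 3 == 0:
            with np.errstate(divide="ignore", invalid="ignore"):
                r = np.abs(delta) / np.abs(prev_delta)
            r = np.clip(np.nanmedian(r[np.isfinite(r)]) if np.isfinite(r).any() else 0.0,
                        0.0, 0.98)
            if r > 0.2:
                proposal = np.maximum(theta_new + (r / (1.0 - r)) * delta, floor)
        if proposal is not None:
            ev_prop = evaluate(proposal, need_traces=True)
            if ev_prop["loglik"] >= ev["loglik"]:
                theta, ev, prev_delta = proposal, ev_prop, None
                continue
        theta = theta_new
        ev = evaluate(theta, need_traces=True)
        prev_delta = delta
    else:
        warnings.warn("EM-REML reached max_iter without convergence", stacklevel=2)

    sg, sp, se_ = (0.0 if v <= 2 * floor else float(v) for v in theta)
    total = sg + sp + se_
    result = VarianceComponents(
        sigma_g2=sg,
        sigma_pe2=sp,
        sigma_e2=se_,
        h2=sg / total,
        repeatability=(sg + sp) / total,
        loglik=float(ev["loglik"]),
        n_iter=it,
        converged=converged,
        loglik_path=path,
    )
    if n_boot > 0:
        result.se_h2, result.se_repeatability = _bootstrap_se(
            X, anim, rec_animals, pe, pedigree, theta, record_animal, n_boot, seed, tol
        )
    return result


def _bootstrap_se(X, anim, rec_animals, pe, pedigree, theta, record_animal,
                  n_boot, seed, tol):
    """Parametric bootstrap SEs for h2 and repeatability at the fitted components."""
    rng = np.random.default_rng(seed)
    A, ids = build_A(pedigree)
    L = np.linalg.cholesky(A + 1e-10 * np.eye(len(A)))
    sg, sp, se_ = theta
    beta = np.zeros(X.shape[1])
    h2s, reps = [], []
    for _ in range(n_boot):
        u = L @ rng.normal(0, np.sqrt(sg), len(ids))
        pvals = rng.normal(0, np.sqrt(sp), len(rec_animals))
        ystar = X @ beta + u[anim] + pvals[pe] + rng.normal(0, np.sqrt(se_), len(anim))
        fit = reml_fit(ystar, X, record_animal, pedigree, tol=max(tol, 1e-6), n_boot=0)
        h2s.append(fit.h2)
        reps.append(fit.repeatability)
    return float(np.std(h2s, ddof=1)), float(np.std(reps, ddof=1))


def design_from_records(records: pd.DataFrame, trait: str = "motility_pct"):
    """Fixed-effects design (intercept, age, interval, collector, season) from records."""
    from .semenqc import _season

    df = records.dropna(subset=[trait, "age_days", "interval_days"]).copy()
    df = df[df["collector_id"].fillna("") != ""]
    df["season"] = _season(df["collection_date"])
    parts = [np.ones(len(df)), df["age_days"].to_numpy(float),
             df["interval_days"].to_numpy(float)]
    for factor in ("collector_id", "season"):
        if df[factor].astype(str).nunique() >= 2:
            parts.append(
                pd.get_dummies(df[factor].astype(str), drop_first=True, dtype=float).to_numpy()
            )
    X = np.column_stack(parts)
    return df[trait].to_numpy(float), X, df["bull_id"].tolist()
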