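"""Kinship-based variance-component heritability.

Model: y = X beta + g + e per family, with cov(g) = sigma2_g * A and
cov(e) = sigma2_e * I, where A = kinship_scale * Phi is the (numerator)
relationship matrix built from pedigree kinship.  Families are independent,
so the likelihood factorises over family blocks; each block is rotated by
the eigenvectors of its A once, after which the profile likelihood in
h2 = sigma2_g / (sigma2_g + sigma2_e) has closed-form beta and total
variance.  The maximiser is found on a coarse h2 grid followed by
golden-section refinement; the standard error of h2 comes from the
observed information (numerical second derivative of the profile
log-likelihood).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .pedigree import KinshipMatrix
from .traits import TraitTable

logger = logging.getLogger(__name__)

#: interior bound keeping h2 away from the [0, 1] boundary
EPS_H2 = 1e-6
#: golden-section convergence tolerance on h2
GOLDEN_TOL = 1e-6
_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


class HeritabilityError(ValueError):
    """Invalid input to the variance-component fit."""


@dataclass(frozen=True)
class VCModelSpec:
    """What to fit: trait, fixed effects, kinship scaling, estimator."""

    trait: str
    fixed: Sequence[str] = ("age", "sex")
    kinship_scale: float = 2.0
    estimator: str = "ML"

    def __post_init__(self) -> None:
        if self.kinship_scale <= 0:
            raise HeritabilityError("kinship_scale must be positive")
        if self.estimator.upper() not in ("ML", "REML"):
            raise HeritabilityError(f"unknown estimator {self.estimator!r}")


@dataclass
class VCFit:
    """Fitted variance components and derived heritability."""

    trait: str
    sigma2_g: float
    sigma2_e: float
    h2: float
    se_h2: float | None
    beta: dict[str, float]
    loglik: float
    converged: bool
    boundary: bool
    n: int
    n_families: int
    estimator: str


@dataclass
class CovarianceStructure:
    """Per-family relationship blocks A = scale * Phi with cached eigen pairs."""

    scale: float
    blocks: dict[str, tuple[list[str], np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )  # fid -> (iids, A, eigenvalues, eigenvectors)


def build_covariance(kin: KinshipMatrix, scale: float = 2.0) -> CovarianceStructure:
    """Relationship matrix per family block, eigendecomposed once.

    With the default scale 2 the block is the numerator relationship
    matrix 2*Phi (diagonal 1 + F).  A numerically negative eigenvalue
    flags a corrupted pedigree block.
    """
    if scale <= 0:
        raise HeritabilityError("scale must be positive")
    cov = CovarianceStructure(scale=scale)
    for fid in kin.family_ids:
        iids, phi = kin.block(fid)
        a = scale * phi
        w, u = np.linalg.eigh(a)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise HeritabilityError(
                f"family {fid!r}: relationship block not positive semidefinite "
                f"(min eigenvalue {w.min():.3g})"
            )
        cov.blocks[fid] = (iids, a, np.clip(w, 0.0, None), u)
    return cov


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------


@dataclass
class _Rotated:
    """Data rotated into the per-family eigenbasis and concatenated."""

    y: np.ndarray
    x: np.ndarray
    d: np.ndarray  # eigenvalues of A aligned with y
    n: int
    p: int
    n_families: int
    y_var: float  # raw trait variance before rotation


_SEX_CODE = {"male": 0.0, "female": 1.0, "unknown": np.nan}


def _design_matrix(df: pd.DataFrame, fixed: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(df))]
    for name in fixed:
        if name not in df.columns:
            raise HeritabilityError(f"fixed covariate {name!r} not in trait table")
        if name == "sex":
            cols.append(df["sex"].map(_SEX_CODE).to_numpy(dtype=float))
        else:
            cols.append(df[name].to_numpy(dtype=float))
    return np.column_stack(cols)


def _assemble(spec: VCModelSpec, traits: TraitTable, kin: KinshipMatrix) -> _Rotated:
    """Subset complete cases, rotate each family block, concatenate."""
    if spec.trait not in traits.values.columns:
        raise HeritabilityError(f"trait {spec.trait!r} not in table")
    if not any(
        step.get("step") == "inverse_normal_transform" for step in traits.provenance
    ):
        logger.warning(
            "trait %s does not appear to be INT-normalized; the Gaussian "
            "model assumes it is", spec.trait,
        )
    df = traits.values
    keep = df[spec.trait].notna()
    for name in spec.fixed:
        if name == "sex":
            keep &= df["sex"].isin(("male", "female"))
        else:
            keep &= df[name].notna()
    df = df[keep]
    if df.empty:
        raise HeritabilityError(f"no complete cases for trait {spec.trait!r}")
    ys, xs, ds = [], [], []
    n_fam = 0
    n_informative_pairs = 0
    for fid, sub in df.groupby("fid", sort=False):
        if fid not in kin:
            raise HeritabilityError(f"family {fid!r} missing from kinship matrix")
        iids, phi = kin.block(fid)
        pos = {iid: k for k, iid in enumerate(iids)}
        try:
            sel = [pos[str(i)] for i in sub["iid"]]
        except KeyError as exc:
            raise HeritabilityError(
                f"individual {exc.args[0]!r} of family {fid!r} missing from kinship"
            ) from exc
        a = spec.kinship_scale * phi[np.ix_(sel, sel)]
        w, u = np.linalg.eigh(a)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise HeritabilityError(
                f"family {fid!r}: relationship block not positive semidefinite"
            )
        w = np.clip(w, 0.0, None)
        y = sub[spec.trait].to_numpy(dtype=float)
        x = _design_matrix(sub, spec.fixed)
        ys.append(u.T @ y)
        xs.append(u.T @ x)
        ds.append(w)
        n_fam += 1
        k = len(sel)
        n_informative_pairs += k * (k - 1) // 2
    if n_informative_pairs < 2:
        raise HeritabilityError(
            f"only {n_informative_pairs} informative relative pairs; need >= 2"
        )
    y = np.concatenate(ys)
    x = np.vstack(xs)
    d = np.concatenate(ds)
    return _Rotated(
        y=y, x=x, d=d, n=len(y), p=x.shape[1], n_families=n_fam,
        y_var=float(df[spec.trait].var()),
    )


def _profile_loglik(rot: _Rotated, h2: float, estimator: str):
    """Profile log-likelihood at fixed h2; beta and sigma2_p are closed-form.

    V = sigma2_p * M with M = h2*A + (1-h2)*I; in the eigenbasis M is
    diagonal with weights w_i = h2*d_i + (1-h2).
    """
    w = h2 * rot.d + (1.0 - h2)
    if w.min() <= 0:
        return -np.inf, np.full(rot.p, np.nan), np.nan
    xw = rot.x / w[:, None]
    xtwx = rot.x.T @ xw
    xtwy = xw.T @ rot.y
    beta = np.linalg.solve(xtwx, xtwy)
    resid = rot.y - rot.x @ beta
    rss = float(resid @ (resid / w))
    if rss <= 0.0:
        return -np.inf, beta, np.nan
    logdet_w = float(np.log(w).sum())
    if estimator == "REML":
        dof = rot.n - rot.p
        sigma2 = rss / dof
        sign, logdet_xx = np.linalg.slogdet(xtwx)
        ll = -0.5 * (
            dof * math.log(2.0 * math.pi * sigma2) + logdet_w + logdet_xx + dof
        )
    else:
        sigma2 = rss / rot.n
        ll = -0.5 * (rot.n * math.log(2.0 * math.pi * sigma2) + logdet_w + rot.n)
    return ll, beta, sigma2


def profile_loglik(
    spec: VCModelSpec, traits: TraitTable, kin: KinshipMatrix, h2: float
) -> tuple[float, np.ndarray, float]:
    """(log-likelihood, beta-hat, sigma2_p-hat) at a fixed heritability.

    Diagnostic entry point; the returned log-likelihood is the full
    Gaussian log-density of the data at the profile maximisers, so it can
    be checked against a dense multivariate-normal evaluation.
    """
    rot = _assemble(spec, traits, kin)
    return _profile_loglik(rot, h2, spec.estimator.upper())


def _golden_section(fn, lo: float, hi: float, tol: float = GOLDEN_TOL) -> float:
    """Deterministic golden-section maximisation of a unimodal function."""
    a, b = lo, hi
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = fn(c), fn(d)
    while b - a > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = fn(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = fn(d)
    return 0.5 * (a + b)


def fit_vc(spec: VCModelSpec, traits: TraitTable, kin: KinshipMatrix) -> VCFit:
    """Maximum-likelihood (or REML) fit of the two-component model.

    The profile log-likelihood in h2 is scanned on a 21-point grid over
    [EPS_H2, 1 - EPS_H2], then refined by golden-section search on the
    bracketing interval.  All steps are deterministic.  Estimates at the
    interior bounds are flagged as boundary solutions and their SE is
    reported as unavailable rather than from a degenerate curvature.
    """
    estimator = spec.estimator.upper()
    rot = _assemble(spec, traits, kin)
    if rot.y_var == 0.0:
        raise HeritabilityError(f"trait {spec.trait!r} has zero variance")

    def ll(h2: float) -> float:
        return _profile_loglik(rot, h2, estimator)[0]

    grid = np.linspace(EPS_H2, 1.0 - EPS_H2, 21)
    values = np.array([ll(h) for h in grid])
    converged = bool(np.isfinite(values).all())
    k = int(np.nanargmax(values))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    h2_hat = _golden_section(ll, lo, hi)
    # snap to the boundary when the maximiser sits against an edge
    if h2_hat <= grid[0] + GOLDEN_TOL and ll(EPS_H2) >= ll(h2_hat):
        h2_hat = EPS_H2
    if h2_hat >= grid[-1] - GOLDEN_TOL and ll(1.0 - EPS_H2) >= ll(h2_hat):
        h2_hat = 1.0 - EPS_H2
    boundary = h2_hat <= EPS_H2 + 1e-5 or h2_hat >= 1.0 - EPS_H2 - 1e-5

    ll_hat, beta, sigma2_p = _profile_loglik(rot, h2_hat, estimator)
    se_h2 = None
    if not boundary:
        delta = 5e-4
        lo_h = max(h2_hat - delta, EPS_H2)
        hi_h = min(h2_hat + delta, 1.0 - EPS_H2)
        step = min(h2_hat - lo_h, hi_h - h2_hat)
        if step > 1e-6:
            curv = (ll(h2_hat + step) - 2.0 * ll_hat + ll(h2_hat - step)) / step**2
            if curv < 0:
                se_h2 = float(1.0 / math.sqrt(-curv))
            else:
                logger.warning(
                    "trait %s: non-concave profile at optimum, SE unavailable",
                    spec.trait,
                )
    names = ["intercept"] + list(spec.fixed)
    return VCFit(
        trait=spec.trait,
        sigma2_g=float(h2_hat * sigma2_p),
        sigma2_e=float((1.0 - h2_hat) * sigma2_p),
        h2=float(h2_hat),
        se_h2=se_h2,
        beta=dict(zip(names, map(float, beta))),
        loglik=float(ll_hat),
        converged=converged,
        boundary=bool(boundary),
        n=rot.n,
        n_families=rot.n_families,
        estimator=estimator,
    )


def h2_table(
    specs: Sequence[VCModelSpec], traits: TraitTable, kin: KinshipMatrix
) -> pd.DataFrame:
    """One row per trait: h2 and SE as percentages (0.1 resolution).

    Per-trait failures are recorded in the ``error`` column; the table is
    emitted regardless.
    """
    rows = []
    for spec in specs:
        try:
            fit = fit_vc(spec, traits, kin)
            rows.append({
                "trait": spec.trait,
                "h2_percent": round(100.0 * fit.h2, 1),
                "se_percent": (
                    round(100.0 * fit.se_h2, 1) if fit.se_h2 is not None else np.nan
                ),
                "n": fit.n,
                "converged": fit.converged,
                "boundary": fit.boundary,
                "error": "",
            })
        except (HeritabilityError, np.linalg.LinAlgError) as exc:
            logger.warning("trait %s failed: %s", spec.trait, exc)
            rows.append({
                "trait": spec.trait, "h2_percent": np.nan, "se_percent": np.nan,
                "n": 0, "converged": False, "boundary": False, "error": str(exc),
            })
    return pd.DataFrame(rows)
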