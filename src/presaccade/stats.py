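"""Multivariate and repeated-measures statistics for ERP and ROI measures.

The analysis unit is the recording session.  Virtual-electrode groups are
tested with a multivariate approach: the member channels form the response
vector and Wilks' Lambda = det(E) / det(E + H) tests each design effect,
with F and degrees of freedom from Rao's approximation.  Repeated-measures
effects are evaluated on within-unit contrast scores: for a within factor
the levels are contracted with orthonormal contrasts, and the resulting
score vectors are tested either univariately (``rm_anova``, with
Greenhouse-Geisser correction for factors with more than two levels) or as
multiple dependent variables (``rm_wilks``, the multivariate approach to
repeated measures).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError


@dataclass
class StatResult:
    effect: str
    wilks: float | None
    F: float
    df_num: float
    df_den: float
    p: float
    epsilon: float | None = None
    means: dict = field(default_factory=dict)


def _rao_f(lam: float, p: int, q: int, v_error: float) -> tuple[float, float, float, float]:
    """Rao's F approximation for Wilks' Lambda (exact for p<=2 or q<=2)."""
    m = v_error + q - (p + q + 1) / 2.0
    denom = p * p + q * q - 5
    s = math.sqrt((p * p * q * q - 4) / denom) if denom > 0 else 1.0
    df1 = p * q
    df2 = m * s - p * q / 2.0 + 1.0
    lam_s = lam ** (1.0 / s)
    F = (1.0 - lam_s) / lam_s * df2 / df1 if lam_s > 0 else np.inf
    pval = float(sps.f.sf(F, df1, df2)) if df2 > 0 else np.nan
    return F, df1, df2, pval


def _wilks(E: np.ndarray, H: np.ndarray) -> float:
    sE, ldE = np.linalg.slogdet(E)
    sEH, ldEH = np.linalg.slogdet(E + H)
    if sE <= 0 or sEH <= 0:
        raise InsufficientDataError(
            "singular error matrix; reduce the number of response variables "
            "or add units"
        )
    return float(np.exp(ldE - ldEH))


def wilks_manova(Y: np.ndarray, groups) -> StatResult:
    """One-way MANOVA: Wilks' Lambda for a between-units grouping factor.

    ``Y`` is units x variables; ``groups`` assigns each unit to a group.
    With a single response variable the Lambda-based F equals the one-way
    ANOVA F exactly.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.ndim == 2 and Y.shape[1] == 1:
        Y = Y.reshape(-1, 1)
    groups = np.asarray(groups)
    n, p = Y.shape
    levels = pd.unique(groups)
    g = len(levels)
    if g < 2:
        raise InsufficientDataError("grouping factor needs at least two levels")
    q = g - 1
    v_error = n - g
    if n < p + g:
        raise InsufficientDataError("need units >= variables + model df")
    grand = Y.mean(axis=0)
    E = np.zeros((p, p))
    H = np.zeros((p, p))
    means = {}
    for lev in levels:
        sub = Y[groups == lev]
        mu = sub.mean(axis=0)
        means[lev] = mu
        d = sub - mu
        E += d.T @ d
        dm = (mu - grand)[:, None]
        H += len(sub) * (dm @ dm.T)
    lam = _wilks(E, H)
    F, df1, df2, pval = _rao_f(lam, p, q, v_error)
    return StatResult("group", lam, F, df1, df2, pval, means={k: v for k, v in means.items()})


# ---------------------------------------------------------------------------
# Repeated measures
# ---------------------------------------------------------------------------

def _orthonormal_contrasts(levels: int) -> np.ndarray:
    """(levels-1) x levels orthonormal contrast rows (difference coding)."""
    C = np.zeros((levels - 1, levels))
    for r in range(levels - 1):
        C[r, : r + 1] = 1.0
        C[r, r + 1] = -(r + 1.0)
        C[r] /= np.linalg.norm(C[r])
    return C


def _effect_contrast(factors: dict[str, list], effect: tuple[str, ...]) -> np.ndarray:
    """Kronecker contrast over the cell axis (cells ordered by itertools.product)."""
    mat = np.ones((1, 1))
    for name, levels in factors.items():
        L = len(levels)
        block = _orthonormal_contrasts(L) if name in effect else np.full((1, L), 1.0 / L)
        mat = np.kron(mat, block)
    return mat  # (q_effect, n_cells)


def cell_matrix(
    df: pd.DataFrame,
    dv: str,
    unit: str,
    factors: dict[str, list],
    value_cols: list[str] | None = None,
) -> tuple[np.ndarray, list]:
    """Pivot a tidy table to units x cells (x variables) arrays.

    Cells are ordered by ``itertools.product`` over the factor levels.  Units
    with incomplete cells are excluded (listwise), mirroring a complete
    within-design.
    """
    cells = list(itertools.product(*factors.values()))
    fnames = list(factors.keys())
    units = sorted(df[unit].unique())
    cols = value_cols or [dv]
    out = np.full((len(units), len(cells), len(cols)), np.nan)
    for ui, u in enumerate(units):
        sub = df[df[unit] == u]
        for ci, cell in enumerate(cells):
            m = np.ones(len(sub), dtype=bool)
            for fn, lev in zip(fnames, cell):
                m &= (sub[fn] == lev).to_numpy()
            if m.sum() == 1:
                out[ui, ci, :] = sub.loc[m, cols].to_numpy()
            elif m.sum() > 1:
                out[ui, ci, :] = sub.loc[m, cols].mean().to_numpy()
    complete = ~np.isnan(out).any(axis=(1, 2))
    return out[complete], [units[i] for i in np.flatnonzero(complete)]


def rm_anova(
    data: np.ndarray, factors: dict[str, list], gg_correction: bool = True
) -> list[StatResult]:
    """Univariate repeated-measures ANOVA from within-unit contrasts.

    ``data`` is units x cells (cells ordered by ``itertools.product`` over
    the factor levels).  Each main effect and interaction is tested from its
    orthonormal contrast scores; effects with more than one contrast degree
    of freedom receive a Greenhouse-Geisser epsilon (applied to the degrees
    of freedom and the p-value, reported in ``epsilon``).
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if n < 2:
        raise InsufficientDataError("repeated-measures ANOVA needs >= 2 units")
    results = []
    names = list(factors.keys())
    for k in range(1, len(names) + 1):
        for effect in itertools.combinations(names, k):
            C = _effect_contrast(factors, effect)
            Z = data @ C.T  # units x q
            q = Z.shape[1]
            zbar = Z.mean(axis=0)
            ss_eff = n * float(zbar @ zbar)
            resid = Z - zbar
            ss_err = float((resid**2).sum())
            df1, df2 = float(q), float(q * (n - 1))
            if ss_err <= 0:
                F = 0.0 if ss_eff <= 0 else np.inf
            else:
                F = (ss_eff / df1) / (ss_err / df2)
            eps = None
            if q > 1 and gg_correction:
                Sz = np.cov(Z.T, bias=False)
                tr = np.trace(Sz)
                eps = float(tr**2 / (q * np.sum(Sz * Sz))) if np.sum(Sz * Sz) > 0 else 1.0
                eps = min(1.0, max(eps, 1.0 / q))
                df1, df2 = df1 * eps, df2 * eps
            pval = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
            results.append(StatResult(" x ".join(effect), None, F, df1, df2, pval, epsilon=eps))
    return results


def rm_wilks(data: np.ndarray, factors: dict[str, list]) -> list[StatResult]:
    """Multivariate approach to repeated measures on multichannel responses.

    ``data`` is units x cells x variables (e.g. the member channels of one
    virtual electrode group).  For each effect, the per-variable contrast
    scores form the multivariate response and Wilks' Lambda tests whether
    their mean vector is zero.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[:, :, None]
    n, _, p_vars = data.shape
    results = []
    names = list(factors.keys())
    for k in range(1, len(names) + 1):
        for effect in itertools.combinations(names, k):
            C = _effect_contrast(factors, effect)
            q = C.shape[0]
            Z = np.einsum("ucv,qc->uqv", data, C).reshape(n, q * p_vars)
            p_eff = Z.shape[1]
            if n - 1 < p_eff:
                raise InsufficientDataError(
                    f"effect {effect}: needs > {p_eff} units for {p_eff} "
                    "response variables"
                )
            zbar = Z.mean(axis=0)
            resid = Z - zbar
            E = resid.T @ resid
            H = n * np.outer(zbar, zbar)
            lam = _wilks(E, H)
            F, df1, df2, pval = _rao_f(lam, p_eff, 1, n - 1)
            results.append(StatResult(" x ".join(effect), lam, F, df1, df2, pval))
    return results


# ---------------------------------------------------------------------------
# Saccade latency summaries
# ---------------------------------------------------------------------------

def latency_table(
    trials: pd.DataFrame, by: tuple[str, ...] = ("cue", "movement")
) -> dict[str, pd.DataFrame]:
    """Condition means, SEs and cueing effects for saccade latencies.

    Only valid (non-catch, non-error, non-blink) trials with a recorded RT
    enter.  Returns the per-cell summary and, when ``cue`` is among the
    grouping factors, the cue-effect differences within each other cell.
    """
    import warnings

    t = trials.copy()
    mask = (t["movement"] != "catch") & t["rt_ms"].notna()
    for col in ("error", "blink"):
        if col in t:
            mask &= ~t[col].astype(bool)
    t = t[mask]
    cells = (
        t.groupby(list(by), observed=True)["rt_ms"]
        .agg(mean="mean", se=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0, n="count")
        .reset_index()
    )
    expected = 1
    for col in by:
        expected *= t[col].nunique()
    if len(cells) < expected:
        warnings.warn("latency_table: empty condition cells omitted", stacklevel=2)
    out = {"cells": cells}
    if "cue" in by and {"cued", "uncued"} <= set(cells["cue"]):
        others = [c for c in by if c != "cue"]
        piv = cells.pivot_table(index=others or None, columns="cue", values="mean")
        piv["cue_effect_ms"] = piv["uncued"] - piv["cued"]
        out["cue_effects"] = piv.reset_index()
    return out
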