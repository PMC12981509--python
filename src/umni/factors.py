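"""Factorability diagnostics and exploratory factor analysis.

The 11 criterion scores are ordinal but are treated as numeric for the
purpose of characterising the latent structure of the index, the common
practice for 5-point scales.  The suite runs, in order:

1. **Bartlett's test of sphericity** — chi-square test that the criterion
   correlation matrix is the identity (no inter-item correlation, nothing to
   factor):  chi2 = -(n - 1 - (2p + 5)/6) * ln det R  on  p(p-1)/2  df.
2. **Kaiser-Meyer-Olkin sampling adequacy** — per-item and overall MSA, the
   ratio of squared raw correlations to squared raw plus squared anti-image
   partial correlations; values above 0.6 are conventionally adequate.
3. **Parallel analysis** — factor-retention on the *reduced* (communality-
   adjusted, squared-multiple-correlation diagonal) correlation matrix:
   retain as many leading observed eigenvalues as exceed the eigenvalues of
   simulated uncorrelated data of identical shape.
4. **Maximum-likelihood factor extraction** with oblique (quartimin/oblimin)
   rotation, followed by grouping each criterion under its highest-|loading|
   factor.

All of this is implemented directly on numpy/scipy; the maximum-likelihood
fit uses the profile likelihood over uniquenesses (eigendecomposition of the
uniqueness-scaled correlation matrix) and the rotation uses the gradient-
projection algorithm.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import ConvergenceError, DegenerateDataError

_PSI_MIN = 0.005  # uniqueness lower bound; hitting it flags a Heywood case


def _as_corr(R) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise DegenerateDataError("correlation matrix must be square")
    if not np.allclose(R, R.T, atol=1e-8):
        raise DegenerateDataError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise DegenerateDataError("correlation matrix must have a unit diagonal")
    return R


def bartlett_sphericity(R, n: int) -> tuple[float, int, float]:
    """Bartlett's test that R is an identity matrix.

    Returns (chi2, df, p).  Requires a symmetric positive-definite R with
    unit diagonal and n > p.
    """
    R = _as_corr(R)
    p = R.shape[0]
    if n <= p:
        raise DegenerateDataError(f"need n > p (got n={n}, p={p})")
    try:
        np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        raise DegenerateDataError("correlation matrix is not positive definite") from None
    sign, logdet = np.linalg.slogdet(R)
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    p_value = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), p_value


@dataclass(frozen=True)
class KmoResult:
    msa_per_item: dict[str, float]
    msa_overall: float
    degenerate: bool  # True when there is no off-diagonal correlation (0/0)


def kmo(R, names: list[str] | None = None) -> KmoResult:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    MSA_j = sum_{i!=j} r_ij^2 / (sum_{i!=j} r_ij^2 + sum_{i!=j} q_ij^2)
    where q are the anti-image partial correlations from the scaled inverse
    of R; the overall MSA pools all off-diagonal pairs.  An identity R makes
    every MSA 0/0: returned as NaN with ``degenerate=True``.
    """
    R = _as_corr(R)
    p = R.shape[0]
    if p < 2:
        raise DegenerateDataError("need at least 2 items")
    names = names or [f"item_{i + 1}" for i in range(p)]
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        raise DegenerateDataError("correlation matrix is singular") from None
    d = 1.0 / np.sqrt(np.diag(Rinv))
    Q = -Rinv * np.outer(d, d)  # partial correlations; diagonal = -1
    np.fill_diagonal(Q, 0.0)
    R0 = R.copy()
    np.fill_diagonal(R0, 0.0)
    r2 = (R0**2).sum(axis=0)
    q2 = (Q**2).sum(axis=0)
    if r2.sum() + q2.sum() == 0:
        nan = float("nan")
        return KmoResult({nm: nan for nm in names}, nan, True)
    with np.errstate(invalid="ignore"):
        per_item = r2 / (r2 + q2)
    overall = float(r2.sum() / (r2.sum() + q2.sum()))
    return KmoResult(
        {nm: float(v) for nm, v in zip(names, per_item)}, overall, False
    )


def _corr_from_data(data) -> tuple[np.ndarray, list[str], int]:
    df = pd.DataFrame(data)
    consts = [str(c) for c in df.columns if df[c].nunique() <= 1]
    if consts:
        raise DegenerateDataError(f"constant column(s): {consts}")
    return np.corrcoef(df.to_numpy(float), rowvar=False), [str(c) for c in df.columns], len(df)


def _reduced_eigenvalues(R: np.ndarray) -> np.ndarray:
    """Eigenvalues of R with squared multiple correlations on the diagonal."""
    smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    Rr = R.copy()
    np.fill_diagonal(Rr, smc)
    return np.linalg.eigvalsh(Rr)[::-1]


@dataclass(frozen=True)
class ParallelAnalysisResult:
    n_factors: int
    observed_eigenvalues: np.ndarray
    simulated_curve: np.ndarray
    criterion: str  # "mean" | "p95"


def parallel_analysis(
    data,
    n_sim: int = 1000,
    seed: int | None = None,
    criterion: str = "mean",
) -> ParallelAnalysisResult:
    """Horn-style parallel analysis on principal-factor eigenvalues.

    The observed reduced-correlation eigenvalues are compared against the
    same quantity from ``n_sim`` simulated uncorrelated normal data sets of
    identical shape; the suggested factor count is the length of the leading
    run of observed eigenvalues exceeding the comparison curve (mean of the
    simulated eigenvalues by default, 95th percentile with ``"p95"``).
    """
    if criterion not in ("mean", "p95"):
        raise DegenerateDataError(f"unknown comparison criterion {criterion!r}")
    R, _, n = _corr_from_data(data)
    p = R.shape[0]
    if n < p + 1:
        raise DegenerateDataError(f"need at least p+1 rows (got n={n}, p={p})")
    obs = _reduced_eigenvalues(R)
    rng = np.random.default_rng(seed)
    sim = np.empty((n_sim, p))
    for i in range(n_sim):
        Z = rng.standard_normal((n, p))
        sim[i] = _reduced_eigenvalues(np.corrcoef(Z, rowvar=False))
    curve = sim.mean(axis=0) if criterion == "mean" else np.percentile(sim, 95, axis=0)
    k = 0
    while k < p and obs[k] > curve[k]:
        k += 1
    return ParallelAnalysisResult(k, obs, curve, criterion)


def _ml_extract(R: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Maximum-likelihood factor extraction via the uniqueness profile
    likelihood; returns (unrotated loadings, uniquenesses, n_iter)."""
    p = R.shape[0]

    def objective(psi: np.ndarray) -> float:
        scale = 1.0 / np.sqrt(psi)
        M = R * np.outer(scale, scale)
        lam = np.linalg.eigvalsh(M)[::-1][k:]
        lam = np.clip(lam, 1e-12, None)
        return float(np.sum(lam - np.log(lam) - 1.0))

    smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    psi0 = np.clip(1.0 - 0.5 * smc, _PSI_MIN, 1.0)
    res = optimize.minimize(
        objective, psi0, method="L-BFGS-B",
        bounds=[(_PSI_MIN, 1.0)] * p,
        options={"maxiter": 1000, "ftol": 1e-12},
    )
    if not res.success:
        raise ConvergenceError(
            f"ML factor extraction did not converge: {res.message}",
            n_iter=int(res.nit),
        )
    psi = res.x
    scale = 1.0 / np.sqrt(psi)
    M = R * np.outer(scale, scale)
    vals, vecs = np.linalg.eigh(M)
    vals, vecs = vals[::-1][:k], vecs[:, ::-1][:, :k]
    load = np.sqrt(psi)[:, None] * vecs * np.sqrt(np.clip(vals - 1.0, 0, None))
    return load, psi, int(res.nit)


def _quartimin(L: np.ndarray) -> tuple[float, np.ndarray]:
    k = L.shape[1]
    L2 = L**2
    X = L2 @ (np.ones((k, k)) - np.eye(k))
    return float(np.sum(L2 * X) / 4.0), L * X


def _oblimin_rotate(
    A: np.ndarray, max_iter: int = 1000, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Gradient-projection oblique rotation with the quartimin criterion.

    Returns (rotated loadings, factor correlation matrix, converged).
    """
    p, k = A.shape
    if k == 1:
        return A.copy(), np.ones((1, 1)), True
    T = np.eye(k)
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _quartimin(L)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    converged = False
    for _ in range(max_iter):
        Gp = G - T @ np.diag(np.sum(T * G, axis=0))
        s = np.linalg.norm(Gp)
        if s < tol:
            converged = True
            break
        al *= 2.0
        for _ in range(60):
            X = T - al * Gp
            v = 1.0 / np.sqrt(np.sum(X**2, axis=0))
            Tt = X @ np.diag(v)
            Ti = np.linalg.inv(Tt)
            L = A @ Ti.T
            ft, Gq = _quartimin(L)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        T, f = Tt, ft
        G = -(L.T @ Gq @ Ti).T
    phi = T.T @ T
    return L, phi, converged


@dataclass(frozen=True)
class EfaResult:
    loadings: pd.DataFrame  # criteria x factors (columns F1..Fk)
    uniquenesses: pd.Series
    factor_corr: np.ndarray
    n_iter: int
    heywood: bool
    rotation: str


def efa(data, k: int, rotation: str = "oblimin") -> EfaResult:
    """Maximum-likelihood EFA with oblique rotation.

    ``data`` is an n x p table (n > p rows required); ``k`` factors are
    extracted (k < p).  Heywood cases (a uniqueness pinned at its lower
    bound) are flagged, not fatal.  Column signs are normalised so each
    factor's dominant loading is positive; grouping downstream uses
    absolute loadings so sign flips never change groupings.
    """
    R, names, n = _corr_from_data(data)
    p = R.shape[0]
    if not 1 <= k < p:
        raise DegenerateDataError(f"factor count k={k} must be in [1, p-1]")
    if n <= p:
        raise DegenerateDataError(f"need more rows than items (n={n}, p={p})")
    if rotation not in ("oblimin", "none"):
        raise DegenerateDataError(f"unknown rotation {rotation!r}")
    A, psi, n_iter = _ml_extract(R, k)
    if rotation == "oblimin":
        L, phi, rot_ok = _oblimin_rotate(A)
        if not rot_ok:
            warnings.warn("oblimin rotation hit its iteration limit", stacklevel=2)
    else:
        L, phi = A, np.eye(k)
    # sign convention: dominant loading of each factor positive
    for j in range(k):
        if L[np.argmax(np.abs(L[:, j])), j] < 0:
            L[:, j] = -L[:, j]
            phi[j, :] *= -1
            phi[:, j] *= -1
    cols = [f"F{j + 1}" for j in range(k)]
    return EfaResult(
        pd.DataFrame(L, index=names, columns=cols),
        pd.Series(psi, index=names, name="uniqueness"),
        phi, n_iter, bool(np.any(psi <= _PSI_MIN + 1e-9)), rotation,
    )


def group_by_loading(loadings: pd.DataFrame) -> dict[int, list[str]]:
    """Assign each criterion to the factor where it loads strongest (by
    |loading|); ties break to the lowest factor index with a warning."""
    k = loadings.shape[1]
    groups: dict[int, list[str]] = {j + 1: [] for j in range(k)}
    for crit, row in loadings.iterrows():
        absrow = row.abs().to_numpy()
        best = int(np.argmax(absrow))
        if (absrow == absrow[best]).sum() > 1:
            warnings.warn(
                f"criterion {crit!r}: tied loadings, assigned to factor {best + 1}",
                stacklevel=2,
            )
        groups[best + 1].append(str(crit))
    return groups


@dataclass(frozen=True)
class FactorReport:
    """Full factorability + EFA report for one score table."""

    n: int
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    msa_per_item: dict[str, float]
    msa_overall: float
    n_factors_suggested: int
    loadings: pd.DataFrame | None
    groupings: dict[int, list[str]] | None
    efa_skipped_reason: str | None = None
    observed_eigenvalues: np.ndarray | None = None
    simulated_curve: np.ndarray | None = None
    factor_corr: np.ndarray | None = None
    heywood: bool = False


def run_factor_suite(
    data,
    n_sim: int = 1000,
    seed: int | None = None,
    rotation: str = "oblimin",
    kmo_minimum: float = 0.5,
    pa_criterion: str = "mean",
) -> FactorReport:
    """Bartlett -> KMO -> parallel analysis -> EFA -> grouping, end to end.

    EFA is skipped (with the reason recorded) when Bartlett fails to reject
    sphericity at 0.05, when overall KMO is below ``kmo_minimum``, or when
    parallel analysis suggests zero factors.
    """
    R, names, n = _corr_from_data(data)
    chi2, df, p_value = bartlett_sphericity(R, n)
    km = kmo(R, names)
    pa = parallel_analysis(data, n_sim=n_sim, seed=seed, criterion=pa_criterion)

    skipped = None
    if p_value >= 0.05:
        skipped = f"Bartlett test does not reject sphericity (p={p_value:.3g})"
    elif not km.degenerate and km.msa_overall < kmo_minimum:
        skipped = f"overall KMO {km.msa_overall:.3f} below {kmo_minimum}"
    elif pa.n_factors == 0:
        skipped = "parallel analysis suggests zero factors"

    loadings = groupings = phi = None
    heywood = False
    if skipped is None:
        result = efa(data, k=pa.n_factors, rotation=rotation)
        loadings, phi, heywood = result.loadings, result.factor_corr, result.heywood
        groupings = group_by_loading(loadings)
    else:
        warnings.warn(f"EFA skipped: {skipped}", stacklevel=2)

    return FactorReport(
        n=n, bartlett_chi2=chi2, bartlett_df=df, bartlett_p=p_value,
        msa_per_item=km.msa_per_item, msa_overall=km.msa_overall,
        n_factors_suggested=pa.n_factors,
        loadings=loadings, groupings=groupings, efa_skipped_reason=skipped,
        observed_eigenvalues=pa.observed_eigenvalues,
        simulated_curve=pa.simulated_curve,
        factor_corr=phi, heywood=heywood,
    )


def write_factor_report(report: FactorReport, path: str | Path) -> None:
    """FactorReport as JSON (loadings inlined as a nested mapping)."""
    payload = {
        "n": report.n,
        "bartlett": {
            "chi2": report.bartlett_chi2, "df": report.bartlett_df,
            "p": report.bartlett_p,
        },
        "kmo": {
            "per_item": report.msa_per_item, "overall": report.msa_overall,
        },
        "n_factors_suggested": report.n_factors_suggested,
        "efa_skipped_reason": report.efa_skipped_reason,
        "heywood": report.heywood,
        "loadings": (
            None if report.loadings is None
            else {c: report.loadings[c].round(6).to_dict()
                  for c in report.loadings.columns}
        ),
        "groupings": (
            None if report.groupings is None
            else {str(k): v for k, v in report.groupings.items()}
        ),
    }

    def _clean(obj):
        if isinstance(obj, float) and np.isnan(obj):
            return None
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, list):
            return [_clean(v) for v in obj]
        return obj

    Path(path).write_text(
        json.dumps(_clean(payload), indent=2) + "\n", encoding="utf-8"
    )


def write_eigenvalue_csv(report: FactorReport, path: str | Path) -> None:
    if report.observed_eigenvalues is None:
        raise DegenerateDataError("report has no eigenvalue traces")
    pd.DataFrame({
        "component": np.arange(1, len(report.observed_eigenvalues) + 1),
        "observed": report.observed_eigenvalues,
        "simulated": report.simulated_curve,
    }).to_csv(path, index=False, encoding="utf-8")
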