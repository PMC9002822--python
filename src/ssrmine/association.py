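"""Q+K mixed-linear-model marker-trait association for multi-allelic SSRs.

Model per trait and environment, on accession replicate means y:

    y = mu + Q v + marker allele-class effects + u + e,
    u ~ N(0, sigma_g^2 K),   e ~ N(0, sigma_e^2 I)

Q (admixture proportions, one column dropped) corrects stratification; the
kinship random effect u corrects cryptic relatedness.  Variance components
are estimated once by REML under the no-marker null on the eigendecomposed
kinship (a single variance-ratio parameter), then reused for every marker
— the population-parameters-previously-determined strategy.  Each marker
enters as a categorical allele-class term (reference = most frequent
allele; NULL is an ordinary class) and is tested with an omnibus F-type
test on generalized-least-squares-whitened data, so one p-value per marker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

from .datamodel import (
    KinshipMatrix,
    PhenotypeTable,
    QMatrix,
    SSRGenotypeTable,
    is_missing,
    is_null,
)
from .popgen import assign_subpopulations, ADMIXED

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Kinship


def kinship_matrix(g: SSRGenotypeTable) -> KinshipMatrix:
    """Allele-sharing kinship: pairwise proportion of matching alleles
    across co-scored loci, centered by the mean off-diagonal value,
    truncated below at 0; diagonal fixed at 1.

    NULL counts as an ordinary allele class (two lines sharing a
    non-amplified state are similar there); MISSING calls are skipped.
    """
    acc = g.accessions
    n = len(acc)
    match = np.zeros((n, n))
    scored = np.zeros((n, n))
    for marker in g.markers:
        col = g.calls[marker]
        codes = np.full(n, -1)
        labels: dict = {}
        for i, v in enumerate(col):
            if is_missing(v):
                continue
            key = "NULL" if is_null(v) else v
            codes[i] = labels.setdefault(key, len(labels))
        valid = codes >= 0
        vv = valid[:, None] & valid[None, :]
        scored += vv
        match += vv & (codes[:, None] == codes[None, :])
    if (scored[np.triu_indices(n, 1)] == 0).any():
        raise ValueError("some accession pair shares no scored loci")
    sim = match / np.maximum(scored, 1)
    off = sim[np.triu_indices(n, 1)]
    mean_off = off.mean()
    k = (sim - mean_off) / (1.0 - mean_off)
    k = np.clip(k, 0.0, 1.0)
    np.fill_diagonal(k, 1.0)
    return KinshipMatrix(pd.DataFrame(k, index=acc, columns=acc))


# ---------------------------------------------------------------------------
# REML on the kinship eigendecomposition


@dataclass(eq=False)
class MLMFit:
    """Null-model variance components and fixed effects."""

    sigma_g2: float
    sigma_e2: float
    beta: np.ndarray
    reml_loglik: float
    delta: float  # sigma_g2 / sigma_e2


def _reml_loglik(log_delta, s, yt, xt):
    """Restricted log-likelihood profiled over the variance ratio.

    ``s`` are kinship eigenvalues; ``yt``/``xt`` the rotated response and
    fixed-effect design.
    """
    delta = np.exp(log_delta)
    n, p = xt.shape
    w = delta * s + 1.0  # Var(yt) = sigma_e2 * diag(w)
    xw = xt / w[:, None]
    xtx = xt.T @ xw
    beta = np.linalg.solve(xtx, xw.T @ yt)
    r = yt - xt @ beta
    rss = float(r @ (r / w))
    sigma_e2 = rss / (n - p)
    _, logdet_xtx = np.linalg.slogdet(xtx)
    ll = -0.5 * (
        (n - p) * np.log(2 * np.pi * sigma_e2)
        + np.sum(np.log(w))
        + logdet_xtx
        + (n - p)
    )
    return ll, beta, sigma_e2


def fit_null_mlm(y: np.ndarray, x: np.ndarray, k: np.ndarray, tol: float = 1e-8) -> MLMFit:
    """REML fit of the no-marker mixed model by bounded scalar search
    over log(sigma_g2/sigma_e2) on the kinship eigendecomposition."""
    s, u = np.linalg.eigh(k)
    s = np.clip(s, 0.0, None)
    yt, xt = u.T @ y, u.T @ x

    def neg(log_delta):
        return -_reml_loglik(log_delta, s, yt, xt)[0]

    res = minimize_scalar(neg, bounds=(-12.0, 12.0), method="bounded",
                          options={"xatol": tol})
    ll, beta, sigma_e2 = _reml_loglik(res.x, s, yt, xt)
    delta = float(np.exp(res.x))
    return MLMFit(
        sigma_g2=delta * sigma_e2,
        sigma_e2=sigma_e2,
        beta=beta,
        reml_loglik=ll,
        delta=delta,
    )


# ---------------------------------------------------------------------------
# Scan


def _allele_design(g: SSRGenotypeTable, accessions, marker):
    """Allele-class dummy matrix (reference = most frequent class).

    Returns (matrix, class labels, row mask of accessions scored at the
    marker).  NULL is an ordinary class; MISSING rows are masked out.
    """
    col = g.calls.loc[accessions, marker]
    keys = ["NULL" if is_null(v) else v for v in col]
    mask = np.array([not is_missing(v) for v in col])
    scored = [k for k, m in zip(keys, mask) if m]
    if not scored:
        return None, [], mask
    counts = pd.Series(scored).value_counts()
    classes = list(counts.index)  # most frequent first = reference
    if len(classes) < 2:
        return None, classes, mask
    dummies = np.zeros((mask.sum(), len(classes) - 1))
    for i, k in enumerate(scored):
        j = classes.index(k)
        if j > 0:
            dummies[i, j - 1] = 1.0
    return dummies, classes, mask


def _ols_rss(x, y):
    beta, res, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    r = y - x @ beta
    return float(r @ r), rank


def mlm_scan(
    g: SSRGenotypeTable,
    p: PhenotypeTable,
    q: QMatrix | None,
    k: KinshipMatrix,
    trait: str,
    env=None,
    q_threshold: float | None = 0.9,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Q+K mixed-model scan of every marker for one trait/environment.

    ``q_threshold`` replicates the pre-mapping filter that drops accessions
    whose maximum admixture proportion does not exceed the threshold
    (pass ``None`` to retain admixed accessions).  Returns a DataFrame with
    marker, p_value, fdr_adjusted_p, significant, pve_pct, df and allele
    class count; markers with fewer than two allele classes are skipped
    and logged.
    """
    means = p.accession_means(trait, env)
    acc = [a for a in g.accessions if a in means.index and a in k.accessions]
    if q is not None:
        acc = [a for a in acc if a in q.accessions]
        if q_threshold is not None:
            assigned = assign_subpopulations(q, q_threshold)
            acc = [a for a in acc if assigned[a] != ADMIXED]
    if len(acc) < 10:
        raise ValueError(f"only {len(acc)} accessions shared across inputs")
    y = means.loc[acc].to_numpy(dtype=float)
    x0 = np.ones((len(acc), 1))
    if q is not None:
        # drop one admixture column to avoid singularity with the intercept
        x0 = np.hstack([x0, q.proportions.loc[acc].to_numpy(dtype=float)[:, :-1]])
    kmat = k.values.loc[acc, acc].to_numpy(dtype=float)
    # guard against non-positive-definite kinship
    eigmin = np.linalg.eigvalsh(kmat).min()
    if eigmin < -1e-8:
        # routine for the truncated allele-sharing estimator
        logger.info("kinship not PSD (min eig %.3g); adding ridge", eigmin)
        kmat = kmat + (1e-6 - eigmin) * np.eye(len(acc))

    fit = fit_null_mlm(y, x0, kmat)
    v = fit.sigma_g2 * kmat + fit.sigma_e2 * np.eye(len(acc))
    l_full = np.linalg.cholesky(v)

    rows = []
    for marker in g.markers:
        dummies, classes, mask = _allele_design(g, acc, marker)
        if dummies is None:
            logger.info("marker %s skipped: <2 allele classes", marker)
            continue
        if mask.all():
            l = l_full
            yy, xx0 = y, x0
        else:
            idx = np.flatnonzero(mask)
            l = np.linalg.cholesky(v[np.ix_(idx, idx)])
            yy, xx0 = y[mask], x0[mask]
        yw = solve_triangular(l, yy, lower=True)
        x0w = solve_triangular(l, xx0, lower=True)
        x1w = solve_triangular(l, np.hstack([xx0, dummies]), lower=True)
        rss0, rank0 = _ols_rss(x0w, yw)
        rss1, rank1 = _ols_rss(x1w, yw)
        df_marker = rank1 - rank0
        df_resid = len(yw) - rank1
        if df_marker < 1 or df_resid < 1 or rss1 <= 0:
            continue
        f = ((rss0 - rss1) / df_marker) / (rss1 / df_resid)
        pval = float(stats.f.sf(f, df_marker, df_resid))
        tss = float(((yw - yw.mean()) ** 2).sum())
        pve = 100.0 * max(0.0, rss0 - rss1) / tss if tss > 0 else 0.0
        rows.append(
            {
                "marker": marker,
                "trait": trait,
                "env": env if env is not None else "combined",
                "n_classes": len(classes),
                "df": df_marker,
                "f_stat": f,
                "p_value": min(1.0, max(pval, np.finfo(float).tiny)),
                "pve_pct": min(pve, 100.0),
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        adj, rej = bh_fdr(out["p_value"].to_numpy(), fdr_q)
        out["fdr_adjusted_p"] = adj
        out["significant"] = rej
    out.attrs["null_fit"] = fit
    return out


def bh_fdr(pvalues, q: float = 0.05):
    """Benjamini-Hochberg step-up FDR control.

    Returns ``(adjusted p-values, rejection flags)`` at level ``q``.
    """
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        raise ValueError("empty p-value input")
    if ((pvalues <= 0) | (pvalues > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    rej, adj, _, _ = multipletests(pvalues, alpha=q, method="fdr_bh")
    return adj, rej


def stable_markers(results_by_env: dict) -> tuple[set, dict]:
    """Markers significant (FDR flag) in every environment.

    ``results_by_env`` maps environment -> mlm_scan DataFrame for one
    trait.  Returns ``(stable set, {env: env-specific set})`` where an
    environment-specific marker is significant there but not in all
    environments.
    """
    if len(results_by_env) < 2:
        raise ValueError("need >= 2 environments")
    sig = {
        env: set(df.loc[df["significant"], "marker"])
        for env, df in results_by_env.items()
    }
    stable = set.intersection(*sig.values())
    specific = {env: s - stable for env, s in sig.items()}
    return stable, specific
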