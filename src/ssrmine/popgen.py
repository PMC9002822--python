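"""Diversity, distance/tree, structure-summary, differentiation and LD
statistics for multi-allelic SSR data on inbred (haploid-equivalent) lines.

All frequency-based statistics exclude MISSING calls; NULL (non-amplified)
calls are excluded by default as well — the null allele is a baseline
device for effect estimation, not a biological allele — but every function
takes ``include_null=True`` to count it as an allele class.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj

from .datamodel import QMatrix, SSRGenotypeTable, is_missing, is_null

ADMIXED = "ADMIXED"

#: Sentinel Nei distance for groups sharing no alleles (J_xy = 0), so that
#: neighbor-joining stays finite; such pairs carry ``infinite=True``.
NEI_SENTINEL = 30.0


# ---------------------------------------------------------------------------
# Per-locus diversity


def _locus_frequencies(g: SSRGenotypeTable, marker, include_null: bool) -> pd.Series:
    return g.allele_frequencies(marker, include_null=include_null)


def informativeness_class(pic: float) -> str:
    """Discriminating-power class: PIC > 0.5 high, 0.25 < PIC <= 0.5
    moderate, else slight."""
    if pic > 0.5:
        return "high"
    if pic > 0.25:
        return "moderate"
    return "slight"


def locus_summary(g: SSRGenotypeTable, include_null: bool = False) -> pd.DataFrame:
    """Allele number, major allele frequency, gene diversity and PIC.

    Gene diversity (expected heterozygosity) He = 1 - sum p_i^2.  PIC is
    Botstein's index: He minus the pairwise term
    sum_{i<j} 2 p_i^2 p_j^2.
    """
    rows = []
    for marker in g.markers:
        p = _locus_frequencies(g, marker, include_null).to_numpy()
        he = 1.0 - float(np.sum(p**2))
        pair = sum(2.0 * p[i] ** 2 * p[j] ** 2 for i in range(len(p)) for j in range(i + 1, len(p)))
        pic = he - pair
        rows.append(
            {
                "marker": marker,
                "n_alleles": len(p),
                "major_allele_freq": float(p.max()),
                "gene_diversity": he,
                "pic": pic,
                "class": informativeness_class(pic),
            }
        )
    return pd.DataFrame(rows).set_index("marker")


# ---------------------------------------------------------------------------
# Nei distance and neighbor-joining


def _group_frequencies(g: SSRGenotypeTable, members, marker, include_null: bool):
    col = g.calls.loc[list(members), marker]
    scored = [v for v in col if not is_missing(v) and (include_null or not is_null(v))]
    if not scored:
        return None
    return pd.Series(scored).value_counts(normalize=True)


def nei_distance(
    g: SSRGenotypeTable,
    grouping: dict | None = None,
    include_null: bool = False,
):
    """Nei's standard genetic distance between groups (or accessions).

    D = -ln( J_xy / sqrt(J_x J_y) ) with the allele-frequency products
    J averaged over loci before the log.  ``grouping`` maps group label ->
    accession list; omitted, each accession is its own group.  Returns
    ``(DataFrame distance matrix, DataFrame bool flags)`` where a flag marks
    a pair with J_xy = 0 reported as the finite sentinel.
    """
    if grouping is None:
        grouping = {acc: [acc] for acc in g.accessions}
    labels = list(grouping)
    if len(labels) < 2:
        raise ValueError("need at least 2 units")
    freqs = {
        lab: {m: _group_frequencies(g, members, m, include_null) for m in g.markers}
        for lab, members in grouping.items()
    }
    D = pd.DataFrame(0.0, index=labels, columns=labels)
    flags = pd.DataFrame(False, index=labels, columns=labels)
    for x, y in itertools.combinations(labels, 2):
        jx = jy = jxy = 0.0
        n_shared = 0
        for m in g.markers:
            fx, fy = freqs[x][m], freqs[y][m]
            if fx is None or fy is None:
                continue
            n_shared += 1
            jx += float((fx**2).sum())
            jy += float((fy**2).sum())
            shared = fx.index.intersection(fy.index)
            jxy += float((fx[shared] * fy[shared]).sum())
        if n_shared == 0:
            raise ValueError(f"groups {x!r} and {y!r} share no scored loci")
        jx, jy, jxy = jx / n_shared, jy / n_shared, jxy / n_shared
        if jxy <= 0:
            d, inf = NEI_SENTINEL, True
        else:
            d, inf = -math.log(jxy / math.sqrt(jx * jy)), False
        D.at[x, y] = D.at[y, x] = max(0.0, d)
        flags.at[x, y] = flags.at[y, x] = inf
    return D, flags


def nj_tree(D: pd.DataFrame, clamp_negative: bool = False):
    """Saitou-Nei neighbor-joining tree from a symmetric distance matrix.

    Returns a scikit-bio TreeNode.  NJ can produce negative branch lengths
    on non-additive input; they are reported as-is unless
    ``clamp_negative`` is set.
    """
    arr = D.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 leaves")
    tree = nj(DistanceMatrix(arr, [str(i) for i in D.index]))
    if clamp_negative:
        for node in tree.traverse():
            if node.length is not None and node.length < 0:
                node.length = 0.0
    return tree


# ---------------------------------------------------------------------------
# Evanno delta-K


def evanno_delta_k(logliks: pd.DataFrame) -> pd.DataFrame:
    """Second-difference statistic for choosing the subpopulation number.

    ``logliks`` is long format with columns K, replicate, loglik (>= 3
    consecutive K, >= 2 replicates each).  For interior K,
    deltaK = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd L(K); the K
    with maximal deltaK is the supported subpopulation number.  A K whose
    replicate sd is 0 gets deltaK = NaN and ``undefined=True``.
    """
    grp = logliks.groupby("K")["loglik"]
    ks = sorted(grp.groups)
    if len(ks) < 3:
        raise ValueError("need >= 3 K values")
    if any(b - a != ks[1] - ks[0] for a, b in zip(ks, ks[1:])) or ks[1] - ks[0] != 1:
        raise ValueError("K values must be consecutive")
    if (grp.count() < 2).any():
        raise ValueError("need >= 2 replicates per K")
    mean, sd = grp.mean(), grp.std(ddof=1)
    rows = []
    for i, k in enumerate(ks):
        lp = mean[ks[i + 1]] - mean[k] if i + 1 < len(ks) else np.nan
        if 0 < i < len(ks) - 1:
            lpp = abs(mean[ks[i + 1]] - 2 * mean[k] + mean[ks[i - 1]])
            dk = lpp / sd[k] if sd[k] > 0 else np.nan
        else:
            lpp = dk = np.nan
        rows.append(
            {
                "K": k,
                "mean_loglik": mean[k],
                "sd_loglik": sd[k],
                "Lprime": lp,
                "abs_Lpp": lpp,
                "deltaK": dk,
                "undefined": bool(0 < i < len(ks) - 1 and sd[k] == 0),
            }
        )
    out = pd.DataFrame(rows).set_index("K")
    out.attrs["best_K"] = int(out["deltaK"].idxmax()) if out["deltaK"].notna().any() else None
    return out


def assign_subpopulations(q: QMatrix, threshold: float = 0.9) -> pd.Series:
    """Assign each accession to its majority subpopulation if the maximum
    admixture proportion strictly exceeds ``threshold``; otherwise
    ADMIXED."""
    p = q.proportions
    best = p.idxmax(axis=1)
    maxval = p.max(axis=1)
    out = best.where(maxval > threshold, ADMIXED)
    out.name = "subpop"
    return out


# ---------------------------------------------------------------------------
# AMOVA


def _mismatch_matrix(g: SSRGenotypeTable, accessions, include_null: bool) -> np.ndarray:
    """Pairwise count of allele differences across co-scored loci."""
    acc = list(accessions)
    n = len(acc)
    calls = g.calls.loc[acc]
    d = np.zeros((n, n))
    # encode each marker to integer codes; missing -> -1
    for marker in g.markers:
        col = calls[marker]
        codes = np.full(n, -1)
        labels: dict = {}
        for i, v in enumerate(col):
            if is_missing(v) or (not include_null and is_null(v)):
                continue
            key = "NULL" if is_null(v) else v
            codes[i] = labels.setdefault(key, len(labels))
        valid = codes >= 0
        diff = (codes[:, None] != codes[None, :]) & valid[:, None] & valid[None, :]
        d += diff
    return d


@dataclass
class AmovaResult:
    df_among: int
    df_within: int
    ssd_among: float
    ssd_within: float
    sigma2_among: float  # raw, may be negative
    sigma2_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    p_value: float
    n_permutations: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "df": [self.df_among, self.df_within],
                "SSD": [self.ssd_among, self.ssd_within],
                "variance": [self.sigma2_among, self.sigma2_within],
                "pct": [self.pct_among, self.pct_within],
            },
            index=["among", "within"],
        )


def _amova_components(d2: np.ndarray, labels: np.ndarray):
    n = len(labels)
    groups = np.unique(labels)
    ssd_total = d2[np.triu_indices(n, 1)].sum() / n
    ssd_within = 0.0
    sizes = []
    for gl in groups:
        idx = np.flatnonzero(labels == gl)
        sizes.append(len(idx))
        sub = d2[np.ix_(idx, idx)]
        ssd_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ssd_among = ssd_total - ssd_within
    df_a, df_w = len(groups) - 1, n - len(groups)
    ms_w = ssd_within / df_w
    n0 = (n - sum(s**2 for s in sizes) / n) / df_a
    sigma_a = (ssd_among / df_a - ms_w) / n0
    return ssd_among, ssd_within, sigma_a, ms_w, df_a, df_w


def amova(
    g: SSRGenotypeTable,
    groups: dict,
    n_permutations: int = 999,
    seed: int = 0,
    include_null: bool = False,
) -> AmovaResult:
    """One-level analysis of molecular variance over squared allele-
    mismatch distances.

    ``groups`` maps group label -> accession list (>= 2 groups of >= 2).
    Negative among-group components are reported raw and truncated to zero
    only for the percentage computation.  The permutation p-value shuffles
    group labels and uses the add-one correction (b+1)/(m+1).
    """
    if len(groups) < 2 or any(len(m) < 2 for m in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 members each")
    accessions = [a for members in groups.values() for a in members]
    labels = np.concatenate(
        [np.full(len(m), i) for i, m in enumerate(groups.values())]
    )
    d2 = _mismatch_matrix(g, accessions, include_null)
    ssd_a, ssd_w, sig_a, sig_w, df_a, df_w = _amova_components(d2, labels)
    sig_a_t = max(0.0, sig_a)
    total = sig_a_t + sig_w
    pct_a = 100.0 * sig_a_t / total if total > 0 else 0.0
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        _, _, sig_perm, _, _, _ = _amova_components(d2, perm)
        if sig_perm >= sig_a:
            b += 1
    return AmovaResult(
        df_among=df_a,
        df_within=df_w,
        ssd_among=ssd_a,
        ssd_within=ssd_w,
        sigma2_among=sig_a,
        sigma2_within=sig_w,
        pct_among=pct_a,
        pct_within=100.0 - pct_a,
        phi_st=sig_a_t / total if total > 0 else 0.0,
        p_value=(b + 1) / (n_permutations + 1),
        n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# Pairwise Fst (Weir-Cockerham-type, haploid-equivalent counts)


def _theta_sums(g: SSRGenotypeTable, members1, members2, include_null: bool):
    """Per-pair numerator/denominator sums of the ANOVA theta estimator."""
    num = den = 0.0
    polymorphic = False
    for marker in g.markers:
        f1 = _group_frequencies(g, members1, marker, include_null)
        f2 = _group_frequencies(g, members2, marker, include_null)
        if f1 is None or f2 is None:
            continue
        col1 = g.calls.loc[list(members1), marker]
        col2 = g.calls.loc[list(members2), marker]
        n1 = sum(1 for v in col1 if not is_missing(v) and (include_null or not is_null(v)))
        n2 = sum(1 for v in col2 if not is_missing(v) and (include_null or not is_null(v)))
        if n1 < 2 or n2 < 2:
            continue
        alleles = f1.index.union(f2.index)
        if len(alleles) < 2:
            continue
        polymorphic = True
        n = n1 + n2
        nc = (n - (n1**2 + n2**2) / n) / 1.0  # r - 1 = 1
        for a in alleles:
            p1 = float(f1.get(a, 0.0))
            p2 = float(f2.get(a, 0.0))
            pbar = (n1 * p1 + n2 * p2) / n
            msa = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / 1.0
            msw = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n - 2)
            sigma_a = (msa - msw) / nc
            num += sigma_a
            den += sigma_a + msw
    return num, den, polymorphic


def pairwise_fst(
    g: SSRGenotypeTable,
    groups: dict,
    n_permutations: int = 0,
    seed: int = 0,
    include_null: bool = False,
):
    """Pairwise Weir-Cockerham-type theta between groups, ratio-of-sums
    over loci and alleles, with optional permutation p-values.

    Returns ``(theta DataFrame, p-value DataFrame)``; a pair with no
    polymorphic shared locus gets NaN.
    """
    if len(groups) < 2 or any(len(m) < 2 for m in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 members each")
    labels = list(groups)
    theta = pd.DataFrame(np.nan, index=labels, columns=labels)
    pvals = pd.DataFrame(np.nan, index=labels, columns=labels)
    rng = np.random.default_rng(seed)
    for x, y in itertools.combinations(labels, 2):
        num, den, poly = _theta_sums(g, groups[x], groups[y], include_null)
        if not poly or den == 0:
            continue
        obs = num / den
        theta.at[x, y] = theta.at[y, x] = obs
        if n_permutations > 0:
            pool = list(groups[x]) + list(groups[y])
            nx = len(groups[x])
            b = 0
            for _ in range(n_permutations):
                perm = rng.permutation(pool)
                pn, pdn, pp = _theta_sums(g, perm[:nx], perm[nx:], include_null)
                if pp and pdn != 0 and pn / pdn >= obs:
                    b += 1
            pvals.at[x, y] = pvals.at[y, x] = (b + 1) / (n_permutations + 1)
    np.fill_diagonal(theta.values, 0.0)
    return theta, pvals


# ---------------------------------------------------------------------------
# Multi-allelic D'


def _dprime_from_calls(a: list, b: list) -> float:
    """Multi-allelic D' from paired haploid calls (no missing)."""
    n = len(a)
    fa = pd.Series(a).value_counts(normalize=True)
    fb = pd.Series(b).value_counts(normalize=True)
    if len(fa) < 2 or len(fb) < 2:
        raise ValueError("monomorphic locus in pair")
    hap = pd.crosstab(pd.Series(a), pd.Series(b), normalize=True)
    total = 0.0
    for ai in fa.index:
        for bj in fb.index:
            pij = float(hap.at[ai, bj]) if (ai in hap.index and bj in hap.columns) else 0.0
            pi, qj = float(fa[ai]), float(fb[bj])
            d = pij - pi * qj
            if d >= 0:
                dmax = min(pi * (1 - qj), (1 - pi) * qj)
            else:
                dmax = min(pi * qj, (1 - pi) * (1 - qj))
            if dmax > 0:
                total += pi * qj * abs(d / dmax)
    return total


def ld_dprime(
    g: SSRGenotypeTable,
    pairs=None,
    n_permutations: int = 1000,
    seed: int = 0,
    include_null: bool = False,
) -> pd.DataFrame:
    """Standardized multi-allelic linkage disequilibrium D' per locus pair.

    D' is the allele-frequency-weighted mean of |D'_ij| over allele pairs;
    inbred lines expose haplotypes directly, so no phasing is needed.  The
    permutation p shuffles one locus's calls.  Pairs are all marker pairs
    by default; each row carries an ``intra_chromosomal`` flag when a map
    is attached.  Monomorphic pairs report NaN with ``undefined=True``.
    """
    if pairs is None:
        pairs = list(itertools.combinations(g.markers, 2))
    rng = np.random.default_rng(seed)
    rows = []
    for m1, m2 in pairs:
        keep = [
            acc
            for acc in g.accessions
            if all(
                not is_missing(v) and (include_null or not is_null(v))
                for v in (g.calls.at[acc, m1], g.calls.at[acc, m2])
            )
        ]
        a = ["NULL" if is_null(g.calls.at[acc, m1]) else g.calls.at[acc, m1] for acc in keep]
        b = ["NULL" if is_null(g.calls.at[acc, m2]) else g.calls.at[acc, m2] for acc in keep]
        intra = (
            g.marker_map.chromosome(m1) == g.marker_map.chromosome(m2)
            if g.marker_map is not None
            else None
        )
        try:
            dp = _dprime_from_calls(a, b)
        except ValueError:
            rows.append(
                {"locus1": m1, "locus2": m2, "dprime": np.nan, "p_value": np.nan,
                 "n_permutations": 0, "intra_chromosomal": intra, "undefined": True}
            )
            continue
        count = 0
        for _ in range(n_permutations):
            perm = list(rng.permutation(b))
            if _dprime_from_calls(a, perm) >= dp:
                count += 1
        p = (count + 1) / (n_permutations + 1) if n_permutations else np.nan
        rows.append(
            {"locus1": m1, "locus2": m2, "dprime": dp, "p_value": p,
             "n_permutations": n_permutations, "intra_chromosomal": intra, "undefined": False}
        )
    return pd.DataFrame(rows)


def ld_summary(ld: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Fraction of significant pairs and their mean D'."""
    ok = ld[~ld["undefined"]]
    sig = ok[ok["p_value"] < alpha]
    return {
        "n_pairs": int(len(ok)),
        "n_significant": int(len(sig)),
        "pct_significant": 100.0 * len(sig) / len(ok) if len(ok) else np.nan,
        "mean_dprime_significant": float(sig["dprime"].mean()) if len(sig) else np.nan,
    }
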