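"""RSTEP-LRT QTL mapping for chromosome segment substitution lines.

CSSL panels carry one or a few donor segments in an otherwise uniform
background, but real panels overlap, so a per-marker t-test is biased by
segments elsewhere in the genome.  RSTEP-LRT controls that background:
stepwise regression first picks cofactor markers; each marker is then
tested with a likelihood-ratio contrast between the model with the marker
plus the other cofactors and the model with the other cofactors only,

    LR = n * ln(RSS_reduced / RSS_full),   LOD = LR / (2 ln 10).

Markers are coded DONOR = +1, BACKGROUND = -1, so the reported additive
effect is half the phenotypic change of a full segment substitution.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CSSLGenotypeTable, PhenotypeTable, TRAITS

logger = logging.getLogger(__name__)

LOG10_2 = 2.0 * math.log(10.0)


@dataclass
class ScanConfig:
    """RSTEP-LRT settings.

    ``lod_threshold`` follows common CSSL practice (2.5).  ``p_entry`` /
    ``p_exit`` govern forward inclusion and backward elimination of
    cofactors; the defaults (0.01 / 0.02) are deliberately strict because
    stepwise selection screens every marker — raw 0.05 entry over ~10^2
    candidates overfits the background model in a ~53-line panel and
    inflates the genome-wide false-positive rate at the LOD threshold.
    ``coding`` is "signed" (+1/-1, default — additive effect is
    half the substitution effect) or "dummy" (0/1 — the coefficient is the
    full substitution effect).
    """

    lod_threshold: float = 2.5
    p_entry: float = 0.01
    p_exit: float = 0.02
    max_cofactors: int | None = None
    coding: str = "signed"
    #: when testing a marker, cofactors whose genotype correlation with it
    #: exceeds this are dropped from the background model, so overlapping
    #: segments do not absorb the tested marker's own effect
    cofactor_r_max: float = 0.7

    def validate(self) -> None:
        if self.lod_threshold <= 0:
            raise ValueError("LOD threshold must be positive")
        if self.p_entry > self.p_exit:
            raise ValueError("entry p must be <= exit p")
        if self.coding not in ("signed", "dummy"):
            raise ValueError(f"unknown coding {self.coding!r}")


@dataclass
class QTLResult:
    name: str
    trait: str
    marker: str
    chromosome: int | None
    position_cM: float | None
    lod: float
    pve_pct: float
    add: float
    env: object
    block_members: list = field(default_factory=list)


def _collapse_collinear(x: pd.DataFrame):
    """Collapse identical genotype columns to one representative.

    Returns (collapsed DataFrame, {representative: [members]}).  Identical
    columns are common in CSSLs where a segment spans several markers.
    """
    blocks: dict = {}
    reps: dict = {}
    for m in x.columns:
        key = tuple(x[m])
        if key in blocks:
            reps[blocks[key]].append(m)
        else:
            blocks[key] = m
            reps[m] = [m]
    collapsed = x[list(reps)]
    n_dropped = x.shape[1] - collapsed.shape[1]
    if n_dropped:
        logger.info("collapsed %d collinear marker columns", n_dropped)
    return collapsed, reps


def _rss(x: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    r = y - x @ beta
    return float(r @ r)


def _partial_f_p(x_base: np.ndarray, col: np.ndarray, y: np.ndarray) -> float:
    """p-value of adding one column to an OLS model."""
    n = len(y)
    rss0 = _rss(x_base, y)
    x1 = np.hstack([x_base, col[:, None]])
    rss1 = _rss(x1, y)
    df_resid = n - np.linalg.matrix_rank(x1)
    if df_resid < 1 or rss1 <= 0 or rss0 - rss1 <= 1e-12:
        return 1.0
    f = (rss0 - rss1) / (rss1 / df_resid)
    return float(stats.f.sf(f, 1, df_resid))


def _stepwise_select(x: pd.DataFrame, y: np.ndarray, cfg: ScanConfig) -> list:
    """Forward-backward stepwise OLS cofactor selection."""
    n = len(y)
    max_cof = cfg.max_cofactors if cfg.max_cofactors is not None else max(1, n // 5)
    if max_cof > n - 3:
        logger.warning("reducing max cofactors from %d to %d (too few lines)", max_cof, n - 3)
        max_cof = max(1, n - 3)
    selected: list = []
    while True:
        base = np.hstack([np.ones((n, 1))] + [x[m].to_numpy()[:, None] for m in selected])
        # forward step
        best_m, best_p = None, 1.0
        if len(selected) < max_cof:
            for m in x.columns:
                if m in selected:
                    continue
                p = _partial_f_p(base, x[m].to_numpy(), y)
                if p < best_p:
                    best_m, best_p = m, p
        changed = False
        if best_m is not None and best_p <= cfg.p_entry:
            selected.append(best_m)
            changed = True
        # backward step
        removed = True
        while removed and len(selected) > 1:
            removed = False
            worst_m, worst_p = None, 0.0
            for m in selected:
                others = [o for o in selected if o != m]
                xb = np.hstack([np.ones((n, 1))] + [x[o].to_numpy()[:, None] for o in others])
                p = _partial_f_p(xb, x[m].to_numpy(), y)
                if p > worst_p:
                    worst_m, worst_p = m, p
            if worst_m is not None and worst_p >= cfg.p_exit:
                selected.remove(worst_m)
                removed = changed = True
        if not changed:
            break
    return selected


def marker_lod(
    x: pd.DataFrame, y: np.ndarray, marker, cofactors: list, r_max: float = 1.0
) -> tuple[float, float, float]:
    """(LOD, additive effect, PVE%) for one marker given cofactors.

    Full model: intercept + cofactors-without-marker + marker; reduced:
    intercept + cofactors-without-marker.  LR = n ln(RSS_r / RSS_f).
    Cofactors with |genotype correlation| > ``r_max`` to the tested marker
    are excluded from both models.
    """
    n = len(y)
    others = [c for c in cofactors if c != marker]
    if r_max < 1.0:
        mcol = x[marker].to_numpy()
        kept = []
        for c in others:
            ccol = x[c].to_numpy()
            if np.std(ccol) == 0 or np.std(mcol) == 0:
                kept.append(c)
                continue
            if abs(np.corrcoef(mcol, ccol)[0, 1]) <= r_max:
                kept.append(c)
        others = kept
    x_red = np.hstack([np.ones((n, 1))] + [x[c].to_numpy()[:, None] for c in others])
    x_full = np.hstack([x_red, x[marker].to_numpy()[:, None]])
    rss_r, rss_f = _rss(x_red, y), _rss(x_full, y)
    if rss_f <= 0:
        rss_f = np.finfo(float).tiny
    lr = n * math.log(rss_r / rss_f)
    lod = max(0.0, lr / LOG10_2)
    beta, _, _, _ = np.linalg.lstsq(x_full, y, rcond=None)
    add = float(beta[-1])
    tss = float(((y - y.mean()) ** 2).sum())
    pve = 100.0 * max(0.0, rss_r - rss_f) / tss if tss > 0 else 0.0
    return lod, add, min(pve, 100.0)


def rstep_lrt_scan(
    cssl: CSSLGenotypeTable,
    p: PhenotypeTable,
    trait: str,
    env=None,
    cfg: ScanConfig | None = None,
) -> list[QTLResult]:
    """RSTEP-LRT scan of every marker; QTL reported at LOD >= threshold.

    Response: line replicate means.  Collinear marker blocks are collapsed
    before selection and the block's representative (peak) marker is
    reported with the member list attached.  QTL are named qTRAIT-CHR with
    a .k suffix when several QTL for the trait share a chromosome.
    """
    cfg = cfg or ScanConfig()
    cfg.validate()
    means = p.accession_means(trait, env)
    lines = [l for l in cssl.lines if l in means.index]
    if len(lines) < 3:
        raise ValueError("fewer than 3 phenotyped lines")
    y = means.loc[lines].to_numpy(dtype=float)
    if float(np.var(y)) == 0:
        logger.warning("zero-variance trait %s; no scan", trait)
        return []
    signed = cssl.signed().loc[lines]
    if cfg.coding == "dummy":
        signed = (signed + 1.0) / 2.0
    # drop monomorphic markers, collapse collinear blocks
    poly = signed.loc[:, signed.nunique() > 1]
    if poly.shape[1] == 0:
        return []
    x, blocks = _collapse_collinear(poly)
    cofactors = _stepwise_select(x, y, cfg)
    hits = []
    for m in x.columns:
        lod, add, pve = marker_lod(x, y, m, cofactors, cfg.cofactor_r_max)
        if lod >= cfg.lod_threshold:
            hits.append((m, lod, add, pve))
    # one QTL per collapsed block is automatic (blocks were collapsed);
    # attach map info and name by trait/chromosome
    mmap = cssl.marker_map
    hits_info = []
    for m, lod, add, pve in hits:
        chrom = mmap.chromosome(m) if mmap is not None else None
        pos = mmap.position(m) if mmap is not None else None
        hits_info.append((m, chrom, pos, lod, add, pve))
    hits_info.sort(key=lambda t: (t[1] if t[1] is not None else 0, t[2] if t[2] is not None else 0))
    per_chrom: dict = {}
    for m, chrom, *_ in hits_info:
        per_chrom[chrom] = per_chrom.get(chrom, 0) + 1
    seen: dict = {}
    out = []
    for m, chrom, pos, lod, add, pve in hits_info:
        seen[chrom] = seen.get(chrom, 0) + 1
        idx = seen[chrom] if per_chrom[chrom] > 1 else None
        out.append(
            QTLResult(
                name=name_qtl(trait, chrom if chrom is not None else 0, idx),
                trait=trait,
                marker=m,
                chromosome=chrom,
                position_cM=pos,
                lod=lod,
                pve_pct=pve,
                add=add,
                env=env if env is not None else "combined",
                block_members=blocks[m],
            )
        )
    return out


def name_qtl(trait: str, chromosome: int, index_on_chromosome: int | None = None) -> str:
    """QTL name in the standard rice nomenclature: q + trait + "-" +
    chromosome, with a ".k" suffix when several QTL for the trait share
    the chromosome (e.g. q2IN-7.1, q2IN-7.2)."""
    if trait not in TRAITS:
        raise ValueError(f"unknown trait {trait!r}")
    base = f"q{trait}-{chromosome}"
    return base if index_on_chromosome is None else f"{base}.{index_on_chromosome}"


def substitution_gain(
    results: list[QTLResult], trait: str, mode: str = "twice_add_per_locus"
) -> float:
    """Predicted trait change from substituting every detected QTL segment.

    ``mode="sum_add"`` sums the additive effects; ``"twice_add_per_locus"``
    sums twice each additive effect (a full donor-for-background
    substitution changes the trait by 2*Add under +/-1 coding).  An empty
    result list yields 0 with a warning.
    """
    if mode not in ("sum_add", "twice_add_per_locus"):
        raise ValueError(f"unknown mode {mode!r}")
    rel = [r for r in results if r.trait == trait]
    if not rel:
        logger.warning("no QTL for trait %s; substitution gain 0", trait)
        return 0.0
    factor = 1.0 if mode == "sum_add" else 2.0
    return factor * sum(r.add for r in rel)


def results_frame(results: list[QTLResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "qtl": r.name,
                "trait": r.trait,
                "marker": r.marker,
                "chromosome": r.chromosome,
                "position_cM": r.position_cM,
                "LOD": r.lod,
                "PVE_pct": r.pve_pct,
                "Add_cm": r.add,
                "env": r.env,
            }
            for r in results
        ]
    )
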