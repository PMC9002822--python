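"""Synthetic natural-population and CSSL datasets with ground truth.

The natural-population generator emulates the regime of a diverse inbred
rice panel: ~500 accessions drawn from ~8 admixed subpopulations, genotyped
at ~260 multi-allelic SSR loci (2-25 alleles each), with six correlated
height-architecture traits measured over 2 years x 3 replicates at
broad-sense heritabilities of roughly 0.7-0.97.

The admixture model is deliberately simple so that truth is available in
closed form: accession admixture proportions are symmetric-Dirichlet, each
call draws its source subpopulation from those proportions, and
subpopulation allele-frequency vectors diverge from a shared ancestral
vector under a Balding-Nichols-style Dirichlet with divergence parameter
``F`` (larger F = more drift, higher Fst).  Loci are exchangeable (no
linkage) unless downstream analyses construct LD themselves.

The CSSL generator places 1-3 donor segments per line uniformly on the
genetic map, emulating a chromosome segment substitution line panel of ~53
lines in a uniform background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    BACKGROUND,
    DONOR,
    MISSING,
    NULL,
    CSSLGenotypeTable,
    MarkerMap,
    PhenotypeTable,
    QMatrix,
    SSRGenotypeTable,
    TRAITS,
    is_missing,
    is_null,
)

RICE_CHROMOSOMES = 12


@dataclass
class PopulationSimConfig:
    """Configuration for the natural-population generator.

    Defaults are the study regime: 504 accessions, 262 SSR loci, K=8
    subpopulations.  ``alpha`` is the symmetric-Dirichlet admixture
    concentration (0.005 makes ~92% of accessions assignable at Q > 0.9,
    matching a panel where 474 of 504 accessions exceeded that threshold).
    ``divergence`` is the Balding-Nichols F governing subpopulation drift
    (0.5 reproduces the strongly differentiated subpopulations, pairwise
    Fst ~0.4-0.6, seen in geographically structured rice germplasm).
    ``p_null_locus`` is the fraction of loci segregating a null
    (non-amplified) allele; ``missing_rate`` is the per-call dropout rate.
    """

    n_accessions: int = 504
    n_loci: int = 262
    n_subpops: int = 8
    alpha: float = 0.005
    allele_range: tuple[int, int] = (2, 25)
    divergence: float = 0.5
    p_null_locus: float = 0.3
    missing_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_accessions, self.n_loci, self.n_subpops) < 1:
            raise ValueError("counts must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not (0 < self.divergence < 1):
            raise ValueError("divergence must lie in (0, 1)")
        lo, hi = self.allele_range
        if not (2 <= lo <= hi):
            raise ValueError("allele_range must satisfy 2 <= lo <= hi")


@dataclass
class QTLSpec:
    """Planted additive architecture for the natural population.

    ``effects``: trait -> list of (marker, {allele label -> effect in cm}).
    ``intercepts``: trait -> baseline mean (cm).  ``env_offsets``: additive
    year effects.  ``genetic_sd`` is accession-level polygenic noise shared
    by replicates; ``replicate_sd`` is within-plot measurement error.
    ``subpop_effect_sd`` scales subpopulation-level genetic offsets
    (accession value += admixture-weighted subpop effects): heritable
    height traits in a geographically structured panel differ between
    subpopulations, and it is exactly this stratification that the Q+K
    model must correct; set 0 for an unstructured phenotype.
    """

    effects: dict = field(default_factory=dict)
    intercepts: dict = field(default_factory=dict)
    env_offsets: dict = field(default_factory=dict)
    genetic_sd: float = 5.0
    replicate_sd: float = 2.0
    subpop_effect_sd: float = 5.0


@dataclass
class CSSLSimConfig:
    """Configuration for the CSSL panel generator (default: 53 lines)."""

    n_lines: int = 53
    marker_map: MarkerMap | None = None
    segments_per_line: tuple[int, int] = (1, 3)
    segment_length_cM: tuple[float, float] = (10.0, 40.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_lines < 2:
            raise ValueError("need >= 2 lines")
        if self.segment_length_cM[0] <= 0:
            raise ValueError("segment lengths must be positive")
        if self.marker_map is None:
            raise ValueError("marker_map is required")


def default_marker_map(n_loci: int, seed: int = 0) -> MarkerMap:
    """Evenly spread ``n_loci`` markers over the 12 rice chromosomes."""
    rng = np.random.default_rng(seed)
    per = np.full(RICE_CHROMOSOMES, n_loci // RICE_CHROMOSOMES)
    per[: n_loci % RICE_CHROMOSOMES] += 1
    rows = []
    i = 1
    for chrom, k in enumerate(per, start=1):
        # rice chromosomes are ~100-180 cM
        length = float(rng.uniform(100, 180))
        positions = np.sort(rng.uniform(0, length, size=k))
        for pos in positions:
            rows.append({"marker": f"RM{i:04d}", "chromosome": chrom, "position_cM": round(pos, 1)})
            i += 1
    return MarkerMap(pd.DataFrame(rows).set_index("marker"))


def simulate_natural_population(cfg: PopulationSimConfig):
    """Simulate an admixed inbred panel.

    Returns ``(genotypes, true_q, true_freqs)`` where ``true_freqs`` maps
    marker -> DataFrame (subpopulations x allele labels) of the per-
    subpopulation allele frequencies actually used.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    K = cfg.n_subpops
    accessions = [f"ACC{i:04d}" for i in range(1, cfg.n_accessions + 1)]
    marker_map = default_marker_map(cfg.n_loci, seed=cfg.seed)
    markers = marker_map.markers

    q = rng.dirichlet(np.full(K, cfg.alpha), size=cfg.n_accessions)
    # tiny concentrations can underflow to an all-zero row: make it one-hot
    bad = ~np.isfinite(q).all(axis=1) | (q.sum(axis=1) <= 0)
    for i in np.flatnonzero(bad):
        q[i] = 0.0
        q[i, rng.integers(K)] = 1.0
    q = q / q.sum(axis=1, keepdims=True)
    true_q = QMatrix(
        pd.DataFrame(q, index=accessions, columns=[f"Q{k+1}" for k in range(K)])
    )
    cum_q = np.cumsum(q, axis=1)

    F = cfg.divergence
    lo, hi = cfg.allele_range
    calls = pd.DataFrame(index=accessions, columns=markers, dtype=object)
    true_freqs: dict = {}
    for marker in markers:
        n_alleles = int(rng.integers(lo, hi + 1))
        labels = [int(100 + 2 * k) for k in range(n_alleles)]
        has_null = rng.random() < cfg.p_null_locus
        if has_null:
            labels[-1] = NULL  # one segregating non-amplified allele
        while True:
            ancestral = rng.dirichlet(np.ones(n_alleles))
            if has_null and ancestral[-1] > 0.25:
                # keep the null a minority baseline class, never the major allele
                excess = ancestral[-1] - 0.25
                ancestral[-1] = 0.25
                ancestral[:-1] += excess * ancestral[:-1] / ancestral[:-1].sum()
            # Balding-Nichols: subpop freqs ~ Dirichlet(ancestral * (1-F)/F)
            sub = rng.dirichlet(np.maximum(ancestral, 1e-6) * (1 - F) / F, size=K)
            # vectorized draw: subpop of origin per accession, then allele
            origin = (rng.random(cfg.n_accessions)[:, None] > cum_q).sum(axis=1)
            origin = np.minimum(origin, K - 1)
            u = rng.random(cfg.n_accessions)
            cum = np.cumsum(sub, axis=1)
            idx = np.minimum((u[:, None] > cum[origin]).sum(axis=1), n_alleles - 1)
            drop = rng.random(cfg.n_accessions) < cfg.missing_rate
            scored_non_null = (~drop) & (idx < n_alleles - 1 if has_null else ~drop)
            # redraw loci that drifted to an all-null or all-missing panel
            if scored_non_null.any():
                break
        true_freqs[marker] = pd.DataFrame(
            sub, index=[f"Q{k+1}" for k in range(K)], columns=[str(l) for l in labels]
        )
        for a, acc in enumerate(accessions):
            calls.at[acc, marker] = MISSING if drop[a] else labels[idx[a]]
    return SSRGenotypeTable(calls, marker_map), true_q, true_freqs


def choose_qtl_marker(
    g: SSRGenotypeTable,
    true_q: QMatrix,
    min_null: int = 10,
    freq_range: tuple[float, float] = (0.15, 0.7),
):
    """Pick a (marker, allele) suited to planting a detectable QTL.

    Association mapping with structure correction can only see effects
    that vary *within* subpopulations: an allele that doubles as a
    subpopulation indicator is absorbed by the Q and kinship terms.  This
    helper scores each candidate allele by its frequency spread across
    the truth-assigned subpopulations and returns the least-differentiated
    allele at a marker that also segregates a null-allele baseline class
    (``min_null`` carriers), so the same marker supports effect-size
    estimation against the null baseline.
    """
    from .popgen import assign_subpopulations

    assigned = assign_subpopulations(true_q)
    subpops = [s for s in assigned.unique() if s != "ADMIXED"]
    candidates = []
    for marker in g.markers:
        col = g.calls[marker]
        n_null = sum(1 for v in col if is_null(v))
        if n_null < min_null:
            continue
        freqs = g.allele_frequencies(marker)
        for allele, f in freqs.items():
            if not (freq_range[0] <= f <= freq_range[1]):
                continue
            per_sub = []
            for s in subpops:
                members = assigned[assigned == s].index
                calls = [v for v in col[members] if not is_missing(v) and not is_null(v)]
                if len(calls) < 5:
                    continue
                per_sub.append(np.mean([v == allele for v in calls]))
            if len(per_sub) < 2:
                continue
            # normalize the spread by the binomial SD so common alleles are
            # not penalized merely for having larger absolute fluctuations
            spread = (max(per_sub) - min(per_sub)) / math.sqrt(f * (1 - f))
            candidates.append((spread, abs(f - 1.0 / 3.0), marker, allele))
    if not candidates:
        raise ValueError("no marker satisfies the QTL-planting criteria")
    _, _, marker, allele = min(candidates, key=lambda t: t[0])
    return marker, allele


def simulate_phenotypes(
    g: SSRGenotypeTable,
    spec: QTLSpec,
    n_envs: int = 2,
    n_reps: int = 3,
    seed: int = 0,
    q: QMatrix | None = None,
):
    """Simulate replicated multi-environment phenotypes from planted QTL.

    value = intercept + sum of carried allele effects + admixture-weighted
    subpopulation offsets (when ``q`` is given and ``spec.subpop_effect_sd``
    > 0) + environment offset + accession-level genetic noise (shared by
    replicates and environments) + replicate error.
    Returns ``(PhenotypeTable, truth)`` where truth
    holds, per trait, the realized genetic variance (variance of total
    genetic values across accessions), the replicate error variance, the
    planted per-allele effects and the implied broad-sense heritability
    h2 = sigma_g2 / (sigma_g2 + sigma_e2 / n_reps).
    """
    rng = np.random.default_rng(seed)
    envs = [f"E{j+1}" for j in range(n_envs)]
    accessions = g.accessions
    rows = []
    truth: dict = {"traits": {}, "genetic_sd": spec.genetic_sd, "replicate_sd": spec.replicate_sd}
    traits = list(spec.intercepts) or list(TRAITS)
    for trait in traits:
        genetic = pd.Series(0.0, index=accessions)
        for marker, allele_effects in spec.effects.get(trait, []):
            if marker not in g.markers:
                raise ValueError(f"QTL marker {marker!r} absent from genotypes")
            col = g.calls[marker]
            present = {
                v for v in col if not is_missing(v)
            }
            for allele, eff in allele_effects.items():
                key = NULL if is_null(allele) or allele == NULL else allele
                if key not in present:
                    import warnings

                    warnings.warn(f"allele {allele!r} at {marker!r} absent; effect unused")
            for acc in accessions:
                v = col[acc]
                if is_missing(v):
                    continue
                key = NULL if is_null(v) else v
                genetic[acc] += allele_effects.get(key, 0.0)
        poly = rng.normal(0.0, spec.genetic_sd, size=len(accessions))
        genetic = genetic + poly
        if q is not None and spec.subpop_effect_sd > 0:
            u = rng.normal(0.0, spec.subpop_effect_sd, size=q.n_subpops)
            genetic = genetic + q.proportions.loc[accessions].to_numpy() @ u
        intercept = spec.intercepts.get(trait, 100.0)
        for j, env in enumerate(envs):
            offset = spec.env_offsets.get(env, 0.0)
            for r in range(1, n_reps + 1):
                noise = rng.normal(0.0, spec.replicate_sd, size=len(accessions))
                for a, acc in enumerate(accessions):
                    rows.append(
                        {
                            "accession": acc,
                            "trait": trait,
                            "env": env,
                            "rep": r,
                            "value": max(0.0, intercept + genetic[acc] + offset + noise[a]),
                        }
                    )
        sigma_g2 = float(np.var(genetic.to_numpy(), ddof=1))
        sigma_e2 = float(spec.replicate_sd**2)
        truth["traits"][trait] = {
            "sigma_g2": sigma_g2,
            "sigma_e2": sigma_e2,
            "h2": sigma_g2 / (sigma_g2 + sigma_e2 / n_reps),
            "effects": spec.effects.get(trait, []),
        }
    return PhenotypeTable(pd.DataFrame(rows)), truth


def simulate_cssl_population(cfg: CSSLSimConfig):
    """Simulate a CSSL panel: background genome with 1-3 donor segments.

    Returns ``(CSSLGenotypeTable, segments)`` with ``segments`` a list per
    line of (chromosome, start_cM, end_cM) tuples.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    mmap = cfg.marker_map
    chrom_ends = mmap.table.groupby("chromosome")["position_cM"].max()
    if (chrom_ends < cfg.segment_length_cM[0]).all():
        raise ValueError("every chromosome is shorter than the minimum segment")
    lines = [f"CSSL{i:02d}" for i in range(1, cfg.n_lines + 1)]
    codes = pd.DataFrame(BACKGROUND, index=lines, columns=mmap.markers, dtype=object)
    truth = {}
    lo_n, hi_n = cfg.segments_per_line
    for line in lines:
        n_seg = int(rng.integers(lo_n, hi_n + 1))
        segs = []
        for _ in range(n_seg):
            chrom = int(rng.choice(chrom_ends.index))
            length = float(rng.uniform(*cfg.segment_length_cM))
            length = min(length, float(chrom_ends[chrom]))
            start = float(rng.uniform(0, chrom_ends[chrom] - length)) if chrom_ends[chrom] > length else 0.0
            segs.append((chrom, start, start + length))
        truth[line] = segs
        for marker in mmap.markers:
            c, pos = mmap.chromosome(marker), mmap.position(marker)
            if any(c == sc and s <= pos <= e for sc, s, e in segs):
                codes.at[line, marker] = DONOR
    table = CSSLGenotypeTable(codes, background="BG-parent", donor="DONOR-parent", marker_map=mmap)
    return table, truth


def simulate_cssl_phenotypes(
    cssl: CSSLGenotypeTable,
    effects: dict,
    error_sd: float = 1.0,
    n_reps: int = 3,
    seed: int = 0,
    trait: str = "PH",
    baseline: float = 100.0,
    env: str = "E1",
) -> PhenotypeTable:
    """Phenotypes for a CSSL panel under +/-1 coding.

    line value = baseline + sum over QTL markers of (signed code x additive
    effect) + line-level noise; replicates share the line genetic value and
    add independent error.  A donor-for-background substitution at one QTL
    therefore shifts the trait by twice the additive effect.
    """
    if error_sd < 0:
        raise ValueError("error SD must be nonnegative")
    for m in effects:
        if m not in cssl.markers:
            raise ValueError(f"effect marker {m!r} absent from CSSL table")
    rng = np.random.default_rng(seed)
    signed = cssl.signed()
    rows = []
    for line in cssl.lines:
        genetic = baseline + sum(signed.at[line, m] * a for m, a in effects.items())
        for r in range(1, n_reps + 1):
            rows.append(
                {
                    "accession": line,
                    "trait": trait,
                    "env": env,
                    "rep": r,
                    "value": max(0.0, genetic + rng.normal(0.0, error_sd)),
                }
            )
    return PhenotypeTable(pd.DataFrame(rows))


def simulate_structure_loglik(
    k_range=range(1, 13),
    true_k: int = 8,
    n_replicates: int = 5,
    seed: int = 0,
    slope_before: float = 400.0,
    slope_after: float = 40.0,
    noise_sd: float = 30.0,
    base: float = -90000.0,
) -> pd.DataFrame:
    """Replicate log-likelihood table with a curvature break at ``true_k``.

    Mean L(K) rises piecewise-linearly with slope ``slope_before`` up to the
    true subpopulation number and ``slope_after`` beyond it — the classic
    shape from which the second-difference statistic recovers K.  Returns a
    long DataFrame with columns K, replicate, loglik.
    """
    ks = list(k_range)
    if len(ks) < 3:
        raise ValueError("K range must span at least 3 values")
    if not (min(ks) < true_k < max(ks)):
        raise ValueError("true_k must be interior to k_range")
    rng = np.random.default_rng(seed)
    rows = []
    for k in ks:
        mean = base + slope_before * min(k, true_k) + slope_after * max(0, k - true_k)
        for rep in range(1, n_replicates + 1):
            rows.append({"K": k, "replicate": rep, "loglik": mean + rng.normal(0, noise_sd)})
    return pd.DataFrame(rows)
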