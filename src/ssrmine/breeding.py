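"""Allele phenotypic effects, favorable alleles, mean separation,
heritability, and favorable-allele pyramiding predictions.

The phenotypic effect value (PEV) of allele i at an associated locus is

    a_i = mean phenotype of allele-i carriers
          - mean phenotype of null-allele carriers,

so the non-amplified (null) allele class is the baseline.  A positive PEV
is favorable for traits bred upward (panicle length, first internode); a
negative PEV is favorable for traits bred downward (plant height and the
lower internodes), where shorter means better lodging resistance.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    NULL,
    POSITIVE_FAVORABLE_TRAITS,
    TRAITS,
    PhenotypeTable,
    SSRGenotypeTable,
    is_missing,
    is_null,
)

logger = logging.getLogger(__name__)


class BaselineError(ValueError):
    """No null-allele carriers at a marker while the null baseline is
    required."""


@dataclass
class AlleleEffect:
    marker: str
    allele: object  # bp label (int) or NULL
    pev: float  # cm, signed; 0.0 for the baseline class itself
    n_carriers: int
    n_null: int
    favorable: bool | None = None
    letters: str | None = None
    typical_carrier: str | None = None


def _carrier_groups(g: SSRGenotypeTable, means: pd.Series, marker):
    """Allele -> list of (accession, mean phenotype) for scored carriers."""
    groups: dict = {}
    for acc, v in g.calls[marker].items():
        if is_missing(v) or acc not in means.index:
            continue
        key = NULL if is_null(v) else v
        groups.setdefault(key, []).append((acc, float(means[acc])))
    return groups


def allele_effects(
    g: SSRGenotypeTable,
    p: PhenotypeTable,
    marker: str,
    trait: str,
    env=None,
    fallback_population_baseline: bool = False,
) -> list[AlleleEffect]:
    """PEV of every non-null allele at ``marker`` against the null-allele
    baseline, on accession replicate means (two-environment means when
    ``env`` is None/"combined").

    If the marker has no null carriers, a population-mean baseline can be
    enabled with ``fallback_population_baseline``; by default the absence
    of the baseline class is an error.
    """
    means = p.accession_means(trait, env)
    groups = _carrier_groups(g, means, marker)
    if NULL in groups:
        baseline_vals = [x for _, x in groups[NULL]]
        n_null = len(baseline_vals)
    elif fallback_population_baseline:
        baseline_vals = [float(means[a]) for a in means.index]
        n_null = 0
        logger.warning("marker %s has no null carriers; population-mean baseline used", marker)
    else:
        raise BaselineError(
            f"marker {marker!r} has no null-allele carriers; the phenotypic "
            "effect value requires the null baseline (or enable the "
            "population-mean fallback)"
        )
    baseline = float(np.mean(baseline_vals))
    out = []
    for allele, carriers in sorted(
        ((a, c) for a, c in groups.items() if a != NULL),
        key=lambda t: t[0],
    ):
        vals = [x for _, x in carriers]
        out.append(
            AlleleEffect(
                marker=marker,
                allele=allele,
                pev=float(np.mean(vals)) - baseline,
                n_carriers=len(vals),
                n_null=n_null,
            )
        )
    return out


def favorable_alleles(effects: list[AlleleEffect], trait: str) -> list[AlleleEffect]:
    """Flag and rank favorable alleles for ``trait``.

    Positive PEVs are favorable for PL and 1IN; negative PEVs are favorable
    for PH, 2IN, 3IN and 4IN.  Returns the favorable subset sorted by
    descending |PEV|; the input objects get their ``favorable`` flag set.
    """
    if trait not in TRAITS:
        raise ValueError(f"unknown trait {trait!r}")
    want_positive = trait in POSITIVE_FAVORABLE_TRAITS
    for e in effects:
        e.favorable = (e.pev > 0) if want_positive else (e.pev < 0)
    return sorted((e for e in effects if e.favorable), key=lambda e: -abs(e.pev))


# ---------------------------------------------------------------------------
# Mean separation


def _compact_letter_display(names, different) -> dict:
    """Insert-and-absorb compact letter display.

    ``different[i][j]`` is True when groups i and j differ significantly.
    Returns name -> letter string; groups sharing a letter do not differ.
    """
    n = len(names)
    letters_sets = [set(range(n))]
    for i in range(n):
        for j in range(i + 1, n):
            if not different[i][j]:
                continue
            for s in [s for s in letters_sets if i in s and j in s]:
                letters_sets.remove(s)
                a, b = s - {i}, s - {j}
                for cand in (a, b):
                    if not any(cand <= other for other in letters_sets):
                        letters_sets.append(cand)
    # keep deterministic order: by the best (highest-mean) member index
    letters_sets.sort(key=lambda s: min(s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {name: "" for name in names}
    for letter, s in zip(alphabet, letters_sets):
        for i in s:
            out[names[i]] += letter
    return out


@dataclass
class MeanSeparation:
    anova: pd.DataFrame  # one-way ANOVA table
    f_pvalue: float
    groups: pd.DataFrame  # allele, n, mean, letters
    method: str


def allele_mean_separation(
    g: SSRGenotypeTable,
    p: PhenotypeTable,
    marker: str,
    trait: str,
    env=None,
    method: str = "duncan",
    alpha: float = 0.05,
    min_group_size: int = 2,
) -> MeanSeparation:
    """One-way ANOVA across allele-carrier groups with Duncan multiple-
    range or protected-LSD letter grouping at ``alpha``.

    Duncan compares means ``p`` steps apart in the sorted order against
    the critical range r(alpha_p, p, df) * sqrt(MSE / n_h) with the
    protection level alpha_p = 1 - (1-alpha)^(p-1) and n_h the harmonic
    mean group size.  Protected LSD runs pairwise pooled-variance t-tests
    only when the omnibus F is significant.  Singleton classes are dropped
    (logged).
    """
    if method not in ("duncan", "protected_lsd"):
        raise ValueError(f"unknown method {method!r}")
    means = p.accession_means(trait, env)
    groups = _carrier_groups(g, means, marker)
    usable = {a: [x for _, x in c] for a, c in groups.items() if len(c) >= min_group_size}
    dropped = set(groups) - set(usable)
    if dropped:
        logger.info("marker %s: singleton classes dropped: %s", marker, sorted(map(str, dropped)))
    if len(usable) < 2:
        raise ValueError(f"marker {marker!r}: fewer than 2 usable allele classes")
    names = sorted(usable, key=lambda a: -np.mean(usable[a]))  # descending means
    data = [np.asarray(usable[a], dtype=float) for a in names]
    k = len(data)
    n_total = sum(len(d) for d in data)
    grand = np.concatenate(data).mean()
    ss_between = sum(len(d) * (d.mean() - grand) ** 2 for d in data)
    ss_within = sum(((d - d.mean()) ** 2).sum() for d in data)
    df_b, df_w = k - 1, n_total - k
    ms_b = ss_between / df_b
    mse = ss_within / df_w if df_w > 0 else np.nan
    if mse == 0:
        f_stat, f_p = np.inf, 0.0
    else:
        f_stat = ms_b / mse
        f_p = float(stats.f.sf(f_stat, df_b, df_w))
    anova = pd.DataFrame(
        {
            "df": [df_b, df_w],
            "SS": [ss_between, ss_within],
            "MS": [ms_b, mse],
            "F": [f_stat, np.nan],
            "p": [f_p, np.nan],
        },
        index=["allele", "error"],
    )

    gmeans = [d.mean() for d in data]
    sizes = [len(d) for d in data]
    n_h = k / sum(1.0 / s for s in sizes)
    different = [[False] * k for _ in range(k)]
    if method == "duncan":
        se = np.sqrt(mse / n_h) if mse > 0 else 0.0
        # test ranges widest-first; a non-significant range shields every
        # pair inside it from further testing (multiple-range protection)
        covered = [[False] * k for _ in range(k)]
        for span in range(k, 1, -1):
            for i in range(0, k - span + 1):
                j = i + span - 1
                if covered[i][j]:
                    continue
                crit = duncan_critical_range(span, df_w, mse, n_h, alpha) if mse > 0 else 0.0
                if abs(gmeans[i] - gmeans[j]) > crit:
                    different[i][j] = different[j][i] = True
                else:
                    for a in range(i, j + 1):
                        for b in range(a + 1, j + 1):
                            covered[a][b] = True
    else:  # protected LSD
        if f_p < alpha and mse > 0:
            tcrit = stats.t.ppf(1 - alpha / 2, df_w)
            for i in range(k):
                for j in range(i + 1, k):
                    lsd = tcrit * np.sqrt(mse * (1 / sizes[i] + 1 / sizes[j]))
                    if abs(gmeans[i] - gmeans[j]) > lsd:
                        different[i][j] = different[j][i] = True
    letters = _compact_letter_display(names, different)
    table = pd.DataFrame(
        {
            "allele": names,
            "n": sizes,
            "mean": gmeans,
            "letters": [letters[a] for a in names],
        }
    )
    return MeanSeparation(anova=anova, f_pvalue=f_p, groups=table, method=method)


def duncan_critical_range(span: int, df_error: int, mse: float, n: float, alpha: float = 0.05) -> float:
    """Duncan's shortest significant range for means ``span`` steps apart."""
    alpha_p = 1 - (1 - alpha) ** (span - 1)
    return float(stats.studentized_range.ppf(1 - alpha_p, span, df_error) * np.sqrt(mse / n))


# ---------------------------------------------------------------------------
# Typical carrier


def typical_carrier(
    g: SSRGenotypeTable, p: PhenotypeTable, marker, allele, trait, env=None
) -> str:
    """The carrier whose replicate-mean phenotype is closest to the
    allele-carrier group mean; ties broken by the lexicographically
    smallest accession ID."""
    means = p.accession_means(trait, env)
    carriers = [(a, float(means[a])) for a in g.carriers(marker, allele) if a in means.index]
    if not carriers:
        raise ValueError(f"no phenotyped carriers of {allele!r} at {marker!r}")
    center = float(np.mean([x for _, x in carriers]))
    return min(carriers, key=lambda t: (abs(t[1] - center), str(t[0])))[0]


# ---------------------------------------------------------------------------
# Broad-sense heritability


@dataclass
class HeritabilityResult:
    trait: str
    env: object
    sigma_g2: float
    sigma_e2: float
    n_reps: float
    h2: float


def broad_sense_heritability(p: PhenotypeTable, trait: str, env=None) -> HeritabilityResult:
    """h2 = sigma_g2 / (sigma_g2 + sigma_e2 / n) from a one-way
    random-effects ANOVA over accessions.

    sigma_e2 is the error mean square, sigma_g2 = (MS_accession -
    MS_error) / n truncated at 0, with n the harmonic-mean replicate
    number under unbalanced replication (logged when unbalanced).
    """
    d = p.data[p.data["trait"] == trait]
    if env is not None and env != "combined":
        d = d[d["env"] == env]
    if d.empty:
        raise ValueError(f"no records for {trait!r} / {env!r}")
    reps = d.groupby("accession")["value"]
    counts = reps.count()
    if (counts < 2).all():
        raise ValueError("need >= 2 replicates")
    if counts.nunique() > 1:
        logger.info("unbalanced replication for %s/%s; harmonic mean used", trait, env)
    n_h = len(counts) / (1.0 / counts).sum()
    grand = d["value"].mean()
    ss_acc = float((counts * (reps.mean() - grand) ** 2).sum())
    ss_err = float(((d["value"] - reps.transform("mean")) ** 2).sum())
    df_acc = len(counts) - 1
    df_err = len(d) - len(counts)
    ms_acc = ss_acc / df_acc
    ms_err = ss_err / df_err if df_err > 0 else 0.0
    sigma_e2 = ms_err
    sigma_g2 = max(0.0, (ms_acc - ms_err) / n_h)
    denom = sigma_g2 + sigma_e2 / n_h
    h2 = sigma_g2 / denom if denom > 0 else 0.0
    return HeritabilityResult(
        trait=trait,
        env=env if env is not None else "combined",
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        n_reps=float(n_h),
        h2=h2,
    )


# ---------------------------------------------------------------------------
# Cross prediction


@dataclass
class CrossPrediction:
    parents: tuple
    trait: str
    loci: list = field(default_factory=list)  # covered loci
    complementary_loci: list = field(default_factory=list)
    n_favorable: int = 0
    predicted_increment: float = 0.0


def predict_crosses(
    g: SSRGenotypeTable,
    effects_by_locus: dict,
    parents: list,
    trait: str,
    top_n: int = 5,
    aggregation: str = "mean",
) -> list[CrossPrediction]:
    """Rank parent pairs by pyramidable favorable alleles.

    ``effects_by_locus`` maps marker -> list of favorable AlleleEffect.  A
    locus is covered by a pair when at least one parent carries a
    favorable allele there; complementary loci (covered by exactly one
    parent) measure what each partner adds beyond the other.  The
    predicted increment aggregates each covered locus's best contributed
    PEV by ``aggregation`` ("mean" or "sum"); pairs are ranked by
    (favorable-allele count, |increment|), and the result is symmetric in
    parent order.
    """
    if aggregation not in ("mean", "sum"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    if not effects_by_locus or all(not v for v in effects_by_locus.values()):
        raise ValueError("empty favorable-allele set")
    fav = {
        m: {e.allele: e.pev for e in effs}
        for m, effs in effects_by_locus.items()
        if effs
    }

    def parent_fav(parent, marker):
        v = g.calls.at[parent, marker]
        if is_missing(v):
            return None
        key = NULL if is_null(v) else v
        pev = fav[marker].get(key)
        return (key, pev) if pev is not None else None

    out = []
    for p1, p2 in itertools.combinations(sorted(parents, key=str), 2):
        covered, complementary, alleles, pevs = [], [], set(), []
        for marker in fav:
            c1, c2 = parent_fav(p1, marker), parent_fav(p2, marker)
            if c1 is None and c2 is None:
                continue
            covered.append(marker)
            if (c1 is None) != (c2 is None):
                complementary.append(marker)
            best = max((c for c in (c1, c2) if c is not None), key=lambda t: abs(t[1]))
            pevs.append(best[1])
            for c in (c1, c2):
                if c is not None:
                    alleles.add((marker, c[0]))
        if not covered:
            continue
        inc = float(np.mean(pevs)) if aggregation == "mean" else float(np.sum(pevs))
        out.append(
            CrossPrediction(
                parents=(p1, p2),
                trait=trait,
                loci=covered,
                complementary_loci=complementary,
                n_favorable=len(alleles),
                predicted_increment=inc,
            )
        )
    out.sort(key=lambda c: (-c.n_favorable, -abs(c.predicted_increment), c.parents))
    return out[:top_n]
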