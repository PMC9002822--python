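"""Readers, writers and table-level filters.

All tables are UTF-8 comma-separated CSV with a mandatory header row and
"." as the decimal mark.  Genotype cells are integer fragment sizes in bp,
the token ``NULL`` for a non-amplified allele, or ``NA`` for a missing call.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    BACKGROUND,
    DONOR,
    MISSING,
    NULL,
    CSSLGenotypeTable,
    DataModelError,
    KinshipMatrix,
    MarkerMap,
    PhenotypeTable,
    QMatrix,
    SSRGenotypeTable,
    is_missing,
    is_null,
)

MISSING_TOKENS = {"NA", "", "nan", "NaN"}


class ParseError(ValueError):
    """Raised with row/column context when a file cannot be parsed."""


def _parse_call(raw, accession, marker):
    s = str(raw).strip()
    if s in MISSING_TOKENS:
        return MISSING
    if s == NULL:
        return NULL
    try:
        v = int(s)
    except ValueError:
        raise ParseError(
            f"cell at accession {accession!r}, marker {marker!r}: "
            f"{raw!r} is not an integer bp size, NULL, or NA"
        ) from None
    if v <= 0:
        raise ParseError(f"non-positive fragment size {v} at {accession!r}/{marker!r}")
    return v


def read_marker_map(path) -> MarkerMap:
    df = pd.read_csv(path)
    if "marker" not in df.columns:
        raise ParseError(f"{path}: marker map needs a 'marker' column")
    df = df.set_index("marker")
    try:
        return MarkerMap(df)
    except DataModelError as e:
        raise ParseError(f"{path}: {e}") from e


def read_genotype_table(path, map_path=None) -> SSRGenotypeTable:
    """Read an accession x marker genotype CSV (first column = accession)."""
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    if df.size == 0:
        raise ParseError(f"{path}: empty genotype table")
    calls = pd.DataFrame(index=df.index, columns=df.columns, dtype=object)
    for marker in df.columns:
        for accession, raw in df[marker].items():
            calls.at[accession, marker] = _parse_call(raw, accession, marker)
    marker_map = read_marker_map(map_path) if map_path is not None else None
    try:
        return SSRGenotypeTable(calls, marker_map)
    except DataModelError as e:
        raise ParseError(f"{path}: {e}") from e


def write_genotype_table(g: SSRGenotypeTable, path) -> None:
    out = g.calls.copy()
    for col in out.columns:
        out[col] = [
            "NA" if is_missing(v) else (NULL if is_null(v) else str(int(v)))
            for v in out[col]
        ]
    out.index.name = "accession"
    out.to_csv(path)


def read_phenotype_table(path) -> PhenotypeTable:
    df = pd.read_csv(path)
    try:
        return PhenotypeTable(df)
    except DataModelError as e:
        raise ParseError(f"{path}: {e}") from e


def write_phenotype_table(p: PhenotypeTable, path) -> None:
    p.data.to_csv(path, index=False)


def read_q_matrix(path) -> QMatrix:
    df = pd.read_csv(path, index_col=0)
    try:
        return QMatrix(df)
    except DataModelError as e:
        raise ParseError(f"{path}: {e}") from e


def write_q_matrix(q: QMatrix, path) -> None:
    q.proportions.to_csv(path)


def read_kinship_matrix(path) -> KinshipMatrix:
    df = pd.read_csv(path, index_col=0)
    try:
        return KinshipMatrix(df)
    except DataModelError as e:
        raise ParseError(f"{path}: {e}") from e


def write_kinship_matrix(k: KinshipMatrix, path) -> None:
    k.values.to_csv(path)


def read_cssl_table(path, map_path=None, background="background", donor="donor") -> CSSLGenotypeTable:
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    codes = pd.DataFrame(index=df.index, columns=df.columns, dtype=object)
    for marker in df.columns:
        for line, raw in df[marker].items():
            s = str(raw).strip()
            if s in MISSING_TOKENS:
                codes.at[line, marker] = MISSING
            elif s in (BACKGROUND, DONOR):
                codes.at[line, marker] = s
            else:
                raise ParseError(
                    f"{path}: CSSL code {s!r} at line {line!r}, marker {marker!r} "
                    f"(expected {BACKGROUND!r}, {DONOR!r} or NA)"
                )
    marker_map = read_marker_map(map_path) if map_path is not None else None
    try:
        return CSSLGenotypeTable(codes, background, donor, marker_map)
    except DataModelError as e:
        raise ParseError(f"{path}: {e}") from e


def write_cssl_table(c: CSSLGenotypeTable, path) -> None:
    out = c.codes.copy()
    for col in out.columns:
        out[col] = ["NA" if is_missing(v) else v for v in out[col]]
    out.index.name = "line"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# Filters


def filter_rare_alleles(g: SSRGenotypeTable, threshold: float = 0.05) -> SSRGenotypeTable:
    """Mask calls of alleles at frequency <= ``threshold`` as missing.

    Frequencies are computed over scored, non-null calls.  NULL calls are
    never masked: the null-allele class is the baseline for allele
    phenotypic-effect values and must survive filtering.  Returns a new
    table; the input is untouched.
    """
    if not (0 < threshold < 0.5):
        raise ValueError(f"threshold must lie in (0, 0.5), got {threshold}")
    calls = g.calls.copy()
    for marker in calls.columns:
        col = calls[marker]
        scored = [v for v in col if not is_missing(v) and not is_null(v)]
        if not scored:
            continue
        freqs = pd.Series(scored).value_counts(normalize=True)
        rare = set(freqs[freqs <= threshold].index)
        if not rare:
            continue
        for acc, v in col.items():
            if not is_missing(v) and not is_null(v) and v in rare:
                calls.at[acc, marker] = MISSING
    return SSRGenotypeTable(calls, g.marker_map)


# ---------------------------------------------------------------------------
# STRUCTURE export


def export_structure_input(g: SSRGenotypeTable, path) -> dict:
    """Write a one-row-per-accession flat file in STRUCTURE's input format.

    Alleles (including NULL) are recoded per locus to consecutive integers,
    ordered by ascending fragment size with NULL last; missing calls become
    -9.  The recode dictionary, ``{marker: {code: label}}``, is returned and
    also written alongside as ``<path>.recode.csv``.
    """
    path = Path(path)
    recode: dict = {}
    for marker in g.markers:
        labels = sorted(
            {v for v in g.calls[marker] if not is_missing(v) and not is_null(v)}
        )
        has_null = any(is_null(v) for v in g.calls[marker])
        codes = {lab: i + 1 for i, lab in enumerate(labels)}
        if has_null:
            codes[NULL] = len(labels) + 1
        recode[marker] = {code: lab for lab, code in codes.items()}
    with open(path, "w", encoding="utf-8") as fh:
        for acc in g.accessions:
            row = [str(acc)]
            for marker in g.markers:
                v = g.calls.at[acc, marker]
                if is_missing(v):
                    row.append("-9")
                else:
                    key = NULL if is_null(v) else v
                    row.append(str({lab: c for c, lab in recode[marker].items()}[key]))
            fh.write(" ".join(row) + "\n")
    rows = [
        {"marker": m, "code": c, "allele": lab}
        for m, d in recode.items()
        for c, lab in d.items()
    ]
    pd.DataFrame(rows).to_csv(path.with_suffix(path.suffix + ".recode.csv"), index=False)
    return recode


# ---------------------------------------------------------------------------
# Newick


def write_newick(tree, path) -> None:
    """Write a scikit-bio TreeNode to Newick (6 significant digits)."""
    for tip in tree.tips():
        if tip.name is None:
            raise ValueError("tree has an unlabeled leaf")
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# Descriptive statistics


def phenotype_summary(p: PhenotypeTable) -> pd.DataFrame:
    """Descriptive statistics per (trait, environment) on accession means.

    Mirrors the usual germplasm-panel summary: mean, SD, min, max, skewness,
    excess kurtosis and CV% = 100*SD/mean, all computed on the distribution
    of per-accession replicate means.  CV is NaN when the mean is zero; a
    zero-variance trait reports skewness and kurtosis as 0.
    """
    rows = []
    for (trait, env), d in p.data.groupby(["trait", "env"], sort=True):
        means = d.groupby("accession")["value"].mean().to_numpy()
        if means.size < 2:
            raise DataModelError(f"need >= 2 accessions for ({trait}, {env})")
        mean = float(means.mean())
        sd = float(means.std(ddof=1))
        if sd == 0:
            skew = kurt = 0.0
        else:
            skew = float(stats.skew(means, bias=False))
            kurt = float(stats.kurtosis(means, bias=False))
        cv = math.nan if mean == 0 else 100.0 * sd / mean
        rows.append(
            {
                "trait": trait,
                "env": env,
                "n": means.size,
                "mean": mean,
                "sd": sd,
                "min": float(means.min()),
                "max": float(means.max()),
                "skewness": skew,
                "kurtosis": kurt,
                "cv_pct": cv,
            }
        )
    return pd.DataFrame(rows)
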