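"""Core data containers for the two mapping populations.

The pipeline works on inbred rice material, so every accession carries a
single allele per SSR locus (one band per line on a gel).  A call is one of

* a positive integer — the PCR fragment size in base pairs,
* :data:`NULL` — the locus amplified no product ("null allele"); this is a
  first-class allele state because it is the baseline carrier class for
  allele phenotypic-effect values,
* :data:`MISSING` — no genotype was scored.

NULL and MISSING are deliberately distinct: a null allele is an observed,
heritable state; a missing call is an absence of data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Sentinel for a non-amplified (null) allele.  Stored verbatim in tables.
NULL = "NULL"

#: Sentinel for an unscored call.
MISSING = None

#: The six plant-height architecture traits (cm): plant height, panicle
#: length, and the first to fourth elongated internodes from the top.
TRAITS = ("PH", "PL", "1IN", "2IN", "3IN", "4IN")

#: Traits for which a *positive* allele effect is the breeding goal.
POSITIVE_FAVORABLE_TRAITS = frozenset({"PL", "1IN"})

#: CSSL genotype codes.
BACKGROUND = "B"
DONOR = "D"


class DataModelError(ValueError):
    """Raised when a table violates its structural invariants."""


def is_missing(call) -> bool:
    return call is None or (isinstance(call, float) and np.isnan(call))


def is_null(call) -> bool:
    return isinstance(call, str) and call == NULL


def _check_unique(ids: Iterable, what: str) -> list:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if list(ids).count(x) > 1})
        raise DataModelError(f"duplicate {what} IDs: {dupes[:5]}")
    return ids


@dataclass
class MarkerMap:
    """Genetic map: marker -> (chromosome, position in cM, optional bp span).

    ``table`` is indexed by marker ID with columns ``chromosome`` (int, 1-12
    for rice), ``position_cM`` (non-negative float) and optionally
    ``start_bp`` / ``end_bp``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chromosome", "position_cM"}
        if not required.issubset(self.table.columns):
            raise DataModelError(f"marker map needs columns {sorted(required)}")
        _check_unique(self.table.index, "marker")
        if (self.table["position_cM"] < 0).any():
            raise DataModelError("negative cM position in marker map")

    @property
    def markers(self) -> list:
        return list(self.table.index)

    def chromosome(self, marker) -> int:
        return int(self.table.at[marker, "chromosome"])

    def position(self, marker) -> float:
        return float(self.table.at[marker, "position_cM"])


@dataclass
class SSRGenotypeTable:
    """Accession x SSR-marker call matrix for an inbred panel.

    ``calls`` is an object-dtype DataFrame (rows: accessions, columns:
    markers); cells hold ``int`` fragment sizes, :data:`NULL`, or
    :data:`MISSING` (None/NaN).  ``marker_map`` is optional metadata.
    """

    calls: pd.DataFrame
    marker_map: MarkerMap | None = None

    def __post_init__(self) -> None:
        if self.calls.size == 0:
            raise DataModelError("empty genotype table")
        _check_unique(self.calls.index, "accession")
        _check_unique(self.calls.columns, "marker")
        self.calls = self.calls.astype(object)
        for col in self.calls.columns:
            for acc, v in self.calls[col].items():
                if is_missing(v) or is_null(v):
                    continue
                if not (isinstance(v, (int, np.integer)) and v > 0):
                    raise DataModelError(
                        f"invalid call {v!r} at accession {acc!r}, marker {col!r}: "
                        "expected positive integer bp, NULL, or missing"
                    )
        if self.marker_map is not None:
            unmapped = [m for m in self.markers if m not in self.marker_map.table.index]
            if unmapped:
                raise DataModelError(f"markers absent from map: {unmapped[:5]}")

    @property
    def accessions(self) -> list:
        return list(self.calls.index)

    @property
    def markers(self) -> list:
        return list(self.calls.columns)

    def allele_frequencies(self, marker, include_null: bool = False) -> pd.Series:
        """Allele frequencies at ``marker`` over scored (non-missing) calls.

        NULL carriers are excluded from the denominator unless
        ``include_null`` is set, in which case NULL counts as an allele class.
        """
        col = self.calls[marker]
        scored = [v for v in col if not is_missing(v)]
        if not include_null:
            scored = [v for v in scored if not is_null(v)]
        if not scored:
            raise DataModelError(f"marker {marker!r} has no scored calls")
        counts = pd.Series(scored).value_counts()
        return counts / counts.sum()

    def carriers(self, marker, allele) -> list:
        """Accessions carrying ``allele`` (which may be NULL) at ``marker``."""
        col = self.calls[marker]
        if is_null(allele):
            return [a for a, v in col.items() if is_null(v)]
        return [a for a, v in col.items() if not is_missing(v) and v == allele]

    def copy(self) -> "SSRGenotypeTable":
        return SSRGenotypeTable(self.calls.copy(), self.marker_map)


@dataclass
class PhenotypeTable:
    """Replicated multi-environment trait measurements (cm), long format.

    ``data`` has columns ``accession``, ``trait``, ``env``, ``rep``,
    ``value``; one row per measurement; (accession, trait, env, rep) unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        cols = ["accession", "trait", "env", "rep", "value"]
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise DataModelError(f"phenotype table missing columns {missing}")
        self.data = self.data[cols].reset_index(drop=True)
        bad = set(self.data["trait"]) - set(TRAITS)
        if bad:
            raise DataModelError(f"unknown trait labels: {sorted(bad)}")
        vals = pd.to_numeric(self.data["value"], errors="coerce")
        if vals.isna().any() or not np.isfinite(vals).all():
            raise DataModelError("non-numeric or non-finite phenotype value")
        if (vals < 0).any():
            raise DataModelError("negative phenotype value")
        self.data["value"] = vals.astype(float)
        key = self.data[["accession", "trait", "env", "rep"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise DataModelError(f"duplicate phenotype record {dup}")

    @property
    def traits(self) -> list:
        return sorted(self.data["trait"].unique(), key=TRAITS.index)

    @property
    def environments(self) -> list:
        return sorted(self.data["env"].unique())

    def accession_means(self, trait, env=None) -> pd.Series:
        """Per-accession phenotype means over replicates.

        With ``env=None`` (or ``"combined"``) the mean of per-environment
        accession means is returned, so unbalanced replication in one year
        does not bias the combined value.
        """
        d = self.data[self.data["trait"] == trait]
        if d.empty:
            raise DataModelError(f"no records for trait {trait!r}")
        if env is not None and env != "combined":
            d = d[d["env"] == env]
            if d.empty:
                raise DataModelError(f"no records for trait {trait!r} in env {env!r}")
            return d.groupby("accession")["value"].mean()
        per_env = d.groupby(["accession", "env"])["value"].mean().reset_index()
        return per_env.groupby("accession")["value"].mean()


@dataclass
class QMatrix:
    """Accession x subpopulation admixture proportions (rows sum to 1)."""

    proportions: pd.DataFrame

    def __post_init__(self) -> None:
        p = self.proportions.to_numpy(dtype=float)
        if ((p < -1e-9) | (p > 1 + 1e-9)).any():
            raise DataModelError("Q entries must lie in [0, 1]")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
            raise DataModelError("Q rows must sum to 1 within 1e-6")

    @property
    def accessions(self) -> list:
        return list(self.proportions.index)

    @property
    def n_subpops(self) -> int:
        return self.proportions.shape[1]


@dataclass
class KinshipMatrix:
    """Symmetric accession x accession relatedness coefficients in [0, 1]."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if v.shape[0] != v.shape[1] or list(self.values.index) != list(self.values.columns):
            raise DataModelError("kinship matrix must be square with matching labels")
        if not np.allclose(v, v.T, atol=1e-8):
            raise DataModelError("kinship matrix must be symmetric")
        if ((v < -1e-9) | (v > 1 + 1e-9)).any():
            raise DataModelError("kinship entries must lie in [0, 1]")
        if (np.diag(v) + 1e-12 < v.max(axis=1)).any():
            raise DataModelError("kinship diagonal must be the per-row maximum")

    @property
    def accessions(self) -> list:
        return list(self.values.index)


@dataclass
class CSSLGenotypeTable:
    """Line x marker donor/background coding for a CSSL panel.

    Cells are :data:`BACKGROUND`, :data:`DONOR` or missing.  ``background``
    and ``donor`` name the two parents (e.g. Xiushui79 and C-bao).
    """

    codes: pd.DataFrame
    background: str = "background"
    donor: str = "donor"
    marker_map: MarkerMap | None = None

    def __post_init__(self) -> None:
        _check_unique(self.codes.index, "line")
        _check_unique(self.codes.columns, "marker")
        self.codes = self.codes.astype(object)
        allowed = {BACKGROUND, DONOR}
        for col in self.codes.columns:
            for line, v in self.codes[col].items():
                if is_missing(v):
                    continue
                if v not in allowed:
                    raise DataModelError(
                        f"invalid CSSL code {v!r} at line {line!r}, marker {col!r}"
                    )
        if self.marker_map is not None:
            unmapped = [m for m in self.markers if m not in self.marker_map.table.index]
            if unmapped:
                raise DataModelError(f"CSSL markers absent from map: {unmapped[:5]}")

    @property
    def lines(self) -> list:
        return list(self.codes.index)

    @property
    def markers(self) -> list:
        return list(self.codes.columns)

    def signed(self, missing_as_background: bool = True) -> pd.DataFrame:
        """Numeric coding: DONOR -> +1, BACKGROUND -> -1.

        Under this coding the additive effect of a marker is half the
        phenotypic difference between donor-segment and background lines,
        so a full segment substitution changes the trait by twice the
        additive effect.
        """
        out = pd.DataFrame(index=self.codes.index, columns=self.codes.columns, dtype=float)
        for col in self.codes.columns:
            for line, v in self.codes[col].items():
                if is_missing(v):
                    out.at[line, col] = -1.0 if missing_as_background else np.nan
                else:
                    out.at[line, col] = 1.0 if v == DONOR else -1.0
        return out
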