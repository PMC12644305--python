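"""Harmonization of raw dimension codes to the analysis vocabulary.

Observation (SNOMED-like) codes are mapped to ICD-like codes and truncated
to their first three characters, the hierarchical clinical category.
Hospitalisation codes are ICD-like at source and are only truncated.
Prescription (dm+d-like) codes are mapped to BNF-paragraph-like classes via
a primary table, falling back to the first six characters of a chapter
string for codes missing from it.  Events whose raw code resolves in no
table are dropped from the mapped stream and tallied in an unmapped-code
report.  Matching is case-sensitive: the vocabularies are controlled and
silent case-folding would hide generator bugs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .config import logger

EVENT_COLUMNS = ["patient_id", "dimension", "harmonized_code", "event_date"]


@dataclass
class MappedEvents:
    """Mapped event stream plus the report of dropped (unmapped) codes.

    ``unmapped`` has columns ``raw_code, n_occurrences`` sorted by
    occurrence count descending — the shape of a "top unmapped codes"
    review table.
    """

    events: pd.DataFrame
    unmapped: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["raw_code", "n_occurrences"]))

    def __post_init__(self):
        self.events = self.events.reset_index(drop=True)


def _unmapped_report(raw_codes: pd.Series) -> pd.DataFrame:
    rep = (raw_codes.value_counts().rename_axis("raw_code")
           .reset_index(name="n_occurrences"))
    return rep.sort_values(["n_occurrences", "raw_code"],
                           ascending=[False, True]).reset_index(drop=True)


def _as_lookup(table: pd.DataFrame | None) -> dict[str, str]:
    if table is None or len(table) == 0:
        return {}
    if table["source_code"].duplicated().any():
        dupes = table.loc[table["source_code"].duplicated(), "source_code"].unique()
        raise ValueError(f"duplicate source codes in mapping table: {list(dupes)[:5]}")
    return dict(zip(table["source_code"], table["target_code"]))


def map_and_truncate_observations(events: pd.DataFrame,
                                  table: pd.DataFrame | None,
                                  manual_table: pd.DataFrame | None = None,
                                  ) -> MappedEvents:
    """Map observation/hospitalisation codes and truncate to 3 characters.

    A user-supplied ``manual_table`` is consulted before the primary table
    (the manual-review hook for very common unmapped codes).  When
    ``table`` is ``None`` the raw codes are taken to be ICD-like already
    and are truncated without mapping (the hospitalisation path).
    Truncation keeps codes shorter than three characters as-is.
    """
    bad = set(events["dimension"].unique()) - {"observation", "hospitalisation"}
    if bad:
        raise ValueError(f"unexpected dimensions for this mapper: {sorted(bad)}")
    out = events.copy()
    raw = out["raw_code"].astype(str)
    if table is None:
        mapped = raw
        hit = pd.Series(True, index=out.index)
    else:
        lookup = {**_as_lookup(table), **_as_lookup(manual_table)}
        if not lookup:
            logger.warning("empty mapping table: all %d events unmapped", len(events))
        mapped = raw.map(lookup)
        hit = mapped.notna()
    out["harmonized_code"] = mapped.astype("string").str.slice(0, 3)
    unmapped = _unmapped_report(raw[~hit])
    if len(unmapped):
        logger.info("%d observation events with %d distinct unmapped codes dropped",
                    int(unmapped["n_occurrences"].sum()), len(unmapped))
    return MappedEvents(out.loc[hit, EVENT_COLUMNS], unmapped)


def map_prescriptions(events: pd.DataFrame,
                      table: pd.DataFrame | None,
                      fallback_table: pd.DataFrame | None = None,
                      manual_table: pd.DataFrame | None = None,
                      ) -> MappedEvents:
    """Map prescription codes to BNF-paragraph-like classes.

    Manual overrides first, then the primary table; misses consult the
    fallback table, whose values are chapter strings of which the first
    six characters form the paragraph.  Remaining misses are reported.
    """
    bad = set(events["dimension"].unique()) - {"prescription"}
    if bad:
        raise ValueError(f"unexpected dimensions for the prescription mapper: {sorted(bad)}")
    out = events.copy()
    raw = out["raw_code"].astype(str)
    primary = {**_as_lookup(table), **_as_lookup(manual_table)}
    fallback = _as_lookup(fallback_table)
    if not primary and not fallback and len(events):
        logger.warning("empty mapping tables: all %d events unmapped", len(events))
    mapped = raw.map(primary)
    miss = mapped.isna()
    if fallback and miss.any():
        mapped.loc[miss] = raw[miss].map(fallback).astype("string").str.slice(0, 6)
    hit = mapped.notna()
    out["harmonized_code"] = mapped
    unmapped = _unmapped_report(raw[~hit])
    if len(unmapped):
        logger.info("%d prescription events with %d distinct unmapped codes dropped",
                    int(unmapped["n_occurrences"].sum()), len(unmapped))
    return MappedEvents(out.loc[hit, EVENT_COLUMNS], unmapped)


def apply_code_exclusions(mapped: MappedEvents, exclusion_spec) -> MappedEvents:
    """Drop events whose harmonized code defines exposure or outcome.

    ``exclusion_spec`` is a collection of harmonized codes (drug classes of
    the treatment regimens; the outcome diagnosis class).  Codes backing
    the prespecified covariates are deliberately *not* excluded — they may
    still be informative proxies.
    """
    spec = set(exclusion_spec)
    if not spec:
        return MappedEvents(mapped.events.copy(), mapped.unmapped.copy())
    keep = ~mapped.events["harmonized_code"].isin(spec)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("code exclusions removed %d events (%d codes excluded)",
                    n_drop, len(spec))
    return MappedEvents(mapped.events.loc[keep, EVENT_COLUMNS],
                        mapped.unmapped.copy())


def map_all_dimensions(events: pd.DataFrame,
                       tables: dict[str, pd.DataFrame],
                       exclusion_spec=(),
                       manual_tables: dict[str, pd.DataFrame] | None = None,
                       ) -> MappedEvents:
    """Convenience wrapper: route each dimension to its mapper, pool the
    results, and apply the code exclusions."""
    manual_tables = manual_tables or {}
    parts, reports = [], []
    for dim, sub in events.groupby("dimension", sort=True):
        if dim == "prescription":
            m = map_prescriptions(sub, tables.get("prescription"),
                                  tables.get("prescription_fallback"),
                                  manual_tables.get("prescription"))
        else:
            m = map_and_truncate_observations(
                sub, tables.get(dim) if dim == "observation" else None,
                manual_tables.get(dim))
        parts.append(m.events)
        if len(m.unmapped):
            reports.append(m.unmapped.assign(dimension=dim))
    pooled = MappedEvents(
        pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(columns=EVENT_COLUMNS),
        (pd.concat(reports, ignore_index=True) if reports
         else pd.DataFrame(columns=["raw_code", "n_occurrences", "dimension"])))
    return apply_code_exclusions(pooled, exclusion_spec)
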