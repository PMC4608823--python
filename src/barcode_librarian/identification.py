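"""Best Match and Best Close Match identification criteria.

Every non-singleton specimen is queried against the rest of the library
(leave-one-out).  Best Match (BM) assigns the species of the nearest
reference sequence regardless of distance: true positive when every
minimal-distance reference is conspecific, false positive when none is,
ambiguous when the minimal-distance set spans several species.  Best Close
Match (BCM) additionally requires the nearest match to lie at or below a
distance threshold; queries whose best distance exceeds it are set aside as
false negatives (nearest reference conspecific — the identification would
have been correct) or true negatives (nearest heterospecific).

Species represented by a single sequence can never self-match and are
excluded as queries, but remain available as reference candidates.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .library_io import ReferenceLibrary

Category = Literal["TP", "ambiguous", "FP", "FN", "TN"]


class SingletonQueryError(ValueError):
    """Raised when a query's species has no other sequence to match."""


@dataclass
class MatchOutcome:
    query: str
    query_species: str
    best_match_vouchers: frozenset[str]
    best_distance: float
    assigned_species: frozenset[str]
    category: Category
    threshold_used: float | None = None

    @property
    def representative_match(self) -> str:
        return sorted(self.best_match_vouchers)[0]


def _best_matches(
    query: str,
    matrix: DistanceMatrix,
    library: ReferenceLibrary,
    excluded: frozenset[str],
    epsilon: float,
) -> tuple[frozenset[str], float, frozenset[str]]:
    qrec = library[query]
    if qrec.is_outgroup:
        raise SingletonQueryError(f"{query}: outgroup records are not queried")
    members = library.ingroup().species_members()
    if len([v for v in members.get(qrec.nominal_species, []) if v not in excluded]) < 2:
        raise SingletonQueryError(
            f"{query}: species {qrec.nominal_species!r} has no other sequence"
        )
    candidates = [
        r.voucher_id
        for r in library
        if r.voucher_id != query and not r.is_outgroup and r.voucher_id not in excluded
    ]
    dists = np.array([matrix.get(query, c) for c in candidates])
    finite = ~np.isnan(dists)
    if not finite.any():
        raise ValueError(f"{query}: no defined distance to any candidate")
    dmin = float(np.nanmin(dists))
    at_min = [
        c for c, dv, ok in zip(candidates, dists, finite) if ok and dv <= dmin + epsilon
    ]
    best = frozenset(at_min)
    assigned = frozenset(library[v].nominal_species for v in best)
    return best, dmin, assigned


def best_match(
    query: str,
    matrix: DistanceMatrix,
    library: ReferenceLibrary,
    excluded: Iterable[str] = (),
    epsilon: float = 0.0,
) -> MatchOutcome:
    """Classify one leave-one-out query under the Best Match criterion."""
    excluded = frozenset(excluded)
    best, dmin, assigned = _best_matches(query, matrix, library, excluded, epsilon)
    qsp = library[query].nominal_species
    if len(assigned) >= 2:
        category: Category = "ambiguous"
    elif qsp in assigned:
        category = "TP"
    else:
        category = "FP"
    return MatchOutcome(query, qsp, best, dmin, assigned, category, None)


def best_close_match(
    query: str,
    matrix: DistanceMatrix,
    library: ReferenceLibrary,
    threshold: float,
    excluded: Iterable[str] = (),
    epsilon: float = 0.0,
) -> MatchOutcome:
    """Classify one query under Best Close Match with the given threshold.

    A best distance exactly equal to the threshold still counts as a match.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    excluded = frozenset(excluded)
    best, dmin, assigned = _best_matches(query, matrix, library, excluded, epsilon)
    qsp = library[query].nominal_species
    if dmin <= threshold:
        if len(assigned) >= 2:
            category: Category = "ambiguous"
        elif qsp in assigned:
            category = "TP"
        else:
            category = "FP"
    else:
        category = "FN" if qsp in assigned else "TN"
    return MatchOutcome(query, qsp, best, dmin, assigned, category, threshold)


def identify_all(
    matrix: DistanceMatrix,
    library: ReferenceLibrary,
    criterion: Literal["bm", "bcm"] = "bm",
    thresholds: float | Mapping[str, float] | None = None,
    threshold_level: Literal["dataset", "subfamily", "genus"] = "dataset",
    fallback_threshold: float | None = None,
    excluded: Iterable[str] = (),
    epsilon: float = 0.0,
) -> tuple[list[MatchOutcome], list[str]]:
    """Run BM or BCM for every eligible query in the library.

    ``thresholds`` is either a single dataset-wide value or a mapping from
    group label (subfamily or genus, per ``threshold_level``) to threshold;
    queries in groups without an entry fall back to ``fallback_threshold``.
    Returns the outcomes plus the vouchers skipped as singleton-species or
    explicitly excluded queries.
    """
    excluded = frozenset(excluded)
    outcomes: list[MatchOutcome] = []
    skipped: list[str] = []
    for rec in library.ingroup():
        v = rec.voucher_id
        if v in excluded:
            skipped.append(v)
            continue
        try:
            if criterion == "bm":
                outcomes.append(best_match(v, matrix, library, excluded, epsilon))
            else:
                if thresholds is None:
                    raise ValueError("BCM requires thresholds")
                if isinstance(thresholds, Mapping):
                    group = rec.subfamily if threshold_level == "subfamily" else rec.genus
                    thr = thresholds.get(group, fallback_threshold)
                    if thr is None:
                        raise ValueError(
                            f"{v}: no threshold for group {group!r} and no fallback"
                        )
                else:
                    thr = float(thresholds)
                outcomes.append(best_close_match(v, matrix, library, thr, excluded, epsilon))
        except SingletonQueryError:
            skipped.append(v)
    return outcomes, skipped


@dataclass
class IdentificationSummary:
    label: str
    n_sequences: int
    n_species: int
    n_singleton_species: int
    n_queries: int
    n_tp: int
    n_ambiguous: int
    n_fp: int
    n_fn: int
    n_tn: int

    def pct(self, count: int) -> float:
        return 100.0 * count / self.n_queries if self.n_queries else float("nan")


def summarize(
    outcomes: Sequence[MatchOutcome],
    library: ReferenceLibrary,
    group_by: Literal["dataset", "subfamily", "genus"] = "subfamily",
) -> list[IdentificationSummary]:
    """Tally outcome categories per group with query-count denominators."""
    ingroup = library.ingroup()

    def group_of(rec) -> str:
        if group_by == "dataset":
            return "dataset"
        return rec.subfamily if group_by == "subfamily" else rec.genus

    groups = sorted({group_of(r) for r in ingroup})
    by_group: dict[str, list[MatchOutcome]] = defaultdict(list)
    for o in outcomes:
        by_group[group_of(library[o.query])].append(o)
    summaries = []
    for g in groups:
        recs = [r for r in ingroup if group_of(r) == g]
        species = {r.nominal_species for r in recs}
        sizes = defaultdict(int)
        for r in recs:
            sizes[r.nominal_species] += 1
        singletons = sum(1 for s in species if sizes[s] == 1)
        outs = by_group.get(g, [])
        counts = defaultdict(int)
        for o in outs:
            counts[o.category] += 1
        summaries.append(
            IdentificationSummary(
                label=g,
                n_sequences=len(recs),
                n_species=len(species),
                n_singleton_species=singletons,
                n_queries=len(outs),
                n_tp=counts["TP"],
                n_ambiguous=counts["ambiguous"],
                n_fp=counts["FP"],
                n_fn=counts["FN"],
                n_tn=counts["TN"],
            )
        )
    return summaries


def summaries_frame(summaries: Sequence[IdentificationSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "group": s.label,
                "n_seq": s.n_sequences,
                "n_sp": s.n_species,
                "n_no_conspecific": s.n_singleton_species,
                "n_queries": s.n_queries,
                "TP": s.n_tp,
                "TP_pct": s.pct(s.n_tp),
                "ambiguous": s.n_ambiguous,
                "ambiguous_pct": s.pct(s.n_ambiguous),
                "FP": s.n_fp,
                "FP_pct": s.pct(s.n_fp),
                "FN": s.n_fn,
                "FN_pct": s.pct(s.n_fn),
                "TN": s.n_tn,
                "TN_pct": s.pct(s.n_tn),
            }
        )
    return pd.DataFrame(rows)


def outcomes_frame(outcomes: Sequence[MatchOutcome], library: ReferenceLibrary) -> pd.DataFrame:
    """Per-query outcome table (query, species, matched voucher, d, category)."""
    rows = []
    for o in outcomes:
        rows.append(
            {
                "query_voucher": o.query,
                "query_species": o.query_species,
                "match_voucher": o.representative_match,
                "match_species": "|".join(sorted(o.assigned_species)),
                "d": o.best_distance,
                "category": o.category,
                "threshold": o.threshold_used if o.threshold_used is not None else "",
            }
        )
    return pd.DataFrame(rows)
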