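"""Screening statistics: top-k% overlap, safety index, quadrants, strata.

Operates on the hospital rows of the two-mode centrality table.  The
degree of a hospital is the number of distinct patients who visited it;
its weighted degree is the number of prescriptions it issued.  Two kinds
of hospitals deserve attention: those many (potentially doctor-shopping)
patients visit — high degree — and those issuing many prescriptions per
patient — high weighted degree with low degree.  The overlap of the two
top-1% lists quantifies how far the two signals coincide for a drug, and
the Narcotics Safety Index

    NSI = weighted degree / degree

(the mean number of prescriptions per connected patient) ranks hospitals
for inspection priority.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import pandas as pd

from .records import (
    ConfigError,
    HospitalAttributes,
    REGIONS,
    SIZE_CATEGORIES,
    UNKNOWN,
    get_attributes,
)

logger = logging.getLogger("narcoscreen")


class Quadrant(enum.Enum):
    """Prescription-pattern quadrant by top-k% membership on both axes.

    ``HIGH_D_LOW_W`` marks hub-like hospitals frequently visited without
    proportionally many prescriptions; ``LOW_D_HIGH_W`` marks suspected
    overprescribers (few patients, many prescriptions each);
    ``HIGH_D_HIGH_W`` marks hospitals high on both signals.
    """

    LOW_D_LOW_W = "LOW_D_LOW_W"
    LOW_D_HIGH_W = "LOW_D_HIGH_W"
    HIGH_D_LOW_W = "HIGH_D_LOW_W"
    HIGH_D_HIGH_W = "HIGH_D_HIGH_W"


@dataclass(frozen=True)
class OverlapResult:
    """Top-k% membership overlap between two ranking metrics."""

    k_percent: float
    n_top: int
    set_a: frozenset
    set_b: frozenset
    overlap_fraction: float


def _top_set(df: pd.DataFrame, metric: str, secondary: str, n_top: int) -> frozenset:
    """The n_top hospitals by ``metric`` with deterministic tie-breaking
    (secondary metric descending, then id ascending)."""
    ranked = df.sort_values(
        by=[metric, secondary, "hospital_id"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    return frozenset(ranked["hospital_id"].head(n_top))


def _as_hospital_frame(table: pd.DataFrame) -> pd.DataFrame:
    df = table.copy()
    if "hospital_id" not in df.columns:
        df = df.reset_index().rename(columns={df.index.name or "index":
                                              "hospital_id"})
    for col in ("degree", "weighted_degree"):
        if col not in df.columns:
            raise ConfigError(f"centrality table lacks required column {col!r}")
    return df


def top_percent_overlap(
    hospitals: pd.DataFrame,
    metric_a: str = "degree",
    metric_b: str = "weighted_degree",
    k_percent: float = 1.0,
) -> OverlapResult:
    """Overlap of the top-k% hospital sets under two metrics.

    ``n_top = ceil(k_percent/100 * n_hospitals)`` (ceiling guarantees a
    nonempty set); the overlap fraction is ``|A & B| / n_top``.
    """
    df = _as_hospital_frame(hospitals)
    if df.empty:
        raise ConfigError("no hospitals to rank")
    n_top = math.ceil(k_percent / 100.0 * len(df))
    set_a = _top_set(df, metric_a, metric_b, n_top)
    set_b = _top_set(df, metric_b, metric_a, n_top)
    return OverlapResult(
        k_percent=k_percent,
        n_top=n_top,
        set_a=set_a,
        set_b=set_b,
        overlap_fraction=len(set_a & set_b) / n_top,
    )


def narcotics_safety_index(hospitals: pd.DataFrame) -> pd.DataFrame:
    """Per-hospital NSI = weighted degree / degree, ranked descending.

    Hospitals with degree 0 (possible only for isolated nodes injected
    from outside the network) are excluded with a logged warning.
    """
    df = _as_hospital_frame(hospitals)
    zero = df["degree"] == 0
    if zero.any():
        logger.warning(
            "excluding %d hospital(s) with degree 0 from NSI ranking",
            int(zero.sum()),
        )
        df = df[~zero].copy()
    df["nsi"] = df["weighted_degree"] / df["degree"]
    df = df.sort_values(by=["nsi", "hospital_id"], ascending=[False, True],
                        kind="mergesort")
    return df[["hospital_id", "degree", "weighted_degree", "nsi"]].reset_index(
        drop=True
    )


def classify_pattern(
    hospitals: pd.DataFrame, k_percent: float = 1.0
) -> pd.Series:
    """Quadrant label per hospital, reusing the top-k% sets.

    HIGH on an axis means membership in that metric's top-k% set — the
    same sets the overlap statistic uses, so the quadrant table stays
    consistent with the overlap analysis.
    """
    df = _as_hospital_frame(hospitals)
    res = top_percent_overlap(df, k_percent=k_percent)
    labels = []
    for hid in df["hospital_id"]:
        high_d = hid in res.set_a
        high_w = hid in res.set_b
        labels.append(
            Quadrant.HIGH_D_HIGH_W if high_d and high_w
            else Quadrant.HIGH_D_LOW_W if high_d
            else Quadrant.LOW_D_HIGH_W if high_w
            else Quadrant.LOW_D_LOW_W
        )
    return pd.Series(labels, index=pd.Index(df["hospital_id"]), name="quadrant")


def build_screening_report(
    hospitals: pd.DataFrame,
    attributes: Mapping[str, HospitalAttributes] | None = None,
    k_percent: float = 1.0,
) -> pd.DataFrame:
    """Assemble the per-hospital screening report.

    Columns: degree, weighted degree, NSI, quadrant label, size category
    and region (``UNKNOWN`` when no attribute row exists).  Sorted by
    NSI descending, ties by id.
    """
    nsi = narcotics_safety_index(hospitals)
    quadrants = classify_pattern(hospitals, k_percent=k_percent)
    nsi["quadrant"] = [quadrants[h].value for h in nsi["hospital_id"]]
    nsi["size_category"] = [
        get_attributes(attributes, h).size_category for h in nsi["hospital_id"]
    ]
    nsi["region"] = [
        get_attributes(attributes, h).region for h in nsi["hospital_id"]
    ]
    return nsi


@dataclass
class StratificationResult:
    """Per-category breakdown of a hospital network.

    ``table`` has one row per category (all official codes plus
    ``UNKNOWN`` when present): node count and share, within-category
    edge count, weighted-degree total and share.
    ``cross_category_edge_fraction`` is the fraction of edges joining
    two different categories — for regions, a doctor-shopping signal.
    """

    by: str
    table: pd.DataFrame
    cross_category_edge_fraction: float | None


def stratify(
    G: nx.Graph,
    attributes: Mapping[str, HospitalAttributes] | None,
    by: str = "size_category",
) -> StratificationResult:
    """Stratify a hospital network by size category or region."""
    if by not in ("size_category", "region"):
        raise ConfigError(
            f"unknown attribute {by!r}; expected 'size_category' or 'region'"
        )
    vocab = SIZE_CATEGORIES if by == "size_category" else REGIONS

    def cat(node: str) -> str:
        return getattr(get_attributes(attributes, node), by)

    cats = {n: cat(n) for n in G.nodes}
    categories = list(vocab)  # full vocabulary, zero rows included
    if UNKNOWN in set(cats.values()):
        categories.append(UNKNOWN)

    n_nodes = G.number_of_nodes()
    rows = []
    wdeg = {n: float(G.degree(n, weight="weight")) for n in G.nodes}
    total_w = sum(wdeg.values())
    n_edges = G.number_of_edges()
    n_cross = 0
    within: dict[str, int] = {c: 0 for c in categories}
    for u, v in G.edges:
        if cats[u] == cats[v]:
            within[cats[u]] = within.get(cats[u], 0) + 1
        else:
            n_cross += 1
    for c in categories:
        members = [n for n in G.nodes if cats[n] == c]
        w = sum(wdeg[n] for n in members)
        rows.append({
            by: c,
            "n_nodes": len(members),
            "node_share": len(members) / n_nodes if n_nodes else 0.0,
            "n_edges_within": within.get(c, 0),
            "total_weighted_degree": w,
            "weighted_degree_share": w / total_w if total_w else 0.0,
        })
    table = pd.DataFrame(rows).set_index(by)
    cross = n_cross / n_edges if n_edges else None
    return StratificationResult(by=by, table=table,
                                cross_category_edge_fraction=cross)
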