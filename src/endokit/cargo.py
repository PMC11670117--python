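"""Candidate endocytic-cargo selection and categorisation.

Candidate cargo are enriched proteins that could plausibly have been
endocytosed from the cell surface: proteins with at least one
transmembrane segment that are also annotated as localised to the cell
membrane. Selected cargo are further categorised by annotated
extracellular domains and protein families, and cross-referenced against
externally published cargo lists (e.g. proteins whose surface levels
depend on SNX17 or SNX27).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class CargoSet:
    """Selected candidate cargo with their annotations.

    ``table`` is indexed by protein id with at least ``tm_count``,
    ``cell_membrane``, ``synaptic``, ``domains`` and ``families`` columns
    (the last two semicolon-delimited label strings, empty for none).
    Every member has ``tm_count ≥ 1`` and the cell-membrane flag.
    """

    table: pd.DataFrame
    n_uncovered: int = 0

    @property
    def ids(self) -> set[str]:
        return set(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def _labels(value) -> set[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return set()
    return {x for x in str(value).split(";") if x}


def select_candidate_cargo(enriched: Iterable[str], catalog: pd.DataFrame) -> CargoSet:
    """Filter an enriched set to candidate cargo: TM ≥ 1 AND cell-membrane flag.

    ``catalog`` is indexed by protein id with ``tm_count`` and
    ``cell_membrane`` columns. Enriched ids absent from the catalog are
    excluded and counted (logged as a warning).
    """
    enriched = set(enriched)
    covered = enriched & set(catalog.index)
    n_uncovered = len(enriched) - len(covered)
    if n_uncovered:
        log.warning("%d enriched ids not covered by the annotation catalog", n_uncovered)
    sub = catalog.loc[sorted(covered)]
    keep = (sub["tm_count"].fillna(0) >= 1) & sub["cell_membrane"].fillna(False).astype(bool)
    return CargoSet(table=sub[keep], n_uncovered=n_uncovered)


def cargo_fraction(universe_pm_ids: Iterable[str], cargo: CargoSet | Iterable[str]) -> int:
    """Percentage of a PM-protein universe captured as candidate cargo.

    Computes ``100 · |cargo ∩ universe| / |universe|`` rounded to the
    nearest integer percent. An empty universe is an error.
    """
    universe = set(universe_pm_ids)
    if not universe:
        raise ValueError("empty PM universe")
    ids = cargo.ids if isinstance(cargo, CargoSet) else set(cargo)
    return int(round(100 * len(ids & universe) / len(universe)))


def categorize(cargo: CargoSet) -> tuple[pd.DataFrame, dict[str, int]]:
    """Domain-presence matrix and the domain/family count partition.

    Returns a binary presence matrix (rows = proteins ordered by first
    family label then id, columns = domain labels) and the three-way
    partition: proteins with both a domain and a family annotation, with
    exactly one of the two, and with neither.
    """
    counts = {"domain_and_family": 0, "domain_or_family_only": 0, "neither": 0}
    if cargo.table.empty:
        return pd.DataFrame(), counts

    domains_by_id = {pid: _labels(row.get("domains")) for pid, row in cargo.table.iterrows()}
    families_by_id = {pid: _labels(row.get("families")) for pid, row in cargo.table.iterrows()}
    for pid in cargo.table.index:
        has_d, has_f = bool(domains_by_id[pid]), bool(families_by_id[pid])
        if has_d and has_f:
            counts["domain_and_family"] += 1
        elif has_d or has_f:
            counts["domain_or_family_only"] += 1
        else:
            counts["neither"] += 1

    all_domains = sorted(set().union(*domains_by_id.values())) if domains_by_id else []
    order = sorted(
        cargo.table.index,
        key=lambda pid: (min(families_by_id[pid]) if families_by_id[pid] else "~", pid),
    )
    matrix = pd.DataFrame(
        [[int(d in domains_by_id[pid]) for d in all_domains] for pid in order],
        index=pd.Index(order, name="protein_id"),
        columns=all_domains,
    )
    return matrix, counts


def crossref(
    cargo: CargoSet, external_lists: Mapping[str, Iterable[str]]
) -> dict:
    """Membership patterns of cargo across named external id lists.

    For each cargo protein, a bit-pattern records which external lists
    contain it; the result holds per-pattern counts (pattern key =
    ``+``-joined list names, ``"none"`` for no list) and the fraction of
    cargo unique to this set. Pattern counts always sum to ``|cargo|``.
    """
    lists = {name: set(ids) for name, ids in external_lists.items()}
    names = sorted(lists)
    patterns: dict[str, int] = {}
    for pid in cargo.table.index:
        hit = [n for n in names if pid in lists[n]]
        key = "+".join(hit) if hit else "none"
        patterns[key] = patterns.get(key, 0) + 1
    n = len(cargo.table)
    return {
        "pattern_counts": patterns,
        "n_cargo": n,
        "fraction_unique": (patterns.get("none", 0) / n) if n else 0.0,
    }
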