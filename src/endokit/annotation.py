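"""Term overrepresentation and abundance-category statistics.

Term enrichment follows the SynGO-style analysis: for each curated term
(synaptic location or function), the overlap between an enriched protein
set and the term's members is tested with an upper-tail hypergeometric
test against the detected-protein universe, then BH-adjusted within each
term category (location and function are separate sub-ontologies).

Abundance categorisation reproduces the pie-chart logic comparing
whole-proteome fold changes for IP-selective proteins: *higher in A*,
*equal*, or *higher in B* depending on the whole-cell log2FC against a
symmetric threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust


def term_enrichment(
    hit_set: Iterable[str],
    universe: Iterable[str],
    terms: pd.DataFrame,
) -> pd.DataFrame:
    """Upper-tail hypergeometric overrepresentation per term.

    Parameters
    ----------
    hit_set : iterable of str
        Enriched protein ids; must be a subset of ``universe``.
    universe : iterable of str
        All detected/tested protein ids.
    terms : DataFrame
        Long format with columns ``term_id``, ``term_name``, ``category``,
        ``protein_id``. Memberships are intersected with the universe.

    Returns
    -------
    DataFrame
        One row per term: overlap count, expected count under the
        hypergeometric null, p value ``P[X ≥ overlap]`` with
        ``N = |universe|``, ``K = |term ∩ universe|``, ``n = |hit_set|``,
        BH q value (within each category) and ``log10_q``.
    """
    hits = set(hit_set)
    uni = set(universe)
    offenders = sorted(hits - uni)
    if offenders:
        raise ValueError(f"hit_set ids missing from universe: {offenders}")

    required = {"term_id", "term_name", "category", "protein_id"}
    if not required.issubset(terms.columns):
        raise ValueError(f"terms table needs columns {sorted(required)}")

    N, n = len(uni), len(hits)
    rows = []
    for (term_id, term_name, category), grp in terms.groupby(
        ["term_id", "term_name", "category"], sort=True
    ):
        members = set(grp["protein_id"]) & uni
        K = len(members)
        if K == 0:
            continue
        k = len(members & hits)
        # P[X >= k]; sf(k-1) is exact for the discrete distribution
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        rows.append(
            {
                "term_id": term_id,
                "term_name": term_name,
                "category": category,
                "term_size": K,
                "overlap": k,
                "expected": n * K / N if N else 0.0,
                "p_value": p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "term_id", "term_name", "category", "term_size",
            "overlap", "expected", "p_value",
        ],
    )
    if out.empty:
        out["q_value"] = pd.Series(dtype=float)
        out["log10_q"] = pd.Series(dtype=float)
        return out
    out["q_value"] = np.nan
    for cat, idx in out.groupby("category").groups.items():
        out.loc[idx, "q_value"] = bh_adjust(out.loc[idx, "p_value"].to_numpy())
    out["log10_q"] = np.log10(out["q_value"])
    return out.reset_index(drop=True)


@dataclass
class AbundanceCategories:
    """Per-protein abundance category plus integer-percent fractions."""

    categories: pd.Series  # id -> {"higher_a", "equal", "higher_b", "unknown"}
    percentages: dict[str, int]

    def combined(self, *names: str) -> int:
        """Sum of the rounded percentages for the given categories."""
        return sum(self.percentages.get(n, 0) for n in names)


def abundance_category(
    selective_ids: Iterable[str],
    whole_proteome_fc: Mapping[str, float] | pd.Series,
    fc_thresh: float = 1.0,
) -> AbundanceCategories:
    """Classify IP-selective proteins by whole-proteome abundance change.

    For each id, using the whole-cell ``log2FC(A/B)``: ``higher_a`` when
    FC ≥ ``fc_thresh`` (boundary inclusive), ``higher_b`` when
    FC ≤ −``fc_thresh``, otherwise ``equal``; ids without a whole-proteome
    value are ``unknown``. Percentages are over all selective ids and
    rounded to the nearest integer.
    """
    if isinstance(whole_proteome_fc, pd.Series):
        whole_proteome_fc = whole_proteome_fc.to_dict()
    ids = list(selective_ids)
    cats = {}
    for pid in ids:
        fc = whole_proteome_fc.get(pid)
        if fc is None or (isinstance(fc, float) and np.isnan(fc)):
            cats[pid] = "unknown"
        elif fc >= fc_thresh:
            cats[pid] = "higher_a"
        elif fc <= -fc_thresh:
            cats[pid] = "higher_b"
        else:
            cats[pid] = "equal"
    series = pd.Series(cats, dtype=object)
    n = len(ids)
    pct = {
        name: int(round(100 * sum(1 for c in cats.values() if c == name) / n)) if n else 0
        for name in ("higher_a", "equal", "higher_b", "unknown")
    }
    return AbundanceCategories(categories=series, percentages=pct)
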