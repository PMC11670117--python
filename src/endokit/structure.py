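"""Triage of structure-prediction confidence scores and motif logos.

Structure prediction itself (AlphaFold-class models) happens outside this
package; what arrives here is a table of candidate peptide–receptor
predictions with their ipTM scores (interface predicted TM-score, a
confidence metric on [0, 1] for the predicted interaction interface).
Candidates are triaged at a strict ipTM threshold (default 0.6), and
position-weight-matrix logos summarise the top- and bottom-ranked
predictions.

PWM construction uses add-``pseudocount`` smoothing over the 20 standard
residues; per-position information content is ``log2(20) − H`` bits where
``H`` is the position's Shannon entropy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

AA_ORDER = tuple("ACDEFGHIKLMNPQRSTVWY")
MAX_IC_BITS = float(np.log2(20))


def _as_records(records) -> pd.DataFrame:
    df = records.copy() if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    required = {"candidate_id", "iptm"}
    if not required.issubset(df.columns):
        raise ValueError(f"ipTM records need columns {sorted(required)}")
    bad = df[(df["iptm"] < 0) | (df["iptm"] > 1) | df["iptm"].isna()]
    if not bad.empty:
        raise ValueError(
            f"ipTM outside [0, 1] for record(s): {list(bad['candidate_id'])}"
        )
    return df


def triage(records, threshold: float = 0.6) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split ipTM records into pass/fail sets at a strict threshold.

    A candidate passes iff ``iptm > threshold`` — a score exactly at the
    threshold fails. Returns ``(pass_df, fail_df)``.
    """
    df = _as_records(records)
    mask = df["iptm"] > threshold
    return df[mask].reset_index(drop=True), df[~mask].reset_index(drop=True)


def select_extremes(
    records, n_top: int, n_bottom: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top and bottom candidates by ipTM.

    Sorted by ipTM descending with ties broken by ``candidate_id``
    (lexicographic), so selection is deterministic. Raises when fewer
    than ``n_top + n_bottom`` records are available.
    """
    df = _as_records(records)
    if len(df) < n_top + n_bottom:
        raise ValueError(
            f"need at least {n_top + n_bottom} records, have {len(df)}"
        )
    ordered = df.sort_values(
        ["iptm", "candidate_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    top = ordered.head(n_top).reset_index(drop=True)
    bottom = ordered.tail(n_bottom).iloc[::-1].reset_index(drop=True)
    return top, bottom


@dataclass
class PWM:
    """Position-probability matrix with per-position information content.

    ``probs`` is positions × 20 residues, each row summing to 1;
    ``information`` is per-position IC in bits, bounded by
    ``[0, log2 20]``. Position labels are negative C-terminal offsets for
    C-terminally aligned peptides, else 1-based.
    """

    probs: pd.DataFrame
    information: pd.Series
    n_peptides: int

    def __post_init__(self) -> None:
        row_sums = self.probs.sum(axis=1).to_numpy()
        if not np.allclose(row_sums, 1.0, atol=1e-9):
            raise ValueError("PWM rows must each sum to 1")
        ic = self.information.to_numpy()
        if np.any(ic < -1e-12) or np.any(ic > MAX_IC_BITS + 1e-12):
            raise ValueError("information content out of [0, log2 20]")

    @classmethod
    def from_peptides(
        cls,
        peptides: Sequence[str],
        pseudocount: float = 0.1,
        cterm_aligned: bool = True,
    ) -> "PWM":
        return build_pwm(peptides, pseudocount=pseudocount, cterm_aligned=cterm_aligned)

    def consensus(self) -> str:
        return "".join(self.probs.idxmax(axis=1))

    def plot_logo(self, ax=None):
        """Letter-height logo: residues stacked to the position's IC (bits)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(0.5 * len(self.probs) + 1, 2.5))
        for x, (pos, row) in enumerate(self.probs.iterrows()):
            heights = (row * self.information.loc[pos]).sort_values()
            y = 0.0
            for aa, h in heights.items():
                if h < 0.01:
                    continue
                ax.text(
                    x, y, aa, fontsize=14, ha="center", va="bottom",
                    fontweight="bold", stretch="expanded",
                )
                y += max(h, 0.12)
        ax.set_xticks(range(len(self.probs)))
        ax.set_xticklabels([str(p) for p in self.probs.index])
        ax.set_xlim(-0.6, len(self.probs) - 0.4)
        ax.set_ylim(0, MAX_IC_BITS)
        ax.set_ylabel("bits")
        return ax


def build_pwm(
    peptides: Sequence[str], pseudocount: float = 0.1, cterm_aligned: bool = True
) -> PWM:
    """Build a PWM from equal-length aligned peptides.

    Per position, ``p(aa) = (count + pseudocount) / (n + 20·pseudocount)``.
    SNX27 peptides should be right-aligned (C-terminus), SNX17 peptides on
    the 6-residue motif core; peptides of unequal length are an error.
    """
    peptides = list(peptides)
    if not peptides:
        raise ValueError("no peptides")
    width = len(peptides[0])
    if any(len(p) != width for p in peptides):
        raise ValueError("peptides must all have equal length")
    n = len(peptides)
    counts = np.zeros((width, 20))
    aa_index = {aa: i for i, aa in enumerate(AA_ORDER)}
    for pep in peptides:
        for j, aa in enumerate(pep):
            if aa in aa_index:
                counts[j, aa_index[aa]] += 1
    denom = counts.sum(axis=1, keepdims=True) + 20 * pseudocount
    probs = (counts + pseudocount) / denom

    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log2(probs), 0.0)
    entropy = -plogp.sum(axis=1)
    ic = np.clip(MAX_IC_BITS - entropy, 0.0, MAX_IC_BITS)

    if cterm_aligned:
        positions = [-(width - j) for j in range(width)]
    else:
        positions = list(range(1, width + 1))
    index = pd.Index(positions, name="position")
    return PWM(
        probs=pd.DataFrame(probs, index=index, columns=list(AA_ORDER)),
        information=pd.Series(ic, index=index, name="ic_bits"),
        n_peptides=n,
    )
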