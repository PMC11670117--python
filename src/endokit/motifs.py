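"""Short-linear-motif scanning for endosomal sorting signals.

Two motif classes are recognised:

* **SNX27** — the PDZ domain of SNX27 binds C-terminal ``[S/T]-x-Φ``
  motifs, where Φ is a hydrophobic residue occupying the very C-terminus.
  The core is frequently preceded by acidic residues or by Ser/Thr
  (phospho-acceptor) positions that enhance binding; we report a context
  score counting ``{D, E, S, T}`` in the five residues upstream of the
  core (positions −4..−8 from the C-terminus).
* **SNX17** — the FERM domain of SNX17 binds internal ``ΦxNxx[F/Y]``
  motifs in cytosolic tails.

The hydrophobic alphabet Φ defaults to ``{A, V, L, I, M, F, W, Y}`` and is
configurable, since motif counts depend on this choice. Nonstandard
residues (X, U, B, Z, ...) never match any motif position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Default hydrophobic residue set Φ.
PHI = frozenset("AVLIMFWY")

#: Residues counted by the SNX27 upstream context score.
CONTEXT_RESIDUES = frozenset("DEST")

#: Width of the upstream context window (positions −4..−8).
CONTEXT_WINDOW = 5

SNX27 = "SNX27"
SNX17 = "SNX17"


@dataclass(frozen=True)
class MotifHit:
    """A single motif match within one protein sequence.

    ``start`` is 1-based from the N-terminus; ``offset_from_cterm`` is the
    negative offset of the first motif residue, with the C-terminal residue
    at −1. ``match`` reproduces the matched sequence slice.
    """

    protein_id: str
    motif_class: str
    start: int
    offset_from_cterm: int
    match: str
    context_score: int = 0

    def __post_init__(self) -> None:
        if self.motif_class not in (SNX27, SNX17):
            raise ValueError(f"unknown motif class {self.motif_class!r}")


def _check_sequence(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")


def scan_snx27(seq: str, protein_id: str = "", phi: frozenset = PHI) -> Optional[MotifHit]:
    """Test the C-terminus of ``seq`` for an SNX27 PDZ-binding motif.

    A hit requires the residue at −3 to be S or T and the C-terminal
    residue (−1) to be hydrophobic; position −2 is unrestricted. At most
    one hit per sequence exists since the motif is anchored at the
    C-terminus. Returns ``None`` when there is no match.
    """
    _check_sequence(seq)
    if len(seq) < 3:
        return None
    tail = seq[-3:]
    nonstandard = set(tail) - STANDARD_AA
    if nonstandard:
        warnings.warn(
            f"nonstandard residues {sorted(nonstandard)} at C-terminus of "
            f"{protein_id or 'sequence'}; treated as non-matching"
        )
        return None
    if tail[0] not in "ST" or tail[2] not in phi:
        return None
    context = seq[max(0, len(seq) - 3 - CONTEXT_WINDOW) : len(seq) - 3]
    score = sum(1 for r in context if r in CONTEXT_RESIDUES)
    return MotifHit(
        protein_id=protein_id,
        motif_class=SNX27,
        start=len(seq) - 2,
        offset_from_cterm=-3,
        match=tail,
        context_score=score,
    )


def snx17_window_matches(window: str, phi: frozenset = PHI) -> bool:
    """True when a 6-residue window fits ``ΦxNxx[F/Y]``."""
    if len(window) != 6 or (set(window) - STANDARD_AA):
        return False
    return window[0] in phi and window[2] == "N" and window[5] in "FY"


def scan_snx17(
    seq: str,
    protein_id: str = "",
    tm_end: Optional[int] = None,
    phi: frozenset = PHI,
) -> list[MotifHit]:
    """Scan ``seq`` for internal SNX17 FERM-binding motifs (``ΦxNxx[F/Y]``).

    Every 6-residue window in the scan region is tested and overlapping
    hits are all reported. When ``tm_end`` (1-based position of the last
    transmembrane residue) is given, only the region C-terminal to it is
    scanned — the cytosolic-tail assumption for type-I topology; topology
    itself is never inferred. A ``tm_end`` leaving no 6-residue tail
    yields an empty list.
    """
    _check_sequence(seq)
    n = len(seq)
    first = 0 if tm_end is None else max(0, int(tm_end))
    hits: list[MotifHit] = []
    for i in range(first, n - 5):
        window = seq[i : i + 6]
        if snx17_window_matches(window, phi):
            hits.append(
                MotifHit(
                    protein_id=protein_id,
                    motif_class=SNX17,
                    start=i + 1,
                    offset_from_cterm=i - n,
                    match=window,
                )
            )
    return hits


def cterm_peptide(seq: str, k: int = 15) -> str:
    """Return the C-terminal ``k``-mer (the whole sequence if shorter)."""
    _check_sequence(seq)
    return seq[-k:]


@dataclass
class MotifTable:
    """Proteome-wide scan result: per-protein hits plus summary counts."""

    hits: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def hits_for(self, protein_id: str) -> pd.DataFrame:
        return self.hits[self.hits["protein_id"] == protein_id]


def scan_proteome(
    sequences: Mapping[str, str] | Iterable[tuple[str, str]],
    tm_ends: Optional[Mapping[str, int]] = None,
    phi: frozenset = PHI,
) -> MotifTable:
    """Scan every sequence for both motif classes.

    ``sequences`` maps protein id to sequence (or is an iterable of
    ``(id, sequence)`` pairs; duplicate ids raise). The summary counts
    proteins with an SNX27 hit, proteins with at least one SNX17 hit, and
    total SNX17 motifs — a protein may contribute several motifs.
    """
    pairs = list(sequences.items()) if isinstance(sequences, Mapping) else list(sequences)
    seen: set[str] = set()
    for pid, _ in pairs:
        if pid in seen:
            raise ValueError(f"duplicate protein id {pid!r}")
        seen.add(pid)

    rows = []
    n_snx27 = 0
    snx17_proteins = 0
    snx17_motifs = 0
    for pid, seq in pairs:
        hit27 = scan_snx27(seq, pid, phi=phi)
        if hit27 is not None:
            n_snx27 += 1
            rows.append(hit27)
        tm_end = tm_ends.get(pid) if tm_ends else None
        hits17 = scan_snx17(seq, pid, tm_end=tm_end, phi=phi)
        if hits17:
            snx17_proteins += 1
            snx17_motifs += len(hits17)
            rows.extend(hits17)

    columns = ["protein_id", "motif_class", "start", "offset_from_cterm", "match", "context_score"]
    hits = pd.DataFrame([vars(h) for h in rows], columns=columns)
    summary = {
        "proteins_with_snx27": n_snx27,
        "proteins_with_snx17": snx17_proteins,
        "total_snx17_motifs": snx17_motifs,
    }
    return MotifTable(hits=hits, summary=summary)
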