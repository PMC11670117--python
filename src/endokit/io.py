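"""Readers and writers for the pipeline's file formats.

Tables are tab-separated UTF-8 with a header row; missing values are
written empty and read as either empty or ``"."`` (the dialect of common
proteomics exports). Sequences travel as FASTA via Biopython.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .quant import QuantMatrix
from .simulate import AnnotationCatalog, GroundTruth

NA_VALUES = ["", "."]


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered id → sequence map.

    Wrapped and unwrapped sequence lines are both accepted; duplicate ids
    and empty files are errors.
    """
    path = Path(path)
    records: dict[str, str] = {}
    with open(path) as handle:
        first = handle.read(1)
        if not first:
            raise ValueError(f"empty FASTA file: {path}")
        if first != ">":
            raise ValueError(f"malformed FASTA (no '>' header): {path}")
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in records:
                raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
            records[rec.id] = str(rec.seq)
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(sequences: Mapping[str, str], path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in sequences.items()
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------- tables

def _read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=NA_VALUES, keep_default_na=True, **kwargs)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep="")


def read_quant(path, design_path, mapping: Optional[Mapping[str, str]] = None) -> QuantMatrix:
    """Load a quant TSV plus its design TSV into a validated QuantMatrix.

    ``mapping`` renames design columns of real-world exports onto the
    expected factor names (e.g. ``{"Condition": "genotype"}``). Sample
    sets must match exactly between the two files; the intensity columns
    are reordered to design order.
    """
    quant = _read_tsv(path).set_index("protein_id")
    design = _read_tsv(design_path)
    if mapping:
        design = design.rename(columns=dict(mapping))
    if "sample_id" not in design.columns:
        raise ValueError(f"design table {design_path} needs a sample_id column")
    return QuantMatrix(intensities=quant, design=design)


def write_quant(q: QuantMatrix, quant_path, design_path) -> None:
    write_tsv(q.intensities.reset_index(), quant_path)
    write_tsv(q.design.reset_index(), design_path)


def read_annotations(path) -> pd.DataFrame:
    df = _read_tsv(path).set_index("protein_id")
    df["cell_membrane"] = df["cell_membrane"].astype(bool)
    if "synaptic" in df.columns:
        df["synaptic"] = df["synaptic"].astype(bool)
    for col in ("domains", "families"):
        if col in df.columns:
            df[col] = df[col].fillna("")
    return df


def write_annotations(catalog: AnnotationCatalog, path) -> None:
    write_tsv(catalog.table.reset_index(), path)


def read_terms(path) -> pd.DataFrame:
    return _read_tsv(path)


def write_terms(terms: pd.DataFrame, path) -> None:
    write_tsv(terms, path)


def read_iptm(path) -> pd.DataFrame:
    df = _read_tsv(path)
    required = {"candidate_id", "iptm"}
    if not required.issubset(df.columns):
        raise ValueError(f"ipTM table {path} needs columns {sorted(required)}")
    return df


def write_iptm(df: pd.DataFrame, path) -> None:
    write_tsv(df, path)


def read_timecourse(path) -> pd.DataFrame:
    return _read_tsv(path).set_index("protein_id")


def write_timecourse(df: pd.DataFrame, path) -> None:
    write_tsv(df.reset_index(), path)


def write_enrichment(table: pd.DataFrame, path) -> None:
    write_tsv(table.reset_index(), path)


def read_enrichment(path) -> pd.DataFrame:
    return _read_tsv(path).set_index("protein_id")


def write_motifs(hits: pd.DataFrame, path) -> None:
    write_tsv(hits, path)


def read_id_list(path) -> set[str]:
    """One-protein-id-per-line text file (blank lines ignored)."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


# ---------------------------------------------------------------- JSON

def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = asdict(truth)
    for key in ("enriched_ids", "motif_ids_snx27", "motif_ids_snx17"):
        payload[key] = sorted(payload[key])
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return GroundTruth(
        enriched_ids=set(payload["enriched_ids"]),
        motif_ids_snx27=set(payload["motif_ids_snx27"]),
        motif_ids_snx17=set(payload["motif_ids_snx17"]),
        snx17_positions={k: list(v) for k, v in payload["snx17_positions"].items()},
        incidental_snx17={k: list(v) for k, v in payload["incidental_snx17"].items()},
        cluster_assignment={k: int(v) for k, v in payload["cluster_assignment"].items()},
    )


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
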