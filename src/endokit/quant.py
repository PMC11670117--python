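"""Protein-level quantitative matrices for multiplexed (TMT) proteomics.

A :class:`QuantMatrix` pairs a protein × sample reporter-intensity table
with a sample design table describing the factors of each channel
(genotype tagged/untagged, IP type, cell state, treatment, replicate).
Intensities arrive on the linear scale; :func:`normalize` moves them to
log2 and median-centres each sample so channel-loading differences cancel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass
class QuantMatrix:
    """Protein × sample intensities plus the per-sample design.

    Parameters
    ----------
    intensities : DataFrame
        Indexed by protein id, one column per sample. Linear scale unless
        ``log_scale`` is set. Missing values are NaN.
    design : DataFrame
        Indexed by sample id (or carrying a ``sample_id`` column), one row
        per sample column, with factor columns such as ``genotype``,
        ``ip_type``, ``state``, ``treatment``, ``replicate``.
    log_scale : bool
        Whether intensities are already log2-transformed.
    """

    intensities: pd.DataFrame
    design: pd.DataFrame
    log_scale: bool = False

    def __post_init__(self) -> None:
        design = self.design
        if "sample_id" in design.columns:
            design = design.set_index("sample_id")
        self.design = design
        cols = list(self.intensities.columns)
        if len(set(cols)) != len(cols):
            raise ValueError("duplicate sample columns in intensity matrix")
        missing = [c for c in cols if c not in design.index]
        extra = [s for s in design.index if s not in cols]
        if missing or extra:
            raise ValueError(
                f"sample mismatch between quant and design: "
                f"not in design {missing}, not in quant {extra}"
            )
        # align column order to the design
        self.intensities = self.intensities[list(design.index)]

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.intensities.index)

    def samples_where(self, factor: str, level: str) -> list[str]:
        """Sample ids whose design value for ``factor`` equals ``level``."""
        if factor not in self.design.columns:
            raise KeyError(f"unknown design factor {factor!r}")
        mask = self.design[factor].astype(str) == str(level)
        return list(self.design.index[mask])


def normalize(q: QuantMatrix) -> QuantMatrix:
    """Log2-transform (if needed) and median-centre each sample column.

    After normalization the median of every sample column is zero, which
    removes constant log-scale channel offsets (TMT loading differences).
    Already-normalized input passes through unchanged, so the operation is
    idempotent. An all-missing sample column is an error.
    """
    x = q.intensities.astype(float)
    if not q.log_scale:
        with np.errstate(divide="ignore"):
            arr = np.log2(x.to_numpy())
        arr[~np.isfinite(arr)] = np.nan
        x = pd.DataFrame(arr, index=x.index, columns=x.columns)
    all_missing = [c for c in x.columns if x[c].isna().all()]
    if all_missing:
        raise ValueError(f"sample(s) with no observed intensities: {all_missing}")
    centred = x - x.median(axis=0, skipna=True)
    return replace(q, intensities=centred, log_scale=True)
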