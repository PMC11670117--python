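"""Synthetic organelle-IP experiments with known ground truth.

Every downstream stage of the pipeline — enrichment testing, cargo
selection, motif scanning, ipTM triage and time-course clustering — is
exercised against data generated here, with the planted truth recorded so
sensitivity, false-discovery and recovery rates can be measured exactly.

What is emulated
----------------
* an annotation catalog with compartment labels (lysosome / endosome /
  plasma membrane / other), transmembrane-segment counts, cell-membrane
  flags, synaptic-term memberships and domain/family labels;
* tagged-vs-untagged TMT reporter-intensity matrices: per-protein log2
  baselines, a planted log2 enrichment effect for organelle-resident
  proteins in tagged samples, per-channel loading offsets, and Gaussian
  measurement noise, emitted on the linear scale;
* protein sequences with SNX27 ``[S/T]xΦ`` C-terminal motifs and SNX17
  ``ΦxNxx[F/Y]`` internal motifs planted at configurable rates over a
  uniform residue background (so motif statistics stay analytic);
* differentiation time-courses with template-based cluster structure;
* mock ipTM score tables with separated high (planted) and low (control)
  modes.

All randomness flows from a single seed through named substreams, so the
full bundle is byte-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .motifs import PHI, scan_snx17, snx17_window_matches
from .quant import QuantMatrix

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
ACIDIC_PHOSPHO = np.array(list("DEST"))

COMPARTMENTS = ("lysosome", "endosome", "plasma_membrane")

_DOMAINS = (
    "Ig-like C2-type", "Fibronectin type-III", "EGF-like", "Protein kinase",
    "LDLR class A", "Cadherin", "Laminin G-like", "Sushi",
)
_FAMILIES = (
    "Nectin", "LDLR", "Neurexin", "Immunoglobulin", "Tyrosine protein kinase",
    "Tetraspanin", "SLC transporter", "Potassium channel",
)


def substream(seed: int, name: str) -> np.random.Generator:
    """A named, reproducible child RNG stream derived from one top seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(zlib.crc32(name.encode()),))
    )


@dataclass
class SimConfig:
    """Study-design parameters for one synthetic experiment.

    Defaults mirror the profiled study's design: 1,000 quantified
    proteins, triplicate tagged vs untagged IPs, a planted log2
    enrichment effect of 2.0 for organelle-resident proteins,
    measurement noise of 0.3 log2 units, and TMT channel offsets of
    0.2 log2 units.
    """

    n_proteins: int = 1000
    compartment_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "lysosome": 0.10,
            "endosome": 0.10,
            "plasma_membrane": 0.15,
        }
    )
    enrichment_effect: float | Mapping[str, float] = 2.0
    noise_sd: float = 0.3
    n_replicates_per_group: int = 3
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 2.0
    channel_offset_sd: float = 0.2
    motif_plant_rate_snx27: float = 0.10
    motif_plant_rate_snx17: float = 0.25
    seq_length_range: tuple[int, int] = (60, 400)
    n_timepoints: int = 5
    n_clusters: int = 3
    timecourse_noise_sd: float = 0.2
    iptm_high_params: tuple[float, float] = (10.0, 3.0)
    iptm_low_params: tuple[float, float] = (2.5, 8.0)
    n_iptm_controls: int = 47
    synaptic_rate: float = 0.25
    n_terms: int = 6
    missing_below_quantile: Optional[float] = None
    suppress_background_snx17: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = dict(self.compartment_fractions)
        if any(not (0 <= f <= 1) for f in fracs.values()):
            raise ValueError("compartment fractions must lie in [0, 1]")
        if sum(fracs.values()) > 1 + 1e-12:
            raise ValueError("compartment fractions sum to more than 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_replicates_per_group < 2:
            raise ValueError("need at least 2 replicates per group")
        if self.seq_length_range[0] < 20:
            raise ValueError("minimum sequence length is 20")
        for rate in (self.motif_plant_rate_snx27, self.motif_plant_rate_snx17,
                     self.synaptic_rate):
            if not (0 <= rate <= 1):
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted truth for one simulated experiment."""

    enriched_ids: set[str] = field(default_factory=set)
    motif_ids_snx27: set[str] = field(default_factory=set)
    motif_ids_snx17: set[str] = field(default_factory=set)
    snx17_positions: dict[str, list[int]] = field(default_factory=dict)
    incidental_snx17: dict[str, list[int]] = field(default_factory=dict)
    cluster_assignment: dict[str, int] = field(default_factory=dict)


@dataclass
class AnnotationCatalog:
    """Per-protein annotations plus a long-format synaptic term table."""

    table: pd.DataFrame  # indexed by protein_id
    terms: pd.DataFrame  # term_id, term_name, category, protein_id

    @property
    def ids(self) -> list[str]:
        return list(self.table.index)

    def compartment_map(self) -> pd.Series:
        return self.table["compartment"]


def generate_catalog(config: SimConfig) -> AnnotationCatalog:
    """Draw a protein annotation catalog from the configured fractions.

    Compartment labels are drawn i.i.d. per the configured fractions with
    the remainder labelled ``other`` (cytosol/ER/Golgi/mito residents).
    Plasma-membrane proteins always receive at least one transmembrane
    segment and the cell-membrane flag; lysosomal/endosomal membrane
    proteins carry TM segments with moderate probability. A configurable
    subset carries synaptic-term membership and domain/family labels.
    """
    rng = substream(config.seed, "catalog")
    n = config.n_proteins
    ids = [f"P{i:05d}" for i in range(n)]

    fracs = dict(config.compartment_fractions)
    labels = list(fracs) + ["other"]
    probs = list(fracs.values()) + [1 - sum(fracs.values())]
    compartment = rng.choice(labels, size=n, p=np.clip(probs, 0, 1))

    tm_count = np.zeros(n, dtype=int)
    cell_membrane = np.zeros(n, dtype=bool)
    is_pm = compartment == "plasma_membrane"
    # single- and multi-pass receptors/channels on the cell surface
    tm_count[is_pm] = 1 + rng.poisson(1.5, is_pm.sum())
    cell_membrane[is_pm] = True
    is_organelle_membrane = np.isin(compartment, ("lysosome", "endosome"))
    has_tm = rng.random(n) < 0.5
    tm_count[is_organelle_membrane & has_tm] = 1 + rng.poisson(
        1.0, (is_organelle_membrane & has_tm).sum()
    )

    synaptic = rng.random(n) < config.synaptic_rate

    domains = np.array([""] * n, dtype=object)
    families = np.array([""] * n, dtype=object)
    for i in range(n):
        if tm_count[i] >= 1:
            if rng.random() < 0.5:
                domains[i] = ";".join(
                    rng.choice(_DOMAINS, size=rng.integers(1, 3), replace=False)
                )
            if rng.random() < 0.5:
                families[i] = rng.choice(_FAMILIES)

    table = pd.DataFrame(
        {
            "compartment": compartment,
            "tm_count": tm_count,
            "cell_membrane": cell_membrane,
            "synaptic": synaptic,
            "domains": domains,
            "families": families,
        },
        index=pd.Index(ids, name="protein_id"),
    )

    term_rows = []
    term_names = [
        ("SYNGO:0001", "presynapse", "location"),
        ("SYNGO:0002", "postsynapse", "location"),
        ("SYNGO:0003", "synaptic vesicle", "location"),
        ("SYNGO:0101", "synapse organization", "function"),
        ("SYNGO:0102", "synaptic signaling", "function"),
        ("SYNGO:0103", "transport at the synapse", "function"),
    ][: config.n_terms]
    syn_ids = [pid for pid, s in zip(ids, synaptic) if s]
    for term_id, term_name, category in term_names:
        if not syn_ids:
            break
        members = rng.choice(
            syn_ids, size=max(1, int(0.4 * len(syn_ids))), replace=False
        )
        for pid in members:
            term_rows.append(
                {"term_id": term_id, "term_name": term_name,
                 "category": category, "protein_id": pid}
            )
    terms = pd.DataFrame(
        term_rows, columns=["term_id", "term_name", "category", "protein_id"]
    )
    return AnnotationCatalog(table=table, terms=terms)


def _draw_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(AA, size=length)


def _plant_snx27(rng: np.random.Generator, seq: np.ndarray) -> None:
    # core [S/T]-x-Φ at the C-terminus, acidic/phospho-rich just upstream
    seq[-3] = rng.choice(["S", "T"])
    seq[-2] = rng.choice(AA)
    seq[-1] = rng.choice(sorted(PHI))
    for k in range(4, 7):  # positions −4..−6
        seq[-k] = rng.choice(ACIDIC_PHOSPHO)


def _plant_snx17(rng: np.random.Generator, seq: np.ndarray) -> int:
    # one internal ΦxNxx[F/Y] window, kept clear of the C-terminal triplet
    start = int(rng.integers(0, len(seq) - 9))
    seq[start] = rng.choice(sorted(PHI))
    seq[start + 2] = "N"
    seq[start + 5] = rng.choice(["F", "Y"])
    return start


def _cterm_matches_snx27(seq: np.ndarray) -> bool:
    return seq[-3] in "ST" and seq[-1] in PHI


def generate_sequences(
    catalog: AnnotationCatalog, config: SimConfig
) -> tuple[dict[str, str], GroundTruth]:
    """Generate protein sequences with planted sorting motifs.

    Proteins are chosen for SNX27/SNX17 planting at the configured rates
    (exact counts, ``round(rate · n)``). Background residues are uniform
    over the 20 standard amino acids. Non-planted proteins are
    rejection-sampled so their C-terminal triplet never matches the
    SNX27 pattern; incidental internal SNX17 matches are permitted and
    recorded unless ``suppress_background_snx17`` is set, in which case
    sequences are resampled until the only SNX17 matches are the planted
    ones.
    """
    rng = substream(config.seed, "sequences")
    ids = catalog.ids
    n = len(ids)
    n27 = round(config.motif_plant_rate_snx27 * n)
    n17 = round(config.motif_plant_rate_snx17 * n)
    planted27 = set(map(str, rng.choice(ids, size=n27, replace=False))) if n27 else set()
    planted17 = set(map(str, rng.choice(ids, size=n17, replace=False))) if n17 else set()

    lo, hi = config.seq_length_range
    truth = GroundTruth(
        motif_ids_snx27=planted27, motif_ids_snx17=planted17
    )
    sequences: dict[str, str] = {}
    for pid in ids:
        length = int(rng.integers(lo, hi + 1))
        while True:
            seq = _draw_sequence(rng, length)
            planted_start: Optional[int] = None
            if pid in planted17:
                planted_start = _plant_snx17(rng, seq)
            if pid in planted27:
                _plant_snx27(rng, seq)
            else:
                while _cterm_matches_snx27(seq):
                    seq[-3:] = rng.choice(AA, size=3)
            s = "".join(seq)
            starts = [h.start - 1 for h in scan_snx17(s)]
            if config.suppress_background_snx17:
                expected = [planted_start] if planted_start is not None else []
                if starts != expected:
                    continue  # resample until only the planted window matches
            break
        sequences[pid] = s
        if planted_start is not None:
            truth.snx17_positions[pid] = [planted_start]
        incidental = [st for st in starts if st != planted_start]
        if incidental:
            truth.incidental_snx17[pid] = incidental
    return sequences, truth


def _effect_for(config: SimConfig, compartment: str) -> float:
    eff = config.enrichment_effect
    if isinstance(eff, Mapping):
        return float(eff.get(compartment, 0.0))
    return float(eff) if compartment in COMPARTMENTS else 0.0


def generate_quant(
    catalog: AnnotationCatalog, truth: GroundTruth, config: SimConfig
) -> QuantMatrix:
    """Simulate a tagged-vs-untagged TMT reporter-intensity matrix.

    On the log2 scale each measurement is::

        baseline(protein) + effect · 1[tagged AND enriched]
                          + offset(channel) + Normal(0, noise_sd)

    emitted on the linear scale (``2**x``). Organelle-resident proteins
    (nonzero configured effect) are the planted enriched set, recorded in
    ``truth.enriched_ids``. Channel offsets emulate TMT loading
    differences and are removed by median normalization.
    """
    rng = substream(config.seed, "quant")
    ids = catalog.ids
    n = len(ids)
    r = config.n_replicates_per_group
    samples = [f"tagged_{i + 1}" for i in range(r)] + [
        f"untagged_{i + 1}" for i in range(r)
    ]
    tagged = np.array([s.startswith("tagged") for s in samples])

    effects = np.array(
        [_effect_for(config, c) for c in catalog.table["compartment"]]
    )
    truth.enriched_ids = {pid for pid, e in zip(ids, effects) if e != 0.0}

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)
    offsets = rng.normal(0.0, config.channel_offset_sd, len(samples))
    noise = rng.normal(0.0, config.noise_sd, (n, len(samples)))
    log2 = (
        baseline[:, None]
        + np.outer(effects, tagged.astype(float))
        + offsets[None, :]
        + noise
    )
    linear = np.power(2.0, log2)
    intensities = pd.DataFrame(
        linear, index=pd.Index(ids, name="protein_id"), columns=samples
    )
    if config.missing_below_quantile is not None:
        cut = np.nanquantile(linear, config.missing_below_quantile)
        intensities = intensities.mask(intensities < cut)

    design = pd.DataFrame(
        {
            "sample_id": samples,
            "genotype": ["tagged"] * r + ["untagged"] * r,
            "ip_type": "endo",
            "state": "iNeuron",
            "treatment": "none",
            "replicate": list(range(1, r + 1)) * 2,
        }
    )
    return QuantMatrix(intensities=intensities, design=design)


_TEMPLATES = {
    "up": lambda t: t,
    "down": lambda t: -t,
    "transient": lambda t: -np.abs(t - 0.5) * 2,
    "late": lambda t: np.where(t > 0.6, 1.0, 0.0),
    "early": lambda t: np.where(t < 0.4, 1.0, 0.0),
    "mid_dip": lambda t: np.abs(t - 0.5) * 2,
}


def generate_timecourse(
    catalog: AnnotationCatalog, config: SimConfig
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Simulate differentiation time-course profiles with cluster structure.

    Each protein is assigned one of ``n_clusters`` trajectory templates
    (monotone up/down, transient, step-like) plus Gaussian noise in
    z-space; templates are z-normalised and checked to be pairwise
    separated by at least 3× the noise sd (RMS over timepoints), so the
    planted partition is recoverable. Emitted on the linear scale over
    days 0–12.
    """
    rng = substream(config.seed, "timecourse")
    k = config.n_clusters
    if k < 2:
        raise ValueError("n_clusters must be at least 2")
    if k > len(_TEMPLATES):
        raise ValueError(f"at most {len(_TEMPLATES)} cluster templates available")
    t = np.linspace(0.0, 1.0, config.n_timepoints)
    raw = [fn(t) for fn in list(_TEMPLATES.values())[:k]]
    templates = []
    for shape in raw:
        z = (shape - shape.mean()) / shape.std(ddof=1)
        templates.append(z)
    templates = np.array(templates)

    min_sep = min(
        np.sqrt(np.mean((templates[i] - templates[j]) ** 2))
        for i in range(k)
        for j in range(i + 1, k)
    )
    if min_sep < 3 * config.timecourse_noise_sd:
        raise ValueError(
            f"templates separated by {min_sep:.2f} RMS z units; "
            f"need >= 3 x noise sd ({3 * config.timecourse_noise_sd:.2f})"
        )

    ids = catalog.ids
    assignment = {pid: int(rng.integers(1, k + 1)) for pid in ids}
    days = np.round(np.linspace(0, 12, config.n_timepoints)).astype(int)
    columns = [f"day_{d}" for d in days]
    amplitude = 2.0  # log2 dynamic range of differentiation-driven change
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, len(ids))
    rows = np.empty((len(ids), config.n_timepoints))
    for i, pid in enumerate(ids):
        z = templates[assignment[pid] - 1] + rng.normal(
            0.0, config.timecourse_noise_sd, config.n_timepoints
        )
        rows[i] = baseline[i] + amplitude * z
    matrix = pd.DataFrame(
        np.power(2.0, rows), index=pd.Index(ids, name="protein_id"), columns=columns
    )
    return matrix, assignment


def generate_iptm(
    truth: GroundTruth,
    sequences: Mapping[str, str],
    config: SimConfig,
) -> pd.DataFrame:
    """Mock structure-screen confidence scores for motif candidates.

    Planted-motif candidates draw ipTM from the high-mode Beta
    distribution, control candidates (proteins without a planted motif,
    screened with their C-terminal 15-mer) from the low-mode one. Values
    are guaranteed to lie in [0, 1].
    """
    rng = substream(config.seed, "iptm")
    high_a, high_b = config.iptm_high_params
    low_a, low_b = config.iptm_low_params
    rows = []
    for pid in sorted(truth.motif_ids_snx27):
        pep = sequences[pid][-15:]
        rows.append(
            {
                "candidate_id": f"{pid}|SNX27",
                "protein_id": pid,
                "motif_class": "SNX27",
                "peptide": pep,
                "iptm": float(rng.beta(high_a, high_b)),
                "planted": True,
            }
        )
    for pid in sorted(truth.snx17_positions):
        for start in truth.snx17_positions[pid]:
            pep = sequences[pid][start : start + 6]
            rows.append(
                {
                    "candidate_id": f"{pid}|SNX17|{start + 1}",
                    "protein_id": pid,
                    "motif_class": "SNX17",
                    "peptide": pep,
                    "iptm": float(rng.beta(high_a, high_b)),
                    "planted": True,
                }
            )
    unplanted = sorted(
        set(sequences) - truth.motif_ids_snx27 - truth.motif_ids_snx17
    )
    n_controls = min(config.n_iptm_controls, len(unplanted))
    controls = (
        list(map(str, rng.choice(unplanted, size=n_controls, replace=False)))
        if n_controls
        else []
    )
    for pid in controls:
        rows.append(
            {
                "candidate_id": f"{pid}|control",
                "protein_id": pid,
                "motif_class": "SNX27",
                "peptide": sequences[pid][-15:],
                "iptm": float(rng.beta(low_a, low_b)),
                "planted": False,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["candidate_id", "protein_id", "motif_class", "peptide", "iptm", "planted"],
    )


@dataclass
class SimulatedExperiment:
    """Everything one synthetic study produces, truth included."""

    config: SimConfig
    catalog: AnnotationCatalog
    sequences: dict[str, str]
    quant: QuantMatrix
    timecourse: pd.DataFrame
    iptm: pd.DataFrame
    truth: GroundTruth


def simulate_experiment(config: SimConfig) -> SimulatedExperiment:
    """Run every generator under one config and bundle the outputs."""
    catalog = generate_catalog(config)
    sequences, truth = generate_sequences(catalog, config)
    quant = generate_quant(catalog, truth, config)
    timecourse, clusters = generate_timecourse(catalog, config)
    truth.cluster_assignment = clusters
    iptm = generate_iptm(truth, sequences, config)
    return SimulatedExperiment(
        config=config,
        catalog=catalog,
        sequences=sequences,
        quant=quant,
        timecourse=timecourse,
        iptm=iptm,
        truth=truth,
    )
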