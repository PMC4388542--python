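"""Shared domain types for the iTRAQ differential raft-proteomics pipeline.

The pipeline's canonical in-memory container is a :class:`pandas.DataFrame`
(one row per PSM, protein quantification, or test result).  The dataclasses
here give a typed row-level view of the same information; converters between
the two live alongside the types.  MISSING reporter intensities are
represented as ``NaN`` — never 0, because an absent reporter peak carries no
abundance information while a zero intensity would.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "MISSING",
    "is_missing",
    "normalize_symbol",
    "PSMRecord",
    "ChannelDesign",
    "PipelineConfig",
    "FilterStats",
    "PeptideRatio",
    "ProteinQuant",
    "CombinedQuant",
    "ReferenceStats",
    "DifferentialResult",
    "GeneSet",
    "GeneSetCollection",
    "EnrichmentRow",
    "OverlapSummary",
    "psms_to_frame",
    "frame_to_psms",
    "rows_to_frame",
    "PSM_COLUMNS",
    "CHANNEL_PREFIX",
    "DEFAULT_CONTAMINANT_GENES",
    "DECOY_ACCESSION_PREFIX",
]

#: Sentinel for a missing value (absent reporter peak, undefined statistic).
MISSING = float("nan")

#: TSV column prefix for reporter-channel intensity columns (e.g. ``i113``).
CHANNEL_PREFIX = "i"

#: Accession prefix marking reversed-sequence decoy entries.
DECOY_ACCESSION_PREFIX = "REV_"

#: Keratin-family gene symbols treated as contaminants by default (mouse).
DEFAULT_CONTAMINANT_GENES = frozenset(
    {"Krt1", "Krt2", "Krt5", "Krt8", "Krt9", "Krt10", "Krt14", "Krt16", "Krt18"}
)

#: Fixed (non-channel) columns of a PSM table, in on-disk order.
PSM_COLUMNS = [
    "experiment_id",
    "peptide",
    "protein",
    "gene",
    "confidence",
    "is_decoy",
    "is_contaminant",
]


def is_missing(x) -> bool:
    """True for the MISSING sentinel (NaN) or None."""
    return x is None or (isinstance(x, float) and math.isnan(x))


def normalize_symbol(symbol: str) -> str:
    """Normalize a gene symbol to the mouse convention (Abc1 style).

    Published tables mix UniProt entry names (upper case) with mouse gene
    symbols; set operations on gene lists are only meaningful after this
    harmonization.
    """
    s = str(symbol).strip()
    if not s:
        return s
    return s[0].upper() + s[1:].lower()


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match with per-channel reporter intensities."""

    experiment_id: str
    peptide: str
    protein: str
    gene: str
    confidence: float
    intensities: Mapping[str, float]
    is_decoy: bool = False
    is_contaminant: bool = False

    def __post_init__(self):
        if not (0.0 <= self.confidence <= 100.0):
            raise ValueError(
                f"confidence must be in [0, 100], got {self.confidence!r}"
            )
        if not self.intensities:
            raise ValueError("PSMRecord needs at least one reporter channel")
        for ch, v in self.intensities.items():
            if not is_missing(v) and v < 0:
                raise ValueError(f"negative intensity {v!r} in channel {ch!r}")


@dataclass(frozen=True)
class ChannelDesign:
    """Maps reporter channels to conditions for one 2-plex experiment.

    ``numerator_condition`` / ``denominator_condition`` fix the orientation
    of every ratio downstream (KO/WT by default in this package).
    """

    experiment_id: str
    channel_to_condition: Mapping[str, str]
    numerator_condition: str
    denominator_condition: str

    def __post_init__(self):
        if self.numerator_condition == self.denominator_condition:
            raise ValueError("numerator and denominator conditions must differ")
        conditions = list(self.channel_to_condition.values())
        if len(set(conditions)) != len(conditions):
            raise ValueError(
                f"experiment {self.experiment_id}: one channel per condition required"
            )
        for cond in (self.numerator_condition, self.denominator_condition):
            if cond not in conditions:
                raise ValueError(
                    f"condition {cond!r} has no channel in experiment "
                    f"{self.experiment_id}"
                )

    def channel_for(self, condition: str) -> str:
        for ch, cond in self.channel_to_condition.items():
            if cond == condition:
                return ch
        raise KeyError(condition)

    @property
    def numerator_channel(self) -> str:
        return self.channel_for(self.numerator_condition)

    @property
    def denominator_channel(self) -> str:
        return self.channel_for(self.denominator_condition)

    def swapped(self) -> "ChannelDesign":
        """Design with numerator and denominator conditions exchanged."""
        return ChannelDesign(
            self.experiment_id,
            dict(self.channel_to_condition),
            self.denominator_condition,
            self.numerator_condition,
        )


@dataclass
class PipelineConfig:
    """Tunable thresholds and switches for a full analysis run.

    confidence_threshold
        PSM confidence cut, percent; strict inequality (a PSM passes only
        when confidence > threshold).
    alpha
        Significance level for the differential call.
    min_experiments
        A protein is "quantified" only when it carries a valid ratio in at
        least this many experiments; ``None`` means all experiments present.
    reference_gene
        Internal-reference gene symbol, or ``"AUTO"`` to pick the quantified
        protein whose mean ratio is closest to 1.
    """

    confidence_threshold: float = 95.0
    alpha: float = 0.05
    min_experiments: int | None = None
    reference_gene: str = "AUTO"
    contaminant_genes: frozenset[str] = DEFAULT_CONTAMINANT_GENES
    fdr_formula: str = "decoys_over_targets"  # or "two_decoys_over_all"
    use_welch: bool = False
    on_log_scale: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.min_experiments is not None and self.min_experiments < 1:
            raise ValueError("min_experiments must be >= 1")
        if self.fdr_formula not in ("decoys_over_targets", "two_decoys_over_all"):
            raise ValueError(f"unknown fdr_formula {self.fdr_formula!r}")


@dataclass
class FilterStats:
    """Per-experiment accounting of the identification filter."""

    experiment_id: str
    n_input: int
    n_pass_confidence: int
    n_target_matches: int
    n_decoy_matches: int
    fdr_percent: float
    n_contaminant_removed: int
    n_confidence_rejected: int
    n_passing: int


@dataclass(frozen=True)
class PeptideRatio:
    experiment_id: str
    gene: str
    peptide: str
    ratio: float  # MISSING when invalid
    invalid_reason: str = "none"  # missing_peak | zero_intensity | rejected_confidence | none

    @property
    def is_valid(self) -> bool:
        return self.invalid_reason == "none" and not is_missing(self.ratio)


@dataclass
class ProteinQuant:
    """Per-experiment protein-level ratio from peptide rollup."""

    experiment_id: str
    gene: str
    gm_ratio: float
    geometric_sd: float  # MISSING with < 2 valid peptides
    n_peptides_quantified: int
    n_peptides_identified: int


@dataclass
class CombinedQuant:
    gene: str
    per_experiment_ratios: tuple[float, ...]
    n_experiments_present: int
    mean_ratio: float
    sd_ratio: float  # MISSING with < 2 experiments


@dataclass
class ReferenceStats:
    gene: str
    mean: float
    sd: float
    n: int


@dataclass
class DifferentialResult:
    gene: str
    mean_ratio: float
    sd_ratio: float
    n: int
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    significant: bool
    direction: str  # increased | decreased | unchanged


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    namespace: str  # BP | CC | MF | other
    term_name: str
    genes: frozenset[str]


@dataclass
class GeneSetCollection:
    entries: list[GeneSet]
    population: frozenset[str]

    def __post_init__(self):
        seen = set()
        for e in self.entries:
            if e.term_id in seen:
                raise ValueError(f"duplicate term id {e.term_id!r}")
            seen.add(e.term_id)
            if not e.genes <= self.population:
                raise ValueError(
                    f"term {e.term_id!r} has genes outside the population"
                )

    def __len__(self):
        return len(self.entries)


@dataclass
class EnrichmentRow:
    term_id: str
    namespace: str
    term_name: str
    count: int
    percent: float
    p_value: float
    fold_enrichment: float
    bonferroni: float
    benjamini: float


@dataclass
class OverlapSummary:
    query_size: int
    target_list_size: int
    overlap: frozenset[str]
    overlap_count: int
    percent_of_query: float


# ---------------------------------------------------------------------------
# DataFrame <-> record conversion

def channel_columns(frame: pd.DataFrame) -> list[str]:
    """Reporter-intensity columns of a PSM frame (``i<label>``)."""
    return [c for c in frame.columns if c not in PSM_COLUMNS]


def psms_to_frame(records: Iterable[PSMRecord]) -> pd.DataFrame:
    records = list(records)
    channels: list[str] = []
    for r in records:
        for ch in r.intensities:
            if ch not in channels:
                channels.append(ch)
    rows = []
    for r in records:
        row = {
            "experiment_id": r.experiment_id,
            "peptide": r.peptide,
            "protein": r.protein,
            "gene": r.gene,
            "confidence": r.confidence,
            "is_decoy": r.is_decoy,
            "is_contaminant": r.is_contaminant,
        }
        for ch in channels:
            row[CHANNEL_PREFIX + ch] = r.intensities.get(ch, MISSING)
        rows.append(row)
    cols = PSM_COLUMNS[:5] + [CHANNEL_PREFIX + ch for ch in channels] + PSM_COLUMNS[5:]
    return pd.DataFrame(rows, columns=cols)


def frame_to_psms(frame: pd.DataFrame) -> list[PSMRecord]:
    chan_cols = channel_columns(frame)
    out = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        out.append(
            PSMRecord(
                experiment_id=str(d["experiment_id"]),
                peptide=str(d["peptide"]),
                protein=str(d["protein"]),
                gene=str(d["gene"]),
                confidence=float(d["confidence"]),
                intensities={
                    c[len(CHANNEL_PREFIX):]: float(d[c]) for c in chan_cols
                },
                is_decoy=bool(d["is_decoy"]),
                is_contaminant=bool(d["is_contaminant"]),
            )
        )
    return out


def as_psm_frame(psms) -> pd.DataFrame:
    """Accept either a PSM DataFrame or an iterable of PSMRecord."""
    if isinstance(psms, pd.DataFrame):
        return psms
    return psms_to_frame(psms)


def rows_to_frame(rows: Sequence) -> pd.DataFrame:
    """Tabulate a homogeneous list of dataclass instances."""
    if not rows:
        return pd.DataFrame()
    cols = [f.name for f in fields(rows[0])]
    return pd.DataFrame([[getattr(r, c) for c in cols] for r in rows], columns=cols)
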