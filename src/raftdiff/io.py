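"""Readers and writers for PSM tables, designs, gene sets, and results.

All tables are tab-separated text with a header row.  MISSING values are
written as ``NA`` and parsed back to ``NaN``; an empty cell is accepted on
input.  Round trips are value-identical.
"""

from __future__ import annotations

import logging
from dataclasses import fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    CHANNEL_PREFIX,
    PSM_COLUMNS,
    ChannelDesign,
    GeneSet,
    GeneSetCollection,
    PipelineConfig,
    normalize_symbol,
)

log = logging.getLogger("raftdiff")

NA_REP = "NA"

__all__ = [
    "FormatError",
    "ValidationError",
    "read_psm_table",
    "write_psm_table",
    "read_design_table",
    "write_design_table",
    "read_gene_sets",
    "read_gene_list",
    "write_results_table",
    "read_results_table",
    "read_config",
    "load_identified_proteome",
    "load_quantified_proteome",
    "load_fmrp_targets",
]


class FormatError(ValueError):
    """A file does not conform to the expected tabular dialect."""


class ValidationError(ValueError):
    """Well-formed input carrying invalid values."""


# ---------------------------------------------------------------------------
# PSM tables

def read_psm_table(path) -> pd.DataFrame:
    """Read a PSM table; reporter columns are ``i<channel>``.

    Empty or ``NA`` reporter cells become NaN (a missing peak), never 0.
    Raises :class:`FormatError` when a mandatory column is absent and
    :class:`ValidationError` on negative intensities or out-of-range
    confidences (reported with 1-based data row numbers).
    """
    frame = pd.read_csv(path, sep="\t", dtype={"experiment_id": str},
                        na_values=[NA_REP, ""], keep_default_na=False)
    missing_cols = [c for c in PSM_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise FormatError(
            f"{path}: missing mandatory column(s): {', '.join(missing_cols)}"
        )
    chan_cols = [c for c in frame.columns if c not in PSM_COLUMNS]
    if not chan_cols:
        raise FormatError(f"{path}: no reporter-channel columns (i<label>)")
    for col in chan_cols:
        frame[col] = pd.to_numeric(frame[col])
        bad = frame.index[frame[col] < 0]
        if len(bad):
            raise ValidationError(
                f"{path}: negative intensity in column {col!r}, row {bad[0] + 1}"
            )
    frame["confidence"] = pd.to_numeric(frame["confidence"])
    bad = frame.index[(frame["confidence"] < 0) | (frame["confidence"] > 100)]
    if len(bad):
        raise ValidationError(
            f"{path}: confidence outside [0, 100] at row {bad[0] + 1}"
        )
    for col in ("is_decoy", "is_contaminant"):
        frame[col] = frame[col].astype(bool)
    order = PSM_COLUMNS[:5] + chan_cols + PSM_COLUMNS[5:]
    return frame[order]


def write_psm_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, na_rep=NA_REP)


# ---------------------------------------------------------------------------
# Channel designs

DESIGN_COLUMNS = ["experiment_id", "channel", "condition", "numerator", "denominator"]


def write_design_table(designs: Iterable[ChannelDesign], path) -> None:
    rows = []
    for d in designs:
        for ch, cond in d.channel_to_condition.items():
            rows.append((d.experiment_id, ch, cond,
                         d.numerator_condition, d.denominator_condition))
    pd.DataFrame(rows, columns=DESIGN_COLUMNS).to_csv(path, sep="\t", index=False)


def read_design_table(path) -> dict[str, ChannelDesign]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in DESIGN_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing design column(s): {', '.join(missing)}")
    out: dict[str, ChannelDesign] = {}
    for exp_id, grp in frame.groupby("experiment_id", sort=False):
        out[str(exp_id)] = ChannelDesign(
            experiment_id=str(exp_id),
            channel_to_condition=dict(zip(grp["channel"], grp["condition"])),
            numerator_condition=grp["numerator"].iloc[0],
            denominator_condition=grp["denominator"].iloc[0],
        )
    return out


# ---------------------------------------------------------------------------
# Gene sets and gene lists

_NAMESPACES = {"BP", "CC", "MF"}


def read_gene_sets(path, universe: set[str] | None = None) -> GeneSetCollection:
    """Parse a GMT file (term_id <tab> description <tab> gene ...).

    Namespace is inferred from a ``BP|CC|MF`` token in the term id or
    description (e.g. ``GOTERM_CC``); anything else is ``other``.  Gene
    symbols are case-normalized.  When a universe is given, out-of-universe
    genes are dropped (count logged) and emptied terms removed.
    """
    entries: list[GeneSet] = []
    population: set[str] = set()
    n_dropped = 0
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}: line {lineno}: expected >= 3 fields")
        term_id, desc = parts[0].strip(), parts[1].strip()
        genes = {normalize_symbol(g) for g in parts[2:] if g.strip()}
        namespace = "other"
        for token in _NAMESPACES:
            if token in term_id.upper() or token in desc.upper():
                namespace = token
                break
        if universe is not None:
            universe_norm = {normalize_symbol(g) for g in universe}
            kept = genes & universe_norm
            n_dropped += len(genes) - len(kept)
            genes = kept
        if not genes:
            continue
        entries.append(GeneSet(term_id, namespace, desc, frozenset(genes)))
        population |= genes
    if n_dropped:
        log.info("read_gene_sets: dropped %d gene(s) outside the universe", n_dropped)
    if universe is not None:
        population = {normalize_symbol(g) for g in universe}
    return GeneSetCollection(entries, frozenset(population))


def read_gene_list(path) -> list[str]:
    """Flat gene list, one symbol per line, case-normalized, order kept."""
    out = []
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if s and not s.startswith("#"):
            out.append(normalize_symbol(s))
    return out


# ---------------------------------------------------------------------------
# Generic results tables

def write_results_table(rows, path) -> None:
    """Write a homogeneous collection of dataclass rows (or a DataFrame).

    p-values and other floats keep >= 6 significant digits; MISSING fields
    are written as ``NA``.  An empty collection yields a header-only file
    when the schema is known (DataFrame input).
    """
    if isinstance(rows, pd.DataFrame):
        frame = rows
    else:
        rows = list(rows)
        if not rows:
            Path(path).write_text("")
            return
        cols = [f.name for f in fields(rows[0])]
        frame = pd.DataFrame(
            [[_plain(getattr(r, c)) for c in cols] for r in rows], columns=cols
        )
    frame.to_csv(path, sep="\t", index=False, na_rep=NA_REP, float_format="%.6g")


def _plain(v):
    if isinstance(v, frozenset):
        return ",".join(sorted(v))
    if isinstance(v, tuple):
        return ",".join(f"{x:.6g}" for x in v)
    return v


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA_REP, ""], keep_default_na=False)


# ---------------------------------------------------------------------------
# Run configuration

def read_config(path) -> PipelineConfig:
    """Load a YAML key-value config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"{path}: unknown config key(s): {', '.join(sorted(unknown))}")
    if "contaminant_genes" in raw:
        raw["contaminant_genes"] = frozenset(
            normalize_symbol(g) for g in raw["contaminant_genes"]
        )
    return PipelineConfig(**raw)


# ---------------------------------------------------------------------------
# Bundled reference fixtures (published summary tables of the profiled
# mouse-brain lipid-raft proteome; data, not code)

def _data_path(name: str):
    return resources.files("raftdiff.data").joinpath(name)


def load_identified_proteome() -> pd.DataFrame:
    """133 raft proteins identified in >= 1 experiment (entry name, gene, id)."""
    with resources.as_file(_data_path("raft_proteome_identified.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_quantified_proteome() -> pd.DataFrame:
    """85 proteins quantified in all three experiments.

    Columns include the published mean KO/WT ratio, its SD over the three
    experiments, the published p-value (``p_printed``; the censored entry
    ``>0.999`` parses to 0.999 with ``p_censored`` set) and the published
    significance call.
    """
    with resources.as_file(_data_path("raft_proteome_quantified.tsv")) as p:
        frame = pd.read_csv(p, sep="\t", dtype={"p_printed": str})
    frame["p_censored"] = frame["p_printed"].str.startswith(">")
    frame["p_printed"] = frame["p_printed"].str.lstrip(">").astype(float)
    return frame


def load_fmrp_targets() -> list[str]:
    """41 raft-proteome genes whose transcripts are HITS-CLIP FMRP targets."""
    with resources.as_file(_data_path("fmrp_targets.txt")) as p:
        return read_gene_list(p)
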