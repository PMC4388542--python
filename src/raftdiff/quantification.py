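"""Reporter-ion peptide ratios and geometric protein-level rollup.

Each filtered PSM yields one peptide ratio: numerator-channel intensity over
denominator-channel intensity (KO/WT under the default design).  A ratio is
INVALID — never silently 0 or dropped — when a reporter peak is missing or
has zero intensity.  Valid peptide ratios for one protein in one experiment
are combined multiplicatively: the protein ratio is their geometric mean and
the spread the geometric SD, i.e. mean and sample SD on the natural-log
scale, exponentiated.  Proteins with a single quantified peptide keep their
ratio but carry no spread estimate.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .datamodel import (
    CHANNEL_PREFIX,
    MISSING,
    ChannelDesign,
    PSMRecord,
    PeptideRatio,
    ProteinQuant,
    as_psm_frame,
    is_missing,
)

log = logging.getLogger("raftdiff")

__all__ = ["peptide_ratio", "rollup_protein", "quantify_experiment"]


def peptide_ratio(record: PSMRecord, design: ChannelDesign) -> PeptideRatio:
    """Reporter-ion intensity ratio for one PSM under a channel design."""
    for ch in (design.numerator_channel, design.denominator_channel):
        if ch not in record.intensities:
            raise KeyError(
                f"channel {ch!r} from the design is absent from the PSM "
                f"(has {sorted(record.intensities)})"
            )
    num = record.intensities[design.numerator_channel]
    den = record.intensities[design.denominator_channel]
    if is_missing(num) or is_missing(den):
        return PeptideRatio(record.experiment_id, record.gene, record.peptide,
                            MISSING, "missing_peak")
    if num <= 0 or den <= 0:
        return PeptideRatio(record.experiment_id, record.gene, record.peptide,
                            MISSING, "zero_intensity")
    return PeptideRatio(record.experiment_id, record.gene, record.peptide,
                        num / den, "none")


def rollup_protein(ratios, method: str = "geometric") -> ProteinQuant | None:
    """Combine one protein's peptide ratios (one experiment) into a quant.

    Returns ``None`` (with a logged reason) when no valid ratio exists.
    ``method`` may be ``"geometric"`` (default) or ``"arithmetic"`` for
    sensitivity analysis; the spread is always the geometric SD.
    """
    ratios = list(ratios)
    if not ratios:
        return None
    exp_id = ratios[0].experiment_id
    gene = ratios[0].gene
    valid = np.array([r.ratio for r in ratios if r.is_valid], dtype=float)
    if valid.size == 0:
        log.info("rollup: %s/%s dropped — no valid peptide ratio", exp_id, gene)
        return None
    logs = np.log(valid)
    if method == "geometric":
        center = math.exp(logs.mean())
    elif method == "arithmetic":
        center = float(valid.mean())
    else:
        raise ValueError(f"unknown rollup method {method!r}")
    gsd = math.exp(logs.std(ddof=1)) if valid.size >= 2 else MISSING
    return ProteinQuant(
        experiment_id=exp_id,
        gene=gene,
        gm_ratio=center,
        geometric_sd=gsd,
        n_peptides_quantified=int(valid.size),
        n_peptides_identified=len(ratios),
    )


def quantify_experiment(psms, design: ChannelDesign,
                        method: str = "geometric") -> pd.DataFrame:
    """Vectorized per-protein rollup of a filtered PSM table.

    Returns one row per gene with columns matching :class:`ProteinQuant`.
    Proteins with zero valid peptide ratios are dropped (logged).
    """
    frame = as_psm_frame(psms)
    num_col = CHANNEL_PREFIX + design.numerator_channel
    den_col = CHANNEL_PREFIX + design.denominator_channel
    for col in (num_col, den_col):
        if col not in frame.columns:
            raise KeyError(f"reporter column {col!r} absent from PSM table")
    num = frame[num_col].to_numpy(dtype=float)
    den = frame[den_col].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((num > 0) & (den > 0), num / den, np.nan)

    work = pd.DataFrame({
        "experiment_id": frame["experiment_id"],
        "gene": frame["gene"],
        "ratio": ratio,
        "log_ratio": np.log(ratio),
    })
    rows = []
    for gene, grp in work.groupby("gene", sort=True):
        logs = grp["log_ratio"].dropna()
        n_id = len(grp)
        if logs.empty:
            log.info("rollup: %s/%s dropped — no valid peptide ratio",
                     grp["experiment_id"].iloc[0], gene)
            continue
        if method == "geometric":
            center = math.exp(logs.mean())
        else:
            center = float(grp["ratio"].dropna().mean())
        gsd = math.exp(logs.std(ddof=1)) if len(logs) >= 2 else MISSING
        rows.append((grp["experiment_id"].iloc[0], gene, center, gsd,
                     len(logs), n_id))
    return pd.DataFrame(rows, columns=[
        "experiment_id", "gene", "gm_ratio", "geometric_sd",
        "n_peptides_quantified", "n_peptides_identified",
    ])
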