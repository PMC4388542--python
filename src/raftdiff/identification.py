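"""PSM confidence filtering, contaminant exclusion, and decoy-based FDR.

A PSM survives only when its identification confidence strictly exceeds the
threshold (default 95%), and it is neither a reversed-sequence decoy nor a
contaminant (keratin-family by default).  Decoy matches above the threshold
estimate the false-discovery rate of the accepted target matches.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import (
    DECOY_ACCESSION_PREFIX,
    MISSING,
    FilterStats,
    PipelineConfig,
    as_psm_frame,
)
from .io import ValidationError

__all__ = ["filter_psms", "compute_fdr"]


def compute_fdr(n_decoy: int, n_target: int, formula: str = "decoys_over_targets") -> float:
    """Decoy-estimated FDR of accepted PSMs, as a percentage.

    ``decoys_over_targets`` is 100*D/T; the conservative alternative
    ``two_decoys_over_all`` is 100*2D/(T+D).  Returns 0 when no decoys
    matched and MISSING (NaN) when there are no target matches to rate.
    """
    if n_decoy < 0 or n_target < 0:
        raise ValueError("counts must be non-negative")
    if n_target == 0:
        return MISSING
    if n_decoy == 0:
        return 0.0
    if formula == "decoys_over_targets":
        return 100.0 * n_decoy / n_target
    if formula == "two_decoys_over_all":
        return 100.0 * 2 * n_decoy / (n_target + n_decoy)
    raise ValueError(f"unknown FDR formula {formula!r}")


def filter_psms(psms, config: PipelineConfig | None = None) -> tuple[pd.DataFrame, FilterStats]:
    """Apply the confidence/decoy/contaminant filter to one experiment.

    Returns the passing PSMs and a :class:`FilterStats` whose counts
    reconcile: ``n_input = n_passing + n_confidence_rejected +
    n_decoy_matches + n_contaminant_removed``.  Decoys and contaminants are
    counted among the confidence-passing records before removal, so the
    FDR refers to matches above the threshold.
    """
    config = config or PipelineConfig()
    frame = as_psm_frame(psms)
    exp_ids = frame["experiment_id"].unique()
    if len(exp_ids) > 1:
        raise ValidationError(
            f"filter_psms expects one experiment, got {sorted(map(str, exp_ids))}"
        )
    exp_id = str(exp_ids[0]) if len(exp_ids) else ""

    is_decoy = frame["is_decoy"] | frame["protein"].astype(str).str.startswith(
        DECOY_ACCESSION_PREFIX
    )
    is_contam = frame["is_contaminant"] | frame["gene"].isin(config.contaminant_genes)
    pass_conf = frame["confidence"] > config.confidence_threshold

    n_input = len(frame)
    n_pass_conf = int(pass_conf.sum())
    n_decoy = int((pass_conf & is_decoy).sum())
    n_contam = int((pass_conf & ~is_decoy & is_contam).sum())
    n_target = n_pass_conf - n_decoy
    passing = frame[pass_conf & ~is_decoy & ~is_contam].reset_index(drop=True)

    stats = FilterStats(
        experiment_id=exp_id,
        n_input=n_input,
        n_pass_confidence=n_pass_conf,
        n_target_matches=n_target,
        n_decoy_matches=n_decoy,
        fdr_percent=compute_fdr(n_decoy, n_target, config.fdr_formula),
        n_contaminant_removed=n_contam,
        n_confidence_rejected=n_input - n_pass_conf,
        n_passing=len(passing),
    )
    assert stats.n_input == (
        stats.n_passing + stats.n_confidence_rejected
        + stats.n_decoy_matches + stats.n_contaminant_removed
    )
    return passing, stats
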