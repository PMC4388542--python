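"""Synthetic 2-plex reporter-ion PSM datasets with known ground truth.

Emulates a series of 2-plex isobaric-label experiments (KO vs WT in one MS
run each) with the noise structure the downstream analysis assumes:

* two-tier lognormal noise — per experiment e and protein i the realized
  log-ratio is ln(true_ratio_i) + Normal(0, sigma_e^2) (biological,
  between-experiment), and each peptide's reporter ratio multiplies in
  exp(Normal(0, sigma_p^2)) (technical, within-experiment);
* denominator (WT) reporter intensities are lognormal on an arbitrary
  intensity scale; the numerator is the denominator times the realized
  ratio times the peptide noise factor;
* each reporter peak is independently missing with ``missing_peak_prob``
  (an absent peak, not a zero intensity);
* a fraction of PSMs carries sub-threshold identification confidence;
* reversed-sequence decoy records (``REV_`` accessions) and keratin-like
  contaminant records are appended with no effect on the truth.

Defaults mirror the emulated study: three experiments (pooled animals per
genotype, treated as exchangeable replicates), true fold changes of order
0.66-1.55 for perturbed proteins, sigma_p = 0.2 and sigma_e = 0.1 so that
cross-experiment SDs land in the observed ~0.02-0.6 range.

Everything is deterministic given ``SimParams.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import CHANNEL_PREFIX, ChannelDesign, PSM_COLUMNS

__all__ = ["SimParams", "SimTruth", "generate_dataset", "make_null_battery"]

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_KERATINS = ["Krt1", "Krt2", "Krt9", "Krt10", "Krt14"]

#: Reporter-channel pairs used in alternation across the experiment series
#: (low tag = WT, high tag = KO by default; configurable via the design).
_CHANNEL_PAIRS = [("113", "114"), ("117", "118")]


@dataclass
class SimParams:
    """Parameters of the synthetic experiment series.

    ``true_ratio_map`` assigns KO/WT fold changes to gene symbols
    (``G0001`` ...); unlisted genes are null (ratio 1.0).  SDs are on the
    natural-log scale.
    """

    n_proteins: int = 100
    n_experiments: int = 3
    peptides_per_protein: tuple[int, int] = (2, 8)
    true_ratio_map: dict[str, float] = field(default_factory=dict)
    peptide_noise_sd: float = 0.2
    experiment_noise_sd: float = 0.1
    base_log_intensity_mean: float = 9.0
    base_log_intensity_sd: float = 1.0
    missing_peak_prob: float = 0.05
    subthreshold_prob: float = 0.10
    confidence_threshold: float = 95.0
    decoy_frac: float = 0.05
    contaminant_frac: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.n_experiments < 1:
            raise ValueError("n_experiments must be >= 1")
        lo, hi = self.peptides_per_protein
        if not (1 <= lo <= hi):
            raise ValueError("peptides_per_protein must be a range >= 1")
        for name in ("peptide_noise_sd", "experiment_noise_sd",
                     "base_log_intensity_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("missing_peak_prob", "subthreshold_prob",
                     "decoy_frac", "contaminant_frac"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        for g, r in self.true_ratio_map.items():
            if r <= 0:
                raise ValueError(f"true ratio for {g} must be > 0, got {r}")

    @property
    def genes(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_proteins + 1)]


@dataclass
class SimTruth:
    """Ground truth recorded during generation.

    per_gene
        One row per simulated gene: true ratio and record-class flags.
    realized
        One row per gene x experiment: the realized (biological) ratio the
        experiment measured around, and the peptide count emitted.
    """

    per_gene: pd.DataFrame
    realized: pd.DataFrame

    def true_ratio(self, gene: str) -> float:
        sel = self.per_gene.loc[self.per_gene["gene"] == gene, "true_ratio"]
        return float(sel.iloc[0])


def _design_for(exp_index: int, exp_id: str) -> ChannelDesign:
    wt, ko = _CHANNEL_PAIRS[exp_index % len(_CHANNEL_PAIRS)]
    return ChannelDesign(
        experiment_id=exp_id,
        channel_to_condition={ko: "KO", wt: "WT"},
        numerator_condition="KO",
        denominator_condition="WT",
    )


def _peptide_pool(rng: np.random.Generator, n_proteins: int, max_pep: int):
    lengths = rng.integers(8, 15, size=(n_proteins, max_pep))
    pool = []
    for i in range(n_proteins):
        pool.append([
            "".join(rng.choice(_AMINO_ACIDS, size=lengths[i, j]))
            for j in range(max_pep)
        ])
    return pool


def _confidence(rng, n, threshold, subthreshold_prob):
    sub = rng.random(n) < subthreshold_prob
    high = threshold + (100.0 - threshold) * rng.random(n)
    low = 50.0 + (threshold - 50.0) * rng.random(n)
    return np.where(sub, low, high)


def generate_dataset(params: SimParams):
    """Simulate the experiment series.

    Returns ``(psms_by_experiment, truth, designs_by_experiment)`` where the
    PSM tables are DataFrames in the on-disk PSM schema (reporter columns
    ``i<channel>``) and ``designs_by_experiment`` maps experiment id to its
    :class:`~raftdiff.datamodel.ChannelDesign`.
    """
    genes = params.genes
    true_ratios = np.array([params.true_ratio_map.get(g, 1.0) for g in genes])
    lo, hi = params.peptides_per_protein

    seqs = np.random.SeedSequence(params.seed).spawn(params.n_experiments + 1)
    pool_rng = np.random.default_rng(seqs[0])
    pool = _peptide_pool(pool_rng, params.n_proteins, hi)

    psms: dict[str, pd.DataFrame] = {}
    designs: dict[str, ChannelDesign] = {}
    realized_rows = []

    for e in range(params.n_experiments):
        exp_id = f"exp{e + 1}"
        design = _design_for(e, exp_id)
        designs[exp_id] = design
        rng = np.random.default_rng(seqs[e + 1])

        exp_noise = rng.normal(0.0, 1.0, size=params.n_proteins) * params.experiment_noise_sd
        realized = true_ratios * np.exp(exp_noise)
        n_pep = rng.integers(lo, hi + 1, size=params.n_proteins)

        prot_idx = np.repeat(np.arange(params.n_proteins), n_pep)
        n_psm = prot_idx.size
        den = np.exp(params.base_log_intensity_mean
                     + params.base_log_intensity_sd * rng.normal(0.0, 1.0, n_psm))
        pep_noise = rng.normal(0.0, 1.0, n_psm) * params.peptide_noise_sd
        num = den * realized[prot_idx] * np.exp(pep_noise)

        conf = _confidence(rng, n_psm, params.confidence_threshold,
                           params.subthreshold_prob)
        miss_num = rng.random(n_psm) < params.missing_peak_prob
        miss_den = rng.random(n_psm) < params.missing_peak_prob
        num = np.where(miss_num, np.nan, num)
        den = np.where(miss_den, np.nan, den)

        pep_counter = np.concatenate([np.arange(k) for k in n_pep]) if n_psm else np.array([], int)
        frame = pd.DataFrame({
            "experiment_id": exp_id,
            "peptide": [pool[i][j] for i, j in zip(prot_idx, pep_counter)],
            "protein": [f"P{i + 1:04d}" for i in prot_idx],
            "gene": [genes[i] for i in prot_idx],
            "confidence": np.round(conf, 2),
            "is_decoy": False,
            "is_contaminant": False,
        })
        num_col = CHANNEL_PREFIX + design.numerator_channel
        den_col = CHANNEL_PREFIX + design.denominator_channel
        frame[num_col] = num
        frame[den_col] = den

        extra = []
        n_decoy = int(round(params.decoy_frac * n_psm))
        n_contam = int(round(params.contaminant_frac * n_psm))
        for d in range(n_decoy):
            src = int(rng.integers(0, params.n_proteins))
            pep = pool[src][int(rng.integers(0, hi))][::-1]
            inten = np.exp(params.base_log_intensity_mean
                           + params.base_log_intensity_sd * rng.normal(0.0, 1.0, 2))
            extra.append({
                "experiment_id": exp_id, "peptide": pep,
                "protein": f"REV_P{src + 1:04d}", "gene": f"Rev{src + 1:04d}",
                "confidence": round(50.0 + 50.0 * rng.random(), 2),
                "is_decoy": True, "is_contaminant": False,
                num_col: inten[0], den_col: inten[1],
            })
        for c in range(n_contam):
            sym = _KERATINS[c % len(_KERATINS)]
            inten = np.exp(params.base_log_intensity_mean
                           + params.base_log_intensity_sd * rng.normal(0.0, 1.0, 2))
            extra.append({
                "experiment_id": exp_id,
                "peptide": "".join(rng.choice(_AMINO_ACIDS, size=10)),
                "protein": f"CON_{sym.upper()}", "gene": sym,
                "confidence": round(50.0 + 50.0 * rng.random(), 2),
                "is_decoy": False, "is_contaminant": True,
                num_col: inten[0], den_col: inten[1],
            })
        if extra:
            frame = pd.concat([frame, pd.DataFrame(extra)], ignore_index=True)
        cols = PSM_COLUMNS[:5] + [num_col, den_col] + PSM_COLUMNS[5:]
        psms[exp_id] = frame[cols]

        realized_rows.extend(
            (g, exp_id, realized[i], int(n_pep[i])) for i, g in enumerate(genes)
        )

    truth = SimTruth(
        per_gene=pd.DataFrame({
            "gene": genes,
            "true_ratio": true_ratios,
            "is_decoy": False,
            "is_contaminant": False,
        }),
        realized=pd.DataFrame(realized_rows, columns=[
            "gene", "experiment_id", "realized_ratio", "n_peptides",
        ]),
    )
    return psms, truth, designs


def make_null_battery(n_proteins: int, n_reps: int, params: SimParams | None = None):
    """Independent all-null datasets (every true ratio 1) for calibration.

    Yields ``(seed, dataset)`` tuples; replicate r uses ``params.seed + r``
    so the battery is reproducible and its members independent.
    """
    base = params or SimParams()
    if base.true_ratio_map and any(v != 1.0 for v in base.true_ratio_map.values()):
        raise ValueError("null battery requires all true ratios = 1.0")
    for r in range(n_reps):
        p = replace(base, n_proteins=n_proteins, true_ratio_map={},
                    seed=base.seed + r)
        yield p.seed, generate_dataset(p)
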