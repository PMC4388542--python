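"""Cross-experiment combination and reference-anchored differential testing.

The design this implements: each 2-plex experiment yields one KO/WT ratio
per protein (geometric mean over peptides).  Ratios are combined across the
experiment series by arithmetic mean and sample SD, restricted to proteins
quantified in at least ``min_experiments`` experiments.  Differential raft
association is then called per protein with a two-sample pooled-variance
Student t-test against an internal reference protein whose ratio is ~1 in
all experiments — a ratio of 1 means no change, >1 increased and <1
decreased association in the knockout.

The test is deliberately run on raw ratios with the pooled-variance form
(df = n1 + n2 - 2): with three experiments per side this is the df = 4 test
that reproduces the published per-protein p-values from their printed
summary statistics.  Welch and log-scale variants are available as options;
the log-scale form is statistically preferable (ratios are closer to
lognormal, and it makes the test exactly invariant to swapping the KO/WT
labels) but is not the default because the published analysis is the
raw-ratio test.

The module exposes both a statsmodels-style model/results pair
(:class:`DifferentialAbundanceModel` / :class:`DifferentialAbundanceResults`)
and the underlying functions (:func:`combine_experiments`,
:func:`select_reference`, :func:`reference_ttest`, :func:`call_candidates`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import (
    MISSING,
    CombinedQuant,
    DifferentialResult,
    PipelineConfig,
    ReferenceStats,
    is_missing,
    normalize_symbol,
)

__all__ = [
    "ConfigurationError",
    "InsufficientReplicationError",
    "combine_experiments",
    "select_reference",
    "reference_ttest",
    "ttest_from_ratios",
    "call_candidates",
    "DifferentialAbundanceModel",
    "DifferentialAbundanceResults",
]

AUTO = "AUTO"


class ConfigurationError(ValueError):
    pass


class InsufficientReplicationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Combination across experiments

def combine_experiments(protein_quants: pd.DataFrame,
                        min_experiments: int | None = None
                        ) -> tuple[pd.DataFrame, set[str]]:
    """Combine per-experiment protein quants into cross-experiment summaries.

    ``protein_quants`` stacks the per-experiment rollup tables (columns
    ``experiment_id``, ``gene``, ``gm_ratio``, ...).  Returns

    * a frame with one row per quantified gene — present with a valid ratio
      in at least ``min_experiments`` experiments (default: all experiments
      in the input) — carrying the ordered per-experiment ratios, their
      arithmetic mean and sample SD;
    * the set of genes identified in at least one experiment.
    """
    if protein_quants.empty:
        return (
            pd.DataFrame(columns=["gene", "per_experiment_ratios",
                                  "n_experiments_present", "mean_ratio", "sd_ratio"]),
            set(),
        )
    experiments = sorted(protein_quants["experiment_id"].astype(str).unique())
    if min_experiments is None:
        min_experiments = len(experiments)
    identified_any = set(protein_quants["gene"].astype(str))

    rows = []
    for gene, grp in protein_quants.groupby("gene", sort=True):
        by_exp = grp.set_index(grp["experiment_id"].astype(str))["gm_ratio"]
        ratios = [by_exp.get(e, np.nan) for e in experiments]
        present = [r for r in ratios if not is_missing(r)]
        if len(present) < min_experiments:
            continue
        arr = np.asarray(present, dtype=float)
        rows.append((
            str(gene), tuple(present), len(present),
            float(arr.mean()),
            float(arr.std(ddof=1)) if arr.size >= 2 else MISSING,
        ))
    combined = pd.DataFrame(rows, columns=[
        "gene", "per_experiment_ratios", "n_experiments_present",
        "mean_ratio", "sd_ratio",
    ])
    return combined, identified_any


def select_reference(combined: pd.DataFrame,
                     reference_gene: str = AUTO) -> ReferenceStats:
    """Pick the internal reference protein and return its summary stats.

    A named gene must be in the quantified set.  Under AUTO the quantified
    protein with mean ratio closest to 1 wins, ties broken by smallest SD,
    then lexicographic gene symbol.
    """
    if combined.empty:
        raise ConfigurationError("no quantified proteins to pick a reference from")
    if reference_gene != AUTO:
        sel = combined[combined["gene"] == normalize_symbol(reference_gene)]
        if sel.empty:
            raise ConfigurationError(
                f"reference gene {reference_gene!r} is not in the quantified set"
            )
        row = sel.iloc[0]
    else:
        key = combined.assign(
            _dist=(combined["mean_ratio"] - 1.0).abs(),
            _sd=combined["sd_ratio"].fillna(np.inf),
        ).sort_values(["_dist", "_sd", "gene"], kind="mergesort")
        row = key.iloc[0]
    return ReferenceStats(
        gene=row["gene"], mean=float(row["mean_ratio"]),
        sd=float(row["sd_ratio"]), n=int(row["n_experiments_present"]),
    )


# ---------------------------------------------------------------------------
# The reference-anchored t-test

def _two_sample_t(mean1, sd1, n1, mean2, sd2, n2, welch=False):
    """Signed t statistic (sample 1 minus sample 2), df, and two-tailed p."""
    if n1 < 2 or n2 < 2:
        raise InsufficientReplicationError(
            f"need n >= 2 on both sides, got {n1} and {n2}"
        )
    if is_missing(sd1) or is_missing(sd2) or sd1 < 0 or sd2 < 0:
        raise InsufficientReplicationError("both sides need a defined SD >= 0")
    v1, v2 = sd1 * sd1, sd2 * sd2
    if welch:
        se2 = v1 / n1 + v2 / n2
        if se2 == 0:
            return (0.0, n1 + n2 - 2, 1.0) if mean1 == mean2 else (math.inf, n1 + n2 - 2, 0.0)
        df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        se = math.sqrt(se2)
    else:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        if sp2 == 0:
            return (0.0, df, 1.0) if mean1 == mean2 else (math.inf, df, 0.0)
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (mean1 - mean2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


def _direction(mean_ratio: float) -> str:
    if mean_ratio > 1.0:
        return "increased"
    if mean_ratio < 1.0:
        return "decreased"
    return "unchanged"


def reference_ttest(gene: str, mean: float, sd: float, n: int,
                    reference: ReferenceStats, alpha: float = 0.05,
                    welch: bool = False) -> DifferentialResult:
    """Test one protein's combined ratio against the internal reference.

    Summary-statistic entry point; :func:`ttest_from_ratios` is the
    equivalent raw-vector path and produces identical results.
    """
    t, df, p = _two_sample_t(mean, sd, n, reference.mean, reference.sd,
                             reference.n, welch=welch)
    return DifferentialResult(
        gene=gene, mean_ratio=mean, sd_ratio=sd, n=n,
        t_statistic=t, degrees_of_freedom=df, p_value=p,
        significant=bool(p < alpha), direction=_direction(mean),
    )


def ttest_from_ratios(gene: str, ratios, reference_ratios,
                      reference_gene: str = "", alpha: float = 0.05,
                      welch: bool = False) -> DifferentialResult:
    """Raw per-experiment ratio-vector entry point for the same test."""
    x = np.asarray(list(ratios), dtype=float)
    ref = np.asarray(list(reference_ratios), dtype=float)
    reference = ReferenceStats(reference_gene, float(ref.mean()),
                               float(ref.std(ddof=1)), ref.size)
    return reference_ttest(gene, float(x.mean()), float(x.std(ddof=1)),
                           x.size, reference, alpha=alpha, welch=welch)


def call_candidates(results, alpha: float = 0.05):
    """Partition differential results into the significant set and counts."""
    results = list(results)
    sig = [r for r in results if r.p_value < alpha]
    n_quant = len(results)
    counts = {
        "n_quantified": n_quant,
        "n_significant": len(sig),
        "percent_significant": 100.0 * len(sig) / n_quant if n_quant else 0.0,
        "n_increased": sum(r.direction == "increased" for r in sig),
        "n_decreased": sum(r.direction == "decreased" for r in sig),
    }
    return {r.gene for r in sig}, counts


# ---------------------------------------------------------------------------
# Model / results surface

class DifferentialAbundanceModel:
    """Reference-anchored differential abundance model for ratio data.

    Parameters
    ----------
    data
        One row per protein.  Either per-experiment ratio columns (built via
        :meth:`from_ratios`) or summary-statistic columns ``mean_ratio``,
        ``sd_ratio``, ``n`` (built via :meth:`from_summary`).
    reference
        Gene symbol of the internal reference, or ``"AUTO"``; may also be a
        :class:`ReferenceStats` with externally supplied statistics.
    alpha
        Two-sided significance level for the per-protein call (no
        multiple-testing correction is applied to the call itself; a
        BH-adjusted column is emitted for reference).
    welch, on_log_scale
        Variance model options; defaults reproduce the published analysis.

    Examples
    --------
    >>> model = DifferentialAbundanceModel.from_summary(summaries,
    ...                                                 reference="Hspa8")
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(self, data: pd.DataFrame, *, reference="AUTO",
                 alpha: float = 0.05, welch: bool = False,
                 on_log_scale: bool = False, has_vectors: bool = False):
        if not (0 < alpha < 1):
            raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
        if on_log_scale and not has_vectors:
            raise ConfigurationError(
                "log-scale testing needs per-experiment ratio vectors"
            )
        self.data = data.reset_index(drop=True)
        self.reference = reference
        self.alpha = alpha
        self.welch = welch
        self.on_log_scale = on_log_scale
        self._has_vectors = has_vectors

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_ratios(cls, combined: pd.DataFrame, **kwargs):
        """Build from a combined table carrying ``per_experiment_ratios``."""
        return cls(combined, has_vectors=True, **kwargs)

    @classmethod
    def from_summary(cls, summaries: pd.DataFrame, n: int | None = None, **kwargs):
        """Build from per-protein summary statistics.

        ``summaries`` needs columns ``gene``, ``mean_ratio``, ``sd_ratio``
        and either an ``n`` column or the ``n`` argument.
        """
        frame = summaries.copy()
        if "n" not in frame.columns:
            if n is None:
                raise ConfigurationError("summary input needs per-row n or n=")
            frame["n"] = n
        return cls(frame, has_vectors=False, **kwargs)

    # -- fitting ----------------------------------------------------------

    def _summaries(self) -> pd.DataFrame:
        frame = self.data
        if self._has_vectors:
            mats = [np.asarray(v, dtype=float) for v in frame["per_experiment_ratios"]]
            if self.on_log_scale:
                mats = [np.log(v) for v in mats]
            return pd.DataFrame({
                "gene": frame["gene"],
                "mean_ratio": [float(v.mean()) for v in mats],
                "sd_ratio": [float(v.std(ddof=1)) if v.size >= 2 else MISSING
                             for v in mats],
                "n": [v.size for v in mats],
            })
        return frame[["gene", "mean_ratio", "sd_ratio", "n"]].copy()

    def _resolve_reference(self, summaries: pd.DataFrame) -> ReferenceStats:
        if isinstance(self.reference, ReferenceStats):
            return self.reference
        pick = summaries.rename(columns={"n": "n_experiments_present"})
        if self.on_log_scale:
            # selection rule operates on the ratio scale (closest to 1 <=> log 0)
            pick = pick.assign(mean_ratio=np.exp(pick["mean_ratio"]))
        return select_reference(pick, self.reference)

    def fit(self) -> "DifferentialAbundanceResults":
        summaries = self._summaries()
        # the test needs a spread estimate on both sides
        summaries = summaries[summaries["n"] >= 2].reset_index(drop=True)
        if summaries.empty:
            raise InsufficientReplicationError(
                "no protein has >= 2 replicate ratios to test"
            )
        ref = self._resolve_reference(summaries)
        if self.on_log_scale and not isinstance(self.reference, ReferenceStats):
            row = summaries[summaries["gene"] == ref.gene].iloc[0]
            ref = ReferenceStats(ref.gene, float(row["mean_ratio"]),
                                 float(row["sd_ratio"]), int(row["n"]))
        null_center = 0.0 if self.on_log_scale else 1.0
        rows = []
        for r in summaries.itertuples(index=False):
            t, df, p = _two_sample_t(r.mean_ratio, r.sd_ratio, r.n,
                                     ref.mean, ref.sd, ref.n, welch=self.welch)
            display_mean = math.exp(r.mean_ratio) if self.on_log_scale else r.mean_ratio
            rows.append((r.gene, display_mean, r.sd_ratio, r.n, t, df, p,
                         _direction(display_mean if not self.on_log_scale
                                    else math.exp(r.mean_ratio))))
        table = pd.DataFrame(rows, columns=[
            "gene", "mean_ratio", "sd_ratio", "n", "t_statistic",
            "degrees_of_freedom", "p_value", "direction",
        ])
        table["significant"] = table["p_value"] < self.alpha
        table["p_bh"] = multipletests(table["p_value"], method="fdr_bh")[1]
        return DifferentialAbundanceResults(self, table, ref)


class DifferentialAbundanceResults:
    """Fitted per-protein differential abundance results.

    Attributes
    ----------
    table : pandas.DataFrame
        One row per protein: mean ratio, SD, n, t, df, p, BH-adjusted p,
        significance call at the model's alpha, and direction.
    reference : ReferenceStats
        The internal reference the proteins were tested against.
    """

    def __init__(self, model: DifferentialAbundanceModel,
                 table: pd.DataFrame, reference: ReferenceStats):
        self.model = model
        self.table = table
        self.reference = reference

    @property
    def significant_genes(self) -> set[str]:
        return set(self.table.loc[self.table["significant"], "gene"])

    @property
    def counts(self) -> dict:
        results = self.to_results()
        return call_candidates(results, self.model.alpha)[1]

    def to_results(self) -> list[DifferentialResult]:
        return [
            DifferentialResult(
                gene=r.gene, mean_ratio=r.mean_ratio, sd_ratio=r.sd_ratio,
                n=int(r.n), t_statistic=r.t_statistic,
                degrees_of_freedom=r.degrees_of_freedom, p_value=r.p_value,
                significant=bool(r.significant), direction=r.direction,
            )
            for r in self.table.itertuples(index=False)
        ]

    def summary(self) -> str:
        c = self.counts
        ref = self.reference
        lines = [
            "Reference-anchored differential abundance (two-sample "
            + ("Welch" if self.model.welch else "pooled-variance Student")
            + " t-test)",
            f"Scale: {'log-ratio' if self.model.on_log_scale else 'raw ratio'}"
            f"    alpha: {self.model.alpha:g}",
            f"Internal reference: {ref.gene} "
            f"(mean {ref.mean:.2f} +/- {ref.sd:.3f}, n={ref.n})",
            f"Proteins tested: {c['n_quantified']}   significant: "
            f"{c['n_significant']} ({c['percent_significant']:.1f}%)   "
            f"increased: {c['n_increased']}   decreased: {c['n_decreased']}",
            "-" * 78,
            f"{'gene':<12}{'mean':>8}{'sd':>8}{'n':>4}{'t':>9}{'df':>6}"
            f"{'p':>10}{'p_BH':>10}  call",
        ]
        for r in self.table.sort_values("p_value").itertuples(index=False):
            call = r.direction if r.significant else "ns"
            lines.append(
                f"{r.gene:<12}{r.mean_ratio:>8.3f}{r.sd_ratio:>8.3f}"
                f"{int(r.n):>4}{r.t_statistic:>9.3f}"
                f"{r.degrees_of_freedom:>6.1f}{r.p_value:>10.4f}"
                f"{r.p_bh:>10.4f}  {call}"
            )
        return "\n".join(lines)

    def __repr__(self):
        c = self.counts
        return (f"<DifferentialAbundanceResults: {c['n_quantified']} proteins, "
                f"{c['n_significant']} significant at alpha="
                f"{self.model.alpha:g}>")
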