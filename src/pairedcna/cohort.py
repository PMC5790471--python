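"""Cohort aggregation and group comparison of paired discordance metrics.

Per-pair results (windowed discordance fractions, genome-altered and LOH
fractions, WGD calls) are assembled into one table with a row per
patient, and metrics are compared between groups (treatment-naive vs
post-therapy metastases; synchronous vs metachronous disease) with
two-tailed two-sample t-tests on the raw fractions.  The default test is
the pooled-variance Student's test; Welch's correction is available
behind a flag.  Raw p-values are reported (no multiple-testing
correction), significant at p < 0.05.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .discordance import PairDiscordanceResult
from .profiles_io import PairRecord, ValidationError
from .wgd import WGDCall

__all__ = [
    "ALPHA",
    "CohortTable",
    "GroupComparison",
    "compare_groups",
    "cohort_means",
    "default_comparisons",
    "summarize_cohort",
]

ALPHA = 0.05

COHORT_COLUMNS = [
    "patient_id",
    "timing",
    "met_exposure",
    "n_windows_compared",
    "cn_discordant_fraction",
    "loh_unchanged_fraction",
    "loh_met_only_fraction",
    "loh_primary_only_fraction",
    "loh_difference_fraction",
    "altered_fraction_primary",
    "altered_fraction_met",
    "loh_fraction_primary",
    "loh_fraction_met",
    "wgd_primary",
    "wgd_met",
]

CohortTable = pd.DataFrame  # one row per pair, COHORT_COLUMNS

#: metrics compared between groups by default
DEFAULT_METRICS = (
    "cn_discordant_fraction",
    "loh_met_only_fraction",
    "loh_primary_only_fraction",
)


def summarize_cohort(
    pairs: Sequence[PairRecord],
    discordance_results: Mapping[str, PairDiscordanceResult],
    wgd_calls: Mapping[str, WGDCall],
    fractions: Mapping[str, tuple[float, float]],
) -> CohortTable:
    """Assemble the per-pair cohort table.

    Parameters
    ----------
    pairs
        The sample sheet records; one output row each.
    discordance_results
        patient_id -> paired discordance result.
    wgd_calls
        sample_id -> WGD call (both samples of every pair).
    fractions
        sample_id -> (altered_fraction, loh_fraction) from
        :func:`pairedcna.discordance.genome_fractions`.

    Raises
    ------
    ValidationError
        Naming the patient or sample whose inputs are missing, or if
        ``pairs`` is empty.
    """
    if not pairs:
        raise ValidationError("empty pair list")
    rows = []
    for p in pairs:
        if p.patient_id not in discordance_results:
            raise ValidationError(f"patient {p.patient_id!r}: missing discordance result")
        for s in (p.primary_sample, p.met_sample):
            if s not in wgd_calls:
                raise ValidationError(f"patient {p.patient_id!r}: missing WGD call for {s!r}")
            if s not in fractions:
                raise ValidationError(
                    f"patient {p.patient_id!r}: missing genome fractions for {s!r}"
                )
        d = discordance_results[p.patient_id]
        alt_p, loh_p = fractions[p.primary_sample]
        alt_m, loh_m = fractions[p.met_sample]
        rows.append(
            (
                p.patient_id,
                p.timing,
                p.met_exposure,
                d.n_windows_compared,
                d.cn_discordant_fraction,
                d.loh_unchanged_fraction,
                d.loh_met_only_fraction,
                d.loh_primary_only_fraction,
                d.loh_met_only_fraction + d.loh_primary_only_fraction,
                alt_p,
                alt_m,
                loh_p,
                loh_m,
                wgd_calls[p.primary_sample].is_wgd,
                wgd_calls[p.met_sample].is_wgd,
            )
        )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def cohort_means(table: CohortTable) -> pd.DataFrame:
    """Mean, min and max of each cohort metric (one row per metric)."""
    metrics = [
        c
        for c in COHORT_COLUMNS
        if c.endswith("fraction") or c.endswith("_primary") or c.endswith("_met")
    ]
    numeric = table[[m for m in metrics if table[m].dtype != bool]]
    out = pd.DataFrame(
        {"mean": numeric.mean(), "min": numeric.min(), "max": numeric.max()}
    )
    out.index.name = "metric"
    return out.reset_index()


@dataclasses.dataclass(frozen=True)
class GroupComparison:
    """Two-group t-test result for one cohort metric."""

    metric: str
    grouping: str
    group_labels: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    t_statistic: float
    p_value: float
    welch: bool

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def compare_groups(
    table: CohortTable,
    metric: str,
    grouping: str,
    welch: bool = False,
) -> GroupComparison:
    """Two-tailed two-sample t-test of a metric between two groups.

    Parameters
    ----------
    table
        Cohort table from :func:`summarize_cohort`.
    metric
        Column to compare (e.g. ``cn_discordant_fraction``).
    grouping
        Grouping column: ``met_exposure`` or ``timing``.
    welch
        Use Welch's unequal-variance test instead of the pooled-variance
        Student's test.

    Notes
    -----
    Group labels are ordered alphabetically; the t statistic is
    group[0] minus group[1].  Swapping the labels flips the sign of t
    and leaves p unchanged.
    """
    if grouping not in ("met_exposure", "timing"):
        raise ValidationError(f"grouping must be met_exposure or timing, got {grouping!r}")
    if metric not in table.columns:
        raise ValidationError(f"unknown metric {metric!r}")
    levels = sorted(table[grouping].unique())
    if len(levels) != 2:
        raise ValidationError(
            f"grouping {grouping!r} must have exactly 2 levels, got {levels}"
        )
    a = table.loc[table[grouping] == levels[0], metric].to_numpy(dtype=float)
    b = table.loc[table[grouping] == levels[1], metric].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError(
            f"each group needs n >= 2 (got {len(a)} {levels[0]!r}, {len(b)} {levels[1]!r})"
        )
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(
        metric=metric,
        grouping=grouping,
        group_labels=(levels[0], levels[1]),
        n=(len(a), len(b)),
        means=(float(a.mean()), float(b.mean())),
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        welch=welch,
    )


def default_comparisons(table: CohortTable, welch: bool = False) -> pd.DataFrame:
    """Run the standard metric x grouping comparisons into one table."""
    rows = []
    for grouping in ("met_exposure", "timing"):
        if table[grouping].nunique() != 2:
            continue
        if (table.groupby(grouping).size() < 2).any():
            continue
        for metric in DEFAULT_METRICS:
            c = compare_groups(table, metric, grouping, welch=welch)
            rows.append(
                (
                    c.metric,
                    c.grouping,
                    c.group_labels[0],
                    c.group_labels[1],
                    c.n[0],
                    c.n[1],
                    c.means[0],
                    c.means[1],
                    c.t_statistic,
                    c.p_value,
                    c.significant,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "metric",
            "grouping",
            "group_a",
            "group_b",
            "n_a",
            "n_b",
            "mean_a",
            "mean_b",
            "t_statistic",
            "p_value",
            "significant",
        ],
    )


def plot_cohort(table: CohortTable, path) -> None:
    """Bar-chart panels of per-pair discordance and LOH-class fractions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(10, 6), sharex=True)
    x = np.arange(len(table))
    axes[0].bar(x, table["cn_discordant_fraction"], color="seagreen")
    axes[0].set_ylabel("CN discordant fraction")
    axes[1].bar(x, table["loh_met_only_fraction"], color="navy", label="LOH in met only")
    axes[1].bar(
        x,
        table["loh_primary_only_fraction"],
        bottom=table["loh_met_only_fraction"],
        color="skyblue",
        label="LOH in primary only",
    )
    axes[1].set_ylabel("LOH class fraction")
    axes[1].set_xticks(x, table["patient_id"], rotation=90)
    axes[1].legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
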