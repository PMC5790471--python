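"""Gene-level copy-number/LOH status and metastasis-private event counts.

A gene's status in a sample is the state of the segment with the largest
overlap of the gene footprint (TSS to the last base of the longest
transcript) — the same largest-overlap rule used for windows.  Across a
paired cohort, an amplification (or loss) is "private to the metastasis"
for a gene when the metastasis carries the event and the paired primary
carries no event of that class; counts are tabulated per gene over the
evaluable pairs.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .profiles_io import (
    CNCategory,
    GeneModel,
    PairRecord,
    SegmentedProfile,
    ValidationError,
    classify_state,
    is_loh,
)

__all__ = [
    "GeneStatusTable",
    "PrivateEventSummary",
    "concordance_rate",
    "gene_status",
    "private_events",
]

logger = logging.getLogger(__name__)

# category sets defining an "event" for Table-style tabulation
AMP_BROAD = frozenset({CNCategory.GAIN, CNCategory.AMP})
AMP_STRICT = frozenset({CNCategory.AMP})
LOSS_BROAD = frozenset({CNCategory.LOSS, CNCategory.HOMDEL})
LOSS_STRICT = frozenset({CNCategory.HOMDEL})

#: columns of a gene status table
GENE_STATUS_COLUMNS = [
    "sample_id",
    "symbol",
    "chromosome",
    "gene_start",
    "gene_end",
    "total_cn",
    "minor_cn",
    "loh",
    "category",
    "seg_start",
    "seg_end",
]

GeneStatusTable = pd.DataFrame  # alias; one row per (sample, gene)


def gene_status(profile: SegmentedProfile, genes: Sequence[GeneModel]) -> GeneStatusTable:
    """Call per-gene copy-number status for one sample.

    Returns a DataFrame with one row per gene (``GENE_STATUS_COLUMNS``).
    Genes with no overlapping segment have nullable-NA copy numbers and
    category ``None``.  Overlap ties are broken toward the segment with
    the smaller start.
    """
    symbols = [g.symbol for g in genes]
    if len(set(symbols)) != len(symbols):
        raise ValidationError("duplicate gene symbols in annotation")
    for g in genes:
        if g.chromosome not in profile.layout:
            raise ValidationError(
                f"gene {g.symbol} on {g.chromosome!r} absent from profile layout"
            )

    trees: dict[str, IntervalTree] = {}
    for chrom, sub in profile.data.groupby("chromosome", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            (row.start, row.end, (row.total_cn, row.minor_cn))
            for row in sub.itertuples(index=False)
        )

    rows = []
    for g in genes:
        hit = None  # (overlap, seg_start, seg_end, total, minor)
        for iv in trees.get(g.chromosome, IntervalTree()).overlap(g.start, g.end):
            ov = min(iv.end, g.end) - max(iv.begin, g.start)
            cand = (ov, -iv.begin)
            if hit is None or cand > (hit[0], -hit[1]):
                hit = (ov, iv.begin, iv.end, *iv.data)
        if hit is None:
            rows.append(
                (None, g.symbol, g.chromosome, g.start, g.end, pd.NA, pd.NA, pd.NA, None, pd.NA, pd.NA)
            )
        else:
            _, s, e, total, minor = hit
            with warnings.catch_warnings():
                # copy numbers above the nominal AMP cap are routine in
                # doubled genomes; the profile-level reader already warned
                warnings.simplefilter("ignore", UserWarning)
                category = classify_state(total, minor).value
            rows.append(
                (
                    None,
                    g.symbol,
                    g.chromosome,
                    g.start,
                    g.end,
                    total,
                    minor,
                    is_loh(total, minor),
                    category,
                    s,
                    e,
                )
            )
    df = pd.DataFrame(rows, columns=GENE_STATUS_COLUMNS)
    df["sample_id"] = profile.sample_id
    for col in ("total_cn", "minor_cn", "seg_start", "seg_end"):
        df[col] = df[col].astype("Int64")
    df["loh"] = df["loh"].astype("boolean")
    return df


def _status_lookup(statuses: GeneStatusTable) -> dict[tuple[str, str], str | None]:
    """(sample, symbol) -> category string or None (missing)."""
    return {
        (row.sample_id, row.symbol): row.category
        for row in statuses.itertuples(index=False)
    }


@dataclasses.dataclass(frozen=True)
class PrivateEventSummary:
    """Per-gene counts of metastasis-private amplification and loss.

    ``table`` has one row per gene with columns symbol, chromosome,
    n_pairs (evaluable pairs), amp_private_to_met, loss_private_to_met,
    amp_private_fraction, loss_private_fraction plus the formatted
    "k/n (pct %)" strings used in report tables.
    """

    table: pd.DataFrame
    amp_categories: frozenset
    loss_categories: frozenset

    def formatted(self) -> pd.DataFrame:
        def fmt(k, n):
            pct = 0.0 if n == 0 else 100.0 * k / n
            return f"{k}/{n} ({pct:.1f} %)"

        out = self.table[["symbol", "chromosome"]].copy()
        out["amp_private_to_met"] = [
            fmt(k, n) for k, n in zip(self.table["amp_private_to_met"], self.table["n_pairs"])
        ]
        out["loss_private_to_met"] = [
            fmt(k, n) for k, n in zip(self.table["loss_private_to_met"], self.table["n_pairs"])
        ]
        return out


def private_events(
    pairs: Sequence[PairRecord],
    statuses: GeneStatusTable,
    genes: Sequence[GeneModel],
    strict: bool = False,
) -> PrivateEventSummary:
    """Tabulate metastasis-private amplification/loss per gene.

    Parameters
    ----------
    pairs
        Primary/metastasis pairings; both samples of each pair must
        appear in ``statuses`` (pairs missing a gene's status in either
        sample are excluded for that gene and logged).
    statuses
        Concatenated :func:`gene_status` tables for all samples.
    genes
        Gene annotation (defines row order).
    strict
        If True, "amplification" means category AMP only and "loss"
        means HOMDEL only; by default gains (CN 3-5) and single-copy
        losses also count.
    """
    amp_set = AMP_STRICT if strict else AMP_BROAD
    loss_set = LOSS_STRICT if strict else LOSS_BROAD
    amp_names = {c.value for c in amp_set}
    loss_names = {c.value for c in loss_set}
    lookup = _status_lookup(statuses)
    present = {s for s, _ in lookup}
    for p in pairs:
        for s in (p.primary_sample, p.met_sample):
            if s not in present:
                raise ValidationError(f"sample {s!r} absent from gene status table")

    rows = []
    for g in genes:
        n_eval = amp_priv = loss_priv = 0
        for p in pairs:
            cat_p = lookup.get((p.primary_sample, g.symbol))
            cat_m = lookup.get((p.met_sample, g.symbol))
            if cat_p is None or cat_m is None:
                logger.info(
                    "gene %s: pair %s excluded (missing status)", g.symbol, p.patient_id
                )
                continue
            n_eval += 1
            if cat_m in amp_names and cat_p not in amp_names:
                amp_priv += 1
            if cat_m in loss_names and cat_p not in loss_names:
                loss_priv += 1
        rows.append((g.symbol, g.chromosome, n_eval, amp_priv, loss_priv))
    table = pd.DataFrame(
        rows,
        columns=["symbol", "chromosome", "n_pairs", "amp_private_to_met", "loss_private_to_met"],
    )
    with np.errstate(invalid="ignore"):
        table["amp_private_fraction"] = np.where(
            table["n_pairs"] > 0, table["amp_private_to_met"] / table["n_pairs"], np.nan
        )
        table["loss_private_fraction"] = np.where(
            table["n_pairs"] > 0, table["loss_private_to_met"] / table["n_pairs"], np.nan
        )
    return PrivateEventSummary(table=table, amp_categories=amp_set, loss_categories=loss_set)


def concordance_rate(
    pairs: Sequence[PairRecord],
    statuses: GeneStatusTable,
    genes: Sequence[GeneModel],
    wgd_correction: bool = False,
) -> tuple[int, float, pd.Series]:
    """Fraction of genes whose status is shared within every pair.

    A gene counts as concordant (shared) only when its status matches
    between primary and metastasis in every pair in which both statuses
    are available; genes with no evaluable pair are excluded from the
    denominator.

    Parameters
    ----------
    wgd_correction
        By default "shared" means identical category.  With the
        correction, a pair also counts as shared when the metastasis
        total exceeds the primary total by 1 or 2 copies with unchanged
        LOH status — the same forgiveness the windowed comparison
        applies, without which a doubled metastasis genome renders
        nearly every gene nominally discordant.

    Returns
    -------
    (n_concordant, fraction, per_gene)
        ``per_gene`` is a boolean Series indexed by symbol (NA where a
        gene had no evaluable pair).
    """
    lookup = _status_lookup(statuses)
    full = {
        (row.sample_id, row.symbol): row for row in statuses.itertuples(index=False)
    }
    flags: dict[str, object] = {}
    for g in genes:
        verdict: object = pd.NA
        for p in pairs:
            cat_p = lookup.get((p.primary_sample, g.symbol))
            cat_m = lookup.get((p.met_sample, g.symbol))
            if cat_p is None or cat_m is None:
                continue
            if verdict is pd.NA:
                verdict = True
            shared = cat_p == cat_m
            if not shared and wgd_correction:
                row_p = full[(p.primary_sample, g.symbol)]
                row_m = full[(p.met_sample, g.symbol)]
                diff = int(row_m.total_cn) - int(row_p.total_cn)
                shared = diff in (1, 2) and bool(row_p.loh) == bool(row_m.loh)
            if not shared:
                verdict = False
        flags[g.symbol] = verdict
    per_gene = pd.Series(flags, dtype="boolean")
    evaluable = per_gene.dropna()
    if len(evaluable) == 0:
        raise ValidationError("no gene evaluable in any pair")
    n_conc = int(evaluable.sum())
    return n_conc, n_conc / len(evaluable), per_gene
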