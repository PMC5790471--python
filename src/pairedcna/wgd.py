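"""Whole-genome-duplication detection from segmented profiles.

A genome is called whole-genome duplicated when more than 70% of the
length of at least half of the chromosomes sits at total copy number 3 or
4 with both parental alleles present (minor-allele copy number >= 1).
Doubled-then-LOH genomes (e.g. uniform (4,0)) therefore do not qualify:
the rule requires biallelic near-tetraploidy.

Fraction denominators are full chromosome lengths from the layout, so
bases not covered by any segment count against, never toward, a WGD call.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .profiles_io import GenomeLayout, SegmentedProfile, ValidationError

__all__ = ["WGDCall", "detect_wgd", "WGD_TOTAL_CN", "WGD_CHROM_FRACTION"]

WGD_TOTAL_CN = (3, 4)  # closed integer set "between 3 and 4"
WGD_CHROM_FRACTION = 0.70  # per-chromosome fraction threshold, strict


@dataclasses.dataclass(frozen=True)
class WGDCall:
    """WGD decision with per-chromosome diagnostics.

    Attributes
    ----------
    is_wgd
        True iff at least half the chromosomes (inclusive, ceil(n/2))
        have more than 70% of their length at biallelic CN 3-4.
    per_chromosome_fraction
        Chromosome -> fraction of its full length with total CN in
        {3, 4} and minor CN >= 1.
    qualifying_chromosomes
        Number of chromosomes whose fraction exceeds 0.70.
    genome_fraction_34_biallelic
        Same state as a fraction of total genome length.  Reported as a
        diagnostic only (typically > 0.45 in duplicated genomes); the
        decision is the per-chromosome rule.
    """

    sample_id: str
    is_wgd: bool
    per_chromosome_fraction: dict[str, float]
    qualifying_chromosomes: int
    genome_fraction_34_biallelic: float


def detect_wgd(profile: SegmentedProfile, layout: GenomeLayout | None = None) -> WGDCall:
    """Call whole-genome duplication for one segmented profile.

    Parameters
    ----------
    profile
        Validated segmented profile.
    layout
        Coordinate frame supplying chromosome lengths; defaults to the
        profile's own layout and must contain every profile chromosome.

    Raises
    ------
    ValidationError
        If the profile has no segments or uses a chromosome absent from
        the layout.
    """
    layout = layout if layout is not None else profile.layout
    if len(profile) == 0:
        raise ValidationError(f"sample {profile.sample_id!r}: empty profile")
    df = profile.data
    unknown = set(df["chromosome"]) - set(layout.names)
    if unknown:
        raise ValidationError(
            f"sample {profile.sample_id!r}: chromosome(s) {sorted(unknown)} not in layout"
        )

    qualifying_len = (df["end"] - df["start"]).where(
        df["total_cn"].isin(WGD_TOTAL_CN) & (df["minor_cn"] >= 1), 0
    )
    per_chrom_num = qualifying_len.groupby(df["chromosome"]).sum()

    fractions: dict[str, float] = {}
    for name in layout.names:
        num = int(per_chrom_num.get(name, 0))
        fractions[name] = num / layout.length(name)

    n_qual = int(np.sum([f > WGD_CHROM_FRACTION for f in fractions.values()]))
    needed = math.ceil(len(layout) / 2)
    genome_fraction = float(qualifying_len.sum()) / layout.total_length
    return WGDCall(
        sample_id=profile.sample_id,
        is_wgd=n_qual >= needed,
        per_chromosome_fraction=fractions,
        qualifying_chromosomes=n_qual,
        genome_fraction_34_biallelic=genome_fraction,
    )
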