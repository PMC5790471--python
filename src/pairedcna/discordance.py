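"""Fixed-window paired copy-number and LOH discordance.

The genome is tiled into fixed windows (10 kb by default); each window
takes the allele-specific state of the segment with the largest overlap
inside it.  For a primary/metastasis pair, the per-window copy-number
difference is the metastasis total minus the primary total.  A window is
copy-number concordant when the difference is zero or — with the
whole-genome-duplication (WGD) correction enabled — when it is +1 or +2
copies with unchanged LOH status, since a doubling of the metastasis
genome raises totals without selecting between alleles.  LOH is
classified separately per window into three states: unchanged, LOH
acquired in the metastasis, or heterozygosity retained in the metastasis
(LOH only in the primary).

The copy-number and LOH metrics are deliberately independent: a window
at (2,0) vs (2,1) is copy-number concordant (difference 0) but falls in
the ``het_retained_in_met`` LOH class.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator

import numpy as np
import pandas as pd

from .profiles_io import (
    GenomeLayout,
    SegmentedProfile,
    ValidationError,
    classify_states,
)

__all__ = [
    "DEFAULT_WINDOW_SIZE",
    "PairDiscordanceResult",
    "WindowGrid",
    "WindowStateTrack",
    "assign_windows",
    "compare_pair",
    "genome_fractions",
    "tile_genome",
]

DEFAULT_WINDOW_SIZE = 10_000

# per-window LOH class codes
LOH_UNCHANGED = 0
LOH_IN_MET = 1
HET_RETAINED_IN_MET = 2
LOH_CLASS_NAMES = {
    LOH_UNCHANGED: "unchanged",
    LOH_IN_MET: "loh_in_met",
    HET_RETAINED_IN_MET: "het_retained_in_met",
}
# per-window CN labels
CN_NOT_COMPARED = -1
CN_CONCORDANT = 0
CN_DISCORDANT = 1


@dataclasses.dataclass(frozen=True)
class WindowGrid:
    """Adjacent fixed-size windows tiling a genome layout.

    Every chromosome is covered by ``ceil(length / window_size)`` windows;
    the last window of a chromosome may be shorter.  Windows are indexed
    globally in layout order.
    """

    layout: GenomeLayout
    window_size: int
    chrom_offsets: tuple[int, ...]  # cumulative window counts, len = n_chrom + 1

    @property
    def n_windows(self) -> int:
        return self.chrom_offsets[-1]

    def __len__(self) -> int:
        return self.n_windows

    def chrom_slice(self, name: str) -> slice:
        i = self.layout.rank(name)
        return slice(self.chrom_offsets[i], self.chrom_offsets[i + 1])

    def windows(self) -> Iterator[tuple[str, int, int]]:
        """Yield (chromosome, start, end) in global window order."""
        ws = self.window_size
        for name, length in self.layout.chromosomes:
            for start in range(0, length, ws):
                yield name, start, min(start + ws, length)

    def window_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.windows(), columns=["chromosome", "start", "end"])


def tile_genome(layout: GenomeLayout, window_size: int = DEFAULT_WINDOW_SIZE) -> WindowGrid:
    """Tile a genome layout into fixed windows.

    Parameters
    ----------
    layout
        Chromosome names and lengths; may be empty (yields an empty grid).
    window_size
        Window width in bp; must be positive.
    """
    if window_size <= 0:
        raise ValidationError(f"window_size must be positive, got {window_size}")
    offsets = [0]
    for _, length in layout.chromosomes:
        offsets.append(offsets[-1] + -(-length // window_size))
    return WindowGrid(layout=layout, window_size=window_size, chrom_offsets=tuple(offsets))


@dataclasses.dataclass
class WindowStateTrack:
    """Per-window copy-number state for one sample on a grid.

    ``total_cn``/``minor_cn`` are -1 where no segment overlaps the window
    (missing); ``loh`` is False there and ``category_codes`` holds -1.
    """

    sample_id: str
    grid: WindowGrid
    total_cn: np.ndarray  # int32, -1 = missing
    minor_cn: np.ndarray  # int32, -1 = missing

    @property
    def missing(self) -> np.ndarray:
        return self.total_cn < 0

    @property
    def loh(self) -> np.ndarray:
        return (self.minor_cn == 0) & (self.total_cn >= 1)

    @property
    def category_codes(self) -> np.ndarray:
        return classify_states(self.total_cn, self.minor_cn)

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.window_frame()
        df["total_cn"] = self.total_cn
        df["minor_cn"] = self.minor_cn
        df["loh"] = self.loh
        df.loc[self.missing, ["total_cn", "minor_cn"]] = -1
        return df


def assign_windows(profile: SegmentedProfile, grid: WindowGrid) -> WindowStateTrack:
    """Assign each window the state of its largest overlapping segment.

    For every window the segment with the largest overlap length inside
    the window determines (total_cn, minor_cn); overlap ties go to the
    segment with the smaller start.  Windows overlapped by no segment are
    missing.
    """
    layout = grid.layout
    unknown = set(profile.data["chromosome"]) - set(layout.names)
    if unknown:
        raise ValidationError(
            f"sample {profile.sample_id!r}: chromosome(s) {sorted(unknown)} not in grid layout"
        )
    ws = grid.window_size
    n = grid.n_windows
    total = np.full(n, -1, dtype=np.int32)
    minor = np.full(n, -1, dtype=np.int32)
    best = np.zeros(n, dtype=np.int64)  # best overlap so far

    for chrom, sub in profile.data.groupby("chromosome", sort=False):
        sl = grid.chrom_slice(chrom)
        length = layout.length(chrom)
        n_chrom_windows = sl.stop - sl.start
        win_starts = np.arange(n_chrom_windows, dtype=np.int64) * ws
        win_ends = np.minimum(win_starts + ws, length)
        # segments arrive sorted by start; with a strict improvement test
        # the leftmost segment wins overlap ties
        for row in sub.itertuples(index=False):
            w0 = row.start // ws
            w1 = (row.end - 1) // ws + 1
            ov = np.minimum(win_ends[w0:w1], row.end) - np.maximum(win_starts[w0:w1], row.start)
            seg_slice = slice(sl.start + w0, sl.start + w1)
            upd = ov > best[seg_slice]
            if upd.any():
                idx = np.flatnonzero(upd) + seg_slice.start
                best[idx] = ov[upd]
                total[idx] = row.total_cn
                minor[idx] = row.minor_cn
    return WindowStateTrack(profile.sample_id, grid, total, minor)


@dataclasses.dataclass
class PairDiscordanceResult:
    """Windowed copy-number and LOH discordance for one sample pair.

    Fractions are over ``n_windows_compared`` — the windows with a state
    in both samples.  The three LOH-class fractions sum to 1 over those
    windows.  ``cn_labels`` holds -1 (not compared), 0 (concordant) or
    1 (discordant) per window; ``loh_classes`` holds -1 or the LOH class
    code.
    """

    patient_id: str
    grid: WindowGrid
    n_windows_compared: int
    cn_discordant_fraction: float
    loh_unchanged_fraction: float
    loh_met_only_fraction: float
    loh_primary_only_fraction: float
    wgd_correction: bool
    cn_labels: np.ndarray
    loh_classes: np.ndarray
    wgd_primary: bool | None = None
    wgd_met: bool | None = None

    def to_frame(self) -> pd.DataFrame:
        """Per-window BED-like table of discordance labels."""
        df = self.grid.window_frame()
        df["cn_label"] = np.array(["not_compared", "concordant", "cn_discordant"])[
            self.cn_labels.astype(np.int64) + 1
        ]
        df["loh_class"] = [
            "not_compared" if c < 0 else LOH_CLASS_NAMES[c] for c in self.loh_classes
        ]
        return df

    def summary(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "n_windows_compared": self.n_windows_compared,
            "cn_discordant_fraction": self.cn_discordant_fraction,
            "loh_unchanged_fraction": self.loh_unchanged_fraction,
            "loh_met_only_fraction": self.loh_met_only_fraction,
            "loh_primary_only_fraction": self.loh_primary_only_fraction,
        }


def compare_pair(
    primary: WindowStateTrack,
    met: WindowStateTrack,
    wgd_correction: bool = True,
    patient_id: str | None = None,
) -> PairDiscordanceResult:
    """Compare a primary and metastasis window track on the same grid.

    Parameters
    ----------
    primary, met
        Window state tracks built on the identical grid.
    wgd_correction
        Forgive per-window differences of +1 or +2 copies (metastasis
        minus primary) when the LOH status is unchanged; differences of
        -1/-2 are never forgiven (no primary-only doubling is assumed).
    patient_id
        Label for the result; defaults to "primary_sample|met_sample".

    Raises
    ------
    ValidationError
        If the two tracks are on different grids or no window has a
        state in both samples.
    """
    if primary.grid is not met.grid and (
        primary.grid.window_size != met.grid.window_size
        or primary.grid.layout.chromosomes != met.grid.layout.chromosomes
    ):
        raise ValidationError("window tracks are on different grids")
    both = ~primary.missing & ~met.missing
    n = int(both.sum())
    if n == 0:
        raise ValidationError("no window has a state in both samples")

    diff = met.total_cn.astype(np.int64) - primary.total_cn
    loh_equal = primary.loh == met.loh
    concordant = diff == 0
    if wgd_correction:
        concordant |= ((diff == 1) | (diff == 2)) & loh_equal

    cn_labels = np.full(len(primary.grid), CN_NOT_COMPARED, dtype=np.int8)
    cn_labels[both] = np.where(concordant[both], CN_CONCORDANT, CN_DISCORDANT)

    loh_classes = np.full(len(primary.grid), -1, dtype=np.int8)
    loh_classes[both] = LOH_UNCHANGED
    loh_classes[both & met.loh & ~primary.loh] = LOH_IN_MET
    loh_classes[both & primary.loh & ~met.loh] = HET_RETAINED_IN_MET

    return PairDiscordanceResult(
        patient_id=patient_id or f"{primary.sample_id}|{met.sample_id}",
        grid=primary.grid,
        n_windows_compared=n,
        cn_discordant_fraction=float((cn_labels == CN_DISCORDANT).sum()) / n,
        loh_unchanged_fraction=float((loh_classes == LOH_UNCHANGED).sum()) / n,
        loh_met_only_fraction=float((loh_classes == LOH_IN_MET).sum()) / n,
        loh_primary_only_fraction=float((loh_classes == HET_RETAINED_IN_MET).sum()) / n,
        wgd_correction=wgd_correction,
        cn_labels=cn_labels,
        loh_classes=loh_classes,
    )


def genome_fractions(
    profile: SegmentedProfile, layout: GenomeLayout | None = None
) -> tuple[float, float]:
    """Fractions of the covered genome that are CN-altered and LOH.

    Returns
    -------
    (altered_fraction, loh_fraction)
        ``altered_fraction`` is the fraction of segment-covered bases
        with total copy number != 2 (copy-neutral LOH is *not* a
        copy-number change); ``loh_fraction`` is the fraction with the
        minor allele absent at total CN >= 1.  Denominators are the
        segment-covered bases, not full chromosome lengths.
    """
    if len(profile) == 0:
        raise ValidationError(f"sample {profile.sample_id!r}: empty profile")
    df = profile.data
    lengths = (df["end"] - df["start"]).to_numpy()
    covered = int(lengths.sum())
    altered = int(lengths[(df["total_cn"] != 2).to_numpy()].sum())
    loh = int(lengths[((df["minor_cn"] == 0) & (df["total_cn"] >= 1)).to_numpy()].sum())
    return altered / covered, loh / covered
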