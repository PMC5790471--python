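"""Paired tumor/metastasis copy-number profile simulator with ground truth.

Each simulated patient starts as a diploid heterozygous genome.  Trunk
events (shared clone) are applied to both branches; each branch then
acquires private segment-level events — losses, gains, amplifications,
homozygous deletions and copy-neutral LOH — optionally followed by a
whole-genome doubling of either branch.  Alternatively, a *targeted*
mode plants window-aligned private events on the metastasis (copy-number
discordance) and on either branch (LOH classes) so that the planted
genome fractions are known exactly.

Ground truth is computed from the generator's own state maps by an
independent reference implementation of the largest-overlap windowing
and the +1/+2 doubling-correction comparison, so the analysis pipeline
can be validated end to end without external data.

Emitted profiles cover every base of the layout (segmentation gaps are a
property of real array data that this generator does not emulate).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .profiles_io import (
    GeneModel,
    GenomeLayout,
    PairRecord,
    SegmentedProfile,
    ValidationError,
    classify_state,
    write_gene_annotation,
    write_profile,
    write_sample_sheet,
)

__all__ = [
    "CohortSimulation",
    "GroundTruth",
    "SimulationConfig",
    "default_layout",
    "hg_like_layout",
    "make_gene_panel",
    "reference_gene_category",
    "simulate_cohort",
    "simulate_pair",
    "window_states_reference",
]

EVENT_TYPES = ("loss", "gain", "amp", "homdel", "cn_loh")
DEFAULT_EVENT_WEIGHTS: Mapping[str, float] = {
    "loss": 0.30,
    "gain": 0.30,
    "amp": 0.05,
    "homdel": 0.05,
    "cn_loh": 0.30,
}

#: copies added by the planted (targeted-mode) discordant gain; +3 is
#: never forgiven by the +1/+2 doubling correction
PLANTED_GAIN = 3


def default_layout(n_chromosomes: int = 22, chrom_length: int = 5_000_000) -> GenomeLayout:
    """Scaled-down autosome layout (22 x 5 Mb by default, 11,000 windows)."""
    return GenomeLayout(
        tuple((f"chr{i}", chrom_length) for i in range(1, n_chromosomes + 1))
    )


_HG19_AUTOSOMES = (
    ("chr1", 249_250_621), ("chr2", 243_199_373), ("chr3", 198_022_430),
    ("chr4", 191_154_276), ("chr5", 180_915_260), ("chr6", 171_115_067),
    ("chr7", 159_138_663), ("chr8", 146_364_022), ("chr9", 141_213_431),
    ("chr10", 135_534_747), ("chr11", 135_006_516), ("chr12", 133_851_895),
    ("chr13", 115_169_878), ("chr14", 107_349_540), ("chr15", 102_531_392),
    ("chr16", 90_354_753), ("chr17", 81_195_210), ("chr18", 78_077_248),
    ("chr19", 59_128_983), ("chr20", 63_025_520), ("chr21", 48_129_895),
    ("chr22", 51_304_566),
)


def hg_like_layout() -> GenomeLayout:
    """Full-size human autosome layout (hg19 lengths) for realism runs."""
    return GenomeLayout(_HG19_AUTOSOMES)


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated primary/metastasis pair.

    Attributes
    ----------
    layout
        Genome over which events are drawn (default scaled 22 x 5 Mb).
    window_size
        Window width used for planted targets and ground truth.
    trunk_event_rate
        Expected (Poisson) number of shared-clone events per genome.
    branch_event_rate_primary, branch_event_rate_met
        Expected private events per branch (free mode only).
    event_length_min, event_length_max
        Log-uniform event length range in bp.
    event_type_weights
        Probabilities over loss/gain/amp/homdel/cn_loh; must sum to 1.
    target_discordance, target_loh_met, target_loh_primary
        Planted genome fractions (targeted mode).  Setting any of them
        switches the branch stage to exact window-aligned planting and
        disables the Poisson branch events; their sum must not exceed 1.
    wgd_primary, wgd_met
        Apply a whole-genome doubling to the branch.
    wgd_after_fraction
        Fraction of branch events applied before the doubling (1.0 =
        doubling last, i.e. late WGD).
    loh_bias
        Probability that a loss event removes the minor allele.
    hot_chromosomes, hot_weight
        Event placement (trunk, branch and planted) is concentrated on a
        "hot" chromosome subset (default: just under half the layout)
        with this relative weight, emulating the recurrent chromosome-
        level clustering of real somatic copy-number alterations; the
        remaining chromosomes stay mostly quiet, which is also what
        keeps a doubled genome detectable by the per-chromosome WGD
        rule.
    seed
        Seed of the generator; identical (config, seed) reproduces
        byte-identical profiles.
    """

    layout: GenomeLayout = dataclasses.field(default_factory=default_layout)
    window_size: int = 10_000
    trunk_event_rate: float = 25.0
    branch_event_rate_primary: float = 8.0
    branch_event_rate_met: float = 8.0
    event_length_min: int = 100_000
    event_length_max: int = 1_200_000
    event_type_weights: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_EVENT_WEIGHTS)
    )
    target_discordance: float | None = None
    target_loh_met: float | None = None
    target_loh_primary: float | None = None
    wgd_primary: bool = False
    wgd_met: bool = False
    wgd_after_fraction: float = 1.0
    loh_bias: float = 0.7
    hot_chromosomes: tuple[str, ...] | None = None
    hot_weight: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("trunk_event_rate", "branch_event_rate_primary", "branch_event_rate_met"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 < self.event_length_min <= self.event_length_max:
            raise ValidationError("event lengths must satisfy 0 < min <= max")
        if set(self.event_type_weights) - set(EVENT_TYPES):
            raise ValidationError(f"unknown event type in weights; allowed: {EVENT_TYPES}")
        if abs(sum(self.event_type_weights.values()) - 1.0) > 1e-9:
            raise ValidationError("event_type_weights must sum to 1")
        if not 0.0 <= self.loh_bias <= 1.0:
            raise ValidationError("loh_bias must be in [0, 1]")
        if not 0.0 <= self.wgd_after_fraction <= 1.0:
            raise ValidationError("wgd_after_fraction must be in [0, 1]")
        targets = [self.target_discordance, self.target_loh_met, self.target_loh_primary]
        for t in targets:
            if t is not None and not 0.0 <= t <= 1.0:
                raise ValidationError(f"target fraction {t} outside [0, 1]")
        if self.hot_weight < 1.0:
            raise ValidationError("hot_weight must be >= 1")
        if self.hot_chromosomes is not None:
            unknown = set(self.hot_chromosomes) - set(self.layout.names)
            if unknown:
                raise ValidationError(f"hot chromosome(s) {sorted(unknown)} not in layout")
        total = sum(t or 0.0 for t in targets)
        if total > 1.0:
            raise ValidationError(
                f"infeasible targets: planted fractions sum to {total:.3f} > 1 "
                "(the three planted classes occupy disjoint windows)"
            )

    @property
    def targeted(self) -> bool:
        return any(
            t is not None
            for t in (self.target_discordance, self.target_loh_met, self.target_loh_primary)
        )


class _ChromState:
    """Piecewise-constant (total, minor) state along one chromosome."""

    __slots__ = ("length", "starts", "t", "m")

    def __init__(self, length: int):
        self.length = length
        self.starts = np.array([0], dtype=np.int64)
        self.t = np.array([2], dtype=np.int64)
        self.m = np.array([1], dtype=np.int64)

    def copy(self) -> "_ChromState":
        new = _ChromState.__new__(_ChromState)
        new.length = self.length
        new.starts = self.starts.copy()
        new.t = self.t.copy()
        new.m = self.m.copy()
        return new

    def _split(self, pos: int) -> None:
        if pos <= 0 or pos >= self.length:
            return
        i = int(np.searchsorted(self.starts, pos, side="right")) - 1
        if self.starts[i] == pos:
            return
        self.starts = np.insert(self.starts, i + 1, pos)
        self.t = np.insert(self.t, i + 1, self.t[i])
        self.m = np.insert(self.m, i + 1, self.m[i])

    def apply(self, start: int, end: int, fn) -> None:
        """Apply fn(t, m) -> (t, m) to all pieces inside [start, end)."""
        self._split(start)
        self._split(end)
        i0 = int(np.searchsorted(self.starts, start, side="right")) - 1
        if start <= 0:
            i0 = 0
        i1 = int(np.searchsorted(self.starts, min(end, self.length), side="left"))
        if end >= self.length:
            i1 = len(self.starts)
        t, m = fn(self.t[i0:i1].copy(), self.m[i0:i1].copy())
        t = np.maximum(t, 0)
        m = np.clip(m, 0, None)
        m = np.minimum(m, t - m)  # minor is the lesser allele
        m = np.maximum(m, 0)
        m[t == 0] = 0
        self.t[i0:i1] = t
        self.m[i0:i1] = m

    def whole_genome_double(self) -> None:
        self.t *= 2
        self.m *= 2

    def merged(self) -> list[tuple[int, int, int, int]]:
        """(start, end, total, minor) with adjacent equal states merged."""
        n = len(self.starts)
        keep = [0] + [
            i for i in range(1, n) if self.t[i] != self.t[i - 1] or self.m[i] != self.m[i - 1]
        ]
        starts = self.starts[keep]
        ends = np.append(starts[1:], self.length)
        return [
            (int(s), int(e), int(self.t[i]), int(self.m[i]))
            for s, e, i in zip(starts, ends, keep)
        ]


Genome = dict  # chromosome name -> _ChromState


def _new_genome(layout: GenomeLayout) -> Genome:
    return {name: _ChromState(length) for name, length in layout.chromosomes}


def _copy_genome(genome: Genome) -> Genome:
    return {name: st.copy() for name, st in genome.items()}


def _hot_chromosomes(cfg: SimulationConfig) -> tuple[str, ...]:
    if cfg.hot_chromosomes is not None:
        return cfg.hot_chromosomes
    names = cfg.layout.names
    every_other = names[::2]
    # ~40% of chromosomes, leaving a quiet majority of chromosomes
    return every_other[: max(1, round(0.4 * len(names)))]


def _chrom_weights(cfg: SimulationConfig) -> np.ndarray:
    hot = set(_hot_chromosomes(cfg))
    return np.array(
        [cfg.hot_weight if name in hot else 1.0 for name in cfg.layout.names]
    )


def _draw_events(rng: np.random.Generator, cfg: SimulationConfig, n_events: int) -> list:
    """Draw (chrom, start, end, fn) free events; fn mutates (t, m) arrays."""
    layout = cfg.layout
    names = layout.names
    lengths = np.array([layout.length(c) for c in names], dtype=float)
    weighted = lengths * _chrom_weights(cfg)
    probs = weighted / weighted.sum()
    types = list(cfg.event_type_weights)
    type_p = np.array([cfg.event_type_weights[k] for k in types])
    events = []
    for _ in range(n_events):
        ci = int(rng.choice(len(names), p=probs))
        chrom, chrom_len = names[ci], int(lengths[ci])
        elen = int(
            round(
                math.exp(
                    rng.uniform(math.log(cfg.event_length_min), math.log(cfg.event_length_max))
                )
            )
        )
        elen = max(1, min(elen, chrom_len))
        start = int(rng.integers(0, chrom_len - elen + 1))
        etype = types[int(rng.choice(len(types), p=type_p))]
        if etype == "loss":
            remove_minor = bool(rng.random() < cfg.loh_bias)

            def fn(t, m, remove_minor=remove_minor):
                live = t > 0
                if remove_minor:
                    m = np.where(live, np.maximum(m - 1, 0), m)
                t = np.where(live, t - 1, t)
                return t, m

        elif etype in ("gain", "amp"):
            k = int(rng.integers(1, 4)) if etype == "gain" else int(rng.integers(4, 8))

            def fn(t, m, k=k):
                return np.where(t > 0, t + k, t), m

        elif etype == "homdel":

            def fn(t, m):
                return np.zeros_like(t), np.zeros_like(m)

        else:  # cn_loh

            def fn(t, m):
                return t, np.where(t >= 1, 0, m)

        events.append((chrom, start, start + elen, fn))
    return events


def _apply_events(genome: Genome, events: Sequence[tuple]) -> None:
    for chrom, start, end, fn in events:
        genome[chrom].apply(start, end, fn)


# ---------------------------------------------------------------------------
# reference (oracle) windowing — independent of pairedcna.discordance

def _window_bounds(layout: GenomeLayout, window_size: int):
    for name, length in layout.chromosomes:
        for s in range(0, length, window_size):
            yield name, s, min(s + window_size, length)


def _reference_states_from_rows(rows_by_chrom, layout: GenomeLayout, window_size: int):
    """Largest-overlap window states by direct per-window scan.

    ``rows_by_chrom``: chrom -> list of (start, end, total, minor), sorted,
    non-overlapping.  Returns int64 arrays (total, minor) with -1 where no
    row overlaps a window.  Overlap ties go to the leftmost row.
    """
    totals: list[int] = []
    minors: list[int] = []
    for name, length in layout.chromosomes:
        rows = rows_by_chrom.get(name, [])
        i = 0
        for ws_start in range(0, length, window_size):
            ws_end = min(ws_start + window_size, length)
            while i < len(rows) and rows[i][1] <= ws_start:
                i += 1
            best_ov, best_t, best_m = 0, -1, -1
            j = i
            while j < len(rows) and rows[j][0] < ws_end:
                ov = min(rows[j][1], ws_end) - max(rows[j][0], ws_start)
                if ov > best_ov:  # strict: leftmost row wins ties
                    best_ov, best_t, best_m = ov, rows[j][2], rows[j][3]
                j += 1
            totals.append(best_t)
            minors.append(best_m)
    return np.array(totals, dtype=np.int64), np.array(minors, dtype=np.int64)


def window_states_reference(profile: SegmentedProfile, window_size: int = 10_000):
    """Reference largest-overlap window assignment for a profile.

    A deliberately simple per-window scan used as the independent check
    of the vectorized assignment in :mod:`pairedcna.discordance`.
    Returns (total, minor) arrays with -1 for windows without data.
    """
    rows_by_chrom: dict[str, list] = {}
    for row in profile.data.itertuples(index=False):
        rows_by_chrom.setdefault(row.chromosome, []).append(
            (int(row.start), int(row.end), int(row.total_cn), int(row.minor_cn))
        )
    return _reference_states_from_rows(rows_by_chrom, profile.layout, window_size)


def _genome_rows(genome: Genome, layout: GenomeLayout):
    return {name: genome[name].merged() for name, _ in layout.chromosomes}


def _reference_compare(tp, mp, tm, mm, correction: bool):
    """Windowed pair comparison on state arrays (reference semantics)."""
    both = (tp >= 0) & (tm >= 0)
    n = int(both.sum())
    diff = tm - tp
    loh_p = (mp == 0) & (tp >= 1)
    loh_m = (mm == 0) & (tm >= 1)
    loh_equal = loh_p == loh_m
    conc = diff == 0
    if correction:
        conc = conc | (((diff == 1) | (diff == 2)) & loh_equal)
    cn_disc = int((both & ~conc).sum())
    unchanged = int((both & loh_equal).sum())
    loh_in_met = int((both & loh_m & ~loh_p).sum())
    het_ret = int((both & loh_p & ~loh_m).sum())
    return n, cn_disc, unchanged, loh_in_met, het_ret


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """Known per-pair answers, computed from the generator's state maps."""

    patient_id: str
    seed: int
    wgd_primary: bool
    wgd_met: bool
    target_discordance: float | None
    target_loh_met: float | None
    target_loh_primary: float | None
    n_windows: int
    cn_discordant_fraction: float
    cn_discordant_fraction_uncorrected: float
    loh_unchanged_fraction: float
    loh_met_only_fraction: float
    loh_primary_only_fraction: float

    def as_row(self) -> dict:
        return dataclasses.asdict(self)


def _plant_spans(
    rng: np.random.Generator,
    per_chrom_windows: np.ndarray,
    needed: int,
    free: np.ndarray,
    eligible: np.ndarray | None,
    min_w: int,
    max_w: int,
    chrom_weights: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Reserve ~log-uniform-length runs of free (and eligible) windows.

    Returns global-window-index spans [g0, g1).  Falls back to single
    windows when contiguous placement keeps colliding.
    """
    offsets = np.concatenate([[0], np.cumsum(per_chrom_windows)])
    weights = per_chrom_windows.astype(float)
    if chrom_weights is not None:
        weights = weights * chrom_weights
    probs = weights / weights.sum()
    spans: list[tuple[int, int]] = []
    attempts = 0
    while needed > 0:
        if attempts >= 5000:
            mask = free if eligible is None else (free & eligible)
            idxs = np.flatnonzero(mask)[:needed]
            if len(idxs) < needed:
                raise ValidationError(
                    f"infeasible planting: {needed} windows requested but only "
                    f"{len(idxs)} eligible windows remain"
                )
            for g in idxs:
                free[g] = False
                spans.append((int(g), int(g) + 1))
            return spans
        attempts += 1
        run = int(round(math.exp(rng.uniform(math.log(min_w), math.log(max_w)))))
        run = max(1, min(run, needed))
        ci = int(rng.choice(len(per_chrom_windows), p=probs))
        cw = int(per_chrom_windows[ci])
        run = min(run, cw)
        s = int(rng.integers(0, cw - run + 1))
        g0, g1 = int(offsets[ci]) + s, int(offsets[ci]) + s + run
        if not free[g0:g1].all():
            continue
        if eligible is not None and not eligible[g0:g1].all():
            continue
        free[g0:g1] = False
        spans.append((g0, g1))
        needed -= run
    return spans


def _spans_to_intervals(
    spans: Sequence[tuple[int, int]], layout: GenomeLayout, window_size: int
) -> list[tuple[str, int, int]]:
    per_chrom = np.array(
        [-(-length // window_size) for _, length in layout.chromosomes], dtype=np.int64
    )
    offsets = np.concatenate([[0], np.cumsum(per_chrom)])
    out = []
    for g0, g1 in spans:
        ci = int(np.searchsorted(offsets, g0, side="right")) - 1
        name, length = layout.chromosomes[ci]
        w0 = g0 - int(offsets[ci])
        w1 = g1 - int(offsets[ci])
        out.append((name, w0 * window_size, min(w1 * window_size, length)))
    return out


def simulate_pair(
    config: SimulationConfig, patient_id: str
) -> tuple[SegmentedProfile, SegmentedProfile, GroundTruth]:
    """Simulate one primary/metastasis pair with known ground truth.

    Returns
    -------
    (primary, met, truth)
        Profiles named ``{patient_id}_P`` / ``{patient_id}_M`` and the
        :class:`GroundTruth` computed by the reference implementation.

    Notes
    -----
    In targeted mode the planted copy-number event adds +3 copies to the
    metastasis over window-aligned intervals (never forgiven by the
    +1/+2 correction), and LOH-class events are planted only on windows
    that are heterozygous in the trunk, so planted fractions are
    realized exactly up to rounding to whole windows.  Combining targets
    with a one-sided whole-genome doubling re-introduces genuine
    doubling discordance over trunk gains; the realized truth reflects
    it.
    """
    rng = np.random.default_rng(config.seed)
    layout = config.layout
    ws = config.window_size

    trunk = _new_genome(layout)
    n_trunk = int(rng.poisson(config.trunk_event_rate))
    _apply_events(trunk, _draw_events(rng, config, n_trunk))

    primary = _copy_genome(trunk)
    met = _copy_genome(trunk)

    if config.targeted:
        per_chrom_windows = np.array(
            [-(-length // ws) for _, length in layout.chromosomes], dtype=np.int64
        )
        n_windows = int(per_chrom_windows.sum())
        trunk_t, trunk_m = _reference_states_from_rows(
            _genome_rows(trunk, layout), layout, ws
        )
        het = trunk_m >= 1
        free = np.ones(n_windows, dtype=bool)
        min_w = max(1, config.event_length_min // ws)
        max_w = max(min_w, config.event_length_max // ws)
        chrom_weights = _chrom_weights(config)

        def planted(target, eligible):
            if target is None or target == 0.0:
                return []
            needed = int(round(target * n_windows))
            return _plant_spans(
                rng, per_chrom_windows, needed, free, eligible, min_w, max_w, chrom_weights
            )

        cn_spans = planted(config.target_discordance, None)
        loh_met_spans = planted(config.target_loh_met, het)
        loh_prim_spans = planted(config.target_loh_primary, het)

        if config.wgd_primary:
            for st in primary.values():
                st.whole_genome_double()
        if config.wgd_met:
            for st in met.values():
                st.whole_genome_double()

        # Planted events are applied after any doubling, in doubling-aware
        # forms chosen so that (a) the CN-discordant windows differ by an
        # amount the +1/+2 correction never forgives, with LOH unchanged,
        # and (b) the LOH-class windows keep identical total copy number
        # in both branches (pure allelic events).  In particular a doubled
        # genome keeps its biallelic 3-4 state outside the planted LOH
        # windows, as a genuinely duplicated genome would.
        wp, wm = config.wgd_primary, config.wgd_met

        def gain(k):
            def fn(t, m):
                return t + k, m

            return fn

        def loss_keep_loh(t, m):
            # one-copy loss that preserves the LOH flag (post-doubling the
            # minor count is even, so m>=2 stays >=1 and m=0 stays 0)
            live = t > 0
            return np.where(live, t - 1, t), np.where(live & (m > 0), m - 1, m)

        def strip_minor_scaled(factor):
            # remove the minor allele and rescale the total to match the
            # other branch's doubling state, so total CN stays concordant
            def fn(t, m):
                t2 = t // 2 if factor == 0.5 else t * int(factor)
                return t2, np.zeros_like(m)

            return fn

        if wm and wp:
            cn_genome, cn_fn = met, loss_keep_loh
        elif wm:
            cn_genome, cn_fn = primary, gain(PLANTED_GAIN)
        else:
            cn_genome, cn_fn = met, gain(PLANTED_GAIN + (2 if wp else 0))
        lm_factor = 2 if (wp and not wm) else (0.5 if (wm and not wp) else 1)
        lp_factor = 2 if (wm and not wp) else (0.5 if (wp and not wm) else 1)

        for chrom, s, e in _spans_to_intervals(cn_spans, layout, ws):
            cn_genome[chrom].apply(s, e, cn_fn)
        for chrom, s, e in _spans_to_intervals(loh_met_spans, layout, ws):
            met[chrom].apply(s, e, strip_minor_scaled(lm_factor))
        for chrom, s, e in _spans_to_intervals(loh_prim_spans, layout, ws):
            primary[chrom].apply(s, e, strip_minor_scaled(lp_factor))
    else:
        for genome, rate, flag in (
            (primary, config.branch_event_rate_primary, config.wgd_primary),
            (met, config.branch_event_rate_met, config.wgd_met),
        ):
            events = _draw_events(rng, config, int(rng.poisson(rate)))
            k = int(math.floor(config.wgd_after_fraction * len(events)))
            _apply_events(genome, events[:k])
            if flag:
                for st in genome.values():
                    st.whole_genome_double()
            _apply_events(genome, events[k:])

    def to_profile(genome: Genome, sample_id: str, role: str) -> SegmentedProfile:
        rows = []
        for name, _ in layout.chromosomes:
            for s, e, t, m in genome[name].merged():
                rows.append((name, s, e, t, m))
        df = pd.DataFrame(rows, columns=["chromosome", "start", "end", "total_cn", "minor_cn"])
        return SegmentedProfile(sample_id, df, layout, role=role)

    primary_profile = to_profile(primary, f"{patient_id}_P", "primary")
    met_profile = to_profile(met, f"{patient_id}_M", "metastasis")

    tp, mp = _reference_states_from_rows(_genome_rows(primary, layout), layout, ws)
    tm, mm = _reference_states_from_rows(_genome_rows(met, layout), layout, ws)
    n, cn_disc, unchanged, loh_in_met, het_ret = _reference_compare(tp, mp, tm, mm, True)
    _, cn_disc_raw, _, _, _ = _reference_compare(tp, mp, tm, mm, False)
    truth = GroundTruth(
        patient_id=patient_id,
        seed=config.seed,
        wgd_primary=config.wgd_primary,
        wgd_met=config.wgd_met,
        target_discordance=config.target_discordance,
        target_loh_met=config.target_loh_met,
        target_loh_primary=config.target_loh_primary,
        n_windows=n,
        cn_discordant_fraction=cn_disc / n,
        cn_discordant_fraction_uncorrected=cn_disc_raw / n,
        loh_unchanged_fraction=unchanged / n,
        loh_met_only_fraction=loh_in_met / n,
        loh_primary_only_fraction=het_ret / n,
    )
    return primary_profile, met_profile, truth


def reference_gene_category(profile: SegmentedProfile, gene: GeneModel) -> str | None:
    """Largest-overlap gene status by direct scan (reference for tests)."""
    best_ov, best = 0, None
    for row in profile.chromosome_table(gene.chromosome).itertuples(index=False):
        ov = min(row.end, gene.end) - max(row.start, gene.start)
        if ov > best_ov:
            best_ov, best = ov, (row.total_cn, row.minor_cn)
    if best is None:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return classify_state(*best).value


def make_gene_panel(
    layout: GenomeLayout,
    n_candidate: int = 188,
    n_actionable: int = 24,
    length_min: int = 20_000,
    length_max: int = 1_000_000,
    seed: int = 0,
) -> list[GeneModel]:
    """Randomly place a candidate + actionable gene panel on a layout."""
    rng = np.random.default_rng(seed)
    names = layout.names
    lengths = np.array([layout.length(c) for c in names], dtype=float)
    probs = lengths / lengths.sum()
    genes: list[GeneModel] = []
    for panel, count, prefix in (
        ("candidate188", n_candidate, "CAND"),
        ("actionable24", n_actionable, "ACT"),
    ):
        for i in range(count):
            ci = int(rng.choice(len(names), p=probs))
            chrom_len = int(lengths[ci])
            glen = int(
                round(math.exp(rng.uniform(math.log(length_min), math.log(length_max))))
            )
            glen = max(1, min(glen, chrom_len))
            start = int(rng.integers(0, chrom_len - glen + 1))
            genes.append(
                GeneModel(f"{prefix}{i + 1:03d}", names[ci], start, start + glen, panel)
            )
    return genes


# default cohort design: the 16-patient paired study layout
DEFAULT_N_PAIRS = 16
DEFAULT_N_POST_THERAPY = 6  # metastasis sampled after chemotherapy
DEFAULT_N_METACHRONOUS = 7
DEFAULT_N_WGD_BOTH = 4
DEFAULT_N_WGD_MET_ONLY = 5
#: planted group means: treatment-naive pairs carry higher copy-number
#: discordance; post-therapy metastases carry more metastasis-private LOH
DEFAULT_GROUP_DISCORDANCE = {"naive": 0.28, "post_therapy": 0.12}
DEFAULT_GROUP_LOH_MET = {"naive": 0.03, "post_therapy": 0.11}
DEFAULT_GROUP_LOH_PRIMARY = {"naive": 0.09, "post_therapy": 0.02}
DEFAULT_DISCORDANCE_SD = 0.08
DEFAULT_LOH_SD = 0.02


@dataclasses.dataclass
class CohortSimulation:
    """A simulated paired cohort plus its ground truth."""

    layout: GenomeLayout
    pairs: list[PairRecord]
    profiles: dict[str, SegmentedProfile]
    truths: dict[str, GroundTruth]
    configs: dict[str, SimulationConfig]
    genes: list[GeneModel]

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame([t.as_row() for t in self.truths.values()])

    def write(self, outdir) -> dict[str, str]:
        """Write chrom sizes, profiles, sample sheet, genes and truth TSVs."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "chrom_sizes": outdir / "chrom_sizes.tsv",
            "profiles": outdir / "profiles.seg",
            "sample_sheet": outdir / "sample_sheet.tsv",
            "genes": outdir / "genes.bed",
            "ground_truth": outdir / "ground_truth.tsv",
        }
        self.layout.to_tsv(paths["chrom_sizes"])
        write_profile(list(self.profiles.values()), paths["profiles"])
        write_sample_sheet(self.pairs, paths["sample_sheet"])
        write_gene_annotation(self.genes, paths["genes"])
        self.truth_table().to_csv(paths["ground_truth"], sep="\t", index=False)
        return {k: str(v) for k, v in paths.items()}


def _scaled_count(k_of_16: int, n_pairs: int) -> int:
    return int(round(k_of_16 * n_pairs / DEFAULT_N_PAIRS))


def simulate_cohort(
    base_config: SimulationConfig | None = None,
    n_pairs: int = DEFAULT_N_PAIRS,
    exposures: Sequence[str] | None = None,
    timings: Sequence[str] | None = None,
    group_discordance: Mapping[str, float] = DEFAULT_GROUP_DISCORDANCE,
    group_loh_met: Mapping[str, float] = DEFAULT_GROUP_LOH_MET,
    group_loh_primary: Mapping[str, float] = DEFAULT_GROUP_LOH_PRIMARY,
    discordance_sd: float = DEFAULT_DISCORDANCE_SD,
    loh_sd: float = DEFAULT_LOH_SD,
    n_wgd_both: int | None = None,
    n_wgd_met_only: int | None = None,
    gene_panel: Sequence[GeneModel] | None = None,
    seed: int | None = None,
) -> CohortSimulation:
    """Simulate a paired cohort mirroring the 16-patient study design.

    Parameters
    ----------
    base_config
        Template per-pair config; per-pair targets, WGD flags and seeds
        are derived from it.
    n_pairs
        Number of patients; default 16.
    exposures, timings
        Per-pair group labels; defaults scale the study's 10 naive /
        6 post-therapy and 9 synchronous / 7 metachronous split and
        shuffle the assignment.
    group_discordance, group_loh_met, group_loh_primary
        Planted per-group mean fractions; per-pair values are drawn from
        clipped normals with ``discordance_sd`` / ``loh_sd``.
    n_wgd_both, n_wgd_met_only
        Pairs with doubling of both branches / the metastasis only
        (defaults scale the study's 4 and 5 of 16).
    seed
        Overrides ``base_config.seed`` for the cohort-level draws.

    Raises
    ------
    ValidationError
        If a group-label list does not match ``n_pairs`` or uses labels
        absent from the group-mean maps.
    """
    if n_pairs < 1:
        raise ValidationError("n_pairs must be >= 1")
    base = base_config if base_config is not None else SimulationConfig()
    rng = np.random.default_rng(base.seed if seed is None else seed)

    if exposures is None:
        n_post = _scaled_count(DEFAULT_N_POST_THERAPY, n_pairs)
        exposures = ["post_therapy"] * n_post + ["naive"] * (n_pairs - n_post)
        exposures = list(rng.permutation(exposures))
    if timings is None:
        n_meta = _scaled_count(DEFAULT_N_METACHRONOUS, n_pairs)
        timings = ["metachronous"] * n_meta + ["synchronous"] * (n_pairs - n_meta)
        timings = list(rng.permutation(timings))
    for name, labels, allowed in (
        ("exposures", exposures, set(group_discordance)),
        ("timings", timings, {"synchronous", "metachronous"}),
    ):
        if len(labels) != n_pairs:
            raise ValidationError(f"{name} has {len(labels)} entries for {n_pairs} pairs")
        if set(labels) - allowed:
            raise ValidationError(f"{name} contains labels outside {sorted(allowed)}")

    if n_wgd_both is None:
        n_wgd_both = _scaled_count(DEFAULT_N_WGD_BOTH, n_pairs)
    if n_wgd_met_only is None:
        n_wgd_met_only = _scaled_count(DEFAULT_N_WGD_MET_ONLY, n_pairs)
    if n_wgd_both + n_wgd_met_only > n_pairs:
        raise ValidationError("WGD pair counts exceed n_pairs")
    wgd_flags = (
        [("both")] * n_wgd_both
        + ["met_only"] * n_wgd_met_only
        + ["none"] * (n_pairs - n_wgd_both - n_wgd_met_only)
    )
    wgd_flags = list(rng.permutation(wgd_flags))

    def draw_target(mean: float, sd: float) -> float:
        return float(np.clip(rng.normal(mean, sd), 0.0, 0.8))

    genes = (
        list(gene_panel)
        if gene_panel is not None
        else make_gene_panel(base.layout, seed=int(rng.integers(0, 2**31 - 1)))
    )

    pairs: list[PairRecord] = []
    profiles: dict[str, SegmentedProfile] = {}
    truths: dict[str, GroundTruth] = {}
    configs: dict[str, SimulationConfig] = {}
    for i in range(n_pairs):
        patient = f"P{i + 1:02d}"
        exposure = exposures[i]
        cfg = dataclasses.replace(
            base,
            target_discordance=draw_target(group_discordance[exposure], discordance_sd),
            target_loh_met=draw_target(group_loh_met[exposure], loh_sd),
            target_loh_primary=draw_target(group_loh_primary[exposure], loh_sd),
            wgd_primary=wgd_flags[i] == "both",
            wgd_met=wgd_flags[i] in ("both", "met_only"),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        primary, met, truth = simulate_pair(cfg, patient)
        purity_p = round(float(rng.uniform(0.55, 0.95)), 2)
        purity_m = round(float(rng.uniform(0.55, 0.98)), 2)
        pairs.append(
            PairRecord(
                patient_id=patient,
                primary_sample=primary.sample_id,
                met_sample=met.sample_id,
                timing=timings[i],
                met_exposure=exposure,
                purity_primary=purity_p,
                purity_met=purity_m,
            )
        )
        profiles[primary.sample_id] = primary
        profiles[met.sample_id] = met
        truths[patient] = truth
        configs[patient] = cfg
    return CohortSimulation(
        layout=base.layout,
        pairs=pairs,
        profiles=profiles,
        truths=truths,
        configs=configs,
        genes=genes,
    )
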