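"""Brute-force per-base reference implementations used only by tests.

Everything here trades efficiency for obviousness: states are expanded
to one entry per base pair and rules are applied by direct counting, so
the vectorized implementations in the package can be checked exactly on
small genomes.
"""

from __future__ import annotations

import math

import numpy as np

from pairedcna.profiles_io import GenomeLayout, SegmentedProfile


def per_base_arrays(profile: SegmentedProfile, layout: GenomeLayout):
    """chrom -> (total, minor, segment_index) per-base arrays; -1 = no data."""
    out = {}
    seg_index = 0
    rows_by_chrom: dict[str, list] = {c: [] for c in layout.names}
    for row in profile.data.itertuples(index=False):
        rows_by_chrom[row.chromosome].append(row)
    for chrom in layout.names:
        L = layout.length(chrom)
        t = np.full(L, -1, dtype=np.int64)
        m = np.full(L, -1, dtype=np.int64)
        sid = np.full(L, -1, dtype=np.int64)
        for row in rows_by_chrom[chrom]:
            t[row.start : row.end] = row.total_cn
            m[row.start : row.end] = row.minor_cn
            sid[row.start : row.end] = seg_index
            seg_index += 1
        out[chrom] = (t, m, sid)
    return out


def brute_window_states(profile: SegmentedProfile, layout: GenomeLayout, window_size: int):
    """Largest-overlap window assignment by per-base counting.

    For every window, count the bases contributed by each distinct
    segment and take the segment with the most bases; ties go to the
    segment with the smaller start (segments are enumerated in sorted
    order, so the smaller index has the smaller start).
    """
    arrays = per_base_arrays(profile, layout)
    totals, minors = [], []
    for chrom in layout.names:
        L = layout.length(chrom)
        t, m, sid = arrays[chrom]
        for ws_start in range(0, L, window_size):
            ws_end = min(ws_start + window_size, L)
            ids, counts = np.unique(sid[ws_start:ws_end], return_counts=True)
            mask = ids >= 0
            ids, counts = ids[mask], counts[mask]
            if len(ids) == 0:
                totals.append(-1)
                minors.append(-1)
                continue
            best = ids[np.lexsort((ids, -counts))][0]
            base = np.flatnonzero(sid[ws_start:ws_end] == best)[0] + ws_start
            totals.append(int(t[base]))
            minors.append(int(m[base]))
    return np.array(totals), np.array(minors)


def brute_chrom_fractions(profile: SegmentedProfile, layout: GenomeLayout):
    """Per-chromosome biallelic-3/4 fraction by base counting."""
    arrays = per_base_arrays(profile, layout)
    fractions = {}
    for chrom in layout.names:
        t, m, _ = arrays[chrom]
        qualifying = ((t == 3) | (t == 4)) & (m >= 1)
        fractions[chrom] = qualifying.sum() / layout.length(chrom)
    return fractions


def brute_genome_fractions(profile: SegmentedProfile, layout: GenomeLayout):
    """(altered, loh) fractions over covered bases, by base counting."""
    arrays = per_base_arrays(profile, layout)
    covered = altered = loh = 0
    for chrom in layout.names:
        t, m, _ = arrays[chrom]
        has = t >= 0
        covered += has.sum()
        altered += (has & (t != 2)).sum()
        loh += (has & (m == 0) & (t >= 1)).sum()
    return altered / covered, loh / covered


def brute_compare(tp, mp, tm, mm, correction: bool):
    """Pair comparison by per-window scalar rule application."""
    n = cn_disc = unchanged = loh_met = loh_prim = 0
    for i in range(len(tp)):
        if tp[i] < 0 or tm[i] < 0:
            continue
        n += 1
        lp = mp[i] == 0 and tp[i] >= 1
        lm = mm[i] == 0 and tm[i] >= 1
        diff = tm[i] - tp[i]
        ok = diff == 0 or (correction and diff in (1, 2) and lp == lm)
        if not ok:
            cn_disc += 1
        if lp == lm:
            unchanged += 1
        elif lm:
            loh_met += 1
        else:
            loh_prim += 1
    return n, cn_disc, unchanged, loh_met, loh_prim


def pooled_t(a, b):
    """Textbook pooled-variance two-sample t and two-sided p."""
    from scipy.stats import t as tdist

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t_stat = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * tdist.sf(abs(t_stat), na + nb - 2)
    return t_stat, p


def random_profile(rng, layout: GenomeLayout, sample_id: str, max_segments: int = 20):
    """A random valid profile: sorted, non-overlapping, gaps allowed."""
    import pandas as pd

    rows = []
    n_total = int(rng.integers(1, max_segments + 1))
    states = [(0, 0), (1, 0), (2, 0), (2, 1), (3, 1), (4, 2), (4, 0), (5, 1), (6, 2), (7, 0)]
    for _ in range(n_total):
        chrom = layout.names[int(rng.integers(0, len(layout)))]
        L = layout.length(chrom)
        start = int(rng.integers(0, L - 1))
        end = int(rng.integers(start + 1, L + 1))
        t, m = states[int(rng.integers(0, len(states)))]
        rows.append((chrom, start, end, t, m))
    # drop overlaps, keeping earlier rows
    kept = []
    for chrom, start, end, t, m in sorted(rows, key=lambda r: (r[0], r[1])):
        if kept and kept[-1][0] == chrom and start < kept[-1][2]:
            continue
        kept.append((chrom, start, end, t, m))
    df = pd.DataFrame(kept, columns=["chromosome", "start", "end", "total_cn", "minor_cn"])
    return SegmentedProfile(sample_id, df, layout)
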