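"""Domain types, copy-number state classification, and tabular I/O.

Segmented allele-specific copy-number profiles are the input boundary of
this package: each sample is a set of non-overlapping genomic intervals
annotated with total and minor-allele integer copy number, as produced by
upstream SNP-array (or sequencing) segmentation.  This module defines the
in-memory containers (:class:`GenomeLayout`, :class:`SegmentedProfile`,
:class:`GeneModel`, :class:`PairRecord`), the five-category copy-number
state classification used throughout, and readers/writers for the plain
TSV formats (SEG-like profile, chromosome sizes, BED4+panel gene
annotation, paired sample sheet).

Coordinates are 0-based half-open (BED convention) everywhere, in files
and in memory.
"""

from __future__ import annotations

import dataclasses
import enum
import warnings
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CNCategory",
    "GeneModel",
    "GenomeLayout",
    "PairRecord",
    "ParseError",
    "Segment",
    "SegmentedProfile",
    "ValidationError",
    "classify_state",
    "classify_states",
    "is_loh",
    "read_chrom_sizes",
    "read_gene_annotation",
    "read_profile",
    "read_profiles",
    "read_sample_sheet",
    "write_profile",
    "write_sample_sheet",
]

PROFILE_COLUMNS = ["sample_id", "chromosome", "start", "end", "total_cn", "minor_cn"]
SHEET_COLUMNS = [
    "patient_id",
    "primary_sample",
    "met_sample",
    "timing",
    "met_exposure",
    "purity_primary",
    "purity_met",
]

TIMINGS = ("synchronous", "metachronous")
EXPOSURES = ("naive", "post_therapy")
ROLES = ("primary", "metastasis", "normal")

MIN_PURITY = 0.5  # study inclusion threshold; below it we warn, not fail


class ValidationError(ValueError):
    """An in-memory object violates a domain invariant."""


class ParseError(ValueError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = f"{path}:{line}: " if line is not None else (f"{path}: " if path else "")
        super().__init__(f"{loc}{message}")
        self.path = path
        self.line = line


class CNCategory(str, enum.Enum):
    """Five-state copy-number category plus the diploid-heterozygous baseline.

    The five altered states are homozygous deletion (total CN 0), loss
    (CN 1), copy-neutral LOH (CN 2 with minor allele absent), gain
    (CN 3-5) and amplification (CN >= 6); ``NEUTRAL_HET`` is the normal
    (2,1) state.
    """

    HOMDEL = "HOMDEL"
    LOSS = "LOSS"
    NEUTRAL_HET = "NEUTRAL_HET"
    CN_LOH = "CN_LOH"
    GAIN = "GAIN"
    AMP = "AMP"


# stable integer codes for vectorized classification
_CATEGORY_BY_CODE = [
    CNCategory.HOMDEL,
    CNCategory.LOSS,
    CNCategory.NEUTRAL_HET,
    CNCategory.CN_LOH,
    CNCategory.GAIN,
    CNCategory.AMP,
]
CATEGORY_CODES: Mapping[CNCategory, int] = {c: i for i, c in enumerate(_CATEGORY_BY_CODE)}
MISSING_CODE = -1


def _validate_cn(total_cn: int, minor_cn: int) -> None:
    if total_cn < 0 or minor_cn < 0:
        raise ValidationError(
            f"copy numbers must be non-negative, got (total={total_cn}, minor={minor_cn})"
        )
    if minor_cn > total_cn - minor_cn:
        raise ValidationError(
            f"minor_cn must be the lesser allele (minor <= total - minor), "
            f"got (total={total_cn}, minor={minor_cn})"
        )


def classify_state(total_cn: int, minor_cn: int) -> CNCategory:
    """Classify an allele-specific copy-number pair into a category.

    Parameters
    ----------
    total_cn
        Total integer copy number of the interval.
    minor_cn
        Copy number of the minor (lesser) parental allele.

    Returns
    -------
    CNCategory

    Notes
    -----
    Total copy number above 8 is still classified ``AMP`` (open-ended top
    bin) with a warning: the category table caps at 8 only because higher
    values are rare on arrays.
    """
    total_cn = int(total_cn)
    minor_cn = int(minor_cn)
    _validate_cn(total_cn, minor_cn)
    if total_cn == 0:
        return CNCategory.HOMDEL
    if total_cn == 1:
        return CNCategory.LOSS
    if total_cn == 2:
        return CNCategory.CN_LOH if minor_cn == 0 else CNCategory.NEUTRAL_HET
    if total_cn <= 5:
        return CNCategory.GAIN
    if total_cn > 8:
        warnings.warn(
            "total_cn exceeds the nominal amplification cap of 8; classified AMP",
            stacklevel=2,
        )
    return CNCategory.AMP


def classify_states(total_cn: np.ndarray, minor_cn: np.ndarray) -> np.ndarray:
    """Vectorized :func:`classify_state`; returns int8 category codes.

    Entries with ``total_cn < 0`` are treated as missing and mapped to
    ``MISSING_CODE`` (-1).
    """
    t = np.asarray(total_cn)
    m = np.asarray(minor_cn)
    bad = (t >= 0) & ((m < 0) | (m > t - m))
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"invalid copy-number pair (total={t.flat[i]}, minor={m.flat[i]})"
        )
    codes = np.select(
        [
            t < 0,
            t == 0,
            t == 1,
            (t == 2) & (m == 0),
            t == 2,
            t <= 5,
        ],
        [
            MISSING_CODE,
            CATEGORY_CODES[CNCategory.HOMDEL],
            CATEGORY_CODES[CNCategory.LOSS],
            CATEGORY_CODES[CNCategory.CN_LOH],
            CATEGORY_CODES[CNCategory.NEUTRAL_HET],
            CATEGORY_CODES[CNCategory.GAIN],
        ],
        default=CATEGORY_CODES[CNCategory.AMP],
    ).astype(np.int8)
    return codes


def category_from_code(code: int) -> CNCategory | None:
    return None if code == MISSING_CODE else _CATEGORY_BY_CODE[code]


def is_loh(total_cn: int, minor_cn: int) -> bool:
    """True when one parental allele is absent at a retained locus.

    Homozygous deletion (total = 0) is not counted as LOH.
    """
    return minor_cn == 0 and total_cn >= 1


@dataclasses.dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths; the canonical coordinate frame.

    The order given here is the sort order used by every downstream
    per-chromosome output, window grid and profile.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names in layout")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def __contains__(self, name: str) -> bool:
        return name in self.lengths

    def __len__(self) -> int:
        return len(self.chromosomes)

    def length(self, name: str) -> int:
        try:
            return self.lengths[name]
        except KeyError:
            raise ValidationError(f"unknown chromosome {name!r}") from None

    def rank(self, name: str) -> int:
        """Position of a chromosome in the canonical order."""
        return self.names.index(name)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.chromosomes, columns=["name", "length"]).to_csv(
            path, sep="\t", index=False, header=False
        )


def read_chrom_sizes(path) -> GenomeLayout:
    """Read a 2-column (name, length) TSV into a :class:`GenomeLayout`."""
    chroms: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError("expected 2 tab-separated columns", path, lineno)
            try:
                length = int(parts[1])
            except ValueError:
                raise ParseError(f"non-integer length {parts[1]!r}", path, lineno) from None
            chroms.append((parts[0], length))
    return GenomeLayout(tuple(chroms))


@dataclasses.dataclass(frozen=True)
class Segment:
    """One constant-state genomic interval (0-based half-open)."""

    chromosome: str
    start: int
    end: int
    total_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"segment {self.chromosome}:{self.start}-{self.end} has start >= end"
            )
        _validate_cn(self.total_cn, self.minor_cn)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def loh(self) -> bool:
        return is_loh(self.total_cn, self.minor_cn)

    @property
    def category(self) -> CNCategory:
        return classify_state(self.total_cn, self.minor_cn)


class SegmentedProfile:
    """One sample's allele-specific segmented copy-number profile.

    Wraps a pandas DataFrame with columns ``chromosome, start, end,
    total_cn, minor_cn``, kept sorted in layout order with segments
    non-overlapping within each chromosome.

    Parameters
    ----------
    sample_id
        Sample identifier (matches the sample sheet).
    data
        Segment table; validated, sorted and copied on construction.
    layout
        Coordinate frame; all segments must lie inside it.
    role
        ``primary``, ``metastasis`` or ``normal`` (metadata only).
    purity
        Tumor-cell fraction in [0, 1], optional metadata.  Values below
        0.5 (the usual array-analysis inclusion threshold) warn.
    """

    def __init__(
        self,
        sample_id: str,
        data: pd.DataFrame,
        layout: GenomeLayout,
        role: str = "primary",
        purity: float | None = None,
    ) -> None:
        if role not in ROLES:
            raise ValidationError(f"role must be one of {ROLES}, got {role!r}")
        if purity is not None and not (0.0 <= purity <= 1.0):
            raise ValidationError(f"purity must be in [0, 1], got {purity}")
        if purity is not None and purity < MIN_PURITY:
            warnings.warn(
                f"sample {sample_id!r} has purity {purity:.2f} < {MIN_PURITY}; "
                "copy-number calls may be unreliable",
                stacklevel=2,
            )
        self.sample_id = str(sample_id)
        self.role = role
        self.purity = purity
        self.layout = layout
        df = data.loc[:, ["chromosome", "start", "end", "total_cn", "minor_cn"]].copy()
        df["chromosome"] = df["chromosome"].astype(str)
        for col in ("start", "end", "total_cn", "minor_cn"):
            df[col] = df[col].astype(np.int64)
        self._df = self._validate(df)

    def _validate(self, df: pd.DataFrame) -> pd.DataFrame:
        unknown = set(df["chromosome"]) - set(self.layout.names)
        if unknown:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown chromosome(s) {sorted(unknown)}"
            )
        rank = {c: i for i, c in enumerate(self.layout.names)}
        df = df.sort_values(
            ["chromosome", "start"], key=lambda s: s.map(rank) if s.name == "chromosome" else s
        ).reset_index(drop=True)
        if (df["start"] >= df["end"]).any():
            row = df[df["start"] >= df["end"]].iloc[0]
            raise ValidationError(
                f"sample {self.sample_id!r}: segment "
                f"{row.chromosome}:{row.start}-{row.end} has start >= end"
            )
        if (df["total_cn"] < 0).any() or (df["minor_cn"] < 0).any():
            raise ValidationError(f"sample {self.sample_id!r}: negative copy number")
        bad = df["minor_cn"] > df["total_cn"] - df["minor_cn"]
        if bad.any():
            row = df[bad].iloc[0]
            raise ValidationError(
                f"sample {self.sample_id!r}: minor_cn > total_cn - minor_cn at "
                f"{row.chromosome}:{row.start}-{row.end} "
                f"(total={row.total_cn}, minor={row.minor_cn})"
            )
        for chrom, sub in df.groupby("chromosome", sort=False):
            if int(sub["end"].max()) > self.layout.length(chrom):
                raise ValidationError(
                    f"sample {self.sample_id!r}: segment beyond end of {chrom}"
                )
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if len(sub) > 1 and (starts[1:] < ends[:-1]).any():
                i = int(np.flatnonzero(starts[1:] < ends[:-1])[0])
                raise ValidationError(
                    f"sample {self.sample_id!r}: overlapping segments on {chrom} "
                    f"at {starts[i + 1]} < {ends[i]}"
                )
        return df

    @property
    def data(self) -> pd.DataFrame:
        """Segment table (read-only view; copy before mutating)."""
        return self._df

    @property
    def segments(self) -> Iterator[Segment]:
        for row in self._df.itertuples(index=False):
            yield Segment(row.chromosome, row.start, row.end, row.total_cn, row.minor_cn)

    def __len__(self) -> int:
        return len(self._df)

    def covered_length(self) -> int:
        return int((self._df["end"] - self._df["start"]).sum())

    def chromosome_table(self, chromosome: str) -> pd.DataFrame:
        return self._df[self._df["chromosome"] == chromosome]

    @classmethod
    def from_segments(
        cls,
        sample_id: str,
        segments: Iterable[Segment],
        layout: GenomeLayout,
        role: str = "primary",
        purity: float | None = None,
    ) -> "SegmentedProfile":
        rows = [
            (s.chromosome, s.start, s.end, s.total_cn, s.minor_cn) for s in segments
        ]
        df = pd.DataFrame(rows, columns=["chromosome", "start", "end", "total_cn", "minor_cn"])
        return cls(sample_id, df, layout, role=role, purity=purity)


def _read_profile_table(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except Exception as exc:  # malformed TSV structure
        raise ParseError(f"cannot read profile table: {exc}", path) from exc
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing column(s) {missing}", path, line=1)
    # header is line 1 (comments above the header would shift this, which
    # we accept: line numbers are best-effort diagnostics)
    for col in ("start", "end", "total_cn", "minor_cn"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() | (converted % 1 != 0)
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-integer {col} value {df[col].iloc[idx]!r}", path, line=idx + 2
            )
        df[col] = converted.astype(np.int64)
    return df


def read_profiles(
    path,
    layout: GenomeLayout,
    roles: Mapping[str, str] | None = None,
    purities: Mapping[str, float] | None = None,
) -> dict[str, SegmentedProfile]:
    """Read a (possibly multi-sample) SEG-like TSV into profiles by sample."""
    df = _read_profile_table(path)
    out: dict[str, SegmentedProfile] = {}
    for sample_id, sub in df.groupby("sample_id", sort=False):
        try:
            out[sample_id] = SegmentedProfile(
                sample_id,
                sub,
                layout,
                role=(roles or {}).get(sample_id, "primary"),
                purity=(purities or {}).get(sample_id),
            )
        except ValidationError as exc:
            raise ParseError(str(exc), path) from exc
    return out


def read_profile(
    path,
    layout: GenomeLayout,
    sample_id: str | None = None,
    role: str = "primary",
    purity: float | None = None,
) -> SegmentedProfile:
    """Read a single sample's profile from a SEG-like TSV.

    If the file contains several samples, ``sample_id`` selects one.
    """
    df = _read_profile_table(path)
    samples = df["sample_id"].unique().tolist()
    if sample_id is None:
        if len(samples) != 1:
            raise ParseError(
                f"file contains {len(samples)} samples {samples}; pass sample_id",
                path,
            )
        sample_id = samples[0]
    elif sample_id not in samples:
        raise ParseError(f"sample {sample_id!r} not present in file", path)
    sub = df[df["sample_id"] == sample_id]
    try:
        return SegmentedProfile(sample_id, sub, layout, role=role, purity=purity)
    except ValidationError as exc:
        raise ParseError(str(exc), path) from exc


def write_profile(profiles: SegmentedProfile | Sequence[SegmentedProfile], path) -> None:
    """Write one or more profiles to a SEG-like TSV (fixed column order)."""
    if isinstance(profiles, SegmentedProfile):
        profiles = [profiles]
    frames = []
    for p in profiles:
        df = p.data.copy()
        df.insert(0, "sample_id", p.sample_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, columns=PROFILE_COLUMNS, lineterminator="\n"
    )


@dataclasses.dataclass(frozen=True)
class GeneModel:
    """A gene footprint: TSS to the last base of the longest transcript."""

    symbol: str
    chromosome: str
    start: int
    end: int
    panel: str = "candidate188"  # candidate188 | actionable24 | both

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"gene {self.symbol}: start >= end")
        if self.panel not in ("candidate188", "actionable24", "both"):
            raise ValidationError(f"gene {self.symbol}: unknown panel {self.panel!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def read_gene_annotation(path, layout: GenomeLayout) -> list[GeneModel]:
    """Read a BED4(+panel) gene annotation, validated against a layout."""
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError("expected at least 4 BED columns", path, lineno)
            chrom, start_s, end_s, symbol = parts[:4]
            panel = parts[4] if len(parts) > 4 and parts[4] else "candidate188"
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError("non-integer coordinate", path, lineno) from None
            if chrom not in layout:
                raise ParseError(f"unknown chromosome {chrom!r}", path, lineno)
            if end > layout.length(chrom):
                raise ParseError(f"gene {symbol} extends beyond {chrom}", path, lineno)
            if symbol in seen:
                raise ParseError(f"duplicate gene symbol {symbol!r}", path, lineno)
            seen.add(symbol)
            try:
                genes.append(GeneModel(symbol, chrom, start, end, panel))
            except ValidationError as exc:
                raise ParseError(str(exc), path, lineno) from exc
    return genes


def write_gene_annotation(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chromosome}\t{g.start}\t{g.end}\t{g.symbol}\t{g.panel}\n")


@dataclasses.dataclass(frozen=True)
class PairRecord:
    """One patient's primary/metastasis pairing with grouping metadata."""

    patient_id: str
    primary_sample: str
    met_sample: str
    timing: str  # synchronous | metachronous
    met_exposure: str  # naive | post_therapy
    purity_primary: float | None = None
    purity_met: float | None = None

    def __post_init__(self) -> None:
        if self.primary_sample == self.met_sample:
            raise ValidationError(
                f"patient {self.patient_id}: primary and metastasis samples must differ"
            )
        if self.timing not in TIMINGS:
            raise ValidationError(
                f"patient {self.patient_id}: timing must be one of {TIMINGS}"
            )
        if self.met_exposure not in EXPOSURES:
            raise ValidationError(
                f"patient {self.patient_id}: met_exposure must be one of {EXPOSURES}"
            )


def read_sample_sheet(path) -> list[PairRecord]:
    """Read the paired sample sheet TSV into :class:`PairRecord` rows."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except Exception as exc:
        raise ParseError(f"cannot read sample sheet: {exc}", path) from exc
    required = SHEET_COLUMNS[:5]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"missing column(s) {missing}", path, line=1)
    records: list[PairRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        def _purity(col: str):
            if col not in df.columns:
                return None
            val = getattr(row, col)
            return None if pd.isna(val) or val == "" else float(val)

        try:
            records.append(
                PairRecord(
                    patient_id=row.patient_id,
                    primary_sample=row.primary_sample,
                    met_sample=row.met_sample,
                    timing=row.timing,
                    met_exposure=row.met_exposure,
                    purity_primary=_purity("purity_primary"),
                    purity_met=_purity("purity_met"),
                )
            )
        except ValidationError as exc:
            raise ParseError(str(exc), path, line=i + 2) from exc
    return records


def write_sample_sheet(pairs: Sequence[PairRecord], path) -> None:
    rows = [
        (
            p.patient_id,
            p.primary_sample,
            p.met_sample,
            p.timing,
            p.met_exposure,
            "" if p.purity_primary is None else p.purity_primary,
            "" if p.purity_met is None else p.purity_met,
        )
        for p in pairs
    ]
    pd.DataFrame(rows, columns=SHEET_COLUMNS).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )
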