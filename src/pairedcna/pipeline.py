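"""End-to-end orchestration: profiles -> WGD -> discordance -> genes -> cohort.

Every stage writes a TSV with a commented header carrying the package
version, a hash of the run configuration and the seed, so reruns with an
identical configuration produce byte-identical files; a manifest records
a SHA-256 checksum per output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import cohort_means, default_comparisons, summarize_cohort
from .discordance import assign_windows, compare_pair, genome_fractions, tile_genome
from .genes import concordance_rate, gene_status, private_events
from .profiles_io import (
    read_chrom_sizes,
    read_gene_annotation,
    read_profiles,
    read_sample_sheet,
)
from .wgd import detect_wgd

__all__ = ["RunConfig", "StageError", "run_pipeline"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end run."""

    profiles: str
    chrom_sizes: str
    sample_sheet: str
    genes: str | None = None
    outdir: str = "pairedcna_out"
    window_size: int = 10_000
    wgd_correction: bool = True
    strict_gene_events: bool = False
    per_window: bool = False
    seed: int = 0

    def config_hash(self) -> str:
        # outdir is excluded: where results land must not change them
        payload = dataclasses.asdict(self)
        payload.pop("outdir")
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise StageError("config", f"unknown config key(s) {sorted(unknown)}")
        return cls(**raw)


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# pairedcna {__version__}\tconfig={config.config_hash()}\tseed={config.seed}\n"
        )
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Run every analysis stage; returns the output manifest (path -> sha256).

    Raises
    ------
    StageError
        Any stage failure, named after the stage that raised it.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, str(exc)) from exc

    for name, path in (
        ("inputs", config.profiles),
        ("inputs", config.chrom_sizes),
        ("inputs", config.sample_sheet),
    ):
        if not Path(path).exists():
            raise StageError(name, f"missing input file {path}")
    if config.genes is not None and not Path(config.genes).exists():
        raise StageError("inputs", f"missing gene annotation {config.genes}")

    layout = stage("read", read_chrom_sizes, config.chrom_sizes)
    pairs = stage("read", read_sample_sheet, config.sample_sheet)
    roles = {}
    purities = {}
    for p in pairs:
        roles[p.primary_sample] = "primary"
        roles[p.met_sample] = "metastasis"
        purities[p.primary_sample] = p.purity_primary
        purities[p.met_sample] = p.purity_met
    purities = {k: v for k, v in purities.items() if v is not None}
    profiles = stage("read", read_profiles, config.profiles, layout, roles, purities)
    for p in pairs:
        for s in (p.primary_sample, p.met_sample):
            if s not in profiles:
                raise StageError("read", f"sample {s!r} (patient {p.patient_id}) not in profiles")

    logger.info("read %d samples, %d pairs", len(profiles), len(pairs))
    outputs: dict[str, pd.DataFrame] = {}

    # whole-genome duplication + genome fractions per sample
    wgd_calls = {s: stage("wgd", detect_wgd, prof, layout) for s, prof in profiles.items()}
    fracs = {s: stage("fractions", genome_fractions, prof) for s, prof in profiles.items()}
    outputs["wgd_calls.tsv"] = pd.DataFrame(
        [
            {
                "sample_id": s,
                "is_wgd": c.is_wgd,
                "qualifying_chromosomes": c.qualifying_chromosomes,
                "genome_fraction_34_biallelic": c.genome_fraction_34_biallelic,
            }
            for s, c in wgd_calls.items()
        ]
    )

    # windowed pair discordance
    grid = stage("windows", tile_genome, layout, config.window_size)
    tracks = {s: stage("windows", assign_windows, prof, grid) for s, prof in profiles.items()}
    results = {}
    per_window_frames = []
    for p in pairs:
        res = stage(
            "compare",
            compare_pair,
            tracks[p.primary_sample],
            tracks[p.met_sample],
            config.wgd_correction,
            p.patient_id,
        )
        res.wgd_primary = wgd_calls[p.primary_sample].is_wgd
        res.wgd_met = wgd_calls[p.met_sample].is_wgd
        results[p.patient_id] = res
        if config.per_window:
            pw = res.to_frame()
            pw.insert(0, "patient_id", p.patient_id)
            per_window_frames.append(pw)
    outputs["pair_discordance.tsv"] = pd.DataFrame([r.summary() for r in results.values()])
    if per_window_frames:
        outputs["per_window_labels.tsv"] = pd.concat(per_window_frames, ignore_index=True)

    # gene-level status and private events
    if config.genes is not None:
        genes = stage("genes", read_gene_annotation, config.genes, layout)
        status_frames = [stage("genes", gene_status, prof, genes) for prof in profiles.values()]
        statuses = pd.concat(status_frames, ignore_index=True)
        outputs["gene_status.tsv"] = statuses
        summary = stage("genes", private_events, pairs, statuses, genes, config.strict_gene_events)
        outputs["private_events.tsv"] = summary.table
        outputs["private_events_formatted.tsv"] = summary.formatted()
        n_conc, frac, per_gene = stage(
            "genes", concordance_rate, pairs, statuses, genes, config.wgd_correction
        )
        outputs["gene_concordance.tsv"] = pd.DataFrame(
            {
                "symbol": per_gene.index,
                "concordant": per_gene.values,
            }
        )
        outputs["gene_concordance_summary.tsv"] = pd.DataFrame(
            [
                {
                    "n_genes": int(per_gene.notna().sum()),
                    "n_concordant": n_conc,
                    "concordant_fraction": frac,
                }
            ]
        )

    # cohort summary and group comparisons
    table = stage("cohort", summarize_cohort, pairs, results, wgd_calls, fracs)
    outputs["cohort.tsv"] = table
    outputs["cohort_means.tsv"] = cohort_means(table)
    comparisons = stage("cohort", default_comparisons, table)
    outputs["group_comparisons.tsv"] = comparisons

    manifest: dict[str, str] = {}
    for fname, df in outputs.items():
        path = outdir / fname
        _write_tsv(df, path, config)
        manifest[fname] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest_df = pd.DataFrame(sorted(manifest.items()), columns=["file", "sha256"])
    _write_tsv(manifest_df, outdir / "manifest.tsv", config)
    logger.info("wrote %d outputs to %s", len(manifest), outdir)
    return manifest
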