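"""End-to-end orchestration: generator -> counting -> TE -> reports.

A :class:`RunConfig` fully determines a run; outputs are plain TSV plus a
manifest listing every table with a SHA-256 checksum, so two runs of the
same config produce byte-identical manifests.  The log (timings, QC tallies)
is the only non-deterministic artifact and is excluded from the manifest.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from itertools import chain
from pathlib import Path

import yaml

from . import counting, synthetic_data, te_analysis
from .counting import LibraryMeta
from .io_formats import write_alignments, write_annotation

__all__ = ["RunConfig", "run_end_to_end"]

logger = logging.getLogger("mitoribo")


@dataclass(frozen=True)
class RunConfig:
    """Validated parameters of one end-to-end run; seed is mandatory."""

    seed: int
    out_dir: str
    n_reads: int = 200_000
    spike_read_fraction: float = 0.05
    softclip_prob: float = 0.1
    rpf_length_mean_rescue: float = 33.0
    rpf_length_mean_ko: float = 31.0
    rpf_length_sd: float = 2.0
    pseudocount: float = 0.0
    write_sam: bool = False
    rna_fold_overrides: dict = field(default_factory=dict)
    te_fold_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if not (0 < self.spike_read_fraction < 1):
            raise ValueError("spike_read_fraction must lie in (0, 1)")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError(f"{path}: config must set a seed")
        if "out_dir" not in raw:
            raise ValueError(f"{path}: config must set out_dir")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_end_to_end(config: RunConfig) -> Path:
    """Simulate, count, and analyze one KO-vs-rescue contrast.

    Writes annotation, preset, counts, QC, length-distribution and TE tables
    plus a checksum manifest into ``config.out_dir`` and returns that path.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    annotation = synthetic_data.make_mito_annotation()
    preset = synthetic_data.default_ko_preset()
    if config.rna_fold_overrides or config.te_fold_overrides:
        rna = {**preset.rna_fold, **config.rna_fold_overrides}
        te = {**preset.te_fold, **config.te_fold_overrides}
        preset = synthetic_data.KOPreset(rna, te)
    write_annotation(annotation, out / "annotation.tsv")
    _write_preset(preset, out / "preset.tsv")

    specs = synthetic_data.library_specs_for_contrast(
        n_reads=config.n_reads,
        seed=config.seed,
        spike_read_fraction=config.spike_read_fraction,
        rpf_length_mean_rescue=config.rpf_length_mean_rescue,
        rpf_length_mean_ko=config.rpf_length_mean_ko,
        rpf_length_sd=config.rpf_length_sd,
        softclip_prob=config.softclip_prob,
    )
    libraries = {s.library_id: LibraryMeta(s.assay, s.condition) for s in specs}

    logger.info("simulate: %d libraries x %d reads", len(specs), config.n_reads)
    if config.write_sam:
        for spec in specs:
            write_alignments(
                synthetic_data.sample_library(spec, annotation, preset),
                out / f"{spec.library_id}.sam",
                annotation,
            )

    stream = chain.from_iterable(
        synthetic_data.sample_library(s, annotation, preset) for s in specs
    )
    table = counting.count_features(stream, annotation, libraries)
    logger.info("count: QC\n%s", table.qc)
    table.counts.to_csv(out / "counts.tsv", sep="\t")
    table.qc.to_csv(out / "qc.tsv", sep="\t")

    rpf_stream = chain.from_iterable(
        synthetic_data.sample_library(s, annotation, preset) for s in specs if s.assay == "RPF"
    )
    dist = counting.length_distribution(rpf_stream, annotation, target_only=True)
    long = dist.counts.stack().rename("count").reset_index()
    long.columns = ["length", "library_id", "count"]
    frac = dist.fractions().stack().rename("fraction").reset_index()
    long["fraction"] = frac["fraction"]
    long.to_csv(out / "length_distribution.tsv", sep="\t", index=False)

    te = te_analysis.compute_te_result(table, pseudocount=config.pseudocount)
    te.to_csv(out / "te_results.tsv", sep="\t")

    # config.yaml embeds the output path, so it stays out of the manifest to
    # keep manifests comparable across output directories.
    tables = sorted(
        p
        for p in out.iterdir()
        if p.suffix in (".tsv", ".sam") and p.name != "manifest.tsv"
    )
    with open(out / "manifest.tsv", "w") as fh:
        fh.write("file\tsha256\n")
        for p in tables:
            fh.write(f"{p.name}\t{_sha256(p)}\n")
    logger.info("run complete in %.1fs -> %s", time.time() - t0, out)
    return out


def _write_preset(preset: synthetic_data.KOPreset, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("feature_id\trna_fold\tte_fold\n")
        for fid in sorted(preset.rna_fold):
            fh.write(f"{fid}\t{preset.rna_fold[fid]:.6g}\t{preset.te_fold[fid]:.6g}\n")
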