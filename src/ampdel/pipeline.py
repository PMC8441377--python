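"""Pipeline orchestration: simulate -> align -> quantify -> report.

Stages hand off through TSV files in the output directory so each stage can
be run, inspected and tested independently; a JSON manifest records package
version, parameters (including every filtering threshold in force), seeds and
SHA-256 checksums of all inputs, making silent input changes detectable and
reruns byte-reproducible for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .amplicon_model import (
    AmpliconReference,
    GuidePair,
    design_summary,
    load_guides_tsv,
    load_reference_fasta,
    make_pairs,
)
from .deletion_quant import (
    DEFAULT_WINDOW,
    aggregate_replicates,
    deletion_spectrum,
    make_calls,
    quantify_library,
)
from .split_alignment import FilterParams, align_and_classify, write_alignment_tsv
from .synthetic_reads import TruthConfig, simulate_library, write_fastq, write_truth_tsv

__all__ = ["ConfigError", "DataError", "RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3


class ConfigError(Exception):
    """Bad or missing configuration; CLI exit code 2."""


class DataError(Exception):
    """Malformed or empty data at some stage; CLI exit code 3."""


@dataclass
class RunConfig:
    reference_fasta: Path
    guides_tsv: Path
    outdir: Path
    fastqs: list[Path] = field(default_factory=list)
    simulate: dict | None = None  # TruthConfig fields + n_libraries
    window: int = DEFAULT_WINDOW
    filters: FilterParams = field(default_factory=FilterParams)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.reference_fasta = Path(self.reference_fasta)
        self.guides_tsv = Path(self.guides_tsv)
        self.outdir = Path(self.outdir)
        self.fastqs = [Path(p) for p in self.fastqs]
        if not self.reference_fasta.exists():
            raise ConfigError(f"reference file not found: {self.reference_fasta}")
        if not self.guides_tsv.exists():
            raise ConfigError(f"guide file not found: {self.guides_tsv}")
        for f in self.fastqs:
            if not f.exists():
                raise ConfigError(f"FASTQ not found: {f}")
        if not self.fastqs and self.simulate is None:
            raise ConfigError("need either fastqs or a simulate block")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} is not a mapping")
        filt = raw.pop("filters", {})
        try:
            return cls(filters=FilterParams(**filt), **raw)
        except TypeError as e:
            raise ConfigError(str(e)) from e


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _simulated_libraries(config: RunConfig, reference, pairs) -> list[tuple[str, Path]]:
    sim = dict(config.simulate)
    n_libraries = int(sim.pop("n_libraries", 3))
    out = []
    for i in range(n_libraries):
        lib_id = f"sim{i + 1}"
        tc = TruthConfig(
            reference=reference,
            pairs=tuple(pairs),
            seed=int(config.seed) + i,
            **sim,
        )
        reads, truth = simulate_library(tc)
        fq = config.outdir / f"{lib_id}.fastq"
        write_fastq(reads, fq)
        write_truth_tsv(truth, config.outdir / f"{lib_id}.truth.tsv")
        out.append((lib_id, fq))
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    config.outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    try:
        reference = load_reference_fasta(config.reference_fasta)
        guides = load_guides_tsv(config.guides_tsv, reference)
    except ValueError as e:
        raise ConfigError(str(e)) from e
    pairs = make_pairs(guides)
    if not pairs:
        raise ConfigError("guide design yields no upstream/downstream pairs")
    design_summary(reference, pairs).to_csv(
        config.outdir / "design_summary.tsv", sep="\t", index=False
    )

    if config.simulate is not None:
        try:
            libraries = _simulated_libraries(config, reference, pairs)
        except ValueError as e:
            raise ConfigError(str(e)) from e
    else:
        libraries = [(f.stem, f) for f in config.fastqs]

    from .split_alignment import read_fastx

    quants = []
    all_calls = []
    for lib_id, fq in libraries:
        reads = read_fastx(fq)
        if not reads:
            raise DataError(f"library {lib_id}: no reads in {fq}")
        aligned = align_and_classify(reads, reference, config.filters)
        write_alignment_tsv(aligned, config.outdir / f"{lib_id}.alignments.tsv")
        try:
            q = quantify_library(aligned, pairs, config.window, lib_id)
        except ValueError as e:
            raise DataError(f"library {lib_id}: {e}") from e
        quants.append(q)
        calls = make_calls(aligned, pairs, config.window)
        all_calls.extend(calls)
        pd.DataFrame(
            [
                {
                    "library_id": lib_id,
                    "read_id": c.read_id,
                    "start": c.start,
                    "end": c.end,
                    "size": c.size,
                    "assigned_pair": c.assigned_pair,
                }
                for c in calls
            ]
        ).to_csv(config.outdir / f"{lib_id}.calls.tsv", sep="\t", index=False)

    quant_df = pd.concat([q.to_frame() for q in quants], ignore_index=True)
    quant_df.to_csv(config.outdir / "library_quant.tsv", sep="\t", index=False)
    agg = aggregate_replicates(quants)
    agg.to_csv(config.outdir / "replicate_summary.tsv", sep="\t", index=False)

    if all_calls:
        spectrum, dispersion = deletion_spectrum(all_calls, pairs)
        spectrum.to_csv(config.outdir / "spectrum.tsv", sep="\t", index=False)
        dispersion.to_csv(config.outdir / "breakpoint_dispersion.tsv", sep="\t", index=False)

    # plot-ready long format: one row per library x pair with the deleted span
    cut = {p.pair_id: (p.us_guide.cut_site, p.ds_guide.cut_site) for p in pairs}
    long_rows = [
        {
            "library_id": q.library_id,
            "pair_id": pid,
            "us_cut_site": cut[pid][0],
            "ds_cut_site": cut[pid][1],
            "efficiency": q.efficiencies[pid],
        }
        for q in quants
        for pid in q.efficiencies
    ]
    pd.DataFrame(long_rows).to_csv(
        config.outdir / "deletion_map_long.tsv", sep="\t", index=False
    )

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "window_bp": config.window,
        "filters": dataclasses.asdict(config.filters),
        "reference": {"name": reference.name, "length": len(reference.sequence)},
        "libraries": [lib_id for lib_id, _ in libraries],
        "inputs_sha256": {
            str(config.reference_fasta): _sha256(config.reference_fasta),
            str(config.guides_tsv): _sha256(config.guides_tsv),
            **{str(fq): _sha256(fq) for _, fq in libraries},
        },
        "counts": {
            q.library_id: {
                "total": q.total_reads,
                "mapped": q.mapped_reads,
                "wt": q.wt_reads,
                "spliced": q.spliced_reads,
                "ambiguous": q.ambiguous_spliced,
                "unassigned": q.unassigned_spliced,
            }
            for q in quants
        },
    }
    with open(config.outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def render_report(outdir: str | Path, fmt: str = "png") -> Path:
    """Render the per-pair efficiency summary and deletion map to an image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    agg = pd.read_csv(outdir / "replicate_summary.tsv", sep="\t")
    long = pd.read_csv(outdir / "deletion_map_long.tsv", sep="\t")

    fig, axes = plt.subplots(1, 2, figsize=(11, 4.5))
    ax = axes[0]
    ax.bar(agg["pair_id"], 100 * agg["mean_efficiency"], yerr=100 * agg["sd"],
           color="#3b8686", capsize=3)
    ax.set_ylabel("deletion efficiency (%)")
    ax.set_xlabel("sgRNA pair")
    ax.tick_params(axis="x", rotation=45)

    ax = axes[1]
    libs = sorted(long["library_id"].unique())
    pairs_ = sorted(long["pair_id"].unique())
    y = 0
    for lib in libs:
        sub = long[long["library_id"] == lib]
        for _, row in sub.iterrows():
            ax.plot([row["us_cut_site"], row["ds_cut_site"]], [y, y],
                    lw=1 + 8 * row["efficiency"], color="#c94c4c",
                    solid_capstyle="butt")
            y += 1
    ax.set_yticks([])
    ax.set_xlabel("amplicon position (bp)")
    ax.set_title("deleted spans (line width ~ efficiency)")
    fig.tight_layout()
    out = outdir / f"report.{fmt}"
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
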