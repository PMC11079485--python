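"""One-command orchestration of the sweep scan.

Stages: read inputs -> hard filters -> MAF/call-rate filter -> (optional
LD pruning) -> windowed pi/F_ST/ROD -> top-tail dual thresholds -> region
merge -> gene overlap -> report.  Every run writes the window table, the
region BED, the flat gene list, a ``summary.json`` of per-stage counts and
realized thresholds, a log, and a manifest (effective config + input
checksums) so runs are reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io_formats import (
    FormatError,
    GenomicInterval,
    InputError,
    read_gff3,
    read_population_map,
    read_vcf,
    write_bed,
)
from .popgen_windows import WindowSpec, compute_window_stats, make_windows
from .sweep_scan import (
    empirical_threshold,
    genes_in_regions,
    merge_windows,
    regions_to_frame,
    select_sweep_windows,
)
from .variant_filtering import (
    HardFilterThresholds,
    LdPruneParams,
    apply_hard_filters,
    filter_maf_callrate,
    ld_prune,
)

__all__ = ["RunConfig", "run_scan", "PipelineError"]

log = logging.getLogger("domestiscan")


class PipelineError(Exception):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Effective parameters of one scan run (field defaults are the
    published study's settings where it states them)."""

    vcf: str = ""
    popmap: str = ""
    gff: str = ""  # empty -> gene step skipped
    pop1: str = "cultivated"  # the swept/domesticated population
    pop2: str = "wild"
    window_size: int = 100_000
    window_step: int = 10_000
    top: float = 0.05
    hard_filters: bool = True
    maf_min: float = 0.01
    call_rate_min: float = 0.9
    ld_prune: bool = False
    prune_window: int = 50
    prune_step: int = 10
    prune_r2: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.top <= 1.0):
            raise ValueError("top must be in (0, 1]")
        WindowSpec(self.window_size, self.window_step)  # validates
        LdPruneParams(self.prune_window, self.prune_step, self.prune_r2)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Parse a flat ``key=value`` config file; kwargs override file values."""
        values: dict[str, object] = {}
        fields = {f: t for f, t in cls.__annotations__.items()}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise FormatError(f"{path}:{lineno}: expected key=value")
                key, val = (x.strip() for x in line.split("=", 1))
                if key not in fields:
                    raise FormatError(f"{path}:{lineno}: unknown key {key!r}")
                values[key] = _coerce(val, str(fields[key]))
        values.update(overrides)
        return cls(**values)  # type: ignore[arg-type]


def _coerce(val: str, annotation: str) -> object:
    if "bool" in annotation:
        if val.lower() in {"true", "1", "yes"}:
            return True
        if val.lower() in {"false", "0", "no"}:
            return False
        raise FormatError(f"not a boolean: {val!r}")
    if "int" in annotation:
        return int(val)
    if "float" in annotation:
        return float(val)
    return val


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_scan(config: RunConfig, out_dir: str | Path) -> Path:
    """Run the full scan; returns the output directory.

    Deterministic given inputs and config.  On stage failure, partial
    outputs are removed and a stage-labelled :class:`PipelineError` is
    raised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run_scan_inner(config, out)
    except Exception as e:
        stage = getattr(e, "stage", "unknown")
        for name in ("windows.tsv", "regions.bed", "genes.txt", "summary.json"):
            (out / name).unlink(missing_ok=True)
        log.error("stage %s failed: %s", stage, e)
        raise PipelineError(f"stage {stage}: {e}") from e
    finally:
        log.removeHandler(handler)
        handler.close()


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not hasattr(exc, "stage"):
                try:
                    exc.stage = name  # type: ignore[attr-defined]
                except Exception:
                    pass
            if exc is None:
                log.info("stage %s: done", name)
            return False

    return _Ctx()


def _run_scan_inner(config: RunConfig, out: Path) -> Path:
    summary: dict = {"config": asdict(config), "version": __version__}

    with _stage("read"):
        gm, skipped = read_vcf(config.vcf, keep_info=config.hard_filters)
        popmap = read_population_map(config.popmap)
        pop1 = popmap.samples(config.pop1)
        pop2 = popmap.samples(config.pop2)
        if not pop1 or not pop2:
            raise InputError(
                f"population labels {config.pop1!r}/{config.pop2!r} not both present"
            )
        summary["input"] = {
            "sites": gm.n_sites,
            "skipped_records": skipped,
            "samples": gm.n_samples,
            "pop_sizes": {config.pop1: len(pop1), config.pop2: len(pop2)},
        }
        log.info(
            "read %d biallelic SNPs (%d records skipped), %d samples",
            gm.n_sites, skipped, gm.n_samples,
        )

    with _stage("filter"):
        if config.hard_filters:
            gm, per_rule = apply_hard_filters(gm)
            summary["hard_filter"] = {
                "removed_per_rule": per_rule,
                "sites_after": gm.n_sites,
            }
        n_before = gm.n_sites
        gm = filter_maf_callrate(gm, config.maf_min, config.call_rate_min)
        summary["maf_callrate"] = {
            "removed": n_before - gm.n_sites,
            "sites_after": gm.n_sites,
        }
        if config.ld_prune:
            kept = ld_prune(
                gm,
                LdPruneParams(config.prune_window, config.prune_step, config.prune_r2),
            )
            summary["ld_prune"] = {
                "removed": gm.n_sites - len(kept),
                "sites_after": len(kept),
            }
            gm = gm.take_sites(kept)
        log.info("%d sites remain after filtering", gm.n_sites)

    with _stage("windows"):
        if not gm.contig_lengths:
            raise InputError("no contig lengths in VCF header; cannot window")
        windows = make_windows(
            gm.contig_lengths, WindowSpec(config.window_size, config.window_step)
        )
        stats = compute_window_stats(gm, pop1, pop2, windows)
        stats.to_csv(out / "windows.tsv", sep="\t", index=False, float_format="%.8g")
        summary["windows"] = {
            "total": len(stats),
            "fst_defined": int(stats["fst"].notna().sum()),
            "rod_defined": int(stats["rod"].notna().sum()),
        }

    with _stage("sweep"):
        fst_thr = empirical_threshold(stats["fst"].to_numpy(), config.top)
        rod_thr = empirical_threshold(stats["rod"].to_numpy(), config.top)
        selected = select_sweep_windows(stats, fst_thr, rod_thr)
        regions = merge_windows(selected)
        write_bed(
            [r.interval for r in regions],
            out / "regions.bed",
            scores={r.interval: r.max_fst for r in regions},
            names={
                r.interval: f"sweep{i + 1:03d}" for i, r in enumerate(regions)
            },
        )
        summary["sweep"] = {
            "fst_threshold": fst_thr,
            "rod_threshold": rod_thr,
            "selected_windows": len(selected),
            "regions": len(regions),
        }
        log.info(
            "thresholds fst>%.4g rod>%.4g -> %d windows, %d regions",
            fst_thr, rod_thr, len(selected), len(regions),
        )

    with _stage("genes"):
        if config.gff:
            genes = read_gff3(config.gff)
            regions, flat = genes_in_regions(regions, genes)
            (out / "genes.txt").write_text("".join(g + "\n" for g in flat))
            summary["genes"] = {"annotated": len(genes), "in_regions": len(flat)}
        else:
            summary["genes"] = {"skipped": True}
            log.info("no GFF provided; gene step skipped")
        regions_to_frame(regions).to_csv(
            out / "regions.tsv", sep="\t", index=False, float_format="%.8g"
        )

    with _stage("report"):
        (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        manifest = {
            "version": __version__,
            "config": asdict(config),
            "config_sha256": hashlib.sha256(
                json.dumps(asdict(config), sort_keys=True).encode()
            ).hexdigest(),
            "inputs": {
                name: _sha256(Path(p))
                for name, p in (
                    ("vcf", config.vcf),
                    ("popmap", config.popmap),
                    ("gff", config.gff),
                )
                if p
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
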