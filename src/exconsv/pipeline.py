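"""End-to-end pipeline: QC filter -> motif classification -> conservation ->
EC region calling, with a TOML configuration, manifest, and TSV outputs.

Outputs written to the configured directory:

* ``qc_report.tsv``     one row per input sequence (QC outcome);
* ``calls.tsv``         motif-based classification calls;
* ``hits.tsv``          individual motif hits;
* ``conservation.tsv``  long-format per-position grades, one row per
  (reference position, group);
* ``ec_track.tsv``      per-position EC and smoothed EC with region labels;
* ``ec_regions.tsv``    the called regions;
* ``manifest.json``     tool version, config echo, input checksums.

All TSVs start with ``#`` metadata lines.  The run is deterministic given
fixed inputs and configuration; the manifest's checksums change iff any
input byte changes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .conservation import GRADE_MASKED, ConservationProfile, profiles_for_groups
from .ec_regions import ECConfig, ec_pipeline_positions_report
from .motif_scan import MotifConfig, classify_subunit, scan_record
from .seqio_filter import (
    MaskSpec,
    build_column_map,
    qc_filter,
    read_aligned_fasta,
    read_fasta,
    read_group_map,
    read_mask,
    ungapped_reference,
)

logger = logging.getLogger("exconsv")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    alignment: Path
    reference_id: str
    out_dir: Path
    sequences: Optional[Path] = None
    group_map: Optional[Path] = None
    mask: Optional[Path] = None
    focal_group: str = "D1"
    other_groups: tuple[str, ...] = ("B1", "E1")
    motif_cfg: MotifConfig = field(default_factory=MotifConfig)
    ec_cfg: ECConfig = field(default_factory=ECConfig)
    background: str = "robinson"
    min_coverage: int = 4
    min_length: int = 900
    metal_a_motif: str = "DFDGD"
    log_level: str = "INFO"
    seed: int = 0
    resume: bool = False

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        try:
            with open(path, "rb") as fh:
                raw = tomllib.load(fh)
        except (OSError, tomllib.TOMLDecodeError) as exc:
            raise PipelineError("config", f"cannot read {path}: {exc}") from exc
        inputs = raw.get("inputs", {})
        pipe = raw.get("pipeline", {})
        base = path.parent

        def _path(key: str, required: bool = False) -> Optional[Path]:
            value = inputs.get(key)
            if value is None:
                if required:
                    raise PipelineError("config", f"missing inputs.{key}")
                return None
            p = Path(value)
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise PipelineError("config", f"inputs.{key} does not exist: {p}")
            return p

        cfg = cls(
            alignment=_path("alignment", required=True),
            sequences=_path("sequences"),
            group_map=_path("group_map"),
            mask=_path("mask"),
            reference_id=pipe.get("reference_id", ""),
            out_dir=Path(pipe.get("out_dir", "exconsv_out")),
            focal_group=pipe.get("focal_group", "D1"),
            other_groups=tuple(pipe.get("other_groups", ("B1", "E1"))),
            motif_cfg=MotifConfig(**raw.get("motifs", {})),
            ec_cfg=ECConfig(**raw.get("ec", {})),
            background=raw.get("conservation", {}).get("background", "robinson"),
            min_coverage=raw.get("conservation", {}).get("min_coverage", 4),
            min_length=raw.get("qc", {}).get("min_length", 900),
            metal_a_motif=raw.get("qc", {}).get("metal_a_motif", "DFDGD"),
            log_level=pipe.get("log_level", "INFO"),
            seed=pipe.get("seed", 0),
        )
        if not cfg.reference_id:
            raise PipelineError("config", "pipeline.reference_id is required")
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, meta: dict) -> None:
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def conservation_long_table(
    profiles: dict[str, ConservationProfile], ref_seq: str
) -> pd.DataFrame:
    frames = []
    for group, prof in profiles.items():
        frames.append(
            pd.DataFrame(
                {
                    "ref_pos": np.arange(1, prof.ref_length + 1),
                    "ref_aa": list(ref_seq),
                    "group": group,
                    "raw_score": prof.raw_scores,
                    "grade": prof.grades,
                    "coverage": prof.coverage,
                    "masked_flag": (prof.grades == GRADE_MASKED).astype(int),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def profiles_from_table(table: pd.DataFrame) -> dict[str, ConservationProfile]:
    """Rebuild conservation profiles from a conservation.tsv table."""
    profiles: dict[str, ConservationProfile] = {}
    for group, sub in table.groupby("group", sort=False):
        sub = sub.sort_values("ref_pos")
        profiles[str(group)] = ConservationProfile(
            group=str(group),
            grades=sub["grade"].to_numpy(dtype=int),
            raw_scores=sub["raw_score"].to_numpy(dtype=float),
            coverage=sub["coverage"].to_numpy(dtype=int),
        )
    return profiles


def run_full(cfg: PipelineConfig) -> Path:
    """Run the full pipeline; returns the output directory.

    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"tool": f"exconsv {__version__}"}

    # --- config echo + manifest -------------------------------------------
    inputs = {
        name: path
        for name, path in (
            ("sequences", cfg.sequences),
            ("alignment", cfg.alignment),
            ("group_map", cfg.group_map),
            ("mask", cfg.mask),
        )
        if path is not None
    }
    for name, path in inputs.items():
        if not Path(path).exists():
            raise PipelineError("config", f"input {name} does not exist: {path}")
    manifest = {
        "version": __version__,
        "inputs": {name: _sha256(Path(p)) for name, p in inputs.items()},
        "config": _jsonable(cfg),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    # --- QC + motif classification ----------------------------------------
    records = None
    if cfg.sequences is not None:
        try:
            records = read_fasta(cfg.sequences)
        except ValueError as exc:
            raise PipelineError("qc", str(exc)) from exc
        _, reports = qc_filter(records, cfg.min_length, cfg.metal_a_motif)
        qc_df = pd.DataFrame(
            [
                {
                    "record_id": r.record_id,
                    "passed": int(r.passed),
                    "length": r.length,
                    "has_metal_a": int(r.has_metal_a),
                    "fail_reasons": ",".join(r.fail_reasons),
                }
                for r in reports
            ]
        )
        _write_tsv(qc_df, out / "qc_report.tsv", meta)
        logger.info("qc: %d/%d records passed", int(qc_df["passed"].sum()), len(qc_df))

        try:
            hit_rows, call_rows = [], []
            for rec in records:
                evidence = scan_record(rec, cfg.motif_cfg)
                for hit in (evidence["heptad"], evidence["cyc"]):
                    if hit is not None:
                        hit_rows.append(
                            {
                                "id": rec.id,
                                "motif_class": hit.motif_class,
                                "start": hit.start,
                                "end": hit.end,
                                "matched_text": hit.matched_text,
                                "score": hit.score,
                            }
                        )
                call = classify_subunit(rec, evidence, cfg.motif_cfg)
                call_rows.append(
                    {
                        "id": rec.id,
                        "label": call.label,
                        "rule_fired": call.rule_fired,
                        **{f"ev_{k}": v for k, v in call.evidence.items()},
                    }
                )
        except ValueError as exc:
            raise PipelineError("scan", str(exc)) from exc
        _write_tsv(
            pd.DataFrame(
                hit_rows,
                columns=["id", "motif_class", "start", "end", "matched_text", "score"],
            ),
            out / "hits.tsv",
            meta,
        )
        _write_tsv(pd.DataFrame(call_rows), out / "calls.tsv", meta)

    # --- alignment + coordinate map ---------------------------------------
    try:
        groups = read_group_map(cfg.group_map) if cfg.group_map else None
        aln = read_aligned_fasta(cfg.alignment, groups, cfg.reference_id)
        cmap = build_column_map(aln)
        ref_seq = ungapped_reference(aln)
        mask = read_mask(cfg.mask) if cfg.mask else MaskSpec()
        mask.validate(cmap.ref_length)
    except ValueError as exc:
        raise PipelineError("align", str(exc)) from exc

    # --- conservation profiles --------------------------------------------
    wanted = (cfg.focal_group, *cfg.other_groups)
    conservation_path = out / "conservation.tsv"
    profiles = None
    if cfg.resume and conservation_path.exists():
        table = pd.read_csv(conservation_path, sep="\t", comment="#")
        profiles = profiles_from_table(table)
        if set(wanted) - set(profiles):
            profiles = None  # cached table does not cover the requested groups
        else:
            logger.info("conserve: resumed from %s", conservation_path)
    if profiles is None:
        try:
            profiles = profiles_for_groups(
                aln, cmap, wanted, mask, cfg.min_coverage, cfg.background
            )
        except ValueError as exc:
            raise PipelineError("conserve", str(exc)) from exc
        _write_tsv(
            conservation_long_table(profiles, ref_seq), conservation_path, meta
        )

    # --- EC track + regions ------------------------------------------------
    try:
        positions, regions_df, _ = ec_pipeline_positions_report(
            profiles[cfg.focal_group],
            [profiles[g] for g in cfg.other_groups],
            cfg.ec_cfg,
            ref_seq=ref_seq,
        )
    except ValueError as exc:
        raise PipelineError("ec", str(exc)) from exc
    _write_tsv(positions, out / "ec_track.tsv", meta)
    _write_tsv(regions_df, out / "ec_regions.tsv", meta)
    logger.info("ec: called %d regions", len(regions_df))
    return out


def plot_ec_track(
    track: pd.DataFrame, regions: pd.DataFrame, out_path: str | Path
) -> Path:
    """Line plot of the smoothed EC track with shaded, labeled regions."""
    if track.empty:
        raise ValueError("empty EC track")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    ax.plot(track["ref_pos"], track["ma"], color="0.3", lw=1.0)
    ax.axhline(0, color="0.8", lw=0.5)
    for _, row in regions.iterrows():
        ax.axvspan(row["start"], row["end"], color="mediumpurple", alpha=0.35)
        ax.text(
            (row["start"] + row["end"]) / 2,
            ax.get_ylim()[1] * 0.9,
            row["label"],
            ha="center",
            fontsize=8,
        )
    ax.set_xlabel("reference position (aa)")
    ax.set_ylabel("smoothed EC")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
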