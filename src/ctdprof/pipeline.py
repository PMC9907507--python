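"""End-to-end pipeline: segment -> profile -> conserve -> classify.

A :class:`RunConfig` names the inputs and thresholds; :func:`run_pipeline`
executes the stages in order, writes each stage's TSV/JSON next to the
others in the output directory, and records a machine-readable manifest
(tool version, resolved config, input checksums, per-stage row counts).
Reruns with identical inputs produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .classification import (
    DEFAULT_SITES_CTBP1,
    audit_reference_sites,
    catalog_endings,
    classify_paralog,
    rank_species_calls,
    scan_sumo_sites,
)
from .idr_composition import (
    aggregate_by_group,
    composition_profile,
    read_grouping_table,
    select_longest_ctd,
)
from .msa_conservation import annotate_columns, find_conserved_blocks
from .records import SequenceError
from .segmentation import SegmentationError, classify_isoform, segment_domains
from .seq_io import read_fasta, read_msa, write_report

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised when a run configuration fails validation."""


@dataclass
class RunConfig:
    fasta: str
    out_dir: str
    msa: Optional[str] = None
    msa_dialect: str = "aligned_fasta"
    grouping: Optional[str] = None
    ref1: Optional[str] = None
    ref2: Optional[str] = None
    ntd_anchor: str = "RPLVALL"
    ctd_anchor: str = "NCVN"
    max_mismatch: int = 1
    short_threshold: int = 40
    ribeye_threshold: int = 300
    min_block: int = 5
    max_break: int = 1
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("fasta", "msa", "grouping", "ref1", "ref2"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{name} path does not exist: {path}")
        if not 0 <= self.max_mismatch < len(self.ctd_anchor):
            raise ConfigError("max_mismatch must be smaller than the shortest anchor")
        if self.short_threshold < 1 or self.ribeye_threshold < 1:
            raise ConfigError("thresholds must be positive")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all configured stages; returns the manifest (also written to disk)."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest: dict = {
        "tool": "ctdprof",
        "version": __version__,
        "config": asdict(config),
        "inputs": {},
        "stages": {},
    }
    for name in ("fasta", "msa", "grouping", "ref1", "ref2"):
        path = getattr(config, name)
        if path is not None:
            manifest["inputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    records = read_fasta(config.fasta)

    # --- segment ---
    t0 = time.perf_counter()
    seg_rows = []
    segmented = []
    excluded = []
    for rec in records:
        try:
            seg = segment_domains(
                rec,
                ntd_anchor=config.ntd_anchor,
                ctd_anchor=config.ctd_anchor,
                max_mismatch=config.max_mismatch,
            )
        except SegmentationError as exc:
            excluded.append({"id": rec.id, "reason": str(exc)})
            continue
        iso = classify_isoform(
            seg,
            rec,
            short_threshold=config.short_threshold,
            ribeye_threshold=config.ribeye_threshold,
        )
        segmented.append((rec, seg, iso))
        seg_rows.append(
            {
                "id": rec.id,
                "species": rec.species,
                "ntd_start": seg.ntd[0], "ntd_end": seg.ntd[1],
                "core_start": seg.core[0], "core_end": seg.core[1],
                "ctd_start": seg.ctd[0], "ctd_end": seg.ctd[1],
                "flags": ",".join(sorted(seg.flags)),
                "form": iso.form,
                "ending_label": iso.ending_label,
                "ctd_length": iso.ctd_length,
                "ntd_extension": iso.ntd_extension,
            }
        )
    write_report(seg_rows, out_dir / "segments.tsv", "tsv")
    if excluded:
        write_report(excluded, out_dir / "excluded.tsv", "tsv")
        for row in excluded:
            log.warning("excluded %s: %s", row["id"], row["reason"])
    log.info("segment stage: %.3fs", time.perf_counter() - t0)
    manifest["stages"]["segment"] = {"rows": len(seg_rows), "excluded": len(excluded)}

    # --- profile ---
    t0 = time.perf_counter()
    have_species = all(rec.species for rec, _s, _i in segmented) and segmented
    profile_rows = []
    if have_species:
        ctds = select_longest_ctd((rec, seg) for rec, seg, _ in segmented)
        profiles = {sp: composition_profile(ctd) for sp, ctd in sorted(ctds.items())}
        for sp, prof in profiles.items():
            profile_rows.append(prof.as_row(species=sp, id=ctds[sp].id))
    else:
        profiles = {}
        for rec, seg, _ in segmented:
            lo, hi = seg.ctd
            if hi <= lo:
                continue
            prof = composition_profile(rec.residues[lo:hi])
            profile_rows.append(prof.as_row(species=rec.species, id=rec.id))
    write_report(profile_rows, out_dir / "profiles.tsv", "tsv")
    stage = {"rows": len(profile_rows)}
    if config.grouping and profiles:
        grouping = read_grouping_table(config.grouping)
        summaries = aggregate_by_group(profiles, grouping)
        group_rows = []
        for summary in summaries:
            row = {"group": summary.group, "n_species": summary.n_species}
            for fieldname, stats in summary.stats.items():
                for stat, value in stats.items():
                    row[f"{fieldname}_{stat}"] = float(value)
            group_rows.append(row)
        write_report(group_rows, out_dir / "group_summaries.tsv", "tsv")
        stage["groups"] = len(group_rows)
    log.info("profile stage: %.3fs", time.perf_counter() - t0)
    manifest["stages"]["profile"] = stage

    # --- conserve ---
    if config.msa:
        t0 = time.perf_counter()
        msa = read_msa(config.msa, dialect=config.msa_dialect)
        annotations = annotate_columns(msa)
        write_report(
            [
                {
                    "column": a.column,
                    "primary_class": a.primary_class,
                    "primary_residue": a.primary_residue,
                    "secondary_residue": a.secondary_residue or "",
                    "occupancy": a.occupancy,
                }
                for a in annotations
            ],
            out_dir / "conservation.tsv",
            "tsv",
        )
        blocks = find_conserved_blocks(
            annotations, msa, min_len=config.min_block, max_break=config.max_break
        )
        with (out_dir / "blocks.json").open("w") as fh:
            json.dump(
                [
                    {
                        "start": b.start,
                        "end": b.end,
                        "consensus": b.consensus,
                        "mean_occupancy": round(b.mean_occupancy, 4),
                    }
                    for b in blocks
                ],
                fh,
                indent=2,
            )
            fh.write("\n")
        log.info("conserve stage: %.3fs", time.perf_counter() - t0)
        manifest["stages"]["conserve"] = {"columns": len(annotations), "blocks": len(blocks)}

    # --- classify ---
    if config.ref1 and config.ref2:
        t0 = time.perf_counter()
        ref1 = read_fasta(config.ref1)[0]
        ref2 = read_fasta(config.ref2)[0]
        calls = []
        for rec, _seg, _iso in segmented:
            calls.append(classify_paralog(rec, ref1, ref2, max_anchor_mismatch=config.max_mismatch))
        by_species: dict = {}
        for (rec, _s, _i), call in zip(segmented, calls):
            by_species.setdefault(rec.species, []).append(call)
        for species_calls in by_species.values():
            rank_species_calls(species_calls)
        write_report(
            [
                {
                    "id": c.query_id,
                    "family": c.family,
                    "identity_to_ref1": c.identity_to_ref1,
                    "identity_to_ref2": c.identity_to_ref2,
                    "ctd_start_motif": c.ctd_start_motif or "",
                    "ctd_end_motif": c.ctd_end_motif or "",
                    "evidence": ";".join(c.evidence),
                }
                for c in calls
            ],
            out_dir / "paralogs.tsv",
            "tsv",
        )
        sumo_rows = []
        for rec, seg, _ in segmented:
            lo, hi = seg.ctd
            for site in scan_sumo_sites(rec.residues[lo:hi]):
                sumo_rows.append(
                    {
                        "id": rec.id,
                        "k_position_in_ctd": site.k_position,
                        "context": site.context,
                    }
                )
        write_report(sumo_rows, out_dir / "sumo_sites.tsv", "tsv",
                     columns=["id", "k_position_in_ctd", "context"])
        endings = catalog_endings([rec for rec, _s, _i in segmented])
        write_report(
            [
                {"id": rid, **entry}
                for rid, entry in endings.items()
            ],
            out_dir / "endings.tsv",
            "tsv",
        )
        audits = {
            rec.id: [
                asdict(a)
                for a in audit_reference_sites(rec, ref1, DEFAULT_SITES_CTBP1)
            ]
            for rec, _s, _i in segmented
        }
        with (out_dir / "site_audits.json").open("w") as fh:
            json.dump(audits, fh, indent=2)
            fh.write("\n")
        log.info("classify stage: %.3fs", time.perf_counter() - t0)
        manifest["stages"]["classify"] = {"rows": len(calls), "sumo_sites": len(sumo_rows)}

    with (out_dir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return manifest
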