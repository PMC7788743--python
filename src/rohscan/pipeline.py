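"""One-shot orchestration: simulate (or load) → QC → detect → inbreeding
→ islands, with plain-TSV stage outputs and a machine-readable manifest.

Every intermediate is a diffable text table, and re-running with the same
config and inputs reproduces identical outputs (timestamps live in a
separate manifest field so manifests are otherwise comparable).
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .detect import RohParams, detect_roh, runs_per_chromosome, summarize_by_breed
from .inbreeding import inbreeding_table, summarize_inbreeding
from .io import (
    GenotypePanel,
    check_metadata_covers,
    read_metadata,
    read_ped_map,
    write_metadata,
    write_ped_map,
    write_roh_table,
)
from .islands import (
    analyze_islands,
    annotate_islands,
    call_islands,
    incidence_per_snp,
    islands_to_frame,
)
from .qc import QcParams, apply_qc
from .simulate import SimConfig, default_config, simulate_panel, write_truth

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "detect", "inbreeding", "islands")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    out_dir,
    sim_config: SimConfig | None = None,
    ped_path=None,
    map_path=None,
    meta_path=None,
    qc_params: QcParams | None = None,
    roh_params: RohParams | None = None,
    l_auto: int | None = None,
    island_min_samples: int = 20,
    island_max_gap_bp: int = 0,
    stages: tuple[str, ...] = STAGES,
    config_echo: dict | None = None,
) -> dict:
    """Run the pipeline stages in fixed order; returns the manifest dict.

    Exactly one input source is required: a :class:`SimConfig` (stage
    ``simulate`` writes PED/MAP + metadata + truth) or real
    ``ped_path``/``map_path``/``meta_path`` files. ``l_auto=None`` makes
    F_ROH use the SNP-covered span of the post-QC map, the sensible mode
    for synthetic genomes.
    """
    if (sim_config is None) == (ped_path is None):
        raise ValueError("provide either sim_config or ped/map/meta paths, not both")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "rohscan",
        "version": __version__,
        "stages_requested": list(stages),
        "stages_completed": [],
        "config": config_echo or {},
        "tables": {},
        "timestamps": {"started": datetime.now(timezone.utc).isoformat()},
    }

    def _record(name: str, path: Path, n_rows: int) -> None:
        manifest["tables"][name] = {"path": path.name, "rows": int(n_rows)}

    try:
        if "simulate" in stages and sim_config is not None:
            panel, meta, truth = simulate_panel(sim_config)
            ped, mp = out / "panel.ped", out / "panel.map"
            write_ped_map(panel, ped, mp, meta)
            write_metadata(meta, out / "metadata.tsv")
            write_truth(truth, out / "truth.tsv")
            manifest["seed"] = sim_config.seed
            manifest["input_digests"] = {"panel.ped": _sha256(ped), "panel.map": _sha256(mp)}
            _record("metadata", out / "metadata.tsv", len(meta))
            _record("truth_intervals", out / "truth.tsv", len(truth.intervals))
            manifest["stages_completed"].append("simulate")
        else:
            panel = read_ped_map(ped_path, map_path)
            meta = read_metadata(meta_path)
            check_metadata_covers(panel, meta)
            manifest["input_digests"] = {
                Path(ped_path).name: _sha256(Path(ped_path)),
                Path(map_path).name: _sha256(Path(map_path)),
            }

        if "qc" in stages:
            panel, report = apply_qc(panel, qc_params)
            meta = meta[meta["animal_id"].isin(set(panel.animal_ids))].reset_index(drop=True)
            pd.DataFrame([report.as_dict()]).to_csv(out / "qc_report.tsv", sep="\t", index=False)
            _record("qc_report", out / "qc_report.tsv", 1)
            manifest["qc"] = report.as_dict()
            manifest["stages_completed"].append("qc")

        runs = None
        if "detect" in stages:
            runs = detect_roh(panel, meta, roh_params)
            write_roh_table(runs, out / "roh.tsv")
            _record("roh", out / "roh.tsv", len(runs))
            breed_summary = summarize_by_breed(runs, meta)
            breed_summary.to_csv(out / "roh_breed_summary.tsv", sep="\t", index=False)
            _record("roh_breed_summary", out / "roh_breed_summary.tsv", len(breed_summary))
            per_chrom = runs_per_chromosome(runs, meta)
            per_chrom.to_csv(out / "roh_per_chromosome.tsv", sep="\t")
            _record("roh_per_chromosome", out / "roh_per_chromosome.tsv", len(per_chrom))
            manifest["stages_completed"].append("detect")

        if "inbreeding" in stages:
            if runs is None:
                raise ValueError("inbreeding stage requires the detect stage")
            records = inbreeding_table(runs, panel, meta, l_auto=l_auto)
            records.to_csv(out / "inbreeding.tsv", sep="\t", index=False)
            _record("inbreeding", out / "inbreeding.tsv", len(records))
            summary = summarize_inbreeding(records)
            summary.to_csv(out / "inbreeding_breed_summary.tsv", sep="\t", index=False)
            _record("inbreeding_breed_summary", out / "inbreeding_breed_summary.tsv", len(summary))
            manifest["stages_completed"].append("inbreeding")

        if "islands" in stages:
            if runs is None:
                raise ValueError("islands stage requires the detect stage")
            inc = incidence_per_snp(runs, panel.snp_map, meta)
            inc.to_csv(out / "incidence.tsv", sep="\t", index=False)
            _record("incidence", out / "incidence.tsv", len(inc))
            islands = call_islands(
                inc, min_samples=island_min_samples, max_gap_bp=island_max_gap_bp
            )
            annotate_islands(islands, runs, panel.snp_map, meta)
            island_tab = islands_to_frame(islands)
            island_tab.to_csv(out / "islands.tsv", sep="\t", index=False)
            _record("islands", out / "islands.tsv", len(island_tab))
            anova = analyze_islands(islands, runs, panel.snp_map, meta)
            anova.to_csv(out / "island_anova.tsv", sep="\t", index=False)
            _record("island_anova", out / "island_anova.tsv", len(anova))
            manifest["stages_completed"].append("islands")
    finally:
        manifest["timestamps"]["finished"] = datetime.now(timezone.utc).isoformat()
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    return manifest


def default_run(out_dir, seed: int) -> dict:
    """Full pipeline on the default five-breed synthetic design."""
    cfg = default_config(seed)
    return run_pipeline(
        out_dir,
        sim_config=cfg,
        l_auto=None,
        config_echo={"design": "default_config", "seed": seed},
    )
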