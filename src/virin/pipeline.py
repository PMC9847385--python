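"""End-to-end pipeline driver: stage composition, manifests, TSV outputs.

Each stage communicates with the next only through declared file formats
(SAM/FASTA/TSV), so a run is restartable at any stage.  Every run writes a
manifest carrying the package version, the effective config and its hash,
and input checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

import virin
from virin.annotation import annotate_all, annotated_table, summary_tables
from virin.breakpoint_calling import BreakpointCluster, call_sample
from virin.config import PipelineConfig
from virin.io_formats import (
    read_bed,
    read_fasta,
    read_gene_model,
    read_sam,
    write_breakpoint_tsv,
)

logger = logging.getLogger(__name__)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def clusters_to_table(clusters: list[BreakpointCluster]) -> pd.DataFrame:
    rows = []
    for c in clusters:
        rows.append(
            {
                "sample_id": c.sample_id,
                "chrom": c.chrom,
                "pos_1based": c.representative_pos,
                "virus_id": c.virus_id,
                "evidence": "softclip" if c.exact_members else "discordant",
                "support": c.support,
                "region_class": ".",
                "dnase": 0,
                "repeat_class": ".",
                "gene_name": ".",
                "gene_type": ".",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "chrom", "pos_1based", "virus_id", "evidence", "support",
            "region_class", "dnase", "repeat_class", "gene_name", "gene_type",
        ],
    )


def run_all(
    sam_path,
    panel_path,
    out_dir,
    config: PipelineConfig | None = None,
    sample_id: str = "sample",
    dnase_bed=None,
    repeats_bed=None,
    genes_gtf=None,
) -> pd.DataFrame:
    """Run extract -> screen -> assemble -> call (-> annotate) on one sample.

    Writes ``<sample>.breakpoints.tsv`` (and annotated/summary TSVs when
    tracks are supplied) plus ``manifest.json`` under ``out_dir``; returns the
    breakpoint table.
    """
    config = config or PipelineConfig()
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sam_path, panel_path = Path(sam_path), Path(panel_path)

    panel = read_fasta(panel_path)
    alignment = list(read_sam(sam_path))
    logger.info("run-all %s: %d alignment records, %d panel viruses",
                sample_id, len(alignment), len(panel))
    clusters = call_sample(alignment, panel, config=config, sample_id=sample_id)

    if genes_gtf is not None or dnase_bed is not None or repeats_bed is not None:
        gene_model = read_gene_model(genes_gtf) if genes_gtf else None
        dnase = read_bed(dnase_bed) if dnase_bed else []
        repeats = read_bed(repeats_bed) if repeats_bed else []
        for iv in repeats:
            iv.attrs.setdefault("repeat_class", iv.name)
        from virin.io_formats import GeneModel

        annotated = annotate_all(
            clusters, gene_model or GeneModel(genes=[]), dnase, repeats, config.annotation
        )
        table = annotated_table(annotated)
        for name, df in summary_tables(annotated).items():
            df.to_csv(out_dir / f"{sample_id}.{name}.tsv", sep="\t", index=False)
    else:
        table = clusters_to_table(clusters)

    write_breakpoint_tsv(table, out_dir / f"{sample_id}.breakpoints.tsv")

    manifest = {
        "package": "virin",
        "version": virin.__version__,
        "sample_id": sample_id,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "inputs": {
            "sam": {"path": str(sam_path), "sha256_16": _checksum(sam_path)},
            "panel": {"path": str(panel_path), "sha256_16": _checksum(panel_path)},
        },
        "n_breakpoint_clusters": int(len(table)),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return table
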