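"""Readers and writers for the pipeline's tabular, image and JSON formats.

Formats are deliberately plain: genotype matrices and trait tables as TSV,
per-animal echo records as CSV, image pairs as 16-bit grayscale TIFF, scan
results as TSV, thresholds as JSON, MAP founder paths as BED.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .haplotype import HaplotypeProbs, map_path_intervals
from .qtl import QTLScan, Thresholds
from .simulate import FounderPanel, MosaicGenome

__all__ = [
    "write_genotype_tsv",
    "read_genotype_tsv",
    "write_echo_csv",
    "read_echo_csv",
    "write_image_pair",
    "read_image_pair",
    "write_trait_table",
    "read_trait_table",
    "write_scan_tsv",
    "write_thresholds_json",
    "read_thresholds_json",
    "write_map_path_bed",
    "write_truth_json",
]


def write_genotype_tsv(
    panel: FounderPanel, genomes: list[MosaicGenome], path
) -> None:
    """Rows = SNPs: chrom, pos, 8 founder alleles, then one column per strain."""
    rows = []
    for chrom in panel.chrom_names:
        pos = panel.snp_positions[chrom]
        alle = panel.founder_alleles[chrom]
        calls = np.stack([g.genotypes[chrom] for g in genomes], axis=1)
        block = pd.DataFrame({"chrom": chrom, "pos": pos})
        for k, fid in enumerate(panel.founder_ids):
            block[fid] = alle[:, k]
        for j, g in enumerate(genomes):
            block[g.strain_id] = calls[:, j]
        rows.append(block)
    pd.concat(rows).to_csv(path, sep="\t", index=False)


def read_genotype_tsv(path, chrom_length: int = 100_000_000):
    """Inverse of :func:`write_genotype_tsv`; returns ``(panel, strain_calls)``.

    ``strain_calls`` maps strain id to a ``chrom -> calls`` dict as consumed
    by haplotype inference. Chromosome lengths are not stored in the TSV;
    pass the true length if segments near chromosome ends matter.
    """
    df = pd.read_csv(path, sep="\t")
    founder_ids = tuple(df.columns[2:10])
    strain_ids = list(df.columns[10:])
    chroms = list(dict.fromkeys(df["chrom"]))
    positions, alleles = {}, {}
    calls: dict[str, dict[str, np.ndarray]] = {s: {} for s in strain_ids}
    for chrom in chroms:
        block = df[df["chrom"] == chrom]
        positions[chrom] = block["pos"].to_numpy(dtype=np.int64)
        alleles[chrom] = block[list(founder_ids)].to_numpy(dtype=np.int8)
        for s in strain_ids:
            calls[s][chrom] = block[s].to_numpy(dtype=np.int8)
    panel = FounderPanel(
        founder_ids, [(c, chrom_length) for c in chroms], positions, alleles
    )
    return panel, calls


def write_echo_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_echo_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_image_pair(polarized, brightfield, pol_path, bf_path) -> None:
    """Write float images in [0, ~1] as 16-bit grayscale TIFF."""
    for img, p in ((polarized, pol_path), (brightfield, bf_path)):
        arr = np.asarray(img, dtype=float)
        scaled = np.clip(arr, 0, 1) * 65535.0
        tifffile.imwrite(p, scaled.astype(np.uint16))


def read_image_pair(pol_path, bf_path):
    """Read a TIFF pair back to floats in [0, 1]."""
    pol = tifffile.imread(pol_path).astype(float) / 65535.0
    bf = tifffile.imread(bf_path).astype(float) / 65535.0
    return pol, bf


def write_trait_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def read_trait_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_scan_tsv(qscan: QTLScan, path) -> None:
    qscan.to_frame().to_csv(path, sep="\t", index=False)


def write_thresholds_json(thresholds: Thresholds, path) -> None:
    payload = {
        "cutoffs": {str(a): v for a, v in thresholds.cutoffs.items()},
        "n_perm": thresholds.n_perm,
        "seed": thresholds.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_thresholds_json(path) -> dict:
    payload = json.loads(Path(path).read_text())
    payload["cutoffs"] = {float(a): v for a, v in payload["cutoffs"].items()}
    return payload


def write_map_path_bed(probs: HaplotypeProbs, path) -> None:
    """MAP founder path as BED: chrom, start, end, founder index."""
    with open(path, "w") as fh:
        for chrom, start, end, founder in map_path_intervals(probs):
            fh.write(f"{chrom}\t{start}\t{end}\tfounder_{founder}\n")


def write_truth_json(truth: dict, path) -> None:
    """Serialize a ground-truth dict (Series/arrays become plain lists)."""

    def convert(obj):
        if isinstance(obj, pd.Series):
            return obj.to_dict()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        return obj

    Path(path).write_text(json.dumps(convert(truth), indent=1))
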