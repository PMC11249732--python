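"""Standard-format I/O: VCF panels, cluster/phenotype/association tables.

Coordinate conventions: user-facing files carry 1-based inclusive bp
coordinates (VCF convention); internally everything is 0-based half-open.
The conversion is confined to this module. Every table written here starts
with ``##`` header lines recording the tool version and the run
configuration, seed included, so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .caller import ROHCluster
from .blocks import MatchBlock
from .panel import GenotypePanel, make_site_meta
from .simulate import IBDSegment

logger = logging.getLogger("rohdice")

__all__ = [
    "RunConfig",
    "read_vcf",
    "write_vcf",
    "write_clusters_tsv",
    "read_clusters_tsv",
    "write_ibd_tsv",
    "read_ibd_tsv",
    "read_phenotypes_tsv",
    "write_phenotypes_tsv",
]


@dataclass
class RunConfig:
    """Parameters of a cluster-calling run, echoed into output headers."""

    min_sites: int = 100
    min_width: int = 100
    objective: str = "width"
    seed: int = 0
    max_member_het: float = 0.01
    genetic_map: str | None = None

    def __post_init__(self):
        if self.min_sites < 1:
            raise ValueError("min_sites must be >= 1")
        if self.min_width < 2:
            raise ValueError("min_width must be >= 2")
        if not 0 <= self.max_member_het <= 1:
            raise ValueError("max_member_het must be in [0, 1]")
        if self.objective not in ("width", "length"):
            raise ValueError(f"unknown objective {self.objective!r}")

    def header_lines(self):
        return [
            f"##rohdice_version={__version__}",
            f"##min_sites={self.min_sites}",
            f"##min_width={self.min_width}",
            f"##objective={self.objective}",
            f"##seed={self.seed}",
            f"##max_member_het={self.max_member_het}",
        ]


def read_vcf(path, keep_samples=None) -> GenotypePanel:
    """Read a diploid biallelic VCF into a genotype panel.

    Genotypes map 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2. Multi-allelic records
    and records with any missing genotype are skipped (counts logged). An
    optional ``keep_samples`` collection restricts the panel's columns.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF contains no samples")
    if keep_samples is not None:
        keep_set = set(keep_samples)
        col_idx = [i for i, s in enumerate(samples) if s in keep_set]
        if not col_idx:
            raise ValueError("keep_samples retains no sample")
        samples = [samples[i] for i in col_idx]
    else:
        col_idx = None

    rows, chroms, positions, ids = [], [], [], []
    n_multi = n_missing = 0
    last = {}
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gt = var.gt_types  # 0=hom-ref, 1=het, 2=hom-alt, 3=unknown (gts012)
        if col_idx is not None:
            gt = gt[col_idx]
        if (gt == 3).any():
            n_missing += 1
            continue
        if var.CHROM in last and var.POS <= last[var.CHROM]:
            raise ValueError(
                f"{path}: unsorted positions on {var.CHROM} at {var.POS}"
            )
        last[var.CHROM] = var.POS
        rows.append(gt.astype(np.int8))
        chroms.append(var.CHROM)
        positions.append(var.POS)
        ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
    if n_multi or n_missing:
        logger.info(
            "read_vcf(%s): skipped %d multi-allelic and %d missing-GT records",
            path, n_multi, n_missing,
        )
    if not rows:
        raise ValueError(f"{path}: no usable biallelic records")
    values = np.stack(rows, axis=1)  # samples x sites
    meta = pd.DataFrame({"chrom": chroms, "pos": positions, "id": ids})
    return GenotypePanel(values=values, sample_ids=samples, site_meta=meta)


def write_vcf(panel: GenotypePanel, path) -> None:
    """Write a genotype panel as an uncompressed diploid VCF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=rohdice-{__version__}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(panel.site_meta["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        gt_str = np.array(["0/0", "0/1", "1/1"])
        for j in range(panel.n_sites):
            meta = panel.site_meta.iloc[j]
            gts = "\t".join(gt_str[panel.values[:, j]])
            fh.write(
                f"{meta['chrom']}\t{meta['pos']}\t{meta['id']}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_clusters_tsv(clusters, path, config: RunConfig) -> None:
    """Write called clusters with the run configuration in the header."""
    cols = [
        "chrom", "start_site", "end_site", "bp_start", "bp_end",
        "n_members", "genetic_length_cm", "consensus", "member_ids",
    ]
    with open(path, "w") as fh:
        for line in config.header_lines():
            fh.write(line + "\n")
        fh.write("\t".join(cols) + "\n")
        for c in clusters:
            cm = "" if c.genetic_length_cm is None else f"{c.genetic_length_cm:.6g}"
            fh.write(
                "\t".join(
                    [
                        c.chrom, str(c.start), str(c.end), str(c.bp_start),
                        str(c.bp_end), str(c.n_members), cm, c.consensus,
                        ",".join(map(str, c.member_ids)),
                    ]
                )
                + "\n"
            )


def read_clusters_tsv(path, sample_index=None):
    """Read a cluster table back into :class:`ROHCluster` objects.

    ``sample_index`` optionally maps sample IDs to panel row indices; absent
    that, member indices are synthesized from the order of first appearance
    (the member *IDs* are authoritative in the file).
    """
    clusters = []
    auto_index = {}
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if header is None:
                header = line.split("\t")
                continue
            rec = dict(zip(header, line.split("\t")))
            ids = rec["member_ids"].split(",") if rec["member_ids"] else []
            if sample_index is not None:
                idx = frozenset(sample_index[s] for s in ids)
            else:
                for s in ids:
                    auto_index.setdefault(s, len(auto_index))
                idx = frozenset(auto_index[s] for s in ids)
            blk = MatchBlock(
                int(rec["start_site"]), int(rec["end_site"]), idx, rec["consensus"]
            )
            clusters.append(
                ROHCluster(
                    block=blk,
                    chrom=rec["chrom"],
                    bp_start=int(rec["bp_start"]),
                    bp_end=int(rec["bp_end"]),
                    member_ids=ids,
                    member_het_fraction={},
                    genetic_length_cm=(
                        float(rec["genetic_length_cm"])
                        if rec.get("genetic_length_cm")
                        else None
                    ),
                )
            )
    return clusters


def write_ibd_tsv(segments, path, seed=None) -> None:
    """BED-like within-individual IBD truth table."""
    with open(path, "w") as fh:
        fh.write(f"##rohdice_version={__version__}\n")
        if seed is not None:
            fh.write(f"##seed={seed}\n")
        fh.write("individual\tbp_start\tbp_end\tancestor\n")
        for s in segments:
            fh.write(f"{s.individual}\t{s.bp_start}\t{s.bp_end}\t{s.ancestor}\n")


def read_ibd_tsv(path):
    segs = []
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if header is None:
                header = line.split("\t")
                continue
            rec = dict(zip(header, line.split("\t")))
            segs.append(
                IBDSegment(
                    individual=int(rec["individual"]),
                    bp_start=int(rec["bp_start"]),
                    bp_end=int(rec["bp_end"]),
                    ancestor=int(rec.get("ancestor", -1)),
                )
            )
    return segs


def write_phenotypes_tsv(sample_ids, values, path, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(f"##rohdice_version={__version__}\n")
        if seed is not None:
            fh.write(f"##seed={seed}\n")
        fh.write("sample_id\tvalue\n")
        for s, v in zip(sample_ids, values):
            fh.write(f"{s}\t{v:.10g}\n")


def read_phenotypes_tsv(path) -> dict:
    out = {}
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if header is None:
                header = line.split("\t")
                continue
            s, v = line.split("\t")
            out[s] = float(v)
    return out
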