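"""End-to-end ROH diplotype cluster calling.

Pipeline: collapse the {0,1,2} genotype panel onto {0,1} (heterozygous cells
assigned by a fair, seeded coin), enumerate match blocks with the requested
objective, then post-process: members whose within-block heterozygosity
exceeds ``max_member_het`` are removed, clusters falling below the width
cut-off are dropped, and clusters with identical span and consensus are
merged.

The default run parameters of interest in practice are ``L=100`` sites and
``W=100`` individuals — long enough that a spurious cluster emerging from the
random heterozygote assignment is vanishingly unlikely (two 100-site windows
with independent coin flips collide with probability 2^-100 per heterozygous
mismatch pattern), and wide enough to support downstream association tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blocks import MatchBlock, find_length_maximal, find_width_maximal
from .panel import BinaryPanel, GenotypePanel

__all__ = [
    "ROHCluster",
    "compress_genotypes",
    "call_roh_clusters",
    "consensus_of",
    "merge_clusters",
]


class ConsistencyError(RuntimeError):
    """Internal invariant violated (block members disagree on the span)."""


@dataclass
class ROHCluster:
    """An ROH diplotype cluster with genomic coordinates attached.

    ``bp_start``/``bp_end`` are 1-based inclusive physical coordinates taken
    from the panel's site metadata; site indices in ``block`` remain 0-based
    half-open. ``member_het_fraction`` maps each retained sample ID to the
    fraction of its in-block sites that were heterozygous before compression.
    """

    block: MatchBlock
    chrom: str
    bp_start: int
    bp_end: int
    member_ids: list
    member_het_fraction: dict
    genetic_length_cm: float | None = None

    @property
    def start(self) -> int:
        return self.block.start

    @property
    def end(self) -> int:
        return self.block.end

    @property
    def members(self) -> frozenset:
        return self.block.members

    @property
    def consensus(self) -> str:
        return self.block.consensus

    @property
    def n_members(self) -> int:
        return len(self.block.members)


def compress_genotypes(panel: GenotypePanel, seed: int) -> BinaryPanel:
    """Collapse genotypes onto {0,1}: 0 -> 0, 2 -> 1, 1 -> Bernoulli(1/2).

    Deterministic given ``seed``; two runs with the same seed produce
    identical panels, and runs with different seeds may differ only where
    ``het_mask`` is set.
    """
    values = np.asarray(panel.values)
    bad = ~np.isin(values, (0, 1, 2))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"genotype outside {{0,1,2}} at row {i}, column {j}")
    het = values == 1
    out = (values == 2).astype(np.uint8)
    rng = np.random.default_rng(seed)
    out[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.uint8)
    return BinaryPanel(
        values=out,
        het_mask=het,
        sample_ids=list(panel.sample_ids),
        site_meta=panel.site_meta.copy(),
    )


def consensus_of(block: MatchBlock, panel: BinaryPanel) -> str:
    """The shared compressed sequence of a block (unanimous by construction)."""
    members = sorted(block.members)
    sub = panel.values[members, block.start : block.end]
    if not (sub == sub[0]).all():
        raise ConsistencyError(
            f"block members disagree on span [{block.start}, {block.end})"
        )
    return "".join("01"[v] for v in sub[0])


def merge_clusters(clusters):
    """Merge clusters with identical (start, end, consensus), uniting members.

    Idempotent: merging an already-merged list returns it unchanged.
    """
    groups = {}
    for c in clusters:
        groups.setdefault((c.start, c.end, c.consensus), []).append(c)
    out = []
    for (s, e, cons), grp in sorted(groups.items()):
        members = frozenset().union(*(c.members for c in grp))
        ids = sorted({i for c in grp for i in c.member_ids})
        het = {}
        for c in grp:
            het.update(c.member_het_fraction)
        first = grp[0]
        out.append(
            ROHCluster(
                block=MatchBlock(s, e, members, cons),
                chrom=first.chrom,
                bp_start=first.bp_start,
                bp_end=first.bp_end,
                member_ids=ids,
                member_het_fraction=het,
                genetic_length_cm=first.genetic_length_cm,
            )
        )
    out.sort(key=lambda c: (c.start, c.end, min(c.members)))
    return out


def call_roh_clusters(
    panel: GenotypePanel,
    L: int,
    W: int,
    objective: str = "width",
    seed: int = 0,
    max_member_het: float = 0.01,
) -> list:
    """Call ROH diplotype clusters from a genotype panel.

    Parameters
    ----------
    panel
        Diploid {0,1,2} genotype panel (one chromosome).
    L, W
        Minimum number of consecutive sites and minimum number of member
        individuals.
    objective
        ``"width"`` (maximize members; preferred for association work) or
        ``"length"`` (maximize sites).
    seed
        Governs all heterozygote coin flips; recorded by the I/O layer in
        output headers.
    max_member_het
        Members whose heterozygous fraction within the block span exceeds
        this are removed; clusters whose width then falls below ``W`` are
        dropped.
    """
    if objective not in ("width", "length"):
        raise ValueError(f"unknown objective {objective!r}")
    bpanel = compress_genotypes(panel, seed)
    finder = find_width_maximal if objective == "width" else find_length_maximal
    blocks = finder(bpanel, L, W)
    positions = bpanel.positions
    chroms = bpanel.site_meta["chrom"].to_numpy()
    cm = (
        bpanel.site_meta["cm"].to_numpy()
        if "cm" in bpanel.site_meta.columns
        else None
    )

    clusters = []
    for blk in blocks:
        members = sorted(blk.members)
        het_frac = bpanel.het_mask[members, blk.start : blk.end].mean(axis=1)
        kept = [m for m, h in zip(members, het_frac) if h <= max_member_het]
        if len(kept) < W:
            continue
        het_map = {
            bpanel.sample_ids[m]: float(h)
            for m, h in zip(members, het_frac)
            if h <= max_member_het
        }
        clusters.append(
            ROHCluster(
                block=MatchBlock(blk.start, blk.end, frozenset(kept), blk.consensus),
                chrom=str(chroms[blk.start]),
                bp_start=int(positions[blk.start]),
                bp_end=int(positions[blk.end - 1]),
                member_ids=sorted(bpanel.sample_ids[m] for m in kept),
                member_het_fraction=het_map,
                genetic_length_cm=(
                    float(cm[blk.end - 1] - cm[blk.start]) if cm is not None else None
                ),
            )
        )
    return merge_clusters(clusters)
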