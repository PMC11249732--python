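"""Ground-truth cluster construction and accuracy/power metrics.

Ground truth: the within-individual IBD segments of a simulated panel are
painted onto an interim genotype panel — each covered individual becomes
homozygous over the segment, with alleles drawn once per (ancestral node,
site) so that individuals autozygous for the same ancestral haplotype carry
identical diplotypes. Sites outside any segment are filled heterozygous and
are excluded from matching. Running the block finder on this interim panel
(heterozygous filler masked out) yields the clusters that are *truly there by
descent*, against which the caller's output is scored.

Metrics operate in (member, site) *cell* space: the overlap of two clusters
is the number of shared member-site cells, which penalizes both wrong members
and wrong spans. Site-space overlap (span only) is available via
``mode="sites"`` for sensitivity analysis.

* ``accuracy`` — mean over reported clusters of the best-matching truth
  cluster's overlap ratio (what fraction of each report is real);
* ``power`` — mean over truth clusters of the (capped) cumulative overlap
  from all reported clusters (what fraction of the truth is recovered,
  crediting piecewise recovery by several smaller reports).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .blocks import find_length_maximal, find_width_maximal
from .panel import GenotypePanel, make_site_meta

__all__ = [
    "GroundTruthCluster",
    "ground_truth_clusters",
    "overlap_ratio",
    "accuracy",
    "power",
]


@dataclass(frozen=True)
class GroundTruthCluster:
    """A cluster known to be present: half-open site span plus member set."""

    start: int
    end: int
    members: frozenset
    consensus: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_members(self) -> int:
        return len(self.members)


def ground_truth_clusters(
    ibd,
    site_meta,
    L: int,
    W: int,
    seed: int = 0,
    n_individuals: int | None = None,
    objective: str = "width",
    panel: GenotypePanel | None = None,
):
    """Project IBD segments onto the site grid and extract truth clusters.

    Parameters
    ----------
    ibd
        Within-individual :class:`~rohdice.simulate.IBDSegment` list.
    site_meta
        Site metadata frame of the panel the segments refer to (1-based bp
        positions on the same coordinate system as the segments' 0-based
        half-open bp intervals).
    L, W
        Cluster thresholds applied to the truth, matching the target scale
        of the evaluation.
    seed
        Governs the per-(ancestor, site) allele draws of the painting (only
        used when no ``panel`` is supplied).
    n_individuals
        Panel height; inferred from the segments when omitted.
    panel
        The clean (error-free) genotype panel the segments were derived
        from. When given, each IBD span is painted with the individual's own
        homozygous genotypes — segments descending from nested ancestral
        nodes (the same inherited haplotype seen at different coalescence
        heights) then merge into one cluster automatically, and sites made
        heterozygous by private mutations on the descent paths are excluded,
        exactly as descent dictates. Without a panel, alleles are drawn once
        per (ancestral node, site), which groups sharing individuals by
        genealogical identity but treats nested ancestors as distinct.

    Returns
    -------
    (GenotypePanel, list[GroundTruthCluster])
        The interim painted panel and the truth clusters found on it.
    """
    positions = np.asarray(site_meta["pos"], dtype=np.int64)
    N = positions.size
    if n_individuals is None:
        if not ibd:
            raise ValueError("cannot infer panel height from an empty segment list")
        n_individuals = max(s.individual for s in ibd) + 1
    M = n_individuals
    if panel is not None and panel.values.shape != (M, N):
        raise ValueError("panel shape does not match segment/site grid")

    values = np.ones((M, N), dtype=np.int8)  # heterozygous filler: no matching
    segs = sorted(ibd, key=lambda s: (s.ancestor, s.individual, s.bp_start))
    pos0 = positions - 1  # back to 0-based genome coordinates
    rng_root = np.random.SeedSequence(seed)
    n_outside = 0
    group_alleles = None
    current_group = None
    for seg in segs:
        i0 = int(np.searchsorted(pos0, seg.bp_start, side="left"))
        i1 = int(np.searchsorted(pos0, seg.bp_end, side="left"))
        if i1 <= i0:
            n_outside += 1
            continue
        if panel is not None:
            values[seg.individual, i0:i1] = panel.values[seg.individual, i0:i1]
            continue
        if seg.ancestor != current_group:
            current_group = seg.ancestor
            group_rng = np.random.default_rng(
                np.random.SeedSequence(
                    entropy=rng_root.entropy, spawn_key=(max(current_group, 0),)
                )
            )
            group_alleles = group_rng.integers(0, 2, size=N, dtype=np.int8) * 2
        values[seg.individual, i0:i1] = group_alleles[i0:i1]
    if n_outside:
        warnings.warn(
            f"{n_outside} IBD segment(s) covered no site and were clipped away",
            stacklevel=2,
        )

    interim = GenotypePanel(
        values=values,
        sample_ids=[f"ind{i}" for i in range(M)],
        site_meta=site_meta.copy()
        if hasattr(site_meta, "copy")
        else make_site_meta(positions),
    )
    finder = find_width_maximal if objective == "width" else find_length_maximal
    blocks = finder(
        (values == 2).astype(np.uint8), L, W, exclude_mask=values == 1
    )
    truth = [
        GroundTruthCluster(
            start=b.start, end=b.end, members=b.members, consensus=b.consensus
        )
        for b in blocks
    ]
    return interim, truth


# ---------------------------------------------------------------------------
# Overlap metrics
# ---------------------------------------------------------------------------


def _span_overlap(a, b) -> int:
    return max(0, min(a.end, b.end) - max(b.start, a.start))


def _cell_overlap(a, b, mode: str) -> int:
    ov = _span_overlap(a, b)
    if mode == "sites":
        return ov
    return len(a.members & b.members) * ov


def _cluster_size(c, mode: str) -> int:
    if mode == "sites":
        return c.end - c.start
    return len(c.members) * (c.end - c.start)


def overlap_ratio(reported, truth, mode: str = "cells") -> float:
    """|cells(reported) & cells(truth)| / |cells(reported)|, in [0, 1]."""
    return _cell_overlap(reported, truth, mode) / _cluster_size(reported, mode)


def _overlap_matrix(reported, truth, mode: str) -> np.ndarray:
    """Pairwise cell overlaps, reported x truth, vectorized."""
    if not reported or not truth:
        return np.zeros((len(reported), len(truth)))
    rs = np.array([c.start for c in reported])
    re = np.array([c.end for c in reported])
    ts_ = np.array([c.start for c in truth])
    te = np.array([c.end for c in truth])
    span = np.clip(
        np.minimum(re[:, None], te[None, :]) - np.maximum(rs[:, None], ts_[None, :]),
        0,
        None,
    )
    if mode == "sites":
        return span.astype(float)
    all_members = sorted({m for c in reported for m in c.members}
                         | {m for c in truth for m in c.members})
    index = {m: i for i, m in enumerate(all_members)}
    R = np.zeros((len(reported), len(all_members)), dtype=np.int32)
    T = np.zeros((len(truth), len(all_members)), dtype=np.int32)
    for i, c in enumerate(reported):
        R[i, [index[m] for m in c.members]] = 1
    for i, c in enumerate(truth):
        T[i, [index[m] for m in c.members]] = 1
    shared = R @ T.T
    return (shared * span).astype(float)


def accuracy(reported, truth, mode: str = "cells") -> float:
    """Mean over reported clusters of the best truth overlap ratio."""
    if not reported:
        raise ValueError("accuracy is undefined for an empty reported list")
    ov = _overlap_matrix(reported, truth, mode)
    sizes = np.array([_cluster_size(c, mode) for c in reported], dtype=float)
    best = ov.max(axis=1) if ov.size else np.zeros(len(reported))
    return float(np.mean(best / sizes))


def power(reported, truth, mode: str = "cells") -> float:
    """Mean over truth clusters of the capped cumulative recovered fraction."""
    if not truth:
        raise ValueError("power is undefined for an empty truth list")
    ov = _overlap_matrix(reported, truth, mode)
    sizes = np.array([_cluster_size(c, mode) for c in truth], dtype=float)
    cum = ov.sum(axis=0) if ov.size else np.zeros(len(truth))
    return float(np.mean(np.minimum(1.0, cum / sizes)))
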