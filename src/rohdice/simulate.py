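"""Synthetic genotype panels: coalescent simulation and planted fixtures.

Two generators are provided.

``simulate_coalescent_panel`` draws a diploid panel from a coalescent model
of a European-ancestry founder population, using msprime for genealogies and
mutations and tskit for within-individual IBD segments (maximal genomic
intervals over which an individual's two haplotypes coalesce in the same
ancestral node — i.e. true runs of homozygosity by descent). ROH diplotype
*clusters* require many individuals to be autozygous for the same ancestral
haplotype at the same locus, which is characteristic of founder populations;
the default demography is therefore a small sustained isolate (see
:func:`european_founder_demography`) sampled against a European-scale
ancestral background. With the standard human mutation rate of 1.25e-8 per
bp per generation this yields roughly 2.4e4 sites at MAF >= 1% from 200
diploids over 10 Mbp.

``plant_clusters`` builds small panels with known, planted ROH diplotype
clusters on an independent-site background (~18% heterozygous cells), for
unit tests and calibration: the truth is exact by construction.
"""
# The default demography is a sustained founder isolate rather than a broad
# out-of-Africa model: broad European models produce essentially no shared
# autozygosity at the cluster widths this package targets, so an evaluation
# panel drawn from one would contain no ground truth to recover.

from __future__ import annotations

import math
from dataclasses import dataclass

import msprime
import numpy as np

from .panel import GenotypePanel, make_site_meta

__all__ = [
    "IBDSegment",
    "european_founder_demography",
    "simulate_coalescent_panel",
    "plant_clusters",
]

#: Standard human per-bp per-generation rates.
DEFAULT_MUTATION_RATE = 1.25e-8
DEFAULT_RECOMBINATION_RATE = 1e-8


@dataclass(frozen=True)
class IBDSegment:
    """A region where one individual's two haplotypes are IBD (an ROH).

    ``bp_start``/``bp_end`` are half-open 0-based genome coordinates.
    ``ancestor`` is the genealogical node in which the two haplotypes
    coalesce; segments sharing an ancestor descend from the same haplotype.
    """

    individual: int
    bp_start: int
    bp_end: int
    ancestor: int = -1

    def __post_init__(self):
        if self.bp_end <= self.bp_start:
            raise ValueError("bp_end must exceed bp_start")
        if self.individual < 0:
            raise ValueError("individual index must be non-negative")


def european_founder_demography(
    isolate_size: float = 30,
    isolate_duration: float = 50,
    ancestral_size: float = 40_000,
) -> msprime.Demography:
    """European-ancestry founder-isolate demography (single deme).

    A sustained, severe founder event: the sampled deme has held
    ``isolate_size`` diploids for the last ``isolate_duration`` generations,
    after splitting from a European-scale ancestral population of constant
    ``ancestral_size``. The sustained small epoch is what produces ROH
    diplotype clusters — many individuals autozygous for the same founder
    haplotype over long stretches — at the widths (tens to hundreds of
    carriers) this package targets; the large ancestral size maintains the
    pre-founding marker diversity of a European panel. Defaults give ~2.4e4
    sites at MAF >= 1% for 200 diploids over 10 Mbp at the standard human
    mutation rate.
    """
    demog = msprime.Demography()
    demog.add_population(name="EUR_ISOLATE", initial_size=isolate_size)
    demog.add_population_parameters_change(
        time=isolate_duration, initial_size=ancestral_size, growth_rate=0
    )
    return demog


def _derive_seeds(seed: int, n: int) -> list[int]:
    """n independent sub-seeds in [1, 2^31) derived from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31 - 2)) + 1 for s in state]


def simulate_coalescent_panel(
    n_diploid: int,
    length_bp: int = 10_000_000,
    error_rate: float = 0.0,
    seed: int = 1,
    maf_min: float = 0.01,
    mutation_rate: float = DEFAULT_MUTATION_RATE,
    recombination_rate: float = DEFAULT_RECOMBINATION_RATE,
    demography: msprime.Demography | None = None,
    min_ibd_span: float = 2_000,
):
    """Simulate a diploid genotype panel with within-individual IBD truth.

    Parameters
    ----------
    n_diploid
        Number of diploid individuals sampled from the founder deme.
    length_bp
        Simulated region length (one chromosome).
    error_rate
        Per-cell genotyping error probability; an erroneous cell is redrawn
        uniformly from the two other genotype states.
    seed
        Master seed; ancestry, mutations and errors use independent derived
        streams, so ``error_rate=0`` and ``error_rate>0`` runs share the same
        underlying panel.
    maf_min
        Sites with minor allele frequency below this are removed (default 1%).
    demography
        Override the default founder demography.
    min_ibd_span
        Shortest IBD segment reported, in bp; segments far below the site
        spacing times the shortest match length of interest cannot support a
        cluster.

    Returns
    -------
    (GenotypePanel, list[IBDSegment])
    """
    if n_diploid < 2:
        raise ValueError("n_diploid must be >= 2")
    if length_bp < 100_000:
        raise ValueError("length_bp must be >= 1e5")
    anc_seed, mut_seed, err_seed = _derive_seeds(seed, 3)
    if demography is None:
        demography = european_founder_demography()
    deme = demography.populations[0].name
    ts = msprime.sim_ancestry(
        samples={deme: n_diploid},
        demography=demography,
        sequence_length=length_bp,
        recombination_rate=recombination_rate,
        random_seed=anc_seed,
    )
    mts = msprime.sim_mutations(
        ts, rate=mutation_rate, random_seed=mut_seed,
        model=msprime.BinaryMutationModel(),
    )
    G = mts.genotype_matrix()  # sites x haplotypes, {0,1}
    geno = (G[:, ::2] + G[:, 1::2]).T.astype(np.int8)  # individuals x sites
    ac = geno.sum(axis=0, dtype=np.int64)
    n_alleles = 2 * n_diploid
    maf = np.minimum(ac, n_alleles - ac) / n_alleles
    keep = maf >= maf_min
    geno = geno[:, keep]
    positions = mts.sites_position[keep].astype(np.int64) + 1  # 1-based

    if error_rate > 0:
        rng = np.random.default_rng(err_seed)
        err = rng.random(geno.shape) < error_rate
        shift = rng.integers(1, 3, size=int(err.sum()), dtype=np.int8)
        geno[err] = (geno[err] + shift) % 3

    panel = GenotypePanel(
        values=geno,
        sample_ids=[f"ind{i}" for i in range(n_diploid)],
        site_meta=make_site_meta(positions, chrom="1"),
    )

    segments = []
    for i in range(n_diploid):
        res = ts.ibd_segments(
            within=[2 * i, 2 * i + 1], min_span=min_ibd_span, store_segments=True
        )
        for _, seg_list in res.items():
            for seg in seg_list:
                segments.append(
                    IBDSegment(
                        individual=i,
                        bp_start=int(seg.left),
                        bp_end=int(seg.right),
                        ancestor=int(seg.node),
                    )
                )
    segments.sort(key=lambda s: (s.individual, s.bp_start, s.ancestor))
    return panel, segments


def plant_clusters(
    M: int,
    N: int,
    cluster_specs,
    seed: int = 0,
    background_alt_freq: float = 0.1,
):
    """Panel with planted ROH diplotype clusters on a random background.

    ``cluster_specs`` is a list of ``(start, end, n_members, het_noise_rate)``
    tuples: each plants one shared homozygous diplotype over sites
    ``[start, end)`` into ``n_members`` randomly chosen individuals, then
    flips each planted cell to heterozygous with the given noise rate.

    Background genotypes are independent Hardy-Weinberg draws at alternative
    allele frequency ``background_alt_freq`` (0.1 gives the ~18% heterozygous
    cells typical of array data).

    Returns ``(GenotypePanel, list_of_truth)`` where each truth entry is a
    :class:`~rohdice.evaluate.GroundTruthCluster`.
    """
    from .evaluate import GroundTruthCluster

    rng = np.random.default_rng(seed)
    p = background_alt_freq
    probs = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    values = rng.choice(np.arange(3, dtype=np.int8), size=(M, N), p=probs)

    planted = np.full((M, N), -1, dtype=np.int8)  # what each cell was planted to
    truth = []
    for start, end, n_members, noise in cluster_specs:
        if not (0 <= start < end <= N):
            raise ValueError(f"span [{start}, {end}) outside [0, {N})")
        if n_members > M:
            raise ValueError("member count exceeds panel size")
        members = np.sort(rng.choice(M, size=n_members, replace=False))
        consensus = rng.integers(0, 2, size=end - start, dtype=np.int8) * 2
        prior = planted[np.ix_(members, np.arange(start, end))]
        clash = (prior >= 0) & (prior != consensus[np.newaxis, :])
        if clash.any():
            raise ValueError(
                "overlapping planted spans assign contradictory diplotypes"
            )
        values[np.ix_(members, np.arange(start, end))] = consensus
        planted[np.ix_(members, np.arange(start, end))] = consensus
        if noise > 0:
            flip = rng.random((n_members, end - start)) < noise
            block = values[np.ix_(members, np.arange(start, end))]
            block[flip] = 1
            values[np.ix_(members, np.arange(start, end))] = block
        truth.append(
            GroundTruthCluster(
                start=int(start),
                end=int(end),
                members=frozenset(int(m) for m in members),
                consensus="".join("01"[v // 2] for v in consensus),
            )
        )
    panel = GenotypePanel(
        values=values,
        sample_ids=[f"ind{i}" for i in range(M)],
        site_meta=make_site_meta(100 * np.arange(1, N + 1), chrom="1"),
    )
    return panel, truth
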