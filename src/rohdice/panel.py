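"""In-memory containers for diploid genotype panels and compressed binary panels.

A :class:`GenotypePanel` holds unphased biallelic genotypes coded as the count
of the alternative allele (0, 1, 2). A :class:`BinaryPanel` is the result of
collapsing a genotype panel onto the haplotype-like alphabet {0, 1}: homozygous
reference maps to 0, homozygous alternative to 1, and heterozygous cells are
assigned at random (recorded in ``het_mask``). Site metadata travels with both
containers as a :class:`pandas.DataFrame` with one row per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypePanel", "BinaryPanel", "make_site_meta"]

#: Required columns of the per-site metadata frame.
SITE_COLUMNS = ("chrom", "pos", "id")


def make_site_meta(positions, chrom="1", ids=None, cm=None) -> pd.DataFrame:
    """Build a site-metadata frame from 1-based bp positions.

    Parameters
    ----------
    positions
        Strictly increasing 1-based physical positions.
    chrom
        Chromosome label shared by all sites (panels are per-chromosome).
    ids
        Optional site identifiers; defaults to ``"site<i>"``.
    cm
        Optional genetic positions in centimorgans.
    """
    positions = np.asarray(positions, dtype=np.int64)
    n = positions.size
    meta = pd.DataFrame(
        {
            "chrom": [str(chrom)] * n,
            "pos": positions,
            "id": list(ids) if ids is not None else [f"site{i}" for i in range(n)],
        }
    )
    if cm is not None:
        meta["cm"] = np.asarray(cm, dtype=float)
    return meta


def _validate_sites(site_meta: pd.DataFrame, n_sites: int) -> None:
    if len(site_meta) != n_sites:
        raise ValueError(
            f"site_meta has {len(site_meta)} rows for {n_sites} sites"
        )
    for col in SITE_COLUMNS:
        if col not in site_meta.columns:
            raise ValueError(f"site_meta is missing required column {col!r}")
    for _, grp in site_meta.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError("bp positions must be strictly increasing per chromosome")


@dataclass
class GenotypePanel:
    """M individuals x N biallelic sites, values in {0, 1, 2}.

    ``values[i, j]`` counts the alternative allele of individual ``i`` at site
    ``j``. Sites are 0-indexed internally; 1-based bp coordinates live only in
    ``site_meta``.
    """

    values: np.ndarray
    sample_ids: list[str]
    site_meta: pd.DataFrame

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2 or self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("values must be a non-empty 2-D M x N matrix")
        bad = (self.values < 0) | (self.values > 2)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"genotype out of {{0,1,2}} at individual {i} (row {i}), site {j}"
            )
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length does not match number of rows")
        _validate_sites(self.site_meta, self.values.shape[1])

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    @property
    def positions(self) -> np.ndarray:
        """1-based bp positions, one per site."""
        return self.site_meta["pos"].to_numpy()


@dataclass
class BinaryPanel:
    """Compressed {0, 1} panel plus the mask of formerly heterozygous cells.

    For true haplotype data ``het_mask`` is all ``False``.
    """

    values: np.ndarray
    het_mask: np.ndarray = None
    sample_ids: list[str] = None
    site_meta: pd.DataFrame = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.ndim != 2 or self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("values must be a non-empty 2-D M x N matrix")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("binary panel cells must be 0 or 1")
        if self.het_mask is None:
            self.het_mask = np.zeros_like(self.values, dtype=bool)
        self.het_mask = np.asarray(self.het_mask, dtype=bool)
        if self.het_mask.shape != self.values.shape:
            raise ValueError("het_mask must have the same shape as values")
        if self.sample_ids is None:
            self.sample_ids = [f"sample{i}" for i in range(self.values.shape[0])]
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length does not match number of rows")
        if self.site_meta is None:
            self.site_meta = make_site_meta(np.arange(1, self.values.shape[1] + 1))
        _validate_sites(self.site_meta, self.values.shape[1])

    @property
    def n_sequences(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return self.site_meta["pos"].to_numpy()
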