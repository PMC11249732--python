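"""Positional Burrows-Wheeler transform (PBWT) core.

The PBWT maintains, site by site, the ordering of a binary panel's sequences
by their *reversed prefix* (columns k-1, k-2, ..., 0), together with a
divergence array giving, for each sorted position, the start of the longest
match to the preceding sequence in the sort. Sequences sharing a long suffix
ending at the current site are therefore adjacent, which is what makes
multi-sequence match-block enumeration a linear scan.

Conventions (fixed throughout the package):

* sites are 0-based, intervals half-open ``[start, end)``;
* ``d[0] = k`` is a sentinel (the top sequence has no predecessor);
* ties in reverse-prefix order are broken by original sequence index, so the
  transform is stable and deterministic.

``advance`` optionally takes a per-sequence ``missing`` mask for the column:
a missing cell matches nothing (not even another missing cell). This supports
panels in which heterozygous cells must be excluded from matching, as used
when deriving ground-truth clusters from IBD-painted interim panels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PBWTState", "init_state", "advance", "oracle_sort"]


@dataclass
class PBWTState:
    """PBWT arrays valid *before* site ``k``.

    Attributes
    ----------
    k
        Site index; ``a`` and ``d`` describe the sort by the reversed prefix
        ending just before column ``k``.
    a
        Positional prefix array: permutation of ``0..M-1``.
    d
        Divergence array: ``d[i]`` is the smallest ``s`` such that sequences
        ``a[i]`` and ``a[i-1]`` agree on columns ``[s, k)``; ``d[0] = k``.
    """

    k: int
    a: np.ndarray
    d: np.ndarray

    @property
    def n_sequences(self) -> int:
        return self.a.size


def init_state(M: int) -> PBWTState:
    """State before site 0: identity permutation, all-zero divergence."""
    if M < 1:
        raise ValueError(f"M must be >= 1, got {M}")
    return PBWTState(k=0, a=np.arange(M, dtype=np.int64), d=np.zeros(M, dtype=np.int64))


def _group_divergence(d: np.ndarray, idx: np.ndarray, k: int) -> np.ndarray:
    """Divergence values for one allele group after a stable split.

    ``idx`` holds the (sorted) positions of the group's members in the current
    sort. The new divergence of the group's first member is the sentinel
    ``k + 1``; for subsequent members it is the maximum of ``d`` over the
    half-open stretch of skipped-plus-own positions ``(idx[j-1], idx[j]]`` —
    the usual transitive-match argument: the match of two sequences separated
    in the sort starts where the worst intervening match starts.
    """
    out = np.empty(idx.size, dtype=d.dtype)
    if idx.size == 0:
        return out
    out[0] = k + 1
    if idx.size > 1:
        # np.maximum.reduceat over d[: idx[-1] + 1] with boundaries at
        # idx[:-1] + 1 yields exactly the per-segment maxima; segments are
        # never empty because idx is strictly increasing.
        out[1:] = np.maximum.reduceat(d[: idx[-1] + 1], idx[:-1] + 1)
    return out


def advance(state: PBWTState, column, missing=None) -> PBWTState:
    """Advance the PBWT by one site.

    Parameters
    ----------
    state
        State valid before site ``k``.
    column
        Length-M {0,1} vector of alleles at site ``k`` in *original* sequence
        order (not sort order).
    missing
        Optional length-M boolean vector; ``True`` cells match nothing at this
        column. Missing sequences are placed after the allele-1 group (stably)
        with sentinel divergence.

    Returns
    -------
    PBWTState
        New state valid before site ``k + 1``. Sequences with allele 0 at
        column ``k`` precede those with allele 1, each sub-list preserving
        prior order.
    """
    column = np.asarray(column)
    M = state.n_sequences
    if column.shape != (M,):
        raise ValueError(f"column has shape {column.shape}, expected ({M},)")
    k, a, d = state.k, state.a, state.d
    alle = column[a]
    if missing is None:
        miss = np.zeros(M, dtype=bool)
    else:
        missing = np.asarray(missing, dtype=bool)
        if missing.shape != (M,):
            raise ValueError(f"missing has shape {missing.shape}, expected ({M},)")
        miss = missing[a]

    idx0 = np.flatnonzero(~miss & (alle == 0))
    idx1 = np.flatnonzero(~miss & (alle != 0))
    idxm = np.flatnonzero(miss)

    new_a = np.concatenate([a[idx0], a[idx1], a[idxm]])
    d0 = _group_divergence(d, idx0, k)
    d1 = _group_divergence(d, idx1, k)
    # missing cells never match: divergence pinned to the sentinel
    dm = np.full(idxm.size, k + 1, dtype=d.dtype)
    new_d = np.concatenate([d0, d1, dm])
    return PBWTState(k=k + 1, a=new_a, d=new_d)


def oracle_sort(panel, k: int, missing=None):
    """Quadratic brute-force reverse-prefix sort — the normative reference.

    Sorts sequences by columns ``k-1, k-2, ..., 0`` (ties by original index)
    and recomputes divergences from first principles. Accepts a
    :class:`~rohdice.panel.BinaryPanel` or a plain 2-D {0,1} array. With a
    ``missing`` mask (same shape), missing cells sort after both alleles and
    never agree with anything, mirroring :func:`advance`.

    Returns ``(a, d)``.
    """
    values = np.asarray(getattr(panel, "values", panel))
    M, N = values.shape
    if not (0 <= k <= N):
        raise ValueError(f"k={k} out of range for panel with {N} sites")
    if missing is None:
        missing = np.zeros_like(values, dtype=bool)
    else:
        missing = np.asarray(missing, dtype=bool)
    # missing cells get the largest symbol so the group order matches advance
    sym = np.where(missing, 2, values)

    def key(i):
        return tuple(sym[i, k - 1 :: -1]) if k > 0 else ()

    a = sorted(range(M), key=lambda i: (key(i), i))

    def agree(i, j, col):
        return (
            not missing[i, col]
            and not missing[j, col]
            and values[i, col] == values[j, col]
        )

    d = np.zeros(M, dtype=np.int64)
    d[0] = k
    for pos in range(1, M):
        i, j = a[pos], a[pos - 1]
        s = k
        while s > 0 and agree(i, j, s - 1):
            s -= 1
        d[pos] = s
    return np.asarray(a, dtype=np.int64), d
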